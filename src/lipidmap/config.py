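"""Run configuration: YAML schema, validation and defaults.

A run takes exactly one of two input modes: ``synthetic`` (build the
membrane + pentamer and simulate the toy dynamics) or ``inputs`` (read
user-supplied coordinate/trajectory files).  Analysis defaults follow the
standard protocol: 0.6 nm contact cutoff, last half of the run at 10 ns
frame spacing.  Unknown keys are rejected with every offending key named.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, ValidationError, model_validator

from .exceptions import ConfigError


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class WindowConfig(_Strict):
    last_fraction: float = 0.5
    stride_dt_ns: float = 10.0


class TruthSiteConfig(_Strict):
    name: str
    leaflet: str
    selectivity: str
    well_depth_kt: float
    width_nm: float
    radius_nm: float
    angle_deg: float | None = None
    wedge: int | None = None
    available_in: list[str] = ["inactive", "active"]


class SyntheticConfig(_Strict):
    nominal_per_leaflet: int = 150
    box_a_nm: float = 11.0
    box_c_nm: float = 6.0
    n_frames: int = 200
    step_dt_ns: float = 0.5
    frame_dt_ns: float = 10.0
    flipflop_rate_per_ns: float = 1e-4
    diffusion_nm2_per_ns: dict[str, float] = {}
    protein_core_radius_nm: float = 1.4
    sites: list[TruthSiteConfig] = []


class InputsConfig(_Strict):
    coordinates: str
    trajectory: str | None = None
    naming_config: str | None = None


class LigandSiteConfig(_Strict):
    name: str | None = None
    pdb: str | None = None
    ligand: str | None = None
    radius_nm: float = 0.7
    wedge: int | None = None
    wedge_half_width_deg: float = 25.0
    leaflet: str = "extracellular"

    @model_validator(mode="after")
    def _one_kind(self):
        if (self.pdb is None) == (self.wedge is None):
            raise ValueError("site needs exactly one of (pdb + ligand) or wedge")
        if self.pdb is not None and self.ligand is None:
            raise ValueError("pdb site needs a ligand residue name")
        return self


class RunConfig(_Strict):
    synthetic: SyntheticConfig | None = None
    inputs: InputsConfig | None = None
    state: str = "inactive"
    window: WindowConfig = WindowConfig()
    cutoff_nm: float = 0.6
    bin2d_nm: float = 0.2
    voxel3d_nm: float = 0.1
    repeats: int = 1
    sites: list[LigandSiteConfig] = []
    outdir: str = "results"
    seed: int = 0

    @model_validator(mode="after")
    def _exactly_one_input(self):
        if (self.synthetic is None) == (self.inputs is None):
            raise ValueError("exactly one of 'synthetic' or 'inputs' required")
        return self


def validate_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Raises :class:`ConfigError` listing every offending key on schema
    violations, and on referenced files that do not exist.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    try:
        cfg = RunConfig.model_validate(data)
    except ValidationError as exc:
        keys = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            keys.append(f"{loc}: {err['msg']}")
        raise ConfigError(
            "invalid run configuration:\n  " + "\n  ".join(keys), keys=keys
        ) from exc
    missing = []
    if cfg.inputs is not None:
        for p in (cfg.inputs.coordinates, cfg.inputs.trajectory,
                  cfg.inputs.naming_config):
            if p is not None and not Path(p).exists():
                missing.append(p)
    for s in cfg.sites:
        if s.pdb is not None and not Path(s.pdb).exists():
            missing.append(s.pdb)
    if missing:
        raise ConfigError(f"referenced files do not exist: {missing}", keys=missing)
    return cfg
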