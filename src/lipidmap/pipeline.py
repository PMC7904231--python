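"""Pipeline orchestration: synthesize -> simulate -> window -> densities ->
contacts -> sites -> report, re-runnable per stage from on-disk intermediates.

Every stage writes its outputs under the configured output directory and the
final manifest records software version, seed and a hash of the resolved
configuration; identical configuration + seed give identical numeric
outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import RunConfig
from .contacts import contact_series, contact_table, lipid_hierarchy
from .density import (
    assign_leaflets,
    average_grids,
    density2d,
    density3d,
    export_density,
    symmetry_report,
)
from .dynamics import PlantedSite, SyntheticTruth, simulate, site_positions
from .dynamics import truth_from_yaml, truth_to_yaml
from .exceptions import EmptySelectionError, LipidmapError
from .membrane import LEAFLETS, MembraneSpec, PentamerModel, build_membrane
from .sites import (
    SiteDefinition,
    interface_penetration,
    load_site_from_structure,
    site_enrichment,
)
from .trajio import (
    AnalysisWindow,
    NamingConfig,
    read_system,
    select_window,
    write_system,
)

logger = logging.getLogger(__name__)

LIPID_TYPES = ("POPC", "POPE", "DOPS", "SM", "CHOL")


def _outdir(config: RunConfig) -> Path:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.model_dump(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _truth_from_config(config: RunConfig) -> SyntheticTruth:
    syn = config.synthetic
    sites = [PlantedSite(
        name=s.name, leaflet=s.leaflet, selectivity=s.selectivity,
        well_depth=s.well_depth_kt, width=s.width_nm, radius=s.radius_nm,
        angle_deg=s.angle_deg, wedge=s.wedge,
        available_in=frozenset(s.available_in)) for s in syn.sites]
    return SyntheticTruth(
        sites=sites, diffusion=dict(syn.diffusion_nm2_per_ns),
        flipflop_rate=syn.flipflop_rate_per_ns, state=config.state,
        protein_core_radius=syn.protein_core_radius_nm)


def _repeat_seeds(config: RunConfig) -> list[int]:
    return [config.seed + r for r in range(config.repeats)]


def stage_synthesize(config: RunConfig) -> list[Path]:
    """Build per-repeat membranes; write GRO coordinates + planted truth YAML."""
    if config.synthetic is None:
        raise LipidmapError("synthesize stage requires a synthetic config")
    out = _outdir(config)
    syn = config.synthetic
    spec = MembraneSpec(nominal_per_leaflet=syn.nominal_per_leaflet)
    pent = PentamerModel.make()
    paths = []
    for seed in _repeat_seeds(config):
        top, init = build_membrane(spec, pent, (syn.box_a_nm, syn.box_c_nm),
                                   seed=seed)
        gro = out / f"system_rep{seed}.gro"
        write_system(top, init, gro)
        paths.append(gro)
    truth_to_yaml(_truth_from_config(config), out / "truth.yaml")
    return paths


def stage_simulate(config: RunConfig) -> list[Path]:
    """Run the toy dynamics for every repeat; write XTC trajectories."""
    out = _outdir(config)
    truth = truth_from_yaml(out / "truth.yaml")
    syn = config.synthetic
    paths = []
    for seed in _repeat_seeds(config):
        gro = out / f"system_rep{seed}.gro"
        top, init = read_system(gro)
        write_every = max(1, int(round(syn.frame_dt_ns / syn.step_dt_ns)))
        traj = simulate(top, init, truth, n_steps=syn.n_frames * write_every,
                        step_dt=syn.step_dt_ns, write_every=write_every,
                        seed=seed)
        xtc = out / f"traj_rep{seed}.xtc"
        write_system(top, traj, out / f"frame0_rep{seed}.gro", xtc)
        paths.append(xtc)
    return paths


def _load_repeat(config: RunConfig, seed: int):
    out = _outdir(config)
    naming = None
    if config.inputs is not None and config.inputs.naming_config:
        naming = NamingConfig.from_yaml(config.inputs.naming_config)
    if config.inputs is not None:
        top, traj = read_system(config.inputs.coordinates,
                                config.inputs.trajectory, naming)
    else:
        top, traj = read_system(out / f"system_rep{seed}.gro",
                                out / f"traj_rep{seed}.xtc")
        traj.metadata.update(_synthetic_metadata(config, top, traj))
    window = AnalysisWindow(config.window.last_fraction,
                            config.window.stride_dt_ns)
    return top, select_window(traj, window)


def _synthetic_metadata(config: RunConfig, top, traj) -> dict:
    prot = top.protein_mask
    meta = {"state": config.state, "box": traj.box[0].tolist()}
    if prot.any():
        axis = traj.coords[0, prot, :2].mean(axis=0)
        meta["axis_xy"] = axis.tolist()
        meta["footprint_radius_nm"] = float(
            np.linalg.norm(traj.coords[0, prot, :2] - axis, axis=1).max())
    return meta


def stage_densities(config: RunConfig) -> dict:
    """Per-leaflet 2D maps and 3D grids per lipid type; C5 symmetry report."""
    out = _outdir(config)
    grids2d: dict = {}
    grids3d: dict = {}
    for seed in _repeat_seeds(config):
        top, win = _load_repeat(config, seed)
        assignment = assign_leaflets(win, top)
        present = sorted(set(top.lipid_types[top.lipid_mask]))
        for lt in present:
            for leaflet in LEAFLETS:
                try:
                    g = density2d(win, top, assignment, lt, leaflet,
                                  config.bin2d_nm)
                except EmptySelectionError:
                    logger.info("skipping empty selection %s/%s", lt, leaflet)
                    continue
                grids2d.setdefault((lt, leaflet), []).append(g)
            grids3d.setdefault(lt, []).append(
                density3d(win, top, lt, "any", config.voxel3d_nm))
    written = []
    for (lt, leaflet), gs in grids2d.items():
        avg = average_grids(gs)
        path = out / f"density2d_{lt}_{leaflet}_{config.state}.csv"
        export_density(avg, path)
        written.append(str(path))
    for lt, gs in grids3d.items():
        avg = average_grids(gs)
        path = out / f"density3d_{lt}_{config.state}.dx"
        export_density(avg, path)
        written.append(str(path))
    sym = None
    key = ("CHOL", "extracellular")
    if key in grids2d and len(grids2d[key]) > 1:
        rep = symmetry_report(grids2d[key])
        sym = {"per_repeat": rep.per_repeat,
               "repeat_average": rep.repeat_average,
               "median_single": rep.median_single}
        pd.DataFrame({"repeat": _repeat_seeds(config),
                      "c5_deviation": rep.per_repeat}).to_csv(
            out / f"symmetry_{config.state}.csv", index=False)
    return {"files": written, "symmetry": sym}


def stage_contacts(config: RunConfig) -> dict:
    """Contact-duration table over all repeats, plus the lipid hierarchy."""
    out = _outdir(config)
    series = []
    for seed in _repeat_seeds(config):
        top, win = _load_repeat(config, seed)
        series.append(contact_series(win, top, cutoff=config.cutoff_nm))
    table = contact_table(series, collapse_subunits=True)
    table.to_csv(out / f"contacts_{config.state}.csv")
    rows = []
    for stat in ("max", "mean-top-20"):
        order, ties = lipid_hierarchy(table, stat)
        rows.append({"statistic": stat, "order": ">".join(order), "ties": ties})
    pd.DataFrame(rows).to_csv(out / f"hierarchy_{config.state}.csv", index=False)
    return {"table": str(out / f"contacts_{config.state}.csv"),
            "hierarchy": rows}


def stage_sites(config: RunConfig) -> dict:
    """Site enrichment / interface penetration for the configured sites."""
    out = _outdir(config)
    if not config.sites:
        return {"reports": []}
    reports = []
    for seed in _repeat_seeds(config)[:1]:
        top, win = _load_repeat(config, seed)
        grid = density3d(win, top, "CHOL", "hydroxyl", config.voxel3d_nm)
        meta = grid.metadata
        axis_xy = meta.get("axis_xy")
        angles = 90.0 + 36.0 + 72.0 * np.arange(5)
        for sc in config.sites:
            if sc.pdb is not None:
                defs = load_site_from_structure(sc.pdb, sc.ligand, sc.radius_nm)
            else:
                z0 = win.coords[0, top.lipid_mask, 2].mean()
                slab = (z0 - 2.5, z0 + 2.5)
                defs = [SiteDefinition(
                    name=sc.name or f"wedge{sc.wedge}", radius=sc.radius_nm,
                    wedge=(sc.wedge, sc.wedge_half_width_deg, sc.leaflet))]
            for site in defs:
                kw = {}
                if site.wedge is not None:
                    kw = {"interface_angles_deg": angles, "slab": slab}
                rep = site_enrichment(grid, site, axis_xy=axis_xy, **kw)
                reports.append(rep.as_row())
        if meta.get("footprint_radius_nm"):
            pen = interface_penetration(
                grid, axis_xy, angles, 25.0,
                threshold=max(1e-9, 0.25 * float(grid.values.max())))
            pen.to_csv(out / f"penetration_{config.state}.csv", index=False)
    df = pd.DataFrame(reports)
    df.to_csv(out / f"sites_{config.state}.csv", index=False)
    return {"reports": reports}


def stage_report(config: RunConfig, results: dict) -> Path:
    out = _outdir(config)
    manifest = {"version": __version__, "seed": config.seed,
                "config_hash": config_hash(config),
                "state": config.state,
                "generated": time.strftime("%Y-%m-%d %H:%M:%S"),
                "results": results}
    path = out / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return path


def run_pipeline(config: RunConfig) -> dict:
    """Execute all requested stages; abort with the failing stage's name."""
    results: dict = {}
    stages = []
    if config.synthetic is not None:
        stages += [
            ("synthesize", lambda: [str(p) for p in stage_synthesize(config)]),
            ("simulate", lambda: [str(p) for p in stage_simulate(config)]),
        ]
    stages += [("densities", lambda: stage_densities(config)),
               ("contacts", lambda: stage_contacts(config)),
               ("sites", lambda: stage_sites(config))]
    for name, fn in stages:
        t0 = time.time()
        try:
            results[name] = fn()
        except Exception as exc:
            results[name] = f"FAILED: {exc}"
            stage_report(config, results)
            raise LipidmapError(f"stage {name!r} failed: {exc}") from exc
        logger.info("stage %s done in %.1fs", name, time.time() - t0)
    results["manifest"] = str(stage_report(config, results))
    return results
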