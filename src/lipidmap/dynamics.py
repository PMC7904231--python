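"""Toy lipid dynamics with planted, state-dependent binding sites.

Lipids undergo overdamped (Brownian) lateral diffusion in the membrane plane
within a potential composed of attractive Gaussian wells ("planted sites"),
each restricted to one lipid type, one leaflet and a set of conformational
states.  Energies are in kT units at an implicit single temperature, so the
position update is

    x(t+dt) = x(t) + D F(x) dt + sqrt(2 D dt) xi,   F = -grad U,
    U(x) = - sum_s depth_s exp(-|x - x_s|^2 / (2 width_s^2)),

with a hard reflective disc of radius ``protein_core_radius`` around the
pore axis standing in for the protein's excluded volume, and hexagonal
periodic wrapping.  Cholesterol additionally flips between leaflets as a
Poisson process (instantaneous z teleport); all other lipids keep their
leaflet.  Protein beads never move.

Randomness is organised as one counter-based (Philox) stream per molecule,
keyed by ``(seed, molecule id)``, so changing the molecule count does not
reshuffle the noise of unrelated molecules.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import BudgetExceededError, InvalidSpecError, StabilityError
from .trajio import Topology, Trajectory, box_center, nearest_image_shift_2d

STATES = ("inactive", "active")
DEFAULT_DIFFUSION = 0.01  # nm^2/ns, order of Martini lipid lateral diffusion


@dataclass(frozen=True)
class PlantedSite:
    """An attractive Gaussian well for one lipid type in one leaflet.

    Anchored either at an explicit polar position about the pore axis
    (``angle_deg`` set) or at a subunit interface (``wedge`` set, index 0-4).
    Wedge-anchored sites are replicated five-fold under the C5 symmetry of
    the pentamer; the index only selects the canonical copy for reporting.
    """

    name: str
    leaflet: str
    selectivity: str                 # lipid type
    well_depth: float                # kT
    width: float                     # nm
    radius: float                    # nm, radial distance from the pore axis
    angle_deg: float | None = None
    wedge: int | None = None
    available_in: frozenset = frozenset(STATES)

    def __post_init__(self):
        if self.well_depth < 0:
            raise InvalidSpecError("well_depth must be >= 0")
        if self.width <= 0:
            raise InvalidSpecError("width must be > 0")
        if (self.angle_deg is None) == (self.wedge is None):
            raise InvalidSpecError("exactly one of angle_deg / wedge required")
        if self.wedge is not None and not (0 <= self.wedge <= 4):
            raise InvalidSpecError("wedge index must be 0-4")
        if not set(self.available_in) <= set(STATES):
            raise InvalidSpecError(f"unknown states in available_in: {self.available_in}")


@dataclass
class SyntheticTruth:
    """Planted ground truth of a synthetic run."""

    sites: list = field(default_factory=list)
    diffusion: dict = field(default_factory=dict)   # lipid type -> nm^2/ns
    flipflop_rate: float = 0.0                      # events/ns per CHOL molecule
    state: str = "inactive"
    protein_core_radius: float = 1.4                # nm, hard reflective disc
    subunit_phase_deg: float = 90.0
    leaflet_z: dict = field(default_factory=lambda: {"extracellular": 1.8,
                                                     "intracellular": -1.8})

    def __post_init__(self):
        if self.state not in STATES:
            raise InvalidSpecError(f"unknown state {self.state!r}")
        if not (math.isfinite(self.flipflop_rate) and self.flipflop_rate >= 0):
            raise InvalidSpecError("flipflop_rate must be finite and >= 0")
        for t, d in self.diffusion.items():
            if not (math.isfinite(d) and d >= 0):
                raise InvalidSpecError(f"diffusion coefficient for {t} invalid: {d}")

    def diffusion_of(self, lipid_type: str) -> float:
        return self.diffusion.get(lipid_type, DEFAULT_DIFFUSION)

    def active_sites(self) -> list:
        return [s for s in self.sites if self.state in s.available_in]

    def interface_angles_deg(self) -> np.ndarray:
        """Angles of the five subunit-interface wedges about the pore axis."""
        return self.subunit_phase_deg + 36.0 + 72.0 * np.arange(5)


def concrete_sites(truth: SyntheticTruth, axis_xy: np.ndarray
                   ) -> list[tuple[PlantedSite, np.ndarray]]:
    """Expand planted sites to concrete in-plane positions.

    Wedge-anchored sites produce five copies (one per interface) so the
    planted truth is exactly C5-symmetric.
    """
    out = []
    for site in truth.active_sites():
        if site.angle_deg is not None:
            angles = [site.angle_deg]
        else:
            angles = list(truth.interface_angles_deg())
        for ang in angles:
            th = math.radians(ang)
            xy = axis_xy + site.radius * np.array([math.cos(th), math.sin(th)])
            out.append((site, xy))
    return out


def site_positions(truth: SyntheticTruth, axis_xy: np.ndarray) -> dict[str, np.ndarray]:
    """Concrete positions grouped by site name (n_copies x 2)."""
    groups: dict[str, list] = {}
    for site, xy in concrete_sites(truth, axis_xy):
        groups.setdefault(site.name, []).append(xy)
    return {k: np.array(v) for k, v in groups.items()}


def _per_molecule_generators(seed: int, mol_ids: np.ndarray) -> list:
    return [np.random.Generator(np.random.Philox(key=np.array(
        [seed & 0xFFFFFFFFFFFFFFFF, int(m)], dtype=np.uint64)))
        for m in mol_ids]


def simulate(topology: Topology, init: Trajectory, truth: SyntheticTruth,
             n_steps: int, step_dt: float, write_every: int, seed: int
             ) -> Trajectory:
    """Run the toy dynamics and return frames every ``write_every`` steps.

    Frames are written at steps ``write_every, 2*write_every, ...`` with
    times ``k * write_every * step_dt`` (ns).  The protein is static; the
    per-frame box is constant.  Bit-identical for identical inputs and seed.
    """
    if step_dt <= 0 or n_steps < 0 or write_every <= 0:
        raise InvalidSpecError("n_steps >= 0, step_dt > 0, write_every > 0 required")
    coords0 = init.coords[0].copy()
    box = init.box[0]
    inplane = box[:2, :2]
    inv_inplane = np.linalg.inv(inplane)
    center = box_center(box)
    mid_z = center[2]

    mols, anchor_idx = topology.anchor_indices()
    n_mol = len(mols)
    type_of = topology.lipid_type_of_molecule()
    mol_types = np.array([type_of[m] for m in mols])
    d_coef = np.array([truth.diffusion_of(t) for t in mol_types])
    dt = float(step_dt)

    prot = topology.protein_mask
    if prot.any():
        axis_xy = coords0[prot, :2].mean(axis=0)
        core_r = truth.protein_core_radius
    else:
        axis_xy = center[:2].copy()
        core_r = 0.0

    sites = concrete_sites(truth, axis_xy)
    leaflet_label = {"extracellular": 0, "intracellular": 1}
    for site, _ in sites:
        d = truth.diffusion_of(site.selectivity)
        if math.sqrt(4.0 * d * dt) > 0.5 * site.width:
            raise StabilityError(
                f"RMS step {math.sqrt(4 * d * dt):.3g} nm exceeds half the width "
                f"of site {site.name!r} ({site.width} nm); reduce step_dt")

    # per-molecule state
    xy = coords0[anchor_idx, :2].copy()
    z = coords0[anchor_idx, 2].copy()
    leaflet = (z <= mid_z).astype(np.int8)          # 0 = extracellular
    sign = np.ones(n_mol)

    # per-bead offsets from the molecule anchor
    lipid_bead_idx = np.flatnonzero(topology.lipid_mask)
    mol_pos_of = {m: i for i, m in enumerate(mols)}
    bead_mol = np.array([mol_pos_of[m] for m in topology.mol_ids[lipid_bead_idx]])
    dxy_beads = coords0[lipid_bead_idx, :2] - xy[bead_mol]
    dz_beads = coords0[lipid_bead_idx, 2] - z[bead_mol]

    # site target masks (leaflet of CHOL can change; recompute cheaply)
    site_data = []
    for site, sxy in sites:
        site_data.append((mol_types == site.selectivity,
                          leaflet_label[site.leaflet],
                          sxy, site.well_depth, site.width ** 2))

    sqrt_term = np.sqrt(2.0 * d_coef * dt)
    chol = np.flatnonzero(mol_types == "CHOL")
    lam_dt = truth.flipflop_rate * dt
    gens = _per_molecule_generators(seed, mols)

    n_frames = n_steps // write_every
    frames = np.empty((n_frames, topology.n_beads, 3))
    times = (np.arange(1, n_frames + 1) * write_every * dt)
    n_flips = 0
    frame_i = 0

    chunk = 4096
    step = 0
    lz = truth.leaflet_z
    while step < n_steps:
        this = min(chunk, n_steps - step)
        noise = np.empty((n_mol, this, 2))
        for i, g in enumerate(gens):
            noise[i] = g.standard_normal((this, 2))
        if len(chol) and lam_dt > 0:
            flip_u = np.empty((len(chol), this))
            for j, i in enumerate(chol):
                flip_u[j] = gens[i].random(this)
        for k in range(this):
            force = np.zeros((n_mol, 2))
            for tmask, lf, sxy, depth, w2 in site_data:
                if depth == 0.0:
                    continue
                mask = tmask & (leaflet == lf)
                if not mask.any():
                    continue
                d = nearest_image_shift_2d(xy[mask] - sxy, box)
                r2 = np.einsum("ij,ij->i", d, d)
                g = depth * np.exp(-r2 / (2.0 * w2)) / w2
                force[mask] -= g[:, None] * d
            xy += d_coef[:, None] * force * dt + sqrt_term[:, None] * noise[:, k, :]
            if core_r > 0.0:
                d_ax = nearest_image_shift_2d(xy - axis_xy, box)
                r = np.sqrt(np.einsum("ij,ij->i", d_ax, d_ax))
                inside = r < core_r
                if inside.any():
                    rr = np.maximum(r[inside], 1e-12)
                    scale = (2.0 * core_r - rr) / rr
                    xy[inside] = xy[inside] + d_ax[inside] * (scale - 1.0)[:, None]
            # wrap into the primitive cell
            frac = xy @ inv_inplane
            frac -= np.floor(frac)
            xy = frac @ inplane
            if len(chol) and lam_dt > 0:
                flips = np.flatnonzero(flip_u[:, k] < lam_dt)
                if len(flips):
                    idx = chol[flips]
                    leaflet[idx] ^= 1
                    sign[idx] *= -1.0
                    z[idx] = mid_z + np.where(leaflet[idx] == 0,
                                              lz["extracellular"], lz["intracellular"])
                    n_flips += len(flips)
            step += 1
            if step % write_every == 0:
                frames[frame_i] = coords0
                frames[frame_i, lipid_bead_idx, 0] = xy[bead_mol, 0] + dxy_beads[:, 0]
                frames[frame_i, lipid_bead_idx, 1] = xy[bead_mol, 1] + dxy_beads[:, 1]
                frames[frame_i, lipid_bead_idx, 2] = z[bead_mol] + sign[bead_mol] * dz_beads
                frame_i += 1

    out = Trajectory(times=times, coords=frames,
                     box=np.repeat(box[None, :, :], n_frames, axis=0),
                     metadata={"state": truth.state, "seed": int(seed),
                               "n_flips": int(n_flips), "box": box.tolist(),
                               "step_dt_ns": dt, "write_every": int(write_every),
                               "axis_xy": axis_xy.tolist(),
                               "footprint_radius_nm": float(
                                   np.linalg.norm(coords0[prot, :2] - axis_xy,
                                                  axis=1).max()) if prot.any() else 0.0})
    out.validate(topology.n_beads)
    return out


def truth_residence_oracle(truth: SyntheticTruth, site: PlantedSite,
                           n_samples: int = 200, seed: int = 0,
                           dt: float | None = None,
                           max_steps: int = 500_000) -> tuple[float, float]:
    """Monte-Carlo mean first-passage time out of a planted site (ns).

    A single lipid starts at the site anchor and diffuses in the isolated
    site's potential until it first leaves the exit radius 2 x width; exit
    times are averaged over ``n_samples`` independent walkers.  Returns
    ``(mean, standard error)``.  Raises :class:`BudgetExceededError`
    (carrying the partial estimate) if any walker survives ``max_steps``.
    """
    if n_samples < 100:
        raise InvalidSpecError("n_samples must be >= 100")
    d_coef = truth.diffusion_of(site.selectivity)
    if d_coef <= 0:
        raise InvalidSpecError("diffusion coefficient must be positive")
    w = site.width
    if dt is None:
        dt = (w / 8.0) ** 2 / (4.0 * d_coef)
    rng = np.random.default_rng(seed)
    pos = np.zeros((n_samples, 2))
    exit_time = np.full(n_samples, np.nan)
    alive = np.ones(n_samples, dtype=bool)
    w2 = w * w
    exit_r2 = (2.0 * w) ** 2
    sqrt_term = math.sqrt(2.0 * d_coef * dt)
    for step in range(1, max_steps + 1):
        idx = np.flatnonzero(alive)
        if len(idx) == 0:
            break
        p = pos[idx]
        r2 = np.einsum("ij,ij->i", p, p)
        g = site.well_depth * np.exp(-r2 / (2.0 * w2)) / w2
        p = p + d_coef * (-g[:, None] * p) * dt \
            + sqrt_term * rng.standard_normal((len(idx), 2))
        pos[idx] = p
        out = np.einsum("ij,ij->i", p, p) > exit_r2
        if out.any():
            exited = idx[out]
            exit_time[exited] = step * dt
            alive[exited] = False
    if alive.any():
        t = np.where(alive, max_steps * dt, exit_time)
        raise BudgetExceededError(
            f"{alive.sum()} of {n_samples} walkers still bound after "
            f"{max_steps} steps", partial_mean=float(np.mean(t)),
            partial_sem=float(np.std(t, ddof=1) / math.sqrt(n_samples)),
            n_done=int((~alive).sum()))
    mean = float(np.mean(exit_time))
    sem = float(np.std(exit_time, ddof=1) / math.sqrt(n_samples))
    return mean, sem


# ---------------------------------------------------------------------------
# YAML round trip of the planted truth

def truth_to_yaml(truth: SyntheticTruth, path: str | Path) -> None:
    data = {
        "state": truth.state,
        "flipflop_rate_per_ns": truth.flipflop_rate,
        "diffusion_nm2_per_ns": dict(truth.diffusion),
        "protein_core_radius_nm": truth.protein_core_radius,
        "subunit_phase_deg": truth.subunit_phase_deg,
        "leaflet_z_nm": dict(truth.leaflet_z),
        "sites": [{
            "name": s.name, "leaflet": s.leaflet, "selectivity": s.selectivity,
            "well_depth_kt": s.well_depth, "width_nm": s.width,
            "radius_nm": s.radius, "angle_deg": s.angle_deg, "wedge": s.wedge,
            "available_in": sorted(s.available_in),
        } for s in truth.sites],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def truth_from_yaml(path: str | Path) -> SyntheticTruth:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    sites = [PlantedSite(
        name=s["name"], leaflet=s["leaflet"], selectivity=s["selectivity"],
        well_depth=s["well_depth_kt"], width=s["width_nm"], radius=s["radius_nm"],
        angle_deg=s.get("angle_deg"), wedge=s.get("wedge"),
        available_in=frozenset(s["available_in"])) for s in data.get("sites", [])]
    return SyntheticTruth(
        sites=sites, diffusion=data.get("diffusion_nm2_per_ns", {}),
        flipflop_rate=data.get("flipflop_rate_per_ns", 0.0),
        state=data.get("state", "inactive"),
        protein_core_radius=data.get("protein_core_radius_nm", 1.4),
        subunit_phase_deg=data.get("subunit_phase_deg", 90.0),
        leaflet_z=data.get("leaflet_z_nm", {"extracellular": 1.8,
                                            "intracellular": -1.8}))
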