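"""Reference synthetic-study scenarios with planted ground truth.

These functions define the package's standard validation conditions: an
asymmetric five-lipid neuronal membrane around a static C5 pentamer,
simulated with the toy dynamics, then analyzed by the density/contact/site
stages.  Problem sizes (150 lipids per leaflet, ~10^5 lipid-frames per run,
10 ns frame spacing, analysis on the last half of each run) are chosen so
each scenario runs in seconds to a few minutes on one CPU while leaving the
planted effects well resolved.  Both the test-suite and the acceptance
script drive these scenarios; their parameters are the study conditions and
are not tuned per run.
"""

from __future__ import annotations

import numpy as np

from . import density as dens
from . import sites as sites_mod
from .contacts import contact_series, contact_table, lipid_hierarchy
from .dynamics import PlantedSite, SyntheticTruth, simulate, site_positions
from .membrane import MembraneSpec, PentamerModel, build_membrane
from .oracles import brute_force_contact_series, brute_force_durations
from .trajio import AnalysisWindow, Trajectory, hexagonal_box, select_window

BOX_A, BOX_C = 11.0, 6.0           # nm, hexagonal prism cell
FRAME_DT_NS = 10.0                 # trajectory frame spacing
STEP_DT_NS = 0.5                   # integration step when sites are present
DIFFUSION = 0.005                  # nm^2/ns for every lipid type
CORE_RADIUS = 1.4                  # nm, reflective protein core
WINDOW = AnalysisWindow(last_fraction=0.5, stride_dt=FRAME_DT_NS)

#: planted well depths (kT) of the lipid-hierarchy scenario
HIERARCHY_DEPTHS = {"CHOL": 6.0, "DOPS": 4.0, "POPC": 1.0, "POPE": 1.0, "SM": 1.0}
_HIER_GEOMETRY = {
    # lipid type -> (leaflet, angle about the pore axis, deg); each angle is
    # one subunit's lipid-facing outer helix so the site hugs that helix
    "CHOL": ("extracellular", 18.0),
    "POPC": ("extracellular", 90.0),
    "SM": ("extracellular", 162.0),
    "DOPS": ("intracellular", 234.0),
    "POPE": ("intracellular", 306.0),
}


def neuronal_spec(nominal: int = 150) -> MembraneSpec:
    return MembraneSpec(nominal_per_leaflet=nominal)


def default_pentamer() -> PentamerModel:
    return PentamerModel.make()


def _base_truth(state: str, sites: list) -> SyntheticTruth:
    return SyntheticTruth(
        sites=sites, diffusion={t: DIFFUSION for t in HIERARCHY_DEPTHS},
        flipflop_rate=1e-4, state=state, protein_core_radius=CORE_RADIUS)


def hierarchy_truth(state: str = "inactive") -> SyntheticTruth:
    """Annular binding sites of graded depth: CHOL 6 kT > PS 4 kT > rest 1 kT.

    Each lipid type's site is replicated five-fold (one copy per subunit's
    lipid-facing outer helix) so the planted truth is C5-symmetric, matching
    the five-subunit averaging of the contact statistics.
    """
    sites = []
    for lt, depth in HIERARCHY_DEPTHS.items():
        leaflet, angle = _HIER_GEOMETRY[lt]
        for k in range(5):
            sites.append(PlantedSite(
                name=f"{lt.lower()}-annular-{k}", leaflet=leaflet,
                selectivity=lt, well_depth=depth, width=0.25, radius=2.45,
                angle_deg=angle + 72.0 * k))
    return _base_truth(state, sites)


def state_truth(state: str) -> SyntheticTruth:
    """A single interface CHOL site, available only in the active state."""
    site = PlantedSite(
        name="interface-chol", leaflet="extracellular", selectivity="CHOL",
        well_depth=6.0, width=0.35, radius=1.8, wedge=0,
        available_in=frozenset({"active"}))
    return _base_truth(state, [site])


def c5_truth() -> SyntheticTruth:
    """A C5-symmetric interface CHOL site present in both states."""
    site = PlantedSite(
        name="interface-chol-sym", leaflet="extracellular", selectivity="CHOL",
        well_depth=3.0, width=0.4, radius=2.0, wedge=0)
    return _base_truth("inactive", [site])


def synthesize_and_run(truth: SyntheticTruth, seed: int, n_frames: int,
                       nominal: int = 150, step_dt: float = STEP_DT_NS,
                       pentamer: PentamerModel | None = None):
    """Build the membrane, run the toy dynamics, return (topology, trajectory)."""
    spec = neuronal_spec(nominal)
    pent = default_pentamer() if pentamer is None else pentamer
    top, init = build_membrane(spec, pent, (BOX_A, BOX_C), seed=seed)
    write_every = max(1, int(round(FRAME_DT_NS / step_dt)))
    traj = simulate(top, init, truth, n_steps=n_frames * write_every,
                    step_dt=step_dt, write_every=write_every, seed=seed)
    return top, traj


# ---------------------------------------------------------------------------
# scenario drivers

def run_hierarchy(seed: int, n_frames: int = 660) -> dict:
    """Recover the planted lipid interaction hierarchy from contact durations."""
    top, traj = synthesize_and_run(hierarchy_truth(), seed, n_frames)
    win = select_window(traj, WINDOW)
    series = contact_series(win, top, cutoff=0.6)
    table = contact_table([series], collapse_subunits=True)
    by_max, _ = lipid_hierarchy(table, "max")
    by_top20, _ = lipid_hierarchy(table, "mean-top-20")
    lipid_frames = traj.n_frames * len(top.lipid_molecules())
    return {"by_max": by_max, "by_top20": by_top20, "table": table,
            "lipid_frames": lipid_frames}


def hierarchy_recovered(result: dict) -> bool:
    """True when CHOL ranks first and PS (DOPS) second by both statistics."""
    return all(order[0] == "CHOL" and order[1] == "DOPS"
               for order in (result["by_max"], result["by_top20"]))


def run_state_pair(seed: int, n_frames: int = 660) -> dict:
    """Paired active/inactive runs probing the state-gated interface site.

    Returns CHOL site enrichments, per-wedge penetration depths (threshold
    at 25% of the wedge-density maximum across the state pair, one common
    value for both grids) and the state-difference summary.
    """
    results = {}
    for state in ("active", "inactive"):
        truth = state_truth(state)
        top, traj = synthesize_and_run(truth, seed, n_frames)
        win = select_window(traj, WINDOW)
        grid_fine = dens.density3d(win, top, "CHOL", "hydroxyl", voxel_size=0.1)
        grid_coarse = dens.density3d(win, top, "CHOL", "hydroxyl", voxel_size=0.25)
        results[state] = {"top": top, "win": win, "grid": grid_fine,
                          "coarse": grid_coarse, "truth": truth}
    truth = results["active"]["truth"]
    meta = results["active"]["grid"].metadata
    axis_xy = np.asarray(meta["axis_xy"])
    footprint = float(meta["footprint_radius_nm"])
    z_site = BOX_C / 2.0 + truth.leaflet_z["extracellular"]
    pts = site_positions(truth, axis_xy)["interface-chol"]
    site = sites_mod.SiteDefinition(
        name="interface-chol", radius=0.7,
        points=np.column_stack([pts, np.full(len(pts), z_site)]))

    enrichment = {}
    for state in ("active", "inactive"):
        rep = sites_mod.site_enrichment(results[state]["grid"], site,
                                        footprint_radius=footprint,
                                        axis_xy=axis_xy)
        enrichment[state] = rep.enrichment

    angles = truth.interface_angles_deg()
    wedge_max = 0.0
    for state in ("active", "inactive"):
        g = results[state]["coarse"]
        wedge_max = max(wedge_max, float(g.values.max()))
    threshold = 0.25 * wedge_max
    depths = {}
    for state in ("active", "inactive"):
        pen = sites_mod.interface_penetration(
            results[state]["coarse"], axis_xy, angles,
            wedge_half_width_deg=25.0, threshold=threshold,
            footprint_radius=footprint)
        depths[state] = pen
    diff = sites_mod.state_difference(results["active"]["grid"],
                                      results["inactive"]["grid"])
    lipid_frames = (results["active"]["win"].n_frames
                    * len(results["active"]["top"].lipid_molecules()))
    return {"enrichment": enrichment, "penetration": depths,
            "threshold": threshold, "difference": diff, "site": site,
            "axis_xy": axis_xy, "footprint": footprint,
            "lipid_frames": lipid_frames,
            "grids": {s: results[s]["grid"] for s in results}}


def run_c5_repeats(seed: int, n_repeats: int = 10, n_frames: int = 120) -> dict:
    """Independent repeats of a C5-symmetric truth; convergence of symmetry."""
    grids = []
    conservation_errors = []
    truth = c5_truth()
    for r in range(n_repeats):
        top, traj = synthesize_and_run(truth, seed + r, n_frames)
        assignment = dens.assign_leaflets(traj, top)
        g = dens.density2d(traj, top, assignment, "CHOL", "extracellular",
                           bin_size=0.2)
        conservation_errors.append(
            abs(g.integral - g.metadata["time_avg_count"])
            / g.metadata["time_avg_count"])
        grids.append(g)
    report = dens.symmetry_report(grids)
    return {"report": report, "grids": grids,
            "max_conservation_error": float(max(conservation_errors))}


def run_flipflop(seed: int, nominal: int = 100, n_steps: int = 4000,
                 step_dt: float = 5.0, write_every: int = 4) -> dict:
    """Cholesterol flip-flop statistics against the Poisson expectation."""
    spec = neuronal_spec(nominal)
    top, init = build_membrane(spec, PentamerModel.empty(), (10.0, BOX_C),
                               seed=seed)
    truth = SyntheticTruth(sites=[], diffusion={t: DIFFUSION for t in
                                                HIERARCHY_DEPTHS},
                           flipflop_rate=1e-4, state="inactive",
                           protein_core_radius=0.0)
    traj = simulate(top, init, truth, n_steps=n_steps, step_dt=step_dt,
                    write_every=write_every, seed=seed)
    assignment = dens.assign_leaflets(traj, top)
    observed = int(np.sum(assignment.labels[1:] != assignment.labels[:-1]))
    n_chol = int(np.sum([t == "CHOL" for t in
                         top.lipid_type_of_molecule().values()]))
    span = float(traj.times[-1] - traj.times[0])
    expected = truth.flipflop_rate * n_chol * span
    return {"observed": observed, "expected": expected,
            "bound": 4.0 * np.sqrt(expected), "n_chol": n_chol,
            "span_ns": span, "n_flips_events": traj.metadata["n_flips"]}


def run_windowing(seed: int) -> dict:
    """A 40 us run at 10 ns spacing windowed to its last half."""
    spec = neuronal_spec(5)
    top, init = build_membrane(spec, PentamerModel.empty(), (6.0, BOX_C),
                               seed=seed)
    truth = SyntheticTruth(sites=[], diffusion={}, flipflop_rate=0.0,
                           protein_core_radius=0.0)
    traj = simulate(top, init, truth, n_steps=4000, step_dt=10.0,
                    write_every=1, seed=seed)
    win = select_window(traj, AnalysisWindow(last_fraction=0.5, stride_dt=10.0))
    return {"n_frames": win.n_frames, "t_first": float(win.times[0]),
            "t_last": float(win.times[-1]), "total_ns": float(traj.times[-1])}


def run_duration_oracle(seed: int, n_series: int = 1000) -> dict:
    """durations_from_series against the brute-force run-length scanner."""
    from .contacts import durations_from_series

    rng = np.random.default_rng(seed)
    mismatches = 0
    for _ in range(n_series):
        n = int(rng.integers(1, 200))
        p = rng.random()
        v = rng.random(n) < p
        dt = float(rng.uniform(0.5, 20.0))
        fast = durations_from_series(v, dt).tolist()
        slow = brute_force_durations(v, dt)
        if not np.allclose(fast, slow):
            mismatches += 1
    return {"n_series": n_series, "mismatches": mismatches}


def run_contact_oracle(seed: int, n_frames: int = 500) -> dict:
    """contact_series against the all-pairs 27-image distance scan."""
    spec = neuronal_spec(5)
    pent = PentamerModel.make(n_res_per_helix=2)
    box = hexagonal_box(5.0, 4.0)
    top, init = build_membrane(spec, pent, (5.0, 4.0), seed=seed)
    rng = np.random.default_rng(seed)
    frac = rng.random((n_frames, top.n_beads, 3))
    coords = frac @ box
    traj = Trajectory(times=np.arange(1, n_frames + 1, dtype=float) * 10.0,
                      coords=coords,
                      box=np.repeat(box[None], n_frames, axis=0))
    fast = contact_series(traj, top, cutoff=0.6)
    slow = brute_force_contact_series(traj, top, cutoff=0.6)
    return {"n_frames": n_frames,
            "mismatches": int(np.sum(fast.bools != slow)),
            "n_pairs": int(fast.bools.size)}


def random_grid_symmetry(seed: int, n_grids: int = 5) -> dict:
    """Idempotence of C5 symmetrization on random grids."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_grids):
        values = rng.random((40, 40))
        g = dens.DensityGrid2D(origin=np.zeros(2), bin_size=0.2, values=values,
                               metadata={"axis_xy": [4.0, 4.0]})
        sym = dens.symmetrize_c5(g)
        worst = max(worst, dens.c5_deviation(sym))
    return {"max_deviation_of_symmetrized": worst}
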