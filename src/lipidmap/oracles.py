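"""Brute-force reference implementations.

Deliberately slow, obviously-correct counterparts of the accelerated
routines (run-length scanning, neighbor-grid contact search).  They are used
as independent oracles by the test-suite and the validation scenarios and
must stay free of the optimized code paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np

from .trajio import Topology, Trajectory


def brute_force_durations(series, dt: float) -> list[float]:
    """Run-length scan of a boolean vector by explicit iteration."""
    out = []
    run = 0
    for v in list(series) + [False]:
        if v:
            run += 1
        elif run:
            out.append(run * dt)
            run = 0
    return out


def brute_force_min_image(p: np.ndarray, q: np.ndarray, box: np.ndarray,
                          n_images: int = 2) -> float:
    """Minimum distance over (2 n_images + 1)^3 lattice images."""
    best = np.inf
    rng = range(-n_images, n_images + 1)
    for i, j, k in itertools.product(rng, rng, rng):
        shift = i * box[0] + j * box[1] + k * box[2]
        best = min(best, float(np.linalg.norm(p - q + shift)))
    return best


def brute_force_contact_series(trajectory: Trajectory, topology: Topology,
                               cutoff: float = 0.6) -> np.ndarray:
    """All-pairs distance scan over 27 images, no neighbor lists.

    Returns a boolean array (residues x lipid molecules x frames) with
    residues ordered by sorted (subunit, local resid) and molecules by
    sorted molecule id, matching :func:`lipidmap.contacts.contact_series`.
    """
    prot_idx = np.flatnonzero(topology.protein_mask)
    lip_idx = np.flatnonzero(topology.lipid_mask)
    res_keys = sorted({(topology.subunits[i], int(topology.resids[i]) % 1000)
                       for i in prot_idx})
    res_row = {k: r for r, k in enumerate(res_keys)}
    mols = np.unique(topology.mol_ids[lip_idx])
    mol_col = {m: c for c, m in enumerate(mols)}

    shifts = np.array([i * trajectory.box[0][0] + j * trajectory.box[0][1]
                       + k * trajectory.box[0][2]
                       for i, j, k in itertools.product((-1, 0, 1), repeat=3)])
    out = np.zeros((len(res_keys), len(mols), trajectory.n_frames), dtype=bool)
    for f in range(trajectory.n_frames):
        p = trajectory.coords[f, prot_idx]
        q = trajectory.coords[f, lip_idx]
        # (P, L, 27) distances
        d = p[:, None, None, :] - q[None, :, None, :] + shifts[None, None, :, :]
        dmin = np.sqrt((d ** 2).sum(axis=-1)).min(axis=-1)
        hit = dmin <= cutoff
        for pi, li in zip(*np.nonzero(hit)):
            i = prot_idx[pi]
            row = res_row[(topology.subunits[i], int(topology.resids[i]) % 1000)]
            out[row, mol_col[topology.mol_ids[lip_idx[li]]], f] = True
    return out


def free_exit_time_walker(width: float, diffusion: float, n_samples: int,
                          seed: int, dt: float | None = None) -> tuple[float, float]:
    """First-exit time of a free random walk from a disc of radius 2 x width.

    Independent of the simulator: a plain Gaussian random walk with no
    potential, used to cross-check the residence oracle at zero well depth.
    """
    if dt is None:
        dt = (width / 8.0) ** 2 / (4.0 * diffusion)
    rng = np.random.default_rng(seed)
    r_exit2 = (2.0 * width) ** 2
    times = np.empty(n_samples)
    sigma = np.sqrt(2.0 * diffusion * dt)
    for s in range(n_samples):
        pos = np.zeros(2)
        step = 0
        while True:
            step += 1
            pos = pos + sigma * rng.standard_normal(2)
            if pos @ pos > r_exit2:
                times[s] = step * dt
                break
    return float(times.mean()), float(times.std(ddof=1) / np.sqrt(n_samples))
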