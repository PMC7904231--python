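"""Per-residue continuous-contact-duration statistics per lipid type.

A protein residue and a lipid molecule are "in contact" in a frame when any
bead of the residue lies within the cutoff (default 0.6 nm, the first lipid
shell) of any bead of the molecule, under minimum-image distances in the
triclinic cell.  A continuous contact is a maximal run of consecutive
contact frames; runs touching either end of the analysis window are counted
at their observed length (no censoring correction, recorded in the output).

The per-(residue, lipid type) mean duration pools events across all
molecules of the type, all repeats and - when subunit collapsing is on -
the five aligned subunit copies of the residue.  Event pooling weights the
average by evidence; per-molecule mean-of-means averaging is available via
``mode="per-molecule"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    AlignmentError,
    EmptySelectionError,
    GeometryError,
    LipidmapError,
    MappingError,
)
from .trajio import Topology, Trajectory

logger = logging.getLogger(__name__)


@dataclass
class ContactSeries:
    """Boolean contact vectors per (protein residue, lipid molecule)."""

    bools: np.ndarray                 # (R, M, F)
    residue_keys: list                # [(subunit, local resid), ...] length R
    mol_ids: np.ndarray               # (M,)
    mol_types: np.ndarray             # (M,)
    dt: float                         # frame spacing, ns
    cutoff: float                     # nm

    @property
    def n_frames(self) -> int:
        return self.bools.shape[2]


def contact_series(trajectory: Trajectory, topology: Topology,
                   cutoff: float = 0.6) -> ContactSeries:
    """Compute any-bead/any-bead contact series for every residue-lipid pair.

    Uses MDAnalysis' grid-accelerated capped distance search; the brute-force
    all-pairs scan is retained in the test-suite as the oracle.
    """
    if cutoff <= 0:
        raise LipidmapError("cutoff must be positive")
    box0 = trajectory.box[0]
    shortest = min(np.linalg.norm(box0, axis=1))
    if cutoff >= shortest / 2.0:
        raise GeometryError(
            f"cutoff {cutoff} nm >= half the shortest box vector ({shortest / 2.0} nm)")
    prot_idx = np.flatnonzero(topology.protein_mask)
    lip_idx = np.flatnonzero(topology.lipid_mask)
    if len(prot_idx) == 0 or len(lip_idx) == 0:
        raise EmptySelectionError("need protein and lipid beads for contacts")

    stride = 1000
    res_key_per_bead = [(topology.subunits[i], int(topology.resids[i]) % stride)
                        for i in prot_idx]
    residue_keys = sorted(set(res_key_per_bead))
    res_row = {k: r for r, k in enumerate(residue_keys)}
    prot_rows = np.array([res_row[k] for k in res_key_per_bead])

    mols = np.unique(topology.mol_ids[lip_idx])
    mol_col = {m: c for c, m in enumerate(mols)}
    lip_cols = np.array([mol_col[m] for m in topology.mol_ids[lip_idx]])
    type_of = topology.lipid_type_of_molecule()
    mol_types = np.array([type_of[m] for m in mols])

    from MDAnalysis.lib.distances import capped_distance
    from MDAnalysis.lib.mdamath import triclinic_box

    n_frames = trajectory.n_frames
    bools = np.zeros((len(residue_keys), len(mols), n_frames), dtype=bool)
    for f in range(n_frames):
        dims = triclinic_box(*trajectory.box[f])
        pairs = capped_distance(
            trajectory.coords[f, prot_idx].astype(np.float32),
            trajectory.coords[f, lip_idx].astype(np.float32),
            max_cutoff=cutoff, box=dims.astype(np.float32),
            return_distances=False)
        if len(pairs):
            bools[prot_rows[pairs[:, 0]], lip_cols[pairs[:, 1]], f] = True

    if n_frames > 1:
        dt = float(np.min(np.diff(trajectory.times)))
    else:
        dt = float(trajectory.metadata.get("step_dt_ns", 1.0))
    return ContactSeries(bools=bools, residue_keys=residue_keys, mol_ids=mols,
                         mol_types=mol_types, dt=dt, cutoff=cutoff)


def durations_from_series(series: np.ndarray, dt: float) -> np.ndarray:
    """Durations (ns) of maximal runs of consecutive True frames.

    Runs touching either end of the window are included at their observed
    length.  Empty input yields an empty array.
    """
    if dt <= 0:
        raise LipidmapError("dt must be positive")
    v = np.asarray(series, dtype=bool).astype(np.int8)
    if v.size == 0:
        return np.zeros(0)
    d = np.diff(np.concatenate(([0], v, [0])))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return (ends - starts).astype(float) * dt


@dataclass
class ContactTable:
    """Per-(residue, lipid type) contact-duration summary."""

    frame: pd.DataFrame
    collapse_subunits: bool
    mode: str
    boundary_runs: str = "uncensored"

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)

    def lipid_types(self) -> list[str]:
        return sorted(self.frame["lipid_type"].unique())


def contact_table(repeats: list[ContactSeries], collapse_subunits: bool = True,
                  mode: str = "pooled") -> ContactTable:
    """Aggregate contact series of one or more repeats into a contact table.

    Pools all event durations of a lipid type's molecules across repeats
    (and across the five aligned subunit copies when collapsing); the mean
    is over pooled events.  ``mode="per-molecule"`` averages per-series
    means instead.  Occupancy is the fraction of frames in which at least
    one molecule of the type touches the residue, averaged over repeats
    (and subunit copies).
    """
    if not repeats:
        raise LipidmapError("no contact series given")
    if mode not in ("pooled", "per-molecule"):
        raise LipidmapError(f"unknown averaging mode {mode!r}")
    keys0 = repeats[0].residue_keys
    for rep in repeats[1:]:
        if rep.residue_keys != keys0:
            raise AlignmentError("residue indexing differs across repeats")

    lipid_types = sorted(set(np.concatenate([r.mol_types for r in repeats])))
    if collapse_subunits:
        groups: dict = {}
        for r, (su, local) in enumerate(keys0):
            groups.setdefault(local, []).append(r)
        group_items = [(local, "*", rows) for local, rows in sorted(groups.items())]
    else:
        group_items = [(local, su, [r]) for r, (su, local) in enumerate(keys0)]

    rows_out = []
    for local, su, rows in group_items:
        for lt in lipid_types:
            durations = []
            per_series_means = []
            occ_fractions = []
            for rep in repeats:
                cols = np.flatnonzero(rep.mol_types == lt)
                if len(cols) == 0:
                    continue
                sub = rep.bools[np.ix_(rows, cols)]        # (rows, cols, F)
                any_contact = sub.any(axis=1)              # (rows, F)
                occ_fractions.extend(any_contact.mean(axis=1).tolist())
                active = np.argwhere(sub.any(axis=2))
                for ri, ci in active:
                    durs = durations_from_series(sub[ri, ci], rep.dt)
                    durations.append(durs)
                    per_series_means.append(durs.mean())
            durations = (np.concatenate(durations) if durations else np.zeros(0))
            n_events = len(durations)
            if mode == "pooled":
                mean = float(durations.mean()) if n_events else 0.0
            else:
                mean = float(np.mean(per_series_means)) if per_series_means else 0.0
            rows_out.append({
                "residue": int(local), "subunit": su, "lipid_type": lt,
                "mean_duration_ns": mean,
                "n_events": int(n_events),
                "max_duration_ns": float(durations.max()) if n_events else 0.0,
                "occupancy": float(np.mean(occ_fractions)) if occ_fractions else 0.0,
            })
    return ContactTable(frame=pd.DataFrame(rows_out),
                        collapse_subunits=collapse_subunits, mode=mode)


def lipid_hierarchy(table: ContactTable, statistic: str = "max"
                    ) -> tuple[list[str], bool]:
    """Order lipid types by interaction duration, descending.

    ``statistic`` is ``max`` (largest per-residue mean duration) or
    ``mean-top-20`` (mean over the 20 largest per-residue mean durations).
    Returns (ordered types, tie flag); exact ties keep input order (stable).
    """
    df = table.frame
    if df.empty:
        raise EmptySelectionError("empty contact table")
    types = list(dict.fromkeys(df["lipid_type"]))
    if len(types) < 2:
        raise LipidmapError("hierarchy needs >= 2 lipid types")
    summaries = []
    for lt in types:
        vals = np.sort(df.loc[df["lipid_type"] == lt, "mean_duration_ns"].values)[::-1]
        if statistic == "max":
            summaries.append(float(vals[0]))
        elif statistic == "mean-top-20":
            summaries.append(float(vals[:20].mean()))
        else:
            raise LipidmapError(f"unknown hierarchy statistic {statistic!r}")
    order = sorted(range(len(types)), key=lambda i: -summaries[i])
    ordered = [types[i] for i in order]
    svals = [summaries[i] for i in order]
    ties = any(a == b for a, b in zip(svals, svals[1:]))
    return ordered, ties


def export_bfactor(table: ContactTable, lipid_type: str,
                   structure_path: str | Path, out_path: str | Path) -> int:
    """Write a PDB whose B-factor column carries per-residue mean durations.

    Residues of the structure are matched by residue number against the
    table's residue indices; unmapped residues get 0 with a logged warning.
    Returns the number of unmapped residues.
    """
    import warnings

    import MDAnalysis as mda

    df = table.frame
    sub = df[df["lipid_type"] == lipid_type]
    if sub.empty:
        raise EmptySelectionError(f"no rows for lipid type {lipid_type!r}")
    by_res = dict(zip(sub["residue"].astype(int), sub["mean_duration_ns"]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(structure_path))
        if not hasattr(u.atoms, "tempfactors"):
            u.add_TopologyAttr("tempfactors")
        unmapped = 0
        mapped = 0
        for res in u.residues:
            val = by_res.get(int(res.resid) % 1000)
            if val is None:
                unmapped += 1
                val = 0.0
            else:
                mapped += 1
            res.atoms.tempfactors = min(max(float(val), 0.0), 999.99)
        if mapped == 0:
            raise MappingError("no table residue maps onto the structure")
        if unmapped:
            logger.warning("%d structure residues had no table entry", unmapped)
        u.atoms.write(str(out_path))
    return unmapped
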