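"""Leaflet assignment, 2D/3D lipid densities and C5 symmetry diagnostics.

Densities are absolute time-averaged number densities: a 2D grid holds mean
molecules per nm^2 (one anchor bead per molecule), a 3D grid molecules per
nm^3 when the bead selector picks one bead per molecule and bead densities
otherwise (flagged in the metadata).  Every grid satisfies the conservation
invariant  sum(values) * cell_volume = time-averaged selected count.

The five-fold symmetrization is an exact group-average projection: grid
cells are grouped into orbits by (radial bin, angular bin within a 72 degree
sector[, z slice]) about the pore axis and each orbit is replaced by its
mean.  Unlike interpolation-based rotation averaging this is idempotent and
mass-conserving to machine precision, which makes the symmetry deviation of
a symmetrized grid exactly zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import (
    CommensurabilityError,
    EmptySelectionError,
    GeometryError,
    InvalidSpecError,
    LipidmapError,
    SelectionError,
    UndefinedMetricError,
)
from .trajio import ROLES, Topology, Trajectory

LEAFLET_CODE = {"extracellular": 0, "intracellular": 1}


@dataclass
class LeafletAssignment:
    """Per-frame leaflet label of every lipid molecule (0 = extracellular)."""

    mol_ids: np.ndarray          # (M,)
    labels: np.ndarray           # (F, M) int8

    def column_of(self, mol_id: int) -> int:
        hits = np.flatnonzero(self.mol_ids == mol_id)
        if len(hits) == 0:
            raise SelectionError(f"molecule {mol_id} not in assignment")
        return int(hits[0])


def assign_leaflets(trajectory: Trajectory, topology: Topology) -> LeafletAssignment:
    """Assign every lipid to a leaflet per frame.

    The instantaneous midplane z* is the mean z of all lipid anchor beads
    (phosphate for phospholipids, hydroxyl for cholesterol); a lipid is
    extracellular iff its anchor sits above z*.  Assignments may change
    across frames (cholesterol flip-flop).
    """
    mols, anchor_idx = topology.anchor_indices()
    z = trajectory.coords[:, anchor_idx, 2]              # (F, M)
    zstar = z.mean(axis=1, keepdims=True)
    labels = (z <= zstar).astype(np.int8)                # above midplane -> 0
    return LeafletAssignment(mol_ids=mols, labels=labels)


@dataclass
class DensityGrid2D:
    origin: np.ndarray           # (2,) nm, lower corner
    bin_size: float
    values: np.ndarray           # (nx, ny), molecules / nm^2
    metadata: dict = field(default_factory=dict)

    @property
    def integral(self) -> float:
        return float(self.values.sum() * self.bin_size ** 2)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.bin_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.bin_size
        return x, y


@dataclass
class DensityGrid3D:
    origin: np.ndarray           # (3,) nm
    voxel_size: float
    values: np.ndarray           # (nx, ny, nz)
    metadata: dict = field(default_factory=dict)

    @property
    def integral(self) -> float:
        return float(self.values.sum() * self.voxel_size ** 3)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        nx, ny, nz = self.values.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.voxel_size
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.voxel_size
        z = self.origin[2] + (np.arange(nz) + 0.5) * self.voxel_size
        return x, y, z


#: fixed grid padding (nm) beyond the cell's bounding rectangle; covers beads
#: of molecule-whole-wrapped lipids that overhang the primitive cell
_GRID_PAD = 0.6


def _inplane_extent(box: np.ndarray, pts: np.ndarray) -> tuple[float, float, float, float]:
    """Box-derived in-plane extent (padded); independent of the data so that
    grids from different repeats/states are commensurate by construction."""
    v1, v2 = box[0], box[1]
    x_lo = min(0.0, v2[0]) - _GRID_PAD
    x_hi = max(v1[0], v1[0] + v2[0]) + _GRID_PAD
    y_lo = min(0.0, v2[1]) - _GRID_PAD
    y_hi = max(0.0, v2[1]) + _GRID_PAD
    if (pts[:, 0].min() < x_lo or pts[:, 0].max() > x_hi
            or pts[:, 1].min() < y_lo or pts[:, 1].max() > y_hi):
        raise GeometryError("coordinates outside the padded cell extent; "
                            "wrap the trajectory before computing densities")
    return x_lo, x_hi, y_lo, y_hi


def _edges(lo: float, hi: float, h: float) -> np.ndarray:
    n = max(1, int(np.ceil((hi - lo) / h - 1e-9)))
    return lo + np.arange(n + 1) * h


def density2d(trajectory: Trajectory, topology: Topology,
              assignment: LeafletAssignment, lipid_type: str, leaflet: str,
              bin_size: float = 0.2) -> DensityGrid2D:
    """Time-averaged 2D anchor-bead density of one lipid type in one leaflet.

    Each molecule of ``lipid_type`` currently assigned to ``leaflet``
    contributes one count per frame to the bin containing its anchor (x, y);
    values are counts / (n_frames * bin_area).
    """
    if bin_size <= 0:
        raise InvalidSpecError("bin_size must be positive")
    if leaflet not in LEAFLET_CODE:
        raise SelectionError(f"unknown leaflet {leaflet!r}")
    mols, anchor_idx = topology.anchor_indices()
    type_of = topology.lipid_type_of_molecule()
    sel = np.flatnonzero(np.array([type_of[m] for m in mols]) == lipid_type)
    if len(sel) == 0:
        raise EmptySelectionError(f"no molecules of lipid type {lipid_type!r}")
    # align assignment columns with anchor order
    cols = np.array([assignment.column_of(mols[i]) for i in sel])
    in_leaflet = assignment.labels[:, cols] == LEAFLET_CODE[leaflet]   # (F, m)
    xy = trajectory.coords[:, anchor_idx[sel], :2]                     # (F, m, 2)
    pts = xy[in_leaflet]
    if len(pts) == 0:
        raise EmptySelectionError(
            f"no {lipid_type} molecule ever occupies the {leaflet} leaflet")
    x_lo, x_hi, y_lo, y_hi = _inplane_extent(trajectory.box[0], pts)
    xe = _edges(x_lo, x_hi + 1e-9, bin_size)
    ye = _edges(y_lo, y_hi + 1e-9, bin_size)
    h, _, _ = np.histogram2d(pts[:, 0], pts[:, 1], bins=(xe, ye))
    n_frames = trajectory.n_frames
    values = h / (n_frames * bin_size ** 2)
    meta = {"lipid_type": lipid_type, "leaflet": leaflet,
            "n_frames": int(n_frames), "n_repeats": 1,
            "state": trajectory.metadata.get("state"),
            "convention": "anchor-bead per molecule",
            "time_avg_count": float(len(pts)) / n_frames,
            "axis_xy": trajectory.metadata.get("axis_xy"),
            "footprint_radius_nm": trajectory.metadata.get("footprint_radius_nm"),
            "box": trajectory.box[0].tolist(),
            "window": trajectory.metadata.get("window")}
    return DensityGrid2D(origin=np.array([xe[0], ye[0]]), bin_size=bin_size,
                         values=values, metadata=meta)


def density3d(trajectory: Trajectory, topology: Topology, lipid_type: str,
              role_selector: str = "any", voxel_size: float = 0.1) -> DensityGrid3D:
    """Time-averaged 3D density of selected beads of one lipid type.

    ``role_selector`` is one of ``any``, ``cationic-headgroup``,
    ``phosphate``, ``hydroxyl``, ``tail``.  Values are counts /
    (n_frames * voxel_volume); molecules/nm^3 when the selector picks one
    bead per molecule, bead density otherwise (``per_molecule`` flag).
    """
    if voxel_size <= 0:
        raise InvalidSpecError("voxel_size must be positive")
    if role_selector != "any" and role_selector not in ROLES:
        raise SelectionError(f"unknown bead role {role_selector!r}")
    mask = topology.lipid_mask & (topology.lipid_types == lipid_type)
    if role_selector != "any":
        mask &= topology.roles == role_selector
    sel = np.flatnonzero(mask)
    if len(sel) == 0:
        raise EmptySelectionError(
            f"no beads match lipid type {lipid_type!r}, role {role_selector!r}")
    n_mols = len(np.unique(topology.mol_ids[sel]))
    pts = trajectory.coords[:, sel, :].reshape(-1, 3)
    box = trajectory.box[0]
    x_lo, x_hi, y_lo, y_hi = _inplane_extent(box, pts)
    z_lo = -_GRID_PAD
    z_hi = box[2, 2] + _GRID_PAD
    if pts[:, 2].min() < z_lo or pts[:, 2].max() > z_hi:
        raise GeometryError("z coordinates outside the padded cell extent")
    edges = (_edges(x_lo, x_hi + 1e-9, voxel_size),
             _edges(y_lo, y_hi + 1e-9, voxel_size),
             _edges(z_lo, z_hi + 1e-9, voxel_size))
    h, _ = np.histogramdd(pts, bins=edges)
    n_frames = trajectory.n_frames
    values = h / (n_frames * voxel_size ** 3)
    meta = {"lipid_type": lipid_type, "role_selector": role_selector,
            "n_frames": int(n_frames), "n_repeats": 1,
            "state": trajectory.metadata.get("state"),
            "beads_per_molecule": len(sel) / n_mols,
            "per_molecule": len(sel) == n_mols,
            "time_avg_count": float(len(pts)) / n_frames,
            "axis_xy": trajectory.metadata.get("axis_xy"),
            "footprint_radius_nm": trajectory.metadata.get("footprint_radius_nm"),
            "box": trajectory.box[0].tolist(),
            "window": trajectory.metadata.get("window")}
    return DensityGrid3D(origin=np.array([edges[0][0], edges[1][0], edges[2][0]]),
                         voxel_size=voxel_size, values=values, metadata=meta)


def equal_composition_isovalue(reference_iso: float, fraction: float,
                               n_types: int) -> float:
    """Isovalue at which a lipid's density is displayed as if all types were
    equally abundant.

    Scales the reference isovalue by ``fraction / (1 / n_types)``, so a lipid
    at exactly the equal-composition fraction keeps the reference isovalue.
    """
    if n_types == 0:
        raise InvalidSpecError("n_types must be >= 1")
    if not (0.0 <= fraction <= 1.0):
        raise InvalidSpecError("fraction must be within [0, 1]")
    return reference_iso * fraction * n_types


# ---------------------------------------------------------------------------
# C5 symmetry

def _grid_axis(grid, axis_xy) -> np.ndarray:
    if axis_xy is None:
        axis_xy = grid.metadata.get("axis_xy")
    if axis_xy is None:
        raise GeometryError("no symmetry axis given and none in grid metadata")
    axis_xy = np.asarray(axis_xy, dtype=float)[:2]
    nx, ny = grid.values.shape[:2]
    h = grid.bin_size if isinstance(grid, DensityGrid2D) else grid.voxel_size
    lo = grid.origin[:2]
    hi = lo + np.array([nx, ny]) * h
    if not (lo[0] <= axis_xy[0] <= hi[0] and lo[1] <= axis_xy[1] <= hi[1]):
        raise GeometryError(f"symmetry axis {axis_xy} outside grid bounds")
    return axis_xy


def _orbit_keys(grid, axis_xy: np.ndarray) -> np.ndarray:
    """Flat orbit key per cell: cells sharing a key form one C5 orbit."""
    h = grid.bin_size if isinstance(grid, DensityGrid2D) else grid.voxel_size
    if isinstance(grid, DensityGrid2D):
        x, y = grid.cell_centers()
        gx, gy = np.meshgrid(x, y, indexing="ij")
        zidx = np.zeros_like(gx, dtype=int)
    else:
        x, y, z = grid.cell_centers()
        gx, gy, gz = np.meshgrid(x, y, z, indexing="ij")
        zidx = np.broadcast_to(np.arange(len(z))[None, None, :], gx.shape)
    dx = gx - axis_xy[0]
    dy = gy - axis_xy[1]
    r = np.hypot(dx, dy)
    theta = np.mod(np.arctan2(dy, dx), 2.0 * np.pi)
    sector = 2.0 * np.pi / 5.0
    theta_local = np.mod(theta, sector)
    r_bin = np.floor(r / h).astype(int)
    # angular resolution ~ one cell of arc per 72 degree sector at that radius
    n_ang = np.maximum(1, np.round(2.0 * np.pi * (r_bin + 0.5) / 5.0).astype(int))
    a_bin = np.minimum((theta_local / (sector / n_ang)).astype(int), n_ang - 1)
    max_a = int(n_ang.max()) + 1
    max_r = int(r_bin.max()) + 1
    return (zidx.astype(np.int64) * max_r + r_bin) * max_a + a_bin


def symmetrize_c5(grid, axis_xy=None):
    """Project a grid onto its C5-symmetric part about the pore axis.

    Exact orbit averaging: cells are keyed by (z slice, radial bin, angular
    bin within a 72 degree sector) and each orbit is replaced by its mean.
    Idempotent; total integral preserved to machine precision.
    """
    axis_xy = _grid_axis(grid, axis_xy)
    keys = _orbit_keys(grid, axis_xy).ravel()
    flat = grid.values.ravel()
    uniq, inverse = np.unique(keys, return_inverse=True)
    sums = np.bincount(inverse, weights=flat, minlength=len(uniq))
    counts = np.bincount(inverse, minlength=len(uniq))
    means = sums / counts
    values = means[inverse].reshape(grid.values.shape)
    meta = {**grid.metadata, "symmetrized": "C5 orbit average",
            "axis_xy": axis_xy.tolist()}
    if isinstance(grid, DensityGrid2D):
        return DensityGrid2D(origin=grid.origin.copy(), bin_size=grid.bin_size,
                             values=values, metadata=meta)
    return DensityGrid3D(origin=grid.origin.copy(), voxel_size=grid.voxel_size,
                         values=values, metadata=meta)


def c5_deviation(grid, axis_xy=None) -> float:
    """Normalized L1 distance to the symmetrized grid, in [0, 1].

    ``sum |g - S(g)| / (2 sum g)``; 0 for exactly C5-symmetric grids, 0.8 for
    mass confined to a single 72 degree sector.
    """
    total = grid.values.sum()
    if total <= 0:
        raise UndefinedMetricError("C5 deviation undefined for an all-zero grid")
    sym = symmetrize_c5(grid, axis_xy)
    return float(np.abs(grid.values - sym.values).sum() / (2.0 * total))


def average_grids(grids: list):
    """Arithmetic mean of commensurate per-repeat grids."""
    if not grids:
        raise LipidmapError("no grids to average")
    g0 = grids[0]
    for g in grids[1:]:
        _check_commensurate(g0, g)
    values = np.mean([g.values for g in grids], axis=0)
    meta = {**g0.metadata, "n_repeats": len(grids)}
    if isinstance(g0, DensityGrid2D):
        return DensityGrid2D(origin=g0.origin.copy(), bin_size=g0.bin_size,
                             values=values, metadata=meta)
    return DensityGrid3D(origin=g0.origin.copy(), voxel_size=g0.voxel_size,
                         values=values, metadata=meta)


def _check_commensurate(a, b) -> None:
    ha = a.bin_size if isinstance(a, DensityGrid2D) else a.voxel_size
    hb = b.bin_size if isinstance(b, DensityGrid2D) else b.voxel_size
    if (a.values.shape != b.values.shape or abs(ha - hb) > 1e-12
            or not np.allclose(a.origin, b.origin, atol=1e-9)):
        raise CommensurabilityError(
            f"grids not commensurate: shapes {a.values.shape}/{b.values.shape}, "
            f"spacing {ha}/{hb}, origins {a.origin}/{b.origin}")


@dataclass
class SymmetryReport:
    """C5 convergence diagnostic over simulation repeats."""

    per_repeat: list[float]
    repeat_average: float
    pairwise_l1: np.ndarray

    @property
    def median_single(self) -> float:
        return float(np.median(self.per_repeat))


def symmetry_report(grids: list, axis_xy=None) -> SymmetryReport:
    """Per-repeat C5 deviations, deviation of the repeat-average grid, and
    pairwise normalized L1 distances between repeats."""
    devs = [c5_deviation(g, axis_xy) for g in grids]
    avg = average_grids(grids)
    n = len(grids)
    pw = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            denom = grids[i].values.sum() + grids[j].values.sum()
            pw[i, j] = pw[j, i] = np.abs(
                grids[i].values - grids[j].values).sum() / denom
    return SymmetryReport(per_repeat=devs,
                          repeat_average=c5_deviation(avg, axis_xy),
                          pairwise_l1=pw)


# ---------------------------------------------------------------------------
# export / import

def export_density(grid, path: str | Path) -> None:
    """Write a 3D grid as OpenDX (via gridData) or a 2D grid as CSV."""
    if grid.values.size == 0:
        raise LipidmapError("refusing to export an empty grid")
    path = Path(path)
    if isinstance(grid, DensityGrid3D):
        from gridData import Grid
        g = Grid(grid.values,
                 origin=grid.origin + grid.voxel_size / 2.0,
                 delta=grid.voxel_size)
        g.export(str(path), "dx")
    else:
        meta = json.dumps(_jsonable(grid.metadata))
        header = (f"# lipidmap 2D density, molecules/nm^2\n"
                  f"# origin_nm = {float(grid.origin[0])!r} {float(grid.origin[1])!r}\n"
                  f"# bin_size_nm = {float(grid.bin_size)!r}\n"
                  f"# metadata = {meta}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, grid.values, delimiter=",")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (np.ndarray, list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def load_density3d(path: str | Path) -> DensityGrid3D:
    from gridData import Grid
    g = Grid(str(path))
    voxel = float(g.delta[0])
    origin = np.asarray(g.origin, dtype=float) - voxel / 2.0
    return DensityGrid3D(origin=origin, voxel_size=voxel,
                         values=np.asarray(g.grid), metadata={"source": str(path)})


def load_density2d(path: str | Path) -> DensityGrid2D:
    origin = None
    bin_size = None
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if "origin_nm" in line:
                origin = np.array([float(t) for t in line.split("=")[1].split()])
            elif "bin_size_nm" in line:
                bin_size = float(line.split("=")[1])
            elif "metadata" in line:
                meta = json.loads(line.split("=", 1)[1])
    values = np.loadtxt(path, delimiter=",", comments="#")
    values = np.atleast_2d(values)
    if origin is None or bin_size is None:
        raise LipidmapError(f"{path}: missing grid header")
    return DensityGrid2D(origin=origin, bin_size=bin_size, values=values,
                         metadata=meta)
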