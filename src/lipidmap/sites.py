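"""Density overlap with structurally defined ligand sites and state contrasts.

Quantifies how a lipid's 3D density overlaps a ligand's binding site (e.g. a
positive allosteric modulator between two subunits, or an anionic-lipid
pocket), how densities differ between conformational states, and how deeply
density penetrates the five subunit-interface wedges.

Site regions are vertical cylinders: voxels whose in-plane distance to any
reference point is within the inclusion radius, restricted to the z slab
spanned by the reference points (padded by the radius).  The bulk reference
is the same z slab beyond twice the protein footprint radius.  Registration
of the reference structure onto the trajectory frame is the caller's
responsibility; the package only validates overlap.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .density import DensityGrid3D, _check_commensurate
from .exceptions import GeometryError, InvalidSpecError, NotFoundError

PROTEIN_RESNAMES = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
WATER_RESNAMES = {"HOH", "WAT", "W", "SOL", "TIP3"}


@dataclass
class SiteDefinition:
    """A ligand site: reference points plus inclusion radius, or a wedge."""

    name: str
    radius: float
    points: np.ndarray | None = None          # (n, 3) nm
    wedge: tuple | None = None                # (index 0-4, half width deg, leaflet)

    def __post_init__(self):
        if self.radius <= 0:
            raise InvalidSpecError("site radius must be positive")
        has_points = self.points is not None and len(self.points) > 0
        if not has_points and self.wedge is None:
            raise InvalidSpecError("site needs >= 1 reference point or a wedge")


@dataclass
class SiteReport:
    site: str
    state: str | None
    mean_site_density: float          # molecules/nm^3
    bulk_density: float
    enrichment: float | None          # site/bulk, None when bulk == 0
    occupancy: float                  # integral over site voxels, molecules
    n_site_voxels: int

    def as_row(self) -> dict:
        return {"site": self.site, "state": self.state,
                "mean_site_density": self.mean_site_density,
                "bulk_density": self.bulk_density,
                "enrichment": self.enrichment, "occupancy": self.occupancy,
                "n_site_voxels": self.n_site_voxels}


def load_site_from_structure(pdb_path: str | Path, ligand_resname: str,
                             radius: float = 0.7) -> list[SiteDefinition]:
    """One SiteDefinition per copy of a ligand residue in a PDB (coords in nm).

    Raises :class:`NotFoundError` listing the available hetero residue names
    when the ligand is absent.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(pdb_path))
    sel = u.atoms[u.atoms.resnames == ligand_resname]
    if len(sel) == 0:
        hetero = sorted({rn for rn in u.atoms.resnames
                         if rn not in PROTEIN_RESNAMES and rn not in WATER_RESNAMES})
        raise NotFoundError(
            f"no residue named {ligand_resname!r} in {pdb_path}; "
            f"hetero residues present: {hetero}", available=hetero)
    out = []
    for res in sel.residues:
        chain = ""
        if hasattr(res.atoms, "chainIDs") and len(res.atoms):
            chain = str(res.atoms.chainIDs[0])
        elif hasattr(res, "segid"):
            chain = str(res.segid).strip()
        out.append(SiteDefinition(
            name=f"{ligand_resname}_{chain or 'X'}{res.resid}",
            radius=radius, points=res.atoms.positions / 10.0))
    return out


def _voxel_centers(grid: DensityGrid3D):
    x, y, z = grid.cell_centers()
    return np.meshgrid(x, y, z, indexing="ij")


def _site_mask(grid: DensityGrid3D, site: SiteDefinition,
               axis_xy=None, interface_angles_deg=None,
               slab: tuple[float, float] | None = None) -> np.ndarray:
    gx, gy, gz = _voxel_centers(grid)
    if site.points is not None and len(site.points):
        zs = site.points[:, 2]
        lo, hi = (zs.min() - site.radius, zs.max() + site.radius) if slab is None else slab
        in_slab = (gz >= lo) & (gz <= hi)
        mask = np.zeros(grid.values.shape, dtype=bool)
        for p in site.points:
            d2 = (gx - p[0]) ** 2 + (gy - p[1]) ** 2
            mask |= d2 <= site.radius ** 2
        return mask & in_slab
    # wedge site
    if axis_xy is None:
        axis_xy = grid.metadata.get("axis_xy")
    if axis_xy is None:
        raise GeometryError("wedge site requires a pore axis")
    if interface_angles_deg is None:
        raise GeometryError("wedge site requires interface angles")
    if slab is None:
        raise GeometryError("wedge site requires a z slab")
    index, half_width, _leaflet = site.wedge
    center = math.radians(interface_angles_deg[int(index)])
    theta = np.arctan2(gy - axis_xy[1], gx - axis_xy[0])
    dtheta = np.mod(theta - center + np.pi, 2.0 * np.pi) - np.pi
    return (np.abs(dtheta) <= math.radians(half_width)) \
        & (gz >= slab[0]) & (gz <= slab[1])


def site_enrichment(grid: DensityGrid3D, site: SiteDefinition,
                    footprint_radius: float | None = None,
                    axis_xy=None, interface_angles_deg=None,
                    slab: tuple[float, float] | None = None) -> SiteReport:
    """Mean in-site density, bulk density and their ratio for one site.

    Bulk voxels share the site's z slab but lie beyond twice the protein
    footprint radius from the pore axis.  Raises :class:`GeometryError` when
    the site does not intersect the grid.
    """
    if axis_xy is None:
        axis_xy = grid.metadata.get("axis_xy")
    if footprint_radius is None:
        footprint_radius = grid.metadata.get("footprint_radius_nm")
    mask = _site_mask(grid, site, axis_xy, interface_angles_deg, slab)
    if not mask.any():
        raise GeometryError(f"site {site.name!r} does not intersect the grid")
    gx, gy, gz = _voxel_centers(grid)
    zvals = gz[mask]
    lo, hi = float(zvals.min()), float(zvals.max())
    in_slab = (gz >= lo - 1e-9) & (gz <= hi + 1e-9)
    # lipid-accessible = inside the periodic cell (the grid's bounding
    # rectangle has empty corners outside the hexagonal cell)
    box = grid.metadata.get("box")
    if box is not None:
        inv = np.linalg.inv(np.asarray(box)[:2, :2])
        frac = np.stack([gx, gy], axis=-1) @ inv
        in_cell = np.all((frac >= 0.0) & (frac < 1.0), axis=-1)
        in_slab = in_slab & in_cell
    if axis_xy is not None and footprint_radius:
        r = np.hypot(gx - axis_xy[0], gy - axis_xy[1])
        bulk = in_slab & (r > 2.0 * footprint_radius) & ~mask
    else:
        bulk = in_slab & ~mask
    if not bulk.any():
        raise GeometryError("no bulk voxels available for reference")
    mean_site = float(grid.values[mask].mean())
    mean_bulk = float(grid.values[bulk].mean())
    return SiteReport(
        site=site.name, state=grid.metadata.get("state"),
        mean_site_density=mean_site, bulk_density=mean_bulk,
        enrichment=(mean_site / mean_bulk) if mean_bulk > 0 else None,
        occupancy=float(grid.values[mask].sum() * grid.voxel_size ** 3),
        n_site_voxels=int(mask.sum()))


@dataclass
class StateDifferenceGrid:
    """Voxelwise (active - inactive) density with summary statistics."""

    grid: DensityGrid3D
    l1: float
    signed_max: float
    max_location: np.ndarray          # (3,) nm, voxel center

    @property
    def values(self) -> np.ndarray:
        return self.grid.values


def state_difference(grid_active: DensityGrid3D,
                     grid_inactive: DensityGrid3D) -> StateDifferenceGrid:
    """Exact voxelwise subtraction of commensurate grids (no resampling)."""
    _check_commensurate(grid_active, grid_inactive)
    diff = grid_active.values - grid_inactive.values
    flat = np.abs(diff).argmax()
    idx = np.unravel_index(flat, diff.shape)
    x, y, z = grid_active.cell_centers()
    loc = np.array([x[idx[0]], y[idx[1]], z[idx[2]]])
    meta = {**grid_active.metadata,
            "difference": f"{grid_active.metadata.get('state')} - "
                          f"{grid_inactive.metadata.get('state')}"}
    out = DensityGrid3D(origin=grid_active.origin.copy(),
                        voxel_size=grid_active.voxel_size, values=diff,
                        metadata=meta)
    return StateDifferenceGrid(grid=out, l1=float(np.abs(diff).sum()),
                               signed_max=float(diff[idx]), max_location=loc)


def interface_penetration(grid: DensityGrid3D, axis_xy,
                          interface_angles_deg,
                          wedge_half_width_deg: float,
                          threshold: float,
                          footprint_radius: float | None = None) -> pd.DataFrame:
    """Radial penetration depth of supra-threshold density per interface wedge.

    For each of the five wedges, the depth is ``R_ref - r_min`` where
    ``r_min`` is the smallest radial distance from the pore axis at which a
    voxel in the wedge exceeds ``threshold`` and ``R_ref`` the protein
    footprint radius; wedges with no supra-threshold voxel report depth 0
    with an ``empty`` flag.
    """
    if threshold <= 0:
        raise InvalidSpecError("threshold must be positive")
    if axis_xy is None:
        axis_xy = grid.metadata.get("axis_xy")
    if axis_xy is None:
        raise GeometryError("penetration analysis requires a pore axis")
    if footprint_radius is None:
        footprint_radius = grid.metadata.get("footprint_radius_nm")
    if not footprint_radius:
        raise GeometryError("penetration analysis requires a footprint radius")
    gx, gy, _ = _voxel_centers(grid)
    r = np.hypot(gx - axis_xy[0], gy - axis_xy[1])
    theta = np.arctan2(gy - axis_xy[1], gx - axis_xy[0])
    rows = []
    for k, ang in enumerate(interface_angles_deg):
        center = math.radians(ang)
        dtheta = np.mod(theta - center + np.pi, 2.0 * np.pi) - np.pi
        wedge = np.abs(dtheta) <= math.radians(wedge_half_width_deg)
        above = wedge & (grid.values > threshold)
        if above.any():
            r_min = float(r[above].min())
            depth = max(0.0, footprint_radius - r_min)
            empty = False
        else:
            r_min, depth, empty = float("nan"), 0.0, True
        rows.append({"wedge": k, "angle_deg": float(ang), "r_min_nm": r_min,
                     "depth_nm": depth, "empty": empty})
    return pd.DataFrame(rows)
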