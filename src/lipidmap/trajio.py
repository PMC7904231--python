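"""Coordinate/trajectory I/O, analysis windows and periodic geometry.

All coordinates are handled in nm (GRO native; PDB is converted from Å on
read) and times in ns.  File reading and writing is delegated to MDAnalysis;
this module owns the annotated :class:`Topology`, the in-memory
:class:`Trajectory` (frames x beads x 3, per-frame triclinic box) and the
periodic-geometry helpers every downstream stage uses.

The hexagonal prism simulation cell is represented as a triclinic lattice
with vectors ``(a,0,0)``, ``(-a/2, a*sqrt(3)/2, 0)``, ``(0,0,c)``.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .exceptions import (
    AnnotationError,
    FormatError,
    GeometryError,
    LipidmapError,
    ResolutionError,
    SelectionError,
    StructuralMismatchError,
)

logger = logging.getLogger(__name__)

# bead-role vocabulary
ROLE_CATIONIC = "cationic-headgroup"
ROLE_PHOSPHATE = "phosphate"
ROLE_HYDROXYL = "hydroxyl"
ROLE_TAIL = "tail"
ROLE_BACKBONE = "backbone"
ROLE_SIDECHAIN = "sidechain"
ROLE_OTHER = "other"
ROLES = (ROLE_CATIONIC, ROLE_PHOSPHATE, ROLE_HYDROXYL, ROLE_TAIL,
         ROLE_BACKBONE, ROLE_SIDECHAIN, ROLE_OTHER)

AMINO_ACIDS = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}


@dataclass
class NamingConfig:
    """Maps residue names to lipid types and bead names to roles.

    The defaults cover the Martini names used by the synthetic builder
    (POPC/POPE/DOPS/DPSM/CHOL; beads NC3/NH3/PO4/ROH/CNO, tails C*/D*,
    protein BB/SC*).  Protein subunit identity is encoded in the residue
    numbering: ``resid = subunit_index * subunit_resid_stride + local_index``.
    """

    lipid_types: dict[str, str]
    bead_roles: dict[str, str]
    bead_role_prefixes: dict[str, str]
    anchors: dict[str, str]
    protein_resnames: set[str]
    solvent_resnames: set[str]
    subunit_resid_stride: int = 1000

    @classmethod
    def default(cls) -> "NamingConfig":
        return cls(
            lipid_types={"POPC": "POPC", "POPE": "POPE", "DOPS": "DOPS",
                         "DPSM": "SM", "CHOL": "CHOL"},
            bead_roles={"NC3": ROLE_CATIONIC, "NH3": ROLE_CATIONIC,
                        "PO4": ROLE_PHOSPHATE, "ROH": ROLE_HYDROXYL,
                        "CNO": ROLE_OTHER, "BB": ROLE_BACKBONE},
            bead_role_prefixes={"SC": ROLE_SIDECHAIN, "GL": ROLE_OTHER,
                                "C": ROLE_TAIL, "D": ROLE_TAIL},
            anchors={"POPC": "PO4", "POPE": "PO4", "DOPS": "PO4",
                     "SM": "PO4", "CHOL": "ROH"},
            protein_resnames=set(AMINO_ACIDS),
            solvent_resnames={"W", "WN", "NA+", "CL-", "NA", "CL", "ION"},
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NamingConfig":
        base = cls.default()
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("lipid_types", "bead_roles", "bead_role_prefixes", "anchors"):
            if key in data:
                getattr(base, key).update(data[key])
        for key in ("protein_resnames", "solvent_resnames"):
            if key in data:
                getattr(base, key).update(data[key])
        if "subunit_resid_stride" in data:
            base.subunit_resid_stride = int(data["subunit_resid_stride"])
        return base

    def role_of(self, bead_name: str) -> str:
        if bead_name in self.bead_roles:
            return self.bead_roles[bead_name]
        for prefix in sorted(self.bead_role_prefixes, key=len, reverse=True):
            if bead_name.startswith(prefix):
                return self.bead_role_prefixes[prefix]
        return ROLE_OTHER


@dataclass
class Topology:
    """Per-bead annotation of the system.

    All fields are 1-D numpy arrays of equal length (one entry per bead).
    Bead ids are implicit (dense 0..n-1 array index).
    """

    bead_names: np.ndarray
    mol_ids: np.ndarray
    mol_classes: np.ndarray      # protein | lipid | solvent | other
    lipid_types: np.ndarray      # '' for non-lipid beads
    resids: np.ndarray
    resnames: np.ndarray
    subunits: np.ndarray         # '' for non-protein beads
    roles: np.ndarray

    def __post_init__(self):
        n = len(self.bead_names)
        for name in ("mol_ids", "mol_classes", "lipid_types", "resids",
                     "resnames", "subunits", "roles"):
            if len(getattr(self, name)) != n:
                raise AnnotationError(f"topology field {name!r} length mismatch")

    @property
    def n_beads(self) -> int:
        return len(self.bead_names)

    @property
    def protein_mask(self) -> np.ndarray:
        return self.mol_classes == "protein"

    @property
    def lipid_mask(self) -> np.ndarray:
        return self.mol_classes == "lipid"

    def validate(self) -> None:
        lip = self.lipid_mask
        if np.any(self.lipid_types[lip] == ""):
            raise AnnotationError("lipid bead without a lipid_type")
        prot = self.protein_mask
        if np.any(self.subunits[prot] == ""):
            raise AnnotationError("protein bead without a subunit id")

    def lipid_molecules(self) -> np.ndarray:
        """Unique molecule ids of lipid molecules, sorted."""
        return np.unique(self.mol_ids[self.lipid_mask])

    def lipid_type_of_molecule(self) -> dict[int, str]:
        lip = self.lipid_mask
        return dict(zip(self.mol_ids[lip].tolist(), self.lipid_types[lip].tolist()))

    def anchor_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """One anchor bead per lipid molecule.

        Phosphate bead for phospholipids, hydroxyl bead for cholesterol.
        Returns (molecule ids, bead indices), aligned.  Raises
        :class:`AnnotationError` naming the molecule if an anchor is missing.
        """
        lip_idx = np.flatnonzero(self.lipid_mask)
        mols, mol_idx = [], []
        order = np.argsort(self.mol_ids[lip_idx], kind="stable")
        lip_idx = lip_idx[order]
        for mol, grp in itertools.groupby(lip_idx, key=lambda i: self.mol_ids[i]):
            grp = list(grp)
            roles = self.roles[grp]
            want = ROLE_HYDROXYL if self.lipid_types[grp[0]] == "CHOL" else ROLE_PHOSPHATE
            hits = [g for g, r in zip(grp, roles) if r == want]
            if not hits:
                raise AnnotationError(
                    f"lipid molecule {mol} ({self.lipid_types[grp[0]]}) has no "
                    f"{want} anchor bead")
            mols.append(mol)
            mol_idx.append(hits[0])
        return np.asarray(mols), np.asarray(mol_idx)


@dataclass
class Trajectory:
    """Frames x beads x 3 coordinates (nm), per-frame triclinic box, times (ns)."""

    times: np.ndarray            # (F,) ns, strictly increasing
    coords: np.ndarray           # (F, N, 3) nm
    box: np.ndarray              # (F, 3, 3) nm, rows are lattice vectors
    metadata: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    def validate(self, n_beads: int | None = None) -> None:
        if self.coords.shape[0] != self.n_frames or self.box.shape[0] != self.n_frames:
            raise LipidmapError("frame count mismatch between times/coords/box")
        if n_beads is not None and self.coords.shape[1] != n_beads:
            raise StructuralMismatchError(
                f"trajectory has {self.coords.shape[1]} beads, topology {n_beads}")
        if not np.all(np.isfinite(self.coords)):
            raise LipidmapError("non-finite coordinates")
        if self.n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise LipidmapError("times not strictly increasing")
        if np.any(np.linalg.det(self.box) <= 0):
            raise GeometryError("box with non-positive volume")


@dataclass
class AnalysisWindow:
    """Keep the last ``last_fraction`` of a run, subsampled at ``stride_dt`` ns."""

    last_fraction: float = 0.5
    stride_dt: float = 10.0

    def __post_init__(self):
        if not (0 < self.last_fraction <= 1):
            raise LipidmapError("last_fraction must be in (0, 1]")
        if self.stride_dt <= 0:
            raise LipidmapError("stride_dt must be positive")


# ---------------------------------------------------------------------------
# periodic geometry

def hexagonal_box(a: float, c: float) -> np.ndarray:
    """Triclinic cell for a hexagonal prism of in-plane lattice constant ``a``."""
    return np.array([[a, 0.0, 0.0],
                     [-a / 2.0, a * np.sqrt(3.0) / 2.0, 0.0],
                     [0.0, 0.0, c]])


def box_center(box: np.ndarray) -> np.ndarray:
    return 0.5 * box.sum(axis=0)


def wrap_points(points: np.ndarray, box: np.ndarray,
                dims: tuple[int, ...] = (0, 1, 2)) -> np.ndarray:
    """Wrap points into the primitive cell (fractional coords in [0,1))."""
    frac = points @ np.linalg.inv(box)
    for d in dims:
        frac[..., d] -= np.floor(frac[..., d])
    return frac @ box


_SHIFT_GRID_27 = np.array(list(itertools.product((-1, 0, 1), repeat=3)), dtype=float)


def min_image_distance(p: np.ndarray, q: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image distance over the 27 nearest lattice images.

    Accepts single points (shape ``(3,)``) or arrays ``(M, 3)``; broadcasts
    elementwise.  Valid for separations below half the shortest lattice
    vector, which holds for all cutoffs used here.
    """
    if np.linalg.det(box) <= 0:
        raise GeometryError("degenerate box (volume <= 0)")
    p = np.atleast_2d(np.asarray(p, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    d = p - q                                    # (M, 3)
    # reduce to the nearest lattice point first so the 27-image search is
    # exhaustive regardless of how far apart the raw points are
    d -= np.round(d @ np.linalg.inv(box)) @ box
    shifts = _SHIFT_GRID_27 @ box                # (27, 3)
    dist = np.linalg.norm(d[:, None, :] + shifts[None, :, :], axis=-1).min(axis=1)
    return dist[0] if dist.shape == (1,) else dist


def nearest_image_shift_2d(dxy: np.ndarray, box: np.ndarray) -> np.ndarray:
    """In-plane minimum-image displacement via fractional rounding.

    Exact for displacements well below half the cell (site-force geometry);
    cheap enough for the inner simulation loop.
    """
    inplane = box[:2, :2]
    frac = dxy @ np.linalg.inv(inplane)
    frac -= np.round(frac)
    return frac @ inplane


# ---------------------------------------------------------------------------
# reading and writing

def _mda():
    # deferred import: MDAnalysis is heavy and noisy at import time
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        import MDAnalysis as mda
    return mda


def _precheck_gro(path: Path) -> None:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 3:
        raise FormatError(f"{path}: truncated GRO file", line=len(lines))
    try:
        n = int(lines[1].strip())
    except ValueError as exc:
        raise FormatError(f"{path}: unreadable atom count", line=2) from exc
    if len(lines) < n + 3:
        raise FormatError(
            f"{path}: declares {n} atoms but ends early", line=len(lines))


def _classify(resname: str, naming: NamingConfig) -> str:
    if resname in naming.lipid_types:
        return "lipid"
    if resname in naming.protein_resnames:
        return "protein"
    if resname in naming.solvent_resnames:
        return "solvent"
    return "other"


def read_system(coordinate_path: str | Path,
                trajectory_path: str | Path | None = None,
                naming: NamingConfig | None = None) -> tuple[Topology, Trajectory]:
    """Read a GRO/PDB coordinate file (plus optional XTC/DCD) into annotated form.

    Residue names and bead names are interpreted through ``naming``;
    unmatched residue names are classified ``other`` with a logged warning.
    Without a trajectory file, a single-frame trajectory is returned.
    """
    naming = naming or NamingConfig.default()
    coordinate_path = Path(coordinate_path)
    if not coordinate_path.exists():
        raise FileNotFoundError(coordinate_path)
    if coordinate_path.suffix.lower() == ".gro":
        _precheck_gro(coordinate_path)
    mda = _mda()
    try:
        if trajectory_path is None:
            u = mda.Universe(str(coordinate_path))
        else:
            u = mda.Universe(str(coordinate_path), str(trajectory_path))
    except FileNotFoundError:
        raise
    except (ValueError, OSError, EOFError) as exc:
        msg = str(exc)
        if "atoms" in msg and trajectory_path is not None:
            raise StructuralMismatchError(
                f"bead count mismatch between {coordinate_path} and "
                f"{trajectory_path}: {msg}") from exc
        raise FormatError(f"cannot parse {coordinate_path}: {msg}") from exc

    atoms = u.atoms
    resnames = atoms.resnames.astype(str)
    names = atoms.names.astype(str)
    resids = atoms.resids.astype(int)

    classes = np.array([_classify(rn, naming) for rn in resnames])
    unmatched = sorted(set(resnames[classes == "other"]))
    if unmatched:
        logger.warning("unmatched residue names classified 'other': %s", unmatched)

    lipid_types = np.array([naming.lipid_types.get(rn, "") for rn in resnames])
    roles = np.empty(len(atoms), dtype=object)
    for i, (nm, cls) in enumerate(zip(names, classes)):
        roles[i] = naming.role_of(nm)
    roles = roles.astype(str)

    # molecule ids: whole protein = one molecule; every other residue = one
    mol_ids = np.empty(len(atoms), dtype=int)
    next_id = 0
    protein_id = None
    prev_res = None
    cur = -1
    for i, (cls, rid, rn) in enumerate(zip(classes, resids, resnames)):
        key = (cls, rid, rn)
        if cls == "protein":
            if protein_id is None:
                protein_id = next_id
                next_id += 1
            mol_ids[i] = protein_id
        else:
            if key != prev_res:
                cur = next_id
                next_id += 1
            mol_ids[i] = cur
        prev_res = key if cls != "protein" else None

    stride = naming.subunit_resid_stride
    subunits = np.array([
        chr(ord("A") + (rid // stride) % 26) if cls == "protein" else ""
        for cls, rid in zip(classes, resids)])

    top = Topology(bead_names=names, mol_ids=mol_ids, mol_classes=classes,
                   lipid_types=lipid_types, resids=resids, resnames=resnames,
                   subunits=subunits, roles=roles)

    from MDAnalysis.lib.mdamath import triclinic_vectors
    n_frames = len(u.trajectory)
    coords = np.empty((n_frames, len(atoms), 3))
    boxes = np.empty((n_frames, 3, 3))
    times = np.empty(n_frames)
    for f, ts in enumerate(u.trajectory):
        coords[f] = atoms.positions / 10.0          # Angstrom -> nm
        boxes[f] = triclinic_vectors(ts.dimensions) / 10.0
        times[f] = (ts.time or 0.0) / 1000.0        # ps -> ns
    if n_frames == 1:
        times[0] = max(times[0], 0.0)
    traj = Trajectory(times=times, coords=coords, box=boxes)
    traj.validate(top.n_beads)
    return top, traj


def write_system(topology: Topology, trajectory: Trajectory,
                 coordinate_path: str | Path,
                 trajectory_path: str | Path | None = None) -> None:
    """Write GRO (first frame) and optionally XTC/DCD (all frames)."""
    if trajectory.n_frames == 0:
        raise LipidmapError("refusing to write an empty trajectory")
    trajectory.validate(topology.n_beads)
    mda = _mda()
    from MDAnalysis.lib.mdamath import triclinic_box

    n = topology.n_beads
    # residues: consecutive runs of equal (resid, resname)
    res_index = np.zeros(n, dtype=int)
    r = 0
    for i in range(1, n):
        if (topology.resids[i] != topology.resids[i - 1]
                or topology.resnames[i] != topology.resnames[i - 1]):
            r += 1
        res_index[i] = r
    n_res = r + 1
    first_atom = np.zeros(n_res, dtype=int)
    seen = set()
    for i in range(n):
        if res_index[i] not in seen:
            seen.add(res_index[i])
            first_atom[res_index[i]] = i

    seg_labels = []
    res_seg = np.zeros(n_res, dtype=int)
    for ri in range(n_res):
        i = first_atom[ri]
        label = topology.subunits[i] if topology.mol_classes[i] == "protein" else "MEMB"
        if label not in seg_labels:
            seg_labels.append(label)
        res_seg[ri] = seg_labels.index(label)

    u = mda.Universe.empty(n_atoms=n, n_residues=n_res, n_segments=len(seg_labels),
                           atom_resindex=res_index, residue_segindex=res_seg,
                           trajectory=True)
    u.add_TopologyAttr("names", topology.bead_names.tolist())
    u.add_TopologyAttr("resnames", [topology.resnames[i] for i in first_atom])
    u.add_TopologyAttr("resids", [int(topology.resids[i]) for i in first_atom])
    u.add_TopologyAttr("segids", seg_labels)
    u.add_TopologyAttr("chainIDs", [
        (topology.subunits[i] or "M")[:1] for i in range(n)])

    def _load_frame(f: int):
        u.atoms.positions = trajectory.coords[f] * 10.0
        u.dimensions = triclinic_box(*(trajectory.box[f] * 10.0))
        u.trajectory.ts.time = trajectory.times[f] * 1000.0
        u.trajectory.ts.frame = f

    _load_frame(0)
    with mda.Writer(str(coordinate_path), n) as w:
        w.write(u.atoms)
    if trajectory_path is not None:
        with mda.Writer(str(trajectory_path), n) as w:
            for f in range(trajectory.n_frames):
                _load_frame(f)
                w.write(u.atoms)


# ---------------------------------------------------------------------------
# windows and centering

def select_window(trajectory: Trajectory, window: AnalysisWindow,
                  time_tol: float = 1e-6) -> Trajectory:
    """Keep frames with time > (1 - last_fraction) * T_end, then subsample.

    Half-open convention: a frame exactly at the cut boundary is excluded.
    Subsampling starts from the first kept frame and assumes uniform native
    spacing.
    """
    if trajectory.n_frames == 0:
        raise LipidmapError("empty trajectory")
    times = trajectory.times
    t_end = times[-1]
    cut = (1.0 - window.last_fraction) * t_end
    keep = np.flatnonzero(times > cut + time_tol)
    if len(keep) == 0:
        raise LipidmapError("window selected no frames")
    if len(times) > 1:
        native = float(np.min(np.diff(times)))
        if window.stride_dt < native - time_tol:
            raise ResolutionError(
                f"stride {window.stride_dt} ns finer than native spacing {native} ns")
        step = max(1, int(round(window.stride_dt / native)))
    else:
        step = 1
    keep = keep[::step]
    return Trajectory(times=times[keep].copy(),
                      coords=trajectory.coords[keep].copy(),
                      box=trajectory.box[keep].copy(),
                      metadata={**trajectory.metadata,
                                "window": {"last_fraction": window.last_fraction,
                                           "stride_dt_ns": window.stride_dt}})


def center_on_protein(trajectory: Trajectory, topology: Topology) -> Trajectory:
    """Translate each frame so the protein centroid sits at the box center.

    Non-protein molecules are re-wrapped molecule-whole; no rotation applied.
    Valid because the protein is positionally restrained in the source data.
    """
    prot = topology.protein_mask
    if not prot.any():
        raise SelectionError("no protein beads in topology")
    coords = trajectory.coords.copy()
    mol_ids = topology.mol_ids
    uniq, mol_index = np.unique(mol_ids, return_inverse=True)
    protein_mols = set(np.unique(mol_ids[prot]).tolist())
    wrap_mol = np.array([m not in protein_mols for m in uniq])
    for f in range(trajectory.n_frames):
        box = trajectory.box[f]
        shift = box_center(box) - coords[f][prot].mean(axis=0)
        coords[f] += shift
        # molecule-whole wrap of non-protein molecules
        centroid = np.zeros((len(uniq), 3))
        np.add.at(centroid, mol_index, coords[f])
        counts = np.bincount(mol_index, minlength=len(uniq))[:, None]
        centroid /= counts
        frac = centroid @ np.linalg.inv(box)
        mol_shift = -np.floor(frac) @ box
        mol_shift[~wrap_mol] = 0.0
        coords[f] += mol_shift[mol_index]
    return Trajectory(times=trajectory.times.copy(), coords=coords,
                      box=trajectory.box.copy(), metadata=dict(trajectory.metadata))
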