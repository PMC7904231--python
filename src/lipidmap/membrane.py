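"""Synthetic asymmetric membrane and static C5 pentamer builder.

The default membrane emulates a simplified human neuronal plasma membrane of
five lipid species (POPC, POPE, DOPS, sphingomyelin, cholesterol) with
different mole fractions in the extracellular and intracellular leaflets;
DOPS is absent from the extracellular leaflet.  The protein inclusion is a
static, exactly C5-symmetric pseudo-pentamer: five identical subunits of
coarse-grained residues arranged on three concentric rings of transmembrane
pseudo-helices around a central pore axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .exceptions import InvalidSpecError, PackingError
from .trajio import NamingConfig, Topology, Trajectory, box_center, hexagonal_box

EXTRACELLULAR = "extracellular"
INTRACELLULAR = "intracellular"
LEAFLETS = (EXTRACELLULAR, INTRACELLULAR)

#: leaflet mole percents of the default neuronal membrane model
NEURONAL_PERCENTS = {
    EXTRACELLULAR: {"POPC": 24.4, "POPE": 11.1, "DOPS": 0.0, "SM": 19.9, "CHOL": 44.7},
    INTRACELLULAR: {"POPC": 13.7, "POPE": 21.5, "DOPS": 16.9, "SM": 3.0, "CHOL": 44.9},
}

#: Martini-style residue name per lipid type
RESNAME_OF_TYPE = {"POPC": "POPC", "POPE": "POPE", "DOPS": "DOPS",
                   "SM": "DPSM", "CHOL": "CHOL"}

# bead templates: (bead name, in-plane offset (nm, molecule frame),
#                  z offset from the anchor bead, positive = away from midplane)
LIPID_TEMPLATES = {
    "POPC": [("NC3", (0.00, 0.00), +0.30), ("PO4", (0.00, 0.00), 0.00),
             ("C1A", (+0.12, 0.00), -0.55), ("C1B", (-0.12, 0.00), -1.00)],
    "POPE": [("NH3", (0.00, 0.00), +0.30), ("PO4", (0.00, 0.00), 0.00),
             ("C1A", (+0.12, 0.00), -0.55), ("C1B", (-0.12, 0.00), -1.00)],
    "DOPS": [("CNO", (0.00, 0.00), +0.30), ("PO4", (0.00, 0.00), 0.00),
             ("D1A", (+0.12, 0.00), -0.55), ("D1B", (-0.12, 0.00), -1.00)],
    "SM":   [("NC3", (0.00, 0.00), +0.30), ("PO4", (0.00, 0.00), 0.00),
             ("C1A", (+0.12, 0.00), -0.55), ("C1B", (-0.12, 0.00), -1.00)],
    "CHOL": [("ROH", (0.00, 0.00), 0.00),
             ("C1", (+0.08, 0.00), -0.45), ("C2", (-0.08, 0.00), -0.85)],
}


def apportion_counts(percent_map: dict[str, float], nominal_n: int) -> dict[str, int]:
    """Integer lipid counts from mole percents, round-half-up per type.

    ``count_i = round(percent_i * nominal_n / 100)``.  The leaflet total may
    differ from ``nominal_n`` when the percents do not sum to exactly 100
    (the default extracellular column sums to 100.1).  Deterministic.
    """
    if nominal_n <= 0:
        raise InvalidSpecError("nominal_n must be positive")
    out = {}
    for lipid, pct in percent_map.items():
        if pct < 0:
            raise InvalidSpecError(f"negative mole percent for {lipid}: {pct}")
        out[lipid] = int(math.floor(pct * nominal_n / 100.0 + 0.5))
    return out


@dataclass
class MembraneSpec:
    """Leaflet-resolved composition and geometry of the synthetic bilayer."""

    per_leaflet_percent: dict[str, dict[str, float]] = field(
        default_factory=lambda: {lf: dict(NEURONAL_PERCENTS[lf]) for lf in LEAFLETS})
    nominal_per_leaflet: int = 150
    leaflet_z: dict[str, float] = field(
        default_factory=lambda: {EXTRACELLULAR: +1.8, INTRACELLULAR: -1.8})
    headgroup_noise_sd: float = 0.05

    def __post_init__(self):
        for leaflet, pmap in self.per_leaflet_percent.items():
            if leaflet not in LEAFLETS:
                raise InvalidSpecError(f"unknown leaflet {leaflet!r}")
            for lipid, pct in pmap.items():
                if pct < 0:
                    raise InvalidSpecError(f"negative percent {lipid}={pct} in {leaflet}")
            total = sum(pmap.values())
            if abs(total - 100.0) > 0.2:
                raise InvalidSpecError(
                    f"{leaflet} percents sum to {total}, outside 100 +/- 0.2")
        if self.headgroup_noise_sd < 0:
            raise InvalidSpecError("headgroup_noise_sd must be >= 0")

    def counts(self, leaflet: str) -> dict[str, int]:
        return apportion_counts(self.per_leaflet_percent[leaflet],
                                self.nominal_per_leaflet)


def _rot_z(deg: float) -> np.ndarray:
    th = math.radians(deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class PentamerModel:
    """Static, exactly C5-symmetric pseudo-pentamer around the z pore axis.

    Bead positions are relative to the pore axis through the origin.  Residue
    indexing is identical across the five subunits; each residue carries a
    backbone (BB) and a sidechain (SC1) bead and belongs to one of three
    concentric transmembrane rings (inner/middle/outer).
    """

    positions: np.ndarray          # (N, 3) nm
    resid_local: np.ndarray        # per bead, 1-based within subunit
    resnames: np.ndarray
    bead_names: np.ndarray
    subunits: np.ndarray           # 'A'..'E'
    rings: np.ndarray              # per bead: inner | middle | outer
    subunit_phase_deg: float = 90.0

    RESNAME_CYCLE = ("ALA", "LEU", "VAL", "PHE", "SER", "THR", "ILE", "MET")

    #: four straight transmembrane pseudo-helices per subunit:
    #: (ring label, radius nm, angular offset from the subunit axis, deg)
    HELICES = (("inner", 1.0, 0.0),      # pore-lining, M2-like
               ("middle", 1.6, -20.0),   # M1-like
               ("middle", 1.6, +20.0),   # M3-like
               ("outer", 2.2, 0.0))      # lipid-facing, M4-like

    @classmethod
    def make(cls, n_res_per_helix: int = 19,
             z_span: tuple[float, float] = (-1.4, 1.4),
             subunit_phase_deg: float = 90.0,
             sidechain_dr: float = 0.15) -> "PentamerModel":
        pos_a, resid, resnames, names, rings = [], [], [], [], []
        local = 0
        zs = np.linspace(z_span[0], z_span[1], n_res_per_helix)
        for ring, radius, offset in cls.HELICES:
            ang = subunit_phase_deg + offset
            th = math.radians(ang)
            for z in zs:
                local += 1
                bb = np.array([radius * math.cos(th), radius * math.sin(th), z])
                sc = np.array([(radius + sidechain_dr) * math.cos(th),
                               (radius + sidechain_dr) * math.sin(th), z + 0.08])
                rn = cls.RESNAME_CYCLE[(local - 1) % len(cls.RESNAME_CYCLE)]
                for nm, p in (("BB", bb), ("SC1", sc)):
                    pos_a.append(p)
                    resid.append(local)
                    resnames.append(rn)
                    names.append(nm)
                    rings.append(ring)
        pos_a = np.array(pos_a)
        all_pos, all_res, all_rn, all_nm, all_su, all_ring = [], [], [], [], [], []
        for s in range(5):
            rot = _rot_z(72.0 * s)
            all_pos.append(pos_a @ rot.T)
            all_res.extend(resid)
            all_rn.extend(resnames)
            all_nm.extend(names)
            all_su.extend([chr(ord("A") + s)] * len(resid))
            all_ring.extend(rings)
        return cls(positions=np.vstack(all_pos),
                   resid_local=np.array(all_res),
                   resnames=np.array(all_rn), bead_names=np.array(all_nm),
                   subunits=np.array(all_su), rings=np.array(all_ring),
                   subunit_phase_deg=subunit_phase_deg)

    @classmethod
    def empty(cls) -> "PentamerModel":
        z = np.zeros(0)
        return cls(positions=np.zeros((0, 3)), resid_local=z.astype(int),
                   resnames=z.astype(str), bead_names=z.astype(str),
                   subunits=z.astype(str), rings=z.astype(str))

    @property
    def n_beads(self) -> int:
        return len(self.positions)

    @property
    def footprint_radius(self) -> float:
        """Largest in-plane bead radius from the pore axis (0 if empty)."""
        if self.n_beads == 0:
            return 0.0
        return float(np.linalg.norm(self.positions[:, :2], axis=1).max())

    def c5_deviation(self) -> float:
        """Max distance between the 72 degree-rotated beads and their images."""
        if self.n_beads == 0:
            return 0.0
        rot = self.positions @ _rot_z(72.0).T
        n_per = self.n_beads // 5
        image = np.vstack([self.positions[n_per:], self.positions[:n_per]])
        return float(np.abs(rot - image).max())


def build_membrane(spec: MembraneSpec, pentamer: PentamerModel,
                   box: np.ndarray | tuple[float, float], seed: int,
                   min_spacing: float = 0.45,
                   protein_margin: float = 0.3,
                   max_tries_per_lipid: int = 2000
                   ) -> tuple[Topology, Trajectory]:
    """Place lipids uniformly at random in each leaflet plane around the protein.

    Lipids are excluded from a disc of radius ``footprint + protein_margin``
    around the pore axis and kept at least ``min_spacing`` apart (in-plane,
    minimum image, within the same leaflet).  Reproducible from ``seed``.
    Returns an annotated topology and a single-frame trajectory (t = 0) whose
    box is the hexagonal prism cell.
    """
    if isinstance(box, tuple):
        box = hexagonal_box(*box)
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    center = box_center(box)
    inplane = box[:2, :2]
    inv_inplane = np.linalg.inv(inplane)
    excl_r = pentamer.footprint_radius + protein_margin if pentamer.n_beads else 0.0

    def min_image_xy(d):
        f = d @ inv_inplane
        f -= np.round(f)
        return f @ inplane

    bead_names, mol_ids, classes, ltypes = [], [], [], []
    resids, resnames, subunits = [], [], []
    coords = []

    # protein first: molecule id 0, resid encodes subunit via stride 1000
    if pentamer.n_beads:
        for i in range(pentamer.n_beads):
            su_index = ord(pentamer.subunits[i]) - ord("A")
            bead_names.append(pentamer.bead_names[i])
            mol_ids.append(0)
            classes.append("protein")
            ltypes.append("")
            resids.append(su_index * 1000 + int(pentamer.resid_local[i]))
            resnames.append(pentamer.resnames[i])
            subunits.append(pentamer.subunits[i])
        coords.append(pentamer.positions + center)

    next_mol = 1 if pentamer.n_beads else 0
    lipid_resid = 10000
    for leaflet in LEAFLETS:
        counts = spec.counts(leaflet)
        type_list = [t for t, c in counts.items() for _ in range(c)]
        placed = np.zeros((0, 2))
        sign = 1.0 if spec.leaflet_z[leaflet] > 0 else -1.0
        for lipid_type in type_list:
            ok = False
            for _ in range(max_tries_per_lipid):
                f12 = rng.random(2)
                xy = f12 @ inplane
                d_ax = min_image_xy((xy - center[:2])[None, :])[0]
                if np.hypot(*d_ax) < excl_r:
                    continue
                if len(placed):
                    d = min_image_xy(placed - xy)
                    if (np.einsum("ij,ij->i", d, d) < min_spacing ** 2).any():
                        continue
                ok = True
                break
            if not ok:
                raise PackingError(
                    leaflet, f"could not place a {lipid_type} lipid in the "
                    f"{leaflet} leaflet after {max_tries_per_lipid} tries")
            placed = np.vstack([placed, xy])
            z_anchor = (center[2] + spec.leaflet_z[leaflet]
                        + rng.normal(0.0, spec.headgroup_noise_sd))
            ori = rng.random() * 2.0 * np.pi
            c, s = math.cos(ori), math.sin(ori)
            lipid_resid += 1
            template = LIPID_TEMPLATES[lipid_type]
            mol_coords = np.empty((len(template), 3))
            for k, (nm, (ox, oy), dz) in enumerate(template):
                mol_coords[k] = (xy[0] + c * ox - s * oy,
                                 xy[1] + s * ox + c * oy,
                                 z_anchor + sign * dz)
                bead_names.append(nm)
                mol_ids.append(next_mol)
                classes.append("lipid")
                ltypes.append(lipid_type)
                resids.append(lipid_resid)
                resnames.append(RESNAME_OF_TYPE[lipid_type])
                subunits.append("")
            coords.append(mol_coords)
            next_mol += 1

    naming = NamingConfig.default()
    roles = np.array([naming.role_of(nm) for nm in bead_names], dtype=str)
    top = Topology(bead_names=np.array(bead_names, dtype=str),
                   mol_ids=np.array(mol_ids, dtype=int),
                   mol_classes=np.array(classes, dtype=str),
                   lipid_types=np.array(ltypes, dtype=str),
                   resids=np.array(resids, dtype=int),
                   resnames=np.array(resnames, dtype=str),
                   subunits=np.array(subunits, dtype=str),
                   roles=roles)
    all_coords = (np.vstack(coords) if coords else np.zeros((0, 3)))[None, :, :]
    traj = Trajectory(times=np.array([0.0]), coords=all_coords,
                      box=box[None, :, :],
                      metadata={"builder_seed": int(seed)})
    return top, traj
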