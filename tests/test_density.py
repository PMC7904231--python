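"""Leaflet assignment, density grids, isovalue reweighting, C5 symmetry."""

import numpy as np
import pytest

from lipidmap.density import (
    DensityGrid2D,
    DensityGrid3D,
    assign_leaflets,
    average_grids,
    c5_deviation,
    density2d,
    density3d,
    equal_composition_isovalue,
    export_density,
    load_density2d,
    load_density3d,
    symmetrize_c5,
    symmetry_report,
)
from lipidmap.exceptions import (
    CommensurabilityError,
    EmptySelectionError,
    GeometryError,
    InvalidSpecError,
    LipidmapError,
    SelectionError,
    UndefinedMetricError,
)
from lipidmap.trajio import Topology, Trajectory, hexagonal_box


def _lipid_topology(entries):
    """entries: list of (lipid_type, anchor_bead_name)."""
    n = len(entries)
    return Topology(
        bead_names=np.array([e[1] for e in entries]),
        mol_ids=np.arange(n),
        mol_classes=np.array(["lipid"] * n),
        lipid_types=np.array([e[0] for e in entries]),
        resids=np.arange(1, n + 1),
        resnames=np.array([e[0] for e in entries]),
        subunits=np.array([""] * n),
        roles=np.array(["hydroxyl" if e[0] == "CHOL" else "phosphate"
                        for e in entries]),
    )


def _static_traj(positions, n_frames=1, box_a=10.0, box_c=10.0):
    box = hexagonal_box(box_a, box_c)
    coords = np.repeat(np.asarray(positions, dtype=float)[None],
                       n_frames, axis=0)
    return Trajectory(times=np.arange(1, n_frames + 1, dtype=float),
                      coords=coords,
                      box=np.repeat(box[None], n_frames, axis=0))


class TestAssignLeaflets:
    def test_sign_of_offset(self):
        top = _lipid_topology([("POPC", "PO4"), ("POPC", "PO4"),
                               ("CHOL", "ROH")])
        traj = _static_traj([[1, 1, 5.8], [2, 2, 2.2], [3, 3, 3.0]])
        a = assign_leaflets(traj, top)
        # midplane z* ~ 3.67: above -> extracellular (0)
        assert a.labels[0].tolist() == [0, 1, 1]

    def test_constant_without_flipflop(self, small_run):
        top, traj = small_run
        a = assign_leaflets(traj, top)
        assert np.all(a.labels == a.labels[0])


class TestDensity2D:
    def test_immobile_lipid_single_bin(self):
        top = _lipid_topology([("POPC", "PO4"), ("POPC", "PO4")])
        traj = _static_traj([[3.05, 3.05, 5.0], [6.0, 6.0, 1.0]],
                            n_frames=100)
        a = assign_leaflets(traj, top)
        g = density2d(traj, top, a, "POPC", "extracellular", bin_size=0.2)
        assert g.values.max() == pytest.approx(25.0)    # 1 / 0.04 nm^2
        assert (g.values > 0).sum() == 1
        assert g.integral == pytest.approx(1.0)

    def test_conservation_invariant(self, small_run):
        top, traj = small_run
        a = assign_leaflets(traj, top)
        g = density2d(traj, top, a, "CHOL", "extracellular", 0.2)
        assert abs(g.integral - g.metadata["time_avg_count"]) \
            <= 1e-9 * g.metadata["time_avg_count"]

    def test_unknown_lipid_fails_loudly(self, small_run):
        top, traj = small_run
        a = assign_leaflets(traj, top)
        with pytest.raises(EmptySelectionError):
            density2d(traj, top, a, "PIP2", "extracellular", 0.2)

    def test_absent_leaflet_combination_fails_loudly(self, small_run):
        top, traj = small_run
        a = assign_leaflets(traj, top)
        with pytest.raises(EmptySelectionError):
            # DOPS is intracellular-only and cannot flip
            density2d(traj, top, a, "DOPS", "extracellular", 0.2)


class TestDensity3D:
    def test_immobile_bead_voxel_value(self):
        top = _lipid_topology([("CHOL", "ROH")])
        traj = _static_traj([[3.05, 3.05, 5.05]], n_frames=10)
        g = density3d(traj, top, "CHOL", "hydroxyl", voxel_size=0.1)
        assert g.values.max() == pytest.approx(1000.0)  # 1 / 0.001 nm^3
        assert g.integral == pytest.approx(1.0)
        assert g.metadata["per_molecule"] is True

    def test_tail_selector_counts_beads(self, small_run):
        top, traj = small_run
        g = density3d(traj, top, "CHOL", "tail", voxel_size=0.2)
        n_chol = sum(1 for t in top.lipid_type_of_molecule().values()
                     if t == "CHOL")
        # CHOL carries two tail beads
        assert g.integral == pytest.approx(2 * n_chol, rel=1e-9)
        assert g.metadata["per_molecule"] is False

    def test_unknown_role_rejected(self, small_run):
        top, traj = small_run
        with pytest.raises(SelectionError):
            density3d(traj, top, "CHOL", "glycerol")


class TestEqualCompositionIsovalue:
    def test_equal_composition_fixed_point(self):
        assert equal_composition_isovalue(7.7, 0.2, 5) == pytest.approx(7.7)

    def test_arithmetic(self):
        assert equal_composition_isovalue(5.0, 0.4, 5) == pytest.approx(10.0)

    def test_cholesterol_total_fraction(self):
        # a 44.8% lipid shown at reference 6.7 -> isovalue 15 molecules/nm^3
        assert equal_composition_isovalue(6.7, 0.448, 5) \
            == pytest.approx(15.0, abs=0.01)

    def test_zero_types_rejected(self):
        with pytest.raises(InvalidSpecError):
            equal_composition_isovalue(1.0, 0.2, 0)
        with pytest.raises(InvalidSpecError):
            equal_composition_isovalue(1.0, 1.5, 5)


def _blob_grid(center, sigma=0.25, n=50, h=0.2, axis=(5.0, 5.0)):
    x = (np.arange(n) + 0.5) * h
    gx, gy = np.meshgrid(x, x, indexing="ij")
    values = np.exp(-((gx - center[0]) ** 2 + (gy - center[1]) ** 2)
                    / (2 * sigma ** 2))
    return DensityGrid2D(origin=np.zeros(2), bin_size=h, values=values,
                         metadata={"axis_xy": list(axis)})


class TestSymmetrizeC5:
    def test_idempotent(self, rng):
        g = DensityGrid2D(origin=np.zeros(2), bin_size=0.2,
                          values=rng.random((40, 40)),
                          metadata={"axis_xy": [4.0, 4.0]})
        once = symmetrize_c5(g)
        twice = symmetrize_c5(once)
        assert np.abs(once.values - twice.values).max() < 1e-12

    def test_symmetric_input_is_fixed_point(self, rng):
        g = DensityGrid2D(origin=np.zeros(2), bin_size=0.2,
                          values=rng.random((40, 40)),
                          metadata={"axis_xy": [4.0, 4.0]})
        sym = symmetrize_c5(g)
        again = symmetrize_c5(sym)
        np.testing.assert_allclose(sym.values, again.values, atol=1e-12)
        assert c5_deviation(sym) < 1e-12

    def test_smooth_ring_nearly_unchanged(self):
        x = (np.arange(50) + 0.5) * 0.2
        gx, gy = np.meshgrid(x, x, indexing="ij")
        r = np.hypot(gx - 5.0, gy - 5.0)
        ring = np.exp(-((r - 2.0) ** 2) / (2 * 0.6 ** 2))
        g = DensityGrid2D(origin=np.zeros(2), bin_size=0.2, values=ring,
                          metadata={"axis_xy": [5.0, 5.0]})
        assert c5_deviation(g) < 0.05

    def test_mass_conserved(self, rng):
        g = _blob_grid((6.5, 5.0))
        sym = symmetrize_c5(g)
        assert sym.integral == pytest.approx(g.integral, rel=1e-9)

    def test_blob_splits_into_five_equal_sectors(self):
        # sector masses agree to the orbit-discretization accuracy (~5%)
        g = _blob_grid((6.8, 5.0), sigma=0.45)
        sym = symmetrize_c5(g)
        x, y = sym.cell_centers()
        gx, gy = np.meshgrid(x, y, indexing="ij")
        theta = np.mod(np.arctan2(gy - 5.0, gx - 5.0), 2 * np.pi)
        sector = (theta // (2 * np.pi / 5)).astype(int)
        masses = [sym.values[sector == k].sum() * 0.04 for k in range(5)]
        np.testing.assert_allclose(masses, g.integral / 5, rtol=0.05)

    def test_3d_symmetrization(self, rng):
        g = DensityGrid3D(origin=np.zeros(3), voxel_size=0.25,
                          values=rng.random((30, 30, 8)),
                          metadata={"axis_xy": [3.75, 3.75]})
        sym = symmetrize_c5(g)
        assert c5_deviation(sym) < 1e-12
        assert sym.integral == pytest.approx(g.integral, rel=1e-9)

    def test_axis_outside_grid_rejected(self):
        g = _blob_grid((5.0, 5.0))
        with pytest.raises(GeometryError):
            symmetrize_c5(g, axis_xy=[50.0, 50.0])


class TestC5Deviation:
    def test_single_sector_mass_gives_point_eight(self):
        # mass confined to one 72-degree sector, away from the axis
        n, h = 60, 0.2
        x = (np.arange(n) + 0.5) * h
        gx, gy = np.meshgrid(x, x, indexing="ij")
        dx, dy = gx - 6.0, gy - 6.0
        r = np.hypot(dx, dy)
        theta = np.mod(np.arctan2(dy, dx), 2 * np.pi)
        values = ((r > 2.0) & (r < 4.0) & (theta > 0.15)
                  & (theta < 2 * np.pi / 5 - 0.15)).astype(float)
        g = DensityGrid2D(origin=np.zeros(2), bin_size=h, values=values,
                          metadata={"axis_xy": [6.0, 6.0]})
        # 4/5 of the mass is redistributed; orbit discretization leaks ~5%
        assert c5_deviation(g) == pytest.approx(0.8, rel=0.05)

    def test_all_zero_grid_rejected(self):
        g = DensityGrid2D(origin=np.zeros(2), bin_size=0.2,
                          values=np.zeros((10, 10)),
                          metadata={"axis_xy": [1.0, 1.0]})
        with pytest.raises(UndefinedMetricError):
            c5_deviation(g)


class TestRepeatAveraging:
    def test_average_and_report(self, rng):
        grids = []
        base = _blob_grid((6.5, 5.0)).values
        for _ in range(4):
            noisy = base + rng.normal(0, 0.02, base.shape).clip(-0.01, None)
            grids.append(DensityGrid2D(origin=np.zeros(2), bin_size=0.2,
                                       values=np.abs(noisy),
                                       metadata={"axis_xy": [5.0, 5.0]}))
        rep = symmetry_report(grids)
        assert len(rep.per_repeat) == 4
        assert rep.pairwise_l1.shape == (4, 4)
        avg = average_grids(grids)
        np.testing.assert_allclose(
            avg.values, np.mean([g.values for g in grids], axis=0))

    def test_commensurability_enforced(self, rng):
        a = _blob_grid((5.0, 5.0))
        b = DensityGrid2D(origin=np.array([0.1, 0.0]), bin_size=0.2,
                          values=a.values.copy(), metadata=a.metadata)
        with pytest.raises(CommensurabilityError):
            average_grids([a, b])

    def test_disjoint_half_windows_agree_within_noise(self, small_run):
        """Stationary run: grids from disjoint half-windows converge."""
        top, traj = small_run
        a = assign_leaflets(traj, top)
        halves = []
        mid = traj.n_frames // 2
        for sl in (slice(0, mid), slice(mid, None)):
            sub = Trajectory(times=traj.times[sl], coords=traj.coords[sl],
                             box=traj.box[sl], metadata=traj.metadata)
            halves.append(density2d(sub, top, assign_leaflets(sub, top),
                                    "CHOL", "extracellular", 0.5))
        l1 = np.abs(halves[0].values - halves[1].values).sum()
        total = halves[0].values.sum() + halves[1].values.sum()
        assert 0 < l1 / total < 1.0


class TestExport:
    def test_dx_roundtrip(self, tmp_path, rng):
        g = DensityGrid3D(origin=np.array([1.0, 2.0, 3.0]), voxel_size=0.25,
                          values=rng.random((8, 6, 4)), metadata={})
        path = tmp_path / "g.dx"
        export_density(g, path)
        back = load_density3d(path)
        np.testing.assert_allclose(back.values, g.values, atol=1e-6)
        np.testing.assert_allclose(back.origin, g.origin, atol=1e-6)
        assert back.voxel_size == pytest.approx(0.25)

    def test_csv_roundtrip(self, tmp_path, rng):
        g = DensityGrid2D(origin=np.array([-1.0, 0.5]), bin_size=0.2,
                          values=rng.random((7, 5)),
                          metadata={"lipid_type": "CHOL",
                                    "leaflet": "extracellular"})
        path = tmp_path / "g.csv"
        export_density(g, path)
        back = load_density2d(path)
        np.testing.assert_allclose(back.values, g.values, rtol=1e-12)
        np.testing.assert_allclose(back.origin, g.origin)
        assert back.metadata["lipid_type"] == "CHOL"

    def test_empty_grid_rejected(self, tmp_path):
        g = DensityGrid2D(origin=np.zeros(2), bin_size=0.2,
                          values=np.zeros((0, 0)), metadata={})
        with pytest.raises(LipidmapError):
            export_density(g, tmp_path / "empty.csv")
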