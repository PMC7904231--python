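"""Continuous-contact durations, pooling, hierarchy and B-factor export."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lipidmap.contacts import (
    ContactSeries,
    ContactTable,
    contact_series,
    contact_table,
    durations_from_series,
    export_bfactor,
    lipid_hierarchy,
)
from lipidmap.exceptions import EmptySelectionError, GeometryError, MappingError
from lipidmap.oracles import brute_force_durations
from lipidmap.trajio import Topology, Trajectory, hexagonal_box


def _two_bead_system(distance):
    """One single-bead residue and one single-bead lipid at given distance."""
    top = Topology(
        bead_names=np.array(["BB", "PO4"]),
        mol_ids=np.array([0, 1]),
        mol_classes=np.array(["protein", "lipid"]),
        lipid_types=np.array(["", "POPC"]),
        resids=np.array([1, 10001]),
        resnames=np.array(["ALA", "POPC"]),
        subunits=np.array(["A", ""]),
        roles=np.array(["backbone", "phosphate"]),
    )
    box = hexagonal_box(10.0, 10.0)
    coords = np.array([[[5.0, 5.0, 5.0], [5.0 + distance, 5.0, 5.0]]])
    coords = np.repeat(coords, 5, axis=0)
    traj = Trajectory(times=np.arange(1, 6, dtype=float),
                      coords=coords, box=np.repeat(box[None], 5, axis=0))
    return top, traj


class TestContactSeries:
    def test_below_cutoff_all_true(self):
        top, traj = _two_bead_system(0.59)
        cs = contact_series(traj, top, cutoff=0.6)
        assert cs.bools.all()

    def test_above_cutoff_all_false(self):
        top, traj = _two_bead_system(0.61)
        cs = contact_series(traj, top, cutoff=0.6)
        assert not cs.bools.any()

    def test_cutoff_across_periodic_boundary(self):
        top, traj = _two_bead_system(9.5)      # 0.5 via the periodic image
        cs = contact_series(traj, top, cutoff=0.6)
        assert cs.bools.all()

    def test_cutoff_too_large_rejected(self):
        top, traj = _two_bead_system(0.5)
        with pytest.raises(GeometryError):
            contact_series(traj, top, cutoff=6.0)


class TestDurations:
    def test_run_length_arithmetic(self):
        v = [True, True, False, True, True, True, False]
        d = durations_from_series(v, 10.0)
        assert sorted(d.tolist()) == [20.0, 30.0]
        assert d.mean() == pytest.approx(25.0)

    def test_all_false_empty(self):
        assert durations_from_series([False] * 5, 10.0).size == 0
        assert durations_from_series([], 10.0).size == 0

    def test_boundary_runs_uncensored(self):
        d = durations_from_series([True, True, False, True], 1.0)
        assert sorted(d.tolist()) == [1.0, 2.0]

    @given(st.lists(st.booleans(), max_size=100),
           st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force(self, series, dt):
        fast = durations_from_series(series, dt).tolist()
        slow = brute_force_durations(series, dt)
        assert fast == pytest.approx(slow)

    @given(st.lists(st.booleans(), min_size=1, max_size=80))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_reversal_invariance(self, series):
        fwd = sorted(durations_from_series(series, 1.0).tolist())
        rev = sorted(durations_from_series(series[::-1], 1.0).tolist())
        assert fwd == rev

    @given(st.lists(st.booleans(), min_size=2, max_size=80))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_coarsening_never_decreases_mean(self, series):
        """OR-coarsening frame pairs merges runs, so the mean duration of a
        non-empty series can only grow."""
        v = np.asarray(series, dtype=bool)
        if v.size % 2:
            v = np.append(v, False)
        coarse = v[0::2] | v[1::2]
        fine_d = durations_from_series(v, 1.0)
        coarse_d = durations_from_series(coarse, 2.0)
        if fine_d.size:
            assert coarse_d.mean() >= fine_d.mean() - 1e-12

    def test_occupancy_identity(self, rng):
        v = rng.random(200) < 0.3
        d = durations_from_series(v, 10.0)
        assert d.sum() == pytest.approx(v.sum() * 10.0)


def _series_from_bools(bools, keys, types, dt=10.0):
    bools = np.asarray(bools, dtype=bool)
    return ContactSeries(bools=bools, residue_keys=keys,
                         mol_ids=np.arange(bools.shape[1]),
                         mol_types=np.asarray(types), dt=dt, cutoff=0.6)


class TestContactTable:
    def test_equal_weight_pooling_across_subunits(self):
        """Five subunit copies with one event each of 1..5 frames pool to a
        mean of 30 ns at dt = 10."""
        keys = [(su, 1) for su in "ABCDE"]
        f = 10
        bools = np.zeros((5, 1, f), dtype=bool)
        for i in range(5):
            bools[i, 0, : i + 1] = True
        cs = _series_from_bools(bools, keys, ["CHOL"])
        table = contact_table([cs], collapse_subunits=True)
        row = table.frame.iloc[0]
        assert row["mean_duration_ns"] == pytest.approx(30.0)
        assert row["n_events"] == 5
        assert row["max_duration_ns"] == pytest.approx(50.0)

    def test_degenerate_pooling_equals_series_mean(self):
        bools = np.array([[[True, True, False, True, True, True, False]]])
        cs = _series_from_bools(bools, [("A", 1)], ["CHOL"])
        table = contact_table([cs], collapse_subunits=False)
        assert table.frame.iloc[0]["mean_duration_ns"] == pytest.approx(25.0)

    def test_per_molecule_mode(self):
        # molecule 1: one 4-frame event; molecule 2: two 1-frame events
        bools = np.zeros((1, 2, 8), dtype=bool)
        bools[0, 0, :4] = True
        bools[0, 1, 5] = True
        bools[0, 1, 7] = True
        cs = _series_from_bools(bools, [("A", 1)], ["CHOL", "CHOL"])
        pooled = contact_table([cs], mode="pooled").frame.iloc[0]
        permol = contact_table([cs], mode="per-molecule").frame.iloc[0]
        assert pooled["mean_duration_ns"] == pytest.approx(60.0 / 3)
        assert permol["mean_duration_ns"] == pytest.approx((40.0 + 10.0) / 2)

    def test_occupancy_is_any_contact_fraction(self):
        bools = np.zeros((1, 2, 10), dtype=bool)
        bools[0, 0, :3] = True
        bools[0, 1, 2:5] = True
        cs = _series_from_bools(bools, [("A", 1)], ["CHOL", "CHOL"])
        table = contact_table([cs], collapse_subunits=False)
        assert table.frame.iloc[0]["occupancy"] == pytest.approx(0.5)

    def test_misaligned_repeats_rejected(self):
        a = _series_from_bools(np.zeros((1, 1, 4), bool), [("A", 1)], ["CHOL"])
        b = _series_from_bools(np.zeros((1, 1, 4), bool), [("A", 2)], ["CHOL"])
        from lipidmap.exceptions import AlignmentError

        with pytest.raises(AlignmentError):
            contact_table([a, b])

    def test_planted_site_residues_recovered(self, hierarchy_result):
        """Top CHOL residues sit on the lipid-facing outer helix carrying
        the planted extracellular site."""
        df = hierarchy_result["table"].frame
        chol = df[df["lipid_type"] == "CHOL"].sort_values(
            "mean_duration_ns", ascending=False)
        top_decile = chol.head(max(1, len(chol) // 10))
        # outer helix = local residues 58..76; extracellular site -> upper z
        assert (top_decile["residue"] >= 58).all()


class TestHierarchy:
    def _table(self, maxima):
        rows = []
        for lt, mx in maxima.items():
            for r, v in enumerate([mx, mx / 2, 0.0]):
                rows.append({"residue": r, "subunit": "*", "lipid_type": lt,
                             "mean_duration_ns": v, "n_events": 1,
                             "max_duration_ns": v, "occupancy": 0.1})
        return ContactTable(frame=pd.DataFrame(rows), collapse_subunits=True,
                            mode="pooled")

    def test_sort_by_max(self):
        order, ties = lipid_hierarchy(
            self._table({"CHOL": 50.0, "DOPS": 30.0, "POPC": 10.0}), "max")
        assert order == ["CHOL", "DOPS", "POPC"]
        assert not ties

    def test_exact_tie_flagged_stable(self):
        order, ties = lipid_hierarchy(
            self._table({"POPC": 10.0, "POPE": 10.0}), "max")
        assert order == ["POPC", "POPE"]     # input order preserved
        assert ties

    def test_empty_table_rejected(self):
        empty = ContactTable(frame=pd.DataFrame(), collapse_subunits=True,
                             mode="pooled")
        with pytest.raises(EmptySelectionError):
            lipid_hierarchy(empty, "max")


class TestBfactorExport:
    def _structure(self, tmp_path):
        from lipidmap.membrane import PentamerModel
        from lipidmap.membrane import MembraneSpec, build_membrane

        pent = PentamerModel.make(n_res_per_helix=2)
        spec = MembraneSpec(per_leaflet_percent={
            "extracellular": {"POPC": 100.0},
            "intracellular": {"POPC": 100.0}}, nominal_per_leaflet=1)
        top, traj = build_membrane(spec, pent, (8.0, 6.0), seed=0)
        from lipidmap.trajio import write_system

        path = tmp_path / "structure.pdb"
        write_system(top, traj, path)
        return path

    def _table(self, values):
        rows = [{"residue": r, "subunit": "*", "lipid_type": "CHOL",
                 "mean_duration_ns": v, "n_events": 1, "max_duration_ns": v,
                 "occupancy": 0.1} for r, v in values.items()]
        return ContactTable(frame=pd.DataFrame(rows), collapse_subunits=True,
                            mode="pooled")

    def test_roundtrip_values(self, tmp_path):
        structure = self._structure(tmp_path)
        table = self._table({r: float(r) for r in range(1, 9)})
        out = tmp_path / "colored.pdb"
        export_bfactor(table, "CHOL", structure, out)
        import MDAnalysis as mda

        u = mda.Universe(str(out))
        prot = u.select_atoms("protein")
        for res in prot.residues:
            assert res.atoms.tempfactors[0] == pytest.approx(
                res.resid % 1000, abs=0.01)

    def test_unmapped_residues_zero_with_warning(self, tmp_path):
        structure = self._structure(tmp_path)
        table = self._table({1: 5.0})
        out = tmp_path / "colored.pdb"
        unmapped = export_bfactor(table, "CHOL", structure, out)
        assert unmapped > 0

    def test_no_mapping_rejected(self, tmp_path):
        structure = self._structure(tmp_path)
        table = self._table({999: 5.0})
        with pytest.raises(MappingError):
            export_bfactor(table, "CHOL", structure, tmp_path / "x.pdb")
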