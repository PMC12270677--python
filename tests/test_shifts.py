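import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lariat.shifts import (
    RANDOM_COIL_HA,
    SecondaryShiftProfile,
    ShiftTable,
    classify_proline_shift,
    detect_strand_runs,
    proline_noe_evidence,
    read_shifts,
    secondary_shifts,
    write_shifts,
)


def _table(values, res_names=None):
    """ShiftTable with given αH values keyed by residue number."""
    t = ShiftTable()
    for res, v in values.items():
        name = (res_names or {}).get(res, "ALA")
        t.set(res, name, "HA", v)
    return t


class TestSecondaryShifts:
    def test_reference_values_give_zero(self):
        t = _table({i: RANDOM_COIL_HA["A"] for i in range(1, 11)})
        prof = secondary_shifts(t)
        assert np.allclose(prof.delta, 0.0)
        assert prof.n_positive == 0 and prof.n_negative == 0

    def test_planted_positive_window_flagged(self):
        vals = {i: RANDOM_COIL_HA["A"] - 0.05 for i in range(1, 21)}
        for i in range(11, 16):
            vals[i] = RANDOM_COIL_HA["A"] + 0.3
        prof = secondary_shifts(t := _table(vals))
        assert prof.n_positive == 5
        assert prof.strand_segments == [(11, 15)]

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(-2.0, 2.0))
    def test_linearity_in_constant_offset(self, c):
        base = {i: 4.0 + 0.1 * i for i in range(1, 8)}
        p0 = secondary_shifts(_table(base))
        p1 = secondary_shifts(_table({k: v + c for k, v in base.items()}))
        assert np.allclose(p1.delta, p0.delta + c)

    def test_glycine_averages_both_alpha_protons(self):
        t = ShiftTable()
        t.set(1, "GLY", "HA2", 4.00)
        t.set(1, "GLY", "HA3", 4.20)
        prof = secondary_shifts(t)
        assert prof.delta[0] == pytest.approx(4.10 - RANDOM_COIL_HA["G"])

    def test_residue_missing_from_reference_skipped(self):
        t = _table({1: 4.5, 2: 4.5})
        t.set(3, "XYZ", "HA", 4.5)
        with pytest.warns(UserWarning, match="absent"):
            prof = secondary_shifts(t)
        assert list(prof.residues) == [1, 2]


class TestStrandRuns:
    def _profile(self, deltas, start=1):
        res = np.arange(start, start + len(deltas))
        d = np.asarray(deltas, float)
        return SecondaryShiftProfile(res, d, int((d > 0).sum()), int((d < 0).sum()))

    def test_alternating_signs_no_segments(self):
        prof = self._profile([0.2, -0.2] * 8)
        assert detect_strand_runs(prof, min_run=4) == []

    def test_run_of_five_detected(self):
        prof = self._profile([-0.1, 0.1, 0.1, 0.1, 0.1, 0.1, -0.1])
        assert detect_strand_runs(prof, min_run=4) == [(2, 6)]

    def test_zero_is_not_positive(self):
        prof = self._profile([0.1, 0.1, 0.0, 0.1, 0.1, 0.1, 0.1])
        assert detect_strand_runs(prof, min_run=4) == [(4, 7)]

    def test_numbering_gap_breaks_run(self):
        prof = SecondaryShiftProfile(
            np.array([1, 2, 3, 7, 8, 9, 10]),
            np.array([0.1] * 7), 7, 0)
        assert detect_strand_runs(prof, min_run=4) == [(7, 10)]

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1, 1, allow_nan=False), min_size=1, max_size=40),
           st.integers(2, 6))
    def test_segments_maximal_and_disjoint(self, deltas, min_run):
        prof = self._profile(deltas)
        segs = detect_strand_runs(prof, min_run=min_run)
        d = dict(zip(prof.residues, prof.delta))
        ends = []
        for lo, hi in segs:
            assert hi - lo + 1 >= min_run
            assert all(d[r] > 0 for r in range(lo, hi + 1))
            # maximality: neighbours are absent or non-positive
            assert d.get(lo - 1, 0.0) <= 0.0
            assert d.get(hi + 1, 0.0) <= 0.0
            ends.append((lo, hi))
        for (a1, b1), (a2, b2) in zip(ends, ends[1:]):
            assert b1 < a2


class TestProlineClassifier:
    @pytest.mark.parametrize("delta, expected", [
        (0.0, "trans"), (3.0, "trans"), (4.8, "trans"),
        (4.81, "ambiguous"), (7.03, "ambiguous"), (9.14, "ambiguous"),
        (9.15, "cis"), (10.0, "cis"), (14.4, "cis"),
        (-1.0, "outside_calibration"), (15.0, "outside_calibration"),
    ])
    def test_calibration_intervals(self, delta, expected):
        assert classify_proline_shift(delta) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_proline_shift(float("nan"))


class TestNoeEvidence:
    def test_alpha_delta_peak_means_trans(self):
        peaks = [(1, "HA", 2, "HD2")]
        assert proline_noe_evidence(peaks, 2) == "alpha_delta_trans"

    def test_reversed_atom_order_equivalent(self):
        peaks = [(2, "HD2", 1, "HA")]
        assert proline_noe_evidence(peaks, 2) == "alpha_delta_trans"

    def test_empty_list_gives_none(self):
        assert proline_noe_evidence([], 2) == "none"

    def test_both_peak_types_conflict(self):
        peaks = [(1, "HA", 2, "HD2"), (1, "HA", 2, "HA")]
        assert proline_noe_evidence(peaks, 2) == "conflict"

    def test_non_proline_rejected(self):
        with pytest.raises(ValueError):
            proline_noe_evidence([], 2, res_name="ALA")


def test_profile_plot_written(tmp_path):
    vals = {i: RANDOM_COIL_HA["A"] + (0.3 if 4 <= i <= 8 else -0.1)
            for i in range(1, 13)}
    prof = secondary_shifts(_table(vals))
    out = tmp_path / "profile.svg"
    from lariat.shifts import plot_profile

    plot_profile(prof, out)
    assert out.stat().st_size > 0


class TestIO:
    def _sample(self):
        t = ShiftTable()
        t.set(1, "CYS", "HA", 4.71)
        t.set(2, "PRO", "HA", 4.42)
        t.set(2, "PRO", "CB", 32.1)
        t.set(2, "PRO", "CG", 27.3)
        t.set(3, "GLY", "HA2", 3.9)
        return t

    def test_tsv_roundtrip(self, tmp_path):
        t = self._sample()
        path = tmp_path / "shifts.tsv"
        write_shifts(t, path)
        back = read_shifts(path)
        assert back.shifts == t.shifts
        assert back.res_name == t.res_name

    def test_nmrstar_roundtrip(self, tmp_path):
        t = self._sample()
        path = tmp_path / "shifts.str"
        write_shifts(t, path)
        back = read_shifts(path)
        assert back.shifts == pytest.approx(t.shifts)

    def test_nmrstar_fixture_rows(self, tmp_path):
        path = tmp_path / "three.str"
        path.write_text(
            "data_x\nloop_\n"
            "  _Atom_chem_shift.ID\n  _Atom_chem_shift.Comp_index_ID\n"
            "  _Atom_chem_shift.Comp_ID\n  _Atom_chem_shift.Atom_ID\n"
            "  _Atom_chem_shift.Val\n"
            "  1 1 CYS HA 4.71\n  2 2 PRO CB 32.10\n  3 2 PRO CG 27.30\n"
            "stop_\n")
        t = read_shifts(path)
        assert len(t.shifts) == 3
        assert t.proline_cb_cg(2) == pytest.approx(4.8)

    def test_malformed_row_reports_line(self, tmp_path):
        path = tmp_path / "bad.str"
        path.write_text(
            "data_x\nloop_\n"
            "  _Atom_chem_shift.ID\n  _Atom_chem_shift.Comp_index_ID\n"
            "  _Atom_chem_shift.Comp_ID\n  _Atom_chem_shift.Atom_ID\n"
            "  _Atom_chem_shift.Val\n"
            "  1 1 CYS HA\n"
            "stop_\n")
        with pytest.raises(ValueError, match=":8"):
            read_shifts(path)
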