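import numpy as np
import pytest

from lariat.restraints import (
    DihedralRestraint,
    DistanceRestraint,
    RestraintSet,
    proline_omega_toggle,
    project_restraints,
    read_aco,
    read_restraints_tsv,
    read_upl,
    score_structure,
    write_aco,
    write_restraints_tsv,
    write_upl,
)
from lariat.sequence_mass import parse_sequence
from lariat.structures import StructureEnsemble


def _ca_chain(distances):
    """Linear Cα chain with prescribed consecutive gaps."""
    xs = np.concatenate([[0.0], np.cumsum(distances)])
    coords = np.stack([xs, np.zeros_like(xs), np.zeros_like(xs)], axis=1)
    n = len(xs)
    return StructureEnsemble(
        res_num=np.arange(1, n + 1),
        res_name=np.array(["ALA"] * n),
        atom_name=np.array(["CA"] * n),
        coords=coords,
    )


class TestScore:
    def test_satisfied_restraints_score_zero(self):
        st = _ca_chain([3.8, 3.8])
        rs = RestraintSet(distance=[DistanceRestraint(1, "CA", 3, "CA", 8.0)])
        rep = score_structure(st, rs)
        assert rep.target_function == 0.0
        assert rep.n_violations == 0

    def test_excess_above_cutoff_counts(self):
        st = _ca_chain([3.8])          # distance 3.8
        rs = RestraintSet(distance=[DistanceRestraint(1, "CA", 2, "CA", 3.3)])
        rep = score_structure(st, rs)  # excess 0.5
        assert rep.target_function == pytest.approx(0.25)
        assert rep.n_distance_violations == 1

    def test_excess_below_cutoff_still_contributes(self):
        st = _ca_chain([3.8])
        rs = RestraintSet(distance=[DistanceRestraint(1, "CA", 2, "CA", 3.7)])
        rep = score_structure(st, rs)  # excess 0.1 < 0.2 Å cutoff
        assert rep.target_function == pytest.approx(0.01)
        assert rep.n_violations == 0

    def test_agrees_with_bruteforce_oracle(self, rng):
        # independent per-restraint loop, no shared code path
        n = 12
        coords = rng.normal(scale=6.0, size=(n, 3))
        st = StructureEnsemble(np.arange(1, n + 1), ["ALA"] * n, ["CA"] * n, coords)
        restraints = [
            DistanceRestraint(int(i), "CA", int(j), "CA", float(u))
            for i, j, u in zip(rng.integers(1, n + 1, 40),
                               rng.integers(1, n + 1, 40),
                               rng.uniform(1.0, 12.0, 40))
            if i != j
        ]
        rep = score_structure(st, RestraintSet(distance=restraints))
        tf = viol = 0.0
        for r in restraints:
            d = np.linalg.norm(coords[r.res_i - 1] - coords[r.res_j - 1])
            excess = max(0.0, d - r.upper)
            tf += excess ** 2
            viol += excess > 0.2
        assert rep.target_function == pytest.approx(tf)
        assert rep.n_distance_violations == viol

    def test_rigid_motion_invariance(self, rng):
        from scipy.spatial.transform import Rotation

        st = _ca_chain([3.8, 3.8, 3.8])
        rs = RestraintSet(distance=[DistanceRestraint(1, "CA", 4, "CA", 7.0)])
        base = score_structure(st, rs).target_function
        R = Rotation.random(random_state=7).as_matrix()
        moved = st.with_coords(st.coords @ R.T + rng.normal(size=3))
        assert score_structure(moved, rs).target_function == pytest.approx(base)

    def test_monotone_under_bound_tightening(self):
        st = _ca_chain([3.8, 3.8])
        tfs = [
            score_structure(
                st, RestraintSet(distance=[DistanceRestraint(1, "CA", 3, "CA", u)])
            ).target_function
            for u in (8.0, 7.0, 6.0, 5.0)
        ]
        assert all(b >= a for a, b in zip(tfs, tfs[1:]))

    def test_unresolvable_atom_named(self):
        st = _ca_chain([3.8])
        rs = RestraintSet(distance=[DistanceRestraint(1, "HA", 2, "CA", 5.0)])
        with pytest.raises(ValueError, match="HA"):
            score_structure(st, rs)

    def test_quadratic_in_excess(self):
        # doubling the excess quadruples the penalty
        st1 = _ca_chain([4.0])
        st2 = _ca_chain([4.2])
        rs = RestraintSet(distance=[DistanceRestraint(1, "CA", 2, "CA", 3.8)])
        tf1 = score_structure(st1, rs).target_function
        tf2 = score_structure(st2, rs).target_function
        assert tf2 / tf1 == pytest.approx(4.0)


class TestOmega:
    def test_toggle_is_involution(self):
        seq = parse_sequence("CPDAVYTC")
        rs = RestraintSet(dihedral=[DihedralRestraint(2, "omega", 170.0, -170.0)])
        back = proline_omega_toggle(
            proline_omega_toggle(rs, 2, "cis", seq), 2, "trans", seq)
        assert back.dihedral == rs.dihedral

    def test_cis_range_centred_at_zero(self):
        seq = parse_sequence("CPDAVYTC")
        out = proline_omega_toggle(RestraintSet(), 2, "cis", seq)
        (dr,) = out.dihedral
        assert dr.lower == -10.0 and dr.upper == 10.0

    def test_non_proline_rejected(self):
        seq = parse_sequence("CPDAVYTC")
        with pytest.raises(ValueError, match="not proline"):
            proline_omega_toggle(RestraintSet(), 3, "cis", seq)

    def test_cis_toggle_penalizes_trans_geometry(self):
        # a trans-built chain (3.8 Å virtual bonds) scores worse under a cis
        # omega restraint than under a trans one
        st = _ca_chain([3.8, 3.8])
        seq = parse_sequence("APA")
        cis = proline_omega_toggle(RestraintSet(), 2, "cis", seq)
        trans = proline_omega_toggle(RestraintSet(), 2, "trans", seq)
        tf_cis = score_structure(st, cis).target_function
        tf_trans = score_structure(st, trans).target_function
        assert tf_cis > tf_trans
        assert tf_trans == 0.0


class TestProjection:
    def test_non_coarse_atoms_padded_onto_ca(self):
        seq = parse_sequence("ACDEF")
        rs = RestraintSet(distance=[DistanceRestraint(1, "HA", 4, "HN", 5.0)])
        out = project_restraints(rs, seq)
        (r,) = out.distance
        assert (r.atom_i, r.atom_j) == ("CA", "CA")
        assert r.upper == pytest.approx(5.0 + 3.0)

    def test_coarse_atoms_untouched(self):
        seq = parse_sequence("CCDEF")
        rs = RestraintSet(distance=[DistanceRestraint(1, "SG", 4, "CA", 4.0)])
        out = project_restraints(rs, seq)
        assert out.distance == rs.distance


class TestIO:
    def test_upl_roundtrip(self, tmp_path):
        seq = parse_sequence("CPDAVYTC")
        restraints = [DistanceRestraint(1, "CA", 8, "SG", 5.5),
                      DistanceRestraint(2, "CA", 7, "CA", 4.25)]
        path = tmp_path / "test.upl"
        write_upl(restraints, path, seq)
        assert read_upl(path) == restraints

    def test_aco_roundtrip(self, tmp_path):
        seq = parse_sequence("CPDAVYTC")
        restraints = [DihedralRestraint(2, "omega", -10.0, 10.0),
                      DihedralRestraint(3, "phi", -120.0, -60.0)]
        path = tmp_path / "test.aco"
        write_aco(restraints, path, seq)
        assert read_aco(path) == restraints

    def test_tsv_roundtrip(self, tmp_path):
        rs = RestraintSet(
            distance=[DistanceRestraint(1, "CA", 8, "SG", 5.5, hbond=True)],
            dihedral=[DihedralRestraint(2, "omega", 170.0, -170.0)],
        )
        path = tmp_path / "restraints.tsv"
        write_restraints_tsv(rs, path)
        back = read_restraints_tsv(path)
        assert back.distance == rs.distance
        assert back.dihedral == rs.dihedral

    def test_malformed_upl_reports_line(self, tmp_path):
        path = tmp_path / "bad.upl"
        path.write_text("1 CYS CA 8\n")
        with pytest.raises(ValueError, match=":1"):
            read_upl(path)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            DistanceRestraint(1, "CA", 2, "CA", -1.0)
        with pytest.raises(ValueError):
            DihedralRestraint(1, "omega", 400.0, 10.0)
        with pytest.raises(ValueError):
            DihedralRestraint(1, "tau", 0.0, 10.0)
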