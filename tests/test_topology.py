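import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from lariat.connectivity import DisulfideConnectivity
from lariat.synthetic import make_threaded_lariats, mirror
from lariat.topology import (
    classify_dlk,
    close_curve,
    decompose_lariats,
    gauss_linking_number,
    linking_number,
    loop_handedness,
)


def circle(radius=1.0, center=(0, 0, 0), normal="z", n=64):
    t = np.linspace(0.0, 2.0 * np.pi, n)
    if normal == "z":
        pts = np.stack([np.cos(t), np.sin(t), np.zeros_like(t)], 1)
    else:
        pts = np.stack([np.cos(t), np.zeros_like(t), np.sin(t)], 1)
    return radius * pts + np.asarray(center, float)


def fourier_loop(rng, n=60, scale=3.0):
    """Random smooth closed curve from a low-order Fourier series."""
    t = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    pts = np.zeros((n, 3))
    for k in range(1, 4):
        a = rng.normal(scale=scale / k, size=3)
        b = rng.normal(scale=scale / k, size=3)
        pts += np.outer(np.cos(k * t), a) + np.outer(np.sin(k * t), b)
    return np.vstack([pts, pts[:1]])


class TestLinkingNumber:
    def test_separated_squares_unlinked(self):
        sq = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0], [0, 0, 0]], float)
        assert linking_number(sq, sq + np.array([5.0, 0, 0])) == 0

    def test_hopf_link_is_unit(self):
        a = circle(normal="z")
        b = circle(center=(1, 0, 0), normal="y")
        lk, residual = linking_number(a, b, return_residual=True)
        assert abs(lk) == 1
        assert residual < 1e-3
        # numeric Gauss double-integral oracle at fine discretization
        assert round(gauss_linking_number(a, b, subdivide=6)) == lk

    def test_mirror_flips_sign(self):
        a = circle(normal="z")
        b = circle(center=(1, 0, 0), normal="y")
        am, bm = a.copy(), b.copy()
        am[:, 0] *= -1
        bm[:, 0] *= -1
        assert linking_number(am, bm) == -linking_number(a, b)

    def test_agrees_with_gauss_oracle_on_random_pairs(self):
        from lariat.topology import curve_separation

        rng = np.random.default_rng(2025)
        checked = 0
        while checked < 50:
            a = fourier_loop(rng)
            b = fourier_loop(rng) + rng.normal(scale=2.0, size=3)
            if curve_separation(a, b) < 0.4:
                continue  # below the oracle's discretization scale
            try:
                lk = linking_number(a, b)
            except ValueError:
                continue
            gauss = gauss_linking_number(a, b, subdivide=4)
            if abs(gauss - round(gauss)) > 0.05:
                continue
            assert lk == round(gauss)
            checked += 1

    def test_rigid_motion_and_scale_invariance(self):
        a = circle(normal="z")
        b = circle(center=(1, 0, 0), normal="y")
        base = linking_number(a, b)
        R = Rotation.from_rotvec([0.4, 0.2, -0.9]).as_matrix()
        t = np.array([3.0, -2.0, 7.0])
        assert linking_number(a @ R.T + t, b @ R.T + t) == base
        assert linking_number(2.5 * a, 2.5 * b) == base

    def test_subdivision_invariance(self):
        from lariat.topology import _subdivided

        a = circle(normal="z", n=20)
        b = circle(center=(1, 0, 0), normal="y", n=20)
        assert (linking_number(_subdivided(a, 4), _subdivided(b, 4))
                == linking_number(a, b))

    def test_touching_curves_rejected(self):
        a = circle(normal="z")
        with pytest.raises(ValueError, match="perturb"):
            linking_number(a, a + np.array([0.0, 0.0, 1e-9]))

    def test_open_curve_closed_automatically(self):
        # an arc threading a loop once links it after lasso closure
        a = circle(radius=2.0, normal="z")
        arc = np.array([[0.0, 0.0, -4.0], [0.0, 0.0, 4.0]])
        assert abs(linking_number(a, arc)) == 1

    def test_closure_keeps_curve_closed(self):
        a = circle(radius=2.0, normal="z")
        arc = np.array([[0.0, 0.0, -4.0], [0.1, 0.0, 4.0]])
        closed = close_curve(arc, a)
        assert np.allclose(closed[0], closed[-1])


class TestHandedness:
    @staticmethod
    def helix(sense=+1, n=40):
        s = np.linspace(0.0, 4.0 * np.pi, n)
        return np.stack([np.cos(s), sense * np.sin(s), 0.4 * s], 1)

    def test_right_handed_helix(self):
        assert loop_handedness(self.helix(+1)) == "right"

    def test_left_handed_helix(self):
        assert loop_handedness(self.helix(-1)) == "left"

    def test_mirror_flips_verdict(self):
        h = self.helix(+1)
        m = h.copy()
        m[:, 0] *= -1
        assert {loop_handedness(h), loop_handedness(m)} == {"right", "left"}

    def test_planar_loop_indeterminate(self):
        assert loop_handedness(circle(n=16)[:-1]) == "indeterminate"

    def test_rotation_translation_invariant(self):
        h = self.helix(+1)
        R = Rotation.from_rotvec([1.0, -0.3, 0.2]).as_matrix()
        assert loop_handedness(h @ R.T + np.array([4.0, 5.0, -6.0])) == "right"

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            loop_handedness(np.zeros((3, 3)))


class TestLariats:
    def test_loop_spans_follow_connectivity_not_coordinates(self, rng):
        from lariat.structures import StructureEnsemble

        n = 12
        for _ in range(3):
            coords = rng.normal(scale=8.0, size=(n + 2, 3))
            res_num = list(range(1, n + 1)) + [2, 9]
            res_name = ["CYS" if r in (2, 9) else "ALA" for r in res_num]
            atom_name = ["CA"] * n + ["SG", "SG"]
            st = StructureEnsemble(res_num, res_name, atom_name, coords)
            lar = decompose_lariats(st, DisulfideConnectivity(((2, 9),)))
            assert len(lar) == 1
            assert lar[0].loop_residues == (2, 9)
            assert len(lar[0].tail_paths) == 2

    def test_two_cysteine_chain_tails_are_flanks(self, rng):
        from lariat.structures import StructureEnsemble

        coords = np.vstack([rng.normal(scale=6.0, size=(8, 3)),
                            rng.normal(scale=6.0, size=(2, 3))])
        res_num = [1, 2, 3, 4, 5, 6, 7, 8, 3, 6]
        res_name = ["CYS" if r in (3, 6) else "GLY" for r in res_num]
        atom_name = ["CA"] * 8 + ["SG", "SG"]
        st = StructureEnsemble(res_num, res_name, atom_name, coords)
        (lar,) = decompose_lariats(st, DisulfideConnectivity(((3, 6),)))
        assert np.allclose(lar.loop_path[0], lar.loop_path[-1])
        assert len(lar.tail_paths) == 2

    def test_granulin_spans(self, reference_structure):
        conn = DisulfideConnectivity(((1, 14), (8, 23), (15, 24)))
        lar = decompose_lariats(reference_structure, conn)
        assert [l.loop_residues for l in lar] == [(1, 14), (8, 23), (15, 24)]


class TestDLK:
    def test_threaded_toy_is_dlk(self):
        st, truth = make_threaded_lariats(threaded=True, seed=0)
        lariats = decompose_lariats(st, truth["connectivity"])
        dlk, pairs, M = classify_dlk(lariats)
        assert dlk is True
        assert (0, 1) in pairs and (1, 0) in pairs

    def test_unthreaded_toy_is_not_dlk(self):
        st, truth = make_threaded_lariats(threaded=False, seed=0)
        lariats = decompose_lariats(st, truth["connectivity"])
        dlk, _, M = classify_dlk(lariats)
        assert dlk is False
        assert not M.any()

    def test_mirrored_toy_still_dlk(self):
        st, truth = make_threaded_lariats(threaded=True, seed=1)
        lariats = decompose_lariats(mirror(st), truth["connectivity"])
        assert classify_dlk(lariats)[0] is True
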