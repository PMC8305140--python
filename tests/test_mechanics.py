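"""Cell mechanics: pair forces, BM coupling, apical links, volumes, motion."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial import cKDTree

from cryptsim import mechanics as M
from cryptsim.mechanics import ForceParams


@pytest.fixture
def fp():
    return ForceParams()


def sphere_volume(R):
    return 4.0 / 3.0 * np.pi * R ** 3


class TestPairForce:
    def test_repulsion_vanishes_at_contact(self, fp):
        Ra = Rb = 3.5
        # at exact contact only the (attractive) adhesion tail remains
        f = M.pair_force(Ra + Rb, Ra, Rb, fp)
        assert f <= 0.0

    def test_overlapping_cells_repel(self, fp):
        Ra = Rb = 3.5
        f = M.pair_force(0.8 * (Ra + Rb), Ra, Rb, fp)
        assert f > 0

    def test_zero_beyond_cutoff(self, fp):
        Ra = Rb = 3.5
        assert M.pair_force(1.25 * (Ra + Rb), Ra, Rb, fp) == 0.0

    def test_adhesive_well_in_shell(self, fp):
        Ra = Rb = 3.5
        d = 1.1 * (Ra + Rb)
        assert M.pair_force(d, Ra, Rb, fp) < 0.0

    def test_force_is_negative_potential_gradient(self, fp):
        rng = np.random.default_rng(5)
        Ra, Rb = 3.0, 4.0
        eps = 1e-7
        for d in rng.uniform(0.3 * (Ra + Rb), 1.3 * (Ra + Rb), 20):
            fd = -(M.pair_potential(d + eps, Ra, Rb, fp)
                   - M.pair_potential(d - eps, Ra, Rb, fp)) / (2 * eps)
            assert M.pair_force(d, Ra, Rb, fp) == pytest.approx(
                fd, abs=1e-6 * fp.k_rep)


class TestCellCellForces:
    def test_antisymmetric_pairs(self, fp):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 12, (15, 3))
        radii = np.full(15, 3.5)
        pairs = M.contact_pairs(pos, radii)
        F = M.cell_cell_forces(pos, radii, pairs, fp)
        assert np.linalg.norm(F.sum(axis=0)) < 1e-9 * max(
            np.abs(F).max(), 1.0)

    def test_overlap_pushes_apart(self, fp):
        pos = np.array([[0.0, 0, 0], [5.0, 0, 0]])
        radii = np.array([3.5, 3.5])
        pairs = np.array([[0, 1]])
        F = M.cell_cell_forces(pos, radii, pairs, fp)
        assert F[0, 0] < 0 and F[1, 0] > 0

    def test_coincident_centres_resolved(self, fp):
        pos = np.zeros((2, 3))
        radii = np.array([3.5, 3.5])
        pairs = np.array([[0, 1]])
        rng = np.random.default_rng(0)
        F = M.cell_cell_forces(pos, radii, pairs, fp, rng)
        assert np.all(np.isfinite(F))
        assert np.abs(F).max() > 0


class TestCellBMForces:
    def make_plane(self, n=7, spacing=4.0):
        xs, ys = np.meshgrid(np.arange(n) * spacing, np.arange(n) * spacing)
        knots = np.stack([xs.ravel(), ys.ravel(), np.zeros(n * n)], axis=1)
        normals = np.tile([0.0, 0.0, 1.0], (n * n, 1))
        return knots, normals

    def test_zero_force_at_rest_height(self, fp):
        knots, normals = self.make_plane()
        centre = knots[24]  # middle knot
        R = 3.5
        pos = (centre + np.array([0, 0, R]))[None, :]
        tree = cKDTree(knots)
        Fc, Fk, att = M.cell_bm_forces(
            pos, np.array([24]), knots, tree, fp,
            knot_normals=normals, rest_height=R, side=np.array([1.0]))
        # adhesion balanced; only planar-symmetric knot repulsion along z
        assert abs(Fc[0, 0]) < 1e-9 and abs(Fc[0, 1]) < 1e-9
        assert att[0] == 24

    def test_normal_displacement_restores(self, fp):
        knots, normals = self.make_plane()
        R = 3.5
        tree = cKDTree(knots)

        def adhesion_z(height):
            pos = (knots[24] + np.array([0, 0, height]))[None, :]
            # suppress knot repulsion to isolate the tether
            quiet = ForceParams(**{**fp.__dict__, "k_bm_rep": 1e-12})
            Fc, _, _ = M.cell_bm_forces(
                pos, np.array([24]), knots, tree, quiet,
                knot_normals=normals, rest_height=R, side=np.array([1.0]))
            return Fc[0, 2]

        assert adhesion_z(R + 1.0) < 0   # pulled back toward the membrane
        assert adhesion_z(R - 1.0) > 0   # pushed away from the plane
        assert adhesion_z(R) == pytest.approx(0.0, abs=1e-12)

    def test_momentum_bookkeeping(self, fp):
        rng = np.random.default_rng(9)
        knots, normals = self.make_plane()
        tree = cKDTree(knots)
        pos = rng.uniform(5, 19, (10, 3))
        pos[:, 2] = rng.uniform(1.0, 4.0, 10)
        attach = tree.query(pos)[1]
        Fc, Fk, _ = M.cell_bm_forces(
            pos, attach, knots, tree, fp, knot_normals=normals,
            rest_height=3.5, side=np.ones(10))
        total = Fc.sum(axis=0) + Fk.sum(axis=0)
        scale = max(np.abs(Fc).max(), np.abs(Fk).max())
        assert np.linalg.norm(total) < 1e-12 * max(scale, 1.0)

    def test_reattachment_on_stretch(self, fp):
        knots, normals = self.make_plane()
        tree = cKDTree(knots)
        # cell far from its stale attachment knot hops to the nearest one
        pos = (knots[30] + np.array([0, 0, 2.0]))[None, :]
        Fc, Fk, att = M.cell_bm_forces(
            pos, np.array([0]), knots, tree, fp,
            knot_normals=normals, rest_height=3.5, side=np.array([1.0]))
        assert att[0] == 30


class TestApicalForces:
    def test_zero_at_rest_length(self, fp):
        R = 3.5
        d = fp.s_apical * 2 * R
        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        F = M.apical_forces(pos, np.array([R, R]), np.array([[0, 1]]),
                            np.zeros(2, bool), fp)
        assert np.abs(F).max() < 1e-12

    def test_stretched_ring_contracts(self, fp):
        R = 3.5
        rest = fp.s_apical * 2 * R
        # 6 cells on a ring whose neighbour spacing is 10% above rest
        ring_r = 1.1 * rest
        ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
        pos = np.stack([ring_r * np.cos(ang), ring_r * np.sin(ang),
                        np.zeros(6)], axis=1)
        links = np.array([[i, (i + 1) % 6] for i in range(6)])
        F = M.apical_forces(pos, np.full(6, R), links, np.zeros(6, bool), fp)
        radial = np.einsum("ij,ij->i", F, pos / np.linalg.norm(
            pos, axis=1, keepdims=True))
        assert np.all(radial < 0)  # net inward contraction on each cell

    def test_shrinking_partner_amplifies_contraction(self, fp):
        R = 3.5
        d = 1.05 * fp.s_apical * 2 * R
        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        radii = np.array([R, R])
        links = np.array([[0, 1]])
        f_normal = M.apical_forces(pos, radii, links,
                                   np.array([False, False]), fp)
        f_shrink = M.apical_forces(pos, radii, links,
                                   np.array([False, True]), fp)
        # inward pull on cell 0 strictly stronger toward the dying cell
        assert f_shrink[0, 0] > f_normal[0, 0] > 0


class TestActualVolume:
    def test_isolated_cell_uncompressed(self):
        VT = np.array([180.0])
        VA = M.actual_volume(VT, np.array([3.5]), np.zeros((1, 3)),
                             np.empty((0, 2), dtype=int))
        assert VA[0] == VT[0]

    def test_two_spheres_monte_carlo(self):
        # own-cap subtraction: V_A = V_T - own cap beyond the radical
        # plane; oracle = Monte-Carlo estimate of the exclusive volume
        rng = np.random.default_rng(123)
        R = 3.5
        d = 5.0
        VT = np.array([sphere_volume(R)] * 2)
        pos = np.array([[0.0, 0, 0], [d, 0, 0]])
        VA = M.actual_volume(VT, np.array([R, R]), pos,
                             np.array([[0, 1]]))
        n = 1_000_000
        pts = rng.uniform(-R, R, (n, 3))
        inside = np.linalg.norm(pts, axis=1) < R
        other = np.linalg.norm(pts - np.array([d, 0, 0]), axis=1) < R
        exclusive = np.sum(inside & ~other) + 0.5 * np.sum(inside & other)
        mc = exclusive / n * (2 * R) ** 3
        assert VA[0] == pytest.approx(mc, rel=0.01)

    def test_membrane_plane_cut(self):
        R = 3.5
        VT = np.array([sphere_volume(R)])
        # centre 1 um from the membrane plane: lose the cap beyond it
        VA = M.actual_volume(VT, np.array([R]), np.zeros((1, 3)),
                             np.empty((0, 2), dtype=int),
                             plane_dist=np.array([1.0]))
        h = 1.0
        cap = np.pi * (R - h) ** 2 * (2 * R + h) / 3.0
        assert VA[0] == pytest.approx(VT[0] - cap, rel=1e-12)

    def test_floor_at_tenth_of_target(self):
        R = 3.5
        VT = np.array([sphere_volume(R)] * 4)
        pos = np.zeros((4, 3))
        pos[1:, 0] = 0.5  # three deeply overlapping neighbours
        pairs = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
        VA = M.actual_volume(VT, np.full(4, R), pos, pairs)
        assert np.all(VA >= 0.1 * VT - 1e-12)

    def test_never_exceeds_target(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(0, 10, (20, 3))
        radii = rng.uniform(2.5, 4.0, 20)
        VT = sphere_volume(radii)
        pairs = M.contact_pairs(pos, radii)
        VA = M.actual_volume(VT, radii, pos, pairs)
        assert np.all(VA <= VT + 1e-12)


class TestIntegrateMotion:
    def test_zero_force_keeps_positions(self):
        pos = np.arange(12.0).reshape(4, 3)
        out = M.integrate_motion(pos, np.zeros_like(pos), 1.0, 0.1)
        np.testing.assert_array_equal(out, pos)

    def test_frozen_entities_do_not_move(self):
        pos = np.zeros((2, 3))
        F = np.ones((2, 3))
        frozen = np.array([True, False])
        out = M.integrate_motion(pos, F, 1.0, 0.1, frozen=frozen)
        np.testing.assert_array_equal(out[0], pos[0])
        assert np.all(out[1] != pos[1])

    def test_unstable_step_aborts(self):
        pos = np.zeros((1, 3))
        F = np.array([[1000.0, 0, 0]])
        with pytest.raises(RuntimeError, match="unstable"):
            M.integrate_motion(pos, F, 1.0, 0.1, max_step=3.5)

    def test_pair_relaxes_to_force_balance(self, fp):
        """Two adhering cells released from overlap settle at the zero of
        the pair force law (root-finder oracle)."""
        R = 3.5
        radii = np.array([R, R])
        pos = np.array([[0.0, 0, 0], [0.8 * 2 * R, 0, 0]])
        pairs = np.array([[0, 1]])
        for _ in range(8000):
            F = M.cell_cell_forces(pos, radii, pairs, fp)
            pos = M.integrate_motion(pos, F, fp.gamma, fp.dt_mech)
        d_final = np.linalg.norm(pos[1] - pos[0])
        d_star = brentq(lambda d: M.pair_force(d, R, R, fp),
                        0.5 * 2 * R, 1.199 * 2 * R)
        assert d_final == pytest.approx(d_star, abs=1e-3)

    def test_halving_dt_converges(self, fp):
        R = 3.5
        radii = np.array([R, R])

        def relax(dt):
            pos = np.array([[0.0, 0, 0], [5.5, 0, 0]])
            pairs = np.array([[0, 1]])
            for _ in range(int(40.0 / dt)):
                F = M.cell_cell_forces(pos, radii, pairs, fp)
                pos = M.integrate_motion(pos, F, fp.gamma, dt)
            return pos

        d = np.linalg.norm(relax(0.02) - relax(0.01))
        assert d < 1e-3


def test_contact_graph_matches_bruteforce():
    rng = np.random.default_rng(17)
    for _ in range(5):
        pos = rng.uniform(0, 25, (40, 3))
        radii = rng.uniform(2.0, 4.5, 40)
        pairs = {tuple(p) for p in M.contact_pairs(pos, radii)}
        brute = set()
        for i in range(40):
            for j in range(i + 1, 40):
                if np.linalg.norm(pos[i] - pos[j]) < 1.2 * (radii[i] + radii[j]):
                    brute.add((i, j))
        assert pairs == brute
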