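"""Registration building blocks: correspondence, rigid alignment, Newmark
integration, and the energy terms checked against independent brute-force
oracles."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import skinstrain.registration as reg
from skinstrain import (FrameState, RegistrationParams, SimConfig,
                        closest_points, generate_sequence, match_markers,
                        newmark_update, rigid_prealign)
from skinstrain.mesh import MarkerSet, markers_at


@pytest.fixture(scope="module")
def tiny_tube():
    """10-vertex tube (5 around x 2 along) for exhaustive energy checks."""
    cfg = SimConfig(n_frames=2, n_circumferential=5, n_axial=2, n_markers=3,
                    noise_sigma_mm=0.0, seed=0)
    return generate_sequence(cfg)


def random_state(n, rng, dT=0.01, scale=0.05):
    """A FrameState with small random transforms and derivatives."""
    s = FrameState.identity(n, dT)
    s.T = s.T + rng.normal(0, scale, (n, 3, 3))
    s.t = rng.normal(0, scale * 10, (n, 3))
    s.T_dot = rng.normal(0, scale, (n, 3, 3))
    s.t_dot = rng.normal(0, scale * 10, (n, 3))
    s.T_ddot = rng.normal(0, scale, (n, 3, 3))
    s.t_ddot = rng.normal(0, scale * 10, (n, 3))
    return s


class TestCorrespondence:
    def test_identity_clouds(self, rng):
        pts = rng.normal(size=(50, 3))
        np.testing.assert_array_equal(closest_points(pts, pts), np.arange(50))

    def test_matches_exhaustive_search(self, rng):
        target = rng.normal(size=(200, 3))
        query = rng.normal(size=(300, 3))
        idx = closest_points(query, target)
        d = np.linalg.norm(query[:, None] - target[None], axis=2)
        np.testing.assert_array_equal(idx, d.argmin(axis=1))

    def test_two_point_target(self):
        target = np.array([[0, 0, 0], [10, 0, 0.0]])
        assert closest_points(np.array([[7.0, 0, 0]]), target)[0] == 1


class TestMarkerMatching:
    def _sets(self, pos_a, pos_b):
        return (MarkerSet(np.arange(len(pos_a)), pos_a),
                MarkerSet(np.arange(len(pos_b)), pos_b))

    def test_identical_sets_identity_pairing(self, rng):
        p = rng.normal(size=(8, 3)) * 20
        a, b = self._sets(p, p.copy())
        pairs, med = match_markers(a, b)
        np.testing.assert_array_equal(pairs[:, 0], pairs[:, 1])
        assert med == 0.0

    def test_uniform_translation_all_paired(self, rng):
        p = rng.normal(size=(8, 3)) * 20
        a, b = self._sets(p, p + [1.0, 0, 0])
        pairs, med = match_markers(a, b, prev_median_distance=5.0 / 3, factor=3.0)
        assert len(pairs) == 8
        assert med == pytest.approx(1.0)

    def test_outlier_pair_excluded(self, rng):
        p = rng.normal(size=(8, 3)) * 20
        q = p.copy()
        q[3] += 50.0  # gross mismatch
        a, b = self._sets(p, q)
        pairs, _ = match_markers(a, b, prev_median_distance=5.0 / 3,
                                 factor=3.0)
        assert 3 not in pairs[:, 0]
        assert len(pairs) == 7

    def test_mutual_nn_matches_bruteforce(self, rng):
        p = rng.normal(size=(10, 3)) * 10
        q = rng.normal(size=(12, 3)) * 10
        a, b = self._sets(p, q)
        pairs, _ = match_markers(a, b, prev_median_distance=np.inf)
        d = np.linalg.norm(p[:, None] - q[None], axis=2)
        expect = {(i, d[i].argmin()) for i in range(10)
                  if d[:, d[i].argmin()].argmin() == i}
        assert {tuple(r) for r in pairs} == expect


class TestRigidPrealign:
    def test_identity_when_aligned(self, tiny_tube):
        R, t = rigid_prealign(tiny_tube.template, tiny_tube.template)
        np.testing.assert_allclose(R, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_recovers_known_transform_exactly(self, tiny_tube):
        mesh = tiny_tube.template
        R_true = Rotation.from_rotvec([0.05, -0.08, 0.1]).as_matrix()
        t_true = np.array([2.0, -1.0, 3.0])
        target = mesh.with_vertices(mesh.vertices @ R_true.T + t_true)
        mi = np.arange(mesh.n_vertices)  # every vertex as a known marker
        R, t = rigid_prealign(mesh, target,
                              marker_pairs=(mi, target.vertices))
        np.testing.assert_allclose(R, R_true, atol=1e-6)
        np.testing.assert_allclose(t, t_true, atol=1e-6)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-9)

    def test_rotation_recovered_under_noise(self, rng):
        cfg = SimConfig(n_frames=2, n_circumferential=24, n_axial=40,
                        noise_sigma_mm=0.0, seed=1)
        mesh = generate_sequence(cfg).template
        R_true = Rotation.from_rotvec([0.03, 0.02, -0.04]).as_matrix()
        noisy = mesh.vertices @ R_true.T + rng.normal(0, 0.5,
                                                      mesh.vertices.shape)
        target = mesh.with_vertices(noisy)
        mi = np.arange(0, mesh.n_vertices, 7)
        R, _ = rigid_prealign(mesh, target, marker_pairs=(mi, noisy[mi]))
        err = Rotation.from_matrix(R_true.T @ R).magnitude()
        assert np.degrees(err) < 0.5

    def test_collinear_correspondences_raise(self):
        from skinstrain import SurfaceMesh
        line = np.stack([np.linspace(0, 10, 8), np.zeros(8), np.zeros(8)], 1)
        mesh = SurfaceMesh(line, np.array([[0, 1, 2]]))
        with pytest.raises(ValueError, match="degenerate|rank"):
            rigid_prealign(mesh, mesh)


class TestNewmark:
    def test_rest_state_unchanged(self):
        prev = FrameState.identity(4, 0.01)
        T, t, Td, td = newmark_update(prev, np.zeros((4, 3, 3)),
                                      np.zeros((4, 3)), 0.25, 0.5, 0.01)
        np.testing.assert_array_equal(T, prev.T)
        np.testing.assert_array_equal(t, 0.0)
        np.testing.assert_array_equal(Td, 0.0)
        np.testing.assert_array_equal(td, 0.0)

    @pytest.mark.parametrize("beta,gamma", [(0.0, 0.0), (0.25, 0.5),
                                            (0.4, 0.9), (0.5, 1.0)])
    def test_exact_for_constant_acceleration(self, beta, gamma, rng):
        # closed form x(t) = x0 + v0 t + a t^2 / 2 for any (beta, gamma)
        dT = 0.01
        a_const = rng.normal(size=(3, 3))
        state = FrameState.identity(3, dT)
        state.t = rng.normal(size=(3, 3))
        state.t_dot = rng.normal(size=(3, 3))
        state.t_ddot = a_const.copy()
        x0, v0 = state.t.copy(), state.t_dot.copy()
        for k in range(1, 6):
            _, t, _, td = newmark_update(state, np.zeros((3, 3, 3)), a_const,
                                         beta, gamma, dT)
            state.t, state.t_dot = t, td
            tt = k * dT
            np.testing.assert_allclose(t, x0 + v0 * tt + 0.5 * a_const * tt**2,
                                       rtol=1e-12, atol=1e-14)
            np.testing.assert_allclose(td, v0 + a_const * tt, rtol=1e-12)

    def test_explicit_scheme_at_beta_gamma_zero(self, rng):
        dT = 0.02
        prev = FrameState.identity(2, dT)
        prev.t = rng.normal(size=(2, 3))
        prev.t_dot = rng.normal(size=(2, 3))
        prev.t_ddot = rng.normal(size=(2, 3))
        current_acc = rng.normal(size=(2, 3))  # must be ignored
        _, t, _, td = newmark_update(prev, np.zeros((2, 3, 3)), current_acc,
                                     0.0, 0.0, dT)
        np.testing.assert_allclose(
            t, prev.t + dT * prev.t_dot + 0.5 * dT**2 * prev.t_ddot, rtol=1e-12)
        np.testing.assert_allclose(td, prev.t_dot + dT * prev.t_ddot,
                                   rtol=1e-12)


class TestEnergyOracles:
    """Each energy term vs an independent term-by-term evaluation."""

    def test_closest_point_energy(self, tiny_tube, rng):
        mesh = tiny_tube.template
        n = mesh.n_vertices
        state = random_state(n, rng)
        target = mesh.with_vertices(mesh.vertices + rng.normal(0, 0.3, (n, 3)))
        corr = rng.integers(0, n, n)
        val = reg.energy_closest(state, mesh, target, corr, np.eye(3))
        # brute force (identity rigid pose, so x_hat = x)
        expect = 0.0
        for i in range(n):
            x, nrm = mesh.vertices[i], mesh.normals[i]
            y = target.vertices[corr[i]]
            y_t = x + np.dot(nrm, y - x) * nrm
            r = state.T[i] @ x + state.t[i] - y_t
            expect += r @ r
        assert val == pytest.approx(expect, rel=1e-10)

    def test_tangential_displacement_annihilated(self, tiny_tube):
        mesh = tiny_tube.template
        n = mesh.n_vertices
        state = FrameState.identity(n, 0.01)
        # offset every target vertex strictly tangentially to the template
        tangents = np.cross(mesh.normals, [0.0, 0.0, 1.0])
        tangents /= np.linalg.norm(tangents, axis=1)[:, None]
        target = mesh.with_vertices(mesh.vertices + 0.5 * tangents)
        val = reg.energy_closest(state, mesh, target, np.arange(n), np.eye(3))
        assert val == pytest.approx(0.0, abs=1e-18)

    def test_pure_normal_displacement_squared(self, tiny_tube):
        mesh = tiny_tube.template
        n = mesh.n_vertices
        state = FrameState.identity(n, 0.01)
        delta = 0.37
        target = mesh.with_vertices(mesh.vertices + delta * mesh.normals)
        val = reg.energy_closest(state, mesh, target, np.arange(n), np.eye(3))
        assert val == pytest.approx(n * delta**2, rel=1e-10)

    def test_feature_energy(self, tiny_tube, rng):
        mesh = tiny_tube.template
        state = random_state(mesh.n_vertices, rng)
        mi = np.array([0, 3, 7])
        q = mesh.vertices[mi] + rng.normal(0, 1, (3, 3))
        val = reg.energy_feature(state, mesh, mi, q)
        expect = sum(
            np.sum((state.T[i] @ mesh.vertices[i] + state.t[i] - q[j]) ** 2)
            for j, i in enumerate(mi))
        assert val == pytest.approx(expect, rel=1e-10)

    def test_spatial_energies(self, tiny_tube, rng):
        mesh = tiny_tube.template
        n = mesh.n_vertices
        state = random_state(n, rng)
        e_acap, e_cons, e_sm = reg.energy_spatial(state, mesh)
        # ACAP via per-vertex SVD closed form
        exp_acap = 0.0
        for i in range(n):
            U, S, Vt = np.linalg.svd(state.T[i])
            d = np.sign(np.linalg.det(U @ Vt))
            s = (S[0] + S[1] + d * S[2]) / 3.0
            R = U @ np.diag([1, 1, d]) @ Vt
            exp_acap += np.sum((state.T[i] - s * R) ** 2)
        assert e_acap == pytest.approx(exp_acap, rel=1e-10)
        rings = mesh.one_ring()
        exp_cons = exp_sm = 0.0
        for i in range(n):
            for j in rings[i]:
                x = mesh.vertices[j]
                d = (state.T[i] @ x + state.t[i]) - (state.T[j] @ x + state.t[j])
                exp_cons += d @ d
                exp_sm += np.sum((state.T[i] - state.T[j]) ** 2)
                exp_sm += np.sum((state.t[i] - state.t[j]) ** 2)
        assert e_cons == pytest.approx(exp_cons, rel=1e-10)
        assert e_sm == pytest.approx(exp_sm, rel=1e-10)

    def test_spatial_zero_for_identity_and_common_similarity(self, tiny_tube):
        mesh = tiny_tube.template
        n = mesh.n_vertices
        state = FrameState.identity(n, 0.01)
        assert reg.energy_spatial(state, mesh) == (0.0, 0.0, 0.0)
        sR = 1.3 * Rotation.from_rotvec([0.2, 0.1, -0.3]).as_matrix()
        state.T = np.broadcast_to(sR, (n, 3, 3)).copy()
        state.t = np.tile([1.0, 2.0, 3.0], (n, 1))
        e_acap, e_cons, e_sm = reg.energy_spatial(state, mesh)
        assert e_acap == pytest.approx(0.0, abs=1e-18)
        assert e_cons == pytest.approx(0.0, abs=1e-18)
        assert e_sm == pytest.approx(0.0, abs=1e-18)

    def test_acap_positive_for_anisotropic_stretch(self, tiny_tube):
        mesh = tiny_tube.template
        n = mesh.n_vertices
        state = FrameState.identity(n, 0.01)
        state.T[0] = np.diag([2.0, 1.0, 1.0])
        e_acap, _, _ = reg.energy_spatial(state, mesh)
        # closest scaled rotation to diag(2,1,1) is (4/3) I
        expect = np.sum((np.diag([2.0, 1.0, 1.0]) - 4.0 / 3 * np.eye(3)) ** 2)
        assert e_acap == pytest.approx(expect, rel=1e-10)

    def test_temporal_energy(self, rng):
        n = 6
        Tdd = rng.normal(size=(n, 3, 3))
        tdd = rng.normal(size=(n, 3))
        Td = rng.normal(size=(n, 3, 3))
        td = rng.normal(size=(n, 3))
        w_v, w_lin = 0.37, 2.1
        val = reg.energy_temporal(Tdd, tdd, Td, td, w_v, w_lin)
        expect = 0.0
        for i in range(n):
            expect += td[i] @ td[i] * w_v + tdd[i] @ tdd[i]
            expect += w_lin * (np.trace(Td[i].T @ Td[i]) * w_v
                               + np.trace(Tdd[i].T @ Tdd[i]))
        assert val == pytest.approx(expect, rel=1e-10)

    def test_single_acceleration_unit(self):
        Tdd = np.zeros((1, 3, 3))
        tdd = np.array([[1.0, 0, 0]])
        zero = np.zeros((1, 3, 3)), np.zeros((1, 3))
        assert reg.energy_temporal(Tdd, tdd, zero[0], zero[1], 0.0, 1.0) == 1.0


class TestQuadraticSolve:
    def _system(self, tiny_tube, rng, params):
        mesh = tiny_tube.template
        n = mesh.n_vertices
        prev = random_state(n, rng, scale=0.01)
        target = mesh.with_vertices(mesh.vertices + rng.normal(0, 0.2, (n, 3)))
        corr = np.arange(n)
        x_hat = mesh.vertices
        y_t, valid = reg.projected_closest_targets(
            x_hat, mesh.normals, np.eye(3), target.vertices, corr)
        base = reg.newmark_base(prev, params.beta, params.gamma, prev.dT)
        acap = reg.closest_scaled_rotation(base[0])
        mi = np.array([1, 4])
        J, b = reg.assemble_system(mesh, x_hat, y_t, valid, mi,
                                   target.vertices[mi], acap, base, params,
                                   prev.dT)
        return J, b

    def test_sparse_minimizer_matches_dense_lstsq(self, tiny_tube, rng):
        params = RegistrationParams()
        J, b = self._system(tiny_tube, rng, params)
        a_sparse = reg.solve_accelerations(J, b)
        a_dense, *_ = np.linalg.lstsq(J.toarray(), b, rcond=None)
        scale = max(np.abs(a_dense).max(), 1.0)
        np.testing.assert_allclose(a_sparse, a_dense, atol=1e-6 * scale)

    def test_solve_never_increases_quadratic_energy(self, tiny_tube, rng):
        params = RegistrationParams()
        J, b = self._system(tiny_tube, rng, params)
        a = reg.solve_accelerations(J, b)
        assert np.sum((J @ a - b) ** 2) <= np.sum(b**2) + 1e-12


class TestEnergyBreakdown:
    def test_weighted_sum_identity_after_solve(self, noisy_sim):
        params = RegistrationParams()
        prev = FrameState.identity(noisy_sim.template.n_vertices, noisy_sim.dt)
        mi = noisy_sim.marker_indices
        state, e, _, _ = reg.register_frame(
            noisy_sim.template, noisy_sim.targets[0], prev, params,
            marker_indices=mi,
            marker_targets=noisy_sim.targets[0].vertices[mi])
        expect = (e.w_C * e.e_closest + e.w_F * e.e_feature
                  + e.w_S * (e.e_acap + e.e_consist + e.e_smooth)
                  + e.w_T * e.e_temporal)
        assert e.total == pytest.approx(expect, rel=1e-9)
        assert min(e.e_closest, e.e_feature, e.e_acap, e.e_consist,
                   e.e_smooth, e.e_temporal) >= 0.0
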