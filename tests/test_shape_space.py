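"""Geometry of the pre-shape sphere: Helmert transform, Procrustes
distance and mean, tangent projection and exponential map."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation
from scipy.stats import special_ortho_group

import adashape as ada
from adashape.exceptions import (
    DegenerateConfigurationError,
    InvalidDimensionError,
    InvalidInputError,
    OutOfDomainError,
)
from adashape.shape_space import _helmert_apply, _helmert_transpose_apply


def _rand_config(seed, k=8, scale=30.0):
    r = np.random.default_rng(seed)
    return ada.ConfigurationMatrix(r.normal(size=(k, 3)) * scale)


class TestHelmert:
    def test_k2_single_row(self):
        H = ada.helmert_submatrix(2)
        np.testing.assert_allclose(H, [[-1 / np.sqrt(2), 1 / np.sqrt(2)]])

    @given(st.integers(min_value=2, max_value=40))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rows_orthonormal_and_zero_sum(self, k):
        H = ada.helmert_submatrix(k)
        np.testing.assert_allclose(H @ H.T, np.eye(k - 1), atol=1e-12)
        np.testing.assert_allclose(H @ np.ones(k), 0.0, atol=1e-12)

    def test_invalid_k(self):
        with pytest.raises(InvalidDimensionError):
            ada.helmert_submatrix(1)

    def test_fast_apply_matches_explicit_matrix(self):
        r = np.random.default_rng(3)
        X = r.normal(size=(9, 3))
        H = ada.helmert_submatrix(9)
        np.testing.assert_allclose(_helmert_apply(X), H @ X, atol=1e-12)
        Y = r.normal(size=(8, 3))
        np.testing.assert_allclose(_helmert_transpose_apply(Y), H.T @ Y, atol=1e-12)


class TestPreShape:
    def test_unit_norm_and_centroid_size(self):
        X = _rand_config(0)
        Y = ada.to_preshape(X)
        assert abs(np.linalg.norm(Y.matrix) - 1.0) < 1e-10
        np.testing.assert_allclose(
            Y.centroid_size, np.linalg.norm(X.coords - X.coords.mean(0))
        )

    def test_translation_invariance(self):
        X = _rand_config(1)
        shifted = ada.ConfigurationMatrix(X.coords + np.array([5.0, -3.0, 11.0]))
        Ya, Yb = ada.to_preshape(X), ada.to_preshape(shifted)
        np.testing.assert_allclose(Ya.matrix, Yb.matrix, atol=1e-12)
        np.testing.assert_allclose(Ya.centroid_size, Yb.centroid_size)

    def test_scale_homogeneity(self):
        X = _rand_config(2)
        Y1 = ada.to_preshape(X)
        Y2 = ada.to_preshape(ada.ConfigurationMatrix(2.5 * X.coords))
        np.testing.assert_allclose(Y1.matrix, Y2.matrix, atol=1e-12)
        np.testing.assert_allclose(Y2.centroid_size, 2.5 * Y1.centroid_size)

    def test_coincident_landmarks_rejected(self):
        with pytest.raises(DegenerateConfigurationError):
            ada.to_preshape(ada.ConfigurationMatrix(np.ones((5, 3))))


class TestOptimalRotation:
    def test_identity_for_same_preshape(self):
        Y = ada.to_preshape(_rand_config(4))
        np.testing.assert_allclose(ada.optimal_rotation(Y, Y), np.eye(3), atol=1e-8)

    def test_undoes_known_rotation(self):
        S = ada.to_preshape(_rand_config(5))
        R = special_ortho_group.rvs(3, random_state=np.random.default_rng(5))
        Y = ada.PreShape(S.matrix @ R, 1.0)
        np.testing.assert_allclose(ada.optimal_rotation(S, Y), R.T, atol=1e-8)

    def test_maximizes_trace_over_random_rotations(self):
        r = np.random.default_rng(6)
        S = ada.to_preshape(_rand_config(61))
        Y = ada.to_preshape(_rand_config(62))
        G = ada.optimal_rotation(S, Y)
        A = S.matrix.T @ Y.matrix
        best = np.trace(A @ G)
        for _ in range(1000):
            Q = special_ortho_group.rvs(3, random_state=r)
            assert np.trace(A @ Q) <= best + 1e-12
        assert np.linalg.det(G) > 0


class TestProcrustesDistance:
    def test_zero_on_self(self):
        X = _rand_config(7)
        assert ada.full_procrustes_distance(X, X) < 1e-10

    def test_similarity_invariance(self):
        r = np.random.default_rng(8)
        X = _rand_config(8)
        for _ in range(5):
            beta = float(np.exp(r.uniform(np.log(0.1), np.log(10))))
            R = special_ortho_group.rvs(3, random_state=r)
            t = r.normal(size=3) * 100
            X2 = ada.ConfigurationMatrix(beta * X.coords @ R + t)
            assert ada.full_procrustes_distance(X, X2) < 1e-8

    def test_symmetry_and_range(self):
        for s in range(5):
            X1, X2 = _rand_config(s), _rand_config(100 + s)
            d12 = ada.full_procrustes_distance(X1, X2)
            d21 = ada.full_procrustes_distance(X2, X1)
            assert abs(d12 - d21) < 1e-10
            assert 0.0 <= d12 <= 1.0

    def test_matches_brute_force_minimization(self):
        """d_F is the minimum of ||Y2 - beta*Y1*R|| over scale and SO(3):
        check against direct numeric optimization (rotation-vector
        parameterization, multistart) on a 4-landmark pair."""
        from scipy.optimize import minimize

        Y1 = ada.to_preshape(_rand_config(9, k=4)).matrix
        Y2 = ada.to_preshape(_rand_config(10, k=4)).matrix

        def objective(params):
            beta = params[0]
            R = Rotation.from_rotvec(params[1:]).as_matrix()
            return np.linalg.norm(Y2 - beta * Y1 @ R)

        r = np.random.default_rng(11)
        best = np.inf
        for _ in range(25):
            x0 = np.concatenate([[r.uniform(0.2, 2.0)], r.normal(size=3)])
            res = minimize(objective, x0, method="Nelder-Mead",
                           options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
            best = min(best, res.fun)
        d = ada.full_procrustes_distance(ada.PreShape(Y1, 1.0), ada.PreShape(Y2, 1.0))
        assert abs(d - best) < 1e-4


class TestProcrustesMean:
    def test_mean_of_identical_shapes(self):
        r = np.random.default_rng(12)
        X = _rand_config(12)
        ens = []
        for _ in range(6):
            beta = float(np.exp(r.uniform(np.log(0.5), np.log(2))))
            R = special_ortho_group.rvs(3, random_state=r)
            ens.append(ada.ConfigurationMatrix(beta * X.coords @ R + r.normal(size=3) * 50))
        mean = ada.procrustes_mean(ens)
        assert mean.converged
        assert ada.full_procrustes_distance(
            ada.reconstruct_configuration(mean.pole), X) < 1e-8

    def test_two_point_symmetry(self, concentrated_ensemble):
        X1, X2 = concentrated_ensemble[0], concentrated_ensemble[1]
        mean = ada.procrustes_mean([X1, X2])
        pole = ada.reconstruct_configuration(mean.pole)
        d1 = ada.full_procrustes_distance(pole, X1)
        d2 = ada.full_procrustes_distance(pole, X2)
        assert abs(d1 - d2) < 1e-6
        # Frechet objective at the pole beats either endpoint
        for cand in (X1, X2):
            obj_c = sum(ada.full_procrustes_distance(cand, Z) ** 2 for Z in (X1, X2))
            obj_p = d1**2 + d2**2
            assert obj_p <= obj_c + 1e-10

    def test_objective_trace_non_increasing(self, concentrated_ensemble):
        mean = ada.procrustes_mean(concentrated_ensemble)
        tr = mean.objective_trace
        assert all(b <= a + 1e-10 for a, b in zip(tr, tr[1:]))

    def test_local_minimality_probe(self, concentrated_ensemble):
        mean = ada.procrustes_mean(concentrated_ensemble)
        pres = [ada.to_preshape(X) for X in concentrated_ensemble]
        obj0 = sum(ada.full_procrustes_distance(mean.pole, Y) ** 2 for Y in pres)
        r = np.random.default_rng(13)
        s = mean.pole.matrix.ravel(order="F")
        for _ in range(100):
            w = r.normal(size=s.size) * 1e-3
            w -= s * (s @ w)  # project into the tangent space at the pole
            Yp = ada.exp_map(w, mean)
            obj = sum(ada.full_procrustes_distance(Yp, Y) ** 2 for Y in pres)
            assert obj0 <= obj + 1e-12

    def test_order_and_similarity_invariance(self, concentrated_ensemble):
        mean0 = ada.procrustes_mean(concentrated_ensemble)
        r = np.random.default_rng(14)
        perm = r.permutation(len(concentrated_ensemble))
        transformed = []
        for i in perm:
            X = concentrated_ensemble[i]
            beta = float(np.exp(r.uniform(np.log(0.5), np.log(2))))
            R = special_ortho_group.rvs(3, random_state=r)
            transformed.append(
                ada.ConfigurationMatrix(beta * X.coords @ R + r.normal(size=3) * 40)
            )
        mean1 = ada.procrustes_mean(transformed)
        d = ada.full_procrustes_distance(
            ada.reconstruct_configuration(mean0.pole),
            ada.reconstruct_configuration(mean1.pole),
        )
        assert d < 1e-6

    def test_empty_ensemble_rejected(self):
        with pytest.raises(InvalidInputError):
            ada.procrustes_mean([])


class TestTangentSpace:
    def test_pole_maps_to_origin(self, concentrated_ensemble):
        mean = ada.procrustes_mean(concentrated_ensemble)
        v = ada.tangent_coordinates(mean.pole, mean)
        np.testing.assert_allclose(v.v, 0.0, atol=1e-10)

    def test_orthogonal_to_pole_with_unit_bound(self, concentrated_ensemble):
        mean = ada.procrustes_mean(concentrated_ensemble)
        s = mean.pole.matrix.ravel(order="F")
        for X in concentrated_ensemble:
            v = ada.tangent_coordinates(ada.to_preshape(X), mean)
            assert abs(s @ v.v) < 1e-8
            assert v.norm <= 1 + 1e-10

    def test_norm_is_sin_of_procrustes_angle(self, concentrated_ensemble):
        mean = ada.procrustes_mean(concentrated_ensemble)
        for X in concentrated_ensemble:
            Y = ada.to_preshape(X)
            G = ada.optimal_rotation(mean.pole, Y)
            cos = np.trace(mean.pole.matrix.T @ Y.matrix @ G)
            v = ada.tangent_coordinates(Y, mean)
            assert abs(v.norm - np.sqrt(max(0.0, 1 - cos**2))) < 1e-8

    def test_similarity_invariance_of_tangent_coords(self, concentrated_ensemble):
        mean = ada.procrustes_mean(concentrated_ensemble)
        r = np.random.default_rng(15)
        for X in concentrated_ensemble[:4]:
            v0 = ada.tangent_coordinates(ada.to_preshape(X), mean).v
            beta = float(np.exp(r.uniform(np.log(0.1), np.log(10))))
            R = special_ortho_group.rvs(3, random_state=r)
            X2 = ada.ConfigurationMatrix(beta * X.coords @ R + r.normal(size=3) * 80)
            v1 = ada.tangent_coordinates(ada.to_preshape(X2), mean).v
            np.testing.assert_allclose(v0, v1, atol=1e-7)

    def test_exp_log_roundtrip_exact(self, concentrated_ensemble):
        mean = ada.procrustes_mean(concentrated_ensemble)
        for X in concentrated_ensemble:
            Y = ada.to_preshape(X)
            G = ada.optimal_rotation(mean.pole, Y)
            back = ada.exp_map(ada.tangent_coordinates(Y, mean), mean)
            assert np.linalg.norm(back.matrix - Y.matrix @ G) < 1e-10

    def test_exp_map_of_zero_is_pole(self, concentrated_ensemble):
        mean = ada.procrustes_mean(concentrated_ensemble)
        Y = ada.exp_map(np.zeros(mean.pole.matrix.size), mean)
        np.testing.assert_allclose(Y.matrix, mean.pole.matrix, atol=1e-12)

    def test_exp_map_rejects_long_vectors(self, concentrated_ensemble):
        mean = ada.procrustes_mean(concentrated_ensemble)
        v = np.zeros(mean.pole.matrix.size)
        v[0] = 1.5
        with pytest.raises(OutOfDomainError):
            ada.exp_map(v, mean)


class TestReconstruction:
    def test_preshape_roundtrip(self):
        Y = ada.to_preshape(_rand_config(16))
        X = ada.reconstruct_configuration(Y)
        Y2 = ada.to_preshape(X)
        np.testing.assert_allclose(Y.matrix, Y2.matrix, atol=1e-10)
        np.testing.assert_allclose(X.coords.sum(axis=0), 0.0, atol=1e-10)

    def test_distance_preserved_under_reconstruction(self):
        Y1, Y2 = ada.to_preshape(_rand_config(17)), ada.to_preshape(_rand_config(18))
        d_pre = ada.full_procrustes_distance(Y1, Y2)
        d_rec = ada.full_procrustes_distance(
            ada.reconstruct_configuration(Y1), ada.reconstruct_configuration(Y2)
        )
        assert abs(d_pre - d_rec) < 1e-8

    def test_rescale_to_centroid_size(self):
        Y = ada.to_preshape(_rand_config(19))
        X = ada.reconstruct_configuration(Y, centroid_size=123.0)
        assert abs(np.linalg.norm(_helmert_apply(X.coords)) - 123.0) < 1e-9
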