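"""Diffusion-potential embedding: every stage against independent oracles."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import spearmanr

import neurotraj as nt
from neurotraj.exceptions import ConfigurationError, ContractError
from neurotraj.phate_embed import (
    LOG_FLOOR,
    alpha_decay_kernel,
    diffusion_operator,
    metric_mds,
    potential_distance,
    select_t_vne,
    spatial_weights,
    variance_explained,
    von_neumann_entropy,
)


def reference_pipeline(X, knn, alpha, t, gamma=LOG_FLOOR):
    """Straight-line re-computation of kernel -> P -> P^t -> U from the
    defining formulas (no eigendecomposition, no shared code paths)."""
    n = X.shape[0]
    D = squareform(pdist(X))
    eps = np.sort(D, axis=1)[:, knn]
    K = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            K[i, j] = 0.5 * np.exp(-((D[i, j] / eps[i]) ** alpha)) + 0.5 * np.exp(
                -((D[i, j] / eps[j]) ** alpha)
            )
    P = K / K.sum(axis=1, keepdims=True)
    Pt = np.linalg.matrix_power(P, t)
    logPt = np.log(Pt + gamma)
    U = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            U[i, j] = np.sqrt(np.sum((logPt[i] - logPt[j]) ** 2))
    return K, P, Pt, U


class TestAlphaDecayKernel:
    def test_diagonal_is_one_and_symmetric(self, rng):
        X = rng.standard_normal((30, 5))
        aff = alpha_decay_kernel(X, knn=5, alpha=35)
        assert np.allclose(np.diag(aff.K), 1.0)
        assert np.allclose(aff.K, aff.K.T)
        assert aff.K.min() >= 0 and aff.K.max() <= 1 + 1e-12

    def test_distance_at_bandwidth_gives_inverse_e(self):
        # three collinear unit-spaced points, knn=1: eps_i = 1 for all,
        # so K(0,1) = 1/2 e^-1 + 1/2 e^-1 = e^-1
        X = np.array([[0.0], [1.0], [2.0]])
        aff = alpha_decay_kernel(X, knn=1, alpha=35)
        assert aff.K[0, 1] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_separated_clusters_have_underflow_affinity(self):
        X, labels = nt.make_toy_manifold("two_clusters", n_points=60, noise_sd=0.05,
                                         seed=0)
        aff = alpha_decay_kernel(X, knn=5, alpha=35)
        inter = aff.K[np.ix_(labels == 0, labels == 1)]
        assert inter.max() < 1e-12

    def test_duplicate_points_raise_bandwidth_error(self):
        X = np.zeros((12, 3))
        with pytest.raises(ContractError, match="bandwidth"):
            alpha_decay_kernel(X, knn=5, alpha=35)


class TestDiffusionOperator:
    def test_rows_sum_to_one(self, rng):
        X = rng.standard_normal((25, 4))
        op = diffusion_operator(alpha_decay_kernel(X, knn=4))
        assert np.allclose(op.P.sum(axis=1), 1.0, atol=1e-12)

    def test_identity_kernel_gives_identity_operator(self):
        op = diffusion_operator(np.eye(6))
        assert np.allclose(op.P, np.eye(6))

    def test_leading_eigenvalue_is_one(self, rng):
        X = rng.standard_normal((25, 4))
        op = diffusion_operator(alpha_decay_kernel(X, knn=4))
        assert abs(op.eigenvalues[0]) == pytest.approx(1.0, abs=1e-10)

    def test_power_matches_repeated_multiplication(self, rng):
        X = rng.standard_normal((6, 3))
        op = diffusion_operator(alpha_decay_kernel(X, knn=2, alpha=4))
        brute = np.linalg.matrix_power(op.P, 7)
        assert np.allclose(op.power(7), brute, atol=1e-8)


class TestVonNeumannEntropy:
    def test_entropy_nonincreasing_on_random_operators(self, rng):
        for _ in range(20):
            X = rng.standard_normal((20, 3))
            op = diffusion_operator(alpha_decay_kernel(X, knn=3, alpha=4))
            H = von_neumann_entropy(op, t_max=40)
            assert np.all(np.diff(H) <= 1e-10)

    def test_two_disconnected_blocks_approach_log2(self):
        K = np.zeros((8, 8))
        K[:4, :4] = 1.0
        K[4:, 4:] = 1.0
        op = diffusion_operator(K)
        H = von_neumann_entropy(op, t_max=200)
        assert H[-1] == pytest.approx(np.log(2), abs=1e-6)

    def test_identity_operator_has_no_knee(self):
        op = diffusion_operator(np.eye(10))
        with pytest.raises(ContractError, match="supply t"):
            select_t_vne(op, t_max=20)

    def test_selected_t_is_positive_integer_in_range(self, rng):
        X = rng.standard_normal((40, 4))
        op = diffusion_operator(alpha_decay_kernel(X, knn=5, alpha=10))
        t = select_t_vne(op, t_max=60)
        assert isinstance(t, int) and 1 <= t <= 60


class TestPotentialDistance:
    def test_metric_axioms(self, rng):
        X = rng.standard_normal((15, 3))
        op = diffusion_operator(alpha_decay_kernel(X, knn=3, alpha=4))
        U = potential_distance(op, t=3)
        assert np.allclose(np.diag(U), 0.0, atol=1e-9)
        assert np.allclose(U, U.T, atol=1e-9)

    def test_duplicate_diffusion_profiles_have_zero_distance(self):
        K = np.ones((5, 5))
        op = diffusion_operator(K)
        U = potential_distance(op, t=2)
        assert np.allclose(U, 0.0, atol=1e-9)

    def test_disconnected_graph_error_names_components(self):
        K = np.zeros((7, 7))
        K[:3, :3] = 1.0
        K[3:, 3:] = 1.0
        op = diffusion_operator(K)
        with pytest.raises(ContractError, match="2 connected components"):
            potential_distance(op, t=2)

    def test_small_instance_oracle_equivalence(self, rng):
        """Kernel, diffusion operator, powers, and potential distances all
        match an independent straight-line recomputation within 1e-8."""
        for seed in range(3):
            X = np.random.default_rng(seed).standard_normal((8, 3))
            aff = alpha_decay_kernel(X, knn=3, alpha=6)
            op = diffusion_operator(aff)
            t = 4
            U = potential_distance(op, t)
            K_ref, P_ref, Pt_ref, U_ref = reference_pipeline(X, knn=3, alpha=6, t=t)
            assert np.allclose(aff.K, K_ref, atol=1e-8)
            assert np.allclose(op.P, P_ref, atol=1e-8)
            assert np.allclose(op.power(t), Pt_ref, atol=1e-8)
            assert np.allclose(U, U_ref, atol=1e-8)


def procrustes_rmsd(A, B):
    """RMSD after optimal rotation/reflection + translation alignment."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    R, _ = np.linalg.qr(np.eye(A.shape[1]))
    U, _, Vt = np.linalg.svd(B.T @ A)
    B_rot = B @ (U @ Vt)
    return np.sqrt(np.mean((A - B_rot) ** 2))


class TestMetricMDS:
    def test_exactly_embeddable_distances_recovered(self, rng):
        pts = rng.standard_normal((40, 3))
        U = squareform(pdist(pts))
        coords, stress = metric_mds(U, n_dims=3)
        assert procrustes_rmsd(pts, coords) < 1e-6

    def test_duplicate_points_embed_coincidently(self, rng):
        pts = rng.standard_normal((10, 3))
        pts[3] = pts[7]
        U = squareform(pdist(pts))
        coords, _ = metric_mds(U, n_dims=3)
        assert np.allclose(coords[3], coords[7], atol=1e-6)

    def test_majorization_never_increases_stress(self, rng):
        from neurotraj.phate_embed import _classical_mds, _stress

        for seed in range(5):
            r = np.random.default_rng(seed)
            U = squareform(pdist(r.standard_normal((25, 6))))
            coords, stress = metric_mds(U, n_dims=3)
            init_stress = _stress(U, _classical_mds(U, 3))
            assert stress <= init_stress + 1e-12

    def test_asymmetric_input_rejected(self, rng):
        U = rng.random((5, 5))
        with pytest.raises(ContractError):
            metric_mds(U, n_dims=3)

    def test_stress_competitive_with_sklearn_smacof(self, rng):
        """Independent cross-check: our majorization reaches a stress in the
        same range as scikit-learn's SMACOF on the same dissimilarities."""
        from sklearn.manifold import smacof

        U = squareform(pdist(rng.standard_normal((30, 5))))
        coords, stress = metric_mds(U, n_dims=3)
        _, sk_stress = smacof(U, n_components=3, n_init=2, random_state=0,
                              normalized_stress=False)
        assert stress <= 1.2 * sk_stress


class TestVarianceAndWeights:
    def test_all_variance_in_first_dimension(self):
        coords = np.zeros((50, 3))
        coords[:, 0] = np.linspace(-1, 1, 50)
        frac = variance_explained(coords)
        assert np.allclose(frac, [1.0, 0.0, 0.0], atol=1e-12)

    def test_isotropic_gaussian_has_equal_fractions(self, rng):
        coords = rng.standard_normal((5000, 5))
        frac = variance_explained(coords)
        assert np.allclose(frac, 0.2, atol=0.02)
        assert frac.sum() == pytest.approx(1.0, abs=1e-12)

    def test_self_correlated_region_has_weight_one(self, rng):
        coords = rng.standard_normal((100, 3))
        responses = np.column_stack([coords[:, 0], rng.standard_normal(100)])
        W = spatial_weights(responses, coords)
        assert W.shape == (2, 3)
        assert W[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_noise_regions_have_small_weights(self, rng):
        coords = rng.standard_normal((702, 3))
        responses = rng.standard_normal((702, 50))
        W = spatial_weights(responses, coords)
        # null Pearson at n = 702: sd ~ 1/sqrt(702) = 0.038; 0.1 is ~2.6 sd
        assert np.mean(np.abs(W) < 0.1) > 0.95

    def test_zero_variance_region_warns_and_zeroes(self, rng):
        coords = rng.standard_normal((50, 3))
        responses = np.zeros((50, 2))
        responses[:, 0] = rng.standard_normal(50)
        with pytest.warns(UserWarning, match="zero-variance"):
            W = spatial_weights(responses, coords)
        assert np.allclose(W[1], 0.0)


class TestFullRecipe:
    def test_noisy_curve_ordering_recovered(self):
        """The first embedding coordinate orders a noisy 1-D curve:
        Spearman |rho| > 0.95 against the true ordering."""
        # noise_sd 0.12 ~ signal RMS (0.6) / 5, i.e. an SNR-5 curve
        X, order = nt.make_toy_manifold("noisy_curve", n_points=200, ambient_dim=10,
                                        noise_sd=0.12, seed=0)
        emb = nt.phate(X, nt.PhateParams())
        rho = spearmanr(order, emb.coords[:, 0]).statistic
        assert abs(rho) > 0.95

    def test_variance_fractions_nonincreasing_and_stress_finite(self, fitted_responses):
        emb = nt.phate(fitted_responses.values, nt.PhateParams())
        assert np.all(np.diff(emb.variance_fraction) <= 1e-12)
        assert np.isfinite(emb.stress)
        assert emb.coords.shape == (fitted_responses.n_samples, 5)

    def test_embedding_is_deterministic(self):
        X, _ = nt.make_toy_manifold("noisy_curve", n_points=80, noise_sd=0.05, seed=3)
        a = nt.phate(X, nt.PhateParams())
        b = nt.phate(X, nt.PhateParams())
        assert np.array_equal(a.coords, b.coords)
        assert a.embedding_id == b.embedding_id

    def test_invalid_params_rejected(self):
        X, _ = nt.make_toy_manifold("noisy_curve", n_points=50, seed=0)
        with pytest.raises(ConfigurationError):
            nt.phate(X, nt.PhateParams(n_dims=2))
        with pytest.raises(ConfigurationError):
            nt.phate(X, nt.PhateParams(knn=50))
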