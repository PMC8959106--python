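"""Gaussian process core: kernel, evidence, fitting, posterior."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from igpg import gpr
from igpg.gpr import KernelConfig, fit, kernel_matrix, log_marginal_likelihood, predict


def _dense_posterior_oracle(X, y, Xq, cfg):
    """Direct-inverse GP posterior, no factorizations."""
    y = np.asarray(y, dtype=float)
    mu = y.mean()
    K = kernel_matrix(X, X, cfg) + cfg.noise_variance * np.eye(len(y))
    Kinv = np.linalg.inv(K)
    Ks = kernel_matrix(Xq, X, cfg)
    mean = Ks @ Kinv @ (y - mu) + mu
    var = cfg.signal_variance - np.einsum("ij,jk,ik->i", Ks, Kinv, Ks)
    return mean, var


class TestKernel:
    def test_zero_distance_gives_signal_variance(self):
        cfg = KernelConfig(signal_variance=2.5, lengthscale=0.7)
        K = kernel_matrix(np.array([[1.0, 2.0]]), np.array([[1.0, 2.0]]), cfg)
        assert K.shape == (1, 1)
        assert K[0, 0] == pytest.approx(2.5, abs=1e-15)

    def test_distant_points_decay_to_zero(self):
        cfg = KernelConfig(lengthscale=1.0)
        K = kernel_matrix(np.array([[0.0]]), np.array([[1e8]]), cfg)
        assert K[0, 0] < 1e-300

    def test_matches_scalar_oracle_on_grid(self):
        cfg = KernelConfig(signal_variance=1.0, lengthscale=1.0)
        X = np.array([[0.0], [1.0], [2.0]])
        K = kernel_matrix(X, X, cfg)
        expected = np.exp(
            -0.5 * np.array([[0, 1, 4], [1, 0, 1], [4, 1, 0]], dtype=float)
        )
        assert np.max(np.abs(K - expected)) < 1e-12

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kernel_matrix(np.zeros((2, 3)), np.zeros((2, 2)), KernelConfig())

    def test_ard_lengthscales_weight_dimensions(self):
        cfg = KernelConfig(lengthscale=np.array([1.0, 10.0]), ard=True)
        X1 = np.array([[0.0, 0.0]])
        X2 = np.array([[1.0, 0.0], [0.0, 10.0]])
        K = kernel_matrix(X1, X2, cfg)
        assert K[0, 0] == pytest.approx(K[0, 1], abs=1e-15)


class TestEvidence:
    def test_single_zero_point_closed_form(self):
        # K + noise = 1 exactly
        cfg = KernelConfig(signal_variance=0.5, noise_variance=0.5)
        lml = log_marginal_likelihood(np.array([[0.0]]), np.array([0.0]), cfg)
        assert lml == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-9)

    def test_matches_direct_inverse_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(4, 2))
        y = rng.normal(size=4)
        cfg = KernelConfig(signal_variance=1.3, lengthscale=0.8, noise_variance=0.2)
        K = kernel_matrix(X, X, cfg) + cfg.noise_variance * np.eye(4)
        expected = (
            -0.5 * y @ np.linalg.inv(K) @ y
            - 0.5 * np.linalg.slogdet(K)[1]
            - 2 * np.log(2 * np.pi)
        )
        assert log_marginal_likelihood(X, y, cfg) == pytest.approx(expected, abs=1e-8)

    def test_larger_noise_preferred_on_pure_noise_data(self):
        diffs = []
        for k in range(20):
            rng = np.random.default_rng(400 + k)
            X = rng.uniform(0, 5, size=(30, 1))
            y = rng.normal(0, 1, 30)
            lo = KernelConfig(signal_variance=1.0, lengthscale=1.0, noise_variance=0.5)
            hi = KernelConfig(signal_variance=1.0, lengthscale=1.0, noise_variance=1.0)
            diffs.append(
                log_marginal_likelihood(X, y, hi) - log_marginal_likelihood(X, y, lo)
            )
        assert np.mean(diffs) > 0


class TestFitPredict:
    def test_single_point_interpolated_with_fixed_hyperparameters(self):
        cfg = KernelConfig(noise_variance=0.0)
        model = fit(np.array([[0.3]]), np.array([2.0]), cfg, optimize=False)
        mean, var = predict(model, np.array([[0.3]]))
        assert mean[0] == pytest.approx(2.0, abs=1e-9)
        assert var[0] < 1e-6

    def test_prior_reversion_far_from_data(self):
        cfg = KernelConfig(signal_variance=2.0, lengthscale=1.0, noise_variance=0.1)
        rng = np.random.default_rng(0)
        X = rng.normal(size=(6, 1))
        y = rng.normal(3.0, 1.0, 6)
        model = fit(X, y, cfg, optimize=False)
        mean, var = predict(model, np.array([[1e6]]))
        assert mean[0] == pytest.approx(y.mean(), abs=1e-9)
        assert var[0] == pytest.approx(2.0, abs=1e-9)

    def test_posterior_matches_direct_inverse_oracle(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(5, 3))
        y = rng.normal(size=5)
        Xq = rng.normal(size=(3, 3))
        cfg = KernelConfig(signal_variance=1.7, lengthscale=1.2, noise_variance=0.3)
        model = fit(X, y, cfg, optimize=False)
        mean, var = predict(model, Xq)
        mean_ref, var_ref = _dense_posterior_oracle(X, y, Xq, cfg)
        assert np.max(np.abs(mean - mean_ref)) < 1e-8
        assert np.max(np.abs(var - var_ref)) < 1e-8

    def test_oracle_agreement_up_to_m50(self):
        rng = np.random.default_rng(10)
        for m in (2, 10, 50):
            X = rng.normal(size=(m, 4))
            y = rng.normal(size=m)
            Xq = rng.normal(size=(5, 4))
            cfg = KernelConfig(signal_variance=0.9, lengthscale=1.5, noise_variance=0.05)
            model = fit(X, y, cfg, optimize=False)
            mean, var = predict(model, Xq)
            mean_ref, var_ref = _dense_posterior_oracle(X, y, Xq, cfg)
            assert np.max(np.abs(mean - mean_ref)) < 1e-8
            assert np.max(np.abs(var - var_ref)) < 1e-8

    def test_constant_targets_predict_the_constant(self):
        X = np.random.default_rng(1).normal(size=(8, 2))
        model = fit(X, np.full(8, 4.2), KernelConfig(seed=0))
        mean, var = predict(model, np.zeros((3, 2)))
        assert np.max(np.abs(mean - 4.2)) < 1e-6
        assert np.max(var) < 1e-6

    def test_lengthscale_recovery_from_known_gp(self):
        ok = 0
        for k in range(20):
            rng = np.random.default_rng(300 + k)
            X = rng.uniform(0, 10, size=(40, 1))
            truth = KernelConfig(signal_variance=1.0, lengthscale=1.0, noise_variance=0.01)
            K = kernel_matrix(X, X, truth) + truth.noise_variance * np.eye(40)
            y = rng.multivariate_normal(np.zeros(40), K)
            model = fit(X, y, KernelConfig(seed=k, n_restarts=5))
            ell = float(np.atleast_1d(model.config.lengthscale)[0])
            ok += 0.5 <= ell <= 2.0
        assert ok >= 16  # within a factor of 2 in >= 80% of replicates

    def test_sklearn_posterior_cross_check(self):
        sklearn_gp = pytest.importorskip("sklearn.gaussian_process")
        from sklearn.gaussian_process.kernels import RBF, ConstantKernel

        rng = np.random.default_rng(12)
        X = rng.normal(size=(12, 2))
        y = rng.normal(size=12)
        cfg = KernelConfig(signal_variance=1.4, lengthscale=0.9, noise_variance=0.2)
        model = fit(X, y, cfg, optimize=False)
        mean, var = predict(model, X[:5] + 0.1)

        ref = sklearn_gp.GaussianProcessRegressor(
            kernel=ConstantKernel(1.4, "fixed") * RBF(0.9, "fixed"),
            alpha=0.2,
            optimizer=None,
        ).fit(X, y - y.mean())
        mean_ref, std_ref = ref.predict(X[:5] + 0.1, return_std=True)
        assert np.max(np.abs(mean - (mean_ref + y.mean()))) < 1e-8
        assert np.max(np.abs(var - std_ref**2)) < 1e-8


class TestPosteriorProperties:
    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 10_000))
    def test_variance_bounded_by_prior_and_permutation_invariant(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(3, 12))
        X = rng.normal(size=(m, 2))
        y = rng.normal(size=m)
        Xq = rng.normal(size=(4, 2))
        cfg = KernelConfig(
            signal_variance=float(rng.uniform(0.2, 3.0)),
            lengthscale=float(rng.uniform(0.3, 2.0)),
            noise_variance=float(rng.uniform(0.01, 0.5)),
        )
        model = fit(X, y, cfg, optimize=False)
        mean, var = predict(model, Xq)
        assert np.all(var <= cfg.signal_variance + 1e-9)

        perm = rng.permutation(m)
        model_p = fit(X[perm], y[perm], cfg, optimize=False)
        mean_p, var_p = predict(model_p, Xq)
        assert np.max(np.abs(mean - mean_p)) < 1e-9
        assert np.max(np.abs(var - var_p)) < 1e-9

    def test_duplicated_observation_never_increases_variance(self):
        rng = np.random.default_rng(21)
        X = rng.normal(size=(6, 1))
        y = rng.normal(size=6)
        cfg = KernelConfig(signal_variance=1.0, lengthscale=1.0, noise_variance=0.1)
        Xq = np.linspace(-3, 3, 25)[:, None]
        _, var1 = predict(fit(X, y, cfg, optimize=False), Xq)
        X2 = np.vstack([X, X[:1]])
        y2 = np.append(y, y[0])
        _, var2 = predict(fit(X2, y2, cfg, optimize=False), Xq)
        assert np.all(var2 <= var1 + 1e-9)

    def test_zero_dimensional_inputs_fall_back_to_mean(self):
        # all body-parameter slots constant -> empty design matrix
        X = np.zeros((5, 0))
        y = np.array([1.0, 2.0, 3.0, 2.0, 2.0])
        model = fit(X, y, KernelConfig(noise_variance=0.5), optimize=False)
        mean, var = predict(model, np.zeros((2, 0)))
        assert mean == pytest.approx([y.mean(), y.mean()], abs=0.2)


def test_serialization_round_trip_bit_identical():
    rng = np.random.default_rng(33)
    X = rng.normal(size=(10, 3))
    y = rng.normal(size=10)
    model = fit(X, y, KernelConfig(seed=2, n_restarts=3))
    import json

    payload = json.loads(json.dumps(gpr.model_to_dict(model)))
    clone = gpr.model_from_dict(payload)
    Xq = rng.normal(size=(6, 3))
    m1, v1 = predict(model, Xq)
    m2, v2 = predict(clone, Xq)
    assert np.array_equal(m1, m2)
    assert np.array_equal(v1, v2)
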