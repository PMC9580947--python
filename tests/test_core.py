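import numpy as np
import pytest
from scipy import stats

from rvmgs.core import (
    DegenerateFitError,
    PosteriorState,
    RVMConfig,
    build_design_matrix,
    fit,
    fit_rvm,
    log_marginal_likelihood,
    posterior_stats,
    predict,
    update_hyperparameters,
)
from rvmgs.kernels import KernelSpec


# ---------------------------------------------------------------- design matrix
def test_basis_design_matrix_prepends_intercept():
    X = np.array([[0.0, 1.0], [1.0, 0.0]])
    dm = build_design_matrix(X, KernelSpec.linear_basis())
    assert np.array_equal(dm.values, [[1, 0, 1], [1, 1, 0]])
    assert dm.column_meaning(0) == ("intercept", None)
    assert dm.column_meaning(2) == ("feature_index", 1)


def test_linear_kernel_design_matrix_is_gram_matrix():
    dm = build_design_matrix(np.eye(2), KernelSpec.linear())
    assert np.array_equal(dm.values, np.eye(2))
    assert dm.column_meaning(1) == ("training_point_index", 1)


def test_gaussian_kernel_design_has_unit_diagonal(small_binary_X):
    dm = build_design_matrix(small_binary_X, KernelSpec.gaussian(2e-4))
    assert np.allclose(np.diag(dm.values), 1.0)
    assert dm.n_columns == small_binary_X.shape[0]


def test_kernel_intercept_column_is_optional(small_binary_X):
    dm = build_design_matrix(small_binary_X, KernelSpec.linear(), include_kernel_intercept=True)
    assert dm.n_columns == small_binary_X.shape[0] + 1
    assert np.array_equal(dm.values[:, 0], np.ones(small_binary_X.shape[0]))


def test_non_binary_genotypes_rejected_in_basis_mode():
    X = np.array([[0.0, 2.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match=r"row 0, column 1"):
        build_design_matrix(X, KernelSpec.linear_basis())
    # kernel mode accepts arbitrary reals
    build_design_matrix(X, KernelSpec.linear())


def test_degenerate_design_sizes_rejected():
    with pytest.raises(ValueError):
        build_design_matrix(np.ones((1, 3)), KernelSpec.linear_basis())


# ---------------------------------------------------------------- posterior
def test_posterior_identity_design_closed_form():
    Sigma, mu = posterior_stats(np.eye(2), np.array([2.0, 4.0]), np.ones(2), 1.0)
    assert np.allclose(Sigma, 0.5 * np.eye(2), atol=1e-12)
    assert np.allclose(mu, [1.0, 2.0], atol=1e-12)


def test_huge_precision_pins_weight_to_zero(rng):
    Phi = rng.normal(size=(20, 3))
    t = rng.normal(size=20)
    alpha = np.array([1.0, 1e12, 1.0])
    _, mu = posterior_stats(Phi, t, alpha, 0.5)
    assert abs(mu[1]) < 1e-6


def test_posterior_matches_dense_inverse_oracle():
    rng = np.random.default_rng(0)
    for _ in range(25):
        n = int(rng.integers(5, 30))
        k = int(rng.integers(1, 9))
        Phi = rng.normal(size=(n, k))
        t = rng.normal(size=n)
        alpha = rng.uniform(0.1, 5.0, k)
        sigma2 = float(rng.uniform(0.2, 2.0))
        Sigma, mu = posterior_stats(Phi, t, alpha, sigma2)
        B = Phi.T @ Phi / sigma2 + np.diag(alpha)
        Sigma_o = np.linalg.inv(B)
        assert np.allclose(Sigma, Sigma_o, atol=1e-8)
        assert np.allclose(mu, Sigma_o @ Phi.T @ t / sigma2, atol=1e-8)


def test_posterior_covariance_is_symmetric(rng):
    Phi = rng.normal(size=(15, 6))
    Sigma, _ = posterior_stats(Phi, rng.normal(size=15), np.full(6, 0.5), 1.3)
    assert np.allclose(Sigma, Sigma.T, rtol=1e-12)


def test_posterior_survives_duplicate_columns(rng):
    col = rng.normal(size=(12, 1))
    Phi = np.hstack([col, col, col])  # rank-1 design; prior still regularises
    Sigma, mu = posterior_stats(Phi, rng.normal(size=12), np.full(3, 1e-6), 1.0)
    assert np.isfinite(Sigma).all() and np.isfinite(mu).all()


def test_posterior_validates_inputs(rng):
    Phi = rng.normal(size=(5, 2))
    with pytest.raises(ValueError):
        posterior_stats(Phi, np.zeros(5), np.array([1.0, -1.0]), 1.0)
    with pytest.raises(ValueError):
        posterior_stats(Phi, np.zeros(5), np.ones(3), 1.0)


# ---------------------------------------------------------------- hyper updates
def _state_from(Phi, t, alpha, sigma2):
    Sigma, mu = posterior_stats(Phi, t, alpha, sigma2)
    return PosteriorState(
        active=np.arange(len(alpha)), alpha=alpha, sigma2=sigma2, mu=mu, Sigma=Sigma, log_ml=0.0
    )


def test_alpha_update_closed_form():
    # alpha_new = (1 - alpha*Sigma_ii) / mu_i^2 with mu=1, Sigma_ii=0.5, alpha=1
    state = PosteriorState(
        active=np.array([0]),
        alpha=np.array([1.0]),
        sigma2=1.0,
        mu=np.array([1.0]),
        Sigma=np.array([[0.5]]),
        log_ml=0.0,
    )
    alpha_new, _ = update_hyperparameters(state, np.ones((2, 1)), np.array([1.0, 1.0]))
    assert alpha_new[0] == pytest.approx(0.5, abs=1e-12)


def test_sigma2_update_arithmetic():
    # N=2, ||t - Phi mu||^2 = 1, sum(gamma) = 1  ->  sigma2_new = 1
    Phi = np.array([[1.0], [0.0]])
    t = np.array([1.0, 1.0])  # mu below chosen so residual norm^2 = 1
    state = PosteriorState(
        active=np.array([0]),
        alpha=np.array([2.0]),
        sigma2=1.0,
        mu=np.array([1.0]),
        Sigma=np.array([[0.0]]),  # gamma = 1 - 2*0 = 1
        log_ml=0.0,
    )
    _, sigma2_new = update_hyperparameters(state, Phi, t)
    assert sigma2_new == pytest.approx(1.0, abs=1e-12)


def test_zero_posterior_mean_signals_pruning(rng):
    Phi = rng.normal(size=(10, 2))
    state = PosteriorState(
        active=np.arange(2),
        alpha=np.array([1.0, 1.0]),
        sigma2=1.0,
        mu=np.array([0.5, 0.0]),
        Sigma=0.1 * np.eye(2),
        log_ml=0.0,
    )
    alpha_new, _ = update_hyperparameters(state, Phi, rng.normal(size=10), alpha_prune_threshold=1e12)
    assert alpha_new[1] == 1e12


def test_saturated_fit_raises_degenerate_error():
    # gamma sums to N: no degrees of freedom left for the noise
    Phi = np.eye(2)
    state = PosteriorState(
        active=np.arange(2),
        alpha=np.array([1.0, 1.0]),
        sigma2=1.0,
        mu=np.array([1.0, 1.0]),
        Sigma=np.zeros((2, 2)),  # gamma_i = 1 each
        log_ml=0.0,
    )
    with pytest.raises(DegenerateFitError):
        update_hyperparameters(state, Phi, np.array([1.0, 2.0]))


# ---------------------------------------------------------------- log evidence
def test_log_evidence_collapses_to_noise_density_when_pruned():
    sigma2, t1 = 0.7, 1.3
    value = log_marginal_likelihood(np.array([[1.0]]), np.array([t1]), np.array([1e16]), sigma2)
    expected = -0.5 * (np.log(2 * np.pi * sigma2) + t1**2 / sigma2)
    assert value == pytest.approx(expected, abs=1e-6)


def test_log_evidence_matches_explicit_covariance_oracle():
    rng = np.random.default_rng(1)
    for _ in range(25):
        n = int(rng.integers(3, 30))
        k = int(rng.integers(1, 9))
        Phi = rng.normal(size=(n, k))
        t = rng.normal(size=n)
        alpha = rng.uniform(0.1, 5.0, k)
        sigma2 = float(rng.uniform(0.2, 2.0))
        value = log_marginal_likelihood(Phi, t, alpha, sigma2)
        C = sigma2 * np.eye(n) + Phi @ np.diag(1.0 / alpha) @ Phi.T
        oracle = stats.multivariate_normal.logpdf(t, mean=np.zeros(n), cov=C)
        assert value == pytest.approx(oracle, abs=1e-8)


# ---------------------------------------------------------------- fitting
def test_zero_targets_give_empty_model(small_binary_X, basis_spec):
    model = fit(small_binary_X, np.zeros(60), basis_spec)
    assert model.n_relevance_vectors == 0
    assert np.allclose(predict(model, small_binary_X), 0.0)


def test_constant_targets_give_empty_model_predicting_the_constant(small_binary_X, basis_spec):
    model = fit(small_binary_X, np.full(60, 3.7), basis_spec)
    assert model.n_relevance_vectors == 0
    assert np.allclose(predict(model, small_binary_X[:5]), 3.7)


def test_noiseless_single_marker_recovered_exactly(rng):
    X = rng.integers(0, 2, (60, 6)).astype(float)
    t = 3.0 * X[:, 2]
    model = fit(X, t, KernelSpec.linear_basis(), RVMConfig(noise="joint"))
    markers = model.marker_indices
    assert list(markers) == [2]
    weight = model.marker_weights[0]
    assert weight == pytest.approx(3.0, abs=1e-3)
    assert np.allclose(predict(model, X), t, atol=1e-3)


def test_missing_targets_rejected(small_binary_X, basis_spec):
    t = np.ones(60)
    t[3] = np.nan
    with pytest.raises(ValueError, match="missing"):
        fit(small_binary_X, t, basis_spec)


def test_frozen_hyperparameters_reproduce_ridge_solution(rng):
    lam = 0.7
    X = rng.integers(0, 2, (40, 8)).astype(float)
    t = rng.normal(size=40)
    cfg = RVMConfig(alpha_init=lam, sigma2_init_fraction=0.5)
    dm = build_design_matrix(X, KernelSpec.linear_basis())
    model = fit_rvm(dm, t, cfg, freeze_hyperparameters=True)
    tc = t - t.mean()
    sigma2 = 0.5 * tc.var()
    Phi = dm.values
    ridge = np.linalg.solve(Phi.T @ Phi + lam * sigma2 * np.eye(9), Phi.T @ tc)
    assert np.allclose(model.relevance_weights, ridge, atol=1e-8)


def test_active_set_only_shrinks_across_sweeps(sparse_problem, basis_spec):
    X, t, _, _ = sparse_problem
    trace = []
    dm = build_design_matrix(X, basis_spec)
    fit_rvm(dm, t, RVMConfig(noise="joint"), active_trace=trace)
    sets = [set(a.tolist()) for a in trace]
    for earlier, later in zip(sets, sets[1:]):
        assert later <= earlier


def test_sparse_signal_support_recovered(sparse_problem):
    X, t, causal, beta = sparse_problem
    model = fit(X, t, KernelSpec.linear_basis(), RVMConfig(noise="joint"))
    assert set(causal.tolist()) <= set(model.marker_indices.tolist())
    # far fewer columns than markers survive
    assert model.n_relevance_vectors < 0.25 * X.shape[1]
    recovered = {m: w for m, w in zip(model.marker_indices, model.marker_weights)}
    for m in causal:
        assert np.sign(recovered[m]) == np.sign(beta[m])


def test_target_scaling_equivariance(sparse_problem, basis_spec):
    X, t, _, _ = sparse_problem
    c = 3.5
    m1 = fit(X, t, basis_spec)
    m2 = fit(X, c * t, basis_spec)
    assert np.array_equal(m1.relevance_indices, m2.relevance_indices)
    assert np.allclose(m2.relevance_weights, c * m1.relevance_weights, rtol=1e-6)
    assert m2.sigma2 == pytest.approx(c**2 * m1.sigma2, rel=1e-6)


def test_kernel_rvm_is_sparse_in_training_points(sim_pair):
    X, t, _, _ = sim_pair
    model = fit(X, t, KernelSpec.gaussian(2e-3))
    assert 0 < model.n_relevance_vectors < 0.5 * X.shape[0]
    assert model.rv_inputs.shape == (model.n_relevance_vectors, X.shape[1])


# ---------------------------------------------------------------- prediction
def test_kernel_prediction_is_weighted_kernel_sum():
    model_input = np.array([[1.0, 0.0, 1.0]])
    w = 2.5
    from rvmgs.core import RVMModel

    model = RVMModel(
        basis_kind="kernel",
        relevance_indices=np.array([0]),
        relevance_weights=np.array([w]),
        sigma2=1.0,
        n_features=3,
        kernel=KernelSpec.gaussian(0.1),
        rv_inputs=model_input,
        target_mean=0.0,
        n_training=10,
    )
    x_new = np.array([[1.0, 1.0, 1.0]])
    kappa = np.exp(-0.1 * 1.0)  # one coordinate differs
    assert predict(model, x_new)[0] == pytest.approx(w * kappa, abs=1e-12)


def test_intercept_only_basis_model_predicts_constant():
    from rvmgs.core import RVMModel

    model = RVMModel(
        basis_kind="linear_basis",
        relevance_indices=np.array([-1]),
        relevance_weights=np.array([0.4]),
        sigma2=1.0,
        n_features=4,
        target_mean=2.0,
        n_training=10,
    )
    assert np.allclose(predict(model, np.zeros((5, 4))), 2.4)


def test_training_predictions_equal_design_times_weights(sparse_problem, basis_spec):
    X, t, _, _ = sparse_problem
    model = fit(X, t, basis_spec)
    dm = build_design_matrix(X, basis_spec)
    cols = [np.flatnonzero(dm.columns == i)[0] for i in model.relevance_indices]
    direct = dm.values[:, cols] @ model.relevance_weights + model.target_mean
    assert np.allclose(predict(model, X), direct, atol=1e-10)


def test_prediction_rejects_wrong_marker_count(sim_pair, basis_spec):
    X, t, _, _ = sim_pair
    model = fit(X, t, basis_spec)
    with pytest.raises(ValueError, match="markers"):
        predict(model, X[:, :-1])
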