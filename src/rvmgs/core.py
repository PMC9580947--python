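"""Sparse Bayesian regression engine (relevance vector machine).

The model is standard Bayesian linear regression over a set of basis
functions, with an independent zero-mean Gaussian prior on each weight
whose precision ``alpha_i`` is optimised by type-II maximum likelihood
(automatic relevance determination).  Iterating the posterior statistics
and the hyperparameter re-estimation drives most ``alpha_i`` to infinity;
the surviving basis functions are the relevance vectors.

Two design-matrix layouts are supported:

* ``linear_basis`` — column 0 is an all-ones intercept and columns
  ``1..M`` are the marker genotypes themselves, so the relevance vectors
  are *markers* (embedded feature selection);
* ``kernel`` — one column per training individual,
  ``Phi[i, j] = K(x_i, x_j)``, so the relevance vectors are *training
  individuals* and the model predicts ``y* = sum_r w_r K(x*, x_r)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .kernels import KernelSpec, kernel_matrix

__all__ = [
    "DesignMatrix",
    "RVMConfig",
    "PosteriorState",
    "RVMModel",
    "RVMFitError",
    "IllConditionedError",
    "DegenerateFitError",
    "build_design_matrix",
    "posterior_stats",
    "update_hyperparameters",
    "log_marginal_likelihood",
    "fit_rvm",
    "predict",
]

logger = logging.getLogger(__name__)

#: Sentinel column index for the intercept in ``DesignMatrix.columns``.
INTERCEPT = -1

#: Largest per-sweep |log alpha| movement still considered settled.
_ALPHA_MOTION_TOL = 0.05


class RVMFitError(RuntimeError):
    """Base class for unrecoverable failures of the RVM iteration."""


class IllConditionedError(RVMFitError):
    """Posterior factorisation failed even after a jitter retry."""


class DegenerateFitError(RVMFitError):
    """Noise-variance update denominator ``N - sum(gamma)`` is not positive."""


@dataclass
class DesignMatrix:
    """Design matrix ``Phi`` plus the meaning of each of its columns.

    ``columns[j]`` is the marker index (``linear_basis`` mode) or the
    training-point index (``kernel`` mode) of column ``j``; the value
    ``INTERCEPT`` (= -1) marks an all-ones intercept column.
    ``training_inputs`` keeps the raw genotype rows in kernel mode so a
    fitted model can evaluate ``K(x*, x_r)`` at prediction time.
    """

    values: np.ndarray
    basis_kind: str  # "linear_basis" | "kernel"
    columns: np.ndarray
    kernel: KernelSpec | None = None
    training_inputs: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def column_meaning(self, j: int) -> tuple[str, int | None]:
        c = int(self.columns[j])
        if c == INTERCEPT:
            return ("intercept", None)
        kind = "feature_index" if self.basis_kind == "linear_basis" else "training_point_index"
        return (kind, c)


@dataclass(frozen=True)
class RVMConfig:
    """Tunable knobs of the type-II maximum-likelihood iteration.

    ``alpha_init`` starts every weight precision weakly informative;
    ``sigma2_init_fraction`` sets the noise variance to that fraction of
    ``var(t)`` (default 1.0: until the evidence says otherwise, all
    target variance is treated as noise — the weakly-informative
    ceiling).  Columns whose precision reaches ``alpha_prune_threshold``
    are removed permanently.  The loop stops when the relative change of
    the log marginal likelihood drops below ``logml_rel_tolerance`` or
    after ``max_iterations`` sweeps.  ``clamp_sigma2_min`` floors the
    noise variance at that fraction of ``var(t)`` so noiseless targets do
    not divide by zero.

    ``noise`` selects how the noise variance is handled:

    * ``"fixed"`` (default) — sigma2 stays at its initial value and only
      the weight precisions are re-estimated.  On marker designs with
      far more columns than individuals, joint noise re-estimation is
      structurally unstable: while the active set can still interpolate,
      the residual collapses, sigma2 free-falls and the model saturates
      with noise-fitting columns.  Fixing the noise level keeps the
      automatic relevance determination honest in that regime.
    * ``"joint"`` — after the precision-only phase converges, noise
      re-estimation sweeps are joined in until alpha *and* sigma2 reach
      a joint fixed point.  Appropriate for well-posed problems with
      fewer basis functions than observations.
    """

    alpha_init: float = 1e-3
    sigma2_init_fraction: float = 1.0
    alpha_prune_threshold: float = 1e12
    max_iterations: int = 1000
    logml_rel_tolerance: float = 1e-6
    clamp_sigma2_min: float = 1e-10
    include_kernel_intercept: bool = False
    noise: str = "fixed"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha_init <= 0:
            raise ValueError("alpha_init must be positive")
        if not 0 < self.sigma2_init_fraction <= 1:
            raise ValueError("sigma2_init_fraction must lie in (0, 1]")
        if self.alpha_prune_threshold < 1e6:
            raise ValueError("alpha_prune_threshold must be at least 1e6")
        if self.max_iterations < 1 or self.logml_rel_tolerance <= 0 or self.clamp_sigma2_min <= 0:
            raise ValueError("iteration limits and tolerances must be positive")
        if self.noise not in ("fixed", "joint"):
            raise ValueError("noise must be 'fixed' or 'joint'")


@dataclass
class PosteriorState:
    """Live quantities of one sweep of the RVM iteration."""

    active: np.ndarray  # column indices into the DesignMatrix
    alpha: np.ndarray
    sigma2: float
    mu: np.ndarray
    Sigma: np.ndarray
    log_ml: float


@dataclass
class RVMModel:
    """A converged RVM fit.

    ``relevance_indices`` hold marker indices (basis mode) or
    training-point indices (kernel mode); the value -1 denotes the
    intercept.  ``target_mean``/``target_scale`` record the target
    standardisation applied before fitting, inverted by :func:`predict`.
    An empty model (no surviving columns) predicts ``target_mean``.
    """

    basis_kind: str
    relevance_indices: np.ndarray
    relevance_weights: np.ndarray
    sigma2: float
    n_features: int
    kernel: KernelSpec | None = None
    rv_inputs: np.ndarray | None = None  # genotype rows of the kernel RVs
    target_mean: float = 0.0
    target_scale: float = 1.0
    n_iterations: int = 0
    log_ml: float = float("nan")
    alpha: np.ndarray | None = None  # converged precisions, aligned with relevance_indices
    n_training: int = 0  # individuals the model was fitted on

    @property
    def n_relevance_vectors(self) -> int:
        return int(self.relevance_indices.size)

    @property
    def marker_indices(self) -> np.ndarray:
        """Relevance markers of a basis model, intercept excluded."""
        if self.basis_kind != "linear_basis":
            raise ValueError("marker_indices is defined only for linear-basis models")
        keep = self.relevance_indices != INTERCEPT
        return self.relevance_indices[keep]

    @property
    def marker_weights(self) -> np.ndarray:
        if self.basis_kind != "linear_basis":
            raise ValueError("marker_weights is defined only for linear-basis models")
        keep = self.relevance_indices != INTERCEPT
        return self.relevance_weights[keep]


def build_design_matrix(
    X: np.ndarray,
    spec: KernelSpec,
    include_kernel_intercept: bool = False,
) -> DesignMatrix:
    """Build the design matrix for a genotype matrix under a basis family.

    Basis mode returns the ``N x (M+1)`` matrix whose first column is the
    intercept and whose remaining columns are the (strictly 0/1) marker
    genotypes.  Kernel mode returns the ``N x N`` Gram matrix (plus an
    optional leading intercept column).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, m = X.shape
    if n < 2 or m < 1:
        raise ValueError(f"genotype matrix must have N >= 2 individuals and M >= 1 markers, got {n} x {m}")
    if spec.family == "linear_basis":
        if not np.isin(X, (0.0, 1.0)).all():
            bad = np.argwhere(~np.isin(X, (0.0, 1.0)))[0]
            raise ValueError(
                f"linear-basis mode requires strictly 0/1 genotypes; "
                f"found {X[bad[0], bad[1]]!r} at row {bad[0]}, column {bad[1]}"
            )
        values = np.hstack([np.ones((n, 1)), X])
        columns = np.concatenate([[INTERCEPT], np.arange(m)])
        return DesignMatrix(values=values, basis_kind="linear_basis", columns=columns)
    gram = kernel_matrix(X, X, spec)
    if include_kernel_intercept:
        values = np.hstack([np.ones((n, 1)), gram])
        columns = np.concatenate([[INTERCEPT], np.arange(n)])
    else:
        values = gram
        columns = np.arange(n)
    return DesignMatrix(
        values=values, basis_kind="kernel", columns=columns, kernel=spec, training_inputs=X.copy()
    )


def _chol_spd(B: np.ndarray) -> np.ndarray:
    """Cholesky factor of an SPD matrix with one diagonal-jitter retry."""
    try:
        return linalg.cholesky(B, lower=True)
    except linalg.LinAlgError:
        jitter = 1e-10 * np.trace(B) / B.shape[0]
        try:
            return linalg.cholesky(B + jitter * np.eye(B.shape[0]), lower=True)
        except linalg.LinAlgError as exc:
            raise IllConditionedError(
                "posterior factorisation failed even with diagonal jitter; "
                "the active design is numerically singular"
            ) from exc


def _posterior_from_gram(
    G: np.ndarray, q: np.ndarray, alpha: np.ndarray, sigma2: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Posterior (Sigma, mu) and log|B| from Gram statistics.

    ``G = Phi^T Phi`` and ``q = Phi^T t`` for the active columns;
    ``B = G / sigma2 + diag(alpha)`` is the posterior precision.
    """
    B = G / sigma2 + np.diag(alpha)
    L = _chol_spd(B)
    logdet_B = 2.0 * float(np.sum(np.log(np.diag(L))))
    Sigma = linalg.cho_solve((L, True), np.eye(B.shape[0]))
    Sigma = 0.5 * (Sigma + Sigma.T)
    mu = linalg.cho_solve((L, True), q) / sigma2
    return Sigma, mu, logdet_B


def posterior_stats(
    Phi_active: np.ndarray, t: np.ndarray, alpha: np.ndarray, sigma2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior covariance and mean of the weights over the active columns.

    ``Sigma = (Phi^T Phi / sigma2 + diag(alpha))^{-1}`` and
    ``mu = Sigma Phi^T t / sigma2``, computed through a Cholesky
    factorisation of the posterior precision (never a generic inverse).
    """
    Phi_active = np.atleast_2d(np.asarray(Phi_active, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    if alpha.size != Phi_active.shape[1]:
        raise ValueError("alpha length must equal the number of active columns")
    if np.any(alpha <= 0) or sigma2 <= 0:
        raise ValueError("alpha entries and sigma2 must be positive")
    Sigma, mu, _ = _posterior_from_gram(Phi_active.T @ Phi_active, Phi_active.T @ t, alpha, sigma2)
    return Sigma, mu


def update_hyperparameters(
    state: PosteriorState,
    Phi_active: np.ndarray,
    t: np.ndarray,
    *,
    alpha_prune_threshold: float = 1e12,
    clamp_sigma2_min: float = 0.0,
) -> tuple[np.ndarray, float]:
    """One type-II maximum-likelihood re-estimation of ``alpha`` and ``sigma2``.

    ``alpha_i <- gamma_i / mu_i^2`` with ``gamma_i = 1 - alpha_i Sigma_ii``
    (the well-determinedness of weight i), and
    ``sigma2 <- ||t - Phi mu||^2 / (N - sum_i gamma_i)``.  A weight whose
    posterior mean is exactly zero, or whose ``gamma_i`` underflows to
    zero, gets ``alpha_prune_threshold`` as a prune signal.
    """
    Phi_active = np.atleast_2d(np.asarray(Phi_active, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    n = t.size
    mu, Sigma, alpha = state.mu, state.Sigma, state.alpha
    gamma = np.clip(1.0 - alpha * np.diag(Sigma), 0.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_new = gamma / np.square(mu)
    # mu == 0 (prior pinned the weight) or gamma == 0 (no evidence for it):
    # either way the column is due for pruning.
    alpha_new[~np.isfinite(alpha_new) | (alpha_new <= 0)] = alpha_prune_threshold

    denom = n - float(np.sum(gamma))
    if denom <= 0:
        raise DegenerateFitError(
            f"noise-variance denominator N - sum(gamma) = {denom:.3g} <= 0: "
            "the model is saturated (as many well-determined weights as data points)"
        )
    resid = t - Phi_active @ mu
    sigma2_new = float(resid @ resid) / denom
    sigma2_new = max(sigma2_new, clamp_sigma2_min)
    return alpha_new, sigma2_new


def log_marginal_likelihood(
    Phi_active: np.ndarray, t: np.ndarray, alpha: np.ndarray, sigma2: float
) -> float:
    """Log evidence ``log N(t | 0, C)`` with ``C = sigma2 I + Phi A^{-1} Phi^T``.

    Evaluated through the k x k posterior precision
    ``B = Phi^T Phi / sigma2 + diag(alpha)`` using the determinant and
    Woodbury identities (cost ``O(N k^2)``; ``C`` is never formed):
    ``log|C| = N log sigma2 - sum log alpha + log|B|`` and
    ``t^T C^{-1} t = (t^T t - t^T Phi mu) / sigma2``.
    """
    Phi_active = np.atleast_2d(np.asarray(Phi_active, dtype=float))
    t = np.asarray(t, dtype=float).ravel()
    alpha = np.asarray(alpha, dtype=float).ravel()
    n = t.size
    _, mu, logdet_B = _posterior_from_gram(
        Phi_active.T @ Phi_active, Phi_active.T @ t, alpha, sigma2
    )
    value = _log_ml_from_parts(n, sigma2, alpha, logdet_B, float(t @ t), float((Phi_active.T @ t) @ mu))
    if not np.isfinite(value):
        raise RVMFitError(f"log marginal likelihood is not finite ({value})")
    return value


def _log_ml_from_parts(
    n: int, sigma2: float, alpha: np.ndarray, logdet_B: float, tt: float, qmu: float
) -> float:
    logdet_C = n * np.log(sigma2) - float(np.sum(np.log(alpha))) + logdet_B
    quad = (tt - qmu) / sigma2
    return -0.5 * (n * np.log(2.0 * np.pi) + logdet_C + quad)


def _empty_model(Phi: DesignMatrix, t_mean: float, sigma2: float, n_iter: int) -> RVMModel:
    logger.warning("all basis columns pruned; returning an empty model that predicts the target mean")
    n_features = (
        Phi.training_inputs.shape[1]
        if Phi.basis_kind == "kernel"
        else int(Phi.n_columns - 1)
    )
    return RVMModel(
        basis_kind=Phi.basis_kind,
        relevance_indices=np.empty(0, dtype=int),
        relevance_weights=np.empty(0),
        sigma2=sigma2,
        n_features=n_features,
        kernel=Phi.kernel,
        rv_inputs=None,
        target_mean=t_mean,
        n_iterations=n_iter,
        alpha=np.empty(0),
        n_training=Phi.n,
    )


def fit_rvm(
    Phi: DesignMatrix,
    t: np.ndarray,
    config: RVMConfig | None = None,
    *,
    freeze_hyperparameters: bool = False,
    log_ml_trace: list | None = None,
    active_trace: list | None = None,
) -> RVMModel:
    """Fit an RVM by full-batch evidence maximisation with basis pruning.

    Every column starts with precision ``alpha_init``; each sweep
    recomputes the posterior, re-estimates the hyperparameters according
    to ``config.noise`` (see :class:`RVMConfig`), permanently removes
    columns whose precision reached the prune threshold, and stops when
    the log marginal likelihood has converged.

    With ``freeze_hyperparameters=True`` the hyperparameters stay at
    their initial values and a single posterior evaluation is returned —
    the penalised-least-squares (ridge) limit of the model.  If
    ``log_ml_trace`` is a list, the per-sweep log marginal likelihood is
    appended to it.
    """
    config = config or RVMConfig()
    t = np.asarray(t, dtype=float).ravel()
    if np.isnan(t).any():
        raise ValueError("targets contain missing values; filter them out before fitting")
    n = Phi.n
    if t.size != n:
        raise ValueError(f"target length {t.size} does not match design rows {n}")
    if n < 2:
        raise ValueError("need at least two training individuals")

    t_mean = float(np.mean(t))
    tc = t - t_mean
    var_t = float(np.var(tc))
    if var_t == 0.0:  # constant target: no signal, nothing to fit
        return _empty_model(Phi, t_mean, config.clamp_sigma2_min, 0)

    sigma2 = config.sigma2_init_fraction * var_t
    sigma2_floor = config.clamp_sigma2_min * var_t

    # Gram statistics of the full design, sliced per sweep as columns drop.
    G = Phi.values.T @ Phi.values
    q = Phi.values.T @ tc
    tt = float(tc @ tc)

    active = np.arange(Phi.n_columns)
    alpha = np.full(Phi.n_columns, config.alpha_init)

    update_sigma2 = False  # joined in after the alpha-phase converges
    log_ml_prev = -np.inf
    log_ml = -np.inf
    mu = np.empty(0)
    n_iter = 0
    for n_iter in range(1, config.max_iterations + 1):
        Ga = G[np.ix_(active, active)]
        qa = q[active]
        Sigma, mu, logdet_B = _posterior_from_gram(Ga, qa, alpha, sigma2)
        log_ml = _log_ml_from_parts(n, sigma2, alpha, logdet_B, tt, float(qa @ mu))
        if not np.isfinite(log_ml):
            raise RVMFitError(f"log marginal likelihood is not finite ({log_ml}) at sweep {n_iter}")
        if log_ml_trace is not None:
            log_ml_trace.append(log_ml)
        if active_trace is not None:
            active_trace.append(active.copy())

        if freeze_hyperparameters:
            log_ml_prev = log_ml
            break

        gamma = np.clip(1.0 - alpha * np.diag(Sigma), 0.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            alpha_new = gamma / np.square(mu)
        alpha_new[~np.isfinite(alpha_new) | (alpha_new <= 0)] = config.alpha_prune_threshold
        if update_sigma2:
            denom = n - float(np.sum(gamma))
            if denom > 0:
                resid = tc - Phi.values[:, active] @ mu
                sigma2 = max(float(resid @ resid) / denom, sigma2_floor)
        # precisions still travelling towards the prune threshold move by a
        # roughly constant log factor per sweep while the evidence has long
        # plateaued; convergence therefore also requires the precisions to
        # have stopped moving, so no column is left mid-prune.
        max_dlog_alpha = float(np.max(np.abs(np.log(alpha_new / alpha))))
        alpha = alpha_new

        keep = alpha < config.alpha_prune_threshold
        pruned = not keep.all()
        if pruned:
            active = active[keep]
            alpha = alpha[keep]
        if active.size == 0:
            return _empty_model(Phi, t_mean, sigma2, n_iter)

        converged = (
            np.isfinite(log_ml_prev)
            and abs(log_ml - log_ml_prev) < config.logml_rel_tolerance * abs(log_ml_prev)
            and not pruned
            and max_dlog_alpha < _ALPHA_MOTION_TOL
        )
        log_ml_prev = log_ml
        if converged:
            if config.noise == "fixed" or update_sigma2:
                break
            # alpha-phase done: join noise re-estimation and keep sweeping
            update_sigma2 = True
            log_ml_prev = -np.inf

    if not freeze_hyperparameters:
        # Final posterior consistent with the last hyperparameter values.
        Ga = G[np.ix_(active, active)]
        _, mu, _ = _posterior_from_gram(Ga, q[active], alpha, sigma2)

    rv_inputs = None
    if Phi.basis_kind == "kernel":
        point_cols = Phi.columns[active] != INTERCEPT
        rv_inputs = Phi.training_inputs[Phi.columns[active][point_cols]]
        n_features = Phi.training_inputs.shape[1]
    else:
        n_features = Phi.n_columns - 1
    return RVMModel(
        basis_kind=Phi.basis_kind,
        relevance_indices=Phi.columns[active].copy(),
        relevance_weights=np.asarray(mu, dtype=float),
        sigma2=float(sigma2),
        n_features=int(n_features),
        kernel=Phi.kernel,
        rv_inputs=rv_inputs,
        target_mean=t_mean,
        n_iterations=n_iter,
        log_ml=float(log_ml_prev),
        alpha=np.asarray(alpha, dtype=float),
        n_training=n,
    )


def predict(model: RVMModel, X_new: np.ndarray) -> np.ndarray:
    """Predict targets for new individuals from a fitted model.

    Kernel mode sums ``w_r K(x*, x_r)`` over the relevance vectors; basis
    mode evaluates ``w_0 + sum_m w_m x*[m]`` over the relevance markers.
    The recorded target standardisation is inverted.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.n_features:
        raise ValueError(
            f"X_new has {X_new.shape[1]} markers but the model was trained with {model.n_features}"
        )
    q = X_new.shape[0]
    y = np.zeros(q)
    if model.n_relevance_vectors:
        if model.basis_kind == "kernel":
            is_intercept = model.relevance_indices == INTERCEPT
            w_pts = model.relevance_weights[~is_intercept]
            if w_pts.size:
                K = kernel_matrix(X_new, model.rv_inputs, model.kernel)
                y = K @ w_pts
            y = y + float(model.relevance_weights[is_intercept].sum())
        else:
            is_intercept = model.relevance_indices == INTERCEPT
            idx = model.relevance_indices[~is_intercept]
            w = model.relevance_weights[~is_intercept]
            y = X_new[:, idx] @ w + float(model.relevance_weights[is_intercept].sum())
    return y * model.target_scale + model.target_mean


def fit(
    X: np.ndarray,
    t: np.ndarray,
    spec: KernelSpec,
    config: RVMConfig | None = None,
) -> RVMModel:
    """Convenience wrapper: build the design matrix for ``spec`` and fit."""
    config = config or RVMConfig()
    Phi = build_design_matrix(X, spec, include_kernel_intercept=config.include_kernel_intercept)
    return fit_rvm(Phi, t, config)
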