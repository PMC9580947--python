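"""Bagged ensembles of linear-basis RVMs for marker ranking.

Each ensemble member is a linear-basis RVM trained on a random
subsample (without replacement) of the individuals.  A marker's rank is
the number of members that retained it as a relevance vector; markers
never selected are reported as unranked.  The mean relevance weight over
the selecting members gives each marker a signed effect estimate
(trait-increasing or trait-decreasing).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .core import RVMConfig, RVMFitError, RVMModel, fit
from .kernels import KernelSpec

__all__ = [
    "EnsembleConfig",
    "MarkerRanking",
    "subsample_indices",
    "fit_ensemble",
    "rank_markers",
    "influential_markers",
    "top_k",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnsembleConfig:
    """Bagging parameters: 400 members at 50–60% subsampling by default."""

    n_models: int = 400
    subsample_fraction_range: tuple[float, float] = (0.50, 0.60)
    threshold_fraction: float = 0.5
    base_seed: int = 0
    parallel_workers: int = 0  # 0 or 1 -> serial
    max_failure_fraction: float = 0.10

    def __post_init__(self) -> None:
        lo, hi = self.subsample_fraction_range
        if not (0 < lo <= hi < 1):
            raise ValueError("subsample_fraction_range must satisfy 0 < lo <= hi < 1")
        if self.n_models < 2:
            raise ValueError("n_models must be at least 2")
        if not 0 < self.threshold_fraction <= 1:
            raise ValueError("threshold_fraction must lie in (0, 1]")


@dataclass
class MarkerRanking:
    """Aggregated relevance-vector counts and signed mean weights.

    ``order`` lists the ranked markers (count > 0) sorted by count
    descending, ties by absolute mean weight descending, final ties by
    marker index ascending — a deterministic total order.  Markers with
    count 0 never appeared as relevance vectors and are unranked.
    """

    n_models_run: int
    counts: np.ndarray  # per marker, length M
    mean_weights: np.ndarray  # 0 where count == 0
    order: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        ranked = np.flatnonzero(self.counts > 0)
        sort_key = np.lexsort(
            (ranked, -np.abs(self.mean_weights[ranked]), -self.counts[ranked])
        )
        self.order = ranked[sort_key]

    @property
    def n_markers(self) -> int:
        return int(self.counts.size)

    @property
    def rank_fractions(self) -> np.ndarray:
        return self.counts / self.n_models_run

    @property
    def signs(self) -> np.ndarray:
        """+1 / -1 / 0 per marker (0 for unranked or exactly-zero mean weight)."""
        return np.sign(self.mean_weights).astype(int)

    def to_frame(self) -> pd.DataFrame:
        """Ranked markers as a table, one row per ranked marker, in order."""
        o = self.order
        return pd.DataFrame(
            {
                "marker": o,
                "count": self.counts[o].astype(int),
                "rank_fraction": self.rank_fractions[o],
                "mean_weight": self.mean_weights[o],
                "sign": np.where(self.mean_weights[o] > 0, "+", np.where(self.mean_weights[o] < 0, "-", "0")),
            }
        ).reset_index(drop=True)


def subsample_indices(n: int, fraction: float, rng_seed: int) -> np.ndarray:
    """``floor(fraction * n)`` distinct indices drawn uniformly without replacement."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie strictly between 0 and 1")
    size = int(np.floor(fraction * n))
    if size < 2:
        raise ValueError(f"subsample of {size} individuals from {n} is too small to fit on")
    rng = np.random.default_rng(rng_seed)
    return np.sort(rng.choice(n, size=size, replace=False))


def _fit_member(j: int, X: np.ndarray, t: np.ndarray, cfg: EnsembleConfig, rvm_cfg: RVMConfig):
    seed = cfg.base_seed + j
    lo, hi = cfg.subsample_fraction_range
    fraction = float(np.random.default_rng(seed).uniform(lo, hi))
    rows = subsample_indices(X.shape[0], fraction, seed)
    try:
        model = fit(X[rows], t[rows], KernelSpec.linear_basis(), rvm_cfg)
        return model, None
    except RVMFitError as exc:  # pragma: no cover - rare numerical failure
        return None, (seed, str(exc))


def fit_ensemble(
    X: np.ndarray,
    t: np.ndarray,
    cfg: EnsembleConfig | None = None,
    rvm_cfg: RVMConfig | None = None,
) -> list[RVMModel]:
    """Train ``cfg.n_models`` basis RVMs on independent subsamples.

    Member ``j`` is seeded with ``base_seed + j`` (for both its
    subsample fraction and its row draw), so the result is identical
    whether members run serially or across ``parallel_workers``.
    Individual member failures are tolerated up to
    ``max_failure_fraction`` and logged with their seeds.
    """
    cfg = cfg or EnsembleConfig()
    rvm_cfg = rvm_cfg or RVMConfig()
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if np.isnan(t).any():
        raise ValueError("targets contain missing values; filter them out before fitting")

    jobs = range(cfg.n_models)
    if cfg.parallel_workers > 1:
        results = Parallel(n_jobs=cfg.parallel_workers)(
            delayed(_fit_member)(j, X, t, cfg, rvm_cfg) for j in jobs
        )
    else:
        results = [_fit_member(j, X, t, cfg, rvm_cfg) for j in jobs]

    models = [m for m, _ in results if m is not None]
    failures = [err for _, err in results if err is not None]
    for seed, msg in failures:
        logger.warning("ensemble member with seed %d failed: %s", seed, msg)
    if len(failures) > cfg.max_failure_fraction * cfg.n_models:
        raise RVMFitError(
            f"{len(failures)} of {cfg.n_models} ensemble members failed "
            f"(> {cfg.max_failure_fraction:.0%}); seeds: {[s for s, _ in failures]}"
        )
    return models


def rank_markers(models: list[RVMModel], n_markers: int | None = None) -> MarkerRanking:
    """Aggregate relevance markers over basis-RVM members into a ranking.

    ``counts[m]`` is the number of members whose relevance vectors
    include marker ``m`` (the intercept never participates);
    ``mean_weights[m]`` averages the relevance weights over exactly
    those members.
    """
    if not models:
        raise ValueError("no models to rank")
    for mod in models:
        if mod.basis_kind != "linear_basis":
            raise ValueError("marker ranking requires linear-basis models, got a kernel model")
    if n_markers is None:
        n_markers = models[0].n_features
    counts = np.zeros(n_markers, dtype=int)
    weight_sums = np.zeros(n_markers)
    for mod in models:
        idx = mod.marker_indices
        counts[idx] += 1
        weight_sums[idx] += mod.marker_weights
    with np.errstate(invalid="ignore"):
        mean_weights = np.where(counts > 0, weight_sums / np.maximum(counts, 1), 0.0)
    return MarkerRanking(n_models_run=len(models), counts=counts, mean_weights=mean_weights)


def influential_markers(r: MarkerRanking, threshold_fraction: float | None = None) -> pd.DataFrame:
    """Markers selected by at least ``threshold_fraction`` of the members.

    The defining rule for "most influential markers": a marker qualifies
    when at least that fraction of the ensemble retained it as a
    relevance vector (default half).  Order is inherited from the
    ranking; signs mark trait-increasing (+) and trait-decreasing (−)
    effects.
    """
    threshold = 0.5 if threshold_fraction is None else threshold_fraction
    if not 0 < threshold <= 1:
        raise ValueError("threshold_fraction must lie in (0, 1]")
    frame = r.to_frame()
    return frame[frame["rank_fraction"] >= threshold].reset_index(drop=True)


def top_k(r: MarkerRanking, k: int) -> pd.DataFrame:
    """First ``k`` markers of the deterministic ranking order."""
    if k < 1:
        raise ValueError("k must be positive")
    if k > r.n_markers:
        raise ValueError(f"k = {k} exceeds the number of markers ({r.n_markers})")
    n_ranked = r.order.size
    if k > n_ranked:
        warnings.warn(
            f"only {n_ranked} markers were ever selected; returning all of them instead of {k}",
            stacklevel=2,
        )
        k = n_ranked
    return r.to_frame().head(k).reset_index(drop=True)
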