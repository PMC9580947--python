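"""Repeated k-fold cross-validation, model selection and correlations.

Prediction accuracy is the coefficient of determination
``R^2 = 1 - SS_res / SS_tot`` on held-out individuals, computed per
fold, averaged within each repeat; the spread across repeat means is
the reported stability.  Model selection compares basis/kernel
candidates on identical fold partitions and breaks exact ties in favour
of the simpler family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold

from .core import RVMConfig, fit, predict
from .kernels import FAMILY_COMPLEXITY, KernelSpec

__all__ = [
    "CVConfig",
    "CVResult",
    "r_squared",
    "pearson_correlation",
    "repeated_kfold_cv",
    "select_model",
]


@dataclass(frozen=True)
class CVConfig:
    """10 repeats of 10-fold cross-validation by default, freshly shuffled per repeat."""

    repeats: int = 10
    folds: int = 10
    seed: int = 0
    shuffle: bool = True

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be at least 2")
        if self.repeats < 1:
            raise ValueError("repeats must be at least 1")


@dataclass
class CVResult:
    """Cross-validated accuracy of one model candidate."""

    model_label: str
    per_fold_r2: np.ndarray  # repeats x folds
    spec: KernelSpec | None = None

    @property
    def per_repeat_mean_r2(self) -> np.ndarray:
        return self.per_fold_r2.mean(axis=1)

    @property
    def mean_r2(self) -> float:
        return float(self.per_repeat_mean_r2.mean())

    @property
    def std_r2(self) -> float:
        """Sample standard deviation across the repeat means."""
        reps = self.per_repeat_mean_r2
        return float(reps.std(ddof=1)) if reps.size > 1 else 0.0


def r_squared(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot`` (may be negative)."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size:
        raise ValueError("y_true and y_pred must have equal length")
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("y_true is constant; R^2 is undefined")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def pearson_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Sample Pearson correlation coefficient between two vectors."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError("vectors must have equal length")
    if a.size < 3:
        raise ValueError("need at least three observations")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValueError("correlation is undefined for a constant vector")
    ac = a - a.mean()
    bc = b - b.mean()
    return float((ac @ bc) / np.sqrt((ac @ ac) * (bc @ bc)))


def repeated_kfold_cv(
    X: np.ndarray,
    t: np.ndarray,
    spec: KernelSpec,
    rvm_cfg: RVMConfig | None = None,
    cv_cfg: CVConfig | None = None,
) -> CVResult:
    """Repeatedly cross-validate one model candidate.

    Repeat ``r`` partitions the individuals with seed ``cv_cfg.seed + r``,
    fits on each training fold and scores R^2 on the held-out fold.
    Individuals with missing targets must be removed beforehand.
    """
    rvm_cfg = rvm_cfg or RVMConfig()
    cv_cfg = cv_cfg or CVConfig()
    X = np.asarray(X, dtype=float)
    t = np.asarray(t, dtype=float).ravel()
    if np.isnan(t).any():
        raise ValueError("targets contain missing values; align/filter first")
    n = t.size
    if n < cv_cfg.folds:
        raise ValueError(f"cannot make {cv_cfg.folds} folds from {n} individuals")

    per_fold = np.empty((cv_cfg.repeats, cv_cfg.folds))
    for r in range(cv_cfg.repeats):
        splitter = KFold(
            n_splits=cv_cfg.folds,
            shuffle=cv_cfg.shuffle,
            random_state=(cv_cfg.seed + r) if cv_cfg.shuffle else None,
        )
        for f, (train_idx, test_idx) in enumerate(splitter.split(X)):
            model = fit(X[train_idx], t[train_idx], spec, rvm_cfg)
            per_fold[r, f] = r_squared(t[test_idx], predict(model, X[test_idx]))
    return CVResult(model_label=spec.label(), per_fold_r2=per_fold, spec=spec)


def _simplicity_key(spec: KernelSpec) -> tuple:
    return (FAMILY_COMPLEXITY[spec.family], spec.gamma or 0.0, spec.c, spec.d)


def select_model(
    X: np.ndarray,
    t: np.ndarray,
    candidates: list[KernelSpec],
    rvm_cfg: RVMConfig | None = None,
    cv_cfg: CVConfig | None = None,
) -> tuple[KernelSpec, list[CVResult]]:
    """Cross-validate every candidate and return the best plus the full table.

    The winner maximises mean R^2; exact ties go to the simpler family
    (linear basis < linear kernel < polynomial < gaussian), then to the
    smaller kernel parameters.
    """
    if not candidates:
        raise ValueError("need at least one candidate")
    table = [repeated_kfold_cv(X, t, spec, rvm_cfg, cv_cfg) for spec in candidates]
    return table[_best_index(table)].spec, table


def _best_index(table: list[CVResult]) -> int:
    best_idx = 0
    for i in range(1, len(table)):
        better = table[i].mean_r2 > table[best_idx].mean_r2
        tied_simpler = table[i].mean_r2 == table[best_idx].mean_r2 and _simplicity_key(
            table[i].spec
        ) < _simplicity_key(table[best_idx].spec)
        if better or tied_simpler:
            best_idx = i
    return best_idx


def default_candidates(gamma_grid=None) -> list[KernelSpec]:
    """Linear basis, linear kernel, and one Gaussian per bandwidth in the grid."""
    from .kernels import DEFAULT_GAMMA_GRID

    grid = DEFAULT_GAMMA_GRID if gamma_grid is None else gamma_grid
    return [KernelSpec.linear_basis(), KernelSpec.linear()] + [
        KernelSpec.gaussian(g) for g in grid
    ]
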