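"""Nested cross-validation, hyperparameter grids, and method comparison.

The protocol is an outer k-fold split where hyperparameters are tuned by an
inner k-fold grid search on the *first* outer training set only; the selected
configuration is reused for every remaining outer fold.  Standardization
statistics are always computed on the training portion and applied to the
held-out portion, so no information leaks across the split.  Failed fits are
recorded as NaN correlations and excluded from fold means with an explicit
failure count.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.stats
from sklearn.model_selection import KFold

from .exceptions import GraphSccaError, ValidationError
from .penalty_graph import FeatureGraph
from .solver import ColumnScaler, PairedData, SccaConfig, canonical_correlation, fit

__all__ = ["CvGrid", "CvResult", "run_nested_cv", "compare_methods"]

logger = logging.getLogger(__name__)

DEFAULT_PENALTY_VALUES = (1e-3, 1e-2, 1e-1, 1.0, 1e1, 1e2, 1e3)
DEFAULT_GAMMA_VALUES = (0.1, 1.0, 10.0)


@dataclass(frozen=True)
class CvGrid:
    """Hyperparameter grid; ``coupling="tied"`` sets lambda1=lambda2 etc."""

    lambda_values: tuple[float, ...] = DEFAULT_PENALTY_VALUES
    beta_values: tuple[float, ...] = DEFAULT_PENALTY_VALUES
    gamma_values: tuple[float, ...] = DEFAULT_GAMMA_VALUES
    coupling: str = "tied"

    def __post_init__(self) -> None:
        for name in ("lambda_values", "beta_values", "gamma_values"):
            vals = tuple(sorted(float(v) for v in getattr(self, name)))
            if any(v <= 0 for v in vals):
                raise ValidationError(f"{name} must all be > 0")
            object.__setattr__(self, name, vals)
        if self.coupling not in ("tied", "free"):
            raise ValidationError("coupling must be 'tied' or 'free'")

    @property
    def n_candidates(self) -> int:
        nl, nb, ng = (
            len(self.lambda_values),
            len(self.beta_values),
            len(self.gamma_values),
        )
        if self.coupling == "tied":
            return nl * nb * ng
        return nl**2 * nb**2 * ng**2

    def candidates(self, base: SccaConfig | None = None) -> list[SccaConfig]:
        """Enumerate candidate configs deterministically (ascending, lambda-major)."""
        base = base or SccaConfig()
        out: list[SccaConfig] = []
        if self.coupling == "tied":
            for lam, beta, gamma in itertools.product(
                self.lambda_values, self.beta_values, self.gamma_values
            ):
                out.append(
                    base.replace(
                        lambda1=lam, lambda2=lam,
                        beta1=beta, beta2=beta,
                        gamma1=gamma, gamma2=gamma,
                    )
                )
        else:
            for l1, l2, b1, b2, g1, g2 in itertools.product(
                self.lambda_values, self.lambda_values,
                self.beta_values, self.beta_values,
                self.gamma_values, self.gamma_values,
            ):
                out.append(
                    base.replace(
                        lambda1=l1, lambda2=l2,
                        beta1=b1, beta2=b2,
                        gamma1=g1, gamma2=g2,
                    )
                )
        return out


@dataclass
class CvResult:
    """Per-fold correlations plus the tuning outcome."""

    train_correlations: np.ndarray
    test_correlations: np.ndarray
    selected_config: SccaConfig
    fold_test_indices: list[np.ndarray]
    inner_mean_scores: np.ndarray = field(repr=False, default=None)
    comparison_pvalues: dict = field(default_factory=dict)

    @property
    def n_failed_test(self) -> int:
        return int(np.sum(~np.isfinite(self.test_correlations)))

    @property
    def n_failed_train(self) -> int:
        return int(np.sum(~np.isfinite(self.train_correlations)))

    @property
    def mean_train(self) -> float:
        return _nan_excluded_mean(self.train_correlations)

    @property
    def mean_test(self) -> float:
        return _nan_excluded_mean(self.test_correlations)


def _nan_excluded_mean(x: np.ndarray) -> float:
    """Fold mean with NaN (failed) entries excluded; NaN if all failed."""
    x = np.asarray(x, dtype=float)
    ok = np.isfinite(x)
    if not ok.any():
        return float("nan")
    return float(x[ok].mean())


def _fit_and_score(
    data: PairedData,
    graphs: tuple[FeatureGraph | None, FeatureGraph | None],
    config: SccaConfig,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
) -> tuple[float, float]:
    """Fit on the training rows, score train and held-out correlations.

    Held-out rows are transformed with the training statistics.  Any solver
    failure is folded into the NaN convention instead of raised.
    """
    try:
        sx = ColumnScaler.fit(data.X[train_idx], data.x_features)
        sy = ColumnScaler.fit(data.Y[train_idx], data.y_features)
        train = PairedData(
            X=sx.transform(data.X[train_idx]),
            Y=sy.transform(data.Y[train_idx]),
            sample_ids=[data.sample_ids[i] for i in train_idx],
            x_features=list(data.x_features),
            y_features=list(data.y_features),
            standardized=True,
        )
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            result = fit(train, graphs, config)
        test_corr = canonical_correlation(
            result.u, result.v, sx.transform(data.X[test_idx]), sy.transform(data.Y[test_idx])
        )
        return result.train_correlation, float(test_corr)
    except GraphSccaError as err:
        logger.debug("fold fit failed (%s); recording NaN", err)
        return float("nan"), float("nan")


def run_nested_cv(
    data: PairedData,
    graphs: tuple[FeatureGraph | None, FeatureGraph | None] | None = None,
    grid: CvGrid | None = None,
    k: int = 5,
    seed: int = 0,
    base_config: SccaConfig | None = None,
) -> CvResult:
    """Nested k-fold CV with tuning on the first outer training set only.

    Selection maximizes the NaN-excluded mean inner-validation correlation;
    ties go to the later (larger-penalty) candidate in the deterministic
    enumeration, preferring sparser solutions.
    """
    if grid is None:
        grid = CvGrid()
    if graphs is None:
        graphs = (None, None)
    base_config = base_config or SccaConfig()
    n = data.n
    if n < 2 * k:
        raise ValidationError(f"need n >= 2k samples for {k}-fold CV (n={n})")

    outer = list(
        KFold(n_splits=k, shuffle=True, random_state=seed).split(np.arange(n))
    )

    # inner grid search on the first outer training set only
    first_train = outer[0][0]
    inner = list(
        KFold(n_splits=k, shuffle=True, random_state=seed + 1).split(first_train)
    )
    candidates = grid.candidates(base_config)
    inner_means = np.full(len(candidates), -np.inf)
    for ci, cand in enumerate(candidates):
        scores = []
        for tr, va in inner:
            _, s = _fit_and_score(data, graphs, cand, first_train[tr], first_train[va])
            scores.append(s)
        mean = _nan_excluded_mean(np.asarray(scores))
        inner_means[ci] = -np.inf if np.isnan(mean) else mean
    best = int(np.flatnonzero(inner_means == inner_means.max())[-1])
    selected = candidates[best]
    logger.info(
        "inner CV selected candidate %d/%d (mean inner corr %.4f): "
        "lambda=%.3g beta=%.3g gamma=%.3g",
        best + 1, len(candidates), inner_means[best],
        selected.lambda1, selected.beta1, selected.gamma1,
    )

    train_corrs = np.empty(k)
    test_corrs = np.empty(k)
    fold_test = []
    for fi, (tr, te) in enumerate(outer):
        train_corrs[fi], test_corrs[fi] = _fit_and_score(data, graphs, selected, tr, te)
        fold_test.append(te)
    return CvResult(
        train_correlations=train_corrs,
        test_correlations=test_corrs,
        selected_config=selected,
        fold_test_indices=fold_test,
        inner_mean_scores=inner_means,
    )


def compare_methods(
    fold_scores_a: Sequence[float], fold_scores_b: Sequence[float]
) -> float:
    """Two-sided paired t-test p-value between two methods' fold scores.

    Pairs with a NaN on either side are dropped; fewer than two usable pairs
    (or all-NaN input) returns NaN, marking the comparison unavailable.
    Identical score vectors give p = 1 (zero t statistic).
    """
    a = np.asarray(fold_scores_a, dtype=float)
    b = np.asarray(fold_scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValidationError("fold score vectors must have equal length")
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2:
        return float("nan")
    d = a[ok] - b[ok]
    if np.all(d == d[0]):  # zero-variance differences: t-test degenerates
        return 1.0 if d[0] == 0 else 0.0
    return float(scipy.stats.ttest_rel(a[ok], b[ok]).pvalue)
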