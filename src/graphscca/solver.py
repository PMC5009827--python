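"""The alternating, iteratively-reweighted sparse CCA solver.

Given paired standardized matrices X (n x p) and Y (n x q), the solver seeks
loadings (u, v) minimizing

    -u' X' Y v
      + lambda1 * ||u||_goscar + lambda2 * ||v||_goscar
      + beta1/2 * ||u||_1     + beta2/2 * ||v||_1
      + gamma1/2 * ||X u||_2^2 + gamma2/2 * ||Y v||_2^2

by alternating closed-form half-quadratic updates: with the other loading
fixed and weights rebuilt at the current iterate, each side solves the
symmetric positive-definite linear system

    (lambda (L + Lhat) + beta Lambda + gamma M'M) w = M'N other

where (M, N) = (X, Y) for the u-side and (Y, X) for the v-side.  Each solve
minimizes a quadratic majorizer of the zeta-smoothed objective, so the
smoothed objective decreases monotonically (the basis of the convergence
test suite).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.linalg
import scipy.sparse.linalg

from .exceptions import NumericalError, ValidationError
from .penalty_graph import FeatureGraph, GoscarWeights, reweight

__all__ = [
    "PairedData",
    "SccaConfig",
    "SccaFit",
    "ColumnScaler",
    "standardize",
    "objective",
    "update_loading",
    "fit",
    "canonical_correlation",
    "stationarity_residuals",
]

logger = logging.getLogger(__name__)

_JITTER_SCALES = (0.0, 1e-10, 1e-8, 1e-6)


def _as_labels(labels, n: int, prefix: str) -> list[str]:
    if labels is None:
        return [f"{prefix}{i + 1}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise ValidationError(f"expected {n} labels, got {len(labels)}")
    return labels


@dataclass
class PairedData:
    """Two sample-aligned numeric matrices with row/column labels."""

    X: np.ndarray
    Y: np.ndarray
    sample_ids: Sequence[str] | None = None
    x_features: Sequence[str] | None = None
    y_features: Sequence[str] | None = None
    standardized: bool = False

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        if self.X.ndim != 2 or self.Y.ndim != 2:
            raise ValidationError("X and Y must be 2-D matrices")
        if self.X.shape[0] != self.Y.shape[0]:
            raise ValidationError(
                f"X has {self.X.shape[0]} samples but Y has {self.Y.shape[0]}"
            )
        if not np.all(np.isfinite(self.X)) or not np.all(np.isfinite(self.Y)):
            raise ValidationError("X/Y contain NaN or Inf entries")
        self.sample_ids = _as_labels(self.sample_ids, self.X.shape[0], "s")
        self.x_features = _as_labels(self.x_features, self.X.shape[1], "x")
        self.y_features = _as_labels(self.y_features, self.Y.shape[1], "y")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return self.Y.shape[1]


@dataclass
class ColumnScaler:
    """Center each column, then scale it to unit l2 norm.

    After the transform every training column has zero mean and unit norm, so
    the Gram matrix of a side equals its sample correlation matrix and
    ``x_i' x_i = 1``.  Held-out data must be transformed with the *training*
    statistics.
    """

    mean_: np.ndarray
    scale_: np.ndarray

    @classmethod
    def fit(cls, M: np.ndarray, names: Sequence[str] | None = None) -> "ColumnScaler":
        M = np.asarray(M, dtype=float)
        mean = M.mean(axis=0)
        norms = np.linalg.norm(M - mean, axis=0)
        bad = np.flatnonzero(norms == 0)
        if bad.size:
            label = names[bad[0]] if names is not None else f"column {bad[0]}"
            raise ValidationError(f"zero-variance column: {label}")
        return cls(mean_=mean, scale_=norms)

    def transform(self, M: np.ndarray) -> np.ndarray:
        return (np.asarray(M, dtype=float) - self.mean_) / self.scale_


def standardize(data: PairedData) -> PairedData:
    """Column-standardize both matrices (zero mean, unit l2 norm); idempotent."""
    sx = ColumnScaler.fit(data.X, data.x_features)
    sy = ColumnScaler.fit(data.Y, data.y_features)
    return PairedData(
        X=sx.transform(data.X),
        Y=sy.transform(data.Y),
        sample_ids=list(data.sample_ids),
        x_features=list(data.x_features),
        y_features=list(data.y_features),
        standardized=True,
    )


@dataclass(frozen=True)
class SccaConfig:
    """Penalty weights and solver controls.

    ``rescale="per_iteration"`` renormalizes each loading to its unit
    projected norm after every update (the correlation is scale invariant);
    ``rescale="final"`` leaves iterates unscaled — the mode under which the
    objective trace is provably monotone — and rescales only at report time.
    """

    lambda1: float = 0.1
    lambda2: float = 0.1
    beta1: float = 0.1
    beta2: float = 0.1
    gamma1: float = 1.0
    gamma2: float = 1.0
    zeta: float = 1e-10
    tau: float = 1e-5
    max_iter: int = 100
    init: str = "ones"
    seed: int = 0
    rescale: str = "per_iteration"
    dense_cap: int = 5000

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "beta1", "beta2"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.gamma1 <= 0 or self.gamma2 <= 0:
            raise ValidationError("gamma1 and gamma2 must be > 0")
        if self.zeta <= 0:
            raise ValidationError("zeta must be > 0")
        if self.tau <= 0:
            raise ValidationError("tau must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.init not in ("ones", "random"):
            raise ValidationError("init must be 'ones' or 'random'")
        if self.rescale not in ("per_iteration", "final"):
            raise ValidationError("rescale must be 'per_iteration' or 'final'")

    def replace(self, **kwargs) -> "SccaConfig":
        return replace(self, **kwargs)


@dataclass
class SccaFit:
    """Result of one solver run."""

    u: np.ndarray
    v: np.ndarray
    objective_trace: np.ndarray
    n_iter: int
    converged: bool
    train_correlation: float
    config: SccaConfig | None = None
    weights_u: GoscarWeights | None = field(default=None, repr=False)
    weights_v: GoscarWeights | None = field(default=None, repr=False)
    # last iterates before the report-time rescale; with rescale="final" these
    # are the fixed point of the update map (used by the KKT diagnostics)
    u_raw: np.ndarray | None = field(default=None, repr=False)
    v_raw: np.ndarray | None = field(default=None, repr=False)
    # normalization factors applied inside the last iteration (1.0 when
    # rescale="final"); the per-iteration fixed point satisfies the
    # stationarity equations with the bilinear term divided by these
    scale_u: float = 1.0
    scale_v: float = 1.0


def _smooth_abs(x: np.ndarray, zeta: float) -> np.ndarray:
    if zeta > 0:
        return np.sqrt(x * x + zeta)
    return np.abs(x)


def _goscar_term(u: np.ndarray, graph: FeatureGraph, zeta: float) -> float:
    if graph.n_edges == 0:
        return 0.0
    ui = u[graph.edges[:, 0]]
    uj = u[graph.edges[:, 1]]
    return float(
        0.5 * (_smooth_abs(ui - uj, zeta).sum() + _smooth_abs(ui + uj, zeta).sum())
    )


def objective(
    u: np.ndarray,
    v: np.ndarray,
    data: PairedData,
    config: SccaConfig,
    graphs: tuple[FeatureGraph, FeatureGraph],
    zeta: float = 0.0,
) -> float:
    """Penalized objective value; ``zeta > 0`` evaluates the smooth surrogate."""
    graph_u, graph_v = graphs
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape[0] != data.p or v.shape[0] != data.q:
        raise ValidationError("loading lengths do not match data dimensions")
    Xu = data.X @ u
    Yv = data.Y @ v
    val = -float(Xu @ Yv)
    val += config.lambda1 * _goscar_term(u, graph_u, zeta)
    val += config.lambda2 * _goscar_term(v, graph_v, zeta)
    val += 0.5 * config.beta1 * float(_smooth_abs(u, zeta).sum())
    val += 0.5 * config.beta2 * float(_smooth_abs(v, zeta).sum())
    val += 0.5 * config.gamma1 * float(Xu @ Xu)
    val += 0.5 * config.gamma2 * float(Yv @ Yv)
    return val


def _solve_dense(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """SPD solve with escalating diagonal jitter; never forms an inverse."""
    mean_diag = float(np.mean(np.diag(A)))
    if not np.isfinite(mean_diag) or mean_diag <= 0:
        mean_diag = 1.0
    b_norm = max(float(np.linalg.norm(b)), 1.0)
    last_err: Exception | None = None
    for eps in _JITTER_SCALES:
        Aj = A if eps == 0.0 else A + (eps * mean_diag) * np.eye(A.shape[0])
        try:
            c, low = scipy.linalg.cho_factor(Aj, check_finite=False)
            w = scipy.linalg.cho_solve((c, low), b, check_finite=False)
        except scipy.linalg.LinAlgError as err:
            last_err = err
            continue
        if not np.all(np.isfinite(w)):
            last_err = NumericalError("non-finite solution")
            continue
        resid = float(np.linalg.norm(A @ w - b)) / b_norm
        if eps == 0.0 and resid > 1e-8:
            last_err = NumericalError(f"residual {resid:.3e} too large")
            continue
        if eps > 0.0:
            warnings.warn(
                f"linear system required diagonal jitter {eps:.0e} "
                f"(relative residual {resid:.3e})",
                RuntimeWarning,
                stacklevel=3,
            )
        return w
    raise NumericalError(
        f"linear system unsolvable after jitter escalation "
        f"(dim={A.shape[0]}, mean diag={mean_diag:.3e}): {last_err}"
    )


def _solve_matfree(
    M: np.ndarray,
    weights: GoscarWeights,
    lam: float,
    beta: float,
    gamma: float,
    b: np.ndarray,
) -> np.ndarray:
    """Conjugate-gradient path for feature counts above ``dense_cap``."""
    p = M.shape[1]
    diag = beta * weights.lambda_diag

    def matvec(x):
        return lam * weights.penalty_matvec(x) + diag * x + gamma * (M.T @ (M @ x))

    op = scipy.sparse.linalg.LinearOperator((p, p), matvec=matvec)
    w, info = scipy.sparse.linalg.cg(op, b, rtol=1e-10, atol=0.0, maxiter=20 * p)
    if info != 0 or not np.all(np.isfinite(w)):
        raise NumericalError(f"conjugate gradient failed (info={info})")
    return w


def update_loading(
    side: str,
    data: PairedData,
    other_loading: np.ndarray,
    weights: GoscarWeights,
    config: SccaConfig,
    *,
    gram: np.ndarray | None = None,
    cross: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form update of one side's loading with the other side fixed.

    Solves ``(lambda (L + Lhat) + beta Lambda + gamma M'M) w = M'N other``
    where (M, N) = (X, Y) for ``side="u"`` and (Y, X) for ``side="v"``.
    ``gram``/``cross`` may carry precomputed ``M'M`` and ``M'N``.
    """
    if side == "u":
        M, N = data.X, data.Y
        lam, beta, gamma = config.lambda1, config.beta1, config.gamma1
    elif side == "v":
        M, N = data.Y, data.X
        lam, beta, gamma = config.lambda2, config.beta2, config.gamma2
    else:
        raise ValidationError("side must be 'u' or 'v'")
    other_loading = np.asarray(other_loading, dtype=float).ravel()
    if other_loading.shape[0] != N.shape[1]:
        raise ValidationError("other_loading length does not match")
    if weights.graph.n_features != M.shape[1]:
        raise ValidationError("weights do not match this side's feature count")

    b = cross @ other_loading if cross is not None else M.T @ (N @ other_loading)
    p = M.shape[1]
    if p > config.dense_cap:
        return _solve_matfree(M, weights, lam, beta, gamma, b)
    G = gram if gram is not None else M.T @ M
    A = lam * (weights.L + weights.L_hat) + np.diag(beta * weights.lambda_diag)
    A += gamma * G
    return _solve_dense(A, b)


def _projected_norm(M: np.ndarray, w: np.ndarray) -> float:
    return float(np.linalg.norm(M @ w))


def _rescaled(M: np.ndarray, w: np.ndarray) -> np.ndarray:
    s = _projected_norm(M, w)
    if s <= 0 or not np.isfinite(s):
        raise NumericalError("cannot rescale: projected loading has zero norm")
    return w / s


def _initial_loadings(
    data: PairedData, config: SccaConfig
) -> tuple[np.ndarray, np.ndarray]:
    if config.init == "random":
        rng = np.random.default_rng(config.seed)
        u0 = rng.standard_normal(data.p)
        v0 = rng.standard_normal(data.q)
    else:
        u0 = np.ones(data.p)
        v0 = np.ones(data.q)
    return _rescaled(data.X, u0), _rescaled(data.Y, v0)


def fit(
    data: PairedData,
    graphs: tuple[FeatureGraph | None, FeatureGraph | None] | None,
    config: SccaConfig | None = None,
    init_loadings: tuple[np.ndarray, np.ndarray] | None = None,
) -> SccaFit:
    """Run the alternating reweighted solver to convergence.

    Each iteration rebuilds this side's weights at the current iterate, solves
    the SPD system for that side, then does the same for the other side.
    Convergence requires ``max|du| <= tau`` and ``max|dv| <= tau`` in the same
    iteration.  The returned loadings are rescaled so that ``||Xu|| = 1`` and
    ``||Yv|| = 1``.
    """
    config = config or SccaConfig()
    if not data.standardized:
        raise ValidationError("fit requires standardized data (see standardize())")
    graph_u, graph_v = graphs if graphs is not None else (None, None)
    if graph_u is None:
        graph_u = FeatureGraph.complete(data.p)
    if graph_v is None:
        graph_v = FeatureGraph.complete(data.q)
    if graph_u.n_features != data.p or graph_v.n_features != data.q:
        raise ValidationError("graph sizes do not match data dimensions")

    X, Y = data.X, data.Y
    XtX = X.T @ X if data.p <= config.dense_cap else None
    YtY = Y.T @ Y if data.q <= config.dense_cap else None
    XtY = X.T @ Y
    per_iter = config.rescale == "per_iteration"

    if init_loadings is not None:
        u0, v0 = init_loadings
        u = np.asarray(u0, dtype=float).ravel().copy()
        v = np.asarray(v0, dtype=float).ravel().copy()
        if u.shape[0] != data.p or v.shape[0] != data.q:
            raise ValidationError("init_loadings lengths do not match data")
    else:
        u, v = _initial_loadings(data, config)
    trace: list[float] = []
    converged = False
    n_iter = 0
    scale_u = scale_v = 1.0
    weights_u = weights_v = None
    for n_iter in range(1, config.max_iter + 1):
        weights_u = reweight(u, graph_u, config.zeta)
        u_new = update_loading(
            "u", data, v, weights_u, config, gram=XtX, cross=XtY
        )
        if per_iter:
            scale_u = _projected_norm(X, u_new)
            u_new = _rescaled(X, u_new)
        weights_v = reweight(v, graph_v, config.zeta)
        v_new = update_loading(
            "v", data, u_new, weights_v, config, gram=YtY, cross=XtY.T
        )
        if per_iter:
            scale_v = _projected_norm(Y, v_new)
            v_new = _rescaled(Y, v_new)

        obj = objective(u_new, v_new, data, config, (graph_u, graph_v), zeta=config.zeta)
        if not np.isfinite(obj):
            raise NumericalError(f"objective became non-finite at iteration {n_iter}")
        trace.append(obj)
        du = float(np.max(np.abs(u_new - u)))
        dv = float(np.max(np.abs(v_new - v)))
        u, v = u_new, v_new
        logger.debug("iter %d: objective=%.6g du=%.3g dv=%.3g", n_iter, obj, du, dv)
        if du <= config.tau and dv <= config.tau:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"solver did not converge within {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    u_raw, v_raw = u.copy(), v.copy()
    u = _rescaled(X, u)
    v = _rescaled(Y, v)
    corr = canonical_correlation(u, v, X, Y)
    logger.info(
        "fit finished: n_iter=%d converged=%s objective=%.6g train_corr=%.4f",
        n_iter,
        converged,
        trace[-1],
        corr,
    )
    return SccaFit(
        u=u,
        v=v,
        objective_trace=np.asarray(trace),
        n_iter=n_iter,
        converged=converged,
        train_correlation=corr,
        config=config,
        weights_u=weights_u,
        weights_v=weights_v,
        u_raw=u_raw,
        v_raw=v_raw,
        scale_u=scale_u,
        scale_v=scale_v,
    )


def canonical_correlation(
    u: np.ndarray, v: np.ndarray, X_eval: np.ndarray, Y_eval: np.ndarray
) -> float:
    """Pearson correlation of the projected scores; NaN flags a failed estimate.

    Follows the reporting convention that an all-zero loading (or a projection
    with zero variance) yields NaN rather than an exception.
    """
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    X_eval = np.asarray(X_eval, dtype=float)
    Y_eval = np.asarray(Y_eval, dtype=float)
    if X_eval.shape[1] != u.shape[0] or Y_eval.shape[1] != v.shape[0]:
        raise ValidationError("loading/matrix dimension mismatch")
    if not np.any(u) or not np.any(v):
        return float("nan")
    a = X_eval @ u
    b = Y_eval @ v
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.clip((a @ b) / (na * nb), -1.0, 1.0))


def kkt_residuals(result: SccaFit, data: PairedData) -> tuple[np.ndarray, np.ndarray]:
    """Stationarity residuals at the converged fit using its stored matrices.

    Evaluates the two stationarity equations with the reweighting matrices
    from the final solves and the bilinear term divided by the last
    normalization factors; at convergence the max-norm is of order ``tau``.
    """
    if result.config is None or result.weights_u is None or result.weights_v is None:
        raise ValidationError("fit does not carry converged weights/config")
    cfg = result.config
    X, Y = data.X, data.Y
    wu, wv = result.weights_u, result.weights_v
    if cfg.rescale == "final" and result.u_raw is not None:
        u, v = result.u_raw, result.v_raw  # the unscaled fixed point
    else:
        u, v = result.u, result.v
    ru = (
        -X.T @ (Y @ v) / result.scale_u
        + cfg.lambda1 * wu.penalty_matvec(u)
        + cfg.beta1 * wu.lambda_diag * u
        + cfg.gamma1 * (X.T @ (X @ u))
    )
    rv = (
        -Y.T @ (X @ u) / result.scale_v
        + cfg.lambda2 * wv.penalty_matvec(v)
        + cfg.beta2 * wv.lambda_diag * v
        + cfg.gamma2 * (Y.T @ (Y @ v))
    )
    return ru, rv


def stationarity_residuals(
    u: np.ndarray,
    v: np.ndarray,
    data: PairedData,
    graphs: tuple[FeatureGraph, FeatureGraph],
    config: SccaConfig,
    bilinear_scale: tuple[float, float] = (1.0, 1.0),
) -> tuple[np.ndarray, np.ndarray]:
    """Gradients of the smoothed objective at (u, v) with weights rebuilt there.

    At an exact fixed point of the unscaled updates both residuals vanish;
    near convergence their max-norm is small, which the test suite uses as a
    KKT check.  Under per-iteration rescaling the fixed point satisfies the
    same equations with the bilinear term divided by the last normalization
    factors, passed as ``bilinear_scale = (fit.scale_u, fit.scale_v)``.
    """
    graph_u, graph_v = graphs
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    su, sv = bilinear_scale
    wu = reweight(u, graph_u, config.zeta)
    wv = reweight(v, graph_v, config.zeta)
    X, Y = data.X, data.Y
    ru = (
        -X.T @ (Y @ v) / su
        + config.lambda1 * wu.penalty_matvec(u)
        + config.beta1 * wu.lambda_diag * u
        + config.gamma1 * (X.T @ (X @ u))
    )
    rv = (
        -Y.T @ (X @ u) / sv
        + config.lambda2 * wv.penalty_matvec(v)
        + config.beta2 * wv.lambda_diag * v
        + config.gamma2 * (Y.T @ (Y @ v))
    )
    return ru, rv
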