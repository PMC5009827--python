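"""Feature graphs, the graph-OSCAR penalty, and the reweighting matrices.

The structured penalty on a loading vector ``u`` over an undirected feature
graph with edge set ``E`` is

    sum_{(i,j) in E} max(|u_i|, |u_j|)
        = 1/2 sum_{(i,j) in E} |u_i - u_j|  +  1/2 sum_{(i,j) in E} |u_i + u_j|,

which on a complete graph is the classic octagonal (OSCAR) penalty over all
feature pairs.  The half-quadratic solver replaces each absolute value by the
smooth surrogate ``sqrt(x^2 + zeta)`` and works with per-edge weights

    w_ij    = 1 / (2 sqrt((u_i - u_j)^2 + zeta))      (difference weights)
    what_ij = 1 / (2 sqrt((u_i + u_j)^2 + zeta))      (sum weights)

assembled into a Laplacian ``L = D - W`` and its signless analogue
``Lhat = Dhat + What``, together with the elementwise diagonal
``Lambda_kk = 1 / (2 sqrt(u_k^2 + zeta))`` for the lasso term.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "FeatureGraph",
    "GoscarWeights",
    "goscar_norm",
    "init_weights",
    "reweight",
]


@dataclass(frozen=True)
class FeatureGraph:
    """An undirected, simple graph over the features of one data side.

    Edges are stored as an ``(m, 2)`` integer array with ``i < j`` per row,
    sorted lexicographically; indices are 0-based.
    """

    n_features: int
    edges: np.ndarray

    def __post_init__(self) -> None:
        if self.n_features <= 0:
            raise ValidationError("n_features must be a positive integer")
        edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        if edges.size:
            if edges.min() < 0 or edges.max() >= self.n_features:
                raise ValidationError(
                    f"edge indices must lie in [0, {self.n_features})"
                )
            if np.any(edges[:, 0] == edges[:, 1]):
                raise ValidationError("self-loops are not allowed")
            lo = edges.min(axis=1)
            hi = edges.max(axis=1)
            edges = np.unique(np.column_stack([lo, hi]), axis=0)
        object.__setattr__(self, "edges", edges)

    @classmethod
    def from_pairs(
        cls, n_features: int, pairs: Iterable[Sequence[int]]
    ) -> "FeatureGraph":
        pairs = list(pairs)
        arr = (
            np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
            if pairs
            else np.empty((0, 2), dtype=np.int64)
        )
        return cls(n_features, arr)

    @classmethod
    def complete(cls, n_features: int) -> "FeatureGraph":
        """The complete graph: penalty becomes plain OSCAR over all pairs."""
        i, j = np.triu_indices(n_features, k=1)
        return cls(n_features, np.column_stack([i, j]))

    @classmethod
    def empty(cls, n_features: int) -> "FeatureGraph":
        return cls(n_features, np.empty((0, 2), dtype=np.int64))

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])

    @property
    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_features, dtype=np.int64)
        if self.n_edges:
            np.add.at(deg, self.edges[:, 0], 1)
            np.add.at(deg, self.edges[:, 1], 1)
        return deg


def _check_length(u: np.ndarray, graph: FeatureGraph) -> np.ndarray:
    u = np.asarray(u, dtype=float).ravel()
    if u.shape[0] != graph.n_features:
        raise ValidationError(
            f"loading length {u.shape[0]} != graph.n_features {graph.n_features}"
        )
    return u


def goscar_norm(u: np.ndarray, graph: FeatureGraph, method: str = "max") -> float:
    """Graph-OSCAR penalty of ``u`` over ``graph``.

    ``method="max"`` evaluates ``sum max(|u_i|, |u_j|)``; ``method="split"``
    evaluates the algebraically identical half-sum decomposition
    ``1/2 sum |u_i - u_j| + 1/2 sum |u_i + u_j|``.
    """
    u = _check_length(u, graph)
    if graph.n_edges == 0:
        return 0.0
    ui = u[graph.edges[:, 0]]
    uj = u[graph.edges[:, 1]]
    if method == "max":
        return float(np.maximum(np.abs(ui), np.abs(uj)).sum())
    if method == "split":
        return float(0.5 * (np.abs(ui - uj).sum() + np.abs(ui + uj).sum()))
    raise ValidationError(f"unknown method {method!r}")


@dataclass
class GoscarWeights:
    """Reweighting state for one side: edge weights plus derived matrices.

    ``w`` and ``w_hat`` hold per-edge difference/sum weights aligned with
    ``graph.edges``; ``lambda_diag`` is the positive diagonal for the lasso
    term.  Dense ``W``, ``W_hat``, ``D``, ``D_hat``, ``L``, ``L_hat`` are
    materialized lazily; ``penalty_matvec`` gives an edge-wise
    ``(L + L_hat) @ x`` without forming dense matrices.
    """

    graph: FeatureGraph
    w: np.ndarray
    w_hat: np.ndarray
    lambda_diag: np.ndarray
    _dense: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        m = self.graph.n_edges
        p = self.graph.n_features
        self.w = np.asarray(self.w, dtype=float).ravel()
        self.w_hat = np.asarray(self.w_hat, dtype=float).ravel()
        self.lambda_diag = np.asarray(self.lambda_diag, dtype=float).ravel()
        if self.w.shape[0] != m or self.w_hat.shape[0] != m:
            raise ValidationError("edge weight arrays must match the edge count")
        if self.lambda_diag.shape[0] != p:
            raise ValidationError("lambda_diag must have one entry per feature")
        if np.any(self.w < 0) or np.any(self.w_hat < 0):
            raise ValidationError("edge weights must be nonnegative")
        if np.any(self.lambda_diag <= 0):
            raise ValidationError("lambda_diag entries must be strictly positive")

    def _dense_pair(self, vals: np.ndarray) -> np.ndarray:
        p = self.graph.n_features
        M = np.zeros((p, p))
        if self.graph.n_edges:
            i = self.graph.edges[:, 0]
            j = self.graph.edges[:, 1]
            M[i, j] = vals
            M[j, i] = vals
        return M

    @property
    def W(self) -> np.ndarray:
        if "W" not in self._dense:
            self._dense["W"] = self._dense_pair(self.w)
        return self._dense["W"]

    @property
    def W_hat(self) -> np.ndarray:
        if "W_hat" not in self._dense:
            self._dense["W_hat"] = self._dense_pair(self.w_hat)
        return self._dense["W_hat"]

    @property
    def row_sums(self) -> np.ndarray:
        return self.W.sum(axis=1)

    @property
    def row_sums_hat(self) -> np.ndarray:
        return self.W_hat.sum(axis=1)

    @property
    def D(self) -> np.ndarray:
        return np.diag(self.row_sums)

    @property
    def D_hat(self) -> np.ndarray:
        return np.diag(self.row_sums_hat)

    @property
    def L(self) -> np.ndarray:
        """Graph Laplacian D - W; quadratic form sum w_ij (u_i - u_j)^2."""
        return self.D - self.W

    @property
    def L_hat(self) -> np.ndarray:
        """Signless analogue D_hat + W_hat; quadratic form sum what_ij (u_i + u_j)^2."""
        return self.D_hat + self.W_hat

    def penalty_matvec(self, x: np.ndarray) -> np.ndarray:
        """Edge-wise evaluation of ``(L + L_hat) @ x``."""
        x = np.asarray(x, dtype=float).ravel()
        out = np.zeros_like(x)
        if self.graph.n_edges:
            i = self.graph.edges[:, 0]
            j = self.graph.edges[:, 1]
            diff = x[i] - x[j]
            tot = x[i] + x[j]
            np.add.at(out, i, self.w * diff + self.w_hat * tot)
            np.add.at(out, j, -self.w * diff + self.w_hat * tot)
        return out


def init_weights(
    graph: FeatureGraph,
    u0: np.ndarray | None = None,
    zeta: float = 1e-10,
) -> GoscarWeights:
    """Initial reweighting state: every edge weight (difference and sum) is 1/2.

    ``lambda_diag`` is seeded from ``u0`` when given (same smoothing rule as
    :func:`reweight`), else set to ones.
    """
    m = graph.n_edges
    half = np.full(m, 0.5)
    if u0 is None:
        lam = np.ones(graph.n_features)
    else:
        if zeta <= 0:
            raise ValidationError("zeta must be > 0")
        u0 = _check_length(u0, graph)
        lam = 1.0 / (2.0 * np.sqrt(u0 * u0 + zeta))
    return GoscarWeights(graph, half, half.copy(), lam)


def reweight(u: np.ndarray, graph: FeatureGraph, zeta: float = 1e-10) -> GoscarWeights:
    """Rebuild all weights from the current loading with ``zeta`` smoothing.

    Smoothing is applied uniformly (not only at exact zeros), matching the
    smooth surrogate the solver actually minimizes, so every entry is finite.
    """
    if zeta <= 0:
        raise ValidationError("zeta must be > 0")
    u = _check_length(u, graph)
    if graph.n_edges:
        ui = u[graph.edges[:, 0]]
        uj = u[graph.edges[:, 1]]
        w = 1.0 / (2.0 * np.sqrt((ui - uj) ** 2 + zeta))
        w_hat = 1.0 / (2.0 * np.sqrt((ui + uj) ** 2 + zeta))
    else:
        w = np.empty(0)
        w_hat = np.empty(0)
    lam = 1.0 / (2.0 * np.sqrt(u * u + zeta))
    return GoscarWeights(graph, w, w_hat, lam)
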