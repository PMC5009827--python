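"""Synthetic paired-data generator with known ground-truth loadings.

The generator follows a four-step latent-factor protocol:

1. choose group-structured true loadings u (length p) and v (length q);
2. draw latent scores z ~ N(0, I_n);
3. draw row i of X from N(z_i * u, Sigma_x) with
   (Sigma_x)_jk = exp(-|u_j - u_k|), and row i of Y likewise from v;
4. flip the signs of half of the first nonzero group of u *and* of the
   corresponding columns of X (same on the Y side), so the products are
   unchanged: X' u' = X u exactly.

The stored truths are the post-swap loadings — what a correct method should
recover.  Sign swaps make methods that guess the sign of pairwise sample
correlations fail, while sum+difference penalization is unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import NumericalError, ValidationError
from .solver import PairedData

__all__ = [
    "SyntheticScenario",
    "SyntheticDraw",
    "make_scenario",
    "generate",
    "exp_abs_cov",
    "DEFAULT_SCENARIOS",
    "TUNED_SCENARIO_PENALTIES",
    "tuned_config",
]

Group = tuple[int, int, float]  # (start, stop, value), stop exclusive


def _build_loading(p: int, groups: Sequence[Group]) -> np.ndarray:
    u = np.zeros(p)
    seen = np.zeros(p, dtype=bool)
    if not groups:
        raise ValidationError("at least one nonzero group is required per side")
    for start, stop, value in groups:
        if not (0 <= start < stop <= p):
            raise ValidationError(f"group ({start}, {stop}) out of range for p={p}")
        if value == 0:
            raise ValidationError("group values must be nonzero")
        if seen[start:stop].any():
            raise ValidationError(f"group ({start}, {stop}) overlaps another group")
        seen[start:stop] = True
        u[start:stop] = value
    return u


def _swap_indices(groups: Sequence[Group], swap_fraction: float) -> np.ndarray:
    start, stop, _ = groups[0]
    size = stop - start
    k = int(np.floor(size * swap_fraction))
    return np.arange(start, start + k)


@dataclass(frozen=True)
class SyntheticScenario:
    """Fully specified ground truth for one paired dataset."""

    n: int
    p: int
    q: int
    u_groups: tuple[Group, ...]
    v_groups: tuple[Group, ...]
    swap_fraction: float = 0.5
    name: str | None = None

    def __post_init__(self) -> None:
        if self.n < 2 or self.p < 1 or self.q < 1:
            raise ValidationError("dimensions must satisfy n >= 2, p >= 1, q >= 1")
        if not (0.0 <= self.swap_fraction <= 1.0):
            raise ValidationError("swap_fraction must lie in [0, 1]")
        # validates ranges / overlap / nonzero values
        _build_loading(self.p, self.u_groups)
        _build_loading(self.q, self.v_groups)

    @property
    def u_pre_swap(self) -> np.ndarray:
        return _build_loading(self.p, self.u_groups)

    @property
    def v_pre_swap(self) -> np.ndarray:
        return _build_loading(self.q, self.v_groups)

    @property
    def u_swap_indices(self) -> np.ndarray:
        return _swap_indices(self.u_groups, self.swap_fraction)

    @property
    def v_swap_indices(self) -> np.ndarray:
        return _swap_indices(self.v_groups, self.swap_fraction)

    @property
    def u_true(self) -> np.ndarray:
        """Post-swap truth (what a correct method should recover)."""
        u = self.u_pre_swap
        u[self.u_swap_indices] *= -1.0
        return u

    @property
    def v_true(self) -> np.ndarray:
        v = self.v_pre_swap
        v[self.v_swap_indices] *= -1.0
        return v


@dataclass
class SyntheticDraw:
    """One sampled dataset together with its latent scores and scenario."""

    data: PairedData
    z: np.ndarray
    scenario: SyntheticScenario


# Four shipped layouts at n=80, p=100, q=120 with distinct group structures
# and signal scales.  Scenario "1" is the high-SNR default used by the
# recovery checks; the others vary block count, placement, and sign.
DEFAULT_SCENARIOS: dict[str, dict] = {
    "1": dict(
        u_groups=((0, 15, 2.0), (40, 55, 2.0)),
        v_groups=((0, 15, 2.0), (60, 78, 2.0)),
    ),
    "2": dict(
        u_groups=((0, 8, 1.2), (30, 38, 0.9), (60, 70, 1.5)),
        v_groups=((10, 20, 1.0), (50, 62, 1.3)),
    ),
    "3": dict(
        u_groups=((10, 20, 0.8), (50, 60, -1.1)),
        v_groups=((0, 15, 0.7), (40, 50, -1.2), (90, 100, 0.9)),
    ),
    "4": dict(
        u_groups=((0, 6, 0.6), (20, 35, 1.8), (70, 78, -0.9)),
        v_groups=((30, 45, 1.6), (80, 92, -0.8)),
    ),
}


# Penalty settings selected offline on tuning seeds (100-102) from the
# default grid {1e-3..1e3}: among candidates whose held-out correlations were
# statistically indistinguishable from the best, the most reliably converging
# one was kept.  "recovery" is the scenario-1 setting that best recovers the
# true loading direction (used by the sign-swap recovery checks, where
# convergence within the iteration cap is not required).
TUNED_SCENARIO_PENALTIES: dict[str, dict[str, float]] = {
    "1": dict(lam=1e-3, beta=1e-2),
    "2": dict(lam=1e-3, beta=1e-2),
    "3": dict(lam=1e-3, beta=1e-2),
    "4": dict(lam=1e-3, beta=1e-2),
    "recovery": dict(lam=1e-2, beta=1e-1),
}


def tuned_config(key: str, **overrides):
    """SccaConfig with the offline-tuned penalties for a default scenario."""
    from .solver import SccaConfig

    pen = TUNED_SCENARIO_PENALTIES[str(key)]
    kwargs = dict(
        lambda1=pen["lam"], lambda2=pen["lam"],
        beta1=pen["beta"], beta2=pen["beta"],
    )
    kwargs.update(overrides)
    return SccaConfig(**kwargs)


def make_scenario(
    name: str | int | None = None,
    *,
    n: int = 80,
    p: int = 100,
    q: int = 120,
    u_groups: Sequence[Group] | None = None,
    v_groups: Sequence[Group] | None = None,
    swap_fraction: float = 0.5,
) -> SyntheticScenario:
    """Build a scenario from a shipped preset name ("1".."4") or raw parameters."""
    if name is not None:
        key = str(name)
        if key not in DEFAULT_SCENARIOS:
            raise ValidationError(
                f"unknown scenario {key!r}; available: {sorted(DEFAULT_SCENARIOS)}"
            )
        preset = DEFAULT_SCENARIOS[key]
        u_groups = preset["u_groups"]
        v_groups = preset["v_groups"]
        return SyntheticScenario(
            n=n, p=p, q=q,
            u_groups=tuple(u_groups), v_groups=tuple(v_groups),
            swap_fraction=swap_fraction, name=key,
        )
    if u_groups is None or v_groups is None:
        raise ValidationError("provide a preset name or both u_groups and v_groups")
    return SyntheticScenario(
        n=n, p=p, q=q,
        u_groups=tuple(tuple(g) for g in u_groups),
        v_groups=tuple(tuple(g) for g in v_groups),
        swap_fraction=swap_fraction,
    )


def exp_abs_cov(w: np.ndarray) -> np.ndarray:
    """Covariance kernel exp(-|w_j - w_k|): unit diagonal, symmetric, PSD."""
    w = np.asarray(w, dtype=float).ravel()
    return np.exp(-np.abs(w[:, None] - w[None, :]))


def _psd_factor(sigma: np.ndarray) -> np.ndarray:
    """Symmetric factor F with F F' = sigma (eigendecomposition, clipped)."""
    vals, vecs = np.linalg.eigh(sigma)
    if vals.min() < -1e-8:
        raise NumericalError(
            f"covariance is not PSD (min eigenvalue {vals.min():.3e})"
        )
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def generate(scenario: SyntheticScenario, seed: int = 0) -> SyntheticDraw:
    """Draw one dataset; deterministic for a fixed seed."""
    rng = np.random.default_rng(seed)
    n, p, q = scenario.n, scenario.p, scenario.q
    u_pre = scenario.u_pre_swap
    v_pre = scenario.v_pre_swap

    z = rng.standard_normal(n)
    fx = _psd_factor(exp_abs_cov(u_pre))
    fy = _psd_factor(exp_abs_cov(v_pre))
    X = np.outer(z, u_pre) + rng.standard_normal((n, p)) @ fx.T
    Y = np.outer(z, v_pre) + rng.standard_normal((n, q)) @ fy.T

    # sign swap: flip loading entries and matching data columns together,
    # leaving X @ u (and Y @ v) bit-identical
    X[:, scenario.u_swap_indices] *= -1.0
    Y[:, scenario.v_swap_indices] *= -1.0

    data = PairedData(
        X=X,
        Y=Y,
        sample_ids=[f"s{i + 1}" for i in range(n)],
        x_features=[f"x{j + 1}" for j in range(p)],
        y_features=[f"y{j + 1}" for j in range(q)],
    )
    return SyntheticDraw(data=data, z=z, scenario=scenario)
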