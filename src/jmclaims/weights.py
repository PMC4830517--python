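"""Fading-weight kernels and the recency-weighted cumulative effect.

The hazard of death is allowed to depend on a policyholder's *history* of
expected claim activity through

    F(t) = \\int_0^t wbar(t - s) m(s) ds,

where ``m`` is the expected log1p-claims trajectory and ``wbar`` is a
nonnegative weighting kernel that fades with elapsed time ``u = t - s``,
so recent demand for care weighs more than old demand.  Three kernel
families are provided:

* ``exponential`` with decay rate ``lam``:  wbar(u) = lam * exp(-lam * u)
* ``uniform`` over a window L:             wbar(u) = 1/L       for u < L
* ``linear`` decay over a window L:        wbar(u) = 2(L-u)/L^2 for u < L

Each integrates to one over [0, inf); the ``normalize="interval"`` variant
instead rescales the kernel so that it integrates to one over the
realised history [0, t].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from ._quad import legendre_01

FAMILIES = ("exponential", "uniform", "linear")
NORMALIZE_MODES = ("inf", "interval")


@dataclass(frozen=True)
class WeightFunction:
    """A fading kernel.

    Parameters
    ----------
    family:
        One of ``"exponential"``, ``"uniform"``, ``"linear"``.
    rate:
        Decay rate (exponential) or window length in years (uniform,
        linear).  Must be positive.
    normalize:
        ``"inf"`` (default) keeps the kernel a density on [0, inf);
        ``"interval"`` rescales it to integrate to one over [0, t] for the
        horizon t at which F is evaluated.
    """

    family: str = "exponential"
    rate: float = 2.9957
    normalize: str = "inf"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown weight family {self.family!r}")
        if self.normalize not in NORMALIZE_MODES:
            raise ValueError(f"unknown normalize mode {self.normalize!r}")
        if not self.rate > 0:
            raise ValueError("weight rate/window must be positive")

    # -- raw (over-[0,inf) normalized) kernel -------------------------------
    def _raw(self, u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        if self.family == "exponential":
            return self.rate * np.exp(-self.rate * u)
        L = self.rate
        if self.family == "uniform":
            return np.where(u <= L, 1.0 / L, 0.0)
        # linear decay
        return np.where(u <= L, 2.0 * (L - u) / L**2, 0.0)

    def mass(self, t) -> np.ndarray:
        """Integral of the raw kernel over [0, t] (closed form)."""
        t = np.asarray(t, dtype=float)
        if self.family == "exponential":
            return 1.0 - np.exp(-self.rate * t)
        L = self.rate
        x = np.minimum(t, L)
        if self.family == "uniform":
            return x / L
        return (2.0 * L * x - x**2) / L**2

    def value(self, u, horizon: float | None = None) -> np.ndarray:
        """Kernel density at elapsed time ``u`` >= 0.

        For ``normalize="interval"`` a horizon ``t`` is required, and the
        raw kernel is divided by its mass over [0, horizon].
        """
        u = np.asarray(u, dtype=float)
        if np.any(u < 0):
            raise ValueError("elapsed time u must be nonnegative")
        v = self._raw(u)
        if self.normalize == "interval":
            if horizon is None:
                raise ValueError("interval normalization requires a horizon")
            m = self.mass(horizon)
            v = v / np.where(m > 0, m, np.nan)
        return v


def exponential_rate_from_last_year_share(p: float = 0.95) -> float:
    """Decay rate such that the final year carries a share ``p`` of weight.

    For the exponential kernel, the weight mass in the last year before
    the evaluation point is 1 - exp(-lam), so lam = -log(1 - p).
    """
    if not 0 < p < 1:
        raise ValueError("p must be in (0, 1)")
    return float(-np.log1p(-p))


def default_weight() -> WeightFunction:
    """Exponential kernel with 95% of its mass in the most recent year."""
    return WeightFunction("exponential", exponential_rate_from_last_year_share(0.95), "inf")


def _support_lower(w: WeightFunction, t) -> np.ndarray:
    """Lower integration limit: the kernel support clipped to [0, t].

    Windowed kernels vanish (and kink) at elapsed time L; the
    exponential kernel is truncated where it has decayed below ~1e-16
    relative.  Restricting the rule to the support keeps Gauss-Legendre
    spectrally accurate.
    """
    t = np.asarray(t, dtype=float)
    if w.family == "exponential":
        return np.maximum(0.0, t - 36.0 / w.rate)
    return np.maximum(0.0, t - w.rate)


def _n_panels(w: WeightFunction, t_max: float) -> int:
    """Composite panels so the exponential kernel varies by <= e^5 per panel."""
    if w.family != "exponential":
        return 1
    lo = float(_support_lower(w, t_max))
    return max(1, min(8, int(np.ceil(w.rate * (t_max - lo) / 5.0))))


def cumulative_weighted_effect(
    traj: Callable[[np.ndarray], np.ndarray],
    w: WeightFunction,
    t: float,
    n_points: int = 15,
) -> float:
    """Gauss-Legendre approximation of F(t) = int_0^t wbar(t-s) m(s) ds.

    The rule is applied on the kernel support (composite panels for the
    exponential family, whose integrand spans many e-foldings).
    ``traj`` must be vectorised over its time argument.  Deterministic
    given the rule size ``n_points``.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    if t == 0:
        return 0.0
    x, wt = legendre_01(n_points)
    lo = float(_support_lower(w, t))
    edges = np.linspace(lo, t, _n_panels(w, t) + 1)
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        s = a + (b - a) * x
        vals = w.value(t - s, horizon=t) * np.asarray(traj(s), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("trajectory not evaluable on [0, t]")
        total += (b - a) * np.sum(wt * vals)
    return float(total)


def kernel_moments(
    w: WeightFunction, t: np.ndarray, n_points: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """(W0(t), W1(t)) with W0 = int_0^t wbar(t-s) ds, W1 = int_0^t wbar(t-s) s ds.

    For a trajectory linear in time, m(s) = a + b s, the weighted
    cumulative effect factorises as F(t) = a W0(t) + b W1(t); these two
    kernel moments are all the survival machinery ever needs.  Computed
    with the same inner Gauss-Legendre rule as
    :func:`cumulative_weighted_effect`; vectorised over ``t``.
    """
    t = np.asarray(t, dtype=float)
    x, wt = legendre_01(n_points)
    lo = _support_lower(w, t)
    horizon = t[..., None] if w.normalize == "interval" else None
    W0 = np.zeros_like(t)
    W1 = np.zeros_like(t)
    n_pan = _n_panels(w, float(t.max()) if t.size else 0.0)
    edges = np.linspace(0.0, 1.0, n_pan + 1)
    span = t - lo
    for e0, e1 in zip(edges[:-1], edges[1:]):
        a = lo + e0 * span
        width = (e1 - e0) * span
        s = a[..., None] + width[..., None] * x  # (..., n_points)
        vals = w.value(np.maximum(t[..., None] - s, 0.0), horizon=horizon)
        W0 = W0 + width * np.sum(wt * vals, axis=-1)
        W1 = W1 + width * np.sum(wt * vals * s, axis=-1)
    if w.normalize == "interval":
        # F(0) is defined as 0; mass(0) = 0 produced NaNs there
        W0 = np.where(t > 0, W0, 0.0)
        W1 = np.where(t > 0, W1, 0.0)
    return W0, W1


ASSOCIATION_MODES = ("weighted-cumulative", "current-value", "value-plus-slope")


def association_feature(
    beta: np.ndarray,
    b_pair: np.ndarray,
    t: float,
    mode: str = "weighted-cumulative",
    weight: WeightFunction | None = None,
    n_points: int = 15,
):
    """Feature(s) of the subject trajectory entering the log-hazard.

    ``weighted-cumulative`` returns F(m(.)) at t; ``current-value``
    returns m(t); ``value-plus-slope`` returns the pair (m(t), m'(t)),
    each multiplied downstream by its own association coefficient.
    """
    b0, b1 = float(b_pair[0]), float(b_pair[1])
    a = float(beta[0]) + b0
    slope = float(beta[1]) + b1
    if mode == "current-value":
        return a + slope * t
    if mode == "value-plus-slope":
        return (a + slope * t, slope)
    if mode == "weighted-cumulative":
        if weight is None:
            weight = default_weight()
        return cumulative_weighted_effect(lambda s: a + slope * s, weight, t, n_points)
    raise ValueError(f"unknown association mode {mode!r}")
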