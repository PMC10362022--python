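"""Mutation-rate estimation from fluctuation assays.

The median-based estimator solves r = 1.24*m + m*ln(m) for the expected
mutations per culture m, where r is the median mutant colony count, then
divides by the median viable titer: mu = m / N. The median of an even
number of cultures is the mean of the central order statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "LC_CONSTANT",
    "FluctuationData",
    "FluctuationEstimate",
    "EstimatorUndefinedError",
    "lea_coulson_m",
    "mutation_rate",
    "estimate_from_cultures",
]

LC_CONSTANT = 1.24


class EstimatorUndefinedError(ValueError):
    """Median mutant count is zero (or negative): the median estimator has no
    answer — use more cultures or larger cultures."""


@dataclass
class FluctuationData:
    """Mutant counts and viable titers for N parallel cultures."""

    r_values: np.ndarray
    titers: np.ndarray
    true_mu: float | None = None

    def __post_init__(self) -> None:
        self.r_values = np.asarray(self.r_values)
        self.titers = np.asarray(self.titers)
        if self.r_values.ndim != 1 or self.r_values.size < 2:
            raise ValueError("need at least two cultures")
        if self.r_values.shape != self.titers.shape:
            raise ValueError("r_values and titers differ in length")
        if (self.r_values < 0).any():
            raise ValueError("mutant counts must be non-negative")
        if (self.titers <= 0).any():
            raise ValueError("titers must be positive")


@dataclass
class FluctuationEstimate:
    m: float
    mu: float
    r_median: float
    n_median: float
    lc_constant: float = LC_CONSTANT


def _f(m: float, r: float) -> float:
    return r - LC_CONSTANT * m - m * np.log(m)


def lea_coulson_m(r_median: float, tol: float = 1e-10) -> float:
    """Solve r - 1.24*m - m*ln(m) = 0 for m > 0.

    f is strictly decreasing on the admissible branch, so the root is
    bracketed (expanding geometrically if needed) and refined by Brent's
    method to relative tolerance ``tol``.
    """
    r = float(r_median)
    if r <= 0:
        raise EstimatorUndefinedError(
            "median mutant count must be positive; the median-based estimator "
            "has no zero-median form — use more cultures"
        )
    lo = max(r / 10.0, 1e-6)
    hi = max(10.0 * r, 10.0)
    while _f(lo, r) <= 0 and lo > 1e-300:
        lo /= 10.0
    while _f(hi, r) >= 0 and hi < 1e300:
        hi *= 10.0
    if not (_f(lo, r) > 0 > _f(hi, r)):
        raise RuntimeError(f"failed to bracket the root for r={r}")
    m = optimize.brentq(_f, lo, hi, args=(r,), rtol=tol, xtol=1e-300, maxiter=500)
    return float(m)


def mutation_rate(m: float, n_median: float) -> float:
    """mu = m / N (mutations per cell per division)."""
    if m <= 0 or n_median <= 0:
        raise ValueError("m and the median titer must be positive")
    return m / n_median


def _median(values: np.ndarray) -> float:
    # even count -> mean of the central order statistics
    return float(np.median(values))


def estimate_from_cultures(data: FluctuationData, tol: float = 1e-10) -> FluctuationEstimate:
    """Compose medians, the Lea-Coulson solve and mu = m/N, with provenance."""
    r_med = _median(data.r_values)
    n_med = _median(data.titers)
    m = lea_coulson_m(r_med, tol=tol)
    return FluctuationEstimate(
        m=m,
        mu=mutation_rate(m, n_med),
        r_median=r_med,
        n_median=n_med,
    )
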