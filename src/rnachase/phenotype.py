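"""Growth, protein-stability, ROS, dot-blot and molecules-per-cell
quantifications, plus the shared ANOVA/Tukey and t-test helpers.

Generation time comes from a least-squares fit of log2(OD) vs time on the
exponential window; protein half-life from a natural-log fit of the
loading-control-normalized signal; group comparisons dispatch to a
two-tailed t-test for two groups and one-way ANOVA with Tukey HSD and a
compact letter display for three or more.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "MeasurementSeries",
    "generation_time",
    "protein_half_life",
    "normalize_ros",
    "relative_quant",
    "molecules_per_cell",
    "anova_tukey",
    "GroupComparison",
]


@dataclass
class MeasurementSeries:
    """Time-stamped replicate measurements (OD600, fluorescence or AU)."""

    time: np.ndarray
    value: np.ndarray
    replicate: np.ndarray | None = None
    group: str = ""
    unit: str = "min"

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if self.time.shape != self.value.shape:
            raise ValueError("time and value differ in length")
        if self.replicate is None:
            self.replicate = np.ones(self.time.shape, dtype=int)
        else:
            self.replicate = np.asarray(self.replicate, dtype=int)
        if (self.value < 0).any():
            raise ValueError("measurement values must be >= 0")
        for rep in np.unique(self.replicate):
            t = self.time[self.replicate == rep]
            if (np.diff(t) <= 0).any():
                raise ValueError(f"time not strictly increasing in replicate {rep}")

    def replicates(self) -> list[tuple[int, np.ndarray, np.ndarray]]:
        return [
            (int(r), self.time[self.replicate == r], self.value[self.replicate == r])
            for r in np.unique(self.replicate)
        ]


def _auto_window(t: np.ndarray, log2_od: np.ndarray,
                 min_points: int = 4, r2_min: float = 0.99) -> slice:
    """Longest contiguous run with log-linear R^2 >= r2_min, >= min_points."""
    n = t.size
    best: tuple[int, int] | None = None
    for i in range(n):
        for j in range(i + min_points, n + 1):
            res = stats.linregress(t[i:j], log2_od[i:j])
            if res.rvalue**2 >= r2_min:
                if best is None or (j - i) > (best[1] - best[0]):
                    best = (i, j)
    if best is None:
        raise ValueError("no log-linear exponential window found")
    return slice(*best)


def generation_time(
    series: MeasurementSeries,
    window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Doubling time in minutes: g = 1/slope of log2(OD) vs time.

    ``window`` restricts the fit to an OD range; by default the longest
    log-linear run is auto-selected per replicate. Returns (mean g, SD over
    replicates; SD is NaN for a single replicate).
    """
    gs = []
    for _, t, od in series.replicates():
        if window is not None:
            keep = (od >= window[0]) & (od <= window[1])
            t, od = t[keep], od[keep]
        if (od <= 0).any():
            raise ValueError("non-positive OD in the fitting window")
        if t.size < 3:
            raise ValueError("need at least 3 points in the exponential window")
        log2_od = np.log2(od)
        if window is None:
            sl = _auto_window(t, log2_od)
            t, log2_od = t[sl], log2_od[sl]
        res = stats.linregress(t, log2_od)
        if res.slope <= 0:
            raise ValueError("non-positive growth slope: culture not growing")
        gs.append(1.0 / res.slope)
    gs = np.asarray(gs)
    return float(gs.mean()), float(gs.std(ddof=1)) if gs.size > 1 else float("nan")


def protein_half_life(
    series: MeasurementSeries,
    loading_control: MeasurementSeries,
) -> float:
    """Protein half-life in the series' time unit, or inf when stable.

    Signal/control ratios are normalized to the first time point, fitted as
    ln(ratio) vs t by unweighted least squares; t_half = ln2/|slope|.
    A non-negative slope is reported as stable (inf).
    """
    if not np.array_equal(series.time, loading_control.time):
        raise ValueError("signal and loading control must share time points")
    if (loading_control.value <= 0).any():
        raise ValueError("loading control values must be positive")
    ratio = series.value / loading_control.value
    if ratio[0] <= 0:
        raise ValueError("zero signal at t=0: cannot normalize")
    frac = ratio / ratio[0]
    if (frac <= 0).any():
        raise ValueError("signal vanished: log fit undefined")
    res = stats.linregress(series.time, np.log(frac))
    if res.slope >= 0:
        return float("inf")
    return float(np.log(2.0) / abs(res.slope))


def normalize_ros(fluorescence: float | np.ndarray, od600: float | np.ndarray):
    """Fluorescence normalized by OD600."""
    od = np.asarray(od600, dtype=float)
    if (od <= 0).any():
        raise ValueError("OD600 must be positive")
    out = np.asarray(fluorescence, dtype=float) / od
    return float(out) if out.ndim == 0 else out


def relative_quant(signals: Mapping[str, float], reference: str) -> dict[str, float]:
    """Signals divided by the reference sample's signal; reference maps to 1."""
    if reference not in signals:
        raise KeyError(f"reference sample {reference!r} not among the signals")
    ref = float(signals[reference])
    if ref <= 0:
        raise ValueError("reference signal must be positive")
    return {k: float(v) / ref for k, v in signals.items()}


def molecules_per_cell(
    ec_molecules: float,
    tagged_fold_ec_over_h: float,
    untagged_fold_h_over_tagged: float,
) -> tuple[float, float]:
    """Molecules-per-cell estimate from tagged/untagged fold ratios.

    fold_deficit = tagged_fold / untagged_fold; estimate = molecules / deficit.
    Exact arithmetic on its inputs.
    """
    if min(ec_molecules, tagged_fold_ec_over_h, untagged_fold_h_over_tagged) <= 0:
        raise ValueError("all inputs must be positive")
    fold_deficit = tagged_fold_ec_over_h / untagged_fold_h_over_tagged
    return fold_deficit, ec_molecules / fold_deficit


@dataclass
class GroupComparison:
    """Result of anova_tukey: omnibus stat/p, pairwise p-values, letters."""

    statistic: float
    pvalue: float
    test: str  # "anova" or "t-test"
    pairwise: pd.DataFrame = field(default_factory=pd.DataFrame)
    letters: dict[str, str] = field(default_factory=dict)


def _letter_display(names: list[str], means: np.ndarray,
                    sig: np.ndarray) -> dict[str, str]:
    """Greedy compact letter display from a pairwise significance matrix."""
    order = np.argsort(-means, kind="stable")
    groups: list[set[int]] = []  # sets of group indices sharing a letter
    for i in order:
        placed = False
        for g in groups:
            if all(not sig[i, j] for j in g):
                g.add(i)
                placed = True
        if not placed:
            groups.append({i})
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {n: "" for n in names}
    for li, g in enumerate(groups):
        for i in sorted(g):
            letters[names[i]] += alphabet[li]
    return letters


def anova_tukey(groups: Mapping[str, Sequence[float]], alpha: float = 0.05) -> GroupComparison:
    """Two groups: two-tailed t-test. Three or more: one-way ANOVA + Tukey HSD
    with a compact letter display (groups sharing a letter are not
    significantly different at ``alpha``)."""
    names = list(groups)
    values = [np.asarray(groups[n], dtype=float) for n in names]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    if any(v.size < 2 for v in values):
        raise ValueError("every group needs at least two values")
    if len(names) == 2:
        t, p = stats.ttest_ind(values[0], values[1], equal_var=True)
        return GroupComparison(statistic=float(t), pvalue=float(p), test="t-test")

    f, p = stats.f_oneway(*values)
    if not np.isfinite(f):  # all groups identical and constant
        f, p = 0.0, 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        hsd = stats.tukey_hsd(*values)  # zero within-group variance -> NaN q
    k = len(names)
    rows = []
    sig = np.zeros((k, k), dtype=bool)
    for i in range(k):
        for j in range(i + 1, k):
            pij = float(hsd.pvalue[i, j])
            sig[i, j] = sig[j, i] = pij < alpha
            rows.append({"group_a": names[i], "group_b": names[j], "pvalue": pij})
    means = np.array([v.mean() for v in values])
    letters = _letter_display(names, means, sig)
    return GroupComparison(
        statistic=float(f), pvalue=float(p), test="anova",
        pairwise=pd.DataFrame(rows), letters=letters,
    )
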