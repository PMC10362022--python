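"""Rifampicin-chase stability pipeline.

Percent of T0 CPM remaining at T4 per gene and strain, a four-category
classification (1 most stable .. 4 least stable, half-open intervals closed
on the lower bound), per-strain category distributions, pairwise
lower/equal/higher stability calls, and a Pearson chi-square comparison of
category distributions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnalysisConfig, CountMatrix, SampleSheet
from .expression import cpm

__all__ = [
    "percent_remaining",
    "assign_category",
    "assign_categories",
    "stability_table",
    "category_distribution",
    "compare_strains",
    "chi_square_distributions",
    "implied_half_life",
]


def percent_remaining(
    cpm_t0: np.ndarray | pd.Series,
    cpm_t4: np.ndarray | pd.Series,
    cap: float | None = 100.0,
    floor: float = 1.0,
) -> pd.DataFrame:
    """Percent of T0 CPM maintained at T4, per gene.

    Replicate-averaged CPM vectors in, a frame out with columns
    ``pct_remaining`` (capped), ``pct_raw`` and ``assessable``. Genes whose
    T0 CPM is below ``floor`` are flagged not assessable (NaN percent) —
    never a division error.
    """
    t0 = np.asarray(cpm_t0, dtype=float)
    t4 = np.asarray(cpm_t4, dtype=float)
    if t0.shape != t4.shape:
        raise ValueError("T0 and T4 CPM vectors differ in length")
    assessable = t0 >= floor
    raw = np.full(t0.shape, np.nan)
    np.divide(t4, t0, out=raw, where=assessable)
    raw *= 100.0
    pct = raw if cap is None else np.minimum(raw, cap)
    index = cpm_t0.index if isinstance(cpm_t0, pd.Series) else None
    return pd.DataFrame(
        {"pct_remaining": pct, "pct_raw": raw, "assessable": assessable},
        index=index,
    )


def assign_category(pct: float, bounds: tuple[float, float, float] = (25.0, 50.0, 75.0)) -> int:
    """Category 1..4 from percent remaining: 1 = [b2, inf), 4 = [0, b0)."""
    if np.isnan(pct):
        raise ValueError("cannot categorize a not-assessable gene (NaN percent)")
    if pct < 0:
        raise ValueError("percent remaining must be >= 0")
    b0, b1, b2 = bounds
    if pct >= b2:
        return 1
    if pct >= b1:
        return 2
    if pct >= b0:
        return 3
    return 4


def assign_categories(pct: np.ndarray | pd.Series,
                      bounds: tuple[float, float, float] = (25.0, 50.0, 75.0)) -> np.ndarray:
    """Vectorized assign_category; NaN percent maps to 0 (not assessable)."""
    p = np.asarray(pct, dtype=float)
    b0, b1, b2 = bounds
    cat = np.zeros(p.shape, dtype=int)
    ok = ~np.isnan(p)
    cat[ok & (p < b0)] = 4
    cat[ok & (p >= b0) & (p < b1)] = 3
    cat[ok & (p >= b1) & (p < b2)] = 2
    cat[ok & (p >= b2)] = 1
    return cat


def implied_half_life(pct: float, decay_time: float = 4.0) -> float:
    """Auxiliary t1/2 back-calculation decay_time / -log2(pct/100) (extension)."""
    if not 0 < pct < 100:
        return np.inf if pct >= 100 else 0.0
    return decay_time / -np.log2(pct / 100.0)


def stability_table(
    matrix: CountMatrix,
    sheet: SampleSheet,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Full per-gene stability table across all strains in the sheet.

    For each strain, replicate CPMs are arithmetic-averaged per timepoint
    before the ratio. Output columns per strain: ``pct_remaining_<s>``,
    ``pct_raw_<s>``, ``category_<s>`` (0 = not assessable).
    """
    config = config or AnalysisConfig()
    values = cpm(matrix)
    out = pd.DataFrame({"gene_id": matrix.gene_ids})
    for strain in sheet.strains:
        s_t0 = sheet.samples_for(strain=strain, timepoint="T0")
        s_t4 = sheet.samples_for(strain=strain, timepoint="T4")
        if not s_t0 or not s_t4:
            raise ValueError(f"strain {strain!r} lacks a T0/T4 pair in the sheet")
        mean_t0 = values[s_t0].mean(axis=1)
        mean_t4 = values[s_t4].mean(axis=1)
        pr = percent_remaining(mean_t0, mean_t4, cap=config.pct_cap,
                               floor=config.assessability_floor)
        out[f"pct_remaining_{strain}"] = pr["pct_remaining"].to_numpy()
        out[f"pct_raw_{strain}"] = pr["pct_raw"].to_numpy()
        out[f"category_{strain}"] = assign_categories(
            pr["pct_remaining"].to_numpy(), config.category_bounds
        )
    return out


def category_distribution(table: pd.DataFrame, strain: str) -> np.ndarray:
    """Counts over categories 1..4 for one strain (assessable genes only)."""
    col = f"category_{strain}"
    if col not in table.columns:
        raise ValueError(f"no category column for strain {strain!r}")
    cats = table[col].to_numpy()
    cats = cats[cats > 0]
    if cats.size == 0:
        raise ValueError(f"strain {strain!r} has no assessable genes")
    return np.array([(cats == c).sum() for c in (1, 2, 3, 4)])


def compare_strains(
    table: pd.DataFrame,
    strain_x: str,
    strain_y: str,
    mode: str = "category",
    delta: float = 0.0,
) -> pd.DataFrame:
    """Per-gene L/=/H stability call for strain X relative to strain Y.

    ``category`` mode (default): H iff category(X) < category(Y), L iff
    greater, = otherwise. ``percent`` mode: H iff pct(X) > pct(Y) + delta,
    L iff pct(X) < pct(Y) - delta. Only genes assessable in both strains
    are called.
    """
    cx = table[f"category_{strain_x}"].to_numpy()
    cy = table[f"category_{strain_y}"].to_numpy()
    ok = (cx > 0) & (cy > 0)
    if mode == "category":
        call = np.where(cx < cy, "H", np.where(cx > cy, "L", "="))
    elif mode == "percent":
        px = table[f"pct_remaining_{strain_x}"].to_numpy()
        py = table[f"pct_remaining_{strain_y}"].to_numpy()
        call = np.where(px > py + delta, "H", np.where(px < py - delta, "L", "="))
    else:
        raise ValueError(f"unknown comparison mode {mode!r}")
    out = pd.DataFrame({
        "gene_id": table["gene_id"],
        "call": np.where(ok, call, "NA"),
    })
    out.attrs["totals"] = {
        lab: int((out.loc[ok, "call"] == lab).sum()) for lab in ("L", "=", "H")
    }
    return out


def chi_square_distributions(dist_list: list[np.ndarray]) -> tuple[float, int, float]:
    """Pearson chi-square over a strains x categories contingency table."""
    if len(dist_list) < 2:
        raise ValueError("need at least two category distributions")
    table = np.asarray(dist_list, dtype=float)
    expected = stats.contingency.expected_freq(table)
    if (expected <= 0).any():
        raise ValueError("chi-square undefined: a cell has zero expected count")
    stat, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)
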