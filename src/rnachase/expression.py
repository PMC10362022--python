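"""Normalization and threshold-based differential expression.

Counts-per-million and trimmed-mean-of-M-values (TMM) scaling follow the
conventional definitions (two-sided 30% trim on M, 5% on A, inverse
approximate-binomial-variance precision weights, factors centred to
geometric mean 1). Differential calls use an exact-style conditional
negative-binomial two-group test at a common method-of-moments dispersion,
Benjamini-Hochberg adjustment, and a pure threshold predicate
(FDR < 0.01 and |log2FC| >= 1 by default).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AnalysisConfig, CountMatrix

__all__ = [
    "NormFactors",
    "cpm",
    "tmm_factors",
    "nb_two_group_test",
    "bh_adjust",
    "select_degs",
    "overlap_sets",
    "regulon_enrichment",
]

DISPERSION_FLOOR = 1e-8


@dataclass
class NormFactors:
    """Per-sample TMM scaling factors; effective library = library x factor."""

    sample_ids: list[str]
    factors: np.ndarray
    reference_sample: str

    def __post_init__(self) -> None:
        self.factors = np.asarray(self.factors, dtype=float)
        if (self.factors <= 0).any():
            raise ValueError("TMM factors must be strictly positive")

    def effective_library_sizes(self, matrix: CountMatrix) -> np.ndarray:
        idx = [self.sample_ids.index(s) for s in matrix.sample_ids]
        return np.asarray(matrix.library_sizes, dtype=float) * self.factors[idx]


def cpm(matrix: CountMatrix, factors: NormFactors | None = None) -> pd.DataFrame:
    """Counts per million against (effective) library sizes.

    Without factors each column sums to 1e6 exactly (when library sizes are
    the column sums).
    """
    lib = np.asarray(matrix.library_sizes, dtype=float)
    if (lib <= 0).any():
        raise ValueError("zero or negative library size")
    if factors is not None:
        lib = factors.effective_library_sizes(matrix)
    values = matrix.counts / lib * 1e6
    return pd.DataFrame(values, index=pd.Index(matrix.gene_ids, name="gene"),
                        columns=matrix.sample_ids)


def _choose_reference(cpm_values: np.ndarray) -> int:
    # sample whose upper-quartile CPM is closest to the mean upper quartile
    uq = np.quantile(cpm_values, 0.75, axis=0)
    return int(np.argmin(np.abs(uq - uq.mean())))


def tmm_factors(
    matrix: CountMatrix,
    reference_sample: str | None = None,
    m_trim: float = 0.30,
    a_trim: float = 0.05,
) -> NormFactors:
    """Trimmed mean of M-values scaling factors.

    Per sample, M = log2 ratio vs the reference (library-size scaled), A = mean
    log2 abundance; genes zero in either sample are dropped, the extreme 30% of
    M and 5% of A are trimmed on each side, and the surviving M values are
    averaged with 1/(approximate binomial variance) weights. Factors are
    centred so their geometric mean is 1.
    """
    if matrix.n_samples < 2:
        raise ValueError("TMM needs at least two samples")
    counts = matrix.counts.astype(float)
    lib = np.asarray(matrix.library_sizes, dtype=float)
    if reference_sample is None:
        ref = _choose_reference(counts / lib * 1e6)
    else:
        ref = matrix.sample_ids.index(reference_sample)

    yr, lr = counts[:, ref], lib[ref]
    log_factors = np.zeros(matrix.n_samples)
    for k in range(matrix.n_samples):
        if k == ref:
            continue
        yk, lk = counts[:, k], lib[k]
        keep = (yk > 0) & (yr > 0)
        if not keep.any():
            raise ValueError(
                f"sample {matrix.sample_ids[k]!r} shares no expressed genes "
                f"with the reference {matrix.sample_ids[ref]!r}"
            )
        pk, pr = yk[keep] / lk, yr[keep] / lr
        m = np.log2(pk / pr)
        a = 0.5 * np.log2(pk * pr)
        w = (lk - yk[keep]) / (lk * yk[keep]) + (lr - yr[keep]) / (lr * yr[keep])
        n = m.size
        lo_m, hi_m = np.floor(n * m_trim) + 1, n - np.floor(n * m_trim)
        lo_a, hi_a = np.floor(n * a_trim) + 1, n - np.floor(n * a_trim)
        rank_m = stats.rankdata(m, method="average")
        rank_a = stats.rankdata(a, method="average")
        kept = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
        if not kept.any() or w[kept].sum() == 0:
            log_factors[k] = 0.0
        else:
            with np.errstate(divide="ignore"):
                inv_w = 1.0 / w[kept]
            log_factors[k] = float(np.sum(inv_w * m[kept]) / np.sum(inv_w))
    factors = 2.0 ** log_factors
    factors /= np.exp(np.mean(np.log(factors)))
    return NormFactors(
        sample_ids=list(matrix.sample_ids),
        factors=factors,
        reference_sample=matrix.sample_ids[ref],
    )


def _common_dispersion(norm_counts: np.ndarray, groups: list[np.ndarray]) -> float:
    """Common method-of-moments NB dispersion on library-equalized counts.

    Per (gene, group) cell phi_g = (var - mean)/mean^2; a crude pooled
    estimate seeds inverse-variance weights ~1/(phi0 + 1/mean)^2, whose
    weighted mean is far less dominated by the few highest-expressed genes
    than the plain pooled ratio. Floored at DISPERSION_FLOOR.
    """
    means, variances = [], []
    for idx in groups:
        sub = norm_counts[:, idx]
        means.append(sub.mean(axis=1))
        variances.append(sub.var(axis=1, ddof=1))
    m = np.concatenate(means)
    v = np.concatenate(variances)
    ok = m > 0
    m, v = m[ok], v[ok]
    if m.size == 0 or (m**2).sum() == 0:
        return DISPERSION_FLOOR
    phi0 = max(float(np.sum(v - m) / np.sum(m**2)), DISPERSION_FLOOR)
    w = 1.0 / (phi0 + 1.0 / m) ** 2
    phi_g = (v - m) / m**2
    return max(float(np.sum(w * phi_g) / np.sum(w)), DISPERSION_FLOOR)


def _exact_nb_pvalue(ya: int, yb: int, na: int, nb: int, phi: float) -> float:
    """Two-sided conditional NB test for a single gene.

    Group sums ya, yb of na and nb equalized samples; under the null each
    sample is NB(mu, phi) with common mu, so the group sums are
    NB(na*mu, phi/na) and NB(nb*mu, phi/nb). Conditioning on the total, the
    p-value sums the probabilities of all splits no more likely than the
    observed one (double-tail).
    """
    total = ya + yb
    if total == 0:
        return 1.0
    mu = total / (na + nb)
    a = np.arange(total + 1)
    ra, rb = na / phi, nb / phi
    pa = ra / (ra + na * mu)
    pb = rb / (rb + nb * mu)
    logp = stats.nbinom.logpmf(a, ra, pa) + stats.nbinom.logpmf(total - a, rb, pb)
    logp -= logp.max()
    p = np.exp(logp)
    p_obs = p[ya]
    pval = p[p <= p_obs * (1.0 + 1e-10)].sum() / p.sum()
    return float(min(pval, 1.0))


def nb_two_group_test(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    factors: NormFactors | None = None,
) -> pd.DataFrame:
    """Per-gene two-group NB test; returns gene_id, log2fc (A vs B), pvalue.

    Counts are scaled to the geometric-mean effective library size; log2FC is
    the ratio of normalized group means with a pseudo-count of half the
    smallest nonzero mean; the p-value is the exact-style conditional NB
    double tail at a pooled common dispersion. All-zero genes get
    (log2fc 0, p 1).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("need at least two samples per group")
    idx_a = np.array([matrix.sample_ids.index(s) for s in group_a])
    idx_b = np.array([matrix.sample_ids.index(s) for s in group_b])
    lib = np.asarray(matrix.library_sizes, dtype=float)
    if factors is not None:
        lib = factors.effective_library_sizes(matrix)
    ref_lib = float(np.exp(np.mean(np.log(lib[np.concatenate([idx_a, idx_b])]))))
    norm = matrix.counts.astype(float) * (ref_lib / lib)

    phi = _common_dispersion(norm, [idx_a, idx_b])

    mean_a = norm[:, idx_a].mean(axis=1)
    mean_b = norm[:, idx_b].mean(axis=1)
    nonzero = np.concatenate([mean_a[mean_a > 0], mean_b[mean_b > 0]])
    pseudo = 0.5 * nonzero.min() if nonzero.size else 0.5
    # pseudo-count only where a mean is zero: avoids +-inf without perturbing
    # the fold change of genes expressed on both sides
    adj_a = np.where(mean_a > 0, mean_a, pseudo)
    adj_b = np.where(mean_b > 0, mean_b, pseudo)
    log2fc = np.log2(adj_a / adj_b)

    eq = np.rint(norm).astype(np.int64)
    sum_a = eq[:, idx_a].sum(axis=1)
    sum_b = eq[:, idx_b].sum(axis=1)
    pvalues = np.ones(matrix.n_genes)
    for g in range(matrix.n_genes):
        if sum_a[g] + sum_b[g] == 0:
            log2fc[g] = 0.0
            continue
        pvalues[g] = _exact_nb_pvalue(
            int(sum_a[g]), int(sum_b[g]), len(idx_a), len(idx_b), phi
        )
    return pd.DataFrame(
        {"gene_id": matrix.gene_ids, "log2fc": log2fc, "pvalue": pvalues}
    )


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR; ties broken by stable sort on p."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def select_degs(table: pd.DataFrame, config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Apply the DEG predicate: fdr < threshold and |log2fc| >= threshold."""
    config = config or AnalysisConfig()
    out = table.copy()
    if "fdr" not in out.columns:
        out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out["is_deg"] = (out["fdr"] < config.fdr_threshold) & (
        out["log2fc"].abs() >= config.lfc_threshold
    )
    out["direction"] = np.where(out["log2fc"] > 0, "up",
                                np.where(out["log2fc"] < 0, "down", "none"))
    return out


def overlap_sets(deg_sets: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """Counts for every region of the Venn partition of the named sets."""
    names = list(deg_sets)
    if len(names) < 2:
        raise ValueError("need at least two sets to overlap")
    sets = {k: frozenset(v) for k, v in deg_sets.items()}
    universe = frozenset().union(*sets.values())
    rows = []
    for membership in itertools.product([False, True], repeat=len(names)):
        if not any(membership):
            continue
        region = universe
        for name, inside in zip(names, membership):
            region = region & sets[name] if inside else region - sets[name]
        rows.append({
            "region": "&".join(n for n, m in zip(names, membership) if m)
            + ("" if all(membership) else "_only" if sum(membership) == 1 else ""),
            **{n: m for n, m in zip(names, membership)},
            "count": len(region),
        })
    return pd.DataFrame(rows)


def regulon_enrichment(
    deg_set: Iterable[str],
    universe: Iterable[str],
    regulons: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Per-regulon 2x2 Fisher exact enrichment with BH across regulons."""
    degs = set(deg_set)
    uni = set(universe)
    if not degs <= uni:
        raise ValueError("DEG set must be a subset of the universe")
    rows = []
    for name, genes in regulons.items():
        members = set(genes) & uni
        if not members:
            warnings.warn(f"regulon {name!r} is empty within the universe; skipped",
                          stacklevel=2)
            continue
        a = len(degs & members)
        b = len(degs - members)
        c = len(members - degs)
        d = len(uni) - a - b - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
        rows.append({"regulon": name, "n_regulon": len(members), "n_overlap": a,
                     "odds_ratio": odds, "pvalue": p})
    result = pd.DataFrame(rows)
    if len(result):
        result["fdr"] = bh_adjust(result["pvalue"].to_numpy())
    return result
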