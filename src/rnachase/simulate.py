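"""Synthetic-data generators with recorded ground truth.

Stand-ins for the deposited RNA-Seq experiments and the bench assays:
negative-binomial expression matrices with known differential genes,
rifampicin-chase T0/T4 pairs with known half-lives and stability
categories, a synchronous-doubling fluctuation-assay simulator, and
noisy phenotype measurement series. All randomness flows from one seed
through spawned child generators, so identical spec + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core_io import CountMatrix, SampleSheet
from .fluctuation import FluctuationData
from .phenotype import MeasurementSeries

__all__ = [
    "ExpressionSimSpec",
    "DecaySimSpec",
    "FluctuationSimSpec",
    "simulate_expression",
    "simulate_decay",
    "simulate_fluctuation",
    "simulate_measurements",
]

DEFAULT_STRAINS = ("pnp+", "dpnp", "PNPT1Ec")

#: category proportions shaped like the observed strain contrast:
#: the heterologous-enzyme strain piles up in category 1 (stable),
#: the wild type in category 4 (unstable).
DEFAULT_CATEGORY_PRESETS = {
    "pnp+": (0.15, 0.20, 0.25, 0.40),
    "dpnp": (0.30, 0.30, 0.25, 0.15),
    "PNPT1Ec": (0.55, 0.25, 0.12, 0.08),
}


def _spawn(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + dispersion * mu^2."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


@dataclass
class ExpressionSimSpec:
    n_genes: int = 2000
    strains: tuple[str, ...] = DEFAULT_STRAINS
    n_replicates: int = 3
    mean_log_expression: tuple[float, float] = (0.0, 1.0)  # lognormal loc/scale
    dispersion: float = 0.05
    deg_fraction: float = 0.0
    effect_size: float = 1.0
    library_size: int = 5_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.deg_fraction <= 1.0:
            raise ValueError("deg_fraction must be in [0, 1]")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if self.library_size <= 0:
            raise ValueError("library_size must be positive")
        if self.n_genes < 1 or self.n_replicates < 1 or len(self.strains) < 1:
            raise ValueError("n_genes, n_replicates and strains must be non-empty")


def simulate_expression(spec: ExpressionSimSpec) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """NB count matrix for all strains plus a truth table of true log2FCs.

    The first strain is the reference; per non-reference strain a
    ``deg_fraction`` of genes receives a +/- ``effect_size`` log2 shift.
    The truth table has one ``shift_<strain>`` column per strain and
    ``true_log2fc_<A>_vs_<B>`` columns for every strain pair.
    """
    rng_base, rng_deg, rng_counts = _spawn(spec.seed, 3)
    loc, scale = spec.mean_log_expression
    base = rng_base.lognormal(loc, scale, size=spec.n_genes)

    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    shifts = {spec.strains[0]: np.zeros(spec.n_genes)}
    n_deg = int(round(spec.deg_fraction * spec.n_genes))
    for strain in spec.strains[1:]:
        shift = np.zeros(spec.n_genes)
        if n_deg:
            chosen = rng_deg.choice(spec.n_genes, size=n_deg, replace=False)
            signs = rng_deg.choice([-1.0, 1.0], size=n_deg)
            shift[chosen] = signs * spec.effect_size
        shifts[strain] = shift

    sample_ids, strain_col, rep_col, columns = [], [], [], []
    for strain in spec.strains:
        rel = base * 2.0 ** shifts[strain]
        prob = rel / rel.sum()
        mean = prob * spec.library_size
        for rep in range(1, spec.n_replicates + 1):
            sample_ids.append(f"{strain}_T0_r{rep}")
            strain_col.append(strain)
            rep_col.append(rep)
            columns.append(_nb_sample(rng_counts, mean, spec.dispersion))
    counts = np.column_stack(columns)

    sheet = SampleSheet(pd.DataFrame({
        "sample_id": sample_ids,
        "strain": strain_col,
        "timepoint": "T0",
        "replicate": rep_col,
    }))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        matrix = CountMatrix(gene_ids=gene_ids, sample_ids=sample_ids, counts=counts)

    truth = pd.DataFrame({"gene_id": gene_ids})
    for strain in spec.strains:
        truth[f"shift_{strain}"] = shifts[strain]
    for i, a in enumerate(spec.strains):
        for b in spec.strains[i + 1:]:
            truth[f"true_log2fc_{a}_vs_{b}"] = shifts[a] - shifts[b]
    return matrix, sheet, truth


@dataclass
class DecaySimSpec:
    category_proportions: Mapping[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_PRESETS)
    )
    halflife_ranges: Mapping[int, tuple[float, float]] | None = None
    category_bounds: tuple[float, float, float] = (25.0, 50.0, 75.0)
    decay_time: float = 4.0
    # T4 re-sequences the same culture, so only technical overdispersion
    # applies (well below the 0.05 between-replicate default); 0 = deterministic
    noise: float = 0.02
    margin: float = 2.0  # percent points kept clear of category edges
    seed: int = 0

    def __post_init__(self) -> None:
        for strain, props in self.category_proportions.items():
            p = np.asarray(props, dtype=float)
            if p.size != 4 or (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"category proportions for {strain!r} must be 4 "
                                 "non-negative values summing to 1")
        if self.decay_time <= 0:
            raise ValueError("decay_time must be positive")
        if self.noise < 0:
            raise ValueError("noise dispersion must be >= 0")
        if self.halflife_ranges is not None:
            for cat, (lo, hi) in self.halflife_ranges.items():
                if lo <= 0 or hi < lo:
                    raise ValueError(f"bad half-life range for category {cat}")
                for t_half in (lo, hi):
                    pct = 100.0 * 2.0 ** (-self.decay_time / t_half)
                    if _category_of(pct, self.category_bounds) != cat:
                        raise ValueError(
                            f"half-life {t_half} min maps outside category {cat} "
                            f"bounds at t={self.decay_time}"
                        )

    def pct_interval(self, category: int) -> tuple[float, float]:
        edges = (0.0, *self.category_bounds, 100.0)
        lo = edges[4 - category] + self.margin
        hi = edges[5 - category] - self.margin
        if category == 4:
            lo = max(lo, 1.0)  # keep t1/2 > 0
        return lo, hi


def _category_of(pct: float, bounds: tuple[float, float, float]) -> int:
    b0, b1, b2 = bounds
    return 1 if pct >= b2 else 2 if pct >= b1 else 3 if pct >= b0 else 4


def simulate_decay(
    spec: DecaySimSpec,
    baseline: CountMatrix,
    sheet: SampleSheet,
) -> tuple[CountMatrix, SampleSheet, pd.DataFrame]:
    """Pair every T0 sample with a simulated T4 sample after rifampicin.

    Expected T4 count = T0 count x 2^(-decay_time/t1/2); with ``noise`` > 0
    the T4 counts are NB-resampled around that mean, otherwise rounded.
    T4 library sizes are carried over from the T0 columns (depth-matched),
    so noiseless percent remaining in CPM equals the true decayed fraction.
    Truth columns per strain: t_half, true_pct, true_category.
    """
    rngs = _spawn(spec.seed, 2)
    rng_cat, rng_noise = rngs
    strains = sheet.strains
    n_genes = baseline.n_genes

    truth = pd.DataFrame({"gene_id": baseline.gene_ids})
    half_lives: dict[str, np.ndarray] = {}
    for strain in strains:
        props = spec.category_proportions.get(strain)
        if props is None:
            raise ValueError(f"no category proportions for strain {strain!r}")
        cats = rng_cat.choice([1, 2, 3, 4], size=n_genes, p=np.asarray(props, float))
        if spec.halflife_ranges is not None:
            t_half = np.empty(n_genes)
            for c in (1, 2, 3, 4):
                lo, hi = spec.halflife_ranges[c]
                sel = cats == c
                t_half[sel] = rng_cat.uniform(lo, hi, size=sel.sum())
            pct = 100.0 * 2.0 ** (-spec.decay_time / t_half)
        else:
            pct = np.empty(n_genes)
            for c in (1, 2, 3, 4):
                lo, hi = spec.pct_interval(c)
                sel = cats == c
                pct[sel] = rng_cat.uniform(lo, hi, size=sel.sum())
            t_half = spec.decay_time / -np.log2(pct / 100.0)
        half_lives[strain] = t_half
        truth[f"t_half_{strain}"] = t_half
        truth[f"true_pct_{strain}"] = pct
        truth[f"true_category_{strain}"] = cats

    all_ids = list(baseline.sample_ids)
    all_counts = [baseline.counts]
    t0_lib = baseline.counts.sum(axis=0)
    lib_sizes = list(t0_lib)
    t0_frame = sheet.frame.copy()
    t0_frame["library_size"] = [
        int(t0_lib[baseline.sample_ids.index(s)]) for s in t0_frame["sample_id"]
    ]
    rows = [t0_frame]
    t4_ids, t4_cols, t4_rows = [], [], []
    for i, sid in enumerate(baseline.sample_ids):
        row = sheet.frame[sheet.frame["sample_id"] == sid].iloc[0]
        if row["timepoint"] != "T0":
            raise ValueError(f"baseline sample {sid!r} is not a T0 sample")
        strain = row["strain"]
        frac = 2.0 ** (-spec.decay_time / half_lives[strain])
        mean = baseline.counts[:, i] * frac
        if spec.noise > 0:
            t4 = _nb_sample(rng_noise, mean, spec.noise)
        else:
            t4 = np.rint(mean).astype(np.int64)
        new_id = f"{strain}_T4_r{int(row['replicate'])}"
        t4_ids.append(new_id)
        t4_cols.append(t4)
        lib_sizes.append(t0_lib[i])  # depth-matched chase
        t4_rows.append({"sample_id": new_id, "strain": strain,
                        "timepoint": "T4", "replicate": int(row["replicate"]),
                        "library_size": int(t0_lib[i])})
    combined = CountMatrix(
        gene_ids=list(baseline.gene_ids),
        sample_ids=all_ids + t4_ids,
        counts=np.column_stack(all_counts + [np.column_stack(t4_cols)]),
        library_sizes=np.asarray(lib_sizes),
    )
    combined_sheet = SampleSheet(pd.concat(
        rows + [pd.DataFrame(t4_rows)], ignore_index=True
    ))
    return combined, combined_sheet, truth


@dataclass
class FluctuationSimSpec:
    n_cultures: int = 12
    n0: int = 100
    nf: int = 100_000
    mu: float = 1e-4
    plating_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.n0 < self.nf:
            raise ValueError("n0 must be smaller than nf")
        if not 0.0 <= self.mu < 1.0:
            raise ValueError("mu must be in [0, 1)")
        if not 0.0 < self.plating_fraction <= 1.0:
            raise ValueError("plating_fraction must be in (0, 1]")
        if self.n_cultures < 2:
            raise ValueError("need at least two cultures")


def simulate_fluctuation(spec: FluctuationSimSpec) -> FluctuationData:
    """Forward synchronous-doubling mutation model.

    Each generation every cell divides; each daughter cell mutates with
    probability mu; mutants breed true. Generations = round(log2(nf/n0)),
    the realized final population n0*2^g is recorded as the titer. Mutant
    counts (and implicitly titers) are binomially thinned by the plating
    fraction.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    generations = int(round(np.log2(spec.nf / spec.n0)))
    if generations < 1:
        raise ValueError("nf/n0 must allow at least one doubling")
    actual_nf = spec.n0 * 2**generations
    r_values = np.empty(spec.n_cultures, dtype=np.int64)
    for c in range(spec.n_cultures):
        wild, mutant = spec.n0, 0
        for _ in range(generations):
            daughters = 2 * wild
            new_mutants = rng.binomial(daughters, spec.mu) if spec.mu > 0 else 0
            wild = daughters - new_mutants
            mutant = 2 * mutant + new_mutants
        if spec.plating_fraction < 1.0:
            mutant = int(rng.binomial(mutant, spec.plating_fraction))
        r_values[c] = mutant
    titer = int(round(actual_nf * spec.plating_fraction))
    return FluctuationData(
        r_values=r_values,
        titers=np.full(spec.n_cultures, titer, dtype=np.int64),
        true_mu=spec.mu,
    )


def simulate_measurements(kind: str, params: Mapping | None = None, seed: int = 0):
    """Phenotype fixtures with multiplicative log-normal noise.

    kind="growth": OD doubling every ``g`` minutes -> (MeasurementSeries, truth)
    kind="western_decay": fractions 2^(-t/t_half) -> (MeasurementSeries, truth)
    kind="ros": per-group (fluorescence, od600) replicates -> (DataFrame, truth)
    kind="dotblot": signals at true ratios vs a reference -> (DataFrame, truth)
    """
    params = dict(params or {})
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    noise = float(params.pop("noise", 0.0))

    def jitter(n):
        return np.exp(rng.normal(0.0, noise, size=n)) if noise > 0 else np.ones(n)

    if kind == "growth":
        g = float(params.pop("g", 30.0))
        od0 = float(params.pop("od0", 0.05))
        times = np.asarray(params.pop("times", np.arange(0, 121, 10)), dtype=float)
        n_rep = int(params.pop("n_replicates", 1))
        t = np.tile(times, n_rep)
        rep = np.repeat(np.arange(1, n_rep + 1), times.size)
        od = od0 * 2.0 ** (t / g) * jitter(t.size)
        series = MeasurementSeries(time=t, value=od, replicate=rep, group="growth")
        return series, {"g": g, "od0": od0}

    if kind == "western_decay":
        t_half = float(params.pop("t_half", 78.0))  # minutes
        times = np.asarray(params.pop("times", [0.0, 20.0, 40.0, 60.0]), dtype=float)
        frac = 2.0 ** (-times / t_half) * jitter(times.size)
        series = MeasurementSeries(time=times, value=frac, group="western_decay")
        return series, {"t_half": t_half}

    if kind == "ros":
        groups = dict(params.pop("groups", {"a": 2000.0, "b": 4000.0}))
        od = float(params.pop("od600", 0.5))
        n_rep = int(params.pop("n_replicates", 3))
        rows = []
        for name, true_nf in groups.items():
            fl = true_nf * od * jitter(n_rep)
            for r in range(1, n_rep + 1):
                rows.append({"group": name, "replicate": r,
                             "fluorescence": fl[r - 1], "od600": od})
        return pd.DataFrame(rows), {"normalized_fluorescence": groups}

    if kind == "dotblot":
        ratios = dict(params.pop("ratios", {"ref": 1.0, "test": 6.0}))
        reference = params.pop("reference", next(iter(ratios)))
        base = float(params.pop("base_signal", 1000.0))
        n_rep = int(params.pop("n_replicates", 3))
        rows = []
        for name, ratio in ratios.items():
            sig = base * ratio * jitter(n_rep)
            for r in range(1, n_rep + 1):
                rows.append({"sample": name, "replicate": r, "signal": sig[r - 1]})
        return pd.DataFrame(rows), {"ratios": ratios, "reference": reference}

    raise ValueError(f"unknown measurement kind {kind!r}")
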