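"""Shared data model, tabular readers/writers and run configuration.

All tables are plain tab-separated text with a header row, decimal point,
no thousands separators, so integer round-trips are bit-exact and real
round-trips are reproducible to float precision. Downstream stages consume
only the types defined here and never touch files themselves.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CountMatrix",
    "SampleSheet",
    "AnalysisConfig",
    "CountTableError",
    "read_count_table",
    "read_sample_sheet",
    "write_results",
    "read_results",
    "load_config",
    "save_config",
]


class CountTableError(ValueError):
    """Raised on malformed count tables or inconsistent sample metadata."""


@dataclass
class CountMatrix:
    """Integer read counts, genes x samples, with per-sample library sizes.

    ``library_sizes`` defaults to column sums; an explicitly supplied value
    (e.g. total mapped reads, or a depth-matched reference) is kept as given
    but must be strictly positive.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # shape (n_genes, n_samples), integer dtype
    library_sizes: np.ndarray | None = None
    all_zero_warning: bool = field(default=False, init=False)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise CountTableError(
                f"count array shape {counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.asarray(counts) == np.floor(counts)):
                bad = np.argwhere(counts != np.floor(counts))[0]
                raise CountTableError(
                    f"non-integer count at gene {self.gene_ids[bad[0]]!r}, "
                    f"sample {self.sample_ids[bad[1]]!r}: {counts[bad[0], bad[1]]!r}"
                )
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            bad = np.argwhere(counts < 0)[0]
            raise CountTableError(
                f"negative count at gene {self.gene_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}: {counts[bad[0], bad[1]]}"
            )
        self.counts = counts.astype(np.int64)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            dup = _first_duplicate(self.gene_ids)
            raise CountTableError(f"duplicate gene id {dup!r}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise CountTableError(f"duplicate sample id {dup!r}")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        else:
            ls = np.asarray(self.library_sizes, dtype=np.int64)
            if ls.shape != (len(self.sample_ids),):
                raise CountTableError("library_sizes length does not match samples")
            if (ls <= 0).any():
                raise CountTableError("library sizes must be strictly positive")
            self.library_sizes = ls
        if (self.counts.sum(axis=0) == 0).any():
            self.all_zero_warning = True
            warnings.warn("one or more samples have all-zero counts", stacklevel=3)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.gene_ids, name="gene"),
                            columns=self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return CountMatrix(
                gene_ids=list(self.gene_ids),
                sample_ids=list(sample_ids),
                counts=self.counts[:, idx],
                library_sizes=np.asarray(self.library_sizes)[idx],
            )


@dataclass
class SampleSheet:
    """Per-sample metadata: strain, timepoint label (T0/T4), replicate, and an
    optional explicit library_size column (e.g. a depth-matched reference)."""

    frame: pd.DataFrame  # columns: sample_id, strain, timepoint, replicate

    REQUIRED = ("sample_id", "strain", "timepoint", "replicate")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise CountTableError(f"sample sheet missing columns: {missing}")
        f = self.frame.reset_index(drop=True).copy()
        f["sample_id"] = f["sample_id"].astype(str)
        f["strain"] = f["strain"].astype(str)
        f["timepoint"] = f["timepoint"].astype(str)
        f["replicate"] = f["replicate"].astype(int)
        if "library_size" in f.columns:
            f["library_size"] = f["library_size"].astype(np.int64)
            if (f["library_size"] <= 0).any():
                raise CountTableError("library_size in the sheet must be positive")
        if f["sample_id"].duplicated().any():
            dup = f.loc[f["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise CountTableError(f"duplicate sample_id in sheet: {dup!r}")
        if (f["replicate"] < 1).any():
            raise CountTableError("replicate numbers must be >= 1")
        triple = f[["strain", "timepoint", "replicate"]]
        if triple.duplicated().any():
            row = triple[triple.duplicated()].iloc[0]
            raise CountTableError(
                f"duplicate (strain, timepoint, replicate) triple: {tuple(row)}"
            )
        self.frame = f

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame["sample_id"])

    def samples_for(self, strain: str | None = None,
                    timepoint: str | None = None) -> list[str]:
        f = self.frame
        if strain is not None:
            f = f[f["strain"] == strain]
        if timepoint is not None:
            f = f[f["timepoint"] == timepoint]
        return list(f["sample_id"])

    @property
    def strains(self) -> list[str]:
        return list(dict.fromkeys(self.frame["strain"]))


@dataclass
class AnalysisConfig:
    """Flat run configuration; every threshold used downstream lives here."""

    fdr_threshold: float = 0.01
    lfc_threshold: float = 1.0
    category_bounds: tuple[float, ...] = (25.0, 50.0, 75.0)
    decay_time: float = 4.0
    rng_seed: int = 0
    pct_cap: float | None = 100.0
    assessability_floor: float = 1.0
    recovery_threshold: float = 0.90
    min_count: int = 0
    min_samples: int = 0
    library_size_mode: str = "column_sum"

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValueError("fdr_threshold must be in (0, 1)")
        if self.lfc_threshold < 0:
            raise ValueError("lfc_threshold must be >= 0")
        b = tuple(float(x) for x in self.category_bounds)
        if len(b) != 3 or any(not 0 < x < 100 for x in b) or any(
            b[i] >= b[i + 1] for i in range(len(b) - 1)
        ):
            raise ValueError("category_bounds must be strictly increasing within (0, 100)")
        self.category_bounds = b

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["category_bounds"] = list(self.category_bounds)
        return d


def _first_duplicate(items: Sequence[str]) -> str:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    raise AssertionError("no duplicate found")


def read_sample_sheet(path: str | Path) -> SampleSheet:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    return SampleSheet(frame)


def read_count_table(path: str | Path, sheet: SampleSheet) -> CountMatrix:
    """Read a TSV count table (first column gene ids) against a sample sheet.

    The returned matrix contains exactly the sheet's samples, in sheet order.
    Malformed cells, duplicated genes, or samples missing from the table are
    hard errors naming the offender.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0)
    raw.index = raw.index.astype(str)
    table_samples = [str(c) for c in raw.columns]
    missing = [s for s in sheet.sample_ids if s not in table_samples]
    if missing:
        raise CountTableError(f"samples in sheet but not in {path}: {missing}")
    extra = [s for s in table_samples if s not in set(sheet.sample_ids)]
    if extra:
        raise CountTableError(f"samples in {path} absent from the sheet: {extra}")
    ordered = raw[sheet.sample_ids]
    for col in ordered.columns:
        vals = ordered[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        if numeric.isna().any():
            gene = vals.index[numeric.isna()][0]
            raise CountTableError(
                f"non-numeric count at gene {gene!r}, sample {col!r}: "
                f"{vals.loc[gene]!r}"
            )
    values = ordered.to_numpy()
    library_sizes = None
    if "library_size" in sheet.frame.columns:
        library_sizes = sheet.frame["library_size"].to_numpy()
    return CountMatrix(
        gene_ids=list(ordered.index),
        sample_ids=sheet.sample_ids,
        counts=values,
        library_sizes=library_sizes,
    )


def write_count_table(matrix: CountMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, sep="\t")


def write_results(table: pd.DataFrame, path: str | Path) -> None:
    """Write any results table as deterministic TSV (rows sorted by first column)."""
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty results table")
    out = table.copy()
    sort_col = out.columns[0]
    out = out.sort_values(sort_col, kind="stable").reset_index(drop=True)
    out.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Load the flat YAML config; keyword overrides win over file values."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a flat mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "category_bounds" in data:
        data["category_bounds"] = tuple(data["category_bounds"])
    return AnalysisConfig(**data)


def save_config(config: AnalysisConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
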