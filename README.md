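# rnachase

Analysis pipeline for bacterial RNA-stability and expression experiments:

- **Rifampicin-chase stability**: percent of T0 CPM remaining at T4 per gene,
  a four-category classification (1 = most stable … 4 = least stable, bounds
  25/50/75%, half-open intervals closed on the lower bound), per-strain
  category distributions, pairwise lower/equal/higher (L/=/H) stability calls
  and a Pearson chi-square comparison of distributions.
- **Differential expression**: CPM, TMM normalization (two-sided 30%/5% trims,
  precision weights), an exact-style conditional negative-binomial two-group
  test with a pooled method-of-moments common dispersion,
  Benjamini–Hochberg FDR, and threshold selection (FDR < 0.01 and
  |log2FC| ≥ 1 by default), plus Venn-region overlap counts and Fisher-exact
  regulon enrichment.
- **Fluctuation test**: mutation-rate estimation from parallel-culture mutant
  counts via the Lea–Coulson median estimator
  (solve r − 1.24·m − m·ln m = 0, then µ = m / median titer).
- **Phenotypes**: generation time from log-linear OD fits, protein half-life
  from loading-control-normalized decay, ROS fluorescence/OD normalization,
  dot-blot relative quantification, molecules-per-cell arithmetic, and
  t-test / one-way ANOVA + Tukey HSD helpers with a compact letter display.
- **Synthetic data**: seeded generators for all of the above with recorded
  ground truth (negative-binomial count matrices with known DEGs, T0/T4 decay
  pairs with known half-lives and categories, a synchronous-doubling
  fluctuation simulator, noisy measurement series), so every stage is
  verifiable end to end without external downloads.

## Command line

All file formats are plain tab-separated text with a header. The sample sheet
has columns `sample_id, strain, timepoint, replicate` and optionally
`library_size` (explicit per-sample library sizes, e.g. depth-matched T4
libraries); count tables have gene ids in the first column and one column per
sample.

```sh
# full synthetic pipeline with one seed; writes a run manifest
rnachase run-all --workdir out/ --seed 1
rnachase report --workdir out/

# individual stages
rnachase simulate   --workdir out/ --seed 1
rnachase de         --counts out/counts.tsv --sheet out/samples.tsv \
                    --contrast pnp+:dpnp --out out/degs.tsv
rnachase stability  --counts out/counts.tsv --sheet out/samples.tsv \
                    --out-prefix out/stability
rnachase fluctuation --data out/fluctuation.tsv --out out/mu.tsv
rnachase phenotype  --growth out/growth.tsv --decay out/western.tsv \
                    --ros out/ros.tsv --dotblot out/dotblot.tsv \
                    --out out/phenotype.tsv
```

Every subcommand that applies thresholds accepts `--config config.yaml`, a
flat YAML file; keys and defaults: `fdr_threshold: 0.01`,
`lfc_threshold: 1.0`, `category_bounds: [25, 50, 75]`, `decay_time: 4`,
`pct_cap: 100`, `assessability_floor: 1.0` (minimum mean T0 CPM for a gene to
be classifiable), `recovery_threshold: 0.9`, `min_count`/`min_samples`
(low-count DE pre-filters, off by default — enabling them mainly trims
low-power tests and slightly raises sensitivity at fixed FDR), `rng_seed`.

## Notes

- Percent remaining is a ratio of CPM values; values above 100% are capped at
  100 by default (`pct_cap: null` keeps raw values; the raw percent is always
  retained in a `pct_raw_*` column). An auxiliary half-life back-calculation
  `decay_time / −log2(pct/100)` is available as
  `stability.implied_half_life` (extension, not part of the categorical
  scheme).
- The L/=/H strain comparison is category-based by default; a raw-percent
  rule with threshold δ is available via
  `compare_strains(..., mode="percent", delta=...)`.
- The fluctuation estimator is the median-based form only; it is not
  invariant to partial plating (a known limitation of median estimators),
  and no maximum-likelihood variant is provided.
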