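# metaeval

Benchmark metabolomics data-processing schemes by how closely the processed
semiquantitative (peak-area) data resembles paired absolute-concentration
data.  The pipeline applies every scheme in a 97-cell grid — 6
transformations, 6 scalings, their 36 combinations, ccmn normalization, and
ccmn combined with each of those (6 + 6 + 36) — fits PLS-DA on every
processed dataset, and scores each scheme by the similarity of its
variable-importance (VIP) profile to the one obtained from the
concentration reference:

```
similarity(x, y) = 1 - sqrt( sum_i (x_i - y_i)^2 )
```

reported both literally and with the VIP vectors normalized to unit
Euclidean norm.  Supporting modules cover the two-stage missing-value
policy (groupwise-minimum substitution for structural below-LOD absence,
then missForest-style random-forest imputation), internal-standard
normalizations (ccmn, nomis, single-IS ratio), data-property diagnostics
(Shapiro–Wilk normality, skewness, CV, fold-difference trends, RLA), PCA /
PLS-DA with VIPs, hierarchical clustering of VIP profiles, and a synthetic
generator of paired concentration/peak-area datasets with a shared
multiplicative per-sample error.

## Test

```bash
python -m pytest tests/
```

## CLI

```bash
# paired synthetic data (milk-like or urine-like design)
metaeval simulate --design milk --seed 1 --out data/

# apply one processing scheme to a wide CSV
metaeval process --in data/area.csv --scheme ccmn+sqrt+none --out processed.csv

# run the full 97-scheme benchmark against the concentration reference
metaeval evaluate --area data/area.csv --conc data/conc.csv --out report/

# render a ranked summary
metaeval report --in report/ --format md
```

The exchange format is a wide CSV: a `# unit_tag:` comment line, then a
header `sample_id,group,sample_type[,replicate],<feature...>`; empty cells
(or `NA`) are missing values, and internal standards are flagged via a
`# internal_standards:` comment, a sidecar feature-metadata CSV, or a name
prefix (see `metaeval.io.read_dataset`).

`metaeval evaluate` writes `similarity.csv`, `vips.csv`, `clustering.json`,
`profile_pca.csv` and a resolved `config.json`; schemes whose preconditions
fail on the given data (e.g. a log transform of a zero) are recorded as
skipped, never silently dropped.

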