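# pbmckit

A tested pipeline for case/control PBMC single-cell analysis:

- **simulate** — synthetic multi-sample cohorts with negative-binomial counts
  (var = μ + φμ²), planted per-cell-type up/down differential programs scaled
  by a per-sample shared activation scalar, composition shifts, doublets,
  sex-linked markers and mitochondrial fractions, plus matching reference
  panels and gene-level risk-score tables. Everything downstream is testable
  against the generated truth.
- **qc** — gene-prevalence filter (detected in ≥ 0.1% of cells), mitochondrial
  fraction cap (≤ 7%), cluster-specific strict windows on the number of
  detected genes, doublet exclusion, and a per-sample sex-concordance check
  from Y/X marker expression.
- **project** — depth-normalized cells correlated with reference cell-type
  profiles over feature genes; correlations sharpened by a sign-preserving
  fourth power and row-z-transformed; average-linkage clustering on
  correlation distance with a silhouette-guided dynamic cut; cluster
  annotation with an explicit ambiguity rule; sequential multi-resolution
  re-annotation through per-compartment subpanels.
- **composition** — per-sample cell-type proportions (and ratio features),
  covariate regression with partial F-tests, and a per-cell log2 case
  enrichment over each cell's 50 nearest neighbors in PCA space.
- **de** — per-(sample, cell type) pseudo-bulk summation with the < 5-cell and
  < 5%-of-samples exclusions; a minimal NB-Wald pipeline (median-of-ratios
  size factors, trend-shrunk dispersions, vectorized IRLS, BH correction);
  DEG calling at |log2FC| ≥ log2(1.3), q ≤ 0.1; evidence scores
  (|log2FC| × −log10 q); cell-level NB GLM marker tests.
- **enrich** — k-means modules on DEG fold-change profiles, one-sided Fisher
  overlap tests, hypergeometric over-representation, and unweighted
  (exponent 0) preranked gene-set enrichment with a permutation null.
- **tmz** — the per-sample metagene z-score (mean z of up-DEGs minus mean z of
  down-DEGs per cell type), sample subtyping into low/intermediate/high,
  clinical association tests (OLS, Spearman, Kruskal-Wallis, paired t), and
  quantile-mapped projection of external bulk expression onto the cohort's
  score distribution.
- **gwas** — min-max-normalized evidence scores of significant genes used as a
  gene-level covariate in a one-sided regression against external risk
  scores (optionally excluding a genomic region), and effector-gene selection
  (top-200 risk ∩ upper 30% of normalized evidence).
- **io_cli** — MTX/TSV readers and writers, YAML pipeline configuration, a
  deterministic end-to-end orchestrator with an output manifest, and the CLI.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds one test per acceptance criterion.
Criterion 6's magnitude bound on the permuted-label neighborhood
enrichment (mean |e| < 0.15 at k = 50) contradicts the exact
hypergeometric null of its own formula (E|e| ≈ 0.32) and is expected to
fail; the attainable invariants (null centered at zero, exact
antisymmetry) are asserted in `tests/test_composition.py`.

## CLI

```sh
pbmckit simulate --out cohort/ --seed 1 --n-case 10 --n-control 10
pbmckit qc --in cohort/ --out qc/ --mito-max 0.07
pbmckit project --in qc/ --panel major.tsv --out labels.tsv
pbmckit composition --labels labels.tsv --covars covars.tsv --out comp/
pbmckit de --in qc/ --labels labels.tsv --out de/
pbmckit enrich --ranked ranked.tsv --gmt sets.gmt --out gsea.tsv
pbmckit tmz --in qc/ --labels labels.tsv --deg-sets de/deg_sets.json --out tmz.tsv
pbmckit gwas --deg-table de/deg_table.tsv --risk risk.tsv --out gwas/
pbmckit run --out pipeline/ --seed 1       # full pipeline on a simulated cohort
```

`pbmckit run` executes qc → project → composition → de → enrich → tmz →
gwas, skipping stages whose inputs are missing, and writes a
`manifest.json` of output file hashes; reruns with the same config and
seed are bit-identical.

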