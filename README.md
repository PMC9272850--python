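# dmcortexome

Downstream transcriptome-dysregulation analysis for myotonic dystrophy (DM)
frontal cortex, packaged as a tested, reusable pipeline. It is aimed at
computational biologists working with bulk RNA-seq of repeat-expansion
disorders who have upstream quantifications in hand (exon inclusion levels
from MISO-style tools, TPM from a quantifier, a DE table, single-molecule
repeat spans from optical mapping) and want the statistics downstream of
them:

* **Mis-splicing detection** — per-event two-sided Wilcoxon rank-sum on ψ
  (percent spliced in) between affected and unaffected groups, significance
  at |Δψ| > 0.2 and p < 0.01, with a label-shuffling false-discovery
  estimate and a shuffled-null check of the pairwise ψ correlation
  structure.
* **Severity scores** — per-sample splicing dysregulation
  S_i = mean_e |ψ_{i,e} − μ_e| over the significant events (μ_e the
  unaffected mean), and the analogous expression score
  G_i = mean_g |log₂(TPM_{i,g}+1) − μ_g| over regulated genes.
* **Motif enrichment** — k-mer counts in five windows around each cassette
  exon (±250 nt of each splice site plus the exon), one-sided binomial tests
  against background skipped exons with Bonferroni correction over
  4^k × 5 tests, separately for aberrantly included and excluded exons, with
  optional joining of in-vitro Bind-N-Seq binding enrichments.
* **Bayesian deconvolution** — per-sample cell-type proportions
  θ ~ Dirichlet(1) with Σθ_c = 1, marker-based log-normal likelihood,
  posterior by an adaptive Metropolis sampler with R̂-gated convergence,
  pruning of cell types below 2.5%, and group comparison of proportions.
* **Biomarker prioritization** — regulated genes ranked by CSF
  detectability, |Pearson R| with S, and expression level.
* **Repeat mosaicism** — CTG unit estimates from single-molecule spans,
  50/75/90th percentiles per sample, and their correlation with S.
* **Cross-dataset comparisons** — tissue/disease overlap with sub-sampling
  capture estimates, and placement of patient severity between mouse MBNL
  knockout genotypes via orthologous exons.

A synthetic-cohort generator with fully recorded ground truth (latent
severity gradient, responsive exons, cell-type mixtures, planted YGCY-like
motifs, bimodal repeat distributions) makes the entire pipeline exercisable
and testable without any downloads. See `docs/methods.md` for models,
parameter choices, and limitations.

## Worked example

Simulate a cohort (8 unaffected + 21 affected, 130 responsive exons among
2130) and run the full pipeline:

```sh
dmcortexome all --simulate --out run --seed 11
```

which logs each stage and finishes with

```
completed stages: simulate, splice-test, fdr, score, correlate, motif,
deconvolve, expr-score, celltype-enrich, biomarkers, repeats
```

`run/` then contains `splicing_results.tsv` (per-event Δψ, p, direction),
`splicing_scores.tsv` (S per sample), `motif_enrichment.tsv`,
`proportions.tsv`, `expression_scores.tsv` (G), `biomarkers.tsv`,
`repeat_summaries.tsv` and a `manifest.json` recording seeds, thresholds and
output hashes. Identical seeds reproduce byte-identical results.

The same stages are ordinary library calls:

```python
from dmcortexome import (CohortConfig, simulate_cohort, test_events,
                         estimate_fdr_by_shuffle, splicing_score)

psi, tpm, truth, de = simulate_cohort(CohortConfig(seed=1))
res = test_events(psi, "DM1", "unaffected")      # dpsi_min=0.2, alpha=0.01
print(res.n_significant())                        # 53
fdr = estimate_fdr_by_shuffle(psi, "DM1", "unaffected", n_shuffles=10, seed=12)
print(fdr["mean_shuffled"], fdr["fdr"])           # 0.0 0.0
s = splicing_score(psi, res.significant_events, "unaffected")
print(s.table["score"].round(3).head(3).tolist()) # [0.036, 0.039, 0.038]
```

Here 53 of the 130 planted responsive exons clear both thresholds at this
seed and noise level, ten label shuffles yield zero significant events (an
estimated FDR well under 5%), and unaffected samples sit near S ≈ 0.04 — the
beta-noise floor — while affected samples spread up the severity gradient
(Spearman between S and the latent severity ≈ 0.99).

Individual stages are also exposed as subcommands (`splice-test`, `fdr`,
`score`, `correlate`, `motif`, `deconvolve`, `expr-score`,
`celltype-enrich`, `biomarkers`, `repeats`, `overlap`, `subsample`,
`ko-compare`); run `dmcortexome --help` for the full list and
`dmcortexome <cmd> --help` for the file formats each expects.

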