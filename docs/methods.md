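# Methods

This note documents the statistical models, the synthetic-cohort generator,
the numerical choices, and the limitations of `dmcortexome`. It is written for
a reader who wants to know exactly what each stage computes and what the test
suite does and does not demonstrate about real data.

## Mis-splicing detection and severity scoring

For each alternative-splicing event, per-sample inclusion levels ψ ∈ [0, 1]
are compared between affected (DM1) and unaffected groups with a two-sided
Wilcoxon rank-sum test on the non-missing values. An event is called
dysregulated when |Δψ| > 0.2 and p < 0.01, where Δψ is the difference of
group means (affected − unaffected), so "included" means inclusion increases
in disease. Events with fewer than two informative values in either group are
untestable and excluded from the family.

The exact null distribution of the rank-sum statistic is used whenever the
pooled values are tie-free and the cohort has ≤ 64 samples; tied data fall
back to the normal approximation with midrank tie correction and continuity
correction. The exact path matters for calibration: at 8 vs 21 samples the
continuity-corrected approximation is conservative enough to push the
fraction of null events with p < 0.01 visibly below 0.01, while the exact
test sits on the nominal level (both behaviors are measured in the test
suite's type-I check).

**False-discovery estimate.** Group labels are permuted independently per
event (a cohort-wise single permutation is available as an option), the full
test is re-run, and FDR is estimated as the mean shuffled significant count
divided by the observed count. This is the same label-shuffling logic used to
produce the null for ψ cross-correlations, where Pearson R is computed for
every pair of dysregulated events across all samples (groups pooled) and
compared with the shuffled-null R distribution by a two-sample
Kolmogorov–Smirnov test.

**Splicing dysregulation score.** S_i is the mean over dysregulated events of
|ψ_{i,e} − μ_e|, with μ_e the unaffected-group mean of event e. Events with
missing ψ for a sample are dropped from that sample's mean rather than
zero-filled — zero-filling would bias mildly affected patients toward the
control baseline. The display panel keeps dysregulated events whose ψ range
among unaffected samples is strictly below 0.25.

## Motif enrichment

Five sequence windows are interrogated per cassette exon: 250 nt downstream
of the upstream exon, 250 nt upstream of the cassette, the cassette itself,
250 nt downstream of the cassette, and 250 nt upstream of the downstream
exon. When an intron is shorter than 500 nt, its two windows are truncated at
the intron midpoint so they never overlap and never reach into the
neighboring exons. Minus-strand events are reverse-complemented so regions
are named in transcript orientation. Coordinates are 0-based half-open
everywhere.

k-mers (k = 4 or 5 in practice; any k ≥ 1 accepted) are counted in
overlapping windows, skipping windows containing N. Enrichment of a target
set (e.g. aberrantly included exons) over a background set (all other
skipped exons) is tested per region with a one-sided upper-tail binomial
test at the background frequency p0, Bonferroni-corrected over the full
family of 4^k k-mers × 5 regions within one direction set; included and
excluded exons form separate analyses. Background k-mers with zero counts
have p0 floored at one pseudo-occurrence to keep the test defined. A
depletion (lower-tail) mode exists but is off by default. k is always an
explicit parameter — there is no per-disease default.

## Bayesian cell-type deconvolution

Markers are selected from a gene × cell-type single-cell reference: per cell
type, genes are ranked by the enrichment ratio (expression in the type ÷ mean
across the other types), the top 50 compiled, and the union intersected with
the genes expressed in the bulk dataset.

Per bulk sample, proportions θ over C cell types carry a flat Dirichlet(1)
prior with Σθ_c = 1 enforced by construction (softmax parameterization, with
the Σ log θ Jacobian giving the exact uniform-on-simplex measure). Reference
columns and the observed marker vector are normalized to sum to one, making
the model invariant to any positive rescaling of the bulk profile. The
default likelihood is log-normal, log(y_g + ε) ~ Normal(log(Σ_c θ_c·ref̃_{g,c}
+ ε), σ) with ε = 10⁻⁶, σ given a half-normal(1) prior; a linear-Normal
alternative is selectable. The noise scale is parameterized as
σ = 10⁻³ + exp(u) — the additive floor keeps the posterior proper on
noise-free input (a pure reference column would otherwise send σ → 0 and let
the softmax coordinates drift indefinitely).

The posterior is explored by random-walk Metropolis with a Laplace-informed
proposal: the mode is found by derivative-free optimization, the proposal
covariance is the regularized inverse Hessian at the mode scaled by 2.38²/d,
the global scale is tuned to ≈30% acceptance during warmup, and retained
draws are thinned 5:1. Defaults are 4 chains × 1000 retained draws after
1000 warmup iterations. Convergence is gated on split-R̂ < 1.01 over all θ
components (computed with ArviZ); chains falling short are extended with
doubled draws up to two times before the fit raises an error carrying the
diagnostics — there are no silent results. Cell types whose cohort-mean
posterior falls below 2.5% are pruned (markers dropped) and the model re-fit.
Group differences in posterior-mean proportions use a two-sided rank-sum with
Benjamini–Hochberg adjustment.

## Expression dysregulation and biomarkers

Regulated genes satisfy q < 0.01 and |log2 fold-change| ≥ 1. The threshold is
interpreted on the log2 scale: a linear fold-change of 1 would be a
tautology. The expression dysregulation score G_i is the mean over regulated
genes of |log2(TPM+1) − unaffected-mean log2(TPM+1)|; the +1 pseudocount is a
fixed convention. Single regulated genes (and optionally gene pairs: sum of
log2(TPM+1) for same-direction pairs, difference for opposite) are Pearson-
correlated with S across samples; the null shuffles expression among samples
per gene. The log base cancels exactly in single-gene correlations and is
negligible for pairs.

Cell-type specificity divides a gene's expression in a type by its mean
across types (its expected value under uniform expression); a gene is
assigned to its argmax type when the score exceeds 3, otherwise left
unassigned. Enrichment of specific genes within up/down sets against the
unchanged background uses a two-sided Fisher exact test with the direction
read off the odds ratio. Biomarker candidates are regulated genes ranked
lexicographically: CSF-detectable first, then |R| with S descending, then
unaffected-mean log2(TPM+1) descending, with gene identifier as a stable
tie-break — a declared reconstruction of the three published criteria
(CSF-detectable, strongly correlated, well expressed).

Differential expression itself is consumed, not computed: the bundled
stand-in (per-gene rank-sum on log2(TPM+1) with BH q, labelled
`stand_in_ranksum_bh` in its metadata) exists so the synthetic pipeline is
exercisable end-to-end, and is not a substitute for a transcript-level DE
model on real data.

## Repeat-length mosaicism

Single-molecule inter-label spans at the repeat locus are converted to CTG
units as (span − reference flank)/3 with no clamping — negative estimates
are retained because measurement noise at the normal allele is of the order
of ±140 units, and discarding them would bias percentiles upward. The
reference inter-label distance is a required input, never defaulted.
Percentiles (50/75/90 by default) use linear interpolation between closest
ranks on the pooled molecule population; no mixture model separates normal
from expanded alleles. Percentile summaries are Pearson-correlated with S
pairwise-complete across samples.

## Cross-dataset comparisons

Overlap analyses re-threshold stored per-event statistics at |Δψ| ≥ 0.1,
p ≤ 0.01 and classify reference-dataset events as shared, expressed-but-not-
dysregulated, or not expressed in each other dataset; exclusive Venn regions
and pairwise Δψ concordance (Pearson on shared events) are reported.
Capture-fraction estimates re-run the full test on k case samples drawn
without replacement (controls intact unless requested otherwise; 100
repetitions by default) against a reference event list. Knockout placement
intersects human-dysregulated events with mouse events passing |Δψ| > 0.1,
p < 0.05 vs wild type through a one-to-one ortholog map, requires the shared
exons to be observed in all datasets, computes S per sample against each
species' own baseline, and emits the combined ordering. The shared-exon count
is always derived, never hard-coded.

## Synthetic cohort generator

The generator is first-class code: it defines the conditions under which
every downstream guarantee is tested.

* **Cohort**: 8 unaffected + 21 affected samples. A latent severity
  s_i ~ Uniform(0.15, 1) for affected, 0 for unaffected. The lower bound
  keeps a mildest-case regime reachable without degenerating the cohort.
* **ψ**: 130 responsive + 2000 null exons. Responsive exon e has baseline
  ψ0_e, direction d_e (+1 with probability 31/101, the published
  included/excluded split), and amplitude a_e ~ Uniform(0.25, 0.48); the
  per-sample mean is clip(ψ0 + d·a·s, 0.01, 0.99) and observed ψ is Beta
  with that mean and concentration κ = 100 (unaffected SD ≈ 0.04). The
  amplitude range is chosen so group |Δψ| of responsive exons sits near and
  above the 0.2 detection threshold — mirroring a study design in which the
  responsive panel is by construction the detectable one. Dose-response is
  linear in severity; that choice is recorded in `truth.json` so tests never
  assume more.
* **Proportions**: per-sample logits around (neuron .40, oligodendrocyte .25,
  astrocyte .20, endothelial .10, microglia .05) with N(0, 0.3²) noise and
  the microglia logit shifted by +1.2·s, then softmax-renormalized. The
  logit noise is set so inter-individual scatter matches what published
  cohort plots show: large enough that the small compositional dent in the
  other cell types from the microglia shift is not statistically detectable,
  while the microglia increase itself is.
* **Expression**: 2000 genes; 120 constructed specific genes per cell type
  (≈8–12× own-type enrichment); bulk TPM is the proportion-weighted mix of
  the reference, times 2^{β·s} for DE genes (|β| ~ Uniform(1.5, 3.5); 90 down
  drawn 70% from neuron-specific genes, 70 up drawn 70% from
  microglia/endothelial-specific genes), times log-normal noise at 20% CV.
* **Sequences**: uniform-random backgrounds; TGCTT and GCTGC planted at 2.5×
  the uniform 4⁻ᵏ frequency in the upstream-intron windows of included-
  direction exons and the downstream-intron windows of excluded-direction
  exons, by overwriting Poisson-many random window positions; exons and a
  1000-event background set are never planted.
* **Molecules**: 200 per sample; with probability ½ a normal-allele
  measurement, units ~ Normal(23, 142) truncated at 0; otherwise (affected
  only) an expanded-allele measurement, units log-normal with median
  400 + 4000·s and log-sd 0.6. Spans are units × 3 bp plus a fixed 10 kb
  reference flank.
* **Streams**: one seed spawns independent child streams per component, so
  requesting molecules does not perturb ψ draws; identical seeds reproduce
  byte-identical outputs.

**What the generator does not emulate** — and hence what passing tests do not
show about real data: realistic sequence composition (uniform background
only), read-level noise and coverage-dependent ψ uncertainty, missing-data
patterns, correlated gene-gene expression beyond the cell-type mixture,
age/sex covariate structure, and any nonlinearity of the dose-response.
Parameter-recovery results for the deconvolution hold under the generator's
log-normal noise, which matches the fitted likelihood; real mismatch between
noise and model will inflate errors. One deliberate, realistic confound is
kept: DE effects are planted on cell-type-specific genes, so deconvolution of
the generated bulk absorbs part of the intrinsic expression change into
proportion shifts — the acceptance script's fitted neuron/microglia q-values
reflect that, while the clean parameter-recovery experiment isolates the
sampler's accuracy.

## Numerical choices and degenerate inputs

* ψ outside [0, 1], duplicate identifiers, unmapped samples, and negative
  spans are hard errors at I/O time; missing ψ is preserved, never imputed.
* Identical groups give Δψ = 0, p = 1; constant events are skipped in
  correlation analyses and logged in the skip counter; empty molecule sets
  yield missing percentile summaries; correlations report NaN on constant
  input rather than raising.
* Bonferroni-adjusted p = min(1, p × 4^k × 5) per direction set; BH is used
  where a false-discovery interpretation is wanted (DE stand-in, proportion
  tests).
* The sampler seed hierarchy derives all child streams from the single run
  seed via `numpy.random.SeedSequence.spawn`; no stage reads global state.
* Problem sizes in the test suite and acceptance script (10–20 seeds for
  Monte-Carlo properties, 29 mixtures at 2000 draws for deconvolution
  recovery, 5–10 label shuffles for FDR) were chosen as the smallest runs
  whose pass/fail criteria have comfortable statistical margins.

## Known limitations

* Covariate-adjusted testing (age/sex) is reporting-only; no model.
* The rank-sum DE stand-in has no dispersion modelling; on real data use a
  dedicated DE tool and feed its table in.
* The deconvolution assumes the reference profiles are correct up to
  multiplicative noise; systematic platform effects between single-cell
  reference and bulk are not modelled.
* Two-sided Fisher tests; one-sided variants would be marginally more
  powerful where the direction is pre-specified.
* The Metropolis sampler is adequate for ≤ ~10 cell types; many more would
  warrant a gradient-based sampler.
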