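# Methods

This note documents the statistical models implemented in `cdk9sig`, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot show about real data.

## Control-anchored normalization

CDK9 inhibition represses essentially all pol II transcription, so any
normalization that assumes most genes are unchanged (total counts,
median-of-ratios over all genes, TMM) is invalid: it would cancel the very
effect under study. Size factors are instead estimated from 31 RNA
pol I/III transcripts (5S rRNA genes, U6 snRNAs, 7SK, 7SL, RMRP, RPPH1,
5.8S rRNA genes), whose synthesis is CDK9-independent.

For each control gene g with no zero count, the per-sample ratio
`counts_gj / GM_g` is formed (`GM_g` = geometric mean across samples);
`s_j` is the **median** of these ratios over control genes, rescaled so the
geometric mean of `s_j` is 1. The median was chosen over the arithmetic
mean for robustness to a single aberrant control transcript; an
arithmetic-mean mode (`method="mean"`) is available for strict replication.
If every control gene has a zero count somewhere, a pseudocount of 0.5 is
added to control rows only (with a logged warning). Control genes are
exempt from the low-expression filter so normalization can never be starved
by filtering.

Precision is limited by control-gene counting noise: with NB dispersion α
the per-gene ratio has CV ≥ √α regardless of depth, so with G controls the
per-sample standard error of `log s_j` is ~`1.25·√(α/G)` for the median
estimator (≈5% at α = 0.05, G = 20). This is a Cramér–Rao-type floor — no
estimator of a per-sample factor can beat `√(α/G)` — so recovery tests
assess the estimator's *expectation* (bias), not single draws.

## Differential expression

Counts follow NB(μ, α) with `Var = μ + αμ²` (α is "the dispersion"
everywhere in this package). Per gene, a GLM with log link, a two-group
indicator and `log s_j` offsets is fitted (statsmodels IRLS) at a fixed
per-gene dispersion; `log2FC = β₁/ln 2`, Wald `z = β₁/SE`, two-sided normal
p-values, Benjamini–Hochberg adjustment.

Dispersion is estimated by method of moments on normalized counts within
each compared group (`α̂ = max(0, (v−μ)/μ²)`, pooled by degrees of
freedom), then shrunk toward a parametric trend `α(μ) = a + b/μ` fitted by
least squares across informative genes: `α = w·trend + (1−w)·raw` with
`w = 0.5` by default. This replaces full empirical-Bayes machinery with a
transparent two-parameter trend; at three samples per arm the shrinkage is
what keeps the Wald test calibrated (the null simulation in the acceptance
tests rejects at 5.0% for nominal 5%). Genes with zero within-group
variance carry no dispersion information and are floored at 1e-8 directly.
No independent filtering, outlier replacement, or fold-change shrinkage is
applied; the ranking fold change is the raw MLE.

Conventions: activation contrasts compare stimulated-untreated against
resting cells; treatment contrasts compare NVP-2-treated against untreated
within a stimulation. Coupling analyses drop genes that are unestimable in
either contrast (count logged). Swapping group labels negates every log2FC
and leaves p-values unchanged (verified to ~1e-7, the IRLS convergence
scale).

## Signature derivation

Repressed set: among genes with FDR < 0.01 and negative log2FC, the 250
with the most negative fold change (fewer if fewer qualify). Insensitive
set: up to 110 genes with |log2FC| ≤ 1e-6, relaxed to nearest-zero
ordering when too few sit exactly at zero — how the original 110-gene set
was frozen is not derivable, so capacity-with-relaxation is the surrogate.
All ties break lexicographically on gene id, making the derivation
deterministic. The pol I/III normalization anchors are excluded from the
insensitive set: their zero fold change is forced by the normalization
itself and they are absent from cohort expression platforms.

## Single-sample enrichment (GSVA-style)

Per gene, expression is transformed to a relative-expression statistic by a
Gaussian-kernel smoothed cross-sample CDF with bandwidth `sd/4`
(`z_ij = mean_k Φ((x_ij − x_ik)/h_i)`); this is location-invariant per
gene, and zero-variance genes are flattened to 0 with a warning. Per
sample, genes are ordered by decreasing statistic (ties by gene id) and the
gene at position i (0-based, p genes) receives the symmetric rank weight
`|(p − i) − p/2|`. A random walk accumulates `weight^τ` (τ = 1, normalized
within the set) on set members and `−1/(p − k)` elsewhere; the enrichment
score is the maximum positive deviation plus the minimum negative
deviation, hence ES ∈ [−1, 1]. Kernel, bandwidth divisor, τ, and an
optional log2(x+1) pre-transform for count-scale cohorts are configurable;
the Gaussian kernel is the default for all cohorts. The implementation is
verified against an independent loop-level transcription of this recipe to
1e-9.

One consequence of scoring *relative* ranks deserves emphasis: when a
subset of genes genuinely moves up in some samples, every other gene's rank
is displaced downward in those samples, so even a truly unaffected control
set acquires a small opposite-sign score shift. The artifact shrinks with
the background size (it is ~1% of ranks for a 250-gene signature against a
20,000-gene universe) but it never vanishes; negative-control behavior
should be judged against this floor rather than against exact nullity.

## Preranked GSEA

Rankings use `sign(log2FC)·(−log10 p)` (multiplying by the sign and
dividing by it coincide), p floored at 1e-300, ties broken by gene id.
Hit increments are `|score|^exponent` normalized over in-set genes
(exponent 1 by default; an all-zero plateau falls back to uniform hits),
miss increments uniform; ES is the walk deviation of maximum magnitude.
Significance is an empirical two-sided p from random same-size gene sets
drawn from the ranked universe — the natural null for a preranked analysis,
where no sample labels exist — with minimum attainable p of
`1/(n_permutations + 1)`; no multilevel refinement is attempted. BH is
applied across sets when several are tested. Leading-edge genes are the
members at or before (after, for negative ES) the walk extremum. The
expression universe can first be restricted to genes at ≥1 FPKM in both
the untreated and treated arms (CPM proxy with a logged notice when gene
lengths are unavailable).

## ChIP-seq integration

Coordinates are BED-style 0-based half-open. A peak's distance to a TSS is
0 if the TSS lies inside the peak, else
`min(|TSS − start|, |TSS − (end−1)|)`; distance is strand-agnostic. Each
peak is assigned to the gene minimizing this distance (ties to the
lexicographically smallest gene id). Genes with ≥1 peak at ≤2 kb are
promoter-bound; genes with ≥1 peak at ≥2 kb are enhancer-associated (both
boundaries inclusive). Occupancy at a TSS window is
`RPKM = reads/((window/1000)·(total/10⁶))`; the input channel is subtracted
**after** RPKM conversion — the two channels have different depths, so
subtraction in RPKM space is the scale-consistent order — and negative
differences are retained so downstream correlations stay unbiased.
Occupancy change (stimulated − resting, input-subtracted) is correlated
with treatment log2FC by Spearman rank correlation.

## Cohort scoring and response prediction

Cohorts are scored per sample against the repressed and insensitive sets;
when the design has a `timepoint` column only pre-treatment samples are
used. Group contrasts use the Welch (unequal-variance) t-test — chosen
where plain "unpaired t test" leaves pooling unspecified; a pooled mode is
available. ROC analysis takes **non-responder as the positive class**
(signature enrichment tracks non-response); AUC is computed by the rank
(Mann–Whitney) formulation with average-rank tie handling, which equals the
pair-counting definition exactly, and a threshold sweep over observed
scores gives the curve. Clinical-index association uses Spearman ρ with
pairwise deletion of missing values. All shared genes form the scoring
background (the filtered-universe alternative is unstated upstream and not
applied).

## Synthetic data: what it emulates and what it does not

**Treatment experiment.** NB counts (gamma-Poisson) for five arms —
resting, untreated/NVP-2 × primary stimulation/restimulation — with
log2-uniform baselines (2³–2⁹ mean counts), dispersion 0.05, three samples
per arm, per-sample library factors in [0.5, 2]. ~20% of pol II genes are
activation-induced (log2FC 1–6). NVP-2 applies a uniform −1 log2 shift to
every pol II gene plus an activation-coupled extra term (−0.3·activation
under primary stimulation, −0.5 under restimulation), so repression
correlates with induction and is stronger on restimulation; pol I/III
stand-ins (named after the real anchors so the default control list works)
receive no treatment or activation effect. This is exactly the regime where
control-anchored normalization recovers the truth and total-count
normalization would not. The resting arm exists so the activation contrast
is estimable from data; it can be disabled.

**Cohort.** Log-scale (microarray-like) expression on a 20,000-gene
background — transcriptome scale matters, see the rank-compensation remark
above — with groups HC/responder/non-responder (defaults 20/50/50,
trial-scale). Signature genes shift by `disease_shift` (1 SD) in patients
and an additional `nonresponse_shift` (1 SD) in non-responders; insensitive
genes never shift. A small per-sample heterogeneity (0.25 SD) makes
severity continuous, and clinical indices (Mayo-, PUCAI-,
calprotectin-like) couple to the per-sample shift with strength 0.3,
emulating the weak clinical correlation regime.

**ChIP.** TSS annotations on five synthetic chromosomes, promoter-proximal
peaks for bound genes, and Poisson window counts for resting, stimulated,
and input channels at fixed depth, with a configurable background rate.
Occupancy gains are uniform by default with an implied repression
(`coupling × gain + noise`); alternatively a supplied per-gene repression
profile drives both the gain and the binding probability, which is how the
end-to-end pipeline couples ChIP occupancy to the RNA-seq truth.

Not emulated: read-level artifacts (the generators start at counts), batch
and platform effects across cohorts, gene–gene correlation beyond the
signature shift, dropout structure, paired-sample designs, and single-cell
data. Passing tests therefore demonstrate correctness of the statistical
machinery under the generating assumptions, not robustness to those
real-data complications.

## Problem sizes and numerical choices

Test simulations use 400–2,000 genes at 3 samples per arm for DE (the
coupling analyses use 1,727 and 936-gene strata, the sizes of the
corresponding real analyses), 20,000-gene cohorts at up to 50 samples per
group, and 100-seed sweeps for power/calibration checks. Permutation
counts default to 10,000 for analysis and 200–2,000 in tests. Other
numerical conventions: p-value floor 1e-300 in rankings; dispersion floor
1e-8; GLM non-convergence yields NA rows (counted in logs) rather than
exceptions; all randomness descends from explicit seeds, with the pipeline
deriving per-stage seeds from a single top-level seed via SHA-256 so stages
are individually reproducible; identical configurations reproduce
byte-identical outputs.

## Known limitations

- The dispersion estimator is deliberately simple; at n = 3 per arm its
  per-gene estimates are noisy and accuracy rests on the trend shrinkage.
  Genes with extreme outliers are not down-weighted.
- Wald tests with a normal reference are mildly approximate at these
  sample sizes; the acceptance suite verifies calibration empirically
  rather than assuming it.
- The permutation GSEA p-value resolution is bounded by the permutation
  count; very small p-values saturate at `1/(n_permutations+1)`.
- Single-sample scores are relative within a cohort; scores are not
  comparable across cohorts without the insensitive-set reference, and the
  rank-compensation floor described above bounds how "null" any negative
  control can look.
- ROC/AUC at small cohort sizes is dominated by rank noise (null SD ≈ 0.09
  at 20 vs 20); conclusions at that scale need seed sweeps, which is how
  the tests phrase them.
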