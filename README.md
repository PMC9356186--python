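# cdk9sig

Tools for deriving a CDK9-inhibitor-repressed transcriptional signature from
treated/untreated CD4+ T-cell RNA-seq, integrating it with P-TEFb / T-bet
ChIP-seq occupancy, and scoring IBD patient cohorts to discriminate anti-TNF
responders from non-responders.

## The problem

CDK9 (with cyclin T, forming P-TEFb) phosphorylates RNA polymerase II
serine 2 and licenses transcriptional elongation. Small-molecule CDK9
inhibitors such as NVP-2 globally repress pol II transcription, hitting
activation-induced genes in stimulated CD4+ T cells hardest. Because the
repression is genome-wide, ordinary total-count RNA-seq normalization is
invalid — it would absorb the global shift into the size factors. This
package therefore anchors normalization to 31 RNA pol I / pol III
transcripts (5S rRNA, U6, 7SK, 7SL, RMRP, RPPH1, 5.8S rRNA), whose
synthesis does not require P-TEFb.

The pipeline:

1. **preprocess** — low-expression filter (keep genes with ≥6 counts in ≥3
   samples), control-anchored median-of-ratios size factors `s_j`,
   log2 normalization.
2. **diffexpr** — per-gene negative-binomial GLM
   (`Var = μ + αμ²`, `log μ_gj = log s_j + β₀ + β₁ x_j`), Wald test on β₁,
   Benjamini–Hochberg FDR; activation–repression coupling (Pearson),
   primary-stimulation (PS) vs restimulation (RS) contrasts (Mann–Whitney).
3. **genesets** — the repressed signature: the 250 most-repressed genes at
   FDR < 0.01, plus a 110-gene insensitive control set (|log2FC| ≈ 0);
   GSVA-style single-sample enrichment (Gaussian-kernel cross-sample CDF,
   symmetric rank weights, random-walk statistic, ES ∈ [−1, 1]); preranked
   permutation GSEA on `sign(log2FC)·(−log10 p)` rankings.
4. **chipseq** — peak-to-nearest-TSS assignment (BED, 0-based half-open),
   promoter-bound (≤2 kb) and enhancer-associated (≥2 kb) gene classes,
   TSS-window RPKM with input subtraction, occupancy–repression Spearman.
5. **cohort** — per-patient signature scores, Welch t contrasts between
   clinical groups, ROC prediction of anti-TNF non-response (AUC via the
   rank/Mann–Whitney formulation), Spearman correlation with clinical
   indices (Mayo, PUCAI, fecal calprotectin).
6. **synthetic** — seeded generators for all three data modalities with
   recorded ground truth, used throughout the test suite.

## Worked example

The whole pipeline runs self-contained on synthetic data:

```bash
cdk9sig run --seed 1 --outdir demo_out
cat demo_out/run_report.txt
```

which prints (seed 1, 1000 simulated pol II genes + 31 control stand-ins,
3 samples per arm):

```
n_genes_input = 1031
n_repressed = 250
n_insensitive = 110
signature_precision_vs_truth = 1.0
coupling_rs_pearson_r = -0.9108
ps_rs_mannwhitney_p = 0.017261359118764055
n_bound_genes = 507
occupancy_spearman_rho = -0.4302
gsea_bound_es = -0.7309
gsea_bound_p = 0.001996007984031936
repressed_welch_p = 4.0571840417275513e-35
repressed_auc = 0.9988
```

Reading the report: the derived 250-gene repressed set contains only truly
repressed genes (`precision 1.0`); repression strength tracks activation
strength (`Pearson r = −0.91`); restimulated cells are repressed more than
primary-stimulated ones (Mann–Whitney p = 0.017); genes gaining P-TEFb
occupancy on stimulation are more repressed (`Spearman ρ = −0.43`, bound-set
GSEA p = 0.002); and on the simulated patient cohort the repressed-set score
separates anti-TNF non-responders from responders almost perfectly
(`AUC = 0.999`, Welch p ≈ 4e-35).

Individual stages are also exposed (`cdk9sig simulate | preprocess | de |
signature | score | gsea | chip assign | cohort score | cohort roc`), and
every CLI command is a thin wrapper over an importable function.

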