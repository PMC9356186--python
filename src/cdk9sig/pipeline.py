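"""End-to-end orchestration: preprocess -> DE -> signature -> GSEA -> ChIP -> cohort.

All stages run from a single :class:`PipelineConfig`. When no input paths are
given the synthetic generators supply the data (seeded from the config), so
the full pipeline can run self-contained. Every output is a plain TSV or
key-value text file stamped with the config hash and seed; reruns with the
same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, fields, replace
from pathlib import Path

import pandas as pd

from . import chipseq, cohort as cohort_mod, diffexpr, genesets, preprocess, synthetic

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All stage parameters; defaults are the study's published constants
    (6-count/3-sample filter, FDR 0.01, 250/110 set capacities, 2-kb TSS
    window, FPKM threshold 1, adjusted p < .05)."""

    counts_path: str | None = None
    design_path: str | None = None
    gmt_path: str | None = None
    bed_path: str | None = None
    tss_path: str | None = None
    cohort_expr_path: str | None = None
    cohort_design_path: str | None = None
    outdir: str = "cdk9sig_out"
    seed: int = 1
    # preprocess
    min_count: int = 6
    min_samples: int = 3
    pseudocount: float = 1.0
    size_factor_method: str = "median"
    # differential expression
    shrinkage: float = 0.5
    de_alpha: float = 0.05
    # signature
    n_sig: int = 250
    n_ctrl: int = 110
    fdr_max: float = 0.01
    lfc_min: float = 2.0
    # gene-set scoring
    n_permutations: int = 2000
    weight_exponent: float = 1.0
    tau: float = 1.0
    bandwidth_divisor: float = 4.0
    fpkm_threshold: float = 1.0
    # chip
    window_bp: int = 2000
    enhancer_min_bp: int = 2000
    # synthetic fallbacks
    sim_n_genes: int = 2000
    sim_samples_per_arm: int = 3


def serialize_config(config) -> str:
    """Flat ``key = value`` text; round-trips through parse_config."""
    lines = []
    for f in sorted(fields(config), key=lambda f: f.name):
        v = getattr(config, f.name)
        if isinstance(v, tuple):
            v = ",".join(str(x) for x in v)
        lines.append(f"{f.name} = {v}")
    return "\n".join(lines) + "\n"


def parse_config(text: str, cls=PipelineConfig):
    """Parse a flat key-value config; values are coerced to the field types."""
    raw = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, val = line.partition("=")
        raw[key.strip()] = val.strip()
    kwargs = {}
    for f in fields(cls):
        if f.name not in raw:
            continue
        v = raw[f.name]
        if v in ("None", ""):
            kwargs[f.name] = None
        elif "int" in str(f.type) and "tuple" not in str(f.type):
            kwargs[f.name] = int(v)
        elif "float" in str(f.type) and "tuple" not in str(f.type):
            kwargs[f.name] = float(v)
        elif "bool" in str(f.type):
            kwargs[f.name] = v == "True"
        elif "tuple" in str(f.type):
            kwargs[f.name] = tuple(float(x) for x in v.split(","))
        else:
            kwargs[f.name] = v
    return cls(**kwargs)


def config_hash(config) -> str:
    """Hash of the analysis-relevant parameters (output location excluded)."""
    text = "\n".join(
        line for line in serialize_config(config).splitlines()
        if not line.startswith("outdir ")
    )
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed split below 2**31."""
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig, treatment_sim=None) -> dict:
    """Execute the full pipeline; returns a dict of in-memory results.

    Writes stage TSVs and a key-value run report under ``config.outdir``.
    Any stage failure raises with the stage name prepended. *treatment_sim*
    optionally overrides the synthetic treatment-experiment configuration
    (e.g. a null-effect configuration for calibration runs).
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"config_hash": config_hash(config), "seed": config.seed}
    report: list[tuple[str, object]] = [
        ("config_hash", results["config_hash"]),
        ("seed", config.seed),
    ]

    def stage(name):
        logger.info("pipeline stage: %s", name)
        return name

    try:
        name = stage("inputs")
        truth = None
        if config.counts_path:
            cm = preprocess.read_counts(config.counts_path)
            design = pd.read_csv(config.design_path, sep="\t", index_col=0)
        else:
            sim = treatment_sim or synthetic.TreatmentSimConfig(
                seed=_stage_seed(config.seed, "treatment"),
                n_genes=config.sim_n_genes,
                samples_per_arm=config.sim_samples_per_arm,
            )
            cm, design, truth = synthetic.simulate_treatment_experiment(sim)
        report.append(("n_genes_input", cm.counts.shape[0]))

        name = stage("preprocess")
        filtered = preprocess.filter_low_expression(cm, config.min_count, config.min_samples)
        report.append(("n_genes_after_filter", filtered.counts.shape[0]))
        sf = preprocess.control_size_factors(filtered, method=config.size_factor_method)
        nm = preprocess.normalize_counts(filtered, sf, config.pseudocount)
        preprocess.write_counts(filtered, out / "counts_filtered.tsv")
        preprocess.write_size_factors(sf, out / "size_factors.tsv")
        nm.log2.to_csv(out / "log2_normalized.tsv", sep="\t", index_label="gene")

        name = stage("differential_expression")
        de = {}
        contrasts = [("treatment_ps", "untreated-PS", "NVP2-PS"),
                     ("treatment_rs", "untreated-RS", "NVP2-RS")]
        arms = set(design["arm"])
        if synthetic.UNSTIMULATED_ARM in arms:
            contrasts += [("activation_ps", synthetic.UNSTIMULATED_ARM, "untreated-PS"),
                          ("activation_rs", synthetic.UNSTIMULATED_ARM, "untreated-RS")]
        for key, a, b in contrasts:
            disp = diffexpr.estimate_dispersions(nm, design, a, b, config.shrinkage)
            de[key] = diffexpr.nb_wald_test(nm, design, disp, a, b)
            diffexpr.write_de(de[key], out / f"de_{key}.tsv")
            report.append((f"n_na_{key}", int(de[key]["log2fc"].isna().sum())))
        results["de"] = de

        name = stage("signature")
        sig = genesets.derive_signature(
            de["treatment_rs"], config.n_sig, config.fdr_max, config.n_ctrl,
            provenance="NVP2-RS vs untreated-RS",
            exclude=tuple(filtered.gene_ids[filtered.control_flags]),
        )
        genesets.write_gmt([sig.repressed, sig.insensitive], out / "signature.gmt")
        results["signature"] = sig
        report.append(("n_repressed", len(sig.repressed)))
        report.append(("n_insensitive", len(sig.insensitive)))
        if truth is not None:
            truly_rep = set(
                truth.genes.index[
                    (~truth.genes["is_control"]) & (truth.genes["treatment_lfc_rs"] < -1e-9)
                ]
            )
            members = set(sig.repressed.members)
            prec = len(members & truly_rep) / len(members) if members else float("nan")
            report.append(("signature_precision_vs_truth", round(prec, 4)))
            results["signature_precision"] = prec

        name = stage("coupling")
        if "activation_rs" in de:
            coup = diffexpr.activation_repression_coupling(de["activation_rs"], de["treatment_rs"])
            results["coupling_rs"] = coup
            report.append(("coupling_rs_pearson_r", round(coup.pearson_r, 4)))
        contrast = diffexpr.compare_ps_rs_repression(de["treatment_ps"], de["treatment_rs"])
        results["ps_rs_contrast"] = contrast
        report.append(("ps_rs_mannwhitney_p", contrast.p_value))

        name = stage("chip")
        if config.bed_path:
            peaks = chipseq.read_bed(config.bed_path)
            tss = chipseq.read_tss(config.tss_path)
            occ = None
        else:
            chip_cfg = synthetic.ChipSimConfig(
                seed=_stage_seed(config.seed, "chip"), n_genes=config.sim_n_genes
            )
            # couple occupancy to the simulated repression so the integration
            # stages see the activation-recruitment structure end to end
            rep_lfc = None
            if truth is not None:
                rep_lfc = truth.genes.loc[~truth.genes["is_control"], "treatment_lfc_rs"]
            peaks, tss, occ, _chip_truth = synthetic.simulate_chip(chip_cfg, rep_lfc)
        assignments = chipseq.assign_peaks_to_genes(peaks, tss)
        bound = chipseq.classify_bound_genes(assignments, config.window_bp)
        assignments.to_csv(out / "peak_assignments.tsv", sep="\t", index=False)
        report.append(("n_bound_genes", len(bound)))
        results["bound_genes"] = bound
        if occ is not None:
            occ_table = chipseq.tss_occupancy(occ)
            occ_table.to_csv(out / "tss_occupancy.tsv", sep="\t")
            corr = chipseq.occupancy_repression_correlation(occ_table, de["treatment_rs"])
            results["occupancy_correlation"] = corr
            report.append(("occupancy_spearman_rho", round(corr.rho, 4)))
        if bound:
            gsea_params = genesets.GseaParams(
                weight_exponent=config.weight_exponent,
                n_permutations=config.n_permutations,
                seed=_stage_seed(config.seed, "gsea"),
            )
            ranked = genesets.rank_genes(de["treatment_rs"])
            in_univ = [g for g in bound if g in set(ranked.index)]
            if 0 < len(in_univ) < len(ranked):
                res = genesets.preranked_gsea(
                    ranked, genesets.GeneSet("PTEFb_bound", tuple(in_univ)), gsea_params
                )
                results["gsea_bound"] = res
                report.append(("gsea_bound_es", round(res.es, 4)))
                report.append(("gsea_bound_p", res.p_value))

        name = stage("cohort")
        if len(sig.repressed) == 0:
            logger.warning("cohort stage skipped: repressed signature is empty")
            report.append(("cohort_stage", "skipped (empty repressed set)"))
            (out / "run_report.txt").write_text(
                "".join(f"{k} = {v}\n" for k, v in report)
            )
            (out / "config.txt").write_text(serialize_config(config))
            return results
        if config.cohort_expr_path:
            expr = pd.read_csv(config.cohort_expr_path, sep="\t", index_col=0)
            cdesign = pd.read_csv(config.cohort_design_path, sep="\t", index_col=0)
        else:
            cc = synthetic.CohortSimConfig(
                seed=_stage_seed(config.seed, "cohort"),
                n_genes=config.sim_n_genes,
                signature_ids=tuple(sig.repressed.members) or None,
                insensitive_ids=tuple(sig.insensitive.members),
            )
            if cc.signature_ids is None:
                cc = replace(cc, insensitive_ids=None)
            expr, cdesign, _ctruth = synthetic.simulate_cohort(cc)
        cohort_mod.validate_design(cdesign)
        gsva_params = genesets.GsvaParams(
            bandwidth_divisor=config.bandwidth_divisor, tau=config.tau
        )
        scores = cohort_mod.score_cohort(expr, sig, gsva_params, design=cdesign)
        scores.to_csv(out / "cohort_scores.tsv", sep="\t", index_label="set")
        results["cohort_scores"] = scores
        if "response" in cdesign.columns and cdesign["response"].notna().any():
            test = cohort_mod.group_enrichment_test(
                scores.loc[sig.repressed.name], cdesign, "response",
                "responder", "non-responder",
            )
            roc = cohort_mod.roc_response(
                scores.loc[sig.repressed.name], cdesign["response"]
            )
            roc.curve.to_csv(out / "roc_curve.tsv", sep="\t", index=False)
            results["response_test"] = test
            results["roc"] = roc
            report.append(("repressed_welch_p", test.p_value))
            report.append(("repressed_auc", round(roc.auc, 4)))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    (out / "run_report.txt").write_text(
        "".join(f"{k} = {v}\n" for k, v in report)
    )
    (out / "config.txt").write_text(serialize_config(config))
    return results
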