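"""Signature scoring of patient cohorts and anti-TNF response prediction.

Pre-treatment expression profiles are scored per sample against the
repressed and insensitive gene sets; scores are contrasted between clinical
groups (Welch t-test), used to classify responders vs non-responders (ROC,
positive class = non-responder, since signature enrichment tracks
non-response), and correlated with clinical severity indices (Spearman).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve

from .chipseq import CorrelationResult
from .genesets import GsvaParams, Signature, gsva_scores

logger = logging.getLogger(__name__)

DIAGNOSES = {"HC", "UC", "CD"}
RESPONSES = {"responder", "non-responder"}
REMISSIONS = {"remission", "active"}


@dataclass
class GroupTestResult:
    mean_difference: float
    t_statistic: float
    p_value: float
    n_a: int
    n_b: int


@dataclass
class RocResult:
    auc: float
    curve: pd.DataFrame  # threshold, sensitivity, specificity
    mann_whitney_p: float
    positive_class: str = "non-responder"


def validate_design(design: pd.DataFrame) -> pd.DataFrame:
    """Check label vocabularies; returns the design unchanged."""
    if "diagnosis" in design.columns:
        bad = set(design["diagnosis"].dropna()) - DIAGNOSES
        if bad:
            raise ValueError(f"unknown diagnosis labels: {sorted(bad)}")
    for col, vocab in (("response", RESPONSES), ("remission", REMISSIONS)):
        if col in design.columns:
            bad = set(design[col].dropna()) - vocab
            if bad:
                raise ValueError(f"unknown {col} labels: {sorted(bad)}")
    return design


def score_cohort(
    expr: pd.DataFrame,
    signature: Signature,
    params: GsvaParams | None = None,
    design: pd.DataFrame | None = None,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Per-sample enrichment scores for the repressed and insensitive sets.

    Delegates to :func:`cdk9sig.genesets.gsva_scores` without rescaling.
    When the design carries a ``timepoint`` column only pre-treatment samples
    are scored. Signature genes absent from the cohort are dropped with a
    logged fraction; overlap below *min_overlap* of a set draws a warning,
    zero overlap is an error.
    """
    if design is not None and "timepoint" in design.columns:
        pre = design.index[design["timepoint"] == "pre"]
        kept = expr.columns.intersection(pre)
        logger.info("score_cohort: restricting to %d pre-treatment samples", len(kept))
        expr = expr[kept]
    if expr.shape[1] < 3:
        raise ValueError("cohort must have >= 3 samples")
    for gs in (signature.repressed, signature.insensitive):
        present = sum(g in expr.index for g in gs.members)
        if present == 0:
            raise ValueError(f"set {gs.name!r} has zero overlap with the cohort")
        frac = present / len(gs)
        logger.info("score_cohort: %s overlap %.0f%%", gs.name, 100 * frac)
        if frac < min_overlap:
            logger.warning(
                "score_cohort: set %r overlap %.0f%% below floor %.0f%%",
                gs.name, 100 * frac, 100 * min_overlap,
            )
    return gsva_scores(expr, [signature.repressed, signature.insensitive], params)


def group_enrichment_test(
    scores: pd.Series,
    design: pd.DataFrame,
    column: str,
    group_a: str,
    group_b: str,
    welch: bool = True,
) -> GroupTestResult:
    """Two-sided t-test of per-sample scores between two design groups.

    Welch (unequal variance) by default; ``welch=False`` pools variances.
    Returns mean(group_b) - mean(group_a).
    """
    lab = design[column].reindex(scores.index)
    a = scores[lab == group_a].dropna()
    b = scores[lab == group_b].dropna()
    if len(a) < 2 or len(b) < 2:
        raise ValueError(f"need >= 2 samples per group in {column!r}")
    t, p = stats.ttest_ind(b, a, equal_var=not welch)
    return GroupTestResult(
        mean_difference=float(b.mean() - a.mean()),
        t_statistic=float(t),
        p_value=float(p),
        n_a=len(a),
        n_b=len(b),
    )


def roc_auc_rank(scores: np.ndarray, positive: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank formulation, ties at half weight."""
    ranks = stats.rankdata(scores)  # average ranks handle ties exactly
    n_pos = int(positive.sum())
    n_neg = len(scores) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_response(
    scores: pd.Series,
    labels: pd.Series,
    positive_class: str = "non-responder",
) -> RocResult:
    """ROC analysis of signature scores against anti-TNF response labels.

    Higher score predicts the positive class (non-responder by default).
    AUC uses the rank (Mann-Whitney) formulation with tie correction; the
    accompanying p-value is the two-sided Mann-Whitney test of score
    separation between classes.
    """
    lab = labels.reindex(scores.index)
    ok = scores.notna() & lab.notna()
    s = scores[ok].to_numpy(dtype=float)
    pos = (lab[ok] == positive_class).to_numpy()
    if pos.all() or not pos.any():
        raise ValueError("ROC requires both classes present")
    auc = roc_auc_rank(s, pos)
    if np.ptp(s) == 0:
        mw_p = 1.0
    else:
        _, mw_p = stats.mannwhitneyu(s[pos], s[~pos], alternative="two-sided",
                                     method="asymptotic")
    fpr, tpr, thr = roc_curve(pos.astype(int), s)
    curve = pd.DataFrame({"threshold": thr, "sensitivity": tpr, "specificity": 1 - fpr})
    return RocResult(auc=auc, curve=curve, mann_whitney_p=float(mw_p),
                     positive_class=positive_class)


def clinical_correlation(
    scores: pd.Series, design: pd.DataFrame, score_name: str
) -> CorrelationResult:
    """Spearman correlation of enrichment scores with a clinical index.

    Samples with a missing clinical value are excluded pairwise; all-missing
    is an error.
    """
    if score_name not in design.columns:
        raise ValueError(f"clinical score {score_name!r} not in design")
    clin = design[score_name].reindex(scores.index)
    ok = scores.notna() & clin.notna()
    if ok.sum() == 0:
        raise ValueError(f"clinical score {score_name!r} is missing for all samples")
    if ok.sum() < 3:
        raise ValueError("need >= 3 samples with the clinical score present")
    x, y = scores[ok].to_numpy(), clin[ok].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("clinical correlation: constant vector, rho undefined")
        return CorrelationResult(np.nan, np.nan, int(ok.sum()))
    rho, p = stats.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), int(ok.sum()))
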