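"""Negative-binomial Wald differential expression and activation/repression coupling.

Counts for gene g in sample j are modelled as NB(mu_gj, alpha_g) with
Var = mu + alpha * mu^2 and log mu_gj = log s_j + beta0_g + beta1_g * x_j,
where s_j is the control-anchored size factor (an offset, not a divisor of
the response) and x_j indicates the second group. The Wald statistic
beta1 / SE(beta1) is referred to the standard normal; p-values are adjusted
by Benjamini-Hochberg.

Dispersion is estimated by a method-of-moments estimate pooled within groups,
shrunk toward a parametric mean-dispersion trend alpha(mu) = a + b / mu.
This stabilizes per-gene estimates at the small replicate numbers typical of
these experiments (three donors per arm).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DISPERSION_FLOOR = 1e-8

DE_COLUMNS = ["base_mean", "log2fc", "se", "wald_p", "fdr", "dispersion"]


@dataclass
class CouplingResult:
    """Pearson correlation between activation and treatment fold changes."""

    pearson_r: float
    p_value: float
    n_genes: int


@dataclass
class TwoSampleResult:
    """Mann-Whitney U contrast of two log2FC distributions."""

    u_statistic: float
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    pearson_r: float | None = None
    pearson_p: float | None = None


def _group_samples(design: pd.DataFrame, group: str) -> pd.Index:
    if "arm" not in design.columns:
        raise ValueError("design must have an 'arm' column")
    samples = design.index[design["arm"] == group]
    if len(samples) == 0:
        raise ValueError(f"no samples in group {group!r}")
    return samples


def estimate_dispersions(
    nm,
    design: pd.DataFrame,
    group_a: str,
    group_b: str,
    shrinkage: float = 0.5,
    floor: float = DISPERSION_FLOOR,
) -> pd.Series:
    """Per-gene NB dispersion for the two compared groups.

    Method of moments on size-factor-normalized counts within each group,
    alpha = (var - mean) / mean^2 truncated at zero, pooled across the two
    groups weighted by degrees of freedom, then shrunk toward a fitted
    a + b/mu trend: alpha_hat = w * trend + (1 - w) * raw.
    """
    sa, sb = _group_samples(design, group_a), _group_samples(design, group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    raw = np.zeros(nm.normalized.shape[0])
    wsum = 0.0
    mu_overall = np.zeros_like(raw)
    var_total = np.zeros_like(raw)
    n_groups = 0
    for samples in (sa, sb):
        x = nm.normalized[samples].to_numpy(dtype=float)
        mu = x.mean(axis=1)
        v = x.var(axis=1, ddof=1)
        w = len(samples) - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (v - mu) / mu**2, 0.0)
        raw += w * np.clip(a, 0.0, None)
        wsum += w
        mu_overall += mu
        var_total += v
        n_groups += 1
    raw /= wsum
    mu_overall /= n_groups

    trend = _fit_dispersion_trend(mu_overall, raw)
    alpha = shrinkage * trend + (1.0 - shrinkage) * raw
    # genes with no within-group variability carry no dispersion information
    alpha[var_total == 0] = floor
    alpha = np.maximum(alpha, floor)
    return pd.Series(alpha, index=nm.normalized.index, name="dispersion")


def _fit_dispersion_trend(mu: np.ndarray, raw: np.ndarray) -> np.ndarray:
    """Least-squares fit of alpha(mu) = a + b/mu over informative genes."""
    ok = (mu > 0) & (raw > 0)
    if ok.sum() < 10:
        # too few informative genes: flat trend at the mean raw dispersion
        level = float(raw[ok].mean()) if ok.any() else 0.0
        return np.full_like(raw, level)
    X = np.column_stack([np.ones(ok.sum()), 1.0 / mu[ok]])
    coef, *_ = np.linalg.lstsq(X, raw[ok], rcond=None)
    a, b = np.clip(coef, 0.0, None)
    with np.errstate(divide="ignore"):
        tr = a + b / np.where(mu > 0, mu, np.inf)
    return tr


def nb_wald_test(
    nm,
    design: pd.DataFrame,
    dispersions: pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Per-gene NB GLM Wald test of *group_b* versus *group_a*.

    Returns a DataFrame indexed by gene with columns base_mean, log2fc, se,
    wald_p, fdr, dispersion. log2fc > 0 means higher expression in group_b.
    Genes that cannot be fitted (all-zero counts, non-convergence) get NaN
    rows; their count is logged.
    """
    sa, sb = _group_samples(design, group_a), _group_samples(design, group_b)
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each compared group needs >= 2 samples")
    samples = sa.append(sb)
    y_all = nm.counts[samples].to_numpy(dtype=float)
    offset = np.log(nm.size_factors.loc[samples].to_numpy(dtype=float))
    x = np.concatenate([np.zeros(len(sa)), np.ones(len(sb))])
    X = np.column_stack([np.ones_like(x), x])
    alpha = dispersions.reindex(nm.counts.index).to_numpy(dtype=float)

    n_genes = y_all.shape[0]
    log2fc = np.full(n_genes, np.nan)
    se = np.full(n_genes, np.nan)
    pvals = np.full(n_genes, np.nan)
    base_mean = nm.normalized[samples].mean(axis=1).to_numpy()

    n_failed = 0
    for i in range(n_genes):
        y = y_all[i]
        if y.sum() == 0:
            n_failed += 1
            continue
        a_g = max(float(alpha[i]), DISPERSION_FLOOR)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fam = sm.families.NegativeBinomial(alpha=a_g)
                res = sm.GLM(y, X, family=fam, offset=offset).fit(maxiter=100)
            if not res.converged:
                n_failed += 1
                continue
        except Exception:
            n_failed += 1
            continue
        beta, bse = res.params[1], res.bse[1]
        if not np.isfinite(beta) or not np.isfinite(bse) or bse == 0:
            n_failed += 1
            continue
        log2fc[i] = beta / LN2
        se[i] = bse / LN2
        pvals[i] = 2.0 * stats.norm.sf(abs(beta / bse))
    if n_failed:
        logger.info("nb_wald_test: %d/%d genes unestimable (NA)", n_failed, n_genes)

    fdr = bh_adjust(pd.Series(pvals, index=nm.counts.index)).to_numpy()
    return pd.DataFrame(
        {
            "base_mean": base_mean,
            "log2fc": log2fc,
            "se": se,
            "wald_p": pvals,
            "fdr": fdr,
            "dispersion": alpha,
        },
        index=nm.counts.index.rename("gene"),
    )


def bh_adjust(p: pd.Series | np.ndarray | list) -> pd.Series:
    """Benjamini-Hochberg step-up adjusted p-values; NaNs pass through."""
    s = pd.Series(p, dtype=float) if not isinstance(p, pd.Series) else p.astype(float)
    valid = s.notna()
    vals = s[valid].to_numpy()
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    out = pd.Series(np.nan, index=s.index, name="fdr")
    if valid.any():
        out[valid] = multipletests(vals, method="fdr_bh")[1]
    return out


def activation_induced_genes(
    de_activation: pd.DataFrame, lfc_min: float = 2.0, fdr_max: float = 0.01
) -> list[str]:
    """Genes induced by stimulation: log2FC >= lfc_min and FDR < fdr_max."""
    sel = (de_activation["log2fc"] >= lfc_min) & (de_activation["fdr"] < fdr_max)
    return list(de_activation.index[sel.fillna(False)])


def activation_repression_coupling(
    de_activation: pd.DataFrame, de_treatment: pd.DataFrame
) -> CouplingResult:
    """Pearson correlation between activation log2FC and treatment log2FC.

    Genes with NaN in either contrast are dropped (logged). A constant
    vector makes r undefined; NaN is returned with a warning.
    """
    shared = de_activation.index.intersection(de_treatment.index)
    if len(shared) < 3:
        raise ValueError("fewer than 3 shared genes")
    a = de_activation.loc[shared, "log2fc"]
    t = de_treatment.loc[shared, "log2fc"]
    ok = a.notna() & t.notna()
    n_drop = int((~ok).sum())
    if n_drop:
        logger.info("coupling: dropped %d genes with NA fold changes", n_drop)
    a, t = a[ok].to_numpy(), t[ok].to_numpy()
    if len(a) < 3:
        raise ValueError("fewer than 3 genes after NA removal")
    if np.ptp(a) == 0 or np.ptp(t) == 0:
        logger.warning("coupling: constant fold-change vector, correlation undefined")
        return CouplingResult(np.nan, np.nan, len(a))
    r, p = stats.pearsonr(a, t)
    return CouplingResult(float(r), float(p), len(a))


def compare_ps_rs_repression(
    de_ps: pd.DataFrame, de_rs: pd.DataFrame, genes=None
) -> TwoSampleResult:
    """Contrast NVP-2 repression during primary vs secondary stimulation.

    Mann-Whitney U (two-sided, normal approximation with tie correction) on
    the treatment log2FC distributions of *genes* in the two contrasts, plus
    the paired Pearson correlation over the shared genes.
    """
    if genes is None:
        genes = de_ps.index.intersection(de_rs.index)
    genes = pd.Index(genes)
    x = de_ps.loc[genes.intersection(de_ps.index), "log2fc"].dropna()
    y = de_rs.loc[genes.intersection(de_rs.index), "log2fc"].dropna()
    if len(x) == 0 or len(y) == 0:
        raise ValueError("gene set does not overlap both DE results")
    u, p = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    shared = x.index.intersection(y.index)
    r = rp = None
    if len(shared) >= 3 and np.ptp(x.loc[shared]) > 0 and np.ptp(y.loc[shared]) > 0:
        r, rp = (float(v) for v in stats.pearsonr(x.loc[shared], y.loc[shared]))
    return TwoSampleResult(
        u_statistic=float(u),
        p_value=float(p),
        median_a=float(x.median()),
        median_b=float(y.median()),
        n_a=len(x),
        n_b=len(y),
        pearson_r=r,
        pearson_p=rp,
    )


def write_de(de: pd.DataFrame, path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


def read_de(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene")
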