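"""Gene sets, signature derivation, single-sample enrichment, preranked GSEA.

The repressed signature is the set of genes most strongly down-regulated by
the CDK9 inhibitor NVP-2 (ranked by fold change among genes at FDR < 0.01,
capacity 250 by default); the insensitive control set collects genes whose
log2 fold change is (closest to) zero (capacity 110). Patient samples are
scored per gene set with a GSVA-style statistic: a Gaussian-kernel smoothed
cross-sample CDF turns each gene's expression into a relative-expression
value, genes are ranked per sample, and a weighted Kolmogorov-Smirnov-like
random walk over the ranking yields an enrichment score in [-1, 1] (positive:
set members concentrate at the top of the sample's expression ranking).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .diffexpr import bh_adjust

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # keeps -log10(p) finite in ranking scores


@dataclass(frozen=True)
class GeneSet:
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


@dataclass(frozen=True)
class Signature:
    """Repressed gene set plus insensitive (negative-control) gene set."""

    repressed: GeneSet
    insensitive: GeneSet
    provenance: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.repressed.members) & set(self.insensitive.members)
        if overlap:
            raise ValueError(f"repressed/insensitive sets overlap: {sorted(overlap)[:5]}")


@dataclass
class GseaParams:
    weight_exponent: float = 1.0
    n_permutations: int = 10_000
    seed: int = 0
    expression_filter_threshold: float = 1.0

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be >= 0")
        if self.n_permutations < 100:
            raise ValueError("n_permutations must be >= 100")


@dataclass
class GsvaParams:
    kernel: str = "gaussian"  # or "ecdf"
    bandwidth_divisor: float = 4.0
    tau: float = 1.0
    log_transform: bool = False  # log2(x+1) the matrix first (count-scale cohorts)

    def __post_init__(self) -> None:
        if self.bandwidth_divisor <= 0:
            raise ValueError("bandwidth_divisor must be > 0")
        if self.kernel not in ("gaussian", "ecdf"):
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass
class EnrichmentResult:
    name: str
    es: float
    p_value: float
    n_permutations: int
    set_size: int
    leading_edge: list[str]


def read_gmt(path) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: GMT line needs name, description, members")
            sets.append(GeneSet(fields[0], tuple(g for g in fields[2:] if g)))
    return sets


def write_gmt(sets: list[GeneSet], path, description: str = "cdk9sig") -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, description, *s.members]) + "\n")


def derive_signature(
    de: pd.DataFrame,
    n_sig: int = 250,
    fdr_max: float = 0.01,
    n_ctrl: int = 110,
    zero_tol: float = 1e-6,
    provenance: str = "",
    exclude=(),
) -> Signature:
    """Derive repressed and insensitive gene sets from a treatment DE table.

    Repressed: among genes with FDR < fdr_max and negative log2FC, the n_sig
    with the most negative fold change (fewer if fewer qualify). Insensitive:
    up to n_ctrl genes with |log2FC| <= zero_tol; if fewer qualify the set is
    filled by nearest-to-zero ordering. Ties break lexicographically on gene
    id so the derivation is fully deterministic. *exclude* lists gene ids
    barred from either set — typically the pol I/III normalization anchors,
    whose zero fold change is a consequence of the normalization itself.
    """
    d = de.dropna(subset=["log2fc", "fdr"]).copy()
    if len(exclude):
        d = d.drop(index=[g for g in exclude if g in d.index])
    d = d.sort_index()  # lexicographic gene-id baseline for tie-breaking

    passing = d[(d["fdr"] < fdr_max) & (d["log2fc"] < 0)]
    order = np.lexsort((passing.index.to_numpy(), passing["log2fc"].to_numpy()))
    repressed_ids = tuple(passing.index.to_numpy()[order][:n_sig])
    if len(repressed_ids) == 0:
        logger.warning("derive_signature: no gene passes FDR < %g; empty repressed set", fdr_max)

    pool = d.drop(index=list(repressed_ids))
    absfc = pool["log2fc"].abs()
    exact = pool[absfc <= zero_tol]
    order = np.lexsort((exact.index.to_numpy(), exact["log2fc"].abs().to_numpy()))
    insens_ids = list(exact.index.to_numpy()[order][:n_ctrl])
    if len(insens_ids) < n_ctrl:
        rest = pool.drop(index=insens_ids)
        order = np.lexsort((rest.index.to_numpy(), rest["log2fc"].abs().to_numpy()))
        insens_ids += list(rest.index.to_numpy()[order][: n_ctrl - len(insens_ids)])

    return Signature(
        repressed=GeneSet("NVP2_repressed", repressed_ids),
        insensitive=GeneSet("NVP2_insensitive", tuple(insens_ids)),
        provenance=provenance,
    )


def _kernel_cdf(expr: np.ndarray, params: GsvaParams) -> np.ndarray:
    """Per-gene cross-sample relative-expression statistic (genes x samples).

    Gaussian kernel: z_ij = mean_k Phi((x_ij - x_ik) / h_i), h_i = sd_i / D.
    Location-invariant per gene by construction. Zero-variance genes get a
    flat statistic of 0 (warned), so they cannot drive any walk.
    """
    p, n = expr.shape
    z = np.empty_like(expr, dtype=float)
    if params.kernel == "ecdf":
        for i in range(p):
            x = expr[i]
            z[i] = (x[:, None] >= x[None, :]).mean(axis=1)
        return z
    sd = expr.std(axis=1, ddof=1)
    flat = sd == 0
    if flat.any():
        logger.warning("gsva: %d zero-variance genes, statistic set to 0", int(flat.sum()))
    h = np.where(flat, 1.0, sd / params.bandwidth_divisor)
    chunk = max(1, int(4e6 // (n * n)))
    for lo in range(0, p, chunk):
        hi = min(lo + chunk, p)
        diff = (expr[lo:hi, :, None] - expr[lo:hi, None, :]) / h[lo:hi, None, None]
        z[lo:hi] = special.ndtr(diff).mean(axis=2)
    z[flat] = 0.0
    return z


def gsva_scores(
    expr: pd.DataFrame,
    sets: list[GeneSet],
    params: GsvaParams | None = None,
) -> pd.DataFrame:
    """GSVA-style per-sample enrichment scores (gene sets x samples).

    For each sample, genes are ordered by decreasing relative-expression
    statistic (ties broken by gene id) and assigned a symmetric rank score
    |rank - p/2|; the walk accumulates |rank score|^tau (normalized within
    the set) on set members and a uniform penalty elsewhere. The enrichment
    score is the maximum positive deviation plus the minimum negative
    deviation of the walk, hence lies in [-1, 1]. Deterministic.
    """
    params = params or GsvaParams()
    if expr.shape[1] < 3:
        raise ValueError("gsva_scores needs >= 3 samples for cross-sample CDFs")
    if expr.index.duplicated().any():
        raise ValueError("duplicate gene ids in expression matrix")
    x = expr.to_numpy(dtype=float)
    if params.log_transform:
        x = np.log2(x + 1.0)
    p, n = x.shape
    z = _kernel_cdf(x, params)

    # gene-id codes for deterministic tie-breaking
    id_codes = np.argsort(np.argsort(expr.index.to_numpy()))
    # decreasing-statistic order per sample; ties by ascending gene id
    orders = np.empty((n, p), dtype=np.intp)
    for j in range(n):
        orders[j] = np.lexsort((id_codes, -z[:, j]))
    # symmetric rank score: position i (0-based) in decreasing order
    rank_score = np.abs((p - np.arange(p, dtype=float)) - p / 2.0)

    index_of = {g: i for i, g in enumerate(expr.index)}
    scores = np.full((len(sets), n), np.nan)
    for si, gs in enumerate(sets):
        idx = [index_of[g] for g in gs.members if g in index_of]
        if not idx:
            logger.warning("gsva: set %r has no overlap with expression matrix", gs.name)
            continue
        mask = np.zeros(p, dtype=bool)
        mask[idx] = True
        k = len(idx)
        if k == p:
            raise ValueError(f"set {gs.name!r} covers the whole gene universe")
        for j in range(n):
            o = orders[j]
            m = mask[o]
            w = np.where(m, rank_score**params.tau, 0.0)
            sw = w.sum()
            steps = np.where(m, w / sw if sw > 0 else 1.0 / k, -1.0 / (p - k))
            walk = np.cumsum(steps)
            scores[si, j] = max(walk.max(), 0.0) + min(walk.min(), 0.0)
    return pd.DataFrame(scores, index=[s.name for s in sets], columns=expr.columns)


def rank_genes(de: pd.DataFrame) -> pd.Series:
    """Ranking metric sign(log2FC) * (-log10 p), sorted descending.

    Ties (including the zero-fold-change plateau) break lexicographically on
    gene id for determinism. NaN rows are dropped.
    """
    d = de.dropna(subset=["log2fc", "wald_p"])
    score = np.sign(d["log2fc"]) * (-np.log10(np.maximum(d["wald_p"], P_FLOOR)))
    order = np.lexsort((d.index.to_numpy(), -score.to_numpy()))
    return pd.Series(score.to_numpy()[order], index=d.index.to_numpy()[order], name="rank_score")


def _gsea_walk(w: np.ndarray, mask: np.ndarray, n_miss: int) -> np.ndarray:
    sw = w[mask].sum()
    # all-zero in-set weights (e.g. p=0 plateau): fall back to equal hits
    hits = w / sw if sw > 0 else np.full_like(w, 1.0 / mask.sum())
    return np.cumsum(np.where(mask, hits, -1.0 / n_miss))


def preranked_gsea(
    ranked: pd.Series,
    gene_set: GeneSet,
    params: GseaParams | None = None,
    rng: np.random.Generator | None = None,
) -> EnrichmentResult:
    """Weighted KS enrichment of *gene_set* in a descending ranked list.

    Hit increments are proportional to |score|^p normalized over in-set genes;
    miss increments are uniform. ES is the walk deviation of maximum
    magnitude. The empirical two-sided p-value comes from random same-size
    gene sets drawn from the ranked universe (minimum attainable p is
    1/(n_permutations + 1)). Leading-edge genes are the set members at or
    before (after, for negative ES) the walk extremum.
    """
    params = params or GseaParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    genes = ranked.index.to_numpy()
    scores = ranked.to_numpy(dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("ranking scores must be finite")
    in_univ = np.isin(genes, list(gene_set.members))
    k = int(in_univ.sum())
    n = len(genes)
    if len(gene_set) > n:
        raise ValueError("gene set larger than ranked universe")
    if k == 0:
        raise ValueError(f"set {gene_set.name!r} does not intersect the ranked universe")
    if k == n:
        raise ValueError("gene set covers the whole ranked universe")

    w = np.abs(scores) ** params.weight_exponent
    walk = _gsea_walk(w, in_univ, n - k)
    peak = int(np.argmax(np.abs(walk)))
    es = float(walk[peak])

    # permutation null: random same-size sets from the universe
    abs_perm = np.empty(params.n_permutations)
    chunk = max(1, int(5e6 // n))
    done = 0
    miss_step = -1.0 / (n - k)
    while done < params.n_permutations:
        b = min(chunk, params.n_permutations - done)
        masks = np.zeros((b, n), dtype=bool)
        for r in range(b):
            masks[r, rng.choice(n, size=k, replace=False)] = True
        wmat = np.where(masks, w[None, :], 0.0)
        sw = wmat.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            steps = np.where(masks, wmat / sw, miss_step)
        zero_sw = (sw[:, 0] == 0)
        if zero_sw.any():
            steps[zero_sw] = np.where(masks[zero_sw], 1.0 / k, miss_step)
        walks = np.cumsum(steps, axis=1)
        abs_perm[done : done + b] = np.abs(walks).max(axis=1)
        done += b
    p_emp = (1.0 + np.sum(abs_perm >= abs(es) - 1e-12)) / (params.n_permutations + 1.0)

    if es >= 0:
        le_idx = np.flatnonzero(in_univ[: peak + 1])
    else:
        le_idx = peak + np.flatnonzero(in_univ[peak:])
    return EnrichmentResult(
        name=gene_set.name,
        es=es,
        p_value=float(p_emp),
        n_permutations=params.n_permutations,
        set_size=k,
        leading_edge=list(genes[le_idx]),
    )


def preranked_gsea_multi(
    ranked: pd.Series, sets: list[GeneSet], params: GseaParams | None = None
) -> pd.DataFrame:
    """Run preranked GSEA over several sets; BH-adjust across them."""
    params = params or GseaParams()
    rng = np.random.default_rng(params.seed)
    rows = [preranked_gsea(ranked, s, params, rng=rng) for s in sets]
    df = pd.DataFrame(
        {
            "es": [r.es for r in rows],
            "p_value": [r.p_value for r in rows],
            "set_size": [r.set_size for r in rows],
            "leading_edge_size": [len(r.leading_edge) for r in rows],
        },
        index=pd.Index([r.name for r in rows], name="set"),
    )
    df["fdr"] = bh_adjust(df["p_value"]).to_numpy()
    return df


def expression_filter(
    counts: pd.DataFrame,
    untreated_samples,
    treated_samples,
    gene_lengths: pd.Series | None = None,
    threshold: float = 1.0,
) -> pd.Index:
    """Restrict to genes expressed in both the untreated and treated arms.

    Expression is FPKM when gene lengths are available (library size = total
    counts per sample); otherwise counts-per-million are used as a proxy, with
    a logged notice. A gene is kept when its arm-mean expression is >=
    *threshold* in the untreated AND the treated arm.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    totals = counts.sum(axis=0)
    per_million = counts / (totals / 1e6)
    if gene_lengths is not None:
        expr = per_million.div(gene_lengths.reindex(counts.index) / 1e3, axis=0)
    else:
        logger.info("expression_filter: no gene lengths; using CPM proxy for FPKM")
        expr = per_million
    keep = (expr[list(untreated_samples)].mean(axis=1) >= threshold) & (
        expr[list(treated_samples)].mean(axis=1) >= threshold
    )
    return counts.index[keep]


def gene_set_fc_comparison(
    de: pd.DataFrame, set_a: GeneSet, set_b: GeneSet
):
    """Mann-Whitney U contrast of log2FC between two fixed gene sets."""
    from .diffexpr import TwoSampleResult

    a = de.loc[de.index.intersection(list(set_a.members)), "log2fc"].dropna()
    b = de.loc[de.index.intersection(list(set_b.members)), "log2fc"].dropna()
    if len(a) == 0 or len(b) == 0:
        raise ValueError("gene set does not intersect the DE result")
    pooled = np.concatenate([a, b])
    if np.ptp(pooled) == 0:
        u, p = len(a) * len(b) / 2.0, 1.0
    else:
        u, p = (float(v) for v in stats.mannwhitneyu(a, b, alternative="two-sided",
                                                     method="asymptotic"))
    return TwoSampleResult(
        u_statistic=float(u), p_value=float(p),
        median_a=float(a.median()), median_b=float(b.median()),
        n_a=len(a), n_b=len(b),
    )
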