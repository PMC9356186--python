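"""Peak-to-TSS assignment, promoter/enhancer classification, TSS occupancy.

Coordinates are BED-style throughout: 0-based, half-open intervals
[start, end). A peak's distance to a TSS is 0 when the TSS falls inside the
peak, otherwise the distance from the nearest occupied base,
min(|TSS - start|, |TSS - (end-1)|). Distance is strand-agnostic; strand is
carried for interface completeness only.

Genes with at least one peak within 2 kb of their TSS are "bound"
(promoter-proximal); genes with at least one peak >= 2 kb away are
"enhancer-associated". Occupancy at a TSS window is quantified as RPKM
(reads / (window kb x million aligned reads)); the input-channel RPKM is
subtracted afterwards and may leave negative values, which are retained so
downstream correlations stay unbiased.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]
TSS_COLUMNS = ["gene", "chrom", "tss_position", "strand"]


@dataclass
class OccupancyCounts:
    """Per-gene TSS-window read counts per channel, with per-channel totals."""

    counts: pd.DataFrame  # genes x channels (e.g. resting, stimulated, input)
    totals: dict[str, int]  # total aligned reads per channel
    window_bp: int


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(BED_COLUMNS)]
    df.columns = BED_COLUMNS[: df.shape[1]]
    _validate_intervals(df)
    return df


def write_bed(peaks: pd.DataFrame, path) -> None:
    _validate_intervals(peaks)
    cols = [c for c in BED_COLUMNS if c in peaks.columns]
    peaks[cols].to_csv(path, sep="\t", header=False, index=False)


def _validate_intervals(df: pd.DataFrame) -> None:
    if (df["start"] < 0).any() or (df["start"] >= df["end"]).any():
        raise ValueError("invalid interval: need 0 <= start < end")
    if (df["chrom"].astype(str) == "").any():
        raise ValueError("empty chromosome name")


def read_tss(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TSS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing TSS columns {sorted(missing)}")
    if df["gene"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene ids in TSS table")
    if not df["strand"].isin(["+", "-"]).all():
        raise ValueError(f"{path}: strand must be '+' or '-'")
    return df


def write_tss(tss: pd.DataFrame, path) -> None:
    tss[TSS_COLUMNS].to_csv(path, sep="\t", index=False)


def assign_peaks_to_genes(peaks: pd.DataFrame, tss: pd.DataFrame) -> pd.DataFrame:
    """Assign each peak to the gene with the nearest TSS on its chromosome.

    Returns the peak table with ``gene`` and ``distance`` columns appended.
    Ties break lexicographically on gene id; peaks on chromosomes without
    any TSS keep ``gene = NaN``.
    """
    if len(tss) == 0:
        raise ValueError("empty TSS annotation")
    peaks = peaks.reset_index(drop=True).copy()
    peaks["gene"] = pd.NA
    peaks["distance"] = np.nan
    for chrom, pk in peaks.groupby("chrom"):
        t = tss[tss["chrom"] == chrom]
        if len(t) == 0:
            continue
        t = t.sort_values("gene", kind="stable")
        pos = t["tss_position"].to_numpy(dtype=np.int64)
        start = pk["start"].to_numpy(dtype=np.int64)[:, None]
        last = (pk["end"].to_numpy(dtype=np.int64) - 1)[:, None]
        d = np.minimum(np.abs(pos[None, :] - start), np.abs(pos[None, :] - last))
        inside = (pos[None, :] >= start) & (pos[None, :] <= last)
        d = np.where(inside, 0, d)
        best = d.argmin(axis=1)  # first minimum = smallest gene id on ties
        peaks.loc[pk.index, "gene"] = t["gene"].to_numpy()[best]
        peaks.loc[pk.index, "distance"] = d[np.arange(len(pk)), best]
    return peaks


def classify_bound_genes(assignments: pd.DataFrame, window_bp: int = 2000) -> list[str]:
    """Genes with >= 1 assigned peak within *window_bp* of the TSS (inclusive)."""
    ok = assignments.dropna(subset=["gene"])
    sel = ok[ok["distance"] <= window_bp]
    return sorted(sel["gene"].unique())


def classify_enhancer_genes(assignments: pd.DataFrame, min_bp: int = 2000) -> list[str]:
    """Genes with >= 1 assigned peak at distance >= *min_bp* from the TSS."""
    ok = assignments.dropna(subset=["gene"])
    sel = ok[ok["distance"] >= min_bp]
    return sorted(sel["gene"].unique())


def tss_occupancy(
    occ: OccupancyCounts,
    stimulated: str = "stimulated",
    resting: str = "resting",
    input_channel: str = "input",
) -> pd.DataFrame:
    """RPKM occupancy per gene and channel, input-subtracted, with delta.

    rpkm = reads / ((window_bp / 1000) * (total / 1e6)). The input RPKM is
    subtracted from each ChIP channel (may go negative; not clamped).
    delta_occupancy = stimulated - resting input-subtracted RPKM.
    """
    if occ.window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    out = pd.DataFrame(index=occ.counts.index.rename("gene"))
    kb = occ.window_bp / 1000.0
    rpkm = {}
    for ch in occ.counts.columns:
        total = occ.totals[ch]
        if total <= 0:
            raise ValueError(f"channel {ch!r} has zero total aligned reads")
        if (occ.counts[ch] < 0).any():
            raise ValueError(f"negative read counts in channel {ch!r}")
        rpkm[ch] = occ.counts[ch] / (kb * (total / 1e6))
        out[f"reads_{ch}"] = occ.counts[ch]
        out[f"rpkm_{ch}"] = rpkm[ch]
    for ch in (resting, stimulated):
        out[f"rpkm_sub_{ch}"] = rpkm[ch] - rpkm[input_channel]
    out["delta_occupancy"] = out[f"rpkm_sub_{stimulated}"] - out[f"rpkm_sub_{resting}"]
    return out


def occupancy_repression_correlation(
    occupancy: pd.DataFrame, de: pd.DataFrame
) -> CorrelationResult:
    """Spearman rho between stimulation-induced occupancy change and NVP-2 log2FC."""
    shared = occupancy.index.intersection(de.index)
    d = pd.DataFrame(
        {"delta": occupancy.loc[shared, "delta_occupancy"],
         "lfc": de.loc[shared, "log2fc"]}
    ).dropna()
    if len(d) < 3:
        raise ValueError("fewer than 3 shared genes")
    if np.ptp(d["delta"]) == 0 or np.ptp(d["lfc"]) == 0:
        logger.warning("occupancy correlation: constant vector, rho undefined")
        return CorrelationResult(np.nan, np.nan, len(d))
    rho, p = stats.spearmanr(d["delta"], d["lfc"])
    return CorrelationResult(float(rho), float(p), len(d))


def bound_gene_repression_contrast(
    bound_genes, de_ps: pd.DataFrame, de_rs: pd.DataFrame
):
    """Mann-Whitney U on NVP-2 log2FC of bound genes, PS arm vs RS arm."""
    from .diffexpr import compare_ps_rs_repression

    bound = pd.Index(bound_genes)
    if len(bound.intersection(de_ps.index)) == 0 or len(bound.intersection(de_rs.index)) == 0:
        raise ValueError("bound gene set does not intersect both DE results")
    return compare_ps_rs_repression(de_ps, de_rs, genes=bound)
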