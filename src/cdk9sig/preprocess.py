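"""Count-matrix ingestion, low-expression filtering, and control-anchored normalization.

Under global RNA polymerase II repression (as induced by CDK9 inhibitors),
total-count normalization is invalid: it would absorb the genuine genome-wide
shift into the size factors. Normalization is therefore anchored to RNA pol I
and pol III transcripts (5S rRNA, U6, 7SK, 7SL, RMRP, RPPH1, 5.8S rRNA),
whose synthesis does not require P-TEFb and is unaffected by CDK9 inhibition.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: RNA pol I / pol III transcripts used as normalization anchors.
DEFAULT_CONTROL_TRANSCRIPTS: tuple[str, ...] = (
    "RNA5S12", "RNA5S11", "RNA5S3", "RNA5S1", "RNA5S5", "RNA5S10",
    "RNA5S8", "RNA5S17", "RNA5S4", "RNA5S6", "RNA5S9", "RNA5S14",
    "RNA5S2", "RNU6-7", "RNA5S15", "RN7SK", "RNA5S16", "RNU6-8",
    "RNA5S7", "RNA5S13", "RNU6-1", "RNU6-2", "RNU6-9", "RMRP",
    "RN7SL2", "RNA5-8SN3", "RN7SL1", "RPPH1", "RNA5-8SN1", "RNA5-8SN2",
    "RN7SL3",
)


class FormatError(ValueError):
    """Malformed input file (duplicate ids, negative or non-integer counts)."""


class NormalizationError(ValueError):
    """Size factors cannot be estimated from the available control genes."""


class DegenerateInputError(ValueError):
    """An operation produced an empty or otherwise unusable result."""


@dataclass
class CountMatrix:
    """Gene x sample integer count matrix with control-gene flags.

    Parameters
    ----------
    counts
        Non-negative integer counts, genes as rows, samples as columns.
    control_flags
        Boolean per gene; True marks pol I/III normalization anchors.
    gene_lengths
        Optional per-gene length in bp (needed for FPKM filtering).
    """

    counts: pd.DataFrame
    control_flags: pd.Series
    gene_lengths: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id: {dup!r}")
        if (self.counts.to_numpy() < 0).any():
            raise FormatError("negative counts present")
        self.control_flags = self.control_flags.reindex(self.counts.index)
        if self.control_flags.isna().any():
            raise ValueError("control_flags must cover every gene")
        self.control_flags = self.control_flags.astype(bool)

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def subset_genes(self, genes: pd.Index) -> "CountMatrix":
        lengths = None if self.gene_lengths is None else self.gene_lengths.loc[genes]
        return CountMatrix(self.counts.loc[genes], self.control_flags.loc[genes], lengths)


@dataclass
class NormalizedMatrix:
    """Size-factor normalized counts plus their log2 transform.

    Carries the raw counts and size factors so downstream NB GLMs can work on
    counts with ``log(s_j)`` offsets, which is the statistically correct use
    of the normalization.
    """

    normalized: pd.DataFrame
    log2: pd.DataFrame
    counts: pd.DataFrame
    size_factors: pd.Series
    control_flags: pd.Series
    gene_lengths: pd.Series | None = None
    pseudocount: float = 1.0


def read_counts(
    path,
    control_list: tuple[str, ...] | list[str] = DEFAULT_CONTROL_TRANSCRIPTS,
    lengths: pd.Series | None = None,
) -> CountMatrix:
    """Read a gene x sample counts TSV (first column gene ids) into a CountMatrix.

    Control flags are set by exact symbol match against *control_list*.
    Raises :class:`FormatError` on duplicate ids or negative/non-integer counts,
    naming the offending row/column.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate gene id {dup!r}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric count column")
    bad = np.argwhere((arr < 0) | (arr != np.floor(arr)))
    if bad.size:
        i, j = bad[0]
        raise FormatError(
            f"{path}: invalid count {arr[i, j]!r} at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r} (must be a non-negative integer)"
        )
    flags = pd.Series(df.index.isin(set(control_list)), index=df.index)
    return CountMatrix(df.astype(np.int64), flags, lengths)


def write_counts(m: CountMatrix, path) -> None:
    m.counts.to_csv(path, sep="\t", index_label="gene")


def filter_low_expression(
    m: CountMatrix, min_count: int = 6, min_samples: int = 3
) -> CountMatrix:
    """Drop lowly expressed genes: keep genes with >= *min_count* counts in
    >= *min_samples* samples.

    Control (pol I/III) genes are exempt, so the normalization anchors can
    never be starved by the filter. Gene order is preserved. Raises
    :class:`DegenerateInputError` if nothing survives.
    """
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    enough = (m.counts >= min_count).sum(axis=1) >= min_samples
    keep = enough | m.control_flags
    if not keep.any():
        raise DegenerateInputError("low-expression filter removed every gene")
    out = m.subset_genes(m.gene_ids[keep])
    logger.info("low-expression filter: kept %d/%d genes", keep.sum(), len(keep))
    return out


def control_size_factors(m: CountMatrix, method: str = "median") -> pd.Series:
    """Per-sample size factors from the control (pol I/III) transcripts.

    For each control gene g with no zero count, the per-sample ratio
    counts_gj / GM_g is formed (GM_g the geometric mean of g across samples);
    s_j is the median of these ratios over control genes (``method="mean"``
    gives the arithmetic mean instead). Factors are rescaled so their
    geometric mean is 1. If every control gene has a zero somewhere, a 0.5
    pseudocount is added to control rows only (logged) before retrying.
    """
    if method not in ("median", "mean"):
        raise ValueError(f"unknown method {method!r}")
    ctrl = m.counts.loc[m.control_flags].to_numpy(dtype=float)
    if ctrl.shape[0] == 0:
        raise NormalizationError("no control genes present")
    usable = (ctrl > 0).all(axis=1)
    if not usable.any():
        if (ctrl.sum(axis=1) == 0).all():
            raise NormalizationError("all control genes have zero counts")
        logger.warning(
            "every control gene has a zero count; adding pseudocount 0.5 "
            "to control rows for size-factor estimation"
        )
        ctrl = ctrl + 0.5
        usable = np.ones(ctrl.shape[0], dtype=bool)
    ctrl = ctrl[usable]
    log_gm = np.mean(np.log(ctrl), axis=1, keepdims=True)
    ratios = ctrl / np.exp(log_gm)
    s = np.median(ratios, axis=0) if method == "median" else np.mean(ratios, axis=0)
    s = s / math.exp(np.mean(np.log(s)))
    return pd.Series(s, index=m.sample_ids, name="size_factor")


def normalize_counts(
    m: CountMatrix, size_factors: pd.Series, pseudocount: float = 1.0
) -> NormalizedMatrix:
    """Divide each sample by its size factor; log2(normalized + pseudocount)."""
    if not size_factors.index.equals(m.sample_ids):
        if set(size_factors.index) != set(m.sample_ids):
            raise ValueError("size factors do not match sample ids")
        size_factors = size_factors.loc[m.sample_ids]
    if (size_factors <= 0).any():
        raise ValueError("size factors must be positive")
    norm = m.counts / size_factors
    return NormalizedMatrix(
        normalized=norm,
        log2=np.log2(norm + pseudocount),
        counts=m.counts,
        size_factors=size_factors,
        control_flags=m.control_flags,
        gene_lengths=m.gene_lengths,
        pseudocount=pseudocount,
    )


def write_size_factors(s: pd.Series, path) -> None:
    s.rename("factor").rename_axis("sample").to_csv(path, sep="\t")


def read_size_factors(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.iloc[:, 0].rename("size_factor")
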