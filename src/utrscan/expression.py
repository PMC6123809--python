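"""Gene-expression layer: RPKM normalization, AR activity score, and
rank correlation across samples."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AR_GENES", "rpkm", "ar_activity", "spearman"]

# the seven androgen-receptor-regulated genes whose median expression
# defines the AR activity score
AR_GENES = ("TMPRSS2", "KLK2", "KLK3", "SLC45A3", "FKBP5", "NKX3-1", "ACSL3")


def rpkm(
    counts: pd.DataFrame,
    transcript_length_bp: pd.Series | Sequence[float],
    library_size: pd.Series | Sequence[float] | None = None,
) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads.

    ``rpkm = counts * 1e9 / (transcript_length_bp * library_size)``; the
    library size defaults to each sample's column sum.
    """
    lengths = pd.Series(transcript_length_bp, index=counts.index, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    if library_size is None:
        lib = counts.sum(axis=0).astype(float)
    else:
        lib = pd.Series(library_size, index=counts.columns, dtype=float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts.astype(float).mul(1e9).div(lengths, axis=0).div(lib, axis=1)


def ar_activity(expr: pd.DataFrame, genes: Sequence[str] = AR_GENES) -> pd.Series:
    """Per-sample AR activity score: median expression of the seven
    AR-regulated genes. All seven must be present; a silent median over
    fewer genes is refused."""
    missing = [g for g in genes if g not in expr.index]
    if missing:
        raise KeyError(f"AR activity score requires all genes; missing: {missing}")
    return expr.loc[list(genes)].median(axis=0)


def spearman(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of midranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("vectors must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    return float(stats.spearmanr(x, y).statistic)
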