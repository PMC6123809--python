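"""In-house read preprocessing: smoothed base-quality tail trimming and
SNP-genotype verification of cfDNA/WBC sample pairing."""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

__all__ = [
    "SequencedRead",
    "PairingResult",
    "trim_low_quality_tail",
    "verify_pairing",
]

# CIGAR operations that consume query bases
_QUERY_OPS = set("MIS=X")
_REF_OPS = set("MD=XN")


@dataclass(frozen=True)
class SequencedRead:
    """A sequenced read with per-base Phred qualities and alignment CIGAR."""

    read_id: str
    mate: int
    chrom: str
    start: int  # 0-based leftmost aligned position
    cigar: tuple[tuple[str, int], ...]  # e.g. (("M", 100), ("S", 50))
    seq: str
    baseq: tuple[int, ...]
    flagged_empty: bool = False

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.baseq):
            raise ValueError("seq and baseq lengths differ")
        consumed = sum(n for op, n in self.cigar if op in _QUERY_OPS)
        if consumed != len(self.seq):
            raise ValueError(
                f"CIGAR consumes {consumed} query bases but read has {len(self.seq)}"
            )


def smoothed_quality(baseq: Sequence[int], window: int) -> np.ndarray:
    """Centered moving average of base qualities with edge-shrinking window.

    At each position the window extends ``window // 2`` bases to each side,
    truncated at the read ends (so edge positions average over fewer bases).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    q = np.asarray(baseq, dtype=float)
    n = q.size
    half = window // 2
    cs = np.concatenate([[0.0], np.cumsum(q)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (cs[hi] - cs[lo]) / (hi - lo)


def _truncate_cigar(cigar, keep: int):
    """Keep the first ``keep`` query bases; drop trailing non-query ops."""
    out = []
    used = 0
    for op, n in cigar:
        if op in _QUERY_OPS:
            take = min(n, keep - used)
            if take > 0:
                out.append((op, take))
            used += take
            if used >= keep:
                break
        else:
            out.append((op, n))
    while out and out[-1][0] not in _QUERY_OPS:
        out.pop()
    return tuple(out)


def trim_low_quality_tail(
    read: SequencedRead, window: int = 11, threshold: float = 30.0
) -> SequencedRead:
    """Trim the low-quality 3' tail of a read (smoothed baseq < threshold).

    Scanning from the 3' end inward, the read is truncated after the last
    position whose smoothed (centered moving average) quality meets the
    threshold; only the tail is touched, 5' bases are never removed.
    Trimming is applied repeatedly until a fixed point, since truncation
    shrinks the smoothing window at the new 3' edge. A read whose every
    position is below threshold is emitted with zero length and flagged.
    """
    current = read
    while len(current.seq) > 0:
        sm = smoothed_quality(current.baseq, window)
        good = np.nonzero(sm >= threshold)[0]
        keep = int(good[-1]) + 1 if good.size else 0
        if keep == len(current.seq):
            return current
        current = replace(
            current,
            seq=current.seq[:keep],
            baseq=current.baseq[:keep],
            cigar=_truncate_cigar(current.cigar, keep),
            flagged_empty=(keep == 0),
        )
        if keep == 0:
            return current
    return current


@dataclass(frozen=True)
class PairingResult:
    concordance: float | None
    verdict: str  # "pass" | "fail" | "indeterminate"
    n_snps_used: int


def _genotype(af: float, het_lo: float, het_hi: float) -> int:
    if af < het_lo:
        return 0  # hom-ref
    if af > het_hi:
        return 2  # hom-alt
    return 1  # het


def verify_pairing(
    cfdna_afs: Sequence[float],
    wbc_afs: Sequence[float],
    min_snps: int = 20,
    cfdna_depths: Sequence[int] | None = None,
    wbc_depths: Sequence[int] | None = None,
    min_depth: int = 20,
    het_bounds: tuple[float, float] = (0.15, 0.85),
    min_concordance: float = 0.90,
) -> PairingResult:
    """Verify a cfDNA/WBC pairing from germline SNP genotypes.

    Allele fractions at shared SNP sites are discretized into hom-ref /
    het / hom-alt (het band ``[0.15, 0.85]`` by default) and the pairing
    passes when the fraction of concordant genotype calls reaches
    ``min_concordance``. Sites below ``min_depth`` in either sample are
    dropped; with fewer than ``min_snps`` usable sites the verdict is
    "indeterminate", never "fail".
    """
    cf = np.asarray(cfdna_afs, dtype=float)
    wb = np.asarray(wbc_afs, dtype=float)
    if cf.shape != wb.shape:
        raise ValueError("genotype vectors must have equal length")
    usable = np.ones(cf.shape, dtype=bool)
    if cfdna_depths is not None:
        usable &= np.asarray(cfdna_depths) >= min_depth
    if wbc_depths is not None:
        usable &= np.asarray(wbc_depths) >= min_depth
    cf, wb = cf[usable], wb[usable]
    n = int(cf.size)
    if n < min_snps:
        return PairingResult(None, "indeterminate", n)
    lo, hi = het_bounds
    g_cf = np.array([_genotype(a, lo, hi) for a in cf])
    g_wb = np.array([_genotype(a, lo, hi) for a in wb])
    conc = float(np.mean(g_cf == g_wb))
    return PairingResult(conc, "pass" if conc >= min_concordance else "fail", n)
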