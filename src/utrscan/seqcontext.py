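"""Sequence context around indel breakpoints.

GC content in sliding windows and as a function of signed distance from
breakpoints, k-mer composition of breakpoint neighborhoods versus the
whole region, mechanistic classification of indels (repeat-unit deletion
vs short tandem duplication), and conservation-score contrast between
mutation neighborhoods and the region background.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mutstats import ranksum_test
from .pileup import normalize_indel

__all__ = [
    "gc_sliding",
    "gc_around_breakpoints",
    "kmer_neighborhood",
    "classify_indel_mechanism",
    "conservation_contrast",
]

_GC = frozenset("GCgc")
_ACGT = frozenset("ACGTacgt")


def gc_sliding(seq: str, window: int = 20) -> np.ndarray:
    """GC fraction in every length-``window`` window (step 1).

    Ambiguous bases are excluded from numerator and denominator; a window
    of only ambiguous bases yields NaN.
    """
    if len(seq) < window:
        raise ValueError("sequence shorter than window")
    is_gc = np.array([b in _GC for b in seq], dtype=float)
    is_known = np.array([b in _ACGT for b in seq], dtype=float)
    kern = np.ones(window)
    gc = np.convolve(is_gc, kern, mode="valid")
    known = np.convolve(is_known, kern, mode="valid")
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(known > 0, gc / known, np.nan)


def gc_around_breakpoints(
    reference: Mapping[str, str],
    breakpoints: Sequence[tuple[str, int]],
    max_distance: int = 100,
) -> pd.DataFrame:
    """Mean GC indicator at each signed distance from the left breakpoint.

    For distance d in [-max_distance, max_distance], averages the per-base
    GC indicator at ``pos + d`` over all breakpoints; positions falling
    outside the contig are excluded from that distance's mean, never
    padded.
    """
    dists = np.arange(-max_distance, max_distance + 1)
    sums = np.zeros(dists.size)
    ns = np.zeros(dists.size)
    for chrom, pos in breakpoints:
        seq = reference[chrom]
        for i, d in enumerate(dists):
            p = pos + d
            if 0 <= p < len(seq) and seq[p] in _ACGT:
                sums[i] += seq[p] in _GC
                ns[i] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(ns > 0, sums / ns, np.nan)
    return pd.DataFrame({"distance": dists, "mean_gc": mean, "n": ns.astype(int)})


def _count_kmers(seq: str, k: int, counts: dict[str, int]) -> None:
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k].upper()
        if set(kmer) <= _ACGT:
            counts[kmer] = counts.get(kmer, 0) + 1


def kmer_neighborhood(
    reference: Mapping[str, str],
    breakpoints: Sequence[tuple[str, int]],
    region: tuple[str, int, int],
    k: int = 4,
    flank: int = 20,
) -> pd.DataFrame:
    """k-mer frequencies around breakpoints versus the whole region.

    Overlapping k-mers are counted in ``[pos - flank, pos + flank)``
    around every breakpoint (pooled) and across the full region, each
    normalized to frequencies. The result table carries one row per
    observed k-mer with both frequencies and the deviation, sorted by
    largest deviation for enrichment reporting.
    """
    if flank < k:
        raise ValueError("flank must be at least k")
    neigh: dict[str, int] = {}
    for chrom, pos in breakpoints:
        seq = reference[chrom]
        lo, hi = max(0, pos - flank), min(len(seq), pos + flank)
        _count_kmers(seq[lo:hi], k, neigh)
    reg: dict[str, int] = {}
    chrom, s, e = region
    _count_kmers(reference[chrom][s:e], k, reg)
    n_tot = sum(neigh.values()) or 1
    r_tot = sum(reg.values()) or 1
    kmers = sorted(set(neigh) | set(reg))
    df = pd.DataFrame(
        {
            "kmer": kmers,
            "freq_neighborhood": [neigh.get(m, 0) / n_tot for m in kmers],
            "freq_region": [reg.get(m, 0) / r_tot for m in kmers],
        }
    )
    df["deviation"] = df["freq_neighborhood"] - df["freq_region"]
    return df.sort_values("deviation", ascending=False, ignore_index=True)


def classify_indel_mechanism(
    reference: Mapping[str, str] | str,
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
) -> str:
    """Mechanistic class of a normalized indel.

    A deletion is a ``repeat_unit_deletion`` when the deleted sequence
    equals the immediately adjacent reference segment of the same length
    on either side (it removes one unit of a tandem repeat, e.g.
    AATAATAAT -> AATAAT). An insertion is a ``tandem_duplication`` when
    the inserted sequence duplicates the immediately adjacent reference
    segment; the defining case is a copy of the segment 5' of the
    insertion point, but after left-alignment that same event presents
    its copy on the 3' side, so both flanks are checked. Everything else
    (including substitutions and complex events) is ``other``. The input
    is re-normalized first, so the classification is invariant to the
    representation supplied.
    """
    seq = reference if isinstance(reference, str) else reference[chrom]
    pos, ref, alt = normalize_indel(seq, pos, ref, alt)
    if len(ref) > 1 and len(alt) == 1 and ref[0] == alt[0]:  # deletion
        deleted = ref[1:]
        n = len(deleted)
        start = pos + 1
        right = seq[start + n : start + 2 * n].upper()
        left = seq[max(0, start - n) : start].upper()
        if deleted == right or deleted == left:
            return "repeat_unit_deletion"
        return "other"
    if len(alt) > 1 and len(ref) == 1 and ref[0] == alt[0]:  # insertion
        inserted = alt[1:]
        n = len(inserted)
        point = pos + 1  # insertion falls before this reference position
        preceding = seq[max(0, point - n) : point].upper()
        following = seq[point : point + n].upper()
        if inserted in (preceding, following):
            return "tandem_duplication"
        return "other"
    return "other"


def conservation_contrast(
    scores: np.ndarray,
    breakpoints: Sequence[int],
    region: tuple[int, int],
    flank: int = 20,
) -> tuple[float, float, float]:
    """Mean conservation near breakpoints vs the region background.

    ``scores`` is a per-base conservation track indexed in the same
    coordinates as ``breakpoints`` and ``region``. Neighborhood values are
    pooled over ``+-flank`` around each breakpoint and compared with the
    whole-region values by the rank-sum test. Returns (mean_neighborhood,
    mean_region, p).
    """
    scores = np.asarray(scores, dtype=float)
    s, e = region
    neigh = []
    for bp in breakpoints:
        lo, hi = max(s, bp - flank), min(e, bp + flank)
        neigh.append(scores[lo:hi])
    neigh_vals = np.concatenate(neigh) if neigh else np.array([])
    region_vals = scores[s:e]
    if neigh_vals.size == 0:
        raise ValueError("no breakpoint neighborhoods inside the region")
    p = ranksum_test(neigh_vals, region_vals)
    return float(neigh_vals.mean()), float(region_vals.mean()), p
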