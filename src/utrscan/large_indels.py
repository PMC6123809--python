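"""Split-read detection of large (up to 500 bp) insertions and deletions.

Reads that fail to align contiguously (e.g. because they span a large
indel) are split into two fixed-length anchors taken from the 5' and 3'
ends of the read. Each anchor is placed on the reference by unique exact
k-mer match; anchor pairs whose implied inner distance differs from the
read geometry are discordant and are grouped by breakpoint signature.
After collapsing PCR/optical duplicates on read start positions, clusters
supported by at least ``min_fragments`` unique cfDNA fragments and
implying an event of at most ``max_len`` bp are emitted, with the
inserted sequence reconstructed from the unaligned middle segments by
majority vote.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .pileup import normalize_indel

__all__ = [
    "Anchor",
    "AnchorPair",
    "BreakpointCluster",
    "LargeIndelCall",
    "KmerIndex",
    "split_reads",
    "align_anchors",
    "cluster_discordant",
    "dedupe_fragments",
    "call_large_indels",
    "detect_large_indels",
]

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Anchor:
    read_id: str
    side: str  # "five_prime" | "three_prime"
    chrom: str | None = None
    pos: int | None = None  # 0-based aligned start
    strand: str | None = None

    @property
    def placed(self) -> bool:
        return self.pos is not None


@dataclass
class AnchorPair:
    read_id: str
    seq: str
    anchor_len: int
    five: Anchor
    three: Anchor


@dataclass
class ClusterMember:
    read_id: str
    read_start: int  # aligned start of the 5' anchor; dedupe key
    left_bp: int
    right_bp: int
    inserted_seq: str | None


@dataclass
class BreakpointCluster:
    chrom: str
    kind: str  # "deletion" | "insertion" | "unclassified"
    left_bp: int  # left-aligned reference breakpoint
    right_bp: int
    length: int
    members: list[ClusterMember] = field(default_factory=list)
    unique_fragments: int | None = None

    @property
    def signature(self) -> tuple:
        return (self.chrom, self.left_bp, self.right_bp, self.kind)


@dataclass(frozen=True)
class LargeIndelCall:
    chrom: str
    pos: int  # left breakpoint, 0-based
    kind: str  # "deletion" | "insertion"
    length: int
    sequence: str | None  # inserted sequence when reconstructible
    unique_fragments: int
    n_members: int


class KmerIndex:
    """Exact-match k-mer index over the reference (forward strand).

    Lookups try the query and its reverse complement; a hit is returned
    only when exactly one placement exists genome-wide across both
    orientations.
    """

    def __init__(self, reference: Mapping[str, str], k: int):
        self.k = k
        self._index: dict[str, tuple[str, int] | None] = {}
        for chrom, seq in reference.items():
            s = seq.upper()
            for i in range(len(s) - k + 1):
                kmer = s[i : i + k]
                if kmer in self._index:
                    self._index[kmer] = None  # ambiguous
                else:
                    self._index[kmer] = (chrom, i)

    def lookup(self, seq: str) -> tuple[str, int, str] | None:
        """Unique placement of ``seq`` as (chrom, pos, strand), else None."""
        fwd = self._index.get(seq.upper(), "missing")
        rev = self._index.get(revcomp(seq).upper(), "missing")
        fwd_hit = fwd if fwd not in ("missing", None) else None
        rev_hit = rev if rev not in ("missing", None) else None
        ambiguous = fwd is None or rev is None
        if ambiguous:
            return None
        if fwd_hit and rev_hit:
            return None
        if fwd_hit:
            return (fwd_hit[0], fwd_hit[1], "+")
        if rev_hit:
            return (rev_hit[0], rev_hit[1], "-")
        return None


@dataclass
class SplitStats:
    n_reads: int = 0
    skipped_short: int = 0
    dropped_unplaced: int = 0
    dropped_ambiguous: int = 0  # counted within unplaced (no unique hit)


def split_reads(
    reads: Iterable[tuple[str, str]],
    anchor_len: int = 30,
    stats: SplitStats | None = None,
) -> list[AnchorPair]:
    """Split each (read_id, seq) into 5' and 3' anchors of ``anchor_len`` bp.

    Reads shorter than twice the anchor length cannot contribute two
    disjoint anchors and are skipped (counted, not an error).
    """
    out = []
    for read_id, seq in reads:
        if stats is not None:
            stats.n_reads += 1
        if len(seq) < 2 * anchor_len:
            if stats is not None:
                stats.skipped_short += 1
            continue
        out.append(
            AnchorPair(
                read_id, seq, anchor_len,
                Anchor(read_id, "five_prime"),
                Anchor(read_id, "three_prime"),
            )
        )
    return out


def align_anchors(
    pairs: Sequence[AnchorPair],
    index: KmerIndex,
    stats: SplitStats | None = None,
) -> list[AnchorPair]:
    """Place both anchors of each pair by unique exact match.

    Pairs whose anchors cannot both be placed (no hit, ambiguous hit, or
    inconsistent orientation) are dropped with a counter. When the read
    originates from the reverse strand the pair is canonicalized to the
    forward orientation (sequence reverse-complemented, anchors swapped)
    so downstream geometry is strand-free.
    """
    placed = []
    for pair in pairs:
        k = pair.anchor_len
        hit5 = index.lookup(pair.seq[:k])
        hit3 = index.lookup(pair.seq[-k:])
        if hit5 is None or hit3 is None:
            if stats is not None:
                stats.dropped_unplaced += 1
            continue
        if hit5[0] != hit3[0] or hit5[2] != hit3[2]:
            if stats is not None:
                stats.dropped_unplaced += 1
            continue
        if hit5[2] == "-":
            pair = AnchorPair(pair.read_id, revcomp(pair.seq), k, pair.five, pair.three)
            hit5, hit3 = (hit3[0], hit3[1], "+"), (hit5[0], hit5[1], "+")
        pair.five = Anchor(pair.read_id, "five_prime", hit5[0], hit5[1], "+")
        pair.three = Anchor(pair.read_id, "three_prime", hit3[0], hit3[1], "+")
        placed.append(pair)
    return placed


def _refine_breakpoints(
    pair: AnchorPair, ref_seq: str
) -> tuple[str, int, int, str | None] | None:
    """Canonical breakpoints implied by a discordant pair.

    Returns (kind, left_bp, right_bp, inserted_seq) or None when the read
    cannot be explained as a simple deletion/insertion between its anchors.
    The maximal reference-matching prefix and suffix of the read bracket
    the admissible junction placements. Any admissible placement describes
    the same local haplotype, so the read's own placement is immediately
    re-normalized against the reference (left-aligned, VCF-style): inside
    repeats — tandem-duplication insertions especially — every read then
    reports the identical breakpoint signature instead of one truncated at
    its own start position. ``left_bp`` is the first affected reference
    base (start of the deleted segment, or the insertion point), and the
    inserted sequence is returned in its left-aligned rotation.
    """
    seq = pair.seq.upper()
    L = len(seq)
    p1 = pair.five.pos
    p2 = pair.three.pos
    end3 = p2 + pair.anchor_len  # reference end of the 3' anchor
    delta = (p2 - p1) - (L - pair.anchor_len)  # >0 deletion, <0 insertion
    if delta == 0:
        return None  # concordant
    # maximal prefix of read matching reference from p1
    pref = 0
    while pref < L and p1 + pref < len(ref_seq) and seq[pref] == ref_seq[p1 + pref].upper():
        pref += 1
    # maximal suffix of read matching reference ending at end3
    suf = 0
    while suf < L and end3 - suf - 1 >= 0 and seq[L - suf - 1] == ref_seq[end3 - suf - 1].upper():
        suf += 1
    if delta > 0:  # deletion of delta bp
        b_min = p1 + L - suf
        b_max = p1 + pref
        if b_min > b_max:
            return None  # junction inconsistent with a clean deletion
        b = max(b_min, p1)  # left-most junction expressible within this read
        if b < 1 or b + delta > len(ref_seq):
            return None
        ref_a = ref_seq[b - 1 : b + delta]
        alt_a = ref_seq[b - 1]
    else:
        ins_len = -delta
        b_min = p1 + L - suf - ins_len
        b_max = p1 + pref
        if b_min > b_max:
            return None
        b = max(b_min, p1)
        j = b - p1
        if b < 1 or j + ins_len > L:
            return None
        ref_a = ref_seq[b - 1]
        alt_a = ref_a + seq[j : j + ins_len]
    try:
        npos, _nref, nalt = normalize_indel(ref_seq, b - 1, ref_a, alt_a)
    except ValueError:
        return None
    if delta > 0:
        return ("deletion", npos + 1, npos + 1 + delta, None)
    return ("insertion", npos + 1, npos + 1, nalt[1:])


def cluster_discordant(
    pairs: Sequence[AnchorPair],
    reference: Mapping[str, str],
    pos_tolerance: int = 5,
) -> list[BreakpointCluster]:
    """Group discordant anchor pairs by breakpoint signature.

    A pair is discordant when the implied inner distance between its
    anchors differs from ``read_len - 2 * anchor_len``. Signatures
    (chrom, left breakpoint, right breakpoint, event kind) are merged
    when both positions agree within ``pos_tolerance`` bp; with tolerance
    0 only identical signatures cluster.
    """
    sigs: list[tuple[tuple, ClusterMember]] = []
    for pair in pairs:
        chrom = pair.five.chrom
        refined = _refine_breakpoints(pair, reference[chrom])
        if refined is None:
            continue
        kind, lb, rb, ins = refined
        sigs.append(
            ((chrom, kind, lb, rb), ClusterMember(pair.read_id, pair.five.pos, lb, rb, ins))
        )
    sigs.sort(key=lambda t: (t[0][0], t[0][1], t[0][2], t[0][3], t[1].read_id))
    clusters: list[BreakpointCluster] = []
    for (chrom, kind, lb, rb), member in sigs:
        merged = False
        for cl in clusters:
            if (
                cl.chrom == chrom
                and cl.kind == kind
                and abs(cl.left_bp - lb) <= pos_tolerance
                and abs(cl.right_bp - rb) <= pos_tolerance
            ):
                cl.members.append(member)
                merged = True
                break
        if not merged:
            length = rb - lb if kind == "deletion" else len(member.inserted_seq or "")
            clusters.append(BreakpointCluster(chrom, kind, lb, rb, length, [member]))
    return clusters


def dedupe_fragments(cluster: BreakpointCluster) -> BreakpointCluster:
    """Collapse members sharing a read start position (duplicate fragments)."""
    cluster.unique_fragments = len({m.read_start for m in cluster.members})
    return cluster


def _vote_sequence(members: Sequence[ClusterMember]) -> str | None:
    seqs = [m.inserted_seq for m in members if m.inserted_seq]
    if not seqs:
        return None
    counts: dict[str, int] = {}
    for s in seqs:
        counts[s] = counts.get(s, 0) + 1
    best = max(sorted(counts), key=lambda s: counts[s])
    return best


def call_large_indels(
    clusters: Sequence[BreakpointCluster],
    min_fragments: int = 3,
    max_len: int = 500,
) -> list[LargeIndelCall]:
    """Emit events supported by >= ``min_fragments`` unique fragments.

    Events longer than ``max_len`` bp (or shorter than 1 bp) are excluded
    by design; insertion sequence is the majority vote over member middle
    segments.
    """
    calls = []
    for cl in clusters:
        if cl.unique_fragments is None:
            cl = dedupe_fragments(cl)
        if cl.kind == "unclassified":
            continue
        if cl.unique_fragments < min_fragments:
            continue
        if not 1 <= cl.length <= max_len:
            continue
        seq = _vote_sequence(cl.members) if cl.kind == "insertion" else None
        calls.append(
            LargeIndelCall(
                cl.chrom, cl.left_bp, cl.kind, cl.length, seq,
                cl.unique_fragments, len(cl.members),
            )
        )
    return sorted(calls, key=lambda c: (c.chrom, c.pos, c.kind, c.length))


def detect_large_indels(
    reads: Iterable[tuple[str, str]],
    reference: Mapping[str, str],
    anchor_len: int = 30,
    pos_tolerance: int = 5,
    min_fragments: int = 3,
    max_len: int = 500,
    index: KmerIndex | None = None,
) -> list[LargeIndelCall]:
    """End-to-end split-read pipeline over a sample's unaligned reads."""
    if index is None:
        index = KmerIndex(reference, anchor_len)
    stats = SplitStats()
    pairs = split_reads(reads, anchor_len, stats)
    placed = align_anchors(pairs, index, stats)
    clusters = cluster_discordant(placed, reference, pos_tolerance)
    for cl in clusters:
        dedupe_fragments(cl)
    return call_large_indels(clusters, min_fragments, max_len)
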