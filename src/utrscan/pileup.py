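"""Per-position allele counting from aligned reads.

Alleles are keyed by descriptor: an SNV is the alternate base ("T"); an
indel is a VCF-style (ref, alt) string pair anchored at its left-aligned
start column. All indels are normalized (left-aligned, parsimonious)
before counting, so every CIGAR representation of the same event inside a
repeat collapses to a single descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import pysam

__all__ = ["PileupColumn", "normalize_indel", "build_pileup", "read_pileup_tsv", "write_pileup_tsv"]

Allele = str | tuple[str, str]


@dataclass
class PileupColumn:
    """Read support for every allele observed at one position of one sample."""

    chrom: str
    pos: int  # 0-based
    ref_base: str
    depth: int
    allele_counts: dict[Allele, int] = field(default_factory=dict)

    def af(self, allele: Allele) -> float:
        if self.depth == 0:
            return 0.0
        return self.allele_counts.get(allele, 0) / self.depth


def normalize_indel(seq: str, pos: int, ref: str, alt: str) -> tuple[int, str, str]:
    """Left-align and parsimony-trim an indel against its contig sequence.

    Standard VCF normalization: while both alleles end in the same base,
    drop it (extending left with the previous reference base whenever an
    allele would empty); then trim shared leading bases. The result is the
    unique left-most anchored representation, e.g. every placement of a
    3 bp deletion inside an AACAAC microsatellite maps to the same
    (pos, ref, alt).
    """
    if ref == alt:
        raise ValueError("not a variant: ref == alt")
    ref, alt = ref.upper(), alt.upper()
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 0:
                    raise ValueError("cannot left-extend past contig start")
                pos -= 1
                b = seq[pos].upper()
                ref, alt = b + ref, b + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def _iter_read_events(read: pysam.AlignedSegment, ref_seq: str):
    """Yield (kind, ref_pos, data) events from one aligned read.

    kind "cover": data = span length (reference positions covered by an
    aligned or deleted segment); kind "snv": data = alt base; kind
    "indel": data = raw (ref, alt) at anchor position (base before event).
    Soft-clipped bases are excluded entirely.
    """
    rp = read.reference_start
    qp = 0
    seq = read.query_sequence
    for op, length in read.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            yield ("cover", rp, length)
            for i in range(length):
                b = seq[qp + i].upper()
                if b != ref_seq[rp + i].upper() and b != "N":
                    yield ("snv", rp + i, b)
            rp += length
            qp += length
        elif op == 1:  # I
            if rp > 0:
                anchor = rp - 1
                ref = ref_seq[anchor].upper()
                alt = ref + seq[qp : qp + length].upper()
                yield ("indel", anchor, (ref, alt))
            qp += length
        elif op == 2:  # D
            yield ("cover", rp, length)
            if rp > 0:
                anchor = rp - 1
                ref = ref_seq[anchor : rp + length].upper()
                alt = ref_seq[anchor].upper()
                yield ("indel", anchor, (ref, alt))
            rp += length
        elif op == 3:  # N
            rp += length
        elif op == 4:  # S
            qp += length
        # H, P consume nothing relevant


def build_pileup(
    alignments: str | Iterable[pysam.AlignedSegment],
    reference: Mapping[str, str],
) -> dict[str, dict[int, PileupColumn]]:
    """Build per-position allele counts for one sample.

    ``alignments`` is a SAM path or an iterable of mapped pysam reads.
    Depth counts reference positions covered by aligned (M/=/X) or deleted
    (D) segments; soft-clips are excluded. Mismatches become SNV alleles;
    CIGAR I/D operations become indel alleles anchored at the base before
    the event and then left-align normalized.
    """
    if isinstance(alignments, str):
        with pysam.AlignmentFile(alignments, "r", check_sq=False) as fh:
            reads = [r for r in fh if not r.is_unmapped and not r.is_secondary]
    else:
        reads = [r for r in alignments if not r.is_unmapped]
    columns: dict[str, dict[int, PileupColumn]] = {}
    for read in reads:
        chrom = read.reference_name
        if chrom not in reference:
            raise KeyError(f"read {read.query_name} aligned to unknown contig {chrom!r}")
        ref_seq = reference[chrom]
        by_pos = columns.setdefault(chrom, {})

        def col(p: int) -> PileupColumn:
            c = by_pos.get(p)
            if c is None:
                c = by_pos[p] = PileupColumn(chrom, p, ref_seq[p].upper(), 0)
            return c

        for kind, p, data in _iter_read_events(read, ref_seq):
            if kind == "cover":
                for q in range(p, p + data):
                    col(q).depth += 1
            elif kind == "snv":
                c = col(p)
                c.allele_counts[data] = c.allele_counts.get(data, 0) + 1
            else:
                ref, alt = data
                np_, nref, nalt = normalize_indel(ref_seq, p, ref, alt)
                c = col(np_)
                key = (nref, nalt)
                c.allele_counts[key] = c.allele_counts.get(key, 0) + 1
    return columns


# ---------------------------------------------------------------------------
# Pileup TSV dialect: chrom, pos (0-based), ref, depth, alleles
# where alleles is ";"-joined  allele descriptor "=" count;  SNVs are a
# single base, indels "REF>ALT". Empty allele field is ".".

def write_pileup_tsv(columns: dict[str, dict[int, PileupColumn]], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\tdepth\talleles\n")
        for chrom in sorted(columns):
            for pos in sorted(columns[chrom]):
                c = columns[chrom][pos]
                parts = []
                for allele, n in sorted(c.allele_counts.items(), key=repr):
                    desc = allele if isinstance(allele, str) else f"{allele[0]}>{allele[1]}"
                    parts.append(f"{desc}={n}")
                fh.write(
                    f"{chrom}\t{c.pos}\t{c.ref_base}\t{c.depth}\t"
                    f"{';'.join(parts) if parts else '.'}\n"
                )


def read_pileup_tsv(path: str) -> dict[str, dict[int, PileupColumn]]:
    out: dict[str, dict[int, PileupColumn]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("chrom\t"):
            raise ValueError("not a pileup TSV (missing header)")
        for line in fh:
            chrom, pos, ref, depth, alleles = line.rstrip("\n").split("\t")
            col = PileupColumn(chrom, int(pos), ref, int(depth))
            if alleles != ".":
                for part in alleles.split(";"):
                    desc, n = part.rsplit("=", 1)
                    key: Allele = tuple(desc.split(">", 1)) if ">" in desc else desc
                    col.allele_counts[key] = int(n)
            out.setdefault(chrom, {})[col.pos] = col
    return out
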