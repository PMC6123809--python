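"""Gene models, UTR derivation, region classification and mutation rates.

A gene model carries one or more transcripts (exon and CDS intervals,
0-based half-open). UTRs are derived from the predominantly expressed
transcript; region classification applies a strict priority so that a
putative UTR variant overlapping *any* annotated CDS of the gene (in any
splice variant) is classified as coding. The coverage-normalized mutation
rate divides the somatic mutation count by the megabases of sequence
exceeding a depth floor and by the number of ctDNA-positive samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

__all__ = [
    "Transcript",
    "GeneModel",
    "RegionIndex",
    "RateResult",
    "derive_utrs",
    "classify_variant",
    "consequence",
    "mutation_rate",
    "write_gff3",
    "read_gff3",
]

Interval = tuple[int, int]

REGION_CLASSES = ("CDS", "UTR5", "UTR3", "intron", "intergenic")


@dataclass(frozen=True)
class Transcript:
    tx_id: str
    exons: tuple[Interval, ...]
    cds: tuple[Interval, ...]

    def __post_init__(self) -> None:
        for ivs in (self.exons, self.cds):
            for s, e in ivs:
                if e <= s:
                    raise ValueError(f"empty or inverted interval ({s}, {e})")
        ex = sorted(self.exons)
        if any(ex[i][1] > ex[i + 1][0] for i in range(len(ex) - 1)):
            raise ValueError("overlapping exons within a transcript")
        exon_pos = set()
        for s, e in self.exons:
            exon_pos.update(range(s, e))
        for s, e in self.cds:
            if not set(range(s, e)) <= exon_pos:
                raise ValueError("CDS interval outside exons")

    @property
    def span(self) -> Interval:
        return (min(s for s, _ in self.exons), max(e for _, e in self.exons))

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)


@dataclass
class GeneModel:
    gene: str
    chrom: str
    strand: str  # "+" or "-"
    transcripts: list[Transcript]
    predominant: str | None = None  # tx_id; defaults to longest CDS

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        if not self.transcripts:
            raise ValueError("gene model requires at least one transcript")

    @property
    def span(self) -> Interval:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return (min(starts), max(ends))

    def predominant_transcript(self) -> Transcript:
        if self.predominant is not None:
            for t in self.transcripts:
                if t.tx_id == self.predominant:
                    return t
            raise KeyError(f"predominant transcript {self.predominant!r} not in model")
        return max(self.transcripts, key=lambda t: (t.cds_length, t.tx_id))

    def all_cds(self) -> list[Interval]:
        out: list[Interval] = []
        for t in self.transcripts:
            out.extend(t.cds)
        return sorted(out)


@dataclass(frozen=True)
class UTRs:
    utr5: tuple[Interval, ...]
    utr3: tuple[Interval, ...]


def derive_utrs(
    model: GeneModel,
    expression_ranks: Mapping[str, float] | None = None,
) -> UTRs:
    """UTR intervals of the predominantly expressed transcript.

    ``expression_ranks`` (tx_id -> expression) selects the predominant
    transcript; without it the designated (or longest-CDS) transcript is
    used. Exonic sequence outside the CDS is assigned 5' or 3' by strand.
    A transcript without CDS marks the gene non-coding: no UTRs.
    """
    if expression_ranks:
        known = [t for t in model.transcripts if t.tx_id in expression_ranks]
        if known:
            tx = max(known, key=lambda t: (expression_ranks[t.tx_id], t.tx_id))
        else:
            tx = model.predominant_transcript()
    else:
        tx = model.predominant_transcript()
    if not tx.cds:
        return UTRs((), ())
    cds_start = min(s for s, _ in tx.cds)
    cds_end = max(e for _, e in tx.cds)
    left: list[Interval] = []
    right: list[Interval] = []
    for s, e in sorted(tx.exons):
        if s < cds_start:
            left.append((s, min(e, cds_start)))
        if e > cds_end:
            right.append((max(s, cds_end), e))
    if model.strand == "+":
        return UTRs(tuple(left), tuple(right))
    return UTRs(tuple(right), tuple(left))


def _overlaps(start: int, end: int, ivs: Iterable[Interval]) -> bool:
    return any(s < end and start < e for s, e in ivs)


class RegionIndex:
    """Interval index over a set of gene models for region classification."""

    def __init__(self, models: Sequence[GeneModel]):
        self.models = list(models)
        self._trees: dict[str, IntervalTree] = {}
        self._utrs: dict[str, UTRs] = {}
        for i, m in enumerate(self.models):
            s, e = m.span
            self._trees.setdefault(m.chrom, IntervalTree()).addi(s, e, i)
            self._utrs[m.gene] = derive_utrs(m)

    def utrs(self, gene: str) -> UTRs:
        return self._utrs[gene]

    def genes_overlapping(self, chrom: str, start: int, end: int) -> list[GeneModel]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = sorted(tree.overlap(start, end), key=lambda iv: iv.data)
        return [self.models[iv.data] for iv in hits]


def classify_variant(
    chrom: str,
    start: int,
    end: int,
    index: RegionIndex,
) -> list[tuple[str | None, str]]:
    """Region class of a variant interval, per overlapping gene.

    Priority within a gene: CDS > UTR5/UTR3 > intron. A variant overlapping
    any CDS interval of any splice variant of the gene is CDS even if it
    also lies inside a UTR of the predominant transcript. Positions outside
    every gene span are intergenic: the result is then ``[(None,
    "intergenic")]``. SNVs use ``end = start + 1``.
    """
    if end <= start:
        raise ValueError("variant interval must be non-empty (0-based half-open)")
    hits = index.genes_overlapping(chrom, start, end)
    if not hits:
        return [(None, "intergenic")]
    out: list[tuple[str | None, str]] = []
    for m in hits:
        if _overlaps(start, end, m.all_cds()):
            out.append((m.gene, "CDS"))
            continue
        utrs = index.utrs(m.gene)
        if _overlaps(start, end, utrs.utr5):
            out.append((m.gene, "UTR5"))
        elif _overlaps(start, end, utrs.utr3):
            out.append((m.gene, "UTR3"))
        else:
            out.append((m.gene, "intron"))
    return out


def _coding_positions(tx: Transcript, strand: str) -> list[int]:
    pos = [p for s, e in sorted(tx.cds) for p in range(s, e)]
    return pos if strand == "+" else pos[::-1]


_COMP = str.maketrans("ACGTacgt", "TGCAtgca")


def consequence(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
    reference: Mapping[str, str],
    index: RegionIndex | None = None,
) -> str:
    """Minimal coding-consequence prediction against one gene model.

    CDS SNVs are translated through the standard genetic code on the
    predominant transcript (synonymous / missense / stopgain); CDS indels
    are frameshift iff their length is not a multiple of 3. Indels touching
    an exon-intron junction of the predominant transcript are labeled
    ``splice_region`` without a codon call. UTR indels are never
    frameshifts: UTRs are untranslated.
    """
    if index is None:
        index = RegionIndex([model])
    vstart, vend = pos, pos + max(len(ref), 1)
    hits = dict()
    for gene, cls in classify_variant(chrom, vstart, vend, index):
        if gene == model.gene:
            hits[model.gene] = cls
    cls = hits.get(model.gene, "intergenic")
    if cls == "UTR5" or cls == "UTR3":
        return "utr"
    if cls == "intron":
        return "intronic"
    if cls == "intergenic":
        return "intergenic"
    # CDS
    tx = model.predominant_transcript()
    is_indel = len(ref) != len(alt)
    if is_indel:
        # splice check: the changed interval crosses a CDS-exon boundary
        changed = (pos + 1, vend) if len(ref) > 1 else (pos, pos + 1)
        inside = any(s <= changed[0] and changed[1] <= e for s, e in tx.cds)
        if not inside:
            return "splice_region"
        delta = abs(len(ref) - len(alt))
        return "frameshift_indel" if delta % 3 else "inframe_indel"
    # SNV
    coding = _coding_positions(tx, model.strand)
    try:
        idx = coding.index(pos)
    except ValueError:
        return "splice_region"  # in a CDS of another splice form only
    codon_i = idx // 3
    codon_pos = coding[codon_i * 3 : codon_i * 3 + 3]
    if len(codon_pos) < 3:
        return "splice_region"  # incomplete terminal codon
    seq = reference[chrom]
    def base_at(p: int, override: str | None = None) -> str:
        b = override if override is not None else seq[p]
        return b.translate(_COMP) if model.strand == "-" else b
    old = "".join(base_at(p) for p in codon_pos)
    new = "".join(base_at(p, alt if p == pos else None) for p in codon_pos)
    aa_old = str(Seq(old).translate())
    aa_new = str(Seq(new).translate())
    if aa_new == aa_old:
        return "synonymous"
    if aa_new == "*":
        return "stopgain"
    return "missense"


@dataclass(frozen=True)
class RateResult:
    """Coverage- and cohort-normalized mutation rate for one region."""

    region: str
    mutation_count: int
    covered_mb: float
    n_samples: int
    rate: float | None  # mutations per Mb per ctDNA-positive sample
    undefined: bool = False


def mutation_rate(
    mutation_count: int,
    depth: Mapping[str, np.ndarray],
    intervals: Sequence[tuple[str, int, int]],
    samples: pd.DataFrame,
    depth_floor: int = 200,
    ctdna_floor: float = 0.02,
    region: str = "",
) -> RateResult:
    """Mutations per megabase of well-covered sequence per eligible sample.

    The denominator counts genomic positions whose pooled depth is strictly
    greater than ``depth_floor`` (in megabases) and cfDNA samples whose
    ctDNA fraction is strictly greater than ``ctdna_floor``. With zero
    covered megabases the rate is undefined and flagged, never silently 0
    or infinite.
    """
    covered = 0
    for chrom, s, e in intervals:
        track = depth.get(chrom)
        if track is None or len(track) < e:
            raise ValueError(f"depth track does not cover {chrom}:{s}-{e}")
        covered += int(np.count_nonzero(np.asarray(track[s:e]) > depth_floor))
    covered_mb = covered / 1e6
    is_cf = samples["type"] == "cfDNA" if "type" in samples.columns else np.ones(len(samples), bool)
    n_samples = int(((samples["ctdna_fraction"] > ctdna_floor) & is_cf).sum())
    if covered_mb == 0 or n_samples == 0:
        return RateResult(region, mutation_count, covered_mb, n_samples, None, undefined=True)
    return RateResult(
        region, mutation_count, covered_mb, n_samples,
        mutation_count / covered_mb / n_samples,
    )


# ---------------------------------------------------------------------------
# GFF3 I/O (gene -> mRNA -> exon/CDS; 1-based inclusive on disk)

def write_gff3(models: Sequence[GeneModel], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gs, ge = m.span
            fh.write(
                f"{m.chrom}\tutrscan\tgene\t{gs + 1}\t{ge}\t.\t{m.strand}\t.\t"
                f"ID={m.gene}\n"
            )
            pred = m.predominant_transcript().tx_id
            for t in m.transcripts:
                ts, te = t.span
                extra = ";predominant=1" if t.tx_id == pred else ""
                fh.write(
                    f"{m.chrom}\tutrscan\tmRNA\t{ts + 1}\t{te}\t.\t{m.strand}\t.\t"
                    f"ID={t.tx_id};Parent={m.gene}{extra}\n"
                )
                for s, e in sorted(t.exons):
                    fh.write(
                        f"{m.chrom}\tutrscan\texon\t{s + 1}\t{e}\t.\t{m.strand}\t.\t"
                        f"Parent={t.tx_id}\n"
                    )
                for s, e in sorted(t.cds):
                    fh.write(
                        f"{m.chrom}\tutrscan\tCDS\t{s + 1}\t{e}\t.\t{m.strand}\t0\t"
                        f"Parent={t.tx_id}\n"
                    )


def read_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        txs = []
        pred = None
        for mrna in db.children(gene, featuretype="mRNA"):
            exons = tuple(
                sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="exon"))
            )
            cds = tuple(
                sorted((f.start - 1, f.end) for f in db.children(mrna, featuretype="CDS"))
            )
            txs.append(Transcript(mrna.id, exons, cds))
            if mrna.attributes.get("predominant", ["0"])[0] == "1":
                pred = mrna.id
        models.append(GeneModel(gene.id, gene.seqid, gene.strand, txs, predominant=pred))
    return models
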