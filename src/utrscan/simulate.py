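"""Synthetic targeted-panel cfDNA cohort generator.

Generates, from a single seed, everything the downstream analysis needs:
a reference (one contig per gene with flanks), gene models with UTR/CDS
structure, per-sample pileups for paired cfDNA/WBC samples, split-read
evidence for large indels, sample metadata with ctDNA fractions, and a
truth table of every planted event.

The statistical model: per-position depth is Poisson around the panel
mean; sequencing errors are i.i.d. substitutions at a per-base rate split
evenly across the three non-reference bases; germline heterozygous SNPs
appear at allele fraction ~0.5 in both the cfDNA and WBC sample of a
patient; planted somatic events appear only in cfDNA with expected allele
fraction ``ctdna_fraction x clonality / 2`` (heterozygous, single-copy).
One designated gene receives an indel-dominant 3'-UTR hypermutation
process. Indels up to ``max_pileup_indel`` bp enter the pileup as CIGAR-
derived alleles; longer events instead emit unaligned reads drawn from
the mutant haplotype, exercising the split-read caller.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .pileup import PileupColumn, normalize_indel
from .regions import GeneModel, RegionIndex, Transcript, write_gff3

__all__ = [
    "SimulationError",
    "GeneStructure",
    "PlannedEvent",
    "SimConfig",
    "Cohort",
    "plant_large_indel",
    "default_gene_structures",
    "standard_somatic_spec",
    "simulate_cohort",
    "write_cohort",
]

_BASES = np.array(list("ACGT"))
_BASE_IDX = {b: i for i, b in enumerate("ACGT")}


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class GeneStructure:
    """Genomic layout of one simulated two-exon gene on its own contig."""

    name: str
    strand: str = "+"
    utr5_len: int = 150
    cds_lens: tuple[int, int] = (600, 600)
    intron_len: int = 300
    utr3_len: int = 1300
    flank: int = 200

    @property
    def contig_len(self) -> int:
        return 2 * self.flank + self.utr5_len + sum(self.cds_lens) + self.intron_len + self.utr3_len


@dataclass
class PlannedEvent:
    """One somatic event to plant: where, what, and in which patient."""

    gene: int
    region: str  # CDS | UTR5 | UTR3 | intron | intergenic
    kind: Literal["SNV", "del", "ins"]
    length: int = 1
    clonality: float = 1.0
    patient: int | None = None  # assigned by the simulator when None
    mechanism: str = "auto"  # auto | repeat_unit | tandem | random
    timepoints: tuple[int, ...] | str = "all"

    def __post_init__(self) -> None:
        if not 0 < self.clonality <= 1:
            raise SimulationError("clonality must be in (0, 1]")
        if self.kind != "SNV" and not 1 <= self.length <= 500:
            raise SimulationError("indel length must be in [1, 500]")


@dataclass
class SimConfig:
    """Study conditions for one simulated cohort.

    Defaults reflect the targeted mCRPC panel being emulated: mean on-
    target depth 751x, ctDNA-positive patients only, one gene carrying an
    indel-dominant 3'-UTR hypermutation present in 12% of patients. The
    per-base substitution error rate (0.001) is a conventional
    short-read figure; the platform's true error model is not part of the
    emulation target.
    """

    seed: int = 0
    n_genes: int = 6
    gene_structure: tuple[GeneStructure, ...] | None = None
    panel_depth_mean: float = 751.0
    per_base_error: float = 0.001
    n_patients: int = 290
    timepoints_per_patient: int = 1
    ctdna_fractions: Sequence[float] | None = None  # per cfDNA sample
    germline_snp_rate: float = 1e-3
    wbc_indel_noise_rate: float = 2e-6
    somatic_spec: list[PlannedEvent] | None = None
    hypermut_gene: int = 0
    hypermut_prevalence: float = 0.12
    read_length: int = 150
    max_pileup_indel: int = 20
    duplicate_rate: float = 0.10
    unaligned_fraction: float = 1.0


def default_gene_structures(n_genes: int, hypermut_gene: int = 0) -> tuple[GeneStructure, ...]:
    """One two-exon gene per contig; the hypermutated gene gets the longer
    3'-UTR (1800 bp vs 1300 bp), alternating strands across the panel."""
    out = []
    for i in range(n_genes):
        out.append(
            GeneStructure(
                name=f"G{i + 1:02d}",
                strand="+" if i % 2 == 0 else "-",
                utr3_len=1800 if i == hypermut_gene else 1300,
            )
        )
    return tuple(out)


def plant_large_indel(
    reference: str,
    position: int,
    kind: Literal["del", "ins"],
    length: int,
    sequence_rule: Literal["tandem", "repeat_unit", "random"] = "random",
    rng: np.random.Generator | None = None,
    insert_seq: str | None = None,
) -> tuple[str, str, str]:
    """Apply one indel to a reference haplotype.

    Returns ``(haplotype, ref_allele, alt_allele)`` with VCF-style anchored
    alleles at ``position - 1``. Insertions are placed *before*
    ``position``; with ``sequence_rule="tandem"`` the inserted sequence
    duplicates ``reference[position - length, position)``. Deletions remove
    ``reference[position, position + length)``; ``sequence_rule=
    "repeat_unit"`` additionally requires that the deleted segment equals
    an immediately adjacent segment of the same length (one unit of a
    tandem repeat). Lengths outside [1, 500] are rejected: the downstream
    caller excludes them by design.
    """
    if not 1 <= length <= 500:
        raise SimulationError(f"indel length {length} outside [1, 500]")
    if position <= 0 or position >= len(reference):
        raise SimulationError("position outside reference")
    if kind == "ins":
        if sequence_rule == "tandem":
            if position - length < 0:
                raise SimulationError("tandem insertion would extend past contig start")
            ins = reference[position - length : position]
        elif insert_seq is not None:
            ins = insert_seq
        else:
            if rng is None:
                raise SimulationError("random insertion requires an rng or insert_seq")
            ins = "".join(rng.choice(_BASES, size=length))
        hap = reference[:position] + ins + reference[position:]
        anchor = reference[position - 1]
        return hap, anchor, anchor + ins
    if kind == "del":
        if position + length > len(reference):
            raise SimulationError("deletion extends past contig end")
        deleted = reference[position : position + length]
        if sequence_rule == "repeat_unit":
            right = reference[position + length : position + 2 * length]
            left = reference[position - length : position]
            if deleted not in (right, left):
                raise SimulationError(
                    "repeat_unit deletion requires an adjacent identical repeat unit"
                )
        hap = reference[:position] + reference[position + length :]
        anchor = reference[position - 1]
        return hap, anchor + deleted, anchor
    raise SimulationError(f"unknown indel kind {kind!r}")


# ---------------------------------------------------------------------------
# reference and gene models

_REPEAT_MOTIFS = ("AAT", "AACAAC", "CT")


def _build_gene(rng: np.random.Generator, gs: GeneStructure) -> tuple[str, GeneModel, list]:
    seq = rng.choice(_BASES, size=gs.contig_len)
    f = gs.flank
    if gs.strand == "+":
        utr5 = (f, f + gs.utr5_len)
        cds1 = (utr5[1], utr5[1] + gs.cds_lens[0])
        intron = (cds1[1], cds1[1] + gs.intron_len)
        cds2 = (intron[1], intron[1] + gs.cds_lens[1])
        utr3 = (cds2[1], cds2[1] + gs.utr3_len)
        exons = ((utr5[0], cds1[1]), (cds2[0], utr3[1]))
    else:
        utr3 = (f, f + gs.utr3_len)
        cds2 = (utr3[1], utr3[1] + gs.cds_lens[1])
        intron = (cds2[1], cds2[1] + gs.intron_len)
        cds1 = (intron[1], intron[1] + gs.cds_lens[0])
        utr5 = (cds1[1], cds1[1] + gs.utr5_len)
        exons = ((utr3[0], cds2[1]), (cds1[0], utr5[1]))
    # embed tandem repeat runs in the 3'-UTR so repeat-unit deletions and
    # microsatellite normalization have real substrate
    repeat_loci = []
    u3s, u3e = utr3
    span = u3e - u3s
    offsets = (span // 5, span // 2, 4 * span // 5)
    for motif, off in zip(_REPEAT_MOTIFS, offsets):
        n_units = 3
        start = u3s + off
        run = (motif * n_units)[: n_units * len(motif)]
        if start + len(run) < u3e:
            seq[start : start + len(run)] = list(run)
            repeat_loci.append((start, len(motif), n_units))
    model = GeneModel(
        gs.name,
        f"chr_{gs.name}",
        gs.strand,
        [Transcript(f"{gs.name}.t1", exons, (cds1, cds2) if gs.strand == "+" else (cds2, cds1))],
    )
    return "".join(seq), model, repeat_loci


# ---------------------------------------------------------------------------
# somatic event planning

def _draw_lengths(rng, n, median, upper):
    """Integer indel lengths, roughly geometric with the given median."""
    lam = np.log(2) / max(median - 0.5, 0.5)
    lens = 1 + np.floor(rng.exponential(1 / lam, size=n)).astype(int)
    return np.clip(lens, 1, upper)


def standard_somatic_spec(config: SimConfig, rng: np.random.Generator) -> list[PlannedEvent]:
    """The standard cohort's planted-event list.

    The hypermutated gene receives one 3'-UTR event in a fixed 12% of
    patients, 80% of them indels (deletion:insertion roughly 22:6 as in
    the mutational process being emulated, deletion lengths median 8 bp up
    to 89 bp, insertion lengths median 18 bp). A fraction of deletions
    remove one unit of an embedded tandem repeat and most insertions are
    short tandem duplications. Every other gene carries a background of
    coding SNVs (a minority subclonal at clonality 0.4), occasional CDS
    indels, and a low, substitution-dominated UTR mutation load.
    """
    events: list[PlannedEvent] = []
    if config.n_patients == 0:
        return events
    n_h = int(round(config.hypermut_prevalence * config.n_patients))
    n_indel = int(round(0.8 * n_h))
    n_del = int(round(n_indel * 22 / 28))
    n_ins = n_indel - n_del
    n_snv = n_h - n_indel
    hg = config.hypermut_gene
    del_lens = _draw_lengths(rng, n_del, median=8, upper=89)
    ins_lens = np.minimum(_draw_lengths(rng, n_ins, median=18, upper=60), 60)
    n_repeat = min(n_del, max(1, round(n_del * 5 / 22)))
    for i, ln in enumerate(del_lens):
        mech = "repeat_unit" if i < n_repeat else "random"
        ln = 3 if mech == "repeat_unit" else int(ln)
        events.append(PlannedEvent(hg, "UTR3", "del", ln, 1.0, mechanism=mech))
    n_tandem = max(0, n_ins - max(1, n_ins // 6))
    for i, ln in enumerate(ins_lens):
        mech = "tandem" if i < n_tandem else "random"
        events.append(PlannedEvent(hg, "UTR3", "ins", int(ln), 1.0, mechanism=mech))
    for _ in range(n_snv):
        events.append(PlannedEvent(hg, "UTR3", "SNV"))
    # background load in the other genes, scaled to cohort size: roughly a
    # dozen coding mutations per recurrently mutated driver gene, a couple
    # of (mostly substitution) UTR events, and some intronic/flank noise
    scale = config.n_patients / 290.0

    def n_of(base: int) -> int:
        return max(1, int(round(base * scale)))

    for g in range(config.n_genes):
        if g == hg:
            continue
        for _ in range(n_of(9)):
            events.append(PlannedEvent(g, "CDS", "SNV", clonality=1.0))
        for _ in range(n_of(3)):
            events.append(PlannedEvent(g, "CDS", "SNV", clonality=0.4))
        events.append(PlannedEvent(g, "CDS", "del", 3))
        events.append(PlannedEvent(g, "CDS", "del", 2))
        for _ in range(n_of(2)):
            events.append(PlannedEvent(g, "UTR3", "SNV"))
        if g % 2 == 1:
            events.append(PlannedEvent(g, "UTR3", "del", 4))
        events.append(PlannedEvent(g, "UTR5", "SNV"))
        for _ in range(n_of(2)):
            events.append(PlannedEvent(g, "intron", "SNV"))
        events.append(PlannedEvent(g, "intergenic", "SNV"))
    return events


# ---------------------------------------------------------------------------
# cohort containers

@dataclass
class ContigPileup:
    depth: np.ndarray  # int32, length L
    alt: np.ndarray  # int16, shape (4, L); row of the reference base is 0
    indels: dict[tuple[int, str, str], int] = field(default_factory=dict)


@dataclass
class PlantedTruth:
    patient: str
    sample: str
    chrom: str
    pos: int
    ref: str
    alt: str
    kind: str
    length: int
    clonality: float
    expected_af: float
    region: str
    gene: str
    mechanism: str
    channel: str  # "pileup" | "split"


@dataclass
class Cohort:
    config: SimConfig
    reference: dict[str, str]
    models: list[GeneModel]
    samples: pd.DataFrame
    pileups: dict[str, dict[str, ContigPileup]]
    split_reads: dict[str, list[tuple[str, str]]]
    truth: pd.DataFrame
    repeat_loci: dict[str, list[tuple[int, int, int]]]
    ref_index: dict[str, np.ndarray] = field(default_factory=dict)

    def pileup_columns(
        self, sample: str, sites: Sequence[tuple[str, int]]
    ) -> dict[str, dict[int, PileupColumn]]:
        """Materialize PileupColumn objects for selected sites of a sample."""
        out: dict[str, dict[int, PileupColumn]] = {}
        sp = self.pileups[sample]
        for chrom, pos in sites:
            cp = sp[chrom]
            col = PileupColumn(chrom, pos, self.reference[chrom][pos], int(cp.depth[pos]))
            ref_i = _BASE_IDX[col.ref_base]
            for b_i in range(4):
                if b_i == ref_i:
                    continue
                n = int(cp.alt[b_i, pos])
                if n:
                    col.allele_counts["ACGT"[b_i]] = n
            for (ipos, iref, ialt), n in cp.indels.items():
                if ipos == pos and n:
                    col.allele_counts[(iref, ialt)] = col.allele_counts.get((iref, ialt), 0) + n
            out.setdefault(chrom, {})[pos] = col
        return out


# ---------------------------------------------------------------------------
# the generator

def _region_intervals(model: GeneModel, index: RegionIndex, contig_len: int, region: str):
    tx = model.predominant_transcript()
    utrs = index.utrs(model.gene)
    if region == "CDS":
        return list(tx.cds)
    if region == "UTR5":
        return list(utrs.utr5)
    if region == "UTR3":
        return list(utrs.utr3)
    if region == "intron":
        s, e = model.span
        exonic = sorted(tx.exons)
        out, cur = [], s
        for es, ee in exonic:
            if cur < es:
                out.append((cur, es))
            cur = max(cur, ee)
        return out
    if region == "intergenic":
        s, e = model.span
        return [(10, s - 10), (e + 10, contig_len - 10)]
    raise SimulationError(f"unknown region {region!r}")


def _place_event(
    ev: PlannedEvent,
    model: GeneModel,
    index: RegionIndex,
    seq: str,
    repeat_loci: list,
    used: set[tuple[int, int]],
    rng: np.random.Generator,
) -> tuple[int, str, str, str]:
    """Choose a locus and construct normalized (pos, ref, alt)."""
    margin = 5
    pad = ev.length + 2
    if ev.mechanism == "repeat_unit":
        candidates = [(p, unit, n) for p, unit, n in repeat_loci if unit == ev.length]
        if not candidates:
            raise SimulationError(f"no embedded repeat of unit {ev.length} for {ev}")
        p, unit, _n = candidates[rng.integers(len(candidates))]
        pos0 = p + unit  # delete the second unit; identical unit precedes it
        _hap, ref, alt = plant_large_indel(seq, pos0, "del", unit, "repeat_unit")
        npos, nref, nalt = normalize_indel(seq, pos0 - 1, ref, alt)
        used.add((npos - pad, npos + pad))
        return npos, nref, nalt, "repeat_unit"
    intervals = _region_intervals(model, index, len(seq), ev.region)
    for _attempt in range(200):
        s, e = intervals[rng.integers(len(intervals))]
        if e - s <= 2 * (margin + pad):
            continue
        pos0 = int(rng.integers(s + margin + pad, e - margin - pad))
        claim = (pos0 - pad, pos0 + pad)
        if any(a < claim[1] and claim[0] < b for a, b in used):
            continue
        if ev.kind == "SNV":
            ref = seq[pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            used.add(claim)
            return pos0, ref, alt, "substitution"
        if ev.kind == "del":
            rule = "random"
            _hap, ref, alt = plant_large_indel(seq, pos0, "del", ev.length, rule, rng)
            mech = "random"
        else:
            rule = "tandem" if ev.mechanism == "tandem" else "random"
            _hap, ref, alt = plant_large_indel(seq, pos0, "ins", ev.length, rule, rng)
            mech = rule
        npos, nref, nalt = normalize_indel(seq, pos0 - 1, ref, alt)
        # reject placements whose normalized form collides with a prior event
        if any(a < npos + pad and npos - pad < b for a, b in used):
            continue
        used.add((npos - pad, npos + pad))
        return npos, nref, nalt, mech
    raise SimulationError(f"could not place event {ev} without overlap")


def _spanning_reads(
    seq: str,
    ev_pos: int,
    ref: str,
    alt: str,
    depth: int,
    af: float,
    read_len: int,
    anchor: int,
    duplicate_rate: float,
    rng: np.random.Generator,
    tag: str,
) -> list[tuple[str, str]]:
    """Unaligned reads from the mutant haplotype spanning a large indel."""
    if len(ref) > len(alt):  # deletion
        d = len(ref) - len(alt)
        b = ev_pos + 1
        hap = seq[:b] + seq[b + d :]
        junction = b
        ins_len = 0
    else:
        ins_len = len(alt) - len(ref)
        b = ev_pos + 1
        hap = seq[:b] + alt[1:] + seq[b:]
        junction = b
    window = read_len - 2 * anchor - ins_len
    if window <= 0:
        return []
    n_span = int(rng.binomial(depth, min(1.0, af * window / read_len)))
    lo = max(0, junction + ins_len + anchor - read_len)
    hi = min(junction - anchor, len(hap) - read_len)
    if hi < lo:
        return []
    out = []
    starts = rng.integers(lo, hi + 1, size=n_span)
    for k, s in enumerate(sorted(starts.tolist())):
        rseq = hap[s : s + read_len]
        if rng.random() < 0.5:
            rseq = rseq.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        rid = f"{tag}:f{k}:s{s}"
        out.append((rid, rseq))
        if rng.random() < duplicate_rate:
            out.append((f"{rid}:dup", rseq))
    return out


def simulate_cohort(config: SimConfig) -> Cohort:
    """Generate the full synthetic cohort for one configuration.

    All randomness flows from ``config.seed``; rerunning with the same
    config is bit-reproducible. Planted events overlapping at the same
    locus in one sample are rejected during placement with a diagnostic.
    """
    rng = np.random.default_rng(config.seed)
    structures = config.gene_structure or default_gene_structures(
        config.n_genes, config.hypermut_gene
    )
    if len(structures) != config.n_genes:
        raise SimulationError("gene_structure length must equal n_genes")

    reference: dict[str, str] = {}
    models: list[GeneModel] = []
    repeat_loci: dict[str, list] = {}
    for gs in structures:
        seq, model, loci = _build_gene(rng, gs)
        reference[model.chrom] = seq
        models.append(model)
        repeat_loci[model.chrom] = loci
    index = RegionIndex(models)

    # --- samples and metadata
    n_cf = config.n_patients * config.timepoints_per_patient
    if config.ctdna_fractions is not None:
        ctdna = np.asarray(config.ctdna_fractions, dtype=float)
        if ctdna.shape != (n_cf,):
            raise SimulationError(f"ctdna_fractions must have length {n_cf}")
        if np.any((ctdna < 0) | (ctdna > 1)):
            raise SimulationError("ctdna_fractions must lie in [0, 1]")
    else:
        ctdna = np.clip(rng.beta(2.0, 5.0, size=n_cf), 0.025, 0.9)
    rows = []
    k = 0
    for p in range(config.n_patients):
        pid = f"P{p + 1:03d}"
        for t in range(config.timepoints_per_patient):
            rows.append((f"{pid}-cf{t + 1}", pid, t + 1, "cfDNA", float(ctdna[k])))
            k += 1
        rows.append((f"{pid}-wbc", pid, 0, "WBC", 0.0))
    samples = pd.DataFrame(
        rows, columns=["sample_id", "patient_id", "timepoint", "type", "ctdna_fraction"]
    )

    # --- plan somatic events and assign patients
    spec = config.somatic_spec
    if spec is None:
        spec = standard_somatic_spec(config, rng)
    by_gene: dict[int, list[PlannedEvent]] = {}
    for ev in spec:
        if ev.gene >= config.n_genes:
            raise SimulationError(f"event references gene {ev.gene} >= n_genes")
        by_gene.setdefault(ev.gene, []).append(ev)
    for g, evs in by_gene.items():
        unassigned = [e for e in evs if e.patient is None]
        if not unassigned:
            continue
        if config.n_patients == 0:
            raise SimulationError("events planned but cohort has no patients")
        # one event per patient where possible (keeps planted patient
        # prevalence exact); small cohorts may stack events per patient
        replace = len(unassigned) > config.n_patients
        chosen = rng.choice(config.n_patients, size=len(unassigned), replace=replace)
        for e, p in zip(unassigned, chosen.tolist()):
            e.patient = p

    # place every event on its gene's contig (per patient overlap guard)
    placed: dict[int, list] = {p: [] for p in range(config.n_patients)}
    used_per_patient: dict[int, set] = {p: set() for p in range(config.n_patients)}
    for g, evs in sorted(by_gene.items()):
        model = models[g]
        seq = reference[model.chrom]
        for ev in evs:
            pos, ref, alt, mech = _place_event(
                ev, model, index, seq, repeat_loci[model.chrom],
                used_per_patient[ev.patient], rng,
            )
            placed[ev.patient].append((ev, model, pos, ref, alt, mech))

    # --- germline SNPs per patient
    germline: dict[int, list[tuple[str, int, str]]] = {}
    for p in range(config.n_patients):
        sites = []
        for chrom, seq in reference.items():
            mask = rng.random(len(seq)) < config.germline_snp_rate
            for pos in np.nonzero(mask)[0].tolist():
                ref = seq[pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                sites.append((chrom, pos, alt))
        germline[p] = sites

    # --- per-sample pileups
    pileups: dict[str, dict[str, ContigPileup]] = {}
    split_reads: dict[str, list[tuple[str, str]]] = {}
    truth_rows: list[PlantedTruth] = []
    err3 = config.per_base_error / 3.0
    ref_idx = {
        chrom: np.array([_BASE_IDX[b] for b in seq], dtype=np.int8)
        for chrom, seq in reference.items()
    }

    for _, srow in samples.iterrows():
        sid = srow.sample_id
        pnum = int(srow.patient_id[1:]) - 1
        sp: dict[str, ContigPileup] = {}
        for chrom, seq in reference.items():
            L = len(seq)
            depth = rng.poisson(config.panel_depth_mean, size=L).astype(np.int32)
            alt = np.empty((4, L), dtype=np.int16)
            for b_i in range(4):
                alt[b_i] = rng.binomial(depth, err3)
            alt[ref_idx[chrom], np.arange(L)] = 0
            sp[chrom] = ContigPileup(depth, alt)
        # germline het SNPs in both cfDNA and WBC
        for chrom, pos, galt in germline[pnum]:
            cp = sp[chrom]
            cp.alt[_BASE_IDX[galt], pos] = rng.binomial(cp.depth[pos], 0.5)
        if srow.type == "WBC" and config.wbc_indel_noise_rate > 0:
            total = sum(len(s) for s in reference.values())
            n_noise = rng.poisson(config.wbc_indel_noise_rate * total)
            chroms = sorted(reference)
            for _ in range(n_noise):
                chrom = chroms[rng.integers(len(chroms))]
                seq = reference[chrom]
                pos = int(rng.integers(1, len(seq) - 2))
                npos, nref, nalt = normalize_indel(seq, pos - 1, seq[pos - 1 : pos + 1], seq[pos - 1])
                key = (npos, nref, nalt)
                cp = sp[chrom]
                cp.indels[key] = cp.indels.get(key, 0) + int(rng.integers(1, 4))
        # planted somatic events, cfDNA only
        if srow.type == "cfDNA":
            reads_out: list[tuple[str, str]] = []
            for ev, model, pos, ref, alt_allele, mech in placed[pnum]:
                if ev.timepoints != "all" and srow.timepoint not in ev.timepoints:
                    continue
                af = srow.ctdna_fraction * ev.clonality / 2.0
                chrom = model.chrom
                cp = sp[chrom]
                seq = reference[chrom]
                indel_len = abs(len(ref) - len(alt_allele))
                if ev.kind == "SNV":
                    n = rng.binomial(cp.depth[pos], af)
                    cp.alt[_BASE_IDX[alt_allele], pos] = n
                    channel = "pileup"
                elif indel_len <= config.max_pileup_indel:
                    key = (pos, ref, alt_allele)
                    cp.indels[key] = cp.indels.get(key, 0) + int(rng.binomial(cp.depth[pos], af))
                    channel = "pileup"
                else:
                    reads_out.extend(
                        _spanning_reads(
                            seq, pos, ref, alt_allele, int(cp.depth[pos]), af,
                            config.read_length, 30, config.duplicate_rate, rng,
                            tag=f"{sid}:{model.gene}:{pos}",
                        )
                    )
                    channel = "split"
                truth_rows.append(
                    PlantedTruth(
                        srow.patient_id, sid, chrom, pos, ref, alt_allele,
                        ev.kind, indel_len if ev.kind != "SNV" else 0,
                        ev.clonality, af, ev.region, model.gene, mech, channel,
                    )
                )
            split_reads[sid] = reads_out
        pileups[sid] = sp

    truth = pd.DataFrame([dataclasses.asdict(t) for t in truth_rows])
    if truth.empty:
        truth = pd.DataFrame(
            columns=[f.name for f in dataclasses.fields(PlantedTruth)]
        )
    return Cohort(
        config, reference, models, samples, pileups, split_reads, truth,
        repeat_loci, ref_idx,
    )


# ---------------------------------------------------------------------------
# on-disk form (all plain text)

def _write_fasta(reference: Mapping[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(reference):
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_cohort(cohort: Cohort, outdir: str, write_pileups: bool = True) -> None:
    """Write the cohort as FASTA + GFF3 + TSV (metadata, truth, pileups,
    unaligned split reads). Rerunning with the same config produces
    byte-identical files."""
    import os

    os.makedirs(outdir, exist_ok=True)
    _write_fasta(cohort.reference, os.path.join(outdir, "reference.fa"))
    write_gff3(cohort.models, os.path.join(outdir, "genes.gff3"))
    cohort.samples.to_csv(os.path.join(outdir, "samples.tsv"), sep="\t", index=False)
    cohort.truth.to_csv(os.path.join(outdir, "truth.tsv"), sep="\t", index=False)
    with open(os.path.join(outdir, "unaligned_reads.tsv"), "w") as fh:
        fh.write("sample_id\tread_id\tseq\n")
        for sid in sorted(cohort.split_reads):
            for rid, seq in cohort.split_reads[sid]:
                fh.write(f"{sid}\t{rid}\t{seq}\n")
    if not write_pileups:
        return
    pdir = os.path.join(outdir, "pileups")
    os.makedirs(pdir, exist_ok=True)
    for sid in sorted(cohort.pileups):
        sp = cohort.pileups[sid]
        with open(os.path.join(pdir, f"{sid}.tsv"), "w") as fh:
            fh.write("chrom\tpos\tref\tdepth\talleles\n")
            for chrom in sorted(sp):
                cp = sp[chrom]
                seq = cohort.reference[chrom]
                indels_by_pos: dict[int, list] = {}
                for (pos, iref, ialt), n in sorted(cp.indels.items()):
                    indels_by_pos.setdefault(pos, []).append((iref, ialt, n))
                nz = np.nonzero(cp.alt.sum(axis=0))[0]
                interesting = sorted(set(nz.tolist()) | set(indels_by_pos))
                for pos in interesting:
                    parts = []
                    for b_i in range(4):
                        n = int(cp.alt[b_i, pos])
                        if n:
                            parts.append(f"{'ACGT'[b_i]}={n}")
                    for iref, ialt, n in indels_by_pos.get(pos, []):
                        parts.append(f"{iref}>{ialt}={n}")
                    fh.write(
                        f"{chrom}\t{pos}\t{seq[pos]}\t{int(cp.depth[pos])}\t"
                        f"{';'.join(parts) if parts else '.'}\n"
                    )
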