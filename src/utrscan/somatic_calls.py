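"""Five-condition somatic mutation caller with a WBC-cohort background model.

A candidate allele in a cfDNA sample is called somatic iff all of:

1. allele fraction >= ``min_af`` (default 1%),
2. supporting reads >= ``min_alt_reads`` (default 10),
3. allele fraction >= ``bg_ratio`` (25) x the background error rate, the
   average allele fraction across all WBC samples of the cohort,
4. allele fraction >= ``wbc_ratio`` (3) x the allele fraction in the same
   patient's WBC sample,
5. the paired WBC sample has >= ``min_wbc_depth`` (20) reads at the site.

Each condition is evaluated and reported individually so filtered
candidates can be audited.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .pileup import Allele, PileupColumn

logger = logging.getLogger(__name__)

__all__ = [
    "CallerThresholds",
    "BackgroundModel",
    "SomaticCall",
    "call_somatic",
    "evaluate_allele",
    "write_vcf",
    "read_vcf_calls",
]

FILTER_NAMES = ("min_af", "min_alt_reads", "bg_ratio", "wbc_ratio", "wbc_depth")


@dataclass(frozen=True)
class CallerThresholds:
    min_af: float = 0.01
    min_alt_reads: int = 10
    bg_ratio: float = 25.0
    wbc_ratio: float = 3.0
    min_wbc_depth: int = 20


class BackgroundModel:
    """Cohort-wide background error rate per site and allele.

    The background allele fraction is computed from WBC samples only, with
    a single pseudocount on both counts:

        bg_af = (total alt reads across WBC cohort + 1) / (total WBC depth + 1)

    so an allele never observed in any WBC sample still has a small,
    depth-dependent positive background instead of an exact zero (which
    would make the 25x condition vacuous), and a site with no WBC coverage
    at all has background 1.0, blocking calls there.
    """

    def __init__(self) -> None:
        self._depth: dict[tuple[str, int], int] = {}
        self._alt: dict[tuple[str, int, Allele], int] = {}
        self._warned_contigs: set[str] = set()

    @classmethod
    def from_wbc_pileups(
        cls, pileups: Iterable[dict[str, dict[int, PileupColumn]]]
    ) -> "BackgroundModel":
        bg = cls()
        for sample in pileups:
            for chrom, cols in sample.items():
                for pos, col in cols.items():
                    bg.add_site(chrom, pos, col.depth, col.allele_counts)
        return bg

    def add_site(self, chrom: str, pos: int, depth: int, allele_counts: Mapping[Allele, int]) -> None:
        key = (chrom, pos)
        self._depth[key] = self._depth.get(key, 0) + depth
        for allele, n in allele_counts.items():
            akey = (chrom, pos, allele)
            self._alt[akey] = self._alt.get(akey, 0) + n

    def cohort_depth(self, chrom: str, pos: int) -> int:
        return self._depth.get((chrom, pos), 0)

    def af(self, chrom: str, pos: int, allele: Allele) -> float:
        depth = self._depth.get((chrom, pos), 0)
        if depth == 0 and chrom not in self._warned_contigs:
            self._warned_contigs.add(chrom)
            logger.warning(
                "site %s:%d absent from background model; pseudocount rule "
                "yields background 1.0 (further sites on this contig not logged)",
                chrom, pos,
            )
        alt = self._alt.get((chrom, pos, allele), 0)
        return (alt + 1) / (depth + 1)

    # ------------------------------------------------------------------
    # TSV serialization: chrom, pos, allele, cohort_alt, cohort_depth

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("chrom\tpos\tallele\tcohort_alt\tcohort_depth\n")
            seen = set()
            for (chrom, pos, allele), alt in sorted(self._alt.items(), key=repr):
                desc = allele if isinstance(allele, str) else f"{allele[0]}>{allele[1]}"
                fh.write(f"{chrom}\t{pos}\t{desc}\t{alt}\t{self.cohort_depth(chrom, pos)}\n")
                seen.add((chrom, pos))
            for (chrom, pos), depth in sorted(self._depth.items()):
                if (chrom, pos) not in seen:
                    fh.write(f"{chrom}\t{pos}\t.\t0\t{depth}\n")

    @classmethod
    def from_tsv(cls, path: str) -> "BackgroundModel":
        bg = cls()
        with open(path) as fh:
            fh.readline()
            for line in fh:
                chrom, pos, desc, alt, depth = line.rstrip("\n").split("\t")
                key = (chrom, int(pos))
                bg._depth[key] = int(depth)
                if desc != ".":
                    allele: Allele = tuple(desc.split(">", 1)) if ">" in desc else desc
                    bg._alt[(chrom, int(pos), allele)] = int(alt)
        return bg


@dataclass
class SomaticCall:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    alt_reads: int
    depth: int
    af: float
    background_af: float
    wbc_af: float
    wbc_depth: int
    filters: dict[str, bool] = field(default_factory=dict)
    sample: str | None = None
    region: str | None = None
    gene: str | None = None

    @property
    def passed(self) -> bool:
        return all(self.filters.get(n, False) for n in FILTER_NAMES)


def _allele_ref_alt(col: PileupColumn, allele: Allele) -> tuple[str, str]:
    if isinstance(allele, str):
        return col.ref_base, allele
    return allele


def evaluate_allele(
    cf_col: PileupColumn,
    allele: Allele,
    wbc_col: PileupColumn | None,
    background: BackgroundModel,
    thresholds: CallerThresholds = CallerThresholds(),
) -> SomaticCall:
    """Evaluate the five somatic-call conditions for one allele at one site."""
    alt_reads = cf_col.allele_counts.get(allele, 0)
    af = cf_col.af(allele)
    wbc_depth = wbc_col.depth if wbc_col is not None else 0
    wbc_af = wbc_col.af(allele) if wbc_col is not None else 0.0
    bg = background.af(cf_col.chrom, cf_col.pos, allele)
    ref, alt = _allele_ref_alt(cf_col, allele)
    filters = {
        "min_af": af >= thresholds.min_af,
        "min_alt_reads": alt_reads >= thresholds.min_alt_reads,
        "bg_ratio": af >= thresholds.bg_ratio * bg,
        "wbc_ratio": af >= thresholds.wbc_ratio * wbc_af,
        "wbc_depth": wbc_depth >= thresholds.min_wbc_depth,
    }
    return SomaticCall(
        cf_col.chrom, cf_col.pos, ref, alt, alt_reads, cf_col.depth,
        af, bg, wbc_af, wbc_depth, filters,
    )


def call_somatic(
    cfdna: dict[str, dict[int, PileupColumn]],
    wbc: dict[str, dict[int, PileupColumn]],
    background: BackgroundModel,
    thresholds: CallerThresholds = CallerThresholds(),
    keep_filtered: bool = False,
) -> list[SomaticCall]:
    """Run the five-condition caller over a sample's pileup.

    Every allele at every cfDNA column is evaluated independently
    (multi-allelic sites yield one record per allele). Only calls passing
    all five conditions are returned unless ``keep_filtered`` is set, in
    which case failed candidates are included with their per-condition
    flags for auditing.
    """
    out: list[SomaticCall] = []
    for chrom in sorted(cfdna):
        wbc_chrom = wbc.get(chrom, {})
        for pos in sorted(cfdna[chrom]):
            col = cfdna[chrom][pos]
            if not col.allele_counts:
                continue
            wbc_col = wbc_chrom.get(pos)
            for allele in sorted(col.allele_counts, key=repr):
                call = evaluate_allele(col, allele, wbc_col, background, thresholds)
                if call.passed or keep_filtered:
                    out.append(call)
    return out


# ---------------------------------------------------------------------------
# VCF 4.2 output

# one record per allele, so every INFO field is scalar
_VCF_INFO = (
    ('AF', '1', 'Float', 'Alternate allele fraction in cfDNA'),
    ('ALT_READS', '1', 'Integer', 'Reads supporting the alternate allele'),
    ('DP', '1', 'Integer', 'cfDNA read depth at site'),
    ('BG_AF', '1', 'Float', 'Cohort WBC background allele fraction (pseudocounted)'),
    ('WBC_AF', '1', 'Float', 'Allele fraction in the paired WBC sample'),
    ('WBC_DP', '1', 'Integer', 'Paired WBC depth at site'),
    ('REGION', '1', 'String', 'Region class (CDS/UTR5/UTR3/intron/intergenic)'),
    ('GENE', '1', 'String', 'Gene symbol'),
)


def _fmt(x: float) -> str:
    return repr(float(x))  # shortest round-trip representation


def write_vcf(
    calls: list[SomaticCall],
    path: str,
    reference: Mapping[str, str] | None = None,
    sample: str | None = None,
) -> None:
    """Write passing calls as VCF 4.2 (1-based positions).

    Calls must be sorted by (chrom, pos); unsorted input is an error, not
    silently reordered. INFO carries all five filter quantities so a
    round-trip read-back reproduces them exactly.
    """
    order = [(c.chrom, c.pos) for c in calls]
    if order != sorted(order):
        raise ValueError("calls must be sorted by (chrom, pos)")
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=utrscan\n")
        if sample:
            fh.write(f"##utrscan_sample={sample}\n")
        if reference:
            for name in sorted(reference):
                fh.write(f"##contig=<ID={name},length={len(reference[name])}>\n")
        for key, num, typ, desc in _VCF_INFO:
            fh.write(f'##INFO=<ID={key},Number={num},Type={typ},Description="{desc}">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            info = (
                f"AF={_fmt(c.af)};ALT_READS={c.alt_reads};DP={c.depth};"
                f"BG_AF={_fmt(c.background_af)};WBC_AF={_fmt(c.wbc_af)};"
                f"WBC_DP={c.wbc_depth}"
            )
            if c.region:
                info += f";REGION={c.region}"
            if c.gene:
                info += f";GENE={c.gene}"
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref}\t{c.alt}\t.\tPASS\t{info}\n"
            )


def read_vcf_calls(path: str) -> list[SomaticCall]:
    """Read back a utrscan VCF into SomaticCall records."""
    out: list[SomaticCall] = []
    sample = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("##utrscan_sample="):
                sample = line.rstrip("\n").split("=", 1)[1]
                continue
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _flt, info = line.rstrip("\n").split("\t")[:8]
            kv = dict(p.split("=", 1) for p in info.split(";"))
            call = SomaticCall(
                chrom, int(pos) - 1, ref, alt,
                int(kv["ALT_READS"]), int(kv["DP"]), float(kv["AF"]),
                float(kv["BG_AF"]), float(kv["WBC_AF"]), int(kv["WBC_DP"]),
                {n: True for n in FILTER_NAMES},
                sample=sample, region=kv.get("REGION"), gene=kv.get("GENE"),
            )
            out.append(call)
    return out
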