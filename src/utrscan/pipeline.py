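"""End-to-end cohort pipeline and gene x region summary reports.

Composes the stages over a simulated (or loaded) cohort: WBC-cohort
background estimation, five-condition somatic calling per cfDNA sample,
split-read large-indel detection, region classification and consequence
annotation, ctDNA-corrected allele fractions, per-gene/region counts and
coverage-normalized rates, patient-level prevalence, and longitudinal
clone trajectories.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import mutstats
from .large_indels import KmerIndex, detect_large_indels
from .pileup import PileupColumn, normalize_indel
from .regions import GeneModel, RegionIndex, classify_variant, consequence, mutation_rate
from .simulate import Cohort, SimConfig, simulate_cohort, _BASE_IDX
from .somatic_calls import CallerThresholds, SomaticCall, call_somatic

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run_pipeline", "analyze_cohort", "summarize_by_gene_region"]

TABLE_COLUMNS = [
    "sample_id", "patient_id", "timepoint", "ctdna_fraction",
    "chrom", "pos", "ref", "alt", "gene", "region", "consequence",
    "kind", "length", "alt_reads", "depth", "af", "corrected_af",
    "background_af", "wbc_af", "wbc_depth", "channel",
]


class _ArrayBackground:
    """WBC-cohort background over the simulator's array pileups.

    Same pseudocount rule as :class:`somatic_calls.BackgroundModel`:
    (cohort alt reads + 1) / (cohort depth + 1).
    """

    def __init__(self, cohort: Cohort, wbc_ids: list[str]):
        ref = cohort.reference
        self.depth = {c: np.zeros(len(s), dtype=np.int64) for c, s in ref.items()}
        self.alt = {c: np.zeros((4, len(s)), dtype=np.int64) for c, s in ref.items()}
        self.indels: dict[tuple[str, int, str, str], int] = {}
        for sid in wbc_ids:
            for chrom, cp in cohort.pileups[sid].items():
                self.depth[chrom] += cp.depth
                self.alt[chrom] += cp.alt
                for (pos, iref, ialt), n in cp.indels.items():
                    key = (chrom, pos, iref, ialt)
                    self.indels[key] = self.indels.get(key, 0) + n

    def cohort_depth(self, chrom: str, pos: int) -> int:
        return int(self.depth[chrom][pos])

    def af(self, chrom: str, pos: int, allele) -> float:
        depth = int(self.depth[chrom][pos])
        if isinstance(allele, str):
            alt = int(self.alt[chrom][_BASE_IDX[allele], pos])
        else:
            alt = self.indels.get((chrom, pos, allele[0], allele[1]), 0)
        return (alt + 1) / (depth + 1)


def _candidate_sites(cohort: Cohort, sid: str, thresholds: CallerThresholds):
    """Sites passing the two monotone necessary conditions (allele support
    and allele fraction) for at least one allele; the full five-condition
    caller then decides. Purely an equivalent-output pruning step."""
    sites = []
    sp = cohort.pileups[sid]
    for chrom in sorted(sp):
        cp = sp[chrom]
        depth = np.maximum(cp.depth, 1)
        support = cp.alt >= thresholds.min_alt_reads
        fraction = cp.alt >= thresholds.min_af * depth
        hits = np.nonzero((support & fraction).any(axis=0))[0]
        sites.extend((chrom, int(p)) for p in hits)
        for (pos, _ref, _alt), n in cp.indels.items():
            d = max(int(cp.depth[pos]), 1)
            if n >= thresholds.min_alt_reads and n >= thresholds.min_af * d:
                sites.append((chrom, pos))
    return sorted(set(sites))


@dataclass
class PipelineResult:
    cohort: Cohort
    table: pd.DataFrame  # one row per (variant, sample)
    summary: pd.DataFrame  # gene x region x kind counts + rates + prevalence
    region_rates: pd.DataFrame  # per region class across the panel
    trajectories: list
    logs: dict = field(default_factory=dict)


def _call_kind(ref: str, alt: str) -> tuple[str, int]:
    if len(ref) == len(alt) == 1:
        return "sub", 0
    if len(ref) > len(alt):
        return "del", len(ref) - len(alt)
    return "ins", len(alt) - len(ref)


def _depth_track(cohort: Cohort, eligible_cf: list[str]) -> dict[str, np.ndarray]:
    """Pooled (mean over eligible cfDNA samples) per-position depth."""
    track = {c: np.zeros(len(s)) for c, s in cohort.reference.items()}
    for sid in eligible_cf:
        for chrom, cp in cohort.pileups[sid].items():
            track[chrom] += cp.depth
    n = max(len(eligible_cf), 1)
    return {c: v / n for c, v in track.items()}


def analyze_cohort(
    cohort: Cohort,
    thresholds: CallerThresholds = CallerThresholds(),
    depth_floor: int = 200,
    ctdna_floor: float = 0.02,
    clone_min_ctdna: float = 0.05,
    min_fragments: int = 3,
    max_indel_len: int = 500,
) -> PipelineResult:
    """Run calling, annotation and summaries over an in-memory cohort."""
    models = cohort.models
    index = RegionIndex(models)
    model_by_gene = {m.gene: m for m in models}
    samples = cohort.samples
    wbc_by_patient = {
        r.patient_id: r.sample_id for r in samples.itertuples() if r.type == "WBC"
    }
    cf_samples = [r for r in samples.itertuples() if r.type == "cfDNA"]
    logs: dict = {"skipped_samples": [], "filter_fail_counts": dict.fromkeys(
        ("min_af", "min_alt_reads", "bg_ratio", "wbc_ratio", "wbc_depth"), 0
    ), "n_candidates": 0}

    wbc_ids = sorted(wbc_by_patient.values())
    background = _ArrayBackground(cohort, wbc_ids)
    kmer_index = (
        KmerIndex(cohort.reference, 30)
        if any(cohort.split_reads.get(r.sample_id) for r in cf_samples)
        else None
    )

    rows = []
    for r in cf_samples:
        sid = r.sample_id
        wbc_sid = wbc_by_patient.get(r.patient_id)
        if wbc_sid is None:
            logger.warning("no WBC pair for %s; sample skipped", sid)
            logs["skipped_samples"].append(sid)
            continue
        sites = _candidate_sites(cohort, sid, thresholds)
        logs["n_candidates"] += len(sites)
        cf_cols = cohort.pileup_columns(sid, sites)
        wbc_cols = cohort.pileup_columns(wbc_sid, sites)
        calls = call_somatic(cf_cols, wbc_cols, background, thresholds, keep_filtered=True)
        passed: list[tuple[SomaticCall, str]] = []
        for c in calls:
            if c.passed:
                passed.append((c, "pileup"))
            else:
                for name, ok in c.filters.items():
                    if not ok:
                        logs["filter_fail_counts"][name] += 1
        # split-read channel for large indels
        reads = cohort.split_reads.get(sid) or []
        if reads and kmer_index is not None:
            for ev in detect_large_indels(
                reads, cohort.reference, index=kmer_index,
                min_fragments=min_fragments, max_len=max_indel_len,
            ):
                seq = cohort.reference[ev.chrom]
                if ev.kind == "deletion":
                    p0 = ev.pos - 1
                    ref = seq[p0 : ev.pos + ev.length]
                    alt = seq[p0]
                else:
                    p0 = ev.pos - 1
                    ref = seq[p0]
                    alt = seq[p0] + (ev.sequence or "")
                    if not ev.sequence:
                        continue
                npos, nref, nalt = normalize_indel(seq, p0, ref, alt)
                cp = cohort.pileups[sid][ev.chrom]
                depth = int(cp.depth[npos])
                window = cohort.config.read_length - 60 - (ev.length if ev.kind == "insertion" else 0)
                eff = max(depth * window / cohort.config.read_length, 1.0)
                af = min(ev.unique_fragments / eff, 1.0)
                passed.append((
                    SomaticCall(
                        ev.chrom, npos, nref, nalt, ev.unique_fragments, depth,
                        af, 0.0, 0.0, 0,
                        {n: True for n in ("min_af", "min_alt_reads", "bg_ratio",
                                           "wbc_ratio", "wbc_depth")},
                    ),
                    "split",
                ))
        for c, channel in passed:
            kind, length = _call_kind(c.ref, c.alt)
            corr = mutstats.corrected_af(c.af, r.ctdna_fraction, floor=ctdna_floor)
            vstart, vend = c.pos, c.pos + max(len(c.ref), 1)
            for gene, region in classify_variant(c.chrom, vstart, vend, index):
                if gene is None:
                    cons = "intergenic"
                else:
                    cons = consequence(
                        c.chrom, c.pos, c.ref, c.alt, model_by_gene[gene],
                        cohort.reference, index,
                    )
                rows.append(
                    (sid, r.patient_id, r.timepoint, r.ctdna_fraction,
                     c.chrom, c.pos, c.ref, c.alt, gene, region, cons,
                     kind, length, c.alt_reads, c.depth, c.af, corr.corrected,
                     c.background_af, c.wbc_af, c.wbc_depth, channel)
                )
    table = pd.DataFrame(rows, columns=TABLE_COLUMNS)

    eligible_cf = [
        r.sample_id for r in cf_samples if r.ctdna_fraction > ctdna_floor
    ]
    depth_track = _depth_track(cohort, eligible_cf)
    summary, region_rates = summarize_by_gene_region(
        table, samples, models, depth_track, depth_floor, ctdna_floor
    )

    trajectories = []
    if (samples[samples["type"] == "cfDNA"].groupby("patient_id")["timepoint"].nunique() >= 2).any():
        obs = _clone_observations(cohort, table, clone_min_ctdna)
        if not obs.empty:
            trajectories = mutstats.track_clones(obs, min_ctdna=clone_min_ctdna)

    return PipelineResult(cohort, table, summary, region_rates, trajectories, logs)


def _clone_observations(cohort: Cohort, table: pd.DataFrame, min_ctdna: float) -> pd.DataFrame:
    """Per (patient, mutation, timepoint) detection evidence for clone
    tracking, including timepoints where the mutation was not called."""
    if table.empty:
        return pd.DataFrame()
    cf = cohort.samples[cohort.samples["type"] == "cfDNA"]
    muts = table.drop_duplicates(subset=["patient_id", "chrom", "pos", "ref", "alt"])
    rows = []
    called_keys = {
        (t.sample_id, t.chrom, t.pos, t.ref, t.alt) for t in table.itertuples()
    }
    for m in muts.itertuples():
        patient_samples = cf[cf["patient_id"] == m.patient_id]
        for s in patient_samples.itertuples():
            cp = cohort.pileups[s.sample_id][m.chrom]
            depth = int(cp.depth[m.pos])
            if len(m.ref) == len(m.alt) == 1:
                reads = int(cp.alt[_BASE_IDX[m.alt], m.pos])
            else:
                reads = int(cp.indels.get((m.pos, m.ref, m.alt), 0))
            corr = mutstats.corrected_af(
                min(reads / max(depth, 1), 1.0), s.ctdna_fraction
            )
            rows.append(
                (m.patient_id, m.chrom, m.pos, m.ref, m.alt, s.timepoint,
                 s.ctdna_fraction,
                 (s.sample_id, m.chrom, m.pos, m.ref, m.alt) in called_keys,
                 reads, depth, corr.corrected)
            )
    return pd.DataFrame(
        rows,
        columns=["patient", "chrom", "pos", "ref", "alt", "timepoint",
                 "ctdna_fraction", "called", "supporting_reads", "depth",
                 "corrected_af"],
    )


def summarize_by_gene_region(
    table: pd.DataFrame,
    samples: pd.DataFrame,
    models: list[GeneModel],
    depth_track: dict[str, np.ndarray],
    depth_floor: int = 200,
    ctdna_floor: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Gene x region counts, coverage-normalized rates and patient
    prevalence, plus panel-wide per-region-class rates.

    A mutation seen at several timepoints of one patient counts once in
    the prevalence numerator (identity: chrom, pos, ref, alt after
    normalization); eligible patients are those with at least one
    ctDNA-positive cfDNA sample. Regions with zero covered megabases are
    flagged undefined rather than reported as 0.
    """
    index = RegionIndex(models)
    cf = samples[samples["type"] == "cfDNA"]
    eligible_patients = set(
        cf.loc[cf["ctdna_fraction"] > ctdna_floor, "patient_id"]
    )
    n_eligible = len(eligible_patients)

    def region_intervals(model: GeneModel, region: str):
        tx = model.predominant_transcript()
        utrs = index.utrs(model.gene)
        if region == "CDS":
            return [(model.chrom, s, e) for s, e in tx.cds]
        if region == "UTR5":
            return [(model.chrom, s, e) for s, e in utrs.utr5]
        if region == "UTR3":
            return [(model.chrom, s, e) for s, e in utrs.utr3]
        if region == "intron":
            s0, e0 = model.span
            exonic = sorted(tx.exons)
            out, cur = [], s0
            for es, ee in exonic:
                if cur < es:
                    out.append((model.chrom, cur, es))
                cur = max(cur, ee)
            if cur < e0:
                out.append((model.chrom, cur, e0))
            return out
        return []

    rows = []
    for model in models:
        for region in ("CDS", "UTR5", "UTR3", "intron"):
            sub = table[(table["gene"] == model.gene) & (table["region"] == region)] if not table.empty else table
            dedup = (
                sub.drop_duplicates(subset=["patient_id", "chrom", "pos", "ref", "alt"])
                if not sub.empty else sub
            )
            count = len(dedup)
            by_kind = dedup["kind"].value_counts().to_dict() if count else {}
            ivs = region_intervals(model, region)
            rate = mutation_rate(
                count, depth_track, ivs, samples, depth_floor, ctdna_floor,
                region=f"{model.gene}:{region}",
            )
            n_pat = dedup["patient_id"].nunique() if count else 0
            rows.append(
                (model.gene, region, count,
                 by_kind.get("sub", 0), by_kind.get("del", 0), by_kind.get("ins", 0),
                 rate.covered_mb, rate.n_samples, rate.rate, rate.undefined,
                 n_pat, n_pat / n_eligible if n_eligible else np.nan)
            )
    summary = pd.DataFrame(
        rows,
        columns=["gene", "region", "count", "n_sub", "n_del", "n_ins",
                 "covered_mb", "n_samples", "rate_per_mb_per_sample",
                 "rate_undefined", "n_patients", "patient_fraction"],
    )

    region_rows = []
    for region in ("CDS", "UTR5", "UTR3", "intron"):
        ivs = []
        for model in models:
            ivs.extend(region_intervals(model, region))
        sub = table[table["region"] == region] if not table.empty else table
        dedup = (
            sub.drop_duplicates(subset=["patient_id", "chrom", "pos", "ref", "alt"])
            if not sub.empty else sub
        )
        rate = mutation_rate(
            len(dedup), depth_track, ivs, samples, depth_floor, ctdna_floor,
            region=region,
        )
        region_rows.append(
            (region, len(dedup), rate.covered_mb, rate.n_samples, rate.rate,
             rate.undefined)
        )
    region_rates = pd.DataFrame(
        region_rows,
        columns=["region", "count", "covered_mb", "n_samples",
                 "rate_per_mb_per_sample", "rate_undefined"],
    )
    return summary, region_rates


def run_pipeline(
    config: SimConfig | dict,
    thresholds: CallerThresholds = CallerThresholds(),
    **kwargs,
) -> PipelineResult:
    """Simulate a cohort from ``config`` and analyze it end to end.

    Deterministic given the config (seed included): rerunning returns
    identical tables.
    """
    if isinstance(config, dict):
        config = SimConfig(**config)
    cohort = simulate_cohort(config)
    return analyze_cohort(cohort, thresholds=thresholds, **kwargs)
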