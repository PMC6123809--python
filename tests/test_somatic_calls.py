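"""The five-condition caller: oracle equivalence, boundaries, monotonicity,
germline specificity, and VCF round-trips."""

import numpy as np
import pytest

from utrscan.pileup import PileupColumn
from utrscan.somatic_calls import (
    BackgroundModel,
    CallerThresholds,
    SomaticCall,
    call_somatic,
    read_vcf_calls,
    write_vcf,
)


def column(pos, ref, depth, counts, chrom="c1"):
    return PileupColumn(chrom, pos, ref, depth, dict(counts))


def background_with(chrom, pos, allele, alt, depth):
    bg = BackgroundModel()
    bg.add_site(chrom, pos, depth, {allele: alt} if alt else {})
    return bg


def brute_force(cf_cols, wbc_cols, bg, th):
    """Independent literal application of the five inequalities."""
    out = set()
    for chrom, cols in cf_cols.items():
        for pos, col in cols.items():
            for allele, n in col.allele_counts.items():
                af = n / col.depth if col.depth else 0.0
                w = wbc_cols.get(chrom, {}).get(pos)
                wbc_af = (w.allele_counts.get(allele, 0) / w.depth) if w and w.depth else 0.0
                wbc_depth = w.depth if w else 0
                ok = (
                    af >= th.min_af
                    and n >= th.min_alt_reads
                    and af >= th.bg_ratio * bg.af(chrom, pos, allele)
                    and af >= th.wbc_ratio * wbc_af
                    and wbc_depth >= th.min_wbc_depth
                )
                if ok:
                    out.add((chrom, pos, allele))
    return out


def random_battery(seed, n=10_000):
    """Random pileup columns straddling all five thresholds."""
    rng = np.random.default_rng(seed)
    cf, wbc = {"c1": {}}, {"c1": {}}
    bg = BackgroundModel()
    for pos in range(n):
        depth = int(rng.integers(50, 1200))
        ref = "ACGT"[rng.integers(4)]
        col = column(pos, ref, depth, {})
        for allele in {"ACGT"[rng.integers(4)] for _ in range(rng.integers(0, 3))}:
            if allele != ref:
                col.allele_counts[allele] = int(rng.integers(0, 60))
        if rng.random() < 0.3:
            col.allele_counts[(ref + "A", ref)] = int(rng.integers(0, 40))
        cf["c1"][pos] = col
        wdepth = int(rng.integers(0, 200))
        wcol = column(pos, ref, wdepth, {})
        for allele in list(col.allele_counts):
            if rng.random() < 0.5 and wdepth:
                wcol.allele_counts[allele] = int(rng.integers(0, 8))
        wbc["c1"][pos] = wcol
        bg.add_site("c1", pos, int(rng.integers(0, 20_000)),
                    {a: int(rng.integers(0, 12)) for a in col.allele_counts
                     if rng.random() < 0.5})
    return cf, wbc, bg


class TestCaller:
    def test_clean_somatic_site_is_called(self):
        cf = {"c1": {10: column(10, "A", 800, {"T": 40})}}
        wbc = {"c1": {10: column(10, "A", 100, {})}}
        bg = background_with("c1", 10, "T", 2, 15_000)
        calls = call_somatic(cf, wbc, bg)
        assert len(calls) == 1
        c = calls[0]
        assert (c.ref, c.alt, c.alt_reads) == ("A", "T", 40)
        assert c.passed and all(c.filters.values())

    def test_nine_supporting_reads_fails_support_flag_only(self):
        cf = {"c1": {10: column(10, "A", 100, {"T": 9})}}
        wbc = {"c1": {10: column(10, "A", 100, {})}}
        bg = background_with("c1", 10, "T", 0, 15_000)
        calls = call_somatic(cf, wbc, bg, keep_filtered=True)
        assert len(calls) == 1
        assert not calls[0].passed
        assert calls[0].filters["min_alt_reads"] is False
        assert calls[0].filters["min_af"] is True

    def test_germline_het_snp_blocked_by_paired_wbc(self):
        cf = {"c1": {10: column(10, "A", 800, {"T": 390})}}
        wbc = {"c1": {10: column(10, "A", 750, {"T": 370})}}
        bg = background_with("c1", 10, "T", 370 * 20, 750 * 20)
        assert call_somatic(cf, wbc, bg) == []

    def test_site_missing_from_background_blocks_call(self):
        # pseudocount rule: no WBC coverage anywhere -> background 1.0
        cf = {"c1": {10: column(10, "A", 800, {"T": 400})}}
        wbc = {"c1": {10: column(10, "A", 100, {})}}
        assert call_somatic(cf, wbc, BackgroundModel()) == []

    def test_matches_brute_force_on_random_battery(self):
        cf, wbc, bg = random_battery(seed=17)
        th = CallerThresholds()
        got = {(c.chrom, c.pos, c.alt if len(c.ref) == 1 and len(c.alt) == 1
                else (c.ref, c.alt))
               for c in call_somatic(cf, wbc, bg, th)}
        assert got == brute_force(cf, wbc, bg, th)

    def test_raising_any_threshold_never_adds_a_call(self):
        cf, wbc, bg = random_battery(seed=29, n=2000)
        base = CallerThresholds()
        baseline = {(c.pos, repr(c.alt)) for c in call_somatic(cf, wbc, bg, base)}
        tighter = [
            CallerThresholds(min_af=0.02),
            CallerThresholds(min_alt_reads=15),
            CallerThresholds(bg_ratio=40),
            CallerThresholds(wbc_ratio=5),
            CallerThresholds(min_wbc_depth=50),
        ]
        for th in tighter:
            got = {(c.pos, repr(c.alt)) for c in call_somatic(cf, wbc, bg, th)}
            assert got <= baseline

    def test_multiallelic_site_evaluated_per_allele(self):
        cf = {"c1": {10: column(10, "A", 1000, {"T": 40, "G": 5})}}
        wbc = {"c1": {10: column(10, "A", 100, {})}}
        bg = BackgroundModel()
        bg.add_site("c1", 10, 20_000, {})
        calls = call_somatic(cf, wbc, bg)
        assert [c.alt for c in calls] == ["T"]


class TestBackgroundModel:
    def test_pseudocount_rule(self):
        bg = background_with("c1", 5, "T", 3, 10_000)
        assert bg.af("c1", 5, "T") == pytest.approx(4 / 10_001)
        assert bg.af("c1", 5, "G") == pytest.approx(1 / 10_001)

    def test_tsv_round_trip(self, tmp_path):
        bg = BackgroundModel()
        bg.add_site("c1", 5, 10_000, {"T": 3, ("TA", "T"): 2})
        bg.add_site("c1", 9, 8_000, {})
        path = str(tmp_path / "bg.tsv")
        bg.to_tsv(path)
        back = BackgroundModel.from_tsv(path)
        for allele in ("T", "G", ("TA", "T")):
            assert back.af("c1", 5, allele) == bg.af("c1", 5, allele)
        assert back.cohort_depth("c1", 9) == 8_000


class TestVcf:
    def make_calls(self):
        flags = dict.fromkeys(
            ("min_af", "min_alt_reads", "bg_ratio", "wbc_ratio", "wbc_depth"), True
        )
        return [
            SomaticCall("c1", 99, "A", "T", 40, 800, 0.05, 1 / 15001, 0.0, 100,
                        dict(flags), region="UTR3", gene="G1"),
            SomaticCall("c1", 150, "GAAC", "G", 22, 751, 22 / 751, 2e-4,
                        1 / 300, 300, dict(flags), region="CDS", gene="G1"),
        ]

    def test_zero_calls_yields_valid_header_only_vcf(self, tmp_path):
        path = str(tmp_path / "empty.vcf")
        write_vcf([], path, reference={"c1": "ACGT" * 100})
        lines = open(path).read().splitlines()
        assert lines[0] == "##fileformat=VCFv4.2"
        assert lines[-1].startswith("#CHROM")
        assert read_vcf_calls(path) == []

    def test_zero_based_pos_becomes_one_based(self, tmp_path):
        path = str(tmp_path / "one.vcf")
        write_vcf(self.make_calls()[:1], path)
        data = [l for l in open(path) if not l.startswith("#")]
        assert data[0].split("\t")[1] == "100"

    def test_round_trip_reproduces_filter_quantities_exactly(self, tmp_path):
        calls = self.make_calls()
        path = str(tmp_path / "rt.vcf")
        write_vcf(calls, path, reference={"c1": "A" * 500})
        back = read_vcf_calls(path)
        for orig, got in zip(calls, back):
            assert (got.chrom, got.pos, got.ref, got.alt) == (
                orig.chrom, orig.pos, orig.ref, orig.alt
            )
            assert got.af == orig.af
            assert got.background_af == orig.background_af
            assert got.wbc_af == orig.wbc_af
            assert (got.alt_reads, got.depth, got.wbc_depth) == (
                orig.alt_reads, orig.depth, orig.wbc_depth
            )

    def test_vcf_parsable_by_pysam(self, tmp_path):
        import pysam

        path = str(tmp_path / "p.vcf")
        write_vcf(self.make_calls(), path, reference={"c1": "A" * 500})
        with pysam.VariantFile(path) as vf:
            recs = list(vf)
        assert [r.pos for r in recs] == [100, 151]
        assert recs[0].info["ALT_READS"] == 40
        assert recs[0].info["AF"] == pytest.approx(0.05)

    def test_unsorted_input_rejected(self, tmp_path):
        calls = list(reversed(self.make_calls()))
        with pytest.raises(ValueError, match="sorted"):
            write_vcf(calls, str(tmp_path / "x.vcf"))
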