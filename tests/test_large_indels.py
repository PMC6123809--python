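"""Split-read large-indel detection: anchors, placement, clustering,
deduplication, and calling rules."""

import numpy as np
import pytest

from utrscan.large_indels import (
    BreakpointCluster,
    ClusterMember,
    KmerIndex,
    SplitStats,
    align_anchors,
    call_large_indels,
    cluster_discordant,
    dedupe_fragments,
    detect_large_indels,
    revcomp,
    split_reads,
)
from utrscan.simulate import plant_large_indel


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(101)
    return {"c1": "".join(rng.choice(list("ACGT"), size=8000))}


@pytest.fixture(scope="module")
def index(reference):
    return KmerIndex(reference, 30)


def spanning_reads(hap, junction, n, read_len=150, span_margin=0, prefix="r", step=None):
    """Reads from a mutant haplotype whose anchors flank the junction."""
    lo = junction + span_margin + 30 - read_len
    hi = junction - 30
    starts = np.linspace(lo, hi, n).astype(int) if step is None else [
        lo + i * step for i in range(n)
    ]
    return [(f"{prefix}{i}", hap[s : s + read_len]) for i, s in enumerate(starts)]


class TestSplitReads:
    def test_anchors_partition_the_read_ends(self):
        seq = "".join(np.random.default_rng(0).choice(list("ACGT"), size=150))
        [pair] = split_reads([("r", seq)])
        assert pair.seq[:30] + pair.seq[30:120] + pair.seq[-30:] == seq

    def test_short_read_skipped_with_counter(self):
        stats = SplitStats()
        out = split_reads([("short", "A" * 59), ("ok", "C" * 60)], stats=stats)
        assert [p.read_id for p in out] == ["ok"]
        assert stats.skipped_short == 1


class TestAlignAnchors:
    def test_unique_exact_match_placed(self, reference, index):
        seq = reference["c1"]
        pairs = split_reads([("r", seq[1000:1150])])
        [placed] = align_anchors(pairs, index)
        assert placed.five.pos == 1000
        assert placed.three.pos == 1120

    def test_reverse_complement_read_canonicalized(self, reference, index):
        seq = reference["c1"]
        pairs = split_reads([("r", revcomp(seq[1000:1150]))])
        [placed] = align_anchors(pairs, index)
        assert placed.five.pos == 1000 and placed.seq == seq[1000:1150]

    def test_ambiguous_anchor_dropped(self, reference):
        seq = reference["c1"]
        dup_ref = {"c1": seq + seq[1000:1060] + seq[4000:]}  # anchor occurs twice
        idx = KmerIndex(dup_ref, 30)
        stats = SplitStats()
        out = align_anchors(split_reads([("r", seq[1000:1150])]), idx, stats)
        assert out == [] and stats.dropped_unplaced == 1

    def test_single_mismatch_dropped_under_exact_matching(self, reference, index):
        seq = reference["c1"]
        read = seq[1000:1150]
        mutated = ("T" if read[10] != "T" else "G") .join([read[:10], read[11:]])
        stats = SplitStats()
        assert align_anchors(split_reads([("r", mutated)]), index, stats) == []
        assert stats.dropped_unplaced == 1


class TestClusterDiscordant:
    def test_concordant_pair_produces_no_cluster(self, reference, index):
        pairs = align_anchors(split_reads([("r", reference["c1"][1000:1150])]), index)
        assert cluster_discordant(pairs, reference) == []

    def test_five_reads_over_89bp_deletion_form_one_cluster(self, reference, index):
        hap, _, _ = plant_large_indel(reference["c1"], 3000, "del", 89)
        pairs = align_anchors(
            split_reads(spanning_reads(hap, 3000, 5)), index
        )
        clusters = cluster_discordant(pairs, reference)
        assert len(clusters) == 1
        cl = clusters[0]
        assert cl.kind == "deletion"
        assert cl.right_bp - cl.left_bp == 89
        assert len(cl.members) == 5

    def test_position_tolerance_semantics(self, reference):
        def member(lb):
            return ClusterMember("r", lb - 40, lb, lb + 50, None)

        # two signatures 3 bp apart: merged at tolerance 5, distinct at 0
        sigs = [(2000, member(2000)), (2003, member(2003))]

        def clusters_with(tol):
            out = []
            for lb, m in sigs:
                for cl in out:
                    if abs(cl.left_bp - lb) <= tol and abs(cl.right_bp - (lb + 50)) <= tol:
                        cl.members.append(m)
                        break
                else:
                    out.append(BreakpointCluster("c1", "deletion", lb, lb + 50, 50, [m]))
            return out

        assert len(clusters_with(5)) == 1
        assert len(clusters_with(0)) == 2


class TestDedupe:
    def test_unique_start_positions_counted(self):
        members = [ClusterMember("r", s, 100, 150, None) for s in (10, 10, 20, 20, 20, 30)]
        cl = BreakpointCluster("c1", "deletion", 100, 150, 50, members)
        assert dedupe_fragments(cl).unique_fragments == 3

    def test_all_identical_starts_collapse_to_one(self):
        members = [ClusterMember("r", 5, 100, 150, None) for _ in range(6)]
        cl = BreakpointCluster("c1", "deletion", 100, 150, 50, members)
        assert dedupe_fragments(cl).unique_fragments == 1

    def test_random_duplication_matches_set_cardinality(self):
        rng = np.random.default_rng(3)
        starts = rng.integers(0, 40, size=200).tolist()
        cl = BreakpointCluster(
            "c1", "deletion", 100, 150, 50,
            [ClusterMember("r", s, 100, 150, None) for s in starts],
        )
        assert dedupe_fragments(cl).unique_fragments == len(set(starts))


class TestCalling:
    def test_two_unique_fragments_not_called(self, reference, index):
        hap, _, _ = plant_large_indel(reference["c1"], 3000, "del", 50)
        reads = spanning_reads(hap, 3000, 2)
        reads.append((reads[0][0] + ":dup", reads[0][1]))  # duplicate fragment
        assert detect_large_indels(reads, reference, index=index) == []

    def test_600bp_deletion_excluded(self, reference, index):
        hap, _, _ = plant_large_indel(reference["c1"], 3000, "del", 500)
        hap600 = reference["c1"][:3000] + reference["c1"][3600:]
        ev500 = detect_large_indels(
            spanning_reads(hap, 3000, 8), reference, index=index
        )
        ev600 = detect_large_indels(
            spanning_reads(hap600, 3000, 8), reference, index=index
        )
        assert [e.length for e in ev500] == [500]
        assert ev600 == []

    def test_99bp_tandem_insertion_sequence_reconstructed(self, reference):
        # 250 bp reads so both anchors clear the 99 bp insert
        hap, _, alt = plant_large_indel(reference["c1"], 4000, "ins", 99, "tandem")
        reads = spanning_reads(hap, 4000, 8, read_len=250, span_margin=99)
        [ev] = detect_large_indels(reads, reference, max_len=500)
        assert ev.kind == "insertion" and ev.length == 99
        # left-aligned insertion point: one repeat unit upstream
        assert ev.pos == 4000 - 99
        assert ev.sequence == reference["c1"][3901:4000]
        assert ev.unique_fragments >= 3

    def test_postconditions_hold_on_random_event_battery(self, reference, index):
        rng = np.random.default_rng(8)
        seq = reference["c1"]
        events = []
        reads = []
        for i, pos in enumerate(range(500, 7000, 900)):
            length = int(rng.integers(31, 400))
            kind = "del" if i % 2 == 0 else "ins"
            if kind == "ins":
                length = min(length, 80)
            hap, _, _ = plant_large_indel(seq, pos, kind, length, "random", rng)
            margin = length if kind == "ins" else 0
            n = int(rng.integers(2, 10))
            reads.extend(
                spanning_reads(hap, pos, n, read_len=250, span_margin=margin,
                               prefix=f"e{i}_")
            )
            events.append((pos, kind, length, n))
        calls = detect_large_indels(reads, reference, index=index, max_len=500)
        for c in calls:
            assert c.unique_fragments >= 3
            assert 1 <= c.length <= 500
        called = {(c.kind, c.length) for c in calls}
        for pos, kind, length, n in events:
            full = {"del": "deletion", "ins": "insertion"}[kind]
            if n >= 3:
                assert (full, length) in called
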