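"""Statistical layer: exact tests against enumeration oracles, corrected
allele fractions, clone trajectory classification."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

from utrscan import mutstats


def fisher_oracle(a, b, c, d, method):
    """Exact-rational full enumeration of the conditional null."""
    r1, c1 = a + b, a + c
    n = a + b + c + d
    denom = math.comb(n, c1)
    lo, hi = max(0, c1 - (c + d)), min(r1, c1)
    probs = {
        k: Fraction(math.comb(r1, k) * math.comb(n - r1, c1 - k), denom)
        for k in range(lo, hi + 1)
    }
    p_obs = probs[a]
    if method == "minlike":
        return float(sum(p for p in probs.values() if p <= p_obs))
    left = sum(p for k, p in probs.items() if k <= a)
    right = sum(p for k, p in probs.items() if k >= a)
    return float(min(1, 2 * min(left, right)))


def binomial_oracle(count1, e1, count2, e2):
    n = count1 + count2
    p0 = Fraction(e1, e1 + e2)
    probs = [
        Fraction(math.comb(n, k)) * p0**k * (1 - p0) ** (n - k) for k in range(n + 1)
    ]
    return float(sum(p for p in probs if p <= probs[count1]))


class TestFisherExact:
    def test_two_balanced_tables(self):
        # only two tables share these margins, each with probability 1/2
        assert mutstats.fisher_exact([[1, 0], [0, 1]]) == pytest.approx(1.0)

    @pytest.mark.parametrize("method", ["minlike", "doubling"])
    def test_exhaustive_small_tables_match_enumeration(self, method):
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n + 1 - a):
                    for c in range(n + 1 - a - b):
                        d = n - a - b - c
                        t = [[a, b], [c, d]]
                        if min(a + b, c + d, a + c, b + d) == 0:
                            continue
                        expect = fisher_oracle(a, b, c, d, method)
                        got = mutstats.fisher_exact(t, method=method)
                        assert got == pytest.approx(expect, rel=1e-10, abs=1e-300)

    @pytest.mark.parametrize("method", ["minlike", "doubling"])
    def test_random_tables_margins_30_match_enumeration(self, method):
        rng = np.random.default_rng(11)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 31, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            expect = fisher_oracle(int(a), int(b), int(c), int(d), method)
            got = mutstats.fisher_exact([[a, b], [c, d]], method=method)
            assert got == pytest.approx(expect, rel=1e-12)

    def test_invariant_under_simultaneous_row_and_column_swap(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 40, size=4))
            p1 = mutstats.fisher_exact([[a, b], [c, d]])
            p2 = mutstats.fisher_exact([[d, c], [b, a]])
            assert p1 == pytest.approx(p2, rel=1e-9)

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            mutstats.fisher_exact([[0, 0], [5, 3]])


class TestBinomialRateTest:
    def test_perfectly_null_configuration(self):
        assert mutstats.binomial_rate_test(5, 1.0, 5, 1.0) == pytest.approx(1.0)

    def test_one_sided_extreme_closed_form(self):
        # all 20 events in one arm with equal exposure: 2 * 0.5^20
        p = mutstats.binomial_rate_test(0, 1.0, 20, 1.0)
        assert p == pytest.approx(2 * 0.5**20, rel=1e-9)

    def test_random_configurations_match_summation_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(50)[:50]:
            c1, c2 = (int(x) for x in rng.integers(0, 25, size=2))
            e1, e2 = (int(x) for x in rng.integers(1, 10, size=2))
            if c1 + c2 == 0:
                continue
            got = mutstats.binomial_rate_test(c1, e1, c2, e2)
            assert got == pytest.approx(binomial_oracle(c1, e1, c2, e2), rel=1e-9)

    def test_zero_total_count_is_null(self):
        assert mutstats.binomial_rate_test(0, 1.0, 0, 1.0) == 1.0


class TestRanksum:
    def test_identical_multisets_are_null(self):
        assert mutstats.ranksum_test([1, 2, 3], [3, 1, 2]) == pytest.approx(1.0)

    def test_complete_separation_small_sample_exact(self):
        # 2 of the C(6,3)=20 equally likely rank assignments are as extreme
        assert mutstats.ranksum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_all_values_identical(self):
        assert mutstats.ranksum_test([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_large_sample_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(19)
        x = rng.normal(0.0, 1.0, size=60)
        y = rng.normal(0.4, 1.0, size=55)
        p = mutstats.ranksum_test(x, y)
        pooled = np.concatenate([x, y])
        ranks = pd.Series(pooled).rank().to_numpy()
        obs = ranks[: x.size].sum()
        n_perm = 20000
        stat = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(ranks)
            stat[i] = perm[: x.size].sum()
        mu = ranks.sum() * x.size / pooled.size
        p_perm = np.mean(np.abs(stat - mu) >= abs(obs - mu) - 1e-9)
        se = math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert p == pytest.approx(p_perm, abs=max(4 * se, 5e-3))


class TestCorrectedAF:
    def test_clonal_heterozygous_maps_to_half(self):
        assert mutstats.corrected_af(0.15, 0.30).corrected == pytest.approx(0.5)

    def test_complete_loh_maps_to_one(self):
        assert mutstats.corrected_af(0.30, 0.30).corrected == pytest.approx(1.0)

    def test_linear_in_raw_af(self):
        c1 = mutstats.corrected_af(0.05, 0.4).corrected
        c2 = mutstats.corrected_af(0.10, 0.4).corrected
        c3 = mutstats.corrected_af(0.15, 0.4).corrected
        assert c2 == pytest.approx(2 * c1)
        assert c3 == pytest.approx(3 * c1)

    def test_low_ctdna_sample_excluded_not_corrected(self):
        r = mutstats.corrected_af(0.01, 0.015)
        assert r.excluded and r.corrected is None

    def test_full_convention_doubles(self):
        half = mutstats.corrected_af(0.15, 0.30).corrected
        full = mutstats.corrected_af(0.15, 0.30, convention="full").corrected
        assert full == pytest.approx(2 * half)


def _obs(rows):
    return pd.DataFrame(
        rows,
        columns=["patient", "chrom", "pos", "ref", "alt", "timepoint",
                 "ctdna_fraction", "called", "supporting_reads", "depth",
                 "corrected_af"],
    )


class TestTrackClones:
    MUT = ("P1", "c1", 100, "A", "T")

    def test_detected_at_all_timepoints_is_persistent(self):
        obs = _obs([(*self.MUT, t, 0.2, True, 50, 600, 0.5) for t in (1, 2, 3)])
        [traj] = mutstats.track_clones(obs)
        assert traj.classification == "persistent"

    def test_absent_then_detected_is_late_rising(self):
        obs = _obs([
            (*self.MUT, 1, 0.2, False, 0, 700, 0.0),
            (*self.MUT, 2, 0.3, True, 60, 700, 0.4),
        ])
        [traj] = mutstats.track_clones(obs)
        assert traj.classification == "late_rising"

    def test_detected_then_absent_is_lost(self):
        obs = _obs([
            (*self.MUT, 1, 0.3, True, 60, 700, 0.4),
            (*self.MUT, 2, 0.2, False, 0, 700, 0.0),
        ])
        [traj] = mutstats.track_clones(obs)
        assert traj.classification == "lost"

    def test_few_stray_reads_are_indeterminate_not_absent(self):
        obs = _obs([
            (*self.MUT, 1, 0.2, False, 4, 700, 0.01),
            (*self.MUT, 2, 0.3, True, 60, 700, 0.4),
        ])
        [traj] = mutstats.track_clones(obs)
        statuses = [s for _, s, _, _ in traj.timepoints]
        assert statuses[0] == "indeterminate"
        assert traj.classification != "late_rising"

    def test_low_depth_never_counts_as_clone_loss(self):
        obs = _obs([
            (*self.MUT, 1, 0.3, True, 60, 700, 0.4),
            (*self.MUT, 2, 0.2, False, 0, 80, 0.0),  # depth < 200
        ])
        [traj] = mutstats.track_clones(obs)
        assert traj.classification != "lost"

    def test_single_eligible_timepoint_excluded(self):
        obs = _obs([
            (*self.MUT, 1, 0.2, True, 50, 600, 0.5),
            (*self.MUT, 2, 0.01, True, 50, 600, 0.5),  # below ctDNA gate
        ])
        assert mutstats.track_clones(obs) == []
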