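"""Site-level caller benchmarks.

Builds batteries of simulated pileup columns (paired cfDNA/WBC plus a
WBC background cohort) and measures the five-condition caller's
sensitivity, without constructing a full cohort. Used by the acceptance
script and by the performance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pileup import PileupColumn
from .somatic_calls import BackgroundModel, CallerThresholds, call_somatic

__all__ = ["SiteBattery", "simulate_site_battery", "caller_sensitivity"]


@dataclass
class SiteBattery:
    cfdna: dict[str, dict[int, PileupColumn]]
    wbc: dict[str, dict[int, PileupColumn]]
    background: BackgroundModel
    true_af: np.ndarray  # planted allele fraction per site
    alt_base: list[str]


def simulate_site_battery(
    seed: int,
    n_sites: int = 500,
    af_low: float = 0.035,
    af_high: float = 0.05,
    depth_mean: float = 751.0,
    per_base_error: float = 0.001,
    n_background_wbc: int = 20,
    chrom: str = "sites",
) -> SiteBattery:
    """Independent variant sites with planted somatic substitutions.

    Each site: cfDNA depth ~ Poisson(depth_mean) with a planted alternate
    allele at a fraction drawn uniformly from [af_low, af_high] plus
    substitution errors at ``per_base_error`` (split over the three
    non-reference bases); a paired WBC sample at the same mean depth with
    errors only; and a background cohort of ``n_background_wbc``
    error-only WBC samples.
    """
    rng = np.random.default_rng(seed)
    err3 = per_base_error / 3.0
    bases = "ACGT"
    cf_cols: dict[int, PileupColumn] = {}
    wbc_cols: dict[int, PileupColumn] = {}
    bg = BackgroundModel()
    afs = rng.uniform(af_low, af_high, size=n_sites)
    alt_bases: list[str] = []
    for i in range(n_sites):
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        alt_bases.append(alt)
        depth = int(rng.poisson(depth_mean))
        col = PileupColumn(chrom, i, ref, depth)
        for b in bases:
            if b == ref:
                continue
            n_err = int(rng.binomial(depth, err3))
            if b == alt:
                n_err += int(rng.binomial(depth, afs[i]))
            if n_err:
                col.allele_counts[b] = n_err
        cf_cols[i] = col
        wdepth = int(rng.poisson(depth_mean))
        wcol = PileupColumn(chrom, i, ref, wdepth)
        for b in bases:
            if b == ref:
                continue
            n_err = int(rng.binomial(wdepth, err3))
            if n_err:
                wcol.allele_counts[b] = n_err
        wbc_cols[i] = wcol
        for _ in range(n_background_wbc):
            bdepth = int(rng.poisson(depth_mean))
            counts = {}
            for b in bases:
                if b == ref:
                    continue
                n_err = int(rng.binomial(bdepth, err3))
                if n_err:
                    counts[b] = n_err
            bg.add_site(chrom, i, bdepth, counts)
    return SiteBattery({chrom: cf_cols}, {chrom: wbc_cols}, bg, afs, alt_bases)


def caller_sensitivity(
    seed: int,
    n_sites: int = 500,
    thresholds: CallerThresholds = CallerThresholds(),
    **battery_kwargs,
) -> float:
    """Percent of planted variant sites recovered by the caller."""
    battery = simulate_site_battery(seed, n_sites=n_sites, **battery_kwargs)
    calls = call_somatic(battery.cfdna, battery.wbc, battery.background, thresholds)
    chrom = next(iter(battery.cfdna))
    called = {(c.pos, c.alt) for c in calls}
    hit = sum(
        1 for i, alt in enumerate(battery.alt_base) if (i, alt) in called
    )
    return 100.0 * hit / n_sites
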