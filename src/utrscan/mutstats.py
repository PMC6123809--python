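"""Statistical layer for cfDNA mutation analysis.

Exact two-sided Fisher test (log-space hypergeometric enumeration),
binomial comparison of region-normalized mutation rates, Wilcoxon
rank-sum, ctDNA-fraction-corrected allele fractions, and longitudinal
clone tracking across serial cfDNA samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp

logger = logging.getLogger(__name__)

__all__ = [
    "ContingencyTable",
    "CorrectedAF",
    "CloneTrajectory",
    "fisher_exact",
    "binomial_rate_test",
    "ranksum_test",
    "corrected_af",
    "track_clones",
]


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of counts; rows are groups, columns outcome / non-outcome."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError(f"contingency counts must be non-negative integers, got {v}")

    @property
    def margins(self) -> tuple[int, int, int, int]:
        return (self.a + self.b, self.c + self.d, self.a + self.c, self.b + self.d)


def _as_table(table) -> ContingencyTable:
    if isinstance(table, ContingencyTable):
        return table
    (a, b), (c, d) = table
    return ContingencyTable(int(a), int(b), int(c), int(d))


def fisher_exact(
    table,
    method: Literal["minlike", "doubling"] = "minlike",
) -> float:
    """Two-sided Fisher exact test on a 2x2 table.

    The null distribution of the top-left cell, conditional on all margins,
    is hypergeometric; probabilities are accumulated in log-space.

    Two two-sided conventions are offered, because both are in wide use and
    published p-values are frequently only reproducible under one of them:

    - ``minlike`` (default): sum of the probabilities of all tables with the
      observed margins whose probability does not exceed that of the observed
      table (the convention of R's ``fisher.test`` and ``scipy``).
    - ``doubling``: twice the smaller one-sided tail, capped at 1.

    Parameters
    ----------
    table : 2x2 nested sequence or :class:`ContingencyTable`
    method : two-sided convention, see above.
    """
    t = _as_table(table)
    r1, r2, c1, _c2 = t.margins
    if min(t.margins) == 0:
        raise ValueError("Fisher exact test requires all margins to be positive")
    n = t.a + t.b + t.c + t.d
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(k, n, r1, c1)
    log_obs = logp[t.a - lo]
    if method == "minlike":
        # relative tolerance guards against ties lost to rounding
        mask = logp <= log_obs + 1e-7
        p = float(np.exp(logsumexp(logp[mask])))
    elif method == "doubling":
        left = float(np.exp(logsumexp(logp[k <= t.a])))
        right = float(np.exp(logsumexp(logp[k >= t.a])))
        p = 2.0 * min(left, right)
    else:
        raise ValueError(f"unknown method {method!r}")
    return min(p, 1.0)


def binomial_rate_test(
    count1: int,
    exposure1: float,
    count2: int,
    exposure2: float,
) -> float:
    """Two-sided binomial comparison of two mutation rates.

    Conditional on the total count ``n = count1 + count2``, ``count1`` is
    Binomial(n, exposure1 / (exposure1 + exposure2)) under the null
    hypothesis of equal rates per unit exposure (e.g. per megabase per
    sample). The two-sided p-value sums the probabilities of all outcomes no
    more likely than the observed one.
    """
    if exposure1 <= 0 or exposure2 <= 0:
        raise ValueError("exposures must be positive")
    if count1 < 0 or count2 < 0:
        raise ValueError("counts must be non-negative")
    n = count1 + count2
    if n == 0:
        logger.warning("binomial_rate_test called with zero total count; p = 1")
        return 1.0
    p0 = exposure1 / (exposure1 + exposure2)
    return float(stats.binomtest(count1, n, p0, alternative="two-sided").pvalue)


def ranksum_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test with midrank ties.

    Small samples without ties are evaluated by exact enumeration of the
    Mann-Whitney U distribution; otherwise a normal approximation with
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    if np.all(combined == combined[0]):
        return 1.0
    has_ties = np.unique(combined).size < combined.size
    if not has_ties and max(x.size, y.size) <= 20:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue)


@dataclass(frozen=True)
class CorrectedAF:
    """Allele fraction rescaled by sample ctDNA fraction.

    Under a heterozygous single-copy model a clonal mutation has cfDNA allele
    fraction ``ctdna_fraction / 2``, so ``raw_af / ctdna_fraction`` estimates
    ``clonality / 2``: clonal heterozygous events map to 0.5 and values above
    0.5 indicate loss of heterozygosity or amplification of the mutant allele.
    """

    raw_af: float
    ctdna_fraction: float
    corrected: float | None
    excluded: bool = False


def corrected_af(
    raw_af: float,
    ctdna_fraction: float,
    floor: float = 0.02,
    convention: Literal["half", "full"] = "half",
) -> CorrectedAF:
    """ctDNA-fraction-corrected allele fraction.

    Samples at or below the ctDNA ``floor`` (default 2%) are excluded rather
    than corrected, mirroring the ctDNA-positivity gate of the cohort
    analysis. ``convention="half"`` (default) returns ``raw / ctdna`` so that
    a clonal heterozygous mutation maps to 0.5; ``convention="full"`` returns
    ``raw / (ctdna / 2)`` mapping it to 1.0.
    """
    if not 0.0 <= raw_af <= 1.0:
        raise ValueError("raw_af must be in [0, 1]")
    if ctdna_fraction <= floor:
        return CorrectedAF(raw_af, ctdna_fraction, None, excluded=True)
    corr = raw_af / ctdna_fraction
    if convention == "full":
        corr *= 2.0
    return CorrectedAF(raw_af, ctdna_fraction, corr)


@dataclass
class CloneTrajectory:
    """Detection history of one mutation across a patient's timepoints."""

    patient: str
    mutation: tuple
    timepoints: list = field(default_factory=list)  # (timepoint, status, reads, corrected_af)
    classification: str = "indeterminate"


_DETECTED = "detected"
_ABSENT = "absent"
_INDET = "indeterminate"


def _timepoint_status(called: bool, reads: int, depth: int, min_absent_depth: int) -> str:
    if called:
        return _DETECTED
    if reads == 0 and depth >= min_absent_depth:
        return _ABSENT
    return _INDET


def _classify(statuses: list[str]) -> str:
    det = [i for i, s in enumerate(statuses) if s == _DETECTED]
    if not det:
        return _INDET
    if all(s == _DETECTED for s in statuses):
        return "persistent"
    if any(s == _ABSENT for s in statuses[det[-1] + 1 :]):
        return "lost"
    if any(s == _ABSENT for s in statuses[: det[0]]):
        return "late_rising"
    return _INDET


def track_clones(
    observations: pd.DataFrame,
    min_ctdna: float = 0.05,
    min_absent_depth: int = 200,
) -> list[CloneTrajectory]:
    """Classify mutation trajectories across serial ctDNA-positive samples.

    ``observations`` has one row per (patient, mutation, timepoint) with
    columns: patient, chrom, pos, ref, alt, timepoint, ctdna_fraction,
    called (bool), supporting_reads, depth, corrected_af.

    A timepoint is eligible when its ctDNA fraction exceeds ``min_ctdna``;
    patients with fewer than two eligible timepoints are excluded. A mutation
    is *detected* where called, *absent* where zero supporting reads are seen
    at depth >= ``min_absent_depth`` (so low coverage is never mistaken for
    clone loss), and *indeterminate* otherwise (e.g. 1-9 stray reads).
    Classifications: persistent (detected throughout), late_rising (absent
    early, detected later), lost (detected then absent).
    """
    required = {
        "patient", "chrom", "pos", "ref", "alt", "timepoint",
        "ctdna_fraction", "called", "supporting_reads", "depth",
    }
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    obs = observations[observations["ctdna_fraction"] > min_ctdna]
    trajectories: list[CloneTrajectory] = []
    for (patient, chrom, pos, ref, alt), grp in obs.groupby(
        ["patient", "chrom", "pos", "ref", "alt"], sort=True
    ):
        grp = grp.sort_values("timepoint")
        if grp["timepoint"].nunique() < 2:
            continue
        traj = CloneTrajectory(patient=patient, mutation=(chrom, pos, ref, alt))
        statuses = []
        for _, row in grp.iterrows():
            status = _timepoint_status(
                bool(row["called"]), int(row["supporting_reads"]),
                int(row["depth"]), min_absent_depth,
            )
            statuses.append(status)
            traj.timepoints.append(
                (row["timepoint"], status, int(row["supporting_reads"]),
                 row.get("corrected_af", float("nan")))
            )
        traj.classification = _classify(statuses)
        trajectories.append(traj)
    return trajectories
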