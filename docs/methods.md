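# Methods

This note documents the models and numerical choices behind `utrscan`:
what each stage computes, the defaults and why, what the synthetic cohort
does and does not emulate, and the design decisions taken where more than
one reasonable convention exists.

## The somatic caller

A candidate allele at a site in a cfDNA sample is called somatic iff all
five conditions hold:

1. allele fraction (AF) ≥ `min_af` (default 0.01),
2. supporting reads ≥ `min_alt_reads` (default 10),
3. AF ≥ `bg_ratio` (25) × the cohort background error rate,
4. AF ≥ `wbc_ratio` (3) × the AF in the same patient's WBC sample,
5. paired-WBC depth ≥ `min_wbc_depth` (20).

The background error rate is the average allele fraction across all WBC
samples in the cohort. Two zero-handling conventions had to be fixed:

- **Cohort background pseudocount.** `bg = (Σ alt + 1) / (Σ depth + 1)`.
  An allele never observed in any WBC sample therefore has a small,
  depth-dependent positive background (≈ 1/Σdepth) rather than an exact
  zero that would make the 25× condition vacuous. A site with no WBC
  coverage at all gets background 1.0, i.e. no call is possible there —
  deliberately conservative. The rule is monotone in the evidence.
- **Paired WBC.** No pseudocount: `3 × 0 = 0`, so a clean paired normal
  never blocks a call. The cohort background is the noise guard.

A consequence worth knowing: the background model inherits the *germline
variation* of the cohort, not just its sequencing error. At a position
where other patients carry a heterozygous SNP with the same alternate
base, the background AF is roughly `(n_carriers × 0.5) / n_cohort`, and
condition 3 demands a correspondingly higher somatic AF. With 290
patients one carrier raises the required AF to ≈ 4.3%. This suppresses
recurrent-SNP positions genome-wide (a desirable property for a somatic
caller without population filters) at the cost of sensitivity for true
somatic events that coincide with polymorphic sites; in the standard
simulation this costs ~2% of planted substitutions. The per-patient
germline is handled by condition 4 regardless.

Multi-allelic sites are evaluated per allele, one VCF record each; strand
is ignored (no strand-bias filter is part of the method). The 1% AF floor
is applied to normalized alleles (below). All five condition outcomes are
recorded per candidate for audit, and the caller's output is tested to be
identical to a brute-force application of the five inequalities.

## Indel representation

Indels are normalized to the left-aligned, parsimonious VCF representation
(anchored at the base before the event) before counting, calling, and
comparison. This is what makes a deletion inside a microsatellite — where
every read may place the gap differently — a single countable allele. The
normalization loop is the standard one: right-trim shared trailing bases
(left-extending with the previous reference base when an allele empties),
then trim shared leading bases.

## Split-read large-indel detection

Events too large to survive gapped alignment (here: > 20 bp, configurable)
are recovered from unaligned reads:

1. each read is split into two 30 bp anchors (5′ and 3′ ends);
2. anchors are placed on the reference by *unique exact* k-mer match
   (k = anchor length), trying both orientations; ambiguous or unmatched
   anchors drop the pair, with counters;
3. a pair is discordant when the anchor distance differs from
   `read_len − 2 × anchor_len`; the sign and size of the discrepancy give
   the event type and length;
4. the maximal reference-matching prefix and suffix of the read bracket
   the admissible junction placements; the read's placement is
   re-normalized against the reference so that all reads of one event —
   including every rotation of a tandem-duplication insertion — share one
   breakpoint signature;
5. signatures are clustered with a ± 5 bp position tolerance (the
   clustering granularity is otherwise unspecified in the underlying
   method; 5 bp is this package's default and a flag);
6. duplicates are collapsed on fragment start positions;
7. clusters with ≥ 3 unique fragments and event length 1–500 bp are
   emitted; longer events are excluded by design. Inserted sequence is
   reconstructed by majority vote over the reads' middle segments.

Exact-match anchor placement is a deliberate simplification relative to
genome-scale alignment, sufficient for panel-sized references; a
mismatch-tolerant aligner could be substituted behind the same interface.
Manual breakpoint curation is replaced by a machine-readable evidence
record (member fragments, votes) per event. Geometry limits apply:
both anchors must fit in reference sequence, so an insertion is
recoverable only when `read_len ≥ ins_len + 2 × anchor_len`; with 150 bp
reads that means insertions up to ~90 bp, and the read length is a
parameter where larger events matter.

## Regions and rates

UTRs are derived from the predominantly expressed transcript (selected by
expression rank when provided, else longest CDS): exonic sequence outside
the CDS, 5′/3′ by strand. Classification priority is CDS > UTR > intron >
intergenic, with the CDS check taken over *all* splice variants of the
gene — a variant inside the predominant transcript's 3′-UTR that overlaps
any annotated CDS is counted as coding, never as UTR. A variant
overlapping two genes is reported once per gene.

The mutation rate for a region is

    count / covered_Mb / n_samples

where `covered_Mb` counts positions with pooled depth strictly > 200× (the
pooled track is the mean across ctDNA-positive cfDNA samples; a per-sample
denominator would be an alternative reading and is not used) and
`n_samples` counts cfDNA samples with ctDNA fraction strictly > 2%. A zero
denominator yields an explicitly undefined rate, never 0 or ∞.

The consequence classifier is minimal by design: CDS SNVs are translated
through the standard code on the predominant transcript; CDS indels are
frameshift iff length mod 3 ≠ 0; indels touching an exon boundary are
`splice_region` with no codon call; UTR indels are always `utr` — UTRs are
untranslated, so no UTR event is ever a frameshift.

## Statistics

- **Fisher exact** (own implementation, log-space hypergeometric with
  `logsumexp`): both two-sided conventions are exposed —
  `minlike` (default; sum of all tables no more probable than observed,
  as in R and scipy) and `doubling` (twice the smaller tail, capped at 1).
  Published p-values from multi-tool analyses are often reproducible only
  under one or the other; offering both makes reproduction checks honest
  rather than approximate. Both are verified against exact-rational
  enumeration oracles.
- **Binomial rate comparison**: conditional on the total count, count₁ is
  binomial with success probability exposure₁/(exposure₁+exposure₂) under
  equal rates; two-sided by minimum-likelihood summation.
- **Rank-sum**: Wilcoxon/Mann-Whitney with midrank ties; exact enumeration
  for tie-free samples up to n = 20, else normal approximation with
  continuity correction.
- **Corrected AF**: `raw_af / ctdna_fraction`, so a clonal heterozygous
  single-copy mutation maps to 0.5 and values above 0.5 indicate loss of
  heterozygosity or mutant-allele amplification. The alternative scale
  (`raw / (ctdna/2)`, clonal het ↦ 1.0) is available via
  `convention="full"`. Samples at ctDNA ≤ 2% are excluded, not corrected.
- **Clone tracking**: across a patient's ctDNA-positive (> 5%) timepoints,
  a mutation is *detected* where called and *absent* only where zero
  supporting reads are seen at ≥ 200× depth — low coverage is never read
  as clone loss, and 1–9 stray reads are *indeterminate*. Trajectories
  classify as persistent, late-rising, or lost.

## Sequence context

GC content uses 20 bp sliding windows (ambiguous bases excluded from both
numerator and denominator); breakpoint profiles average the per-base GC
indicator at each signed distance from the left breakpoint of the
normalized event, excluding out-of-bounds offsets rather than padding.
4-mers are counted overlapping in ± 20 bp neighborhoods (single reference
strand) and compared with whole-region frequencies. Mechanism rules:
a deletion is a *repeat-unit deletion* iff the deleted sequence equals the
immediately adjacent segment of equal length on either side; an insertion
is a *tandem duplication* iff the inserted sequence duplicates the
immediately adjacent reference segment — the defining picture is a copy of
the 5′ flank, but left-alignment rotates that same event so that its copy
sits 3′ of the insertion point, so both flanks are checked and the
classification is representation-invariant.

## The synthetic cohort

The generator is the package's test bed and defines its study conditions;
everything flows from one seed and reruns are byte-identical.

Defaults: 6 genes, one per contig, two exons (UTR5 150 bp, CDS 600+600 bp,
intron 300 bp, UTR3 1300 bp; 1800 bp for the hypermutated gene), 200 bp
flanks; mean on-target depth 751× (Poisson per position); per-base
substitution error 0.001 split evenly over the three non-reference bases
(a conventional short-read figure — the emulated platform's error model is
not public, and error *indels* are not simulated; WBC indel noise has its
own small knob, 2 × 10⁻⁶/bp, so the caller's background channel is still
exercised for indels); 290 ctDNA-positive patients, one timepoint each;
ctDNA fractions Beta(2, 5) clipped to [0.025, 0.9] (median ≈ 0.26,
a realistic progression-cohort profile); germline het SNP rate 10⁻³/bp.

Planted somatic structure: the hypermutated gene receives one 3′-UTR event
in exactly 12% of patients — 80% indels, deletion:insertion ≈ 22:6,
deletion lengths ~geometric with median 8 bp (≤ 89), insertion lengths
median 18 bp; about a quarter of deletions remove one unit of a tandem
repeat embedded in the UTR, and most insertions are tandem duplications.
Every other gene carries ~12 coding mutations (a quarter subclonal at
clonality 0.4), two CDS indels, ~2 (substitution-dominated) 3′-UTR events,
and light UTR5/intron/flank noise, scaled with cohort size. Expected
somatic AF is `ctdna × clonality / 2` (heterozygous single-copy, matching
the corrected-AF convention); germline SNPs appear at AF 0.5 in both
channels; somatic events are absent from WBC.

Indels ≤ 20 bp enter the pileup as alleles; larger events instead emit
spanning reads from the mutant haplotype (count binomial in depth, AF and
the spanning-window fraction; ~10% duplicated to exercise fragment
dedup), which feed the split-read caller. The pipeline's union of the two
channels recovers planted indels across 1–500 bp.

Not emulated: fragment-length biology and GC-coverage bias, UMIs,
error indels, mapping artifacts, subclonal phylogenies, copy-number
change (depth is flat in expectation even across planted deletions).
Passing tests therefore demonstrate the *logic* of the pipeline — filter
correctness, normalization, geometry, statistics — under idealized noise,
not robustness to real-world alignment pathology.

## Performance checks and problem sizes

The test suite's cohort-level checks run on the standard 290-patient
configuration (~25 kb panel, 580 samples, ~10 s to simulate and ~1 s to
analyze): planted prevalence is recovered within the exact binomial 95%
acceptance region of 0.12 and the hypermutated gene ranks first by 3′-UTR
rate; planted clonal/subclonal mutations yield median corrected AFs of
0.50/0.20 (± 0.05); large indels of 31–500 bp with ≥ 8 spanning reads are
recovered at ± 5 bp with ≥ 3 unique fragments while a 600 bp deletion and
a 2-fragment cluster are rejected. Caller sensitivity is measured on 500
independent simulated sites at AF 3.5–5% and depth 751× (the regime where
the assay claims > 90% sensitivity); the measured value is ≈ 100%,
comfortably above the bound — sensitivity at this depth only degrades
near the 10-read/1% floors (AF ≲ 2%).

## Known limitations

- Exact-match anchors make the large-indel caller reference-scale bound;
  real genomes need a mismatch-tolerant anchor aligner and a repeat-aware
  uniqueness test.
- The pooled-depth denominator of the rate statistic ignores per-sample
  coverage dropout; per-sample denominators would be preferable when
  coverage is heterogeneous.
- The pairing verifier's thresholds (het band 0.15–0.85, concordance
  0.90) and the trimmer's smoothing window (11, centered, edge-shrinking,
  3′-only, iterated to a fixed point for idempotence) are this package's
  documented choices; the original in-house tools they mirror are not
  specified to this level of detail.
- `splice_region` short-circuits codon calls; full HGVS-style consequence
  ranking is out of scope.
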