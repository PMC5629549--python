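# Methods

This note documents the models implemented in `seqcnv`, the choices made
where the design was genuinely open, and what the synthetic benchmark
does and does not demonstrate.

## Signal model

Sequencing data is reduced to an ordered marker track per chromosome.
Sample SNVs become *snv* markers; maximal runs of covered positions
without a sample SNV become *interval* markers, additionally split at
every common population-SNP position so that marker boundaries coincide
with the sites an array would probe.  Coordinates are 1-based inclusive
internally and in the signal file; BED input/output converts to and from
0-based half-open.

**LRR.** `LRR = log2((d + c) / (D + c))` with observed depth `d`,
chromosome mean depth `D`, and pseudocount `c = 0.5` (default).  The
pseudocount keeps homozygous deletions (`d = 0`) finite — at 20X they
land near −5.4 — while preserving monotonicity in `d`.  Interval markers
use the mean depth over the interval.

**Centering.** After normalization the diploid signal should cluster at
0.  `center_lrr` subtracts the per-chromosome *median* marker LRR: the
median is robust to the minority of markers inside CNV regions, which a
mean would not be (a single large homozygous deletion shifts the
chromosome mean by far more than 0.02).  One consequence is a small
systematic residual: single-site depth is Poisson, and
`E[log2 d] < log2 E[d]`, so the diploid *mean* LRR sits ≈0.02–0.03 below
the diploid *median* at 20X.  Median centering zeroes the median, so the
copy-neutral mean after centering is ≈−0.027 rather than 0 exactly.  We
accept this: the alternative (mean centering) is not robust, and the
residual is far smaller than the narrowest class separation.

**BAF.** `alt / (ref + alt)` at positions with a variant call; all other
markers carry the conventional sentinel value `2`, which contributes
nothing to any likelihood.  Population frequencies attach to an SNV
marker only when position *and* both alleles match the frequency table,
avoiding misassignment at multiallelic sites.

Sex chromosomes: normalization is per chromosome, so a haploid chrX/chrY
reads as CN≈1 relative to its own mean.  The expected-ploidy override is
left to the caller (calibrate on known regions, or supply an HMM config
with shifted means); autosomes are the supported target.

## Hidden Markov model

Six states in fixed order `CN0, CN1, CN2, LOH, CN3, CN4`, copy numbers
0, 1, 2, 2, 3, 4.  LOH shares the diploid LRR emission (identical mean
and SD, enforced) but admits only homozygous BAF clusters — that is the
entire basis on which a copy-neutral uniparental region is separable
from ordinary diploid sequence.

**LRR emissions.** Per state a Gaussian `N(mu_s, sigma_s)`, mixed with a
small uniform outlier component (`outlier_frac = 0.01`, uniform density
1/8 over the plausible LRR range) so that no finite observation has
−inf log-likelihood.  The default means/SDs are a 20X sequencing
calibration: (−3.739099, 2.56), (−0.727964, 0.3), (0, 0.16),
(0.395454, 0.127), (0.658622, 0.124) for CN 0–4.

**Recalibration.** Those defaults are themselves the product of
measuring class-conditional LRR on data with known copy number, and any
change of platform, coverage or pipeline shifts them (e.g. a clean
marker-level simulation puts three copies at log2(3/2) ≈ 0.585, almost
exactly between the default CN3 and CN4 means).  `calibrate_lrr_params`
therefore re-estimates per-class means/SDs from known regions (truth
intervals or validated calls), with an SD floor of 0.05 to prevent
degenerate certainty (an all-zero-depth CN0 class otherwise collapses to
SD ≈ 0.004).  The benchmark pipeline calibrates per sample; the CLI
exposes it as `call --calibrate-truth`.

**BAF emissions.** A genotype-cluster mixture of truncated Gaussians on
[0, 1].  Cluster centers are the possible alternate-allele fractions of
the state's allele composition: uniform for CN0 (no alleles, no
information), {0, 1} for CN1 and LOH, {0, ½, 1} for CN2, quarters and
thirds for CN4/CN3.  Weights follow Hardy–Weinberg over the state's
allele count given the marker's population frequency (binomial(n, p);
for LOH the two copies are one parental allele duplicated, giving
weights (1−p, p)); uniform weights when no frequency is attached.
Cluster spread is `max(0.05, sqrt(c(1−c)/depth))`: the binomial
read-sampling scale when depth is known (at 20X a heterozygous BAF has
SD ≈ 0.11, not the array-era 0.05), with the fixed `baf_het_sd = 0.05`
as floor and as fallback for markers without depth.  The same
`outlier_frac` uniform floor is mixed in, which both robustifies the
mixture and guarantees finiteness when a cluster weight is exactly zero
(pop_freq 0 or 1).  This depth-aware spread is what keeps ordinary
binomial wobble of heterozygous BAF (0.35–0.45 at depth 20) from being
misread as evidence for three copies.

**Transitions.** A plain 6×6 matrix, independent of marker spacing.
Self-probabilities: 0.999 for CN2; 0.89 for CN0/CN1/CN3/CN4 — CNV states
revert readily, which favors changing state at true boundaries; 0.999
for LOH, whose blocks are megabase-scale.  Off-diagonal mass from a
non-diploid state goes 90% back to CN2 and the remainder uniformly to
the other states; from CN2 it splits uniformly over the five non-diploid
states.  Initial distribution: CN2 = 0.995, rest uniform.  A
consequence of the sticky LOH state is a detection floor: entering and
leaving LOH costs ≈15.5 nats against ≈0.35 nats per homozygous marker of
evidence, so LOH runs shorter than ~50 markers (~10 kb at default
density) are by design not callable; the intended LOH scale is
megabases.

**Decoding and calls.** Exact Viterbi in log space (numba-compiled, with
a pure-NumPy fallback), ties broken deterministically toward the lower
state index; verified against exhaustive path enumeration.  Maximal
non-CN2 runs become calls spanning first to last marker; confidence is
the emission-only log-likelihood margin over CN2 across the segment.
Default filters: ≥3 markers, no length filter.  `merge_calls` joins
same-state calls across gaps below a fraction of the merged span
(standard post-processing for fragmented long events) but is *not* part
of the default pipeline: with events placed only ~100 kb apart, gap
merging bridges distinct events and costs more recall than
fragmentation costs precision.

**Region validation.** `validate_region` sums marker emissions under the
five copy-number hypotheses 0–4 (LOH excluded) and reports all five
log-likelihoods plus the argmax, ties toward 2.  This is the
re-genotyping mode for candidate regions from any source.

## Simulator

Signal mode generates the marker track directly — the canonical
desk-scale path.  Per chromosome: common-SNP sites are laid with
exponential gaps at half the target marker density (site markers plus
inter-site interval markers ≈ 4.83 markers/kb); each site gets
independent EUR and AFR alternate-allele frequencies drawn from
Beta(2, 2) (a symmetric common-variant spectrum); the maternal haplotype
samples alleles at EUR frequencies, the paternal at AFR frequencies.

Events per sample (defaults): 54 zero-copy, 64 one-copy, 74 three-copy,
44 four-copy CNVs and 4 LOH blocks — 240 events.  CNV lengths cycle
deterministically through the grid 1, 1.5, 2, 2.5, 3, 3.5, 4, 5, 6, 8,
10, 20, 30, 40, 50, 75, 100, 150, 200, 500, 1000, 5000 kb (cycling
guarantees grid coverage even in small runs); LOH blocks are 5 Mb.
Counts are Poisson around the defaults, or exact with `exact_counts`.
Events are spread over chromosomes by remaining capacity and placed left
to right with exponential gaps (mean 100 kb), never overlapping.
Capacity-balanced spreading (rather than filling chromosome 1 first)
keeps every chromosome majority-diploid, without which per-chromosome
median centering would be meaningless at desk scale.  The default
genome is three chromosomes totaling 360 Mb (~1.7 M markers/sample,
~30% of each chromosome inside events) — large enough to host the full
event load, small enough that a ten-sample study runs in ~2 minutes.

Coverage: each marker draws `depth ~ Poisson(lambda * u) / u` with
`lambda = mean_coverage * cn/2 * m(g)` and `u = (L + rl − 1)/rl` read
events for a marker of length `L` at read length `rl = 100` — the read,
not the base, is the unit of sampling noise, which gives diploid
interval markers an LRR spread of ≈0.14 (single-base SNV markers: ≈0.33).
Markers straddling an event boundary use the overlap-weighted copy
number.  GC bias: per-marker GC `g ~ Beta(20, 25)` and multiplier
`m(g) = 1 − 1.5 (g − 0.45)^2` clipped to [0.2, 1.2] — a unimodal
coverage response peaking near balanced GC.  Allele counts at SNV
markers are binomial over the event-adjusted allele composition
(CN1/CN3 drop or duplicate one randomly chosen haplotype, CN4 both, LOH
duplicates the recorded parent), so LOH regions are homozygous *by
construction*.  One seeded generator drives everything in a fixed order;
output is bit-identical for a given config.

Sequence mode (`generate_fasta`) edits a reference breakpoint-exactly —
SNV substitution per haplotype, then deletions / tandem duplications /
LOH copy-over applied right to left — for small fixtures; read-level
simulation (FASTQ, mapping) is out of scope.

What signal mode deliberately omits: read mapping artifacts,
variant-calling errors, spatially correlated GC waves, sequencing error
in BAF.  Passing benchmarks here therefore demonstrate the decoder and
harness under clean marker-level noise; they bound real-data
performance from above, particularly recall (see below).

## Evaluation

Calls match truth when they share ≥70% of *both* lengths (reciprocal —
the stricter convention; one-way and other fractions are configurable).
Matching is one-to-one and greedy in decreasing overlap, so extra calls
on one truth interval count as false positives.  Classes: per copy
number (0, 1, 3, 4), LOH (which only ever matches LOH), and grouped
deletions (0+1) / duplications (3+4).  Precision = TP/(TP+FP),
recall = TP/(TP+FN); empty denominators are reported as undefined
("NA"), never silently as 0 or 1.  `pr_by_min_length` sweeps minimum
event lengths (default 0–50 kb in 1 kb steps) filtering both sets, for
ROC-style curves.

## Benchmark outcomes and known limitations

The ten-sample study (defaults, exact counts, per-sample calibration,
70% reciprocal matching) yields: CN0 0.830/0.807, CN1 0.883/0.917,
CN3 0.881/0.873, CN4 0.927/0.923, LOH 1.000/1.000
(precision/recall, aggregated).  LOH precision is exactly 1 — no false
LOH call occurs in any sample, as a single confidently heterozygous
marker vetoes the state.  Because the generator omits read-level noise,
recall is near the ceiling set by marker-boundary quantization: the
events still missed are almost entirely the 1–2.5 kb grid lengths
(5–12 markers), where call boundaries snap to marker edges and the 70%
reciprocal requirement fails.  Real-read pipelines sit well below these
numbers; these figures validate the decoder, not sequencing reality.

Other limitations: no trio/family calling; no GC-wave correction of
LRR; transitions ignore inter-marker distance; confidences are
log-likelihood margins, not p-values; sex chromosomes need external
ploidy handling.
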