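# Methods

## Problem setting

Libraries built from charred plant remains (and extraction blanks) contain
at best a trace of endogenous DNA. Three artifacts can then masquerade as
authentic ancient signal: spurious mapping of very short reads, laboratory
contamination, and false index assignment ("sample bleeding") from other
libraries in the same multiplexed sequencing pool. The package implements
the screens that separate these artifacts from genuine signal and a
simulator that reproduces their statistical structure so the screens can be
validated end to end.

## In-read index recovery

Single-indexed libraries carry a sample-specific 7 bp index in the P7
primer. The index is normally read by dedicated index cycles, but when the
insert is short the ordinary sequencing cycles run through the 34 bp P7
adapter and into the index, so the read itself records which sample the
molecule came from. The assay layout is fixed: 12 bp adapter prefix +
22 bp spacer + 6 bp of index = 40 cycles beyond the insert, hence a read is
*readable* iff insert ≤ read_length − 40.

Matching is exact and deliberately asymmetric: the 12 bp prefix must match
exactly (confirming the adapter), the 22 bp spacer is not checked at all
(sequencing error rises toward read ends; requiring it would discard many
true events), and the 6 bp index must match exactly against the registry of
the pool's indexes truncated to their first 6 bases. Indexes are required
to differ pairwise by ≥ 3 substitutions and to stay distinct after
truncation, so one sequencing error cannot convert one index into another.
Reads with no prefix hit or a truncated index window are "unreadable" and
excluded from denominators; reads whose index window matches no registered
sample (including windows containing N) are "unrecognized" — kept in the
denominator so that correct + foreign + unrecognized = readable always
holds. When the prefix occurs more than once, the first occurrence wins
(deterministic, and the layout makes later occurrences filler artifacts).

Per library, reads are partitioned into **mapped** (present in the
post-filter alignment set) and **background** (everything else), and the
foreign-index fraction is computed in each. The paired difference across
libraries is tested with the exact Wilcoxon signed-rank test; the pooled
foreign/readable ratio estimates the flow-cell hop rate, with a 95% Wilson
score interval (well-behaved near zero, unlike the Wald interval).

## Rank tests

Both tests use midranks for ties and the "smaller side" statistic
convention (W = min(W⁺, W⁻); U = min(U₁, U₂)). Exact two-sided p-values
are tail probabilities of the permutation distribution: for the signed-rank
test, P(W⁺ ≤ w) + P(W⁺ ≥ T − w) over all 2ⁿ sign assignments, computed by
convolution over doubled (hence integer) midranks — identical to brute
force but polynomial cost, used for n ≤ 25; for Mann-Whitney,
P(min(U₁,U₂) ≤ U) over all C(n₁+n₂, n₁) labelings, used for n₁+n₂ ≤ 12.
Because both permutation distributions are symmetric these equal the usual
doubled one-tailed values; the implementations agree exactly with
`scipy.stats` on tie-free cases (checked in the test suite, where scipy and
brute-force enumeration serve as independent oracles). Above the exact
cutoffs, a normal approximation with tie correction and a 0.5 continuity
correction toward the mean is used. Zero paired differences are dropped;
an all-zero input is a degenerate-input error.

## Read preprocessing

Trimming is single-end, mirroring common aDNA practice: minimum retained
length 25, adapter mismatch *rate* ≤ 1/3 over the matched overlap, trailing
Ns and bases with quality ≤ 2 stripped, offset-33 qualities. The adapter
search takes the smallest position where the 12 bp adapter prefix overlaps
the read (≥ 4 bases of overlap at the 3′ end) within the mismatch
tolerance. Trimming iterates cut → tail-strip to a fixpoint: cutting can
expose a new short adapter overlap at the fresh 3′ end, and a single pass
would leave it behind; the fixpoint makes trimming idempotent at the cost
of occasionally removing a few extra 3′ bases. At mismatch rate 1/3 an
adapter-like 12-mer occurs by chance at ~0.3% per position, so a small
fraction of reads is trimmed slightly short of the true junction; this is
inherent to overlap trimming, not an error (the exact-match policy
recovers the true insert length on simulated data, which is how the
correspondence is tested). Exact dereplication keeps the first occurrence
of each sequence and reports per-sequence duplicate counts.

## Mapping and filters

SAM ingestion (via pysam) drops unmapped/secondary/supplementary records,
converts to 0-based half-open coordinates and recovers mismatches from MD
tags, re-expressed in the read's as-sequenced orientation. The packaged
*toy mapper* exists so tests and demonstrations need no external aligner:
exact k-mer seeds (k = 16) are located in an indexed genome in both
orientations and extended ungapped across the full read; a unique locus
gets MapQ 37, multiple loci MapQ 0, and extensions with > 30% mismatches
are rejected. Seeds are taken at offsets 0 *and* k rather than the 5′ end
only: a 5′-terminal C→T — precisely the damage signal being profiled —
would otherwise exclude damaged reads from the alignment set and bias the
profile. The mapper is a fixture, not a re-implementation of bwa.

Filtering order is fixed and asserted: MapQ ≥ 25 first, then duplicate
removal. Duplicates share (unclipped 5′ reference coordinate, strand,
aligned length); the member with the greatest summed base quality survives,
ties broken by smallest read id. Including the aligned length is slightly
stricter than classic single-end MarkDuplicates (5′ + strand only); a flag
restores the looser key. Percent-mapped is 100 × mapped-after-filters /
raw reads, tabulated for every library × genome pair including zeros.

Group averages over the packaged per-library metadata table are computed in
decimal arithmetic and rounded half-away-from-zero, so printed-precision
inputs reproduce their printed averages (0.00075 → 0.0008 at 4 digits).
The packaged table's enriched-vs-shotgun comparison (n₁ = 24, n₂ = 20)
gives U = 187, p = 0.215 — close to, but not exactly, the value obtained
from unrounded per-library rates, because the packaged table carries only
3 decimal places; it is exposed as a worked example rather than a frozen
expectation.

## Damage model and profile

The simulator applies terminal deamination with position-p probability
d·λ^(p−1): C→T from the 5′ end (rate d5) and G→A from the 3′ end (rate
d3), a single-stranded-overhang-style geometric decay that matches the
smooth profiles damage tools report. Defaults d5 = d3 = 0.3, λ = 0.5
represent clearly damaged ancient material. The profiler counts, per
1-based position from each read end, reference-C (resp. -G) opportunities
and the fraction read as T (resp. A); minus-strand alignments are profiled
in read orientation. Bayesian parameter estimation and fragmentation plots
are out of scope — only misincorporation frequencies are computed.

The signature classifier is explicit because visual judgement does not
automate: an end is positive when its terminal frequency is ≥ 0.05, at
least 2× the position-10 frequency, and rests on ≥ 200 opportunities
(otherwise "insufficient data"); either end suffices by default. The
thresholds are conservative stand-ins and are ordinary configuration.

## Synthetic pools

`simulate_pool` draws, per sample: source (endogenous genome with the
sample's endogenous fraction, otherwise a dedicated "contaminant" genome —
blanks are samples with no source genome), a log-normal insert length
(parameterized by mean/sd of the length itself, rounded, floored at 20 bp,
defaults mean 45/sd 12 — short ancient-like fragments that make most reads
index-readable at read length 100), a uniform genomic position and strand,
damage (endogenous fragments only; contaminant reads are modern and
undamaged), and the read layout insert + adapter + true sample's index +
filler, truncated to the read length. The filler tiles the *reversed*
adapter so it can never spuriously contain the assay prefix followed by a
registered index at the correct offset. Qualities are constant Q37 with an
optional Q2 tail. With probability hop_rate (default 0.003, the literature
estimate for single-indexed libraries) the read is assigned to a uniformly
chosen other sample; the in-read index always stays the true sample's.
One integer seed drives every draw.

What the generator does *not* emulate: paired-end reads and collapsing,
indel and platform-specific error profiles, enrichment-capture chemistry,
and realistic microbial metagenomes (the contaminant genome is a random
sequence). Passing tests therefore demonstrate correctness of the
bookkeeping, the estimators and the statistics under the modelled
artifacts — not robustness to sequencing error in the adapter prefix or
index (which the exact-match rule deliberately sacrifices for specificity).

`simulate_bleed_fractions` draws the per-library paired fractions directly
— mapped uniform on [4%, 39%], background uniform on [0.002%, 0.09%],
n = 16 — for exercising the paired test at the fraction level without
simulating reads.

## Coverage screen and low-complexity flag

A query survives the coverage filter iff its best hit (highest bitscore,
first on ties) spans ≥ min_cov of the query length, min_cov ∈ {0.95, 0.99};
the boundary is inclusive ("less than 95% disregarded" implies retaining
exactly 95%). Phylogenetic intersection analysis itself is a separately
published tool and is not re-implemented; only the downstream coverage
screen and the non-duplicate cross-check (set intersection of retained
query ids with deduplicated re-mapped read ids) are. The low-complexity
flag is a deliberately simple analog of repeat masking: the Simpson
concentration of overlapping 3-mers in a sliding 64 bp window, flagged at
≥ 0.15. A homopolymer scores 1.0, a dinucleotide repeat 0.5, random
sequence ≈ 0.03; the 3-mer count multiset is preserved under reverse
complement, so the flag is strand-symmetric.

## Problem sizes and numerical choices

Simulated validations use desk-scale problems chosen to give comfortable
statistical resolution: distributional checks run at 10⁴–2×10⁵ reads and
assert agreement within 3 binomial standard deviations of the configured
rate; the hop-rate recovery pool (4 × 50 000 reads at 0.3% hopping) yields
≈ 1.8×10⁵ readable indexes, giving a relative standard error of ≈ 4% on
the estimate. Genome-scale mapping to real multi-gigabase references is
out of scope — the toy mapper and synthetic genomes (10⁴–10⁵ bp) stand in,
with by-construction oracles. Exact-test cutoffs (n ≤ 25 signed-rank,
n₁+n₂ ≤ 12 Mann-Whitney) keep exact computation instantaneous while
covering the study-sized inputs; beyond them the corrected normal
approximation agrees with scipy. Reports round floats to six decimals and
fix column order so reruns are byte-identical.

## Known limitations

* Exact index matching cannot see hopped reads whose index window acquired
  a sequencing error; the hop-rate estimator is accordingly a slight
  underestimate on error-prone real data (unbiased on simulated data,
  which models no index-window errors).
* The mapped/background partition inherits any imperfection of the
  upstream filters; reads that fail MapQ filtering count as background.
* The damage classifier's thresholds are heuristics for automation, not a
  calibrated model; borderline profiles should be inspected.
* Single-index chemistry only; dual-index (i7 + i5) recovery and
  error-correcting index matching are out of scope.
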