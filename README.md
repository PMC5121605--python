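# charauth

Authenticity assessment for low-endogenous ancient-DNA sequencing libraries
— the kind produced from charred archaeobotanical remains, extraction
blanks, or any material where only a vanishing fraction of reads is genuine.
When fewer than ~0.3% of a library's reads map to the target genome, the
signal is smaller than common technical artifacts, and apparent "ancient"
reads can be explained entirely by index hopping from a high-endogenous
library sequenced in the same multiplexed pool. `charauth` packages the
analyses needed to expose that failure mode:

* **Cross-genome mapping rates** — trim and filter reads (MapQ ≥ 25,
  duplicate removal by 5′ coordinate/strand/length), tabulate
  percent-mapped per library × genome, and compare groups with an exact
  Mann-Whitney U test. Genuine samples should not map comparably well to
  unrelated genomes.
* **Damage profiling** — per-position C→T (5′) and G→A (3′)
  misincorporation frequencies, the canonical post-mortem deamination
  signal, with an explicit signature classifier.
* **Sample-bleeding detection (the core)** — recover each read's sample
  index *from the read itself*: find an exact match of the first 12 bp of
  the P7 adapter, skip the 22 bp spacer without checking it, and read the
  6 bp index, which is only possible when the insert is at most
  read-length − 40 bp. Comparing in-read indexes against the demultiplexed
  labels, separately for genome-mapped and background reads, quantifies
  false index assignment; the paired difference is tested with an exact
  Wilcoxon signed-rank test and the pool-wide hop rate is estimated with a
  Wilson interval.
* **Coverage screening** — retain taxonomic hits only when the best
  (highest-bitscore) match covers ≥ 95% or ≥ 99% of the read, flag
  low-complexity sequences, and cross-check survivors against non-duplicate
  re-mapped reads.
* **Synthetic pools** — a generator for multiplexed single-indexed pools
  with known ground truth: configurable hop rate, log-normal insert lengths
  driving adapter read-through, geometric-decay terminal deamination, and
  endogenous/contaminant mixtures. Every stage of the package is testable
  without any external data.

## The statistics at the core

For paired foreign-index fractions $(m_i, b_i)$ across $n$ libraries the
signed-rank statistic is $W = \min(W^+, W^-)$, the smaller of the rank sums
of positive and negative differences (midranks for ties, zero differences
dropped). The two-sided p-value is exact for $n \le 25$, computed from the
full distribution of $W^+$ over all $2^n$ sign assignments. When every
mapped fraction exceeds its paired background — the regime the analysis is
designed to expose — $W = 0$ and $p = 2 \cdot 2^{-n}$.

The two-sample comparison uses $U = \min(U_1, U_2)$ with
$U_1 + U_2 = n_1 n_2$, exact by enumeration of all
$\binom{n_1+n_2}{n_1}$ labelings for small samples, and a tie- and
continuity-corrected normal approximation otherwise.

The pool-wide hop rate is estimated as
$\hat{h} = \sum_\ell f_\ell / \sum_\ell r_\ell$ (foreign over readable
in-read indexes across all libraries) with a 95% Wilson score interval.

## Worked example

```python
from charauth import (BleedScenario, simulate_bleed_fractions,
                      wilcoxon_signed_rank)

df = simulate_bleed_fractions(BleedScenario(seed=1))
w, p = wilcoxon_signed_rank(list(zip(df.mapped_fraction,
                                     df.background_fraction)))
print(df.head(3).round(4).to_string(index=False))
print(f"W = {w:g}, two-sided p = {p:.3g}, n = {len(df)}")
```

prints

```
library  mapped_fraction  background_fraction
 lib_01           0.2191               0.0001
 lib_02           0.3727               0.0004
 lib_03           0.0905               0.0002
W = 0, two-sided p = 3.05e-05, n = 16
```

Each library's foreign-index fraction among genome-mapped reads (4–39%)
sits orders of magnitude above its background level (0.002–0.09%), so all
16 paired differences are positive: W = 0 and the exact two-sided p is
2·2⁻¹⁶ ≈ 3.05×10⁻⁵. That is the statistical fingerprint of mapped "ancient"
reads that actually bled in from another sample.

Estimating a pool-wide hop rate from reads alone (4 samples × 20 000 reads
simulated with 0.3% hopping):

```python
from charauth import (GenomeSet, PoolConfig, simulate_pool, IndexRegistry,
                      IndexAssayConfig, count_indexes, estimate_hop_rate,
                      generate_genomes)
from charauth.synthetic_data import default_samples

genomes = GenomeSet(list(generate_genomes(1, [100000], 0.45, 8).items()))
samples = default_samples(4, source_genome="genome_1")
pool = PoolConfig(samples=tuple(samples), hop_rate=0.003, read_len=100,
                  insert_mean=45.0, insert_sd=12.0,
                  n_reads_per_sample=20000, seed=1)
reads, truth = simulate_pool(pool, genomes)
registry = IndexRegistry.from_samples(samples)
counts = count_indexes(reads, lambda rid: "background",
                       IndexAssayConfig(), registry)
est = estimate_hop_rate(counts)
print(f"hop-rate estimate: {est.rate:.4%} "
      f"(95% CI {est.ci_low:.4%} - {est.ci_high:.4%})")
```

prints

```
hop-rate estimate: 0.3081% (95% CI 0.2701% - 0.3514%)
```

The command-line tool exposes the same stages
(`charauth simulate | trim | derep | map-toy | filter | summarize |
compare-groups | damage | bleed | covfilter | run`); `charauth run` executes
the whole pipeline from a JSON config and writes TSV tables plus one
`summary.json`. `charauth compare-groups` reproduces the packaged
per-library metadata summaries, e.g. rice enrichment-method averages of
0.01% (in-solution target), 0.004% (whole-genome) and 0.0008% (solid-state)
mapped reads.

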