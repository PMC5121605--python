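"""Synthetic multiplexed sequencing pools with known ground truth.

The generator emulates the statistical structure an authenticity analysis of
single-indexed, short-insert libraries relies on:

* per-sample 7-bp P7 indexes (pairwise Hamming distance >= 3), of which the
  first 6 bases are recoverable in-read behind the adapter;
* index hopping ("sample bleeding"): each read is demultiplexed to the wrong
  sample with a configurable probability (default anchored at 0.3%, the
  literature estimate for single-indexed libraries);
* adapter read-through: inserts shorter than read_len - 40 leave enough
  cycles to sequence the 12-bp adapter prefix, 22-bp spacer and 6-bp index;
* terminal cytosine-deamination damage: C->T at the 5' end and G->A at the
  3' end with geometrically decaying position rates d * lam**(p-1);
* an endogenous/contaminant mixture per sample, contaminant reads being
  drawn (undamaged) from a dedicated "contaminant" genome.

All randomness flows from a single integer seed for reproducibility.
"""
from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .preprocess import ReadRecord, write_fastq
from .seqs import DNA_ALPHABET, P7_ADAPTER, ASSAY_PREFIX, hamming, revcomp

CONTAMINANT_ID = "contaminant"

_BASES = np.frombuffer(b"ACGT", dtype="S1")

RngLike = Union[int, np.random.Generator]


def _as_rng(seed: RngLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


class GenomeSet:
    """Ordered collection of (genome_id, A/C/G/T sequence) pairs."""

    def __init__(self, entries: Sequence[tuple[str, str]]):
        ids = [gid for gid, _ in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("genome ids must be unique")
        for gid, seq in entries:
            if not seq:
                raise ValueError(f"genome {gid!r}: empty sequence")
            if set(seq) - DNA_ALPHABET:
                raise ValueError(f"genome {gid!r}: alphabet restricted to A/C/G/T")
        self._entries = tuple((gid, seq) for gid, seq in entries)
        self._by_id = dict(self._entries)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(gid for gid, _ in self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, gid: str) -> bool:
        return gid in self._by_id

    def __getitem__(self, gid: str) -> str:
        return self._by_id[gid]

    def items(self):
        return iter(self._entries)


@dataclasses.dataclass(frozen=True)
class SampleSpec:
    """One multiplexed library: its index and read composition."""

    sample_id: str
    index7: str
    endogenous_fraction: float = 1.0
    source_genome: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.index7) != 7 or set(self.index7) - DNA_ALPHABET:
            raise ValueError(f"sample {self.sample_id!r}: index7 must be 7 A/C/G/T bases")
        if not (0.0 <= self.endogenous_fraction <= 1.0):
            raise ValueError("endogenous_fraction must be in [0, 1]")


@dataclasses.dataclass(frozen=True)
class DamageModel:
    """Terminal misincorporation model: rate d * lam**(p-1) at position p."""

    d5: float = 0.0
    d3: float = 0.0
    lam: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.d5 <= 1.0 and 0.0 <= self.d3 <= 1.0):
            raise ValueError("d5 and d3 must be in [0, 1]")
        if not (0.0 <= self.lam < 1.0):
            raise ValueError("lam must be in [0, 1)")


#: Moderately damaged ancient material: ~30% terminal C->T / G->A halving
#: with each position inward, a profile shape typical of published aDNA
#: misincorporation plots.
DEFAULT_DAMAGE = DamageModel(d5=0.3, d3=0.3, lam=0.5)

MIN_INSERT = 20


@dataclasses.dataclass(frozen=True)
class PoolConfig:
    """One multiplexed pool: samples, hop rate, read geometry, damage, seed."""

    samples: tuple[SampleSpec, ...]
    hop_rate: float = 0.003
    read_len: int = 100
    insert_mean: float = 45.0
    insert_sd: float = 12.0
    n_reads_per_sample: int = 1000
    damage: DamageModel = DEFAULT_DAMAGE
    adapter: str = P7_ADAPTER
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", tuple(self.samples))
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample ids")
        if not (0.0 <= self.hop_rate <= 1.0):
            raise ValueError("hop_rate must be in [0, 1]")
        if len(self.adapter) != 34:
            raise ValueError("adapter must be 34 bases")
        if self.adapter[:12] != ASSAY_PREFIX:
            raise ValueError("adapter must start with the 12-base assay prefix")
        if self.read_len < 40 + MIN_INSERT:
            raise ValueError(f"read_len must be >= {40 + MIN_INSERT}")
        if self.insert_mean <= 0 or self.insert_sd < 0:
            raise ValueError("insert_mean must be > 0 and insert_sd >= 0")
        for a in self.samples:
            for b in self.samples:
                if a.sample_id < b.sample_id and hamming(a.index7, b.index7) < 3:
                    raise ValueError(
                        f"indexes of {a.sample_id!r} and {b.sample_id!r} differ "
                        "by fewer than 3 substitutions"
                    )
        six = {}
        for s in self.samples:
            key = s.index7[:6]
            if key in six:
                raise ValueError(
                    f"first-6-base index collision between {six[key]!r} and {s.sample_id!r}"
                )
            six[key] = s.sample_id


@dataclasses.dataclass(frozen=True)
class BleedScenario:
    """Paired foreign-index fraction draws for mapped vs background reads.

    Defaults reflect the regime the analysis is designed to expose: foreign
    fractions of 4-39% among genome-mapped reads against background levels of
    0.002-0.09% among everything else, across 16 libraries.
    """

    n_libraries: int = 16
    mapped_fraction_range: tuple[float, float] = (0.04, 0.39)
    background_fraction_range: tuple[float, float] = (0.00002, 0.0009)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.mapped_fraction_range, self.background_fraction_range):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ValueError("fraction ranges must satisfy 0 <= lo <= hi <= 1")
        if self.n_libraries < 1:
            raise ValueError("n_libraries must be >= 1")


def generate_genomes(
    k: int, lengths: Sequence[int], gc: float, seed: RngLike
) -> GenomeSet:
    """Random i.i.d. genomes with P(G or C) = gc; deterministic per seed."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if len(lengths) != k:
        raise ValueError("lengths must have exactly k entries")
    if any(n < 1 for n in lengths):
        raise ValueError("genome lengths must be >= 1")
    if not (0.0 <= gc <= 1.0):
        raise ValueError("gc must be in [0, 1]")
    rng = _as_rng(seed)
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    entries = []
    for i, n in enumerate(lengths):
        idx = rng.choice(4, size=int(n), p=probs)
        entries.append((f"genome_{i + 1}", _BASES[idx].tobytes().decode()))
    return GenomeSet(entries)


def apply_damage_tracked(
    fragment: str, model: DamageModel, seed: RngLike
) -> tuple[str, list[int]]:
    """Damaged fragment plus the 1-based positions that were substituted."""
    if not fragment:
        raise ValueError("fragment must be non-empty")
    rng = _as_rng(seed)
    n = len(fragment)
    arr = np.frombuffer(fragment.encode(), dtype="S1").copy()
    decay = model.lam ** np.arange(n)
    u5 = rng.random(n)
    u3 = rng.random(n)
    ct = (arr == b"C") & (u5 < model.d5 * decay)
    ga = (arr == b"G") & (u3 < model.d3 * decay[::-1])
    arr[ct] = b"T"
    arr[ga] = b"A"
    positions = [int(p) + 1 for p in np.flatnonzero(ct | ga)]
    return arr.tobytes().decode(), positions


def apply_damage(fragment: str, model: DamageModel, seed: RngLike) -> str:
    """C->T near the 5' end and G->A near the 3' end at rate d * lam**(p-1)."""
    return apply_damage_tracked(fragment, model, seed)[0]


def render_read(
    insert: str,
    index7: str,
    adapter: str,
    read_len: int,
    low_quality_tail_fraction: float = 0.0,
) -> tuple[str, tuple[int, ...]]:
    """Lay out insert ++ adapter ++ index ++ filler, truncated to read_len.

    The filler tiles the reversed adapter so it can never spuriously contain
    the assay prefix followed by a registered index at the right offset.
    Qualities are constant Q37 apart from an optional low-quality (Q2) 3'
    tail covering the given fraction of cycles.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    layout = insert + adapter + index7
    if len(layout) < read_len:
        filler = adapter[::-1]
        reps = math.ceil((read_len - len(layout)) / len(filler))
        layout += filler * reps
    bases = layout[:read_len]
    quals = [37] * read_len
    n_tail = int(round(low_quality_tail_fraction * read_len))
    for i in range(read_len - n_tail, read_len):
        quals[i] = 2
    return bases, tuple(quals)


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    if sd == 0:
        return math.log(mean), 0.0
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def simulate_pool(
    config: PoolConfig, genomes: GenomeSet
) -> tuple[dict[str, list[ReadRecord]], pd.DataFrame]:
    """Simulate one multiplexed pool.

    Each read is written to its *assigned* sample's output (wrong sample with
    probability hop_rate) while the in-read index is always the *true*
    sample's. Returns per-assigned-sample reads and a truth table with one
    row per read (read_id, true_sample, assigned_sample, insert_len, source,
    damage_positions).
    """
    needs_contaminant = any(
        s.source_genome is None or s.endogenous_fraction < 1.0 for s in config.samples
    )
    if needs_contaminant and CONTAMINANT_ID not in genomes:
        raise ValueError(
            f"genome set must contain a {CONTAMINANT_ID!r} genome for "
            "contaminant/blank reads"
        )
    for s in config.samples:
        if s.source_genome is not None and s.source_genome not in genomes:
            raise ValueError(f"unknown source genome {s.source_genome!r}")
    rng = _as_rng(config.seed)
    mu, sigma = _lognormal_params(config.insert_mean, config.insert_sd)
    sample_ids = [s.sample_id for s in config.samples]
    reads: dict[str, list[ReadRecord]] = {sid: [] for sid in sample_ids}
    rows = []
    for s in config.samples:
        others = [x for x in sample_ids if x != s.sample_id]
        for i in range(config.n_reads_per_sample):
            endo = rng.random() < s.endogenous_fraction and s.source_genome is not None
            source = s.source_genome if endo else CONTAMINANT_ID
            genome = genomes[source]
            draw = rng.lognormal(mu, sigma) if sigma > 0 else config.insert_mean
            insert_len = max(MIN_INSERT, int(round(draw)))
            insert_len = min(insert_len, len(genome))
            pos = int(rng.integers(0, len(genome) - insert_len + 1))
            fragment = genome[pos : pos + insert_len]
            if rng.random() < 0.5:
                fragment = revcomp(fragment)
            if source != CONTAMINANT_ID:
                fragment, dpos = apply_damage_tracked(fragment, config.damage, rng)
            else:
                dpos = []
            bases, quals = render_read(
                fragment, s.index7, config.adapter, config.read_len
            )
            if config.hop_rate > 0 and rng.random() < config.hop_rate and others:
                assigned = others[int(rng.integers(0, len(others)))]
            else:
                assigned = s.sample_id
            read_id = f"{s.sample_id}:{i:06d}"
            reads[assigned].append(ReadRecord(read_id, bases, quals, assigned))
            rows.append(
                {
                    "read_id": read_id,
                    "true_sample": s.sample_id,
                    "assigned_sample": assigned,
                    "insert_len": insert_len,
                    "source": source,
                    "damage_positions": ",".join(str(p) for p in dpos),
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "read_id",
            "true_sample",
            "assigned_sample",
            "insert_len",
            "source",
            "damage_positions",
        ],
    )
    return reads, truth


def write_pool(
    reads: dict[str, list[ReadRecord]], truth: pd.DataFrame, out_dir
) -> None:
    """Persist a simulated pool: one FASTQ per sample plus truth.tsv."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    for sid in sorted(reads):
        write_fastq(reads[sid], os.path.join(out_dir, f"{sid}.fastq"))
    truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)


def simulate_bleed_fractions(scenario: BleedScenario) -> pd.DataFrame:
    """Independent uniform draws of paired (mapped, background) fractions."""
    rng = _as_rng(scenario.seed)
    m_lo, m_hi = scenario.mapped_fraction_range
    b_lo, b_hi = scenario.background_fraction_range
    mapped = rng.uniform(m_lo, m_hi, scenario.n_libraries)
    background = rng.uniform(b_lo, b_hi, scenario.n_libraries)
    return pd.DataFrame(
        {
            "library": [f"lib_{i + 1:02d}" for i in range(scenario.n_libraries)],
            "mapped_fraction": mapped,
            "background_fraction": background,
        }
    )


def default_index_set(n: int, seed: RngLike = 12345) -> list[str]:
    """n 7-bp indexes, pairwise Hamming >= 3 and injective on the first 6."""
    rng = _as_rng(seed)
    chosen: list[str] = []
    attempts = 0
    while len(chosen) < n:
        attempts += 1
        if attempts > 100000:
            raise RuntimeError("could not construct index set")
        cand = "".join(_BASES[rng.integers(0, 4, 7)].astype(str))
        if all(hamming(cand, c) >= 3 for c in chosen) and all(
            cand[:6] != c[:6] for c in chosen
        ):
            chosen.append(cand)
    return chosen


def default_samples(
    n: int,
    source_genome: Optional[str] = None,
    endogenous_fraction: float = 1.0,
    seed: RngLike = 12345,
) -> list[SampleSpec]:
    """Convenience: n samples with an auto-generated compliant index set."""
    indexes = default_index_set(n, seed)
    return [
        SampleSpec(f"sample_{i + 1}", idx, endogenous_fraction, source_genome)
        for i, idx in enumerate(indexes)
    ]
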