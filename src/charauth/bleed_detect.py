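"""Detection of false index assignment ("sample bleeding") by in-read index
recovery.

When a library molecule's insert is shorter than read_length - 40, the
sequencing cycles run through the 12-bp P7 adapter prefix, a 22-bp spacer
and the first 6 bases of the sample index, so the index a read *actually
carries* can be compared with the index the instrument demultiplexed it by.
Reads whose in-read index belongs to another sample are "bled" (hopped). The
module counts correct/foreign/unrecognized indexes per library separately
for genome-mapped and background (unmapped) reads, tests the paired
difference with an exact Wilcoxon signed-rank test and estimates the
pool-wide hop rate with a Wilson interval.

Matching is deliberately exact and asymmetric: the 12-bp prefix and the 6-bp
index must match exactly while the intervening 22-bp spacer is not checked
at all, tolerating sequencing error in the adapter body. The 7th index base
is ignored.
"""
from __future__ import annotations

import dataclasses
from collections import Counter
from typing import Callable, Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .preprocess import ReadRecord
from .seqs import ASSAY_PREFIX, DNA_ALPHABET, hamming
from .stats import wilcoxon_signed_rank  # noqa: F401  (module surface)

UNREADABLE = "unreadable"
UNRECOGNIZED = "unrecognized"
PARTITIONS = ("mapped", "background")


@dataclasses.dataclass(frozen=True)
class IndexAssayConfig:
    """Structural constants of in-read index recovery (12 + 22 + 6 = 40)."""

    prefix: str = ASSAY_PREFIX
    spacer_len: int = 22
    index_len: int = 6

    def __post_init__(self) -> None:
        if set(self.prefix) - DNA_ALPHABET:
            raise ValueError("prefix must be A/C/G/T")
        if self.spacer_len < 0 or self.index_len < 1:
            raise ValueError("invalid spacer/index length")

    @property
    def margin(self) -> int:
        """Minimum cycles beyond the insert for a fully readable index."""
        return len(self.prefix) + self.spacer_len + self.index_len


class IndexRegistry:
    """Injective map from observed 6-base index to sample id."""

    def __init__(self, samples: Mapping[str, str], index_len: int = 6):
        self._by_observed: dict[str, str] = {}
        self.index7 = dict(samples)
        ids = list(samples)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                if hamming(samples[a], samples[b]) < 3:
                    raise ValueError(
                        f"indexes of {a!r} and {b!r} differ by fewer than 3 bases"
                    )
        for sid, idx7 in samples.items():
            key = idx7[:index_len]
            if key in self._by_observed:
                raise ValueError(
                    f"index collision: {sid!r} and {self._by_observed[key]!r} share "
                    f"the first {index_len} bases"
                )
            self._by_observed[key] = sid

    @classmethod
    def from_samples(cls, samples: Iterable) -> "IndexRegistry":
        """Build from SampleSpec-like objects (sample_id, index7)."""
        return cls({s.sample_id: s.index7 for s in samples})

    @property
    def sample_ids(self) -> tuple[str, ...]:
        return tuple(self.index7)

    def lookup(self, observed: str) -> str:
        return self._by_observed.get(observed, UNRECOGNIZED)


def recover_index(
    bases: str, cfg: IndexAssayConfig, registry: IndexRegistry
) -> str:
    """Sample id carried in-read, or "unrecognized"/"unreadable".

    The first exact occurrence of the adapter prefix anchors the assay; the
    observed index is the ``index_len`` bases starting ``spacer_len`` after
    the prefix. Reads without the prefix, or whose index window would extend
    past the read end, are unreadable.
    """
    if not bases:
        raise ValueError("bases must be non-empty")
    i = bases.find(cfg.prefix)
    if i < 0:
        return UNREADABLE
    if i + cfg.margin > len(bases):
        return UNREADABLE
    lo = i + len(cfg.prefix) + cfg.spacer_len
    observed = bases[lo : lo + cfg.index_len]
    return registry.lookup(observed)


@dataclasses.dataclass
class PartitionCounts:
    readable_total: int = 0
    correct: int = 0
    foreign: Counter = dataclasses.field(default_factory=Counter)
    unrecognized: int = 0

    def check_conservation(self) -> None:
        if self.correct + sum(self.foreign.values()) + self.unrecognized != (
            self.readable_total
        ):
            raise AssertionError("index count conservation violated")


@dataclasses.dataclass
class IndexCounts:
    """Per-(library, partition) index tallies from in-read recovery."""

    rows: dict[tuple[str, str], PartitionCounts]

    def get(self, library: str, partition: str) -> PartitionCounts:
        return self.rows[(library, partition)]

    @property
    def libraries(self) -> list[str]:
        return sorted({lib for lib, _ in self.rows})

    def to_frame(self) -> pd.DataFrame:
        records = []
        for (lib, part), c in sorted(self.rows.items()):
            records.append(
                {
                    "library": lib,
                    "partition": part,
                    "readable_total": c.readable_total,
                    "correct": c.correct,
                    "foreign": sum(c.foreign.values()),
                    "unrecognized": c.unrecognized,
                }
            )
        return pd.DataFrame(records)


PartitionLabels = Union[Mapping[str, str], Callable[[str], str]]


def count_indexes(
    reads_by_library: Mapping[str, Sequence[ReadRecord]],
    partition_labels: PartitionLabels,
    cfg: IndexAssayConfig,
    registry: IndexRegistry,
) -> IndexCounts:
    """Tally recovered indexes per library and partition.

    ``partition_labels`` maps read ids to "mapped"/"background". Unreadable
    reads are excluded from the readable totals; rows exist for every
    (library, partition) pair even when empty.
    """
    if callable(partition_labels):
        label_of = partition_labels
    else:
        label_of = partition_labels.__getitem__
    rows = {
        (lib, part): PartitionCounts()
        for lib in reads_by_library
        for part in PARTITIONS
    }
    for lib, reads in reads_by_library.items():
        for read in reads:
            part = label_of(read.read_id)
            if part not in PARTITIONS:
                raise ValueError(
                    f"unknown partition label {part!r} for read {read.read_id!r}"
                )
            outcome = recover_index(read.bases, cfg, registry)
            if outcome == UNREADABLE:
                continue
            counts = rows[(lib, part)]
            counts.readable_total += 1
            if outcome == UNRECOGNIZED:
                counts.unrecognized += 1
            elif outcome == lib:
                counts.correct += 1
            else:
                counts.foreign[outcome] += 1
    result = IndexCounts(rows)
    for c in rows.values():
        c.check_conservation()
    return result


def bleed_fraction(
    counts: IndexCounts,
    library: str,
    partition: str,
    foreign_set: Iterable[str],
) -> float:
    """Fraction of a partition's readable reads carrying a foreign index."""
    c = counts.get(library, partition)
    if c.readable_total == 0:
        raise ValueError(
            f"undefined fraction: no readable reads in {library!r}/{partition!r}"
        )
    foreign_set = set(foreign_set)
    return sum(n for sid, n in c.foreign.items() if sid in foreign_set) / (
        c.readable_total
    )


@dataclasses.dataclass(frozen=True)
class HopRateEstimate:
    rate: float
    ci_low: float
    ci_high: float
    foreign: int
    readable: int


def estimate_hop_rate(counts: IndexCounts) -> HopRateEstimate:
    """Pool-wide foreign-index fraction with a 95% Wilson interval."""
    foreign = sum(sum(c.foreign.values()) for c in counts.rows.values())
    readable = sum(c.readable_total for c in counts.rows.values())
    if readable == 0:
        raise ValueError("undefined hop rate: no readable reads in pool")
    lo, hi = proportion_confint(foreign, readable, alpha=0.05, method="wilson")
    return HopRateEstimate(foreign / readable, float(lo), float(hi), foreign, readable)


@dataclasses.dataclass(frozen=True)
class BleedReport:
    """Per-library foreign fractions plus the paired signed-rank test."""

    per_library: pd.DataFrame
    w_statistic: float
    p_value: float
    n_pairs: int

    def to_json_dict(self) -> dict:
        return {
            "per_library": self.per_library.to_dict(orient="records"),
            "w_statistic": self.w_statistic,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
        }


def build_bleed_report(
    counts: IndexCounts,
    foreign_sets: Optional[Mapping[str, Iterable[str]]] = None,
    registry: Optional[IndexRegistry] = None,
) -> BleedReport:
    """Assemble mapped vs background foreign fractions and test the pairs.

    By default each library's foreign set is "all other samples" in the
    registry (or all other libraries in the counts). Libraries lacking
    readable reads in either partition get NaN fractions and are excluded
    from the paired test.
    """
    libraries = counts.libraries
    all_ids = set(registry.sample_ids) if registry is not None else set(libraries)
    records = []
    pairs = []
    for lib in libraries:
        if foreign_sets is not None:
            fset = set(foreign_sets[lib])
        else:
            fset = all_ids - {lib}
        fracs = {}
        for part in PARTITIONS:
            try:
                fracs[part] = bleed_fraction(counts, lib, part, fset)
            except ValueError:
                fracs[part] = float("nan")
        records.append(
            {
                "library": lib,
                "mapped_foreign_fraction": fracs["mapped"],
                "background_foreign_fraction": fracs["background"],
            }
        )
        if fracs["mapped"] == fracs["mapped"] and fracs["background"] == (
            fracs["background"]
        ):  # both non-NaN
            pairs.append((fracs["mapped"], fracs["background"]))
    nonzero = [p for p in pairs if p[0] != p[1]]
    if nonzero:
        w, p = wilcoxon_signed_rank(pairs)
    else:
        w, p = float("nan"), float("nan")
    return BleedReport(
        per_library=pd.DataFrame(records),
        w_statistic=w,
        p_value=p,
        n_pairs=len(pairs),
    )
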