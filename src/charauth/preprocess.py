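"""Single-end read trimming, filtering and exact dereplication.

Adapter trimming follows overlap semantics: the 3' end of a read that runs
through the insert continues into the library adapter, so the adapter prefix
is searched at every position allowing a bounded mismatch *rate* over the
overlapping bases. Reads are then stripped of trailing Ns and low-quality
tails and discarded if they fall below a minimum length, mirroring common
ancient-DNA pipelines (minimum length 25, mismatch rate 1/3, quality floor 2,
offset-33 qualities).
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

from .seqs import ASSAY_PREFIX


@dataclasses.dataclass(frozen=True)
class ReadRecord:
    """One sequencing read with offset-33-decoded qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    library: str = ""

    def __post_init__(self) -> None:
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: bases ({len(self.bases)}) and "
                f"qualities ({len(self.quals)}) differ in length"
            )
        if any(q < 0 for q in self.quals):
            raise ValueError(f"read {self.read_id!r}: negative quality value")

    def __len__(self) -> int:
        return len(self.bases)


@dataclasses.dataclass(frozen=True)
class TrimPolicy:
    """Adapter/quality trimming parameters.

    ``max_mismatch_rate`` bounds the mismatch fraction of the adapter overlap
    (1/3 reproduces the common ``--mm 3`` convention); ``min_overlap`` is the
    shortest 3'-end overlap considered evidence of adapter read-through.
    """

    adapter_prefix: str = ASSAY_PREFIX
    max_mismatch_rate: float = 1.0 / 3.0
    min_length: int = 25
    quality_floor: int = 2
    trim_ns: bool = True
    trim_qualities: bool = True
    quality_base: int = 33
    min_overlap: int = 4

    def __post_init__(self) -> None:
        if not (0.0 <= self.max_mismatch_rate < 1.0):
            raise ValueError("max_mismatch_rate must be in [0, 1)")
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")


def find_adapter_start(bases: str, policy: TrimPolicy) -> Optional[int]:
    """Smallest position where the adapter prefix overlaps within tolerance.

    The overlap at position ``p`` is ``bases[p:p+len(prefix)]`` against the
    prefix (shorter at the read end); overlaps below ``policy.min_overlap``
    are ignored. Returns ``None`` when no position qualifies. ``N`` counts as
    a mismatch.
    """
    if not bases:
        raise ValueError("bases must be non-empty")
    prefix = policy.adapter_prefix
    n = len(bases)
    for p in range(n - policy.min_overlap + 1):
        overlap = min(len(prefix), n - p)
        mism = 0
        limit = policy.max_mismatch_rate * overlap
        window = bases[p : p + overlap]
        for x, y in zip(window, prefix):
            if x != y:
                mism += 1
        if mism <= limit:
            return p
    return None


def _strip_tail(bases: str, quals: tuple[int, ...], policy: TrimPolicy) -> int:
    """New length after removing trailing Ns / low-quality bases."""
    end = len(bases)
    while end > 0:
        b = bases[end - 1]
        q = quals[end - 1]
        if policy.trim_ns and b == "N":
            end -= 1
        elif policy.trim_qualities and q <= policy.quality_floor:
            end -= 1
        else:
            break
    return end


def trim_read(read: ReadRecord, policy: TrimPolicy) -> Optional[ReadRecord]:
    """Trim adapter and tails; ``None`` when the read falls below min_length.

    Trimming iterates (adapter cut, tail strip) to a fixpoint so that
    trimming is idempotent: cutting can expose a new short adapter overlap at
    the 3' end, which a single pass would leave behind.
    """
    bases, quals = read.bases, read.quals
    while True:
        start = find_adapter_start(bases, policy) if bases else None
        if start is not None:
            bases, quals = bases[:start], quals[:start]
        if bases:
            end = _strip_tail(bases, quals, policy)
            bases, quals = bases[:end], quals[:end]
        if start is None or not bases:
            break
    if len(bases) < policy.min_length:
        return None
    return ReadRecord(read.read_id, bases, tuple(quals), read.library)


def dereplicate_exact(
    reads: Iterable[ReadRecord],
) -> tuple[list[ReadRecord], list[int]]:
    """Collapse exact sequence duplicates, keeping first occurrences.

    Returns the retained reads in input order plus, aligned with them, the
    number of input reads carrying each retained sequence.
    """
    seen: dict[str, int] = {}
    uniques: list[ReadRecord] = []
    counts: list[int] = []
    for read in reads:
        idx = seen.get(read.bases)
        if idx is None:
            seen[read.bases] = len(uniques)
            uniques.append(read)
            counts.append(1)
        else:
            counts[idx] += 1
    return uniques, counts


def read_fastq(path, library: str = "") -> Iterator[ReadRecord]:
    """Stream a FASTQ file (offset-33) as ReadRecords."""
    for rec in SeqIO.parse(str(path), "fastq"):
        yield ReadRecord(
            rec.id,
            str(rec.seq).upper(),
            tuple(rec.letter_annotations["phred_quality"]),
            library,
        )


def write_fastq(reads: Sequence[ReadRecord], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n")
            fh.write("".join(chr(q + 33) for q in r.quals) + "\n")
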