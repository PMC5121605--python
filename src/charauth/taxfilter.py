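"""Coverage-based filtering of tabular homology hits and related screens.

Taxonomic assignments of very short reads are screened by query coverage:
a read is kept only when its closest database match (highest bitscore)
spans at least 95% (or 99%) of the read. A triplet-concentration
low-complexity flag stands in for repeat screening, and a bookkeeping
cross-check intersects coverage-retained reads with the deduplicated set
that re-mapped to the source genome.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import pandas as pd

from .seqs import revcomp  # noqa: F401  (re-exported convenience)

#: Standard 12 BLAST outfmt-6 columns plus a trailing query_length column.
HIT_COLUMNS = [
    "query_id",
    "subject_label",
    "percent_identity",
    "alignment_length",
    "mismatches",
    "gap_opens",
    "query_start",
    "query_end",
    "subject_start",
    "subject_end",
    "evalue",
    "bitscore",
    "query_length",
]


@dataclasses.dataclass(frozen=True)
class HomologyHit:
    """One homology hit with 1-based inclusive query coordinates."""

    query_id: str
    subject_label: str
    query_start: int
    query_end: int
    query_length: int
    bitscore: float

    def __post_init__(self) -> None:
        if not (1 <= self.query_start <= self.query_end <= self.query_length):
            raise ValueError(
                f"hit {self.query_id!r}->{self.subject_label!r}: coordinates "
                f"violate 1 <= start <= end <= length"
            )

    @property
    def coverage(self) -> float:
        return (self.query_end - self.query_start + 1) / self.query_length


def read_hits_tsv(path) -> list[HomologyHit]:
    """Load hits from a BLAST outfmt-6-style TSV with a query_length column."""
    df = pd.read_csv(path, sep="\t", header=None, names=HIT_COLUMNS)
    return [
        HomologyHit(
            query_id=str(r.query_id),
            subject_label=str(r.subject_label),
            query_start=int(r.query_start),
            query_end=int(r.query_end),
            query_length=int(r.query_length),
            bitscore=float(r.bitscore),
        )
        for r in df.itertuples()
    ]


def coverage_filter(hits: Sequence[HomologyHit], min_cov: float) -> list[str]:
    """Queries whose closest match covers at least ``min_cov`` of their length.

    The closest match is the highest-bitscore hit (first in input order on
    ties); the coverage boundary is inclusive. Returns query ids in order of
    first appearance.
    """
    if not (0.0 < min_cov <= 1.0):
        raise ValueError("min_cov must be in (0, 1]")
    best: dict[str, HomologyHit] = {}
    order: list[str] = []
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            order.append(hit.query_id)
        elif hit.bitscore > cur.bitscore:
            best[hit.query_id] = hit
    return [q for q in order if best[q].coverage >= min_cov]


def low_complexity_flag(
    bases: str, window: int = 64, threshold: float = 0.15
) -> bool:
    """Flag sequences dominated by few triplets (simple repeats, homopolymers).

    Slides a window and computes the Simpson concentration of overlapping
    3-mers (sum of squared frequencies); the flag is raised when any window
    reaches ``threshold``. The score is invariant under reverse complement.
    """
    n = len(bases)
    if n < 3:
        raise ValueError("sequence must be at least 3 bases")
    win = min(window, n)
    best = 0.0
    for start in range(0, n - win + 1):
        chunk = bases[start : start + win]
        counts: dict[str, int] = {}
        for i in range(len(chunk) - 2):
            t = chunk[i : i + 3]
            counts[t] = counts.get(t, 0) + 1
        total = len(chunk) - 2
        score = sum(c * c for c in counts.values()) / (total * total)
        if score > best:
            best = score
    return best >= threshold


def crosscheck_nonduplicates(
    retained_query_ids: Iterable[str], deduplicated_read_ids: Iterable[str]
) -> tuple[int, list[str]]:
    """How many coverage-retained reads survive as non-duplicate mappers."""
    overlap = sorted(set(retained_query_ids) & set(deduplicated_read_ids))
    return len(overlap), overlap
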