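"""Alignment ingestion, MapQ/duplicate filtering and mapping-rate summaries.

The filters reproduce a standard ancient-DNA mapping screen: keep primary
mapped alignments with MapQ >= 25, then collapse PCR/optical duplicates by
their unclipped 5' reference coordinate, strand and aligned length, keeping
the copy with the highest summed base quality. Percent-mapped tables across
multiple reference genomes support the cross-genome authenticity comparison
(reads from a genuine sample should not map comparably well to unrelated
genomes), with group averages and a Mann-Whitney comparison on top.
"""
from __future__ import annotations

import dataclasses
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Callable, Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .preprocess import ReadRecord
from .seqs import complement, revcomp
from .stats import mann_whitney_u  # noqa: F401  (module surface)
from .synthetic_data import GenomeSet

METHOD_CLASSES = ("shotgun", "target", "WG", "SS")


@dataclasses.dataclass(frozen=True)
class Alignment:
    """One read placed on one genome (0-based half-open coordinates).

    ``mismatch_list`` holds (read_pos, ref_base, read_base) triples in the
    read's own (as-sequenced) orientation; for minus-strand alignments the
    reference base is complemented accordingly.
    """

    read_id: str
    library: str
    genome_id: str
    start: int
    strand: str
    mapq: int
    aligned_length: int
    mismatch_list: tuple[tuple[int, str, str], ...] = ()
    base_qual_sum: int = 0

    def __post_init__(self) -> None:
        if self.mapq < 0:
            raise ValueError("mapq must be >= 0")
        if self.aligned_length < 1:
            raise ValueError("aligned_length must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        for pos, _, _ in self.mismatch_list:
            if not (0 <= pos < self.aligned_length):
                raise ValueError("mismatch position outside aligned length")

    @property
    def five_prime(self) -> int:
        """Unclipped 5' reference coordinate of the read."""
        return self.start if self.strand == "+" else self.start + self.aligned_length


@dataclasses.dataclass(frozen=True)
class LibraryMeta:
    """Descriptors of one sequencing library (metadata fixture row)."""

    library: str
    method_class: str
    platform: str
    avg_read_length: int
    raw_reads: int
    percent_mapped: Optional[float]

    def __post_init__(self) -> None:
        if self.method_class not in METHOD_CLASSES:
            raise ValueError(f"method_class must be one of {METHOD_CLASSES}")
        if self.percent_mapped is not None and self.percent_mapped < 0:
            raise ValueError("percent_mapped must be >= 0")


def parse_sam(path, library: Optional[str] = None) -> list[Alignment]:
    """Parse a SAM file into Alignments.

    Unmapped, secondary and supplementary records are dropped; mismatches are
    recovered from the MD tag when present. The library label defaults to the
    record's RG tag.
    """
    out: list[Alignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        recno = 0
        try:
            for rec in sam:
                recno += 1
                if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                    continue
                lib = library
                if lib is None:
                    lib = rec.get_tag("RG") if rec.has_tag("RG") else ""
                qlen = rec.query_length or (
                    len(rec.query_sequence) if rec.query_sequence else 0
                )
                mismatches: list[tuple[int, str, str]] = []
                if rec.has_tag("MD") and rec.query_sequence:
                    seq = rec.query_sequence
                    for qpos, _, refbase in rec.get_aligned_pairs(
                        matches_only=True, with_seq=True
                    ):
                        if refbase is None or qpos is None:
                            continue
                        if refbase.islower():
                            read_base = seq[qpos]
                            if rec.is_reverse:
                                mismatches.append(
                                    (
                                        qlen - 1 - qpos,
                                        complement(refbase.upper()),
                                        complement(read_base),
                                    )
                                )
                            else:
                                mismatches.append(
                                    (qpos, refbase.upper(), read_base)
                                )
                mismatches.sort()
                quals = rec.query_qualities
                out.append(
                    Alignment(
                        read_id=rec.query_name,
                        library=lib,
                        genome_id=rec.reference_name,
                        start=rec.reference_start,
                        strand="-" if rec.is_reverse else "+",
                        mapq=rec.mapping_quality,
                        aligned_length=rec.reference_length or qlen,
                        mismatch_list=tuple(mismatches),
                        base_qual_sum=int(sum(quals)) if quals is not None else 0,
                    )
                )
        except (ValueError, OSError) as exc:
            raise ValueError(f"malformed SAM record near record {recno + 1}: {exc}")
    return out


def _kmer_index(genomes: GenomeSet, k: int) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for gid, seq in genomes.items():
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append((gid, i))
    return index


def toy_map(
    reads: Iterable[ReadRecord],
    genomes: GenomeSet,
    k: int = 16,
    max_mismatch_frac: float = 0.3,
) -> list[Alignment]:
    """Fixture mapper: exact k-mer seeding plus ungapped full-read extension.

    Seeds are taken at offsets 0 and k of the read in both orientations so a
    single damaged terminal base cannot hide the read from the mapper. A
    unique extending locus gets MapQ 37, multiple loci MapQ 0 (one alignment
    at the lexicographically first locus is emitted), no locus means the read
    is left unaligned. Candidates whose extension exceeds
    ``max_mismatch_frac`` mismatches are rejected.
    """
    index = _kmer_index(genomes, k)
    out: list[Alignment] = []
    for read in reads:
        L = len(read.bases)
        if L < k:
            continue
        candidates: set[tuple[str, int, str]] = set()
        for oriented, strand in ((read.bases, "+"), (revcomp(read.bases), "-")):
            for offset in (0, k):
                if offset + k > L:
                    continue
                seed = oriented[offset : offset + k]
                for gid, pos in index.get(seed, ()):
                    start = pos - offset
                    if start < 0 or start + L > len(genomes[gid]):
                        continue
                    candidates.add((gid, start, strand))
        accepted = []
        for gid, start, strand in sorted(candidates):
            oriented = read.bases if strand == "+" else revcomp(read.bases)
            ref = genomes[gid][start : start + L]
            mism = sum(a != b for a, b in zip(oriented, ref))
            if mism <= max_mismatch_frac * L:
                accepted.append((gid, start, strand, oriented, ref))
        if not accepted:
            continue
        gid, start, strand, oriented, ref = accepted[0]
        mismatches = []
        for i, (a, b) in enumerate(zip(oriented, ref)):
            if a != b:
                if strand == "+":
                    mismatches.append((i, b, a))
                else:
                    mismatches.append((L - 1 - i, complement(b), complement(a)))
        mismatches.sort()
        out.append(
            Alignment(
                read_id=read.read_id,
                library=read.library,
                genome_id=gid,
                start=start,
                strand=strand,
                mapq=37 if len(accepted) == 1 else 0,
                aligned_length=L,
                mismatch_list=tuple(mismatches),
                base_qual_sum=int(sum(read.quals)),
            )
        )
    return out


def filter_mapq(
    alignments: Iterable[Alignment], threshold: int = 25
) -> list[Alignment]:
    """Keep alignments with MapQ >= threshold."""
    return [a for a in alignments if a.mapq >= threshold]


def remove_duplicates(
    alignments: Sequence[Alignment], use_length: bool = True
) -> tuple[list[Alignment], float]:
    """Collapse duplicate sets sharing (5' coordinate, strand[, length]).

    Within a set the alignment with the greatest base quality sum survives
    (ties broken by the lexicographically smallest read id). Returns the
    survivors in input order and the removed fraction.
    """
    alignments = list(alignments)
    if not alignments:
        return [], 0.0
    best: dict[tuple, Alignment] = {}
    for a in alignments:
        key = (a.genome_id, a.five_prime, a.strand) + (
            (a.aligned_length,) if use_length else ()
        )
        cur = best.get(key)
        if (
            cur is None
            or a.base_qual_sum > cur.base_qual_sum
            or (a.base_qual_sum == cur.base_qual_sum and a.read_id < cur.read_id)
        ):
            best[key] = a
    keep = {id(a) for a in best.values()}
    survivors = [a for a in alignments if id(a) in keep]
    frac = (len(alignments) - len(survivors)) / len(alignments)
    return survivors, frac


def mapping_rate_table(
    alignments: Iterable[Alignment],
    raw_totals: dict[str, int],
    genome_ids: Optional[Sequence[str]] = None,
    mapq_threshold: int = 25,
) -> pd.DataFrame:
    """Per (library, genome) mapped counts and percentages after filters.

    Applies the MapQ filter and then duplicate removal within each
    (library, genome) group; ``percent_mapped`` is 100 * mapped / raw.
    Includes zero rows for every library x genome combination.
    """
    for lib, total in raw_totals.items():
        if total <= 0:
            raise ValueError(f"library {lib!r}: raw total must be > 0")
    alignments = list(alignments)
    if genome_ids is None:
        genome_ids = sorted({a.genome_id for a in alignments})
    groups: dict[tuple[str, str], list[Alignment]] = {}
    for a in alignments:
        groups.setdefault((a.library, a.genome_id), []).append(a)
    rows = []
    for lib in sorted(raw_totals):
        for gid in genome_ids:
            group = filter_mapq(groups.get((lib, gid), []), mapq_threshold)
            deduped, dup_frac = remove_duplicates(group)
            mapped = len(deduped)
            rows.append(
                {
                    "library": lib,
                    "genome_id": gid,
                    "raw_reads": raw_totals[lib],
                    "mapped_after_filters": mapped,
                    "percent_mapped": 100.0 * mapped / raw_totals[lib],
                    "duplicate_fraction": dup_frac,
                }
            )
    return pd.DataFrame(rows)


Selector = Union[Callable[[pd.Series], bool], Sequence[bool], pd.Series]


def group_average(
    meta: pd.DataFrame, selector: Selector, round_digits: int
) -> float:
    """Mean percent_mapped of a library group, rounded half-away-from-zero.

    ``selector`` is a row predicate or boolean mask. Averaging is done in
    decimal arithmetic so printed-precision inputs reproduce their printed
    averages (e.g. 0.00075 -> 0.0008 at 4 digits).
    """
    if callable(selector):
        mask = meta.apply(selector, axis=1)
    else:
        mask = pd.Series(selector, index=meta.index)
    values = meta.loc[mask, "percent_mapped"].dropna()
    if values.empty:
        raise ValueError("empty library group")
    dec = [Decimal(str(v)) for v in values]
    mean = sum(dec) / len(dec)
    quantum = Decimal(1).scaleb(-round_digits)
    return float(mean.quantize(quantum, rounding=ROUND_HALF_UP))


_METHOD_CLASS = {
    "shotgun": "shotgun",
    "target enrichment": "target",
    "target enrichment WG": "WG",
    "target enrichment SS": "SS",
}


def load_library_metadata() -> pd.DataFrame:
    """Packaged per-library metadata fixture (51 libraries incl. blanks).

    Columns: library, platform, method, method_class, library_build, species,
    is_blank, avg_read_length, raw_reads, percent_mapped (NaN for blanks).
    """
    path = resources.files("charauth").joinpath("data/library_metadata.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t")
    df["method_class"] = df["method"].map(_METHOD_CLASS)
    if df["method_class"].isna().any():
        raise ValueError("unrecognized method label in metadata fixture")
    df["is_blank"] = df["library"].str.startswith("Blank_")
    df["species"] = np.where(
        df["is_blank"],
        "blank",
        df["library"].str.extract(r"^([A-Za-z]+)", expand=False).str.lower(),
    )
    return df
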