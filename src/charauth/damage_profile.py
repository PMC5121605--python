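"""Positional misincorporation profiling and a damage-signature classifier.

Post-mortem cytosine deamination leaves elevated C->T mismatch frequencies
at the 5' ends of ancient reads (and G->A at 3' ends in double-stranded
libraries), decaying inward. The profile here counts, for each position from
either read end, the number of reference C (resp. G) "opportunities" and the
fraction of them read as T (resp. A). Reads aligned to the minus strand are
profiled in their own (as-sequenced) orientation, so damage is always
measured in read coordinates.
"""
from __future__ import annotations

import dataclasses
from typing import Iterable

import numpy as np
import pandas as pd

from .mapping_filter import Alignment
from .seqs import revcomp
from .synthetic_data import GenomeSet


@dataclasses.dataclass(frozen=True)
class DamageProfile:
    """Per-position misincorporation frequencies from both read ends.

    ``ct5[p-1]`` is the C->T frequency at 1-based position p from the 5' end
    (NaN where no reference C was seen); ``ga3`` is the analogous G->A
    frequency counted from the 3' end. ``opp_*`` are the opportunity counts.
    """

    window: int
    ct5: np.ndarray
    ga3: np.ndarray
    opp_c5: np.ndarray
    opp_g3: np.ndarray
    ct5_counts: np.ndarray
    ga3_counts: np.ndarray
    n_alignments: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "position": np.arange(1, self.window + 1),
                "ct5": self.ct5,
                "ga3": self.ga3,
                "opportunities_c5": self.opp_c5,
                "opportunities_g3": self.opp_g3,
            }
        )


def misincorporation_profile(
    alignments: Iterable[Alignment], genomes: GenomeSet, window: int = 25
) -> DamageProfile:
    """Count C->T (5' end) and G->A (3' end) frequencies by read position.

    The reference slice under each alignment provides the opportunity
    denominators; the alignment's mismatch list provides the substitutions.
    Frequencies beyond the longest read are reported as NaN.
    """
    alignments = list(alignments)
    if not alignments:
        raise ValueError("insufficient data: no alignments to profile")
    opp_c5 = np.zeros(window, dtype=np.int64)
    opp_g3 = np.zeros(window, dtype=np.int64)
    ct5 = np.zeros(window, dtype=np.int64)
    ga3 = np.zeros(window, dtype=np.int64)
    for a in alignments:
        ref = genomes[a.genome_id][a.start : a.start + a.aligned_length]
        if a.strand == "-":
            ref = revcomp(ref)  # orient reference to read coordinates
        L = len(ref)
        mism = {pos: (rb, qb) for pos, rb, qb in a.mismatch_list}
        w5 = min(window, L)
        for p in range(w5):
            if ref[p] == "C":
                opp_c5[p] += 1
                entry = mism.get(p)
                if entry is not None and entry[1] == "T":
                    ct5[p] += 1
        for p in range(w5):
            idx = L - 1 - p
            if ref[idx] == "G":
                opp_g3[p] += 1
                entry = mism.get(idx)
                if entry is not None and entry[1] == "A":
                    ga3[p] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        f5 = np.where(opp_c5 > 0, ct5 / np.maximum(opp_c5, 1), np.nan)
        f3 = np.where(opp_g3 > 0, ga3 / np.maximum(opp_g3, 1), np.nan)
    return DamageProfile(
        window=window,
        ct5=f5,
        ga3=f3,
        opp_c5=opp_c5,
        opp_g3=opp_g3,
        ct5_counts=ct5,
        ga3_counts=ga3,
        n_alignments=len(alignments),
    )


def _end_signature(
    freq: np.ndarray,
    opp: np.ndarray,
    min_terminal: float,
    decay_ratio: float,
    min_opportunities: int,
) -> tuple[bool, str]:
    if opp[0] < min_opportunities:
        return False, "insufficient data"
    terminal = freq[0]
    if np.isnan(terminal) or terminal < min_terminal:
        return False, f"terminal rate {0.0 if np.isnan(terminal) else terminal:.3f} below {min_terminal}"
    interior = freq[9] if len(freq) > 9 and opp[9] > 0 else 0.0
    if terminal < decay_ratio * interior:
        return False, f"no decay: terminal {terminal:.3f} vs position-10 {interior:.3f}"
    return True, f"terminal {terminal:.3f}, position-10 {interior:.3f}"


def has_damage_signature(
    profile: DamageProfile,
    min_terminal: float = 0.05,
    decay_ratio: float = 2.0,
    min_opportunities: int = 200,
    require_both_ends: bool = False,
) -> tuple[bool, str]:
    """Boolean damage call with a human-readable rationale.

    An end shows the signature when its terminal misincorporation frequency
    is at least ``min_terminal``, exceeds ``decay_ratio`` times the
    position-10 frequency, and rests on at least ``min_opportunities``
    reference bases. By default either end suffices.
    """
    ok5, why5 = _end_signature(
        profile.ct5, profile.opp_c5, min_terminal, decay_ratio, min_opportunities
    )
    ok3, why3 = _end_signature(
        profile.ga3, profile.opp_g3, min_terminal, decay_ratio, min_opportunities
    )
    verdict = (ok5 and ok3) if require_both_ends else (ok5 or ok3)
    rationale = f"5' C->T: {why5}; 3' G->A: {why3}"
    if not verdict and "insufficient data" in (why5, why3) and why5 == why3:
        rationale = "insufficient data"
    return verdict, rationale
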