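"""Small sequence helpers and packaged adapter constants."""
from __future__ import annotations

# Illumina P7 read-through adapter as seen from read 1 (34 bases). The first
# 12 bases are the in-read index assay prefix; the remaining 22 form the
# spacer between that prefix and the sample index.
P7_ADAPTER = "AGATCGGAAGAGCACACGTCTGAACTCCAGTCAC"
ASSAY_PREFIX = P7_ADAPTER[:12]
ADAPTER_SPACER = P7_ADAPTER[12:]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA_ALPHABET = frozenset("ACGT")


def complement(base: str) -> str:
    return base.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
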