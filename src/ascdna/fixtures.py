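"""Deterministic generators and golden data for tests and demos.

``worked_example`` returns a fully traced 60-bit encoding — every
intermediate view from bit stream to concatenated strand — that anchors the
codec's behaviour.  ``benchmark_bit_counts`` lists the bit sizes of the
standard 11-sequence DNA compression corpus (chloroplast, human,
mitochondrial and viral genomes), counted at 8 bits per sequence character;
only the sizes are carried, so capacity tabulation needs no downloads.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

__all__ = [
    "WorkedExample",
    "worked_example",
    "random_bits",
    "random_dna",
    "benchmark_bit_counts",
    "benchmark_composition_rows",
]


@dataclass(frozen=True)
class WorkedExample:
    """A 60-bit message traced through every stage of the codec."""

    bit_stream: str
    words: tuple[str, ...]
    extended_words: tuple[str, ...]
    bases: str
    clusters: tuple[int, ...]
    primer: str

    @property
    def concatenated(self) -> str:
        return self.primer + self.bases


_WORDS = (
    "010 001 010 101 001 101 010 010 010 000 "
    "010 010 000 001 010 011 010 000 010 101"
).split()


def worked_example() -> WorkedExample:
    """The canonical 60-bit example, verbatim at every stage."""
    return WorkedExample(
        bit_stream="".join(_WORDS),
        words=tuple(_WORDS),
        extended_words=tuple("0" + w for w in _WORDS),
        bases="TGTAGATTTTTTTGTGTTTA",
        clusters=(1, 0, 1, 0, 0, 0, 1, 1, 1, 0, 1, 1, 0, 0, 1, 1, 1, 0, 1, 0),
        primer="GGACGCACGG",
    )


def random_bits(n: int, seed: int) -> str:
    """``n`` uniform random bits, reproducible for a fixed seed."""
    if n < 0:
        raise ValueError(f"bit count must be non-negative, got {n}")
    rng = random.Random(seed)
    return "".join(rng.choice("01") for _ in range(n))


def random_dna(n: int, seed: int) -> str:
    """``n`` uniform random bases, reproducible for a fixed seed."""
    if n < 0:
        raise ValueError(f"base count must be non-negative, got {n}")
    rng = random.Random(seed)
    return "".join(rng.choice("ACGT") for _ in range(n))


def benchmark_bit_counts() -> list[tuple[str, int]]:
    """Bit sizes of the 11 standard benchmark sequences (8 bits/char)."""
    return [
        ("CHMPXX", 968_192),
        ("CHNTXX", 1_246_752),
        ("HEHCMVCG", 1_834_832),
        ("HUMDYSTROP", 310_160),
        ("HUMGHCSA", 531_960),
        ("HUMHBB", 586_464),
        ("HUMHDAB", 470_912),
        ("HUMHPRTB", 453_896),
        ("MPOMTCG", 1_492_864),
        ("MTPACG", 802_512),
        ("VACCG", 1_533_896),
    ]


def benchmark_composition_rows() -> list[dict[str, int]]:
    """Published per-base counts of sample oligos at four lengths."""
    return [
        {"length": 100, "A": 21, "G": 29, "C": 16, "T": 34},
        {"length": 1_000, "A": 120, "G": 235, "C": 300, "T": 345},
        {"length": 10_000, "A": 2_504, "G": 2_487, "C": 2_756, "T": 2_253},
        {"length": 100_000, "A": 32_155, "G": 17_569, "C": 16_541, "T": 33_735},
    ]
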