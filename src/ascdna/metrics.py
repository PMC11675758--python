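"""Capacity, compression-ratio and base-composition metrics.

Three quantities characterize one encoding run:

* storage capacity ``bpn = bits stored / sequence length`` (bases in the
  full primer+payload output);
* compression ratio ``CR(%) = S_out / S_in * 100`` over symbol counts
  (input bit symbols vs output base symbols) — lower is better;
* GC content ``(|G| + |C|) / n`` of the output strand, a proxy for the
  thermal stability of synthesized oligos.

The closed-form length model ``payload = ceil(n/3)``,
``primer = ceil(payload/2)`` predicts the encoded length of any ``n``-bit
input without running the codec, so capacity can be tabulated for benchmark
corpora from their bit counts alone.  Benchmark files are conventionally
counted at 8 bits per sequence character (ASCII text), not 2 bits per base;
both accountings are supported.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .codec import AscdnaError, DNA_ALPHABET, EncodedMessage, _normalize_dna

__all__ = [
    "LengthPrediction",
    "CapacityReport",
    "CompressionReport",
    "CompositionReport",
    "predicted_encoded_length",
    "predicted_bpn",
    "measured_bpn",
    "compression_ratio",
    "composition",
    "capacity_table",
    "format_table",
]

#: Number of significant figures used when printing bpn values.
BPN_SIGFIGS = 9


class UndefinedRatioError(AscdnaError):
    """A ratio whose denominator would be zero."""


class LengthPrediction(NamedTuple):
    payload: int
    primer: int
    total: int


@dataclass(frozen=True)
class CapacityReport:
    """Storage density of one encoded message."""

    bits_stored: int
    payload_bases: int
    primer_bases: int

    @property
    def sequence_length(self) -> int:
        return self.payload_bases + self.primer_bases

    @property
    def bpn(self) -> float:
        return self.bits_stored / self.sequence_length


@dataclass(frozen=True)
class CompressionReport:
    """Symbol-count compression ratio of one encoding run."""

    input_symbols: int
    output_symbols: int

    @property
    def ratio_percent(self) -> float:
        return 100.0 * self.output_symbols / self.input_symbols


@dataclass(frozen=True)
class CompositionReport:
    """Per-base counts and GC statistics of a DNA sequence."""

    a: int
    c: int
    g: int
    t: int

    @property
    def length(self) -> int:
        return self.a + self.c + self.g + self.t

    @property
    def gc_count(self) -> int:
        return self.g + self.c

    @property
    def gc_fraction(self) -> float:
        return self.gc_count / self.length


def predicted_encoded_length(n_bits: int) -> LengthPrediction:
    """Closed-form encoded length for an ``n_bits``-bit message."""
    if n_bits < 0:
        raise AscdnaError(f"bit count must be non-negative, got {n_bits}")
    payload = -(-n_bits // 3)
    primer = -(-payload // 2)
    return LengthPrediction(payload=payload, primer=primer, total=payload + primer)


def predicted_bpn(n_bits: int) -> float:
    """Predicted bits-per-nucleotide for an ``n_bits``-bit message.

    Equals exactly 2.0 iff ``n_bits`` is divisible by 6; ceil effects pull
    it below 2.0 otherwise (and below 1.5 only for messages under 8 bits).
    """
    if n_bits <= 0:
        raise UndefinedRatioError("bpn is undefined for an empty message")
    return n_bits / predicted_encoded_length(n_bits).total


def measured_bpn(bits_stored: int, encoded: EncodedMessage) -> CapacityReport:
    """Capacity of an actual encoded message (primer + payload bases)."""
    if len(encoded) == 0:
        raise UndefinedRatioError("bpn is undefined for an empty message")
    return CapacityReport(
        bits_stored=bits_stored,
        payload_bases=len(encoded.payload),
        primer_bases=len(encoded.primer),
    )


def compression_ratio(input_symbols: int, output_symbols: int) -> CompressionReport:
    """Symbol-count compression ratio; exactly 50% when bits % 6 == 0."""
    if input_symbols <= 0:
        raise UndefinedRatioError("compression ratio needs a non-empty input")
    return CompressionReport(input_symbols=input_symbols, output_symbols=output_symbols)


def composition(sequence: str) -> CompositionReport:
    """Count A/C/G/T and report GC content of a non-empty DNA sequence."""
    seq = _normalize_dna(sequence)
    if not seq:
        raise AscdnaError("composition is undefined for an empty sequence")
    return CompositionReport(
        a=seq.count("A"), c=seq.count("C"), g=seq.count("G"), t=seq.count("T")
    )


def format_bpn(value: float, sigfigs: int = BPN_SIGFIGS) -> str:
    return f"{value:.{sigfigs}g}"


def capacity_table(
    rows: Iterable[tuple[str, int]], bits_per_char: int = 8
) -> list[dict]:
    """Capacity-model rows for named inputs.

    ``rows`` pairs a name with a size: a bit count when ``bits_per_char`` is
    1, otherwise a character count multiplied out at ``bits_per_char`` bits
    per character (8 for ASCII benchmark files, 2 for binarized DNA).
    """
    out = []
    for name, size in rows:
        n_bits = size * bits_per_char
        pred = predicted_encoded_length(n_bits)
        out.append(
            {
                "name": name,
                "bits": n_bits,
                "payload_bases": pred.payload,
                "primer_bases": pred.primer,
                "total_bases": pred.total,
                "bpn": predicted_bpn(n_bits) if n_bits else float("nan"),
            }
        )
    return out


def format_table(rows: Sequence[dict], fmt: str = "tsv") -> str:
    """Render report rows as a TSV table or JSON array."""
    if fmt == "json":
        return json.dumps(list(rows), indent=2)
    if fmt != "tsv":
        raise AscdnaError(f"unknown table format: {fmt!r}")
    if not rows:
        return ""
    cols = list(rows[0])
    lines = ["\t".join(cols)]
    for row in rows:
        lines.append(
            "\t".join(
                format_bpn(row[c]) if isinstance(row[c], float) else str(row[c])
                for c in cols
            )
        )
    return "\n".join(lines)
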