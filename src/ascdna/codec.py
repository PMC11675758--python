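"""Reversible spatial-encoding DNA storage codec.

The codec stores 3 message bits per payload nucleotide.  Each 3-bit word
``w = b2 b1 b0`` is zero-extended to a 4-bit word ``w' = 0 b2 b1 b0`` and
looked up in a codebook built on a two-dimensional spatial domain: the four
DNA base vectors appear once in each of two half-planes ("Cluster 0" and
"Cluster 1"), giving eight distinct (base, cluster) pairs — one per 4-bit
word with a zero most-significant bit.  The payload records the bases; the
cluster-bit stream is compressed two bits per base into a prepended
"primer" sequence (a metadata channel, not a PCR primer).  Total output is
``ceil(n/3) + ceil(ceil(n/3)/2)`` bases for an ``n``-bit message, i.e. half
the symbol count of the message whenever ``n`` is divisible by 6.

All bit material is represented as Python ``str`` of ``'0'``/``'1'``
characters; DNA sequences are uppercase ``str`` over ``ACGT``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence, Tuple

__all__ = [
    "AscdnaError",
    "AlphabetError",
    "BitLengthError",
    "CodebookDomainError",
    "MalformedMessageError",
    "Codebook",
    "EncodedMessage",
    "DEFAULT_CODEBOOK",
    "PAYLOAD_BITS_TO_BASE",
    "PAYLOAD_BASE_TO_BITS",
    "PRIMER_BASE_TO_BITS",
    "PRIMER_BITS_TO_BASE",
    "dna_to_bits",
    "bits_to_dna",
    "split_words",
    "extend_word",
    "truncate_word",
    "encode_word",
    "decode_word",
    "clusters_to_primer",
    "primer_to_clusters",
    "encode_bits",
    "encode_dna",
    "split_concatenated",
    "decode_message",
]

DNA_ALPHABET = "ACGT"

#: Payload bit<->base translation (2 bits per base): 00-T, 01-G, 10-C, 11-A.
PAYLOAD_BITS_TO_BASE: Mapping[str, str] = {"00": "T", "01": "G", "10": "C", "11": "A"}
PAYLOAD_BASE_TO_BITS: Mapping[str, str] = {b: p for p, b in PAYLOAD_BITS_TO_BASE.items()}

#: Primer base<->bit translation (distinct from the payload table by design):
#: A-00, T-01, G-10, C-11.
PRIMER_BASE_TO_BITS: Mapping[str, str] = {"A": "00", "T": "01", "G": "10", "C": "11"}
PRIMER_BITS_TO_BASE: Mapping[str, str] = {p: b for b, p in PRIMER_BASE_TO_BITS.items()}


class AscdnaError(ValueError):
    """Base class for all codec errors."""


class AlphabetError(AscdnaError):
    """A symbol outside the ACGT alphabet (position reported)."""


class BitLengthError(AscdnaError):
    """A bit string has an impossible length for the requested operation."""


class CodebookDomainError(AscdnaError):
    """A 4-bit word outside the codebook domain (MSB must be 0)."""


class MalformedMessageError(AscdnaError):
    """An encoded message whose structure violates the codec's length laws."""


def _check_bits(bits: str) -> None:
    for i, c in enumerate(bits):
        if c not in "01":
            raise AscdnaError(f"not a binary digit at position {i}: {c!r}")


def _normalize_dna(sequence: str) -> str:
    seq = sequence.upper()
    for i, c in enumerate(seq):
        if c not in DNA_ALPHABET:
            raise AlphabetError(f"invalid DNA symbol at position {i}: {sequence[i]!r}")
    return seq


@dataclass(frozen=True)
class Codebook:
    """Bijection between MSB-0 4-bit words and (base, cluster) pairs.

    The default mapping follows the closed-form spatial-domain rule: for
    ``w' = 0 b2 b1 b0`` the base is the payload-table base of the bit pair
    ``b2 b0`` and the cluster bit is ``b1``.  Equivalently, in Cluster 0 the
    base vectors for T/G/C/A carry the suffixes 00/01 and in Cluster 1 the
    suffixes 10/11.  An alternative bijection over the same domain may be
    injected.
    """

    payload_map: Mapping[str, Tuple[str, int]]
    inverse_map: Mapping[Tuple[str, int], str] = field(init=False)

    def __post_init__(self) -> None:
        domain = {f"0{v:03b}" for v in range(8)}
        if set(self.payload_map) != domain:
            raise AscdnaError("codebook domain must be the 8 MSB-0 4-bit words")
        pairs = set(self.payload_map.values())
        if len(pairs) != 8:
            raise AscdnaError("codebook must be a bijection onto 8 distinct pairs")
        for base, cluster in pairs:
            if base not in DNA_ALPHABET or cluster not in (0, 1):
                raise AscdnaError(f"invalid codebook pair ({base!r}, {cluster!r})")
        object.__setattr__(
            self, "inverse_map", {pair: w4 for w4, pair in self.payload_map.items()}
        )


def _default_payload_map() -> dict[str, Tuple[str, int]]:
    mapping = {}
    for v in range(8):
        b2, b1, b0 = (v >> 2) & 1, (v >> 1) & 1, v & 1
        base = PAYLOAD_BITS_TO_BASE[f"{b2}{b0}"]
        mapping[f"0{b2}{b1}{b0}"] = (base, b1)
    return mapping


DEFAULT_CODEBOOK = Codebook(payload_map=_default_payload_map())


@dataclass(frozen=True)
class EncodedMessage:
    """A primer + payload pair together with the pre-padding bit length.

    ``original_bit_length`` disambiguates trailing pad bits: the encoder
    right-pads the message with zeros to a multiple of three, so the payload
    alone determines the bit count only up to two bits.
    """

    primer: str
    payload: str
    original_bit_length: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "primer", _normalize_dna(self.primer))
        object.__setattr__(self, "payload", _normalize_dna(self.payload))
        p = len(self.payload)
        if len(self.primer) != -(-p // 2):
            raise MalformedMessageError(
                f"primer length {len(self.primer)} != ceil(payload/2) = {-(-p // 2)}"
            )
        pad = 3 * p - self.original_bit_length
        if not 0 <= pad <= 2:
            raise MalformedMessageError(
                f"original_bit_length {self.original_bit_length} incompatible "
                f"with payload of {p} bases (pad {pad} outside 0..2)"
            )

    @property
    def concatenated(self) -> str:
        """Primer followed by payload — the synthesized strand."""
        return self.primer + self.payload

    def __len__(self) -> int:
        return len(self.primer) + len(self.payload)


def dna_to_bits(sequence: str) -> str:
    """Binarize a DNA sequence at 2 bits per base (T-00, G-01, C-10, A-11)."""
    seq = _normalize_dna(sequence)
    return "".join(PAYLOAD_BASE_TO_BITS[c] for c in seq)


def bits_to_dna(bits: str) -> str:
    """Inverse of :func:`dna_to_bits`; requires an even number of bits."""
    _check_bits(bits)
    if len(bits) % 2:
        raise BitLengthError(f"bit length {len(bits)} is not even")
    return "".join(PAYLOAD_BITS_TO_BASE[bits[i : i + 2]] for i in range(0, len(bits), 2))


def split_words(bits: str) -> Tuple[list[str], int]:
    """Split bits into 3-bit words, right-padding with zeros.

    Returns the word list and the number of pad bits appended (0, 1 or 2).
    """
    _check_bits(bits)
    pad = -len(bits) % 3
    padded = bits + "0" * pad
    return [padded[i : i + 3] for i in range(0, len(padded), 3)], pad


def extend_word(w: str) -> str:
    """Zero-extend a 3-bit word at the MSB; the numeric value is unchanged."""
    _check_bits(w)
    if len(w) != 3:
        raise BitLengthError(f"word must have 3 bits, got {len(w)}")
    return "0" + w


def truncate_word(w4: str) -> str:
    """Drop the zero MSB of a 4-bit word; inverse of :func:`extend_word`."""
    _check_bits(w4)
    if len(w4) != 4:
        raise BitLengthError(f"extended word must have 4 bits, got {len(w4)}")
    if w4[0] != "0":
        raise CodebookDomainError(f"extended word MSB must be 0, got {w4!r}")
    return w4[1:]


def encode_word(w4: str, codebook: Codebook = DEFAULT_CODEBOOK) -> Tuple[str, int]:
    """Map an MSB-0 4-bit word to its (base, cluster-bit) pair."""
    _check_bits(w4)
    if len(w4) != 4:
        raise BitLengthError(f"extended word must have 4 bits, got {len(w4)}")
    if w4[0] != "0":
        raise CodebookDomainError(f"extended word MSB must be 0, got {w4!r}")
    return codebook.payload_map[w4]


def decode_word(base: str, cluster: int, codebook: Codebook = DEFAULT_CODEBOOK) -> str:
    """Exact inverse of :func:`encode_word`; all 8 pairs are valid."""
    base = _normalize_dna(base)
    if cluster not in (0, 1):
        raise AscdnaError(f"cluster bit must be 0 or 1, got {cluster!r}")
    return codebook.inverse_map[(base, cluster)]


def clusters_to_primer(
    clusters: Sequence[int], codebook: Codebook = DEFAULT_CODEBOOK
) -> str:
    """Compress a cluster-bit stream into primer bases, two bits per base.

    An odd-length stream is right-padded with a single 0 before pairing.
    """
    for i, c in enumerate(clusters):
        if c not in (0, 1):
            raise AscdnaError(f"cluster bit at position {i} must be 0 or 1: {c!r}")
    bits = "".join(str(c) for c in clusters)
    if len(bits) % 2:
        bits += "0"
    return "".join(PRIMER_BITS_TO_BASE[bits[i : i + 2]] for i in range(0, len(bits), 2))


def primer_to_clusters(
    primer: str, codebook: Codebook = DEFAULT_CODEBOOK
) -> list[int]:
    """Expand a primer back to its cluster bits (two per base, pad included)."""
    seq = _normalize_dna(primer)
    out: list[int] = []
    for c in seq:
        pair = PRIMER_BASE_TO_BITS[c]
        out.append(int(pair[0]))
        out.append(int(pair[1]))
    return out


def encode_bits(bits: str, codebook: Codebook = DEFAULT_CODEBOOK) -> EncodedMessage:
    """Encode a bit string into a primer + payload message.

    The payload has ``ceil(n/3)`` bases and the primer ``ceil(payload/2)``
    bases for an ``n``-bit input.
    """
    words, _ = split_words(bits)
    bases = []
    clusters = []
    for w in words:
        base, cluster = encode_word(extend_word(w), codebook)
        bases.append(base)
        clusters.append(cluster)
    primer = clusters_to_primer(clusters, codebook)
    return EncodedMessage(
        primer=primer, payload="".join(bases), original_bit_length=len(bits)
    )


def encode_dna(sequence: str, codebook: Codebook = DEFAULT_CODEBOOK) -> EncodedMessage:
    """Encode a DNA sequence: binarize at 2 bits per base, then encode."""
    return encode_bits(dna_to_bits(sequence), codebook)


def split_concatenated(
    sequence: str, original_bit_length: int | None = None
) -> EncodedMessage:
    """Split a concatenated primer+payload strand back into a message.

    For a total of ``T`` bases the payload holds ``floor(2T/3)`` bases and
    the primer the remaining third (exactly ``T/3`` when the payload length
    is even).  When ``original_bit_length`` is not given it defaults to
    ``3 * payload`` (no trailing pad assumed).
    """
    seq = _normalize_dna(sequence)
    total = len(seq)
    p = (2 * total) // 3
    primer_len = total - p
    if primer_len != -(-p // 2):
        raise MalformedMessageError(
            f"total length {total} is not realizable as payload + ceil(payload/2)"
        )
    if original_bit_length is None:
        original_bit_length = 3 * p
    return EncodedMessage(
        primer=seq[:primer_len],
        payload=seq[primer_len:],
        original_bit_length=original_bit_length,
    )


def decode_message(msg: EncodedMessage, codebook: Codebook = DEFAULT_CODEBOOK) -> str:
    """Recover the original bits: exact inverse of :func:`encode_bits`."""
    clusters = primer_to_clusters(msg.primer, codebook)[: len(msg.payload)]
    words = [
        truncate_word(decode_word(base, cluster, codebook))
        for base, cluster in zip(msg.payload, clusters)
    ]
    return "".join(words)[: msg.original_bit_length]
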