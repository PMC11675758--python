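"""Container formats and byte/bit packing.

Encoded messages travel as plain FASTA.  The description line carries
``key=value`` metadata tokens; the key ``ascdna_bits`` records the original
(pre-padding) bit length so the decoder can strip trailing pad bits.  A
sidecar mode writes the metadata to ``<path>.meta.json`` instead, for
pipelines that strip FASTA descriptions.

Message input may also be raw binary (packed MSB-first, 8 bits per byte) or
0/1 text with whitespace ignored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .codec import AlphabetError, AscdnaError, DNA_ALPHABET

__all__ = [
    "ORIGINAL_BITS_KEY",
    "Record",
    "MessageContainer",
    "bytes_to_bits",
    "bits_to_bytes",
    "read_container",
    "write_container",
]

#: Description-line key holding the original bit length of an encoded record.
ORIGINAL_BITS_KEY = "ascdna_bits"

FORMATS = ("fasta", "bits", "raw")


def bytes_to_bits(data: bytes) -> str:
    """Unpack bytes to bits, MSB-first within each byte."""
    return "".join(f"{b:08b}" for b in data)


def bits_to_bytes(bits: str) -> bytes:
    """Pack bits (length divisible by 8) back to bytes; inverse of unpack."""
    if len(bits) % 8:
        raise AscdnaError(f"bit length {len(bits)} is not divisible by 8")
    return bytes(int(bits[i : i + 8], 2) for i in range(0, len(bits), 8))


@dataclass
class Record:
    """One named sequence with its metadata.

    ``sequence`` is DNA for FASTA containers and a 0/1 string for bit
    containers (``metadata['kind'] == 'bits'``).
    """

    id: str
    sequence: str
    metadata: dict[str, str] = field(default_factory=dict)

    @property
    def original_bit_length(self) -> int | None:
        v = self.metadata.get(ORIGINAL_BITS_KEY)
        return int(v) if v is not None else None


@dataclass
class MessageContainer:
    records: list[Record] = field(default_factory=list)

    def __iter__(self) -> Iterator[Record]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _parse_description(rec_id: str, description: str) -> dict[str, str]:
    meta: dict[str, str] = {}
    for token in description.split():
        if token == rec_id:
            continue
        if "=" in token:
            key, _, value = token.partition("=")
            meta[key] = value
    return meta


def _apply_policy(record_id: str, seq: str, strict: bool) -> tuple[str, int]:
    seq = seq.upper()
    kept = []
    skipped = 0
    for i, c in enumerate(seq):
        if c in DNA_ALPHABET:
            kept.append(c)
        elif strict:
            raise AlphabetError(
                f"record {record_id!r}: invalid DNA symbol at position {i}: {c!r}"
            )
        else:
            skipped += 1
    return "".join(kept), skipped


def read_container(
    path: str | Path, format: str = "fasta", strict: bool = True
) -> MessageContainer:
    """Read a message container from ``path``.

    ``format`` is one of ``fasta`` (DNA records), ``bits`` (0/1 text,
    whitespace ignored) or ``raw`` (arbitrary bytes, unpacked MSB-first).
    Under the strict alphabet policy any non-ACGT character in FASTA input
    is an error; otherwise offending characters are dropped and counted in
    the record metadata under ``skipped``.
    """
    path = Path(path)
    if format not in FORMATS:
        raise AscdnaError(f"unknown container format: {format!r}")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "raw":
        bits = bytes_to_bits(path.read_bytes())
        return MessageContainer([Record(path.name, bits, {"kind": "bits"})])
    if format == "bits":
        text = path.read_text()
        bits = "".join(text.split())
        for i, c in enumerate(bits):
            if c not in "01":
                raise AscdnaError(f"not a binary digit at position {i}: {c!r}")
        return MessageContainer([Record(path.name, bits, {"kind": "bits"})])

    sidecar = _read_sidecar(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        meta = _parse_description(rec.id, rec.description)
        meta.update(sidecar.get(rec.id, {}))
        seq, skipped = _apply_policy(rec.id, str(rec.seq), strict)
        if skipped:
            meta["skipped"] = str(skipped)
        records.append(Record(rec.id, seq, meta))
    return MessageContainer(records)


def _read_sidecar(path: Path) -> dict[str, dict[str, str]]:
    sidecar_path = path.with_name(path.name + ".meta.json")
    if not sidecar_path.exists():
        return {}
    raw = json.loads(sidecar_path.read_text())
    return {rid: {k: str(v) for k, v in meta.items()} for rid, meta in raw.items()}


def write_container(
    container: MessageContainer,
    path: str | Path,
    format: str = "fasta",
    sidecar: bool = False,
) -> None:
    """Write a container; ``read_container`` round-trips it bit-exactly.

    FASTA output is wrapped at 60 columns with metadata in the description
    line, or in ``<path>.meta.json`` when ``sidecar`` is true.  Input order
    is preserved so output files are reproducible byte-for-byte.
    """
    path = Path(path)
    if format not in FORMATS:
        raise AscdnaError(f"unknown container format: {format!r}")
    if format == "raw":
        (rec,) = container.records
        path.write_bytes(bits_to_bytes(rec.sequence))
        return
    if format == "bits":
        (rec,) = container.records
        path.write_text(rec.sequence + "\n" if rec.sequence else "")
        return

    seq_records = []
    sidecar_meta: dict[str, dict[str, str]] = {}
    for rec in container:
        if sidecar:
            description = ""
            if rec.metadata:
                sidecar_meta[rec.id] = dict(rec.metadata)
        else:
            description = " ".join(f"{k}={v}" for k, v in rec.metadata.items())
        seq_records.append(
            SeqRecord(Seq(rec.sequence), id=rec.id, description=description)
        )
    SeqIO.write(seq_records, str(path), "fasta")
    if sidecar:
        sidecar_path = path.with_name(path.name + ".meta.json")
        sidecar_path.write_text(json.dumps(sidecar_meta, indent=2) + "\n")
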