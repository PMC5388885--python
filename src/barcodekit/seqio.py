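"""Sequence I/O, normalization and quality masking.

All sequences handled by the toolkit are normalized to the five-letter
alphabet ``{A, C, G, T, N}``: input is uppercased and every other character
(IUPAC ambiguity codes, U, gaps, ...) becomes ``N``.  Both assemblers and the
reference-database model are defined only over this alphabet.

Quality scores are integer Phred values.  FASTQ files are assumed Phred+33
(Sanger/modern Illumina); the offset is configurable.

Labelled barcode FASTA files use the header dialect
``>species|specimen_id|locus`` (the species field may contain spaces).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FastaHeaderError, FastqParseError

#: Characters that survive normalization.
ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGTN = re.compile(r"[^ACGTN]")

FASTA_DELIMITER = "|"


def normalize_sequence(seq: str) -> str:
    """Uppercase ``seq`` and replace every character outside ACGTN with N."""
    return _NON_ACGTN.sub("N", seq.upper())


def reverse_complement(seq: str) -> str:
    """Reverse complement over the ACGTN alphabet (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class QualityRead:
    """One sequencer read: bases, per-base Phred qualities and orientation."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    direction: str = "unknown"  # forward | reverse | unknown

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise FastqParseError(
                f"record {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        object.__setattr__(self, "quals", tuple(int(q) for q in self.quals))

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class PrimerPair:
    """Forward/reverse PCR primers for one locus, both given 5'→3' as synthesized."""

    locus: str
    forward: str
    reverse: str

    def __post_init__(self):
        for name in ("forward", "reverse"):
            seq = getattr(self, name)
            if not seq:
                raise ValueError(f"{name} primer must be non-empty")
            if set(seq) - set("ACGT"):
                raise ValueError(
                    f"{name} primer {seq!r} contains characters outside ACGT"
                )


@dataclass(frozen=True)
class BarcodeRecord:
    """A species-labelled barcode sequence; the unit of the reference model."""

    species: str
    specimen_id: str
    locus: str
    sequence: str

    def __post_init__(self):
        if not self.species:
            raise ValueError("species label must be non-empty")
        if not self.sequence:
            raise ValueError("sequence must be non-empty")

    @property
    def genus(self) -> str:
        """First whitespace-delimited token of the species label."""
        return self.species.split()[0]


def read_fastq(path, offset: int = 33) -> list[QualityRead]:
    """Parse a 4-line-record FASTQ file into normalized :class:`QualityRead` s.

    Bases are uppercased and non-ACGT characters become N.  A record whose
    base and quality strings differ in length raises :class:`FastqParseError`
    naming the record.
    """
    fmt = {33: "fastq", 64: "fastq-illumina"}.get(offset)
    if fmt is None:
        raise ValueError(f"unsupported quality offset {offset}")
    reads: list[QualityRead] = []
    try:
        for rec in SeqIO.parse(str(path), fmt):
            reads.append(
                QualityRead(
                    read_id=rec.id,
                    bases=normalize_sequence(str(rec.seq)),
                    quals=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:  # Biopython names the offending record
        raise FastqParseError(str(exc)) from exc
    return reads


def write_fastq(reads: Iterable[QualityRead], path, offset: int = 33) -> None:
    """Write reads as Phred+33 FASTQ (offset 64 also supported)."""
    fmt = {33: "fastq", 64: "fastq-illumina"}[offset]
    records = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


def mask_low_quality(read: QualityRead, q_min: int = 30) -> QualityRead:
    """Replace every base whose quality is below ``q_min`` with N.

    Qualities are left untouched, so the operation is idempotent.  Q == q_min
    is kept.
    """
    bases = "".join(
        "N" if q < q_min else b for b, q in zip(read.bases, read.quals)
    )
    return QualityRead(read.read_id, bases, read.quals, read.direction)


def _format_header(record: BarcodeRecord) -> str:
    for fld in (record.species, record.specimen_id, record.locus):
        if FASTA_DELIMITER in fld:
            raise FastaHeaderError(
                f"field {fld!r} contains the reserved delimiter {FASTA_DELIMITER!r}"
            )
    return FASTA_DELIMITER.join((record.species, record.specimen_id, record.locus))


def write_fasta(records: Iterable[BarcodeRecord], path) -> None:
    """Write labelled barcodes as FASTA with ``>species|specimen_id|locus`` headers."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=_format_header(r), description="")
        for r in records
    ]
    SeqIO.write(seq_records, str(path), "fasta")


def read_fasta(path) -> list[BarcodeRecord]:
    """Read labelled barcodes written by :func:`write_fasta`.

    Headers must contain exactly two ``|`` delimiters; anything else raises
    :class:`FastaHeaderError` naming the record.  Sequences are normalized.
    """
    records: list[BarcodeRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        header = rec.description or rec.id
        parts = header.split(FASTA_DELIMITER)
        if len(parts) != 3:
            raise FastaHeaderError(
                f"header {header!r} is not of the form species|specimen_id|locus"
            )
        species, specimen_id, locus = (p.strip() for p in parts)
        records.append(
            BarcodeRecord(
                species=species,
                specimen_id=specimen_id,
                locus=locus,
                sequence=normalize_sequence(str(rec.seq)),
            )
        )
    return records
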