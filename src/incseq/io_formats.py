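"""Sequence and table I/O.

All other modules work on :class:`SequenceRecord` objects; this module is the
only place that touches FASTA/FASTQ files (via Biopython's SeqIO) and the
tab-separated report files the command-line tools write.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "SequenceRecord",
    "read_sequences",
    "write_sequences",
    "write_table",
    "revcomp",
]

_ALPHABET = set("ACGTN")
# IUPAC one-letter ambiguity codes that are collapsed to N.
_IUPAC_OTHER = set("RYSWKMBDHVU")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One named nucleotide sequence (read, reference or consensus).

    The sequence is normalized on construction: lower case is upper-cased and
    IUPAC ambiguity codes other than N are replaced by N (with a warning).
    ``qual`` holds per-base phred scores when the record came from FASTQ.
    """

    id: str
    seq: str
    description: str = ""
    qual: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        seq = self.seq.upper()
        extra = set(seq) - _ALPHABET
        if extra:
            bad = extra - _IUPAC_OTHER
            if bad:
                raise ValueError(
                    f"record {self.id!r}: illegal characters {sorted(bad)}"
                )
            warnings.warn(
                f"record {self.id!r}: ambiguity codes {sorted(extra)} mapped to N",
                stacklevel=2,
            )
            seq = "".join(c if c in _ALPHABET else "N" for c in seq)
        # Empty sequences are tolerated in memory (an aggressive error model
        # can delete every base); file I/O rejects them.
        self.seq = seq
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "SequenceRecord":
        qual = None if self.qual is None else list(reversed(self.qual))
        return SequenceRecord(self.id, revcomp(self.seq), self.description, qual)


def _detect_format(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line[0]
                break
        else:
            return "fasta"  # empty file: harmless default
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise ValueError(f"{path}: cannot detect format from first character {first!r}")


def read_sequences(path: str | Path, format: str = "auto") -> list[SequenceRecord]:
    """Read FASTA or FASTQ into a list of :class:`SequenceRecord`.

    Records come back in file order.  A duplicate id is an error: downstream
    bookkeeping (truth tables, reports) keys on read ids.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        format = _detect_format(path)
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")

    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for i, rec in enumerate(SeqIO.parse(str(path), format)):
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r} (record {i})")
        seen.add(rec.id)
        qual = rec.letter_annotations.get("phred_quality")
        if len(rec.seq) == 0:
            raise ValueError(f"{path}: malformed record {i}: empty sequence")
        try:
            records.append(
                SequenceRecord(
                    id=rec.id,
                    seq=str(rec.seq),
                    description=rec.description,
                    qual=list(qual) if qual is not None else None,
                )
            )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed record {i}: {exc}") from exc
    return records


def write_sequences(
    records: Iterable[SequenceRecord], path: str | Path, format: str = "fasta"
) -> None:
    """Write records as FASTA (wrapped at 80 columns) or FASTQ (phred+33)."""
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    out = []
    for rec in records:
        if not rec.seq:
            raise ValueError(f"record {rec.id!r}: cannot write empty sequence")
        srec = SeqRecord(Seq(rec.seq), id=rec.id, description=rec.description)
        if format == "fastq":
            if rec.qual is None:
                raise ValueError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            srec.letter_annotations["phred_quality"] = list(rec.qual)
        out.append(srec)
    if format == "fasta":
        from Bio.SeqIO.FastaIO import FastaWriter

        with open(path, "w") as fh:
            FastaWriter(fh, wrap=80).write_file(out)
    else:
        SeqIO.write(out, str(path), "fastq")


def write_table(rows: Sequence[dict], path: str | Path, columns: list[str] | None = None) -> None:
    """Write a list of records as a TSV with a header row.

    Column order follows ``columns`` when given, otherwise first-seen order.
    Values containing tabs or newlines are rejected rather than quoted.
    """
    if columns is None:
        columns = []
        for row in rows:
            for key in row:
                if key not in columns:
                    columns.append(key)
    for i, row in enumerate(rows):
        for key, val in row.items():
            if isinstance(val, str) and ("\t" in val or "\n" in val):
                raise ValueError(f"row {i}, field {key!r}: tab/newline not allowed in TSV")
    df = pd.DataFrame(list(rows), columns=columns)
    df.to_csv(path, sep="\t", index=False)
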