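"""Sequence and table input/output.

Transcripts ("unitigs" in assembler parlance: distinct assembled sequences,
contigs plus singletons) are modelled as immutable records over the DNA
alphabet {A, C, G, T, N}.  FASTA/FASTQ parsing is delegated to Biopython's
low-level iterators; this module adds strict validation with line-number
reporting and a round-trip-safe writer.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "Transcript",
    "SequenceRead",
    "ReadSet",
    "ParseError",
    "read_sequences",
    "write_sequences",
    "write_report",
    "read_table",
    "reverse_complement",
]

_VALID_CHARS = frozenset("ACGTN")
# EC number: four dot-separated fields; a trailing class-level dash is allowed.
_EC_RE = re.compile(r"^\d+\.\d+\.\d+\.(?:\d+|-)$")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """Malformed sequence file; the message names the offending line."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def _validate_ec(ec: str) -> None:
    if not _EC_RE.match(ec):
        raise ValueError(f"malformed EC number: {ec!r}")


@dataclass(frozen=True)
class Transcript:
    """A distinct assembled sequence with optional enzyme annotations.

    ``truth_origin`` ({'host', 'symbiont'}) is only ever set by the
    synthetic-community generator; real data carries ``None``.
    """

    id: str
    sequence: str
    ec_annotations: frozenset[str] = frozenset()
    truth_origin: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("transcript id must be non-empty")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _VALID_CHARS
        if bad:
            raise ValueError(
                f"transcript {self.id}: invalid characters {sorted(bad)}"
            )
        object.__setattr__(self, "ec_annotations", frozenset(self.ec_annotations))
        for ec in self.ec_annotations:
            _validate_ec(ec)
        if self.truth_origin not in (None, "host", "symbiont"):
            raise ValueError(f"invalid truth_origin {self.truth_origin!r}")

    @property
    def length_bp(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class SequenceRead:
    id: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class ReadSet:
    """An ordered collection of sequencing reads."""

    reads: list[SequenceRead] = field(default_factory=list)
    paired: bool = False

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


def read_sequences(path: str | Path, format: str = "fasta"):
    """Read a FASTA file into ``[Transcript]`` or a FASTQ file into a ReadSet.

    Order is preserved, sequences are upper-cased, N is retained.  Malformed
    records raise :class:`ParseError` naming the line number.
    """
    path = Path(path)
    if format == "fasta":
        return _read_fasta(path)
    if format == "fastq":
        return _read_fastq(path)
    raise ValueError(f"unknown format {format!r}")


def _read_fasta(path: Path) -> list[Transcript]:
    transcripts: list[Transcript] = []
    seen: set[str] = set()
    with open(path) as handle:
        for n_rec, (title, seq) in enumerate(SimpleFastaParser(handle)):
            name = title.split(None, 1)[0] if title else ""
            line = _locate_fasta_header(path, n_rec)
            if not name:
                raise ParseError(f"{path}:{line}: empty FASTA header")
            if not seq:
                raise ParseError(
                    f"{path}:{line}: record {name!r} has a header but no sequence"
                )
            if name in seen:
                raise ParseError(f"{path}:{line}: duplicate id {name!r}")
            seen.add(name)
            try:
                transcripts.append(Transcript(id=name, sequence=seq))
            except ValueError as exc:
                raise ParseError(f"{path}:{line}: {exc}") from exc
    return transcripts


def _locate_fasta_header(path: Path, record_index: int) -> int:
    """Line number (1-based) of the record_index-th '>' header."""
    count = -1
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            if raw.startswith(">"):
                count += 1
                if count == record_index:
                    return lineno
    return 0


def _read_fastq(path: Path) -> ReadSet:
    reads: list[SequenceRead] = []
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            # FASTQ records written by this package are strictly 4 lines, so
            # the failing record starts at line 4*index + 1.
            line = 4 * index + 1
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(f"{path}:{line}: {exc}") from exc
            name = title.split(None, 1)[0]
            seq = seq.upper()
            if set(seq) - _VALID_CHARS:
                raise ParseError(
                    f"{path}:{line}: read {name!r} has non-ACGTN characters"
                )
            if len(qual) != len(seq):
                raise ParseError(
                    f"{path}:{line}: read {name!r} quality/sequence length mismatch"
                )
            reads.append(SequenceRead(id=name, sequence=seq, quality=qual))
            index += 1
    return ReadSet(reads=reads, paired=False)


def write_sequences(
    records: Iterable[Transcript] | ReadSet,
    path: str | Path,
    format: str = "fasta",
    wrap: int = 80,
) -> None:
    """Write transcripts as FASTA (wrapped at ``wrap`` columns) or reads as FASTQ."""
    path = Path(path)
    if format == "fasta":
        with open(path, "w") as out:
            for rec in records:
                out.write(f">{rec.id}\n")
                seq = rec.sequence
                for i in range(0, len(seq), wrap):
                    out.write(seq[i : i + wrap] + "\n")
    elif format == "fastq":
        reads = records.reads if isinstance(records, ReadSet) else records
        with open(path, "w") as out:
            for rec in reads:
                qual = rec.quality if getattr(rec, "quality", None) else "I" * len(rec.sequence)
                out.write(f"@{rec.id}\n{rec.sequence}\n+\n{qual}\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _to_frame(report) -> pd.DataFrame:
    if isinstance(report, pd.DataFrame):
        return report
    if hasattr(report, "to_frame"):
        return report.to_frame()
    raise TypeError(f"cannot serialize {type(report).__name__} as a table")


def write_report(report, path: str | Path, format: str = "tsv") -> None:
    """Serialize a report or fixture table to TSV or JSON.

    RPKM (and other float) cells are written with one decimal place; re-reading
    a TSV report with :func:`read_table` yields an equal table.
    """
    path = Path(path)
    if format == "tsv":
        frame = _to_frame(report)
        frame.to_csv(path, sep="\t", index=False, float_format="%.1f")
    elif format == "json":
        if hasattr(report, "to_dict") and not isinstance(report, pd.DataFrame):
            payload = report.to_dict()
        else:
            frame = _to_frame(report)
            payload = frame.to_dict(orient="records")
        with open(path, "w") as out:
            json.dump(payload, out, indent=2)
            out.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def read_table(path: str | Path) -> pd.DataFrame:
    """Read back a TSV report written by :func:`write_report`."""
    return pd.read_csv(path, sep="\t")
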