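"""Sequence, read and interval I/O.

All coordinates in this package are 0-based half-open (BED convention);
1-based positions appear only in rendered reports. FASTA/FASTQ parsing is
delegated to Biopython; BED and TSV go through pandas. Truth sidecars —
per-read simulation ground truth (source interval, strand, per-molecule
methylation level) — are plain TSV keyed by read id.
"""

from __future__ import annotations

import gzip
import io as _stdio
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

VALID_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ParseError(ValueError):
    """A file did not parse under the named standard."""


class ValidationError(ValueError):
    """A record violated an invariant (alphabet, coordinates, lengths)."""


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """A named nucleotide sequence (reference, consensus, or read)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValidationError(
                f"record {self.id!r}: invalid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class GenomicInterval:
    """0-based half-open interval on a named reference."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValidationError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class ReadRecord:
    """A sequencing read with optional qualities and simulation truth."""

    id: str
    sequence: str
    qualities: Optional[list[int]] = None
    truth: Optional[dict] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - VALID_ALPHABET
        if bad:
            raise ValidationError(
                f"read {self.id!r}: invalid characters {sorted(bad)}"
            )
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise ValidationError(
                f"read {self.id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _open_text(path, mode="rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path, format: str = "fasta") -> list:
    """Read FASTA into SequenceRecords or FASTQ into ReadRecords.

    Records come back in file order, sequence case normalised to upper.
    Malformed records raise :class:`ParseError` naming the record index and
    approximate line.
    """
    format = format.lower()
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unsupported format {format!r}")
    out: list = []
    with _open_text(path) as handle:
        try:
            for i, rec in enumerate(SeqIO.parse(handle, format)):
                if format == "fasta":
                    out.append(
                        SequenceRecord(rec.id, str(rec.seq), rec.description)
                    )
                else:
                    out.append(
                        ReadRecord(
                            rec.id,
                            str(rec.seq),
                            list(rec.letter_annotations["phred_quality"]),
                        )
                    )
        except ValueError as exc:
            line = 4 * len(out) + 1 if format == "fastq" else None
            where = f" near line {line}" if line else ""
            raise ParseError(
                f"{path}: malformed {format.upper()} record "
                f"{len(out)}{where}: {exc}"
            ) from exc
    ids = [r.id for r in out]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"{path}: duplicate record ids {dup[:5]}")
    return out


def write_sequences(records: Iterable, path, format: str = "fasta") -> None:
    """Write SequenceRecords/ReadRecords as FASTA or FASTQ.

    Reads without qualities get a constant phred score of 40.
    """
    format = format.lower()
    bio = []
    for rec in records:
        b = _BioSeqRecord(
            Seq(rec.sequence),
            id=rec.id,
            description=getattr(rec, "description", "") or "",
        )
        if format == "fastq":
            quals = getattr(rec, "qualities", None)
            b.letter_annotations["phred_quality"] = (
                list(quals) if quals is not None else [40] * len(rec.sequence)
            )
        bio.append(b)
    with _open_text(path, "wt") as handle:
        SeqIO.write(bio, handle, format)


def read_intervals(path) -> list[GenomicInterval]:
    """Read BED (>=3 columns) into 0-based half-open intervals."""
    intervals: list[GenomicInterval] = []
    with _open_text(path) as handle:
        for i, line in enumerate(handle):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}: line {i + 1}: fewer than 3 BED columns")
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-" else "+"
            try:
                intervals.append(GenomicInterval(chrom, start, end, strand))
            except ValidationError as exc:
                raise ValidationError(f"{path}: record {i}: {exc}") from exc
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path) -> None:
    with _open_text(path, "wt") as handle:
        for iv in intervals:
            handle.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t0\t{iv.strand}\n")


def write_table(table, path) -> None:
    """Write a DataFrame (or list of dicts) as TSV with a header row."""
    df = table if isinstance(table, pd.DataFrame) else pd.DataFrame(table)
    df.to_csv(path, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: pd.DataFrame, path) -> None:
    """Write a truth sidecar TSV; first column must be ``read_id``."""
    if "read_id" not in truth.columns:
        raise ValidationError("truth sidecar requires a 'read_id' column")
    cols = ["read_id"] + [c for c in truth.columns if c != "read_id"]
    truth[cols].to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str})
    if "read_id" not in df.columns:
        raise ParseError(f"{path}: truth sidecar lacks 'read_id' column")
    return df
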