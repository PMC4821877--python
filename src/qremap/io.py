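"""Readers and writers for the plain-text formats the pipeline exchanges.

Coordinate convention: every genomic interval anywhere in this package
is 0-based, half-open (BED convention).  :func:`to_display` is the one
place 1-based inclusive display coordinates are produced.

Missing-value convention: the literal string ``NA`` is the only missing
sentinel in tables; it is read as a pandas NA (never coerced to 0) and
written back as ``NA``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger("qremap")


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class SchemaError(ValueError):
    """A table is missing required columns."""


class AnnotationError(ValueError):
    """Exon annotation violates the per-transcript invariants."""


@dataclass(frozen=True, order=True)
class AnnotationRecord:
    """One exon of one transcript (0-based half-open interval).

    ``exon_index`` counts exons in transcription order: 0 is the 5'-most
    exon of the mature transcript, which for minus-strand transcripts is
    the exon with the largest genomic start.
    """

    chrom: str
    start: int
    end: int
    strand: str
    gene_id: str
    transcript_id: str
    exon_index: int


ANNOTATION_COLUMNS = ["chrom", "start", "end", "strand", "gene_id", "transcript_id", "exon_index"]


def to_display(start: int, end: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive display coordinates."""
    return start + 1, end


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: sequence}`` mapping.

    Sequences are uppercased; T and U are both accepted and preserved as
    read.  Empty files, empty records and text before the first header
    raise :class:`FormatError` naming the offending line or record.
    """
    path = Path(path)
    first = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                first = (lineno, line.rstrip("\n"))
                break
    if first is None:
        raise FormatError(f"{path}: empty FASTA file")
    if not first[1].startswith(">"):
        raise FormatError(f"{path}: line {first[0]}: expected a '>' header, got {first[1][:40]!r}")

    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with an empty header")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        if rec.id in records:
            raise FormatError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    return records


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 60) -> None:
    """Write ``{id: sequence}`` to FASTA, wrapping lines at ``width``."""
    out = []
    for name, seq in records.items():
        if not seq:
            raise FormatError(f"refusing to write empty sequence for {name!r}")
        out.append(SeqRecord(Seq(seq), id=str(name), description=""))
    writer = SeqIO.FastaIO.FastaWriter(str(path), wrap=width)
    writer.write_file(out)


def read_annotation(path: str | Path) -> list[AnnotationRecord]:
    """Read a BED-like TSV of exon records and validate per-transcript invariants.

    Requires a header with the :data:`ANNOTATION_COLUMNS`.  Within one
    transcript, exon intervals must be non-overlapping and the strand
    must be consistent; violations raise :class:`AnnotationError`
    naming the transcript.
    """
    df = read_table(path, {c: None for c in ANNOTATION_COLUMNS})
    records = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if start >= end:
            raise AnnotationError(
                f"{path}: transcript {row.transcript_id!r}: start {start} >= end {end}"
            )
        if row.strand not in ("+", "-"):
            raise AnnotationError(
                f"{path}: transcript {row.transcript_id!r}: bad strand {row.strand!r}"
            )
        records.append(
            AnnotationRecord(
                chrom=str(row.chrom),
                start=start,
                end=end,
                strand=str(row.strand),
                gene_id=str(row.gene_id),
                transcript_id=str(row.transcript_id),
                exon_index=int(row.exon_index),
            )
        )
    validate_annotation(records, source=str(path))
    return sorted(records, key=lambda r: (r.gene_id, r.transcript_id, r.start))


def validate_annotation(records: Iterable[AnnotationRecord], source: str = "annotation") -> None:
    """Check non-overlap and strand consistency per transcript."""
    by_tx: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        by_tx.setdefault(rec.transcript_id, []).append(rec)
    for tx, recs in by_tx.items():
        strands = {r.strand for r in recs}
        if len(strands) > 1:
            raise AnnotationError(f"{source}: transcript {tx!r} mixes strands {sorted(strands)}")
        chroms = {r.chrom for r in recs}
        if len(chroms) > 1:
            raise AnnotationError(f"{source}: transcript {tx!r} spans chromosomes {sorted(chroms)}")
        ordered = sorted(recs, key=lambda r: r.start)
        for a, b in zip(ordered, ordered[1:]):
            if b.start < a.end:
                raise AnnotationError(
                    f"{source}: transcript {tx!r}: exons ({a.start},{a.end}) and "
                    f"({b.start},{b.end}) overlap"
                )


def write_annotation(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    df = pd.DataFrame([vars(r) if not hasattr(r, "_asdict") else r._asdict() for r in records],
                      columns=ANNOTATION_COLUMNS)
    write_table(df, path)


def read_table(path: str | Path, schema: Mapping[str, str | None] | Sequence[str]) -> pd.DataFrame:
    """Read a TSV with a header, enforcing the required columns of ``schema``.

    ``schema`` maps required column names to pandas dtypes (``None``
    leaves the inferred dtype).  Only the literal string ``NA`` is read
    as missing; a missing required column raises :class:`SchemaError`
    listing all missing names.
    """
    if not isinstance(schema, Mapping):
        schema = {c: None for c in schema}
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
    for col, dtype in schema.items():
        if dtype is not None:
            df[col] = df[col].astype(dtype)
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with header; NA values are written as the ``NA`` sentinel."""
    df.to_csv(path, sep="\t", index=False, na_rep="NA")
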