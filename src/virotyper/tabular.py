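"""Readers and writers for the tabular formats the pipeline consumes and emits.

Alignment hit tables follow the 12-column BLAST/DIAMOND tabular convention
(``outfmt 6``): qseqid, sseqid, pident, length, mismatch, gapopen, qstart,
qend, sstart, send, evalue, bitscore.  Coordinates are 1-based inclusive and
are never converted internally.  Count tables are TSV with virotypes as rows
and samples as columns; floats are serialized at repr precision so that a
write/read round trip is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

HIT_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

METADATA_COLUMNS = ["refseq_id", "genome_length", "family", "genome_type", "host_lineage"]

GENOME_TYPES = {"dsDNA", "ssDNA", "dsRNA", "ssRNA"}


class ParseError(ValueError):
    """A malformed row in a tabular input; names the row and field."""


@dataclass(frozen=True)
class HitRecord:
    """One alignment hit: the atom of both identification stages."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(f"percent identity {self.percent_identity} outside [0, 100]")
        if self.alignment_length < 1:
            raise ValueError(f"alignment length {self.alignment_length} < 1")
        if self.evalue < 0:
            raise ValueError(f"negative e-value {self.evalue}")
        if self.bit_score < 0:
            raise ValueError(f"negative bit score {self.bit_score}")


@dataclass(frozen=True)
class VirusMetadata:
    """Per-reference-genome metadata: length (bp), family, and host lineage."""

    refseq_id: str
    genome_length: int
    family: str
    genome_type: str
    host_lineage: str

    def __post_init__(self) -> None:
        if self.genome_length < 1:
            raise ValueError(f"{self.refseq_id}: genome length must be positive")


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    length: int
    sample_id: str

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.read_id}: read length must be positive")


def _parse_float(token: str, row: int, field: str) -> float:
    # locale-independent: decimal point only, no thousands separators
    if "," in token:
        raise ParseError(f"row {row}: field {field!r}: thousands separators not accepted: {token!r}")
    try:
        value = float(token)
    except ValueError as exc:
        raise ParseError(f"row {row}: field {field!r}: not a number: {token!r}") from exc
    if math.isnan(value):
        raise ParseError(f"row {row}: field {field!r}: NaN not accepted")
    return value


def _parse_int(token: str, row: int, field: str) -> int:
    try:
        return int(token)
    except ValueError as exc:
        raise ParseError(f"row {row}: field {field!r}: not an integer: {token!r}") from exc


def parse_hit_row(fields: Sequence[str], row: int = 0) -> HitRecord:
    if len(fields) != 12:
        raise ParseError(f"row {row}: expected 12 tab-separated fields, got {len(fields)}")
    try:
        return HitRecord(
            query_id=fields[0],
            subject_id=fields[1],
            percent_identity=_parse_float(fields[2], row, "pident"),
            alignment_length=_parse_int(fields[3], row, "length"),
            mismatches=_parse_int(fields[4], row, "mismatch"),
            gap_opens=_parse_int(fields[5], row, "gapopen"),
            query_start=_parse_int(fields[6], row, "qstart"),
            query_end=_parse_int(fields[7], row, "qend"),
            subject_start=_parse_int(fields[8], row, "sstart"),
            subject_end=_parse_int(fields[9], row, "send"),
            evalue=_parse_float(fields[10], row, "evalue"),
            bit_score=_parse_float(fields[11], row, "bitscore"),
        )
    except ValueError as exc:
        if isinstance(exc, ParseError):
            raise
        raise ParseError(f"row {row}: {exc}") from exc


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tabular hit file into records.

    An empty file yields an empty list; any malformed row raises
    :class:`ParseError` naming the 1-based row.
    """
    records: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            records.append(parse_hit_row(line.split("\t"), row=lineno))
    return records


def hits_to_frame(hits: Iterable[HitRecord] | pd.DataFrame) -> pd.DataFrame:
    """Columnar view of a hit table (columns named as in ``outfmt 6``)."""
    if isinstance(hits, pd.DataFrame):
        missing = set(HIT_COLUMNS) - set(hits.columns)
        if missing:
            raise ValueError(f"hit frame missing columns: {sorted(missing)}")
        return hits
    rows = [
        (h.query_id, h.subject_id, h.percent_identity, h.alignment_length,
         h.mismatches, h.gap_opens, h.query_start, h.query_end,
         h.subject_start, h.subject_end, h.evalue, h.bit_score)
        for h in hits
    ]
    return pd.DataFrame(rows, columns=HIT_COLUMNS)


def read_hit_frame(path: str | Path) -> pd.DataFrame:
    return hits_to_frame(read_hit_table(path))


def write_hit_frame(frame: pd.DataFrame, path: str | Path) -> None:
    hits_to_frame(frame).to_csv(path, sep="\t", header=False, index=False)


def read_virus_metadata(path: str | Path) -> pd.DataFrame:
    """Read a virus metadata TSV, indexed by refseq_id.

    Duplicated refseq_id values and non-positive genome lengths are errors.
    """
    df = pd.read_csv(path, sep="\t", dtype={"refseq_id": str})
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"metadata missing columns: {sorted(missing)}")
    dupes = df["refseq_id"][df["refseq_id"].duplicated()]
    if not dupes.empty:
        raise ParseError(f"duplicate refseq_id values: {sorted(dupes.unique())}")
    bad = df[df["genome_length"] <= 0]
    if not bad.empty:
        raise ParseError(f"non-positive genome_length for {sorted(bad['refseq_id'])}")
    return df.set_index("refseq_id")


def write_virus_metadata(meta: pd.DataFrame, path: str | Path) -> None:
    meta.reset_index().to_csv(path, sep="\t", index=False)


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Count table TSV: virotypes as rows, samples as columns, header row."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any() or df.columns.duplicated().any():
        raise ParseError("count table has duplicated row or column labels")
    if (df.to_numpy() < 0).any():
        raise ParseError("count table has negative entries")
    return df

def write_count_table(table: pd.DataFrame, path: str | Path) -> None:
    # repr-precision floats guarantee read(write(x)) == x
    table.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def read_reads_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "sample_id": str})
    if (df["length"] < 1).any():
        raise ParseError("read table has non-positive lengths")
    return df


def write_reads_table(reads: pd.DataFrame, path: str | Path) -> None:
    reads.to_csv(path, sep="\t", index=False)


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).write_text(newick if newick.endswith("\n") else newick + "\n")


def read_newick(path: str | Path) -> str:
    return Path(path).read_text().strip()


def read_fasta_lengths(path: str | Path) -> dict[str, int]:
    """Sequence IDs and lengths from a FASTA file (the only fields used)."""
    from Bio import SeqIO

    return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
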