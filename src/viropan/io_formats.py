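"""Readers and writers for the on-disk formats the pipeline touches.

All readers validate strictly and reject malformed input rather than
coercing it; every writer/reader pair is an exact inverse on valid data.
Reads are gzip-transparent (detected by magic bytes, not extension).

Formats
-------
* protein FASTA (one record per header, unique ids)
* 12-column tab-separated pairwise-similarity hit tables (the standard
  BLAST "outfmt 6" dialect; extra trailing columns are ignored with a
  warning)
* newick trees with optional branch lengths and internal-node support
  labels (via :mod:`dendropy`)
* gene-content matrices as TSV: first column taxon id, header row of
  family ids, non-negative integer cells
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, List, Union

import dendropy
import pandas as pd

PathLike = Union[str, Path]

__all__ = [
    "FormatError",
    "SequenceRecord",
    "HitRecord",
    "read_fasta",
    "write_fasta",
    "read_hit_table",
    "write_hit_table",
    "read_newick",
    "write_newick",
    "read_content_matrix",
    "write_content_matrix",
]


class FormatError(ValueError):
    """An input file violates the dialect this pipeline expects."""


@dataclass(frozen=True)
class SequenceRecord:
    """A single protein sequence; ``residues`` may contain '-' only when the
    record is a row of an alignment."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has no residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class HitRecord:
    """One row of a pairwise similarity search (BLAST tabular convention:
    1-based inclusive coordinates, percent identity of the local alignment)."""

    query_id: str
    subject_id: str
    pct_identity: float
    aln_length: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError(f"pct_identity {self.pct_identity} outside [0, 100]")
        if self.evalue < 0:
            raise ValueError(f"negative E-value {self.evalue}")
        if self.aln_length < 1:
            raise ValueError(f"alignment length {self.aln_length} < 1")
        if self.q_start > self.q_end:
            raise ValueError(f"q_start {self.q_start} > q_end {self.q_end}")


def _open_text(path: PathLike) -> io.TextIOWrapper:
    """Open ``path`` for reading as UTF-8 text, decompressing gzip content
    transparently (detected from the two magic bytes)."""
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="utf-8")
    return io.TextIOWrapper(raw, encoding="utf-8")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: PathLike) -> List[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    The reader is deliberately strict so that problems surface at parse
    time with a line number: duplicate ids, empty sequences, and sequence
    data before the first header are all rejected.
    """
    records: List[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: List[str] = []

    def flush() -> None:
        if header is None:
            return
        residues = "".join(chunks)
        if not residues:
            raise FormatError(
                f"{path}: line {header_line}: record {header!r} has an empty sequence"
            )
        if header in seen:
            raise FormatError(
                f"{path}: line {header_line}: duplicate record id {header!r}"
            )
        seen.add(header)
        records.append(SequenceRecord(id=header, residues=residues))

    with _open_text(path) as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                name = line[1:].split()[0] if line[1:].strip() else ""
                if not name:
                    raise FormatError(f"{path}: line {lineno}: empty FASTA header")
                header, header_line, chunks = name, lineno, []
            else:
                if header is None:
                    raise FormatError(
                        f"{path}: line {lineno}: sequence data before the first '>' header"
                    )
                chunks.append(line)
        flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: PathLike, width: int = 60) -> None:
    """Write records to ``path`` in FASTA, wrapping residues at ``width``."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Hit tables (BLAST tabular, outfmt 6)
# ---------------------------------------------------------------------------

_N_HIT_COLUMNS = 12


def read_hit_table(path: PathLike) -> List[HitRecord]:
    """Parse a 12-column tab-separated hit table.

    Lines starting with ``#`` are comments and skipped. Rows with fewer
    than 12 columns are format errors naming the row; extra trailing
    columns (some tools append query/subject coverage) are ignored with a
    single warning per file.
    """
    hits: List[HitRecord] = []
    warned_extra = False
    with _open_text(path) as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.rstrip("\n").rstrip("\r")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < _N_HIT_COLUMNS:
                raise FormatError(
                    f"{path}: row {lineno}: expected {_N_HIT_COLUMNS} tab-separated "
                    f"columns, found {len(fields)}"
                )
            if len(fields) > _N_HIT_COLUMNS and not warned_extra:
                warnings.warn(
                    f"{path}: rows carry more than {_N_HIT_COLUMNS} columns; "
                    "extra columns are ignored",
                    stacklevel=2,
                )
                warned_extra = True
            try:
                hit = HitRecord(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    aln_length=int(fields[3]),
                    mismatches=int(fields[4]),
                    gap_opens=int(fields[5]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    evalue=float(fields[10]),
                    bit_score=float(fields[11]),
                )
            except ValueError as exc:
                raise FormatError(f"{path}: row {lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def write_hit_table(hits: Iterable[HitRecord], path: PathLike) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pct_identity:.2f}",
                        str(h.aln_length),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.q_start),
                        str(h.q_end),
                        str(h.s_start),
                        str(h.s_end),
                        f"{h.evalue:.3g}",
                        f"{h.bit_score:.6g}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Newick trees
# ---------------------------------------------------------------------------

def read_newick(path: PathLike) -> dendropy.Tree:
    """Read a newick tree. Internal-node labels (bootstrap supports written
    as integer percentages) and branch lengths are preserved."""
    with _open_text(path) as fh:
        text = fh.read()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse-error types
        raise FormatError(f"{path}: not a valid newick tree: {exc}") from exc
    return tree


def write_newick(tree: dendropy.Tree, path: PathLike) -> None:
    """Write ``tree`` as newick; branch lengths at 10 significant digits so a
    round trip preserves them to well under 1e-9."""
    text = tree.as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
        real_value_format_specifier=".10g",
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


# ---------------------------------------------------------------------------
# Gene-content matrices
# ---------------------------------------------------------------------------

def read_content_matrix(path: PathLike) -> pd.DataFrame:
    """Read a taxa x families content matrix (TSV, first column taxon id).

    Cells must be non-negative integers; anything else is a format error.
    """
    with _open_text(path) as fh:
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype=str)
    try:
        values = df.apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric cell in content matrix: {exc}") from exc
    if values.isna().any().any():
        raise FormatError(f"{path}: missing cell in content matrix")
    if (values.to_numpy() % 1 != 0).any():
        raise FormatError(f"{path}: non-integer cell in content matrix")
    if (values.to_numpy() < 0).any():
        raise FormatError(f"{path}: negative cell in content matrix")
    out = values.astype(int)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    out.index.name = "taxon"
    return out


def write_content_matrix(matrix: pd.DataFrame, path: PathLike) -> None:
    out = matrix.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t")
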