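"""Readers and writers for the external formats the pipeline touches.

FASTA/FASTQ, aligned FASTA, Newick with supports, the 12-column tabular hit
format (outfmt-6 dialect; only the first four columns are consumed), and the
TSV metadata sidecar.  All validation is strict: ragged alignments, empty
sequences and malformed numeric fields raise :class:`ParseError` naming the
offending entry.  All coordinates in reports are 1-based.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Sequence, Union

from Bio import SeqIO

from .hits import Hit, HitList
from .records import Read, ReferenceRecord
from .tree import SupportTree, parse_newick

__all__ = [
    "ParseError",
    "Alignment",
    "read_fasta",
    "read_fastq",
    "read_reads",
    "read_alignment",
    "read_newick",
    "write_newick",
    "read_hits_tabular",
    "read_metadata",
    "attach_metadata",
    "write_fasta",
    "write_fastq",
    "write_metadata",
]

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file."""


def _header_line_numbers(path: PathLike) -> Dict[str, int]:
    """1-based line number of each FASTA/FASTQ header, for error messages."""
    out: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(">") or line.startswith("@"):
                ident = line[1:].split()[0] if len(line) > 1 else ""
                out.setdefault(ident, lineno)
    return out


def read_fasta(path: PathLike) -> List[ReferenceRecord]:
    """Read a FASTA file into sequence-only :class:`ReferenceRecord` objects.

    Sequences are uppercased and RNA ``U`` is mapped to ``T``.  An entry with
    an empty sequence or header is a parse error naming its line.
    """
    records: List[ReferenceRecord] = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not rec.id or not seq:
            lineno = _header_line_numbers(path).get(rec.id, 0)
            raise ParseError(
                f"{path}: entry {rec.id!r} at line {lineno}: empty "
                f"{'header' if not rec.id else 'sequence'}"
            )
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        records.append(ReferenceRecord(id=rec.id, seq=seq))
    return records


def read_fastq(path: PathLike) -> List[Read]:
    """Read FASTQ into :class:`Read` objects with per-base Phred qualities."""
    reads: List[Read] = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            Read(
                id=rec.id,
                seq=str(rec.seq),
                qual=list(rec.letter_annotations["phred_quality"]),
            )
        )
    return reads


def read_reads(path: PathLike) -> List[Read]:
    """Read amplicon reads from FASTA or FASTQ, sniffing by first character."""
    with open(path) as fh:
        first = fh.read(1)
    if first == "@":
        return read_fastq(path)
    return [Read(id=r.id, seq=r.seq) for r in read_fasta(path)]


@dataclass
class Alignment:
    """A multiple sequence alignment: equal-length gapped rows."""

    ids: List[str]
    rows: List[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        if not self.rows:
            raise ValueError("empty alignment")
        ncols = len(self.rows[0])
        for ident, row in zip(self.ids, self.rows):
            if len(row) != ncols:
                raise ParseError(
                    f"alignment row {ident!r} has length {len(row)}, "
                    f"expected {ncols}"
                )
        self.rows = [r.upper() for r in self.rows]

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> str:
        """Column *j* (0-based) as a string of characters."""
        return "".join(row[j] for row in self.rows)

    def row(self, ident: str) -> str:
        return self.rows[self.ids.index(ident)]


def read_alignment(path: PathLike) -> Alignment:
    """Read an aligned FASTA file; ragged rows raise naming the offender."""
    ids: List[str] = []
    rows: List[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        ids.append(rec.id)
        rows.append(str(rec.seq))
    if not ids:
        raise ParseError(f"{path}: no alignment rows")
    return Alignment(ids, rows)


def read_newick(path: PathLike) -> SupportTree:
    """Read a Newick tree; numeric internal labels become supports."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: SupportTree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def read_hits_tabular(path: PathLike) -> List[HitList]:
    """Read tabular hits (outfmt-6 dialect), grouped and re-sorted per query.

    Only the first four columns are used: query id, subject id, percent
    identity, alignment length.  Rows are regrouped by query (order of first
    appearance) and re-sorted by the HitList contract regardless of file
    order.
    """
    per_query: Dict[str, List[Hit]] = {}
    with open(path) as fh:
        for rowno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 4:
                raise ParseError(f"{path}: row {rowno}: expected >=4 columns")
            qid, sid = row[0], row[1]
            try:
                pct = float(row[2])
                alen = int(float(row[3]))
            except ValueError as exc:
                raise ParseError(
                    f"{path}: row {rowno}: non-numeric identity/length field"
                ) from exc
            per_query.setdefault(qid, []).append(
                Hit(subject_id=sid, pct_identity=pct, align_len=alen)
            )
    return [HitList(qid, hits) for qid, hits in per_query.items()]


_META_COLUMNS = ("id", "name", "lineage", "cultivated", "provenance", "type_strain")

_TRUE = {"true", "1", "yes", "t"}


def _parse_bool(value: str) -> bool:
    return str(value).strip().lower() in _TRUE


def read_metadata(path: PathLike) -> Dict[str, dict]:
    """Read the TSV metadata sidecar keyed by record id.

    Columns: ``id`` (required), ``name``, ``lineage`` (semicolon-separated,
    domain first), ``cultivated``, ``provenance``, ``type_strain``.  Absent
    optional columns default to unknown/false.
    """
    meta: Dict[str, dict] = {}
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ParseError(f"{path}: metadata TSV needs an 'id' column")
        for rowno, row in enumerate(reader, start=2):
            ident = (row.get("id") or "").strip()
            if not ident:
                raise ParseError(f"{path}: row {rowno}: empty id")
            name = (row.get("name") or "").strip() or None
            lineage_raw = (row.get("lineage") or "").strip()
            lineage = tuple(
                t.strip() for t in lineage_raw.split(";") if t.strip()
            )
            provenance = (row.get("provenance") or "unknown").strip() or "unknown"
            meta[ident] = {
                "name": name,
                "lineage": lineage,
                "cultivated": _parse_bool(row.get("cultivated") or ""),
                "provenance": provenance,
                "is_type_strain": _parse_bool(row.get("type_strain") or ""),
            }
    return meta


def attach_metadata(
    records: Sequence[ReferenceRecord], meta: Dict[str, dict]
) -> List[ReferenceRecord]:
    """Return records with metadata fields filled in from the sidecar."""
    out = []
    for rec in records:
        m = meta.get(rec.id)
        if m is None:
            out.append(rec)
        else:
            out.append(ReferenceRecord(id=rec.id, seq=rec.seq, **m))
    return out


def write_fasta(records: Sequence[Union[ReferenceRecord, Read]], path: PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 80):
                fh.write(rec.seq[i : i + 80] + "\n")


def write_fastq(reads: Sequence[Read], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else [30] * len(r.seq)
            qstr = "".join(chr(q + 33) for q in qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qstr}\n")


def write_metadata(records: Sequence[ReferenceRecord], path: PathLike) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(_META_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.name or "",
                    ";".join(r.lineage),
                    str(r.cultivated).lower(),
                    r.provenance,
                    str(r.is_type_strain).lower(),
                ]
            )
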