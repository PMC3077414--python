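"""Reading and writing the standard formats the pipeline consumes.

FASTA sequences (via Bio.SeqIO), BED12/GFF3 gene models, and
tab-separated tables.  Internal coordinates are 0-based half-open
everywhere; user-facing reports print 1-based inclusive.

IUPAC ambiguity codes are legal only in pattern files, never in genome
or fragment FASTA: sequences are restricted to {A,C,G,T,N} (lowercase
accepted and uppercased) and anything else is rejected at parse time.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "GenomeAssembly",
    "GeneModel",
    "SeqIOError",
    "read_fasta",
    "write_fasta",
    "read_gene_models",
    "write_table",
]

_VALID_SEQ = re.compile(r"^[ACGTN]*$")


class SeqIOError(ValueError):
    """Raised for malformed sequence, gene-model or table input."""


@dataclass(frozen=True)
class SequenceRecord:
    """A named DNA sequence over the {A,C,G,T,N} alphabet."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id:
            raise SeqIOError("sequence record id must be non-empty")
        if not _VALID_SEQ.match(self.sequence):
            bad = next(
                (i, c)
                for i, c in enumerate(self.sequence)
                if c not in "ACGTN"
            )
            raise SeqIOError(
                f"record {self.id!r}: illegal character {bad[1]!r} "
                f"at position {bad[0]}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeAssembly:
    """An ordered multi-record sequence collection (genome or fragment set)."""

    records: tuple[SequenceRecord, ...]

    def __post_init__(self) -> None:
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SeqIOError(f"duplicate record id {dup!r}")

    @property
    def total_length(self) -> int:
        return sum(r.length for r in self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def get(self, record_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)


@dataclass(frozen=True)
class GeneModel:
    """A gene as a strand plus sorted, non-overlapping exon intervals.

    Coordinates are 0-based half-open.  Introns are the gaps between
    consecutive exons; numbering (exon 1, intron 1, ...) is strand-aware,
    i.e. follows transcript orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise SeqIOError(
                f"gene {self.gene_id!r}: unknown strand {self.strand!r}"
            )
        if not self.exons:
            raise SeqIOError(f"gene {self.gene_id!r}: no exons")
        for s, e in self.exons:
            if e <= s:
                raise SeqIOError(f"gene {self.gene_id!r}: empty exon ({s},{e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise SeqIOError(
                    f"gene {self.gene_id!r}: exons overlap or are unsorted"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )


def read_fasta(path: str | Path) -> GenomeAssembly:
    """Read a multi-record FASTA file into a :class:`GenomeAssembly`.

    Records keep file order; sequences are uppercased; ``N`` is
    preserved.  Duplicate ids and characters outside {A,C,G,T,N}
    raise :class:`SeqIOError`.
    """
    path = Path(path)
    if not path.exists():
        raise SeqIOError(f"no such file: {path}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise SeqIOError(f"{path}: no records")
    return GenomeAssembly(tuple(records))


def write_fasta(
    assembly: GenomeAssembly | Iterable[SequenceRecord],
    path: str | Path,
    width: int = 70,
) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in assembly:
            fh.write(f">{rec.id}\n")
            for i in range(0, rec.length, width):
                fh.write(rec.sequence[i : i + width] + "\n")


def _parse_bed12_line(line: str, lineno: int) -> GeneModel:
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 12:
        raise SeqIOError(f"line {lineno}: BED12 needs 12 fields, got {len(fields)}")
    chrom, start, _end, name = fields[0], int(fields[1]), int(fields[2]), fields[3]
    strand = fields[5]
    n_blocks = int(fields[9])
    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
    if len(sizes) != n_blocks or len(starts) != n_blocks:
        raise SeqIOError(f"line {lineno}: blockCount disagrees with block lists")
    if starts != sorted(starts):
        raise SeqIOError(f"line {lineno}: blockStarts not sorted")
    exons = tuple((start + s, start + s + sz) for s, sz in zip(starts, sizes))
    return GeneModel(gene_id=name, chrom=chrom, strand=strand, exons=exons)


def _parse_gff3(path: Path) -> list[GeneModel]:
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) != 9:
                raise SeqIOError(f"line {lineno}: GFF3 needs 9 fields")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = f
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise SeqIOError(f"line {lineno}: gene without ID")
                genes[gid] = {"chrom": chrom, "strand": strand, "exons": []}
            elif ftype == "exon":
                parent = attr.get("Parent")
                if parent not in genes:
                    raise SeqIOError(
                        f"line {lineno}: exon Parent {parent!r} unknown"
                    )
                # GFF3 is 1-based inclusive; convert to 0-based half-open
                genes[parent]["exons"].append((int(start) - 1, int(end)))
    models = []
    for gid, g in genes.items():
        if not g["exons"]:
            raise SeqIOError(f"gene {gid!r}: no exon children")
        models.append(
            GeneModel(
                gene_id=gid,
                chrom=g["chrom"],
                strand=g["strand"],
                exons=tuple(sorted(g["exons"])),
            )
        )
    return models


def read_gene_models(path: str | Path, format: str = "bed12") -> list[GeneModel]:
    """Read gene models from BED12 or GFF3.

    Exons come out sorted ascending and non-overlapping in 0-based
    half-open coordinates regardless of the input dialect.
    """
    path = Path(path)
    if not path.exists():
        raise SeqIOError(f"no such file: {path}")
    if format == "bed12":
        models = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, 1):
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                models.append(_parse_bed12_line(line, lineno))
        return models
    if format == "gff3":
        return _parse_gff3(path)
    raise SeqIOError(f"unknown gene-model format {format!r}")


def write_table(
    rows: Sequence[Mapping[str, object]],
    path: str | Path,
    columns: Sequence[str] | None = None,
) -> None:
    """Write uniform records as a header-led, tab-separated, UTF-8 table.

    Fields must be tab-free; rows must share a schema.
    """
    rows = list(rows)
    if columns is None:
        if not rows:
            raise SeqIOError("cannot infer columns from zero rows")
        columns = list(rows[0].keys())
    for row in rows:
        if list(row.keys()) != list(columns):
            raise SeqIOError("rows do not share a schema")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            cells = []
            for c in columns:
                cell = str(row[c])
                if "\t" in cell:
                    raise SeqIOError(f"field {c!r} contains a tab")
                cells.append(cell)
            fh.write("\t".join(cells) + "\n")
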