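"""Classification of fragment loci against gene models.

Each ChIP fragment locus is assigned exactly one category:

* intragenic — overlaps a gene span; reported with the exon or intron
  of largest overlap, numbered 1-based in transcript orientation
  (strand-aware, so "intron 1" is the first intron of the transcript);
* intergenic — on a gene-bearing chromosome but outside all gene
  spans; reported with the nearest gene by edge distance, its
  strand-aware upstream/downstream relation, and the edge-to-edge gap;
* unplaced — on a contig carrying no gene models (or explicitly
  flagged unplaced).

Ties: feature ties break toward the exon; gene ties break toward the
larger overlap then the lexicographically smaller gene id.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .seq_io import GeneModel, write_table

__all__ = [
    "FragmentLocus",
    "Annotation",
    "AnnotationSummary",
    "classify",
    "tally",
    "parse_location_label",
    "tally_table",
    "format_distance",
    "write_annotation_tsv",
]

UNPLACED = "unplaced"


@dataclass(frozen=True)
class FragmentLocus:
    fragment_id: str
    chrom: str  # or "unplaced"
    start: int  # 0-based half-open
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"{self.fragment_id!r}: empty locus")


@dataclass(frozen=True)
class Annotation:
    fragment_id: str
    category: str  # intragenic | intergenic | unplaced
    feature: str | None = None  # "exon k" | "intron k"
    gene_id: str | None = None
    relation: str | None = None  # upstream | downstream
    distance: int | None = None  # edge-to-edge bp

    def __post_init__(self) -> None:
        if self.category == "intragenic":
            ok = self.feature and self.gene_id and self.relation is None and self.distance is None
        elif self.category == "intergenic":
            ok = (
                self.feature is None
                and self.gene_id
                and self.relation in ("upstream", "downstream")
                and self.distance is not None
            )
        elif self.category == UNPLACED:
            ok = not any((self.feature, self.gene_id, self.relation, self.distance))
        else:
            ok = False
        if not ok:
            raise ValueError(f"inconsistent annotation for {self.fragment_id!r}")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _feature_of(frag: FragmentLocus, gene: GeneModel) -> str:
    """Exon/intron of largest overlap, numbered in transcript orientation."""
    n_ex = len(gene.exons)
    candidates: list[tuple[int, int, str, int]] = []  # (overlap, exon_priority, kind, number)
    for i, ex in enumerate(gene.exons):
        number = i + 1 if gene.strand == "+" else n_ex - i
        candidates.append((_overlap((frag.start, frag.end), ex), 1, "exon", number))
    introns = gene.introns
    n_in = len(introns)
    for j, intr in enumerate(introns):
        number = j + 1 if gene.strand == "+" else n_in - j
        candidates.append((_overlap((frag.start, frag.end), intr), 0, "intron", number))
    # largest overlap wins; exon beats intron on ties
    ov, _prio, kind, number = max(candidates, key=lambda t: (t[0], t[1]))
    if ov == 0:
        # overlaps the span edge without covering an exon/intron interior
        # (cannot happen: span is the union of exons and introns)
        raise AssertionError("span overlap without feature overlap")
    return f"{kind} {number}"


def classify(frag: FragmentLocus, genes: Iterable[GeneModel]) -> Annotation:
    """Assign one category (intragenic / intergenic / unplaced) to a locus."""
    genes_here = [g for g in genes if g.chrom == frag.chrom]
    if frag.chrom == UNPLACED or not genes_here:
        return Annotation(fragment_id=frag.fragment_id, category=UNPLACED)
    overlapping = [
        (g, _overlap((frag.start, frag.end), g.span))
        for g in genes_here
        if _overlap((frag.start, frag.end), g.span) > 0
    ]
    if overlapping:
        # largest overlap wins; tie -> lexicographically smaller gene_id
        best_ov = max(ov for _, ov in overlapping)
        gene = min(
            (g for g, ov in overlapping if ov == best_ov),
            key=lambda g: g.gene_id,
        )
        return Annotation(
            fragment_id=frag.fragment_id,
            category="intragenic",
            feature=_feature_of(frag, gene),
            gene_id=gene.gene_id,
        )
    # intergenic: nearest gene by edge distance
    def edge_distance(g: GeneModel) -> int:
        gs, ge = g.span
        if frag.end <= gs:
            return gs - frag.end
        return frag.start - ge

    gene = min(genes_here, key=lambda g: (edge_distance(g), g.gene_id))
    gs, ge = gene.span
    if frag.end <= gs:
        dist = gs - frag.end
        relation = "upstream" if gene.strand == "+" else "downstream"
    else:
        dist = frag.start - ge
        relation = "downstream" if gene.strand == "+" else "upstream"
    return Annotation(
        fragment_id=frag.fragment_id,
        category="intergenic",
        gene_id=gene.gene_id,
        relation=relation,
        distance=dist,
    )


@dataclass(frozen=True)
class AnnotationSummary:
    n: int
    by_category: dict[str, int]
    by_intron: dict[int, int]
    by_exon: dict[int, int]


def tally(annotations: Sequence[Annotation]) -> AnnotationSummary:
    """Counts per category and per exon/intron index (a partition of the input)."""
    cats = Counter(a.category for a in annotations)
    introns: Counter[int] = Counter()
    exons: Counter[int] = Counter()
    for a in annotations:
        if a.feature:
            kind, num = a.feature.split()
            if kind == "intron":
                introns[int(num)] += 1
            elif kind == "exon":
                exons[int(num)] += 1
    return AnnotationSummary(
        n=len(annotations),
        by_category=dict(cats),
        by_intron=dict(introns),
        by_exon=dict(exons),
    )


def parse_location_label(localization: str, location_to_gene: str) -> tuple[str, str | None]:
    """Interpret a printed locus row into (category, feature).

    ``localization`` is a cytoband or the literal 'unplaced';
    ``location_to_gene`` is 'intron k', 'exon k', 'upstream', or
    'downstream'.
    """
    loc = (location_to_gene or "").strip()
    if localization.strip().lower() == UNPLACED:
        return UNPLACED, None
    if loc.startswith(("intron", "exon")):
        return "intragenic", loc
    if loc in ("upstream", "downstream"):
        return "intergenic", None
    raise ValueError(f"unrecognized location {localization!r} / {location_to_gene!r}")


def tally_table(table: pd.DataFrame) -> AnnotationSummary:
    """Tally a printed locus table (columns localization, location_to_gene)."""
    annos = []
    for row in table.itertuples():
        category, feature = parse_location_label(
            str(row.localization), str(row.location_to_gene)
        )
        if category == "intragenic":
            anno = Annotation(str(row.clone), category, feature=feature, gene_id=str(row.gene))
        elif category == "intergenic":
            anno = Annotation(
                str(row.clone), category, gene_id=str(row.gene),
                relation=str(row.location_to_gene), distance=0,
            )
        else:
            anno = Annotation(str(row.clone), UNPLACED)
        annos.append(anno)
    return tally(annos)


def format_distance(bp: int) -> str:
    """Human-readable gap: '900 bp' below 1 kb, else kb with <=1 decimal."""
    if bp < 1000:
        return f"{bp} bp"
    kb = bp / 1000
    return f"{kb:.1f} kb".replace(".0 kb", " kb")


def write_annotation_tsv(
    annotations: Sequence[Annotation],
    path: str | Path,
    lengths: dict[str, int] | None = None,
    at_percent: dict[str, float] | None = None,
) -> None:
    """Report mirroring the clone-table layout (1-based human-readable)."""
    rows = []
    for a in annotations:
        rows.append(
            {
                "fragment": a.fragment_id,
                "length_bp": (lengths or {}).get(a.fragment_id, "-"),
                "at_percent": (
                    f"{at_percent[a.fragment_id]:.0f}"
                    if at_percent and a.fragment_id in at_percent
                    else "-"
                ),
                "category": a.category,
                "gene": a.gene_id or "-",
                "location_to_gene": a.feature or a.relation or "-",
                "distance": format_distance(a.distance) if a.distance is not None else "-",
            }
        )
    write_table(
        rows, path,
        columns=["fragment", "length_bp", "at_percent", "category", "gene",
                 "location_to_gene", "distance"],
    )
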