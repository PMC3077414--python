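"""Conserved short segments shared between ChIP fragments.

A seed-and-extend ungapped aligner in the style of blastn tuned for
short sequences: exact shared words of length 7 seed ungapped
extensions scored reward +1 / mismatch -3, with an X-drop cutoff and
trim-back to the maximal-scoring segment.  Every extended seed is
reported (the permissive limit of running with a very high E-value
threshold and the low-complexity filter off); no E-value statistics
are computed.

Fixed-length alignments (11 and 12 bp in the original analysis) are
collected as plus-orientation query-side strings and deduplicated
exactly; the resulting segment set feeds the sequence logo.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import reverse_complement

from .seq_io import GenomeAssembly, SequenceRecord, write_fasta, write_table

__all__ = [
    "SeedHit",
    "UngappedAlignment",
    "SegmentSet",
    "AlignParams",
    "index_words",
    "extend_hit",
    "all_pairs_matches",
    "collect_segments",
    "write_alignments_tsv",
    "write_segments_fasta",
]


@dataclass(frozen=True)
class AlignParams:
    """blastn-short-like scoring: word 7, match +1, mismatch -3, X-drop 10."""

    word_size: int = 7
    reward: int = 1
    penalty: int = -3
    xdrop: int = 10

    def __post_init__(self) -> None:
        if self.word_size < 4:
            raise ValueError("word_size must be >= 4")
        if self.reward <= 0 or self.penalty >= 0 or self.xdrop < 0:
            raise ValueError("need reward > 0, penalty < 0, xdrop >= 0")


@dataclass(frozen=True)
class SeedHit:
    query_id: str
    subject_id: str
    qpos: int
    spos: int
    word: str

    @property
    def k(self) -> int:
        return len(self.word)


@dataclass(frozen=True)
class UngappedAlignment:
    """A maximal ungapped segment pair between two fragments.

    ``qstart`` indexes the query plus strand.  ``sstart`` is the start
    on the strand of the subject that was aligned: for strand '-' it
    indexes the reverse complement of the subject; ``subject_plus_start``
    converts back to subject plus-strand coordinates.
    """

    query_id: str
    subject_id: str
    qstart: int
    sstart: int
    length: int
    identities: int
    score: int
    strand: str
    subject_length: int

    @property
    def subject_plus_start(self) -> int:
        if self.strand == "+":
            return self.sstart
        return self.subject_length - (self.sstart + self.length)


@dataclass(frozen=True)
class SegmentSet:
    """Deduplicated fixed-length aligned segments (plus orientation)."""

    segment_length: int
    segments: tuple[str, ...]

    def __post_init__(self) -> None:
        if any(len(s) != self.segment_length for s in self.segments):
            raise ValueError("segment length mismatch")
        if len(set(self.segments)) != len(self.segments):
            raise ValueError("duplicate segments")

    @property
    def n(self) -> int:
        return len(self.segments)


def index_words(
    fragments: Sequence[SequenceRecord] | GenomeAssembly,
    k: int = 7,
) -> dict[str, list[tuple[str, int]]]:
    """Map every N-free k-mer to its (fragment id, position) occurrences."""
    fragments = list(fragments)
    if not fragments:
        raise ValueError("no fragments")
    if k < 4:
        raise ValueError("k must be >= 4")
    if all(f.length < k for f in fragments):
        raise ValueError(f"word size {k} exceeds every fragment length")
    index: dict[str, list[tuple[str, int]]] = {}
    for frag in fragments:
        seq = frag.sequence
        for i in range(len(seq) - k + 1):
            word = seq[i : i + k]
            if "N" in word:
                continue
            index.setdefault(word, []).append((frag.id, i))
    return index


def _extend(
    query: str,
    subject: str,
    qpos: int,
    spos: int,
    k: int,
    params: AlignParams,
) -> tuple[int, int, int, int, int]:
    """X-drop extension of an exact seed; returns (qstart, sstart, length, identities, score)."""
    reward, penalty, xdrop = params.reward, params.penalty, params.xdrop
    # right of the seed
    best_right, best_dr = 0, 0
    run = 0
    dr = 0
    while qpos + k + dr < len(query) and spos + k + dr < len(subject):
        run += reward if query[qpos + k + dr] == subject[spos + k + dr] else penalty
        dr += 1
        if run > best_right:
            best_right, best_dr = run, dr
        if run < best_right - xdrop:
            break
    # left of the seed
    best_left, best_dl = 0, 0
    run = 0
    dl = 0
    while qpos - dl > 0 and spos - dl > 0:
        run += reward if query[qpos - dl - 1] == subject[spos - dl - 1] else penalty
        dl += 1
        if run > best_left:
            best_left, best_dl = run, dl
        if run < best_left - xdrop:
            break
    qstart = qpos - best_dl
    sstart = spos - best_dl
    length = k + best_dl + best_dr
    identities = sum(
        1 for i in range(length) if query[qstart + i] == subject[sstart + i]
    )
    score = identities * reward + (length - identities) * params.penalty
    return qstart, sstart, length, identities, score


def extend_hit(
    hit: SeedHit,
    query: str,
    subject: str,
    params: AlignParams = AlignParams(),
) -> UngappedAlignment:
    """Extend an exact seed word into its maximal-scoring ungapped alignment."""
    k = hit.k
    if query[hit.qpos : hit.qpos + k] != hit.word or subject[hit.spos : hit.spos + k] != hit.word:
        raise ValueError("seed does not match the given sequences")
    qstart, sstart, length, identities, score = _extend(
        query, subject, hit.qpos, hit.spos, k, params
    )
    return UngappedAlignment(
        query_id=hit.query_id,
        subject_id=hit.subject_id,
        qstart=qstart,
        sstart=sstart,
        length=length,
        identities=identities,
        score=score,
        strand="+",
        subject_length=len(subject),
    )


def _pair_alignments(
    q: SequenceRecord,
    s: SequenceRecord,
    params: AlignParams,
) -> list[UngappedAlignment]:
    k = params.word_size
    out: dict[tuple, UngappedAlignment] = {}
    qwords: dict[str, list[int]] = {}
    for i in range(q.length - k + 1):
        w = q.sequence[i : i + k]
        if "N" not in w:
            qwords.setdefault(w, []).append(i)
    for strand, sseq in (("+", s.sequence), ("-", reverse_complement(s.sequence))):
        for j in range(len(sseq) - k + 1):
            w = sseq[j : j + k]
            if w not in qwords:
                continue
            for i in qwords[w]:
                qstart, sstart, length, identities, score = _extend(
                    q.sequence, sseq, i, j, k, params
                )
                # distinct seeds trimming to the same segment merge here
                key = (qstart, sstart, length, strand)
                if key not in out:
                    out[key] = UngappedAlignment(
                        query_id=q.id,
                        subject_id=s.id,
                        qstart=qstart,
                        sstart=sstart,
                        length=length,
                        identities=identities,
                        score=score,
                        strand=strand,
                        subject_length=s.length,
                    )
    return list(out.values())


def all_pairs_matches(
    fragments: Sequence[SequenceRecord] | GenomeAssembly,
    params: AlignParams = AlignParams(),
) -> list[UngappedAlignment]:
    """Ungapped matches over all unordered fragment pairs, both subject strands.

    Self-pairs are excluded; output is sorted by (query, subject, qstart).
    """
    fragments = list(fragments)
    if len(fragments) < 2:
        raise ValueError("need at least 2 fragments")
    out: list[UngappedAlignment] = []
    for a in range(len(fragments)):
        for b in range(a + 1, len(fragments)):
            out.extend(_pair_alignments(fragments[a], fragments[b], params))
    out.sort(key=lambda al: (al.query_id, al.subject_id, al.qstart, al.sstart, al.strand))
    return out


def collect_segments(
    alignments: Iterable[UngappedAlignment],
    segment_length: int,
    fragments: Sequence[SequenceRecord] | GenomeAssembly,
) -> SegmentSet:
    """Exact-length query-side segments, deduplicated, lexicographic order."""
    seqs = {f.id: f.sequence for f in fragments}
    found: set[str] = set()
    for al in alignments:
        if al.length != segment_length:
            continue
        seg = seqs[al.query_id][al.qstart : al.qstart + al.length]
        found.add(seg)
    return SegmentSet(segment_length=segment_length, segments=tuple(sorted(found)))


def write_alignments_tsv(alignments: Sequence[UngappedAlignment], path: str | Path) -> None:
    rows = [
        {
            "query": al.query_id,
            "subject": al.subject_id,
            "qstart": al.qstart,
            "qend": al.qstart + al.length,
            "sstart": al.subject_plus_start,
            "send": al.subject_plus_start + al.length,
            "strand": al.strand,
            "length": al.length,
            "identities": al.identities,
            "score": al.score,
        }
        for al in alignments
    ]
    columns = [
        "query", "subject", "qstart", "qend", "sstart", "send",
        "strand", "length", "identities", "score",
    ]
    write_table(rows, path, columns=columns)


def write_segments_fasta(segset: SegmentSet, path: str | Path) -> None:
    recs = [
        SequenceRecord(f"segment_{i + 1}", s) for i, s in enumerate(segset.segments)
    ]
    write_fasta(recs, path)
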