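"""Degenerate consensus expansion, genome scanning, and occurrence statistics.

An IUPAC consensus (e.g. the 15-mers ATATTCGCGAWWATT / ATATTGCGCAWWATT,
W = A or T) is expanded into the plain-sequence set it denotes; a genome
is then scanned for every exact occurrence of any member.  Under a
uniform i.i.d. base model a set of K distinct L-mers is expected once
every 4^L / K bp, so the ratio of expected to observed spacing measures
over- (or under-) representation of the consensus in the genome.

Matching is exact-set matching: overlapping occurrences all count,
windows containing N never match, and a position matching several
variants counts once per (position, strand).  The scan is implemented
as a 2-bit rolling-code window lookup; its contract is equivalence with
a naive sliding-window search.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import reverse_complement

from .seq_io import GenomeAssembly

__all__ = [
    "IUPACPattern",
    "PatternSet",
    "Match",
    "MatchReport",
    "expand_iupac",
    "read_patterns",
    "scan",
    "expected_spacing",
    "observed_spacing",
    "overrepresentation",
    "write_matches_bed",
    "write_summary_json",
]

# the 15 standard nucleotide codes (Biopython also defines nonstandard X)
_CODE = {b: tuple(ambiguous_dna_values[b]) for b in "ACGTMRWSYKVHDBN"}


@dataclass(frozen=True)
class IUPACPattern:
    """A degenerate consensus over the 15 IUPAC nucleotide codes."""

    pattern: str

    def __post_init__(self) -> None:
        if len(self.pattern) < 1:
            raise ValueError("empty pattern")
        for c in self.pattern:
            if c not in _CODE:
                raise ValueError(f"invalid IUPAC code {c!r} in {self.pattern!r}")

    @property
    def L(self) -> int:
        return len(self.pattern)

    def expand(self) -> frozenset[str]:
        return frozenset(
            "".join(p) for p in itertools.product(*(_CODE[c] for c in self.pattern))
        )


@dataclass(frozen=True)
class PatternSet:
    """A set of distinct plain ACGT strings of one common length."""

    sequences: frozenset[str]

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("empty pattern set")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("pattern set members differ in length")
        for s in self.sequences:
            if any(c not in "ACGT" for c in s):
                raise ValueError(f"non-ACGT member {s!r}")

    @property
    def L(self) -> int:
        return len(next(iter(self.sequences)))

    @property
    def K(self) -> int:
        return len(self.sequences)


@dataclass(frozen=True)
class Match:
    sequence_id: str
    start: int  # 0-based
    strand: str  # '+' or '-'
    variant: str  # the matching member, plus-strand pattern orientation


@dataclass(frozen=True)
class MatchReport:
    """Scan result with the observed-vs-expected spacing arithmetic."""

    matches: tuple[Match, ...]
    G: int
    L: int
    K: int

    @property
    def n(self) -> int:
        return len(self.matches)

    @property
    def observed_spacing(self) -> float | None:
        """Genome bp per match; undefined (None) when there are no matches."""
        return None if self.n == 0 else self.G / self.n

    @property
    def expected_spacing(self) -> float:
        return expected_spacing(self.L, self.K)

    @property
    def ratio(self) -> float | None:
        if self.n == 0:
            return None
        return overrepresentation(self.expected_spacing, self.observed_spacing)


def expand_iupac(patterns: IUPACPattern | Iterable[IUPACPattern]) -> PatternSet:
    """Expand one or more same-length IUPAC patterns to their plain-sequence union."""
    if isinstance(patterns, IUPACPattern):
        patterns = [patterns]
    patterns = list(patterns)
    if not patterns:
        raise ValueError("no patterns given")
    if len({p.L for p in patterns}) != 1:
        raise ValueError("patterns differ in length")
    out: set[str] = set()
    for p in patterns:
        out |= p.expand()
    return PatternSet(frozenset(out))


def read_patterns(path: str | Path) -> PatternSet:
    """Read a pattern file: one IUPAC string per line, '#' comments."""
    pats = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip().upper()
            if line:
                pats.append(IUPACPattern(line))
    if not pats:
        raise ValueError(f"{path}: no patterns")
    return expand_iupac(pats)


_LUT = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _LUT[_b] = _i


def _encode(seq: str) -> np.ndarray:
    """Map bases to 0..3, N (and anything else) to -1."""
    return _LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pattern_ints(sequences: Iterable[str]) -> np.ndarray:
    vals = []
    for s in sequences:
        v = 0
        for c in s:
            v = v * 4 + "ACGT".index(c)
        vals.append(v)
    return np.unique(np.array(vals, dtype=np.int64))


def _window_codes(codes: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Rolling 2-bit codes of all length-L windows and their N-free mask."""
    m = len(codes) - L + 1
    if m <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    acc = np.zeros(m, dtype=np.int64)
    ok = np.ones(m, dtype=bool)
    for j in range(L):
        c = codes[j : j + m]
        ok &= c >= 0
        acc = acc * 4 + np.where(c >= 0, c, 0)
    return acc, ok


def scan(
    genome: GenomeAssembly,
    patterns: PatternSet,
    strands: str = "forward",
) -> MatchReport:
    """Find every occurrence of every pattern-set member in the genome.

    ``strands='both'`` additionally reports positions whose reverse
    complement matches, once each with strand '-'.  L must fit in the
    2-bit rolling code (L <= 31).
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    if len(genome) == 0:
        raise ValueError("empty genome")
    L = patterns.L
    if L > 31:
        raise ValueError("pattern length > 31 unsupported")
    fwd = _pattern_ints(patterns.sequences)
    rc_lookup = None
    if strands == "both":
        rc_lookup = _pattern_ints(reverse_complement(s) for s in patterns.sequences)
    matches: list[Match] = []
    for rec in genome:
        acc, ok = _window_codes(_encode(rec.sequence), L)
        hit_f = ok & np.isin(acc, fwd)
        for pos in np.flatnonzero(hit_f):
            matches.append(Match(rec.id, int(pos), "+", rec.sequence[pos : pos + L]))
        if rc_lookup is not None:
            hit_r = ok & np.isin(acc, rc_lookup)
            for pos in np.flatnonzero(hit_r):
                matches.append(
                    Match(
                        rec.id,
                        int(pos),
                        "-",
                        reverse_complement(rec.sequence[pos : pos + L]),
                    )
                )
    matches.sort(key=lambda m: (m.sequence_id, m.start, m.strand))
    return MatchReport(
        matches=tuple(matches), G=genome.total_length, L=L, K=patterns.K
    )


def expected_spacing(L: int, K: int) -> float:
    """Expected bp per match of a K-member L-mer set under uniform i.i.d. bases.

    expected_spacing(15, 4096) = 4**15 / 4096 = 262144.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > 4**L:
        raise ValueError(f"K={K} exceeds 4^{L}")
    return (4**L) / K


def observed_spacing(G: int, n: int) -> float:
    """Observed bp per match, G/n; undefined for n = 0."""
    if G < 1:
        raise ValueError("G must be >= 1")
    if n == 0:
        raise ZeroDivisionError("no matches: observed spacing undefined")
    return G / n


def overrepresentation(expected: float, observed: float) -> float:
    """Ratio expected/observed spacing: >1 means the set occurs more often than chance."""
    if expected <= 0 or observed <= 0:
        raise ValueError("spacings must be positive")
    return expected / observed


def write_matches_bed(report: MatchReport, path: str | Path) -> None:
    """Write matches as BED6 (name = matched variant, score = 0)."""
    with open(path, "w") as fh:
        for m in report.matches:
            fh.write(
                f"{m.sequence_id}\t{m.start}\t{m.start + report.L}\t"
                f"{m.variant}\t0\t{m.strand}\n"
            )


def write_summary_json(report: MatchReport, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "n": report.n,
                "G": report.G,
                "L": report.L,
                "K": report.K,
                "observed_spacing": report.observed_spacing,
                "expected_spacing": report.expected_spacing,
                "ratio": report.ratio,
            },
            fh,
            indent=2,
        )
        fh.write("\n")
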