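"""Position frequency matrices and information-content sequence logos.

Per-position information content for DNA with a uniform background is

    ic_i = 2 + sum_b f_ib * log2(f_ib)        (0*log0 = 0),

so a fully conserved column carries 2 bits and a uniform column 0.
Letter heights are frequency times column information.  An optional
small-sample correction e(n) = 3 / (2 * ln2 * n) may be subtracted from
each column (floored at 0); it is off by default so that identical
segment sets always give identical logos regardless of n.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .seq_io import write_table
from .short_match import SegmentSet

__all__ = [
    "PositionFrequencyMatrix",
    "LogoMatrix",
    "build_pfm",
    "information_content",
    "write_logo_tsv",
    "plot_logo",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Exact per-column letter counts over n equal-length segments."""

    counts: tuple[tuple[int, int, int, int], ...]  # per position, A/C/G/T
    n: int

    @property
    def length(self) -> int:
        return len(self.counts)

    @property
    def frequencies(self) -> tuple[tuple[float, float, float, float], ...]:
        return tuple(
            tuple(c / self.n for c in col) for col in self.counts
        )


@dataclass(frozen=True)
class LogoMatrix:
    ic: tuple[float, ...]  # bits per position, in [0, 2]
    heights: tuple[tuple[float, float, float, float], ...]  # bits, A/C/G/T


def build_pfm(segments: SegmentSet) -> PositionFrequencyMatrix:
    """Count letters per column; no pseudocounts."""
    if segments.n == 0:
        raise ValueError("empty segment set")
    L = segments.segment_length
    counts = [[0, 0, 0, 0] for _ in range(L)]
    for seg in segments.segments:
        if len(seg) != L:
            raise ValueError("segment length mismatch")
        for i, c in enumerate(seg):
            counts[i][_BASES.index(c)] += 1
    return PositionFrequencyMatrix(
        counts=tuple(tuple(col) for col in counts), n=segments.n
    )


def information_content(
    pfm: PositionFrequencyMatrix,
    small_sample_correction: bool = False,
) -> LogoMatrix:
    """Per-column information in bits and letter heights f_ib * ic_i."""
    ics: list[float] = []
    heights: list[tuple[float, float, float, float]] = []
    e_n = 3.0 / (2.0 * math.log(2) * pfm.n) if small_sample_correction else 0.0
    for col in pfm.frequencies:
        f = np.array(col)
        nz = f[f > 0]
        ic = 2.0 + float(np.sum(nz * np.log2(nz)))
        ic = max(0.0, ic - e_n)
        ics.append(ic)
        heights.append(tuple(float(x * ic) for x in f))
    return LogoMatrix(ic=tuple(ics), heights=tuple(heights))


def write_logo_tsv(logo: LogoMatrix, path: str | Path) -> None:
    rows = [
        {
            "position": i + 1,
            "ic": f"{logo.ic[i]:.6f}",
            "height_A": f"{h[0]:.6f}",
            "height_C": f"{h[1]:.6f}",
            "height_G": f"{h[2]:.6f}",
            "height_T": f"{h[3]:.6f}",
        }
        for i, h in enumerate(logo.heights)
    ]
    write_table(
        rows, path,
        columns=["position", "ic", "height_A", "height_C", "height_G", "height_T"],
    )


def plot_logo(logo: LogoMatrix, path: str | Path) -> None:
    """Render the logo as stacked per-position letter bars (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}
    fig, ax = plt.subplots(figsize=(max(4, len(logo.ic) * 0.6), 3))
    for i, hs in enumerate(logo.heights):
        bottom = 0.0
        # draw small letters first so the dominant base tops the stack
        for h, base in sorted(zip(hs, _BASES)):
            if h <= 0:
                continue
            ax.bar(i + 1, h, bottom=bottom, color=colors[base], width=0.85)
            ax.text(
                i + 1, bottom + h / 2, base,
                ha="center", va="center", fontsize=8, color="white",
            )
            bottom += h
    ax.set_xlabel("position")
    ax.set_ylabel("bits")
    ax.set_ylim(0, 2)
    ax.set_xticks(range(1, len(logo.ic) + 1))
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
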