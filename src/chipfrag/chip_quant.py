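"""ChIP-qPCR fold enrichment from threshold-cycle pairs.

Enrichment of immunoprecipitated DNA over the no-antibody control is
fold = 2^(Ct_NoAb - Ct_IP): one qPCR cycle of difference corresponds to
a doubling of starting material.  Mean enrichment is the arithmetic
mean of the per-sample folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .seq_io import write_table

__all__ = [
    "QpcrSample",
    "EnrichmentResult",
    "fold_enrichment",
    "mean_enrichment",
    "read_qpcr_tsv",
    "write_enrichment_tsv",
]


@dataclass(frozen=True)
class QpcrSample:
    id: str
    ct_ip: float
    ct_noab: float

    def __post_init__(self) -> None:
        for ct in (self.ct_ip, self.ct_noab):
            if not math.isfinite(ct) or ct <= 0:
                raise ValueError(f"sample {self.id!r}: Ct must be positive and finite")


@dataclass(frozen=True)
class EnrichmentResult:
    id: str
    delta_ct: float
    fold: float


def fold_enrichment(sample: QpcrSample) -> EnrichmentResult:
    """Fold enrichment 2^(Ct_NoAb - Ct_IP) of one sample."""
    delta = sample.ct_noab - sample.ct_ip
    return EnrichmentResult(id=sample.id, delta_ct=delta, fold=2.0**delta)


def mean_enrichment(samples: Sequence[QpcrSample]) -> float:
    """Arithmetic mean of the per-sample fold enrichments."""
    if not samples:
        raise ValueError("no samples")
    return sum(fold_enrichment(s).fold for s in samples) / len(samples)


def read_qpcr_tsv(path: str | Path) -> list[QpcrSample]:
    """Read a TSV with columns id, ct_ip, ct_noab."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    missing = {"id", "ct_ip", "ct_noab"} - set(df.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    return [
        QpcrSample(id=str(r.id), ct_ip=float(r.ct_ip), ct_noab=float(r.ct_noab))
        for r in df.itertuples()
    ]


def write_enrichment_tsv(samples: Sequence[QpcrSample], path: str | Path) -> None:
    rows = []
    for s in samples:
        r = fold_enrichment(s)
        rows.append(
            {
                "id": s.id,
                "ct_ip": f"{s.ct_ip:.2f}",
                "ct_noab": f"{s.ct_noab:.2f}",
                "delta_ct": f"{r.delta_ct:.2f}",
                "fold_enrichment": f"{r.fold:.2f}",
            }
        )
    write_table(rows, path, columns=["id", "ct_ip", "ct_noab", "delta_ct", "fold_enrichment"])
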