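"""Synthetic inputs for every pipeline stage.

Generates genomes with controlled window-level AT composition, planted
consensus motifs with ground truth, ChIP-like fragments whose sampling
is biased toward AT-rich starts, non-overlapping gene models, and qPCR
Ct tables.  Everything is bit-reproducible under the config seed.

The background composition is a two-component Gaussian mixture over
per-500-bp-window AT fractions (defaults 0.7 weight at 0.56 and 0.3 at
0.64, clamped to [0.05, 0.95]).  A mixture rather than a single
Gaussian is used because genomic AT distributions are right-shifted
and skewed, not normal; the marginal mean lands near the 59% genomic
average.  Fragment counts and lengths default to the scale of the
cloning experiment the pipeline models: 49 fragments of 105-1848 bp,
with an additive AT bias (default +0.06 AT fraction) realized by
exponentially tilting the start-position distribution toward AT-rich
regions, calibrated so the mean selected fragment AT sits the requested
shift above the genome mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .locus_annotator import FragmentLocus
from .chip_quant import QpcrSample
from .motif_engine import PatternSet
from .seq_io import GeneModel, GenomeAssembly, SequenceRecord

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "plant_motifs",
    "simulate_fragments",
    "simulate_gene_models",
    "simulate_qpcr",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study; defaults mirror the modelled experiment."""

    seed: int = 0
    chrom_lengths: tuple[int, ...] = (500_000, 300_000)
    window_size: int = 500
    # (weight, mean AT fraction, sd) per component
    at_mixture: tuple[tuple[float, float, float], ...] = (
        (0.7, 0.56, 0.05),
        (0.3, 0.64, 0.07),
    )
    n_fragments: int = 49
    fragment_length_range: tuple[int, int] = (105, 1848)
    fragment_at_shift: float = 0.06
    motif_density: float = 20.0  # expected plants per Mbp
    gene_density: float = 10.0  # genes per Mbp
    exon_count_range: tuple[int, int] = (2, 8)
    exon_length_range: tuple[int, int] = (80, 300)
    intron_length_range: tuple[int, int] = (200, 2000)
    qpcr_n: int = 5
    qpcr_delta_ct_mean: float = 7.64
    qpcr_delta_ct_sd: float = 1.13
    qpcr_ct_ip: float = 30.0

    def __post_init__(self) -> None:
        w = sum(c[0] for c in self.at_mixture)
        if abs(w - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")
        if any(c[0] < 0 or c[2] < 0 for c in self.at_mixture):
            raise ValueError("invalid mixture component")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        lo, hi = self.fragment_length_range
        if not (0 < lo <= hi):
            raise ValueError("bad fragment length range")

    def rng(self, stream: int) -> np.random.Generator:
        """An independent, reproducible stream keyed on (seed, stream)."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


def _draw_window_at(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    weights = np.array([c[0] for c in config.at_mixture])
    means = np.array([c[1] for c in config.at_mixture])
    sds = np.array([c[2] for c in config.at_mixture])
    comp = rng.choice(len(weights), size=n, p=weights)
    at = rng.normal(means[comp], sds[comp])
    return np.clip(at, 0.05, 0.95)


def simulate_genome(config: SimulationConfig) -> GenomeAssembly:
    """Genome with per-window AT drawn from the mixture, i.i.d. bases within."""
    rng = config.rng(1)
    records = []
    for ci, length in enumerate(config.chrom_lengths):
        w = config.window_size
        n_win = math.ceil(length / w)
        at = _draw_window_at(config, rng, n_win)
        # per-base probabilities: A and T each at/2, C and G each (1-at)/2
        per_base_at = np.repeat(at, w)[:length]
        u = rng.random(length)
        v = rng.random(length)
        is_at = u < per_base_at
        pick = v < 0.5
        codes = np.where(is_at, np.where(pick, 0, 3), np.where(pick, 1, 2))
        seq = _BASES[codes].tobytes().decode("ascii")
        records.append(SequenceRecord(f"chr{ci + 1}", seq))
    return GenomeAssembly(tuple(records))


def plant_motifs(
    genome: GenomeAssembly,
    patterns: PatternSet,
    density: float,
    config: SimulationConfig,
) -> tuple[GenomeAssembly, list[tuple[str, int, str]]]:
    """Overwrite Poisson(density x Mbp) non-overlapping positions with variants.

    Returns the modified genome and the ground-truth (chrom, start,
    variant) list.  Planting retries a bounded number of times before
    declaring the density infeasible.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    rng = config.rng(2)
    L = patterns.L
    variants = sorted(patterns.sequences)
    out_records = []
    truth: list[tuple[str, int, str]] = []
    for rec in genome:
        if L >= rec.length:
            raise ValueError(f"pattern length {L} >= chromosome {rec.id}")
        n_plant = rng.poisson(density * rec.length / 1e6)
        taken: list[tuple[int, int]] = []
        seq = bytearray(rec.sequence, "ascii")
        placed = 0
        attempts = 0
        while placed < n_plant:
            attempts += 1
            if attempts > 100 * n_plant + 100:
                raise ValueError("motif density too high to place without overlap")
            pos = int(rng.integers(0, rec.length - L + 1))
            if any(pos < e and pos + L > s for s, e in taken):
                continue
            var = variants[int(rng.integers(0, len(variants)))]
            seq[pos : pos + L] = var.encode("ascii")
            taken.append((pos, pos + L))
            truth.append((rec.id, pos, var))
            placed += 1
        out_records.append(SequenceRecord(rec.id, seq.decode("ascii")))
    truth.sort()
    return GenomeAssembly(tuple(out_records)), truth


def _at_fraction_prefix(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_at = ((arr == ord("A")) | (arr == ord("T"))).astype(np.int64)
    return np.concatenate([[0], np.cumsum(is_at)])


def simulate_fragments(
    genome: GenomeAssembly,
    config: SimulationConfig,
) -> tuple[list[SequenceRecord], list[FragmentLocus]]:
    """ChIP-like fragments with start sampling tilted toward AT-rich regions.

    Candidate starts are weighted exp(beta * fragment AT), with beta
    chosen per fragment length so the expected AT of the selected
    fragment exceeds the genome mean by ``fragment_at_shift``.
    """
    rng = config.rng(3)
    lo, hi = config.fragment_length_range
    max_len = max(r.length for r in genome)
    if lo > max_len:
        raise ValueError("fragment length exceeds every chromosome")
    prefixes = {r.id: _at_fraction_prefix(r.sequence) for r in genome}
    chrom_weights = np.array([r.length for r in genome], dtype=float)
    chrom_weights /= chrom_weights.sum()
    records: list[SequenceRecord] = []
    loci: list[FragmentLocus] = []
    for i in range(config.n_fragments):
        length = int(rng.integers(lo, hi + 1))
        # redraw chromosome until the fragment fits
        for _ in range(1000):
            ci = int(rng.choice(len(genome.records), p=chrom_weights))
            rec = genome.records[ci]
            if length <= rec.length:
                break
        else:
            raise ValueError("fragment length exceeds chromosome lengths")
        pre = prefixes[rec.id]
        at = (pre[length:] - pre[:-length]) / length  # AT of every candidate start
        if config.fragment_at_shift > 0:
            var = float(np.var(at))
            beta = config.fragment_at_shift / var if var > 1e-12 else 0.0
            logw = beta * (at - at.max())
            w = np.exp(logw)
            p = w / w.sum()
            start = int(rng.choice(len(at), p=p))
        else:
            start = int(rng.integers(0, len(at)))
        frag_id = f"frag{i + 1}"
        records.append(SequenceRecord(frag_id, rec.sequence[start : start + length]))
        loci.append(FragmentLocus(frag_id, rec.id, start, start + length))
    return records, loci


def simulate_gene_models(
    genome: GenomeAssembly,
    config: SimulationConfig,
) -> list[GeneModel]:
    """Non-overlapping genes with random strands and exon counts from config."""
    rng = config.rng(4)
    models: list[GeneModel] = []
    for rec in genome:
        n_genes = int(round(config.gene_density * rec.length / 1e6))
        if n_genes == 0:
            continue
        # build gene structures first, then allocate the leftover space to gaps
        structures = []
        for _ in range(n_genes):
            n_ex = int(rng.integers(config.exon_count_range[0], config.exon_count_range[1] + 1))
            ex_lens = rng.integers(
                config.exon_length_range[0], config.exon_length_range[1] + 1, size=n_ex
            )
            in_lens = rng.integers(
                config.intron_length_range[0], config.intron_length_range[1] + 1, size=n_ex - 1
            )
            structures.append((ex_lens, in_lens))
        total = sum(int(e.sum() + i.sum()) for e, i in structures)
        free = rec.length - total
        if free < 0:
            raise ValueError(f"gene density infeasible on {rec.id}")
        # n_genes + 1 random gaps summing to the free space
        cuts = np.sort(rng.integers(0, free + 1, size=n_genes))
        gaps = np.diff(np.concatenate([[0], cuts, [free]]))
        pos = 0
        for gi, (ex_lens, in_lens) in enumerate(structures):
            pos += int(gaps[gi])
            exons = []
            p = pos
            for k, el in enumerate(ex_lens):
                exons.append((p, p + int(el)))
                p += int(el)
                if k < len(in_lens):
                    p += int(in_lens[k])
            strand = "+" if rng.random() < 0.5 else "-"
            models.append(
                GeneModel(
                    gene_id=f"{rec.id}_g{gi + 1}",
                    chrom=rec.id,
                    strand=strand,
                    exons=tuple(exons),
                )
            )
            pos = p
    return models


def simulate_qpcr(config: SimulationConfig) -> list[QpcrSample]:
    """Ct pairs with ΔCt ~ Normal(mean, sd) over a fixed IP baseline."""
    if config.qpcr_delta_ct_sd < 0:
        raise ValueError("sd must be >= 0")
    rng = config.rng(5)
    delta = rng.normal(config.qpcr_delta_ct_mean, config.qpcr_delta_ct_sd, config.qpcr_n)
    return [
        QpcrSample(
            id=f"S{i + 1}",
            ct_ip=config.qpcr_ct_ip,
            ct_noab=config.qpcr_ct_ip + float(d),
        )
        for i, d in enumerate(delta)
    ]
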