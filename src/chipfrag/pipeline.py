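"""End-to-end orchestration of the fragment-characterization analyses.

Runs, in order: AT-composition statistics, the degenerate-consensus
genome scan, cross-fragment short matching feeding the sequence logo,
qPCR enrichment, and locus annotation.  Stages whose inputs are not
given are skipped and noted in the run log.  Re-running with an
identical config writes bit-identical data outputs.
"""

from __future__ import annotations

import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .chip_quant import read_qpcr_tsv, write_enrichment_tsv, mean_enrichment
from .composition_stats import (
    compare_fragments_to_genome,
    write_histogram_tsv,
    write_ranksum_json,
)
from .locus_annotator import FragmentLocus, classify, tally, write_annotation_tsv
from .composition_stats import at_content
from .logo_builder import build_pfm, information_content, write_logo_tsv
from .motif_engine import read_patterns, scan, write_matches_bed, write_summary_json
from .seq_io import read_fasta, read_gene_models
from .short_match import (
    AlignParams,
    all_pairs_matches,
    collect_segments,
    write_alignments_tsv,
    write_segments_fasta,
)

__all__ = ["RunConfig", "PipelineError", "run", "read_fragment_loci"]


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    fragments_fasta: str
    genome_fasta: str
    outdir: str
    patterns_file: str | None = None
    gene_models_file: str | None = None
    gene_models_format: str = "bed12"
    fragment_loci_file: str | None = None
    qpcr_file: str | None = None
    window_size: int = 500
    word_size: int = 7
    segment_lengths: tuple[int, ...] = (11, 12)
    strands: str = "forward"
    seed: int = 0


def read_fragment_loci(path: str | Path) -> list[FragmentLocus]:
    """Read fragment loci from a TSV (fragment_id, chrom, start, end; 0-based)."""
    loci = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {c: i for i, c in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            loci.append(
                FragmentLocus(
                    fragment_id=f[idx["fragment_id"]],
                    chrom=f[idx["chrom"]],
                    start=int(f[idx["start"]]),
                    end=int(f[idx["end"]]),
                )
            )
    return loci


def run(config: RunConfig) -> dict:
    """Execute every configured stage; returns the run-log dictionary."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": {
            "window_size": config.window_size,
            "word_size": config.word_size,
            "segment_lengths": list(config.segment_lengths),
            "strands": config.strands,
        },
        "stages": {},
    }

    def stage(name: str):
        def deco(fn):
            try:
                result = fn()
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
                raise PipelineError(name, exc) from exc
            log["stages"][name] = result

        return deco

    fragments = read_fasta(config.fragments_fasta)
    genome = read_fasta(config.genome_fasta)

    @stage("composition_stats")
    def _atstats():
        cmp = compare_fragments_to_genome(
            fragments, genome, window_size=config.window_size
        )
        write_histogram_tsv(cmp, outdir / "at_histogram.tsv")
        write_ranksum_json(cmp, outdir / "at_ranksum.json")
        return {
            "n_fragments": len(cmp.fragment_at),
            "n_windows": cmp.profile.n_windows,
            "p_greater": cmp.result_greater.p_two_sided,
        }

    if config.patterns_file:

        @stage("motif_engine")
        def _scan():
            patterns = read_patterns(config.patterns_file)
            report = scan(genome, patterns, strands=config.strands)
            write_matches_bed(report, outdir / "motif_matches.bed")
            write_summary_json(report, outdir / "motif_summary.json")
            return {"n_matches": report.n, "K": report.K}

    else:
        log["stages"]["motif_engine"] = "skipped: no pattern file"

    @stage("short_match")
    def _shortmatch():
        params = AlignParams(word_size=config.word_size)
        alignments = all_pairs_matches(fragments, params)
        write_alignments_tsv(alignments, outdir / "alignments.tsv")
        info = {"n_alignments": len(alignments), "logos": {}}
        for sl in config.segment_lengths:
            segset = collect_segments(alignments, sl, fragments)
            write_segments_fasta(segset, outdir / f"segments_{sl}bp.fasta")
            if segset.n:
                logo = information_content(build_pfm(segset))
                write_logo_tsv(logo, outdir / f"logo_{sl}bp.tsv")
            info["logos"][str(sl)] = segset.n
        return info

    if config.qpcr_file:

        @stage("chip_quant")
        def _qpcr():
            samples = read_qpcr_tsv(config.qpcr_file)
            write_enrichment_tsv(samples, outdir / "enrichment.tsv")
            return {"n_samples": len(samples), "mean_fold": mean_enrichment(samples)}

    else:
        log["stages"]["chip_quant"] = "skipped: no qPCR table"

    if config.gene_models_file and config.fragment_loci_file:

        @stage("locus_annotator")
        def _annotate():
            genes = read_gene_models(
                config.gene_models_file, format=config.gene_models_format
            )
            loci = read_fragment_loci(config.fragment_loci_file)
            annos = [classify(l, genes) for l in loci]
            lengths = {l.fragment_id: l.end - l.start for l in loci}
            at = {
                rec.id: at_content(rec.sequence)
                for rec in fragments
                if rec.id in lengths
            }
            write_annotation_tsv(annos, outdir / "annotations.tsv", lengths, at)
            return tally(annos).by_category

    else:
        log["stages"]["locus_annotator"] = "skipped: need gene models and fragment loci"

    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=2)
        fh.write("\n")
    return log
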