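"""Bundled reference tables from the HMGA2 ChIP-cloning experiment.

Two small plain-text tables ship with the package: the GAPDH qPCR
threshold cycles of the five immunoprecipitated samples, and the locus
table of the 49 cloned ChIP fragments (length, AT%, cytoband, nearest
gene, exon/intron or upstream/downstream relation, distance).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .chip_quant import QpcrSample, read_qpcr_tsv

__all__ = ["clone_loci", "qpcr_samples"]


def _data_path(name: str):
    return resources.files("chipfrag").joinpath("data", name)


def clone_loci() -> pd.DataFrame:
    """The 49 cloned ChIP fragment loci as a DataFrame."""
    with resources.as_file(_data_path("chip_clone_loci.tsv")) as p:
        return pd.read_csv(p, sep="\t", dtype={"clone": str})


def qpcr_samples() -> list[QpcrSample]:
    """GAPDH Ct pairs (IP vs no-antibody control) of the five ChIP samples."""
    with resources.as_file(_data_path("gapdh_qpcr_ct.tsv")) as p:
        return read_qpcr_tsv(p)
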