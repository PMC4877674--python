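"""Bundled example datasets.

Summary tables from a published two-library chilling-stress study of
vegetable soybean miRNAs, shipped so the arithmetic of the reporting layer
(log2 ratios, DE partitioning, category percentages) can be exercised on
real published numbers without any external download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def _path(name: str):
    return resources.files("soymir.data").joinpath(name)


def chilling_de_mirnas() -> pd.DataFrame:
    """51 chilling-responsive soybean miRNAs: sequence, normalized read
    values (reads per million miRNA reads) in control and chilling
    libraries, and the reported log2(chilling/control)."""
    with resources.as_file(_path("chilling_de_mirnas.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def chilling_target_categories() -> pd.DataFrame:
    """Degradome target counts per category (0–4) for the same study
    (898 targets in total)."""
    with resources.as_file(_path("chilling_target_categories.tsv")) as p:
        return pd.read_csv(p, sep="\t")
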