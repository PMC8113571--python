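"""Published genome-survey summary tables shipped as package data.

These are the printed summary numbers of the spinach Sp75 chromosome-level
SSR survey and its 48-accession validation panel: per-chromosome locus
counts, the stepwise marker-development cascade per motif class, and the
per-marker validation statistics (Na, He, PIC). They let the accounting and
diversity arithmetic be exercised against a real published surface without
re-running the genome-scale analysis.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd


def _load(name: str) -> pd.DataFrame:
    with files("ssrscape.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, sep="\t")


def chromosome_summary() -> pd.DataFrame:
    """Per-chromosome length, SSR count and polymorphic-SSR count."""
    return _load("sp75_chromosome_summary.tsv")


def filter_cascade() -> pd.DataFrame:
    """Stepwise screening counts per motif class (Di .. Hexa)."""
    return _load("sp75_filter_cascade.tsv")


def validation_markers() -> pd.DataFrame:
    """The 36 assayed validation markers with Na/He/PIC (NA where no amplification)."""
    return _load("sp75_validation_markers.tsv")
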