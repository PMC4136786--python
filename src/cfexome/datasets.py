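"""Bundled example data."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_cohort() -> pd.DataFrame:
    """Example monitoring cohort: seven breast and one prostate cancer
    patient, with the number of tumor-derived point mutations retained
    after eligibility filtering and the plasma detection results."""
    with resources.files("cfexome.data").joinpath("cohort_sites.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
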