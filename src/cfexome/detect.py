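"""Pooled ctDNA detection against the background pool.

Because a patient's individual somatic sites see only a handful of reads
each, evidence is pooled: mutant and reference counts are summed across
all tracked sites and the pooled 2x2 table (sample vs background) is
tested with a one-sided Fisher's exact test, alternative "sample mutant
fraction greater than background". The reported ctDNA fraction is the raw
pooled mutant fraction, with no background subtraction and no
multiple-testing correction across patients.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom


@dataclass
class DetectionResult:
    sample: str
    n_sites: int
    sample_alt: int
    sample_ref: int
    bg_alt: int
    bg_ref: int
    ctdna_fraction: float
    p_value: float
    alpha: float
    detected: bool


def pool_counts(site_counts: pd.DataFrame) -> tuple[int, int]:
    """Sum alt and ref over a patient's tracked sites."""
    if len(site_counts) == 0:
        raise ValueError("no tracked sites to pool")
    return int(site_counts["n_alt"].sum()), int(site_counts["n_ref"].sum())


def fisher_one_sided(sample_alt: int, sample_ref: int,
                     bg_alt, bg_ref) -> float | np.ndarray:
    """One-sided Fisher's exact p, alternative: sample fraction greater.

    Exact hypergeometric tail probability of >= ``sample_alt`` mutant
    reads in the sample given the table margins. ``sample_alt = 0`` gives
    p = 1 exactly. Vectorizes over ``sample_alt``.
    """
    sample_alt = np.asarray(sample_alt)
    if (np.any(sample_alt < 0) or sample_ref < 0
            or np.any(np.asarray(bg_alt) < 0) or np.any(np.asarray(bg_ref) < 0)):
        raise ValueError("counts must be non-negative")
    M = sample_alt + sample_ref + bg_alt + bg_ref
    n_draw = sample_alt + sample_ref
    K = sample_alt + bg_alt
    p = hypergeom.sf(sample_alt - 1, M, K, n_draw)
    p = np.minimum(p, 1.0)
    if p.ndim == 0:
        return float(p)
    return p


def detect(sample_counts: pd.DataFrame, bg_alt: int, bg_ref: int,
           sample: str = "sample", alpha: float = 0.05) -> DetectionResult:
    """Pool a sample's site counts and test them against its background.

    The background must already exclude this sample and any sample whose
    tumor shares its mutations (see `noise.background_pool`).
    """
    if bg_alt + bg_ref == 0:
        raise ValueError("empty background pool")
    alt, ref = pool_counts(sample_counts)
    frac = alt / (alt + ref) if alt + ref else 0.0
    p = fisher_one_sided(alt, ref, bg_alt, bg_ref)
    return DetectionResult(
        sample=sample, n_sites=len(sample_counts), sample_alt=alt,
        sample_ref=ref, bg_alt=int(bg_alt), bg_ref=int(bg_ref),
        ctdna_fraction=frac, p_value=p, alpha=alpha, detected=p < alpha)


def detect_cohort(counts: pd.DataFrame, pools: pd.DataFrame,
                  alpha: float = 0.05) -> pd.DataFrame:
    """Per-sample detection table (fraction, p-value) for a whole cohort.

    ``counts`` stacks per-sample `noise.count_alleles` outputs (with
    ``sample`` and ``cutoff`` columns); ``pools`` is the matching
    `noise.background_pool` output.
    """
    rows = []
    for r in pools.itertuples():
        mine = counts[(counts["sample"] == r.sample)
                      & (counts["cutoff"] == r.cutoff)]
        res = detect(mine, r.bg_alt, r.bg_ref, sample=r.sample, alpha=alpha)
        rows.append({
            "sample": res.sample, "cutoff": r.cutoff, "n_sites": res.n_sites,
            "sample_alt": res.sample_alt, "sample_ref": res.sample_ref,
            "bg_alt": res.bg_alt, "bg_ref": res.bg_ref,
            "ctdna_fraction": res.ctdna_fraction, "p_value": res.p_value,
            "detected": res.detected})
    return pd.DataFrame(rows)
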