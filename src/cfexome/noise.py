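"""Background-noise estimation and quality-cutoff optimization.

At each tracked somatic site the pileup is tallied into mutant (alternate
allele), reference, other-base and masked-N counts, per base-quality
cutoff. Pooling those tallies over background samples — every sample
whose tumor does not carry the mutation — gives the noise rate

    noise = sum(mutant) / (sum(mutant) + sum(reference)),

the probability that a background base at a tracked site spuriously reads
as the mutant allele. Because merge- and consensus-boosted qualities mark
bases with multi-source support, sweeping the cutoff trades data
retention against noise; the optimal cutoff minimizes the noise rate,
preferring higher retention on ties.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .io import AlignedFragment

Q_GRID_DEFAULT = np.arange(0, 51)


def pileup_bases(fragments: Iterable[AlignedFragment],
                 sites: pd.DataFrame) -> pd.DataFrame:
    """Per-site base observations with qualities, one row per read base.

    ``sites`` needs columns ``chrom, pos, ref, alt``. Returns a DataFrame
    with columns ``chrom, pos, base_class (alt|ref|other|masked), qual``.
    Sites never covered simply contribute no rows.
    """
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): sub.sort_values("pos") for c, sub in sites.groupby("chrom")}
    rows = []
    for f in fragments:
        sub = by_chrom.get(f.chrom)
        if sub is None:
            continue
        pos = sub["pos"].to_numpy()
        i0, i1 = np.searchsorted(pos, [f.start, f.end])
        for i in range(i0, i1):
            p = pos[i]
            base = f.seq[p - f.start]
            q = f.qual[p - f.start]
            if base == "N":
                cls = "masked"
            elif base == sub["alt"].iat[i]:
                cls = "alt"
            elif base == sub["ref"].iat[i]:
                cls = "ref"
            else:
                cls = "other"
            rows.append((f.chrom, int(p), cls, int(q)))
    return pd.DataFrame(rows, columns=["chrom", "pos", "base_class", "qual"])


def count_alleles(fragments: Iterable[AlignedFragment], sites: pd.DataFrame,
                  cutoff: int = 0, sample: str | None = None) -> pd.DataFrame:
    """Allele counts per site at one quality cutoff.

    Non-N bases with quality >= cutoff are tallied as ``n_alt``/``n_ref``/
    ``n_other``; N bases always land in ``n_masked`` and never enter
    rates. Sites outside every alignment get all-zero rows.
    """
    obs = pileup_bases(fragments, sites)
    out = sites[["chrom", "pos", "ref", "alt"]].copy()
    for col in ("n_alt", "n_ref", "n_other", "n_masked"):
        out[col] = 0
    out["cutoff"] = cutoff
    if sample is not None:
        out["sample"] = sample
    if obs.empty:
        return out
    keep = (obs["base_class"] == "masked") | (obs["qual"] >= cutoff)
    obs = obs[keep]
    tab = (obs.groupby(["chrom", "pos", "base_class"]).size()
           .unstack(fill_value=0))
    idx = out.set_index(["chrom", "pos"]).index
    for cls, col in (("alt", "n_alt"), ("ref", "n_ref"),
                     ("other", "n_other"), ("masked", "n_masked")):
        if cls in tab.columns:
            out[col] = tab[cls].reindex(idx, fill_value=0).to_numpy()
    return out


def noise_rate(pool_alt: int, pool_ref: int) -> float:
    """Mutant fraction of the pooled background; NaN when the pool is empty."""
    if pool_alt < 0 or pool_ref < 0:
        raise ValueError("counts must be non-negative")
    total = pool_alt + pool_ref
    if total == 0:
        return float("nan")
    return pool_alt / total


def sweep_cutoffs(observations: pd.DataFrame,
                  q_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Noise rate, data retention and log2 mutant/reference ratio per cutoff.

    ``observations`` is the `pileup_bases` output pooled over background
    samples. ``fraction_data_left`` is reference reads retained at q
    relative to q=0; ``log2_ratio`` compares retained mutant vs reference
    proportions (NaN once either side empties).
    """
    q_grid = Q_GRID_DEFAULT if q_grid is None else np.asarray(q_grid)
    if np.any(np.diff(q_grid) < 0):
        raise ValueError("q_grid must be sorted ascending")
    alt_q = observations.loc[observations["base_class"] == "alt", "qual"]
    ref_q = observations.loc[observations["base_class"] == "ref", "qual"]
    alt0, ref0 = len(alt_q), len(ref_q)
    rows = []
    for q in q_grid:
        a = int((alt_q >= q).sum())
        r = int((ref_q >= q).sum())
        frac_left = r / ref0 if ref0 else float("nan")
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (a / alt0) / (r / ref0) if alt0 and ref0 and r else np.nan
        rows.append({
            "q": int(q),
            "noise_rate": noise_rate(a, r),
            "fraction_data_left": frac_left,
            "log2_ratio": float(np.log2(ratio)) if ratio and ratio > 0 else float("nan"),
            "n_alt": a, "n_ref": r,
        })
    return pd.DataFrame(rows)


def optimal_cutoff(table: pd.DataFrame) -> int:
    """Cutoff minimizing the noise rate.

    Ties prefer larger ``fraction_data_left``, then smaller q. Rows with
    undefined (NaN) noise rate are ignored; all-undefined raises.
    """
    if table.empty:
        raise ValueError("empty cutoff table")
    ok = table.dropna(subset=["noise_rate"])
    if ok.empty:
        raise ValueError("noise rate undefined at every cutoff")
    best = min(ok.itertuples(),
               key=lambda r: (r.noise_rate, -r.fraction_data_left, r.q))
    return int(best.q)


def background_pool(counts: pd.DataFrame,
                    site_carriers: dict[tuple[str, int], set[str]] | None = None
                    ) -> pd.DataFrame:
    """Leave-one-out background pools per sample.

    ``counts`` stacks `count_alleles` outputs over samples (needs a
    ``sample`` column). For each target sample the pool sums ``n_alt`` and
    ``n_ref`` over that sample's sites across all *other* samples,
    excluding at each site any sample listed in ``site_carriers`` (samples
    whose primary tumor carries the same mutation). Returns one row per
    (sample, cutoff) with ``bg_alt`` and ``bg_ref``.
    """
    if "sample" not in counts.columns:
        raise ValueError("counts need a 'sample' column")
    site_carriers = site_carriers or {}
    rows = []
    for (target, cutoff), mine in counts.groupby(["sample", "cutoff"]):
        my_sites = set(zip(mine["chrom"], mine["pos"]))
        others = counts[(counts["sample"] != target)
                        & (counts["cutoff"] == cutoff)]
        bg_alt = bg_ref = 0
        for r in others.itertuples():
            key = (r.chrom, r.pos)
            if key not in my_sites:
                continue
            if r.sample in site_carriers.get(key, set()):
                continue
            bg_alt += r.n_alt
            bg_ref += r.n_ref
        rows.append({"sample": target, "cutoff": cutoff,
                     "bg_alt": bg_alt, "bg_ref": bg_ref})
    return pd.DataFrame(rows)
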