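"""Genomic eligibility mask for ctDNA positions.

Somatic sites are only counted where the genome is uniquely mappable and
free of germline contamination: positions within a flank (default 50 bp)
of a low-mappability region, inside a simple repeat, or at a known
germline variant are excluded. Intervals are 0-based half-open
throughout; "within 50 bp" means the distance from the site to the
nearest base of the excluded interval is <= 50.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EXCLUSION_SOURCES = ("mappability", "repeat", "germline")


def _merge_intervals(iv: np.ndarray) -> np.ndarray:
    """Sort and coalesce overlapping/adjacent [start, end) intervals."""
    if len(iv) == 0:
        return np.empty((0, 2), dtype=np.int64)
    iv = iv[np.lexsort((iv[:, 1], iv[:, 0]))]
    out = [list(iv[0])]
    for s, e in iv[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return np.asarray(out, dtype=np.int64)


@dataclass
class GenomicMask:
    """Per-chromosome exclusion intervals with provenance labels.

    ``excluded`` maps chrom -> merged interval array; ``by_source`` keeps
    the per-source (expanded) intervals so removals can be attributed.
    A position is eligible iff it falls in no excluded interval.
    """

    excluded: dict[str, np.ndarray] = field(default_factory=dict)
    by_source: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)

    def _contains(self, table: dict[str, np.ndarray], chrom: str,
                  pos) -> np.ndarray:
        pos = np.atleast_1d(np.asarray(pos, dtype=np.int64))
        iv = table.get(chrom)
        if iv is None or len(iv) == 0:
            return np.zeros(pos.shape, dtype=bool)
        idx = np.searchsorted(iv[:, 0], pos, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(pos.shape, dtype=bool)
        hit[ok] = pos[ok] < iv[idx[ok], 1]
        return hit

    def is_excluded(self, chrom: str, pos) -> np.ndarray:
        return self._contains(self.excluded, chrom, pos)

    def is_eligible(self, chrom: str, pos) -> np.ndarray:
        return ~self.is_excluded(chrom, pos)

    def excluded_by(self, source: str, chrom: str, pos) -> np.ndarray:
        return self._contains(self.by_source.get(source, {}), chrom, pos)


def _read_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2], names=["chrom", "start", "end"])
    return df


def build_mask(mappability_track: pd.DataFrame | str | Path | None = None,
               germline_sites: pd.DataFrame | str | Path | None = None,
               repeat_track: pd.DataFrame | str | Path | None = None,
               flank: int = 50) -> GenomicMask:
    """Assemble the exclusion mask from interval tracks.

    ``mappability_track`` holds regions already thresholded at
    mappability < 1; each is expanded by ``flank`` on both sides. Repeat
    intervals and germline positions (interval rows, or a ``chrom,pos``
    table treated as 1 bp intervals) are excluded as-is. Any argument may
    be a BED path, a DataFrame, or None (empty track).
    """
    if flank < 0:
        raise ValueError("flank must be >= 0")

    def load(track, expand=0, point=False):
        if track is None:
            return {}
        if not isinstance(track, pd.DataFrame):
            track = _read_bed(track)
        df = track.copy()
        if point and "pos" in df.columns:
            df = df.assign(start=df["pos"], end=df["pos"] + 1)
        if (df["start"] >= df["end"]).any():
            raise ValueError("malformed interval: start >= end")
        out = {}
        for chrom, sub in df.groupby("chrom"):
            iv = sub[["start", "end"]].to_numpy(dtype=np.int64)
            iv[:, 0] = np.maximum(iv[:, 0] - expand, 0)
            iv[:, 1] += expand
            out[str(chrom)] = _merge_intervals(iv)
        return out

    by_source = {
        "mappability": load(mappability_track, expand=flank),
        "repeat": load(repeat_track),
        "germline": load(germline_sites, point=True),
    }
    chroms = set().union(*(d.keys() for d in by_source.values()))
    excluded = {}
    for c in chroms:
        parts = [d[c] for d in by_source.values() if c in d]
        excluded[c] = _merge_intervals(np.vstack(parts))
    return GenomicMask(excluded, by_source)


def filter_sites(sites: pd.DataFrame, mask: GenomicMask
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Retain sites eligible under the mask; report removals by source.

    ``sites`` needs ``chrom`` and ``pos`` columns. Returns (retained
    sites, report) where the report counts, per exclusion source, how many
    sites that source alone would remove (a site inside several sources
    counts toward each), plus totals.
    """
    if not {"chrom", "pos"}.issubset(sites.columns):
        raise ValueError("sites need 'chrom' and 'pos' columns")
    sites = sites.reset_index(drop=True)
    keep = np.ones(len(sites), dtype=bool)
    source_hits = {s: 0 for s in EXCLUSION_SOURCES}
    for chrom, sub in sites.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        keep[sub.index.to_numpy()] = mask.is_eligible(str(chrom), pos)
        for s in EXCLUSION_SOURCES:
            source_hits[s] += int(mask.excluded_by(s, str(chrom), pos).sum())
    retained = sites.loc[keep].reset_index(drop=True)
    rows = [{"source": s, "n_removed": source_hits[s]} for s in EXCLUSION_SOURCES]
    rows.append({"source": "total_removed", "n_removed": int((~keep).sum())})
    rows.append({"source": "retained", "n_removed": int(keep.sum())})
    return retained, pd.DataFrame(rows)


def write_mask_bed(mask: GenomicMask, path: str | Path) -> Path:
    """Write the merged exclusion intervals as BED."""
    rows = [(c, int(s), int(e))
            for c in sorted(mask.excluded) for s, e in mask.excluded[c]]
    pd.DataFrame(rows, columns=["chrom", "start", "end"]).to_csv(
        path, sep="\t", header=False, index=False)
    return Path(path)
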