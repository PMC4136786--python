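"""Monte-Carlo sensitivity of pooled ctDNA detection.

Maps the detection limit of the pooled Fisher test as a function of ctDNA
fraction and cfDNA input mass. Each iteration draws the sample's pooled
mutant count from Binomial(pooled depth, fraction) and tests it against a
fixed background table; sensitivity is the share of iterations reaching
p < alpha, and the 95% detection limit is the smallest fraction whose
sensitivity reaches 0.95.

Pooled depth follows the assay arithmetic: an exome tracks ~50 somatic
variants, a 30 ng cfDNA input holds mass/3.218 pg haploid genome copies,
of which the capture efficiency (~4.7%) is observable, and the quality
filter keeps a pipeline-dependent fraction of bases. A WGS mode instead
fixes per-site coverage (default 30x) over ~3000 variants.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import binom

from .detect import fisher_one_sided

PG_PER_HAPLOID_GENOME = 3.218
BACKGROUND_POOL_READS = 517_973


def haploid_copies(mass_pg: float) -> int:
    """Haploid genome copies in a DNA mass (3.218 pg per haploid copy)."""
    if mass_pg <= 0:
        raise ValueError("mass must be positive")
    return int(round(mass_pg / PG_PER_HAPLOID_GENOME))


def expected_mutant_reads(coverage: float, n_variants: float,
                          kept_fraction: float, ctdna_fraction: float) -> float:
    """Expected pooled mutant reads: coverage x variants x kept x fraction."""
    if min(coverage, n_variants, kept_fraction, ctdna_fraction) < 0:
        raise ValueError("all factors must be >= 0")
    return coverage * n_variants * kept_fraction * ctdna_fraction


def default_fraction_grid(n: int = 40) -> np.ndarray:
    return np.logspace(np.log10(1e-5), np.log10(0.05), n)


@dataclass
class SimConfig:
    """Parameters of the sensitivity simulation (defaults: optimized exome
    pipeline — 50 variants, 4.7% capture efficiency, 61% of bases kept,
    background pool of 517,973 reads at noise rate 1/35,419)."""

    fractions: np.ndarray = field(default_factory=default_fraction_grid)
    input_mass_ng: tuple[float, ...] = (30.0,)
    pg_per_haploid_genome: float = PG_PER_HAPLOID_GENOME
    capture_efficiency: float = 0.047
    n_variants: int = 50
    mode: str = "exome"            # "exome" or "wgs"
    coverage: float = 30.0         # per-site depth, WGS mode only
    kept_fraction: float = 0.61
    bg_pool_size: int = BACKGROUND_POOL_READS
    bg_noise_rate: float = 1.0 / 35_419
    bg_alt: int | None = None      # overrides pool_size x noise_rate
    bg_ref: int | None = None
    iterations: int = 1000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if np.any((self.fractions <= 0) | (self.fractions >= 1)):
            raise ValueError("fractions must lie in (0, 1)")
        if not 0 < self.capture_efficiency <= 1:
            raise ValueError("capture_efficiency must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.mode not in ("exome", "wgs"):
            raise ValueError("mode must be 'exome' or 'wgs'")

    @property
    def background(self) -> tuple[int, int]:
        if self.bg_alt is not None and self.bg_ref is not None:
            return self.bg_alt, self.bg_ref
        alt = int(round(self.bg_pool_size * self.bg_noise_rate))
        return alt, self.bg_pool_size - alt

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        cfg = json.loads(Path(path).read_text())
        if "input_mass_ng" in cfg:
            cfg["input_mass_ng"] = tuple(cfg["input_mass_ng"])
        return cls(**cfg)


def sample_depth(config: SimConfig, mass_ng: float) -> int:
    """Pooled read depth across tracked variants for one input mass.

    Exome: (mass / 3.218 pg) haploid copies x capture efficiency gives the
    per-site depth; pooled over variants and scaled by the kept fraction.
    WGS: fixed coverage x variants x kept fraction (mass plays no role).
    """
    if config.mode == "wgs":
        pooled = config.coverage * config.n_variants * config.kept_fraction
    else:
        copies = mass_ng * 1000.0 / config.pg_per_haploid_genome
        pooled = (copies * config.capture_efficiency
                  * config.n_variants * config.kept_fraction)
    pooled = int(round(pooled))
    if pooled <= 0:
        raise ValueError("pooled depth is zero; increase input or coverage")
    return pooled


def _sensitivity_at(depth: int, fraction: float, bg_alt: int, bg_ref: int,
                    alpha: float, u: np.ndarray) -> float:
    """Share of iterations with one-sided Fisher p < alpha.

    Iterations are driven by common random numbers: pre-drawn uniforms are
    pushed through the binomial quantile function, so sensitivity is
    non-decreasing in fraction and depth draw-by-draw, not just in
    expectation.
    """
    alts = binom.ppf(u, depth, fraction).astype(np.int64)
    uniq, counts = np.unique(alts, return_counts=True)
    p = np.array([fisher_one_sided(int(a), depth - int(a), bg_alt, bg_ref)
                  for a in uniq])
    return float(counts[p < alpha].sum() / u.size)


def simulate_sensitivity(config: SimConfig) -> pd.DataFrame:
    """Sensitivity per (fraction, input mass), with Monte-Carlo SE."""
    bg_alt, bg_ref = config.background
    if bg_alt + bg_ref <= 0:
        raise ValueError("invalid background pool")
    rng = np.random.default_rng(config.seed)
    u = rng.random(config.iterations)
    rows = []
    for mass in config.input_mass_ng:
        depth = sample_depth(config, mass)
        for f in config.fractions:
            s = _sensitivity_at(depth, float(f), bg_alt, bg_ref,
                                config.alpha, u)
            rows.append({
                "fraction": float(f), "mass_ng": float(mass), "depth": depth,
                "sensitivity": s,
                "se": float(np.sqrt(s * (1 - s) / config.iterations))})
    return pd.DataFrame(rows)


def simulate_sensitivity_empirical(config: SimConfig,
                                   site_depths: np.ndarray) -> pd.DataFrame:
    """Sensitivity with sample reads resampled over an empirical site pool.

    Instead of one pooled binomial, each iteration distributes the pooled
    depth over tracked sites with probabilities proportional to the
    empirical per-site depths, then draws each read's mutant indicator
    with probability equal to the ctDNA fraction. Marginally equivalent to
    the binomial mode; provided for fidelity to resampling from observed
    per-site read pools.
    """
    site_depths = np.asarray(site_depths, dtype=float)
    if site_depths.sum() <= 0:
        raise ValueError("empirical site pool is empty")
    bg_alt, bg_ref = config.background
    rng = np.random.default_rng(config.seed)
    rows = []
    for mass in config.input_mass_ng:
        depth = sample_depth(config, mass)
        for f in config.fractions:
            hits = 0
            for _ in range(config.iterations):
                alt = int(rng.binomial(depth, f))
                if fisher_one_sided(alt, depth - alt, bg_alt, bg_ref) < config.alpha:
                    hits += 1
            s = hits / config.iterations
            rows.append({
                "fraction": float(f), "mass_ng": float(mass), "depth": depth,
                "sensitivity": s,
                "se": float(np.sqrt(s * (1 - s) / config.iterations))})
    return pd.DataFrame(rows)


def detection_limit(curve: pd.DataFrame, target: float = 0.95,
                    mass_ng: float | None = None) -> float | None:
    """Smallest ctDNA fraction whose sensitivity reaches ``target``.

    Takes the first grid fraction at or above the target and refines it by
    log-linear interpolation against the preceding grid point. Returns
    None when the curve never crosses the target ("beyond range"). Use
    ``1 / detection_limit(...)`` for the reciprocal form.
    """
    df = curve if mass_ng is None else curve[curve["mass_ng"] == mass_ng]
    df = df.sort_values("fraction")
    above = df[df["sensitivity"] >= target]
    if above.empty:
        return None
    hi = above.iloc[0]
    prev = df[df["fraction"] < hi["fraction"]]
    if prev.empty or hi["sensitivity"] == target:
        return float(hi["fraction"])
    lo = prev.iloc[-1]
    if lo["sensitivity"] >= target or hi["sensitivity"] == lo["sensitivity"]:
        return float(hi["fraction"])
    t = (target - lo["sensitivity"]) / (hi["sensitivity"] - lo["sensitivity"])
    logf = np.log(lo["fraction"]) + t * (np.log(hi["fraction"]) - np.log(lo["fraction"]))
    return float(np.exp(logf))
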