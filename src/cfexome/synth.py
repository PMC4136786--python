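"""Synthetic cell-free DNA library generator with full ground truth.

Emulates the salient structure of a cfDNA sequencing library: short
fragments peaking around 180 bp, 2x100 bp paired-end reads whose mates
overlap for typical fragments, PCR-duplicate families amplified from a
single starting molecule, and two distinct error channels — PCR errors
shared by every read of a family, and sequencer errors private to each
read. Tumor-derived molecules carry the alternate allele at the somatic
sites they cover, spiked at a known ctDNA fraction, so every downstream
stage (merging, duplicate consensus, allele counting, detection) can be
scored against exact provenance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AlignedFragment, write_sam, phred_to_string

BASES = np.array(["A", "C", "G", "T"])
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SynthConfig:
    """Parameters of the synthetic cfDNA library.

    Defaults follow the characteristics of real cell-free DNA libraries:
    a ~180 bp fragment-size peak, 2x100 bp reads, and a per-base
    substitution error rate of 0.29%.
    """

    genome_length: int = 100_000
    n_variant_sites: int = 50
    ctdna_fraction: float = 0.0
    fragment_size_mean: float = 180.0
    fragment_size_sd: float = 40.0
    read_length: int = 100
    seq_error_rate: float = 0.0029
    pcr_error_rate: float = 1e-4
    duplicate_rate_mean: float = 3.0
    n_molecules: int = 1000
    base_quality: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ctdna_fraction", "seq_error_rate", "pcr_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.duplicate_rate_mean < 1.0:
            raise ValueError("duplicate_rate_mean is reads per molecule, >= 1")
        if self.read_length < 1 or self.genome_length < 1:
            raise ValueError("read_length and genome_length must be positive")

    @property
    def fragment_bounds(self) -> tuple[int, int]:
        # truncation window for fragment sizes: [50, 2*read_length + 50]
        return 50, 2 * self.read_length + 50

    @classmethod
    def from_json(cls, path: str | Path) -> "SynthConfig":
        return cls(**json.loads(Path(path).read_text()))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))


@dataclass
class TruthTable:
    """Ground-truth provenance for a simulated library.

    ``molecules`` has one row per starting molecule (fragment coordinates,
    tumor/normal origin, family size, PCR-error positions); ``reads`` has
    one row per emitted read pair (sequencer-error positions per mate).
    Positions are 0-based genome coordinates; error lists are
    comma-separated ``pos:base`` tokens (empty string when none).
    """

    molecules: pd.DataFrame
    reads: pd.DataFrame

    def write(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        self.molecules.to_csv(f"{prefix}.molecules.tsv", sep="\t", index=False)
        self.reads.to_csv(f"{prefix}.reads.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix: str | Path) -> "TruthTable":
        mol = pd.read_csv(f"{prefix}.molecules.tsv", sep="\t", keep_default_na=False)
        rds = pd.read_csv(f"{prefix}.reads.tsv", sep="\t", keep_default_na=False)
        return cls(mol, rds)


def make_reference(config: SynthConfig, rng: np.random.Generator | None = None):
    """Random reference sequence plus variant sites spaced >= read_length apart.

    Returns ``(sequence, sites)`` where ``sites`` is a DataFrame with
    columns ``pos, ref, alt``. Sites are kept at least one read length from
    either end so every site can be fully covered by a fragment.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    L, n, spacing = config.genome_length, config.n_variant_sites, config.read_length
    if L < 10 * config.fragment_size_mean:
        raise ValueError("genome_length must be >= 10x fragment_size_mean")
    seq = "".join(rng.choice(BASES, size=L))
    if n == 0:
        empty = pd.DataFrame({"chrom": pd.Series(dtype=str),
                              "pos": pd.Series(dtype=int),
                              "ref": pd.Series(dtype=str),
                              "alt": pd.Series(dtype=str)})
        return seq, empty
    lo, hi = spacing, L - spacing
    # sorted draws in a shrunken window, then re-inflate: guarantees spacing
    slack = (hi - lo) - (n - 1) * spacing
    if slack < 0:
        raise ValueError(
            f"cannot place {n} sites with spacing {spacing} in genome of {L} bp"
        )
    raw = np.sort(rng.choice(slack + 1, size=n, replace=False) if slack + 1 >= n
                  else np.zeros(n, dtype=int))
    pos = raw + lo + np.arange(n) * spacing
    ref = np.array([seq[p] for p in pos])
    alt = np.array([rng.choice(BASES[BASES != r]) for r in ref])
    return seq, pd.DataFrame({"chrom": "chr1", "pos": pos,
                              "ref": ref, "alt": alt})


def _inject(seq_arr: np.ndarray, rate: float, rng: np.random.Generator):
    """Substitute bases uniformly at ``rate``; returns (array, error positions/bases)."""
    hits = np.flatnonzero(rng.random(seq_arr.size) < rate)
    out = []
    for i in hits:
        new = rng.choice(BASES[BASES != seq_arr[i]])
        seq_arr[i] = new
        out.append((int(i), str(new)))
    return seq_arr, out


def _fmt_errors(errs, offset: int = 0) -> str:
    return ",".join(f"{p + offset}:{b}" for p, b in errs)


def simulate_library(config: SynthConfig, reference: str, sites: pd.DataFrame):
    """Draw molecules, amplify into duplicate families, emit paired reads.

    Fragment lengths are truncated-normal; a molecule covering one or more
    variant sites is tumor-derived with probability ``ctdna_fraction`` and
    then carries the alternate allele at every covered site. Each molecule
    founds a PCR family of geometric size (mean ``duplicate_rate_mean``);
    PCR errors hit the family template once, sequencer errors hit each read
    independently.

    Returns ``(reads, truth)`` where ``reads`` is a list of
    ``(read_id, seq1, qual1, seq2, qual2)`` and ``truth`` a `TruthTable`.
    """
    rng = np.random.default_rng(config.seed)
    L, rl = config.genome_length, config.read_length
    lo, hi = config.fragment_bounds
    site_pos = sites["pos"].to_numpy() if len(sites) else np.empty(0, dtype=int)
    site_alt = sites["alt"].to_numpy() if len(sites) else np.empty(0, dtype=str)

    mol_rows, read_rows, reads = [], [], []
    for m in range(config.n_molecules):
        # truncated-normal fragment length by rejection
        while True:
            flen = int(round(rng.normal(config.fragment_size_mean,
                                        config.fragment_size_sd)))
            if lo <= flen <= min(hi, L):
                break
        start = int(rng.integers(0, L - flen + 1))
        end = start + flen
        frag = np.array(list(reference[start:end]))

        covered = np.flatnonzero((site_pos >= start) & (site_pos < end))
        tumor = bool(covered.size and rng.random() < config.ctdna_fraction)
        if tumor:
            frag[site_pos[covered] - start] = site_alt[covered]

        fam = int(rng.geometric(1.0 / config.duplicate_rate_mean))
        frag, pcr_errs = _inject(frag, config.pcr_error_rate, rng)
        mol_rows.append({
            "molecule_id": m, "start": start, "end": end, "tumor": tumor,
            "family_size": fam, "pcr_errors": _fmt_errors(pcr_errs, start),
        })
        template = "".join(frag)
        for r in range(fam):
            rid = f"m{m}r{r}"
            r1 = np.array(list(template[:rl]))
            r2 = np.array(list(revcomp(template[-rl:] if flen >= rl else template)))
            r1, e1 = _inject(r1, config.seq_error_rate, rng)
            r2, e2 = _inject(r2, config.seq_error_rate, rng)
            # genome coords: mate1 forward from start, mate2 reverse from end
            # (mate-2 error bases complemented back to the forward strand)
            g1 = _fmt_errors(e1, start)
            g2 = ",".join(f"{end - 1 - p}:{b.translate(_COMP)}" for p, b in e2)
            q = [config.base_quality] * len(r1)
            reads.append((rid, "".join(r1), list(q), "".join(r2),
                          [config.base_quality] * len(r2)))
            read_rows.append({"read_id": rid, "molecule_id": m,
                              "seq_errors_r1": g1, "seq_errors_r2": g2})

    truth = TruthTable(pd.DataFrame(mol_rows), pd.DataFrame(read_rows))
    return reads, truth


def write_fastq_pair(reads, prefix: str | Path) -> tuple[Path, Path]:
    """Write the read list as a phred+33 FASTQ pair ``<prefix>_1/2.fastq``."""
    p1, p2 = Path(f"{prefix}_1.fastq"), Path(f"{prefix}_2.fastq")
    with open(p1, "w") as f1, open(p2, "w") as f2:
        for rid, s1, q1, s2, q2 in reads:
            f1.write(f"@{rid}\n{s1}\n+\n{phred_to_string(q1)}\n")
            f2.write(f"@{rid}\n{s2}\n+\n{phred_to_string(q2)}\n")
    return p1, p2


def truth_alignments(truth: TruthTable, reads, chrom: str = "chr1",
                     merged: bool = False) -> list[AlignedFragment]:
    """Place reads at their true coordinates, standing in for the aligner.

    ``merged=False`` expects the raw pair list from `simulate_library` and
    emits both mates as aligned fragments carrying mate outer coordinates;
    ``merged=True`` expects single-end records ``(read_id, seq, qual)``
    (e.g. from the overlap merger) and places each at its molecule's
    fragment start on the forward strand. Output is coordinate-sorted.
    """
    mol = truth.molecules.set_index("molecule_id")
    frags: list[AlignedFragment] = []
    if merged:
        for rid, seq, qual in reads:
            m = int(rid[1:].split("r")[0])
            start = int(mol.at[m, "start"])
            frags.append(AlignedFragment(
                id=rid, chrom=chrom, start=start, end=start + len(seq),
                strand="+", merged=True, seq=seq, qual=list(qual)))
    else:
        for rid, s1, q1, s2, q2 in reads:
            m = int(rid[1:].split("r")[0])
            start, end = int(mol.at[m, "start"]), int(mol.at[m, "end"])
            frags.append(AlignedFragment(
                id=rid, chrom=chrom, start=start, end=start + len(s1),
                strand="+", merged=False, seq=s1, qual=list(q1),
                mate_start=start, mate_end=end))
            frags.append(AlignedFragment(
                id=rid, chrom=chrom, start=end - len(s2), end=end,
                strand="-", merged=False, seq=revcomp(s2), qual=list(q2)[::-1],
                mate_start=start, mate_end=end))
    frags.sort(key=lambda f: (f.chrom, f.start, f.end, f.id))
    return frags


def write_alignments(truth: TruthTable, reads, path: str | Path,
                     chrom: str = "chr1", chrom_length: int | None = None,
                     merged: bool = False) -> Path:
    """Write coordinate-sorted SAM of reads placed at their true positions."""
    frags = truth_alignments(truth, reads, chrom=chrom, merged=merged)
    if chrom_length is None:
        chrom_length = max((f.end for f in frags), default=0) + 1
    return write_sam(frags, path, {chrom: chrom_length})
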