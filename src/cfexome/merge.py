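"""Overlap merging of paired-end reads with concordance quality boosting.

For short cfDNA fragments sequenced 2x100 bp the mates overlap; the
overlap is located by scanning alignment offsets of the
reverse-complemented second mate against the first. In the merged product,
concordant overlapping bases keep the base and sum the two phred scores
(capped at 45), discordant overlapping bases are masked to N with
quality 2. A base observed twice therefore carries a score no single read
can reach, which is what the downstream quality-cutoff filter exploits.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .io import read_fastq, write_fastq
from .synth import revcomp

MAX_MERGED_QUALITY = 45
DISCORDANT_QUALITY = 2


@dataclass
class ReadPair:
    id: str
    seq1: str
    qual1: list[int]
    seq2: str
    qual2: list[int]

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError("seq/qual length mismatch")


@dataclass
class MergedRead:
    id: str
    seq: str
    qual: list[int]
    merged: bool
    template_length: int


def find_overlap(pair: ReadPair, min_overlap: int = 15,
                 max_mismatch_rate: float = 0.1) -> int | None:
    """Offset of the reverse-complemented mate 2 against mate 1, or None.

    The offset is the position of mate 2's first base within the template
    implied by mate 1; the implied template length is ``offset + len2``.
    All offsets from full read-through (negative template shrink excluded:
    offsets range over [-(len2-min_overlap) .. len1-min_overlap]) are
    scanned; among acceptable offsets (overlap >= min_overlap, mismatch
    fraction <= max_mismatch_rate, N counting as mismatch) the one with the
    most matches wins, ties broken toward longer overlap (smaller offset).
    """
    if not pair.seq1 or not pair.seq2:
        raise ValueError("empty read")
    s1, s2 = pair.seq1, revcomp(pair.seq2)
    n1, n2 = len(s1), len(s2)
    best = None  # (matches, overlap, offset)
    for offset in range(-(n2 - min_overlap), n1 - min_overlap + 1):
        lo, hi = max(0, offset), min(n1, offset + n2)
        ov = hi - lo
        if ov < min_overlap:
            continue
        a, b = s1[lo:hi], s2[lo - offset:hi - offset]
        matches = sum(1 for x, y in zip(a, b)
                      if x == y and x != "N")
        if (ov - matches) > max_mismatch_rate * ov:
            continue
        cand = (matches, ov, -offset)
        if best is None or cand > best:
            best = cand
    return -best[2] if best else None


def merge_pair(pair: ReadPair, offset: int) -> MergedRead:
    """Collapse an overlapping pair at the accepted offset.

    Non-overlap bases are copied with their original quality; concordant
    overlap bases get quality min(q1+q2, 45); discordant (or N-containing)
    columns become N with quality 2. When the fragment is shorter than a
    read (negative offset, adapter read-through) the product is trimmed to
    the template.
    """
    s1, q1 = pair.seq1, pair.qual1
    s2, q2 = revcomp(pair.seq2), pair.qual2[::-1]
    n1, n2 = len(s1), len(s2)
    tlen = offset + n2
    if tlen < 1 or offset > n1:
        raise ValueError(f"offset {offset} out of range")
    # offset >= 0: template spans both reads; offset < 0: read-through,
    # trim the product to the template implied by mate 2's start
    length = max(n1, tlen) if offset >= 0 else tlen
    seq, qual = [], []
    for pos in range(length):
        in1 = pos < n1 and pos < length
        in2 = 0 <= pos - offset < n2
        if in1 and in2:
            b1, b2 = s1[pos], s2[pos - offset]
            if b1 == b2 and b1 != "N":
                seq.append(b1)
                qual.append(min(q1[pos] + q2[pos - offset], MAX_MERGED_QUALITY))
            else:
                seq.append("N")
                qual.append(DISCORDANT_QUALITY)
        elif in1:
            seq.append(s1[pos])
            qual.append(q1[pos])
        else:
            seq.append(s2[pos - offset])
            qual.append(q2[pos - offset])
    return MergedRead(pair.id, "".join(seq), qual, True, len(seq))


def merge_read_pairs(pairs, min_overlap: int = 15,
                     max_mismatch_rate: float = 0.1):
    """Merge an iterable of ReadPair; returns (merged list, unmerged list)."""
    merged, unmerged = [], []
    for p in pairs:
        off = find_overlap(p, min_overlap, max_mismatch_rate)
        if off is None:
            unmerged.append(p)
        else:
            merged.append(merge_pair(p, off))
    return merged, unmerged


def merge_fastq(fq1: str | Path, fq2: str | Path, out_prefix: str | Path,
                min_overlap: int = 15, max_mismatch_rate: float = 0.1):
    """File-level driver: merged reads to one FASTQ, leftover pairs to two."""
    pairs = [ReadPair(i1, s1, q1, s2, q2)
             for (i1, s1, q1), (_, s2, q2) in zip(read_fastq(fq1), read_fastq(fq2))]
    merged, unmerged = merge_read_pairs(pairs, min_overlap, max_mismatch_rate)
    write_fastq(((m.id, m.seq, m.qual) for m in merged),
                f"{out_prefix}.merged.fastq")
    write_fastq(((p.id, p.seq1, p.qual1) for p in unmerged),
                f"{out_prefix}.unmerged_1.fastq")
    write_fastq(((p.id, p.seq2, p.qual2) for p in unmerged),
                f"{out_prefix}.unmerged_2.fastq")
    return merged, unmerged
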