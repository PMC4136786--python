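"""Shared record types and SAM/FASTQ plumbing."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pysam

FAMILY_SIZE_TAG = "cD"  # family size on consensus reads
MERGED_TAG = "cM"       # 1 if the record is an overlap-merged single-end read


def phred_to_string(quals: Iterable[int]) -> str:
    return "".join(chr(q + 33) for q in quals)


def string_to_phred(s: str) -> list[int]:
    return [ord(c) - 33 for c in s]


@dataclass
class AlignedFragment:
    """A mapped read (merged single-end, or one mate of an unmerged pair).

    Coordinates are 0-based half-open. For unmerged mates, ``mate_start`` /
    ``mate_end`` hold the template's outer coordinates (leftmost start,
    rightmost end across both mates) so that pair-aware duplicate keys can
    be formed from either mate.
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str
    merged: bool
    seq: str
    qual: list[int]
    mate_start: int | None = None
    mate_end: int | None = None
    family_size: int = 1

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.seq):
            raise ValueError("fragment span must equal sequence length")
        if len(self.seq) != len(self.qual):
            raise ValueError("seq and qual lengths differ")
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")

    @property
    def template_length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """5' coordinate: leftmost base on +, rightmost base on -."""
        return self.start if self.strand == "+" else self.end - 1


def write_sam(fragments: Iterable[AlignedFragment], path: str | Path,
              chrom_lengths: dict[str, int]) -> Path:
    """Write fragments as a coordinate-sorted SAM file."""
    path = Path(path)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": n} for c, n in chrom_lengths.items()],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        tid = {c: i for i, c in enumerate(chrom_lengths)}
        for f in fragments:
            a = pysam.AlignedSegment()
            a.query_name = f.id
            a.query_sequence = f.seq
            a.query_qualities = pysam.qualitystring_to_array(
                phred_to_string(f.qual))
            a.reference_id = tid[f.chrom]
            a.reference_start = f.start
            a.cigarstring = f"{len(f.seq)}M"
            a.mapping_quality = 60
            a.flag = 16 if f.strand == "-" else 0
            a.set_tag(MERGED_TAG, 1 if f.merged else 0)
            a.set_tag(FAMILY_SIZE_TAG, f.family_size)
            if f.mate_start is not None and f.mate_end is not None:
                a.set_tag("ms", f.mate_start)
                a.set_tag("me", f.mate_end)
            out.write(a)
    return path


def read_sam(path: str | Path) -> Iterator[AlignedFragment]:
    """Stream a SAM/BAM file back into `AlignedFragment` records."""
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            if a.is_unmapped:
                raise ValueError(f"unaligned record {a.query_name}")
            yield AlignedFragment(
                id=a.query_name,
                chrom=a.reference_name,
                start=a.reference_start,
                end=a.reference_start + len(a.query_sequence),
                strand="-" if a.is_reverse else "+",
                merged=bool(a.get_tag(MERGED_TAG)) if a.has_tag(MERGED_TAG) else True,
                seq=a.query_sequence,
                qual=list(a.query_qualities),
                mate_start=a.get_tag("ms") if a.has_tag("ms") else None,
                mate_end=a.get_tag("me") if a.has_tag("me") else None,
                family_size=a.get_tag(FAMILY_SIZE_TAG) if a.has_tag(FAMILY_SIZE_TAG) else 1,
            )


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, list[int]]]:
    """Yield (id, seq, phred qualities) from a phred+33 FASTQ file."""
    with pysam.FastxFile(str(path)) as fh:
        for rec in fh:
            yield rec.name, rec.sequence, string_to_phred(rec.quality)


def write_fastq(records: Iterable[tuple[str, str, list[int]]],
                path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{phred_to_string(qual)}\n")
    return path
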