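"""Length-aware PCR-duplicate grouping and consensus calling.

Standard single-end duplicate marking keys reads on mapped start position
alone, which over-collapses cfDNA libraries: fragment sizes vary, so two
distinct starting molecules frequently share a 5' coordinate. Here merged
single-end reads are keyed on (chromosome, strand, 5' start, template
length), separating same-start molecules of different length; unmerged
pairs fall back to the usual both-ends key. Each family is collapsed to a
consensus read: a column keeps its base when at least 75% of family
members agree, with the supporters' phred scores summed (capped at 50);
otherwise the column is masked to N with quality 2. Boosted scores flag
multi-molecule support for downstream quality filtering — they are not
calling evidence weights.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .io import AlignedFragment

MAX_CONSENSUS_QUALITY = 50
MASKED_QUALITY = 2
CONSENSUS_AGREEMENT = 0.75


@dataclass(frozen=True)
class DuplicateKey:
    chrom: str
    strand: str
    five_prime: int
    template_length: int | None  # None for pair keys (both ends fix the span)
    mate_span: tuple[int, int] | None = None


def duplicate_key(frag: AlignedFragment, length_aware: bool = True) -> DuplicateKey:
    """Duplicate-family key for a fragment.

    Merged reads: (chrom, strand, 5' start, template length); with
    ``length_aware=False`` the length field is dropped, mimicking standard
    single-end duplicate marking. Unmerged mates are keyed on both outer
    coordinates plus orientation, as in ordinary paired dedup.
    """
    if frag.merged:
        return DuplicateKey(frag.chrom, frag.strand, frag.five_prime,
                            frag.template_length if length_aware else None)
    if frag.mate_start is None or frag.mate_end is None:
        raise ValueError(f"unmerged fragment {frag.id} lacks mate coordinates")
    return DuplicateKey(frag.chrom, frag.strand, frag.five_prime, None,
                        (frag.mate_start, frag.mate_end))


def group_duplicates(fragments: Iterable[AlignedFragment],
                     length_aware: bool = True
                     ) -> Iterator[list[AlignedFragment]]:
    """Stream duplicate families from coordinate-sorted fragments.

    Families sharing a key always share a leftmost start, so the buffer
    holds only fragments at the current (chrom, start) and memory stays
    bounded by the densest start position. Unsorted input raises.
    """
    buffer: dict[DuplicateKey, list[AlignedFragment]] = {}
    current: tuple[str, int] | None = None
    for f in fragments:
        pos = (f.chrom, f.start)
        if current is not None and pos < current:
            raise ValueError("input fragments are not coordinate-sorted")
        if pos != current:
            yield from buffer.values()
            buffer = {}
            current = pos
        buffer.setdefault(duplicate_key(f, length_aware), []).append(f)
    yield from buffer.values()


def consensus(family: list[AlignedFragment]) -> AlignedFragment:
    """Collapse one duplicate family into a consensus read.

    Per column: the modal base (N never counts as modal) is kept iff its
    frequency is at least 75% of the family size — inclusive, so 3 of 4
    passes — with quality equal to the summed scores of the reads carrying
    it, capped at 50. Any other column, including modal-base ties, is
    masked to N with quality 2. Singleton families pass through unchanged.
    """
    if not family:
        raise ValueError("empty family")
    first = family[0]
    if len(family) == 1:
        return first
    n = first.template_length
    if any(f.template_length != n for f in family):
        raise ValueError("mixed-length family violates the duplicate key")
    size = len(family)
    seq, qual, n_masked = [], [], 0
    for col in range(n):
        counts: dict[str, int] = {}
        qsums: dict[str, int] = {}
        for f in family:
            b = f.seq[col]
            if b == "N":
                continue
            counts[b] = counts.get(b, 0) + 1
            qsums[b] = qsums.get(b, 0) + f.qual[col]
        modal = max(counts, key=counts.get) if counts else None
        if modal is not None and counts[modal] >= CONSENSUS_AGREEMENT * size:
            seq.append(modal)
            qual.append(min(qsums[modal], MAX_CONSENSUS_QUALITY))
        else:
            seq.append("N")
            qual.append(MASKED_QUALITY)
            n_masked += 1
    out = AlignedFragment(
        id=f"{first.id}:fam{size}", chrom=first.chrom, start=first.start,
        end=first.end, strand=first.strand, merged=first.merged,
        seq="".join(seq), qual=qual, family_size=size)
    return out


def consensus_stream(fragments: Iterable[AlignedFragment]
                     ) -> Iterator[AlignedFragment]:
    """Length-aware grouping followed by per-family consensus."""
    for family in group_duplicates(fragments, length_aware=True):
        yield consensus(family)


def mark_only(fragments: Iterable[AlignedFragment], length_aware: bool = False
              ) -> Iterator[AlignedFragment]:
    """Keep one read per key without consensus (Picard-style dedup).

    Default key ignores template length (start-only), the behaviour of
    standard single-end duplicate removal; the first read of each family
    survives with qualities untouched.
    """
    for family in group_duplicates(fragments, length_aware=length_aware):
        yield family[0]
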