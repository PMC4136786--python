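"""Duplicate keys, family grouping, consensus rules, error suppression."""

from collections import Counter

import numpy as np
import pytest

from cfexome.io import AlignedFragment
from cfexome.dedup import (duplicate_key, group_duplicates, consensus,
                           consensus_stream, mark_only,
                           MAX_CONSENSUS_QUALITY, MASKED_QUALITY)
from cfexome.merge import ReadPair, merge_read_pairs
from cfexome.synth import truth_alignments


def frag(id="r", start=100, length=80, strand="+", chrom="chr1",
         seq=None, qual=None, merged=True):
    seq = seq or "A" * length
    qual = qual or [30] * length
    return AlignedFragment(id=id, chrom=chrom, start=start,
                           end=start + length, strand=strand, merged=merged,
                           seq=seq, qual=qual)


class TestDuplicateKey:
    def test_length_distinguishes_same_start_molecules(self):
        a, b = frag(length=166), frag(length=180)
        assert duplicate_key(a) != duplicate_key(b)
        assert duplicate_key(a, length_aware=False) == \
            duplicate_key(b, length_aware=False)

    def test_identical_coordinates_share_key(self):
        assert duplicate_key(frag(id="x")) == duplicate_key(frag(id="y"))

    def test_minus_strand_keys_on_rightmost_base(self):
        a = frag(start=100, length=80, strand="-")
        b = frag(start=120, length=60, strand="-")  # same 3' (left), same 5' end
        assert a.five_prime == b.five_prime == 179
        assert duplicate_key(a, length_aware=False) == \
            duplicate_key(b, length_aware=False)
        assert duplicate_key(a) != duplicate_key(b)

    def test_unmerged_pair_needs_mate_coordinates(self):
        f = frag(merged=False)
        with pytest.raises(ValueError):
            duplicate_key(f)


class TestGroupDuplicates:
    def test_small_family_structure(self):
        frags = [frag(id="a"), frag(id="b"), frag(id="c", start=500)]
        fams = sorted(len(f) for f in group_duplicates(iter(frags)))
        assert fams == [1, 2]

    def test_matches_bruteforce_key_hash(self, small_merged):
        _, _, frags = small_merged
        streamed = Counter(
            tuple(sorted(f.id for f in fam))
            for fam in group_duplicates(frags))
        brute: dict = {}
        for f in frags:
            brute.setdefault(duplicate_key(f), []).append(f.id)
        assert streamed == Counter(tuple(sorted(v)) for v in brute.values())

    def test_key_partition_equals_truth_families(self, clean_library,
                                                 clean_merged):
        """When no two molecules collide on (start, length), the key
        partition is exactly the generator's family partition."""
        _, _, _, reads, truth = clean_library
        _, _, frags = clean_merged
        mol = truth.molecules
        coords = list(zip(mol["start"], mol["end"]))
        colliding = {m for (s, e), m in zip(coords, mol["molecule_id"])
                     if Counter(coords)[(s, e)] > 1}
        truth_part = {}
        for f in frags:
            m = int(f.id[1:].split("r")[0])
            if m not in colliding:
                truth_part.setdefault(m, set()).add(f.id)
        key_part = {frozenset(f.id for f in fam)
                    for fam in group_duplicates(frags)}
        for fam_ids in truth_part.values():
            assert frozenset(fam_ids) in key_part

    def test_unsorted_input_rejected(self):
        frags = [frag(start=500), frag(start=100)]
        with pytest.raises(ValueError):
            list(group_duplicates(iter(frags)))

    def test_empty_input(self):
        assert list(group_duplicates(iter([]))) == []


class TestConsensus:
    def test_three_of_four_passes_inclusive_threshold(self):
        fam = [frag(id=i, length=1, seq=b, qual=[30])
               for i, b in zip("abcd", "AAAC")]
        c = consensus(fam)
        assert c.seq == "A"
        assert c.qual == [min(90, MAX_CONSENSUS_QUALITY)]
        assert c.family_size == 4

    def test_even_split_masked(self):
        fam = [frag(id=i, length=1, seq=b, qual=[40]) for i, b in zip("ab", "AC")]
        c = consensus(fam)
        assert c.seq == "N" and c.qual == [MASKED_QUALITY]

    def test_quality_sums_only_supporting_reads(self):
        fam = [frag(id=i, length=1, seq=b, qual=[q])
               for i, (b, q) in enumerate(zip("AAAC", [10, 11, 12, 40]))]
        assert consensus(fam).qual == [33]  # 10+11+12, C's 40 excluded

    def test_member_N_counts_to_size_not_modal(self):
        # 3 A's of 4 members (one N): 3 >= 0.75*4 passes
        fam = [frag(id=i, length=1, seq=b, qual=[20])
               for i, b in zip("abcd", "AAAN")]
        assert consensus(fam).seq == "A"
        # 2 A's of 3 members (one N): 2 < 0.75*3 fails
        fam = [frag(id=i, length=1, seq=b, qual=[20]) for i, b in zip("abc", "AAN")]
        assert consensus(fam).seq == "N"

    def test_singleton_passes_through_unchanged(self):
        f = frag(qual=[37] * 80)
        c = consensus([f])
        assert c.seq == f.seq and c.qual == f.qual and c.id == f.id

    def test_mixed_length_family_rejected(self):
        with pytest.raises(ValueError):
            consensus([frag(length=10), frag(length=12)])


class TestMarkOnly:
    def test_start_only_collapses_what_length_aware_keeps(self):
        frags = sorted([frag(id="a", length=166), frag(id="b", length=180)],
                       key=lambda f: f.start)
        assert len(list(mark_only(iter(frags)))) == 1
        assert len(list(mark_only(iter(frags), length_aware=True))) == 2

    def test_unique_starts_identity(self):
        frags = [frag(id="a", start=10), frag(id="b", start=200)]
        assert [f.id for f in mark_only(iter(frags))] == ["a", "b"]

    def test_length_aware_retains_at_least_start_only(self, small_merged):
        _, _, frags = small_merged
        n_start = len(list(mark_only(iter(frags))))
        n_aware = len(list(mark_only(iter(frags), length_aware=True)))
        # key refinement: always >=; variable cfDNA lengths make it strict
        assert n_aware > n_start


class TestErrorSuppression:
    def test_consensus_removes_read_level_but_not_family_errors(
            self, small_library, small_merged):
        """Sequencer errors vanish in families >=3 unless they reach 75%
        agreement; PCR (family-level) errors survive consensus."""
        cfg, ref, _, reads, truth = small_library
        _, _, frags = small_merged
        by_mol = {}
        for fam in group_duplicates(frags):
            m = int(fam[0].id[1:].split("r")[0])
            by_mol.setdefault(m, []).append((fam, consensus(fam)))
        mol = truth.molecules.set_index("molecule_id")
        pcr_checked = seq_removed = seq_total = 0
        for m, items in by_mol.items():
            if len(items) != 1:
                continue  # molecule collided with another key; skip
            fam, cons = items[0]
            start = int(mol.at[m, "start"])
            if cons.template_length != int(mol.at[m, "end"]) - start:
                continue
            # family-level PCR errors survive in the consensus base
            pcr = mol.at[m, "pcr_errors"]
            if isinstance(pcr, str) and pcr:
                for tok in pcr.split(","):
                    p, b = tok.split(":")
                    col = int(p) - start
                    if cons.seq[col] == b:
                        pcr_checked += 1
            # read-level errors: absent from consensus unless >=75% agree
            if len(fam) < 3:
                continue
            rd = truth.reads[truth.reads["molecule_id"] == m]
            for r in rd.itertuples():
                for errs in (r.seq_errors_r1, r.seq_errors_r2):
                    if not errs:
                        continue
                    for tok in errs.split(","):
                        p, b = tok.split(":")
                        col = int(p) - start
                        if not 0 <= col < cons.template_length:
                            continue
                        carriers = sum(1 for f in fam if f.seq[col] == b)
                        seq_total += 1
                        if carriers < 0.75 * len(fam):
                            assert cons.seq[col] != b
                            seq_removed += 1
        assert pcr_checked > 0
        assert seq_total > 0 and seq_removed / seq_total > 0.9

    def test_n_masked_counts_low_agreement_columns(self):
        fam = [frag(id=i, length=3, seq=s, qual=[30] * 3)
               for i, s in zip("ab", ["ACG", "ATG"])]
        c = consensus(fam)
        assert c.seq == "ANG"
        assert sum(1 for b in c.seq if b == "N") == 1
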