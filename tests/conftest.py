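import numpy as np
import pytest

from cfexome.merge import ReadPair, merge_read_pairs
from cfexome.synth import (SynthConfig, make_reference, simulate_library,
                           truth_alignments)


def merge_and_align(reads, truth):
    """Merge a synthetic read list and place the products at true coords."""
    pairs = [ReadPair(r, s1, q1, s2, q2) for r, s1, q1, s2, q2 in reads]
    merged, unmerged = merge_read_pairs(pairs)
    frags = truth_alignments(truth, [(m.id, m.seq, m.qual) for m in merged],
                             merged=True)
    return merged, unmerged, frags


@pytest.fixture(scope="session")
def small_library():
    """A small spiked library with full truth, shared across tests."""
    cfg = SynthConfig(genome_length=30_000, n_variant_sites=10,
                      ctdna_fraction=0.05, n_molecules=400,
                      duplicate_rate_mean=3.0, seed=7)
    ref, sites = make_reference(cfg)
    reads, truth = simulate_library(cfg, ref, sites)
    return cfg, ref, sites, reads, truth


@pytest.fixture(scope="session")
def small_merged(small_library):
    _, _, _, reads, truth = small_library
    return merge_and_align(reads, truth)


@pytest.fixture(scope="session")
def clean_library():
    """Error-free library: exact geometry checks (merging, dedup truth)."""
    cfg = SynthConfig(genome_length=30_000, n_variant_sites=8,
                      ctdna_fraction=0.1, n_molecules=300,
                      seq_error_rate=0.0, pcr_error_rate=0.0,
                      duplicate_rate_mean=2.0, seed=11)
    ref, sites = make_reference(cfg)
    reads, truth = simulate_library(cfg, ref, sites)
    return cfg, ref, sites, reads, truth


@pytest.fixture(scope="session")
def clean_merged(clean_library):
    _, _, _, reads, truth = clean_library
    return merge_and_align(reads, truth)


@pytest.fixture(scope="session")
def noisy_pipelines():
    """A tumor-free library with an elevated error rate processed three
    ways: raw mates, merged reads, duplicate consensus. The high error
    rate gives noise-rate comparisons enough events to be stable."""
    from cfexome.dedup import consensus_stream
    cfg = SynthConfig(genome_length=15_000, n_variant_sites=40,
                      ctdna_fraction=0.0, fragment_size_mean=140,
                      fragment_size_sd=20, seq_error_rate=0.02,
                      pcr_error_rate=1e-4, duplicate_rate_mean=3.0,
                      n_molecules=2000, seed=21)
    ref, sites = make_reference(cfg)
    reads, truth = simulate_library(cfg, ref, sites)
    raw = truth_alignments(truth, reads, merged=False)
    _, _, merged_frags = merge_and_align(reads, truth)
    cons = sorted(consensus_stream(merged_frags),
                  key=lambda f: (f.chrom, f.start))
    return sites, raw, merged_frags, cons
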