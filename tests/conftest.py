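"""Shared fixtures: a tiny synthetic genome (2 x 100 kb) with tags, built
once per session. All fixtures are generated programmatically."""

import numpy as np
import pytest

from chipscape import gc as gcmod
from chipscape import synth
from chipscape.tracks import (count_fragments, extend_tags,
                              normalize_per_million, smooth)

TINY_REPEATS = [("LTR", 5, 400, 0.58), ("satellite", 5, 500, 0.35)]


@pytest.fixture(scope="session")
def tiny_config():
    return synth.SyntheticGenomeConfig(
        n_chroms=2, chrom_length=100_000, n_genes=10, n_icrs=2,
        n_snps_per_icr=5, repeat_spec=list(TINY_REPEATS), seed=42)


@pytest.fixture(scope="session")
def tiny_genome(tiny_config):
    return synth.build_genome(tiny_config)


@pytest.fixture(scope="session")
def tiny_gc(tiny_genome):
    haps, _ = tiny_genome
    return gcmod.gc_track(haps["maternal"], 100)


@pytest.fixture(scope="session")
def tiny_field(tiny_genome, tiny_gc):
    _, truth = tiny_genome
    return synth.build_enrichment_field(truth, tiny_gc)


@pytest.fixture(scope="session")
def tiny_tags(tiny_genome, tiny_field):
    _, truth = tiny_genome
    return synth.simulate_tags(truth, tiny_field, 20_000, 20_000, seed=7)


@pytest.fixture(scope="session")
def tiny_tracks(tiny_genome, tiny_tags):
    """Raw, per-million and smoothed tracks for the tiny ChIP/input pair."""
    _, truth = tiny_genome
    chip, inp = tiny_tags
    out = {}
    for label, tags in [("chip", chip), ("input", inp)]:
        frags = extend_tags(tags, 200, truth.chrom_lengths)
        raw = count_fragments(frags, 100, truth.chrom_lengths, label)
        pm = normalize_per_million(raw)
        out[label] = {"raw": raw, "pm": pm, "smooth": smooth(pm, 2)}
    return out


def uniform_count_track(truth, n_tags, seed, window_size=100):
    """Poisson-free multinomial uniform library, counted on the grid."""
    field = synth.uniform_field(truth, window_size)
    chip, _ = synth.simulate_tags(truth, field, n_tags, 1, seed=seed)
    frags = extend_tags(chip, 200, truth.chrom_lengths)
    return count_fragments(frags, window_size, truth.chrom_lengths, f"u{seed}")
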