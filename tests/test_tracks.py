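"""Window-track operations: extension, counting, normalization, smoothing,
enrichment — spec'd examples plus conservation/scale-invariance properties."""

import numpy as np
import pandas as pd
import pytest

from chipscape.tracks import (EmptyLibraryError, IncompatibleTracksError,
                              WindowTrack, count_fragments,
                              enrichment_over_input, extend_tags,
                              normalize_per_million, smooth)

CHROMS = {"chr1": 2000}


def tag_df(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "length", "strand",
                                       "hap", "snps"])


@pytest.mark.parametrize("strand,start,expected", [
    ("+", 1000, (1000, 1200)),
    ("-", 1000, (850, 1050)),
])
def test_extend_tags_follows_strand(strand, start, expected):
    tags = tag_df([("chr1", start, 50, strand, "M", "")])
    frags = extend_tags(tags, 200, CHROMS)
    assert (frags["start"].iloc[0], frags["end"].iloc[0]) == expected


def test_extend_tags_clips_at_chromosome_bounds():
    tags = tag_df([("chr1", 0, 50, "+", "M", "")])
    frags = extend_tags(tags, 200, {"chr1": 100})
    assert (frags["start"].iloc[0], frags["end"].iloc[0]) == (0, 100)


def test_count_fragments_overlap_rule():
    frags = pd.DataFrame({"chrom": ["chr1"], "start": [1000], "end": [1200]})
    track = count_fragments(frags, 100, CHROMS)
    v = track.values["chr1"]
    assert v[10] == 1 and v[11] == 1 and v.sum() == 2

    frags = pd.DataFrame({"chrom": ["chr1"], "start": [950], "end": [1150]})
    v = count_fragments(frags, 100, CHROMS).values["chr1"]
    assert v[9] == 1 and v[10] == 1 and v[11] == 1 and v.sum() == 3


def test_count_fragments_empty_and_conservation():
    empty = count_fragments(pd.DataFrame({"chrom": [], "start": [], "end": []}),
                            100, CHROMS)
    assert empty.values["chr1"].sum() == 0

    rng = np.random.default_rng(1)
    starts = rng.integers(0, 1800, size=200)
    frags = pd.DataFrame({"chrom": "chr1", "start": starts, "end": starts + 150})
    track = count_fragments(frags, 100, CHROMS)
    windows_per_frag = (frags["end"] - 1) // 100 - frags["start"] // 100 + 1
    assert track.values["chr1"].sum() == windows_per_frag.sum()


def test_normalize_per_million():
    tr = WindowTrack(100, {"chr1": np.array([4.0, 0.0])}, total_tags=200_000)
    pm = normalize_per_million(tr)
    assert pm.values["chr1"][0] == pytest.approx(20.0)
    # a library of exactly 1e6 tags is unchanged
    tr = WindowTrack(100, {"chr1": np.array([4.0])}, total_tags=1_000_000)
    assert normalize_per_million(tr).values["chr1"][0] == pytest.approx(4.0)
    # duplicating every tag leaves the normalized track identical
    tr2 = WindowTrack(100, {"chr1": np.array([8.0])}, total_tags=2_000_000)
    assert normalize_per_million(tr2).values["chr1"][0] == pytest.approx(4.0)
    with pytest.raises(EmptyLibraryError):
        normalize_per_million(WindowTrack(100, {"chr1": np.zeros(1)},
                                          total_tags=0))


def test_smooth_examples_and_mean_preservation():
    tr = WindowTrack(100, {"chr1": np.array([0.0, 3.0, 0.0])})
    assert smooth(tr, 0).values["chr1"] == pytest.approx([0, 3, 0])
    assert smooth(tr, 1).values["chr1"] == pytest.approx([1.5, 1.0, 1.5])
    const = WindowTrack(100, {"chr1": np.full(50, 7.0)})
    assert smooth(const, 3).values["chr1"] == pytest.approx(np.full(50, 7.0))
    rng = np.random.default_rng(2)
    tr = WindowTrack(100, {"chr1": rng.poisson(10, 5000).astype(float)})
    sm = smooth(tr, 2)
    assert sm.values["chr1"].mean() == pytest.approx(
        tr.values["chr1"].mean(), rel=0.01)


def test_enrichment_over_input():
    chip = WindowTrack(100, {"chr1": np.array([9.0, 5.0])}, units="per_million")
    inp = WindowTrack(100, {"chr1": np.array([2.0, 5.0])}, units="per_million")
    enr = enrichment_over_input(chip, inp, pseudocount=1.0)
    assert enr.values["chr1"][0] == pytest.approx(10 / 3)
    assert enr.values["chr1"][1] == pytest.approx(1.0)
    log = enrichment_over_input(chip, chip, pseudocount=1.0, log2=True)
    assert log.values["chr1"] == pytest.approx([0.0, 0.0])
    with pytest.raises(IncompatibleTracksError):
        enrichment_over_input(chip, WindowTrack(50, {"chr1": np.zeros(2)}))


def test_enrichment_scale_invariance_under_library_duplication():
    rng = np.random.default_rng(3)
    raw_c = rng.poisson(8, 100).astype(float)
    raw_i = rng.poisson(8, 100).astype(float)
    one = enrichment_over_input(
        normalize_per_million(WindowTrack(100, {"c": raw_c}, total_tags=10_000)),
        normalize_per_million(WindowTrack(100, {"c": raw_i}, total_tags=10_000)))
    dup = enrichment_over_input(
        normalize_per_million(WindowTrack(100, {"c": 3 * raw_c}, total_tags=30_000)),
        normalize_per_million(WindowTrack(100, {"c": 3 * raw_i}, total_tags=30_000)))
    assert dup.values["c"] == pytest.approx(one.values["c"])
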