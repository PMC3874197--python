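"""Peak-caller checks: lambda arithmetic, brute-force scan equivalence,
planted-block detection, merge rules, and Venn comparison."""

import numpy as np
import pytest

from chipscape.intervals import GenomicInterval
from chipscape.peaks import (Peak, PeakCallConfig, call_peaks,
                             compare_peak_sets, local_lambda,
                             significant_windows)
from chipscape.stats import poisson_upper_tail
from chipscape.tracks import WindowTrack


def track(values, window_size=100, total=None, label=""):
    return WindowTrack(window_size, {"chr1": np.asarray(values, dtype=float)},
                       sample_label=label, total_tags=total)


def test_local_lambda_uniform_input_equals_genome_mean():
    tr = track(np.full(500, 12.0))
    cfg = PeakCallConfig()
    assert local_lambda(tr, "chr1", 25_000, cfg) == pytest.approx(12.0)


def test_local_lambda_takes_maximum_over_spans():
    v = np.full(500, 2.0)
    v[240:260] = 50.0  # local spike raises lambda near it
    tr = track(v)
    cfg = PeakCallConfig()
    near = local_lambda(tr, "chr1", 25_000, cfg)
    far = local_lambda(tr, "chr1", 1_000, cfg)
    mean = v.mean()
    assert near > mean
    assert far == pytest.approx(mean)


def test_local_lambda_hand_built_three_windows():
    tr = track([0.0, 30.0, 0.0])
    cfg = PeakCallConfig(local_windows=(300,))
    # local mean over all 3 windows = 10 = genome mean
    assert local_lambda(tr, "chr1", 150, cfg) == pytest.approx(10.0)
    with pytest.raises(IndexError):
        local_lambda(tr, "chr1", 10_000, cfg)


def test_matched_uniform_tracks_produce_no_peaks():
    rng = np.random.default_rng(4)
    chip = track(rng.poisson(10, 2000).astype(float), total=20_000)
    inp = track(rng.poisson(10, 2000).astype(float), total=20_000)
    assert call_peaks(chip, inp) == []


def test_planted_tenfold_block_yields_one_peak_with_summit_inside():
    rng = np.random.default_rng(5)
    base = rng.poisson(10, 2000).astype(float)
    chip_v = base.copy()
    chip_v[1000:1010] = rng.poisson(100, 10)  # 1-kb block, 10-fold
    chip = track(chip_v, total=int(chip_v.sum()))
    inp = track(rng.poisson(10, 2000).astype(float), total=int(chip_v.sum()))
    peaks = call_peaks(chip, inp)
    assert len(peaks) == 1
    pk = peaks[0]
    assert 100_000 <= pk.summit < 101_000
    assert pk.interval.start <= pk.summit < pk.interval.end
    assert pk.fold_enrichment > 1
    assert 0 < pk.p_value < 1e-5


def test_merge_gap_rule_controls_peak_count():
    base = np.full(2000, 10.0)
    near, far = base.copy(), base.copy()
    # blocks separated by exactly one window (100 bp gap = merge_gap): merged
    near[1000:1005] = 200.0
    near[1006:1011] = 200.0
    # blocks separated by 300 bp: distinct
    far[1000:1005] = 200.0
    far[1008:1013] = 200.0
    inp = track(np.full(2000, 10.0), total=20_000)
    assert len(call_peaks(track(near, total=20_000), inp)) == 1
    assert len(call_peaks(track(far, total=20_000), inp)) == 2


def brute_force_candidates(chip, inp, cfg):
    """Independent per-window scan: direct mean computations, direct tail."""
    chip_v = chip.values["chr1"]
    inp_v = inp.values["chr1"] * (chip.total_tags / inp.total_tags)
    background = inp_v.mean()
    w = cfg.window_size
    out = []
    for i in range(len(chip_v)):
        lam = background
        for span in cfg.local_windows:
            k = span // w
            if k % 2 == 0:
                k += 1
            lo, hi = max(0, i - k // 2), min(len(inp_v), i + k // 2 + 1)
            lam = max(lam, inp_v[lo:hi].mean())
        p = poisson_upper_tail(int(round(chip_v[i])), max(lam, 1e-9))
        if p < cfg.p_threshold:
            out.append(i)
    return np.array(out, dtype=int)


def test_candidate_windows_match_brute_force_scan():
    cfg = PeakCallConfig()
    for seed in range(3):
        rng = np.random.default_rng(seed)
        chip_v = rng.poisson(8, 1000).astype(float)
        chip_v[rng.integers(0, 990):][:8] += rng.poisson(60, 8)
        inp_v = rng.poisson(8, 1000).astype(float)
        chip = track(chip_v, total=int(chip_v.sum()))
        inp = track(inp_v, total=int(inp_v.sum()))
        got = np.flatnonzero(significant_windows(chip, inp, cfg)["chr1"])
        expected = brute_force_candidates(chip, inp, cfg)
        assert np.array_equal(got, expected)


def mk_peak(chrom, start, end):
    return Peak(GenomicInterval(chrom, start, end), (start + end) // 2,
                10, 1, 1e-9, 10)


def test_compare_peak_sets_venn_rules():
    a = [mk_peak("chr1", 100, 200), mk_peak("chr1", 1000, 1100)]
    b = [mk_peak("chr1", 199, 300), mk_peak("chr2", 0, 50)]
    res = compare_peak_sets(a, b)
    assert res == {"a_only": 1, "b_only": 1, "common_a": 1, "common_b": 1}
    same = compare_peak_sets(a, a)
    assert same["common_a"] == same["common_b"] == 2
    assert same["a_only"] == same["b_only"] == 0
    assert compare_peak_sets(a, [])["common_a"] == 0
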