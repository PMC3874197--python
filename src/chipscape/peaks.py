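"""Local-Poisson peak calling on window tracks.

A deliberately transparent variant of the classic ChIP-seq local-Poisson
test: the candidate unit is the fixed 100-bp analysis window, the background
expectation (lambda_local) is the maximum of the genome-wide mean and
centered local means (1/5/10 kb spans by default) computed from the input
library rescaled to ChIP depth, and windows with an upper-tail Poisson
probability below the threshold are merged into peaks. Fragment extension
is fixed (no fragment-shift model) and no duplicate filtering is applied;
the statistical core — max-of-local-lambdas Poisson scoring at P < 1e-5 —
is preserved and oracle-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .intervals import GenomicInterval, build_trees, query_overlaps
from .stats import poisson_upper_tail, poisson_upper_tail_vec
from .tracks import WindowTrack


@dataclass
class Peak:
    interval: GenomicInterval
    summit: int
    chip_count: float
    lambda_local: float
    p_value: float
    fold_enrichment: float


@dataclass
class PeakCallConfig:
    p_threshold: float = 1e-5
    window_size: int = 100
    merge_gap: int = 100
    local_windows: Tuple[int, ...] = (1000, 5000, 10000)

    def validate(self) -> None:
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must be in (0,1)")
        for span in self.local_windows:
            if span % self.window_size != 0:
                raise ValueError(
                    f"local window span {span} not a multiple of window_size")


def _centered_mean(v: np.ndarray, k_windows: int) -> np.ndarray:
    """Truncated centered moving average over an odd number of windows."""
    k = k_windows + (1 - k_windows % 2)  # force odd for symmetry
    kernel = np.ones(k)
    sums = np.convolve(v, kernel, mode="same")
    counts = np.convolve(np.ones_like(v), kernel, mode="same")
    return sums / counts


def _lambda_track(input_track: WindowTrack, config: PeakCallConfig,
                  scale: float) -> Dict[str, np.ndarray]:
    """Per-window expected ChIP fragments under the background model."""
    scaled = {c: v * scale for c, v in input_track.values.items()}
    background = float(np.concatenate(list(scaled.values())).mean())
    lam = {}
    for chrom, v in scaled.items():
        best = np.full_like(v, background)
        for span in config.local_windows:
            best = np.maximum(best, _centered_mean(v, span // config.window_size))
        lam[chrom] = np.maximum(best, 1e-9)
    return lam


def local_lambda(input_track: WindowTrack, chrom: str, position: int,
                 config: PeakCallConfig = PeakCallConfig(),
                 scale: float = 1.0) -> float:
    """Expected background count for the window containing `position`.

    max(genome-wide mean, centered 1/5/10-kb local means) of the input track
    scaled by `scale` (the ChIP/input depth ratio).
    """
    if chrom not in input_track.values:
        raise KeyError(f"unknown chromosome {chrom!r}")
    widx = position // input_track.window_size
    if not 0 <= widx < len(input_track.values[chrom]):
        raise IndexError(f"position {position} outside {chrom}")
    lam = _lambda_track(input_track, config, scale)
    return float(lam[chrom][widx])


def significant_windows(chip: WindowTrack, input_track: WindowTrack,
                        config: PeakCallConfig = PeakCallConfig()
                        ) -> Dict[str, np.ndarray]:
    """Boolean per-window significance mask (the pre-merge candidate set)."""
    chip.require_same_grid(input_track)
    config.validate()
    scale = _depth_scale(chip, input_track)
    lam = _lambda_track(input_track, config, scale)
    out = {}
    for chrom, counts in chip.values.items():
        p = poisson_upper_tail_vec(np.round(counts).astype(np.int64), lam[chrom])
        out[chrom] = p < config.p_threshold
    return out


def _depth_scale(chip: WindowTrack, input_track: WindowTrack) -> float:
    chip_total = chip.total_tags or float(np.concatenate(
        list(chip.values.values())).sum())
    inp_total = input_track.total_tags or float(np.concatenate(
        list(input_track.values.values())).sum())
    if not inp_total:
        raise ValueError("input library is empty")
    return chip_total / inp_total


def call_peaks(chip: WindowTrack, input_track: WindowTrack,
               config: PeakCallConfig = PeakCallConfig()) -> List[Peak]:
    """Call peaks: score every window, threshold, merge nearby candidates.

    Candidate windows separated by at most `merge_gap` bp are merged; the
    summit is the center of the candidate window with maximal ChIP count
    (leftmost on ties); the peak p-value is the minimum window p; chip_count
    and lambda_local are sums over the merged candidate windows.
    """
    chip.require_same_grid(input_track)
    config.validate()
    w = config.window_size
    scale = _depth_scale(chip, input_track)
    lam = _lambda_track(input_track, config, scale)
    peaks: List[Peak] = []
    for chrom, counts in chip.values.items():
        icounts = np.round(counts).astype(np.int64)
        p = poisson_upper_tail_vec(icounts, lam[chrom])
        cand = np.flatnonzero(p < config.p_threshold)
        if len(cand) == 0:
            continue
        # split candidate runs where the bp gap between windows > merge_gap
        gaps = (np.diff(cand) - 1) * w
        breaks = np.flatnonzero(gaps > config.merge_gap)
        bounds = np.concatenate([[0], breaks + 1, [len(cand)]])
        for bi in range(len(bounds) - 1):
            run = cand[bounds[bi]:bounds[bi + 1]]
            first, last = int(run[0]), int(run[-1])
            run_counts = icounts[run]
            best = run[int(np.argmax(run_counts))]  # argmax is leftmost on ties
            summit = int(best) * w + w // 2
            chip_count = float(run_counts.sum())
            lam_sum = float(lam[chrom][run].sum())
            peaks.append(Peak(
                interval=GenomicInterval(chrom, first * w, (last + 1) * w),
                summit=summit,
                chip_count=chip_count,
                lambda_local=lam_sum,
                p_value=float(p[run].min()),
                fold_enrichment=chip_count / lam_sum,
            ))
    return peaks


def compare_peak_sets(peaks_a: Sequence[Peak], peaks_b: Sequence[Peak]
                      ) -> Dict[str, int]:
    """Venn-style comparison: a peak is common iff it overlaps (>= 1 bp) any
    peak of the other set; common peaks are counted once per set."""
    ivs_a = [p.interval for p in peaks_a]
    ivs_b = [p.interval for p in peaks_b]
    trees_a = build_trees(ivs_a)
    trees_b = build_trees(ivs_b)
    common_a = sum(1 for iv in ivs_a
                   if query_overlaps(trees_b, iv.chrom, iv.start, iv.end))
    common_b = sum(1 for iv in ivs_b
                   if query_overlaps(trees_a, iv.chrom, iv.start, iv.end))
    return {
        "a_only": len(ivs_a) - common_a,
        "b_only": len(ivs_b) - common_b,
        "common_a": common_a,
        "common_b": common_b,
    }
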