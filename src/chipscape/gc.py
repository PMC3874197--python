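"""Genome-wide G+C composition and enrichment stratified by G+C.

Non-overlapping windows (default 100 bp) are the stratification unit;
windows containing any N base are flagged unanalyzable (NaN) and excluded
from all downstream stratification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .stats import rank_sum_test
from .tracks import GC_FRACTION, WindowTrack


def _seq_to_array(sequence: str) -> np.ndarray:
    return np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")


def gc_track(sequences: Dict[str, str], window_size: int = 100) -> WindowTrack:
    """Per-window G+C fraction; windows containing N are NaN.

    The final partial window (if chromosome length is not a multiple of the
    window size) is scored over its actual length.
    """
    values = {}
    for chrom, seq in sequences.items():
        arr = _seq_to_array(seq)
        is_gc = (arr == b"G") | (arr == b"C")
        is_n = ~((arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T"))
        nw = -(-len(arr) // window_size)
        pad = nw * window_size - len(arr)
        gc_sum = np.add.reduceat(is_gc, np.arange(0, len(arr), window_size))
        n_sum = np.add.reduceat(is_n, np.arange(0, len(arr), window_size))
        lens = np.full(nw, window_size)
        if pad:
            lens[-1] = window_size - pad
        v = gc_sum / lens
        v[n_sum > 0] = np.nan
        values[chrom] = v
    return WindowTrack(window_size, values, GC_FRACTION, "gc")


def interval_gc(sequences: Dict[str, str], iv: GenomicInterval) -> float:
    """G+C fraction over a full interval (N bases excluded from both
    numerator and denominator)."""
    arr = _seq_to_array(sequences[iv.chrom][iv.start:iv.end])
    valid = (arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T")
    if valid.sum() == 0:
        return np.nan
    gc = ((arr == b"G") | (arr == b"C")).sum()
    return float(gc / valid.sum())


@dataclass
class GCStratification:
    """Enrichment summarized within G+C bins.

    ``table`` has one row per non-empty bin: bin_low, bin_high, n, mean,
    median. Empty bins are absent, not zero.
    """

    bin_edges: np.ndarray
    table: pd.DataFrame

    @property
    def n_windows(self) -> int:
        return int(self.table["n"].sum())


def enrichment_by_gc(enrichment: WindowTrack, gc: WindowTrack,
                     bin_width: float = 0.05) -> GCStratification:
    """Bucket windows by G+C and summarize enrichment per bucket.

    Windows unanalyzable (NaN) in either track are excluded.
    """
    enrichment.require_same_grid(gc)
    e = enrichment.all_values()
    g = gc.all_values()
    ok = np.isfinite(e) & np.isfinite(g)
    e, g = e[ok], g[ok]
    edges = np.arange(0.0, 1.0 + bin_width / 2, bin_width)
    if edges[-1] < 1.0:
        edges = np.append(edges, 1.0)
    idx = np.clip(np.digitize(g, edges) - 1, 0, len(edges) - 2)
    df = pd.DataFrame({"bin": idx, "e": e})
    agg = df.groupby("bin")["e"].agg(n="size", mean="mean", median="median")
    table = pd.DataFrame({
        "bin_low": edges[agg.index.to_numpy()],
        "bin_high": edges[agg.index.to_numpy() + 1],
        "n": agg["n"].to_numpy(),
        "mean": agg["mean"].to_numpy(),
        "median": agg["median"].to_numpy(),
    }).reset_index(drop=True)
    return GCStratification(bin_edges=edges, table=table)


def compare_group_gc(intervals_a: Sequence[GenomicInterval],
                     intervals_b: Sequence[GenomicInterval],
                     sequences: Dict[str, str]) -> Tuple[float, float, float]:
    """Compare the G+C composition of two interval groups.

    Returns (mean_gc_a, mean_gc_b, two-sided rank-sum p). The test is exact
    by enumeration for small pooled sizes (see :mod:`chipscape.stats`).
    """
    if len(intervals_a) == 0 or len(intervals_b) == 0:
        raise ValueError("both interval groups must be non-empty")
    gc_a = np.array([interval_gc(sequences, iv) for iv in intervals_a])
    gc_b = np.array([interval_gc(sequences, iv) for iv in intervals_b])
    p = rank_sum_test(gc_a, gc_b)
    return float(np.mean(gc_a)), float(np.mean(gc_b)), p
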