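"""Fixed-width window tracks: fragment extension, counting, normalization,
smoothing, and enrichment over input.

Tags are held in a pandas DataFrame with columns ``chrom, start, length,
strand, hap, snps`` (``hap``/``snps`` carry the simulator's haplotype payload
and may be empty for real data). Fragments are DataFrames with ``chrom,
start, end``. A :class:`WindowTrack` holds one float vector per chromosome
on a fixed grid of ``window_size`` bp windows; NaN marks windows excluded
from analysis (e.g. windows containing N bases in a G+C track).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np
import pandas as pd

TAG_COLUMNS = ["chrom", "start", "length", "strand", "hap", "snps"]

RAW_COUNT = "raw_count"
PER_MILLION = "per_million"
RATIO = "ratio"
LOG2_RATIO = "log2_ratio"
GC_FRACTION = "gc_fraction"


class IncompatibleTracksError(ValueError):
    """Two tracks are not on the same window grid."""


class EmptyLibraryError(ValueError):
    """Normalization requested for a library with zero tags."""


def n_windows(chrom_length: int, window_size: int) -> int:
    return -(-chrom_length // window_size)  # ceil division


@dataclass
class WindowTrack:
    """Per-chromosome numeric vectors on a fixed window grid."""

    window_size: int
    values: Dict[str, np.ndarray]
    units: str = RAW_COUNT
    sample_label: str = ""
    total_tags: Optional[int] = None

    def chroms(self) -> list:
        return list(self.values)

    def same_grid(self, other: "WindowTrack") -> bool:
        return (
            self.window_size == other.window_size
            and self.chroms() == other.chroms()
            and all(
                len(self.values[c]) == len(other.values[c]) for c in self.values
            )
        )

    def require_same_grid(self, other: "WindowTrack") -> None:
        if not self.same_grid(other):
            raise IncompatibleTracksError(
                f"window grids differ: {self.sample_label!r} vs {other.sample_label!r}"
            )

    def all_values(self) -> np.ndarray:
        """Genome-wide concatenation in chromosome order."""
        return np.concatenate([self.values[c] for c in self.values])

    def with_values(self, values: Dict[str, np.ndarray], units: str,
                    sample_label: Optional[str] = None) -> "WindowTrack":
        return WindowTrack(
            window_size=self.window_size,
            values=values,
            units=units,
            sample_label=self.sample_label if sample_label is None else sample_label,
            total_tags=self.total_tags,
        )


@dataclass
class EnrichmentTrack(WindowTrack):
    pseudocount: float = 1.0
    chip_label: str = ""
    input_label: str = ""


def empty_tags() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        TAG_COLUMNS, [str, np.int64, np.int64, str, str, str])})


def extend_tags(tags: pd.DataFrame, fragment_length: int,
                chrom_lengths: Dict[str, int]) -> pd.DataFrame:
    """Extend each tag to the estimated fragment size, MACS-style.

    A + strand tag at 5' position s becomes [s, s+fragment_length); a -
    strand tag whose read covers [s, s+len) becomes
    [s+len-fragment_length, s+len). Fragments are clipped to chromosome
    bounds.
    """
    if len(tags) == 0:
        return pd.DataFrame({"chrom": [], "start": [], "end": []})
    start = tags["start"].to_numpy()
    length = tags["length"].to_numpy()
    plus = (tags["strand"] == "+").to_numpy()
    frag_start = np.where(plus, start, start + length - fragment_length)
    frag_end = np.where(plus, start + fragment_length, start + length)
    lens = tags["chrom"].map(chrom_lengths).to_numpy()
    frag_start = np.clip(frag_start, 0, None)
    frag_end = np.minimum(frag_end, lens)
    return pd.DataFrame(
        {"chrom": tags["chrom"].to_numpy(), "start": frag_start, "end": frag_end}
    )


def count_fragments(fragments: pd.DataFrame, window_size: int,
                    chrom_lengths: Dict[str, int],
                    sample_label: str = "") -> WindowTrack:
    """Per-window count of fragments overlapping each window by >= 1 bp.

    Uses a difference array per chromosome: a fragment [s, e) overlaps
    windows s//w .. (e-1)//w inclusive.
    """
    values = {
        c: np.zeros(n_windows(length, window_size))
        for c, length in chrom_lengths.items()
    }
    total = int(len(fragments))
    for chrom, sub in fragments.groupby("chrom", sort=False):
        if chrom not in values:
            raise KeyError(f"fragment on unknown chromosome {chrom!r}")
        nw = len(values[chrom])
        first = sub["start"].to_numpy() // window_size
        last = (sub["end"].to_numpy() - 1) // window_size
        diff = np.zeros(nw + 1)
        np.add.at(diff, first, 1)
        np.add.at(diff, last + 1, -1)
        values[chrom] = np.cumsum(diff[:-1])
    return WindowTrack(window_size, values, RAW_COUNT, sample_label, total)


def normalize_per_million(track: WindowTrack) -> WindowTrack:
    """Scale values to tags-per-million for cross-library comparison."""
    if not track.total_tags:
        raise EmptyLibraryError("cannot normalize a library with zero tags")
    scale = 1e6 / track.total_tags
    values = {c: v * scale for c, v in track.values.items()}
    out = track.with_values(values, PER_MILLION)
    return out


def smooth(track: WindowTrack, half_width: int) -> WindowTrack:
    """Centered moving average over (2*half_width + 1) windows.

    Truncated at chromosome ends: the divisor is the number of windows
    actually inside the chromosome, so a constant track stays constant.
    """
    if half_width < 0:
        raise ValueError("half_width must be >= 0")
    if half_width == 0:
        return track.with_values(dict(track.values), track.units)
    kernel = np.ones(2 * half_width + 1)
    values = {}
    for chrom, v in track.values.items():
        sums = np.convolve(v, kernel, mode="same")
        counts = np.convolve(np.ones_like(v), kernel, mode="same")
        values[chrom] = sums / counts
    return track.with_values(values, track.units)


def enrichment_over_input(chip: WindowTrack, input_track: WindowTrack,
                          pseudocount: float = 1.0,
                          log2: bool = False) -> EnrichmentTrack:
    """Per-window (chip + pc) / (input + pc), both in per-million units."""
    chip.require_same_grid(input_track)
    values = {}
    for chrom in chip.values:
        ratio = (chip.values[chrom] + pseudocount) / (
            input_track.values[chrom] + pseudocount
        )
        values[chrom] = np.log2(ratio) if log2 else ratio
    return EnrichmentTrack(
        window_size=chip.window_size,
        values=values,
        units=LOG2_RATIO if log2 else RATIO,
        sample_label=f"{chip.sample_label}/{input_track.sample_label}",
        total_tags=chip.total_tags,
        pseudocount=pseudocount,
        chip_label=chip.sample_label,
        input_label=input_track.sample_label,
    )
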