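"""Cross-sample co-enrichment over shared 100-bp windows.

Joint window tables, hexagonal 2-D histograms with the display transforms
used for count-like signals (log10(1+x), asinh), Pearson correlation, and
multi-track correlation matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Dict, List, Sequence

import numpy as np
import pandas as pd

from .tracks import WindowTrack

TRANSFORMS: Dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "identity": lambda x: x,
    "log10_1p": lambda x: np.log10(1.0 + x),
    "asinh": np.arcsinh,
}


class UndefinedCorrelationError(ValueError):
    """Correlation undefined (fewer than two pairs or zero variance)."""


def get_transform(kind: str) -> Callable[[np.ndarray], np.ndarray]:
    if kind not in TRANSFORMS:
        raise ValueError(f"unknown transform {kind!r}; choose from {list(TRANSFORMS)}")
    return TRANSFORMS[kind]


def joint_window_table(track_a: WindowTrack, track_b: WindowTrack) -> pd.DataFrame:
    """One (a, b) value pair per window analyzable in both tracks, in
    genomic order."""
    track_a.require_same_grid(track_b)
    a = track_a.all_values()
    b = track_b.all_values()
    ok = np.isfinite(a) & np.isfinite(b)
    return pd.DataFrame({"a": a[ok], "b": b[ok]})


@dataclass
class HexbinGrid:
    """Pointy-top hexagonal 2-D histogram in transformed coordinates."""

    gridsize: int
    centers: np.ndarray  # (n_hex, 2)
    counts: np.ndarray   # (n_hex,)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def hexbin(pairs: pd.DataFrame, transform: str = "log10_1p",
           gridsize: int = 50) -> HexbinGrid:
    """Hexagonally bin transformed (a, b) pairs.

    A pointy-top tessellation with `gridsize` hexagons across the x-range is
    laid over the transformed bounding box (alternate rows offset by half a
    hexagon width); each point goes to its nearest hexagon center. The hex
    lattice is the union of two rectangular lattices, so nearest-center
    assignment reduces to rounding into each sublattice and taking the
    closer of the two candidates.
    """
    if gridsize < 1:
        raise ValueError("gridsize must be >= 1")
    if len(pairs) == 0:
        return HexbinGrid(gridsize, np.empty((0, 2)), np.empty(0, dtype=np.int64))
    f = get_transform(transform)
    x = f(pairs["a"].to_numpy(dtype=float))
    y = f(pairs["b"].to_numpy(dtype=float))
    xmin, xmax = float(x.min()), float(x.max())
    ymin, ymax = float(y.min()), float(y.max())
    dx = (xmax - xmin) / gridsize or 1.0  # hexagon width
    dy = dx * np.sqrt(3.0) / 2.0  # vertical row spacing = 1.5 * hexagon size
    # sublattice A: centers at (xmin + i*dx,        ymin + j*2*dy)
    # sublattice B: centers at (xmin + (i+0.5)*dx,  ymin + (j+0.5)*2*dy)
    # i.e. even rows unshifted, odd rows shifted by dx/2, rows dy apart
    ix_a = np.round((x - xmin) / dx)
    iy_a = np.round((y - ymin) / (2 * dy))
    ix_b = np.round((x - xmin) / dx - 0.5)
    iy_b = np.round((y - ymin) / (2 * dy) - 0.5)
    cx_a, cy_a = xmin + ix_a * dx, ymin + iy_a * 2 * dy
    cx_b, cy_b = xmin + (ix_b + 0.5) * dx, ymin + (iy_b + 0.5) * 2 * dy
    d_a = (x - cx_a) ** 2 + (y - cy_a) ** 2
    d_b = (x - cx_b) ** 2 + (y - cy_b) ** 2
    use_a = d_a <= d_b
    cx = np.where(use_a, cx_a, cx_b)
    cy = np.where(use_a, cy_a, cy_b)
    key = pd.DataFrame({"cx": np.round(cx, 9), "cy": np.round(cy, 9)})
    grouped = key.groupby(["cx", "cy"], sort=True).size().reset_index(name="n")
    centers = grouped[["cx", "cy"]].to_numpy()
    counts = grouped["n"].to_numpy()
    return HexbinGrid(gridsize, centers, counts)


def pearson_tracks(track_a: WindowTrack, track_b: WindowTrack,
                   transform: str = "log10_1p") -> float:
    """Pearson correlation of transformed per-window values."""
    pairs = joint_window_table(track_a, track_b)
    f = get_transform(transform)
    a = f(pairs["a"].to_numpy(dtype=float))
    b = f(pairs["b"].to_numpy(dtype=float))
    if len(a) < 2:
        raise UndefinedCorrelationError("need at least two shared windows")
    if np.std(a) == 0 or np.std(b) == 0:
        raise UndefinedCorrelationError("zero variance after transform")
    return float(np.corrcoef(a, b)[0, 1])


def correlation_matrix(tracks: Sequence[WindowTrack], labels: Sequence[str],
                       transform: str = "log10_1p") -> pd.DataFrame:
    """Symmetric matrix of pairwise Pearson r (pairwise-complete windows).

    Undefined cells (zero variance) are NaN; the diagonal is 1.
    """
    k = len(tracks)
    mat = np.full((k, k), np.nan)
    np.fill_diagonal(mat, 1.0)
    for i in range(k):
        for j in range(i + 1, k):
            try:
                r = pearson_tracks(tracks[i], tracks[j], transform)
            except UndefinedCorrelationError:
                r = np.nan
            mat[i, j] = mat[j, i] = r
    return pd.DataFrame(mat, index=list(labels), columns=list(labels))
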