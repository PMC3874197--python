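"""Anchor-centered profile matrices and clustering.

Rows are anchors (TSSs, CpG-island centers, peak summits), columns are
fixed-width bins spanning a symmetric flank around the anchor point. Minus-
strand anchors are flipped in oriented mode so column 0 is always the 5'
(upstream) side; interval anchors (CpG islands) are conventionally analyzed
non-oriented around their midpoints. Rows are grouped by enrichment level
for median profiles, or clustered with deterministic k-means for heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
from sklearn.cluster import KMeans

from .intervals import GenomicInterval
from .tracks import WindowTrack


@dataclass
class AnchorMatrix:
    anchors: List[GenomicInterval]
    flank: int
    bin: int
    values: np.ndarray  # anchors x bins; NaN marks out-of-genome bins
    oriented: bool = True
    cluster_labels: Optional[np.ndarray] = None

    @property
    def n_bins(self) -> int:
        return 2 * self.flank // self.bin


def anchor_point(iv: GenomicInterval) -> int:
    """Point anchor: TSS for stranded point/gene intervals, midpoint else."""
    if len(iv) <= 1:
        return iv.start
    if iv.strand == "+":
        return iv.start
    if iv.strand == "-":
        return iv.end - 1
    return iv.midpoint


def build_anchor_matrix(track: WindowTrack, anchors: Sequence[GenomicInterval],
                        flank: int = 5000, bin: int = 100,
                        oriented: bool = True) -> AnchorMatrix:
    """Extract per-anchor rows of track values in bins across +/- flank.

    Each bin's value is the mean of the track windows it covers; bins
    falling outside the chromosome are NaN (edge padding). With
    oriented=True, minus-strand anchor rows are reversed.
    """
    if flank % bin != 0:
        raise ValueError(f"bin {bin} must divide flank {flank}")
    if bin % track.window_size != 0:
        raise ValueError(
            f"bin {bin} must be a multiple of the track window size "
            f"{track.window_size}")
    wpb = bin // track.window_size
    n_bins = 2 * flank // bin
    rows = np.full((len(anchors), n_bins), np.nan)
    for ai, iv in enumerate(anchors):
        v = track.values.get(iv.chrom)
        if v is None:
            raise KeyError(f"anchor on unknown chromosome {iv.chrom!r}")
        point = anchor_point(iv)
        left = point - flank
        for bi in range(n_bins):
            bstart = left + bi * bin
            bend = bstart + bin
            if bstart < 0 or bend > len(v) * track.window_size:
                continue
            wfirst = bstart // track.window_size
            rows[ai, bi] = v[wfirst:wfirst + wpb].mean()
        if oriented and iv.strand == "-":
            rows[ai] = rows[ai, ::-1]
    return AnchorMatrix(anchors=list(anchors), flank=flank, bin=bin,
                        values=rows, oriented=oriented)


def group_anchors_by_enrichment(scores: Sequence[float], n_groups: int
                                ) -> np.ndarray:
    """Quantile groups of near-equal size; group 0 is the most enriched.

    Ties are broken by input (genomic) order, so the assignment is
    deterministic and stable across runs.
    """
    scores = np.asarray(scores, dtype=float)
    if n_groups < 1:
        raise ValueError("n_groups must be >= 1")
    if n_groups > len(scores):
        raise ValueError("n_groups exceeds anchor count")
    order = np.argsort(-scores, kind="stable")
    groups = np.empty(len(scores), dtype=np.int64)
    for gi, chunk in enumerate(np.array_split(order, n_groups)):
        groups[chunk] = gi
    return groups


def median_profile(matrix: AnchorMatrix,
                   rows: Optional[Sequence[int]] = None) -> np.ndarray:
    """Column-wise median over a row group, ignoring missing bins."""
    values = matrix.values if rows is None else matrix.values[list(rows)]
    if values.shape[0] == 0:
        raise ValueError("median profile of an empty group")
    with np.errstate(all="ignore"):
        return np.nanmedian(values, axis=0)


def cluster_rows(matrix: AnchorMatrix, k: int, seed: int = 0):
    """Deterministic k-means over rows.

    Missing bins are imputed as the row mean; centers are initialized by
    greedy farthest-point from a seeded start, then refined by Lloyd
    iterations; labels are relabeled by descending cluster mean signal so
    output is stable. Returns (labels, cluster_mean_profiles).
    """
    X = matrix.values.copy()
    n = X.shape[0]
    if k < 1 or k > n:
        raise ValueError(f"k must be in [1, {n}]")
    row_means = np.nanmean(np.where(np.isnan(X), np.nan, X), axis=1)
    row_means = np.nan_to_num(row_means)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(row_means, np.nonzero(nan_mask)[0])

    rng = np.random.default_rng(seed)
    centers = [X[int(rng.integers(n))]]
    for _ in range(1, k):
        d2 = np.min(
            [((X - c) ** 2).sum(axis=1) for c in centers], axis=0)
        centers.append(X[int(np.argmax(d2))])
    km = KMeans(n_clusters=k, init=np.array(centers), n_init=1,
                max_iter=300, random_state=0)
    raw_labels = km.fit_predict(X)

    order = np.argsort(-np.array(
        [X[raw_labels == c].mean() if np.any(raw_labels == c) else -np.inf
         for c in range(k)]), kind="stable")
    relabel = np.empty(k, dtype=np.int64)
    relabel[order] = np.arange(k)
    labels = relabel[raw_labels]
    profiles = np.vstack([
        X[labels == c].mean(axis=0) if np.any(labels == c)
        else np.full(X.shape[1], np.nan)
        for c in range(k)
    ])
    matrix.cluster_labels = labels
    return labels, profiles
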