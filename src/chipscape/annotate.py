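"""Sequence- and interval-based annotation.

CpG-island detection (G+C > 50%, length > 200 bp, observed/expected CpG
> 0.6), peak genomic localization against gene models, promoter marking
fractions, and per-repeat-class read accounting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, build_trees, query_overlaps

PROMOTER = "promoter"
GENE_BODY = "gene_body"
INTERGENIC = "intergenic"


@dataclass
class CpGIsland:
    interval: GenomicInterval
    gc_fraction: float
    obs_exp_cpg: float
    length: int


def _score_region(arr: np.ndarray) -> Tuple[float, float]:
    """(gc_fraction, obs/exp CpG) of a sequence array; obs/exp = CpG*L/(C*G)."""
    n_c = int((arr == b"C").sum())
    n_g = int((arr == b"G").sum())
    length = len(arr)
    gc = (n_c + n_g) / length
    n_cpg = int(((arr[:-1] == b"C") & (arr[1:] == b"G")).sum())
    oe = (n_cpg * length) / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    return gc, oe


def detect_cpg_islands(sequence: str, chrom: str = "", min_gc: float = 0.5,
                       min_len: int = 200, min_oe: float = 0.6,
                       window: int = 200, step: int = 1) -> List[CpGIsland]:
    """Sliding-window CpG-island detection.

    Windows of `window` bp slide at `step`; windows passing the G+C and
    observed/expected-CpG thresholds (and containing no N) seed islands;
    overlapping or adjacent passing windows are merged, the merged region is
    re-scored over its full span, and retained only if the merged region
    itself satisfies all three criteria (strict inequalities).
    """
    arr = np.frombuffer(sequence.upper().encode("ascii"), dtype="S1")
    length = len(arr)
    if length < window:
        return []
    is_c = (arr == b"C").astype(np.int64)
    is_g = (arr == b"G").astype(np.int64)
    is_n = (~((arr == b"A") | (arr == b"C") | (arr == b"G") | (arr == b"T"))
            ).astype(np.int64)
    is_cpg = np.zeros(length, dtype=np.int64)
    is_cpg[:-1] = (arr[:-1] == b"C") & (arr[1:] == b"G")

    cum = lambda x: np.concatenate([[0], np.cumsum(x)])
    cc, cg, cn, ccpg = cum(is_c), cum(is_g), cum(is_n), cum(is_cpg)
    starts = np.arange(0, length - window + 1, step)
    ends = starts + window
    n_c = cc[ends] - cc[starts]
    n_g = cg[ends] - cg[starts]
    n_n = cn[ends] - cn[starts]
    # CpG dinucleotides fully inside the window start at [start, end-1)
    n_cpg = ccpg[ends - 1] - ccpg[starts]
    with np.errstate(divide="ignore", invalid="ignore"):
        gc = (n_c + n_g) / window
        oe = np.where((n_c > 0) & (n_g > 0),
                      n_cpg * window / np.maximum(n_c * n_g, 1), 0.0)
    passing = (gc > min_gc) & (oe > min_oe) & (n_n == 0)
    idx = np.flatnonzero(passing)
    if len(idx) == 0:
        return []

    islands: List[CpGIsland] = []
    seed_starts = starts[idx]
    # merge passing windows whose spans overlap or touch
    breaks = np.flatnonzero(np.diff(seed_starts) > window)
    run_bounds = np.concatenate([[0], breaks + 1, [len(seed_starts)]])
    for i in range(len(run_bounds) - 1):
        first = int(seed_starts[run_bounds[i]])
        last = int(seed_starts[run_bounds[i + 1] - 1]) + window
        region = arr[first:last]
        r_gc, r_oe = _score_region(region)
        if r_gc > min_gc and (last - first) > min_len and r_oe > min_oe:
            islands.append(CpGIsland(
                interval=GenomicInterval(chrom, first, last),
                gc_fraction=r_gc, obs_exp_cpg=r_oe, length=last - first))
    return islands


def promoter_intervals(genes: Sequence[GenomicInterval],
                       promoter_window: int = 1000) -> List[GenomicInterval]:
    """TSS +/- promoter_window for each gene (clipped at zero)."""
    out = []
    for g in genes:
        tss = g.start if g.strand == "+" else g.end - 1
        out.append(GenomicInterval(g.chrom, max(0, tss - promoter_window),
                                   tss + promoter_window + 1, g.strand, g.name))
    return out


def classify_peak_locations(peaks: Sequence[GenomicInterval],
                            genes: Sequence[GenomicInterval],
                            promoter_window: int = 1000
                            ) -> Tuple[List[str], Dict[str, float]]:
    """Assign each peak to promoter / gene_body / intergenic (precedence in
    that order) and report class fractions."""
    prom_trees = build_trees(promoter_intervals(genes, promoter_window))
    gene_trees = build_trees(genes)
    classes = []
    for p in peaks:
        if query_overlaps(prom_trees, p.chrom, p.start, p.end):
            classes.append(PROMOTER)
        elif query_overlaps(gene_trees, p.chrom, p.start, p.end):
            classes.append(GENE_BODY)
        else:
            classes.append(INTERGENIC)
    n = max(len(classes), 1)
    fractions = {k: classes.count(k) / n
                 for k in (PROMOTER, GENE_BODY, INTERGENIC)}
    return classes, fractions


def promoter_marked_fraction(peaks: Sequence[GenomicInterval],
                             genes: Sequence[GenomicInterval],
                             promoter_window: int = 1000
                             ) -> Tuple[float, int, int]:
    """Fraction of promoters overlapped by at least one peak.

    Returns (fraction, n_marked_promoters, n_promoters); the numerator
    counts distinct promoters, not peaks.
    """
    if len(genes) == 0:
        raise ValueError("promoter fraction undefined with zero genes")
    peak_trees = build_trees(peaks)
    proms = promoter_intervals(genes, promoter_window)
    marked = sum(
        1 for pr in proms if query_overlaps(peak_trees, pr.chrom, pr.start, pr.end)
    )
    return marked / len(proms), marked, len(proms)


def _five_prime_positions(tags: pd.DataFrame) -> Tuple[np.ndarray, np.ndarray]:
    """5' reference position per tag: leftmost base for +, rightmost for -."""
    start = tags["start"].to_numpy()
    length = tags["length"].to_numpy()
    plus = (tags["strand"] == "+").to_numpy()
    return tags["chrom"].to_numpy(), np.where(plus, start, start + length - 1)


def _merge_sorted(ivs: Sequence[GenomicInterval]) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    per_chrom: Dict[str, list] = {}
    for iv in ivs:
        per_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, spans in per_chrom.items():
        spans.sort()
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        a = np.array(merged)
        out[chrom] = (a[:, 0], a[:, 1])
    return out


def _class_fraction(tags: pd.DataFrame, spans: Dict[str, Tuple[np.ndarray, np.ndarray]]) -> float:
    if len(tags) == 0:
        return 0.0
    chroms, pos = _five_prime_positions(tags)
    hits = 0
    for chrom, (starts, ends) in spans.items():
        m = chroms == chrom
        p = pos[m]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = idx >= 0
        hits += int((ok & (p < ends[np.clip(idx, 0, None)])).sum())
    return hits / len(tags)


def repeat_class_enrichment(chip_tags: pd.DataFrame, input_tags: pd.DataFrame,
                            repeat_intervals: Dict[str, Sequence[GenomicInterval]]
                            ) -> pd.DataFrame:
    """Per-repeat-class read accounting.

    A tag belongs to a class if its 5' position lies in a class interval.
    Classes are reported independently (a tag in two classes counts once in
    each). fraction = class tags / library size; ratio = chip_fraction /
    input_fraction, NaN when the input fraction is zero.
    """
    rows = []
    for cls, ivs in repeat_intervals.items():
        spans = _merge_sorted(ivs) if len(ivs) else {}
        cf = _class_fraction(chip_tags, spans)
        inf = _class_fraction(input_tags, spans)
        ratio = cf / inf if inf > 0 else np.nan
        rows.append((cls, cf, inf, ratio))
    return pd.DataFrame(rows, columns=["class", "chip_fraction",
                                       "input_fraction", "ratio"]).set_index("class")
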