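"""Synthetic diploid genome and ChIP/input tag simulator.

The generator emulates the statistical structure of an allele-specific
histone-mark ChIP-seq study on a diploid genome:

* a background genome of i.i.d. bases at a configurable G+C fraction,
* genes whose promoters carry planted CpG islands (G+C-rich, CpG-dense),
* imprinting-control-region (ICR) analogs: CpG-island-like loci carrying
  haplotype-distinguishing SNPs and a mono-allelic enrichment skew,
* repeat classes — G+C-richer LTR/LINE/SINE analogs that the G+C-driven
  enrichment field boosts, and low-G+C satellite analogs that it does not,
* a per-window relative enrichment field that is flat below a G+C breakpoint
  and rises monotonically above it,
* ChIP fragments sampled proportional to the field (midpoint model) and
  input fragments sampled uniformly, each reported as one sequenced tag.

Every run returns a :class:`SyntheticTruth` ground-truth record so each
downstream stage can be tested for recovery of what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .intervals import GenomicInterval
from .tracks import WindowTrack, n_windows

BASES = np.array(list("ACGT"))

#: repeat classes as (class_name, copy_count, unit_length, unit_gc)
DEFAULT_REPEAT_SPEC: List[Tuple[str, int, int, float]] = [
    ("LTR", 30, 400, 0.58),
    ("LINE", 30, 1000, 0.55),
    ("SINE", 60, 150, 0.56),
    ("satellite", 30, 500, 0.35),
]


class PlacementError(RuntimeError):
    """Requested features cannot be placed without overlap."""


@dataclass
class SyntheticGenomeConfig:
    """Parameters of the synthetic diploid genome.

    Defaults give 2 chromosomes x 1 Mb with 50 genes, 5 ICR analogs with 10
    SNPs each, and four repeat classes — a desk-scale genome that runs in
    minutes on one CPU.
    """

    n_chroms: int = 2
    chrom_length: int = 1_000_000
    background_gc: float = 0.40
    n_genes: int = 50
    gene_length: int = 2_000
    promoter_gc: float = 0.60
    cgi_length_range: Tuple[int, int] = (500, 1500)
    n_icrs: int = 5
    icr_length: int = 1_000
    n_snps_per_icr: int = 10
    repeat_spec: List[Tuple[str, int, int, float]] = dc_field(
        default_factory=lambda: list(DEFAULT_REPEAT_SPEC)
    )
    read_length: int = 50
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        fracs = {"background_gc": self.background_gc,
                 "promoter_gc": self.promoter_gc,
                 "error_rate": self.error_rate}
        for name, f in fracs.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {f}")
        for name, v in [("n_chroms", self.n_chroms),
                        ("chrom_length", self.chrom_length),
                        ("gene_length", self.gene_length),
                        ("icr_length", self.icr_length),
                        ("read_length", self.read_length)]:
            if v <= 0:
                raise ValueError(f"{name} must be > 0, got {v}")
        for name, v in [("n_genes", self.n_genes), ("n_icrs", self.n_icrs),
                        ("n_snps_per_icr", self.n_snps_per_icr)]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        lo, hi = self.cgi_length_range
        if not (200 < lo <= hi):
            raise ValueError(f"cgi_length_range must satisfy 200 < lo <= hi, got {lo, hi}")
        for cls, count, unit_len, unit_gc in self.repeat_spec:
            if count < 0 or unit_len <= 0 or not 0 <= unit_gc <= 1:
                raise ValueError(f"invalid repeat spec entry {cls!r}")


@dataclass
class EnrichmentField:
    """Per-window relative ChIP sampling weight plus per-ICR allelic skew.

    ``lambda_rel`` has mean 1 over all windows; ``allelic_fraction`` is the
    probability that an ICR-overlapping ChIP tag derives from the modified
    (maternal, by convention) haplotype.
    """

    window_size: int
    lambda_rel: Dict[str, np.ndarray]
    allelic_fraction: float = 0.9
    gc_breakpoint: float = 0.5
    max_fold: float = 8.0

    def validate(self) -> None:
        if not 0.5 <= self.allelic_fraction <= 1.0:
            raise ValueError("allelic_fraction must be in [0.5, 1.0]")
        for chrom, lam in self.lambda_rel.items():
            if np.any(lam < 0):
                raise ValueError(f"lambda_rel negative on {chrom}")

    def as_track(self) -> WindowTrack:
        return WindowTrack(self.window_size,
                           {c: v.copy() for c, v in self.lambda_rel.items()},
                           units="ratio", sample_label="lambda_rel")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for closed-loop testing."""

    config: SyntheticGenomeConfig
    chrom_lengths: Dict[str, int]
    genes: List[GenomicInterval]              # stranded, named
    features: Dict[str, List[GenomicInterval]]  # CGI, ICR, repeat classes
    snps: pd.DataFrame                        # chrom, pos (0-based), maternal, paternal
    field: Optional[EnrichmentField] = None

    @property
    def tss(self) -> List[GenomicInterval]:
        out = []
        for g in self.genes:
            pos = g.start if g.strand == "+" else g.end - 1
            out.append(GenomicInterval(g.chrom, pos, pos + 1, g.strand, g.name))
        return out


def _random_bases(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _cpg_island_sequence(rng: np.random.Generator, length: int, gc: float,
                         oe_target: float = 1.6) -> np.ndarray:
    """G+C-rich sequence with interleaved CpG dinucleotides.

    Enough CpGs are planted at even offsets to push observed/expected CpG to
    roughly ``oe_target``; the remaining positions are filled i.i.d. at an
    adjusted G+C so the overall composition hits ``gc``.
    """
    n_cpg = int(round(oe_target * gc * gc / 4.0 * length))
    n_cpg = min(n_cpg, length // 2)
    fill_len = length - 2 * n_cpg
    fill_gc = (gc * length - 2 * n_cpg) / fill_len if fill_len > 0 else 0.0
    fill_gc = min(max(fill_gc, 0.0), 1.0)
    seq = _random_bases(rng, length, fill_gc)
    starts = rng.choice(np.arange(0, length - 1, 2), size=n_cpg, replace=False)
    seq[starts] = "C"
    seq[starts + 1] = "G"
    return seq


def _place_units(rng: np.random.Generator, occupied: List[Tuple[int, int]],
                 chrom_length: int, unit_length: int, n_units: int,
                 class_name: str, margin: int = 200,
                 max_tries: int = 2000) -> List[int]:
    """Place n_units non-overlapping starts, updating `occupied` in place."""
    placed = []
    for _ in range(n_units):
        for _try in range(max_tries):
            start = int(rng.integers(margin, chrom_length - unit_length - margin))
            end = start + unit_length
            if all(end + margin <= s or e + margin <= start for s, e in occupied):
                occupied.append((start, end))
                placed.append(start)
                break
        else:
            raise PlacementError(
                f"could not place feature of class {class_name!r} "
                f"({n_units} x {unit_length} bp) without overlap"
            )
    return placed


def _split_counts(total: int, n_chroms: int) -> List[int]:
    base, rem = divmod(total, n_chroms)
    return [base + (1 if i < rem else 0) for i in range(n_chroms)]


def build_genome(config: SyntheticGenomeConfig
                 ) -> Tuple[Dict[str, Dict[str, str]], SyntheticTruth]:
    """Build the diploid genome and its ground-truth record.

    Returns ``(haplotypes, truth)`` where ``haplotypes`` maps haplotype name
    ("maternal"/"paternal") to {chrom: sequence}. The two haplotypes are
    identical except at SNP positions; the maternal sequence is the
    reference by convention.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_lengths = {c: config.chrom_length for c in chrom_names}

    genes: List[GenomicInterval] = []
    features: Dict[str, List[GenomicInterval]] = {"CGI": [], "ICR": []}
    for cls, *_ in config.repeat_spec:
        features.setdefault(cls, [])
    snp_rows = []
    maternal: Dict[str, np.ndarray] = {}

    genes_per_chrom = _split_counts(config.n_genes, config.n_chroms)
    icrs_per_chrom = _split_counts(config.n_icrs, config.n_chroms)
    repeats_per_chrom = {
        cls: _split_counts(count, config.n_chroms)
        for cls, count, _, _ in config.repeat_spec
    }

    for ci, chrom in enumerate(chrom_names):
        seq = _random_bases(rng, config.chrom_length, config.background_gc)
        occupied: List[Tuple[int, int]] = []

        # gene units: gene body plus a promoter CpG island centred on the TSS
        for gi in range(genes_per_chrom[ci]):
            cgi_len = int(rng.integers(config.cgi_length_range[0],
                                       config.cgi_length_range[1] + 1))
            unit_len = config.gene_length + cgi_len  # bounding box upper bound
            start = _place_units(rng, occupied, config.chrom_length,
                                 unit_len, 1, "gene")[0]
            strand = "+" if rng.random() < 0.5 else "-"
            if strand == "+":
                tss = start + cgi_len // 2
                gene_iv = GenomicInterval(chrom, tss, tss + config.gene_length,
                                          strand, f"gene_{chrom}_{gi}")
            else:
                tss = start + unit_len - cgi_len // 2 - 1
                gene_iv = GenomicInterval(chrom, tss - config.gene_length + 1,
                                          tss + 1, strand, f"gene_{chrom}_{gi}")
            cgi_start = tss - cgi_len // 2
            cgi_iv = GenomicInterval(chrom, cgi_start, cgi_start + cgi_len,
                                     None, f"CGI_{chrom}_{gi}")
            seq[cgi_iv.start:cgi_iv.end] = _cpg_island_sequence(
                rng, cgi_len, config.promoter_gc)
            genes.append(gene_iv)
            features["CGI"].append(cgi_iv)

        # ICR analogs: CpG-island-like loci carrying haplotype SNPs
        for ii in range(icrs_per_chrom[ci]):
            start = _place_units(rng, occupied, config.chrom_length,
                                 config.icr_length, 1, "ICR")[0]
            icr_iv = GenomicInterval(chrom, start, start + config.icr_length,
                                     None, f"ICR_{chrom}_{ii}")
            seq[start:start + config.icr_length] = _cpg_island_sequence(
                rng, config.icr_length, config.promoter_gc)
            features["ICR"].append(icr_iv)
            if config.n_snps_per_icr > 0:
                pos = rng.choice(
                    np.arange(start + 10, start + config.icr_length - 10),
                    size=config.n_snps_per_icr, replace=False)
                for p in sorted(int(x) for x in pos):
                    ref = seq[p]
                    alts = [b for b in "ACGT" if b != ref]
                    alt = alts[int(rng.integers(0, 3))]
                    snp_rows.append((chrom, p, str(ref), alt))

        # repeat classes
        for cls, _count, unit_len, unit_gc in config.repeat_spec:
            for ri in range(repeats_per_chrom[cls][ci]):
                start = _place_units(rng, occupied, config.chrom_length,
                                     unit_len, 1, cls)[0]
                seq[start:start + unit_len] = _random_bases(rng, unit_len, unit_gc)
                features[cls].append(GenomicInterval(
                    chrom, start, start + unit_len, None, f"{cls}_{chrom}_{ri}"))

        maternal[chrom] = seq

    snps = pd.DataFrame(snp_rows, columns=["chrom", "pos", "maternal", "paternal"])
    paternal = {c: seq.copy() for c, seq in maternal.items()}
    for _, row in snps.iterrows():
        paternal[row["chrom"]][row["pos"]] = row["paternal"]

    haplotypes = {
        "maternal": {c: "".join(s) for c, s in maternal.items()},
        "paternal": {c: "".join(s) for c, s in paternal.items()},
    }
    truth = SyntheticTruth(config=config, chrom_lengths=chrom_lengths,
                           genes=sorted(genes, key=lambda g: (g.chrom, g.start)),
                           features={k: sorted(v, key=lambda f: (f.chrom, f.start))
                                     for k, v in features.items()},
                           snps=snps.sort_values(["chrom", "pos"]).reset_index(drop=True))
    return haplotypes, truth


def build_enrichment_field(truth: SyntheticTruth, gc_track: WindowTrack,
                           gc_breakpoint: float = 0.5, max_fold: float = 8.0,
                           icr_boost: float = 3.0,
                           allelic_fraction: float = 0.9) -> EnrichmentField:
    """Turn a G+C track into a relative enrichment field.

    lambda_rel = 1 for windows at or below the breakpoint and rises linearly
    with G+C above it, reaching ``max_fold`` at breakpoint + 0.25 (capped at
    G+C = 1). ICR windows get an extra ``icr_boost`` factor. The field is
    renormalized to mean 1 so n_chip stays the expected genome-wide depth.
    """
    if not 0.0 < gc_breakpoint < 1.0:
        raise ValueError(f"gc_breakpoint must be in (0,1), got {gc_breakpoint}")
    if max_fold <= 0:
        raise ValueError("max_fold must be positive")
    top = min(gc_breakpoint + 0.25, 1.0)
    lam: Dict[str, np.ndarray] = {}
    for chrom, gc in gc_track.values.items():
        g = np.nan_to_num(gc, nan=gc_breakpoint)  # N windows: background rate
        frac = np.clip((g - gc_breakpoint) / (top - gc_breakpoint), 0.0, 1.0)
        lam[chrom] = 1.0 + (max_fold - 1.0) * frac
    w = gc_track.window_size
    for icr in truth.features.get("ICR", []):
        first, last = icr.start // w, (icr.end - 1) // w
        lam[icr.chrom][first:last + 1] *= icr_boost
    mean = np.concatenate(list(lam.values())).mean()
    lam = {c: v / mean for c, v in lam.items()}
    field = EnrichmentField(window_size=w, lambda_rel=lam,
                            allelic_fraction=allelic_fraction,
                            gc_breakpoint=gc_breakpoint, max_fold=max_fold)
    field.validate()
    return field


def uniform_field(truth: SyntheticTruth, window_size: int = 100,
                  allelic_fraction: float = 0.5) -> EnrichmentField:
    """A flat field (lambda_rel = 1 everywhere): the input-library model."""
    lam = {c: np.ones(n_windows(length, window_size))
           for c, length in truth.chrom_lengths.items()}
    return EnrichmentField(window_size=window_size, lambda_rel=lam,
                           allelic_fraction=allelic_fraction)


def _format_payload(positions: Sequence[int], bases: Sequence[str]) -> str:
    return ",".join(f"{p}:{b}" for p, b in zip(positions, bases))


def simulate_tags(truth: SyntheticTruth, field: EnrichmentField,
                  n_chip: int, n_input: int, fragment_length: int = 200,
                  seed: int = 0,
                  haplotypes: Optional[Dict[str, Dict[str, str]]] = None
                  ) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate ChIP and input tag libraries.

    Fragment midpoints are sampled per 100-bp window — uniformly for input,
    proportional to ``field.lambda_rel`` for ChIP — then one sequenced tag
    (read) is reported per fragment, on a uniformly random strand, its 5'
    end flanking the fragment. ICR-overlapping ChIP tags derive from the
    maternal haplotype with probability ``field.allelic_fraction``; all
    other tags are 50:50. Tags whose read spans SNP positions carry the
    drawn haplotype's base at each SNP.
    """
    if n_chip <= 0 or n_input <= 0:
        raise ValueError("n_chip and n_input must be positive")
    if fragment_length > min(truth.chrom_lengths.values()):
        raise ValueError("fragment_length exceeds chromosome length")
    rng = np.random.default_rng(seed)
    chip = _simulate_library(truth, field, n_chip, fragment_length, rng,
                             skew_icrs=True)
    inp_field = uniform_field(truth, field.window_size)
    inp = _simulate_library(truth, inp_field, n_input, fragment_length, rng,
                            skew_icrs=False)
    return chip, inp


def _simulate_library(truth: SyntheticTruth, field: EnrichmentField,
                      n_tags: int, fragment_length: int,
                      rng: np.random.Generator, skew_icrs: bool) -> pd.DataFrame:
    cfg = truth.config
    w = field.window_size
    chroms = list(truth.chrom_lengths)
    # flat arrays over the genome-wide window grid
    window_chrom_idx, window_start, window_len, weights = [], [], [], []
    for ci, chrom in enumerate(chroms):
        length = truth.chrom_lengths[chrom]
        nw = n_windows(length, w)
        starts = np.arange(nw) * w
        ends = np.minimum(starts + w, length)
        window_chrom_idx.append(np.full(nw, ci))
        window_start.append(starts)
        wl = ends - starts
        window_len.append(wl)
        weights.append(field.lambda_rel[chrom] * wl)
    window_chrom_idx = np.concatenate(window_chrom_idx)
    window_start = np.concatenate(window_start)
    window_len = np.concatenate(window_len)
    p = np.concatenate(weights)
    p = p / p.sum()

    widx = rng.choice(len(p), size=n_tags, p=p)
    mid = window_start[widx] + np.floor(
        rng.random(n_tags) * window_len[widx]).astype(np.int64)
    chrom_idx = window_chrom_idx[widx]
    chrom_len = np.array([truth.chrom_lengths[c] for c in chroms])[chrom_idx]
    frag_start = np.clip(mid - fragment_length // 2, 0, None)
    frag_end = np.minimum(frag_start + fragment_length, chrom_len)
    frag_start = np.clip(frag_end - fragment_length, 0, frag_start)

    plus = rng.random(n_tags) < 0.5
    read_len = np.minimum(cfg.read_length, frag_end - frag_start)
    start = np.where(plus, frag_start, frag_end - read_len)
    strand = np.where(plus, "+", "-")

    # haplotype of origin
    hap_is_maternal = rng.random(n_tags) < 0.5
    if skew_icrs and field.allelic_fraction != 0.5:
        in_icr = np.zeros(n_tags, dtype=bool)
        for icr in truth.features.get("ICR", []):
            ci = chroms.index(icr.chrom)
            m = (chrom_idx == ci) & (start < icr.end) & (start + read_len > icr.start)
            in_icr |= m
        hap_is_maternal[in_icr] = (
            rng.random(int(in_icr.sum())) < field.allelic_fraction)
    hap = np.where(hap_is_maternal, "M", "P")

    # SNP base payload for reads spanning SNP positions
    payloads = [""] * n_tags
    if len(truth.snps):
        snp_by_chrom = {c: g for c, g in truth.snps.groupby("chrom")}
        for ti in np.flatnonzero(_overlaps_any_snp(
                chroms, chrom_idx, start, read_len, snp_by_chrom)):
            chrom = chroms[chrom_idx[ti]]
            sub = snp_by_chrom[chrom]
            m = (sub["pos"] >= start[ti]) & (sub["pos"] < start[ti] + read_len[ti])
            if not m.any():
                continue
            pos = sub.loc[m, "pos"].to_numpy()
            col = "maternal" if hap[ti] == "M" else "paternal"
            bases = sub.loc[m, col].to_list()
            if cfg.error_rate > 0:
                bases = [
                    (rng.choice([x for x in "ACGT" if x != b])
                     if rng.random() < cfg.error_rate else b)
                    for b in bases
                ]
            payloads[ti] = _format_payload(pos, bases)

    return pd.DataFrame({
        "chrom": np.array(chroms, dtype=object)[chrom_idx],
        "start": start.astype(np.int64),
        "length": read_len.astype(np.int64),
        "strand": strand,
        "hap": hap,
        "snps": payloads,
    })


def _overlaps_any_snp(chroms, chrom_idx, start, read_len, snp_by_chrom):
    hit = np.zeros(len(start), dtype=bool)
    for ci, chrom in enumerate(chroms):
        sub = snp_by_chrom.get(chrom)
        if sub is None:
            continue
        pos = np.sort(sub["pos"].to_numpy())
        m = chrom_idx == ci
        s = start[m]
        e = s + read_len[m]
        # read overlaps a SNP iff some pos in [s, e)
        idx = np.searchsorted(pos, s, side="left")
        hit_m = (idx < len(pos)) & (pos[np.minimum(idx, len(pos) - 1)] < e)
        hit[np.flatnonzero(m)] = hit_m
    return hit
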