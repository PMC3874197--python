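"""SNP-based allelic partitioning of tags at designated loci.

Tags overlapping haplotype-distinguishing SNPs are assigned to the maternal
or paternal chromosome when every informative base matches that haplotype;
tags with no informative SNP, a non-allelic base, or conflicting matches
stay unassigned. Per-locus allelic ratios are tested against the 50:50
expectation with an exact two-sided binomial test (minimum-likelihood
convention) and thresholded into a mono-/bi-allelic call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence

import pandas as pd

from .intervals import GenomicInterval
from .stats import binom_two_sided

MATERNAL = "maternal"
PATERNAL = "paternal"
UNASSIGNED = "unassigned"

MATERNAL_BIASED = "maternal_biased"
PATERNAL_BIASED = "paternal_biased"
BIALLELIC = "biallelic"
INSUFFICIENT = "insufficient"


@dataclass
class SnpTable:
    """Per-SNP haplotype bases: chrom, 0-based pos, maternal, paternal."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        if len(t):
            if t.duplicated(["chrom", "pos"]).any():
                raise ValueError("duplicate SNP positions")
            if (t["maternal"] == t["paternal"]).any():
                raise ValueError("SNP with identical parental bases")
        self._lookup = {
            (row.chrom, row.pos): (row.maternal, row.paternal)
            for row in t.itertuples()
        }

    def swapped(self) -> "SnpTable":
        t = self.table.rename(columns={"maternal": "paternal",
                                       "paternal": "maternal"})
        return SnpTable(t[["chrom", "pos", "maternal", "paternal"]])


@dataclass
class AllelicCounts:
    locus: GenomicInterval
    maternal: int
    paternal: int
    unassigned: int
    ratio: Optional[float]     # maternal / (maternal + paternal)
    binom_p: Optional[float]   # exact two-sided vs 0.5

    @property
    def informative(self) -> int:
        return self.maternal + self.paternal


def parse_payload(payload: str) -> Dict[int, str]:
    """Parse the tag-name SNP payload 'pos:base,pos:base' into a dict."""
    if not payload:
        return {}
    out = {}
    for item in payload.split(","):
        pos, base = item.split(":")
        out[int(pos)] = base
    return out


def assign_tag(chrom: str, payload: str, snps: SnpTable) -> str:
    """Assign one tag from its observed bases at SNP positions.

    maternal/paternal only when every informative base matches that
    haplotype; anything else (no SNP, non-allelic base, conflict) is
    unassigned.
    """
    observed = parse_payload(payload)
    votes = set()
    for pos, base in observed.items():
        alleles = snps._lookup.get((chrom, pos))
        if alleles is None:
            continue
        mat, pat = alleles
        if base == mat:
            votes.add(MATERNAL)
        elif base == pat:
            votes.add(PATERNAL)
        else:
            return UNASSIGNED  # non-allelic base
    if len(votes) == 1:
        return votes.pop()
    return UNASSIGNED  # no informative SNP, or conflicting matches


def allelic_counts(tags: pd.DataFrame, locus: GenomicInterval,
                   snps: SnpTable) -> AllelicCounts:
    """Partition the tags overlapping `locus` between the haplotypes."""
    m = (
        (tags["chrom"] == locus.chrom)
        & (tags["start"] < locus.end)
        & (tags["start"] + tags["length"] > locus.start)
    )
    sub = tags.loc[m]
    n_mat = n_pat = n_un = 0
    for row in sub.itertuples():
        call = assign_tag(row.chrom, row.snps, snps)
        if call == MATERNAL:
            n_mat += 1
        elif call == PATERNAL:
            n_pat += 1
        else:
            n_un += 1
    n = n_mat + n_pat
    ratio = n_mat / n if n > 0 else None
    p = binom_two_sided(n_mat, n) if n > 0 else None
    return AllelicCounts(locus, n_mat, n_pat, n_un, ratio, p)


def classify_locus(counts: AllelicCounts, min_informative: int = 10,
                   ratio_cutoff: float = 0.7, alpha: float = 0.01) -> str:
    """Threshold an AllelicCounts into a mono-/bi-allelic call."""
    if counts.informative < min_informative:
        return INSUFFICIENT
    assert counts.ratio is not None and counts.binom_p is not None
    if counts.binom_p < alpha:
        if counts.ratio >= ratio_cutoff:
            return MATERNAL_BIASED
        if counts.ratio <= 1.0 - ratio_cutoff:
            return PATERNAL_BIASED
    return BIALLELIC


def allelic_report(tags: pd.DataFrame, loci: Sequence[GenomicInterval],
                   snps: SnpTable, min_informative: int = 10,
                   ratio_cutoff: float = 0.7, alpha: float = 0.01
                   ) -> pd.DataFrame:
    """Per-locus allelic table: counts, ratio, exact p, classification."""
    rows = []
    for locus in loci:
        c = allelic_counts(tags, locus, snps)
        rows.append({
            "locus": locus.name or f"{locus.chrom}:{locus.start}-{locus.end}",
            "chrom": locus.chrom, "start": locus.start, "end": locus.end,
            "n_maternal": c.maternal, "n_paternal": c.paternal,
            "n_unassigned": c.unassigned,
            "ratio": c.ratio, "binom_p": c.binom_p,
            "call": classify_locus(c, min_informative, ratio_cutoff, alpha),
        })
    return pd.DataFrame(rows)
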