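"""Readers and writers for the text formats the pipeline exchanges.

Conventions: BED is native 0-based half-open; VCF is 1-based and converted
on I/O (REF = maternal, ALT = paternal); tag BED6 name fields carry the
simulator's haplotype payload as ``hap=M;snp=pos:base,...``; tracks go out
as 4-column bedGraph or TSV.
"""

from __future__ import annotations

import os
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from pyfaidx import Fasta

from .intervals import GenomicInterval
from .peaks import Peak
from .tracks import TAG_COLUMNS, WindowTrack


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: Dict[str, str], path: str) -> None:
    records = [SeqRecord(Seq(seq), id=chrom, description="")
               for chrom, seq in sequences.items()]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> Dict[str, str]:
    with Fasta(path, as_raw=True, sequence_always_upper=True) as fa:
        return {name: str(fa[name][:]) for name in fa.keys()}


# ---------------------------------------------------------------- tag BED6

def _tag_name(hap: str, snps: str) -> str:
    name = f"hap={hap}" if hap else "hap=."
    if snps:
        name += f";snp={snps}"
    return name


def write_tags_bed(tags: pd.DataFrame, path: str) -> None:
    names = [_tag_name(h, s) for h, s in zip(tags["hap"], tags["snps"])]
    out = pd.DataFrame({
        "chrom": tags["chrom"],
        "start": tags["start"],
        "end": tags["start"] + tags["length"],
        "name": names,
        "score": 0,
        "strand": tags["strand"],
    })
    out.to_csv(path, sep="\t", header=False, index=False)


def read_tags_bed(path: str) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      dtype={"chrom": str, "name": str, "strand": str})
    hap, snps = [], []
    for name in bed["name"]:
        h, s = ".", ""
        for part in str(name).split(";"):
            if part.startswith("hap="):
                h = part[4:]
            elif part.startswith("snp="):
                s = part[4:]
        hap.append(h)
        snps.append(s)
    return pd.DataFrame({
        "chrom": bed["chrom"],
        "start": bed["start"].astype(np.int64),
        "length": (bed["end"] - bed["start"]).astype(np.int64),
        "strand": bed["strand"],
        "hap": hap,
        "snps": snps,
    })[TAG_COLUMNS]


# ---------------------------------------------------------------- feature BED

def write_features_bed(features: Sequence[GenomicInterval], path: str) -> None:
    rows = [(iv.chrom, iv.start, iv.end, iv.name or ".", 0, iv.strand or ".")
            for iv in features]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_features_bed(path: str) -> List[GenomicInterval]:
    if os.path.getsize(path) == 0:
        return []
    bed = pd.read_csv(path, sep="\t", header=None,
                      names=["chrom", "start", "end", "name", "score", "strand"],
                      dtype={"chrom": str, "name": str, "strand": str})
    out = []
    for row in bed.itertuples():
        strand = None if row.strand in (".", "nan") else row.strand
        name = None if row.name in (".", "nan") else str(row.name)
        out.append(GenomicInterval(row.chrom, int(row.start), int(row.end),
                                   strand, name))
    return out


# ---------------------------------------------------------------- tracks

def write_track_bedgraph(track: WindowTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom, v in track.values.items():
            starts = np.arange(len(v)) * track.window_size
            for s, val in zip(starts, v):
                if np.isfinite(val):
                    fh.write(f"{chrom}\t{s}\t{s + track.window_size}\t{val:g}\n")


def write_track_tsv(track: WindowTrack, path: str) -> None:
    frames = []
    for chrom, v in track.values.items():
        starts = np.arange(len(v)) * track.window_size
        frames.append(pd.DataFrame({
            "chrom": chrom, "start": starts,
            "end": starts + track.window_size, "value": v}))
    pd.concat(frames).to_csv(path, sep="\t", index=False)


def read_track_tsv(path: str, units: str = "raw_count",
                   sample_label: str = "") -> WindowTrack:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    window_size = int((df["end"] - df["start"]).iloc[0])
    values = {str(chrom): sub["value"].to_numpy(dtype=float)
              for chrom, sub in df.groupby("chrom", sort=False)}
    return WindowTrack(window_size, values, units, sample_label)


# ---------------------------------------------------------------- narrowPeak

def write_narrowpeak(peaks: Sequence[Peak], path: str) -> None:
    """BED6+4: signalValue = fold enrichment, pValue = -log10 p, qValue = -1,
    peak = summit offset from the interval start."""
    rows = []
    for i, p in enumerate(peaks):
        iv = p.interval
        mlog10 = -np.log10(max(p.p_value, 1e-300))
        rows.append((iv.chrom, iv.start, iv.end, f"peak_{i + 1}",
                     min(1000, int(10 * p.fold_enrichment)), ".",
                     f"{p.fold_enrichment:.5g}", f"{mlog10:.5g}", -1,
                     p.summit - iv.start))
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_narrowpeak(path: str) -> List[Peak]:
    if os.path.getsize(path) == 0:
        return []
    cols = ["chrom", "start", "end", "name", "score", "strand",
            "signal", "neglog10p", "q", "peak"]
    df = pd.read_csv(path, sep="\t", header=None, names=cols,
                     dtype={"chrom": str})
    out = []
    for row in df.itertuples():
        p_value = 10 ** (-row.neglog10p)
        fold = row.signal
        out.append(Peak(
            interval=GenomicInterval(row.chrom, int(row.start), int(row.end)),
            summit=int(row.start) + int(row.peak),
            chip_count=np.nan, lambda_local=np.nan,
            p_value=p_value, fold_enrichment=fold))
    return out


# ---------------------------------------------------------------- VCF

def write_snps_vcf(snps: pd.DataFrame, chrom_lengths: Dict[str, int],
                   path: str) -> None:
    """Minimal VCF 4.2: REF = maternal, ALT = paternal, 0-based positions
    converted to 1-based on write."""
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    with pysam.VariantFile(path, "w", header=header) as vf:
        for i, row in enumerate(snps.itertuples()):
            rec = vf.new_record(contig=row.chrom, start=int(row.pos),
                                stop=int(row.pos) + 1,
                                alleles=(row.maternal, row.paternal),
                                id=f"snp_{i + 1}")
            vf.write(rec)


def read_snps_vcf(path: str) -> pd.DataFrame:
    rows = []
    with pysam.VariantFile(path) as vf:
        for rec in vf:
            rows.append((rec.contig, rec.start, rec.ref, rec.alts[0]))
    return pd.DataFrame(rows, columns=["chrom", "pos", "maternal", "paternal"])
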