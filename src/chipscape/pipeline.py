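"""End-to-end orchestration.

One config drives the whole analysis: simulate a diploid genome with two
ChIP libraries (two "cell types" sharing one enrichment field) plus matched
inputs, then tracks -> peak calling -> annotation -> G+C stratification ->
anchor profiles -> co-enrichment -> allelic partitioning. Each stage writes
its outputs before the next starts, and a run manifest records config hash,
seeds, and a checksum for every output file, so identical config + seed
reproduces identical manifests.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
import os
import zlib
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import annotate as ann
from . import coenrich as ce
from . import gc as gcmod
from . import io as cio
from . import profiles as prof
from . import synth
from .allelic import SnpTable, allelic_report
from .peaks import PeakCallConfig, call_peaks, compare_peak_sets
from .tracks import (count_fragments, enrichment_over_input, extend_tags,
                     normalize_per_million, smooth)

logger = logging.getLogger("chipscape")

STAGES = ["simulate", "tracks", "callpeaks", "annotate", "gcstrata",
          "profiles", "coenrich", "allelic"]

DEFAULT_CONFIG: Dict = {
    "seed": 0,
    "outdir": "chipscape_out",
    "synthetic": {
        "n_chroms": 2,
        "chrom_length": 1_000_000,
        "background_gc": 0.40,
        "n_genes": 50,
        "gene_length": 2_000,
        "promoter_gc": 0.60,
        "cgi_length_range": [500, 1500],
        "n_icrs": 5,
        "icr_length": 1_000,
        "n_snps_per_icr": 10,
        "repeat_spec": [list(r) for r in synth.DEFAULT_REPEAT_SPEC],
        "read_length": 50,
        "error_rate": 0.0,
        "gc_breakpoint": 0.5,
        "max_fold": 8.0,
        "icr_boost": 3.0,
        "allelic_fraction": 0.9,
        "n_chip": 200_000,
        "n_input": 200_000,
        "fragment_length": 200,
    },
    "tracks": {
        "window_size": 100,
        "pseudocount": 1.0,
        "smooth_half_width": 2,
    },
    "peaks": {
        "enabled": True,
        "p_threshold": 1e-5,
        "merge_gap": 100,
        "local_windows": [1000, 5000, 10000],
    },
    "annotate": {
        "promoter_window": 1000,
    },
    "gcstrata": {
        "bin_width": 0.05,
    },
    "profiles": {
        "flank": 5000,
        "bin": 100,
        "n_groups": 4,
        "k_clusters": 3,
    },
    "coenrich": {
        "transform": "log10_1p",
        "gridsize": 50,
    },
    "allelic": {
        "min_informative": 10,
        "ratio_cutoff": 0.7,
        "alpha": 0.01,
    },
}


class ConfigError(ValueError):
    pass


def merge_config(user: Optional[Dict]) -> Dict:
    """Deep-merge a user config over the shipped defaults."""
    cfg = copy.deepcopy(DEFAULT_CONFIG)

    def _merge(base: Dict, over: Dict) -> None:
        for k, v in over.items():
            if k not in base:
                raise ConfigError(f"unknown config key {k!r}")
            if isinstance(base[k], dict) and isinstance(v, dict):
                _merge(base[k], v)
            else:
                base[k] = v

    if user:
        _merge(cfg, user)
    return cfg


def load_config(path: Optional[str]) -> Dict:
    if path is None:
        return merge_config(None)
    with open(path) as fh:
        return merge_config(yaml.safe_load(fh) or {})


def stage_seed(global_seed: int, stage: str) -> int:
    """One knob, independent streams: per-stage seed from the stage name."""
    return (int(global_seed) ^ zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class Run:
    """Holds in-memory state passed between stages plus the manifest."""

    def __init__(self, config: Dict):
        self.config = config
        self.outdir = config["outdir"]
        os.makedirs(self.outdir, exist_ok=True)
        cfg_json = json.dumps(config, sort_keys=True)
        self.manifest: Dict = {
            "version": __version__,
            "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
            "seed": config["seed"],
            "stages": {},
        }
        self.state: Dict = {}

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    def record(self, stage: str, outputs: List[str],
               skipped: bool = False) -> None:
        self.manifest["stages"][stage] = {
            "seed": stage_seed(self.config["seed"], stage),
            "skipped": skipped,
            "outputs": {os.path.basename(p): _sha256(p) for p in outputs},
        }


# ------------------------------------------------------------------ stages

def stage_simulate(run: Run) -> None:
    sc = run.config["synthetic"]
    cfg = synth.SyntheticGenomeConfig(
        n_chroms=sc["n_chroms"], chrom_length=sc["chrom_length"],
        background_gc=sc["background_gc"], n_genes=sc["n_genes"],
        gene_length=sc["gene_length"], promoter_gc=sc["promoter_gc"],
        cgi_length_range=tuple(sc["cgi_length_range"]), n_icrs=sc["n_icrs"],
        icr_length=sc["icr_length"], n_snps_per_icr=sc["n_snps_per_icr"],
        repeat_spec=[tuple(r) for r in sc["repeat_spec"]],
        read_length=sc["read_length"], error_rate=sc["error_rate"],
        seed=stage_seed(run.config["seed"], "simulate"))
    haplotypes, truth = synth.build_genome(cfg)
    w = run.config["tracks"]["window_size"]
    gc_tr = gcmod.gc_track(haplotypes["maternal"], w)
    field = synth.build_enrichment_field(
        truth, gc_tr, gc_breakpoint=sc["gc_breakpoint"],
        max_fold=sc["max_fold"], icr_boost=sc["icr_boost"],
        allelic_fraction=sc["allelic_fraction"])
    seed = stage_seed(run.config["seed"], "simulate")
    libraries = {}
    for li, label in enumerate(["es", "mef"]):
        chip, inp = synth.simulate_tags(
            truth, field, sc["n_chip"], sc["n_input"],
            fragment_length=sc["fragment_length"], seed=seed + 1 + li)
        libraries[label] = {"chip": chip, "input": inp}

    outputs = []
    for hap in ("maternal", "paternal"):
        p = run.path(f"genome_{hap}.fa")
        cio.write_fasta(haplotypes[hap], p)
        outputs.append(p)
    p = run.path("reference.fa")
    cio.write_fasta(haplotypes["maternal"], p)
    outputs.append(p)
    for label, lib in libraries.items():
        for kind in ("chip", "input"):
            p = run.path(f"tags_{label}_{kind}.bed")
            cio.write_tags_bed(lib[kind], p)
            outputs.append(p)
    feats = [iv for ivs in truth.features.values() for iv in ivs]
    p = run.path("features.bed")
    cio.write_features_bed(
        sorted(feats, key=lambda f: (f.chrom, f.start)), p)
    outputs.append(p)
    p = run.path("genes.bed")
    cio.write_features_bed(truth.genes, p)
    outputs.append(p)
    p = run.path("snps.vcf")
    cio.write_snps_vcf(truth.snps, truth.chrom_lengths, p)
    outputs.append(p)
    p = run.path("truth_field.tsv")
    cio.write_track_tsv(field.as_track(), p)
    outputs.append(p)
    p = run.path("config_echo.yaml")
    echo = {k: v for k, v in run.config.items() if k != "outdir"}
    with open(p, "w") as fh:
        yaml.safe_dump(echo, fh, sort_keys=True)
    outputs.append(p)

    run.state.update(haplotypes=haplotypes, truth=truth, field=field,
                     gc_track=gc_tr, libraries=libraries)
    run.record("simulate", outputs)


def stage_tracks(run: Run) -> None:
    tc = run.config["tracks"]
    sc = run.config["synthetic"]
    truth = run.state["truth"]
    outputs = []
    tracks = {}
    for label, lib in run.state["libraries"].items():
        for kind in ("chip", "input"):
            frags = extend_tags(lib[kind], sc["fragment_length"],
                                truth.chrom_lengths)
            raw = count_fragments(frags, tc["window_size"],
                                  truth.chrom_lengths, f"{label}_{kind}")
            pm = normalize_per_million(raw)
            sm = smooth(pm, tc["smooth_half_width"])
            tracks[f"{label}_{kind}"] = {"raw": raw, "pm": pm, "smooth": sm}
        enr = enrichment_over_input(
            tracks[f"{label}_chip"]["smooth"], tracks[f"{label}_input"]["smooth"],
            pseudocount=tc["pseudocount"])
        tracks[f"{label}_enrichment"] = enr
        p = run.path(f"enrichment_{label}.bedgraph")
        cio.write_track_bedgraph(enr, p)
        outputs.append(p)
        p = run.path(f"density_{label}_chip.tsv")
        cio.write_track_tsv(tracks[f"{label}_chip"]["smooth"], p)
        outputs.append(p)
    run.state["tracks"] = tracks
    run.record("tracks", outputs)


def stage_callpeaks(run: Run) -> None:
    pc = run.config["peaks"]
    if not pc["enabled"]:
        logger.info("callpeaks disabled; skipping peak-dependent stages")
        run.record("callpeaks", [], skipped=True)
        return
    config = PeakCallConfig(
        p_threshold=pc["p_threshold"],
        window_size=run.config["tracks"]["window_size"],
        merge_gap=pc["merge_gap"],
        local_windows=tuple(pc["local_windows"]))
    outputs = []
    peak_sets = {}
    for label in ("es", "mef"):
        peaks = call_peaks(run.state["tracks"][f"{label}_chip"]["raw"],
                           run.state["tracks"][f"{label}_input"]["raw"], config)
        peak_sets[label] = peaks
        p = run.path(f"peaks_{label}.narrowPeak")
        cio.write_narrowpeak(peaks, p)
        outputs.append(p)
        logger.info("callpeaks[%s]: %d peaks", label, len(peaks))
    venn = compare_peak_sets(peak_sets["es"], peak_sets["mef"])
    p = run.path("peak_venn.json")
    with open(p, "w") as fh:
        json.dump(venn, fh, indent=1)
    outputs.append(p)
    run.state["peak_sets"] = peak_sets
    run.record("callpeaks", outputs)


def stage_annotate(run: Run) -> None:
    ac = run.config["annotate"]
    truth = run.state["truth"]
    ref = run.state["haplotypes"]["maternal"]
    outputs = []
    islands = []
    for chrom, seq in ref.items():
        islands.extend(ann.detect_cpg_islands(seq, chrom=chrom))
    p = run.path("cpg_islands.tsv")
    pd.DataFrame([{
        "chrom": i.interval.chrom, "start": i.interval.start,
        "end": i.interval.end, "gc": i.gc_fraction, "obs_exp": i.obs_exp_cpg,
    } for i in islands]).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    run.state["cpg_islands"] = islands

    if "peak_sets" in run.state:
        rows = []
        for label, peaks in run.state["peak_sets"].items():
            ivs = [pk.interval for pk in peaks]
            _, fractions = ann.classify_peak_locations(
                ivs, truth.genes, ac["promoter_window"])
            frac, n_marked, n_prom = ann.promoter_marked_fraction(
                ivs, truth.genes, ac["promoter_window"])
            rows.append({"sample": label, **fractions,
                         "promoter_marked_fraction": frac,
                         "n_marked_promoters": n_marked,
                         "n_promoters": n_prom})
        p = run.path("peak_annotation.tsv")
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        outputs.append(p)
    else:
        logger.info("annotate: no peaks available; peak localization skipped")

    repeat_classes = {cls: ivs for cls, ivs in truth.features.items()
                      if cls not in ("CGI", "ICR")}
    rep = ann.repeat_class_enrichment(
        run.state["libraries"]["es"]["chip"],
        run.state["libraries"]["es"]["input"], repeat_classes)
    p = run.path("repeat_enrichment.tsv")
    rep.to_csv(p, sep="\t")
    outputs.append(p)
    run.record("annotate", outputs)


def stage_gcstrata(run: Run) -> None:
    gcc = run.config["gcstrata"]
    outputs = []
    for label in ("es", "mef"):
        strat = gcmod.enrichment_by_gc(run.state["tracks"][f"{label}_enrichment"],
                                       run.state["gc_track"], gcc["bin_width"])
        p = run.path(f"gc_stratification_{label}.tsv")
        strat.table.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        run.state[f"gc_strat_{label}"] = strat
    run.record("gcstrata", outputs)


def stage_profiles(run: Run) -> None:
    pc = run.config["profiles"]
    truth = run.state["truth"]
    track = run.state["tracks"]["es_chip"]["smooth"]
    matrix = prof.build_anchor_matrix(track, truth.tss, flank=pc["flank"],
                                      bin=pc["bin"], oriented=True)
    labels, cluster_profiles = prof.cluster_rows(
        matrix, pc["k_clusters"], seed=stage_seed(run.config["seed"], "profiles"))
    outputs = []
    p = run.path("tss_matrix.tsv")
    pd.DataFrame(matrix.values).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    p = run.path("tss_clusters.tsv")
    pd.DataFrame({
        "anchor": [a.name for a in matrix.anchors], "cluster": labels,
    }).to_csv(p, sep="\t", index=False)
    outputs.append(p)

    if "peak_sets" in run.state:
        peaks = run.state["peak_sets"]["es"]
        if peaks:
            summits = [pk.interval.__class__(pk.interval.chrom, pk.summit,
                                             pk.summit + 1) for pk in peaks]
            smat = prof.build_anchor_matrix(track, summits, flank=pc["flank"],
                                            bin=pc["bin"], oriented=False)
            n_groups = min(pc["n_groups"], len(peaks))
            groups = prof.group_anchors_by_enrichment(
                [pk.fold_enrichment for pk in peaks], n_groups)
            med = {g: prof.median_profile(smat, np.flatnonzero(groups == g))
                   for g in range(n_groups)}
            p = run.path("summit_median_profiles.tsv")
            pd.DataFrame(med).to_csv(p, sep="\t", index=False)
            outputs.append(p)
    run.record("profiles", outputs)


def stage_coenrich(run: Run) -> None:
    cc = run.config["coenrich"]
    tr = run.state["tracks"]
    pairs = ce.joint_window_table(tr["es_enrichment"], tr["mef_enrichment"])
    grid = ce.hexbin(pairs, cc["transform"], cc["gridsize"])
    outputs = []
    p = run.path("coenrich_hexbin.tsv")
    pd.DataFrame({"center_x": grid.centers[:, 0] if len(grid.centers) else [],
                  "center_y": grid.centers[:, 1] if len(grid.centers) else [],
                  "count": grid.counts}).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    # headline replicate correlation: plain Pearson on the smoothed densities
    # (transforms are display conventions for the hexbin axes)
    r = ce.pearson_tracks(tr["es_chip"]["smooth"], tr["mef_chip"]["smooth"],
                          "identity")
    r_transformed = ce.pearson_tracks(tr["es_chip"]["smooth"],
                                      tr["mef_chip"]["smooth"], cc["transform"])
    names = ["es_chip", "mef_chip", "es_input", "mef_input"]
    mat = ce.correlation_matrix([tr[n]["pm"] for n in names], names,
                                cc["transform"])
    p = run.path("correlation_matrix.tsv")
    mat.to_csv(p, sep="\t")
    outputs.append(p)
    p = run.path("coenrich_summary.json")
    with open(p, "w") as fh:
        json.dump({"pearson_r_es_vs_mef": r,
                   "pearson_r_es_vs_mef_transformed": r_transformed,
                   "n_windows": len(pairs)}, fh)
    outputs.append(p)
    run.state["pearson_r"] = r
    run.record("coenrich", outputs)


def stage_allelic(run: Run) -> None:
    ac = run.config["allelic"]
    truth = run.state["truth"]
    snps = SnpTable(truth.snps)
    icrs = truth.features.get("ICR", [])
    outputs = []
    for label, kind in [("es", "chip"), ("es", "input")]:
        rep = allelic_report(run.state["libraries"][label][kind], icrs, snps,
                             min_informative=ac["min_informative"],
                             ratio_cutoff=ac["ratio_cutoff"],
                             alpha=ac["alpha"])
        p = run.path(f"allelic_{label}_{kind}.tsv")
        rep.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        run.state[f"allelic_{label}_{kind}"] = rep
    run.record("allelic", outputs)


STAGE_FUNCS = {
    "simulate": stage_simulate,
    "tracks": stage_tracks,
    "callpeaks": stage_callpeaks,
    "annotate": stage_annotate,
    "gcstrata": stage_gcstrata,
    "profiles": stage_profiles,
    "coenrich": stage_coenrich,
    "allelic": stage_allelic,
}


def run_pipeline(config: Optional[Dict] = None) -> Dict:
    """Run all stages in order; returns the manifest (also written to disk)."""
    cfg = merge_config(config)
    run = Run(cfg)
    for stage in STAGES:
        logger.info("stage %s: start", stage)
        try:
            STAGE_FUNCS[stage](run)
        except Exception as exc:
            raise RuntimeError(f"pipeline failed in stage {stage!r}: {exc}") from exc
        logger.info("stage %s: done", stage)
    manifest_path = run.path("manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(run.manifest, fh, indent=1)
    return run.manifest


def make_fixtures(scale: str = "tiny", outdir: str = "fixtures",
                  seed: int = 0) -> Dict:
    """Generate packaged test inputs by simulation (never by download)."""
    if scale == "tiny":
        over = {"synthetic": {"n_chroms": 2, "chrom_length": 100_000,
                              "n_genes": 10, "n_icrs": 2,
                              "n_snps_per_icr": 5,
                              "repeat_spec": [["LTR", 5, 400, 0.58],
                                              ["satellite", 5, 500, 0.35]],
                              "n_chip": 20_000, "n_input": 20_000}}
    elif scale == "default":
        over = {}
    else:
        raise ConfigError(f"unknown fixture scale {scale!r}")
    over["outdir"] = outdir
    over["seed"] = seed
    return run_pipeline(over)
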