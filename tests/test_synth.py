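"""Generator contracts: determinism, composition, conservation, field shape,
and closed-loop statistical oracles at tiny scale."""

import numpy as np
import pytest

from chipscape import gc as gcmod
from chipscape import synth
from chipscape.annotate import detect_cpg_islands
from chipscape.tracks import WindowTrack


def test_featureless_config_gives_identical_haplotypes():
    cfg = synth.SyntheticGenomeConfig(n_chroms=1, chrom_length=50_000,
                                      n_genes=0, n_icrs=0, repeat_spec=[],
                                      seed=5)
    haps, truth = synth.build_genome(cfg)
    assert haps["maternal"] == haps["paternal"]
    assert len(truth.snps) == 0
    assert all(len(v) == 0 for v in truth.features.values())


def test_same_seed_reproduces_genome_and_tags(tiny_config):
    h1, t1 = synth.build_genome(tiny_config)
    h2, t2 = synth.build_genome(tiny_config)
    assert h1 == h2
    assert t1.snps.equals(t2.snps)
    assert [str(g) for g in t1.genes] == [str(g) for g in t2.genes]
    gct = gcmod.gc_track(h1["maternal"], 100)
    field = synth.build_enrichment_field(t1, gct)
    a_chip, a_inp = synth.simulate_tags(t1, field, 5000, 5000, seed=9)
    b_chip, b_inp = synth.simulate_tags(t2, field, 5000, 5000, seed=9)
    assert a_chip.equals(b_chip) and a_inp.equals(b_inp)


def test_background_gc_matches_binomial_expectation():
    cfg = synth.SyntheticGenomeConfig(n_chroms=1, chrom_length=1_000_000,
                                      n_genes=0, n_icrs=0, repeat_spec=[],
                                      background_gc=0.40, seed=11)
    haps, _ = synth.build_genome(cfg)
    seq = haps["maternal"]["chr1"]
    gc = (seq.count("G") + seq.count("C")) / len(seq)
    se = np.sqrt(0.4 * 0.6 / 1_000_000)
    assert abs(gc - 0.40) <= 3 * se


def test_haplotypes_differ_exactly_at_snps(tiny_genome):
    haps, truth = tiny_genome
    diffs = []
    for chrom in truth.chrom_lengths:
        mat = np.frombuffer(haps["maternal"][chrom].encode(), dtype="S1")
        pat = np.frombuffer(haps["paternal"][chrom].encode(), dtype="S1")
        for pos in np.flatnonzero(mat != pat):
            diffs.append((chrom, int(pos)))
    expected = set(zip(truth.snps["chrom"], truth.snps["pos"]))
    assert set(diffs) == expected
    assert (truth.snps["maternal"] != truth.snps["paternal"]).all()
    # every SNP lies inside exactly one ICR
    for row in truth.snps.itertuples():
        containing = [icr for icr in truth.features["ICR"]
                      if icr.contains_point(row.chrom, row.pos)]
        assert len(containing) == 1


def test_planted_features_pass_and_fail_cgi_criteria(tiny_genome):
    haps, truth = tiny_genome
    for cls, should_pass in [("CGI", True), ("ICR", True), ("satellite", False)]:
        for iv in truth.features[cls]:
            seq = haps["maternal"][iv.chrom][iv.start:iv.end]
            islands = detect_cpg_islands(seq, chrom=iv.chrom)
            assert bool(islands) == should_pass, f"{cls} {iv.name}"


def test_field_flat_below_breakpoint_and_bounded_monotone_above():
    truth = _bare_truth(chrom_length=400)
    gct = WindowTrack(100, {"chr1": np.array([0.3, 0.3, 0.3, 0.3])},
                      units="gc_fraction")
    field = synth.build_enrichment_field(truth, gct, gc_breakpoint=0.5)
    assert field.lambda_rel["chr1"] == pytest.approx(np.ones(4))

    gct = WindowTrack(100, {"chr1": np.array([0.4, 0.7])}, units="gc_fraction")
    field = synth.build_enrichment_field(truth, gct, gc_breakpoint=0.5,
                                         max_fold=5.0)
    lam = field.lambda_rel["chr1"]
    ratio = lam[1] / lam[0]
    assert 1.0 < ratio <= 5.0
    assert lam.mean() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        synth.build_enrichment_field(truth, gct, gc_breakpoint=1.5)


def _bare_truth(chrom_length):
    cfg = synth.SyntheticGenomeConfig(n_chroms=1, chrom_length=chrom_length,
                                      n_genes=0, n_icrs=0, repeat_spec=[])
    return synth.SyntheticTruth(config=cfg,
                                chrom_lengths={"chr1": chrom_length},
                                genes=[], features={"ICR": []},
                                snps=synth.pd.DataFrame(
                                    columns=["chrom", "pos", "maternal",
                                             "paternal"]))


def test_uniform_field_tags_are_poisson_uniform_per_window():
    cfg = synth.SyntheticGenomeConfig(n_chroms=1, chrom_length=200_000,
                                      n_genes=0, n_icrs=0, repeat_spec=[],
                                      seed=13)
    _, truth = synth.build_genome(cfg)
    field = synth.uniform_field(truth)
    n = 100_000
    chip, _ = synth.simulate_tags(truth, field, n, 10, seed=21)
    # recover sampled fragment midpoints from read 5' ends
    mid = np.where(chip["strand"] == "+",
                   chip["start"] + 100, chip["start"] + chip["length"] - 100)
    interior = (mid >= 1000) & (mid < 199_000)
    counts = np.bincount(mid[interior] // 100, minlength=2000)[10:1990]
    expected = n * 100 / 200_000
    z = (counts - expected) / np.sqrt(expected)
    assert abs(counts.mean() - expected) < 3 * np.sqrt(expected / len(counts))
    assert (np.abs(z) <= 3).mean() > 0.99  # multinomial tails behave


def test_tag_conservation_and_bounds(tiny_genome, tiny_field, tiny_tags):
    _, truth = tiny_genome
    chip, inp = tiny_tags
    assert len(chip) == 20_000 and len(inp) == 20_000
    for tags in (chip, inp):
        lens = tags["chrom"].map(truth.chrom_lengths)
        assert (tags["start"] >= 0).all()
        assert ((tags["start"] + tags["length"]) <= lens).all()
        # haplotype payload only on tags overlapping a SNP
        has_payload = tags["snps"] != ""
        assert has_payload.sum() > 0 or tags is inp


def test_allelic_fraction_recovered_within_binomial_se(tiny_genome, tiny_field,
                                                       tiny_tags):
    _, truth = tiny_genome
    chip, _ = tiny_tags
    snp_tags = chip[chip["snps"] != ""]
    n = len(snp_tags)
    f = tiny_field.allelic_fraction
    frac = (snp_tags["hap"] == "M").mean()
    assert abs(frac - f) <= 3 * np.sqrt(f * (1 - f) / n)


def test_placement_failure_names_feature_class():
    cfg = synth.SyntheticGenomeConfig(n_chroms=1, chrom_length=30_000,
                                      n_genes=0, n_icrs=0,
                                      repeat_spec=[("satellite", 100, 2000, 0.35)])
    with pytest.raises(synth.PlacementError, match="satellite"):
        synth.build_genome(cfg)


def test_fragment_length_longer_than_chromosome_rejected(tiny_genome,
                                                         tiny_field):
    _, truth = tiny_genome
    with pytest.raises(ValueError):
        synth.simulate_tags(truth, tiny_field, 10, 10,
                            fragment_length=200_001)
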