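"""Annotation checks: CpG-island criteria, peak localization precedence,
promoter marking, repeat-class accounting."""

import numpy as np
import pandas as pd
import pytest

from chipscape.annotate import (classify_peak_locations, detect_cpg_islands,
                                promoter_marked_fraction,
                                repeat_class_enrichment)
from chipscape.intervals import GenomicInterval


def test_cg_repeat_is_one_island_with_expected_scores():
    islands = detect_cpg_islands("CG" * 150, chrom="chr1")
    assert len(islands) == 1
    isl = islands[0]
    assert (isl.interval.start, isl.interval.end) == (0, 300)
    assert isl.gc_fraction == pytest.approx(1.0)
    # obs/exp = (150 * 300) / (150 * 150)
    assert isl.obs_exp_cpg == pytest.approx(2.0)


def test_at_sequence_and_n_windows_yield_no_islands():
    assert detect_cpg_islands("AT" * 300) == []
    assert detect_cpg_islands("CG" * 100 + "N" + "CG" * 99) == []


def test_islands_are_disjoint_and_satisfy_criteria():
    rng = np.random.default_rng(6)
    bg = "".join(rng.choice(list("ACGT"), p=[0.3, 0.2, 0.2, 0.3], size=5000))
    seq = bg[:1000] + "CG" * 300 + bg[1000:3000] + "CG" * 250 + bg[3000:]
    islands = detect_cpg_islands(seq, chrom="chr1")
    assert len(islands) >= 2
    for isl in islands:
        assert isl.gc_fraction > 0.5
        assert isl.length > 200
        assert isl.obs_exp_cpg > 0.6
    spans = sorted((i.interval.start, i.interval.end) for i in islands)
    assert all(a[1] <= b[0] for a, b in zip(spans, spans[1:]))


GENES = [GenomicInterval("chr1", 10_000, 20_000, "+", "gA"),
         GenomicInterval("chr1", 50_000, 60_000, "-", "gB")]


def test_peak_location_precedence():
    peaks = [
        GenomicInterval("chr1", 9_900, 10_100),   # spans TSS of gA
        GenomicInterval("chr1", 15_000, 15_200),  # inside gA body
        GenomicInterval("chr1", 59_500, 60_100),  # spans TSS of gB (- strand)
        GenomicInterval("chr1", 30_000, 30_200),  # nowhere
    ]
    classes, fractions = classify_peak_locations(peaks, GENES, 1000)
    assert classes == ["promoter", "gene_body", "promoter", "intergenic"]
    assert sum(fractions.values()) == pytest.approx(1.0)
    # permutation invariance of the fractions
    _, fr2 = classify_peak_locations(peaks[::-1], GENES, 1000)
    assert fr2 == fractions
    classes, _ = classify_peak_locations(peaks, [], 1000)
    assert classes == ["intergenic"] * 4


def test_promoter_marked_fraction_counts_distinct_promoters():
    both = [GenomicInterval("chr1", 9_000, 11_000),
            GenomicInterval("chr1", 9_500, 10_500),  # same promoter again
            GenomicInterval("chr1", 59_000, 61_000)]
    frac, n_marked, n_prom = promoter_marked_fraction(both, GENES, 1000)
    assert (frac, n_marked, n_prom) == (1.0, 2, 2)
    assert promoter_marked_fraction([], GENES, 1000)[0] == 0.0
    one = [GenomicInterval("chr1", 9_000, 11_000)]
    assert promoter_marked_fraction(one, GENES, 1000)[0] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        promoter_marked_fraction(one, [], 1000)


def tags_at(positions, chrom="chr1", strand="+"):
    return pd.DataFrame({"chrom": chrom, "start": positions, "length": 50,
                         "strand": strand, "hap": "M", "snps": ""})


def test_repeat_accounting_identical_libraries_and_empty_class():
    tags = tags_at([100, 5_000, 9_000, 20_000])
    reps = {"LTR": [GenomicInterval("chr1", 4_000, 6_000)],
            "SINE": [GenomicInterval("chr1", 100_000, 100_500)]}
    table = repeat_class_enrichment(tags, tags.copy(), reps)
    assert table.loc["LTR", "ratio"] == pytest.approx(1.0)
    assert table.loc["SINE", "chip_fraction"] == 0.0
    assert np.isnan(table.loc["SINE", "ratio"])


def test_five_prime_position_rule_for_minus_strand():
    # read [95,145) on minus strand: 5' end at 144, inside the repeat [140,200)
    plus = tags_at([95], strand="+")
    minus = tags_at([95], strand="-")
    reps = {"LTR": [GenomicInterval("chr1", 140, 200)]}
    assert repeat_class_enrichment(plus, plus, reps).loc["LTR", "chip_fraction"] == 0.0
    assert repeat_class_enrichment(minus, minus, reps).loc["LTR", "chip_fraction"] == 1.0


def test_repeat_enrichment_invariant_to_library_duplication():
    rng = np.random.default_rng(7)
    chip = tags_at(rng.integers(0, 50_000, 500))
    inp = tags_at(rng.integers(0, 50_000, 400))
    reps = {"LTR": [GenomicInterval("chr1", 10_000, 20_000)]}
    once = repeat_class_enrichment(chip, inp, reps)
    dup = repeat_class_enrichment(pd.concat([chip, chip]),
                                  pd.concat([inp, inp]), reps)
    assert dup.loc["LTR", "ratio"] == pytest.approx(once.loc["LTR", "ratio"])


def test_simulated_repeat_classes_follow_field(tiny_genome, tiny_field,
                                              tiny_tags):
    """Closed loop: class-fraction ratio matches mean class lambda; the
    boosted G+C-rich LTR analogs come out enriched, the low-G+C satellite
    analogs do not."""
    _, truth = tiny_genome
    chip, inp = tiny_tags
    reps = {cls: truth.features[cls] for cls in ("LTR", "satellite")}
    table = repeat_class_enrichment(chip, inp, reps)
    for cls in reps:
        lam = np.concatenate([
            tiny_field.lambda_rel[iv.chrom][iv.start // 100:(iv.end - 1) // 100 + 1]
            for iv in reps[cls]])
        expected = lam.mean()
        frac = table.loc[cls, "input_fraction"]
        se = np.sqrt(frac * (1 - frac) / len(chip)) / max(frac, 1e-9)
        assert abs(table.loc[cls, "ratio"] - expected) <= 4 * se * expected
    assert table.loc["LTR", "ratio"] > 1.2
    assert table.loc["satellite", "ratio"] < 1.1
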