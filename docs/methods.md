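# Methods

This note records the statistical conventions, default parameters, and the
design decisions behind them — what the package computes, what the
synthetic data do and do not emulate, and where the genuinely open choices
were made.

## Coordinates and containers

All internal coordinates are 0-based half-open (BED convention); VCF
positions are converted on I/O. The universal numeric container is the
`WindowTrack`: one float vector per chromosome on a fixed grid of
`window_size` (default 100 bp) windows, with NaN marking windows excluded
from analysis (windows containing N bases). Tags are rows of a DataFrame
(`chrom, start, length, strand, hap, snps`); `start` is always the leftmost
reference base of the read, and the 5′ end of a minus-strand read is its
rightmost base.

## Synthetic study design

The generator emulates the statistical structure of a two-cell-type,
allele-aware histone-mark ChIP-seq study:

* **Genome.** `n_chroms` × `chrom_length` (default 2 × 1 Mb) of i.i.d.
  bases at `background_gc` = 0.40, as two full haplotype sequences that
  differ only at SNP positions (maternal = reference by convention).
* **Genes and promoter islands.** 50 genes (2 kb bodies, random strand),
  each with a CpG island (500–1500 bp, G+C 0.60) centred on its TSS.
  Island sequence interleaves explicit CpG dinucleotides (enough for an
  observed/expected CpG target of ~1.6) into an i.i.d. fill whose
  composition is adjusted so the overall G+C hits the target — the simplest
  model that exercises both the G+C and the CpG-o/e code paths. No
  dinucleotide model elsewhere.
* **ICR analogs.** 5 island-like loci (1 kb) carrying 10 SNPs each; every
  SNP lies inside exactly one ICR.
* **Repeat classes.** `(class, copies, unit length, unit G+C)` defaults:
  LTR 30 × 400 bp at 0.58, LINE 30 × 1 kb at 0.55, SINE 60 × 150 bp at
  0.56, satellite 30 × 500 bp at 0.35. The G+C-rich classes sit above the
  enrichment breakpoint and therefore come out enriched; the satellite
  analog sits below it and does not. This encodes the *enrichment-follows-
  G+C* structure of the study system; it does not reproduce RepeatMasker
  compositions (real LINEs are A/T-richer).
* **Enrichment field.** Per-window relative ChIP sampling weight derived
  from the G+C track: 1 below `gc_breakpoint` (0.5), rising linearly to
  `max_fold` (8) at breakpoint + 0.25, ICR windows further multiplied by
  `icr_boost` (3), then renormalized to mean 1. The true functional form of
  enrichment versus G+C in real data is unknown; monotone-above-breakpoint
  is a declared modeling choice. Note the two natural conventions —
  "below-breakpoint weight exactly 1" and "genome-wide mean exactly 1" —
  are mutually exclusive once any window is boosted; the mean-1 convention
  is used (sampling renormalizes weights regardless), so below-breakpoint
  windows carry weight 1/Z with Z ≈ 1.07 at defaults. Consequently the
  expected read-fraction ratio of a neutral repeat class is its mean window
  weight (≈0.93), slightly below 1; tests assert that exact oracle.
* **Libraries.** Fragment midpoints are the sampled positions (uniform per
  window for input, weight-proportional for ChIP), which makes expected
  window counts exactly proportional to the field — a clean oracle. One
  50-bp read per 200-bp fragment, 5′ end flanking the fragment on a random
  strand. ICR-overlapping ChIP reads derive from the maternal haplotype
  with probability `allelic_fraction` (0.9); everything else is 50:50.
  Reads report the true haplotype base (sequencing error rate is a config
  option, default 0). Default depth 2 × 10^5 ChIP + 2 × 10^5 input tags per
  cell type; two cell types share one field.

What the simulator does **not** model: duplicate reads and PCR artifacts,
mappability and alignment error, fragment-size dispersion, chromatin
contamination structure, dinucleotide composition outside islands, and any
cell-type difference in the underlying field. Passing closed-loop tests
therefore demonstrates correctness of the analysis arithmetic under the
stated generative model, not robustness to those real-data artifacts.

## Tracks

Extension follows the fixed-fragment convention: a plus-strand tag at 5′
position s becomes [s, s+200); a minus-strand tag ending at e becomes
[e−200, e); both clipped at chromosome bounds. Window counts use ≥1-bp
overlap (pileup-style), while the simulator samples midpoints — the two
agree in expectation, which the tests exploit. Per-million scaling uses the
library's total tag count. Smoothing is a centered moving average over
2·`half_width`+1 windows (default half_width 2 ≈ 500 bp), truncated at
chromosome ends by dividing by the actual window count; the exact kernel of
published density pipelines is rarely stated, so this is a declared config
default, not a claim about any particular tool. Enrichment is
(chip+c)/(input+c) on per-million tracks with pseudocount c = 1 per-million
unit (config-exposed).

## Peak calling

A transparent local-Poisson caller. Simplifications relative to the classic
implementation, stated openly: no fragment-shift model estimation
(extension fixed at 200 bp), no duplicate filtering, the candidate unit is
the fixed 100-bp window rather than a sliding 2×bandwidth window, and
λ_local is the maximum of the genome-wide mean and centered 1/5/10-kb means
of the input only, after linear rescaling of the input to ChIP depth (the
even spans are widened by one window to stay centered). The statistical
core — upper-tail Poisson test at P < 1e-5 against a max-of-lambdas
background — is preserved and is verified window-for-window against a
brute-force scan. Candidates separated by ≤ `merge_gap` (100 bp) merge;
summit = center of the candidate window with maximal ChIP count (leftmost
on ties, for determinism); peak `chip_count` and `lambda_local` are summed
over the merged *candidate* windows (not intervening gap windows), keeping
fold enrichment coherent with the tested windows. Counts are integers by
construction; values are rounded defensively before testing. Output is
narrowPeak (signal = fold, pValue = −log10 p, qValue = −1). No q-values/FDR
(thresholding is on P), no broad-peak mode, no paired-end handling.

## Annotation

CpG islands: 200-bp windows sliding at step 1; windows with G+C > 0.5 and
o/e CpG > 0.6 (CpGs counted fully inside the window; windows containing N
skipped entirely) seed islands; overlapping/adjacent passing windows merge
and the merged region is re-scored, kept only if it itself passes all three
criteria, with strict inequalities — so an isolated single seed (length
exactly 200) is dropped. Merge-then-rescore is one of several published
variants; recovery of planted islands, not agreement with any external
island list, is the validation surface. Peak localization uses precedence
promoter > gene body > intergenic with promoter = TSS ± 1000 bp
(config-exposed; "promoter" has no canonical width). Promoter marking
counts distinct promoters overlapped by ≥1 peak. Repeat accounting assigns
a tag to a class when its 5′ position lies in a class interval; overlapping
classes each count the tag once (classes are reported independently);
within a class, intervals are merged first so a tag is never double-counted.

## G+C landscape

Non-overlapping 100-bp windows (sliding windows exist only inside the
island detector), G+C per window over the window's actual length (the final
partial window divides by its true size), NaN for windows containing N.
Stratification bins have width 0.05 (the display binning of enrichment-vs-
G+C figures is conventional, not canonical); empty bins are absent, not
zero, and both mean and median are emitted because either may be the
quantity plotted in comparable studies. Group comparisons use the rank-sum
test below.

## Statistics

* Poisson upper tail: survival function of the Poisson distribution
  (regularized incomplete gamma), stable in log space; verified against
  direct series summation to 1e-12 relative error for counts ≤ 50.
* Exact binomial: two-sided minimum-likelihood convention (sum of all
  outcome probabilities no larger than the observed outcome's); verified
  against full 2^n enumeration for n ≤ 12.
* Rank-sum: exact by enumeration of all C(n, n_a) group assignments of the
  observed (midranked) pooled values when n_a + n_b ≤ 12, with two-sided
  p = 2·min(P(W ≤ w), P(W ≥ w)) capped at 1; otherwise the normal
  approximation with tie and continuity corrections. The exact branch is
  verified against an independent permutation oracle for all group sizes
  ≤ 6, including ties.

## Profiles and clustering

Anchor matrices are rows of track values in `bin`-bp bins (bin must be a
multiple of the track window; each bin averages the windows it covers)
across ± `flank` (5 kb) around the anchor point — TSS for stranded anchors,
midpoint for intervals (CpG islands are conventionally analyzed
non-oriented). Minus-strand rows are reversed in oriented mode so column 0
is always upstream; out-of-genome bins are NaN. Enrichment grouping is
quantile-based with ties broken by genomic order (group 0 = most enriched).
Clustering is k-means on rows (NaN imputed as row mean): greedy
farthest-point initialization from a seeded start, Lloyd refinement, labels
relabeled by descending cluster mean signal for stable output. Clustering
is validated by recovery of constructed structure; no attempt is made to
match any specific heatmap tool's normalization. Display caps (e.g. a 0–60
color range) are presentation choices and never enter computation.

## Co-enrichment

Joint tables pair windows analyzable in both tracks, in genomic order.
The hexbin is a pointy-top tessellation with `gridsize` hexagons across the
transformed x-range, alternate rows offset by half a hexagon width; the
lattice is the union of two rectangular sublattices, so nearest-center
assignment reduces to rounding into each sublattice and taking the closer
candidate (verified against brute-force distance minimization). Axis
transforms: identity, log10(1+x), asinh — the standard compressions for
count-like signals. Correlation defaults to log10(1+x)-transformed values
(declared, since published figures state transforms only for axes), with
identity available; the pipeline's headline cross-sample correlation is
reported on untransformed smoothed densities — the plain reading of a
"Pearson's r" between two samples' window signals — alongside the
transformed value. Matrix cells use pairwise-complete windows; undefined
cells (zero variance) are NaN, the diagonal is 1.

## Allelic analysis

Assignment is conservative: a tag is maternal/paternal only if *every*
informative base matches that haplotype; a non-allelic base or a
conflicting pair discards the tag (no majority voting, no error-model
genotype likelihoods), mirroring how direct-sequencing traces are read.
Locus classification defaults — ≥10 informative tags, ratio cutoff 0.7,
exact-binomial α = 0.01 — are artifact conventions, config-exposed; the
qualitative readouts such analyses rest on in practice print no numeric
cutoffs. The symmetric contracts (swapping parental labels swaps counts,
maps ratio to 1−ratio, leaves p unchanged) are tested. Haplotypes are
given, never phased.

## Pipeline

One global seed; per-stage seeds derive from CRC32 of the stage name XOR
the seed (one knob, independent streams, all below 2^31). Stages run in
fixed order (simulate → tracks → callpeaks → annotate → gcstrata →
profiles → coenrich → allelic), each writing its outputs before the next
starts; disabling peaks skips the peak-dependent outputs with explicit log
entries. The manifest records a config hash and a SHA-256 per output file;
identical config + seed reproduces identical checksums. The config echo
excludes the output directory (a path is not part of the analysis).
Problem sizes used throughout testing: the default 2 × 1 Mb / 2 × 10^5-tag
study for recovery checks, and a 2 × 100 kb / 2 × 10^4-tag variant for
fast closed-loop sweeps; both run in seconds to minutes on one CPU.

## Known limitations

* The window grid is the resolution floor everywhere: summits are window
  centers, island boundaries are base-precise but profile bins are not.
* The caller's specificity guarantee is asymptotic in the Poisson model;
  overdispersed real backgrounds would need a local-lambda model richer
  than input means.
* The generator's diploidy is SNP-only (no indels/SVs), so read placement
  is identical across haplotypes by construction.
* Exact rank-sum enumeration is exponential; the 12-observation cap is a
  hard switch, not a continuity-matched blend, so p-values straddling the
  switch use different conventions.
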