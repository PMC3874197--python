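# Example configuration: every stage default, ready to edit.
# Run with: chipscape run-all --config config.example.yaml --seed 1 --outdir out
seed: 0
outdir: chipscape_out
synthetic:
  n_chroms: 2
  chrom_length: 1000000
  background_gc: 0.4
  n_genes: 50
  gene_length: 2000
  promoter_gc: 0.6
  cgi_length_range:
  - 500
  - 1500
  n_icrs: 5
  icr_length: 1000
  n_snps_per_icr: 10
  repeat_spec:
  - - LTR
    - 30
    - 400
    - 0.58
  - - LINE
    - 30
    - 1000
    - 0.55
  - - SINE
    - 60
    - 150
    - 0.56
  - - satellite
    - 30
    - 500
    - 0.35
  read_length: 50
  error_rate: 0.0
  gc_breakpoint: 0.5
  max_fold: 8.0
  icr_boost: 3.0
  allelic_fraction: 0.9
  n_chip: 200000
  n_input: 200000
  fragment_length: 200
tracks:
  window_size: 100
  pseudocount: 1.0
  smooth_half_width: 2
peaks:
  enabled: true
  p_threshold: 1.0e-05
  merge_gap: 100
  local_windows:
  - 1000
  - 5000
  - 10000
annotate:
  promoter_window: 1000
gcstrata:
  bin_width: 0.05
profiles:
  flank: 5000
  bin: 100
  n_groups: 4
  k_clusters: 3
coenrich:
  transform: log10_1p
  gridsize: 50
allelic:
  min_informative: 10
  ratio_cutoff: 0.7
  alpha: 0.01
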