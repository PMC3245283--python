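# Demo pipeline run: a small simulated experiment that finishes in seconds.
# All filter thresholds default to the published values
# (window 500, rpm > 20, ratio > 20, p < 0.001, +/-5 kb flank).
outdir: demo_run
seed: 42
sim:
  n_chroms: 1
  chrom_length: 200000
  n_genes: 6
  gene_length_range: [3000, 6000]
  n_cgis: 6
  cgi_length: 1500
  n_repeats: 12
  repeat_length_range: [300, 600]
  region_size: 4000
  n_dmrs: 10
  reads_per_library: 40000
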