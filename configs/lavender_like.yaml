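# Lavender-like demo: two WGDs (29.6 and 6.9 MYA), outgroup split 36.4 MYA,
# synonymous rate 6.59e-9 /site/year (simulator default), retention 0.7.
# The full chain (homology -> synteny -> Ks -> mixture -> dating) should
# recover both WGD dates and the calibrated rate.
seed: 1
outdir: results/lavender_like
sim:
  n_chrom: 2
  genes_per_chrom: 120
  codons_per_gene: 300
  wgd_times_mya: [29.6, 6.9]
  retention_per_wgd: 0.7
  outgroup_split_mya: 36.4
params:
  min_identity: 50.0
  max_evalue: 1.0e-20
  min_anchors: 5
  max_gap: 25
  divergence_mya: 36.4
  correlation_cutoff: 0.7
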