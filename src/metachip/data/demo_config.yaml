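# Demo configuration: a small end-to-end run on simulated data.
# `metachip simulate --config demo_config.yaml --outdir demo` writes a fixture
# directory that the profile/rank/overlap/motif subcommands consume unchanged.
seed: 1

binning:
  n_body_bins: 10
  flank_bp: 3000
  n_flank_bins: 20
  smooth_window: 5

simulate:
  n_genes: 150
  gene_length: [1000, 3000]
  intergenic: [3000, 5000]
  probe_spacing: 50
  probe_length: 50
  baseline: 1.0
  bump_center: -150.0
  bump_sd: 400.0
  noise_sd: 0.2
  frac_marked: 0.6
  repeat_frac: 0.3
  promoter_len: 500
  amplitudes:
    wt: {starved: 1.3, fed: 1.2}
    oga-1: {starved: 1.1, fed: 1.6}

paths:
  genes: genes.bed
  marked_genes: marked_genes.txt
  gene_sets: [marked_genes.txt]
  promoters_fasta: promoters.fasta
  background_fasta: background.fasta
  expression: expression.tsv
  tracks:
    - {sample: wt_starved, path: wt_starved.bedgraph, genotype: wt, condition: starved}
    - {sample: wt_fed, path: wt_fed.bedgraph, genotype: wt, condition: fed}
    - {sample: oga1_starved, path: oga1_starved.bedgraph, genotype: oga-1, condition: starved}
    - {sample: oga1_fed, path: oga1_fed.bedgraph, genotype: oga-1, condition: fed}

rank:
  fed: oga1_fed
  starved: oga1_starved
  bin_size: 25

responsiveness:
  threshold_log2: 1.5
  bin_size: 25

overlap:
  universe_size: 150
  lists: [delta_top.txt, delta_bottom.txt, marked_genes.txt]

motif:
  k: 8
  collapse_rc: true
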