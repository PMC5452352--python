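# Demo study: a small two-temperature splicing experiment with three
# genotypes (wild type plus two histone-methyltransferase mutants).
sim:
  seed: 21
  n_genes: 60
analysis:
  n_draws: 20000
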