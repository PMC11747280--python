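# Demo study: two 12 Mb chromosomes, six induced breaks, WT vs cohesin-depleted.
seed: 7
genotypes: [WT, RAD21-]
genome:
  n_chrom: 2
  chrom_length: 12000000
  n_asisi: 10
  n_cut: 6
  n_baits: 2
  min_cut_spacing: 2400000
hic:
  depth: 300000.0
junctions:
  n_junctions: 2000
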