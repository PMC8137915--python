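# Default synthetic study: mouse-like 20-chromosome genome, six Rb fusions,
# round-spermatid maps at 500 kbp with a 50-kbp TAD zoom.
outdir: out
seed: 1
n_chrom: 20
genome_scale: 1.0
resolution: 500000
tad_resolution: 50000
n_pairs: 1000000
cell_types: [RS]
fusions:
  chr3|chr8: heterozygous
  chr6|chr10: heterozygous
  chr5|chr15: heterozygous
  chr9|chr11: homozygous
  chr12|chr13: homozygous
  chr4|chr14: homozygous
min_count: 10
z_threshold: 2.58
overlap_threshold: 0.75
het_bounds: [1.2, 1.6]
hom_threshold: 1.8
insulation_window: 10
tad_delta: 0.5
foci_n_cells: 40
foci_n_individuals: 3
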