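# robfusion3d

Analysis of how Robertsonian (Rb) chromosomal fusions reshape the
three-dimensional folding of the genome and the meiotic recombination
landscape in the house mouse.

Rb fusions join two acrocentric chromosomes at their centromeres into a
single metacentric. In wild mice carrying such fusions, this has consequences
at every level of nuclear organization: chromosomes involved in fusions show
concentrated heterologous (trans) contact at their pericentromeric ends,
inter-/intrachromosomal contact ratios shift in a cell-type-specific way
through spermatogenesis, A/B compartments and TADs reorganize, and the
distribution of crossovers (COs, cytologically MLH1 foci on the synaptonemal
complex) along chromosome arms is displaced. This package implements the full
analysis stack for that study design — Hi-C style contact-map processing,
fusion detection and zygosity classification, compartment and TAD dynamics,
and crossover-landscape statistics — together with a synthetic-data generator
that emulates the study's cell types, so every step is testable without
external data.

## The statistics at the core

* **Matrix processing.** Valid contact pairs are binned into a genome-wide
  symmetric matrix at a fixed resolution (50 kbp or 500 kbp), bins with a
  marginal below `min_count = 10` are masked, and the matrix is balanced by
  iterative correction (ICE) so every unmasked bin has equal visibility.
  Observed/expected transforms divide each cis cell by the mean contact at
  its genomic separation (sum of contacts at that separation over the number
  of possible bin pairs), differential maps are `log2((B + c) / (A + c))`,
  and replicate agreement is a stratum-adjusted correlation of 2D-smoothed
  maps (smoothing radius 5, separations beyond 10 Mbp, chrY excluded, one
  score per chromosome).
* **Fusion detection and zygosity.** A fusion mapped onto the standard
  acrocentric reference appears as trans contact between the partners'
  pericentromeric ends. Per chromosome pair the summed trans contact is
  standardized against a robust expected value, `z = (N − E)/√E`, and pairs
  beyond `median + k·MAD` are flagged. In haploid round spermatids the
  fused-pair **interaction ratio** (fused-pair mean per-bin-pair trans
  contact over the mean among pairs of non-fused chromosomes) reads out
  zygosity: ≈ 2 for homozygous fusions (every nucleus carries the
  metacentric) and 1.2–1.6 for heterozygous ones (half do).
* **Ectopic trans regions.** Per-bin trans signal is Z-scored across
  informative bins; bins with Z > 2.58 in the Rb map and not in the standard
  map are condition-specific interchromosomal regions, intersectable with
  promoter windows (−2 kbp to the TSS, strand-aware).
* **Compartments and TADs.** A/B compartments come from the sign of the
  leading eigenvector of the per-chromosome O/E correlation matrix, oriented
  by gene density; switching is the fraction of informative bins changing
  label. Insulation is the log2 ratio of each bin's diamond mean to the
  chromosome average; boundaries are insulation minima with prominence above
  a threshold (the border score), and domains between boundaries are classed
  stable / merged / split / rearranged between conditions by a 75 %
  reciprocal-overlap rule.
* **Recombination.** Per chromosome arm the MLH1 focus count (0/1/2/3+),
  focus positions as % of axis length from the centromere in ten intervals,
  CO density (foci/µm), synaptonemal-complex axis lengths, stratification by
  synapsis state and by single/double centromeric signal, and the MLH1–RAD51
  (CO–DSB) relationship across individuals — compared with the study's
  nonparametric battery (Mann–Whitney, Kruskal–Wallis, Wilcoxon rank-sum,
  Pearson's χ², Spearman, Dunn's tests with Bonferroni adjustment).

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic data
(seed 1 by default; `scratch/` holds bulky intermediates, `results/` the
tables):

```bash
python analysis/01_simulate_cohort.py     # pair files + foci tables
python analysis/02_build_matrices.py      # bin, mask, ICE, reproducibility
python analysis/03_fusion_topology.py     # detection, zygosity, regions
python analysis/04_compartments_tads.py   # compartments, TADs, meta-borders
python analysis/05_recombination.py       # crossover landscape
```

`03_fusion_topology.py` prints, for a round-spermatid map simulated with six
fusions (3.8, 6.10, 5.15 heterozygous; 9.11, 12.13, 4.14 homozygous):

```
zygosity calls (100% agree with simulated truth):
       pair  interaction_ratio     zygosity        truth
  chr3|chr8              1.513 heterozygous heterozygous
 chr10|chr6              1.497 heterozygous heterozygous
 chr15|chr5              1.437 heterozygous heterozygous
 chr11|chr9              2.030   homozygous   homozygous
chr12|chr13              1.941   homozygous   homozygous
 chr14|chr4              2.061   homozygous   homozygous

pericentromeric trans, fused vs non-fused chromosomes: Mann-Whitney p = 7.80e-03
Rb-specific PD trans regions (Z > 2.58): 45 bins of 5274 informative (0.85% of the genome)
```

All six fusions are detected with no false positives, the interaction ratios
separate cleanly into the heterozygous (≈ 1.5) and homozygous (≈ 2) classes,
fused pericentromeres carry significantly more trans contact per million than
non-fused ones, and under one percent of the genome is called as
Rb-specific interchromosomal territory in primary spermatocytes.

The same pipeline runs end to end from one config:

```bash
robfusion3d run --config configs/example.yaml --seed 1 --out out/
robfusion3d simulate hic --cell-type RS --seed 1 --out rs.pairs.tsv
robfusion3d simulate foci --seed 1 --out foci.tsv
```

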