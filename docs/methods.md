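# Methods

## Scope and design

The package reimplements, as a tested pipeline over synthetic data, an
analysis of how Robertsonian (Rb) fusions alter 3D genome folding and meiotic
recombination in the mouse. Real inputs would be valid Hi-C contact pairs and
spermatocyte immunofluorescence foci tables; the `simulate` module generates
both with the statistical structure the downstream operations assume, so the
whole stack is exercised end to end at desk scale. All coordinates are
0-based and half-open; bins are `[start, start + resolution)`; the assembly
is acrocentric (centromere at position 0 on every chromosome), mirroring the
mouse karyotype in which fusions arise.

## The contact-pair generator

Contacts are drawn from an explicit finite mixture. Component masses are
relative weights (cis fixed at 1.0):

| component | what it emulates | draw |
|---|---|---|
| cis | distance-dependent polymer contact | chromosome ∝ length; separation `s ~ s^(−α)` on [1 kbp, L]; modulated by plaid and TADs via rejection |
| trans background | random heterologous contact | both ends length-proportional, distinct chromosomes |
| chromocenter | pericentromeric clustering in round spermatids | partner chromosomes length-proportional; positions in the first 3.5 Mbp |
| fused arms | the Rb fusion junction seen in unfused coordinates | positions in the partners' first 3.5 Mbp; one component per fusion |
| loops | corner peaks of loop domains | pairs pinned to consecutive TAD boundary pairs |

Latent structure is planted once per simulation: the A/B plaid is derived
deterministically from the assembly's blocky gene-density track (gene-rich
blocks, mean 2 Mbp, are the A compartment; same-compartment cis pairs are
enriched by `1 + compartment_strength`), and TAD boundaries are drawn with
domain lengths uniform in 0.5–1.5× the 800 kbp mean (within-domain pairs
enriched by `1 + tad_strength`).

Cell-type profiles encode the study's qualitative regimes and are package
defaults, not measured values: fibroblast (α = 1.0, crisp plaid 0.8, TADs
1.5, trans 0.15), pachytene/diplotene P/D (α = 0.7, faded plaid 0.1, weak
TADs, trans 0.15 with a ×2 meiotic boost, no chromocenter), round spermatid
RS (α = 1.3, plaid 0.6, trans 0.10, chromocenter 0.03).

Three generator choices deserve note:

* **Penetrance by thinning.** A fusion's component is selected with a
  p-independent weight; with probability `1 − p` the draw falls back to an
  ordinary trans pair. This models the haploid round-spermatid population —
  a heterozygous fusion is present in half the nuclei — and makes the
  expected fused pericentromeric mass exactly linear in penetrance
  (homozygous p = 1, heterozygous p = 0.5).
* **Size-normalized fusion mass.** Each fusion's weight is scaled by its
  partner length product relative to the genome-mean pair product. The
  zygosity statistic is a per-bin-pair mean, so a fixed mass would make the
  ratio depend on which chromosomes fused; the normalization makes all
  fusions of one zygosity share one ratio, as observed.
* **Length-proportional chromocenter partners.** Drawing chromocenter
  partners uniformly over pairs would hand small chromosome pairs a
  systematically inflated per-bin-pair mean (a structural outlier unrelated
  to fusions); length-proportional drawing keeps the per-cell contribution
  uniform across pairs.

`fused_arm_weight` is the one calibrated constant: fixed once by
`scripts/calibrate_fused_arm_weight.py` so that penetrance-1.0 simulations of
the mouse-like 20-chromosome genome (10⁶ pairs, 500-kbp bins, masked raw
counts) give a mean fused-pair interaction ratio of 2.0, the homozygous
value. The frozen result is 6.80 × 10⁻⁴. Because the fused excess is linear
in penetrance on raw counts, heterozygous maps then land at ≈ 1.5, inside
the printed 1.2–1.6 interval, with no further tuning.

The foci generator draws, per chromosome arm: a CO count from the arm type's
categorical over {0, 1, 2, 3}; focus positions from Beta densities on
relative axis position (single-CO arms distal-skewed, two-CO arms
proximal + distal); axis length from a Normal (means 8.5 µm MetHet > 7.5 µm
acrocentric > 6.5 µm MetHom, encoding the observed axis elongation in
heterozygotes and shortening in homozygotes); a synapsis state for MetHet
arms (synapsed 0.60 / open 0.25 / asynapsed 0.15), with COs on asynapsed
arms concentrated at a synapsis boundary near 40 % of arm length; a
double-centromere flag for MetHom arms (probability 0.20, within the
observed 8–34 % range) that displaces COs distally by 15 points; and a
per-cell RAD51 count, Poisson with mean 10 × the cell's CO total.

## Matrix operations

* **ICE.** Single-pass marginal correction per iteration; convergence when
  the relative variance of unmasked marginals falls below `tol = 1e-5`
  (≤ 200 iterations). Zero-marginal bins are auto-masked. Weights satisfy
  `raw = balanced · w_i · w_j`, so raw counts are recoverable.
* **O/E.** Cis expected per separation is pooled over the genome: the sum of
  contacts at that bin separation divided by the number of possible unmasked
  bin pairs at it (strata with none are skipped). Trans cells are divided by
  the global mean over possible unmasked trans cell pairs — the named
  upstream tools handle cis only, so the trans convention is this package's
  documented choice. Cells that are zero in the sparse map stay zero, which
  is also their correct O/E.
* **Differential maps** use a pseudocount of 1 raw-count equivalent by
  default (zero handling is unstated upstream).
* **Reproducibility.** Per chromosome, cis maps are mean-filtered (radius 5
  bins); per distance stratum the Pearson correlation of the two smoothed
  diagonals is taken over positions whose filter window is complete (the
  shared edge-truncation profile would otherwise correlate any two maps),
  and strata are combined with weights `N·sd_a·sd_b`. The study's
  "considered distance over 10 Mbp" is read literally as a lower bound;
  `distance_mode="max"` gives the conventional upper-bound reading. chrY is
  excluded by default, yielding 20 scores on the mouse karyotype whose mean
  is the replicate score.

## Fusion topology

The per-pair statistic is the mean per-bin-pair trans interaction (denominator
= unmasked bin-pair count, so chromosome size cancels). Detection standardizes
the pair totals as `z = (N − E)/√E`, where `E` is the median per-cell density
times the pair's cell count — variance-stabilized (unit variance under a
Poisson null for any pair size) and invariant under global rescaling — and
flags `z > median + k·MAD`. The default `k = 8` puts the threshold at ≈ 5.4 σ:
small enough that heterozygous fusions (≈ +10 σ at 10⁶ pairs) are found, as
all six fusions are in every cell type, and large enough that no false
positive is expected across hundreds of null maps (at ≈ 3.4 σ, the
5-MAD threshold familiar from outlier work, each 190-pair map would carry a
~7 % false-positive chance).

Zygosity is the fused-pair mean over the mean among pairs of chromosomes not
involved in any fusion; heterozygous in [1.2, 1.6], homozygous at ≥ 1.8
(operationalizing "around 2"), ambiguous otherwise; thresholds configurable.
Pair-ratio statistics run on masked **raw** (depth-normalized) matrices: ICE
nearly doubles fused pericentromeric marginals and then suppresses them,
making the ratio concave in penetrance (a homozygous-calibrated weight would
push heterozygous maps to ≈ 1.67); on raw counts the excess is exactly
linear, and the statistic is scale-free. ICE-balanced matrices remain the
input for O/E, compartments, TADs and region calling.

Trans-region calling Z-scores each bin's summed trans signal against the
distribution of that signal across informative bins (bins, not cells, are
the paper's unit); bins with Z > 2.58 in the Rb map that do not also exceed
the threshold in the standard map are reported with their strongest partner
chromosome. On an i.i.d. Gaussian null with an independent null as the
comparison map, the called fraction is the one-sided 2.58 tail times the
probability the comparison bin is quiet, ≈ 0.49 % — the calibration the
acceptance script recomputes. A perfectly flat trans distribution calls
nothing (rather than erroring): nothing stands out.

## Compartments and TADs

Compartments are called per chromosome (trans artifacts stay out): O/E →
Pearson correlation over unmasked, non-constant bins → leading eigenvector,
scaled by √eigenvalue (only the sign is interpreted), oriented so the
positive sign has the higher mean gene density; A where positive, B where
negative, NA at exact zeros and masked bins. Chromosomes with fewer than 10
informative bins are skipped with a warning.

Insulation is single-scale diamond insulation: for bin *i*, the mean contact
in `{(u, d): i−w ≤ u < i < d ≤ i+w}` (default w = 10 bins), as log2 over the
chromosome mean diamond, undefined within w bins of ends and masks; a zero
diamond maps to −∞ (an infinitely strong boundary, kept as such). The
implementation stores only the 2w-wide diagonal band, so genome-wide 50-kbp
tracks are cheap; a brute-force oracle checks it in the suite. Boundaries
are local minima with prominence (depth below the lower flanking local
maximum) above `delta`; the default `delta = 0.5` separates planted
boundaries (depth ≈ log2(1 + tad_strength) ≈ 1.3) from shallow
counting-noise minima (≲ 0.4 at realistic depths); at 0.1 the planted-domain
precision target is unreachable. Reorganization classes follow the 75 % rule:
stable = reciprocal overlap above threshold; merged = the domain covers ≥ 75 %
of two or more partner domains; split = one partner domain covers it and at
least one sibling; rearranged otherwise — so swapping conditions exchanges
merged and split, a property the suite asserts against an independent
interval oracle.

## Recombination statistics

Positions are measured from the centromere (0 %) to the distal telomere
(100 %); for double-centromere arms the proximal signal defines the origin.
Counts above 3 are binned as "3+". Histograms use ten half-open intervals
with the last closed. Pearson's χ² is computed without continuity
correction and flagged when any expected count is below 5. Mann–Whitney
p-values are exact on small tie-free samples (checked against full rank
enumeration). Dunn's post-hoc z-tests on mean ranks use the standard tie
correction and Bonferroni capping, `min(1, m·p)`. Interindividual CO
variation is the coefficient of variation of per-cell MLH1 counts per
individual; the CO/DSB ratio is per-individual `mean(MLH1)/mean(RAD51)`,
with the Spearman correlation across ≥ 3 individuals.

## Pipeline

`run_pipeline` drives simulate → matrices → topology → compartments → TADs →
recombination from a `PipelineConfig` (YAML-loadable), writing stage outputs
and a `report.json` keyed by seed. Chromosome-scale statistics run on the
full-length 20-chromosome genome at 500 kbp (10⁶ pairs by default — the
scale at which the zygosity calibration holds). Sub-megabase TAD statistics
run on a dedicated 20-Mbp single-chromosome zoom at 50 kbp with matched
depth: spread over the whole genome, desk-scale pair counts leave diamond
means noise-dominated and boundary calls meaningless, so the pipeline zooms
rather than pretending genome-wide 50-kbp calls are informative.

## What the synthetic data does and does not show

The generator reproduces the features the statistics consume: power-law cis
decay with cell-type exponents, a plaid tied to gene density, block TADs
with corner peaks, uniform trans background with meiotic elevation,
chromocenter clustering, penetrance-scaled fusion contact, and categorical
CO counts/positions with the observed arm-type orderings. It does not model
polymer physics, restriction fragments, mappability or copy-number artifacts,
distance-dependent plaid attenuation, loop extrusion dynamics, or CO
interference (foci within an arm are drawn independently). Consequently,
passing tests certify the correctness and calibration of the *statistics* —
recovery of planted structure, null behavior, threshold semantics — not that
real chromatin behaves like the generator. Two desk-scale honesty notes:
replicate-reproducibility scores on half-sampled synthetic maps are low
(along-stratum heterogeneity at 500 kbp is mostly sub-bin in the generator,
so strata are noise-dominated), and round-spermatid compartment calls at 10⁶
pairs are depth-limited — the fibroblast profile, whose plaid is strongest,
is the reference for label-accuracy checks, as real RS compartment analyses
rest on far deeper libraries.

## Known limitations

* The zygosity thresholds are calibrated for the packaged RS profile on
  500-kbp maps; other profiles reuse the same fused-arm weight but their
  ratios are not separately calibrated.
* The trans-region caller assumes an approximately unimodal per-bin trans
  distribution; maps dominated by chromocenter signal veto pericentromeric
  calls through the comparison-map filter by design (such bins are hot in
  both conditions).
* Dunn's test uses the normal approximation (no exact small-sample mode).
* The reproducibility score is a single-scale stratum-adjusted correlation,
  not the named multi-resolution tool; agreement with it on real data has
  not been assessed.
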