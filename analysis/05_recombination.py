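"""Crossover landscape of the simulated spermatocyte cohort.

Reads the foci table written by 01_simulate_cohort.py and reproduces the study's
cytological summaries: per-arm CO-count categoricals with chi-square
comparisons, positional histograms and cumulative curves, CO density and
axis-length comparisons, synapsis- and centromere-stratified distributions,
the synapsis-boundary CO fraction, the MLH1-RAD51 relationship, and
interindividual variation.  Tables under results/recombination/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from robfusion3d.recomb import (
    axis_length_summary,
    co_density,
    co_dsb_relationship,
    interindividual_cv,
    positional_histogram,
    read_foci,
    stratified_distribution,
    summarize_counts,
    synapsis_boundary_co_fraction,
)

DATA = Path("scratch/cohort/foci.tsv")
OUT = Path("results/recombination")
OUT.mkdir(parents=True, exist_ok=True)

cells = read_foci(DATA)
print(f"loaded {len(cells)} cells from {len({c.individual_id for c in cells})} individuals")

counts = summarize_counts(cells)
rows = [
    {"arm_type": g, **{f"co_{k}": v for k, v in d.items()}}
    for g, d in counts["proportions"].items()
]
pd.DataFrame(rows).to_csv(OUT / "co_count_distribution.tsv", sep="\t", index=False)
print(
    f"CO-count distributions differ between arm types: "
    f"chi2 = {counts['chi_square']:.1f}, p = {counts['p_value']:.2e}"
)

hist_rows = []
for arm_type in counts["proportions"]:
    for n_co in (1, 2):
        try:
            h = positional_histogram(cells, arm_filter=arm_type, n_co_filter=n_co)
        except ValueError:
            continue
        for i, f in enumerate(h["frequencies"]):
            hist_rows.append(
                {
                    "arm_type": arm_type,
                    "n_co": n_co,
                    "interval": f"{10 * i}-{10 * (i + 1)}",
                    "frequency": f,
                    "cumulative": h["cumulative"][i],
                }
            )
pd.DataFrame(hist_rows).to_csv(OUT / "positional_histograms.tsv", sep="\t", index=False)

dens = co_density(cells)
print("CO density (foci/um):", {k: round(v, 3) for k, v in dens["mean_density"].items()})
axes = axis_length_summary(cells)
print("axis length (um):", {k: round(v, 2) for k, v in axes["mean"].items()})

strat = stratified_distribution(cells, "centromere_signals", arm_filter="MetHom")
for cen, h in strat["strata"].items():
    print(
        f"MetHom {cen}-CEN arms: median CO position interval "
        f"{10 * int(np.searchsorted(h['cumulative'], 0.5))}%+ ({h['n_foci']} foci)"
    )

syn = stratified_distribution(cells, "synapsis_state", arm_filter="MetHet")
print("MetHet synapsis strata sizes:", {k: v["n_arms"] for k, v in syn["strata"].items()})
frac = synapsis_boundary_co_fraction(cells, tolerance_pct=5)
print(f"fraction of COs at the synapsis boundary on asynapsed arms: {frac:.2f}")

dsb = co_dsb_relationship(cells)
dsb["per_individual"].to_csv(OUT / "co_dsb.tsv", sep="\t", index=False)
print(
    f"MLH1-RAD51 across individuals: Spearman rho = {dsb['spearman_rho']:.2f}, "
    f"mean CO/DSB ratio = {dsb['per_individual']['co_dsb_ratio'].mean():.3f}"
)
cv = interindividual_cv(cells)
cv.to_csv(OUT / "interindividual_cv.tsv", sep="\t", index=False)
print(f"interindividual CV of MLH1/cell: {cv['cv'].mean():.3f} (mean over individuals)")
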