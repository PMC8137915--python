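"""Chromosome-level topology: fusion detection, zygosity, ectopic regions.

Loads the matrices from 02_build_matrices.py and asks the questions the
study asks of its Hi-C maps: which chromosome pairs are fused, in which
zygosity, how fused and non-fused pericentromeres differ, and which bins
carry condition-specific trans interaction (Z > 2.58).  Tables go to
results/topology/.
"""

from pathlib import Path

import pandas as pd

from robfusion3d.matrix import load_matrix
from robfusion3d.pipeline import DEFAULT_FUSIONS
from robfusion3d.topology import (
    call_trans_interaction_regions,
    classify_fusion_zygosity,
    detect_fusions,
    inter_intra_ratio,
    interchromosomal_ratio_heatmap,
    pericentromeric_trans,
)

MAT = Path("scratch/matrices")
OUT = Path("results/topology")
OUT.mkdir(parents=True, exist_ok=True)

rb_raw = load_matrix(str(MAT / "RS_rb.raw"), 500_000)
st_raw = load_matrix(str(MAT / "RS_st.raw"), 500_000)
rb_ice = load_matrix(str(MAT / "RS_rb.ice"), 500_000)
st_ice = load_matrix(str(MAT / "RS_st.ice"), 500_000)

heatmap = interchromosomal_ratio_heatmap(rb_ice, st_ice)
heatmap.to_csv(OUT / "pair_ratio_heatmap.tsv", sep="\t", index=False)

ii = pd.concat(
    [
        inter_intra_ratio(rb_raw).assign(condition="rb"),
        inter_intra_ratio(st_raw).assign(condition="st"),
    ]
)
ii.to_csv(OUT / "inter_intra_ratio.tsv", sep="\t", index=False)

candidates = detect_fusions(rb_raw)
candidates.to_csv(OUT / "fusion_candidates.tsv", sep="\t", index=False)
print("detected fusion candidates:")
print(candidates[["chrom1", "chrom2", "ratio_to_median", "z_score"]].to_string(index=False))

truth_by_pair = {tuple(sorted(k)): v for k, v in DEFAULT_FUSIONS.items()}
calls = classify_fusion_zygosity(rb_raw, [tuple(p) for p in DEFAULT_FUSIONS])
zyg = pd.DataFrame(
    [
        {
            "pair": "|".join(c.chrom_pair),
            "interaction_ratio": round(c.interaction_ratio, 3),
            "zygosity": c.zygosity,
            "truth": truth_by_pair[c.chrom_pair],
        }
        for c in calls
    ]
)
zyg.to_csv(OUT / "zygosity.tsv", sep="\t", index=False)
agree = (zyg["zygosity"] == zyg["truth"]).mean()
print(f"\nzygosity calls ({agree:.0%} agree with simulated truth):")
print(zyg.to_string(index=False))

fused = {c for pair in DEFAULT_FUSIONS for c in pair}
nonfused = set(rb_raw.chrom_names) - fused - {"chrY"}
peri = pericentromeric_trans(rb_raw, fused=fused, nonfused=nonfused)
pd.DataFrame(
    [{"chrom": c, "trans_per_million": v} for c, v in peri["per_chrom"].items()]
).to_csv(OUT / "pericentromeric_trans.tsv", sep="\t", index=False)
print(
    f"\npericentromeric trans, fused vs non-fused chromosomes: "
    f"Mann-Whitney p = {peri['p_value']:.2e}"
)

# ectopic trans regions are called on primary-spermatocyte (PD) maps, where
# heterologous interaction redistributes genome-wide
pd_rb = load_matrix(str(MAT / "PD_rb.ice"), 500_000)
pd_st = load_matrix(str(MAT / "PD_st.ice"), 500_000)
regions = call_trans_interaction_regions(pd_rb, pd_st, z_threshold=2.58)
regions.bins.to_csv(OUT / "trans_regions.bed", sep="\t", header=False, index=False)
print(
    f"Rb-specific PD trans regions (Z > 2.58): {len(regions.bins)} bins "
    f"of {regions.n_informative} informative "
    f"({100 * regions.called_fraction:.2f}% of the genome)"
)
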