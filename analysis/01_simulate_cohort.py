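"""Simulate the synthetic study cohort.

Generates, for the Rb karyotype (six fusions: 3.8, 6.10, 5.15 heterozygous;
9.11, 12.13, 4.14 homozygous) and an all-acrocentric standard karyotype,
round-spermatid (RS) and pachytene/diplotene (PD) contact-pair files on a mouse-like 20-chromosome genome,
plus spermatocyte MLH1/RAD51 foci tables for three Rb and three standard
individuals.  Pair files and foci tables go to scratch/cohort/ (inputs for the later steps).
"""

import sys
from pathlib import Path

import pandas as pd

from robfusion3d.genome import Karyotype, mouse_like_lengths, simulate_genome
from robfusion3d.pipeline import DEFAULT_FUSIONS
from robfusion3d.profiles import default_foci_params, default_profile
from robfusion3d.simulate import (
    simulate_contact_pairs,
    simulate_foci_cells,
    write_chrom_sizes,
    write_foci,
    write_pairs,
)

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
N_PAIRS = 1_000_000
OUT = Path("scratch/cohort")
OUT.mkdir(parents=True, exist_ok=True)

genome = simulate_genome(20, mouse_like_lengths(20), seed=SEED)
write_chrom_sizes(genome, OUT / "chrom.sizes")

karyotypes = {
    "rb": Karyotype(list(DEFAULT_FUSIONS), dict(DEFAULT_FUSIONS)),
    "st": Karyotype([], {}),
}
for cell_type in ("RS", "PD"):
    profile = default_profile(cell_type)
    for i, (name, kt) in enumerate(karyotypes.items()):
        pairs = simulate_contact_pairs(
            genome, kt, profile, N_PAIRS, seed=SEED * 10 + 2 * i + (cell_type == "PD")
        )
        write_pairs(pairs, OUT / f"{cell_type}_{name}.pairs.tsv")
        print(f"wrote {len(pairs):,} {cell_type} pairs for the {name} condition")

params = default_foci_params()
tables = []
for ind in range(3):
    tables.append(
        simulate_foci_cells(
            params, 50, {"AcrRb": 7, "MetHet": 3, "MetHom": 3},
            seed=SEED * 100 + ind, individual_id=f"Rb{ind + 1}",
        )
    )
for ind in range(3):
    tables.append(
        simulate_foci_cells(
            params, 50, {"AcrSt": 19},
            seed=SEED * 100 + 50 + ind, individual_id=f"St{ind + 1}",
        )
    )
foci = pd.concat(tables, ignore_index=True)
write_foci(foci, OUT / "foci.tsv")
print(f"wrote foci for {foci['cell_id'].nunique()} cells, "
      f"{foci['individual_id'].nunique()} individuals -> {OUT / 'foci.tsv'}")
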