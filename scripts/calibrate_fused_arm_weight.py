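"""One-time calibration of the RS profile's fused_arm_weight.

Finds the fused-arm mixture weight at which a fully penetrant (homozygous)
fusion yields a mean fused-pair interaction ratio of 2.0 — the homozygous
value — on masked raw 500-kbp round-spermatid maps of the mouse-like
20-chromosome genome (10^6 pairs per map, averaged over seeds).  Pair-ratio
statistics are computed on depth-normalized raw counts (the ratio is
scale-free), under which the fused-pair excess is exactly linear in
penetrance, so the heterozygous (penetrance 0.5) ratio follows as ~1.5.
The result is frozen into
``robfusion3d.profiles.CALIBRATED_RS_FUSED_ARM_WEIGHT``.

Run from the repository root:

    python scripts/calibrate_fused_arm_weight.py [--seeds 8] [--target 2.0]
"""

from __future__ import annotations

import argparse

import numpy as np

from robfusion3d.genome import Karyotype, mouse_like_lengths, simulate_genome
from robfusion3d.matrix import bin_pairs, mask_low_count_bins
from robfusion3d.profiles import default_profile
from robfusion3d.simulate import simulate_contact_pairs
from robfusion3d.topology import classify_fusion_zygosity

FUSION = ("chr3", "chr8")


def mean_ratio(weight: float, n_seeds: int, n_pairs: int = 1_000_000) -> float:
    genome = simulate_genome(20, mouse_like_lengths(20), seed=0)
    karyotype = Karyotype([FUSION], {FUSION: "homozygous"})
    profile = default_profile("RS", fused_arm_weight=weight)
    ratios = []
    for seed in range(n_seeds):
        pairs = simulate_contact_pairs(genome, karyotype, profile, n_pairs, seed=seed)
        mat = mask_low_count_bins(bin_pairs(pairs, genome, 500_000))
        (call,) = classify_fusion_zygosity(mat, [FUSION])
        ratios.append(call.interaction_ratio)
    return float(np.mean(ratios))


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seeds", type=int, default=8)
    ap.add_argument("--target", type=float, default=2.0)
    args = ap.parse_args()

    # the excess ratio is linear in the weight, so the secant method converges
    # in a couple of iterations
    w0, w1 = 1e-3, 3e-3
    r0 = mean_ratio(w0, args.seeds)
    print(f"weight {w0:.4e} -> ratio {r0:.4f}")
    for _ in range(6):
        r1 = mean_ratio(w1, args.seeds)
        print(f"weight {w1:.4e} -> ratio {r1:.4f}")
        if abs(r1 - args.target) < 0.005:
            break
        w0, w1, r0 = w1, w1 + (args.target - r1) * (w1 - w0) / (r1 - r0), r1
        if w1 <= 0:
            raise RuntimeError("calibration diverged")
    print(f"\ncalibrated fused_arm_weight = {w1:.4e}")
    print("freeze this into robfusion3d.profiles.CALIBRATED_RS_FUSED_ARM_WEIGHT")


if __name__ == "__main__":
    main()
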