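"""A/B compartment calling from the leading eigenvector of the O/E correlation map.

Per chromosome, the observed/expected cis matrix over unmasked bins is turned
into a Pearson correlation matrix; the eigenvector of its largest eigenvalue
carries the plaid, and its sign is oriented so that the positive (A)
compartment has the higher mean gene density.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import ContactMatrix, observed_expected

__all__ = [
    "CompartmentTrack",
    "call_compartments",
    "compartment_sizes",
    "compartment_switch_ratio",
]


@dataclass
class CompartmentTrack:
    """Per-bin signed eigenvector values with A/B labels (NA where undefined)."""

    bins: pd.DataFrame  # chrom, start, end, eigen_value, label
    resolution: int

    def labels(self) -> np.ndarray:
        return self.bins["label"].to_numpy()


def call_compartments(
    matrix: ContactMatrix,
    gene_density: np.ndarray,
    min_bins: int = 10,
) -> CompartmentTrack:
    """Call A/B compartments per chromosome.

    ``gene_density`` is a per-bin nonnegative track matching the matrix bin
    table.  Chromosomes with fewer than ``min_bins`` unmasked bins are skipped
    (their bins are labeled NA).  Label A where the oriented eigenvector is
    positive, B where negative; exact zeros and masked bins are NA.
    """
    if len(gene_density) != matrix.n_bins:
        raise ValueError("gene_density length must match bin count")
    oe = matrix if matrix.metadata.get("oe") else observed_expected(matrix)
    out = matrix.bins[["chrom", "start", "end"]].copy()
    eigen = np.full(matrix.n_bins, np.nan)
    for chrom, sl in matrix.chrom_slices().items():
        block = np.asarray(oe.counts[sl, sl].todense())
        active = ~matrix.mask[sl]
        # bins with no variation carry no plaid information
        active &= block.std(axis=1) > 0
        if active.sum() < min_bins:
            warnings.warn(f"{chrom}: fewer than {min_bins} informative bins; skipped")
            continue
        sub = block[np.ix_(active, active)]
        corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        vals, vecs = np.linalg.eigh(corr)
        lead = vecs[:, -1] * np.sqrt(max(vals[-1], 0.0))
        dens = np.asarray(gene_density[sl], dtype=float)[active]
        mean_pos = dens[lead > 0].mean() if (lead > 0).any() else -np.inf
        mean_neg = dens[lead < 0].mean() if (lead < 0).any() else -np.inf
        if mean_neg > mean_pos:
            lead = -lead
        vec = np.full(sl.stop - sl.start, np.nan)
        vec[active] = lead
        eigen[sl] = vec
    out["eigen_value"] = eigen
    out["label"] = np.where(
        np.isnan(eigen) | (eigen == 0), "NA", np.where(eigen > 0, "A", "B")
    )
    return CompartmentTrack(bins=out, resolution=matrix.resolution)


def compartment_sizes(track: CompartmentTrack) -> dict:
    """Mean compartment size in bp per label and overall.

    Consecutive same-label runs (within a chromosome) merge into one
    compartment; NA bins break runs.
    """
    if len(track.bins) == 0:
        raise ValueError("empty compartment track")
    runs: dict[str, list[int]] = {"A": [], "B": []}
    for _, chrom_bins in track.bins.groupby("chrom", sort=False):
        labels = chrom_bins["label"].to_numpy()
        starts = chrom_bins["start"].to_numpy()
        ends = chrom_bins["end"].to_numpy()
        i = 0
        while i < len(labels):
            if labels[i] == "NA":
                i += 1
                continue
            j = i
            while j + 1 < len(labels) and labels[j + 1] == labels[i]:
                j += 1
            runs[labels[i]].append(int(ends[j] - starts[i]))
            i = j + 1
    sizes = {
        label: (float(np.mean(v)) if v else float("nan")) for label, v in runs.items()
    }
    all_runs = runs["A"] + runs["B"]
    sizes["overall"] = float(np.mean(all_runs)) if all_runs else float("nan")
    sizes["n_compartments"] = len(all_runs)
    return sizes


def compartment_switch_ratio(a: CompartmentTrack, b: CompartmentTrack) -> dict:
    """Conserved fraction of informative bins plus per-direction switch counts.

    Bins NA in either track are excluded from the denominator.  Also reports
    the Pearson r^2 between the two eigenvector tracks over shared bins.
    """
    if not a.bins[["chrom", "start", "end"]].equals(b.bins[["chrom", "start", "end"]]):
        raise ValueError("tracks have mismatched bin tables")
    la, lb = a.labels(), b.labels()
    informative = (la != "NA") & (lb != "NA")
    total = int(informative.sum())
    if total == 0:
        raise ValueError("no informative bins shared by the two tracks")
    a_to_b = int(((la == "A") & (lb == "B") & informative).sum())
    b_to_a = int(((la == "B") & (lb == "A") & informative).sum())
    switched = a_to_b + b_to_a
    ea = a.bins["eigen_value"].to_numpy()
    eb = b.bins["eigen_value"].to_numpy()
    both = np.isfinite(ea) & np.isfinite(eb)
    if both.sum() > 1 and ea[both].std() > 0 and eb[both].std() > 0:
        r2 = float(np.corrcoef(ea[both], eb[both])[0, 1] ** 2)
    else:
        r2 = float("nan")
    return {
        "conserved_fraction": 1.0 - switched / total,
        "switch_ratio": switched / total,
        "n_informative": total,
        "A_to_B": a_to_b,
        "B_to_A": b_to_a,
        "eigen_r2": r2,
    }
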