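"""Chromosome-level interaction structure: fusion detection, zygosity,
ectopic trans-region calling, pericentromeric and X-autosome quantification.

A Robertsonian fusion mapped onto the standard acrocentric reference appears
as concentrated trans contact between the pericentromeric ends of the two
partner chromosomes; in haploid round spermatids its dosage (zygosity) is
readable from the fused-pair interaction ratio: ~2 for homozygous fusions
(every nucleus carries the metacentric) and 1.2-1.6 for heterozygous ones
(half the nuclei do).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .matrix import ContactMatrix

__all__ = [
    "FusionCall",
    "TransRegionSet",
    "interchromosomal_ratio_heatmap",
    "inter_intra_ratio",
    "detect_fusions",
    "classify_fusion_zygosity",
    "call_trans_interaction_regions",
    "region_gene_overlap",
    "pericentromeric_trans",
    "chromosome_trans_distribution",
    "read_bed6",
]


@dataclass
class FusionCall:
    chrom_pair: tuple[str, str]
    interaction_ratio: float
    zygosity: str  # heterozygous | homozygous | ambiguous

    def __post_init__(self) -> None:
        self.chrom_pair = tuple(sorted(self.chrom_pair))
        if self.interaction_ratio < 0:
            raise ValueError("interaction_ratio must be >= 0")


@dataclass
class TransRegionSet:
    bins: pd.DataFrame  # chrom, start, end, partner_chrom, z_score
    z_threshold: float = 2.58
    n_informative: int = 0

    def __post_init__(self) -> None:
        if len(self.bins) and (self.bins["z_score"] <= self.z_threshold).any():
            raise ValueError("reported z_scores must exceed z_threshold")

    @property
    def called_fraction(self) -> float:
        """Called bins as a fraction of informative bins."""
        return len(self.bins) / self.n_informative if self.n_informative else float("nan")


def _pair_mean_table(
    matrix: ContactMatrix, exclude_chroms: tuple[str, ...]
) -> pd.DataFrame:
    """Mean per-bin-pair trans interaction for every unordered chromosome pair.

    The denominator counts unmasked bin pairs, so the statistic is comparable
    across chromosomes of different size.
    """
    chroms = [c for c in matrix.chrom_names if c not in exclude_chroms]
    cid = matrix.chrom_index()
    order = {c: i for i, c in enumerate(matrix.chrom_names)}
    coo = sp.triu(matrix.counts, k=1).tocoo()
    good = ~(matrix.mask[coo.row] | matrix.mask[coo.col])
    ci, cj = cid[coo.row[good]], cid[coo.col[good]]
    data = coo.data[good]
    trans = ci != cj
    n_chrom = len(matrix.chrom_names)
    key = ci[trans] * n_chrom + cj[trans]
    sums = np.bincount(key, weights=data[trans], minlength=n_chrom * n_chrom)
    unmasked = np.bincount(cid[~matrix.mask], minlength=n_chrom)
    rows = []
    for a_i, a in enumerate(chroms):
        for b in chroms[a_i + 1 :]:
            ia, ib = order[a], order[b]
            denom = unmasked[ia] * unmasked[ib]
            total = sums[ia * n_chrom + ib] + sums[ib * n_chrom + ia]
            rows.append(
                {
                    "chrom1": a,
                    "chrom2": b,
                    "mean_interaction": total / denom if denom else np.nan,
                    "n_bin_pairs": int(denom),
                }
            )
    return pd.DataFrame(rows)


def interchromosomal_ratio_heatmap(
    rb: ContactMatrix,
    st: ContactMatrix,
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> pd.DataFrame:
    """Per-chromosome-pair mean trans interaction in each condition and their ratio.

    ratio = Rb / standard; values above 1 mean more interaction in the Rb
    condition.
    """
    a = _pair_mean_table(rb, exclude_chroms)
    b = _pair_mean_table(st, exclude_chroms)
    if set(zip(a["chrom1"], a["chrom2"])) != set(zip(b["chrom1"], b["chrom2"])):
        raise ValueError("chromosome sets differ between matrices")
    merged = a.merge(b, on=["chrom1", "chrom2"], suffixes=("_rb", "_st"))
    merged["ratio"] = merged["mean_interaction_rb"] / merged["mean_interaction_st"]
    return merged


def inter_intra_ratio(
    matrix: ContactMatrix, exclude_chroms: tuple[str, ...] = ("chrY",)
) -> pd.DataFrame:
    """Per chromosome: total trans interaction involving it / its total cis."""
    cid = matrix.chrom_index()
    coo = sp.triu(matrix.counts).tocoo()
    good = ~(matrix.mask[coo.row] | matrix.mask[coo.col])
    ci, cj, data = cid[coo.row[good]], cid[coo.col[good]], coo.data[good]
    n_chrom = len(matrix.chrom_names)
    cis_sum = np.bincount(ci[ci == cj], weights=data[ci == cj], minlength=n_chrom)
    trans = ci != cj
    trans_sum = np.bincount(ci[trans], weights=data[trans], minlength=n_chrom)
    trans_sum += np.bincount(cj[trans], weights=data[trans], minlength=n_chrom)
    rows = []
    for i, chrom in enumerate(matrix.chrom_names):
        if chrom in exclude_chroms:
            continue
        ratio = trans_sum[i] / cis_sum[i] if cis_sum[i] > 0 else np.nan
        rows.append({"chrom": chrom, "trans": trans_sum[i], "cis": cis_sum[i], "ratio": ratio})
    return pd.DataFrame(rows)


def detect_fusions(
    matrix: ContactMatrix,
    background_exclusion: list[tuple[str, str]] | None = None,
    k: float = 8.0,
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> pd.DataFrame:
    """Flag chromosome pairs whose trans interaction is an outlier.

    Per-pair trans totals are standardized against a robust expected value
    (the median per-cell density times the pair's bin-pair count), giving a
    variance-stabilized score z = (N - E) / sqrt(E) that is comparable across
    chromosome pairs of any size; pairs whose score exceeds
    median + k*MAD of all scores are flagged.  Pairs listed in
    ``background_exclusion`` are left out of the median/MAD estimation but
    still evaluated.  Candidates are returned sorted by the ratio of their
    per-cell density to the background median.
    """
    chroms = [c for c in matrix.chrom_names if c not in exclude_chroms]
    if len(chroms) < 3:
        raise ValueError("need at least 3 chromosomes to detect fusions")
    table = _pair_mean_table(matrix, exclude_chroms)
    density = table["mean_interaction"].to_numpy()
    cells = table["n_bin_pairs"].to_numpy().astype(float)
    bg = np.ones(len(table), dtype=bool)
    if background_exclusion:
        excl = {tuple(sorted(p)) for p in background_exclusion}
        bg = ~table.apply(
            lambda r: tuple(sorted((r["chrom1"], r["chrom2"]))) in excl, axis=1
        ).to_numpy()
    med_density = float(np.median(density[bg]))
    expected = med_density * cells
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(expected > 0, (density * cells - expected) / np.sqrt(expected), np.nan)
    med_z = float(np.nanmedian(z[bg]))
    mad_z = float(np.nanmedian(np.abs(z[bg] - med_z)))
    threshold = med_z + k * mad_z
    out = table.copy()
    out["z_score"] = z
    out["ratio_to_median"] = density / med_density if med_density > 0 else np.nan
    out = out[z >= threshold] if k > 0 else out[z >= med_z]
    return out.sort_values("ratio_to_median", ascending=False).reset_index(drop=True)


def classify_fusion_zygosity(
    rs_matrix: ContactMatrix,
    fused_pairs: list[tuple[str, str]],
    het_bounds: tuple[float, float] = (1.2, 1.6),
    hom_threshold: float = 1.8,
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> list[FusionCall]:
    """Classify fusions as homozygous or heterozygous from a round-spermatid map.

    interaction_ratio = fused-pair mean per-bin-pair trans interaction over
    the mean among chromosome pairs with neither partner in any fusion.
    Heterozygous when the ratio lies in ``het_bounds``; homozygous at or above
    ``hom_threshold``; ambiguous otherwise.
    """
    if not fused_pairs:
        raise ValueError("fused_pairs must be nonempty")
    table = _pair_mean_table(rs_matrix, exclude_chroms)
    pair_value = {
        tuple(sorted((r.chrom1, r.chrom2))): r.mean_interaction
        for r in table.itertuples()
    }
    fused = [tuple(sorted(p)) for p in fused_pairs]
    for pair in fused:
        if pair not in pair_value:
            raise ValueError(f"fused pair {pair} absent from matrix")
    fused_chroms = {c for p in fused for c in p}
    bg_values = [
        v
        for (a, b), v in pair_value.items()
        if a not in fused_chroms and b not in fused_chroms and np.isfinite(v)
    ]
    if not bg_values:
        raise ValueError("no non-fused background pairs available")
    background = float(np.mean(bg_values))
    calls = []
    for pair in fused:
        ratio = pair_value[pair] / background
        if het_bounds[0] <= ratio <= het_bounds[1]:
            zyg = "heterozygous"
        elif ratio >= hom_threshold:
            zyg = "homozygous"
        else:
            zyg = "ambiguous"
        calls.append(FusionCall(pair, float(ratio), zyg))
    return calls


def _bin_trans_signal(
    matrix: ContactMatrix, exclude_chroms: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-bin summed trans interaction, informative-bin mask, and the
    per-bin x per-chromosome partner sum matrix."""
    cid = matrix.chrom_index()
    n_chrom = len(matrix.chrom_names)
    excluded = np.array([c in exclude_chroms for c in matrix.chrom_names])
    coo = sp.triu(matrix.counts, k=1).tocoo()
    good = (
        ~(matrix.mask[coo.row] | matrix.mask[coo.col])
        & (cid[coo.row] != cid[coo.col])
        & ~excluded[cid[coo.row]]
        & ~excluded[cid[coo.col]]
    )
    row, col, data = coo.row[good], coo.col[good], coo.data[good]
    n = matrix.n_bins
    partner = np.zeros((n, n_chrom))
    np.add.at(partner, (row, cid[col]), data)
    np.add.at(partner, (col, cid[row]), data)
    signal = partner.sum(axis=1)
    informative = ~matrix.mask & ~excluded[cid]
    return signal, informative, partner


def call_trans_interaction_regions(
    rb: ContactMatrix,
    st: ContactMatrix | None,
    z_threshold: float = 2.58,
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> TransRegionSet:
    """Call bins with exceptionally high trans interaction in the Rb map.

    The per-bin summed trans signal is standardized (Z-score) against its
    distribution over informative bins; bins exceeding ``z_threshold`` are
    called, and, when a standard-condition map is given, only if the same bin
    does not also exceed the threshold there (condition-specific regions).
    Each called bin reports its strongest partner chromosome.
    """
    sig_rb, info, partner = _bin_trans_signal(rb, exclude_chroms)

    def zscores(signal, informative):
        vals = signal[informative]
        if len(vals) < 2:
            raise ValueError("degenerate trans distribution (fewer than 2 informative bins)")
        sd = vals.std()
        z = np.full(len(signal), -np.inf)
        if sd == 0:  # flat distribution: nothing stands out, nothing is called
            return z
        z[informative] = (signal[informative] - vals.mean()) / sd
        return z

    z_rb = zscores(sig_rb, info)
    called = info & (z_rb > z_threshold)
    if st is not None:
        sig_st, info_st, _ = _bin_trans_signal(st, exclude_chroms)
        z_st = zscores(sig_st, info_st)
        called &= ~(z_st > z_threshold)
    names = np.array(rb.chrom_names)
    rows = []
    for b in np.flatnonzero(called):
        partner_chrom = names[int(np.argmax(partner[b]))]
        rows.append(
            {
                "chrom": rb.bins.iloc[b]["chrom"],
                "start": int(rb.bins.iloc[b]["start"]),
                "end": int(rb.bins.iloc[b]["end"]),
                "partner_chrom": partner_chrom,
                "z_score": float(z_rb[b]),
            }
        )
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "partner_chrom", "z_score"])
    return TransRegionSet(bins=bins, z_threshold=z_threshold, n_informative=int(info.sum()))


def read_bed6(path) -> pd.DataFrame:
    """Parse a BED6 gene file (chrom, start, end, name, score, strand).

    Malformed records raise with the offending line number.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise ValueError(f"{path}:{lineno}: expected 6 BED columns, got {len(parts)}")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
            if parts[5] not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be + or -")
            if end < start:
                raise ValueError(f"{path}:{lineno}: end < start")
            rows.append(
                {
                    "chrom": parts[0],
                    "start": start,
                    "end": end,
                    "name": parts[3],
                    "score": parts[4],
                    "strand": parts[5],
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])


def region_gene_overlap(
    regions: TransRegionSet,
    gene_intervals: pd.DataFrame,
    promoter_upstream: int = 2000,
) -> pd.DataFrame:
    """Genes whose promoter window overlaps a called bin (half-open semantics).

    The promoter is [TSS - promoter_upstream, TSS) on the + strand and
    [TSS, TSS + promoter_upstream) on the - strand, with the TSS at the
    gene's 5' end.
    """
    plus = gene_intervals["strand"] == "+"
    prom_start = np.where(
        plus,
        gene_intervals["start"] - promoter_upstream,
        gene_intervals["end"],
    )
    prom_end = np.where(
        plus,
        gene_intervals["start"],
        gene_intervals["end"] + promoter_upstream,
    )
    rows = []
    for region in regions.bins.itertuples():
        sel = (
            (gene_intervals["chrom"] == region.chrom)
            & (prom_start < region.end)
            & (prom_end > region.start)
        )
        for gene in gene_intervals[sel].itertuples():
            rows.append(
                {
                    "chrom": region.chrom,
                    "region_start": region.start,
                    "region_end": region.end,
                    "gene": gene.name,
                    "strand": gene.strand,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "region_start", "region_end", "gene", "strand"])


def pericentromeric_trans(
    matrix: ContactMatrix,
    fused: set[str],
    nonfused: set[str],
    window: float = 3.5e6,
    centromeres: dict[str, int] | None = None,
    exclude_chroms: tuple[str, ...] = ("chrY",),
) -> dict:
    """Trans interaction per million total contacts at pericentromeric bins.

    The pericentromeric window spans [centromere, centromere + window); for
    acrocentric assemblies the centromere sits at 0.  Returns per-chromosome
    totals, per-bin values for the two chromosome groups, and a two-sided
    Mann-Whitney comparison between them.
    """
    if window < matrix.resolution:
        raise ValueError("window must be at least one bin")
    signal, info, _ = _bin_trans_signal(matrix, exclude_chroms)
    per_million = 1e6 / matrix.total_counts if matrix.total_counts > 0 else 0.0
    starts = matrix.bins["start"].to_numpy()
    chroms = matrix.bins["chrom"].to_numpy()
    per_chrom: dict[str, float] = {}
    group_values: dict[str, list[float]] = {"fused": [], "nonfused": []}
    for chrom in matrix.chrom_names:
        if chrom in exclude_chroms:
            continue
        cen = (centromeres or {}).get(chrom, 0)
        sel = (chroms == chrom) & (starts >= cen) & (starts < cen + window)
        vals = signal[sel] * per_million
        per_chrom[chrom] = float(vals.sum())
        if chrom in fused:
            group_values["fused"].extend(vals)
        elif chrom in nonfused:
            group_values["nonfused"].extend(vals)
    result = {"per_chrom": per_chrom, "per_bin": group_values}
    if group_values["fused"] and group_values["nonfused"]:
        u, p = stats.mannwhitneyu(
            group_values["fused"], group_values["nonfused"], alternative="two-sided"
        )
        result["mannwhitney_u"] = float(u)
        result["p_value"] = float(p)
    return result


def chromosome_trans_distribution(
    matrix: ContactMatrix, chrom: str, exclude_chroms: tuple[str, ...] = ("chrY",)
) -> pd.DataFrame:
    """Per-bin summed trans interaction of ``chrom`` with all autosomes."""
    if chrom not in matrix.chrom_names:
        raise ValueError(f"unknown chromosome {chrom}")
    autosomes = [
        c
        for c in matrix.chrom_names
        if c not in (chrom, *exclude_chroms) and c not in ("chrX", "chrY")
    ]
    cid = matrix.chrom_index()
    order = {c: i for i, c in enumerate(matrix.chrom_names)}
    auto_ids = {order[c] for c in autosomes}
    target = order[chrom]
    coo = sp.triu(matrix.counts, k=1).tocoo()
    good = ~(matrix.mask[coo.row] | matrix.mask[coo.col])
    row, col, data = coo.row[good], coo.col[good], coo.data[good]
    n = matrix.n_bins
    signal = np.zeros(n)
    sel = (cid[row] == target) & np.isin(cid[col], list(auto_ids))
    np.add.at(signal, row[sel], data[sel])
    sel = (cid[col] == target) & np.isin(cid[row], list(auto_ids))
    np.add.at(signal, col[sel], data[sel])
    sl = matrix.chrom_slices()[chrom]
    out = matrix.bins.iloc[sl].copy()
    out["trans_value"] = signal[sl]
    return out.reset_index(drop=True)
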