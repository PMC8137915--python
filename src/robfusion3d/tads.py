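"""Insulation scores, TAD boundaries, reorganization classes and meta-borders.

The insulation score of bin *i* is the log2 ratio of the mean interaction in
the diamond spanning ``window`` bins on either side of *i* over the
chromosome-wide mean diamond, so 0 marks average insulation and minima mark
boundaries.  Domains tile the chromosome between consecutive boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ContactMatrix

__all__ = [
    "TadSet",
    "TadReorgReport",
    "insulation_score",
    "call_tads",
    "classify_tad_reorganization",
    "meta_border",
    "insulation_variance_compare",
]


@dataclass
class TadSet:
    domains: pd.DataFrame  # chrom, start, end (bp)
    boundaries: pd.DataFrame  # chrom, position (bp), border_score
    insulation: pd.DataFrame  # chrom, start, end, score (NaN undefined)
    resolution: int

    @property
    def mean_length(self) -> float:
        if len(self.domains) == 0:
            return float("nan")
        return float((self.domains["end"] - self.domains["start"]).mean())

    @property
    def insulation_variance(self) -> float:
        scores = self.insulation["score"].to_numpy()
        return float(np.nanvar(scores))


@dataclass
class TadReorgReport:
    classes: pd.DataFrame  # chrom, start, end, class
    frequencies: dict[str, float] = field(default_factory=dict)


def insulation_score(matrix: ContactMatrix, window: int = 10) -> pd.DataFrame:
    """Diamond insulation score per bin.

    For each bin i the mean interaction in the diamond
    {(u, d): i-window <= u < i < d <= i+window} is computed on the cis
    sub-matrix; the score is log2(diamond mean / chromosome mean diamond).
    Undefined (NaN) within ``window`` bins of chromosome ends and at bins
    whose diamond touches a masked bin.  Chromosomes shorter than
    ``2*window + 1`` bins are skipped.
    """
    import scipy.sparse as sp

    out = matrix.bins[["chrom", "start", "end"]].copy()
    scores = np.full(matrix.n_bins, np.nan)
    for chrom, sl in matrix.chrom_slices().items():
        n = sl.stop - sl.start
        if n < 2 * window + 1:
            warnings.warn(f"{chrom}: shorter than 2*window+1 bins; insulation skipped")
            continue
        # banded storage: band[u, k] = M[u, u + k] for k in 1..2*window,
        # enough to evaluate every diamond without densifying the block
        block = sp.triu(matrix.counts[sl, sl], k=1).tocoo()
        sep = block.col - block.row
        keep = sep <= 2 * window
        band = np.zeros((n, 2 * window + 1))
        band[block.row[keep], sep[keep]] = block.data[keep]
        cum = np.cumsum(band, axis=1)  # cum[u, k] = sum of band[u, 1..k]

        bad = matrix.mask[sl]
        badcum = np.concatenate(([0], np.cumsum(bad)))
        diamonds = np.full(n, np.nan)
        idx = np.arange(window, n - window)
        # diamond(i) = sum_{t=1..w} sum_{k=t+1..t+w} band[i - t, k]
        total = np.zeros(len(idx))
        for t in range(1, window + 1):
            u = idx - t
            total += cum[u, np.minimum(t + window, 2 * window)] - cum[u, t]
        usable = (badcum[idx + window + 1] - badcum[idx - window]) == 0
        diamonds[idx[usable]] = total[usable] / (window * window)
        mean_diamond = np.nanmean(diamonds) if np.isfinite(diamonds).any() else np.nan
        if not np.isfinite(mean_diamond) or mean_diamond <= 0:
            continue
        # a zero diamond is a real (infinitely deep) boundary: keep -inf
        with np.errstate(divide="ignore", invalid="ignore"):
            chrom_scores = np.log2(diamonds / mean_diamond)
        scores[sl] = chrom_scores
    out["score"] = scores
    return out


def _local_extrema(values: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of strict-ish local minima and maxima on a track with NaNs."""
    minima, maxima = [], []
    n = len(values)
    for i in range(n):
        if np.isnan(values[i]):
            continue
        left = next(
            (values[j] for j in range(i - 1, -1, -1) if not np.isnan(values[j]) and values[j] != values[i]),
            None,
        )
        right = next(
            (values[j] for j in range(i + 1, n) if not np.isnan(values[j]) and values[j] != values[i]),
            None,
        )
        if left is None or right is None:
            continue
        if values[i] < left and values[i] < right:
            minima.append(i)
        elif values[i] > left and values[i] > right:
            maxima.append(i)
    return minima, maxima


def call_tads(insulation: pd.DataFrame, delta: float = 0.5) -> TadSet:
    """Boundaries at insulation minima whose prominence exceeds ``delta``.

    The default ``delta`` separates domain boundaries (depth ~log2(1 +
    within-domain enrichment)) from shallow minima produced by counting noise
    on the distance-decay background.

    The border score of a minimum is its depth relative to the lower of the
    two flanking local maxima; domains span between consecutive boundaries
    and chromosome ends (restricted to the region where the score is
    defined).
    """
    if insulation["score"].isna().all():
        raise ValueError("insulation track has no defined scores")
    resolution = int((insulation["end"] - insulation["start"]).mode()[0])
    dom_rows, bound_rows = [], []
    for chrom, chrom_bins in insulation.groupby("chrom", sort=False):
        values = chrom_bins["score"].to_numpy()
        starts = chrom_bins["start"].to_numpy()
        ends = chrom_bins["end"].to_numpy()
        defined = np.flatnonzero(~np.isnan(values))
        if len(defined) == 0:
            continue
        minima, maxima = _local_extrema(values)
        accepted = []
        with np.errstate(invalid="ignore"):
            finite_max = lambda arr: np.nanmax(arr) if (~np.isnan(arr)).any() else np.nan  # noqa: E731
        for m in minima:
            left_max = [values[j] for j in maxima if j < m]
            right_max = [values[j] for j in maxima if j > m]
            flank_left = max(left_max) if left_max else finite_max(values[: m + 1])
            flank_right = max(right_max) if right_max else finite_max(values[m:])
            depth = min(flank_left, flank_right) - values[m]
            if depth > delta:
                accepted.append((m, float(depth)))
        for m, depth in accepted:
            bound_rows.append(
                {"chrom": chrom, "position": int(starts[m]), "border_score": depth}
            )
        edges = [int(starts[defined[0]])] + [int(starts[m]) for m, _ in accepted] + [
            int(ends[defined[-1]])
        ]
        for s, e in zip(edges[:-1], edges[1:]):
            if e > s:
                dom_rows.append({"chrom": chrom, "start": s, "end": e})
    return TadSet(
        domains=pd.DataFrame(dom_rows, columns=["chrom", "start", "end"]),
        boundaries=pd.DataFrame(bound_rows, columns=["chrom", "position", "border_score"]),
        insulation=insulation,
        resolution=resolution,
    )


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def classify_tad_reorganization(
    a: TadSet, b: TadSet, overlap_threshold: float = 0.75
) -> TadReorgReport:
    """Classify every domain of ``a`` against the domain set ``b``.

    stable: some b-domain has reciprocal overlap above the threshold;
    merged: the a-domain covers at least the threshold fraction of two or
    more b-domains; split: a single b-domain covers the a-domain and also
    covers at least one other a-domain (one TAD divided into several);
    rearranged otherwise.
    """
    if len(a.domains) == 0 or len(b.domains) == 0:
        raise ValueError("empty TAD set")
    rows = []
    b_by_chrom = dict(tuple(b.domains.groupby("chrom", sort=False)))
    a_by_chrom = dict(tuple(a.domains.groupby("chrom", sort=False)))
    for dom in a.domains.itertuples():
        b_doms = b_by_chrom.get(dom.chrom)
        cls = "rearranged"
        if b_doms is not None:
            len_a = dom.end - dom.start
            ov = np.array(
                [_overlap(dom.start, dom.end, r.start, r.end) for r in b_doms.itertuples()]
            )
            len_b = (b_doms["end"] - b_doms["start"]).to_numpy()
            reciprocal = (ov / len_a > overlap_threshold) & (ov / len_b > overlap_threshold)
            if reciprocal.any():
                cls = "stable"
            elif int((ov / len_b > overlap_threshold).sum()) >= 2:
                cls = "merged"
            else:
                covering = np.flatnonzero(ov / len_a > overlap_threshold)
                if len(covering):
                    big = b_doms.iloc[covering[0]]
                    sibs = a_by_chrom[dom.chrom]
                    ov_a = np.array(
                        [_overlap(big.start, big.end, r.start, r.end) for r in sibs.itertuples()]
                    )
                    frac = ov_a / (sibs["end"] - sibs["start"]).to_numpy()
                    if int((frac > overlap_threshold).sum()) >= 2:
                        cls = "split"
        rows.append({"chrom": dom.chrom, "start": dom.start, "end": dom.end, "class": cls})
    classes = pd.DataFrame(rows)
    freqs = (classes["class"].value_counts() / len(classes)).to_dict()
    for key in ("stable", "merged", "split", "rearranged"):
        freqs.setdefault(key, 0.0)
    return TadReorgReport(classes=classes, frequencies=freqs)


def meta_border(
    matrix: ContactMatrix, boundaries: pd.DataFrame, flank: float = 500e3
) -> tuple[np.ndarray, int]:
    """Average O/E sub-matrix centered on each boundary +/- ``flank``.

    ``boundaries`` needs columns chrom, position.  Boundaries whose window
    extends past a chromosome end are skipped; the count of usable
    boundaries is returned alongside the aggregated map.
    """
    w = int(flank // matrix.resolution)
    size = 2 * w + 1
    agg = np.zeros((size, size))
    used = 0
    slices = matrix.chrom_slices()
    for bd in boundaries.itertuples():
        sl = slices.get(bd.chrom)
        if sl is None:
            continue
        n = sl.stop - sl.start
        center = int(bd.position // matrix.resolution)
        if center - w < 0 or center + w >= n:
            continue
        block = np.asarray(
            matrix.counts[sl, sl][center - w : center + w + 1, center - w : center + w + 1].todense()
        )
        agg += block
        used += 1
    if used == 0:
        raise ValueError("no usable boundaries (all too close to chromosome ends)")
    return agg / used, used


def insulation_variance_compare(a: pd.DataFrame, b: pd.DataFrame) -> dict:
    """Variance of defined insulation scores per condition plus a spread test.

    The two-sided Mann-Whitney is run on absolute deviations from each
    track's median — a variance-style two-sample comparison.
    """
    va = a["score"].to_numpy()
    vb = b["score"].to_numpy()
    va = va[np.isfinite(va)]
    vb = vb[np.isfinite(vb)]
    if len(va) < 2 or len(vb) < 2:
        raise ValueError("need at least 2 defined scores per track")
    dev_a = np.abs(va - np.median(va))
    dev_b = np.abs(vb - np.median(vb))
    u, p = stats.mannwhitneyu(dev_a, dev_b, alternative="two-sided")
    return {
        "variance_a": float(va.var()),
        "variance_b": float(vb.var()),
        "mannwhitney_u": float(u),
        "p_value": float(p),
    }
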