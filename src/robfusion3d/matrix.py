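"""Genome-wide contact matrices: binning, masking, balancing, transforms.

A :class:`ContactMatrix` stores a symmetric sparse matrix over a genome-wide
bin table (0-based, half-open bins of fixed resolution), a mask of excluded
bins, and optional iterative-correction weights such that
``raw = balanced * w_i * w_j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .genome import GenomeAssembly, make_bin_table

__all__ = [
    "ContactMatrix",
    "bin_pairs",
    "mask_low_count_bins",
    "ice_normalize",
    "observed_expected",
    "log2_differential",
    "scale_to_depth",
    "replicate_reproducibility",
    "save_matrix",
    "load_matrix",
]


@dataclass
class ContactMatrix:
    resolution: int
    bins: pd.DataFrame  # chrom, start, end, bin_id
    counts: sp.csr_matrix  # symmetric, both triangles stored
    mask: np.ndarray = None  # bool, True = excluded
    weights: np.ndarray | None = None  # per-bin balancing factors
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.bins)
        if self.counts.shape != (n, n):
            raise ValueError("counts shape does not match bin table")
        if self.mask is None:
            self.mask = np.zeros(n, dtype=bool)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def total_counts(self) -> float:
        """Sum over the upper triangle including the diagonal."""
        return float((self.counts.sum() + self.counts.diagonal().sum()) / 2.0)

    @property
    def chrom_names(self) -> list[str]:
        return list(dict.fromkeys(self.bins["chrom"]))

    def chrom_slices(self) -> dict[str, slice]:
        out = {}
        chroms = self.bins["chrom"].to_numpy()
        for chrom in self.chrom_names:
            idx = np.flatnonzero(chroms == chrom)
            out[chrom] = slice(int(idx[0]), int(idx[-1]) + 1)
        return out

    def chrom_index(self) -> np.ndarray:
        """Integer chromosome id per bin."""
        order = {c: i for i, c in enumerate(self.chrom_names)}
        return self.bins["chrom"].map(order).to_numpy()

    def cis_dense(self, chrom: str) -> np.ndarray:
        sl = self.chrom_slices()[chrom]
        return np.asarray(self.counts[sl, sl].todense())

    def copy(self) -> "ContactMatrix":
        return replace(
            self,
            counts=self.counts.copy(),
            mask=self.mask.copy(),
            weights=None if self.weights is None else self.weights.copy(),
            metadata=dict(self.metadata),
        )


def bin_pairs(pairs: pd.DataFrame, genome: GenomeAssembly, resolution: int) -> ContactMatrix:
    """Bin contact records into a genome-wide square matrix.

    Each pair increments its (bin_i, bin_j) cell by one (diagonal allowed).
    Records on unknown chromosomes or outside chromosome bounds are skipped
    and counted in ``metadata['n_out_of_bounds']``.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    bins = make_bin_table(genome, resolution)
    n = len(bins)
    offsets = {}
    pos = 0
    for chrom in genome.chrom_names:
        offsets[chrom] = pos
        pos += -(-genome.chrom_lengths[chrom] // resolution)

    if len(pairs) == 0:
        counts = sp.csr_matrix((n, n))
        return ContactMatrix(resolution, bins, counts, metadata={"n_out_of_bounds": 0})

    def to_bin(chroms: pd.Series, positions: pd.Series):
        off = chroms.map(offsets)
        lengths = chroms.map(genome.chrom_lengths)
        ok = off.notna() & (positions >= 0) & (positions < lengths.fillna(-1))
        idx = (off.fillna(0).to_numpy(dtype=np.int64)
               + positions.to_numpy(dtype=np.int64) // resolution)
        return idx, ok.to_numpy()

    i, ok1 = to_bin(pairs["chrom1"], pairs["pos1"])
    j, ok2 = to_bin(pairs["chrom2"], pairs["pos2"])
    keep = ok1 & ok2
    i, j = i[keep], j[keep]
    data = np.ones(len(i))
    upper = sp.coo_matrix((data, (np.minimum(i, j), np.maximum(i, j))), shape=(n, n)).tocsr()
    counts = upper + upper.T - sp.diags(upper.diagonal())
    return ContactMatrix(
        resolution,
        bins,
        counts.tocsr(),
        metadata={"n_out_of_bounds": int(len(pairs) - keep.sum())},
    )


def mask_low_count_bins(matrix: ContactMatrix, min_count: float = 10) -> ContactMatrix:
    """Add bins whose marginal sum is below ``min_count`` to the mask."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    out = matrix.copy()
    if min_count == 0:
        return out
    marginals = np.asarray(out.counts.sum(axis=1)).ravel()
    out.mask = out.mask | (marginals < min_count)
    return out


def ice_normalize(
    matrix: ContactMatrix, max_iter: int = 200, tol: float = 1e-5
) -> ContactMatrix:
    """Iterative correction: rescale until every unmasked bin has equal visibility.

    Single-pass marginal correction per iteration; convergence when the
    relative variance of unmasked marginals (var / mean^2) drops below
    ``tol``.  Bins with a zero marginal are auto-masked.  Weights are stored
    so that ``raw = balanced * w_i * w_j``.
    """
    out = matrix.copy()
    n = out.n_bins
    marg = np.asarray(out.counts.sum(axis=1)).ravel()
    out.mask = out.mask | (marg == 0)
    active = ~out.mask
    if not active.any():
        raise ValueError("all bins masked; nothing to balance")

    counts = out.counts.astype(float).tolil()
    # zero masked rows/cols so they do not contribute
    masked_idx = np.flatnonzero(out.mask)
    if len(masked_idx):
        counts[masked_idx, :] = 0
        counts[:, masked_idx] = 0
    counts = counts.tocsr()

    weights = np.ones(n)
    for _ in range(max_iter):
        marg = np.asarray(counts.sum(axis=1)).ravel()
        m = marg[active]
        mean = m.mean()
        if mean == 0:
            raise ValueError("active sub-matrix is empty")
        rel_var = m.var() / mean**2
        if rel_var < tol:
            break
        delta = np.ones(n)
        delta[active] = marg[active] / mean
        delta[delta == 0] = 1.0
        d = sp.diags(1.0 / delta)
        counts = d @ counts @ d
        weights *= delta
    out.counts = counts.tocsr()
    out.weights = np.where(out.mask, np.nan, weights)
    out.metadata["balanced"] = True
    return out


def _cis_possible_pairs(matrix: ContactMatrix) -> np.ndarray:
    """Number of unmasked bin pairs at each cis separation, pooled over chromosomes."""
    max_n = max(sl.stop - sl.start for sl in matrix.chrom_slices().values())
    possible = np.zeros(max_n)
    for chrom, sl in matrix.chrom_slices().items():
        ind = (~matrix.mask[sl]).astype(float)
        ac = np.correlate(ind, ind, mode="full")[len(ind) - 1 :]
        # ac[0] counts i==i pairs (diagonal), ac[d] pairs at separation d
        possible[: len(ac)] += ac
    return possible


def observed_expected(matrix: ContactMatrix) -> ContactMatrix:
    """Divide cis cells by the per-separation expected value and trans cells by
    the genome-wide mean trans value.

    The cis expected at separation ``d`` is the sum of contacts at that
    separation over the genome divided by the number of possible unmasked
    cell pairs at that separation; strata with no possible pairs are skipped.
    Masked cells are dropped (undefined).
    """
    out = matrix.copy()
    chrom_idx = matrix.chrom_index()
    coo = sp.triu(matrix.counts).tocoo()
    unmasked = ~(matrix.mask[coo.row] | matrix.mask[coo.col])
    row, col, data = coo.row[unmasked], coo.col[unmasked], coo.data[unmasked]
    cis = chrom_idx[row] == chrom_idx[col]

    possible = _cis_possible_pairs(matrix)
    sep = col[cis] - row[cis]
    sums = np.bincount(sep, weights=data[cis], minlength=len(possible))
    with np.errstate(divide="ignore", invalid="ignore"):
        expected = np.where(possible > 0, sums[: len(possible)] / possible, np.nan)

    # trans expected: total trans mass / possible unmasked trans cell pairs
    u_per_chrom = np.bincount(chrom_idx[~matrix.mask])
    u_total = u_per_chrom.sum()
    possible_trans = (u_total**2 - (u_per_chrom**2).sum()) / 2.0
    trans_sum = data[~cis].sum()
    trans_expected = trans_sum / possible_trans if possible_trans > 0 else np.nan

    values = np.empty(len(data))
    values[cis] = data[cis] / expected[sep]
    if trans_expected and np.isfinite(trans_expected) and trans_expected > 0:
        values[~cis] = data[~cis] / trans_expected
    else:
        values[~cis] = np.nan
    good = np.isfinite(values)
    upper = sp.coo_matrix(
        (values[good], (row[good], col[good])), shape=matrix.counts.shape
    ).tocsr()
    out.counts = (upper + upper.T - sp.diags(upper.diagonal())).tocsr()
    out.metadata["oe"] = True
    out.metadata["trans_expected"] = float(trans_expected)
    return out


def log2_differential(
    reference: ContactMatrix, other: ContactMatrix, pseudocount: float = 1.0
) -> ContactMatrix:
    """log2((other + pseudocount) / (reference + pseudocount)) per cell.

    With the Rb condition as reference, positive values mean more interaction
    in the other (standard) condition.  Cells zero in both maps are zero by
    construction and left unstored.
    """
    if reference.resolution != other.resolution or not reference.bins[
        ["chrom", "start", "end"]
    ].equals(other.bins[["chrom", "start", "end"]]):
        raise ValueError("matrices have mismatched bin tables")
    out = reference.copy()
    a = sp.triu(reference.counts).tocoo()
    b = sp.triu(other.counts).tocoo()
    n = reference.n_bins
    keys_a = a.row.astype(np.int64) * n + a.col
    keys_b = b.row.astype(np.int64) * n + b.col
    keys = np.union1d(keys_a, keys_b)
    va = np.zeros(len(keys))
    vb = np.zeros(len(keys))
    va[np.searchsorted(keys, keys_a)] = a.data
    vb[np.searchsorted(keys, keys_b)] = b.data
    vals = np.log2((vb + pseudocount) / (va + pseudocount))
    row, col = keys // n, keys % n
    upper = sp.coo_matrix((vals, (row, col)), shape=(n, n)).tocsr()
    out.counts = (upper + upper.T - sp.diags(upper.diagonal())).tocsr()
    out.mask = reference.mask | other.mask
    out.metadata = {"log2_differential": True, "pseudocount": pseudocount}
    return out


def scale_to_depth(matrix: ContactMatrix, target: float = 1e8) -> ContactMatrix:
    """Rescale all cells so the upper-triangle total equals ``target``."""
    total = matrix.total_counts
    if total <= 0:
        raise ValueError("matrix has zero total counts; cannot scale")
    out = matrix.copy()
    out.counts = out.counts * (target / total)
    out.metadata["depth_scaled_to"] = target
    return out


def replicate_reproducibility(
    a: ContactMatrix,
    b: ContactMatrix,
    smoothing: int = 5,
    min_distance: float = 10e6,
    exclude_chroms: tuple[str, ...] = ("chrY",),
    distance_mode: str = "min",
) -> tuple[dict[str, float], float]:
    """Stratum-adjusted correlation between two replicate maps, per chromosome.

    Cis sub-matrices are smoothed with a 2D mean filter of the given bin
    radius; per distance stratum the Pearson correlation of the two smoothed
    diagonals is computed and strata are averaged with weights
    ``N_k * sd_a_k * sd_b_k``.  With ``distance_mode='min'`` only separations
    greater than ``min_distance`` are considered (the study's convention);
    ``'max'`` inverts this to the usual upper-bound convention.  Chromosomes
    with no usable stratum score NaN and are excluded from the mean.
    """
    from scipy.ndimage import uniform_filter

    if not a.bins[["chrom", "start", "end"]].equals(b.bins[["chrom", "start", "end"]]):
        raise ValueError("matrices have mismatched bin tables")
    if distance_mode not in ("min", "max"):
        raise ValueError("distance_mode must be 'min' or 'max'")
    scores: dict[str, float] = {}
    slices = a.chrom_slices()
    cut_bins = int(min_distance // a.resolution)
    for chrom in a.chrom_names:
        if chrom in exclude_chroms:
            continue
        sl = slices[chrom]
        mat_a = np.asarray(a.counts[sl, sl].todense())
        mat_b = np.asarray(b.counts[sl, sl].todense())
        bad = a.mask[sl] | b.mask[sl]
        mat_a[bad, :] = 0.0
        mat_a[:, bad] = 0.0
        mat_b[bad, :] = 0.0
        mat_b[:, bad] = 0.0
        size = 2 * smoothing + 1
        sm_a = uniform_filter(mat_a, size=size, mode="constant")
        sm_b = uniform_filter(mat_b, size=size, mode="constant")
        n = mat_a.shape[0]
        num = 0.0
        den = 0.0
        strata = (
            range(cut_bins + 1, n) if distance_mode == "min" else range(0, min(cut_bins + 1, n))
        )
        for d in strata:
            xa = np.diagonal(sm_a, offset=d)
            xb = np.diagonal(sm_b, offset=d)
            good = ~(bad[: n - d] | bad[d:])
            # drop positions whose smoothing window is truncated by the matrix
            # edge: the shared truncation profile would correlate any two maps
            u = np.arange(n - d)
            good &= (u >= smoothing) & (u + d + smoothing < n)
            xa, xb = xa[good], xb[good]
            if len(xa) < 2:
                continue
            sa, sb = xa.std(), xb.std()
            if sa == 0 or sb == 0:
                continue
            r = float(np.corrcoef(xa, xb)[0, 1])
            w = len(xa) * sa * sb
            num += w * r
            den += w
        scores[chrom] = num / den if den > 0 else float("nan")
    defined = [v for v in scores.values() if np.isfinite(v)]
    mean = float(np.mean(defined)) if defined else float("nan")
    return scores, mean


# ---------------------------------------------------------------------------
# on-disk text format: bin table as BED + upper-triangle sparse TSV


def save_matrix(matrix: ContactMatrix, prefix: str) -> None:
    """Write ``<prefix>.bins.bed``, ``<prefix>.counts.tsv`` and ``<prefix>.bininfo.tsv``."""
    matrix.bins.to_csv(f"{prefix}.bins.bed", sep="\t", header=False, index=False)
    coo = sp.triu(matrix.counts).tocoo()
    pd.DataFrame({"bin1_id": coo.row, "bin2_id": coo.col, "count": coo.data}).to_csv(
        f"{prefix}.counts.tsv", sep="\t", index=False
    )
    info = pd.DataFrame(
        {
            "bin_id": matrix.bins["bin_id"],
            "masked": matrix.mask.astype(int),
            "weight": matrix.weights if matrix.weights is not None else np.nan,
        }
    )
    info.to_csv(f"{prefix}.bininfo.tsv", sep="\t", index=False)


def load_matrix(prefix: str, resolution: int) -> ContactMatrix:
    bins = pd.read_csv(
        f"{prefix}.bins.bed", sep="\t", names=["chrom", "start", "end", "bin_id"]
    )
    tri = pd.read_csv(f"{prefix}.counts.tsv", sep="\t")
    n = len(bins)
    upper = sp.coo_matrix(
        (tri["count"], (tri["bin1_id"], tri["bin2_id"])), shape=(n, n)
    ).tocsr()
    counts = upper + upper.T - sp.diags(upper.diagonal())
    info = pd.read_csv(f"{prefix}.bininfo.tsv", sep="\t")
    weights = info["weight"].to_numpy()
    if np.all(np.isnan(weights)):
        weights = None
    return ContactMatrix(
        resolution,
        bins,
        counts.tocsr(),
        mask=info["masked"].to_numpy().astype(bool),
        weights=weights,
    )
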