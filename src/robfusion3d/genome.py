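"""Genome assemblies, karyotypes and bin tables.

The coordinate frame mirrors the mouse (mm10) convention used throughout the
package: all-acrocentric karyotypes place every centromere at position 0, so a
Robertsonian (Rb) fusion joins two chromosomes at their proximal ends.  All
coordinates are 0-based, half-open; bins are ``[start, start + resolution)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenomeAssembly",
    "Karyotype",
    "simulate_genome",
    "mouse_like_lengths",
    "make_bin_table",
]

#: Approximate mm10 chromosome lengths in bp (chr1..chr19, chrX, chrY).
_MM10_MBP = [
    195.5, 182.1, 160.0, 156.5, 151.8, 149.7, 145.4, 129.4, 124.6, 130.7,
    122.1, 120.1, 120.4, 124.9, 104.0, 98.2, 94.9, 90.7, 61.4, 171.0, 91.7,
]


def _default_names(n_chrom: int) -> list[str]:
    """chr1..chr19 then chrX, chrY for mouse-like counts; plain numbering otherwise."""
    if n_chrom <= 19:
        return [f"chr{i}" for i in range(1, n_chrom + 1)]
    if n_chrom == 20:
        return [f"chr{i}" for i in range(1, 20)] + ["chrX"]
    if n_chrom == 21:
        return [f"chr{i}" for i in range(1, 20)] + ["chrX", "chrY"]
    return [f"chr{i}" for i in range(1, n_chrom + 1)]


@dataclass
class GenomeAssembly:
    """Chromosome names/lengths, centromere positions and an optional gene-density track.

    ``gene_density`` is stored at a fixed track resolution
    (``density_resolution`` bp per element, chromosomes concatenated in order)
    and can be re-binned to any matrix resolution with :meth:`gene_density_at`.
    """

    chrom_names: list[str]
    chrom_lengths: dict[str, int]
    centromere_pos: dict[str, int] = field(default_factory=dict)
    gene_density: np.ndarray | None = None
    density_resolution: int = 500_000

    def __post_init__(self) -> None:
        for name in self.chrom_names:
            length = self.chrom_lengths[name]
            if length <= 0:
                raise ValueError(f"chromosome {name} has nonpositive length {length}")
            cen = self.centromere_pos.setdefault(name, 0)
            if not 0 <= cen <= length:
                raise ValueError(f"centromere of {name} outside [0, {length}]")
        if self.gene_density is not None:
            expected = self.n_bins(self.density_resolution)
            if len(self.gene_density) != expected:
                raise ValueError(
                    f"gene_density has {len(self.gene_density)} values, "
                    f"expected {expected} at {self.density_resolution} bp"
                )
            if np.any(np.asarray(self.gene_density) < 0):
                raise ValueError("gene_density must be nonnegative")

    def n_bins(self, resolution: int) -> int:
        return int(sum(-(-self.chrom_lengths[c] // resolution) for c in self.chrom_names))

    def bins_per_chrom(self, resolution: int) -> dict[str, int]:
        return {c: -(-self.chrom_lengths[c] // resolution) for c in self.chrom_names}

    def gene_density_at(self, resolution: int) -> np.ndarray:
        """Gene density re-binned (by mean) from the stored track resolution."""
        if self.gene_density is None:
            raise ValueError("assembly has no gene-density track")
        out: list[np.ndarray] = []
        offset = 0
        for chrom in self.chrom_names:
            n_src = -(-self.chrom_lengths[chrom] // self.density_resolution)
            track = np.asarray(self.gene_density[offset : offset + n_src], dtype=float)
            offset += n_src
            n_dst = -(-self.chrom_lengths[chrom] // resolution)
            # mean of source elements whose midpoint falls in each target bin
            mids = (np.arange(n_src) + 0.5) * self.density_resolution
            idx = np.minimum((mids // resolution).astype(int), n_dst - 1)
            sums = np.bincount(idx, weights=track, minlength=n_dst)
            cnts = np.bincount(idx, minlength=n_dst).astype(float)
            cnts[cnts == 0] = 1.0
            out.append(sums / cnts)
        return np.concatenate(out)


@dataclass
class Karyotype:
    """A set of Rb fusions with per-fusion zygosity.

    Fusions are unordered chromosome pairs; a chromosome may appear in at most
    one fusion.  Penetrance is derived: 1.0 for homozygous fusions (both
    homologs fused, so every haploid nucleus carries the metacentric) and 0.5
    for heterozygous ones (half of round-spermatid nuclei carry it).
    """

    fusions: list[tuple[str, str]] = field(default_factory=list)
    zygosity: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fusions = [tuple(sorted(f)) for f in self.fusions]
        self.zygosity = {tuple(sorted(k)): v for k, v in self.zygosity.items()}
        seen: set[str] = set()
        for pair in self.fusions:
            a, b = pair
            if a == b:
                raise ValueError(f"fusion joins {a} with itself")
            if a in seen or b in seen:
                raise ValueError(f"chromosome in more than one fusion: {pair}")
            seen.update(pair)
            zyg = self.zygosity.get(pair)
            if zyg not in ("homozygous", "heterozygous"):
                raise ValueError(f"fusion {pair} needs zygosity homozygous|heterozygous")

    def penetrance(self, pair: tuple[str, str]) -> float:
        return 1.0 if self.zygosity[tuple(sorted(pair))] == "homozygous" else 0.5

    @property
    def fused_chroms(self) -> set[str]:
        return {c for pair in self.fusions for c in pair}


def mouse_like_lengths(n_chrom: int = 21, scale: float = 1.0) -> list[int]:
    """mm10-like chromosome lengths (bp), optionally scaled down for small tests."""
    if not 1 <= n_chrom <= 21:
        raise ValueError("mouse-like genome has 1..21 chromosomes")
    return [int(m * 1e6 * scale) for m in _MM10_MBP[:n_chrom]]


def simulate_genome(
    n_chrom: int,
    lengths: list[int],
    seed: int,
    density_resolution: int = 500_000,
    ab_block_mean_bp: float = 2e6,
) -> GenomeAssembly:
    """Make an acrocentric assembly with a blocky pseudo-random gene-density track.

    The gene-density track alternates between gene-rich and gene-poor blocks
    (geometric block lengths, mean ``ab_block_mean_bp``); the rich/poor
    partition doubles as the ground-truth A/B plaid for the contact simulator.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    if len(lengths) != n_chrom:
        raise ValueError("lengths must have n_chrom entries")
    if any(l <= 0 for l in lengths):
        raise ValueError("chromosome lengths must be positive")
    names = _default_names(n_chrom)
    chrom_lengths = dict(zip(names, (int(l) for l in lengths)))
    rng = np.random.default_rng(seed)
    block_mean_bins = max(1.0, ab_block_mean_bp / density_resolution)
    density: list[np.ndarray] = []
    for name in names:
        n = -(-chrom_lengths[name] // density_resolution)
        sign = rng.integers(0, 2) * 2 - 1  # starting compartment
        track = np.empty(n)
        i = 0
        while i < n:
            run = 1 + rng.geometric(1.0 / block_mean_bins)
            run = min(run, n - i)
            base = 8.0 if sign > 0 else 2.0  # genes per bin, A-rich vs B-poor
            track[i : i + run] = rng.gamma(shape=4.0, scale=base / 4.0, size=run)
            sign = -sign
            i += run
        density.append(track)
    return GenomeAssembly(
        chrom_names=names,
        chrom_lengths=chrom_lengths,
        centromere_pos={n: 0 for n in names},
        gene_density=np.concatenate(density),
        density_resolution=density_resolution,
    )


def make_bin_table(genome: GenomeAssembly, resolution: int) -> pd.DataFrame:
    """Tile every chromosome with half-open bins of ``resolution`` bp.

    Returns a DataFrame with columns chrom, start, end, bin_id; the last bin of
    each chromosome is clipped to the chromosome end.
    """
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    rows = []
    for chrom in genome.chrom_names:
        length = genome.chrom_lengths[chrom]
        starts = np.arange(0, length, resolution, dtype=np.int64)
        ends = np.minimum(starts + resolution, length)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    table = pd.concat(rows, ignore_index=True)
    table["bin_id"] = np.arange(len(table))
    return table
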