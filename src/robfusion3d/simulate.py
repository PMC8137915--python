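"""Synthetic contact pairs and spermatocyte foci tables.

Contact pairs are drawn from an explicit finite mixture whose components map
one-to-one onto the phenomena the downstream analyses quantify:

* **cis** (weight 1.0): chromosome chosen proportional to length, separation
  from a truncated power law ``s^(-decay_exponent)``, modulated by the
  compartment plaid (same-sign bins enriched) and TAD blocks (within-domain
  enrichment) via rejection sampling;
* **trans background** (weight ``trans_background * meiotic_trans_boost``):
  uniform random heterologous pairs;
* **chromocenter** (weight ``chromocenter_weight``): pericentromeric bins of a
  random chromosome pair, emulating the round-spermatid chromocenter;
* **fused arms** (weight ``fused_arm_weight`` per fusion): pericentromeric
  pairs between the two partners of each Rb fusion.  Penetrance is applied by
  thinning: with probability ``1 - p`` the draw falls back to an ordinary
  trans-background pair, modelling the fraction of haploid nuclei that do not
  carry a heterozygous metacentric.  Expected fused pericentromeric mass is
  therefore exactly linear in penetrance;
* **loops** (weight ``loop_weight``): cis pairs pinned to TAD boundary-pair
  corners (loop-domain corner peaks).

Fused-arm contacts are emitted in reference (unfused) coordinates, i.e. as
trans pairs between the two partner chromosomes, matching how a fusion appears
on maps aligned to a standard all-acrocentric assembly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeAssembly, Karyotype
from .profiles import ArmParams, CellTypeProfile, FociSimParams

__all__ = [
    "GenomeStructure",
    "simulate_structure",
    "simulate_contact_pairs",
    "mixture_weights",
    "simulate_foci_cells",
    "write_pairs",
    "read_pairs",
    "write_chrom_sizes",
    "write_foci",
]

_MIN_SEP = 1_000  # bp; lower cutoff of the cis power law


@dataclass
class GenomeStructure:
    """Ground-truth latent structure used by the generator (and by tests).

    ``plaid_sign``: per-chromosome ±1 arrays at ``resolution`` (A = +1);
    ``tad_boundaries``: per-chromosome sorted boundary positions in bp
    (excluding 0 and the chromosome end).
    """

    resolution: int
    plaid_sign: dict[str, np.ndarray]
    tad_boundaries: dict[str, np.ndarray]


def simulate_structure(
    genome: GenomeAssembly,
    seed: int,
    resolution: int = 500_000,
    tad_mean_bp: float = 800_000,
) -> GenomeStructure:
    """Derive the plaid from the assembly's gene-density track and plant TADs.

    The A/B sign is +1 where gene density exceeds the chromosome median (the
    gene-rich blocks written by :func:`robfusion3d.genome.simulate_genome`),
    so the plaid is deterministic given the assembly.  TAD boundaries are
    drawn once per structure seed with mean domain length ``tad_mean_bp``.
    """
    rng = np.random.default_rng(seed)
    density = genome.gene_density_at(resolution)
    plaid: dict[str, np.ndarray] = {}
    tads: dict[str, np.ndarray] = {}
    offset = 0
    for chrom in genome.chrom_names:
        n = -(-genome.chrom_lengths[chrom] // resolution)
        track = density[offset : offset + n]
        offset += n
        plaid[chrom] = np.where(track > np.median(track), 1, -1).astype(np.int8)
        bounds = []
        pos = 0.0
        length = genome.chrom_lengths[chrom]
        while True:
            pos += rng.uniform(0.5 * tad_mean_bp, 1.5 * tad_mean_bp)
            if pos >= length:
                break
            bounds.append(pos)
        tads[chrom] = np.asarray(bounds, dtype=np.int64)
    return GenomeStructure(resolution=resolution, plaid_sign=plaid, tad_boundaries=tads)


def mixture_weights(
    genome: GenomeAssembly, karyotype: Karyotype, profile: CellTypeProfile
) -> dict[str, float]:
    """Unnormalized mixture masses of the generator's components.

    Each fusion's mass is scaled by its partner length product relative to
    the genome-average chromosome-pair product, so the fused-pair interaction
    ratio (a per-bin-pair mean) is independent of which chromosomes fused —
    matching the observation that fusions of one zygosity share one ratio.
    """
    weights = {
        "cis": 1.0,
        "trans": profile.effective_trans,
        "chromocenter": profile.chromocenter_weight,
        "loop": profile.loop_weight,
    }
    lengths = [genome.chrom_lengths[c] for c in genome.chrom_names]
    if len(lengths) >= 2:
        total = float(sum(lengths))
        sumsq = float(sum(l * l for l in lengths))
        ref = (total * total - sumsq) / (len(lengths) * (len(lengths) - 1))
    else:
        ref = None
    for pair in karyotype.fusions:
        size = genome.chrom_lengths[pair[0]] * genome.chrom_lengths[pair[1]]
        scale = size / ref if ref else 1.0
        weights[f"fused:{pair[0]}|{pair[1]}"] = profile.fused_arm_weight * scale
    return weights


def _power_law_separations(rng, n: int, alpha: float, smax: np.ndarray) -> np.ndarray:
    """Inverse-CDF samples of p(s) ~ s^-alpha on [_MIN_SEP, smax] (vectorized)."""
    u = rng.random(n)
    a, b = float(_MIN_SEP), smax.astype(float)
    if abs(alpha - 1.0) < 1e-12:
        return a * np.exp(u * np.log(b / a))
    e = 1.0 - alpha
    return (a**e + u * (b**e - a**e)) ** (1.0 / e)


def simulate_contact_pairs(
    genome: GenomeAssembly,
    karyotype: Karyotype,
    profile: CellTypeProfile,
    n_pairs: int,
    seed: int,
    structure: GenomeStructure | None = None,
) -> pd.DataFrame:
    """Draw ``n_pairs`` contact records (chrom1, pos1, chrom2, pos2).

    Output follows the sorted-pair convention: chrom1 precedes chrom2 in
    genome order; pos1 <= pos2 within a chromosome.  Reproducible and
    byte-identical for identical inputs and seed.
    """
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    for pair in karyotype.fusions:
        for chrom in pair:
            if chrom not in genome.chrom_lengths:
                raise ValueError(f"fusion chromosome {chrom} not in genome")
    if structure is None:
        structure = simulate_structure(genome, seed=seed)
    rng = np.random.default_rng(seed)
    cols = {"chrom1": [], "pos1": [], "chrom2": [], "pos2": []}
    if n_pairs == 0:
        return pd.DataFrame(cols).astype(
            {"chrom1": str, "pos1": np.int64, "chrom2": str, "pos2": np.int64}
        )

    names = genome.chrom_names
    order = {c: i for i, c in enumerate(names)}
    lengths = np.array([genome.chrom_lengths[c] for c in names], dtype=float)
    lprob = lengths / lengths.sum()
    pericen = min(profile.pericentromere_bp, lengths.min())

    weights = mixture_weights(genome, karyotype, profile)
    if len(names) < 2:  # no heterologous partner exists
        for key in list(weights):
            if key != "cis" and key != "loop":
                weights[key] = 0.0
    keys = list(weights)
    w = np.array([weights[k] for k in keys])
    counts = rng.multinomial(n_pairs, w / w.sum())

    chunks: list[pd.DataFrame] = []
    for key, n in zip(keys, counts):
        if n == 0:
            continue
        if key == "cis":
            chunks.append(_draw_cis(rng, n, genome, profile, structure, lprob))
        elif key == "trans":
            chunks.append(_draw_trans(rng, n, names, lengths, lprob))
        elif key == "chromocenter":
            # partners drawn proportional to length, as for background trans,
            # so larger chromosomes contribute more chromocenter mass
            ci = rng.choice(len(names), size=n, p=lprob)
            cj = rng.choice(len(names), size=n, p=lprob)
            redo = ci == cj
            while redo.any():
                k = int(redo.sum())
                ci[redo] = rng.choice(len(names), size=k, p=lprob)
                cj[redo] = rng.choice(len(names), size=k, p=lprob)
                redo = ci == cj
            chunks.append(
                pd.DataFrame(
                    {
                        "chrom1": np.array(names)[ci],
                        "pos1": rng.integers(0, int(pericen), size=n),
                        "chrom2": np.array(names)[cj],
                        "pos2": rng.integers(0, int(pericen), size=n),
                    }
                )
            )
        elif key == "loop":
            chunks.append(_draw_loops(rng, n, genome, structure, lprob))
        else:  # fused:<a>|<b>
            a, b = key.split(":", 1)[1].split("|")
            p = karyotype.penetrance((a, b))
            hit = rng.random(n) < p
            n_hit = int(hit.sum())
            if n_hit:
                chunks.append(
                    pd.DataFrame(
                        {
                            "chrom1": a,
                            "pos1": rng.integers(0, int(pericen), size=n_hit),
                            "chrom2": b,
                            "pos2": rng.integers(0, int(pericen), size=n_hit),
                        }
                    )
                )
            if n - n_hit:  # nuclei without the metacentric: ordinary trans contact
                chunks.append(_draw_trans(rng, n - n_hit, names, lengths, lprob))

    pairs = pd.concat(chunks, ignore_index=True)
    # canonical sorted-pair convention
    o1 = pairs["chrom1"].map(order).to_numpy()
    o2 = pairs["chrom2"].map(order).to_numpy()
    flip = (o1 > o2) | ((o1 == o2) & (pairs["pos1"].to_numpy() > pairs["pos2"].to_numpy()))
    c1, c2 = pairs["chrom1"].to_numpy().copy(), pairs["chrom2"].to_numpy().copy()
    p1, p2 = pairs["pos1"].to_numpy().copy(), pairs["pos2"].to_numpy().copy()
    c1[flip], c2[flip] = c2[flip], c1[flip]
    p1[flip], p2[flip] = p2[flip], p1[flip]
    out = pd.DataFrame(
        {"chrom1": c1, "pos1": p1.astype(np.int64), "chrom2": c2, "pos2": p2.astype(np.int64)}
    )
    return out.iloc[rng.permutation(len(out))].reset_index(drop=True)


def _draw_cis(rng, n, genome, profile, structure, lprob) -> pd.DataFrame:
    names = genome.chrom_names
    res = structure.resolution
    out_c, out_p1, out_p2 = [], [], []
    need = n
    wmax = (1.0 + profile.compartment_strength) * (1.0 + profile.tad_strength)
    while need > 0:
        m = max(2 * need, 1024)
        ci = rng.choice(len(names), size=m, p=lprob)
        length = np.array([genome.chrom_lengths[c] for c in names], dtype=float)[ci]
        sep = _power_law_separations(rng, m, profile.decay_exponent, length - 1)
        sep = np.minimum(sep, length - 1)
        p1 = rng.random(m) * (length - sep)
        p2 = p1 + sep
        # modulation weights from plaid and TAD co-membership
        wgt = np.ones(m)
        for k, chrom in enumerate(names):
            sel = ci == k
            if not sel.any():
                continue
            sign = structure.plaid_sign[chrom]
            b1 = np.minimum((p1[sel] // res).astype(int), len(sign) - 1)
            b2 = np.minimum((p2[sel] // res).astype(int), len(sign) - 1)
            same_comp = sign[b1] == sign[b2]
            bounds = structure.tad_boundaries[chrom]
            d1 = np.searchsorted(bounds, p1[sel])
            d2 = np.searchsorted(bounds, p2[sel])
            wloc = np.where(same_comp, 1.0 + profile.compartment_strength, 1.0)
            wloc = wloc * np.where(d1 == d2, 1.0 + profile.tad_strength, 1.0)
            wgt[sel] = wloc
        keep = rng.random(m) < wgt / wmax
        k = min(int(keep.sum()), need)
        idx = np.flatnonzero(keep)[:k]
        out_c.append(np.array(names)[ci[idx]])
        out_p1.append(p1[idx].astype(np.int64))
        out_p2.append(p2[idx].astype(np.int64))
        need -= k
    return pd.DataFrame(
        {
            "chrom1": np.concatenate(out_c),
            "pos1": np.concatenate(out_p1),
            "chrom2": np.concatenate(out_c),
            "pos2": np.concatenate(out_p2),
        }
    )


def _draw_trans(rng, n, names, lengths, lprob) -> pd.DataFrame:
    # both ends length-proportional, jointly conditioned on distinct chromosomes:
    # P({i, j}) = 2 l_i l_j / (1 - sum_k l_k^2)
    ci = rng.choice(len(names), size=n, p=lprob)
    cj = rng.choice(len(names), size=n, p=lprob)
    redo = ci == cj
    while redo.any():
        k = int(redo.sum())
        ci[redo] = rng.choice(len(names), size=k, p=lprob)
        cj[redo] = rng.choice(len(names), size=k, p=lprob)
        redo = ci == cj
    p1 = (rng.random(n) * lengths[ci]).astype(np.int64)
    p2 = (rng.random(n) * lengths[cj]).astype(np.int64)
    arr = np.array(names)
    return pd.DataFrame({"chrom1": arr[ci], "pos1": p1, "chrom2": arr[cj], "pos2": p2})


def _draw_loops(rng, n, genome, structure, lprob) -> pd.DataFrame:
    """Pairs pinned near consecutive TAD boundary pairs (loop-domain corners)."""
    names = genome.chrom_names
    res = structure.resolution
    rows = {"chrom1": [], "pos1": [], "chrom2": [], "pos2": []}
    # domains with both ends at internal boundaries or chromosome ends
    domains = []
    for chrom in names:
        edges = np.concatenate(([0], structure.tad_boundaries[chrom], [genome.chrom_lengths[chrom]]))
        for s, e in zip(edges[:-1], edges[1:]):
            domains.append((chrom, int(s), int(e)))
    pick = rng.integers(0, len(domains), size=n)
    for idx in pick:
        chrom, s, e = domains[idx]
        jitter = res // 4 or 1
        a = min(max(s + int(rng.integers(0, jitter)), 0), genome.chrom_lengths[chrom] - 1)
        b = min(max(e - 1 - int(rng.integers(0, jitter)), 0), genome.chrom_lengths[chrom] - 1)
        rows["chrom1"].append(chrom)
        rows["pos1"].append(min(a, b))
        rows["chrom2"].append(chrom)
        rows["pos2"].append(max(a, b))
    return pd.DataFrame(rows)


def gaussian_null_trans_matrix(
    n_bins: int,
    seed: int,
    mean: float = 100.0,
    sd: float = 10.0,
    resolution: int = 500_000,
):
    """A two-chromosome contact matrix whose per-bin trans signals are i.i.d. Gaussian.

    Bin *i* of the first chromosome is paired with bin *i* of the second in a
    single trans cell carrying a Normal(mean, sd) value (truncated at 0), so
    each bin's summed trans signal is one Gaussian draw.  Used for null
    calibration of the trans-region caller.
    """
    from .matrix import ContactMatrix
    import scipy.sparse as sp

    if n_bins % 2:
        raise ValueError("n_bins must be even (two equal chromosomes)")
    half = n_bins // 2
    length = half * resolution
    genome = GenomeAssembly(
        chrom_names=["chrA", "chrB"],
        chrom_lengths={"chrA": length, "chrB": length},
        centromere_pos={"chrA": 0, "chrB": 0},
    )
    from .genome import make_bin_table

    bins = make_bin_table(genome, resolution)
    rng = np.random.default_rng(seed)
    values = np.clip(rng.normal(mean, sd, size=half), 1e-6, None)
    rows = np.arange(half)
    cols = half + np.arange(half)
    upper = sp.coo_matrix((values, (rows, cols)), shape=(n_bins, n_bins)).tocsr()
    counts = (upper + upper.T).tocsr()
    return ContactMatrix(resolution, bins, counts)


# ---------------------------------------------------------------------------
# foci simulation


def simulate_foci_cells(
    params: FociSimParams,
    n_cells: int,
    arms_per_cell: dict[str, int],
    seed: int | None = None,
    individual_id: str = "M1",
    cell_id_offset: int = 0,
) -> pd.DataFrame:
    """Simulate per-arm MLH1/RAD51 records for ``n_cells`` spermatocytes.

    Returns the flat arm table used on disk (one row per chromosome arm):
    individual_id, cell_id, arm_id, arm_type, synapsis_state,
    centromere_signals, axis_length_um, mlh1_positions_pct (semicolon-joined),
    synapsis_boundary_pct, rad51_count.

    Per arm, the CO count is drawn from the arm type's categorical; positions
    are Beta draws reported as % of axis length from the centromere (0-100);
    on asynapsed arms the foci concentrate at the synapsis boundary; 2-CEN
    arms get a distal displacement.  The cell's RAD51 count is Poisson with
    mean ``rad51_per_co`` x total CO count.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    rows = []
    for ci in range(n_cells):
        cell = f"{individual_id}_c{cell_id_offset + ci}"
        total_co = 0
        cell_rows = []
        for arm_type, n_arms in arms_per_cell.items():
            ap = params.arms.get(arm_type)
            if ap is None:
                raise ValueError(f"no parameters for arm type {arm_type!r}")
            for ai in range(n_arms):
                row = _draw_arm(rng, params, arm_type, ap)
                row.update(individual_id=individual_id, cell_id=cell, arm_id=f"{arm_type}_{ai}")
                total_co += len(row.pop("_positions"))
                cell_rows.append(row)
        rad51 = int(rng.poisson(params.rad51_per_co * total_co))
        for row in cell_rows:
            row["rad51_count"] = rad51
        rows.extend(cell_rows)
    cols = [
        "individual_id",
        "cell_id",
        "arm_id",
        "arm_type",
        "synapsis_state",
        "centromere_signals",
        "axis_length_um",
        "mlh1_positions_pct",
        "synapsis_boundary_pct",
        "rad51_count",
    ]
    return pd.DataFrame(rows)[cols]


def _draw_arm(rng, params: FociSimParams, arm_type: str, ap: ArmParams) -> dict:
    counts = sorted(ap.co_count_probs)
    probs = np.array([ap.co_count_probs[c] for c in counts])
    n_co = int(rng.choice(counts, p=probs))
    axis = max(float(rng.normal(ap.axis_length_mean_um, ap.axis_length_sd_um)), 0.5)
    two_cen = bool(rng.random() < ap.double_centromere_prob)
    synapsis = "NA"
    boundary = np.nan
    if ap.synapsis_probs is not None:
        states = sorted(ap.synapsis_probs)
        synapsis = str(rng.choice(states, p=np.array([ap.synapsis_probs[s] for s in states])))
        if synapsis == "asynapsed":
            boundary = float(
                np.clip(
                    rng.normal(params.synapsis_boundary_mean_pct, params.synapsis_boundary_sd_pct),
                    5,
                    95,
                )
            )
    positions = _draw_positions(rng, n_co, ap, two_cen, synapsis, boundary)
    return {
        "arm_type": arm_type,
        "synapsis_state": synapsis,
        "centromere_signals": 2 if two_cen else 1,
        "axis_length_um": round(axis, 3),
        "mlh1_positions_pct": ";".join(f"{p:.2f}" for p in positions),
        "synapsis_boundary_pct": boundary,
        "_positions": positions,
    }


def _draw_positions(rng, n_co, ap: ArmParams, two_cen, synapsis, boundary) -> list[float]:
    if n_co == 0:
        return []
    if synapsis == "asynapsed" and np.isfinite(boundary):
        # COs pile up at the synapsed/asynapsed front
        pos = np.clip(rng.normal(boundary, 3.0, size=n_co), 0, 100)
        return sorted(float(p) for p in pos)
    if n_co == 1:
        a, b = ap.pos_one_co
        pos = [100 * rng.beta(a, b)]
    elif n_co == 2:
        (a1, b1), (a2, b2) = ap.pos_two_co
        pos = [100 * rng.beta(a1, b1), 100 * rng.beta(a2, b2)]
    else:
        a, b = ap.pos_one_co
        pos = list(100 * rng.beta(a, b, size=n_co))
    if two_cen:
        pos = [min(p + ap.two_cen_distal_shift_pct, 100.0) for p in pos]
    return sorted(float(p) for p in pos)


# ---------------------------------------------------------------------------
# plain-text interfaces


def write_pairs(pairs: pd.DataFrame, path) -> None:
    """TSV, one record per contact: chrom1, pos1, chrom2, pos2 (no header)."""
    pairs.to_csv(path, sep="\t", header=False, index=False)


def read_pairs(path) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep="\t",
        names=["chrom1", "pos1", "chrom2", "pos2"],
        dtype={"chrom1": str, "pos1": np.int64, "chrom2": str, "pos2": np.int64},
    )


def write_chrom_sizes(genome: GenomeAssembly, path) -> None:
    with open(path, "w") as fh:
        for chrom in genome.chrom_names:
            fh.write(f"{chrom}\t{genome.chrom_lengths[chrom]}\n")


def write_foci(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
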