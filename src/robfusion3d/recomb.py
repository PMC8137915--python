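"""Crossover-landscape statistics from spermatocyte foci tables.

MLH1 foci mark class-I crossovers (COs) on the synaptonemal complex (SC);
RAD51 foci mark the double-strand breaks (DSBs) they mature from.  Focus
positions are recorded as a percentage of the SC axis length measured from
the centromere (0%) toward the distal telomere (100%).  All group
comparisons use the nonparametric battery dispatched by
:func:`compare_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ArmRecord",
    "FociCell",
    "read_foci",
    "cells_to_table",
    "summarize_counts",
    "positional_histogram",
    "co_density",
    "axis_length_summary",
    "stratified_distribution",
    "synapsis_boundary_co_fraction",
    "co_dsb_relationship",
    "compare_groups",
    "dunn_bonferroni",
    "interindividual_cv",
]

ARM_TYPES = ("AcrBL6", "AcrSt", "AcrRb", "MetHet", "MetHom")
COUNT_CATEGORIES = ("0", "1", "2", "3+")


@dataclass
class ArmRecord:
    arm_id: str
    arm_type: str
    axis_length_um: float
    mlh1_positions: list[float]
    centromere_signals: int = 1
    synapsis_state: str = "NA"
    synapsis_boundary_pct: float | None = None
    rad51_count: int | None = None

    def __post_init__(self) -> None:
        if self.axis_length_um <= 0:
            raise ValueError(f"arm {self.arm_id}: axis length must be > 0")
        for pos in self.mlh1_positions:
            if not 0 <= pos <= 100:
                raise ValueError(f"arm {self.arm_id}: position {pos} outside [0, 100]")
        if self.centromere_signals not in (1, 2):
            raise ValueError(f"arm {self.arm_id}: centromere_signals must be 1 or 2")
        if self.synapsis_state != "NA" and self.arm_type != "MetHet":
            raise ValueError(
                f"arm {self.arm_id}: synapsis_state applies to MetHet arms only"
            )

    @property
    def n_co(self) -> int:
        return len(self.mlh1_positions)


@dataclass
class FociCell:
    individual_id: str
    cell_id: str
    arms: list[ArmRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.arms:
            raise ValueError(f"cell {self.cell_id} has no arms")

    @property
    def total_mlh1(self) -> int:
        return sum(a.n_co for a in self.arms)

    @property
    def rad51_count(self) -> int | None:
        for arm in self.arms:
            if arm.rad51_count is not None:
                return arm.rad51_count
        return None


def read_foci(path) -> list[FociCell]:
    """Read the per-arm TSV written by the simulator into FociCell objects.

    Validation failures report the 1-based data line number.
    """
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"mlh1_positions_pct": str, "synapsis_state": str},
        keep_default_na=False,
        na_values=[""],
    )
    cells: dict[str, FociCell] = {}
    order: list[str] = []
    for lineno, row in enumerate(table.itertuples(index=False), start=2):
        raw = row.mlh1_positions_pct
        raw = "" if (not isinstance(raw, str)) else raw.strip()
        try:
            positions = [float(x) for x in raw.split(";") if x != ""]
            boundary = getattr(row, "synapsis_boundary_pct", float("nan"))
            arm = ArmRecord(
                arm_id=row.arm_id,
                arm_type=row.arm_type,
                axis_length_um=float(row.axis_length_um),
                mlh1_positions=positions,
                centromere_signals=int(row.centromere_signals),
                synapsis_state=str(row.synapsis_state),
                synapsis_boundary_pct=None if pd.isna(boundary) else float(boundary),
                rad51_count=None if pd.isna(row.rad51_count) else int(row.rad51_count),
            )
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        key = f"{row.individual_id}\t{row.cell_id}"
        if key not in cells:
            cells[key] = FociCell(str(row.individual_id), str(row.cell_id), [arm])
            order.append(key)
        else:
            cells[key].arms.append(arm)
    return [cells[k] for k in order]


def cells_to_table(cells: list[FociCell]) -> pd.DataFrame:
    """Flat per-arm view used by the summary operations."""
    rows = []
    for cell in cells:
        for arm in cell.arms:
            rows.append(
                {
                    "individual_id": cell.individual_id,
                    "cell_id": cell.cell_id,
                    "arm_id": arm.arm_id,
                    "arm_type": arm.arm_type,
                    "n_co": arm.n_co,
                    "positions": arm.mlh1_positions,
                    "axis_length_um": arm.axis_length_um,
                    "centromere_signals": arm.centromere_signals,
                    "synapsis_state": arm.synapsis_state,
                    "synapsis_boundary_pct": arm.synapsis_boundary_pct,
                    "rad51_count": arm.rad51_count,
                }
            )
    return pd.DataFrame(rows)


def _count_category(n: int) -> str:
    return str(n) if n < 3 else "3+"


def summarize_counts(cells: list[FociCell], group_by: str = "arm_type") -> dict:
    """CO-count categorical (0/1/2/3+) per group plus a chi-square comparison.

    With a single group the comparison is skipped.  The chi-square (Pearson,
    no continuity correction) is flagged when any expected count drops
    below 5.
    """
    table = cells_to_table(cells)
    if len(table) == 0:
        raise ValueError("no arms to summarize")
    table["category"] = table["n_co"].map(_count_category)
    groups = sorted(table[group_by].unique())
    props = {}
    counts = np.zeros((len(groups), len(COUNT_CATEGORIES)))
    for gi, group in enumerate(groups):
        sub = table[table[group_by] == group]
        for cj, cat in enumerate(COUNT_CATEGORIES):
            counts[gi, cj] = (sub["category"] == cat).sum()
        props[group] = {
            cat: counts[gi, cj] / len(sub) for cj, cat in enumerate(COUNT_CATEGORIES)
        }
    result = {"proportions": props, "n_per_group": {g: int(c.sum()) for g, c in zip(groups, counts)}}
    if len(groups) >= 2:
        used = counts[:, counts.sum(axis=0) > 0]
        chi2, p, dof, expected = stats.chi2_contingency(used, correction=False)
        result.update(
            chi_square=float(chi2),
            p_value=float(p),
            dof=int(dof),
            low_expected_warning=bool((expected < 5).any()),
        )
    return result


def positional_histogram(
    cells: list[FociCell],
    arm_filter=None,
    n_co_filter: int | None = None,
    n_intervals: int = 10,
) -> dict:
    """Focus frequencies per relative-position interval plus the cumulative curve.

    Intervals are half-open ([0,10), ..., [90,100]); the last is closed so a
    focus at exactly 100% is counted.  ``arm_filter`` is a predicate over the
    flat arm rows (or an arm_type string); ``n_co_filter`` restricts to arms
    with that many COs.
    """
    table = cells_to_table(cells)
    if isinstance(arm_filter, str):
        table = table[table["arm_type"] == arm_filter]
    elif callable(arm_filter):
        table = table[table.apply(arm_filter, axis=1)]
    if n_co_filter is not None:
        table = table[table["n_co"] == n_co_filter]
    positions = [p for plist in table["positions"] for p in plist]
    if not positions:
        raise ValueError("no foci left after filtering")
    edges = np.linspace(0, 100, n_intervals + 1)
    idx = np.minimum(np.digitize(positions, edges[1:-1], right=False), n_intervals - 1)
    hist = np.bincount(idx, minlength=n_intervals) / len(positions)
    return {
        "edges": edges,
        "frequencies": hist,
        "cumulative": np.cumsum(hist),
        "n_foci": len(positions),
        "n_arms": int(len(table)),
    }


def co_density(cells: list[FociCell], group_by: str = "arm_type") -> dict:
    """Per-arm CO density (foci per um of SC axis) with pairwise Mann-Whitney."""
    table = cells_to_table(cells)
    table["density"] = table["n_co"] / table["axis_length_um"]
    groups = sorted(table[group_by].unique())
    values = {g: table.loc[table[group_by] == g, "density"].to_numpy() for g in groups}
    result = {
        "mean_density": {g: float(v.mean()) for g, v in values.items()},
        "values": values,
        "pairwise": {},
    }
    for i, g1 in enumerate(groups):
        for g2 in groups[i + 1 :]:
            u, p = stats.mannwhitneyu(values[g1], values[g2], alternative="two-sided")
            result["pairwise"][(g1, g2)] = {"U": float(u), "p_value": float(p)}
    return result


def axis_length_summary(cells: list[FociCell], group_by: str = "arm_type") -> dict:
    """Per-group axis-length mean/SD, per-cell total SC length and Dunn's tests."""
    table = cells_to_table(cells)
    groups = sorted(table[group_by].unique())
    values = {g: table.loc[table[group_by] == g, "axis_length_um"].to_numpy() for g in groups}
    per_cell = table.groupby(["individual_id", "cell_id"])["axis_length_um"].sum()
    result = {
        "mean": {g: float(v.mean()) for g, v in values.items()},
        "sd": {g: float(v.std(ddof=1)) if len(v) > 1 else float("nan") for g, v in values.items()},
        "per_cell_total_um": per_cell,
    }
    if len(groups) >= 2:
        result["dunn"] = dunn_bonferroni([values[g] for g in groups], labels=groups)
    return result


def stratified_distribution(
    cells: list[FociCell],
    stratify_by: str,
    arm_filter=None,
    n_co_filter: int | None = None,
    n_intervals: int = 10,
) -> dict:
    """Positional histograms split by synapsis state or centromere-signal count.

    Empty strata are omitted (listed under ``empty_strata``).
    """
    if stratify_by not in ("synapsis_state", "centromere_signals"):
        raise ValueError("stratify_by must be synapsis_state or centromere_signals")
    table = cells_to_table(cells)
    if isinstance(arm_filter, str):
        table = table[table["arm_type"] == arm_filter]
    elif callable(arm_filter):
        table = table[table.apply(arm_filter, axis=1)]
    strata = sorted(table[stratify_by].unique(), key=str)
    out: dict = {"strata": {}, "empty_strata": []}
    if isinstance(arm_filter, str):
        base_filter = lambda r, t=arm_filter: r["arm_type"] == t  # noqa: E731
    elif callable(arm_filter):
        base_filter = arm_filter
    else:
        base_filter = lambda r: True  # noqa: E731
    for stratum in strata:
        try:
            hist = positional_histogram(
                cells,
                arm_filter=lambda r, s=stratum: base_filter(r) and r[stratify_by] == s,
                n_co_filter=n_co_filter,
                n_intervals=n_intervals,
            )
        except ValueError:
            out["empty_strata"].append(stratum)
            continue
        out["strata"][stratum] = hist
    return out


def synapsis_boundary_co_fraction(cells: list[FociCell], tolerance_pct: float = 5) -> float:
    """Fraction of COs on asynapsed arms lying within ``tolerance_pct`` of the
    synapsed/asynapsed boundary."""
    table = cells_to_table(cells)
    asyn = table[
        (table["synapsis_state"] == "asynapsed") & table["synapsis_boundary_pct"].notna()
    ]
    if len(asyn) == 0:
        raise ValueError("no asynapsed arms with a recorded synapsis boundary")
    at_boundary = 0
    total = 0
    for row in asyn.itertuples():
        for pos in row.positions:
            total += 1
            if abs(pos - row.synapsis_boundary_pct) <= tolerance_pct:
                at_boundary += 1
    return at_boundary / total if total else float("nan")


def co_dsb_relationship(cells: list[FociCell]) -> dict:
    """Per-individual MLH1 and RAD51 means, their Spearman correlation, and the
    CO/DSB ratio mean(MLH1)/mean(RAD51) per individual.

    With fewer than 3 individuals carrying RAD51 counts, the correlation is
    reported as undefined while ratios are still returned.
    """
    per_ind: dict[str, dict[str, list[float]]] = {}
    for cell in cells:
        rec = per_ind.setdefault(cell.individual_id, {"mlh1": [], "rad51": []})
        rec["mlh1"].append(cell.total_mlh1)
        if cell.rad51_count is not None:
            rec["rad51"].append(cell.rad51_count)
    rows = []
    for ind, rec in per_ind.items():
        mean_mlh1 = float(np.mean(rec["mlh1"]))
        mean_rad51 = float(np.mean(rec["rad51"])) if rec["rad51"] else float("nan")
        rows.append(
            {
                "individual_id": ind,
                "mean_mlh1": mean_mlh1,
                "mean_rad51": mean_rad51,
                "co_dsb_ratio": mean_mlh1 / mean_rad51 if mean_rad51 else float("nan"),
            }
        )
    summary = pd.DataFrame(rows)
    defined = summary["mean_rad51"].notna() & (summary["mean_rad51"] > 0)
    result = {"per_individual": summary}
    if defined.sum() >= 3:
        rho, p = stats.spearmanr(
            summary.loc[defined, "mean_mlh1"], summary.loc[defined, "mean_rad51"]
        )
        result["spearman_rho"] = float(rho)
        result["p_value"] = float(p)
    else:
        result["spearman_rho"] = None
        result["p_value"] = None
    return result


def interindividual_cv(cells: list[FociCell]) -> pd.DataFrame:
    """Coefficient of variation of per-cell MLH1 counts, per individual."""
    rows = []
    per_ind: dict[str, list[int]] = {}
    for cell in cells:
        per_ind.setdefault(cell.individual_id, []).append(cell.total_mlh1)
    for ind, counts in per_ind.items():
        arr = np.asarray(counts, dtype=float)
        mean = arr.mean()
        rows.append(
            {
                "individual_id": ind,
                "mean_mlh1_per_cell": mean,
                "cv": float(arr.std(ddof=1) / mean) if len(arr) > 1 and mean > 0 else float("nan"),
                "n_cells": len(arr),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nonparametric test dispatch


def dunn_bonferroni(samples: list[np.ndarray], labels: list | None = None) -> dict:
    """Dunn's post-hoc z-tests on mean ranks with Bonferroni adjustment.

    Ties are handled with the standard tie correction; adjusted
    p = min(1, m * p) with m the number of pairwise comparisons.
    """
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two samples")
    sizes = [len(s) for s in samples]
    if min(sizes) == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([np.asarray(s, dtype=float) for s in samples])
    ranks = stats.rankdata(pooled)
    n = len(pooled)
    mean_ranks = []
    start = 0
    for size in sizes:
        mean_ranks.append(ranks[start : start + size].mean())
        start += size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12 * (n - 1)) if n > 1 else 0.0
    m = k * (k - 1) // 2
    out = {}
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term) * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
            p = 2 * stats.norm.sf(abs(z))
            key = (
                (labels[i], labels[j]) if labels is not None else (i, j)
            )
            out[key] = {"z": float(z), "p_value": float(p), "p_adjusted": min(1.0, m * p)}
    return out


def compare_groups(samples: list, test: str, labels: list | None = None) -> dict:
    """Dispatch the study's nonparametric battery.

    ``test`` is one of mann_whitney, kruskal_wallis, dunn_bonferroni,
    wilcoxon_rank_sum, spearman, chi_square.  Mann-Whitney uses the exact
    null distribution on small samples without ties (scipy's default).
    """
    arrays = [np.asarray(s, dtype=float) for s in samples]
    if any(len(a) == 0 for a in arrays):
        raise ValueError("empty sample")
    if test == "mann_whitney":
        if len(arrays) != 2:
            raise ValueError("mann_whitney needs exactly two samples")
        u, p = stats.mannwhitneyu(arrays[0], arrays[1], alternative="two-sided")
        return {"statistic": float(u), "p_value": float(p)}
    if test == "wilcoxon_rank_sum":
        if len(arrays) != 2:
            raise ValueError("wilcoxon_rank_sum needs exactly two samples")
        z, p = stats.ranksums(arrays[0], arrays[1])
        return {"statistic": float(z), "p_value": float(p)}
    if test == "kruskal_wallis":
        h, p = stats.kruskal(*arrays)
        return {"statistic": float(h), "p_value": float(p)}
    if test == "dunn_bonferroni":
        return dunn_bonferroni(arrays, labels=labels)
    if test == "spearman":
        if len(arrays) != 2 or len(arrays[0]) != len(arrays[1]):
            raise ValueError("spearman needs two paired samples")
        rho, p = stats.spearmanr(arrays[0], arrays[1])
        return {"statistic": float(rho), "p_value": float(p)}
    if test == "chi_square":
        table = np.asarray(samples, dtype=float)
        chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
        return {
            "statistic": float(chi2),
            "p_value": float(p),
            "dof": int(dof),
            "low_expected_warning": bool((expected < 5).any()),
        }
    raise ValueError(f"unknown test {test!r}")
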