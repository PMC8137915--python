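"""Crossover-landscape statistics and the nonparametric test battery."""

import itertools
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from robfusion3d.profiles import default_foci_params
from robfusion3d.recomb import (
    ArmRecord,
    FociCell,
    axis_length_summary,
    cells_to_table,
    co_density,
    co_dsb_relationship,
    compare_groups,
    dunn_bonferroni,
    interindividual_cv,
    positional_histogram,
    read_foci,
    stratified_distribution,
    summarize_counts,
    synapsis_boundary_co_fraction,
)
from robfusion3d.simulate import simulate_foci_cells, write_foci


def make_cells(arm_specs, individual="M1"):
    """arm_specs: list of dicts per cell; each dict maps kwargs for ArmRecord."""
    cells = []
    for ci, arms in enumerate(arm_specs):
        records = [
            ArmRecord(arm_id=f"a{ai}", **kw) for ai, kw in enumerate(arms)
        ]
        cells.append(FociCell(individual, f"{individual}_c{ci}", records))
    return cells


def arm(n_co=1, arm_type="AcrSt", axis=10.0, **kw):
    positions = kw.pop("positions", list(np.linspace(20, 80, n_co)) if n_co else [])
    return dict(
        arm_type=arm_type, axis_length_um=axis, mlh1_positions=positions, **kw
    )


def mann_whitney_oracle(x, y):
    """Exact two-sided Mann-Whitney p by enumeration of rank assignments."""
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    u_obs = ranks[:nx].sum() - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(nx + ny), nx):
        r = ranks[list(combo)]
        us.append(r.sum() - nx * (nx + 1) / 2)
    us = np.asarray(us)
    p = 2 * min((us <= u_obs).mean(), (us >= u_obs).mean())
    return u_obs, min(p, 1.0)


class TestReadFoci:
    def test_round_trip(self, tmp_path):
        table = simulate_foci_cells(
            default_foci_params(), 3, {"AcrRb": 4, "MetHom": 2}, seed=1
        )
        path = tmp_path / "foci.tsv"
        write_foci(table, path)
        cells = read_foci(path)
        assert len(cells) == 3
        assert all(len(c.arms) == 6 for c in cells)
        back = cells_to_table(cells)
        assert back["n_co"].sum() == sum(
            len(s.split(";")) if s else 0 for s in table["mlh1_positions_pct"]
        )

    def test_position_out_of_range_rejected_with_line(self, tmp_path):
        table = simulate_foci_cells(default_foci_params(), 1, {"AcrSt": 2}, seed=2)
        table.loc[1, "mlh1_positions_pct"] = "105.0"
        path = tmp_path / "bad.tsv"
        write_foci(table, path)
        with pytest.raises(ValueError, match="line 3"):
            read_foci(path)

    def test_empty_positions_is_zero_focus_arm(self, tmp_path):
        table = simulate_foci_cells(default_foci_params(), 1, {"AcrSt": 1}, seed=3)
        table.loc[0, "mlh1_positions_pct"] = ""
        path = tmp_path / "zero.tsv"
        write_foci(table, path)
        (cell,) = read_foci(path)
        assert cell.arms[0].n_co == 0


class TestSummarizeCounts:
    def test_all_single_co(self):
        cells = make_cells([[arm(n_co=1)] * 5])
        out = summarize_counts(cells)
        assert out["proportions"]["AcrSt"]["1"] == 1.0
        assert "chi_square" not in out  # single group: comparison skipped

    def test_chi_square_matches_closed_form(self):
        """2x2 table [[10,90],[30,70]]: expected [[20,80],[20,80]], so
        chi2 = 100/20 + 100/80 + 100/20 + 100/80 = 12.5."""
        out = compare_groups([[10, 90], [30, 70]], test="chi_square")
        assert out["statistic"] == pytest.approx(12.5)

    def test_identical_groups_p_one(self):
        cells = make_cells([[arm(n_co=1, arm_type="AcrSt"), arm(n_co=1, arm_type="AcrRb")] * 10])
        out = summarize_counts(cells)
        assert out["p_value"] == pytest.approx(1.0)

    def test_counts_above_three_binned(self):
        cells = make_cells([[arm(n_co=5, positions=[10, 20, 30, 40, 50])]])
        out = summarize_counts(cells)
        assert out["proportions"]["AcrSt"]["3+"] == 1.0


class TestPositionalHistogram:
    def test_uniform_positions_within_3se(self):
        rng = np.random.default_rng(0)
        positions = rng.uniform(0, 100, 10_000)
        cells = make_cells([[arm(positions=[p]) for p in positions]])
        hist = positional_histogram(cells)
        se = np.sqrt(0.1 * 0.9 / 10_000)
        assert np.all(np.abs(hist["frequencies"] - 0.1) < 3 * se)

    def test_point_mass_at_95_fills_last_interval(self):
        cells = make_cells([[arm(positions=[95.0])] * 4])
        hist = positional_histogram(cells)
        assert hist["frequencies"][-1] == 1.0

    def test_position_100_counted_in_last_closed_interval(self):
        cells = make_cells([[arm(positions=[100.0])]])
        hist = positional_histogram(cells)
        assert hist["frequencies"][-1] == 1.0

    def test_cumulative_ends_at_one(self):
        rng = np.random.default_rng(1)
        cells = make_cells([[arm(positions=[rng.uniform(0, 100)]) for _ in range(50)]])
        hist = positional_histogram(cells)
        assert hist["cumulative"][-1] == pytest.approx(1.0)

    def test_empty_filter_rejected(self):
        cells = make_cells([[arm(n_co=1)]])
        with pytest.raises(ValueError):
            positional_histogram(cells, arm_filter="MetHom")


class TestCoDensity:
    def test_single_focus_density(self):
        cells = make_cells([[arm(n_co=1, axis=10.0)]])
        out = co_density(cells)
        assert out["mean_density"]["AcrSt"] == pytest.approx(0.1)

    def test_doubling_axis_halves_density(self):
        a = co_density(make_cells([[arm(n_co=1, axis=5.0)] * 4]))
        b = co_density(make_cells([[arm(n_co=1, axis=10.0)] * 4]))
        assert b["mean_density"]["AcrSt"] == pytest.approx(a["mean_density"]["AcrSt"] / 2)

    def test_null_comparison_rarely_significant(self):
        """Two groups drawn from one distribution: p > 0.05 in >= 90% of seeds."""
        significant = 0
        n_seeds = 40
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            cells = make_cells(
                [
                    [arm(n_co=int(rng.integers(0, 3)), arm_type=t, axis=float(rng.normal(10, 1)))
                     for t in ["AcrSt"] * 40 + ["AcrRb"] * 40]
                ]
            )
            out = co_density(cells)
            if out["pairwise"][("AcrRb", "AcrSt")]["p_value"] <= 0.05:
                significant += 1
        assert significant <= 0.1 * n_seeds


class TestAxisLength:
    def test_per_cell_total(self):
        cells = make_cells([[arm(axis=5.0)] * 20])
        out = axis_length_summary(cells)
        assert out["per_cell_total_um"].iloc[0] == pytest.approx(100.0)

    def test_identical_groups_adjusted_p_one(self):
        cells = make_cells(
            [[arm(axis=5.0, arm_type="AcrSt"), arm(axis=5.0, arm_type="AcrRb")] * 6]
        )
        out = axis_length_summary(cells)
        for res in out["dunn"].values():
            assert res["p_adjusted"] == pytest.approx(1.0)

    def test_shifted_group_flagged(self):
        rng = np.random.default_rng(3)
        arms = []
        for t, shift in (("AcrSt", 0.0), ("AcrRb", 0.0), ("MetHom", 3.0)):
            arms += [arm(axis=float(rng.normal(10 + shift, 1)), arm_type=t) for _ in range(60)]
        out = axis_length_summary(make_cells([arms]))
        dunn = out["dunn"]
        assert dunn[("AcrRb", "MetHom")]["p_adjusted"] < 0.01
        assert dunn[("AcrSt", "MetHom")]["p_adjusted"] < 0.01
        assert dunn[("AcrRb", "AcrSt")]["p_adjusted"] > 0.05


class TestStratified:
    def test_single_stratum_when_all_synapsed(self):
        cells = make_cells(
            [[arm(arm_type="MetHet", synapsis_state="synapsed", n_co=1)] * 5]
        )
        out = stratified_distribution(cells, "synapsis_state")
        assert list(out["strata"]) == ["synapsed"]

    def test_constant_field_equals_unstratified(self):
        rng = np.random.default_rng(4)
        cells = make_cells(
            [[arm(positions=[float(rng.uniform(0, 100))]) for _ in range(50)]]
        )
        strat = stratified_distribution(cells, "centromere_signals")
        plain = positional_histogram(cells)
        np.testing.assert_allclose(strat["strata"][1]["frequencies"], plain["frequencies"])

    def test_planted_distal_shift_in_two_cen_stratum(self):
        """Simulated 2-CEN arms are displaced distally: their cumulative curve
        is dominated by the 1-CEN curve."""
        params = default_foci_params()
        met = replace(params.arms["MetHom"], double_centromere_prob=0.5)
        params = type(params)(arms={"MetHom": met}, seed=0)
        table = simulate_foci_cells(params, 400, {"MetHom": 4}, seed=5)
        path_cells = []
        from robfusion3d.recomb import read_foci as _read

        import io

        buf = io.StringIO()
        table.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        cells = _read(buf)
        out = stratified_distribution(cells, "centromere_signals", arm_filter="MetHom")
        cum1 = out["strata"][1]["cumulative"]
        cum2 = out["strata"][2]["cumulative"]
        assert np.all(cum2[:-1] <= cum1[:-1] + 1e-12)
        assert cum2[:-1].sum() < cum1[:-1].sum()


class TestSynapsisBoundary:
    def cells_with_boundary(self, positions, boundary=40.0):
        return make_cells(
            [
                [
                    arm(
                        arm_type="MetHet",
                        synapsis_state="asynapsed",
                        synapsis_boundary_pct=boundary,
                        positions=positions,
                    )
                ]
            ]
        )

    def test_focus_at_boundary_counted(self):
        assert synapsis_boundary_co_fraction(self.cells_with_boundary([40.0])) == 1.0

    def test_focus_far_from_boundary_not_counted(self):
        assert synapsis_boundary_co_fraction(self.cells_with_boundary([90.0])) == 0.0

    def test_all_foci_at_boundaries_fraction_one(self):
        cells = self.cells_with_boundary([38.0, 42.0])
        assert synapsis_boundary_co_fraction(cells, tolerance_pct=5) == 1.0

    def test_no_asynapsed_arms_rejected(self):
        cells = make_cells([[arm(n_co=1)]])
        with pytest.raises(ValueError):
            synapsis_boundary_co_fraction(cells)


class TestCoDsb:
    def individuals(self, ratios):
        cells = []
        for ind, (mlh1, rad51) in enumerate(ratios):
            cells += [
                FociCell(
                    f"M{ind}",
                    f"M{ind}_c{ci}",
                    [
                        ArmRecord(
                            arm_id="a0",
                            arm_type="AcrSt",
                            axis_length_um=10.0,
                            mlh1_positions=[50.0] * mlh1,
                            rad51_count=rad51,
                        )
                    ],
                )
                for ci in range(3)
            ]
        return cells

    def test_exact_tenfold_relationship(self):
        cells = self.individuals([(1, 10), (2, 20), (3, 30)])
        out = co_dsb_relationship(cells)
        assert out["spearman_rho"] == pytest.approx(1.0)
        np.testing.assert_allclose(out["per_individual"]["co_dsb_ratio"], 0.1)

    def test_two_individuals_correlation_undefined(self):
        cells = self.individuals([(1, 10), (2, 20)])
        out = co_dsb_relationship(cells)
        assert out["spearman_rho"] is None
        assert len(out["per_individual"]) == 2

    def test_independent_counts_rarely_significant(self):
        n_seeds = 30
        significant = 0
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            cells = self.individuals(
                [(int(rng.integers(1, 6)), int(rng.integers(10, 60))) for _ in range(10)]
            )
            out = co_dsb_relationship(cells)
            if out["p_value"] is not None and out["p_value"] <= 0.05:
                significant += 1
        assert significant <= 0.1 * n_seeds


class TestInterindividualCV:
    def test_cv_computed_per_individual(self):
        cells = make_cells([[arm(n_co=1)] * 2, [arm(n_co=2, positions=[10, 90])] * 2])
        out = interindividual_cv(cells)
        counts = np.array([2.0, 4.0])
        assert out["cv"].iloc[0] == pytest.approx(counts.std(ddof=1) / counts.mean())


class TestCompareGroups:
    def test_mann_whitney_matches_enumeration_oracle(self):
        """Exact small-sample Mann-Whitney agrees with brute-force enumeration
        of all rank arrangements (n <= 4, no ties)."""
        cases = [
            ([1, 2, 3], [4, 5, 6]),
            ([1, 4], [2, 3]),
            ([1, 2, 5, 7], [3, 4, 6, 8]),
            ([10], [1, 2, 3]),
        ]
        for x, y in cases:
            got = compare_groups([x, y], test="mann_whitney")
            u, p = mann_whitney_oracle(np.asarray(x, float), np.asarray(y, float))
            assert got["p_value"] == pytest.approx(p), (x, y)

    def test_mann_whitney_u_zero_exact_p(self):
        out = compare_groups([[1, 2, 3], [4, 5, 6]], test="mann_whitney")
        assert out["statistic"] == 0.0
        assert out["p_value"] == pytest.approx(0.1)

    def test_spearman_perfect_monotone(self):
        out = compare_groups([[1, 2, 3, 4], [10, 20, 30, 40]], test="spearman")
        assert out["statistic"] == pytest.approx(1.0)

    def test_dunn_bonferroni_cap(self):
        rng = np.random.default_rng(5)
        samples = [rng.standard_normal(20) for _ in range(3)]
        out = dunn_bonferroni(samples)
        for res in out.values():
            assert res["p_adjusted"] == pytest.approx(min(1.0, 3 * res["p_value"]))
            assert res["p_adjusted"] <= 1.0

    def test_kruskal_identical_groups(self):
        out = compare_groups([[1, 2, 3], [1, 2, 3]], test="kruskal_wallis")
        assert out["p_value"] > 0.9

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([[1, 2], []], test="mann_whitney")

    def test_unknown_test_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([[1], [2]], test="anova")


class TestParameterRecovery:
    def test_all_categoricals_recovered_within_3se(self):
        """Every arm type's CO-count categorical is recovered by
        summarize_counts within 3 binomial SE at 10^4 arms."""
        params = default_foci_params()
        arms_per_cell = {t: 4 for t in params.arms}
        table = simulate_foci_cells(params, 500, arms_per_cell, seed=6)
        import io

        buf = io.StringIO()
        table.to_csv(buf, sep="\t", index=False)
        buf.seek(0)
        cells = read_foci(buf)
        out = summarize_counts(cells)
        for arm_type, ap in params.arms.items():
            n = out["n_per_group"][arm_type]
            assert n == 2000
            probs = dict(ap.co_count_probs)
            probs.setdefault(3, 0.0)
            for cat, p_true in (("0", probs[0]), ("1", probs[1]), ("2", probs[2]), ("3+", probs[3])):
                se = np.sqrt(max(p_true * (1 - p_true), 1e-12) / n)
                assert abs(out["proportions"][arm_type][cat] - p_true) <= max(3 * se, 0.005)
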