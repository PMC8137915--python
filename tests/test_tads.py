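"""Insulation scores, TAD calling, reorganization classes and meta-borders."""

import numpy as np
import pandas as pd
import pytest

from robfusion3d.tads import (
    TadSet,
    call_tads,
    classify_tad_reorganization,
    insulation_score,
    insulation_variance_compare,
    meta_border,
)

from conftest import matrix_from_dense


def insulation_oracle(dense, window, mask=None):
    """Brute-force diamond means and log2 ratio, independent of the banded code."""
    n = dense.shape[0]
    mask = np.zeros(n, dtype=bool) if mask is None else mask
    diamonds = np.full(n, np.nan)
    for i in range(window, n - window):
        if mask[i - window : i + window + 1].any():
            continue
        total = 0.0
        for u in range(i - window, i):
            for d in range(i + 1, i + window + 1):
                total += dense[u, d]
        diamonds[i] = total / (window * window)
    mean = np.nanmean(diamonds)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log2(diamonds / mean)


def make_insulation_track(scores, resolution=50_000, chrom="chr1"):
    n = len(scores)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": np.arange(n) * resolution,
            "end": (np.arange(n) + 1) * resolution,
            "score": scores,
        }
    )


def make_tadset(domains, resolution=50_000):
    dom = pd.DataFrame(domains, columns=["chrom", "start", "end"])
    bounds = pd.DataFrame(
        [
            {"chrom": c, "position": e, "border_score": 1.0}
            for c, _, e in domains[:-1]
        ]
    )
    track = make_insulation_track(np.zeros(2), resolution)
    return TadSet(domains=dom, boundaries=bounds, insulation=track, resolution=resolution)


class TestInsulationScore:
    def test_uniform_matrix_scores_zero(self):
        n = 30
        dense = np.full((n, n), 3.0)
        m = matrix_from_dense(dense, {"chr1": n * 50_000}, 50_000)
        track = insulation_score(m, window=5)
        defined = track["score"].dropna()
        np.testing.assert_allclose(defined, 0.0, atol=1e-12)
        assert track["score"].iloc[:5].isna().all()  # undefined near ends

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(6)
        n = 40
        dense = rng.poisson(6, (n, n)).astype(float)
        dense = np.triu(dense, 1)
        dense = dense + dense.T
        mask = np.zeros(n, dtype=bool)
        mask[17] = True
        m = matrix_from_dense(dense, {"chr1": n * 50_000}, 50_000, mask=mask)
        track = insulation_score(m, window=3)
        expected = insulation_oracle(dense, window=3, mask=mask)
        np.testing.assert_allclose(track["score"].to_numpy(), expected, atol=1e-9)

    def test_two_block_junction_is_global_minimum(self):
        """Two on-diagonal blocks with no inter-block contact dip exactly at
        the junction (diamond means computed by hand on a 10-bin toy)."""
        n = 10
        dense = np.zeros((n, n))
        dense[:5, :5] = 4.0
        dense[5:, 5:] = 4.0
        np.fill_diagonal(dense, 4.0)
        m = matrix_from_dense(dense, {"chr1": n * 50_000}, 50_000)
        track = insulation_score(m, window=2)
        scores = track["score"].to_numpy()
        oracle = insulation_oracle(dense, window=2)
        np.testing.assert_allclose(scores, oracle, atol=1e-9)
        assert np.nanargmin(scores) in (4, 5)  # junction bins straddling the border

    def test_depth_invariance_after_scaling(self):
        rng = np.random.default_rng(7)
        n = 30
        dense = rng.poisson(5, (n, n)).astype(float)
        dense = dense + dense.T
        a = matrix_from_dense(dense, {"chr1": n * 50_000}, 50_000)
        b = matrix_from_dense(2 * dense, {"chr1": n * 50_000}, 50_000)
        np.testing.assert_allclose(
            insulation_score(a, 4)["score"], insulation_score(b, 4)["score"], atol=1e-12
        )

    def test_short_chromosome_skipped_with_warning(self):
        dense = np.ones((5, 5))
        m = matrix_from_dense(dense, {"chr1": 5 * 50_000}, 50_000)
        with pytest.warns(UserWarning):
            track = insulation_score(m, window=10)
        assert track["score"].isna().all()


class TestCallTads:
    def test_monotone_track_has_no_boundaries(self):
        track = make_insulation_track(np.linspace(-1, 1, 20))
        tset = call_tads(track, delta=0.1)
        assert len(tset.boundaries) == 0
        assert len(tset.domains) == 1

    def test_single_minimum_with_depth(self):
        scores = np.array([0.5, 0.4, 0.0, 0.4, 0.5])
        tset = call_tads(make_insulation_track(scores), delta=0.1)
        assert len(tset.boundaries) == 1
        assert tset.boundaries.iloc[0]["border_score"] == pytest.approx(0.5)
        assert tset.boundaries.iloc[0]["position"] == 2 * 50_000

    def test_delta_above_depth_suppresses_boundary(self):
        scores = np.array([0.5, 0.4, 0.0, 0.4, 0.5])
        tset = call_tads(make_insulation_track(scores), delta=0.6)
        assert len(tset.boundaries) == 0

    def test_domains_tile_defined_region(self):
        rng = np.random.default_rng(8)
        scores = rng.standard_normal(50)
        scores[:3] = np.nan
        tset = call_tads(make_insulation_track(scores), delta=0.2)
        doms = tset.domains.sort_values("start")
        assert doms.iloc[0]["start"] == 3 * 50_000
        assert (doms["start"].to_numpy()[1:] == doms["end"].to_numpy()[:-1]).all()

    def test_all_nan_track_rejected(self):
        with pytest.raises(ValueError):
            call_tads(make_insulation_track(np.full(10, np.nan)))


def reorg_oracle(a_domains, b_domains, thr=0.75):
    """Independent nested-loop implementation of the reorganization classes."""

    def ov(x, y):
        return max(0, min(x[2], y[2]) - max(x[1], y[1]))

    classes = []
    for dom in a_domains:
        la = dom[2] - dom[1]
        bs = [b for b in b_domains if b[0] == dom[0]]
        if any(ov(dom, b) / la > thr and ov(dom, b) / (b[2] - b[1]) > thr for b in bs):
            classes.append("stable")
        elif sum(ov(dom, b) / (b[2] - b[1]) > thr for b in bs) >= 2:
            classes.append("merged")
        else:
            cls = "rearranged"
            for b in bs:
                if ov(dom, b) / la > thr:
                    covered = sum(
                        ov(a2, b) / (a2[2] - a2[1]) > thr for a2 in a_domains if a2[0] == dom[0]
                    )
                    if covered >= 2:
                        cls = "split"
                    break
            classes.append(cls)
    return classes


class TestClassifyReorganization:
    def test_identical_sets_all_stable(self):
        doms = [("chr1", 0, 1_000_000), ("chr1", 1_000_000, 2_500_000)]
        report = classify_tad_reorganization(make_tadset(doms), make_tadset(doms))
        assert report.frequencies["stable"] == 1.0

    def test_one_domain_covering_two_is_merged(self):
        a = make_tadset([("chr1", 0, 10_000_000)])
        b = make_tadset([("chr1", 0, 5_000_000), ("chr1", 5_000_000, 10_000_000)])
        report = classify_tad_reorganization(a, b)
        assert report.classes.iloc[0]["class"] == "merged"
        # and in the opposite direction the halves are split
        back = classify_tad_reorganization(b, a)
        assert (back.classes["class"] == "split").all()

    def test_reciprocal_overlap_080_is_stable(self):
        a = make_tadset([("chr1", 0, 10_000_000)])
        b = make_tadset([("chr1", 1_000_000, 11_000_000)])  # 9/10 and 9/10 reciprocal
        report = classify_tad_reorganization(a, b)
        assert report.classes.iloc[0]["class"] == "stable"

    def test_swap_maps_merged_to_split_on_random_sets(self):
        rng = np.random.default_rng(9)

        def random_domains(seed):
            rr = np.random.default_rng(seed)
            edges = np.sort(rr.choice(np.arange(1, 40), size=8, replace=False)) * 1_000_000
            edges = np.concatenate(([0], edges, [40_000_000]))
            return [("chr1", int(s), int(e)) for s, e in zip(edges[:-1], edges[1:])]

        for trial in range(5):
            a_dom = random_domains(rng.integers(1e6))
            b_dom = random_domains(rng.integers(1e6))
            fwd = classify_tad_reorganization(make_tadset(a_dom), make_tadset(b_dom))
            bwd = classify_tad_reorganization(make_tadset(b_dom), make_tadset(a_dom))
            assert (fwd.classes["class"] == reorg_oracle(a_dom, b_dom)).all()
            assert (fwd.classes["class"] == "stable").sum() == (
                bwd.classes["class"] == "stable"
            ).sum()

    def test_empty_set_rejected(self):
        doms = make_tadset([("chr1", 0, 1_000_000)])
        empty = TadSet(
            domains=pd.DataFrame(columns=["chrom", "start", "end"]),
            boundaries=pd.DataFrame(columns=["chrom", "position", "border_score"]),
            insulation=make_insulation_track(np.zeros(2)),
            resolution=50_000,
        )
        with pytest.raises(ValueError):
            classify_tad_reorganization(doms, empty)


class TestMetaBorder:
    def test_uniform_oe_gives_flat_metaplot(self):
        n = 40
        m = matrix_from_dense(np.ones((n, n)), {"chr1": n * 50_000}, 50_000)
        bounds = pd.DataFrame({"chrom": ["chr1"] * 2, "position": [15 * 50_000, 25 * 50_000]})
        agg, used = meta_border(m, bounds, flank=250_000)
        assert used == 2
        np.testing.assert_allclose(agg, 1.0)

    def test_boundary_near_edge_skipped(self):
        n = 40
        m = matrix_from_dense(np.ones((n, n)), {"chr1": n * 50_000}, 50_000)
        bounds = pd.DataFrame({"chrom": ["chr1"] * 2, "position": [100_000, 20 * 50_000]})
        agg, used = meta_border(m, bounds, flank=500_000)
        assert used == 1

    def test_corner_peaks_aggregate_above_background(self, fib_profile):
        """Loop-domain maps place extra mass at domain corner pixels; the
        aggregated meta-border map is enriched off-center."""
        from robfusion3d.genome import Karyotype, simulate_genome
        from robfusion3d.matrix import bin_pairs, mask_low_count_bins, observed_expected
        from robfusion3d.simulate import simulate_contact_pairs, simulate_structure

        genome = simulate_genome(1, [20_000_000], seed=10)
        struct = simulate_structure(genome, seed=10, resolution=500_000, tad_mean_bp=2_000_000)
        from dataclasses import replace

        profile = replace(fib_profile, loop_weight=0.1, compartment_strength=0.0)
        pairs = simulate_contact_pairs(
            genome, Karyotype([], {}), profile, 300_000, seed=11, structure=struct
        )
        m = observed_expected(mask_low_count_bins(bin_pairs(pairs, genome, 50_000)))
        bounds = pd.DataFrame(
            {"chrom": "chr1", "position": struct.tad_boundaries["chr1"]}
        )
        agg, used = meta_border(m, bounds, flank=500_000)
        assert used >= 3
        center = agg.shape[0] // 2
        corner_mean = agg[center, center]  # boundary pixel carries corner mass
        background = np.median(agg)
        assert corner_mean > background

    def test_no_usable_boundaries_rejected(self):
        n = 10
        m = matrix_from_dense(np.ones((n, n)), {"chr1": n * 50_000}, 50_000)
        bounds = pd.DataFrame({"chrom": ["chr1"], "position": [50_000]})
        with pytest.raises(ValueError):
            meta_border(m, bounds, flank=500_000)


class TestInsulationVarianceCompare:
    def test_identical_tracks_equal_variance_high_p(self):
        rng = np.random.default_rng(10)
        track = make_insulation_track(rng.standard_normal(200))
        out = insulation_variance_compare(track, track)
        assert out["variance_a"] == out["variance_b"]
        assert out["p_value"] > 0.9

    def test_doubled_spread_quadruples_variance(self):
        rng = np.random.default_rng(11)
        scores = rng.standard_normal(500)
        a = make_insulation_track(scores)
        b = make_insulation_track(2 * scores)
        out = insulation_variance_compare(a, b)
        assert out["variance_b"] / out["variance_a"] == pytest.approx(4.0)
        assert out["p_value"] < 1e-6

    def test_null_shows_no_systematic_rejection(self):
        """Equal-variance Gaussian samples are not systematically rejected."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_trials = 40
        for _ in range(n_trials):
            a = make_insulation_track(rng.standard_normal(500))
            b = make_insulation_track(rng.standard_normal(500))
            if insulation_variance_compare(a, b)["p_value"] < 0.05:
                rejections += 1
        assert rejections <= 0.05 * n_trials + 3 * np.sqrt(n_trials * 0.05 * 0.95)

    def test_too_few_scores_rejected(self):
        track = make_insulation_track([0.1])
        with pytest.raises(ValueError):
            insulation_variance_compare(track, track)
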