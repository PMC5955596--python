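"""Skew scores, the matched-region null, significance and group comparison."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from apskew.regions import Region
from apskew.skew import (
    MatchError,
    NullModel,
    RegionSignalPair,
    accessibility_skew,
    accessibility_skew_for_region,
    build_null,
    compare_groups,
    draw_matched_regions,
    positional_skew,
    score_region,
)
from apskew.tracks_io import CoverageTrack, GenomeTable, Interval

from conftest import random_track


def make_region(half="anterior", name="r", start=100, end=200):
    return Region(Interval("chr1", start, end, name=name), "enhancer", half)


def make_null(mu=0.0, sigma=0.2):
    rng = np.random.default_rng(0)
    return NullModel(
        matched_regions=[],
        rand_skews=rng.normal(mu, sigma, 100),
        mu=mu,
        sigma=sigma,
        normality_stat=0.0,
        normality_p=1.0,
    )


class TestPositionalSkew:
    @pytest.mark.parametrize(
        "ant,post,expected",
        [(1083, 336, 0.5264), (755, 686, 0.0479), (648, 211, 0.5087), (513, 175, 0.4913)],
    )
    def test_worked_signal_pairs(self, ant, post, expected):
        """Half-embryo signal pairs at eve and gt enhancers."""
        assert positional_skew(ant, post) == pytest.approx(expected, abs=5e-5)

    def test_extremes_and_symmetry(self):
        assert positional_skew(5, 5) == 0.0
        assert positional_skew(3, 0) == 1.0
        assert positional_skew(0, 3) == -1.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            positional_skew(-1, 2)

    def test_both_zero_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            positional_skew(0, 0)

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(
        a=st.floats(0, 1e6, allow_nan=False),
        b=st.floats(0, 1e6, allow_nan=False),
        c=st.floats(1e-3, 1e3),
    )
    def test_score_laws(self, a, b, c):
        """Antisymmetry, scale invariance, and range on arbitrary pairs."""
        if a + b == 0:
            return
        s = positional_skew(a, b)
        assert -1.0 <= s <= 1.0
        assert positional_skew(b, a) == pytest.approx(-s, abs=1e-12)
        assert positional_skew(c * a, c * b) == pytest.approx(s, abs=1e-9)


class TestAccessibilitySkew:
    def test_anterior_region_equals_positional(self):
        r = make_region("anterior")
        assert accessibility_skew_for_region(r, 1083, 336) == pytest.approx(0.5264, abs=5e-5)

    def test_posterior_region_negates_positional(self):
        r = make_region("posterior")
        assert accessibility_skew_for_region(r, 1083, 336) == pytest.approx(-0.5264, abs=5e-5)

    def test_equal_halves_zero(self):
        assert accessibility_skew(4.0, 4.0) == 0.0

    def test_dv_region_rejected(self):
        with pytest.raises(ValueError, match="active half"):
            accessibility_skew_for_region(make_region("dorsal"), 1, 2)

    def test_signed_identity_on_grid(self, rng):
        """accessibility == sign(active half) * positional, exactly."""
        pairs = rng.random((200, 2)) * 1000 + 0.5
        for a, p in pairs:
            pos = positional_skew(a, p)
            assert accessibility_skew_for_region(make_region("anterior"), a, p) == pos
            assert accessibility_skew_for_region(make_region("posterior"), a, p) == -pos


class TestDrawMatchedRegions:
    def test_uniform_track_all_match(self):
        genome = GenomeTable((("chr1", 10_000),))
        track = CoverageTrack(genome, {"chr1": np.ones(10_000)})
        draws = draw_matched_regions(100, 100.0, track, k=10, tolerance=0.0, rng=1)
        assert len(draws) == 10
        for d in draws:
            assert len(d) == 100
            assert track.interval_total(d.chrom, d.start, d.end) == 100.0

    def test_full_exclusion_errors(self):
        genome = GenomeTable((("chr1", 10_000),))
        track = CoverageTrack(genome, {"chr1": np.ones(10_000)})
        with pytest.raises(MatchError):
            draw_matched_regions(
                100, 100.0, track,
                exclusion=[Interval("chr1", 0, 10_000)],
                k=1, max_tries=2000, rng=1,
            )

    def test_draws_verify_by_brute_force(self, sim_world):
        """Every draw re-checks against tolerance and exclusion predicates."""
        spec, truth, ant, post, whole, catalog = sim_world
        roi = truth.peaks[0][0]
        roi_total = whole.interval_total(roi.chrom, roi.start, roi.end)
        exclusion = [iv for iv, _, _ in truth.peaks[:10]]
        draws = draw_matched_regions(
            len(roi), roi_total, whole, exclusion=exclusion, k=8, tolerance=0.05, rng=3
        )
        for d in draws:
            total = float(whole[d.chrom][d.start : d.end].sum())
            assert abs(total - roi_total) / roi_total <= 0.05
            assert len(d) == len(roi)
            for ex in exclusion:
                assert not d.overlaps(ex)

    def test_reproducible_given_seed(self, sim_world):
        spec, truth, ant, post, whole, catalog = sim_world
        roi = truth.peaks[1][0]
        total = whole.interval_total(roi.chrom, roi.start, roi.end)
        a = draw_matched_regions(len(roi), total, whole, k=5, rng=77)
        b = draw_matched_regions(len(roi), total, whole, k=5, rng=77)
        assert a == b


class TestBuildNull:
    def test_symmetric_tracks_give_mu_near_zero(self, sim_world):
        spec, truth, ant, post, whole, catalog = sim_world
        null = build_null(list(catalog)[:40], ant, post, whole, k=10, rng_seed=5)
        assert abs(null.mu) < 4 * null.sigma / np.sqrt(null.rand_skews.size) + 0.02

    def test_proportional_tracks_degenerate(self):
        genome = GenomeTable((("chr1", 50_000),))
        rng = np.random.default_rng(2)
        post = random_track(genome, rng, density=1.0)
        ant = post.scaled(2.0)  # skew is 1/3 everywhere -> sigma 0
        rois = [Interval("chr1", s, s + 200) for s in range(0, 5000, 500)]
        with pytest.raises(ValueError, match="sigma"):
            build_null(rois, ant, post, post, k=3, tolerance=0.2, rng_seed=0)

    def test_mu_sigma_match_direct_recomputation(self, sim_world):
        spec, truth, ant, post, whole, catalog = sim_world
        null = build_null(list(catalog)[:20], ant, post, whole, k=5, rng_seed=11)
        skews = []
        for _, draws in null.matched_regions:
            for d in draws:
                a = float(ant[d.chrom][d.start : d.end].sum())
                p = float(post[d.chrom][d.start : d.end].sum())
                skews.append((a - p) / (a + p))
        assert null.mu == pytest.approx(np.mean(skews), rel=1e-12)
        assert null.sigma == pytest.approx(np.std(skews, ddof=1), rel=1e-12)


class TestScoreRegion:
    def test_skew_at_null_mean_not_significant(self):
        null = make_null(mu=0.1, sigma=0.2)
        # ant/post chosen so positional skew == mu
        pair = RegionSignalPair(make_region(), x_anterior=110.0, x_posterior=90.0)
        res = score_region(pair, null)
        assert res.z == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert not res.significant

    def test_quantile_at_alpha(self):
        null = make_null(mu=0.0, sigma=0.2)
        skew = 1.959964 * 0.2
        a = 500 * (1 + skew) / 2
        p = 500 * (1 - skew) / 2
        res = score_region(RegionSignalPair(make_region(), a, p), null)
        assert res.p == pytest.approx(0.05, abs=1e-4)

    def test_worked_z_and_p(self):
        """Anterior enhancer with (1083, 336) against a (0, 0.2) null."""
        null = make_null(mu=0.0, sigma=0.2)
        res = score_region(RegionSignalPair(make_region(), 1083.0, 336.0), null)
        assert res.z == pytest.approx(2.632, abs=5e-4)
        assert res.p == pytest.approx(0.00849, abs=5e-5)
        assert res.significant
        assert res.accessibility_skew == pytest.approx(res.positional_skew)

    def test_degenerate_pair_flagged(self):
        res = score_region(RegionSignalPair(make_region(), 0.0, 0.0), make_null())
        assert res.degenerate
        assert res.positional_skew == 0.0
        assert np.isnan(res.z) and np.isnan(res.p)
        assert not res.significant

    def test_p_is_two_tailed_normal(self):
        null = make_null(mu=0.0, sigma=0.1)
        res = score_region(RegionSignalPair(make_region(), 30.0, 70.0), null)
        assert res.z == pytest.approx(-4.0)
        assert res.p == pytest.approx(2 * stats.norm.sf(4.0), rel=1e-12)


class TestCompareGroups:
    def test_identical_groups(self, rng):
        g = rng.normal(0, 0.2, 30).tolist()
        cmp = compare_groups({"anterior": g, "dorsal": list(g)})
        row = cmp.tukey.iloc[0]
        assert row["diff"] == pytest.approx(0.0, abs=1e-12)
        assert row["p_adj"] > 0.9

    def test_diff_equals_mean_difference(self, rng):
        groups = {
            cls: rng.normal(mu, 0.2, 25).tolist()
            for cls, mu in [("anterior", 0.3), ("posterior", -0.1), ("dorsal", 0.0)]
        }
        cmp = compare_groups(groups)
        for _, row in cmp.tukey.iterrows():
            expected = np.mean(groups[row["group2"]]) - np.mean(groups[row["group1"]])
            assert row["diff"] == pytest.approx(expected, rel=1e-12)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups({"a": [1.0, 2.0], "b": [1.0]})

    def test_separated_groups_significant(self, rng):
        cmp = compare_groups(
            {
                "anterior": rng.normal(0.3, 0.2, 30).tolist(),
                "dorsal": rng.normal(0.0, 0.2, 30).tolist(),
            }
        )
        assert cmp.tukey["p_adj"].iloc[0] < 0.01
        assert cmp.ttests["p"].iloc[0] < 0.01

    def test_tukey_agrees_with_r_style_ordering(self, rng):
        """Adjusted p within [0,1] and symmetric-ish for exchangeable groups."""
        groups = {c: rng.normal(0, 0.2, 20).tolist() for c in ("a", "b", "c")}
        cmp = compare_groups(groups)
        assert ((cmp.tukey["p_adj"] >= 0) & (cmp.tukey["p_adj"] <= 1)).all()
        assert len(cmp.tukey) == 3 and len(cmp.ttests) == 3
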