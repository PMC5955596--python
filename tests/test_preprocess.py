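"""Fragment shifting, coverage construction, normalization and extraction."""

import numpy as np
import pytest

from apskew.preprocess import (
    apply_normalization,
    coverage_from_fragments,
    fit_no_intercept,
    region_signal,
    scale_to_depth,
    shift_fragments,
    tile_signal,
)
from apskew.tracks_io import CoverageTrack, FragmentSet, GenomeTable, Interval

from conftest import random_track


def frags(*records):
    return FragmentSet.from_intervals([Interval(*r) for r in records])


class TestShiftFragments:
    def test_plus_strand_moves_plus_four(self, small_genome):
        out = shift_fragments(frags(("chr1", 100, 150, "+")), small_genome)
        assert out.to_intervals() == [Interval("chr1", 104, 154, "+")]

    def test_minus_strand_moves_minus_five(self, small_genome):
        out = shift_fragments(frags(("chr1", 100, 150, "-")), small_genome)
        assert out.to_intervals() == [Interval("chr1", 95, 145, "-")]

    def test_emptied_by_clipping_dropped(self, small_genome):
        out = shift_fragments(frags(("chr1", 0, 3, "-")), small_genome)
        assert len(out) == 0

    def test_length_preserved_away_from_bounds(self, small_genome, rng):
        starts = rng.integers(10, 900, size=50)
        fs = FragmentSet(
            chroms=np.array(["chr1"] * 50, dtype=object),
            starts=starts,
            ends=starts + rng.integers(20, 80, size=50),
            strands=np.where(rng.random(50) < 0.5, "+", "-").astype("U1"),
        )
        out = shift_fragments(fs, small_genome)
        np.testing.assert_array_equal(np.sort(out.lengths), np.sort(fs.lengths))


class TestCoverage:
    def test_single_fragment_pileup(self, small_genome):
        track = coverage_from_fragments(frags(("chr1", 0, 5, "+")), small_genome)
        assert track["chr1"][:6].tolist() == [1, 1, 1, 1, 1, 0]
        assert track.total() == 5

    def test_duplicate_fragments_stack(self, small_genome):
        track = coverage_from_fragments(
            frags(("chr1", 10, 20, "+"), ("chr1", 10, 20, "-")), small_genome
        )
        assert track["chr1"][10:20].tolist() == [2] * 10

    def test_matches_brute_force_counting(self, small_genome, rng):
        starts = rng.integers(0, 950, size=200)
        fs = FragmentSet(
            chroms=np.array(["chr1"] * 200, dtype=object),
            starts=starts,
            ends=starts + rng.integers(1, 50, size=200),
            strands=np.array(["+"] * 200, dtype="U1"),
        )
        track = coverage_from_fragments(fs, small_genome)
        brute = np.zeros(1000)
        for s, e in zip(fs.starts, fs.ends):
            brute[s:e] += 1
        np.testing.assert_array_equal(track["chr1"], brute)
        assert track.total() == fs.lengths.sum()


class TestDepthScaling:
    def test_factor_two(self, small_genome, rng):
        track = random_track(small_genome, rng)
        scaled = scale_to_depth(track, 5_000_000, 10_000_000)
        np.testing.assert_allclose(scaled["chr1"], 2 * track["chr1"])

    def test_identity_when_equal(self, small_genome, rng):
        track = random_track(small_genome, rng)
        same = scale_to_depth(track, 10_000_000, 10_000_000)
        np.testing.assert_array_equal(same["chr1"], track["chr1"])

    def test_zero_mapped_reads_rejected(self, small_genome):
        with pytest.raises(ValueError):
            scale_to_depth(CoverageTrack(small_genome), 0)

    def test_total_scales_exactly(self, small_genome, rng):
        track = random_track(small_genome, rng)
        scaled = scale_to_depth(track, 3_000_000, 10_000_000)
        assert scaled.total() == pytest.approx(track.total() * 10 / 3, rel=1e-12)


class TestNoInterceptFit:
    def test_exact_doubling(self, small_genome, rng):
        ref = random_track(small_genome, rng, density=1.0)
        sample = ref.scaled(2.0)
        fit = fit_no_intercept(sample, ref, bin_size=100)
        assert fit.slope == pytest.approx(2.0, rel=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_identity_slope(self, small_genome, rng):
        ref = random_track(small_genome, rng, density=1.0)
        assert fit_no_intercept(ref, ref, bin_size=100).slope == pytest.approx(1.0)

    @pytest.mark.parametrize("c", [0.5, 1.0, 3.7])
    def test_scaled_reference_recovers_c(self, small_genome, rng, c):
        ref = random_track(small_genome, rng, density=0.8)
        fit = fit_no_intercept(ref.scaled(c), ref, bin_size=50)
        assert fit.slope == pytest.approx(c, rel=1e-12)

    def test_slope_matches_direct_summation(self, small_genome, rng):
        ref = random_track(small_genome, rng, density=0.9)
        sample = random_track(small_genome, np.random.default_rng(99), density=0.9)
        bin_size = 100
        x, y = [], []
        for chrom, length in small_genome.entries:
            for s in range(0, length, bin_size):
                xb = ref[chrom][s : s + bin_size].sum()
                if xb > 0:
                    x.append(xb)
                    y.append(sample[chrom][s : s + bin_size].sum())
        x, y = np.array(x), np.array(y)
        expected = (x * y).sum() / (x * x).sum()
        fit = fit_no_intercept(sample, ref, bin_size=bin_size)
        assert fit.slope == pytest.approx(expected, rel=1e-12)
        assert fit.n_bins == len(x)

    def test_zero_reference_rejected(self, small_genome, rng):
        with pytest.raises(ValueError, match="zero total"):
            fit_no_intercept(random_track(small_genome, rng), CoverageTrack(small_genome))

    def test_apply_then_refit_gives_unit_slope(self, small_genome, rng):
        ref = random_track(small_genome, rng, density=0.8)
        sample = random_track(small_genome, np.random.default_rng(7), density=0.8)
        fit = fit_no_intercept(sample, ref, bin_size=100)
        normalized = apply_normalization(sample, fit)
        refit = fit_no_intercept(normalized, ref, bin_size=100)
        assert abs(refit.slope - 1.0) < 1e-9

    def test_non_positive_slope_rejected(self, small_genome, rng):
        from apskew.preprocess import NormalizationFit

        with pytest.raises(ValueError):
            apply_normalization(
                random_track(small_genome, rng),
                NormalizationFit(slope=0.0, n_bins=5, bin_size=10, r_squared=0.0),
            )


class TestTiling:
    def test_even_bins(self):
        genome = GenomeTable((("chr1", 10),))
        track = CoverageTrack(genome, {"chr1": np.ones(10)})
        tiles = tile_signal(track, 5)
        assert [(t[0].start, t[0].end, t[1]) for t in tiles] == [(0, 5, 5.0), (5, 10, 5.0)]

    def test_partial_last_bin(self):
        genome = GenomeTable((("chr1", 10),))
        track = CoverageTrack(genome, {"chr1": np.ones(10)})
        assert [t[1] for t in tile_signal(track, 4)] == [4.0, 4.0, 2.0]

    def test_totals_conserved(self, small_genome, rng):
        track = random_track(small_genome, rng)
        for bin_size in (1, 7, 100, 10_000):
            assert sum(t[1] for t in tile_signal(track, bin_size)) == pytest.approx(
                track.total(), rel=1e-12
            )


class TestRegionSignal:
    def test_zero_track(self, small_genome):
        track = CoverageTrack(small_genome)
        assert region_signal(track, Interval("chr1", 10, 300)) == 0.0

    def test_constant_track_sum_and_mean(self, small_genome):
        track = CoverageTrack(small_genome, {"chr1": np.full(1000, 2.0)})
        region = Interval("chr1", 100, 200)
        assert region_signal(track, region, "sum") == 200.0
        assert region_signal(track, region, "mean") == 2.0

    def test_matches_brute_force(self, small_genome, rng):
        track = random_track(small_genome, rng)
        for _ in range(20):
            s = int(rng.integers(0, 990))
            e = int(rng.integers(s + 1, 1000))
            assert region_signal(track, Interval("chr1", s, e)) == pytest.approx(
                float(track["chr1"][s:e].sum()), rel=1e-12
            )

    def test_additive_over_partition(self, small_genome, rng):
        track = random_track(small_genome, rng)
        whole = region_signal(track, Interval("chr1", 0, 900))
        parts = sum(
            region_signal(track, Interval("chr1", s, s + 100)) for s in range(0, 900, 100)
        )
        assert parts == pytest.approx(whole, rel=1e-12)

    def test_out_of_range_rejected(self, small_genome):
        with pytest.raises(ValueError):
            region_signal(CoverageTrack(small_genome), Interval("chr1", 500, 1500))
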