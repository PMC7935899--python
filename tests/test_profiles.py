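"""Normalization, smoothing, and the quantitative profile summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import spliceclip as sc
from spliceclip.profiles import NormalizedProfile

import oracles


def profile_of(values, name="substrate", **kw):
    return NormalizedProfile(name, np.asarray(values, dtype=float), **kw)


def track_of(counts, name="substrate"):
    return sc.CrosslinkTrack(name, np.asarray(counts, dtype=np.int64))


class TestNormalize:
    def test_per_million_background(self):
        prof = sc.normalize(track_of([30, 0]), 150_000)
        assert prof.values[0] == pytest.approx(200.0)
        assert prof.values[1] == 0.0

    def test_zero_background_is_an_error(self):
        with pytest.raises(ValueError, match="raw"):
            sc.normalize(track_of([1]), 0)

    def test_doubling_background_halves_values(self):
        t = track_of([10, 20, 30])
        a = sc.normalize(t, 1000).values
        b = sc.normalize(t, 2000).values
        assert np.allclose(a, 2 * b)


class TestSubtractControl:
    def test_pointwise_difference_retains_negatives(self):
        out = sc.subtract_control(
            profile_of([5.0, 1.0], provenance=("raw", "normalized")),
            profile_of([2.0, 4.0], provenance=("raw", "normalized")),
        )
        assert list(out.values) == [3.0, -3.0]
        assert out.meta["has_negative"]
        assert out.is_subtracted

    def test_zero_control_is_identity(self):
        sig = profile_of([1.0, 2.0, 3.0])
        out = sc.subtract_control(sig, profile_of([0.0, 0.0, 0.0]))
        assert np.array_equal(out.values, sig.values)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            sc.subtract_control(profile_of([1.0]), profile_of([1.0, 2.0]))


class TestGaussianSmooth:
    def test_interior_impulse_mass_one(self):
        v = np.zeros(101)
        v[50] = 1.0
        out = sc.gaussian_smooth(profile_of(v), 10)
        assert out.values.sum() == pytest.approx(1.0, abs=1e-9)

    def test_constant_profile_unchanged_in_interior(self):
        # interior = beyond the reach of boundary-renormalized sources
        out = sc.gaussian_smooth(profile_of(np.ones(60)), 10)
        assert np.allclose(out.values[10:-10], 1.0, atol=1e-9)

    def test_matches_naive_convolution_oracle(self, rng):
        v = rng.random(200) * 10
        out = sc.gaussian_smooth(profile_of(v), 10)
        want = oracles.naive_gaussian_smooth(v, 10)
        assert np.max(np.abs(out.values - want)) < 1e-9

    def test_mass_conserved_with_boundary_signal(self, rng):
        v = rng.random(50)
        v[:3] += 20.0  # mass piled on the boundary
        out = sc.gaussian_smooth(profile_of(v), 10)
        assert abs(out.values.sum() - v.sum()) <= 1e-6 * np.abs(v).sum()

    @pytest.mark.parametrize("window", [1, 2, 5, 10, 21])
    def test_mass_conservation_across_window_sizes(self, window, rng):
        v = rng.random(80)
        out = sc.gaussian_smooth(profile_of(v), window)
        assert abs(out.values.sum() - v.sum()) <= 1e-6 * np.abs(v).sum()


class TestSpeciesProportions:
    def _tracks(self, counts):
        return {
            name: sc.CrosslinkTrack(name, np.array([n], dtype=np.int64))
            for name, n in counts.items()
        }

    def test_simple_proportions(self):
        df = sc.species_proportions(self._tracks({"substrate": 80, "U2": 15, "U5": 5}))
        assert df.loc["substrate", "proportion"] == pytest.approx(0.80)
        assert df.loc["U2", "proportion"] == pytest.approx(0.15)
        assert df.proportion.sum() == pytest.approx(1.0, abs=1e-12)

    def test_replicate_summing_equals_concatenation(self):
        r1 = self._tracks({"substrate": 10, "U2": 5})
        r2 = self._tracks({"substrate": 30, "U2": 15})
        combined = sc.species_proportions([r1, r2])
        concat = sc.species_proportions(self._tracks({"substrate": 40, "U2": 20}))
        assert np.allclose(combined.proportion, concat.proportion)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sc.species_proportions(self._tracks({"substrate": 0}))


class TestEnrichment:
    def _tracks(self, counts, index):
        return {
            name: sc.CrosslinkTrack(name, np.array([counts.get(name, 0)], dtype=np.int64))
            for name in index.references
        }

    def test_fourfold_fraction_gives_log2fc_two(self, index):
        # fractions 0.4 vs 0.1 for U2 after within-sample normalization
        tagged = self._tracks({"U1": 199, "U2": 399, "U4": 99, "U5": 199, "U6": 99}, index)
        untag = self._tracks({"U1": 299, "U2": 99, "U4": 199, "U5": 199, "U6": 199}, index)
        df = sc.snrna_enrichment(tagged, untag, index, pseudocount=1)
        assert df.loc["U2", "tagged_fraction"] == pytest.approx(0.4)
        assert df.loc["U2", "untagged_fraction"] == pytest.approx(0.1)
        assert df.loc["U2", "log2fc"] == pytest.approx(2.0)
        assert df.tagged_fraction.sum() == pytest.approx(1.0)

    def test_identical_libraries_all_zero(self, index):
        t = self._tracks({"U1": 5, "U2": 10, "U4": 2, "U5": 7, "U6": 3}, index)
        df = sc.snrna_enrichment(t, t, index)
        assert np.allclose(df.log2fc, 0.0)

    def test_zero_count_finite_via_pseudocount(self, index):
        tagged = self._tracks({"U1": 0, "U2": 15, "U4": 3, "U5": 3, "U6": 3}, index)
        untag = self._tracks({"U1": 15, "U2": 0, "U4": 3, "U5": 3, "U6": 3}, index)
        df = sc.snrna_enrichment(tagged, untag, index, pseudocount=1)
        # hand-computed with pseudocounts: f_tag(U2) = 16/29, f_untag(U2) = 1/29
        assert df.loc["U2", "log2fc"] == pytest.approx(np.log2(16.0))
        assert np.isfinite(df.log2fc).all()


class TestWeightedSummary:
    def test_degenerate_single_position(self):
        v = np.zeros(100)
        v[56] = 7.0
        s = sc.weighted_position_summary(profile_of(v))
        assert s.median == s.q1 == s.q3 == 56

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(st.lists(st.integers(min_value=0, max_value=6), min_size=5, max_size=40))
    def test_quantiles_match_expansion_oracle(self, weights):
        w = np.asarray(weights, dtype=float)
        if w.sum() == 0:
            w[2] = 1.0
        expanded = np.repeat(np.arange(len(w)), w.astype(int)).astype(float)
        s = sc.weighted_position_summary(profile_of(w))
        for q, got in [(0.25, s.q1), (0.5, s.median), (0.75, s.q3)]:
            assert got == np.quantile(expanded, q, method="inverted_cdf")

    def test_doubling_weights_is_invariant(self, rng):
        w = rng.integers(0, 10, 50).astype(float)
        w[4] += 1
        a = sc.weighted_position_summary(profile_of(w))
        b = sc.weighted_position_summary(profile_of(2 * w))
        assert a == b

    def test_whiskers_within_fences_and_outliers_reported(self):
        v = np.zeros(200)
        v[90:110] = 10.0
        v[199] = 1.0  # lone far outlier
        s = sc.weighted_position_summary(profile_of(v))
        assert s.q1 <= s.median <= s.q3
        assert s.whisker_low >= s.q1 - 1.5 * s.iqr
        assert s.whisker_high <= s.q3 + 1.5 * s.iqr
        assert 199 in s.outliers

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            sc.weighted_position_summary(profile_of([1.0, -0.5]))

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            sc.weighted_position_summary(profile_of([0.0, 0.0]))


class TestFindMainPeak:
    def test_flat_positive_profile_tie_breaks_left(self, substrate):
        prof = profile_of(np.ones(len(substrate)))
        rel = sc.find_main_peak(prof, substrate, region=(150, 200), anchor="brA")
        assert rel == substrate.to_relative(150, "brA")

    def test_all_negative_has_no_peak(self, substrate):
        prof = profile_of(-np.ones(len(substrate)))
        assert sc.find_main_peak(prof, substrate) is None

    def test_masked_positions_excluded(self, substrate):
        v = np.ones(len(substrate))
        v[substrate.brA] = 100.0
        prof = profile_of(v, mask={substrate.brA})
        rel = sc.find_main_peak(prof, substrate)
        assert rel != 0


class TestPeakComparison:
    def test_identical_groups(self):
        r = sc.compare_peak_positions([30, 30, 30], [30, 30, 30])
        assert (r.t, r.p) == (0.0, 1.0)

    def test_matches_pooled_variance_formula(self):
        a, b = [29, 30, 31], [19, 20, 21]
        r = sc.compare_peak_positions(a, b)
        t_hand, df_hand = oracles.pooled_t(a, b)
        assert r.t == pytest.approx(t_hand)
        assert r.df == df_hand == 4
        from scipy import stats
        assert r.p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand))

    def test_swapping_groups_negates_t(self):
        a, b = [29, 30, 31], [19, 22, 21]
        r1 = sc.compare_peak_positions(a, b)
        r2 = sc.compare_peak_positions(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_degenerate_unequal_means_flagged(self):
        r = sc.compare_peak_positions([5, 5], [9, 9])
        assert r.degenerate and r.p == 0.0


class TestPlotting:
    def test_figures_render_without_error(self, substrate, rng):
        from spliceclip import plotting

        v = np.abs(rng.normal(size=len(substrate)))
        prof = profile_of(v)
        ax = plotting.plot_profile(prof, substrate)
        assert ax.get_xlabel().endswith("brA")
        summary = sc.weighted_position_summary(prof)
        plotting.plot_position_box(summary)
        props = sc.species_proportions({"substrate": track_of(rng.integers(1, 5, 10))})
        plotting.plot_species_proportions(props)


class TestPipelineAlgebra:
    def test_normalization_linear_over_replicates(self, rng):
        c1 = rng.integers(0, 20, 100)
        c2 = rng.integers(0, 20, 100)
        n1, n2 = 4000, 6000
        combined = sc.normalize(track_of(c1 + c2), n1 + n2).values
        weighted = (
            n1 * sc.normalize(track_of(c1), n1).values
            + n2 * sc.normalize(track_of(c2), n2).values
        ) / (n1 + n2)
        assert np.allclose(combined, weighted)

    def test_sharp_boundary_half_maximum_near_ss3(self, substrate):
        # uniform intron signal, zero in exon 2: the smoothed drop's
        # half-maximum crossing stays within half a window of the 3'-SS
        v = np.zeros(len(substrate))
        a, b = substrate.intron
        v[a:b] = 10.0
        smoothed = sc.gaussian_smooth(profile_of(v), 10).values
        interior = smoothed[substrate.brA - 30]
        crossing = None
        for pos in range(b - 10, min(b + 10, len(v))):
            if smoothed[pos] >= interior / 2 > smoothed[pos + 1]:
                crossing = pos
                break
        assert crossing is not None
        assert abs(crossing - substrate.ss3) <= 5
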