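"""Band intensities, group summaries, ANOVA + Tukey HSD."""

import numpy as np
import pytest
from scipy import stats

from ramanstage.band_stats import (
    BandIntensityTable,
    anova_tukey,
    band_intensity,
    difference_spectrum,
    group_band_table,
    mean_sd_spectrum,
)
from ramanstage.preprocess import PreprocessConfig, preprocess_all
from ramanstage.spectral_core import (
    BandDefinition,
    GroupedSpectra,
    Spectrum,
    band_by_center,
)
from ramanstage.synthetic_data import SyntheticConfig, simulate_groups


def make_table(groups: dict, band=1002.0):
    bands = (band_by_center(band),)
    table = {
        (g, band): np.asarray(v, dtype=float) for g, v in groups.items()
    }
    return BandIntensityTable(table, tuple(groups), bands)


class TestBandIntensity:
    def test_normalized_spectrum_anchor_band_is_one(self, axis):
        grouped, _ = simulate_groups(SyntheticConfig(seed=1))
        processed, _ = preprocess_all(grouped, PreprocessConfig())
        s = processed["2D_PCa"][0]
        assert band_intensity(s, band_by_center(780)) == 1.0

    def test_zero_spectrum_gives_zero(self, axis):
        s = Spectrum(axis, np.zeros(axis.n_points))
        assert band_intensity(s, band_by_center(1444)) == 0.0

    def test_known_peak_height_recovered(self, axis):
        from ramanstage.synthetic_data import PeakSpec

        h = 2.4
        peak = PeakSpec(1444.0, 12.0, h)
        s = Spectrum(axis, peak.profile(axis.values))
        assert band_intensity(s, band_by_center(1444)) == pytest.approx(h, rel=0.01)

    def test_window_outside_axis_rejected(self):
        from ramanstage.spectral_core import WavenumberAxis

        axis = WavenumberAxis(np.linspace(700, 1000, 50))
        s = Spectrum(axis, np.ones(50))
        with pytest.raises(ValueError):
            band_intensity(s, BandDefinition(1444.0, 8.0))


class TestGroupBandTable:
    def test_default_synthetic_groups_show_reduced_late_means(self):
        grouped, _ = simulate_groups(SyntheticConfig(seed=2))
        processed, _ = preprocess_all(grouped)
        table = group_band_table(processed)
        for band in (1002.0, 1261.0, 1444.0, 1654.0):
            early = table.samples("3D_d23+5", band).mean()
            assert table.samples("3D_d23+10", band).mean() < early
            assert table.samples("3D_d23+15", band).mean() < early

    def test_n_is_20_per_cell(self):
        grouped, _ = simulate_groups(SyntheticConfig(seed=2))
        processed, _ = preprocess_all(grouped)
        summary = group_band_table(processed).summary()
        assert (summary["n"] == 20).all()

    def test_identical_spectra_have_zero_sd(self, axis):
        grouped = GroupedSpectra()
        y = np.ones(axis.n_points)
        for _ in range(3):
            grouped.add("g", Spectrum(axis, y))
        summary = group_band_table(grouped, [1444.0]).summary()
        assert (summary["sd"] == 0).all()

    def test_unknown_band_rejected(self, axis):
        grouped = GroupedSpectra()
        for _ in range(2):
            grouped.add("g", Spectrum(axis, np.ones(axis.n_points)))
        with pytest.raises(KeyError):
            group_band_table(grouped, [1500.0])


class TestAnovaTukey:
    def test_textbook_three_group_f_statistic(self):
        # hand-computable one-way ANOVA sums of squares
        groups = {
            "a": [6, 8, 4, 5, 3, 4],
            "b": [8, 12, 9, 11, 6, 8],
            "c": [13, 9, 11, 8, 7, 12],
        }
        table = make_table(groups)
        result = anova_tukey(table)
        f, p = result.anova[1002.0]
        f_ref, p_ref = stats.f_oneway(*groups.values())
        assert f == pytest.approx(f_ref, abs=1e-6)
        assert p == pytest.approx(p_ref, abs=1e-9)

    def test_identical_groups_give_f_zero_p_one(self):
        table = make_table({"a": [1, 2, 3], "b": [1, 2, 3]})
        result = anova_tukey(table)
        f, p = result.anova[1002.0]
        assert f == 0.0 and p == 1.0

    def test_matches_scipy_tukey_hsd(self, rng):
        groups = {k: rng.normal(i, 1, 12) for i, k in enumerate("abcd")}
        table = make_table(groups)
        ours = anova_tukey(table).pairs
        ref = stats.tukey_hsd(*groups.values())
        keys = list(groups)
        for _, row in ours.iterrows():
            i, j = keys.index(row["group_a"]), keys.index(row["group_b"])
            assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-8)

    def test_tukey_p_not_below_pairwise_t(self, rng):
        groups = {k: rng.normal(0, 1, 10) for k in "abcd"}
        table = make_table(groups)
        pairs = anova_tukey(table).pairs
        for _, row in pairs.iterrows():
            t_p = stats.ttest_ind(
                table.samples(row["group_a"], 1002.0),
                table.samples(row["group_b"], 1002.0),
            ).pvalue
            assert row["p_adj"] >= t_p - 1e-12

    def test_zero_variance_unequal_means_degenerate_flag(self):
        table = make_table({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        result = anova_tukey(table)
        assert result.degenerate
        assert result.pairs["p_adj"].iloc[0] == 0.0
        assert result.pairs["tier"].iloc[0] == 0.001

    def test_f_invariant_to_shift_and_scale(self, rng):
        base = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
        f0 = anova_tukey(make_table(base)).anova[1002.0][0]
        shifted = {k: np.asarray(v) + 100.0 for k, v in base.items()}
        scaled = {k: np.asarray(v) * 7.0 for k, v in base.items()}
        assert anova_tukey(make_table(shifted)).anova[1002.0][0] == pytest.approx(f0)
        assert anova_tukey(make_table(scaled)).anova[1002.0][0] == pytest.approx(f0)

    def test_significance_tiers(self):
        rng = np.random.default_rng(0)
        strong = {"a": rng.normal(0, 0.1, 20), "b": rng.normal(5, 0.1, 20)}
        pairs = anova_tukey(make_table(strong)).pairs
        assert pairs["tier"].iloc[0] == 0.001

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_tukey(make_table({"a": [1, 2, 3]}))

    def test_type_one_error_calibrated_under_null(self):
        """All groups drawn identically: rejection rate at alpha=0.05 over
        2000 replicates lies in [0.03, 0.07]."""
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            groups = [rng.normal(0.0, 1.0, 20) for _ in range(4)]
            f, p, msw, dfw = _anova(groups)
            if p < 0.05:
                rejections += 1
        assert 0.03 <= rejections / n_rep <= 0.07


def _anova(groups):
    from ramanstage.band_stats import _one_way_anova

    return _one_way_anova([np.asarray(g, dtype=float) for g in groups])


class TestSpectraSummaries:
    def test_mean_sd_closed_form(self, axis):
        zero = Spectrum(axis, np.zeros(axis.n_points))
        two = Spectrum(axis, np.full(axis.n_points, 2.0))
        mean, sd = mean_sd_spectrum([zero, two])
        np.testing.assert_allclose(mean.intensities, 1.0)
        np.testing.assert_allclose(sd.intensities, np.sqrt(2.0))

    def test_identical_spectra_zero_sd(self, axis):
        s = Spectrum(axis, np.ones(axis.n_points))
        _, sd = mean_sd_spectrum([s, Spectrum(axis, np.ones(axis.n_points))])
        np.testing.assert_array_equal(sd.intensities, 0)

    def test_single_spectrum_rejected(self, axis):
        with pytest.raises(ValueError):
            mean_sd_spectrum([Spectrum(axis, np.zeros(axis.n_points))])

    def test_group_mean_converges_to_model_at_root_n(self):
        """Mean of n simulated spectra approaches the noiseless model ~1/sqrt(n)."""
        errors = []
        for n in (20, 80, 320):
            cfg = SyntheticConfig(
                seed=13, n_spectra_per_group=n, baseline_scale=0.0,
                spike_rate=0.0, weight_jitter=0.0,
            )
            grouped, truth = simulate_groups(cfg)
            clean = truth.clean[("2D_PCa", 0)]
            mean = grouped.matrix("2D_PCa").mean(axis=0)
            errors.append(np.sqrt(np.mean((mean - clean) ** 2)))
        assert errors[2] < errors[0]
        # halving expected per 4x n: allow generous slack around 0.5
        assert errors[1] / errors[0] < 0.75
        assert errors[2] / errors[1] < 0.75

    def test_difference_spectrum_antisymmetric_and_localized(self, clean_config):
        import dataclasses

        cfg = dataclasses.replace(
            clean_config,
            staged_bands=(1444.0,),
            reduction_factors=(("3D_d23+10", 0.6),),
        )
        grouped, _ = simulate_groups(cfg)
        d = difference_spectrum(grouped, "3D_d23+5", "3D_d23+10")
        d_rev = difference_spectrum(grouped, "3D_d23+10", "3D_d23+5")
        np.testing.assert_allclose(d.intensities, -d_rev.intensities)
        peak_at = grouped.axis.values[np.argmax(np.abs(d.intensities))]
        assert abs(peak_at - 1444.0) <= 8.0

    def test_difference_of_group_with_itself_is_zero(self, clean_config):
        grouped, _ = simulate_groups(clean_config)
        d = difference_spectrum(grouped, "2D_PCa", "2D_PCa")
        np.testing.assert_array_equal(d.intensities, 0)

    def test_unknown_group_rejected(self, clean_config):
        grouped, _ = simulate_groups(clean_config)
        with pytest.raises(KeyError):
            difference_spectrum(grouped, "2D_PCa", "nope")
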