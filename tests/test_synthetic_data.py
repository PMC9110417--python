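"""Ground-truthed generator: component spectra, grouped spectra, cubes."""

import numpy as np
import pytest

from ramanstage.spectral_core import WavenumberAxis, band_by_center
from ramanstage.synthetic_data import (
    BASE_CELL_WEIGHTS,
    ComponentModel,
    PeakSpec,
    SyntheticConfig,
    component_spectrum,
    default_components,
    layout_from_masks,
    reference_spectrum,
    simulate_cube,
    simulate_groups,
)

STAGED = (1002.0, 1261.0, 1444.0, 1654.0)


def band_height(intensities, axis, center, half=8.0):
    return intensities[axis.window_mask(center, half)].max()


class TestPeaksAndComponents:
    def test_lorentzian_closed_form(self):
        # value at center = amplitude; at center +/- FWHM/2 = amplitude / 2
        peak = PeakSpec(center_cm1=1000.0, fwhm_cm1=10.0, amplitude=3.0)
        prof = peak.profile(np.array([1000.0, 995.0, 1005.0, 1010.0]))
        np.testing.assert_allclose(prof, [3.0, 1.5, 1.5, 3.0 / 5.0], rtol=1e-12)

    def test_lorentzian_on_grid_within_interpolation_tolerance(self, axis):
        peak = PeakSpec(center_cm1=1000.0, fwhm_cm1=10.0, amplitude=3.0)
        prof = peak.profile(axis.values)
        assert prof[axis.index_of(1000.0)] == pytest.approx(3.0, rel=0.02)

    def test_gaussian_and_voigt_shapes_normalized_at_center(self):
        for shape in ("gaussian", "pseudo_voigt"):
            peak = PeakSpec(1000.0, 10.0, 2.0, shape=shape, eta=0.3)
            assert peak.profile(np.array([1000.0]))[0] == pytest.approx(2.0, rel=1e-12)

    def test_zero_peak_model_gives_zero_spectrum(self, axis):
        s = component_spectrum(ComponentModel("empty", ()), axis)
        assert not s.intensities.any()

    def test_actin_model_has_local_maxima_at_actin_bands(self, axis):
        s = component_spectrum(default_components()["actin"], axis)
        x = s.intensities
        for center in STAGED:
            i = axis.index_of(center)
            j = np.argmax(x[max(i - 2, 0) : i + 3]) + i - 2
            assert x[j] >= x[j - 1] and x[j] >= x[j + 1], center

    def test_myosin_cellular_shifts_from_reference(self, axis):
        ref = component_spectrum(default_components()["myosin_reference"], axis)
        cell = component_spectrum(default_components()["myosin_cellular"], axis)
        # reference bands at 1320/1670 move to 1336/1654 inside cells
        assert band_height(ref.intensities, axis, 1320, 4) > band_height(
            cell.intensities, axis, 1320, 4
        )
        assert band_height(cell.intensities, axis, 1336, 4) > band_height(
            ref.intensities, axis, 1336, 4
        )
        assert band_height(ref.intensities, axis, 1670, 4) > band_height(
            cell.intensities, axis, 1670, 4
        )

    def test_out_of_range_peak_warns_and_contributes_tail(self):
        axis = WavenumberAxis(np.linspace(700, 1800, 50))
        model = ComponentModel("edge", (PeakSpec(2000.0, 12.0, 1.0),))
        with pytest.warns(UserWarning, match="outside the axis"):
            s = component_spectrum(model, axis)
        assert 0 < s.intensities.max() < 1.0


class TestSimulateGroups:
    def test_four_groups_of_twenty_selected_spectra(self):
        grouped, _ = simulate_groups(SyntheticConfig(seed=1))
        assert grouped.labels == ("2D_PCa", "3D_d23+5", "3D_d23+10", "3D_d23+15")
        assert all(len(grouped[g]) == 20 for g in grouped.labels)

    def test_seed_determinism(self):
        a, _ = simulate_groups(SyntheticConfig(seed=42))
        b, _ = simulate_groups(SyntheticConfig(seed=42))
        for g in a.labels:
            np.testing.assert_array_equal(a.matrix(g), b.matrix(g))

    def test_different_seeds_differ(self):
        a, _ = simulate_groups(SyntheticConfig(seed=1))
        b, _ = simulate_groups(SyntheticConfig(seed=2))
        assert not np.array_equal(a.matrix("2D_PCa"), b.matrix("2D_PCa"))

    def test_all_nuisances_off_groups_share_mean_when_unmodulated(self, clean_config):
        import dataclasses

        cfg = dataclasses.replace(clean_config, reduction_factors=())
        grouped, _ = simulate_groups(cfg)
        ref = grouped.matrix("2D_PCa").mean(axis=0)
        for g in grouped.labels[1:]:
            np.testing.assert_allclose(grouped.matrix(g).mean(axis=0), ref)

    def test_planted_reduction_ratio_at_1444(self, clean_config):
        grouped, _ = simulate_groups(clean_config)
        axis = clean_config.axis
        early = band_height(grouped.matrix("3D_d23+5").mean(0), axis, 1444)
        mid = band_height(grouped.matrix("3D_d23+10").mean(0), axis, 1444)
        late = band_height(grouped.matrix("3D_d23+15").mean(0), axis, 1444)
        assert mid / early == pytest.approx(0.7, abs=0.01)
        assert late / early == pytest.approx(0.55, abs=0.01)

    def test_dna_band_unaffected_by_stage(self, clean_config):
        # the internal standard changes only through far tails of the
        # staged bands (< 0.5%), never through its own amplitude
        grouped, _ = simulate_groups(clean_config)
        axis = clean_config.axis
        heights = [
            band_height(grouped.matrix(g).mean(0), axis, 780) for g in grouped.labels
        ]
        np.testing.assert_allclose(heights, heights[0], rtol=5e-3)

    def test_ground_truth_reconstructs_zero_noise_spectra(self, clean_config):
        import dataclasses

        cfg = dataclasses.replace(clean_config, baseline_scale=0.2)
        grouped, truth = simulate_groups(cfg)
        comps = default_components()
        from ramanstage.synthetic_data import _group_component_matrix

        for g in grouped.labels:
            names, mat = _group_component_matrix(cfg, g, comps)
            for i, s in enumerate(grouped[g]):
                w = np.array([truth.concentrations[(g, i)][n] for n in names])
                t = np.linspace(-1, 1, cfg.axis.n_points)
                baseline = np.polynomial.polynomial.polyval(
                    t, truth.baseline_coeffs[(g, i)]
                )
                np.testing.assert_allclose(
                    s.intensities, w @ mat + baseline, atol=1e-9
                )

    def test_ground_truth_noise_closes_the_budget(self):
        cfg = SyntheticConfig(seed=6, spike_rate=0.0)
        grouped, truth = simulate_groups(cfg)
        key = ("2D_PCa", 0)
        s = grouped["2D_PCa"][0].intensities
        t = np.linspace(-1, 1, cfg.axis.n_points)
        baseline = np.polynomial.polynomial.polyval(t, truth.baseline_coeffs[key])
        np.testing.assert_allclose(
            s, truth.clean[key] + baseline + truth.noise[key], atol=1e-9
        )

    def test_spikes_recorded_at_injected_positions(self):
        cfg = SyntheticConfig(seed=9, spike_rate=2.0, noise_sd=0.0)
        grouped, truth = simulate_groups(cfg)
        key = ("2D_PCa", 0)
        s = grouped["2D_PCa"][0].intensities
        t = np.linspace(-1, 1, cfg.axis.n_points)
        baseline = np.polynomial.polynomial.polyval(t, truth.baseline_coeffs[key])
        resid = s - truth.clean[key] - baseline
        np.testing.assert_array_equal(np.flatnonzero(resid > 1e-9), truth.spikes[key])

    def test_fewer_than_two_spectra_rejected(self):
        with pytest.raises(ValueError):
            simulate_groups(SyntheticConfig(seed=1, n_spectra_per_group=1))

    def test_weight_monotonicity_in_band_heights(self, axis):
        # increasing a component's weight raises its band heights (no noise)
        comps = default_components()
        actin = component_spectrum(comps["actin"], axis).intensities
        dna = component_spectrum(comps["DNA"], axis).intensities
        for w in (0.5, 1.0, 2.0):
            mix = dna + w * actin
            lo = dna + 0.9 * w * actin
            for center in STAGED:
                assert band_height(mix, axis, center) > band_height(lo, axis, center)


class TestSimulateCube:
    def test_default_geometry_40x40_1600_pixels(self):
        cube, _ = simulate_cube(SyntheticConfig(seed=1))
        assert (cube.rows, cube.cols) == (40, 40)
        assert cube.n_pixels == 1600
        assert cube.extent_um == (80.0, 80.0)

    def test_zero_cells_gives_baseline_noise_only(self):
        cfg = SyntheticConfig(seed=2, n_cells=0, rows=12, cols=12)
        cube, truth = simulate_cube(cfg)
        assert not truth.masks["actin_rich"].any()
        assert not truth.masks["cell"].any()
        # no component signal anywhere: recorded clean spectra are zero
        assert all(not c.any() for c in truth.clean.values())

    def test_planted_mask_pixels_beat_background_at_1444(self, clean_config):
        import dataclasses

        cfg = dataclasses.replace(clean_config, rows=16, cols=16)
        cell = np.zeros((16, 16), dtype=bool)
        cell[2:10, 2:14] = True
        actin = np.zeros_like(cell)
        actin[4:8, 4:9] = True
        layout = layout_from_masks(cfg, cell, actin_rich=actin)
        cube, truth = simulate_cube(cfg, layout=layout)
        axis = cfg.axis
        h = cube.pixels[:, :, axis.window_mask(1444, 8)].max(axis=2)
        assert h[actin].min() > h[~truth.masks["cell"]].max()

    def test_cell_radius_exceeding_grid_raises(self):
        cfg = SyntheticConfig(seed=1, rows=6, cols=6, cell_radius_um=(20.0, 30.0))
        with pytest.raises(ValueError, match="radius"):
            simulate_cube(cfg)

    def test_determinism(self, small_cube_config):
        a, _ = simulate_cube(small_cube_config)
        b, _ = simulate_cube(small_cube_config)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_masks_have_cube_shape_and_rich_regions_disjoint(self, small_cube_config):
        cube, truth = simulate_cube(small_cube_config)
        for name in ("cell", "actin_rich", "myosin_rich"):
            assert truth.masks[name].shape == (cube.rows, cube.cols)
        assert not (truth.masks["actin_rich"] & truth.masks["myosin_rich"]).any()

    def test_reference_spectrum_names(self, axis):
        for name in ("actin", "myosin_reference", "DNA"):
            s = reference_spectrum(name, axis)
            assert s.intensities.max() > 0
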