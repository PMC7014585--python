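"""Spectral covariates: derivative filtering, peaks, indices, assembly."""

import numpy as np
import pytest
from scipy.signal import savgol_filter

from vegspec.features import (
    DerivativeSpectrum,
    FeatureConfig,
    SavgolDerivative,
    assemble_covariates,
    band_ratio_features,
    detect_red_edge_peaks,
    load_index_registry,
    min_reflectance_feature,
    red_edge_peak_covariates,
    region_extrema_features,
    savgol_first_derivative,
    select_smoothing_level,
    vegetation_indices,
)
from vegspec.spectra import SpectraError, Spectrum, WavelengthGrid

from conftest import make_dataset


def naive_savgol_d1(wavelengths, values, window, polyorder):
    """Independent oracle: explicit local polynomial fit per window."""
    n = len(wavelengths)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        lo = min(max(i - half, 0), n - window)
        sel = slice(lo, lo + window)
        coeffs = np.polyfit(wavelengths[sel] - wavelengths[i], values[sel],
                            polyorder)
        out[i] = coeffs[-2]  # linear coefficient = derivative at centre
    return out


class TestSavgolDerivative:
    def test_linear_spectrum_exact(self):
        grid = WavelengthGrid(np.arange(400.0, 700.0, 10.0))
        r = 0.0002 * grid.wavelengths
        d = savgol_first_derivative(Spectrum(grid, r), 7, 2)
        np.testing.assert_allclose(d.d1, 0.0002, atol=1e-12)

    def test_quadratic_interior_exact(self):
        grid = WavelengthGrid(np.arange(400.0, 700.0, 10.0))
        wl = grid.wavelengths
        a, b, c = 0.3, -4e-4, 3e-7
        r = a + b * wl + c * wl**2
        d = savgol_first_derivative(Spectrum(grid, r), 7, 2)
        np.testing.assert_allclose(d.d1[3:-3], (b + 2 * c * wl)[3:-3], atol=1e-9)

    def test_matches_explicit_polyfit_oracle(self, fine_grid):
        wl = fine_grid.wavelengths
        r = 0.3 + 0.2 * np.sin(wl / 50.0)
        d = savgol_first_derivative(Spectrum(fine_grid, r), 9, 2)
        np.testing.assert_allclose(d.d1, naive_savgol_d1(wl, r, 9, 2), atol=1e-9)

    def test_matches_central_difference_of_smoothed(self, fine_grid):
        wl = fine_grid.wavelengths
        r = 0.3 + 0.2 * np.sin(wl / 50.0)
        smoothed = savgol_filter(r, 9, 2)
        fd = np.gradient(smoothed, wl)
        d = savgol_first_derivative(Spectrum(fine_grid, r), 9, 2)
        np.testing.assert_allclose(d.d1[4:-4], fd[4:-4], atol=1e-3)

    def test_matches_scipy_on_uniform_grid(self, fine_grid):
        rng = np.random.default_rng(3)
        r = np.clip(0.3 + 0.05 * rng.standard_normal(len(fine_grid)), 0, 1)
        ours = savgol_first_derivative(Spectrum(fine_grid, r), 9, 3).d1
        ref = savgol_filter(r, 9, 3, deriv=1, delta=2.0, mode="interp")
        np.testing.assert_allclose(ours, ref, atol=1e-10)

    def test_uneven_grid_polynomial_exact(self):
        rng = np.random.default_rng(5)
        wl = np.sort(rng.uniform(400, 800, 60))
        grid = WavelengthGrid(wl)
        r = 0.2 + 1e-4 * wl + 2e-7 * wl**2
        r = r / r.max() * 0.8
        d = SavgolDerivative(grid, 7, 2).apply_matrix(r[None, :])[0]
        scale = 0.8 / (0.2 + 1e-4 * wl + 2e-7 * wl**2).max()
        np.testing.assert_allclose(d, scale * (1e-4 + 4e-7 * wl), atol=1e-9)

    def test_linearity(self, fine_grid):
        rng = np.random.default_rng(11)
        r1 = rng.uniform(0.1, 0.5, len(fine_grid))
        r2 = rng.uniform(0.1, 0.5, len(fine_grid))
        op = SavgolDerivative(fine_grid, 9, 2)
        combo = op.apply_matrix((0.3 * r1 + 0.6 * r2)[None, :])[0]
        parts = 0.3 * op.apply_matrix(r1[None, :])[0] \
            + 0.6 * op.apply_matrix(r2[None, :])[0]
        np.testing.assert_allclose(combo, parts, atol=1e-12)

    @pytest.mark.parametrize("window,polyorder", [(8, 2), (5, 5), (9999, 2)])
    def test_invalid_window_rejected(self, fine_grid, window, polyorder):
        with pytest.raises(SpectraError):
            SavgolDerivative(fine_grid, window, polyorder)


class TestMinReflectance:
    def test_constructed_minimum(self, uniform_grid):
        r = np.full(len(uniform_grid), 0.2)
        r[uniform_grid.index_of(680.0)] = 0.04
        pos, val = min_reflectance_feature(Spectrum(uniform_grid, r))
        assert (pos, val) == (680.0, 0.04)

    def test_tie_goes_to_lowest_wavelength(self, uniform_grid):
        r = np.full(len(uniform_grid), 0.2)
        pos, val = min_reflectance_feature(Spectrum(uniform_grid, r))
        assert pos == 660.0 and val == 0.2

    def test_empty_region_rejected(self, uniform_grid):
        spectrum = Spectrum(uniform_grid, np.full(len(uniform_grid), 0.2))
        with pytest.raises(SpectraError):
            min_reflectance_feature(spectrum, region=(660.0, 650.0))


class TestRegionExtrema:
    def _deriv(self, grid, d1):
        return DerivativeSpectrum(grid, d1)

    def test_constructed_bump_and_dip(self, uniform_grid):
        wl = uniform_grid.wavelengths
        d1 = (0.01 * np.exp(-0.5 * ((wl - 520) / 8) ** 2)
              - 0.01 * np.exp(-0.5 * ((wl - 600) / 8) ** 2))
        recs = region_extrema_features(self._deriv(uniform_grid, d1))
        by_region = {r["region"]: r for r in recs}
        assert by_region[(495.0, 550.0)]["max_pos"] == 520.0
        assert by_region[(550.0, 650.0)]["min_pos"] == 600.0

    def test_zero_derivative_ties_to_first_band(self, uniform_grid):
        recs = region_extrema_features(
            self._deriv(uniform_grid, np.zeros(len(uniform_grid))))
        for rec in recs:
            lo, _ = rec["region"]
            first = uniform_grid.wavelengths[uniform_grid.indices_in(lo, rec["region"][1])[0]]
            assert rec["min_pos"] == rec["max_pos"] == first
            assert rec["min_val"] == rec["max_val"] == 0.0

    def test_five_regions_yield_twenty_values(self, uniform_grid):
        recs = region_extrema_features(
            self._deriv(uniform_grid, np.zeros(len(uniform_grid))))
        assert len(recs) * 4 == 20


def exhaustive_peak_scan(wl, d1, lo, hi, max_peaks):
    """Independent oracle: plain interior-point scan with plateau handling."""
    peaks = []
    i = 1
    n = len(d1)
    while i < n - 1:
        j = i
        while j < n - 1 and d1[j + 1] == d1[j]:
            j += 1
        if j < n - 1 and d1[i - 1] < d1[i] and d1[j] > d1[j + 1]:
            if lo <= wl[i] <= hi and d1[i] > 0:
                peaks.append((wl[i], d1[i]))
        i = j + 1
    if len(peaks) > max_peaks:
        peaks = sorted(peaks, key=lambda ph: (-ph[1], ph[0]))[:max_peaks]
    return sorted(peaks)


class TestRedEdgePeaks:
    def _grid(self):
        return WavelengthGrid(np.arange(650.0, 801.0, 2.0))

    def _bumps(self, grid, centres, heights, width=5.0):
        wl = grid.wavelengths
        d1 = np.zeros(len(wl))
        for c, h in zip(centres, heights):
            d1 += h * np.exp(-0.5 * ((wl - c) / width) ** 2)
        return DerivativeSpectrum(grid, d1)

    def test_two_bumps_found_in_order(self):
        grid = self._grid()
        peaks = detect_red_edge_peaks(self._bumps(grid, [706, 726], [0.01, 0.008]))
        assert [p.position for p in peaks] == [706.0, 726.0]
        assert [p.index for p in peaks] == [1, 2]

    def test_monotone_derivative_has_no_peaks(self):
        grid = self._grid()
        d1 = np.linspace(0.001, 0.01, len(grid))
        assert detect_red_edge_peaks(DerivativeSpectrum(grid, d1)) == []

    def test_four_bumps_keep_three_tallest_in_wavelength_order(self):
        grid = self._grid()
        deriv = self._bumps(grid, [696, 710, 724, 740],
                            [0.004, 0.010, 0.006, 0.008], width=3.0)
        peaks = detect_red_edge_peaks(deriv, max_peaks=3)
        oracle = exhaustive_peak_scan(grid.wavelengths, deriv.d1, 690, 750, 3)
        assert [(p.position, p.height) for p in peaks] == oracle
        assert [p.position for p in peaks] == sorted(p.position for p in peaks)

    def test_plateau_reported_at_lowest_wavelength(self):
        grid = self._grid()
        d1 = np.zeros(len(grid))
        i = grid.index_of(710.0)
        d1[i:i + 3] = 0.01
        peaks = detect_red_edge_peaks(DerivativeSpectrum(grid, d1))
        assert len(peaks) == 1 and peaks[0].position == 710.0

    def test_equals_exhaustive_scan_on_random_fixtures(self):
        grid = self._grid()
        rng = np.random.default_rng(42)
        for _ in range(200):
            d1 = rng.standard_normal(len(grid)) * 0.01
            if rng.random() < 0.3:  # inject plateaus
                k = rng.integers(1, len(grid) - 4)
                d1[k:k + 3] = d1[k]
            deriv = DerivativeSpectrum(grid, d1)
            got = [(p.position, p.height)
                   for p in detect_red_edge_peaks(deriv, max_peaks=3)]
            want = exhaustive_peak_scan(grid.wavelengths, d1, 690, 750, 3)
            assert got == pytest.approx(want)


class TestPeakCovariates:
    def _peaks(self, spec_list):
        from vegspec.features import RedEdgePeak
        return [RedEdgePeak(position=p, height=h, index=i + 1)
                for i, (p, h) in enumerate(spec_list)]

    def _spectrum(self):
        grid = WavelengthGrid(np.arange(650.0, 801.0, 2.0))
        return Spectrum(grid, np.full(len(grid), 0.3))

    def test_height_ratio(self):
        cov = red_edge_peak_covariates(self._peaks([(705, 0.004), (725, 0.002)]),
                                       self._spectrum(), "airborne")
        assert cov["repk_height_ratio_1_2"] == pytest.approx(2.0)

    def test_missing_peaks_give_nan(self):
        cov = red_edge_peak_covariates(self._peaks([(705, 0.004)]),
                                       self._spectrum(), "airborne")
        assert np.isnan(cov["repk_height_ratio_1_2"])
        assert np.isnan(cov["repk_height_ratio_1_3"])
        assert np.isnan(cov["repk_height_ratio_2_3"])

    def test_field_mode_wavelength_ratio(self):
        cov = red_edge_peak_covariates(self._peaks([(705, 0.004), (725, 0.002)]),
                                       self._spectrum(), "field")
        assert cov["repk_pos_ratio_1_2"] == pytest.approx(705 / 725, abs=1e-4)
        assert cov["repk_maxrefl"] == pytest.approx(0.3)

    def test_airborne_mode_has_no_positional_covariates(self):
        cov = red_edge_peak_covariates(self._peaks([(705, 0.004)]),
                                       self._spectrum(), "airborne")
        assert not any(k.startswith("repk_pos") for k in cov)


class TestVegetationIndices:
    def _spectrum_with(self, grid, pairs, default=0.3):
        r = np.full(len(grid), default)
        for wl_nm, val in pairs:
            r[grid.index_of(wl_nm)] = val
        return Spectrum(grid, r)

    def test_ndvi_pinned_value(self, uniform_grid):
        s = self._spectrum_with(uniform_grid, [(800, 0.5), (670, 0.1)])
        assert vegetation_indices(s)["NDVI"] == pytest.approx(2 / 3, abs=1e-4)

    def test_flat_spectrum_symmetric_indices_vanish(self, uniform_grid):
        s = Spectrum(uniform_grid, np.full(len(uniform_grid), 0.25))
        vi = vegetation_indices(s)
        for name in ("ARI", "RVSI", "CAI", "PRI", "NDVI", "NDLI"):
            assert vi[name] == pytest.approx(0.0, abs=1e-12)
        assert vi["WBI"] == pytest.approx(1.0)
        assert vi["RGRI"] == pytest.approx(1.0)

    def test_scale_invariant_indices(self, grass_spectrum):
        scaled = Spectrum(grass_spectrum.grid, grass_spectrum.reflectance * 1.8)
        vi1 = vegetation_indices(grass_spectrum)
        vi2 = vegetation_indices(scaled)
        for name in ("NDVI", "PRI", "RGRI", "WBI"):
            assert vi2[name] == pytest.approx(vi1[name], rel=1e-9)
        # NDLI's numerator is scale-free but its denominator -log(R1754*R1680)
        # shifts by -2*log(c); check the exact transformation instead
        r1754 = grass_spectrum.at(1754.0)
        r1680 = grass_spectrum.at(1680.0)
        num = np.log(r1680) - np.log(r1754)
        den = -np.log(r1754) - np.log(r1680)
        assert vi1["NDLI"] == pytest.approx(num / den, rel=1e-9)
        assert vi2["NDLI"] == pytest.approx(num / (den - 2 * np.log(1.8)), rel=1e-9)
        # ARI scales as 1/c, mARI is scale-free, CAI and RVSI scale as c
        assert vi2["ARI"] == pytest.approx(vi1["ARI"] / 1.8, rel=1e-9)
        assert vi2["mARI"] == pytest.approx(vi1["mARI"], rel=1e-9)
        assert vi2["CAI"] == pytest.approx(vi1["CAI"] * 1.8, rel=1e-9)
        assert vi2["RVSI"] == pytest.approx(vi1["RVSI"] * 1.8, rel=1e-9)

    def test_nonpositive_log_argument_yields_nan(self):
        grid = WavelengthGrid(np.arange(1600.0, 1801.0, 2.0))
        r = np.full(len(grid), 0.3)
        r[grid.index_of(1754.0)] = 0.0
        ndli = [d for d in load_index_registry() if d.name == "NDLI"][0]
        assert np.isnan(ndli.evaluate(Spectrum(grid, r)))


class TestBandRatios:
    @pytest.mark.parametrize("n,expected", [(13, 78), (8, 28)])
    def test_pair_count(self, n, expected):
        grid = WavelengthGrid(np.linspace(400, 2400, n))
        s = Spectrum(grid, np.linspace(0.1, 0.5, n))
        assert len(band_ratio_features(s)) == expected

    def test_ratio_value_and_orientation(self):
        grid = WavelengthGrid(np.array([500.0, 800.0]))
        s = Spectrum(grid, np.array([0.2, 0.4]))
        ratios = band_ratio_features(s)
        assert ratios["ratio_500_800"] == pytest.approx(0.5)

    def test_zero_denominator_gives_nan(self):
        grid = WavelengthGrid(np.array([500.0, 800.0]))
        s = Spectrum(grid, np.array([0.2, 0.0]))
        assert np.isnan(band_ratio_features(s)["ratio_500_800"])

    def test_scale_invariance(self):
        grid = WavelengthGrid(np.linspace(400, 2400, 6))
        rng = np.random.default_rng(1)
        r = rng.uniform(0.1, 0.6, 6)
        r1 = band_ratio_features(Spectrum(grid, r))
        r2 = band_ratio_features(Spectrum(grid, r * 2.3))
        for k in r1:
            assert r2[k] == pytest.approx(r1[k], rel=1e-12)


class TestAssembly:
    def test_multispectral_census(self, small_scene):
        from vegspec.bandsim import builtin_bandset, simulate_multispectral
        sim = simulate_multispectral(small_scene.dataset.subset(np.arange(10)),
                                     builtin_bandset("sim8"))
        table = assemble_covariates(sim, FeatureConfig(mode="multispectral"))
        census = table.census()
        assert census["reflectance"] == 8
        assert census["ratio"] == 28
        assert len(table.columns) == 8 + 28 + census.get("index", 0)

    def test_airborne_derivative_family_covers_every_band(self, small_scene):
        ds = small_scene.dataset.subset(np.arange(8))
        table = assemble_covariates(ds, FeatureConfig(mode="airborne"))
        assert table.census()["derivative"] == len(ds.grid)

    def test_census_is_reproducible(self, small_scene):
        ds = small_scene.dataset.subset(np.arange(6))
        t1 = assemble_covariates(ds, FeatureConfig(mode="airborne"))
        t2 = assemble_covariates(ds, FeatureConfig(mode="airborne"))
        assert t1.columns == t2.columns

    def test_missing_peaks_imputed_not_dropped(self, uniform_grid):
        # one sample with red-edge peaks, one flat sample without any
        rng = np.random.default_rng(2)
        wl = uniform_grid.wavelengths
        with_edge = 0.05 + 0.4 / (1 + np.exp(-(wl - 720) / 10))
        w2 = 0.05 + 0.35 / (1 + np.exp(-(wl - 705) / 12))
        flat = np.full(len(wl), 0.2)
        ds = make_dataset(uniform_grid, np.vstack([with_edge, w2, flat]),
                          ["a", "a", "b"])
        table = assemble_covariates(ds, FeatureConfig(mode="airborne"))
        assert table.n_samples == 3
        col = table.table["repk_height_1"]
        assert np.isfinite(col).all()
        # the flat sample received the median of the defined samples
        assert col.iloc[2] == pytest.approx(np.median(col.iloc[:2]))

    def test_train_only_imputation(self, uniform_grid):
        wl = uniform_grid.wavelengths
        s1 = 0.05 + 0.4 / (1 + np.exp(-(wl - 720) / 10))
        flat = np.full(len(wl), 0.2)
        ds = make_dataset(uniform_grid, np.vstack([s1, flat, flat]),
                          ["a", "b", "b"])
        table = assemble_covariates(ds, FeatureConfig(mode="airborne"),
                                    train_mask=np.array([True, True, False]))
        # validation row's missing peak filled from training median only
        assert table.table["repk_height_1"].iloc[2] == \
            pytest.approx(table.table["repk_height_1"].iloc[0])


class TestSmoothingSelection:
    def _separable_scene(self):
        from vegspec.synthetic import (SyntheticConfig, default_archetypes,
                                       generate_scene)
        cfg = SyntheticConfig(archetypes=default_archetypes(2, 2), n_bands=81,
                              wide_patches_per_category=2,
                              narrow_patches_per_category=0, noise_sd=0.002,
                              smooth_noise_sd=0.0)
        return generate_scene(cfg, seed=3)

    def test_single_candidate_returned(self, small_scene):
        labels = small_scene.dataset.labels("finest")
        two = np.unique(labels)[:2]
        idx = np.r_[np.nonzero(labels == two[0])[0][:20],
                    np.nonzero(labels == two[1])[0][:20]]
        ds = small_scene.dataset.subset(idx)
        window, scores = select_smoothing_level(ds, "finest", [9], ntree=20)
        assert window == 9 and set(scores) == {9}

    def test_tie_goes_to_smaller_window(self):
        scene = self._separable_scene()
        ds = scene.dataset
        # classes fully separable: both windows reach identical (perfect) OOB
        window, scores = select_smoothing_level(ds, "finest", [11, 5],
                                                ntree=30, seed=0)
        if scores[5] == scores[11]:
            assert window == 5
        else:
            assert window == max(scores, key=lambda w: (scores[w], -w))

    def test_degenerate_labels_rejected(self):
        scene = self._separable_scene()
        ds = scene.dataset
        ds.meta["label_finest"] = "same"
        with pytest.raises(SpectraError):
            select_smoothing_level(ds, "finest", [5, 9], ntree=10)
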