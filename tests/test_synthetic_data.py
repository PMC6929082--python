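"""Generator: population statistics, band model, filter, IO."""

import dataclasses

import numpy as np
import pytest

from pearssc import (Band, GeneratorConfig, apply_small_fruit_filter,
                     generate_population, simulate_absorbance,
                     simulate_reflectance)
from pearssc.synthetic_data import (SUBSET_LABELS, read_csv,
                                    reflectance_from_counts,
                                    wavelength_grid, write_csv)


def _pair_sides(samples):
    by_fruit = {}
    for s in samples:
        by_fruit.setdefault(s.fruit_id, {})[s.side] = s
    return by_fruit


class TestPopulationStatistics:
    def test_side_to_side_ssc_spread(self, survey_scale_pop):
        """Std of the per-fruit SSC difference matches the configured
        0.62 degBrix heterogeneity within Monte-Carlo error."""
        pairs = _pair_sides(survey_scale_pop)
        diffs = np.array([p[0].ssc - p[1].ssc for p in pairs.values()])
        assert abs(diffs.mean()) < 0.05
        assert np.std(diffs) == pytest.approx(0.62, abs=0.05)

    def test_ssc_mean_and_coverage(self, survey_scale_pop):
        pairs = _pair_sides(survey_scale_pop)
        # drift adds +0.3 to subsets D-E, so check the undrifted subsets
        abc = np.array([(p[0].ssc + p[1].ssc) / 2
                        for p in pairs.values()
                        if p[0].subset_label in "ABC"])
        assert abs(abc.mean() - 13.0) < 0.1
        within = np.mean(np.abs(abc - 13.0) <= 2 * 1.725)
        assert 0.93 <= within <= 0.99

    def test_attribute_ranges(self, survey_scale_pop):
        diam = np.array([s.diameter for s in survey_scale_pop])
        temp = np.array([s.temperature for s in survey_scale_pop])
        assert diam.min() >= 43.0 and diam.max() <= 81.0
        assert temp.min() > 0.0 and temp.max() < 45.0

    def test_subset_labels_partition(self, survey_scale_pop):
        counts = {lab: 0 for lab in SUBSET_LABELS}
        for s in survey_scale_pop:
            counts[s.subset_label] += 1
        total = sum(counts.values())
        assert total == len(survey_scale_pop)
        for lab, frac in zip(SUBSET_LABELS, (0.2,) * 5):
            assert counts[lab] / total == pytest.approx(frac, abs=0.01)

    def test_zero_delta_makes_sides_identical(self):
        pop = generate_population(GeneratorConfig(n_fruits=20, seed=3,
                                                  delta_ssc_sd=0.0))
        for pair in _pair_sides(pop).values():
            assert pair[0].ssc == pair[1].ssc

    def test_determinism_bit_identical(self):
        cfg = GeneratorConfig(n_fruits=15, seed=9)
        a, b = generate_population(cfg), generate_population(cfg)
        for sa, sb in zip(a, b):
            assert sa.ssc == sb.ssc and sa.temperature == sb.temperature
            assert np.array_equal(sa.reflectance, sb.reflectance)

    def test_late_subset_e_oversamples_extreme_sizes(self, survey_scale_pop):
        pairs = _pair_sides(survey_scale_pop)
        def extreme_frac(labels):
            d = np.array([p[0].diameter for p in pairs.values()
                          if p[0].subset_label in labels])
            return np.mean((d < 50) | (d > 74))
        assert extreme_frac("E") > extreme_frac("ABC") + 0.1


class TestBandModel:
    def test_noiseless_reflectance_matches_band_sum_oracle(self):
        """With no noise, no scatter and T=20 the output is exactly
        10**(-A) of the deterministic band sum, re-coded independently."""
        cfg = GeneratorConfig(n_fruits=1, seed=0, noise_sd=0.0,
                              scatter_slope_per_mm=0.0)
        wl = wavelength_grid()
        ssc, chl = 14.2, 0.8
        got = simulate_reflectance(ssc, chl, 20.0, 60.0, cfg,
                                   np.random.default_rng(0))
        x = (wl - wl[0]) / (wl[-1] - wl[0])
        expect = 0.35 + 0.15 * x
        for band in cfg.band_library:
            scale = {"chl": chl, "sugar": ssc, "water": 1.0}[band.kind]
            expect = expect + scale * band.amplitude * np.exp(
                -0.5 * ((wl - band.center_nm) / band.width_nm) ** 2)
        np.testing.assert_allclose(got, 10.0 ** (-expect), rtol=1e-12)

    def test_ssc_difference_localized_to_sugar_bands(self):
        cfg = GeneratorConfig(n_fruits=1, seed=0)
        wl = wavelength_grid()
        d = simulate_absorbance(15.0, 1.0, 20.0, cfg) - \
            simulate_absorbance(10.0, 1.0, 20.0, cfg)
        sugar = [b for b in cfg.band_library if b.kind == "sugar"]
        for b in sugar:
            assert d[np.argmin(np.abs(wl - b.center_nm))] > 1e-3
        far = np.all([np.abs(wl - b.center_nm) > 6 * b.width_nm
                      for b in sugar], axis=0)
        assert np.all(np.abs(d[far]) < 1e-7)

    def test_chlorophyll_difference_localized_near_680(self):
        cfg = GeneratorConfig(n_fruits=1, seed=0)
        wl = wavelength_grid()
        d = simulate_absorbance(13.0, 1.5, 20.0, cfg) - \
            simulate_absorbance(13.0, 0.0, 20.0, cfg)
        chl_width = next(b.width_nm for b in cfg.band_library
                         if b.kind == "chl")
        assert d[np.argmin(np.abs(wl - 680.0))] > 0.1
        assert np.all(np.abs(d[np.abs(wl - 680.0) > 6 * chl_width]) < 1e-7)

    def test_absorbance_linear_in_ssc_at_band_center(self):
        """The noiseless absorbance at a sugar band center regresses on SSC
        with exactly the analytic band-sum slope."""
        cfg = GeneratorConfig(n_fruits=1, seed=0)
        wl = wavelength_grid()
        idx = int(np.argmin(np.abs(wl - 840.0)))
        sscs = np.linspace(8.0, 18.0, 7)
        vals = np.array([simulate_absorbance(s, 1.0, 20.0, cfg)[idx]
                         for s in sscs])
        slope = np.polyfit(sscs, vals, 1)[0]
        analytic = sum(
            b.amplitude * np.exp(-0.5 * ((wl[idx] - b.center_nm)
                                         / b.width_nm) ** 2)
            for b in cfg.band_library if b.kind == "sugar")
        assert slope == pytest.approx(analytic, rel=1e-9)

    def test_temperature_shifts_vibrational_bands(self):
        cfg = GeneratorConfig(n_fruits=1, seed=0)
        wl = wavelength_grid()
        cold = simulate_absorbance(13.0, 0.0, 5.0, cfg)
        warm = simulate_absorbance(13.0, 0.0, 35.0, cfg)
        region = (wl > 900) & (wl < 1040)
        assert np.max(np.abs(warm - cold)[region]) > 1e-4
        # chlorophyll band (electronic) does not move
        chl_idx = np.argmin(np.abs(wl - 680.0))
        d_chl = simulate_absorbance(13.0, 1.0, 5.0, cfg)[chl_idx] - \
            simulate_absorbance(13.0, 1.0, 35.0, cfg)[chl_idx]
        assert abs(d_chl) < 1e-3


class TestSmallFruitFilter:
    def _pop_with_diameters(self, diams):
        cfg = GeneratorConfig(n_fruits=len(diams), seed=4)
        pop = generate_population(cfg)
        for s in pop:
            s.diameter = float(diams[s.fruit_id])
        return pop

    def test_removes_both_sides_below_threshold(self):
        pop = self._pop_with_diameters([41.0, 60.0])
        kept = apply_small_fruit_filter(pop)
        assert len(kept) == 2 and all(s.fruit_id == 1 for s in kept)

    @pytest.mark.parametrize("diams,expected", [
        ((40.0, 42.0, 60.0), 4),
        ((50.0, 60.0, 70.0), 6),
    ])
    def test_retained_counts(self, diams, expected):
        kept = apply_small_fruit_filter(self._pop_with_diameters(diams))
        assert len(kept) == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            apply_small_fruit_filter([])


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_fruits": 0},
        {"subset_fractions": (0.3, 0.3, 0.3, 0.05, 0.04)},
        {"ssc_sd": -1.0},
        {"ssc_range": (12.0, 14.0)},
        {"band_library": (Band(2000.0, 10.0, 0.1, "sugar"),)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GeneratorConfig(**kwargs)

    def test_json_round_trip(self):
        cfg = GeneratorConfig(n_fruits=7, seed=2, delta_ssc_sd=0.5)
        again = GeneratorConfig.from_json(cfg.to_json())
        assert again == cfg


class TestIO:
    def test_csv_round_trip(self, tmp_path):
        pop = generate_population(GeneratorConfig(n_fruits=5, seed=6))
        path = tmp_path / "pears.csv"
        write_csv(pop, path)
        header = path.read_text().splitlines()[0]
        assert header.startswith(
            "fruit_id,side,subset,temperature_C,diameter_mm,ssc_brix,r_0432.0")
        back = read_csv(path)
        assert len(back) == len(pop)
        for a, b in zip(pop, back):
            assert (a.fruit_id, a.side, a.subset_label) == \
                (b.fruit_id, b.side, b.subset_label)
            assert a.ssc == pytest.approx(b.ssc, abs=1e-12)
            np.testing.assert_allclose(a.reflectance, b.reflectance,
                                       atol=1e-12)

    def test_reflectance_from_counts(self):
        raw = np.array([300.0, 400.0])
        dark = np.array([100.0, 100.0])
        ref = np.array([1100.0, 1100.0])
        np.testing.assert_allclose(
            reflectance_from_counts(raw, dark, ref), [0.2, 0.3])
        with pytest.raises(ValueError):
            reflectance_from_counts(raw, dark, np.array([50.0, 50.0]))
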