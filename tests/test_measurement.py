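"""Measurement-processing stages: calorimetry, acoustics, fits, Monte-Carlo."""

import numpy as np
import pytest

from paphantom.laws import (
    AbsorptionLawParams,
    AttenuationLawParams,
    PhantomComposition,
    ScatteringLawParams,
    absorption_coefficient,
    attenuation_law,
    reduced_scattering,
)
from paphantom.measurement import (
    CalorimetryRecord,
    WaterModel,
    WaveformPair,
    attenuation_spectrum,
    calorimeter_cp,
    coefficient_of_variation,
    cross_correlation_delay,
    cv_summary,
    fit_absorption_model,
    fit_power_law,
    fit_scattering_model,
    impedance_and_transmission,
    montecarlo_uncertainty,
    speed_of_sound,
)
from paphantom.synthetic import GeneratorConfig, gen_waveform_pair


class TestCalorimetry:
    def test_water_against_water_returns_c_water(self):
        """Energy-balance identity: a 'phantom' that is water gives 4180."""
        rec = CalorimetryRecord(m_water=0.1, m_phantom=0.1, T_water=20.0,
                                T_phantom=10.0, T_eq=15.0, C_calo=0.0)
        cp, _ = calorimeter_cp(rec)
        assert cp == pytest.approx(4180.0)

    def test_hand_computed_record(self):
        # single-expression oracle: [(100 + 0.2*4180)*(20.9-19.0)] / [0.05*(19.0-2.5)]
        rec = CalorimetryRecord(m_water=0.2, m_phantom=0.05, T_water=20.9,
                                T_phantom=2.5, T_eq=19.0, C_calo=100.0)
        cp, budget = calorimeter_cp(rec)
        expected = (100.0 + 0.2 * 4180.0) * (20.9 - 19.0) / (0.05 * (19.0 - 2.5))
        assert cp == pytest.approx(expected, rel=1e-12)
        assert budget.expanded > 0
        assert budget.expanded == pytest.approx(1.96 * budget.combined)

    def test_zero_input_uncertainty_gives_zero_budget(self):
        rec = CalorimetryRecord(m_water=0.2, m_phantom=0.05, T_water=20.9,
                                T_phantom=2.5, T_eq=19.0, C_calo=100.0,
                                u_T=0.0, u_m=0.0)
        _, budget = calorimeter_cp(rec)
        assert budget.expanded == 0.0

    def test_degenerate_equilibrium_rejected(self):
        with pytest.raises(ValueError):
            CalorimetryRecord(m_water=0.2, m_phantom=0.05, T_water=20.9,
                              T_phantom=2.5, T_eq=2.5, C_calo=100.0)


class TestWaterModel:
    def test_sound_speed_at_20C_rounds_to_1482(self):
        assert round(WaterModel().sound_speed(20.0)) == 1482

    def test_attenuation_anchor_at_20MHz(self):
        assert WaterModel().attenuation(20.0) == pytest.approx(0.85)


class TestSpeedOfSound:
    def test_zero_delay_returns_water_speed(self):
        cfg = GeneratorConfig(waveform_fs=1e9)
        water = WaterModel()
        cw = water.sound_speed(19.9)
        pair = gen_waveform_pair(cw, water.attenuation, 0.019, cfg, water)
        cs, _ = speed_of_sound(pair, water)
        assert cs == pytest.approx(cw, rel=1e-6)

    def test_closed_form_arithmetic(self):
        # cs = cw / (1 + dt*cw/h) at cw=1482.3, h=0.019, dt=-1e-7
        cs = 1482.3 / (1.0 + (-1e-7) * 1482.3 / 0.019)
        assert cs == pytest.approx(1493.96, abs=0.01)

    def test_temperature_correction_slope(self):
        """0.6 m/s per deg C back to the reference day temperature."""
        cfg = GeneratorConfig(waveform_fs=1e9)
        water = WaterModel()
        pair_warm = gen_waveform_pair(1490.0, water.attenuation, 0.019, cfg,
                                      water, T_water=21.3)
        cs_warm, _ = speed_of_sound(pair_warm, water, reference_T=19.9)
        cs_raw, _ = speed_of_sound(pair_warm, water, reference_T=21.3)
        assert cs_raw - cs_warm == pytest.approx(0.6 * (21.3 - 19.9), abs=1e-9)
        assert cs_warm == pytest.approx(1490.0 - 0.84, abs=0.05)

    def test_roundtrip_recovers_truth_within_0p1pct(self):
        cfg = GeneratorConfig(waveform_fs=1e9)
        comp = PhantomComposition(c_agarose=1.0)
        pair = gen_waveform_pair(
            1488.0, lambda f: attenuation_law(comp, f), 0.019, cfg)
        cs, budget = speed_of_sound(pair)
        assert cs == pytest.approx(1488.0, rel=1e-3)
        assert budget.combined > 0

    def test_negative_delay_means_faster_than_water(self):
        cfg = GeneratorConfig(waveform_fs=1e9)
        water = WaterModel()
        pair = gen_waveform_pair(1493.0, water.attenuation, 0.019, cfg, water)
        assert cross_correlation_delay(pair) < 0


class TestAttenuationSpectrum:
    def _pair(self, ref, sam, fs=1e9, h=0.019):
        return WaveformPair(reference_trace=ref, sample_trace=sam,
                            sampling_rate=fs, h=h, T_water=19.9)

    def test_identical_traces_give_water_attenuation(self):
        rng = np.random.default_rng(0)
        trace = rng.standard_normal(2000)
        water = WaterModel()
        f, alpha = attenuation_spectrum(self._pair(trace, trace), water)
        assert np.allclose(alpha, water.attenuation(f))

    def test_uniform_halving_adds_constant_offset(self):
        rng = np.random.default_rng(1)
        trace = rng.standard_normal(2000)
        water = WaterModel()
        h = 0.019
        f, a_full = attenuation_spectrum(self._pair(trace, trace, h=h), water)
        _, a_half = attenuation_spectrum(self._pair(trace, 0.5 * trace, h=h), water)
        offset = 20.0 * np.log10(2.0) / (h * 100.0)
        assert np.allclose(a_half - a_full, offset)

    def test_synthetic_power_law_recovered_within_2pct(self):
        cfg = GeneratorConfig(waveform_fs=1e9)
        pair = gen_waveform_pair(1488.0, lambda f: 0.01 * f**1.9, 0.019, cfg)
        f, alpha = attenuation_spectrum(pair, band=(15.0, 35.0))
        fit = fit_power_law(f, alpha)
        assert fit.a0 == pytest.approx(0.01, rel=0.02)
        assert fit.n == pytest.approx(1.9, rel=0.02)

    def test_thickness_invariance_per_cm(self):
        """Doubling h with the same per-cm attenuation leaves alpha unchanged."""
        cfg = GeneratorConfig(waveform_fs=1e9)
        law = lambda f: 0.01 * f**1.8
        f1, a1 = attenuation_spectrum(
            gen_waveform_pair(1488.0, law, 0.010, cfg), band=(15, 35))
        f2, a2 = attenuation_spectrum(
            gen_waveform_pair(1488.0, law, 0.020, cfg), band=(15, 35))
        assert np.allclose(a1, a2, rtol=1e-6)


class TestPowerLawFit:
    def test_exact_recovery_on_noiseless_input(self):
        f = np.linspace(15.0, 35.0, 40)
        fit = fit_power_law(f, 0.0098 * f**1.765)
        assert fit.a0 == pytest.approx(0.0098, rel=1e-12)
        assert fit.n == pytest.approx(1.765, rel=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_consistency_with_attenuation_law_slice(self):
        comp = PhantomComposition(c_agarose=1.0)
        p = AttenuationLawParams()
        f = np.linspace(15.0, 35.0, 50)
        fit = fit_power_law(f, attenuation_law(comp, f, p))
        assert fit.a0 == pytest.approx(p.a2 + p.a1, rel=1e-6)
        assert fit.n == pytest.approx(p.b2 + p.b1, rel=1e-6)

    def test_noise_robustness_median_exponent(self, rng):
        f = np.linspace(15.0, 35.0, 40)
        truth = 0.0098 * f**1.765
        exponents = []
        for _ in range(100):
            noisy = truth * (1.0 + 0.05 * rng.standard_normal(f.size))
            if np.any(noisy <= 0):
                continue
            exponents.append(fit_power_law(f, noisy).n)
        assert abs(np.median(exponents) - 1.765) < 0.05

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_power_law([15, 20, 25], [1.0, -0.5, 2.0])


class TestAbsorptionFit:
    def _dataset(self, params, noise_cv=0.0, rng=None):
        concs = [0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0]
        lams = np.arange(490.0, 836.0, 25.0)
        C, L, M = [], [], []
        for c in concs:
            mu = absorption_coefficient(PhantomComposition(c_agarose=c), lams,
                                        params)
            if noise_cv:
                mu = mu * (1.0 + noise_cv * rng.standard_normal(lams.size))
            C.extend([c] * lams.size)
            L.extend(lams)
            M.extend(np.atleast_1d(mu))
        return np.array(C), np.array(L), np.array(M)

    def test_noiseless_recovery_to_4_significant_figures(self):
        truth = AbsorptionLawParams()
        C, L, M = self._dataset(truth)
        fit = fit_absorption_model(C, L, M)
        assert fit.a == pytest.approx(truth.a, rel=1e-4)
        assert fit.b == pytest.approx(truth.b, abs=1e-3)
        assert fit.c == pytest.approx(truth.c, rel=1e-4)

    def test_amplitude_scale_equivariance(self):
        truth = AbsorptionLawParams()
        C, L, M = self._dataset(truth)
        fit = fit_absorption_model(C, L, 2.0 * M)
        assert fit.a == pytest.approx(2 * truth.a, rel=1e-4)
        assert fit.b == pytest.approx(2 * truth.b, abs=2e-3)
        assert fit.c == pytest.approx(truth.c, rel=1e-4)

    def test_width_recovered_within_its_standard_error_under_noise(self, rng):
        """With 2% multiplicative noise the fitted width should land inside
        the +/- 5 nm standard-error band in at least 80% of repeats."""
        truth = AbsorptionLawParams()
        hits = 0
        n_rep = 50
        for _ in range(n_rep):
            C, L, M = self._dataset(truth, noise_cv=0.02, rng=rng)
            fit = fit_absorption_model(C, L, M)
            hits += abs(fit.c - truth.c) <= 5.0
        assert hits / n_rep >= 0.8

    def test_insufficient_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_absorption_model([1.0] * 5, [500, 525, 550, 575, 600],
                                 [0.3] * 5)


class TestScatteringFit:
    def _dataset(self, params, noise_cv=0.0, rng=None):
        concs = [0.25, 0.35, 0.5, 0.65, 1.0]
        lams = np.arange(590.0, 816.0, 25.0)
        C, L, M = [], [], []
        for c in concs:
            mu = reduced_scattering(PhantomComposition(c_tio2=c), lams, params)
            if noise_cv:
                mu = mu * (1.0 + noise_cv * rng.standard_normal(lams.size))
            C.extend([c] * lams.size)
            L.extend(lams)
            M.extend(np.atleast_1d(mu))
        return np.array(C), np.array(L), np.array(M)

    @pytest.mark.parametrize("pooling", ["two-stage", "simultaneous"])
    def test_noiseless_recovery(self, pooling):
        truth = ScatteringLawParams()
        C, L, M = self._dataset(truth)
        fit = fit_scattering_model(C, L, M, pooling=pooling)
        assert fit.a_rm == pytest.approx(0.0, abs=1e-6)
        assert fit.x == pytest.approx(truth.x, rel=1e-3)
        assert fit.y == pytest.approx(truth.y, rel=1e-3)

    def test_pure_rayleigh_input_reaches_equivalent_minimum(self):
        """lambda^-4 data: either the Rayleigh weight goes to 1 or the Mie
        exponent goes to 4 (degenerate but equivalent minima)."""
        lams = np.arange(590.0, 816.0, 25.0)
        concs = [0.25, 0.5, 1.0]
        C = np.repeat(concs, lams.size)
        L = np.tile(lams, len(concs))
        M = C * 9.0 * (L / 1000.0) ** -4.0
        fit = fit_scattering_model(C, L, M)
        assert fit.a_rm > 0.99 or fit.y == pytest.approx(4.0, abs=0.01)

    def test_median_prediction_error_under_7pct_noise(self, rng):
        truth = ScatteringLawParams()
        errors = []
        for _ in range(50):
            C, L, M = self._dataset(truth, noise_cv=0.07, rng=rng)
            fit = fit_scattering_model(C, L, M)
            pred = np.array([
                reduced_scattering(PhantomComposition(c_tio2=c), l, fit)
                for c, l in zip(C, L)])
            true = np.array([
                reduced_scattering(PhantomComposition(c_tio2=c), l, truth)
                for c, l in zip(C, L)])
            errors.append(np.median(np.abs(pred - true) / true))
        assert np.median(errors) <= 0.07


class TestImpedance:
    def test_phantom_endpoint_impedance(self):
        Z, _ = impedance_and_transmission(1018.0, 1493.0)
        assert Z == pytest.approx(1.52, abs=5e-3)

    def test_matched_impedance_transmits_fully(self):
        Z, T = impedance_and_transmission(998.0, 1482.966, Z_ref=998.0 * 1482.966e-6)
        assert T == pytest.approx(1.0)

    def test_printed_transmission_value(self):
        _, T = impedance_and_transmission(1018.0, 1493.0, Z_ref=1.48)
        assert round(T, 3) == 0.987


class TestMonteCarlo:
    def test_zero_width_gives_zero_cv(self):
        cv = montecarlo_uncertainty(lambda v: 3.0 * v, [10.0], n_trials=100,
                                    half_width=0.0, seed=0)
        assert cv == 0.0

    def test_identity_inversion_matches_uniform_closed_form(self):
        # uniform(mu +/- w/2): CV = w / (mu * sqrt(12))
        cv = montecarlo_uncertainty(lambda v: v, [100.0], n_trials=5000,
                                    half_width=5.0, seed=7)
        assert cv == pytest.approx(10.0 / (100.0 * np.sqrt(12.0)), rel=0.05)

    def test_linear_inversion_scale_invariance(self):
        kw = dict(n_trials=2000, half_width=5.0, seed=3)
        cv_id = montecarlo_uncertainty(lambda v: v, [100.0], **kw)
        cv_lin = montecarlo_uncertainty(lambda v: 3.0 * v, [100.0], **kw)
        assert cv_lin == pytest.approx(cv_id, rel=1e-12)

    def test_bit_reproducible_under_fixed_seed(self):
        kw = dict(n_trials=500, half_width=2.0, seed=42)
        a = montecarlo_uncertainty(lambda v: v**2, [10.0, 20.0], **kw)
        b = montecarlo_uncertainty(lambda v: v**2, [10.0, 20.0], **kw)
        assert np.array_equal(a, b)

    def test_zero_mean_output_rejected(self):
        with pytest.raises(ZeroDivisionError):
            montecarlo_uncertainty(lambda v: v - v, [1.0], n_trials=10,
                                   half_width=0.5, seed=0)


class TestCoefficientOfVariation:
    def test_identical_replicates(self):
        assert coefficient_of_variation([5.0, 5.0, 5.0]) == 0.0

    def test_hand_value(self):
        assert coefficient_of_variation([9.0, 10.0, 11.0]) == pytest.approx(0.1)

    def test_scale_invariance(self):
        base = coefficient_of_variation([9.0, 10.0, 11.0])
        assert coefficient_of_variation([90.0, 100.0, 110.0]) \
            == pytest.approx(base)

    def test_group_summary(self):
        mean, sd = cv_summary([[9, 10, 11], [18, 20, 22]])
        assert mean == pytest.approx(0.1)
        assert sd == pytest.approx(0.0, abs=1e-12)
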