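"""Quantum yields, the steady-state light-field model, and screening."""

import numpy as np
import pytest

from lakephotochem import photochem, synthio
from lakephotochem.exceptions import (
    InvalidArgumentError,
    InvalidInputError,
    OutOfRangeError,
    SuspectResultWarning,
)
from lakephotochem.photochem import (
    CompoundKinetics,
    LakeOpticalModel,
    LightField,
    PhotoConstants,
    SECONDS_PER_MONTH,
)


class TestFitFirstOrder:
    def test_exact_exponential(self):
        t = np.linspace(0, 20000, 12)
        fit = photochem.fit_first_order(t, 1e-5 * np.exp(-1e-4 * t))
        assert fit.k_obs == pytest.approx(1e-4, rel=1e-12)

    def test_constant_trace_zero_rate(self):
        t = np.linspace(0, 1000, 6)
        assert photochem.fit_first_order(t, np.full(6, 2e-5)).k_obs == pytest.approx(
            0.0, abs=1e-15
        )

    def test_noisy_recovery_within_3pct(self):
        t = np.linspace(0, 20000, 12)
        ks = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            sigma = np.sqrt(np.log1p(0.02**2))
            c = 1e-5 * np.exp(-1e-4 * t) * np.exp(rng.normal(-sigma**2 / 2, sigma, 12))
            ks.append(photochem.fit_first_order(t, c).k_obs)
        assert np.mean(ks) == pytest.approx(1e-4, rel=0.03)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            photochem.fit_first_order(np.arange(3.0), np.ones(3))
        with pytest.raises(InvalidInputError):
            photochem.fit_first_order(np.arange(4.0), np.array([1.0, 1.0, -1.0, 1.0]))


class TestActinometry:
    def test_pna_quantum_yield_linear_form(self, constants):
        # Phi_PNA = 0.29 * [pyridine] + 0.00029
        assert photochem.pna_quantum_yield(0.01, constants) == pytest.approx(0.00319)

    def test_scale_round_trip(self, solar_field, constants):
        trace = synthio.gen_pna_trace(1.0, 0.005, solar_field, constants=constants)
        s = photochem.actinometry_scale(trace, 0.005, solar_field, constants)
        assert s == pytest.approx(1.0, abs=1e-6)

    def test_doubled_lamp_doubles_scale(self, solar_field, constants):
        trace = synthio.gen_pna_trace(2.0, 0.005, solar_field, constants=constants)
        s = photochem.actinometry_scale(trace, 0.005, solar_field, constants)
        assert s == pytest.approx(2.0, rel=1e-6)

    def test_nonpositive_pyridine_rejected(self, solar_field, constants):
        trace = synthio.gen_pna_trace(1.0, 0.005, solar_field, constants=constants)
        with pytest.raises(InvalidArgumentError):
            photochem.actinometry_scale(trace, 0.0, solar_field, constants)


class TestRateLightAbsorption:
    def test_zero_absorbance_zero_rate(self, solar_field):
        wl = np.arange(250.0, 601.0)
        from lakephotochem.optics import AbsorbanceSpectrum

        spec = AbsorbanceSpectrum(wl, np.zeros_like(wl))
        assert photochem.rate_light_absorption(spec, solar_field) == 0.0

    def test_linearity_in_irradiance(self, solar_field):
        spec = synthio.gen_spectrum(2.0, 0.018)
        r1 = photochem.rate_light_absorption(spec, solar_field, scale=1.0)
        r2 = photochem.rate_light_absorption(spec, solar_field, scale=2.0)
        assert r2 == pytest.approx(2 * r1, rel=1e-12)

    def test_single_wavelength_hand_oracle(self):
        # one nonzero grid point at 400 nm: the trapezoid collapses to one
        # term, z0 * 1 nm, and the rate is z0 * (1 - exp(-a_cm L)) / L * 1000
        from lakephotochem.optics import AbsorbanceSpectrum

        wl = np.arange(290.0, 551.0)
        z = np.zeros_like(wl)
        z0 = 3e-10
        z[wl == 400.0] = z0
        field = LightField(wl, z)
        a_m = 50.0  # 1/m at every wavelength
        spec = AbsorbanceSpectrum(wl, np.full_like(wl, a_m))
        path = 1.1
        expected = z0 * 1.0 * (1 - np.exp(-a_m / 100 * path)) / path * 1000.0
        got = photochem.rate_light_absorption(spec, field, path_cm=path)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_absorbance(self, solar_field):
        lo = photochem.rate_light_absorption(synthio.gen_spectrum(1.0, 0.018), solar_field)
        hi = photochem.rate_light_absorption(synthio.gen_spectrum(2.0, 0.018), solar_field)
        assert hi > lo


class TestApparentQuantumYield:
    def test_steady_state_division(self, constants):
        # k_obs = 1e-5 /s with k_rxn,FFA = 1e8 /M/s -> [1O2]ss,exp = 1e-13 M
        qy = photochem.apparent_quantum_yield(
            1e-5, ra=2e-5 * constants.k_d_delta / 1e8, constants=constants
        )
        assert qy.one_o2_ss_exp == pytest.approx(1e-13, rel=1e-12)
        assert qy.phi_app == pytest.approx(0.5, rel=1e-12)

    def test_generator_round_trip_noise_free(self, constants):
        ra = 1.25e-5
        trace = synthio.gen_kinetics(0.022, ra, "FFA", noise_cv=0.0, constants=constants)
        k = photochem.fit_first_order(trace).k_obs
        qy = photochem.apparent_quantum_yield(k, ra, constants)
        assert qy.phi_app == pytest.approx(0.022, rel=1e-9)

    def test_srnom_normalization_ratio(self, constants):
        ra = 1.25e-5
        k = constants.k_rxn_ffa * 0.024 * ra / constants.k_d_delta
        qy = photochem.apparent_quantum_yield(k, ra, constants, phi_srnom=0.0214)
        assert qy.phi_ratio_srnom == pytest.approx(0.024 / 0.0214, rel=1e-9)
        assert qy.phi_ratio_srnom == pytest.approx(1.12, abs=0.01)

    def test_suspect_yield_warns(self, constants):
        with pytest.warns(SuspectResultWarning):
            photochem.apparent_quantum_yield(1.0, ra=1e-9, constants=constants)


class TestOpticalSubmodels:
    def test_euphotic_depth_unit_cases(self):
        assert photochem.euphotic_depth(1.0) == pytest.approx(4.6 / 0.15 * 100, rel=1e-12)
        assert photochem.euphotic_depth(4.0) == pytest.approx(686.19, abs=0.01)

    def test_euphotic_depth_power_law_homogeneity(self):
        ratio = photochem.euphotic_depth(8.0) / photochem.euphotic_depth(4.0)
        assert ratio == pytest.approx(2 ** -1.08, rel=1e-12)

    def test_kd_direct_evaluation(self):
        assert photochem.kd_lambda(4.0, 440.0) == pytest.approx(
            np.exp(-0.01347 * 440 + 5.36 * 4**0.157), rel=1e-12
        )
        assert photochem.kd_lambda(4.0, 440.0) == pytest.approx(2.089, abs=2e-3)

    @pytest.mark.parametrize("doc", [2.0, 4.0, 10.0])
    def test_kd_monotone_decreasing_in_wavelength(self, doc):
        wl = np.arange(290.0, 551.0)
        kd = photochem.kd_lambda(doc, wl)
        assert np.all(np.diff(kd) < 0)

    @pytest.mark.parametrize("doc", [1.0, 4.0, 12.0])
    def test_kd_wavelength_separability(self, doc):
        ratio = photochem.kd_lambda(doc, 290.0) / photochem.kd_lambda(doc, 550.0)
        assert ratio == pytest.approx(np.exp(-0.01347 * (290 - 550)), rel=1e-12)

    def test_kd_range_check(self):
        with pytest.raises(OutOfRangeError):
            photochem.kd_lambda(4.0, 600.0)


class TestSteadyState:
    def test_zero_quantum_yield_zero_concentrations(self, solar_field):
        lake = LakeOpticalModel.from_doc(4.0, solar_field.wavelengths)
        ss = photochem.steady_state_1o2(0.0, solar_field, lake)
        assert ss.c_euphotic == 0.0 and ss.c_near_surface == 0.0

    def test_depth_average_tends_to_surface_for_thin_layer(self, solar_field):
        lake = LakeOpticalModel.from_doc(4.0, solar_field.wavelengths)
        thin = photochem.LakeOpticalModel(
            doc=4.0, z_euphotic_cm=1e-5, kd_cm=lake.kd_cm,
            wavelengths=lake.wavelengths,
        )
        ss = photochem.steady_state_1o2(0.022, solar_field, thin)
        assert ss.c_euphotic / ss.c_near_surface == pytest.approx(1.0, abs=1e-6)

    def test_depth_average_bounded_by_surface(self, solar_field):
        for doc in (1.0, 4.0, 12.0):
            lake = LakeOpticalModel.from_doc(doc, solar_field.wavelengths)
            ss = photochem.steady_state_1o2(0.022, solar_field, lake)
            assert 0 < ss.c_euphotic <= ss.c_near_surface

    def test_single_wavelength_hand_oracle(self):
        # collapse the sum to one wavelength and check the closed form
        wl = np.arange(290.0, 551.0)
        z = np.zeros_like(wl)
        z0 = 4e-10
        z[wl == 440.0] = z0
        field = LightField(
            wl, z, cf=0.6, f_backscatter=0.02, f_abs_cdom=1.0,
            surface_reflection=0.066, pathlength_factor=1.2,
        )
        kd_cm = np.full_like(wl, 0.02)
        z_eu = 500.0
        lake = photochem.LakeOpticalModel(4.0, z_eu, kd_cm, wl)
        phi, kd_delta = 0.022, 2.76e5
        zcal = z0 * (1 - 0.066) * 1.2
        expected = (
            phi / kd_delta * 0.6
            * zcal * (1 - np.exp(-0.02 * z_eu)) / z_eu * (1 - 0.02) * 1.0 * 1000.0
        )
        ss = photochem.steady_state_1o2(
            phi, field, lake, PhotoConstants(k_d_delta=kd_delta)
        )
        assert ss.c_euphotic == pytest.approx(expected, rel=1e-12)

    def test_linearity_in_quantum_yield(self, solar_field):
        lake = LakeOpticalModel.from_doc(4.0, solar_field.wavelengths)
        c1 = photochem.steady_state_1o2(0.01, solar_field, lake).c_euphotic
        c2 = photochem.steady_state_1o2(0.02, solar_field, lake).c_euphotic
        assert c2 == pytest.approx(2 * c1, rel=1e-12)

    def test_strictly_increasing_in_doc(self, solar_field):
        docs = np.linspace(1.0, 15.0, 29)
        cs = [
            photochem.steady_state_1o2(
                0.022, solar_field, LakeOpticalModel.from_doc(d, solar_field.wavelengths)
            ).c_euphotic
            for d in docs
        ]
        assert np.all(np.diff(cs) > 0)

    def test_epilimnion_variant_uses_supplied_depth(self, solar_field):
        lake = LakeOpticalModel.from_doc(4.0, solar_field.wavelengths)
        ss = photochem.steady_state_1o2(
            0.022, solar_field, lake, epilimnion_depth_cm=lake.z_euphotic_cm / 2
        )
        assert ss.c_epilimnion is not None
        assert ss.c_euphotic < ss.c_epilimnion < ss.c_near_surface


class TestHalfLifeAndScreening:
    def test_seconds_unit_identity(self):
        assert photochem.half_life(np.log(2.0), 1.0, unit="s") == pytest.approx(1.0)

    def test_month_conversion(self):
        t = photochem.half_life(1.8e6, 3.6e-16)
        assert t == pytest.approx(np.log(2) / (1.8e6 * 3.6e-16) / SECONDS_PER_MONTH)

    def test_doubling_concentration_halves_half_life(self):
        assert photochem.half_life(1e6, 2e-15) == pytest.approx(
            photochem.half_life(1e6, 1e-15) / 2
        )

    def test_boundary_classes(self):
        # exact boundaries are assigned to the slower class
        assert photochem.classify_fate(0.0) == photochem.FATE_COMPARABLE
        assert photochem.classify_fate(1.0) == photochem.FATE_SLOWER
        assert photochem.classify_fate(-1e-12) == photochem.FATE_FASTER
        tau_years = 2.0
        c = 1e-15
        # choose k so t_half sits just above tau (t_half = 100 tau -> ratio 2)
        k_eq = np.log(2) / (c * tau_years * 12 * SECONDS_PER_MONTH)
        res = photochem.screen_compounds(
            [CompoundKinetics("x", k_eq)], c, tau_years
        )[0]
        assert res.log10_ratio == pytest.approx(0.0, abs=1e-12)
        res100 = photochem.screen_compounds(
            [CompoundKinetics("y", k_eq / 100)], c, tau_years
        )[0]
        assert res100.log10_ratio == pytest.approx(2.0, abs=1e-12)
        assert res100.fate_class == photochem.FATE_SLOWER

    def test_class_counts_equal_enumeration(self):
        compounds = synthio.gen_compounds(106, seed=3)
        c, tau = 2e-15, 1.5
        results = photochem.screen_compounds(compounds, c, tau)
        # independent enumeration of the classification
        expected = {"faster_than_flushing": 0, "comparable": 0, "slower": 0}
        for cmp_ in compounds:
            t_half = np.log(2) / (cmp_.k_rxn * c) / SECONDS_PER_MONTH
            lr = np.log10(t_half / (tau * 12))
            if lr < 0:
                expected["faster_than_flushing"] += 1
            elif lr < 1:
                expected["comparable"] += 1
            else:
                expected["slower"] += 1
        got = {k: sum(r.fate_class == k for r in results) for k in expected}
        assert got == expected
        assert all(
            r.fate_class == photochem.classify_fate(r.log10_ratio) for r in results
        )

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            photochem.half_life(0.0, 1e-15)
        with pytest.raises(InvalidArgumentError):
            photochem.screen_compounds([], 1e-15, 0.0)
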