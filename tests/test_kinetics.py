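"""Kinetic model fitting and physical conversions."""

import math

import numpy as np
import pytest

from svdecon.kinetics import (
    BiExpModel,
    DampedSinusoidModel,
    SingleExpModel,
    SPEED_OF_LIGHT_CM_S,
    acoustic_wavelength,
    fit_biexp,
    fit_biexp_joint,
    fit_damped_sinusoid_joint,
    fit_single_exp,
    size_ratio_from_masses,
    wavenumber_to_period,
    wavenumber_to_thz,
)


class TestSingleExp:
    def test_exact_recovery_noise_free(self):
        t = np.linspace(0.0, 180.0, 45)
        truth = SingleExpModel(b=0.274, a=0.588, tau=58.0)
        fit = fit_single_exp(t, truth(t))
        assert np.isclose(fit.model.tau, 58.0, rtol=1e-6)
        assert np.isclose(fit.model.a, 0.588, rtol=1e-6)
        assert np.isclose(fit.model.b, 0.274, rtol=1e-6)
        assert fit.rss < 1e-12

    def test_recovery_under_noise(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0.0, 180.0, 45)
        truth = SingleExpModel(b=0.274, a=0.588, tau=58.0)
        f = truth(t) + rng.normal(0.0, 0.005, size=t.size)
        fit = fit_single_exp(t, f)
        assert np.isclose(fit.model.tau, 58.0, rtol=0.1)
        assert fit.stderr and fit.stderr["tau"] > 0

    def test_decay_form_equivalence(self):
        m = SingleExpModel(b=0.2, a=0.8, tau=3.0)
        a_dec, b_dec = m.decay_params()
        t = np.linspace(0, 10, 30)
        assert np.allclose(m(t), b_dec + a_dec * np.exp(-t / m.tau), atol=1e-14)

    def test_constant_input_flagged(self):
        t = np.linspace(0.0, 10.0, 20)
        fit = fit_single_exp(t, np.full(20, 3.7))
        assert "tau_unidentifiable_constant_input" in fit.flags
        assert math.isnan(fit.model.tau)
        assert np.isclose(fit.model.b, 3.7)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            fit_single_exp([0.0, 1.0, 2.0], [1.0, 2.0, 3.0])  # too few
        with pytest.raises(ValueError):
            fit_single_exp([0.0, 2.0, 1.0, 3.0], [1.0, 2.0, 3.0, 4.0])  # not increasing

    def test_deterministic_rerun(self):
        rng = np.random.default_rng(2)
        t = np.linspace(0.0, 5.0, 25)
        f = SingleExpModel(0.1, 1.0, 0.9)(t) + rng.normal(0, 0.01, 25)
        f1 = fit_single_exp(t, f)
        f2 = fit_single_exp(t, f.copy())
        assert f1.model.tau == f2.model.tau
        assert f1.rss == f2.rss


class TestBiExp:
    def test_exact_recovery_noise_free(self):
        t = np.linspace(0.0, 20.0, 200)
        truth = BiExpModel(b=0.05, a1=0.7, tau1=0.4, a2=0.4, tau2=9.0)
        fit = fit_biexp(t, truth(t))
        assert np.isclose(fit.model.tau1, 0.4, rtol=1e-4)
        assert np.isclose(fit.model.tau2, 9.0, rtol=1e-4)

    def test_recovery_within_one_percent_small_noise(self):
        rng = np.random.default_rng(21)
        t = np.linspace(0.0, 20.0, 200)
        truth = BiExpModel(b=0.0, a1=0.7, tau1=0.4, a2=0.4, tau2=9.0)
        f = truth(t) + rng.normal(0.0, 1e-4, size=t.size)
        fit = fit_biexp(t, f)
        assert np.isclose(fit.model.tau1, 0.4, rtol=0.01)
        assert np.isclose(fit.model.tau2, 9.0, rtol=0.01)

    def test_tau_ordering_enforced(self):
        t = np.linspace(0.0, 20.0, 120)
        f = BiExpModel(0.0, 0.5, 0.3, 0.5, 6.0)(t)
        fit = fit_biexp(t, f)
        assert fit.model.tau1 < fit.model.tau2

    def test_single_phase_input_collapses(self):
        t = np.linspace(0.0, 20.0, 100)
        f = SingleExpModel(b=0.1, a=1.0, tau=2.0)(t)
        fit = fit_biexp(t, f)
        # degenerate second phase: tiny amplitude, or near-equal taus (flagged)
        a1, a2 = fit.model.a1, fit.model.a2
        small = min(abs(a1), abs(a2))
        assert (small < 1e-3 * max(abs(a1), abs(a2))
                or "time_constants_poorly_separated" in fit.flags)
        # and the dominant time constant is right
        dom_tau = fit.model.tau1 if abs(a1) >= abs(a2) else fit.model.tau2
        assert np.isclose(dom_tau, 2.0, rtol=0.05)

    def test_joint_fit_shares_time_constants(self):
        rng = np.random.default_rng(51)
        t = np.linspace(0.0, 20.0, 200)
        rows = np.vstack([
            BiExpModel(b=0.0, a1=0.8, tau1=0.4, a2=0.1, tau2=9.0)(t),
            BiExpModel(b=0.1, a1=-0.2, tau1=0.4, a2=0.9, tau2=9.0)(t),
            BiExpModel(b=0.0, a1=0.3, tau1=0.4, a2=0.5, tau2=9.0)(t),
        ]) + rng.normal(0.0, 1e-3, size=(3, 200))
        fits = fit_biexp_joint(t, rows)
        taus = {(f.model.tau1, f.model.tau2) for f in fits}
        assert len(taus) == 1  # shared across rows
        assert np.isclose(fits[0].model.tau1, 0.4, rtol=0.02)
        assert np.isclose(fits[0].model.tau2, 9.0, rtol=0.02)
        # per-row amplitudes differ
        assert not np.isclose(fits[0].model.a1, fits[1].model.a1, rtol=0.1)

    def test_model_comparison_prefers_biexp_for_biphasic_data(self):
        rng = np.random.default_rng(31)
        t = np.linspace(0.0, 20.0, 200)
        truth = BiExpModel(b=0.0, a1=0.6, tau1=0.4, a2=0.5, tau2=9.0)
        f = truth(t) + rng.normal(0.0, 1e-3, size=t.size)
        rss1 = fit_single_exp(t, f).rss
        rss2 = fit_biexp(t, f).rss
        assert rss1 / rss2 > 10.0


class TestDampedSinusoidJoint:
    def _truth_rows(self, t, omega=11.49, tau=0.9, eps=1.0):
        env = np.exp(-np.power(t / tau, eps))
        r1 = 1.0 * np.cos(omega * t) * env
        r2 = 0.8 * np.sin(omega * t) * env
        return np.vstack([r1, r2])

    def test_shared_frequency_recovery(self):
        t = np.linspace(0.0, 1.1, 40)
        rows = self._truth_rows(t)
        fits = fit_damped_sinusoid_joint(t, rows, fix_epsilon=1.0)
        for fit in fits:
            assert np.isclose(fit.model.omega, 11.49, rtol=1e-3)
            assert np.isclose(fit.model.tau, 0.9, rtol=0.02)
        # quadrature pair: phases differ by ~90 deg
        dphase = abs(fits[0].model.alpha - fits[1].model.alpha)
        assert np.isclose(dphase % math.pi, math.pi / 2, atol=0.02)

    def test_recovery_under_noise(self):
        rng = np.random.default_rng(41)
        t = np.linspace(0.0, 1.1, 40)
        rows = self._truth_rows(t) + rng.normal(0.0, 0.01, size=(2, 40))
        fits = fit_damped_sinusoid_joint(t, rows, fix_epsilon=1.0)
        assert np.isclose(fits[0].model.omega, 11.49, rtol=0.02)

    def test_zero_rows_flagged(self):
        t = np.linspace(0.0, 1.0, 16)
        fits = fit_damped_sinusoid_joint(t, np.zeros((2, 16)))
        assert all("zero_amplitude_rows" in f.flags for f in fits)

    def test_free_epsilon_not_much_worse_than_true_fixed(self):
        t = np.linspace(0.0, 1.1, 40)
        rows = self._truth_rows(t, eps=1.0)
        rss_fixed = sum(f.rss for f in fit_damped_sinusoid_joint(t, rows, fix_epsilon=1.0))
        rss_free = sum(f.rss for f in fit_damped_sinusoid_joint(t, rows))
        assert rss_free <= max(rss_fixed, 1e-12) * 1.05 + 1e-12

    def test_low_frequency_flagged(self):
        t = np.linspace(0.0, 1.0, 20)
        # less than one period inside the window
        rows = np.cos(2.0 * t)[None, :]
        fits = fit_damped_sinusoid_joint(t, rows)
        assert any("frequency_unidentifiable" in fl for f in fits for fl in f.flags)


class TestConversions:
    def test_period_values(self):
        # printed values for the oscillations this analysis interprets
        assert np.isclose(wavenumber_to_period(40.0), 0.83, atol=0.005)
        assert np.isclose(wavenumber_to_period(44.0), 0.76, atol=0.005)
        assert np.isclose(wavenumber_to_period(25.0), 1.33, atol=0.005)

    def test_frequency_values(self):
        assert np.isclose(wavenumber_to_thz(40.0), 1.2, atol=0.01)
        assert np.isclose(wavenumber_to_thz(60.0), 1.8, atol=0.01)

    def test_period_frequency_reciprocal(self):
        for nu in (25.0, 40.0, 44.0, 61.0):
            assert np.isclose(wavenumber_to_period(nu) * wavenumber_to_thz(nu), 1.0,
                              rtol=1e-12)

    def test_period_ratios(self):
        # period is reciprocal in wavenumber, so the ratio inverts
        assert np.isclose(wavenumber_to_period(40.0) / wavenumber_to_period(44.0),
                          44.0 / 40.0, rtol=1e-12)
        assert np.isclose(wavenumber_to_period(40.0) / wavenumber_to_period(25.0),
                          25.0 / 40.0, rtol=1e-12)

    def test_acoustic_wavelength(self):
        # 2 km/s sound velocity at 40 cm^-1: lambda ~ 16.7 A, standing wave ~ 33 A
        lam = acoustic_wavelength(2.0, 40.0)
        assert np.isclose(lam, 2.0e5 / (SPEED_OF_LIGHT_CM_S * 40.0) * 1e8, rtol=1e-12)
        assert np.isclose(acoustic_wavelength(2.0, 40.0, standing_wave=True), 2 * lam,
                          rtol=1e-12)
        # linear in velocity, reciprocal in wavenumber
        assert np.isclose(acoustic_wavelength(4.0, 40.0), 2 * lam, rtol=1e-12)
        assert np.isclose(acoustic_wavelength(2.0, 80.0), lam / 2, rtol=1e-12)

    def test_size_ratio_cube_root(self):
        r = size_ratio_from_masses([50.0, 400.0])
        assert np.isclose(r[1], 2.0, rtol=1e-12)
        assert r[0] == 1.0

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            wavenumber_to_period(0.0)
        with pytest.raises(ValueError):
            wavenumber_to_thz(-5.0)
        with pytest.raises(ValueError):
            acoustic_wavelength(0.0, 40.0)
        with pytest.raises(ValueError):
            size_ratio_from_masses([10.0, -1.0])
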