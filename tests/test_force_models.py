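"""Unit and property tests for WLC elasticity and Bell-Evans kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from a2mech import (
    BellEvansParams,
    WLCParams,
    bell_rate,
    crossover_force,
    evans_ritchie_force,
    fit_bell_evans,
    fit_wlc,
    stability_profile,
    wlc_extension,
    wlc_force,
)
from a2mech.errors import (
    DegenerateParametersError,
    DomainError,
    InputError,
)

KBT = 4.114


class TestWLCForward:
    def test_zero_extension_gives_zero_force(self, no_cfh_wlc):
        assert wlc_force(0.0, no_cfh_wlc) == 0.0

    def test_half_contour_evaluation(self):
        # x/Lc = 0.5: bracket = 1 - 0.25 + 0.5 = 1.25, prefactor kBT/Lp
        params = WLCParams(40.0, 0.38)
        assert wlc_force(20.0, params) == pytest.approx(13.53, abs=0.005)

    def test_hookean_limit(self, no_cfh_wlc):
        # F ~ 3 kBT x / (2 Lp Lc) for tiny fractional extension
        x = 1e-4 * no_cfh_wlc.contour_length
        hooke = (
            3.0
            * no_cfh_wlc.kBT
            * x
            / (2.0 * no_cfh_wlc.persistence_length * no_cfh_wlc.contour_length)
        )
        assert wlc_force(x, no_cfh_wlc) == pytest.approx(hooke, rel=0.01)

    @pytest.mark.parametrize("bad_x", [-1.0, 55.3, 60.0])
    def test_domain_errors(self, no_cfh_wlc, bad_x):
        with pytest.raises(DomainError):
            wlc_force(bad_x, no_cfh_wlc)

    def test_strictly_monotone(self, no_cfh_wlc):
        x = np.linspace(0.0, 0.999 * no_cfh_wlc.contour_length, 500)
        f = wlc_force(x, no_cfh_wlc)
        assert np.all(np.diff(f) > 0)

    def test_divergence_near_contour_length(self, no_cfh_wlc):
        assert wlc_force(0.999999 * no_cfh_wlc.contour_length, no_cfh_wlc) > 1e6


class TestWLCInverse:
    def test_zero_force(self, no_cfh_wlc):
        assert wlc_extension(0.0, no_cfh_wlc) == 0.0

    def test_inverse_of_forward_example(self):
        params = WLCParams(40.0, 0.38)
        x = wlc_extension(wlc_force(20.0, params), params)
        assert x == pytest.approx(20.0, abs=1e-9)

    def test_negative_force_rejected(self, no_cfh_wlc):
        with pytest.raises(DomainError):
            wlc_extension(-1.0, no_cfh_wlc)

    def test_round_trip_on_grid(self, no_cfh_wlc):
        x = np.linspace(0.0, 0.99 * no_cfh_wlc.contour_length, 100)
        back = wlc_extension(wlc_force(x, no_cfh_wlc), no_cfh_wlc)
        assert np.max(np.abs(back - x)) < 1e-9 * no_cfh_wlc.contour_length

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        frac=st.floats(0.0, 0.98),
        lc=st.floats(10.0, 100.0),
        lp=st.floats(0.1, 2.0),
    )
    def test_round_trip_property(self, frac, lc, lp):
        params = WLCParams(lc, lp)
        x = frac * lc
        assert wlc_extension(wlc_force(x, params), params) == pytest.approx(
            x, abs=1e-9 * lc
        )


class TestFitWLC:
    def _clean_data(self, params, n=30, fmax=20.0):
        f = np.linspace(1.0, fmax, n)
        return f, wlc_extension(f, params)

    @pytest.mark.parametrize("objective", ["force", "extension"])
    def test_exact_recovery_on_clean_data(self, no_cfh_wlc, objective):
        f, x = self._clean_data(no_cfh_wlc)
        fit = fit_wlc(f, x, objective=objective)
        assert fit.params.contour_length == pytest.approx(55.3, rel=1e-6)
        assert fit.params.persistence_length == pytest.approx(0.28, rel=1e-6)

    def test_fixed_lp_closed_form_exact(self, no_cfh_wlc):
        f, x = self._clean_data(no_cfh_wlc)
        fit = fit_wlc(f, x, objective="extension", fix_Lp=0.28)
        assert fit.params.contour_length == pytest.approx(55.3, rel=1e-9)

    def test_noisy_recovery_within_a_few_percent(self, no_cfh_wlc):
        rng = np.random.default_rng(2)
        f = np.linspace(2.0, 20.0, 50)
        x = wlc_extension(f, no_cfh_wlc) * (1.0 + rng.normal(0.0, 0.02, 50))
        fit = fit_wlc(f, x)
        assert fit.params.contour_length == pytest.approx(55.3, rel=0.05)

    def test_under_determined_input_rejected(self):
        with pytest.raises(InputError):
            fit_wlc([1.0, 2.0], [5.0, 10.0])

    def test_reports_standard_errors(self, no_cfh_wlc):
        rng = np.random.default_rng(3)
        f = np.linspace(2.0, 20.0, 40)
        x = wlc_extension(f, no_cfh_wlc) + rng.normal(0.0, 0.3, 40)
        fit = fit_wlc(f, x, objective="extension")
        assert fit.stderr["contour_length_nm"] > 0
        assert fit.n_points == 40


class TestBellRate:
    def test_zero_force_returns_k0(self, no_cfh_kinetics):
        assert bell_rate(0.0, no_cfh_kinetics) == pytest.approx(0.15)

    def test_one_thermal_unit_of_force(self, no_cfh_kinetics):
        # gamma * F = kBT => rate = k0 * e
        force = KBT / 0.71
        assert bell_rate(force, no_cfh_kinetics) == pytest.approx(
            0.15 * math.e, rel=1e-12
        )

    def test_force_insensitive_when_gamma_zero(self):
        params = BellEvansParams(k0=0.2, gamma=0.0)
        f = np.linspace(0, 50, 11)
        assert np.allclose(bell_rate(f, params), 0.2)

    def test_monotone_in_force(self, wt_cfh_kinetics):
        f = np.linspace(0, 30, 100)
        assert np.all(np.diff(bell_rate(f, wt_cfh_kinetics)) > 0)


class TestEvansRitchie:
    def test_reference_rate(self, no_cfh_kinetics):
        fstar = evans_ritchie_force(10.0, no_cfh_kinetics)
        assert fstar == pytest.approx(14.15, abs=0.01)
        assert 8.0 < fstar < 20.0  # inside the observed rupture band

    def test_zero_at_threshold_rate(self, no_cfh_kinetics):
        r0 = no_cfh_kinetics.k0 * KBT / no_cfh_kinetics.gamma
        with pytest.warns(UserWarning):
            assert evans_ritchie_force(r0, no_cfh_kinetics) == 0.0

    def test_clamped_below_threshold(self, no_cfh_kinetics):
        with pytest.warns(UserWarning):
            assert evans_ritchie_force(1e-3, no_cfh_kinetics) == 0.0

    def test_affine_in_log_rate(self, no_cfh_kinetics):
        # slope of F* against ln r is kBT / gamma
        rates = np.array([5.0, 10.0, 20.0])
        fstars = evans_ritchie_force(rates, no_cfh_kinetics)
        increments = np.diff(fstars)
        expected = KBT * math.log(2.0) / 0.71
        assert np.allclose(increments, expected, atol=1e-9)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(DomainError):
            evans_ritchie_force(10.0, BellEvansParams(k0=0.15, gamma=0.0))


class TestFitBellEvans:
    def test_exact_recovery_on_clean_data(self, no_cfh_kinetics):
        rates = np.array([1.0, 3.0, 10.0, 30.0, 100.0])
        fstars = evans_ritchie_force(rates, no_cfh_kinetics)
        fit = fit_bell_evans(rates, fstars)
        assert fit.params.k0 == pytest.approx(0.15, rel=1e-6)
        assert fit.params.gamma == pytest.approx(0.71, rel=1e-6)

    def test_two_points_determine_the_line(self, wt_cfh_kinetics):
        rates = np.array([5.0, 50.0])
        fstars = evans_ritchie_force(rates, wt_cfh_kinetics)
        fit = fit_bell_evans(rates, fstars)
        assert fit.params.k0 == pytest.approx(0.017, rel=1e-6)
        assert fit.params.gamma == pytest.approx(1.88, rel=1e-6)

    def test_linear_and_nls_agree_on_clean_data(self, no_cfh_kinetics):
        rates = np.array([2.0, 8.0, 25.0, 80.0])
        fstars = evans_ritchie_force(rates, no_cfh_kinetics)
        nls = fit_bell_evans(rates, fstars, method="nls")
        lin = fit_bell_evans(rates, fstars, method="linear")
        assert nls.params.k0 == pytest.approx(lin.params.k0, rel=1e-6)
        assert nls.params.gamma == pytest.approx(lin.params.gamma, rel=1e-6)

    def test_identical_rates_rejected(self):
        with pytest.raises(InputError):
            fit_bell_evans([10.0, 10.0, 10.0], [14.0, 14.2, 14.1])


class TestCrossover:
    def test_wild_type_crossover_near_8pN(self, no_cfh_kinetics, wt_cfh_kinetics):
        fx = crossover_force(no_cfh_kinetics, wt_cfh_kinetics)
        assert fx == pytest.approx(7.66, abs=0.005)

    def test_mutant_crossover(self, no_cfh_kinetics, mutant_cfh_kinetics):
        fx = crossover_force(no_cfh_kinetics, mutant_cfh_kinetics)
        assert fx == pytest.approx(9.11, abs=0.005)

    def test_rates_equal_at_crossover(self, no_cfh_kinetics, wt_cfh_kinetics):
        fx = crossover_force(no_cfh_kinetics, wt_cfh_kinetics)
        ra = bell_rate(fx, no_cfh_kinetics)
        rb = bell_rate(fx, wt_cfh_kinetics)
        assert ra == pytest.approx(rb, rel=1e-12)

    def test_symmetric_in_arguments(self, no_cfh_kinetics, wt_cfh_kinetics):
        assert crossover_force(no_cfh_kinetics, wt_cfh_kinetics) == pytest.approx(
            crossover_force(wt_cfh_kinetics, no_cfh_kinetics), rel=1e-12
        )

    def test_identical_parameters_degenerate(self, no_cfh_kinetics):
        with pytest.raises(DegenerateParametersError):
            crossover_force(no_cfh_kinetics, no_cfh_kinetics)

    def test_mismatched_thermal_energy_rejected(self, no_cfh_kinetics):
        other = BellEvansParams(k0=0.017, gamma=1.88, kBT=4.2)
        with pytest.raises(InputError):
            crossover_force(no_cfh_kinetics, other)


class TestStabilityProfile:
    def test_stabilized_at_zero_force(self, no_cfh_kinetics, wt_cfh_kinetics):
        ratio = stability_profile([0.0], no_cfh_kinetics, wt_cfh_kinetics)
        assert ratio[0] == pytest.approx(0.017 / 0.15, rel=1e-12)
        assert ratio[0] < 1.0

    def test_unity_at_crossover(self, no_cfh_kinetics, wt_cfh_kinetics):
        fx = crossover_force(no_cfh_kinetics, wt_cfh_kinetics)
        ratio = stability_profile([fx], no_cfh_kinetics, wt_cfh_kinetics)
        assert ratio[0] == pytest.approx(1.0, rel=1e-12)

    def test_destabilized_above_crossover(self, no_cfh_kinetics, wt_cfh_kinetics):
        ratio = stability_profile([15.0], no_cfh_kinetics, wt_cfh_kinetics)
        assert ratio[0] > 1.0

    def test_empty_grid_rejected(self, no_cfh_kinetics, wt_cfh_kinetics):
        with pytest.raises(InputError):
            stability_profile([], no_cfh_kinetics, wt_cfh_kinetics)


class TestParameterInvariants:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"contour_length": -1.0, "persistence_length": 0.3},
            {"contour_length": 50.0, "persistence_length": 0.0},
            {"contour_length": 50.0, "persistence_length": 0.3, "kBT": -4.0},
        ],
    )
    def test_wlc_params_validated(self, kwargs):
        with pytest.raises(DomainError):
            WLCParams(**kwargs)

    def test_bell_params_validated(self):
        with pytest.raises(DomainError):
            BellEvansParams(k0=-0.1, gamma=0.7)
        with pytest.raises(DomainError):
            BellEvansParams(k0=0.1, gamma=-0.7)
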