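"""Tests for event detection and rupture statistics."""

import math

import numpy as np
import pytest

from a2mech import (
    BellEvansParams,
    PullingProtocol,
    PullingTrace,
    UnfoldingPathway,
    detect_unfolding_events,
    estimate_loading_rate,
    evans_ritchie_force,
    force_histogram,
    most_probable_force,
    simulate_experiment,
    simulate_rupture_forces,
    simulate_trace,
    summarize_extensions,
    wlc_fractional_extension,
)
from a2mech.errors import FitError, InputError


def _plain_ramp(rate=10.0, dt=0.002, fmax=25.0, trace_id="ramp"):
    t = np.arange(0.0, fmax / rate, dt)
    return PullingTrace(
        trace_id=trace_id,
        time=t,
        force=rate * t,
        extension=2.0 * rate * t,
        loading_rate=rate,
    )


class TestDetection:
    def test_noiseless_single_event_matches_ground_truth(self):
        pathway = UnfoldingPathway.single_step()
        protocol = PullingProtocol(
            loading_rate=10.0, noise_sd_force=0.0, noise_sd_extension=0.0
        )
        trace = simulate_trace(pathway, protocol, seed=3)
        events = detect_unfolding_events(trace)
        assert len(events) == 1
        truth = trace.ground_truth_events[0]
        # rupture force is the last pre-drop sample: within one ramp step
        step = protocol.loading_rate * protocol.sampling_interval
        assert abs(events[0].rupture_force - truth.force) <= step + 1e-9
        jump = truth.delta_Lc * wlc_fractional_extension(truth.force, 0.28)
        assert events[0].extension_gain == pytest.approx(jump, abs=0.2)

    def test_two_step_trace_yields_two_events(self):
        pathway = UnfoldingPathway.two_step()
        protocol = PullingProtocol(
            loading_rate=20.0, noise_sd_force=0.0, noise_sd_extension=0.0
        )
        trace = simulate_trace(pathway, protocol, seed=8)
        assert len(trace.ground_truth_events) == 2
        events = detect_unfolding_events(trace)
        assert len(events) == 2
        assert events[0].time < events[1].time

    def test_smooth_ramp_has_no_events(self):
        assert detect_unfolding_events(_plain_ramp()) == []

    def test_bad_thresholds_rejected(self):
        with pytest.raises(InputError):
            detect_unfolding_events(_plain_ramp(), min_force_drop=0.0)
        with pytest.raises(InputError):
            detect_unfolding_events(_plain_ramp(), min_extension_gain=-1.0)

    def test_perfect_recall_and_precision_at_low_noise(self):
        # noise SD at 1/4 of the force-drop threshold: detection should be
        # exact on a high-force pathway where every jump clears the gain bar
        pathway = UnfoldingPathway.single_step(k0=0.02)
        protocol = PullingProtocol(
            loading_rate=30.0,
            noise_sd_force=0.25,
            noise_sd_extension=1.0,
            max_force=40.0,
        )
        result = simulate_experiment(
            pathway, [30.0], 50, seed=21, protocol=protocol
        )
        n_detected = n_truth = 0
        for trace in result.traces:
            events = detect_unfolding_events(trace)
            n_detected += len(events)
            n_truth += len(trace.ground_truth_events)
            assert len(events) <= len(trace.ground_truth_events)
        assert n_detected == n_truth

    def test_events_bounded_by_pathway_transitions(self):
        pathway = UnfoldingPathway.two_step()
        result = simulate_experiment(pathway, [20.0], 30, seed=5)
        for trace in result.traces:
            assert len(detect_unfolding_events(trace)) <= 2


class TestMostProbableForce:
    def test_single_value_bin_center(self):
        force, half = most_probable_force([12.0, 12.0, 12.0], bin_width=1.0)
        assert force == pytest.approx(12.5)
        assert half == pytest.approx(0.5)

    def test_matches_analytic_mode_at_large_n(self, no_cfh_kinetics):
        forces = simulate_rupture_forces(no_cfh_kinetics, 10.0, 10_000, seed=4)
        mode, _ = most_probable_force(forces, bin_width=1.0)
        assert abs(mode - evans_ritchie_force(10.0, no_cfh_kinetics)) <= 1.0

    def test_tie_broken_toward_lower_force(self):
        # two equally tall bins: [5,6) and [9,10)
        forces = [5.2, 5.7, 9.1, 9.8]
        mode, _ = most_probable_force(forces, bin_width=1.0)
        assert mode == pytest.approx(5.5)

    def test_invariant_to_event_ordering(self, no_cfh_kinetics):
        forces = simulate_rupture_forces(no_cfh_kinetics, 10.0, 500, seed=6)
        a = most_probable_force(forces, 1.0)
        b = most_probable_force(forces[::-1], 1.0)
        assert a == b

    def test_small_origin_shift_moves_mode_at_most_one_bin(self, no_cfh_kinetics):
        forces = simulate_rupture_forces(no_cfh_kinetics, 10.0, 500, seed=8)
        a, _ = most_probable_force(forces, 1.0)
        b, _ = most_probable_force(forces + 0.05, 1.0)  # shift < bin/10
        assert abs(a - b) <= 1.0

    def test_empty_events_rejected(self):
        with pytest.raises(InputError):
            most_probable_force([], 1.0)

    def test_histogram_structure(self):
        hist = force_histogram([8.2, 9.3, 9.7, 14.1], bin_width=1.0)
        assert hist.counts.sum() == 4
        widths = np.diff(hist.bin_edges)
        assert np.allclose(widths, 1.0)


class TestSummarizeExtensions:
    def test_gaussian_summary_recovers_mean_and_hwhm(self):
        rng = np.random.default_rng(12)
        gains = rng.normal(40.0, 4.0, 500)
        summary = summarize_extensions(gains)
        assert summary.gaussian_mean == pytest.approx(40.0, abs=0.5)
        expected_hwhm = 4.0 * math.sqrt(2.0 * math.log(2.0))  # ~4.71
        assert summary.half_width_half_max == pytest.approx(expected_hwhm, rel=0.1)
        assert summary.n_events == 500

    def test_identical_values_degenerate(self):
        with pytest.raises(FitError):
            summarize_extensions([10.0, 10.0, 10.0])

    def test_too_few_events_rejected(self):
        with pytest.raises(InputError):
            summarize_extensions([10.0, 11.0])

    def test_high_force_gains_reach_the_long_extension_band(self):
        # when ruptures occur at forces where the fractional extension
        # exceeds 0.54, a 55.3 nm contour gain shows as a 30-50 nm jump
        forces = np.linspace(22.0, 35.0, 20)
        xi = wlc_fractional_extension(forces, 0.28)
        assert np.all(xi > 0.54)
        gains = 55.3 * xi
        assert np.all((gains > 30.0) & (gains < 50.0))


class TestLoadingRateEstimate:
    def _trace_with_event(self, noise_sd=0.0, seed=0):
        pathway = UnfoldingPathway.single_step()
        protocol = PullingProtocol(
            loading_rate=10.0,
            noise_sd_force=noise_sd,
            noise_sd_extension=0.0,
        )
        trace = simulate_trace(pathway, protocol, seed=seed)
        events = detect_unfolding_events(trace, min_extension_gain=1.0)
        return trace, events[0]

    def test_noiseless_ramp_recovers_nominal_rate(self):
        trace, event = self._trace_with_event()
        assert estimate_loading_rate(trace, event) == pytest.approx(10.0, rel=1e-6)

    def test_noisy_ramp_within_five_percent(self):
        trace, event = self._trace_with_event(noise_sd=0.3, seed=14)
        assert estimate_loading_rate(trace, event) == pytest.approx(10.0, rel=0.05)

    def test_short_window_falls_back_to_nominal(self):
        trace, event = self._trace_with_event()
        with pytest.warns(UserWarning):
            rate = estimate_loading_rate(
                trace, event, ramp_start_time=event.time - 0.005
            )
        assert rate == pytest.approx(10.0)
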