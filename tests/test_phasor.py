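"""Phasor estimation, tracking error, effort/error circle, scaling."""

import numpy as np
import pytest

from vmtrack.phasor import (
    AnalysisConfig,
    FrequencyResponse,
    circle_position,
    circular_mean_lag,
    estimate_frequency_response,
    fit_scaling_factor,
    phase_lag_vectors,
    tracking_error,
)
from vmtrack.simulate import CONTROL_TEMPLATE, PATIENT_TEMPLATE, LoopConfig, TrialRecord, closed_loop_fr


def _trial_from(traj, response, mask=None):
    return TrialRecord(
        time=traj.time.copy(),
        target=traj.angle.copy(),
        elbow=np.asarray(response, float),
        cursor=np.asarray(response, float),
        mask=mask,
    )


class TestEstimator:
    def test_identity_response_gives_unit_phasors(self, short_trajectory, short_spec):
        trial = _trial_from(short_trajectory, short_trajectory.angle)
        fr = estimate_frequency_response([trial], short_spec.frequencies)
        np.testing.assert_allclose(fr.phasors, 1.0 + 0.0j, atol=1e-9)

    def test_pure_delay_theorem(self, short_trajectory, short_spec):
        tau = 0.1
        delayed = short_trajectory.evaluate(short_trajectory.time - tau)
        trial = _trial_from(short_trajectory, delayed)
        fr = estimate_frequency_response([trial], short_spec.frequencies)
        np.testing.assert_allclose(fr.gain, 1.0, atol=1e-9)
        np.testing.assert_allclose(
            fr.phase_lag_deg, 360.0 * short_spec.frequencies * tau % 360.0, atol=1e-6
        )

    def test_invariant_to_added_linear_trend(self, short_trajectory, short_spec):
        base = short_trajectory.evaluate(short_trajectory.time - 0.05)
        trend = 0.5 + 0.03 * short_trajectory.time
        fr0 = estimate_frequency_response(
            [_trial_from(short_trajectory, base)], short_spec.frequencies
        )
        fr1 = estimate_frequency_response(
            [_trial_from(short_trajectory, base + trend)], short_spec.frequencies
        )
        np.testing.assert_allclose(fr0.phasors, fr1.phasors, atol=1e-9)

    def test_masked_samples_fall_back_to_other_trials(
        self, short_trajectory, short_spec
    ):
        clean = short_trajectory.evaluate(short_trajectory.time - 0.08)
        corrupted = clean.copy()
        n = len(clean)
        bad = slice(int(0.6 * n), int(0.65 * n))
        corrupted[bad] = 40.0  # a cough, say
        mask = np.ones(n, bool)
        mask[bad] = False
        fr = estimate_frequency_response(
            [
                _trial_from(short_trajectory, clean),
                _trial_from(short_trajectory, corrupted, mask=mask),
            ],
            short_spec.frequencies,
        )
        ref = estimate_frequency_response(
            [_trial_from(short_trajectory, clean)], short_spec.frequencies
        )
        np.testing.assert_allclose(fr.phasors, ref.phasors, atol=1e-9)

    def test_fully_masked_samples_are_interpolated(self, short_trajectory, short_spec):
        clean = short_trajectory.evaluate(short_trajectory.time - 0.08)
        corrupted = clean.copy()
        n = len(clean)
        bad = slice(int(0.62 * n), int(0.625 * n))  # 200 ms gap
        corrupted[bad] = 40.0
        mask = np.ones(n, bool)
        mask[bad] = False
        fr = estimate_frequency_response(
            [_trial_from(short_trajectory, corrupted, mask=mask)],
            short_spec.frequencies,
        )
        ref = estimate_frequency_response(
            [_trial_from(short_trajectory, clean)], short_spec.frequencies
        )
        assert np.abs(fr.phasors - ref.phasors).max() < 0.05

    def test_all_masked_window_errors(self, short_trajectory, short_spec):
        n = len(short_trajectory.time)
        trial = _trial_from(
            short_trajectory, short_trajectory.angle, mask=np.zeros(n, bool)
        )
        with pytest.raises(ValueError, match="masked"):
            estimate_frequency_response([trial], short_spec.frequencies)

    def test_off_bin_frequency_named_in_error(self, short_trajectory):
        trial = _trial_from(short_trajectory, short_trajectory.angle)
        with pytest.raises(ValueError, match="0.512"):
            estimate_frequency_response([trial], np.array([0.512]))

    def test_single_sine_mode_averages_per_trial_phasors(
        self, short_trajectory, short_spec
    ):
        a = _trial_from(short_trajectory, short_trajectory.evaluate(short_trajectory.time - 0.05))
        b = _trial_from(short_trajectory, short_trajectory.evaluate(short_trajectory.time - 0.05))
        fr = estimate_frequency_response(
            [a, b], short_spec.frequencies, average_across_trials=False
        )
        ref = estimate_frequency_response([a], short_spec.frequencies)
        np.testing.assert_allclose(fr.phasors, ref.phasors, atol=1e-9)

    def test_time_domain_rms_error_consistent_with_phasor(self, short_spec):
        # for a pure sinusoid, the RMS of the error signal equals
        # A*|phasor - 1|/sqrt(2)
        from vmtrack.stimulus import generate_single_sine

        traj = generate_single_sine(0.85, short_spec)
        response = 0.8 * traj.evaluate(traj.time - 0.1)
        trial = _trial_from(traj, response)
        fr = estimate_frequency_response([trial], np.array([0.85]))
        start = int(20.0 * 1000)
        rms = np.sqrt(np.mean((response[start:] - traj.angle[start:]) ** 2))
        predicted = 2.0 * np.abs(fr.phasors[0] - 1.0) / np.sqrt(2.0)
        assert rms == pytest.approx(predicted, rel=0.01)


class TestPhasorQuantities:
    def test_tracking_error_examples(self):
        fr = FrequencyResponse(
            np.array([0.1, 0.15, 0.25]),
            np.array([1.0 + 0j, 0.0 + 0j, np.exp(-1j * np.pi / 2)]),
        )
        err, aggregate = tracking_error(fr, n_lowest=3)
        np.testing.assert_allclose(err, [0.0, 1.0, np.sqrt(2.0)])
        assert aggregate == pytest.approx(1.0 + np.sqrt(2.0))

    def test_aggregate_uses_lowest_frequencies_only(self):
        freqs = np.array([0.1, 0.15, 0.25, 0.35, 0.55, 2.35])
        phasors = np.ones(6, complex)
        phasors[-1] = 0.0  # large error at the highest frequency
        _, aggregate = tracking_error(FrequencyResponse(freqs, phasors), n_lowest=5)
        assert aggregate == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "phasor,expected",
        [
            (0.5 + 0.0j, "inside"),
            (1.0 + 0.0j, "on"),
            (-1.0j, "outside"),  # unit gain at 90 degrees lag
            (0.0 + 0.0j, "on"),
        ],
    )
    def test_circle_position(self, phasor, expected):
        assert circle_position(phasor) == expected

    def test_phase_lag_vectors_and_circular_mean(self):
        lags = np.array([10.0, 20.0, 30.0])
        fr = FrequencyResponse(
            np.array([0.1, 0.25, 0.55]),
            2.0 * np.exp(-1j * np.radians(lags)),  # gain 2, pure lags
        )
        u = phase_lag_vectors(fr)
        np.testing.assert_allclose(np.abs(u), 1.0)
        assert circular_mean_lag(lags) == pytest.approx(20.0)
        assert circular_mean_lag(np.array([350.0, 10.0])) == pytest.approx(0.0, abs=1e-9)
        assert circular_mean_lag(np.array([77.0])) == pytest.approx(77.0)

    def test_zero_gain_phasor_has_no_phase(self):
        fr = FrequencyResponse(np.array([0.1]), np.array([0.0 + 0.0j]))
        with pytest.raises(ValueError):
            phase_lag_vectors(fr)


class TestScalingFactor:
    def _fr(self, phasors):
        freqs = np.array([0.1, 0.15, 0.25, 0.35, 0.55, 0.65])
        return FrequencyResponse(freqs, np.asarray(phasors, complex))

    def test_exact_inverse(self):
        rng = np.random.default_rng(0)
        v = rng.standard_normal(6) + 1j * rng.standard_normal(6)
        res = fit_scaling_factor(self._fr(0.8 * v), self._fr(v))
        assert res.scaling_factor == pytest.approx(1.25)
        assert res.residual == pytest.approx(0.0, abs=1e-12)

    def test_identity(self):
        v = np.exp(-1j * np.linspace(0.1, 1.0, 6))
        assert fit_scaling_factor(self._fr(v), self._fr(v)).scaling_factor == pytest.approx(1.0)

    def test_matches_grid_search_oracle(self):
        # realistic case: a rescaled response with phasor noise
        rng = np.random.default_rng(7)
        v = np.exp(-1j * np.linspace(0.2, 1.5, 6))
        p = v / 1.3 + 0.1 * (rng.standard_normal(6) + 1j * rng.standard_normal(6))
        res = fit_scaling_factor(self._fr(p), self._fr(v))
        grid = np.linspace(0.1, 3.0, 30001)
        costs = [np.sum(np.abs(s * p[:5] - v[:5]) ** 2) for s in grid]
        assert res.scaling_factor == pytest.approx(grid[int(np.argmin(costs))], abs=1e-3)

    def test_scaling_does_not_touch_phase(self):
        rng = np.random.default_rng(1)
        v = np.exp(-1j * np.linspace(0.2, 1.5, 6))
        p = v / 0.8 + 0.05 * (rng.standard_normal(6) + 1j * rng.standard_normal(6))
        s = fit_scaling_factor(self._fr(p), self._fr(v)).scaling_factor
        assert s > 0
        np.testing.assert_allclose(np.angle(s * p), np.angle(p))

    def test_zero_power_rejected(self):
        with pytest.raises(ValueError):
            fit_scaling_factor(self._fr(np.zeros(6)), self._fr(np.ones(6)))


class TestCohortDirection:
    def test_patients_lag_more_at_the_highest_frequency(self):
        f = np.array([2.35])
        lag = lambda subj: np.mod(
            -np.degrees(np.angle(closed_loop_fr(subj, f, LoopConfig()))), 360.0
        )[0]
        assert lag(PATIENT_TEMPLATE) > lag(CONTROL_TEMPLATE)

    def test_bin_exactness_of_default_design(self):
        # 80 s retained at 1 kHz -> 0.0125 Hz bins; all 15 stimulated
        # frequencies are exact multiples
        from vmtrack.stimulus import build_spec

        k = build_spec().frequencies / 0.0125
        np.testing.assert_allclose(k, np.round(k), atol=1e-9)
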