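"""Crossover-model structures, fitting, selection, bootstrap, TD checks."""

import numpy as np
import pandas as pd
import pytest

from vmtrack.crossover import (
    BEST4_LOWEST_ERR,
    BEST4_LOWEST_VAR,
    DEGENERATE_STRUCTURES,
    FULL_FREE,
    PARAM_NAMES,
    CrossoverModel,
    FitReport,
    ModelStructure,
    average_fr,
    bootstrap_ci,
    consistency,
    enumerate_structures,
    fd_error,
    loo_evaluate,
    model_fr,
    select_models,
    simulate_model_td,
    simulate_phasor_cohort,
    td_error,
)
from vmtrack.phasor import FrequencyResponse
from vmtrack.simulate import LoopConfig, SubjectParams, simulate_tracking

TRUTH = np.array([2.7, 2.7, 0.39, 0.39, 0.210, 0.141, 0.141, 0.0])
FREQS = np.array(
    [0.10, 0.15, 0.25, 0.35, 0.55, 0.65, 0.85, 0.95,
     1.15, 1.45, 1.55, 1.85, 2.05, 2.15, 2.35]
)


def _cohort_fr(params=TRUTH, noise=0.0, n_pairs=5, seed=0):
    return simulate_phasor_cohort(params, FREQS, n_pairs=n_pairs, noise_sd=noise, seed=seed)


class TestModelFR:
    def test_dc_limit_is_visual_gain(self):
        h_pat, h_con = model_fr(TRUTH * [1, 1, 1, 1, 0, 0, 0, 0], np.array([1e-5]))
        assert abs(h_pat[0] - 0.39) < 1e-3
        assert abs(h_con[0] - 0.39) < 1e-3

    def test_open_loop_magnitude(self):
        params = np.array([2.0, 2.0, 1.0, 1.0, 0.1, 0.1, 0.0, 0.0])
        f = np.array([0.25, 1.0])
        h, _ = model_fr(params, f, kind="open_loop")
        np.testing.assert_allclose(np.abs(h), 2.0 / (2 * np.pi * f))

    def test_against_independent_complex_arithmetic(self):
        # hand-evaluated loop formula at each default frequency
        s = 2j * np.pi * FREQS
        expect_pat = (
            0.39 * np.exp(-s * 0.210) * 2.7 / s
        ) / (1 + np.exp(-s * 0.141) * 2.7 / s)
        expect_con = (
            0.39 * np.exp(-s * 0.141) * 2.7 / s
        ) / (1 + 2.7 / s)
        h_pat, h_con = model_fr(TRUTH, FREQS)
        np.testing.assert_allclose(h_pat, expect_pat, rtol=1e-12)
        np.testing.assert_allclose(h_con, expect_con, rtol=1e-12)


class TestFDError:
    def _data(self, phasors):
        return FrequencyResponse(FREQS, phasors)

    def test_zero_for_exact_model(self):
        h_pat, h_con = model_fr(TRUTH, FREQS)
        assert fd_error(TRUTH, self._data(h_pat), self._data(h_con)) == pytest.approx(0.0)

    def test_null_model_against_unit_gain_data(self):
        # a pure gain of zero predicts nothing; unit-gain data at 15
        # frequencies contributes error 15 per cohort
        zeros = np.zeros(8)
        ones = np.ones(15, complex)
        err = fd_error(zeros, self._data(ones), self._data(ones), kind="pure_gain")
        assert err == pytest.approx(30.0)

    def test_matches_naive_loop_summation(self):
        rng = np.random.default_rng(3)
        data_p = rng.standard_normal(15) + 1j * rng.standard_normal(15)
        data_c = rng.standard_normal(15) + 1j * rng.standard_normal(15)
        h_pat, h_con = model_fr(TRUTH, FREQS)
        naive = sum(abs(data_c[i] - h_con[i]) ** 2 for i in range(15)) + sum(
            abs(data_p[i] - h_pat[i]) ** 2 for i in range(15)
        )
        got = fd_error(TRUTH, self._data(data_p), self._data(data_c))
        assert got == pytest.approx(naive, rel=1e-12)

    def test_mismatched_grids_rejected(self):
        a = FrequencyResponse(FREQS, np.ones(15, complex))
        b = FrequencyResponse(FREQS * 2, np.ones(15, complex))
        with pytest.raises(ValueError):
            fd_error(TRUTH, a, b)


class TestStructures:
    def test_full_free_has_eight_parameters(self):
        assert FULL_FREE.n_free == 8

    def test_best4_has_four(self):
        assert BEST4_LOWEST_ERR.n_free == 4
        p = BEST4_LOWEST_ERR.expand(np.array([2.7, 0.39, 0.210, 0.141]))
        assert dict(zip(PARAM_NAMES, p)) == {
            "k_patient": 2.7, "k_control": 2.7,
            "visual_gain_patient": 0.39, "visual_gain_control": 0.39,
            "visual_delay_patient": 0.210, "visual_delay_control": 0.141,
            "feedback_delay_patient": 0.141, "feedback_delay_control": 0.0,
        }

    def test_zero_fixing_partial_group_rejected(self):
        with pytest.raises(ValueError):
            ModelStructure(
                gain_groups=[[n] for n in PARAM_NAMES[:4]],
                delay_groups=[list(PARAM_NAMES[4:])],
                zero_delays=frozenset({"feedback_delay_control"}),
            )

    def test_enumeration_contains_expected_members(self):
        structures = enumerate_structures()
        keys = {s.key() for s in structures}
        assert FULL_FREE.key() in keys
        assert BEST4_LOWEST_ERR.key() in keys
        assert BEST4_LOWEST_VAR.key() in keys
        for st in DEGENERATE_STRUCTURES:
            assert st.key() in keys
        # all-delays-yoked-and-zeroed reduces to the delay-free loop and
        # appears exactly once despite many generating partitions
        delay_free = ModelStructure(
            gain_groups=[[n] for n in PARAM_NAMES[:4]],
            zero_delays=frozenset(PARAM_NAMES[4:]),
        )
        assert sum(1 for s in structures if s.key() == delay_free.key()) == 1
        assert len(structures) == len(keys)
        assert len(structures) > 500

    def test_enumeration_free_counts_within_bounds(self):
        for st in enumerate_structures():
            assert 1 <= st.n_free <= 8


class TestFitting:
    def test_noiseless_recovery(self):
        cohort = _cohort_fr()
        res = CrossoverModel.from_cohort(cohort, BEST4_LOWEST_ERR).fit(
            n_restarts=10, seed=1
        )
        assert res.fd_error < 1e-8
        np.testing.assert_allclose(res.params.to_numpy(), TRUTH, rtol=0.01, atol=1e-4)

    def test_more_restarts_never_worse(self):
        cohort = _cohort_fr(noise=0.05, seed=4)
        model = CrossoverModel.from_cohort(cohort, BEST4_LOWEST_ERR)
        e1 = model.fit(n_restarts=1, seed=9).fd_error
        e10 = model.fit(n_restarts=10, seed=9).fd_error
        assert e10 <= e1 + 1e-12

    def test_fit_deterministic_given_seed(self):
        cohort = _cohort_fr(noise=0.05, seed=4)
        model = CrossoverModel.from_cohort(cohort, BEST4_LOWEST_ERR)
        a = model.fit(n_restarts=5, seed=3)
        b = model.fit(n_restarts=5, seed=3)
        np.testing.assert_array_equal(a.free_params, b.free_params)

    def test_summary_mentions_structure_and_units(self):
        res = CrossoverModel.from_cohort(_cohort_fr(), BEST4_LOWEST_ERR).fit(
            n_restarts=5, seed=0
        )
        text = res.summary()
        assert "Best 4 (Lowest Err)" in text
        assert "visual_delay_patient" in text and "1/s" in text

    def test_gain_condition_shifts_match_partial_compensation(self):
        # a subject that partially compensates for an applied cursor gain
        # fits with lower k and higher visual gain under gain 1.35, and
        # the reverse under 0.65, delays unchanged
        from vmtrack.simulate import CONTROL_TEMPLATE, PATIENT_TEMPLATE, adapted_subject, closed_loop_fr

        fits = {}
        for g in (1.0, 1.35, 0.65):
            pairs = []
            loop = LoopConfig(display_delay=0.0, applied_feedback_gain=g)
            fr = {}
            for label, tmpl in (("p", PATIENT_TEMPLATE), ("c", CONTROL_TEMPLATE)):
                subj = adapted_subject(tmpl, g)
                fr[label] = FrequencyResponse(FREQS, closed_loop_fr(subj, FREQS, loop))
            res = CrossoverModel(
                fr["p"], fr["c"], BEST4_LOWEST_ERR, applied_feedback_gain=g
            ).fit(n_restarts=10, seed=2)
            fits[g] = res.params
        assert fits[1.35]["k_patient"] < fits[1.0]["k_patient"] < fits[0.65]["k_patient"]
        assert (
            fits[1.35]["visual_gain_patient"]
            > fits[1.0]["visual_gain_patient"]
            > fits[0.65]["visual_gain_patient"]
        )
        for g in (1.35, 0.65):
            assert fits[g]["visual_delay_patient"] == pytest.approx(
                fits[1.0]["visual_delay_patient"], abs=0.005
            )


class TestConsistency:
    def test_identical_rows_are_perfectly_consistent(self):
        m = np.tile(np.arange(8.0), (5, 1))
        assert consistency(m) == pytest.approx(0.0, abs=1e-12)

    def test_two_row_hand_svd(self):
        m = np.zeros((2, 8))
        m[1, 0] = 2.0  # residuals are +/-1 in one column
        assert consistency(m) == pytest.approx(np.sqrt(2.0))

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        m = rng.standard_normal((6, 8))
        shuffled = m[rng.permutation(6)]
        assert consistency(m) == pytest.approx(consistency(shuffled))


class TestLeaveOneOut:
    def test_identical_pairs_make_loo_equal_insample(self):
        cohort = _cohort_fr(n_pairs=4)
        report = loo_evaluate(BEST4_LOWEST_ERR, cohort, n_restarts=5, seed=0)
        assert report.loo_errors.shape == (4,)
        assert report.mean_loo_error == pytest.approx(0.0, abs=1e-7)
        assert report.consistency == pytest.approx(0.0, abs=1e-3)

    def test_fold_and_matrix_shapes(self):
        cohort = _cohort_fr(noise=0.05, n_pairs=5, seed=2)
        report = loo_evaluate(BEST4_LOWEST_ERR, cohort, n_restarts=5, seed=0)
        assert report.param_sets.shape == (5, 8)
        assert list(report.param_sets.columns) == list(PARAM_NAMES)
        assert report.mean_loo_error > 0

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            loo_evaluate(BEST4_LOWEST_ERR, _cohort_fr(n_pairs=2), n_restarts=2)


class TestSelection:
    def _report(self, st, loo, cons):
        return FitReport(st, loo, cons)

    def test_single_report_selected(self):
        r = self._report(BEST4_LOWEST_ERR, 1.0, 1.0)
        assert select_models([r]) == [r]

    def test_dominated_report_excluded(self):
        good = self._report(BEST4_LOWEST_ERR, 1.0, 1.0)
        bad = self._report(FULL_FREE, 2.0, 2.0)
        front = select_models([good, bad])
        assert good in front and bad not in front

    def test_incomparable_reports_both_kept_and_labelled(self):
        a = self._report(BEST4_LOWEST_ERR, 1.0, 2.0)
        b = self._report(BEST4_LOWEST_VAR, 2.0, 1.0)
        front = select_models([a, b])
        assert len(front) == 2 and a in front and b in front
        assert a.label == "lowest error"
        assert b.label == "lowest variance"


class TestBootstrap:
    def test_zero_noise_gives_zero_width_intervals(self):
        ci = bootstrap_ci(
            BEST4_LOWEST_ERR, _cohort_fr(n_pairs=4), B=5, n_restarts=5, seed=0
        )
        np.testing.assert_allclose(ci["hi"] - ci["lo"], 0.0, atol=1e-4)

    def test_intervals_widen_with_noise(self):
        widths = {}
        for sd in (0.02, 0.2):
            ci = bootstrap_ci(
                BEST4_LOWEST_ERR,
                _cohort_fr(noise=sd, n_pairs=5, seed=6),
                B=8,
                n_restarts=5,
                seed=1,
            )
            widths[sd] = (ci["hi"] - ci["lo"])["k_patient"]
        assert widths[0.2] > widths[0.02]

    def test_bootstrap_deterministic(self):
        kw = dict(B=4, n_restarts=3, seed=7)
        a = bootstrap_ci(BEST4_LOWEST_ERR, _cohort_fr(noise=0.05, n_pairs=4, seed=1), **kw)
        b = bootstrap_ci(BEST4_LOWEST_ERR, _cohort_fr(noise=0.05, n_pairs=4, seed=1), **kw)
        pd.testing.assert_frame_equal(a, b)


class TestTimeDomain:
    def test_td_error_examples(self):
        n = 100_000
        x = np.random.default_rng(0).standard_normal(n)
        assert td_error(x, x, x, x) == pytest.approx(0.0)
        assert td_error(x + 1.0, x, x, x) == pytest.approx(1.0)
        assert td_error(x + 1.0, x, x + 1.0, x) == pytest.approx(2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            td_error(np.zeros(10), np.zeros(11), np.zeros(10), np.zeros(10))

    def test_model_simulation_self_consistency(self, sum_of_sines):
        # simulating the fitted loop reproduces a noiseless subject with
        # the same parameters (display latency excluded on both sides)
        pred_p, pred_c = simulate_model_td(TRUTH, sum_of_sines)
        loop = LoopConfig(display_delay=0.0, n_trials=1, seed=0)
        obs_p = simulate_tracking(
            SubjectParams(k=2.7, visual_gain=0.39, visual_delay=0.210, feedback_delay=0.141),
            sum_of_sines, loop,
        )[0].elbow
        obs_c = simulate_tracking(
            SubjectParams(k=2.7, visual_gain=0.39, visual_delay=0.141, feedback_delay=0.0),
            sum_of_sines, loop,
        )[0].elbow
        assert td_error(pred_p, obs_p, pred_c, obs_c) < 1e-12


class TestAverageFR:
    def test_complex_mean(self):
        a = FrequencyResponse(FREQS, np.full(15, 1 + 1j))
        b = FrequencyResponse(FREQS, np.full(15, 3 - 1j))
        avg = average_fr([a, b])
        np.testing.assert_allclose(avg.phasors, 2.0 + 0j)

    def test_mismatched_grids_rejected(self):
        a = FrequencyResponse(FREQS, np.ones(15, complex))
        b = FrequencyResponse(FREQS + 0.05, np.ones(15, complex))
        with pytest.raises(ValueError):
            average_fr([a, b])
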