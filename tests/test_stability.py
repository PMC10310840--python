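import numpy as np
import pandas as pd
import pytest

from microstim.datamodel import InvalidInputError
from microstim.responsiveness import compute_response_tensor
from microstim.stability import (
    StabilityResult,
    compute_stability,
    cross_day_matrix,
    day_vectors,
    days_until_r2_below,
    group_stability_comparison,
    trial_vectors,
    within_day_stability,
)
from microstim.synth import SyntheticConfig, generate_experiment


def _geometric_matrix(rho, n):
    """Cross-day matrix with r(i, j) = rho ** |i - j|."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :]).astype(float)


class TestWithinDayStability:
    def test_identical_trials_give_unit_scalar(self):
        m = np.tile(np.random.default_rng(0).normal(size=20), (5, 1))
        _, scalar = within_day_stability(m)
        assert scalar == pytest.approx(1.0)

    def test_independent_noise_gives_near_zero(self):
        m = np.random.default_rng(1).normal(size=(10, 2000))
        _, scalar = within_day_stability(m)
        assert abs(scalar) < 0.05

    def test_signal_variance_fraction_sets_expected_correlation(self):
        """With half the variance shared across trials, pairwise r ~ 0.5."""
        rng = np.random.default_rng(2)
        shared = rng.normal(0, 1, 2000)
        m = shared[None, :] + rng.normal(0, 1, (12, 2000))
        _, scalar = within_day_stability(m)
        assert scalar == pytest.approx(0.5, abs=0.05)

    def test_zero_variance_trial_excluded(self):
        rng = np.random.default_rng(3)
        m = rng.normal(size=(4, 50))
        m[2] = 1.0  # flat population vector: correlation undefined
        corr, scalar = within_day_stability(m)
        assert np.isnan(corr[2, 0]) and np.isnan(corr[0, 2])
        assert np.isfinite(scalar)

    def test_too_small_inputs_undefined(self):
        _, scalar = within_day_stability(np.zeros((1, 10)))
        assert np.isnan(scalar)
        _, scalar = within_day_stability(np.zeros((5, 2)))
        assert np.isnan(scalar)

    def test_row_affine_invariance(self):
        """Pearson matrices are invariant to positive per-trial rescaling."""
        rng = np.random.default_rng(4)
        m = rng.normal(size=(6, 100))
        scales = rng.uniform(0.5, 3.0, 6)[:, None]
        offsets = rng.normal(0, 2, 6)[:, None]
        c0, s0 = within_day_stability(m)
        c1, s1 = within_day_stability(m * scales + offsets)
        np.testing.assert_allclose(c0, c1, atol=1e-10)
        assert s0 == pytest.approx(s1, abs=1e-10)


class TestTrialVectors:
    @pytest.fixture(scope="class")
    def session_tensor(self):
        cfg = SyntheticConfig(
            n_expressing=10, n_non_expressing=20, n_ambiguous=0,
            n_sessions=1, trials_per_session=60, stage_schedule=["detect_0v9"],
        )
        exp, gt = generate_experiment(cfg, seed=6)
        s = exp.sessions[0]
        return s, compute_response_tensor(s), gt

    def test_inclusion_rules_differ_only_by_columns(self, session_tensor):
        s, tensor, _ = session_tensor
        m_all, ids_all = trial_vectors(s, tensor, inclusion="all")
        m_resp, ids_resp = trial_vectors(s, tensor, inclusion="ever_responsive")
        assert set(ids_resp) <= set(ids_all)
        cols = [ids_all.index(i) for i in ids_resp]
        np.testing.assert_array_equal(m_all[:, cols], m_resp)

    def test_row_norms_track_shared_trial_gain(self):
        cfg = SyntheticConfig(
            n_expressing=0, n_non_expressing=200, n_ambiguous=0,
            n_sessions=1, trials_per_session=50, stage_schedule=["detect_0v9"],
            prob_max_non_expressing=1.0, prob_sd=0.0, drift_sd_non_expressing=0.0,
            drift_turnover_ratio=0.0, trial_gain_sd=0.5, noise_sd=0.02,
        )
        exp, gt = generate_experiment(cfg, seed=7)
        s = exp.sessions[0]
        tensor = compute_response_tensor(s)
        m, _ = trial_vectors(s, tensor, inclusion="all")
        mask = tensor.pulse_counts == 9
        gains = gt.trial_gain[0][tensor.trial_indices][mask]
        norms = np.linalg.norm(m, axis=1)
        assert np.corrcoef(norms, gains)[0, 1] > 0.9

    def test_too_few_trials_undefined(self, session_tensor):
        s, tensor, _ = session_tensor
        m, _ = trial_vectors(s, tensor, pulse_count=3)  # absent in detect stage
        assert m.shape[0] == 0


class TestDayVectors:
    def test_recovers_latent_day_amplitudes(self):
        cfg = SyntheticConfig(
            n_expressing=0, n_non_expressing=150, n_ambiguous=0,
            n_sessions=4, trials_per_session=40, stage_schedule=["detect_0v9"] * 4,
            prob_max_non_expressing=1.0, prob_sd=0.0, drift_jitter_ratio=0.0,
            trial_gain_sd=0.0, noise_sd=0.05,
        )
        exp, gt = generate_experiment(cfg, seed=8)
        tensors = {s.session_day: compute_response_tensor(s) for s in exp.sessions}
        mat, days, ids = day_vectors(exp, tensors, inclusion="all")
        order = [gt.neuron_ids.index(i) for i in ids]
        for d in range(len(days)):
            latent = gt.day_amplitude[d][order]
            assert np.corrcoef(mat[d], latent)[0, 1] > 0.95

    def test_absent_neuron_contributes_to_no_pair(self):
        rng = np.random.default_rng(9)
        day_mat = rng.normal(size=(3, 15))
        day_mat[1, 0] = np.nan  # neuron 0 absent on day 2
        cross = cross_day_matrix(day_mat, min_overlap=5)
        both = ~np.isnan(day_mat[0]) & ~np.isnan(day_mat[1])
        expected = np.corrcoef(day_mat[0, both], day_mat[1, both])[0, 1]
        assert cross[0, 1] == pytest.approx(expected)
        # the (0, 2) pair is unaffected by day-2 absence
        assert cross[0, 2] == pytest.approx(np.corrcoef(day_mat[0], day_mat[2])[0, 1])

    def test_min_overlap_enforced(self):
        day_mat = np.random.default_rng(10).normal(size=(2, 12))
        day_mat[1, :5] = np.nan
        assert np.isnan(cross_day_matrix(day_mat, min_overlap=10)[0, 1])


class TestDaysUntil:
    def test_perfect_correlation_censored(self):
        assert days_until_r2_below(np.ones((5, 5)), 0) is None

    def test_geometric_decay_example(self):
        # r = 0.9^lag: R2 crosses 0.5 at lag 4 (0.81^3 = 0.531, 0.81^4 = 0.430)
        assert days_until_r2_below(_geometric_matrix(0.9, 8), 0) == 4

    def test_immediate_crossing(self):
        assert days_until_r2_below(_geometric_matrix(0.5, 4), 0) == 1

    def test_nonincreasing_in_threshold(self):
        m = _geometric_matrix(0.85, 10)
        thresholds = [0.2, 0.4, 0.6, 0.8]
        vals = [days_until_r2_below(m, 0, threshold=t) for t in thresholds]
        vals = [np.inf if v is None else v for v in vals]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_calendar_counting(self):
        m = _geometric_matrix(0.5, 3)
        assert days_until_r2_below(m, 0, day_labels=[1, 4, 9], count="calendar") == 3

    def test_nan_entries_skipped(self):
        m = _geometric_matrix(0.5, 4)
        m[0, 1] = m[1, 0] = np.nan
        assert days_until_r2_below(m, 0) == 2

    def test_start_day_needs_subsequent_day(self):
        with pytest.raises(InvalidInputError):
            days_until_r2_below(_geometric_matrix(0.9, 3), 2)


def _fake_result(subject, scalar_by_day, days_until, days):
    return StabilityResult(
        subject_id=subject,
        opsin_class="non_expressing",
        within_day=pd.DataFrame(
            {"session_day": days, "mean_upper_triangle_r": scalar_by_day,
             "n_trials": 20, "n_neurons": 50}
        ),
        cross_day=np.zeros((len(days), len(days))),
        session_days=list(days),
        days_until=days_until,
    )


class TestGroupComparison:
    def test_within_day_metric_two_groups(self):
        results = [
            ("learner", _fake_result("l1", [0.6, 0.6, 0.6], [2, 2], [1, 2, 3])),
            ("learner", _fake_result("l2", [0.5, 0.5, 0.5], [2, 2], [1, 2, 3])),
            ("non_learner", _fake_result("n1", [0.3, 0.3, 0.3], [1, 1], [1, 2, 3])),
            ("non_learner", _fake_result("n2", [0.2, 0.2, 0.2], [1, 1], [1, 2, 3])),
        ]
        res = group_stability_comparison(results, "within_day_mean", (1, 3))
        assert not res.no_common_support
        assert res.comparison.group_means["learner"] > res.comparison.group_means["non_learner"]

    def test_censored_start_days_excluded_for_everyone(self):
        results = [
            ("learner", _fake_result("l1", [0.5] * 3, [5, None], [1, 2, 3])),
            ("learner", _fake_result("l2", [0.5] * 3, [4, 3], [1, 2, 3])),
            ("non_learner", _fake_result("n1", [0.3] * 3, [2, 1], [1, 2, 3])),
            ("non_learner", _fake_result("n2", [0.3] * 3, [1, 1], [1, 2, 3])),
        ]
        res = group_stability_comparison(results, "days_until", (1, 2))
        # start day 2 censored for l1 -> only start day 1 contributes
        assert res.per_subject["value"].tolist() == [5.0, 4.0, 2.0, 1.0]

    def test_no_common_support_flagged(self):
        results = [
            ("learner", _fake_result("l1", [0.5] * 3, [None, None], [1, 2, 3])),
            ("non_learner", _fake_result("n1", [0.3] * 3, [1, 1], [1, 2, 3])),
        ]
        res = group_stability_comparison(results, "days_until", (1, 2))
        assert res.no_common_support

    def test_subject_without_window_values_excluded_with_flag(self):
        results = [
            ("learner", _fake_result("l1", [np.nan, np.nan, np.nan], [2, 2], [1, 2, 3])),
            ("learner", _fake_result("l2", [0.5] * 3, [2, 2], [1, 2, 3])),
            ("non_learner", _fake_result("n1", [0.3] * 3, [1, 1], [1, 2, 3])),
        ]
        res = group_stability_comparison(results, "within_day_mean", (1, 3))
        assert "l1" in res.excluded_subjects

    def test_unknown_metric_rejected(self):
        with pytest.raises(InvalidInputError):
            group_stability_comparison([], "nope", (1, 3))


def test_compute_stability_end_to_end(tiny_experiment):
    exp, _ = tiny_experiment
    tensors = {s.session_day: compute_response_tensor(s) for s in exp.sessions}
    res = compute_stability(exp, "non_expressing", tensors=tensors)
    assert len(res.within_day) == len(exp.sessions)
    assert res.cross_day.shape[0] == len(res.session_days)
    # matrices are symmetric with unit diagonal where defined
    np.testing.assert_allclose(res.cross_day, res.cross_day.T, atol=1e-12)
    assert np.allclose(np.diag(res.cross_day), 1.0)
    assert len(res.days_until) == max(len(res.session_days) - 1, 0)
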