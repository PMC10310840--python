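import numpy as np
import pandas as pd
import pytest

from microstim.decoding import roc_auc
from microstim.responsiveness import (
    EventDetectorConfig,
    baseline_distribution,
    classify_responsive,
    compare_groups,
    compute_response_tensor,
    extract_evoked,
    spontaneous_rate,
    stimulus_exclusion_mask,
    summarize_by_pulse,
    top_responders,
    whisking_encoding_score,
    zscore_evoked,
)
from microstim.synth import (
    SyntheticConfig,
    generate_experiment,
    generate_null_session,
    generate_whisking_data,
    saturating_curve,
)
from .conftest import make_session


class TestExtractEvoked:
    def test_constant_trace(self):
        s = make_session(n_neurons=2, n_trials=3, dff=np.full((2, 36), 1.5))
        evoked, kept = extract_evoked(s)
        np.testing.assert_allclose(evoked, 1.5)
        assert kept.tolist() == [0, 1, 2]

    def test_two_frame_mean(self):
        s = make_session(n_neurons=1, n_trials=1)
        open_ = s.trials[0].shutter_open_frame
        s.dff[0, open_] = 0.4
        s.dff[0, open_ + 1] = 0.8
        evoked, _ = extract_evoked(s)
        assert evoked[0, 0] == pytest.approx(0.6)

    def test_truncated_trial_dropped_with_warning(self):
        s = make_session(n_neurons=1, n_trials=2)
        s.trials[-1].shutter_open_frame = s.n_frames - 1
        with pytest.warns(UserWarning, match="truncated"):
            evoked, kept = extract_evoked(s)
        assert kept.tolist() == [0]

    def test_kernel_closed_form(self):
        """Evoked matches A * mean(exp(-dt/tau)) over the two frame offsets."""
        cfg = SyntheticConfig(
            n_expressing=1, n_non_expressing=1, n_ambiguous=0,
            n_sessions=1, trials_per_session=6, stage_schedule=["detect_0v9"],
            pre_frames=20, post_frames=60, amp_log_sd=0.0, prob_max_expressing=1.0, prob_max_non_expressing=1.0,
            prob_sd=0.0, drift_sd_expressing=0.0, drift_sd_non_expressing=0.0,
            drift_turnover_ratio=0.0, trial_gain_sd=0.0, noise_sd=0.0,
        )
        exp, gt = generate_experiment(cfg, seed=0)
        s = exp.sessions[0]
        evoked, kept = extract_evoked(s)
        decay = np.exp(-1.0 / (cfg.frame_rate * cfg.tau_calcium))
        kernel_factor = (1.0 + decay) / 2.0
        latent = gt.latent_evoked[0][kept]
        np.testing.assert_allclose(evoked, latent * kernel_factor, rtol=1e-3, atol=1e-3)


class TestBaselineDistribution:
    def test_sample_counts_per_mode(self):
        s = make_session(n_neurons=2, n_trials=10, pre=6)
        assert baseline_distribution(s, n_frames=6, mode="per_frame").n_samples == 60
        assert baseline_distribution(s, n_frames=6, mode="matched").n_samples == 50
        assert baseline_distribution(s, n_frames=6, mode="per_trial_mean").n_samples == 10

    def test_gaussian_sd_consistency(self):
        rng = np.random.default_rng(0)
        s = make_session(n_neurons=3, n_trials=60, pre=20, dff=rng.normal(0, 0.3, (3, 60 * 30)))
        stats = baseline_distribution(s, n_frames=20, mode="per_frame")
        np.testing.assert_allclose(stats.sd, 0.3, rtol=0.05)

    def test_percentile_bounds_on_uniform(self):
        rng = np.random.default_rng(1)
        s = make_session(n_neurons=2, n_trials=200, pre=20, dff=rng.uniform(0, 1, (2, 200 * 30)))
        stats = baseline_distribution(s, n_frames=20, mode="per_frame")
        np.testing.assert_allclose(stats.p_low, 0.025, atol=0.01)
        np.testing.assert_allclose(stats.p_high, 0.975, atol=0.01)

    def test_truncated_window_warns(self):
        s = make_session(n_neurons=1, n_trials=2, pre=5)
        with pytest.warns(UserWarning, match="truncated"):
            baseline_distribution(s, n_frames=39)


class TestClassifyResponsive:
    def test_extreme_values_flagged_and_median_not(self):
        rng = np.random.default_rng(2)
        s = make_session(n_neurons=1, n_trials=30, pre=20, dff=rng.normal(0, 0.1, (1, 30 * 30)))
        stats = baseline_distribution(s, n_frames=20)
        above = np.array([[stats.p_high[0] + 1.0]])
        at_median = np.array([[np.median(s.dff)]])
        assert classify_responsive(above, stats)[0, 0]
        assert not classify_responsive(at_median, stats)[0, 0]
        # ties at the bound are not responsive (strict exceedance)
        assert not classify_responsive(stats.p_high[None, :], stats)[0, 0]

    @pytest.mark.parametrize("noise", ["gaussian", "lognormal", "ar1"])
    def test_null_false_positive_rate_is_five_percent(self, noise):
        """Two-tailed 5% criterion holds for any stationary noise shape."""
        s = generate_null_session(300, 100, 0.15, seed=8, noise=noise)
        tensor = compute_response_tensor(s)
        assert 0.042 <= tensor.responsive.mean() <= 0.058

    def test_per_frame_baseline_understates_rate(self):
        """Per-frame pooling is narrower than the 2-frame evoked statistic."""
        s = generate_null_session(200, 100, 0.15, seed=9)
        frac = compute_response_tensor(s, baseline_mode="per_frame").responsive.mean()
        assert frac < 0.03


class TestZscore:
    def test_at_mean_and_two_sd(self):
        rng = np.random.default_rng(3)
        s = make_session(n_neurons=1, n_trials=50, pre=20, dff=rng.normal(0.2, 0.1, (1, 50 * 30)))
        stats = baseline_distribution(s, n_frames=20)
        z = zscore_evoked(np.array([[stats.mean[0]], [stats.mean[0] + 2 * stats.sd[0]]]), stats)
        np.testing.assert_allclose(z[:, 0], [0.0, 2.0], atol=1e-12)

    def test_zero_sd_neuron_excluded(self):
        s = make_session(n_neurons=2, n_trials=5)
        s.dff[1] = np.random.default_rng(0).normal(size=s.n_frames)
        stats = baseline_distribution(s, n_frames=6)
        with pytest.warns(UserWarning, match="zero baseline sd"):
            z = zscore_evoked(np.zeros((5, 2)), stats)
        assert np.isnan(z[:, 0]).all()
        assert np.isfinite(z[:, 1]).all()

    def test_offset_invariance(self):
        """Adding a constant to a neuron's trace changes neither z nor flags."""
        s = generate_null_session(20, 40, 0.15, seed=10)
        t0 = compute_response_tensor(s)
        s.dff[3] += 5.0
        t1 = compute_response_tensor(s)
        np.testing.assert_allclose(t0.evoked_z, t1.evoked_z, atol=1e-9)
        np.testing.assert_array_equal(t0.responsive, t1.responsive)


class TestSummaries:
    @pytest.fixture(scope="class")
    def rich_session(self):
        cfg = SyntheticConfig(
            n_expressing=25, n_non_expressing=50, n_ambiguous=0,
            n_sessions=1, trials_per_session=250, stage_schedule=["full"],
            extreme_weight=1.0, drift_sd_expressing=0.1, drift_sd_non_expressing=0.1,
        )
        exp, gt = generate_experiment(cfg, seed=21)
        return exp, gt

    def test_fraction_responsive_monotone_in_pulse_count(self, rich_session):
        exp, _ = rich_session
        s = exp.sessions[0]
        tensor = compute_response_tensor(s)
        classes = {nid: exp.neurons[nid].opsin_class for nid in s.neuron_ids}
        df = summarize_by_pulse(s, tensor, neuron_classes=classes)
        for cls, sub in df.groupby("opsin_class"):
            sub = sub.sort_values("pulse_count")
            vals = sub["fraction_responsive"].to_numpy()
            assert all(b >= a - 0.03 for a, b in zip(vals, vals[1:]))

    def test_response_probability_recovers_generator_curve(self):
        """With detection certain, median response probability equals q * g(p)."""
        cfg = SyntheticConfig(
            n_expressing=25, n_non_expressing=25, n_ambiguous=0,
            n_sessions=1, trials_per_session=250, stage_schedule=["full"],
            extreme_weight=1.0, amp_mean_expressing=5.0, amp_mean_non_expressing=5.0,
            amp_log_sd=0.0, noise_sd=0.1, drift_sd_expressing=0.0,
            drift_sd_non_expressing=0.0, drift_turnover_ratio=0.0, trial_gain_sd=0.0,
        )
        exp, gt = generate_experiment(cfg, seed=22)
        s = exp.sessions[0]
        tensor = compute_response_tensor(s)
        expressing = [nid for nid in s.neuron_ids if exp.neurons[nid].opsin_class == "expressing"]
        cols = tensor.columns_for(expressing)
        q = gt.q_max[[s.neuron_ids.index(n) for n in expressing]]
        for count in (3, 9):
            tmask = tensor.pulse_counts == count
            measured = np.median(tensor.responsive[np.ix_(tmask, cols)].mean(axis=0))
            expected = np.median(q) * saturating_curve(count, cfg.prob_halfsat_pulses)
            assert measured == pytest.approx(expected, abs=0.08)

    def test_deterministic_responder_probability_one(self):
        cfg = SyntheticConfig(
            n_expressing=3, n_non_expressing=3, n_ambiguous=0,
            n_sessions=1, trials_per_session=60, stage_schedule=["full"],
            amp_mean_expressing=5.0, amp_mean_non_expressing=5.0, amp_log_sd=0.0,
            amp_halfsat_pulses=0.05, prob_max_expressing=1.0,
            prob_max_non_expressing=1.0, prob_sd=0.0,
            prob_halfsat_pulses=0.05, drift_sd_expressing=0.0,
            drift_sd_non_expressing=0.0, drift_turnover_ratio=0.0,
            trial_gain_sd=0.0, noise_sd=0.05,
        )
        exp, _ = generate_experiment(cfg, seed=2)
        s = exp.sessions[0]
        tensor = compute_response_tensor(s)
        for count in sorted(set(tensor.pulse_counts.tolist())):
            if count == 0:
                continue
            assert tensor.responsive[tensor.pulse_counts == count].all()


class TestTopResponders:
    def test_identical_neurons_select_nothing(self):
        s = make_session(n_neurons=10, n_trials=6)
        rng = np.random.default_rng(4)
        shared = rng.normal(0, 0.1, s.n_frames)
        s.dff = np.tile(shared, (10, 1))
        tensor = compute_response_tensor(s)
        assert top_responders([tensor], percentile=95) == set()

    def test_dominant_neuron_always_selected(self):
        s = generate_null_session(40, 30, 0.1, seed=12)
        for tr in s.trials:
            s.dff[7, tr.shutter_open_frame : tr.shutter_open_frame + 2] += 3.0
        tensor = compute_response_tensor(s)
        assert "n0007" in top_responders([tensor], percentile=99)

    def test_99_subset_of_95(self, tiny_experiment):
        exp, _ = tiny_experiment
        tensors = [compute_response_tensor(s) for s in exp.sessions]
        assert top_responders(tensors, 99) <= top_responders(tensors, 95)

    def test_recovers_latent_amplitude_ranks(self):
        cfg = SyntheticConfig(
            n_expressing=0, n_non_expressing=60, n_ambiguous=0,
            n_sessions=1, trials_per_session=80, stage_schedule=["detect_0v9"],
            amp_log_sd=1.5, prob_max_non_expressing=1.0, prob_sd=0.0,
            drift_sd_non_expressing=0.0, drift_turnover_ratio=0.0, noise_sd=0.1,
        )
        hits = 0
        for seed in range(3):
            exp, gt = generate_experiment(cfg, seed=seed)
            tensor = compute_response_tensor(exp.sessions[0])
            selected = top_responders([tensor], 95)
            true_top = set(np.array(gt.neuron_ids)[np.argsort(gt.day_amplitude[0])[-3:]])
            hits += len(selected & true_top) >= 2
        assert hits >= 2


class TestSpontaneous:
    def test_flat_trace_zero_rate(self):
        s = make_session(n_neurons=2, n_trials=4, pre=10, post=30)
        assert (spontaneous_rate(s) == 0).all()

    def test_exclusion_mask_counts(self):
        s = make_session(n_neurons=1, n_trials=3, pre=10, closed=2, post=40, frame_rate=7.0)
        cfg = EventDetectorConfig()
        keep = stimulus_exclusion_mask(s, cfg)
        per_stim = round(7.0 * 1.0) + round(7.0 * 5.0)  # 7 + 35 frames
        assert (~keep).sum() == 3 * per_stim

    def test_event_rate_recovery(self):
        """Inserted kernel events are recovered within 15% at high SNR."""
        rng = np.random.default_rng(13)
        n_frames = 4200  # 10 min at 7 Hz
        dff = rng.normal(0, 0.05, (1, n_frames))
        kernel = 1.2 * np.exp(-np.arange(12) / (7 * 1.5))
        true_rate = 8.0  # events per minute
        onsets = np.sort(rng.choice(np.arange(50, n_frames - 50), int(true_rate * 10), replace=False))
        onsets = onsets[np.diff(np.concatenate([[0], onsets])) > 14]
        for o in onsets:
            dff[0, o : o + 12] += kernel
        s = make_session(n_neurons=1, n_trials=1, pre=6, closed=2, post=4)
        s.dff = dff
        s.trials = s.trials[:1]
        s.trials[0].shutter_close_frame = 6
        s.trials[0].shutter_open_frame = 8
        rate = spontaneous_rate(s)[0]
        inserted = len(onsets) / (s.dff.shape[1] / 7.0 / 60.0)
        assert abs(rate - inserted) / inserted < 0.15


class TestWhisking:
    def test_proportional_trace_scores_one(self):
        angle, dff, _ = generate_whisking_data(1, 600, 1.0, gain=0.05, noise_sd=0.0, seed=1)
        score, member = whisking_encoding_score(dff[0], angle)
        assert score > 0.99 and member

    def test_independent_trace_not_member(self):
        angle, dff, _ = generate_whisking_data(1, 600, 0.0, gain=0.05, noise_sd=0.1, seed=2)
        score, member = whisking_encoding_score(dff[0], angle)
        assert abs(score) < 0.15 and not member

    def test_exclusion_windows_and_min_samples(self):
        angle, dff, _ = generate_whisking_data(1, 200, 1.0, gain=0.05, noise_sd=0.0, seed=3)
        score, member = whisking_encoding_score(dff[0], angle, exclusion_windows=[(0, 195)])
        assert np.isnan(score) and not member

    def test_membership_separates_coupled_neurons(self):
        """Encoding scores separate coupled from uncoupled neurons (AUC > 0.9)."""
        angle, dff, coupled = generate_whisking_data(60, 1500, 0.5, gain=0.03, noise_sd=0.1, seed=4)
        scores = np.array([whisking_encoding_score(d, angle)[0] for d in dff])
        assert roc_auc(scores[coupled], scores[~coupled]) > 0.9


class TestCompareGroups:
    def test_shifted_groups_detected(self):
        rng = np.random.default_rng(14)
        df = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(20)],
                "group": ["a"] * 10 + ["b"] * 10,
                "day": 1,
                "value": np.concatenate([rng.normal(0, 1, 10), rng.normal(3, 1, 10)]),
            }
        )
        res = compare_groups(df)
        assert res.p_value < 0.05
        assert res.group_means["b"] > res.group_means["a"]

    def test_permuting_labels_destroys_significance(self):
        rng = np.random.default_rng(15)
        values = np.concatenate([rng.normal(0, 1, 8), rng.normal(2.5, 1, 8)])
        labels = np.array(["a"] * 8 + ["b"] * 8)
        sig = 0
        for _ in range(100):
            perm = rng.permutation(labels)
            df = pd.DataFrame(
                {"subject": [f"s{i}" for i in range(16)], "group": perm, "day": 1, "value": values}
            )
            sig += compare_groups(df).p_value < 0.05
        assert sig <= 20

    def test_day_bin_filtering(self):
        df = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2", "s2", "s3", "s3", "s4", "s4"],
                "group": ["a", "a", "a", "a", "b", "b", "b", "b"],
                "day": [1, 9, 1, 9, 1, 9, 1, 9],
                "value": [0.0, 100.0, 0.0, 100.0, 1.0, 100.0, 1.0, 100.0],
            }
        )
        res = compare_groups(df, day_bins=(1, 3))
        assert res.group_means == {"a": 0.0, "b": 1.0}
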