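"""Synthetic trial-structured calcium-imaging experiments.

The generator emulates the statistical structure that the analysis stages
assume, so every stage is testable without recorded data:

* saturating, monotone pulse-count dependence of evoked transient amplitude
  and per-trial response probability, with opsin-expressing neurons stronger
  and more reliable than (indirectly driven) non-expressing neurons;
* trial-to-trial response fluctuations (per-neuron response failures,
  private multiplicative jitter, and a shared per-trial gain);
* across-session drift with a configurable per-class "instability scale"
  that drives three proportional components: a stationary AR(1) day-level
  amplitude multiplier (day-to-day autocorrelation ``drift_day_rho``),
  per-trial private jitter, and per-day turnover (random re-draw of a
  neuron's base amplitude);
* training-related sparsification concentrated in the most responsive
  neurons (amplitude decay rate proportional to amplitude percentile);
* choice coupled, via a logistic model, to the pooled evoked activity of
  strongly responsive non-expressing neurons.

ΔF/F traces are built as frame noise plus single-exponential calcium
transients (GCaMP6s-like, tau = 1.5 s) placed at shutter reopening.
Everything is deterministic given the seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm

from .behavior import permute_pulses
from .datamodel import (
    Experiment,
    InvalidInputError,
    NeuronMeta,
    STAGE_COUNTS,
    SessionRecording,
    TrialRecord,
    classify_opsin,
)

LOW_SIDE = (0, 1, 3)
HIGH_SIDE = (7, 9)


def saturating_curve(pulse_count, halfsat: float) -> np.ndarray:
    """Monotone saturating pulse-count curve, 0 at 0 pulses and 1 at 9.

    ``f(p) = (1 - exp(-p/halfsat)) / (1 - exp(-9/halfsat))``.
    """
    p = np.asarray(pulse_count, dtype=float)
    return (1.0 - np.exp(-p / halfsat)) / (1.0 - np.exp(-9.0 / halfsat))


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic subject.

    Defaults describe a "learner"-regime subject at desk scale; drift
    magnitudes are calibrated only to reproduce qualitative orderings
    (the source recordings carry no quantitative drift parameters).
    """

    # population
    n_expressing: int = 40
    n_non_expressing: int = 80
    n_ambiguous: int = 5
    # schedule
    n_sessions: int = 8
    trials_per_session: int = 60
    stage_schedule: Optional[List[str]] = None  # None -> standard progression
    extreme_weight: float = 8.0  # 1- and 9-pulse presentation weight in late stages
    # imaging geometry
    frame_rate: float = 7.0
    pre_frames: int = 39  # baseline frames preceding shutter closure
    closed_frames: int = 4  # ~505 ms shutter closure at 7 Hz
    post_frames: int = 9
    # response model
    amp_mean_expressing: float = 0.6  # mean evoked transient amplitude at 9 pulses
    amp_mean_non_expressing: float = 0.3
    amp_log_sd: float = 1.0  # per-neuron lognormal amplitude spread
    amp_halfsat_pulses: float = 4.0
    prob_max_expressing: float = 0.75  # per-trial transient probability at 9 pulses
    prob_max_non_expressing: float = 0.45
    prob_sd: float = 0.1
    prob_halfsat_pulses: float = 2.5
    tau_calcium: float = 1.5  # s, single-exponential decay
    noise_sd: float = 0.15  # frame-level ΔF/F noise
    trial_gain_sd: float = 0.05  # lognormal sd of shared per-trial gain
    # drift (per-class instability scale; all three components are lognormal
    # in the scale so a k-fold scale change moves them together)
    drift_sd_expressing: float = 0.25
    drift_sd_non_expressing: float = 0.3
    drift_day_rho: float = 0.9  # day-to-day autocorrelation of the AR(1) multiplier
    drift_jitter_ratio: float = 1.0  # per-trial private jitter log-sd = ratio * drift_sd
    drift_turnover_ratio: float = 0.3  # per-day re-draw prob = ratio * drift_sd
    sparsification_rate: float = 0.0  # per-session decay at the top amplitude percentile
    # behavior
    dprime_start: float = 0.3
    dprime_max: float = 2.5
    dprime_tau_sessions: float = 3.0
    choice_coupling: float = 0.0  # logistic slope on pooled non-expressing activity (z)
    responder_prob_threshold: float = 0.25  # "strongly responsive" ground-truth gate
    ignore_prob: float = 0.02
    early_lick_prob: float = 0.0  # enables licks inside the evoked window
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "amp_log_sd",
            "prob_sd",
            "noise_sd",
            "trial_gain_sd",
            "drift_sd_expressing",
            "drift_sd_non_expressing",
            "drift_jitter_ratio",
            "drift_turnover_ratio",
            "sparsification_rate",
            "choice_coupling",
        ):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be >= 0")
        if not 0.0 < self.drift_day_rho <= 1.0:
            raise InvalidInputError("drift_day_rho must be in (0, 1]")
        for name in ("prob_max_expressing", "prob_max_non_expressing", "ignore_prob", "early_lick_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise InvalidInputError(f"{name} must be in [0, 1]")
        if self.n_sessions < 1 or self.trials_per_session < 1:
            raise InvalidInputError("need at least one session and one trial")
        if self.pre_frames < 1 or self.closed_frames < 1 or self.post_frames < 2:
            raise InvalidInputError("need >=1 pre/closed frame and >=2 post frames")
        if self.stage_schedule is not None:
            if len(self.stage_schedule) != self.n_sessions:
                raise InvalidInputError("stage_schedule length must equal n_sessions")
            for st in self.stage_schedule:
                if st not in STAGE_COUNTS:
                    raise InvalidInputError(f"unknown task stage {st!r}")

    def replace(self, **kw) -> "SyntheticConfig":
        return dataclasses.replace(self, **kw)

    def schedule(self) -> List[str]:
        if self.stage_schedule is not None:
            return list(self.stage_schedule)
        sched = []
        for d in range(1, self.n_sessions + 1):
            if d <= 2:
                sched.append("detect_0v9")
            elif d == 3:
                sched.append("disc_1v9")
            elif d == 4:
                sched.append("disc_13v79")
            else:
                sched.append("full")
        return sched

    def target_dprime(self, session_day: int) -> float:
        """Behavioral sensitivity trajectory (saturating exponential)."""
        return self.dprime_max - (self.dprime_max - self.dprime_start) * np.exp(
            -(session_day - 1) / self.dprime_tau_sessions
        )


@dataclass
class GroundTruth:
    """Latent quantities emitted by the generator, for recovery tests."""

    neuron_ids: List[str]
    opsin_class: np.ndarray  # str per neuron
    q_max: np.ndarray  # per-neuron response probability at 9 pulses
    day_amplitude: np.ndarray  # sessions x neurons effective amplitude (incl. drift)
    trial_gain: List[np.ndarray]  # per session, shared per-trial gain
    latent_evoked: List[np.ndarray]  # per session, trials x neurons transient amplitude
    pooled_drive: List[np.ndarray]  # per session, standardized pooled responder activity
    responder_ids: List[str]  # non-expressing responders used for choice coupling
    choice_coupling: float

    def to_hdf5(self, group) -> None:
        import h5py

        sdt = h5py.string_dtype(encoding="utf-8")
        group.create_dataset("neuron_ids", data=np.array(self.neuron_ids, dtype=object), dtype=sdt)
        group.create_dataset("opsin_class", data=np.array(self.opsin_class, dtype=object), dtype=sdt)
        group.create_dataset("q_max", data=self.q_max)
        group.create_dataset("day_amplitude", data=self.day_amplitude)
        group.attrs["choice_coupling"] = self.choice_coupling
        group.create_dataset(
            "responder_ids", data=np.array(self.responder_ids, dtype=object), dtype=sdt
        )
        for d, (g_, le, pz) in enumerate(zip(self.trial_gain, self.latent_evoked, self.pooled_drive)):
            sg = group.create_group(f"session_{d:03d}")
            sg.create_dataset("trial_gain", data=g_)
            sg.create_dataset("latent_evoked", data=le)
            sg.create_dataset("pooled_drive", data=pz)


def _stage_weights(stage: str, extreme_weight: float) -> Tuple[Tuple[int, ...], np.ndarray]:
    counts = STAGE_COUNTS[stage]
    if stage in ("detect_0v9", "disc_1v9"):
        w = np.ones(len(counts))
    else:
        w = np.array([extreme_weight if c in (1, 9) else (2.0 if c == 5 else 1.0) for c in counts])
    return counts, w / w.sum()


def _make_neurons(cfg: SyntheticConfig, rng) -> Tuple[List[str], Dict[str, NeuronMeta]]:
    """Neuron metadata with red-channel statistics matching the class labels."""
    ids: List[str] = []
    meta: Dict[str, NeuronMeta] = {}
    specs = [
        ("expressing", cfg.n_expressing, (0.6, 0.95), (0.4, 0.9)),
        ("non_expressing", cfg.n_non_expressing, (0.0, 0.15), (0.0, 0.08)),
        ("ambiguous", cfg.n_ambiguous, (0.25, 0.45), (0.12, 0.2)),
    ]
    k = 0
    for cls, n, red_rng, frac_rng in specs:
        for _ in range(n):
            nid = f"n{k:04d}"
            red = float(rng.uniform(*red_rng))
            frac = float(rng.uniform(*frac_rng))
            assigned = classify_opsin(red, frac)
            assert assigned == cls, (assigned, cls)
            meta[nid] = NeuronMeta(
                neuron_id=nid,
                plane=int(rng.integers(0, 3)),
                xy=(float(rng.uniform(0, 800)), float(rng.uniform(0, 800))),
                redness=red,
                red_pixel_fraction=frac,
                opsin_class=cls,
            )
            ids.append(nid)
            k += 1
    return ids, meta


def generate_experiment(
    config: SyntheticConfig, seed: Optional[int] = None, subject_id: str = "synth"
) -> Tuple[Experiment, GroundTruth]:
    """Generate one subject's full experiment plus its latent ground truth."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    neuron_ids, neurons = _make_neurons(cfg, rng)
    n_neurons = len(neuron_ids)
    classes = np.array([neurons[i].opsin_class for i in neuron_ids], dtype=object)
    is_exp = classes == "expressing"
    is_ne = classes == "non_expressing"

    # per-neuron latent response parameters (ambiguous neurons behave like
    # weak non-expressing cells)
    amp_mean = np.where(is_exp, cfg.amp_mean_expressing, cfg.amp_mean_non_expressing)
    base_amp = amp_mean * np.exp(
        rng.normal(-0.5 * cfg.amp_log_sd**2, cfg.amp_log_sd, n_neurons)
    )
    q_mean = np.where(is_exp, cfg.prob_max_expressing, cfg.prob_max_non_expressing)
    q_max = np.clip(q_mean + rng.normal(0.0, cfg.prob_sd, n_neurons), 0.0, 1.0)
    drift_sd = np.where(is_exp, cfg.drift_sd_expressing, cfg.drift_sd_non_expressing)
    jitter_sd = cfg.drift_jitter_ratio * drift_sd
    turnover_p = np.clip(cfg.drift_turnover_ratio * drift_sd, 0.0, 0.5)

    # sparsification decays the largest-amplitude neurons fastest
    order = np.argsort(np.argsort(base_amp))
    amp_percentile = order / max(n_neurons - 1, 1)

    g9 = float(saturating_curve(9, cfg.prob_halfsat_pulses))
    responders = [
        nid
        for nid, ne, q in zip(neuron_ids, is_ne, q_max)
        if ne and q * g9 > cfg.responder_prob_threshold
    ]
    responder_mask = np.array([nid in set(responders) for nid in neuron_ids])

    decay = float(np.exp(-1.0 / (cfg.frame_rate * cfg.tau_calcium)))
    frames_per_trial = cfg.pre_frames + cfg.closed_frames + cfg.post_frames
    schedule = cfg.schedule()

    dev = rng.normal(0.0, 1.0, n_neurons)  # unit-variance stationary AR(1) state
    sessions: List[SessionRecording] = []
    gt_day_amp = np.zeros((cfg.n_sessions, n_neurons))
    gt_gain: List[np.ndarray] = []
    gt_latent: List[np.ndarray] = []
    gt_pooled: List[np.ndarray] = []

    for d in range(1, cfg.n_sessions + 1):
        stage = schedule[d - 1]
        counts, weights = _stage_weights(stage, cfg.extreme_weight)
        if d > 1:
            # turnover: re-draw base amplitude for a drift-scaled fraction
            redraw = rng.random(n_neurons) < turnover_p
            if np.any(redraw):
                base_amp[redraw] = amp_mean[redraw] * np.exp(
                    rng.normal(-0.5 * cfg.amp_log_sd**2, cfg.amp_log_sd, int(redraw.sum()))
                )
            # stationary AR(1) day-level multiplier state
            dev = cfg.drift_day_rho * dev + np.sqrt(
                1.0 - cfg.drift_day_rho**2
            ) * rng.normal(0.0, 1.0, n_neurons)
        # lognormal mean-1 multiplier: exp(sigma z - sigma^2/2)
        day_mult = np.exp(drift_sd * dev - 0.5 * drift_sd**2)
        spars = np.maximum(1.0 - cfg.sparsification_rate * amp_percentile, 0.0) ** (d - 1)
        eff_amp = base_amp * day_mult * spars
        gt_day_amp[d - 1] = eff_amp

        nt = cfg.trials_per_session
        pulse_counts = rng.choice(counts, size=nt, p=weights)
        f_p = saturating_curve(pulse_counts, cfg.amp_halfsat_pulses)
        g_p = saturating_curve(pulse_counts, cfg.prob_halfsat_pulses)
        occur = rng.random((nt, n_neurons)) < (g_p[:, None] * q_max[None, :])
        # mean-1 lognormal private jitter per (trial, neuron)
        jitter = np.exp(
            jitter_sd[None, :] * rng.normal(0.0, 1.0, (nt, n_neurons))
            - 0.5 * jitter_sd[None, :] ** 2
        )
        gain = (
            np.exp(rng.normal(-0.5 * cfg.trial_gain_sd**2, cfg.trial_gain_sd, nt))
            if cfg.trial_gain_sd > 0
            else np.ones(nt)
        )
        # choice couples to the non-expressing-specific component (shared
        # gain excluded), the locus the analyses are designed to detect
        drive = eff_amp[None, :] * f_p[:, None] * occur * jitter
        latent = drive * gain[:, None]
        if responder_mask.any():
            pooled = drive[:, responder_mask].mean(axis=1)
            psd = pooled.std()
            pooled_z = (pooled - pooled.mean()) / psd if psd > 1e-12 else np.zeros(nt)
        else:
            pooled_z = np.zeros(nt)

        # behavior: logistic choice on signed stimulus strength + coupling
        dprime_target = cfg.target_dprime(d)
        p_half = norm.cdf(dprime_target / 2.0)
        alpha = float(np.log(p_half / (1.0 - p_half)))
        s_p = (pulse_counts - 4.5) / 4.5
        p_right = 1.0 / (1.0 + np.exp(-(alpha * s_p + cfg.choice_coupling * pooled_z)))
        u_choice = rng.random(nt)
        u_ignore = rng.random(nt)
        reward_draw = rng.random(nt)  # rewarded side of 5-pulse trials
        u_early = rng.random(nt)
        lick_late = rng.uniform(1.2, 2.0, nt)
        lick_early = rng.uniform(0.2, 0.8, nt)

        dff = np.zeros((n_neurons, nt * frames_per_trial))
        trials: List[TrialRecord] = []
        for t in range(nt):
            start = t * frames_per_trial
            close = start + cfg.pre_frames
            open_ = close + cfg.closed_frames
            dff[:, open_] = latent[t]
            count = int(pulse_counts[t])
            if count in LOW_SIDE:
                rewarded = "left"
            elif count in HIGH_SIDE:
                rewarded = "right"
            else:
                rewarded = "either"
            if u_ignore[t] < cfg.ignore_prob:
                choice, outcome, lick = "none", "ignore", None
            else:
                choice = "right" if u_choice[t] < p_right[t] else "left"
                actual = rewarded if rewarded != "either" else ("right" if reward_draw[t] < 0.5 else "left")
                outcome = "correct" if choice == actual else "incorrect"
                lick = float(lick_early[t] if u_early[t] < cfg.early_lick_prob else lick_late[t])
            trials.append(
                TrialRecord(
                    trial_index=t,
                    pulse_count=count,
                    pulse_bins=permute_pulses(count, rng),
                    rewarded_side=rewarded,
                    choice=choice,
                    outcome=outcome,
                    first_lick_time=lick,
                    shutter_close_frame=close,
                    shutter_open_frame=open_,
                )
            )
        # kernel-convolved transients plus frame noise
        dff = lfilter([1.0], [1.0, -decay], dff, axis=1)
        dff += rng.normal(0.0, cfg.noise_sd, dff.shape)
        sessions.append(
            SessionRecording(
                session_day=d,
                dff=dff,
                frame_rate=cfg.frame_rate,
                trials=trials,
                neuron_ids=list(neuron_ids),
                task_stage=stage,
            )
        )
        gt_gain.append(gain)
        gt_latent.append(latent)
        gt_pooled.append(pooled_z)

    exp = Experiment(subject_id=subject_id, sessions=sessions, neurons=neurons)
    exp.validate()
    gt = GroundTruth(
        neuron_ids=list(neuron_ids),
        opsin_class=classes,
        q_max=q_max,
        day_amplitude=gt_day_amp,
        trial_gain=gt_gain,
        latent_evoked=gt_latent,
        pooled_drive=gt_pooled,
        responder_ids=responders,
        choice_coupling=cfg.choice_coupling,
    )
    return exp, gt


def generate_null_session(
    n_neurons: int,
    n_trials: int,
    noise_sd: float,
    seed: int,
    frame_rate: float = 7.0,
    pre_frames: int = 39,
    closed_frames: int = 4,
    post_frames: int = 9,
    noise: str = "gaussian",
    ar_coef: float = 0.8,
) -> SessionRecording:
    """Pure-noise session with valid trial structure (no stimulus effect).

    All pulse counts appear; ``noise`` selects the frame-noise family
    (``gaussian``, ``lognormal``, or ``ar1``) so percentile-based response
    classification can be calibrated against arbitrary baseline shapes.
    """
    if n_trials < 1 or n_neurons < 1:
        raise InvalidInputError("need at least one trial and one neuron")
    rng = np.random.default_rng(seed)
    frames_per_trial = pre_frames + closed_frames + post_frames
    n_frames = n_trials * frames_per_trial
    if noise == "gaussian":
        dff = rng.normal(0.0, noise_sd, (n_neurons, n_frames))
    elif noise == "lognormal":
        raw = rng.lognormal(0.0, 1.0, (n_neurons, n_frames))
        dff = noise_sd * (raw - np.exp(0.5)) / np.sqrt(np.exp(2.0) - np.exp(1.0))
    elif noise == "ar1":
        eps = rng.normal(0.0, 1.0, (n_neurons, n_frames))
        dff = lfilter([1.0], [1.0, -ar_coef], eps, axis=1)
        dff *= noise_sd * np.sqrt(1.0 - ar_coef**2)
    else:
        raise InvalidInputError(f"unknown noise family {noise!r}")
    all_counts = (0, 1, 3, 5, 7, 9)
    trials = []
    for t in range(n_trials):
        count = all_counts[t % len(all_counts)]
        close = t * frames_per_trial + pre_frames
        if count in LOW_SIDE:
            rewarded = "left"
        elif count in HIGH_SIDE:
            rewarded = "right"
        else:
            rewarded = "either"
        choice = "right" if rng.random() < 0.5 else "left"
        actual = rewarded if rewarded != "either" else ("right" if rng.random() < 0.5 else "left")
        trials.append(
            TrialRecord(
                trial_index=t,
                pulse_count=count,
                pulse_bins=permute_pulses(count, rng),
                rewarded_side=rewarded,
                choice=choice,
                outcome="correct" if choice == actual else "incorrect",
                first_lick_time=float(rng.uniform(1.2, 2.0)),
                shutter_close_frame=close,
                shutter_open_frame=close + closed_frames,
            )
        )
    s = SessionRecording(
        session_day=1,
        dff=dff,
        frame_rate=frame_rate,
        trials=trials,
        neuron_ids=[f"n{k:04d}" for k in range(n_neurons)],
        task_stage="full",
    )
    s.validate()
    return s


def learner_regime_config(**overrides) -> SyntheticConfig:
    """Desk-scale "learner" study conditions for cohort comparisons.

    Detection-stage sessions throughout (9-pulse trials present every day),
    14 training days, and reliable non-expressing responders so the
    cross-day correlation decays gradually rather than being swamped by
    response-failure noise.  The non-learner regime
    (:func:`non_learner_regime_config`) differs ONLY in a 4x non-expressing
    drift scale, isolating the drift manipulation.
    """
    base = dict(
        n_expressing=30,
        n_non_expressing=120,
        n_ambiguous=4,
        n_sessions=14,
        trials_per_session=44,
        stage_schedule=["detect_0v9"] * 14,
        amp_log_sd=0.6,
        prob_max_non_expressing=0.7,
        drift_sd_expressing=0.5,
        drift_sd_non_expressing=0.3,
        choice_coupling=0.0,
        sparsification_rate=0.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def non_learner_regime_config(**overrides) -> SyntheticConfig:
    """Non-learner regime: 4x the learner non-expressing drift scale."""
    overrides.setdefault("drift_sd_non_expressing", 1.2)
    return learner_regime_config(**overrides)


def half_life_config(rho: float, **overrides) -> SyntheticConfig:
    """Pure geometric-drift conditions for cross-day half-life recovery.

    Homogeneous amplitudes, deterministic responses, no jitter/turnover/
    shared gain and low noise, so the day-lag correlation of the population
    vector is (to close approximation) the AR(1) multiplier correlation
    ``rho**lag`` and days-until-R²<0.5 has the analytic target
    ``ceil(ln 0.5 / (2 ln rho))``.
    """
    base = dict(
        n_expressing=0,
        n_non_expressing=300,
        n_ambiguous=0,
        n_sessions=12,
        trials_per_session=40,
        stage_schedule=["detect_0v9"] * 12,
        amp_log_sd=0.0,
        prob_max_non_expressing=1.0,
        prob_sd=0.0,
        drift_sd_non_expressing=0.25,
        drift_day_rho=rho,
        drift_jitter_ratio=0.0,
        drift_turnover_ratio=0.0,
        trial_gain_sd=0.0,
        noise_sd=0.05,
        ignore_prob=0.0,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


def choice_cohort_config(coupling: float = 1.5, **overrides) -> SyntheticConfig:
    """Single final-stage expert session for choice-coupling cohorts."""
    base = dict(
        n_expressing=30,
        n_non_expressing=60,
        n_ambiguous=4,
        n_sessions=1,
        trials_per_session=200,
        stage_schedule=["full"],
        dprime_start=1.0,
        choice_coupling=coupling,
    )
    base.update(overrides)
    return SyntheticConfig(**base)


@dataclass
class CohortMember:
    label: str  # "learner" | "non_learner"
    experiment: Experiment
    ground_truth: GroundTruth


def make_cohort(
    learner_config: SyntheticConfig,
    non_learner_config: SyntheticConfig,
    n_per_group: Tuple[int, int],
    seed: int,
) -> List[CohortMember]:
    """Reproducible cohort of labelled subjects (learners then non-learners)."""
    n_l, n_n = n_per_group
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_l + n_n)
    out: List[CohortMember] = []
    for k in range(n_l):
        child_seed = int(children[k].generate_state(1)[0] % (2**31))
        exp, gt = generate_experiment(learner_config, seed=child_seed, subject_id=f"learner_{k}")
        out.append(CohortMember("learner", exp, gt))
    for k in range(n_n):
        child_seed = int(children[n_l + k].generate_state(1)[0] % (2**31))
        exp, gt = generate_experiment(
            non_learner_config, seed=child_seed, subject_id=f"non_learner_{k}"
        )
        out.append(CohortMember("non_learner", exp, gt))
    return out


def generate_whisking_data(
    n_neurons: int,
    n_frames: int,
    coupled_fraction: float,
    gain: float,
    noise_sd: float,
    seed: int,
    smooth_frames: int = 5,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Whisker-angle trace plus ΔF/F traces linearly coupled to it.

    Returns ``(angle, dff, coupled_mask)``.  The angle is smoothed gaussian
    noise (degrees); coupled neurons carry ``gain * angle`` plus noise,
    uncoupled neurons pure noise.
    """
    rng = np.random.default_rng(seed)
    raw = rng.normal(0.0, 1.0, n_frames + 4 * smooth_frames)
    kernel = np.exp(-0.5 * (np.arange(-2 * smooth_frames, 2 * smooth_frames + 1) / smooth_frames) ** 2)
    kernel /= kernel.sum()
    angle = np.convolve(raw, kernel, mode="same")[2 * smooth_frames : 2 * smooth_frames + n_frames]
    angle = 10.0 * angle / angle.std()
    coupled = rng.random(n_neurons) < coupled_fraction
    dff = rng.normal(0.0, noise_sd, (n_neurons, n_frames))
    dff[coupled] += gain * angle[None, :]
    return angle, dff, coupled
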