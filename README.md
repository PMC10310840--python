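# microstim

Analysis toolkit for chronic two-photon calcium-imaging experiments in
which animals learn to discriminate cortical optical microstimulation.
Mice report the number of LED pulses (0–9, 5 ms at 20 Hz) delivered over an
opsin-expressing cortical patch by licking left (low counts) or right (high
counts); imaging tracks opsin-expressing and non-expressing neurons across
training days.  The package implements the full analysis chain for such
experiments — and a synthetic generator of trial-structured recordings so
the chain can be exercised, calibrated and tested without the original
data.  It is written for systems neuroscientists analyzing trial-aligned
ΔF/F recordings with chronic cross-day neuron tracking.

## What it computes

* **Evoked responses** — per-trial evoked ΔF/F (mean of the two frames
  after shutter reopening), two-tailed percentile responsiveness against
  each neuron's pooled baseline distribution (responsive iff evoked ΔF/F
  exceeds the 97.5th or falls below the 2.5th baseline percentile), and
  baseline z-scoring.
* **Behavior** — sliding 61-trial percent correct and
  d′ = z(hit) − z(false alarm) with 1/(2n) rate clipping; the learner
  criterion (peak windowed d′ ≥ 1.5 on two consecutive sessions, sustained
  at the horizon session); psychometric curves with Wilson intervals.
* **Choice** — right-vs-left evoked contrasts per neuron (Welch t) and
  peak-normalized population curves over strongly responsive neurons
  (response probability > 0.25), with paired across-subject tests.
* **Stability** — within-day trial-pair Pearson matrices over 9-pulse
  population vectors (mean strict upper triangle) and cross-day matrices of
  per-day mean vectors, summarized as days-until-R² < 0.5, where
  R² = r² of the day-pair Pearson correlation.
* **Decoding** — per-neuron ideal-observer ROC/AUC for high (7, 9) vs low
  (0, 1, 3) pulse counts via the rank identity
  AUC = P(high > low) + ½·P(tie); top-5% mean AUC and fraction AUC > 0.75
  per session and opsin class.
* **Light model** — power density in tissue from an 8×8 point-source LED
  grid through Fresnel interfaces, exponential scattering and half-sphere
  spreading.
* **Synthetic data** — saturating pulse-count response curves, distinct
  expressing/non-expressing populations, per-trial response failures and
  gain fluctuations, AR(1) day-level drift with turnover, sparsification,
  and choice coupled to pooled non-expressing activity.  See
  `docs/methods.md` for the model and its deliberate simplifications.

## Worked example

Simulate one subject (8 training days, 60 trials/day, 20 opsin-expressing
and 40 non-expressing neurons, choice coupled to non-expressing activity)
and run every analysis:

```bash
cat > config.yaml <<EOF
simulate:
  n_expressing: 20
  n_non_expressing: 40
  n_ambiguous: 2
  n_sessions: 8
  trials_per_session: 60
  choice_coupling: 1.0
EOF
microstim --config config.yaml --seed 1 --out demo simulate --subject-id mouse1
microstim --config config.yaml --seed 1 --out demo report demo/mouse1.h5
```

`demo/mouse1_behavior.csv` shows the subject crossing the learning
criterion on day 2 (peak windowed d′ 1.37 → 2.61):

```
subject_id,session_day,n_trials,n_included,percent_correct,peak_dprime,task_stage
mouse1,1,60,60,75,1.36967940668,detect_0v9
mouse1,2,60,60,90,2.61451746765,detect_0v9
mouse1,3,60,57,89.4736842105,2.51712746684,disc_1v9
```

`demo/mouse1_decoding_summary.csv` shows the expressing population
decoding the stimulus better than the non-expressing one (day-1 top-5%
mean AUC 0.949 vs 0.880; fraction AUC > 0.75: 0.75 vs 0.15):

```
subject_id,session_day,opsin_class,n_neurons,top5_mean_auc,fraction_auc_above_0p75
mouse1,1,expressing,20,0.948832035595,0.75
mouse1,1,non_expressing,40,0.879866518354,0.15
```

and `demo/mouse1_stability_cross.csv` reports, per start day, how many
days until the squared day-pair correlation drops below one half (day 1:
3 days; censored starts are flagged rather than coerced to numbers):

```
subject_id,opsin_class,start_day,days_until_r2_below_0p5,censored
mouse1,expressing,1,3,False
```

The same pipeline is available as a library (`generate_experiment`,
`compute_response_tensor`, `compute_stability`, `decoding_table`,
`population_choice_curve`, `evaluate_learning_cohort`, ...), returning
numpy arrays and pandas DataFrames.

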