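# eegtau

Detection of voluntary movement intention from EEG using the **relaxation
time of the autocorrelation function** as a single-trial feature,
benchmarked against classical **event-related desynchronization (ERD)**
band power.

## The problem

Movement-based brain-computer interfaces usually detect intention from
band-power changes: the sensorimotor μ rhythm (8–13 Hz) attenuates around
voluntary movement (ERD). Band power, however, ignores how the EEG's
*temporal dependencies* reorganise. During movement preparation the EEG
autocorrelation decays more slowly — the signal stays correlated with its
past for longer — and this change is broadband rather than tied to a
specific frequency. This package implements that temporal-dependence
marker end to end and compares it with ERD, for researchers building or
evaluating asynchronous movement-intention detectors.

## The two features

For each 1 s window (stepped by 100 ms over a −3…+3 s epoch around the
tap), on each bipolar channel:

**Relaxation time τ.** The normalized autocorrelation of the demeaned
window s(0..N−1) is

    R(Δ) = Σₜ (s(t) − s̄)(s(t+Δ) − s̄) / Σₜ (s(t) − s̄)²

an oscillatory, decaying sequence. The decaying exponential

    R(Δ) ~ C e^(−t/τ),   C = 1 (R is normalized)

is least-squares fitted to the positive local maxima of R over the first
half of the positive lags; the decay constant τ (seconds) is the feature.
Large τ = slow decay = long-lived temporal dependence. Fit quality is
reported as R².

**ERD %.** Band-pass, square, upper-envelope smooth; with baseline power
R from −2…−1.5 s and window power A(i),

    ERD(i) = (A(i) − R) / R × 100.

**Classification.** Per channel and window, a two-class linear
discriminant (equal priors, pooled variance) separates tap from rest
trials; sensitivity (true-positive rate) is estimated by 10 repeats of
10 stratified 80/20 shuffle-splits. The chance level is the smallest
k/n with P(X ≥ k) ≤ 0.05 under X ~ Binomial(n, ½); the earliest window
whose sensitivity reaches it gives the detection time (negative =
prediction before movement onset).

The synthetic-data generator provides sessions with closed-form ground
truth: a background AR(2) process resonant at 10 Hz whose pole radius ρ
switches from 0.99 to 0.995 inside the intention interval (−0.5…+1 s) —
its autocorrelation envelope is ρ^Δ, so τ = −1/(fs ln ρ) exactly — plus a
μ rhythm whose amplitude drops to 0.5 during movement (ERD), plus white
noise. See `docs/methods.md` for every modelling choice.

## Worked example

```python
import eegtau

cfg = eegtau.SynthConfig(
    channel_labels=("C3", "P3"),
    n_trials_per_condition=40,
    conditions=("right", "rest"),
    seed=2,
)
rec, events = eegtau.generate_session(cfg)
trials = eegtau.preprocess_session(
    rec, events, scheme=eegtau.BipolarScheme((("C3", "P3"),))
)
feats, curves, threshold, best, det = eegtau.analyze_session(
    trials, feature="acf", band="wide", scheme=eegtau.CvScheme(seed=2)
)
print(f"chance threshold : {threshold:.2f}")
print(f"best channel     : {best}")
print(f"peak sensitivity : {det.peak_sensitivity:.3f} at t = {det.peak_time:+.1f} s")
print(f"first crossing   : {det.first_crossing_time:+.1f} s")
report = eegtau.tau_tap_vs_rest_test(feats)
print(f"tau tap vs rest  : t = {report.statistic:.2f}, p = {report.p_value:.2g}")
```

prints

```
chance threshold : 0.65
best channel     : C3-P3
peak sensitivity : 0.685 at t = +0.8 s
first crossing   : -0.7 s
tau tap vs rest  : t = 3.55, p = 0.00071
```

Read: with 40 tap trials the binomial chance level is 26/40 = 0.65; the
cross-validated sensitivity of the τ feature peaks at 0.685 shortly after
the tap and first exceeds chance 0.7 s *before* the registered onset —
the relaxation time carries predictive movement information. The Welch
t-test confirms that per-trial mean τ around the onset separates tap from
rest (p < 0.001). Individual seeds vary; across 20 simulated sessions the
mean detected crossing is about −0.4 s.

## Command line

```bash
eegtau simulate --out sim/ --seed 1            # EDF + events TSV
eegtau preprocess --recording sim/recording.edf --events sim/events.tsv --out pre/
eegtau features --epochs pre/ --feature acf --band wide --out tau.tsv
eegtau classify --out run/ --seed 1 --feature acf --band wide
eegtau cohort --out cohort/ --participants 8 --feature acf
```

`simulate` writes a standard 16-bit EDF; `classify` and `cohort` write
TSV curves, JSON summaries and the group statistics (Wilcoxon signed-rank
band comparisons with Holm–Bonferroni correction).

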