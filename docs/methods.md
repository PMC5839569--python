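# Methods

This note records the models, conventions and numerical choices behind
`eegtau`, and what the synthetic validation does and does not establish.

## Preprocessing

Filtering uses 4th-order Butterworth designs applied forward–backward
(`scipy.signal.sosfiltfilt`), i.e. zero phase and effective order 8:
0.5 Hz high-pass (DC/drift), 48–52 Hz band-stop (line noise; "notch at
50 Hz" realised as a ±2 Hz stop band), 60 Hz low-pass. The per-channel
mean is subtracted after filtering. Filtering and the bipolar montage are
both linear, so they commute (tested to 1e−6). Causal/online filtering is
out of scope.

The longitudinal bipolar montage over the nine motor channels is
F3−C3, Fz−Cz, F4−C4, C3−P3, Cz−Pz, C4−P4; each derived channel is anode
minus cathode. Epochs span 3 s either side of the tap onset and are
demeaned per trial and channel (whole-trial mean — the demeaning exists
to zero the trial, not to baseline-correct a sub-interval). Events whose
epoch would run off the recording are dropped with a logged warning, not
padded: padding would distort autocorrelation estimates.

Sample-index convention: time t maps to sample round(t·fs); the window
ending at t is the half-open slice of round(1 s·fs) samples starting at
round((t−1+pre)·fs). For a [−3, +3] s epoch the end-time grid is
−2.0, −1.9, …, +3.0 (51 windows); every feature at time t is computed on
[t−1, t], so a feature "at" t uses only data up to t.

An ICA-style artefact cleaner can be plugged in as a pre-epoching
`Recording -> Recording` transform (`epoch_trials(transform=...)`);
the default is identity.

## Relaxation time τ

Per window: demean, normalized autocorrelation (biased estimator, FFT
implementation checked against the double-loop definition to 1e−10),
collect the anchor (0, 1) plus all strictly positive local maxima of
R(Δ) for 1 ≤ Δ ≤ floor(N/2) (plateaus count once, at their first sample),
then fit e^(−t/τ) with C fixed at 1 by minimising the SSE over
τ ∈ [1e−4, 10] s. The minimiser is a 400-point log-spaced grid scan
followed by bounded scalar refinement (xatol 1e−9), so the global minimum
is found; it agrees with a 10⁵-point grid search to 1e−4 on noisy
fixtures. R² = 1 − SSE/SST with SST about the mean of the fitted points
(anchor included); it can be negative for a terrible fit, and the
invariant 0 ≤ R² ≤ 1 is only guaranteed for well-posed fits. Windows with
fewer than three fit points, zero variance, or a failed optimisation are
flagged invalid; a trial is excluded from classification when more than
half its windows are invalid.

**Known estimator bias at 1 s windows.** For a narrowband process with
relaxation time τ₀ ≈ 0.1–0.2 s, a 1 s window spans only 5–10 e-folding
times. The sample ACF of such a short window is quasi-periodic: its local
maxima at mid-to-long lags sit well above the ensemble envelope ρ^Δ, and
selecting *positive maxima* rectifies estimation noise upward. The fitted
τ on 1 s windows is therefore biased high — simulation shows a median
ratio to the closed form of ≈ 1.3–1.4 at ρ = 0.99 and ≈ 1.05 at
ρ = 0.995, converging as the window grows (≤ 8% error at 32 s windows,
which is how the closed-form recovery is validated). The bias is shared
by movement and rest windows; the *contrast* in τ, which classification
uses, survives it, and median τ remains strictly increasing in ρ at 1 s
windows. Consequence for interpretation: absolute τ values from 1 s
windows overstate the true relaxation time of the underlying process.

## ERD

Band power via the envelope method: square the band-passed signal, then
interpolate linearly through the strict local extrema of the squared
signal (endpoints included). Single-trial ERD uses the upper envelope;
the grand average uses the mean of upper and lower envelopes of the
trial-averaged power, which suppresses spurious peaks. The single-trial
baseline R is the envelope mean over −2.0…−1.5 s *of the same trial*;
with fewer than two interior extrema the squared signal is used as-is.

The grand-average variant subtracts the pointwise cross-trial mean of
the band-passed signal before squaring (evoked-activity removal) — the
intertrial-variance reading, which is the only one that does not zero
the average; all-identical trials therefore produce a degenerate baseline
and an explicit error rather than a 0/0.

ERD is scale invariant by construction, and responds quadratically to
amplitude: a gain a on the μ waveform gives (a² − 1)·100 percent at
windows fully inside the gain plateau. With the default gain timeline
(ramp from −0.5 s, hold over [0, +1] s) the only fully-plateau 1 s
window is the one ending at +1.0 s; earlier windows straddle the ramp
and report shallower ERD.

The ERSP view computes per-trial spectrograms (0.5 s Hann segments, 90%
overlap, power scaling — chosen to match the 100 ms feature grid),
averages within condition, and reports movement minus rest in dB over
0.5–60 Hz.

## Classification and detection

The univariate two-class LDA with equal priors and pooled variance
reduces in closed form to the midpoint rule: classify to the nearer class
mean, boundary at the midpoint. That closed form is the implementation
(verified against an independent pooled-covariance LDA on seeded data);
when the class means coincide the posterior is exactly ½ and test points
are assigned by a seeded coin flip, so uninformative features score ~0.5
rather than collapsing to one class.

Cross-validation: 10 repeats × 10 stratified shuffle-splits at 80/20.
The stated 80/20 fractions are honoured rather than strict 10-fold
(which would imply 90/10); sensitivity is pooled over the splits of a
repeat, then averaged over repeats (sd across repeats reported). The CV
seed is offset per window (base + 1000·window index) so windows are
reproducible but decoupled. Trials with an invalid feature at a window
are dropped from that window only.

The chance threshold is the smallest k/n with P(X ≥ k) ≤ α for
X ~ Binomial(n, ½) — chance success probability ½ for a balanced
two-class problem, α = 0.05. n is the number of tap trials. Detection
time is the earliest grid end-time whose sensitivity reaches the
threshold; sessions that never cross have no detection time. The most
responsive channel maximises peak sensitivity, ties broken by earlier
peak, then montage order.

## Group statistics

Per participant, tap vs rest is tested with Welch's two-sample t-test on
per-trial mean τ over the onset windows (end-times in [−0.5, +1.0] s,
configurable). Across participants, peak sensitivities of the four bands
(0.5–8, 8–13, 13–30, 0.5–30 Hz) are compared pairwise (6 pairs) with the
paired Wilcoxon signed-rank test — Pratt handling of zero differences,
exact distribution for ≤ 25 pairs without zeros, normal approximation
with continuity correction otherwise — with Holm–Bonferroni correction
over the 6 p-values. The two feature families are compared by a single
Wilcoxon over participant × band pairs pooled. A simulated "cohort" is a
set of independently seeded sessions standing in for participants.

## The synthetic generator

Each channel is `amplitude_uv` × (background + μ + noise):

* **Background**: AR(2) with poles ρ·e^(±i·2π·f_osc/fs)
  (a₁ = 2ρcosθ, a₂ = −ρ²), resonant at f_osc = 10 Hz. Its ACF is a damped
  cosine with envelope ρ^Δ, hence relaxation time τ = −1/(fs·ln ρ) —
  the closed-form ground truth. In movement trials the pole radius
  switches ρ_rest = 0.99 → ρ_move = 0.995 inside the intention interval
  (−0.5…+1.0 s); the AR state carries across the switch (no signal
  discontinuity) and innovations are rescaled so the stationary variance
  is identical for both radii. The switch therefore changes temporal
  dependence, not power — the pole switch and the ERD are independent
  dials.
* **μ rhythm**: by default a second AR(2) at f_osc with fixed pole radius
  ρ_rest; for noise-free ERD fixtures a random-phase sinusoid
  (`mu_kind="sinusoid"`). Its waveform is multiplied by the ERD gain:
  1 → erd_scale (default 0.5) linearly over −0.5…0 s, held over 0…+1 s,
  recovered by +1.5 s. Power scales exactly with gain², giving the
  quadratic ERD law.
* **Noise**: white, sd 0.1 of the unit-variance components (≈ 1 µV on a
  10 µV signal — realistic amplifier noise after filtering). An optional
  shared source (`mixing`) is added equally to all channels so the
  bipolar montage demonstrably suppresses common background.

Trials of the configured conditions are laid out in seeded-random order
with uniform 1–1.5 s gaps between epochs. Identical config and seed give
bit-identical output.

Default sizes are a single participant's session: 1024 Hz, 9 motor
channels (or any subset), 40 trials per condition, 6 s epochs. The ρ
contrast 0.99 → 0.995 roughly doubles τ (0.097 → 0.195 s) and was chosen
for a clear but not trivial effect: per-window discrimination is AUC
≈ 0.7, so peak cross-validated sensitivities land in the high 0.60s,
just above the n = 40 chance level of 0.65 — deliberately in the regime
where detection is possible but not saturated.

**What the generator does not emulate**: 1/f broadband background
spectra away from the resonance, eye-blink/EMG artefacts, evoked
(phase-locked) responses, scalp volume conduction and realistic
topographies, lateralisation of the μ ERD, participant heterogeneity
beyond the seed. Passing the synthetic validation shows the estimators
and the decision chain are correct under the stated model; it does not
by itself establish effect sizes on recorded EEG.

One structural caveat: because the background resonates at the same
10 Hz as the μ rhythm, the pole-radius switch also reshapes the
background's spectrum (same variance concentrated into a narrower peak),
which perturbs off-peak spectral density in the movement-minus-rest
spectrogram. The μ-specific ERSP dip is therefore validated on ERD-only
sessions (ρ_move = ρ_rest), where the band-power pathway is isolated.

## Validation problem sizes

The validation suite uses: 100 random windows for the ACF definition;
50 noisy fixtures against a 10⁵-point grid search for the fit; 200
windows of 32 s for closed-form τ recovery and 200 windows of 1 s per ρ
for monotonicity; 20 trials per condition for the ERD law; 20 seeded
sessions (40 tap + 40 rest each, one bipolar pair) for end-to-end
detection; 3 null sessions, 3 label shuffles and 200 summary-level null
cohorts for the null controls. The single-pair sessions use C3/P3 — the
channel pair where the aggregate τ build-up is clearest — and keep the
stated trial counts, sampling rate and effect sizes.
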