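# Methods

`painhfa` analyzes how broadband high-frequency activity (HFA, 70–150 Hz)
in stereo-EEG recordings relates to a participant's evaluation of a tonic
thermal pain stimulus. This note documents the models and procedures the
package implements, the assumptions behind them, and the choices made
where the design was genuinely open.

## Task and data model

A trial consists of ten seconds of contact between the hand and a
thermoelectric surface, followed by a binary report ("was that
painful?") and a graded 0–10 rating (VAS). Stimulus temperature is
selected per trial by an adaptive Bayesian staircase so that it hovers
near the participant's pain threshold. Recordings are continuous
multichannel LFPs (µV) sampled at 1 kHz with per-contact anatomical
labels; contacts collapse to gyral regions by keeping the token before
the first underscore of the atlas label (hemisphere and subdivision
dropped). White-matter contacts are excluded, and a region enters group
analysis only when at least three unique patients carry contacts there —
re-checked after artifact rejection, since rejection can empty a
patient's contribution.

## Preprocessing

The pipeline runs, in order: artifact detection on raw µV epochs,
common-median re-referencing, epoch extraction, downsampling to 500 Hz.

Four rejection rules with fixed thresholds flag (trial, channel)
epochs: 60 Hz Welch power above 100 µV²/Hz (1 s Hann segments, 50%
overlap, chosen for ~1 Hz resolution at both 1 kHz and 500 Hz);
maximum slope above 300 µV/ms at native resolution; variance below
1 µV²; any sample at the amplifier saturation code (±6553 µV). A fifth,
robust rule flags spike/epileptiform outliers: per channel, each
retained epoch is summarized by its peak absolute deviation from the
channel median, and an epoch is rejected when that peak exceeds the
median of the peaks by more than three scaled MADs (1.4826 × raw MAD,
the normal-consistent convention). The peak-based reference population
is essential: a rule applied to individual samples of continuous noise
would reject virtually every epoch, because the maximum of a few
thousand samples always exceeds 2–3 robust SDs.

Detection runs **before** re-referencing because two rules are only
meaningful on raw code values: a flat channel acquires the (negated)
common median after referencing, and the saturation plateau no longer
equals ±6553 µV once the median is subtracted. The mask is carried onto
the referenced epochs; rejected epochs never enter any statistic.

Epochs are extracted from −3100 to +1100 ms around the hand-on and
hand-off events: 100 ms wider on each side than the statistical span so
that the −3000..−2000 ms baseline and the latest 500–1000 ms analysis
window are clear of filter edge transients (the outer 100 ms margin is
excluded from every statistic).

## HFA extraction

Per epoch and channel: 4th-order Butterworth bandpass 70–150 Hz applied
forward–backward (zero phase), magnitude of the analytic (Hilbert)
signal, 300 ms centered moving average (the window shrinks at epoch
edges), then z-scoring of the whole epoch against the mean and SD of
the −3..−2 s pre-event baseline, per trial and channel. Smoothing
precedes z-scoring. Baselines with zero SD are flagged and excluded.
Because every step from referencing to z-scoring is linear or
scale-free, the z-scored output is invariant to global amplitude
scaling.

## Window models

The analysis tiles 500 ms windows stepping by 250 ms: (−250, 1000) ms
around hand-on and (−1000, 1000) ms around hand-off. For each region,
event and window, the feature `A` is the mean z-scored envelope over
the window, then over the patient's retained contacts in the region,
one row per trial. Two mixed models are fitted per window:

    y ~ 1 + A + (1 + A | temperature) + (1 + A | patient)

with a binomial (logit) family for the binary report and a gaussian
(identity) family for the VAS rating. Temperatures rounded to 0.1 °C
form the levels of the temperature factor. Random effects are crossed,
with independent intercept and slope variances per factor.

### Estimation

The solver (`painhfa.glmm.MixedGLM`) maximizes the Laplace
approximation to the marginal likelihood: penalized IRLS solves for the
fixed effects and random-effect modes jointly at fixed variance
components, and a derivative-free Nelder–Mead search optimizes the log
standard deviations (plus the residual SD for the gaussian family).
This is the estimator lme4's `glmer` uses at `nAGQ=0`, and the two
agree to three decimals on test fixtures; the gaussian solver is
likewise checked against statsmodels MixedLM with crossed variance
components. The solver is written in-package because the permutation
procedure needs on the order of 10⁴–10⁵ refits per analysis, and a
warm-started refit at fixed variance components costs ~1–2 ms — two
orders of magnitude faster than the general-purpose alternatives.
Standard errors are Wald, conditional on the estimated variance
components; quasi-complete separation (|linear predictor| > 20) and
inner-solver failures are flagged.

### Permutation significance

Responses are shuffled **within patient** (keeping `A`, temperature and
patient identity fixed, thereby preserving per-patient base rates and
the random-effect structure under the null) and the model refit
`n_perm` times (1000 by default). Fixed effects and random-effect modes
are re-estimated per permutation; the variance components are held at
the observed-data estimates, because re-optimizing them per permutation
costs 30–100 ms each and changes the pseudo-t by a second-order amount
— the real t is computed at the same variance components, preserving
exchangeability to first order (`refit_variance=True` restores the full
re-optimization). Non-converged refits are dropped and logged; a result
is marked unreliable when more than 10% drop.

The real t is significant when outside the 2.5–97.5 percentile range of
the pseudo-t null. The two-sided p-value counts pseudo-t values more
extreme than the real t *in the tail matching its sign* (a literal
"greater than" count breaks for negative coefficients), floored at one
count: p = 2·max(c, 1)/n_perm, so the smallest attainable p is 0.002 at
1000 permutations. Note the percentile-bounds rule has exact level
2·(0.025·(n−1)+1)/(n+1) under exchangeability — about 5.9% at 200
permutations, converging to 5% as n grows — which the calibration test
accounts for.

No multiple-comparison correction is applied across regions or windows;
each window test stands alone.

### Accuracy and interpretation

Binary-model accuracy is the misclassification percentage of the fitted
conditional probabilities at the 0.5 threshold (lower is better). VAS
accuracy is reported as mean absolute error plus a fitted-vs-real
scatter with Spearman correlation, since no parametric accuracy formula
is uniquely implied for the graded response. A binomial coefficient β
is read as 100·β percent change in the proportion of "yes" responses
per z unit of HFA — a linear reading of the logit slope, most accurate
near probability 0.5 and documented as such.

## Synthetic studies

The generator produces complete studies with known ground truth so that
every stage can be validated without patient data.

**Behavior.** The staircase is exact grid Bayes: a uniform prior over
candidate thresholds (40–48 °C, 0.5 °C steps by default), a logistic
psychometric likelihood of assumed slope 2 /°C, and proposals at the
posterior-mean threshold snapped to the grid. The observer follows a
signal-detection formulation: percept x = T − threshold + ε with
ε ~ Logistic(0, 1/slope), report "painful" iff x > 0 (marginally this
is exactly the logistic psychometric), VAS = gain·max(0, x) plus
gaussian reporting noise, clamped to [0, 10] and rounded to integers,
and a latent pain drive logistic(slope·x) shared by both reports and
the neural effect. The shared percept matters: were the latent drive a
deterministic function of temperature, the report would be independent
of the neural signal given temperature, and a model with temperature
random effects would correctly estimate a null slope. Default observer
thresholds are N(44.5, 1) °C clipped to the grid; with the staircase
hovering near threshold, most VAS ratings land in 0–4. Lapse rate
defaults to 0.02.

**Recordings.** Background is 1/f noise (40 µV SD, 0.3 Hz floor) plus a
5 µV 60 Hz line component (safely below the rejection threshold),
synthesized in the frequency domain and split into its 70–150 Hz
component and the remainder. Event-locked effects multiply the band
component by a gain 1 + effect·latent·(v₀/m₀) inside the configured
windows (50 ms cosine ramps), where m₀ and v₀ are the mean and typical
within-1-s SD of the smoothed envelope, measured once on a background
realization processed with the same chain as the pipeline (decimation,
filter, Hilbert, smoothing). This calibration makes a requested
"1 z-unit per unit latent pain" effect appear as approximately that
shift in the pipeline's own z units; the 300 ms smoothing attenuates
windows overlapping the effect edges by a predictable factor (about
0.85 for an interior 500 ms window). Trials occupy fixed slots of
10 s stimulation + 5 s inter-trial interval, with the hand-on event
placed so the −3..−2 s baseline always falls inside the preceding
interval; total duration is exactly n_trials × 15 s.

**Artifacts.** Each injected artifact exceeds its rejection threshold
by a configurable margin (default 3×): epoch-wide 60 Hz noise and flat
segments (covering the full extraction span), one-sample steps above
300 µV/ms, 100 ms plateaus at exactly ±6553 µV, and smooth 25 ms-SD
bumps sized from the channel's own peak statistics so they trip the
MAD rule but not the slope rule. Every injection is logged with
location, enabling recall/false-positive scoring.

**What the generator does not emulate.** Real sEEG features absent
here: spatial correlation between neighboring contacts, non-stationary
background spectra, true epileptiform morphology (spikes are smooth
bumps), reference-electrode drift, and any physiological structure in
regions other than the injected effects. Passing tests therefore show
the pipeline recovers what it is designed to recover under realistic
noise levels — not that any particular patient-level neuroscience
finding would replicate.

## Validation sizes and tolerances

The test suite uses, as the package's own validation design: type-I
calibration on one null study (20 patients × 20 trials, 16 regions, 352
region×window×family tests at 200 permutations) with the rejection
count checked against the binomial band at the procedure's exact finite
permutation level; parameter recovery over 100 studies (20 patients ×
20 trials, three effect-region contacts — the cohort's own ITG
sampling density) with 95% Wald intervals required to cover the
large-sample reference estimate (from a 100-patient run) at ≥90%;
artifact recall 1.0 with false positives <5% on a four-patient study
with two artifacts of each kind per patient. Numerical tolerances:
envelope oracle 2% against an analytic sine, z-scored baselines
standardized to 1e-6, scale invariance to 1e-9, OLS/GLM degenerate
reductions to 1e-6.

## Known limitations

- The binomial SEs are conditional Wald; with ~20 patients they
  undercover slightly relative to profile or bootstrap intervals.
- Holding variance components fixed across permutation refits is an
  approximation; it is exact under the null only asymptotically.
- The gaussian model for the 0–10 rating ignores the bounded support;
  fitted conditional responses can leave the scale.
- Negative effect sizes are supported only down to complete suppression
  of the band component's modulated fraction (the gain is floored at
  0.05).
- QUEST is simplified to exact grid-based updating with a logistic
  psychometric; proposals use the posterior mean, not expected
  information gain.
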