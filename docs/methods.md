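# Methods

`pitchmimic` implements a complete simulation-and-analysis pipeline for a
two-modality pitch-imitation experiment: participants hear short melodies and
reproduce them either by singing or by whistling, and the question is how
accurate and how precise each production system is. Because the package ships
no human recordings, every stage is exercised against a generative model of
imitation performances whose parameters are known, so the analysis chain can
be validated by parameter recovery rather than by re-measuring people.

## Stimuli

**Composition.** A melody is a sequence of five chromatic scale degrees. The
first note is uniform over the chromatic degrees 0–11; each subsequent
interval is uniform over the integers −4…+4 semitones; a candidate melody is
accepted only if all notes lie within one octave (degrees 0–12), otherwise
the whole melody is redrawn. Whole-melody rejection (rather than redrawing
the offending note) was an open choice; it is the simpler scheme with a
well-defined stationary distribution. Rejection biases the accepted sample
toward smaller spans, but in the unconstrained two-note case the interval
distribution is exactly uniform, which the tests exploit as an oracle. A
repeated note (interval 0) is permitted. Each study uses two independent
45-melody sets, one per modality.

**Registers.** Scale degree `d` maps to frequency `root · 2^(d/12)`. Sung
stimuli use roots of 110 Hz (A2, male) or 220 Hz (A3, female); whistled
stimuli use 880 Hz (A5). Each register spans exactly one octave.

**Synthesis.** Whistle-timbre stimuli are sine tones of 750 ms separated by
50 ms of silence, written as 44.1 kHz / 16-bit PCM WAV. The onset envelope is
parametric — raised-cosine attack (default 40 ms), unit sustain, 10 ms
raised-cosine release — because the empirical whistle-onset envelope it
stands in for is not recoverable; the envelope shape is acoustically
immaterial to scoring, which only consumes F0. "Equal sound pressure" is
implemented as equal peak level across notes.

## Generative model of imitation

All pitch quantities live on the cents scale relative to the task register's
root (0 = degree 0, 1200 = the octave). A produced note is

    produced = target + bias_m + γ_m · (habitual_m − target) + ε_perc + ε_motor,m

- `bias_m` (cents): constant flat/sharp offset per modality.
- `γ_m ∈ [0,1)`: linear compression toward the modality's habitual pitch
  ("vocal laziness"). It generates the flat-at-high / sharp-at-low error
  profile, with slope −γ of error on target pitch.
- `ε_perc ~ N(0, σ_perc²)`: perceptual/memory noise, one SD per participant
  **shared by both modalities** — the shared stage of the
  propagation-of-error account, and the only mechanism coupling singing and
  whistling performance.
- `ε_motor,m ~ N(0, σ_motor,m²)`: modality-specific motor-execution noise.

Gaussian noise on the cents scale is an assumption of convenience (cents is
the analysis scale; no distributional form is implied by the design). With
probability `p_octave_error` a note additionally jumps ±1200 cents, so the
>1000-cent verification rule has real work to do. Per note, with probability
`p_omit` the note is dropped and with `p_duplicate` it is produced twice
(each copy independently noised); these trials exercise the wrong-note-count
exclusion. The defaults `p_omit = p_duplicate = 0.0037` make the total
per-note count-changing probability 0.0074, i.e. an expected
`1 − (1 − 0.0074)^5 ≈ 3.6 %` of trials excluded, matching the exclusion rate
the design anticipates.

**Population.** A cohort draws each participant's parameters from Normal
population distributions (SD-like parameters truncated at 0, γ clipped to
[0, 0.95]). The defaults describe a 28-participant cohort in which singing
is noisier and more strongly compressed than whistling, habitual singing
pitches sit low in the stimulus octave and habitual whistling pitches high,
sung bias is flat and whistled bias sharp:

| parameter | sing | whistle | units |
|---|---|---|---|
| habitual pitch | N(300, 200) | N(900, 200) | cents |
| producible range low | N(−300, 200) | N(−300, 200) | cents |
| producible range high | N(1500, 200) | N(1500, 200) | cents |
| motor noise SD | N(70, 18) | N(25, 8) | cents |
| bias | N(−50, 30) | N(+30, 20) | cents |
| compression γ | N(0.25, 0.08) | N(0.10, 0.05) | — |
| perceptual noise SD | N(60, 35) (shared) | | cents |

These are stipulated defaults, not estimates: they were chosen once so that
the simulated cohort's geometry is the one the pipeline is meant to detect —
sung imprecision exceeding whistled imprecision by a few tens of cents,
discrimination scores with mean ≈ 88 % and SD ≈ 7–9 %, and singing/whistling
imprecision that remains positively correlated after controlling for
perceptual ability (because motor noise, not only perception, varies across
people). The producible-range defaults deliberately leave a small fraction
of participants unable to reach the top of the stimulus octave so the
range-exclusion rule is exercised.

**Perceptual covariate.** The melodic-discrimination battery is simulated as
90 same/different trials in three 30-trial difficulty levels (transpositions
of 300, 150, 50 cents). Per trial, P(correct) = logistic(Δ/σ_perc), which
runs from 1 (σ→0) to chance 0.5 (σ→∞); the score is percent correct over the
binomial draws. The binomial trial noise is what makes the covariate an
imperfect readout of σ_perc — as any finite test of perception is — and is
the reason partialling it out does not annihilate the shared variance.

**What the simulator does not emulate.** Vibrato, drift within a note,
respiratory dynamics, attention lapses, learning across trials, and any
nonlinearity of compression near the range edges. Passing tests therefore
show that the analysis chain recovers the truth of *this* model, not that
the model is a complete account of human imitation.

## Scoring

`cents(f, ref) = log2(f/ref) · 1200`, referenced to the register root. Note
error is produced − target; interval error is the difference of adjacent-note
differences. F0 of recorded audio is estimated from the central 250 ms of
each note window by unbiased autocorrelation: first confident peak (>0.5) in
the 50–2500 Hz lag range, parabolic interpolation, then refinement at the
highest in-range multiple of the period (clean-tone error < 0.3 cents;
unvoiced segments are flagged rather than valued).

Exclusions: trials with ≠ 5 produced notes (alignment of omitted/duplicated
positions is undefined — alignment is positional and only valid at the full
count), and trials whose *target* contains any note outside the
participant's producible range for that modality. Every exclusion carries a
machine-readable reason.

- **Inaccuracy** = mean signed error (cents).
- **Imprecision** = unweighted mean, across pitch classes, of the
  within-class sample SD (ddof = 1) of errors. Pitch class is the target's
  chromatic degree (0–12) for notes and the signed target interval in
  semitones (−4…+4) for intervals; classes with < 2 observations are
  dropped. Weighting classes by count, and n vs n−1, were open choices; the
  unweighted/n−1 convention is fixed and tested against a two-pass oracle.
- Notes with |error| > 1000 cents are flagged and annotated with their
  nearest-octave-corrected residual. They are **kept** by default (the rule
  is a verification, not a filter); an octave-correction mode folds them to
  the nearest octave and is used wherever injected octave errors would
  otherwise contaminate noise estimation (parameter recovery, and the
  replicated sign-pattern experiment, whose interval imprecision
  correlations are visibly attenuated by ±1200-cent outliers that each hit
  two adjacent intervals).

Under this scoring, the generative model implies the identities the tests
assert: a noiseless performer scores 0 everywhere; a pure transposition
moves note inaccuracy one-to-one and leaves interval scores at 0; note
imprecision estimates `√(σ_perc² + σ_motor,m²)` up to the small-sample SD
shrinkage factor c4(n); note inaccuracy estimates
`bias_m + γ_m(habitual_m − mean target)`. Because compression is linear and
interval scores are transposition-invariant, the model predicts **zero**
expected modality effect on interval inaccuracy — an effect a real cohort
may show for reasons outside this model.

## Inference

Scores are analysed in long format (one row per participant × modality) with
random-intercept linear mixed models: `score ~ modality + MBEA + (1 |
participant)`. Effects are tested by dropping one fixed effect at a time;
the reported F is the Wald F of the dropped single-df coefficient from the
REML fit, with a between-within (containment) denominator df — within-
participant terms get `N − n_participants − p_within` df, between-
participant terms `n_participants − p_between − 1` (≈ 26–27 here, close to
what a Kenward–Roger adjustment yields for this balanced design; the nested
ML likelihood-ratio statistic is carried alongside as a diagnostic). The
fixed-effect estimates are cross-checked in the tests against an independent
lme4/lmerTest fit.

Estimates are reported 2-SD standardized: inputs centred and divided by
twice their population SD, so the estimate is the expected outcome
difference between predictor levels 1 SD below and above the mean; for the
balanced binary modality contrast this equals the raw between-condition
difference exactly. CIs are percentile intervals from a cluster bootstrap
(default 1000 iterations) that resamples whole participants — row resampling
would break the random-intercept structure. Partial correlations residualize
both scores on the controls and correlate the residuals (t-test on
`n − k − 2` df); the implementation is verified against the recursion
formula and against `pingouin`. The post-hoc model regresses per-
participant × modality × pitch-class mean errors on modality, target pitch
and their interaction (all 2-SD standardized) with a participant random
intercept; a negative pitch slope is the compression signature and a
positive interaction (whistle coded high) means compression is stronger for
singing.

Degenerate inputs: zero-variance predictors raise; near-zero random-
intercept variance is reported as a `singular` flag rather than an
exception; bootstrap refit failures are skipped and counted, and an
all-failure resample set raises.

## Parameter recovery and calibration

`recover_parameters` simulates replicate cohorts, octave-corrects errors,
and estimates per participant × modality: γ as minus the OLS slope of note
error on target cents, bias as the intercept minus γ̂ · habitual (habitual
pitch is known ground truth in the simulation, as it would be measured
directly in a real study), and the effective noise SD as the imprecision
score with each class SD divided by c4(n). It reports the bias and RMSE of
each estimator. At the default design (28 × 45 trials) all estimators are
unbiased within Monte-Carlo error; the effective-SD estimator retains a
small (~1 %) residual inflation from octave jumps that noise pushes back
under the 1000-cent threshold, visible only at large replicate counts.

Type-I calibration of the modality test is checked by simulating score
tables directly from the random-intercept model with no modality gap — the
cleanest probe of the test itself, uncontaminated by generator structure —
at 1000 replicates against a binomial band around 5 %.

## Problem sizes

Default analyses use the full study design (28 participants × 90 trials ×
5 notes ≈ 12,600 notes). The test suite validates the replicated claims at
200 simulation replicates (sign pattern), 1000 replicates (type-I
calibration), and 10,000 melodies (composer constraints); the parameter-
recovery driver uses 10 replicate cohorts. These sizes give Monte-Carlo
standard errors comfortably below the effect magnitudes being checked.

## Known limitations

- The between-within df rule is an approximation; small-sample p-values can
  differ slightly from Kenward–Roger (the paper-standard adjustment) in
  unbalanced designs.
- The F0 estimator targets clean, near-periodic tones; it is not a
  substitute for a production pitch tracker on breathy or creaky voice.
- Linear compression cannot represent saturating compression near the range
  edges; range exclusions are based on the target stimulus, not on whether
  the produced note actually hit the range limit.
- The MBEA simulator models only the pitch subscales, with a stylized
  three-level difficulty grid.
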