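# Methods

## Observer models

Both models share the signal-detection front end: per trial a decision
variable `dv ~ N(mu, sigma)` with signed evidence strength `mu` (direction ×
motion coherence, in proportion-coherence units, |mu| ≤ 0.5) and internal
noise `sigma`. The choice is the sign of `dv − c`; the decision bound `c`
defaults to 0 (unbiased). `sign(0)` is defined as +1 — a probability-zero
event for continuous `dv`, pinned down for determinism.

Confidence is the probability of having been correct given a distance from
the bound, `f(x) = Φ(x/σ)` (equivalently `0.5·[1 + erf(x/(σ√2))]`). The
Belief State model evaluates `f(|dv − c|)` (internal, trial-varying); the
Stimulus State model evaluates `f(|mu − c|)` (external, fixed within a
coherence level). Uncertainty is `1 − confidence`; the reward prediction
error is `feedback − confidence` with binary, veridical feedback, and the
post-feedback pupil prediction is its complement `1 − PE`.

Group internal noise defaults to σ = 1/7.5 ≈ 0.133, the reciprocal of the
probit psychometric slope. `fit_internal_noise` fits
P(choice = up) = Φ(β·μ + bias) by maximum likelihood with a free intercept;
only the slope enters σ̂ = 1/β. Fitting choice against signed evidence
(rather than accuracy against |evidence|) matches the bias-free model while
tolerating sample bias; under c = 0 both parameterizations give the same
slope. Perfectly separable data are rejected before fitting (the slope
diverges).

`predict_from_evidence` turns a per-trial evidence scalar into expected
model variables conditioned on the trial's accuracy. For the Belief State
model this is the analytic conditional mean of `f(|dv|)` over the `dv`
distribution truncated to the correct (or error) side, computed through the
identity `E[Φ(dv/σ); dv > 0] = P(dv > 0, dv − σZ > 0)` with independent
standard-normal `Z` — a bivariate-normal orthant probability — rather than
by re-simulation; a simulation oracle checks it in the tests. Motion-energy
readouts are mapped to μ units by an affine within-subject calibration
(least-squares regression of |nominal μ| on |motion energy|), because raw
motion-energy units are arbitrary; values outside [−0.5, 0.5] after
calibration are clipped with a warning.

## Synthetic experiments

The generator emulates a 2AFC random-dot motion task with delayed monetary
feedback. Defaults are the study design: 15 subjects, 24 blocks of 25
trials, Hard trials (2/3 of trials) at the coherence giving 70% accuracy at
σ = 0.133 (|μ| ≈ 0.0697), Easy trials (1/3) at 85% (|μ| ≈ 0.1378);
choice-to-feedback delays and inter-trial intervals uniform over
{3.5, 5.5, 7.5, 9.5, 11.5} s; pre-stimulus baseline period uniform
0.5–7 s; stimulus 0.75 s; response deadline 2.25 s; 12-s padding at block
edges. Session reward maps mean accuracy linearly from 50% → 0 € to
100% → 10 €, floored at chance.

Reaction times follow `RT = 0.9 + 0.6·uncertainty + N(0, 0.15) s`,
truncated to (0.15 s, deadline]. The base/slope/noise values were chosen
once so that mean RTs land near 1.13 s (Easy) vs 1.22 s (Hard) and errors
are slower than correct responses within difficulty — the qualitative
uncertainty signature — since only that pattern, not a generative RT model,
is constrained by the behavioral findings.

The pupil forward model works in arbitrary tracker units around a baseline
of 1000 a.u.:

* **IRF**: the classic Erlang-type kernel `h(t) ∝ t^n · exp(−n·t/t_max)`
  with shape n = 10.1 and peak time t_max = 0.93 s. The empirical IRF has
  no agreed closed form; this parameterization is the standard one in
  pupillometry and is config-overridable. The kernel decays below 1% of its
  peak by ~2.4 s, which motivates the 3–6 s sustained analysis window.
* **Transients** at cue, choice and feedback: impulses convolved with the
  peak-normalized kernel (gains 5/5/10 a.u. ≈ 0.5–1% signal change).
* **Sustained components**: a boxcar from choice to feedback with amplitude
  `30 · uncertainty` a.u. and a boxcar from feedback to trial end with
  amplitude `15 · (1 − prediction error)` a.u., both convolved with the
  area-normalized kernel so the amplitude is the plateau level. The
  generating model ("belief" or "stimulus") selects which uncertainty/PE
  drive these amplitudes — the stored ground truth downstream recovery is
  judged against. Amplitudes were set to produce sustained responses of
  roughly 0.5–2% signal change, the magnitude seen in task-evoked pupil
  data.
* **Noise and artifacts**: white Gaussian noise (sd 5 a.u.), Poisson blinks
  at 0.2 Hz with a 150-ms dropout (samples forced to 0, mimicking tracker
  signal loss), a small negative blink-locked transient (−10 a.u.) so
  nuisance deconvolution has a real response to remove, and a refractory
  gap preventing overlapping blinks. Motion energy is emitted as
  `μ + N(0, 0.25·coherence)` — a jittered scalar standing in for filtering
  the dot stimulus; the jitter magnitude is a design choice (within-condition
  evidence variability exists, its size is not documented).

What the generator does **not** emulate: luminance transients of the
feedback colors, gaze-position foreshortening, saccades (the nuisance
design simply omits absent event types), missed-response trials (the
pipeline tolerates and counts trials lacking a lock event), slow
non-stationary drifts, and any learning across blocks. Passing end-to-end
tests therefore demonstrate that the pipeline recovers what the forward
model encodes — not that real data are free of these confounds.

## Preprocessing

Four ordered steps, enforced through a provenance record (re-applying a
step, or applying one out of order, raises):

1. linear interpolation over blink windows padded ±0.1 s, merged when
   overlapping, edge blinks extended with the nearest valid sample;
2. third-order Butterworth band-pass 0.01–6 Hz, zero-phase. The squared
   magnitude response (the forward–backward gain) is applied in the
   frequency domain on a reflection-padded copy: time-domain recursion at a
   normalized corner of ~1e-4 produces slowly-decaying edge transients that
   leak ~5–13% of out-of-band power, while the spectral application is
   exact, linear, and passes the frequency-response oracles (gain ≈ 1 at
   3 Hz, < 1e-3 at 20 Hz, ~1e-14 at DC);
3. FIR deconvolution of blink (and saccade, when present) responses:
   lagged boxcar-basis regressors, 6-s window at 0.25-s resolution, plus an
   intercept column (the band-passed series is mean-centred; without the
   intercept the kernel estimate is biased by the event-train mean), least
   squares, fitted event responses subtracted. Kernel lags are reported at
   bin centres since each weight estimates the bin-averaged kernel;
4. percent signal change about the block mean. Because band-passing removes
   the mean first, the pipeline captures the raw block mean beforehand and
   passes it as the reference; a non-positive mean raises in either path.

Series are then decimated (polyphase, anti-aliased) to a 50-Hz analysis
rate — enough to resolve the 0.01–6 Hz passband while keeping the cluster
tests fast; the acquisition-rate default stays at 1000 Hz in the design
object.

The pupil IRF is estimated with the same FIR machinery against auditory-cue
events of the control session (25-trial blocks, 2–6 s uniform intervals, so
responses overlap by construction); at least 25 cues are required. The
estimate reports peak latency and return-to-baseline (first post-peak lag
at or below 1% of the peak, covering both noisy zero crossings and smooth
decay).

## Epoching and windows

Choice-locked and feedback-locked epochs span −1 to 6 s at 50 Hz (351
samples). Baselines are 0.5-s means before a reference event, computed from
the continuous series: pre-stimulus (cue) for choice-locked responses and
for the pre-feedback scalar; pre-feedback for the feedback-locked
responses, which isolates the feedback-evoked change from the level already
reached during anticipation. Baseline correction is idempotent (stored
baselines are zeroed after subtraction).

Scalar windows are half-open `[start, end)` — the edge convention is a
design choice: the sustained window 3–6 s after the locking event and the
pre-feedback window −0.5–0 s before feedback. Analyses keep only trials
whose relevant delay is ≥ 7.5 s (choice→feedback delay for pre-feedback
analyses, ITI for post-feedback analyses): 3 of 5 delay levels, so ~3/5 of
trials, minimizing contamination by the next event.

## Statistics

* **2×2 RM-ANOVA** (Difficulty × Accuracy) on per-subject cell means, via
  pingouin; with two-level factors the interaction F equals the squared
  paired t of the per-subject interaction contrast, which the tests verify.
* **Cluster-based permutation test** on per-subject contrast time courses:
  pointwise paired t, cluster-forming threshold at two-tailed p < 0.05,
  clusters of contiguous same-sign supra-threshold samples scored by summed
  t, null distribution of the maximum |mass| from random whole-subject
  sign flips (default 1000, seeded), add-one-corrected p. The
  cluster-forming threshold and permutation count are conventional defaults.
  Family-wise error under an exchangeable white-noise null is verified at
  ~5% by simulation; the implementation is cross-checked against MNE's
  one-sample cluster test in the unit tests.
* **Paired permutation tests** (two-tailed sign flips on differences) for
  post-hocs and group tests; the null is enumerated exhaustively whenever
  2^n fits in the permutation budget, giving exact p values for n ≤ 13 at
  the default 10,000.
* **RT residualization**: within-subject least squares of the pupil scalar
  (or each time point) on RT, mean re-added so units stay interpretable.
* **Evidence regressions**: per-subject slopes of (RT-corrected) pupil on
  absolute evidence, separately for error and correct trials; the
  interaction is the slope difference, tested by sign-flip permutation.
  Subjects with fewer than 10 trials in either class are excluded.
* **Model-pupil correlations**: per-subject Pearson r between model
  predictions and pupil scalars under three schemes — the four
  Difficulty × Accuracy cell means; six equal-count bins of the model
  prediction (error trials only, evidence-driven predictions); and
  single-trial pairing (error trials only). Equal-count binning uses
  within-subject ranks with stable tie-breaking (bin counts differ by ≤ 1).
  Group inference applies the sign-flip permutation test to Fisher-z
  transformed r; models are compared by the paired version of the same
  test. The single-trial variant is computed per subject and then
  group-tested — a pooling interpretation, since trial-wise pooling across
  subjects would conflate within- and between-subject variance.
* No cross-window multiplicity correction is applied; each window is
  reported on its own, matching the reporting convention of this analysis
  style.

## Orchestration and reproducibility

A single `RunConfig` seed drives every stage through spawned substreams
(design, behavior, per-block pupil noise, permutation nulls), so a run is
bit-reproducible from config + seed; the result bundle includes a manifest
with the config and a hash of the behavior table. Unknown configuration
keys are rejected. Intermediate products move between stages in memory in
`run_all`; the TSV writers in `io` (samples, events with expanded
blink start/end rows, behavior, scalar tables) serve the stepwise CLI and
archival.

Problem sizes for the shipped end-to-end checks: 15 subjects × 24 blocks
× 25 trials with pupil synthesized at 100 Hz (analysis at 50 Hz either
way), 1000 permutations for the omnibus tests, 500 simulated experiments ×
250 permutations for the family-wise-error calibration. These sizes keep a
full run in the tens of seconds on one core while leaving the smallest
design cell (Easy-Error, long delays only) with enough trials per subject
for stable cell means; at a quarter of the trial count that cell becomes
unstable and the interaction tests lose power.

## Known limitations

* The forward pupil model is linear-time-invariant; real pupil responses
  saturate and their kernel varies across subjects.
* Stimulus-model predictions from motion energy on error trials correlate
  negatively with belief-driven pupil data by construction (uncertainty
  falls with evidence on the stimulus account but rises on errors under the
  belief account); with few error trials per subject these binned
  correlations are noisy.
* `estimate_irf`'s return-to-baseline measure depends on the 1%-of-peak
  criterion; with heavy noise it can trigger early.
* The probit fit assumes a stable σ within the fitted data; block-to-block
  coherence adjustments are not modelled.
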