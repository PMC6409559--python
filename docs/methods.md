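# Methods

## Model forms

All models describe body-mass-normalized VO2 (mL·kg⁻¹·min⁻¹) as a
function of time t (s) from the onset of constant-load exercise.  The
exponential forms are sums of delayed first-order responses
H(t − TD)·A·(1 − e^−(t−TD)/τ), gated by the Heaviside step with
H(0) = 1.  Evaluation is continuous at each delay because the
exponential factor vanishes there; numerically the gated term is
computed as A·(1 − e^−max(t−TD,0)/τ), which is identical and cannot
overflow for t far below TD.

| name | free parameters | notes |
|---|---|---|
| `mono_simple` | A0, Ap, τp | no delay |
| `mono_td` | A0, Ap, TDp, τp | the standard phase-II model |
| `mono_td_fixed_baseline` | Ap, TDp, τp | A0 fixed to a measured resting baseline |
| `bi_td` | A0, Ap, TDp, τp, Asc, TDsc, τsc | adds the slow component |
| `bi_fastzero_td` | A0, Ap, τp, Asc, TDsc, τsc | TDp fixed at 0 |
| `tri` | A0, Ac, τc, Ap, TDp, τp, Asc, TDsc, τsc | cardiodynamic term active from t = 0, no delay of its own |
| `logistic` | A0, Ap, k, t50 | sigmoidal alternative |

These seven concrete parameterizations are the variants in common use
for on-transient kinetics; `tri`'s phase-I term was given no separate
delay (the cardiodynamic response begins with the first breath), and the
logistic is the standard four-parameter sigmoid.  Declared nestings
(simple ⊂ complex, used to gate the F-test):
mono_simple ⊂ mono_td ⊂ bi_td ⊂ tri, mono_td_fixed_baseline ⊂ mono_td,
bi_fastzero_td ⊂ bi_td, plus transitive closures.

Physiological invariants enforced at evaluation: time constants strictly
positive, amplitudes and delays non-negative, TDsc > TDp.  Whether A0 is
estimated or fixed is a per-fit option; fitted is the default.

## Derived measures

End-exercise VO2 is the mean over the final 60 s (configurable); the
resting baseline is the mean over the final 120 s of a separate resting
recording.  The realized slow-component amplitude is
Asc_end = Asc·(1 − e^−(t_end−TDsc)/τsc); the model-free alternative is
vo2_end − (Ap + A0), which may legitimately be negative and is reported
as-is.

## Preprocessing

The default pipeline for kinetics fitting is: drop the cardiodynamic
phase (t < 20 s, half-open so a breath at exactly 20 s survives) and fit
raw breaths.  Smoothing filters are provided for exploration but
deliberately not applied by default — the bootstrap propagates the
observed breath-to-breath noise, and pre-smoothing would understate
parameter uncertainty.

* **Rolling-SD exclusion** (default window 15 breaths, k = 4): a breath
  is an outlier when it deviates from the mean of its centered window —
  computed *excluding the breath itself* — by more than k local SDs.
  Single pass (no iterative re-filtering, which can cascade); breaths
  without a full centered window (the first and last ⌊window/2⌋) are
  never excluded, because an asymmetric window on a curved signal reads
  curvature as deviation.  A zero local SD excludes nothing.  With these
  conventions a noise-free model curve is never filtered for any k ≥ 1.
* **Box average**: half-open bins [i·box, (i+1)·box); one sample per
  non-empty bin at the bin midpoint; empty bins emit nothing.
* **Moving average**: centered, odd window (even windows are rejected
  rather than silently shifted), shrinking symmetrically at the edges;
  timestamps unchanged.
* **1-s interpolation**: linear, onto integer seconds inside the
  observed span; never extrapolates.
* **Ensemble average**: each transition interpolated to the 1-s grid,
  then averaged per second over the overlapping range.
* Duplicate timestamps are averaged on load, before any invariant check.

Every operation appends a parameterized record to the series' edit log;
replaying the log on the raw series reproduces the processed series
bit-exactly, which is the audit trail for any editing of the signal.

## Fitting

Bounded nonlinear least squares (scipy's trust-region-reflective
`least_squares`) with tight tolerances (1e-14) so that noise-free data
are recovered to machine precision.  Default bounds are wide, not
infinite: amplitudes [0, 100] mL·kg⁻¹·min⁻¹, delays [0, t_end] s, time
constants (0.1, 300] s, logistic rate (0.001, 2] s⁻¹.  The TDsc > TDp
ordering cannot be expressed as a box constraint while both are free; it
is enforced at model validation and holds at any physically sensible
optimum.  Starting values are data-driven: baseline from the first 10 s,
the observed rise split 100% (mono) or 80/20 (bi) between fast and slow
amplitudes, delays and time constants at typical severe-intensity values
(TDp 15 s, τp 25 s, TDsc 120 s, τsc 60 s).  On a failed solve, up to 5
restarts from ±20% uniformly jittered starts (deterministic given the
seed) are tried before reporting non-convergence with the best
candidate.

## Residual bootstrap

B = 1000 resamples by default.  Residuals are resampled with
replacement, added to the fitted curve at the observed times, and the
model refit warm-started from the original estimates (a deliberate
choice for speed and stability; with a converged original fit the warm
start is also the natural basin).  Summaries per parameter: mean, SD,
CV% = 100·SD/|mean| (reported as missing when the mean is 0), and the
percentile 95% CI taken as the order statistics bracketing the
2.5/97.5% points (lower/higher interpolation), which degenerates
correctly to the two order statistics at B = 2.  More than 20% failed
refits raises an error carrying the partial summary.

## Model comparison

The extra-sum-of-squares F-test for nested fits:
F = (ΔRSS/Δdf) / (RSS_complex/df_complex), p from the upper tail of
F(Δdf, df_complex); at α = 0.05 the complex model is preferred when
p < α, otherwise "no difference" — the simpler model is never declared
superior.  A perfect complex fit against an imperfect simple one reports
F = ∞, p = 0.  Shapiro–Wilk on each residual vector is a diagnostic
only; it never gates fitting.  The test always uses the series the
models were fitted to (raw or filtered alike).  Note that under the null
the richer model's extra parameters sit on the boundary (Asc = 0), so
the nominal F reference distribution is approximate and the test runs
somewhat conservative (empirically ≈3% type-I error at α = 0.05 under
the conditions of the calibration test).

## Synthetic data

The generator evaluates a model curve on a 1-s grid over 0–315 s
(roughly the duration of a 400-m even-paced swim test) and adds i.i.d.
Gaussian noise (σ = 2 mL·kg⁻¹·min⁻¹ for the noisy variants; breath-level
noise of this order is typical of snorkel-based swimming measurements).
Truth parameters default to plausible severe-intensity group means
(A0 = 8.8, fast amplitude ≈ 40–44, TDp ≈ 21–24 s, τp ≈ 16–27 s,
Asc = 7, TDsc = 137 s, τsc = 60 s, depending on form); they are
configuration, recorded in JSON sidecars next to every generated file,
not claims about any particular dataset.  Negative noisy samples are
clipped to 0 and counted in the sidecar.

What the generator does *not* emulate: irregular breath timing (it
samples uniformly), stroke-locked breathing artifacts, heteroscedastic
or autocorrelated noise, and errant-breath outliers.  Passing recovery
and coverage tests therefore demonstrate correctness of the estimation
machinery under the stated noise model, not robustness to every artifact
of real poolside data.

## Calibration results exercised by the test suite

* Noise-free round trip: for all seven forms, fitting a generated
  noise-free series returns the generating parameters to < 1e-6 relative
  error and the 1000-resample bootstrap SD of every parameter is 0 to
  machine precision.
* Noisy recovery (bi-exponential, σ = 2, 200 replicates): bias of Ap and
  τp within two Monte-Carlo SEs of zero.
* Bootstrap 95% CI coverage for Ap and τp within [90%, 98%] over 300
  simulated series (B = 200 per series to keep the experiment tractable
  at these replicate counts).
* F-test type-I error within [3%, 7%] over 1000 null replicates.
* Optimizer RSS at or below a coarse 8-points-per-axis grid search over
  the bounded box on 20 randomized instances.

## Known limitations

Off-transient (recovery) kinetics are not modelled.  Only box bounds are
supported (no linear inequality TDsc − TDp > 0 during optimization).
The slow component's timing parameters (TDsc, τsc) are weakly identified
at realistic noise levels — bootstrap CVs of 30–45% are normal, and
their bootstrap CIs can be slightly conservative near the t_end bound.
The F-test's nominal size is approximate for boundary-constrained
nonlinear nests (see above).
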