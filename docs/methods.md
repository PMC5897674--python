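# Methods

This note documents the models, conventions and numerical choices behind
the package, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Micro-movement normalization

A validated waveform is reduced to strictly alternating local maxima and
minima. Conventions, chosen for determinism:

* Boundary samples are never extrema; a plateau contributes its first
  sample.
* Only peaks with a local minimum on **both** sides are retained — the
  normalization below is undefined otherwise — so the first/last
  extremum of a window is discarded when one flank is missing.
* `min_prominence` defaults to 0 (every strict sign change counts);
  filtering is opt-in because raw peak counts are themselves a metric of
  interest. After prominence filtering, alternation is re-established by
  keeping the lowest valley between consecutive retained peaks.

Each retained peak maps to the unit interval as
`AM = peak / (peak + flank_avg)`, where `flank_avg` averages **every**
sample from the left flanking minimum to the right flanking minimum,
both endpoints and the peak included. The inclusive window keeps
`AM < 1` strictly and makes the value a deterministic function of the
window. AM is exactly invariant under positive rescaling of the signal
(both numerator and denominator are linear in the signal), which is the
point: allometric amplitude differences between individuals vanish while
the *fluctuation structure* is preserved. Higher AM means a lower local
signal level relative to the peak; for a fixed peak, AM is strictly
decreasing in the flanking average.

Timing micro-movements (NTM) apply the same idea to the sequence of
inter-peak intervals (TM). Two modes are implemented because mapping a
min-to-min window onto a *discrete array* of intervals admits more than
one reading:

* `series_minima` (default): the TM sequence is treated as a discrete
  signal and its own local peaks are normalized. Because neighbouring
  array elements are immediately adjacent, the convention here differs
  from the waveform case in two deliberate ways: array endpoints may
  serve as flanking minima (otherwise a 3-interval sequence could never
  produce a value), and the window average excludes the peak itself, so
  `tm = [1, 3, 1]` yields `3/(3+1) = 0.75`.
* `global_mean`: every interval maps through `tm/(tm + mean(tm))`; a
  constant sequence gives 0.5 everywhere.

Both modes are scale-invariant; neither is asserted to be uniquely
correct, and the mode is recorded in every output.

## Gamma estimation

Micro-movement (or inter-beat-interval) samples are modelled as i.i.d.
draws from the two-parameter Gamma family. The MLE is computed by Newton
iteration on the profile shape equation
`log a − ψ(a) = log(mean) − mean(log x)` from a method-of-moments start
(`a₀ = mean²/var`), with `b = mean/a`; the left-hand side is strictly
decreasing in `a`, so the root is unique. Convergence tolerance is a
relative 1e−12 with a hard cap of 100 iterations (non-convergence raises
with diagnostics; in practice 4–6 iterations suffice). The implementation
agrees with an independent fitter (scipy's) to ~1e−6 relative and is
cross-checked against it in the test suite.

Confidence intervals (default level 0.95) are Wald intervals from the
observed Fisher information evaluated at the MLE in the
`(log a, log b)` parameterization, back-transformed — this keeps both
interval ends positive and is the documented construction behind every
"95% CI" the package reports. At the MLE the score vanishes, so the
information matrix has the closed form
`[[n a² ψ′(a), n a], [n a, n a]]`. Monte-Carlo calibration (1,000
replicates of n = 300) puts the empirical shape-CI coverage at ~94.7%,
within 2 points of nominal; the residual shortfall is the usual
first-order Wald optimism plus the small-sample bias of the shape MLE.

Hard floor n ≥ 10; below 100 samples a warning flags that the intervals
are loose (hundreds of peaks per condition is the intended regime).
Fitting is restricted to the Gamma family (the exponential is nested at
`a = 1`); a log-likelihood comparison against exponential, lognormal and
normal candidates is available as a reporting utility but never replaces
the Gamma fit.

Moments are closed forms of the fit: mean `a·b`, variance `a·b²`,
skewness `2/√a`, kurtosis `3 + 6/a`, and NSR = variance/mean = `b`
exactly — the identity that makes the scale axis of the Gamma plane a
noise axis.

Histograms (display only; never used for fitting) use Freedman–Diaconis
binning, `h = 2·IQR·n^(−1/3)`, with linear-interpolation quantiles and a
2-equal-bin fallback when the IQR is zero.

## Distribution-shift statistics

* Two-sample KS with asymptotic p-values for condition-to-condition
  shifts; all pairwise tests in a report carry both raw and
  Benjamini–Hochberg-adjusted p-values (raw values remain primary).
* One-sample KS against a normal with the sample's mean and SD. The
  default p ignores that the normal's parameters were estimated from the
  same sample, which biases it conservative (the Lilliefors issue); a
  Monte-Carlo-calibrated p is available by flag rather than silently
  substituted.
* Log-log power-law fit: ordinary least squares of `log b` on `log a`
  across plane points, natural log by default (base-10 selectable). When
  all points share the same mean `μ = a·b`, `log b = log μ − log a`
  identically, so the slope is −1 and the intercept `log μ` to machine
  precision; estimation noise on real fits perturbs this only mildly, so
  slopes near −1 with varying intercepts diagnose conserved
  micro-movement means across a cohort.

## ECG / inter-beat intervals

The ECG is band-pass filtered at 5–30 Hz (2nd-order Butterworth, the
band that concentrates QRS energy and excludes baseline wander), applied
**bidirectionally**: zero phase distortion preserves R-peak times, which
is what the IBI analysis consumes; the doubled effective attenuation is
accepted. R-peaks are local maxima above half of a rolling 5 s amplitude
envelope, separated by a 250 ms refractory period (~240 bpm ceiling);
polarity is auto-corrected by comparing extreme excursions of the two
signs. Intervals ≥ 2× the running median of the preceding intervals are
flagged as suspected missed beats and kept — flagging replaces the
manual plot inspection a human analyst would do, and nothing is imputed.
IBI values feed the Gamma fit directly in seconds, without unit-interval
normalization.

## Kinematics

Derivatives use Savitzky–Golay smoothing differentiation (default
window 21 samples ≈ 87 ms at 240 Hz, polynomial order 3, both
configurable; endpoints by one-sided fits). Naive finite differences
amplify instrumentation noise quadratically with derivative order;
local-polynomial differentiation is the standard reproducible stand-in
for proprietary smoothing chains. Speed is the norm of the smoothed
position derivative; angular acceleration is the absolute smoothed
derivative of the angular-rate magnitude — a non-negative magnitude
waveform, as the amplitude normalization requires.

Trials split at the sample of minimum hand-to-target distance (hand
speed is near-zero there). Movement onset/offset use a threshold of 5%
of the trial's maximum speed sustained for ≥ 50 ms; the offset search
first waits for the backward motion to rise above threshold so the
near-zero dip at the turnaround itself is not mistaken for the end of
movement. Segments are half-open `[start, end)` sample intervals;
forward and backward partition the movement exactly. Reconstruction of
angular velocity from raw orientation quaternions is out of scope — an
angular-rate channel (scalar or 3-component) is expected.

Behavioral validation metrics per trial: movement time (touch − prompt),
time-estimation error (|response × full-scale − tone delay|, with a
configurable full-scale seconds value defaulting to 1.0 for the 0–1
response scale), and angular-acceleration peak counts per segment.
Missing events yield missing values, never zeros. Condition contrasts
use the two-sided paired t-test (df = n − 1) with an explicit degenerate
flag when the paired differences have zero variance.

## Synthetic data

The generator emulates the *structure* of a cognitive-load pointing
study: per condition, 60 trials of ~1.5 s out-and-back minimum-jerk
reaches to a fixed target at 240 Hz (bell-shaped speed, zero velocity at
the turnaround), three condition presets (control / low load / high
load) in which higher load plants denser acceleration-peak trains and
slower reaches, trial events (prompt, touch, tone at 100/400/700 ms
delays, response on a 0–1 scale), and an ECG channel at 256 Hz whose
inter-beat intervals follow a Gamma law, rendered as biphasic
difference-of-Gaussians QRS-like pulses (80 ms support, spectral content
inside the 5–30 Hz detection band) with optional white noise at a set
SNR and 0.3 Hz baseline wander.

The angular-rate channel is constructed so the *derived* angular
acceleration carries planted spike structure: compact `sech²`
acceleration bumps (width parameter 20 ms) whose peak amplitudes are
i.i.d. draws from the condition's Gamma law and whose gaps follow a
Gamma law clipped below 140 ms so neighbouring bumps stay separable
after smoothing. Bump signs alternate toward a positive baseline so the
angular rate remains a positive magnitude signal, and a tiny 8 Hz
tremor floor (0.1% of the mean planted amplitude) keeps rest periods
from being numerically flat — real sensors never are — which also
guarantees genuine flanking minima around every planted peak. Bumps are
kept ≥ 25 ms clear of the turnaround so the planted forward/backward
assignment is unambiguous. All randomness flows through one seeded
generator; the planted truth (bump indices and amplitudes, per-segment
counts, split samples, beat times, seeds) is returned with the data and
serializable alongside any export.

What passing tests on this generator do and do not show: recovery of
planted peak counts, amplitudes, gaps and Gamma parameters demonstrates
that the extraction and estimation chain is faithful under realistic
sampling, smoothing and noise floors. The generated AM values are *not*
themselves Gamma draws — the normalization maps amplitudes through the
flank average, and AM is confined to [0.5, 1) by construction — so
end-to-end parameter recovery is asserted on the recovered raw peak
amplitudes (the quantities that were planted), while the AM/NTM outputs
are checked for range, scale invariance and element-wise agreement with
the planted normalization. The generator does not emulate biomechanics,
multi-sensor kinematic chains, P/T waves or respiratory sinus
arrhythmia, or inter-trial learning effects; conclusions about real
recordings still require real recordings.

Extraction on simulated sessions uses a prominence floor of 0.2% of the
99th-percentile in-segment acceleration (ignoring numerically tiny
ripples and the tremor floor) and a 0.4 s detection pad around each
trial's movement window so edge peaks keep their flanking minima. With
these defaults, planted per-trial peak counts are recovered exactly on
the seeds exercised in the tests; very rarely (~1 peak in 500) a bump
drawn with amplitude below ~1.5% of a close neighbour merges into its
smoothed shoulder, an inherent resolution limit of smoothing-based
detection rather than a bug.

Problem sizes in the test suite and acceptance script are chosen for
desk-scale reproducibility: 20–60 trial sessions, 6–9 participant
cohorts, 5–10 minute ECG stretches, 1,000-replicate calibration runs —
all comfortably inside a few seconds to a couple of minutes on one CPU,
while keeping every estimate in its intended n ≳ 100 regime.

## Numerical choices and degenerate inputs

* Uniform-sampling tolerance: 1% of the sampling interval; files beyond
  it are rejected, not resampled.
* NaNs: reject by default; interior NaNs may be linearly interpolated on
  request (counted in the validation report); boundary NaNs always fail.
* Gamma density evaluated in log space; at `x = 0` it is `1/b` for
  `a = 1`, 0 for `a > 1`, and +∞ for `a < 1`.
* Zero-denominator peaks (flat zero windows) are dropped with a warning
  rather than producing 0/0.
* Constant TM sequences have no interior extrema: `series_minima` NTM is
  empty with a warning; `global_mean` gives 0.5 everywhere.
* Degenerate log-log scatters (no spread in shape) and zero-variance
  paired differences raise/flag instead of returning unstable numbers.
* JSON reports serialize non-finite values as `null` with a warning flag
  and carry schema version, parameters, config hash and seed.

## Limitations

* Wald CIs are first-order; for n well below 100 they undercover and the
  package says so rather than correcting silently.
* The asymptotic KS p-value against a moment-matched normal is
  conservative (estimated parameters); use the Monte-Carlo flag when the
  decision is marginal.
* Peak detection resolution is bounded by the smoothing bandwidth;
  structure finer than ~half the smoothing window cannot be separated.
* Single-window estimation per condition only; no time-varying
  (streaming) Gamma tracking, no Bayesian or mixture extensions.
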