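# spiba

Micro-movement spike trains and personalized Gamma-process signatures
from biophysical waveforms.

## The problem

Continuous physiological recordings — hand kinematics during pointing,
the electrocardiogram — fluctuate from moment to moment in the amplitude
and timing of their peaks. Conventional analyses average these
fluctuations away and assume normality; in practice the empirical
distributions are skewed, differ from person to person, and shift within
a single experimental session as cognitive demands change. This package
implements a statistical platform for *individualized* analysis of such
signals: instead of grouped normal-theory statistics, each person's
fluctuations are converted into a standardized spike train and their
probability distribution is estimated empirically, with confidence
intervals, so that shifts across conditions can be tracked per person.

It is intended for researchers working with kinematic traces (~240 Hz
motion capture), ECG (~256 Hz), or any non-negative biophysical waveform
whose peak statistics carry signal.

## The method

1. **Micro-movement normalization.** Local peaks and valleys of the
   waveform are extracted. Each peak amplitude is mapped to

   `AM = peak / (peak + mean(min-to-min window))`

   giving unit-less *amplitude micro-movements* strictly inside (0, 1),
   invariant under rescaling of the signal (so anatomical/allometric
   differences drop out). Inter-peak intervals (TM, seconds) and their
   normalized counterpart (NTM) carry the timing information.

2. **Gamma estimation.** The micro-movement samples are fit by maximum
   likelihood to the two-parameter Gamma family

   `f(x | a, b) = x^(a-1) e^(-x/b) / (Γ(a) b^a)`

   with shape `a` and scale `b`. The mean is `a·b` and the variance
   `a·b²`, so the scale equals the **noise-to-signal ratio**
   (NSR = variance/mean = `b`). 95% confidence intervals come from the
   observed Fisher information on (log a, log b). Estimates are placed
   on the **Gamma parameter plane** (shape on x, scale on y): `a = 1` is
   the memoryless exponential boundary, large `a` approaches the
   Gaussian; higher `b` means noisier signal.

3. **Shift tracking.** Condition-to-condition shifts are quantified with
   two-sample Kolmogorov–Smirnov tests between empirically estimated
   distributions, one-sample KS tests against a moment-matched normal,
   log-log power-law fits of the plane scatter (slope ≈ −1 when the
   micro-movement means are conserved), and a four-moment scatter
   (mean, variance, skewness, kurtosis).

The pipeline also covers the surrounding signal processing: 5–30 Hz
2nd-order Butterworth band-pass for ECG, R-peak detection and inter-beat
intervals, Savitzky–Golay smoothing differentiation for speed and
angular acceleration, and segmentation of pointing trials into the
goal-directed forward reach and the spontaneous backward retraction at
the minimum hand-to-target distance.

A fully ground-truthed synthetic-data module generates study-structured
sessions (3 conditions × 60 trials, ~1.5 s out-and-back reaches at
240 Hz, ECG with Gamma-distributed inter-beat intervals) so every stage
is testable without any data download.

## Worked example

```python
import spiba
from spiba.synthetic_data import DEFAULT_TARGET

# a simulated 60-trial block whose angular-acceleration peak amplitudes
# follow Gamma(shape=2.5, scale=0.08)
session, truth = spiba.simulate_pointing_session(
    n_trials=60, condition="low_load", gamma_params=(2.5, 0.08), seed=1)

mm = spiba.extract_micromovements(session, DEFAULT_TARGET)
am = mm[("AM", "forward")]
fit = spiba.fit_gamma_mle(am.raw_values)
m = spiba.gamma_moments(fit)
res = spiba.ks_vs_normal(am.values)
```

This prints (via the obvious f-strings):

```
forward AM peaks: 246 (planted 246)
shape a = 2.493  95% CI [2.112, 2.944]
scale b = 0.0761  95% CI [0.0633, 0.0915]
NSR = 0.0761  mean = 0.1897  skewness = 1.267
KS vs moment-matched normal: D = 0.1169, p = 2.41e-03
```

Every planted acceleration peak was recovered; the fitted shape and
scale cover the generating law (2.5, 0.08) within their 95% intervals;
the NSR equals the scale by construction; and the normalized
micro-movements reject normality (p < 0.01) — the skewness that grouped
normal-theory statistics would miss.

The same stages are available from the shell:

```
spiba simulate session --seed 1 --out data/
spiba segment --traj data/traj.csv --events data/events.csv --target "0,30,10" --out segs.csv
spiba ecg --in data/ecg.csv --fs 256 --out ibi.csv
spiba fit --in ibi.csv --conf 0.95 --out fit.json
spiba run --config config.yaml --seed 1 --out results/
```

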