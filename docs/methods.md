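# Methods

This note documents the models, estimators, parameter choices and known
limitations behind `stridemod`. It is the place to look when a default
needs to be questioned or changed.

## Stride segmentation

Strides are trough-to-trough cycles of the paw x-position. The procedure
is: artifact removal → 50 ms sliding average → peak/trough detection →
vertex refinement → duration gating.

* **Artifact removal** (`clean_trace`): tracking losses appear as
  near-instantaneous square pulses. A transient whose rise and fall both
  complete within 5 samples and exceed 0.5 AU is replaced by linear
  interpolation and its samples are flagged untracked. A trace with more
  than 20% flagged samples is rejected as unusable.
* **Smoothing** (`smooth_trace`): centered moving average, window rounded
  to the nearest odd sample count (50 ms at 240 Hz → 13 samples). Edges
  use shrinking windows rather than zero padding, which would fabricate
  troughs at the trace ends.
* **Detection** (`detect_strides`): troughs and peaks on the smoothed
  trace with prominence ≥ 0.2 AU and minimum separation 100 ms. A boxcar
  shifts the vertex of an asymmetric sawtooth by up to ~2 samples, so
  each extremum is refined: first on a light 5-sample average (robust to
  single-sample noise), then within ±1 sample on the raw trace (removes
  the small bias the light average itself introduces). Only
  trough→peak→trough triples with exactly one interior peak and
  plant-to-plant duration in [100, 500] ms become strides. On noiseless
  synthetic sawtooths this recovers every interior stride boundary within
  one sample.
* **Slopes**: the stance (plant→lift) and swing (lift→next plant) slopes
  are estimated by least squares over the central 70% of each segment.
  For an ideal sawtooth this equals the endpoint slope
  (amplitude/duration of the phase); unlike the endpoint form it is
  insensitive to ±1-sample jitter of the detected vertices, which matters
  because slopes enter the slip criteria as ratios with a 20% band.
* **Bin allocation** (`allocate_bins`): 10 bins split by the session's
  median stance fraction with half-up rounding, clamped to [1, 9] per
  phase (0.65 → 7 stance / 3 swing; 0.70 → 7/3; 0.50 → 5/5). The
  rounding rule is configurable; re-analysis with 10 equal-width bins is
  supported and leaves class assignments unchanged on the synthetic
  suite.
* **Rest epochs** (`detect_rest`): maximal intervals ≥ 500 ms in which
  the rolling 200 ms peak-to-peak amplitude stays below 10% of the median
  stride amplitude. Rest-state firing statistics require ≥ 2 s total
  rest. The two window lengths are operational choices (the criterion
  itself is the 10% threshold) and are configurable.

## Firing-rate estimators

The instantaneous firing rate is defined as 1/ISI held over the interval
— a step function, undefined before the first and after the last spike.
Bin averages are exact time-weighted integrals of this step function
(implemented through the cumulative spike-position function, which is
piecewise linear with slope 1/ISI). This definition slightly smooths
sharp rate transitions on the scale of one ISI; at the 80–160 spikes/s
rates typical here that is ≤ ~10 ms.

The modulation index MI = (FRmax − FRmin)/(FRmax + FRmin) over the 10-bin
curve is invariant to rate scaling; binned averaging attenuates a
sinusoidal tuning by the bin-width sinc factor (~1.6% at 10 bins), so
recovered MI sits just below the generative value (0.38–0.39 for a true
0.4).

**Kuiper test**: V = D⁺ + D⁻ against the uniform CDF of stride phases,
with Stephens' finite-n correction and the standard asymptotic series for
p. **Rayleigh test**: R = mean resultant length, p ≈
exp(√(1+4n+4(n²−(nR)²)) − (1+2n)). Both approximations are validated in
the test suite against 10,000-draw Monte-Carlo nulls at n = 10, 50, 200
rather than trusted at small n.

## Modulation classes

The modulation classes originate as a manual taxonomy; here they are operationalized
quantitatively. The first two circular harmonics of the mean-subtracted
10-bin rate curve are compared:

* fundamental power ≥ 2× second-harmonic power → the phase of the rate
  fundamental relative to the paw-position fundamental assigns
  I (|Δφ| < 45°), II (|Δφ − 180°| < 45°), III (rate leads by 45–135°),
  IV (lags by 45–135°);
* second harmonic dominant (≥ 2×) → bins one quarter stride before/after
  the lift decide V (local maxima there) or VI (local minima), accepting
  an extremum within ±1 bin of the quarter-stride position to absorb bin
  quantization;
* otherwise, or when Kuiper p ≥ 0.05 or MI < 0.05 → VII (unclassified).

"±90° from the lift" is interpreted as ±¼ of the stride *in time*; the
conversion to warped (stance/swing-normalized) bin coordinates uses the
session's median stance fraction. The dominance ratio (2×), sector width
(±45°) and MI floor (0.05) are explicit, configurable thresholds. On
synthetic cohorts (all six classes, 150 strides/cell, Poisson spiking)
recovery is ≥ 90%, with residual errors only to adjacent phase classes or
VII.

## Optogenetic responses

Step PSTHs use 50 ms bins over the 1 s stimulus with the 1 s pre-stimulus
rate as baseline (per-trial by default; a per-condition baseline is an
option). Train PSTHs assign each stimulus spike a latency from the most
recent pulse onset (spikes before the first pulse are excluded), bin at
1 ms over one inter-pulse interval, and normalize to spikes per pulse —
so summed probability × frequency equals the mean stimulus rate exactly
(count conservation, asserted in tests). Pulse groups are contiguous
thirds of the pulse sequence with the remainder to the late group. The
ISI CV uses intervals fully inside the analysis window and requires ≥ 2
intervals.

## Slip analysis

Screening discards trials where a rest epoch overlaps the stimulus
without running resuming before trial end, or where the last pre-stimulus
stride deviates > 50% from the median of the three before it. The control
stride is the last stride ending at or before light onset, with a 30 ms
grace for strides barely overlapping the stimulus; trials without one are
*unresolved*. Unresolved trials are *not* counted as slips by default
(the original screening convention counted analogous trials, accepting a ≤ 7% error;
`unresolved_as_slip=True` replicates that choice).

Classification compares every stride starting within the 1 s stimulus to
the control stride: duration ratio ≥ 1.2 → prolonged, ≤ 0.8 → incomplete,
stance or swing slope ratio ≤ 0.8 → arrested; boundaries are inclusive
(a 1e-9 tolerance keeps them inclusive under float rounding). Strides
straddling the stimulus offset are evaluated on slope criteria only. Two
or more distinct criteria (counting stance- and swing-slope reductions
separately) mark the trial *altered*. For non-slips the stride deviating
most from control (maximal relative deviation across duration and both
slopes) is reported.

**Latency**: the control stride's trajectory, phase-aligned to the gait
at light onset, is tiled forward as a prediction of unperturbed
locomotion. The first divergence > 20% of stride amplitude sustained
≥ 25 ms identifies the offending stride; latency is reported from light
onset to that stride's plant. Divergence itself accumulates gradually
(a 30% slowed stride needs ~100 ms to drift 0.2 AU from the template), so
dating the slip at the divergence sample would systematically overshoot;
anchoring to the start of the deviating stride matches the construction
"a slip is a deviant stride" and recovers injected 120 ms latencies
within ±25 ms in > 95% of trials.

**Step-vs-train comparison**: all (step, train) trial pairs within a cell
with stimulus rates within 10 spikes/s, both ≥ 10 spikes/s (a trial may
appear in several pairs). McNemar's test on discordant pairs uses the
continuity-uncorrected χ² = (b−c)²/(b+c) when b+c ≥ 25 and the exact
two-sided binomial otherwise; b+c = 0 gives p = 1 by convention. The χ²
test for slip-probability independence reports df = k−1 for k conditions.

## Modulation correlation

Light-on tuning on non-slip trials uses strides fully inside stimulus
windows (≥ 5 required) with the session's bin allocation; Pearson r on
the two 10-bin curves. For slip trials the template's absolute bin
durations are tiled from stimulus onset across the slip epoch and rates
are averaged across tilings (a single-tiling option exists; tiling from
slip onset instead of stimulus onset is supported, stimulus onset is the
default). With only 10 points, per-trial r values are treated
descriptively via the r ≥ 0.4 criterion, not tested for significance.
Prolonged strides are binned lift-aligned and the peak-bin angle
θ = 36° × (light-on peak − control peak) is wrapped to (−180°, 180°];
argmax ties go to the lowest bin index.

## LFP

Sweep averages are filtered with a 4th-order Butterworth band-pass
(50–1000 Hz) applied forward-backward (zero phase; the effective
magnitude response is the square of the design response, which is what
the tests check against). The PSD is a single boxcar periodogram over the
1 s stimulus window (1 Hz resolution) — matching a plain FFT description
rather than Welch averaging — with 60 ± 2 Hz interpolated away. Harmonic
peaks are the maxima within ±2 Hz of k·f_stim, quantified as prominence
over the median power in a ±10 Hz surround; prominence > 3 is flagged.
Per-sweep spectra before averaging are available as an option.

## Synthetic sessions

The generator produces what the analysis assumes, with labels:

* **Stride durations**: running speed wanders multiplicatively as
  exp(a · triangle(i/P)) with period P = 200 strides, plus i.i.d.
  relative jitter (5 ms at the 222 ms mean). The amplitude a is solved so
  the marginal SD matches the configured 71 ms
  (a·sinh 2a / 2 sinh² a = 1 + CV²); durations are clamped to
  [140, 419] ms. Multiplicative: relative stride-to-stride drift is the
  same at fast and slow gait. Triangular: the drift magnitude per stride
  is constant (4a/P ≈ 1.1%), and one full cycle spans a default
  200-stride session so configured mean and SD are realized per session.
  The slow/fast split is the substantive modeling choice: pooled stride
  statistics (mean 222, SD 71, range ≈ 140–380 ms) coexist with the
  local regularity of steady running (consecutive strides within a few
  percent) that ±20% slip criteria presuppose.
* **Paw trace**: per-stride linear sawtooth (stance rises over the stance
  fraction, 0.65 ± 0.015 across strides; amplitude 1 AU), Gaussian
  tracking noise (SD 0.015 AU), optional full-scale 1–3-sample artifacts
  (0.1/s), rest epochs rendered as flat segments with jitter well under
  10% of stride amplitude.
* **Spikes**: inhomogeneous renewal process via time rescaling. Unit-mean
  increments are Exp(1) (Poisson, default) or Gamma(k, 1/k) for regular,
  sub-Poisson firing (the CV analyses are only meaningful if the
  generator can produce CV < 1). The rate follows the stride-phase tuning
  curve of the configured class with analytically exact MI; rest segments
  fire at the rest rate (defaults: Purkinje 93 spikes/s rest,
  +26 running; CbN 85/+16).
* **Optogenetics**: steps add a signed rate offset with an onset
  transient (amplitude ×1.5 decaying with τ = 100 ms — the kinetics are
  free parameters shaping an initial transient then plateau); trains add
  (Purkinje) or delete (CbN) pulse-locked spikes: insertion at
  2.5 ± 0.5 ms after pulse onset with probability `lock_prob`, deletion
  within 2–6 ms. A deterministic mode emits exactly one spike per pulse
  at the lock latency. An optional post-offset rebound adds a rate bonus
  for 200 ms.
* **Slips**: one stride per slip trial is edited — prolonged/incomplete
  scale its duration by (1±m) relative to its predecessor, arrested
  scales amplitude (hence both slopes) by (1−m); magnitudes ≤ 0.2 are
  rejected as sub-threshold by construction. Trials are anchored so the
  slip stride's plant falls 120 ms after light onset, and anchors shift
  forward when an edit would leave the 100–500 ms detectable-stride
  regime. During incomplete/arrested slips the stride tuning is flattened
  to its mean (modulation abolished); prolonged strides keep their tuning
  stretched with the stride, enabling the lift-aligned polar analysis.
  Both behaviors are configurable per trial.
* **LFP**: damped-oscillation kernel (300 Hz, τ = 10 ms, ≤ 50 ms or 80%
  of the pulse period) at each pulse time, plus white noise and a 60 Hz
  mains sinusoid; 10 sweeps at 10 kHz.

What the generator does **not** emulate: biomechanics (slips are
geometric edits, not dynamics), multi-limb coordination, electrode drift,
spike-sorting errors, complex-spike/simple-spike structure, or
correlations between firing and behavior beyond the imposed tuning.
Passing tests therefore demonstrate that the estimators recover the
assumed structure at realistic signal-to-noise, not that real recordings
satisfy the assumptions.

## Numerical choices and degenerate inputs

Rates are clipped at zero with a warning when stimulus offsets drive the
intensity negative. Tests with fewer than 8 samples return NaN p-values;
correlation of a constant vector is NaN and excluded from threshold
summaries; McNemar with no discordant pairs returns p = 1. All
randomness flows from a single seed through `numpy.random.default_rng`;
generation and the full pipeline are bit-reproducible for a fixed seed.

## Problem sizes

The test suite and the acceptance script use desk-scale cohorts chosen as
the package's own verification sizes: sessions of 120–200 strides,
cohorts of 48 cells (8 per modulation class), 50 seeded slip sessions
(100 slip and 100 non-slip trials), 25-session correlation cohorts, and
10,000-draw Monte-Carlo nulls. Estimates at these sizes are stable to
within the tolerances asserted; larger cohorts shrink the Monte-Carlo
error but do not change the conclusions.

## Known limitations

* The modulation classifier is a proxy for a manual taxonomy; its
  thresholds are principled but not fitted to human judgments.
* Stride detection assumes a sawtooth-like trace; gaits with double
  peaks per cycle (e.g., partial weight-bearing corrections) would need
  different peak constraints.
* The slip latency estimator reports the start of the first deviant
  stride; a perturbation expressed mid-stride (e.g., a transient slope
  change that recovers) is dated at that stride's plant.
* Template tiling assumes the pre-stimulus stride is representative; if
  gait was accelerating into the stimulus the correlation is biased
  downward for non-slips as well.
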