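# Methods

`swdus` estimates fetal cardiac valve timings from single-channel Doppler
ultrasound (DUS) audio.  The chain is: swarm decomposition of the raw signal
into oscillatory components (OCs), selection of the high-frequency valve
component, envelope extraction, reference-free cardiac-cycle segmentation,
per-cycle valve-event search, interval computation, and nonparametric group
statistics.  This note records the model, the choices that were genuinely
open, and what the synthetic benchmark does and does not demonstrate.

## Swarm filtering

A swarm of `M` members hunts the input sequence as prey.  Member `i` keeps
position `p_i` and velocity `v_i`, updated per sample `n` with flexibility
`delta`:

```
v_i[n] = v_i[n-1] + delta * (F_Dr,i[n] + F_Coh,i[n])
p_i[n] = p_i[n-1] + delta * v_i[n]
```

The driving force attracts members to the prey and dissipates their momentum,

```
F_Dr,i[n] = drive_gain * (s[n] - p_i[n-1]) - v_i[n-1]
```

and the cohesion force pulls members toward the swarm barycenter
(`cohesion_gain`), with optional short-range repulsion below
`repulsion_scale` (off by default).  The filter output is the barycenter.
The velocity-drag term is essential: without it the barycenter recursion is
an undamped resonator (pole product exactly 1), so no steady-state response
exists and the operator cannot act as a band-pass filter.  With drag the
barycenter obeys a two-pole resonator whose poles `r·e^{±jw}` are placed
exactly by inverting the recursion:

```
delta      = 1 - r^2
drive_gain = (1 + r^2 - 2 r cos w) / delta^2
```

with `w = 2*pi*f_c/fs` and `r = exp(-sharpness · w · (pi - w)/pi)`.  The
`(pi - w)/pi` taper keeps presets near Nyquist resonant (a heavily damped
pole pair close to `w = pi` otherwise peaks at Nyquist itself and has no
interior gain maximum).  `cohesion_gain` is capped so the member-deviation
dynamics (same recursion with gain `drive_gain + cohesion_gain`) stay
strictly stable.  All force terms are degree-1 in the state, so the filter
is exactly homogeneous in scale.

Each pass runs the member recursion forward over the samples and then
backward over its own output (`filtfilt` style).  A single causal sweep has
a phase rotation near ±pi/2 at its own center frequency, which would both
decorrelate a pure center-frequency tone from its filtered copy and delay
every burst by the group delay, biasing all valve timings; the
forward–backward sweep is zero-phase, so burst peak positions are unbiased.
Members start evenly spread over `[x0 - eps, x0 + eps]` (`eps = 1e-6 ·
max(1, |x0|)`) with zero velocity — deterministic, no randomness anywhere in
the module.  Divergence (any `|p_i| > 1e6 · max|s|`) raises immediately;
it indicates a `delta` outside the stable region.

## Calibration and the preset bank

The binding contract of a preset is its measured response, not its internal
constants.  `calibrate_swf` sweeps unit probe sinusoids over a log grid in
`(0, fs/2)`, records steady-state RMS gain over the central half of each
probe, and stores the gain-maximizing frequency, the −3 dB bandwidth and the
peak gain; presets with no interior maximum are dropped with a warning.  The
default bank is 12 presets log-spaced over `[0.005·fs, 0.45·fs]` (5–450 Hz
at the 1 kHz DUS rate): low bands for cardiac wall motion, high bands for
valve clicks.  Measured centers are strictly increasing; a copy of the table
ships as `data/default_calibration_fs1000.csv` and is regenerated by the
same routine.

## Swarm decomposition (sifting)

Each iteration estimates the residual's dominant frequency (Welch PSD
argmax), picks the calibrated preset nearest in log-frequency, and builds an
OC by consecutive swarm-filter applications (early stop when two passes
correlate ≥ 0.999).  Two design points matter:

* **Least-squares subtraction.**  The passband gain is not unity, so the raw
  OC is rescaled by `alpha = <residual, oc> / <oc, oc>` before subtraction.
  Reconstruction (`sum of OCs + residual = input`) stays exact by
  construction; correlations are scale-free.
* **Two passes by default.**  A zero-phase pass applies `|H|^2`; `k` passes
  apply `|H|^(2k)`, shrinking the effective bandwidth like `1/sqrt(k)`.
  With many passes the loop peels a broadband component (e.g. the ~30 Hz
  wall band of a DUS record, widened by its beat-rate amplitude modulation)
  in thin spectral slices and exhausts the component budget before reaching
  the valve band.  Measured on synthetic DUS, residual energy after the loop
  was 0.7 / 3.6 / 13 / 43 % for 1 / 2 / 5 / 10 passes.  Two passes keep the
  consecutive-application (sifting) structure with negligible narrowing.

The loop stops when residual energy falls below `residual_threshold` (1%)
of the input, when `max_components` (8) is reached, or when an extracted OC
carries < 0.1% of the residual's energy (stall: nothing oscillatory left).

## Envelope and instantaneous energy

Envelope = rectify, zero-phase 4th-order Butterworth low-pass, multiply by
`pi/2`, clip negatives.  The `pi/2` factor is the rectified-mean correction
(mean of `|sin|` is `2/pi`), so a unit tone has envelope ≈ 1 and
instantaneous energy (squared envelope) ≈ 1.  `compute_envelope` defaults to
a 25 Hz cutoff; the event pipeline uses 60 Hz, because the Mc and Ao bursts
sit only ~40 ms apart and their interfering carriers produce an amplitude
notch that a 25 Hz filter smears into a single blob (costing ~20% of Ao
detections), while 60 Hz keeps the notch and still rejects rectification
ripple at twice the carrier (≥ 300 Hz).

## Reference-free cycle anchors

The anchor is a surrogate for the ECG R-peak, defined as the leading
50%-height crossing of the beat's first valve burst (Mc follows R by
0–50 ms, so this edge approximates R; measured bias ≈ −2 ms on synthetic
data).  Finding which burst is "first" is the hard part: per beat the
envelope carries two burst pairs (Mc/Ao systolic, Ac/Mo diastolic), and the
intra-beat Ao→Ac gap (~140 ms) is nearly as long as the diastolic pause
(~155 ms), so naive peak picking with a refractory period anchors a
noticeable fraction of beats on the wrong pair.  The detector therefore:

1. estimates the beat period from the envelope autocorrelation
   (lags 250–700 ms, the physiologic fetal RR range);
2. smooths the envelope just below the beat rate (`min(3.5 Hz, 1.3/T)`) and
   collects candidate humps;
3. finds the max-weight path through the candidates whose steps are
   period-consistent (deviations from an integer number of periods
   penalized; up to three missed beats bridged by virtual positions);
4. aligns the whole tracked grid against the four-event window template by
   the global shift that places the most burst peaks inside windows;
5. refines each anchor to the Mc leading edge, repairs anchors that
   disagree with their neighbors' interpolation, and finally re-aligns every
   anchor by cross-correlating its cycle against the beat-median envelope
   template (matching the whole four-burst profile averages the individual
   event jitters, taking per-beat anchor noise to ~3 ms).

Every step is deterministic.  In ECG-reference mode externally supplied
R-peaks are validated (strictly increasing, in range) and used verbatim.

## Event search and intervals

Cycles are the half-open spans between consecutive anchors; each cycle's
envelope segment is z-normalized (mean 0, sd 1 with the n−1 denominator;
zero-variance segments are rejected, as are beats with RR outside
250–700 ms).  Events are searched inside fixed windows after the anchor —
Mc 0–50, Ao 50–100, Ac 140–260, Mo 260–330 ms — clipped to the cycle and
treated half-open in samples.  Peaks are sign changes (+→−) of the first
difference of the normalized envelope; the highest peak above the
`noise_floor` (0.5 normalized units) wins, ties to the earlier peak; an
empty window is a missing event, never an error.

Intervals per beat: `ICT = t(Ao) − t(Mc)`, `VET = t(Ac) − t(Ao)`,
`IRT = t(Mo) − t(Ac)`, `PEP = EDT + ICT`, `STI = PEP + VET`.  `EDT` is the
electromechanical delay from electrical onset to Mc; no formula for PEP is
given with the published tables, but all three printed group rows satisfy
`PEP = ICT + 25 ms` exactly, so EDT defaults to 25 ms and is flagged as a
reverse-engineered convention, configurable.  Missing operands propagate;
negative differences (ordering violations) are set missing and flagged.
Rounding to 1 decimal happens only at reporting time.

## Group statistics

Subjects are the analysis units: per-subject interval means over retained
beats, then per group mean and `SE = sd(n−1)/sqrt(n)`.  Group comparison
uses the nonparametric pair — Kruskal–Wallis (tie-corrected H, chi-square
p with k−1 df) and two-sided Mann–Whitney–Wilcoxon for the three pairs,
exact when both groups have ≤ 20 untied values, normal approximation with
tie/continuity corrections otherwise, raw (unadjusted) p-values.  The
age–interval correlation is implemented as Spearman rank correlation
between gestational age (week if available, else group rank) and subject
interval means over pooled adjacent groups; the published tables do not
state their correlation's definition, so ours is documented as an
interpretation, not a reproduction.  ANOVA is deliberately omitted in
favor of the nonparametric pair that produced the published comparisons.

## Synthetic data

`generate_dus` emulates the morphology the pipeline exploits, with defaults
chosen as the study conditions: 60 s at 1 kHz; RR drawn per beat from
N(410, 12²) ms clipped to 250–700 ms (printed group means span ~405–423 ms);
four Gaussian-windowed tone bursts per beat (250 Hz carrier, 15 ms-sd
window, unit amplitude) at offsets N(15,3²)/N(55,4²)/N(195,5²)/N(270,4²) ms
— inside the standard windows and near the printed group timings; a 30 Hz
wall-motion tone amplitude-modulated once per beat (amplitude 0.8); white
Gaussian noise scaled to the requested SNR against the noiseless mixture
(10 dB default, ±0.5 dB verified; optional pink noise).  Ground truth
records every jittered event time and the implied per-beat intervals.
`generate_fecg` places a Ricker wavelet at each anchor for exercising
ECG-reference mode.  `generate_cohort` draws subject-level interval means
from group distributions and reconstructs event offsets as cumulative sums;
`simulate_subject_means` is the lightweight surrogate (no waveforms) for
statistical power studies.

What the generator does *not* model: Doppler speckle, transducer and fetal
movement artifacts, maternal interference, signal dropouts, beat-to-beat
morphology changes, and per-event carrier differences.  Passing the
synthetic benchmark therefore demonstrates the correctness of the
decomposition, segmentation and timing machinery under controlled
conditions — not clinical performance on real recordings.

Note also an adversarial feature kept deliberately: with these offsets the
true Ao time is N(55, 4²) ms against a window starting at 50 ms, so ~10% of
beats have Ao jittered outside its window and are correctly reported
missing; detection completeness on this benchmark saturates near 90–95%,
not 100%.

## Problem sizes and numerical conventions

The test suite exercises 20 seeded 60 s recordings at 10 dB SNR for timing
recovery, 200-replicate power simulations, and a 1000-replicate null
calibration of the Kruskal–Wallis test (type-I error ≤ 7% at nominal 5%).
The acceptance script draws 200 replicate cohorts of 16/21/29 subjects.
Indexing is 0-based with half-open segments; times are seconds in files and
milliseconds in interval columns; CSV is UTF-8/comma/`.`-decimal with
mandatory headers; missing values are empty cells.  The swarm kernel is
JIT-compiled with numba when available and falls back to the identical pure
Python loop otherwise.

## Known limitations

* The swarm force model is one concrete realization of the qualitative
  prey/cohesion description; other realizations with the same measured
  band-pass response would behave identically at the contract level, but
  internal member trajectories are not comparable to other implementations.
* A power simulation configured from the published group summaries
  (subject sd = SE·√n, n = 16/21/29) yields Kruskal–Wallis power of roughly
  0.6 (STI), 0.1 (IRT) and 0.7 (PEP) at alpha = 0.05 — the published
  significance of IRT in particular is not reproducible from its printed
  mean/SE under a normal model.  The acceptance script reports this honestly
  rather than adjusting the simulation.
* Decomposition is offline by design (zero-phase passes need the whole
  record); the method is not suitable for real-time use.
* Anchors assume quasi-periodic rhythm within 250–700 ms RR; arrhythmic
  records would defeat the period tracking.
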