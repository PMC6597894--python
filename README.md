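# swdus — fetal cardiac timing from Doppler ultrasound via swarm decomposition

Continuous fetal monitoring usually stops at heart rate, but the *timing*
of the cardiac valve motions carries much more: the systolic time intervals
change with gestational age and with compromised cardiac function.  A
1 MHz-class Doppler ultrasound (DUS) transducer hears those motions as
audio-band bursts — the closing and opening of the mitral (Mc, Mo) and
aortic (Ao, Ac) valves — buried in wall-motion components and noise, and
the signal is nonstationary enough that fixed filters or wavelets with
global parameters do poorly.

`swdus` implements **swarm decomposition (SWD)** for this problem: a
data-driven decomposition in which a virtual swarm (positions `p_i`,
velocities `v_i`, flexibility `δ`) hunts the signal as prey,

```
v_i[n] = v_i[n-1] + δ·(F_Dr,i[n] + F_Coh,i[n]),   p_i[n] = p_i[n-1] + δ·v_i[n],
```

and the swarm barycenter acts as a band-pass filter whose response is set
by the driving/cohesion forces.  Iterating a sifting-like loop peels the
signal into oscillatory components (OCs) with exact additive
reconstruction.  On top of the decomposition the package:

* selects the high-frequency valve component and computes its envelope;
* segments cardiac cycles **without any ECG reference** (autocorrelation
  period tracking + template alignment of the beat grid), or from supplied
  R-peaks for validation;
* locates Mc, Ao, Ac, Mo per beat inside the standard search windows
  (0–50, 50–100, 140–260, 260–330 ms after the anchor);
* derives per-beat intervals `ICT = Ao−Mc`, `VET = Ac−Ao`, `IRT = Mo−Ac`,
  `PEP = EDT + ICT` (electromechanical delay, default 25 ms),
  `STI = PEP + VET`;
* aggregates per subject and compares gestational-age groups with
  Kruskal–Wallis, pairwise Mann–Whitney and Spearman age correlations;
* generates synthetic DUS with full ground truth so every stage is
  testable without recordings.

See `docs/methods.md` for the model details and design rationale.

## Worked example

Reference-free event detection on a synthetic 60 s recording at 10 dB SNR
(`python examples/detect_valve_events.py`):

```
beats generated 147, anchors found 144
median |anchor error| 2.0 ms
beats with all four events: 138/143 (96.5%)
  Mc: median |timing error| 4.8 ms over 143 beats
  Ao: median |timing error| 4.2 ms over 138 beats
  Ac: median |timing error| 5.5 ms over 143 beats
  Mo: median |timing error| 4.5 ms over 143 beats
```

The pipeline finds essentially every beat without an ECG reference, anchors
them within ~2 ms of the true beat onsets, and recovers the four valve
events to a few milliseconds — small against the ~35–210 ms intervals
derived from them.  The two-tone decomposition check
(`python examples/decompose_two_tone.py`) prints

```
OC1: center  299.8 Hz, energy share 50.1%, corr with 300 Hz tone +0.9998
OC2: center   49.8 Hz, energy share 49.8%, corr with 50 Hz tone +0.9999
residual energy 0.03% of input; reconstruction error 1.4e-17
```

i.e. each tone lands in its own component and components + residual re-add
to the input exactly.  `examples/cohort_statistics.py` runs the full
group-statistics report on a simulated 16/21/29-subject cohort.

## Command line

The same stages are exposed as a CLI for shell use:

```
swdus simulate --duration 60 --seed 1 --out dus.wav      # + truth CSVs
swdus decompose dus.wav --out components.csv
swdus detect dus.wav --out events.csv                    # add --r-peaks for ECG-reference mode
swdus intervals events.csv --out intervals.csv --group early
swdus stats intervals.csv --out report/
```

Logging goes to stderr, results to files; a YAML config (`swd:`, `events:`,
`stats:`, `synthetic:` blocks) can override any default.

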