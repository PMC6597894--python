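"""Valve-event detection on a decomposed Doppler ultrasound signal.

The high-frequency oscillatory component of a fetal DUS recording carries the
valve clicks: mitral closure (Mc), aortic opening (Ao), aortic closure (Ac)
and mitral opening (Mo), in that order within each cardiac cycle.  This
module computes the component's envelope, finds one anchor per beat (a
surrogate for the ECG R-peak), cuts the envelope into per-cycle segments,
z-normalizes each segment and locates the four events inside fixed search
windows relative to the anchor.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .records import SignalRecord
from .swd import DecompositionConfig, DecompositionResult, swarm_decompose

logger = logging.getLogger(__name__)

EVENT_NAMES = ("mc", "ao", "ac", "mo")

__all__ = [
    "EVENT_NAMES",
    "EventWindows",
    "CycleSegment",
    "ValveEventSet",
    "AnchorOptions",
    "PipelineConfig",
    "PipelineResult",
    "compute_envelope",
    "select_valve_component",
    "detect_cycle_anchors",
    "segment_cycles",
    "normalize_segment",
    "detect_valve_events",
    "run_event_pipeline",
]


@dataclass(frozen=True)
class EventWindows:
    """Search windows (ms from the beat anchor) for the four valve events.

    Defaults follow the established fetal valve-timing windows: Mc 0-50 ms,
    Ao 50-100 ms, Ac 140-260 ms, Mo 260-330 ms after the R-peak.
    """

    mc: tuple[float, float] = (0.0, 50.0)
    ao: tuple[float, float] = (50.0, 100.0)
    ac: tuple[float, float] = (140.0, 260.0)
    mo: tuple[float, float] = (260.0, 330.0)

    def __post_init__(self) -> None:
        for name in EVENT_NAMES:
            a, b = getattr(self, name)
            if not a < b:
                raise ValueError(f"window {name} must have start < end")

    def window(self, name: str) -> tuple[float, float]:
        return getattr(self, name)


@dataclass(frozen=True)
class CycleSegment:
    """One cardiac cycle of the normalized envelope, ``[start_idx, end_idx)``."""

    start_idx: int
    end_idx: int
    rr_ms: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.end_idx <= self.start_idx:
            raise ValueError("empty segment")


@dataclass
class ValveEventSet:
    """Per-beat valve-event times in ms from the beat anchor (NaN = missing)."""

    beat_index: int
    t_mc_ms: float = math.nan
    t_ao_ms: float = math.nan
    t_ac_ms: float = math.nan
    t_mo_ms: float = math.nan
    quality_flags: dict = field(default_factory=dict)

    def time(self, name: str) -> float:
        return getattr(self, f"t_{name}_ms")

    def all_present(self) -> bool:
        return all(not math.isnan(self.time(n)) for n in EVENT_NAMES)


def compute_envelope(component: np.ndarray, fs: float, smooth_cutoff_hz: float = 25.0) -> np.ndarray:
    """Amplitude envelope: rectify, zero-phase low-pass, rescale, clip.

    The rectified mean of a sinusoid of amplitude ``A`` is ``2A/pi``; after
    low-pass smoothing the envelope is multiplied by ``pi/2`` so a unit tone
    yields an envelope of one (the documented rectified-mean correction).
    Zero-phase filtering keeps burst timing unbiased.  Negative excursions
    introduced by the filter are clipped to zero.
    """
    if not (0 < smooth_cutoff_hz < fs / 2):
        raise ValueError("smooth_cutoff_hz must lie in (0, fs/2)")
    x = np.abs(np.asarray(component, dtype=float))
    sos = sps.butter(4, smooth_cutoff_hz, btype="low", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, x) * (np.pi / 2.0)
    return np.clip(env, 0.0, None)


def select_valve_component(decomp: DecompositionResult, min_freq_hz: float = 100.0) -> int:
    """Index of the highest-energy component in the valve (high-frequency) band.

    Falls back to the component with the highest center frequency when no
    component reaches ``min_freq_hz``.
    """
    if not decomp.components:
        raise ValueError("decomposition has no components")
    qualifying = [
        i
        for i, c in enumerate(decomp.components)
        if np.isfinite(c.center_freq_hz) and c.center_freq_hz >= min_freq_hz
    ]
    if qualifying:
        return max(qualifying, key=lambda i: decomp.components[i].energy_fraction)
    centers = [
        c.center_freq_hz if np.isfinite(c.center_freq_hz) else -np.inf for c in decomp.components
    ]
    return int(np.argmax(centers))


@dataclass(frozen=True)
class AnchorOptions:
    """Tuning for envelope-based cycle-anchor detection.

    The detector estimates the beat period from the envelope autocorrelation,
    smooths the envelope just below the beat rate (capped at
    ``beat_smooth_hz``) so roughly one hump survives per beat, tracks one
    hump per cycle sequentially, aligns the tracked grid globally against the
    four-event window template, and finally refines each anchor to the
    leading 50%-height crossing of the beat's first valve burst (Mc).  Mc
    follows the R-peak by 0-50 ms, so this leading edge approximates the
    R-peak.  ``k_mad`` sets the burst threshold (median + k*MAD of the
    envelope, which tracks the inter-burst baseline because bursts are
    sparse).
    """

    min_rr_ms: float = 250.0
    max_rr_ms: float = 700.0
    k_mad: float = 3.0
    beat_smooth_hz: float = 3.5
    min_prominence_frac: float = 0.1
    template_windows: "EventWindows | None" = None


def detect_cycle_anchors(
    envelope: np.ndarray,
    fs: float,
    opts: AnchorOptions | None = None,
    r_peak_indices: np.ndarray | None = None,
) -> np.ndarray:
    """Per-beat anchor sample indices from the valve-component envelope.

    In ECG-reference mode (``r_peak_indices`` given) the supplied indices are
    validated for strict monotonicity and returned unchanged.
    """
    env = np.asarray(envelope, dtype=float)
    if r_peak_indices is not None:
        anchors = np.asarray(r_peak_indices, dtype=np.int64)
        if anchors.size < 2:
            raise ValueError("insufficient beats")
        if np.any(np.diff(anchors) <= 0):
            raise ValueError("r-peak indices must be strictly increasing")
        if anchors[0] < 0 or anchors[-1] >= env.size:
            raise ValueError("r-peak indices outside the signal")
        return anchors

    opts = opts or AnchorOptions()
    if env.size / fs < 2.0:
        raise ValueError("need at least 2 s of signal to detect beats")
    if np.any(env < 0):
        raise ValueError("envelope must be non-negative")

    period = _estimate_period(env, fs, opts)
    grid = _track_beats(env, fs, period, opts)
    if grid.size < 2:
        raise ValueError("insufficient beats")

    # burst peaks on the raw envelope
    med = float(np.median(env))
    mad = float(np.median(np.abs(env - med)))
    thr = med + opts.k_mad * mad
    bursts, _ = sps.find_peaks(env, height=thr, distance=max(1, int(0.015 * fs)))
    if bursts.size < 2:
        raise ValueError("insufficient beats")

    windows = opts.template_windows or EventWindows()
    shift = _align_to_template(grid, bursts, fs, period, windows)
    mc_hi = int(windows.mc[1] / 1000.0 * fs)
    anchors: list[int] = []
    for g in grid:
        a = int(round(g + shift))
        lo = max(0, a - int(0.030 * fs))
        hi = min(env.size, a + mc_hi + 1)
        if hi - lo < 3:
            continue
        cand = bursts[(bursts >= lo) & (bursts < hi)]
        if cand.size:
            first = int(cand[0])  # earliest burst near the anchor = Mc
            half = 0.5 * env[first]
            j = first
            while j > lo and env[j - 1] >= half:
                j -= 1
            a = j
        if 0 <= a < env.size:
            anchors.append(a)
    anchors_arr = np.array(sorted(set(anchors)), dtype=np.int64)
    # drop anchors closer than half the minimum RR (duplicate beats)
    keep = [0]
    min_gap = int(0.5 * opts.min_rr_ms / 1000.0 * fs)
    for i in range(1, anchors_arr.size):
        if anchors_arr[i] - anchors_arr[keep[-1]] >= min_gap:
            keep.append(i)
    anchors_arr = anchors_arr[keep] if anchors_arr.size else anchors_arr
    if anchors_arr.size < 2:
        raise ValueError("insufficient beats")
    anchors_arr = _fix_anchor_outliers(anchors_arr, env, bursts, fs)
    anchors_arr = _template_refine(anchors_arr, env, fs, period)
    if anchors_arr.size < 2:
        raise ValueError("insufficient beats")
    return anchors_arr


def _fix_anchor_outliers(
    anchors: np.ndarray, env: np.ndarray, bursts: np.ndarray, fs: float
) -> np.ndarray:
    """Re-refine anchors that disagree with their neighbours' prediction.

    An anchor that latched onto the wrong burst (e.g. Ao instead of Mc) sits
    tens of ms off the locally interpolated beat grid; such outliers are
    re-anchored to the burst rise nearest the prediction.
    """
    a = anchors.astype(float).copy()
    tol = 0.025 * fs
    for _ in range(2):
        for k in range(1, a.size - 1):
            pred = 0.5 * (a[k - 1] + a[k + 1])
            if abs(a[k] - pred) <= tol:
                continue
            lo, hi = pred - 0.045 * fs, pred + 0.030 * fs
            cand = bursts[(bursts >= lo + 0.015 * fs) & (bursts <= hi + 0.020 * fs)]
            if cand.size:
                first = int(cand[0])
                half = 0.5 * env[first]
                j = first
                while j > int(lo) and j > 0 and env[j - 1] >= half:
                    j -= 1
                a[k] = j
            else:
                a[k] = pred
    out = np.unique(np.round(a).astype(np.int64))
    return out[(out >= 0) & (out < env.size)]


def _template_refine(
    anchors: np.ndarray, env: np.ndarray, fs: float, period: float, max_shift_ms: float = 45.0
) -> np.ndarray:
    """Align each anchor to the beat-median envelope template.

    The median cycle profile (all beats aligned at their current anchors) is
    cross-correlated with each beat locally; the correlating shift replaces
    the anchor.  Matching against the whole four-burst profile averages the
    individual event jitters, so per-beat anchor noise drops well below the
    jitter of any single burst edge.  Two iterations (the template sharpens
    once anchors improve).
    """
    if anchors.size < 5:
        return anchors
    pre = int(0.050 * fs)
    length = int(0.85 * period) + pre
    max_shift = int(max_shift_ms / 1000.0 * fs)
    a = anchors.astype(np.int64).copy()
    x = env - float(np.median(env))
    for _ in range(2):
        segs = []
        for ai in a:
            lo = ai - pre
            if lo < 0 or lo + length > x.size:
                continue
            segs.append(x[lo : lo + length])
        if len(segs) < 5:
            return a
        template = np.median(np.vstack(segs), axis=0)
        template = template - template.mean()
        norm_t = np.linalg.norm(template)
        if norm_t == 0.0:
            return a
        new = []
        for ai in a:
            best_s, best_c = 0, -np.inf
            for s in range(-max_shift, max_shift + 1):
                lo = ai + s - pre
                if lo < 0 or lo + length > x.size:
                    continue
                seg = x[lo : lo + length]
                c = float(np.dot(seg, template))
                if c > best_c:
                    best_c, best_s = c, s
            new.append(ai + best_s)
        a = np.unique(np.array(new, dtype=np.int64))
    return a


def _estimate_period(env: np.ndarray, fs: float, opts: AnchorOptions) -> float:
    """Beat period (samples) from the envelope autocorrelation."""
    x = env - env.mean()
    if np.max(np.abs(x)) == 0.0:
        raise ValueError("insufficient beats")
    ac = sps.fftconvolve(x, x[::-1], mode="full")[x.size - 1 :]
    lo = int(opts.min_rr_ms / 1000.0 * fs)
    hi = min(int(opts.max_rr_ms / 1000.0 * fs) + 1, ac.size)
    if hi - lo < 2:
        raise ValueError("insufficient beats")
    lag = lo + int(np.argmax(ac[lo:hi]))
    if ac[lag] <= 0:
        raise ValueError("insufficient beats")
    return float(lag)


def _track_beats(env: np.ndarray, fs: float, period: float, opts: AnchorOptions) -> np.ndarray:
    """One smoothed-envelope hump position per beat, by sequential tracking.

    Peaks of the beat-rate-smoothed envelope are chained from the strongest
    one outward, each time looking for a peak one local period ahead (within
    +-30%); where none exists a virtual position is inserted so the grid
    survives dropouts.  This resolves the ambiguity between the systolic
    (Mc/Ao) and diastolic (Ac/Mo) burst pairs, which plain peak picking with
    a refractory distance does not.
    """
    cutoff = min(opts.beat_smooth_hz, 1.3 * fs / period)
    sos = sps.butter(2, cutoff, btype="low", fs=fs, output="sos")
    sm = sps.sosfiltfilt(sos, env)
    p10, p90 = np.percentile(sm, [10, 90])
    prom = opts.min_prominence_frac * max(p90 - p10, 1e-12)
    peaks, _ = sps.find_peaks(sm, prominence=prom, distance=max(1, int(0.4 * period)))
    if peaks.size < 2:
        raise ValueError("insufficient beats")

    # max-weight path through the peaks with period-consistent steps: each
    # kept peak earns ~1, deviations from an integer number of periods and
    # skipped beats are penalized; up to 3-beat dropouts are bridged.
    w = 1.0 + 0.2 * sm[peaks] / max(float(sm[peaks].max()), 1e-12)
    n = peaks.size
    dp = w.copy()
    prev = np.full(n, -1, dtype=np.int64)
    for i in range(1, n):
        for j in range(i - 1, -1, -1):
            gap = float(peaks[i] - peaks[j])
            if gap > 3.45 * period:
                break
            m = max(1, int(round(gap / period)))
            if m > 3:
                continue
            dev = abs(gap - m * period) / period
            if dev > 0.35:
                continue
            cand = dp[j] + w[i] - 1.5 * dev - 0.55 * (m - 1)
            if cand > dp[i]:
                dp[i] = cand
                prev[i] = j
    path = [int(np.argmax(dp))]
    while prev[path[-1]] >= 0:
        path.append(int(prev[path[-1]]))
    path = path[::-1]
    grid: list[float] = [float(peaks[path[0]])]
    for j, i in zip(path[:-1], path[1:]):
        gap = float(peaks[i] - peaks[j])
        m = max(1, int(round(gap / period)))
        for k in range(1, m):  # fill dropouts with evenly spaced virtual beats
            grid.append(float(peaks[j]) + gap * k / m)
        grid.append(float(peaks[i]))
    return np.array(grid)


def _align_to_template(
    grid: np.ndarray,
    bursts: np.ndarray,
    fs: float,
    period: float,
    windows: EventWindows,
) -> float:
    """Global shift (samples) placing the most burst peaks inside the windows.

    The tracked humps have a stable but unknown phase relative to the R-peak;
    sliding the whole grid and scoring how many of the four event windows
    capture a burst, summed over beats, recovers that phase.  Ties prefer the
    largest (least negative) shift.
    """
    shifts = np.arange(-0.85 * period, 0.26 * period, max(1.0, 0.002 * fs))
    win_samp = [
        (int(windows.window(n)[0] / 1000.0 * fs), int(windows.window(n)[1] / 1000.0 * fs))
        for n in EVENT_NAMES
    ]
    scores = np.zeros(shifts.size)
    half = 0.7 * period
    for g in grid:
        rel = bursts[(bursts >= g - half) & (bursts <= g + half + max(w[1] for w in win_samp))] - g
        if rel.size == 0:
            continue
        for si, s in enumerate(shifts):
            r = rel - s
            scores[si] += sum(1 for a, b in win_samp if np.any((r >= a) & (r < b)))
    best = scores.max()
    # last argmax -> largest shift among ties
    return float(shifts[np.where(scores == best)[0][-1]])


def segment_cycles(signal_len: int, anchors: np.ndarray, fs: float) -> list[tuple[int, int, float]]:
    """Half-open per-cycle boundaries ``(start, end, rr_ms)`` between anchors.

    Samples before the first and after the last anchor are discarded; the
    K-1 segments exactly tile ``[anchors[0], anchors[-1])``.
    """
    anchors = np.asarray(anchors, dtype=np.int64)
    if anchors.size < 2:
        raise ValueError("need at least 2 anchors")
    if np.any(np.diff(anchors) <= 0):
        raise ValueError("anchors must be strictly increasing")
    if anchors[-1] >= signal_len or anchors[0] < 0:
        raise ValueError("anchors outside the signal")
    out = []
    for a, b in zip(anchors[:-1], anchors[1:]):
        out.append((int(a), int(b), (b - a) * 1000.0 / fs))
    return out


def normalize_segment(values: np.ndarray) -> np.ndarray:
    """Z-normalize: subtract the mean, divide by the sample sd (n-1)."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("segment too short to normalize")
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        raise ValueError("degenerate segment")
    return (v - v.mean()) / sd


def detect_valve_events(
    segment: CycleSegment,
    fs: float,
    windows: EventWindows | None = None,
    noise_floor: float = 0.5,
) -> ValveEventSet:
    """Locate the four valve events inside one normalized cycle segment.

    Peaks are sign changes (+ to -) of the first difference of the envelope;
    inside each window (clipped to the segment) the highest peak above
    ``noise_floor`` wins, ties broken toward the earlier peak.  Events with no
    qualifying peak are reported missing (NaN), never as errors.
    """
    windows = windows or EventWindows()
    v = segment.values
    d = np.diff(v)
    # peak at i when d[i-1] > 0 and d[i] <= 0 (first sample of a plateau)
    peak_idx = np.where((d[:-1] > 0) & (d[1:] <= 0))[0] + 1
    result = ValveEventSet(beat_index=0)
    for name in EVENT_NAMES:
        a, b = windows.window(name)
        lo_ms, hi_ms = max(a, 0.0), min(b, segment.rr_ms)
        if hi_ms <= lo_ms:
            result.quality_flags[f"{name}_window_empty"] = True
            continue
        lo = int(np.ceil(lo_ms * fs / 1000.0))
        hi = min(int(np.ceil(hi_ms * fs / 1000.0)), v.size)  # half-open [lo, hi)
        cand = peak_idx[(peak_idx >= lo) & (peak_idx < hi)]
        cand = cand[v[cand] >= noise_floor]
        if cand.size == 0:
            continue
        best = cand[int(np.argmax(v[cand]))]  # argmax returns first max: earlier tie wins
        setattr(result, f"t_{name}_ms", best * 1000.0 / fs)
    times = [result.time(n) for n in EVENT_NAMES]
    if all(not math.isnan(t) for t in times) and not (times[0] < times[1] < times[2] < times[3]):
        result.quality_flags["ordering_violation"] = True
    return result


@dataclass
class PipelineConfig:
    """End-to-end configuration for :func:`run_event_pipeline`."""

    swd: DecompositionConfig = field(default_factory=DecompositionConfig)
    # 60 Hz resolves valve bursts ~40 ms apart (Mc/Ao) that a heavier smoothing
    # merges, while still rejecting rectification ripple (>= 2x carrier).
    envelope_cutoff_hz: float = 60.0
    anchor: AnchorOptions = field(default_factory=AnchorOptions)
    windows: EventWindows = field(default_factory=EventWindows)
    noise_floor: float = 0.5
    min_valve_freq_hz: float = 100.0
    rr_bounds_ms: tuple[float, float] = (250.0, 700.0)


@dataclass
class PipelineResult:
    events: list[ValveEventSet]
    rr_ms: list[float]
    anchors_idx: np.ndarray
    anchor_times_s: np.ndarray
    valve_component_index: int
    decomposition: DecompositionResult
    envelope: np.ndarray
    n_rejected_beats: int = 0


def run_event_pipeline(
    signal: SignalRecord,
    config: PipelineConfig | None = None,
    r_peak_times_s: np.ndarray | None = None,
) -> PipelineResult:
    """Full chain: decompose, select valve component, find anchors, detect events.

    ``r_peak_times_s`` switches to ECG-reference mode, using external R-peak
    times (seconds) as cycle anchors.  Beats whose RR falls outside
    ``rr_bounds_ms`` (physiologic fetal range) or whose envelope segment is
    degenerate are rejected.
    """
    config = config or PipelineConfig()
    if signal.duration_s < 5.0:
        raise ValueError("need at least 5 s of signal")
    decomp = swarm_decompose(signal, config.swd)
    idx = select_valve_component(decomp, config.min_valve_freq_hz)
    env = compute_envelope(decomp.components[idx].samples, signal.fs, config.envelope_cutoff_hz)
    if r_peak_times_s is not None:
        r_idx = np.round((np.asarray(r_peak_times_s, float) - signal.t0) * signal.fs).astype(np.int64)
        r_idx = r_idx[(r_idx >= 0) & (r_idx < len(signal))]
        anchors = detect_cycle_anchors(env, signal.fs, config.anchor, r_peak_indices=r_idx)
    else:
        anchors = detect_cycle_anchors(env, signal.fs, config.anchor)
    boundaries = segment_cycles(len(signal), anchors, signal.fs)

    events: list[ValveEventSet] = []
    rrs: list[float] = []
    n_rejected = 0
    lo_rr, hi_rr = config.rr_bounds_ms
    for k, (a, b, rr) in enumerate(boundaries):
        if not (lo_rr <= rr <= hi_rr):
            n_rejected += 1
            continue
        try:
            values = normalize_segment(env[a:b])
        except ValueError:
            n_rejected += 1
            continue
        seg = CycleSegment(start_idx=a, end_idx=b, rr_ms=rr, values=values)
        ev = detect_valve_events(seg, signal.fs, config.windows, config.noise_floor)
        ev.beat_index = k
        events.append(ev)
        rrs.append(rr)
    n_missing = sum(0 if e.all_present() else 1 for e in events)
    logger.info(
        "pipeline: %d beats (%d rejected), %d with incomplete events",
        len(events),
        n_rejected,
        n_missing,
    )
    return PipelineResult(
        events=events,
        rr_ms=rrs,
        anchors_idx=anchors,
        anchor_times_s=signal.t0 + anchors / signal.fs,
        valve_component_index=idx,
        decomposition=decomp,
        envelope=env,
        n_rejected_beats=n_rejected,
    )
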