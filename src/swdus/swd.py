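"""Swarm filtering (SwF) and swarm decomposition (SWD).

The swarm filter treats the input sequence as the trajectory of a prey
hunted by a virtual swarm of ``M`` members.  Each member ``i`` carries a
position ``p_i`` and velocity ``v_i`` updated at every sample ``n``::

    v_i[n] = v_i[n-1] + delta * (F_Dr,i[n] + F_Coh,i[n])
    p_i[n] = p_i[n-1] + delta * v_i[n]

with a driving force pulling members toward the prey (the current input
sample) while dissipating their momentum,

    F_Dr,i[n] = drive_gain * (s[n] - p_i[n-1]) - v_i[n-1],

and a cohesion force that keeps the swarm together (attractive toward the
swarm barycenter, optionally repulsive at short range to avoid collisions),

    F_Coh,i[n] = cohesion_gain * (mean_j p_j[n-1] - p_i[n-1]) + repulsion.

The filter output is the mean member position.  The barycenter obeys a
second-order resonator whose poles are placed exactly by ``SwFParams.for_band``,
so each parameter preset behaves as a band-pass filter; the sweep is run
forward and then backward over the signal so the response is zero-phase
(timing of transient bursts is not biased).

Swarm decomposition (SWD) peels Oscillatory Components (OCs) off a
multicomponent signal by a sifting-like loop: estimate the dominant frequency
of the residual, pick the calibrated preset nearest in log-frequency, extract
an OC by repeated swarm filtering, subtract it, repeat.
"""
from __future__ import annotations

import functools
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .records import SignalRecord

logger = logging.getLogger(__name__)

__all__ = [
    "SwFParams",
    "SwarmDivergenceError",
    "OscillatoryComponent",
    "DecompositionResult",
    "DecompositionConfig",
    "CalibrationEntry",
    "CalibrationTable",
    "estimate_dominant_frequency",
    "swarm_filter",
    "extract_oscillatory_component",
    "swarm_decompose",
    "calibrate_swf",
    "default_preset_family",
    "default_calibration",
    "instantaneous_energy",
]


class SwarmDivergenceError(RuntimeError):
    """Raised when the swarm state leaves the admissible region."""


@dataclass(frozen=True)
class SwFParams:
    """Swarm-filter parameter preset.

    ``delta`` is the swarm flexibility (the virtual time step between state
    updates); ``drive_gain`` scales the prey attraction; ``cohesion_gain``
    the attraction toward the swarm barycenter; ``repulsion_scale`` the
    distance below which members repel (0 disables repulsion);
    ``n_passes`` how many consecutive filter applications build one OC.
    """

    delta: float
    drive_gain: float
    n_members: int = 20
    cohesion_gain: float = 0.0
    repulsion_scale: float = 0.0
    n_passes: int = 2

    def __post_init__(self) -> None:
        if not (self.delta > 0):
            raise ValueError("delta must be positive")
        if not (self.drive_gain > 0):
            raise ValueError("drive_gain must be positive")
        if self.n_members < 2:
            raise ValueError("need at least 2 swarm members")
        if self.cohesion_gain < 0 or self.repulsion_scale < 0:
            raise ValueError("cohesion_gain and repulsion_scale must be non-negative")
        if self.n_passes < 1:
            raise ValueError("n_passes must be >= 1")

    @classmethod
    def for_band(
        cls,
        center_freq_hz: float,
        fs: float,
        sharpness: float = 0.353,
        n_members: int = 20,
        n_passes: int = 2,
    ) -> "SwFParams":
        """Design a preset whose barycenter resonates at ``center_freq_hz``.

        The barycenter dynamics form a two-pole resonator; we place its poles
        at ``r * exp(+-j*w)`` with ``w = 2*pi*f/fs`` and
        ``r = exp(-sharpness * w * (pi - w)/pi)`` — constant-Q at low
        frequency, with the bandwidth tapering toward Nyquist so that every
        preset keeps an interior resonance (a heavily damped pole pair near
        ``w = pi`` would otherwise peak at Nyquist itself).  The default
        ``sharpness`` makes a 12-band log-spaced family over
        ``[0.005*fs, 0.45*fs]`` overlap generously.  Inverting the barycenter
        recursion gives ``delta = 1 - r^2`` and
        ``drive_gain = (1 + r^2 - 2*r*cos(w)) / delta^2`` exactly.
        """
        if not (0 < center_freq_hz < fs / 2):
            raise ValueError("center frequency must lie in (0, fs/2)")
        w = 2.0 * np.pi * center_freq_hz / fs
        r = float(np.exp(-sharpness * w * (np.pi - w) / np.pi))
        delta = 1.0 - r * r
        drive_gain = (1.0 + r * r - 2.0 * r * np.cos(w)) / delta**2
        # Member deviations from the barycenter obey the same recursion with
        # gain drive_gain + cohesion_gain; keep their poles inside the unit
        # circle with margin (budget delta^2*g_c < 1 + r^2 + 2 r cos w).
        budget = (1.0 + r * r + 2.0 * r * np.cos(w)) / delta**2
        cohesion_gain = float(min(drive_gain, 0.25 * max(budget, 0.0)))
        return cls(
            delta=delta,
            drive_gain=float(drive_gain),
            n_members=n_members,
            cohesion_gain=cohesion_gain,
            n_passes=n_passes,
        )


# ---------------------------------------------------------------------------
# state-update kernel (numba-accelerated when available)
# ---------------------------------------------------------------------------

def _sweep_py(x, m, delta, gd, gc, rep, spread, bound):
    n = x.shape[0]
    p = np.empty(m)
    v = np.zeros(m)
    for i in range(m):
        p[i] = x[0] - spread + 2.0 * spread * i / (m - 1)
    y = np.empty(n)
    for t in range(n):
        pm = 0.0
        for i in range(m):
            pm += p[i]
        pm /= m
        for i in range(m):
            f = gd * (x[t] - p[i]) - v[i] + gc * (pm - p[i])
            if rep > 0.0:
                for j in range(m):
                    if j == i:
                        continue
                    d = p[i] - p[j]
                    ad = abs(d)
                    if ad < rep:
                        s = 1.0 if (d > 0.0 or (d == 0.0 and i > j)) else -1.0
                        f += gc * s * (rep - ad) / rep
            v[i] += delta * f
        ok = True
        out = 0.0
        for i in range(m):
            p[i] += delta * v[i]
            out += p[i]
            if not np.isfinite(p[i]) or abs(p[i]) > bound:
                ok = False
        y[t] = out / m
        if not ok:
            return y, False
    return y, True


try:  # pragma: no cover - exercised implicitly everywhere
    import numba

    _sweep = numba.njit(cache=True, nogil=True)(_sweep_py)
except Exception:  # pragma: no cover - numba is a hard dependency in practice
    _sweep = _sweep_py
    logger.warning("numba unavailable; swarm filtering will run in pure Python")


def _one_direction(x: np.ndarray, params: SwFParams, spread: float, bound: float) -> np.ndarray:
    y, ok = _sweep(
        x,
        params.n_members,
        params.delta,
        params.drive_gain,
        params.cohesion_gain,
        params.repulsion_scale,
        spread,
        bound,
    )
    if not ok:
        raise SwarmDivergenceError("swarm diverged (reduce delta)")
    return y


def swarm_filter(
    signal: SignalRecord,
    params: SwFParams,
    init_spread: float | None = None,
) -> np.ndarray:
    """Apply one zero-phase swarm-filter pass; returns the filtered samples.

    Members start evenly spread in ``[x[0]-eps, x[0]+eps]`` with zero velocity,
    ``eps = 1e-6 * max(1, |x[0]|)`` unless ``init_spread`` is given; the sweep
    runs forward over the samples, then backward over its own output, so the
    net response is zero-phase.  With ``init_spread`` scaled along with the
    input the operator is exactly homogeneous: ``swarm_filter(c*x, c*eps) ==
    c * swarm_filter(x, eps)`` (repulsion disabled).
    """
    x = signal.samples
    bound = 1e6 * max(float(np.max(np.abs(x))), 1e-6)
    spread = init_spread if init_spread is not None else 1e-6 * max(1.0, abs(float(x[0])))
    y = _one_direction(x, params, spread, bound)
    yr = np.ascontiguousarray(y[::-1])
    spread2 = init_spread if init_spread is not None else 1e-6 * max(1.0, abs(float(yr[0])))
    z = _one_direction(yr, params, spread2, bound)
    return np.ascontiguousarray(z[::-1])


# ---------------------------------------------------------------------------
# spectral helpers
# ---------------------------------------------------------------------------

def estimate_dominant_frequency(signal: SignalRecord) -> float:
    """Frequency (Hz) of the maximum of a smoothed PSD of the signal.

    Uses Welch averaging of the mean-removed signal; raises if the signal has
    no oscillatory content (zero variance).
    """
    x = signal.samples
    if x.size < 64:
        raise ValueError("need at least 64 samples to estimate a dominant frequency")
    x = x - x.mean()
    if np.max(np.abs(x)) == 0.0:
        raise ValueError("no oscillatory content")
    nperseg = min(x.size, 2048)
    f, pxx = sps.welch(x, fs=signal.fs, nperseg=nperseg, detrend=False)
    # skip the DC bin
    k = 1 + int(np.argmax(pxx[1:]))
    return float(f[k])


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationEntry:
    preset_id: str
    params: SwFParams
    center_freq_hz: float
    bandwidth_hz: float
    peak_gain: float


@dataclass
class CalibrationTable:
    """Measured frequency responses for a family of SwF presets.

    Rows are sorted by measured center frequency; ``nearest`` looks a preset
    up by log-frequency distance.  Lookup requires the measured centers to be
    strictly monotone along the family.
    """

    entries: list[CalibrationEntry]
    fs: float

    def __post_init__(self) -> None:
        self.entries = sorted(self.entries, key=lambda e: e.center_freq_hz)
        centers = [e.center_freq_hz for e in self.entries]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("calibrated center frequencies must be strictly increasing")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def centers_hz(self) -> np.ndarray:
        return np.array([e.center_freq_hz for e in self.entries])

    def nearest(self, freq_hz: float) -> CalibrationEntry:
        if not self.entries:
            raise ValueError("empty calibration table")
        f = max(freq_hz, 1e-9)
        d = np.abs(np.log(self.centers_hz) - np.log(f))
        return self.entries[int(np.argmin(d))]

    def to_frame(self):
        import pandas as pd

        rows = []
        for e in self.entries:
            rows.append(
                dict(
                    preset_id=e.preset_id,
                    delta=e.params.delta,
                    n_members=e.params.n_members,
                    drive_gain=e.params.drive_gain,
                    cohesion_gain=e.params.cohesion_gain,
                    center_freq_hz=e.center_freq_hz,
                    bandwidth_hz=e.bandwidth_hz,
                    peak_gain=e.peak_gain,
                )
            )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float) -> "CalibrationTable":
        import pandas as pd

        df = pd.read_csv(path)
        entries = []
        for _, row in df.iterrows():
            params = SwFParams(
                delta=float(row["delta"]),
                drive_gain=float(row["drive_gain"]),
                n_members=int(row["n_members"]),
                cohesion_gain=float(row["cohesion_gain"]),
            )
            entries.append(
                CalibrationEntry(
                    preset_id=str(row["preset_id"]),
                    params=params,
                    center_freq_hz=float(row["center_freq_hz"]),
                    bandwidth_hz=float(row["bandwidth_hz"]),
                    peak_gain=float(row.get("peak_gain", np.nan)),
                )
            )
        return cls(entries=entries, fs=fs)


def default_preset_family(fs: float, n_presets: int = 12) -> list[SwFParams]:
    """Log-spaced preset family covering ``[0.005*fs, 0.45*fs]``.

    At the 1 kHz sampling rate of the Doppler recordings this spans 5-450 Hz:
    low bands for cardiac wall motion, high bands for valve clicks.
    """
    f_lo, f_hi = 0.005 * fs, 0.45 * fs
    centers = np.geomspace(f_lo, f_hi, n_presets)
    return [SwFParams.for_band(f, fs) for f in centers]


def _probe_gain(params: SwFParams, f: float, fs: float) -> float:
    dur = max(1.0, 8.0 / f)
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    x = np.sin(2 * np.pi * f * t)
    rec = SignalRecord(x, fs, label="probe")
    y = swarm_filter(rec, params)
    lo, hi = n // 4, 3 * n // 4  # central half: transients excluded
    rx = np.sqrt(np.mean(x[lo:hi] ** 2))
    ry = np.sqrt(np.mean(y[lo:hi] ** 2))
    return ry / rx


def calibrate_swf(
    preset_family: list[SwFParams],
    fs: float,
    probe_freqs: np.ndarray | None = None,
) -> CalibrationTable:
    """Measure each preset's band-pass response with swept probe sinusoids.

    For every preset the steady-state gain (RMS out / RMS in over the central
    half of the probe) is recorded on a log-spaced frequency grid; the table
    stores the gain-maximizing frequency and the -3 dB bandwidth.  Presets
    with no interior gain maximum are rejected with a warning.
    """
    if not preset_family:
        raise ValueError("preset family must be nonempty")
    if probe_freqs is None:
        probe_freqs = np.geomspace(0.002 * fs, 0.48 * fs, 97)
    probe_freqs = np.asarray(probe_freqs, dtype=float)
    entries: list[CalibrationEntry] = []
    for k, params in enumerate(preset_family):
        try:
            gains = np.array([_probe_gain(params, f, fs) for f in probe_freqs])
        except SwarmDivergenceError:
            warnings.warn(f"preset {k} diverged during calibration; rejected")
            continue
        i = int(np.argmax(gains))
        if i == 0 or i == gains.size - 1:
            warnings.warn(f"preset {k} has no interior gain maximum; rejected")
            continue
        fc = float(probe_freqs[i])
        gmax = float(gains[i])
        half = gmax / np.sqrt(2.0)
        # -3 dB crossings on both flanks (log-frequency interpolation);
        # fall back to the grid edge if a flank never drops below half power.
        lo = probe_freqs[0]
        for j in range(i, 0, -1):
            if gains[j - 1] < half:
                lo = np.interp(half, [gains[j - 1], gains[j]], [probe_freqs[j - 1], probe_freqs[j]])
                break
        hi = probe_freqs[-1]
        for j in range(i, gains.size - 1):
            if gains[j + 1] < half:
                hi = np.interp(
                    half, [gains[j + 1], gains[j]], [probe_freqs[j + 1], probe_freqs[j]]
                )
                break
        entries.append(
            CalibrationEntry(
                preset_id=f"p{k:02d}",
                params=params,
                center_freq_hz=fc,
                bandwidth_hz=float(hi - lo),
                peak_gain=gmax,
            )
        )
    return CalibrationTable(entries=entries, fs=fs)


@functools.lru_cache(maxsize=8)
def default_calibration(fs: float = 1000.0) -> CalibrationTable:
    """Calibrated default preset family for sampling rate ``fs`` (cached)."""
    return calibrate_swf(default_preset_family(fs), fs)


# ---------------------------------------------------------------------------
# decomposition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OscillatoryComponent:
    """One extracted oscillatory component (OC)."""

    samples: np.ndarray
    center_freq_hz: float
    iteration: int
    energy_fraction: float


@dataclass
class DecompositionResult:
    components: list[OscillatoryComponent]
    residual: np.ndarray
    fs: float

    def reconstruction(self) -> np.ndarray:
        out = self.residual.copy()
        for c in self.components:
            out += c.samples
        return out

    def to_frame(self, t0: float = 0.0):
        import pandas as pd

        n = self.residual.size
        data = {"time_s": t0 + np.arange(n) / self.fs}
        for i, c in enumerate(self.components, start=1):
            data[f"oc{i}"] = c.samples
        data["residual"] = self.residual
        return pd.DataFrame(data)


@dataclass
class DecompositionConfig:
    """Settings for :func:`swarm_decompose`.

    ``residual_threshold`` is the fraction of input energy below which the
    residual is considered exhausted; ``min_component_energy`` stops the loop
    when an extracted OC carries almost none of the residual's energy (the
    filter bank no longer latches onto anything oscillatory).
    """

    calibration: CalibrationTable | None = None
    auto_calibrate: bool = True
    residual_threshold: float = 0.01
    max_components: int = 8
    min_component_energy: float = 1e-3
    stop_correlation: float = 0.999


def extract_oscillatory_component(
    signal: SignalRecord,
    params: SwFParams,
    stop_correlation: float = 0.999,
) -> OscillatoryComponent:
    """Build one OC by consecutive swarm-filter applications.

    The output of pass ``k`` feeds pass ``k+1``; iteration stops early when
    two consecutive passes correlate at ``stop_correlation`` or better.
    """
    x = signal.samples
    e_in = float(np.dot(x, x))
    if e_in == 0.0:
        return OscillatoryComponent(
            samples=np.zeros_like(x), center_freq_hz=float("nan"), iteration=1, energy_fraction=0.0
        )
    y = x
    for _ in range(params.n_passes):
        y2 = swarm_filter(signal.with_samples(y), params)
        c = _pearson(y, y2)
        y = y2
        if c >= stop_correlation:
            break
    e_out = float(np.dot(y, y))
    if e_out == 0.0 or e_in == 0.0:
        center = float("nan")
    else:
        try:
            center = estimate_dominant_frequency(signal.with_samples(y))
        except ValueError:
            center = float("nan")
    frac = 0.0 if e_in == 0.0 else e_out / e_in
    return OscillatoryComponent(samples=y, center_freq_hz=center, iteration=1, energy_fraction=frac)


def swarm_decompose(
    signal: SignalRecord,
    config: DecompositionConfig | None = None,
) -> DecompositionResult:
    """Decompose a signal into oscillatory components plus a residual.

    Sifting loop: estimate the residual's dominant frequency, pick the
    calibrated preset nearest in log-frequency, extract an OC, rescale it by
    its least-squares projection onto the residual, subtract, repeat until the
    residual energy drops below ``residual_threshold`` times the input energy
    or ``max_components`` is reached.  The component list plus residual always
    reconstructs the input exactly (by construction).
    """
    config = config or DecompositionConfig()
    if len(signal) < 256:
        raise ValueError("need at least 256 samples to decompose")
    table = config.calibration
    if table is None:
        if not config.auto_calibrate:
            raise ValueError("no calibration table supplied and auto-calibration disabled")
        table = default_calibration(signal.fs)

    x = signal.samples
    e0 = float(np.dot(x, x))
    residual = x.copy()
    components: list[OscillatoryComponent] = []
    if e0 == 0.0:
        return DecompositionResult(components=components, residual=residual, fs=signal.fs)

    while len(components) < config.max_components:
        e_res = float(np.dot(residual, residual))
        if e_res <= config.residual_threshold * e0:
            break
        try:
            f_dom = estimate_dominant_frequency(signal.with_samples(residual))
        except ValueError:
            break
        entry = table.nearest(f_dom)
        oc = extract_oscillatory_component(
            signal.with_samples(residual), entry.params, config.stop_correlation
        )
        denom = float(np.dot(oc.samples, oc.samples))
        if denom == 0.0:
            break
        alpha = float(np.dot(residual, oc.samples)) / denom
        scaled = alpha * oc.samples
        e_comp = float(np.dot(scaled, scaled))
        if e_comp < config.min_component_energy * e_res:
            logger.debug("stalled at component %d (preset %s)", len(components) + 1, entry.preset_id)
            break
        residual = residual - scaled
        try:
            center = estimate_dominant_frequency(signal.with_samples(scaled))
        except ValueError:
            center = float("nan")
        components.append(
            OscillatoryComponent(
                samples=scaled,
                center_freq_hz=center,
                iteration=len(components) + 1,
                energy_fraction=e_comp / e0,
            )
        )
        logger.debug(
            "OC %d: preset %s, center %.1f Hz, energy fraction %.3g",
            len(components),
            entry.preset_id,
            center,
            e_comp / e0,
        )
    return DecompositionResult(components=components, residual=residual, fs=signal.fs)


def instantaneous_energy(
    component: OscillatoryComponent | np.ndarray,
    fs: float,
    smooth_cutoff_hz: float = 25.0,
) -> np.ndarray:
    """Squared envelope of a component (non-negative, same length)."""
    from .events import compute_envelope

    samples = component.samples if isinstance(component, OscillatoryComponent) else np.asarray(component, float)
    env = compute_envelope(samples, fs, smooth_cutoff_hz)
    return env**2
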