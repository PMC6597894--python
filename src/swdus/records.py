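"""Basic waveform container shared by all pipeline stages."""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SignalRecord:
    """A uniformly sampled real-valued waveform.

    Parameters
    ----------
    samples : array-like
        Signal values (arbitrary units). Must be finite and at least 2 long.
    fs : float
        Sampling rate in Hz (> 0).
    label : str
        Free-text provenance label.
    t0 : float
        Start time in seconds of the first sample.
    """

    samples: np.ndarray
    fs: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        x = np.ascontiguousarray(self.samples, dtype=np.float64)
        if x.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if x.size < 2:
            raise ValueError("need at least 2 samples")
        if not np.all(np.isfinite(x)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        object.__setattr__(self, "samples", x)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return self.t0 + np.arange(self.samples.size) / self.fs

    def with_samples(self, samples: np.ndarray, label: str | None = None) -> "SignalRecord":
        return SignalRecord(samples, self.fs, self.label if label is None else label, self.t0)
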