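"""Sampled time-series container shared by every processing stage."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class ConfigurationError(ValueError):
    """Raised when a parameter set is internally inconsistent."""


@dataclass
class Signal:
    """A uniformly sampled single-channel time series.

    Parameters
    ----------
    data:
        1-D array of samples. Converted to float64 on construction.
    fs:
        Sampling rate in Hz; must be positive.
    units:
        Physical units of the samples (informational).
    """

    data: np.ndarray
    fs: float
    units: str = "uV"

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 1:
            raise ValueError(f"Signal data must be 1-D, got shape {self.data.shape}")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ConfigurationError(f"sampling rate must be positive, got {self.fs}")

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Record duration in seconds."""
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "Signal":
        return Signal(self.data.copy(), self.fs, self.units)

    def __len__(self) -> int:
        return self.n_samples


def as_samples(x) -> np.ndarray:
    """Accept a Signal or a plain 1-D array and return the sample array."""
    if isinstance(x, Signal):
        return x.data
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D sample array")
    return arr
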