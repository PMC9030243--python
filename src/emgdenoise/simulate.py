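"""Synthetic EEG/EMG generator.

Clean EEG is a sum of sinusoids with random frequencies in a low band; the
muscle artifact is bandpass-filtered white noise injected in burst windows.
Everything is driven by a single integer seed so records are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .signal import ConfigurationError, Signal

#: Burst windows (seconds, half-open) used by the reference simulation protocol.
DEFAULT_BURST_WINDOWS = ((0.0, 1.3), (2.0, 4.2), (7.6, 8.5))


@dataclass
class SimulationSpec:
    """Parameters of one simulated contaminated-EEG record.

    ``amplitude`` is the per-sinusoid amplitude of the clean EEG (the overall
    record scale is a free parameter of the protocol); ``artifact_gain`` is
    the RMS ratio of the EMG burst to the clean EEG.
    """

    duration_s: float = 10.0
    fs: float = 250.0
    n_sinusoids: int = 20
    freq_range: tuple[float, float] = (0.1, 30.0)
    emg_band: tuple[float, float] = (5.0, 45.0)
    burst_windows: tuple[tuple[float, float], ...] = DEFAULT_BURST_WINDOWS
    artifact_gain: float = 2.0
    amplitude: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.duration_s <= 0 or self.fs <= 0:
            raise ConfigurationError("duration_s and fs must be positive")
        nyq = self.fs / 2
        lo, hi = self.freq_range
        if not (0 < lo < hi < nyq):
            raise ConfigurationError(
                f"freq_range must satisfy 0 < low < high < fs/2, got {self.freq_range}"
            )
        elo, ehi = self.emg_band
        if not (0 < elo < ehi < nyq):
            raise ConfigurationError(
                f"emg_band must lie inside (0, fs/2), got {self.emg_band}"
            )
        if self.n_sinusoids < 0:
            raise ConfigurationError("n_sinusoids must be >= 0")
        windows = tuple(tuple(w) for w in self.burst_windows)
        for start, end in windows:
            if not (0 <= start < end <= self.duration_s):
                raise ConfigurationError(f"burst window {(start, end)} outside record")
        for (s1, e1), (s2, e2) in zip(windows, windows[1:]):
            if s2 < e1:
                raise ConfigurationError("burst windows must be non-overlapping and sorted")
        self.burst_windows = windows

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class SimulatedRecord:
    """A clean/artifact/corrupted triple with the burst sample mask."""

    clean: Signal
    emg: Signal
    corrupted: Signal
    burst_mask: np.ndarray
    spec: SimulationSpec | None = None

    def __post_init__(self):
        n = self.clean.n_samples
        if not (self.emg.n_samples == n == self.corrupted.n_samples == self.burst_mask.size):
            raise ValueError("clean, emg, corrupted and burst_mask must share length")


def _clean_rng(spec: SimulationSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[0])


def _emg_rng(spec: SimulationSpec) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])


def generate_clean_eeg(spec: SimulationSpec) -> Signal:
    """Sum of ``n_sinusoids`` sinusoids with frequencies drawn uniformly from
    ``freq_range`` and phases uniform on [0, 2*pi)."""
    rng = _clean_rng(spec)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    freqs = rng.uniform(spec.freq_range[0], spec.freq_range[1], spec.n_sinusoids)
    phases = rng.uniform(0.0, 2 * np.pi, spec.n_sinusoids)
    data = np.zeros(n)
    for f, ph in zip(freqs, phases):
        data += spec.amplitude * np.sin(2 * np.pi * f * t + ph)
    return Signal(data, spec.fs)


def generate_emg(spec: SimulationSpec) -> Signal:
    """Zero-phase bandpassed white noise, RMS-scaled to
    ``artifact_gain * rms(clean)``."""
    lo, hi = spec.emg_band
    if lo >= hi:
        raise ConfigurationError("degenerate emg band")
    rng = _emg_rng(spec)
    n = spec.n_samples
    noise = rng.standard_normal(n)
    sos = butter(4, [lo, hi], btype="bandpass", fs=spec.fs, output="sos")
    emg = sosfiltfilt(sos, noise)
    rms = np.sqrt(np.mean(emg**2))
    if rms == 0 or spec.artifact_gain == 0:
        return Signal(np.zeros(n), spec.fs)
    clean_rms = np.sqrt(np.mean(generate_clean_eeg(spec).data ** 2))
    return Signal(emg / rms * spec.artifact_gain * clean_rms, spec.fs)


def burst_mask(windows, n_samples: int, fs: float) -> np.ndarray:
    """Boolean mask of half-open windows [start, end) converted with floor()."""
    mask = np.zeros(n_samples, dtype=bool)
    for start, end in windows:
        i0 = int(np.floor(start * fs))
        i1 = int(np.floor(end * fs))
        if i0 < 0 or i1 > n_samples:
            raise IndexError(f"burst window {(start, end)} outside record")
        mask[i0:i1] = True
    return mask


def contaminate(clean: Signal, emg: Signal, windows) -> SimulatedRecord:
    """Add the artifact to the clean signal inside the burst windows only."""
    if clean.n_samples != emg.n_samples or clean.fs != emg.fs:
        raise ValueError("clean and emg must share length and sampling rate")
    mask = burst_mask(windows, clean.n_samples, clean.fs)
    masked_emg = np.where(mask, emg.data, 0.0)
    corrupted = clean.data + masked_emg
    return SimulatedRecord(
        clean=clean.copy(),
        emg=Signal(masked_emg, clean.fs),
        corrupted=Signal(corrupted, clean.fs),
        burst_mask=mask,
    )


def simulate_record(spec: SimulationSpec) -> SimulatedRecord:
    """Generate the clean/artifact/corrupted triple for one spec."""
    clean = generate_clean_eeg(spec)
    emg = generate_emg(spec)
    record = contaminate(clean, emg, spec.burst_windows)
    record.spec = spec
    return record


def make_training_set(
    n_per_class: int, spec: SimulationSpec
) -> tuple[list[Signal], np.ndarray]:
    """Balanced labeled epochs: ``n_per_class`` clean ("NC-EEG") and
    ``n_per_class`` contaminated ("C-EEG") records with distinct seeds.

    Returns (epochs, labels) with labels aligned to epochs.
    """
    if n_per_class < 1:
        raise ConfigurationError("n_per_class must be >= 1")
    child_seeds = np.random.SeedSequence(spec.seed).generate_state(
        2 * n_per_class, np.uint64
    )
    epochs: list[Signal] = []
    labels: list[str] = []
    for i in range(n_per_class):
        sub = dataclasses.replace(spec, seed=int(child_seeds[i]))
        epochs.append(generate_clean_eeg(sub))
        labels.append("NC-EEG")
    for i in range(n_per_class):
        sub = dataclasses.replace(spec, seed=int(child_seeds[n_per_class + i]))
        epochs.append(simulate_record(sub).corrupted)
        labels.append("C-EEG")
    return epochs, np.array(labels)
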