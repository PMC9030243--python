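"""Wavelet packet decomposition/reconstruction and data-driven selection.

The transform is the orthogonal two-channel filter bank applied with circular
(periodized) boundary handling.  Odd-length nodes are extended by repeating
the last sample before splitting; reconstruction truncates back, so the
round trip is exact for every orthonormal filter in the table.

Subbands are kept in natural (filter-bank) order: the lowpass child of node
j comes before its highpass sibling, giving nodes d(i,1)..d(i,2^i).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._filters import SCALING_FILTERS
from .signal import Signal, as_samples

#: Mother-wavelet candidates scored by default in :func:`select_wavelet`.
DEFAULT_CANDIDATES = (
    ["haar"]
    + [f"db{i}" for i in range(2, 13)]
    + [f"sym{i}" for i in range(2, 9)]
    + [f"coif{i}" for i in range(1, 6)]
    + [f"fk{i}" for i in (4, 6, 8, 14, 18, 22)]
)


def available_wavelets() -> list[str]:
    return sorted(SCALING_FILTERS, key=lambda n: (n.rstrip("0123456789"), len(n), n))


@dataclass(frozen=True)
class WaveletSpec:
    """An orthogonal wavelet identified by name, with its filter pair."""

    name: str
    dec_lo: tuple[float, ...]
    mode: str = "periodization"

    @classmethod
    def from_name(cls, name: str, mode: str = "periodization") -> "WaveletSpec":
        try:
            lo = SCALING_FILTERS[name]
        except KeyError:
            raise ValueError(
                f"unknown wavelet {name!r}; available: {available_wavelets()}"
            ) from None
        return cls(name=name, dec_lo=tuple(lo), mode=mode)

    @property
    def lowpass(self) -> np.ndarray:
        return np.asarray(self.dec_lo)

    @property
    def highpass(self) -> np.ndarray:
        """Quadrature-mirror partner g[k] = (-1)^k h[L-1-k]."""
        lo = self.lowpass
        sign = (-1.0) ** np.arange(lo.size)
        return sign * lo[::-1]

    @property
    def filter_length(self) -> int:
        return len(self.dec_lo)


def _coerce_wavelet(w) -> WaveletSpec:
    if isinstance(w, WaveletSpec):
        return w
    return WaveletSpec.from_name(str(w))


@dataclass
class WPDCoefficients:
    """Full packet tree at one level: 2^level subband vectors in natural order."""

    level: int
    subbands: list[np.ndarray]
    signal_length: int
    fs: float
    wavelet: WaveletSpec

    def __post_init__(self):
        if len(self.subbands) != 2**self.level:
            raise ValueError(
                f"expected {2**self.level} subbands at level {self.level}, "
                f"got {len(self.subbands)}"
            )
        self.subbands = [np.asarray(s, dtype=np.float64) for s in self.subbands]

    @property
    def n_subbands(self) -> int:
        return 2**self.level

    def copy_with(self, subbands: list[np.ndarray]) -> "WPDCoefficients":
        return WPDCoefficients(
            level=self.level,
            subbands=[np.asarray(s, dtype=np.float64).copy() for s in subbands],
            signal_length=self.signal_length,
            fs=self.fs,
            wavelet=self.wavelet,
        )


def _pad_even(x: np.ndarray) -> np.ndarray:
    if x.size % 2:
        return np.concatenate([x, x[-1:]])
    return x


def _analysis_step(x: np.ndarray, lo: np.ndarray, hi: np.ndarray):
    """One circular filter-bank split; returns (approx, detail)."""
    x = _pad_even(x)
    n = x.size
    L = lo.size
    if n < 2 * L:
        raise ValueError(
            f"node of length {n} too short for filter of length {L}; "
            "reduce the decomposition level"
        )
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(L)[None, :]) % n
    windows = x[idx]
    return windows @ lo, windows @ hi


def _synthesis_step(a: np.ndarray, d: np.ndarray, lo: np.ndarray, hi: np.ndarray,
                    out_len: int) -> np.ndarray:
    """Transpose of :func:`_analysis_step`; truncates padding to ``out_len``."""
    if a.size != d.size:
        raise ValueError("approximation/detail length mismatch")
    n = 2 * a.size
    L = lo.size
    out = np.zeros(n)
    pos = 2 * np.arange(a.size)
    for k in range(L):
        np.add.at(out, (pos + k) % n, lo[k] * a + hi[k] * d)
    return out[:out_len]


def _node_lengths(signal_length: int, level: int) -> list[list[int]]:
    """Per-level node lengths implied by the odd-length padding rule."""
    lengths = [[signal_length]]
    for _ in range(level):
        nxt = []
        for n in lengths[-1]:
            half = (n + 1) // 2
            nxt.extend([half, half])
        lengths.append(nxt)
    return lengths


def wpd_decompose(x, w, level: int, fs: float | None = None) -> WPDCoefficients:
    """Full wavelet-packet tree of ``x`` at ``level``.

    ``x`` may be a :class:`Signal` or a plain array (then ``fs`` applies).
    """
    if level < 0:
        raise ValueError("level must be >= 0")
    wav = _coerce_wavelet(w)
    data = as_samples(x)
    if fs is None:
        fs = x.fs if isinstance(x, Signal) else 1.0
    lo, hi = wav.lowpass, wav.highpass
    if data.size < lo.size:
        raise ValueError("signal shorter than the wavelet filter")
    nodes = [data]
    for _ in range(level):
        nxt = []
        for node in nodes:
            a, d = _analysis_step(node, lo, hi)
            nxt.extend([a, d])
        nodes = nxt
    return WPDCoefficients(
        level=level,
        subbands=nodes,
        signal_length=data.size,
        fs=fs,
        wavelet=wav,
    )


def wpd_reconstruct(c: WPDCoefficients) -> Signal:
    """Invert :func:`wpd_decompose`."""
    lo, hi = c.wavelet.lowpass, c.wavelet.highpass
    lengths = _node_lengths(c.signal_length, c.level)
    for i, (sub, expected) in enumerate(zip(c.subbands, lengths[c.level])):
        if sub.size != expected:
            raise ValueError(
                f"subband {i} has length {sub.size}, expected {expected}"
            )
    nodes = [np.asarray(s, dtype=np.float64) for s in c.subbands]
    for lev in range(c.level, 0, -1):
        parents = []
        parent_lengths = lengths[lev - 1]
        for j in range(0, len(nodes), 2):
            parents.append(
                _synthesis_step(nodes[j], nodes[j + 1], lo, hi, parent_lengths[j // 2])
            )
        nodes = parents
    return Signal(nodes[0], c.fs)


def reconstruction_error(x, w, level: int) -> float:
    """Mean squared difference between ``x`` and its decompose/reconstruct
    round trip."""
    data = as_samples(x)
    fs = x.fs if isinstance(x, Signal) else 1.0
    rec = wpd_reconstruct(wpd_decompose(data, w, level, fs=fs))
    return float(np.mean((data - rec.data) ** 2))


def select_wavelet(signals, candidates=None, level: int = 3):
    """Pick the candidate with the smallest mean round-trip error.

    Returns ``(best, errors)`` where ``errors`` maps candidate name to its
    mean reconstruction error across ``signals``.
    """
    if candidates is None:
        candidates = DEFAULT_CANDIDATES
    candidates = [_coerce_wavelet(c) for c in candidates]
    if not candidates:
        raise ValueError("need at least one candidate wavelet")
    signals = list(signals)
    if not signals:
        raise ValueError("need at least one signal")
    errors = {
        c.name: float(np.mean([reconstruction_error(s, c, level) for s in signals]))
        for c in candidates
    }
    best = min(candidates, key=lambda c: errors[c.name])
    return best, errors


def subband_entropy(coeffs) -> float:
    """Non-normalized Shannon entropy sum(c^2 * ln(c^2)) with 0*ln(0) = 0.

    May be negative; the natural log is used throughout.
    """
    c = np.asarray(coeffs, dtype=np.float64)
    if c.size == 0:
        raise ValueError("empty coefficient vector")
    e = c**2
    nz = e > 0
    return float(np.sum(e[nz] * np.log(e[nz])))


def pick_level(approx_entropies, detail_entropies) -> int | None:
    """First level (1-based) at which the approximation entropy drops strictly
    below the detail entropy, or None if it never does."""
    for j, (ea, ed) in enumerate(zip(approx_entropies, detail_entropies), start=1):
        if ea < ed:
            return j
    return None


def select_level(x, w, max_level: int = 5) -> int:
    """Iterated-DWT level selection: the smallest level whose approximation
    entropy is below its sibling detail entropy; ``max_level`` (with a
    warning) if the criterion is never met."""
    if max_level < 1:
        raise ValueError("max_level must be >= 1")
    wav = _coerce_wavelet(w)
    lo, hi = wav.lowpass, wav.highpass
    node = as_samples(x)
    se_ca, se_cd = [], []
    for _ in range(max_level):
        a, d = _analysis_step(node, lo, hi)
        se_ca.append(subband_entropy(a))
        se_cd.append(subband_entropy(d))
        node = a
    level = pick_level(se_ca, se_cd)
    if level is None:
        warnings.warn(
            f"approximation entropy never dropped below detail entropy up to "
            f"level {max_level}; returning max_level",
            stacklevel=2,
        )
        return max_level
    return level
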