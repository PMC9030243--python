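"""One-dimensional non-local-means estimation of subband coefficient vectors.

Each sample is replaced by a weighted average of the samples inside a search
neighbourhood, the weight of a neighbour decaying exponentially with the
squared difference between the patches surrounding the two samples:

    w(s, eta) = exp( -d2(s, eta) / (2 * L * lambda^2) )

where d2 sums squared differences over patch offsets in [-P, P], L is the
number of offsets actually compared (offsets falling outside the vector are
dropped, not padded), and the self term is included with weight 1.

Because the patch distances do not depend on the bandwidth, they are
precomputed once per vector (:class:`NLMEngine`); sweeping lambda -- as the
bandwidth optimizer does thousands of times -- then costs only the
exponential and two reductions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wavelet import WPDCoefficients


@dataclass(frozen=True)
class NLMParams:
    """patch half-width P, search half-width M, bandwidth lambda."""

    P: int = 4
    M: int = 50
    lam: float = 0.1

    def __post_init__(self):
        if self.P < 1:
            raise ValueError("patch half-width P must be >= 1")
        if self.M < self.P:
            raise ValueError("search half-width M must be >= P")
        if not (self.lam > 0):
            raise ValueError("bandwidth lambda must be > 0")


class NLMEngine:
    """Precomputed patch distances for one vector, reusable across bandwidths."""

    def __init__(self, v, P: int, M: int):
        v = np.asarray(v, dtype=np.float64)
        if v.ndim != 1:
            raise ValueError("expected a 1-D vector")
        if v.size <= 2 * P + 1:
            raise ValueError(
                f"vector of length {v.size} shorter than one patch (2P+1={2*P+1})"
            )
        if P < 1 or M < P:
            raise ValueError("require P >= 1 and M >= P")
        self.v = v
        self.P = P
        self.M = M
        n = v.size
        # For each offset t in [-M, M], samples s in [lo_t, hi_t] have a valid
        # neighbour s+t; store the patch distance and offset count per s.
        self._offsets = []
        for t in range(-M, M + 1):
            lo = max(0, -t)
            hi = n - 1 - max(0, t)
            if lo > hi:
                continue
            seg = np.arange(lo, hi + 1)
            diff2 = (v[seg] - v[seg + t]) ** 2
            cs = np.concatenate([[0.0], np.cumsum(diff2)])
            # window [max(lo, s-P), min(hi, s+P)] relative to lo
            j0 = np.maximum(seg - P, lo) - lo
            j1 = np.minimum(seg + P, hi) - lo
            d2 = cs[j1 + 1] - cs[j0]
            count = (j1 - j0 + 1).astype(np.float64)
            self._offsets.append((t, lo, hi, d2, count, v[seg + t]))

    def filter(self, lam: float) -> np.ndarray:
        """Apply the estimator with bandwidth ``lam``."""
        if not (lam > 0):
            raise ValueError("bandwidth lambda must be > 0")
        n = self.v.size
        num = np.zeros(n)
        den = np.zeros(n)
        inv = 1.0 / (2.0 * lam * lam)
        for t, lo, hi, d2, count, neighbours in self._offsets:
            w = np.exp(-d2 * inv / count)
            num[lo : hi + 1] += w * neighbours
            den[lo : hi + 1] += w
        return num / den


def nlm_filter(v, params: NLMParams) -> np.ndarray:
    """Non-local-means estimate of ``v`` (see module docstring)."""
    return NLMEngine(v, params.P, params.M).filter(params.lam)


def correct_subbands(
    c: WPDCoefficients, P: int, M: int, lambdas
) -> WPDCoefficients:
    """Filter subband j with bandwidth lambdas[j]; structure preserved."""
    lambdas = np.asarray(lambdas, dtype=np.float64)
    if lambdas.size != c.n_subbands:
        raise ValueError(
            f"need {c.n_subbands} bandwidths for level {c.level}, got {lambdas.size}"
        )
    corrected = [
        nlm_filter(sub, NLMParams(P=P, M=M, lam=float(lam)))
        for sub, lam in zip(c.subbands, lambdas)
    ]
    return c.copy_with(corrected)


def sar(d, d_hat) -> float:
    """Signal-to-artifact ratio 10*log10(std(d)/std(d - d_hat)) in dB.

    Population standard deviations; +inf when the estimate leaves the
    vector unaltered.
    """
    d = np.asarray(d, dtype=np.float64)
    d_hat = np.asarray(d_hat, dtype=np.float64)
    if d.shape != d_hat.shape:
        raise ValueError("length mismatch between d and d_hat")
    resid_std = np.std(d - d_hat)
    if resid_std == 0.0:
        return np.inf
    return float(10.0 * np.log10(np.std(d) / resid_std))
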