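"""Regenerate src/emgdenoise/_filters.py (frozen orthogonal scaling filters).

Daubechies, symlet and coiflet coefficients are extracted from PyWavelets
(only needed at generation time; the generated table is committed so the
package has no runtime dependency on it).  The Fejer-Korovkin filters are
constructed from scratch: the squared magnitude response of the scaling
filter is the Fejer-Korovkin kernel smoothing of the ideal half-band
response, with its odd harmonic part rescaled so that H(0) = sqrt(2)
(valid scaling filter).  Where that rescaling pushes the polynomial
marginally below zero, the nearest nonnegative half-band polynomial is
substituted (least-squares over the odd harmonics).  The filter is the
minimum-phase spectral factor, polished by Newton iteration onto the
exact orthonormal quadrature-mirror manifold.

Usage:  python scripts/gen_filters.py > src/emgdenoise/_filters.py
"""

from __future__ import annotations

import sys

import numpy as np
from mpmath import fsum, mp, mpf, pi, polyroots, sin, sqrt
from scipy.optimize import minimize

mp.dps = 60

FK_LENGTHS = [4, 6, 8, 14, 18, 22]


def _fk_halfband_poly(N: int) -> np.ndarray:
    """Cosine coefficients p[0..N-1] of P(xi) = |H(xi)|^2 for fkN."""
    n = N - 1
    beta = pi / (n + 2)
    a = [sin((j + 1) * beta) for j in range(n + 1)]
    norm = fsum([x ** 2 for x in a])
    p = [mpf(1)] + [mpf(0)] * n
    for k in range(1, n + 1, 2):
        r = fsum([a[j] * a[j + k] for j in range(n + 1 - k)]) / norm
        p[k] = r * mpf(2) / (pi * k) * (1 if k % 4 == 1 else -1)
    t = mpf(1) / (2 * fsum(p[1:]))
    for k in range(1, n + 1):
        p[k] *= t
    return np.array([float(x) for x in p])


def _nearest_nonnegative(p: np.ndarray) -> np.ndarray:
    """Least-squares projection of the odd harmonics onto {P >= 0, P(0)=2}."""
    n = len(p) - 1
    odd = np.arange(1, n + 1, 2)
    xi = np.linspace(0.0, np.pi, 4096)
    cosmat = 2.0 * np.cos(np.outer(xi, odd))

    def val(q):
        return 1.0 + cosmat @ q

    if val(p[odd]).min() >= 0.0:
        return p
    res = minimize(
        lambda q: np.sum((q - p[odd]) ** 2),
        p[odd],
        jac=lambda q: 2.0 * (q - p[odd]),
        constraints=[
            {"type": "eq", "fun": lambda q: np.sum(q) - 0.5},
            {"type": "ineq", "fun": val, "jac": lambda q: cosmat},
        ],
        method="SLSQP",
        options={"ftol": 1e-18, "maxiter": 500},
    )
    q = res.x
    out = p.copy()
    out[odd] = q
    return out


def _min_phase_factor(p: np.ndarray) -> np.ndarray:
    """Minimum-phase spectral factor h of the nonnegative half-band P."""
    n = len(p) - 1
    coeffs = [mpf(float(p[abs(k)])) for k in range(n, -n - 1, -1)]
    roots = polyroots(coeffs, maxsteps=500, extraprec=300)
    tol = mpf("1e-3")
    inside = [r for r in roots if abs(r) < 1 - tol]
    circle = [r for r in roots if abs(abs(r) - 1) <= tol]
    keep = list(inside)
    used = [False] * len(circle)
    for i, r in enumerate(circle):  # circle zeros have even multiplicity:
        if used[i]:                 # pair them up and keep one per pair,
            continue                # projected exactly onto the circle
        used[i] = True
        j_best, d_best = None, None
        for j in range(i + 1, len(circle)):
            if not used[j] and (d_best is None or abs(circle[j] - r) < d_best):
                j_best, d_best = j, abs(circle[j] - r)
        assert j_best is not None
        used[j_best] = True
        m = (r + circle[j_best]) / 2
        keep.append(m / abs(m))
    assert len(keep) == n, (len(keep), n)
    poly = [mpf(1)]
    for r in keep:
        nxt = [mpf(0)] * (len(poly) + 1)
        for i, c in enumerate(poly):
            nxt[i] += c
            nxt[i + 1] -= c * r
        poly = nxt
    h = np.array([float(x.real) for x in poly])
    h /= np.linalg.norm(h)
    if h.sum() < 0:
        h = -h
    return h


def _polish(h: np.ndarray) -> np.ndarray:
    """Newton least-norm correction onto {sum h = sqrt2, acorr(2m) = delta}."""
    N = len(h)
    for _ in range(50):
        res = [h @ h - 1.0, h.sum() - np.sqrt(2)]
        jac = [2.0 * h, np.ones(N)]
        for m in range(1, N // 2):
            res.append(h[: N - 2 * m] @ h[2 * m:])
            row = np.zeros(N)
            row[: N - 2 * m] += h[2 * m:]
            row[2 * m:] += h[: N - 2 * m]
            jac.append(row)
        res = np.array(res)
        if np.abs(res).max() < 1e-15:
            break
        J = np.vstack(jac)
        h = h - J.T @ np.linalg.solve(J @ J.T, res)
    return h


def fejer_korovkin(N: int) -> np.ndarray:
    return _polish(_min_phase_factor(_nearest_nonnegative(_fk_halfband_poly(N))))


def main() -> None:
    import pywt

    names = (
        ["haar"]
        + [f"db{i}" for i in range(2, 13)]
        + [f"sym{i}" for i in range(2, 9)]
        + [f"coif{i}" for i in range(1, 6)]
    )
    table = {}
    for name in names:
        table[name] = np.asarray(pywt.Wavelet(name).filter_bank[0], dtype=float)
    for N in FK_LENGTHS:
        table[f"fk{N}"] = fejer_korovkin(N)

    for name, lo in table.items():
        N = len(lo)
        worst = max(
            abs(lo[: N - 2 * m] @ lo[2 * m:]) for m in range(1, N // 2)
        ) if N > 2 else 0.0
        print(
            f"# check {name}: |sum-sqrt2|={abs(lo.sum()-np.sqrt(2)):.1e} "
            f"|norm-1|={abs(lo@lo-1):.1e} max|acorr|={worst:.1e}",
            file=sys.stderr,
        )

    print('"""Frozen orthogonal scaling (lowpass decomposition) filters.')
    print()
    print("Generated by scripts/gen_filters.py -- do not edit by hand.")
    print('"""')
    print()
    print("SCALING_FILTERS = {")
    for name, lo in table.items():
        print(f'    "{name}": [')
        for v in lo:
            print(f"        {float(v)!r},")
        print("    ],")
    print("}")


if __name__ == "__main__":
    main()
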