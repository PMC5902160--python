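"""Circular statistics: Kuiper and Rayleigh tests.

Both tests ask whether a sample of circular positions (stride phases in
[0, 1), or spike phases within a stimulus cycle) deviates from uniformity.
Kuiper's test is a rotation-invariant analogue of Kolmogorov-Smirnov and is
sensitive to any departure from uniformity; the Rayleigh test is most
powerful against unimodal (single preferred phase) alternatives and is the
natural test for pulse-locked spiking.

The p-value approximations are the standard asymptotic series (Stephens'
n-corrected series for Kuiper; the Zar/upper-tail approximation for
Rayleigh). Their small-n accuracy is verified elsewhere against brute-force
permutation nulls rather than trusted blindly.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kuiper_uniformity", "rayleigh_test", "circular_harmonic"]

KUIPER_MIN_N = 8
RAYLEIGH_MIN_N = 8


def kuiper_statistic(phases: np.ndarray) -> float:
    """Kuiper V = D+ + D- of phases in [0, 1) against the uniform CDF."""
    u = np.sort(np.asarray(phases, dtype=float) % 1.0)
    n = u.size
    if n == 0:
        raise ValueError("no phases")
    i = np.arange(1, n + 1)
    d_plus = np.max(i / n - u)
    d_minus = np.max(u - (i - 1) / n)
    return float(d_plus + d_minus)


def _kuiper_pvalue(v: float, n: int) -> float:
    # Stephens (1970) finite-n correction, then the asymptotic series.
    lam = v * (np.sqrt(n) + 0.155 + 0.24 / np.sqrt(n))
    if lam < 0.4:
        return 1.0
    k = np.arange(1, 101)
    a = 4.0 * k**2 * lam**2
    terms = (a - 1.0) * np.exp(-a / 2.0)
    p = 2.0 * float(np.sum(terms))
    return float(min(max(p, 0.0), 1.0))


def kuiper_uniformity(phases: np.ndarray) -> tuple[float, float]:
    """Kuiper test of phases in [0, 1) against circular uniformity.

    Returns
    -------
    (V, p) : statistic and asymptotic p-value. Requires n >= 8; below that
        the p-value is undefined (NaN) though V is still returned.
    """
    phases = np.asarray(phases, dtype=float)
    v = kuiper_statistic(phases)
    if phases.size < KUIPER_MIN_N:
        return v, float("nan")
    return v, _kuiper_pvalue(v, phases.size)


def rayleigh_test(angles: np.ndarray) -> tuple[float, float]:
    """Rayleigh test for a unimodal departure from circular uniformity.

    Parameters
    ----------
    angles : array of angles in radians.

    Returns
    -------
    (R, p) : mean resultant length and approximate p-value
        p = exp(sqrt(1 + 4n + 4(n^2 - (nR)^2)) - (1 + 2n)).
    """
    theta = np.asarray(angles, dtype=float)
    n = theta.size
    if n == 0:
        raise ValueError("no angles")
    c = np.sum(np.cos(theta))
    s = np.sum(np.sin(theta))
    r = float(np.hypot(c, s) / n)
    if n < RAYLEIGH_MIN_N:
        return r, float("nan")
    nr = n * r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - nr**2)) - (1.0 + 2.0 * n))
    return r, float(min(p, 1.0))


def mean_direction(angles: np.ndarray) -> float:
    """Circular mean direction in radians, in (-pi, pi]."""
    theta = np.asarray(angles, dtype=float)
    return float(np.arctan2(np.sum(np.sin(theta)), np.sum(np.cos(theta))))


def circular_harmonic(values: np.ndarray, harmonic: int = 1) -> complex:
    """Complex Fourier coefficient of a binned circular curve.

    Bins are taken as equally spaced around the cycle at their centers.
    Returns sum(values * exp(-i * 2*pi*h * center)) / n; the angle of the
    conjugate gives the phase of the harmonic's peak.
    """
    y = np.asarray(values, dtype=float)
    n = y.size
    centers = (np.arange(n) + 0.5) / n
    return complex(np.sum(y * np.exp(-2j * np.pi * harmonic * centers)) / n)
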