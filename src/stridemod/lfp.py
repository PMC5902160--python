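"""Local field potential averaging, filtering and spectral analysis.

LFP sweeps recorded during optical stimulation reveal population-level
Purkinje firing: stimulus-locked coherent spiking appears as peaks in the
power spectrum at the train frequency and its harmonics. Ten sweeps per
condition are averaged, band-pass filtered 50 Hz - 1 kHz (4th-order
zero-phase Butterworth), and a 1 Hz-resolution periodogram is computed with
the 60 Hz mains line blanked.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .datatypes import LFPSweeps

__all__ = ["average_and_filter", "psd", "harmonic_peaks"]

BAND_HZ = (50.0, 1000.0)
FILTER_ORDER = 4
BLANK_HZ = 60.0
BLANK_HALF_WIDTH_HZ = 2.0


def average_and_filter(
    sweeps: LFPSweeps,
    band: tuple[float, float] = BAND_HZ,
    order: int = FILTER_ORDER,
) -> np.ndarray:
    """Pointwise sweep average, band-pass filtered (zero-phase).

    Requires >= 2 sweeps of equal length (enforced by the container).
    """
    if sweeps.n_sweeps < 2:
        raise ValueError("need at least 2 sweeps")
    mean = sweeps.sweeps.mean(axis=0)
    sos = signal.butter(order, band, btype="bandpass", fs=sweeps.fs, output="sos")
    return signal.sosfiltfilt(sos, mean)


def psd(
    trace: np.ndarray,
    fs: float = 10_000.0,
    blank_hz: float | None = BLANK_HZ,
    blank_half_width: float = BLANK_HALF_WIDTH_HZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-window periodogram at ~1 Hz resolution with 60 Hz blanked.

    The trace should cover the 1 s stimulus window (>= 1 s required for
    1 Hz resolution). Power within 60 +/- 2 Hz is replaced by linear
    interpolation between the neighboring bins ('blanked').
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < fs:
        raise ValueError("trace shorter than 1 s; frequency resolution would exceed 1 Hz")
    freqs, power = signal.periodogram(trace, fs=fs, window="boxcar")
    if blank_hz is not None:
        band = (freqs >= blank_hz - blank_half_width) & (freqs <= blank_hz + blank_half_width)
        if band.any() and (~band).sum() >= 2:
            power = power.copy()
            power[band] = np.interp(freqs[band], freqs[~band], power[~band])
    return freqs, power


PROMINENCE_FLAG = 3.0


def harmonic_peaks(
    freqs: np.ndarray,
    power: np.ndarray,
    stim_freq: float,
    max_hz: float = 1000.0,
    peak_half_width: float = 2.0,
    surround_hz: float = 10.0,
    prominence_flag: float = PROMINENCE_FLAG,
) -> list[dict]:
    """Peak power at each harmonic of the stimulation frequency.

    For every harmonic k*stim_freq <= ``max_hz``: the maximal power within
    +/- 2 Hz, its prominence relative to the median power in a +/- 10 Hz
    surround (harmonic band excluded), and a flag for prominence > 3.
    """
    out = []
    k = 1
    while k * stim_freq <= max_hz:
        f0 = k * stim_freq
        near = (freqs >= f0 - peak_half_width) & (freqs <= f0 + peak_half_width)
        around = (
            (freqs >= f0 - surround_hz) & (freqs <= f0 + surround_hz) & ~near
        )
        if not near.any() or not around.any():
            k += 1
            continue
        peak = float(np.max(power[near]))
        background = float(np.median(power[around]))
        prom = peak / background if background > 0 else np.inf
        out.append(
            {
                "harmonic": k,
                "freq_hz": f0,
                "power": peak,
                "prominence": prom,
                "flagged": prom > prominence_flag,
            }
        )
        k += 1
    return out
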