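"""Stride segmentation from paw-tracking traces.

The hind paw's x-position during running is sawtooth-like: the trace rises
while the paw moves backward on the treadmill (stance) and falls as the paw
swings forward. A stride is one trough-to-trough cycle (plant -> lift ->
next plant). This module cleans tracking-loss artifacts, smooths the trace,
detects strides, allocates normalized stance/swing bins, and finds rest
epochs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .datatypes import PawTrace, Stride, StrideSet

__all__ = [
    "clean_trace",
    "smooth_trace",
    "detect_strides",
    "allocate_bins",
    "bin_edges",
    "detect_rest",
    "stride_phase",
]

# Detection defaults; the duration gate (100-500 ms) is the acceptance
# criterion for a stride, the rest are peak-finding parameters chosen to
# operate cleanly in that regime.
MIN_STRIDE_MS = 100.0
MAX_STRIDE_MS = 500.0
PROMINENCE_AU = 0.2
MIN_TROUGH_SEP_MS = 100.0

ARTIFACT_MAX_SAMPLES = 5
ARTIFACT_AMPLITUDE_AU = 0.5
MAX_FLAGGED_FRACTION = 0.2


class TraceUnusableError(ValueError):
    """Raised when too many samples are tracking artifacts."""


def clean_trace(
    trace: PawTrace,
    max_samples: int = ARTIFACT_MAX_SAMPLES,
    amplitude: float = ARTIFACT_AMPLITUDE_AU,
) -> PawTrace:
    """Remove brief square-pulse tracking-loss transients.

    The tracker occasionally loses the paw for a few frames, producing
    near-instantaneous full-scale square pulses. Samples belonging to a
    transient whose rise and fall both complete within ``max_samples`` and
    whose excursion exceeds ``amplitude`` AU are replaced by linear
    interpolation and their tracked flag cleared.

    Raises
    ------
    TraceUnusableError
        If more than 20% of samples end up flagged.
    """
    x = trace.x.copy()
    bad = ~trace.tracked.copy()

    d = np.diff(x)
    jump_up = np.flatnonzero(d > amplitude)
    jump_dn = np.flatnonzero(d < -amplitude)
    # Pair each rising jump with the first opposite jump within max_samples
    # (and vice versa for negative-going pulses).
    for starts, ends in ((jump_up, jump_dn), (jump_dn, jump_up)):
        for i in starts:
            j_candidates = ends[(ends > i) & (ends <= i + max_samples)]
            if j_candidates.size:
                j = int(j_candidates[0])
                bad[i + 1 : j + 1] = True

    if bad.mean() > MAX_FLAGGED_FRACTION:
        raise TraceUnusableError(
            f"{bad.mean():.0%} of samples flagged as artifacts (>20%)"
        )
    if bad.any():
        good = ~bad
        idx = np.arange(x.size)
        x[bad] = np.interp(idx[bad], idx[good], x[good])
    return PawTrace(x, trace.fs, ~bad, trace.t0)


def smooth_trace(trace: PawTrace, window_ms: float = 50.0) -> PawTrace:
    """Centered sliding-average filter (default 50 ms).

    The window is rounded to the nearest odd sample count (13 samples at
    240 Hz); edges use shrinking windows so the trace keeps its length
    without zero-padding (padding would fabricate troughs at the ends).
    """
    n_win = int(round(window_ms * trace.fs / 1000.0))
    if n_win < 2:
        raise ValueError("smoothing window must span at least 2 samples")
    if n_win % 2 == 0:
        n_win += 1
    sm = (
        pd.Series(trace.x)
        .rolling(n_win, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )
    return PawTrace(sm, trace.fs, trace.tracked.copy(), trace.t0)


def _refine_extremum(x: np.ndarray, i: int, half_win: int, kind: str) -> int:
    """Move an extremum found on the smoothed trace to the vertex.

    A 50 ms boxcar shifts the vertex of an asymmetric sawtooth by a couple
    of samples, so each smoothed-trace extremum is relocated to the min/max
    — within +/- half the smoothing window — of the trace after a light
    5-sample average that suppresses single-sample noise without moving the
    vertex by more than a sample.
    """
    lo = max(0, i - half_win)
    hi = min(x.size, i + half_win + 1)
    seg = np.convolve(x[max(0, lo - 2) : hi + 2], np.ones(5) / 5.0, mode="same")
    seg = seg[lo - max(0, lo - 2) : lo - max(0, lo - 2) + (hi - lo)]
    off = int(np.argmin(seg) if kind == "trough" else np.argmax(seg))
    pos = lo + off
    # The light average can bias the vertex by ~1 sample on an asymmetric
    # sawtooth; a final raw-trace adjustment within +/-1 sample removes it.
    lo2 = max(0, pos - 1)
    seg2 = x[lo2 : min(x.size, pos + 2)]
    off2 = int(np.argmin(seg2) if kind == "trough" else np.argmax(seg2))
    return lo2 + off2


def _segment_slope(x: np.ndarray, t: np.ndarray, i0: int, i1: int, trim: float = 0.15) -> float:
    """Straight-line slope of a stance/swing segment.

    Fit by least squares over the central (1 - 2*trim) of the segment —
    identical to the endpoint slope for an ideal sawtooth, but insensitive
    to single-sample jitter of the detected vertices.
    """
    n = i1 - i0
    k = int(np.floor(trim * n))
    a, b = i0 + k, i1 - k + 1
    if b - a < 3:
        a, b = i0, i1 + 1
    ts, xs = t[a:b], x[a:b]
    tc = ts - ts.mean()
    denom = float(np.dot(tc, tc))
    if denom == 0:
        return float("nan")
    return float(np.dot(tc, xs - xs.mean()) / denom)


def detect_strides(
    trace: PawTrace,
    smoothed: PawTrace | None = None,
    prominence: float = PROMINENCE_AU,
    min_sep_ms: float = MIN_TROUGH_SEP_MS,
    min_ms: float = MIN_STRIDE_MS,
    max_ms: float = MAX_STRIDE_MS,
    smooth_window_ms: float = 50.0,
) -> StrideSet:
    """Detect trough-to-trough strides.

    ``trace`` should already be cleaned; it is smoothed here unless a
    pre-smoothed companion is passed. Troughs and peaks are found on the
    smoothed trace (prominence >= 0.2 AU, trough separation >= 100 ms),
    refined on the raw trace, and each trough->peak->trough triple with
    plant-to-plant duration in [100, 500] ms and exactly one interior peak
    becomes a stride. Slopes are straight-line rates over the stance
    (plant->lift) and swing (lift->next plant); the swing slope is reported
    as a magnitude.
    """
    if smoothed is None:
        smoothed = smooth_trace(trace, smooth_window_ms)
    fs = trace.fs
    dist = max(1, int(round(min_sep_ms * fs / 1000.0)))
    troughs, _ = find_peaks(-smoothed.x, prominence=prominence, distance=dist)
    peaks, _ = find_peaks(smoothed.x, prominence=prominence, distance=dist)

    half_win = int(round(smooth_window_ms * fs / 1000.0)) // 2
    troughs = np.unique(
        [_refine_extremum(trace.x, i, half_win, "trough") for i in troughs]
    )
    peaks = np.unique([_refine_extremum(trace.x, i, half_win, "peak") for i in peaks])

    strides: list[Stride] = []
    t = trace.times
    for a, b in zip(troughs[:-1], troughs[1:]):
        inner = peaks[(peaks > a) & (peaks < b)]
        if inner.size != 1:
            continue
        dur_ms = (t[b] - t[a]) * 1e3
        if not (min_ms <= dur_ms <= max_ms):
            continue
        p = int(inner[0])
        amp = 0.5 * (trace.x[p] - trace.x[a]) + 0.5 * (trace.x[p] - trace.x[b])
        stance_slope = _segment_slope(trace.x, t, a, p)
        swing_slope = abs(_segment_slope(trace.x, t, p, b))
        strides.append(
            Stride(
                plant=float(t[a]),
                lift=float(t[p]),
                next_plant=float(t[b]),
                amplitude=float(amp),
                stance_slope=float(stance_slope),
                swing_slope=float(swing_slope),
            )
        )

    sset = StrideSet(strides)
    if strides:
        n_st, n_sw = allocate_bins(sset)
        sset.n_stance_bins, sset.n_swing_bins = n_st, n_sw
    if not sset.sufficient:
        warnings.warn(
            f"only {len(strides)} strides detected (<30): session-level "
            "statistics are unreliable",
            stacklevel=2,
        )
    return sset


def allocate_bins(strides: StrideSet | list[Stride], n_bins: int = 10) -> tuple[int, int]:
    """Split ``n_bins`` normalized-stride bins between stance and swing.

    Uses the session's median stance fraction with half-up rounding (a
    median of 0.65 gives 7 stance bins), clamped so both phases keep at
    least one bin.
    """
    sts = list(strides)
    if not sts:
        raise ValueError("no strides")
    r = float(np.median([s.stance_fraction for s in sts]))
    n_stance = int(np.floor(n_bins * r + 0.5))  # half-up
    n_stance = min(max(n_stance, 1), n_bins - 1)
    return n_stance, n_bins - n_stance


def bin_edges(stride: Stride, n_stance: int, n_swing: int) -> np.ndarray:
    """The 11 time edges of the normalized, lift-aligned stride bins.

    Stance [plant, lift] is divided into ``n_stance`` equal sub-intervals
    and swing [lift, next_plant] into ``n_swing``; edge ``n_stance`` falls
    on the lift exactly.
    """
    stance = np.linspace(stride.plant, stride.lift, n_stance + 1)
    swing = np.linspace(stride.lift, stride.next_plant, n_swing + 1)
    return np.concatenate([stance[:-1], swing])


def stride_phase(stride: Stride, t: np.ndarray, n_stance: int, n_bins: int = 10) -> np.ndarray:
    """Normalized stride phase in [0, 1) of times within a stride.

    The phase coordinate matches the bin allocation: stance occupies
    [0, n_stance/n_bins) and swing the remainder, so bin k covers
    [k/n_bins, (k+1)/n_bins).
    """
    t = np.asarray(t, dtype=float)
    r = n_stance / n_bins
    phi = np.where(
        t < stride.lift,
        r * (t - stride.plant) / (stride.lift - stride.plant),
        r + (1 - r) * (t - stride.lift) / (stride.next_plant - stride.lift),
    )
    return np.clip(phi, 0.0, np.nextafter(1.0, 0.0))


REST_WINDOW_MS = 200.0
REST_MIN_MS = 500.0
REST_AMPLITUDE_FRACTION = 0.1
REST_TOTAL_REQUIRED_S = 2.0


def detect_rest(
    trace: PawTrace,
    strides: StrideSet,
    window_ms: float = REST_WINDOW_MS,
    min_duration_ms: float = REST_MIN_MS,
    fraction: float = REST_AMPLITUDE_FRACTION,
) -> list[tuple[float, float]]:
    """Rest epochs: paw nearly motionless relative to stride amplitude.

    Maximal intervals of at least ``min_duration_ms`` in which the rolling
    peak-to-peak amplitude (200 ms window) stays below ``fraction`` (10%) of
    the median stride amplitude. Session-level rest statistics additionally
    require the total rest to exceed 2 s; callers can check with
    :func:`total_rest`.
    """
    if not len(strides):
        raise ValueError("need at least one stride to scale rest detection")
    amp = strides.median_amplitude
    n_win = max(2, int(round(window_ms * trace.fs / 1000.0)))
    s = pd.Series(trace.x)
    ptp = (
        s.rolling(n_win, center=True, min_periods=1).max()
        - s.rolling(n_win, center=True, min_periods=1).min()
    ).to_numpy()
    quiet = ptp < fraction * amp

    epochs: list[tuple[float, float]] = []
    t = trace.times
    min_len = int(round(min_duration_ms * trace.fs / 1000.0))
    edges = np.diff(quiet.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if quiet[0]:
        starts.insert(0, 0)
    if quiet[-1]:
        ends.append(quiet.size)
    for a, b in zip(starts, ends):
        if b - a >= min_len:
            epochs.append((float(t[a]), float(t[min(b, t.size - 1)])))
    return epochs


def total_rest(epochs: list[tuple[float, float]]) -> float:
    """Total rest duration, s."""
    return float(sum(b - a for a, b in epochs))
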