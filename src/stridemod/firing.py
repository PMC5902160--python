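"""Firing-rate analysis: instantaneous rates, stride-phase tuning,
modulation indices, and modulation-class assignment.

The central quantity is the 10-bin stride tuning curve: each stride is
divided into stance and swing bins (see :mod:`stridemod.strides`), the
instantaneous firing rate (IFR, reciprocal interspike interval held over
the interval) is averaged within each bin, and bins are averaged across
strides. The modulation index MI = (FR_max - FR_min)/(FR_max + FR_min)
summarizes modulation depth; the modulation class summarizes the phase
relationship between firing and paw position.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .circular import circular_harmonic, kuiper_uniformity
from .datatypes import PawTrace, SpikeTrain, Stride, StrideSet
from .strides import bin_edges, stride_phase, total_rest, REST_TOTAL_REQUIRED_S

__all__ = [
    "InstantaneousRate",
    "BinnedTuning",
    "binned_tuning",
    "spike_stride_phases",
    "modulation_index",
    "rest_run_rates",
    "classify_modulation",
    "population_average",
    "rate_velocity_regression",
    "CLASS_NAMES",
]

CLASS_NAMES = {
    1: "I (in phase)",
    2: "II (anti-phase)",
    3: "III (90 deg lead)",
    4: "IV (90 deg lag)",
    5: "V (two peaks)",
    6: "VI (two troughs)",
    7: "VII (unclassified)",
}


class InstantaneousRate:
    """IFR as a piecewise-constant step function.

    IFR(t) = 1/ISI_i for t in [spike_i, spike_{i+1}); undefined before the
    first and after the last spike. The cumulative spike-position function
    F(t) = interp(t; spike_times, 0..n-1) is piecewise linear with slope
    1/ISI, so time-weighted bin means reduce to differences of F.
    """

    def __init__(self, spikes: SpikeTrain | np.ndarray):
        times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes)
        self.times = np.asarray(times, dtype=float)
        self.defined = self.times.size >= 2

    @property
    def support(self) -> tuple[float, float]:
        if not self.defined:
            return (np.nan, np.nan)
        return (float(self.times[0]), float(self.times[-1]))

    def __call__(self, t) -> np.ndarray:
        """IFR at arbitrary times (NaN where undefined)."""
        t = np.asarray(t, dtype=float)
        if not self.defined:
            return np.full(t.shape, np.nan)
        idx = np.searchsorted(self.times, t, side="right") - 1
        valid = (idx >= 0) & (idx < self.times.size - 1)
        out = np.full(t.shape, np.nan)
        isi = np.diff(self.times)
        out[valid] = 1.0 / isi[idx[valid]]
        return out

    def _cumulative(self, t: np.ndarray) -> np.ndarray:
        return np.interp(t, self.times, np.arange(self.times.size, dtype=float))

    def bin_means(self, edges: np.ndarray) -> np.ndarray:
        """Time-weighted mean IFR over the intervals between ``edges``.

        ``edges`` may be a 1-D array of m+1 edges or a 2-D (k, m+1) array of
        per-stride edges. Intervals are clipped to the IFR support; an
        interval wholly outside it yields NaN.
        """
        edges = np.asarray(edges, dtype=float)
        if not self.defined:
            return np.full(edges.shape[:-1] + (edges.shape[-1] - 1,), np.nan)
        t0, t1 = self.support
        clipped = np.clip(edges, t0, t1)
        f = self._cumulative(clipped)
        widths = np.diff(clipped, axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            means = np.diff(f, axis=-1) / widths
        means[widths <= 0] = np.nan
        return means

    def mean_over(self, t0: float, t1: float) -> float:
        return float(self.bin_means(np.array([t0, t1]))[0])


@dataclass
class BinnedTuning:
    """10-bin stride tuning curve of one cell."""

    rates: np.ndarray  # spikes/s per bin
    paw: np.ndarray  # mean paw position per bin, AU
    n_strides: int
    n_stance_bins: int
    stance_fraction: float = 0.65  # median stance fraction (time units)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.paw = np.asarray(self.paw, dtype=float)

    @property
    def n_bins(self) -> int:
        return self.rates.size

    @property
    def fr_max(self) -> float:
        return float(np.max(self.rates))

    @property
    def fr_min(self) -> float:
        return float(np.min(self.rates))

    @property
    def peak_bin(self) -> int:
        return int(np.argmax(self.rates))


def _stride_edges_matrix(strides: StrideSet, n_stance: int, n_swing: int) -> np.ndarray:
    return np.vstack([bin_edges(s, n_stance, n_swing) for s in strides])


def _paw_bin_means(trace: PawTrace, edges: np.ndarray) -> np.ndarray:
    """Time-weighted mean paw position within bin edges via trapezoid cumsum."""
    t = trace.times
    c = np.concatenate([[0.0], np.cumsum(0.5 * (trace.x[1:] + trace.x[:-1]) / trace.fs)])
    f = np.interp(edges, t, c)
    widths = np.diff(edges, axis=-1)
    return np.diff(f, axis=-1) / widths


def binned_tuning(
    spikes: SpikeTrain,
    strides: StrideSet,
    trace: PawTrace | None = None,
    require_sufficient: bool = True,
) -> BinnedTuning:
    """Average binned IFR (and paw position) across strides.

    For each stride the IFR is averaged within each of the 10 stance/swing
    bins (time-weighted integral of the IFR step function), then bins are
    averaged across strides. Strides with no defined IFR in a bin are
    ignored for that bin; a bin with no contributing stride raises.
    """
    if require_sufficient and not strides.sufficient:
        raise ValueError("fewer than 30 strides; pass require_sufficient=False to override")
    if not len(strides):
        raise ValueError("no strides")
    n_st, n_sw = strides.n_stance_bins, strides.n_swing_bins
    if n_st + n_sw != 10 or n_st < 1:
        raise ValueError("stride set has no valid bin allocation")
    edges = _stride_edges_matrix(strides, n_st, n_sw)
    ifr = InstantaneousRate(spikes)
    per_stride = ifr.bin_means(edges)  # (n_strides, 10)
    if np.all(np.isnan(per_stride), axis=0).any():
        raise ValueError("a bin has no defined IFR in any stride")
    rates = np.nanmean(per_stride, axis=0)

    if trace is not None:
        paw = np.mean(_paw_bin_means(trace, edges), axis=0)
    else:
        paw = np.full(10, np.nan)
    sf = float(np.median([s.stance_fraction for s in strides]))
    return BinnedTuning(rates, paw, len(strides), n_st, sf)


def spike_stride_phases(spikes: SpikeTrain, strides: StrideSet) -> np.ndarray:
    """Normalized stride phase of every spike falling within a stride."""
    phases = []
    for s in strides:
        sp = spikes.slice(s.plant, s.next_plant)
        if sp.size:
            phases.append(stride_phase(s, sp, strides.n_stance_bins))
    if not phases:
        return np.empty(0)
    return np.concatenate(phases)


def modulation_index(tuning: BinnedTuning) -> tuple[float, float, float]:
    """(MI, St_MI, Sw_MI): modulation depth over all, stance, swing bins.

    MI = (FR_max - FR_min)/(FR_max + FR_min) over the 10-bin curve; the
    stance/swing variants restrict the extrema to stance or swing bins.
    """

    def _mi(r: np.ndarray) -> float:
        hi, lo = float(np.max(r)), float(np.min(r))
        if hi + lo <= 0:
            return float("nan")
        return (hi - lo) / (hi + lo)

    r = tuning.rates
    n_st = tuning.n_stance_bins
    return _mi(r), _mi(r[:n_st]), _mi(r[n_st:])


def rest_run_rates(
    spikes: SpikeTrain,
    rest_epochs: list[tuple[float, float]],
    strides: StrideSet,
    tuning: BinnedTuning | None = None,
    ifr_bin_ms: float = 20.0,
) -> dict:
    """Rest vs run firing statistics.

    rest_mean requires total rest >= 2 s (else None); run statistics
    require a session-level stride set (>=30 strides). run_min/run_max are
    the extrema of the 10-bin tuning curve. 20 ms-binned IFR samples are
    returned for both states for histogramming.
    """
    out: dict = {
        "rest_mean": None,
        "run_mean": None,
        "run_min": None,
        "run_max": None,
        "rest_ifr": np.empty(0),
        "run_ifr": np.empty(0),
    }
    ifr = InstantaneousRate(spikes)
    w = ifr_bin_ms / 1e3

    rest_total = total_rest(rest_epochs)
    if rest_total >= REST_TOTAL_REQUIRED_S:
        n = sum(spikes.count(a, b) for a, b in rest_epochs)
        out["rest_mean"] = n / rest_total
        samples = []
        for a, b in rest_epochs:
            edges = np.arange(a, b, w)
            if edges.size > 1:
                samples.append(ifr.bin_means(edges))
        if samples:
            vals = np.concatenate(samples)
            out["rest_ifr"] = vals[np.isfinite(vals)]

    if strides.sufficient:
        run_time = sum(s.duration for s in strides)
        n = sum(spikes.count(s.plant, s.next_plant) for s in strides)
        out["run_mean"] = n / run_time
        if tuning is None:
            tuning = binned_tuning(spikes, strides)
        out["run_min"] = tuning.fr_min
        out["run_max"] = tuning.fr_max
        samples = []
        for s in strides:
            edges = np.arange(s.plant, s.next_plant, w)
            if edges.size > 1:
                samples.append(ifr.bin_means(edges))
        if samples:
            vals = np.concatenate(samples)
            out["run_ifr"] = vals[np.isfinite(vals)]
    return out


# Classification thresholds (explicit quantitative proxy for
# manual-by-investigator classification); all configurable.
HARMONIC_DOMINANCE = 2.0
PHASE_SECTOR_DEG = 45.0
MIN_CLASS_MI = 0.05
KUIPER_ALPHA = 0.05


def _time_fraction_to_bin(tf: float, stance_fraction: float, n_stance: int, n_bins: int = 10) -> int:
    """Map a time fraction of the stride to its normalized bin index."""
    tf = tf % 1.0
    r = n_stance / n_bins
    if tf < stance_fraction:
        phi = r * tf / stance_fraction
    else:
        phi = r + (1 - r) * (tf - stance_fraction) / (1 - stance_fraction)
    return min(int(phi * n_bins), n_bins - 1)


def classify_modulation(
    tuning: BinnedTuning,
    kuiper_p: float | None = None,
    mi: float | None = None,
    dominance: float = HARMONIC_DOMINANCE,
    sector_deg: float = PHASE_SECTOR_DEG,
    min_mi: float = MIN_CLASS_MI,
    alpha: float = KUIPER_ALPHA,
) -> int:
    """Assign a modulation class (1-7) from the 10-bin tuning curve.

    The first two circular harmonics of the mean-subtracted rate curve are
    compared. If the fundamental dominates (power >= ``dominance`` x second
    harmonic), the phase of the rate fundamental relative to the paw
    fundamental assigns class I (in phase, |dphi| < 45 deg), II (anti-phase),
    III (leading by ~90 deg) or IV (lagging). If the second harmonic
    dominates, bins one quarter stride before/after the lift decide V (local
    maxima there) or VI (local minima). Anything else — including
    non-significant Kuiper uniformity (p >= alpha) or MI < ``min_mi`` — is
    class VII.
    """
    if mi is None:
        mi = modulation_index(tuning)[0]
    if (kuiper_p is not None and kuiper_p >= alpha) or not np.isfinite(mi) or mi < min_mi:
        return 7

    r = tuning.rates - np.mean(tuning.rates)
    c1, c2 = circular_harmonic(r, 1), circular_harmonic(r, 2)
    p1, p2 = abs(c1) ** 2, abs(c2) ** 2

    if p1 >= dominance * p2:
        paw = tuning.paw
        if np.all(np.isfinite(paw)):
            cp = circular_harmonic(paw - np.mean(paw), 1)
        else:
            # Without a paw curve, use the lift phase as the paw peak.
            cp = np.exp(-2j * np.pi * (tuning.n_stance_bins / tuning.n_bins))
        # angle(c1) = -2*pi*peak_phase, so negate to get rate peak minus
        # paw peak: negative = rate leads (peaks earlier in the stride).
        dphi = -np.angle(c1 / cp, deg=True)
        if abs(dphi) < sector_deg:
            return 1
        if abs(abs(dphi) - 180.0) < sector_deg:
            return 2
        if -180.0 + sector_deg <= dphi <= -sector_deg:
            return 3
        if sector_deg <= dphi <= 180.0 - sector_deg:
            return 4
        return 7
    if p2 >= dominance * p1:
        sf, n_st = tuning.stance_fraction, tuning.n_stance_bins
        rates = tuning.rates
        n = rates.size
        left = np.roll(rates, 1)
        right = np.roll(rates, -1)
        is_max = (rates >= left) & (rates >= right)
        is_min = (rates <= left) & (rates <= right)
        hits = []
        for tf in (sf - 0.25, sf + 0.25):
            b = _time_fraction_to_bin(tf, sf, n_st, n)
            # Bin quantization: accept a local extremum within one bin of
            # the quarter-stride position.
            window = [(b - 1) % n, b, (b + 1) % n]
            if any(is_max[w] for w in window):
                hits.append("max")
            elif any(is_min[w] for w in window):
                hits.append("min")
            else:
                hits.append("none")
        if hits == ["max", "max"]:
            return 5
        if hits == ["min", "min"]:
            return 6
        return 7
    return 7


def kuiper_from_session(spikes: SpikeTrain, strides: StrideSet) -> tuple[float, float]:
    """Kuiper uniformity test of spike phases across all strides."""
    return kuiper_uniformity(spike_stride_phases(spikes, strides))


def population_average(tunings: list[BinnedTuning], normalize: bool = False) -> np.ndarray:
    """Per-bin mean tuning curve across cells.

    With ``normalize`` each cell's curve is first scaled to [0, 1] by its
    own min/max so strongly firing cells do not dominate.
    """
    if len(tunings) < 2:
        raise ValueError("need at least two cells")
    curves = np.vstack([t.rates for t in tunings])
    if normalize:
        lo = curves.min(axis=1, keepdims=True)
        hi = curves.max(axis=1, keepdims=True)
        rng = np.where(hi > lo, hi - lo, 1.0)
        curves = (curves - lo) / rng
    return curves.mean(axis=0)


def rate_velocity_regression(
    spikes: SpikeTrain,
    trace: PawTrace,
    strides: StrideSet,
    smooth_window_ms: float = 50.0,
) -> tuple[float, float, float]:
    """OLS regression of IFR on paw velocity during strides.

    Velocity is the derivative of the smoothed paw trace; IFR and velocity
    are paired at paw sample times inside strides where the IFR is defined.
    Returns (slope, Pearson r, two-sided p).
    """
    from .strides import smooth_trace

    sm = smooth_trace(trace, smooth_window_ms)
    vel = np.gradient(sm.x) * trace.fs
    t = trace.times
    ifr = InstantaneousRate(spikes)
    mask = np.zeros(t.size, dtype=bool)
    for s in strides:
        mask |= (t >= s.plant) & (t < s.next_plant)
    rates = ifr(t[mask])
    v = vel[mask]
    ok = np.isfinite(rates)
    if ok.sum() < 10:
        raise ValueError("fewer than 10 paired samples")
    res = stats.linregress(v[ok], rates[ok])
    return float(res.slope), float(res.rvalue), float(res.pvalue)
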