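"""Preservation or disruption of stride-related modulation under light.

On non-slip trials the stride cycle is intact, so light-on strides can be
binned exactly like control strides and the two 10-bin tuning curves
correlated (Pearson r). On slip trials the stride is by definition
disrupted, so the last pre-stimulus stride serves as a template: its bin
durations are tiled forward across the slip epoch and the firing rate in
the tiled bins is correlated with the template-stride rates. Prolonged
strides are a special case analyzed lift-aligned on polar coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .circular import mean_direction, rayleigh_test
from .datatypes import SpikeTrain, StimulusTrial, Stride, StrideSet
from .firing import BinnedTuning, InstantaneousRate, binned_tuning
from .strides import bin_edges

__all__ = [
    "nonslip_tuning_correlation",
    "slip_template_correlation",
    "prolonged_polar",
    "polar_population",
    "threshold_summary",
]

R_THRESHOLD = 0.4


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 2 or np.ptp(a[ok]) == 0 or np.ptp(b[ok]) == 0:
        return float("nan")
    return float(stats.pearsonr(a[ok], b[ok])[0])


def nonslip_tuning_correlation(
    spikes: SpikeTrain,
    strides_no_light: StrideSet,
    strides_light_on: StrideSet,
    min_light_strides: int = 5,
) -> float:
    """Pearson r between no-light and light-on 10-bin tuning curves.

    Light-on strides come from non-slip trials only; both conditions use
    the session's bin allocation. NaN when either curve is constant or
    there are fewer than ``min_light_strides`` light-on strides.
    """
    if len(strides_light_on) < min_light_strides:
        return float("nan")
    strides_light_on.n_stance_bins = strides_no_light.n_stance_bins
    strides_light_on.n_swing_bins = strides_no_light.n_swing_bins
    t_off = binned_tuning(spikes, strides_no_light, require_sufficient=False)
    t_on = binned_tuning(spikes, strides_light_on, require_sufficient=False)
    return _pearson(t_off.rates, t_on.rates)


def template_tiled_rates(
    spikes: SpikeTrain,
    template: Stride,
    n_stance: int,
    n_swing: int,
    start: float,
    stop: float,
    average_tilings: bool = True,
) -> np.ndarray:
    """Firing rate per template bin, tiled forward from ``start``.

    The template stride's absolute bin durations are repeated across
    [start, stop]; the mean IFR per tiled bin is averaged across complete
    and partial tilings. With ``average_tilings`` False only the first
    tiling is used.
    """
    rel_edges = bin_edges(template, n_stance, n_swing) - template.plant
    dur = template.duration
    ifr = InstantaneousRate(spikes)
    n_tilings = max(1, int(np.ceil((stop - start) / dur)))
    if not average_tilings:
        n_tilings = 1
    rows = []
    for k in range(n_tilings):
        e = start + k * dur + rel_edges
        if e[0] >= stop:
            break
        rows.append(ifr.bin_means(np.minimum(e, stop)))
    if not rows:
        return np.full(rel_edges.size - 1, np.nan)
    return np.nanmean(np.vstack(rows), axis=0)


def slip_template_correlation(
    spikes: SpikeTrain,
    trial: StimulusTrial,
    template: Stride,
    n_stance: int,
    n_swing: int,
    start: float | None = None,
    average_tilings: bool = True,
) -> float:
    """Pearson r between firing during the slip epoch and the template stride.

    The template's 10-bin rates are compared with the rates in the same
    (absolute-duration) bins tiled forward from stimulus onset (or from
    ``start``, e.g. slip onset) across the slip epoch. NaN when fewer than
    2 bins are defined.
    """
    ifr = InstantaneousRate(spikes)
    template_rates = ifr.bin_means(bin_edges(template, n_stance, n_swing))
    start = trial.onset if start is None else start
    tiled = template_tiled_rates(
        spikes, template, n_stance, n_swing, start, trial.offset, average_tilings
    )
    ok = np.isfinite(template_rates) & np.isfinite(tiled)
    if ok.sum() < 2:
        return float("nan")
    return _pearson(template_rates, tiled)


@dataclass
class PolarAlignment:
    """Light-on peak-bin angle relative to the control peak (0 deg = same bin)."""

    theta_deg: float
    light_peak_bin: int
    control_peak_bin: int


def prolonged_polar(
    spikes: SpikeTrain,
    prolonged: Stride,
    control_tuning: BinnedTuning,
    n_stance: int,
    n_swing: int,
) -> PolarAlignment:
    """Lift-aligned polar comparison of a prolonged stride to control tuning.

    The prolonged stride is itself divided into the session's 10 stance/
    swing bins (lift-aligned); theta = 36 deg x (light-on peak bin -
    control peak bin), wrapped to (-180, 180]. Ties in the peak bin go to
    the lowest index.
    """
    ifr = InstantaneousRate(spikes)
    rates = ifr.bin_means(bin_edges(prolonged, n_stance, n_swing))
    light_peak = int(np.nanargmax(rates))
    control_peak = control_tuning.peak_bin
    n = control_tuning.n_bins
    d = (light_peak - control_peak) % n
    theta = d * (360.0 / n)
    if theta > 180.0:
        theta -= 360.0
    return PolarAlignment(theta, light_peak, control_peak)


def polar_population(alignments: list[PolarAlignment]) -> dict:
    """Population summary of polar alignments.

    Mean resultant length and direction, a Rayleigh test for nonuniformity,
    and the fraction of trials in the 'right half' (|theta| < 90 deg,
    i.e. peak within a quarter cycle of the control peak).
    """
    theta = np.deg2rad([a.theta_deg for a in alignments])
    r, p = rayleigh_test(theta)
    return {
        "n": len(alignments),
        "resultant": r,
        "rayleigh_p": p,
        "mean_direction_deg": float(np.rad2deg(mean_direction(theta))),
        "fraction_right_half": float(np.mean(np.abs(np.rad2deg(theta)) < 90.0)),
    }


def threshold_summary(r_values, threshold: float = R_THRESHOLD) -> dict:
    """Fraction of defined correlation coefficients at or above threshold."""
    r = np.asarray(list(r_values), dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        raise ValueError("no defined correlations")
    n_above = int(np.sum(r >= threshold))
    return {"n_above": n_above, "n_total": int(r.size), "fraction": n_above / r.size}
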