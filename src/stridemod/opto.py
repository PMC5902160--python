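"""Responses to 1 s optogenetic step and train stimuli.

Steps (continuous light) shift firing rates; trains (1 ms pulses at
50-200 Hz) entrain spikes at millisecond precision. Steps are summarized
as 50 ms-bin PSTHs relative to baseline; trains as 1 ms-bin spike
probability per pulse cycle, split into early/middle/late thirds of the
pulse sequence. Pulse locking is tested with the Rayleigh statistic on
within-cycle spike phases.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circular import rayleigh_test
from .datatypes import SpikeTrain, StimulusTrial

__all__ = [
    "PSTH",
    "step_psth",
    "train_psth",
    "rayleigh_locking",
    "stim_rate_change",
    "rebound_rate",
    "isi_cv",
    "pool_low_intensities",
]

LOW_INTENSITIES_MW = (0.56, 0.65)


@dataclass
class PSTH:
    """Peri-stimulus histogram: rate per bin (steps) or spike probability
    per 1 ms bin per pulse (trains)."""

    edges: np.ndarray  # bin edges, s (steps: from onset; trains: from pulse)
    values: np.ndarray
    baseline: float
    kind: str  # "step" | "train"
    group: str = "whole"  # whole | early | middle | late
    n_trials: int = 0

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def step_psth(
    spikes: SpikeTrain,
    trials: list[StimulusTrial],
    bin_ms: float = 50.0,
    baseline_per_trial: bool = True,
) -> tuple[PSTH, list[dict]]:
    """PSTH (spikes/s, 50 ms bins) over the 1 s step, averaged over trials.

    The baseline is the mean rate over the 1 s immediately before stimulus
    onset, averaged per trial (default) or pooled across the condition.
    Also returns per-trial pre/stim rates.
    """
    if not trials:
        raise ValueError("no trials")
    w = bin_ms / 1e3
    n_bins = int(round(trials[0].duration / w))
    counts = np.zeros(n_bins)
    per_trial = []
    baselines = []
    for tr in trials:
        rel = spikes.slice(tr.onset, tr.offset) - tr.onset
        counts += np.histogram(rel, bins=n_bins, range=(0.0, tr.duration))[0]
        pre = spikes.rate(tr.onset - 1.0, tr.onset)
        stim = spikes.rate(tr.onset, tr.offset)
        baselines.append(pre)
        per_trial.append({"trial_id": tr.trial_id, "pre_rate": pre, "stim_rate": stim})
    rate = counts / (len(trials) * w)
    baseline = float(np.mean(baselines))
    edges = np.arange(n_bins + 1) * w
    return PSTH(edges, rate, baseline, "step", n_trials=len(trials)), per_trial


def _pulse_groups(n_pulses: int) -> dict[str, np.ndarray]:
    """Early/middle/late contiguous thirds of the pulse sequence.

    Any remainder goes to the late group (100 pulses -> 33/33/34).
    """
    third = n_pulses // 3
    idx = np.arange(n_pulses)
    return {
        "early": idx[:third],
        "middle": idx[third : 2 * third],
        "late": idx[2 * third :],
    }


def train_psth(
    spikes: SpikeTrain,
    trials: list[StimulusTrial],
    bin_ms: float = 1.0,
) -> dict[str, PSTH]:
    """Pulse-locked spike-probability PSTHs for train trials.

    Each spike during the stimulus is assigned a latency from the most
    recent pulse onset (spikes before the first pulse are excluded);
    latencies are histogrammed in 1 ms bins across one inter-pulse interval
    and divided by the number of pulses, giving spikes per pulse per bin.
    Returned for the whole train and the early/middle/late thirds of the
    pulse sequence. Baseline is the mean spike probability per 1 ms over
    the 1 s pre-stimulus window.
    """
    if not trials:
        raise ValueError("no trials")
    freq = trials[0].freq_hz
    if freq is None:
        raise ValueError("train_psth requires train trials")
    period = 1.0 / freq
    w = bin_ms / 1e3
    n_bins = max(1, int(round(period / w)))

    groups = {g: np.zeros(n_bins) for g in ("whole", "early", "middle", "late")}
    n_pulses_group = {g: 0 for g in groups}
    pre_prob = []
    for tr in trials:
        pulses = tr.pulse_onsets
        gidx = _pulse_groups(pulses.size)
        sp = spikes.slice(pulses[0], tr.offset)
        k = np.searchsorted(pulses, sp, side="right") - 1
        lat = sp - pulses[k]
        hist_bin = np.minimum((lat / w).astype(int), n_bins - 1)
        groups["whole"] += np.bincount(hist_bin, minlength=n_bins)
        n_pulses_group["whole"] += pulses.size
        for g, idx in gidx.items():
            sel = np.isin(k, idx)
            groups[g] += np.bincount(hist_bin[sel], minlength=n_bins)
            n_pulses_group[g] += idx.size
        pre_prob.append(spikes.count(tr.onset - 1.0, tr.onset) / 1000.0 * bin_ms)
    baseline = float(np.mean(pre_prob))
    edges = np.arange(n_bins + 1) * w
    out = {}
    for g, c in groups.items():
        vals = c / max(n_pulses_group[g], 1)
        out[g] = PSTH(edges, vals, baseline, "train", group=g, n_trials=len(trials))
    return out


def rayleigh_locking(
    spikes: SpikeTrain, pulse_onsets: np.ndarray, freq_hz: float
) -> tuple[float, float]:
    """Rayleigh test of pulse locking during a train.

    Spike latencies from the most recent pulse map to cycle phase
    theta = 2*pi * latency * freq; returns (R, p). Requires >= 8 spikes
    during the stimulus (p is NaN below that).
    """
    pulses = np.asarray(pulse_onsets, dtype=float)
    period = 1.0 / freq_hz
    sp = spikes.slice(pulses[0], pulses[-1] + period)
    k = np.searchsorted(pulses, sp, side="right") - 1
    lat = sp - pulses[k]
    theta = 2 * np.pi * lat * freq_hz
    return rayleigh_test(theta)


def stim_rate_change(spikes: SpikeTrain, trial: StimulusTrial) -> dict:
    """Mean rates over the 1 s pre-stimulus and stimulus windows and their
    difference (stim - pre)."""
    pre = spikes.rate(trial.onset - 1.0, trial.onset)
    stim = spikes.rate(trial.onset, trial.offset)
    return {"pre_rate": pre, "stim_rate": stim, "delta": stim - pre}


def rebound_rate(spikes: SpikeTrain, trial: StimulusTrial, window_ms: float = 200.0) -> dict:
    """Rates in the 200 ms before vs after stimulus offset (post-step rebound)."""
    w = window_ms / 1e3
    return {
        "pre_off": spikes.rate(trial.offset - w, trial.offset),
        "post_off": spikes.rate(trial.offset, trial.offset + w),
    }


def isi_cv(spikes: SpikeTrain, window: tuple[float, float]) -> float:
    """Coefficient of variation of ISIs fully inside ``window``.

    Requires >= 2 ISIs (>= 3 spikes); returns NaN otherwise (the trial is
    excluded from CV statistics).
    """
    sp = spikes.slice(*window)
    if sp.size < 3:
        return float("nan")
    isi = np.diff(sp)
    return float(np.std(isi) / np.mean(isi))


def pool_low_intensities(trials: list[StimulusTrial]) -> list[StimulusTrial]:
    """Relabel the two lowest step intensities as one pooled condition.

    The two weakest steps evoke indistinguishable responses, so analyses
    may pool them; pooled trials get intensity equal to the lower value.
    """
    lo = min(LOW_INTENSITIES_MW)
    out = []
    for tr in trials:
        if tr.kind == "step" and tr.intensity_mw in LOW_INTENSITIES_MW:
            tr = StimulusTrial(
                tr.trial_id, tr.kind, tr.onset, tr.duration, lo,
                pre_s=tr.pre_s, post_s=tr.post_s,
            )
        out.append(tr)
    return out
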