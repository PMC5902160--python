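"""Classification of stimulation trials as slips or non-slips.

A slip is a light-evoked stride irregularity: relative to the last complete
pre-stimulus (control) stride, at least one stride during the 1 s stimulus
with duration >= 20% longer (prolonged), >= 20% shorter (incomplete), or a
stance or swing slope >= 20% lower (arrested). Trials meeting two or more
criteria are additionally flagged 'altered'. The module also screens trials
(running must continue; pre-stimulus gait must be steady), estimates slip
latency, tabulates slip probabilities per condition, and implements the
rate-matched step-vs-train McNemar comparison.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .datatypes import (
    PawTrace,
    SCREEN_ACCEPTED,
    SCREEN_DISCARDED_PRESTIM,
    SCREEN_DISCARDED_STOP,
    SCREEN_UNRESOLVED,
    SpikeTrain,
    StimulusTrial,
    Stride,
    StrideSet,
    TrialOutcome,
)

__all__ = [
    "screen_trial",
    "reference_stride",
    "classify_trial",
    "slip_latency",
    "slip_probability",
    "rate_match_pairs",
    "mcnemar",
]

SLIP_THRESHOLD = 0.2  # >= 20% deviation, boundary inclusive
_EPS = 1e-9  # keeps the ">= 20%" boundary inclusive under float rounding
REFERENCE_GRACE_S = 0.030  # tolerated overlap of the control stride into the stimulus
PRESTIM_CHANGE_LIMIT = 0.5  # 50% deviation of last pre-stim stride vs prior median


def screen_trial(
    trial: StimulusTrial,
    strides: StrideSet,
    rest_epochs: list[tuple[float, float]] | None = None,
    prestim_change_limit: float = PRESTIM_CHANGE_LIMIT,
) -> str:
    """Screen a trial before slip classification.

    Discards trials in which running ceased during the stimulus without
    resuming before trial end (a rest epoch overlapping the stimulus), or
    in which the last pre-stimulus stride deviates by more than 50% from
    the median of the three preceding strides. Returns a screen status
    string.
    """
    plants = strides.plant_times
    ends = np.array([s.next_plant for s in strides])
    pre = np.flatnonzero(ends <= trial.onset + REFERENCE_GRACE_S)
    if pre.size == 0:
        return SCREEN_UNRESOLVED

    if rest_epochs:
        trial_end = trial.offset + trial.post_s
        for a, b in rest_epochs:
            if a < trial.offset and b > trial.onset:  # overlaps stimulus
                resumed = np.any((plants > b) & (plants < trial_end))
                if not resumed:
                    return SCREEN_DISCARDED_STOP

    last = pre[-1]
    if last >= 3:
        prior = strides.durations_ms[last - 3 : last]
        ref = strides[last].duration_ms
        if abs(ref - np.median(prior)) / np.median(prior) > prestim_change_limit:
            return SCREEN_DISCARDED_PRESTIM
    return SCREEN_ACCEPTED


def reference_stride(
    trial: StimulusTrial,
    strides: StrideSet,
    grace_s: float = REFERENCE_GRACE_S,
) -> Stride | None:
    """The last complete pre-stimulus (control) stride.

    The last stride ending at or before stimulus onset; a stride running at
    most ``grace_s`` (30 ms) into the stimulus still qualifies. Returns
    None (trial unresolved) when no such stride exists.
    """
    candidates = [s for s in strides if s.next_plant <= trial.onset + grace_s]
    return candidates[-1] if candidates else None


def _stride_deviation(stride: Stride, ref: Stride) -> dict:
    return {
        "duration_ratio": stride.duration / ref.duration,
        "stance_slope_ratio": stride.stance_slope / ref.stance_slope,
        "swing_slope_ratio": stride.swing_slope / ref.swing_slope,
    }


def _metrics(stride: Stride) -> dict:
    return {
        "duration_ms": stride.duration_ms,
        "stance_slope": stride.stance_slope,
        "swing_slope": stride.swing_slope,
        "plant": stride.plant,
    }


def classify_trial(
    trial: StimulusTrial,
    strides: StrideSet,
    reference: Stride | None = None,
    threshold: float = SLIP_THRESHOLD,
    unresolved_as_slip: bool = False,
    rest_epochs: list[tuple[float, float]] | None = None,
) -> TrialOutcome:
    """Classify one screened trial as slip / non-slip.

    Every stride overlapping the 1 s stimulus window is compared to the
    control stride: duration ratio >= 1+threshold -> prolonged; <=
    1-threshold -> incomplete; stance or swing slope <= (1-threshold) x
    control -> arrested (both slopes reduced still counts as the one
    'arrested' category but contributes to the altered bookkeeping). Any
    hit makes the trial a slip; >= 2 distinct criteria make it 'altered'.
    For non-slips the stimulus-window stride deviating most from control is
    reported. Trials with no classifiable stride in the window are
    'unresolved' unless ``unresolved_as_slip`` replicates the original
    screening convention of counting them as slips.
    """
    screen = screen_trial(trial, strides, rest_epochs)
    out = TrialOutcome(trial.trial_id, screen=screen, condition=trial.condition, kind=trial.kind)
    if screen != SCREEN_ACCEPTED:
        return out
    if reference is None:
        reference = reference_stride(trial, strides)
    if reference is None:
        out.screen = SCREEN_UNRESOLVED
        return out
    out.reference_metrics = _metrics(reference)

    onset, offset = trial.window
    cats: set[str] = set()
    distinct_hits: set[str] = set()
    worst = None
    worst_dev = -1.0
    slip_stride = None
    for s in strides:
        if s.next_plant <= onset or s.plant >= offset:
            continue
        if s.plant < onset:
            continue  # the pre-stimulus stride itself
        dev = _stride_deviation(s, reference)
        stride_cats = set()
        slope_only = s.next_plant > offset  # straddles stimulus offset
        if not slope_only:
            if dev["duration_ratio"] >= 1.0 + threshold - _EPS:
                stride_cats.add("prolonged")
            if dev["duration_ratio"] <= 1.0 - threshold + _EPS:
                stride_cats.add("incomplete")
        slope_hits = [
            k for k in ("stance_slope_ratio", "swing_slope_ratio")
            if dev[k] <= 1.0 - threshold + _EPS
        ]
        if slope_hits:
            stride_cats.add("arrested")
        if stride_cats:
            cats |= stride_cats
            distinct_hits |= stride_cats - {"arrested"}
            distinct_hits |= set(slope_hits)
            if slip_stride is None:
                slip_stride = s
        score = max(
            abs(dev["duration_ratio"] - 1.0),
            abs(dev["stance_slope_ratio"] - 1.0),
            abs(dev["swing_slope_ratio"] - 1.0),
        )
        if score > worst_dev:
            worst_dev = score
            worst = s

    if worst is None:
        out.screen = SCREEN_UNRESOLVED
        if unresolved_as_slip:
            out.label = "slip"
        return out

    out.worst_metrics = _metrics(worst)
    if cats:
        out.label = "slip"
        out.categories = frozenset(cats)
        out.altered = len(distinct_hits) >= 2
        out.worst_metrics = _metrics(slip_stride)
    else:
        out.label = "non_slip"
    return out


DIVERGENCE_FRACTION = 0.2
DIVERGENCE_SUSTAIN_MS = 25.0


def slip_latency(
    trial: StimulusTrial,
    outcome: TrialOutcome,
    trace: PawTrace,
    strides: StrideSet,
    reference: Stride | None = None,
    fraction: float = DIVERGENCE_FRACTION,
    sustain_ms: float = DIVERGENCE_SUSTAIN_MS,
) -> float | None:
    """Latency (ms) from stimulus onset to slip onset.

    The control stride's trajectory is tiled forward from stimulus onset
    (phase-aligned to the ongoing stride) as a prediction of unperturbed
    locomotion. The first sample at which the paw diverges from this
    template by more than ``fraction`` (20%) of the stride amplitude,
    sustained for >= 25 ms, identifies the offending stride; the latency is
    reported from stimulus onset to that stride's plant (the slip's onset),
    or to the divergence itself when it precedes any detected stride.
    Returns None for non-slips or when no unambiguous onset exists.
    """
    if not outcome.is_slip:
        return None
    if reference is None:
        reference = reference_stride(trial, strides)
    if reference is None:
        return None

    fs = trace.fs
    t = trace.times
    i0 = int(np.searchsorted(t, reference.plant))
    i1 = int(np.searchsorted(t, reference.next_plant))
    if i1 - i0 < 4:
        return None
    template = trace.x[i0:i1]
    dur = reference.duration

    onset = trial.onset
    # Phase within the ongoing stride cycle at stimulus onset, assuming the
    # pre-stimulus rhythm continues.
    phase0 = (onset - reference.plant) % dur
    sel = (t >= onset) & (t < trial.offset)
    tt = t[sel]
    tau = (tt - onset + phase0) % dur
    pred = np.interp(tau, np.arange(template.size) / fs, template)
    dev = np.abs(trace.x[sel] - pred) > fraction * max(reference.amplitude, 1e-9)

    need = max(1, int(round(sustain_ms * fs / 1000.0)))
    run = 0
    div_idx = None
    for i, d in enumerate(dev):
        run = run + 1 if d else 0
        if run >= need:
            div_idx = i - need + 1
            break
    if div_idx is None:
        return None
    t_div = tt[div_idx]
    # Anchor to the start of the stride containing the divergence.
    plants = [s.plant for s in strides if onset <= s.plant <= t_div]
    t_slip = max(plants) if plants else t_div
    return float((t_slip - onset) * 1e3)


def slip_probability(outcomes: list[TrialOutcome], group_by: str = "condition") -> dict:
    """Slip counts and proportions per condition, with independence tests.

    Only accepted trials with a label are counted. Returns a dict of
    ``{condition: {"n_slip": ..., "n_total": ..., "p_slip": ...}}`` plus
    a chi-square test for independence across conditions (if >= 2
    conditions with trials).
    """
    table: dict[str, dict] = {}
    for o in outcomes:
        if o.label is None:
            continue
        key = getattr(o, group_by)
        row = table.setdefault(key, {"n_slip": 0, "n_total": 0})
        row["n_total"] += 1
        row["n_slip"] += int(o.is_slip)
    for row in table.values():
        row["p_slip"] = row["n_slip"] / row["n_total"]
    result = {"conditions": table}
    if len(table) >= 2:
        counts = np.array(
            [[r["n_slip"], r["n_total"] - r["n_slip"]] for r in table.values()]
        )
        if np.all(counts.sum(axis=0) > 0):
            chi2, p, dof, _ = stats.chi2_contingency(counts)
            result["chi2"] = float(chi2)
            result["chi2_p"] = float(p)
            result["chi2_dof"] = int(dof)
        if len(table) == 2:
            _, p = stats.fisher_exact(counts)
            result["fisher_p"] = float(p)
    return result


RATE_MATCH_TOLERANCE_HZ = 10.0
RATE_FLOOR_HZ = 10.0


def rate_match_pairs(
    step_trials: list[dict],
    train_trials: list[dict],
    tolerance_hz: float = RATE_MATCH_TOLERANCE_HZ,
    floor_hz: float = RATE_FLOOR_HZ,
) -> list[tuple[dict, dict]]:
    """All (step, train) trial pairs from the same cell with similar rates.

    Each trial dict needs ``cell``, ``stim_rate`` and ``slip`` keys. Pairs
    require |rate_step - rate_train| <= 10 spikes/s and both rates >= 10
    spikes/s; a trial may enter many pairs.
    """
    pairs = []
    for s in step_trials:
        if s["stim_rate"] < floor_hz:
            continue
        for tr in train_trials:
            if tr["stim_rate"] < floor_hz:
                continue
            if s.get("cell") != tr.get("cell"):
                continue
            if abs(s["stim_rate"] - tr["stim_rate"]) <= tolerance_hz:
                pairs.append((s, tr))
    return pairs


def mcnemar(pairs: list[tuple[bool, bool]] | None = None, b: int | None = None, c: int | None = None) -> dict:
    """McNemar's test for paired binary slip outcomes.

    ``pairs`` is a list of (step_slip, train_slip) booleans, or pass the
    discordant counts directly: ``b`` = step-only slips, ``c`` = train-only
    slips. Uses the continuity-uncorrected chi-square (b-c)^2/(b+c) with an
    asymptotic p when b+c >= 25, and the exact two-sided binomial test
    otherwise. b + c = 0 gives p = 1 by convention.
    """
    n_pairs = None
    p_step = p_train = None
    if pairs is not None:
        arr = np.asarray(pairs, dtype=bool)
        b = int(np.sum(arr[:, 0] & ~arr[:, 1]))
        c = int(np.sum(~arr[:, 0] & arr[:, 1]))
        n_pairs = arr.shape[0]
        p_step = float(arr[:, 0].mean())
        p_train = float(arr[:, 1].mean())
    if b is None or c is None:
        raise ValueError("provide pairs or both b and c")
    n_disc = b + c
    out: dict = {"b": b, "c": c}
    if n_disc == 0:
        out.update(statistic=0.0, p=1.0, method="none")
    elif n_disc >= 25:
        chi2 = (b - c) ** 2 / n_disc
        out.update(
            statistic=float(chi2),
            p=float(stats.chi2.sf(chi2, df=1)),
            method="chi2",
        )
    else:
        res = stats.binomtest(min(b, c), n_disc, 0.5, alternative="two-sided")
        out.update(statistic=float(min(b, c)), p=float(res.pvalue), method="exact")
    if n_pairs:
        out["n_pairs"] = n_pairs
        out["p_slip_step"] = p_step
        out["p_slip_train"] = p_train
        out["b_fraction"] = b / n_pairs
        out["c_fraction"] = c / n_pairs
    return out
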