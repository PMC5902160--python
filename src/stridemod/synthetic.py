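"""Ground-truth-labeled synthetic sessions.

Generates paw traces, spike trains, optogenetic stimuli, slips and LFP
sweeps with the statistical structure the analysis assumes, so every
downstream stage can be verified against known labels at desk scale.

The generative model, in brief:

* Stride durations follow a slow sinusoidal speed modulation (period
  ~100 strides) plus small per-stride jitter, clamped to the configured
  range. The slow/fast split reflects locomotion on a non-motorized
  treadmill: running speed drifts over seconds while consecutive strides
  are locally regular — which is also what makes the +/-20% slip criteria
  meaningful.
* The paw trace is a piecewise-linear sawtooth per stride (stance rises
  over ``stance_fraction`` of the stride, swing falls over the rest,
  amplitude 1 AU) with additive Gaussian tracking noise, optional
  full-scale square-pulse tracking-loss artifacts, and near-flat rest
  epochs.
* Spikes come from an inhomogeneous renewal process (Poisson by default;
  a gamma shape > 1 gives the sub-Poisson regularity of real cerebellar
  firing) whose rate follows a stride-phase tuning curve from one of six
  modulation classes with an analytically exact modulation index.
* Light steps add a signed rate offset with an onset transient; light
  trains add (Purkinje) or delete (CbN) pulse-locked spikes in a
  millisecond window after each pulse.
* Injected slips edit one stride per trial: prolonged/incomplete scale its
  duration relative to its predecessor, arrested scales its slopes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .datatypes import LFPSweeps, PawTrace, SpikeTrain, StimulusTrial, Stride

__all__ = [
    "SessionConfig",
    "SlipSpec",
    "TrialSpec",
    "GroundTruth",
    "Session",
    "gen_tuning",
    "generate_session",
    "gen_lfp",
    "write_session",
    "cbn_config",
]

SLIP_CATEGORIES = ("prolonged", "incomplete", "arrested")


@dataclass
class SessionConfig:
    """Parameters of one synthetic recording session.

    Defaults emulate a stride-modulated Purkinje cell: strides of
    222 +/- 71 ms (range 140-419 ms), stance ~65% of the cycle, rest rate
    93 spikes/s with a +26 spikes/s running offset, modulation index 0.4.
    """

    seed: int = 0
    n_strides: int = 200
    stride_mean_ms: float = 222.0
    stride_sd_ms: float = 71.0
    stride_min_ms: float = 140.0
    stride_max_ms: float = 419.0
    stance_fraction: float = 0.65
    rest_epochs: list[tuple[float, float]] = field(default_factory=list)  # (start, duration) s
    cell_type: str = "Purkinje"
    base_rest_rate_hz: float = 93.0
    run_rate_offset_hz: float = 26.0
    tuning_class: int = 1
    target_mi: float = 0.4
    paw_sample_hz: float = 240.0
    noise_sd_au: float = 0.015
    artifact_rate_hz: float = 0.1
    # Stride-duration process: slow speed drift + local jitter.
    stride_jitter_ms: float = 5.0
    speed_period_strides: int = 200
    stance_fraction_jitter: float = 0.015
    # Renewal shape: 1 = Poisson; > 1 = more regular (sub-Poisson CV).
    renewal_shape: float = 1.0
    margin_s: float = 1.0

    def __post_init__(self) -> None:
        if not (self.stride_min_ms <= self.stride_mean_ms <= self.stride_max_ms):
            raise ValueError("require stride_min <= stride_mean <= stride_max")
        if not (0.0 < self.target_mi < 1.0):
            raise ValueError("target_mi must be in (0, 1)")
        if not (0.0 < self.stance_fraction < 1.0):
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.cell_type not in ("Purkinje", "CbN"):
            raise ValueError("cell_type must be 'Purkinje' or 'CbN'")
        if self.tuning_class not in range(1, 7):
            raise ValueError("tuning_class must be 1..6")

    @property
    def run_rate_hz(self) -> float:
        return self.base_rest_rate_hz + self.run_rate_offset_hz


def cbn_config(**overrides) -> SessionConfig:
    """SessionConfig with CbN-cell defaults (rest 85, run offset +16)."""
    kw = dict(cell_type="CbN", base_rest_rate_hz=85.0, run_rate_offset_hz=16.0)
    kw.update(overrides)
    return SessionConfig(**kw)


@dataclass
class SlipSpec:
    """Requested slip for one trial."""

    category: str = "prolonged"
    magnitude: float = 0.3
    latency_ms: float = 120.0

    def __post_init__(self) -> None:
        if self.category not in SLIP_CATEGORIES:
            raise ValueError(f"category must be one of {SLIP_CATEGORIES}")
        if self.magnitude <= 0.2:
            raise ValueError(
                "slip magnitude <= 0.2 would be sub-threshold by construction"
            )
        if self.magnitude >= 0.9:
            raise ValueError("slip magnitude must be < 0.9")


@dataclass
class TrialSpec:
    """One optogenetic trial: stimulus pattern, rate/timing effects, slip.

    ``rate_effect_hz`` is the signed rate offset during the stimulus
    (positive for Purkinje, negative for CbN under ChR2 drive of Purkinje
    cells). ``lock_prob`` is the probability that a train pulse evokes
    (Purkinje) or suppresses (CbN) a spike in the lock window.
    ``modulation`` controls stride tuning during the stimulus: "preserved"
    keeps it, "abolished" flattens it to its mean, None picks a default
    (abolished for incomplete/arrested slips, preserved otherwise —
    prolonged strides keep their tuning stretched with the stride).
    """

    kind: str = "step"
    intensity_mw: float = 1.7
    freq_hz: float | None = None
    pulse_ms: float = 1.0
    rate_effect_hz: float = 0.0
    lock_prob: float = 0.0
    lock_latency_ms: float = 2.5
    lock_window_ms: float = 1.0
    suppress_window_ms: tuple[float, float] = (2.0, 6.0)
    rebound_hz: float = 0.0
    transient_fraction: float = 0.5
    transient_tau_s: float = 0.1
    slip: SlipSpec | None = None
    modulation: str | None = None
    deterministic_lock: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("step", "train"):
            raise ValueError("kind must be 'step' or 'train'")
        if self.kind == "train":
            if self.freq_hz is None:
                raise ValueError("train requires freq_hz")
            if 1.0 / self.freq_hz <= self.pulse_ms / 1e3:
                raise ValueError("pulse period must exceed pulse width")
        elif self.freq_hz is not None:
            raise ValueError("step has no frequency")
        if not (0.0 <= self.lock_prob <= 1.0):
            raise ValueError("lock_prob must be in [0, 1]")
        if self.modulation not in (None, "preserved", "abolished"):
            raise ValueError("modulation must be None, 'preserved' or 'abolished'")

    def resolved_modulation(self) -> str:
        if self.modulation is not None:
            return self.modulation
        if self.slip is not None and self.slip.category in ("incomplete", "arrested"):
            return "abolished"
        return "preserved"


@dataclass
class GroundTruth:
    """Generation-time labels for every downstream stage."""

    strides: list[Stride]
    rest_epochs: list[tuple[float, float]]
    artifacts: list[tuple[int, int]]  # sample index ranges
    tuning_class: int
    target_mi: float
    trial_info: list[dict]  # per trial: slip labels, anchor stride, modulation
    stance_fractions: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def durations_ms(self) -> np.ndarray:
        return np.array([s.duration_ms for s in self.strides])

    @property
    def plant_times(self) -> np.ndarray:
        return np.array([s.plant for s in self.strides])


@dataclass
class Session:
    """One generated session bundle."""

    config: SessionConfig
    paw: PawTrace
    spikes: SpikeTrain
    trials: list[StimulusTrial]
    truth: GroundTruth
    lfp: dict[str, LFPSweeps] = field(default_factory=dict)


def gen_tuning(
    class_id: int,
    base_rate: float,
    target_mi: float,
    stance_fraction: float = 0.65,
):
    """Stride-phase tuning function for one modulation class.

    Returns a vectorized ``f(time_fraction) -> spikes/s`` over the
    normalized stride (0 = plant, ``stance_fraction`` = lift). The
    sinusoidal amplitude is ``target_mi * base_rate`` so the modulation
    index (max-min)/(max+min) equals ``target_mi`` exactly.

    Classes: I peak at the lift (in phase with paw position), II anti-phase,
    III peak a quarter stride before the lift (leading), IV a quarter
    stride after (lagging), V two peaks at +/- a quarter stride from the
    lift, VI two troughs there.
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if not (0.0 < target_mi < 1.0):
        raise ValueError("target_mi must be in (0, 1)")
    s = stance_fraction
    m = target_mi

    def f(tf):
        tf = np.asarray(tf, dtype=float)
        if class_id == 1:
            mod = m * np.cos(2 * np.pi * (tf - s))
        elif class_id == 2:
            mod = -m * np.cos(2 * np.pi * (tf - s))
        elif class_id == 3:
            mod = m * np.cos(2 * np.pi * (tf - s + 0.25))
        elif class_id == 4:
            mod = m * np.cos(2 * np.pi * (tf - s - 0.25))
        elif class_id == 5:
            mod = -m * np.cos(4 * np.pi * (tf - s))
        elif class_id == 6:
            mod = m * np.cos(4 * np.pi * (tf - s))
        else:
            raise ValueError("class_id must be 1..6")
        return base_rate * (1.0 + mod)

    return f


def _log_amplitude_for_cv(cv: float) -> float:
    """Amplitude a of a multiplicative exp(a*triangle) speed modulation
    whose marginal coefficient of variation is ``cv``.

    The triangular profile is uniform on [-a, a], so
    E[exp] = sinh(a)/a and 1+cv^2 = E[exp(2U)]/E[exp(U)]^2
    = a*sinh(2a)/(2*sinh(a)^2).
    """
    from scipy.optimize import brentq

    if cv <= 0:
        return 0.0

    def f(a: float) -> float:
        return a * np.sinh(2 * a) / (2 * np.sinh(a) ** 2) - (1.0 + cv**2)

    return float(brentq(f, 1e-6, 3.0))


def _stride_durations(cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative slow speed drift + per-stride jitter, clamped to range.

    Running speed wanders as exp(a * triangle(i / P)): multiplicative, so
    stride-to-stride *relative* drift is uniform across fast and slow
    running, and triangular, so the drift magnitude per stride is constant
    (4a/P) while the marginal distribution still spans the configured
    duration range. This reproduces the pooled duration statistics while
    keeping consecutive strides locally regular, matching the within-trial
    stability reported for unperturbed locomotion — the regime in which
    +/-20% deviation criteria are meaningful.
    """
    from scipy.signal import sawtooth

    n = cfg.n_strides
    jitter_rel = cfg.stride_jitter_ms / cfg.stride_mean_ms
    cv_slow_sq = max((cfg.stride_sd_ms / cfg.stride_mean_ms) ** 2 - jitter_rel**2, 0.0)
    a = _log_amplitude_for_cv(np.sqrt(cv_slow_sq))
    phi0 = rng.uniform(0, 2 * np.pi)
    i = np.arange(n)
    tri = sawtooth(2 * np.pi * i / cfg.speed_period_strides + phi0, width=0.5)
    norm = np.sinh(a) / a if a > 0 else 1.0
    base = (cfg.stride_mean_ms / norm) * np.exp(a * tri)
    dur = base * (1.0 + rng.normal(0.0, jitter_rel, n))
    return np.clip(dur, cfg.stride_min_ms, cfg.stride_max_ms)


def _assign_trial_anchors(
    cfg: SessionConfig, trials: list[TrialSpec], durations_ms: np.ndarray
) -> list[int]:
    """Anchor stride index per trial; the slip stride (or the stride whose
    plant sits ~latency after onset for non-slip trials).

    For slip trials the anchor is nudged (within a few strides) so the
    edited stride stays inside the detectable 100-500 ms stride regime —
    an injected 'slip' shorter than the minimum accepted stride duration
    would not be a stride at all.
    """
    mean_s = cfg.stride_mean_ms / 1e3
    context = 2.0 + 1.0 + 2.0 + 1.0  # pre + stim + post + spacing
    gap = int(np.ceil(context / mean_s))
    first = int(np.ceil(2.5 / mean_s)) + 1
    tail = int(np.ceil(3.0 / mean_s))

    def _edit_ok(spec: TrialSpec, j: int) -> bool:
        if spec.slip is None:
            return True
        m = spec.slip.magnitude
        prev = durations_ms[j - 1]
        if spec.slip.category == "incomplete":
            return (1.0 - m) * prev >= 110.0
        if spec.slip.category == "prolonged":
            return (1.0 + m) * prev <= 490.0
        return True

    anchors: list[int] = []
    cursor = first
    for spec in trials:
        j = cursor
        while j + tail < cfg.n_strides and not _edit_ok(spec, j):
            j += 1
        if j + tail >= cfg.n_strides:
            raise ValueError(
                f"n_strides={cfg.n_strides} too small for {len(trials)} trials "
                "with the requested slip edits; increase n_strides"
            )
        anchors.append(j)
        cursor = j + gap
    return anchors


def generate_session(
    cfg: SessionConfig,
    trials: list[TrialSpec] | None = None,
    with_lfp: bool = False,
) -> Session:
    """Generate a full labeled session.

    Trials are laid out sequentially with 2 s pre / 1 s stimulus / 2 s post
    context; each trial is anchored to a stride whose plant falls
    ``slip.latency_ms`` (120 ms by default) after stimulus onset, and slip
    edits are applied to that stride. Bit-reproducible given ``cfg.seed``.
    """
    trials = trials or []
    rng = np.random.default_rng(cfg.seed)

    durations = _stride_durations(cfg, rng)  # ms
    sfracs = np.clip(
        cfg.stance_fraction + rng.normal(0, cfg.stance_fraction_jitter, cfg.n_strides),
        0.45,
        0.85,
    )
    amps = np.ones(cfg.n_strides)

    anchors = _assign_trial_anchors(cfg, trials, durations)
    trial_info: list[dict] = []
    for t_idx, (spec, j) in enumerate(zip(trials, anchors)):
        info = {
            "trial_id": t_idx,
            "kind": spec.kind,
            "anchor_stride": j,
            "modulation": spec.resolved_modulation(),
            "slip": None,
        }
        if spec.slip is not None:
            m = spec.slip.magnitude
            cat = spec.slip.category
            if cat == "prolonged":
                durations[j] = (1.0 + m) * durations[j - 1]
            elif cat == "incomplete":
                durations[j] = (1.0 - m) * durations[j - 1]
            elif cat == "arrested":
                amps[j] = 1.0 - m
            info["slip"] = {
                "category": cat,
                "magnitude": m,
                "latency_ms": spec.slip.latency_ms,
                "stride_index": j,
            }
        trial_info.append(info)

    # Timeline: leading margin, strides (with rest pauses inserted at the
    # nearest stride boundary), trailing margin.
    lead = cfg.margin_s + (2.5 if trials else 0.0)
    rest_requests = sorted(cfg.rest_epochs)
    rest_actual: list[tuple[float, float]] = []
    starts = np.empty(cfg.n_strides)
    ends = np.empty(cfg.n_strides)
    cursor = lead
    req_i = 0
    for i in range(cfg.n_strides):
        if req_i < len(rest_requests) and cursor >= rest_requests[req_i][0]:
            dur_rest = rest_requests[req_i][1]
            rest_actual.append((cursor, cursor + dur_rest))
            cursor += dur_rest
            req_i += 1
        starts[i] = cursor
        cursor += durations[i] / 1e3
        ends[i] = cursor

    strides = []
    for i in range(cfg.n_strides):
        d = durations[i] / 1e3
        lift = starts[i] + sfracs[i] * d
        strides.append(
            Stride(
                plant=float(starts[i]),
                lift=float(lift),
                next_plant=float(ends[i]),
                amplitude=float(amps[i]),
                stance_slope=float(amps[i] / (sfracs[i] * d)),
                swing_slope=float(amps[i] / ((1 - sfracs[i]) * d)),
            )
        )

    total_dur = cursor + cfg.margin_s + (3.5 if trials else 0.0)
    fs = cfg.paw_sample_hz
    n_samp = int(np.ceil(total_dur * fs))
    t = np.arange(n_samp) / fs

    # Piecewise-linear sawtooth via knot interpolation.
    knots_t = [0.0]
    knots_x = [0.0]
    for s in strides:
        for ta, xa in ((s.plant, 0.0), (s.lift, s.amplitude), (s.next_plant, 0.0)):
            if ta > knots_t[-1]:
                knots_t.append(ta)
                knots_x.append(xa)
    knots_t.append(total_dur)
    knots_x.append(0.0)
    x = np.interp(t, knots_t, knots_x)

    rest_mask = np.zeros(n_samp, dtype=bool)
    for a, b in rest_actual:
        rest_mask |= (t >= a) & (t < b)
    x[rest_mask] = 0.0
    if cfg.noise_sd_au > 0:
        x = x + rng.normal(0.0, cfg.noise_sd_au, n_samp)

    artifacts: list[tuple[int, int]] = []
    if cfg.artifact_rate_hz > 0:
        n_art = rng.poisson(cfg.artifact_rate_hz * total_dur)
        art_starts = np.sort(rng.integers(5, n_samp - 10, size=n_art))
        prev_end = -10
        for a in art_starts:
            w = int(rng.integers(1, 4))
            if a <= prev_end + 6:  # keep artifacts separated
                continue
            x[a : a + w] += 1.0
            artifacts.append((int(a), int(a + w)))
            prev_end = a + w

    paw = PawTrace(x, fs)

    # --- Stimulus trials -------------------------------------------------
    stim_trials: list[StimulusTrial] = []
    for info, spec in zip(trial_info, trials):
        j = info["anchor_stride"]
        latency = (spec.slip.latency_ms if spec.slip else 120.0) / 1e3
        onset = strides[j].plant - latency
        if spec.kind == "train":
            n_p = int(round(spec.freq_hz * 1.0))
            pulses = onset + np.arange(n_p) / spec.freq_hz
            stim_trials.append(
                StimulusTrial(
                    info["trial_id"], "train", onset,
                    intensity_mw=spec.intensity_mw, freq_hz=spec.freq_hz,
                    pulse_onsets=pulses,
                )
            )
            info["pulse_onsets"] = pulses
        else:
            stim_trials.append(
                StimulusTrial(info["trial_id"], "step", onset, intensity_mw=spec.intensity_mw)
            )
        info["onset"] = onset

    # --- Firing rate profile ---------------------------------------------
    run_base = cfg.run_rate_hz
    rate = np.full(n_samp, cfg.base_rest_rate_hz)
    idx = np.searchsorted(starts, t, side="right") - 1
    idx_c = np.clip(idx, 0, cfg.n_strides - 1)
    in_stride = (idx >= 0) & (idx < cfg.n_strides) & (t < ends[idx_c]) & ~rest_mask
    si = idx[in_stride]
    rel = (t[in_stride] - starts[si]) / (durations[si] / 1e3)
    rel = np.clip(rel, 0.0, 1.0)
    tuning = gen_tuning(cfg.tuning_class, run_base, cfg.target_mi, cfg.stance_fraction)
    rate[in_stride] = tuning(rel)
    rate[rest_mask] = cfg.base_rest_rate_hz

    for info, spec, tr in zip(trial_info, trials, stim_trials):
        w = (t >= tr.onset) & (t < tr.offset)
        if info["modulation"] == "abolished":
            rate[w] = run_base
        shape = 1.0 + spec.transient_fraction * np.exp(
            -(t[w] - tr.onset) / spec.transient_tau_s
        )
        rate[w] = rate[w] + spec.rate_effect_hz * shape
        if spec.rebound_hz:
            wr = (t >= tr.offset) & (t < tr.offset + 0.2)
            rate[wr] = rate[wr] + spec.rebound_hz

    if np.any(rate < 0):
        warnings.warn("negative instantaneous rate clipped at 0", stacklevel=2)
        rate = np.clip(rate, 0.0, None)

    spikes = _sample_renewal(rate, t, cfg.renewal_shape, rng)

    # --- Train locking / deterministic windows ----------------------------
    for info, spec, tr in zip(trial_info, trials, stim_trials):
        if spec.kind != "train":
            continue
        pulses = info["pulse_onsets"]
        if spec.deterministic_lock:
            keep = (spikes < tr.onset) | (spikes >= tr.offset)
            locked = pulses + spec.lock_latency_ms / 1e3
            spikes = np.sort(np.concatenate([spikes[keep], locked]))
            continue
        if spec.lock_prob <= 0:
            continue
        hit = rng.random(pulses.size) < spec.lock_prob
        if cfg.cell_type == "Purkinje":
            lat = spec.lock_latency_ms / 1e3 + (rng.random(int(hit.sum())) - 0.5) * (
                spec.lock_window_ms / 1e3
            )
            spikes = np.sort(np.concatenate([spikes, pulses[hit] + lat]))
        else:
            w0, w1 = (v / 1e3 for v in spec.suppress_window_ms)
            drop = np.zeros(spikes.size, dtype=bool)
            for p in pulses[hit]:
                drop |= (spikes >= p + w0) & (spikes < p + w1)
            spikes = spikes[~drop]

    spikes = np.unique(spikes)
    train = SpikeTrain(spikes, span=(0.0, total_dur))

    truth = GroundTruth(
        strides=strides,
        rest_epochs=rest_actual,
        artifacts=artifacts,
        tuning_class=cfg.tuning_class,
        target_mi=cfg.target_mi,
        trial_info=trial_info,
        stance_fractions=sfracs,
    )

    lfp = {}
    if with_lfp:
        for info, spec in zip(trial_info, trials):
            if spec.kind == "train":
                pulses = np.asarray(info["pulse_onsets"]) - info["onset"]
                lfp[f"train_{spec.freq_hz:g}Hz"] = gen_lfp(
                    pulses, seed=int(rng.integers(2**31))
                )
    return Session(cfg, paw, train, stim_trials, truth, lfp)


def _sample_renewal(
    rate: np.ndarray, t: np.ndarray, shape: float, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous renewal process by time rescaling.

    Unit-mean increments (Exp(1) for Poisson, Gamma(shape, 1/shape) for
    regular firing) are accumulated in rescaled time and mapped back
    through the inverse cumulative intensity.
    """
    dt = np.diff(t)
    lam = np.concatenate([[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * dt)])
    total = lam[-1]
    if total <= 0:
        return np.empty(0)
    n_draw = int(total + 6 * np.sqrt(total) + 20)
    if shape == 1.0:
        inc = rng.exponential(1.0, n_draw)
    else:
        inc = rng.gamma(shape, 1.0 / shape, n_draw)
    arr = np.cumsum(inc)
    while arr[-1] < total:
        extra = rng.exponential(1.0, n_draw) if shape == 1.0 else rng.gamma(shape, 1.0 / shape, n_draw)
        arr = np.concatenate([arr, arr[-1] + np.cumsum(extra)])
    arr = arr[arr < total]
    return np.interp(arr, lam, t)


def gen_lfp(
    pulse_times: np.ndarray,
    kernel_freq_hz: float = 300.0,
    kernel_tau_s: float = 0.010,
    kernel_duration_s: float | None = None,
    noise_sd: float = 1.0,
    mains_amp: float = 0.5,
    n_sweeps: int = 10,
    fs: float = 10_000.0,
    duration_s: float = 1.0,
    seed: int = 0,
) -> LFPSweeps:
    """Synthetic LFP sweeps: damped-oscillation kernel at each pulse time
    plus white noise and a 60 Hz mains contaminant; 10 sweeps at 10 kHz."""
    pulse_times = np.asarray(pulse_times, dtype=float)
    period = (
        float(np.min(np.diff(np.sort(pulse_times)))) if pulse_times.size > 1 else np.inf
    )
    if kernel_duration_s is None:
        # ~50 ms damped oscillation for a step onset; shortened for trains
        # so pulse responses do not smear into the next cycle.
        kernel_duration_s = min(0.050, 0.8 * period)
    elif kernel_duration_s >= period:
        raise ValueError("kernel duration must be shorter than the pulse period")
    rng = np.random.default_rng(seed)
    n = int(duration_s * fs)
    tk = np.arange(int(kernel_duration_s * fs)) / fs
    kernel = np.exp(-tk / kernel_tau_s) * np.sin(2 * np.pi * kernel_freq_hz * tk)
    clean = np.zeros(n)
    for p in pulse_times:
        i = int(round(p * fs))
        if 0 <= i < n:
            seg = kernel[: n - i]
            clean[i : i + seg.size] += seg
    t = np.arange(n) / fs
    sweeps = np.empty((n_sweeps, n))
    for k in range(n_sweeps):
        sweeps[k] = (
            clean
            + mains_amp * np.sin(2 * np.pi * 60.0 * t + rng.uniform(0, 2 * np.pi))
            + rng.normal(0.0, noise_sd, n)
        )
    return LFPSweeps(sweeps, fs=fs)


def write_session(session: Session, outdir: str | Path) -> None:
    """Write a session bundle as flat CSV/JSON files."""
    import pandas as pd

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paw = session.paw
    pd.DataFrame(
        {
            "time_s": paw.times,
            "x_au": paw.x,
            "tracked_flag": paw.tracked.astype(int),
        }
    ).to_csv(outdir / "paw.csv", index=False)
    pd.DataFrame({"spike_time_s": session.spikes.times}).to_csv(
        outdir / "spikes.csv", index=False
    )
    rows = []
    for tr in session.trials:
        rows.append(
            {
                "trial_id": tr.trial_id,
                "kind": tr.kind,
                "onset_s": tr.onset,
                "duration_s": tr.duration,
                "intensity_mw": tr.intensity_mw,
                "freq_hz": tr.freq_hz if tr.freq_hz is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(outdir / "stimuli.csv", index=False)

    truth = session.truth
    gt = {
        "tuning_class": truth.tuning_class,
        "target_mi": truth.target_mi,
        "rest_epochs": truth.rest_epochs,
        "strides": [
            {
                "plant_s": s.plant,
                "lift_s": s.lift,
                "next_plant_s": s.next_plant,
                "amplitude_au": s.amplitude,
            }
            for s in truth.strides
        ],
        "trials": [
            {k: v for k, v in info.items() if k != "pulse_onsets"}
            for info in truth.trial_info
        ],
    }
    (outdir / "ground_truth.json").write_text(json.dumps(gt, indent=1, default=float))
    for cond, sw in session.lfp.items():
        df = pd.DataFrame(sw.sweeps.T, columns=[f"v_uV_{k+1}" for k in range(sw.n_sweeps)])
        df.insert(0, "time_s", sw.times)
        df.to_csv(outdir / f"lfp_{cond}.csv", index=False)
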