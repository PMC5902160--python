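"""Core in-memory containers shared across the analysis stages.

Positions are in AU (1 AU = full forward-to-backward range of the paw within
the tracking region of interest), times in seconds, rates in spikes/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PawTrace",
    "SpikeTrain",
    "Stride",
    "StrideSet",
    "StimulusTrial",
    "TrialOutcome",
    "LFPSweeps",
]


@dataclass
class PawTrace:
    """Uniformly sampled paw x-position.

    Parameters
    ----------
    x : ndarray
        Normalized x-position, AU.
    fs : float
        Sample rate, Hz (nominally ~240 frames/s).
    tracked : ndarray of bool, optional
        Per-sample flag; False marks samples where the tracker lost the paw.
    t0 : float
        Time of the first sample, s.
    """

    x: np.ndarray
    fs: float
    tracked: np.ndarray | None = None
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1:
            raise ValueError("paw trace must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sample rate must be positive")
        if self.tracked is None:
            self.tracked = np.ones(self.x.size, dtype=bool)
        else:
            self.tracked = np.asarray(self.tracked, dtype=bool)
            if self.tracked.size != self.x.size:
                raise ValueError("tracked flag length mismatch")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.x.size) / self.fs

    @property
    def duration(self) -> float:
        return self.x.size / self.fs

    def copy(self) -> "PawTrace":
        return PawTrace(self.x.copy(), self.fs, self.tracked.copy(), self.t0)


@dataclass
class SpikeTrain:
    """Sorted spike times over a recording span."""

    times: np.ndarray
    span: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")
        if self.span is None:
            if self.times.size:
                self.span = (float(self.times[0]), float(self.times[-1]))
            else:
                self.span = (0.0, 0.0)
        t0, t1 = self.span
        if self.times.size and (self.times[0] < t0 or self.times[-1] > t1):
            raise ValueError("spikes outside recording span")

    @property
    def n(self) -> int:
        return self.times.size

    def count(self, t0: float, t1: float) -> int:
        """Number of spikes in [t0, t1)."""
        lo, hi = np.searchsorted(self.times, [t0, t1])
        return int(hi - lo)

    def rate(self, t0: float, t1: float) -> float:
        """Mean firing rate (count / window) over [t0, t1)."""
        if t1 <= t0:
            raise ValueError("empty window")
        return self.count(t0, t1) / (t1 - t0)

    def slice(self, t0: float, t1: float) -> np.ndarray:
        lo, hi = np.searchsorted(self.times, [t0, t1])
        return self.times[lo:hi]


@dataclass
class Stride:
    """One trough-to-trough locomotor cycle.

    plant -> (stance, paw moves backward, trace rises) -> lift ->
    (swing, paw moves forward, trace falls) -> next plant.
    """

    plant: float
    lift: float
    next_plant: float
    amplitude: float = 1.0
    stance_slope: float = float("nan")
    swing_slope: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.plant < self.lift < self.next_plant):
            raise ValueError("require plant < lift < next_plant")

    @property
    def duration(self) -> float:
        return self.next_plant - self.plant

    @property
    def duration_ms(self) -> float:
        return 1e3 * self.duration

    @property
    def stance_fraction(self) -> float:
        return (self.lift - self.plant) / self.duration


@dataclass
class StrideSet:
    """Detected strides plus the session's stance/swing bin allocation."""

    strides: list[Stride]
    n_stance_bins: int = 0
    n_swing_bins: int = 0
    source: str = ""

    MIN_SESSION_STRIDES = 30

    def __len__(self) -> int:
        return len(self.strides)

    def __iter__(self):
        return iter(self.strides)

    def __getitem__(self, i):
        return self.strides[i]

    @property
    def sufficient(self) -> bool:
        """True when enough strides for session-level statistics."""
        return len(self.strides) >= self.MIN_SESSION_STRIDES

    @property
    def durations_ms(self) -> np.ndarray:
        return np.array([s.duration_ms for s in self.strides])

    @property
    def plant_times(self) -> np.ndarray:
        return np.array([s.plant for s in self.strides])

    @property
    def median_amplitude(self) -> float:
        return float(np.median([s.amplitude for s in self.strides]))


@dataclass
class StimulusTrial:
    """One 1 s optogenetic step or train epoch with 2 s pre/post context."""

    trial_id: int
    kind: str  # "step" | "train"
    onset: float
    duration: float = 1.0
    intensity_mw: float = 1.7
    freq_hz: float | None = None
    pulse_onsets: np.ndarray | None = None
    pre_s: float = 2.0
    post_s: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("step", "train"):
            raise ValueError("kind must be 'step' or 'train'")
        if self.kind == "train":
            if self.freq_hz is None:
                raise ValueError("train requires freq_hz")
            if self.pulse_onsets is None:
                n = int(round(self.freq_hz * self.duration))
                self.pulse_onsets = self.onset + np.arange(n) / self.freq_hz
            else:
                self.pulse_onsets = np.asarray(self.pulse_onsets, dtype=float)
        elif self.freq_hz is not None:
            raise ValueError("step stimulus has no frequency")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    @property
    def window(self) -> tuple[float, float]:
        return (self.onset, self.offset)

    @property
    def condition(self) -> str:
        if self.kind == "step":
            return f"step_{self.intensity_mw:g}mW"
        return f"train_{self.freq_hz:g}Hz"


# Screen / label vocabulary for trial outcomes.
SCREEN_ACCEPTED = "accepted"
SCREEN_DISCARDED_STOP = "discarded_stop"
SCREEN_DISCARDED_PRESTIM = "discarded_prestim_change"
SCREEN_UNRESOLVED = "unresolved"


@dataclass
class TrialOutcome:
    """Per-trial slip classification."""

    trial_id: int
    screen: str = SCREEN_ACCEPTED
    label: str | None = None  # "slip" | "non_slip"
    categories: frozenset[str] = field(default_factory=frozenset)
    altered: bool = False
    latency_ms: float | None = None
    reference_metrics: dict | None = None
    worst_metrics: dict | None = None
    condition: str = ""
    kind: str = ""

    @property
    def is_slip(self) -> bool:
        return self.label == "slip"


@dataclass
class LFPSweeps:
    """A set of LFP sweeps for one stimulation condition (10 expected)."""

    sweeps: np.ndarray  # (n_sweeps, n_samples), µV
    fs: float = 10_000.0
    condition: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.sweeps = np.atleast_2d(np.asarray(self.sweeps, dtype=float))

    @property
    def n_sweeps(self) -> int:
        return self.sweeps.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.sweeps.shape[1]) / self.fs
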