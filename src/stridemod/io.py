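"""Flat-file I/O for session bundles (CSV/JSON only, diffable)."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import LFPSweeps, PawTrace, SpikeTrain, StimulusTrial, Stride, StrideSet

__all__ = [
    "read_paw_csv",
    "read_spikes_csv",
    "read_stimuli_csv",
    "read_lfp_csv",
    "write_strides_csv",
    "read_strides_csv",
    "write_outcomes_csv",
]


def read_paw_csv(path: str | Path) -> PawTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    tracked = (
        df["tracked_flag"].to_numpy().astype(bool)
        if "tracked_flag" in df
        else None
    )
    return PawTrace(df["x_au"].to_numpy(), fs=float(fs), tracked=tracked, t0=float(t[0]))


def read_spikes_csv(path: str | Path, span: tuple[float, float] | None = None) -> SpikeTrain:
    df = pd.read_csv(path)
    return SpikeTrain(np.sort(df["spike_time_s"].to_numpy()), span=span)


def read_stimuli_csv(path: str | Path) -> list[StimulusTrial]:
    df = pd.read_csv(path)
    trials = []
    for _, row in df.iterrows():
        freq = row.get("freq_hz")
        freq = None if (freq is None or pd.isna(freq) or freq == "") else float(freq)
        trials.append(
            StimulusTrial(
                trial_id=int(row["trial_id"]),
                kind=str(row["kind"]),
                onset=float(row["onset_s"]),
                duration=float(row.get("duration_s", 1.0)),
                intensity_mw=float(row.get("intensity_mw", 1.7)),
                freq_hz=freq,
            )
        )
    return trials


def read_lfp_csv(path: str | Path, condition: str = "") -> LFPSweeps:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / np.median(np.diff(t))
    cols = [c for c in df.columns if c != "time_s"]
    return LFPSweeps(df[cols].to_numpy().T, fs=float(fs), condition=condition, t0=float(t[0]))


def write_strides_csv(strides: StrideSet, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "plant_s": s.plant,
                "lift_s": s.lift,
                "next_plant_s": s.next_plant,
                "duration_ms": s.duration_ms,
                "stance_slope": s.stance_slope,
                "swing_slope": s.swing_slope,
                "amplitude_au": s.amplitude,
            }
            for s in strides
        ]
    ).to_csv(path, index=False)


def read_strides_csv(path: str | Path) -> StrideSet:
    df = pd.read_csv(path)
    strides = [
        Stride(
            plant=row["plant_s"],
            lift=row["lift_s"],
            next_plant=row["next_plant_s"],
            amplitude=row.get("amplitude_au", 1.0),
            stance_slope=row["stance_slope"],
            swing_slope=row["swing_slope"],
        )
        for _, row in df.iterrows()
    ]
    sset = StrideSet(strides)
    if strides:
        from .strides import allocate_bins

        sset.n_stance_bins, sset.n_swing_bins = allocate_bins(sset)
    return sset


def write_outcomes_csv(outcomes, path: str | Path) -> None:
    rows = []
    for o in outcomes:
        rows.append(
            {
                "trial_id": o.trial_id,
                "screen": o.screen,
                "label": o.label or "",
                "categories": "|".join(sorted(o.categories)),
                "altered": int(o.altered),
                "latency_ms": "" if o.latency_ms is None else o.latency_ms,
                "condition": o.condition,
                "kind": o.kind,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
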