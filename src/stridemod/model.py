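"""Session-level model/results objects.

:class:`LocomotionSession` bundles one cell's recording (paw trace, spike
train, optional optogenetic trials) and :meth:`~LocomotionSession.fit`
runs the full analysis chain — trace cleaning, stride detection, stride-
phase tuning and modulation classification, step/train responses, slip
classification and modulation-correlation analyses — returning a
:class:`SessionResults` with the estimates and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import correlation as corr
from . import firing, opto, slips as slipmod, strides as stride_ops
from .datatypes import PawTrace, SpikeTrain, StimulusTrial, StrideSet, TrialOutcome
from .firing import BinnedTuning

__all__ = ["LocomotionSession", "SessionResults"]


@dataclass
class SessionResults:
    """Fitted estimates for one session."""

    strides: StrideSet
    rest_epochs: list[tuple[float, float]]
    tuning: BinnedTuning | None = None
    mi: float = float("nan")
    st_mi: float = float("nan")
    sw_mi: float = float("nan")
    kuiper_v: float = float("nan")
    kuiper_p: float = float("nan")
    modulation_class: int = 7
    rest_run: dict = field(default_factory=dict)
    step_responses: list[dict] = field(default_factory=list)
    train_responses: list[dict] = field(default_factory=list)
    step_psth: opto.PSTH | None = None
    train_psths: dict = field(default_factory=dict)
    outcomes: list[TrialOutcome] = field(default_factory=list)
    slip_tables: dict = field(default_factory=dict)
    nonslip_r: float = float("nan")
    slip_correlations: list[dict] = field(default_factory=list)
    polar_alignments: list = field(default_factory=list)

    @property
    def n_slips(self) -> int:
        return sum(o.is_slip for o in self.outcomes)

    def summary(self) -> str:
        lines = ["Locomotion session summary", "=" * 42]
        lines.append(f"strides detected          {len(self.strides):>8d}")
        if len(self.strides):
            d = self.strides.durations_ms
            lines.append(f"stride duration (ms)      {d.mean():8.1f} +/- {d.std():.1f}")
            lines.append(
                f"bin allocation            {self.strides.n_stance_bins} stance / "
                f"{self.strides.n_swing_bins} swing"
            )
        rr = self.rest_run
        if rr.get("rest_mean") is not None:
            lines.append(f"rest rate (spikes/s)      {rr['rest_mean']:8.1f}")
        if rr.get("run_mean") is not None:
            lines.append(f"run rate (spikes/s)       {rr['run_mean']:8.1f}")
            lines.append(
                f"run min/max (spikes/s)    {rr['run_min']:8.1f} / {rr['run_max']:.1f}"
            )
        if self.tuning is not None:
            lines.append(
                f"modulation index          {self.mi:8.2f} "
                f"(stance {self.st_mi:.2f}, swing {self.sw_mi:.2f})"
            )
            lines.append(f"Kuiper p                  {self.kuiper_p:8.2g}")
            lines.append(
                f"modulation class          {firing.CLASS_NAMES[self.modulation_class]:>8s}"
            )
        if self.outcomes:
            labeled = [o for o in self.outcomes if o.label]
            lines.append(
                f"trials (slip/labeled)     {self.n_slips:>4d} / {len(labeled)}"
            )
        if np.isfinite(self.nonslip_r):
            lines.append(f"non-slip tuning corr r    {self.nonslip_r:8.2f}")
        if self.slip_correlations:
            rvals = [c["r"] for c in self.slip_correlations if np.isfinite(c["r"])]
            if rvals:
                frac = corr.threshold_summary(rvals)["fraction"]
                lines.append(f"slip trials with r>=0.4   {frac:8.1%}")
        return "\n".join(lines)


class LocomotionSession:
    """One cell's recording during treadmill locomotion.

    Parameters
    ----------
    paw : PawTrace
        Raw paw-tracking trace (cleaned and smoothed internally).
    spikes : SpikeTrain
    trials : list of StimulusTrial, optional
        Optogenetic step/train trials.
    cell_type : str
        "Purkinje" or "CbN"; only used for labeling.
    """

    def __init__(
        self,
        paw: PawTrace,
        spikes: SpikeTrain,
        trials: list[StimulusTrial] | None = None,
        cell_type: str = "Purkinje",
        cell_id: str = "",
    ):
        self.paw = paw
        self.spikes = spikes
        self.trials = trials or []
        self.cell_type = cell_type
        self.cell_id = cell_id

    @classmethod
    def from_csv(cls, paw_csv, spikes_csv, stimuli_csv=None, **kw) -> "LocomotionSession":
        from .io import read_paw_csv, read_spikes_csv, read_stimuli_csv

        trials = read_stimuli_csv(stimuli_csv) if stimuli_csv else None
        return cls(read_paw_csv(paw_csv), read_spikes_csv(spikes_csv), trials, **kw)

    @classmethod
    def from_synthetic(cls, session) -> "LocomotionSession":
        """Build from a :class:`stridemod.synthetic.Session`."""
        return cls(
            session.paw,
            session.spikes,
            session.trials,
            cell_type=session.config.cell_type,
        )

    # ------------------------------------------------------------------
    def fit(self, unresolved_as_slip: bool = False) -> SessionResults:
        """Run the full analysis chain and return a results object."""
        cleaned = stride_ops.clean_trace(self.paw)
        smoothed = stride_ops.smooth_trace(cleaned)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            all_strides = stride_ops.detect_strides(cleaned, smoothed)
        rest = (
            stride_ops.detect_rest(cleaned, all_strides) if len(all_strides) else []
        )
        res = SessionResults(strides=all_strides, rest_epochs=rest)
        if not len(all_strides):
            return res

        stim_windows = [t.window for t in self.trials]

        def in_stimulus(s):
            return any(s.next_plant > a and s.plant < b for a, b in stim_windows)

        no_light = StrideSet(
            [s for s in all_strides if not in_stimulus(s)],
            all_strides.n_stance_bins,
            all_strides.n_swing_bins,
        )

        if no_light.sufficient:
            tuning = firing.binned_tuning(self.spikes, no_light, cleaned)
            res.tuning = tuning
            res.mi, res.st_mi, res.sw_mi = firing.modulation_index(tuning)
            res.kuiper_v, res.kuiper_p = firing.kuiper_from_session(self.spikes, no_light)
            res.modulation_class = firing.classify_modulation(
                tuning, kuiper_p=res.kuiper_p, mi=res.mi
            )
            res.rest_run = firing.rest_run_rates(self.spikes, rest, no_light, tuning)
        else:
            res.rest_run = firing.rest_run_rates(self.spikes, rest, no_light)

        if not self.trials:
            return res

        # --- optogenetic responses ------------------------------------
        steps = [t for t in self.trials if t.kind == "step"]
        trains = [t for t in self.trials if t.kind == "train"]
        if steps:
            psth, per_trial = opto.step_psth(self.spikes, steps)
            res.step_psth = psth
            for t, d in zip(steps, per_trial):
                d.update(opto.stim_rate_change(self.spikes, t))
                d.update(opto.rebound_rate(self.spikes, t))
                d["cv"] = opto.isi_cv(self.spikes, t.window)
                d["condition"] = t.condition
                d["cell"] = self.cell_id
            res.step_responses = per_trial
        if trains:
            by_freq: dict[float, list[StimulusTrial]] = {}
            for t in trains:
                by_freq.setdefault(t.freq_hz, []).append(t)
            for f, ts in by_freq.items():
                res.train_psths[f] = opto.train_psth(self.spikes, ts)
            per_trial = []
            for t in trains:
                d = {"trial_id": t.trial_id, "condition": t.condition, "cell": self.cell_id}
                d.update(opto.stim_rate_change(self.spikes, t))
                d["cv"] = opto.isi_cv(self.spikes, t.window)
                d["rayleigh_R"], d["rayleigh_p"] = opto.rayleigh_locking(
                    self.spikes, t.pulse_onsets, t.freq_hz
                )
                per_trial.append(d)
            res.train_responses = per_trial

        # --- slips ------------------------------------------------------
        outcomes = []
        for t in self.trials:
            ref = slipmod.reference_stride(t, all_strides)
            o = slipmod.classify_trial(
                t, all_strides, ref,
                unresolved_as_slip=unresolved_as_slip, rest_epochs=rest,
            )
            if o.is_slip:
                o.latency_ms = slipmod.slip_latency(t, o, cleaned, all_strides, ref)
            outcomes.append(o)
        res.outcomes = outcomes
        labeled = [o for o in outcomes if o.label]
        if labeled:
            res.slip_tables["by_condition"] = slipmod.slip_probability(labeled)
            res.slip_tables["by_kind"] = slipmod.slip_probability(labeled, group_by="kind")

        # --- modulation correlation --------------------------------------
        nonslip_ids = {o.trial_id for o in outcomes if o.label == "non_slip"}
        light_on = [
            s
            for t in self.trials
            if t.trial_id in nonslip_ids
            for s in all_strides
            if s.plant >= t.onset and s.next_plant <= t.offset
        ]
        if res.tuning is not None and light_on:
            res.nonslip_r = corr.nonslip_tuning_correlation(
                self.spikes,
                no_light,
                StrideSet(light_on, no_light.n_stance_bins, no_light.n_swing_bins),
            )
        by_id = {t.trial_id: t for t in self.trials}
        for o in outcomes:
            if not o.is_slip:
                continue
            t = by_id[o.trial_id]
            ref = slipmod.reference_stride(t, all_strides)
            if ref is None:
                continue
            r = corr.slip_template_correlation(
                self.spikes, t, ref,
                all_strides.n_stance_bins, all_strides.n_swing_bins,
            )
            res.slip_correlations.append(
                {"trial_id": o.trial_id, "kind": o.kind, "r": r}
            )
            if "prolonged" in o.categories and res.tuning is not None:
                slip_stride = next(
                    (
                        s
                        for s in all_strides
                        if o.worst_metrics and abs(s.plant - o.worst_metrics["plant"]) < 1e-9
                    ),
                    None,
                )
                if slip_stride is not None:
                    res.polar_alignments.append(
                        corr.prolonged_polar(
                            self.spikes, slip_stride, res.tuning,
                            all_strides.n_stance_bins, all_strides.n_swing_bins,
                        )
                    )
        return res

    # ------------------------------------------------------------------
    def plot_tuning(self, results: SessionResults, ax=None):
        """Tuning curve with paw position overlay (QC figure)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = results.tuning
        bins = np.arange(1, t.n_bins + 1)
        ax.plot(bins, t.rates, "r.-", label="IFR (spikes/s)")
        ax.axvline(t.n_stance_bins + 0.5, ls=":", c="k", label="lift")
        ax2 = ax.twinx()
        ax2.plot(bins, t.paw, "b.-", label="paw (AU)")
        ax.set_xlabel("normalized stride bin")
        ax.set_ylabel("spikes/s")
        ax2.set_ylabel("paw position (AU)")
        return ax
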