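"""Slip screening, classification, latency, probabilities, McNemar."""

import numpy as np
import pytest

from stridemod.datatypes import (
    SCREEN_ACCEPTED,
    SCREEN_DISCARDED_PRESTIM,
    SCREEN_UNRESOLVED,
    StimulusTrial,
    Stride,
    StrideSet,
    TrialOutcome,
)
from stridemod.model import LocomotionSession
from stridemod.slips import (
    classify_trial,
    mcnemar,
    rate_match_pairs,
    reference_stride,
    screen_trial,
    slip_probability,
)
from stridemod.synthetic import SessionConfig, SlipSpec, TrialSpec, cbn_config, generate_session


def _regular_strides(n=40, dur=0.25, sf=0.65, start=0.0):
    out = []
    for i in range(n):
        a = start + i * dur
        out.append(
            Stride(
                plant=a, lift=a + sf * dur, next_plant=a + dur,
                amplitude=1.0,
                stance_slope=1.0 / (sf * dur), swing_slope=1.0 / ((1 - sf) * dur),
            )
        )
    return StrideSet(out, 7, 3)


class TestScreen:
    def test_steady_running_accepted(self):
        strides = _regular_strides()
        trial = StimulusTrial(0, "step", onset=5.01)
        assert screen_trial(trial, strides) == SCREEN_ACCEPTED

    def test_prestim_change_discarded(self):
        strides = _regular_strides(n=20)
        doubled = Stride(
            plant=5.0, lift=5.3, next_plant=5.5,
            stance_slope=2.0, swing_slope=5.0,
        )
        sset = StrideSet(list(strides) + [doubled], 7, 3)
        trial = StimulusTrial(0, "step", onset=5.51)
        assert screen_trial(trial, sset) == SCREEN_DISCARDED_PRESTIM

    def test_no_prestim_stride_unresolved(self):
        strides = _regular_strides(start=10.0)
        trial = StimulusTrial(0, "step", onset=5.0)
        assert screen_trial(trial, strides) == SCREEN_UNRESOLVED

    def test_generator_stop_discarded(self):
        # rest epoch spanning the stimulus window, no resumption
        cfg = cbn_config(seed=42, n_strides=60, rest_epochs=[(6.2, 4.0)])
        trials = [TrialSpec(kind="step", rate_effect_hz=-40.0)]
        sess = generate_session(cfg, trials)
        res = LocomotionSession.from_synthetic(sess).fit()
        t = sess.trials[0]
        covered = any(a < t.offset and b > t.onset for a, b in res.rest_epochs)
        if covered:  # rest landed on the stimulus for this geometry
            assert res.outcomes[0].screen in (
                "discarded_stop", SCREEN_UNRESOLVED,
            )


class TestReference:
    def test_latest_prestim_chosen(self):
        strides = _regular_strides(n=30, dur=0.25)
        trial = StimulusTrial(0, "step", onset=5.01)  # stride 19 ends at 5.0
        ref = reference_stride(trial, strides)
        assert ref.next_plant == pytest.approx(5.0)

    def test_grace_rule(self):
        strides = _regular_strides(n=30, dur=0.25)
        # stride ending 20 ms after onset qualifies under 30 ms grace
        trial = StimulusTrial(0, "step", onset=4.98)
        assert reference_stride(trial, strides).next_plant == pytest.approx(5.0)
        # ending 50 ms after onset does not
        trial2 = StimulusTrial(1, "step", onset=4.95)
        assert reference_stride(trial2, strides).next_plant == pytest.approx(4.75)


class TestClassify:
    def _with_modified_stride(self, dur_ratio=1.0, slope_ratio=1.0):
        strides = list(_regular_strides(n=24, dur=0.25))
        # replace the stride starting 0.25 s into the stimulus (onset 5.01)
        k = 21  # plant = 5.25
        s = strides[k]
        new_dur = 0.25 * dur_ratio
        strides[k] = Stride(
            plant=s.plant, lift=s.plant + 0.65 * new_dur, next_plant=s.plant + new_dur,
            stance_slope=s.stance_slope * slope_ratio,
            swing_slope=s.swing_slope * slope_ratio,
        )
        # shift later strides to keep plants increasing
        shift = new_dur - 0.25
        for j in range(k + 1, len(strides)):
            t = strides[j]
            strides[j] = Stride(
                plant=t.plant + shift, lift=t.lift + shift, next_plant=t.next_plant + shift,
                stance_slope=t.stance_slope, swing_slope=t.swing_slope,
            )
        return StrideSet(strides, 7, 3), StimulusTrial(0, "step", onset=5.01)

    def test_identical_strides_non_slip(self):
        sset, trial = self._with_modified_stride()
        out = classify_trial(trial, sset)
        assert out.label == "non_slip" and not out.categories

    def test_prolonged_doubled_duration(self):
        # 250 -> 522 ms, a typical prolonged-stride magnitude
        sset, trial = self._with_modified_stride(dur_ratio=522 / 250)
        out = classify_trial(trial, sset)
        assert out.label == "slip" and "prolonged" in out.categories

    def test_arrested_halved_slope(self):
        # stance slope 5.5 -> 2.7 AU/s
        sset, trial = self._with_modified_stride(slope_ratio=2.7 / 5.5)
        out = classify_trial(trial, sset)
        assert out.label == "slip" and out.categories == {"arrested"}
        assert out.altered  # both stance and swing slopes reduced

    def test_boundary_ratio_inclusive(self):
        sset, trial = self._with_modified_stride(dur_ratio=1.2)
        out = classify_trial(trial, sset)
        assert out.label == "slip" and "prolonged" in out.categories

    def test_just_below_boundary_non_slip(self):
        sset, trial = self._with_modified_stride(dur_ratio=1.19)
        out = classify_trial(trial, sset)
        assert "prolonged" not in out.categories

    def test_incomplete(self):
        sset, trial = self._with_modified_stride(dur_ratio=0.7, slope_ratio=1.0)
        out = classify_trial(trial, sset)
        assert out.label == "slip" and "incomplete" in out.categories


class TestGeneratorRecovery:
    def test_sensitivity_specificity_and_latency(self):
        """Injected slips (m=0.3) recovered with sens/spec >= 0.95; latency
        within +/-25 ms of the injected 120 ms in >= 90% of slips."""
        tp = fn = tn = fp = 0
        lat_ok = lat_n = 0
        cat_ok = cat_n = 0
        cats = ["prolonged", "incomplete", "arrested"]
        for seed in range(25):
            trials = [
                TrialSpec(kind="step", rate_effect_hz=-40.0),
                TrialSpec(kind="step", rate_effect_hz=-40.0, slip=SlipSpec(cats[seed % 3], 0.3)),
                TrialSpec(kind="step", rate_effect_hz=-40.0),
                TrialSpec(kind="step", rate_effect_hz=-40.0, slip=SlipSpec(cats[(seed + 1) % 3], 0.3)),
            ]
            sess = generate_session(cbn_config(seed=seed, n_strides=200), trials)
            res = LocomotionSession.from_synthetic(sess).fit()
            truth = {i["trial_id"]: i["slip"] for i in sess.truth.trial_info}
            for o in res.outcomes:
                if o.label is None:
                    continue
                ts = truth[o.trial_id]
                if ts:
                    if o.is_slip:
                        tp += 1
                        cat_n += 1
                        cat_ok += ts["category"] in o.categories
                        if o.latency_ms is not None:
                            lat_n += 1
                            lat_ok += abs(o.latency_ms - 120.0) <= 25.0
                    else:
                        fn += 1
                else:
                    fp += o.is_slip
                    tn += not o.is_slip
        assert tp / (tp + fn) >= 0.95
        assert tn / (tn + fp) >= 0.95
        assert cat_ok / cat_n >= 0.9
        assert lat_ok / lat_n >= 0.9


class TestSlipProbability:
    def test_exact_fractions(self):
        outcomes = []
        # control: 1 slip / 77 trials; ChR2: 31 / 33
        for i in range(77):
            outcomes.append(
                TrialOutcome(i, label="slip" if i == 0 else "non_slip", condition="control")
            )
        for i in range(33):
            outcomes.append(
                TrialOutcome(100 + i, label="slip" if i < 31 else "non_slip", condition="chr2")
            )
        table = slip_probability(outcomes)
        assert table["conditions"]["control"]["p_slip"] == pytest.approx(1 / 77)
        assert round(100 * table["conditions"]["control"]["p_slip"], 1) == 1.3
        assert round(100 * table["conditions"]["chr2"]["p_slip"], 1) == 93.9
        assert table["fisher_p"] < 0.001
        assert table["chi2_p"] < 0.001

    def test_zero_slips(self):
        outcomes = [TrialOutcome(i, label="non_slip", condition="c") for i in range(10)]
        table = slip_probability(outcomes)
        assert table["conditions"]["c"]["p_slip"] == 0.0


class TestRateMatching:
    def test_pairing_rules(self):
        step = [{"cell": "a", "stim_rate": 71.0, "slip": True}]
        trains = [
            {"cell": "a", "stim_rate": 75.0, "slip": False},  # paired
            {"cell": "a", "stim_rate": 85.0, "slip": False},  # too far
            {"cell": "b", "stim_rate": 72.0, "slip": False},  # other cell
        ]
        pairs = rate_match_pairs(step, trains)
        assert len(pairs) == 1
        assert pairs[0][1]["stim_rate"] == 75.0

    def test_rate_floor(self):
        step = [{"cell": "a", "stim_rate": 8.0, "slip": True}]
        trains = [{"cell": "a", "stim_rate": 9.0, "slip": True}]
        assert rate_match_pairs(step, trains) == []

    def test_trial_reuse(self):
        step = [{"cell": "a", "stim_rate": 70.0}, {"cell": "a", "stim_rate": 72.0}]
        trains = [{"cell": "a", "stim_rate": 71.0}]
        assert len(rate_match_pairs(step, trains)) == 2


class TestMcNemar:
    def test_paired_discordant_counts(self):
        out = mcnemar(b=127, c=31)
        assert out["statistic"] == pytest.approx((127 - 31) ** 2 / 158)
        assert out["statistic"] == pytest.approx(58.33, abs=0.01)
        assert out["p"] < 0.001
        assert out["method"] == "chi2"

    def test_symmetric_is_one(self):
        out = mcnemar(b=5, c=5)
        assert out["p"] == pytest.approx(1.0)

    def test_exact_small_counts(self):
        out = mcnemar(b=10, c=0)
        assert out["method"] == "exact"
        assert out["p"] == pytest.approx(2 * 0.5**10, rel=1e-9)

    def test_exact_equals_binomial_oracle(self):
        from scipy.stats import binom

        for b in range(0, 13):
            for c in range(0, 13):
                n = b + c
                if n == 0 or n >= 25:
                    continue
                out = mcnemar(b=b, c=c)
                k = min(b, c)
                # two-tailed exact binomial, symmetric p=1/2 null
                p_oracle = min(1.0, 2 * binom.cdf(k, n, 0.5) - (binom.pmf(k, n, 0.5) if 2 * k == n else 0.0))
                assert out["p"] == pytest.approx(p_oracle, rel=1e-9)

    def test_matches_statsmodels(self):
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = [[100, 127], [31, 306]]
        ours = mcnemar(b=127, c=31)
        theirs = sm_mcnemar(table, exact=False, correction=False)
        assert ours["statistic"] == pytest.approx(float(theirs.statistic))
        assert ours["p"] == pytest.approx(float(theirs.pvalue))
        small = mcnemar(b=7, c=2)
        theirs_exact = sm_mcnemar([[5, 7], [2, 5]], exact=True)
        assert small["p"] == pytest.approx(float(theirs_exact.pvalue))

    def test_from_pairs(self):
        pairs = [(True, False)] * 4 + [(False, True)] * 1 + [(True, True)] * 5
        out = mcnemar(pairs)
        assert out["b"] == 4 and out["c"] == 1
        assert out["n_pairs"] == 10
        assert out["p_slip_step"] == pytest.approx(0.9)
        assert out["p_slip_train"] == pytest.approx(0.6)
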