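"""Preprocessing contracts: filtering, ocular regression, epoching, rules."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy import signal

import erppls
from erppls.containers import Recording
from erppls.preprocess import (
    InclusionRule,
    _butter_sos,
    filtered_eog_regressors,
    include_subject,
    rejection_report,
)


def sine_recording(freq, rate=500.0, seconds=20.0, amp=1.0):
    t = np.arange(int(seconds * rate)) / rate
    data = amp * np.sin(2 * np.pi * freq * t)[None, :]
    return Recording(data, rate, ("Cz",), ("EEG",))


def eeg_eog_recording(data):
    n_eeg = data.shape[0] - 2
    return Recording(
        data, 500.0,
        tuple(f"E{i}" for i in range(n_eeg)) + ("EOG1", "EOG2"),
        ("EEG",) * n_eeg + ("EOG", "EOG"),
    )


class TestBandpass:
    def test_passband_identity(self):
        rec = erppls.bandpass(sine_recording(10.0), 1.0, 25.0)
        mid = rec.data[0, 2000:8000]
        assert np.abs(mid).max() == pytest.approx(1.0, rel=0.05)

    def test_stopband_attenuation(self):
        rec = erppls.bandpass(sine_recording(50.0), 1.0, 25.0)
        mid = rec.data[0, 2000:8000]
        assert np.abs(mid).max() < 0.1  # >= 90% reduction

    def test_octave_attenuation_20db(self):
        # analytic zero-phase response one octave beyond both edges
        sos = _butter_sos(1.0, 25.0, 500.0, 4)
        _, h = signal.sosfreqz(sos, worN=[0.5, 50.0], fs=500.0)
        assert np.all(np.abs(h) ** 2 < 0.1)  # 20 dB in the two-pass response

    def test_dc_removed(self):
        rec = sine_recording(10.0)
        rec = rec.copy_with(rec.data + 100.0)
        out = erppls.bandpass(rec, 1.0, 25.0)
        assert np.abs(out.data[0, 2000:8000].mean()) < 1.0

    def test_invalid_band_rejected(self):
        rec = sine_recording(10.0)
        for low, high in [(25.0, 1.0), (0.0, 25.0), (1.0, 300.0)]:
            with pytest.raises(ValueError):
                erppls.bandpass(rec, low, high)


class TestEogRegression:
    def test_exact_recovery_of_linear_contamination(self, rng):
        n = 30000
        eog = np.cumsum(rng.standard_normal((2, n)), axis=1)
        probe = eeg_eog_recording(np.vstack([np.zeros((1, n)), eog]))
        f = filtered_eog_regressors(probe)
        clean = rng.standard_normal((3, n))
        design = np.vstack([np.ones(n), f])
        # make the clean part exactly orthogonal to the regressors
        clean -= (clean @ np.linalg.pinv(design)) @ design
        contaminated = clean + 0.3 * f[0] + 0.7 * f[1]
        rec = eeg_eog_recording(np.vstack([contaminated, eog]))
        out = erppls.regress_out_eog(rec)
        assert np.abs(out.data[:3] - clean).max() < 1e-8

    def test_orthogonal_eog_leaves_signal(self, rng):
        n = 20000
        eog = np.cumsum(rng.standard_normal((2, n)), axis=1)
        probe = eeg_eog_recording(np.vstack([np.zeros((1, n)), eog]))
        f = filtered_eog_regressors(probe)
        clean = rng.standard_normal((2, n))
        design = np.vstack([np.ones(n), f])
        clean -= (clean @ np.linalg.pinv(design)) @ design
        rec = eeg_eog_recording(np.vstack([clean, eog]))
        out = erppls.regress_out_eog(rec)
        assert np.allclose(out.data[:2], clean, atol=1e-8)

    def test_residual_uncorrelated_with_regressors(self, rng):
        n = 20000
        data = rng.standard_normal((4, n))
        rec = eeg_eog_recording(data)
        out = erppls.regress_out_eog(rec)
        f = filtered_eog_regressors(rec)
        for i in range(2):
            for j in range(2):
                r = np.corrcoef(out.data[i], f[j])[0, 1]
                assert abs(r) < 1e-10

    def test_never_increases_variance(self, rng):
        data = rng.standard_normal((5, 15000))
        rec = eeg_eog_recording(data)
        out = erppls.regress_out_eog(rec)
        assert np.all(out.data[:3].var(axis=1) <= rec.data[:3].var(axis=1) + 1e-12)

    def test_zero_variance_eog_skipped_with_warning(self, rng, caplog):
        data = rng.standard_normal((3, 5000))
        data[1:] = 0.0
        rec = eeg_eog_recording(data)
        with caplog.at_level("WARNING"):
            out = erppls.regress_out_eog(rec)
        assert "zero-variance" in caplog.text
        assert np.allclose(out.data[0], rec.data[0])

    def test_requires_both_roles(self, rng):
        rec = Recording(rng.standard_normal((2, 100)), 500.0, ("a", "b"), ("EEG", "EEG"))
        with pytest.raises(ValueError):
            erppls.regress_out_eog(rec)


class TestDetrend:
    def test_ramp_removed(self):
        ramp = np.arange(10000, dtype=float)[None, :]
        rec = Recording(ramp, 500.0, ("Cz",), ("EEG",))
        assert np.abs(erppls.detrend(rec).data).max() < 1e-6

    def test_constant_removed(self):
        rec = Recording(np.full((1, 5000), 5.0), 500.0, ("Cz",), ("EEG",))
        assert np.abs(erppls.detrend(rec).data).max() < 1e-9

    def test_matches_scipy_polyfit(self, rng):
        data = rng.standard_normal((3, 8000))
        rec = Recording(data, 500.0, ("a", "b", "c"), ("EEG",) * 3)
        ours = erppls.detrend(rec).data
        theirs = signal.detrend(data, axis=1, type="linear")
        assert np.allclose(ours, theirs, atol=1e-9)

    def test_residual_slope_negligible(self, rng):
        data = rng.standard_normal((2, 6000)) + np.linspace(0, 50, 6000)
        rec = Recording(data, 500.0, ("a", "b"), ("EEG",) * 2)
        out = erppls.detrend(rec).data
        t = np.arange(6000)
        slope = np.polyfit(t, out.T, 1)[0]
        assert np.abs(slope).max() < 1e-12


def events_frame(onsets, conditions=None, responses=None):
    n = len(onsets)
    return pd.DataFrame(
        {
            "onset_sample": onsets,
            "condition": conditions or ["congruent"] * n,
            "rt_seconds": [1.5] * n,
            "response": responses or ["correct"] * n,
        }
    )


class TestEpoching:
    def test_impulse_alignment(self):
        data = np.zeros((1, 3000))
        data[0, 1000] = 7.0
        rec = Recording(data, 500.0, ("Cz",), ("EEG",))
        ep = erppls.epoch(rec, events_frame([1000]))
        t0 = int(np.argmin(np.abs(ep.times_ms)))
        assert ep.times_ms[t0] == 0.0
        assert ep.data[0, 0, t0] == 7.0

    def test_shape_contract(self, rng):
        rec = Recording(rng.standard_normal((2, 40000)), 500.0, ("a", "b"), ("EEG",) * 2)
        onsets = 200 + 1200 * np.arange(30)
        ep = erppls.epoch(rec, events_frame(list(onsets)))
        assert ep.data.shape == (30, 2, 500)
        assert ep.n_dropped_edge == 0

    def test_boundary_trial_dropped(self, rng):
        rec = Recording(rng.standard_normal((1, 2000)), 500.0, ("Cz",), ("EEG",))
        ep = erppls.epoch(rec, events_frame([500, 1950]))
        assert ep.n_trials == 1 and ep.n_dropped_edge == 1

    def test_empty_events_give_empty_set(self, rng):
        rec = Recording(rng.standard_normal((1, 2000)), 500.0, ("Cz",), ("EEG",))
        ep = erppls.epoch(rec, events_frame([]))
        assert ep.n_trials == 0


class TestBaseline:
    def test_baseline_mean_zero(self, rng):
        rec = Recording(rng.standard_normal((2, 20000)) + 3.0, 500.0,
                        ("a", "b"), ("EEG",) * 2)
        ep = erppls.epoch(rec, events_frame([500, 2000, 4000]))
        ep = erppls.baseline_correct(ep)
        sel = (ep.times_ms >= -200) & (ep.times_ms < 0)
        assert np.abs(ep.data[:, :, sel].mean(axis=2)).max() < 1e-10

    def test_offset_template_recovered(self):
        data = np.zeros((1, 5000))
        t = erppls.epoch_time_grid()
        template = np.exp(-((t - 400) ** 2) / (2 * 60.0**2))
        data[0, 900:1400] = template + 10.0
        rec = Recording(data, 500.0, ("Cz",), ("EEG",))
        ep = erppls.baseline_correct(erppls.epoch(rec, events_frame([1000])))
        # baseline window holds the constant 10, so exactly it is removed
        assert np.allclose(ep.data[0, 0], template + 10.0 - (10.0 + template[:100].mean()))

    def test_rerun_is_idempotent(self, rng):
        rec = Recording(rng.standard_normal((1, 5000)), 500.0, ("Cz",), ("EEG",))
        ep = erppls.baseline_correct(erppls.epoch(rec, events_frame([1000, 3000])))
        again = erppls.baseline_correct(ep)
        assert np.abs(again.data - ep.data).max() < 1e-10

    def test_baseline_outside_window_rejected(self, rng):
        rec = Recording(rng.standard_normal((1, 5000)), 500.0, ("Cz",), ("EEG",))
        ep = erppls.epoch(rec, events_frame([1000]))
        with pytest.raises(ValueError):
            erppls.baseline_correct(ep, (-500.0, 0.0))


class TestAmplitudeRejection:
    def make_epochs(self, offsets):
        data = np.zeros((len(offsets), 1, 500))
        for i, off in enumerate(offsets):
            data[i] += off
        rec_like = erppls.Epochs(
            data=data, times_ms=erppls.epoch_time_grid(), rate=500.0,
            channels=("Cz",), roles=("EEG",), trial_index=np.arange(len(offsets)),
        )
        return rec_like

    def test_zero_trial_retained(self):
        ep = erppls.reject_amplitude(self.make_epochs([0.0]))
        assert not ep.amplitude_rejected[0]

    def test_constant_200_rejected(self):
        ep = erppls.reject_amplitude(self.make_epochs([200.0]))
        assert ep.amplitude_rejected[0]

    def test_three_constructed_outliers_rejected(self):
        offsets = [0, 5, -10, 200, 20, -180, 0, 151, 30, -40]
        ep = erppls.reject_amplitude(self.make_epochs(offsets))
        assert ep.amplitude_rejected.sum() == 3
        assert list(np.flatnonzero(ep.amplitude_rejected)) == [3, 5, 7]

    def test_boundary_not_rejected(self):
        ep = erppls.reject_amplitude(self.make_epochs([150.0, -150.0]))
        assert not ep.amplitude_rejected.any()

    def test_peak_to_peak_mode(self):
        ep = self.make_epochs([0.0])
        ep.data[0, 0, ::2] = 100.0
        ep.data[0, 0, 1::2] = -100.0
        flagged = erppls.reject_amplitude(ep, limit=150.0, mode="peak_to_peak")
        assert flagged.amplitude_rejected[0]
        kept = erppls.reject_amplitude(ep, limit=150.0, mode="median")
        assert not kept.amplitude_rejected[0]

    def test_eog_channels_ignored(self):
        data = np.zeros((1, 2, 500))
        data[0, 1] = 400.0  # EOG way out of range
        ep = erppls.Epochs(
            data=data, times_ms=erppls.epoch_time_grid(), rate=500.0,
            channels=("Cz", "EOG1"), roles=("EEG", "EOG"), trial_index=np.arange(1),
        )
        assert not erppls.reject_amplitude(ep).amplitude_rejected[0]


class TestResponseSelection:
    def test_counts(self, rng):
        rec = Recording(rng.standard_normal((1, 20000)), 500.0, ("Cz",), ("EEG",))
        responses = ["correct"] * 7 + ["incorrect", "none", "incorrect"]
        ev = events_frame(list(200 + 1200 * np.arange(10)), responses=responses)
        ep = erppls.select_responses(erppls.epoch(rec, ev), ev)
        assert ep.retained.sum() == 7

    def test_missing_column_rejected(self, rng):
        rec = Recording(rng.standard_normal((1, 2000)), 500.0, ("Cz",), ("EEG",))
        ev = events_frame([1000]).drop(columns=["response"])
        ep_ev = events_frame([1000])
        ep = erppls.epoch(rec, ep_ev)
        with pytest.raises(ValueError):
            erppls.select_responses(ep, ev)


class TestInclusion:
    def make_events(self, n_correct, n_bad):
        responses = ["correct"] * n_correct + ["incorrect"] * n_bad
        return events_frame(list(range(len(responses))), responses=responses)

    def test_typical_subject_included(self):
        d = include_subject(self.make_events(82, 19), {"iq": 96})
        assert d.included and d.reasons == []

    def test_boundary_correct_strict(self):
        d = include_subject(self.make_events(20, 5), {"iq": 100})
        assert not d.included and "correct" in d.reasons[0]
        assert include_subject(self.make_events(21, 5), {"iq": 100}).included

    def test_boundary_bad_strict(self):
        d = include_subject(self.make_events(50, 60), {"iq": 100})
        assert not d.included
        assert include_subject(self.make_events(50, 59), {"iq": 100}).included

    def test_low_iq_excluded_with_reason(self):
        d = include_subject(self.make_events(50, 10), {"iq": 69.9})
        assert not d.included and any("IQ" in r for r in d.reasons)

    def test_all_reasons_reported(self):
        d = include_subject(self.make_events(5, 80), {"iq": 60})
        assert len(d.reasons) == 3

    def test_rule_validation(self):
        with pytest.raises(ValueError):
            InclusionRule(min_correct=0)


class TestFullChain:
    def test_rejection_report_partitions_trials(self, tiny_study):
        sub = tiny_study.subjects[0]
        ep = erppls.preprocess_subject(sub.recording, sub.events)
        rep = rejection_report(ep)
        assert (
            rep["rejected_amplitude"] + rep["rejected_response"] + rep["retained"]
            == rep["n_trials"]
        )

    def test_chain_output_shape(self, tiny_study):
        sub = tiny_study.subjects[0]
        ep = erppls.preprocess_subject(sub.recording, sub.events)
        assert ep.data.shape[1:] == (8, 500)
        sel = (ep.times_ms >= -200) & (ep.times_ms < 0)
        assert np.abs(ep.data[:, :, sel].mean(axis=2)).max() < 1e-9

    def test_drop_channels(self, tiny_study):
        sub = tiny_study.subjects[0]
        cfg = replace(erppls.PreprocessConfig(), drop_channels=("F7",))
        ep = erppls.preprocess_subject(sub.recording, sub.events, cfg)
        assert "F7" not in ep.channels and ep.data.shape[1] == 7
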