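"""Preprocessing chain: continuous recording -> clean, selected epochs.

The fixed order of operations is: band-pass filter (1-25 Hz) -> drop listed
bad channels -> ocular-artifact regression (EOG band-passed 1-7 Hz, then
projected out of every EEG channel) -> linear detrend -> epoch to
[-200, 800) ms -> baseline correction over [-200, 0) ms -> median-amplitude
trial rejection at +/-150 uV -> correct-response selection.  Subject-level
inclusion requires more than 20 correct trials, fewer than 60 incorrect or
missed trials, and IQ of at least 70.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from .containers import (
    BASELINE_WINDOW_MS,
    EPOCH_WINDOW_MS,
    Epochs,
    Recording,
    epoch_time_grid,
    validate_events,
)

logger = logging.getLogger(__name__)

DEFAULT_BAND = (1.0, 25.0)
DEFAULT_EOG_BAND = (1.0, 7.0)


@dataclass(frozen=True)
class InclusionRule:
    """Subject-level inclusion thresholds (all strict as documented)."""

    min_correct: int = 20   # included iff correct > min_correct
    max_bad: int = 60       # included iff incorrect + none < max_bad
    min_iq: float = 70.0    # included iff IQ >= min_iq
    amp_limit: float = 150.0

    def __post_init__(self) -> None:
        if min(self.min_correct, self.max_bad) <= 0 or self.min_iq <= 0:
            raise ValueError("inclusion thresholds must be positive")


@dataclass(frozen=True)
class PreprocessConfig:
    band: tuple[float, float] = DEFAULT_BAND
    eog_band: tuple[float, float] = DEFAULT_EOG_BAND
    epoch_window_ms: tuple[float, float] = EPOCH_WINDOW_MS
    baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS
    amp_limit: float = 150.0
    amp_mode: str = "median"  # or "peak_to_peak"
    drop_channels: tuple[str, ...] = ()
    filter_order: int = 4


def _butter_sos(low: float, high: float, rate: float, order: int = 4):
    if not 0.0 < low < high < rate / 2.0:
        raise ValueError(
            f"invalid band ({low}, {high}) Hz for sampling rate {rate} Hz"
        )
    return signal.butter(order, [low, high], btype="bandpass", fs=rate, output="sos")


def _sosfiltfilt(sos: np.ndarray, data: np.ndarray) -> np.ndarray:
    # run the filter in the dtype of the data (single-precision recordings
    # stay single precision end to end)
    return signal.sosfiltfilt(sos.astype(data.dtype, copy=False), data, axis=1)


def bandpass(
    recording: Recording, low: float, high: float, order: int = 4,
    roles: tuple[str, ...] | None = None,
) -> Recording:
    """Zero-phase Butterworth band-pass (applied forward and backward).

    With ``roles`` given, only channels of those roles are filtered (the
    preprocessing chain band-passes the EEG leads; the EOG channels receive
    their own 1-7 Hz filter inside the regression step).
    """
    sos = _butter_sos(low, high, recording.rate, order)
    if roles is None:
        return recording.copy_with(_sosfiltfilt(sos, recording.data))
    out = recording.data.copy()
    idx = [i for i, r in enumerate(recording.roles) if r in roles]
    out[idx] = _sosfiltfilt(sos, recording.data[idx])
    return recording.copy_with(out)


def regress_out_eog(
    recording: Recording,
    eog_band: tuple[float, float] = DEFAULT_EOG_BAND,
    filter_order: int = 4,
) -> Recording:
    """Project the band-passed (1-7 Hz) EOG channels out of every EEG channel.

    A joint least-squares regression on the continuous signals: each EEG
    channel is replaced by its residual after removing the best linear
    combination of all filtered EOG regressors (plus an intercept).  A
    zero-variance EOG channel is skipped with a warning.  The residual is
    exactly uncorrelated with the regressors and never has larger variance
    than the input.
    """
    eeg_idx = recording.role_indices("EEG")
    eog_idx = recording.role_indices("EOG")
    if not eeg_idx or not eog_idx:
        raise ValueError("need at least one EEG and one EOG channel")

    sos = _butter_sos(eog_band[0], eog_band[1], recording.rate, filter_order)
    regressors = _sosfiltfilt(sos, recording.data[eog_idx])

    keep = regressors.std(axis=1) > 0
    if not keep.all():
        skipped = [recording.channels[eog_idx[i]] for i in np.flatnonzero(~keep)]
        logger.warning("zero-variance EOG regressors skipped: %s", skipped)
    regressors = regressors[keep]

    out = recording.data.copy()
    if regressors.shape[0]:
        # least squares via the normal equations: the design is tiny
        # (intercept + <= 2 regressors), so this is exact and fast
        dtype = recording.data.dtype
        design = np.vstack(
            [np.ones(recording.n_samples, dtype=dtype), regressors]
        )
        gram = (design @ design.T).astype(np.float64)
        moment = (design @ recording.data[eeg_idx].T).astype(np.float64)
        coef = np.linalg.solve(gram, moment).astype(dtype)
        out[eeg_idx] = recording.data[eeg_idx] - coef.T @ design
    return recording.copy_with(out)


def filtered_eog_regressors(
    recording: Recording,
    eog_band: tuple[float, float] = DEFAULT_EOG_BAND,
    filter_order: int = 4,
) -> np.ndarray:
    """The (n_eog, n_samples) regressors exactly as the regression sees them."""
    sos = _butter_sos(eog_band[0], eog_band[1], recording.rate, filter_order)
    return signal.sosfiltfilt(sos, recording.data[recording.role_indices("EOG")], axis=1)


def detrend(recording: Recording) -> Recording:
    """Remove the per-channel best-fit line (slope and intercept).

    Closed-form simple linear regression on the (centered) sample index;
    identical to a least-squares line fit per channel.
    """
    n = recording.n_samples
    dtype = recording.data.dtype
    t = (np.arange(n) - (n - 1) / 2.0).astype(dtype)
    denom = float(np.arange(n, dtype=np.float64).var() * n)  # = t @ t, exactly
    mean = recording.data.mean(axis=1, keepdims=True)
    slope = (recording.data @ t) / dtype.type(denom)
    return recording.copy_with(recording.data - mean - slope[:, None] * t)


def epoch(
    recording: Recording,
    events: pd.DataFrame,
    window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
) -> Epochs:
    """Cut one stimulus-locked epoch per event on the half-open window grid.

    Events whose window falls outside the recording are dropped and counted
    (``n_dropped_edge``); an empty event table yields an empty epoch set.
    """
    validate_events(events)
    rate = recording.rate
    times = epoch_time_grid(rate, window_ms)
    pre = int(round(-window_ms[0] / 1000.0 * rate))
    n_time = times.size

    onsets = np.asarray(events["onset_sample"], dtype=int)
    starts = onsets - pre
    ok = (starts >= 0) & (starts + n_time <= recording.n_samples)
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("dropped %d event(s) without full epoch support", n_dropped)

    kept = np.flatnonzero(ok)
    idx = starts[kept][:, None] + np.arange(n_time)[None, :]
    data = recording.data[:, idx].transpose(1, 0, 2).copy()
    return Epochs(
        data=data,
        times_ms=times,
        rate=rate,
        channels=recording.channels,
        roles=recording.roles,
        trial_index=events.index.to_numpy()[kept],
        n_dropped_edge=n_dropped,
    )


def baseline_correct(
    epochs: Epochs, baseline_ms: tuple[float, float] = BASELINE_WINDOW_MS
) -> Epochs:
    """Subtract the mean over the pre-stimulus baseline, per trial and channel."""
    lo, hi = baseline_ms
    t = epochs.times_ms
    if lo < t[0] or hi > t[-1] + (1000.0 / epochs.rate):
        raise ValueError(f"baseline {baseline_ms} outside epoch window")
    sel = (t >= lo) & (t < hi)
    if not sel.any():
        raise ValueError("baseline window contains no samples")
    corrected = epochs.data - epochs.data[:, :, sel].mean(axis=2, keepdims=True)
    return Epochs(
        data=corrected,
        times_ms=epochs.times_ms,
        rate=epochs.rate,
        channels=epochs.channels,
        roles=epochs.roles,
        trial_index=epochs.trial_index,
        amplitude_rejected=epochs.amplitude_rejected.copy(),
        response_rejected=epochs.response_rejected.copy(),
        n_dropped_edge=epochs.n_dropped_edge,
    )


def reject_amplitude(
    epochs: Epochs, limit: float = 150.0, mode: str = "median"
) -> Epochs:
    """Flag trials whose per-channel epoch median exceeds +/- limit uV.

    The signed within-epoch median per EEG channel is compared to the
    limit; EOG channels are ignored (they only serve as regressors).  A
    ``"peak_to_peak"`` mode is available as an alternative criterion.
    """
    eeg = epochs.data[:, [i for i, r in enumerate(epochs.roles) if r == "EEG"], :]
    if mode == "median":
        stat = np.median(eeg, axis=2)
        bad = (np.abs(stat) > limit).any(axis=1)
    elif mode == "peak_to_peak":
        ptp = eeg.max(axis=2) - eeg.min(axis=2)
        bad = (ptp > limit).any(axis=1)
    else:
        raise ValueError(f"unknown rejection mode {mode!r}")
    if bad.any():
        logger.info("amplitude rejection flagged %d trial(s)", int(bad.sum()))
    out = epochs.amplitude_rejected | bad
    return Epochs(
        data=epochs.data,
        times_ms=epochs.times_ms,
        rate=epochs.rate,
        channels=epochs.channels,
        roles=epochs.roles,
        trial_index=epochs.trial_index,
        amplitude_rejected=out,
        response_rejected=epochs.response_rejected.copy(),
        n_dropped_edge=epochs.n_dropped_edge,
    )


def select_responses(epochs: Epochs, events: pd.DataFrame) -> Epochs:
    """Keep only correct-response trials (incorrect and missed are flagged)."""
    if "response" not in events:
        raise ValueError("event table has no 'response' column")
    responses = events.loc[epochs.trial_index, "response"].to_numpy()
    flagged = responses != "correct"
    return Epochs(
        data=epochs.data,
        times_ms=epochs.times_ms,
        rate=epochs.rate,
        channels=epochs.channels,
        roles=epochs.roles,
        trial_index=epochs.trial_index,
        amplitude_rejected=epochs.amplitude_rejected.copy(),
        response_rejected=epochs.response_rejected | flagged,
        n_dropped_edge=epochs.n_dropped_edge,
    )


@dataclass
class InclusionDecision:
    included: bool
    reasons: list[str] = field(default_factory=list)
    n_correct: int = 0
    n_bad: int = 0


def include_subject(
    events: pd.DataFrame,
    metadata: dict,
    rule: InclusionRule = InclusionRule(),
) -> InclusionDecision:
    """Apply the strict subject-inclusion thresholds.

    Included iff correct > ``min_correct`` AND incorrect+none < ``max_bad``
    AND IQ >= ``min_iq``; the decision lists every failed criterion.
    """
    responses = events["response"]
    n_correct = int((responses == "correct").sum())
    n_bad = int((responses != "correct").sum())
    reasons = []
    if not n_correct > rule.min_correct:
        reasons.append(
            f"correct trials {n_correct} not greater than {rule.min_correct}"
        )
    if not n_bad < rule.max_bad:
        reasons.append(
            f"incorrect/no-response trials {n_bad} not fewer than {rule.max_bad}"
        )
    iq = metadata.get("iq")
    if iq is not None and iq < rule.min_iq:
        reasons.append(f"IQ {iq:.1f} below {rule.min_iq:.0f}")
    return InclusionDecision(
        included=not reasons, reasons=reasons, n_correct=n_correct, n_bad=n_bad
    )


def preprocess_subject(
    recording: Recording,
    events: pd.DataFrame,
    config: PreprocessConfig = PreprocessConfig(),
) -> Epochs:
    """Run the full fixed-order chain for one subject."""
    rec = bandpass(recording, *config.band, order=config.filter_order, roles=("EEG",))
    if config.drop_channels:
        rec = rec.drop_channels(list(config.drop_channels))
    rec = regress_out_eog(rec, config.eog_band, config.filter_order)
    rec = detrend(rec)
    ep = epoch(rec, events, config.epoch_window_ms)
    ep = baseline_correct(ep, config.baseline_ms)
    ep = reject_amplitude(ep, config.amp_limit, config.amp_mode)
    ep = select_responses(ep, events)
    return ep


def rejection_report(epochs: Epochs) -> dict[str, int]:
    """Per-subject accounting: every rejected trial in exactly one category."""
    amp = epochs.amplitude_rejected
    resp = epochs.response_rejected & ~amp  # amplitude takes precedence
    return {
        "n_trials": epochs.n_trials,
        "dropped_edge": epochs.n_dropped_edge,
        "rejected_amplitude": int(amp.sum()),
        "rejected_response": int(resp.sum()),
        "retained": int(epochs.retained.sum()),
    }
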