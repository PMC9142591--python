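"""Synthetic ERP studies with known ground truth.

Generates complete studies — two groups of subjects, three task conditions —
as continuous 500 Hz recordings (six EEG + two EOG channels) plus per-trial
event tables, so every downstream stage (filtering, ocular-artifact
regression, epoching, averaging, PLS) can be tested without real data.

The generative model per subject is additive::

    EEG(t)  = ERP template (Gaussian bumps per component, condition-specific
              amplitude, per-channel topography gain, subject gain)
            + 1/f background noise
            + blink process mixed in with frontal-weighted coefficients
    EOG(t)  = blink process + small measurement noise

Blinks are positive raised-cosine pulses of 300 ms, the stereotypical blink
morphology, arriving as a Poisson process.  Behavioral responses are
Bernoulli-correct with log-normal reaction times measured from the end of
the second spoken word.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import fft as sp_fft

from .containers import (
    CONDITIONS,
    EEG_CHANNELS,
    EOG_CHANNELS,
    EPOCH_WINDOW_MS,
    GROUPS,
    SAMPLING_RATE,
    Recording,
    epoch_time_grid,
)

BLINK_DURATION_S = 0.3
#: Relative blink gain of the second EOG lead; keeps the two regressors
#: correlated but not collinear.
EOG2_BLINK_GAIN = 0.8


class InvalidDesignError(ValueError):
    """Raised when a requested stimulus schedule cannot be balanced."""


@dataclass(frozen=True)
class ErpComponent:
    """Gaussian-bump generative template for one ERP component.

    ``center_ms``/``width_ms`` place a Gaussian of SD ``width_ms`` after
    stimulus onset; ``amplitude_uv`` is the signed peak value and
    ``channel_gains`` the scalp topography (one multiplier in [0, 1] per EEG
    channel, ordered as :data:`~erppls.containers.EEG_CHANNELS`).
    """

    name: str
    center_ms: float
    width_ms: float
    amplitude_uv: float
    channel_gains: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.width_ms <= 0:
            raise ValueError("width_ms must be positive")
        if len(self.channel_gains) != len(EEG_CHANNELS):
            raise ValueError(
                f"channel_gains must have {len(EEG_CHANNELS)} entries "
                f"(one per EEG channel)"
            )


@dataclass(frozen=True)
class Schedule:
    """Trial onsets (samples) and the balanced condition sequence."""

    onsets: np.ndarray
    conditions: np.ndarray
    iti_s: float
    rate: float


@dataclass
class GroundTruth:
    """Full generative description of one synthetic study.

    ``amplitudes`` maps (group, condition, component name) to the planted
    peak amplitude in μV; it is the only place group x condition effects
    enter.  Everything else is shared across cells.
    """

    components: tuple[ErpComponent, ...]
    amplitudes: dict[tuple[str, str, str], float]
    noise_sd: float = 10.0
    eog_noise_sd: float = 5.0
    blink_rate: float = 0.15
    blink_amplitude: float = 150.0
    eog_mixing: dict[str, float] = field(
        default_factory=lambda: {
            "F7": 0.10, "Fz": 0.15, "F8": 0.10, "Cz": 0.06, "CP5": 0.04, "Pz": 0.02,
        }
    )
    p_correct: float = 0.8
    rt_lognormal_params: tuple[float, float] = (0.425, 0.30)
    n_trials_per_condition: int = 85
    n_subjects_per_group: tuple[int, int] = (15, 37)
    iti_s: float = 2.5
    subject_gain_sd: float = 0.2
    iq_by_group: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"ASD": (95.7, 21.0), "TD": (109.6, 13.7)}
    )
    rate: float = SAMPLING_RATE
    #: Montage subset to record (defaults to the full six-electrode set);
    #: large simulation studies may restrict it to the analyzed electrodes.
    eeg_channels: tuple[str, ...] = EEG_CHANNELS
    #: Floating dtype of the generated recordings.  Large Monte-Carlo
    #: studies may use "float32"; microvolt-scale signals lose nothing
    #: relevant at single precision.
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_correct <= 1.0:
            raise ValueError("p_correct must lie in [0, 1]")
        if self.n_trials_per_condition <= 0 or any(
            n <= 0 for n in self.n_subjects_per_group
        ):
            raise ValueError("all counts must be positive")
        if not all(math.isfinite(v) for v in self.eog_mixing.values()):
            raise ValueError("eog_mixing coefficients must be finite")
        unknown = set(self.eeg_channels) - set(EEG_CHANNELS)
        if unknown:
            raise ValueError(f"unknown EEG channels: {sorted(unknown)}")

    @property
    def n_trials(self) -> int:
        return self.n_trials_per_condition * len(CONDITIONS)

    def components_for(self, group: str, condition: str) -> tuple[ErpComponent, ...]:
        """Components with amplitudes substituted for the given design cell."""
        out = []
        for comp in self.components:
            amp = self.amplitudes.get((group, condition, comp.name), comp.amplitude_uv)
            out.append(replace(comp, amplitude_uv=amp))
        return tuple(out)


def default_ground_truth() -> GroundTruth:
    """Study conditions mirroring the published cohort and effects.

    15 vs 37 subjects, 85 trials per condition at 80% accuracy, RT mean
    near 1.6 s.  Planted amplitudes reproduce the qualitative findings: the
    TD-like group shows a 2 μV P600 congruency effect (centro-parietal)
    absent in the ASD-like group, and the groups differ on the incongruent
    N400 and on P600 amplitudes.
    """
    n400 = ErpComponent(
        name="N400", center_ms=400.0, width_ms=60.0, amplitude_uv=-2.0,
        #             F7   Fz   F8   Cz   CP5  Pz
        channel_gains=(0.4, 0.6, 0.4, 0.9, 0.9, 0.7),
    )
    p600 = ErpComponent(
        name="P600", center_ms=650.0, width_ms=80.0, amplitude_uv=2.0,
        channel_gains=(0.3, 0.5, 0.3, 0.9, 0.8, 1.0),
    )
    amplitudes = {
        # N400: group difference in the incongruent conditions only.
        ("ASD", "congruent", "N400"): -2.0,
        ("ASD", "incongruent-semantic", "N400"): -2.5,
        ("ASD", "incongruent-pragmatic", "N400"): -2.5,
        ("TD", "congruent", "N400"): -2.0,
        ("TD", "incongruent-semantic", "N400"): -4.0,
        ("TD", "incongruent-pragmatic", "N400"): -4.0,
        # P600: 2 μV congruency effect in the TD-like group only.
        ("ASD", "congruent", "P600"): 3.0,
        ("ASD", "incongruent-semantic", "P600"): 3.0,
        ("ASD", "incongruent-pragmatic", "P600"): 3.0,
        ("TD", "congruent", "P600"): 2.0,
        ("TD", "incongruent-semantic", "P600"): 4.0,
        ("TD", "incongruent-pragmatic", "P600"): 4.0,
    }
    return GroundTruth(components=(n400, p600), amplitudes=amplitudes)


def make_schedule(
    n_trials: int,
    iti_s: float = 2.5,
    seed: int | np.random.Generator = 0,
    rate: float = SAMPLING_RATE,
    response_window_s: float = 1.0,
    start_s: float = 2.0,
) -> Schedule:
    """Balanced randomized condition sequence with evenly spaced onsets.

    Conditions are assigned as evenly as possible (each count within 1 of
    n_trials/3); any remainder trials go to distinct randomly chosen
    conditions.  Onsets must leave room for the epoch plus the response
    window, so ``iti_s`` may not fall below that sum.
    """
    if n_trials < 3:
        raise InvalidDesignError("need at least 3 trials (one per condition)")
    epoch_len_s = (EPOCH_WINDOW_MS[1] - EPOCH_WINDOW_MS[0]) / 1000.0
    if iti_s < epoch_len_s + response_window_s:
        raise InvalidDesignError(
            f"inter-trial interval {iti_s} s is shorter than epoch "
            f"({epoch_len_s} s) plus response window ({response_window_s} s)"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base, rem = divmod(n_trials, len(CONDITIONS))
    counts = np.full(len(CONDITIONS), base)
    if rem:
        counts[rng.choice(len(CONDITIONS), size=rem, replace=False)] += 1
    labels = np.repeat(np.arange(len(CONDITIONS)), counts)
    rng.shuffle(labels)
    onsets = (start_s + iti_s * np.arange(n_trials)) * rate
    return Schedule(
        onsets=np.round(onsets).astype(int),
        conditions=np.array([CONDITIONS[i] for i in labels]),
        iti_s=iti_s,
        rate=rate,
    )


def erp_waveform(
    components: tuple[ErpComponent, ...] | list[ErpComponent],
    time_ms: np.ndarray,
) -> np.ndarray:
    """Per-channel template in μV: sum of Gaussian bumps times channel gains.

    Returns an (n_eeg_channels, n_time) array; a component with zero
    amplitude contributes exactly zero.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    wave = np.zeros((len(EEG_CHANNELS), time_ms.size))
    for comp in components:
        if comp.amplitude_uv == 0.0:
            continue
        bump = comp.amplitude_uv * np.exp(
            -((time_ms - comp.center_ms) ** 2) / (2.0 * comp.width_ms**2)
        )
        wave += np.outer(comp.channel_gains, bump)
    return wave


def pink_noise(
    shape: tuple[int, int],
    sd: float,
    rng: np.random.Generator,
    dtype: str | np.dtype = "float64",
    max_freq: float | None = None,
    normalize: str = "empirical",
) -> np.ndarray:
    """1/f-power background noise, scaled to the requested RMS per channel.

    The shaped spectrum is drawn directly in the frequency domain (a
    Gaussian process with amplitude spectrum 1/sqrt(f) has 1/f power) on an
    FFT-friendly padded length and truncated back.  ``max_freq`` (in cycles
    per sample) optionally band-limits the draw; content above it would be
    discarded by a subsequent band-pass anyway, so Monte-Carlo studies can
    skip generating it.  ``normalize="empirical"`` rescales each channel to
    the realized RMS; ``"expected"`` uses the analytic process RMS instead
    (cheaper, and unbiased across channels).
    """
    n_ch, n_samp = shape
    dtype = np.dtype(dtype)
    if sd == 0.0 or n_samp == 0:
        return np.zeros(shape, dtype=dtype)
    n_fft = sp_fft.next_fast_len(n_samp)
    n_freq = n_fft // 2 + 1
    freqs = np.fft.rfftfreq(n_fft)
    n_draw = n_freq if max_freq is None else int(np.searchsorted(freqs, max_freq))
    gain = np.zeros(n_draw, dtype=dtype)
    gain[1:] = 1.0 / np.sqrt(freqs[1:n_draw])
    spec = np.zeros((n_ch, n_freq), dtype=np.complex64 if dtype == np.float32
                    else np.complex128)
    re = rng.standard_normal((n_ch, n_draw), dtype=dtype)
    im = rng.standard_normal((n_ch, n_draw), dtype=dtype)
    spec[:, :n_draw] = (re + 1j * im) * gain
    noise = sp_fft.irfft(spec, n=n_fft, axis=1)[:, :n_samp]
    if normalize == "expected":
        # Var(x_t) = 4/n^2 * sum_k g_k^2 for a Hermitian spectrum with unit
        # Gaussian real/imaginary parts at each drawn bin
        expected_rms = np.sqrt(4.0 * np.sum(gain.astype(np.float64) ** 2)) / n_fft
        return noise * dtype.type(sd / expected_rms)
    rms = noise.std(axis=1, keepdims=True)
    rms[rms == 0] = 1.0
    return noise * (sd / rms)


def blink_train(
    n_samples: int, rate_hz: float, blink_rate: float, amplitude: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson train of positive raised-cosine blink pulses (300 ms each)."""
    trace = np.zeros(n_samples)
    duration = n_samples / rate_hz
    n_blinks = rng.poisson(blink_rate * duration)
    if n_blinks == 0:
        return trace
    pulse_len = int(round(BLINK_DURATION_S * rate_hz))
    t = np.arange(pulse_len) / rate_hz
    pulse = amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / BLINK_DURATION_S))
    starts = np.sort(rng.integers(0, max(1, n_samples - pulse_len), size=n_blinks))
    for s in starts:
        trace[s : s + pulse_len] += pulse
    return trace


def _draw_behavior(
    n_trials: int, truth: GroundTruth, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Response labels and RTs. Non-correct trials split 3:1 incorrect:none."""
    correct = rng.random(n_trials) < truth.p_correct
    response = np.where(correct, "correct", "incorrect").astype(object)
    miss = (~correct) & (rng.random(n_trials) < 0.25)
    response[miss] = "none"
    mu, sigma = truth.rt_lognormal_params
    rt = rng.lognormal(mean=mu, sigma=sigma, size=n_trials)
    rt[response == "none"] = np.nan
    return response, rt


def generate_subject(
    truth: GroundTruth, group: str, seed: int | np.random.Generator
) -> tuple[Recording, pd.DataFrame]:
    """One subject's continuous recording and event table.

    Deterministic given (truth, group, seed).  The trial-averaged epochs of
    the noise-free recording equal the planted templates exactly.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rate = truth.rate
    schedule = make_schedule(truth.n_trials, truth.iti_s, rng, rate=rate)

    n_samples = int(schedule.onsets[-1] + 0.8 * rate + 2.0 * rate)
    montage = tuple(truth.eeg_channels)
    sub_idx = [EEG_CHANNELS.index(ch) for ch in montage]
    n_eeg, n_eog = len(montage), len(EOG_CHANNELS)

    gain = max(0.2, 1.0 + truth.subject_gain_sd * rng.standard_normal())
    grid = epoch_time_grid(rate)
    pre = int(round(-EPOCH_WINDOW_MS[0] / 1000.0 * rate))
    templates = {
        c: gain * erp_waveform(truth.components_for(group, c), grid)[sub_idx]
        for c in CONDITIONS
    }

    eeg = pink_noise((n_eeg, n_samples), truth.noise_sd, rng, truth.dtype)
    for onset, cond in zip(schedule.onsets, schedule.conditions):
        sl = slice(onset - pre, onset - pre + grid.size)
        eeg[:, sl] += templates[cond]

    blink = blink_train(
        n_samples, rate, truth.blink_rate, truth.blink_amplitude, rng
    ).astype(eeg.dtype, copy=False)
    mixing = np.array(
        [truth.eog_mixing.get(ch, 0.0) for ch in montage], dtype=eeg.dtype
    )
    eeg += mixing[:, None] * blink

    eog = pink_noise((n_eog, n_samples), truth.eog_noise_sd, rng, truth.dtype)
    eog[0] += blink
    eog[1] += EOG2_BLINK_GAIN * blink

    response, rt = _draw_behavior(truth.n_trials, truth, rng)
    events = pd.DataFrame(
        {
            "onset_sample": schedule.onsets,
            "condition": schedule.conditions,
            "rt_seconds": rt,
            "response": response,
        }
    )
    recording = Recording(
        data=np.vstack([eeg, eog]),
        rate=rate,
        channels=montage + EOG_CHANNELS,
        roles=("EEG",) * n_eeg + ("EOG",) * n_eog,
    )
    return recording, events


@dataclass
class SubjectData:
    subject_id: str
    group: str
    iq: float
    recording: Recording
    events: pd.DataFrame


@dataclass
class Study:
    """Bundle of per-subject recordings, events and metadata."""

    subjects: list[SubjectData]
    truth: GroundTruth
    seed: int

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.subjects],
                "group": [s.group for s in self.subjects],
                "iq": [s.iq for s in self.subjects],
            }
        )


def _truncated_normal(
    mean: float, sd: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    return float(np.clip(mean, lo, hi))


def generate_study(truth: GroundTruth, seed: int) -> Study:
    """Full two-group study; deterministic given (truth, seed).

    Subject streams are spawned from one seed sequence, so adding a subject
    never perturbs the noise realizations of the others.
    """
    root = np.random.SeedSequence(seed)
    n_total = sum(truth.n_subjects_per_group)
    streams = root.spawn(n_total)
    subjects: list[SubjectData] = []
    i = 0
    for group, n_sub in zip(GROUPS, truth.n_subjects_per_group):
        for _ in range(n_sub):
            rng = np.random.default_rng(streams[i])
            iq_mean, iq_sd = truth.iq_by_group.get(group, (100.0, 15.0))
            iq = _truncated_normal(iq_mean, iq_sd, 40.0, 160.0, rng)
            recording, events = generate_subject(truth, group, rng)
            subjects.append(
                SubjectData(
                    subject_id=f"sub-{i + 1:02d}",
                    group=group,
                    iq=iq,
                    recording=recording,
                    events=events,
                )
            )
            i += 1
    return Study(subjects=subjects, truth=truth, seed=seed)
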