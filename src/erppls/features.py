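"""Per-subject ERPs, component-window feature vectors, behavioral summary.

ERPs are arithmetic means over retained trials, per condition and channel.
The N400 window is [200, 500) ms and the P600 window [500, 800) ms; at
500 Hz each half-open window holds exactly 150 samples, so concatenating the
two reproduces the ERP over [200, 800) with no shared boundary sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import CONDITIONS, Epochs


@dataclass(frozen=True)
class ComponentWindow:
    """Half-open analysis window [start_ms, end_ms) for one ERP component."""

    name: str
    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if self.end_ms <= self.start_ms:
            raise ValueError("window end must exceed start")

    def n_samples(self, rate: float) -> int:
        return int(round((self.end_ms - self.start_ms) * rate / 1000.0))


N400 = ComponentWindow("N400", 200.0, 500.0)
P600 = ComponentWindow("P600", 500.0, 800.0)
COMPONENTS = (N400, P600)


@dataclass
class SubjectERP:
    """Condition-wise trial-averaged waveforms for one subject.

    ``means[condition]`` is channels x time; conditions with zero retained
    trials are simply absent from the mapping.
    """

    means: dict[str, np.ndarray]
    n_trials_used: dict[str, int]
    times_ms: np.ndarray
    channels: tuple[str, ...]
    rate: float

    def channel_index(self, label: str) -> int:
        try:
            return self.channels.index(label)
        except ValueError:
            raise KeyError(f"unknown channel {label!r}") from None


class AllTrialsRejectedError(RuntimeError):
    """No condition retains a single trial; the subject cannot contribute."""


def average_erp(epochs: Epochs, events: pd.DataFrame) -> SubjectERP:
    """Average the retained epochs per condition and channel.

    Rejected trials never enter the mean.  Conditions with no retained
    trials are reported as absent rather than as zero waveforms; if every
    condition is empty the subject is unusable and an error is raised so the
    inclusion logic can record it.
    """
    conditions = events.loc[epochs.trial_index, "condition"].to_numpy()
    retained = epochs.retained
    means: dict[str, np.ndarray] = {}
    counts: dict[str, int] = {}
    for cond in CONDITIONS:
        sel = retained & (conditions == cond)
        n = int(sel.sum())
        if n == 0:
            continue
        means[cond] = epochs.data[sel].mean(axis=0)
        counts[cond] = n
    if not means:
        raise AllTrialsRejectedError("no retained trials in any condition")
    return SubjectERP(
        means=means,
        n_trials_used=counts,
        times_ms=epochs.times_ms.copy(),
        channels=epochs.channels,
        rate=epochs.rate,
    )


def window_slice(times_ms: np.ndarray, window: ComponentWindow) -> np.ndarray:
    """Boolean mask selecting the half-open [start, end) window samples."""
    return (times_ms >= window.start_ms) & (times_ms < window.end_ms)


def extract_window(
    erp: SubjectERP, window: ComponentWindow, channel: str, condition: str
) -> np.ndarray:
    """Feature vector: the ERP samples of one channel inside the window."""
    if condition not in erp.means:
        raise KeyError(f"no ERP for condition {condition!r}")
    ch = erp.channel_index(channel)
    return erp.means[condition][ch, window_slice(erp.times_ms, window)].copy()


@dataclass
class FeatureMatrix:
    """Subjects-within-cells by features matrix for the PLS analyses.

    Rows are grouped contiguously by design cell in declared cell order;
    ``row_labels`` carries (subject, group, condition) per row so the
    permutation schemes can respect the repeated-measures structure.
    """

    values: np.ndarray
    row_labels: list[tuple[str, str, str]]
    cells: list[tuple[str, str]]
    cell_sizes: list[int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.row_labels) != self.values.shape[0]:
            raise ValueError("one label per row required")
        if sum(self.cell_sizes) != self.values.shape[0]:
            raise ValueError("cell sizes must sum to the row count")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def cell_of_row(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.cells)), self.cell_sizes)

    @property
    def subjects(self) -> list[str]:
        return [s for s, _, _ in self.row_labels]


def build_feature_matrix(
    erps: dict[str, SubjectERP],
    groups: dict[str, str],
    cells: list[tuple[str, str]],
    window: ComponentWindow,
    channel: str,
) -> FeatureMatrix:
    """Stack per-subject window vectors into the declared design cells.

    Each cell is a (group, condition) pair; the subjects of that group that
    have an ERP for that condition contribute one row each, in sorted
    subject order (downstream statistics are invariant to within-cell row
    order).  Every cell must gather at least two subjects.
    """
    rows, labels, sizes = [], [], []
    for group, condition in cells:
        members = sorted(
            s for s, g in groups.items()
            if g == group and s in erps and condition in erps[s].means
        )
        if len(members) < 2:
            raise ValueError(
                f"design cell (group={group!r}, condition={condition!r}) "
                f"has fewer than 2 subjects"
            )
        for s in members:
            rows.append(extract_window(erps[s], window, channel, condition))
            labels.append((s, group, condition))
        sizes.append(len(members))
    return FeatureMatrix(
        values=np.vstack(rows), row_labels=labels,
        cells=list(cells), cell_sizes=sizes,
    )


def behavioral_summary(
    events_by_subject: dict[str, pd.DataFrame], groups: dict[str, str]
) -> pd.DataFrame:
    """Per-group, per-condition trial counts, accuracy and reaction times.

    RT statistics use correct trials only (the task defines RT from the end
    of the second word); a cell with no responded trials reports NaN.
    """
    per_subject = []
    for subject, events in events_by_subject.items():
        for cond, sub in events.groupby("condition", observed=True):
            n_total = len(sub)
            n_correct = int((sub["response"] == "correct").sum())
            rts = sub.loc[sub["response"] == "correct", "rt_seconds"].dropna()
            per_subject.append(
                {
                    "group": groups[subject],
                    "subject": subject,
                    "condition": cond,
                    "n_trials": n_total,
                    "n_correct": n_correct,
                    "percent_correct": 100.0 * n_correct / n_total if n_total else np.nan,
                    "mean_rt": rts.mean() if len(rts) else np.nan,
                }
            )
    df = pd.DataFrame(per_subject)
    out = (
        df.groupby(["group", "condition"], observed=True)
        .agg(
            n_trials_mean=("n_trials", "mean"),
            n_trials_sd=("n_trials", "std"),
            n_correct_mean=("n_correct", "mean"),
            n_correct_sd=("n_correct", "std"),
            percent_correct_mean=("percent_correct", "mean"),
            percent_correct_sd=("percent_correct", "std"),
            rt_mean=("mean_rt", "mean"),
            rt_sd=("mean_rt", "std"),
        )
        .reset_index()
    )
    return out
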