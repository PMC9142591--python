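"""On-disk formats: HDF5 containers, events TSV, plain-text key=value config.

A study bundle on disk is one directory holding ``recordings.h5`` (one group
per subject with a channels x time dataset and channel metadata), one
``<subject>_events.tsv`` per subject with columns onset_sample, condition,
rt_seconds, response, a ``participants.tsv`` metadata table and a
``ground_truth.cfg`` key=value file for test harnesses.  Epoch sets persist
to HDF5 with named dimensions (trial, channel, time) and the window, rate
and rejection masks as attributes/datasets.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import Epochs, Recording, validate_events
from .simulate import GroundTruth, Study, SubjectData


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    validate_events(events)
    cols = ["onset_sample", "condition", "response", "rt_seconds"]
    events[cols].to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t", na_values=["n/a"])
    return validate_events(events)


def _write_recording(grp: h5py.Group, rec: Recording) -> None:
    grp.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
    grp.attrs["rate"] = rec.rate
    grp.attrs["channels"] = list(rec.channels)
    grp.attrs["roles"] = list(rec.roles)


def _read_recording(grp: h5py.Group) -> Recording:
    return Recording(
        data=grp["data"][()],
        rate=float(grp.attrs["rate"]),
        channels=tuple(str(c) for c in grp.attrs["channels"]),
        roles=tuple(str(r) for r in grp.attrs["roles"]),
    )


def write_config(values: dict, path: str | Path) -> Path:
    """Plain-text ``key = value`` config, one entry per line."""
    path = Path(path)
    lines = [f"{k} = {v}" for k, v in values.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_config(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        key, _, value = line.partition("=")
        out[key.strip()] = value.strip()
    return out


def _truth_to_config(truth: GroundTruth) -> dict:
    cfg: dict[str, object] = {
        "noise_sd": truth.noise_sd,
        "eog_noise_sd": truth.eog_noise_sd,
        "blink_rate": truth.blink_rate,
        "blink_amplitude": truth.blink_amplitude,
        "p_correct": truth.p_correct,
        "rt_lognormal_mu": truth.rt_lognormal_params[0],
        "rt_lognormal_sigma": truth.rt_lognormal_params[1],
        "n_trials_per_condition": truth.n_trials_per_condition,
        "n_subjects_per_group": ",".join(map(str, truth.n_subjects_per_group)),
        "iti_s": truth.iti_s,
        "subject_gain_sd": truth.subject_gain_sd,
        "rate": truth.rate,
    }
    for ch, w in truth.eog_mixing.items():
        cfg[f"eog_mixing.{ch}"] = w
    for (group, cond, comp), amp in truth.amplitudes.items():
        cfg[f"amplitude.{group}.{cond}.{comp}"] = amp
    return cfg


def write_study(study: Study, out_dir: str | Path) -> Path:
    """Persist a synthetic study bundle (recordings, events, metadata, truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with h5py.File(out_dir / "recordings.h5", "w") as f:
        f.attrs["seed"] = study.seed
        for sub in study.subjects:
            _write_recording(f.create_group(sub.subject_id), sub.recording)
    for sub in study.subjects:
        write_events_tsv(sub.events, out_dir / f"{sub.subject_id}_events.tsv")
    study.metadata.to_csv(out_dir / "participants.tsv", sep="\t", index=False)
    write_config(_truth_to_config(study.truth), out_dir / "ground_truth.cfg")
    return out_dir


def read_study(in_dir: str | Path, truth: GroundTruth | None = None) -> Study:
    """Load a study bundle written by :func:`write_study`.

    The ground-truth config is carried along for provenance but only the
    recorded data, events and metadata are used downstream.
    """
    in_dir = Path(in_dir)
    meta = pd.read_csv(in_dir / "participants.tsv", sep="\t")
    subjects: list[SubjectData] = []
    with h5py.File(in_dir / "recordings.h5", "r") as f:
        seed = int(f.attrs.get("seed", -1))
        for _, row in meta.iterrows():
            sid = row["subject"]
            subjects.append(
                SubjectData(
                    subject_id=sid,
                    group=row["group"],
                    iq=float(row["iq"]),
                    recording=_read_recording(f[sid]),
                    events=read_events_tsv(in_dir / f"{sid}_events.tsv"),
                )
            )
    if truth is None:
        from .simulate import default_ground_truth

        truth = default_ground_truth()
    return Study(subjects=subjects, truth=truth, seed=seed)


def write_epochs(epochs: Epochs, path: str | Path) -> Path:
    """Persist one subject's epochs with named dims and rejection masks."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        d = f.create_dataset(
            "epochs", data=epochs.data, compression="gzip", compression_opts=1
        )
        d.dims[0].label = "trial"
        d.dims[1].label = "channel"
        d.dims[2].label = "time"
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset("trial_index", data=epochs.trial_index)
        f.create_dataset("amplitude_rejected", data=epochs.amplitude_rejected)
        f.create_dataset("response_rejected", data=epochs.response_rejected)
        f.attrs["rate"] = epochs.rate
        f.attrs["channels"] = list(epochs.channels)
        f.attrs["roles"] = list(epochs.roles)
        f.attrs["window_ms"] = [epochs.times_ms[0], epochs.times_ms[-1]]
        f.attrs["n_dropped_edge"] = epochs.n_dropped_edge
    return path


def read_epochs(path: str | Path) -> Epochs:
    with h5py.File(path, "r") as f:
        return Epochs(
            data=f["epochs"][()],
            times_ms=f["times_ms"][()],
            rate=float(f.attrs["rate"]),
            channels=tuple(str(c) for c in f.attrs["channels"]),
            roles=tuple(str(r) for r in f.attrs["roles"]),
            trial_index=f["trial_index"][()],
            amplitude_rejected=f["amplitude_rejected"][()],
            response_rejected=f["response_rejected"][()],
            n_dropped_edge=int(f.attrs["n_dropped_edge"]),
        )


def write_null_distributions(results: dict[str, np.ndarray], path: str | Path) -> Path:
    """Archive saliences / null distributions per analysis id."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        for key, arr in results.items():
            f.create_dataset(key, data=np.asarray(arr))
    return path
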