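"""Shared fixtures: small synthetic studies, generated once per session."""

from dataclasses import replace

import numpy as np
import pytest

import erppls


@pytest.fixture(scope="session")
def tiny_truth():
    """A small but complete study: 2+3 subjects, 12 trials per condition."""
    return replace(
        erppls.default_ground_truth(),
        n_subjects_per_group=(3, 3),
        n_trials_per_condition=12,
        iti_s=2.0,
    )


@pytest.fixture(scope="session")
def tiny_study(tiny_truth):
    study = erppls.generate_study(tiny_truth, seed=42)
    for s in study.subjects:  # keep the small cohort fully includable
        s.iq = max(s.iq, 75.0)
    return study


@pytest.fixture(scope="session")
def tiny_processed(tiny_study):
    # the small trial count would fail the default >20-correct rule
    rule = erppls.InclusionRule(min_correct=5, max_bad=60)
    return erppls.preprocess_study(tiny_study, rule=rule)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_synthetic_erps(n_per_group: dict[str, int], seed: int = 0):
    """SubjectERP stand-ins with random waveforms, for design-level tests."""
    rng = np.random.default_rng(seed)
    times = erppls.epoch_time_grid()
    erps, groups = {}, {}
    i = 0
    for group, n in n_per_group.items():
        for _ in range(n):
            sid = f"s{i:03d}"
            erps[sid] = erppls.SubjectERP(
                means={c: rng.standard_normal((6, times.size)) for c in erppls.CONDITIONS},
                n_trials_used={c: 40 for c in erppls.CONDITIONS},
                times_ms=times,
                channels=erppls.EEG_CHANNELS,
                rate=500.0,
            )
            groups[sid] = group
            i += 1
    return erps, groups
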