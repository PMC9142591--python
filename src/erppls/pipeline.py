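"""Study orchestration: the two 24-analysis batteries and their report.

* **Condition battery** — mean-centered PLS over the three task conditions,
  separately per group, ERP component and electrode: 2 groups x 2
  components x 6 electrodes = 24 analyses, within-subject permutations.
* **Group battery** — contrast PLS comparing the groups, separately for the
  congruent condition (2 cells, contrast (1, -1)) and the two incongruent
  sub-conditions pooled into a 4-cell design (default contrast the published
  [1, 1, -1, 1]; a sign-symmetric preset is available): 2 condition sets x 2
  components x 6 electrodes = 24 analyses, between-subject permutations.

Per-analysis permutation seeds are spawned from the master seed by analysis
index, so any single analysis can be re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import CONDITIONS, EEG_CHANNELS, GROUPS
from .features import (
    COMPONENTS,
    ComponentWindow,
    SubjectERP,
    average_erp,
    build_feature_matrix,
)
from .pls import (
    BETWEEN_SUBJECT,
    CONTRAST_PRESETS,
    WITHIN_SUBJECT,
    DesignContrast,
    PermutationScheme,
    contrast_pls,
    mean_centered_pls,
)
from .preprocess import (
    InclusionRule,
    PreprocessConfig,
    include_subject,
    preprocess_subject,
    rejection_report,
)
from .simulate import Study

logger = logging.getLogger(__name__)

ALPHA_DEFAULT = 0.05
INCONGRUENT = (CONDITIONS[1], CONDITIONS[2])


@dataclass(frozen=True)
class StudyDesign:
    groups: tuple[str, ...] = GROUPS
    conditions: tuple[str, ...] = CONDITIONS
    electrodes: tuple[str, ...] = EEG_CHANNELS
    components: tuple[ComponentWindow, ...] = COMPONENTS

    def validate(self) -> None:
        missing = set(CONDITIONS) - set(self.conditions)
        if missing:
            raise ValueError(f"design is missing conditions: {sorted(missing)}")
        if len(self.groups) != 2:
            raise ValueError("design needs exactly two groups")


@dataclass(frozen=True)
class AnalysisSpec:
    """One entry of an analysis plan."""

    battery: str                     # "conditions" | "groups"
    kind: str                        # "mean-centered" | "contrast"
    label: str                       # human-readable comparison
    cells: tuple[tuple[str, str], ...]
    electrode: str
    component: ComponentWindow
    permutation_mode: str
    contrast: DesignContrast | None = None


@dataclass
class AnalysisPlan:
    entries: list[AnalysisSpec]

    def __len__(self) -> int:
        return len(self.entries)


def plan_condition_battery(design: StudyDesign = StudyDesign()) -> AnalysisPlan:
    """Mean-centered PLS across the 3 conditions, per group x component x electrode."""
    design.validate()
    entries = []
    for group in design.groups:
        for component in design.components:
            for electrode in design.electrodes:
                entries.append(
                    AnalysisSpec(
                        battery="conditions",
                        kind="mean-centered",
                        label=f"{group} across conditions",
                        cells=tuple((group, c) for c in design.conditions),
                        electrode=electrode,
                        component=component,
                        permutation_mode=WITHIN_SUBJECT,
                    )
                )
    return AnalysisPlan(entries)


def plan_group_battery(
    design: StudyDesign = StudyDesign(),
    incongruent_contrast: str = "group-incongruent-literal",
    congruent_contrast: str = "group-congruent",
) -> AnalysisPlan:
    """Contrast PLS between groups, per condition set x component x electrode.

    Congruent analyses use 2 cells (one per group); incongruent analyses use
    4 cells ordered (ASD-semantic, ASD-pragmatic, TD-semantic, TD-pragmatic).
    """
    design.validate()
    g1, g2 = design.groups
    condition_sets = {
        "congruent": (
            ((g1, "congruent"), (g2, "congruent")),
            DesignContrast(CONTRAST_PRESETS[congruent_contrast]),
        ),
        "incongruent": (
            tuple((g, c) for g in (g1, g2) for c in INCONGRUENT),
            DesignContrast(CONTRAST_PRESETS[incongruent_contrast]),
        ),
    }
    entries = []
    for set_name, (cells, contrast) in condition_sets.items():
        for component in design.components:
            for electrode in design.electrodes:
                entries.append(
                    AnalysisSpec(
                        battery="groups",
                        kind="contrast",
                        label=f"{g1} vs {g2} {set_name}",
                        cells=cells,
                        electrode=electrode,
                        component=component,
                        permutation_mode=BETWEEN_SUBJECT,
                        contrast=contrast,
                    )
                )
    return AnalysisPlan(entries)


@dataclass
class ProcessedStudy:
    """Preprocessed per-subject ERPs plus inclusion accounting."""

    erps: dict[str, SubjectERP]
    groups: dict[str, str]
    events: dict[str, pd.DataFrame]
    excluded: dict[str, list[str]] = field(default_factory=dict)
    rejection: dict[str, dict[str, int]] = field(default_factory=dict)


def preprocess_study(
    study: Study,
    config: PreprocessConfig = PreprocessConfig(),
    rule: InclusionRule = InclusionRule(),
) -> ProcessedStudy:
    """Run the preprocessing chain and inclusion rule over every subject."""
    out = ProcessedStudy(erps={}, groups={}, events={})
    for sub in study.subjects:
        decision = include_subject(sub.events, {"iq": sub.iq}, rule)
        if not decision.included:
            logger.info("excluding %s: %s", sub.subject_id, decision.reasons)
            out.excluded[sub.subject_id] = decision.reasons
            continue
        epochs = preprocess_subject(sub.recording, sub.events, config)
        out.rejection[sub.subject_id] = rejection_report(epochs)
        out.erps[sub.subject_id] = average_erp(epochs, sub.events)
        out.groups[sub.subject_id] = sub.group
        out.events[sub.subject_id] = sub.events
    return out


def analysis_seed(master_seed: int, index: int) -> int:
    """Per-analysis seed: stable counter scheme off the master seed."""
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31)
    )


def run_plan(
    plan: AnalysisPlan,
    processed: ProcessedStudy,
    seed: int,
    n_perm: int = 1000,
) -> pd.DataFrame:
    """Execute every planned analysis; one row (and one p-value) per entry."""
    rows = []
    for i, spec in enumerate(plan.entries):
        fm = build_feature_matrix(
            processed.erps, processed.groups, list(spec.cells),
            spec.component, spec.electrode,
        )
        scheme = PermutationScheme(
            mode=spec.permutation_mode, n_perm=n_perm,
            seed=analysis_seed(seed, i),
        )
        if spec.kind == "mean-centered":
            result = mean_centered_pls(fm, scheme)
        else:
            assert spec.contrast is not None
            result = contrast_pls(fm, spec.contrast, scheme)
        rows.append(
            {
                "battery": spec.battery,
                "analysis": spec.kind,
                "comparison": spec.label,
                "component": spec.component.name,
                "electrode": spec.electrode,
                "n_cells": fm.n_cells,
                "n_rows": fm.values.shape[0],
                "n_subjects": len(set(fm.subjects)),
                "permutation_mode": spec.permutation_mode,
                "n_perm": n_perm,
                "contrast": (
                    "" if spec.contrast is None
                    else " ".join(f"{w:+.3f}" for w in spec.contrast.weights)
                ),
                "statistic": result.observed_statistic,
                "p_value": result.p_value,
            }
        )
    return pd.DataFrame(rows)


def report_table(results: pd.DataFrame, alpha: float = ALPHA_DEFAULT) -> pd.DataFrame:
    """Wide per-electrode p-value table; significant cells marked with '*'.

    Rows are (component, comparison) and columns the six electrodes, the
    layout of the published group-comparison table.
    """
    def fmt(p: float) -> str:
        return f"{p:.3f}*" if p < alpha else f"{p:.3f}"

    wide = results.pivot_table(
        index=["component", "comparison"], columns="electrode",
        values="p_value", aggfunc="first", observed=True,
    )
    electrodes = [e for e in EEG_CHANNELS if e in wide.columns]
    wide = wide[electrodes]
    return wide.map(fmt).reset_index()


def write_report(
    results: pd.DataFrame,
    out_dir: str | Path,
    alpha: float = ALPHA_DEFAULT,
    fdr: bool = False,
    seed: int | None = None,
    config: dict | None = None,
) -> dict[str, Path]:
    """Write the long results TSV, the wide table, and a provenance sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results = results.copy()
    p = results["p_value"].to_numpy()
    if fdr:
        from statsmodels.stats.multitest import multipletests

        results["significant"] = multipletests(p, alpha=alpha, method="fdr_bh")[0]
    else:
        results["significant"] = p < alpha

    long_path = out_dir / "pls_results.tsv"
    results.to_csv(long_path, sep="\t", index=False)
    wide_path = out_dir / "pls_report.tsv"
    report_table(results, alpha).to_csv(wide_path, sep="\t", index=False)

    cfg = dict(config or {})
    cfg_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    sidecar = {
        "alpha": alpha,
        "correction": "benjamini-hochberg" if fdr else "none (per-analysis p-values)",
        "seed": seed,
        "config_hash": cfg_hash,
        "config": cfg,
        "n_analyses": int(len(results)),
    }
    json_path = out_dir / "pls_report.json"
    json_path.write_text(json.dumps(sidecar, indent=2, default=str))
    return {"long": long_path, "wide": wide_path, "sidecar": json_path}


def run_study(
    study: Study,
    seed: int,
    n_perm: int = 1000,
    config: PreprocessConfig = PreprocessConfig(),
    rule: InclusionRule = InclusionRule(),
    design: StudyDesign = StudyDesign(),
    incongruent_contrast: str = "group-incongruent-literal",
) -> tuple[pd.DataFrame, ProcessedStudy]:
    """Preprocess a study and run both batteries (48 analyses total)."""
    processed = preprocess_study(study, config, rule)
    plan = AnalysisPlan(
        plan_condition_battery(design).entries
        + plan_group_battery(design, incongruent_contrast).entries
    )
    results = run_plan(plan, processed, seed=seed, n_perm=n_perm)
    return results, processed
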