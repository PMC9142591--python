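"""Task Partial Least Squares on ERP feature matrices, with permutation tests.

Both variants operate on the k x p matrix of design-cell mean feature
vectors after grand-mean centering per feature (column means across cells
removed):

* **Mean-centered PLS** decomposes the centered cell-mean matrix by SVD.
  The left singular vectors are the data-driven *design saliences* (one
  overall contrast across cells per latent variable), the right singular
  vectors the feature saliences, and the first singular value is the tested
  statistic.
* **Contrast PLS** projects the centered cell means onto an a-priori unit
  contrast; the statistic is the Euclidean norm of the resulting feature
  salience vector.

Significance comes from a permutation test: between-subject exchangeability
shuffles group membership across subjects (each subject keeps its own
condition rows together); within-subject exchangeability shuffles condition
labels within each subject (conditions are repeated measures).  The p-value
uses the add-one correction p = (1 + #{null >= observed}) / (1 + n_perm),
so it is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .features import FeatureMatrix

logger = logging.getLogger(__name__)

BETWEEN_SUBJECT = "between-subject"
WITHIN_SUBJECT = "within-subject"


@dataclass(frozen=True)
class DesignContrast:
    """A-priori contrast across design cells, stored with unit norm."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.size == 0 or not np.any(w):
            raise ValueError("contrast must not be all-zero")
        object.__setattr__(self, "weights", tuple(w / np.linalg.norm(w)))

    @property
    def vector(self) -> np.ndarray:
        return np.asarray(self.weights)


#: The group-battery presets.  The published incongruent contrast is printed
#: as [1 1 -1 1]; the sign-symmetric variant is the plausible intent.
CONTRAST_PRESETS: dict[str, tuple[float, ...]] = {
    "group-congruent": (1.0, -1.0),
    "group-incongruent-literal": (1.0, 1.0, -1.0, 1.0),
    "group-incongruent-symmetric": (1.0, 1.0, -1.0, -1.0),
}


@dataclass(frozen=True)
class PermutationScheme:
    mode: str
    n_perm: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in (BETWEEN_SUBJECT, WITHIN_SUBJECT):
            raise ValueError(f"unknown permutation mode {self.mode!r}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be at least 1")


@dataclass
class PLSResult:
    singular_values: np.ndarray
    design_saliences: np.ndarray   # k x r, columns orthonormal
    feature_saliences: np.ndarray  # p x r
    observed_statistic: float
    null_distribution: np.ndarray
    p_value: float
    scheme: PermutationScheme | None = None
    kind: str = "mean-centered"
    contrast: DesignContrast | None = None
    warnings: list[str] = field(default_factory=list)


def cell_means(fm: FeatureMatrix) -> np.ndarray:
    """k x p matrix whose row j is the mean feature vector of cell j."""
    return _cell_means(fm.values, fm.cell_of_row, fm.n_cells)


def _cell_means(values: np.ndarray, cell_idx: np.ndarray, k: int) -> np.ndarray:
    out = np.empty((k, values.shape[1]))
    for j in range(k):
        rows = values[cell_idx == j]
        if rows.shape[0] == 0:
            raise ValueError(f"design cell {j} is empty")
        out[j] = rows.mean(axis=0)
    return out


def mean_center(M: np.ndarray) -> np.ndarray:
    """Remove the grand mean per feature (column means across cells -> 0)."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 cells to mean-center")
    return M - M.mean(axis=0, keepdims=True)


def _fix_signs(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Flip each LV so the design-salience element of largest |.| is positive."""
    for j in range(U.shape[1]):
        i = int(np.argmax(np.abs(U[:, j])))
        if U[i, j] < 0:
            U[:, j] *= -1.0
            V[:, j] *= -1.0
    return U, V


def _svd_statistic(values: np.ndarray, cell_idx: np.ndarray, k: int) -> float:
    Mc = mean_center(_cell_means(values, cell_idx, k))
    return float(np.linalg.svd(Mc, compute_uv=False)[0])


def _contrast_statistic_fn(c: np.ndarray) -> Callable[[np.ndarray, np.ndarray, int], float]:
    def stat(values: np.ndarray, cell_idx: np.ndarray, k: int) -> float:
        Mc = mean_center(_cell_means(values, cell_idx, k))
        return float(np.linalg.norm(Mc.T @ c))

    return stat


class _PermutationEngine:
    """Relabels rows under the declared exchangeability and recomputes cells.

    Between-subject mode permutes the subjects' group labels (all rows of a
    subject move together, keeping their conditions); within-subject mode
    permutes the condition labels among each subject's rows.  Either way the
    permuted rows are re-binned into the original design cells.
    """

    def __init__(self, fm: FeatureMatrix, mode: str):
        self.values = fm.values
        self.k = fm.n_cells
        self.mode = mode
        cell_lookup = {cell: j for j, cell in enumerate(fm.cells)}
        groups = np.array([g for _, g, _ in fm.row_labels])
        conds = np.array([c for _, _, c in fm.row_labels])
        subjects = np.array([s for s, _, _ in fm.row_labels])
        uniq, row_subj = np.unique(subjects, return_inverse=True)
        self.row_subject = row_subj
        self.subject_group = np.array(
            [groups[row_subj == i][0] for i in range(uniq.size)]
        )
        # rows of each subject, for within-subject condition shuffles
        self.rows_by_subject = [
            np.flatnonzero(row_subj == i) for i in range(uniq.size)
        ]
        self.row_conds = conds
        self.cell_lookup = cell_lookup
        self.observed_cells = np.array(
            [cell_lookup[(g, c)] for g, c in zip(groups, conds)]
        )

    def permuted_cells(self, rng: np.random.Generator) -> np.ndarray:
        if self.mode == BETWEEN_SUBJECT:
            perm_groups = self.subject_group[rng.permutation(self.subject_group.size)]
            g = perm_groups[self.row_subject]
            return np.array(
                [self.cell_lookup[(gi, ci)] for gi, ci in zip(g, self.row_conds)]
            )
        cells = np.empty(self.values.shape[0], dtype=int)
        for i, rows in enumerate(self.rows_by_subject):
            shuffled = rows[rng.permutation(rows.size)]
            g = self.subject_group[i]
            for r, r_from in zip(rows, shuffled):
                cells[r] = self.cell_lookup[(g, self.row_conds[r_from])]
        return cells


def permutation_test(
    fm: FeatureMatrix,
    statistic_fn: Callable[[np.ndarray, np.ndarray, int], float],
    scheme: PermutationScheme,
) -> tuple[np.ndarray, float]:
    """Null distribution and add-one p-value for the given statistic."""
    engine = _PermutationEngine(fm, scheme.mode)
    observed = statistic_fn(fm.values, engine.observed_cells, engine.k)
    rng = np.random.default_rng(scheme.seed)
    null = np.empty(scheme.n_perm)
    for b in range(scheme.n_perm):
        null[b] = statistic_fn(fm.values, engine.permuted_cells(rng), engine.k)
    p = (1.0 + np.count_nonzero(null >= observed)) / (1.0 + scheme.n_perm)
    return null, float(p)


def mean_centered_pls(fm: FeatureMatrix, scheme: PermutationScheme) -> PLSResult:
    """Data-driven task PLS: SVD of the centered cell-mean matrix.

    The tested statistic is the first singular value; the corresponding
    design salience is the data-driven overall contrast across cells.
    """
    Mc = mean_center(cell_means(fm))
    warnings: list[str] = []
    if np.allclose(Mc, 0.0):
        logger.warning("degenerate all-zero centered cell means; p set to 1")
        warnings.append("degenerate all-zero centered cell-mean matrix")
        k, p = Mc.shape
        return PLSResult(
            singular_values=np.zeros(min(k, p)),
            design_saliences=np.eye(k, min(k, p)),
            feature_saliences=np.zeros((p, min(k, p))),
            observed_statistic=0.0,
            null_distribution=np.zeros(scheme.n_perm),
            p_value=1.0,
            scheme=scheme,
            kind="mean-centered",
            warnings=warnings,
        )
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    U, V = _fix_signs(U, Vt.T)
    null, p = permutation_test(fm, _svd_statistic, scheme)
    return PLSResult(
        singular_values=s,
        design_saliences=U,
        feature_saliences=V,
        observed_statistic=float(s[0]),
        null_distribution=null,
        p_value=p,
        scheme=scheme,
        kind="mean-centered",
    )


def contrast_pls(
    fm: FeatureMatrix, contrast: DesignContrast, scheme: PermutationScheme
) -> PLSResult:
    """A-priori contrast PLS: project centered cell means onto the contrast."""
    c = contrast.vector
    if c.size != fm.n_cells:
        raise ValueError(
            f"contrast has {c.size} weights but the design has {fm.n_cells} cells"
        )
    Mc = mean_center(cell_means(fm))
    salience = Mc.T @ c
    observed = float(np.linalg.norm(salience))
    null, p = permutation_test(fm, _contrast_statistic_fn(c), scheme)
    return PLSResult(
        singular_values=np.array([observed]),
        design_saliences=c[:, None],
        feature_saliences=salience[:, None],
        observed_statistic=observed,
        null_distribution=null,
        p_value=p,
        scheme=scheme,
        kind="contrast",
        contrast=contrast,
    )
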