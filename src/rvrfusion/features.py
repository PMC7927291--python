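"""In-fold feature engineering: z-normalisation and mass-univariate selection.

All statistics here are computed from training rows only and then *applied*
to held-out rows — the no-leakage contract the cross-validation pipeline
depends on.  Selection is strictly mass-univariate: per-voxel Pearson
correlation with the score, with either a Bonferroni threshold
(p < alpha / n_features, the default) or a relaxed threshold with a
guaranteed minimum feature count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ModalityFeatures",
    "NormalizationStats",
    "SelectionResult",
    "zscore_fit",
    "zscore_apply",
    "correlation_screen",
    "select_features",
]


@dataclass
class ModalityFeatures:
    """One modality's subjects x voxels matrix with its voxel identifiers.

    ``voxel_index`` carries the original voxel ids/coordinates so a selected
    submatrix can always be traced back to voxel space.
    """

    modality_tag: str
    matrix: np.ndarray
    voxel_index: np.ndarray

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.voxel_index = np.asarray(self.voxel_index)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.voxel_index):
            raise ValueError(
                f"matrix has {self.matrix.shape[1] if self.matrix.ndim == 2 else '?'}"
                f" columns but voxel_index lists {len(self.voxel_index)}"
            )

    @classmethod
    def from_matrix(cls, modality_tag: str, matrix) -> "ModalityFeatures":
        matrix = np.asarray(matrix, dtype=float)
        return cls(modality_tag, matrix, np.arange(matrix.shape[1]))

    def subset(self, indices) -> "ModalityFeatures":
        indices = np.asarray(indices, dtype=int)
        return ModalityFeatures(
            self.modality_tag, self.matrix[:, indices], self.voxel_index[indices]
        )


@dataclass
class NormalizationStats:
    """Per-column mean and sample SD (ddof=1), fit on training rows only."""

    means: np.ndarray
    sds: np.ndarray
    zero_variance: np.ndarray  # boolean flag per column


@dataclass
class SelectionResult:
    selected_indices: np.ndarray
    r_values: np.ndarray
    p_values: np.ndarray
    threshold_used: float
    mode: str

    @property
    def is_empty(self) -> bool:
        return self.selected_indices.size == 0

    @property
    def n_selected(self) -> int:
        return int(self.selected_indices.size)


def zscore_fit(train_matrix) -> NormalizationStats:
    X = np.asarray(train_matrix, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D training matrix")
    if X.shape[0] < 2:
        raise ValueError("z-scoring needs at least 2 training rows")
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    return NormalizationStats(means=means, sds=sds, zero_variance=sds == 0.0)


def zscore_apply(matrix, stats_: NormalizationStats) -> np.ndarray:
    """(x - mean)/sd per column; constant training columns map to 0."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[1] != stats_.means.size:
        raise ValueError(
            f"matrix has shape {X.shape}, stats cover {stats_.means.size} columns"
        )
    safe_sd = np.where(stats_.zero_variance, 1.0, stats_.sds)
    Z = (X - stats_.means) / safe_sd
    Z[:, stats_.zero_variance] = 0.0
    return Z


def correlation_screen(matrix_z, y) -> tuple[np.ndarray, np.ndarray]:
    """Per-column Pearson r with y and two-sided p from the t distribution.

    p is derived from t = r sqrt((n-2)/(1-r^2)) with df = n-2.  Columns with
    zero variance get r = 0, p = 1 so they can never be selected.
    """
    X = np.asarray(matrix_z, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if X.shape[0] != n:
        raise ValueError("row count mismatch between features and scores")
    if n < 4:
        raise ValueError("correlation screening needs n >= 4")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    x_ss = np.einsum("ij,ij->j", Xc, Xc)
    y_ss = float(yc @ yc)
    denom = np.sqrt(x_ss * y_ss)
    degenerate = denom == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(degenerate, 0.0, (Xc.T @ yc) / np.where(degenerate, 1.0, denom))
    r = np.clip(r, -1.0, 1.0)
    one_minus_r2 = np.clip(1.0 - r**2, 1e-300, None)
    t = r * np.sqrt((n - 2) / one_minus_r2)
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(degenerate, 1.0, np.where(np.abs(r) >= 1.0, 0.0, p))
    return r, p


def select_features(
    r_values,
    p_values,
    n_features: int | None = None,
    mode: str = "bonferroni",
    alpha: float = 0.05,
    relaxed_p: float = 1e-3,
    min_features: int = 10,
) -> SelectionResult:
    """Threshold the screening p-values.

    ``bonferroni``: keep p < alpha / n_features (n_features defaults to the
    vector length, i.e. the modality's feature count).  An empty selection is
    returned as such — a signal, not an error; the pipeline decides the
    fallback.

    ``relaxed``: keep p < relaxed_p; if fewer than ``min_features`` pass, take
    the ``min_features`` smallest p-values instead (ties broken by ascending
    voxel index).
    """
    r = np.asarray(r_values, dtype=float)
    p = np.asarray(p_values, dtype=float)
    if r.shape != p.shape:
        raise ValueError("r and p vectors must have the same length")
    if n_features is None:
        n_features = p.size
    if mode == "bonferroni":
        threshold = alpha / n_features
        selected = np.flatnonzero(p < threshold)
    elif mode == "relaxed":
        threshold = relaxed_p
        selected = np.flatnonzero(p < threshold)
        if selected.size < min_features:
            k = min(min_features, p.size)
            # stable argsort: equal p resolves by ascending index
            selected = np.sort(np.argsort(p, kind="stable")[:k])
    else:
        raise ValueError(f"unknown selection mode {mode!r}")
    return SelectionResult(
        selected_indices=selected,
        r_values=r,
        p_values=p,
        threshold_used=threshold,
        mode=mode,
    )
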