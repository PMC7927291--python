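"""End-to-end prediction pipeline: per-fold selection, RVR, fusion, CV, permutation.

Every fold repeats the full in-fold procedure — z-normalisation statistics
from the training rows, correlation screening and feature selection on the
training rows, model fitting, prediction of the held-out rows — so no
information leaks from test subjects into any trained quantity.  Multimodality
predictions are the arithmetic mean of the mono-modality predictions
("bagging fusion"); fusion never touches selection or training.

Significance of the out-of-fold correlation is assessed by permutation:
each permutation shuffles the scores across subjects once and re-runs the
entire pipeline (selection inside folds included).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations as _combinations

import numpy as np

from .features import select_features, correlation_screen, zscore_apply, zscore_fit
from .rvr import (
    dual_to_primal,
    lr_fit,
    lr_predict,
    rvr_fit,
    rvr_predict,
    PrimalWeights,
    SVRAdapter,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CVScheme",
    "FoldResult",
    "CVResult",
    "PermutationResult",
    "all_combinations",
    "run_fold",
    "run_cv",
    "evaluate",
    "permutation_test",
]


@dataclass
class CVScheme:
    """Cross-validation layout: leave-one-out or repeated k-fold."""

    kind: str = "loocv"
    k: int = 5
    repeats: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("loocv", "kfold"):
            raise ValueError("kind must be 'loocv' or 'kfold'")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("kfold requires k >= 2")
        if self.kind == "kfold" and self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    def folds(self, n: int, rng: np.random.Generator | None = None):
        """Yield (train_idx, test_idx) pairs for one pass over n subjects."""
        if self.kind == "loocv":
            for i in range(n):
                yield np.delete(np.arange(n), i), np.array([i])
        else:
            if self.k > n:
                raise ValueError(f"k={self.k} folds but only {n} subjects")
            rng = rng if rng is not None else np.random.default_rng(self.seed)
            order = rng.permutation(n)
            for test in np.array_split(order, self.k):
                if test.size == 0:
                    raise ValueError("fold assignment produced an empty fold")
                yield np.setdiff1d(np.arange(n), test), np.sort(test)


@dataclass
class FoldResult:
    fold_id: int
    test_idx: np.ndarray
    selection: dict          # modality -> SelectionResult
    models: dict             # modality -> fitted model (None on empty selection)
    mono_predictions: dict   # modality -> predictions for test rows
    fused_predictions: dict  # combination tuple -> predictions for test rows
    weights: dict            # modality -> PrimalWeights (full voxel space)


@dataclass
class CVResult:
    """Out-of-fold evaluation of one modality combination."""

    model_id: tuple
    predicted: np.ndarray    # (n,) for loocv, (repeats, n) for kfold
    observed: np.ndarray
    r: float
    mae: float
    n_selected_mean: dict = field(default_factory=dict)
    r_per_repeat: np.ndarray | None = None
    mae_per_repeat: np.ndarray | None = None
    r_sd: float | None = None
    mae_sd: float | None = None


@dataclass
class PermutationResult:
    observed_r: float
    null_r: np.ndarray
    p_value: float           # strict proportion of null > observed
    p_smoothed: float        # (count + 1) / (n_perm + 1)
    seed: int
    combination: tuple


def all_combinations(modalities) -> list[tuple]:
    """All non-empty combinations: monos, pairs, ..., the full set."""
    mods = list(modalities)
    out = []
    for size in range(1, len(mods) + 1):
        out.extend(_combinations(mods, size))
    return out


def _fit_predict(regressor: str | object, X_tr, y_tr, X_te, rvr_kwargs):
    if regressor == "rvr":
        model = rvr_fit(X_tr, y_tr, **rvr_kwargs)
        return model, rvr_predict(model, X_te)
    if regressor == "lr":
        model = lr_fit(X_tr, y_tr)
        return model, lr_predict(model, X_te)
    if regressor == "svr" or isinstance(regressor, SVRAdapter):
        adapter = regressor if isinstance(regressor, SVRAdapter) else SVRAdapter()
        model = adapter.fit(X_tr, y_tr)
        return model, lr_predict(model, X_te)
    raise ValueError(f"unknown regressor {regressor!r}")


def _fold_weights(regressor, model, sel, n_voxels, modality):
    if model is None:
        return PrimalWeights(w=np.zeros(n_voxels), intercept=0.0, modality_tag=modality)
    if regressor == "rvr":
        return dual_to_primal(
            model,
            selected_indices=sel.selected_indices,
            n_total_voxels=n_voxels,
            modality_tag=modality,
        )
    w_full = np.zeros(n_voxels)
    if getattr(model, "w", None) is not None:
        w_full[sel.selected_indices] = model.w
    return PrimalWeights(w=w_full, intercept=getattr(model, "intercept", 0.0),
                         modality_tag=modality)


def run_fold(
    features: dict,
    scores: np.ndarray,
    train_idx,
    test_idx,
    modalities=None,
    combinations=None,
    regressor="rvr",
    selection_kwargs: dict | None = None,
    rvr_kwargs: dict | None = None,
    fold_id: int = 0,
    compute_weights: bool = True,
) -> FoldResult:
    """One cross-validation fold of the full per-modality procedure.

    For each modality: fit z-statistics on the training rows, apply to both
    partitions, screen and select features on the training rows, fit the
    regressor, predict the test rows.  A modality whose selection comes back
    empty predicts the training mean for this fold (logged).  Fused
    predictions are arithmetic means of the requested mono predictions.
    """
    train_idx = np.asarray(train_idx, dtype=int)
    test_idx = np.asarray(test_idx, dtype=int)
    if train_idx.size == 0 or test_idx.size == 0:
        raise ValueError("train and test sets must be non-empty")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test sets overlap")

    modalities = list(modalities) if modalities is not None else list(features)
    combinations = (
        [tuple(c) for c in combinations]
        if combinations is not None
        else all_combinations(modalities)
    )
    selection_kwargs = selection_kwargs or {}
    rvr_kwargs = rvr_kwargs or {}
    y_tr = np.asarray(scores, dtype=float)[train_idx]

    selection, models, mono_pred, weights = {}, {}, {}, {}
    for m in modalities:
        X = features[m]
        stats_ = zscore_fit(X[train_idx])
        X_tr = zscore_apply(X[train_idx], stats_)
        X_te = zscore_apply(X[test_idx], stats_)
        r, p = correlation_screen(X_tr, y_tr)
        sel = select_features(r, p, n_features=X.shape[1], **selection_kwargs)
        selection[m] = sel
        if sel.is_empty:
            logger.warning(
                "fold %d, modality %s: no features selected; predicting the "
                "training mean", fold_id, m,
            )
            models[m] = None
            mono_pred[m] = np.full(test_idx.size, float(y_tr.mean()))
        else:
            model, pred = _fit_predict(
                regressor, X_tr[:, sel.selected_indices], y_tr,
                X_te[:, sel.selected_indices], rvr_kwargs,
            )
            models[m] = model
            mono_pred[m] = pred
        if compute_weights:
            weights[m] = _fold_weights(regressor, models[m], sel, X.shape[1], m)

    fused = {
        combo: np.mean([mono_pred[m] for m in combo], axis=0) for combo in combinations
    }
    return FoldResult(
        fold_id=fold_id,
        test_idx=test_idx,
        selection=selection,
        models=models,
        mono_predictions=mono_pred,
        fused_predictions=fused,
        weights=weights,
    )


def evaluate(observed, predicted) -> tuple[float, float]:
    """Pearson r and mean absolute error between observed and predicted."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("observed and predicted lengths differ")
    mae = float(np.mean(np.abs(obs - pred)))
    if obs.size < 3 or np.std(pred) == 0.0 or np.std(obs) == 0.0:
        warnings.warn("correlation undefined (constant vector or n < 3)",
                      RuntimeWarning)
        return float("nan"), mae
    r = float(np.corrcoef(obs, pred)[0, 1])
    return r, mae


def run_cv(
    features: dict,
    scores,
    scheme: CVScheme,
    modalities=None,
    combinations=None,
    regressor="rvr",
    selection_kwargs: dict | None = None,
    rvr_kwargs: dict | None = None,
    compute_weights: bool = False,
    return_fold_weights: bool = False,
):
    """Cross-validated out-of-fold evaluation of every requested combination.

    Returns a list of :class:`CVResult` (and, if ``return_fold_weights``, a
    dict modality -> list of per-fold :class:`PrimalWeights`).  For repeated
    k-fold, ``predicted`` is (repeats, n) and per-repeat r/MAE plus their
    mean and SD are reported.
    """
    scores = np.asarray(scores, dtype=float)
    n = scores.size
    modalities = list(modalities) if modalities is not None else list(features)
    combinations = (
        [tuple(c) for c in combinations]
        if combinations is not None
        else all_combinations(modalities)
    )
    needed = sorted({m for c in combinations for m in c}, key=modalities.index)

    repeats = scheme.repeats if scheme.kind == "kfold" else 1
    rng = np.random.default_rng(scheme.seed)
    predicted = {c: np.full((repeats, n), np.nan) for c in combinations}
    n_sel_acc = {m: [] for m in needed}
    fold_weights = {m: [] for m in needed} if (compute_weights or return_fold_weights) else None

    fold_id = 0
    for rep in range(repeats):
        for train_idx, test_idx in scheme.folds(n, rng):
            fr = run_fold(
                features, scores, train_idx, test_idx,
                modalities=needed, combinations=combinations,
                regressor=regressor, selection_kwargs=selection_kwargs,
                rvr_kwargs=rvr_kwargs, fold_id=fold_id,
                compute_weights=fold_weights is not None,
            )
            for c in combinations:
                predicted[c][rep, test_idx] = fr.fused_predictions[c]
            for m in needed:
                n_sel_acc[m].append(fr.selection[m].n_selected)
                if fold_weights is not None:
                    fold_weights[m].append(fr.weights[m])
            fold_id += 1

    results = []
    for c in combinations:
        P = predicted[c]
        assert not np.isnan(P).any(), "some subject was never predicted"
        r_rep = np.empty(repeats)
        mae_rep = np.empty(repeats)
        for rep in range(repeats):
            r_rep[rep], mae_rep[rep] = evaluate(scores, P[rep])
        res = CVResult(
            model_id=c,
            predicted=P[0] if repeats == 1 else P,
            observed=scores,
            r=float(np.mean(r_rep)),
            mae=float(np.mean(mae_rep)),
            n_selected_mean={m: float(np.mean(n_sel_acc[m])) for m in c},
        )
        if repeats > 1:
            res.r_per_repeat = r_rep
            res.mae_per_repeat = mae_rep
            res.r_sd = float(np.std(r_rep, ddof=1))
            res.mae_sd = float(np.std(mae_rep, ddof=1))
        results.append(res)

    if return_fold_weights:
        return results, fold_weights
    return results


def permutation_test(
    features: dict,
    scores,
    scheme: CVScheme,
    combination,
    n_perm: int = 1000,
    seed: int = 0,
    regressor="rvr",
    selection_kwargs: dict | None = None,
    rvr_kwargs: dict | None = None,
) -> PermutationResult:
    """Permutation significance of the out-of-fold correlation.

    Each permutation shuffles the scores over subjects once and re-runs the
    full pipeline for the requested combination.  The p-value is the strict
    proportion of null correlations exceeding the observed one; the smoothed
    (count + 1)/(n_perm + 1) estimator is co-reported.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    combination = tuple(combination)
    scores = np.asarray(scores, dtype=float)

    def _r(y):
        (res,) = run_cv(
            features, y, scheme, modalities=list(combination),
            combinations=[combination], regressor=regressor,
            selection_kwargs=selection_kwargs, rvr_kwargs=rvr_kwargs,
        )
        return res.r

    observed = _r(scores)
    rng = np.random.default_rng(seed)
    null_r = np.empty(n_perm)
    for b in range(n_perm):
        null_r[b] = _r(rng.permutation(scores))
    exceed = int(np.sum(null_r > observed))
    return PermutationResult(
        observed_r=observed,
        null_r=null_r,
        p_value=exceed / n_perm,
        p_smoothed=(exceed + 1) / (n_perm + 1),
        seed=seed,
        combination=combination,
    )
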