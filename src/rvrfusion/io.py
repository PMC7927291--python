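"""Readers, writers, and run configuration.

Formats: TSV for scores, feature matrices, weights and predictions (pandas),
NIfTI-1 for maps/masks/4-D stacks (nibabel; subjects along the 4th axis),
YAML for configs, JSON for result summaries.  All tabular formats carry
explicit subject ids and alignment is always by id, never by row order.
Round trips are lossless at float64.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .pipeline import CVResult, PermutationResult
from .rvr import RVRModel
from .steiger import SteigerResult
from .synthetic import MultimodalDataset, SyntheticConfig
from .atlas import WeightMap

__all__ = [
    "RunConfig",
    "read_scores",
    "write_scores",
    "read_features_tsv",
    "write_features_tsv",
    "read_features_nifti",
    "write_features_nifti",
    "align_subjects",
    "write_dataset",
    "read_dataset",
    "load_config",
    "save_config",
    "save_rvr_model",
    "load_rvr_model",
    "write_cv_result",
    "write_permutation_result",
    "write_steiger_result",
    "write_weight_map",
]


@dataclasses.dataclass
class RunConfig:
    """One pipeline run, fully specified: data source, CV, selection, model.

    ``data_dir`` points at a written dataset (TSV/NIfTI as produced by
    :func:`write_dataset`); alternatively ``synthetic`` holds a
    :class:`~rvrfusion.synthetic.SyntheticConfig`-style mapping.  All seeds
    are explicit — there is no hidden entropy.
    """

    modalities: list
    data_dir: str | None = None
    synthetic: dict | None = None
    cv_kind: str = "loocv"
    cv_k: int = 5
    cv_repeats: int = 100
    selection_mode: str = "bonferroni"
    alpha: float = 0.05
    relaxed_p: float = 1e-3
    min_features: int = 10
    regressor: str = "rvr"
    n_perm: int = 1000
    seed: int = 0
    output_dir: str = "results"

    def __post_init__(self):
        if (self.data_dir is None) == (self.synthetic is None):
            raise ValueError("exactly one of data_dir or synthetic must be set")
        if self.cv_kind not in ("loocv", "kfold"):
            raise ValueError("cv_kind must be 'loocv' or 'kfold'")
        if self.selection_mode not in ("bonferroni", "relaxed"):
            raise ValueError("selection_mode must be 'bonferroni' or 'relaxed'")
        if self.regressor not in ("rvr", "lr", "svr"):
            raise ValueError("regressor must be one of 'rvr', 'lr', 'svr'")
        if not self.modalities:
            raise ValueError("modalities must be non-empty")


def read_scores(path) -> pd.Series:
    """Two-column TSV (subject_id, score) -> Series indexed by subject id."""
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip"
    )
    if "subject_id" not in df.columns or "score" not in df.columns:
        raise ValueError("scores TSV must have columns 'subject_id' and 'score'")
    if df["subject_id"].duplicated().any():
        dupes = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject ids in scores file: {dupes}")
    return df.set_index("subject_id")["score"].astype(float)


def write_scores(scores: pd.Series | dict, path) -> None:
    s = pd.Series(scores, name="score")
    s.rename_axis("subject_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_features_tsv(path) -> pd.DataFrame:
    """Subjects x voxels TSV with a leading subject_id column."""
    df = pd.read_csv(
        path, sep="\t", dtype={"subject_id": str}, float_precision="round_trip"
    )
    if "subject_id" not in df.columns:
        raise ValueError("features TSV must have a 'subject_id' column")
    return df.set_index("subject_id").astype(float)


def write_features_tsv(matrix, subject_ids, path, voxel_ids=None) -> None:
    cols = voxel_ids if voxel_ids is not None else [f"v{j}" for j in range(matrix.shape[1])]
    df = pd.DataFrame(np.asarray(matrix, dtype=float), columns=cols)
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, sep="\t", index=False)


def write_features_nifti(matrix, path, mask=None) -> None:
    """Write a subjects x voxels matrix as one 4-D NIfTI (subjects on axis 4).

    Voxels occupy a flat spatial axis (or the True entries of ``mask``,
    restored in C order).
    """
    X = np.asarray(matrix, dtype=np.float64)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        vol = np.zeros(mask.shape + (X.shape[0],), dtype=np.float64)
        vol[mask, :] = X.T
    else:
        vol = X.T.reshape(X.shape[1], 1, 1, X.shape[0])
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def read_features_nifti(path, mask=None) -> np.ndarray:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if vol.ndim != 4:
        raise ValueError(f"expected a 4-D NIfTI stack, got shape {vol.shape}")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        return vol[mask, :].T
    return vol.reshape(-1, vol.shape[-1]).T


def align_subjects(features: dict, scores: pd.Series) -> tuple[dict, np.ndarray, list]:
    """Intersect-and-order features with scores by subject id; error on mismatch.

    ``features`` maps modality -> DataFrame indexed by subject id.  Every
    subject must appear in the scores and in every modality; offenders are
    listed in the error.
    """
    ids = None
    for m, df in features.items():
        cur = set(df.index)
        ids = cur if ids is None else ids & cur
        missing = cur - set(scores.index)
        if missing:
            raise ValueError(
                f"subjects in modality {m!r} missing from scores: {sorted(missing)}"
            )
    missing = set(scores.index) - ids
    if missing:
        raise ValueError(
            f"subjects in scores missing from features: {sorted(missing)}"
        )
    order = sorted(ids)
    mats = {m: df.loc[order].to_numpy(dtype=float) for m, df in features.items()}
    return mats, scores.loc[order].to_numpy(dtype=float), order


def write_dataset(dataset: MultimodalDataset, out_dir, fmt: str = "tsv") -> dict:
    """Write a dataset's matrices and scores; returns the written paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    write_scores(pd.Series(dataset.scores, index=dataset.subject_ids), out / "scores.tsv")
    paths["scores"] = out / "scores.tsv"
    for m, X in dataset.features.items():
        if fmt == "tsv":
            p = out / f"features_{m}.tsv"
            write_features_tsv(X, dataset.subject_ids, p)
        elif fmt == "nifti":
            p = out / f"features_{m}.nii.gz"
            write_features_nifti(X, p)
        else:
            raise ValueError(f"unknown format {fmt!r}")
        paths[m] = p
    return paths


def read_dataset(in_dir, modalities, fmt: str = "tsv") -> MultimodalDataset:
    in_dir = Path(in_dir)
    scores = read_scores(in_dir / "scores.tsv")
    if fmt == "tsv":
        frames = {m: read_features_tsv(in_dir / f"features_{m}.tsv") for m in modalities}
        mats, y, order = align_subjects(frames, scores)
    elif fmt == "nifti":
        order = list(scores.index)
        mats = {
            m: read_features_nifti(in_dir / f"features_{m}.nii.gz") for m in modalities
        }
        y = scores.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return MultimodalDataset(subject_ids=order, features=mats, scores=y)


def save_config(config, path) -> None:
    d = dataclasses.asdict(config) if dataclasses.is_dataclass(config) else dict(config)
    d = {k: (list(v) if isinstance(v, tuple) else v) for k, v in d.items()}
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path, cls=SyntheticConfig):
    d = yaml.safe_load(Path(path).read_text())
    if "score_range" in d and isinstance(d["score_range"], list):
        d["score_range"] = tuple(d["score_range"])
    return cls(**d)


def save_rvr_model(model: RVRModel, path) -> None:
    """Serialise a fitted model to JSON (arrays as lists, float64-lossless).

    The kernel-mode training reference rows are stored in full so prediction
    works after reload.
    """
    d = {
        "basis": model.basis,
        "alpha": model.alpha.tolist(),
        "mu": model.mu.tolist(),
        "sigma_posterior": model.sigma_posterior.tolist(),
        "noise_var": model.noise_var,
        "active_set": model.active_set.tolist(),
        "n_basis_initial": model.n_basis_initial,
        "y_mean": model.y_mean,
        "train_reference": (
            None if model.train_reference is None else model.train_reference.tolist()
        ),
        "converged": model.converged,
        "n_iter": model.n_iter,
        "n_features": model.n_features,
    }
    Path(path).write_text(json.dumps(d))


def load_rvr_model(path) -> RVRModel:
    d = json.loads(Path(path).read_text())
    return RVRModel(
        basis=d["basis"],
        alpha=np.asarray(d["alpha"], dtype=float),
        mu=np.asarray(d["mu"], dtype=float),
        sigma_posterior=np.atleast_2d(np.asarray(d["sigma_posterior"], dtype=float)),
        noise_var=d["noise_var"],
        active_set=np.asarray(d["active_set"], dtype=int),
        n_basis_initial=d["n_basis_initial"],
        y_mean=d["y_mean"],
        train_reference=(
            None
            if d["train_reference"] is None
            else np.asarray(d["train_reference"], dtype=float)
        ),
        converged=d["converged"],
        n_iter=d["n_iter"],
        n_features=d["n_features"],
    )


def write_cv_result(result: CVResult, subject_ids, out_prefix) -> None:
    """Per-subject out-of-fold predictions (TSV) + a JSON summary."""
    out_prefix = Path(out_prefix)
    pred = np.atleast_2d(result.predicted)
    df = pd.DataFrame(
        {"subject_id": subject_ids, "observed": result.observed,
         "predicted": pred.mean(axis=0)}
    )
    df.to_csv(out_prefix.with_suffix(".predictions.tsv"), sep="\t", index=False)
    summary = {
        "model_id": list(result.model_id),
        "r": result.r,
        "mae": result.mae,
        "n_selected_mean": result.n_selected_mean,
        "r_sd": result.r_sd,
        "mae_sd": result.mae_sd,
    }
    out_prefix.with_suffix(".summary.json").write_text(json.dumps(summary, indent=2))


def write_permutation_result(result: PermutationResult, path) -> None:
    Path(path).write_text(json.dumps({
        "observed_r": result.observed_r,
        "p_value": result.p_value,
        "p_smoothed": result.p_smoothed,
        "n_perm": int(result.null_r.size),
        "combination": list(result.combination),
        "seed": result.seed,
    }, indent=2))


def write_steiger_result(result: SteigerResult, path) -> None:
    Path(path).write_text(json.dumps({
        "t2": result.t2, "df": result.df,
        "p_one_sided": result.p_one_sided, "p_abs": result.p_abs,
    }, indent=2))


def write_weight_map(weight_map: WeightMap, path, mask=None) -> None:
    """Voxel weights as TSV (voxel_id, weight) or 3-D NIfTI by extension."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        w = weight_map.voxel_weights
        if mask is not None:
            mask = np.asarray(mask, dtype=bool)
            vol = np.zeros(mask.shape, dtype=np.float64)
            vol[mask] = w
        else:
            vol = w.reshape(-1, 1, 1)
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
    else:
        pd.DataFrame({
            "voxel_id": np.arange(weight_map.voxel_weights.size),
            "weight": weight_map.voxel_weights,
        }).to_csv(path, sep="\t", index=False)
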