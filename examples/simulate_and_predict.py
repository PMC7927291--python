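"""Generate a synthetic multimodal dataset and evaluate all seven models.

Three modalities with planted voxel clusters drive a behavioural score
(0-4 scale, half the variance explained by the planted signal).  Every
combination of modalities is cross-validated: per fold, features are
z-scored on the training rows, screened by Bonferroni-corrected correlation,
fed to relevance vector regression, and multimodality predictions are the
mean of the mono-modality ones.
"""

import logging

import rvrfusion as rf

logging.disable(logging.WARNING)

config = rf.SyntheticConfig(
    n_subjects=200,
    voxels_per_modality={"alff": 800, "gmv": 800, "fa": 800},
    n_true_voxels={"alff": 10, "gmv": 10, "fa": 10},
    seed=1,
)
dataset = rf.generate_dataset(config)
scheme = rf.CVScheme(kind="kfold", k=5, repeats=1, seed=1)
results = rf.run_cv(dataset.features, dataset.scores, scheme)

print(f"{'model':<18} {'r':>7} {'MAE':>7}  mean features selected")
for res in results:
    tag = "+".join(res.model_id)
    sel = ", ".join(f"{m}:{v:.1f}" for m, v in res.n_selected_mean.items())
    print(f"{tag:<18} {res.r:>7.3f} {res.mae:>7.3f}  {sel}")

print(
    "\nr is the Pearson correlation between observed and out-of-fold "
    "predicted scores;\nMAE is their mean absolute error on the 0-4 scale. "
    "Fused models typically match\nor beat their component models because "
    "averaging cancels modality-specific error."
)
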