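"""Compute ALFF maps from simulated resting-state series with nuisance removal.

Each voxel's series is a slow oscillation (0.03 Hz, inside the 0.01-0.1 Hz
band) plus white noise; motion traces are random walks.  The nuisance design
(intercept, trend, Friston-24 motion expansion, tissue signals, FD spike
regressors) is regressed out before the band amplitude is measured.
"""

import numpy as np

import rvrfusion as rf

ts = rf.generate_timeseries(
    n_subjects=3, timepoints=200, voxels=50, tr_seconds=2.0,
    band_components=[(0.03, 1.0)], seed=0, noise_sd=0.3,
)

for subject, (series, motion) in enumerate(zip(ts.series, ts.motion)):
    fd = rf.framewise_displacement(motion)
    tissue = {
        "csf": series[:, :5].mean(axis=1),
        "wm": series[:, 5:10].mean(axis=1),
        "global": series.mean(axis=1),
    }
    design = rf.build_nuisance_design(
        motion, tissue, include_gsr=True, fd=fd, fd_threshold=0.5
    )
    resid = rf.regress_nuisance(series, design)
    alff = rf.compute_alff(resid, ts.tr_seconds)
    n_spikes = sum(name.startswith("spike") for name in design.column_names)
    print(
        f"subject {subject}: median ALFF {np.median(alff.values):.3f}, "
        f"max FD {fd.max():.3f} mm, {n_spikes} censored frames, "
        f"{design.matrix.shape[1]} nuisance regressors"
    )

print(
    "\nALFF is the mean square-root band power over 0.01-0.1 Hz; the planted "
    "0.03 Hz\noscillation keeps it well above zero even after nuisance "
    "regression."
)
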