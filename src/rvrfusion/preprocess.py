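"""Computational preprocessing: exclusions, nuisance regression, ALFF, masks.

Covers the stages of a resting-state pipeline that are pure numerics (as
opposed to image registration): exclusion bookkeeping, the Friston-24 motion
expansion, framewise displacement and spike regressors, least-squares nuisance
regression with detrending, ALFF band-power computation, and probability-map
thresholding.

Conventions fixed here and relied on throughout:

* FD is the Power-style sum of absolute backward differences of the six
  motion parameters, rotations (radians) scaled by a 50 mm head radius.  This
  differs from Jenkinson's RMS formulation but preserves the threshold
  semantics (frames above 0.5 mm receive spike regressors).
* ALFF uses the amplitude spectrum 2|DFT|/T at non-DC bins, averaged over the
  bins with f_low <= f <= f_high (default 0.01-0.1 Hz).
* The mask threshold is strict: a voxel is kept iff probability > threshold.
* Row 0 of the lagged Friston-24 block is zero-padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import Roster

__all__ = [
    "ExclusionCriteria",
    "ExclusionReport",
    "NuisanceDesign",
    "ALFFMap",
    "apply_exclusions",
    "friston24",
    "framewise_displacement",
    "build_nuisance_design",
    "regress_nuisance",
    "compute_alff",
    "make_mask",
]


@dataclass
class ExclusionCriteria:
    max_translation_mm: float = 2.0
    max_rotation_deg: float = 2.0
    required_volumes: int = 0
    fd_threshold_mm: float = 0.5

    def __post_init__(self):
        for v in (self.max_translation_mm, self.max_rotation_deg, self.fd_threshold_mm):
            if v <= 0:
                raise ValueError("all thresholds must be positive")


@dataclass
class ExclusionReport:
    n_input: int
    counts_per_reason: dict
    n_overlap: int
    included_ids: list
    n_included: int = field(init=False)

    def __post_init__(self):
        self.n_included = len(self.included_ids)


@dataclass
class NuisanceDesign:
    matrix: np.ndarray
    column_names: list


@dataclass
class ALFFMap:
    values: np.ndarray
    band: tuple = (0.01, 0.1)
    tr_seconds: float = 2.0


def apply_exclusions(roster: list[Roster]) -> ExclusionReport:
    """Exclude every subject carrying at least one flag; count the union once."""
    if not roster:
        raise ValueError("roster is empty")
    ids = [r.subject_id for r in roster]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate subject ids: {dupes}")
    counts: dict = {}
    excluded: set = set()
    multi = 0
    for r in roster:
        for flag in r.flags:
            counts[flag] = counts.get(flag, 0) + 1
        if r.flags:
            excluded.add(r.subject_id)
            if len(r.flags) > 1:
                multi += 1
    included = [r.subject_id for r in roster if not r.flags]
    return ExclusionReport(
        n_input=len(roster),
        counts_per_reason=counts,
        n_overlap=multi,
        included_ids=included,
    )


def _check_motion(motion) -> np.ndarray:
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError(f"motion must be (timepoints, 6), got {motion.shape}")
    if not np.isfinite(motion).all():
        raise ValueError("motion parameters contain non-finite values")
    return motion


def friston24(motion) -> np.ndarray:
    """Friston 24-parameter motion expansion.

    Column blocks in order: R, R^2, R_{t-1}, R_{t-1}^2 (six columns each),
    where R_{t-1} is the one-frame lag with a zero first row.
    """
    motion = _check_motion(motion)
    if motion.shape[0] < 2:
        raise ValueError("need at least 2 timepoints")
    lag = np.vstack([np.zeros((1, 6)), motion[:-1]])
    return np.hstack([motion, motion**2, lag, lag**2])


def framewise_displacement(motion, head_radius_mm: float = 50.0) -> np.ndarray:
    """Power-style FD: sum |delta translation| + radius * sum |delta rotation|.

    Rotations are expected in radians.  FD of the first frame is 0.
    """
    motion = _check_motion(motion)
    d = np.abs(np.diff(motion, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius_mm * d[:, 3:].sum(axis=1)
    return np.concatenate([[0.0], fd])


def build_nuisance_design(
    motion,
    tissue_signals: dict,
    include_gsr: bool = True,
    fd: np.ndarray | None = None,
    fd_threshold: float = 0.5,
) -> NuisanceDesign:
    """Assemble the covariate matrix for nuisance regression.

    Columns: intercept, linear trend, the Friston-24 expansion, CSF and WM
    mean signals, the global signal iff ``include_gsr``, and one indicator
    column per frame with FD > ``fd_threshold`` (spike-regression scrubbing —
    censored frames are modelled, not deleted).
    """
    motion = _check_motion(motion)
    T = motion.shape[0]
    cols = [np.ones(T), np.linspace(-1.0, 1.0, T)]
    names = ["intercept", "linear_trend"]
    f24 = friston24(motion)
    cols.extend(f24.T)
    names.extend([f"friston24_{i}" for i in range(24)])
    for key in ("csf", "wm"):
        if key not in tissue_signals:
            raise ValueError(f"tissue_signals must provide {key!r}")
        sig = np.asarray(tissue_signals[key], dtype=float).ravel()
        if sig.size != T:
            raise ValueError(f"{key!r} signal length {sig.size} != {T} timepoints")
        cols.append(sig)
        names.append(key)
    if include_gsr:
        if "global" not in tissue_signals:
            raise ValueError("include_gsr=True requires a 'global' tissue signal")
        g = np.asarray(tissue_signals["global"], dtype=float).ravel()
        if g.size != T:
            raise ValueError("global signal length mismatch")
        cols.append(g)
        names.append("global")
    if fd is not None:
        fd = np.asarray(fd, dtype=float).ravel()
        if fd.size != T:
            raise ValueError("fd length mismatch")
        for t in np.flatnonzero(fd > fd_threshold):
            spike = np.zeros(T)
            spike[t] = 1.0
            cols.append(spike)
            names.append(f"spike_{t}")
    X = np.column_stack(cols)
    # drop exact duplicate columns before the rank check
    _, unique_idx = np.unique(X.T, axis=0, return_index=True)
    rank = np.linalg.matrix_rank(X[:, np.sort(unique_idx)])
    if rank < len(unique_idx):
        raise ValueError(
            f"nuisance design is rank deficient: rank {rank} < "
            f"{len(unique_idx)} unique columns (of {X.shape[1]} total)"
        )
    return NuisanceDesign(matrix=X, column_names=names)


def regress_nuisance(series, design: NuisanceDesign | np.ndarray) -> np.ndarray:
    """Least-squares residuals of each voxel series on the design columns."""
    X = design.matrix if isinstance(design, NuisanceDesign) else np.asarray(design, float)
    S = np.asarray(series, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    if X.shape[0] != S.shape[0]:
        raise ValueError(
            f"design has {X.shape[0]} rows, series has {S.shape[0]} timepoints"
        )
    beta, _, rank, _ = np.linalg.lstsq(X, S, rcond=None)
    if rank < min(X.shape):
        # duplicate columns are tolerated (lstsq picks the min-norm fit);
        # genuine deficiency beyond duplicates was rejected at build time
        n_unique = len(np.unique(X.T, axis=0))
        if rank < n_unique:
            raise ValueError(
                f"singular design: rank {rank} < {n_unique} unique columns"
            )
    return S - X @ beta


def compute_alff(series, tr_seconds: float, band: tuple = (0.01, 0.1)) -> ALFFMap:
    """Amplitude of low-frequency fluctuations per voxel.

    The series is Fourier transformed, the square root of the power spectrum
    (equivalently the amplitude spectrum 2|DFT|/T at non-DC bins) is taken,
    and its mean over the in-band frequency bins is returned.  The band is
    inclusive at both edges and must contain at least two bins.
    """
    S = np.asarray(series, dtype=float)
    if S.ndim == 1:
        S = S[:, None]
    T = S.shape[0]
    f_low, f_high = band
    nyquist = 1.0 / (2.0 * tr_seconds)
    if not 0 <= f_low < f_high:
        raise ValueError("band must satisfy 0 <= f_low < f_high")
    if f_high > nyquist:
        raise ValueError(f"f_high={f_high} exceeds Nyquist ({nyquist:.4f} Hz)")
    freqs = np.fft.rfftfreq(T, d=tr_seconds)
    in_band = (freqs >= f_low) & (freqs <= f_high) & (freqs > 0)
    if in_band.sum() < 2:
        # frequency resolution is 1/(T*tr); need >= 2 bins inside the band
        min_T = int(np.ceil(2.0 / ((f_high - f_low) * tr_seconds))) + 1
        raise ValueError(
            f"band {band} holds {int(in_band.sum())} frequency bins at "
            f"length {T}; at least ~{min_T} timepoints are needed"
        )
    amplitude = 2.0 * np.abs(np.fft.rfft(S, axis=0)) / T
    values = amplitude[in_band].mean(axis=0)
    return ALFFMap(values=values, band=(f_low, f_high), tr_seconds=tr_seconds)


def make_mask(probability_map, threshold: float = 0.2) -> np.ndarray:
    """Binary inclusion mask: voxel kept iff probability > threshold (strict)."""
    p = np.asarray(probability_map, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("probability map values must lie in [0, 1]")
    return p > threshold
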