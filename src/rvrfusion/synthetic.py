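"""Synthetic multimodal datasets with planted, recoverable ground truth.

Real studies of this kind regress a behavioural score (here a working-memory
capacity on a 0-4 scale) on voxel-wise maps from several MRI modalities.  The
generator emulates that setting at desk scale with a forward linear model:

1. a global latent g and per-cluster latents h give each true-weight cluster a
   factor v = sqrt(f) g + sqrt(1-f) h, so distinct modalities share fraction
   ``f`` (= ``shared_signal_fraction``) of their signal variance (the
   functional/structural collinearity seen in real multimodal data);
2. voxels inside a cluster measure v plus i.i.d. noise; all other voxels are
   pure N(0,1) noise;
3. the score is the planted linear combination of the features plus Gaussian
   noise sized to a target signal fraction (``planted_r2``), then mapped
   affinely onto ``score_range``.

Because features are drawn first and scores computed from them, the planted
weight map is the true regression function and parameter recovery is a
well-posed assertion.  Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .atlas import AtlasLabels

__all__ = [
    "SyntheticConfig",
    "PlantedTruth",
    "MultimodalDataset",
    "TimeSeriesSet",
    "Roster",
    "generate_dataset",
    "generate_timeseries",
    "generate_roster",
    "generate_atlas",
]

EXCLUSION_FLAGS = (
    "head_motion",
    "missing_volumes",
    "normalization_failure",
    "dwi_artifact",
)


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults give three 2,000-voxel modalities with two 5-voxel true clusters
    each (within-cluster voxel correlation 0.5), 30% cross-modality signal
    sharing, and score noise sized so the planted linear predictor explains
    half the score variance.
    """

    n_subjects: int = 300
    voxels_per_modality: dict = field(
        default_factory=lambda: {"alff": 2000, "gmv": 2000, "fa": 2000}
    )
    n_true_voxels: dict = field(
        default_factory=lambda: {"alff": 10, "gmv": 10, "fa": 10}
    )
    shared_signal_fraction: float = 0.3
    noise_sd: float | dict = 1.0          # per-voxel residual SD at true voxels
    score_range: tuple = (0.0, 4.0)
    cluster_width: int = 5
    planted_r2: float | None = 0.5        # noise sized for this signal fraction
    score_noise_sd: float = 0.0           # used only when planted_r2 is None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.shared_signal_fraction <= 1.0:
            raise ValueError("shared_signal_fraction must lie in [0, 1]")
        for m, k in self.n_true_voxels.items():
            if k > self.voxels_per_modality[m]:
                raise ValueError(
                    f"modality {m!r}: {k} true voxels exceed "
                    f"{self.voxels_per_modality[m]} voxels"
                )
        for sd in self.noise_sd_map().values():
            if sd < 0:
                raise ValueError("noise_sd must be >= 0")
        if self.cluster_width < 1:
            raise ValueError("cluster_width must be >= 1")
        if self.planted_r2 is not None and not 0.0 < self.planted_r2 <= 1.0:
            raise ValueError("planted_r2 must lie in (0, 1]")

    def noise_sd_map(self) -> dict:
        if isinstance(self.noise_sd, dict):
            return dict(self.noise_sd)
        return {m: float(self.noise_sd) for m in self.voxels_per_modality}

    @property
    def modalities(self) -> list[str]:
        return list(self.voxels_per_modality)


@dataclass
class PlantedTruth:
    """Ground truth of a generated dataset.

    ``weight_maps[m]`` are the generative voxel weights on the *raw* score
    scale; the observed score is ``scale * (sum_m X_m w_m + intercept + eps)
    + offset``.  ``modality_components[m] = X_m w_m`` and ``latent_score`` (the
    noise-free raw predictor) are retained so tests can recompute shared
    variance and signal fractions directly from the truth.
    """

    weight_maps: dict
    intercept: float
    scale: float
    offset: float
    latent_score: np.ndarray
    modality_components: dict
    score_noise_sd: float

    def effective_weights(self, modality: str) -> np.ndarray:
        """Weights on the observed score scale (after the affine map)."""
        return self.scale * self.weight_maps[modality]

    def noise_free_scores(self, features: dict) -> np.ndarray:
        """Observed-scale scores implied by features under the planted model."""
        raw = sum(features[m] @ self.weight_maps[m] for m in self.weight_maps)
        return self.scale * (raw + self.intercept) + self.offset


@dataclass
class MultimodalDataset:
    """Aligned per-modality feature matrices plus behavioural scores."""

    subject_ids: list
    features: dict
    scores: np.ndarray
    truth: PlantedTruth | None = None
    atlas: dict | None = None

    def __post_init__(self):
        n = len(self.subject_ids)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (n,):
            raise ValueError("scores length must equal number of subjects")
        for m, X in self.features.items():
            if X.shape[0] != n:
                raise ValueError(f"modality {m!r} has {X.shape[0]} rows, expected {n}")
            if not np.isfinite(X).all():
                raise ValueError(f"modality {m!r} contains non-finite values")
        if not np.isfinite(self.scores).all():
            raise ValueError("scores contain non-finite values")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def modalities(self) -> list[str]:
        return list(self.features)


@dataclass
class TimeSeriesSet:
    """Per-subject voxel time series with motion traces, for the ALFF stage."""

    series: list                 # each (timepoints, voxels)
    tr_seconds: float
    motion: list                 # each (timepoints, 6)

    def __post_init__(self):
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        for s in self.series:
            if s.shape[0] < 8:
                raise ValueError("time series must have at least 8 timepoints")


@dataclass(frozen=True)
class Roster:
    """One subject's exclusion bookkeeping; flags may overlap."""

    subject_id: str
    flags: frozenset = frozenset()


def _place_clusters(
    n_voxels: int, n_true: int, cluster_width: int, rng: np.random.Generator
) -> list[np.ndarray]:
    """Non-overlapping contiguous index clusters covering n_true voxels."""
    if cluster_width > n_voxels:
        raise ValueError(
            f"cluster_width={cluster_width} exceeds voxel count {n_voxels}"
        )
    sizes = [cluster_width] * (n_true // cluster_width)
    if n_true % cluster_width:
        sizes.append(n_true % cluster_width)
    if sum(sizes) > n_voxels:
        raise ValueError("true voxels do not fit into the voxel space")
    # each cluster lives in its own equal segment of the index range, at a
    # random offset, guaranteeing non-overlap
    n_clusters = len(sizes)
    seg = n_voxels // n_clusters
    clusters = []
    for c, size in enumerate(sizes):
        lo = c * seg
        hi = lo + seg if c < n_clusters - 1 else n_voxels
        start = int(rng.integers(lo, hi - size + 1))
        clusters.append(np.arange(start, start + size))
    return clusters


def generate_dataset(config: SyntheticConfig) -> MultimodalDataset:
    """Draw a multimodal dataset with planted linear signal.

    Deterministic in (config, seed): identical configs give bit-identical
    matrices and scores.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    f = config.shared_signal_fraction
    noise_sd = config.noise_sd_map()

    g = rng.standard_normal(n)  # globally shared latent

    features: dict = {}
    weight_maps: dict = {}
    components: dict = {}
    for m in config.modalities:
        V = config.voxels_per_modality[m]
        X = rng.standard_normal((n, V))
        w = np.zeros(V)
        for cluster in _place_clusters(
            V, config.n_true_voxels[m], config.cluster_width, rng
        ):
            h = rng.standard_normal(n)
            sign = 1.0 if rng.random() < 0.5 else -1.0
            # the shared latent enters sign-aligned with the cluster weight, so
            # cross-modality shared variance is always score-aligned
            v = np.sqrt(f) * sign * g + np.sqrt(1.0 - f) * h
            X[:, cluster] = v[:, None] + noise_sd[m] * rng.standard_normal(
                (n, len(cluster))
            )
            w[cluster] = sign
        features[m] = X
        weight_maps[m] = w
        components[m] = X @ w

    signal = sum(components.values())
    intercept = 0.0
    if config.planted_r2 is not None:
        sig_sd = float(np.std(signal))
        r2 = config.planted_r2
        eps_sd = sig_sd * np.sqrt((1.0 - r2) / r2)
    else:
        eps_sd = config.score_noise_sd
    raw = signal + intercept + eps_sd * rng.standard_normal(n)

    lo, hi = config.score_range
    span = float(np.ptp(raw))
    if span == 0.0:
        scale, offset = 1.0, float((lo + hi) / 2.0 - raw[0])
    else:
        scale = (hi - lo) / span
        offset = lo - scale * float(raw.min())
    scores = scale * raw + offset

    truth = PlantedTruth(
        weight_maps=weight_maps,
        intercept=intercept,
        scale=scale,
        offset=offset,
        latent_score=signal + intercept,
        modality_components=components,
        score_noise_sd=eps_sd,
    )
    ids = [f"sub-{i:04d}" for i in range(n)]
    return MultimodalDataset(subject_ids=ids, features=features, scores=scores, truth=truth)


def generate_timeseries(
    n_subjects: int,
    timepoints: int,
    voxels: int,
    tr_seconds: float,
    band_components: list,
    seed: int = 0,
    noise_sd: float = 0.0,
    motion_step_sd: float = 0.02,
) -> TimeSeriesSet:
    """Sinusoids-plus-noise voxel time series and random-walk motion traces.

    ``band_components`` is a list of (frequency_hz, amplitude) pairs summed
    into every voxel's series with a random phase per voxel.  Frequencies at
    or above Nyquist (1 / (2 TR)) are rejected.
    """
    if timepoints < 8:
        raise ValueError("timepoints must be >= 8")
    nyquist = 1.0 / (2.0 * tr_seconds)
    for freq, _amp in band_components:
        if freq >= nyquist:
            raise ValueError(
                f"component frequency {freq} Hz is at or above Nyquist "
                f"({nyquist:.4f} Hz for TR={tr_seconds}s)"
            )
    rng = np.random.default_rng(seed)
    t = np.arange(timepoints) * tr_seconds
    series, motion = [], []
    for _ in range(n_subjects):
        S = np.zeros((timepoints, voxels))
        for freq, amp in band_components:
            phase = rng.uniform(0, 2 * np.pi, size=voxels)
            S += amp * np.sin(2 * np.pi * freq * t[:, None] + phase[None, :])
        if noise_sd > 0:
            S += noise_sd * rng.standard_normal((timepoints, voxels))
        series.append(S)
        # translations (mm) step at motion_step_sd; rotations (radians) step
        # 50x smaller so both contribute comparably to framewise displacement
        steps = rng.standard_normal((timepoints, 6)) * motion_step_sd
        steps[:, 3:] /= 50.0
        motion.append(np.cumsum(steps, axis=0))
    return TimeSeriesSet(series=series, tr_seconds=tr_seconds, motion=motion)


def generate_roster(
    n_total: int,
    counts_per_flag: dict,
    overlap_spec: dict | None = None,
    seed: int = 0,
) -> list[Roster]:
    """Assign exclusion flags to subjects with exact counts and overlaps.

    ``counts_per_flag`` maps flag name -> number of subjects carrying it;
    ``overlap_spec`` maps a (flag_a, flag_b) pair -> number of subjects
    carrying both.  Flag pairs not listed do not overlap.
    """
    overlap_spec = overlap_spec or {}
    members: dict = {flag: set() for flag in counts_per_flag}
    for pair in overlap_spec:
        for flag in pair:
            if flag not in members:
                raise ValueError(f"overlap references unknown flag {flag!r}")

    rng = np.random.default_rng(seed)
    pool = list(rng.permutation(n_total))

    def take(k: int) -> list:
        if k > len(pool):
            raise ValueError("flag counts exceed the total number of subjects")
        return [pool.pop() for _ in range(k)]

    for (a, b), k in overlap_spec.items():
        if k > counts_per_flag[a] or k > counts_per_flag[b]:
            raise ValueError(
                f"overlap {k} between {a!r} and {b!r} exceeds a flag count"
            )
        shared = take(k)
        members[a].update(shared)
        members[b].update(shared)

    for flag, count in counts_per_flag.items():
        deficit = count - len(members[flag])
        if deficit < 0:
            raise ValueError(f"overlaps over-fill flag {flag!r}")
        members[flag].update(take(deficit))

    flags_by_subject: dict = {}
    for flag, subjects in members.items():
        for s in subjects:
            flags_by_subject.setdefault(s, set()).add(flag)
    return [
        Roster(
            subject_id=f"sub-{i:04d}",
            flags=frozenset(flags_by_subject.get(i, set())),
        )
        for i in range(n_total)
    ]


def generate_atlas(
    n_voxels: int, n_nodes: int, n_networks: int, seed: int = 0
) -> AtlasLabels:
    """Toy parcellation: contiguous voxel blocks as nodes, grouped in networks."""
    if not 1 <= n_nodes <= n_voxels:
        raise ValueError("need 1 <= n_nodes <= n_voxels")
    if not 1 <= n_networks <= n_nodes:
        raise ValueError("need 1 <= n_networks <= n_nodes")
    rng = np.random.default_rng(seed)

    def random_partition(total: int, parts: int) -> np.ndarray:
        """Sizes >= 1 summing to total, via random cut points."""
        if parts == 1:
            return np.array([total])
        cuts = np.sort(rng.choice(np.arange(1, total), size=parts - 1, replace=False))
        return np.diff(np.concatenate([[0], cuts, [total]]))

    node_sizes = random_partition(n_voxels, n_nodes)
    voxel_to_node = np.repeat(np.arange(n_nodes), node_sizes)
    net_sizes = random_partition(n_nodes, n_networks)
    node_to_network = np.repeat(np.arange(n_networks), net_sizes)
    return AtlasLabels(voxel_to_node=voxel_to_node, node_to_network=node_to_network)
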