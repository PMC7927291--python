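"""Fold-averaged weight maps and atlas/network aggregation.

After cross-validation each fold carries a voxel-space weight vector (zeros at
voxels not selected in that fold).  The discriminative weight of a voxel is
its mean across folds; voxel weights are then aggregated to atlas nodes
(mean over member voxels) and to networks (positive and negative node weights
summed separately), mirroring the usual interpretation outputs of kernel
regression studies on parcellated brains.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rvr import PrimalWeights

__all__ = [
    "AtlasLabels",
    "WeightMap",
    "NetworkContributions",
    "average_fold_weights",
    "map_to_atlas",
    "network_contributions",
    "top_regions",
]


@dataclass
class AtlasLabels:
    """Voxel → node and node → network assignment.

    ``voxel_to_node[v]`` is the node id of voxel v (0-based, dense);
    ``node_to_network[k]`` is the network id of node k.  Every node must own
    at least one voxel and every network at least one node.
    """

    voxel_to_node: np.ndarray
    node_to_network: np.ndarray
    node_names: list[str] | None = None
    network_names: list[str] | None = None

    def __post_init__(self):
        self.voxel_to_node = np.asarray(self.voxel_to_node, dtype=int)
        self.node_to_network = np.asarray(self.node_to_network, dtype=int)
        n_nodes = len(self.node_to_network)
        if self.voxel_to_node.min(initial=0) < 0 or (
            self.voxel_to_node.size and self.voxel_to_node.max() >= n_nodes
        ):
            raise ValueError("voxel_to_node references an undefined node")
        present = np.bincount(self.voxel_to_node, minlength=n_nodes)
        if (present == 0).any():
            raise ValueError(
                f"nodes without voxels: {np.flatnonzero(present == 0).tolist()}"
            )

    @property
    def n_nodes(self) -> int:
        return len(self.node_to_network)

    @property
    def n_networks(self) -> int:
        return int(self.node_to_network.max()) + 1 if self.node_to_network.size else 0

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_to_node)


@dataclass
class WeightMap:
    """Fold-averaged voxel discriminative weights for one modality."""

    voxel_weights: np.ndarray
    modality_tag: str | None = None
    n_folds: int = 1

    def __post_init__(self):
        self.voxel_weights = np.asarray(self.voxel_weights, dtype=float)
        if not np.isfinite(self.voxel_weights).all():
            raise ValueError("weight map contains non-finite values")


@dataclass
class NetworkContributions:
    """Per-network sums of positive and of negative node weights."""

    table: pd.DataFrame  # index: network, columns: positive_sum, negative_sum


def average_fold_weights(
    per_fold: list, *, mode: str = "zero_fill", modality_tag: str | None = None
) -> WeightMap:
    """Average voxel weights across folds.

    ``zero_fill`` (default): a voxel not selected in a fold contributes 0 for
    that fold, so the mean divides by the total fold count.  The alternative
    ``selected_only`` averages each voxel only over folds where it carried a
    non-zero weight.
    """
    if not per_fold:
        raise ValueError("empty fold list")
    arrays = [
        np.asarray(pw.w if isinstance(pw, PrimalWeights) else pw, dtype=float)
        for pw in per_fold
    ]
    lengths = {a.shape for a in arrays}
    if len(lengths) != 1:
        raise ValueError(f"folds disagree on voxel space: shapes {sorted(lengths)}")
    stack = np.vstack(arrays)
    if mode == "zero_fill":
        mean = stack.mean(axis=0)
    elif mode == "selected_only":
        nonzero = stack != 0
        counts = nonzero.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean = np.where(counts > 0, stack.sum(axis=0) / np.maximum(counts, 1), 0.0)
    else:
        raise ValueError(f"unknown averaging mode {mode!r}")
    if modality_tag is None and isinstance(per_fold[0], PrimalWeights):
        modality_tag = per_fold[0].modality_tag
    return WeightMap(voxel_weights=mean, modality_tag=modality_tag, n_folds=len(arrays))


def map_to_atlas(weight_map: WeightMap, atlas: AtlasLabels) -> pd.Series:
    """Node weight = mean voxel weight over the node's member voxels."""
    w = weight_map.voxel_weights
    if len(w) != atlas.n_voxels:
        raise ValueError(
            f"weight map has {len(w)} voxels, atlas covers {atlas.n_voxels}"
        )
    sums = np.bincount(atlas.voxel_to_node, weights=w, minlength=atlas.n_nodes)
    counts = np.bincount(atlas.voxel_to_node, minlength=atlas.n_nodes)
    empty = counts == 0
    if empty.any():  # pragma: no cover - AtlasLabels forbids this at build time
        warnings.warn(f"excluding {empty.sum()} nodes with no voxels", RuntimeWarning)
    node_w = np.where(empty, np.nan, sums / np.maximum(counts, 1))
    index = (
        atlas.node_names
        if atlas.node_names is not None
        else [f"node_{k}" for k in range(atlas.n_nodes)]
    )
    return pd.Series(node_w, index=index, name="node_weight").dropna()


def network_contributions(
    node_weights: pd.Series | np.ndarray, atlas: AtlasLabels
) -> NetworkContributions:
    """Sum positive and negative node weights separately within each network."""
    w = np.asarray(node_weights, dtype=float)
    if len(w) != atlas.n_nodes:
        raise ValueError("node weight count does not match atlas")
    pos = np.bincount(
        atlas.node_to_network, weights=np.clip(w, 0, None), minlength=atlas.n_networks
    )
    neg = np.bincount(
        atlas.node_to_network, weights=np.clip(w, None, 0), minlength=atlas.n_networks
    )
    index = (
        atlas.network_names
        if atlas.network_names is not None
        else [f"network_{k}" for k in range(atlas.n_networks)]
    )
    table = pd.DataFrame(
        {"positive_sum": pos, "negative_sum": neg}, index=pd.Index(index, name="network")
    )
    return NetworkContributions(table=table)


def top_regions(
    weights: pd.Series | np.ndarray,
    k: int = 10,
    sign: str = "positive",
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """Rank the k largest positive or most negative entries.

    Ties are broken by ascending index.  If fewer than k entries have the
    requested sign the table is truncated with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if isinstance(weights, pd.Series):
        labels = list(weights.index)
        w = weights.to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(len(w))]
    if sign == "positive":
        mask = w > 0
        order_key = -w
    elif sign == "negative":
        mask = w < 0
        order_key = w
    else:
        raise ValueError("sign must be 'positive' or 'negative'")
    idx = np.flatnonzero(mask)
    # stable sort on (magnitude, index) so ties resolve by ascending index
    idx = idx[np.argsort(order_key[idx], kind="stable")]
    if len(idx) < k:
        warnings.warn(
            f"only {len(idx)} {sign} entries available, requested {k}", RuntimeWarning
        )
    idx = idx[:k]
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(idx) + 1),
            "index": idx,
            "label": [labels[i] for i in idx],
            "weight": w[idx],
        }
    )
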