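"""Per-subject voxel networks and their fROI-level aggregation.

Voxel level: nodes are the active voxels; an undirected link joins voxels
``i`` and ``j`` whenever their Pearson correlation ``C_ij`` reaches an
absolute threshold ``theta``, with link weight ``C_ij``. The threshold acts
on the signed correlation (task-locked couplings are positive in this
setting; negative correlations are excluded rather than rectified). Ties at
exactly ``theta`` are included.

fROI level: an fROI link exists iff at least one voxel-level link crosses
between the two fROIs. Its raw weight is

    W_ij = (# voxel links between i and j) / (size_i + size_j)

and per subject every ``W`` is divided by that subject's largest raw weight
``W_max``, so the normalized weights satisfy ``max W_norm = 1`` in each
individual network with at least one edge.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .errors import InvalidThresholdError, UndefinedCorrelationError

__all__ = [
    "VoxelNetwork",
    "FROINetwork",
    "correlation_matrix",
    "threshold_network",
    "aggregate_froi",
    "normalize_weights",
    "build_voxel_network",
]


def correlation_matrix(bold: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlations of the rows of ``bold``.

    Symmetric, unit diagonal, entries clipped to [-1, 1]. Constant rows are
    rejected: they should have been excluded upstream by the activation
    stage's constant-voxel policy.
    """
    bold = np.asarray(bold, dtype=float)
    if bold.ndim != 2 or bold.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 voxels")
    if bold.shape[1] < 4:
        raise ValueError("need at least 4 volumes")
    if np.any(np.ptp(bold, axis=1) == 0):
        raise UndefinedCorrelationError("constant voxel row; exclude it upstream")
    corr = np.corrcoef(bold)
    corr = np.clip(corr, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return corr


@dataclass
class VoxelNetwork:
    """Weighted voxel graph: node attribute ``froi``, edge attribute ``weight``."""

    graph: nx.Graph
    theta: float

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def froi_sizes(self) -> dict[str, int]:
        """Number of network nodes (active voxels) per fROI."""
        return dict(Counter(froi for _, froi in self.graph.nodes(data="froi")))

    def labels(self) -> dict:
        return {v: froi for v, froi in self.graph.nodes(data="froi")}


def threshold_network(
    corr: np.ndarray,
    labels,
    theta: float,
    voxel_ids=None,
) -> VoxelNetwork:
    """Apply the absolute correlation threshold: edge iff ``C_ij >= theta``.

    Isolated voxels are retained as nodes (they still count toward fROI
    sizes). ``labels`` gives the fROI name per row of ``corr``.
    """
    if not (0.0 < theta < 1.0):
        raise InvalidThresholdError(f"theta must lie in (0, 1), got {theta}")
    corr = np.asarray(corr, dtype=float)
    n = corr.shape[0]
    if corr.shape != (n, n):
        raise ValueError("corr must be square")
    labels = [str(lab) for lab in labels]
    if len(labels) != n:
        raise ValueError("labels length must match corr size")
    if voxel_ids is None:
        voxel_ids = np.arange(n)
    voxel_ids = list(np.asarray(voxel_ids))
    g = nx.Graph()
    for v, froi in zip(voxel_ids, labels):
        g.add_node(v, froi=froi)
    iu, ju = np.triu_indices(n, k=1)
    keep = corr[iu, ju] >= theta
    g.add_weighted_edges_from(
        (voxel_ids[i], voxel_ids[j], float(corr[i, j]))
        for i, j in zip(iu[keep], ju[keep])
    )
    return VoxelNetwork(graph=g, theta=float(theta))


def build_voxel_network(bold, labels, theta, voxel_ids=None) -> VoxelNetwork:
    """Convenience: correlation matrix + thresholding in one call."""
    return threshold_network(correlation_matrix(bold), labels, theta, voxel_ids=voxel_ids)


@dataclass
class FROINetwork:
    """fROI graph: node attribute ``size``; edge attributes ``W`` (raw) and,
    after :func:`normalize_weights`, ``W_norm``."""

    graph: nx.Graph
    w_max: float | None = None  # set by normalize_weights
    subject_id: str | None = None

    @property
    def normalized(self) -> bool:
        return self.w_max is not None

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def edge_weights(self, normalized: bool = True) -> dict[tuple[str, str], float]:
        key = "W_norm" if normalized else "W"
        return {
            tuple(sorted((u, v))): data[key]
            for u, v, data in self.graph.edges(data=True)
            if key in data
        }


def aggregate_froi(vnet: VoxelNetwork, subject_id: str | None = None) -> FROINetwork:
    """Aggregate a voxel network into the fROI network with raw weights.

    ``W_ij = cross_links(i, j) / (size_i + size_j)``; within-fROI voxel links
    contribute to nothing here (sizes count nodes, not links). An fROI pair
    with zero cross links has no edge (absent, not weight 0).
    """
    sizes = vnet.froi_sizes()
    if len(sizes) == 0:
        raise ValueError("voxel network has no nodes")
    cross: Counter = Counter()
    labels = vnet.labels()
    for u, v in vnet.graph.edges():
        fu, fv = labels[u], labels[v]
        if fu != fv:
            cross[tuple(sorted((fu, fv)))] += 1
    g = nx.Graph()
    for froi, size in sizes.items():
        g.add_node(froi, size=size)
    for (fi, fj), n_links in cross.items():
        g.add_edge(fi, fj, W=n_links / (sizes[fi] + sizes[fj]))
    return FROINetwork(graph=g, subject_id=subject_id)


def normalize_weights(fnet: FROINetwork) -> FROINetwork:
    """Divide every raw W by the subject's maximum raw weight (in place).

    An edgeless network is returned unchanged (``w_max`` left unset) with a
    warning; such subjects contribute nothing to the group stage.
    """
    weights = [data["W"] for _, _, data in fnet.graph.edges(data=True)]
    if not weights:
        warnings.warn(
            f"fROI network {fnet.subject_id or ''} has no edges; cannot normalize",
            stacklevel=2,
        )
        return fnet
    w_max = max(weights)
    for _, _, data in fnet.graph.edges(data=True):
        data["W_norm"] = data["W"] / w_max
    fnet.w_max = float(w_max)
    return fnet
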