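"""k-core/k-shell decomposition, shell normalization, and fROI occupancy.

The k-core of a graph is the maximal subgraph in which every node has degree
at least k; a node's core number is the largest k whose k-core contains it,
obtained by iteratively pruning nodes of degree < k. Core numbers depend
only on the topology (edge weights are ignored).

Because each subject's network has its own maximal core, per-subject core
numbers are divided by that subject's ``kcore_max`` before pooling, mapping
the deepest shell of every subject to 1. Occupancy histograms then count,
per fROI, how many voxels land in each normalized-shell bin across the
cohort; a label-permutation null (shuffling fROI labels across a subject's
nodes, keeping the topology and fROI sizes fixed) calibrates how much
maximal-shell occupancy a fROI of that size would show by chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import rng_for
from .errors import UndefinedNormalizationError
from .networks import VoxelNetwork

__all__ = [
    "KShellAssignment",
    "OccupancyHistogram",
    "NullOccupancy",
    "core_decompose",
    "normalized_shells",
    "occupancy_by_froi",
    "null_occupancy",
]


@dataclass
class KShellAssignment:
    """Per-node core numbers of one subject's voxel network."""

    core_number: dict
    subject_id: str | None = None

    @property
    def kcore_max(self) -> int:
        return max(self.core_number.values(), default=0)

    def max_shell_nodes(self) -> set:
        kmax = self.kcore_max
        return {v for v, c in self.core_number.items() if c == kmax}


def _as_graph(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, VoxelNetwork) else graph


def core_decompose(graph) -> KShellAssignment:
    """Core numbers via iterative pruning (topology only, order-independent)."""
    g = _as_graph(graph)
    subject_id = getattr(graph, "subject_id", None)
    if g.number_of_nodes() == 0:
        return KShellAssignment(core_number={}, subject_id=subject_id)
    return KShellAssignment(core_number=nx.core_number(g), subject_id=subject_id)


def normalized_shells(assignment: KShellAssignment) -> dict:
    """Core numbers divided by the subject's kcore_max.

    Values lie in [0, 1] (isolated nodes map to 0; the deepest shell to 1).
    Raises :class:`UndefinedNormalizationError` when the graph is edgeless
    (kcore_max = 0), in which case the subject should be skipped.
    """
    kmax = assignment.kcore_max
    if kmax < 1:
        raise UndefinedNormalizationError(
            f"kcore_max = 0 for subject {assignment.subject_id}; normalization undefined"
        )
    return {v: c / kmax for v, c in assignment.core_number.items()}


@dataclass
class OccupancyHistogram:
    """Cohort-pooled normalized-shell occupancy per fROI.

    ``counts[froi]`` has one entry per bin; bins are equal-width on [0, 1],
    right-closed, with the lowest bin additionally including 0 (isolated
    voxels). ``max_shell_fraction[froi]`` is the fraction of the fROI's
    pooled voxels lying in their subject's maximal shell.
    """

    bin_edges: np.ndarray
    counts: dict[str, np.ndarray]
    max_shell_fraction: dict[str, float]
    totals: dict[str, int]

    def modal_bin(self, froi: str) -> int:
        return int(np.argmax(self.counts[froi]))

    @property
    def n_bins(self) -> int:
        return self.bin_edges.size - 1

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for froi, cnt in sorted(self.counts.items()):
            for b in range(self.n_bins):
                rows.append(
                    {
                        "froi": froi,
                        "bin_low": self.bin_edges[b],
                        "bin_high": self.bin_edges[b + 1],
                        "count": int(cnt[b]),
                    }
                )
        return pd.DataFrame(rows)


CohortAssignments = Sequence[tuple[KShellAssignment, Mapping]]


def _froi_universe(pairs: CohortAssignments) -> set[str]:
    names: set[str] = set()
    for _, labels in pairs:
        names.update(str(f) for f in labels.values())
    return names


def occupancy_by_froi(
    pairs: CohortAssignments,
    froi_filter: Iterable[str] | None = None,
    n_bins: int = 10,
) -> OccupancyHistogram:
    """Pool normalized-shell occupancy per fROI across subjects.

    ``pairs`` is a sequence of (assignment, node->froi labels) per subject.
    Subjects with an edgeless network (kcore_max = 0) are skipped with a
    warning. Counts per fROI sum to that fROI's total analyzed voxels.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    universe = _froi_universe(pairs)
    frois = sorted(universe) if froi_filter is None else list(froi_filter)
    unknown = set(frois) - universe
    if unknown:
        raise ValueError(f"unknown fROI(s) in filter: {sorted(unknown)}")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts = {f: np.zeros(n_bins, dtype=int) for f in frois}
    in_max = {f: 0 for f in frois}
    totals = {f: 0 for f in frois}
    wanted = set(frois)
    for assignment, labels in pairs:
        if assignment.kcore_max < 1:
            warnings.warn(
                f"subject {assignment.subject_id}: edgeless network skipped in occupancy",
                stacklevel=2,
            )
            continue
        shells = normalized_shells(assignment)
        kmax = assignment.kcore_max
        for node, value in shells.items():
            froi = str(labels[node])
            if froi not in wanted:
                continue
            # right-closed bins; 0 falls into the lowest bin
            b = min(int(np.ceil(value * n_bins)) - 1, n_bins - 1) if value > 0 else 0
            counts[froi][b] += 1
            totals[froi] += 1
            if assignment.core_number[node] == kmax:
                in_max[froi] += 1
    frac = {f: (in_max[f] / totals[f] if totals[f] else float("nan")) for f in frois}
    return OccupancyHistogram(
        bin_edges=edges, counts=counts, max_shell_fraction=frac, totals=totals
    )


@dataclass
class NullOccupancy:
    """Label-permutation null for maximal-shell occupancy per fROI."""

    observed: dict[str, float]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    p_value: dict[str, float]
    n_perm: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        frois = sorted(self.observed)
        return pd.DataFrame(
            {
                "froi": frois,
                "observed": [self.observed[f] for f in frois],
                "null_mean": [self.null_mean[f] for f in frois],
                "null_sd": [self.null_sd[f] for f in frois],
                "p": [self.p_value[f] for f in frois],
            }
        )


def null_occupancy(
    pairs: CohortAssignments,
    froi_filter: Iterable[str] | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> NullOccupancy:
    """Randomized voxel-to-fROI assignment null for max-shell occupancy.

    For each permutation, every subject's fROI labels are shuffled across its
    network nodes (fROI sizes and topology, hence core numbers, unchanged);
    the cohort-pooled max-shell fraction per fROI is recomputed. The p-value
    is the two-sided add-one permutation estimate
    ``(1 + #{|null - mean| >= |obs - mean|}) / (n_perm + 1)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    universe = _froi_universe(pairs)
    frois = sorted(universe) if froi_filter is None else list(froi_filter)
    unknown = set(frois) - universe
    if unknown:
        raise ValueError(f"unknown fROI(s) in filter: {sorted(unknown)}")
    index = {f: i for i, f in enumerate(frois)}
    n_froi = len(frois)

    # Per subject: code per node (index into frois, n_froi for "other") and
    # the max-shell indicator; permuting labels == permuting the indicator.
    subjects: list[tuple[np.ndarray, int]] = []
    totals = np.zeros(n_froi, dtype=float)
    obs_counts = np.zeros(n_froi, dtype=float)
    for assignment, labels in pairs:
        if assignment.kcore_max < 1:
            continue
        kmax = assignment.kcore_max
        nodes = list(assignment.core_number)
        codes = np.array([index.get(str(labels[v]), n_froi) for v in nodes])
        top = np.array([assignment.core_number[v] == kmax for v in nodes])
        subjects.append((codes, int(top.sum())))
        totals += np.bincount(codes[codes < n_froi], minlength=n_froi)
        obs_counts += np.bincount(codes[top & (codes < n_froi)], minlength=n_froi)
    if not subjects:
        raise ValueError("no subject with a non-trivial network")

    observed = obs_counts / totals
    rng = rng_for(seed, "null-occupancy")
    null = np.empty((n_perm, n_froi), dtype=float)
    for p in range(n_perm):
        cnt = np.zeros(n_froi, dtype=float)
        for codes, n_top in subjects:
            picked = codes[rng.permutation(codes.size)[:n_top]]
            cnt += np.bincount(picked[picked < n_froi], minlength=n_froi)
        null[p] = cnt / totals
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1) if n_perm > 1 else np.zeros(n_froi)
    dev = np.abs(null - mean[None, :])
    pvals = (1.0 + (dev >= np.abs(observed - mean)[None, :]).sum(axis=0)) / (n_perm + 1.0)
    return NullOccupancy(
        observed={f: float(observed[i]) for f, i in index.items()},
        null_mean={f: float(mean[i]) for f, i in index.items()},
        null_sd={f: float(sd[i]) for f, i in index.items()},
        p_value={f: float(pvals[i]) for f, i in index.items()},
        n_perm=n_perm,
        seed=seed,
    )
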