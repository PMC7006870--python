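"""Cross-subject group analysis: the common network and related summaries.

The common network keeps an fROI link only if it is present (with both of
its fROIs active) in at least ``ceil(presence_fraction * N)`` of the ``N``
subjects, and keeps an fROI only if it is itself that persistent *and*
retains at least one incident link (the common network has no isolated
areas). Each retained link carries the mean and SD of the normalized
per-subject weights. By default the mean runs over the subjects that possess
the link; dividing by the full ``N`` instead is available via
``denominator="all"``.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .errors import AbsentEdgeError
from .networks import FROINetwork

__all__ = [
    "CommonNetwork",
    "build_common_network",
    "link_statistics",
    "rank_froi_strength",
    "pooled_weight_distribution",
    "WeightDistribution",
]


@dataclass
class CommonNetwork:
    """Group-level persistent graph.

    Node attribute ``n_present`` counts subjects where the fROI is active;
    edge attributes are ``weight`` (W^C), ``sd``, ``n_present``.
    """

    graph: nx.Graph
    presence_fraction: float
    n_subjects: int
    denominator: str

    @property
    def min_count(self) -> int:
        return math.ceil(self.presence_fraction * self.n_subjects)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "froi_i": min(u, v),
                "froi_j": max(u, v),
                "W_C": data["weight"],
                "sd": data["sd"],
                "n_present": data["n_present"],
            }
            for u, v, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows, columns=["froi_i", "froi_j", "W_C", "sd", "n_present"]).sort_values(
            ["froi_i", "froi_j"], ignore_index=True
        )


def _edge_weights_by_pair(fnets: list[FROINetwork]) -> dict[tuple[str, str], list[float]]:
    pooled: dict[tuple[str, str], list[float]] = defaultdict(list)
    for fnet in fnets:
        if not fnet.normalized:
            continue  # edgeless subjects carry no links
        for pair, w in fnet.edge_weights(normalized=True).items():
            pooled[pair].append(w)
    return pooled


def build_common_network(
    fnets: list[FROINetwork],
    presence_fraction: float = 0.85,
    denominator: str = "possessors",
) -> CommonNetwork:
    """Extract the persistent fROIs/links across subjects.

    ``denominator="possessors"`` averages W_norm over the subjects that have
    the link (the reported convention); ``"all"`` divides the sum by the full
    cohort size N instead.
    """
    if len(fnets) < 2:
        raise ValueError("need at least 2 subjects")
    if not (0.0 < presence_fraction <= 1.0):
        raise ValueError("presence_fraction must lie in (0, 1]")
    if denominator not in ("possessors", "all"):
        raise ValueError("denominator must be 'possessors' or 'all'")
    n_subjects = len(fnets)
    min_count = math.ceil(presence_fraction * n_subjects)

    node_presence: Counter = Counter()
    for fnet in fnets:
        node_presence.update(list(fnet.graph.nodes()))
    pooled = _edge_weights_by_pair(fnets)

    g = nx.Graph()
    for (fi, fj), weights in sorted(pooled.items()):
        n_present = len(weights)
        if n_present < min_count:
            continue
        if node_presence[fi] < min_count or node_presence[fj] < min_count:
            continue
        arr = np.sort(np.asarray(weights))  # sorted: exact subject-order invariance
        mean = arr.mean() if denominator == "possessors" else arr.sum() / n_subjects
        sd = float(arr.std(ddof=1)) if n_present > 1 else 0.0
        g.add_edge(fi, fj, weight=float(mean), sd=sd, n_present=n_present)
    # Node rule: persistent AND >= 1 retained incident edge (no isolates).
    for node in list(g.nodes()):
        g.nodes[node]["n_present"] = node_presence[node]
    if g.number_of_edges() == 0:
        warnings.warn("no link meets the presence criterion; common network is empty", stacklevel=2)
    return CommonNetwork(
        graph=g,
        presence_fraction=presence_fraction,
        n_subjects=n_subjects,
        denominator=denominator,
    )


def link_statistics(
    fnets: list[FROINetwork], edge: tuple[str, str]
) -> tuple[float, float, int]:
    """Mean, sample SD, and possessor count of one link's W_norm across subjects.

    A single possessor yields sd = 0 (degenerate, flagged by n_present = 1).
    """
    pair = tuple(sorted(edge))
    weights = _edge_weights_by_pair(fnets).get(pair, [])
    if not weights:
        raise AbsentEdgeError(f"edge {pair} present in no subject")
    arr = np.sort(np.asarray(weights))
    sd = float(arr.std(ddof=1)) if arr.size > 1 else 0.0
    return float(arr.mean()), sd, int(arr.size)


def rank_froi_strength(fnet: FROINetwork) -> pd.DataFrame:
    """Connectivity strength (sum of incident W_norm) and rank per fROI.

    Descending ranks starting at 1; ties broken by fROI name. Isolated fROIs
    get strength 0 and the lowest ranks.
    """
    if fnet.n_edges < 1:
        raise ValueError("fROI network has no edges")
    if not fnet.normalized:
        raise ValueError("normalize_weights must be applied first")
    strength = {froi: 0.0 for froi in fnet.graph.nodes()}
    for u, v, data in fnet.graph.edges(data=True):
        strength[u] += data["W_norm"]
        strength[v] += data["W_norm"]
    ordered = sorted(strength.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "froi": [froi for froi, _ in ordered],
            "strength": [s for _, s in ordered],
            "rank": np.arange(1, len(ordered) + 1),
        }
    )


@dataclass
class WeightDistribution:
    """Histogram of all normalized link weights pooled across subjects."""

    counts: np.ndarray
    bin_edges: np.ndarray
    skewness: float
    n_edges: int


def pooled_weight_distribution(
    fnets: list[FROINetwork], bins: int = 20
) -> WeightDistribution:
    """Pooled empirical distribution of W_norm with a skewness statistic."""
    values = np.asarray(
        [w for fnet in fnets for w in fnet.edge_weights(normalized=True).values()]
    )
    if values.size == 0:
        raise ValueError("no edges across the cohort")
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    skew = 0.0 if np.ptp(values) == 0 else float(stats.skew(values))
    return WeightDistribution(
        counts=counts, bin_edges=edges, skewness=skew, n_edges=int(values.size)
    )
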