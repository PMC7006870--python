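"""Rich-club coefficient, degree-preserving rewiring, and threshold sweeps.

The rich-club coefficient at degree k is

    phi(k) = 2 E_>k / (N_>k (N_>k - 1))

where N_>k and E_>k count nodes and edges after removing every node whose
degree (in the original graph, the standard convention) is <= k. Because
connectivity rises with degree by construction, phi is normalized by its
mean over graphs rewired with degree-preserving double-edge swaps:
ratio(k) = phi(k) / phi_rand(k). A rising ratio above 1 indicates that
high-degree nodes interconnect more densely than their degrees alone
explain. phi is computed on the unweighted topology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._rng import child_seed, rng_for
from .errors import InvalidThresholdError
from .networks import VoxelNetwork, correlation_matrix, threshold_network

__all__ = [
    "RichClubCurve",
    "ThresholdSweep",
    "rich_club_coefficient",
    "degree_preserving_rewire",
    "normalized_rich_club",
    "threshold_sensitivity",
]


def _as_graph(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, VoxelNetwork) else graph


def rich_club_coefficient(graph) -> dict[int, float]:
    """phi(k) for k = 0 .. max_degree - 1; k with N_>k < 2 are omitted.

    Degrees for the > k filter are taken in the original graph, so E_>k is
    the number of edges whose both endpoints have original degree > k.
    """
    g = _as_graph(graph)
    if g.number_of_nodes() == 0:
        return {}
    deg = dict(g.degree())
    degrees = np.array(list(deg.values()))
    max_deg = int(degrees.max())
    if max_deg == 0:
        return {}
    # N_>k from the degree histogram; E_>k from min endpoint degree per edge.
    deg_hist = np.bincount(degrees, minlength=max_deg + 1)
    n_gt = degrees.size - np.cumsum(deg_hist)  # n_gt[k] = #nodes with degree > k
    edge_min = np.array([min(deg[u], deg[v]) for u, v in g.edges()], dtype=int)
    if edge_min.size:
        min_hist = np.bincount(edge_min, minlength=max_deg + 1)
        e_gt = edge_min.size - np.cumsum(min_hist)
    else:
        e_gt = np.zeros(max_deg + 1, dtype=int)
    phi: dict[int, float] = {}
    for k in range(max_deg):
        n = int(n_gt[k])
        if n < 2:
            continue
        phi[k] = 2.0 * int(e_gt[k]) / (n * (n - 1))
    return phi


def degree_preserving_rewire(graph, n_swaps: int | None = None, seed: int = 0) -> nx.Graph:
    """Randomize a simple graph with double-edge swaps; degrees are preserved.

    ``n_swaps`` counts attempted swaps (default 10x the edge count); attempts
    creating self-loops or multi-edges are rejected. Graphs admitting no
    valid swap (e.g. complete graphs, < 2 edges) are returned as copies with
    a warning.
    """
    g = _as_graph(graph)
    m = g.number_of_edges()
    n = g.number_of_nodes()
    if m < 2 or m == n * (n - 1) // 2:
        warnings.warn("no admissible double-edge swap; returning the graph unchanged", stacklevel=2)
        out = nx.Graph()
        out.add_nodes_from(g.nodes())
        out.add_edges_from(g.edges())
        return out
    if n_swaps is None:
        n_swaps = 10 * m
    rng = rng_for(seed, "rewire")
    edges = [tuple(e) for e in g.edges()]
    edge_set = {frozenset(e) for e in edges}
    picks = rng.integers(0, m, size=(n_swaps, 2))
    sides = rng.integers(0, 2, size=(n_swaps, 2))
    for (i, j), (si, sj) in zip(picks, sides):
        if i == j:
            continue
        a, b = edges[i]
        if si:
            a, b = b, a
        c, d = edges[j]
        if sj:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == d or c == b:
            continue
        new1, new2 = frozenset((a, d)), frozenset((c, b))
        if new1 == new2 or new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(frozenset((a, b)))
        edge_set.discard(frozenset((c, d)))
        edge_set.add(new1)
        edge_set.add(new2)
        edges[i] = (a, d)
        edges[j] = (c, b)
    out = nx.Graph()
    out.add_nodes_from(g.nodes())
    out.add_edges_from(edges)
    return out


@dataclass
class RichClubCurve:
    """phi(k), its rewired-null statistics, and their ratio."""

    k: np.ndarray
    phi: np.ndarray
    phi_rand_mean: np.ndarray
    phi_rand_sd: np.ndarray
    ratio: np.ndarray  # NaN where phi_rand_mean == 0
    n_null: int
    n_swaps: int
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "phi": self.phi,
                "phi_rand_mean": self.phi_rand_mean,
                "phi_rand_sd": self.phi_rand_sd,
                "ratio": self.ratio,
            }
        )

    def ratio_slope(self) -> float:
        """Least-squares slope of ratio vs k over the defined points."""
        ok = ~np.isnan(self.ratio)
        if ok.sum() < 2:
            return float("nan")
        return float(np.polyfit(self.k[ok], self.ratio[ok], 1)[0])


def normalized_rich_club(
    graph, n_null: int = 100, n_swaps: int | None = None, seed: int = 0
) -> RichClubCurve:
    """phi(k) normalized by the mean over ``n_null`` rewired graphs.

    Rewired graphs share the degree sequence, so phi is defined at exactly
    the same k in every null replicate.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    g = _as_graph(graph)
    phi = rich_club_coefficient(g)
    ks = np.array(sorted(phi), dtype=int)
    obs = np.array([phi[k] for k in ks])
    effective_swaps = 10 * g.number_of_edges() if n_swaps is None else n_swaps
    nulls = np.empty((n_null, ks.size))
    for i in range(n_null):
        rewired = degree_preserving_rewire(g, n_swaps=n_swaps, seed=child_seed(seed, "null", i))
        phi_r = rich_club_coefficient(rewired)
        nulls[i] = [phi_r[k] for k in ks]
    mean = nulls.mean(axis=0) if ks.size else np.empty(0)
    sd = nulls.std(axis=0, ddof=1) if (n_null > 1 and ks.size) else np.zeros(ks.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(mean > 0, obs / mean, np.nan)
    return RichClubCurve(
        k=ks,
        phi=obs,
        phi_rand_mean=mean,
        phi_rand_sd=sd,
        ratio=ratio,
        n_null=n_null,
        n_swaps=int(effective_swaps),
        seed=seed,
    )


@dataclass
class ThresholdSweep:
    """Rich-club curves at the base threshold and relative perturbations."""

    theta0: float
    curves: dict[float, RichClubCurve]  # keyed by delta (0.0 = base)
    slopes: dict[float, float]
    qualitative_agreement: bool


def threshold_sensitivity(
    bold: np.ndarray,
    labels,
    theta0: float,
    deltas: tuple[float, ...] = (-0.05, 0.05),
    n_null: int = 100,
    n_swaps: int | None = None,
    seed: int = 0,
) -> ThresholdSweep:
    """Rebuild the voxel network at theta0*(1+delta) and compare rich clubs.

    The qualitative-agreement flag reports whether the sign of the
    ratio-vs-k slope is the same at every threshold (the curves' rising
    behavior is robust to the perturbation).
    """
    corr = correlation_matrix(bold)
    all_deltas = (0.0,) + tuple(d for d in deltas if d != 0.0)
    curves: dict[float, RichClubCurve] = {}
    slopes: dict[float, float] = {}
    for delta in all_deltas:
        theta = theta0 * (1.0 + delta)
        if not (0.0 < theta < 1.0):
            raise InvalidThresholdError(f"perturbed threshold {theta} outside (0, 1)")
        vnet = threshold_network(corr, labels, theta)
        if vnet.n_edges < 2:
            warnings.warn(f"delta={delta}: network too sparse; curve omitted", stacklevel=2)
            continue
        curve = normalized_rich_club(
            vnet, n_null=n_null, n_swaps=n_swaps, seed=child_seed(seed, "sweep", delta)
        )
        curves[delta] = curve
        slopes[delta] = curve.ratio_slope()
    signs = {np.sign(s) for s in slopes.values() if not np.isnan(s)}
    return ThresholdSweep(
        theta0=theta0,
        curves=curves,
        slopes=slopes,
        qualitative_agreement=(len(signs) == 1),
    )
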