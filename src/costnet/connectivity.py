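"""Correlation matrices and cost-thresholded binary networks.

A subject's network is built by computing the Pearson correlation between
every pair of ROI time series and retaining, at a given wiring cost ``c``,
the ``round(c * N(N-1)/2)`` most strongly positively correlated pairs as
unweighted edges. Working at fixed cost (rather than a fixed correlation
threshold) equates edge counts across subjects and groups, which is what
makes between-group comparison of network *patterns* meaningful. The
smallest correlation among retained edges — the minimal correlation ratio —
is recorded as metadata.

Group-level networks keep the edges present in strictly more than half of a
group's individual networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CorrelationMatrix",
    "BinaryNetwork",
    "GroupNetwork",
    "correlation_matrix",
    "fisher_z",
    "inverse_fisher_z",
    "threshold_by_cost",
    "group_common_network",
    "total_connectivity_percent",
    "n_edges_at_cost",
]


@dataclass
class CorrelationMatrix:
    """Symmetric node x node Pearson correlation matrix."""

    names: list[str]
    values: np.ndarray
    n_frames: int

    def __post_init__(self) -> None:
        v = self.values
        n = len(self.names)
        if v.shape != (n, n):
            raise ValueError("correlation matrix shape does not match node count")
        if not np.allclose(v, v.T):
            raise ValueError("correlation matrix not symmetric")

    def fisher_z(self) -> np.ndarray:
        """Fisher z (atanh) view of the off-diagonal entries; diagonal 0."""
        z = np.zeros_like(self.values)
        off = ~np.eye(len(self.names), dtype=bool)
        z[off] = fisher_z(self.values[off])
        return z


@dataclass
class BinaryNetwork:
    """Undirected unweighted graph at a fixed wiring cost.

    ``adjacency`` is a symmetric boolean matrix with zero diagonal;
    ``min_retained_r`` is the smallest correlation among retained edges
    (NaN when the network was not built from a correlation matrix).
    """

    names: list[str]
    adjacency: np.ndarray
    cost: float
    min_retained_r: float = float("nan")
    swap_failures: int = 0

    def __post_init__(self) -> None:
        a = self.adjacency
        n = len(self.names)
        if a.shape != (n, n):
            raise ValueError("adjacency shape does not match node count")
        if a.dtype != bool:
            self.adjacency = a = a.astype(bool)
        if np.diagonal(a).any():
            raise ValueError("self-loops are not allowed")
        if not (a == a.T).all():
            raise ValueError("adjacency must be symmetric")

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edge_set(self) -> set[tuple[str, str]]:
        """Edges as unordered name pairs, stored sorted."""
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.adjacency[iu]
        return {
            tuple(sorted((self.names[i], self.names[j])))
            for i, j in zip(iu[0][mask], iu[1][mask])
        }

    def degree_sequence(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.names)
        g.add_edges_from(self.edge_set())
        return g


@dataclass
class GroupNetwork:
    """Majority-vote network over a group's individual binary networks."""

    names: list[str]
    edges: set[tuple[str, str]]
    support: dict[tuple[str, str], int]
    group_size: int

    def __post_init__(self) -> None:
        half = self.group_size / 2
        for e in self.edges:
            if self.support[e] <= half:
                raise ValueError(f"edge {e} lacks strict-majority support")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def correlation_matrix(cond) -> CorrelationMatrix:
    """Pearson correlation between every pair of ROI series.

    ``cond`` is a ConditionMatrix (or any object with ``data`` and
    ``roi_names``). Requires at least 3 frames and no constant column.
    """
    data = np.asarray(cond.data, dtype=float)
    names = list(cond.roi_names)
    if data.shape[0] < 3:
        raise ValueError("need at least 3 frames for a correlation matrix")
    spans = np.ptp(data, axis=0)
    if (spans == 0).any():
        bad = [names[i] for i in np.flatnonzero(spans == 0)]
        raise ValueError(f"constant time series for ROI(s): {bad}")
    r = np.corrcoef(data, rowvar=False)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(names=names, values=r, n_frames=data.shape[0])


def fisher_z(r):
    """Variance-stabilizing Fisher transform z = atanh(r); requires |r| < 1."""
    r = np.asarray(r, dtype=float)
    if (np.abs(r) >= 1).any():
        raise ValueError("|r| must be < 1 for the Fisher transform")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse Fisher transform r = tanh(z)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if out.ndim == 0 else out


def n_edges_at_cost(n_nodes: int, cost: float) -> int:
    """Edges retained at a wiring cost: round(cost * N(N-1)/2).

    Rounding is half-away-from-zero, so cost 0.28 on 62 nodes gives
    round(0.28 * 1891) = 529 edges.
    """
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return int(np.floor(cost * n_pairs + 0.5))


def threshold_by_cost(corr: CorrelationMatrix, cost: float) -> BinaryNetwork:
    """Binarize a correlation matrix at a fixed wiring cost.

    The K = round(cost * N(N-1)/2) node pairs with the largest *signed*
    correlation become edges: positive correlations are ranked first and
    anticorrelations can only enter once all positive pairs are used. Ties
    at the cutoff are broken by lexicographic node-pair order. The smallest
    retained correlation is stored as ``min_retained_r``.
    """
    if not 0 < cost <= 1:
        raise ValueError("cost must be in (0, 1]")
    n = len(corr.names)
    k = n_edges_at_cost(n, cost)
    if k == 0:
        raise ValueError(f"cost {cost} retains zero edges on {n} nodes")
    iu, ju = np.triu_indices(n, k=1)
    r = corr.values[iu, ju]
    pairs = sorted(
        range(len(r)),
        key=lambda p: (-r[p], corr.names[iu[p]], corr.names[ju[p]]),
    )
    keep = pairs[:k]
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[keep], ju[keep]] = True
    adj |= adj.T
    return BinaryNetwork(
        names=list(corr.names),
        adjacency=adj,
        cost=cost,
        min_retained_r=float(r[keep].min()),
    )


def group_common_network(networks: list[BinaryNetwork]) -> GroupNetwork:
    """Edges present in strictly more than half of a group's networks."""
    if not networks:
        raise ValueError("empty network list")
    names = networks[0].names
    for net in networks[1:]:
        if net.names != names:
            raise ValueError("all networks must share the same node set")
    counts = np.zeros_like(networks[0].adjacency, dtype=int)
    for net in networks:
        counts += net.adjacency
    n_subj = len(networks)
    iu = np.triu_indices(len(names), k=1)
    support: dict[tuple[str, str], int] = {}
    edges: set[tuple[str, str]] = set()
    for i, j, c in zip(iu[0], iu[1], counts[iu]):
        if c > 0:
            key = tuple(sorted((names[i], names[j])))
            support[key] = int(c)
            if c > n_subj / 2:
                edges.add(key)
    return GroupNetwork(
        names=list(names), edges=edges, support=support, group_size=n_subj
    )


def total_connectivity_percent(g: GroupNetwork) -> float:
    """Retained edges as a percentage of all N(N-1)/2 possible pairs."""
    n = len(g.names)
    n_pairs = n * (n - 1) / 2
    return 100.0 * g.n_edges / n_pairs
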