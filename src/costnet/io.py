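"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: TSV for matrices and tables, GraphML for networks,
JSON for manifests. Edge tables always key on node-name pairs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .connectivity import BinaryNetwork, CorrelationMatrix, GroupNetwork


def write_correlation_matrix(corr: CorrelationMatrix, path) -> None:
    pd.DataFrame(corr.values, index=corr.names, columns=corr.names).to_csv(
        path, sep="\t"
    )


def read_correlation_matrix(path, n_frames: int = 0) -> CorrelationMatrix:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return CorrelationMatrix(
        names=list(table.columns), values=table.to_numpy(), n_frames=n_frames
    )


def write_network_edgelist(net: BinaryNetwork, corr: CorrelationMatrix, path) -> None:
    """Edge list TSV: node_a, node_b, r, z."""
    idx = {n: i for i, n in enumerate(corr.names)}
    rows = []
    for a, b in sorted(net.edge_set()):
        r = corr.values[idx[a], idx[b]]
        rows.append(
            {"node_a": a, "node_b": b, "r": r, "z": float(np.arctanh(r))}
        )
    pd.DataFrame(rows, columns=["node_a", "node_b", "r", "z"]).to_csv(
        path, sep="\t", index=False
    )


def write_group_edgelist(g: GroupNetwork, path) -> None:
    """Group-network TSV with per-edge subject support counts."""
    rows = [
        {"node_a": a, "node_b": b, "support": g.support[(a, b)]}
        for a, b in sorted(g.edges)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "support"]).to_csv(
        path, sep="\t", index=False
    )


def write_graphml(net, path) -> None:
    """Write a BinaryNetwork or GroupNetwork as GraphML."""
    import networkx as nx

    if isinstance(net, GroupNetwork):
        g = nx.Graph()
        g.add_nodes_from(net.names)
        for (a, b) in net.edges:
            g.add_edge(a, b, support=net.support[(a, b)])
    else:
        g = net.to_networkx()
    nx.write_graphml(g, path)


def write_json(payload: dict, path) -> None:
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))
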