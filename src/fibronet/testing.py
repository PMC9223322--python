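"""Utilities for testing substrate detection on abstract graphs.

These wrap arbitrary networkx graphs as degenerate spatial networks (one
node per voxel along a line) and provide an independent networkx-based
route to the shortest-return-length criterion, so the compiled detection
kernels can be cross-checked against a separate implementation.
"""

from __future__ import annotations

import math

import networkx as nx
import numpy as np

from .network import TRANSVERSE, SpatialNetwork


def net_from_graph(g: nx.Graph) -> SpatialNetwork:
    """Wrap an abstract graph as a SpatialNetwork (one node per voxel)."""
    nodes = sorted(g.nodes())
    if nodes != list(range(len(nodes))):
        raise ValueError("graph nodes must be labelled 0..n-1")
    pos = np.stack(
        [
            np.arange(len(nodes), dtype=float),
            np.zeros(len(nodes)),
            np.zeros(len(nodes)),
        ],
        axis=1,
    )
    edges = np.array(
        [[min(u, v), max(u, v)] for u, v in g.edges()], dtype=np.int64
    ).reshape(-1, 2)
    return SpatialNetwork(
        positions=pos,
        voxels=np.floor(pos).astype(np.int64),
        tract_ids=np.zeros(len(nodes), dtype=np.int64),
        edges=edges,
        kinds=np.full(len(edges), TRANSVERSE, np.uint8),
    )


def nx_return_length(g: nx.Graph, node: int, blocked: int) -> float:
    """Independent oracle: shortest alternative path via networkx."""
    h = g.copy()
    h.remove_edge(blocked, node)
    try:
        return nx.shortest_path_length(h, blocked, node) + 1
    except nx.NetworkXNoPath:
        return math.inf


def random_small_graph(seed: int) -> nx.Graph:
    """Mixed trees/cycles on <= 60 nodes, connected, relabelled 0..n-1."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 61))
    kind = seed % 3
    if kind == 0:
        g = nx.gnm_random_graph(n, int(n * rng.uniform(0.9, 1.4)), seed=seed)
    elif kind == 1:
        g = nx.random_labeled_tree(n, seed=int(seed))
        for _ in range(int(rng.integers(0, 4))):  # a few chords -> cycles
            u, v = rng.integers(0, n, 2)
            if u != v:
                g.add_edge(int(u), int(v))
    else:
        g = nx.random_geometric_graph(n, 0.35, seed=seed)
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    return nx.convert_node_labels_to_integers(g)
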