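"""Brute-force discretized TFCE: the slow, obviously-correct oracle.

Connected components are recomputed from scratch at every threshold level
(via :mod:`scipy.sparse.csgraph`), with no state carried between levels.
This engine exists to validate the incremental engine; it shares nothing
with the incremental merge machinery.

Cluster size for FC data counts EDGES in the component, never nodes: under
node-sharing adjacency (two FC edges are neighbors iff they share an ROI) a
cluster is a connected subgraph of the ROI graph, and the number of
variables it contains is its edge count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .core import (
    EdgeRecord,
    EmptyGridError,
    StatMatrix,
    TFCEMap,
    TFCEParams,
    bin_indices,
    build_threshold_grid,
    edge_arrays,
)

__all__ = ["ClusterPartition", "clusters_at_threshold", "tfce_discrete"]


@dataclass(frozen=True)
class ClusterPartition:
    """Node-to-cluster labeling of the active (supra-threshold) subgraph.

    ``label`` maps each active node to a cluster id; ``edges_in_cluster`` and
    ``nodes_in_cluster`` report per-cluster counts.  Nodes touched by no
    supra-threshold edge are absent.
    """

    label: dict[int, int]
    edges_in_cluster: dict[int, int]
    nodes_in_cluster: dict[int, int]

    @property
    def n_clusters(self) -> int:
        return len(self.edges_in_cluster)


def clusters_at_threshold(edges: list[EdgeRecord] | tuple, h: float) -> ClusterPartition:
    """Connected components of the subgraph of edges with ``stat >= h``.

    Adjacency is node-sharing: two edges are neighbors iff they share an ROI,
    so components of edges are exactly components of the thresholded ROI
    graph.  An empty supra-threshold subgraph yields an empty partition.
    """
    if not h > 0:
        raise ValueError(f"threshold must be > 0, got {h}")
    active = [(e[0], e[1]) for e in edges if e[2] >= h]
    if not active:
        return ClusterPartition({}, {}, {})
    nodes = sorted({u for uv in active for u in uv})
    index = {node: i for i, node in enumerate(nodes)}
    iu = np.array([index[u] for u, _ in active])
    iv = np.array([index[v] for _, v in active])
    adj = coo_matrix(
        (np.ones(len(active)), (iu, iv)), shape=(len(nodes), len(nodes))
    )
    _, comp = connected_components(adj, directed=False)
    label = {node: int(comp[index[node]]) for node in nodes}
    edges_in = {}
    for u, _ in active:
        cid = label[u]
        edges_in[cid] = edges_in.get(cid, 0) + 1
    nodes_in = {}
    for node in nodes:
        cid = label[node]
        nodes_in[cid] = nodes_in.get(cid, 0) + 1
    return ClusterPartition(label, edges_in, nodes_in)


def tfce_discrete(m: StatMatrix, p: TFCEParams) -> TFCEMap:
    """Discretized TFCE by full recomputation at every threshold.

    For an edge x with statistic t,

        TFCE(x) = sum_{k=1..floor(t/dh)} c(x, k*dh)^E * (k*dh)^H * dh

    where c(x, k*dh) is the edge count of x's component among edges in bins
    >= k (the exact-arithmetic form of ``stat >= k*dh``).  Edges with
    ``stat < dh`` get 0.
    """
    n = m.n_rois
    iu, iv, stats = edge_arrays(m)
    try:
        grid = build_threshold_grid(float(stats.max()), p.dh)
    except EmptyGridError:
        return TFCEMap(values=np.zeros((n, n)))
    bins = bin_indices(stats, p.dh)
    tfce = np.zeros(stats.shape[0])
    ones = np.ones(stats.shape[0])
    for k in range(1, grid.nth + 1):
        mask = bins >= k
        if not mask.any():
            continue
        adj = coo_matrix((ones[mask], (iu[mask], iv[mask])), shape=(n, n))
        _, comp = connected_components(adj, directed=False)
        # edges per component, looked up through either endpoint
        per_comp = np.bincount(comp[iu[mask]], minlength=comp.max() + 1)
        c = per_comp[comp[iu[mask]]]
        h = k * p.dh
        tfce[mask] += c.astype(float) ** p.E * h**p.H * p.dh
    return TFCEMap.from_edge_values(n, iu, iv, tfce)
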