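"""Independent oracles used by the tests.

These deliberately avoid the package's engine code paths: component
labeling goes through networkx, the exact-TFCE oracle enumerates every
interval between consecutive sorted statistics explicitly, and the voxel
oracle thresholds and labels volumes with scipy.ndimage.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy import ndimage

_STRUCTURE_RANK = {6: 1, 18: 2, 26: 3}


def nx_edge_components(iu, iv, stats, h):
    """Components of the supra-threshold FC subgraph, as frozensets of nodes."""
    g = nx.Graph()
    for u, v, s in zip(iu, iv, stats):
        if s >= h:
            g.add_edge(int(u), int(v))
    return [frozenset(c) for c in nx.connected_components(g)]


def exact_tfce_interval_oracle(n, iu, iv, stats, E, H):
    """Eq.-by-eq interval enumeration: per interval, recompute components."""
    pos = sorted(set(float(s) for s in stats if s > 0))
    heights = [0.0] + pos
    out = np.zeros(len(stats))
    for i in range(1, len(heights)):
        lo, hi = heights[i - 1], heights[i]
        integral = (hi ** (H + 1) - lo ** (H + 1)) / (H + 1)
        g = nx.Graph()
        for e, (u, v, s) in enumerate(zip(iu, iv, stats)):
            if s >= hi:
                g.add_edge(int(u), int(v), idx=e)
        for comp in nx.connected_components(g):
            sub = g.subgraph(comp)
            c = sub.number_of_edges()
            for _, _, data in sub.edges(data=True):
                out[data["idx"]] += c**E * integral
    return out


def exact_voxel_interval_oracle(stats, mask, connectivity, E, H):
    """Interval enumeration for voxel TFCE (cluster size = voxel count)."""
    vals = sorted(set(stats[mask][stats[mask] > 0].tolist()))
    heights = [0.0] + vals
    out = np.zeros(stats.shape)
    structure = ndimage.generate_binary_structure(3, _STRUCTURE_RANK[connectivity])
    for i in range(1, len(heights)):
        lo, hi = heights[i - 1], heights[i]
        integral = (hi ** (H + 1) - lo ** (H + 1)) / (H + 1)
        binary = (stats >= hi) & mask
        labels, n = ndimage.label(binary, structure=structure)
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        c = counts[labels[binary]]
        out[binary] += c.astype(float) ** E * integral
    return out


def voxel_graph_components(graph, h):
    """Components of the voxel graph at threshold h, as flat-index frozensets.

    Nodes activate at their own statistic, edges at their min-endpoint
    weight; singleton active voxels count as their own component.
    """
    g = nx.Graph()
    for v in np.flatnonzero(graph.node_activation >= h):
        g.add_node(int(v))
    for u, v, w in zip(graph.iu, graph.iv, graph.weights):
        if w >= h:
            g.add_edge(int(u), int(v))
    return [
        frozenset(int(graph.flat_index[v]) for v in comp)
        for comp in nx.connected_components(g)
    ]
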