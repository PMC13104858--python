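"""Exact TFCE: piecewise closed-form integration over sorted statistics.

Between two consecutive sorted statistic values the cluster landscape — and
hence every cluster size c(x, h) — is constant, so the TFCE integral can be
evaluated interval by interval in closed form:

    TFCE(x) = sum_i c(x, hs(i))^E * (hs(i)^{H+1} - hs(i-1)^{H+1}) / (H+1)

over the sorted heights hs(0)=0 < hs(1) < ... <= stat(x).  No ``dh``
parameter exists; precision is exact.

The engine processes heights in descending order.  Each cluster carries a
running score and the height at which it was last flushed; touching a
cluster first flushes the pending interval in O(1).  A merge freezes both
constituents (flushed to the merge height) and creates a new cluster whose
parent pointers let any member recover its total by walking up the chain
and subtracting its recorded entry score.

Tied statistics collapse into one height: all edges at a tied height enter
before any flush below it, and the zero-length interval between ties
contributes nothing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    StatMatrix,
    TFCEMap,
    ValidationError,
    edge_arrays,
)

__all__ = [
    "interval_integral",
    "RunningCluster",
    "flush_cluster",
    "tfce_exact",
    "tfce_exact_edges",
]


def interval_integral(a: float, b: float, H: float) -> float:
    """Closed form of ``integral_a^b h^H dh = (b^{H+1} - a^{H+1})/(H+1)``."""
    if H == -1:
        raise ValidationError("height exponent -1 has no closed-form power integral")
    if not 0 <= a <= b:
        raise ValidationError(f"need 0 <= a <= b, got a={a}, b={b}")
    return (b ** (H + 1) - a ** (H + 1)) / (H + 1)


@dataclass
class RunningCluster:
    """One live or frozen cluster of the descending sweep.

    ``size`` is the cluster's TFCE extent (edge count for FC data, node
    count for voxel graphs).  ``accumulated_score`` holds the integral
    contributions flushed so far while this object was live; on a merge the
    object is frozen and ``parent`` points at its successor.
    """

    cid: int
    size: int
    last_flushed_height: float
    accumulated_score: float = 0.0
    parent: "RunningCluster | None" = None


def flush_cluster(c: RunningCluster, down_to: float, E: float, H: float) -> RunningCluster:
    """Accumulate ``size^E * integral(down_to, last_flushed_height)`` in O(1)."""
    if down_to > c.last_flushed_height:
        raise ValidationError(
            f"flush ordering violation: down_to={down_to} above "
            f"last flushed height {c.last_flushed_height}"
        )
    if down_to < c.last_flushed_height:
        c.accumulated_score += c.size**E * interval_integral(
            down_to, c.last_flushed_height, H
        )
        c.last_flushed_height = down_to
    return c


class _ExactSweep:
    """Shared descending-sweep machinery for FC and voxel-graph exact TFCE."""

    def __init__(self, n_nodes: int, E: float, H: float, count_edges: bool):
        self.E = E
        self.H = H
        self.count_edges = count_edges
        self.node_cluster: list[RunningCluster | None] = [None] * n_nodes
        self.clusters: list[RunningCluster] = []
        self._members: list[list[int]] = []

    def _new_cluster(self, size: int, h: float, members: list[int]) -> RunningCluster:
        c = RunningCluster(cid=len(self.clusters), size=size, last_flushed_height=h)
        self.clusters.append(c)
        self._members.append(members)
        return c

    def activate_node(self, v: int, h: float) -> RunningCluster:
        c = self._new_cluster(1 if not self.count_edges else 0, h, [v])
        self.node_cluster[v] = c
        return c

    def add_edge(self, u: int, v: int, h: float) -> tuple[RunningCluster, float]:
        """Insert edge (u, v) at height h; returns (entry cluster, entry score)."""
        cu = self.node_cluster[u]
        cv = self.node_cluster[v]
        if cu is None and cv is None:
            # FC only: both endpoints fresh — new cluster holding one edge
            c = self._new_cluster(1, h, [u, v])
            self.node_cluster[u] = self.node_cluster[v] = c
            return c, c.accumulated_score
        if cu is None or cv is None:
            c = cv if cu is None else cu
            flush_cluster(c, h, self.E, self.H)
            fresh = u if cu is None else v
            self.node_cluster[fresh] = c
            self._members[c.cid].append(fresh)
            c.size += 1  # FC only: one more node brings exactly this edge
            return c, c.accumulated_score
        if cu is cv:
            flush_cluster(cu, h, self.E, self.H)
            if self.count_edges:
                cu.size += 1
            return cu, cu.accumulated_score
        # distinct clusters: freeze both and create the merged successor,
        # relabeling every node of both constituents to the new object
        flush_cluster(cu, h, self.E, self.H)
        flush_cluster(cv, h, self.E, self.H)
        merged = self._new_cluster(
            cu.size + cv.size + (1 if self.count_edges else 0),
            h,
            self._members[cu.cid] + self._members[cv.cid],
        )
        cu.parent = merged
        cv.parent = merged
        for node in self._members[merged.cid]:
            self.node_cluster[node] = merged
        self._members[cu.cid] = []
        self._members[cv.cid] = []
        return merged, merged.accumulated_score

    def finish(self) -> list[float]:
        """Flush all live clusters to height 0 and resolve chain totals.

        Returns ``total[cid]`` = score accumulated in cluster cid plus in
        every ancestor along its parent chain (ancestors are created after
        their children, so a reverse pass resolves totals in one sweep).
        """
        for c in self.clusters:
            if c.parent is None:
                flush_cluster(c, 0.0, self.E, self.H)
        total = [0.0] * len(self.clusters)
        for c in reversed(self.clusters):
            total[c.cid] = c.accumulated_score + (
                total[c.parent.cid] if c.parent is not None else 0.0
            )
        return total


def tfce_exact_edges(
    n: int, iu: np.ndarray, iv: np.ndarray, stats: np.ndarray, E: float, H: float
) -> np.ndarray:
    """Exact per-edge TFCE values on upper-triangle edge arrays (FC)."""
    if H == -1:
        raise ValidationError("height exponent -1 is unsupported")
    pos = np.flatnonzero(stats > 0)
    out = np.zeros(stats.shape[0])
    if pos.size == 0:
        return out
    order = pos[np.argsort(-stats[pos], kind="stable")]
    sweep = _ExactSweep(n, E, H, count_edges=True)
    entries: list[tuple[int, RunningCluster, float]] = []
    for e in order.tolist():
        cluster, score = sweep.add_edge(int(iu[e]), int(iv[e]), float(stats[e]))
        entries.append((e, cluster, score))
    total = sweep.finish()
    for e, cluster, score in entries:
        out[e] = total[cluster.cid] - score
    return out


def tfce_exact(m: StatMatrix, E: float, H: float) -> TFCEMap:
    """Exact TFCE of an FC statistic matrix (cluster size = edge count).

    Equals the limit of the discretized TFCE as ``dh -> 0``; takes no ``dh``.
    """
    if not E > 0:
        raise ValidationError(f"extent exponent must be > 0, got {E}")
    if H < 0:
        raise ValidationError(f"height exponent must be >= 0, got {H}")
    iu, iv, stats = edge_arrays(m)
    vals = tfce_exact_edges(m.n_rois, iu, iv, stats, E, H)
    return TFCEMap.from_edge_values(m.n_rois, iu, iv, vals)
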