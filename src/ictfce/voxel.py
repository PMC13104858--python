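"""Voxel volumes as graphs, and IC-TFCE on voxel data.

A statistic volume with a binary mask becomes a graph with one node per
in-mask voxel (activating at its own statistic) and one edge per adjacent
in-mask voxel pair, weighted by the minimum of the two endpoint statistics.
Since an edge activates no later than either endpoint, the thresholded
graph has exactly the same connected voxel sets as conventional 3D
connected-component labeling of the thresholded volume — which lets the
incremental and exact FC machinery run unchanged on voxel data.

Unlike the FC engines, cluster size here counts NODES (voxels), and
isolated supra-threshold voxels form singleton clusters of size 1.  TFCE
contributions are added directly after each bin of the descending pass; no
separate accumulation matrix is needed.

Adjacency is 6- (face), 18- (face+edge) or 26-connectivity (face+edge+
corner), with 0-based array indices; no world-coordinate (affine)
reasoning happens here — affines are carried through I/O untouched.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core import (
    EmptyGridError,
    TFCEParams,
    ValidationError,
    bin_indices,
    build_threshold_grid,
)
from .exact import _ExactSweep

__all__ = [
    "VoxelImage",
    "VoxelGraph",
    "VoxelPartition",
    "connectivity_offsets",
    "voxel_to_graph",
    "ic_tfce_voxel",
    "voxel_clusters_reference",
    "voxel_tfce_reference",
    "tfce_exact_voxel",
]

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class VoxelImage:
    """A 3D statistic volume with a binary mask and a connectivity choice."""

    stats: np.ndarray
    mask: np.ndarray | None = None
    connectivity: int = 26

    def __post_init__(self) -> None:
        stats = np.asarray(self.stats, dtype=float)
        if stats.ndim != 3:
            raise ValidationError(f"expected a 3D volume, got ndim={stats.ndim}")
        mask = self.mask
        mask = np.ones(stats.shape, dtype=bool) if mask is None else np.asarray(mask, dtype=bool)
        if mask.shape != stats.shape:
            raise ValidationError(
                f"mask shape {mask.shape} does not match volume shape {stats.shape}"
            )
        if self.connectivity not in _CONNECTIVITY_RANK:
            raise ValidationError(
                f"connectivity must be one of 6, 18, 26; got {self.connectivity}"
            )
        if not np.isfinite(stats[mask]).all():
            raise ValidationError("non-finite statistic inside the mask")
        object.__setattr__(self, "stats", stats)
        object.__setattr__(self, "mask", mask)


@dataclass(frozen=True)
class VoxelGraph:
    """Graph form of a voxel volume.

    ``flat_index`` maps node id -> flat (C-order) voxel index into the
    volume; ``iu``/``iv``/``weights`` list the adjacency edges with
    ``weight = min(stat_u, stat_v)``.
    """

    shape: tuple[int, int, int]
    connectivity: int
    flat_index: np.ndarray = field(repr=False)
    node_activation: np.ndarray = field(repr=False)
    iu: np.ndarray = field(repr=False)
    iv: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)

    @property
    def n_nodes(self) -> int:
        return self.flat_index.shape[0]

    @property
    def n_links(self) -> int:
        """M, the number of adjacency links (bounded by 13*N at 26-connectivity)."""
        return self.iu.shape[0]

    def degrees(self) -> np.ndarray:
        return np.bincount(self.iu, minlength=self.n_nodes) + np.bincount(
            self.iv, minlength=self.n_nodes
        )


def connectivity_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    """Half-space neighbor offsets for 6/18/26-connectivity (no duplicates)."""
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValidationError(f"connectivity must be one of 6, 18, 26; got {connectivity}")
    max_nonzero = {6: 1, 18: 2, 26: 3}[connectivity]
    offsets = []
    for off in itertools.product((-1, 0, 1), repeat=3):
        if off == (0, 0, 0) or sum(o != 0 for o in off) > max_nonzero:
            continue
        if off > (0, 0, 0):  # lexicographically positive half only
            offsets.append(off)
    return offsets


def voxel_to_graph(img: VoxelImage) -> VoxelGraph:
    """Convert a masked volume into its node/edge representation.

    One node per in-mask voxel; one edge per in-mask adjacent pair under the
    chosen connectivity, weighted by the minimum endpoint statistic.  An
    empty mask yields an empty graph.
    """
    mask = img.mask
    shape = img.stats.shape
    node_id = np.full(shape, -1, dtype=np.int64)
    flat_index = np.flatnonzero(mask.ravel())
    node_id.ravel()[flat_index] = np.arange(flat_index.size)
    activation = img.stats.ravel()[flat_index]
    all_u: list[np.ndarray] = []
    all_v: list[np.ndarray] = []
    all_w: list[np.ndarray] = []
    for off in connectivity_offsets(img.connectivity):
        src = tuple(
            slice(max(0, -o), min(s, s - o)) for o, s in zip(off, shape)
        )
        dst = tuple(
            slice(max(0, o), min(s, s + o)) for o, s in zip(off, shape)
        )
        pair_mask = mask[src] & mask[dst]
        if not pair_mask.any():
            continue
        a = node_id[src][pair_mask]
        b = node_id[dst][pair_mask]
        w = np.minimum(img.stats[src][pair_mask], img.stats[dst][pair_mask])
        all_u.append(np.minimum(a, b))
        all_v.append(np.maximum(a, b))
        all_w.append(w)
    if all_u:
        iu = np.concatenate(all_u)
        iv = np.concatenate(all_v)
        weights = np.concatenate(all_w)
        order = np.lexsort((iv, iu))
        iu, iv, weights = iu[order], iv[order], weights[order]
    else:
        iu = iv = np.zeros(0, dtype=np.int64)
        weights = np.zeros(0)
    return VoxelGraph(
        shape=shape,
        connectivity=img.connectivity,
        flat_index=flat_index,
        node_activation=activation,
        iu=iu,
        iv=iv,
        weights=weights,
    )


def ic_tfce_voxel(img: VoxelImage, p: TFCEParams) -> np.ndarray:
    """Incremental-cluster TFCE of a voxel volume (cluster size = voxels).

    Nodes activate at their own statistic bins and edges at their weight
    bins; within a bin, node activations are processed before edges so that
    singleton clusters exist before edges join them.  After each bin the
    per-voxel TFCE contribution ``c^E * (k*dh)^H * dh`` is added directly.
    Returns a volume of TFCE values (zero outside the mask and for voxels
    with ``stat < dh``).
    """
    graph = voxel_to_graph(img)
    out = np.zeros(img.stats.shape)
    n = graph.n_nodes
    if n == 0:
        return out
    tmax = float(graph.node_activation.max())
    try:
        grid = build_threshold_grid(tmax, p.dh)
    except EmptyGridError:
        return out
    node_bins = bin_indices(graph.node_activation, p.dh)
    edge_bins = bin_indices(graph.weights, p.dh)
    node_order = np.argsort(node_bins, kind="stable")
    node_bounds = np.searchsorted(node_bins[node_order], np.arange(grid.nth + 2))
    edge_order = np.argsort(edge_bins, kind="stable")
    edge_bounds = np.searchsorted(edge_bins[edge_order], np.arange(grid.nth + 2))
    label: list[int] = [-1] * n
    members: list[list[int]] = []
    node_cnt: list[int] = []
    us = graph.iu.tolist()
    vs = graph.iv.tolist()
    tfce = np.zeros(n)
    for k in range(grid.nth, 0, -1):
        for v in node_order[node_bounds[k] : node_bounds[k + 1]].tolist():
            label[v] = len(node_cnt)
            members.append([v])
            node_cnt.append(1)
        for e in edge_order[edge_bounds[k] : edge_bounds[k + 1]].tolist():
            lu = label[us[e]]
            lv = label[vs[e]]
            if lu == lv:
                continue
            if node_cnt[lu] < node_cnt[lv]:
                lu, lv = lv, lu
            for node in members[lv]:
                label[node] = lu
            members[lu].extend(members[lv])
            members[lv] = []
            node_cnt[lu] += node_cnt[lv]
            node_cnt[lv] = 0
        lab = np.array(label)
        active = lab >= 0
        if active.any():
            c = np.array(node_cnt, dtype=float)[lab[active]]
            tfce[active] += c**p.E * (k * p.dh) ** p.H * p.dh
    out.ravel()[graph.flat_index] = tfce
    return out


@dataclass(frozen=True)
class VoxelPartition:
    """Connected-component labeling of a thresholded volume.

    ``labels`` assigns 1..n_clusters inside clusters and 0 elsewhere;
    ``sizes[cid]`` is the voxel count of cluster cid.
    """

    labels: np.ndarray
    n_clusters: int
    sizes: dict[int, int]

    def voxel_sets(self) -> list[frozenset[int]]:
        """Clusters as frozensets of flat voxel indices (order-independent)."""
        flat = self.labels.ravel()
        return [
            frozenset(np.flatnonzero(flat == cid).tolist())
            for cid in range(1, self.n_clusters + 1)
        ]


def voxel_clusters_reference(img: VoxelImage, h: float) -> VoxelPartition:
    """Oracle clustering: threshold the volume, then 3D component labeling.

    Uses :func:`scipy.ndimage.label` with the structuring element matching
    the image's connectivity; the graph-based clustering must reproduce
    these components voxel-for-voxel.
    """
    if not h > 0:
        raise ValueError(f"threshold must be > 0, got {h}")
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[img.connectivity])
    binary = (img.stats >= h) & img.mask
    labels, n = ndimage.label(binary, structure=structure)
    sizes = {
        cid: int(count)
        for cid, count in zip(range(1, n + 1), ndimage.sum_labels(binary, labels, range(1, n + 1)))
    }
    return VoxelPartition(labels=labels, n_clusters=int(n), sizes=sizes)


def voxel_tfce_reference(img: VoxelImage, p: TFCEParams) -> np.ndarray:
    """Brute-force discretized voxel TFCE: threshold, label, sum per level."""
    out = np.zeros(img.stats.shape)
    in_mask = img.stats[img.mask]
    tmax = float(in_mask.max()) if in_mask.size else 0.0
    try:
        grid = build_threshold_grid(tmax, p.dh)
    except EmptyGridError:
        return out
    structure = ndimage.generate_binary_structure(3, _CONNECTIVITY_RANK[img.connectivity])
    bins = np.where(img.mask, bin_indices(img.stats, p.dh), 0)
    for k in range(1, grid.nth + 1):
        binary = bins >= k
        if not binary.any():
            continue
        labels, n = ndimage.label(binary, structure=structure)
        counts = np.bincount(labels.ravel(), minlength=n + 1)
        c = counts[labels[binary]]
        out[binary] += c.astype(float) ** p.E * (k * p.dh) ** p.H * p.dh
    return out


def tfce_exact_voxel(img: VoxelImage, E: float, H: float) -> np.ndarray:
    """Exact (discretization-free) TFCE on the voxel graph.

    Cluster size counts voxels; heights are the sorted distinct statistics.
    Node activations at a given height are processed before edges at that
    height, mirroring the incremental engine's bin ordering.
    """
    graph = voxel_to_graph(img)
    out = np.zeros(img.stats.shape)
    if graph.n_nodes == 0:
        return out
    # events: (height, kind, index); kind 0 = node activation, 1 = edge
    nodes = np.flatnonzero(graph.node_activation > 0)
    edges = np.flatnonzero(graph.weights > 0)
    events = [(float(graph.node_activation[v]), 0, int(v)) for v in nodes]
    events += [(float(graph.weights[e]), 1, int(e)) for e in edges]
    events.sort(key=lambda t: (-t[0], t[1], t[2]))
    sweep = _ExactSweep(graph.n_nodes, E, H, count_edges=False)
    node_entry: dict[int, int] = {}
    for h, kind, idx in events:
        if kind == 0:
            c = sweep.activate_node(idx, h)
            node_entry[idx] = c.cid
        else:
            sweep.add_edge(int(graph.iu[idx]), int(graph.iv[idx]), h)
    total = sweep.finish()
    tfce = np.zeros(graph.n_nodes)
    for v, cid in node_entry.items():
        tfce[v] = total[cid]
    out.ravel()[graph.flat_index] = tfce
    return out
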