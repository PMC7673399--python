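"""Spatial skeleton graph: construction, neighborhood partitioning, normalization.

The skeleton of a single frame is an undirected graph whose edges are the
natural bone connections.  Graph convolution over it needs (a) a partition of
each node's neighborhood into *root*, *centripetal* (closer to the body
center) and *centrifugal* (farther) subsets, and (b) symmetrically
degree-normalized adjacency operators, one per subset.

"Closer to the body center" is measured by hop distance to a fixed center
joint (the spine base) on the template skeleton, so the partition is static
across frames — a requirement for fixed convolution operators, and consistent
with every frame being re-centered on the spine base anyway.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .gait import DEFAULT_KEYPOINT_INDICES, N_JOINTS, JointSubset

#: Bone list of the 25-joint Kinect V2 skeleton (a spanning tree: 24 edges).
KINECT_V2_EDGES: tuple[tuple[int, int], ...] = (
    (0, 1), (1, 20), (20, 2), (2, 3),          # spine and head
    (20, 4), (4, 5), (5, 6), (6, 7), (7, 21), (6, 22),      # left arm
    (20, 8), (8, 9), (9, 10), (10, 11), (11, 23), (10, 24),  # right arm
    (0, 12), (12, 13), (13, 14), (14, 15),     # left leg
    (0, 16), (16, 17), (17, 18), (18, 19),     # right leg
)

#: Bridges restoring connectivity after key-point selection: dropping the
#: torso joints severs the right shoulder from the spine base, so the bone
#: chain is shortened to a direct SpineBase–ShoulderRight link.
DEFAULT_KEYPOINT_BRIDGES: tuple[tuple[int, int], ...] = ((0, 8),)


@dataclass(frozen=True)
class SkeletonGraph:
    """Undirected graph over ``n_nodes`` joints with a designated center."""

    n_nodes: int
    edges: tuple[tuple[int, int], ...]
    center_index: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for a, b in self.edges:
            if a == b:
                raise ValueError(f"self-edge ({a}, {b})")
            if not (0 <= a < self.n_nodes and 0 <= b < self.n_nodes):
                raise ValueError(f"edge ({a}, {b}) out of range for V={self.n_nodes}")
            key = (min(a, b), max(a, b))
            if key in seen:
                raise ValueError(f"duplicate edge {key}")
            seen.add(key)
        if not 0 <= self.center_index < self.n_nodes:
            raise ValueError("center index out of range")

    @property
    def adjacency(self) -> np.ndarray:
        """Symmetric binary adjacency with zero diagonal."""
        A = np.zeros((self.n_nodes, self.n_nodes))
        for a, b in self.edges:
            A[a, b] = A[b, a] = 1.0
        return A

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def hop_distances(self, source: int) -> np.ndarray:
        """Breadth-first hop distances from ``source``; unreachable = -1."""
        dist = np.full(self.n_nodes, -1, dtype=int)
        dist[source] = 0
        frontier = [source]
        A = self.adjacency
        while frontier:
            nxt = []
            for u in frontier:
                for v in np.nonzero(A[u])[0]:
                    if dist[v] < 0:
                        dist[v] = dist[u] + 1
                        nxt.append(int(v))
            frontier = nxt
        return dist

    def is_connected(self) -> bool:
        return bool((self.hop_distances(self.center_index) >= 0).all())


@dataclass(frozen=True)
class PartitionedAdjacency:
    """Three degree-normalized adjacency operators (root, centripetal, centrifugal).

    ``masks`` are the unnormalized binary assignment matrices; they are
    elementwise disjoint and sum exactly to A + I.  ``subsets`` are the
    normalized operators Λ^{-1/2} · mask · Λ^{-1/2}, all sharing the degree
    matrix Λ of the full A + I.
    """

    subsets: np.ndarray  # (3, V, V) normalized
    masks: np.ndarray    # (3, V, V) binary
    degrees: np.ndarray  # (V,) degrees of A + I

    @property
    def n_nodes(self) -> int:
        return int(self.subsets.shape[1])


def build_graph(
    edges: Iterable[tuple[int, int]],
    n_nodes: int,
    center_index: int = 0,
) -> SkeletonGraph:
    return SkeletonGraph(n_nodes, tuple((int(a), int(b)) for a, b in edges), center_index)


def kinect_v2_graph() -> SkeletonGraph:
    """The default 25-joint skeleton graph, centered on the spine base."""
    return build_graph(KINECT_V2_EDGES, N_JOINTS, center_index=0)


def induced_subgraph(
    graph: SkeletonGraph,
    subset: JointSubset,
    bridges: Sequence[tuple[int, int]] = (),
) -> SkeletonGraph:
    """Subgraph on ``subset`` (nodes reindexed ascending), plus bridge edges.

    Bones whose intermediate joints were removed can be re-linked by listing
    bridges in *original* joint indices.  If the original center joint is not
    in the subset, the retained joint closest to it becomes the new center.
    """
    keep = list(subset.indices)
    if keep[-1] >= graph.n_nodes:
        raise ValueError("subset index out of range for graph")
    remap = {old: new for new, old in enumerate(keep)}
    edges = [
        (remap[a], remap[b])
        for a, b in graph.edges
        if a in remap and b in remap
    ]
    for a, b in bridges:
        if a in remap and b in remap:
            e = (remap[a], remap[b])
            if e not in edges and (e[1], e[0]) not in edges:
                edges.append(e)
    if graph.center_index in remap:
        center = remap[graph.center_index]
    else:
        dist = graph.hop_distances(graph.center_index)
        center = remap[min(keep, key=lambda j: dist[j] if dist[j] >= 0 else np.inf)]
    return SkeletonGraph(len(keep), tuple(edges), center)


def keypoint_graph(
    indices: Sequence[int] = DEFAULT_KEYPOINT_INDICES,
    bridges: Sequence[tuple[int, int]] = DEFAULT_KEYPOINT_BRIDGES,
) -> SkeletonGraph:
    """The default key-point subgraph (lower body + right upper limb)."""
    return induced_subgraph(kinect_v2_graph(), JointSubset(tuple(indices)), bridges)


def partition_spatial_configuration(graph: SkeletonGraph) -> np.ndarray:
    """Binary assignment masks (3, V, V) under the spatial-configuration rule.

    For each node i, every neighbor j of A + I is assigned to exactly one
    subset: *root* iff j == i; *centripetal* iff j is at most as close to the
    center as i (ties go centripetal); *centrifugal* iff j is farther.
    Row i of mask k holds the neighbors of i assigned to subset k.
    """
    if not graph.is_connected():
        dist = graph.hop_distances(graph.center_index)
        stranded = np.nonzero(dist < 0)[0].tolist()
        raise ValueError(f"graph is disconnected; stranded nodes: {stranded}")
    V = graph.n_nodes
    A = graph.adjacency
    dist = graph.hop_distances(graph.center_index)
    masks = np.zeros((3, V, V))
    for i in range(V):
        masks[0, i, i] = 1.0  # the node itself, via the self-connection
        for j in np.nonzero(A[i])[0]:
            if dist[j] <= dist[i]:
                masks[1, i, j] = 1.0
            else:
                masks[2, i, j] = 1.0
    return masks


def normalize_adjacency(mask: np.ndarray, degrees: np.ndarray | None = None) -> np.ndarray:
    """Symmetric normalization Λ^{-1/2} · mask · Λ^{-1/2}.

    ``degrees`` defaults to the row sums of ``mask`` itself; pass the degrees
    of the full A + I when normalizing a partition subset so that all three
    subsets share one Λ.  Zero-degree rows yield zero rows.
    """
    mask = np.asarray(mask, dtype=np.float64)
    if mask.ndim != 2 or mask.shape[0] != mask.shape[1]:
        raise ValueError("mask must be square")
    if (mask < 0).any():
        raise ValueError("mask must be nonnegative")
    if degrees is None:
        degrees = mask.sum(axis=1)
    degrees = np.asarray(degrees, dtype=np.float64)
    inv_sqrt = np.zeros_like(degrees)
    nz = degrees > 0
    inv_sqrt[nz] = degrees[nz] ** -0.5
    return inv_sqrt[:, None] * mask * inv_sqrt[None, :]


def partition_adjacency(graph: SkeletonGraph) -> PartitionedAdjacency:
    """Partition the graph and normalize each subset with the shared Λ of A + I."""
    masks = partition_spatial_configuration(graph)
    a_plus_i = graph.adjacency + np.eye(graph.n_nodes)
    degrees = a_plus_i.sum(axis=1)
    subsets = np.stack([normalize_adjacency(m, degrees) for m in masks])
    return PartitionedAdjacency(subsets=subsets, masks=masks, degrees=degrees)
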