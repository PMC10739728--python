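"""Minimum-spanning-tree cluster lineage inference with start/end constraints.

Cluster centroids (2-D embedding coordinates by default) are joined by a
Euclidean MST over the non-terminal clusters; each designated end cluster is
then attached by a single edge to its nearest non-terminal cluster, which
guarantees terminality. Lineages are the root-to-leaf paths from the start
cluster. Per-cell pseudotime is the arc length of the cell's orthogonal
projection onto the piecewise-linear path through its lineage's centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_embed import Embedding


@dataclass
class LineageGraph:
    centroids: pd.DataFrame  # index cluster; columns x, y (or PC space)
    edges: list[tuple[int, int, float]]  # (a, b, distance), a < b
    lineages: list[list[int]]  # ordered cluster paths from start
    start: int
    ends: tuple[int, ...]


def _kruskal_mst(nodes: list[int], coords: np.ndarray) -> list[tuple[int, int, float]]:
    """Deterministic MST: edges sorted by (distance, a, b), union-find."""
    index = {c: i for i, c in enumerate(nodes)}
    edges = []
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            d = float(np.linalg.norm(coords[index[a]] - coords[index[b]]))
            edges.append((d, a, b))
    edges.sort()
    parent = {c: c for c in nodes}

    def find(c):
        while parent[c] != c:
            parent[c] = parent[parent[c]]
            c = parent[c]
        return c

    out = []
    for d, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            out.append((a, b, d))
        if len(out) == len(nodes) - 1:
            break
    return out


def infer_lineages(
    embedding: Embedding,
    start: int,
    ends=(),
    space: str = "embedding",
) -> LineageGraph:
    """Build the constrained MST over cluster centroids and extract lineages.

    ``space`` selects the coordinate system: ``"embedding"`` (2-D, default)
    or ``"pca"``. ``start`` must not be in ``ends``.
    """
    if embedding.labels is None:
        raise ValueError("embedding has no cluster labels")
    ends = tuple(int(e) for e in ends)
    start = int(start)
    if start in ends:
        raise ValueError("start cluster cannot also be an end cluster")
    labels = np.asarray(embedding.labels)
    clusters = sorted(int(c) for c in np.unique(labels))
    if len(clusters) < 2:
        raise ValueError("need at least 2 clusters")
    for c in (start, *ends):
        if c not in clusters:
            raise ValueError(f"cluster {c} does not exist")
    if space == "embedding":
        if embedding.umap is None:
            raise ValueError("embedding carries no 2-D coordinates")
        coords_all = embedding.umap
    elif space == "pca":
        coords_all = embedding.pcs
    else:
        raise ValueError(f"unknown space {space!r}")

    centroids = np.vstack([coords_all[labels == c].mean(axis=0) for c in clusters])
    cent_df = pd.DataFrame(
        centroids,
        index=pd.Index(clusters, name="cluster"),
        columns=[f"dim{i + 1}" for i in range(centroids.shape[1])],
    )

    non_end = [c for c in clusters if c not in ends]
    if not non_end:
        raise ValueError("at least one cluster must be non-terminal")
    pos = {c: centroids[clusters.index(c)] for c in clusters}
    edges = _kruskal_mst(non_end, np.vstack([pos[c] for c in non_end]))
    for e in ends:
        dists = [(float(np.linalg.norm(pos[e] - pos[c])), c) for c in non_end]
        _, nearest = min(dists)
        a, b = min(e, nearest), max(e, nearest)
        edges.append((a, b, float(np.linalg.norm(pos[a] - pos[b]))))

    adj: dict[int, list[int]] = {c: [] for c in clusters}
    for a, b, _ in edges:
        adj[a].append(b)
        adj[b].append(a)
    for c in adj:
        adj[c].sort()

    # Root-to-leaf paths from the start cluster (DFS, deterministic order).
    lineages: list[list[int]] = []

    def walk(node: int, path: list[int]) -> None:
        children = [c for c in adj[node] if c not in path]
        if not children:
            lineages.append(path.copy())
            return
        for c in children:
            walk(c, path + [c])

    walk(start, [start])
    lineages.sort(key=lambda p: p[-1])
    return LineageGraph(
        centroids=cent_df,
        edges=sorted((min(a, b), max(a, b), d) for a, b, d in edges),
        lineages=lineages,
        start=start,
        ends=ends,
    )


def _project_on_polyline(point: np.ndarray, path: np.ndarray) -> float:
    """Arc length of the closest point on a piecewise-linear path."""
    best_d2 = np.inf
    best_arc = 0.0
    arc = 0.0
    for i in range(len(path) - 1):
        a, b = path[i], path[i + 1]
        seg = b - a
        seg_len = float(np.linalg.norm(seg))
        if seg_len == 0:
            t = 0.0
        else:
            t = float(np.clip(np.dot(point - a, seg) / seg_len**2, 0.0, 1.0))
        proj = a + t * seg
        d2 = float(((point - proj) ** 2).sum())
        if d2 < best_d2 - 1e-12:
            best_d2 = d2
            best_arc = arc + t * seg_len
        arc += seg_len
    if len(path) == 1:
        return 0.0
    return min(best_arc, arc)


def pseudotime(
    graph: LineageGraph, embedding: Embedding, space: str = "embedding"
) -> np.ndarray:
    """Arc-length pseudotime of each cell along its lineage's centroid path."""
    labels = np.asarray(embedding.labels)
    coords = embedding.umap if space == "embedding" else embedding.pcs
    lineage_of: dict[int, int] = {}
    for li, path in enumerate(graph.lineages):
        for c in path:
            lineage_of.setdefault(c, li)
    missing = [c for c in np.unique(labels) if int(c) not in lineage_of]
    if missing:
        raise ValueError(f"clusters {missing} lie on no lineage")
    cent = graph.centroids.to_numpy()
    cluster_index = {c: i for i, c in enumerate(graph.centroids.index)}
    paths = [
        np.vstack([cent[cluster_index[c]] for c in path]) for path in graph.lineages
    ]
    out = np.empty(len(labels))
    for i, lab in enumerate(labels):
        out[i] = _project_on_polyline(coords[i], paths[lineage_of[int(lab)]])
    return out
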