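"""Distance-based phylogenetics over sample profiles.

Samples (tumor regions) are rows of a binary mutation matrix or a
copy-number weight matrix; the distance between two samples is one minus
their Pearson correlation across loci/regions.  Trees are built with
Neighbor-Joining (Saitou & Nei; unrooted, reported with a trifurcating
root) and UPGMA (rooted, ultrametric), both implemented here so that
tie-breaking is deterministic across platforms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import ClusterScheme, default_min_support

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "SampleTree",
    "pearson_distance",
    "neighbor_joining",
    "upgma",
    "cut_clusters",
]


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal distance matrix over labeled samples."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise PhyloError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.all(np.isfinite(self.d)):
            raise PhyloError("distance matrix contains non-finite entries")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise PhyloError("distance matrix is not symmetric")

    def value(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.d[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.labels, columns=self.labels)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="sample")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0  # branch length to parent
    children: list["TreeNode"] = field(default_factory=list)
    height: float = 0.0  # UPGMA merge height; 0 at leaves

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out: list[TreeNode] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.leaves()]

    def min_leaf(self) -> str:
        return min(self.leaf_names())


@dataclass
class SampleTree:
    """Rooted or unrooted (trifurcating-root) tree over sample labels."""

    root: TreeNode
    rooted: bool = True

    def leaf_names(self) -> list[str]:
        return self.root.leaf_names()

    def to_newick(self, precision: int = 6) -> str:
        def fmt(node: TreeNode, top: bool) -> str:
            if node.is_leaf:
                body = node.name
            else:
                body = "(" + ",".join(fmt(c, False) for c in node.children) + ")"
                if node.name:
                    body += node.name
            if top:
                return body
            return f"{body}:{node.length:.{precision}f}"

        return fmt(self.root, True) + ";"

    def cophenetic(self) -> DistanceMatrix:
        """Path-length (patristic) distances between all leaf pairs."""
        labels = sorted(self.leaf_names())
        idx = {name: i for i, name in enumerate(labels)}
        n = len(labels)
        d = np.zeros((n, n))

        def walk(node: TreeNode) -> dict[str, float]:
            if node.is_leaf:
                return {node.name: 0.0}
            maps = []
            for c in node.children:
                m = walk(c)
                maps.append({k: v + c.length for k, v in m.items()})
            for ma, mb in itertools.combinations(maps, 2):
                for a, da in ma.items():
                    for b, db in mb.items():
                        d[idx[a], idx[b]] = d[idx[b], idx[a]] = da + db
            merged: dict[str, float] = {}
            for m in maps:
                merged.update(m)
            return merged

        walk(self.root)
        return DistanceMatrix(labels, d)


def pearson_distance(values, labels: list[str] | None = None) -> DistanceMatrix:
    """1 - Pearson correlation between sample rows.

    ``values`` is a samples x loci array or DataFrame (index = samples).
    The correlation is computed over all retained columns (loci present in
    every sample stay in, matching the presence-filtered discovery matrix);
    a sample with a constant profile has undefined correlation and raises
    an error naming it.
    """
    if isinstance(values, pd.DataFrame):
        labels = list(values.index)
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
        if labels is None:
            raise PhyloError("labels required for array input")
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise PhyloError("need at least 2 sample rows")
    if arr.shape[1] < 2:
        raise PhyloError("need at least 2 loci/region columns")
    sd = arr.std(axis=1)
    for lab, s in zip(labels, sd):
        if s == 0:
            raise PhyloError(f"sample {lab!r} has a constant profile; correlation undefined")
    rho = np.corrcoef(arr)
    d = 1.0 - rho
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    d = np.clip(d, 0.0, 2.0)
    return DistanceMatrix(list(labels), d)


def _check_matrix(D: DistanceMatrix, min_n: int) -> None:
    if len(D.labels) < min_n:
        raise PhyloError(f"need at least {min_n} taxa, got {len(D.labels)}")


def neighbor_joining(D: DistanceMatrix) -> SampleTree:
    """Saitou-Nei Neighbor-Joining.

    At each step the pair minimizing
    ``Q(i, j) = (m - 2) d(i, j) - r_i - r_j`` (``r`` = row sums over active
    nodes) is joined; ties are broken by the lexicographically smallest
    (min-leaf, min-leaf) label pair.  Branch lengths follow the standard
    formulas and may be negative; the result is unrooted, represented with
    a trifurcating root.  On an additive matrix the tree's path metric
    reproduces the input exactly.
    """
    _check_matrix(D, 3)
    nodes: list[TreeNode] = [TreeNode(name=l) for l in D.labels]
    dist: dict[frozenset[int], float] = {}
    ids = list(range(len(nodes)))
    for i, j in itertools.combinations(ids, 2):
        dist[frozenset((i, j))] = float(D.d[i, j])
    next_id = len(nodes)
    node_of = dict(zip(ids, nodes))
    active = list(ids)

    def d(a: int, b: int) -> float:
        return dist[frozenset((a, b))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active if k != i) for i in active}
        best = None
        for i, j in itertools.combinations(active, 2):
            q = (m - 2) * d(i, j) - r[i] - r[j]
            key = tuple(sorted((node_of[i].min_leaf(), node_of[j].min_leaf())))
            cand = (q, key, i, j)
            if best is None or (q < best[0] - 1e-12) or (
                abs(q - best[0]) <= 1e-12 and key < best[1]
            ):
                best = cand
        _, _, i, j = best
        li = 0.5 * d(i, j) + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d(i, j) - li
        node_of[i].length = li
        node_of[j].length = lj
        u = next_id
        next_id += 1
        node_of[u] = TreeNode(children=[node_of[i], node_of[j]])
        for k in active:
            if k in (i, j):
                continue
            dist[frozenset((u, k))] = 0.5 * (d(i, k) + d(j, k) - d(i, j))
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (d(i, j) + d(i, k) - d(j, k))
    lj = 0.5 * (d(i, j) + d(j, k) - d(i, k))
    lk = 0.5 * (d(i, k) + d(j, k) - d(i, j))
    for idx, ln in zip((i, j, k), (li, lj, lk)):
        node_of[idx].length = ln
    children = sorted((node_of[i], node_of[j], node_of[k]), key=TreeNode.min_leaf)
    root = TreeNode(children=children)
    return SampleTree(root=root, rooted=False)


def upgma(D: DistanceMatrix) -> SampleTree:
    """Average-linkage agglomeration; rooted ultrametric tree.

    A merged node sits at height d(pair)/2; cluster-to-cluster distances
    are size-weighted arithmetic means of the member distances (classic
    UPGMA), so on an ultrametric input the cophenetic distances equal the
    input exactly.  Ties broken as in :func:`neighbor_joining`.
    """
    _check_matrix(D, 2)
    nodes: dict[int, TreeNode] = {i: TreeNode(name=l) for i, l in enumerate(D.labels)}
    size = {i: 1 for i in nodes}
    dist: dict[frozenset[int], float] = {}
    for i, j in itertools.combinations(range(len(D.labels)), 2):
        v = float(D.d[i, j])
        if not np.isfinite(v):
            raise PhyloError("non-finite distance")
        dist[frozenset((i, j))] = v
    active = list(nodes)
    next_id = len(nodes)

    while len(active) > 1:
        best = None
        for i, j in itertools.combinations(active, 2):
            v = dist[frozenset((i, j))]
            key = tuple(sorted((nodes[i].min_leaf(), nodes[j].min_leaf())))
            if best is None or (v < best[0] - 1e-12) or (
                abs(v - best[0]) <= 1e-12 and key < best[1]
            ):
                best = (v, key, i, j)
        v, _, i, j = best
        h = v / 2.0
        nodes[i].length = h - nodes[i].height
        nodes[j].length = h - nodes[j].height
        u = next_id
        next_id += 1
        kids = sorted((nodes[i], nodes[j]), key=TreeNode.min_leaf)
        nodes[u] = TreeNode(children=kids, height=h)
        size[u] = size[i] + size[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[frozenset((i, k))]
            djk = dist[frozenset((j, k))]
            dist[frozenset((u, k))] = (size[i] * dik + size[j] * djk) / size[u]
        active = [k for k in active if k not in (i, j)] + [u]

    return SampleTree(root=nodes[active[0]], rooted=True)


def cut_clusters(tree: SampleTree, k: int) -> ClusterScheme:
    """Cut a rooted ultrametric tree into ``k`` leaf groups.

    The k - 1 highest internal nodes are opened (root first), i.e. the
    standard maxclust cut of an agglomerative dendrogram.  Tie between
    equal-height nodes goes to the one with the smallest leaf label.
    Groups are labeled C1..Ck in order of their smallest member.
    """
    if not tree.rooted:
        raise PhyloError("tree cut requires a rooted tree")
    n = len(tree.leaf_names())
    if not 1 <= k <= n:
        raise PhyloError(f"k={k} out of range [1, {n}]")
    groups: list[TreeNode] = [tree.root]
    while len(groups) < k:
        splittable = [g for g in groups if not g.is_leaf]
        node = min(splittable, key=lambda g: (-g.height, g.min_leaf()))
        groups.remove(node)
        groups.extend(node.children)
    groups.sort(key=TreeNode.min_leaf)
    clusters = {f"C{i + 1}": sorted(g.leaf_names()) for i, g in enumerate(groups)}
    return ClusterScheme(
        clusters=clusters,
        min_support={c: default_min_support(len(m)) for c, m in clusters.items()},
    )
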