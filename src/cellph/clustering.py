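"""Agglomerative clustering from a distance matrix, dendrogram cuts, purity.

Bottom-up merging under four linkages (average/single/complete and a
medoid-based Ward), all defined purely from the pairwise distances —
no coordinates are assumed, because the Wasserstein distance between
persistence diagrams is not Euclidean.  The medoid form of Ward's SSE
means merge heights are not guaranteed monotone; they are reported as
computed.

The purity of a cluster C1 with respect to another linkage's tree T2 is
(N - |O|) / (N - |C1|), where O is the leaf set of the smallest subtree of
T2 containing all of C1 (equivalently, of the subtree rooted at the lowest
common ancestor of C1).  Purity 1 means C1 appears as its own subtree in
T2; purity 0 means only the root contains it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, MalformedInputError, ParameterError
from .wasserstein import DistanceMatrix

__all__ = ["Dendrogram", "ClusterAssignment", "LINKAGES", "hca", "cut", "purity"]

LINKAGES = ("average", "single", "complete", "ward")


@dataclass(frozen=True)
class Dendrogram:
    """Merge tree: leaves are 0..n-1; merge i creates cluster id n+i.

    Each merge is (cluster_a, cluster_b, height, new_cluster_id) with
    cluster_a < cluster_b; there are exactly n-1 merges.
    """

    merges: tuple
    leaf_ids: tuple

    def __post_init__(self):
        object.__setattr__(self, "merges", tuple(tuple(m) for m in self.merges))
        object.__setattr__(self, "leaf_ids", tuple(self.leaf_ids))
        if len(self.merges) != len(self.leaf_ids) - 1:
            raise MalformedInputError(
                f"{len(self.leaf_ids)} leaves need {len(self.leaf_ids) - 1} merges, "
                f"got {len(self.merges)}"
            )

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def members(self) -> dict[int, frozenset]:
        """Leaf-index set of every node (leaves and internal clusters)."""
        out = {i: frozenset([i]) for i in range(self.n_leaves)}
        for a, b, _, new in self.merges:
            out[new] = out[a] | out[b]
        return out

    def parents(self) -> dict[int, int]:
        out = {}
        for a, b, _, new in self.merges:
            out[a] = out[b] = new
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.merges), columns=["cluster_a", "cluster_b", "height", "new_cluster_id"]
        )

    def to_newick(self) -> str:
        """Newick serialisation with merge heights as branch lengths."""
        height = {i: 0.0 for i in range(self.n_leaves)}
        label: dict[int, str] = {i: str(self.leaf_ids[i]) for i in range(self.n_leaves)}
        for a, b, h, new in self.merges:
            la = f"{label[a]}:{max(h - height[a], 0.0):.8g}"
            lb = f"{label[b]}:{max(h - height[b], 0.0):.8g}"
            label[new] = f"({la},{lb})"
            height[new] = h
        root = self.merges[-1][3] if self.merges else 0
        return label[root] + ";"


@dataclass(frozen=True)
class ClusterAssignment:
    """Flat clustering: maps every cell id to one of k cluster names."""

    labels: dict
    k: int

    def __post_init__(self):
        if len(set(self.labels.values())) != self.k:
            raise ParameterError("number of distinct labels does not match k")

    def groups(self) -> dict[str, tuple]:
        out: dict[str, list] = {}
        for cid, name in self.labels.items():
            out.setdefault(name, []).append(cid)
        return {name: tuple(sorted(ids)) for name, ids in out.items()}


def _medoid_sse(cluster: Sequence[int], d: np.ndarray) -> float:
    """Sum of squared distances to the cluster medoid.

    The medoid is the member with least total distance to the others;
    ties are broken by the smallest index.
    """
    idx = np.asarray(cluster)
    sub = d[np.ix_(idx, idx)]
    medoid = int(np.argmin(sub.sum(axis=1)))  # argmin returns first = smallest index
    return float(np.sum(sub[medoid] ** 2))


def _linkage_distance(a: Sequence[int], b: Sequence[int], d: np.ndarray, linkage: str) -> float:
    block = d[np.ix_(np.asarray(a), np.asarray(b))]
    if linkage == "average":
        return float(block.mean())
    if linkage == "single":
        return float(block.min())
    if linkage == "complete":
        return float(block.max())
    if linkage == "ward":
        return _medoid_sse(list(a) + list(b), d) - _medoid_sse(a, d) - _medoid_sse(b, d)
    raise ParameterError(f"unknown linkage {linkage!r}")


def hca(m: DistanceMatrix, linkage: str = "average") -> Dendrogram:
    """Agglomerative hierarchical clustering of a distance matrix.

    At each step the pair of active clusters with the minimal inter-cluster
    distance under the chosen linkage is merged, at a height equal to that
    distance.  Ties are broken lexicographically by (smaller cluster id,
    larger cluster id).
    """
    if linkage not in LINKAGES:
        raise ParameterError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    d = m.values
    n = len(m)
    if n < 2:
        raise MalformedInputError("need at least 2 objects")
    active: dict[int, list[int]] = {i: [i] for i in range(n)}
    pair = {
        (i, j): _linkage_distance(active[i], active[j], d, linkage)
        for i, j in itertools.combinations(range(n), 2)
    }
    merges = []
    next_id = n
    for _ in range(n - 1):
        dist, i, j = min((v, i, j) for (i, j), v in pair.items())
        new = next_id
        active[new] = active.pop(i) + active.pop(j)
        merges.append((i, j, dist, new))
        next_id += 1
        pair = {key: v for key, v in pair.items() if i not in key and j not in key}
        for other in active:
            if other != new:
                pair[(other, new)] = _linkage_distance(active[other], active[new], d, linkage)
    return Dendrogram(tuple(merges), tuple(m.ids))


def _cluster_names(count: int) -> list[str]:
    import string

    names = list(string.ascii_uppercase)
    while len(names) < count:
        names.append(f"Z{len(names)}")
    return names[:count]


def cut(dendro: Dendrogram, k: int) -> ClusterAssignment:
    """Cut a dendrogram into k clusters by removing the k-1 highest merges.

    The remaining merges connect the leaves into exactly k components.
    Cluster names A, B, C, ... are assigned by decreasing size, ties by
    the smallest contained leaf index.
    """
    n = dendro.n_leaves
    if not 1 <= k <= n:
        raise ParameterError(f"k must be in [1, {n}], got {k}")
    order = sorted(range(len(dendro.merges)), key=lambda i: (dendro.merges[i][2], i))
    kept = order[: n - k]
    members = dendro.members()
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for mi in kept:
        a, b, _, _ = dendro.merges[mi]
        leaves_a, leaves_b = members[a], members[b]
        ra = find(min(leaves_a))
        for leaf in itertools.chain(leaves_a, leaves_b):
            rb = find(leaf)
            if rb != ra:
                parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for leaf in range(n):
        comps.setdefault(find(leaf), []).append(leaf)
    ordered = sorted(comps.values(), key=lambda c: (-len(c), min(c)))
    names = _cluster_names(len(ordered))
    labels = {}
    for name, comp in zip(names, ordered):
        for leaf in comp:
            labels[dendro.leaf_ids[leaf]] = name
    return ClusterAssignment(labels=labels, k=k)


def purity(c1: Iterable, tree: Dendrogram) -> float:
    """Purity (N - |O|) / (N - |C1|) of cell-id set c1 within a dendrogram.

    O is the leaf set of the smallest subtree of ``tree`` containing all
    of c1 — the subtree rooted at the lowest common ancestor.  This is the
    fixed point of the seed-walk definition (grow from any seed leaf by
    repeatedly moving to the parent until C1 is covered), and is therefore
    independent of the chosen seed.
    """
    ids = set(c1)
    if not ids:
        raise DomainError("c1 must be non-empty")
    id_to_leaf = {cid: i for i, cid in enumerate(tree.leaf_ids)}
    missing = ids - set(id_to_leaf)
    if missing:
        raise MalformedInputError(f"ids not in tree: {sorted(missing)!r}")
    leaves = {id_to_leaf[cid] for cid in ids}
    n = tree.n_leaves
    if len(leaves) == n:
        raise DomainError("purity is undefined when c1 is the full leaf set")
    members = tree.members()
    parents = tree.parents()
    node = min(leaves)
    while not leaves <= members[node]:
        node = parents[node]
    O = members[node]
    p = (n - len(O)) / (n - len(leaves))
    return float(min(max(p, 0.0), 1.0))
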