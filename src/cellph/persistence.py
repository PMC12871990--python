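"""Radial sub-level filtration and dimension-0 persistence with essential pairing.

The filtration function assigns to each graph vertex its Euclidean distance
to the nucleus centre; an edge enters the filtration at the maximum of its
endpoint values.  Tracking connected components of the sub-level graphs
G_a = f^{-1}((-inf, a]) under the elder rule yields the dimension-0
persistence diagram.  The single essential component (born at min f) is
paired with the birth of the essential 1-cycle, which occurs when the last
vertex enters, i.e. at max f — so every diagram point is finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour, ContourGraph, NucleusCenter, build_graph, clean_graph, contains_point
from .errors import ContractError, GeometryError

__all__ = [
    "VertexFunction",
    "PersistenceDiagram",
    "radial_function",
    "sublevel_diagram0",
    "diagram_for_cell",
]


@dataclass(frozen=True)
class VertexFunction:
    """Filtration values aligned with the vertices of a ContourGraph."""

    values: np.ndarray

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float).ravel()
        object.__setattr__(self, "values", vals)
        if np.any(vals < 0):
            raise ContractError("radial filtration values must be >= 0")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PersistenceDiagram:
    """Finite multiset of (birth, death) pairs, essential point included.

    After essential pairing exactly one point has birth = min f and
    death = max f; all other points record elder-rule component deaths.
    Points are stored sorted lexicographically.
    """

    points: np.ndarray
    id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        order = np.lexsort((pts[:, 1], pts[:, 0]))
        pts = pts[order]
        object.__setattr__(self, "points", pts)
        if np.any(pts[:, 0] > pts[:, 1]):
            raise ContractError("diagram has a point with birth > death")
        if not np.all(np.isfinite(pts)):
            raise ContractError("diagram has non-finite coordinates")

    def __len__(self) -> int:
        return len(self.points)

    def multiplicity(self, birth: float, death: float, tol: float = 0.0) -> int:
        """Number of diagram points equal to (birth, death) within tol."""
        d = np.abs(self.points - np.array([birth, death]))
        return int(np.sum(np.all(d <= tol, axis=1)))

    def to_dict(self) -> dict:
        return {"id": self.id, "points": self.points.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "PersistenceDiagram":
        return cls(np.asarray(d["points"], dtype=float), id=d.get("id", ""))


def radial_function(g: ContourGraph, ctr: NucleusCenter) -> VertexFunction:
    """Euclidean distance of each vertex to the nucleus centre.

    The centre must lie strictly inside the contour traced by the graph.
    """
    c = Contour(g.vertices, unit="pixel", id=g.id)
    if not contains_point(c, ctr.xy):
        raise GeometryError(f"centre {ctr.xy.tolist()} is not strictly inside contour {g.id!r}")
    return VertexFunction(np.linalg.norm(g.vertices - ctr.xy, axis=1))


def sublevel_diagram0(g: ContourGraph, f: VertexFunction, id: str | None = None) -> PersistenceDiagram:
    """Dimension-0 sub-level persistence of (g, f) with essential pairing.

    Union-find over vertices; edges are processed in increasing order of
    their entry value max(f(u), f(v)) (ties: vertices first, then edges in
    index order).  When two components merge, the one whose canonical
    representative has the lower (value, index) survives (elder rule); the
    younger dies, contributing a point (its birth, merge value).  Points of
    zero persistence created by a vertex entering an existing component are
    not part of the diagram.  The surviving essential component yields the
    point (min f, max f).
    """
    vals = f.values
    n = len(g)
    if len(vals) != n:
        raise ContractError(f"function has {len(vals)} values for a {n}-vertex graph")

    parent = np.arange(n)

    def find(i: int) -> int:
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    # birth key of a component = (f value, index) of its canonical representative
    birth_val = vals.copy()
    birth_idx = np.arange(n)

    edges = g.edges()
    edge_val = np.maximum(vals[edges[:, 0]], vals[edges[:, 1]])
    order = np.lexsort((np.arange(len(edges)), edge_val))

    points = []
    for e in order:
        u, v = edges[e]
        ru, rv = find(int(u)), find(int(v))
        if ru == rv:
            continue
        # elder rule: lower (birth value, vertex index) survives
        if (birth_val[rv], birth_idx[rv]) < (birth_val[ru], birth_idx[ru]):
            ru, rv = rv, ru
        death = edge_val[e]
        if birth_val[rv] < death:  # drop zero-persistence merges
            points.append((birth_val[rv], death))
        parent[rv] = ru

    points.append((float(vals.min()), float(vals.max())))  # essential pairing
    return PersistenceDiagram(np.array(points), id=id if id is not None else g.id)


def diagram_for_cell(c: Contour, ctr: NucleusCenter, clean: bool = True) -> PersistenceDiagram:
    """Full per-cell signature: build graph, clean, radial filtration, diagram."""
    g = build_graph(c)
    if clean:
        g = clean_graph(g)
    return sublevel_diagram0(g, radial_function(g, ctr))
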