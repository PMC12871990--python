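"""p-Wasserstein distance between persistence diagrams and all-pairs matrices.

Each diagram is augmented with "ghost" copies of the other diagram's
orthogonal projections onto the diagonal: a point (b, d) may be matched to
the diagonal at Euclidean cost (d - b)/sqrt(2), and ghost-ghost matches are
free.  The balanced assignment minimising the sum of p-th power Euclidean
costs is solved exactly (Hungarian algorithm); the distance is the p-th
root of the optimum.  This convention makes W_p a true metric on diagrams.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .errors import MalformedInputError, ParameterError
from .persistence import PersistenceDiagram

__all__ = ["TransportPlan", "DistanceMatrix", "wasserstein", "all_pairs"]

GHOST = "ghost"


@dataclass(frozen=True)
class TransportPlan:
    """Optimal matching of augmented diagrams; `matches` pairs indices into
    the first and second diagram, with GHOST marking a diagonal ghost."""

    matches: tuple
    cost: float


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric all-pairs distance matrix with cell labels."""

    ids: tuple
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "ids", tuple(self.ids))
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise MalformedInputError(f"{n} ids but matrix of shape {vals.shape}")
        if not np.all(np.isfinite(vals)):
            raise MalformedInputError("distance matrix has non-finite entries")
        if not np.allclose(vals, vals.T):
            raise MalformedInputError("distance matrix is not symmetric")
        if np.any(vals < 0) or np.any(np.diag(vals) != 0):
            raise MalformedInputError("distances must be >= 0 with a zero diagonal")

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(tuple(str(c) for c in df.columns), df.to_numpy(dtype=float))


def _diag_cost(points: np.ndarray) -> np.ndarray:
    """Euclidean distance of each (b, d) to its diagonal projection."""
    if len(points) == 0:
        return np.zeros(0)
    return (points[:, 1] - points[:, 0]) / np.sqrt(2.0)


def wasserstein(D1, D2, p: float = 2.0):
    """p-Wasserstein distance between two diagrams, with the optimal plan.

    Returns ``(distance, TransportPlan)``.  ``D1``/``D2`` may be
    PersistenceDiagram objects or bare (n, 2) arrays of (birth, death) pairs.
    """
    if p < 1:
        raise ParameterError(f"p must be >= 1, got {p}")
    P1 = D1.points if isinstance(D1, PersistenceDiagram) else np.asarray(D1, float).reshape(-1, 2)
    P2 = D2.points if isinstance(D2, PersistenceDiagram) else np.asarray(D2, float).reshape(-1, 2)
    n1, n2 = len(P1), len(P2)
    if n1 == 0 and n2 == 0:
        return 0.0, TransportPlan(matches=(), cost=0.0)

    # rows: points of D1 then n2 ghosts; cols: points of D2 then n1 ghosts
    size = n1 + n2
    cost = np.zeros((size, size))
    if n1 and n2:
        cost[:n1, :n2] = cdist(P1, P2) ** p
    cost[:n1, n2:] = (_diag_cost(P1) ** p)[:, None]
    cost[n1:, :n2] = (_diag_cost(P2) ** p)[None, :]
    rows, cols = linear_sum_assignment(cost)
    total = float(cost[rows, cols].sum())
    matches = tuple(
        (int(r) if r < n1 else GHOST, int(c) if c < n2 else GHOST)
        for r, c in zip(rows, cols)
        if r < n1 or c < n2
    )
    return total ** (1.0 / p), TransportPlan(matches=matches, cost=total)


def all_pairs(diagrams: Sequence[PersistenceDiagram], p: float = 2.0) -> DistanceMatrix:
    """All pairwise W_p distances; only the upper triangle is computed."""
    ids = [d.id for d in diagrams]
    if len(ids) < 2:
        raise MalformedInputError("need at least 2 diagrams")
    if len(set(ids)) != len(ids):
        raise MalformedInputError("diagram ids must be unique")
    n = len(diagrams)
    M = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            M[i, j] = M[j, i] = wasserstein(diagrams[i], diagrams[j], p)[0]
    return DistanceMatrix(tuple(ids), M)
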