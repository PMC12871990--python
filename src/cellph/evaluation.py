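"""Embedding and evaluation of contour distance matrices.

Classical multidimensional scaling (double-centred Gram matrix of squared
distances, top positive eigenpairs), pairwise ROC analysis against group
labels (a pair of cells is "positive" when both belong to the same group),
and the nucleus-position sensitivity experiment: jitter every nucleus
centre uniformly in [-s, s] per axis (rejection-sampled to stay inside the
contour), recompute all persistence diagrams and their Wasserstein
distance matrix, and track both the relative Frobenius change delta(s) of
the matrix and the ROC AUC of each provided labelling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .contour import Contour, NucleusCenter, build_graph, clean_graph, contains_point
from .errors import DomainError, GeometryError, ParameterError
from .persistence import radial_function, sublevel_diagram0
from .wasserstein import DistanceMatrix, all_pairs

__all__ = ["Embedding", "RocResult", "SensitivityResult", "cmds", "roc", "sensitivity"]


@dataclass(frozen=True)
class Embedding:
    """cMDS coordinates (n x p) with per-axis explained-variance fractions."""

    ids: tuple
    coordinates: np.ndarray
    explained: np.ndarray


@dataclass(frozen=True)
class RocResult:
    """ROC curve of a distance matrix against a labelling, with AUC and pAUC10.

    pAUC10 is the unnormalised area under the curve up to a false-positive
    rate of 0.1, so its maximum is 0.1.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    pauc10: float


@dataclass(frozen=True)
class SensitivityResult:
    """Per-noise-level statistics over repeats of the centre-jitter experiment."""

    s_levels: np.ndarray
    delta_mean: np.ndarray
    delta_sd: np.ndarray
    auc_mean: np.ndarray  # shape (len(s_levels), n_labelings)
    auc_sd: np.ndarray
    labeling_names: tuple


def cmds(m: DistanceMatrix, p: int = 2) -> Embedding:
    """Classical MDS embedding of a distance matrix into R^p.

    Squares the distances, double-centres with J = I - (1/n) 11^T,
    eigendecomposes B = -J D J / 2, and keeps the top p positive
    eigenpairs; coordinates are V_p Lambda_p^{1/2}.  Explained variance is
    each eigenvalue over the sum of the positive eigenvalues (Wasserstein
    matrices are generally non-Euclidean, so negative eigenvalues occur
    and are excluded from the denominator).  If fewer than p eigenvalues
    are positive, fewer columns are returned with a warning.
    """
    n = len(m)
    if not 1 <= p <= n:
        raise ParameterError(f"p must be in [1, {n}], got {p}")
    D2 = m.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ D2 @ J
    lam, V = np.linalg.eigh(B)
    lam, V = lam[::-1], V[:, ::-1]
    tol = max(lam.max(), 0.0) * 1e-12
    pos = lam > tol
    n_pos = int(pos.sum())
    if n_pos < p:
        warnings.warn(
            f"only {n_pos} positive eigenvalues; returning {n_pos} axes instead of {p}",
            stacklevel=2,
        )
    q = min(p, n_pos)
    coords = V[:, :q] * np.sqrt(lam[:q])
    explained = lam[:q] / lam[pos].sum()
    return Embedding(ids=tuple(m.ids), coordinates=coords, explained=explained)


def roc(m: DistanceMatrix, labels: Mapping) -> RocResult:
    """Pairwise ROC of a distance matrix against a group labelling.

    All unordered pairs are enumerated; a pair is a true relation
    ("positive") when both cells share a group.  Thresholds sweep the
    sorted unique distances; pairs with distance <= threshold are called
    positive.  AUC and pAUC10 are trapezoidal areas.
    """
    groups = np.array([labels[cid] for cid in m.ids])
    if len(set(groups.tolist())) < 2:
        raise DomainError("need at least 2 groups for a ROC analysis")
    iu = np.triu_indices(len(m), k=1)
    dist = m.values[iu]
    positive = (groups[iu[0]] == groups[iu[1]]).astype(float)
    n_pos, n_neg = positive.sum(), len(positive) - positive.sum()
    if n_pos == 0:
        raise DomainError("labelling yields no positive pairs")
    order = np.argsort(dist, kind="stable")
    dist, positive = dist[order], positive[order]
    # group ties: one ROC point per unique threshold value
    boundaries = np.nonzero(np.diff(dist))[0]
    last = np.concatenate([boundaries, [len(dist) - 1]])
    tp = np.cumsum(positive)[last]
    fp = (last + 1) - tp
    tpr = np.concatenate([[0.0], tp / n_pos])
    fpr = np.concatenate([[0.0], fp / n_neg])
    auc = float(np.trapezoid(tpr, fpr))
    cut = np.searchsorted(fpr, 0.1, side="right")
    fpr10 = np.concatenate([fpr[:cut], [0.1]])
    tpr10 = np.concatenate([tpr[:cut], [np.interp(0.1, fpr, tpr)]])
    pauc10 = float(np.trapezoid(tpr10, fpr10))
    return RocResult(fpr=fpr, tpr=tpr, auc=auc, pauc10=pauc10)


def _jitter_center(
    contour: Contour, ctr: NucleusCenter, s: float, rng: np.random.Generator, max_draws: int = 10_000
) -> NucleusCenter:
    """Uniform [-s, s] jitter per axis, redrawn until strictly inside the contour."""
    if s == 0:
        return ctr
    for _ in range(max_draws):
        shift = rng.uniform(-s, s, size=2)
        cand = NucleusCenter(ctr.x + shift[0], ctr.y + shift[1])
        if contains_point(contour, cand.xy):
            return cand
    raise GeometryError(f"no interior centre found for cell {contour.id!r} after {max_draws} draws")


def sensitivity(
    contours: Mapping[str, Contour],
    centres: Mapping[str, NucleusCenter],
    s_levels: Sequence[float],
    repeats: int = 20,
    seed: int = 0,
    labelings: Mapping[str, Mapping] | None = None,
    p: float = 2.0,
    clean: bool = True,
) -> SensitivityResult:
    """Sensitivity of the persistence distance matrix to the nucleus position.

    For every repeat and noise level s the centres are independently
    jittered, diagrams and the W_p matrix recomputed, and delta(s) =
    ||D(s) - D(0)||_F / ||D(0)||_F recorded together with the ROC AUC of
    each labelling.  Randomness is governed by a single seed; each
    (repeat, level, cell) triple derives its own stream, so results do not
    depend on iteration order.
    """
    if repeats < 1:
        raise ParameterError("repeats must be >= 1")
    ids = sorted(contours)
    labelings = dict(labelings or {})
    names = tuple(labelings)
    graphs = {}
    for cid in ids:
        g = build_graph(contours[cid])
        graphs[cid] = clean_graph(g) if clean else g

    def matrix(centre_map) -> DistanceMatrix:
        diagrams = [
            sublevel_diagram0(graphs[cid], radial_function(graphs[cid], centre_map[cid]), id=cid)
            for cid in ids
        ]
        return all_pairs(diagrams, p)

    base = matrix(centres)
    base_norm = np.linalg.norm(base.values)
    s_levels = np.asarray(list(s_levels), dtype=float)
    deltas = np.zeros((len(s_levels), repeats))
    aucs = np.zeros((len(s_levels), repeats, len(names)))
    for si, s in enumerate(s_levels):
        for r in range(repeats):
            jittered = {}
            for ci, cid in enumerate(ids):
                rng = np.random.default_rng(np.random.SeedSequence([seed, si, r, ci]))
                jittered[cid] = _jitter_center(contours[cid], centres[cid], float(s), rng)
            mat = base if s == 0 else matrix(jittered)
            deltas[si, r] = np.linalg.norm(mat.values - base.values) / base_norm
            for li, name in enumerate(names):
                aucs[si, r, li] = roc(mat, labelings[name]).auc
    return SensitivityResult(
        s_levels=s_levels,
        delta_mean=deltas.mean(axis=1),
        delta_sd=deltas.std(axis=1),
        auc_mean=aucs.mean(axis=1),
        auc_sd=aucs.std(axis=1),
        labeling_names=names,
    )
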