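"""Baseline contour distances: aspect ratio, Fourier descriptors, elastic SRVF.

Three classical shape distances used as comparison points for the
persistence signature:

* aspect ratio — ratio of the principal variances of the centred contour,
  compared on a log scale (elongation is multiplicative);
* Fourier descriptors — magnitudes of the low harmonics of the complex
  boundary function z(t) = x(t) + i y(t), invariant to translation,
  rotation and starting point; size is kept (no scale normalisation);
* elastic distance — L2 distance between square-root-velocity (SRV)
  representations, minimised over rotation (closed-form Procrustes),
  starting point (cyclic-shift search) and reparameterisation (dynamic
  programming on a uniform grid).  This is a discrete approximation of the
  elastic shape geodesic distance; it is symmetrised by averaging the two
  directions because DP alignment is not exactly symmetric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contour import Contour
from .errors import DegeneracyError, GeometryError, ParameterError

__all__ = [
    "AspectRatio",
    "FourierDescriptor",
    "SrvCurve",
    "aspect_ratio",
    "aspect_distance",
    "fourier_descriptor",
    "fourier_distance",
    "elastic_distance",
    "resample_closed",
    "ensure_ccw",
]


# ---------------------------------------------------------------- utilities

def signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def ensure_ccw(points: np.ndarray) -> np.ndarray:
    """Return the points traversed counterclockwise (reversing if needed)."""
    if signed_area(points) < 0:
        return points[::-1].copy()
    return points


def resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polyline to n points equally spaced in arc length.

    The starting point is preserved; the closing segment is included in the
    arc length; the output does not repeat the first point.
    """
    closed = np.vstack([points, points[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    if np.any(seg == 0):
        raise GeometryError("zero-length segment in contour")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    target = s[-1] * np.arange(n) / n
    x = np.interp(target, s, closed[:, 0])
    y = np.interp(target, s, closed[:, 1])
    return np.column_stack([x, y])


# ------------------------------------------------------------- aspect ratio

@dataclass(frozen=True)
class AspectRatio:
    """Ratio of major to minor principal variance of a contour; >= 1."""

    value: float

    def __post_init__(self):
        if not self.value >= 1.0:
            raise ParameterError(f"aspect ratio must be >= 1, got {self.value}")


def aspect_ratio(c: Contour, sqrt: bool = False) -> AspectRatio:
    """Rotation/translation-invariant elongation of the contour vertices.

    Centre the points, eigendecompose the 2x2 covariance, and return
    lambda1/lambda2 (variance ratio).  With ``sqrt=True`` the square root
    (ratio of standard deviations, i.e. of effective semi-axes) is
    returned instead; both are 1 for isotropic shapes.
    """
    pts = np.asarray(c.points, float)
    centred = pts - pts.mean(axis=0)
    cov = centred.T @ centred / len(centred)
    lam2, lam1 = np.linalg.eigvalsh(cov)  # ascending
    if lam2 <= 1e-12 * max(lam1, 1.0):
        raise GeometryError(f"contour {c.id!r} is degenerate (collinear points)")
    ratio = lam1 / lam2
    return AspectRatio(float(np.sqrt(ratio)) if sqrt else float(ratio))


def aspect_distance(a1: AspectRatio, a2: AspectRatio) -> float:
    """|log A1 - log A2|: scale-symmetric elongation difference."""
    return abs(float(np.log(a1.value) - np.log(a2.value)))


# ------------------------------------------------------ Fourier descriptors

@dataclass(frozen=True)
class FourierDescriptor:
    """Magnitudes E_1..E_M of the positive harmonics of the boundary function."""

    magnitudes: np.ndarray
    M: int

    def __post_init__(self):
        mags = np.asarray(self.magnitudes, float).ravel()
        object.__setattr__(self, "magnitudes", mags)
        if len(mags) != self.M:
            raise ParameterError(f"expected {self.M} magnitudes, got {len(mags)}")
        if np.any(mags < 0):
            raise ParameterError("magnitudes must be >= 0")


def fourier_descriptor(c: Contour, M: int = 10, n_resample: int = 256) -> FourierDescriptor:
    """Harmonic magnitudes of the contour.

    The contour is resampled to ``n_resample`` equal-arc-length points
    traversed counterclockwise, centred so that F_0 = 0, phase-normalised
    by theta_1 = arg(F_1) (starting-point invariance), and summarised by
    the rotation-invariant magnitudes E_k = |F_k|, k = 1..M.  Physical
    size is informative here, so no scale normalisation is applied.
    """
    if not 1 <= M < n_resample // 2:
        raise ParameterError(f"need 1 <= M < n_resample/2, got M={M}, n={n_resample}")
    pts = ensure_ccw(resample_closed(c.points, n_resample))
    z = pts[:, 0] + 1j * pts[:, 1]
    z = z - z.mean()
    F = np.fft.fft(z) / n_resample
    if np.abs(F[1]) < 1e-12:
        raise DegeneracyError(f"contour {c.id!r}: F_1 = 0, phase normalisation undefined")
    k = np.fft.fftfreq(n_resample, d=1.0 / n_resample)
    F = F * np.exp(-1j * k * np.angle(F[1]))  # F_1 becomes real positive
    return FourierDescriptor(np.abs(F[1 : M + 1]), M)


def fourier_distance(f1: FourierDescriptor, f2: FourierDescriptor) -> float:
    """Euclidean distance between harmonic-magnitude vectors."""
    if f1.M != f2.M:
        raise ParameterError(f"descriptor lengths differ: {f1.M} != {f2.M}")
    return float(np.linalg.norm(f1.magnitudes - f2.magnitudes))


# ----------------------------------------------------------- elastic (SRVF)

@dataclass(frozen=True)
class SrvCurve:
    """Square-root-velocity samples q(t_i) on a uniform parameter grid."""

    samples: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.samples, float)
        object.__setattr__(self, "samples", q)
        if q.ndim != 2 or q.shape[1] != 2 or len(q) < 8:
            raise ParameterError("SRV curve needs an (n>=8, 2) sample array")
        if not np.all(np.isfinite(q)):
            raise ParameterError("SRV samples must be finite")


def _srv(points: np.ndarray) -> SrvCurve:
    """SRV samples q = c' / sqrt(|c'|) of a closed curve on t in [0,1)."""
    n = len(points)
    dt = 1.0 / n
    deriv = (np.roll(points, -1, axis=0) - points) / dt
    speed = np.linalg.norm(deriv, axis=1)
    if np.any(speed == 0):
        raise GeometryError("zero-length segment after resampling")
    return SrvCurve(deriv / np.sqrt(speed)[:, None])


def _l2(q: np.ndarray) -> float:
    return float(np.sqrt(np.sum(q * q) / len(q)))


def _procrustes_rotation(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Rotation R in SO(2) minimising ||q1 - q2 @ R.T||."""
    A = q1.T @ q2
    U, _, Vt = np.linalg.svd(A)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, d]) @ Vt


def _interp_cyclic(q: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Linear interpolation of SRV samples at fractional grid positions in [0, n]."""
    n = len(q)
    ext = np.vstack([q, q[:1]])
    base = np.clip(np.floor(pos).astype(int), 0, n - 1)
    w = (pos - base)[:, None]
    return (1 - w) * ext[base] + w * ext[base + 1]


_DP_STEPS = ((1, 1), (1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2))


def _dp_align(q1: np.ndarray, q2: np.ndarray) -> np.ndarray:
    """Optimal boundary-pinned warping of q2 onto q1 on a uniform grid.

    Dynamic programming over monotone lattice paths from (0,0) to (n,n)
    with local slopes from ``_DP_STEPS``; the step cost integrates
    ||q1(t) - q2(gamma(t)) sqrt(gamma'(t))||^2 along the step.  Returns
    gamma sampled at every grid node i = 0..n (index units, gamma(0)=0,
    gamma(n)=n).
    """
    n = len(q1)
    inf = np.inf
    n_steps = len(_DP_STEPS)
    # per-step local cost matrices C[s][i, j] = cost of arriving at (i, j) by step s
    C = np.full((n_steps, n + 1, n + 1), inf)
    sq1 = np.sum(q1 * q1, axis=1)
    for s, (di, dj) in enumerate(_DP_STEPS):
        m = dj / di
        total = np.zeros((n - di + 1, n - dj + 1))
        i_idx = np.arange(di, n + 1)
        j_idx = np.arange(dj, n + 1)
        for a in range(di):
            rows = i_idx - di + a  # q1 sample indices, <= n-1
            pos = j_idx - dj + m * a
            q2a = _interp_cyclic(q2, pos.astype(float))
            cross = q1[rows] @ q2a.T  # (len(i), len(j))
            total += (
                sq1[rows][:, None]
                + m * np.sum(q2a * q2a, axis=1)[None, :]
                - 2.0 * np.sqrt(m) * cross
            )
        C[s, di:, dj:] = total / n
    dp = np.full((n + 1, n + 1), inf)
    choice = np.zeros((n + 1, n + 1), dtype=np.int8)
    dp[0, 0] = 0.0
    for i in range(1, n + 1):
        cand = np.full((n_steps, n + 1), inf)
        for s, (di, dj) in enumerate(_DP_STEPS):
            if di <= i:
                cand[s, dj:] = dp[i - di, : n + 1 - dj] + C[s, i, dj:]
        best = np.argmin(cand, axis=0)
        dp[i] = cand[best, np.arange(n + 1)]
        choice[i] = best
    # backtrack
    path = [(n, n)]
    i, j = n, n
    while (i, j) != (0, 0):
        di, dj = _DP_STEPS[choice[i, j]]
        i, j = i - di, j - dj
        path.append((i, j))
    path = np.array(path[::-1], dtype=float)
    return np.interp(np.arange(n + 1), path[:, 0], path[:, 1])


def _warp(q: np.ndarray, gamma: np.ndarray) -> np.ndarray:
    """Apply a warping (index units, length n+1) to SRV samples: (q o g) sqrt(g')."""
    n = len(q)
    gdot = np.diff(gamma)  # slope per grid cell, in index units == gamma' in [0,1] units
    return _interp_cyclic(q, gamma[:-1]) * np.sqrt(np.maximum(gdot, 0.0))[:, None]


def _elastic_one_way(q1: np.ndarray, q2: np.ndarray, max_iter: int, tol: float) -> float:
    n = len(q1)
    # coarse starting-point search: best cyclic shift under rotation-only alignment
    best_shift, best_cost = 0, np.inf
    for shift in range(n):
        q2s = np.roll(q2, -shift, axis=0)
        R = _procrustes_rotation(q1, q2s)
        cost = _l2(q1 - q2s @ R.T)
        if cost < best_cost:
            best_cost, best_shift = cost, shift
    q2s = np.roll(q2, -best_shift, axis=0)
    R = _procrustes_rotation(q1, q2s)
    prev = _l2(q1 - q2s @ R.T)
    cost = prev
    for _ in range(max_iter):
        gamma = _dp_align(q1, q2s @ R.T)
        q2w = _warp(q2s, gamma)
        R = _procrustes_rotation(q1, q2w)
        cost = _l2(q1 - q2w @ R.T)
        if prev - cost < tol * max(prev, 1e-30):
            break
        prev = cost
    return min(cost, best_cost)


def elastic_distance(
    c1: Contour,
    c2: Contour,
    n: int = 128,
    max_iter: int = 20,
    tol: float = 1e-6,
) -> float:
    """Elastic (SRVF) distance between two closed contours.

    Both contours are resampled to ``n`` equal-arc-length points, centred
    at their centroids and oriented counterclockwise; the L2 distance
    between SRV representations is then minimised over rotation, cyclic
    starting-point shifts and grid reparameterisations, alternating the
    rotation and warping steps until convergence.  The result is
    symmetrised: d = (d(c1->c2) + d(c2->c1)) / 2.
    """

    def prep(c: Contour) -> np.ndarray:
        pts = ensure_ccw(resample_closed(c.points, n))
        return _srv(pts - pts.mean(axis=0)).samples

    q1, q2 = prep(c1), prep(c2)
    d12 = _elastic_one_way(q1, q2, max_iter, tol)
    d21 = _elastic_one_way(q2, q1, max_iter, tol)
    return 0.5 * (d12 + d21)
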