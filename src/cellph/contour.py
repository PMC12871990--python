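"""Contour data model and I/O.

A cell is represented by an ordered, implicitly closed, simple polygonal
contour (pixel or micron coordinates) together with the centre of mass of
its nucleus, which must lie strictly inside the contour.  The contour is
turned into a cyclic degree-2 graph on which the radial sub-level
filtration is computed, after collapsing axis-aligned runs of pixel
vertices ("cleaning").
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import shapely

from .errors import (
    DegeneracyError,
    GeometryError,
    MalformedInputError,
    ParameterError,
    ParseError,
    UnitError,
)

PIXEL = "pixel"
MICRON = "micron"
_UNITS = (PIXEL, MICRON)


def _as_points(points: Iterable) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise MalformedInputError(f"expected an (n, 2) point array, got shape {pts.shape}")
    return pts


def _is_simple_ring(pts: np.ndarray) -> bool:
    ring = shapely.LineString(np.vstack([pts, pts[:1]]))
    return bool(ring.is_simple)


@dataclass(frozen=True)
class Contour:
    """Ordered simple closed polyline; the first point is not repeated.

    Closure is implicit: the polygon is formed by consecutive points plus
    the segment from the last point back to the first.
    """

    points: np.ndarray
    unit: str = PIXEL
    id: str = ""

    def __post_init__(self):
        pts = _as_points(self.points)
        object.__setattr__(self, "points", pts)
        if self.unit not in _UNITS:
            raise ParameterError(f"unknown unit {self.unit!r}")
        if len(pts) < 3:
            raise MalformedInputError(f"contour {self.id!r} has {len(pts)} points; need >= 3")
        closed = np.vstack([pts, pts[:1]])
        if np.any(np.all(closed[1:] == closed[:-1], axis=1)):
            raise MalformedInputError(f"contour {self.id!r} has identical consecutive points")
        if not _is_simple_ring(pts):
            raise GeometryError(f"contour {self.id!r} is self-intersecting")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def polygon(self) -> shapely.Polygon:
        return shapely.Polygon(self.points)

    def closed_points(self) -> np.ndarray:
        """Points with the first vertex repeated at the end."""
        return np.vstack([self.points, self.points[:1]])


@dataclass(frozen=True)
class NucleusCenter:
    """Centre of mass of the nucleus, in the same unit as its contour."""

    x: float
    y: float

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class ScaleFactor:
    """Pixel-to-micron conversion: a length of n pixels is d = n * s microns."""

    microns_per_pixel: float

    def __post_init__(self):
        if not self.microns_per_pixel > 0:
            raise ParameterError("microns_per_pixel must be > 0")


@dataclass(frozen=True)
class ContourGraph:
    """Cyclic degree-2 graph: vertex i is adjacent to vertices i-1 and i+1 (mod n)."""

    vertices: np.ndarray
    id: str = ""

    def __post_init__(self):
        object.__setattr__(self, "vertices", _as_points(self.vertices))

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def n_edges(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        n = len(self.vertices)
        idx = np.arange(n)
        return np.column_stack([idx, (idx + 1) % n])


def read_contour(path, unit: str = PIXEL, id: str | None = None) -> Contour:
    """Read a contour from a two-column CSV (optional header, one row per vertex).

    A trailing row repeating the first vertex (explicit closure) is dropped.
    The file stem is used as the cell id unless ``id`` is given.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise MalformedInputError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise MalformedInputError(f"{path}: need two numeric columns, found {df.shape[1]}")
    df = df.iloc[:, :2]
    values = df.apply(pd.to_numeric, errors="coerce").to_numpy()
    bad = np.nonzero(np.isnan(values).any(axis=1))[0]
    if bad.size:
        if bad[0] == 0 and bad.size == 1:  # header row
            values = values[1:]
        else:
            rows = bad + 1 if bad[0] != 0 else bad[1:] + 1
            raise ParseError(f"{path}: non-numeric data at row {rows[0]}")
    if len(values) > 1 and np.allclose(values[-1], values[0]):
        values = values[:-1]
    if len(values) < 3:
        raise MalformedInputError(f"{path}: only {len(values)} points; need >= 3")
    return Contour(values, unit=unit, id=id if id is not None else path.stem)


def read_centers(path) -> dict[str, NucleusCenter]:
    """Read a population centre table with columns id, x, y."""
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    df.columns = cols
    if not {"id", "x", "y"} <= set(cols):
        raise MalformedInputError(f"{path}: expected columns id,x,y")
    return {str(r["id"]): NucleusCenter(float(r["x"]), float(r["y"])) for _, r in df.iterrows()}


def to_microns(c: Contour, s: ScaleFactor) -> Contour:
    """Convert a pixel-unit contour to microns (d = n * s per coordinate)."""
    if c.unit != PIXEL:
        raise UnitError(f"contour {c.id!r} is already in microns")
    return replace(c, points=c.points * s.microns_per_pixel, unit=MICRON)


def center_to_microns(ctr: NucleusCenter, s: ScaleFactor) -> NucleusCenter:
    return NucleusCenter(ctr.x * s.microns_per_pixel, ctr.y * s.microns_per_pixel)


def build_graph(c: Contour) -> ContourGraph:
    """Cyclic degree-2 graph on the contour vertices, in contour order."""
    return ContourGraph(c.points, id=c.id)


def clean_graph(g: ContourGraph) -> ContourGraph:
    """Collapse maximal runs of consecutive vertices sharing the same x or y.

    A vertex is dropped exactly when it and both cyclic neighbours agree in
    x, or agree in y: each axis-aligned run keeps only its two endpoints.
    General (oblique) collinearity is deliberately not collapsed.
    """
    pts = g.vertices
    prev = np.roll(pts, 1, axis=0)
    nxt = np.roll(pts, -1, axis=0)
    same_x = (pts[:, 0] == prev[:, 0]) & (pts[:, 0] == nxt[:, 0])
    same_y = (pts[:, 1] == prev[:, 1]) & (pts[:, 1] == nxt[:, 1])
    keep = ~(same_x | same_y)
    if keep.sum() < 3:
        raise DegeneracyError(f"cleaning graph {g.id!r} would leave {int(keep.sum())} vertices")
    return ContourGraph(pts[keep], id=g.id)


def contains_point(c: Contour, p) -> bool:
    """True iff p lies strictly inside the contour polygon (boundary counts as outside)."""
    x, y = float(p[0]), float(p[1])
    return bool(c.polygon.contains(shapely.Point(x, y)))
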