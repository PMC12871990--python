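"""Synthetic contour generators.

Stands in for segmented fluorescence-microscopy outlines: star-shaped
cells with a controllable number of lobes, elongation, radial boundary
noise, and optional pixelation (rasterise + Moore boundary trace) so that
the axis-aligned cleaning step sees realistic staircase runs.  Also
provides the small worked-example filtration used throughout the docs and
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely

from .contour import Contour, ContourGraph, NucleusCenter
from .errors import DegeneracyError, GeometryError, MalformedInputError, ParameterError
from .persistence import VertexFunction

__all__ = [
    "PopulationSpec",
    "worked_example_graph",
    "worked_example_values",
    "lobed_contour",
    "pixelate_contour",
    "generate_population",
    "two_population",
]

#: Cyclic vertex values of the illustrative 14-vertex radial filtration:
#: one global minimum (1), three local minima at 3, three at 4, maxima 4/5.
WORKED_EXAMPLE_VALUES = (1.0, 4.0, 3.0, 5.0, 3.0, 5.0, 3.0, 5.0, 4.0, 5.0, 4.0, 5.0, 4.0, 5.0)

#: Its essential-paired dimension-0 diagram: {(1,5),(3,4),(3,5)x2,(4,5)x3}.
WORKED_EXAMPLE_DIAGRAM = (
    (1.0, 5.0),
    (3.0, 4.0),
    (3.0, 5.0),
    (3.0, 5.0),
    (4.0, 5.0),
    (4.0, 5.0),
    (4.0, 5.0),
)


def worked_example_values() -> tuple[float, ...]:
    return WORKED_EXAMPLE_VALUES


def worked_example_graph() -> tuple[ContourGraph, VertexFunction]:
    """Star polygon realising the worked-example filtration.

    Vertex i sits at radius r_i (the i-th cyclic value) and angle
    2*pi*i/14, so its Euclidean distance to the origin equals its
    filtration value exactly.
    """
    r = np.array(WORKED_EXAMPLE_VALUES)
    theta = 2 * np.pi * np.arange(len(r)) / len(r)
    pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return ContourGraph(pts, id="worked-example"), VertexFunction(r)


def lobed_contour(
    lobes: int,
    r_in: float,
    r_out: float,
    n_points: int = 128,
    elongation: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    unit: str = "micron",
    id: str = "",
) -> tuple[Contour, NucleusCenter]:
    """Star-shaped cell contour with ``lobes`` radial lobes.

    The radius profile is r(theta) = mid + amp*cos(lobes*theta) with
    mid = (r_in + r_out)/2, amp = (r_out - r_in)/2, sampled at n_points
    equally spaced angles, stretched by ``elongation`` along x.  Gaussian
    boundary noise is applied radially (truncated at 3 sd) so the contour
    stays star-shaped about the origin, hence simple; noise_sd must stay
    below r_in/4.  The nucleus centre is the origin.
    """
    if lobes < 0:
        raise ParameterError("lobes must be >= 0")
    if not (r_out > r_in > 0):
        raise ParameterError(f"need r_out > r_in > 0, got r_in={r_in}, r_out={r_out}")
    if n_points < max(3, 4 * lobes):
        raise ParameterError("n_points too small to resolve the lobes")
    if noise_sd < 0 or noise_sd >= r_in / 4:
        raise ParameterError(f"noise_sd must be in [0, r_in/4) = [0, {r_in / 4})")
    if elongation <= 0:
        raise ParameterError("elongation must be > 0")
    theta = 2 * np.pi * np.arange(n_points) / n_points
    mid, amp = (r_in + r_out) / 2.0, (r_out - r_in) / 2.0
    r = mid + amp * np.cos(lobes * theta)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        r = r + np.clip(rng.normal(0.0, noise_sd, n_points), -3 * noise_sd, 3 * noise_sd)
    pts = np.column_stack([elongation * r * np.cos(theta), r * np.sin(theta)])
    return Contour(pts, unit=unit, id=id), NucleusCenter(0.0, 0.0)


def _regularize_mask(mask: np.ndarray) -> np.ndarray:
    """Keep the largest 8-connected component and fill checkerboard corners.

    Diagonal-only (2x2 checkerboard) configurations make the traced
    boundary cross itself; filling one of the two empty cells removes
    them while changing the mask by single pixels only.
    """
    from scipy import ndimage

    mask = mask.copy()
    lab, n = ndimage.label(mask, structure=np.ones((3, 3)))
    if n > 1:
        sizes = ndimage.sum_labels(mask.astype(float), lab, index=np.arange(1, n + 1))
        mask = lab == (1 + int(np.argmax(sizes)))
    for _ in range(20):
        a = mask[:-1, :-1] & mask[1:, 1:] & ~mask[1:, :-1] & ~mask[:-1, 1:]
        b = mask[1:, :-1] & mask[:-1, 1:] & ~mask[:-1, :-1] & ~mask[1:, 1:]
        if not (a.any() or b.any()):
            break
        fill = np.zeros_like(mask)
        fill[1:, :-1] |= a
        fill[:-1, :-1] |= b
        mask = mask | fill
    return mask


def _remove_spurs(seq: list) -> list:
    """Drop one-pixel-wide dead ends from a cyclic boundary trace.

    A spur makes the trace revisit a pixel; the shorter cyclic arc between
    the two visits is the spur and is removed.  Repeats until the trace is
    pixel-wise injective.
    """
    changed = True
    while changed:
        changed = False
        first: dict = {}
        for i, p in enumerate(seq):
            if p in first:
                j = first[p]
                inner = i - j
                seq = seq[:j] + seq[i:] if inner <= len(seq) - inner else seq[j:i]
                changed = True
                break
            first[p] = i
    return seq


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Boundary pixels of a binary mask by Moore-neighbour tracing.

    Deterministic start at the lexicographically smallest (row, col)
    foreground pixel; traversal stops on re-entering the start pixel from
    the initial backtrack direction (Jacob's criterion).  Returns (k, 2)
    integer (row, col) positions, consecutive duplicates removed.
    """
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        raise DegeneracyError("empty mask")
    start = min(zip(rows.tolist(), cols.tolist()))
    # 8-neighbourhood in clockwise order (row, col offsets)
    ring = ((0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1))

    def on(p):
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    boundary = [start]
    backtrack = (start[0], start[1] - 1)  # background: start is leftmost in its topmost row
    p, b = start, backtrack
    for _ in range(8 * len(rows) + 8):
        offset = (b[0] - p[0], b[1] - p[1])
        k = ring.index(offset)
        nxt = None
        for step in range(1, 9):
            cand_off = ring[(k + step) % 8]
            cand = (p[0] + cand_off[0], p[1] + cand_off[1])
            if on(cand):
                nxt = cand
                b = (p[0] + ring[(k + step - 1) % 8][0], p[1] + ring[(k + step - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            break
        p = nxt
        if p == start and b == backtrack:
            break
        boundary.append(p)
    return np.array(boundary, dtype=int)


def pixelate_contour(c: Contour, pixel_size: float) -> Contour:
    """Rasterise a contour and return its pixel-centre boundary trace.

    The polygon is sampled on a square grid of the given pixel size
    (a pixel is foreground when its centre lies inside), the outer
    boundary is traced with the Moore neighbourhood, and the boundary
    pixel centres are returned as a contour in the original units.
    """
    if pixel_size <= 0:
        raise ParameterError("pixel_size must be > 0")
    poly = c.polygon
    xmin, ymin, xmax, ymax = poly.bounds
    nx = int(np.ceil((xmax - xmin) / pixel_size)) + 2
    ny = int(np.ceil((ymax - ymin) / pixel_size)) + 2
    xs = xmin + (np.arange(nx) + 0.5) * pixel_size - pixel_size
    ys = ymin + (np.arange(ny) + 0.5) * pixel_size - pixel_size
    X, Y = np.meshgrid(xs, ys)
    mask = shapely.contains_xy(poly, X.ravel(), Y.ravel()).reshape(ny, nx)
    if mask.sum() < 4:
        raise DegeneracyError(f"contour {c.id!r} is thinner than one pixel at this resolution")
    mask = _regularize_mask(mask)
    trace = _moore_trace(mask)
    seq = _remove_spurs(list(map(tuple, trace.tolist())))
    trace = np.array(seq, dtype=int)
    pts = np.column_stack([xs[trace[:, 1]], ys[trace[:, 0]]])
    try:
        return Contour(pts, unit=c.unit, id=c.id)
    except (GeometryError, MalformedInputError) as exc:
        raise DegeneracyError(
            f"contour {c.id!r} is thinner than one pixel at this resolution"
        ) from exc


@dataclass(frozen=True)
class PopulationSpec:
    """Recipe for one synthetic population of star-shaped cells.

    Ranges are inclusive (low, high) bounds sampled uniformly per cell;
    ``r_out`` bounds must lie strictly above the ``r_in`` bounds.  Units
    are microns unless ``pixelate`` is set, in which case contours are
    rasterised at ``pixel_size``.
    """

    n_cells: int
    lobes: tuple = (3, 5)
    r_in: tuple = (8.0, 12.0)
    r_out: tuple = (20.0, 30.0)
    elongation: tuple = (1.0, 1.5)
    boundary_noise_sd: float = 0.5
    pixelate: bool = False
    pixel_size: float = 0.5
    seed: int = 0
    n_points: int = 128
    name: str = "A"

    def __post_init__(self):
        if self.n_cells < 1:
            raise ParameterError("n_cells must be >= 1")
        if not (self.r_in[0] > 0 and self.r_out[0] > self.r_in[1]):
            raise ParameterError("require r_out range > r_in range > 0")
        if self.boundary_noise_sd >= self.r_in[0] / 4:
            raise ParameterError("boundary_noise_sd must be < min(r_in)/4")


def generate_population(spec: PopulationSpec):
    """Deterministically generate one population.

    Returns ``(contours, centres)`` as id-keyed dicts; cell ids are
    ``{name}-{index:03d}``.  Every cell derives its own random stream from
    (spec.seed, index), so outputs are reproducible and order-independent.
    """
    contours: dict[str, Contour] = {}
    centres: dict[str, NucleusCenter] = {}
    for i in range(spec.n_cells):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, i]))
        lobes = int(rng.integers(spec.lobes[0], spec.lobes[1] + 1))
        r_in = float(rng.uniform(*spec.r_in))
        r_out = float(rng.uniform(*spec.r_out))
        elong = float(rng.uniform(*spec.elongation))
        cid = f"{spec.name}-{i:03d}"
        contour, centre = lobed_contour(
            lobes,
            r_in,
            r_out,
            n_points=spec.n_points,
            elongation=elong,
            noise_sd=spec.boundary_noise_sd,
            seed=int(rng.integers(2**31)),
            id=cid,
        )
        if spec.pixelate:
            contour = pixelate_contour(contour, spec.pixel_size)
        contours[cid] = contour
        centres[cid] = centre
    return contours, centres


def example_populations(n_per_group: int = 6, seed: int = 0, n_points: int = 96):
    """A well-separated demo pair: large lobed stars vs small smooth ellipses.

    The stars emulate spread, star-shaped primary cells (several prominent
    protrusions, radii in the tens of microns); the ellipses emulate a
    compact, mildly elongated epithelial-like line an order of magnitude
    smaller in area.  Their persistence diagrams occupy disjoint regions,
    so the pair is a clean positive control for clustering and ROC.
    """
    stars = PopulationSpec(
        n_cells=n_per_group,
        lobes=(4, 6),
        r_in=(8.0, 12.0),
        r_out=(22.0, 30.0),
        elongation=(1.0, 1.2),
        boundary_noise_sd=0.5,
        n_points=n_points,
        seed=seed,
        name="stars",
    )
    ellipses = PopulationSpec(
        n_cells=n_per_group,
        lobes=(0, 0),
        r_in=(2.0, 3.0),
        r_out=(5.0, 7.0),
        elongation=(1.3, 1.8),
        boundary_noise_sd=0.4,
        n_points=n_points,
        seed=seed + 1,
        name="ellipses",
    )
    return stars, ellipses


def two_population(specA: PopulationSpec, specB: PopulationSpec):
    """Two labelled populations for clustering / ROC experiments.

    Returns ``(contours, centres, labels)`` with ``labels`` mapping each
    cell id to its population name.
    """
    if specA.name == specB.name:
        raise ParameterError("population names must differ")
    ca, xa = generate_population(specA)
    cb, xb = generate_population(specB)
    contours = {**ca, **cb}
    centres = {**xa, **xb}
    labels = {cid: specA.name for cid in ca} | {cid: specB.name for cid in cb}
    return contours, centres, labels
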