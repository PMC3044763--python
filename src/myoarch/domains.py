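"""Lattice representations of micropatterned cell islands.

A cell is confined to a 2D adhesive (ECM) island Omega.  The island is
discretized on a regular square lattice with points at cell centers and the
origin at the island centroid, and the lattice spacing is rescaled so that
the occupied area is exactly 1.  Unit area makes the kinetic constants
portable between shapes: the same fitted parameter set is used for the
stair, square, triangle and circle islands.

Because the contractile-fiber network notionally connects every focal
adhesion to every other one, all downstream physics is an all-pairs sum.
The pairwise geometry (distances, unit directions, line-of-sight
visibility) is therefore precomputed once per domain and cached here.  For
concave islands (the stair, arbitrary masks) a fiber may only connect two
points if the straight segment between them stays inside the island; the
visibility set Lambda(r) encodes that constraint.  For convex islands every
pair is visible and the set is the whole island.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import ndimage

__all__ = [
    "ShapeSpec",
    "DomainLattice",
    "SegmentRaster",
    "make_domain",
    "visibility_pairs",
    "segment_raster",
    "default_resolution",
]

_KINDS = ("square", "triangle", "circle", "stair", "mask")
_CONVEX = frozenset({"square", "triangle", "circle"})

#: default lattice cells across each shape's bounding width, chosen so every
#: built-in island has roughly 300-400 interior points (tractable all-pairs
#: kernels at millisecond per-step cost; see docs/methods.md).
_DEFAULT_RESOLUTION = {"square": 18, "triangle": 28, "circle": 21, "stair": 20}


@dataclass(frozen=True)
class ShapeSpec:
    """Declarative description of a cell island.

    Parameters
    ----------
    kind:
        One of ``square``, ``triangle`` (equilateral), ``circle``,
        ``stair`` (staircase polygon) or ``mask`` (user-supplied occupancy).
    stair_steps:
        Number of steps cut into the staircase hypotenuse (``stair`` only).
        The island is a stack of ``stair_steps + 1`` equal-height rows whose
        widths shrink by one block per row.
    mask:
        Binary occupancy grid (``mask`` kind only); must be one connected
        component.
    """

    kind: str
    stair_steps: int = 2
    mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown shape kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind == "mask" and self.mask is None:
            raise ValueError("kind='mask' requires a mask array")
        if self.stair_steps < 1:
            raise ValueError("stair_steps must be >= 1")

    @property
    def convex(self) -> bool:
        return self.kind in _CONVEX


@dataclass
class DomainLattice:
    """Discretized island with cached all-pairs geometry.

    Attributes
    ----------
    spacing:
        Physical lattice constant after area normalization (occupied area
        = n_points * spacing**2 = 1 exactly).
    points:
        ``(N, 2)`` coordinates of in-cell lattice points, centroid origin.
    occupancy:
        The boolean grid the points were drawn from (row-major, row 0 at
        the bottom of the island).
    area_error:
        Relative discretization error of the occupancy against the ideal
        continuous shape, reported by the constructor.
    """

    kind: str
    spacing: float
    points: np.ndarray
    occupancy: np.ndarray
    area_error: float
    convex: bool
    grid_origin: np.ndarray  # physical coords of occupancy cell (0,0) corner
    point_index: np.ndarray  # grid -> point index, -1 outside
    nearest_point: np.ndarray  # grid -> index of nearest in-cell point
    _dist: Optional[np.ndarray] = field(default=None, repr=False)
    _unit: Optional[np.ndarray] = field(default=None, repr=False)
    _visible: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_points(self) -> int:
        return self.points.shape[0]

    @property
    def delta_area(self) -> float:
        """Unit area per lattice point (delta-A)."""
        return self.spacing**2

    @property
    def area(self) -> float:
        return self.n_points * self.delta_area

    # -- pair geometry -----------------------------------------------------

    def pair_distance(self) -> np.ndarray:
        """``(N, N)`` symmetric matrix of |r - r'|."""
        if self._dist is None:
            d = self.points[:, None, :] - self.points[None, :, :]
            self._dist = np.sqrt((d**2).sum(-1))
        return self._dist

    def pair_direction(self) -> np.ndarray:
        """``(N, N, 2)`` unit vectors n(r -> r'); antisymmetric, zero on the diagonal."""
        if self._unit is None:
            d = self.points[None, :, :] - self.points[:, None, :]
            norm = self.pair_distance().copy()
            np.fill_diagonal(norm, 1.0)
            self._unit = d / norm[:, :, None]
        return self._unit

    def visible(self) -> np.ndarray:
        """``(N, N)`` boolean membership of (r, r') in Lambda(r).

        A pair is visible iff the straight segment between the two points
        never leaves the occupancy.  For convex islands this is every pair
        (the model integrates over the whole cell); for concave islands the
        segment is sampled at sub-lattice resolution.
        """
        if self._visible is None:
            n = self.n_points
            if self.convex:
                self._visible = np.ones((n, n), dtype=bool)
            else:
                self._visible = self._sampled_visibility()
        return self._visible

    def _sampled_visibility(self, oversample: float = 0.25) -> np.ndarray:
        n = self.n_points
        dmax = float(self.pair_distance().max())
        n_s = max(10, int(np.ceil(dmax / (oversample * self.spacing))))
        vis = np.ones((n, n), dtype=bool)
        ts = (np.arange(n_s) + 0.5) / n_s
        p = self.points
        for i in range(n):
            seg = p[i][None, None, :] + ts[None, :, None] * (p - p[i])[:, None, :]
            inside = self.contains(seg.reshape(-1, 2)).reshape(n, n_s)
            vis[i] = inside.all(axis=1)
        vis &= vis.T  # enforce exact symmetry against boundary rounding
        np.fill_diagonal(vis, True)
        return vis

    # -- grid helpers ------------------------------------------------------

    def _to_cells(self, xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        ij = np.floor((xy - self.grid_origin) / self.spacing).astype(np.intp)
        return ij[:, 1], ij[:, 0]  # row, col

    def _inside(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        h, w = self.occupancy.shape
        ok = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        out = np.zeros(rows.shape, dtype=bool)
        out[ok] = self.occupancy[rows[ok], cols[ok]]
        return out

    def contains(self, xy: np.ndarray, eps: float = 1e-9) -> np.ndarray:
        """Closed-set island membership of physical points.

        A point on the shared boundary of an occupied and an empty cell
        belongs to the island (the island is the closed union of occupied
        cells), so membership is tested against every cell within ``eps``
        of the point.  This keeps segments that merely graze a notch
        corner classified as contained.
        """
        out = np.zeros(xy.shape[0], dtype=bool)
        for dx in (-eps, eps):
            for dy in (-eps, eps):
                rows, cols = self._to_cells(xy + np.array([dx, dy]))
                out |= self._inside(rows, cols)
        return out


@dataclass
class SegmentRaster:
    """Conservative rasterization of every visible (i < j) pair segment.

    Each fiber segment is cut into steps of length ~spacing/2 and its length
    apportioned to the lattice cell containing each step midpoint (steps that
    fall in an unoccupied boundary cell of a convex island are snapped to the
    nearest in-cell point, so total length is conserved exactly).  The sparse
    triplets (entry_pair, entry_cell, entry_len) turn any per-pair fiber
    weighting into a per-cell length field with one scatter-add.
    """

    pair_i: np.ndarray
    pair_j: np.ndarray
    pair_len: np.ndarray
    pair_angle: np.ndarray  # direction of each segment folded into [0, pi)
    entry_pair: np.ndarray
    entry_cell: np.ndarray
    entry_len: np.ndarray
    _cell_matrix: object = None  # (n_cells, n_pairs) CSR, built lazily

    def cell_lengths(self, pair_weights: np.ndarray, n_cells: int) -> np.ndarray:
        """Total weighted fiber length landing in each lattice cell."""
        if self._cell_matrix is None or self._cell_matrix.shape[0] != n_cells:
            from scipy import sparse

            self._cell_matrix = sparse.csr_matrix(
                (self.entry_len, (self.entry_cell, self.entry_pair)),
                shape=(n_cells, self.pair_len.size),
            )
        return self._cell_matrix @ pair_weights

    def binned_lengths(self, pair_weights: np.ndarray, n_cells: int, k: int) -> np.ndarray:
        """``(n_cells, k)`` directional fiber-length field."""
        bins = np.minimum((self.pair_angle / np.pi * k).astype(np.intp), k - 1)
        idx = self.entry_cell * k + bins[self.entry_pair]
        flat = np.bincount(
            idx,
            weights=pair_weights[self.entry_pair] * self.entry_len,
            minlength=n_cells * k,
        )
        return flat.reshape(n_cells, k)


def default_resolution(spec: ShapeSpec) -> int:
    if spec.kind == "mask":
        return spec.mask.shape[1]
    if spec.kind == "stair":
        blocks = spec.stair_steps + 2
        return int(np.ceil(_DEFAULT_RESOLUTION["stair"] / blocks) * blocks)
    return _DEFAULT_RESOLUTION[spec.kind]


def make_domain(spec: ShapeSpec, resolution: Optional[int] = None) -> DomainLattice:
    """Construct the lattice for a shape at ``resolution`` cells across.

    The occupancy is drawn at unit nominal cell size, then the spacing is
    rescaled so the occupied area equals 1 (the model's unit-cell-area
    convention); the residual mismatch between the discrete occupancy and
    the ideal continuous shape is reported as ``area_error``.
    """
    if resolution is None:
        resolution = default_resolution(spec)
    if spec.kind != "mask" and resolution < 8:
        raise ValueError("resolution must be >= 8")

    occ, ideal_area = _occupancy(spec, resolution)
    lab, n_comp = ndimage.label(occ, structure=np.ones((3, 3), dtype=int))
    if n_comp != 1:
        raise ValueError(f"occupancy mask has {n_comp} connected components; expected 1")
    n = int(occ.sum())
    if n < 1:
        raise ValueError("occupancy has no interior points")

    rows, cols = np.nonzero(occ)
    # nominal unit-cell coordinates, then area-normalize: n * h^2 = 1
    h = 1.0 / np.sqrt(n)
    xy = np.stack([cols + 0.5, rows + 0.5], axis=1) * h
    centroid = xy.mean(axis=0)
    xy -= centroid
    grid_origin = -centroid  # corner of cell (0,0) in centered coords

    point_index = np.full(occ.shape, -1, dtype=np.intp)
    point_index[rows, cols] = np.arange(n)
    # nearest occupied cell for every grid cell (used to snap boundary-
    # grazing fiber samples in convex domains)
    _, (nr, nc) = ndimage.distance_transform_edt(~occ, return_indices=True)
    nearest_point = point_index[nr, nc]

    area_error = abs(n - ideal_area) / ideal_area

    return DomainLattice(
        kind=spec.kind,
        spacing=h,
        points=xy,
        occupancy=occ,
        area_error=float(area_error),
        convex=spec.convex,
        grid_origin=grid_origin,
        point_index=point_index,
        nearest_point=nearest_point,
    )


def _occupancy(spec: ShapeSpec, res: int) -> tuple[np.ndarray, float]:
    """Boolean occupancy grid at unit cell size plus the ideal continuous area."""
    if spec.kind == "mask":
        occ = np.asarray(spec.mask, dtype=bool)
        return occ, float(occ.sum())
    if spec.kind == "square":
        return np.ones((res, res), dtype=bool), float(res) ** 2
    if spec.kind == "circle":
        c = (res - 1) / 2.0
        ii, jj = np.mgrid[0:res, 0:res]
        occ = (ii - c) ** 2 + (jj - c) ** 2 <= (res / 2.0) ** 2
        return occ, np.pi * (res / 2.0) ** 2
    if spec.kind == "triangle":
        height = int(round(res * np.sqrt(3) / 2))
        ii, jj = np.mgrid[0:height, 0:res]
        x = jj + 0.5
        y = ii + 0.5
        hy = res * np.sqrt(3) / 2
        # equilateral triangle with base [0, res] on y=0, apex at (res/2, hy)
        occ = (y >= 0) & (y <= hy * (1 - np.abs(2 * x / res - 1)))
        return occ, np.sqrt(3) / 4 * res**2
    if spec.kind == "stair":
        # square island with a staircase of `stair_steps` steps cut from the
        # top-right corner; the surviving bottom-right -> top-left diagonal
        # is the major axis, the cut shortens the orthogonal diagonal
        blocks = spec.stair_steps + 2
        if res < 2 * blocks:
            raise ValueError(
                f"resolution {res} cannot resolve the stair notch: need >= 2 cells "
                f"per block, i.e. resolution >= {2 * blocks}"
            )
        block = res / blocks
        ii, jj = np.mgrid[0:res, 0:res]
        bi = np.minimum((ii + 0.5) // block, blocks - 1)
        bj = np.minimum((jj + 0.5) // block, blocks - 1)
        occ = (bi + bj) < blocks + 1
        removed = blocks * (blocks - 1) // 2 - (blocks - 1)
        ideal = block**2 * (blocks**2 - removed)
        return occ.astype(bool), float(ideal)
    raise AssertionError(spec.kind)


def visibility_pairs(domain: DomainLattice) -> np.ndarray:
    """The visibility set Lambda as a symmetric boolean (N, N) matrix."""
    return domain.visible()


def segment_raster(domain: DomainLattice) -> SegmentRaster:
    """Rasterize every visible i < j pair segment onto the lattice.

    Segments are clipped exactly against the lattice grid lines, so each
    crossed cell receives precisely the in-cell chord length.  Exact
    clipping keeps the rasterization equivariant under lattice symmetries
    (a rotated domain produces the rotated fields to rounding error) and
    conserves total fiber length by construction.
    """
    vis = np.triu(domain.visible(), k=1)
    pi, pj = np.nonzero(vis)
    p = domain.points
    a = p[pi]
    seg = p[pj] - a
    length = np.sqrt((seg**2).sum(-1))
    angle = np.mod(np.arctan2(seg[:, 1], seg[:, 0]), np.pi)
    n_pairs = pi.size
    h = domain.spacing
    origin = domain.grid_origin

    # parametric crossings with the vertical and horizontal grid lines,
    # per axis: t such that a + t*seg lies on a grid line
    ts = [np.zeros(n_pairs), np.ones(n_pairs)]
    for ax in (0, 1):
        u0 = (a[:, ax] - origin[ax]) / h
        u1 = u0 + seg[:, ax] / h
        lo = np.ceil(np.minimum(u0, u1)).astype(int)
        hi = np.floor(np.maximum(u0, u1)).astype(int)
        counts = np.maximum(hi - lo + 1, 0)
        if counts.max(initial=0) <= 0:
            continue
        rep = np.repeat(np.arange(n_pairs), counts)
        start = np.repeat(np.cumsum(counts) - counts, counts)
        k = lo[rep] + (np.arange(rep.size) - start)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (k - u0[rep]) / (u1[rep] - u0[rep])
        t = np.clip(t, 0.0, 1.0)
        full = np.full(n_pairs * int(counts.max()), np.nan)
        # scatter back into a padded per-pair matrix for a single lexsort
        slot = np.arange(rep.size) - start
        full[rep * int(counts.max()) + slot] = t
        ts.append(full.reshape(n_pairs, -1))

    # assemble per-pair sorted crossing lists
    cols = [np.asarray(x).reshape(n_pairs, -1) for x in ts]
    tmat = np.concatenate(cols, axis=1)
    tmat = np.sort(tmat, axis=1)  # NaNs go last
    dt = np.diff(tmat, axis=1)
    tmid = 0.5 * (tmat[:, :-1] + tmat[:, 1:])
    valid = np.isfinite(dt) & (dt > 0)
    pair_idx, interval = np.nonzero(valid)
    tm = tmid[pair_idx, interval]
    xy = a[pair_idx] + tm[:, None] * seg[pair_idx]
    rows, colsg = domain._to_cells(xy)
    grid_h, grid_w = domain.occupancy.shape
    rows = np.clip(rows, 0, grid_h - 1)
    colsg = np.clip(colsg, 0, grid_w - 1)
    # interval midpoints are interior to their cell; snapping applies only
    # to boundary-grazing chords of convex hull cells outside the occupancy
    cells = domain.nearest_point[rows, colsg]
    seg_len = dt[pair_idx, interval] * length[pair_idx]

    # compress duplicate (pair, cell) entries
    key = pair_idx.astype(np.int64) * domain.n_points + cells
    uniq, inv = np.unique(key, return_inverse=True)
    entry_len = np.zeros(uniq.size)
    np.add.at(entry_len, inv, seg_len)
    entry_pair = (uniq // domain.n_points).astype(np.intp)
    entry_cell = (uniq % domain.n_points).astype(np.intp)

    return SegmentRaster(
        pair_i=pi,
        pair_j=pj,
        pair_len=length,
        pair_angle=angle,
        entry_pair=entry_pair,
        entry_cell=entry_cell,
        entry_len=entry_len,
    )
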