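"""Coordinate conventions, contour/volume containers, rasterization and
shape-based inter-slice interpolation.

All coordinates are physical millimetres. A volume's voxel index ``(k, j, i)``
maps to physical ``z = z0 + k*Vz``, ``y = y0 + j*Vy``, ``x = x0 + i*Vx``
(0-based, z increasing from the proximal common carotid toward the distal
internal carotid). Contours are closed, counter-clockwise, simple polygons
living on an axial plane of constant z.

Shape-based interpolation between two axial contours is performed as the zero
level set of a linear blend of their signed distance fields, sampled on a fine
common grid and extracted with marching squares.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Literal, Tuple

import numpy as np
import shapely
from scipy.ndimage import distance_transform_edt
from shapely.geometry import Polygon
from skimage import measure

log = logging.getLogger(__name__)

#: default grid spacing (mm) for SDF evaluation; >=4x finer than the finest
#: voxel dimension so that discretization error stays well below typical
#: boundary distances (~1 mm).
SDF_GRID_SPACING = 0.05
#: padding (mm) added around the joint bounding box of contours being blended.
SDF_PADDING = 2.0

BoundaryKind = Literal["MAB", "LIB"]
VesselKind = Literal["CCA", "ICA"]


class DegenerateContourError(ValueError):
    """Raised when a polygon is degenerate (zero area, self-intersecting...)."""


class InterpolationError(RuntimeError):
    """Raised when the blended level set has no zero crossing."""


# ---------------------------------------------------------------------------
# volume container
# ---------------------------------------------------------------------------

@dataclass
class Volume3DUS:
    """Axial image stack with anisotropic voxel spacing.

    ``voxels`` has shape (nz, ny, nx); ``spacing`` is (Vx, Vy, Vz) in mm and
    ``origin`` is (x0, y0, z0) in mm.
    """

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3D array (nz, ny, nx)")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacings must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("voxel intensities must be finite")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def slice_z(self, k: int) -> float:
        """Physical z position (mm) of axial slice ``k``."""
        return self.origin[2] + k * self.spacing[2]

    def nearest_slice(self, z: float) -> int:
        k = int(round((z - self.origin[2]) / self.spacing[2]))
        return min(max(k, 0), self.n_slices - 1)

    @property
    def z_range(self) -> Tuple[float, float]:
        return self.origin[2], self.slice_z(self.n_slices - 1)


# ---------------------------------------------------------------------------
# contour
# ---------------------------------------------------------------------------

def _signed_area(points: np.ndarray) -> float:
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """Closed CCW planar polygon on an axial slice.

    ``points`` is an (n, 2) array of (x, y) in mm; the closing edge from the
    last point back to the first is implicit.
    """

    points: np.ndarray
    z: float
    boundary_kind: BoundaryKind
    vessel: VesselKind = "CCA"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        # drop an explicit closing vertex
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(pts) < 8:
            raise DegenerateContourError(
                f"contour needs >= 8 points, got {len(pts)}")
        area = _signed_area(pts)
        if area < 0:  # enforce CCW orientation
            pts = pts[::-1].copy()
            area = -area
        if area <= 0:
            raise DegenerateContourError("polygon has zero area")
        poly = Polygon(pts)
        if not poly.is_valid or not poly.is_simple:
            raise DegenerateContourError("polygon is self-intersecting")
        self.points = pts

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.points)

    @property
    def area(self) -> float:
        return _signed_area(self.points)

    @property
    def perimeter(self) -> float:
        d = np.diff(np.vstack([self.points, self.points[:1]]), axis=0)
        return float(np.hypot(d[:, 0], d[:, 1]).sum())

    @property
    def centroid(self) -> np.ndarray:
        return np.asarray(self.polygon.centroid.coords[0])

    def contains(self, other: "Contour", tol: float = 1e-9) -> bool:
        """True if ``other`` lies entirely inside this polygon."""
        return self.polygon.buffer(tol).contains(other.polygon)

    def resample(self, n_points: int, anchor: np.ndarray | None = None) -> np.ndarray:
        """Resample the boundary to ``n_points`` equally spaced in arc length.

        If ``anchor`` is given, parameterization starts at the boundary point
        nearest to ``anchor``; otherwise at the first vertex.
        """
        closed = np.vstack([self.points, self.points[:1]])
        seg = np.hypot(*np.diff(closed, axis=0).T)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        total = s[-1]
        start = 0.0
        if anchor is not None:
            # arc-length position of the closest boundary point to the anchor
            dense_t = np.linspace(0.0, total, 2048, endpoint=False)
            dense = np.column_stack([
                np.interp(dense_t, s, closed[:, 0]),
                np.interp(dense_t, s, closed[:, 1]),
            ])
            start = dense_t[np.argmin(np.sum((dense - anchor) ** 2, axis=1))]
        t = (start + np.linspace(0.0, total, n_points, endpoint=False)) % total
        t.sort()
        out = np.column_stack([
            np.interp(t, s, closed[:, 0]),
            np.interp(t, s, closed[:, 1]),
        ])
        # rotate so the first output point is the one at parameter `start`
        k = int(np.argmin(np.abs(t - start)))
        return np.roll(out, -k, axis=0)

    def dense_boundary(self, step: float = SDF_GRID_SPACING) -> np.ndarray:
        """Boundary points at ~``step`` mm arc increments."""
        n = max(int(math.ceil(self.perimeter / step)), 16)
        return self.resample(n)

    def flipped(self, axis: int = 0) -> "Contour":
        """Mirror the contour about ``x=0`` (axis=0) or ``y=0`` (axis=1)."""
        pts = self.points.copy()
        pts[:, axis] = -pts[:, axis]
        return replace(self, points=pts[::-1])


# ---------------------------------------------------------------------------
# contour stack
# ---------------------------------------------------------------------------

@dataclass
class ContourStack:
    """Ordered per-slice (MAB, LIB) contour pairs anchored at a bifurcation.

    Slice positions form an arithmetic sequence with step ``isd`` anchored at
    ``bifurcation_z``; slices with z <= bifurcation belong to the common
    carotid (CCA), slices distal to it to the internal carotid (ICA).
    """

    contours: Dict[float, Tuple[Contour, Contour]] = field(default_factory=dict)
    bifurcation_z: float = 0.0
    isd: float = 1.0

    def __post_init__(self) -> None:
        if self.isd <= 0:
            raise ValueError("isd must be positive")
        self.contours = dict(sorted(self.contours.items()))
        for z, (mab, lib) in self.contours.items():
            if mab.boundary_kind != "MAB" or lib.boundary_kind != "LIB":
                raise ValueError("each slice needs a (MAB, LIB) pair")
            if not mab.contains(lib, tol=1e-6):
                raise ValueError(f"LIB outside MAB at z={z:.3f}")

    @property
    def slice_zs(self) -> np.ndarray:
        return np.asarray(sorted(self.contours), dtype=float)

    @property
    def z_range(self) -> Tuple[float, float]:
        zs = self.slice_zs
        if len(zs) == 0:
            raise ValueError("empty stack")
        return float(zs[0]), float(zs[-1])

    def vessel_of(self, z: float) -> VesselKind:
        return "CCA" if z <= self.bifurcation_z + 1e-9 else "ICA"

    def boundary(self, kind: BoundaryKind) -> Dict[float, Contour]:
        idx = 0 if kind == "MAB" else 1
        return {z: pair[idx] for z, pair in self.contours.items()}

    def subset(self, vessel: VesselKind) -> Dict[float, Tuple[Contour, Contour]]:
        return {z: p for z, p in self.contours.items()
                if self.vessel_of(z) == vessel}


# ---------------------------------------------------------------------------
# rasterization and signed distance
# ---------------------------------------------------------------------------

def rasterize(contour: Contour, grid_spacing: float,
              bounds: Tuple[float, float, float, float]) -> np.ndarray:
    """Binary mask on a regular grid: 1 iff the pixel centre is inside.

    ``bounds`` is (xmin, ymin, xmax, ymax) in mm. Pixel (row j, col i) has its
    centre at ``(xmin + (i + 0.5)*h, ymin + (j + 0.5)*h)``.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    xmin, ymin, xmax, ymax = bounds
    nx = max(int(math.ceil((xmax - xmin) / grid_spacing)), 1)
    ny = max(int(math.ceil((ymax - ymin) / grid_spacing)), 1)
    xs = xmin + (np.arange(nx) + 0.5) * grid_spacing
    ys = ymin + (np.arange(ny) + 0.5) * grid_spacing
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(contour.polygon, gx.ravel(), gy.ravel())
    return inside.reshape(ny, nx)


def _grid_for(contours: List[Contour], spacing: float,
              padding: float = SDF_PADDING):
    pts = np.vstack([c.points for c in contours])
    xmin, ymin = pts.min(axis=0) - padding
    xmax, ymax = pts.max(axis=0) + padding
    nx = int(math.ceil((xmax - xmin) / spacing)) + 1
    ny = int(math.ceil((ymax - ymin) / spacing)) + 1
    xs = xmin + np.arange(nx) * spacing
    ys = ymin + np.arange(ny) * spacing
    return xs, ys


def signed_distance_field(contour: Contour,
                          grid: Tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    """Signed Euclidean distance on a regular grid: negative inside.

    Computed from two Euclidean distance transforms of the inside mask;
    accurate to about one grid step.
    """
    xs, ys = grid
    hx = xs[1] - xs[0] if len(xs) > 1 else 1.0
    hy = ys[1] - ys[0] if len(ys) > 1 else 1.0
    gx, gy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(contour.polygon, gx.ravel(), gy.ravel())
    inside = inside.reshape(len(ys), len(xs))
    if not inside.any():
        raise DegenerateContourError("contour does not cover any grid point")
    d_out = distance_transform_edt(~inside, sampling=(hy, hx))
    d_in = distance_transform_edt(inside, sampling=(hy, hx))
    return d_out - d_in


def _largest_zero_level(fld: np.ndarray, xs: np.ndarray,
                        ys: np.ndarray) -> np.ndarray:
    """Largest-area closed zero-level contour of a scalar field, in mm, CCW."""
    if fld.min() >= 0 or fld.max() <= 0:
        raise InterpolationError("field has no zero level set")
    raw = measure.find_contours(fld, 0.0)
    closed = [c for c in raw if np.allclose(c[0], c[-1])]
    if not closed:
        raise InterpolationError("no closed zero-level component")
    hx = xs[1] - xs[0]
    hy = ys[1] - ys[0]
    best, best_area = None, -1.0
    for c in closed:
        pts = np.column_stack([xs[0] + c[:, 1] * hx, ys[0] + c[:, 0] * hy])
        a = abs(_signed_area(pts[:-1]))
        if a > best_area:
            best, best_area = pts, a
    if len(closed) > 1:
        log.warning("zero level set has %d closed components; keeping largest",
                    len(closed))
    pts = best[:-1]
    if _signed_area(pts) < 0:
        pts = pts[::-1]
    return pts


def interpolate_contour(c_prox: Contour, c_dist: Contour, t: float,
                        grid_spacing: float = SDF_GRID_SPACING) -> Contour:
    """Shape-based interpolation between two axial contours.

    Returns the zero level set of ``(1-t)*SDF(c_prox) + t*SDF(c_dist)`` at
    fraction ``t`` in [0, 1], as a CCW contour positioned at the linearly
    interpolated z.
    """
    if c_prox.boundary_kind != c_dist.boundary_kind:
        raise ValueError("contours must share boundary_kind")
    if not 0.0 <= t <= 1.0:
        raise ValueError("t must be in [0, 1]")
    xs, ys = _grid_for([c_prox, c_dist], grid_spacing)
    f1 = signed_distance_field(c_prox, (xs, ys))
    f2 = signed_distance_field(c_dist, (xs, ys))
    blend = (1.0 - t) * f1 + t * f2
    pts = _largest_zero_level(blend, xs, ys)
    z = (1.0 - t) * c_prox.z + t * c_dist.z
    return Contour(points=pts, z=z, boundary_kind=c_prox.boundary_kind,
                   vessel=c_prox.vessel if t <= 0.5 else c_dist.vessel)


def interpolate_stack_at(stack: ContourStack, targets: np.ndarray,
                         grid_spacing: float = SDF_GRID_SPACING,
                         isd: float | None = None) -> ContourStack:
    """Contour pairs at arbitrary z positions inside the stack's range.

    Positions coinciding with an original slice (within 1e-6 mm) copy it
    exactly; the rest are shape-based interpolations between the bracketing
    originals, with each adjacent pair's SDFs computed once and blended per
    target.
    """
    zs = stack.slice_zs
    if len(zs) == 0:
        raise ValueError("empty stack")
    z_lo, z_hi = stack.z_range
    targets = np.unique(np.asarray(targets, dtype=float))
    targets = targets[(targets >= z_lo - 1e-9) & (targets <= z_hi + 1e-9)]

    out: Dict[float, Tuple[Contour, Contour]] = {}
    cache: Dict[int, tuple] = {}
    for z in targets:
        j = int(np.argmin(np.abs(zs - z)))
        if abs(zs[j] - z) < 1e-6:
            out[float(zs[j])] = stack.contours[zs[j]]
            continue
        i = int(np.searchsorted(zs, z) - 1)
        i = min(max(i, 0), len(zs) - 2)
        if i not in cache:
            pair = (stack.contours[zs[i]], stack.contours[zs[i + 1]])
            cts = [pair[0][0], pair[0][1], pair[1][0], pair[1][1]]
            grid = _grid_for(cts, grid_spacing)
            cache[i] = (pair, grid,
                        [signed_distance_field(c, grid) for c in cts])
        (pair, (xs, ys), (f_m0, f_l0, f_m1, f_l1)) = cache[i]
        t = (z - zs[i]) / (zs[i + 1] - zs[i])
        new_pair = []
        try:
            for kind, f0, f1 in (("MAB", f_m0, f_m1), ("LIB", f_l0, f_l1)):
                blend = (1.0 - t) * f0 + t * f1
                pts = _largest_zero_level(blend, xs, ys)
                src = pair[0] if t <= 0.5 else pair[1]
                idx = 0 if kind == "MAB" else 1
                new_pair.append(Contour(points=pts, z=float(z),
                                        boundary_kind=kind,
                                        vessel=src[idx].vessel))
        except (InterpolationError, DegenerateContourError) as exc:
            # adjacent contours too dissimilar to blend (e.g. a gross
            # misprediction): skip this slice rather than aborting the stack
            log.warning("skipping interpolated slice z=%.2f: %s", z, exc)
            continue
        mab, lib = new_pair
        if not mab.contains(lib, tol=1e-6):
            lib = clip_inside(mab, lib)
        out[float(z)] = (mab, lib)
    return ContourStack(contours=out, bifurcation_z=stack.bifurcation_z,
                        isd=isd if isd is not None else stack.isd)


def reslice_stack(stack: ContourStack, target_step: float,
                  grid_spacing: float = SDF_GRID_SPACING) -> ContourStack:
    """Reslice a contour stack to a finer longitudinal step.

    Output slices sit at every multiple of ``target_step`` inside the stack's
    z-range; the original slices are preserved exactly. New slices come from
    shape-based interpolation between the adjacent originals.
    """
    zs = stack.slice_zs
    if len(zs) == 0:
        raise ValueError("empty stack")
    if target_step <= 0 or target_step > stack.isd + 1e-9:
        raise ValueError("target_step must be in (0, isd]")
    z_lo, z_hi = stack.z_range
    k_lo = int(math.ceil(z_lo / target_step - 1e-9))
    k_hi = int(math.floor(z_hi / target_step + 1e-9))
    targets = np.concatenate([np.arange(k_lo, k_hi + 1) * target_step, zs])
    return interpolate_stack_at(stack, targets, grid_spacing=grid_spacing,
                                isd=target_step)


def clip_inside(mab: Contour, lib: Contour) -> Contour:
    """Clip a LIB polygon to lie inside the MAB (intersection, tiny inward
    buffer to break tangency)."""
    inter = lib.polygon.intersection(mab.polygon.buffer(-1e-6))
    if inter.is_empty:
        raise DegenerateContourError("LIB entirely outside MAB")
    if inter.geom_type == "MultiPolygon":
        inter = max(inter.geoms, key=lambda g: g.area)
    pts = np.asarray(inter.exterior.coords)[:-1]
    if len(pts) < 8:
        # densify a too-coarse clipped ring
        ring = shapely.LineString(np.vstack([pts, pts[:1]]))
        t = np.linspace(0, ring.length, 16, endpoint=False)
        pts = np.asarray([ring.interpolate(d).coords[0] for d in t])
    return Contour(points=pts, z=lib.z, boundary_kind="LIB", vessel=lib.vessel)


def contour_from_mask(mask: np.ndarray, pixel_size: Tuple[float, float],
                      origin: Tuple[float, float], z: float,
                      boundary_kind: BoundaryKind,
                      vessel: VesselKind = "CCA",
                      smooth_window: int = 5) -> Contour:
    """Extract the largest closed iso-0.5 contour of a binary mask as a
    physical-space contour. ``pixel_size`` is (px_x, px_y) mm; pixel (j, i)
    centre maps to ``origin + ((i+0.5)*px_x, (j+0.5)*px_y)``.

    A short circular moving average (``smooth_window`` vertices, ~1 px
    apart) suppresses the half-pixel staircase of marching squares; vessel
    boundaries are smooth at that scale, so the induced bias is negligible.
    """
    padded = np.pad(mask.astype(float), 1)
    raw = measure.find_contours(padded, 0.5)
    closed = [c for c in raw if np.allclose(c[0], c[-1]) and len(c) >= 9]
    if not closed:
        raise DegenerateContourError("no closed component in mask")
    best = max(closed, key=lambda c: abs(_signed_area(c[:-1])))
    px, py = pixel_size
    pts = np.column_stack([
        origin[0] + (best[:-1, 1] - 1 + 0.5) * px,
        origin[1] + (best[:-1, 0] - 1 + 0.5) * py,
    ])
    w = min(smooth_window, max(len(pts) // 4, 1))
    if w > 1:
        kernel = np.ones(w) / w
        sm = np.column_stack([
            np.convolve(np.concatenate([pts[-(w // 2):, d], pts[:, d],
                                        pts[:w // 2, d]]),
                        kernel, mode="valid") for d in (0, 1)])
        if len(sm) >= 8 and Polygon(sm).is_valid:
            pts = sm
    return Contour(points=pts, z=z, boundary_kind=boundary_kind, vessel=vessel)


def circle_contour(radius: float, center: Tuple[float, float] = (0.0, 0.0),
                   z: float = 0.0, n: int = 128,
                   boundary_kind: BoundaryKind = "MAB",
                   vessel: VesselKind = "CCA") -> Contour:
    """Convenience constructor for a circular contour."""
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    pts = np.column_stack([center[0] + radius * np.cos(th),
                           center[1] + radius * np.sin(th)])
    return Contour(points=pts, z=z, boundary_kind=boundary_kind, vessel=vessel)
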