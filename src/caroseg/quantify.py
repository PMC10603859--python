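"""Vessel-wall-volume (VWV) and vessel-wall thickness (VWT) quantification.

VWV is the volume enclosed by the media-adventitia boundary (MAB) surface
minus that enclosed by the lumen-intima boundary (LIB) surface. It is
computed by reslicing the contour stack to a fine longitudinal step with
shape-based interpolation and integrating cross-sectional polygon areas
along z by the trapezoid rule, separately over the CCA and ICA segments.

Point-wise VWT is the distance between corresponding MAB and LIB points; the
correspondence stand-in resamples both contours by normalized arc length from
a common anchor ray and aligns the LIB parameterization to the MAB by the
cyclic shift minimizing total pair distance. Thickness values are flattened
to a 2D L-shaped carotid map: rows are longitudinal positions (CCA proximal
to bifurcation, then ICA), columns are normalized circumference; the ICA
block occupies a column sub-range scaled by the ICA/CCA perimeter ratio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .geometry import (BoundaryKind, Contour, ContourStack, _signed_area,
                       interpolate_stack_at)

VOLUME_RESLICE_STEP = 0.1  # mm, fine step for volume integration
MAP_ROW_STEP = 1.0         # mm, longitudinal spacing of VWT map rows
MAP_N_COLS = 100           # circumferential bins of the VWT map


@dataclass
class CorrespondencePair:
    p_mab: np.ndarray
    p_lib: np.ndarray
    z: float
    theta: float

    @property
    def distance(self) -> float:
        return float(np.hypot(*(self.p_mab - self.p_lib)))


@dataclass
class VWTMap:
    """Flattened L-shaped grid of wall thickness (mm); NaN marks cells
    outside the L-shape."""
    grid: np.ndarray
    row_z: np.ndarray         # longitudinal position per row (mm)
    row_vessel: List[str]     # "CCA" or "ICA" per row
    bifurcation_row: int

    def mean(self) -> float:
        vals = self.grid[np.isfinite(self.grid)]
        if vals.size == 0:
            raise ValueError("empty VWT map")
        return float(vals.mean())

    def max(self) -> float:
        vals = self.grid[np.isfinite(self.grid)]
        if vals.size == 0:
            raise ValueError("empty VWT map")
        return float(vals.max())


def vessel_volume(stack: ContourStack, boundary_kind: BoundaryKind,
                  reslice_step: float = VOLUME_RESLICE_STEP,
                  grid_spacing: float = 0.05,
                  _resliced: ContourStack | None = None) -> float:
    """Volume (mm^3) enclosed by one boundary surface of the stack.

    CCA and ICA segments are integrated separately and summed so that the
    bifurcation does not contribute a cross-branch trapezoid.
    """
    if len(stack.contours) < 2:
        raise ValueError("need >= 2 slices to integrate a volume")
    fine = _resliced if _resliced is not None else _fine_reslice(
        stack, reslice_step, grid_spacing)
    idx = 0 if boundary_kind == "MAB" else 1
    total = 0.0
    for vessel in ("CCA", "ICA"):
        seg = sorted(fine.subset(vessel))
        if len(seg) < 2:
            continue
        zs = np.asarray(seg)
        areas = np.asarray([abs(_signed_area(fine.contours[z][idx].points))
                            for z in seg])
        total += float(np.trapezoid(areas, zs))
    if total == 0.0:
        raise ValueError("zero-length longitudinal extent")
    return total


def _fine_reslice(stack: ContourStack, step: float,
                  grid_spacing: float) -> ContourStack:
    """Slices at every multiple of ``step`` in range plus the originals."""
    lo, hi = stack.z_range
    k = np.arange(math.ceil(lo / step - 1e-9),
                  math.floor(hi / step + 1e-9) + 1)
    targets = np.concatenate([k * step, stack.slice_zs])
    return interpolate_stack_at(stack, targets, grid_spacing=grid_spacing)


def vwv(stack: ContourStack, reslice_step: float = VOLUME_RESLICE_STEP,
        grid_spacing: float = 0.05, per_branch: bool = False):
    """Vessel wall volume (mm^3): enclosed MAB volume minus enclosed LIB
    volume. With ``per_branch`` returns a dict {CCA, ICA, total}."""
    fine = _fine_reslice(stack, reslice_step, grid_spacing)
    if not per_branch:
        v_mab = vessel_volume(stack, "MAB", _resliced=fine)
        v_lib = vessel_volume(stack, "LIB", _resliced=fine)
        return v_mab - v_lib
    out: Dict[str, float] = {}
    for vessel in ("CCA", "ICA"):
        seg = sorted(fine.subset(vessel))
        if len(seg) < 2:
            out[vessel] = 0.0
            continue
        zs = np.asarray(seg)
        wall = np.asarray([
            abs(_signed_area(fine.contours[z][0].points))
            - abs(_signed_area(fine.contours[z][1].points)) for z in seg])
        out[vessel] = float(np.trapezoid(wall, zs))
    out["total"] = out["CCA"] + out["ICA"]
    return out


def correspond(mab: Contour, lib: Contour,
               n_points: int = 100) -> List[CorrespondencePair]:
    """Symmetric-style MAB/LIB point correspondence on one slice.

    Both contours are resampled to ``n_points`` equally spaced in normalized
    arc length, anchored where the ray from the MAB centroid along +x crosses
    each boundary; the LIB parameterization is then cyclically shifted to
    minimize the total pair distance, preserving point order.
    """
    if n_points < 16:
        raise ValueError("n_points must be >= 16")
    if not mab.contains(lib, tol=1e-6):
        raise ValueError("LIB must lie inside MAB")
    center = mab.centroid
    anchor = center + np.array([1e3, 0.0])  # far along +x: picks the crossing
    pm = _anchored_resample(mab, center, n_points)
    pl = _anchored_resample(lib, center, n_points)
    # cyclic-shift alignment of the LIB parameterization
    best_shift, best_cost = 0, np.inf
    for s in range(n_points):
        cost = float(np.sum(np.hypot(*(pm - np.roll(pl, -s, axis=0)).T)))
        if cost < best_cost:
            best_cost, best_shift = cost, s
    pl = np.roll(pl, -best_shift, axis=0)
    return [CorrespondencePair(p_mab=pm[i], p_lib=pl[i], z=mab.z,
                               theta=i / n_points) for i in range(n_points)]


def _anchored_resample(c: Contour, center: np.ndarray, n: int) -> np.ndarray:
    """Resample a contour by arc length starting at its +x crossing from
    ``center``, ordered CCW."""
    dense = c.resample(max(4 * n, 512))
    rel = dense - center
    # boundary point whose polar angle (about the MAB centroid) is closest to 0
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    start = int(np.argmin(np.abs(ang)))
    dense = np.roll(dense, -start, axis=0)
    idx = (np.arange(n) * len(dense)) // n
    return dense[idx]


def vwt_map(stack: ContourStack, n_points: int = MAP_N_COLS,
            row_step: float = MAP_ROW_STEP,
            grid_spacing: float = 0.05) -> VWTMap:
    """Point-wise VWT flattened to the 2D L-shaped carotid map.

    The stack is resliced to ``row_step``; each slice contributes one row of
    correspondences. CCA rows span all columns; ICA rows occupy the leading
    column block scaled by the ICA/CCA mean perimeter ratio (remaining cells
    missing).
    """
    lo, hi = stack.z_range
    k = np.arange(math.ceil(lo / row_step - 1e-9),
                  math.floor(hi / row_step + 1e-9) + 1)
    fine = interpolate_stack_at(stack, k * row_step,
                                grid_spacing=grid_spacing)
    keep = list(fine.slice_zs)
    if not keep:
        raise ValueError("no slices at the map row step")
    cca_per, ica_per = [], []
    for z in keep:
        (cca_per if fine.vessel_of(z) == "CCA" else ica_per).append(
            fine.contours[z][0].perimeter)
    ratio = (np.mean(ica_per) / np.mean(cca_per)) if (cca_per and ica_per) else 1.0
    ica_cols = max(int(round(n_points * min(ratio, 1.0))), 1)

    rows, row_z, row_vessel = [], [], []
    for z in keep:
        mab, lib = fine.contours[z]
        vessel = fine.vessel_of(z)
        pairs = correspond(mab, lib, n_points=max(n_points, 16))
        d = np.asarray([p.distance for p in pairs])
        row = np.full(n_points, np.nan)
        if vessel == "CCA":
            row[:] = d[:n_points]
        else:
            # compress the full circumference into the ICA column block
            src = np.linspace(0, len(d) - 1, ica_cols)
            row[:ica_cols] = np.interp(src, np.arange(len(d)), d)
        rows.append(row)
        row_z.append(z)
        row_vessel.append(vessel)
    grid = np.vstack(rows)
    bif_row = int(np.max(np.nonzero([v == "CCA" for v in row_vessel])[0])) \
        if "CCA" in row_vessel else 0
    return VWTMap(grid=grid, row_z=np.asarray(row_z), row_vessel=row_vessel,
                  bifurcation_row=bif_row)


def map_summary(vmap: VWTMap) -> float:
    """Mean VWT (mm) over the non-missing cells of a map."""
    return vmap.mean()


def map_difference(m1: VWTMap, m2: VWTMap) -> Tuple[np.ndarray, np.ndarray]:
    """Cell-wise paired values over the jointly non-missing common grid.

    Returns (values_1, values_2) as flat arrays aligned by (row, column)
    index; rows are matched by longitudinal position.
    """
    z1 = {round(float(z), 6): i for i, z in enumerate(m1.row_z)}
    z2 = {round(float(z), 6): i for i, z in enumerate(m2.row_z)}
    common = sorted(set(z1) & set(z2))
    if not common:
        raise ValueError("maps share no rows")
    a, b = [], []
    for z in common:
        r1, r2 = m1.grid[z1[z]], m2.grid[z2[z]]
        ok = np.isfinite(r1) & np.isfinite(r2)
        a.append(r1[ok])
        b.append(r2[ok])
    return np.concatenate(a), np.concatenate(b)
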