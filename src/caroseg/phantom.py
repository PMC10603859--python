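"""Synthetic carotid phantoms: geometries, speckle-textured 3DUS-like
volumes, ground-truth contour stacks, baseline/follow-up cohorts, and a
virtual observer emulating repeated manual segmentation.

A phantom covers 15 mm of common carotid artery (CCA) proximal to the
bifurcation and 10 mm of internal carotid artery (ICA) distal to it, at a
voxel spacing near 0.21 x 0.21 x 0.35 mm. An external carotid branch (ECA)
of smaller caliber is rendered distal to the bifurcation as a distractor but
carries no ground-truth contours. Plaques are localized, C1-smooth
thickenings of the wall into the lumen (they reduce the lumen-intima radius
only). Follow-up geometries are progression-only modifications of baseline:
existing plaques grow and small new plaques may appear.

The virtual observer re-localizes the bifurcation with a zero-mean jitter
whose spread grows with the inter-slice distance (ISD), reslices the truth
at the jittered anchor, and perturbs each contour with smooth angular radial
noise (truncated Fourier series, harmonics <= 6).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import Contour, ContourStack, Volume3DUS, clip_inside

log = logging.getLogger(__name__)

DEFAULT_SPACING = (0.21, 0.21, 0.35)
CCA_COVERAGE = 15.0  # mm proximal to the bifurcation
ICA_COVERAGE = 10.0  # mm distal to the bifurcation
CONTOUR_POINTS = 72


@dataclass
class Plaque:
    branch: str             # "CCA" or "ICA"
    z_center: float         # mm
    theta_center: float     # rad
    z_extent: float         # full longitudinal footprint, mm
    theta_extent: float     # full angular footprint, rad
    max_thickness: float    # mm, peak lumen-ward thickening
    hypoechoic: bool = False
    calcified: bool = False

    def bump(self, z: np.ndarray | float, theta: np.ndarray | float):
        """C1-smooth thickness bump (raised-cosine in both directions)."""
        dz = np.abs(np.asarray(z, dtype=float) - self.z_center)
        dth = np.angle(np.exp(1j * (np.asarray(theta, dtype=float)
                                    - self.theta_center)))
        wz = np.where(dz < self.z_extent / 2,
                      np.cos(np.pi * dz / self.z_extent) ** 2, 0.0)
        wt = np.where(np.abs(dth) < self.theta_extent / 2,
                      np.cos(np.pi * dth / self.theta_extent) ** 2, 0.0)
        return self.max_thickness * wz * wt


@dataclass
class CarotidGeometry:
    """Analytic bifurcating carotid geometry.

    Radius functions are smooth in (z, theta); plaques only reduce the
    lumen-intima radius, keeping the wall thickness positive everywhere.
    """

    bifurcation_z: float
    r_mab_cca: float
    r_lib_cca: float
    ica_scale: float = 0.8
    eca_scale: float = 0.55
    taper: float = 0.004            # fractional radius change per mm
    wobble_amp: float = 0.4         # mm lateral centerline wobble
    wobble_period: float = 40.0     # mm
    ica_angle: float = math.radians(35.0)
    branch_sep_rate: float = 0.45   # mm lateral separation per mm of z
    plaques: List[Plaque] = field(default_factory=list)
    min_lumen: float = 0.5          # mm
    min_wall: float = 0.2           # mm

    # ---- centerlines -----------------------------------------------------
    def cca_centerline(self, z: float) -> np.ndarray:
        ph = 2 * np.pi * z / self.wobble_period
        return np.array([self.wobble_amp * np.sin(ph),
                         0.6 * self.wobble_amp * np.cos(ph)])

    def ica_centerline(self, z: float) -> np.ndarray:
        base = self.cca_centerline(self.bifurcation_z)
        dz = max(z - self.bifurcation_z, 0.0)
        u = np.array([np.cos(self.ica_angle), np.sin(self.ica_angle)])
        return base + u * (1.2 + self.branch_sep_rate * dz)

    def eca_centerline(self, z: float) -> np.ndarray:
        base = self.cca_centerline(self.bifurcation_z)
        dz = max(z - self.bifurcation_z, 0.0)
        u = -np.array([np.cos(self.ica_angle * 0.7),
                       np.sin(self.ica_angle * 0.7)])
        return base + u * (1.2 + 1.15 * self.branch_sep_rate * dz)

    def branch_at(self, z: float) -> str:
        return "CCA" if z <= self.bifurcation_z + 1e-9 else "ICA"

    def centerline(self, z: float, branch: Optional[str] = None) -> np.ndarray:
        branch = branch or self.branch_at(z)
        if branch == "CCA":
            return self.cca_centerline(z)
        if branch == "ICA":
            return self.ica_centerline(z)
        return self.eca_centerline(z)

    # ---- radii -----------------------------------------------------------
    def _base_radii(self, branch: str, z: float) -> Tuple[float, float]:
        scale = {"CCA": 1.0, "ICA": self.ica_scale,
                 "ECA": self.eca_scale}[branch]
        t = 1.0 - self.taper * (z - self.bifurcation_z)
        return self.r_mab_cca * scale * t, self.r_lib_cca * scale * t

    def mab_radius(self, z: float, theta, branch: Optional[str] = None):
        branch = branch or self.branch_at(z)
        r, _ = self._base_radii(branch, z)
        return np.full_like(np.asarray(theta, dtype=float), r)

    def lib_radius(self, z: float, theta, branch: Optional[str] = None):
        branch = branch or self.branch_at(z)
        r_mab, r_lib = self._base_radii(branch, z)
        r = np.full_like(np.asarray(theta, dtype=float), r_lib)
        for p in self.plaques:
            if p.branch == branch:
                r = r - p.bump(z, theta)
        return np.clip(r, self.min_lumen,
                       r_mab - self.min_wall)

    # ---- contours --------------------------------------------------------
    def contour_at(self, z: float, boundary_kind: str,
                   n: int = CONTOUR_POINTS,
                   branch: Optional[str] = None) -> Contour:
        branch = branch or self.branch_at(z)
        theta = np.linspace(0, 2 * np.pi, n, endpoint=False)
        r = (self.mab_radius(z, theta, branch) if boundary_kind == "MAB"
             else self.lib_radius(z, theta, branch))
        c = self.centerline(z, branch)
        pts = np.column_stack([c[0] + r * np.cos(theta),
                               c[1] + r * np.sin(theta)])
        vessel = "CCA" if branch == "CCA" else "ICA"
        return Contour(points=pts, z=z, boundary_kind=boundary_kind,
                       vessel=vessel)

    def truth_stack(self, isd: float,
                    bifurcation_z: Optional[float] = None,
                    z_limits: Optional[Tuple[float, float]] = None,
                    n: int = CONTOUR_POINTS,
                    include_ends: bool = False) -> ContourStack:
        """Exact contours on slices ``bif - k*isd`` (CCA, 15 mm) and
        ``bif + k*isd`` (ICA, 10 mm). ``bifurcation_z`` may be a jittered
        anchor; the underlying anatomy always follows the true bifurcation.
        ``include_ends`` appends the exact coverage endpoints when the ISD
        does not divide the coverage (used by the stored truth so that
        volume integrals span the full extent)."""
        anchor = self.bifurcation_z if bifurcation_z is None else bifurcation_z
        zs = np.concatenate([
            anchor - np.arange(0, CCA_COVERAGE + 1e-9, isd)[::-1],
            anchor + np.arange(isd, ICA_COVERAGE + 1e-9, isd),
        ])
        if include_ends:
            ends = np.array([anchor - CCA_COVERAGE, anchor + ICA_COVERAGE])
            extra = [e for e in ends if np.min(np.abs(zs - e)) > 1e-6]
            zs = np.sort(np.concatenate([zs, extra])) if extra else zs
        if z_limits is not None:
            keep = (zs >= z_limits[0]) & (zs <= z_limits[1])
            if not keep.all():
                log.warning("truncating stack to the volume z-range")
            zs = zs[keep]
        contours = {}
        for z in zs:
            contours[float(z)] = (self.contour_at(z, "MAB", n=n),
                                  self.contour_at(z, "LIB", n=n))
        return ContourStack(contours=contours, bifurcation_z=anchor, isd=isd)

    def analytic_wall_volume(self, n_theta: int = 720,
                             n_z: int = 2000) -> float:
        """Reference VWV (mm^3) by direct numerical integration of
        (r_mab^2 - r_lib^2)/2 over theta and z. Independent of the contour/
        reslicing pipeline."""
        total = 0.0
        theta = np.linspace(0, 2 * np.pi, n_theta, endpoint=False)
        for lo, hi, branch in (
                (self.bifurcation_z - CCA_COVERAGE, self.bifurcation_z, "CCA"),
                (self.bifurcation_z, self.bifurcation_z + ICA_COVERAGE, "ICA")):
            zs = np.linspace(lo, hi, n_z)
            areas = np.empty(n_z)
            for i, z in enumerate(zs):
                rm = self.mab_radius(z, theta, branch)
                rl = self.lib_radius(z, theta, branch)
                areas[i] = 0.5 * np.trapezoid(
                    np.concatenate([rm ** 2 - rl ** 2,
                                    [rm[0] ** 2 - rl[0] ** 2]]),
                    np.concatenate([theta, [2 * np.pi]]))
            total += float(np.trapezoid(areas, zs))
        return total


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

@dataclass
class NoiseParams:
    speckle: bool = True
    speckle_shape: float = 4.0     # gamma shape; mean is kept at 1
    blur_sigma_mm: float = 0.25
    shadows: bool = True           # calcification shadow cones
    hypoechoic: bool = True        # darken hypoechoic plaque cores
    lumen_level: float = 0.08
    wall_level: float = 0.75
    background_level: float = 0.45
    seed: int = 0


def render_volume(geometry: CarotidGeometry,
                  spacing: Tuple[float, float, float] = DEFAULT_SPACING,
                  noise: Optional[NoiseParams] = None,
                  extent_xy: Tuple[float, float] = (25.6, 19.2),
                  z_pad: float = 0.7) -> Volume3DUS:
    """Render a speckle-textured axial volume of the geometry.

    Intensity is the tissue-class mean (dark lumen, bright wall, mid-level
    background) modulated by multiplicative gamma speckle and Gaussian blur.
    Optional difficulty cases: hypoechoic plaques darken the wall locally and
    calcified plaques cast an intensity-dropout shadow away from the
    transducer (along +y).
    """
    if any(s <= 0 for s in spacing):
        raise ValueError("spacing must be positive")
    noise = noise or NoiseParams()
    vx, vy, vz = spacing
    x_ext, y_ext = extent_xy
    z0 = geometry.bifurcation_z - CCA_COVERAGE - z_pad
    z1 = geometry.bifurcation_z + ICA_COVERAGE + z_pad
    nx = int(round(x_ext / vx))
    ny = int(round(y_ext / vy))
    nz = int(math.ceil((z1 - z0) / vz)) + 1
    origin = (-x_ext / 2, -y_ext / 2, z0)
    xs = origin[0] + np.arange(nx) * vx
    ys = origin[1] + np.arange(ny) * vy
    gx, gy = np.meshgrid(xs, ys)

    vol = np.full((nz, ny, nx), noise.background_level, dtype=np.float32)
    for k in range(nz):
        z = z0 + k * vz
        sl = vol[k]
        branches = ["CCA"] if z <= geometry.bifurcation_z else ["ICA", "ECA"]
        for branch in branches:
            c = geometry.centerline(z, branch)
            dx, dy = gx - c[0], gy - c[1]
            rho = np.hypot(dx, dy)
            theta = np.arctan2(dy, dx)
            r_mab = geometry.mab_radius(z, theta, branch)
            r_lib = geometry.lib_radius(z, theta, branch)
            sl[rho < r_mab] = noise.wall_level
            sl[rho < r_lib] = noise.lumen_level
            if noise.hypoechoic and branch != "ECA":
                for p in geometry.plaques:
                    if p.branch == branch and p.hypoechoic:
                        b = p.bump(z, theta)
                        in_plaque = (rho >= r_lib) & (rho < r_mab) & (b > 0.1)
                        sl[in_plaque] = 0.45 * noise.wall_level
        if noise.shadows and z <= geometry.bifurcation_z:
            for p in geometry.plaques:
                if p.calcified and p.branch == "CCA" \
                        and abs(z - p.z_center) < p.z_extent / 2:
                    c = geometry.centerline(z, "CCA")
                    surf = c + np.array([np.cos(p.theta_center),
                                         np.sin(p.theta_center)]) \
                        * float(geometry.mab_radius(z, p.theta_center, "CCA"))
                    half_w = 1.2
                    cone = (np.abs(gx - surf[0]) < half_w) & (gy > surf[1])
                    sl[cone] *= 0.35
    rng = np.random.default_rng(noise.seed)
    if noise.speckle:
        k = noise.speckle_shape
        vol *= rng.gamma(k, 1.0 / k, size=vol.shape).astype(np.float32)
    if noise.blur_sigma_mm > 0:
        vol = gaussian_filter(vol, sigma=(noise.blur_sigma_mm / vz,
                                          noise.blur_sigma_mm / vy,
                                          noise.blur_sigma_mm / vx))
    return Volume3DUS(voxels=vol, spacing=spacing, origin=origin)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortParams:
    """Distribution parameters of the synthetic cohort.

    Baseline MAB radii are lognormal around 3.5 mm with lumen/wall ratio
    drawn uniformly; 0-3 plaques per artery. Follow-up is progression-only:
    plaque thickness grows by up to ``progression_growth`` (fractional) and a
    new small plaque appears with probability ``p_new_plaque``; both scale
    with ``progression_noise`` so that 0 yields an exact-copy follow-up.
    """
    r_mab_log_mean: float = math.log(3.5)
    r_mab_log_sd: float = 0.10
    lib_ratio_range: Tuple[float, float] = (0.60, 0.75)
    max_plaques: int = 3
    plaque_thickness_range: Tuple[float, float] = (0.5, 1.5)
    plaque_z_extent_range: Tuple[float, float] = (2.5, 8.0)
    plaque_theta_extent_range: Tuple[float, float] = (math.pi / 3, math.pi)
    p_hypoechoic: float = 0.25
    p_calcified: float = 0.2
    progression_growth: float = 0.25
    p_new_plaque: float = 0.35
    progression_noise: float = 1.0
    bifurcation_z_range: Tuple[float, float] = (15.3, 16.3)
    spacing: Tuple[float, float, float] = DEFAULT_SPACING
    render: bool = True
    noise: NoiseParams = field(default_factory=NoiseParams)

    def validate(self) -> None:
        if self.r_mab_log_sd < 0 or self.max_plaques < 0:
            raise ValueError("invalid cohort parameters")
        lo, hi = self.lib_ratio_range
        if not (0 < lo <= hi < 1):
            raise ValueError("lib_ratio_range must be within (0, 1)")


@dataclass
class PhantomCase:
    patient_id: int
    timepoint: str  # "baseline" | "followup"
    geometry: CarotidGeometry
    volume: Optional[Volume3DUS]
    truth: ContourStack

    @property
    def bifurcation_z(self) -> float:
        return self.geometry.bifurcation_z

    @property
    def key(self) -> Tuple[int, str]:
        return (self.patient_id, self.timepoint)


def _sample_plaque(rng: np.random.Generator, params: CohortParams,
                   bif: float, small: bool = False) -> Plaque:
    branch = "CCA" if rng.random() < 0.7 else "ICA"
    if branch == "CCA":
        zc = rng.uniform(bif - CCA_COVERAGE + 3, bif - 1.5)
    else:
        zc = rng.uniform(bif + 1.5, bif + ICA_COVERAGE - 2)
    lo_t, hi_t = params.plaque_thickness_range
    lo_z, hi_z = params.plaque_z_extent_range
    if small:
        hi_t, hi_z = lo_t + 0.3 * (hi_t - lo_t), lo_z + 0.3 * (hi_z - lo_z)
    return Plaque(
        branch=branch, z_center=zc,
        theta_center=rng.uniform(0, 2 * math.pi),
        z_extent=rng.uniform(lo_z, hi_z),
        theta_extent=rng.uniform(*params.plaque_theta_extent_range),
        max_thickness=rng.uniform(lo_t, hi_t),
        hypoechoic=rng.random() < params.p_hypoechoic,
        calcified=rng.random() < params.p_calcified)


def sample_geometry(rng: np.random.Generator,
                    params: CohortParams) -> CarotidGeometry:
    r_mab = float(rng.lognormal(params.r_mab_log_mean, params.r_mab_log_sd))
    ratio = rng.uniform(*params.lib_ratio_range)
    bif = rng.uniform(*params.bifurcation_z_range)
    geo = CarotidGeometry(bifurcation_z=bif, r_mab_cca=r_mab,
                          r_lib_cca=r_mab * ratio,
                          wobble_amp=rng.uniform(0.2, 0.6),
                          ica_angle=math.radians(rng.uniform(25, 45)))
    n_pl = int(rng.integers(0, params.max_plaques + 1))
    geo.plaques = [_sample_plaque(rng, params, bif) for _ in range(n_pl)]
    return geo


def progress_geometry(rng: np.random.Generator, base: CarotidGeometry,
                      params: CohortParams) -> CarotidGeometry:
    """Progression-only follow-up: grown plaques, possibly one new one."""
    s = params.progression_noise
    plaques = [replace(p, max_thickness=p.max_thickness
                       * (1 + s * rng.uniform(0, params.progression_growth)))
               for p in base.plaques]
    if rng.random() < s * params.p_new_plaque:
        plaques.append(_sample_plaque(rng, params, base.bifurcation_z,
                                      small=True))
    return replace(base, plaques=plaques)


def make_case(geometry: CarotidGeometry, patient_id: int, timepoint: str,
              params: CohortParams, render_seed: int) -> PhantomCase:
    volume = None
    if params.render:
        noise = replace(params.noise, seed=render_seed)
        volume = render_volume(geometry, spacing=params.spacing, noise=noise)
    vz = params.spacing[2]
    z_limits = volume.z_range if volume is not None else None
    truth = geometry.truth_stack(vz, z_limits=z_limits, include_ends=True)
    return PhantomCase(patient_id=patient_id, timepoint=timepoint,
                       geometry=geometry, volume=volume, truth=truth)


def sample_cohort(n_patients: int, params: Optional[CohortParams] = None,
                  seed: int = 0) -> List[Tuple[PhantomCase, PhantomCase]]:
    """Paired baseline/follow-up phantom cases, reproducible from ``seed``."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    params = params or CohortParams()
    params.validate()
    root = np.random.default_rng(seed)
    out = []
    for pid in range(n_patients):
        child = np.random.default_rng(root.integers(2 ** 31))
        base_geo = sample_geometry(child, params)
        fu_geo = progress_geometry(child, base_geo, params)
        rs1 = int(child.integers(2 ** 31))
        rs2 = int(child.integers(2 ** 31))
        out.append((make_case(base_geo, pid, "baseline", params, rs1),
                    make_case(fu_geo, pid, "followup", params, rs2)))
    return out


# ---------------------------------------------------------------------------
# virtual observer
# ---------------------------------------------------------------------------

def _default_bif_sd() -> Dict[float, float]:
    return {1.0: 0.2, 2.0: 0.3, 3.0: 0.6}


@dataclass
class ObserverModel:
    """Stochastic model of repeated manual segmentation.

    ``radial_noise_sd`` is the pointwise SD (mm) of a smooth angular
    perturbation of each contour's radius (truncated Fourier series,
    harmonics <= ``max_harmonic``); ``bifurcation_sd_per_isd`` maps ISD (mm)
    to the SD (mm) of the bifurcation re-localization jitter.
    """
    radial_noise_sd: float = 0.15
    max_harmonic: int = 6
    bifurcation_sd_per_isd: Dict[float, float] = field(
        default_factory=_default_bif_sd)
    seed: int = 0

    def bif_sd(self, isd: float) -> float:
        return self.bifurcation_sd_per_isd.get(float(isd), 0.3)


def _perturb_contour(c: Contour, center: np.ndarray, sd: float,
                     max_h: int, rng: np.random.Generator) -> Contour:
    if sd <= 0:
        return c
    rel = c.points - center
    rho = np.hypot(rel[:, 0], rel[:, 1])
    theta = np.arctan2(rel[:, 1], rel[:, 0])
    s = sd / math.sqrt(max_h + 1)
    f = rng.normal(0, s) * np.ones_like(theta)
    for h in range(1, max_h + 1):
        f = f + rng.normal(0, s) * np.cos(h * theta) \
              + rng.normal(0, s) * np.sin(h * theta)
    rho2 = np.maximum(rho + f, 0.3)
    pts = center + np.column_stack([rho2 * np.cos(theta),
                                    rho2 * np.sin(theta)])
    return replace(c, points=pts)


def virtual_observer(case: PhantomCase, isd: float, model: ObserverModel,
                     trial_seed: int = 0) -> ContourStack:
    """One manual-style segmentation trial at a given ISD.

    The bifurcation anchor is jittered by N(0, sd(ISD)^2) rounded to the
    voxel slice grid; contours are the geometry's exact boundaries at the
    jittered slice positions, perturbed by smooth radial noise, with the LIB
    clipped inside the MAB.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence([model.seed, trial_seed, int(isd * 1000)]))
    vz = case.volume.spacing[2] if case.volume is not None \
        else DEFAULT_SPACING[2]
    sd = model.bif_sd(isd)
    jitter = round(rng.normal(0, sd) / vz) * vz if sd > 0 else 0.0
    anchor = case.geometry.bifurcation_z + jitter
    z_limits = case.volume.z_range if case.volume is not None else None
    stack = case.geometry.truth_stack(isd, bifurcation_z=anchor,
                                      z_limits=z_limits)
    if model.radial_noise_sd <= 0:
        return stack
    out = {}
    for z, (mab, lib) in stack.contours.items():
        center = mab.centroid
        mab2 = _perturb_contour(mab, center, model.radial_noise_sd,
                                model.max_harmonic, rng)
        lib2 = _perturb_contour(lib, center, model.radial_noise_sd,
                                model.max_harmonic, rng)
        if not mab2.contains(lib2, tol=1e-6):
            lib2 = clip_inside(mab2, lib2)
        out[z] = (mab2, lib2)
    return ContourStack(contours=out, bifurcation_z=anchor, isd=isd)
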