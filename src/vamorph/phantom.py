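"""Synthetic temporal-bone CT phantoms with analytic ground truth.

The phantom is the study substrate: a block of dense bone (bright, ~1800 HU)
containing a fluid-filled (dark, ~30 HU) inner-ear lumen consisting of

* a *vestibule*, modeled as an ellipsoid, and
* a *vestibular aqueduct* (VA): a tube of varying circular cross-section
  following a planar circular-arc course from its exit out of the vestibule
  to the operculum.

The tube radius along the normalized course position ``s in [0, 1]`` is a
shape-preserving (monotone, non-overshooting) interpolant through three
control radii — at the vestibule exit, the course midpoint and the
operculum — which realizes the three VA shape archetypes seen in inner-ear
malformations: near-uniform ducts, centrally dilated ducts that narrow
toward both ends, and funnels that flare toward the operculum.

Because every cross-section is a disk centered on the course and the ends
are cut by radial planes, the enclosed volume is exactly
``integral of pi * r(s)^2 ds`` (the first moment of a disk about its center
vanishes, so bending contributes nothing) — this closed form is the
ground-truth oracle for all volumetric measurements downstream.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import integrate, ndimage
from scipy.interpolate import PchipInterpolator

from .errors import DomainError, InvalidParameterError
from .volio import LabelMap, VoxelImage

ARCHETYPES = ("uniform", "funnel", "central_dilatation")


# ---------------------------------------------------------------------------
# radius profile
# ---------------------------------------------------------------------------

@dataclass
class RadiusProfile:
    """Tube radius (mm) as a function of normalized arc position s in [0, 1].

    Monotone cubic (PCHIP) interpolation through (0, r_exit), (0.5, r_mid),
    (1, r_oper): continuous, no overshoot, bounded by the control radii.
    """

    r_exit: float
    r_mid: float
    r_oper: float
    archetype: str = "uniform"

    def __post_init__(self) -> None:
        for name in ("r_exit", "r_mid", "r_oper"):
            if getattr(self, name) <= 0:
                raise InvalidParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.archetype not in ARCHETYPES:
            raise InvalidParameterError(f"unknown archetype {self.archetype!r}")
        self._interp = PchipInterpolator(
            [0.0, 0.5, 1.0], [self.r_exit, self.r_mid, self.r_oper]
        )

    def __call__(self, s):
        s = np.clip(np.asarray(s, dtype=float), 0.0, 1.0)
        return self._interp(s)

    @property
    def max_radius(self) -> float:
        return max(self.r_exit, self.r_mid, self.r_oper)


def classify_archetype(r_exit: float, r_mid: float, r_oper: float) -> str:
    """Tag a radius triple with the dominant shape archetype."""
    if r_mid >= r_exit and r_mid >= r_oper:
        return "central_dilatation" if r_mid > 1.05 * max(r_exit, r_oper) else "uniform"
    if r_oper >= r_exit and r_oper >= r_mid:
        return "funnel" if r_oper > 1.05 * max(r_exit, r_mid) else "uniform"
    return "uniform"


def build_radius_profile(
    archetype: str, r_exit: float, r_mid: float, r_oper: float
) -> RadiusProfile:
    """Validated constructor: the tag must be realizable by the radii.

    ``central_dilatation`` requires the midpoint radius to dominate both
    ends; ``funnel`` requires the operculum radius to dominate; ``uniform``
    accepts any positive triple.
    """
    if archetype == "central_dilatation" and not (r_mid >= r_exit and r_mid >= r_oper):
        raise InvalidParameterError(
            "central_dilatation requires r_mid >= r_exit and r_mid >= r_oper"
        )
    if archetype == "funnel" and not (r_oper >= r_exit and r_oper >= r_mid):
        raise InvalidParameterError("funnel requires r_oper >= r_exit and r_oper >= r_mid")
    return RadiusProfile(r_exit, r_mid, r_oper, archetype)


def analytic_tube_volume(profile: RadiusProfile, length_mm: float) -> float:
    """Exact tube volume ``int_0^L pi r(s/L)^2 ds`` by adaptive quadrature."""
    if length_mm <= 0:
        raise InvalidParameterError(f"length must be > 0, got {length_mm}")
    val, _ = integrate.quad(
        lambda s: math.pi * float(profile(s / length_mm)) ** 2,
        0.0,
        length_mm,
        epsrel=1e-9,
        limit=200,
    )
    return float(val)


# ---------------------------------------------------------------------------
# phantom specification
# ---------------------------------------------------------------------------

@dataclass
class PhantomSpec:
    """Full generative description of one synthetic ear.

    The VA course is a planar circular arc of length ``length_mm`` and bend
    radius ``bend_radius_mm`` (``None`` = straight), starting at
    ``exit_point`` with an exactly axial initial tangent; the course plane
    is tilted ``tilt_deg`` out of the axial plane, so the local tangent
    never leaves the axial plane by more than that angle.
    """

    profile: RadiusProfile
    length_mm: float = 10.0
    bend_radius_mm: float | None = 20.0
    tilt_deg: float = 15.0
    exit_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    vestibule_semi_axes: tuple[float, float, float] = (2.5, 1.5, 1.5)  # along-course, in-plane, out-of-plane
    hu_bone: float = 1800.0
    hu_fluid: float = 30.0
    blur_sigma_mm: float = 0.3
    noise_sd_hu: float = 40.0
    spacing: tuple[float, float, float] = (0.3, 0.3, 0.625)
    seed: int = 0
    grid_origin: tuple[float, float, float] | None = None
    grid_shape: tuple[int, int, int] | None = None
    supersample: int = 3

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise InvalidParameterError("length_mm must be > 0")
        if self.bend_radius_mm is not None and self.bend_radius_mm <= self.profile.max_radius:
            raise InvalidParameterError(
                "bend_radius_mm must exceed the maximum profile radius"
            )
        if any(not (0.1 <= s <= 1.0) for s in self.spacing):
            raise InvalidParameterError(
                f"spacing components must lie in [0.1, 1.0] mm, got {self.spacing}"
            )
        if self.blur_sigma_mm < 0 or self.noise_sd_hu < 0:
            raise InvalidParameterError("blur sigma and noise sd must be >= 0")
        if self.supersample < 3:
            raise InvalidParameterError("supersample factor must be >= 3")

    def noise_free(self) -> "PhantomSpec":
        return replace(self, blur_sigma_mm=0.0, noise_sd_hu=0.0)


@dataclass
class Landmarks:
    """World-mm anatomical landmarks of one ear, as written to the sidecar."""

    seed_point: np.ndarray
    vestibule_exit: np.ndarray
    midpoint: np.ndarray
    operculum: np.ndarray
    exit_normal: np.ndarray       # unit normal of the vestibule-exit cut plane (points into vestibule)
    operculum_normal: np.ndarray  # unit normal of the operculum end plane (points out of the duct)

    def to_dict(self) -> dict:
        return {k: np.asarray(v, dtype=float).tolist() for k, v in self.__dict__.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "Landmarks":
        return cls(**{k: np.asarray(d[k], dtype=float) for k in (
            "seed_point", "vestibule_exit", "midpoint", "operculum",
            "exit_normal", "operculum_normal")})


@dataclass
class GroundTruth:
    """Analytic truth for one synthetic ear."""

    volume_mm3: float
    midpoint_diameter_mm: float
    operculum_diameter_mm: float
    landmarks: Landmarks

    def to_json(self, path) -> Path:
        path = Path(path)
        payload = {
            "volume_mm3": self.volume_mm3,
            "midpoint_diameter_mm": self.midpoint_diameter_mm,
            "operculum_diameter_mm": self.operculum_diameter_mm,
            "landmarks": self.landmarks.to_dict(),
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            d["volume_mm3"],
            d["midpoint_diameter_mm"],
            d["operculum_diameter_mm"],
            Landmarks.from_dict(d["landmarks"]),
        )


# ---------------------------------------------------------------------------
# course geometry
# ---------------------------------------------------------------------------

class _CoursePath:
    """Planar circular-arc (or straight) course with an orthonormal frame.

    Frame: u0 = initial tangent (axial), v0 = in-plane normal toward the
    arc center (tilted ``tilt_deg`` out of the axial plane), n0 = u0 x v0.
    """

    def __init__(self, spec: PhantomSpec):
        # the whole course plane is rotated tilt_deg out of the axial plane,
        # so the duct descends steadily (z span ~ L sin(tilt)) as a real VA
        # does, and every local tangent is ~tilt_deg oblique to the slices
        tau = math.radians(spec.tilt_deg)
        self.p0 = np.asarray(spec.exit_point, dtype=float)
        self.u0 = np.array([math.cos(tau), 0.0, math.sin(tau)])
        self.v0 = np.array([0.0, 1.0, 0.0])
        self.n0 = np.cross(self.u0, self.v0)
        self.L = float(spec.length_mm)
        self.R = None if spec.bend_radius_mm is None else float(spec.bend_radius_mm)
        self.theta = None if self.R is None else self.L / self.R

    def point(self, s):
        s = np.asarray(s, dtype=float)
        if self.R is None:
            return self.p0 + np.multiply.outer(s, self.u0)
        phi = s / self.R
        return (
            self.p0
            + np.multiply.outer(self.R * np.sin(phi), self.u0)
            + np.multiply.outer(self.R * (1.0 - np.cos(phi)), self.v0)
        )

    def tangent(self, s):
        s = np.asarray(s, dtype=float)
        if self.R is None:
            return np.broadcast_to(self.u0, s.shape + (3,)).copy()
        phi = s / self.R
        return np.multiply.outer(np.cos(phi), self.u0) + np.multiply.outer(np.sin(phi), self.v0)

    def coords(self, points: np.ndarray):
        """Return (s_clamped, d_curve, in_range, end_dist) per point.

        ``s_clamped`` is arc length of the nearest course point (clamped to
        [0, L]); ``d_curve`` the distance to it; ``in_range`` whether the
        unclamped foot lies within the arc; ``end_dist`` the arc-length
        overshoot beyond the nearer end (0 when in range).
        """
        q = points - self.p0
        if self.R is None:
            s_raw = q @ self.u0
            s_cl = np.clip(s_raw, 0.0, self.L)
            foot = self.p0 + np.multiply.outer(s_cl, self.u0)
            d = np.linalg.norm(points - foot, axis=-1)
            in_range = (s_raw >= 0.0) & (s_raw <= self.L)
            end_dist = np.maximum(0.0, -s_raw) + np.maximum(0.0, s_raw - self.L)
            return s_cl, d, in_range, end_dist
        center = self.p0 + self.R * self.v0
        w = points - center
        a = w @ self.u0
        b = w @ self.v0
        g = w @ self.n0
        phi = np.arctan2(a, -b)
        phi_cl = np.clip(phi, 0.0, self.theta)
        s_cl = phi_cl * self.R
        foot = self.point(s_cl)
        d = np.linalg.norm(points - foot, axis=-1)
        in_range = (phi >= 0.0) & (phi <= self.theta)
        end_dist = self.R * (np.maximum(0.0, -phi) + np.maximum(0.0, phi - self.theta))
        # keep g referenced for clarity of the radial decomposition
        del g
        return s_cl, d, in_range, end_dist


def ground_truth_for(spec: PhantomSpec) -> GroundTruth:
    """Analytic ground truth (no rasterization needed)."""
    path = _CoursePath(spec)
    prof = spec.profile
    L = spec.length_mm
    lm = Landmarks(
        seed_point=path.point(0.5 * L),
        vestibule_exit=path.point(0.0),
        midpoint=path.point(0.5 * L),
        operculum=path.point(L),
        exit_normal=-path.tangent(0.0),
        operculum_normal=path.tangent(np.asarray(L)),
    )
    return GroundTruth(
        volume_mm3=analytic_tube_volume(prof, L),
        midpoint_diameter_mm=2.0 * float(prof(0.5)),
        operculum_diameter_mm=2.0 * float(prof(1.0)),
        landmarks=lm,
    )


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------

def _vestibule_frame(spec: PhantomSpec, path: _CoursePath):
    """Ellipsoid center + (axes, semi_axes): long axis along the course tangent.

    The center sits one along-course semi-axis behind the exit point (with a
    2% overlap), so the ellipsoid never protrudes past the vestibule-exit
    plane by more than a sliver and the lumen stays connected.
    """
    axes = np.stack([path.u0, path.v0, path.n0])
    semi = np.asarray(spec.vestibule_semi_axes, dtype=float)
    center = path.p0 - 0.98 * semi[0] * path.u0
    return center, axes, semi


def _inside_lumen(points, path, prof, L, center, axes, semi, tube_only=False):
    s_cl, d, in_range, _ = path.coords(points)
    inside_tube = in_range & (d <= prof(s_cl / L))
    if tube_only:
        return inside_tube
    local = (points - center) @ axes.T
    m = np.einsum("...i,...i->...", (local / semi), (local / semi))
    return inside_tube | (m <= 1.0)


def rasterize_phantom(spec: PhantomSpec) -> tuple[VoxelImage, LabelMap, GroundTruth]:
    """Digitize a phantom: HU image, truth VA-lumen label map, ground truth.

    Each voxel's pre-noise HU is ``bone + (fluid - bone) * coverage`` where
    coverage is the fraction of the voxel inside the lumen, estimated by
    ``supersample^3`` subsampling for voxels near the lumen surface (voxels
    far inside/outside are resolved exactly by a clearance bound). Gaussian
    blur and seeded Gaussian noise follow. The truth label map marks voxels
    with VA-tube coverage > 0.5 — the duct between the vestibule-exit plane
    and the operculum end cap, excluding the vestibule.
    """
    path = _CoursePath(spec)
    prof = spec.profile
    L = spec.length_mm
    spacing = np.asarray(spec.spacing, dtype=float)
    center, axes, semi = _vestibule_frame(spec, path)

    # grid: bounding box of lumen + margin (bone collar + blur support)
    margin = 1.5 + 3.0 * spec.blur_sigma_mm
    ss = np.linspace(0.0, L, 256)
    pts = path.point(ss)
    rmax = prof.max_radius
    lo_t = pts.min(axis=0) - rmax - margin
    hi_t = pts.max(axis=0) + rmax + margin
    ext = np.sqrt(((semi[:, None] * axes) ** 2).sum(axis=0))  # world-aligned ellipsoid extent
    lo = np.minimum(lo_t, center - ext - margin)
    hi = np.maximum(hi_t, center + ext + margin)
    if spec.grid_origin is not None and spec.grid_shape is not None:
        origin = np.asarray(spec.grid_origin, dtype=float)
        shape = tuple(int(n) for n in spec.grid_shape)
        gmax = origin + (np.asarray(shape) - 1) * spacing
        if np.any(lo_t + margin < origin - 0.5 * spacing) or np.any(
            hi_t - margin > gmax + 0.5 * spacing
        ):
            raise DomainError("VA tube escapes the requested image bounds")
    else:
        origin = lo
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing[i])) + 1 for i in range(3))

    ii, jj, kk = np.meshgrid(
        np.arange(shape[0]), np.arange(shape[1]), np.arange(shape[2]), indexing="ij"
    )
    centers = origin + np.stack([ii, jj, kk], axis=-1) * spacing
    flat = centers.reshape(-1, 3)
    half_diag = 0.5 * float(np.linalg.norm(spacing)) + 1e-9

    # classify voxels against the tube
    s_cl, d, in_range, end_dist = path.coords(flat)
    r_here = prof(s_cl / L)
    clearance = r_here - d
    tube_full = in_range & (clearance >= half_diag) & (end_dist == 0.0) & (
        np.minimum(s_cl, L - s_cl) >= half_diag
    )
    tube_mixed = (np.abs(clearance) <= half_diag) & (end_dist <= half_diag)
    tube_mixed |= (d <= r_here + half_diag) & (end_dist <= half_diag) & ~tube_full

    # classify against the vestibule ellipsoid
    local = (flat - center) @ axes.T
    m = np.sqrt(np.einsum("ij,ij->i", local / semi, local / semi))
    vest_band = half_diag / float(semi.min())
    vest_full = m <= 1.0 - vest_band
    vest_mixed = np.abs(m - 1.0) <= vest_band

    cov_union = np.zeros(len(flat))
    cov_union[tube_full | vest_full] = 1.0
    cov_tube = np.zeros(len(flat))
    cov_tube[tube_full] = 1.0

    # supersample the surface shell
    n = spec.supersample
    offs = (np.arange(n) + 0.5) / n - 0.5
    oi, oj, ok = np.meshgrid(offs, offs, offs, indexing="ij")
    sub_offsets = np.stack([oi, oj, ok], axis=-1).reshape(-1, 3) * spacing  # (n^3, 3)

    mixed_u = (tube_mixed | vest_mixed) & ~(tube_full | vest_full)
    if mixed_u.any():
        pts_m = flat[mixed_u][:, None, :] + sub_offsets[None, :, :]
        sh = pts_m.shape
        inside = _inside_lumen(
            pts_m.reshape(-1, 3), path, prof, L, center, axes, semi
        ).reshape(sh[0], sh[1])
        cov_union[mixed_u] = inside.mean(axis=1)

    mixed_t = tube_mixed & ~tube_full
    if mixed_t.any():
        pts_m = flat[mixed_t][:, None, :] + sub_offsets[None, :, :]
        sh = pts_m.shape
        inside = _inside_lumen(
            pts_m.reshape(-1, 3), path, prof, L, center, axes, semi, tube_only=True
        ).reshape(sh[0], sh[1])
        cov_tube[mixed_t] = inside.mean(axis=1)

    hu = spec.hu_bone + (spec.hu_fluid - spec.hu_bone) * cov_union.reshape(shape)
    if spec.blur_sigma_mm > 0:
        hu = ndimage.gaussian_filter(hu, sigma=spec.blur_sigma_mm / spacing)
    if spec.noise_sd_hu > 0:
        rng = np.random.default_rng(spec.seed)
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=hu.shape)

    image = VoxelImage(hu.astype(np.float32), tuple(spacing), tuple(origin))
    truth_lumen = LabelMap(
        (cov_tube.reshape(shape) > 0.5).astype(np.uint8), tuple(spacing), tuple(origin)
    )
    return image, truth_lumen, ground_truth_for(spec)


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

# Per-group calibration of the radius generators (radii in mm = diameter/2).
# Medians are the study-population medians; log-sd comes from the reported
# interquartile ratio (sigma = ln(Q3/Q1) / (2 * 0.6745)), capped at 0.5 so the
# group median is a stable summary at simulation sample sizes (the median is
# the calibration target; quartiles are approximate); draws are clipped to the
# reported observed range, with a 0.15 mm floor so that every duct is
# resolvable at the default voxel size.
GROUP_CALIBRATION: dict[str, dict] = {
    "control": {
        "n": 42,
        "oper": {"median": 0.45, "sigma": 0.264, "lo": 0.15, "hi": 0.70},
        # all study controls satisfied midpoint width <= 0.9 mm, so the
        # control generator is truncated at 0.45 mm radius
        "mid": {"median": 0.30, "sigma": 0.249, "lo": 0.15, "hi": 0.45},
    },
    "CH": {
        "n": 18,
        "oper": {"median": 0.55, "sigma": 0.5, "lo": 0.15, "hi": 3.50},
        "mid": {"median": 0.40, "sigma": 0.5, "lo": 0.15, "hi": 1.70},
    },
    "IPI": {
        "n": 12,
        "oper": {"median": 0.70, "sigma": 0.5, "lo": 0.15, "hi": 1.65},
        "mid": {"median": 0.80, "sigma": 0.5, "lo": 0.15, "hi": 1.10},
    },
    "IPII": {
        "n": 11,
        "oper": {"median": 1.70, "sigma": 0.232, "lo": 1.10, "hi": 2.40},
        "mid": {"median": 1.05, "sigma": 0.224, "lo": 0.60, "hi": 1.55},
    },
    "EVAS": {
        "n": 15,
        "oper": {"median": 1.70, "sigma": 0.496, "lo": 0.95, "hi": 2.70},
        "mid": {"median": 1.10, "sigma": 0.5, "lo": 0.50, "hi": 1.90},
    },
}

GROUPS = tuple(GROUP_CALIBRATION)

# EVAS ears sit wholly above the volumetric cutoff in the study population
# (100% sensitivity), so EVAS draws are rejection-sampled above this floor.
EVAS_MIN_VOLUME_MM3 = 18.0


@dataclass
class CohortSpec:
    """Generative description of a five-group study cohort.

    Defaults are the noise-free study conditions: 0.2 mm isotropic voxels,
    no blur, no noise — blur/noise/spacing are exposed for degradation
    experiments.
    """

    group_sizes: dict[str, int] = field(
        default_factory=lambda: {g: GROUP_CALIBRATION[g]["n"] for g in GROUPS}
    )
    calibration: dict[str, dict] = field(
        default_factory=lambda: {g: {k: dict(v) if isinstance(v, dict) else v
                                     for k, v in GROUP_CALIBRATION[g].items()}
                                 for g in GROUPS}
    )
    length_median_mm: float = 10.0
    length_sigma: float = 0.08
    length_range_mm: tuple[float, float] = (8.0, 13.0)
    exit_ratio: float = 0.6          # r_exit median as a fraction of the group's r_mid median
    bend_radius_mm: float = 20.0
    tilt_deg: float = 15.0
    spacing: tuple[float, float, float] = (0.2, 0.2, 0.2)
    blur_sigma_mm: float = 0.0
    noise_sd_hu: float = 0.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.group_sizes.values()):
            raise InvalidParameterError("group sizes must be >= 0")


@dataclass
class CohortMember:
    ear_id: str
    group: str
    spec: PhantomSpec
    truth: GroundTruth


def _calibrated_log_median(median: float, sigma: float, lo: float, hi: float) -> float:
    """Underlying log-median such that the [lo, hi]-truncated log-normal
    has the requested median (truncation otherwise shifts the median)."""
    from scipy.optimize import brentq
    from scipy.stats import norm

    if not (lo < median < hi):
        return math.log(np.clip(median, lo, hi))

    def median_error(mu):
        a = norm.cdf((math.log(lo) - mu) / sigma)
        b = norm.cdf((math.log(hi) - mu) / sigma)
        m = math.exp(mu + sigma * norm.ppf(0.5 * (a + b)))
        return m - median

    span = 6.0 * sigma
    return float(brentq(median_error, math.log(median) - span, math.log(median) + span))


def _draw_lognormal(rng, median, sigma, lo, hi, _cache={}):
    # truncate by resampling (no probability atoms at the range boundaries)
    key = (median, sigma, lo, hi)
    if key not in _cache:
        _cache[key] = _calibrated_log_median(median, sigma, lo, hi)
    mu = _cache[key]
    for _ in range(100):
        v = float(rng.lognormal(mean=mu, sigma=sigma))
        if lo <= v <= hi:
            return v
    return float(np.clip(v, lo, hi))


def sample_cohort(cohort: CohortSpec) -> list[CohortMember]:
    """Draw a deterministic cohort of phantom specs with analytic truth."""
    members: list[CohortMember] = []
    for g_idx, group in enumerate(GROUPS):
        n = cohort.group_sizes.get(group, 0)
        cal = cohort.calibration[group]
        for i in range(n):
            ss = np.random.SeedSequence([cohort.master_seed, g_idx, i])
            rng = np.random.default_rng(ss)
            for _attempt in range(200):
                r_mid = _draw_lognormal(rng, **cal["mid"])
                r_oper = _draw_lognormal(rng, **cal["oper"])
                exit_med = cohort.exit_ratio * cal["mid"]["median"]
                r_exit = _draw_lognormal(
                    rng, exit_med, cal["mid"]["sigma"], 0.15, cal["mid"]["hi"]
                )
                length = _draw_lognormal(
                    rng,
                    cohort.length_median_mm,
                    cohort.length_sigma,
                    *cohort.length_range_mm,
                )
                prof = RadiusProfile(r_exit, r_mid, r_oper,
                                     classify_archetype(r_exit, r_mid, r_oper))
                if group != "EVAS" or analytic_tube_volume(prof, length) > EVAS_MIN_VOLUME_MM3:
                    break
            else:  # pragma: no cover - calibration guarantees acceptance
                raise InvalidParameterError(
                    f"could not draw an EVAS ear above {EVAS_MIN_VOLUME_MM3} mm^3"
                )
            spec = PhantomSpec(
                profile=prof,
                length_mm=length,
                bend_radius_mm=cohort.bend_radius_mm,
                tilt_deg=cohort.tilt_deg,
                blur_sigma_mm=cohort.blur_sigma_mm,
                noise_sd_hu=cohort.noise_sd_hu,
                spacing=cohort.spacing,
                seed=int(ss.generate_state(1)[0] % (2**31)),
            )
            members.append(
                CohortMember(f"{group}_{i:03d}", group, spec, ground_truth_for(spec))
            )
    return members


# ---------------------------------------------------------------------------
# rater perturbation
# ---------------------------------------------------------------------------

@dataclass
class RaterJitter:
    """Magnitudes of the simulated manual-interaction variability."""

    seed_radius_mm: float = 0.3
    angle_deg: float = 10.0
    slice_jitter: int = 1

    def __post_init__(self) -> None:
        if self.seed_radius_mm < 0 or self.angle_deg < 0 or self.slice_jitter < 0:
            raise InvalidParameterError("jitter magnitudes must be >= 0")


@dataclass
class PerturbedLandmarks:
    """A rater's view of the landmarks plus their caliper perturbations."""

    landmarks: Landmarks
    angle_offset_mid_deg: float = 0.0
    angle_offset_oper_deg: float = 0.0
    slice_offset_mid: int = 0
    slice_offset_oper: int = 0


def _uniform_in_sphere(rng, radius: float) -> np.ndarray:
    if radius == 0:
        return np.zeros(3)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    return direction * radius * rng.uniform() ** (1.0 / 3.0)


def perturb_for_rater(
    landmarks: Landmarks, jitter: RaterJitter, seed: int
) -> PerturbedLandmarks:
    """One rater's independent perturbation of the landmark set.

    The seed, vestibule-exit and operculum points are each displaced
    uniformly within a sphere of ``seed_radius_mm``; the caliper line angle
    is jittered uniformly in +/- ``angle_deg`` and the measurement slice by
    an integer in {-slice_jitter, ..., +slice_jitter}, independently at the
    midpoint and the operculum. Plane normals are left unchanged.
    """
    rng = np.random.default_rng(seed)
    new = Landmarks(
        seed_point=landmarks.seed_point + _uniform_in_sphere(rng, jitter.seed_radius_mm),
        vestibule_exit=landmarks.vestibule_exit
        + _uniform_in_sphere(rng, jitter.seed_radius_mm),
        midpoint=landmarks.midpoint.copy(),
        operculum=landmarks.operculum + _uniform_in_sphere(rng, jitter.seed_radius_mm),
        exit_normal=landmarks.exit_normal.copy(),
        operculum_normal=landmarks.operculum_normal.copy(),
    )
    k = jitter.slice_jitter
    return PerturbedLandmarks(
        landmarks=new,
        angle_offset_mid_deg=float(rng.uniform(-jitter.angle_deg, jitter.angle_deg)),
        angle_offset_oper_deg=float(rng.uniform(-jitter.angle_deg, jitter.angle_deg)),
        slice_offset_mid=int(rng.integers(-k, k + 1)),
        slice_offset_oper=int(rng.integers(-k, k + 1)),
    )
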