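"""Morphometry of a segmented vestibular aqueduct.

Implements the study's measurements: VA volume (voxel counting and
watertight surface-mesh integration) and the two axial-plane caliper
diameters — at the midpoint of the duct's course and at the operculum.

Measurement conventions (fixed, discussed in docs/methods.md):

* the course is the mask's 3D topological skeleton, path-traced between
  the vestibule-exit and operculum landmarks and smoothed;
* a diameter is the extent of the binary field along the in-slice line
  through the measurement point *perpendicular to the in-slice projection
  of the local course tangent* (caliper practice on axial images), taken
  between the outermost 0.5 crossings of the trilinearly sampled field;
* the operculum tangent is averaged over the last 1 mm of the course.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage import measure as _skmeasure
from skimage.morphology import skeletonize as _skeletonize

from .errors import (
    CenterlineError,
    GeometryError,
    InvalidParameterError,
    UndefinedDirectionError,
)
from .volio import LabelMap, TriMesh, VoxelImage

_NEIGHBOR_OFFSETS = np.array(
    [
        (di, dj, dk)
        for di in (-1, 0, 1)
        for dj in (-1, 0, 1)
        for dk in (-1, 0, 1)
        if (di, dj, dk) != (0, 0, 0)
    ]
)


# ---------------------------------------------------------------------------
# volumes
# ---------------------------------------------------------------------------

def voxel_volume(mask: LabelMap, spacing=None) -> float:
    """Foreground voxel count times the voxel volume (mm^3)."""
    spacing = mask.spacing if spacing is None else spacing
    sx, sy, sz = spacing
    return float(np.count_nonzero(mask.as_bool())) * sx * sy * sz


def extract_surface(mask: LabelMap, iso: float = 0.5) -> TriMesh:
    """Watertight, outward-oriented mesh of the iso-level of the binary field.

    The mask is zero-padded by one voxel so the surface always closes; the
    vertices are returned in world mm.
    """
    data = mask.as_bool()
    if not data.any():
        raise GeometryError("cannot extract a surface from an empty mask")
    padded = np.pad(data, 1).astype(np.float32)
    verts, faces, _normals, _values = _skmeasure.marching_cubes(
        padded, level=iso, spacing=mask.spacing
    )
    verts = verts + np.asarray(mask.origin) - np.asarray(mask.spacing)
    mesh = TriMesh(verts, faces)
    if _signed_volume(mesh.vertices, mesh.faces) < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    if not _is_watertight(mesh.faces):
        raise GeometryError("extracted surface is not watertight")
    return mesh


def _signed_volume(vertices: np.ndarray, faces: np.ndarray) -> float:
    v0 = vertices[faces[:, 0]]
    v1 = vertices[faces[:, 1]]
    v2 = vertices[faces[:, 2]]
    return float(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum() / 6.0)


def _is_watertight(faces: np.ndarray) -> bool:
    edges = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    edges = np.sort(edges, axis=1)
    _, counts = np.unique(edges, axis=0, return_counts=True)
    return bool(np.all(counts == 2))


def mesh_volume(mesh: TriMesh) -> float:
    """Enclosed volume by the divergence theorem (signed tetrahedra sum)."""
    if not _is_watertight(mesh.faces):
        raise GeometryError("mesh_volume requires a watertight mesh")
    return abs(_signed_volume(mesh.vertices, mesh.faces))


# ---------------------------------------------------------------------------
# centerline
# ---------------------------------------------------------------------------

@dataclass
class Centerline:
    """Arc-length-parameterized course from vestibule exit to operculum."""

    points: np.ndarray  # (N, 3) world mm

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if len(self.points) < 2:
            raise CenterlineError("centerline needs at least two points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        keep = np.concatenate([[True], seg > 1e-9])
        self.points = self.points[keep]
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        self.cum_s = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        return float(self.cum_s[-1])

    def point_at(self, s: float) -> np.ndarray:
        s = float(np.clip(s, 0.0, self.length))
        return np.array(
            [np.interp(s, self.cum_s, self.points[:, a]) for a in range(3)]
        )

    def tangent_at(self, s: float, half_window_mm: float = 0.5) -> np.ndarray:
        a = self.point_at(s - half_window_mm)
        b = self.point_at(s + half_window_mm)
        d = b - a
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise CenterlineError("degenerate tangent window")
        return d / n

    def end_tangent(self, window_mm: float = 1.0) -> np.ndarray:
        """Direction of the terminal (operculum-side) course segment."""
        a = self.point_at(self.length - window_mm)
        b = self.points[-1]
        d = b - a
        n = np.linalg.norm(d)
        if n < 1e-12:
            raise CenterlineError("degenerate terminal segment")
        return d / n

    @property
    def midpoint(self) -> np.ndarray:
        return self.point_at(0.5 * self.length)

    def reversed(self) -> "Centerline":
        return Centerline(self.points[::-1].copy())


def _smooth_polyline(points: np.ndarray) -> np.ndarray:
    """3-point moving average; endpoints fixed."""
    if len(points) < 3:
        return points
    out = points.copy()
    out[1:-1] = (points[:-2] + points[1:-1] + points[2:]) / 3.0
    return out


def skeleton_centerline(mask: LabelMap, endpoint_a, endpoint_b) -> Centerline:
    """Centerline via 3D topological thinning and skeleton-graph path tracing.

    The returned polyline runs from ``endpoint_a`` to ``endpoint_b``
    (world mm), passing through the shortest skeleton path between the
    skeleton voxels nearest each endpoint, with the skeleton part smoothed
    by a 3-point moving average.
    """
    data = mask.as_bool()
    if not data.any():
        raise CenterlineError("empty mask")
    skel = _skeletonize(data)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        # a blob thinner than the thinning template can vanish; fall back to
        # the mask's largest-extent voxel pair is meaningless, so fail loudly
        raise CenterlineError("skeletonization removed all voxels")
    world = mask.index_to_world(coords)
    spacing = np.asarray(mask.spacing)

    index_of = {tuple(c): i for i, c in enumerate(coords)}
    graph = nx.Graph()
    graph.add_nodes_from(range(len(coords)))
    for i, c in enumerate(coords):
        for off in _NEIGHBOR_OFFSETS:
            j = index_of.get(tuple(c + off))
            if j is not None and j > i:
                graph.add_edge(i, j, weight=float(np.linalg.norm(off * spacing)))

    a = np.asarray(endpoint_a, dtype=float)
    b = np.asarray(endpoint_b, dtype=float)
    ia = int(np.argmin(np.linalg.norm(world - a, axis=1)))
    ib = int(np.argmin(np.linalg.norm(world - b, axis=1)))
    try:
        node_path = nx.shortest_path(graph, ia, ib, weight="weight")
    except nx.NetworkXNoPath as exc:
        raise CenterlineError("skeleton is disconnected between the endpoints") from exc
    spine = _smooth_polyline(world[node_path])
    pts = np.vstack([a[None, :], spine, b[None, :]])
    return Centerline(pts)


# ---------------------------------------------------------------------------
# axial caliper width
# ---------------------------------------------------------------------------

def occupancy_field(image: VoxelImage) -> np.ndarray:
    """Continuous lumen-occupancy estimate in [0, 1] from a CT image.

    Anchors the fluid and bone levels at robust percentiles of the image
    and maps attenuation linearly between them; the 0.5 level of this field
    tracks the lumen boundary with sub-voxel precision (Gaussian blur
    preserves the half-level of a step edge).
    """
    lo = float(np.percentile(image.data, 0.5))
    hi = float(np.percentile(image.data, 99.5))
    return np.clip((hi - image.data) / max(hi - lo, 1e-6), 0.0, 1.0)


def axial_width(
    mask: LabelMap,
    at,
    tangent,
    *,
    field: np.ndarray | None = None,
    angle_offset_deg: float = 0.0,
    first_crossing: bool = False,
    step_mm: float | None = None,
) -> float:
    """Caliper width (mm) on the axial slice through ``at``.

    The lumen field is sampled by trilinear interpolation along the
    in-slice line through ``at`` perpendicular to the in-slice projection
    of ``tangent`` (optionally rotated by ``angle_offset_deg``); the width
    is the distance between the outermost 0.5 crossings (or the innermost
    pair around the point with ``first_crossing=True``). Returns 0.0 when
    the line never enters the mask.

    By default the binarized mask itself is the sampled field (accuracy
    limited to the voxel grid); passing a continuous occupancy ``field``
    on the same grid (see :func:`occupancy_field`) restores sub-voxel
    precision. The field is gated to the dilated mask so that only the
    structure under measurement contributes.
    """
    at = np.asarray(at, dtype=float)
    t = np.asarray(tangent, dtype=float)
    t2 = t[:2]
    if np.linalg.norm(t2) < 1e-3:
        raise UndefinedDirectionError(
            "course tangent is perpendicular to the axial plane"
        )
    t2 = t2 / np.linalg.norm(t2)
    perp = np.array([-t2[1], t2[0]])
    if angle_offset_deg:
        ang = math.radians(angle_offset_deg)
        rot = np.array([[math.cos(ang), -math.sin(ang)], [math.sin(ang), math.cos(ang)]])
        perp = rot @ perp
    direction = np.array([perp[0], perp[1], 0.0])

    spacing = np.asarray(mask.spacing)
    if step_mm is None:
        step_mm = float(min(spacing[0], spacing[1]) / 4.0)
    extent = float(np.linalg.norm(np.asarray(mask.shape) * spacing))
    ts = np.arange(-extent, extent + step_mm, step_mm)
    pts = at[None, :] + ts[:, None] * direction[None, :]
    idx = mask.world_to_index(pts).T  # (3, N) continuous indices
    if field is None:
        sampled = mask.as_bool().astype(np.float32)
    else:
        gate = ndimage.binary_dilation(mask.as_bool(), iterations=2)
        sampled = np.where(gate, np.asarray(field, dtype=np.float32), 0.0)
    vals = ndimage.map_coordinates(sampled, idx, order=1, mode="constant", cval=0.0)

    inside = vals >= 0.5
    if not inside.any():
        return 0.0
    # a caliper placed away from the duct measures nothing: require the
    # lumen to reach the measurement point (within a voxel of slack)
    near_t = np.abs(ts[inside]).min()
    if near_t > max(2.0 * step_mm, 0.5 * float(min(spacing[0], spacing[1]))):
        return 0.0

    def _cross(i_out: int, i_in: int) -> float:
        v0, v1 = vals[i_out], vals[i_in]
        frac = (0.5 - v0) / (v1 - v0) if v1 != v0 else 1.0
        return float(ts[i_out] + frac * (ts[i_in] - ts[i_out]))

    where = np.flatnonzero(inside)
    if first_crossing:
        # innermost run containing (or nearest) t = 0
        i0 = int(np.argmin(np.abs(ts[where])))
        run_start = run_end = where[i0]
        while run_start - 1 in where:
            run_start -= 1
        while run_end + 1 in where:
            run_end += 1
        lo_idx, hi_idx = run_start, run_end
    else:
        lo_idx, hi_idx = int(where[0]), int(where[-1])
    left = _cross(lo_idx - 1, lo_idx) if lo_idx > 0 else float(ts[lo_idx])
    right = _cross(hi_idx + 1, hi_idx) if hi_idx < len(ts) - 1 else float(ts[hi_idx])
    return right - left


# ---------------------------------------------------------------------------
# per-ear record
# ---------------------------------------------------------------------------

@dataclass
class MorphometryRecord:
    """All measurements of one ear by one rater."""

    ear_id: str
    rater_id: str
    midpoint_diameter_mm: float
    operculum_diameter_mm: float
    voxel_volume_mm3: float
    mesh_volume_mm3: float
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in (
            "midpoint_diameter_mm",
            "operculum_diameter_mm",
            "voxel_volume_mm3",
            "mesh_volume_mm3",
        ):
            if getattr(self, name) < 0:
                raise InvalidParameterError(f"{name} must be >= 0")


def measure_record(
    image: VoxelImage,
    va_mask: LabelMap,
    centerline: Centerline,
    *,
    ear_id: str = "",
    rater_id: str = "",
    angle_offset_mid_deg: float = 0.0,
    angle_offset_oper_deg: float = 0.0,
    slice_offset_mid: int = 0,
    slice_offset_oper: int = 0,
    first_crossing: bool = False,
    operculum_inset_mm: float | None = None,
) -> MorphometryRecord:
    """Measure one ear: two axial diameters plus voxel and mesh volume.

    A slice offset models measuring on a neighboring axial slice: the
    measurement station moves along the centerline to where the course
    crosses that slice (a rater re-centers the caliper on the duct there);
    the angle offsets rotate the caliper line. Diameters are read from the
    continuous occupancy field of the image (sub-voxel caliper); volumes
    from the mask.
    """
    field = occupancy_field(image) if image is not None else None
    sz = va_mask.spacing[2]
    L = centerline.length

    def station_shift(s: float, n_slices: int) -> float:
        """Along-course displacement equivalent to moving n axial slices."""
        if n_slices == 0:
            return 0.0
        tz = float(centerline.tangent_at(s)[2])
        if abs(tz) < 0.05:
            # near-axial course: the adjacent slice shows the same section
            return 0.0
        return float(np.clip(n_slices * sz / tz, -2.0, 2.0))

    s_mid = 0.5 * L + station_shift(0.5 * L, slice_offset_mid)
    s_mid = float(np.clip(s_mid, 0.0, L))
    d_mid = axial_width(
        va_mask, centerline.point_at(s_mid), centerline.tangent_at(s_mid),
        field=field,
        angle_offset_deg=angle_offset_mid_deg, first_crossing=first_crossing,
    )

    # the caliper line through the exact end cap sits on the 0.5 level of the
    # digitized field and measures a sliver; step one voxel inside the duct
    if operculum_inset_mm is None:
        operculum_inset_mm = max(va_mask.spacing)
    s_oper = L - operculum_inset_mm + station_shift(L - operculum_inset_mm,
                                                    slice_offset_oper)
    s_oper = float(np.clip(s_oper, 0.0, L - operculum_inset_mm))
    t_oper = centerline.end_tangent() if s_oper >= L - operculum_inset_mm - 1e-9 \
        else centerline.tangent_at(s_oper)
    d_oper = axial_width(
        va_mask, centerline.point_at(s_oper), t_oper, field=field,
        angle_offset_deg=angle_offset_oper_deg, first_crossing=first_crossing,
    )

    v_vox = voxel_volume(va_mask)
    mesh = extract_surface(va_mask)
    v_mesh = mesh_volume(mesh)

    flags: list[str] = []
    max_sp = max(va_mask.spacing)
    if 0 < min(d_mid, d_oper) < 2.0 * max_sp:
        flags.append("under_resolved")
    if d_mid == 0.0 or d_oper == 0.0:
        flags.append("caliper_missed_lumen")
    if v_mesh > 0 and abs(v_vox - v_mesh) / v_mesh > 0.15:
        flags.append("volume_mismatch")

    return MorphometryRecord(
        ear_id=ear_id,
        rater_id=rater_id,
        midpoint_diameter_mm=float(d_mid),
        operculum_diameter_mm=float(d_oper),
        voxel_volume_mm3=float(v_vox),
        mesh_volume_mm3=float(v_mesh),
        flags=flags,
    )
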