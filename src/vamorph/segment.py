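"""Semi-automatic VA segmentation.

The clinical procedure this reproduces: threshold the CT to the fluid/air
attenuation band (-1024 to 700 HU inclusive), take the connected component
containing a user-placed seed inside the inner-ear lumen, then cut the
component at two user-supplied planes — the VA exit from the vestibule and
the operculum end plane — leaving the vestibular aqueduct alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidParameterError, SeedMissError, SegmentationFailureError
from .volio import LabelMap, VoxelImage

HU_LOWER_DEFAULT = -1024.0
HU_UPPER_DEFAULT = 700.0


@dataclass
class SegmentationParams:
    """Threshold band (inclusive at both ends) and component connectivity."""

    hu_lower: float = HU_LOWER_DEFAULT
    hu_upper: float = HU_UPPER_DEFAULT
    connectivity: int = 26
    roi_world: tuple[tuple[float, float, float], tuple[float, float, float]] | None = None

    def __post_init__(self) -> None:
        if self.hu_lower >= self.hu_upper:
            raise InvalidParameterError(
                f"hu_lower must be < hu_upper, got {self.hu_lower} >= {self.hu_upper}"
            )
        if self.connectivity not in (6, 18, 26):
            raise InvalidParameterError("connectivity must be 6, 18 or 26")


@dataclass
class CutPlane:
    """Oriented plane; voxels with signed distance <= 0 to it are kept."""

    point: tuple[float, float, float]
    normal: tuple[float, float, float]

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(n)
        if norm < 1e-12:
            raise InvalidParameterError("plane normal must be non-zero")
        self.normal = tuple(n / norm)
        self.point = tuple(float(p) for p in self.point)

    def signed_distance(self, points) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return (points - np.asarray(self.point)) @ np.asarray(self.normal)


_STRUCTURES = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def threshold_mask(image: VoxelImage, params: SegmentationParams) -> LabelMap:
    """Binary mask of voxels with hu_lower <= HU <= hu_upper (inclusive)."""
    data = image.data
    mask = (data >= params.hu_lower) & (data <= params.hu_upper)
    if params.roi_world is not None:
        lo = np.floor(image.world_to_index(params.roi_world[0])).astype(int)
        hi = np.ceil(image.world_to_index(params.roi_world[1])).astype(int)
        lo = np.clip(lo, 0, np.asarray(image.shape) - 1)
        hi = np.clip(hi, 0, np.asarray(image.shape) - 1)
        roi = np.zeros_like(mask)
        roi[lo[0]: hi[0] + 1, lo[1]: hi[1] + 1, lo[2]: hi[2] + 1] = True
        mask &= roi
    return LabelMap.from_bool(mask, image)


def connected_components(mask: LabelMap, connectivity: int = 26) -> tuple[LabelMap, np.ndarray]:
    """Label components 1..C ordered by decreasing voxel count.

    Returns the relabeled map and the per-component counts (index c-1 is
    the count of label c).
    """
    structure = _STRUCTURES[connectivity]
    raw, n = ndimage.label(mask.as_bool(), structure=structure)
    if n == 0:
        return LabelMap(np.zeros(mask.shape, dtype=np.int32), mask.spacing, mask.origin), np.array([], dtype=int)
    counts = np.bincount(raw.ravel())[1:]
    order = np.argsort(-counts, kind="stable")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[1 + order] = np.arange(1, n + 1, dtype=np.int32)
    return LabelMap(remap[raw], mask.spacing, mask.origin), counts[order]


def select_seeded_component(labels: LabelMap, seed_world, snap_mm: float = 0.0) -> LabelMap:
    """The component containing the voxel nearest the world-mm seed point.

    Ties between equidistant voxels resolve to the lowest (i, j, k) index
    (rounding half toward the lower index). A seed landing on background
    raises :class:`SeedMissError` reporting the distance to the nearest
    foreground voxel — unless that distance is within ``snap_mm``, in which
    case the seed snaps to the nearest foreground voxel (modeling an
    operator re-clicking a near-miss on a thin duct).
    """
    idx = np.asarray(labels.world_to_index(seed_world))
    if np.any(np.rint(idx) < 0) or np.any(np.rint(idx) >= np.asarray(labels.shape)):
        raise SeedMissError(f"seed {seed_world} outside image bounds")
    # round half-down so equidistant voxels tie-break to the lower index
    near = tuple(int(np.ceil(v - 0.5)) for v in idx)
    label = int(labels.data[near])
    if label == 0:
        fg = np.argwhere(labels.data > 0)
        if len(fg) == 0:
            raise SeedMissError("seed missed: mask is empty", nearest_mm=float("inf"))
        d = np.linalg.norm((fg - idx) * np.asarray(labels.spacing), axis=1)
        if d.min() <= snap_mm:
            label = int(labels.data[tuple(fg[np.argmin(d)])])
        else:
            raise SeedMissError(
                f"seed fell on background; nearest foreground {d.min():.3f} mm away",
                nearest_mm=float(d.min()),
            )
    return LabelMap.from_bool(labels.data == label, labels)


def clip_by_planes(mask: LabelMap, planes) -> LabelMap:
    """Keep voxels whose centers have signed distance <= 0 to every plane."""
    keep = mask.as_bool()
    if not planes:
        return LabelMap.from_bool(keep, mask)
    fg = np.argwhere(keep)
    if len(fg) == 0:
        return LabelMap.from_bool(keep, mask)
    world = mask.index_to_world(fg)
    ok = np.ones(len(fg), dtype=bool)
    for plane in planes:
        ok &= plane.signed_distance(world) <= 0.0
    out = np.zeros(mask.shape, dtype=bool)
    sel = fg[ok]
    out[sel[:, 0], sel[:, 1], sel[:, 2]] = True
    return LabelMap.from_bool(out, mask)


def isolate_va(
    image: VoxelImage,
    params: SegmentationParams,
    seed_world,
    vestibule_exit_plane: CutPlane,
    operculum_plane: CutPlane,
    snap_mm: float = 0.0,
) -> LabelMap:
    """Threshold -> components -> seeded selection -> clip to the VA segment."""
    mask = threshold_mask(image, params)
    labels, _ = connected_components(mask, params.connectivity)
    component = select_seeded_component(labels, seed_world, snap_mm=snap_mm)
    va = clip_by_planes(component, [vestibule_exit_plane, operculum_plane])
    if not va.as_bool().any():
        raise SegmentationFailureError("VA segmentation produced an empty mask")
    return va
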