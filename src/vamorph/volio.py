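"""Volumetric image, label-map and surface-mesh containers and I/O.

Geometry convention (fixed for the whole package):

* voxel index ``(i, j, k)`` maps to world coordinates
  ``(x, y, z) = origin + index * spacing`` (mm), i.e. the lattice is
  axis-aligned with no rotation; an *axial slice* is a fixed ``k``;
* the voxel value sits at the voxel center, and all point-in-voxel /
  point-in-plane tests use voxel centers;
* indices are 0-based.

Volumes with a non-identity direction matrix are rejected with
:class:`~vamorph.errors.UnsupportedGeometryError` rather than silently
resampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh as _trimesh

from .errors import FormatError, GeometryError, InvalidParameterError, UnsupportedGeometryError

_IMAGE_IO = {
    ".nii": "NiftiImageIO",
    ".nii.gz": "NiftiImageIO",
    ".mha": "MetaImageIO",
}


def _image_io_for(path: Path) -> str:
    name = path.name.lower()
    for ext, io in _IMAGE_IO.items():
        if name.endswith(ext):
            return io
    raise FormatError(f"unknown image extension: {path.name!r} (expected .nii, .nii.gz or .mha)")


@dataclass
class VoxelImage:
    """A 3D scalar lattice (HU) with axis-aligned world geometry.

    ``data[i, j, k]`` lives at world ``origin + (i, j, k) * spacing``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.size == 0:
            raise InvalidParameterError("image lattice must be a non-empty 3D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InvalidParameterError(f"spacing must be 3 positive values, got {self.spacing}")

    # -- geometry ---------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def index_to_world(self, index) -> np.ndarray:
        """Continuous index (i, j, k) -> world mm. Accepts (..., 3) arrays."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, point) -> np.ndarray:
        """World mm -> continuous index. Inverse of :meth:`index_to_world`."""
        point = np.asarray(point, dtype=float)
        return (point - np.asarray(self.origin)) / np.asarray(self.spacing)

    def nearest_index(self, point) -> tuple[int, int, int]:
        idx = np.rint(self.world_to_index(point)).astype(int)
        return tuple(int(v) for v in idx)

    def contains_point(self, point) -> bool:
        idx = np.rint(self.world_to_index(point))
        return bool(np.all(idx >= 0) and np.all(idx < np.asarray(self.shape)))

    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    def same_grid(self, other: "VoxelImage | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelMap(VoxelImage):
    """Integer-valued lattice on the same grid as its source image."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            raise InvalidParameterError("LabelMap data must be integer-valued")
        if self.data.min() < 0:
            raise InvalidParameterError("LabelMap values must be non-negative")

    @classmethod
    def from_bool(cls, mask: np.ndarray, like: VoxelImage) -> "LabelMap":
        return cls(mask.astype(np.uint8), like.spacing, like.origin)

    def as_bool(self) -> np.ndarray:
        return self.data > 0


@dataclass
class TriMesh:
    """Triangle surface mesh with vertices in world mm, 0-based faces."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.vertices) == 0 or len(self.faces) == 0:
            raise GeometryError("empty mesh")

    def to_trimesh(self) -> _trimesh.Trimesh:
        return _trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def is_watertight(self) -> bool:
        return bool(self.to_trimesh().is_watertight)


# -- image I/O -------------------------------------------------------------

def write_image(image: VoxelImage, path) -> Path:
    """Write as NIfTI-1 (.nii/.nii.gz) or MetaImage (.mha) by extension."""
    path = Path(path)
    io = _image_io_for(path)
    # sitk arrays are (z, y, x); our convention is (i, j, k) = (x, y, z)
    arr = np.ascontiguousarray(np.transpose(image.data, (2, 1, 0)))
    img = sitk.GetImageFromArray(arr)
    img.SetSpacing(tuple(image.spacing))
    img.SetOrigin(tuple(image.origin))
    writer = sitk.ImageFileWriter()
    writer.SetImageIO(io)
    writer.SetFileName(str(path))
    try:
        writer.Execute(img)
    except RuntimeError as exc:  # pragma: no cover - depends on sitk internals
        raise FormatError(f"failed to write {path}: {exc}") from exc
    return path


def read_image(path, as_labels: bool = False) -> VoxelImage:
    """Read a .nii/.nii.gz/.mha volume; reject rotated geometries."""
    path = Path(path)
    io = _image_io_for(path)
    reader = sitk.ImageFileReader()
    reader.SetImageIO(io)
    reader.SetFileName(str(path))
    try:
        img = reader.Execute()
    except RuntimeError as exc:
        raise FormatError(f"failed to read {path} as {io}: {exc}") from exc
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise UnsupportedGeometryError(
            f"{path.name}: rotated/oblique direction matrices are not supported"
        )
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    cls = LabelMap if as_labels else VoxelImage
    if as_labels:
        data = data.astype(np.int64)
    return cls(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


# -- mesh I/O --------------------------------------------------------------

def write_mesh(mesh: TriMesh, path) -> Path:
    """Write a mesh as ascii PLY or STL, chosen by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    tm = mesh.to_trimesh()
    if suffix == ".ply":
        payload = tm.export(file_type="ply", encoding="ascii")
    elif suffix == ".stl":
        payload = tm.export(file_type="stl")
    else:
        raise FormatError(f"unknown mesh extension: {path.name!r} (expected .ply or .stl)")
    mode = "wb" if isinstance(payload, bytes) else "w"
    with open(path, mode) as fh:
        fh.write(payload)
    return path


def read_mesh(path) -> TriMesh:
    path = Path(path)
    if path.suffix.lower() not in {".ply", ".stl"}:
        raise FormatError(f"unknown mesh extension: {path.name!r}")
    tm = _trimesh.load_mesh(str(path), process=False)
    return TriMesh(np.asarray(tm.vertices), np.asarray(tm.faces))
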