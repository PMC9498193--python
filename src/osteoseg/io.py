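"""Volume and mesh input/output with explicit grid-geometry bookkeeping.

Volumes are axis-aligned scalar grids stored as ``(slice, row, col)`` arrays
with per-axis physical spacing in millimetres.  The world coordinate of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing``; oblique direction cosines
are rejected on read.  Supported on-disk formats are MetaImage (.mhd/.raw)
and NIfTI (.nii/.nii.gz) for volumes, and binary little-endian PLY (scalar
carrying) plus STL (geometry only) for triangle meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import SimpleITK as sitk
import trimesh

__all__ = [
    "DEFAULT_LABEL_CODES",
    "ImageVolume",
    "LabelVolume",
    "ProbabilityVolume",
    "TriangleMesh",
    "read_volume",
    "read_labels",
    "write_volume",
    "read_mesh",
    "write_mesh",
    "signed_distance_colors",
]

#: Default integer codes for the knee-bone label convention used throughout:
#: background plus femur/tibia with their cartilage shells, and the patella
#: label added on top of the four-structure convention.  Override per dataset.
DEFAULT_LABEL_CODES = {
    "background": 0,
    "femur": 1,
    "femoral_cartilage": 2,
    "tibia": 3,
    "tibial_cartilage": 4,
    "patella": 5,
}


def _as_spacing(spacing) -> np.ndarray:
    s = np.asarray(spacing, dtype=float)
    if s.shape != (3,) or not np.all(s > 0):
        raise ValueError(f"spacing must be 3 strictly positive values, got {spacing!r}")
    return s


def _as_origin(origin) -> np.ndarray:
    o = np.asarray(origin, dtype=float)
    if o.shape != (3,):
        raise ValueError(f"origin must be a 3-vector, got {origin!r}")
    return o


@dataclass
class ImageVolume:
    """A 3D scalar grid in ``(slice, row, col)`` order with mm geometry.

    Parameters
    ----------
    voxels:
        Three-axis scalar array; intensities are in arbitrary scanner units.
    spacing_mm:
        Physical size of one voxel step along each array axis, all > 0.
    origin_mm:
        World position of voxel ``(0, 0, 0)``.
    """

    voxels: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValueError("voxels must be a 3D array with each axis of length >= 1")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = _as_origin(self.origin_mm)

    @property
    def shape(self) -> tuple:
        return self.voxels.shape

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """Physical bounding box ``(min_corner, max_corner)`` of the voxel centres."""
        extent = (np.array(self.shape) - 1) * self.spacing_mm
        return self.origin_mm.copy(), self.origin_mm + extent

    def with_voxels(self, voxels: np.ndarray) -> "ImageVolume":
        return replace(self, voxels=np.asarray(voxels))


@dataclass
class LabelVolume:
    """Integer class grid on the same geometry as its image volume."""

    labels: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    label_codes: dict = field(default_factory=lambda: dict(DEFAULT_LABEL_CODES))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be an integer array")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = _as_origin(self.origin_mm)
        present = set(np.unique(self.labels).tolist())
        known = set(int(v) for v in self.label_codes.values())
        unknown = present - known
        if unknown:
            raise ValueError(
                f"label values {sorted(unknown)} do not appear in label_codes {self.label_codes}"
            )

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def code(self, name: str) -> int:
        if name not in self.label_codes:
            raise KeyError(f"unknown label name {name!r}; known: {sorted(self.label_codes)}")
        return int(self.label_codes[name])

    def mask(self, name: str) -> np.ndarray:
        """Boolean foreground mask of a named structure."""
        return self.labels == self.code(name)


@dataclass
class ProbabilityVolume:
    """Per-voxel foreground probability grid, values in [0, 1]."""

    probs: np.ndarray
    spacing_mm: np.ndarray = field(default_factory=lambda: np.ones(3))
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 3:
            raise ValueError("probs must be a 3D array")
        if self.probs.min() < 0 or self.probs.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        self.spacing_mm = _as_spacing(self.spacing_mm)
        self.origin_mm = _as_origin(self.origin_mm)

    @property
    def shape(self) -> tuple:
        return self.probs.shape


@dataclass
class TriangleMesh:
    """Triangle surface mesh with vertices in mm and an optional vertex scalar.

    ``vertex_scalar`` typically carries a signed surface distance in mm and is
    written to PLY both as a scalar property and as a diverging colour.
    """

    vertices: np.ndarray
    faces: np.ndarray
    vertex_scalar: np.ndarray | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")
        if len(self.faces):
            degenerate = (
                (self.faces[:, 0] == self.faces[:, 1])
                | (self.faces[:, 1] == self.faces[:, 2])
                | (self.faces[:, 0] == self.faces[:, 2])
            )
            if degenerate.any():
                raise ValueError(f"{int(degenerate.sum())} degenerate faces")
        if self.vertex_scalar is not None:
            self.vertex_scalar = np.asarray(self.vertex_scalar, dtype=float).ravel()
            if len(self.vertex_scalar) != len(self.vertices):
                raise ValueError("vertex_scalar length must equal the vertex count")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def is_empty(self) -> bool:
        return len(self.vertices) == 0 or len(self.faces) == 0

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(vertices=self.vertices, faces=self.faces, process=False)

    def is_watertight(self) -> bool:
        return bool(self.as_trimesh().is_watertight)


# ---------------------------------------------------------------------------
# Volume I/O (MetaImage / NIfTI via SimpleITK)

_VOLUME_SUFFIXES = (".mhd", ".nii", ".nii.gz")


def _check_volume_path(path: Path) -> None:
    name = path.name.lower()
    if not any(name.endswith(s) for s in _VOLUME_SUFFIXES):
        raise ValueError(
            f"unsupported volume format for {path}; expected one of {_VOLUME_SUFFIXES}"
        )


def read_volume(path) -> ImageVolume:
    """Read a MetaImage or NIfTI volume.

    The returned array is ordered ``(slice, row, col)``; spacing and origin
    are reordered to match.  Volumes with oblique direction cosines are
    rejected: only axis-aligned grids are supported.
    """
    path = Path(path)
    _check_volume_path(path)
    if not path.exists():
        raise IOError(f"cannot read volume: {path} does not exist")
    try:
        img = sitk.ReadImage(str(path))
    except Exception as exc:  # SimpleITK raises RuntimeError on bad payloads
        raise IOError(f"failed to read volume {path}: {exc}") from exc
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise ValueError(
            f"{path}: oblique direction cosines are not supported (axis-aligned grids only)"
        )
    voxels = sitk.GetArrayFromImage(img)  # (z, y, x) == (slice, row, col)
    spacing = np.array(img.GetSpacing(), dtype=float)[::-1]
    origin = np.array(img.GetOrigin(), dtype=float)[::-1]
    return ImageVolume(voxels=voxels, spacing_mm=spacing, origin_mm=origin)


def read_labels(path, label_codes: dict | None = None) -> LabelVolume:
    """Read an integer label volume; ``label_codes`` defaults to the knee map."""
    vol = read_volume(path)
    labels = vol.voxels
    if not np.issubdtype(labels.dtype, np.integer):
        rounded = np.rint(labels)
        if not np.array_equal(rounded, labels):
            raise ValueError(f"{path}: label volume contains non-integer values")
        labels = rounded.astype(np.int32)
    codes = dict(DEFAULT_LABEL_CODES) if label_codes is None else dict(label_codes)
    return LabelVolume(
        labels=labels,
        spacing_mm=vol.spacing_mm,
        origin_mm=vol.origin_mm,
        label_codes=codes,
    )


def write_volume(volume, path) -> None:
    """Write an :class:`ImageVolume`, :class:`LabelVolume` or
    :class:`ProbabilityVolume` as MetaImage or NIfTI.

    Integer payloads round-trip bit-identically; floats are stored at their
    native precision.
    """
    path = Path(path)
    _check_volume_path(path)
    if not path.parent.exists():
        raise IOError(f"cannot write volume: directory {path.parent} does not exist")
    if isinstance(volume, LabelVolume):
        arr = volume.labels
    elif isinstance(volume, ProbabilityVolume):
        arr = volume.probs
    else:
        arr = volume.voxels
    img = sitk.GetImageFromArray(np.ascontiguousarray(arr))
    img.SetSpacing(tuple(float(s) for s in volume.spacing_mm[::-1]))
    img.SetOrigin(tuple(float(o) for o in volume.origin_mm[::-1]))
    try:
        sitk.WriteImage(img, str(path))
    except Exception as exc:
        raise IOError(f"failed to write volume {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Mesh I/O


def signed_distance_colors(scalar: np.ndarray, vmax: float | None = None) -> np.ndarray:
    """Map a signed scalar to RGB via a symmetric blue-white-red diverging map.

    Zero maps to white (the colour-map centre); ``-vmax`` to pure blue and
    ``+vmax`` to pure red.  ``vmax`` defaults to ``max(|scalar|)``.
    Returns uint8 RGB of shape ``(n, 3)``.
    """
    scalar = np.asarray(scalar, dtype=float).ravel()
    if vmax is None:
        vmax = float(np.max(np.abs(scalar))) if len(scalar) else 0.0
    if vmax <= 0:
        return np.full((len(scalar), 3), 255, dtype=np.uint8)
    t = np.clip(scalar / vmax, -1.0, 1.0)
    rgb = np.empty((len(scalar), 3))
    neg, pos = t < 0, t >= 0
    # blue (0,0,255) -> white -> red (255,0,0), linear in the scalar
    rgb[neg, 0] = 255 * (1 + t[neg])
    rgb[neg, 1] = 255 * (1 + t[neg])
    rgb[neg, 2] = 255
    rgb[pos, 0] = 255
    rgb[pos, 1] = 255 * (1 - t[pos])
    rgb[pos, 2] = 255 * (1 - t[pos])
    return np.rint(rgb).astype(np.uint8)


_PLY_SCALAR_NAME = "signed_distance"


def write_mesh(mesh: TriangleMesh, path, vmax: float | None = None) -> None:
    """Write a mesh as binary little-endian PLY or STL.

    PLY output stores ``vertex_scalar`` (when present) both as a float
    ``signed_distance`` property and as RGB vertex colour under a symmetric
    diverging map (blue = inside / negative, red = outside / positive).
    STL stores geometry only.
    """
    path = Path(path)
    if mesh.is_empty():
        raise ValueError("refusing to write an empty mesh")
    suffix = path.suffix.lower()
    if suffix == ".stl":
        mesh.as_trimesh().export(str(path))
        return
    if suffix != ".ply":
        raise ValueError(f"unsupported mesh format {suffix!r}; use .ply or .stl")

    n_v, n_f = mesh.n_vertices, mesh.n_faces
    scalar = mesh.vertex_scalar
    header = ["ply", "format binary_little_endian 1.0", f"element vertex {n_v}"]
    header += ["property float x", "property float y", "property float z"]
    if scalar is not None:
        header += [
            "property uchar red",
            "property uchar green",
            "property uchar blue",
            f"property float {_PLY_SCALAR_NAME}",
        ]
    header += [f"element face {n_f}", "property list uchar int vertex_indices", "end_header"]

    with open(path, "wb") as fh:
        fh.write(("\n".join(header) + "\n").encode("ascii"))
        verts = mesh.vertices.astype("<f4")
        if scalar is None:
            fh.write(verts.tobytes())
        else:
            colors = signed_distance_colors(scalar, vmax=vmax)
            dt = np.dtype(
                [("xyz", "<f4", 3), ("rgb", "u1", 3), ("scalar", "<f4")]
            )
            rec = np.empty(n_v, dtype=dt)
            rec["xyz"] = verts
            rec["rgb"] = colors
            rec["scalar"] = scalar.astype("<f4")
            fh.write(rec.tobytes())
        fdt = np.dtype([("n", "u1"), ("idx", "<i4", 3)])
        frec = np.empty(n_f, dtype=fdt)
        frec["n"] = 3
        frec["idx"] = mesh.faces.astype("<i4")
        fh.write(frec.tobytes())


def read_mesh(path) -> TriangleMesh:
    """Read a PLY or STL mesh; recovers the signed-distance scalar from PLY."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read mesh: {path} does not exist")
    loaded = trimesh.load(str(path), process=False)
    scalar = None
    raw = loaded.metadata.get("_ply_raw") if hasattr(loaded, "metadata") else None
    if raw is not None:
        vdata = raw.get("vertex", {}).get("data")
        names = getattr(getattr(vdata, "dtype", None), "names", None) or ()
        if _PLY_SCALAR_NAME in names:
            scalar = np.asarray(vdata[_PLY_SCALAR_NAME], dtype=float)
    return TriangleMesh(vertices=np.asarray(loaded.vertices), faces=np.asarray(loaded.faces), vertex_scalar=scalar)
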