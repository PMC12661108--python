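"""Image volumes, world-coordinate geometry and rigid-transform algebra.

Conventions used throughout the package:

* world coordinates are LPS (x = left-right, y = anterior-posterior,
  z = superior-inferior), in millimetres;
* voxel indices are 0-based and refer to voxel *centers*;
* a :class:`VoxelGrid` maps index ``i`` to the world point
  ``origin + orientation @ (spacing * i)``;
* a :class:`RigidTransform` maps world points as ``rotation @ p + translation``
  and is translation-only (identity rotation) everywhere in the default
  pipeline.

NIfTI I/O goes through nibabel; the affine is stored verbatim in the LPS
convention above. Transform files are plain-text 4x4 row-major homogeneous
matrices (one row per line, ``#`` comments allowed), mapping MRI world
points to CT world points unless the header says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import BoundsError, EmptyMaskError, ValidationError

__all__ = [
    "VoxelGrid",
    "RigidTransform",
    "SegmentationMask",
    "IDENTITY",
    "voxel_to_world",
    "world_to_voxel",
    "mask_centroid",
    "compose",
    "invert",
    "resample",
    "load_volume",
    "save_volume",
    "load_mask",
    "save_mask",
    "read_transform",
    "write_transform",
]

_ORTHONORMAL_TOL = 1e-9


def _as_triple(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).reshape(-1)
    if arr.size != 3:
        raise ValidationError(f"{name} must have exactly 3 components, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValidationError(f"{name} must be finite, got {arr}")
    return arr


def _check_rotation(r: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.shape != (3, 3):
        raise ValidationError(f"rotation must be 3x3, got shape {r.shape}")
    if not np.all(np.isfinite(r)):
        raise ValidationError("rotation must be finite")
    if not np.allclose(r @ r.T, np.eye(3), atol=max(tol, 1e-9)):
        raise ValidationError("rotation matrix is not orthonormal")
    if np.linalg.det(r) < 0:
        raise ValidationError("rotation matrix has negative determinant (reflection)")
    return r


@dataclass(frozen=True)
class RigidTransform:
    """A world-coordinate rigid map ``p -> rotation @ p + translation``.

    ``rotation`` defaults to the identity; the registration pipeline is
    translation-only by default, with rotation supported in the algebra for
    completeness.
    """

    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "translation", _as_triple(self.translation, "translation"))
        object.__setattr__(self, "rotation", _check_rotation(self.rotation))

    @property
    def is_translation_only(self) -> bool:
        return bool(np.allclose(self.rotation, np.eye(3), atol=1e-12))

    def apply(self, points) -> np.ndarray:
        """Map world points (shape ``(3,)`` or ``(n, 3)``) through the transform."""
        pts = np.asarray(points, dtype=float)
        single = pts.ndim == 1
        pts = np.atleast_2d(pts)
        out = pts @ self.rotation.T + self.translation
        return out[0] if single else out

    def matrix(self) -> np.ndarray:
        """The 4x4 homogeneous matrix representation."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m) -> "RigidTransform":
        m = np.asarray(m, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"homogeneous matrix must be 4x4, got {m.shape}")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValidationError("last row of a rigid homogeneous matrix must be [0 0 0 1]")
        return cls(translation=m[:3, 3], rotation=m[:3, :3])

    @classmethod
    def from_translation(cls, t) -> "RigidTransform":
        return cls(translation=t)

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return compose(self, other)


IDENTITY = RigidTransform()


def compose(outer: RigidTransform, inner: RigidTransform) -> RigidTransform:
    """Composition ``result(p) = outer(inner(p))``."""
    return RigidTransform(
        rotation=outer.rotation @ inner.rotation,
        translation=outer.rotation @ inner.translation + outer.translation,
    )


def invert(t: RigidTransform) -> RigidTransform:
    """Inverse transform: ``compose(t, invert(t))`` is the identity."""
    rinv = t.rotation.T
    return RigidTransform(rotation=rinv, translation=-(rinv @ t.translation))


@dataclass
class VoxelGrid:
    """A 3-D scalar image with spacing, origin and orientation (mm, LPS).

    ``values`` holds MRI arbitrary units or CT Hounsfield units. ``origin``
    is the world position of the *center* of voxel ``(0, 0, 0)``.
    """

    values: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValidationError(f"values must be 3-D, got ndim={self.values.ndim}")
        self.spacing = _as_triple(self.spacing, "spacing")
        if np.any(self.spacing <= 0):
            raise ValidationError(f"spacing must be positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")
        self.orientation = _check_rotation(self.orientation, tol=1e-6)

    @property
    def dims(self) -> tuple:
        return self.values.shape

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (voxel-center convention)."""
        m = np.eye(4)
        m[:3, :3] = self.orientation * self.spacing[np.newaxis, :]
        m[:3, 3] = self.origin
        return m

    def same_geometry(self, other: "VoxelGrid", tol: float = 1e-6) -> bool:
        return (
            self.dims == other.dims
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
            and np.allclose(self.orientation, other.orientation, atol=tol)
        )

    def world_extent(self) -> tuple:
        """(lo, hi) world bounds of the voxel-center lattice (corner voxels)."""
        idx_corners = np.array(
            [[i, j, k] for i in (0, self.dims[0] - 1) for j in (0, self.dims[1] - 1) for k in (0, self.dims[2] - 1)],
            dtype=float,
        )
        world = idx_corners * self.spacing @ self.orientation.T + self.origin
        return world.min(axis=0), world.max(axis=0)

    def with_values(self, values: np.ndarray) -> "VoxelGrid":
        return replace(self, values=values)


@dataclass
class SegmentationMask(VoxelGrid):
    """A binary mask sharing the geometry of the image it annotates (1 = foreground)."""

    def __post_init__(self):
        super().__post_init__()
        vals = np.asarray(self.values)
        if not np.isin(np.unique(vals), [0, 1]).all():
            raise ValidationError("mask values must be binary (0/1)")
        self.values = vals.astype(np.uint8)

    @property
    def n_foreground(self) -> int:
        return int(self.values.sum())


def voxel_to_world(grid: VoxelGrid, index) -> np.ndarray:
    """World coordinate (mm) of the center of voxel ``index``.

    Raises :class:`BoundsError` naming the axis if the index is outside the grid.
    """
    idx = np.asarray(index, dtype=float)
    single = idx.ndim == 1
    idx2 = np.atleast_2d(idx)
    for axis in range(3):
        bad = (idx2[:, axis] < 0) | (idx2[:, axis] > grid.dims[axis] - 1)
        if bad.any():
            raise BoundsError(
                f"index {idx2[bad][0].tolist()} out of bounds on axis {axis} "
                f"(dims {grid.dims})"
            )
    world = (idx2 * grid.spacing) @ grid.orientation.T + grid.origin
    return world[0] if single else world


def world_to_voxel(grid: VoxelGrid, point) -> np.ndarray:
    """Continuous voxel index of a world point (inverse of :func:`voxel_to_world`)."""
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    idx = ((pts - grid.origin) @ grid.orientation) / grid.spacing
    return idx[0] if np.asarray(point).ndim == 1 else idx


def mask_centroid(mask: SegmentationMask) -> np.ndarray:
    """Unweighted mean of the world coordinates of all foreground voxel centers."""
    fg = np.argwhere(mask.values > 0)
    if fg.shape[0] == 0:
        raise EmptyMaskError("mask has no foreground voxels (segmentation failure?)")
    mean_idx = fg.mean(axis=0)
    return grid_point(mask, mean_idx)


def grid_point(grid: VoxelGrid, continuous_index) -> np.ndarray:
    """World coordinate of a (possibly fractional) voxel index, without bounds checks."""
    idx = np.asarray(continuous_index, dtype=float)
    return idx * grid.spacing @ grid.orientation.T + grid.origin


def resample(
    source: VoxelGrid,
    transform: RigidTransform,
    reference: VoxelGrid,
    interpolation: str = "linear",
    fill_value: float = 0.0,
) -> VoxelGrid:
    """Resample ``source`` onto the geometry of ``reference`` under ``transform``.

    ``transform`` maps *source-frame* world points to *reference-frame* world
    points (moving -> fixed); the output voxel at reference world point ``w``
    samples the source at ``transform.inverse(w)``. Points outside the source
    field of view receive ``fill_value`` (use 0 for MRI, -1000 HU for CT).
    """
    if interpolation not in ("linear", "nearest"):
        raise ValidationError(f"interpolation must be 'linear' or 'nearest', got {interpolation!r}")
    order = 1 if interpolation == "linear" else 0

    inv = invert(transform)
    # reference voxel-center world coordinates
    ii, jj, kk = np.meshgrid(
        np.arange(reference.dims[0]),
        np.arange(reference.dims[1]),
        np.arange(reference.dims[2]),
        indexing="ij",
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(float)
    world_ref = idx * reference.spacing @ reference.orientation.T + reference.origin
    world_src = inv.apply(world_ref)
    src_idx = ((world_src - source.origin) @ source.orientation) / source.spacing

    out = ndimage.map_coordinates(
        np.asarray(source.values, dtype=float),
        src_idx.T,
        order=order,
        mode="constant",
        cval=fill_value,
        prefilter=False,
    ).reshape(reference.dims)
    return VoxelGrid(
        values=out,
        spacing=reference.spacing.copy(),
        origin=reference.origin.copy(),
        orientation=reference.orientation.copy(),
    )


def sample_at_world(
    source: VoxelGrid,
    world_points: np.ndarray,
    interpolation: str = "linear",
    fill_value: float = 0.0,
) -> np.ndarray:
    """Sample ``source`` at arbitrary world points (helper for the cost function)."""
    order = 1 if interpolation == "linear" else 0
    src_idx = ((world_points - source.origin) @ source.orientation) / source.spacing
    return ndimage.map_coordinates(
        np.asarray(source.values, dtype=float),
        src_idx.T,
        order=order,
        mode="constant",
        cval=fill_value,
        prefilter=False,
    )


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def save_volume(grid: VoxelGrid, path) -> None:
    """Write a volume as NIfTI-1; the affine carries the package's LPS convention."""
    img = nib.Nifti1Image(np.asarray(grid.values), grid.affine)
    nib.save(img, str(path))


def load_volume(path) -> VoxelGrid:
    img = nib.load(str(path))
    aff = np.asarray(img.affine, dtype=float)
    lin = aff[:3, :3]
    spacing = np.linalg.norm(lin, axis=0)
    if np.any(spacing <= 0):
        raise ValidationError(f"degenerate affine in {path}")
    orientation = lin / spacing[np.newaxis, :]
    return VoxelGrid(
        values=np.asarray(img.dataobj),
        spacing=spacing,
        origin=aff[:3, 3],
        orientation=orientation,
    )


def save_mask(mask: SegmentationMask, path) -> None:
    img = nib.Nifti1Image(np.asarray(mask.values, dtype=np.uint8), mask.affine)
    nib.save(img, str(path))


def load_mask(path) -> SegmentationMask:
    grid = load_volume(path)
    return SegmentationMask(
        values=(np.asarray(grid.values) > 0.5).astype(np.uint8),
        spacing=grid.spacing,
        origin=grid.origin,
        orientation=grid.orientation,
    )


_TRANSFORM_HEADER = "# rigid transform: 4x4 homogeneous matrix, row-major, maps MRI world (mm) -> CT world (mm)"


def write_transform(t: RigidTransform, path, header: str = _TRANSFORM_HEADER) -> None:
    """Write a plain-text 4x4 homogeneous matrix, one row per line.

    The direction of the map (MRI world -> CT world by default) is recorded
    in a leading ``#`` comment so files remain self-describing.
    """
    lines = [header]
    for row in t.matrix():
        lines.append(" ".join(f"{v:.12g}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_transform(path) -> RigidTransform:
    """Read a plain-text 4x4 transform; ``#`` comment lines are ignored."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        rows.append([float(tok) for tok in line.split()])
    m = np.asarray(rows, dtype=float)
    if m.shape != (4, 4):
        raise ValidationError(f"transform file {path} does not contain a 4x4 matrix (got {m.shape})")
    return RigidTransform.from_matrix(m)
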