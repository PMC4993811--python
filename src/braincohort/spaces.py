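"""Coordinate spaces and spatial transforms.

All world coordinates in this package are RAS+ millimetres.  Two kinds of
precomputed registration are supported: 4x4 affine matrices and dense
displacement (warp) fields.  Transforms are *applied*, never estimated.

An :class:`AffineTransform` maps points of its ``source_space`` into its
``target_space`` by homogeneous multiplication.  A :class:`WarpField` stores a
per-voxel displacement vector in mm on its own grid; applying it adds the
trilinearly interpolated displacement to each point.  Points outside the warp
grid are a hard error — silent extrapolation would corrupt downstream ROI
propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import (
    NonInvertibleError,
    OutOfBoundsError,
    SpaceMismatchError,
    ValidationError,
)

_DET_TOL = 1e-12


@dataclass(frozen=True)
class CoordinateSpace:
    """A named world coordinate frame (RAS+, millimetres)."""

    name: str

    def __post_init__(self):
        if not self.name:
            raise ValidationError("coordinate space name must be non-empty")


def _as_space(space: "CoordinateSpace | str") -> CoordinateSpace:
    return space if isinstance(space, CoordinateSpace) else CoordinateSpace(str(space))


@dataclass(frozen=True)
class AffineTransform:
    """A 4x4 affine mapping source_space -> target_space, in mm.

    The last row must be exactly (0, 0, 0, 1) and the linear 3x3 block must
    be invertible.
    """

    matrix: np.ndarray
    source_space: CoordinateSpace = field(default=CoordinateSpace("unspecified"))
    target_space: CoordinateSpace = field(default=CoordinateSpace("unspecified"))

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError(f"affine matrix must be 4x4, got {m.shape}")
        if not np.all(np.isfinite(m)):
            raise ValidationError("affine matrix contains non-finite entries")
        if not np.array_equal(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValidationError("affine last row must be exactly (0, 0, 0, 1)")
        if abs(np.linalg.det(m[:3, :3])) <= _DET_TOL:
            raise NonInvertibleError("affine linear block is singular")
        m.flags.writeable = False
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "source_space", _as_space(self.source_space))
        object.__setattr__(self, "target_space", _as_space(self.target_space))

    @classmethod
    def identity(cls, space: CoordinateSpace | str = "unspecified") -> "AffineTransform":
        s = _as_space(space)
        return cls(np.eye(4), s, s)

    @property
    def linear(self) -> np.ndarray:
        return self.matrix[:3, :3]

    @property
    def translation(self) -> np.ndarray:
        return self.matrix[:3, 3]


@dataclass(frozen=True)
class WarpField:
    """Dense displacement field: per-voxel (dx, dy, dz) in mm.

    ``displacement`` has shape (nx, ny, nz, 3); ``grid_affine`` maps voxel
    indices of that grid to world mm.
    """

    displacement: np.ndarray
    grid_affine: AffineTransform
    source_space: CoordinateSpace = field(default=CoordinateSpace("unspecified"))
    target_space: CoordinateSpace = field(default=CoordinateSpace("unspecified"))

    def __post_init__(self):
        d = np.asarray(self.displacement, dtype=float)
        if d.ndim != 4 or d.shape[3] != 3:
            raise ValidationError(
                f"displacement must have shape (nx, ny, nz, 3), got {d.shape}")
        if min(d.shape[:3]) < 2:
            raise ValidationError("warp grid needs >= 2 voxels per axis")
        if not np.all(np.isfinite(d)):
            raise ValidationError("displacement field contains non-finite values")
        d.flags.writeable = False
        object.__setattr__(self, "displacement", d)
        object.__setattr__(self, "source_space", _as_space(self.source_space))
        object.__setattr__(self, "target_space", _as_space(self.target_space))

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.displacement.shape[:3]


def compose_affine(a: AffineTransform, b: AffineTransform) -> AffineTransform:
    """Chain two affines: the result applies ``a`` first, then ``b``.

    Requires ``a.target_space == b.source_space``; the result maps
    ``a.source_space`` to ``b.target_space`` and equals the matrix product
    ``b.matrix @ a.matrix``.
    """
    if a.target_space != b.source_space:
        raise SpaceMismatchError(
            f"cannot chain: {a.target_space.name!r} != {b.source_space.name!r}")
    return AffineTransform(b.matrix @ a.matrix, a.source_space, b.target_space)


def invert_affine(a: AffineTransform) -> AffineTransform:
    """Inverse transform, swapping source and target spaces."""
    try:
        inv = np.linalg.inv(a.matrix)
    except np.linalg.LinAlgError as e:  # pragma: no cover - guarded in ctor
        raise NonInvertibleError(str(e)) from e
    inv[3] = [0.0, 0.0, 0.0, 1.0]  # clean rounding noise in the last row
    return AffineTransform(inv, a.target_space, a.source_space)


def _check_points(points) -> np.ndarray:
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValidationError(f"points must be (n, 3), got {pts.shape}")
    if not np.all(np.isfinite(pts)):
        bad = int(np.argwhere(~np.all(np.isfinite(pts), axis=1))[0, 0])
        raise ValidationError(f"non-finite point at index {bad}")
    return pts


def apply_affine_points(a: AffineTransform, points) -> np.ndarray:
    """Map an (n, 3) array of mm points through the affine, preserving order."""
    pts = _check_points(points)
    return pts @ a.linear.T + a.translation


def world_to_voxel(grid_affine: AffineTransform, points) -> np.ndarray:
    """Continuous voxel coordinates of world-mm points on a grid."""
    return apply_affine_points(invert_affine(grid_affine), points)


def _trilinear(grid: np.ndarray, vox: np.ndarray) -> np.ndarray:
    """Trilinear interpolation of a (nx,ny,nz,c) grid at (n,3) voxel coords.

    Assumes all coordinates already validated to lie inside the grid.
    """
    shape = np.array(grid.shape[:3])
    lo = np.floor(vox).astype(int)
    lo = np.minimum(lo, shape - 2)  # points exactly on the far face
    lo = np.maximum(lo, 0)
    frac = vox - lo
    out = np.zeros((vox.shape[0], grid.shape[3]))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                w = (np.where(dx, frac[:, 0], 1 - frac[:, 0])
                     * np.where(dy, frac[:, 1], 1 - frac[:, 1])
                     * np.where(dz, frac[:, 2], 1 - frac[:, 2]))
                out += w[:, None] * grid[lo[:, 0] + dx, lo[:, 1] + dy, lo[:, 2] + dz]
    return out


def _require_inside(vox: np.ndarray, shape, margin: float = 0.0):
    bad = np.any((vox < margin) | (vox > np.array(shape) - 1 - margin), axis=1)
    if np.any(bad):
        idx = int(np.argwhere(bad)[0, 0])
        raise OutOfBoundsError(
            f"point index {idx} falls outside the warp grid "
            f"(voxel coords {np.round(vox[idx], 3).tolist()}, grid {tuple(shape)})")


def apply_warp_points(w: WarpField, points) -> np.ndarray:
    """Displace points by the trilinearly interpolated warp vector.

    Every point must map inside the warp grid's voxel bounding box.
    """
    pts = _check_points(points)
    vox = world_to_voxel(w.grid_affine, pts)
    _require_inside(vox, w.grid_shape)
    return pts + _trilinear(w.displacement, vox)


def local_jacobian_det(w: WarpField, point) -> float:
    """Determinant of the local mapping x -> x + d(x) at a world point.

    The displacement gradient is estimated by central differences with a step
    of one voxel spacing per axis, so the point needs a one-voxel margin from
    the grid boundary.  For a field encoding a global affine the result equals
    |det| of that affine's linear block; values > 1 mean local expansion.
    """
    pt = _check_points(point)
    if pt.shape[0] != 1:
        raise ValidationError("local_jacobian_det takes a single point")
    vox = world_to_voxel(w.grid_affine, pt)
    _require_inside(vox, w.grid_shape, margin=1.0)
    lin = w.grid_affine.linear
    # Directional derivatives of d along the grid axes (step = one voxel
    # spacing), then change of basis to world axes: if G's columns are
    # (d+ - d-) / 2|s_a| for world steps s_a = lin @ e_a, then
    # dd/dx = G @ inv(U) with U's columns the unit directions s_a/|s_a|.
    G = np.empty((3, 3))
    U = np.empty((3, 3))
    for axis in range(3):
        step_vox = np.zeros(3)
        step_vox[axis] = 1.0
        step_mm = lin[:, axis]
        norm = np.linalg.norm(step_mm)
        d_plus = _trilinear(w.displacement, vox + step_vox)[0]
        d_minus = _trilinear(w.displacement, vox - step_vox)[0]
        G[:, axis] = (d_plus - d_minus) / (2.0 * norm)
        U[:, axis] = step_mm / norm
    grad_world = G @ np.linalg.inv(U)
    return float(np.linalg.det(np.eye(3) + grad_world))
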