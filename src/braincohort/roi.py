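"""Spherical regions of interest.

A sphere ROI is the workhorse region primitive: placed once in one subject,
propagated to the rest of the cohort through the registered transforms, and
then used to sample scalar images (mean FA inside the sphere) or to select
the tractography streamlines that cross it.

Radius propagation under a non-rigid transform is under-determined (a sphere
maps to an ellipsoid); the volume-preserving convention is used: the new
radius is the old one times the cube root of the local volume-change
determinant, so rigid transforms leave the radius untouched and a uniform
scale s multiplies it by s.  Propagated spheres are flagged as automatic so a
reviewer knows they still await per-subject fine adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import EmptyRegionError, SpaceMismatchError, ValidationError
from .imaging import StreamlineSet, Volume
from .spaces import (
    AffineTransform,
    CoordinateSpace,
    WarpField,
    apply_affine_points,
    apply_warp_points,
    local_jacobian_det,
    world_to_voxel,
)


@dataclass(frozen=True)
class SphereROI:
    roi_id: str
    subject_id: str
    space: CoordinateSpace
    center: np.ndarray  # world mm
    radius: float  # mm, > 0
    auto_propagated: bool = field(default=False)

    def __post_init__(self):
        c = np.asarray(self.center, dtype=float).reshape(-1)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ValidationError("sphere center must be a finite 3-vector (mm)")
        if not (np.isfinite(self.radius) and self.radius > 0):
            raise ValidationError(f"sphere radius must be > 0, got {self.radius}")
        c.flags.writeable = False
        object.__setattr__(self, "center", c)
        if isinstance(self.space, str):
            object.__setattr__(self, "space", CoordinateSpace(self.space))


def create_sphere(subject_id: str, space, center, radius: float,
                  roi_id: str | None = None, db=None) -> SphereROI:
    """Create (and optionally persist) a sphere ROI.

    When a cohort database is given the ROI is stored there so any other
    analysis stage can retrieve it by id.
    """
    if roi_id is None:
        roi_id = f"{subject_id}:sphere:{np.random.default_rng().integers(1 << 30)}"
    roi = SphereROI(roi_id, subject_id, space, center, float(radius))
    if db is not None:
        db.save_roi(roi)
    return roi


def propagate_sphere(roi: SphereROI, transform: AffineTransform | WarpField,
                     target_subject: str) -> SphereROI:
    """Carry a sphere into another subject through a registered transform.

    The center is mapped exactly; the radius is scaled by the cube root of
    the (local) volume-change determinant.  The result is marked
    auto-propagated: position and size approximate the source sphere and are
    expected to be fine-tuned per subject.
    """
    if transform.source_space != roi.space:
        raise SpaceMismatchError(
            f"transform maps from {transform.source_space.name!r} "
            f"but ROI lives in {roi.space.name!r}")
    if isinstance(transform, AffineTransform):
        new_center = apply_affine_points(transform, roi.center[None, :])[0]
        scale = abs(float(np.linalg.det(transform.linear))) ** (1.0 / 3.0)
    else:
        new_center = apply_warp_points(transform, roi.center[None, :])[0]
        scale = local_jacobian_det(transform, roi.center) ** (1.0 / 3.0)
    return SphereROI(
        roi_id=f"{roi.roi_id}@{target_subject}",
        subject_id=target_subject,
        space=transform.target_space,
        center=new_center,
        radius=roi.radius * scale,
        auto_propagated=True,
    )


def _voxel_centers_in_sphere(v: Volume, roi: SphereROI) -> np.ndarray:
    """Boolean mask (over a candidate bbox) -> flat world distances test.

    Returns the (n, 3) integer voxel indices whose centers lie within
    ``roi.radius`` of the center.
    """
    # conservative voxel-space bounding box: map the 8 corners of the world
    # cube center +/- r, clamp to grid, pad by one voxel
    r = roi.radius
    corners = roi.center + r * np.array(
        [[sx, sy, sz] for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    vox_corners = world_to_voxel(v.voxel_to_world, corners)
    lo = np.floor(vox_corners.min(axis=0)).astype(int) - 1
    hi = np.ceil(vox_corners.max(axis=0)).astype(int) + 1
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.array(v.data.shape) - 1)
    if np.any(hi < lo):
        return np.empty((0, 3), dtype=int)
    ii, jj, kk = np.meshgrid(*(np.arange(a, b + 1) for a, b in zip(lo, hi)),
                             indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    centers = apply_affine_points(v.voxel_to_world, idx.astype(float))
    dist2 = np.sum((centers - roi.center) ** 2, axis=1)
    return idx[dist2 <= r * r]


def mean_in_sphere(v: Volume, roi: SphereROI) -> tuple[float, int]:
    """Mean of a scalar image over voxels whose centers fall in the sphere.

    Membership is voxel-center-in-sphere (no partial-volume weighting);
    returns (mean, n_voxels).  A sphere containing no voxel centers is an
    :class:`EmptyRegionError`, never a NaN.
    """
    if v.space != roi.space:
        raise SpaceMismatchError(
            f"volume in {v.space.name!r} but ROI in {roi.space.name!r}")
    idx = _voxel_centers_in_sphere(v, roi)
    if len(idx) == 0:
        raise EmptyRegionError(
            f"sphere {roi.roi_id} (r={roi.radius} mm) contains no voxel centers")
    vals = v.data[idx[:, 0], idx[:, 1], idx[:, 2]]
    return float(np.mean(vals)), int(len(idx))


def densify_polyline(line: np.ndarray, max_step: float) -> np.ndarray:
    """Subdivide segments so that no step exceeds ``max_step`` mm.

    Original vertices are always kept; extra points are inserted uniformly
    along each over-long segment.
    """
    if max_step <= 0:
        raise ValidationError("max_step must be positive")
    pieces = [line[:1]]
    for a, b in zip(line[:-1], line[1:]):
        seg = np.linalg.norm(b - a)
        n = int(np.ceil(seg / max_step)) if seg > max_step else 1
        t = np.linspace(0.0, 1.0, n + 1)[1:, None]
        pieces.append(a + t * (b - a))
    return np.vstack(pieces)


def streamlines_crossing_sphere(s: StreamlineSet, roi: SphereROI) -> StreamlineSet:
    """Streamlines with at least one (densified) point inside the sphere.

    Segments longer than radius/2 are subdivided before the vertex test so a
    chord that pierces the sphere between two distant vertices is not missed.
    Ids of the surviving streamlines are preserved.
    """
    if s.space != roi.space:
        raise SpaceMismatchError(
            f"streamlines in {s.space.name!r} but ROI in {roi.space.name!r}")
    step = roi.radius / 2.0
    r2 = roi.radius ** 2
    keep = []
    for line, sid in zip(s.streamlines, s.ids):
        dense = densify_polyline(line, step)
        d2 = np.sum((dense - roi.center) ** 2, axis=1)
        if np.any(d2 <= r2):
            keep.append(int(sid))
    return s.subset(keep)


def sphere_contains_points(roi: SphereROI, points: np.ndarray) -> np.ndarray:
    """Boolean mask of points within the sphere (inclusive boundary)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    return np.sum((pts - roi.center) ** 2, axis=1) <= roi.radius ** 2
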