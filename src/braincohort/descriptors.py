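"""Scalar per-subject descriptors derived from geometry.

These operations turn spatial objects into numbers that can sit next to
clinical variables in the cohort database: the volume of a set of segmented
structures, the streamline count / mean length / mean scalar of a bundle, and
plain linear distances.  :func:`capture_descriptor` runs one descriptor over
a whole sample, flags missing subjects instead of dropping them, and records
enough provenance to re-run the computation later.

Averaging convention for "mean scalar along a bundle": the per-streamline
mean is computed first and streamline means are then averaged unweighted, so
a long fiber with many points does not dominate the bundle summary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bundles import EvalContext, eval_bundle
from .errors import MissingDataError, ValidationError
from .imaging import LabelMap, ProjectLayout, StreamlineSet, Volume, project_get
from .roi import SphereROI
from .spaces import _trilinear, world_to_voxel


class AbsentStructureWarning(UserWarning):
    """No voxel carries any of the requested labels; volume reported as 0."""


def structure_volume(lm: LabelMap, labels) -> float:
    """Combined volume (mm^3) of the voxels carrying any of the given labels.

    Volume = matching-voxel count x |det| of the voxel-to-world linear block.
    An absent structure is a warning and volume 0.0, not an error: in real
    cohorts a structure may be genuinely unsegmentable in some subjects.
    """
    labels = set(int(v) for v in labels)
    if not labels:
        raise ValidationError("label set must be non-empty")
    count = int(np.isin(lm.data, list(labels)).sum())
    if count == 0:
        warnings.warn(
            f"no voxels carry labels {sorted(labels)}; structure volume is 0",
            AbsentStructureWarning, stacklevel=2)
    voxel_volume = abs(float(np.linalg.det(lm.voxel_to_world.linear)))
    return count * voxel_volume


def streamline_length(line) -> float:
    """Arc length of a polyline: sum of Euclidean segment lengths (mm)."""
    arr = np.asarray(line, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2:
        raise ValidationError("streamline needs at least 2 points")
    return float(np.sum(np.linalg.norm(np.diff(arr, axis=0), axis=1)))


def linear_distance(p1, p2) -> float:
    """Euclidean distance in mm between two world points."""
    a = np.asarray(p1, dtype=float).reshape(3)
    b = np.asarray(p2, dtype=float).reshape(3)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValidationError("points must be finite")
    return float(np.linalg.norm(a - b))


@dataclass
class BundleStats:
    count: int
    mean_length: float | None  # mm; None for an empty bundle
    mean_scalar: float | None  # None if no scalar given or nothing sampled
    n_points_outside: int = 0  # streamline points outside the scalar grid
    n_streamlines_unsampled: int = 0  # streamlines entirely outside
    missing: bool = False  # empty-bundle signal


def _sample_scalar_along(line: np.ndarray, scalar: Volume) -> tuple[float | None, int]:
    """Per-streamline mean of the trilinearly sampled scalar.

    Points outside the scalar grid are skipped; returns (mean or None,
    number of skipped points).
    """
    vox = world_to_voxel(scalar.voxel_to_world, line)
    shape = np.array(scalar.data.shape)
    inside = np.all((vox >= 0) & (vox <= shape - 1), axis=1)
    n_out = int((~inside).sum())
    if not np.any(inside):
        return None, n_out
    vals = _trilinear(scalar.data[..., None], vox[inside])[:, 0]
    return float(np.mean(vals)), n_out


def bundle_stats(s: StreamlineSet, scalar: Volume | None = None) -> BundleStats:
    """Count, mean length and (optionally) mean scalar of a bundle.

    mean_scalar averages the per-streamline sampled means (two-level
    averaging).  An empty bundle yields count 0 with undefined means, flagged
    missing so cohort aggregation can skip the subject.
    """
    if len(s) == 0:
        return BundleStats(0, None, None, missing=True)
    if scalar is not None and scalar.space != s.space:
        raise ValidationError(
            f"scalar volume in {scalar.space.name!r} but bundle in {s.space.name!r}")
    lengths = [streamline_length(line) for line in s.streamlines]
    mean_scalar = None
    n_out = n_unsampled = 0
    if scalar is not None:
        per_line = []
        for line in s.streamlines:
            m, skipped = _sample_scalar_along(line, scalar)
            n_out += skipped
            if m is None:
                n_unsampled += 1
            else:
                per_line.append(m)
        mean_scalar = float(np.mean(per_line)) if per_line else None
    return BundleStats(len(s), float(np.mean(lengths)), mean_scalar,
                       n_out, n_unsampled)


# ---------------------------------------------------------------------------
# Cohort-level descriptor capture
# ---------------------------------------------------------------------------

_KINDS = {"structure-volume", "bundle-count", "bundle-mean-length",
          "bundle-mean-scalar", "linear-distance"}


@dataclass
class DescriptorSpec:
    """A named recipe for one per-subject scalar.

    parameters by kind:
      structure-volume: ``labelmap`` (project data type), ``labels`` (ids)
      bundle-*: ``streamlines`` (data type), optional ``expression`` with
        ``structures`` ({leaf: {labelmap, labels}}) and ``rois``
        ({leaf: SphereROI}); bundle-mean-scalar adds ``scalar`` (data type)
      linear-distance: ``point1``, ``point2`` (world mm)
    ``space`` selects the coordinate space everything is loaded into.
    """

    name: str
    kind: str
    parameters: dict = field(default_factory=dict)
    space: str | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValidationError(f"unknown descriptor kind {self.kind!r}")

    def provenance(self) -> str:
        params = {k: v for k, v in self.parameters.items()
                  if not isinstance(v, SphereROI)}
        rois = self.parameters.get("rois") or {}
        if rois:
            params["rois"] = {
                k: {"center": list(map(float, r.center)), "radius": r.radius,
                    "space": r.space.name}
                for k, r in rois.items()}
        return json.dumps({"module": "descriptors", "kind": self.kind,
                           "space": self.space, "parameters": params},
                          sort_keys=True, default=str)


def _bundle_for_subject(spec: DescriptorSpec, layout: ProjectLayout,
                        subject_id: str) -> StreamlineSet:
    p = spec.parameters
    lines = project_get(layout, p["streamlines"], subject_id, spec.space)
    expression = p.get("expression")
    if expression is None:
        return lines
    structures = {}
    for leaf, ref in (p.get("structures") or {}).items():
        lm = project_get(layout, ref["labelmap"], subject_id, spec.space)
        structures[leaf] = (lm, set(int(v) for v in ref["labels"]))
    ctx = EvalContext(universe=lines, structures=structures,
                      rois=dict(p.get("rois") or {}))
    return eval_bundle(expression, ctx)


def _value_for_subject(spec: DescriptorSpec, layout: ProjectLayout,
                       subject_id: str) -> float:
    p = spec.parameters
    if spec.kind == "structure-volume":
        lm = project_get(layout, p["labelmap"], subject_id, spec.space)
        return structure_volume(lm, p["labels"])
    if spec.kind == "linear-distance":
        return linear_distance(p["point1"], p["point2"])
    bundle = _bundle_for_subject(spec, layout, subject_id)
    if spec.kind == "bundle-count":
        return float(len(bundle))
    scalar = None
    if spec.kind == "bundle-mean-scalar":
        scalar = project_get(layout, p["scalar"], subject_id, spec.space)
    stats = bundle_stats(bundle, scalar)
    if stats.missing:
        raise MissingDataError(f"subject {subject_id}: empty bundle",
                               subject_id, spec.name)
    if spec.kind == "bundle-mean-length":
        return stats.mean_length
    if stats.mean_scalar is None:
        raise MissingDataError(
            f"subject {subject_id}: bundle entirely outside the scalar grid",
            subject_id, spec.name)
    return stats.mean_scalar


def capture_descriptor(spec: DescriptorSpec, layout: ProjectLayout,
                       sample, db=None) -> pd.Series:
    """Run a descriptor over a sample; one value per subject.

    Subjects whose inputs are missing get NaN (and are counted in
    ``result.attrs['n_missing']``), never silently dropped.  When a cohort
    database is given, the values are stored as a new numeric variable whose
    provenance records the full descriptor configuration.
    """
    subjects = list(sample.subjects) if hasattr(sample, "subjects") else list(sample)
    if not subjects:
        raise ValidationError("sample is empty")
    values, n_missing = {}, 0
    for sid in subjects:
        try:
            values[sid] = _value_for_subject(spec, layout, sid)
        except MissingDataError:
            values[sid] = np.nan
            n_missing += 1
    if n_missing == len(subjects):
        raise MissingDataError(f"descriptor {spec.name!r}: every subject missing")
    result = pd.Series(values, name=spec.name, dtype=float)
    result.attrs["n_missing"] = n_missing
    result.attrs["provenance"] = spec.provenance()
    if db is not None:
        db.add_variable(spec.name, var_type="numeric",
                        description=f"captured descriptor ({spec.kind})",
                        provenance=spec.provenance())
        db.set_values(spec.name, values)
    return result
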