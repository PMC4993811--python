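"""On-disk formats and the per-subject project reader.

Spatial data lives on disk in standard neuroimaging formats (NIfTI-1 volumes
and label maps, TRK/TCK streamlines, legacy ASCII VTK polydata read-only,
plain-text 4x4 affine matrices, 4D NIfTI warp fields).  A
:class:`ProjectLayout` declares, in a YAML file, where each data type lives as
a path template over the subject id, plus the registered transforms between
coordinate spaces; :func:`project_get` is the single entry point that resolves
a (data type, subject, target space) request to a loaded, transformed object.

Everything returned is in world RAS+ millimetres.  TRK files, which store
their own voxel-order convention, are converted to world mm on load via the
header transform (nibabel does this for us).  Volumes are never resampled:
changing space only composes their voxel-to-world affine.
"""

from __future__ import annotations

import glob
import os
import re
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import yaml

from .errors import (
    ConfigurationError,
    FormatError,
    MissingDataError,
    SpaceMismatchError,
    UnsupportedFormatError,
    ValidationError,
)
from .spaces import (
    AffineTransform,
    CoordinateSpace,
    WarpField,
    apply_affine_points,
    apply_warp_points,
    invert_affine,
)

# ---------------------------------------------------------------------------
# In-memory containers
# ---------------------------------------------------------------------------


@dataclass
class Volume:
    """A 3D scalar grid (FA map, t-map...) with a voxel-to-world affine."""

    data: np.ndarray
    voxel_to_world: AffineTransform
    space: CoordinateSpace = field(default=CoordinateSpace("native"))

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValidationError(f"volume must be 3D, got shape {self.data.shape}")
        if isinstance(self.space, str):
            self.space = CoordinateSpace(self.space)


@dataclass
class LabelMap:
    """A 3D integer grid assigning each voxel an anatomical structure id."""

    data: np.ndarray
    voxel_to_world: AffineTransform
    label_table: dict[int, str] = field(default_factory=dict)
    space: CoordinateSpace = field(default=CoordinateSpace("native"))

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            as_int = np.rint(self.data).astype(np.int32)
            if not np.allclose(self.data, as_int):
                raise ValidationError("label map data must be integer")
            self.data = as_int
        if self.data.ndim != 3:
            raise ValidationError(f"label map must be 3D, got {self.data.shape}")
        if self.data.min() < 0:
            raise ValidationError("label values must be non-negative")
        if isinstance(self.space, str):
            self.space = CoordinateSpace(self.space)

    def labels_present(self) -> list[int]:
        vals = np.unique(self.data)
        return [int(v) for v in vals if v != 0]


@dataclass
class StreamlineSet:
    """Ordered tractography polylines in world mm with stable integer ids."""

    streamlines: list[np.ndarray]
    space: CoordinateSpace = field(default=CoordinateSpace("native"))
    ids: np.ndarray | None = None

    def __post_init__(self):
        clean = []
        for i, line in enumerate(self.streamlines):
            arr = np.asarray(line, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValidationError(
                    f"streamline {i} must be an (n>=2, 3) array, got {arr.shape}")
            if not np.all(np.isfinite(arr)):
                raise ValidationError(f"streamline {i} contains non-finite points")
            clean.append(arr)
        self.streamlines = clean
        if self.ids is None:
            self.ids = np.arange(len(clean))
        else:
            self.ids = np.asarray(self.ids, dtype=int)
            if len(self.ids) != len(clean) or len(np.unique(self.ids)) != len(clean):
                raise ValidationError("ids must be unique, one per streamline")
        if isinstance(self.space, str):
            self.space = CoordinateSpace(self.space)

    def __len__(self) -> int:
        return len(self.streamlines)

    def subset(self, keep_ids) -> "StreamlineSet":
        keep = set(int(i) for i in keep_ids)
        lines, ids = [], []
        for line, i in zip(self.streamlines, self.ids):
            if int(i) in keep:
                lines.append(line)
                ids.append(int(i))
        return StreamlineSet(lines, self.space, np.asarray(ids, dtype=int))


# ---------------------------------------------------------------------------
# Volumes / label maps (NIfTI-1)
# ---------------------------------------------------------------------------


def _require_file(path: str):
    if not os.path.exists(path):
        raise FileNotFoundError(f"no such file: {path}")


def read_volume(path: str, space: str | CoordinateSpace = "native") -> Volume:
    _require_file(path)
    try:
        img = nib.load(path)
    except Exception as e:
        raise FormatError(f"cannot parse {path} as NIfTI: {e}") from e
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D volume, got {data.shape}")
    return Volume(data.astype(float), AffineTransform(img.affine), space)


def write_volume(v: Volume, path: str):
    nib.save(nib.Nifti1Image(v.data.astype(np.float64), v.voxel_to_world.matrix), path)


def read_labelmap(path: str, label_table: dict[int, str] | None = None,
                  space: str | CoordinateSpace = "native") -> LabelMap:
    _require_file(path)
    try:
        img = nib.load(path)
    except Exception as e:
        raise FormatError(f"cannot parse {path} as NIfTI: {e}") from e
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected a 3D label map, got {data.shape}")
    return LabelMap(np.rint(data).astype(np.int32), AffineTransform(img.affine),
                    label_table or {}, space)


def write_labelmap(lm: LabelMap, path: str):
    nib.save(nib.Nifti1Image(lm.data.astype(np.int16), lm.voxel_to_world.matrix), path)


# ---------------------------------------------------------------------------
# Affines / warp fields
# ---------------------------------------------------------------------------


def read_affine(path: str, source_space="unspecified",
                target_space="unspecified") -> AffineTransform:
    """Whitespace-delimited 4x4 plain-text matrix (FSL/.mat style)."""
    _require_file(path)
    try:
        m = np.loadtxt(path)
    except Exception as e:
        raise FormatError(f"cannot parse {path} as a 4x4 matrix: {e}") from e
    if m.shape != (4, 4):
        raise FormatError(f"{path}: expected 4x4 matrix, got {m.shape}")
    return AffineTransform(m, source_space, target_space)


def write_affine(a: AffineTransform, path: str):
    np.savetxt(path, a.matrix, fmt="%.10g")


def read_warp(path: str, source_space="unspecified",
              target_space="unspecified") -> WarpField:
    """4D NIfTI with the 4th dimension of size 3 (x, y, z displacement, mm)."""
    _require_file(path)
    img = nib.load(path)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 5 and data.shape[3] == 1:  # ANTs-style (x,y,z,1,3)
        data = data[:, :, :, 0, :]
    if data.ndim != 4 or data.shape[3] != 3:
        raise FormatError(f"{path}: expected (nx,ny,nz,3) warp, got {data.shape}")
    return WarpField(data.astype(float), AffineTransform(img.affine),
                     source_space, target_space)


def write_warp(w: WarpField, path: str):
    nib.save(nib.Nifti1Image(w.displacement.astype(np.float64),
                             w.grid_affine.matrix), path)


# ---------------------------------------------------------------------------
# Streamlines (TRK / TCK / legacy ASCII VTK polydata)
# ---------------------------------------------------------------------------

_STREAMLINE_WRITERS = {".trk", ".tck"}


def read_streamlines(path: str, space: str | CoordinateSpace = "native") -> StreamlineSet:
    """Load a streamline file; dialect chosen by extension.

    TRK and TCK are read with nibabel, which returns points in world RAS mm
    (TRK's voxel-order coordinates are converted via its header transform).
    ``.vtk`` files are parsed as legacy ASCII polydata (POINTS/LINES sections).
    """
    _require_file(path)
    ext = os.path.splitext(path)[1].lower()
    if ext in _STREAMLINE_WRITERS:
        try:
            tractogram = nib.streamlines.load(path)
        except Exception as e:
            raise FormatError(f"cannot parse {path}: {e}") from e
        lines = [np.asarray(s, dtype=float) for s in tractogram.streamlines]
        return StreamlineSet(lines, space)
    if ext == ".vtk":
        return _read_vtk_ascii_polydata(path, space)
    raise UnsupportedFormatError(f"unknown streamline format {ext!r} ({path})")


def write_streamlines(s: StreamlineSet, path: str):
    ext = os.path.splitext(path)[1].lower()
    if ext not in _STREAMLINE_WRITERS:
        raise UnsupportedFormatError(
            f"streamlines can be written as .trk or .tck, not {ext!r}")
    tractogram = nib.streamlines.Tractogram(
        [line.astype(np.float32) for line in s.streamlines],
        affine_to_rasmm=np.eye(4))
    if ext == ".trk":
        header = nib.streamlines.trk.TrkFile.create_empty_header()
        nib.streamlines.save(tractogram, path, header=header)
    else:
        nib.streamlines.save(tractogram, path)


def _read_vtk_ascii_polydata(path: str, space) -> StreamlineSet:
    """Minimal reader for legacy ASCII VTK polydata with POINTS and LINES."""
    with open(path) as fh:
        text = fh.read()
    if "ASCII" not in text.split("\n", 4)[2]:
        raise FormatError(f"{path}: only ASCII legacy VTK polydata is supported")
    tokens = text.split()
    try:
        pi = tokens.index("POINTS")
        n_points = int(tokens[pi + 1])
        coords = np.array(tokens[pi + 3: pi + 3 + 3 * n_points], dtype=float)
        points = coords.reshape(n_points, 3)
        li = tokens.index("LINES")
        n_lines = int(tokens[li + 1])
        cursor = li + 3
        lines = []
        for _ in range(n_lines):
            npts = int(tokens[cursor])
            idx = np.array(tokens[cursor + 1: cursor + 1 + npts], dtype=int)
            lines.append(points[idx])
            cursor += 1 + npts
    except (ValueError, IndexError) as e:
        raise FormatError(f"{path}: truncated or malformed VTK polydata: {e}") from e
    return StreamlineSet(lines, space)


# ---------------------------------------------------------------------------
# Project layout / reader
# ---------------------------------------------------------------------------

_KINDS = {"volume", "labelmap", "streamlines", "affine", "warp"}


@dataclass
class ProjectLayout:
    """Declarative file layout of a cohort project.

    ``data_types`` maps a type name to a dict with keys ``path`` (template
    containing ``{subject}``), ``kind`` (volume | labelmap | streamlines |
    affine | warp) and optionally ``labels`` (label table for label maps).
    ``transforms`` is a list of dicts with ``source``, ``target``, ``kind``
    (affine | warp) and ``path`` template.  ``clinical`` optionally names the
    clinical CSV whose first column lists subject ids.
    """

    root: str
    data_types: dict[str, dict]
    transforms: list[dict] = field(default_factory=list)
    clinical: str | None = None
    native_space: str = "native"

    def __post_init__(self):
        if not os.path.isdir(self.root):
            raise ConfigurationError(f"project root does not exist: {self.root}")
        for name, entry in self.data_types.items():
            if "path" not in entry:
                raise ConfigurationError(f"data type {name!r} lacks a path template")
            if entry.get("kind", "volume") not in _KINDS:
                raise ConfigurationError(
                    f"data type {name!r}: unknown kind {entry.get('kind')!r}")

    @classmethod
    def from_yaml(cls, config_path: str) -> "ProjectLayout":
        _require_file(config_path)
        with open(config_path) as fh:
            cfg = yaml.safe_load(fh)
        root = cfg.get("root", ".")
        if not os.path.isabs(root):
            root = os.path.normpath(os.path.join(os.path.dirname(config_path), root))
        return cls(
            root=root,
            data_types={k: dict(v) for k, v in (cfg.get("data") or {}).items()},
            transforms=list(cfg.get("transforms") or []),
            clinical=cfg.get("clinical"),
            native_space=cfg.get("native_space", "native"),
        )

    def resolve(self, data_type: str, subject_id: str) -> str:
        if data_type not in self.data_types:
            raise ConfigurationError(f"unknown data type {data_type!r}")
        template = self.data_types[data_type]["path"]
        return os.path.join(self.root, template.format(subject=subject_id))

    def clinical_path(self) -> str | None:
        if self.clinical is None:
            return None
        return os.path.join(self.root, self.clinical)


def list_subjects(layout: ProjectLayout) -> list[str]:
    """Sorted, deduplicated subject ids, unioned across every data source.

    A subject with only clinical data (no images) is still listed.
    """
    found: set[str] = set()
    for entry in layout.data_types.values():
        template = entry["path"]
        if "{subject}" not in template:
            continue
        pattern = os.path.join(layout.root, template.format(subject="*"))
        regex = re.escape(os.path.join(layout.root, template)).replace(
            re.escape("{subject}"), "([^/\\\\]+)")
        for hit in glob.glob(pattern):
            m = re.fullmatch(regex, hit)
            if m:
                found.add(m.group(1))
    csv_path = layout.clinical_path()
    if csv_path and os.path.exists(csv_path):
        import pandas as pd

        table = pd.read_csv(csv_path)
        if table.shape[1] >= 1:
            found.update(str(v) for v in table.iloc[:, 0])
    return sorted(found)


def get_transform(layout: ProjectLayout, subject_id: str, source: str,
                  target: str) -> AffineTransform | WarpField | None:
    """Registered transform between two spaces for one subject.

    Returns None for the identity request (source == target).  Declared
    affines are used directly or inverted; warps only directly.
    """
    if source == target:
        return None
    for t in layout.transforms:
        kind = t.get("kind", "affine")
        path_t = t["path"]
        if t["source"] == source and t["target"] == target:
            path = os.path.join(layout.root, path_t.format(subject=subject_id))
            if not os.path.exists(path):
                raise MissingDataError(
                    f"transform file missing for subject {subject_id}: {path}",
                    subject_id, "transform")
            if kind == "affine":
                return read_affine(path, source, target)
            return read_warp(path, source, target)
        if kind == "affine" and t["source"] == target and t["target"] == source:
            path = os.path.join(layout.root, path_t.format(subject=subject_id))
            if not os.path.exists(path):
                raise MissingDataError(
                    f"transform file missing for subject {subject_id}: {path}",
                    subject_id, "transform")
            return invert_affine(read_affine(path, source, target))
    raise SpaceMismatchError(
        f"no registered transform from {source!r} to {target!r}")


def project_get(layout: ProjectLayout, data_type: str, subject_id: str,
                target_space: str | None = None, params: dict | None = None):
    """Load one subject's data, already expressed in ``target_space``.

    Volumes and label maps keep their raw grid; only the voxel-to-world
    affine is composed with the registration (no resampling).  Streamline
    points are mapped explicitly.  A missing file raises
    :class:`MissingDataError` so cohort loops can flag-and-continue.
    """
    params = params or {}
    entry = layout.data_types.get(data_type)
    if entry is None:
        raise ConfigurationError(f"unknown data type {data_type!r}")
    kind = entry.get("kind", "volume")
    path = layout.resolve(data_type, subject_id)
    if not os.path.exists(path):
        raise MissingDataError(
            f"subject {subject_id!r} has no {data_type!r} file ({path})",
            subject_id, data_type)

    native = layout.native_space
    target = target_space or native

    if kind == "affine":
        return read_affine(path, native, target)
    if kind == "warp":
        return read_warp(path, native, target)

    transform = get_transform(layout, subject_id, native, target)

    if kind == "streamlines":
        s = read_streamlines(path, native)
        if transform is None:
            return s
        if isinstance(transform, AffineTransform):
            lines = [apply_affine_points(transform, line) for line in s.streamlines]
        else:
            lines = [apply_warp_points(transform, line) for line in s.streamlines]
        return StreamlineSet(lines, target, s.ids)

    if kind == "labelmap":
        labels = {int(k): str(v) for k, v in (entry.get("labels") or {}).items()}
        lm = read_labelmap(path, labels, native)
        if transform is None:
            return lm
        if not isinstance(transform, AffineTransform):
            raise SpaceMismatchError(
                "label maps can only change space through affine transforms "
                "(no resampling is performed)")
        return LabelMap(lm.data, _compose_voxel_to_world(lm, transform),
                        lm.label_table, target)

    v = read_volume(path, native)
    if transform is None:
        return v
    if not isinstance(transform, AffineTransform):
        raise SpaceMismatchError(
            "volumes can only change space through affine transforms "
            "(no resampling is performed)")
    return Volume(v.data, _compose_voxel_to_world(v, transform), target)


def _compose_voxel_to_world(img, transform: AffineTransform) -> AffineTransform:
    """Voxel-to-target-space affine of an unresampled image (on-disk affines
    carry no space annotation, so compose on the raw matrices)."""
    return AffineTransform(transform.matrix @ img.voxel_to_world.matrix)
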