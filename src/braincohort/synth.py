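"""Fully synthetic multi-group cohort with known ground truth.

Every other stage of the package is testable offline against this generator:
it emulates a three-group developmental cohort (term-born controls, preterm
in incubators, preterm with an early-care intervention) with per-subject
label maps, FA-like scalar maps, tractography bundles, affine registrations
to a common reference, and a clinical table — all with configurable injected
effects recorded in a manifest.

Anatomical realism is deliberately traded for exactness: structures are
ellipsoids and bundles are quadratic Bezier arcs, so containment and
crossing have closed forms and the generator can label every streamline's
ground-truth membership analytically.

Injected effects (the defaults):
  * the mid-callosal structure's volume is scaled per group by
    (1.0, 0.8, 0.9) — the smaller callosum of the preterm groups;
  * ventricles are enlarged in the untreated preterm group (x1.3);
  * an FA-like scalar is shifted down per group (0, -0.05, -0.02);
  * streamline counts per group differ (60, 42, 50);
  * a visuomotor score is shifted by 1.0 within-group SD between the term
    and untreated-preterm groups;
  * interhemispheric transfer time is linearly coupled to the subject's arc
    length (latent r ~ 0.95) within each group, except in a configurable
    number of planted outlier subjects of the untreated preterm group whose
    transfer time is pathologically long regardless of anatomy — these
    exercise the outlier-exclusion refit workflow.

Everything is reproducible from (config, seed); per-subject randomness uses
independent child seeds so changing one subject's draw never shifts another.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError
from .imaging import (
    LabelMap,
    ProjectLayout,
    StreamlineSet,
    Volume,
    write_affine,
    write_labelmap,
    write_streamlines,
    write_volume,
)
from .spaces import AffineTransform

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StructureSpec:
    label: int
    name: str
    center: tuple[float, float, float]  # mm, native base position
    semi_axes: tuple[float, float, float]  # mm
    group_multipliers: dict[str, float] = field(default_factory=dict)  # volume


@dataclass(frozen=True)
class ClinicalVarSpec:
    name: str
    group_means: dict[str, float]
    sd: float


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions of the synthetic cohort. Seed is mandatory."""

    seed: int
    groups: tuple[tuple[str, int], ...] = (
        ("term", 20), ("preterm_control", 20), ("preterm_kmc", 20))
    grid_shape: tuple[int, int, int] = (36, 36, 36)
    voxel_size: float = 2.0  # mm, isotropic
    structures: tuple[StructureSpec, ...] = (
        StructureSpec(1, "nucleus_left", (-14.0, 0.0, -2.0), (7.0, 9.0, 8.0)),
        StructureSpec(2, "nucleus_right", (14.0, 0.0, -2.0), (7.0, 9.0, 8.0)),
        StructureSpec(3, "callosum_mid", (0.0, 0.0, 7.0), (5.0, 12.0, 4.0),
                      {"term": 1.0, "preterm_control": 0.8,
                       "preterm_kmc": 0.9}),
        StructureSpec(4, "ventricles", (0.0, -14.0, 0.0), (6.0, 8.0, 6.0),
                      {"term": 1.0, "preterm_control": 1.3,
                       "preterm_kmc": 1.15}),
    )
    center_jitter_mm: float = 0.5
    shape_jitter: float = 0.03  # lognormal sigma on semi-axes
    # streamline bundle family (one interhemispheric arc family)
    bundle_counts: dict[str, int] = field(default_factory=lambda: {
        "term": 60, "preterm_control": 42, "preterm_kmc": 50})
    bundle_jitter_mm: float = 2.0  # per-streamline lateral offset SD
    bundle_point_noise_mm: float = 0.2  # per-point roughness
    bundle_points: int = 25
    arc_height_mm: float = 22.0  # control-point height of the Bezier arc
    arc_height_jitter: float = 0.3  # x (1 + jitter * latent factor)
    # FA-like scalar field
    fa_base: float = 0.45
    fa_group_shift: dict[str, float] = field(default_factory=lambda: {
        "term": 0.0, "preterm_control": -0.05, "preterm_kmc": -0.02})
    fa_noise_sd: float = 0.02
    # clinical variables
    clinical: tuple[ClinicalVarSpec, ...] = (
        ClinicalVarSpec("vmi", {"term": 110.0, "preterm_control": 100.0,
                                "preterm_kmc": 105.0}, 10.0),
        ClinicalVarSpec("motor_threshold", {"term": 40.0,
                                            "preterm_control": 48.0,
                                            "preterm_kmc": 44.0}, 6.0),
    )
    # transfer time ~ latent arc-length factor, within-group
    transfer_base_ms: float = 18.0
    transfer_slope: float = 2.0  # ms per latent SD of arc length
    transfer_noise_sd: float = 0.25  # -> latent correlation ~ 0.99
    n_outliers: int = 4  # planted in the untreated preterm group
    outlier_shift_sd: float = 20.0  # transfer-time shift in noiseless-slope SDs
    registration_rot_deg: float = 2.0
    registration_trans_mm: float = 2.0

    def __post_init__(self):
        if min(self.grid_shape) < 4 or self.voxel_size <= 0:
            raise ConfigurationError("degenerate grid configuration")
        for s in self.structures:
            for m in s.group_multipliers.values():
                if m <= 0:
                    raise ConfigurationError("volume multipliers must be > 0")

    @property
    def outlier_group(self) -> str:
        return self.groups[1][0] if len(self.groups) > 1 else self.groups[0][0]


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------


def grid_affine(cfg: CohortConfig) -> AffineTransform:
    """Voxel-to-world affine of the centered isotropic native grid."""
    m = np.eye(4)
    m[:3, :3] *= cfg.voxel_size
    m[:3, 3] = -(np.array(cfg.grid_shape) - 1) * cfg.voxel_size / 2.0
    return AffineTransform(m)


def _voxel_center_grid(cfg: CohortConfig) -> np.ndarray:
    aff = grid_affine(cfg)
    idx = np.indices(cfg.grid_shape).reshape(3, -1).T.astype(float)
    return idx @ aff.linear.T + aff.translation


def rasterize_structures(cfg: CohortConfig, structures) -> LabelMap:
    """Paint ellipsoids into an integer grid (later structures overwrite)."""
    centers = _voxel_center_grid(cfg)
    data = np.zeros(cfg.grid_shape, dtype=np.int32).ravel()
    table = {}
    for label, name, center, semi in structures:
        q = np.sum(((centers - np.asarray(center)) / np.asarray(semi)) ** 2, axis=1)
        data[q <= 1.0] = label
        table[label] = name
    return LabelMap(data.reshape(cfg.grid_shape), grid_affine(cfg), table)


def bezier_arc(a, b, c, n_points: int) -> np.ndarray:
    """Quadratic Bezier from a to b with control point c."""
    t = np.linspace(0.0, 1.0, n_points)[:, None]
    a, b, c = (np.asarray(v, dtype=float) for v in (a, b, c))
    return (1 - t) ** 2 * a + 2 * t * (1 - t) * c + t ** 2 * b


def point_in_ellipsoid(points, center, semi_axes) -> np.ndarray:
    pts = np.atleast_2d(points)
    q = np.sum(((pts - np.asarray(center)) / np.asarray(semi_axes)) ** 2, axis=1)
    return q <= 1.0


def ellipsoid_clearance(points, center, semi_axes) -> float:
    """Signed margin (mm, approximate) of a polyline to an ellipsoid surface.

    Positive = the polyline enters the ellipsoid by at least that much;
    negative = it stays at least that far outside.  Uses the normalized
    quadratic form scaled by the smallest semi-axis, exact for spheres and a
    conservative margin proxy for mild anisotropy.
    """
    pts = np.atleast_2d(points)
    q = np.sqrt(np.sum(
        ((pts - np.asarray(center)) / np.asarray(semi_axes)) ** 2, axis=1))
    return float((1.0 - q.min()) * min(semi_axes))


def generate_streamline_family(start, end, control, n: int, jitter: float,
                               seed, point_noise: float = 0.0,
                               n_points: int = 25):
    """Arcs through a corridor: base Bezier plus per-streamline offset.

    Each streamline is the base arc shifted rigidly by a Gaussian offset
    (SD ``jitter`` mm per axis) plus optional per-point roughness.  Returns
    (StreamlineSet, offsets) — membership of the *noiseless* offset curve in
    any ellipsoid is analytic, so crossing ground truth is known per
    streamline.
    """
    rng = np.random.default_rng(seed)
    base = bezier_arc(start, end, control, n_points)
    offsets = rng.normal(0.0, jitter, size=(n, 3)) if n else np.zeros((0, 3))
    lines = []
    for i in range(n):
        line = base + offsets[i]
        if point_noise > 0:
            line = line + rng.normal(0.0, point_noise, size=line.shape)
        lines.append(line)
    return StreamlineSet(lines, "native") if lines else \
        StreamlineSet([], "native"), offsets


def analytic_crossing(start, end, control, offsets, center, semi_axes,
                      n_points: int = 25) -> np.ndarray:
    """Ground-truth crossing flags of the noiseless offset arcs."""
    base = bezier_arc(start, end, control, n_points)
    return np.array([point_in_ellipsoid(base + o, center, semi_axes).any()
                     for o in offsets], dtype=bool)


# ---------------------------------------------------------------------------
# Per-subject simulation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticSubject:
    subject_id: str
    group: str
    labelmap: LabelMap | None
    fa: Volume | None
    streamlines: StreamlineSet
    to_reference: AffineTransform
    structures: list[tuple[int, str, np.ndarray, np.ndarray]]  # realized geometry
    arc: tuple[np.ndarray, np.ndarray, np.ndarray]  # start, end, control
    offsets: np.ndarray
    length_factor: float  # latent arc-length factor (standard normal)
    clinical: dict[str, float]
    is_outlier: bool


def _subject_rng(seed: int, index: int, stream: int) -> np.random.Generator:
    """Independent generator per (subject, modality stream).

    Separate streams mean that skipping a heavy modality (e.g. not
    rasterizing FA in a Monte-Carlo loop) never shifts the draws of the
    others.
    """
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), int(index), int(stream)]))


def _small_rigid(rng, rot_deg: float, trans_mm: float,
                 source: str, target: str) -> AffineTransform:
    angles = np.deg2rad(rng.normal(0.0, rot_deg, size=3))
    cx, cy, cz = np.cos(angles)
    sx, sy, sz = np.sin(angles)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    m = np.eye(4)
    m[:3, :3] = Rz @ Ry @ Rx
    m[:3, 3] = rng.normal(0.0, trans_mm, size=3)
    return AffineTransform(m, source, target)


_ALL_MODALITIES = ("labels", "fa", "arcs")


def simulate_subject(cfg: CohortConfig, subject_id: str, group: str,
                     index: int, is_outlier: bool,
                     modalities=_ALL_MODALITIES) -> SyntheticSubject:
    rng_geom = _subject_rng(cfg.seed, index, 0)
    rng_fa = _subject_rng(cfg.seed, index, 1)
    rng_arc = _subject_rng(cfg.seed, index, 2)
    rng_clin = _subject_rng(cfg.seed, index, 3)

    structures = []
    by_name = {}
    for s in cfg.structures:
        mult = s.group_multipliers.get(group, 1.0)
        semi = (np.asarray(s.semi_axes)
                * mult ** (1.0 / 3.0)
                * np.exp(rng_geom.normal(0.0, cfg.shape_jitter, size=3)))
        center = np.asarray(s.center) + rng_geom.normal(
            0.0, cfg.center_jitter_mm, 3)
        structures.append((s.label, s.name, center, semi))
        by_name[s.name] = (center, semi)
    to_reference = _small_rigid(rng_geom, cfg.registration_rot_deg,
                                cfg.registration_trans_mm, "native", "reference")
    labelmap = None
    if "labels" in modalities:
        labelmap = rasterize_structures(cfg, structures)

    fa = None
    if "fa" in modalities:
        shift = cfg.fa_group_shift.get(group, 0.0)
        fa_data = np.clip(
            cfg.fa_base + shift
            + rng_fa.normal(0.0, cfg.fa_noise_sd, cfg.grid_shape),
            0.0, 1.0)
        fa = Volume(fa_data, grid_affine(cfg))

    length_factor = float(rng_arc.normal())
    if is_outlier:
        # planted outliers have canonical anatomy (latent factor 0, i.e.
        # average-height arcs); what is pathological is their transfer
        # time, set below
        length_factor = 0.0
    start, _ = by_name["nucleus_left"]
    end, _ = by_name["nucleus_right"]
    mid = (start + end) / 2.0
    control = mid + np.array(
        [0.0, 0.0,
         cfg.arc_height_mm * (1.0 + cfg.arc_height_jitter * length_factor)])
    streamlines, offsets = StreamlineSet([], "native"), np.zeros((0, 3))
    if "arcs" in modalities:
        n_lines = cfg.bundle_counts.get(group, 0)
        streamlines, offsets = generate_streamline_family(
            start, end, control, n_lines, cfg.bundle_jitter_mm,
            rng_arc.integers(1 << 31), cfg.bundle_point_noise_mm,
            cfg.bundle_points)

    clinical = {}
    for var in cfg.clinical:
        clinical[var.name] = float(
            rng_clin.normal(var.group_means.get(group, 0.0), var.sd))
    noise = float(rng_clin.normal(0.0, cfg.transfer_noise_sd))
    transfer = cfg.transfer_base_ms + cfg.transfer_slope * length_factor + noise
    if is_outlier:
        transfer = (cfg.transfer_base_ms
                    + cfg.outlier_shift_sd * cfg.transfer_slope + noise)
    clinical["transfer_time"] = transfer

    return SyntheticSubject(
        subject_id, group, labelmap, fa, streamlines, to_reference,
        structures, (start, end, control), offsets, length_factor,
        clinical, is_outlier)


def simulate_cohort(cfg: CohortConfig,
                    modalities=_ALL_MODALITIES) -> list[SyntheticSubject]:
    """All subjects, in-memory.  Outliers are the last ``n_outliers``
    subjects of the outlier group.  ``modalities`` restricts which heavy
    per-subject objects are realised; the draws of every modality are
    independent streams, so a restricted simulation agrees exactly with the
    full one on what it does produce."""
    subjects = []
    index = 0
    for group, n in cfg.groups:
        for k in range(n):
            sid = f"S{index + 1:03d}"
            is_outlier = (group == cfg.outlier_group
                          and k >= n - cfg.n_outliers)
            subjects.append(simulate_subject(cfg, sid, group, index,
                                             is_outlier, modalities))
            index += 1
    return subjects


def clinical_frame(subjects: list[SyntheticSubject]) -> pd.DataFrame:
    rows = []
    for s in subjects:
        row = {"subject": s.subject_id, "group": s.group, **s.clinical}
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# On-disk project generation
# ---------------------------------------------------------------------------

_PROJECT_YAML = "project.yaml"


def generate_cohort(cfg: CohortConfig, out_dir: str
                    ) -> tuple[ProjectLayout, dict]:
    """Write a complete synthetic project and its ground-truth manifest.

    Produces per-subject label maps, FA volumes, TRK bundles and native->
    reference affine files, a clinical CSV, a project YAML consumable by
    :class:`~braincohort.imaging.ProjectLayout`, and ``manifest.json``
    recording every true parameter per subject.
    """
    os.makedirs(out_dir, exist_ok=True)
    subjects = simulate_cohort(cfg)

    manifest = {"seed": cfg.seed,
                "groups": {g: n for g, n in cfg.groups},
                "structures": {
                    s.name: {"label": s.label,
                             "base_center": list(s.center),
                             "base_semi_axes": list(s.semi_axes),
                             "group_multipliers": dict(s.group_multipliers)}
                    for s in cfg.structures},
                "subjects": {}}
    for s in subjects:
        sdir = os.path.join(out_dir, "subjects", s.subject_id)
        os.makedirs(sdir, exist_ok=True)
        write_labelmap(s.labelmap, os.path.join(sdir, "labels.nii"))
        write_volume(s.fa, os.path.join(sdir, "fa.nii"))
        write_streamlines(s.streamlines, os.path.join(sdir, "arcs.trk"))
        write_affine(s.to_reference, os.path.join(sdir, "to_reference.mat"))
        callosum = next(x for x in s.structures if x[1] == "callosum_mid")
        crossing = analytic_crossing(*s.arc, s.offsets, callosum[2], callosum[3],
                                     cfg.bundle_points)
        manifest["subjects"][s.subject_id] = {
            "group": s.group,
            "is_outlier": s.is_outlier,
            "length_factor": s.length_factor,
            "n_streamlines": len(s.streamlines),
            "n_crossing_callosum_true": int(crossing.sum()),
            "structures": {
                name: {"label": label, "center": c.tolist(),
                       "semi_axes": ax.tolist()}
                for label, name, c, ax in s.structures},
            "clinical": s.clinical,
        }

    frame = clinical_frame(subjects)
    frame.to_csv(os.path.join(out_dir, "clinical.csv"), index=False,
                 float_format="%.10g")

    label_table = {s.label: s.name for s in cfg.structures}
    config = {
        "root": ".",
        "native_space": "native",
        "data": {
            "labels": {"path": "subjects/{subject}/labels.nii",
                       "kind": "labelmap", "labels": label_table},
            "fa": {"path": "subjects/{subject}/fa.nii", "kind": "volume"},
            "arcs": {"path": "subjects/{subject}/arcs.trk",
                     "kind": "streamlines"},
        },
        "transforms": [{"source": "native", "target": "reference",
                        "kind": "affine",
                        "path": "subjects/{subject}/to_reference.mat"}],
        "clinical": "clinical.csv",
    }
    with open(os.path.join(out_dir, _PROJECT_YAML), "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)

    return ProjectLayout.from_yaml(os.path.join(out_dir, _PROJECT_YAML)), manifest
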