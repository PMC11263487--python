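"""Parametric cone-tooth jaws with full analytic ground truth.

The generator stands in for a segmented CT scan: a straight jaw line from
joint to tip, conical teeth planted along it, and a single closing-muscle
insertion near the joint (the usual simple-lever setup for a lower jaw).
Every quantity the pipeline later measures — tip/base, height, basal
width, surface area, levers, mechanical advantage, force, stress — is
also computed here from plain closed forms, deliberately *not* through
the geometry/biomechanics modules, so the ground truth is an independent
oracle for the test suite.

Defaults describe a small vertebrate lower jaw: 20 mm jaw, ten 2 mm
conical teeth of 0.5 mm basal radius, muscle inserting 3 mm from the
joint. Under the standard modeling defaults (1 N input force, 90°
insertion) tooth force equals mechanical advantage.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from .errors import ValidationError
from .types import LandmarkSet, ToothMesh

DEFAULT_JAW_LENGTH = 20.0  # mm
DEFAULT_N_TEETH = 10
DEFAULT_TOOTH_HEIGHT = 2.0  # mm
DEFAULT_TOOTH_RADIUS = 0.5  # mm
DEFAULT_SEGMENTS = 128
DEFAULT_INSERTION = (3.0, 0.0, 1.5)  # mm, near-joint coronoid-like point


def cone_surface_area(height: float, radius: float) -> float:
    """Closed-form area of a capped cone: π·r·√(r²+h²) + π·r²."""
    return np.pi * radius * np.hypot(radius, height) + np.pi * radius ** 2


def make_cone(height: float, radius: float, segments: int = DEFAULT_SEGMENTS,
              base_center=(0.0, 0.0, 0.0), axis=(0.0, 0.0, 1.0),
              name: str = "cone", label: int = 1) -> ToothMesh:
    """Closed cone mesh: lateral triangle fan plus base disk.

    The apex sits at ``base_center + height·axis``. The base ring is
    duplicated (sharp edge), so the vertex count is 2·segments + 2 and
    the face count 2·segments.
    """
    if height <= 0 or radius <= 0:
        raise ValidationError("cone height and radius must be positive")
    if segments < 3:
        raise ValidationError("cone needs >= 3 segments")
    base_center = np.asarray(base_center, dtype=float)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(axis, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)

    theta = 2.0 * np.pi * np.arange(segments) / segments
    ring = base_center + radius * (np.outer(np.cos(theta), e1)
                                   + np.outer(np.sin(theta), e2))
    apex = base_center + height * axis
    vertices = np.vstack([ring, ring, apex[None, :], base_center[None, :]])
    i = np.arange(segments)
    j = (i + 1) % segments
    apex_i, center_i = 2 * segments, 2 * segments + 1
    lateral = np.stack([i, j, np.full(segments, apex_i)], axis=1)
    base = np.stack([segments + j, segments + i, np.full(segments, center_i)], axis=1)
    return ToothMesh(name=name, label=label,
                     vertices=vertices, faces=np.vstack([lateral, base]))


@dataclass
class JawSpec:
    """Parameters of one synthetic cone-tooth jaw.

    Tooth positions are distances (mm) along the joint→tip line and must
    be strictly increasing within (0, jaw_length); tilts rotate each cone
    about the jaw's transverse (y) axis, positive toward the jaw tip.
    """

    n_teeth: int = DEFAULT_N_TEETH
    jaw_length: float = DEFAULT_JAW_LENGTH
    positions: np.ndarray | None = None
    heights: np.ndarray | None = None
    radii: np.ndarray | None = None
    tilts_deg: np.ndarray | None = None
    insertion: tuple = DEFAULT_INSERTION
    origin: tuple | None = None
    segments: int = DEFAULT_SEGMENTS
    seed: int = 0
    outlier_index: int | None = None  # bookkeeping set by inject_outlier
    outlier_factor: float | None = None

    def __post_init__(self) -> None:
        n = self.n_teeth
        if self.positions is None:
            self.positions = np.linspace(0.25, 0.9, n) * self.jaw_length
        if self.heights is None:
            self.heights = np.full(n, DEFAULT_TOOTH_HEIGHT)
        if self.radii is None:
            self.radii = np.full(n, DEFAULT_TOOTH_RADIUS)
        if self.tilts_deg is None:
            self.tilts_deg = np.zeros(n)
        for attr in ("positions", "heights", "radii", "tilts_deg"):
            setattr(self, attr, np.asarray(getattr(self, attr), dtype=float))
            if len(getattr(self, attr)) != n:
                raise ValidationError(f"{attr} must have length n_teeth={n}")
        if self.segments < 16:
            raise ValidationError("mesh resolution: segments must be >= 16")
        if np.any(self.heights <= 0) or np.any(self.radii <= 0):
            raise ValidationError("tooth heights and radii must be positive")
        if np.any(np.diff(self.positions) <= 0):
            raise ValidationError("tooth positions must be strictly increasing")
        if self.positions[0] <= 0 or self.positions[-1] >= self.jaw_length:
            raise ValidationError("tooth positions must lie within (0, jaw_length)")
        gaps = np.diff(self.positions)
        min_gaps = self.radii[:-1] + self.radii[1:]
        if np.any(gaps < min_gaps):
            raise ValidationError("teeth overlap: spacing smaller than radii sums")


def _tooth_axis(tilt_deg: float) -> np.ndarray:
    t = np.deg2rad(tilt_deg)
    return np.array([np.sin(t), 0.0, np.cos(t)])


def ground_truth(spec: JawSpec) -> pd.DataFrame:
    """Analytic per-tooth traits under the standard modeling defaults.

    Independent closed forms (no calls into geometry/biomechanics):
    force = mechanical advantage (1 N, 90° defaults), stress = force /
    capped-cone area, width = basal diameter.
    """
    joint = np.zeros(3)
    insertion = np.asarray(spec.insertion, dtype=float)
    in_lever = float(np.linalg.norm(insertion - joint))
    rows = []
    for i in range(spec.n_teeth):
        h, r = float(spec.heights[i]), float(spec.radii[i])
        base = np.array([spec.positions[i], 0.0, 0.0])
        tip = base + h * _tooth_axis(spec.tilts_deg[i])
        out_lever = float(np.linalg.norm(tip - joint))
        ma = in_lever / out_lever
        area = float(cone_surface_area(h, r))
        rows.append({
            "tooth": f"T{i:02d}", "jaw_length": spec.jaw_length,
            "position": float(np.linalg.norm(base - joint)),
            "out_lever": out_lever, "in_lever": in_lever,
            "mechanical_advantage": ma, "force": ma, "stress": ma / area,
            "height": h, "width": 2.0 * r, "aspect_ratio": h / (2.0 * r),
            "surface_area": area,
            "tip_x": tip[0], "tip_y": tip[1], "tip_z": tip[2],
            "base_x": base[0], "base_y": base[1], "base_z": base[2],
            "is_outlier": i == spec.outlier_index,
        })
    return pd.DataFrame(rows)


def make_jaw(spec: JawSpec):
    """Realize a JawSpec: cone meshes, jaw landmarks and ground truth.

    Returns ``(meshes, landmarks, truth)`` where *truth* is the
    :func:`ground_truth` table. Deterministic: the same spec yields
    bit-identical meshes.
    """
    meshes = []
    for i in range(spec.n_teeth):
        base = np.array([spec.positions[i], 0.0, 0.0])
        meshes.append(make_cone(
            float(spec.heights[i]), float(spec.radii[i]), spec.segments,
            base_center=base, axis=_tooth_axis(spec.tilts_deg[i]),
            name=f"T{i:02d}", label=i + 1,
        ))
    points = {
        "jaw_joint": np.zeros(3),
        "jaw_tip": np.array([spec.jaw_length, 0.0, 0.0]),
        "insertion_1": np.asarray(spec.insertion, dtype=float),
    }
    if spec.origin is not None:
        points["origin_1"] = np.asarray(spec.origin, dtype=float)
    return meshes, LandmarkSet(points=points), ground_truth(spec)


def _solve_radius(height: float, target_area: float) -> float:
    """Basal radius of a capped cone of given height and total area."""

    def gap(r):
        return cone_surface_area(height, r) - target_area

    hi = 1.0
    while gap(hi) < 0:
        hi *= 2.0
    return float(brentq(gap, 1e-12, hi, xtol=1e-13, rtol=1e-14))


def inject_outlier(spec: JawSpec, tooth_index: int, stress_factor: float) -> JawSpec:
    """Rescale one tooth's radius so its modeled stress becomes
    ``stress_factor`` × the unmodified jaw's median stress.

    Only the basal radius changes (height, tip and thus the levers are
    untouched), solving π·r·√(r²+h²) + π·r² = F / target_stress for r.
    """
    if stress_factor <= 0:
        raise ValidationError("stress_factor must be positive")
    if not 0 <= tooth_index < spec.n_teeth:
        raise ValidationError(f"tooth_index {tooth_index} out of range "
                              f"(jaw has {spec.n_teeth} teeth)")
    truth = ground_truth(spec)
    target_stress = stress_factor * float(truth["stress"].median())
    force = float(truth["force"].iloc[tooth_index])
    radii = spec.radii.copy()
    radii[tooth_index] = _solve_radius(float(spec.heights[tooth_index]),
                                       force / target_stress)
    return replace(spec, radii=radii, outlier_index=tooth_index,
                   outlier_factor=stress_factor)


def calibrate_homodont(spec: JawSpec) -> JawSpec:
    """Adjust every tooth's radius so all modeled stresses are equal.

    The common stress is the unmodified jaw's median; each radius solves
    the capped-cone area equation for SA_i = F_i / median. The result is
    a perfectly functionally homodont jaw (every residual exactly 1)
    despite the lever gradient along the jaw.
    """
    truth = ground_truth(spec)
    target = float(truth["stress"].median())
    radii = np.array([
        _solve_radius(float(h), float(f) / target)
        for h, f in zip(spec.heights, truth["force"])
    ])
    return replace(spec, radii=radii)


def random_posed_cone(rng, segments: int = 64):
    """A randomly posed cone plus its jaw line and analytic tip/base.

    Height/radius ratio is drawn in [1, 10], pose is a uniform random
    rotation and translation. The jaw line is rigidly transformed along
    with the cone so the base always faces it. Returns a dict with the
    mesh, jaw_joint/jaw_tip, true apex/base and dimensions.
    """
    height = rng.uniform(2.0, 10.0)
    radius = height / rng.uniform(1.0, 10.0)
    rot = Rotation.random(random_state=rng)
    shift = rng.uniform(-20.0, 20.0, size=3)

    base0 = np.zeros(3)
    apex0 = np.array([0.0, 0.0, height])
    joint0 = np.array([-10.0, 0.0, 0.0])
    jaw_tip0 = np.array([10.0, 0.0, 0.0])
    axis = rot.apply([0.0, 0.0, 1.0])
    mesh = make_cone(height, radius, segments,
                     base_center=rot.apply(base0) + shift, axis=axis,
                     name="posed_cone")
    return {
        "mesh": mesh,
        "jaw_joint": rot.apply(joint0) + shift,
        "jaw_tip": rot.apply(jaw_tip0) + shift,
        "apex": rot.apply(apex0) + shift,
        "base": rot.apply(base0) + shift,
        "height": height,
        "radius": radius,
    }


def make_box_labelmap(n_labels: int = 3, box: int = 2, gap: int = 2,
                      spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)):
    """Tiny voxel labelmap: *n_labels* cubic blobs of side *box* voxels.

    Returns ``(volume, directions, origin)`` ready for
    :func:`odontomech.mesh_io.write_labelmap`.
    """
    if n_labels < 0 or box < 1:
        raise ValidationError("need n_labels >= 0 and box >= 1")
    step = box + gap
    shape = (max(n_labels * step + gap, 1) if n_labels else 4, box + 2 * gap, box + 2 * gap)
    vol = np.zeros(shape, dtype=np.int16)
    for lab in range(1, n_labels + 1):
        i0 = gap + (lab - 1) * step
        vol[i0:i0 + box, gap:gap + box, gap:gap + box] = lab
    directions = np.diag(np.asarray(spacing, dtype=float))
    return vol, directions, np.asarray(origin, dtype=float)


def write_jaw_bundle(spec: JawSpec, out_dir) -> dict:
    """Write a jaw fixture to disk: PLY meshes, FCSV+JSON landmarks,
    ground-truth CSV and the spec itself. Returns the path map."""
    from . import mesh_io

    out_dir = Path(out_dir)
    mesh_dir = out_dir / "meshes"
    mesh_dir.mkdir(parents=True, exist_ok=True)
    meshes, landmarks, truth = make_jaw(spec)
    mesh_paths = []
    for m in meshes:
        p = mesh_dir / f"{m.name}.ply"
        mesh_io.write_mesh(m, p)
        mesh_paths.append(p)
    fcsv = out_dir / "landmarks.fcsv"
    js = out_dir / "landmarks.json"
    mesh_io.write_landmarks(landmarks, fcsv)
    mesh_io.write_landmarks(landmarks, js)
    truth_path = out_dir / "ground_truth.csv"
    truth.to_csv(truth_path, index=False)
    spec_path = out_dir / "jaw_spec.json"
    import json

    with open(spec_path, "w", encoding="utf-8") as fh:
        json.dump({
            "n_teeth": spec.n_teeth, "jaw_length": spec.jaw_length,
            "positions": spec.positions.tolist(), "heights": spec.heights.tolist(),
            "radii": spec.radii.tolist(), "tilts_deg": spec.tilts_deg.tolist(),
            "insertion": list(spec.insertion),
            "origin": None if spec.origin is None else list(spec.origin),
            "segments": spec.segments, "seed": spec.seed,
            "outlier_index": spec.outlier_index,
            "outlier_factor": spec.outlier_factor,
        }, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return {"meshes": mesh_paths, "landmarks_fcsv": fcsv, "landmarks_json": js,
            "ground_truth": truth_path, "spec": spec_path}
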