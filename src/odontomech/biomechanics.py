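"""Jaw lever mechanics: in/out levers, muscle input force, per-tooth
output force and tooth stress.

The jaw is modeled as a static third-class lever. For each closing muscle
the in-lever is the jaw joint → insertion distance; for each tooth the
out-lever is the jaw joint → crown tip distance. The force a tooth can
exert is

    F_tooth = Σ_muscles  F_in · sin(α) · (in lever / out lever)

with α the muscle's insertion angle. Defaults — F_in = 1 N and α = 90° —
make tooth force numerically equal to mechanical advantage. Tooth stress
is σ = F_tooth / SA_tooth, the force spread over the crown surface area.

Muscle input force can instead be estimated from muscle anatomy via the
physiological cross-sectional area:

    F_in = volume · cos(pennation) / fiber_length · F_max

where fiber length defaults to the origin–insertion distance and F_max
(maximal isometric muscle stress) defaults to 0.2 N/mm².
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .geometry import ToothGeometry, analyze_tooth
from .types import LandmarkSet, ToothMesh

log = logging.getLogger(__name__)

DEFAULT_INPUT_FORCE_N = 1.0
DEFAULT_INSERTION_ANGLE_DEG = 90.0
DEFAULT_PENNATION_ANGLE_DEG = 0.0
DEFAULT_F_MAX = 0.2  # N/mm², maximal isometric muscle stress


@dataclass
class MuscleSpec:
    """One jaw-closing muscle's geometry and force parameters.

    Force comes either from ``input_force`` directly (default 1 N) or,
    when ``volume`` is given, from the physiological cross-sectional area
    pathway (volume-based estimation wins if both are supplied).
    ``insertion_angle_deg`` is used when no origin landmark is available
    to measure the angle.
    """

    name: str
    insertion: np.ndarray = None
    origin: np.ndarray | None = None
    input_force: float = DEFAULT_INPUT_FORCE_N
    insertion_angle_deg: float = DEFAULT_INSERTION_ANGLE_DEG
    volume: float | None = None  # mm³
    pennation_angle_deg: float = DEFAULT_PENNATION_ANGLE_DEG
    f_max: float = DEFAULT_F_MAX
    fiber_length: float | None = None  # mm

    def __post_init__(self) -> None:
        if self.insertion is not None:
            self.insertion = np.asarray(self.insertion, dtype=float).reshape(3)
        if self.origin is not None:
            self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        if not 0 < self.insertion_angle_deg <= 180:
            raise ValidationError(f"muscle {self.name!r}: insertion angle must be in (0, 180]")
        if not 0 <= self.pennation_angle_deg < 90:
            raise ValidationError(f"muscle {self.name!r}: pennation angle must be in [0, 90)")
        if self.input_force <= 0:
            raise ValidationError(f"muscle {self.name!r}: input force must be positive")
        if self.f_max <= 0:
            raise ValidationError(f"muscle {self.name!r}: F_max must be positive")
        for attr in ("volume", "fiber_length"):
            v = getattr(self, attr)
            if v is not None and v <= 0:
                raise ValidationError(f"muscle {self.name!r}: {attr} must be positive")


@dataclass
class ToothTraits:
    """Per-tooth output record: geometry plus lever mechanics.

    ``in_levers`` and ``mechanical_advantage`` are keyed by muscle name;
    ``force`` is summed over muscles and ``stress = force / surface_area``
    exactly. ``ok`` is False when geometry failed for this tooth, in which
    case ``error`` holds the message and numeric fields are NaN.
    """

    name: str
    jaw_length: float = np.nan
    position: float = np.nan
    out_lever: float = np.nan
    in_levers: dict = field(default_factory=dict)
    mechanical_advantage: dict = field(default_factory=dict)
    force: float = np.nan
    stress: float = np.nan
    height: float = np.nan
    width: float = np.nan
    aspect_ratio: float = np.nan
    surface_area: float = np.nan
    tip: np.ndarray | None = None
    base: np.ndarray | None = None
    ok: bool = True
    error: str | None = None


def levers(jaw: LandmarkSet, muscle: MuscleSpec, tip, base):
    """Lever distances for one tooth and one muscle.

    Returns ``(in_lever, out_lever, position, jaw_length)`` — all straight
    3-D Euclidean distances from the jaw joint to, respectively, the muscle
    insertion, the tooth tip, the tooth base, and the jaw tip (mm).
    """
    joint = jaw.jaw_joint
    tip = np.asarray(tip, dtype=float)
    base = np.asarray(base, dtype=float)
    if muscle.insertion is None:
        raise ValidationError(f"muscle {muscle.name!r}: insertion point required")
    in_lever = float(np.linalg.norm(muscle.insertion - joint))
    out_lever = float(np.linalg.norm(tip - joint))
    position = float(np.linalg.norm(base - joint))
    jaw_length = float(np.linalg.norm(jaw.jaw_tip - joint))
    if in_lever <= 0:
        raise ValidationError(f"muscle {muscle.name!r}: insertion coincides with the jaw joint")
    if out_lever <= 0:
        raise ValidationError("tooth tip coincides with the jaw joint")
    return in_lever, out_lever, position, jaw_length


def input_force(muscle: MuscleSpec) -> float:
    """Input force of one closing muscle, in N.

    Uses the physiological cross-sectional area pathway when ``volume``
    is given (F_in = volume·cos(pennation)/fiber_length · F_max, fiber
    length defaulting to the origin–insertion distance); otherwise returns
    the direct ``input_force`` (default 1 N).
    """
    if muscle.volume is None:
        return float(muscle.input_force)
    if muscle.fiber_length is not None:
        fiber = float(muscle.fiber_length)
    elif muscle.origin is not None and muscle.insertion is not None:
        fiber = float(np.linalg.norm(muscle.origin - muscle.insertion))
    else:
        raise ValidationError(
            f"muscle {muscle.name!r}: volume-based force needs an origin "
            f"landmark or an explicit fiber length"
        )
    if fiber <= 0:
        raise ValidationError(f"muscle {muscle.name!r}: zero fiber length")
    if muscle.input_force != DEFAULT_INPUT_FORCE_N:
        log.info("muscle %r: both direct force and volume given; using the "
                 "volume-based estimate", muscle.name)
    return float(muscle.volume * np.cos(np.deg2rad(muscle.pennation_angle_deg))
                 / fiber * muscle.f_max)


def insertion_angle(jaw_joint, insertion, origin) -> float:
    """Muscle insertion angle α in degrees.

    Measured at the insertion point, between the muscle's line of action
    (insertion → origin) and the in-lever line (insertion → jaw joint), so
    α = 90° is a perpendicular pull delivering maximal torque. Collinear
    geometry (0° or 180°) triggers a warning but the value is returned.
    """
    jaw_joint = np.asarray(jaw_joint, dtype=float)
    insertion = np.asarray(insertion, dtype=float)
    origin = np.asarray(origin, dtype=float)
    a = origin - insertion
    b = jaw_joint - insertion
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na <= 0 or nb <= 0:
        raise ValidationError("insertion angle needs three distinct points")
    cosang = np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0)
    angle = float(np.rad2deg(np.arccos(cosang)))
    if angle < 1e-9 or angle > 180 - 1e-9:
        warnings.warn(f"insertion angle is degenerate ({angle:.3g}°): muscle line "
                      f"of action is collinear with the in-lever")
    return angle


def tooth_force(muscles, in_levers, out_lever: float,
                forces=None, angles_deg=None) -> float:
    """Total force a tooth can exert, in N.

    Σ over muscles of F_in · sin(α) · (in_lever / out_lever). *forces* and
    *angles_deg* may pre-supply F_in and α per muscle; otherwise they are
    derived from each :class:`MuscleSpec` (measured from the origin
    landmark when present, else the spec's ``insertion_angle_deg``).
    """
    if out_lever <= 0:
        raise ValidationError("out-lever must be positive")
    if len(muscles) != len(in_levers):
        raise ValidationError("muscles and in-levers must align")
    total = 0.0
    for k, (m, in_lever) in enumerate(zip(muscles, in_levers)):
        f_in = forces[k] if forces is not None else input_force(m)
        alpha = angles_deg[k] if angles_deg is not None else m.insertion_angle_deg
        total += f_in * np.sin(np.deg2rad(alpha)) * (in_lever / out_lever)
    return float(total)


def tooth_stress(force: float, surface_area: float) -> float:
    """Tooth stress σ = F_tooth / SA_tooth, in N/mm²."""
    if surface_area <= 0:
        raise ValidationError("surface area must be positive")
    return float(force / surface_area)


@dataclass
class ToothOverride:
    """Per-tooth manual adjustments applied before mechanics."""

    tip: np.ndarray | None = None
    base: np.ndarray | None = None
    flip: bool = False


def compute_dentition(meshes, jaw: LandmarkSet, muscles=None,
                      overrides=None, slab_fraction=None) -> list:
    """Run geometry then lever mechanics for every tooth of a dentition.

    *muscles* defaults to one muscle per ``insertion_k`` landmark with the
    standard modeling defaults (1 N, 90°). *overrides* maps tooth name →
    :class:`ToothOverride` (manual tip/base or a flip), honored before any
    mechanics. A geometry failure on one tooth flags that record
    (``ok=False``) and leaves the others untouched.
    """
    if not meshes:
        raise ValidationError("compute_dentition needs at least one tooth mesh")
    if muscles is None:
        ins = jaw.insertions()
        if not ins:
            raise ValidationError("no muscles given and no insertion_k landmarks present")
        muscles = [MuscleSpec(name=f"muscle_{k}", insertion=p, origin=jaw.origin(k))
                   for k, p in ins.items()]
    for m in muscles:
        if m.insertion is None:
            raise ValidationError(f"muscle {m.name!r}: insertion point required")
    overrides = overrides or {}

    # measured insertion angles and input forces are jaw-level, not per tooth
    forces = [input_force(m) for m in muscles]
    angles = []
    for m in muscles:
        if m.origin is not None:
            angles.append(insertion_angle(jaw.jaw_joint, m.insertion, m.origin))
        else:
            angles.append(m.insertion_angle_deg)

    # tie-break vertical for near-isotropic crowns: normal of the plane
    # through jaw joint, jaw tip and the first insertion (when available)
    vertical = None
    v1 = jaw.jaw_tip - jaw.jaw_joint
    v2 = muscles[0].insertion - jaw.jaw_joint
    n = np.cross(v1, v2)
    if np.linalg.norm(n) > 1e-12:
        vertical = n / np.linalg.norm(n)

    records = []
    for mesh in meshes:
        ov = overrides.get(mesh.name, ToothOverride())
        try:
            geo = analyze_tooth(
                mesh, jaw.jaw_joint, jaw.jaw_tip,
                tip=ov.tip, base=ov.base, flip=ov.flip,
                vertical=vertical,
                **({"slab_fraction": slab_fraction} if slab_fraction is not None else {}),
            )
            rec = traits_for_tooth(geo, jaw, muscles, forces=forces, angles_deg=angles)
        except ValidationError as exc:
            log.warning("tooth %r failed: %s", mesh.name, exc)
            rec = ToothTraits(name=mesh.name, ok=False, error=str(exc))
        records.append(rec)
    return records


def traits_for_tooth(geo: ToothGeometry, jaw: LandmarkSet, muscles,
                     forces=None, angles_deg=None) -> ToothTraits:
    """Lever mechanics for one already-measured tooth."""
    in_levers, mas = {}, {}
    out_lever = position = jaw_length = None
    for m in muscles:
        il, out_lever, position, jaw_length = levers(jaw, m, geo.tip, geo.base)
        in_levers[m.name] = il
        mas[m.name] = il / out_lever
    force = tooth_force(muscles, list(in_levers.values()), out_lever,
                        forces=forces, angles_deg=angles_deg)
    stress = tooth_stress(force, geo.surface_area)
    return ToothTraits(
        name=geo.name, jaw_length=jaw_length, position=position,
        out_lever=out_lever, in_levers=in_levers, mechanical_advantage=mas,
        force=force, stress=stress, height=geo.height, width=geo.width,
        aspect_ratio=geo.aspect_ratio, surface_area=geo.surface_area,
        tip=geo.tip, base=geo.base,
    )


def traits_to_frame(records) -> pd.DataFrame:
    """Flatten :class:`ToothTraits` records into a tidy DataFrame.

    Stable column order: tooth, jaw_length, position, out_lever, one
    ``in_lever_<muscle>`` and ``mechanical_advantage_<muscle>`` pair per
    muscle, force, stress, height, width, aspect_ratio, surface_area,
    tip/base coordinates, ok, error.
    """
    muscle_names = []
    for r in records:
        for m in r.in_levers:
            if m not in muscle_names:
                muscle_names.append(m)
    rows = []
    for r in records:
        row = {"tooth": r.name, "jaw_length": r.jaw_length, "position": r.position,
               "out_lever": r.out_lever}
        for m in muscle_names:
            row[f"in_lever_{m}"] = r.in_levers.get(m, np.nan)
            row[f"mechanical_advantage_{m}"] = r.mechanical_advantage.get(m, np.nan)
        row.update(force=r.force, stress=r.stress, height=r.height, width=r.width,
                   aspect_ratio=r.aspect_ratio, surface_area=r.surface_area)
        for label, p in (("tip", r.tip), ("base", r.base)):
            for i, ax in enumerate("xyz"):
                row[f"{label}_{ax}"] = np.nan if p is None else float(p[i])
        row.update(ok=r.ok, error="" if r.error is None else r.error)
        rows.append(row)
    return pd.DataFrame(rows)
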