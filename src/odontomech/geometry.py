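"""Per-tooth shape analysis.

Each tooth is treated as a roughly conical crown: its long axis is found
from the second moments of the surface, the crown tip and base are located
automatically relative to the jaw line (the segment from jaw joint to jaw
tip), and height, basal width, aspect ratio and surface area are measured
from the oriented mesh.

The axis uses the *surface-measure* covariance (exact per-triangle area
integrals, not raw vertex scatter, so the result is independent of how the
surface happens to be triangulated) and selects the eigenvector whose
eigenvalue is most isolated from the other two. For any surface of
revolution the two transverse eigenvalues coincide, so the isolated one is
the symmetry axis whether the crown is tall (axis = largest eigenvalue) or
squat (axis = smallest); plain dominant-eigenvalue selection fails for
crowns wider than tall.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .errors import ValidationError
from .types import ToothMesh

log = logging.getLogger(__name__)

#: fraction of the axial extent used to raise the tip candidate off the crown
TIP_RAISE_FRACTION = 0.1
#: axial slab (fraction of height, measured from the base) used for width
BASAL_SLAB_FRACTION = 0.1
#: relative eigenvalue-isolation gap below which the axis is ambiguous
ISOTROPY_TOL = 1e-9


@dataclass
class ToothGeometry:
    """Oriented per-tooth geometry: crown tip/base, long axis and size traits.

    ``aspect_ratio`` is ``height / width`` by construction; ``surface_area``
    is the exact sum of triangle areas in mm².
    """

    name: str
    tip: np.ndarray
    base: np.ndarray
    axis: np.ndarray
    height: float
    width: float
    aspect_ratio: float
    surface_area: float

    def __post_init__(self) -> None:
        self.tip = np.asarray(self.tip, dtype=float).reshape(3)
        self.base = np.asarray(self.base, dtype=float).reshape(3)
        self.axis = np.asarray(self.axis, dtype=float).reshape(3)
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValidationError(f"tooth {self.name!r}: axis must be a unit vector")
        if not (self.height > 0 and self.width > 0 and self.surface_area > 0):
            raise ValidationError(
                f"tooth {self.name!r}: height, width and surface area must be positive"
            )


def surface_area(mesh: ToothMesh) -> float:
    """Total surface area in mm²: Σ over faces of ½‖(v1−v0)×(v2−v0)‖."""
    tri = mesh.vertices[mesh.faces]
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    area = 0.5 * np.linalg.norm(cross, axis=1).sum()
    if not area > 0:
        raise ValidationError(f"tooth {mesh.name!r}: zero surface area")
    return float(area)


def _surface_moments(vertices: np.ndarray, faces: np.ndarray):
    """Area-weighted surface centroid and covariance (exact triangle integrals)."""
    tri = vertices[faces]
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    cross = np.cross(b - a, c - a)
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    total = areas.sum()
    if total <= 0:
        raise ValidationError("degenerate surface: zero total area")
    w = areas / total
    mu = (w[:, None] * (a + b + c) / 3.0).sum(axis=0)

    d, e = b - a, c - a

    def outer(u, v):
        return u[:, :, None] * v[:, None, :]

    # E[x xT] over each triangle with x = a + u d + v e, (u, v) uniform on
    # the unit simplex: E[u] = 1/3, E[u^2] = 1/6, E[uv] = 1/12.
    exx = (outer(a, a)
           + (outer(a, d) + outer(d, a)) / 3.0
           + (outer(a, e) + outer(e, a)) / 3.0
           + outer(d, d) / 6.0 + outer(e, e) / 6.0
           + (outer(d, e) + outer(e, d)) / 12.0)
    second = (w[:, None, None] * exx).sum(axis=0)
    cov = second - np.outer(mu, mu)
    return mu, cov


def principal_axis(mesh: ToothMesh, vertical=None):
    """Long axis of a tooth.

    Returns ``(centroid, axis)`` where the centroid is the area-weighted
    mean of face centroids and the axis is the unit eigenvector of the
    surface covariance whose eigenvalue is most isolated from the other
    two (the symmetry axis for cone-like crowns of any aspect ratio). The
    sign is canonical but carries no tip/base orientation — see
    :func:`detect_tip_base`.

    Isotropic shapes (e.g. spheres), where all eigenvalues tie, emit a
    warning and break the tie deterministically: prefer the direction most
    aligned with *vertical* (default +z), then the lowest eigen-index.
    """
    centroid, cov = _surface_moments(mesh.vertices, mesh.faces)
    evals, evecs = np.linalg.eigh(cov)  # ascending
    scale = max(evals[-1], 1e-30)
    gaps = np.array([np.min(np.abs(np.delete(evals, i) - evals[i]))
                     for i in range(3)])
    if gaps.max() <= ISOTROPY_TOL * scale:
        warnings.warn(
            f"tooth {mesh.name!r}: principal axis ambiguous "
            f"(eigenvalues tie); deterministic tie-break applied"
        )
        v = np.array([0.0, 0.0, 1.0]) if vertical is None else \
            np.asarray(vertical, dtype=float)
        v = v / max(np.linalg.norm(v), 1e-30)
        scores = np.round(np.abs(evecs.T @ v), 12)
        pick = int(np.argmax(scores))
    else:
        # most isolated eigenvalue; ties broken toward the larger eigenvalue
        pick = int(np.lexsort((evals, gaps))[-1])
    axis = evecs[:, pick]
    lead = int(np.argmax(np.abs(axis)))
    if axis[lead] < 0:
        axis = -axis
    return centroid, axis / np.linalg.norm(axis)


# ---------------------------------------------------------------------------
# self-contained mesh queries (single ray / single point, vectorized over
# triangles — tooth meshes are small, so no spatial index is needed)

def ray_first_hit(vertices, faces, origin, direction):
    """First intersection of a ray with a triangle soup (Möller–Trumbore).

    Returns the hit point closest to *origin* along *direction*, or None.
    """
    tri = vertices[faces]
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    e1 = tri[:, 1] - tri[:, 0]
    e2 = tri[:, 2] - tri[:, 0]
    h = np.cross(direction, e2)
    det = (e1 * h).sum(axis=1)
    eps = 1e-12
    ok = np.abs(det) > eps
    inv = np.zeros_like(det)
    inv[ok] = 1.0 / det[ok]
    s = origin - tri[:, 0]
    u = (s * h).sum(axis=1) * inv
    q = np.cross(s, e1)
    v = (q * direction).sum(axis=1) * inv
    t = (e2 * q).sum(axis=1) * inv
    tol = 1e-9
    hit = ok & (u >= -tol) & (v >= -tol) & (u + v <= 1 + tol) & (t > eps)
    if not hit.any():
        return None
    t_min = t[hit].min()
    return origin + t_min * direction


def closest_surface_point(vertices, faces, point):
    """Nearest point on a triangle soup to *point* (exact, per-triangle)."""
    tri = vertices[faces]
    p = np.asarray(point, dtype=float)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac, ap = b - a, c - a, p - a

    d1 = (ab * ap).sum(1)
    d2 = (ac * ap).sum(1)
    bp = p - b
    d3 = (ab * bp).sum(1)
    d4 = (ac * bp).sum(1)
    cp = p - c
    d5 = (ab * cp).sum(1)
    d6 = (ac * cp).sum(1)

    va = d3 * d6 - d5 * d4
    vb = d5 * d2 - d1 * d6
    vc = d1 * d4 - d3 * d2
    denom = np.where(vb + vc + va != 0, va + vb + vc, 1.0)
    v_in = vb / denom
    w_in = vc / denom
    candidate = a + v_in[:, None] * ab + w_in[:, None] * ac  # face interior

    # edge/vertex regions (Ericson, Real-Time Collision Detection §5.1.5)
    res = candidate.copy()
    t_ab = np.clip(np.where(d1 - d3 != 0, d1 / np.where(d1 - d3 != 0, d1 - d3, 1.0), 0),
                   0, 1)
    on_ab = a + t_ab[:, None] * ab
    t_ac = np.clip(np.where(d2 - d6 != 0, d2 / np.where(d2 - d6 != 0, d2 - d6, 1.0), 0),
                   0, 1)
    on_ac = a + t_ac[:, None] * ac
    num_bc = d4 - d3
    den_bc = (d4 - d3) + (d5 - d6)
    t_bc = np.clip(np.where(den_bc != 0, num_bc / np.where(den_bc != 0, den_bc, 1.0), 0),
                   0, 1)
    on_bc = b + t_bc[:, None] * (c - b)

    res = np.where(((vc <= 0) & (d1 >= 0) & (d3 <= 0))[:, None], on_ab, res)
    res = np.where(((vb <= 0) & (d2 >= 0) & (d6 <= 0))[:, None], on_ac, res)
    res = np.where(((va <= 0) & (d4 - d3 >= 0) & (d5 - d6 >= 0))[:, None], on_bc, res)
    res = np.where(((d1 <= 0) & (d2 <= 0))[:, None], a, res)
    res = np.where(((d3 >= 0) & (d4 <= d3))[:, None], b, res)
    res = np.where(((d6 >= 0) & (d5 <= d6))[:, None], c, res)

    dist2 = ((res - p) ** 2).sum(axis=1)
    return res[int(np.argmin(dist2))]


def _project_to_segment(p, a, b):
    """Orthogonal projection of p onto segment ab, clamped to the segment."""
    ab = b - a
    t = float(np.dot(p - a, ab) / max(np.dot(ab, ab), 1e-30))
    return a + np.clip(t, 0.0, 1.0) * ab


def detect_tip_base(mesh: ToothMesh, jaw_joint, jaw_tip, vertical=None):
    """Locate the crown tip and base center automatically.

    The two extremes of the vertex projections on the principal axis give
    tip/base candidates. The candidate closer to the jaw line — the nearest
    point on the jaw-joint→jaw-tip segment to the tooth centroid — is taken
    as the base side. The base is refined to the first ray–mesh hit walking
    along the axis from outside the crown toward the centroid (center of
    the base); the tip candidate is raised above the crown along the axis
    and snapped to the nearest surface point.

    Returns ``(tip, base)`` as 3-vectors. If the base ray misses the mesh
    (pathological concavity) the extreme vertex is used with a warning.
    """
    jaw_joint = np.asarray(jaw_joint, dtype=float)
    jaw_tip = np.asarray(jaw_tip, dtype=float)
    centroid, axis = principal_axis(mesh, vertical=vertical)
    t = (mesh.vertices - centroid) @ axis
    t_lo, t_hi = float(t.min()), float(t.max())
    extent = t_hi - t_lo
    if extent <= 0:
        raise ValidationError(f"tooth {mesh.name!r}: zero extent along principal axis")
    cand = {"lo": centroid + t_lo * axis, "hi": centroid + t_hi * axis}

    ref = _project_to_segment(centroid, jaw_joint, jaw_tip)
    base_end = "lo" if np.linalg.norm(cand["lo"] - ref) <= np.linalg.norm(cand["hi"] - ref) \
        else "hi"
    tip_end = "hi" if base_end == "lo" else "lo"
    u = axis if tip_end == "hi" else -axis  # unit vector base -> tip

    # slide the base point along the axis until it contacts the tooth
    origin = cand[base_end] - u * (TIP_RAISE_FRACTION * extent)
    base = ray_first_hit(mesh.vertices, mesh.faces, origin, u)
    if base is None:
        warnings.warn(f"tooth {mesh.name!r}: base ray missed the mesh; "
                      f"falling back to the extreme vertex")
        log.warning("tooth %r: base ray missed the mesh", mesh.name)
        base = np.asarray(mesh.vertices[int(np.argmin(t)) if base_end == "lo"
                                        else int(np.argmax(t))], dtype=float)

    # raise the tip candidate above the crown, then snap to the surface
    raised = cand[tip_end] + u * (TIP_RAISE_FRACTION * extent)
    tip = closest_surface_point(mesh.vertices, mesh.faces, raised)
    return np.asarray(tip, dtype=float), np.asarray(base, dtype=float)


def tooth_height_width(mesh: ToothMesh, tip, base,
                       slab_fraction: float = BASAL_SLAB_FRACTION):
    """Crown height and basal width.

    Height is the straight-line tip–base distance. Width is the maximum
    caliper extent of the vertices that lie within the basal *slab_fraction*
    of the crown (measured along the tip−base direction), projected onto the
    plane normal to that direction; for a cone this equals the basal
    diameter 2r.
    """
    tip = np.asarray(tip, dtype=float)
    base = np.asarray(base, dtype=float)
    height = float(np.linalg.norm(tip - base))
    if height <= 0:
        raise ValidationError(f"tooth {mesh.name!r}: tip and base coincide")
    u = (tip - base) / height
    s = (mesh.vertices - base) @ u
    in_slab = s <= slab_fraction * height
    if in_slab.sum() < 3:  # recurved/odd crowns: use the 3 most basal vertices
        in_slab = np.argsort(s)[:3]
    pts = mesh.vertices[in_slab]
    helper = np.array([1.0, 0.0, 0.0])
    if abs(u[0]) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(u, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(u, e1)
    plane = np.stack([pts @ e1, pts @ e2], axis=1)
    width = _max_caliper(plane)
    if width <= 0:
        raise ValidationError(f"tooth {mesh.name!r}: zero basal width")
    return height, float(width)


def _max_caliper(points2d: np.ndarray) -> float:
    """Maximum pairwise distance among 2-D points (via the convex hull)."""
    if len(points2d) > 16:
        try:
            from scipy.spatial import ConvexHull

            points2d = points2d[ConvexHull(points2d).vertices]
        except Exception:  # collinear input: QhullError — fall through
            pass
    diff = points2d[:, None, :] - points2d[None, :, :]
    return float(np.sqrt((diff ** 2).sum(axis=2)).max())


def analyze_tooth(mesh: ToothMesh, jaw_joint, jaw_tip, *,
                  tip=None, base=None, flip: bool = False,
                  slab_fraction: float = BASAL_SLAB_FRACTION,
                  vertical=None) -> ToothGeometry:
    """Full geometric work-up of one tooth.

    Tip/base are detected automatically unless both are supplied as
    overrides; ``flip=True`` exchanges the detected (or supplied) tip and
    base before measuring, for crowns where the jaw-proximity rule guesses
    wrong.
    """
    if (tip is None) != (base is None):
        raise ValidationError(f"tooth {mesh.name!r}: override needs both tip and base")
    if tip is None:
        tip, base = detect_tip_base(mesh, jaw_joint, jaw_tip, vertical=vertical)
    tip = np.asarray(tip, dtype=float)
    base = np.asarray(base, dtype=float)
    if flip:
        tip, base = base, tip
    height, width = tooth_height_width(mesh, tip, base, slab_fraction=slab_fraction)
    area = surface_area(mesh)
    axis = (tip - base) / np.linalg.norm(tip - base)
    return ToothGeometry(
        name=mesh.name, tip=tip, base=base, axis=axis,
        height=height, width=width, aspect_ratio=height / width,
        surface_area=area,
    )


def flip_tip_base(geometries, selection="all"):
    """Exchange tip and base for the selected teeth.

    *geometries* is a list of :class:`ToothGeometry`; *selection* is
    ``"all"`` or a list of tooth names. Height is unchanged; width and all
    downstream lever traits must be recomputed from the flipped
    orientation. Flipping twice restores the original records.
    """
    if selection == "all":
        wanted = {g.name for g in geometries}
    else:
        wanted = set(selection)
        known = {g.name for g in geometries}
        unknown = wanted - known
        if unknown:
            raise ValidationError(f"unknown tooth name(s): {', '.join(sorted(unknown))}")
    out = []
    for g in geometries:
        if g.name in wanted:
            out.append(replace(g, tip=g.base.copy(), base=g.tip.copy(), axis=-g.axis))
        else:
            out.append(g)
    return out
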