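"""Core domain records: tooth meshes and jaw landmark sets.

All coordinates are millimeters in a single right-handed frame (RAS
convention when data come from medical imaging files). No unit inference
is performed on read.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: landmark labels understood by the lever model
REQUIRED_LANDMARKS = ("jaw_joint", "jaw_tip")
INSERTION_RE = re.compile(r"^insertion_([123])$")
ORIGIN_RE = re.compile(r"^origin_([123])$")


@dataclass
class ToothMesh:
    """A closed triangle surface for one tooth.

    Parameters
    ----------
    name : str
        Human-readable tooth label (e.g. ``"T03"``).
    label : int
        Positive integer segment label the tooth came from.
    vertices : (n, 3) float array
        Vertex coordinates in mm.
    faces : (m, 3) int array
        Triangles as vertex-index triples.
    """

    name: str
    label: int
    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.label <= 0:
            raise ValidationError(f"tooth {self.name!r}: label must be positive")
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValidationError(f"tooth {self.name!r}: vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise ValidationError(f"tooth {self.name!r}: faces must be (m, 3)")
        if len(self.vertices) < 4 or len(self.faces) < 4:
            raise ValidationError(
                f"tooth {self.name!r}: degenerate mesh "
                f"({len(self.vertices)} vertices, {len(self.faces)} faces; need >= 4 of each)"
            )
        if not np.all(np.isfinite(self.vertices)):
            raise ValidationError(f"tooth {self.name!r}: non-finite vertex coordinates")
        if self.faces.min() < 0 or self.faces.max() >= len(self.vertices):
            raise ValidationError(f"tooth {self.name!r}: face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class LandmarkSet:
    """Named jaw landmarks defining the lever system.

    ``jaw_joint`` and ``jaw_tip`` are required and must be distinct; up to
    three muscle insertion points (``insertion_1..3``) may be present, each
    optionally paired with its ``origin_k``.
    """

    points: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = {k: np.asarray(v, dtype=float).reshape(3) for k, v in self.points.items()}
        missing = [k for k in REQUIRED_LANDMARKS if k not in self.points]
        if missing:
            raise ValidationError(f"missing required landmark(s): {', '.join(missing)}")
        for p in self.points.values():
            if not np.all(np.isfinite(p)):
                raise ValidationError("non-finite landmark coordinates")
        if np.allclose(self.points["jaw_joint"], self.points["jaw_tip"]):
            raise ValidationError("jaw_joint and jaw_tip must be distinct points")
        for key in self.points:
            m = ORIGIN_RE.match(key)
            if m and f"insertion_{m.group(1)}" not in self.points:
                raise ValidationError(
                    f"landmark {key!r} present without matching insertion_{m.group(1)}"
                )

    @property
    def jaw_joint(self) -> np.ndarray:
        return self.points["jaw_joint"]

    @property
    def jaw_tip(self) -> np.ndarray:
        return self.points["jaw_tip"]

    def insertions(self) -> dict:
        """Map muscle index (1-based) -> insertion point, sorted by index."""
        out = {}
        for key, p in self.points.items():
            m = INSERTION_RE.match(key)
            if m:
                out[int(m.group(1))] = p
        return dict(sorted(out.items()))

    def origin(self, k: int):
        """Origin point for muscle *k*, or None."""
        return self.points.get(f"origin_{k}")

    def __eq__(self, other) -> bool:
        if not isinstance(other, LandmarkSet):
            return NotImplemented
        if set(self.points) != set(other.points):
            return False
        return all(np.allclose(self.points[k], other.points[k]) for k in self.points)
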