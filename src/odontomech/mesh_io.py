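"""Readers and writers for every external format the toolkit touches.

Meshes (PLY/OBJ/STL) go through trimesh; labeled volumes are NRRD (small
built-in parser) or NIfTI (nibabel); landmarks are 3D Slicer fiducial CSV
(FCSV) or plain JSON; trait tables are CSV via pandas.

Internal conventions: millimeters, a single right-handed RAS frame. FCSV
and NRRD files declaring LPS are converted on read (sign flip of the first
two axes) and Slicer files without a coordinate-system header are assumed
LPS, matching recent Slicer defaults.
"""
from __future__ import annotations

import csv
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from . import _nrrd
from .errors import FormatError, ValidationError
from .types import LandmarkSet, ToothMesh

log = logging.getLogger(__name__)

MESH_EXTENSIONS = (".ply", ".obj", ".stl")

_FCSV_COLUMNS = "id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID"


# ---------------------------------------------------------------------------
# meshes

def read_mesh(path, name: str | None = None, label: int = 1) -> ToothMesh:
    """Read one tooth mesh from a PLY/OBJ/STL file (ASCII or binary).

    Coordinates are taken as-is (assumed mm). Raises :class:`FormatError`
    for unreadable files and :class:`ValidationError` for degenerate
    surfaces (< 4 vertices or faces).
    """
    path = Path(path)
    if path.suffix.lower() not in MESH_EXTENSIONS:
        raise FormatError(f"{path}: unsupported mesh extension {path.suffix!r}")
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    try:
        raw = trimesh.load(str(path), force="mesh", process=False)
    except Exception as exc:  # trimesh raises a zoo of types
        raise FormatError(f"{path}: could not be read as {path.suffix}: {exc}") from exc
    if raw is None or not hasattr(raw, "vertices") or len(getattr(raw, "faces", ())) == 0:
        raise FormatError(f"{path}: no triangle data found")
    return ToothMesh(
        name=name if name is not None else path.stem,
        label=label,
        vertices=np.asarray(raw.vertices, dtype=float),
        faces=np.asarray(raw.faces, dtype=np.int64),
    )


def write_mesh(mesh: ToothMesh, path) -> None:
    """Write a tooth mesh. PLY is written as ASCII with float64 coordinates
    (lossless round-trip); OBJ and STL are delegated to trimesh."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".ply":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {mesh.n_vertices}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write(f"element face {mesh.n_faces}\n")
            fh.write("property list uchar int vertex_indices\nend_header\n")
            for v in mesh.vertices:
                fh.write(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}\n")
            for f in mesh.faces:
                fh.write(f"3 {f[0]} {f[1]} {f[2]}\n")
    elif ext in (".obj", ".stl"):
        tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.faces, process=False)
        tm.export(str(path))
    else:
        raise FormatError(f"{path}: unsupported mesh extension {ext!r}")


def read_mesh_dir(directory, pattern: str = "*") -> list[ToothMesh]:
    """Read every PLY/OBJ/STL file in a directory (sorted by name)."""
    directory = Path(directory)
    out = []
    for i, p in enumerate(sorted(directory.glob(pattern)), start=1):
        if p.suffix.lower() in MESH_EXTENSIONS:
            out.append(read_mesh(p, label=i))
    return out


# ---------------------------------------------------------------------------
# labeled volumes

def _voxel_surface(mask: np.ndarray, directions: np.ndarray, origin: np.ndarray):
    """Exact boundary surface of a boolean voxel mask.

    Each voxel at index (i, j, k) is the axis-aligned cell spanning
    index ± 0.5; the returned surface is the set of cell faces between the
    mask and its complement. Deterministic, no smoothing: one unit voxel
    yields surface area exactly 6 (in index units).
    """
    mask = np.asarray(mask, dtype=bool)
    padded = np.pad(mask, 1)
    quads = []  # (n, 4, 3) corner coordinates in index space
    for axis in range(3):
        b, c = [a for a in range(3) if a != axis]
        for sign in (+1, -1):
            neighbor = np.roll(padded, -sign, axis=axis)
            exposed = padded & ~neighbor
            idx = np.argwhere(exposed) - 1  # undo padding
            if len(idx) == 0:
                continue
            center = idx.astype(float)
            corners = np.empty((len(idx), 4, 3))
            # cyclic corner order; wound so the two triangles share a diagonal
            offsets = [(-0.5, -0.5), (0.5, -0.5), (0.5, 0.5), (-0.5, 0.5)]
            for ci, (sb, sc) in enumerate(offsets):
                corner = center.copy()
                corner[:, axis] += 0.5 * sign
                corner[:, b] += sb
                corner[:, c] += sc
                corners[:, ci, :] = corner
            quads.append(corners)
    if not quads:
        return np.empty((0, 3)), np.empty((0, 3), dtype=np.int64)
    quads = np.concatenate(quads, axis=0)
    pts = quads.reshape(-1, 3)
    # corners sit on the half-integer grid: dedupe exactly via 2x integer keys
    keys = np.round(pts * 2).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    vertices = origin + (uniq / 2.0) @ directions
    quad_idx = inverse.reshape(-1, 4)
    faces = np.concatenate(
        [quad_idx[:, [0, 1, 2]], quad_idx[:, [0, 2, 3]]], axis=0
    )
    return vertices, faces


def _load_volume(path, spacing_override=None):
    path = Path(path)
    suffixes = "".join(path.suffixes).lower()
    if path.suffix.lower() == ".nrrd":
        data, directions, origin = _nrrd.read(path)
    elif suffixes.endswith((".nii", ".nii.gz")):
        import nibabel as nib

        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        affine = img.affine  # NIfTI affines map index -> RAS already
        directions = affine[:3, :3].T
        origin = affine[:3, 3]
    else:
        raise FormatError(f"{path}: unsupported labelmap extension (need .nrrd/.nii/.nii.gz)")
    if spacing_override is not None:
        sp = np.asarray(spacing_override, dtype=float).reshape(3)
        norms = np.linalg.norm(directions, axis=1)
        directions = directions / norms[:, None] * sp[:, None]
    return data, directions, origin


def read_labelmap(path, spacing_override=None) -> list[ToothMesh]:
    """Extract one mesh per nonzero integer label of an NRRD/NIfTI volume.

    Surfaces are exact voxel boundaries in physical (mm) coordinates using
    the volume's spacing/origin/direction. Labels whose surface comes out
    empty are skipped with a warning. Raises :class:`ValidationError` for
    non-integer volumes.
    """
    data, directions, origin = _load_volume(path, spacing_override)
    if data.dtype.kind not in "iub":
        if not np.allclose(data, np.round(data)):
            raise ValidationError(f"{path}: labelmap volume must hold integer labels")
        data = np.round(data).astype(np.int64)
    labels = np.unique(data)
    labels = labels[labels > 0]
    meshes = []
    for lab in labels:
        verts, faces = _voxel_surface(data == lab, directions, origin)
        if len(faces) < 4:
            warnings.warn(f"label {int(lab)} produced an empty surface; skipped")
            log.warning("label %d produced an empty surface; skipped", int(lab))
            continue
        meshes.append(
            ToothMesh(name=f"label_{int(lab)}", label=int(lab), vertices=verts, faces=faces)
        )
    return meshes


def write_labelmap(path, data, directions=None, origin=None) -> None:
    """Write an integer volume as NRRD or NIfTI (directions/origin in RAS mm)."""
    path = Path(path)
    data = np.asarray(data)
    directions = np.eye(3) if directions is None else np.asarray(directions, dtype=float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    if path.suffix.lower() == ".nrrd":
        _nrrd.write(path, data, directions, origin)
    elif "".join(path.suffixes).lower().endswith((".nii", ".nii.gz")):
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = directions.T
        affine[:3, 3] = origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
    else:
        raise FormatError(f"{path}: unsupported labelmap extension")


# ---------------------------------------------------------------------------
# landmarks

def read_landmarks(path) -> LandmarkSet:
    """Read jaw landmarks from FCSV (Slicer markups fiducial) or JSON.

    FCSV coordinate-system headers (RAS vs LPS) are honored and points are
    normalized to the internal RAS frame; a missing header means LPS. JSON
    files are taken to be in the internal frame already.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"{path}: no such file")
    if path.suffix.lower() == ".json":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        if not isinstance(raw, dict):
            raise FormatError(f"{path}: JSON landmarks must be a label -> [x,y,z] mapping")
        return LandmarkSet(points={str(k): np.asarray(v, dtype=float) for k, v in raw.items()})
    if path.suffix.lower() != ".fcsv":
        raise FormatError(f"{path}: unsupported landmark extension (need .fcsv or .json)")

    coordsys = "LPS"  # Slicer default when the header is absent
    columns = _FCSV_COLUMNS.split(",")
    rows = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                text = line.lstrip("#").strip()
                key, _, value = text.partition("=")
                key = key.strip().lower()
                value = value.strip()
                if key == "coordinatesystem":
                    coordsys = {"0": "RAS", "1": "LPS"}.get(value, value.upper())
                elif key == "columns":
                    columns = [c.strip() for c in value.split(",")]
                continue
            rows.append(next(csv.reader([line])))
    try:
        ix, iy, iz = columns.index("x"), columns.index("y"), columns.index("z")
        ilabel = columns.index("label")
    except ValueError as exc:
        raise FormatError(f"{path}: FCSV columns header lacks x/y/z/label") from exc

    points = {}
    for row in rows:
        if len(row) <= max(ix, iy, iz, ilabel):
            raise FormatError(f"{path}: malformed FCSV row: {row}")
        p = np.array([float(row[ix]), float(row[iy]), float(row[iz])])
        if coordsys == "LPS":
            p[0], p[1] = -p[0], -p[1]
        elif coordsys != "RAS":
            raise FormatError(f"{path}: unsupported coordinate system {coordsys!r}")
        points[row[ilabel]] = p
    return LandmarkSet(points=points)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    """Write landmarks as FCSV (LPS, Slicer-compatible) or JSON (internal frame)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({k: [float(x) for x in v] for k, v in landmarks.points.items()},
                      fh, indent=1, sort_keys=True)
            fh.write("\n")
        return
    if path.suffix.lower() != ".fcsv":
        raise FormatError(f"{path}: unsupported landmark extension (need .fcsv or .json)")
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("# Markups fiducial file version = 4.11\n")
        fh.write("# CoordinateSystem = LPS\n")
        fh.write(f"# columns = {_FCSV_COLUMNS}\n")
        writer = csv.writer(fh)
        for i, (label, p) in enumerate(landmarks.points.items(), start=1):
            lps = [-p[0], -p[1], p[2]]
            writer.writerow(
                [f"vtkMRMLMarkupsFiducialNode_{i}", repr(float(lps[0])), repr(float(lps[1])),
                 repr(float(lps[2])), 0, 0, 0, 1, 1, 1, 0, label, "", ""]
            )


# ---------------------------------------------------------------------------
# trait tables

def write_traits_table(records, path) -> None:
    """Write per-tooth trait records as CSV (UTF-8, comma, header row).

    One row per tooth, one column per trait; jaw-level quantities (jaw
    length, in-levers) are repeated on every row. Column order is the
    order of :func:`odontomech.biomechanics.traits_to_frame`.
    """
    from .biomechanics import traits_to_frame

    if not records:
        raise ValidationError("cannot write an empty trait table")
    frame = records if isinstance(records, pd.DataFrame) else traits_to_frame(records)
    frame.to_csv(path, index=False)


def read_traits_table(path) -> pd.DataFrame:
    """Read a trait CSV written by :func:`write_traits_table`."""
    return pd.read_csv(path)
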