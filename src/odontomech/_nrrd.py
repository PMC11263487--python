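"""Minimal NRRD labelmap reader/writer.

Supports the subset of NRRD used for 3D integer labelmaps: raw, gzip and
ascii encodings, little/big endian, ``space directions``/``space origin``
headers, and RAS/LPS space names. Data are stored in NRRD's native Fortran
(fastest-axis-first) order.
"""
from __future__ import annotations

import gzip
import re

import numpy as np

from .errors import FormatError

_TYPE_MAP = {
    "signed char": np.int8, "int8": np.int8, "int8_t": np.int8,
    "uchar": np.uint8, "unsigned char": np.uint8, "uint8": np.uint8, "uint8_t": np.uint8,
    "short": np.int16, "int16": np.int16, "int16_t": np.int16,
    "ushort": np.uint16, "unsigned short": np.uint16, "uint16": np.uint16, "uint16_t": np.uint16,
    "int": np.int32, "int32": np.int32, "int32_t": np.int32,
    "uint": np.uint32, "unsigned int": np.uint32, "uint32": np.uint32, "uint32_t": np.uint32,
    "long long": np.int64, "int64": np.int64, "int64_t": np.int64,
    "uint64": np.uint64, "uint64_t": np.uint64,
    "float": np.float32, "double": np.float64,
}

_LPS_NAMES = {"left-posterior-superior", "lps"}
_RAS_NAMES = {"right-anterior-superior", "ras"}


def _parse_vector_list(text: str) -> list:
    """Parse `(a,b,c) (d,e,f) none` style header values."""
    out = []
    for tok in re.findall(r"\(([^)]*)\)|(\bnone\b)", text):
        if tok[1]:
            out.append(None)
        else:
            out.append(np.array([float(x) for x in tok[0].split(",")]))
    return out


def read(path):
    """Read an NRRD volume.

    Returns
    -------
    data : ndarray
        Volume indexed ``[i, j, k]`` matching the header axis order.
    directions : (3, 3) ndarray
        Row *i* is the physical step for axis *i*, in RAS mm.
    origin : (3,) ndarray
        Physical position of index (0, 0, 0), in RAS mm.
    """
    with open(path, "rb") as fh:
        magic = fh.readline()
        if not magic.startswith(b"NRRD"):
            raise FormatError(f"{path}: not an NRRD file")
        fields = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("utf-8").strip()
            if text.startswith("#") or ":" not in text:
                continue
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.lstrip("=").strip()
        payload = fh.read()

    try:
        sizes = [int(s) for s in fields["sizes"].split()]
        dtype = np.dtype(_TYPE_MAP[fields["type"]])
    except KeyError as exc:
        raise FormatError(f"{path}: missing or unsupported NRRD header field: {exc}") from exc
    if len(sizes) != 3:
        raise FormatError(f"{path}: only 3-D NRRD volumes are supported (sizes={sizes})")
    if dtype.itemsize > 1:
        endian = fields.get("endian", "little")
        dtype = dtype.newbyteorder("<" if endian == "little" else ">")

    encoding = fields.get("encoding", "raw")
    if encoding == "raw":
        flat = np.frombuffer(payload, dtype=dtype)
    elif encoding in ("gzip", "gz"):
        flat = np.frombuffer(gzip.decompress(payload), dtype=dtype)
    elif encoding in ("ascii", "text", "txt"):
        flat = np.array(payload.split(), dtype=dtype)
    else:
        raise FormatError(f"{path}: unsupported NRRD encoding {encoding!r}")
    n = int(np.prod(sizes))
    if flat.size < n:
        raise FormatError(f"{path}: truncated NRRD data ({flat.size} < {n} values)")
    data = flat[:n].reshape(sizes, order="F")

    directions = np.eye(3)
    if "space directions" in fields:
        vecs = [v for v in _parse_vector_list(fields["space directions"]) if v is not None]
        if len(vecs) == 3:
            directions = np.vstack(vecs)
    elif "spacings" in fields:
        directions = np.diag([float(s) for s in fields["spacings"].split()])
    origin = np.zeros(3)
    if "space origin" in fields:
        vecs = _parse_vector_list(fields["space origin"])
        if vecs and vecs[0] is not None:
            origin = vecs[0]

    space = fields.get("space", "left-posterior-superior").lower()
    if space in _LPS_NAMES:
        flip = np.array([-1.0, -1.0, 1.0])
        directions = directions * flip
        origin = origin * flip
    elif space not in _RAS_NAMES:
        raise FormatError(f"{path}: unsupported NRRD space {space!r}")
    return np.ascontiguousarray(data), directions, origin


def write(path, data, directions=None, origin=None, space="right-anterior-superior"):
    """Write a 3-D volume as raw little-endian NRRD (directions/origin in RAS mm)."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise FormatError("only 3-D volumes can be written")
    directions = np.eye(3) if directions is None else np.asarray(directions, dtype=float)
    origin = np.zeros(3) if origin is None else np.asarray(origin, dtype=float)
    if space.lower() in _LPS_NAMES:
        flip = np.array([-1.0, -1.0, 1.0])
        directions = directions * flip
        origin = origin * flip
    canonical = {
        np.int8: "int8", np.uint8: "uint8", np.int16: "int16", np.uint16: "uint16",
        np.int32: "int32", np.uint32: "uint32", np.int64: "int64", np.uint64: "uint64",
        np.float32: "float", np.float64: "double",
    }
    name = canonical.get(data.dtype.type)
    if name is None:
        raise FormatError(f"unsupported dtype for NRRD write: {data.dtype}")
    dirs = " ".join("(" + ",".join(repr(float(x)) for x in row) + ")" for row in directions)
    orig = "(" + ",".join(repr(float(x)) for x in origin) + ")"
    header = (
        "NRRD0004\n"
        f"type: {name}\n"
        "dimension: 3\n"
        f"space: {space}\n"
        f"sizes: {data.shape[0]} {data.shape[1]} {data.shape[2]}\n"
        f"space directions: {dirs}\n"
        "kinds: domain domain domain\n"
        "endian: little\n"
        "encoding: raw\n"
        f"space origin: {orig}\n"
        "\n"
    )
    le = data.astype(data.dtype.newbyteorder("<"), copy=False)
    with open(path, "wb") as fh:
        fh.write(header.encode("utf-8"))
        fh.write(np.asfortranarray(le).tobytes(order="F"))
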