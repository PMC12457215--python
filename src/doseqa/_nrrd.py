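"""Minimal NRRD (NRRD0004) reader/writer for axis-aligned 3D research grids.

Supports exactly what the package emits: 3D ``double`` or ``uchar`` arrays,
``raw`` (little-endian) or ``text`` encodings, diagonal space directions and
a voxel-center space origin. This is not a general NRRD implementation; use
pynrrd for anything exotic.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .errors import FormatError, UnsupportedGeometryError

_TYPE_TO_DTYPE = {
    "double": np.float64,
    "float": np.float32,
    "uchar": np.uint8,
    "unsigned char": np.uint8,
    "uint8": np.uint8,
}


def _parse_vector(text: str) -> list[float]:
    return [float(t) for t in text.strip().lstrip("(").rstrip(")").split(",")]


def read(path: Path) -> tuple[np.ndarray, tuple[float, ...], tuple[float, ...]]:
    with open(path, "rb") as fh:
        magic = fh.readline().decode("ascii", "replace").strip()
        if not magic.startswith("NRRD"):
            raise FormatError(f"{path}: not an NRRD file (magic {magic!r})")
        fields: dict[str, str] = {}
        while True:
            line = fh.readline()
            if line in (b"\n", b"\r\n", b""):
                break
            text = line.decode("ascii", "replace").rstrip("\r\n")
            if text.startswith("#"):
                continue
            if ":" not in text:
                raise FormatError(f"{path}: malformed header line {text!r}")
            key, _, value = text.partition(":")
            fields[key.strip().lower()] = value.lstrip("= ").strip()
        data = fh.read()

    if int(fields.get("dimension", "0")) != 3:
        raise FormatError(f"{path}: only 3D NRRD supported")
    dtype = _TYPE_TO_DTYPE.get(fields.get("type", ""))
    if dtype is None:
        raise FormatError(f"{path}: unsupported type {fields.get('type')!r}")
    shape = tuple(int(s) for s in fields["sizes"].split())
    encoding = fields.get("encoding", "raw").lower()

    if "space directions" in fields:
        dirs = [_parse_vector(v) for v in fields["space directions"].split(") (")]
        spacing = []
        for a, d in enumerate(dirs):
            off = [abs(x) for i, x in enumerate(d) if i != a]
            if any(o > 1e-9 for o in off) or d[a] <= 0:
                raise UnsupportedGeometryError(
                    f"{path}: only positive diagonal space directions supported"
                )
            spacing.append(float(d[a]))
    else:
        spacing = [float(s) for s in fields.get("spacings", "1 1 1").split()]
    origin = tuple(_parse_vector(fields.get("space origin", "(0,0,0)")))

    if encoding == "raw":
        arr = np.frombuffer(data, dtype=np.dtype(dtype).newbyteorder("<"))
    elif encoding in ("text", "txt", "ascii"):
        arr = np.array(data.split(), dtype=dtype)
    else:
        raise FormatError(f"{path}: unsupported encoding {encoding!r}")
    if arr.size != int(np.prod(shape)):
        raise FormatError(f"{path}: data size {arr.size} != prod(sizes) {shape}")
    # NRRD stores the fastest axis first; C-order ravel of (z,y,x) -> transpose
    values = arr.reshape(shape[::-1]).transpose(2, 1, 0).astype(dtype)
    return values, origin, tuple(spacing)


def write(
    path: Path,
    values: np.ndarray,
    origin: tuple[float, ...],
    spacing: tuple[float, ...],
    encoding: str = "raw",
) -> None:
    values = np.asarray(values)
    if values.ndim != 3:
        raise FormatError("only 3D arrays supported")
    if values.dtype == np.uint8:
        type_name = "uchar"
    else:
        values = values.astype(np.float64)
        type_name = "double"
    dirs = " ".join(
        "(%s)" % ",".join(repr(float(spacing[a]) if i == a else 0.0) for i in range(3))
        for a in range(3)
    )
    header = [
        "NRRD0004",
        "# generated by doseqa",
        f"type: {type_name}",
        "dimension: 3",
        "space: left-posterior-superior",
        "sizes: %d %d %d" % values.shape,
        f"space directions: {dirs}",
        "kinds: domain domain domain",
        "endian: little",
        f"encoding: {encoding}",
        "space origin: (%r,%r,%r)" % tuple(float(o) for o in origin),
        "",
        "",
    ]
    flat = values.transpose(2, 1, 0).ravel()  # fastest axis first on disk
    with open(path, "wb") as fh:
        fh.write("\n".join(header).encode("ascii"))
        if encoding == "raw":
            fh.write(np.ascontiguousarray(flat, dtype=flat.dtype.newbyteorder("<")).tobytes())
        elif encoding in ("text", "txt", "ascii"):
            if type_name == "uchar":
                fh.write(b" ".join(b"%d" % v for v in flat))
            else:
                fh.write(" ".join(repr(float(v)) for v in flat).encode("ascii"))
        else:
            raise FormatError(f"unsupported encoding {encoding!r}")
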