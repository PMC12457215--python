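"""Minimal DICOM RTDOSE codec (explicit VR little endian only).

Implements just enough of PS3.10/PS3.5 to round-trip the RTDOSE objects this
package writes for synthetic fixtures and to ingest well-formed clinical
RTDOSE exports on axis-aligned grids. Unsupported transfer syntaxes or
non-identity orientations are rejected rather than guessed at.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

from .errors import FormatError, UnsupportedGeometryError

_EXPLICIT_VR_LE = "1.2.840.10008.1.2.1"
_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"
# VRs whose length field is 4 bytes after a 2-byte reserved gap (PS3.5 7.1.2)
_LONG_VRS = {b"OB", b"OW", b"OF", b"OD", b"OL", b"SQ", b"UC", b"UR", b"UT", b"UN"}

_T = lambda g, e: (g << 16) | e  # noqa: E731 - compact tag constructor

TAG_MODALITY = _T(0x0008, 0x0060)
TAG_SOP_CLASS = _T(0x0008, 0x0016)
TAG_SOP_INSTANCE = _T(0x0008, 0x0018)
TAG_IMAGE_POSITION = _T(0x0020, 0x0032)
TAG_IMAGE_ORIENTATION = _T(0x0020, 0x0037)
TAG_SAMPLES_PER_PIXEL = _T(0x0028, 0x0002)
TAG_NUM_FRAMES = _T(0x0028, 0x0008)
TAG_ROWS = _T(0x0028, 0x0010)
TAG_COLS = _T(0x0028, 0x0011)
TAG_PIXEL_SPACING = _T(0x0028, 0x0030)
TAG_BITS_ALLOCATED = _T(0x0028, 0x0100)
TAG_PIXEL_REPRESENTATION = _T(0x0028, 0x0103)
TAG_DOSE_UNITS = _T(0x3004, 0x0002)
TAG_GRID_FRAME_OFFSETS = _T(0x3004, 0x000C)
TAG_DOSE_GRID_SCALING = _T(0x3004, 0x000E)
TAG_PIXEL_DATA = _T(0x7FE0, 0x0010)


def _read_elements(buf: bytes, start: int, stop: int) -> dict[int, tuple[bytes, bytes]]:
    """Walk explicit-VR little-endian elements; return {tag: (vr, value)}."""
    out: dict[int, tuple[bytes, bytes]] = {}
    pos = start
    while pos + 8 <= stop:
        group, elem = struct.unpack_from("<HH", buf, pos)
        vr = buf[pos + 4 : pos + 6]
        if vr in _LONG_VRS:
            (length,) = struct.unpack_from("<I", buf, pos + 8)
            data_start = pos + 12
        else:
            (length,) = struct.unpack_from("<H", buf, pos + 6)
            data_start = pos + 8
        if length == 0xFFFFFFFF:
            raise FormatError("undefined-length elements are not supported")
        value = buf[data_start : data_start + length]
        out[_T(group, elem)] = (vr, value)
        pos = data_start + length
    return out


def _str(elements: dict, tag: int) -> str:
    return elements[tag][1].decode("ascii").strip("\x00 ").strip()


def _floats(elements: dict, tag: int) -> list[float]:
    return [float(p) for p in _str(elements, tag).split("\\")]


def _int(elements: dict, tag: int) -> int:
    vr, value = elements[tag]
    if vr == b"US":
        return struct.unpack("<H", value)[0]
    return int(value.decode("ascii").strip("\x00 "))


def read_rtdose_arrays(
    path: Path,
) -> tuple[np.ndarray, tuple[float, float, float], tuple[float, float, float]]:
    """Return (values[x, y, z] in Gy, origin, spacing) from an RTDOSE file."""
    buf = path.read_bytes()
    if len(buf) < 132 or buf[128:132] != b"DICM":
        raise FormatError(f"{path}: missing DICM magic — not a DICOM part-10 file")

    # file meta group (always explicit VR LE); its length is in (0002,0000)
    group, elem = struct.unpack_from("<HH", buf, 132)
    if (group, elem) != (0x0002, 0x0000):
        raise FormatError(f"{path}: file meta group length element missing")
    (meta_len,) = struct.unpack_from("<I", buf, 140)
    meta_end = 144 + meta_len
    meta = _read_elements(buf, 144, meta_end)
    ts = _str(meta, _T(0x0002, 0x0010)) if _T(0x0002, 0x0010) in meta else ""
    if ts != _EXPLICIT_VR_LE:
        raise FormatError(
            f"{path}: unsupported transfer syntax {ts!r} (explicit VR LE only)"
        )

    el = _read_elements(buf, meta_end, len(buf))
    modality = _str(el, TAG_MODALITY) if TAG_MODALITY in el else ""
    if modality != "RTDOSE":
        raise FormatError(f"{path}: modality {modality!r} is not RTDOSE")

    orient = _floats(el, TAG_IMAGE_ORIENTATION)
    if not np.allclose(orient, [1, 0, 0, 0, 1, 0], atol=1e-6):
        raise UnsupportedGeometryError(
            f"{path}: tilted orientation {orient} not supported (axis-aligned only)"
        )

    rows = _int(el, TAG_ROWS)
    cols = _int(el, TAG_COLS)
    frames = _int(el, TAG_NUM_FRAMES)
    bits = _int(el, TAG_BITS_ALLOCATED)
    if bits not in (16, 32):
        raise FormatError(f"{path}: unsupported BitsAllocated {bits}")
    signed = TAG_PIXEL_REPRESENTATION in el and _int(el, TAG_PIXEL_REPRESENTATION) == 1
    dtype = {16: "<i2" if signed else "<u2", 32: "<i4" if signed else "<u4"}[bits]

    scaling = _floats(el, TAG_DOSE_GRID_SCALING)[0]
    position = _floats(el, TAG_IMAGE_POSITION)
    row_sp, col_sp = _floats(el, TAG_PIXEL_SPACING)  # (between rows=y, cols=x)
    offsets = _floats(el, TAG_GRID_FRAME_OFFSETS)
    if len(offsets) != frames:
        raise FormatError(f"{path}: {len(offsets)} frame offsets for {frames} frames")
    dz = np.diff(offsets)
    if frames > 1 and (not np.allclose(dz, dz[0], atol=1e-6) or dz[0] <= 0):
        raise UnsupportedGeometryError(f"{path}: non-uniform grid frame offsets")
    z_spacing = float(dz[0]) if frames > 1 else 1.0

    stored = np.frombuffer(el[TAG_PIXEL_DATA][1], dtype=dtype, count=frames * rows * cols)
    # pixel data is (frame=z, row=y, col=x); convert to (x, y, z)
    values = (scaling * stored.astype(np.float64)).reshape(frames, rows, cols)
    values = values.transpose(2, 1, 0)
    origin = (position[0], position[1], position[2] + offsets[0])
    spacing = (col_sp, row_sp, z_spacing)
    return values, origin, spacing


def _el_short(group: int, elem: int, vr: bytes, value: bytes) -> bytes:
    if len(value) % 2:
        value += b"\x00" if vr not in (b"DS", b"IS", b"CS", b"LO", b"UI", b"SH") else b" "
    if vr in _LONG_VRS:
        return struct.pack("<HH2sHI", group, elem, vr, 0, len(value)) + value
    return struct.pack("<HH2sH", group, elem, vr, len(value)) + value


def _ds(*vals: float) -> bytes:
    return "\\".join(f"{v:.10g}" for v in vals).encode("ascii")


def write_rtdose_arrays(
    values: np.ndarray,
    origin: tuple[float, float, float],
    spacing: tuple[float, float, float],
    path: Path,
    sop_instance_uid: str = "1.2.826.0.1.3680043.9.7435.1.1",
) -> None:
    """Write (x, y, z)-ordered dose values (Gy) as an explicit-VR-LE RTDOSE."""
    values = np.asarray(values, dtype=np.float64)
    if values.ndim != 3:
        raise FormatError("dose values must be 3D")
    nx, ny, nz = values.shape
    dmax = values.max()
    scaling = dmax / (2**32 - 1) if dmax > 0 else 1.0
    stored = np.round(values / scaling).astype("<u4")
    pixel_data = np.ascontiguousarray(stored.transpose(2, 1, 0)).tobytes()

    meta_body = b"".join(
        [
            _el_short(0x0002, 0x0001, b"OB", b"\x00\x01"),
            _el_short(0x0002, 0x0002, b"UI", _RTDOSE_SOP_CLASS.encode()),
            _el_short(0x0002, 0x0003, b"UI", sop_instance_uid.encode()),
            _el_short(0x0002, 0x0010, b"UI", _EXPLICIT_VR_LE.encode()),
            _el_short(0x0002, 0x0012, b"UI", b"1.2.826.0.1.3680043.9.7435"),
        ]
    )
    offsets = _ds(*(spacing[2] * k for k in range(nz)))
    dataset = b"".join(
        [
            _el_short(0x0008, 0x0016, b"UI", _RTDOSE_SOP_CLASS.encode()),
            _el_short(0x0008, 0x0018, b"UI", sop_instance_uid.encode()),
            _el_short(0x0008, 0x0060, b"CS", b"RTDOSE"),
            _el_short(0x0020, 0x0032, b"DS", _ds(*origin)),
            _el_short(0x0020, 0x0037, b"DS", _ds(1, 0, 0, 0, 1, 0)),
            _el_short(0x0028, 0x0002, b"US", struct.pack("<H", 1)),
            _el_short(0x0028, 0x0004, b"CS", b"MONOCHROME2"),
            _el_short(0x0028, 0x0008, b"IS", str(nz).encode()),
            _el_short(0x0028, 0x0010, b"US", struct.pack("<H", ny)),
            _el_short(0x0028, 0x0011, b"US", struct.pack("<H", nx)),
            _el_short(0x0028, 0x0030, b"DS", _ds(spacing[1], spacing[0])),
            _el_short(0x0028, 0x0100, b"US", struct.pack("<H", 32)),
            _el_short(0x0028, 0x0101, b"US", struct.pack("<H", 32)),
            _el_short(0x0028, 0x0102, b"US", struct.pack("<H", 31)),
            _el_short(0x0028, 0x0103, b"US", struct.pack("<H", 0)),
            _el_short(0x3004, 0x0002, b"CS", b"GY"),
            _el_short(0x3004, 0x0004, b"CS", b"PHYSICAL"),
            _el_short(0x3004, 0x000A, b"CS", b"PLAN"),
            _el_short(0x3004, 0x000C, b"DS", offsets),
            _el_short(0x3004, 0x000E, b"DS", f"{scaling:.16e}".encode()),
            _el_short(0x7FE0, 0x0010, b"OW", pixel_data),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(b"\x00" * 128 + b"DICM")
        fh.write(
            struct.pack("<HH2sH", 0x0002, 0x0000, b"UL", 4)
            + struct.pack("<I", len(meta_body))
        )
        fh.write(meta_body)
        fh.write(dataset)
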