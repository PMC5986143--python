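"""Minimal MRC2014 reader/writer.

Covers the subset of the format this package needs: single-volume files in
mode 0 (int8), 1 (int16), 2 (float32) or 6 (uint16), little-endian, no
extended header on write (extended headers are skipped on read). Data are
stored C-contiguous with x fastest, i.e. numpy shape (nz, ny, nx).
Cell dimensions are in Angstrom per the standard; callers convert to nm.
"""

from __future__ import annotations

import struct
from pathlib import Path

import numpy as np

_HEADER_SIZE = 1024
_MODE_DTYPES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_DTYPE_MODES = {np.dtype(d): m for m, d in _MODE_DTYPES.items()}
# little-endian machine stamp per MRC2014
_MACHST_LE = b"\x44\x44\x00\x00"


class MRCFormatError(ValueError):
    """Raised when a file is not a readable MRC volume."""


def read_mrc(path) -> tuple[np.ndarray, float, np.ndarray]:
    """Read an MRC file.

    Returns (data with shape (nz, ny, nx), voxel size in Angstrom,
    origin in Angstrom as a 3-vector in (z, y, x) order).
    """
    path = Path(path)
    raw = path.read_bytes()
    if len(raw) < _HEADER_SIZE:
        raise MRCFormatError(f"{path}: file shorter than MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    mx, my, mz = struct.unpack_from("<3i", raw, 28)
    xlen, ylen, zlen = struct.unpack_from("<3f", raw, 40)
    nsymbt = struct.unpack_from("<i", raw, 92)[0]
    ox, oy, oz = struct.unpack_from("<3f", raw, 196)
    map_id = raw[208:212]
    if map_id not in (b"MAP ", b"MAP\x00"):
        raise MRCFormatError(f"{path}: missing 'MAP ' identifier (not MRC2014?)")
    if mode not in _MODE_DTYPES:
        raise MRCFormatError(f"{path}: unsupported MRC mode {mode}")
    if min(nx, ny, nz) < 1:
        raise MRCFormatError(f"{path}: bad dimensions ({nx}, {ny}, {nz})")
    dtype = np.dtype(_MODE_DTYPES[mode]).newbyteorder("<")
    count = nx * ny * nz
    start = _HEADER_SIZE + max(nsymbt, 0)
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=start)
    if data.size != count:
        raise MRCFormatError(f"{path}: truncated data section")
    data = data.reshape(nz, ny, nx)
    # voxel size: sampling along x (isotropic files have equal sampling)
    sizes = []
    for length, m in ((xlen, mx), (ylen, my), (zlen, mz)):
        sizes.append(length / m if m > 0 else 0.0)
    voxel = sizes[0]
    if voxel <= 0:
        raise MRCFormatError(f"{path}: nonpositive voxel size in header")
    if not np.allclose(sizes, voxel, rtol=1e-4):
        raise MRCFormatError(f"{path}: anisotropic voxel size unsupported {sizes}")
    return np.ascontiguousarray(data), float(voxel), np.array([oz, oy, ox])


def write_mrc(path, data: np.ndarray, voxel_size_angstrom: float,
              origin_angstrom=(0.0, 0.0, 0.0)) -> None:
    """Write ``data`` (shape (nz, ny, nx)) as a single-volume MRC2014 file."""
    data = np.asarray(data)
    if data.ndim != 3:
        raise MRCFormatError(f"can only write 3D volumes, got ndim={data.ndim}")
    dt = np.dtype(data.dtype).newbyteorder("=")
    if dt not in _DTYPE_MODES:
        raise MRCFormatError(f"unsupported dtype for MRC: {data.dtype}")
    mode = _DTYPE_MODES[dt]
    nz, ny, nx = data.shape
    header = bytearray(_HEADER_SIZE)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 16, 0, 0, 0)          # nxstart..
    struct.pack_into("<3i", header, 28, nx, ny, nz)        # mx, my, mz
    struct.pack_into("<3f", header, 40, nx * voxel_size_angstrom,
                     ny * voxel_size_angstrom, nz * voxel_size_angstrom)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)  # cell angles
    struct.pack_into("<3i", header, 64, 1, 2, 3)           # mapc/mapr/maps
    finite = data[np.isfinite(data)]
    dmin = float(finite.min()) if finite.size else 0.0
    dmax = float(finite.max()) if finite.size else 0.0
    dmean = float(finite.mean()) if finite.size else 0.0
    struct.pack_into("<3f", header, 76, dmin, dmax, dmean)
    struct.pack_into("<2i", header, 88, 0, 0)              # ispg, nsymbt
    struct.pack_into("<i", header, 108, 20140)             # nversion
    oz, oy, ox = (float(v) for v in origin_angstrom)
    struct.pack_into("<3f", header, 196, ox, oy, oz)
    header[208:212] = b"MAP "
    header[212:216] = _MACHST_LE
    rms = float(finite.std()) if finite.size else 0.0
    struct.pack_into("<f", header, 216, rms)
    struct.pack_into("<i", header, 220, 0)                 # nlabl
    le = data.astype(np.dtype(data.dtype).newbyteorder("<"), copy=False)
    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(np.ascontiguousarray(le).tobytes())
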