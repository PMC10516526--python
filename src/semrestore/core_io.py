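"""Data model for FIB-SEM stacks and masks, plus TIFF/MRC readers and writers.

The central container is :class:`ImageStack`, a 3-D grayscale volume indexed
``(z, y, x)`` where ``z`` is the acquisition/milling axis.  All processing
modules operate on 64-bit floats; integer bit depths are recorded at load
time and restored when writing.

Supported on-disk formats are multipage TIFF (8/16-bit integer or 32-bit
float, via :mod:`tifffile`) and MRC2014 volumes (modes 0, 1, 2 and 6, read
and written directly — the format is a fixed 1024-byte header followed by a
raw C-ordered array).
"""

from __future__ import annotations

import os
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import tifffile

__all__ = [
    "ImageStack",
    "MissingMask",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "mask_from_slices",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A 3-D grayscale volume with optional voxel-size metadata.

    Parameters
    ----------
    data
        Array of intensities indexed ``(z, y, x)``.  A 2-D array is accepted
        and promoted to a single-slice stack.  Stored internally as float64.
    voxel_size
        Optional ``(dz, dy, dx)`` voxel size in nanometers.  Metadata only;
        no algorithm in this package depends on it.
    dtype_origin
        The integer dtype the data had on disk, used to restore the original
        bit depth when writing.  ``None`` means the data is natively float.
    """

    data: np.ndarray
    voxel_size: Optional[Tuple[float, float, float]] = None
    dtype_origin: Optional[np.dtype] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.data, dtype=np.float64)
        if arr.ndim == 2:
            arr = arr[np.newaxis, :, :]
        if arr.ndim != 3:
            raise ValueError(f"stack must be 2-D or 3-D, got ndim={arr.ndim}")
        if min(arr.shape) < 1:
            raise ValueError(f"all dimensions must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("stack contains non-finite intensities")
        self.data = arr
        if self.voxel_size is not None:
            self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if self.dtype_origin is not None:
            self.dtype_origin = np.dtype(self.dtype_origin)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_z(self) -> int:
        return self.data.shape[0]

    def copy(self) -> "ImageStack":
        return ImageStack(self.data.copy(), self.voxel_size, self.dtype_origin)

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """New stack with replaced voxel data, metadata carried over."""
        return ImageStack(data, self.voxel_size, self.dtype_origin)


@dataclass
class MissingMask:
    """Boolean volume marking voxels whose value is unknown / to be restored.

    True = missing.  Shape must equal the companion stack's shape.
    """

    mask: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.mask)
        if arr.ndim == 2:
            arr = arr[np.newaxis, :, :]
        if arr.ndim != 3:
            raise ValueError(f"mask must be 2-D or 3-D, got ndim={arr.ndim}")
        self.mask = arr.astype(bool)

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.mask.shape  # type: ignore[return-value]

    @property
    def n_missing(self) -> int:
        return int(self.mask.sum())

    def missing_slices(self) -> list[int]:
        """Indices of z-planes that are entirely masked."""
        full = self.mask.all(axis=(1, 2))
        return [int(z) for z in np.nonzero(full)[0]]


def mask_from_slices(
    shape: Tuple[int, int, int], slices: Sequence[int]
) -> MissingMask:
    """Mask marking entire z-planes as missing.

    Parameters
    ----------
    shape
        ``(n_z, n_y, n_x)`` of the companion stack.
    slices
        z-indices (0-based) of the planes to mark.  Must lie in
        ``[0, n_z)``.
    """
    n_z = int(shape[0])
    mask = np.zeros(shape, dtype=bool)
    for z in slices:
        z = int(z)
        if not 0 <= z < n_z:
            raise ValueError(f"slice index {z} out of range [0, {n_z})")
        mask[z] = True
    return MissingMask(mask)


# ---------------------------------------------------------------------------
# MRC2014 (modes 0, 1, 2, 6), little-endian
# ---------------------------------------------------------------------------

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}
_MRC_MODES_INV = {np.dtype(v): k for k, v in _MRC_MODES.items()}


def _read_mrc(path: Path) -> ImageStack:
    with open(path, "rb") as fh:
        header = fh.read(1024)
        if len(header) < 1024:
            raise IOError(f"cannot read stack from {path}: truncated MRC header")
        nx, ny, nz, mode = struct.unpack_from("<4i", header, 0)
        if header[208:212] not in (b"MAP ", b"MAP\x00"):
            raise IOError(f"cannot read stack from {path}: missing MRC 'MAP ' tag")
        if mode not in _MRC_MODES:
            raise IOError(f"cannot read stack from {path}: unsupported MRC mode {mode}")
        (nsymbt,) = struct.unpack_from("<i", header, 92)
        cella = struct.unpack_from("<3f", header, 40)
        fh.seek(1024 + nsymbt)
        dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
        count = nx * ny * nz
        raw = fh.read(count * dtype.itemsize)
        if len(raw) < count * dtype.itemsize:
            raise IOError(f"cannot read stack from {path}: truncated MRC data")
    arr = np.frombuffer(raw, dtype=dtype, count=count).reshape(nz, ny, nx)
    voxel = None
    if all(c > 0 for c in cella) and nx and ny and nz:
        # cella is in angstroms for the full cell; convert to nm per voxel
        voxel = (cella[2] / nz / 10.0, cella[1] / ny / 10.0, cella[0] / nx / 10.0)
    origin = None if mode == 2 else np.dtype(_MRC_MODES[mode])
    return ImageStack(arr.astype(np.float64), voxel_size=voxel, dtype_origin=origin)


def _write_mrc(stack: ImageStack, path: Path) -> None:
    arr = _to_disk_dtype(stack)
    if arr.dtype not in _MRC_MODES_INV:
        arr = arr.astype(np.float32)
    mode = _MRC_MODES_INV[arr.dtype]
    nz, ny, nx = arr.shape
    if stack.voxel_size is not None:
        dz, dy, dx = stack.voxel_size
        cella = (nx * dx * 10.0, ny * dy * 10.0, nz * dz * 10.0)
    else:
        cella = (float(nx), float(ny), float(nz))
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, nx, ny, nz, mode)
    struct.pack_into("<3i", header, 28, nx, ny, nz)  # mx, my, mz
    struct.pack_into("<3f", header, 40, *cella)
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)
    struct.pack_into("<3i", header, 64, 1, 2, 3)  # mapc, mapr, maps
    struct.pack_into(
        "<3f", header, 76, float(arr.min()), float(arr.max()), float(arr.mean())
    )
    struct.pack_into("<i", header, 88, 1)  # ispg: volume
    header[208:212] = b"MAP "
    header[212:216] = bytes([0x44, 0x44, 0, 0])  # little-endian machine stamp
    struct.pack_into("<f", header, 216, float(arr.std()))
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(np.ascontiguousarray(arr).tobytes())


# ---------------------------------------------------------------------------
# TIFF
# ---------------------------------------------------------------------------

def _read_tiff(path: Path) -> ImageStack:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    if arr.ndim != 3:
        raise IOError(
            f"cannot read stack from {path}: expected grayscale pages, "
            f"got array of ndim {arr.ndim}"
        )
    origin = np.dtype(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else None
    voxel = None
    try:
        with tifffile.TiffFile(path) as tf:
            tags = tf.pages[0].tags
            xres = tags.get("XResolution")
            yres = tags.get("YResolution")
            if xres and yres:
                xr = xres.value[0] / xres.value[1]
                yr = yres.value[0] / yres.value[1]
                if xr > 0 and yr > 0:
                    # resolution is pixels per unit; metadata only
                    voxel = (1.0, 1.0 / yr, 1.0 / xr)
    except Exception:
        voxel = None
    return ImageStack(arr.astype(np.float64), voxel_size=voxel, dtype_origin=origin)


def _to_disk_dtype(stack: ImageStack) -> np.ndarray:
    """Quantize to the recorded origin dtype, or float32 for native floats."""
    if stack.dtype_origin is not None and np.issubdtype(
        stack.dtype_origin, np.integer
    ):
        info = np.iinfo(stack.dtype_origin)
        return np.clip(np.rint(stack.data), info.min, info.max).astype(
            stack.dtype_origin
        )
    return stack.data.astype(np.float32)


def _write_tiff(stack: ImageStack, path: Path) -> None:
    # explicit photometric: 3- or 4-page stacks must not be guessed as RGB
    tifffile.imwrite(path, _to_disk_dtype(stack), photometric="minisblack")


# ---------------------------------------------------------------------------
# public readers / writers
# ---------------------------------------------------------------------------

_MRC_EXT = {".mrc", ".rec", ".st", ".map"}
_TIFF_EXT = {".tif", ".tiff"}


def _infer_format(path: Path) -> str:
    ext = path.suffix.lower()
    if ext in _MRC_EXT:
        return "mrc"
    if ext in _TIFF_EXT:
        return "tiff"
    # sniff: MRC carries 'MAP ' at offset 208
    try:
        with open(path, "rb") as fh:
            head = fh.read(212)
        if len(head) >= 212 and head[208:212] in (b"MAP ", b"MAP\x00"):
            return "mrc"
    except OSError:
        pass
    return "tiff"


def read_stack(path: os.PathLike | str, format: str = "auto") -> ImageStack:
    """Read a 3-D grayscale volume from a multipage TIFF or MRC file.

    Returns the stack in ``(z, y, x)`` order with z the acquisition order.
    A single 2-D image is accepted as an ``n_z = 1`` stack.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read stack from {path}: file does not exist")
    fmt = format if format != "auto" else _infer_format(path)
    try:
        if fmt == "mrc":
            return _read_mrc(path)
        elif fmt == "tiff":
            return _read_tiff(path)
        raise ValueError(f"unknown format {format!r}")
    except IOError:
        raise
    except Exception as exc:  # tifffile raises a zoo of exceptions
        raise IOError(f"cannot read stack from {path}: {exc}") from exc


def write_stack(
    stack: ImageStack, path: os.PathLike | str, format: str = "auto"
) -> None:
    """Write a stack to disk as multipage TIFF or MRC.

    Float data is written as 32-bit float unless an integer origin bit depth
    is recorded on the stack, in which case values are rounded and clipped
    back to that depth.
    """
    path = Path(path)
    if not path.parent.exists():
        raise IOError(f"cannot write stack to {path}: parent directory missing")
    fmt = format
    if fmt == "auto":
        fmt = "mrc" if path.suffix.lower() in _MRC_EXT else "tiff"
    try:
        if fmt == "mrc":
            _write_mrc(stack, path)
        elif fmt == "tiff":
            _write_tiff(stack, path)
        else:
            raise ValueError(f"unknown format {format!r}")
    except (IOError, ValueError):
        raise
    except Exception as exc:
        raise IOError(f"cannot write stack to {path}: {exc}") from exc


def read_mask(path: os.PathLike | str) -> MissingMask:
    """Read a missing-voxel mask stored as an 8-bit (0/255) TIFF volume."""
    stack = read_stack(path, format="tiff")
    return MissingMask(stack.data > 0)


def write_mask(mask: MissingMask, path: os.PathLike | str) -> None:
    """Write a mask as an 8-bit 0/255 TIFF volume."""
    arr = (mask.mask.astype(np.uint8)) * 255
    tifffile.imwrite(Path(path), arr)
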