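"""Reading slice stacks, writing masks, label volumes and reports.

A *slice stack* is an ordered 3-D grayscale volume: axis 0 is the
physical slice axis, axes 1 and 2 are image rows and columns.  Supported
inputs are multi-page TIFF files, directories of equally shaped
single-channel images (ordered by filename), and directories of ESRF EDF
files via a minimal read-only parser (ASCII ``key = value ;`` header
inside braces, padded, then a raw binary payload; ``Dim_1``, ``Dim_2``,
``DataType`` and ``ByteOrder`` are honoured).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["SliceStack", "read_stack", "read_edf", "write_stack",
           "write_label_volume", "read_label_volume", "label_volume_from_islets"]

_IMAGE_SUFFIXES = {".tif", ".tiff", ".png"}

#: EDF DataType header values -> numpy dtype characters
_EDF_DTYPES = {
    "unsignedbyte": "u1",
    "signedbyte": "i1",
    "unsignedshort": "u2",
    "signedshort": "i2",
    "unsignedinteger": "u4",
    "signedinteger": "i4",
    "unsignedlong": "u4",
    "signedlong": "i4",
    "float": "f4",
    "floatvalue": "f4",
    "double": "f8",
    "doublevalue": "f8",
}


@dataclass
class SliceStack:
    """An ordered 3-D grayscale volume with a physical voxel pitch (µm)."""

    voxels: np.ndarray
    voxel_pitch_um: float = 7.8

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"stack must be 3-D, got shape {self.voxels.shape}")
        if self.voxel_pitch_um <= 0:
            raise ValueError("voxel_pitch_um must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple:
        return self.voxels.shape


def read_edf(path) -> np.ndarray:
    """Read one image from a minimal ESRF EDF file."""
    raw = Path(path).read_bytes()
    start = raw.index(b"{")
    end = raw.index(b"}", start)
    header = raw[start + 1:end].decode("ascii", errors="replace")
    meta = {}
    for item in header.split(";"):
        if "=" in item:
            key, _, val = item.partition("=")
            meta[key.strip().lower()] = val.strip()
    try:
        dim1 = int(meta["dim_1"])  # fast axis = columns
        dim2 = int(meta["dim_2"])  # slow axis = rows
        dtype_name = meta["datatype"].lower()
    except KeyError as exc:
        raise ValueError(f"EDF header of {path} lacks required key {exc}") from exc
    if dtype_name not in _EDF_DTYPES:
        raise ValueError(f"unsupported EDF DataType {meta['datatype']!r}")
    order = "<" if meta.get("byteorder", "LowByteFirst").lower() == "lowbytefirst" else ">"
    dtype = np.dtype(order + _EDF_DTYPES[dtype_name])
    # single-image file: the payload is the last dim1*dim2 items; this
    # tolerates both 512-padded and unpadded header blocks
    n = dim1 * dim2
    payload_off = len(raw) - n * dtype.itemsize
    if payload_off <= end:
        raise ValueError(f"EDF payload of {path} truncated")
    data = np.frombuffer(raw, dtype=dtype, count=n, offset=payload_off)
    return data.reshape(dim2, dim1)


def _read_single(path: Path) -> np.ndarray:
    if path.suffix.lower() == ".edf":
        return read_edf(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        img = tifffile.imread(path)
    else:
        img = np.asarray(iio.imread(path))
    if img.ndim == 3 and img.shape[-1] in (3, 4):
        raise ValueError(f"{path} is not single-channel")
    return img


def read_stack(path, pitch: float = 7.8) -> SliceStack:
    """Read a slice stack from a multi-page TIFF or an image directory.

    Directory entries are ordered lexicographically by filename, which is
    the slice order.  Intensities are preserved exactly as stored.
    """
    path = Path(path)
    if path.is_file():
        voxels = tifffile.imread(path)
        if voxels.ndim == 2:
            voxels = voxels[None]
        if voxels.ndim != 3:
            raise ValueError(f"{path}: expected a stack of 2-D pages")
        return SliceStack(voxels, pitch)
    if not path.is_dir():
        raise FileNotFoundError(path)
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in _IMAGE_SUFFIXES | {".edf"})
    if not files:
        raise ValueError(f"no readable slices in {path}")
    slices = [_read_single(p) for p in files]
    shapes = {s.shape for s in slices}
    if len(shapes) > 1:
        raise ValueError(f"slices in {path} have mixed shapes: {sorted(shapes)}")
    return SliceStack(np.stack(slices), pitch)


def write_stack(path, voxels: np.ndarray) -> None:
    """Write a 3-D array as a multi-page TIFF."""
    tifffile.imwrite(path, np.asarray(voxels), photometric="minisblack")


def label_volume_from_islets(islets, shape) -> np.ndarray:
    """Rasterise stitched 3-D islets into an integer label volume.

    Background is 0; islet k (1-based, in list order) paints label k.
    Overlapping voxel sets are an integrity error.
    """
    vol = np.zeros(shape, dtype=np.int32)
    for label, islet in enumerate(islets, start=1):
        for comp in islet.components:
            for (r, c) in comp.pixel_set:
                if vol[comp.slice_index, r, c] != 0:
                    raise ValueError(
                        f"voxel ({comp.slice_index},{r},{c}) claimed by islets "
                        f"{vol[comp.slice_index, r, c]} and {label}")
                vol[comp.slice_index, r, c] = label
    return vol


def write_label_volume(islets, shape, path) -> np.ndarray:
    """Write an integer-labelled TIFF volume for a list of stitched islets."""
    vol = label_volume_from_islets(islets, shape)
    tifffile.imwrite(path, vol, photometric="minisblack")
    return vol


def read_label_volume(path) -> np.ndarray:
    vol = tifffile.imread(path)
    if vol.ndim == 2:
        vol = vol[None]
    return vol
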