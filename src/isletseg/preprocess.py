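"""Contrast enhancement and patch cropping / re-assembly.

The pipeline enhances whole slices with CLAHE, crops training images
into overlapping patches, tiles test images into non-overlapping patches
and pieces per-patch predictions back into a full-resolution map.  A
2048x2048 slice tiles into 16x16 patches of side 128.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import exposure

__all__ = ["PatchSet", "apply_clahe", "extract_training_patches",
           "tile_test_patches", "stitch_predictions"]


@dataclass
class PatchSet:
    """Patches cut from one source image plus their top-left anchors.

    ``source_shape`` is the original (rows, cols); ``padded_shape`` is
    the mirror-padded shape the origins refer to (equal to
    ``source_shape`` when no padding was needed).
    """

    patches: list
    origins: list
    source_shape: tuple
    padded_shape: tuple = None

    def __post_init__(self):
        if self.padded_shape is None:
            self.padded_shape = tuple(self.source_shape)
        if len(self.patches) != len(self.origins):
            raise ValueError("patches and origins must pair up")

    def __len__(self):
        return len(self.patches)


def apply_clahe(image: np.ndarray, clip_limit: float = 0.01,
                tile_grid: tuple = (8, 8)) -> np.ndarray:
    """Contrast-limited adaptive histogram equalisation of one slice.

    ``clip_limit`` is the normalised clipping limit in (0, 1];
    ``tile_grid`` is the number of contextual tiles per axis.  Integer
    inputs come back in their own dtype range; float inputs come back
    in [0, 1].
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D single-channel image, got ndim={image.ndim}")
    if np.ptp(image) == 0:
        return image.copy()  # nothing to redistribute
    kernel = (max(1, image.shape[0] // tile_grid[0]),
              max(1, image.shape[1] // tile_grid[1]))
    out = exposure.equalize_adapthist(image, kernel_size=kernel,
                                      clip_limit=clip_limit)
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        return (out * info.max).astype(image.dtype)
    return out.astype(image.dtype, copy=False)


def _grid_anchors(extent: int, patch: int, stride: int) -> list:
    """Regular stride grid plus a final anchor flush with the border."""
    anchors = list(range(0, extent - patch + 1, stride))
    last = extent - patch
    if anchors[-1] != last:
        anchors.append(last)
    return anchors


def extract_training_patches(image: np.ndarray, mask: np.ndarray,
                             patch_size: int = 128, stride: int = 64):
    """Cut aligned, overlapping image/mask patch pairs for training.

    Returns ``(image_patchset, mask_patchset)`` sharing identical
    origins, so ``patches[i]`` of both were cut at the same anchor.
    """
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image {image.shape} and mask {mask.shape} differ")
    if image.shape[0] < patch_size or image.shape[1] < patch_size:
        raise ValueError(
            f"image {image.shape} smaller than patch size {patch_size}")
    if stride >= patch_size:
        raise ValueError("stride must be smaller than patch_size (overlap required)")
    rows = _grid_anchors(image.shape[0], patch_size, stride)
    cols = _grid_anchors(image.shape[1], patch_size, stride)
    img_patches, mask_patches, origins = [], [], []
    for r in rows:
        for c in cols:
            img_patches.append(image[r:r + patch_size, c:c + patch_size])
            mask_patches.append(mask[r:r + patch_size, c:c + patch_size])
            origins.append((r, c))
    return (PatchSet(img_patches, list(origins), image.shape),
            PatchSet(mask_patches, list(origins), image.shape))


def tile_test_patches(image: np.ndarray, patch_size: int = 128) -> PatchSet:
    """Tile a test image into non-overlapping patches.

    Sides that are not multiples of ``patch_size`` are mirror-padded on
    the right/bottom; the recorded ``source_shape`` lets
    :func:`stitch_predictions` crop the result back.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    pad_r = (-image.shape[0]) % patch_size
    pad_c = (-image.shape[1]) % patch_size
    padded = image
    if pad_r or pad_c:
        padded = np.pad(image, ((0, pad_r), (0, pad_c)), mode="reflect")
    patches, origins = [], []
    for r in range(0, padded.shape[0], patch_size):
        for c in range(0, padded.shape[1], patch_size):
            patches.append(padded[r:r + patch_size, c:c + patch_size])
            origins.append((r, c))
    return PatchSet(patches, origins, image.shape, padded.shape)


def stitch_predictions(patch_set: PatchSet) -> np.ndarray:
    """Piece non-overlapping patch predictions back into one map.

    Each output pixel takes the value of the unique patch covering it;
    gaps or overlaps in the tiling are an error.  If the source was
    padded for tiling, the stitched map is cropped back to
    ``source_shape``.
    """
    if not patch_set.patches:
        raise ValueError("empty patch set")
    out = np.full(patch_set.padded_shape, np.nan,
                  dtype=np.asarray(patch_set.patches[0]).dtype
                  if np.issubdtype(np.asarray(patch_set.patches[0]).dtype, np.floating)
                  else np.float64)
    covered = np.zeros(patch_set.padded_shape, dtype=bool)
    for patch, (r, c) in zip(patch_set.patches, patch_set.origins):
        patch = np.asarray(patch)
        h, w = patch.shape
        if r + h > out.shape[0] or c + w > out.shape[1]:
            raise ValueError(f"patch at {(r, c)} exceeds {out.shape}")
        if covered[r:r + h, c:c + w].any():
            raise ValueError(f"patch at {(r, c)} overlaps a previous patch")
        out[r:r + h, c:c + w] = patch
        covered[r:r + h, c:c + w] = True
    if not covered.all():
        raise ValueError("tiling leaves uncovered pixels")
    sr, sc = patch_set.source_shape
    return out[:sr, :sc]
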