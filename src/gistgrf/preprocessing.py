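"""Breast masking, orientation and cropping of raw mammograms.

The preprocessing contract is: read a grayscale mammogram (DICOM or TIFF),
flip right-sided views so every image has the chest wall on the left,
threshold to a binary breast mask keeping only the largest connected
component (which removes detached corner labels and markers but retains the
pectoral muscle, deliberately), and crop image and mask to the tight
bounding box of the breast.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from skimage import measure

__all__ = [
    "MammogramImage",
    "BreastMask",
    "make_mask",
    "orient_left",
    "crop_to_breast",
    "read_tiff",
    "write_tiff",
    "read_dicom",
    "write_sidecar",
]

DEFAULT_THRESHOLD = 100  # on the 8-bit display scale

VIEWS = ("CC", "MLO")
LATERALITIES = ("L", "R")


@dataclass
class MammogramImage:
    """A single-view grayscale mammogram with acquisition metadata."""

    pixels: np.ndarray
    case_id: str
    view: str
    laterality: str
    bit_depth: int = 8
    oriented: bool = False

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D array")
        if min(self.pixels.shape) < 1:
            raise ValueError("image must have at least one pixel per axis")
        if self.view not in VIEWS:
            raise ValueError(f"view must be one of {VIEWS}, got {self.view!r}")
        if self.laterality not in LATERALITIES:
            raise ValueError(
                f"laterality must be one of {LATERALITIES}, got {self.laterality!r}"
            )
        if self.pixels.min() < 0:
            raise ValueError("pixel values must be non-negative")
        if self.pixels.max() >= 2**self.bit_depth:
            raise ValueError(f"pixel values exceed {self.bit_depth}-bit range")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class BreastMask:
    """Binary breast mask aligned with an image; single connected component."""

    mask: np.ndarray
    threshold_used: int

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask has no true pixels")


def _auto_threshold(bit_depth: int) -> int:
    # the canonical threshold of 100 presumes 8-bit display values
    return DEFAULT_THRESHOLD * 2 ** (bit_depth - 8)


def make_mask(image: MammogramImage, threshold: int | None = None) -> BreastMask:
    """Threshold the image and keep the largest 8-connected component.

    The default threshold is 100 on the 8-bit scale, auto-scaled by
    ``2**(bit_depth-8)`` for deeper images. Detached bright artifacts (corner
    labels, markers) fall into smaller components and are discarded; pectoral
    muscle connected to the breast is kept.
    """
    thr = _auto_threshold(image.bit_depth) if threshold is None else int(threshold)
    if not 0 <= thr < 2**image.bit_depth:
        raise ValueError(f"threshold {thr} outside {image.bit_depth}-bit range")
    binary = image.pixels > thr
    if not binary.any():
        raise ValueError(
            f"no pixel above threshold {thr}; pass an explicit lower threshold"
        )
    labels = measure.label(binary, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0  # background
    keep = counts.argmax()
    return BreastMask(mask=labels == keep, threshold_used=thr)


def orient_left(
    image: MammogramImage, mask: BreastMask | None = None
) -> MammogramImage | tuple[MammogramImage, BreastMask]:
    """Flip right-sided views left-right so the chest wall sits on the left.

    Left-sided views pass through unchanged. If a mask is supplied it is
    flipped alongside the image and both are returned.
    """
    if image.laterality == "R":
        flipped = replace(image, pixels=image.pixels[:, ::-1].copy(), oriented=True)
        if mask is not None:
            return flipped, BreastMask(mask.mask[:, ::-1].copy(), mask.threshold_used)
        return flipped
    out = replace(image, oriented=True)
    if mask is not None:
        return out, mask
    return out


def crop_to_breast(
    image: MammogramImage, mask: BreastMask
) -> tuple[MammogramImage, BreastMask, tuple[int, int, int, int]]:
    """Crop image and mask to the tight bounding box of mask-true pixels.

    Returns the cropped pair plus the half-open box ``(r0, r1, c0, c1)`` in
    the input coordinate frame.
    """
    if mask.mask.shape != image.pixels.shape:
        raise ValueError("mask and image shapes differ")
    rows = np.flatnonzero(mask.mask.any(axis=1))
    cols = np.flatnonzero(mask.mask.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    cropped = replace(image, pixels=image.pixels[r0:r1, c0:c1].copy())
    cmask = BreastMask(mask.mask[r0:r1, c0:c1].copy(), mask.threshold_used)
    return cropped, cmask, (r0, r1, c0, c1)


def _bit_depth_of(arr: np.ndarray) -> int:
    if arr.dtype == np.uint8:
        return 8
    if arr.dtype == np.uint16:
        return 16
    raise ValueError(f"unsupported pixel dtype {arr.dtype}")


def read_tiff(path, case_id: str, view: str, laterality: str) -> MammogramImage:
    import tifffile

    arr = tifffile.imread(str(path))
    return MammogramImage(arr, case_id, view, laterality, bit_depth=_bit_depth_of(arr))


def write_tiff(path, image: MammogramImage) -> None:
    import tifffile

    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    tifffile.imwrite(str(path), image.pixels.astype(dtype))


def read_dicom(path, case_id: str, view: str, laterality: str) -> MammogramImage:
    """Read a grayscale DICOM; MONOCHROME1 is inverted to MONOCHROME2 polarity."""
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array
    bits = int(getattr(ds, "BitsStored", 8 if arr.dtype == np.uint8 else 16))
    if getattr(ds, "PhotometricInterpretation", "MONOCHROME2") == "MONOCHROME1":
        arr = (2**bits - 1) - arr
    return MammogramImage(arr, case_id, view, laterality, bit_depth=bits)


def write_sidecar(path, *, threshold_used: int, flipped: bool, crop_box) -> Path:
    """Record per-image preprocessing provenance next to the image."""
    out = Path(path)
    out.write_text(
        json.dumps(
            {
                "threshold_used": int(threshold_used),
                "flipped": bool(flipped),
                "crop_box": [int(v) for v in crop_box],
            },
            sort_keys=True,
        )
    )
    return out
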