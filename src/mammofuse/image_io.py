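"""Raster I/O and the normalized-[0,1] / raw-[Lmin,Lmax] pixel contract.

The S-curve transform is defined on normalized intensities r in [0, 1];
metrics (EME, AMBE, SD, entropy) are defined on the raw display scale
(0-255 for 8-bit sources).  :class:`GrayImage` carries an explicit
``range_tag`` so a stage can never silently receive pixels on the wrong
scale, plus the display bounds needed to undo the normalization.

Pixels are floating point throughout the pipeline; quantization to 8 bits
happens only in :func:`save_image` (round-half-up), so rounding error never
compounds between stages.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np

__all__ = [
    "GrayImage",
    "FormatError",
    "RangeStateError",
    "load_image",
    "save_image",
    "to_grayscale",
    "normalize",
    "denormalize",
]

# ITU-R BT.601 luma weights, the de-facto standard for 8-bit medical exports.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


class FormatError(ValueError):
    """Unreadable file or unsupported raster format."""


class RangeStateError(ValueError):
    """Operation applied to an image with the wrong range tag."""


@dataclass(frozen=True)
class GrayImage:
    """A 2-D intensity raster with an explicit value-range tag.

    Parameters
    ----------
    pixels
        Height x width float array.
    range_tag
        ``"raw"`` (pixels in ``[l_min, l_max]``) or ``"normalized"``
        (pixels in ``[0, 1]``).
    l_min, l_max
        Display range of the raw representation; carried through
        normalization so it can be undone exactly.
    """

    pixels: np.ndarray
    range_tag: str = "raw"
    l_min: float = 0.0
    l_max: float = 255.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2-D raster, got shape {px.shape}")
        if self.range_tag not in ("raw", "normalized"):
            raise ValueError(f"range_tag must be 'raw' or 'normalized', got {self.range_tag!r}")
        if not self.l_min < self.l_max:
            raise ValueError(f"l_min ({self.l_min}) must be < l_max ({self.l_max})")
        lo, hi = ((0.0, 1.0) if self.range_tag == "normalized" else (self.l_min, self.l_max))
        # tiny float slack so round-tripped values at the endpoints pass
        if px.min() < lo - 1e-9 or px.max() > hi + 1e-9:
            raise ValueError(
                f"{self.range_tag} image has pixels in [{px.min()}, {px.max()}], "
                f"outside [{lo}, {hi}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "GrayImage":
        """Same tag and display range, new pixel raster."""
        return replace(self, pixels=pixels)


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) array to a single luminance channel (BT.601).

    Achromatic pixels (R=G=B) map to their common channel value exactly
    because the luma weights sum to 1.
    """
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        return arr[..., :3] @ _LUMA_WEIGHTS
    raise FormatError(f"cannot interpret array of shape {arr.shape} as an image")


def load_image(path: str | os.PathLike, l_min: float = 0.0, l_max: float = 255.0) -> GrayImage:
    """Read a PGM/PNG/TIFF/JPEG raster as a raw-tagged grayscale image.

    RGB inputs are converted with BT.601 luma weights and floored to the
    integer grid (mirroring 8-bit grayscale export conventions).
    """
    try:
        arr = iio.imread(os.fspath(path))
    except Exception as exc:  # imageio raises many types for bad files
        raise FormatError(f"cannot read image file {os.fspath(path)!r}: {exc}") from exc
    if arr.size == 0:
        raise ValueError(f"zero-sized image in {os.fspath(path)!r}")
    if arr.ndim == 3:
        gray = np.floor(to_grayscale(arr))
    elif arr.ndim == 2:
        gray = np.asarray(arr, dtype=float)
    else:
        raise FormatError(f"unsupported image layout {arr.shape} in {os.fspath(path)!r}")
    return GrayImage(gray, range_tag="raw", l_min=l_min, l_max=l_max)


def save_image(img: GrayImage, path: str | os.PathLike) -> None:
    """Write an image as 8-bit grayscale; quantization happens here only.

    Normalized inputs are denormalized first.  Values are scaled to 0-255
    from ``[l_min, l_max]`` and rounded half-up.
    """
    if img.range_tag == "normalized":
        img = denormalize(img)
    scaled = (img.pixels - img.l_min) / (img.l_max - img.l_min) * 255.0
    quantized = np.floor(scaled + 0.5).clip(0, 255).astype(np.uint8)
    iio.imwrite(os.fspath(path), quantized)


def normalize(img: GrayImage) -> GrayImage:
    """Map raw pixels to [0, 1] by the display range: (p - l_min)/(l_max - l_min)."""
    if img.range_tag != "raw":
        raise RangeStateError("normalize expects a raw-tagged image")
    px = (img.pixels - img.l_min) / (img.l_max - img.l_min)
    return GrayImage(px, range_tag="normalized", l_min=img.l_min, l_max=img.l_max)


def denormalize(img: GrayImage) -> GrayImage:
    """Map normalized pixels back to the raw scale: l_min + p*(l_max - l_min).

    No integer quantization: the inverse of :func:`normalize` up to float
    round-off, so normalize∘denormalize is the identity.
    """
    if img.range_tag != "normalized":
        raise RangeStateError("denormalize expects a normalized-tagged image")
    px = img.l_min + img.pixels * (img.l_max - img.l_min)
    return GrayImage(px, range_tag="raw", l_min=img.l_min, l_max=img.l_max)
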