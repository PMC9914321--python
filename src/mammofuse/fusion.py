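"""Wavelet-domain fusion of the original and enhanced images.

Both images are decomposed with a one-level separable 2-D DWT into an
approximate sub-band (LL, the "AC" low-frequency content) and three
detail sub-bands (LH/HL/HH, the "DC" high-frequency content).
Corresponding coefficients are merged with the maximum selection rule,
F(i,j) = max(A(i,j), B(i,j)), and the fused sub-bands are reconstructed
with the inverse DWT.  The rationale: enhancement can erase diagnostic
features; selecting the stronger coefficient from either source retains
the salient structure of both.

The transform itself is PyWavelets; this module owns the sub-band
bookkeeping, the fusion rule and the shape/clamp contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .image_io import GrayImage

__all__ = ["SubbandSet", "dwt_decompose", "fuse_max", "idwt_reconstruct", "fuse_images"]

#: Boundary extension for the filter banks; symmetric (half-sample) padding
#: is the least artifact-prone choice for images.
DWT_MODE = "symmetric"

_DETAIL_KEYS = ("lh", "hl", "hh")


@dataclass(frozen=True)
class SubbandSet:
    """Wavelet coefficients: deepest-level LL/LH/HL/HH plus, for
    decompositions deeper than one level, the finer detail triples needed
    for exact reconstruction (ordered coarse to fine)."""

    ll: np.ndarray
    lh: np.ndarray
    hl: np.ndarray
    hh: np.ndarray
    wavelet_name: str
    level: int = 1
    finer_details: tuple = field(default=())

    def __post_init__(self) -> None:
        for name in _DETAIL_KEYS:
            band = getattr(self, name)
            if band.shape != self.ll.shape:
                raise ValueError(
                    f"sub-band {name} shape {band.shape} != ll shape {self.ll.shape}"
                )
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if len(self.finer_details) != self.level - 1:
            raise ValueError(
                f"level {self.level} requires {self.level - 1} finer detail triples, "
                f"got {len(self.finer_details)}"
            )

    def bands(self) -> dict[str, np.ndarray]:
        return {"ll": self.ll, "lh": self.lh, "hl": self.hl, "hh": self.hh}


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)


def _wavelet(name: str) -> pywt.Wavelet:
    try:
        return pywt.Wavelet(name)
    except ValueError as exc:
        raise ValueError(f"unknown wavelet {name!r}") from exc


def dwt_decompose(img, wavelet_name: str = "haar", level: int = 1) -> SubbandSet:
    """Separable 2-D DWT (default one level, the single AC/DC split).

    Uses perfect-reconstruction filter banks, so
    ``idwt_reconstruct(dwt_decompose(x), x.shape)`` recovers x to float
    precision at any level.
    """
    px = _pixels(img)
    if px.shape[0] < 2 or px.shape[1] < 2:
        raise ValueError(f"image {px.shape} too small for a 2-D DWT")
    wavelet = _wavelet(wavelet_name)
    coeffs = pywt.wavedec2(px, wavelet, mode=DWT_MODE, level=level)
    ll = coeffs[0]
    lh, hl, hh = coeffs[1]  # deepest-level details
    finer = tuple(coeffs[2:])  # coarse-to-fine remainder, empty for level 1
    return SubbandSet(ll=ll, lh=lh, hl=hl, hh=hh,
                      wavelet_name=wavelet_name, level=level, finer_details=finer)


def fuse_max(a: SubbandSet, b: SubbandSet, mode: str = "plain_max") -> SubbandSet:
    """Merge two sub-band sets coefficient-wise by the maximum rule.

    ``plain_max`` (default, the literal max-max rule): elementwise
    max(A, B) on every sub-band.  ``abs_max``: on the detail bands keep
    whichever coefficient has the larger magnitude, sign preserved
    (plain max on signed detail coefficients discards negative edges);
    LL still uses plain max.
    """
    if a.wavelet_name != b.wavelet_name or a.level != b.level:
        raise ValueError(
            f"cannot fuse {a.wavelet_name}/L{a.level} with {b.wavelet_name}/L{b.level}"
        )
    if a.ll.shape != b.ll.shape:
        raise ValueError(f"sub-band shape mismatch {a.ll.shape} vs {b.ll.shape}")
    if mode not in ("plain_max", "abs_max"):
        raise ValueError(f"unknown fusion mode {mode!r}")

    def merge_detail(ca: np.ndarray, cb: np.ndarray) -> np.ndarray:
        if mode == "plain_max":
            return np.maximum(ca, cb)
        return np.where(np.abs(ca) >= np.abs(cb), ca, cb)

    ll = np.maximum(a.ll, b.ll)
    details = {k: merge_detail(getattr(a, k), getattr(b, k)) for k in _DETAIL_KEYS}
    finer = tuple(
        tuple(merge_detail(da, db) for da, db in zip(ta, tb))
        for ta, tb in zip(a.finer_details, b.finer_details)
    )
    return SubbandSet(ll=ll, wavelet_name=a.wavelet_name, level=a.level,
                      finer_details=finer, **details)


def idwt_reconstruct(s: SubbandSet, target_shape: tuple[int, int]) -> np.ndarray:
    """Inverse transform, cropped to ``target_shape``.

    pywt pads odd-length signals up to even coefficient counts, so the
    inverse can overshoot the original size by one pixel per side; the
    crop restores the exact input dimensions.
    """
    wavelet = _wavelet(s.wavelet_name)
    coeffs = [s.ll, (s.lh, s.hl, s.hh), *s.finer_details]
    rec = pywt.waverec2(coeffs, wavelet, mode=DWT_MODE)
    return rec[: target_shape[0], : target_shape[1]]


def fuse_images(
    original: GrayImage,
    enhanced: GrayImage,
    wavelet_name: str = "haar",
    level: int = 1,
    mode: str = "plain_max",
) -> GrayImage:
    """Full fusion: decompose both, max-fuse, reconstruct, clamp.

    Both inputs must be raw-tagged on the same display scale; the output
    is clamped back into [l_min, l_max] and keeps the input shape.
    """
    if original.range_tag != "raw" or enhanced.range_tag != "raw":
        raise ValueError("fuse_images expects raw-tagged images")
    if original.shape != enhanced.shape:
        raise ValueError(f"shape mismatch {original.shape} vs {enhanced.shape}")
    if (original.l_min, original.l_max) != (enhanced.l_min, enhanced.l_max):
        raise ValueError("inputs are on different display scales")

    sa = dwt_decompose(original, wavelet_name, level)
    sb = dwt_decompose(enhanced, wavelet_name, level)
    fused = idwt_reconstruct(fuse_max(sa, sb, mode), original.shape)
    fused = np.clip(fused, original.l_min, original.l_max)
    return original.with_pixels(fused)
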