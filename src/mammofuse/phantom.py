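"""Reproducible mammogram-like synthetic test images.

Real screening mammograms are low-contrast rasters: a smooth, slowly
varying fibroglandular background, faint lesion masses a few percent
above their surround, occasional bright microcalcification specks only
1-3 pixels across, and acquisition noise.  The phantom emulates exactly
those ingredients — low-pass-filtered Gaussian noise for the tissue
field, additive Gaussian-profile blobs for lesions, impulse specks for
microcalcifications, i.i.d. Gaussian pixel noise — so every pipeline
stage can be exercised and regression-tested without downloading any
clinical database.  It makes no claim to anatomical realism or X-ray
physics.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .image_io import GrayImage

__all__ = ["PhantomSpec", "generate_phantom", "low_contrast_spec"]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic breast image (8-bit raw scale).

    ``tissue_smoothness`` is the correlation length, in pixels, of the
    background field; ``tissue_amplitude`` its intensity swing.
    ``lesion_contrast`` is the additive peak intensity of the Gaussian
    blobs; microcalcifications are specks ``microcalc_contrast`` above
    the local background.
    """

    height: int = 128
    width: int = 128
    background_level: float = 120.0
    tissue_smoothness: float = 12.0
    tissue_amplitude: float = 20.0
    n_lesions: int = 3
    lesion_contrast: float = 25.0
    lesion_radius: tuple[float, float] = (6.0, 14.0)
    n_microcalcs: int = 8
    microcalc_contrast: float = 80.0
    noise_sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError("phantom dimensions must be positive")
        if not 0 <= self.background_level <= 255:
            raise ValueError("background_level must lie in [0, 255]")
        if self.tissue_smoothness <= 0:
            raise ValueError("tissue_smoothness must be > 0")
        if self.n_lesions < 0 or self.n_microcalcs < 0:
            raise ValueError("object counts must be non-negative")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.lesion_radius[1] >= min(self.height, self.width):
            raise ValueError("lesion radius exceeds image size")


def low_contrast_spec(**overrides) -> PhantomSpec:
    """Preset squeezing the dynamic range into roughly [90, 140].

    Imitates poorly acquired, low-entropy screening images: a narrow
    tissue swing, faint lesions and dim specks.
    """
    base = PhantomSpec(
        background_level=115.0,
        tissue_amplitude=8.0,
        lesion_contrast=10.0,
        microcalc_contrast=20.0,
        noise_sigma=1.5,
    )
    return replace(base, **overrides)


def generate_phantom(spec: PhantomSpec) -> tuple[GrayImage, dict]:
    """Render the phantom and its ground-truth annotation.

    Returns a raw-tagged 8-bit-scale image (float pixels, clamped to
    [0, 255]) and a dict with lesion centres/radii and microcalcification
    coordinates.  Identical spec (including seed) gives bitwise-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width

    # smooth tissue background: low-pass-filtered white noise, rescaled to
    # the requested amplitude around background_level
    field = rng.standard_normal((h, w))
    field = gaussian_filter(field, sigma=spec.tissue_smoothness, mode="reflect")
    span = field.max() - field.min()
    if span > 0 and spec.tissue_amplitude > 0:
        field = (field - field.min()) / span - 0.5
        img = spec.background_level + spec.tissue_amplitude * field
    else:
        img = np.full((h, w), spec.background_level, dtype=float)

    yy, xx = np.mgrid[0:h, 0:w]
    lesions = []
    for _ in range(spec.n_lesions):
        r = rng.uniform(*spec.lesion_radius)
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        img += spec.lesion_contrast * np.exp(
            -((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * (r / 2.0) ** 2)
        )
        lesions.append({"y": float(cy), "x": float(cx), "radius": float(r)})

    microcalcs = []
    for _ in range(spec.n_microcalcs):
        cy = int(rng.integers(1, max(h - 1, 2)))
        cx = int(rng.integers(1, max(w - 1, 2)))
        size = int(rng.integers(1, 4))  # 1-3 pixel specks
        img[cy:cy + size, cx:cx + size] += spec.microcalc_contrast
        microcalcs.append({"y": cy, "x": cx, "size": size})

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=(h, w))

    img = np.clip(img, 0.0, 255.0)
    annotation = {
        "spec": asdict(spec),
        "lesions": lesions,
        "microcalcs": microcalcs,
    }
    return GrayImage(img, range_tag="raw", l_min=0.0, l_max=255.0), annotation
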