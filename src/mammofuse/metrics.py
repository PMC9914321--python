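"""Enhancement and fusion quality measures: EME, AMBE, entropy, SD, IQI.

All metrics operate on the raw display scale (0-255 for 8-bit sources);
computing them on normalized [0, 1] data would change the EME/SD/AMBE
scales.  EME is the block-contrast measure used as the swarm optimizer's
fitness; AMBE quantifies brightness preservation against the original;
the IQI is the Wang-Bovik universal image quality index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .image_io import GrayImage

__all__ = ["EMEConfig", "MetricsReport", "eme", "ambe", "entropy", "std_dev", "iqi"]


@dataclass(frozen=True)
class EMEConfig:
    """Block geometry and the floor that keeps log(I_max/I_min) finite.

    Blocks are non-overlapping ``block_h`` x ``block_w`` windows (default
    3 x 3); trailing partial blocks are dropped rather than padded, since
    padding fabricates contrast at the borders.  ``epsilon`` (8-bit units)
    floors I_min; a block whose I_max is itself below epsilon contributes 0.
    """

    block_h: int = 3
    block_w: int = 3
    epsilon: float = 1.0

    def __post_init__(self) -> None:
        if self.block_h < 1 or self.block_w < 1:
            raise ValueError("block dimensions must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")


@dataclass(frozen=True)
class MetricsReport:
    """Per-image quality summary; reference-based fields are None without one."""

    entropy_bits: float
    eme: float
    sd: float
    ambe: float | None = None
    iqi: float | None = None

    def as_dict(self) -> dict:
        return {
            "E": self.entropy_bits,
            "EME": self.eme,
            "SD": self.sd,
            "AMBE": self.ambe,
            "IQI": self.iqi,
        }


def _pixels(img) -> np.ndarray:
    return img.pixels if isinstance(img, GrayImage) else np.asarray(img, dtype=float)


def eme(img, cfg: EMEConfig = EMEConfig()) -> float:
    """Measure of enhancement: mean over non-overlapping blocks of
    20*log10(I_max / max(I_min, epsilon)).

    Larger values mean stronger local contrast; a constant image scores 0.
    """
    px = _pixels(img)
    h, w = px.shape
    bh, bw = cfg.block_h, cfg.block_w
    nb_y, nb_x = h // bh, w // bw
    if nb_y < 1 or nb_x < 1:
        raise ValueError(f"image {h}x{w} smaller than one {bh}x{bw} block")
    blocks = px[: nb_y * bh, : nb_x * bw].reshape(nb_y, bh, nb_x, bw)
    bmax = blocks.max(axis=(1, 3))
    bmin = np.maximum(blocks.min(axis=(1, 3)), cfg.epsilon)
    ratio = np.where(bmax < cfg.epsilon, 1.0, bmax / bmin)  # dark block -> 0 dB
    return float(np.mean(20.0 * np.log10(ratio)))


def ambe(reference, processed) -> float:
    """Absolute mean brightness error |mean(ref) - mean(proc)|; symmetric."""
    a, b = _pixels(reference), _pixels(processed)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    return float(abs(a.mean() - b.mean()))


def entropy(img, levels: int = 256) -> float:
    """Shannon entropy (bits) of the quantized gray-level histogram.

    Raw 0-255 pixels are binned to ``levels`` integer levels; the result
    lies in [0, log2(levels)].
    """
    px = _pixels(img)
    counts = np.bincount(
        np.clip(np.round(px).astype(int), 0, levels - 1).ravel(), minlength=levels
    )
    p = counts[counts > 0] / px.size
    return float(-np.sum(p * np.log2(p)))


def std_dev(img) -> float:
    """Population standard deviation (divide by N) of all pixels."""
    return float(np.std(_pixels(img)))


def iqi(candidate, reference, window: int = 8) -> float:
    """Wang-Bovik universal image quality index, in [-1, 1].

    Per sliding ``window`` x ``window`` patch (stride 1):

        Q = 4 * sigma_xy * mean_x * mean_y
            / ((sigma_x^2 + sigma_y^2) * (mean_x^2 + mean_y^2))

    averaged over all patches where the denominator is nonzero.  Combines
    loss of correlation, luminance distortion and contrast distortion;
    1 means structurally identical.
    """
    x, y = _pixels(candidate), _pixels(reference)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch {x.shape} vs {y.shape}")
    if window > min(x.shape):
        raise ValueError(f"window {window} exceeds image of shape {x.shape}")

    n = window * window
    xw = sliding_window_view(x, (window, window)).reshape(-1, n)
    yw = sliding_window_view(y, (window, window)).reshape(-1, n)
    mx, my = xw.mean(axis=1), yw.mean(axis=1)
    vx = xw.var(axis=1)
    vy = yw.var(axis=1)
    cov = (xw * yw).mean(axis=1) - mx * my
    denom = (vx + vy) * (mx ** 2 + my ** 2)
    valid = denom > 0
    if not valid.any():
        raise ValueError("IQI undefined: every window has zero denominator")
    q = 4.0 * cov[valid] * mx[valid] * my[valid] / denom[valid]
    return float(q.mean())


def full_report(img, reference=None, eme_cfg: EMEConfig = EMEConfig(),
                iqi_window: int = 8) -> MetricsReport:
    """All metrics for one raw-scale image, reference-based ones if given."""
    return MetricsReport(
        entropy_bits=entropy(img),
        eme=eme(img, eme_cfg),
        sd=std_dev(img),
        ambe=None if reference is None else ambe(reference, img),
        iqi=None if reference is None else iqi(img, reference, iqi_window),
    )
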