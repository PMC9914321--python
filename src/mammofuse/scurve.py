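"""Sigmoid (S-curve) gray-level transform, global and tiled.

The mapping of a normalized intensity r is

    s(r) = alpha + (beta - alpha) / (1 + exp(-(r - gamma) / delta))

a logistic curve running from ~alpha (at r << gamma) to ~beta (at
r >> gamma), centred at gamma with width delta.  With the reference
constants (alpha = 0.9642, beta = 8.594e-4, gamma = 0.4962,
delta = 0.07598) beta < alpha, so the printed mapping is DECREASING,
i.e. an intensity-inverting contrast stretch; ``SCurveParams.inverted()``
swaps alpha and beta for the increasing orientation.

Local application divides the image into a k x k grid of tiles,
renormalizes each tile to [0, 1], applies the sigmoid, and restores the
tile's original span; optional CLAHE-style bilinear blending between the
four nearest tile mappings removes seams.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .image_io import GrayImage, RangeStateError

__all__ = ["SCurveParams", "TileSpec", "s_curve_value", "apply_global", "apply_local"]


@dataclass(frozen=True)
class SCurveParams:
    """Constants of the sigmoid gray-level mapping.

    Defaults are the reference hand-tuned values; ``alpha`` and ``beta``
    are the ones the swarm optimizer re-tunes per image.
    """

    alpha: float = 0.9642
    beta: float = 8.594e-4
    gamma: float = 0.4962
    delta: float = 0.07598

    def __post_init__(self) -> None:
        if self.delta <= 0:
            raise ValueError(f"delta must be > 0, got {self.delta}")
        if self.alpha == self.beta:
            raise ValueError("alpha == beta makes the transform constant")

    def inverted(self) -> "SCurveParams":
        """Swap alpha and beta, flipping the curve's orientation."""
        return replace(self, alpha=self.beta, beta=self.alpha)

    def with_tuned(self, alpha: float, beta: float) -> "SCurveParams":
        """Substitute optimizer-tuned asymptote constants."""
        return replace(self, alpha=float(alpha), beta=float(beta))


@dataclass(frozen=True)
class TileSpec:
    """k x k grid of tiles for local application (k=1 degenerates to global)."""

    k: int = 8

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"tile grid size must be >= 1, got {self.k}")


def s_curve_value(r, p: SCurveParams):
    """Evaluate the sigmoid mapping, clamped to [0, 1].

    Accepts scalars or arrays.  At r = gamma the value is exactly
    (alpha + beta)/2, and s(gamma+d) + s(gamma-d) = alpha + beta
    (point symmetry about the midpoint).
    """
    r = np.asarray(r, dtype=float)
    s = p.alpha + (p.beta - p.alpha) / (1.0 + np.exp(-(r - p.gamma) / p.delta))
    out = np.clip(s, 0.0, 1.0)
    return out if out.ndim else float(out)


def apply_global(img: GrayImage, p: SCurveParams) -> GrayImage:
    """Apply the sigmoid elementwise to a whole normalized image."""
    if img.range_tag != "normalized":
        raise RangeStateError("apply_global expects a normalized image")
    return img.with_pixels(s_curve_value(img.pixels, p))


def _tile_edges(n: int, k: int) -> np.ndarray:
    """k+1 tile boundaries covering [0, n] (ceil division for edge tiles)."""
    return np.round(np.linspace(0, n, k + 1)).astype(int)


def _tile_map(tile: np.ndarray, p: SCurveParams, renorm: bool) -> np.ndarray:
    """Renormalize a tile to [0,1], apply the sigmoid, restore its span.

    A constant tile (max == min) passes through unchanged: it carries no
    contrast to stretch.
    """
    tmin, tmax = tile.min(), tile.max()
    if renorm:
        if tmax == tmin:
            return tile.copy()
        t = (tile - tmin) / (tmax - tmin)
        return tmin + s_curve_value(t, p) * (tmax - tmin)
    return s_curve_value(tile, p)


def apply_local(
    img: GrayImage,
    p: SCurveParams,
    tiles: TileSpec = TileSpec(),
    blend: bool = True,
    renormalize_tiles: bool = True,
) -> GrayImage:
    """Apply the sigmoid per tile of a k x k grid.

    With ``blend`` on, each pixel's output is bilinearly interpolated
    between the mappings of the four nearest tiles (the CLAHE
    interpolation scheme), which removes tile-boundary seams.  With
    ``renormalize_tiles`` off the sigmoid acts on the raw normalized
    values inside each tile instead of the tile-stretched ones.
    """
    if img.range_tag != "normalized":
        raise RangeStateError("apply_local expects a normalized image")
    h, w = img.shape
    k = tiles.k
    if k > min(h, w):
        raise ValueError(f"tile grid {k}x{k} exceeds image of shape {h}x{w}")

    ye = _tile_edges(h, k)
    xe = _tile_edges(w, k)
    px = img.pixels

    if not blend:
        out = np.empty_like(px)
        for i in range(k):
            for j in range(k):
                sl = (slice(ye[i], ye[i + 1]), slice(xe[j], xe[j + 1]))
                out[sl] = _tile_map(px[sl], p, renormalize_tiles)
        return img.with_pixels(np.clip(out, 0.0, 1.0))

    # Per-tile affine renormalization stats; a constant tile maps identically.
    tmin = np.empty((k, k))
    tmax = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            block = px[ye[i]:ye[i + 1], xe[j]:xe[j + 1]]
            tmin[i, j], tmax[i, j] = block.min(), block.max()

    yc = (ye[:-1] + ye[1:]) / 2.0  # tile centres
    xc = (xe[:-1] + xe[1:]) / 2.0
    yy = np.arange(h, dtype=float)
    xx = np.arange(w, dtype=float)
    # fractional tile coordinate of each pixel relative to tile centres,
    # clamped so border pixels extrapolate from the outermost tiles
    fy = np.clip(np.interp(yy, yc, np.arange(k)), 0, k - 1)
    fx = np.clip(np.interp(xx, xc, np.arange(k)), 0, k - 1)
    i0 = np.minimum(fy.astype(int), k - 2) if k > 1 else np.zeros(h, dtype=int)
    j0 = np.minimum(fx.astype(int), k - 2) if k > 1 else np.zeros(w, dtype=int)
    wy = (fy - i0)[:, None] if k > 1 else np.zeros((h, 1))
    wx = (fx - j0)[None, :] if k > 1 else np.zeros((1, w))

    out = np.zeros_like(px)
    # accumulate the four bilinear corners; each pass gathers the relevant
    # tile's min/max per pixel and applies that tile's mapping vectorized
    for di in (0, 1):
        for dj in (0, 1):
            wgt = (wy if di else 1 - wy) * (wx if dj else 1 - wx)
            ii = np.minimum(i0 + di, k - 1)
            jj = np.minimum(j0 + dj, k - 1)
            if renormalize_tiles:
                lo = tmin[ii[:, None], jj[None, :]]
                hi = tmax[ii[:, None], jj[None, :]]
                span = hi - lo
                safe = np.where(span > 0, span, 1.0)
                t = np.clip((px - lo) / safe, 0.0, 1.0)
                mapped = np.where(span > 0, lo + s_curve_value(t, p) * span, px)
            else:
                mapped = s_curve_value(px, p)
            out += wgt * mapped
    return img.with_pixels(np.clip(out, 0.0, 1.0))
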