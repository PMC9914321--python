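"""End-to-end orchestration: load → normalize → (PSO-)enhance → fuse → report.

The pipeline mirrors the enhancement/fusion block diagram: the source
image is normalized, enhanced with the S-curve (with alpha/beta tuned by
the swarm when enabled), denormalized, fused with the original in the
wavelet domain, and every stage is scored with the metric suite.  Report
rows carry a stable machine-parseable schema:

    image, stage, E, EME, AMBE, SD, IQI, alpha, beta, seed
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .image_io import GrayImage, load_image, normalize, denormalize, save_image
from .metrics import EMEConfig, full_report
from .pso import PSOConfig, PSOResult, optimize
from .scurve import SCurveParams, TileSpec, apply_global, apply_local
from .fusion import fuse_images

__all__ = ["PipelineConfig", "EnhanceOutcome", "FuseOutcome",
           "run_enhance", "run_fuse", "run_batch"]

logger = logging.getLogger("mammofuse")

REPORT_COLUMNS = ["image", "stage", "E", "EME", "AMBE", "SD", "IQI",
                  "alpha", "beta", "seed"]


@dataclass(frozen=True)
class PipelineConfig:
    """All stage settings in one place; sub-configs validate themselves."""

    scurve: SCurveParams = SCurveParams()
    tiles: TileSpec = TileSpec()
    local: bool = True
    blend: bool = True
    pso: PSOConfig = PSOConfig()
    pso_enabled: bool = True
    wavelet: str = "haar"
    fusion_level: int = 1
    fusion_mode: str = "plain_max"
    eme_cfg: EMEConfig = EMEConfig()
    iqi_window: int = 8


@dataclass(frozen=True)
class EnhanceOutcome:
    enhanced: GrayImage  # raw scale
    params: SCurveParams
    pso_result: PSOResult | None
    rows: list = field(default_factory=list)


@dataclass(frozen=True)
class FuseOutcome:
    enhanced: GrayImage
    fused: GrayImage
    params: SCurveParams
    pso_result: PSOResult | None
    rows: list = field(default_factory=list)


def _row(name: str, stage: str, report, params: SCurveParams, seed) -> dict:
    return {
        "image": name, "stage": stage,
        "E": report.entropy_bits, "EME": report.eme, "AMBE": report.ambe,
        "SD": report.sd, "IQI": report.iqi,
        "alpha": params.alpha, "beta": params.beta, "seed": seed,
    }


def _enhance_image(original: GrayImage, cfg: PipelineConfig):
    """Normalize, optionally tune (alpha, beta), apply the S-curve, denormalize."""
    norm = normalize(original)
    tiles = cfg.tiles if cfg.local else None
    result: PSOResult | None = None
    params = cfg.scurve
    if cfg.pso_enabled:
        result = optimize(norm, base=cfg.scurve, cfg=cfg.pso,
                          tiles=tiles, blend=cfg.blend, eme_cfg=cfg.eme_cfg)
        params = result.best_params
        logger.debug("PSO gBest trace: %s", result.gbest_trace)
    if tiles is None or tiles.k == 1:
        enhanced_norm = apply_global(norm, params)
    else:
        enhanced_norm = apply_local(norm, params, tiles, blend=cfg.blend)
    return denormalize(enhanced_norm), params, result


def run_enhance(cfg: PipelineConfig, image: GrayImage | str, name: str = "image"
                ) -> EnhanceOutcome:
    """Enhance one image (path or loaded) and report original/enhanced metrics."""
    original = load_image(image) if isinstance(image, str) else image
    enhanced, params, result = _enhance_image(original, cfg)
    seed = cfg.pso.seed if cfg.pso_enabled else None
    rows = [
        _row(name, "original", full_report(original, eme_cfg=cfg.eme_cfg), params, seed),
        _row(name, "enhanced",
             full_report(enhanced, reference=original, eme_cfg=cfg.eme_cfg,
                         iqi_window=cfg.iqi_window),
             params, seed),
    ]
    logger.info("enhanced %s: EME %.4f -> %.4f", name, rows[0]["EME"], rows[1]["EME"])
    return EnhanceOutcome(enhanced=enhanced, params=params, pso_result=result, rows=rows)


def run_fuse(cfg: PipelineConfig, image: GrayImage | str, name: str = "image"
             ) -> FuseOutcome:
    """Full pipeline: enhance, fuse with the original, score all three stages."""
    original = load_image(image) if isinstance(image, str) else image
    outcome = run_enhance(cfg, original, name)
    fused = fuse_images(original, outcome.enhanced,
                        wavelet_name=cfg.wavelet, level=cfg.fusion_level,
                        mode=cfg.fusion_mode)
    seed = cfg.pso.seed if cfg.pso_enabled else None
    rows = outcome.rows + [
        _row(name, "fused",
             full_report(fused, reference=original, eme_cfg=cfg.eme_cfg,
                         iqi_window=cfg.iqi_window),
             outcome.params, seed),
    ]
    logger.info("fused %s: EME %.4f", name, rows[-1]["EME"])
    return FuseOutcome(enhanced=outcome.enhanced, fused=fused,
                       params=outcome.params, pso_result=outcome.pso_result,
                       rows=rows)


def rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    """Stable-schema report table (one row per image per stage)."""
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def run_batch(cfg: PipelineConfig, paths: list[str], out_dir: str | None = None,
              fuse: bool = True) -> pd.DataFrame:
    """Process many images; a failing image is logged and skipped."""
    import os

    all_rows: list[dict] = []
    for path in paths:
        name = os.path.basename(path)
        try:
            if fuse:
                outcome = run_fuse(cfg, path, name)
                artifacts = {"enhanced": outcome.enhanced, "fused": outcome.fused}
            else:
                outcome = run_enhance(cfg, path, name)
                artifacts = {"enhanced": outcome.enhanced}
            all_rows.extend(outcome.rows)
            if out_dir is not None:
                stem = os.path.splitext(name)[0]
                for stage, img in artifacts.items():
                    save_image(img, os.path.join(out_dir, f"{stem}_{stage}.png"))
        except Exception as exc:
            logger.error("skipping %s: %s", path, exc)
    return rows_to_frame(all_rows)
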