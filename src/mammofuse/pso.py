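"""Particle swarm tuning of the sigmoid asymptote constants (alpha, beta).

Standard global-best PSO: each particle carries a position x over the
tuned parameters, a velocity v, and its personal best xBest; the swarm
shares a global best gBest.  Per iteration

    v' = w*v + c1*r1*(xBest - x) + c2*r2*(gBest - x)      (r1, r2 ~ U[0,1])
    x' = x + v'

with velocities capped at +-v_max and positions clipped into bounds
(absorbing walls: a clipped component's velocity is zeroed).  The fitness
is the EME of the image enhanced with the candidate constants, so the
swarm drives the S-curve toward maximum block contrast.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .image_io import GrayImage, denormalize
from .metrics import EMEConfig, eme
from .scurve import SCurveParams, TileSpec, apply_global, apply_local

__all__ = ["PSOConfig", "Particle", "PSOResult", "fitness", "optimize"]

DEFAULT_BOUNDS = ((0.5, 1.0), (0.0, 0.5))  # alpha, beta search intervals


@dataclass(frozen=True)
class PSOConfig:
    """Swarm settings.

    Swarm size 30 and 10 iterations are the reference operating point;
    inertia w = 0.7 with c1 = c2 = 1.5 is a common convergent setting.
    ``v_max_frac`` caps each velocity component at that fraction of its
    parameter's bound width.  ``elitist_init`` seeds one particle at the
    base (hand-tuned) constants so the optimized fitness can never fall
    below the unoptimized one.
    """

    swarm_size: int = 30
    iterations: int = 10
    w: float = 0.7
    c1: float = 1.5
    c2: float = 1.5
    bounds: tuple[tuple[float, float], ...] = DEFAULT_BOUNDS
    v_max_frac: float = 0.2
    seed: int = 0
    elitist_init: bool = True

    def __post_init__(self) -> None:
        if self.swarm_size < 2:
            raise ValueError("swarm_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.c1 <= 0 or self.c2 <= 0:
            raise ValueError("c1 and c2 must be > 0")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"degenerate bound [{lo}, {hi}]")
        if self.v_max_frac <= 0:
            raise ValueError("v_max_frac must be > 0")

    @property
    def lows(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    @property
    def highs(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])

    @property
    def v_max(self) -> np.ndarray:
        return self.v_max_frac * (self.highs - self.lows)


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    personal_best_position: np.ndarray
    personal_best_fitness: float


@dataclass(frozen=True)
class PSOResult:
    """Outcome of a swarm run: tuned constants, fitness, and the gBest trace.

    ``gbest_trace`` has one entry for the initial evaluation plus one per
    update iteration and is non-decreasing by construction.
    """

    best_params: SCurveParams
    best_fitness: float
    best_position: np.ndarray
    gbest_trace: tuple[float, ...]
    seed: int


def update_velocity(p: Particle, gbest: np.ndarray, cfg: PSOConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """Inertia + cognitive pull to xBest + social pull to gBest, capped."""
    if p.position.shape != np.shape(gbest):
        raise ValueError("dimension mismatch between particle and gbest")
    r1 = rng.uniform(size=p.position.shape)
    r2 = rng.uniform(size=p.position.shape)
    v = (cfg.w * p.velocity
         + cfg.c1 * r1 * (p.personal_best_position - p.position)
         + cfg.c2 * r2 * (gbest - p.position))
    return np.clip(v, -cfg.v_max, cfg.v_max)


def update_position(p: Particle, cfg: PSOConfig) -> np.ndarray:
    """Unit-time-step move x' = x + v, clipped into bounds.

    A component that hits a bound has its velocity zeroed (absorbing
    walls), so the swarm does not ring against the box.
    """
    x = p.position + p.velocity
    clipped = np.clip(x, cfg.lows, cfg.highs)
    p.velocity = np.where(clipped == x, p.velocity, 0.0)
    return clipped


def fitness(
    img: GrayImage,
    candidate: Sequence[float],
    base: SCurveParams = SCurveParams(),
    tiles: TileSpec | None = TileSpec(),
    blend: bool = True,
    eme_cfg: EMEConfig = EMEConfig(),
) -> float:
    """EME of the image enhanced with candidate (alpha, beta) constants.

    The candidate is substituted into ``base``, the S-curve applied
    (locally over ``tiles`` by default, globally if ``tiles`` is None),
    the result denormalized to the raw scale, and its EME returned.
    """
    alpha, beta = float(candidate[0]), float(candidate[1])
    if alpha == beta:
        return -np.inf  # constant transform: worst possible
    p = base.with_tuned(alpha, beta)
    if tiles is None or tiles.k == 1:
        enhanced = apply_global(img, p)
    else:
        enhanced = apply_local(img, p, tiles, blend=blend)
    return eme(denormalize(enhanced), eme_cfg)


def optimize(
    img: GrayImage | None,
    base: SCurveParams = SCurveParams(),
    cfg: PSOConfig = PSOConfig(),
    tiles: TileSpec | None = TileSpec(),
    blend: bool = True,
    eme_cfg: EMEConfig = EMEConfig(),
    fitness_fn: Callable[[np.ndarray], float] | None = None,
) -> PSOResult:
    """Run the swarm and return the best (alpha, beta) with its EME.

    Positions start uniform within bounds (seeded), velocities at zero;
    each iteration evaluates fitness, updates personal bests where a
    particle improved on itself, promotes the best personal best to gBest
    when it exceeds it, then moves the swarm.  Fully reproducible given
    ``cfg.seed``.  ``fitness_fn`` replaces the image fitness (test hook /
    custom objectives); it receives the position vector.
    """
    if fitness_fn is None:
        if img is None:
            raise ValueError("optimize needs an image or an explicit fitness_fn")
        if img.range_tag != "normalized":
            raise ValueError("optimize expects a normalized image")

        def fitness_fn(x: np.ndarray) -> float:
            return fitness(img, x, base, tiles, blend, eme_cfg)

    rng = np.random.default_rng(cfg.seed)
    dim = len(cfg.bounds)
    positions = rng.uniform(cfg.lows, cfg.highs, size=(cfg.swarm_size, dim))
    if cfg.elitist_init:
        elite = np.clip([base.alpha, base.beta][:dim], cfg.lows, cfg.highs)
        positions[0] = elite
    swarm = [
        Particle(
            position=positions[i].copy(),
            velocity=np.zeros(dim),
            personal_best_position=positions[i].copy(),
            personal_best_fitness=-np.inf,
        )
        for i in range(cfg.swarm_size)
    ]

    gbest_pos = swarm[0].position.copy()
    gbest_fit = -np.inf
    trace: list[float] = []

    def evaluate() -> None:
        nonlocal gbest_pos, gbest_fit
        for part in swarm:
            f = fitness_fn(part.position)
            if f > part.personal_best_fitness:
                part.personal_best_fitness = f
                part.personal_best_position = part.position.copy()
            if f > gbest_fit:
                gbest_fit = f
                gbest_pos = part.position.copy()

    evaluate()
    trace.append(gbest_fit)
    for _ in range(cfg.iterations):
        for part in swarm:
            part.velocity = update_velocity(part, gbest_pos, cfg, rng)
            part.position = update_position(part, cfg)
        evaluate()
        trace.append(gbest_fit)

    tuned = base.with_tuned(gbest_pos[0], gbest_pos[1]) if dim >= 2 else base
    return PSOResult(
        best_params=tuned,
        best_fitness=float(gbest_fit),
        best_position=gbest_pos,
        gbest_trace=tuple(trace),
        seed=cfg.seed,
    )
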