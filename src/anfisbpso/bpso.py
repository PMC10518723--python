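"""Binary particle swarm optimization with a sigmoid transfer function.

Particles live on {0,1}^d. Velocities follow the classical update

    v(t+1) = w * v(t) + c1 * r1 * (Pbest - x(t)) + c2 * r2 * (Gbest - x(t))

with r1, r2 drawn per particle per iteration; the sigmoid of each
velocity component is a bit-set probability, and each position bit is
set to 1 exactly when an independent uniform draw r3 falls strictly
below that probability. Fitness is minimized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SwarmConfig:
    """Swarm hyperparameters.

    The inertia weight decays linearly from ``w`` to ``w_final`` over
    ``max_iters`` (set them equal for a constant weight). ``v_clamp``
    bounds |velocity| so sigmoid probabilities cannot saturate
    irrecoverably; ``stop_patience`` stops the run after that many
    iterations without strict global-best improvement.
    """

    n_particles: int = 20
    dim: int = 8
    w: float = 0.9
    w_final: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    max_iters: int = 100
    seed: int = 0
    v_clamp: float = 6.0
    stop_patience: int = 25

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.dim < 1 or self.max_iters < 1:
            raise ValueError("n_particles, dim and max_iters must be >= 1")
        if min(self.w, self.w_final, self.c1, self.c2) < 0:
            raise ValueError("w, w_final, c1, c2 must be non-negative")


@dataclass
class SwarmState:
    """Positions, velocities and best-so-far bookkeeping."""

    x: np.ndarray  # (n_particles, dim) in {0,1}
    v: np.ndarray  # (n_particles, dim)
    pbest_x: np.ndarray
    pbest_f: np.ndarray
    gbest_x: np.ndarray = field(default=None)  # type: ignore[assignment]
    gbest_f: float = np.inf
    iter: int = 0


def sigmoid_transfer(v):
    """1 / (1 + exp(-v)); strictly increasing, maps velocity to a
    bit-set probability."""
    return 1.0 / (1.0 + np.exp(-np.asarray(v, dtype=float)))


def velocity_update(
    state: SwarmState, cfg: SwarmConfig, r1, r2, w: float | None = None
) -> np.ndarray:
    """Inertia + cognitive + social pull, clamped to [-v_clamp, v_clamp].

    ``r1``/``r2`` are per-particle scalars (or broadcastable arrays) in
    [0, 1].
    """
    w = cfg.w if w is None else w
    r1 = np.reshape(np.asarray(r1, dtype=float), (-1, 1))
    r2 = np.reshape(np.asarray(r2, dtype=float), (-1, 1))
    v = (
        w * state.v
        + cfg.c1 * r1 * (state.pbest_x - state.x)
        + cfg.c2 * r2 * (state.gbest_x - state.x)
    )
    return np.clip(v, -cfg.v_clamp, cfg.v_clamp)


def position_update(v: np.ndarray, r3: np.ndarray) -> np.ndarray:
    """Bit set to 1 iff r3 < sigmoid(v), strictly; per-dimension draws."""
    return (r3 < sigmoid_transfer(v)).astype(np.int8)


def _evaluate(fitness: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    f = float(fitness(x))
    if not np.isfinite(f):
        logger.warning("fitness returned non-finite value; treating as +inf")
        return np.inf
    return f


def optimize(
    fitness: Callable[[np.ndarray], float], cfg: SwarmConfig
) -> tuple[np.ndarray, float, np.ndarray]:
    """Seeded BPSO minimization of ``fitness`` over {0,1}^dim.

    Positions are initialized uniformly at random, velocities at zero.
    Personal/global bests update on strict improvement only (ties keep
    the incumbent). Returns (gbest position, gbest fitness, per-iteration
    gbest trace); the trace is non-increasing by construction.
    """
    rng = np.random.default_rng(cfg.seed)
    x = rng.integers(0, 2, size=(cfg.n_particles, cfg.dim)).astype(np.int8)
    state = SwarmState(
        x=x,
        v=np.zeros((cfg.n_particles, cfg.dim)),
        pbest_x=x.copy(),
        pbest_f=np.full(cfg.n_particles, np.inf),
    )
    trace = []
    stall = 0
    for t in range(cfg.max_iters):
        state.iter = t
        for i in range(cfg.n_particles):
            f = _evaluate(fitness, state.x[i])
            if f < state.pbest_f[i]:
                state.pbest_f[i] = f
                state.pbest_x[i] = state.x[i].copy()
        best = int(np.argmin(state.pbest_f))
        if state.pbest_f[best] < state.gbest_f or state.gbest_x is None:
            state.gbest_f = float(state.pbest_f[best])
            state.gbest_x = state.pbest_x[best].copy()
            stall = 0
        else:
            stall += 1
        trace.append(state.gbest_f)
        if stall >= cfg.stop_patience:
            break
        # linear inertia decay over the full budget
        frac = t / max(cfg.max_iters - 1, 1)
        w = cfg.w + (cfg.w_final - cfg.w) * frac
        r1 = rng.random(cfg.n_particles)
        r2 = rng.random(cfg.n_particles)
        state.v = velocity_update(state, cfg, r1, r2, w=w)
        r3 = rng.random((cfg.n_particles, cfg.dim))
        state.x = position_update(state.v, r3)
    return state.gbest_x, state.gbest_f, np.array(trace)
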