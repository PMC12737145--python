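"""Particle Swarm Optimization over mixed integer/continuous boxes.

Minimizes a black-box objective over a hyperparameter box with the classic
inertia-weight update

    v <- w·v + c1·r1·(p_best − x) + c2·r2·(g_best − x)
    x <- clamp(x + v)

Integer dimensions are searched on a continuous relaxation and rounded at
evaluation time; log-scale dimensions are searched in log space. The full
per-iteration p_best/g_best trace is retained so convergence can be plotted
and audited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = ["Dimension", "SearchSpace", "ParticleState", "PSOTrace", "PSOConfig",
           "init_swarm", "optimize"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Dimension:
    """One search dimension: a named integer or continuous interval."""

    name: str
    lower: float
    upper: float
    integer: bool = False
    log_scale: bool = False

    def __post_init__(self) -> None:
        if not self.lower < self.upper and not (self.integer and self.lower == self.upper):
            raise ValueError(f"dimension {self.name!r}: lower must be < upper")
        if self.integer:
            if self.lower != int(self.lower) or self.upper != int(self.upper):
                raise ValueError(f"integer dimension {self.name!r} needs integer bounds")
            if self.log_scale:
                raise ValueError(f"dimension {self.name!r}: integer+log unsupported")
        if self.log_scale and self.lower <= 0:
            raise ValueError(f"log dimension {self.name!r} needs positive bounds")

    # internal (continuous, possibly log) coordinates
    @property
    def _lo(self) -> float:
        return math.log(self.lower) if self.log_scale else self.lower

    @property
    def _hi(self) -> float:
        return math.log(self.upper) if self.log_scale else self.upper

    def decode(self, z: float) -> float | int:
        x = math.exp(z) if self.log_scale else z
        x = min(self.upper, max(self.lower, x))
        return int(round(x)) if self.integer else x


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of uniquely named dimensions."""

    dimensions: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        if not self.dimensions:
            raise ValueError("search space must have at least one dimension")
        names = [d.name for d in self.dimensions]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate dimension names: {names}")

    def __len__(self) -> int:
        return len(self.dimensions)

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([d._lo for d in self.dimensions])
        hi = np.array([d._hi for d in self.dimensions])
        return lo, hi

    def decode(self, z: np.ndarray) -> dict[str, float | int]:
        return {d.name: d.decode(float(z[i])) for i, d in enumerate(self.dimensions)}


@dataclass
class ParticleState:
    position: np.ndarray
    velocity: np.ndarray
    p_best_position: np.ndarray
    p_best_score: float


@dataclass
class PSOTrace:
    """Per-iteration p_best of every particle plus the running g_best.

    Row 0 records the state right after initial evaluation; row t the state
    after update iteration t.
    """

    p_best: list[list[float]] = field(default_factory=list)
    g_best: list[float] = field(default_factory=list)
    best_position: dict[str, float | int] | None = None

    def record(self, particles: Sequence[ParticleState], g_best_score: float) -> None:
        self.p_best.append([p.p_best_score for p in particles])
        self.g_best.append(g_best_score)

    def to_dict(self) -> dict:
        return {"p_best": self.p_best, "g_best": self.g_best,
                "best_position": self.best_position}


@dataclass(frozen=True)
class PSOConfig:
    """Swarm coefficients. Defaults: inertia 0.7, cognitive and social 1.5,
    velocity clamped at half the box range per dimension."""

    n_particles: int = 10
    n_iterations: int = 20
    inertia: float = 0.7
    cognitive: float = 1.5
    social: float = 1.5
    velocity_clamp: float = 0.5

    def __post_init__(self) -> None:
        if self.n_particles < 1 or self.n_iterations < 1:
            raise ValueError("n_particles and n_iterations must be >= 1")


def init_swarm(space: SearchSpace, n_particles: int, seed: int,
               velocity_clamp: float = 0.5) -> list[ParticleState]:
    """Uniform positions within bounds (log-uniform on log dims), velocities
    uniform in ±(range/2); reproducible under seed."""
    if n_particles < 1:
        raise ValueError("n_particles must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = space.bounds()
    span = hi - lo
    pos = rng.uniform(lo, hi, size=(n_particles, len(space)))
    vel = rng.uniform(-span / 2, span / 2, size=(n_particles, len(space)))
    vel *= 2 * velocity_clamp  # ±clamp·range
    return [
        ParticleState(position=pos[i].copy(), velocity=vel[i].copy(),
                      p_best_position=pos[i].copy(), p_best_score=math.inf)
        for i in range(n_particles)
    ]


def optimize(
    objective: Callable[[Mapping[str, float | int]], float],
    space: SearchSpace,
    config: PSOConfig = PSOConfig(),
    seed: int = 0,
) -> tuple[dict[str, float | int], float, PSOTrace]:
    """Minimize ``objective`` over ``space``; returns (best_position,
    best_score, trace).

    The objective receives the decoded position as a name->value mapping.
    Non-finite objective values are treated as +inf with a logged warning.
    The returned best_score is the minimum value the objective ever returned,
    and the trace's g_best sequence is non-increasing by construction.
    """
    rng = np.random.default_rng(seed)
    lo, hi = space.bounds()
    span = hi - lo
    vmax = config.velocity_clamp * span

    particles = init_swarm(space, config.n_particles, seed=int(rng.integers(2**31)),
                           velocity_clamp=config.velocity_clamp)

    def _eval(z: np.ndarray) -> float:
        val = float(objective(space.decode(z)))
        if not math.isfinite(val):
            log.warning("objective returned non-finite value %r at %s; using +inf",
                        val, space.decode(z))
            return math.inf
        return val

    g_best_score = math.inf
    g_best_pos = particles[0].position.copy()
    trace = PSOTrace()

    for p in particles:
        score = _eval(p.position)
        p.p_best_score = score
        if score < g_best_score:
            g_best_score, g_best_pos = score, p.position.copy()
    trace.record(particles, g_best_score)

    for _ in range(config.n_iterations):
        for p in particles:
            r1 = rng.random(len(space))
            r2 = rng.random(len(space))
            p.velocity = (
                config.inertia * p.velocity
                + config.cognitive * r1 * (p.p_best_position - p.position)
                + config.social * r2 * (g_best_pos - p.position)
            )
            np.clip(p.velocity, -vmax, vmax, out=p.velocity)
            p.position = np.clip(p.position + p.velocity, lo, hi)
            score = _eval(p.position)
            if score < p.p_best_score:
                p.p_best_score = score
                p.p_best_position = p.position.copy()
            if score < g_best_score:
                g_best_score, g_best_pos = score, p.position.copy()
        trace.record(particles, g_best_score)

    best = space.decode(g_best_pos)
    trace.best_position = best
    return best, g_best_score, trace
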