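"""Particle-swarm search over architecture genomes.

Standard global-best PSO on the unit hypercube.  Velocity update

    v' = w * v + c1 * r1 * (pbest - x) + c2 * r2 * (gbest - x)

with r1, r2 ~ U(0,1) drawn per particle per iteration (scalar by default,
matching the update rule's scalar notation; a per-coordinate variant is
available), followed by elementwise velocity clamping and the position update
``x' = x + v'``.  Positions are clipped back into [0, 1] — the decode rule's
precondition — and the velocity component of any clipped coordinate is
zeroed.  Fitness is minimized; ties keep the earlier incumbent so runs are
fully reproducible under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .search_space import GenomeLayout, random_genome

__all__ = ["SwarmConfig", "Particle", "SwarmState", "update_velocity", "update_position", "step", "run"]

logger = logging.getLogger(__name__)

WORST_FITNESS = 1.0


@dataclass(frozen=True)
class SwarmConfig:
    population_size: int = 5
    iterations: int = 40
    inertia_start: float = 0.9
    inertia_end: float = 0.4
    cognitive: float = 1.49445
    social: float = 1.49445
    velocity_clamp: float = 0.2
    stop_threshold: float = 0.0
    per_coordinate_r: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if self.velocity_clamp <= 0:
            raise ValueError("velocity_clamp must be > 0")

    def inertia_at(self, iteration: int) -> float:
        """Linearly decayed inertia weight over the iteration budget."""
        if self.iterations == 1:
            return self.inertia_start
        frac = iteration / (self.iterations - 1)
        return self.inertia_start + (self.inertia_end - self.inertia_start) * min(frac, 1.0)


@dataclass
class Particle:
    position: np.ndarray
    velocity: np.ndarray
    pbest_position: np.ndarray
    pbest_fitness: float = np.inf


@dataclass
class SwarmState:
    particles: list[Particle]
    gbest_position: np.ndarray | None = None
    gbest_fitness: float = np.inf
    history: list[float] = field(default_factory=list)
    iteration: int = 0
    evaluations: int = 0


def update_velocity(
    particle: Particle,
    gbest_position: np.ndarray,
    config: SwarmConfig,
    rng: np.random.Generator,
    inertia: float | None = None,
) -> np.ndarray:
    if particle.position.shape != gbest_position.shape:
        raise ValueError("position/gbest dimension mismatch")
    w = config.inertia_start if inertia is None else inertia
    shape = particle.position.shape if config.per_coordinate_r else ()
    r1 = rng.random(shape)
    r2 = rng.random(shape)
    v = (
        w * particle.velocity
        + config.cognitive * r1 * (particle.pbest_position - particle.position)
        + config.social * r2 * (gbest_position - particle.position)
    )
    return np.clip(v, -config.velocity_clamp, config.velocity_clamp)


def update_position(particle: Particle) -> None:
    """x' = x + v, clipped to [0,1]; clipped coordinates get zero velocity."""
    raw = particle.position + particle.velocity
    clipped = np.clip(raw, 0.0, 1.0)
    particle.velocity = np.where(raw == clipped, particle.velocity, 0.0)
    particle.position = clipped


def _evaluate(state: SwarmState, fitness_fn) -> None:
    for i, p in enumerate(state.particles):
        try:
            f = float(fitness_fn(p.position))
        except Exception:
            logger.exception("fitness evaluation failed for particle %d; assigning worst case", i)
            f = WORST_FITNESS
        state.evaluations += 1
        if f < p.pbest_fitness:  # strict: earlier incumbent wins ties
            p.pbest_fitness = f
            p.pbest_position = p.position.copy()
        if f < state.gbest_fitness:
            state.gbest_fitness = f
            state.gbest_position = p.position.copy()


def step(state: SwarmState, fitness_fn, config: SwarmConfig, rng: np.random.Generator) -> SwarmState:
    """One PSO iteration: evaluate, update bests, then move the swarm."""
    _evaluate(state, fitness_fn)
    state.history.append(state.gbest_fitness)
    inertia = config.inertia_at(state.iteration)
    for p in state.particles:
        p.velocity = update_velocity(p, state.gbest_position, config, rng, inertia)
        update_position(p)
    state.iteration += 1
    return state


def init_swarm(config: SwarmConfig, layout: GenomeLayout, rng: np.random.Generator) -> SwarmState:
    particles = []
    for _ in range(config.population_size):
        pos = random_genome(layout, rng)
        vel = rng.uniform(-config.velocity_clamp, config.velocity_clamp, layout.dimension)
        particles.append(Particle(pos, vel, pos.copy()))
    return SwarmState(particles)


def run(config: SwarmConfig, layout: GenomeLayout, fitness_fn) -> dict:
    """Full search: returns best genome, best fitness and convergence history.

    Stops after the iteration budget or as soon as the global best reaches
    ``stop_threshold``.  Identical seeds give identical trajectories.
    """
    rng = np.random.default_rng(config.seed)
    state = init_swarm(config, layout, rng)
    for _ in range(config.iterations):
        step(state, fitness_fn, config, rng)
        logger.info(
            "iteration %d: gbest fitness %.6f (%d evaluations)",
            state.iteration, state.gbest_fitness, state.evaluations,
        )
        if state.gbest_fitness <= config.stop_threshold:
            break
    return {
        "best_genome": state.gbest_position.copy(),
        "best_fitness": state.gbest_fitness,
        "history": list(state.history),
        "evaluations": state.evaluations,
        "state": state,
    }
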