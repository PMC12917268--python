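"""Sparrow-cougar hybrid metaheuristic for bounded continuous search.

A population of candidate solutions is split each iteration into
producers (the best-ranked fraction, which explore) and scroungers (the
rest, which follow the producers), after which a small randomly chosen
danger group makes an escape move.  The producer step hybridises the
sparrow-search alarm mechanism with a cougar-style velocity pull toward
the global best: under a calm alarm value the producer contracts
geometrically; under an alarmed one its new position is the average of
a noisy sparrow move and a velocity-driven cougar move.

The update rules are exposed as pure functions taking every random
draw explicitly, so unit tests can force draws and check the algebra
directly; the :class:`SparrowCougarOptimizer` wires them to a seeded
generator.  The optimizer is used both on benchmark surfaces and as
the gradient-free trainer of the BiLSTM classifier, where each
position is a flat weight vector and the score is the mean of
validation accuracy, sensitivity and specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil
from typing import Callable

import numpy as np

__all__ = [
    "OptimizerConfig",
    "Population",
    "OptimizeResult",
    "SparrowCougarOptimizer",
    "producer_position",
    "scrounger_position",
    "danger_position",
    "random_search",
    "sphere",
    "rosenbrock",
]


@dataclass(frozen=True)
class OptimizerConfig:
    """Search hyperparameters.

    population_size (e) rows of dimension k move inside ``bounds``;
    ``producer_fraction`` of them act as producers; ``safety_threshold``
    (R in [0.5, 1]) gates the alarm branch; ``cougar_constant`` (p1)
    scales the velocity pull; ``danger_fraction`` (SD) of rows make the
    escape move each iteration; ``alpha`` keeps the flat-fitness escape
    step finite.  ``orientation`` is "maximize" or "minimize".
    """

    dimension: int
    population_size: int = 30
    producer_fraction: float = 0.2
    safety_threshold: float = 0.8
    cougar_constant: float = 2.0
    danger_fraction: float = 0.15
    max_iterations: int = 100
    bounds: tuple[float, float] = (-5.0, 5.0)
    alpha: float = 1e-8
    seed: int = 0
    orientation: str = "maximize"
    target_score: float | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.dimension < 1:
            raise ValueError("dimension must be >= 1")
        if not 0.5 <= self.safety_threshold <= 1.0:
            raise ValueError("safety_threshold must lie in [0.5, 1]")
        if not 0.0 < self.danger_fraction < 1.0:
            raise ValueError("danger_fraction must lie in (0, 1)")
        n_producers = int(round(self.producer_fraction * self.population_size))
        if not 0 < n_producers < self.population_size:
            raise ValueError("producer_fraction must leave both producers and scroungers")
        if self.bounds[0] > self.bounds[1]:
            raise ValueError("bounds must satisfy low <= high")
        if self.orientation not in ("maximize", "minimize"):
            raise ValueError("orientation must be 'maximize' or 'minimize'")

    @property
    def n_producers(self) -> int:
        return int(round(self.producer_fraction * self.population_size))

    @property
    def n_danger(self) -> int:
        return ceil(self.danger_fraction * self.population_size)


@dataclass
class Population:
    """Mutable search state: positions, cougar velocities, raw scores."""

    positions: np.ndarray  # (e, k)
    velocities: np.ndarray  # (e, k)
    scores: np.ndarray  # (e,) raw objective values
    best_position: np.ndarray  # elitist best-so-far
    best_score: float
    worst_position: np.ndarray
    worst_score: float


@dataclass
class OptimizeResult:
    """Outcome of a run: elitist best and the per-iteration trace."""

    x: np.ndarray
    fun: float
    n_iterations: int
    trace: list[dict] = field(default_factory=list)

    @property
    def best_trace(self) -> np.ndarray:
        return np.array([row["best"] for row in self.trace])


# ---------------------------------------------------------------------------
# pure update rules (all random draws passed in explicitly)
# ---------------------------------------------------------------------------


def producer_position(
    position: np.ndarray,
    rank: int,
    config: OptimizerConfig,
    alarm: float,
    gamma: float,
    normal_draw: float,
    velocity: np.ndarray,
    q1: float,
    best_position: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Producer move; returns (new_position, new_velocity).

    Calm branch (alarm < safety threshold): elementwise geometric
    contraction position * exp(-rank / (gamma * i_max)).  Alarmed
    branch: velocity <- velocity + q1 * p1 * (best - position), then the
    average of the sparrow move (position + N * ones) and the cougar
    move (position + velocity).
    """
    position = np.asarray(position, dtype=np.float64)
    velocity = np.asarray(velocity, dtype=np.float64)
    if alarm < config.safety_threshold:
        new = position * np.exp(-rank / (gamma * config.max_iterations))
        return new, velocity.copy()
    new_velocity = velocity + q1 * config.cougar_constant * (best_position - position)
    sparrow_move = position + normal_draw * np.ones_like(position)
    cougar_move = position + new_velocity
    return 0.5 * sparrow_move + 0.5 * cougar_move, new_velocity


def scrounger_position(
    position: np.ndarray,
    rank: int,
    config: OptimizerConfig,
    gamma: float,
    normal_draws: np.ndarray,
    signs: np.ndarray,
    worst_position: np.ndarray,
    producer_pos: np.ndarray,
) -> np.ndarray:
    """Scrounger move for a row of rank > n_producers.

    Starving branch (rank > e/2): N * exp((worst - position) /
    (gamma * i_max)) elementwise, with N a per-coordinate normal draw.
    Following branch: producer + |position - producer| . Q+ . S with Q a
    row of +-1 signs, Q+ its Moore-Penrose pseudoinverse Q.T/k and S the
    all-ones row; the product collapses to producer + mean(|diff| * Q).
    """
    position = np.asarray(position, dtype=np.float64)
    if rank > config.population_size / 2:
        # exponent clamped to keep arithmetic finite; positions are
        # clipped to the bounds afterwards either way
        exponent = (worst_position - position) / (gamma * config.max_iterations)
        return normal_draws * np.exp(np.clip(exponent, -700.0, 700.0))
    diff = np.abs(position - producer_pos)
    k = position.size
    scalar = float(diff @ (signs / k))  # |diff| (1xk) . Q+ (kx1)
    return producer_pos + scalar * np.ones_like(position)


def danger_position(
    position: np.ndarray,
    score: float,
    config: OptimizerConfig,
    gamma: float,
    x_draw: float,
    best_position: np.ndarray,
    best_score: float,
    worst_position: np.ndarray,
    worst_score: float,
) -> np.ndarray:
    """Danger-group escape move (scores on the internal maximize scale).

    A row strictly worse than the best moves toward it:
    best + gamma * |position - best|.  A row at the best score takes a
    fitness-scaled escape step position + X * |position - worst| /
    ((score - worst_score) + alpha), large when fitness is flat.
    """
    position = np.asarray(position, dtype=np.float64)
    if score < best_score:
        return best_position + gamma * np.abs(position - best_position)
    denom = (score - worst_score) + config.alpha
    return position + x_draw * np.abs(position - worst_position) / denom


# ---------------------------------------------------------------------------
# driver
# ---------------------------------------------------------------------------


class SparrowCougarOptimizer:
    """Seed-deterministic driver wiring the update rules to an objective.

    The objective maps a position (1-D array of length ``dimension``) to
    a scalar.  Internally scores are kept on a maximize scale; elitism
    archives the best-so-far position, so the best trace is monotone.
    """

    def __init__(self, config: OptimizerConfig):
        self.config = config

    def _internal(self, raw: float) -> float:
        return raw if self.config.orientation == "maximize" else -raw

    def initialize(self, objective: Callable[[np.ndarray], float], rng: np.random.Generator) -> Population:
        cfg = self.config
        low, high = cfg.bounds
        positions = rng.uniform(low, high, size=(cfg.population_size, cfg.dimension))
        scores = np.array([float(objective(p)) for p in positions])
        internal = np.array([self._internal(s) for s in scores])
        best = int(np.argmax(internal))
        worst = int(np.argmin(internal))
        return Population(
            positions=positions,
            velocities=np.zeros_like(positions),
            scores=scores,
            best_position=positions[best].copy(),
            best_score=scores[best],
            worst_position=positions[worst].copy(),
            worst_score=scores[worst],
        )

    def run(self, objective: Callable[[np.ndarray], float]) -> OptimizeResult:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)
        pop = self.initialize(objective, rng)
        trace: list[dict] = [
            {"iteration": 0, "best": pop.best_score, "mean": float(np.mean(pop.scores))}
        ]

        for iteration in range(1, cfg.max_iterations + 1):
            internal = np.array([self._internal(s) for s in pop.scores])
            order = np.argsort(-internal)  # descending internal score
            alarm = rng.random()
            best_internal = self._internal(pop.best_score)
            worst_internal = float(np.min(internal))
            worst_row = int(np.argmin(internal))

            new_positions = pop.positions.copy()
            for j, row in enumerate(order[: cfg.n_producers]):
                gamma = 1.0 - rng.random()  # U(0, 1]
                new_positions[row], pop.velocities[row] = producer_position(
                    pop.positions[row],
                    rank=j + 1,
                    config=cfg,
                    alarm=alarm,
                    gamma=gamma,
                    normal_draw=float(rng.standard_normal()),
                    velocity=pop.velocities[row],
                    q1=rng.random(),
                    best_position=pop.best_position,
                )
            producer_pos = new_positions[order[0]]
            for j, row in enumerate(order[cfg.n_producers :], start=cfg.n_producers):
                gamma = 1.0 - rng.random()
                new_positions[row] = scrounger_position(
                    pop.positions[row],
                    rank=j + 1,
                    config=cfg,
                    gamma=gamma,
                    normal_draws=rng.standard_normal(cfg.dimension),
                    signs=rng.choice([-1.0, 1.0], size=cfg.dimension),
                    worst_position=pop.positions[worst_row],
                    producer_pos=producer_pos,
                )
            danger_rows = rng.choice(cfg.population_size, size=cfg.n_danger, replace=False)
            for row in danger_rows:
                gamma = rng.random()
                new_positions[row] = danger_position(
                    new_positions[row],
                    score=internal[row],
                    config=cfg,
                    gamma=gamma,
                    x_draw=rng.uniform(-1.0, 1.0),
                    best_position=pop.best_position,
                    best_score=best_internal,
                    worst_position=pop.positions[worst_row],
                    worst_score=worst_internal,
                )

            np.clip(new_positions, cfg.bounds[0], cfg.bounds[1], out=new_positions)
            pop.positions = new_positions
            pop.scores = np.array([float(objective(p)) for p in pop.positions])
            internal = np.array([self._internal(s) for s in pop.scores])

            # elitism: archive the best-so-far, reinject it over the worst row
            it_best = int(np.argmax(internal))
            if internal[it_best] > self._internal(pop.best_score):
                pop.best_position = pop.positions[it_best].copy()
                pop.best_score = pop.scores[it_best]
            it_worst = int(np.argmin(internal))
            pop.positions[it_worst] = pop.best_position
            pop.scores[it_worst] = pop.best_score
            if self._internal(pop.scores[it_worst]) < self._internal(pop.worst_score):
                pop.worst_position = pop.positions[it_worst].copy()
                pop.worst_score = pop.scores[it_worst]

            trace.append(
                {
                    "iteration": iteration,
                    "best": pop.best_score,
                    "mean": float(np.mean(pop.scores)),
                }
            )
            if cfg.target_score is not None and self._internal(pop.best_score) >= self._internal(
                cfg.target_score
            ):
                break

        return OptimizeResult(
            x=pop.best_position.copy(),
            fun=pop.best_score,
            n_iterations=trace[-1]["iteration"],
            trace=trace,
        )


def random_search(
    objective: Callable[[np.ndarray], float], config: OptimizerConfig
) -> OptimizeResult:
    """Equal-budget uniform random search baseline.

    Draws population_size * (max_iterations + 1) points — the same
    number of objective evaluations the metaheuristic spends — and keeps
    the best.
    """
    rng = np.random.default_rng(config.seed)
    low, high = config.bounds
    sign = 1.0 if config.orientation == "maximize" else -1.0
    best_x, best_raw = None, -np.inf
    trace = []
    for iteration in range(config.max_iterations + 1):
        points = rng.uniform(low, high, size=(config.population_size, config.dimension))
        scores = np.array([float(objective(p)) for p in points])
        it_best = int(np.argmax(sign * scores))
        if sign * scores[it_best] > best_raw:
            best_raw = sign * scores[it_best]
            best_x = points[it_best].copy()
        trace.append({"iteration": iteration, "best": sign * best_raw, "mean": float(scores.mean())})
    return OptimizeResult(x=best_x, fun=sign * best_raw, n_iterations=config.max_iterations, trace=trace)


def sphere(x: np.ndarray) -> float:
    """Sum of squares; global minimum 0 at the origin."""
    x = np.asarray(x, dtype=np.float64)
    return float(np.sum(x**2))


def rosenbrock(x: np.ndarray) -> float:
    """Rosenbrock valley; global minimum 0 at the all-ones point."""
    x = np.asarray(x, dtype=np.float64)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))
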