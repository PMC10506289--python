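"""Stochastic Exploration-Selection (ES) minimizer over six pose parameters.

The search space is the box of six pose parameters (three Euler rotations in
degrees, three translations in mm), discretized per axis into 2**10 levels.
An iteration has two phases:

* exploration — every individual takes one random move on the discretized
  neighborhood graph: a uniformly chosen axis, a log-uniform step of 1..r
  levels (r = that axis' exploration radius) in a random direction, clipped
  to the bounds. Moves are accepted unconditionally; diversity is restored
  by selection.
* selection — individuals are paired at random and the worse of each pair is
  replaced by a copy of the better one; the best-ever solution is re-inserted
  over the current worst (elitism), so the best fitness never increases.

The cost function is treated as a black box; candidates with non-finite cost
are rejected (the individual keeps its previous state). The whole run is
reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError
from .geometry import RigidTransform

__all__ = ["SearchBounds", "Population", "explore_step", "select_step", "es_optimize"]

N_LEVELS = 1024  # per-axis discretization of the parameter graph


@dataclass(frozen=True)
class SearchBounds:
    """Per-parameter box limits and exploration radii (in grid levels)."""

    lower: np.ndarray  # (6,) degrees / mm
    upper: np.ndarray  # (6,)
    radius: np.ndarray  # (6,) int, max exploration step in levels

    def __post_init__(self):
        lo = np.asarray(self.lower, dtype=float)
        up = np.asarray(self.upper, dtype=float)
        rad = np.asarray(self.radius, dtype=np.int64)
        if lo.shape != (6,) or up.shape != (6,) or rad.shape != (6,):
            raise ParameterError("bounds and radii must have 6 entries")
        if np.any(lo >= up):
            raise ParameterError("need lower < upper in every dimension")
        if np.any(rad < 0):
            raise ParameterError("exploration radii must be >= 0")
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", up)
        object.__setattr__(self, "radius", rad)

    @classmethod
    def around(
        cls,
        center: RigidTransform,
        rot_deg: float = 15.0,
        trans_mm: float = 15.0,
        radius: int = 256,
    ) -> "SearchBounds":
        """Symmetric box of +/- rot_deg / trans_mm around a center pose."""
        c = center.as_array()
        half = np.array([rot_deg] * 3 + [trans_mm] * 3, dtype=float)
        return cls(lower=c - half, upper=c + half,
                   radius=np.full(6, int(radius), dtype=np.int64))

    @property
    def center(self) -> RigidTransform:
        return RigidTransform.from_array((self.lower + self.upper) / 2.0)

    def to_levels(self, params: np.ndarray) -> np.ndarray:
        span = self.upper - self.lower
        lev = np.rint((params - self.lower) / span * (N_LEVELS - 1))
        return np.clip(lev, 0, N_LEVELS - 1).astype(np.int64)

    def from_levels(self, levels: np.ndarray) -> np.ndarray:
        span = self.upper - self.lower
        return self.lower + levels.astype(float) / (N_LEVELS - 1) * span

    def sample(self, rng: np.random.Generator) -> RigidTransform:
        levels = rng.integers(0, N_LEVELS, size=6)
        return RigidTransform.from_array(self.from_levels(levels))


@dataclass
class Population:
    """Candidate poses with their fitnesses; size is constant."""

    individuals: list  # list of [RigidTransform, float] pairs

    @property
    def size(self) -> int:
        return len(self.individuals)

    @property
    def best(self) -> int:
        fits = [f for _, f in self.individuals]
        return int(np.argmin(fits))

    @property
    def best_fitness(self) -> float:
        return float(self.individuals[self.best][1])


def explore_step(
    theta: RigidTransform,
    bounds: SearchBounds,
    rng: np.random.Generator,
    restart_prob: float = 0.0,
) -> RigidTransform:
    """One random move on the discretized parameter graph, clipped to bounds.

    The neighborhood graph has two kinds of edges: local edges along a
    single axis, with log-uniform length 1..r (r = that axis' exploration
    radius), mixing coarse jumps with single-level refinements; and, with
    probability ``restart_prob``, long-range edges to a uniformly random
    node. The long edges give the walk global coverage of the search box,
    which selection alone cannot provide once the population has focused.
    """
    axis = int(rng.integers(0, 6))
    r = int(bounds.radius[axis])
    if r <= 0:
        return theta
    if restart_prob > 0.0 and rng.random() < restart_prob:
        return bounds.sample(rng)
    levels = bounds.to_levels(theta.as_array())
    k = int(np.exp(rng.uniform(0.0, np.log(r + 1.0))))
    k = min(max(k, 1), r)
    sign = 1 if rng.integers(0, 2) else -1
    levels[axis] = np.clip(levels[axis] + sign * k, 0, N_LEVELS - 1)
    return RigidTransform.from_array(bounds.from_levels(levels))


def select_step(
    population: Population, rng: np.random.Generator | None = None
) -> Population:
    """Pairwise tournament: the loser of each random pair becomes a copy of
    the winner. The best individual always survives."""
    if rng is None:
        rng = np.random.default_rng()
    inds = [list(p) for p in population.individuals]
    order = rng.permutation(len(inds))
    for a in range(0, len(order) - 1, 2):
        i, j = int(order[a]), int(order[a + 1])
        if inds[i][1] <= inds[j][1]:
            inds[j] = list(inds[i])
        else:
            inds[i] = list(inds[j])
    return Population(individuals=inds)


def es_optimize(
    cost,
    bounds: SearchBounds,
    pop_size: int = 20,
    n_iter: int = 800,
    seed: int | None = None,
    stagnation: int | None = None,
    restart_prob: float = 0.1,
):
    """Minimize ``cost`` over the bounded six-parameter graph.

    Returns ``(theta_best, fitness_best, trace)`` where ``trace`` is an
    (n_iter, 7) array holding, per iteration, the best-ever fitness followed
    by the best-ever parameters. ``stagnation``, if given, stops the run
    after that many consecutive unimproved iterations (the trace is then
    truncated).
    """
    if pop_size < 2:
        raise ParameterError("pop_size must be >= 2")
    if n_iter < 1:
        raise ParameterError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)

    def safe_cost(t):
        c = float(cost(t))
        return c if np.isfinite(c) else np.inf

    inds = []
    center = bounds.center
    inds.append([center, safe_cost(center)])
    for _ in range(pop_size - 1):
        t = bounds.sample(rng)
        inds.append([t, safe_cost(t)])
    pop = Population(individuals=inds)

    b = pop.best
    best_theta, best_fit = pop.individuals[b][0], pop.individuals[b][1]
    if not np.isfinite(best_fit):
        raise ParameterError("cost is non-finite on the whole initial population")

    trace = np.empty((n_iter, 7), dtype=float)
    since_improve = 0
    n_done = 0
    for it in range(n_iter):
        # exploration: unconditional random graph moves (non-finite rejected)
        for ind in pop.individuals:
            t_new = explore_step(ind[0], bounds, rng, restart_prob=restart_prob)
            f_new = safe_cost(t_new)
            if np.isfinite(f_new):
                ind[0], ind[1] = t_new, f_new
                if f_new < best_fit:
                    best_theta, best_fit = t_new, f_new
                    since_improve = -1
        # selection with elitist re-insertion of the best-ever solution
        pop = select_step(pop, rng)
        fits = [f for _, f in pop.individuals]
        worst = int(np.argmax(fits))
        if pop.individuals[worst][1] > best_fit:
            pop.individuals[worst] = [best_theta, best_fit]
        trace[it, 0] = best_fit
        trace[it, 1:] = best_theta.as_array()
        n_done = it + 1
        since_improve += 1
        if stagnation is not None and since_improve >= stagnation:
            break
    return best_theta, best_fit, trace[:n_done]
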