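"""Whale Optimization Algorithm and its modified variants.

Four variants behind one contract:

``woa``
    The baseline: shrinking encirclement of the incumbent best, a
    logarithmic-spiral local move, and exploration toward a random peer,
    with the linear coefficient schedule ``a: 2 -> 0``.
``mwoa1``
    Cosine/sine-modulated coefficient schedule: ``a`` decays through a
    ``cos(r)`` factor (and no longer reaches 0), ``A`` and ``C`` pass
    their uniform draws through ``sin``, and the spiral parameter ``l``
    follows the ``a2`` schedule.
``mwoa2``
    Exploration is replaced wholesale by a Gaussian diffusion random
    walk around the incumbent best (spread = agent-to-best distance),
    borrowed from stochastic fractal search; coefficients are standard.
``mwoa3``
    Both modifications combined.

Per iteration each agent first flips a coin with ``switch_probability``
for the spiral move; otherwise the scalar gate ``|A| >= 1`` splits
exploration from encirclement.  The step coefficient ``A`` is drawn
once per agent (it is the same scalar quantity the gate conditions on),
while the wobble coefficient ``C`` is drawn per axis.  Positions are
clamped to the box bounds and an elitist record of the best solution
ever evaluated is maintained, so the returned history is
non-increasing.

All randomness flows from one ``numpy`` Generator seeded by the config,
and branch-specific draws are made only for the agents that take the
branch, so runs are bit-reproducible and variants that never explore
share identical trajectories under the same seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np

logger = logging.getLogger(__name__)

VARIANTS = ("woa", "mwoa1", "mwoa2", "mwoa3")

__all__ = [
    "OptimizerConfig",
    "CoefficientSet",
    "OptimizationResult",
    "SearchSpace",
    "compute_coefficients_standard",
    "compute_coefficients_mwoa1",
    "encircle_update",
    "spiral_update",
    "explore_update",
    "diffusion_walk",
    "optimize",
    "optimize_benchmark",
]


@dataclass
class OptimizerConfig:
    """Control parameters for one optimization run.

    ``spiral_constant`` is the logarithmic-spiral shape constant,
    ``switch_probability`` the spiral-vs-encircle coin (default 0.5),
    ``diffusion_walks`` the number of Gaussian walks per exploring agent
    in mwoa2/mwoa3; with several walks the best is kept (greedy
    selection over the walk series, default 2).
    ``spiral_distance`` selects |X*-X| ("classic") or |C.X*-X|
    ("printed") as the spiral distance term.
    """

    variant: str = "mwoa2"
    n_agents: int = 30
    max_iter: int = 500
    spiral_constant: float = 1.0
    switch_probability: float = 0.5
    diffusion_walks: int = 2
    spiral_distance: str = "classic"
    sigma_damping: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if not 0.0 <= self.switch_probability <= 1.0:
            raise ValueError("switch_probability must lie in [0, 1]")
        if self.n_agents < 2:
            raise ValueError("n_agents must be >= 2")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.diffusion_walks < 0:
            raise ValueError("diffusion_walks must be >= 0")
        if self.spiral_distance not in ("classic", "printed"):
            raise ValueError("spiral_distance must be 'classic' or 'printed'")


@dataclass
class CoefficientSet:
    a: float
    a2: float
    A: np.ndarray
    C: np.ndarray
    l: float


@dataclass
class SearchSpace:
    """A box-bounded continuous search domain."""

    lower_bound: np.ndarray
    upper_bound: np.ndarray

    def __post_init__(self) -> None:
        self.lower_bound = np.atleast_1d(np.asarray(self.lower_bound, dtype=float))
        self.upper_bound = np.atleast_1d(np.asarray(self.upper_bound, dtype=float))
        if self.lower_bound.shape != self.upper_bound.shape:
            raise ValueError("bound shapes differ")
        if not np.all(self.lower_bound < self.upper_bound):
            raise ValueError("lower_bound must be < upper_bound on every axis")

    @property
    def dimension(self) -> int:
        return self.lower_bound.size


@dataclass
class OptimizationResult:
    best_position: np.ndarray
    best_value: float
    history: np.ndarray
    n_evaluations: int
    seed: int
    variant: str
    n_bound_repairs: int = 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "variant": self.variant,
                "seed": self.seed,
                "best_value": self.best_value,
                "best_position": self.best_position.tolist(),
                "n_evaluations": self.n_evaluations,
                "n_bound_repairs": self.n_bound_repairs,
            },
            indent=2,
        )

    def history_csv(self) -> str:
        lines = ["iteration,best_so_far"]
        lines += [f"{i + 1},{float(v)!r}" for i, v in enumerate(self.history)]
        return "\n".join(lines) + "\n"


# ------------------------------------------------------------ coefficients

def _a_standard(iteration: int, max_iter: int) -> float:
    if max_iter < 2:
        logger.warning("max_iter < 2: convergence factor fixed at 2 (degenerate schedule)")
        return 2.0
    return 2.0 * (1.0 - (iteration - 1) / (max_iter - 1))


def compute_coefficients_standard(
    iteration: int, max_iter: int, rng: np.random.Generator, dimension: int = 1
) -> CoefficientSet:
    """Baseline schedule: ``a`` linear from 2 to 0, ``A = 2 a r1 - a``
    with one scalar draw (``|A|`` also serves as the scalar exploration
    gate), ``C = 2 r2`` with per-axis uniform draws, ``l`` uniform in
    [-1, 1]."""
    if not 1 <= iteration <= max_iter:
        raise ValueError("iteration must lie in [1, max_iter]")
    a = _a_standard(iteration, max_iter)
    r1 = rng.uniform(0.0, 1.0)
    r2 = rng.uniform(0.0, 1.0, size=dimension)
    return CoefficientSet(
        a=a, a2=-1.0, A=np.atleast_1d(2.0 * a * r1 - a), C=2.0 * r2, l=rng.uniform(-1.0, 1.0)
    )


def compute_coefficients_mwoa1(
    iteration: int, max_iter: int, rng: np.random.Generator, dimension: int = 1
) -> CoefficientSet:
    """Modified schedule: cosine-damped ``a``/``a2`` and sine-passed draws.

    ``a = 2 - cos(r) (j-1)/(T-1)`` never reaches 0 (it ends in
    ``[1, 2 - cos 1]``); ``A = 2 a sin(r1) - a``, ``C = 2 sin(r2)``, and
    ``l = (a2 - 1) u + 1`` follows the ``a2`` schedule, with
    ``r, r1, r2, u`` fresh uniform draws in [0, 1].
    """
    if max_iter < 2:
        raise ValueError("the modified schedule requires max_iter >= 2")
    if not 1 <= iteration <= max_iter:
        raise ValueError("iteration must lie in [1, max_iter]")
    frac = (iteration - 1) / (max_iter - 1)
    r = rng.uniform(0.0, 1.0)
    a = 2.0 - math.cos(r) * frac
    a2 = -1.0 - math.cos(r) * (iteration - 1) / (max_iter - 1) ** 2
    r1 = rng.uniform(0.0, 1.0)
    r2 = rng.uniform(0.0, 1.0, size=dimension)
    u = rng.uniform(0.0, 1.0)
    return CoefficientSet(
        a=a,
        a2=a2,
        A=np.atleast_1d(2.0 * a * math.sin(r1) - a),
        C=2.0 * np.sin(r2),
        l=(a2 - 1.0) * u + 1.0,
    )


# ------------------------------------------------------------ single moves

def _check_same_dim(*vectors: np.ndarray) -> None:
    shapes = {np.asarray(v).shape[-1] for v in vectors}
    if len(shapes) > 1:
        raise ValueError(f"dimension mismatch between operands: {sorted(shapes)}")


def encircle_update(x: np.ndarray, best: np.ndarray, A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Shrinking encirclement: ``best - A * |C * best - x|`` componentwise."""
    x, best, A, C = (np.asarray(v, float) for v in (x, best, A, C))
    _check_same_dim(x, best)
    return best - A * np.abs(C * best - x)


def spiral_update(
    x: np.ndarray,
    best: np.ndarray,
    l: float | np.ndarray,
    spiral_constant: float = 1.0,
    C: np.ndarray | None = None,
    distance: str = "classic",
) -> np.ndarray:
    """Logarithmic-spiral move toward the best: ``D' e^{w l} cos(2 pi l) + best``.

    ``distance='classic'`` uses ``D' = |best - x|``; ``'printed'`` uses
    ``D' = |C best - x|`` (a known typo lineage in WOA derivatives, kept
    selectable for comparison).
    """
    x, best = np.asarray(x, float), np.asarray(best, float)
    if distance == "printed":
        if C is None:
            raise ValueError("distance='printed' requires the C coefficient")
        d_prime = np.abs(C * best - x)
    else:
        d_prime = np.abs(best - x)
    l = np.asarray(l, float)
    return d_prime * np.exp(spiral_constant * l) * np.cos(2.0 * np.pi * l) + best


def explore_update(x: np.ndarray, x_rand: np.ndarray, A: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Exploration toward a random peer: ``x_rand - A * |C * x_rand - x|``."""
    x, x_rand = np.asarray(x, float), np.asarray(x_rand, float)
    return x_rand - A * np.abs(C * x_rand - x)


def diffusion_walk(
    agent: np.ndarray, best: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One Gaussian diffusion step around the incumbent best.

    Samples ``Normal(mean=best, sd=|agent-best|)`` per axis and adds the
    drift ``lambda*best - lambda_hat*agent`` with two fresh uniform
    scalars in [0, 1].  A zero spread on an axis returns the mean there.
    """
    agent, best = np.asarray(agent, float), np.asarray(best, float)
    _check_same_dim(agent, best)
    sd = np.abs(agent - best)
    lam, lam_hat = rng.uniform(0.0, 1.0, size=2)
    return best + sd * rng.standard_normal(agent.shape) + lam * best - lam_hat * agent


# -------------------------------------------------------------- main loop

def _exploration_mask(A: np.ndarray) -> np.ndarray:
    # scalar gate on the first axis's draw (dominant convention)
    return np.abs(A[:, 0]) >= 1.0


def optimize(
    objective: Callable[[np.ndarray], np.ndarray],
    space: SearchSpace,
    config: OptimizerConfig,
    rng: np.random.Generator | None = None,
    vectorized: bool = True,
) -> OptimizationResult:
    """Run the configured variant's iteration loop and return its result.

    ``objective`` maps a population ``(n, d)`` to values ``(n,)`` when
    ``vectorized``; otherwise a single point ``(d,)`` to a scalar.
    Non-finite objective values cause the offending agent to be
    re-sampled uniformly in bounds (and the event logged).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    lb, ub = space.lower_bound, space.upper_bound
    d = space.dimension
    n = config.n_agents
    T = config.max_iter
    modified_coeffs = config.variant in ("mwoa1", "mwoa3")
    diffusion = config.variant in ("mwoa2", "mwoa3")

    if not vectorized:
        scalar = objective

        def objective(pop: np.ndarray) -> np.ndarray:  # type: ignore[misc]
            return np.array([scalar(row) for row in pop], dtype=float)

    n_evals = 0
    n_repairs = 0

    def evaluate(pop: np.ndarray) -> np.ndarray:
        nonlocal n_evals, n_repairs
        vals = np.asarray(objective(pop), dtype=float)
        n_evals += pop.shape[0]
        bad = ~np.isfinite(vals)
        while np.any(bad):
            logger.warning("re-sampling %d agents with non-finite objective values", bad.sum())
            pop[bad] = rng.uniform(lb, ub, size=(int(bad.sum()), d))
            vals[bad] = np.asarray(objective(pop[bad]), dtype=float)
            n_evals += int(bad.sum())
            bad = ~np.isfinite(vals)
        return vals

    X = rng.uniform(lb, ub, size=(n, d))
    fitness = evaluate(X)
    best_idx = int(np.argmin(fitness))
    best_value = float(fitness[best_idx])
    best_position = X[best_idx].copy()

    history = np.empty(T)
    for j in range(1, T + 1):
        # --- per-agent coefficient draws (fixed order for reproducibility)
        r1 = rng.uniform(0.0, 1.0, size=(n, 1))
        r2 = rng.uniform(0.0, 1.0, size=(n, d))
        if modified_coeffs:
            frac = (j - 1) / (T - 1) if T > 1 else 0.0
            cos_r = np.cos(rng.uniform(0.0, 1.0, size=(n, 1)))
            a = 2.0 - cos_r * frac
            a2 = -1.0 - cos_r * ((j - 1) / (T - 1) ** 2 if T > 1 else 0.0)
            A = 2.0 * a * np.sin(r1) - a
            C = 2.0 * np.sin(r2)
            l = (a2[:, 0] - 1.0) * rng.uniform(0.0, 1.0, size=n) + 1.0
        else:
            a = _a_standard(j, T)
            A = 2.0 * a * r1 - a
            C = 2.0 * r2
            l = rng.uniform(-1.0, 1.0, size=n)
        p = rng.uniform(0.0, 1.0, size=n)

        # spiral with probability switch_probability; otherwise the
        # |A| gate splits exploration from encirclement (classical order)
        spiral = p < config.switch_probability
        explore = ~spiral & _exploration_mask(A)
        encircle = ~spiral & ~explore

        new_X = np.empty_like(X)
        if np.any(encircle):
            new_X[encircle] = encircle_update(
                X[encircle], best_position, A[encircle], C[encircle]
            )
        if np.any(spiral):
            new_X[spiral] = spiral_update(
                X[spiral],
                best_position,
                l[spiral, None],
                config.spiral_constant,
                C=C[spiral],
                distance=config.spiral_distance,
            )
        k = int(explore.sum())
        if k:
            if diffusion:
                sd = np.abs(X[explore] - best_position)
                if config.sigma_damping and j > 1:
                    sd = sd * (math.log(j) / j)
                walks = config.diffusion_walks
                if walks == 0:
                    new_X[explore] = X[explore]
                else:
                    cand_vals = None
                    chosen = None
                    for _ in range(walks):
                        lam = rng.uniform(0.0, 1.0, size=(k, 1))
                        lam_hat = rng.uniform(0.0, 1.0, size=(k, 1))
                        cand = (
                            best_position
                            + sd * rng.standard_normal((k, d))
                            + lam * best_position
                            - lam_hat * X[explore]
                        )
                        if walks == 1:
                            chosen = cand
                            break
                        cand = np.clip(cand, lb, ub)
                        vals = evaluate(cand)
                        if cand_vals is None:
                            cand_vals, chosen = vals, cand
                        else:
                            better = vals < cand_vals
                            cand_vals = np.where(better, vals, cand_vals)
                            chosen[better] = cand[better]
                    new_X[explore] = chosen
            else:
                peers = rng.integers(0, n, size=k)
                new_X[explore] = explore_update(X[explore], X[peers], A[explore], C[explore])

        # bound repair: clamp to the nearest bound
        out_of_bounds = (new_X < lb) | (new_X > ub)
        n_repairs += int(out_of_bounds.sum())
        X = np.clip(new_X, lb, ub)
        fitness = evaluate(X)

        it_best = int(np.argmin(fitness))
        if fitness[it_best] < best_value:  # strict: ties keep the earlier incumbent
            best_value = float(fitness[it_best])
            best_position = X[it_best].copy()
        history[j - 1] = best_value

    return OptimizationResult(
        best_position=best_position,
        best_value=best_value,
        history=history,
        n_evaluations=n_evals,
        seed=config.seed,
        variant=config.variant,
        n_bound_repairs=n_repairs,
    )


def optimize_benchmark(function_id: str, config: OptimizerConfig) -> OptimizationResult:
    """Convenience: run a variant on one of the F1-F23 benchmark functions."""
    from . import benchmarks

    spec = benchmarks.get_spec(function_id)
    rng = np.random.default_rng(config.seed)
    objective = benchmarks.make_objective(function_id, rng=rng if function_id == "F7" else None)
    space = SearchSpace(spec.lower_bound, spec.upper_bound)
    return optimize(objective, space, config, rng=rng)
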