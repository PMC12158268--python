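"""Bird-inspired metaheuristics and the published formulation fitness surface.

Three population-based minimizers for bounded continuous problems are
implemented from their original descriptions:

* **Parrot Optimizer (PO)** — each Pyrrhura molinae individual performs one
  of four stochastically chosen behaviors per iteration: foraging toward
  food/owner position, staying (perching on the owner), communicating with
  the flock, and fear of strangers. Positions move unconditionally; the
  best-ever solution is tracked separately.
* **Pelican Optimization Algorithm (POA)** — two phases per iteration:
  moving toward a randomly generated prey (exploration; the direction flips
  when the prey is worse than the pelican) and winging on the water surface
  in a shrinking neighborhood (exploitation), both with greedy acceptance.
* **Secretary Bird Optimization Algorithm (SBOA)** — a hunting phase whose
  strategy shifts over time from differential prey search through
  consuming to a Levy-flight attack, and an escape phase mixing
  camouflage-style local moves around the best solution with random
  relocation, both with greedy acceptance.

Candidates leaving the box are clamped to the bounds by default (``reflect``
is available). All three record a best-so-far convergence curve and are
fully determined by their seed.

The module also carries the published response-time surface for the
PVA-PEG-BTB film (:func:`fitness_eq2`) and a deterministic grid +
coordinate-refinement minimizer used as an exhaustive cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.optimize import minimize_scalar

ALGORITHMS = ("po", "poa", "sboa")


@dataclass
class ObjectiveFunction:
    """A scalar objective on a box domain."""

    name: str
    evaluate: Callable[..., float]
    bounds: np.ndarray  # (d, 2) array of [low, high]

    def __post_init__(self) -> None:
        self.bounds = np.asarray(self.bounds, dtype=float)
        if self.bounds.ndim != 2 or self.bounds.shape[1] != 2:
            raise ValueError("bounds must be a (d, 2) array")
        if np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("each bound must satisfy low < high")

    @property
    def dim(self) -> int:
        return self.bounds.shape[0]

    def __call__(self, x: np.ndarray) -> float:
        return float(self.evaluate(*np.asarray(x, dtype=float)))


@dataclass
class OptimizationResult:
    algorithm: str
    best_x: np.ndarray
    best_f: float
    convergence: np.ndarray  # best-so-far objective per iteration
    seed: int | None = None
    population_size: int | None = None
    iterations: int | None = None

    def to_dict(self) -> dict:
        return {
            "algorithm": self.algorithm,
            "best_x": np.asarray(self.best_x).tolist(),
            "best_f": float(self.best_f),
            "convergence": np.asarray(self.convergence).tolist(),
            "seed": self.seed,
            "population_size": self.population_size,
            "iterations": self.iterations,
        }


# ---------------------------------------------------------------------------
# The published fitness surface: predicted color-transition time (s) as a
# function of PEG % w/v (x1) and BTB % w/v (x2).
# ---------------------------------------------------------------------------

PEG_BOUNDS = (6.0, 10.0)
BTB_BOUNDS = (0.01, 0.05)


def fitness_eq2(x1, x2):
    """Predicted color-transition time for PEG ``x1`` and BTB ``x2`` (% w/v).

    y = 4.34e4 x2 - 123 x1 - 152 ln(x1 + x2 + ln x2 + x2^2) + 1300 ln x1
        - 668 ln x2 - 4.17e4 x1 x2^2 + 96.6 x1^2 x2 - 4740

    with natural logarithms throughout. Accepts scalars or arrays.
    Raises ``ValueError`` outside the design domain PEG in [6, 10],
    BTB in [0.01, 0.05], or when the composite log argument
    ``x1 + x2 + ln x2 + x2^2`` is not positive.
    """
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if np.any(x1 < PEG_BOUNDS[0]) or np.any(x1 > PEG_BOUNDS[1]):
        raise ValueError(f"x1 (PEG % w/v) must lie in {PEG_BOUNDS}")
    if np.any(x2 < BTB_BOUNDS[0]) or np.any(x2 > BTB_BOUNDS[1]):
        raise ValueError(f"x2 (BTB % w/v) must lie in {BTB_BOUNDS}")
    inner = x1 + x2 + np.log(x2) + x2**2
    if np.any(inner <= 0):
        raise ValueError("composite log argument x1 + x2 + ln(x2) + x2^2 must be positive")
    y = (
        4.34e4 * x2
        - 123.0 * x1
        - 152.0 * np.log(inner)
        + 1300.0 * np.log(x1)
        - 668.0 * np.log(x2)
        - 4.17e4 * x1 * x2**2
        + 96.6 * x1**2 * x2
        - 4740.0
    )
    return float(y) if y.ndim == 0 else y


EQ2_OBJECTIVE = ObjectiveFunction(
    name="eq2",
    evaluate=fitness_eq2,
    bounds=np.array([PEG_BOUNDS, BTB_BOUNDS]),
)


def sphere_objective(dim: int = 2, half_width: float = 5.0) -> ObjectiveFunction:
    """The sphere benchmark sum(x_i^2) on [-half_width, half_width]^dim."""
    return ObjectiveFunction(
        name="sphere",
        evaluate=lambda *x: float(np.sum(np.square(x))),
        bounds=np.array([[-half_width, half_width]] * dim),
    )


# ---------------------------------------------------------------------------
# Shared machinery
# ---------------------------------------------------------------------------


def _apply_bounds(X: np.ndarray, bounds: np.ndarray, mode: str) -> np.ndarray:
    lo, hi = bounds[:, 0], bounds[:, 1]
    if mode == "clamp":
        return np.clip(X, lo, hi)
    if mode == "reflect":
        span = hi - lo
        Y = np.mod(X - lo, 2 * span)
        Y = np.where(Y > span, 2 * span - Y, Y)
        return lo + Y
    raise ValueError(f"unknown boundary mode {mode!r}")


def _evaluate(objective: ObjectiveFunction, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    for i, x in enumerate(X):
        f = objective(x)
        out[i] = f if np.isfinite(f) else np.inf  # NaN candidates are rejected
    return out


def _levy(rng: np.random.Generator, dim: int, beta: float = 1.5) -> np.ndarray:
    # Mantegna's algorithm for a Levy-stable step.
    num = math.gamma(1 + beta) * np.sin(np.pi * beta / 2)
    den = math.gamma((1 + beta) / 2) * beta * 2 ** ((beta - 1) / 2)
    sigma = (num / den) ** (1 / beta)
    u = rng.normal(0, sigma, dim)
    v = rng.normal(0, 1, dim)
    return u / np.abs(v) ** (1 / beta)


def _init_population(
    rng: np.random.Generator, bounds: np.ndarray, pop: int
) -> np.ndarray:
    lo, hi = bounds[:, 0], bounds[:, 1]
    return lo + rng.random((pop, bounds.shape[0])) * (hi - lo)


# ---------------------------------------------------------------------------
# The three metaheuristics
# ---------------------------------------------------------------------------


def _run_po(objective, pop, iters, rng, boundary):
    bounds = objective.bounds
    d = objective.dim
    X = _init_population(rng, bounds, pop)
    F = _evaluate(objective, X)
    ib = int(np.argmin(F))
    best_x, best_f = X[ib].copy(), F[ib]
    curve = np.empty(iters)
    for t in range(1, iters + 1):
        frac = t / iters
        mean_pos = X.mean(axis=0)
        for i in range(pop):
            st = rng.integers(1, 5)
            if st == 1:  # foraging: locate food by owner/food position cues
                x_new = (X[i] - best_x) * _levy(rng, d) + rng.random() * mean_pos * (
                    1 - frac
                ) ** (2 * frac)
            elif st == 2:  # staying: fly to and perch on the owner
                x_new = X[i] + best_x * _levy(rng, d) + rng.standard_normal() * (
                    1 - frac
                ) * np.ones(d)
            elif st == 3:  # communicating with the flock
                if rng.random() <= 0.5:
                    x_new = 0.2 * rng.random() * (1 - frac) * (X[i] - mean_pos)
                else:
                    x_new = 0.2 * rng.random() * np.exp(-t / (rng.random() * iters)) * np.ones(d)
            else:  # fear of strangers: move away, then reorient toward owner
                x_new = (
                    X[i]
                    + rng.random() * np.cos(0.5 * np.pi * frac) * (best_x - X[i])
                    - np.cos(rng.random() * np.pi) * frac ** (2 / iters) * (X[i] - best_x)
                )
            x_new = _apply_bounds(x_new, bounds, boundary)
            f_new = objective(x_new)
            if not np.isfinite(f_new):
                continue
            X[i], F[i] = x_new, f_new
            if f_new < best_f:
                best_x, best_f = x_new.copy(), f_new
        curve[t - 1] = best_f
    return best_x, best_f, curve


def _run_poa(objective, pop, iters, rng, boundary):
    bounds = objective.bounds
    X = _init_population(rng, bounds, pop)
    F = _evaluate(objective, X)
    ib = int(np.argmin(F))
    best_x, best_f = X[ib].copy(), F[ib]
    curve = np.empty(iters)
    for t in range(1, iters + 1):
        # Phase 1: moving toward prey (exploration)
        prey = _init_population(rng, bounds, 1)[0]
        f_prey = objective(prey)
        for i in range(pop):
            I = rng.integers(1, 3)
            if f_prey < F[i]:
                x_new = X[i] + rng.random(objective.dim) * (prey - I * X[i])
            else:
                x_new = X[i] + rng.random(objective.dim) * (X[i] - prey)
            x_new = _apply_bounds(x_new, bounds, boundary)
            f_new = objective(x_new)
            if np.isfinite(f_new) and f_new < F[i]:
                X[i], F[i] = x_new, f_new
        # Phase 2: winging on the water surface (exploitation)
        radius = 0.2 * (1 - t / iters)
        for i in range(pop):
            x_new = X[i] + radius * (2 * rng.random(objective.dim) - 1) * X[i]
            x_new = _apply_bounds(x_new, bounds, boundary)
            f_new = objective(x_new)
            if np.isfinite(f_new) and f_new < F[i]:
                X[i], F[i] = x_new, f_new
        ib = int(np.argmin(F))
        if F[ib] < best_f:
            best_x, best_f = X[ib].copy(), F[ib]
        curve[t - 1] = best_f
    return best_x, best_f, curve


def _run_sboa(objective, pop, iters, rng, boundary):
    bounds = objective.bounds
    d = objective.dim
    X = _init_population(rng, bounds, pop)
    F = _evaluate(objective, X)
    ib = int(np.argmin(F))
    best_x, best_f = X[ib].copy(), F[ib]
    curve = np.empty(iters)
    for t in range(1, iters + 1):
        frac = t / iters
        # Hunting phase (exploration), strategy by thirds of the run
        for i in range(pop):
            if frac < 1 / 3:  # searching for prey: differential move
                r1, r2 = rng.choice(pop, size=2, replace=False)
                x_new = X[i] + (X[r1] - X[r2]) * rng.random(d)
            elif frac < 2 / 3:  # consuming prey: spiral around the best
                rb = rng.standard_normal(d)
                x_new = best_x + np.exp((frac) ** 4) * (rb - 0.5) * (best_x - X[i])
            else:  # attacking prey: Levy-flight strike
                rl = 0.5 * _levy(rng, d)
                x_new = best_x + (1 - frac) ** (2 * frac) * X[i] * rl
            x_new = _apply_bounds(x_new, bounds, boundary)
            f_new = objective(x_new)
            if np.isfinite(f_new) and f_new < F[i]:
                X[i], F[i] = x_new, f_new
        # Escape phase (exploitation)
        for i in range(pop):
            if rng.random() < 0.5:  # camouflage by environment, near the best
                rb = rng.standard_normal(d)
                x_new = best_x + (2 * rb - 1) * (1 - frac) ** 2 * X[i]
            else:  # run or fly away: random relocation
                k = int(rng.integers(1, 3))
                r = rng.choice(pop)
                x_new = X[i] + rng.random(d) * (X[r] - k * X[i])
            x_new = _apply_bounds(x_new, bounds, boundary)
            f_new = objective(x_new)
            if np.isfinite(f_new) and f_new < F[i]:
                X[i], F[i] = x_new, f_new
        ib = int(np.argmin(F))
        if F[ib] < best_f:
            best_x, best_f = X[ib].copy(), F[ib]
        curve[t - 1] = best_f
    return best_x, best_f, curve


_RUNNERS = {"po": _run_po, "poa": _run_poa, "sboa": _run_sboa}


def optimize(
    objective: ObjectiveFunction,
    algorithm: str,
    population_size: int = 30,
    iterations: int = 100,
    seed: int = 0,
    boundary: str = "clamp",
) -> OptimizationResult:
    """Minimize ``objective`` with one of the bird-inspired metaheuristics.

    ``algorithm`` is one of ``po``, ``poa``, ``sboa``. The result carries
    the best solution found and the best-so-far convergence curve (one
    entry per iteration, non-increasing). Identical seeds reproduce the run
    exactly.
    """
    algorithm = algorithm.lower()
    if algorithm not in _RUNNERS:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    if population_size < 2:
        raise ValueError("population_size must be >= 2")
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    best_x, best_f, curve = _RUNNERS[algorithm](
        objective, population_size, iterations, rng, boundary
    )
    return OptimizationResult(
        algorithm=algorithm,
        best_x=best_x,
        best_f=float(best_f),
        convergence=curve,
        seed=seed,
        population_size=population_size,
        iterations=iterations,
    )


def random_search(
    objective: ObjectiveFunction, n_evals: int, seed: int = 0
) -> OptimizationResult:
    """Uniform random search baseline at a fixed evaluation budget."""
    rng = np.random.default_rng(seed)
    X = _init_population(rng, objective.bounds, n_evals)
    F = _evaluate(objective, X)
    curve = np.minimum.accumulate(F)
    ib = int(np.argmin(F))
    return OptimizationResult(
        algorithm="random",
        best_x=X[ib].copy(),
        best_f=float(F[ib]),
        convergence=curve,
        seed=seed,
        population_size=1,
        iterations=n_evals,
    )


def grid_refine_minimize(
    objective: ObjectiveFunction,
    grid_points_per_dim: int = 2000,
    refine_tolerance: float = 1e-8,
) -> OptimizationResult:
    """Deterministic exhaustive grid search plus coordinate refinement.

    Evaluates the objective on a full ``grid_points_per_dim``-per-axis
    lattice over the bounds, then refines the best lattice point by
    repeated one-dimensional bounded minimization along each coordinate
    (bracket = one lattice spacing, shrinking each sweep) until the point
    moves by less than ``refine_tolerance``.
    """
    bounds = objective.bounds
    axes = [np.linspace(lo, hi, grid_points_per_dim) for lo, hi in bounds]
    mesh = np.meshgrid(*axes, indexing="ij")
    try:  # vectorized evaluation when the objective supports arrays
        values = np.asarray(objective.evaluate(*mesh), dtype=float)
        if values.shape != mesh[0].shape:
            raise TypeError
    except (TypeError, ValueError):
        flat = np.stack([m.ravel() for m in mesh], axis=1)
        values = _evaluate(objective, flat).reshape(mesh[0].shape)
    idx = np.unravel_index(np.nanargmin(values), values.shape)
    x = np.array([axes[k][idx[k]] for k in range(objective.dim)])
    f = float(values[idx])
    curve = [f]

    spacing = np.array([(hi - lo) / (grid_points_per_dim - 1) for lo, hi in bounds])
    for _ in range(200):
        x_prev = x.copy()
        for k in range(objective.dim):
            lo = max(bounds[k, 0], x[k] - spacing[k])
            hi = min(bounds[k, 1], x[k] + spacing[k])
            if hi <= lo:
                continue

            def along(v, k=k):
                xv = x.copy()
                xv[k] = v
                return objective(xv)

            res = minimize_scalar(
                along, bounds=(lo, hi), method="bounded",
                options={"xatol": refine_tolerance / 10},
            )
            if res.fun < f:
                x[k], f = float(res.x), float(res.fun)
        curve.append(f)
        spacing = np.maximum(spacing / 2, refine_tolerance / 2)
        if np.max(np.abs(x - x_prev)) < refine_tolerance:
            break
    return OptimizationResult(
        algorithm="grid",
        best_x=x,
        best_f=f,
        convergence=np.asarray(curve),
        seed=None,
        population_size=None,
        iterations=len(curve),
    )
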