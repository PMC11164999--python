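"""Seeded global optimizers: a staged range-narrowing GA and classic DE.

Two metaheuristics are used for parameter estimation in this package:

* a real-coded genetic algorithm wrapped in a *staged range-narrowing*
  procedure — several independent GA runs per stage with randomly drawn
  population sizes and generation counts, after which the search bounds are
  shrunk to the envelope of the stage's optima and the process repeats;
* classic ``rand/1/bin`` differential evolution with one-to-one selection.

Both are bounded minimizers, fully reproducible for a fixed seed, and
record a monotone best-so-far trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = ["GAConfig", "DEConfig", "OptimizeResult", "ga_staged_minimize", "de_minimize"]


@dataclass
class GAConfig:
    """Staged-GA settings.

    Population size and generation count are drawn uniformly from
    ``pop_size_range`` and ``generations_range`` for every restart,
    emulating a trial-and-error sweep over GA hyper-parameters.
    """

    pop_size_range: tuple[int, int] = (20, 100)
    generations_range: tuple[int, int] = (100, 1000)
    n_stages: int = 3
    restarts_per_stage: int = 5
    seed: int = 0
    # internal GA operators (not part of the staged procedure itself)
    tournament_k: int = 3
    crossover_prob: float = 0.9
    mutation_prob: float = 0.2
    mutation_sigma_frac: float = 0.10  # Gaussian sigma as fraction of range
    elitism: int = 1

    def __post_init__(self) -> None:
        if self.pop_size_range[0] < 2 or self.pop_size_range[0] > self.pop_size_range[1]:
            raise ValueError("invalid pop_size_range")
        if self.generations_range[0] < 1 or self.generations_range[0] > self.generations_range[1]:
            raise ValueError("invalid generations_range")
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")


@dataclass
class DEConfig:
    """Differential-evolution settings (rand/1/bin)."""

    pop_size: int | None = None  # default 15 x dimension
    max_generations: int = 200
    F: float = 0.7
    CR: float = 0.9
    seed: int = 0
    tol: float = 1e-10  # stagnation tolerance on the best value

    def __post_init__(self) -> None:
        if not (0.0 < self.F <= 2.0):
            raise ValueError("F must be in (0, 2]")
        if not (0.0 <= self.CR <= 1.0):
            raise ValueError("CR must be in [0, 1]")


@dataclass
class OptimizeResult:
    x: np.ndarray
    fun: float
    trace: list[float] = field(default_factory=list)
    meta: dict = field(default_factory=dict)


def _as_bounds(bounds: Sequence[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if lo.size == 0:
        raise ValueError("empty bounds")
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi)) and np.all(hi > lo)):
        raise ValueError("bounds must be finite with hi > lo")
    return lo, hi


def _evaluate(objective: Callable, X: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        f = np.asarray(objective(X), dtype=float)
    else:
        f = np.array([objective(x) for x in X], dtype=float)
    if np.any(np.isnan(f)):
        raise ValueError("objective returned NaN")
    return f


def _ga_run(objective, lo, hi, pop_size, generations, rng, cfg, vectorized):
    """One plain real-coded GA run. Returns (best_x, best_f, trace)."""
    dim = lo.size
    span = hi - lo
    X = lo + rng.random((pop_size, dim)) * span
    f = _evaluate(objective, X, vectorized)
    order = np.argsort(f)
    best_x, best_f = X[order[0]].copy(), float(f[order[0]])
    trace = [best_f]
    sigma = cfg.mutation_sigma_frac * span
    for _ in range(generations):
        # tournament selection
        idx = rng.integers(0, pop_size, size=(pop_size, cfg.tournament_k))
        winners = idx[np.arange(pop_size), np.argmin(f[idx], axis=1)]
        parents = X[winners]
        # blend (BLX-0.5) crossover on consecutive pairs
        children = parents.copy()
        for i in range(0, pop_size - 1, 2):
            if rng.random() < cfg.crossover_prob:
                p1, p2 = parents[i], parents[i + 1]
                d = p2 - p1
                u = rng.random(dim) * 2.0 - 0.5  # in [-0.5, 1.5]
                children[i] = p1 + u * d
                u = rng.random(dim) * 2.0 - 0.5
                children[i + 1] = p1 + u * d
        # Gaussian mutation
        mut = rng.random((pop_size, dim)) < cfg.mutation_prob
        children = np.where(mut, children + rng.normal(0.0, 1.0, (pop_size, dim)) * sigma, children)
        np.clip(children, lo, hi, out=children)
        fc = _evaluate(objective, children, vectorized)
        # elitism: keep the best-so-far individual
        worst = np.argmax(fc)
        if cfg.elitism and fc[worst] > best_f:
            children[worst] = best_x
            fc[worst] = best_f
        X, f = children, fc
        gen_best = int(np.argmin(f))
        if f[gen_best] < best_f:
            best_f = float(f[gen_best])
            best_x = X[gen_best].copy()
        trace.append(best_f)
    return best_x, best_f, trace


def ga_staged_minimize(
    objective: Callable,
    bounds: Sequence[tuple[float, float]],
    config: GAConfig | None = None,
    vectorized: bool = False,
) -> OptimizeResult:
    """Minimize ``objective`` with the staged range-narrowing GA.

    Stage 1 launches ``restarts_per_stage`` independent GA runs over the
    initial bounds, each with population size and generation count drawn
    from the configured ranges.  Every subsequent stage shrinks the bounds
    to the [min, max] envelope of the previous stage's per-run optima
    (never expanding beyond the originals) and reruns.  The overall best
    point is returned together with a monotone best-so-far trace.

    Set ``vectorized=True`` if ``objective`` accepts an (n, dim) array and
    returns n values; this is much faster for cheap objectives.
    """
    cfg = config or GAConfig()
    lo0, hi0 = _as_bounds(bounds)
    rng = np.random.default_rng(cfg.seed)
    lo, hi = lo0.copy(), hi0.copy()
    best_x, best_f = None, np.inf
    trace: list[float] = []
    stage_meta = []
    for stage in range(cfg.n_stages):
        optima = []
        for _ in range(cfg.restarts_per_stage):
            pop = int(rng.integers(cfg.pop_size_range[0], cfg.pop_size_range[1] + 1))
            gens = int(rng.integers(cfg.generations_range[0], cfg.generations_range[1] + 1))
            x, f, tr = _ga_run(objective, lo, hi, pop, gens, rng, cfg, vectorized)
            optima.append(x)
            for v in tr:
                trace.append(min(v, trace[-1]) if trace else v)
            if f < best_f:
                best_f, best_x = f, x
        optima = np.array(optima)
        new_lo = np.maximum(optima.min(axis=0), lo0)
        new_hi = np.minimum(optima.max(axis=0), hi0)
        # guard against a collapsed interval
        width = np.maximum(new_hi - new_lo, 1e-12 * (hi0 - lo0))
        lo, hi = new_lo, new_lo + width
        stage_meta.append({"stage": stage + 1, "lo": lo.tolist(), "hi": hi.tolist(),
                           "best": float(best_f)})
    return OptimizeResult(
        x=best_x, fun=float(best_f), trace=trace,
        meta={"stages": stage_meta, "seed": cfg.seed,
              "operators": "tournament(k=3), blend crossover, Gaussian mutation, elitism 1"},
    )


def de_minimize(
    objective: Callable,
    bounds: Sequence[tuple[float, float]],
    config: DEConfig | None = None,
    vectorized: bool = False,
) -> OptimizeResult:
    """Classic rand/1/bin differential evolution with one-to-one selection.

    Mutant vectors ``a + F (b - c)`` are built from three distinct random
    population members, binomially crossed with the target, and replace it
    only when they improve — the one-to-one competitive survival rule.
    """
    cfg = config or DEConfig()
    lo, hi = _as_bounds(bounds)
    dim = lo.size
    pop = cfg.pop_size or 15 * dim
    if pop < 4:
        pop = 4
    rng = np.random.default_rng(cfg.seed)
    X = lo + rng.random((pop, dim)) * (hi - lo)
    f = _evaluate(objective, X, vectorized)
    ib = int(np.argmin(f))
    best_x, best_f = X[ib].copy(), float(f[ib])
    trace = [best_f]
    stall = 0
    for _ in range(cfg.max_generations):
        idx = np.arange(pop)
        r1 = rng.integers(0, pop, pop)
        r2 = rng.integers(0, pop, pop)
        r3 = rng.integers(0, pop, pop)
        for arr in (r1, r2, r3):
            clash = arr == idx
            while np.any(clash):
                arr[clash] = rng.integers(0, pop, clash.sum())
                clash = arr == idx
        mutant = X[r1] + cfg.F * (X[r2] - X[r3])
        np.clip(mutant, lo, hi, out=mutant)
        cross = rng.random((pop, dim)) < cfg.CR
        jrand = rng.integers(0, dim, pop)
        cross[np.arange(pop), jrand] = True
        trial = np.where(cross, mutant, X)
        ft = _evaluate(objective, trial, vectorized)
        improved = ft <= f
        X = np.where(improved[:, None], trial, X)
        f = np.where(improved, ft, f)
        ib = int(np.argmin(f))
        if f[ib] < best_f - cfg.tol:
            stall = 0
        else:
            stall += 1
        if f[ib] < best_f:
            best_f = float(f[ib])
            best_x = X[ib].copy()
        trace.append(best_f)
        if stall >= 50:
            break
    return OptimizeResult(x=best_x, fun=best_f, trace=trace,
                          meta={"seed": cfg.seed, "pop": pop, "F": cfg.F, "CR": cfg.CR})
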