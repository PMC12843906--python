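"""Ant-colony optimization over spectral sub-intervals.

Each "route" is a subset of C bands out of the partition scheme.  Ants draw
bands sequentially without replacement with probability proportional to
pheromone^alpha; a subset's fitness is the averaged cross-validation error
(RMSECV, default) or held-out prediction error (RMSEP) of a PLS model on the
subset's columns; after each iteration pheromone evaporates at rate B and
the iteration-best subset deposits Q / fitness on its bands (elitist,
iteration-best deposit), floored at ``tau_min``.

Key colony parameters follow the usual naming: A = number of ants,
B = pheromone evaporation rate in (0,1), C = number of selected bands.
Runs are fully determined by the configured seed; subset fitnesses are
memoised within a run, so revisited subsets cost nothing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .intervals import IntervalScheme, extract_bands
from .pls_core import cross_validate_rmsecv, fit_plsr, predict

__all__ = ["ACOConfig", "ACOResult", "sample_subset", "evaluate_subset",
           "update_pheromone", "run_aco"]

_ZERO_FITNESS_EPS = 1e-12


@dataclass(frozen=True)
class ACOConfig:
    """Colony parameters; defaults follow the optimised operating point
    (300 ants, evaporation 0.3, 10 bands)."""

    n_ants: int = 300
    evaporation_rate: float = 0.3
    n_bands: int = 10
    n_iterations: int = 100
    alpha: float = 1.0
    deposit_q: float = 0.1
    tau_init: float = 1.0
    tau_min: float = 1e-3
    stagnation_limit: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.evaporation_rate < 1.0:
            raise ValueError("evaporation_rate must lie in (0, 1)")
        if self.n_bands < 1:
            raise ValueError("n_bands must be >= 1")
        if self.tau_min <= 0:
            raise ValueError("tau_min must be positive")
        if self.n_ants < 1 or self.n_iterations < 1:
            raise ValueError("n_ants and n_iterations must be >= 1")


@dataclass
class ACOResult:
    """Outcome of one colony run."""

    best_bands: tuple          # sorted ascending (canonical form)
    discovery_order: tuple     # bands in the order the best ant drew them
    best_fitness: float
    fitness_history: list      # best-so-far per iteration (non-increasing)
    pheromone: np.ndarray
    n_evaluations: int = field(default=0)


def sample_subset(pheromone: np.ndarray, n_bands: int, alpha: float,
                  rng: np.random.Generator) -> tuple:
    """Draw ``n_bands`` distinct 1-indexed bands, each sequential draw with
    probability proportional to tau_i^alpha over the remaining bands."""
    tau = np.asarray(pheromone, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("pheromone levels must be positive")
    if n_bands > tau.size:
        raise ValueError(f"cannot draw {n_bands} bands from {tau.size}")
    weights = tau**alpha
    chosen: list[int] = []
    available = np.arange(tau.size)
    for _ in range(n_bands):
        w = weights[available]
        idx = rng.choice(available.size, p=w / w.sum())
        chosen.append(int(available[idx]) + 1)
        available = np.delete(available, idx)
    return tuple(chosen)


def evaluate_subset(
    bands,
    X: np.ndarray,
    Y: np.ndarray,
    scheme: IntervalScheme,
    n_lvs: int,
    metric: str = "rmsecv",
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
) -> float:
    """Fitness of a band subset: averaged RMSECV (default) or RMSEP.

    RMSEP mode fits on (X, Y) and scores on the held-out (X_val, Y_val),
    matching the evaluation criterion of the factor-screening experiment.
    """
    Xb = extract_bands(X, scheme, bands)
    if metric not in ("rmsecv", "rmsep"):
        raise ValueError(f"unknown fitness metric {metric!r}")
    if metric == "rmsep" and (X_val is None or Y_val is None):
        raise ValueError("RMSEP fitness needs a held-out X_val/Y_val")
    try:
        if metric == "rmsecv":
            _, avg = cross_validate_rmsecv(Xb, Y, n_lvs)
            return avg
        model = fit_plsr(Xb, Y, n_lvs)
        resid = np.asarray(Y_val, float) - predict(model, extract_bands(X_val, scheme, bands))
        return float(np.sqrt(np.mean(resid**2, axis=0)).mean())
    except ValueError as exc:
        if "latent variable" in str(exc):
            return float("inf")  # signal-free subset: unfit, not an error
        raise


def update_pheromone(pheromone: np.ndarray, best_subset, best_fitness: float,
                     config: ACOConfig) -> np.ndarray:
    """Evaporate, deposit Q / fitness on the iteration-best bands, clamp."""
    tau = np.asarray(pheromone, dtype=float) * (1.0 - config.evaporation_rate)
    if best_subset:
        denom = max(best_fitness, _ZERO_FITNESS_EPS)
        idx = np.array(sorted(best_subset), dtype=int) - 1
        tau[idx] += config.deposit_q / denom
    return np.maximum(tau, config.tau_min)


def run_aco(
    X: np.ndarray,
    Y: np.ndarray,
    scheme: IntervalScheme,
    config: ACOConfig,
    n_lvs: int = 5,
    metric: str = "rmsecv",
    X_val: np.ndarray | None = None,
    Y_val: np.ndarray | None = None,
) -> ACOResult:
    """Run the colony and return the best-ever band subset.

    Early-stops after ``stagnation_limit`` iterations without improvement.
    """
    if config.n_bands > scheme.n_intervals:
        raise ValueError("n_bands exceeds the number of sub-intervals")
    rng = np.random.default_rng(config.seed)
    tau = np.full(scheme.n_intervals, float(config.tau_init))
    cache: dict[tuple, float] = {}
    best_bands: tuple = ()
    best_order: tuple = ()
    best_fitness = np.inf
    history: list[float] = []
    stagnant = 0
    for _ in range(config.n_iterations):
        iter_best: tuple = ()
        iter_order: tuple = ()
        iter_fitness = np.inf
        for _ in range(config.n_ants):
            order = sample_subset(tau, config.n_bands, config.alpha, rng)
            key = tuple(sorted(order))
            if key not in cache:
                cache[key] = evaluate_subset(
                    key, X, Y, scheme, n_lvs, metric, X_val, Y_val
                )
            fit = cache[key]
            if fit < iter_fitness:
                iter_best, iter_order, iter_fitness = key, order, fit
        tau = update_pheromone(tau, iter_best, iter_fitness, config)
        if iter_fitness < best_fitness:
            best_bands, best_order, best_fitness = iter_best, iter_order, iter_fitness
            stagnant = 0
        else:
            stagnant += 1
        history.append(best_fitness)
        if stagnant >= config.stagnation_limit:
            break
    return ACOResult(
        best_bands=best_bands,
        discovery_order=best_order,
        best_fitness=float(best_fitness),
        fitness_history=history,
        pheromone=tau,
        n_evaluations=len(cache),
    )
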