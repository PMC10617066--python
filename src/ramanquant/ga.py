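"""Adaptive genetic algorithm searching the CNN's initial weight vector.

Each chromosome is the flat vector of every model weight.  Fitness is the
training-set RMSE of a pure forward pass (no gradient steps inside fitness).
Crossover and mutation probabilities adapt per individual: above-average
individuals get rates annealed by both the generation number and a sigmoid of
their relative quality, while below-average individuals always get the
maximum rates -- exploration where the population is weak, exploitation where
it is strong.  Because fitness is an error (smaller is better) the adaptive
rule operates on quality = -error.

An optional catastrophe operator reinitializes the worst fraction of the
population after a stagnation window, protecting the elites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .errors import ConfigError
from .metrics import rmse
from .network import Model, ModelConfig, build_model, predict


@dataclass
class CatastropheConfig:
    enabled: bool = False
    stagnation_window: int = 10
    refresh_fraction: float = 0.5

    def __post_init__(self):
        if not 0 < self.refresh_fraction < 1:
            raise ConfigError("refresh_fraction must be in (0, 1)")
        if self.stagnation_window < 1:
            raise ConfigError("stagnation_window must be >= 1")


@dataclass
class GAConfig:
    """Population and schedule constants.  ``steepness`` is the sigmoid slope
    of the adaptive rate rule; ``adaptive=False`` freezes both probabilities
    at the classic simple-GA settings ``fixed_pc``/``fixed_pm`` (crossover-
    driven search with background mutation), the traditional baseline the
    adaptive schedule is compared against."""

    pop_size: int = 30
    generations: int = 50
    pc_min: float = 0.4
    pc_max: float = 0.9
    pm_min: float = 0.01
    pm_max: float = 0.1
    steepness: float = 1.0
    elitism: int = 1
    mutation_scale: float = 0.1
    adaptive: bool = True
    fixed_pc: float = 0.65
    fixed_pm: float = 0.008
    seed: int = 0
    catastrophe: CatastropheConfig = field(default_factory=CatastropheConfig)

    def __post_init__(self):
        if self.pop_size < 2:
            raise ConfigError("pop_size must be >= 2")
        if self.generations < 0:
            raise ConfigError("generations must be >= 0")
        for lo, hi, name in ((self.pc_min, self.pc_max, "Pc"),
                             (self.pm_min, self.pm_max, "Pm")):
            if not (0 < lo < hi <= 1):
                raise ConfigError(f"need 0 < {name}_min < {name}_max <= 1")
        if self.steepness <= 0:
            raise ConfigError("steepness must be > 0")
        if self.elitism < 1:
            raise ConfigError("elitism must be >= 1")
        if self.mutation_scale <= 0:
            raise ConfigError("mutation_scale must be > 0")


@dataclass
class GAResult:
    best_chromosome: np.ndarray
    best_fitness_per_generation: list[float]
    final_population: list[np.ndarray]
    final_fitness: list[float]
    seed: int


# -- operators ---------------------------------------------------------------

def fitness(chromosome: np.ndarray, X: np.ndarray, y: np.ndarray,
            model: Model) -> float:
    """Training-set RMSE of a forward pass with the chromosome's weights.
    Non-finite predictions yield +inf so such individuals are never elite."""
    model.set_flat(chromosome)
    with np.errstate(over="ignore", invalid="ignore"):
        yhat = predict(model, X)
    if not np.all(np.isfinite(yhat)):
        return float("inf")
    return rmse(y, yhat)


def adaptive_rates(
    f: float, f_avg: float, f_best: float, i: int, G: int, cfg: GAConfig
) -> tuple[float, float]:
    """Per-individual crossover/mutation probabilities.

    Arguments are errors (lower is better); internally quality = -error so the
    above-average branch matches the larger-is-fitter convention.  At exactly
    average quality, and for a degenerate population (best == average), the
    maximum-rate branch applies.  Both outputs always lie inside their bands.
    """
    if G < 1:
        raise ValueError("G must be >= 1")
    if not cfg.adaptive:
        return cfg.fixed_pc, cfg.fixed_pm
    q, q_avg, q_best = -f, -f_avg, -f_best

    def rate(p_min: float, p_max: float) -> float:
        if q <= q_avg or q_best == q_avg:
            return p_max
        z = cfg.steepness * 2.0 * (q - q_avg) / (q_best - q_avg)
        return p_min + (p_max - p_min) * (1.0 - i / G) / (1.0 + np.exp(min(z, 700.0)))

    return rate(cfg.pc_min, cfg.pc_max), rate(cfg.pm_min, cfg.pm_max)


def select(population: Sequence[np.ndarray], fitnesses: Sequence[float],
           rng: np.random.Generator, n_pairs: int) -> list[tuple[int, int]]:
    """Size-2 tournament selection on error (lower wins); returns parent index
    pairs.  Deterministic per drawn pair: the better contestant always wins."""
    n = len(population)
    if n < 2:
        raise ValueError("need at least 2 individuals")
    pairs = []
    for _ in range(n_pairs):
        winners = []
        for _ in range(2):
            a, b = rng.integers(0, n, size=2)
            winners.append(a if fitnesses[a] <= fitnesses[b] else b)
        pairs.append((int(winners[0]), int(winners[1])))
    return pairs


def crossover(a: np.ndarray, b: np.ndarray, pc: float,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Whole-arithmetic blend with probability pc: children alpha*a+(1-alpha)*b
    and (1-alpha)*a+alpha*b, alpha ~ U(0,1); otherwise plain copies.  The
    children always conserve a + b elementwise."""
    if a.shape != b.shape:
        raise ValueError("parents must have equal length")
    if rng.random() < pc:
        alpha = rng.random()
        return alpha * a + (1 - alpha) * b, (1 - alpha) * a + alpha * b
    return a.copy(), b.copy()


def mutate(c: np.ndarray, pm: float, rng: np.random.Generator,
           scale: float) -> np.ndarray:
    """Independent per-gene Gaussian perturbation N(0, scale^2) with
    probability pm."""
    if scale <= 0:
        raise ValueError("scale must be > 0")
    mask = rng.random(c.shape) < pm
    out = c.copy()
    out[mask] += rng.normal(0.0, scale, size=int(mask.sum()))
    return out


def catastrophe(
    population: list[np.ndarray],
    fitnesses: list[float],
    stagnation: int,
    cfg: GAConfig,
    rng: np.random.Generator,
    init_fn: Callable[[np.random.Generator], np.ndarray],
) -> tuple[list[np.ndarray], bool]:
    """Reinitialize the worst ``refresh_fraction`` of the population once the
    best fitness has stalled for the stagnation window; elites untouched."""
    if not cfg.catastrophe.enabled or stagnation < cfg.catastrophe.stagnation_window:
        return population, False
    order = np.argsort(fitnesses)  # best first
    n_refresh = int(np.floor(cfg.catastrophe.refresh_fraction * len(population)))
    n_refresh = min(n_refresh, len(population) - cfg.elitism)
    for idx in order[::-1][:n_refresh]:
        population[int(idx)] = init_fn(rng)
    return population, True


# -- engine -------------------------------------------------------------------

def evolve(
    fitness_fn: Callable[[np.ndarray], float],
    initial_population: list[np.ndarray],
    cfg: GAConfig,
    init_fn: Callable[[np.random.Generator], np.ndarray] | None = None,
) -> GAResult:
    """Generic minimization engine; ``run_ga`` wraps it for CNN weights.

    Per generation: evaluate, copy elites, pair parents by tournament, blend
    with the fitter parent's adaptive Pc, mutate each child with its parent's
    adaptive Pm, optionally apply the catastrophe operator.  Elitism makes the
    best-fitness trajectory non-increasing.
    """
    rng = np.random.default_rng(cfg.seed)
    population = [np.array(ind, dtype=float) for ind in initial_population]
    if len(population) != cfg.pop_size:
        raise ConfigError("initial population size must equal cfg.pop_size")
    if init_fn is None:
        template = population[0]
        init_fn = lambda r: r.normal(0.0, template.std() or 1.0, template.shape)

    fits = [fitness_fn(ind) for ind in population]
    best_trajectory = [float(np.min(fits))]
    stagnation = 0

    for gen in range(cfg.generations):
        order = np.argsort(fits, kind="stable")
        finite = [f for f in fits if np.isfinite(f)]
        f_avg = float(np.mean(finite)) if finite else float("inf")
        f_best = float(fits[order[0]])

        new_pop = [population[int(i)].copy() for i in order[:cfg.elitism]]
        n_pairs = (cfg.pop_size - len(new_pop) + 1) // 2
        pairs = select(population, fits, rng, n_pairs)
        for ia, ib in pairs:
            better = ia if fits[ia] <= fits[ib] else ib
            pc, _ = adaptive_rates(fits[better], f_avg, f_best, gen,
                                   cfg.generations, cfg)
            child1, child2 = crossover(population[ia], population[ib], pc, rng)
            for child, parent in ((child1, ia), (child2, ib)):
                _, pm = adaptive_rates(fits[parent], f_avg, f_best, gen,
                                       cfg.generations, cfg)
                new_pop.append(mutate(child, pm, rng, cfg.mutation_scale))
        population = new_pop[:cfg.pop_size]

        fits = [fitness_fn(ind) for ind in population]
        gen_best = float(np.min(fits))
        if gen_best < best_trajectory[-1] - 1e-15:
            stagnation = 0
        else:
            stagnation += 1
        best_trajectory.append(min(gen_best, best_trajectory[-1]))

        population, triggered = catastrophe(population, fits, stagnation, cfg,
                                            rng, init_fn)
        if triggered:
            stagnation = 0
            fits = [fitness_fn(ind) for ind in population]

    best_idx = int(np.argmin(fits))
    return GAResult(
        best_chromosome=population[best_idx].copy(),
        best_fitness_per_generation=best_trajectory,
        final_population=population,
        final_fitness=[float(f) for f in fits],
        seed=cfg.seed,
    )


def flatten_weights(model: Model) -> np.ndarray:
    """Model weights as one flat chromosome (fixed layer-then-tensor order)."""
    return model.get_flat()


def unflatten(chromosome: np.ndarray, cfg: ModelConfig) -> Model:
    """Fresh model with the chromosome's weights loaded."""
    model = build_model(cfg)
    model.set_flat(chromosome)
    return model


def run_ga(model_cfg: ModelConfig, X: np.ndarray, y: np.ndarray,
           cfg: GAConfig | None = None) -> GAResult:
    """Search initial CNN weights: the initial population is ``pop_size``
    independently seeded weight initializations; the best chromosome found is
    meant to seed gradient training."""
    cfg = cfg or GAConfig()
    y = np.asarray(y, dtype=float)
    scratch = build_model(model_cfg)
    seed_seq = np.random.SeedSequence(cfg.seed)
    init_seeds = seed_seq.generate_state(cfg.pop_size)

    def make_init(seed: int) -> np.ndarray:
        return build_model(replace(model_cfg, seed=int(seed) % 2**31)).get_flat()

    initial = [make_init(s) for s in init_seeds]
    init_std = float(np.std(np.stack(initial)))

    def init_fn(rng: np.random.Generator) -> np.ndarray:
        return build_model(
            replace(model_cfg, seed=int(rng.integers(0, 2**31)))
        ).get_flat()

    # cfg.mutation_scale is relative here: a fraction of the init-weight std
    ga_cfg = replace(cfg, mutation_scale=cfg.mutation_scale * init_std)
    return evolve(lambda c: fitness(c, X, y, scratch), initial, ga_cfg, init_fn)
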