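"""Binary-encoded genetic algorithm for criterion minimisation.

The search follows the classic binary-GA toolbox recipe: Gray-coded binary
chromosomes decoded onto [0, Wmax] per parameter, linear-ranking fitness
assignment, stochastic universal sampling, single-point crossover, per-bit
mutation, and fitness-based reinsertion of a partial offspring generation.
The best-ever individual is always retained, so the best-fitness trace is
non-increasing.  Failed simulations receive infinite objective value and
lose every selection.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .criteria import CriterionEvaluator, CriterionSettings, CriterionSpec, FitnessValue
from .ode_models import ODEModel, TimeSeries, ValidationError, try_simulate

__all__ = [
    "GAConfig",
    "GAResult",
    "EstimateRecord",
    "EstimateSet",
    "InferenceError",
    "run_ga",
    "multi_start",
    "make_objective",
]


logger = logging.getLogger(__name__)


class InferenceError(RuntimeError):
    """Raised when a GA run cannot proceed (e.g. no viable individual)."""


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm settings.

    ``mutation_rate`` of ``None`` resolves to ``0.7 / chromosome_length``.
    ``generation_gap`` is the fraction of the population replaced by
    offspring each generation (fitness-based reinsertion keeps the best
    parents).
    """

    population_size: int = 100
    generations: int = 300
    bits_per_param: int = 20
    crossover_rate: float = 0.7
    mutation_rate: float | None = None
    generation_gap: float = 0.9
    selective_pressure: float = 2.0
    seed: int | None = None
    elitism: bool = True

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.generations < 1:
            raise ValidationError("generations must be >= 1")
        if self.bits_per_param < 1:
            raise ValidationError("bits_per_param must be >= 1")
        for name in ("crossover_rate", "generation_gap"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1]")
        if self.mutation_rate is not None and not 0.0 <= self.mutation_rate <= 1.0:
            raise ValidationError("mutation_rate must lie in [0, 1]")
        if not 1.0 <= self.selective_pressure <= 2.0:
            raise ValidationError("selective_pressure must lie in [1, 2]")


@dataclass
class GAResult:
    """Outcome of one GA run."""

    best_params: np.ndarray
    best_fitness: float
    trace: np.ndarray  # per-generation best-so-far fitness, length generations + 1
    seed: int | None
    n_evaluations: int
    n_failures: int
    criterion_id: str


@dataclass(frozen=True)
class EstimateRecord:
    params: np.ndarray
    fitness: float
    criterion_id: str
    seed: int | None


@dataclass
class EstimateSet:
    """Estimates from repeated GA runs, kept sorted by ascending fitness."""

    records: list[EstimateRecord] = field(default_factory=list)
    failed_starts: int = 0

    def __post_init__(self) -> None:
        self.records = sorted(self.records, key=lambda r: r.fitness)

    def add(self, record: EstimateRecord) -> None:
        self.records.append(record)
        self.records.sort(key=lambda r: r.fitness)

    def top(self, k: int) -> "EstimateSet":
        if k > len(self.records):
            raise ValidationError(f"requested top {k} of only {len(self.records)} records")
        return EstimateSet(self.records[:k], failed_starts=self.failed_starts)

    @property
    def fitnesses(self) -> np.ndarray:
        return np.array([r.fitness for r in self.records])

    @property
    def params_matrix(self) -> np.ndarray:
        return np.array([r.params for r in self.records])

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Encoding
# ---------------------------------------------------------------------------


def decode_population(bits: np.ndarray, n_params: int, bits_per_param: int, wmax: np.ndarray) -> np.ndarray:
    """Decode Gray-coded chromosomes to parameter vectors on [0, Wmax]."""
    pop = bits.reshape(bits.shape[0], n_params, bits_per_param)
    binary = np.logical_xor.accumulate(pop, axis=2)  # Gray -> plain binary
    place = 2.0 ** np.arange(bits_per_param - 1, -1, -1)
    ints = binary @ place
    return ints / (2.0**bits_per_param - 1.0) * wmax


def encode_params(theta: np.ndarray, bits_per_param: int, wmax: np.ndarray) -> np.ndarray:
    """Inverse of :func:`decode_population` for a single vector (nearest grid point)."""
    levels = 2**bits_per_param - 1
    ints = np.rint(np.asarray(theta, dtype=float) / wmax * levels).astype(np.int64)
    ints = np.clip(ints, 0, levels)
    binary = (ints[:, None] >> np.arange(bits_per_param - 1, -1, -1)) & 1
    gray = binary.copy()
    gray[:, 1:] = binary[:, 1:] ^ binary[:, :-1]
    return gray.astype(bool).ravel()


# ---------------------------------------------------------------------------
# Objective plumbing
# ---------------------------------------------------------------------------


def make_objective(
    model: ODEModel,
    obs: TimeSeries,
    spec: CriterionSpec,
    settings: CriterionSettings | None = None,
    *,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> Callable[[np.ndarray], FitnessValue]:
    """Build the GA objective: simulate, then score against ``obs``.

    The simulation is sampled at the measurement knots (both splines are
    then built on the same grid, keeping the comparison symmetric) unless
    ``settings.solution_grid`` requests a denser solution grid for the
    continuous criteria.
    """
    settings = settings or CriterionSettings()
    evaluator = CriterionEvaluator(spec, obs, settings)
    if spec.mode == "continuous" and settings.solution_grid is not None:
        a, b = evaluator.obs_traj.span
        t_eval = np.union1d(obs.times, np.linspace(a, b, settings.solution_grid))
    else:
        t_eval = obs.times

    def objective(theta: np.ndarray) -> FitnessValue:
        sim = try_simulate(model, theta, t_eval, rtol=rtol, atol=atol)
        return evaluator.evaluate(sim)

    return objective


def _linear_ranking_merit(fitness: np.ndarray, sp: float) -> np.ndarray:
    """Merit values in [2-sp, sp]; lowest objective gets the highest merit."""
    n = fitness.size
    order = np.argsort(np.argsort(-fitness, kind="stable"), kind="stable")
    # order[i] = rank of individual i with worst = 0, best = n-1
    if n == 1:
        return np.ones(1)
    return 2.0 - sp + 2.0 * (sp - 1.0) * order / (n - 1.0)


def _sus_select(merit: np.ndarray, n_select: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling; returns selected indices (shuffled)."""
    total = float(np.sum(merit))
    if total <= 0:
        idx = rng.integers(0, merit.size, size=n_select)
        return idx
    cum = np.cumsum(merit)
    step = total / n_select
    start = rng.uniform(0.0, step)
    pointers = start + step * np.arange(n_select)
    idx = np.searchsorted(cum, pointers, side="right")
    idx = np.clip(idx, 0, merit.size - 1)
    rng.shuffle(idx)
    return idx


def run_ga(
    model: ODEModel,
    obs: TimeSeries,
    spec: CriterionSpec,
    config: GAConfig | None = None,
    *,
    settings: CriterionSettings | None = None,
    objective: Callable[[np.ndarray], FitnessValue] | None = None,
    wmax: np.ndarray | None = None,
) -> GAResult:
    """Minimise ``spec`` over the model's parameter box with a binary GA.

    Returns the best individual ever seen and the per-generation
    best-so-far fitness trace.  Runs with identical seeds are
    bit-reproducible.
    """
    config = config or GAConfig()
    if objective is None:
        objective = make_objective(model, obs, spec, settings)
    wmax = np.broadcast_to(
        model.wmax if wmax is None else np.asarray(wmax, dtype=float), (model.n_params,)
    )
    m = model.n_params
    nbits = config.bits_per_param
    chrom_len = m * nbits
    pop_size = config.population_size
    pmut = config.mutation_rate if config.mutation_rate is not None else 0.7 / chrom_len
    rng = np.random.default_rng(config.seed)

    n_eval = 0
    n_fail = 0

    def eval_all(bits: np.ndarray) -> np.ndarray:
        nonlocal n_eval, n_fail
        thetas = decode_population(bits, m, nbits, wmax)
        out = np.empty(bits.shape[0])
        for i, theta in enumerate(thetas):
            fv = objective(theta)
            out[i] = fv.total
            n_eval += 1
            if fv.failed:
                n_fail += 1
        return out

    pop = rng.random((pop_size, chrom_len)) < 0.5
    fitness = eval_all(pop)
    if not np.any(np.isfinite(fitness)):
        raise InferenceError(
            "all individuals failed simulation in generation 0; "
            "check parameter bounds and solver settings"
        )

    best_idx = int(np.argmin(fitness))
    best_bits = pop[best_idx].copy()
    best_fit = float(fitness[best_idx])
    trace = [best_fit]

    n_offspring = max(2, int(round(config.generation_gap * pop_size)))
    n_offspring -= n_offspring % 2  # crossover pairs

    for _ in range(config.generations):
        merit = _linear_ranking_merit(fitness, config.selective_pressure)
        parents_idx = _sus_select(merit, n_offspring, rng)
        offspring = pop[parents_idx].copy()
        # single-point crossover on consecutive pairs
        do_cx = (rng.random(n_offspring // 2) < config.crossover_rate) & (chrom_len > 1)
        points = rng.integers(1, max(chrom_len, 2), size=n_offspring // 2)
        for k in np.nonzero(do_cx)[0]:
            i, j = 2 * k, 2 * k + 1
            cut = points[k]
            tail_i = offspring[i, cut:].copy()
            offspring[i, cut:] = offspring[j, cut:]
            offspring[j, cut:] = tail_i
        # per-bit mutation
        flip = rng.random(offspring.shape) < pmut
        offspring ^= flip
        off_fitness = eval_all(offspring)
        # fitness-based reinsertion: keep the best parents, insert offspring
        keep = np.argsort(fitness, kind="stable")[: pop_size - n_offspring]
        pop = np.vstack([pop[keep], offspring])
        fitness = np.concatenate([fitness[keep], off_fitness])
        gen_best = int(np.argmin(fitness))
        if fitness[gen_best] < best_fit:
            best_fit = float(fitness[gen_best])
            best_bits = pop[gen_best].copy()
        elif config.elitism:
            # re-insert the best-ever individual over the current worst
            worst = int(np.argmax(fitness))
            if fitness[worst] > best_fit:
                pop[worst] = best_bits
                fitness[worst] = best_fit
        trace.append(best_fit)
        if logger.isEnabledFor(logging.DEBUG):
            best_now = decode_population(pop[np.argmin(fitness)][None, :], m, nbits, wmax)[0]
            fv = objective(best_now)
            logger.debug(
                "gen %d: best %.6g per-term %s", len(trace) - 1, best_fit, fv.per_term
            )

    best_params = decode_population(best_bits[None, :], m, nbits, wmax)[0]
    return GAResult(
        best_params=best_params,
        best_fitness=best_fit,
        trace=np.array(trace),
        seed=config.seed,
        n_evaluations=n_eval,
        n_failures=n_fail,
        criterion_id=spec.id,
    )


def derive_start_seed(base_seed: int | None, start_index: int) -> int:
    """Deterministic per-start seed derivation from a single global seed."""
    base = 0 if base_seed is None else int(base_seed)
    ss = np.random.SeedSequence(entropy=base, spawn_key=(start_index,))
    return int(ss.generate_state(1, dtype=np.uint64)[0] % (2**63))


def multi_start(
    model: ODEModel,
    obs: TimeSeries,
    spec: CriterionSpec,
    config: GAConfig | None = None,
    n_starts: int = 100,
    *,
    base_seed: int | None = None,
    settings: CriterionSettings | None = None,
    objective: Callable[[np.ndarray], FitnessValue] | None = None,
) -> EstimateSet:
    """Run ``n_starts`` independently seeded GA searches; collect all estimates.

    A start that aborts (all simulations failing) is recorded in
    ``failed_starts`` rather than raising.
    """
    if n_starts < 1:
        raise ValidationError("n_starts must be >= 1")
    config = config or GAConfig()
    estimates = EstimateSet()
    if objective is None:
        objective = make_objective(model, obs, spec, settings)
    for i in range(n_starts):
        seed = derive_start_seed(base_seed, i)
        cfg = replace(config, seed=seed)
        try:
            result = run_ga(model, obs, spec, cfg, objective=objective)
        except InferenceError:
            estimates.failed_starts += 1
            continue
        estimates.add(
            EstimateRecord(
                params=result.best_params,
                fitness=result.best_fitness,
                criterion_id=spec.id,
                seed=seed,
            )
        )
    return estimates
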