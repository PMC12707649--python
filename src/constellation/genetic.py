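"""Evolutionary search in a generator's latent space.

Each generation: every candidate latent is decoded to an image, the
image's edge contours are scored against the constellation dots, the
top-K candidates become parents, and the next population is built from
parent copies perturbed by per-gene random mutation and (rarely) uniform
crossover.  The loop stops at the generation cap or once the best fitness
has not improved for `patience` consecutive generations.

Defaults follow the tuned search setting: population 1000, 200 parents,
mutation rate 0.5 (random additive), crossover rate 0.01 (uniform),
at most 30 generations, patience 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data import ConstellationImage
from .errors import ContractError, InputError
from .fitness import FitnessConfig, FitnessResult, score_candidate
from .generators import ClassifierHandle, GeneratorHandle


@dataclass
class GAConfig:
    population_size: int = 1000
    n_parents: int = 200
    mutation_rate: float = 0.5      # per-gene probability of perturbation
    mutation_type: str = "random"   # additive uniform [-1, 1]
    crossover_rate: float = 0.01    # per-offspring probability
    crossover_type: str = "uniform"
    max_generations: int = 30
    patience: int = 5
    batch_size: int = 100           # fitness-evaluation chunk
    elitism: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.n_parents < self.population_size):
            raise ContractError("need 0 < n_parents < population_size")
        for r in (self.mutation_rate, self.crossover_rate):
            if not (0.0 <= r <= 1.0):
                raise ContractError("rates must lie in [0, 1]")
        if self.patience > self.max_generations:
            raise ContractError("patience must be <= max_generations")
        if self.mutation_type != "random":
            raise ContractError(f"unknown mutation_type {self.mutation_type!r}")
        if self.crossover_type != "uniform":
            raise ContractError(f"unknown crossover_type {self.crossover_type!r}")


@dataclass
class GenerationRecord:
    generation: int
    best_latent: np.ndarray
    best_fitness: int
    best_label: str | None
    topk_fitness: np.ndarray
    topk_latents: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "generation": self.generation,
            "best_fitness": int(self.best_fitness),
            "best_label": self.best_label,
            "best_latent": [float(v) for v in self.best_latent],
            "topk_fitness": [int(v) for v in self.topk_fitness],
        }


@dataclass
class SearchTrace:
    records: list[GenerationRecord] = field(default_factory=list)
    termination: str = ""           # "max_generations" | "patience"

    def __len__(self):
        return len(self.records)

    @property
    def best_fitness_history(self) -> np.ndarray:
        return np.array([r.best_fitness for r in self.records], dtype=int)


@dataclass
class SolveResult:
    best_latent: np.ndarray
    best_image: np.ndarray          # generator-resolution greyscale
    label: str | None
    label_score: float
    fitness: int
    fitness_result: FitnessResult
    trace: SearchTrace
    method: str = "genetic"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "label": self.label,
            "label_score": float(self.label_score),
            "fitness": int(self.fitness),
            "matched_dots": [int(i) for i in self.fitness_result.matched],
            "contributing_dots":
                [int(i) for i in self.fitness_result.contributing],
            "best_latent": [float(v) for v in self.best_latent],
            "generations": len(self.trace),
            "termination": self.trace.termination,
        }


# ---------------------------------------------------------------------------
# GA primitives
# ---------------------------------------------------------------------------

def initialize_population(generator: GeneratorHandle, n: int,
                          seed: int | np.random.Generator) -> np.ndarray:
    """Draw `n` latents from the generator's prior; reproducible."""
    if n < 1:
        raise ContractError("population size must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    return generator.sample_latents(n, rng)


def select_parents(population: np.ndarray, fitnesses: np.ndarray,
                   k: int) -> np.ndarray:
    """Indices of the K fittest members; ties keep the lower index."""
    population = np.atleast_2d(population)
    fitnesses = np.asarray(fitnesses)
    if len(population) != len(fitnesses):
        raise ContractError("population and fitnesses length mismatch")
    if k > len(population):
        raise ContractError("K exceeds population size")
    order = np.argsort(-fitnesses, kind="stable")
    return order[:k]


def mutate(z: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Each gene independently gets an additive uniform [-1, 1] kick with
    probability `rate`."""
    if not (0.0 <= rate <= 1.0):
        raise ContractError("mutation rate must lie in [0, 1]")
    z = np.asarray(z, dtype=float).copy()
    mask = rng.random(z.shape) < rate
    z[mask] += rng.uniform(-1.0, 1.0, size=int(mask.sum()))
    return z


def crossover(parent_a: np.ndarray, parent_b: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Uniform crossover: each gene copied from either parent with p=0.5."""
    parent_a = np.asarray(parent_a, dtype=float)
    parent_b = np.asarray(parent_b, dtype=float)
    if parent_a.shape != parent_b.shape:
        raise ContractError("parent dimension mismatch")
    take_a = rng.random(parent_a.shape) < 0.5
    return np.where(take_a, parent_a, parent_b)


@dataclass
class _GAState:
    population: np.ndarray     # (N, dim), ranked: parents first
    fitnesses: np.ndarray      # (N,), aligned with population
    rng: np.random.Generator


def _evaluate(latents: np.ndarray, generator: GeneratorHandle,
              stimulus: ConstellationImage, fcfg: FitnessConfig,
              batch_size: int) -> np.ndarray:
    """Fitness of each latent, evaluated in chunks of `batch_size`.

    Scoring is deterministic, so chunking cannot change results; it only
    bounds peak memory for the decoded image batches.
    """
    out = np.empty(len(latents), dtype=int)
    for start in range(0, len(latents), batch_size):
        chunk = latents[start:start + batch_size]
        images = generator.generate_batch(chunk)
        for i, img in enumerate(images):
            out[start + i] = score_candidate(img, stimulus, fcfg).score
    return out


def step_generation(state: _GAState, cfg: GAConfig,
                    generator: GeneratorHandle, stimulus: ConstellationImage,
                    fcfg: FitnessConfig) -> _GAState:
    """One generation: select parents, breed offspring, evaluate.

    Parents keep their cached fitness (scoring is deterministic); with
    elitism they are carried into the next population unchanged, which
    makes the best-fitness sequence non-decreasing.
    """
    n, k = cfg.population_size, cfg.n_parents
    parent_idx = select_parents(state.population, state.fitnesses, k)
    parents = state.population[parent_idx]
    parent_fit = state.fitnesses[parent_idx]
    rng = state.rng

    n_off = n - k if cfg.elitism else n
    offspring = np.empty((n_off, parents.shape[1]))
    for i in range(n_off):
        child = parents[rng.integers(k)]
        if rng.random() < cfg.crossover_rate:
            other = parents[rng.integers(k)]
            child = crossover(child, other, rng)
        offspring[i] = mutate(child, cfg.mutation_rate, rng)
    off_fit = _evaluate(offspring, generator, stimulus, fcfg, cfg.batch_size)

    if cfg.elitism:
        population = np.vstack([parents, offspring])
        fitnesses = np.concatenate([parent_fit, off_fit])
    else:
        population, fitnesses = offspring, off_fit
    return _GAState(population=population, fitnesses=fitnesses, rng=rng)


# ---------------------------------------------------------------------------
# Full solve
# ---------------------------------------------------------------------------

def run_gensearch(stimulus: ConstellationImage, generator: GeneratorHandle,
                  classifier: ClassifierHandle | None,
                  cfg: GAConfig | None = None,
                  fcfg: FitnessConfig | None = None,
                  record_topk_latents: bool = False) -> SolveResult:
    """Solve one constellation by evolutionary search in latent space.

    Runs at most `max_generations` generations and stops early once the
    best fitness has gone `patience` consecutive generations without
    improving.  The final category label comes from the classifier applied
    to the best generated greyscale image (never to its edge map).
    """
    cfg = cfg or GAConfig()
    fcfg = fcfg or FitnessConfig()
    if len(stimulus.dots) < 2:
        raise InputError("stimulus needs at least 2 dots")

    rng = np.random.default_rng(cfg.seed)
    population = initialize_population(generator, cfg.population_size, rng)
    fitnesses = _evaluate(population, generator, stimulus, fcfg,
                          cfg.batch_size)
    state = _GAState(population=population, fitnesses=fitnesses, rng=rng)

    trace = SearchTrace()
    best_fit = -1
    best_latent = None
    stall = 0
    termination = "max_generations"
    for gen in range(1, cfg.max_generations + 1):
        if gen > 1:
            state = step_generation(state, cfg, generator, stimulus, fcfg)
        top = select_parents(state.population, state.fitnesses, cfg.n_parents)
        gen_best_idx = top[0]
        gen_best_fit = int(state.fitnesses[gen_best_idx])
        if gen_best_fit > best_fit:
            best_fit = gen_best_fit
            best_latent = state.population[gen_best_idx].copy()
            stall = 0
        else:
            stall += 1
        best_label = None
        if classifier is not None:
            best_label, _ = classifier.classify(generator.generate(best_latent))
        trace.records.append(GenerationRecord(
            generation=gen,
            best_latent=best_latent.copy(),
            best_fitness=best_fit,
            best_label=best_label,
            topk_fitness=state.fitnesses[top].copy(),
            topk_latents=state.population[top].copy()
            if record_topk_latents else None))
        if stall >= cfg.patience:
            termination = "patience"
            break
    trace.termination = termination

    best_image = generator.generate(best_latent)
    fres = score_candidate(best_image, stimulus, fcfg)
    label, score = (None, 0.0)
    if classifier is not None:
        label, score = classifier.classify(best_image)
    return SolveResult(best_latent=best_latent, best_image=best_image,
                       label=label, label_score=score, fitness=fres.score,
                       fitness_result=fres, trace=trace, method="genetic")
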