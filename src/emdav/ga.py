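"""Evolutionary search over feature subsets, architectures and validation.

A generational binary GA minimizing network fitness (mean test MSE):
linear-rank selection, uniform crossover, uniform random mutation, elitism,
and stall-based stopping. Each generation: evaluate -> log -> copy elites ->
rank-select parents -> crossover -> mutate -> replace non-elite slots.
Fitness evaluations are cached on the genome's active (decoded) region so
duplicate phenotypes never retrain.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .encoding import EncodingSpec, Genome, decode, random_genome
from .nn import FitnessRecord, TrainConfig, fitness_holdout, fitness_kfold


@dataclass(frozen=True)
class GAConfig:
    """GA hyperparameters. Defaults: population 50, uniform crossover at
    0.8, mutation at 0.1, 10% elitism, linear-rank selection with pressure
    2.0, up to 100 generations, stopping after 5 generations without a
    best-MSE improvement above ``stall_epsilon``."""

    population_size: int = 50
    crossover_prob: float = 0.8
    mutation_prob: float = 0.1
    elitism_fraction: float = 0.10
    selection_pressure: float = 2.0
    max_generations: int = 100
    stall_generations: int = 5
    stall_epsilon: float = 1e-4
    mutation_mode: str = "per_individual"  # or "per_bit"
    #: cache fitness on the decoded (active) region only; set False when the
    #: fitness function reads raw bits beyond it (e.g. surrogate fitnesses)
    cache_on_active_region: bool = True
    max_evaluations: int = 20000
    n_holdout_repetitions: int = 20
    k_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        for p in (self.crossover_prob, self.mutation_prob, self.elitism_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.stall_generations < 1 or self.population_size < 2:
            raise ValueError("need stall_generations >= 1 and population >= 2")
        if not 1.0 <= self.selection_pressure <= 2.0:
            raise ValueError("selection_pressure must lie in [1, 2]")
        if self.mutation_mode not in ("per_individual", "per_bit"):
            raise ValueError(f"unknown mutation_mode {self.mutation_mode!r}")

    @property
    def n_elites(self) -> int:
        if self.elitism_fraction == 0:
            return 0
        # at least one elite whenever elitism is on, so the best individual
        # always survives and the best-fitness trace is non-increasing
        return max(1, int(round(self.elitism_fraction * self.population_size)))


# ---------------------------------------------------------------------------
# Operators
# ---------------------------------------------------------------------------

def rank_probabilities(n: int, pressure: float) -> np.ndarray:
    """Linear-rank selection probabilities, index 0 = best individual.

    p(i) = (1/n) * (SP - (2 SP - 2) * i/(n-1)); at SP=2 the worst gets 0.
    """
    if n == 1:
        return np.array([1.0])
    i = np.arange(n)
    p = (pressure - (2.0 * pressure - 2.0) * i / (n - 1)) / n
    return p / p.sum()


def linear_rank_select(fitnesses, n_parents: int, rng: np.random.Generator,
                       pressure: float = 2.0) -> np.ndarray:
    """Sample parent indices with replacement, probability linear in rank
    (ascending MSE: best = most likely). Ties keep first-come order."""
    fitnesses = np.asarray(fitnesses, float)
    if fitnesses.size == 0:
        raise ValueError("empty population")
    if n_parents < 2:
        raise ValueError("need at least 2 parents")
    order = np.argsort(fitnesses, kind="stable")  # best first
    probs = rank_probabilities(fitnesses.size, pressure)
    # tied individuals share the average probability of their tied ranks,
    # so equal fitnesses select uniformly rather than by array position
    per_individual = np.empty(fitnesses.size)
    sorted_fits = fitnesses[order]
    i = 0
    while i < fitnesses.size:
        j = i
        while j < fitnesses.size and sorted_fits[j] == sorted_fits[i]:
            j += 1
        per_individual[order[i:j]] = probs[i:j].mean()
        i = j
    per_individual /= per_individual.sum()
    return rng.choice(fitnesses.size, size=n_parents, replace=True,
                      p=per_individual)


def uniform_crossover(p1: Genome, p2: Genome, prob: float,
                      rng: np.random.Generator):
    """With probability ``prob``, each position independently swaps or keeps
    the parental alleles; otherwise the children are clones."""
    if p1.bits.shape != p2.bits.shape:
        raise ValueError("genome length mismatch")
    if rng.random() >= prob:
        return Genome(p1.bits.copy(), p1.spec), Genome(p2.bits.copy(), p2.spec)
    swap = rng.random(p1.bits.shape[0]) < 0.5
    c1 = np.where(swap, p2.bits, p1.bits)
    c2 = np.where(swap, p1.bits, p2.bits)
    return Genome(c1, p1.spec), Genome(c2, p2.spec)


def mutate(g: Genome, prob: float, rng: np.random.Generator,
           mode: str = "per_individual") -> Genome:
    """Uniform random mutation.

    ``per_individual`` (default): with probability ``prob`` the individual
    mutates, and then each bit flips independently at rate 1/length
    (expected one flip per mutated individual). ``per_bit``: every bit
    flips independently at rate ``prob``.
    """
    bits = g.bits.copy()
    L = bits.shape[0]
    if mode == "per_individual":
        if rng.random() < prob:
            flips = rng.random(L) < 1.0 / L
            bits[flips] ^= 1
    else:
        flips = rng.random(L) < prob
        bits[flips] ^= 1
    return Genome(bits, g.spec)


# ---------------------------------------------------------------------------
# Evolution loop
# ---------------------------------------------------------------------------

@dataclass
class EvolutionResult:
    """Audit log of one evolutionary run."""

    generations: list = field(default_factory=list)  # per-generation summary dicts
    individuals: list = field(default_factory=list)  # per-individual log rows
    best_genome: Genome | None = None
    best_record: FitnessRecord | None = None
    termination_reason: str = ""
    n_evaluations: int = 0      # distinct phenotype evaluations (cache misses)
    n_training_runs: int = 0    # network training runs inside those

    @property
    def best_phenotype(self):
        return decode(self.best_genome) if self.best_genome is not None else None

    @property
    def best_fitness_trace(self):
        return [g["best_mse"] for g in self.generations]

    def individuals_table(self):
        import pandas as pd
        return pd.DataFrame(self.individuals)


def default_fitness(ds, train_cfg: TrainConfig, ga_cfg: GAConfig):
    """Build the genome -> FitnessRecord map used by the search.

    The phenotype's own validation bit selects between repeated hold-out
    (50/25/25) and k-fold evaluation; infeasible phenotypes (empty feature
    mask) get the worst-fitness sentinel without training.
    """
    def fitness(genome: Genome, seed: int) -> FitnessRecord:
        phenotype = decode(genome)
        if not phenotype.feasible:
            return FitnessRecord.infeasible(phenotype.architecture_label())
        if phenotype.validation == "holdout":
            return fitness_holdout(phenotype, ds, train_cfg,
                                   n_repetitions=ga_cfg.n_holdout_repetitions,
                                   seed=seed)
        return fitness_kfold(phenotype, ds, train_cfg, k=ga_cfg.k_folds,
                             seed=seed)
    return fitness


def evolve(ds, ga_cfg: GAConfig, train_cfg: TrainConfig,
           encoding: EncodingSpec, fitness_fn=None) -> EvolutionResult:
    """Run one evolutionary search; returns the audit :class:`EvolutionResult`.

    ``fitness_fn(genome, seed) -> FitnessRecord`` may replace the default
    network fitness (e.g. with a transparent surrogate for testing).
    """
    if ds is not None and ds.n_features != encoding.n_feature_bits:
        raise ValueError("encoding.n_feature_bits must equal the dataset's feature count")
    if fitness_fn is None:
        if ds is None:
            raise ValueError("need a dataset or an explicit fitness_fn")
        if ds.stage != "scaled":
            raise ValueError("dataset must be scaled before evolution")
        fitness_fn = default_fitness(ds, train_cfg, ga_cfg)

    rng = np.random.default_rng(ga_cfg.seed)
    cache: dict[bytes, FitnessRecord] = {}
    result = EvolutionResult()

    def eval_genome(g: Genome) -> FitnessRecord:
        key = g.key(active_only=ga_cfg.cache_on_active_region)
        if key in cache:
            return cache[key]
        if result.n_evaluations >= ga_cfg.max_evaluations:
            raise _BudgetExhausted
        seed = (ga_cfg.seed * 2654435761 + zlib.crc32(key)) % (2 ** 31)
        rec = fitness_fn(g, seed)
        result.n_evaluations += 1
        result.n_training_runs += rec.n_repetitions
        cache[key] = rec
        return rec

    population = [random_genome(encoding, rng)
                  for _ in range(ga_cfg.population_size)]
    best_mse_prev = np.inf
    stall = 0
    reason = "max_generations"
    try:
        for gen in range(ga_cfg.max_generations):
            records = [eval_genome(g) for g in population]
            fits = np.array([r.mean_mse for r in records])
            order = np.argsort(fits, kind="stable")
            best_i = int(order[0])
            for idx, (g, r) in enumerate(zip(population, records)):
                p = decode(g)
                result.individuals.append({
                    "generation": gen, "individual": idx,
                    "genome": g.to_string(),
                    "n_features": p.n_selected,
                    "validation": p.validation,
                    "hidden_layers": p.architecture_label(),
                    "mse": r.mean_mse, "r2": r.mean_r2})
            result.generations.append({
                "generation": gen,
                "best_mse": float(fits[best_i]),
                "mean_mse": float(fits.mean()),
                "worst_mse": float(fits.max()),
                "best_genome": population[best_i].to_string(),
                "evaluations": result.n_evaluations})
            if (result.best_record is None
                    or fits[best_i] < result.best_record.mean_mse):
                result.best_genome = population[best_i]
                result.best_record = records[best_i]

            improvement = best_mse_prev - fits[best_i]
            if improvement < ga_cfg.stall_epsilon:
                stall += 1
                if stall >= ga_cfg.stall_generations:
                    reason = "stall"
                    break
            else:
                stall = 0
            best_mse_prev = min(best_mse_prev, float(fits[best_i]))

            # next generation: elites survive unmodified and stay eligible parents
            elites = [Genome(population[i].bits.copy(), encoding)
                      for i in order[:ga_cfg.n_elites]]
            n_children = ga_cfg.population_size - len(elites)
            children = []
            while len(children) < n_children:
                pa, pb = linear_rank_select(fits, 2, rng,
                                            ga_cfg.selection_pressure)
                c1, c2 = uniform_crossover(population[pa], population[pb],
                                           ga_cfg.crossover_prob, rng)
                children.append(mutate(c1, ga_cfg.mutation_prob, rng,
                                       ga_cfg.mutation_mode))
                if len(children) < n_children:
                    children.append(mutate(c2, ga_cfg.mutation_prob, rng,
                                           ga_cfg.mutation_mode))
            population = elites + children
    except _BudgetExhausted:
        reason = "evaluation_budget"
    result.termination_reason = reason
    return result


class _BudgetExhausted(Exception):
    pass


def run_emdav(ds, ga_cfg: GAConfig, train_cfg: TrainConfig,
              encoding: EncodingSpec, n_executions: int = 20,
              fitness_fn=None):
    """Independent seeded executions of :func:`evolve`.

    Returns ``(results, report)`` where ``report`` is a DataFrame of the
    top phenotypes across all executions sorted ascending by MSE, with
    generation/individual provenance (the consolidated run report).
    """
    import pandas as pd
    results = []
    for i in range(n_executions):
        cfg_i = replace(ga_cfg, seed=(ga_cfg.seed * 1000003 + i) % (2 ** 31))
        results.append(evolve(ds, cfg_i, train_cfg, encoding,
                              fitness_fn=fitness_fn))
    rows = []
    for i, res in enumerate(results):
        for row in res.individuals:
            rows.append({"execution": i, **row})
    table = (pd.DataFrame(rows)
             .sort_values("mse", kind="stable")
             .drop_duplicates(subset="genome")
             .head(10)
             .reset_index(drop=True))
    return results, table
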