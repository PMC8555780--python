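"""Genetic algorithm over the space of mutation categorizations.

Individuals are 96-category categorizations (95 sampled degenerate
patterns plus the joker).  Fitness is the exposure-expression agreement
of `ddcat.fitness`; selection is rank-power based with two-elite
carry-over; variation is category-level crossover plus symbol-level
intersecting mutations.  Categorizations are kept below a 1% ambiguous
assignment rate by greedy replacement of the most conflict-involved
category.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .fitness import (DatasetBundle, FitnessConfig, categorization_fitness,
                      rank_population, selection_probabilities)
from .patterns import (BASES, CategoryPattern, Categorization, JOKER_TEXT,
                       IUPAC_TO_BASES, BASES_TO_IUPAC, assign_universe,
                       parse_pattern)

_SINGLE = list("ACGT")
_PAIRS = list("RYSWKM")
_FLANK_CHOICES = _SINGLE + _PAIRS


@dataclass
class GAConfig:
    population_size: int = 40
    n_ancestors: int = 100
    n_generations: int = 500
    crossover_rate: float = 0.8         # q
    mutation_rate: float = 0.05         # m
    power: float = 5.0
    concentration: float = 10.0         # c
    conflict_threshold: float = 0.01
    max_conflict_rounds: int = 200
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.crossover_rate <= 1 and 0 <= self.mutation_rate <= 1):
            raise ValueError("q and m must lie in [0, 1]")
        if self.power <= 0 or self.concentration < 1:
            raise ValueError("power must be > 0 and c >= 1")
        if self.population_size < 3:
            raise ValueError("population size must be at least 3")


@dataclass
class Individual:
    categorization: Categorization
    fitness: dict = field(default_factory=dict)   # dataset name -> score
    generation_born: int = 0
    origin: str = "ancestor"

    @property
    def key(self) -> tuple:
        """Cache key: the canonical pattern multiset."""
        return tuple(sorted(p.text for p in self.categorization.patterns))


class ConflictResolutionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Ancestor sampling
# ---------------------------------------------------------------------------

def sample_category(c: float, rng: np.random.Generator) -> CategoryPattern:
    """Sample one degenerate category pattern.

    An interval of ``n_symbols`` consecutive non-N symbols (3-7, weighted
    (1, c, 1, 1, 1) with the mode at 4) is placed uniformly among the
    starts that cover the mutation positions 4 and 5; interval symbols are
    drawn uniformly from the 4 single-base and 6 dinucleotide codes,
    subject to a C/T original base and a new base disjoint from it.
    """
    weights = np.array([1.0, float(c), 1.0, 1.0, 1.0])
    n_symbols = int(rng.choice(np.arange(3, 8), p=weights / weights.sum()))
    starts = np.arange(max(0, 5 - n_symbols), min(3, 8 - n_symbols) + 1)
    start = int(rng.choice(starts))
    symbols = ["N"] * 8
    ref = str(rng.choice(["C", "T"]))
    for pos in range(start, start + n_symbols):
        if pos == 3:
            symbols[pos] = ref
        elif pos == 4:
            legal = [s for s in _FLANK_CHOICES
                     if ref not in IUPAC_TO_BASES[s]]
            symbols[pos] = str(rng.choice(legal))
        else:
            symbols[pos] = str(rng.choice(_FLANK_CHOICES))
    return parse_pattern("".join(symbols))


def resolve_conflicts(patterns: list[CategoryPattern],
                      rng: np.random.Generator,
                      concentration: float,
                      threshold: float = 0.01,
                      max_rounds: int = 200) -> Categorization:
    """Replace conflict-involved categories until the ambiguous-assignment
    rate drops below ``threshold``.

    Each round rebuilds the universe assignment table, identifies the
    non-joker category involved in the most ambiguous ties, and replaces
    it with a freshly sampled category; residual ambiguous sequences keep
    a uniformly random tied winner.
    """
    from .patterns import _assign_from_match, _match_matrix, _match_row, \
        _pattern_keys
    pats = list(patterns)
    joker = [i for i, p in enumerate(pats) if p.is_joker]
    m = _match_matrix(pats)
    keys = _pattern_keys(pats)
    for _ in range(max_rounds):
        tie_seed = int(rng.integers(0, 2**31 - 1))
        res = _assign_from_match(m, keys, np.random.default_rng(tie_seed))
        if res.conflict_rate < threshold:
            cat = Categorization(pats, name="sampled", tie_seed=tie_seed)
            cat._result = res
            return cat
        counts = res.tie_counts.copy()
        for j in joker:
            counts[j] = -1
        worst = int(np.argmax(counts))
        new = sample_category(concentration, rng)
        pats[worst] = new
        m[worst] = _match_row(new)
        keys[worst] = _pattern_keys([new])[0]
    raise ConflictResolutionError(
        f"conflict rate still >= {threshold} after {max_rounds} rounds")


def sample_categorization(config: GAConfig,
                          rng: np.random.Generator) -> Individual:
    """95 sampled categories plus the joker, conflict-resolved."""
    pats = [sample_category(config.concentration, rng) for _ in range(95)]
    pats.append(parse_pattern(JOKER_TEXT))
    cat = resolve_conflicts(pats, rng, config.concentration,
                            config.conflict_threshold,
                            config.max_conflict_rounds)
    return Individual(categorization=cat)


# ---------------------------------------------------------------------------
# Variation operators
# ---------------------------------------------------------------------------

def crossover(parent_hi: Individual, parent_lo: Individual,
              rng: np.random.Generator, config: GAConfig,
              generation: int = 0) -> Individual:
    """Category-level crossover.

    A random fraction in (0, 0.4] of the 95 non-joker slots is filled from
    the lower-fitness parent, the rest from the higher-fitness one;
    duplicate patterns collapse and any shortfall is filled with freshly
    sampled categories.
    """
    u = 0.4 * (1.0 - rng.random())           # (0, 0.4]
    n_lo = int(round(u * 95))
    lo_texts = sorted({p.text for p in parent_lo.categorization.patterns
                       if not p.is_joker})
    hi_texts = sorted({p.text for p in parent_hi.categorization.patterns
                       if not p.is_joker})
    take_lo = list(rng.choice(lo_texts, size=min(n_lo, len(lo_texts)),
                              replace=False))
    chosen = dict.fromkeys(take_lo)
    for t in rng.permutation(hi_texts):
        if len(chosen) >= 95:
            break
        chosen.setdefault(str(t))
    while len(chosen) < 95:
        chosen.setdefault(sample_category(config.concentration, rng).text)
    pats = [parse_pattern(t) for t in chosen] + [parse_pattern(JOKER_TEXT)]
    cat = resolve_conflicts(pats, rng, config.concentration,
                            config.conflict_threshold,
                            config.max_conflict_rounds)
    return Individual(categorization=cat, generation_born=generation,
                      origin="crossover")


def _mutate_symbol(symbol: str, position: int, ref: str,
                   rng: np.random.Generator) -> str:
    """Replace a symbol with a different intersecting one (single <-> pair)."""
    bases = IUPAC_TO_BASES[symbol]
    if len(bases) == 1:
        targets = [p for p in _PAIRS if bases in IUPAC_TO_BASES[p]]
    else:
        targets = list(bases)
    if position == 4:
        targets = [t for t in targets if ref not in IUPAC_TO_BASES[t]]
    return str(rng.choice(targets))


def mutate(individual: Individual, m: float, rng: np.random.Generator,
           config: GAConfig, generation: int = 0) -> Individual:
    """Symbol-level mutation applied to each non-joker category w.p. ``m``.

    A uniformly chosen eligible position (non-N, excluding the original
    base) moves between a single base and an intersecting dinucleotide;
    the new-base position stays disjoint from the original base.
    """
    pats = list(individual.categorization.patterns)
    changed = False
    for i, p in enumerate(pats):
        if p.is_joker or rng.random() >= m:
            continue
        text = list(p.text)
        eligible = [j for j in range(8) if j != 3 and text[j] != "N"]
        j = int(rng.choice(eligible))
        text[j] = _mutate_symbol(text[j], j, text[3], rng)
        pats[i] = parse_pattern("".join(text))
        changed = True
    if not changed:
        return Individual(categorization=individual.categorization,
                          fitness=dict(individual.fitness),
                          generation_born=generation, origin="mutation")
    cat = resolve_conflicts(pats, rng, config.concentration,
                            config.conflict_threshold,
                            config.max_conflict_rounds)
    return Individual(categorization=cat, generation_born=generation,
                      origin="mutation")


# ---------------------------------------------------------------------------
# Generation loop
# ---------------------------------------------------------------------------

def _score_population(population: list[Individual],
                      datasets: list[DatasetBundle],
                      fitness_config: FitnessConfig,
                      cache: dict) -> np.ndarray:
    f = np.empty((len(population), len(datasets)))
    for i, ind in enumerate(population):
        for d, ds in enumerate(datasets):
            key = (ind.key, ds.name)
            if key not in cache:
                cache[key] = categorization_fitness(
                    ind.categorization, ds, fitness_config).value
            ind.fitness[ds.name] = cache[key]
            f[i, d] = cache[key]
    return f


def next_generation(population: list[Individual], fitness_matrix: np.ndarray,
                    datasets: list[DatasetBundle], config: GAConfig,
                    rng: np.random.Generator,
                    generation: int = 0) -> list[Individual]:
    """Elitism (top 2 of the average ranking) plus rank-power parent
    selection over the per-dataset and average rankings."""
    table = rank_population(fitness_matrix)
    s = len(population)
    order = np.argsort(table.average)
    elites = [population[order[-1]], population[order[-2]]]
    rankings = [table.per_dataset[:, d] for d in range(len(datasets))]
    rankings.append(table.average)
    new_pop = list(elites)
    while len(new_pop) < s:
        ranking = rankings[int(rng.integers(len(rankings)))]
        p = selection_probabilities(ranking, config.power)
        i1 = int(rng.choice(s, p=p))
        if rng.random() < config.crossover_rate and s > 1:
            p2 = p.copy()
            p2[i1] = 0.0
            p2 /= p2.sum()
            i2 = int(rng.choice(s, p=p2))
            hi, lo = (i1, i2) if ranking[i1] >= ranking[i2] else (i2, i1)
            child = crossover(population[hi], population[lo], rng, config,
                              generation)
        else:
            child = mutate(population[i1], config.mutation_rate, rng, config,
                           generation)
        new_pop.append(child)
    return new_pop


@dataclass
class EvolutionResult:
    best: Individual
    log: pd.DataFrame
    population: list[Individual]


def evolve(datasets: list[DatasetBundle], config: GAConfig,
           fitness_config: FitnessConfig | None = None,
           progress: bool = False) -> EvolutionResult:
    """Run the full genetic algorithm.

    Ancestors are sampled, scored and truncated to the population size by
    average ranking; each generation then applies elitism, selection,
    crossover and mutation.  Fitness values are cached by pattern multiset
    so elites are never re-scored.
    """
    if not datasets:
        raise ValueError("at least one dataset bundle is required")
    fc = fitness_config or FitnessConfig()
    rng = np.random.default_rng(config.seed)
    cache: dict = {}
    ancestors = [sample_categorization(config, rng)
                 for _ in range(config.n_ancestors)]
    f = _score_population(ancestors, datasets, fc, cache)
    table = rank_population(f)
    order = np.argsort(table.average)[::-1]
    population = [ancestors[i] for i in order[:config.population_size]]
    f = f[order[:config.population_size]]
    rows = []

    def log_row(gen, fmat):
        best_i = rank_population(fmat).best_index
        row = {"generation": gen,
               "best_mean_fitness": float(fmat[best_i].mean()),
               "mean_fitness": float(fmat.mean())}
        for d, ds in enumerate(datasets):
            row[f"best_fitness_{ds.name}"] = float(fmat[best_i, d])
        rows.append(row)

    log_row(0, f)
    for gen in range(1, config.n_generations + 1):
        population = next_generation(population, f, datasets, config, rng,
                                     generation=gen)
        f = _score_population(population, datasets, fc, cache)
        log_row(gen, f)
        if progress:  # pragma: no cover - cosmetic
            print(f"generation {gen}: best {rows[-1]['best_mean_fitness']:.4f}")
    best = population[rank_population(f).best_index]
    return EvolutionResult(best=best, log=pd.DataFrame(rows),
                           population=population)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path, population: list[Individual], generation: int,
                    rng: np.random.Generator, config: GAConfig) -> None:
    state = {"generation": generation,
             "config": asdict(config),
             "rng_state": rng.bit_generator.state,
             "population": [
                 {"patterns": [p.text for p in ind.categorization.patterns],
                  "fitness": ind.fitness,
                  "generation_born": ind.generation_born,
                  "origin": ind.origin}
                 for ind in population]}
    with open(path, "w") as fh:
        json.dump(state, fh)


def load_checkpoint(path):
    with open(path) as fh:
        state = json.load(fh)
    config = GAConfig(**state["config"])
    rng = np.random.default_rng()
    rng.bit_generator.state = state["rng_state"]
    population = [
        Individual(categorization=Categorization(
            [parse_pattern(t) for t in ind["patterns"]], name="checkpoint"),
            fitness=ind["fitness"],
            generation_born=ind["generation_born"], origin=ind["origin"])
        for ind in state["population"]]
    return population, state["generation"], rng, config
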