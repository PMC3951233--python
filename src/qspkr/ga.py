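"""Genetic-algorithm descriptor selection with an award/penalty pairwise fitness.

Each chromosome is a binary mask over the descriptor columns ("one" keeps the
descriptor). A chromosome's fitness is scored over every unordered pair of
compounds and every selected descriptor k:

* if the two compounds' normalised PK values differ by at least ``epsilon``
  the pair contributes ``-penalty``;
* otherwise (similar PK) it contributes ``award - |dd_ik - dd_jk|``, i.e. the
  full award minus the descriptor difference, so descriptors that keep
  PK-similar compounds close in descriptor space score highest.

Because the score is a plain sum over selected descriptors, each descriptor
has a fixed marginal contribution on a given dataset. ``FitnessEngine``
precomputes that per-descriptor contribution vector once, after which scoring
a whole population is a single matrix-vector product. Selecting more
descriptors usually lowers the score (each one carries the pair penalties),
which is the parsimony pressure that drives chromosomes toward small
subsets. The ``gene_limit`` (15 by default) is a floor on subset size —
it exists to stop the shrinkage short of abolishing every gene — and the
run ends once the best chromosome sits at that floor with no further
fitness improvement.

The evolutionary loop is: evaluate, tournament parent selection,
single-point crossover, single-gene point mutation, then survivor
selection (by default, truncation of the merged parent + offspring pool
back to the population size). All randomness flows through one seeded
generator so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_normalize import QSPkRDataset

__all__ = [
    "GAConfig",
    "Chromosome",
    "Population",
    "FitnessEngine",
    "GAResult",
    "init_population",
    "pair_term",
    "chromosome_fitness",
    "crossover",
    "mutate",
    "select_next_generation",
    "run_ga",
]

#: a chromosome is a 1-D uint8 array of 0/1 genes, one per descriptor
Chromosome = np.ndarray


@dataclass
class GAConfig:
    """Operator and fitness parameters for the descriptor-selection GA.

    Fitness and operator parameters follow the published procedure: 500
    chromosomes, crossover probability 1, per-chromosome mutation
    probability 0.1, award and penalty of 5, PK-similarity threshold
    ``epsilon`` = 0.1 on the [0, 1] scale, and a 15-gene limit enforced as
    a floor on subset size.

    The scheme parameters the procedure leaves open (selection, offspring
    surplus, convergence budget) default to values sized for the full-scale
    problem (~40 compounds x ~1,500 descriptors): size-8 tournaments,
    4,000 offspring per generation under plus-truncation survival, and a
    200-generation convergence patience. Smaller problems converge long
    before the caps; see the package methods notes for how these were
    chosen.
    """

    population_size: int = 500
    crossover_probability: float = 1.0
    mutation_probability: float = 0.1
    award: float = 5.0
    penalty: float = 5.0
    epsilon: float = 0.1
    gene_limit: int = 15
    max_generations: int = 2000
    elitism_count: int = 1
    tournament_size: int = 8
    # offspring bred per generation; None means population_size. With
    # truncation survival, a surplus of offspring supplies several competing
    # gene deletions per generation, which is what lets selection choose
    # *which* descriptor to drop rather than dropping the first one mutated
    offspring_per_generation: int | None = 4000
    # generations without best-fitness improvement, at the gene-limit floor,
    # before the run is declared converged
    patience: int = 200
    # "plus": next generation = best population_size of parents + children
    # (fully elitist, keeps every improving mutant); "generational": children
    # replace parents apart from the elitism_count copies. Plus-selection is
    # the default because the parsimony pressure advances roughly one gene
    # removal per surviving mutant — purely generational replacement loses
    # most of them and stalls far above the gene limit.
    survivor_strategy: str = "plus"
    # score the pair penalty once per dissimilar pair instead of once per
    # selected descriptor per pair (an alternative reading of the procedure)
    penalty_per_pair: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.crossover_probability <= 1.0:
            raise ValueError("crossover_probability must be in [0, 1]")
        if not 0.0 <= self.mutation_probability <= 1.0:
            raise ValueError("mutation_probability must be in [0, 1]")
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if self.award < 0 or self.penalty < 0:
            raise ValueError("award and penalty must be non-negative")
        if self.gene_limit < 1:
            raise ValueError("gene_limit must be >= 1")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.elitism_count < 0 or self.elitism_count >= self.population_size:
            raise ValueError("elitism_count must be in [0, population_size)")
        if self.survivor_strategy not in ("plus", "generational"):
            raise ValueError("survivor_strategy must be 'plus' or 'generational'")
        if self.tournament_size < 2:
            raise ValueError("tournament_size must be >= 2")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if (self.offspring_per_generation is not None
                and self.offspring_per_generation < 2):
            raise ValueError("offspring_per_generation must be >= 2")


@dataclass
class Population:
    """A generation of chromosomes with an optional fitness ledger."""

    chromosomes: np.ndarray  # (population_size, n_descriptors) uint8
    generation: int = 0
    fitness: np.ndarray | None = None

    @property
    def size(self) -> int:
        return self.chromosomes.shape[0]

    @property
    def n_descriptors(self) -> int:
        return self.chromosomes.shape[1]


@dataclass
class GAResult:
    """Outcome of a GA run."""

    selected_indices: list[int]
    selected_names: list[str]
    best_chromosome: np.ndarray
    best_fitness: float
    fitness_trajectory: list[float]
    best_gene_counts: list[int]
    generations: int
    termination_reason: str
    seed: int | None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "selected_indices": list(map(int, self.selected_indices)),
            "selected_names": list(self.selected_names),
            "best_fitness": float(self.best_fitness),
            "fitness_trajectory": [float(v) for v in self.fitness_trajectory],
            "best_gene_counts": [int(v) for v in self.best_gene_counts],
            "generations": int(self.generations),
            "termination_reason": self.termination_reason,
            "seed": self.seed,
            "warnings": list(self.warnings),
        }


def init_population(n_descriptors: int, config: GAConfig) -> Population:
    """Random initial generation: every gene i.i.d. uniform over {0, 1}."""
    if n_descriptors < 1:
        raise ValueError("n_descriptors must be >= 1")
    rng = np.random.default_rng(config.seed)
    genes = rng.integers(0, 2, size=(config.population_size, n_descriptors),
                         dtype=np.uint8)
    return Population(chromosomes=genes, generation=0)


def pair_term(dp_i: float, dp_j: float, dd_ik: float, dd_jk: float,
              config: GAConfig) -> float:
    """Score one compound pair for one descriptor.

    ``-penalty`` when the normalised PK values differ by at least epsilon,
    ``award - |dd_ik - dd_jk|`` otherwise.
    """
    if abs(dp_i - dp_j) >= config.epsilon:
        return -config.penalty
    return config.award - abs(dd_ik - dd_jk)


class FitnessEngine:
    """Precomputed per-descriptor fitness contributions for one dataset.

    For descriptor k the marginal contribution over all unordered compound
    pairs is ``award * n_similar - S_k - penalty * n_dissimilar`` where
    ``S_k`` sums the descriptor differences over PK-similar pairs. A
    chromosome's fitness is then the dot product of its genes with the
    contribution vector — identical, term for term, to the naive sum over
    pairs and selected descriptors.
    """

    def __init__(self, data: QSPkRDataset, config: GAConfig) -> None:
        self.config = config
        dp = data.dp
        n = data.n_compounds
        iu, ju = np.triu_indices(n, k=1)
        self.n_pairs = iu.size
        similar = np.abs(dp[iu] - dp[ju]) < config.epsilon
        self.n_similar_pairs = int(similar.sum())
        self.n_dissimilar_pairs = int(self.n_pairs - self.n_similar_pairs)
        # descriptor-difference sums over PK-similar pairs only
        if self.n_similar_pairs:
            diffs = np.abs(data.X[iu[similar]] - data.X[ju[similar]])
            s = diffs.sum(axis=0)
        else:
            s = np.zeros(data.n_descriptors)
        self.award_part = config.award * self.n_similar_pairs - s
        if config.penalty_per_pair:
            self.contributions = self.award_part
            self._flat_penalty = config.penalty * self.n_dissimilar_pairs
        else:
            self.contributions = (
                self.award_part - config.penalty * self.n_dissimilar_pairs
            )
            self._flat_penalty = 0.0

    def chromosome_fitness(self, genes: np.ndarray) -> float:
        genes = np.asarray(genes)
        if genes.shape[0] != self.contributions.shape[0]:
            raise ValueError("chromosome length does not match descriptor count")
        if not genes.any():
            return 0.0
        total = float(self.contributions[genes.astype(bool)].sum())
        return total - self._flat_penalty

    def population_fitness(self, chromosomes: np.ndarray) -> np.ndarray:
        fit = chromosomes.astype(float) @ self.contributions
        if self._flat_penalty:
            fit = np.where(chromosomes.any(axis=1), fit - self._flat_penalty, 0.0)
        else:
            fit[~chromosomes.any(axis=1)] = 0.0
        return fit


def chromosome_fitness(chrom: Chromosome, data: QSPkRDataset,
                       config: GAConfig) -> float:
    """Fitness of one chromosome (all-zero chromosomes score 0)."""
    if chrom.shape[0] != data.n_descriptors:
        raise ValueError("chromosome length does not match descriptor count")
    return FitnessEngine(data, config).chromosome_fitness(chrom)


def crossover(parent_a: Chromosome, parent_b: Chromosome,
              rng: np.random.Generator) -> tuple[Chromosome, Chromosome]:
    """Single-point crossover at a break point uniform in {1, ..., L-1}.

    Both segments are non-empty; child 1 takes the head of parent A.
    """
    if parent_a.shape != parent_b.shape:
        raise ValueError("parents must have equal length")
    L = parent_a.shape[0]
    if L < 2:
        return parent_a.copy(), parent_b.copy()
    b = int(rng.integers(1, L))
    child1 = np.concatenate([parent_a[:b], parent_b[b:]])
    child2 = np.concatenate([parent_b[:b], parent_a[b:]])
    return child1, child2


def mutate(chrom: Chromosome, config: GAConfig,
           rng: np.random.Generator) -> Chromosome:
    """Point mutation: pick one gene uniformly, flip it with probability
    ``mutation_probability``; the output differs from the input in at most
    one position."""
    if chrom.shape[0] < 1:
        raise ValueError("chromosome must be non-empty")
    pos = int(rng.integers(chrom.shape[0]))
    u = float(rng.random())
    out = chrom.copy()
    if u < config.mutation_probability:
        out[pos] ^= 1
    return out


def _rank_key(fitness: np.ndarray, chromosomes: np.ndarray):
    """Sort key: higher fitness first, then fewer genes, then lower
    lexicographic bit-string (the parsimony tie-break)."""
    ones = chromosomes.sum(axis=1)

    def key(i: int):
        return (-fitness[i], ones[i], chromosomes[i].tobytes())

    return key


def select_next_generation(pop: Population, engine: FitnessEngine,
                           config: GAConfig,
                           rng: np.random.Generator) -> Population:
    """One generation: tournament parents, crossover, mutation, then
    survivor selection per ``config.survivor_strategy``.

    Offspring that would fall below the gene-limit floor are rejected in
    favour of the contributing parent (crossover) or repaired by re-adding
    a random absent gene (mutation, i.e. the deletion becomes a swap).
    """
    if pop.fitness is None:
        raise ValueError("population has no evaluated fitness ledger")
    chroms = pop.chromosomes
    fitness = pop.fitness
    ones = chroms.sum(axis=1)
    L = pop.n_descriptors
    floor = config.gene_limit

    order = sorted(range(pop.size), key=_rank_key(fitness, chroms))
    rank = np.empty(pop.size, dtype=np.int64)
    rank[order] = np.arange(pop.size)

    if config.survivor_strategy == "generational":
        elites = chroms[order[: config.elitism_count]].copy()
        n_children = config.population_size - elites.shape[0]
    else:
        elites = None
        n_children = (config.offspring_per_generation
                      or config.population_size)

    # tournament winners = best-ranked entrants, drawn per mating pair
    n_pairs = (n_children + 1) // 2
    ent_a = rng.integers(0, pop.size, size=(n_pairs, config.tournament_size))
    ent_b = rng.integers(0, pop.size, size=(n_pairs, config.tournament_size))
    ia = ent_a[np.arange(n_pairs), np.argmin(rank[ent_a], axis=1)]
    ib = ent_b[np.arange(n_pairs), np.argmin(rank[ent_b], axis=1)]

    do_cx = rng.random(n_pairs) < config.crossover_probability
    A, B = chroms[ia], chroms[ib]
    if L >= 2:
        bpts = rng.integers(1, L, size=n_pairs)
        head = np.arange(L)[None, :] < bpts[:, None]
        cx = do_cx[:, None] & ~head
        c1 = np.where(cx, B, A)
        c2 = np.where(cx, A, B)
        low1 = c1.sum(axis=1) < np.minimum(floor, ones[ia])
        low2 = c2.sum(axis=1) < np.minimum(floor, ones[ib])
        c1[low1] = A[low1]
        c2[low2] = B[low2]
    else:
        c1, c2 = A.copy(), B.copy()
    child_block = np.empty((2 * n_pairs, L), dtype=np.uint8)
    child_block[0::2] = c1
    child_block[1::2] = c2
    child_block = child_block[:n_children]

    # point mutation, one candidate gene per chromosome as in mutate()
    pre_ones = child_block.sum(axis=1)
    pos = rng.integers(0, L, size=child_block.shape[0])
    us = rng.random(child_block.shape[0])
    rows = np.flatnonzero(us < config.mutation_probability)
    at_floor = (child_block[rows, pos[rows]] == 1) & (pre_ones[rows] <= floor)
    child_block[rows, pos[rows]] ^= 1
    for r in rows[at_floor]:
        for _ in range(8 * L):  # rejection-sample an absent gene
            j = int(rng.integers(L))
            if child_block[r, j] == 0:
                child_block[r, j] = 1
                break

    if config.survivor_strategy == "generational":
        new = np.vstack([elites, child_block])
    else:
        # truncation over the merged pool keeps every improving mutant
        pool = np.vstack([chroms, child_block])
        pool_fit = engine.population_fitness(pool)
        order = sorted(range(pool.shape[0]), key=_rank_key(pool_fit, pool))
        new = pool[order[: config.population_size]].copy()
    return Population(chromosomes=new, generation=pop.generation + 1)


def run_ga(data: QSPkRDataset, config: GAConfig | None = None) -> GAResult:
    """Evolve descriptor subsets until the best chromosome sits at the
    ``gene_limit`` floor and has stopped improving for ``patience``
    generations (or the generation cap is reached; the termination reason
    is recorded either way).

    Constant descriptor columns are masked out of the population every
    generation so they cannot be selected. Returns the sorted selected
    descriptor indices of the best chromosome plus the full fitness
    trajectory.
    """
    config = config or GAConfig()
    if data.n_compounds < 3:
        raise ValueError("need at least 3 compounds")
    if data.n_descriptors < config.gene_limit:
        raise ValueError("need at least gene_limit descriptors")

    engine = FitnessEngine(data, config)
    warnings: list[str] = []
    if engine.n_similar_pairs == 0:
        warnings.append(
            "no compound pair has a normalised PK difference below epsilon; "
            "the award branch never fires and selection is uninformative"
        )

    # one generator drives the whole run: init draw first, then evolution
    rng = np.random.default_rng(config.seed)
    genes = rng.integers(0, 2, size=(config.population_size, data.n_descriptors),
                         dtype=np.uint8)
    genes[:, data.constant_descriptors] = 0
    pop = Population(chromosomes=genes, generation=0)

    trajectory: list[float] = []
    gene_counts: list[int] = []
    best_c: np.ndarray | None = None
    best_f = -np.inf
    stale = 0
    termination = "max_generations"
    generations = 0
    for gen in range(config.max_generations + 1):
        pop.fitness = engine.population_fitness(pop.chromosomes)
        i_best = min(range(pop.size),
                     key=_rank_key(pop.fitness, pop.chromosomes))
        gen_best = pop.chromosomes[i_best]
        gen_fit = float(pop.fitness[i_best])
        trajectory.append(gen_fit)
        gene_counts.append(int(gen_best.sum()))
        if best_c is None or gen_fit > best_f or (
            gen_fit == best_f and gen_best.sum() < best_c.sum()
        ):
            best_c, best_f = gen_best.copy(), gen_fit
            stale = 0
        else:
            stale += 1
        generations = gen
        # converged: the best subset sits at the gene-limit floor and has
        # stopped improving
        if gen_best.sum() <= config.gene_limit and stale >= config.patience:
            termination = "gene_limit"
            break
        if gen == config.max_generations:
            break
        pop = select_next_generation(pop, engine, config, rng)
        pop.chromosomes[:, data.constant_descriptors] = 0

    assert best_c is not None
    if not best_c.any():
        warnings.append("best chromosome is empty; no descriptor selected")
    selected = np.flatnonzero(best_c)
    return GAResult(
        selected_indices=[int(i) for i in selected],
        selected_names=[data.descriptor_names[i] for i in selected],
        best_chromosome=best_c,
        best_fitness=best_f,
        fitness_trajectory=trajectory,
        best_gene_counts=gene_counts,
        generations=generations,
        termination_reason=termination,
        seed=config.seed,
        warnings=warnings,
    )
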