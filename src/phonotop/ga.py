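"""Micro-genetic algorithm over per-phoneme HMM topologies.

A candidate recognizer is encoded as an integer chromosome of length
m = 2P + 1 for a P-phoneme inventory: genes 1..P give each phoneme's
topology code (0 Bakis-1, 1 Bakis-2, 2 Ergodic), genes P+1..2P its
emitting-state count (3–11), and the final gene the global Gaussian
mixture component count (1–16).  With the standard 40-phoneme inventory
this is the 81-gene layout.

Fitness of a chromosome is the percent word recognition accuracy of the
recognizer it describes, trained on the training split and decoded on the
fitness split.  Evolution uses roulette-wheel selection (with the
negative-fitness shift), gene-wise linear crossover c_i = α·a_i +
(1−α)·b_i, and scheduled mutation with Y = round(β·X) mutated parents and
h = round(β·m) resampled genes, where β steps through
{0, 0.10, 0.30, 0.40, 0.50} as the iteration count passes 10/30/50/70 %
of the budget and α = 1 − β.  Replacement is elitist (μ+λ truncation), so
the best fitness never decreases.  The default budget is T = 30
iterations with a population of X = 10.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import Corpus
from .decoder import DecodingNetwork, Grammar, Lexicon, compile_network, score_corpus
from .topology import (
    BAKIS1,
    BAKIS2,
    ERGODIC,
    MAX_STATES,
    MIN_STATES,
    TOPOLOGY_NAMES,
    TopologySpec,
)
from .training import TrainConfig, train_recognizer

logger = logging.getLogger(__name__)

MIN_MIXTURES = 1
MAX_MIXTURES = 16

#: β levels and the progress percentages at which they switch on; below the
#: first threshold β = 0 (crossover only).
BETA_LEVELS: tuple[tuple[float, float], ...] = (
    (10.0, 0.10),
    (30.0, 0.30),
    (50.0, 0.40),
    (70.0, 0.50),
)


# ---------------------------------------------------------------------------
# chromosome and codec
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Chromosome:
    genes: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, i: int) -> int:
        return self.genes[i]


@dataclass(frozen=True)
class ChromosomeCodec:
    """Fixed phoneme ordering and gene domains for a chromosome of length
    2P + 1."""

    phonemes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.phonemes:
            raise ValueError("empty phoneme inventory")
        if len(set(self.phonemes)) != len(self.phonemes):
            raise ValueError("duplicate phonemes in inventory")

    @property
    def n_phonemes(self) -> int:
        return len(self.phonemes)

    @property
    def length(self) -> int:
        return 2 * self.n_phonemes + 1

    def domain(self, i: int) -> tuple[int, int]:
        """Inclusive (low, high) domain of gene index ``i`` (0-based)."""
        p = self.n_phonemes
        if i < 0 or i >= self.length:
            raise IndexError(f"gene index {i} out of range")
        if i < p:
            return (BAKIS1, ERGODIC)
        if i < 2 * p:
            return (MIN_STATES, MAX_STATES)
        return (MIN_MIXTURES, MAX_MIXTURES)

    def validate(self, chromosome: Chromosome) -> None:
        if len(chromosome) != self.length:
            raise ValueError(
                f"chromosome length {len(chromosome)} != {self.length}"
            )
        for i, g in enumerate(chromosome.genes):
            lo, hi = self.domain(i)
            if not (lo <= g <= hi):
                raise ValueError(
                    f"gene {i} value {g} outside domain [{lo}, {hi}]"
                )

    def encode(
        self, assignment: dict[str, TopologySpec], n_mixtures: int
    ) -> Chromosome:
        genes = [assignment[p].topo_type for p in self.phonemes]
        genes += [assignment[p].n_states for p in self.phonemes]
        genes.append(n_mixtures)
        c = Chromosome(tuple(genes))
        self.validate(c)
        return c

    def decode(
        self, chromosome: Chromosome
    ) -> tuple[dict[str, TopologySpec], int]:
        self.validate(chromosome)
        p = self.n_phonemes
        assignment = {
            ph: TopologySpec(chromosome[i], chromosome[p + i])
            for i, ph in enumerate(self.phonemes)
        }
        return assignment, chromosome[2 * p]

    def uniform(self, topo_type: int, n_states: int, n_mixtures: int) -> Chromosome:
        spec = TopologySpec(topo_type, n_states)
        return self.encode({p: spec for p in self.phonemes}, n_mixtures)

    def random(self, rng: np.random.Generator) -> Chromosome:
        genes = tuple(
            int(rng.integers(*self.domain(i), endpoint=True))
            for i in range(self.length)
        )
        return Chromosome(genes)


def make_codec(inventory: list[str] | tuple[str, ...]) -> ChromosomeCodec:
    return ChromosomeCodec(tuple(inventory))


@dataclass
class Individual:
    chromosome: Chromosome
    fitness: float | None = None


# ---------------------------------------------------------------------------
# population initialization
# ---------------------------------------------------------------------------

def init_population(
    codec: ChromosomeCodec,
    seed: int | np.random.Generator,
    x: int = 10,
    baseline_mixtures: int = 6,
) -> list[Individual]:
    """Seeded initial population.

    The first three individuals are the three uniform baseline systems —
    all-phoneme Bakis-1 with 3 states, Bakis-2 with 4 states and Ergodic
    with 3 states (each at the baseline mixture count) — and the remaining
    individuals are uniform-random over the gene domains.
    """
    if x < 4:
        raise ValueError("population size must be at least 4")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    pop = [
        Individual(codec.uniform(BAKIS1, 3, baseline_mixtures)),
        Individual(codec.uniform(BAKIS2, 4, baseline_mixtures)),
        Individual(codec.uniform(ERGODIC, 3, baseline_mixtures)),
    ]
    while len(pop) < x:
        pop.append(Individual(codec.random(rng)))
    return pop


# ---------------------------------------------------------------------------
# fitness
# ---------------------------------------------------------------------------

class FitnessEvaluator:
    """Trains the recognizer a chromosome describes and scores it on the
    fitness split; results are cached by gene vector (the micro-GA
    revisits chromosomes constantly and training is the cost center)."""

    def __init__(
        self,
        codec: ChromosomeCodec,
        train: Corpus,
        fit: Corpus,
        lexicon: Lexicon,
        grammar: Grammar,
        train_config: TrainConfig = TrainConfig(),
    ):
        self.codec = codec
        self.train = train
        self.fit = fit
        self.lexicon = lexicon
        self.network: DecodingNetwork = compile_network(lexicon, grammar)
        self.train_config = train_config
        self.cache: dict[tuple[int, ...], float] = {}
        self.n_trainings = 0

    def __call__(self, chromosome: Chromosome) -> float:
        key = chromosome.genes
        if key in self.cache:
            return self.cache[key]
        assignment, n_mix = self.codec.decode(chromosome)
        try:
            model_set = train_recognizer(
                assignment,
                n_mix,
                self.train,
                self.train.feature_dim,
                self.train_config,
            )
            wacc, _ = score_corpus(model_set, self.fit, self.network)
        except Exception:  # noqa: BLE001 - a failed build scores worst-case
            logger.exception("fitness evaluation failed; assigning -100")
            wacc = -100.0
        self.n_trainings += 1
        self.cache[key] = wacc
        return wacc


def evaluate_fitness(
    chromosome: Chromosome,
    codec: ChromosomeCodec,
    train: Corpus,
    fit: Corpus,
    lexicon: Lexicon,
    grammar: Grammar,
    train_config: TrainConfig = TrainConfig(),
) -> float:
    """One-shot fitness evaluation (see :class:`FitnessEvaluator`)."""
    return FitnessEvaluator(codec, train, fit, lexicon, grammar, train_config)(
        chromosome
    )


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionDistribution:
    probs: np.ndarray
    cumprobs: np.ndarray
    shift: float


def selection_distribution(fitnesses: list[float]) -> SelectionDistribution:
    """Roulette-wheel probabilities S(x) = F_x / ΣF with the negative
    shift: when any fitness is negative, |min F| is added to all values, so
    the most negative individual gets selection probability exactly 0.  If
    every shifted fitness is 0 the distribution degenerates to uniform."""
    if len(fitnesses) < 2:
        raise ValueError("need at least two individuals")
    f = np.asarray(fitnesses, dtype=float)
    shift = float(-f.min()) if f.min() < 0 else 0.0
    shifted = f + shift
    total = shifted.sum()
    if total <= 0:
        probs = np.full(len(f), 1.0 / len(f))
    else:
        probs = shifted / total
    return SelectionDistribution(probs, np.cumsum(probs), shift)


def roulette_select(
    dist: SelectionDistribution, x: int, rng: np.random.Generator
) -> list[int]:
    """X independent roulette draws (0-based indices); consecutive picks
    form the X/2 parent couples."""
    picks: list[int] = []
    for _ in range(x):
        r = rng.random()
        if r <= 0.0:
            r = np.nextafter(0.0, 1.0)
        picks.append(int(np.searchsorted(dist.cumprobs, r, side="left")))
    return picks


# ---------------------------------------------------------------------------
# reproduction
# ---------------------------------------------------------------------------

def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def linear_crossover(
    a: Chromosome, b: Chromosome, alpha: float, codec: ChromosomeCodec
) -> tuple[Chromosome, Chromosome]:
    """Gene-wise arithmetic blend c_i = α·a_i + (1−α)·b_i (and the mirror
    for d), rounded half-away-from-zero and clamped to each gene's domain."""
    if len(a) != codec.length or len(b) != codec.length:
        raise ValueError("chromosome/codec length mismatch")
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    c_genes, d_genes = [], []
    for i in range(codec.length):
        lo, hi = codec.domain(i)
        ci = _round_half_away(alpha * a[i] + (1 - alpha) * b[i])
        di = _round_half_away(alpha * b[i] + (1 - alpha) * a[i])
        c_genes.append(min(max(ci, lo), hi))
        d_genes.append(min(max(di, lo), hi))
    return Chromosome(tuple(c_genes)), Chromosome(tuple(d_genes))


def mutate_parents(
    population: list[Individual],
    beta: float,
    codec: ChromosomeCodec,
    rng: np.random.Generator,
) -> list[Chromosome]:
    """Y = round(β·X) parents are drawn without replacement; in each,
    h = round(β·m) distinct gene positions are resampled to a *different*
    in-domain value."""
    if not (0.0 <= beta <= 1.0):
        raise ValueError("beta must lie in [0, 1]")
    x = len(population)
    y = _round_half_away(beta * x)
    h = _round_half_away(beta * codec.length)
    if y == 0 or h == 0:
        return []
    chosen = rng.choice(x, size=min(y, x), replace=False)
    out: list[Chromosome] = []
    for idx in chosen:
        genes = list(population[int(idx)].chromosome.genes)
        positions = rng.choice(codec.length, size=min(h, codec.length), replace=False)
        for pos in positions:
            lo, hi = codec.domain(int(pos))
            new = int(rng.integers(lo, hi, endpoint=True))
            while new == genes[pos]:
                new = int(rng.integers(lo, hi, endpoint=True))
            genes[pos] = new
        out.append(Chromosome(tuple(genes)))
    return out


def beta_formula(w: float) -> float:
    """Continuous mutation-rate curve β(w) = 0.2·ln(w) − 0.36 (documentation
    only; the optimizer uses the stepped :func:`beta_schedule`)."""
    if w <= 0:
        return 0.0
    return 0.2 * math.log(w) - 0.36


def beta_schedule(w: float) -> float:
    """Stepped mutation probability: 0 below 10 % progress, then 0.10,
    0.30, 0.40 and 0.50 as w passes 10/30/50/70 %."""
    if not (0.0 <= w <= 100.0):
        raise ValueError("progress percentage w must lie in [0, 100]")
    beta = 0.0
    for threshold, level in BETA_LEVELS:
        if w >= threshold:
            beta = level
    return beta


# ---------------------------------------------------------------------------
# replacement and the full loop
# ---------------------------------------------------------------------------

def replace(
    population: list[Individual], offspring: list[Individual]
) -> list[Individual]:
    """Elitist (μ+λ) truncation: keep the best X of parents + offspring,
    incumbents first on fitness ties.  Best fitness never decreases."""
    for ind in population + offspring:
        if ind.fitness is None:
            raise ValueError("all individuals must be evaluated before replacement")
    pool = list(population) + list(offspring)
    order = sorted(range(len(pool)), key=lambda i: -pool[i].fitness)
    return [pool[i] for i in order[: len(population)]]


@dataclass(frozen=True)
class GAConfig:
    x: int = 10
    t: int = 30
    seed: int = 0
    baseline_mixtures: int = 6
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        if self.x % 2 or self.x < 4:
            raise ValueError("population size must be even and >= 4")
        if self.t < 1:
            raise ValueError("iteration budget must be >= 1")


@dataclass
class GAResult:
    best: Individual
    assignment: pd.DataFrame      # columns: phoneme, topology, n_states
    n_mixtures: int
    history: pd.DataFrame         # columns: iteration, best, mean
    population: list[Individual]
    n_trainings: int


def assignment_table(
    codec: ChromosomeCodec, chromosome: Chromosome
) -> tuple[pd.DataFrame, int]:
    assignment, n_mix = codec.decode(chromosome)
    table = pd.DataFrame(
        {
            "phoneme": list(codec.phonemes),
            "topology": [
                TOPOLOGY_NAMES[assignment[p].topo_type] for p in codec.phonemes
            ],
            "n_states": [assignment[p].n_states for p in codec.phonemes],
        }
    )
    return table, n_mix


def run_micro_ga(
    config: GAConfig,
    codec: ChromosomeCodec,
    train: Corpus,
    fit: Corpus,
    lexicon: Lexicon,
    grammar: Grammar,
    evaluator: FitnessEvaluator | None = None,
) -> GAResult:
    """The full micro-GA loop: init → evaluate → select → crossover →
    mutate → evaluate → elitist replace, for T iterations.

    Fully deterministic under ``config.seed``.  The history dataframe has
    one row for the initial population plus one per iteration.
    """
    rng = np.random.default_rng(config.seed)
    if evaluator is None:
        evaluator = FitnessEvaluator(
            codec, train, fit, lexicon, grammar, config.train
        )
    population = init_population(
        codec, rng, x=config.x, baseline_mixtures=config.baseline_mixtures
    )
    for ind in population:
        ind.fitness = evaluator(ind.chromosome)

    rows = []

    def log_state(iteration: int) -> None:
        fits = [ind.fitness for ind in population]
        rows.append(
            {
                "iteration": iteration,
                "best": max(fits),
                "mean": float(np.mean(fits)),
                "beta": beta_schedule(100.0 * iteration / config.t)
                if iteration < config.t
                else beta_schedule(100.0),
            }
        )

    log_state(0)
    for it in range(config.t):
        w = 100.0 * it / config.t
        beta = beta_schedule(w)
        alpha = 1.0 - beta

        dist = selection_distribution([ind.fitness for ind in population])
        picks = roulette_select(dist, config.x, rng)
        children: list[Chromosome] = []
        for j in range(0, config.x, 2):
            a = population[picks[j]].chromosome
            b = population[picks[j + 1]].chromosome
            children.extend(linear_crossover(a, b, alpha, codec))
        children.extend(mutate_parents(population, beta, codec, rng))

        offspring = [Individual(c, evaluator(c)) for c in children]
        population = replace(population, offspring)
        log_state(it + 1)
        logger.info(
            "iteration %d/%d: beta=%.2f best=%.2f mean=%.2f (trainings=%d)",
            it + 1,
            config.t,
            beta,
            rows[-1]["best"],
            rows[-1]["mean"],
            evaluator.n_trainings,
        )

    best = max(population, key=lambda ind: ind.fitness)
    table, n_mix = assignment_table(codec, best.chromosome)
    return GAResult(
        best=best,
        assignment=table,
        n_mixtures=n_mix,
        history=pd.DataFrame(rows),
        population=population,
        n_trainings=evaluator.n_trainings,
    )
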