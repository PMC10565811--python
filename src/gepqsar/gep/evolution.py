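"""Elitist generational evolution of Karva chromosomes.

Selection is fitness-proportionate roulette (tournament available), always
carrying at least one elite forward unchanged, so the best-so-far fitness
history is non-decreasing.  All randomness flows from the config seed; a
run is fully reproducible from (config, data).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ..tables import DescriptorTable
from .karva import (
    Chromosome,
    FunctionSet,
    Gene,
    chromosome_tree,
    evaluate_chromosome,
    fitness,
    tree_to_text,
)
from . import operators as ops

__all__ = ["DEFAULT_RATES", "GepConfig", "GepModel", "evolve"]

#: Canonical GEP operator rates; all configurable.
DEFAULT_RATES: dict[str, float] = {
    "mutation": 0.044,
    "inversion": 0.1,
    "is_transposition": 0.1,
    "ris_transposition": 0.1,
    "gene_transposition": 0.1,
    "one_point": 0.3,
    "two_point": 0.3,
    "gene_recombination": 0.1,
    "dc_mutation": 0.044,
    "constant_mutation": 0.01,
}


@dataclass(frozen=True)
class GepConfig:
    """Engine configuration.

    Defaults follow the published run: 100 chromosomes of 5 genes, head 8
    (gene length 26 with the constant domain), function set
    {+, -, *, /, tan, inv}, addition linking.
    """

    population: int = 100
    n_genes: int = 5
    head: int = 8
    generations: int = 1000
    function_symbols: tuple[str, ...] = ("+", "-", "*", "/", "tan", "inv")
    use_constants: bool = True
    n_constants: int = 10
    constant_range: tuple[float, float] = (-20.0, 20.0)
    rates: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_RATES))
    elitism: int = 1
    selection: str = "roulette"  # or "tournament"
    seed: int = 0
    fitness_threshold: float | None = None
    protected_value: float = 1.0

    def __post_init__(self) -> None:
        if self.population < 2:
            raise ValueError("population must be at least 2")
        if self.elitism < 1 or self.elitism >= self.population:
            raise ValueError("elitism must be in [1, population)")
        if any(not 0 <= r <= 1 for r in self.rates.values()):
            raise ValueError("operator rates must lie in [0, 1]")
        if self.selection not in ("roulette", "tournament"):
            raise ValueError("selection must be 'roulette' or 'tournament'")
        FunctionSet(self.function_symbols)  # validates symbols

    @property
    def function_set(self) -> FunctionSet:
        return FunctionSet(self.function_symbols)

    def rate(self, name: str) -> float:
        return float(self.rates.get(name, 0.0))


@dataclass(frozen=True)
class GepModel:
    """Best-ever individual of one evolutionary run."""

    best_chromosome: Chromosome
    fitness: float
    history: tuple[float, ...]
    terminals: tuple[str, ...]
    config: GepConfig
    name: str = "GEP"

    def best_tree(self):
        return chromosome_tree(self.best_chromosome, self.config.function_set)

    def predict(self, table: DescriptorTable) -> np.ndarray:
        bindings = table.columns(self.terminals)
        out = evaluate_chromosome(
            self.best_chromosome,
            bindings,
            self.config.function_set,
            self.config.protected_value,
        )
        return np.broadcast_to(np.asarray(out, dtype=float), (table.n_compounds,)).copy()

    def equation(self, precision: int | None = 3) -> str:
        return tree_to_text(self.best_tree(), precision)

    def to_json(self) -> str:
        payload = {
            "genes": [
                {
                    "head": list(g.head),
                    "tail": list(g.tail),
                    "dc": list(g.dc),
                    "constants": list(g.constants),
                }
                for g in self.best_chromosome.genes
            ],
            "linking": self.best_chromosome.linking,
            "terminals": list(self.terminals),
            "fitness": self.fitness,
            "history": list(self.history),
            "equation": self.equation(),
            "config": {
                "population": self.config.population,
                "n_genes": self.config.n_genes,
                "head": self.config.head,
                "generations": self.config.generations,
                "function_symbols": list(self.config.function_symbols),
                "use_constants": self.config.use_constants,
                "n_constants": self.config.n_constants,
                "constant_range": list(self.config.constant_range),
                "elitism": self.config.elitism,
                "selection": self.config.selection,
                "seed": self.config.seed,
                "protected_value": self.config.protected_value,
            },
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GepModel":
        payload = json.loads(text)
        genes = tuple(
            Gene(
                tuple(g["head"]),
                tuple(g["tail"]),
                tuple(int(i) for i in g["dc"]),
                tuple(float(c) for c in g["constants"]),
            )
            for g in payload["genes"]
        )
        cfg = payload["config"]
        config = GepConfig(
            population=cfg["population"],
            n_genes=cfg["n_genes"],
            head=cfg["head"],
            generations=cfg["generations"],
            function_symbols=tuple(cfg["function_symbols"]),
            use_constants=cfg["use_constants"],
            n_constants=cfg["n_constants"],
            constant_range=tuple(cfg["constant_range"]),
            elitism=cfg["elitism"],
            selection=cfg["selection"],
            seed=cfg["seed"],
            protected_value=cfg["protected_value"],
        )
        return cls(
            best_chromosome=Chromosome(genes, payload["linking"]),
            fitness=float(payload["fitness"]),
            history=tuple(float(f) for f in payload["history"]),
            terminals=tuple(payload["terminals"]),
            config=config,
        )


def _select(rng, fits: np.ndarray, k: int, mode: str) -> np.ndarray:
    if mode == "roulette":
        p = fits / fits.sum()
        return rng.choice(len(fits), size=k, p=p)
    # size-2 tournament
    a = rng.integers(len(fits), size=k)
    b = rng.integers(len(fits), size=k)
    return np.where(fits[a] >= fits[b], a, b)


def evolve(
    config: GepConfig,
    train: DescriptorTable,
    terminals: Sequence[str] | None = None,
) -> GepModel:
    """Run one seeded evolutionary search against a training table.

    Terminals default to all descriptor columns of the table.  Returns the
    best-ever chromosome together with the per-generation best-fitness
    history (length generations+1, counting the random initial
    population); the run stops early if ``fitness_threshold`` is reached.
    """
    terminals = tuple(terminals) if terminals is not None else train.descriptor_names
    if not terminals:
        raise ValueError("no terminal symbols: table has no descriptor columns")
    y = train.activity
    if np.ptp(y) == 0:
        raise ValueError("degenerate training activity (constant vector)")
    fs = config.function_set
    bindings = train.columns(terminals)
    rng = np.random.default_rng(config.seed)

    def assess(chrom: Chromosome) -> float:
        pred = evaluate_chromosome(chrom, bindings, fs, config.protected_value)
        pred = np.broadcast_to(np.asarray(pred, dtype=float), y.shape)
        return fitness(pred, y)

    pop = [
        ops.random_chromosome(
            rng, fs, terminals, config.n_genes, config.head,
            config.use_constants, config.n_constants, config.constant_range,
        )
        for _ in range(config.population)
    ]
    fits = np.array([assess(c) for c in pop])
    best_i = int(np.argmax(fits))
    best_chrom, best_fit = pop[best_i], float(fits[best_i])
    history = [best_fit]

    for _ in range(config.generations):
        if config.fitness_threshold is not None and best_fit >= config.fitness_threshold:
            break
        elite_idx = np.argsort(fits)[-config.elitism :]
        elites = [pop[int(i)] for i in elite_idx]
        chosen = _select(rng, fits, config.population - config.elitism, config.selection)
        children = [pop[int(i)] for i in chosen]

        children = [
            ops.mutate(c, fs, terminals, config.rate("mutation"), rng) for c in children
        ]
        if config.use_constants:
            children = [ops.mutate_dc(c, config.rate("dc_mutation"), rng) for c in children]
            children = [
                ops.mutate_constants(c, config.rate("constant_mutation"), config.constant_range, rng)
                for c in children
            ]
        for i, child in enumerate(children):
            if rng.random() < config.rate("inversion"):
                child = ops.invert(child, rng)
            if rng.random() < config.rate("is_transposition"):
                child = ops.transpose_is(child, rng)
            if rng.random() < config.rate("ris_transposition"):
                child = ops.transpose_ris(child, fs, rng)
            if config.n_genes > 1 and rng.random() < config.rate("gene_transposition"):
                child = ops.transpose_gene(child, rng)
            children[i] = child
        for i in range(0, len(children) - 1, 2):
            a, b = children[i], children[i + 1]
            if rng.random() < config.rate("one_point"):
                a, b = ops.recombine_one_point(a, b, rng)
            if rng.random() < config.rate("two_point"):
                a, b = ops.recombine_two_point(a, b, rng)
            if config.n_genes > 1 and rng.random() < config.rate("gene_recombination"):
                a, b = ops.recombine_gene(a, b, rng)
            children[i], children[i + 1] = a, b

        pop = elites + children
        fits = np.array([assess(c) for c in pop])
        gen_best = int(np.argmax(fits))
        if float(fits[gen_best]) > best_fit:
            best_chrom, best_fit = pop[gen_best], float(fits[gen_best])
        history.append(best_fit)

    return GepModel(
        best_chromosome=best_chrom,
        fitness=best_fit,
        history=tuple(history),
        terminals=terminals,
        config=config,
    )
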