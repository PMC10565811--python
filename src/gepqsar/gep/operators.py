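"""Genetic operators on Karva chromosomes.

Every operator is pure (returns new chromosomes) and closed over the genome
structure: head positions stay free (functions, terminals, ``?``), tail and
Dc positions stay within their alphabets, and all lengths are preserved, so
any output decodes.  Randomness comes exclusively from the supplied
numpy Generator.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .karva import CONST_PLACEHOLDER, Chromosome, FunctionSet, Gene, GeneError, gene_structure

__all__ = [
    "random_gene",
    "random_chromosome",
    "chromosome_is_valid",
    "mutate",
    "mutate_dc",
    "mutate_constants",
    "invert",
    "transpose_is",
    "transpose_ris",
    "transpose_gene",
    "recombine_one_point",
    "recombine_two_point",
    "recombine_gene",
]

_MAX_TRANSPOSON = 3


def _alphabets(functions: FunctionSet, terminals: Sequence[str], use_constants: bool):
    tail_alpha = tuple(terminals) + ((CONST_PLACEHOLDER,) if use_constants else ())
    head_alpha = tuple(functions.symbols) + tail_alpha
    return head_alpha, tail_alpha


def random_gene(
    rng: np.random.Generator,
    functions: FunctionSet,
    terminals: Sequence[str],
    head: int,
    use_constants: bool = True,
    n_constants: int = 10,
    constant_range: tuple[float, float] = (-20.0, 20.0),
) -> Gene:
    """Uniformly random structurally valid gene."""
    if not terminals:
        raise GeneError("need at least one terminal symbol")
    tail_len, _ = gene_structure(head, functions.max_arity, use_constants)
    head_alpha, tail_alpha = _alphabets(functions, terminals, use_constants)
    head_syms = tuple(head_alpha[i] for i in rng.integers(len(head_alpha), size=head))
    tail_syms = tuple(tail_alpha[i] for i in rng.integers(len(tail_alpha), size=tail_len))
    if use_constants:
        dc = tuple(int(i) for i in rng.integers(n_constants, size=tail_len))
        lo, hi = constant_range
        constants = tuple(float(c) for c in rng.uniform(lo, hi, size=n_constants))
    else:
        dc, constants = (), ()
    return Gene(head_syms, tail_syms, dc, constants)


def random_chromosome(
    rng: np.random.Generator,
    functions: FunctionSet,
    terminals: Sequence[str],
    n_genes: int,
    head: int,
    use_constants: bool = True,
    n_constants: int = 10,
    constant_range: tuple[float, float] = (-20.0, 20.0),
) -> Chromosome:
    genes = tuple(
        random_gene(rng, functions, terminals, head, use_constants, n_constants, constant_range)
        for _ in range(n_genes)
    )
    return Chromosome(genes)


def chromosome_is_valid(
    chrom: Chromosome, functions: FunctionSet, terminals: Sequence[str]
) -> bool:
    try:
        for gene in chrom.genes:
            gene.validate(functions, terminals)
    except GeneError:
        return False
    return True


def mutate(
    chrom: Chromosome,
    functions: FunctionSet,
    terminals: Sequence[str],
    rate: float,
    rng: np.random.Generator,
) -> Chromosome:
    """Point mutation: each symbol independently resampled with probability
    ``rate``, head positions from the full alphabet, tail positions from
    terminals (and ``?``)."""
    if rate <= 0:
        return chrom
    genes = []
    for gene in chrom.genes:
        head_alpha, tail_alpha = _alphabets(functions, terminals, gene.use_constants)
        head = tuple(
            head_alpha[int(rng.integers(len(head_alpha)))] if rng.random() < rate else s
            for s in gene.head
        )
        tail = tuple(
            tail_alpha[int(rng.integers(len(tail_alpha)))] if rng.random() < rate else s
            for s in gene.tail
        )
        genes.append(Gene(head, tail, gene.dc, gene.constants))
    return Chromosome(tuple(genes), chrom.linking)


def mutate_dc(chrom: Chromosome, rate: float, rng: np.random.Generator) -> Chromosome:
    """Point mutation over the Dc domain: resample constant-pool indices."""
    if rate <= 0:
        return chrom
    genes = []
    for gene in chrom.genes:
        if not gene.use_constants:
            genes.append(gene)
            continue
        k = len(gene.constants)
        dc = tuple(
            int(rng.integers(k)) if rng.random() < rate else i for i in gene.dc
        )
        genes.append(Gene(gene.head, gene.tail, dc, gene.constants))
    return Chromosome(tuple(genes), chrom.linking)


def mutate_constants(
    chrom: Chromosome,
    rate: float,
    constant_range: tuple[float, float],
    rng: np.random.Generator,
) -> Chromosome:
    """Redraw individual random numerical constants with probability ``rate``."""
    if rate <= 0:
        return chrom
    lo, hi = constant_range
    genes = []
    for gene in chrom.genes:
        if not gene.use_constants:
            genes.append(gene)
            continue
        constants = tuple(
            float(rng.uniform(lo, hi)) if rng.random() < rate else c for c in gene.constants
        )
        genes.append(Gene(gene.head, gene.tail, gene.dc, constants))
    return Chromosome(tuple(genes), chrom.linking)


def invert(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Reverse a random segment within the head of one random gene."""
    gi = int(rng.integers(len(chrom.genes)))
    gene = chrom.genes[gi]
    h = len(gene.head)
    if h < 2:
        return chrom
    start = int(rng.integers(h - 1))
    stop = int(rng.integers(start + 1, h)) + 1
    head = gene.head[:start] + tuple(reversed(gene.head[start:stop])) + gene.head[stop:]
    genes = chrom.genes[:gi] + (Gene(head, gene.tail, gene.dc, gene.constants),) + chrom.genes[gi + 1 :]
    return Chromosome(genes, chrom.linking)


def _insert_into_head(head: tuple, segment: tuple, pos: int) -> tuple:
    # insertion shifts the head right; symbols pushed past the head are lost
    return (head[:pos] + segment + head[pos:])[: len(head)]


def transpose_is(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Insertion-sequence transposition: copy a short segment from anywhere
    in a source gene into a non-root position of a target gene's head."""
    genes = list(chrom.genes)
    src = genes[int(rng.integers(len(genes)))]
    seq = src.head + src.tail
    length = int(rng.integers(1, _MAX_TRANSPOSON + 1))
    start = int(rng.integers(len(seq) - length + 1))
    segment = seq[start : start + length]
    ti = int(rng.integers(len(genes)))
    target = genes[ti]
    h = len(target.head)
    if h < 2:
        return chrom
    pos = int(rng.integers(1, h))  # never the root position
    head = _insert_into_head(target.head, segment, pos)
    genes[ti] = Gene(head, target.tail, target.dc, target.constants)
    return Chromosome(tuple(genes), chrom.linking)


def transpose_ris(
    chrom: Chromosome, functions: FunctionSet, rng: np.random.Generator
) -> Chromosome:
    """Root-insertion-sequence transposition: a function-rooted segment is
    copied to the start of the head.  Identity when the scanned gene head
    holds no function symbol."""
    genes = list(chrom.genes)
    gi = int(rng.integers(len(genes)))
    gene = genes[gi]
    h = len(gene.head)
    scan_from = int(rng.integers(h))
    root_pos = next(
        (i for i in range(scan_from, h) if gene.head[i] in functions), None
    )
    if root_pos is None:
        return chrom
    seq = gene.head + gene.tail
    length = int(rng.integers(1, _MAX_TRANSPOSON + 1))
    segment = seq[root_pos : root_pos + length]
    head = _insert_into_head(gene.head, segment, 0)
    genes[gi] = Gene(head, gene.tail, gene.dc, gene.constants)
    return Chromosome(tuple(genes), chrom.linking)


def transpose_gene(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Move one randomly chosen gene to the front of the chromosome."""
    n = len(chrom.genes)
    if n < 2:
        return chrom
    gi = int(rng.integers(n))
    genes = (chrom.genes[gi],) + chrom.genes[:gi] + chrom.genes[gi + 1 :]
    return Chromosome(genes, chrom.linking)


def _flatten(chrom: Chromosome) -> list:
    flat = []
    for gene in chrom.genes:
        flat.extend(gene.head)
        flat.extend(gene.tail)
        flat.extend(gene.dc)
    return flat


def _unflatten(flat: list, template: Chromosome, constant_sources: Sequence[Gene]) -> Chromosome:
    genes = []
    pos = 0
    for gene, const_src in zip(template.genes, constant_sources):
        h, t = len(gene.head), len(gene.tail)
        d = len(gene.dc)
        head = tuple(flat[pos : pos + h]); pos += h
        tail = tuple(flat[pos : pos + t]); pos += t
        dc = tuple(flat[pos : pos + d]); pos += d
        genes.append(Gene(head, tail, dc, const_src.constants))
    return Chromosome(tuple(genes), template.linking)


def _gene_span(chrom: Chromosome, gi: int) -> tuple[int, int]:
    sizes = [len(g.head) + len(g.tail) + len(g.dc) for g in chrom.genes]
    start = sum(sizes[:gi])
    return start, start + sizes[gi]


def _recombine_at(c1: Chromosome, c2: Chromosome, cuts: list[int]) -> tuple[Chromosome, Chromosome]:
    f1, f2 = _flatten(c1), _flatten(c2)
    swap = False
    o1, o2, prev = [], [], 0
    for cut in cuts + [len(f1)]:
        seg1, seg2 = f1[prev:cut], f2[prev:cut]
        o1.extend(seg2 if swap else seg1)
        o2.extend(seg1 if swap else seg2)
        swap = not swap
        prev = cut
    # constants follow the parent that contributed the gene's starting symbol
    def sources(first: Chromosome, second: Chromosome):
        out = []
        for gi in range(len(first.genes)):
            start, _ = _gene_span(first, gi)
            n_swaps = sum(1 for c in cuts if c <= start)
            out.append((first if n_swaps % 2 == 0 else second).genes[gi])
        return out

    child1 = _unflatten(o1, c1, sources(c1, c2))
    child2 = _unflatten(o2, c2, sources(c2, c1))
    return child1, child2


def recombine_one_point(
    c1: Chromosome, c2: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Exchange suffixes of the flattened (head+tail+Dc) parent strings at
    one random cut point."""
    total = len(_flatten(c1))
    cut = int(rng.integers(1, total))
    return _recombine_at(c1, c2, [cut])


def recombine_two_point(
    c1: Chromosome, c2: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Exchange the segment between two random cut points."""
    total = len(_flatten(c1))
    a, b = sorted(int(i) for i in rng.choice(np.arange(1, total), size=2, replace=False))
    return _recombine_at(c1, c2, [a, b])


def recombine_gene(
    c1: Chromosome, c2: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """Swap one whole gene (symbols, Dc and constant pool) between parents."""
    gi = int(rng.integers(len(c1.genes)))
    g1 = c1.genes[:gi] + (c2.genes[gi],) + c1.genes[gi + 1 :]
    g2 = c2.genes[:gi] + (c1.genes[gi],) + c2.genes[gi + 1 :]
    return Chromosome(g1, c1.linking), Chromosome(g2, c2.linking)
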