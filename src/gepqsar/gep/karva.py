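"""Karva genome representation, breadth-first decoding, and protected evaluation.

A gene is three fixed-length strings: a head (functions, terminals, or the
constant placeholder ``?``), a tail of length h*(max_arity-1)+1 (terminals
and ``?`` only), and — when random numerical constants are enabled — a Dc
domain of tail length indexing the gene's constant pool.  With head 8 and
binary functions this gives the classic 8 + 9 + 9 = 26-symbol gene.

Decoding reads the gene breadth-first: the first symbol is the root and each
function node claims the next unclaimed symbols, level by level, so every
syntactically valid gene maps to exactly one finite tree and symbols past
the open reading frame are silently ignored.  Each ``?`` encountered in the
reading frame consumes the next Dc index and becomes a constant leaf.

The unary reciprocal function decodes directly to a division node with a
constant-1 numerator, so trees contain only {+, -, *, /, tan} plus leaves,
and the infix rendering round-trips through the parser exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "FUNCTION_ARITY",
    "CONST_PLACEHOLDER",
    "FunctionSet",
    "Gene",
    "Chromosome",
    "Node",
    "GeneError",
    "gene_structure",
    "decode",
    "evaluate",
    "evaluate_chromosome",
    "chromosome_tree",
    "tree_to_text",
    "parse_expression",
    "fitness",
]

FUNCTION_ARITY: dict[str, int] = {"+": 2, "-": 2, "*": 2, "/": 2, "tan": 1, "inv": 1}
CONST_PLACEHOLDER = "?"
_CONST = "#"  # internal node symbol for constant leaves
_EPS = 1e-12  # |denominator| below this triggers the protected value


class GeneError(ValueError):
    """Raised for structurally malformed genes or chromosomes."""


@dataclass(frozen=True)
class FunctionSet:
    """Operator alphabet available in gene heads."""

    symbols: tuple[str, ...] = ("+", "-", "*", "/", "tan", "inv")

    def __post_init__(self) -> None:
        unknown = [s for s in self.symbols if s not in FUNCTION_ARITY]
        if unknown:
            raise GeneError(f"unknown function symbols: {unknown}")

    def arity(self, symbol: str) -> int:
        return FUNCTION_ARITY[symbol]

    @property
    def max_arity(self) -> int:
        return max(FUNCTION_ARITY[s] for s in self.symbols)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


def gene_structure(head: int, max_arity: int, use_constants: bool = True) -> tuple[int, int]:
    """Tail and total gene length implied by the head size.

    tail = head*(max_arity-1) + 1; the Dc domain, when enabled, adds
    another tail's worth of symbols.
    """
    if head < 1 or max_arity < 1:
        raise GeneError("head and max_arity must be at least 1")
    tail = head * (max_arity - 1) + 1
    length = head + tail + (tail if use_constants else 0)
    return tail, length


@dataclass(frozen=True)
class Gene:
    """One Karva gene: head + tail symbol strings, Dc indices, constant pool."""

    head: tuple[str, ...]
    tail: tuple[str, ...]
    dc: tuple[int, ...] = ()
    constants: tuple[float, ...] = ()

    @property
    def use_constants(self) -> bool:
        return bool(self.constants)

    def validate(self, functions: FunctionSet, terminals: Sequence[str]) -> None:
        tail_len, _ = gene_structure(len(self.head), functions.max_arity, self.use_constants)
        if len(self.tail) != tail_len:
            raise GeneError(f"tail length {len(self.tail)} != required {tail_len}")
        term_ok = set(terminals) | ({CONST_PLACEHOLDER} if self.use_constants else set())
        head_ok = set(functions.symbols) | term_ok
        for sym in self.head:
            if sym not in head_ok:
                raise GeneError(f"illegal head symbol {sym!r}")
        for sym in self.tail:
            if sym in functions.symbols:
                raise GeneError(f"function symbol {sym!r} in tail")
            if sym not in term_ok:
                raise GeneError(f"illegal tail symbol {sym!r}")
        if self.use_constants:
            if len(self.dc) != tail_len:
                raise GeneError("Dc domain must have tail length")
            if any(not 0 <= i < len(self.constants) for i in self.dc):
                raise GeneError("Dc index out of range of the constant pool")


@dataclass(frozen=True)
class Chromosome:
    """Ordered genes combined by a linking operator (addition here)."""

    genes: tuple[Gene, ...]
    linking: str = "+"

    def __post_init__(self) -> None:
        if not self.genes:
            raise GeneError("chromosome needs at least one gene")
        if self.linking != "+":
            raise GeneError("only addition linking is supported")
        heads = {len(g.head) for g in self.genes}
        if len(heads) != 1:
            raise GeneError("all genes must share one head size")


class Node:
    """Expression-tree node: operator, terminal, or constant leaf."""

    __slots__ = ("symbol", "children", "value")

    def __init__(self, symbol: str, children: tuple = (), value: float | None = None):
        self.symbol = symbol
        self.children = children
        self.value = value

    @classmethod
    def const(cls, value: float) -> "Node":
        return cls(_CONST, (), float(value))

    @property
    def is_const(self) -> bool:
        return self.symbol == _CONST

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Node)
            and self.symbol == other.symbol
            and self.value == other.value
            and self.children == other.children
        )

    def __hash__(self):
        return hash((self.symbol, self.value, self.children))

    def __repr__(self):
        return f"Node({tree_to_text(self, precision=None)})"


def decode(gene: Gene, functions: FunctionSet = FunctionSet()) -> Node:
    """Breadth-first (Karva) decoding of a gene into its expression tree."""
    for sym in gene.tail:
        if sym in functions:
            raise GeneError(f"function symbol {sym!r} in tail")
    symbols = gene.head + gene.tail
    head_len = len(gene.head)
    const_counter = 0

    def make(sym: str, pos: int) -> tuple[Node, int]:
        nonlocal const_counter
        if sym in functions:
            if pos >= head_len:
                raise GeneError(f"function symbol {sym!r} in tail (position {pos})")
            return Node(sym), functions.arity(sym)
        if sym == CONST_PLACEHOLDER:
            if not gene.use_constants:
                raise GeneError("constant placeholder in a gene without constants")
            idx = gene.dc[const_counter]
            const_counter += 1
            return Node.const(gene.constants[idx]), 0
        return Node(sym), 0

    root, root_arity = make(symbols[0], 0)
    pending: list[tuple[Node, int]] = [(root, root_arity)]
    next_pos = 1
    while pending:
        node, arity = pending.pop(0)
        if arity == 0:
            continue
        children = []
        for _ in range(arity):
            if next_pos >= len(symbols):
                raise GeneError("gene exhausted before the reading frame closed")
            child, child_arity = make(symbols[next_pos], next_pos)
            next_pos += 1
            children.append(child)
            pending.append((child, child_arity))
        node.children = tuple(children)
    return _normalize_inv(root)


def _normalize_inv(node: Node) -> Node:
    """Rewrite inv(x) as (1/x) so trees use binary operators only."""
    children = tuple(_normalize_inv(c) for c in node.children)
    if node.symbol == "inv":
        return Node("/", (Node.const(1.0), children[0]))
    node.children = children
    return node


def _protect(x, protected_value: float):
    return np.where(np.isfinite(x), x, protected_value)


def evaluate(
    tree: Node,
    bindings: Mapping[str, float | np.ndarray],
    protected_value: float = 1.0,
):
    """Recursive arithmetic evaluation with protected (total) semantics.

    Division by a near-zero denominator (|x| < 1e-12) yields the protected
    value, as does any non-finite intermediate (tangent poles, overflow),
    so the result is always finite.  Terminal symbols are looked up in
    ``bindings``; vector bindings broadcast row-wise.
    """
    with np.errstate(all="ignore"):
        return _eval(tree, bindings, protected_value)


def _eval(node: Node, bindings, pv: float):
    if node.is_const:
        return node.value
    if not node.children:
        try:
            return bindings[node.symbol]
        except KeyError:
            raise GeneError(f"unbound terminal symbol {node.symbol!r}") from None
    sym = node.symbol
    a = _eval(node.children[0], bindings, pv)
    if sym == "tan":
        return _protect(np.tan(a), pv)
    b = _eval(node.children[1], bindings, pv)
    if sym == "+":
        return _protect(a + b, pv)
    if sym == "-":
        return _protect(a - b, pv)
    if sym == "*":
        return _protect(a * b, pv)
    if sym == "/":
        out = np.where(np.abs(b) < _EPS, pv, a / np.where(np.abs(b) < _EPS, 1.0, b))
        return _protect(out, pv)
    raise GeneError(f"unknown operator {sym!r}")


def chromosome_tree(
    chrom: Chromosome, functions: FunctionSet = FunctionSet()
) -> Node:
    """Linked phenotype: per-gene trees combined by the linking operator."""
    trees = [decode(g, functions) for g in chrom.genes]
    linked = trees[0]
    for t in trees[1:]:
        linked = Node("+", (linked, t))
    return linked


def evaluate_chromosome(
    chrom: Chromosome,
    bindings: Mapping[str, float | np.ndarray],
    functions: FunctionSet = FunctionSet(),
    protected_value: float = 1.0,
):
    """Sum of the per-gene tree evaluations (addition linking)."""
    with np.errstate(all="ignore"):
        total = _eval(decode(chrom.genes[0], functions), bindings, protected_value)
        for gene in chrom.genes[1:]:
            total = total + _eval(decode(gene, functions), bindings, protected_value)
        return _protect(total, protected_value)


def fitness(predicted: np.ndarray, observed: np.ndarray) -> float:
    """RMSE-based fitness, f = 1000/(1 + RMSE): in (0, 1000], and 1000
    exactly when predictions match observations."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape:
        raise ValueError("predicted and observed lengths differ")
    if observed.size < 2:
        raise ValueError("need at least 2 observations")
    if np.ptp(observed) == 0:
        raise ValueError("observed vector is constant; fitness undefined")
    rmse = float(np.sqrt(np.mean((predicted - observed) ** 2)))
    return 1000.0 / (1.0 + rmse)


def tree_to_text(tree: Node, precision: int | None = 3) -> str:
    """Deterministic fully parenthesized infix rendering.

    Constants print with ``precision`` decimals (default 3, e.g. 19.840);
    ``precision=None`` uses full repr so rendering round-trips through
    :func:`parse_expression` with exact constant values.
    """
    if tree.is_const:
        if precision is None:
            return repr(float(tree.value))
        return f"{tree.value:.{precision}f}"
    if not tree.children:
        return tree.symbol
    if tree.symbol == "tan":
        return f"tan({tree_to_text(tree.children[0], precision)})"
    a = tree_to_text(tree.children[0], precision)
    b = tree_to_text(tree.children[1], precision)
    return f"({a}{tree.symbol}{b})"


class _Parser:
    """Recursive-descent parser for infix arithmetic over named terminals.

    Accepts the rendering produced by :func:`tree_to_text` as well as free
    infix with conventional precedence (unary minus binds to its operand;
    ``*``/``/`` over ``+``/``-``; both left-associative).
    """

    def __init__(self, text: str):
        self.tokens = self._tokenize(text)
        self.pos = 0

    @staticmethod
    def _tokenize(text: str) -> list[str]:
        import re

        spec = r"\d+\.?\d*(?:[eE][+-]?\d+)?|[A-Za-z_][A-Za-z_0-9]*|[()+\-*/]"
        tokens = re.findall(spec, text)
        if "".join(tokens).replace(" ", "") != text.replace(" ", ""):
            raise ValueError(f"cannot tokenize expression: {text!r}")
        return tokens

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self, expected: str | None = None) -> str:
        tok = self.peek()
        if tok is None or (expected is not None and tok != expected):
            raise ValueError(f"unexpected token {tok!r} at position {self.pos}")
        self.pos += 1
        return tok

    def parse(self) -> Node:
        node = self.expr()
        if self.peek() is not None:
            raise ValueError(f"trailing tokens from {self.peek()!r}")
        return node

    def expr(self) -> Node:
        node = self.term()
        while self.peek() in ("+", "-"):
            op = self.take()
            node = Node(op, (node, self.term()))
        return node

    def term(self) -> Node:
        node = self.unary()
        while self.peek() in ("*", "/"):
            op = self.take()
            node = Node(op, (node, self.unary()))
        return node

    def unary(self) -> Node:
        if self.peek() == "-":
            self.take()
            operand = self.unary()
            if operand.is_const:
                return Node.const(-operand.value)
            return Node("-", (Node.const(0.0), operand))
        return self.atom()

    def atom(self) -> Node:
        tok = self.take()
        if tok == "(":
            node = self.expr()
            self.take(")")
            return node
        if tok[0].isdigit():
            return Node.const(float(tok))
        if self.peek() == "(":  # unary function call
            self.take("(")
            arg = self.expr()
            self.take(")")
            if tok == "tan":
                return Node("tan", (arg,))
            if tok == "inv":
                return Node("/", (Node.const(1.0), arg))
            raise ValueError(f"unknown function {tok!r}")
        return Node(tok)


def parse_expression(text: str) -> Node:
    """Parse an infix expression string back into an expression tree."""
    return _Parser(text).parse()
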