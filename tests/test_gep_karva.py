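"""Karva gene structure, breadth-first decoding, protected evaluation,
fitness, and the infix render/parse round trip."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gepqsar.gep import (
    Chromosome,
    FunctionSet,
    Gene,
    GeneError,
    Node,
    decode,
    evaluate,
    evaluate_chromosome,
    fitness,
    gene_structure,
    parse_expression,
    random_gene,
    tree_to_text,
)

FS = FunctionSet()
TERMINALS = ("a", "b", "c")


def gene_from_kexpr(kexpr, head_len, pad="a"):
    """Build a constant-free gene from the leading symbols of a K-expression."""
    tail_len, _ = gene_structure(head_len, FS.max_arity, use_constants=False)
    symbols = list(kexpr) + [pad] * (head_len + tail_len - len(kexpr))
    return Gene(tuple(symbols[:head_len]), tuple(symbols[head_len : head_len + tail_len]))


class TestGeneStructure:
    @pytest.mark.parametrize(
        "head, arity, constants, expected",
        [
            (8, 2, True, (9, 26)),
            (1, 2, False, (2, 3)),
            (8, 2, False, (9, 17)),
        ],
    )
    def test_tail_and_length_formula(self, head, arity, constants, expected):
        assert gene_structure(head, arity, constants) == expected

    def test_invalid_head_rejected(self):
        with pytest.raises(GeneError):
            gene_structure(0, 2)


class TestDecode:
    def test_terminal_root_is_single_node(self):
        tree = decode(gene_from_kexpr("a", 3))
        assert tree == Node("a")

    def test_karva_two_level_tree(self):
        # root *, children (+, a); + takes (b, c) -> (b+c)*a
        tree = decode(gene_from_kexpr("*+abc", 4))
        assert tree_to_text(tree) == "((b+c)*a)"
        assert evaluate(tree, dict(a=2.0, b=1.0, c=3.0)) == pytest.approx(8.0)

    def test_unary_inverse_chain(self):
        tree = decode(Gene(("inv", "b", "a"), ("a",) * 4))
        assert tree_to_text(tree, precision=None) == "(1.0/b)"
        assert evaluate(tree, dict(a=0.0, b=4.0)) == pytest.approx(0.25)

    def test_function_in_tail_rejected(self):
        with pytest.raises(GeneError, match="tail"):
            decode(Gene(("a", "a", "a"), ("+", "a", "a", "a")))

    def test_constant_placeholder_resolves_through_dc(self):
        # head 2: "?" root -> first Dc index selects from the pool
        gene = Gene(
            ("?", "a"), ("a", "a", "a"), dc=(2, 0, 0), constants=(1.5, -3.0, 7.25)
        )
        tree = decode(gene)
        assert tree == Node.const(7.25)

    @settings(max_examples=150, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_every_random_gene_decodes_deterministically(self, seed):
        rng = np.random.default_rng(seed)
        gene = random_gene(rng, FS, TERMINALS, head=8)
        t1, t2 = decode(gene), decode(gene)
        assert t1 == t2
        # evaluation is finite everywhere
        val = evaluate(t1, dict(a=0.3, b=-1.2, c=0.0))
        assert np.isfinite(val)


class TestProtectedEvaluation:
    def test_simple_addition(self):
        tree = Node("+", (Node("a"), Node("b")))
        assert evaluate(tree, dict(a=1.0, b=2.0)) == pytest.approx(3.0)

    def test_division_by_zero_returns_protected_value(self):
        tree = Node("/", (Node.const(1.0), Node("b")))
        assert evaluate(tree, dict(b=0.0)) == pytest.approx(1.0)
        assert evaluate(tree, dict(b=1e-15)) == pytest.approx(1.0)

    def test_tan_pole_protected(self):
        tree = Node("tan", (Node("a"),))
        big = evaluate(tree, dict(a=np.pi / 2))
        assert np.isfinite(big)

    def test_overflow_protected(self):
        huge = Node("*", (Node.const(1e308), Node.const(1e308)))
        assert float(np.asarray(evaluate(huge, {}))) == pytest.approx(1.0)

    def test_unbound_terminal_raises(self):
        with pytest.raises(GeneError, match="unbound"):
            evaluate(Node("z"), dict(a=1.0))

    def test_vector_bindings_broadcast(self):
        tree = Node("*", (Node("a"), Node("a")))
        out = evaluate(tree, dict(a=np.array([1.0, 2.0, 3.0])))
        np.testing.assert_allclose(out, [1.0, 4.0, 9.0])


class TestChromosomeLinking:
    def test_linked_value_is_sum_of_gene_values(self, rng):
        genes = tuple(random_gene(rng, FS, TERMINALS, head=4) for _ in range(5))
        chrom = Chromosome(genes)
        bindings = dict(a=0.7, b=-0.4, c=2.2)
        per_gene = [float(np.asarray(evaluate(decode(g), bindings))) for g in genes]
        linked = float(np.asarray(evaluate_chromosome(chrom, bindings)))
        assert linked == pytest.approx(sum(per_gene), rel=1e-12)


class TestFitness:
    def test_exact_predictions_score_1000(self, rng):
        y = rng.standard_normal(10)
        assert fitness(y, y) == 1000.0

    def test_rmse_one_scores_500(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        assert fitness(obs + 1.0, obs) == pytest.approx(500.0)

    def test_monotone_in_error(self, rng):
        obs = rng.standard_normal(12)
        e = rng.uniform(0.1, 1.0, 12)
        assert fitness(obs + e, obs) > fitness(obs + 2 * e, obs)

    def test_any_nonzero_error_scores_below_1000(self):
        obs = np.array([0.0, 1.0, 2.0])
        assert fitness(obs + 1e-9, obs) < 1000.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fitness(np.ones(3), np.ones(4))

    def test_constant_observations_rejected(self):
        with pytest.raises(ValueError):
            fitness(np.ones(5), np.ones(5))


class TestRenderParse:
    def test_fully_parenthesized_infix(self):
        tree = Node("*", (Node("+", (Node("b"), Node("c"))), Node("a")))
        assert tree_to_text(tree) == "((b+c)*a)"

    def test_constants_render_with_three_decimals(self):
        assert tree_to_text(Node.const(19.84)) == "19.840"

    def test_parse_respects_precedence(self):
        tree = parse_expression("a+b*c")
        assert tree == Node("+", (Node("a"), Node("*", (Node("b"), Node("c")))))

    def test_negative_constant_parses(self):
        tree = parse_expression("(9.984/-9.910)")
        assert tree == Node("/", (Node.const(9.984), Node.const(-9.910)))

    @settings(max_examples=200, deadline=None)
    @given(seed=st.integers(0, 100_000))
    def test_render_parse_round_trip(self, seed):
        rng = np.random.default_rng(seed)
        gene = random_gene(rng, FS, TERMINALS, head=6)
        tree = decode(gene)
        back = parse_expression(tree_to_text(tree, precision=None))
        assert back == tree
        row = dict(a=0.37, b=-2.1, c=5.0)
        assert float(np.asarray(evaluate(back, row))) == pytest.approx(
            float(np.asarray(evaluate(tree, row))), rel=1e-12
        )
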