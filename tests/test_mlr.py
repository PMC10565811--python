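"""OLS fitting against a normal-equations oracle, leave-one-out R2cv against
a literal refit loop, the correlation filter, and the greedy scan."""

import numpy as np
import pytest

from gepqsar import mlr
from gepqsar.synthetic import (
    HM_COEFFICIENTS,
    HM_INTERCEPT,
    INFORMATIVE_NAMES,
    SyntheticSpec,
    add_correlated_copy,
    generate,
)
from gepqsar.tables import DescriptorTable
from tests.conftest import random_table


def linear_target_table(rng, n, p, noise=0.0):
    values = rng.standard_normal((n, p))
    beta = rng.uniform(-2, 2, size=p)
    activity = 1.5 + values @ beta + noise * rng.standard_normal(n)
    return DescriptorTable(
        tuple(f"c{i}" for i in range(n)),
        tuple(f"X{j}" for j in range(p)),
        values,
        activity,
    )


class TestFitOls:
    def test_matches_normal_equations_oracle(self, rng):
        table = random_table(rng, 12, 3)
        fit = mlr.fit_ols(table, table.descriptor_names)
        X = np.column_stack([np.ones(12), table.values])
        beta = np.linalg.inv(X.T @ X) @ X.T @ table.activity
        assert fit.intercept == pytest.approx(beta[0], abs=1e-8)
        np.testing.assert_allclose(fit.coefficients, beta[1:], atol=1e-8)

    def test_identity_regression(self, rng):
        table = random_table(rng, 10, 2)
        table = DescriptorTable(
            table.compound_ids, table.descriptor_names, table.values,
            table.values[:, 0],
        )
        fit = mlr.fit_ols(table, table.descriptor_names)
        assert fit.coefficients[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.coefficients[1] == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)
        assert fit.s2 == pytest.approx(0.0, abs=1e-20)

    def test_recovers_planted_coefficients_to_4sf(self):
        table = generate(SyntheticSpec(n_compounds=39, noise_sd=0.0, seed=5))
        fit = mlr.fit_ols(table, INFORMATIVE_NAMES)
        assert fit.intercept == pytest.approx(HM_INTERCEPT, rel=1e-4)
        for name, coef in zip(fit.descriptor_names, fit.coefficients):
            assert coef == pytest.approx(HM_COEFFICIENTS[name], rel=1e-4)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_r2_invariant_under_affine_rescaling(self, rng):
        table = linear_target_table(rng, 20, 3, noise=0.5)
        base = mlr.fit_ols(table, table.descriptor_names).r2
        scaled_values = table.values.copy()
        scaled_values[:, 1] = 100.0 * scaled_values[:, 1] - 7.0
        scaled = DescriptorTable(
            table.compound_ids, table.descriptor_names, scaled_values, table.activity
        )
        assert mlr.fit_ols(scaled, table.descriptor_names).r2 == pytest.approx(base, abs=1e-10)

    def test_adding_column_never_decreases_r2(self, rng):
        for _ in range(10):
            table = random_table(rng, 18, 5)
            names = table.descriptor_names
            r2_small = mlr.fit_ols(table, names[:2]).r2
            r2_big = mlr.fit_ols(table, names[:3]).r2
            assert r2_big >= r2_small - 1e-12

    def test_rank_deficiency_rejected(self, rng):
        table = random_table(rng, 10, 2)
        dup = table.with_column("X0_copy", table.values[:, 0])
        with pytest.raises(np.linalg.LinAlgError):
            mlr.fit_ols(dup, ("X0", "X0_copy", "X1"))

    def test_too_few_rows_rejected(self, rng):
        table = random_table(rng, 4, 3)
        with pytest.raises(ValueError):
            mlr.fit_ols(table, table.descriptor_names)

    def test_r2cv_never_exceeds_r2(self, rng):
        for _ in range(10):
            table = random_table(rng, 15, 4)
            fit = mlr.fit_ols(table, table.descriptor_names)
            assert fit.r2_cv <= fit.r2 + 1e-9


class TestLooR2cv:
    def test_matches_brute_force_refit_loop(self, rng):
        table = random_table(rng, 15, 2)
        fast = mlr.loo_r2cv(table, table.descriptor_names)
        # independent oracle: literally refit n times
        X = np.column_stack([np.ones(15), table.values])
        y = table.activity
        press = 0.0
        for i in range(15):
            mask = np.arange(15) != i
            beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
            press += (y[i] - X[i] @ beta) ** 2
        oracle = 1 - press / np.sum((y - y.mean()) ** 2)
        assert fast == pytest.approx(oracle, abs=1e-9)

    def test_perfect_model_scores_one(self):
        table = generate(SyntheticSpec(n_compounds=30, noise_sd=0.0, seed=2))
        assert mlr.loo_r2cv(table, INFORMATIVE_NAMES) == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_cv_below_r2(self, rng):
        table = random_table(rng, 15, 4)  # activity unrelated to columns
        fit = mlr.fit_ols(table, table.descriptor_names)
        assert fit.r2_cv < fit.r2


class TestCorrelationMatrix:
    def test_diagonal_and_antisymmetry(self, rng):
        table = random_table(rng, 10, 1)
        table = table.with_column("neg", -table.values[:, 0])
        m = mlr.correlation_matrix(table, ("X0", "neg"))
        assert m[0, 0] == pytest.approx(1.0)
        assert m[0, 1] == pytest.approx(-1.0)

    def test_matches_direct_formula(self, rng):
        table = random_table(rng, 10, 2)
        m = mlr.correlation_matrix(table, table.descriptor_names)
        a, b = table.values[:, 0], table.values[:, 1]
        cov = np.mean((a - a.mean()) * (b - b.mean()))
        oracle = cov / (a.std() * b.std())
        assert m[0, 1] == pytest.approx(oracle, abs=1e-10)

    def test_constant_column_rejected(self, rng):
        table = random_table(rng, 10, 1).with_column("const", np.ones(10))
        with pytest.raises(ValueError, match="const"):
            mlr.correlation_matrix(table, ("X0", "const"))


class TestSelection:
    def test_duplicate_column_never_coselected(self):
        table = generate(SyntheticSpec(n_compounds=31, noise_sd=0.15, seed=1))
        table = add_correlated_copy(table, "TM2RE", r=1.0, name="TM2RE_dup", seed=2)
        result = mlr.select_descriptors(table, max_k=5, epsilon=None)
        assert not {"TM2RE", "TM2RE_dup"} <= set(result.selected_names)

    def test_selected_respect_correlation_threshold(self):
        for seed in range(3):
            table = generate(SyntheticSpec(n_compounds=31, seed=seed))
            table = add_correlated_copy(table, "MSA", r=0.95, name="MSA_twin", seed=seed)
            result = mlr.select_descriptors(table, epsilon=None)
            off = np.abs(
                result.correlation_matrix - np.eye(len(result.selected_names))
            )
            assert off.max() < 0.8

    def test_scan_r2_is_nondecreasing(self):
        table = generate(SyntheticSpec(n_compounds=31, noise_sd=0.15, seed=4))
        result = mlr.select_descriptors(table, max_k=6, epsilon=None)
        r2s = [rec["r2"] for rec in result.scan]
        assert all(b >= a - 1e-12 for a, b in zip(r2s, r2s[1:]))

    def test_stopping_rule_truncates_weak_gains(self):
        # strong planted signal: the stopping rule should not run to max_k
        table = generate(SyntheticSpec(n_compounds=35, noise_sd=0.05, seed=8))
        full = mlr.select_descriptors(table, max_k=6, epsilon=None)
        stopped = mlr.select_descriptors(table, max_k=6, epsilon=0.02)
        assert len(stopped.selected_names) <= len(full.selected_names)
        assert len(stopped.selected_names) >= 1

    def test_max_k_capped_by_sample_size_rule(self):
        table = generate(SyntheticSpec(n_compounds=20, seed=3))
        result = mlr.select_descriptors(table, max_k=10, epsilon=None)
        assert len(result.selected_names) <= mlr.max_k_rule(20)
        assert mlr.max_k_rule(31) == 6

    def test_all_constant_columns_rejected(self):
        table = DescriptorTable(
            ("a", "b", "c", "d", "e", "f", "g"),
            ("C1", "C2"),
            np.ones((7, 2)),
            np.arange(7.0),
        )
        with pytest.raises(ValueError, match="constant"):
            mlr.select_descriptors(table, max_k=1)
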