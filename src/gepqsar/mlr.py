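"""Heuristic multiple-linear-regression track: OLS fits, leave-one-out
cross-validation, the pairwise-intercorrelation filter, and the greedy
descriptor-count scan.

The selection procedure mirrors CODESSA-style heuristic regression: grow the
descriptor subset one column at a time, always adding the candidate that
maximizes the leave-one-out cross-validated R² among candidates whose
absolute correlation with every already-selected descriptor stays below a
threshold (default 0.8), and stop once the gain fades.  A seeded stochastic
hill-climbing variant is available for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .tables import DescriptorTable

__all__ = [
    "LinearModel",
    "SelectionResult",
    "fit_ols",
    "loo_r2cv",
    "select_descriptors",
    "correlation_matrix",
    "max_k_rule",
]


@dataclass(frozen=True)
class LinearModel:
    """OLS fit summary for one descriptor subset.

    ``t_values`` are absolute t statistics, intercept first, so it has one
    more entry than ``coefficients``.
    """

    intercept: float
    coefficients: tuple[float, ...]
    descriptor_names: tuple[str, ...]
    t_values: tuple[float, ...]
    r2: float
    r2_cv: float
    s2: float
    f_stat: float
    n: int

    def predict(self, table: DescriptorTable) -> np.ndarray:
        x = np.column_stack([table.column(name) for name in self.descriptor_names])
        return self.intercept + x @ np.asarray(self.coefficients)


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of the descriptor-selection scan."""

    selected_names: tuple[str, ...]
    scan: tuple[dict, ...]  # per-k records: k, names, r2, r2_cv, s2, f_stat
    correlation_matrix: np.ndarray
    corr_threshold: float

    def __post_init__(self) -> None:
        c = np.abs(self.correlation_matrix - np.eye(len(self.selected_names)))
        if c.size and c.max() >= self.corr_threshold:
            raise ValueError("selected descriptors violate the correlation threshold")


def _design(table: DescriptorTable, subset: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    x = np.column_stack([table.column(name) for name in subset])
    return sm.add_constant(x, has_constant="add"), table.activity


def _press_r2(X: np.ndarray, y: np.ndarray, resid: np.ndarray) -> float:
    # hat-matrix shortcut: LOO residual e_i / (1 - h_ii)
    q, _ = np.linalg.qr(X)
    h = np.einsum("ij,ij->i", q, q)
    if np.any(h >= 1 - 1e-12):
        raise np.linalg.LinAlgError("leave-one-out refit rank-deficient (leverage 1 row)")
    press = float(np.sum((resid / (1 - h)) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    return 1 - press / sst


def fit_ols(table: DescriptorTable, subset: Sequence[str]) -> LinearModel:
    """Least-squares fit of the activity on the named descriptor columns.

    Reports R², leave-one-out R²cv, the regression residual variance
    s² = SSE/(n-p-1), the overall F statistic and absolute t values.
    """
    subset = tuple(subset)
    n, p = table.n_compounds, len(subset)
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} rows to fit {p} descriptors, have {n}")
    X, y = _design(table, subset)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    res = sm.OLS(y, X).fit()
    return LinearModel(
        intercept=float(res.params[0]),
        coefficients=tuple(float(b) for b in res.params[1:]),
        descriptor_names=subset,
        t_values=tuple(float(abs(t)) for t in res.tvalues),
        r2=float(res.rsquared),
        r2_cv=_press_r2(X, y, res.resid),
        s2=float(res.mse_resid),
        f_stat=float(res.fvalue) if p > 0 else 0.0,
        n=n,
    )


def loo_r2cv(table: DescriptorTable, subset: Sequence[str]) -> float:
    """Leave-one-out cross-validated R²: 1 - PRESS/SST.

    Computed via the hat-matrix identity, which equals the literal
    n-refit loop for OLS.
    """
    subset = tuple(subset)
    if table.n_compounds <= len(subset) + 2:
        raise ValueError("too few rows for leave-one-out cross-validation")
    X, y = _design(table, subset)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return _press_r2(X, y, y - X @ beta)


def correlation_matrix(table: DescriptorTable, subset: Sequence[str]) -> np.ndarray:
    """Pearson correlation matrix of the named descriptor columns."""
    subset = tuple(subset)
    if table.n_compounds < 3:
        raise ValueError("need at least 3 rows for correlations")
    cols = np.column_stack([table.column(name) for name in subset])
    if np.any(cols.std(axis=0) == 0):
        bad = [name for name in subset if table.column(name).std() == 0]
        raise ValueError(f"constant column(s) have undefined correlation: {bad}")
    return np.corrcoef(cols, rowvar=False).reshape(len(subset), len(subset))


def max_k_rule(n: int) -> int:
    """Descriptor-count cap: at most one descriptor per five compounds."""
    return max(1, n // 5)


def _admissible(table, name, selected, corr_threshold):
    for prev in selected:
        r = np.corrcoef(table.column(name), table.column(prev))[0, 1]
        if abs(r) >= corr_threshold:
            return False
    return True


def select_descriptors(
    table: DescriptorTable,
    max_k: int | None = None,
    corr_threshold: float = 0.8,
    k_scan_range: Sequence[int] | None = None,
    epsilon: float | None = 0.02,
    score: str = "r2_cv",
    method: str = "greedy",
    seed: int = 0,
) -> SelectionResult:
    """Stepwise descriptor selection with an intercorrelation filter.

    Greedy forward selection (default): at each step add the admissible
    candidate maximizing the score (leave-one-out R²cv by default; plain R²
    via ``score="r2"``), recording the fit statistics at every subset size.
    The returned subset is truncated at the last step whose score gain was
    at least ``epsilon`` — the "no significant change" stopping rule
    (``epsilon=None`` disables truncation and returns the full subset of
    size ``max_k``).
    ``max_k`` is capped by the one-descriptor-per-five-compounds rule.
    Ties are broken by column order.  ``method="hillclimb"`` runs a seeded
    stochastic swap search of the same subset size instead.
    """
    n = table.n_compounds
    cap = max_k_rule(n)
    max_k = cap if max_k is None else min(max_k, cap)
    if not 0 < corr_threshold <= 1:
        raise ValueError("corr_threshold must be in (0, 1]")
    if n < max_k + 2:
        raise ValueError("too few rows for the requested subset size")
    candidates = [name for name in table.descriptor_names if table.column(name).std() > 0]
    if not candidates:
        raise ValueError("no admissible candidate descriptors (all columns constant)")
    if k_scan_range is not None:
        max_k = min(max_k, max(k_scan_range))

    selected: list[str] = []
    scan: list[dict] = []
    while len(selected) < max_k:
        best_name, best_score, best_fit = None, -np.inf, None
        for name in candidates:
            if name in selected or not _admissible(table, name, selected, corr_threshold):
                continue
            try:
                fit = fit_ols(table, selected + [name])
            except np.linalg.LinAlgError:
                continue
            val = fit.r2_cv if score == "r2_cv" else fit.r2
            if val > best_score:  # strict: ties keep the earlier column
                best_name, best_score, best_fit = name, val, fit
        if best_name is None:
            break
        selected.append(best_name)
        scan.append(
            {
                "k": len(selected),
                "names": tuple(selected),
                "r2": best_fit.r2,
                "r2_cv": best_fit.r2_cv,
                "s2": best_fit.s2,
                "f_stat": best_fit.f_stat,
            }
        )

    # stopping rule: keep growing only while the score gain is >= epsilon
    key = "r2_cv" if score == "r2_cv" else "r2"
    k_final = len(scan)
    if epsilon is not None:
        k_final = 1
        for i in range(1, len(scan)):
            if scan[i][key] - scan[i - 1][key] >= epsilon:
                k_final = i + 1
            else:
                break
    final = list(scan[k_final - 1]["names"]) if scan else []

    if method == "hillclimb" and final:
        final = _hillclimb(table, final, candidates, corr_threshold, key, seed)

    return SelectionResult(
        selected_names=tuple(final),
        scan=tuple(scan),
        correlation_matrix=correlation_matrix(table, final)
        if len(final) >= 1 and n >= 3
        else np.eye(len(final)),
        corr_threshold=corr_threshold,
    )


def _hillclimb(table, subset, candidates, corr_threshold, key, seed, n_iter=200):
    """Seeded stochastic swap search at fixed subset size."""
    rng = np.random.default_rng(seed)
    current = list(subset)

    def score_of(names):
        fit = fit_ols(table, names)
        return fit.r2_cv if key == "r2_cv" else fit.r2

    best = score_of(current)
    for _ in range(n_iter):
        out_i = int(rng.integers(len(current)))
        pool = [c for c in candidates if c not in current]
        if not pool:
            break
        cand = pool[int(rng.integers(len(pool)))]
        trial = current[:out_i] + [cand] + current[out_i + 1 :]
        others = trial[:out_i] + trial[out_i + 1 :]
        if not _admissible(table, cand, others, corr_threshold):
            continue
        try:
            val = score_of(trial)
        except np.linalg.LinAlgError:
            continue
        if val > best:
            current, best = trial, val
    return current
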