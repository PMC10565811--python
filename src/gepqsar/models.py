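"""Reference predictors for the two published final equations, and the
train/test comparison statistics.

The linear reference is the four-descriptor affine model.  The nonlinear
reference is a canonical transcription of the published evolved equation,
which as printed has unbalanced parentheses, the bare token ``tan-2.954``,
an implicit product ``2MSA``, and an undefined symbol ``d2``; every
disambiguation is isolated in the transcription strings below so that
alternative readings stay pluggable (see docs/methods.md for the footnotes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .gep.karva import Node, evaluate, parse_expression
from .synthetic import planted_linear_hm
from .tables import DescriptorTable, SplitPlan

__all__ = [
    "GEP_EQUATION_VARIANTS",
    "ReferenceModel",
    "ComparisonReport",
    "predict_hm",
    "predict_gep_reference",
    "hm_reference",
    "gep_reference",
    "compare",
]

#: Transcriptions of the published evolved equation.  Shared readings:
#: parentheses balanced left-greedily; ``2MSA`` read as 2*MSA;
#: ``9.984/-9.910+TM2RE`` grouped as (9.984/-9.910)+TM2RE; the undefined
#: token ``d2`` kept as a terminal bound to a placeholder constant
#: (default 1.0).  The variants differ in the reading of ``tan-2.954``:
#: ``canonical`` takes tan(-2.954) as a constant subexpression, while
#: ``tan_of_sum`` applies the tangent to the whole difference.
GEP_EQUATION_VARIANTS: dict[str, str] = {
    "canonical": (
        "(FFPQC+(((1/MSA)*tan(MSA))/(1/19.840)))"
        "+((1/(tan(-2.954)-FFPQC))+0.153)"
        "+tan((2*MSA)*((9.984/-9.910)+TM2RE))"
        "+(1/(8.277/(MSA/((FFPQC/ANRIFN)-(1/ANRIFN)))))"
        "+(1/(MSA*tan(((MSA/d2)*ANRIFN)+(1/MSA))))"
    ),
    "tan_of_sum": (
        "(FFPQC+(((1/MSA)*tan(MSA))/(1/19.840)))"
        "+((1/tan(-2.954-FFPQC))+0.153)"
        "+tan((2*MSA)*((9.984/-9.910)+TM2RE))"
        "+(1/(8.277/(MSA/((FFPQC/ANRIFN)-(1/ANRIFN)))))"
        "+(1/(MSA*tan(((MSA/d2)*ANRIFN)+(1/MSA))))"
    ),
}

D2_PLACEHOLDER_DEFAULT = 1.0


@dataclass(frozen=True)
class ReferenceModel:
    """Named row-wise predictor with a provenance note."""

    name: str
    predict_row: Callable[[Mapping[str, float]], float]
    provenance: str = ""

    def predict(self, table: DescriptorTable) -> np.ndarray:
        cols = table.columns()
        return np.array(
            [
                self.predict_row({name: cols[name][i] for name in cols})
                for i in range(table.n_compounds)
            ]
        )


def predict_hm(row: Mapping[str, float]) -> float:
    """Published linear model evaluated on one descriptor row."""
    return planted_linear_hm(row)


def _gep_tree(variant: str) -> Node:
    try:
        return parse_expression(GEP_EQUATION_VARIANTS[variant])
    except KeyError:
        raise ValueError(
            f"unknown transcription variant {variant!r}; choose from {sorted(GEP_EQUATION_VARIANTS)}"
        ) from None


def predict_gep_reference(
    row: Mapping[str, float],
    variant: str = "canonical",
    d2: float = D2_PLACEHOLDER_DEFAULT,
) -> float:
    """Canonical transcription of the published evolved equation, evaluated
    with protected semantics on one descriptor row."""
    bindings = dict(row)
    bindings.setdefault("d2", d2)
    return float(np.asarray(evaluate(_gep_tree(variant), bindings)))


def hm_reference() -> ReferenceModel:
    return ReferenceModel("HM", predict_hm, "published four-descriptor linear model")


def gep_reference(variant: str = "canonical", d2: float = D2_PLACEHOLDER_DEFAULT) -> ReferenceModel:
    return ReferenceModel(
        f"GEP-reference[{variant}]",
        lambda row: predict_gep_reference(row, variant, d2),
        "transcription of the published evolved equation",
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Per-model, per-partition goodness-of-fit records.

    ``r2`` is 1 - SSE/SST on the partition; ``s2`` is SSE/(n-1) on the
    partition (a dispersion convention used only for relative comparison;
    the regression-fit residual variance SSE/(n-p-1) lives on LinearModel).
    """

    entries: tuple[dict, ...] = field(default_factory=tuple)

    def for_model(self, name: str, partition: str) -> dict:
        for e in self.entries:
            if e["model"] == name and e["partition"] == partition:
                return e
        raise KeyError(f"no entry for model {name!r}, partition {partition!r}")

    def to_json(self) -> str:
        slim = [{k: v for k, v in e.items() if k != "residuals"} for e in self.entries]
        return json.dumps({"entries": slim}, indent=2, sort_keys=True)


def _partition_stats(pred: np.ndarray, obs: np.ndarray) -> tuple[float, float]:
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst == 0:
        raise ValueError("degenerate partition: constant activity")
    sse = float(np.sum((obs - pred) ** 2))
    return 1 - sse / sst, sse / (len(obs) - 1)


def compare(
    models: Sequence, table: DescriptorTable, split_plan: SplitPlan
) -> ComparisonReport:
    """Evaluate each model on the train and test partitions separately.

    Models need a ``name`` attribute and a ``predict(table) -> vector``
    method (ReferenceModel and GepModel both qualify).
    """
    n = table.n_compounds
    if len(split_plan.train_indices) + len(split_plan.test_indices) != n:
        raise ValueError("split plan does not match table size")
    entries = []
    for model in models:
        for partition, idx in (
            ("train", split_plan.train_indices),
            ("test", split_plan.test_indices),
        ):
            part = table.subset_rows(idx)
            pred = np.asarray(model.predict(part), dtype=float)
            r2, s2 = _partition_stats(pred, part.activity)
            entries.append(
                {
                    "model": model.name,
                    "partition": partition,
                    "r2": r2,
                    "s2": s2,
                    "n": part.n_compounds,
                    "residuals": (part.activity - pred).tolist(),
                }
            )
    return ComparisonReport(tuple(entries))
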