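"""Synthetic descriptor/activity tables with the statistical structure the models assume.

The quantum-chemical descriptor values behind the published regression were
never deposited, so benchmarks run on simulated tables instead: four
informative descriptors drawn from a multivariate normal with the published
pairwise correlation structure, a configurable number of independent decoy
columns, and a log-activity planted from either the published linear model
or a known nonlinear expression, plus Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping

import numpy as np

from .tables import DescriptorTable

__all__ = [
    "INFORMATIVE_NAMES",
    "DESCRIPTOR_CORRELATION",
    "DEFAULT_SCALES",
    "HM_COEFFICIENTS",
    "HM_INTERCEPT",
    "SyntheticSpec",
    "generate",
    "planted_linear_hm",
    "planted_nonlinear_reference",
    "nonlinear_benchmark_spec",
    "add_correlated_copy",
]

#: The four selected descriptors: molecular surface area, average
#: nucleophilic reactivity index for a nitrogen atom, fractional partial
#: positive surface area (PPSA-2/TMSA), total molecular 2-center resonance
#: energy.
INFORMATIVE_NAMES = ("MSA", "ANRIFN", "FFPQC", "TM2RE")

#: Published pairwise Pearson correlations among the four descriptors.
DESCRIPTOR_CORRELATION = np.array(
    [
        [1.000, -0.072, 0.474, -0.720],
        [-0.072, 1.000, 0.071, -0.104],
        [0.474, 0.071, 1.000, -0.702],
        [-0.720, -0.104, -0.702, 1.000],
    ]
)

#: Marginal (mean, sd) per descriptor.  The true ranges are unpublished;
#: these are chosen so the linear model's coefficient magnitudes are
#: plausible (MSA is surface-area-like, O(100s); the MSA coefficient is
#: O(1e-3)).
DEFAULT_SCALES: dict[str, tuple[float, float]] = {
    "MSA": (500.0, 100.0),
    "ANRIFN": (0.05, 0.02),
    "FFPQC": (20.0, 5.0),
    "TM2RE": (0.5, 0.2),
}

HM_INTERCEPT = -9.023
HM_COEFFICIENTS: dict[str, float] = {
    "MSA": -1.095e-03,
    "ANRIFN": 8.299,
    "FFPQC": 6.249e-02,
    "TM2RE": 4.720,
}


def planted_linear_hm(row: Mapping[str, float]) -> float:
    """Published linear model: affine combination of the four descriptors.

    log IC50 = -9.023 - 1.095e-03*MSA + 8.299*ANRIFN
               + 6.249e-02*FFPQC + 4.720*TM2RE
    """
    try:
        return HM_INTERCEPT + sum(c * float(row[name]) for name, c in HM_COEFFICIENTS.items())
    except KeyError as exc:
        raise KeyError(f"missing descriptor {exc.args[0]!r} for linear model") from None


def planted_nonlinear_reference(row: Mapping[str, float]) -> float:
    """Nonlinear benchmark target: MSA*TM2RE + FFPQC.

    Expressible in two genes over the {+, -, *, /, tan, inv} function set
    (one product gene, one single-terminal gene, addition linking).  Meant
    for standardized descriptor scales (mean 0, sd 1); see
    :func:`nonlinear_benchmark_spec`.
    """
    try:
        return float(row["MSA"]) * float(row["TM2RE"]) + float(row["FFPQC"])
    except KeyError as exc:
        raise KeyError(f"missing descriptor {exc.args[0]!r} for nonlinear model") from None


_PLANTED: dict[str, Callable[[Mapping[str, float]], float]] = {
    "linear_hm": planted_linear_hm,
    "nonlinear_reference": planted_nonlinear_reference,
}


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one simulated descriptor/activity table."""

    n_compounds: int = 39
    n_decoys: int = 16
    target_correlation: np.ndarray = field(
        default_factory=lambda: DESCRIPTOR_CORRELATION.copy()
    )
    descriptor_scales: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_SCALES)
    )
    planted_model: str | Callable[[Mapping[str, float]], float] = "linear_hm"
    noise_sd: float = 0.15
    seed: int = 0

    def __post_init__(self) -> None:
        corr = np.asarray(self.target_correlation, dtype=float)
        object.__setattr__(self, "target_correlation", corr)
        if corr.shape != (4, 4):
            raise ValueError("target_correlation must be 4x4")
        if not np.allclose(corr, corr.T):
            raise ValueError("target_correlation must be symmetric")
        if not np.allclose(np.diag(corr), 1.0):
            raise ValueError("target_correlation must have a unit diagonal")
        eigvals = np.linalg.eigvalsh(corr)
        if eigvals.min() < -1e-10:
            clipped = _nearest_psd(corr)
            raise ValueError(
                "target_correlation is not positive semi-definite "
                f"(min eigenvalue {eigvals.min():.3g}); nearest PSD candidate:\n{clipped}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.n_compounds < 2:
            raise ValueError("n_compounds must be at least 2")
        if isinstance(self.planted_model, str) and self.planted_model not in _PLANTED:
            raise ValueError(
                f"unknown planted_model {self.planted_model!r}; "
                f"choose from {sorted(_PLANTED)} or pass a callable"
            )

    @property
    def planted(self) -> Callable[[Mapping[str, float]], float]:
        if callable(self.planted_model):
            return self.planted_model
        return _PLANTED[self.planted_model]


def _nearest_psd(corr: np.ndarray) -> np.ndarray:
    """Eigenvalue-clipped, rescaled-to-unit-diagonal PSD approximation."""
    w, v = np.linalg.eigh(corr)
    fixed = (v * np.clip(w, 1e-10, None)) @ v.T
    d = np.sqrt(np.diag(fixed))
    return fixed / np.outer(d, d)


def generate(spec: SyntheticSpec) -> DescriptorTable:
    """Draw one table according to the spec; fully reproducible from its seed.

    Informative columns come from a multivariate normal with the requested
    correlation, affinely rescaled to the per-descriptor (mean, sd); decoy
    columns (DEC01, DEC02, ...) are independent standard normals; activity
    is the planted model evaluated row-wise plus Gaussian noise.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    chol = np.linalg.cholesky(spec.target_correlation + 1e-12 * np.eye(4))
    z = rng.standard_normal((n, 4)) @ chol.T
    cols = {}
    for j, name in enumerate(INFORMATIVE_NAMES):
        mean, sd = spec.descriptor_scales[name]
        cols[name] = mean + sd * z[:, j]
    for k in range(spec.n_decoys):
        cols[f"DEC{k + 1:02d}"] = rng.standard_normal(n)
    names = tuple(cols)
    values = np.column_stack([cols[name] for name in names])
    planted = spec.planted
    signal = np.array(
        [planted({name: values[i, j] for j, name in enumerate(names)}) for i in range(n)]
    )
    activity = signal + rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else signal
    ids = tuple(f"syn{i + 1:03d}" for i in range(n))
    return DescriptorTable(ids, names, values, activity)


def nonlinear_benchmark_spec(seed: int, n_compounds: int = 39, noise_sd: float = 0.1) -> SyntheticSpec:
    """Study conditions for the symbolic-regression recovery benchmark.

    Four correlated descriptors on standardized scales (mean 0, sd 1, the
    published correlation structure), no decoys, planted target
    MSA*TM2RE + FFPQC with noise_sd on the log-activity scale.  Unit
    scales keep the target inside the engine's constant range, mirroring
    the common practice of standardizing inputs before symbolic
    regression.
    """
    return SyntheticSpec(
        n_compounds=n_compounds,
        n_decoys=0,
        descriptor_scales={name: (0.0, 1.0) for name in INFORMATIVE_NAMES},
        planted_model="nonlinear_reference",
        noise_sd=noise_sd,
        seed=seed,
    )


def add_correlated_copy(
    table: DescriptorTable, source: str, r: float, name: str, seed: int
) -> DescriptorTable:
    """Append a column with Pearson correlation ~r to an existing column.

    Used to plant near-duplicate decoys for testing the pairwise
    intercorrelation filter.
    """
    if not 0 < abs(r) <= 1:
        raise ValueError("target correlation must be in (0, 1]")
    rng = np.random.default_rng(seed)
    x = table.column(source)
    zx = (x - x.mean()) / x.std()
    noise = rng.standard_normal(len(zx))
    col = r * zx + np.sqrt(max(0.0, 1 - r * r)) * noise
    return table.with_column(name, col)
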