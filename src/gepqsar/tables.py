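"""Descriptor/activity tables, the packaged inhibitor fixture, and train/test splitting.

A QSAR dataset is a compound-by-descriptor numeric matrix with an aligned
activity vector (here log10 of an IC50 in nM).  Tables live on disk as
delimited text with a header row; in memory they are thin frozen wrappers
around numpy arrays with named columns, convertible to/from pandas.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CompoundRecord",
    "DescriptorTable",
    "SplitPlan",
    "TableError",
    "load_table",
    "write_table",
    "log_transform",
    "split",
    "min_activity",
    "max_activity",
    "load_fixture",
    "fixture_dataframe",
    "FIXTURE_RESOURCE",
]

FIXTURE_RESOURCE = "thiazolidinone_ic50.csv"


class TableError(ValueError):
    """Raised for malformed or inconsistent table input."""


@dataclass(frozen=True)
class CompoundRecord:
    """One assay measurement: a compound label and its IC50 in nanomolar."""

    compound_id: str
    ic50_nM: float
    log_ic50: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        if not self.ic50_nM > 0:
            raise TableError(
                f"compound {self.compound_id!r}: IC50 must be positive, got {self.ic50_nM}"
            )
        if np.isnan(self.log_ic50):
            object.__setattr__(self, "log_ic50", float(np.log10(self.ic50_nM)))
        elif abs(self.log_ic50 - np.log10(self.ic50_nM)) > 1e-12:
            raise TableError(
                f"compound {self.compound_id!r}: log_ic50 inconsistent with ic50_nM"
            )


@dataclass(frozen=True)
class DescriptorTable:
    """Compound-by-descriptor matrix with an aligned activity vector."""

    compound_ids: tuple[str, ...]
    descriptor_names: tuple[str, ...]
    values: np.ndarray  # shape (n_compounds, n_descriptors)
    activity: np.ndarray  # shape (n_compounds,)
    activity_name: str = "log_ic50"

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        activity = np.asarray(self.activity, dtype=float)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "activity", activity)
        object.__setattr__(self, "compound_ids", tuple(self.compound_ids))
        object.__setattr__(self, "descriptor_names", tuple(self.descriptor_names))
        n, p = values.shape if values.ndim == 2 else (len(values), 0)
        if values.ndim != 2:
            raise TableError("descriptor values must be a 2-D matrix")
        if len(self.compound_ids) != n or len(activity) != n:
            raise TableError("row count mismatch between ids, values and activity")
        if len(self.descriptor_names) != p:
            raise TableError("column count mismatch with descriptor names")
        if len(set(self.descriptor_names)) != p:
            raise TableError("descriptor names must be unique")
        if len(set(self.compound_ids)) != n:
            dupes = sorted({c for c in self.compound_ids if self.compound_ids.count(c) > 1})
            raise TableError(f"duplicate compound identifiers: {dupes}")
        if not np.all(np.isfinite(values)) or not np.all(np.isfinite(activity)):
            raise TableError("table contains missing or non-finite entries")

    @property
    def n_compounds(self) -> int:
        return len(self.compound_ids)

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.descriptor_names.index(name)
        except ValueError:
            raise TableError(f"no descriptor column named {name!r}") from None
        return self.values[:, j]

    def columns(self, names: Sequence[str] | None = None) -> dict[str, np.ndarray]:
        """Column-name → value-vector view (all descriptors by default)."""
        names = self.descriptor_names if names is None else tuple(names)
        return {name: self.column(name) for name in names}

    def subset_rows(self, indices: Sequence[int]) -> "DescriptorTable":
        idx = np.asarray(indices, dtype=int)
        return DescriptorTable(
            tuple(self.compound_ids[i] for i in idx),
            self.descriptor_names,
            self.values[idx],
            self.activity[idx],
            self.activity_name,
        )

    def with_column(self, name: str, values: np.ndarray) -> "DescriptorTable":
        vals = np.asarray(values, dtype=float).reshape(-1, 1)
        return DescriptorTable(
            self.compound_ids,
            self.descriptor_names + (name,),
            np.hstack([self.values, vals]),
            self.activity,
            self.activity_name,
        )

    def to_dataframe(self, id_column: str = "compound_id") -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.descriptor_names))
        df.insert(0, id_column, list(self.compound_ids))
        df[self.activity_name] = self.activity
        return df


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint train/test row partition, reproducible from its seed."""

    train_indices: tuple[int, ...]
    test_indices: tuple[int, ...]
    seed: int

    def __post_init__(self) -> None:
        train, test = set(self.train_indices), set(self.test_indices)
        if train & test:
            raise TableError("train and test indices overlap")
        n = len(self.train_indices) + len(self.test_indices)
        if train | test != set(range(n)):
            raise TableError("split does not cover all rows exactly once")


def load_table(
    path: str | Path,
    activity_column: str = "log_ic50",
    id_column: str = "compound_id",
    sep: str | None = None,
) -> DescriptorTable:
    """Read a delimited descriptor/activity table.

    The file must carry a header row naming ``id_column`` and
    ``activity_column``; every other column is taken as a numeric
    descriptor, in file order.  Comma and tab delimiters are accepted
    (sniffed from the header when ``sep`` is None).  Missing or
    non-numeric cells are rejected with the offending row and column
    named.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"table file not found: {path}")
    if sep is None:
        header = path.open().readline()
        sep = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty and df.columns.size == 0:
        raise TableError(f"empty table file: {path}")
    return table_from_dataframe(df, activity_column, id_column)


def table_from_dataframe(
    df: pd.DataFrame,
    activity_column: str = "log_ic50",
    id_column: str = "compound_id",
) -> DescriptorTable:
    for col in (id_column, activity_column):
        if col not in df.columns:
            raise TableError(f"required column {col!r} missing from table")
    descriptor_names = [c for c in df.columns if c not in (id_column, activity_column)]
    ids = [str(v) for v in df[id_column]]
    numeric = {}
    for col in descriptor_names + [activity_column]:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.index[parsed.isna()]
        if len(bad):
            row = int(bad[0])
            raise TableError(
                f"non-numeric or missing cell at row {row} "
                f"(compound {ids[row]!r}), column {col!r}"
            )
        numeric[col] = parsed.to_numpy(dtype=float)
    values = (
        np.column_stack([numeric[c] for c in descriptor_names])
        if descriptor_names
        else np.empty((len(ids), 0))
    )
    return DescriptorTable(
        tuple(ids), tuple(descriptor_names), values, numeric[activity_column], activity_column
    )


def write_table(table: DescriptorTable, path: str | Path, sep: str = ",") -> None:
    """Write a table as delimited text; inverse of :func:`load_table`.

    Numeric cells are rendered with ``repr`` precision so decimal inputs
    of modest precision round-trip exactly.
    """
    df = table.to_dataframe()
    df.to_csv(path, sep=sep, index=False)


def log_transform(ic50_values: Sequence[float], labels: Sequence[str] | None = None) -> np.ndarray:
    """Element-wise base-10 logarithm of positive IC50 values."""
    arr = np.asarray(ic50_values, dtype=float)
    bad = np.nonzero(~(arr > 0))[0]
    if bad.size:
        i = int(bad[0])
        who = labels[i] if labels is not None else f"index {i}"
        raise TableError(f"IC50 must be positive for log transform; offending compound: {who}")
    return np.log10(arr)


def split(table: DescriptorTable, n_test: int, seed: int) -> SplitPlan:
    """Uniformly random train/test partition of the table rows."""
    n = table.n_compounds
    if not 0 < n_test < n:
        raise TableError(f"n_test must be in (0, {n}), got {n_test}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    test = tuple(sorted(int(i) for i in perm[:n_test]))
    train = tuple(sorted(int(i) for i in perm[n_test:]))
    return SplitPlan(train, test, seed)


def min_activity(records: Sequence[CompoundRecord]) -> tuple[str, float]:
    """Most potent compound: smallest IC50, first occurrence on ties."""
    if not records:
        raise TableError("empty compound table")
    best = min(records, key=lambda r: r.ic50_nM)
    return best.compound_id, best.ic50_nM


def max_activity(records: Sequence[CompoundRecord]) -> tuple[str, float]:
    """Least potent compound: largest IC50, first occurrence on ties."""
    if not records:
        raise TableError("empty compound table")
    worst = max(records, key=lambda r: r.ic50_nM)
    return worst.compound_id, worst.ic50_nM


def fixture_dataframe() -> pd.DataFrame:
    """The packaged 39-compound thiazolidin-4-one IC50 table.

    Substituent columns (R1/R2/R3/X/A/n/C) are opaque annotation text;
    entries shown only as drawings in the source are marked
    ``(structure)``.  Two rows (2k, 2L) list identical substituents with
    different IC50 and are kept verbatim.
    """
    ref = importlib.resources.files("gepqsar") / "data" / FIXTURE_RESOURCE
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"compound_id": str})


def load_fixture() -> list[CompoundRecord]:
    """Fixture rows as compound records with the log10 activity attached."""
    df = fixture_dataframe()
    return [
        CompoundRecord(str(row.compound_id), float(row.ic50_nM))
        for row in df.itertuples(index=False)
    ]
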