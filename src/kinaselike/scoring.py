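"""Kinase-likeness scoring: the per-compound KLS and the per-library KLSC.

KLS (kinase-like score) of a compound with descriptor vector X is

    KLS = sum_{i=1..9} exp(-(X_i - mu_i)^2 / sigma_i^2)

with (mu_i, sigma_i) taken from a training profile of kinase actives, and
any descriptor falling outside its P10-P90 clamp window contributing
exactly 0.  Note the denominator is sigma^2, not 2 sigma^2: the kernel is
deliberately narrower than a Gaussian density.  KLS ranges from 0 (nothing
kinase-like) to 9 (all nine descriptors at the training means).

KLSC compares two libraries via their 9x9 Pearson descriptor-correlation
matrices: the mean absolute difference over the 36 unordered descriptor
pairs.  Lower is more alike; 0 means identical correlation structure.
KLSC is 1/36 of an L1 metric on the strict upper triangle, hence a true
metric (symmetric, triangle inequality) bounded by 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_io import LibraryTable
from .constants import DESCRIPTOR_NAMES, N_DESCRIPTORS, N_PAIRS
from .descriptors import DescriptorVector
from .errors import DegenerateProfileError, SchemaError, ScoringError
from .profiles import KinaseProfile


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric 9x9 Pearson correlation matrix in canonical descriptor
    order, with the number of rows it was estimated from."""

    values: np.ndarray
    n_rows_used: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.shape != (N_DESCRIPTORS, N_DESCRIPTORS):
            raise SchemaError(
                f"correlation matrix must be {N_DESCRIPTORS}x{N_DESCRIPTORS}, "
                f"got {vals.shape}"
            )
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise SchemaError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(vals), 1.0, atol=1e-12):
            raise SchemaError("correlation matrix must have a unit diagonal")
        if np.nanmax(np.abs(vals)) > 1 + 1e-12:
            raise SchemaError("correlation entries must lie in [-1, 1]")
        object.__setattr__(self, "values", vals)

    def entry(self, a: str, b: str) -> float:
        i, j = DESCRIPTOR_NAMES.index(a), DESCRIPTOR_NAMES.index(b)
        return float(self.values[i, j])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=DESCRIPTOR_NAMES, columns=DESCRIPTOR_NAMES
        )


def _score_matrix(x: np.ndarray, profile: KinaseProfile) -> np.ndarray:
    """Per-descriptor clamped Gaussian terms for an (n, 9) array."""
    mu, sd = profile.means(), profile.sds()
    p10, p90 = profile.p10s(), profile.p90s()
    terms = np.exp(-((x - mu) ** 2) / sd**2)
    inside = (x >= p10) & (x <= p90)
    return np.where(inside, terms, 0.0)


def kls(x: DescriptorVector | np.ndarray, profile: KinaseProfile) -> float:
    """Kinase-like score of one compound; in [0, 9], higher = more
    kinase-like. Raises ScoringError on non-finite descriptors."""
    arr = x.as_array() if isinstance(x, DescriptorVector) else np.asarray(x, dtype=float)
    if arr.shape != (N_DESCRIPTORS,):
        raise ScoringError(f"descriptor vector must have length {N_DESCRIPTORS}")
    bad = ~np.isfinite(arr)
    if bad.any():
        names = [DESCRIPTOR_NAMES[i] for i in np.flatnonzero(bad)]
        raise ScoringError(f"non-finite descriptor value(s): {', '.join(names)}")
    return float(_score_matrix(arr[None, :], profile).sum())


def score_library(table: LibraryTable, profile: KinaseProfile) -> LibraryTable:
    """Score every row of a descriptor table; returns a new table with a
    ``kls`` column appended, row order preserved."""
    x = table.descriptor_frame().to_numpy(dtype=float)
    if len(x) and not np.isfinite(x).all():
        rows = np.flatnonzero(~np.isfinite(x).all(axis=1))
        raise ScoringError(
            f"non-finite descriptors in row(s) {rows[:5].tolist()} "
            f"of table {table.name!r}"
        )
    df = table.df.copy()
    df["kls"] = _score_matrix(x, profile).sum(axis=1) if len(x) else pd.Series(dtype=float)
    return LibraryTable(df, name=table.name)


def correlation_matrix(table: LibraryTable | pd.DataFrame, label: str = "") -> CorrelationMatrix:
    """Pearson correlation between every descriptor pair of a table."""
    if isinstance(table, LibraryTable):
        df = table.descriptor_frame()
        label = label or table.name
    else:
        df = table[list(DESCRIPTOR_NAMES)]
    if len(df) < 3:
        raise DegenerateProfileError("correlation needs at least 3 rows")
    arr = df.to_numpy(dtype=float)
    constant = arr.std(axis=0) == 0
    if constant.any():
        names = [DESCRIPTOR_NAMES[i] for i in np.flatnonzero(constant)]
        raise DegenerateProfileError(
            f"constant descriptor column(s) {', '.join(names)}: "
            "correlation undefined"
        )
    corr = np.corrcoef(arr, rowvar=False)
    # guard against tiny asymmetries from floating point
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return CorrelationMatrix(values=corr, n_rows_used=len(df), label=label)


def klsc(test: CorrelationMatrix, reference: CorrelationMatrix) -> float:
    """Correlation-matrix kinase-likeness score: mean |difference| over the
    36 unordered descriptor pairs. In [0, 2]; lower = more kinase-like."""
    iu = np.triu_indices(N_DESCRIPTORS, k=1)
    diff = np.abs(test.values[iu] - reference.values[iu])
    return float(diff.sum() / N_PAIRS)


def save_matrix(matrix: CorrelationMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path, index=False)


def load_matrix(path: str | Path, n_rows_used: int = 0, label: str = "") -> CorrelationMatrix:
    path = Path(path)
    if not path.exists():
        raise OSError(f"cannot read correlation matrix: {path}")
    df = pd.read_csv(path)
    if tuple(df.columns) != DESCRIPTOR_NAMES:
        raise SchemaError(
            f"matrix columns must be the canonical descriptor names "
            f"{DESCRIPTOR_NAMES}, got {tuple(df.columns)}"
        )
    return CorrelationMatrix(
        values=df.to_numpy(dtype=float), n_rows_used=n_rows_used, label=label
    )


def kbd_reference_matrix() -> CorrelationMatrix:
    """The published descriptor-correlation matrix of the kinase binding
    database (22,615 kinase actives), symmetrized with unit diagonal."""
    with resources.as_file(
        resources.files("kinaselike.data").joinpath("kbd_table3.csv")
    ) as p:
        return load_matrix(p, n_rows_used=22615, label="KBD")
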