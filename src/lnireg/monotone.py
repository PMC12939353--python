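"""Monotone missing-data machinery for the response matrix.

A missingness pattern over p responses is *monotone* when the columns can be
ordered so that each response is at least as observed as the previous one:
with columns sorted by descending missing-cell count, every case that
observes column k also observes columns k+1..p.  Under such a layout the
multivariate posterior factorizes into sequential regressions, which is what
makes the monotone data augmentation sampler largely non-iterative.

Real missingness is rarely exactly monotone; the *fill-in set* is the
minimal set of missing cells (for the chosen column order) whose imputation
completes the monotone pattern.  Only those cells are ever imputed by the
sampler — trailing missing cells integrate out of the factorized posterior.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RegressionData",
    "MonotoneArrangement",
    "detect_patterns",
    "arrange_monotone",
    "invert_arrangement",
    "read_regression_csv",
]


@dataclass
class RegressionData:
    """An n x p positive response matrix with missing cells plus covariates.

    ``Y`` uses NaN for missing cells; ``X`` is fully observed with a leading
    column of ones.
    """

    Y: np.ndarray
    X: np.ndarray
    response_names: list[str] = field(default_factory=list)
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.X = np.asarray(self.X, dtype=float)
        if self.Y.ndim != 2 or self.X.ndim != 2:
            raise ValueError("Y and X must be 2-D arrays")
        if self.Y.shape[0] != self.X.shape[0]:
            raise ValueError("Y and X must have the same number of rows")
        if self.Y.shape[0] == 0:
            raise ValueError("empty dataset (0 rows)")
        if np.isnan(self.X).any():
            raise ValueError("covariate matrix X must be fully observed")
        obs = ~np.isnan(self.Y)
        if np.any(self.Y[obs] <= 0):
            raise ValueError("observed responses must be strictly positive")
        if not self.response_names:
            self.response_names = [f"y{k + 1}" for k in range(self.p)]
        if not self.covariate_names:
            self.covariate_names = ["intercept"] + [
                f"x{j + 1}" for j in range(1, self.r)
            ]

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def p(self) -> int:
        return self.Y.shape[1]

    @property
    def r(self) -> int:
        return self.X.shape[1]

    @property
    def mask(self) -> np.ndarray:
        """Boolean observedness matrix (True = observed)."""
        return ~np.isnan(self.Y)


@dataclass
class MonotoneArrangement:
    """Column/row permutations putting Y into (near-)monotone layout.

    ``pattern_counts[k-1]`` is the number of cases whose first observed
    arranged column is k; a fully missing case counts toward pattern p (its
    single fill-in cell at column p makes the layout uniform).  Applying
    ``row_order``/``column_order`` to the original matrix, the cells in
    ``mask`` together with ``fill_in_cells`` form a monotone pattern: column
    k is covered exactly on the first ``sum(pattern_counts[:k])`` rows (the
    cases of patterns 1..k).
    """

    column_order: np.ndarray
    row_order: np.ndarray
    pattern_counts: np.ndarray
    fill_in_cells: frozenset
    mask: np.ndarray  # observedness in arranged order

    @property
    def n(self) -> int:
        return self.mask.shape[0]

    @property
    def p(self) -> int:
        return self.mask.shape[1]

    def apply(self, M: np.ndarray) -> np.ndarray:
        """Permute an n x p matrix from original into arranged layout."""
        M = np.asarray(M)
        if M.shape != self.mask.shape:
            raise ValueError("shape mismatch with arrangement")
        return M[np.ix_(self.row_order, self.column_order)]


def detect_patterns(data: RegressionData):
    """Distinct observedness patterns with case counts.

    Returns a list of ``(pattern, count)`` pairs where ``pattern`` is a
    boolean p-tuple (True = observed), sorted by first occurrence.
    """
    seen: dict[tuple, int] = {}
    for row in data.mask:
        key = tuple(bool(b) for b in row)
        seen[key] = seen.get(key, 0) + 1
    return list(seen.items())


def arrange_monotone(data: RegressionData) -> MonotoneArrangement:
    """Arrange Y into the monotone layout and identify the fill-in set.

    Columns are ordered by descending missing-cell count (stable in the
    original index); rows are grouped by the index of their first observed
    arranged column, ascending, stable within groups.  The fill-in set is
    the minimal completion for this column order: for each case, the missing
    cells strictly after its first observed arranged column.
    """
    mask = data.mask
    n, p = mask.shape
    missing_per_col = (~mask).sum(axis=0)
    if np.any(missing_per_col == n):
        bad = int(np.argmax(missing_per_col == n))
        raise ValueError(
            f"response column {data.response_names[bad]!r} is entirely missing"
        )
    col_order = np.argsort(-missing_per_col, kind="stable")
    m2 = mask[:, col_order]
    # pattern index = first observed arranged column (1-based); a fully
    # missing row is assigned pattern p (single fill-in cell at column p)
    first_obs = np.where(m2.any(axis=1), m2.argmax(axis=1), p - 1)
    row_order = np.argsort(first_obs, kind="stable")
    m_arr = m2[row_order]
    first_arr = first_obs[row_order]
    counts = np.bincount(first_arr, minlength=p)
    fill = {
        (int(i), int(k))
        for i in range(n)
        for k in range(first_arr[i], p)
        if not m_arr[i, k]
    }
    return MonotoneArrangement(
        column_order=col_order,
        row_order=row_order,
        pattern_counts=counts,
        fill_in_cells=frozenset(fill),
        mask=m_arr,
    )


def invert_arrangement(arr: MonotoneArrangement, arranged: np.ndarray) -> np.ndarray:
    """Map an arranged n x p matrix back to the original layout, bit-exactly."""
    arranged = np.asarray(arranged)
    if arranged.shape != arr.mask.shape:
        raise ValueError("shape mismatch with arrangement")
    out = np.empty_like(arranged)
    out[np.ix_(arr.row_order, arr.column_order)] = arranged
    return out


def read_regression_csv(
    path,
    response_cols: list[str],
    covariate_cols: list[str],
    add_intercept: bool = True,
) -> RegressionData:
    """Read responses and covariates from one CSV table.

    Missing response cells are empty fields or the literal ``NA``; covariates
    must be complete.  An intercept column of ones is prepended unless the
    caller already supplies one.
    """
    df = pd.read_csv(path, na_values=["NA"], keep_default_na=True)
    if len(df) == 0:
        raise ValueError(f"{path}: empty dataset")
    missing = [c for c in list(response_cols) + list(covariate_cols) if c not in df]
    if missing:
        raise ValueError(f"{path}: columns not found: {missing}")
    Y = df[list(response_cols)].to_numpy(dtype=float)
    X = df[list(covariate_cols)].to_numpy(dtype=float)
    cov_names = list(covariate_cols)
    if add_intercept:
        X = np.column_stack([np.ones(len(df)), X])
        cov_names = ["intercept"] + cov_names
    return RegressionData(
        Y=Y, X=X, response_names=list(response_cols), covariate_names=cov_names
    )
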