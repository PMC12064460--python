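"""Ordinal response matrices.

Responses are persons x items integer category codes.  Internally categories
are always coded 0..4 (never = 0); files coded 1..5 are converted on read via
the ``one_based`` dialect.  Missing cells are empty strings on disk and NaN in
memory.  Per-person covariates (sex, age_group, sample_type, language, and the
generating ``true_theta`` for synthetic cohorts) ride along in reserved
columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .banks import ItemBank

__all__ = [
    "ResponseMatrix",
    "ResponseRangeError",
    "EmptySampleError",
    "read_responses",
    "write_responses",
    "listwise_complete",
    "COVARIATE_COLUMNS",
]

COVARIATE_COLUMNS = ("sex", "age_group", "sample_type", "language", "true_theta")


class ResponseRangeError(ValueError):
    """A response code outside the declared category range."""


class EmptySampleError(ValueError):
    """No persons remain after filtering."""


@dataclass
class ResponseMatrix:
    """Persons x items ordinal responses with covariates.

    ``responses`` is a float DataFrame (NaN marks missing) indexed by person
    id with item ids as columns; ``covariates`` shares the index.
    """

    responses: pd.DataFrame
    covariates: pd.DataFrame | None = None
    n_categories: int = 5

    def __post_init__(self) -> None:
        self.responses = self.responses.astype(float)
        vals = self.responses.to_numpy()
        finite = vals[~np.isnan(vals)]
        if finite.size and (
            (finite < 0).any()
            or (finite > self.n_categories - 1).any()
            or (finite != np.round(finite)).any()
        ):
            bad = np.argwhere(
                ~np.isnan(vals)
                & ((vals < 0) | (vals > self.n_categories - 1) | (vals != np.round(vals)))
            )[0]
            raise ResponseRangeError(
                f"response {vals[tuple(bad)]!r} at person {self.responses.index[bad[0]]!r}, "
                f"item {self.responses.columns[bad[1]]!r} outside 0..{self.n_categories - 1}"
            )
        if self.covariates is None:
            self.covariates = pd.DataFrame(index=self.responses.index)
        if not self.covariates.index.equals(self.responses.index):
            raise ValueError("covariates index must match responses index")

    @property
    def n_persons(self) -> int:
        return self.responses.shape[0]

    @property
    def item_ids(self) -> list[str]:
        return [str(c) for c in self.responses.columns]

    @property
    def values(self) -> np.ndarray:
        return self.responses.to_numpy()

    def missing_fraction(self) -> float:
        return float(self.responses.isna().to_numpy().mean())

    def select(self, mask_or_index) -> "ResponseMatrix":
        sub = self.responses.loc[mask_or_index]
        cov = self.covariates.loc[sub.index]
        return ResponseMatrix(sub, cov, self.n_categories)

    def align_to(self, bank: ItemBank) -> "ResponseMatrix":
        """Reorder columns to a bank's item order; error on unknown items."""
        missing = [i for i in bank.item_ids if i not in self.responses.columns]
        if missing:
            raise KeyError(f"response matrix lacks item(s) {missing} of bank {bank.name!r}")
        return ResponseMatrix(
            self.responses[bank.item_ids], self.covariates, self.n_categories
        )


def listwise_complete(matrix: ResponseMatrix) -> ResponseMatrix:
    """Keep only persons with no missing responses (listwise deletion).

    Raises :class:`EmptySampleError` when every person has at least one
    missing response.  The fraction removed is available by comparing
    ``n_persons`` before and after.
    """
    keep = ~matrix.responses.isna().any(axis=1)
    if not keep.any():
        raise EmptySampleError("listwise deletion removed every person")
    return matrix.select(keep)


def read_responses(
    path: str | Path,
    dialect: Literal["zero_based", "one_based"] = "zero_based",
    n_categories: int = 5,
) -> ResponseMatrix:
    """Read a response CSV (persons as rows, item ids as header).

    With ``dialect="one_based"`` the file codes categories 1..n and 1 is
    subtracted on read.  Reserved covariate columns are split off into
    ``covariates``.  An out-of-range code raises
    :class:`ResponseRangeError` naming the cell.
    """
    df = pd.read_csv(path, index_col=0)
    cov_cols = [c for c in df.columns if c in COVARIATE_COLUMNS]
    cov = df[cov_cols] if cov_cols else None
    resp = df.drop(columns=cov_cols).astype(float)
    if dialect == "one_based":
        vals = resp.to_numpy()
        finite = vals[~np.isnan(vals)]
        if finite.size and ((finite < 1).any() or (finite > n_categories).any()):
            raise ResponseRangeError(
                f"one_based file contains codes outside 1..{n_categories}"
            )
        resp = resp - 1
    return ResponseMatrix(resp, cov, n_categories)


def write_responses(
    matrix: ResponseMatrix,
    path: str | Path,
    dialect: Literal["zero_based", "one_based"] = "zero_based",
) -> None:
    """Write a response CSV; inverse of :func:`read_responses`."""
    resp = matrix.responses
    if dialect == "one_based":
        resp = resp + 1
    out = pd.concat([resp, matrix.covariates], axis=1)
    out.index.name = "person_id"
    # integer-looking cells, empty string for missing
    out.to_csv(path, float_format="%.10g")
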