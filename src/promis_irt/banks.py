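"""Item banks for the graded response model.

An item bank is an ordered collection of IRT-calibrated polytomous items
measuring a single construct.  Each item carries a discrimination (slope)
parameter ``a`` on the logistic metric and four ordered category thresholds
``b1..b4`` on the latent-trait (theta) scale, the parameterization used for
five-category PROMIS pediatric items.

Two fixtures ship with the package: the Swedish calibrations of the pediatric
PROMIS anxiety (15 items) and depressive-symptoms (14 items) banks, loadable
by name via :func:`load_item_bank`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemParameters",
    "ItemBank",
    "ItemBankFormatError",
    "ItemBankValidationError",
    "load_item_bank",
    "save_item_bank",
    "FIXTURE_NAMES",
]

FIXTURE_NAMES = ("anxiety_sv", "depressive_sv")

N_CATEGORIES = 5


class ItemBankFormatError(ValueError):
    """Raised when an item-parameter file lacks the expected columns."""


class ItemBankValidationError(ValueError):
    """Raised when item parameters violate model invariants."""


@dataclass(frozen=True)
class ItemParameters:
    """GRM parameters for one polytomous item.

    Parameters
    ----------
    item_id : str
        Item code, e.g. ``"2230R1r"``.
    a : float
        Discrimination (slope) on the logistic metric; must be positive.
    b : tuple of float
        The four category thresholds ``b1 <= b2 <= b3 <= b4`` in theta units;
        ``b[k-1]`` is the trait level at which P(X >= k) = 0.5.
    """

    item_id: str
    a: float
    b: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "b", tuple(float(x) for x in self.b))
        object.__setattr__(self, "a", float(self.a))
        if not np.isfinite(self.a) or self.a <= 0:
            raise ItemBankValidationError(
                f"item {self.item_id!r}: discrimination must be positive, got {self.a}"
            )
        if len(self.b) != N_CATEGORIES - 1:
            raise ItemBankValidationError(
                f"item {self.item_id!r}: expected {N_CATEGORIES - 1} thresholds, "
                f"got {len(self.b)}"
            )
        if any(self.b[i] > self.b[i + 1] for i in range(len(self.b) - 1)):
            raise ItemBankValidationError(
                f"item {self.item_id!r}: thresholds must be non-decreasing, got {self.b}"
            )

    @property
    def n_categories(self) -> int:
        return len(self.b) + 1


@dataclass(frozen=True)
class ItemBank:
    """An ordered, uniquely-labelled collection of :class:`ItemParameters`."""

    name: str
    items: tuple[ItemParameters, ...]
    n_categories: int = N_CATEGORIES

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        ids = [it.item_id for it in self.items]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ItemBankValidationError(f"duplicate item ids: {dupes}")
        for it in self.items:
            if it.n_categories != self.n_categories:
                raise ItemBankValidationError(
                    f"item {it.item_id!r} has {it.n_categories} categories, "
                    f"bank declares {self.n_categories}"
                )

    def __len__(self) -> int:
        return len(self.items)

    def __iter__(self) -> Iterator[ItemParameters]:
        return iter(self.items)

    def __getitem__(self, key: int | str) -> ItemParameters:
        if isinstance(key, str):
            for it in self.items:
                if it.item_id == key:
                    return it
            raise KeyError(key)
        return self.items[key]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def a(self) -> np.ndarray:
        """Discriminations as an array of shape (n_items,)."""
        return np.array([it.a for it in self.items])

    @property
    def b(self) -> np.ndarray:
        """Thresholds as an array of shape (n_items, n_categories - 1)."""
        return np.array([it.b for it in self.items])

    def subset(self, item_ids: Sequence[str], name: str | None = None) -> "ItemBank":
        return ItemBank(
            name=name or self.name,
            items=tuple(self[i] for i in item_ids),
            n_categories=self.n_categories,
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"item_id": it.item_id, "a": it.a, **{f"b{k + 1}": v for k, v in enumerate(it.b)}}
            for it in self.items
        ]
        return pd.DataFrame(rows)


def _bank_from_frame(df: pd.DataFrame, name: str) -> ItemBank:
    b_cols = [f"b{k}" for k in range(1, N_CATEGORIES)]
    required = ["item_id", "a", *b_cols]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ItemBankFormatError(
            f"item bank table is missing column(s) {missing}; expected {required}"
        )
    items = tuple(
        ItemParameters(str(row["item_id"]), float(row["a"]), tuple(row[c] for c in b_cols))
        for _, row in df.iterrows()
    )
    return ItemBank(name=name, items=items)


def load_item_bank(path_or_fixture: str | Path, name: str | None = None) -> ItemBank:
    """Load an item bank from CSV/JSON, or a bundled fixture by name.

    ``"anxiety_sv"`` and ``"depressive_sv"`` resolve to the bundled Swedish
    pediatric PROMIS calibrations (15 and 14 items).  Any other argument is
    treated as a path to a CSV with header ``item_id,a,b1,b2,b3,b4`` or a JSON
    mirror written by :func:`save_item_bank`.
    """
    key = str(path_or_fixture)
    if key in FIXTURE_NAMES:
        ref = resources.files("promis_irt").joinpath(f"data/{key}.csv")
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
        return _bank_from_frame(df, name or key)
    path = Path(path_or_fixture)
    if not path.exists():
        raise FileNotFoundError(
            f"{path!s} is neither a bundled fixture {FIXTURE_NAMES} nor an existing file"
        )
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload["items"])
        return _bank_from_frame(df, name or payload.get("name", path.stem))
    return _bank_from_frame(pd.read_csv(path), name or path.stem)


def save_item_bank(bank: ItemBank, path: str | Path) -> None:
    """Write a bank to CSV (default) or JSON, chosen by file extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "name": bank.name,
            "n_categories": bank.n_categories,
            "items": bank.to_frame().to_dict(orient="records"),
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        bank.to_frame().to_csv(path, index=False, float_format="%.10g")
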