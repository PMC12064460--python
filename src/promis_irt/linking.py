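"""Stocking-Lord linking of two GRM calibrations of the same items.

Two calibrations of the same items live on different theta metrics when they
come from different samples.  The Stocking-Lord method finds the affine
transform theta* = A theta + B that makes the focal calibration's test
characteristic curve (TCC, the summed expected score) match the reference
calibration's, by minimizing

    L(A, B) = sum_q w_q [ TCC_ref(theta_q) - TCC_focal*(theta_q) ]^2

over the quadrature grid, where the transformed focal parameters are
a* = a / A and b* = A b + B.  The typical use here: placing Swedish item
parameters for language-DIF items onto the U.S. reference metric, then
assembling a hybrid bank (reference parameters everywhere, transformed focal
parameters for the DIF items).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .banks import ItemBank, ItemParameters
from .grm import DEFAULT_GRID, QuadratureGrid, expected_score

__all__ = ["LinkingConstants", "stocking_lord", "apply_transform", "build_hybrid_bank"]


@dataclass(frozen=True)
class LinkingConstants:
    """Affine theta transform: slope A (> 0), intercept B."""

    A: float
    B: float
    loss_at_optimum: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.A) and self.A > 0):
            raise ValueError(f"slope A must be positive, got {self.A}")

    def to_json(self) -> str:
        return json.dumps({"A": self.A, "B": self.B, "loss": self.loss_at_optimum})


def _tcc(items: Sequence[ItemParameters], nodes: np.ndarray) -> np.ndarray:
    total = np.zeros_like(nodes)
    for it in items:
        total += expected_score(it, nodes)
    return total


def _transform_items(
    items: Sequence[ItemParameters], A: float, B: float
) -> list[ItemParameters]:
    return [
        ItemParameters(it.item_id, it.a / A, tuple(A * np.asarray(it.b) + B))
        for it in items
    ]


def stocking_lord(
    reference_items: Sequence[ItemParameters],
    focal_items: Sequence[ItemParameters],
    grid: QuadratureGrid = DEFAULT_GRID,
) -> LinkingConstants:
    """Estimate (A, B) matching the focal TCC to the reference TCC.

    Items must be the same set in the same order.  Nelder-Mead from (1, 0),
    with a coarse grid refinement fallback if the local search stalls.
    """
    if len(reference_items) != len(focal_items) or any(
        r.item_id != f.item_id for r, f in zip(reference_items, focal_items)
    ):
        raise ValueError("reference and focal item lists must match in order")
    if min(it.a for it in focal_items) < 1e-3:
        warnings.warn("near-zero discrimination in focal items; linking ill-conditioned")
    tcc_ref = _tcc(reference_items, grid.nodes)
    w = grid.weights

    def loss(x: np.ndarray) -> float:
        A = np.exp(np.clip(x[0], -3, 3))
        transformed = _transform_items(focal_items, A, x[1])
        return float(w @ (tcc_ref - _tcc(transformed, grid.nodes)) ** 2)

    best = minimize(loss, np.array([0.0, 0.0]), method="Nelder-Mead",
                    options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
    # grid-refined fallback in case Nelder-Mead stalled in a poor basin
    if best.fun > 1e-8:
        for logA in np.linspace(-0.7, 0.7, 8):
            for B0 in np.linspace(-1.5, 1.5, 8):
                trial = minimize(loss, np.array([logA, B0]), method="Nelder-Mead",
                                 options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
                if trial.fun < best.fun:
                    best = trial
    A = float(np.exp(best.x[0]))
    return LinkingConstants(A=A, B=float(best.x[1]), loss_at_optimum=float(best.fun))


def apply_transform(
    items: Sequence[ItemParameters], constants: LinkingConstants
) -> list[ItemParameters]:
    """a -> a / A, b_k -> A b_k + B; preserves threshold ordering (A > 0)."""
    return _transform_items(items, constants.A, constants.B)


def build_hybrid_bank(
    reference: ItemBank,
    focal: ItemBank,
    dif_item_ids: Sequence[str],
    grid: QuadratureGrid = DEFAULT_GRID,
    name: str | None = None,
) -> tuple[ItemBank, LinkingConstants]:
    """Reference bank with DIF items replaced by linked focal parameters.

    Linking constants are estimated on the anchor (non-DIF) items shared by
    both banks, then applied to the focal parameters of the DIF items.
    """
    if set(reference.item_ids) != set(focal.item_ids):
        raise ValueError("reference and focal banks must share item ids")
    unknown = [i for i in dif_item_ids if i not in reference.item_ids]
    if unknown:
        raise KeyError(f"dif_item_ids not in banks: {unknown}")
    anchors = [i for i in reference.item_ids if i not in set(dif_item_ids)]
    if not anchors:
        raise ValueError("no anchor items left: every item is marked as DIF")
    constants = stocking_lord(
        [reference[i] for i in anchors], [focal[i] for i in anchors], grid
    )
    linked = {it.item_id: it for it in apply_transform(
        [focal[i] for i in dif_item_ids], constants)}
    items = tuple(
        linked[i] if i in linked else reference[i] for i in reference.item_ids
    )
    bank = ItemBank(name=name or f"{reference.name}_hybrid", items=items,
                    n_categories=reference.n_categories)
    return bank, constants
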