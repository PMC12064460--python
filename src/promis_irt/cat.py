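"""Post-hoc computerized adaptive testing simulation.

A post-hoc CAT replays the adaptive algorithm against already-recorded full
response vectors: items are selected by maximum Fisher information at the
current EAP theta estimate (starting from the item most informative at
theta = 0, the population mean), the recorded response to the selected item
is looked up, and administration stops once the EAP standard error drops to
the ``se_stop`` threshold (default 0.316, i.e. reliability 0.90) or the bank
is exhausted.

:func:`posthoc_simulation` runs the CAT over a whole response matrix and
summarizes performance by deciles of the reference theta (full-bank EAP by
default): per-decile mean theta, RMSE and bias of the CAT estimate against
the reference, mean test length, mean SE, proportion of simulees satisfying
the stop rule, and the implied reliability 1 - mean(SE)^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .banks import ItemBank
from .grm import (
    DEFAULT_GRID,
    QuadratureGrid,
    ThetaEstimate,
    bank_probabilities,
    eap_score_matrix,
    item_information,
)
from .responses import ResponseMatrix

__all__ = [
    "CATConfig",
    "CATResult",
    "SimulationSummary",
    "select_starting_item",
    "select_next_item",
    "run_cat",
    "posthoc_simulation",
]


@dataclass(frozen=True)
class CATConfig:
    """Stopping rule and machinery for one CAT run.

    ``se_stop`` is the standard-error threshold (0.316 corresponds to
    reliability 0.90); ``max_items`` defaults to the full bank.
    """

    se_stop: float = 0.316
    max_items: int | None = None
    min_items: int = 1
    selection_rule: str = "MFI"
    estimator: str = "EAP"
    grid: QuadratureGrid = DEFAULT_GRID

    def __post_init__(self) -> None:
        if self.se_stop <= 0:
            raise ValueError("se_stop must be positive")
        if self.selection_rule != "MFI" or self.estimator != "EAP":
            raise ValueError("only MFI selection with EAP estimation is supported")
        if self.max_items is not None and self.min_items > self.max_items:
            raise ValueError("min_items must not exceed max_items")


@dataclass
class CATResult:
    """Per-person administration trace."""

    person_id: object
    administered_items: list[str]
    theta_trace: list[ThetaEstimate]
    final: ThetaEstimate
    stopped_by: str  # "se_rule" | "exhausted"


def select_starting_item(bank: ItemBank) -> str:
    """Item with maximum information at theta = 0 (ties: first in bank)."""
    if len(bank) == 0:
        raise ValueError("empty bank")
    info = np.array([item_information(it, 0.0) for it in bank])
    return bank.item_ids[int(np.argmax(info))]


def select_next_item(theta: float, bank: ItemBank, remaining: list[str]) -> str:
    """Maximum-Fisher-information selection at the interim theta estimate."""
    if not remaining:
        raise ValueError("no items remaining")
    info = np.array([item_information(bank[i], theta) for i in remaining])
    return remaining[int(np.argmax(info))]


def _eap_from_logpost(logpost: np.ndarray, grid: QuadratureGrid) -> tuple[float, float]:
    p = np.exp(logpost - logpost.max())
    p /= p.sum()
    mean = float(p @ grid.nodes)
    var = float(p @ (grid.nodes - mean) ** 2)
    return mean, float(np.sqrt(max(var, 1e-12)))


def run_cat(
    responses_row,
    bank: ItemBank,
    config: CATConfig | None = None,
    person_id: object = None,
) -> CATResult:
    """Replay an adaptive administration against one recorded response row.

    Responses are looked up, never generated; a missing recorded response to
    the selected item skips that item (with a warning) and selects the next
    most informative one.
    """
    config = config or CATConfig()
    grid = config.grid
    row = np.asarray(responses_row, dtype=float)
    max_items = min(config.max_items or len(bank), len(bank))
    probs = bank_probabilities(bank, grid.nodes)
    col = {iid: j for j, iid in enumerate(bank.item_ids)}

    logpost = np.log(grid.weights)
    theta, se = _eap_from_logpost(logpost, grid)
    remaining = list(bank.item_ids)
    administered: list[str] = []
    trace: list[ThetaEstimate] = []
    stopped_by = "exhausted"
    next_item: str | None = select_starting_item(bank)
    while remaining and len(administered) < max_items:
        if next_item is None:
            next_item = select_next_item(theta, bank, remaining)
        x = row[col[next_item]]
        remaining.remove(next_item)
        if np.isnan(x):
            warnings.warn(f"no recorded response for item {next_item!r}; skipped")
            next_item = None
            continue
        logpost = logpost + np.log(np.maximum(probs[col[next_item], int(x)], 1e-300))
        administered.append(next_item)
        theta, se = _eap_from_logpost(logpost, grid)
        trace.append(ThetaEstimate(theta, se, len(administered)))
        if len(administered) >= config.min_items and se <= config.se_stop:
            stopped_by = "se_rule"
            break
        next_item = None
    final = trace[-1] if trace else ThetaEstimate(theta, se, 0)
    return CATResult(person_id, administered, trace, final, stopped_by)


@dataclass
class SimulationSummary:
    """Decile-level and overall post-hoc CAT performance."""

    deciles: pd.DataFrame | None
    overall: dict[str, float]
    per_person: pd.DataFrame
    reference: str  # "full_bank_eap" | "true_theta"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"SimulationSummary(n={len(self.per_person)}, reference={self.reference!r}, "
            f"mean_test_length={self.overall['mean_test_length']:.2f}, "
            f"rmse={self.overall['mean_rmse']:.3f})"
        )


def posthoc_simulation(
    matrix: ResponseMatrix,
    bank: ItemBank,
    config: CATConfig | None = None,
    reference: str = "full_bank_eap",
) -> SimulationSummary:
    """Run the post-hoc CAT over every person and summarize by deciles.

    ``reference`` selects the comparison theta for bias/RMSE: the full-bank
    EAP estimate (default, the observable benchmark) or the generating
    ``true_theta`` covariate of a synthetic cohort.  Persons are ranked by
    the reference theta and split into ten equal groups (deciles D1..D10,
    D1 lowest); samples under 20 persons get only the overall summary.
    """
    config = config or CATConfig()
    aligned = matrix.align_to(bank)
    resp = aligned.values
    if np.isnan(resp).any():
        raise ValueError("posthoc_simulation requires complete recorded responses")
    full_theta, full_se = eap_score_matrix(resp, bank, config.grid)
    if reference == "true_theta":
        if "true_theta" not in aligned.covariates.columns:
            raise ValueError("matrix has no true_theta covariate")
        ref_theta = aligned.covariates["true_theta"].to_numpy(dtype=float)
    elif reference == "full_bank_eap":
        ref_theta = full_theta
    else:
        raise ValueError(f"unknown reference {reference!r}")

    rows = []
    for i in range(aligned.n_persons):
        res = run_cat(resp[i], bank, config, person_id=aligned.responses.index[i])
        rows.append(
            {
                "person_id": res.person_id,
                "cat_theta": res.final.theta,
                "cat_se": res.final.se,
                "test_length": len(res.administered_items),
                "stopped_by_se_rule": res.stopped_by == "se_rule",
                "full_theta": full_theta[i],
                "full_se": full_se[i],
                "ref_theta": ref_theta[i],
            }
        )
    per_person = pd.DataFrame(rows)

    err = per_person["cat_theta"] - per_person["ref_theta"]
    overall = {
        "n": float(len(per_person)),
        "mean_test_length": float(per_person["test_length"].mean()),
        "mean_rmse": float(np.sqrt(np.mean(err**2))),
        "mean_bias": float(err.mean()),
        "correlation_cat_vs_full": float(
            np.corrcoef(per_person["cat_theta"], per_person["full_theta"])[0, 1]
        ) if len(per_person) > 1 and per_person["cat_theta"].std() > 0 else float("nan"),
        "proportion_stop_satisfied": float(per_person["stopped_by_se_rule"].mean()),
    }

    deciles = None
    if len(per_person) >= 20:
        order = np.lexsort((np.arange(len(per_person)), per_person["ref_theta"].to_numpy()))
        blocks = np.array_split(order, 10)
        recs = []
        for d, idx in enumerate(blocks, start=1):
            sub = per_person.iloc[idx]
            e = sub["cat_theta"] - sub["ref_theta"]
            mse = float(sub["cat_se"].mean())
            recs.append(
                {
                    "decile": f"D{d}",
                    "n": len(sub),
                    "mean_theta": float(sub["ref_theta"].mean()),
                    "rmse": float(np.sqrt(np.mean(e**2))),
                    "mean_bias": float(e.mean()),
                    "mean_test_length": float(sub["test_length"].mean()),
                    "mean_se": mse,
                    "proportion_stop_satisfied": float(sub["stopped_by_se_rule"].mean()),
                    "reliability": 1.0 - mse**2,
                }
            )
        deciles = pd.DataFrame(recs).set_index("decile")
    return SimulationSummary(deciles, overall, per_person, reference)
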