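"""Orlando-Thissen S-X^2 item fit for the graded response model.

The statistic compares observed and model-expected response-category
frequencies conditional on the summed score over the whole bank.  The
summed-score likelihoods come from the Lord-Wingersky recursion generalized
to polytomous items; expected conditional probabilities are

    E(X_j = k | S = s) =
        int P_jk(theta) S_{-j}(s - k | theta) phi(theta) dtheta
        / int S(s | theta) phi(theta) dtheta

evaluated on the quadrature grid.  Sparse cells are collapsed (adjacent
summed-score levels merged, then adjacent categories within a level) until
every expected count reaches the floor of 1; degrees of freedom are the
collapsed cell count minus one free constraint per score level minus the
number of item parameters.  An item fits adequately when p > 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2

from .banks import ItemBank
from .grm import DEFAULT_GRID, QuadratureGrid, bank_probabilities
from .responses import ResponseMatrix

__all__ = ["ItemFitResult", "lord_wingersky", "s_x2_item_fit", "ALPHA_ITEM_FIT"]

ALPHA_ITEM_FIT = 0.001


@dataclass(frozen=True)
class ItemFitResult:
    item_id: str
    s_x2: float
    df: int
    p: float

    @property
    def fit_ok(self) -> bool:
        return self.p > ALPHA_ITEM_FIT


def lord_wingersky(probs: np.ndarray) -> np.ndarray:
    """Summed-score likelihoods by the Lord-Wingersky recursion.

    Parameters
    ----------
    probs : array (n_items, n_categories, n_nodes)
        Category probabilities at each quadrature node.

    Returns
    -------
    array (max_score + 1, n_nodes) with ``out[s, q] = P(S = s | theta_q)``.
    """
    J, K, Q = probs.shape
    out = probs[0].copy()
    max_score = K - 1
    for j in range(1, J):
        new = np.zeros((max_score + K, Q))
        for k in range(K):
            new[k : k + max_score + 1] += out * probs[j, k][None, :]
        out = new
        max_score += K - 1
    return out


def _collapse_rows(expected_rows, observed_rows, floor: float):
    """Merge adjacent summed-score levels until each level's cells can reach
    the floor; returns merged (expected, observed) row lists."""
    exp_m: list[np.ndarray] = []
    obs_m: list[np.ndarray] = []
    for e, o in zip(expected_rows, observed_rows):
        if exp_m and exp_m[-1].sum() < floor * len(exp_m[-1]):
            # previous merged block still too sparse overall: extend it
            width = max(len(exp_m[-1]), len(e))
            ee = np.zeros(width)
            oo = np.zeros(width)
            ee[: len(exp_m[-1])] += exp_m[-1]
            oo[: len(obs_m[-1])] += obs_m[-1]
            ee[: len(e)] += e
            oo[: len(o)] += o
            exp_m[-1], obs_m[-1] = ee, oo
        else:
            exp_m.append(e.copy())
            obs_m.append(o.copy())
    return exp_m, obs_m


def _collapse_categories(e: np.ndarray, o: np.ndarray, floor: float):
    """Within one score level, merge adjacent category cells until every
    expected cell >= floor (or a single cell remains)."""
    e, o = list(e), list(o)
    i = 0
    while i < len(e):
        if e[i] < floor and len(e) > 1:
            j = i + 1 if i + 1 < len(e) else i - 1
            e[min(i, j)] = e[i] + e[j]
            o[min(i, j)] = o[i] + o[j]
            del e[max(i, j)], o[max(i, j)]
            i = 0  # restart scan after a merge
        else:
            i += 1
    return np.array(e), np.array(o)


def s_x2_item_fit(
    matrix: ResponseMatrix,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
    min_expected: float = 1.0,
) -> list[ItemFitResult]:
    """S-X^2 fit statistic for every item of a calibrated bank.

    ``matrix`` must be listwise-complete and aligned to ``bank``.  Items whose
    collapsed table cannot support a test (fewer cells than constraints) are
    skipped with a warning.
    """
    resp = matrix.align_to(bank).values
    if np.isnan(resp).any():
        raise ValueError("s_x2_item_fit requires a listwise-complete matrix")
    resp = resp.astype(int)
    n, J = resp.shape
    K = bank.n_categories
    probs = bank_probabilities(bank, grid.nodes)  # (J, K, Q)
    w = grid.weights
    total = resp.sum(axis=1)
    S_full = lord_wingersky(probs)  # (S_max+1, Q)
    denom = S_full @ w  # P(S = s)

    results: list[ItemFitResult] = []
    n_params = K  # one slope + K-1 thresholds
    for j in range(J):
        rest_probs = np.delete(probs, j, axis=0)
        S_rest = lord_wingersky(rest_probs)  # (S_max-K+2, Q)
        max_rest = S_rest.shape[0] - 1
        expected_rows, observed_rows = [], []
        for s in range(1, S_full.shape[0] - 1):  # extremes are deterministic
            ks = [k for k in range(K) if 0 <= s - k <= max_rest]
            num = np.array([(probs[j, k] * S_rest[s - k]) @ w for k in ks])
            if denom[s] <= 0 or num.sum() <= 0:
                continue
            cond = num / denom[s]
            n_s = np.count_nonzero(total == s)
            obs = np.array([np.count_nonzero((total == s) & (resp[:, j] == k)) for k in ks])
            expected_rows.append(cond * n_s)
            observed_rows.append(obs.astype(float))
        exp_m, obs_m = _collapse_rows(expected_rows, observed_rows, min_expected)
        x2 = 0.0
        n_cells = 0
        n_rows = 0
        for e, o in zip(exp_m, obs_m):
            if e.sum() <= 0:
                continue
            e2, o2 = _collapse_categories(e, o, min_expected)
            if len(e2) < 2:
                continue
            x2 += float(np.sum((o2 - e2) ** 2 / np.maximum(e2, 1e-12)))
            n_cells += len(e2)
            n_rows += 1
        df = n_cells - n_rows - n_params
        if df < 1:
            warnings.warn(
                f"item {bank.item_ids[j]!r}: collapsed S-X^2 table too small "
                f"({n_cells} cells); item skipped"
            )
            continue
        p = float(chi2.sf(x2, df))
        results.append(ItemFitResult(bank.item_ids[j], x2, df, p))
    return results
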