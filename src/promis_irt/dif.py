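"""Differential item functioning by ordinal logistic regression.

The lordif-style procedure: score every person on the whole bank (EAP theta,
the matching variable), then for each item compare three nested
proportional-odds models of the item response

    M0: cumulative-logit(y) ~ theta
    M1: cumulative-logit(y) ~ theta + group
    M2: cumulative-logit(y) ~ theta + group + theta x group

McFadden's pseudo-R^2 (1 - ll_model / ll_null) is computed for each, and an
item is flagged for uniform DIF when R^2 rises by at least 2 percentage
points from M0 to M1, for non-uniform DIF when it rises by at least 2 points
from M1 to M2.  One purification round (re-scoring on the unflagged items
and re-scanning) is applied by default.

The proportional-odds fits go through statsmodels' ``OrderedModel`` with a
logit link; a ridge-penalized direct fit is the fallback when Newton/BFGS
fails (e.g. quasi-separation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit

from .banks import ItemBank
from .grm import DEFAULT_GRID, QuadratureGrid, eap_score_matrix
from .responses import ResponseMatrix

__all__ = [
    "DIFResult",
    "ordinal_logistic_fit",
    "null_loglik",
    "mcfadden_delta_r2",
    "dif_scan",
    "DIF_R2_THRESHOLD",
]

DIF_R2_THRESHOLD = 0.02
MIN_GROUP_N = 25


@dataclass(frozen=True)
class DIFResult:
    """Per-item DIF decision with all three nested pseudo-R^2 changes."""

    item_id: str
    r2_null_to_uniform: float
    r2_uniform_to_nonuniform: float
    r2_total: float
    flagged: bool
    dif_type: str  # none | uniform | nonuniform


def _polr_negloglik(params: np.ndarray, y: np.ndarray, X: np.ndarray, n_cat: int,
                    ridge: float = 0.0) -> float:
    k = X.shape[1]
    beta = params[:k]
    cut = np.concatenate([[params[k]], params[k] + np.cumsum(np.exp(params[k + 1:]))])
    eta = X @ beta
    # P(y <= m) = expit(cut_m - eta)
    cum = expit(cut[None, :] - eta[:, None])
    full = np.hstack([np.zeros((len(y), 1)), cum, np.ones((len(y), 1))])
    p = np.maximum(full[np.arange(len(y)), y + 1] - full[np.arange(len(y)), y], 1e-12)
    return -float(np.sum(np.log(p))) + ridge * float(beta @ beta)


def ordinal_logistic_fit(
    y: np.ndarray, X: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Proportional-odds MLE: returns (slopes, ordered cutpoints, loglik).

    ``y`` holds integer categories (degenerate categories are relabelled to
    consecutive codes first); ``X`` is the covariate matrix without an
    intercept (the cutpoints absorb it).  Falls back to a ridge-stabilized
    direct optimization with a warning when the standard fit fails.
    """
    y = np.asarray(y)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    cats = np.unique(y)
    y_rel = np.searchsorted(cats, y)
    n_cat = cats.size
    if n_cat < 2:
        raise ValueError("response is constant; ordinal model undefined")
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = OrderedModel(y_rel, X, distr="logit")
            res = model.fit(method="bfgs", disp=False, maxiter=200)
        converged = bool(res.mle_retvals.get("converged", True))
        llf = float(res.llf)
        k = X.shape[1]
        beta = np.asarray(res.params[:k], dtype=float)
        raw = np.asarray(res.params[k:], dtype=float)
        cut = np.concatenate([[raw[0]], raw[0] + np.cumsum(np.exp(raw[1:]))])
        if converged and np.isfinite(llf):
            return beta, cut, llf
    except Exception:  # pragma: no cover - rare numerical failure
        converged = False
    warnings.warn("ordinal logistic fit unstable; ridge-stabilized refit used")
    k = X.shape[1]
    x0 = np.concatenate([np.zeros(k), [0.0], np.zeros(n_cat - 2)])
    sol = minimize(
        _polr_negloglik, x0, args=(y_rel, X, n_cat, 1e-4), method="BFGS",
        options={"maxiter": 500},
    )
    beta = sol.x[:k]
    cut = np.concatenate([[sol.x[k]], sol.x[k] + np.cumsum(np.exp(sol.x[k + 1:]))])
    return beta, cut, -_polr_negloglik(sol.x, y_rel, X, n_cat, 0.0)


def null_loglik(y: np.ndarray) -> float:
    """Intercept-only multinomial log-likelihood sum_k n_k log(n_k / n)."""
    _, counts = np.unique(y, return_counts=True)
    n = counts.sum()
    return float(np.sum(counts * np.log(counts / n)))


def mcfadden_delta_r2(
    loglik_small: float, loglik_large: float, loglik_null: float, tol: float = 1e-6
) -> float:
    """Change in McFadden pseudo-R^2 = 1 - ll / ll_null between nested fits."""
    if loglik_large < loglik_small - tol:
        raise ValueError(
            f"models not nested: larger model log-likelihood {loglik_large:.6f} "
            f"< smaller {loglik_small:.6f}"
        )
    r2_small = 1.0 - loglik_small / loglik_null
    r2_large = 1.0 - loglik_large / loglik_null
    return max(r2_large - r2_small, 0.0)


def _scan_once(
    resp: np.ndarray,
    item_ids: list[str],
    theta: np.ndarray,
    g: np.ndarray,
) -> list[DIFResult]:
    results = []
    for j, item_id in enumerate(item_ids):
        y = resp[:, j].astype(int)
        if len(np.unique(y)) < 2:
            warnings.warn(f"item {item_id!r}: constant response, skipped")
            continue
        ll_null = null_loglik(y)
        X0 = theta[:, None]
        X1 = np.column_stack([theta, g])
        X2 = np.column_stack([theta, g, theta * g])
        _, _, ll0 = ordinal_logistic_fit(y, X0)
        _, _, ll1 = ordinal_logistic_fit(y, X1)
        _, _, ll2 = ordinal_logistic_fit(y, X2)
        ll1 = max(ll1, ll0)  # guard tiny optimizer slack in nested fits
        ll2 = max(ll2, ll1)
        d_uni = mcfadden_delta_r2(ll0, ll1, ll_null)
        d_non = mcfadden_delta_r2(ll1, ll2, ll_null)
        d_tot = mcfadden_delta_r2(ll0, ll2, ll_null)
        if d_uni >= DIF_R2_THRESHOLD:
            dif_type = "uniform"
        elif d_non >= DIF_R2_THRESHOLD:
            dif_type = "nonuniform"
        else:
            dif_type = "none"
        results.append(
            DIFResult(item_id, d_uni, d_non, d_tot, dif_type != "none", dif_type)
        )
    return results


def dif_scan(
    matrix: ResponseMatrix,
    group: np.ndarray,
    bank: ItemBank,
    purify: bool = True,
    grid: QuadratureGrid = DEFAULT_GRID,
) -> list[DIFResult]:
    """Scan every item of a bank for DIF between two groups.

    ``group`` is a two-level label vector aligned with the matrix rows.  The
    matching variable is the EAP theta from all items; when purification is
    on and the first pass flags items, theta is re-estimated from the
    unflagged items and the scan repeated once.
    """
    aligned = matrix.align_to(bank)
    resp = aligned.values
    if np.isnan(resp).any():
        raise ValueError("dif_scan requires a listwise-complete matrix")
    levels = np.unique(np.asarray(group))
    if levels.size != 2:
        raise ValueError(f"group must have exactly two levels, got {levels!r}")
    g = (np.asarray(group) == levels[1]).astype(float)
    small = [lv for lv, c in zip(levels, np.bincount(g.astype(int))) if c < MIN_GROUP_N]
    if small:
        warnings.warn(f"group level(s) {small} have < {MIN_GROUP_N} rows; scan skipped")
        return []
    theta, _ = eap_score_matrix(resp, bank, grid)
    results = _scan_once(resp, aligned.item_ids, theta, g)
    flagged = [r.item_id for r in results if r.flagged]
    if purify and flagged and len(flagged) < len(bank):
        keep = [i for i in aligned.item_ids if i not in flagged]
        sub = bank.subset(keep)
        cols = [aligned.item_ids.index(i) for i in keep]
        theta2, _ = eap_score_matrix(resp[:, cols], sub, grid)
        results = _scan_once(resp, aligned.item_ids, theta2, g)
    return results
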