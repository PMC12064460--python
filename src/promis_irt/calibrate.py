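"""Marginal maximum likelihood calibration of the graded response model.

Bock-Aitkin EM with a fixed quadrature grid and a standard-normal latent
density.  The E-step computes each person's posterior over the grid nodes
from the current item parameters; the M-step maximizes, item by item, the
expected complete-data log-likelihood

    sum_{k,q} r_{jkq} log P_jk(theta_q)

over (a_j, b_j1..b_j4), with expected counts r_{jkq} accumulated from the
posteriors.  The threshold ordering constraint is enforced by optimizing
(log a, b1, log successive differences).  The marginal log-likelihood is
non-decreasing across cycles, the standard EM guarantee; convergence is
declared when the largest absolute parameter change falls below ``tol``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .banks import ItemBank, ItemParameters
from .grm import DEFAULT_GRID, QuadratureGrid, bank_probabilities
from .responses import ResponseMatrix

__all__ = ["GRMFitConfig", "GRMFitResult", "fit_grm", "CalibrationError", "marginal_loglik"]


class CalibrationError(ValueError):
    """Raised when the data cannot support a GRM calibration."""


@dataclass(frozen=True)
class GRMFitConfig:
    grid: QuadratureGrid = DEFAULT_GRID
    tol: float = 1e-4
    max_iter: int = 500


@dataclass
class GRMFitResult:
    bank: ItemBank
    loglik_trace: list[float]
    n_iter: int
    converged: bool

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1]


def _item_probs(a: float, b: np.ndarray, nodes: np.ndarray) -> np.ndarray:
    """(K, Q) category probabilities for one item."""
    from scipy.special import expit

    pstar = expit(a * (nodes[None, :] - b[:, None]))  # (K-1, Q)
    full = np.vstack([np.ones_like(nodes), pstar, np.zeros_like(nodes)])
    return -np.diff(full, axis=0)


def _pack(a: float, b: np.ndarray) -> np.ndarray:
    d = np.diff(b)
    return np.concatenate([[np.log(a)], [b[0]], np.log(np.maximum(d, 1e-6))])


def _unpack(x: np.ndarray) -> tuple[float, np.ndarray]:
    a = float(np.exp(np.clip(x[0], -6, 4)))
    b = x[1] + np.concatenate([[0.0], np.cumsum(np.exp(np.clip(x[2:], -20, 4)))])
    return a, b


def marginal_loglik(
    responses: np.ndarray, bank: ItemBank, grid: QuadratureGrid = DEFAULT_GRID
) -> float:
    """Marginal log-likelihood of a complete persons x items array."""
    probs = bank_probabilities(bank, grid.nodes)
    n, J = responses.shape
    logl = np.tile(np.log(grid.weights), (n, 1))
    for j in range(J):
        logl += np.log(np.maximum(probs[j, responses[:, j].astype(int), :], 1e-300))
    m = logl.max(axis=1, keepdims=True)
    return float(np.sum(m[:, 0] + np.log(np.exp(logl - m).sum(axis=1))))


def _start_values(responses: np.ndarray, n_categories: int) -> tuple[np.ndarray, np.ndarray]:
    """Marginal-proportion starting thresholds with unit slopes."""
    n, J = responses.shape
    a0 = np.full(J, 1.5)
    b0 = np.empty((J, n_categories - 1))
    for j in range(J):
        x = responses[:, j]
        for k in range(1, n_categories):
            p_ge = np.clip(np.mean(x >= k), 1.0 / (n + 1), 1 - 1.0 / (n + 1))
            b0[j, k - 1] = -np.log(p_ge / (1 - p_ge)) / a0[j]
        b0[j] = np.maximum.accumulate(b0[j])
        b0[j] += 1e-4 * np.arange(n_categories - 1)  # break exact ties
    return a0, b0


def fit_grm(
    matrix: ResponseMatrix,
    config: GRMFitConfig | None = None,
    bank_name: str = "calibrated",
) -> GRMFitResult:
    """Calibrate GRM item parameters from a listwise-complete response matrix.

    Raises :class:`CalibrationError` if any item shows fewer than two observed
    categories.  Emits a non-convergence warning (with the trace preserved in
    the result) if ``max_iter`` cycles are exhausted.
    """
    config = config or GRMFitConfig()
    resp = matrix.values
    if np.isnan(resp).any():
        raise CalibrationError("fit_grm requires a listwise-complete matrix")
    resp = resp.astype(int)
    n, J = resp.shape
    K = matrix.n_categories
    for j in range(J):
        if len(np.unique(resp[:, j])) < 2:
            raise CalibrationError(
                f"item {matrix.item_ids[j]!r} has a single observed category"
            )

    nodes, logw = config.grid.nodes, np.log(config.grid.weights)
    Q = nodes.size
    a, b = _start_values(resp, K)
    # one-hot expansion used to accumulate expected counts
    onehot = np.zeros((J, K, n))
    for j in range(J):
        onehot[j, resp[:, j], np.arange(n)] = 1.0

    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, config.max_iter + 1):
        # E-step
        logP = np.empty((J, K, Q))
        for j in range(J):
            logP[j] = np.log(np.maximum(_item_probs(a[j], b[j], nodes), 1e-300))
        logpost = np.tile(logw, (n, 1))
        for j in range(J):
            logpost += logP[j, resp[:, j], :]
        m = logpost.max(axis=1, keepdims=True)
        ll = float(np.sum(m[:, 0] + np.log(np.exp(logpost - m).sum(axis=1))))
        trace.append(ll)
        post = np.exp(logpost - m)
        post /= post.sum(axis=1, keepdims=True)  # (n, Q)

        # M-step, item by item
        max_change = 0.0
        for j in range(J):
            r = onehot[j] @ post  # (K, Q) expected counts

            def negloglik(x, r=r):
                aj, bj = _unpack(x)
                P = np.maximum(_item_probs(aj, bj, nodes), 1e-300)
                return -float(np.sum(r * np.log(P)))

            x0 = _pack(a[j], b[j])
            sol = minimize(negloglik, x0, method="BFGS", options={"gtol": 1e-6, "maxiter": 80})
            if sol.fun <= negloglik(x0):
                aj_new, bj_new = _unpack(sol.x)
            else:  # keep current point; EM step must not decrease the objective
                aj_new, bj_new = a[j], b[j]
            max_change = max(
                max_change, abs(aj_new - a[j]), float(np.max(np.abs(bj_new - b[j])))
            )
            a[j], b[j] = aj_new, bj_new

        if max_change < config.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"GRM EM did not converge in {config.max_iter} cycles "
            f"(last log-likelihood {trace[-1]:.3f})",
            RuntimeWarning,
        )
    items = tuple(
        ItemParameters(matrix.item_ids[j], a[j], tuple(b[j])) for j in range(J)
    )
    bank = ItemBank(name=bank_name, items=items, n_categories=K)
    return GRMFitResult(bank=bank, loglik_trace=trace, n_iter=it, converged=converged)
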