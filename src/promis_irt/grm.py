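"""Samejima's graded response model: probabilities, information, EAP scoring.

The model: for an item with discrimination ``a`` and ordered thresholds
``b_1..b_{K-1}``, the probability of responding in category ``k`` or higher is
a logistic curve

    P*(X >= k | theta) = 1 / (1 + exp(-a (theta - b_k)))

(scaling constant D = 1, the convention of mirt-style calibrations), and the
category probability is the adjacent difference P*(X >= k) - P*(X >= k+1).

Latent-trait scoring is expected a posteriori (EAP): the posterior mean of
theta under a standard-normal prior, with the posterior standard deviation
reported as the standard error.  Integrals are evaluated on a fixed
quadrature grid; the default is 61 equally spaced nodes on [-4, 4] with
renormalized standard-normal weights, the range over which PROMIS traits are
conventionally scored.

T-scores are the affine rescaling T = 10 theta + 50 (population mean 50,
SD 10), and IRT reliability at a given precision is 1 - SE^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit
from scipy.stats import norm

from .banks import ItemBank, ItemParameters

__all__ = [
    "QuadratureGrid",
    "ThetaEstimate",
    "category_probabilities",
    "cumulative_probabilities",
    "item_information",
    "test_information",
    "expected_score",
    "bank_probabilities",
    "eap_score",
    "eap_score_matrix",
    "theta_to_tscore",
    "tscore_to_theta",
    "se_to_reliability",
]


@dataclass(frozen=True)
class QuadratureGrid:
    """Fixed integration grid over theta.

    ``nodes`` are strictly increasing; ``weights`` are positive and sum to 1.
    """

    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.size < 2 or np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be a strictly increasing 1-D array")
        if weights.shape != nodes.shape or np.any(weights <= 0):
            raise ValueError("weights must be positive and match nodes")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights / weights.sum())

    @classmethod
    def standard_normal(
        cls, n_nodes: int = 61, bounds: tuple[float, float] = (-4.0, 4.0)
    ) -> "QuadratureGrid":
        """Equally spaced nodes with renormalized N(0,1) density weights."""
        nodes = np.linspace(bounds[0], bounds[1], n_nodes)
        return cls(nodes, norm.pdf(nodes))

    def __len__(self) -> int:
        return len(self.nodes)


DEFAULT_GRID = QuadratureGrid.standard_normal()


@dataclass(frozen=True)
class ThetaEstimate:
    """Latent-trait point estimate with its standard error."""

    theta: float
    se: float
    n_items_used: int

    @property
    def tscore(self) -> float:
        return theta_to_tscore(self.theta)

    @property
    def reliability(self) -> float:
        return se_to_reliability(self.se)


def cumulative_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """P(X >= k | theta) for k = 1..K-1; shape (..., K-1)."""
    theta = np.asarray(theta, dtype=float)
    b = np.asarray(item.b)
    return expit(item.a * (theta[..., None] - b))


def category_probabilities(item: ItemParameters, theta) -> np.ndarray:
    """Category probabilities P(X = k | theta), k = 0..K-1; shape (..., K).

    Non-negative and summing to one by construction (adjacent differences of
    the monotone cumulative curves, padded with 1 and 0).
    """
    theta = np.asarray(theta, dtype=float)
    pstar = cumulative_probabilities(item, theta)
    ones = np.ones(theta.shape + (1,))
    zeros = np.zeros(theta.shape + (1,))
    full = np.concatenate([ones, pstar, zeros], axis=-1)
    return -np.diff(full, axis=-1)


def item_information(item: ItemParameters, theta) -> np.ndarray | float:
    """Fisher information of one item at theta.

    I(theta) = sum_k (dP_k/dtheta)^2 / P_k with dP*_k/dtheta = a P*_k (1-P*_k).
    """
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    pstar = cumulative_probabilities(item, theta_arr)
    dstar = item.a * pstar * (1.0 - pstar)
    zeros = np.zeros(theta_arr.shape + (1,))
    dfull = np.concatenate([zeros, dstar, zeros], axis=-1)
    dp = -np.diff(dfull, axis=-1)
    p = category_probabilities(item, theta_arr)
    info = np.sum(np.where(p > 1e-300, dp**2 / np.maximum(p, 1e-300), 0.0), axis=-1)
    return info if np.ndim(theta) else float(info[0])


def test_information(bank: ItemBank, theta) -> np.ndarray | float:
    """Total information: the sum of item informations (local independence)."""
    theta_arr = np.atleast_1d(np.asarray(theta, dtype=float))
    total = np.zeros_like(theta_arr)
    for item in bank:
        total += item_information(item, theta_arr)
    return total if np.ndim(theta) else float(total[0])


def expected_score(item: ItemParameters, theta) -> np.ndarray | float:
    """E[X | theta]; non-decreasing in theta under the GRM."""
    p = category_probabilities(item, np.asarray(theta, dtype=float))
    k = np.arange(p.shape[-1])
    out = (p * k).sum(axis=-1)
    return out if np.ndim(theta) else float(out)


def bank_probabilities(bank: ItemBank, nodes: np.ndarray) -> np.ndarray:
    """Probability tensor of shape (n_items, n_categories, n_nodes)."""
    nodes = np.asarray(nodes, dtype=float)
    out = np.empty((len(bank), bank.n_categories, nodes.size))
    for j, item in enumerate(bank):
        out[j] = category_probabilities(item, nodes).T
    return out


def _posterior(
    responses_row: np.ndarray, probs: np.ndarray, grid: QuadratureGrid
) -> np.ndarray:
    """Unnormalized posterior over grid nodes; missing responses skipped."""
    logpost = np.log(grid.weights)
    for j, x in enumerate(responses_row):
        if np.isnan(x):
            continue
        logpost = logpost + np.log(np.maximum(probs[j, int(x)], 1e-300))
    logpost -= logpost.max()
    post = np.exp(logpost)
    return post / post.sum()


def eap_score(
    responses_row,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
) -> ThetaEstimate:
    """EAP estimate of theta from one (possibly incomplete) response row.

    The posterior combines the standard-normal prior (the grid weights) with
    the GRM likelihood of the answered items; missing items are skipped.
    With nothing answered the prior mean/SD is returned.
    """
    row = np.asarray(responses_row, dtype=float)
    probs = bank_probabilities(bank, grid.nodes)
    post = _posterior(row, probs, grid)
    mean = float(post @ grid.nodes)
    var = float(post @ (grid.nodes - mean) ** 2)
    return ThetaEstimate(mean, float(np.sqrt(max(var, 1e-12))), int(np.sum(~np.isnan(row))))


def eap_score_matrix(
    responses: np.ndarray,
    bank: ItemBank,
    grid: QuadratureGrid = DEFAULT_GRID,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized EAP over a persons x items array; returns (theta, se)."""
    responses = np.asarray(responses, dtype=float)
    probs = bank_probabilities(bank, grid.nodes)  # (J, K, Q)
    logw = np.log(grid.weights)
    n, J = responses.shape
    logpost = np.tile(logw, (n, 1))
    for j in range(J):
        x = responses[:, j]
        answered = ~np.isnan(x)
        if answered.any():
            idx = x[answered].astype(int)
            logpost[answered] += np.log(np.maximum(probs[j, idx, :], 1e-300))
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    theta = post @ grid.nodes
    var = (post * (grid.nodes[None, :] - theta[:, None]) ** 2).sum(axis=1)
    return theta, np.sqrt(np.maximum(var, 1e-12))


def theta_to_tscore(theta):
    """T = 10 theta + 50 (reference mean 50, SD 10)."""
    return np.asarray(theta, dtype=float) * 10.0 + 50.0 if np.ndim(theta) else theta * 10.0 + 50.0


def tscore_to_theta(tscore):
    """Inverse of :func:`theta_to_tscore`."""
    return (np.asarray(tscore, dtype=float) - 50.0) / 10.0 if np.ndim(tscore) else (tscore - 50.0) / 10.0


def se_to_reliability(se):
    """IRT reliability at precision SE: 1 - SE^2."""
    se = np.asarray(se, dtype=float) if np.ndim(se) else se
    return 1.0 - se**2
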