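"""IRT assumption checks: unidimensionality, local independence, monotonicity.

The checks mirror standard practice for ordinal patient-reported-outcome
data:

* polychoric correlations (two-step ML: thresholds from marginal category
  proportions via normal quantiles, then one-dimensional likelihood
  maximization over the latent correlation);
* Kaiser-Meyer-Olkin sampling adequacy from anti-image partial correlations;
* parallel analysis of the polychoric eigenvalues against random data with
  matched marginals;
* exploratory factor analysis by iterated principal factors (unweighted
  least squares on the polychoric matrix);
* a one-factor confirmatory fit whose residual correlations index local
  independence, with approximate CFI/TLI/RMSEA/SRMR fit indices (least
  squares, not the scaled DWLS values a lavaan analysis would print);
* Mokken-type scalability coefficients H (observed / maximal covariance).

Decision rules: first factor explains >= 20% of variance and eigenvalue
ratio > 4 (unidimensionality); |residual correlation| > 0.20 flags local
dependence; item H > 0.30 and scale H > 0.50 support monotone homogeneity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import multivariate_normal, norm

from .responses import ResponseMatrix

__all__ = [
    "AssumptionReport",
    "polychoric_corr",
    "polychoric_matrix",
    "kmo",
    "parallel_analysis",
    "efa_wls",
    "cfa_one_factor",
    "mokken_h",
    "assumption_report",
    "nearest_psd",
]

RESIDUAL_CUT = 0.20
FIRST_FACTOR_PROP_CUT = 0.20
EIGEN_RATIO_CUT = 4.0
H_ITEM_CUT = 0.30
H_SCALE_CUT = 0.50


# ---------------------------------------------------------------- polychoric

def _thresholds(x: np.ndarray, n_categories: int) -> np.ndarray:
    """Normal quantiles of the cumulative marginal proportions (K-1 values)."""
    n = x.size
    cum = np.array([np.mean(x <= k) for k in range(n_categories - 1)])
    cum = np.clip(cum, 1.0 / (2 * n), 1 - 1.0 / (2 * n))
    return norm.ppf(cum)


def _cell_probs(tau_x: np.ndarray, tau_y: np.ndarray, rho: float) -> np.ndarray:
    """Rectangle probabilities of a standard bivariate normal."""
    tx = np.concatenate([[-np.inf], tau_x, [np.inf]])
    ty = np.concatenate([[-np.inf], tau_y, [np.inf]])
    gx, gy = np.meshgrid(np.clip(tx, -8, 8), np.clip(ty, -8, 8), indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    bvn = multivariate_normal([0.0, 0.0], [[1.0, rho], [rho, 1.0]], allow_singular=True)
    cdf = bvn.cdf(pts).reshape(gx.shape)
    cell = cdf[1:, 1:] - cdf[:-1, 1:] - cdf[1:, :-1] + cdf[:-1, :-1]
    return np.maximum(cell, 1e-12)


def polychoric_corr(x: np.ndarray, y: np.ndarray, n_categories: int = 5) -> float:
    """Two-step ML polychoric correlation of two ordinal variables."""
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        raise ValueError("polychoric correlation needs >= 2 observed categories")
    tau_x = _thresholds(x, n_categories)
    tau_y = _thresholds(y, n_categories)
    counts = np.zeros((n_categories, n_categories))
    np.add.at(counts, (x, y), 1.0)

    def negloglik(rho: float) -> float:
        return -float(np.sum(counts * np.log(_cell_probs(tau_x, tau_y, rho))))

    sol = minimize_scalar(negloglik, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-5})
    return float(sol.x)


def nearest_psd(corr: np.ndarray, eps: float = 1e-6) -> tuple[np.ndarray, bool]:
    """Clip negative eigenvalues and restore the unit diagonal."""
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= eps:
        return corr, False
    vals = np.maximum(vals, eps)
    fixed = vecs @ np.diag(vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed, True


def polychoric_matrix(
    matrix: ResponseMatrix | np.ndarray, n_categories: int = 5
) -> np.ndarray:
    """Pairwise polychoric correlation matrix (PSD-smoothed if needed)."""
    data = matrix.values if isinstance(matrix, ResponseMatrix) else np.asarray(matrix)
    if np.isnan(data).any():
        raise ValueError("polychoric_matrix requires listwise-complete data")
    data = data.astype(int)
    p = data.shape[1]
    R = np.eye(p)
    for i in range(p):
        for j in range(i + 1, p):
            R[i, j] = R[j, i] = polychoric_corr(data[:, i], data[:, j], n_categories)
    R, smoothed = nearest_psd(R)
    if smoothed:
        warnings.warn("polychoric matrix smoothed to nearest positive semi-definite")
    return R


# ----------------------------------------------------------------------- KMO

def kmo(corr: np.ndarray) -> tuple[float, np.ndarray]:
    """Kaiser-Meyer-Olkin sampling adequacy (overall, per item).

    KMO = sum r^2 / (sum r^2 + sum q^2) over off-diagonal entries, where q
    are the anti-image partial correlations from the inverse matrix.
    """
    corr = np.asarray(corr, dtype=float)
    inv = np.linalg.inv(corr)
    d = 1.0 / np.sqrt(np.diag(inv))
    partial = -inv * np.outer(d, d)
    np.fill_diagonal(partial, 0.0)
    r2 = corr**2
    np.fill_diagonal(r2, 0.0)
    q2 = partial**2
    overall = r2.sum() / (r2.sum() + q2.sum())
    per_item = r2.sum(axis=1) / (r2.sum(axis=1) + q2.sum(axis=1))
    return float(overall), per_item


# ----------------------------------------------------- parallel analysis / EFA

def parallel_analysis(
    matrix: ResponseMatrix,
    n_random: int = 100,
    seed: int | None = None,
    n_categories: int = 5,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Polychoric eigenvalues against marginal-matched random data.

    Random datasets keep each item's marginal category distribution but
    shuffle persons independently per item, destroying all association.
    Factors are retained while the observed eigenvalue exceeds the mean
    random eigenvalue of the same rank.

    Returns (observed eigenvalues, n_factors_retained, mean random
    eigenvalues).
    """
    data = matrix.values.astype(int)
    n, p = data.shape
    R = polychoric_matrix(matrix, n_categories)
    eig = np.sort(np.linalg.eigvalsh(R))[::-1]
    rng = np.random.default_rng(seed)
    rand = np.zeros((n_random, p))
    for r in range(n_random):
        shuffled = np.column_stack([rng.permutation(data[:, j]) for j in range(p)])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            Rr = polychoric_matrix(shuffled, n_categories)
        rand[r] = np.sort(np.linalg.eigvalsh(Rr))[::-1]
    rand_mean = rand.mean(axis=0)
    retained = 0
    for lam, ref in zip(eig, rand_mean):
        if lam > ref:
            retained += 1
        else:
            break
    return eig, retained, rand_mean


def efa_wls(
    corr: np.ndarray, n_factors: int = 1, max_iter: int = 500, tol: float = 1e-7
) -> tuple[np.ndarray, float]:
    """Least-squares exploratory factor analysis (iterated principal factors).

    Minimizes the (unit-weight) least-squares discrepancy between the
    off-diagonal correlations and the factor-model reproduction; returns
    loadings (p x m) and the proportion of total variance carried by the
    first factor.  Heywood communalities are clipped with a warning.
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    try:
        smc = 1.0 - 1.0 / np.diag(np.linalg.inv(R))
    except np.linalg.LinAlgError:
        smc = np.full(p, 0.5)
    h2 = np.clip(smc, 0.05, 0.99)
    L = np.zeros((p, n_factors))
    for _ in range(max_iter):
        Rr = R.copy()
        np.fill_diagonal(Rr, h2)
        vals, vecs = np.linalg.eigh(Rr)
        order = np.argsort(vals)[::-1][:n_factors]
        lam = np.maximum(vals[order], 0.0)
        L = vecs[:, order] * np.sqrt(lam)
        # fix sign: dominant loading positive
        for m in range(n_factors):
            if L[np.argmax(np.abs(L[:, m])), m] < 0:
                L[:, m] = -L[:, m]
        h2_new = np.sum(L**2, axis=1)
        if np.any(h2_new > 1.0):
            warnings.warn("Heywood case: communality > 1 clipped")
            h2_new = np.minimum(h2_new, 0.995)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new
    proportion = float(np.sum(L[:, 0] ** 2) / p)
    return L, proportion


# ------------------------------------------------------------------------ CFA

def _ml_discrepancy(S: np.ndarray, Sigma: np.ndarray) -> float:
    p = S.shape[0]
    sign, logdet_sigma = np.linalg.slogdet(Sigma)
    _, logdet_s = np.linalg.slogdet(S)
    return float(logdet_sigma - logdet_s + np.trace(S @ np.linalg.inv(Sigma)) - p)


def cfa_one_factor(
    corr: np.ndarray, n: int
) -> tuple[dict[str, float], np.ndarray, list[tuple[int, int, float]]]:
    """One-factor confirmatory fit of a (polychoric) correlation matrix.

    Least-squares estimation of loadings; residual correlations index local
    dependence (|residual| > 0.20 flagged).  Fit indices (CFI, TLI, RMSEA,
    SRMR) use the unscaled maximum-likelihood chi-square approximation on the
    fitted structure — close in spirit, but not equal, to the scaled DWLS
    values ordinal-CFA software reports.

    Returns (fit_indices, residual matrix, flagged (i, j, residual) pairs).
    """
    R = np.asarray(corr, dtype=float)
    p = R.shape[0]
    if n <= p:
        raise ValueError("sample size must exceed the number of items")
    L0, _ = efa_wls(R, 1)
    lam0 = np.clip(L0[:, 0], -0.98, 0.98)
    mask = ~np.eye(p, dtype=bool)

    def loss(lam: np.ndarray) -> float:
        res = R - np.outer(lam, lam)
        return float(np.sum(res[mask] ** 2))

    sol = minimize(loss, lam0, method="L-BFGS-B",
                   bounds=[(-0.999, 0.999)] * p, options={"maxiter": 500})
    if not sol.success and loss(sol.x) > loss(lam0):
        raise RuntimeError(f"one-factor CFA failed to converge: {sol.message}")
    lam = sol.x
    residual = R - np.outer(lam, lam)
    np.fill_diagonal(residual, 0.0)
    flagged = [
        (i, j, float(residual[i, j]))
        for i in range(p)
        for j in range(i + 1, p)
        if abs(residual[i, j]) > RESIDUAL_CUT
    ]
    Sigma = np.outer(lam, lam)
    np.fill_diagonal(Sigma, 1.0)
    Sigma, _ = nearest_psd(Sigma, 1e-4)
    T = max((n - 1) * _ml_discrepancy(R, Sigma), 0.0)
    df = p * (p + 1) // 2 - 2 * p
    T_b = max((n - 1) * _ml_discrepancy(R, np.eye(p)), 0.0)
    df_b = p * (p - 1) // 2
    cfi = 1.0 - max(T - df, 0.0) / max(T_b - df_b, 1e-12)
    tli_num = T_b / df_b - T / df
    tli = tli_num / max(T_b / df_b - 1.0, 1e-12)
    rmsea = float(np.sqrt(max(T - df, 0.0) / (df * (n - 1))))
    srmr = float(np.sqrt(np.sum(residual[mask] ** 2) / (p * (p - 1))))
    fit = {"cfi": float(min(cfi, 1.0)), "tli": float(min(tli, 1.0)),
           "rmsea": rmsea, "srmr": srmr}
    return fit, residual, flagged


# --------------------------------------------------------------------- Mokken

def _covmax(px: np.ndarray, py: np.ndarray) -> float:
    """Maximal covariance of two ordinal variables with given marginals
    (comonotonic / Guttman coupling by the northwest-corner rule)."""
    K = px.size
    vals = np.arange(K)
    ex, ey = vals @ px, vals @ py
    i = j = 0
    rx, ry = px[0], py[0]
    exy = 0.0
    while i < K and j < K:
        m = min(rx, ry)
        exy += m * i * j
        rx -= m
        ry -= m
        if rx <= 1e-15:
            i += 1
            rx = px[i] if i < K else 0.0
        if ry <= 1e-15:
            j += 1
            ry = py[j] if j < K else 0.0
    return exy - ex * ey


def _h_coefficients(data: np.ndarray, n_categories: int):
    n, p = data.shape
    cov = np.cov(data.T, bias=True)
    cmax = np.zeros((p, p))
    marg = [np.bincount(data[:, j], minlength=n_categories) / n for j in range(p)]
    for i in range(p):
        for j in range(i + 1, p):
            cmax[i, j] = cmax[j, i] = _covmax(marg[i], marg[j])
    off = ~np.eye(p, dtype=bool)
    h_items = np.array([
        cov[i, off[i]].sum() / cmax[i, off[i]].sum() for i in range(p)
    ])
    iu = np.triu_indices(p, 1)
    h_scale = cov[iu].sum() / cmax[iu].sum()
    return h_items, float(h_scale)


def mokken_h(
    matrix: ResponseMatrix | np.ndarray,
    n_boot: int = 100,
    seed: int | None = None,
    n_categories: int = 5,
) -> tuple[np.ndarray, float, float]:
    """Loevinger-type scalability coefficients (item H_i, scale H, SE).

    H compares observed inter-item covariances to the maximum attainable
    under the marginals; H = 1 for perfect Guttman ordering, ~0 for
    independent items.  The scale-H standard error is a person bootstrap
    (``n_boot`` resamples; 0 disables it and returns NaN).
    """
    data = matrix.values if isinstance(matrix, ResponseMatrix) else np.asarray(matrix)
    if np.isnan(data).any():
        raise ValueError("mokken_h requires listwise-complete data")
    data = data.astype(int)
    if np.any(data.std(axis=0) == 0):
        raise ValueError("zero-variance item: scalability undefined")
    h_items, h_scale = _h_coefficients(data, n_categories)
    se = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        n = data.shape[0]
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            sample = data[idx]
            if np.any(sample.std(axis=0) == 0):
                continue
            reps.append(_h_coefficients(sample, n_categories)[1])
        if len(reps) > 1:
            se = float(np.std(reps, ddof=1))
    return h_items, h_scale, se


# --------------------------------------------------------------------- report

@dataclass
class AssumptionReport:
    """Aggregated verdicts mirroring a standard IRT-assumptions table."""

    kmo_overall: float
    kmo_per_item: np.ndarray
    eigenvalues: np.ndarray
    first_factor_proportion: float
    eigen_ratio_1_2: float
    fit_indices: dict[str, float]
    residual_corr_max: float
    locally_dependent_pairs: list[tuple[str, str, float]]
    h_per_item: np.ndarray
    h_scale: float
    h_scale_se: float
    unidimensional: bool = field(init=False)
    locally_independent: bool = field(init=False)
    monotone: bool = field(init=False)

    def __post_init__(self) -> None:
        self.unidimensional = (
            self.first_factor_proportion >= FIRST_FACTOR_PROP_CUT
            and self.eigen_ratio_1_2 > EIGEN_RATIO_CUT
        )
        self.locally_independent = len(self.locally_dependent_pairs) == 0
        self.monotone = bool(
            np.all(self.h_per_item > H_ITEM_CUT) and self.h_scale > H_SCALE_CUT
        )

    def to_dict(self) -> dict:
        return {
            "kmo_overall": self.kmo_overall,
            "kmo_per_item": list(map(float, self.kmo_per_item)),
            "eigenvalues": list(map(float, self.eigenvalues)),
            "first_factor_proportion": self.first_factor_proportion,
            "eigen_ratio_1_2": self.eigen_ratio_1_2,
            "fit_indices": self.fit_indices,
            "residual_corr_max": self.residual_corr_max,
            "locally_dependent_pairs": self.locally_dependent_pairs,
            "h_per_item": list(map(float, self.h_per_item)),
            "h_scale": self.h_scale,
            "h_scale_se": self.h_scale_se,
            "unidimensional": self.unidimensional,
            "locally_independent": self.locally_independent,
            "monotone": self.monotone,
        }


def assumption_report(
    efa_matrix: ResponseMatrix,
    cfa_matrix: ResponseMatrix,
    n_random: int = 20,
    n_boot: int = 50,
    seed: int | None = None,
) -> AssumptionReport:
    """Run all assumption checks, EFA-side checks on one half of the sample
    and the confirmatory fit on the other (split to avoid double-dipping)."""
    R_efa = polychoric_matrix(efa_matrix)
    kmo_overall, kmo_items = kmo(R_efa)
    eig, _, _ = parallel_analysis(efa_matrix, n_random=n_random, seed=seed)
    _, prop = efa_wls(R_efa, 1)
    ratio = float(eig[0] / max(eig[1], 1e-12))
    R_cfa = polychoric_matrix(cfa_matrix)
    fit, residual, flagged_idx = cfa_one_factor(R_cfa, cfa_matrix.n_persons)
    ids = cfa_matrix.item_ids
    flagged = [(ids[i], ids[j], r) for i, j, r in flagged_idx]
    res_max = float(np.max(np.abs(residual))) if residual.size else 0.0
    # monotonicity on the pooled sample
    pooled = np.vstack([efa_matrix.values, cfa_matrix.values])
    h_items, h_scale, h_se = mokken_h(pooled, n_boot=n_boot, seed=seed)
    return AssumptionReport(
        kmo_overall=kmo_overall,
        kmo_per_item=kmo_items,
        eigenvalues=eig,
        first_factor_proportion=prop,
        eigen_ratio_1_2=ratio,
        fit_indices=fit,
        residual_corr_max=res_max,
        locally_dependent_pairs=flagged,
        h_per_item=h_items,
        h_scale=h_scale,
        h_scale_se=h_se,
    )
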