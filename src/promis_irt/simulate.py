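"""Synthetic response data with the structure the analysis pipeline assumes.

The generator plays the role of the study cohort: a two-group sample
(school and child-and-adolescent-psychiatry, CAP) of adolescents answering
five-category symptom items, with latent traits on a standard-normal
reference metric.  Default group sizes (637 school / 291 CAP) and latent
means (school -0.23, CAP 0.50 — the published known-group T-scores 47.7 and
55.0 mapped through theta = (T - 50) / 10) reproduce the cohort the Swedish
pediatric PROMIS validation describes; missingness is injected completely at
random at a configurable rate (default 3.4%).

Responses are drawn from the graded response model of a given item bank, so
every downstream check (assumptions, calibration recovery, DIF, CAT) sees
data whose generating process is known exactly.

``thetas_from_decile_means`` rebuilds a validation sample from a published
decile profile (per-decile mean thetas and simulee counts); the profiles of
the Swedish anxiety (n=196) and depressive-symptoms (n=199) post-hoc CAT
validation samples ship as :data:`ANXIETY_VALIDATION_DECILES` and
:data:`DEPRESSIVE_VALIDATION_DECILES`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .banks import ItemBank, ItemParameters
from .grm import bank_probabilities
from .responses import ResponseMatrix

__all__ = [
    "CohortConfig",
    "simulate_responses",
    "generate_cohort",
    "inject_dif",
    "thetas_from_decile_means",
    "ANXIETY_VALIDATION_DECILES",
    "DEPRESSIVE_VALIDATION_DECILES",
]

# Published post-hoc CAT validation decile profiles (Swedish parameters):
# mean theta and number of simulees per reported decile.
ANXIETY_VALIDATION_DECILES = {
    "means": (-1.42, -0.81, -0.50, -0.18, 0.15, 0.34, 0.54, 0.89, 1.48),
    "counts": (39, 20, 19, 20, 20, 19, 19, 20, 20),
}
DEPRESSIVE_VALIDATION_DECILES = {
    "means": (-1.45, -0.73, -0.45, -0.24, 0.14, 0.39, 0.68, 0.93, 1.47),
    "counts": (40, 20, 20, 19, 20, 20, 18, 22, 20),
}


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort layout.

    Latent means are on the theta metric; defaults invert the published
    known-group T-scores (school 47.7, CAP 55.0).  ``sd_theta`` defaults to
    the reference-population value 1.0 (within-group latent SDs are not
    published; 1.2 approximates the printed pooled T-score SDs if wanted).
    """

    n_school: int = 637
    n_cap: int = 291
    mean_theta_school: float = -0.23
    mean_theta_cap: float = 0.50
    sd_theta: float = 1.0
    missing_rate: float = 0.034
    prop_female_school: float = 0.611
    prop_female_cap: float = 0.714
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_school < 0 or self.n_cap < 0:
            raise ValueError("group sizes must be non-negative")
        if self.sd_theta <= 0:
            raise ValueError("sd_theta must be positive")
        if not 0 <= self.missing_rate <= 0.2:
            raise ValueError("missing_rate must lie in [0, 0.2]")


def simulate_responses(
    bank: ItemBank,
    thetas: np.ndarray,
    seed: int | np.random.Generator | None = None,
    covariates: pd.DataFrame | None = None,
) -> ResponseMatrix:
    """Draw GRM responses for each theta; stores true_theta as a covariate."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    thetas = np.asarray(thetas, dtype=float)
    n = thetas.size
    J = len(bank)
    resp = np.empty((n, J))
    for j, item in enumerate(bank):
        from .grm import category_probabilities

        p = category_probabilities(item, thetas)  # (n, K)
        cum = np.cumsum(p, axis=1)
        u = rng.random(n)
        resp[:, j] = (u[:, None] > cum).sum(axis=1)
    index = pd.RangeIndex(n, name="person_id")
    cov = covariates.copy() if covariates is not None else pd.DataFrame(index=index)
    cov.index = index
    cov["true_theta"] = thetas
    df = pd.DataFrame(resp, index=index, columns=bank.item_ids)
    return ResponseMatrix(df, cov, bank.n_categories)


def generate_cohort(bank: ItemBank, config: CohortConfig | None = None) -> ResponseMatrix:
    """Simulate the default two-group cohort from an item bank.

    Thetas are normal within group; sex and age-group labels are assigned at
    the configured proportions (they drive nothing in the generator and exist
    as DIF grouping labels); missing cells are MCAR at ``missing_rate``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_school + config.n_cap
    thetas = np.concatenate([
        rng.normal(config.mean_theta_school, config.sd_theta, config.n_school),
        rng.normal(config.mean_theta_cap, config.sd_theta, config.n_cap),
    ])
    sample_type = np.array(["school"] * config.n_school + ["cap"] * config.n_cap)
    p_female = np.where(sample_type == "school", config.prop_female_school,
                        config.prop_female_cap)
    sex = np.where(rng.random(n) < p_female, "female", "male")
    age_group = np.where(rng.random(n) < 0.5, "12-15", "16-20")
    cov = pd.DataFrame({
        "sex": sex,
        "age_group": age_group,
        "sample_type": sample_type,
        "language": "sv",
    })
    matrix = simulate_responses(bank, thetas, rng, cov)
    if config.missing_rate > 0:
        mask = rng.random(matrix.responses.shape) < config.missing_rate
        vals = matrix.responses.to_numpy()
        vals[mask] = np.nan
        matrix.responses.iloc[:, :] = vals
    return matrix


def inject_dif(
    bank: ItemBank,
    item_ids: list[str],
    b_shift: float = 0.0,
    a_ratio: float = 1.0,
) -> ItemBank:
    """Focal-group bank with planted DIF on selected items.

    ``b_shift`` moves all thresholds (uniform DIF); ``a_ratio`` scales the
    discrimination (non-uniform DIF).  Thresholds stay ordered because the
    shift is common to all of them.
    """
    unknown = [i for i in item_ids if i not in bank.item_ids]
    if unknown:
        raise KeyError(f"unknown item id(s): {unknown}")
    targets = set(item_ids)
    items = tuple(
        ItemParameters(
            it.item_id,
            it.a * a_ratio if it.item_id in targets else it.a,
            tuple(np.asarray(it.b) + b_shift) if it.item_id in targets else it.b,
        )
        for it in bank
    )
    return ItemBank(name=f"{bank.name}_dif", items=items, n_categories=bank.n_categories)


def thetas_from_decile_means(
    decile_means,
    counts,
    jitter_sd: float = 0.15,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Rebuild a theta vector from a published decile profile.

    Each decile contributes ``counts[i]`` thetas at ``decile_means[i]`` plus
    N(0, jitter_sd) noise; jitter 0 replicates the means exactly.
    """
    decile_means = np.asarray(decile_means, dtype=float)
    counts = np.asarray(counts)
    if decile_means.shape != counts.shape:
        raise ValueError("decile_means and counts must have matching lengths")
    if np.any(counts < 0) or np.any(counts != counts.astype(int)):
        raise ValueError("counts must be non-negative integers")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    thetas = np.repeat(decile_means, counts.astype(int))
    if jitter_sd > 0:
        thetas = thetas + rng.normal(0.0, jitter_sd, thetas.size)
    return thetas
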