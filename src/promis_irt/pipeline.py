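"""End-to-end validation pipeline and sample-level statistics.

Orchestrates the full analysis for one item bank: listwise deletion, a 50/50
split for the factor-analytic assumption checks (EFA-side checks on one
half, confirmatory fit on the other), an evaluation/validation split
(~78/22, matching "slightly under 80%" evaluation-sample practice), GRM
calibration on the evaluation sample with S-X^2 item fit, DIF scans,
optional hybrid-bank linking, and the post-hoc CAT on the validation
sample.  Also houses the known-group comparison (Welch t-test and Cohen's d
on T-scores) and floor/ceiling screening.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .assumptions import AssumptionReport, assumption_report
from .banks import ItemBank, load_item_bank
from .calibrate import GRMFitConfig, GRMFitResult, fit_grm
from .cat import CATConfig, SimulationSummary, posthoc_simulation
from .dif import DIFResult, dif_scan
from .grm import eap_score_matrix, theta_to_tscore
from .itemfit import ItemFitResult, s_x2_item_fit
from .responses import ResponseMatrix, listwise_complete
from .simulate import CohortConfig, generate_cohort

__all__ = [
    "PipelineConfig",
    "PipelineReport",
    "KnownGroupResult",
    "split_sample",
    "known_group_analysis",
    "floor_ceiling",
    "run_full_pipeline",
]

FLOOR_CEILING_CUT = 15.0  # percent


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of :func:`run_full_pipeline`."""

    bank: str = "anxiety_sv"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    evaluation_fraction: float = 0.78
    seed: int = 0
    cat: CATConfig = field(default_factory=CATConfig)
    dif_comparisons: tuple[str, ...] = ("sample_type",)
    n_random_parallel: int = 20
    n_boot_mokken: int = 50
    calibration: GRMFitConfig = field(default_factory=GRMFitConfig)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not 0.5 < self.evaluation_fraction < 0.95:
            raise ValueError("evaluation_fraction must lie in (0.5, 0.95)")


@dataclass(frozen=True)
class KnownGroupResult:
    """Welch t-test and Cohen's d comparing group mean T-scores."""

    mean_t_school: float
    mean_t_cap: float
    t_statistic: float
    df: float
    p: float
    cohens_d: float
    d_ci: tuple[float, float]

    @property
    def effect_band(self) -> str:
        d = abs(self.cohens_d)
        if d >= 0.8:
            return "large"
        if d >= 0.5:
            return "medium"
        if d >= 0.2:
            return "small"
        return "negligible"


def split_sample(
    n: int, fraction: float, seed: int | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Random disjoint evaluation/validation index split.

    |evaluation| = round(fraction * n); reproducible under ``seed``.
    """
    if n < 2:
        raise ValueError("need at least two persons to split")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(fraction * n))
    k = min(max(k, 1), n - 1)
    return np.sort(perm[:k]), np.sort(perm[k:])


def known_group_analysis(tscores: np.ndarray, groups: np.ndarray) -> KnownGroupResult:
    """Welch two-sample comparison of T-scores between two groups.

    Cohen's d uses the pooled SD with a normal-approximation 95% CI.  Group
    order follows sorted label order (alphabetical: "cap" before "school"
    with the default labels); the t statistic is group1 - group2.
    """
    tscores = np.asarray(tscores, dtype=float)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if levels.size != 2:
        raise ValueError(f"known-group analysis needs exactly two groups, got {levels!r}")
    x1 = tscores[groups == levels[0]]
    x2 = tscores[groups == levels[1]]
    if min(x1.size, x2.size) < 2:
        raise ValueError("each group needs at least two observations")
    welch = stats.ttest_ind(x1, x2, equal_var=False)
    n1, n2 = x1.size, x2.size
    sp = np.sqrt(((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2))
    d = float((x1.mean() - x2.mean()) / sp) if sp > 0 else 0.0
    se_d = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    means = {lv: float(tscores[groups == lv].mean()) for lv in levels}
    mean_school = means.get("school", means[levels[-1]])
    mean_cap = means.get("cap", means[levels[0]])
    return KnownGroupResult(
        mean_t_school=mean_school,
        mean_t_cap=mean_cap,
        t_statistic=float(welch.statistic),
        df=float(welch.df),
        p=float(welch.pvalue),
        cohens_d=d,
        d_ci=(float(d - 1.96 * se_d), float(d + 1.96 * se_d)),
    )


def floor_ceiling(matrix: ResponseMatrix) -> dict[str, float | bool]:
    """Percent of persons at the minimum / maximum possible raw sum score.

    Flags either effect above 15%.  Requires complete rows.
    """
    vals = matrix.values
    if np.isnan(vals).any():
        raise ValueError("floor_ceiling requires complete rows")
    total = vals.sum(axis=1)
    max_possible = (matrix.n_categories - 1) * vals.shape[1]
    floor_pct = float(np.mean(total == 0) * 100)
    ceiling_pct = float(np.mean(total == max_possible) * 100)
    return {
        "floor_pct": floor_pct,
        "ceiling_pct": ceiling_pct,
        "floor_flag": floor_pct > FLOOR_CEILING_CUT,
        "ceiling_flag": ceiling_pct > FLOOR_CEILING_CUT,
    }


@dataclass
class PipelineReport:
    """Everything :func:`run_full_pipeline` computes, stage by stage."""

    config: PipelineConfig
    missing_fraction: float
    n_complete: int
    assumptions: AssumptionReport
    calibration: GRMFitResult
    item_fit: list[ItemFitResult]
    dif: dict[str, list[DIFResult]]
    known_group: KnownGroupResult
    floor_ceiling: dict[str, float | bool]
    cat_summary: SimulationSummary

    def item_table(self) -> pd.DataFrame:
        """Calibrated parameters with item fit, one row per item."""
        params = self.calibration.bank.to_frame().set_index("item_id")
        fit = pd.DataFrame(
            [
                {"item_id": r.item_id, "s_x2": r.s_x2, "df": r.df, "p": r.p,
                 "fit_ok": r.fit_ok}
                for r in self.item_fit
            ]
        ).set_index("item_id")
        return params.join(fit)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.item_table().to_csv(out / "item_parameters.csv")
        if self.cat_summary.deciles is not None:
            self.cat_summary.deciles.to_csv(out / "cat_deciles.csv")
        self.cat_summary.per_person.to_csv(out / "cat_per_person.csv", index=False)
        dif_rows = [
            {"comparison": comp, "item_id": r.item_id,
             "r2_null_to_uniform": r.r2_null_to_uniform,
             "r2_uniform_to_nonuniform": r.r2_uniform_to_nonuniform,
             "r2_total": r.r2_total, "flagged": r.flagged, "dif_type": r.dif_type}
            for comp, results in self.dif.items() for r in results
        ]
        pd.DataFrame(dif_rows).to_csv(out / "dif_results.csv", index=False)
        summary = {
            "missing_fraction": self.missing_fraction,
            "n_complete": self.n_complete,
            "assumptions": self.assumptions.to_dict(),
            "known_group": asdict(self.known_group),
            "floor_ceiling": self.floor_ceiling,
            "cat_overall": self.cat_summary.overall,
            "calibration": {
                "loglik": self.calibration.loglik,
                "n_iter": self.calibration.n_iter,
                "converged": self.calibration.converged,
            },
            "seed": self.config.seed,
        }
        (out / "summary.json").write_text(json.dumps(summary, indent=1, default=str))


def run_full_pipeline(config: PipelineConfig | None = None) -> PipelineReport:
    """Run the whole validation analysis on a synthetic cohort.

    Stages: cohort generation, listwise deletion, split-half assumption
    checks, evaluation/validation split, GRM calibration + S-X^2 on the
    evaluation sample, DIF scans, known-group and floor/ceiling statistics,
    post-hoc CAT on the validation sample scored with the calibrated bank.
    """
    config = config or PipelineConfig()
    bank = load_item_bank(config.bank)
    cohort = generate_cohort(bank, config.cohort)
    missing = cohort.missing_fraction()
    complete = listwise_complete(cohort)

    half_a, half_b = split_sample(complete.n_persons, 0.5, seed=config.seed)
    assumptions = assumption_report(
        complete.select(complete.responses.index[half_a]),
        complete.select(complete.responses.index[half_b]),
        n_random=config.n_random_parallel,
        n_boot=config.n_boot_mokken,
        seed=config.seed,
    )

    ev_idx, va_idx = split_sample(
        complete.n_persons, config.evaluation_fraction, seed=config.seed + 1
    )
    evaluation = complete.select(complete.responses.index[ev_idx])
    validation = complete.select(complete.responses.index[va_idx])

    calibration = fit_grm(evaluation, config.calibration, bank_name=f"{bank.name}_fit")
    item_fit = s_x2_item_fit(evaluation, calibration.bank, config.calibration.grid)

    dif_results: dict[str, list[DIFResult]] = {}
    for comp in config.dif_comparisons:
        labels = complete.covariates[comp].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            dif_results[comp] = dif_scan(complete, labels, calibration.bank)

    theta_all, _ = eap_score_matrix(complete.values, calibration.bank)
    tscores = theta_to_tscore(theta_all)
    known = known_group_analysis(tscores, complete.covariates["sample_type"].to_numpy())
    fc = floor_ceiling(complete)

    cat_summary = posthoc_simulation(validation, calibration.bank, config.cat)

    report = PipelineReport(
        config=config,
        missing_fraction=missing,
        n_complete=complete.n_persons,
        assumptions=assumptions,
        calibration=calibration,
        item_fit=item_fit,
        dif=dif_results,
        known_group=known,
        floor_ceiling=fc,
        cat_summary=cat_summary,
    )
    if config.output_dir:
        report.save(config.output_dir)
    return report
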