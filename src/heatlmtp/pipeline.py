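"""Scenario-grid orchestration: exclusion cascade, panels, ratios, TMLE.

A scenario grid crosses temperature indicators (overall / daytime /
nighttime), heat-threshold percentiles (0.80 / 0.85 / 0.90), and shift
magnitudes k in {1, 2, 3} degC; each cell yields one results row with
the natural-course mean, the counterfactual mean, their contrast theta
with EIF inference, and the provenance needed to audit it (resolved
threshold, truncation diagnostics, library, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .cohort import SyntheticCohort
from .exposure import (
    Direction,
    ExposurePanel,
    Indicator,
    ShiftPolicy,
    count_spikes_matrix,
    resolve_threshold,
)
from .learners import LearnerLibrary
from .ratios import estimate_ratios, truncate
from .tmle import (
    DEFAULT_OUTCOME_BOUNDS,
    natural_course_mean,
    tmle_contrast,
    tmle_policy_mean,
)

logger = logging.getLogger(__name__)

#: The cold-spike confounder: mirror of the heat definition at the 10th
#: percentile with runs of >= 2 days, fixed across the scenario grid.
COLD_PERCENTILE = 0.10


@dataclass(frozen=True)
class ExclusionStage:
    label: str
    removed: int
    remaining: int


@dataclass
class ExclusionLedger:
    """Ordered record of sample-exclusion stages with running remainders."""

    initial: int
    stages: list[ExclusionStage] = field(default_factory=list)

    @property
    def final(self) -> int:
        return self.stages[-1].remaining if self.stages else self.initial

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": "initial", "removed": 0, "remaining": self.initial}]
        rows += [
            {"label": s.label, "removed": s.removed, "remaining": s.remaining}
            for s in self.stages
        ]
        return pd.DataFrame(rows)


def apply_exclusion_cascade(
    initial_count: int, removals: Sequence[tuple[str, int]]
) -> ExclusionLedger:
    """Run an ordered exclusion cascade on counts.

    Each removal is a ``(label, count)`` pair; remainders decrease
    monotonically and a removal exceeding the current remainder is an
    error.
    """
    if initial_count < 0:
        raise ValueError("initial count must be nonnegative")
    ledger = ExclusionLedger(initial=initial_count)
    remaining = initial_count
    for label, removed in removals:
        if removed < 0:
            raise ValueError(f"stage {label!r}: negative removal")
        if removed > remaining:
            raise ValueError(
                f"stage {label!r}: removing {removed} exceeds the "
                f"{remaining} remaining participants"
            )
        remaining -= removed
        ledger.stages.append(ExclusionStage(label, removed, remaining))
    return ledger


def apply_exclusion_predicates(
    table: pd.DataFrame, exclusions: Sequence[tuple[str, Callable[[pd.DataFrame], pd.Series]]]
) -> tuple[pd.DataFrame, ExclusionLedger]:
    """Drop rows stage by stage; returns the kept table and the ledger.

    Each exclusion is ``(label, predicate)`` where the predicate marks
    rows to *remove*.
    """
    ledger = ExclusionLedger(initial=len(table))
    kept = table
    for label, predicate in exclusions:
        drop = np.asarray(predicate(kept), dtype=bool)
        removed = int(drop.sum())
        kept = kept.loc[~drop]
        ledger.stages.append(ExclusionStage(label, removed, len(kept)))
    return kept, ledger


@dataclass
class ScenarioGrid:
    """The full crossing of indicators x percentiles x shifts."""

    indicators: tuple[Indicator, ...] = (
        Indicator.OVERALL, Indicator.DAYTIME, Indicator.NIGHTTIME,
    )
    percentiles: tuple[float, ...] = (0.90, 0.85, 0.80)
    shifts: tuple[float, ...] = (1.0, 2.0, 3.0)
    seed: int = 0
    library: str = "fast"
    folds: int = 5
    truncation_quantile: float = 0.999
    truncation_scope: str = "pooled"
    min_run: int = 2
    cross_fit: bool = False

    def __post_init__(self) -> None:
        self.indicators = tuple(Indicator(i) for i in self.indicators)
        if not (self.indicators and self.percentiles and self.shifts):
            raise ValueError("the scenario grid must be non-empty")

    def cells(self):
        for ind in self.indicators:
            for pct in self.percentiles:
                for k in self.shifts:
                    yield ind, pct, k


def build_panels(
    temps: np.ndarray,
    child_ids: np.ndarray,
    policy: ShiftPolicy,
    cold_policy: ShiftPolicy,
) -> ExposurePanel:
    """Vectorised panel construction from an N x 840 temperature matrix."""
    heat = count_spikes_matrix(
        temps + policy.k, policy.threshold_value, policy.min_run, Direction.ABOVE
    )
    cold = count_spikes_matrix(
        temps, cold_policy.threshold_value, cold_policy.min_run, Direction.BELOW
    )
    return ExposurePanel(
        child_ids=child_ids,
        counts=heat,
        cold_counts=cold,
        policy=policy,
        provenance="factual" if policy.k == 0 else "counterfactual",
    )


def run_scenario(
    cohort: SyntheticCohort,
    indicator: Indicator,
    percentile: float,
    k: float,
    grid: ScenarioGrid,
    natural_cache: dict | None = None,
) -> dict:
    """One grid cell: threshold -> panels -> ratios -> TMLE -> contrast."""
    library = LearnerLibrary.named(grid.library)
    temps = cohort.temperatures(indicator)
    pooled = temps.ravel()
    threshold = resolve_threshold(pooled, percentile)
    cold_threshold = resolve_threshold(pooled, COLD_PERCENTILE)
    policy_kwargs = dict(
        indicator=indicator,
        threshold_percentile=percentile,
        min_run=grid.min_run,
        threshold_value=threshold,
    )
    factual_policy = ShiftPolicy(k=0.0, **policy_kwargs)
    shift_policy = ShiftPolicy(k=k, **policy_kwargs)
    cold_policy = ShiftPolicy(
        k=0.0, indicator=indicator, threshold_percentile=COLD_PERCENTILE,
        min_run=grid.min_run, threshold_value=cold_threshold,
        direction=Direction.BELOW,
    )
    factual = build_panels(temps, cohort.child_ids, factual_policy, cold_policy)
    counterfactual = build_panels(temps, cohort.child_ids, shift_policy, cold_policy)

    raw_ratios = estimate_ratios(
        factual, counterfactual, cohort.covariates,
        library=library, folds=grid.folds, seed=grid.seed,
    )
    ratios = truncate(
        raw_ratios, grid.truncation_quantile, grid.truncation_scope
    )
    shift_result = tmle_policy_mean(
        cohort.log_outcome, factual, counterfactual, ratios,
        cohort.covariates, library=library, folds=grid.folds,
        seed=grid.seed + 1000, cross_fit=grid.cross_fit,
    )
    cache_key = (indicator, percentile)
    if natural_cache is not None and cache_key in natural_cache:
        natural_result = natural_cache[cache_key]
    else:
        natural_result = natural_course_mean(
            cohort.log_outcome, factual, cohort.covariates,
            library=library, folds=grid.folds, seed=grid.seed + 2000,
            cross_fit=grid.cross_fit,
        )
        if natural_cache is not None:
            natural_cache[cache_key] = natural_result
    contrast = tmle_contrast(shift_result, natural_result)
    return {
        "indicator": indicator.value,
        "percentile": percentile,
        "k": k,
        "threshold": threshold,
        "cold_threshold": cold_threshold,
        "psi_natural": contrast.psi_natural,
        "psi_shift": contrast.psi_shift,
        "theta": contrast.theta,
        "se_theta": contrast.se_theta,
        "ci_low": contrast.ci95[0],
        "ci_high": contrast.ci95[1],
        "p_value": contrast.p_value,
        "bt_natural": contrast.back_transformed_natural,
        "bt_shift": contrast.back_transformed_shift,
        "empirical_mean": natural_result.empirical_mean,
        "ratio_mean": float(ratios.ratios.mean()),
        "ratio_median": float(np.median(ratios.ratios)),
        "ratio_max": float(ratios.ratios.max()),
        "fraction_truncated": ratios.fraction_truncated,
        "truncation_quantile": grid.truncation_quantile,
        "library": grid.library,
        "folds": grid.folds,
        "seed": grid.seed,
    }


def run_grid(cohort: SyntheticCohort, grid: ScenarioGrid) -> pd.DataFrame:
    """Run every grid cell; per-cell failures are recorded, not fatal.

    Raises only if *all* cells fail.  The number of scenarios run is
    logged (p-values are reported unadjusted for multiplicity).
    """
    rows, failures = [], []
    natural_cache: dict = {}
    for indicator, percentile, k in grid.cells():
        label = f"{indicator.value}/p{percentile:.2f}/k={k:g}"
        try:
            logger.info("running scenario %s", label)
            rows.append(
                run_scenario(cohort, indicator, percentile, k, grid, natural_cache)
            )
        except Exception as exc:  # noqa: BLE001 - per-cell isolation
            logger.error("scenario %s failed: %s", label, exc)
            failures.append({"scenario": label, "error": str(exc)})
    if not rows:
        raise RuntimeError(
            f"all {len(failures)} scenario cells failed; first error: "
            f"{failures[0]['error']}"
        )
    results = pd.DataFrame(rows)
    results.attrs["failures"] = failures
    results.attrs["n_scenarios"] = len(rows)
    logger.info(
        "grid complete: %d scenarios, %d failures (p-values unadjusted)",
        len(rows), len(failures),
    )
    return results


def plot_exposure_distributions(
    factual: ExposurePanel, counterfactual: ExposurePanel, path
) -> None:
    """Boxplots of factual vs counterfactual spike counts per period."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = factual.n_periods
    fig, ax = plt.subplots(figsize=(10, 4))
    pos = np.arange(1, t + 1)
    ax.boxplot(
        [factual.counts[:, i] for i in range(t)],
        positions=pos - 0.18, widths=0.3,
        boxprops=dict(color="tab:blue"), medianprops=dict(color="tab:blue"),
    )
    ax.boxplot(
        [counterfactual.counts[:, i] for i in range(t)],
        positions=pos + 0.18, widths=0.3,
        boxprops=dict(color="tab:red"), medianprops=dict(color="tab:red"),
    )
    ax.set_xticks(pos)
    ax.set_xticklabels([str(p) for p in pos])
    ax.set_xlabel("10-week period")
    ax.set_ylabel("Number of heat spikes")
    ax.set_title(
        f"Factual (blue) vs counterfactual (red), k={counterfactual.policy.k:g} degC"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def impute_covariates(table: pd.DataFrame) -> pd.DataFrame:
    """Simple mean/mode imputation for covariates with missing values.

    A convenience for external data only (synthetic cohorts are
    complete); this is deliberately plain single imputation, not a
    chained-equations procedure.
    """
    out = table.copy()
    for col in out.columns:
        if out[col].isna().any():
            if pd.api.types.is_numeric_dtype(out[col]):
                nunique = out[col].nunique(dropna=True)
                fill = (
                    out[col].mode(dropna=True).iloc[0]
                    if nunique <= 10
                    else out[col].mean()
                )
            else:
                fill = out[col].mode(dropna=True).iloc[0]
            out[col] = out[col].fillna(fill)
    return out
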