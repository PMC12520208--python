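"""Density-ratio estimation by classification, with truncation.

For each period t the ratio of the counterfactual to the factual
conditional exposure density, evaluated at the observed exposure, is
estimated with the classification trick: stack 2N rows — the observed
(history, exposure) pair labelled 0 and the same history with the
shifted exposure labelled 1 — fit a probability model, and convert the
predicted probability at the factual row to an odds,
``r_t = p / (1 - p)``.  Because the classes are stacked 1:1 by
construction no prevalence correction is needed.  The ratios are the
longitudinal analogue of stabilized inverse-probability weights: under
the null shift they concentrate near 1.

History is conditioned in full (no Markov assumption): baseline
covariates, cold-spike counts through period t, and heat-spike counts
through period t-1, with the within-period ordering covariates ->
cold_t -> heat_t.

Extreme ratios signal practical positivity violations; they are capped
at an empirical quantile (99.9th percentile by default, pooled across
periods) before use in the targeting step.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import FunctionTransformer, StandardScaler

from .exposure import ExposurePanel
from .learners import LearnerLibrary, LearnerSpec, fit_stack, predict_stack

logger = logging.getLogger(__name__)

#: Classifier probabilities are clipped into [eps, 1-eps] before the odds
#: transform; clipping events are logged (practical positivity guard).
PROB_CLIP_EPS = 1e-6


@dataclass
class DensityRatioPanel:
    """Per-period density ratios for one shift policy.

    ``ratios`` is N x T and nonnegative; ``cumulative_products`` holds
    ``w_t = prod_{s<=t} r_s`` recomputed from the (possibly truncated)
    ratios — these are the weights the TMLE targeting step uses.
    """

    ratios: np.ndarray
    truncation_quantile: float | None = None
    truncation_scope: str = "pooled"  # "pooled" | "per-period"
    pre_truncation_mean: float | None = None
    pre_truncation_median: float | None = None
    pre_truncation_max: float | None = None
    truncation_threshold: float | np.ndarray | None = None
    fraction_truncated: float = 0.0

    def __post_init__(self) -> None:
        self.ratios = np.asarray(self.ratios, dtype=float)
        if self.ratios.ndim != 2:
            raise ValueError("ratios must be an N x T matrix")
        if np.any(self.ratios < 0):
            raise ValueError("density ratios must be nonnegative")

    @property
    def n_periods(self) -> int:
        return self.ratios.shape[1]

    @property
    def cumulative_products(self) -> np.ndarray:
        return np.cumprod(self.ratios, axis=1)

    def summary(self) -> pd.DataFrame:
        """Per-period diagnostics: mean, median, max, fraction at cap."""
        rows = []
        for t in range(self.n_periods):
            r = self.ratios[:, t]
            cap = self.truncation_threshold
            if isinstance(cap, np.ndarray):
                cap = cap[t]
            rows.append(
                {
                    "period": t + 1,
                    "mean": float(r.mean()),
                    "median": float(np.median(r)),
                    "max": float(r.max()),
                    "fraction_truncated": float(np.mean(r >= cap)) if cap is not None else 0.0,
                }
            )
        return pd.DataFrame(rows)


def history_features(
    covariates: pd.DataFrame,
    heat_counts: np.ndarray,
    cold_counts: np.ndarray,
    t: int,
    include_current_heat: bool = False,
) -> np.ndarray:
    """Feature matrix for the full history H_t (0-based period t).

    Contains all baseline covariates, cold counts for periods 1..t+1, and
    heat counts for periods 1..t (plus the current period's heat count
    when ``include_current_heat``).
    """
    blocks = [covariates.to_numpy(dtype=float), cold_counts[:, : t + 1]]
    stop = t + 1 if include_current_heat else t
    if stop > 0:
        blocks.append(heat_counts[:, :stop])
    return np.column_stack(blocks)


def _screened_count_glm(n_screened: int) -> LearnerSpec:
    """Parametric candidate tailored to count-valued shift interventions.

    For (near-)Poisson per-period counts the true log density ratio is a
    quadratic in the count with a climatology-dependent slope, so a
    logistic model on the engineered block [a, a^2, a x normals, normals,
    extras] is (close to) correctly specified.  Offered to the stack as a
    screened member — standard SuperLearner practice of including a
    parametric candidate alongside the flexible ones; the meta-weights
    decide whether it is used.
    """

    def make(seed: int):
        select = FunctionTransformer(lambda X: X[:, -n_screened:])
        return make_pipeline(
            select, StandardScaler(), LogisticRegression(max_iter=1000)
        )

    return LearnerSpec("count_glm", lambda seed: None, make)


def _period_aligned_columns(covariates: pd.DataFrame, t: int) -> list[str]:
    """Covariate columns specific to period t+1 (suffix ``_p<period>``)."""
    suffix = f"_p{t + 1}"
    return [c for c in covariates.columns if c.endswith(suffix)]


def estimate_ratios(
    factual: ExposurePanel,
    counterfactual: ExposurePanel,
    covariates: pd.DataFrame,
    library: LearnerLibrary | None = None,
    folds: int = 5,
    seed: int = 0,
    screen_extra_columns: Sequence[str] = ("climate",),
) -> DensityRatioPanel:
    """Estimate per-period density ratios via the classification trick.

    Every stack member receives the full history; in addition the
    feature matrix carries an engineered block — the current count, its
    square, and its interactions with any period-aligned covariates
    (columns suffixed ``_p<period>``, e.g. climatological normals) — and
    the library is augmented with a screened logistic member restricted
    to that block (see :func:`_screened_count_glm`).

    Returns the untruncated panel; apply :func:`truncate` before using
    the ratios as targeting weights.
    """
    if factual.counts.shape != counterfactual.counts.shape:
        raise ValueError("factual and counterfactual panels must be congruent")
    if not np.array_equal(factual.child_ids, counterfactual.child_ids):
        raise ValueError("panels do not cover the same children")
    if factual.n_children != len(covariates):
        raise ValueError("covariate table does not match the panels")
    if library is None:
        library = LearnerLibrary.fast()

    n, n_periods = factual.counts.shape
    ratios = np.empty((n, n_periods), dtype=float)
    labels = np.concatenate([np.zeros(n), np.ones(n)])
    extra = [c for c in screen_extra_columns if c in covariates.columns]
    n_clipped = 0
    for t in range(n_periods):
        hist = history_features(
            covariates, factual.counts, factual.cold_counts, t
        )
        aligned = _period_aligned_columns(covariates, t)
        z = covariates[aligned].to_numpy(dtype=float) if aligned else np.empty((n, 0))
        z_extra = covariates[extra].to_numpy(dtype=float) if extra else np.empty((n, 0))

        def block(a: np.ndarray) -> np.ndarray:
            cols = [hist, a[:, np.newaxis], (a**2)[:, np.newaxis]]
            if z.shape[1]:
                cols += [a[:, np.newaxis] * z, z]
            if z_extra.shape[1]:
                cols.append(z_extra)
            return np.column_stack(cols)

        x_fact = block(factual.counts[:, t].astype(float))
        x_cf = block(counterfactual.counts[:, t].astype(float))
        n_screened = x_fact.shape[1] - hist.shape[1]
        ratio_library = LearnerLibrary(
            tuple(library.members) + (_screened_count_glm(n_screened),),
            name=f"{library.name}+count_glm",
        )
        stack = fit_stack(
            np.vstack([x_fact, x_cf]),
            labels,
            ratio_library,
            folds=folds,
            seed=seed + t,
            task="binary-probability",
        )
        p = predict_stack(stack, x_fact)
        clipped = (p < PROB_CLIP_EPS) | (p > 1 - PROB_CLIP_EPS)
        n_clipped += int(clipped.sum())
        p = np.clip(p, PROB_CLIP_EPS, 1 - PROB_CLIP_EPS)
        ratios[:, t] = p / (1.0 - p)
    if n_clipped:
        logger.warning(
            "density-ratio classifier returned %d probabilities outside "
            "[%.0e, 1-%.0e]; clipped", n_clipped, PROB_CLIP_EPS, PROB_CLIP_EPS,
        )
    return DensityRatioPanel(ratios=ratios)


def truncate(
    panel: DensityRatioPanel,
    quantile: float = 0.999,
    scope: str = "pooled",
) -> DensityRatioPanel:
    """Cap ratios above an empirical quantile (positivity safeguard).

    ``scope="pooled"`` (default) computes one cap over all N x T ratios;
    ``scope="per-period"`` caps each period at its own quantile.
    ``quantile=1.0`` is the identity.  The cap is the largest observed
    ratio at or below the requested quantile (lower order statistic), so
    values are always capped at a ratio that actually occurred.
    """
    if not 0.5 < quantile <= 1.0:
        raise ValueError("truncation quantile must lie in (0.5, 1]")
    if scope not in {"pooled", "per-period"}:
        raise ValueError("scope must be 'pooled' or 'per-period'")
    r = panel.ratios
    pre_mean, pre_median, pre_max = (
        float(r.mean()), float(np.median(r)), float(r.max()),
    )
    if quantile == 1.0:
        capped, threshold = r.copy(), None
    elif scope == "pooled":
        threshold = float(np.quantile(r, quantile, method="lower"))
        capped = np.minimum(r, threshold)
    else:
        threshold = np.quantile(r, quantile, axis=0, method="lower")
        capped = np.minimum(r, threshold[np.newaxis, :])
    return DensityRatioPanel(
        ratios=capped,
        truncation_quantile=quantile,
        truncation_scope=scope,
        pre_truncation_mean=pre_mean,
        pre_truncation_median=pre_median,
        pre_truncation_max=pre_max,
        truncation_threshold=threshold,
        fraction_truncated=float(np.mean(r > capped)),
    )


def identity_ratios(n: int, n_periods: int) -> DensityRatioPanel:
    """All-ones ratios (the natural course / identity shift)."""
    return DensityRatioPanel(ratios=np.ones((n, n_periods)))
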