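"""Synthetic birth cohort with known counterfactual ground truth.

The generator emulates the statistical structure the heat/language
analysis assumes: seasonal daily temperatures with child-level
heterogeneity and AR(1) day-to-day persistence, four enrollment waves
spread over the year (tying each child's 120-week exposure calendar to a
different seasonal phase), ~10 baseline covariates — some correlated with
the enrollment wave, inducing season/covariate confounding — a cold-spike
time-varying confounder derived from the same series, and a vocabulary
score (0..100 words) whose log-scale structural equation is reduced by
per-period heat-spike counts.

Because the structural equation is known, the counterfactual mean outcome
under any additive temperature shift can be computed exactly by Monte
Carlo (:func:`true_policy_mean`), providing the ground truth against
which the TMLE pipeline is validated.  A shift by ``k`` degC moves the
whole daily weather, so overall, daytime, and nighttime indicators all
rise together; the structural outcome responds through heat-spike counts
of the *overall* indicator, making the overall-indicator analysis the
correctly specified one and the other indicators proxies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .exposure import (
    DAYS_PER_PERIOD,
    N_DAYS,
    N_PERIODS,
    DailyTemperatureSeries,
    Indicator,
    ShiftPolicy,
    count_spikes_matrix,
)

#: Per-heat-spike log-score decrement calibrated so that a +3 degC shift
#: lowers the population mean log score by about 0.10 (the order of the
#: reported 3 degC effects); see docs/methods.md.
DEFAULT_GAMMA = 0.008
#: Per-cold-spike log-score decrement (time-varying confounder effect).
DEFAULT_DELTA = 0.006

#: Structural thresholds (degC): population 90th / 10th percentiles of the
#: default overall daily temperature distribution.
DEFAULT_HEAT_THRESHOLD = 20.6
DEFAULT_COLD_THRESHOLD = 3.1

LOG_CEILING = float(np.log(101.0))  # log(score + 1) for a perfect score


def _default_covariate_effects() -> np.ndarray:
    # modest log-scale effects; first three covariates are wave-linked
    return np.array(
        [0.06, -0.05, 0.04, 0.03, -0.03, 0.05, -0.04, 0.02, -0.02, 0.03]
    )


@dataclass
class CohortConfig:
    """Generation parameters for the synthetic cohort.

    Temperature model (degC): ``T_i(d) = seasonal_mean +
    seasonal_amplitude * sin(2*pi*(d + start_i - phase_days)/365) + b_i +
    e_i(d)`` with ``b_i ~ N(0, child_sd^2)`` and ``e_i`` stationary AR(1)
    with lag-one coefficient ``ar_coefficient`` and marginal SD
    ``noise_sd``.  ``start_i`` is the enrollment-wave day-of-year plus a
    small jitter.

    Outcome model (log scale): ``L_i = alpha0 + W_i @ covariate_effects
    - sum_t period_effects[t] * A_it - sum_t cold_effects[t] * C_it +
    eps_i`` with ``eps_i ~ N(0, outcome_noise_sd^2)``; the integer word
    score is ``clip(round(exp(L_i) - 1), 0, 100)`` and the analysed
    outcome is ``log(score + 1)``.  ``A_it`` / ``C_it`` are heat / cold
    spike counts of the overall indicator at the structural thresholds.
    """

    n_children: int = 2000
    seed: int = 0
    seasonal_mean: float = 11.83
    seasonal_amplitude: float = 8.0
    phase_days: int = 91  # sine peak at day ~182 of year (early July)
    child_sd: float = 0.3
    ar_coefficient: float = 0.7
    noise_sd: float = 3.5
    n_covariates: int = 10
    covariate_effects: np.ndarray = field(default_factory=_default_covariate_effects)
    period_effects: np.ndarray = field(
        default_factory=lambda: np.full(N_PERIODS, DEFAULT_GAMMA)
    )
    cold_effects: np.ndarray = field(
        default_factory=lambda: np.full(N_PERIODS, DEFAULT_DELTA)
    )
    confounding_strength: float = 0.5
    outcome_noise_sd: float = 0.2
    alpha0: float = 4.35
    heat_threshold: float = DEFAULT_HEAT_THRESHOLD
    cold_threshold: float = DEFAULT_COLD_THRESHOLD
    min_run: int = 2
    day_offset: float = 6.0   # daytime = overall + offset (+- jitter)
    night_offset: float = 5.5  # nighttime = overall - offset (+- jitter)
    outcome_floor: int = 0
    outcome_ceiling: int = 100

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be >= 1")
        if not 0 <= self.ar_coefficient < 1:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.noise_sd < 0 or self.child_sd < 0 or self.outcome_noise_sd < 0:
            raise ValueError("standard deviations must be nonnegative")
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        if self.covariate_effects.shape[0] != self.n_covariates:
            raise ValueError("covariate_effects length must equal n_covariates")
        self.period_effects = np.asarray(self.period_effects, dtype=float)
        self.cold_effects = np.asarray(self.cold_effects, dtype=float)
        if self.period_effects.shape[0] != N_PERIODS:
            raise ValueError(f"period_effects must have length {N_PERIODS}")
        if self.cold_effects.shape[0] != N_PERIODS:
            raise ValueError(f"cold_effects must have length {N_PERIODS}")


#: Enrollment-wave start days of year ("four periods throughout the year").
WAVE_STARTS = np.array([15, 106, 197, 288])


@dataclass
class SyntheticCohort:
    """A generated cohort: temperatures, covariates, and outcomes."""

    config: CohortConfig
    child_ids: np.ndarray
    overall: np.ndarray      # N x 840 daily mean temperature
    daytime: np.ndarray      # N x 840 daily maximum temperature
    nighttime: np.ndarray    # N x 840 daily minimum temperature
    covariates: pd.DataFrame
    wave: np.ndarray         # enrollment wave index 0..3 (not a covariate)
    heat_counts: np.ndarray  # structural N x 12 heat-spike counts
    cold_counts: np.ndarray  # structural N x 12 cold-spike counts
    score: np.ndarray        # integer word score 0..100
    log_outcome: np.ndarray  # log(score + 1), the analysed outcome

    @property
    def n_children(self) -> int:
        return self.child_ids.shape[0]

    def temperatures(self, indicator: Indicator | str) -> np.ndarray:
        indicator = Indicator(indicator)
        return {
            Indicator.OVERALL: self.overall,
            Indicator.DAYTIME: self.daytime,
            Indicator.NIGHTTIME: self.nighttime,
        }[indicator]

    def series(self, indicator: Indicator | str) -> list[DailyTemperatureSeries]:
        indicator = Indicator(indicator)
        temps = self.temperatures(indicator)
        return [
            DailyTemperatureSeries(cid, indicator, temps[i])
            for i, cid in enumerate(self.child_ids)
        ]

    def write_csvs(self, out_dir) -> dict[str, Path]:
        """Write temperature / covariate / outcome CSVs (the dialects the
        exposure module reads)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        n = self.n_children
        temps = pd.DataFrame(
            {
                "child_id": np.repeat(self.child_ids, N_DAYS),
                "day": np.tile(np.arange(1, N_DAYS + 1), n),
                "tmean": self.overall.ravel(),
                "tmax": self.daytime.ravel(),
                "tmin": self.nighttime.ravel(),
            }
        )
        paths = {
            "temperatures": out / "temperatures.csv",
            "covariates": out / "covariates.csv",
            "outcomes": out / "outcomes.csv",
        }
        temps.to_csv(paths["temperatures"], index=False, float_format="%.3f")
        cov = self.covariates.copy()
        cov.insert(0, "child_id", self.child_ids)
        cov.to_csv(paths["covariates"], index=False, float_format="%.5f")
        pd.DataFrame(
            {
                "child_id": self.child_ids,
                "score": self.score,
                "log_score": self.log_outcome,
            }
        ).to_csv(paths["outcomes"], index=False, float_format="%.6f")
        return paths


def _simulate_weather(
    config: CohortConfig, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Overall daily temperatures (n x 840), waves, start days, intercepts."""
    wave = rng.integers(0, 4, size=n)
    # conception day: wave start plus gestational/recruitment spread
    start = WAVE_STARTS[wave] + rng.integers(-21, 22, size=n)
    b = rng.normal(0.0, config.child_sd, size=n)
    days = np.arange(1, N_DAYS + 1)
    seasonal = config.seasonal_mean + config.seasonal_amplitude * np.sin(
        2 * np.pi * (days[np.newaxis, :] + start[:, np.newaxis] - config.phase_days)
        / 365.0
    )
    rho = config.ar_coefficient
    innov_sd = config.noise_sd * np.sqrt(1.0 - rho**2)
    innov = rng.normal(0.0, innov_sd, size=(n, N_DAYS))
    innov[:, 0] = rng.normal(0.0, config.noise_sd, size=n)  # stationary start
    ar = lfilter([1.0], [1.0, -rho], innov, axis=1)
    return seasonal + b[:, np.newaxis] + ar, wave, start, b


def _simulate_covariates(
    config: CohortConfig,
    wave: np.ndarray,
    start: np.ndarray,
    climate: np.ndarray,
    rng: np.random.Generator,
) -> pd.DataFrame:
    n = wave.shape[0]
    wave_score = (wave - 1.5) / 1.5  # centered, in [-1, 1]
    cols = {}
    for j in range(config.n_covariates):
        name = f"w{j}"
        if j == 0:
            cols[name] = rng.binomial(1, 0.51, size=n).astype(float)  # child sex
        elif j < 4:
            # wave-linked covariates: the season/covariate confounding channel
            shift = config.confounding_strength * wave_score * (1.0 if j % 2 else -1.0)
            cols[name] = rng.normal(shift, 1.0, size=n)
        elif j == 4:
            cols[name] = rng.binomial(1, 0.3, size=n).astype(float)
        else:
            cols[name] = rng.normal(0.0, 1.0, size=n)
    # Measured design/climate covariates (known in a birth cohort): season
    # of conception and the child's local climate offset.  These drive the
    # exposure process across all periods, so conditioning on them is what
    # makes sequential exchangeability hold for the analysis.
    angle = 2 * np.pi * (start - config.phase_days) / 365.0
    cols["conception_sin"] = np.sin(angle)
    cols["conception_cos"] = np.cos(angle)
    cols["climate"] = climate
    # Climatological normals of the child's exposure calendar: the expected
    # number of hot (> heat_threshold) days in each 10-week period given
    # the conception date and local climate offset, computed from the
    # seasonal weather model (the analogue of exceedance frequencies from
    # station normals).  Adjusting for the exposure calendar's climatology
    # is what renders the remaining spike variation quasi-random given
    # measured covariates.  Cold-day normals are omitted: they are close
    # to deterministic functions of the heat normals (both are smooth
    # transforms of the same phase) and add collinearity, not information.
    days = np.arange(1, N_DAYS + 1)
    seasonal = (
        config.seasonal_mean
        + climate[:, np.newaxis]
        + config.seasonal_amplitude
        * np.sin(
            2 * np.pi
            * (days[np.newaxis, :] + start[:, np.newaxis] - config.phase_days)
            / 365.0
        )
    )
    z_hot = (seasonal - config.heat_threshold) / config.noise_sd
    hot_norm = _std_normal_cdf(z_hot).reshape(n, N_PERIODS, DAYS_PER_PERIOD).sum(axis=2)
    for t in range(N_PERIODS):
        cols[f"heat_norm_p{t + 1}"] = hot_norm[:, t]
    return pd.DataFrame(cols)


def _std_normal_cdf(z: np.ndarray) -> np.ndarray:
    from scipy.special import ndtr

    return ndtr(z)


def _structural_log_outcome(
    config: CohortConfig,
    covariates: np.ndarray,
    heat_counts: np.ndarray,
    cold_counts: np.ndarray,
    eps: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Latent log score -> (integer word score, analysed log outcome).

    Only the first ``n_covariates`` columns (the W block) carry direct
    outcome effects; the appended design/climate covariates act on the
    outcome solely through the exposure process.
    """
    latent = (
        config.alpha0
        + covariates[:, : config.n_covariates] @ config.covariate_effects
        - heat_counts @ config.period_effects
        - cold_counts @ config.cold_effects
        + eps
    )
    score = np.clip(
        np.rint(np.exp(latent) - 1.0), config.outcome_floor, config.outcome_ceiling
    ).astype(int)
    return score, np.log(score + 1.0)


def _structural_counts(
    config: CohortConfig, overall: np.ndarray, k: float = 0.0
) -> tuple[np.ndarray, np.ndarray]:
    """Heat counts under a +k shift; cold counts always factual."""
    heat = count_spikes_matrix(
        overall + k, config.heat_threshold, config.min_run, "above"
    )
    cold = count_spikes_matrix(
        overall, config.cold_threshold, config.min_run, "below"
    )
    return heat, cold


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a full cohort; identical config and seed give identical data."""
    rng = np.random.default_rng(config.seed)
    n = config.n_children
    overall, wave, start, climate = _simulate_weather(config, n, rng)
    day_jit = rng.normal(0.0, 0.5, size=n)
    night_jit = rng.normal(0.0, 0.5, size=n)
    daytime = (
        overall
        + (config.day_offset + day_jit)[:, np.newaxis]
        + rng.normal(0.0, 0.8, size=(n, N_DAYS))
    )
    nighttime = (
        overall
        - (config.night_offset + night_jit)[:, np.newaxis]
        + rng.normal(0.0, 0.8, size=(n, N_DAYS))
    )
    covariates = _simulate_covariates(config, wave, start, climate, rng)
    heat, cold = _structural_counts(config, overall)
    eps = rng.normal(0.0, config.outcome_noise_sd, size=n)
    score, log_outcome = _structural_log_outcome(
        config, covariates.to_numpy(), heat, cold, eps
    )
    return SyntheticCohort(
        config=config,
        child_ids=np.arange(1, n + 1),
        overall=overall,
        daytime=daytime,
        nighttime=nighttime,
        covariates=covariates,
        wave=wave,
        heat_counts=heat,
        cold_counts=cold,
        score=score,
        log_outcome=log_outcome,
    )


@dataclass(frozen=True)
class PolicyTruth:
    """Monte-Carlo ground truth for a shift policy on a cohort config."""

    policy: ShiftPolicy
    true_counterfactual_mean: float
    true_natural_mean: float
    true_theta: float
    mc_replicates: int
    mc_standard_error: float


def true_policy_mean(
    config: CohortConfig,
    policy: ShiftPolicy,
    mc_replicates: int = 200_000,
    batch_size: int = 20_000,
    tol: float | None = None,
) -> PolicyTruth:
    """Exact (up to Monte-Carlo error) counterfactual mean under a shift.

    Simulates fresh children from the structural model, applies the
    ``k``-degree shift to the daily weather, recomputes structural spike
    counts, and evaluates the structural outcome equation — never the
    estimator.  Factual and counterfactual outcomes share the same noise
    draws, so ``mc_standard_error`` (for theta) reflects only the paired
    difference.  The shift moves the whole weather, so the truth depends
    on the policy only through ``k``.
    """
    if mc_replicates < 1:
        raise ValueError("mc_replicates must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x7A57]))
    sum_cf = sum_nat = sum_sq_diff = sum_diff = 0.0
    done = 0
    while done < mc_replicates:
        m = min(batch_size, mc_replicates - done)
        overall, wave, start, climate = _simulate_weather(config, m, rng)
        covariates = _simulate_covariates(config, wave, start, climate, rng).to_numpy()
        eps = rng.normal(0.0, config.outcome_noise_sd, size=m)
        heat_f, cold = _structural_counts(config, overall, k=0.0)
        heat_cf, _ = _structural_counts(config, overall, k=policy.k)
        _, y_nat = _structural_log_outcome(config, covariates, heat_f, cold, eps)
        _, y_cf = _structural_log_outcome(config, covariates, heat_cf, cold, eps)
        diff = y_cf - y_nat
        sum_cf += y_cf.sum()
        sum_nat += y_nat.sum()
        sum_diff += diff.sum()
        sum_sq_diff += (diff**2).sum()
        done += m
    mean_cf = sum_cf / done
    mean_nat = sum_nat / done
    theta = sum_diff / done
    var_diff = max(sum_sq_diff / done - theta**2, 0.0)
    mc_se = float(np.sqrt(var_diff / done))
    if tol is not None and mc_se > tol:
        raise ValueError(
            f"Monte-Carlo SE {mc_se:.2e} exceeds requested tolerance "
            f"{tol:.2e} at {done} replicates"
        )
    return PolicyTruth(
        policy=policy,
        true_counterfactual_mean=float(mean_cf),
        true_natural_mean=float(mean_nat),
        true_theta=float(theta),
        mc_replicates=done,
        mc_standard_error=mc_se,
    )


def write_config(config: CohortConfig, path) -> None:
    """Flat key=value text serialisation of a cohort config."""
    lines = []
    for key, value in vars(config).items():
        if isinstance(value, np.ndarray):
            value = ",".join(f"{v:g}" for v in value)
        lines.append(f"{key} = {value}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path) -> CohortConfig:
    """Parse the flat key=value config dialect written by write_config."""
    fields = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        if key in {"covariate_effects", "period_effects", "cold_effects"}:
            fields[key] = np.array([float(v) for v in value.split(",")])
        elif key in {
            "n_children", "seed", "phase_days", "n_covariates", "min_run",
            "outcome_floor", "outcome_ceiling",
        }:
            fields[key] = int(value)
        else:
            fields[key] = float(value)
    return CohortConfig(**fields)
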