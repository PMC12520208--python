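"""Heat-spike exposure construction from daily temperature series.

The exposure calendar spans 120 weeks (30 prenatal gestation weeks plus 90
postnatal weeks), concatenated into 840 daily values and partitioned into
12 consecutive 10-week (70-day) periods.  Within each period the exposure
is the number of *heat spikes*: maximal runs of at least ``min_run``
consecutive days with the daily temperature strictly above a high
percentile threshold.  A mirrored low-threshold count ("cold spikes")
serves as a time-varying confounder.

Counterfactual exposures arise from additive shift interventions
``d(Temp, k) = Temp + k`` applied to every daily value; the cold-spike
confounder is always computed from the factual (unshifted) series because
the hypothetical intervention modifies heat exposure only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: Exposure calendar: 12 periods x 10 weeks x 7 days.
N_PERIODS = 12
DAYS_PER_PERIOD = 70
N_DAYS = N_PERIODS * DAYS_PER_PERIOD  # 840
N_WEEKS = N_DAYS // 7  # 120


class Indicator(str, Enum):
    """Daily temperature indicator (proxy for time-of-day exposure)."""

    OVERALL = "overall"    # daily mean temperature
    DAYTIME = "daytime"    # daily maximum temperature
    NIGHTTIME = "nighttime"  # daily minimum temperature


class Direction(str, Enum):
    ABOVE = "above"
    BELOW = "below"


@dataclass(frozen=True)
class DailyTemperatureSeries:
    """One child's daily temperatures for a single indicator.

    ``values[d]`` is the temperature (degC) on calendar day ``d + 1``;
    days 1..210 are prenatal (gestation weeks 1-30) and days 211..840
    postnatal (weeks 1-90).
    """

    child_id: object
    indicator: Indicator
    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1:
            raise ValueError("temperature values must be a 1-d sequence")
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"non-finite temperature values for child {self.child_id!r}"
            )
        object.__setattr__(self, "values", vals)

    @property
    def n_days(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ShiftPolicy:
    """An additive temperature-shift intervention and its spike definition.

    Parameters
    ----------
    k
        Additive shift in degC applied to every daily value; ``k=0`` is the
        natural course.  Restricted to ``|k| <= 5`` so that the shifted
        exposure distribution stays within the support of the factual one
        (the positivity rationale for modified treatment policies).
    indicator
        Which daily indicator the spikes are counted on.
    threshold_percentile
        Percentile of the pooled daily distribution defining a hot (or
        cold) day; the study grid uses 0.80 / 0.85 / 0.90.
    min_run
        Minimum number of consecutive qualifying days for a spike.
    threshold_value
        Resolved threshold in degC.  May be supplied directly (e.g. the
        cohort values 20.6 / 27.5 / 15.3 degC for overall / daytime /
        nighttime at the 90th percentile) or resolved from pooled data
        with :func:`resolve_threshold`.
    direction
        ``above`` for heat spikes, ``below`` for the cold confounder.
    """

    k: float = 0.0
    indicator: Indicator = Indicator.OVERALL
    threshold_percentile: float = 0.90
    min_run: int = 2
    threshold_value: float | None = None
    direction: Direction = Direction.ABOVE

    def __post_init__(self) -> None:
        if not 0 < self.threshold_percentile < 1:
            raise ValueError("threshold_percentile must lie in (0, 1)")
        if self.min_run < 1:
            raise ValueError("min_run must be >= 1")
        if abs(self.k) > 5:
            raise ValueError(
                "|k| > 5 degC is outside the declared plausible range for "
                "shift interventions (positivity guard)"
            )

    def resolved(self, pooled_values: np.ndarray) -> "ShiftPolicy":
        """Return a copy with ``threshold_value`` resolved from pooled data."""
        if self.threshold_value is not None:
            return self
        pct = self.threshold_percentile
        if self.direction is Direction.BELOW:
            pct = 1.0 - pct
        return replace(self, threshold_value=resolve_threshold(pooled_values, pct))


@dataclass
class ExposurePanel:
    """Per-period spike counts for a cohort under one exposure regime.

    ``counts`` is the N x T heat-spike matrix produced under ``policy``
    (shifted temperatures if ``policy.k != 0``); ``cold_counts`` is the
    N x T cold-spike confounder matrix, always from factual temperatures.
    """

    child_ids: np.ndarray
    counts: np.ndarray
    cold_counts: np.ndarray
    policy: ShiftPolicy
    provenance: str  # "factual" | "counterfactual"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.cold_counts = np.asarray(self.cold_counts, dtype=int)
        if self.counts.shape != self.cold_counts.shape:
            raise ValueError("heat and cold count matrices must share a shape")
        if np.any(self.counts < 0) or np.any(self.cold_counts < 0):
            raise ValueError("spike counts must be nonnegative")

    @property
    def n_children(self) -> int:
        return self.counts.shape[0]

    @property
    def n_periods(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Long-format CSV-ready table, one row per child-period."""
        n, t = self.counts.shape
        return pd.DataFrame(
            {
                "child_id": np.repeat(self.child_ids, t),
                "period": np.tile(np.arange(1, t + 1), n),
                "heat_spikes": self.counts.ravel(),
                "cold_spikes": self.cold_counts.ravel(),
                "provenance": self.provenance,
                "k": self.policy.k,
                "threshold": self.policy.threshold_value,
            }
        )


def resolve_threshold(pooled_daily_values: Sequence[float], percentile: float) -> float:
    """Empirical percentile of the pooled daily temperature distribution.

    Uses linear interpolation between closest order statistics (numpy's
    default quantile convention), fixed for reproducibility.
    """
    values = np.asarray(pooled_daily_values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot resolve a threshold from no data")
    if not np.all(np.isfinite(values)):
        raise ValueError("pooled temperatures contain non-finite values")
    if not 0 < percentile < 1:
        raise ValueError("percentile must lie in (0, 1)")
    return float(np.quantile(values, percentile, method="linear"))


def apply_shift(series: DailyTemperatureSeries, k: float) -> DailyTemperatureSeries:
    """Shift every daily value by ``k`` degC (the intervention d(Temp,k))."""
    if k == 0:
        return series
    return replace(series, values=series.values + float(k))


def count_spikes(
    series: DailyTemperatureSeries,
    threshold: float,
    min_run: int = 2,
    direction: Direction | str = Direction.ABOVE,
) -> np.ndarray:
    """Count spikes per 10-week period for one child.

    A spike is one maximal run of at least ``min_run`` consecutive days
    strictly above (``direction="above"``) or strictly below
    (``direction="below"``) the threshold.  Runs are evaluated within each
    70-day period independently: a run straddling a period boundary counts
    toward a period only if its within-period segment reaches ``min_run``
    days.  Returns an integer vector of length 12.
    """
    if series.n_days != N_DAYS:
        raise ValueError(
            f"expected a {N_DAYS}-day series (120 weeks), got {series.n_days} days"
        )
    return count_spikes_matrix(
        series.values[np.newaxis, :], threshold, min_run, direction
    )[0]


def count_spikes_matrix(
    values: np.ndarray,
    threshold: float,
    min_run: int = 2,
    direction: Direction | str = Direction.ABOVE,
) -> np.ndarray:
    """Vectorised spike counting for an N x 840 matrix of daily values.

    Returns an N x 12 integer matrix.  Semantics are identical to
    :func:`count_spikes` applied row by row.
    """
    direction = Direction(direction)
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] != N_DAYS:
        raise ValueError(
            f"expected an N x {N_DAYS} matrix, got shape {values.shape}"
        )
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    if direction is Direction.ABOVE:
        qual = values > threshold
    else:
        qual = values < threshold
    n = values.shape[0]
    blocks = qual.reshape(n, N_PERIODS, DAYS_PER_PERIOD)
    # run starts: qualifying day not preceded (within the block) by one
    prev = np.concatenate(
        [np.zeros((n, N_PERIODS, 1), dtype=bool), blocks[:, :, :-1]], axis=2
    )
    starts = blocks & ~prev
    if min_run == 1:
        return starts.sum(axis=2)
    # a start at day j begins a run of >= min_run iff the window sum of the
    # next min_run days equals min_run; starts too close to the block end
    # cannot reach min_run within the period and never qualify
    csum = np.concatenate(
        [
            np.zeros((n, N_PERIODS, 1), dtype=int),
            np.cumsum(blocks.astype(int), axis=2),
        ],
        axis=2,
    )
    win = csum[:, :, min_run:] - csum[:, :, : DAYS_PER_PERIOD - min_run + 1]
    long_enough = win == min_run
    return np.sum(
        starts[:, :, : DAYS_PER_PERIOD - min_run + 1] & long_enough, axis=2
    ).astype(int)


def build_exposure_panel(
    all_series: Iterable[DailyTemperatureSeries],
    policy: ShiftPolicy,
    cold_policy: ShiftPolicy,
) -> ExposurePanel:
    """Build the N x 12 exposure panel for a cohort under one policy.

    Heat spikes are counted on the ``policy.k``-shifted series at
    ``policy.threshold_value``; cold spikes always on the factual series
    (the intervention leaves the confounder's cause untouched).  Both
    policies must carry resolved threshold values.
    """
    if policy.threshold_value is None or cold_policy.threshold_value is None:
        raise ValueError("policies must carry resolved threshold values")
    if cold_policy.direction is not Direction.BELOW:
        raise ValueError("cold_policy must use direction='below'")

    ids, heat_rows, cold_rows = [], [], []
    for series in all_series:
        if series.n_days != N_DAYS:
            raise ValueError(
                f"child {series.child_id!r}: expected {N_DAYS}-day series, "
                f"got {series.n_days}"
            )
        shifted = apply_shift(series, policy.k)
        heat_rows.append(
            count_spikes(
                shifted, policy.threshold_value, policy.min_run, Direction.ABOVE
            )
        )
        cold_rows.append(
            count_spikes(
                series, cold_policy.threshold_value, cold_policy.min_run,
                Direction.BELOW,
            )
        )
        ids.append(series.child_id)
    if not ids:
        raise ValueError("no temperature series supplied")
    return ExposurePanel(
        child_ids=np.asarray(ids),
        counts=np.vstack(heat_rows),
        cold_counts=np.vstack(cold_rows),
        policy=policy,
        provenance="factual" if policy.k == 0 else "counterfactual",
    )


def read_temperature_csv(path) -> dict[Indicator, list[DailyTemperatureSeries]]:
    """Read a long-format daily temperature CSV.

    Expected columns: ``child_id, day, tmean, tmax, tmin`` with 1-based
    day indices.  Returns one list of series per indicator, each sorted by
    child id with days in calendar order.
    """
    df = pd.read_csv(path)
    required = {"child_id", "day", "tmean", "tmax", "tmin"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"temperature CSV missing columns: {sorted(missing)}")
    col_for = {
        Indicator.OVERALL: "tmean",
        Indicator.DAYTIME: "tmax",
        Indicator.NIGHTTIME: "tmin",
    }
    out: dict[Indicator, list[DailyTemperatureSeries]] = {i: [] for i in col_for}
    for child_id, grp in df.sort_values(["child_id", "day"]).groupby(
        "child_id", sort=True
    ):
        days = grp["day"].to_numpy()
        if days[0] != 1 or np.any(np.diff(days) != 1):
            raise ValueError(
                f"child {child_id!r}: day index must run 1..D without gaps"
            )
        for ind, col in col_for.items():
            out[ind].append(
                DailyTemperatureSeries(
                    child_id=child_id,
                    indicator=ind,
                    values=grp[col].to_numpy(dtype=float),
                )
            )
    return out


def write_exposure_csv(panel: ExposurePanel, path) -> None:
    panel.to_frame().to_csv(path, index=False)
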