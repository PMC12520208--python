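import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heatlmtp.exposure import (
    N_DAYS,
    N_PERIODS,
    DailyTemperatureSeries,
    Direction,
    ExposurePanel,
    Indicator,
    ShiftPolicy,
    apply_shift,
    build_exposure_panel,
    count_spikes,
    count_spikes_matrix,
    read_temperature_csv,
    resolve_threshold,
    write_exposure_csv,
)

from conftest import brute_force_spike_counts


def make_series(values, child_id="c1"):
    return DailyTemperatureSeries(child_id, Indicator.OVERALL, np.asarray(values, float))


class TestResolveThreshold:
    def test_degenerate_distribution(self):
        assert resolve_threshold([12.0] * 100, 0.9) == 12.0

    def test_linear_interpolation_matches_order_statistic_oracle(self):
        values = np.arange(1.0, 11.0)
        # sort-and-interpolate oracle: position q*(n-1) between order stats
        pos = 0.9 * 9
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        expected = values[lo] + (pos - lo) * (values[hi] - values[lo])
        assert resolve_threshold(values, 0.9) == pytest.approx(expected)
        assert expected == pytest.approx(9.1)

    @pytest.mark.parametrize("bad", [[], [1.0, np.nan], [np.inf]])
    def test_rejects_empty_or_nonfinite(self, bad):
        with pytest.raises(ValueError):
            resolve_threshold(bad, 0.9)

    def test_rejects_percentile_outside_unit_interval(self):
        with pytest.raises(ValueError):
            resolve_threshold([1.0, 2.0], 1.5)


class TestApplyShift:
    def test_zero_shift_is_identity(self):
        s = make_series(np.linspace(0, 30, N_DAYS))
        assert apply_shift(s, 0.0) is s

    @pytest.mark.parametrize("k", [1.0, 2.0, 3.0])
    def test_adds_k_to_every_day(self, k):
        s = make_series(np.linspace(0, 30, N_DAYS))
        np.testing.assert_allclose(apply_shift(s, k).values, s.values + k)

    def test_threshold_translation_symmetry(self):
        rng = np.random.default_rng(3)
        s = make_series(rng.normal(12, 6, N_DAYS))
        tau, k = 18.0, 2.0
        shifted = apply_shift(s, k)
        np.testing.assert_array_equal(
            count_spikes(shifted, tau, 2), count_spikes(s, tau - k, 2)
        )


class TestCountSpikes:
    def test_all_below_threshold_gives_zeros(self):
        s = make_series(np.full(N_DAYS, 5.0))
        np.testing.assert_array_equal(count_spikes(s, 10.0, 2), np.zeros(12))

    def test_isolated_hot_day_is_not_a_spike(self):
        values = np.full(N_DAYS, 5.0)
        values[30] = 25.0
        s = make_series(values)
        np.testing.assert_array_equal(count_spikes(s, 10.0, 2), np.zeros(12))

    def test_two_consecutive_hot_days_are_one_spike(self):
        values = np.full(N_DAYS, 5.0)
        values[30:32] = 25.0  # one run of 2 in period 1
        values[100:110] = 25.0  # one long run in period 2
        s = make_series(values)
        expected = np.zeros(12, int)
        expected[0] = expected[1] = 1
        np.testing.assert_array_equal(count_spikes(s, 10.0, 2), expected)

    def test_run_straddling_boundary_needs_min_run_within_each_period(self):
        values = np.full(N_DAYS, 5.0)
        values[69:71] = 25.0  # last day of period 1 + first day of period 2
        s = make_series(values)
        np.testing.assert_array_equal(count_spikes(s, 10.0, 2), np.zeros(12))
        values[68:72] = 25.0  # two days on each side
        s = make_series(values)
        expected = np.zeros(12, int)
        expected[0] = expected[1] = 1
        np.testing.assert_array_equal(count_spikes(s, 10.0, 2), expected)

    def test_exceedance_is_strict(self):
        values = np.full(N_DAYS, 10.0)
        s = make_series(values)
        np.testing.assert_array_equal(count_spikes(s, 10.0, 2), np.zeros(12))

    def test_wrong_length_raises_and_names_840(self):
        with pytest.raises(ValueError, match="840"):
            count_spikes(make_series(np.zeros(100)), 1.0, 2)

    @pytest.mark.parametrize("min_run", [1, 2, 3])
    @pytest.mark.parametrize("direction", ["above", "below"])
    def test_agrees_with_brute_force_oracle(self, min_run, direction):
        rng = np.random.default_rng(42 + min_run)
        for _ in range(25):
            values = rng.normal(10, 5, N_DAYS)
            s = make_series(values)
            np.testing.assert_array_equal(
                count_spikes(s, 10.0, min_run, direction),
                brute_force_spike_counts(values, 10.0, min_run, direction),
            )

    def test_matrix_version_matches_per_row(self):
        rng = np.random.default_rng(5)
        mat = rng.normal(10, 5, (8, N_DAYS))
        out = count_spikes_matrix(mat, 11.0, 2)
        for i in range(8):
            np.testing.assert_array_equal(
                out[i], count_spikes(make_series(mat[i]), 11.0, 2)
            )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_joint_shift_of_k_and_threshold(self, seed):
        rng = np.random.default_rng(seed)
        values = rng.normal(10, 6, N_DAYS)
        s = make_series(values)
        delta = float(rng.uniform(0.1, 3.0))
        base = count_spikes(apply_shift(s, 1.0), 15.0, 2)
        moved = count_spikes(apply_shift(s, 1.0 + delta), 15.0 + delta, 2)
        np.testing.assert_array_equal(base, moved)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_positive_shift_preserves_spike_presence(self, seed):
        # warming can merge adjacent runs (so per-period counts may drop),
        # but every factual run remains inside some counterfactual run:
        # a period with a spike keeps at least one spike after warming
        rng = np.random.default_rng(seed)
        s = make_series(rng.normal(10, 6, N_DAYS))
        factual = count_spikes(s, 15.0, 2)
        shifted = count_spikes(apply_shift(s, 2.0), 15.0, 2)
        assert np.all(shifted[factual >= 1] >= 1)
        assert np.all(shifted <= 70 // 2)

    def test_count_bound_floor_70_over_min_run(self):
        # alternating hot/cold pairs maximise run count
        values = np.tile(np.repeat([25.0, 5.0], 2), N_DAYS // 4 + 1)[:N_DAYS]
        counts = count_spikes(make_series(values), 10.0, 2)
        assert counts.max() <= 70 // 2


class TestShiftPolicy:
    def test_rejects_extreme_shift(self):
        with pytest.raises(ValueError, match="plausible"):
            ShiftPolicy(k=6.0)

    def test_rejects_bad_percentile_and_min_run(self):
        with pytest.raises(ValueError):
            ShiftPolicy(threshold_percentile=0.0)
        with pytest.raises(ValueError):
            ShiftPolicy(min_run=0)

    def test_resolved_fills_threshold_from_pooled_data(self):
        pol = ShiftPolicy(threshold_percentile=0.9).resolved(np.arange(1.0, 11.0))
        assert pol.threshold_value == pytest.approx(9.1)
        cold = ShiftPolicy(
            threshold_percentile=0.9, direction=Direction.BELOW
        ).resolved(np.arange(1.0, 11.0))
        assert cold.threshold_value == pytest.approx(1.9)  # mirrored tail


class TestBuildExposurePanel:
    def _toy_series(self):
        base = np.full(N_DAYS, 10.0)
        a = base.copy(); a[0:3] = 25.0            # one heat spike, period 1
        b = base.copy(); b[70:72] = 25.0; b[140:142] = -5.0
        c = base.copy()                            # nothing
        return [make_series(a, "a"), make_series(b, "b"), make_series(c, "c")]

    def test_hand_computed_counts(self):
        policy = ShiftPolicy(k=0.0, threshold_value=20.0)
        cold = ShiftPolicy(k=0.0, threshold_value=0.0, direction=Direction.BELOW)
        panel = build_exposure_panel(self._toy_series(), policy, cold)
        expected_heat = np.zeros((3, 12), int)
        expected_heat[0, 0] = 1
        expected_heat[1, 1] = 1
        expected_cold = np.zeros((3, 12), int)
        expected_cold[1, 2] = 1
        np.testing.assert_array_equal(panel.counts, expected_heat)
        np.testing.assert_array_equal(panel.cold_counts, expected_cold)
        assert panel.provenance == "factual"

    def test_zero_shift_panel_equals_counterfactual_panel(self):
        series = self._toy_series()
        cold = ShiftPolicy(k=0.0, threshold_value=0.0, direction=Direction.BELOW)
        factual = build_exposure_panel(
            series, ShiftPolicy(k=0.0, threshold_value=20.0), cold
        )
        null_cf = build_exposure_panel(
            series, ShiftPolicy(k=0.0, threshold_value=20.0), cold
        )
        np.testing.assert_array_equal(factual.counts, null_cf.counts)

    def test_cold_counts_come_from_unshifted_series(self):
        series = self._toy_series()
        cold = ShiftPolicy(k=0.0, threshold_value=0.0, direction=Direction.BELOW)
        shifted = build_exposure_panel(
            series, ShiftPolicy(k=3.0, threshold_value=20.0), cold
        )
        factual = build_exposure_panel(
            series, ShiftPolicy(k=0.0, threshold_value=20.0), cold
        )
        np.testing.assert_array_equal(shifted.cold_counts, factual.cold_counts)
        assert shifted.provenance == "counterfactual"

    def test_requires_resolved_thresholds_and_cold_direction(self):
        series = self._toy_series()
        with pytest.raises(ValueError, match="resolved"):
            build_exposure_panel(series, ShiftPolicy(), ShiftPolicy(direction="below"))
        with pytest.raises(ValueError, match="below"):
            build_exposure_panel(
                series,
                ShiftPolicy(threshold_value=20.0),
                ShiftPolicy(threshold_value=0.0),
            )


class TestCsvRoundTrip:
    def test_temperature_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        n = 3
        df = pd.DataFrame(
            {
                "child_id": np.repeat([f"c{i}" for i in range(n)], N_DAYS),
                "day": np.tile(np.arange(1, N_DAYS + 1), n),
                "tmean": rng.normal(12, 6, n * N_DAYS),
                "tmax": rng.normal(18, 6, n * N_DAYS),
                "tmin": rng.normal(7, 6, n * N_DAYS),
            }
        )
        path = tmp_path / "temps.csv"
        df.to_csv(path, index=False)
        series = read_temperature_csv(path)
        assert {s.child_id for s in series[Indicator.OVERALL]} == {"c0", "c1", "c2"}
        got = next(s for s in series[Indicator.NIGHTTIME] if s.child_id == "c1")
        np.testing.assert_allclose(
            got.values, df.loc[df.child_id == "c1", "tmin"].to_numpy()
        )

    def test_exposure_csv_has_declared_columns(self, tmp_path):
        policy = ShiftPolicy(k=1.0, threshold_value=20.0)
        panel = ExposurePanel(
            child_ids=np.array(["a", "b"]),
            counts=np.ones((2, 12), int),
            cold_counts=np.zeros((2, 12), int),
            policy=policy,
            provenance="counterfactual",
        )
        path = tmp_path / "panel.csv"
        write_exposure_csv(panel, path)
        back = pd.read_csv(path)
        assert list(back.columns) == [
            "child_id", "period", "heat_spikes", "cold_spikes",
            "provenance", "k", "threshold",
        ]
        assert len(back) == 24
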