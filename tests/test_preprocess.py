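import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import mirnadx as mx
from mirnadx.preprocess import (
    call_present_and_subtract,
    floor_undetected,
    negative_control_stats,
    quantile_normalize,
)
from mirnadx.types import NegativeControlStats, RawArrayCollection


class TestNegativeControlStats:
    def test_constant_signals_zero_variance(self):
        s = negative_control_stats(np.full(20, 100.0))
        assert s.trimmed_mean == 100.0
        assert s.trimmed_sd == 0.0
        assert s.presence_threshold == 100.0

    def test_trimmed_mean_sd_threshold_on_1_to_20(self):
        # trimming 5% from each end of 1..20 keeps 2..19:
        # mean 10.5, sample variance 28.5, threshold 10.5 + 2*sqrt(28.5)
        s = negative_control_stats(np.arange(1.0, 21.0), trim_fraction=0.05, sd_multiplier=2.0)
        assert s.n_used == 18
        assert s.trimmed_mean == pytest.approx(10.5)
        assert s.trimmed_sd == pytest.approx(np.sqrt(28.5))
        assert s.presence_threshold == pytest.approx(10.5 + 2 * np.sqrt(28.5))
        assert s.presence_threshold == pytest.approx(21.177, abs=5e-4)

    def test_too_few_survivors_rejected(self):
        with pytest.raises(ValueError, match="need >= 3"):
            negative_control_stats(np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="non-negative"):
            negative_control_stats(np.array([-1.0, 2.0, 3.0, 4.0]))


def _raw_one_sample(signals, nc):
    probe_ids = [f"p{i}" for i in range(len(signals))]
    return RawArrayCollection(
        probe_signals=pd.DataFrame({"S1": signals}, index=probe_ids),
        nc_signals=pd.DataFrame({"S1": nc}, index=[f"nc{i}" for i in range(len(nc))]),
    )


class TestPresentCallAndSubtraction:
    def test_detected_signal_is_background_subtracted(self):
        raw = _raw_one_sample([100.0], [10.0] * 5)
        stats = {"S1": NegativeControlStats(10.0, 10.0, 30.0, 5)}
        subtracted, detected = call_present_and_subtract(raw, stats)
        assert bool(detected.loc["p0", "S1"])
        assert subtracted.loc["p0", "S1"] == 90.0

    def test_signal_equal_to_threshold_is_not_detected(self):
        raw = _raw_one_sample([30.0], [10.0] * 5)
        stats = {"S1": NegativeControlStats(10.0, 10.0, 30.0, 5)}
        _, detected = call_present_and_subtract(raw, stats)
        assert not bool(detected.loc["p0", "S1"])

    def test_minimal_excess_above_constant_controls(self):
        c = 50.0
        raw = _raw_one_sample([c + 1.0], [c] * 10)
        stats = {"S1": negative_control_stats(np.full(10, c))}
        subtracted, detected = call_present_and_subtract(raw, stats)
        assert bool(detected.loc["p0", "S1"])
        assert subtracted.loc["p0", "S1"] == 1.0

    def test_missing_stats_rejected(self):
        raw = _raw_one_sample([10.0], [1.0] * 5)
        with pytest.raises(ValueError, match="missing negative-control stats"):
            call_present_and_subtract(raw, {})

    @given(
        base=st.floats(min_value=1.0, max_value=1e4),
        bump=st.floats(min_value=0.0, max_value=1e4),
    )
    @settings(max_examples=50, deadline=None)
    def test_present_call_monotone_in_signal(self, base, bump):
        """Raising a probe's raw signal can never flip detected -> undetected."""
        nc = np.linspace(5, 15, 20)
        stats = {"S1": negative_control_stats(nc)}
        lo = _raw_one_sample([base], nc)
        hi = _raw_one_sample([base + bump], nc)
        _, det_lo = call_present_and_subtract(lo, stats)
        _, det_hi = call_present_and_subtract(hi, stats)
        assert bool(det_hi.loc["p0", "S1"]) >= bool(det_lo.loc["p0", "S1"])


class TestFloorUndetected:
    def test_undetected_floored_to_min_detected_minus_offset(self):
        subtracted = pd.DataFrame(
            {"S1": [2.0 ** 4.0, 2.0 ** 7.2, 2.0 ** 9.1, 5.0]},
            index=["a", "b", "c", "d"],
        )
        detected = pd.DataFrame({"S1": [True, True, True, False]}, index=subtracted.index)
        out = floor_undetected(subtracted, detected, 0.1)
        np.testing.assert_allclose(out["S1"][:3], [4.0, 7.2, 9.1])
        assert out.loc["d", "S1"] == pytest.approx(3.9)

    def test_all_detected_is_plain_log2(self):
        subtracted = pd.DataFrame({"S1": [4.0, 16.0]}, index=["a", "b"])
        detected = pd.DataFrame({"S1": [True, True]}, index=subtracted.index)
        out = floor_undetected(subtracted, detected)
        np.testing.assert_allclose(out["S1"], [2.0, 4.0])

    def test_nonpositive_subtracted_value_floored_even_if_called_present(self):
        subtracted = pd.DataFrame({"S1": [8.0, 0.0]}, index=["a", "b"])
        detected = pd.DataFrame({"S1": [True, True]}, index=subtracted.index)
        out = floor_undetected(subtracted, detected, 0.1)
        assert out.loc["b", "S1"] == pytest.approx(3.0 - 0.1)

    def test_sample_with_no_detected_probe_is_an_error(self):
        subtracted = pd.DataFrame({"S1": [1.0, 2.0]}, index=["a", "b"])
        detected = pd.DataFrame({"S1": [False, False]}, index=subtracted.index)
        with pytest.raises(ValueError, match="S1"):
            floor_undetected(subtracted, detected)


class TestQuantileNormalize:
    def test_hand_computed_rank_means(self):
        values = pd.DataFrame({"A": [2.0, 4.0, 6.0], "B": [3.0, 5.0, 7.0]})
        out = quantile_normalize(values)
        np.testing.assert_allclose(out["A"], [2.5, 4.5, 6.5])
        np.testing.assert_allclose(out["B"], [2.5, 4.5, 6.5])

    def test_identical_samples_unchanged(self):
        values = pd.DataFrame({"A": [1.0, 5.0, 3.0], "B": [1.0, 5.0, 3.0]})
        pd.testing.assert_frame_equal(quantile_normalize(values), values)

    def test_order_is_restored_not_sorted(self):
        values = pd.DataFrame({"A": [6.0, 2.0, 4.0], "B": [7.0, 3.0, 5.0]})
        out = quantile_normalize(values)
        np.testing.assert_allclose(out["A"], [6.5, 2.5, 4.5])

    def test_sample_permutation_invariance(self):
        rng = np.random.default_rng(2)
        values = pd.DataFrame(rng.normal(8, 1, size=(30, 4)), columns=list("ABCD"))
        out1 = quantile_normalize(values)
        out2 = quantile_normalize(values[["D", "B", "A", "C"]])
        pd.testing.assert_frame_equal(out1, out2[out1.columns])

    def test_sorted_columns_identical_without_ties(self):
        rng = np.random.default_rng(3)
        values = pd.DataFrame(rng.normal(8, 1, size=(50, 5)))
        out = quantile_normalize(values).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), ref)

    def test_ties_receive_mean_of_reference_values(self):
        values = pd.DataFrame({"A": [1.0, 1.0, 10.0], "B": [2.0, 4.0, 6.0]})
        out = quantile_normalize(values)
        # column A's tied pair shares the mean of the two lowest reference values
        ref = np.sort(values.to_numpy(), axis=0).mean(axis=1)
        assert out.loc[0, "A"] == out.loc[1, "A"] == pytest.approx(ref[:2].mean())

    def test_missing_values_rejected(self):
        values = pd.DataFrame({"A": [1.0, np.nan], "B": [2.0, 3.0]})
        with pytest.raises(ValueError, match="flooring"):
            quantile_normalize(values)


class TestPreprocessPipeline:
    def test_full_pipeline_output_is_log2_with_mask(self, small_cohort):
        raw, annotations = small_cohort
        matrix = mx.preprocess(raw)
        assert matrix.scale == "log2"
        assert matrix.values.shape == raw.probe_signals.shape
        assert matrix.detected.shape == raw.probe_signals.shape
        assert np.isfinite(matrix.values.to_numpy()).all()

    def test_absent_fraction_recovered_by_present_call(self):
        gc = mx.GeneratorConfig(
            group_sizes={mx.ClinicalGroup.HEALTHY: 20},
            n_probes=1000,
            marker_effects={},
            absent_probe_fraction=0.3,
            rng_seed=5,
        )
        raw, _ = mx.generate_cohort(gc)
        matrix = mx.preprocess(raw)
        undetected_frac = 1.0 - matrix.detected.to_numpy().mean()
        assert undetected_frac == pytest.approx(0.3, abs=0.05)

    def test_per_group_normalization_matches_columns(self, small_cohort):
        raw, annotations = small_cohort
        groups = pd.Series({a.sample_id: a.group.value for a in annotations})
        pooled = mx.preprocess(raw)
        batched = mx.preprocess(raw, groups=groups)
        assert list(batched.values.columns) == list(pooled.values.columns)
        assert not np.allclose(batched.values, pooled.values)

    def test_log2_input_refused_by_scale_guard(self):
        m = mx.ExpressionMatrix(
            values=pd.DataFrame({"S1": [1.0]}, index=["p"]), scale="log2"
        )
        with pytest.raises(ValueError, match="linear"):
            m.require_scale("linear", "preprocessing")
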