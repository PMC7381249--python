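import numpy as np
import pandas as pd
import pytest

from cd8mir.io_core import Cd8mirError, ExpressionMatrix, NoiseStats, ValidationError, ValueKind
from cd8mir.microarray import (
    cyclic_loess_normalize,
    default_min_detected,
    detection_call,
    filter_top_expressed,
    inverse_log2_transform,
    log2_transform,
    qc_filter_samples,
)
from cd8mir.simulate import MicroarraySimConfig, simulate_microarray


def _noise(sample_ids, mean, sd):
    return NoiseStats(
        pd.DataFrame(
            {"noise_mean": mean, "noise_sd": sd}, index=pd.Index(sample_ids, name="sample_id")
        )
    )


class TestDetectionCall:
    def test_detected_and_corrected(self):
        mat = ExpressionMatrix(pd.DataFrame({"s1": [25.0]}, index=["f1"]), ValueKind.RAW_INTENSITY)
        det = detection_call(mat, _noise(["s1"], [10.0], [5.0]))
        assert bool(det.mask.loc["f1", "s1"])
        assert det.corrected.data.loc["f1", "s1"] == pytest.approx(15.0)

    def test_below_threshold_missing(self):
        # threshold is 20; 19 and the boundary 20 both fail (strict >)
        mat = ExpressionMatrix(
            pd.DataFrame({"s1": [19.0, 20.0]}, index=["f1", "f2"]), ValueKind.RAW_INTENSITY
        )
        det = detection_call(mat, _noise(["s1"], [10.0], [5.0]))
        assert not det.mask.any().any()
        assert det.corrected.data.isna().all().all()

    def test_missing_noise_record(self, small_intensity_matrix):
        with pytest.raises(ValidationError, match="noise"):
            detection_call(small_intensity_matrix, _noise(["s1"], [10.0], [5.0]))

    def test_cellwise_oracle(self):
        rng = np.random.default_rng(5)
        vals = rng.uniform(0, 60, size=(50, 3))
        mat = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"f{i}" for i in range(50)], columns=["a", "b", "c"]),
            ValueKind.RAW_INTENSITY,
        )
        nm, nsd = [10.0, 20.0, 5.0], [2.0, 4.0, 1.0]
        det = detection_call(mat, _noise(["a", "b", "c"], nm, nsd))
        for i in range(50):
            for j, s in enumerate(["a", "b", "c"]):
                expected = vals[i, j] > nm[j] + 2 * nsd[j]
                assert bool(det.mask.iloc[i, j]) == expected
                if expected:
                    assert det.corrected.data.iloc[i, j] == pytest.approx(
                        max(vals[i, j] - nm[j], 0.0)
                    )
                else:
                    assert np.isnan(det.corrected.data.iloc[i, j])

    def test_idempotent_with_zero_noise(self):
        rng = np.random.default_rng(6)
        vals = rng.uniform(1, 100, size=(20, 2))
        mat = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"f{i}" for i in range(20)], columns=["a", "b"]),
            ValueKind.RAW_INTENSITY,
        )
        zero = _noise(["a", "b"], [0.0, 0.0], [0.0, 0.0])
        once = detection_call(mat, zero)
        twice = detection_call(once.corrected, zero)
        pd.testing.assert_frame_equal(once.corrected.data, twice.corrected.data)


class TestQcFilter:
    def _det(self, counts):
        from cd8mir.microarray import DetectionResult

        mask = pd.DataFrame(True, index=["f1"], columns=list(counts))
        corrected = ExpressionMatrix(
            pd.DataFrame(1.0, index=["f1"], columns=list(counts)), ValueKind.RAW_INTENSITY
        )
        return DetectionResult(mask, corrected, pd.Series(counts))

    def test_low_count_excluded(self):
        qc = qc_filter_samples(self._det({"a": 500, "b": 480, "c": 12}), 100)
        assert qc.retained == ["a", "b"]
        assert qc.excluded == {"c": 12}

    def test_zero_threshold_identity(self):
        qc = qc_filter_samples(self._det({"a": 0, "b": 5}), 0)
        assert qc.retained == ["a", "b"]

    def test_all_excluded_hard_error(self):
        with pytest.raises(Cd8mirError, match="all samples"):
            qc_filter_samples(self._det({"a": 1}), 10)

    def test_planted_bad_samples_excluded(self):
        cfg = MicroarraySimConfig(seed=42, n_bad_samples=2)
        raw, noise, _meta, truth = simulate_microarray(cfg)
        det = detection_call(raw, noise)
        qc = qc_filter_samples(det, default_min_detected(raw.shape[0]))
        assert sorted(qc.excluded) == truth.bad_samples
        assert len(truth.bad_samples) == 2


class TestExpressionFilter:
    def test_threshold_filter(self):
        df = pd.DataFrame({"s1": [100.0, 79.0, 81.0], "s2": [100.0, 79.0, 81.0]},
                          index=["f1", "f2", "f3"])
        mat = ExpressionMatrix(df, ValueKind.RAW_INTENSITY)
        kept = filter_top_expressed(mat, mean_threshold=80)
        assert kept.feature_ids == ["f1", "f3"]

    def test_zero_threshold_identity(self, small_intensity_matrix):
        kept = filter_top_expressed(small_intensity_matrix, mean_threshold=0)
        assert kept.feature_ids == small_intensity_matrix.feature_ids

    def test_top_n_mode(self, small_intensity_matrix):
        kept = filter_top_expressed(small_intensity_matrix, top_n=1)
        assert kept.feature_ids == ["f1"]

    def test_empty_result_hard_error(self, small_intensity_matrix):
        with pytest.raises(Cd8mirError, match="no features"):
            filter_top_expressed(small_intensity_matrix, mean_threshold=1e9)


class TestLog2:
    def test_zero_maps_to_zero(self):
        mat = ExpressionMatrix(pd.DataFrame({"s1": [0.0, 127.0]}, index=["f1", "f2"]),
                               ValueKind.RAW_INTENSITY)
        out = log2_transform(mat)
        assert out.data.loc["f1", "s1"] == pytest.approx(0.0)
        assert out.data.loc["f2", "s1"] == pytest.approx(7.0)
        assert out.value_kind is ValueKind.LOG2

    def test_roundtrip(self, small_intensity_matrix):
        back = inverse_log2_transform(log2_transform(small_intensity_matrix))
        assert np.allclose(back.data.to_numpy(), small_intensity_matrix.data.to_numpy(), atol=1e-12)

    def test_wrong_kind_rejected(self, seeded_log2_matrix):
        with pytest.raises(ValidationError, match="value_kind"):
            log2_transform(seeded_log2_matrix)


class TestCyclicLoess:
    def test_identical_arrays_unchanged(self):
        rng = np.random.default_rng(3)
        col = rng.normal(8, 1, 50)
        df = pd.DataFrame({"a": col, "b": col}, index=[f"f{i}" for i in range(50)])
        mat = ExpressionMatrix(df, ValueKind.LOG2)
        out = cyclic_loess_normalize(mat)
        assert np.allclose(out.data.to_numpy(), df.to_numpy(), atol=1e-8)
        assert out.value_kind is ValueKind.NORMALIZED_LOG2

    def test_constant_offset_removed(self):
        rng = np.random.default_rng(4)
        col = rng.normal(8, 1, 200)
        df = pd.DataFrame({"a": col, "b": col + 0.8}, index=[f"f{i}" for i in range(200)])
        out = cyclic_loess_normalize(ExpressionMatrix(df, ValueKind.LOG2))
        m = out.data["a"] - out.data["b"]
        assert abs(m.median()) < 1e-3

    def test_median_abs_m_non_increasing(self):
        # 4 arrays with genuine per-sample offsets: each sweep shrinks the
        # worst per-pair median |M|
        from itertools import combinations

        rng = np.random.default_rng(44)
        base = rng.normal(8, 1, 200)
        df = pd.DataFrame(
            {f"s{i}": base + off + rng.normal(0, 0.05, 200)
             for i, off in enumerate([0.0, 0.5, 1.0, 1.5])},
            index=[f"f{i}" for i in range(200)],
        )

        def worst_median_abs_m(values):
            return max(
                float(np.median(np.abs(values[:, i] - values[:, j])))
                for i, j in combinations(range(values.shape[1]), 2)
            )

        prev = worst_median_abs_m(df.to_numpy())
        for iterations in (1, 2, 3):
            out = cyclic_loess_normalize(ExpressionMatrix(df, ValueKind.LOG2),
                                         iterations=iterations)
            cur = worst_median_abs_m(out.data.to_numpy())
            assert cur <= prev + 1e-6
            prev = cur

    def test_pair_adjustments_cancel(self):
        # total shift across a complete two-sample pair must cancel exactly
        rng = np.random.default_rng(9)
        df = pd.DataFrame(
            {"a": rng.normal(8, 1, 80), "b": rng.normal(8.5, 1, 80)},
            index=[f"f{i}" for i in range(80)],
        )
        mat = ExpressionMatrix(df, ValueKind.LOG2)
        out = cyclic_loess_normalize(mat, iterations=1)
        delta = out.data.to_numpy() - df.to_numpy()
        assert np.abs(delta.sum(axis=1)).max() < 1e-9

    def test_too_few_complete_features(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [1.0, 2.0]}, index=["f1", "f2"])
        with pytest.raises(Cd8mirError, match="complete features"):
            cyclic_loess_normalize(ExpressionMatrix(df, ValueKind.LOG2))

    def test_missing_values_stay_missing(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(
            {"a": rng.normal(8, 1, 40), "b": rng.normal(8, 1, 40)},
            index=[f"f{i}" for i in range(40)],
        )
        df.iloc[0, 0] = np.nan
        out = cyclic_loess_normalize(ExpressionMatrix(df, ValueKind.LOG2))
        assert np.isnan(out.data.iloc[0, 0])
        assert np.isfinite(out.data.iloc[0, 1])
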