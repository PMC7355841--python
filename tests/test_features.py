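"""Feature vectors, dataset assembly, standardization and splitting."""

import numpy as np
import pytest

from gazerr.features import (
    FEATURE_NAMES,
    REDUCED_FEATURE_NAMES,
    LabeledDataset,
    MissingAOIError,
    assemble_dataset,
    build_feature_vector,
    errors_per_aoi,
    sample_stats,
    split,
    standardize,
    trace_features,
)
from gazerr.pipeline import sessions_to_error_traces
from gazerr.simulate import SimulationSpec, default_profiles, simulate_study


class TestErrorsPerAoi:
    def test_constant_error(self):
        idx = np.repeat(np.arange(1, 16), 4)
        out = errors_per_aoi(np.full(60, 2.0), idx)
        np.testing.assert_array_equal(out, np.full(15, 2.0))
        assert len(out) == 15

    def test_single_aoi_mean(self):
        idx = np.repeat(np.arange(1, 16), 2)
        err = np.zeros(30)
        err[:2] = [1.0, 3.0]
        out = errors_per_aoi(err, idx)
        assert out[0] == 2.0 and np.all(out[1:] == 0)

    def test_missing_aoi_rejected(self):
        with pytest.raises(MissingAOIError):
            errors_per_aoi(np.zeros(4), np.array([1, 2, 3, 4]))


class TestSampleStats:
    def test_constant_sample(self):
        m, sd, iqr, hi, lo = sample_stats(np.full(10, 4.0))
        assert m == 4.0 and sd == 0.0 and iqr == 0.0 and hi == lo == 4.0

    def test_hand_computed_bimodal(self):
        vals = np.array([0.0] * 4 + [4.0] * 4)
        m, sd, iqr, hi, lo = sample_stats(vals)
        assert m == 2.0
        assert sd == pytest.approx(2.138, abs=1e-3)
        assert hi - m == pytest.approx(1.481, abs=1e-3)
        assert m - lo == pytest.approx(1.481, abs=1e-3)

    def test_interpolated_iqr(self):
        _, _, iqr, _, _ = sample_stats(np.arange(1.0, 9.0))
        assert iqr == 3.5

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            sample_stats(np.array([1.0]))


class TestBuildFeatureVector:
    def test_length_and_order(self):
        fv = build_feature_vector(np.arange(15.0), (1.0, 2.0, 3.0, 4.0, 5.0))
        assert len(fv.values) == 20
        np.testing.assert_array_equal(fv.values[:15], np.arange(15.0))
        np.testing.assert_array_equal(fv.values[15:], [1, 2, 3, 4, 5])

    def test_reduced_projection(self):
        fv = build_feature_vector(np.zeros(15), (1.0, 2.0, 3.0, 4.0, 5.0))
        assert len(fv.reduced) == 5
        np.testing.assert_array_equal(fv.reduced, [1, 2, 3, 4, 5])

    def test_zero_errors_give_zero_vector(self):
        idx = np.repeat(np.arange(1, 16), 4)
        fv = trace_features(np.zeros(60), idx)
        np.testing.assert_array_equal(fv.values, np.zeros(20))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            build_feature_vector(np.zeros(14), (1, 2, 3, 4, 5))


@pytest.fixture(scope="module")
def one_participant_traces():
    spec = SimulationSpec(platform="desktop", participants=1, seed=5)
    sessions = simulate_study(spec, default_profiles("desktop"))
    return sessions_to_error_traces(sessions)


class TestAssembleDataset:
    def test_single_participant_user_distance(self, one_participant_traces):
        ds = assemble_dataset(one_participant_traces, scope="user_distance")
        assert ds.n_samples == 120          # 30 per condition x 4 classes
        assert len(ds.class_names) == 4

    def test_thirty_samples_per_participant_condition(self, one_participant_traces):
        ds = assemble_dataset(one_participant_traces, scope="user_distance")
        per_label = {c: (ds.labels == c).sum() for c in ds.class_names}
        assert all(v == 30 for v in per_label.values())

    def test_pose_scope_relabels_neutral(self, one_participant_traces):
        ds = assemble_dataset(one_participant_traces, scope="pose")
        assert sorted(ds.class_names) == ["neutral", "pitch20", "roll20", "yaw20"]

    def test_mixed_scope_has_seven_classes(self, one_participant_traces):
        ds = assemble_dataset(one_participant_traces, scope="mixed")
        assert ds.n_samples == 210 and len(ds.class_names) == 7

    def test_missing_condition_reported(self, one_participant_traces):
        incomplete = [t for t in one_participant_traces if t.condition != "UD70"]
        with pytest.raises(ValueError, match="UD70"):
            assemble_dataset(incomplete, scope="user_distance")

    def test_flip_variants_share_statistical_features(self, one_participant_traces):
        ds = assemble_dataset(one_participant_traces, scope="user_distance")
        prov = ds.provenance
        stats_cols = slice(15, 20)
        base = (prov["variant"] == "original").to_numpy()
        for flip in ("hflip", "vflip"):
            sel = (prov["variant"] == flip).to_numpy()
            np.testing.assert_allclose(
                ds.matrix[sel][:, stats_cols], ds.matrix[base][:, stats_cols],
                atol=1e-9)
            # AOI-indexed features permute rather than match
            assert not np.allclose(ds.matrix[sel][:, :15], ds.matrix[base][:, :15])


class TestStandardize:
    def test_three_point_column(self):
        ds = LabeledDataset(matrix=np.array([[1.0], [2.0], [3.0]]),
                            labels=np.array(["a", "b", "a"]),
                            feature_names=("mean_err",))
        out = standardize(ds)
        np.testing.assert_allclose(
            out.matrix[:, 0], [-1.2247, 0.0, 1.2247], atol=1e-4)

    def test_idempotent(self, rng):
        ds = LabeledDataset(matrix=rng.normal(size=(50, 4)),
                            labels=np.array(["a", "b"] * 25),
                            feature_names=("f1", "f2", "f3", "f4"))
        once = standardize(ds)
        twice = standardize(once)
        np.testing.assert_allclose(twice.matrix, once.matrix, atol=1e-12)

    def test_postconditions_on_random_matrix(self, rng):
        ds = LabeledDataset(matrix=rng.normal(3, 7, size=(200, 6)),
                            labels=np.repeat(["a", "b"], 100),
                            feature_names=tuple("abcdef"))
        out = standardize(ds)
        np.testing.assert_allclose(out.matrix.mean(axis=0), 0, atol=1e-9)
        np.testing.assert_allclose(out.matrix.std(axis=0), 1, atol=1e-9)

    def test_constant_column_dropped_with_warning(self, rng):
        mat = np.column_stack([rng.normal(size=20), np.full(20, 2.0)])
        ds = LabeledDataset(matrix=mat, labels=np.array(["a", "b"] * 10),
                            feature_names=("live", "dead"))
        with pytest.warns(UserWarning, match="dead"):
            out = standardize(ds)
        assert out.feature_names == ("live",)


class TestSplit:
    @pytest.fixture
    def dataset(self, rng):
        return LabeledDataset(matrix=rng.normal(size=(2400, 5)),
                              labels=np.repeat(["a", "b", "c", "d"], 600),
                              feature_names=tuple("vwxyz"))

    def test_thirty_percent_split_sizes(self, dataset):
        train, test = split(dataset, 0.30, seed=0)
        assert train.n_samples == 1680 and test.n_samples == 720

    def test_stratification_preserved(self, dataset):
        train, test = split(dataset, 0.30, seed=0)
        for c in "abcd":
            assert abs((test.labels == c).sum() - 180) <= 1

    def test_same_seed_same_split(self, dataset):
        a = split(dataset, 0.30, seed=3)[1]
        b = split(dataset, 0.30, seed=3)[1]
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_invalid_fraction_rejected(self, dataset):
        with pytest.raises(ValueError):
            split(dataset, 1.5)
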