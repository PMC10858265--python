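"""Binding-specificity regression: feature counts, nested CV, profiles."""

import math

import numpy as np
import pytest

from flankshape.binding import (
    BindingRecord,
    BindingSpecificityModel,
    FeatureConfig,
    aggregate_profiles,
    cap_scan,
    encode_feature_matrix,
    expected_feature_counts,
    fit_l2_nested_cv,
    read_binding_table,
)
from flankshape.features import register_default_features
from flankshape.synthetic import GroundTruthPredictor, make_ground_truth

REG = register_default_features()


class ZeroPredictor:
    """Stand-in shape predictor emitting zero profiles of the right length."""

    def __init__(self, node_kind):
        self.node_kind = node_kind

    def predict(self, seq, depth=None, symmetrize=False):
        n = len(seq) - 1 if self.node_kind == "per-step" else len(seq)
        return np.zeros(n)


def random_records(rng, n=60, length=12):
    seqs = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]
    return [BindingRecord(s, float(rng.uniform(0.1, 1.0))) for s in seqs]


class TestFeatureCounts:
    @pytest.mark.parametrize("n", range(5, 31))
    def test_kmer_formulas_exhaustive(self, n):
        rng = np.random.default_rng(n)
        records = random_records(rng, n=4, length=n)
        for orders, formula in [
            ((1,), 4 * n),
            ((2,), 16 * (n - 1)),
            ((3,), 64 * (n - 2)),
            ((1, 2, 3), 4 * n + 16 * (n - 1) + 64 * (n - 2)),
        ]:
            config = FeatureConfig(kmer_orders=orders)
            X, labels = encode_feature_matrix(records, config)
            assert X.shape[1] == formula
            assert len(labels) == formula

    @pytest.mark.parametrize("n", range(5, 31))
    def test_shape_column_counts(self, n):
        """n columns per bp/groove feature, n-1 per step feature."""
        rng = np.random.default_rng(100 + n)
        records = random_records(rng, n=4, length=n)
        names = REG.preset("13shape")
        predictors = {
            name: ZeroPredictor(REG.lookup(name).node_kind) for name in names
        }
        config = FeatureConfig(kmer_orders=(), shape_features=tuple(names))
        X, _ = encode_feature_matrix(records, config, predictors)
        expected = 7 * n + 6 * (n - 1)
        assert X.shape[1] == expected
        assert expected == expected_feature_counts(
            n, config, {m: REG.lookup(m).node_kind for m in names}
        )

    def test_thirteen_shape_sixteen_mer_is_202(self):
        rng = np.random.default_rng(0)
        records = random_records(rng, n=4, length=16)
        names = REG.preset("13shape")
        predictors = {m: ZeroPredictor(REG.lookup(m).node_kind) for m in names}
        config = FeatureConfig(kmer_orders=(), shape_features=tuple(names))
        X, _ = encode_feature_matrix(records, config, predictors)
        assert X.shape[1] == 202

    def test_onehot_rows(self):
        records = [BindingRecord("ACGT", 1.0), BindingRecord("TTTT", 0.5)]
        X, labels = encode_feature_matrix(records, FeatureConfig(kmer_orders=(1,)))
        assert X[0].tolist() == [1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1]
        assert labels[0] == "1mer_p1_A"

    def test_missing_predictor_rejected(self):
        records = [BindingRecord("ACGT", 1.0)] * 3
        config = FeatureConfig(kmer_orders=(1,), shape_features=("MGW",))
        with pytest.raises(ValueError, match="MGW"):
            encode_feature_matrix(records, config)

    def test_length_mismatch_rejected(self):
        records = [BindingRecord("ACGT", 1.0), BindingRecord("ACGTA", 0.5)]
        with pytest.raises(ValueError, match="aligned"):
            encode_feature_matrix(records, FeatureConfig(kmer_orders=(1,)))


class TestNestedCv:
    def test_oof_predictions_partition_rows(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 5))
        y = rng.normal(size=50)
        result = fit_l2_nested_cv(X, y, seed=0)
        assert result.oof_predictions.shape == (50,)
        # every row assigned to exactly one fold, all folds used
        assert sorted(set(result.fold_assignment)) == list(range(10))
        assert len(result.fold_lambdas) == 10

    def test_tiny_lambda_matches_normal_equations(self):
        """With the penalty forced to ~0, nested CV reduces to OLS on each
        outer training set; check the full-data fit against lstsq."""
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 5))
        beta = rng.normal(size=5)
        y = X @ beta
        from sklearn.linear_model import Ridge

        model = Ridge(alpha=1e-12)
        model.fit(X, y)
        beta_ols, *_ = np.linalg.lstsq(
            np.column_stack([X, np.ones(50)]), y, rcond=None
        )
        np.testing.assert_allclose(model.coef_, beta_ols[:5], atol=1e-6)
        result = fit_l2_nested_cv(X, y, seed=0, lambda_grid=[1e-12])
        np.testing.assert_allclose(result.oof_predictions, y, atol=1e-6)

    def test_noiseless_linear_target_recovered(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(80, 6))
        y = X @ rng.normal(size=6) + 0.5
        result = fit_l2_nested_cv(X, y, seed=0)
        assert result.r_squared >= 0.999

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_permuted_labels_have_no_signal(self, seed):
        rng = np.random.default_rng(40 + seed)
        X = rng.normal(size=(100, 5))
        y = X @ rng.normal(size=5)
        y_perm = rng.permutation(y)
        result = fit_l2_nested_cv(X, y_perm, seed=seed)
        assert result.r_squared <= 0.05

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_l2_nested_cv(np.ones((10, 2)), np.ones(10))

    def test_shape_features_add_signal_over_sequence_alone(self):
        """When log-affinity is a noiseless linear readout of true shape
        profiles, adding shape columns to 1-mers raises pooled R^2."""
        gtm_bp = make_ground_truth(seed=21, radius=3, noise_sd=0.0,
                                   terminal_mask_margin=0)
        gtm_step = make_ground_truth(seed=22, radius=3, noise_sd=0.0,
                                     node_kind="per-step",
                                     terminal_mask_margin=0)
        predictors = {
            "synthetic": GroundTruthPredictor(gtm_bp),
            "synthetic-step": GroundTruthPredictor(gtm_step),
        }
        rng = np.random.default_rng(23)
        n, length = 120, 14
        records = []
        w_bp = rng.normal(size=length)
        w_step = rng.normal(size=length - 1)
        for _ in range(n):
            seq = "".join(rng.choice(list("ACGT"), size=length))
            shape_bp = predictors["synthetic"].predict(seq)
            shape_step = predictors["synthetic-step"].predict(seq)
            affinity = float(np.exp(shape_bp @ w_bp + shape_step @ w_step))
            records.append(BindingRecord(seq, affinity))
        r2 = {}
        for tag, shape_names in [("1mer", ()), ("1mer+shape",
                                                tuple(predictors))]:
            config = FeatureConfig(kmer_orders=(1,), shape_features=shape_names,
                                   log_affinity=True)
            for s in (0, 1, 2):
                res = BindingSpecificityModel(records, config,
                                              predictors).fit(seed=s)
                r2.setdefault(tag, []).append(res.r_squared)
        for s in range(3):
            assert r2["1mer+shape"][s] > r2["1mer"][s]


class TestAggregateProfiles:
    def setup_method(self):
        self.gtm = make_ground_truth(seed=30, radius=2, noise_sd=0.0,
                                     terminal_mask_margin=0)
        self.predictor = GroundTruthPredictor(self.gtm)
        rng = np.random.default_rng(31)
        self.records = random_records(rng, n=100, length=12)

    def test_top_quarter_kept_by_default(self):
        out = aggregate_profiles(self.records, self.predictor)
        assert out["profiles"].shape == (25, 12)

    def test_rows_sorted_by_descending_affinity(self):
        out = aggregate_profiles(self.records, self.predictor)
        affs = out["affinities"]
        assert affs[0] == max(r.affinity for r in self.records)
        assert np.all(np.diff(affs) <= 0)

    def test_full_fraction_keeps_all(self):
        out = aggregate_profiles(self.records, self.predictor, top_fraction=1.0)
        assert out["profiles"].shape[0] == 100

    def test_ceiling_rule(self):
        out = aggregate_profiles(self.records[:10], self.predictor,
                                 top_fraction=0.25)
        assert out["profiles"].shape[0] == math.ceil(2.5)

    def test_bin_means(self):
        out = aggregate_profiles(self.records, self.predictor, n_bins=5)
        assert out["bin_means"].shape == (5, 12)


class TestCapScan:
    def setup_method(self):
        gtm = make_ground_truth(seed=32, radius=2, noise_sd=0.0,
                                terminal_mask_margin=0)
        self.predictor = GroundTruthPredictor(gtm)

    def test_small_core_enumerated(self):
        out = cap_scan("AAAA", "AAAA", core_length=3, predictor=self.predictor)
        assert out["n_sequences"] == 64
        assert out["enumerated"]

    def test_summary_is_boxplot_convention(self):
        out = cap_scan("GC", "GC", core_length=2, predictor=self.predictor)
        iqr = out["q3"] - out["q1"]
        np.testing.assert_allclose(out["whisker_low"], out["q1"] - 1.5 * iqr)
        np.testing.assert_allclose(out["whisker_high"], out["q3"] + 1.5 * iqr)

    def test_seeded_sampling_reproducible(self):
        a = cap_scan("A", "A", core_length=10, predictor=self.predictor,
                     sample_size=40, seed=5, enumerate_limit=100)
        b = cap_scan("A", "A", core_length=10, predictor=self.predictor,
                     sample_size=40, seed=5, enumerate_limit=100)
        np.testing.assert_array_equal(a["profiles"], b["profiles"])
        assert not a["enumerated"]


class TestIo:
    def test_read_binding_table(self, tmp_path):
        path = tmp_path / "binding.tsv"
        path.write_text("# comment\nACGT\t0.9\nTTAA\t0.1\n")
        records = read_binding_table(path)
        assert records == [BindingRecord("ACGT", 0.9), BindingRecord("TTAA", 0.1)]
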