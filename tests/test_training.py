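"""Training: file dialect, loss, gradients, convergence, grid search."""

import numpy as np
import pytest

from flankshape.features import NormalizationStats, register_default_features
from flankshape.network import ModelConfig, ShapeNet
from flankshape.training import (
    TrainingExample,
    attach_targets,
    evaluate_layerwise_mae,
    grid_search,
    load_training_file,
    multi_layer_masked_mae,
    train_feature_model,
    write_training_file,
    _mae_grads,
)

REG = register_default_features()
MGW = REG.lookup("MGW")

FAST = dict(n_shape_layers=2, filter_size=6, dropout_ratio=0.0,
            learning_rate=0.05, momentum=0.9, batch_size=8)


def make_examples(rng, n=12, lo=8, hi=14, margin=1):
    out = []
    for i in range(n):
        length = int(rng.integers(lo, hi + 1))
        seq = "".join(rng.choice(list("ACGT"), size=length))
        raw = rng.normal(5.0, 1.0, size=length)
        mask = np.ones(length, dtype=bool)
        mask[:margin] = mask[-margin:] = False
        raw[~mask] = np.nan
        out.append(TrainingExample(f"s{i}", seq, raw, mask))
    return out


class TestTrainingFile:
    def test_na_parsing(self, tmp_path):
        path = tmp_path / "mgw.tsv"
        path.write_text("s1\tACGTT\tNA,4.1,4.5,4.2,NA\n"
                        "s2\tACGTTAA\tNA,4.0,4.4,4.1,4.3,4.2,NA\n")
        examples, stats = load_training_file(path, MGW)
        assert examples[0].mask.tolist() == [False, True, True, True, False]
        assert np.isnan(examples[0].raw[0])
        # variable-length records accepted in one file
        assert [len(e.sequence) for e in examples] == [5, 7]

    def test_round_trip_precision(self, tmp_path):
        rng = np.random.default_rng(0)
        examples = make_examples(rng, n=5)
        path = tmp_path / "f.tsv"
        write_training_file(path, [(e.seq_id, e.sequence, e.raw) for e in examples])
        back, _ = load_training_file(path, MGW)
        for a, b in zip(examples, back):
            np.testing.assert_allclose(
                a.raw[a.mask], b.raw[b.mask], rtol=0, atol=1e-12
            )
            assert a.mask.tolist() == b.mask.tolist()

    def test_ragged_row_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("s1\tACGT\t1.0,2.0\n")
        with pytest.raises(ValueError, match="values"):
            load_training_file(path, MGW)

    def test_non_numeric_token_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("s1\tACGT\t1.0,2.0,x,4.0\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_training_file(path, MGW)


class TestLoss:
    def test_perfect_predictions_zero(self):
        t = np.array([[0.1, -0.2, 0.3]])
        m = np.ones_like(t, dtype=bool)
        assert multi_layer_masked_mae([t.copy(), t.copy()], t, m) == 0.0

    def test_single_layer_arithmetic(self):
        preds = [np.array([[0.5, 0.5]])]
        targets = np.array([[0.0, 1.0]])
        mask = np.ones((1, 2), dtype=bool)
        assert multi_layer_masked_mae(preds, targets, mask) == pytest.approx(0.5)

    def test_masked_targets_ignored(self):
        preds = [np.array([[0.5, 0.5, 0.5]])]
        mask = np.array([[True, False, True]])
        a = multi_layer_masked_mae(preds, np.array([[0.0, 99.0, 1.0]]), mask)
        b = multi_layer_masked_mae(preds, np.array([[0.0, -99.0, 1.0]]), mask)
        assert a == b

    def test_all_masked_rejected(self):
        with pytest.raises(ValueError):
            multi_layer_masked_mae(
                [np.zeros((1, 2))], np.zeros((1, 2)), np.zeros((1, 2), bool)
            )


class TestGradients:
    def test_analytic_matches_finite_differences(self):
        """Backprop through shape layers checked against central differences
        on a 5-node toy input, 1e-4 relative."""
        cfg = ModelConfig(n_shape_layers=2, filter_size=5, dropout_ratio=0.0,
                          epochs=1)
        net = ShapeNet(MGW, cfg, init_seed=3)
        from flankshape.encoding import add_caps, encode_mono

        X = add_caps(encode_mono("ACGTA")).matrix[None]
        rng = np.random.default_rng(0)
        T = rng.normal(size=(1, 7))
        M = np.ones((1, 7), dtype=bool)
        M[0, 0] = M[0, -1] = False

        def loss():
            saved = {k: v.copy() for k, v in net.buffers.items()}
            heads = net.forward(X, training=True)
            net.buffers = saved
            return multi_layer_masked_mae(heads, T, M)

        heads, cache = net.forward(X, training=True, want_cache=True)
        grads = net.backward(cache, _mae_grads(heads, T, M))
        eps = 1e-6
        check_rng = np.random.default_rng(1)
        for name, arr in net.params.items():
            flat_idx = check_rng.choice(arr.size, size=min(3, arr.size),
                                        replace=False)
            for fi in flat_idx:
                ix = np.unravel_index(fi, arr.shape)
                orig = arr[ix]
                arr[ix] = orig + eps
                lp = loss()
                arr[ix] = orig - eps
                lm = loss()
                arr[ix] = orig
                fd = (lp - lm) / (2 * eps)
                assert grads[name][ix] == pytest.approx(
                    fd, rel=1e-4, abs=1e-7
                ), name


class TestTrainFeatureModel:
    def test_constant_target_converges(self):
        rng = np.random.default_rng(4)
        examples = make_examples(rng, n=24)
        c_norm = 0.3
        stats = NormalizationStats(median=5.0, p1=3.0, p99=7.0)
        for ex in examples:
            ex.raw = np.where(ex.mask, 5.0 + c_norm * stats.range, np.nan)
        attach_targets(examples, stats)
        cfg = ModelConfig(epochs=400, seed=0,
                          **{**FAST, "batch_size": 32})
        run = train_feature_model(examples, MGW, cfg, stats=stats)
        for ex in examples[:3]:
            prof = run.net.forward_sequence(ex.sequence)
            assert np.all(np.abs(prof[ex.mask] - c_norm) < 0.02)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_loss_decreases(self, seed):
        rng = np.random.default_rng(10 + seed)
        examples = make_examples(rng, n=16)
        # learnable signal: value depends on the base identity
        for ex in examples:
            vals = np.array([{"A": 4.0, "C": 5.0, "G": 6.0, "T": 5.5}[b]
                             for b in ex.sequence])
            ex.raw = np.where(ex.mask, vals, np.nan)
        stats = NormalizationStats(median=5.0, p1=4.0, p99=6.0)
        attach_targets(examples, stats)
        cfg = ModelConfig(epochs=60, seed=seed, **FAST)
        run = train_feature_model(examples, MGW, cfg, stats=stats)
        assert run.loss_history[-1] < run.loss_history[0]

    def test_same_seed_identical_history(self):
        rng = np.random.default_rng(6)
        examples = make_examples(rng, n=8)
        stats = NormalizationStats(median=5.0, p1=3.0, p99=7.0)
        attach_targets(examples, stats)
        cfg = ModelConfig(epochs=5, seed=3,
                          **{**FAST, "dropout_ratio": 0.4})
        run1 = train_feature_model(examples, MGW, cfg, stats=stats)
        run2 = train_feature_model(examples, MGW, cfg, stats=stats)
        np.testing.assert_array_equal(run1.loss_history, run2.loss_history)

    def test_masked_nodes_do_not_influence_training(self):
        rng = np.random.default_rng(7)
        examples = make_examples(rng, n=8, margin=2)
        stats = NormalizationStats(median=5.0, p1=3.0, p99=7.0)
        attach_targets(examples, stats)
        cfg = ModelConfig(epochs=5, seed=1, **FAST)
        run1 = train_feature_model(examples, MGW, cfg, stats=stats)
        # garbage values at masked nodes
        for ex in examples:
            ex.targets = np.where(ex.mask, ex.targets, 1e6)
        run2 = train_feature_model(examples, MGW, cfg, stats=stats)
        np.testing.assert_array_equal(run1.loss_history, run2.loss_history)
        for name in run1.net.params:
            np.testing.assert_array_equal(
                run1.net.params[name], run2.net.params[name]
            )

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train_feature_model([], MGW, ModelConfig(epochs=1, **FAST))


class TestGridSearch:
    def _examples(self):
        rng = np.random.default_rng(20)
        examples = make_examples(rng, n=14)
        stats = NormalizationStats(median=5.0, p1=3.0, p99=7.0)
        attach_targets(examples, stats)
        return examples, stats

    def test_single_config_returned(self):
        examples, stats = self._examples()
        cfg = ModelConfig(epochs=3, seed=0, **FAST)
        result = grid_search(examples, MGW, [cfg], split_seed=0, stats=stats)
        assert result.best_config == cfg

    def test_best_is_argmin(self):
        examples, stats = self._examples()
        grid = [ModelConfig(epochs=e, seed=0, **FAST) for e in (1, 10)]
        result = grid_search(examples, MGW, grid, split_seed=0, stats=stats)
        assert all(result.best_mae <= row["val_mae"] for row in result.table)
        assert all(len(row["layer_mae"]) == FAST["n_shape_layers"]
                   for row in result.table)

    def test_default_config_is_published_setting(self):
        cfg = ModelConfig()
        assert cfg.n_shape_layers == 7
        assert cfg.learning_rate == 0.05
        assert cfg.epochs == 1500
        assert cfg.momentum == 0.95
        assert cfg.dropout_ratio == 0.5
        assert cfg.filter_size == 64

    def test_empty_grid_rejected(self):
        examples, stats = self._examples()
        with pytest.raises(ValueError):
            grid_search(examples, MGW, [], stats=stats)


class TestParameterRecovery:
    """Headline property: the depth-7 net recovers a radius-4 flank-decay
    ground truth well beyond what a pentamer table can represent."""

    def test_beats_pentamer_table_at_half_error(self, recovery_experiment):
        run = recovery_experiment["runs"][0]
        cmp = run["comparison"]
        assert cmp["net_mae"] < 0.5 * cmp["table_mae"]

    def test_layerwise_mae_non_increasing_to_radius(self, recovery_experiment):
        radius = recovery_experiment["gtm"].radius
        lw = recovery_experiment["runs"][0]["layerwise_mae"]
        assert np.all(np.diff(lw[:radius]) <= 0)
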