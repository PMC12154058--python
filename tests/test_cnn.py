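"""Architecture contracts, schedule arithmetic, memorisation and determinism."""

import numpy as np
import pytest

from fritqc import GeneratorConfig, simulate_origin_dataset
from fritqc.cnn import (CNNResults, CNNSpec, ConfigurationError, SpectralCNN,
                        TrainConfig, build_model, dt_baseline, svm_baseline)


def closed_form_param_count(input_length=801, n_out=4, dense=64,
                            filters=(16, 32, 64, 128, 256), k=3):
    """Arithmetic oracle: conv W+b, BN gamma+beta, dense W+b, layer by layer."""
    total = 0
    c_in = 1
    for c in filters:
        total += c * c_in * k + c          # convolution
        total += 2 * c                     # batch norm
        c_in = c
    total += c_in * dense + dense          # hidden dense
    total += dense * n_out + n_out         # output
    return total


class TestArchitecture:
    def test_classification_head_has_four_outputs(self):
        bm = build_model(CNNSpec(), "classify", 801)
        assert bm.shape_trace()[-1][1] == (4,)

    def test_pca_input_builds_without_pooling_regression_head(self):
        bm = build_model(CNNSpec.for_input(10), "regress", 10)
        assert bm.shape_trace()[-1][1] == (1,)
        # no downsampling: positional extent stays 10 through the blocks
        conv_shapes = [s for name, s in bm.shape_trace() if name == "Conv1d"]
        assert all(s[1] == 10 for s in conv_shapes)

    def test_too_short_input_error_names_block(self):
        with pytest.raises(ConfigurationError, match="block"):
            build_model(CNNSpec(), "classify", 8)

    def test_parameter_count_matches_arithmetic_oracle(self):
        bm = build_model(CNNSpec(), "classify", 801)
        assert bm.n_params == closed_form_param_count()
        bm_r = build_model(CNNSpec.for_input(10), "regress", 10)
        assert bm_r.n_params == closed_form_param_count(10, n_out=1)

    def test_parameter_count_independent_of_batch_size(self):
        X = np.random.default_rng(0).standard_normal((12, 64))
        y = np.array([0, 1, 2, 3] * 3)
        for bs in (1, 5, 12):
            m = SpectralCNN((X, y), task="classify",
                            config=TrainConfig(seed=0, batch_size=bs))
            res = m.fit(epochs=1, record_val=False)
            assert res.model.n_params == closed_form_param_count(64)

    def test_five_blocks_enforced(self):
        with pytest.raises(ConfigurationError):
            CNNSpec(conv_filters=(16, 32))


class TestSchedule:
    def test_lr_at_epoch_100_is_64_micro(self):
        assert TrainConfig().learning_rate(100) == pytest.approx(6.4e-5)

    def test_schedule_closed_form_every_epoch(self):
        cfg = TrainConfig(lr0=1e-4, lr_decay=0.8, decay_every=50)
        for epoch in range(0, 300, 7):
            assert cfg.learning_rate(epoch) == pytest.approx(
                1e-4 * 0.8 ** (epoch // 50))

    def test_history_records_schedule(self):
        X = np.random.default_rng(1).standard_normal((8, 64))
        y = np.array([0, 1] * 4)
        cfg = TrainConfig(seed=0, lr0=1e-3, decay_every=2)
        res = SpectralCNN((X, y), task="classify", config=cfg).fit(
            epochs=5, record_val=False)
        np.testing.assert_allclose(
            res.history["lr"], [cfg.learning_rate(e) for e in range(5)])

    def test_validation_rejects_bad_config(self):
        with pytest.raises(ValueError):
            TrainConfig(lr0=0.0)
        with pytest.raises(ValueError):
            TrainConfig(batch_size=0)


@pytest.fixture(scope="module")
def tiny_train():
    """Ten spectra, easily memorised (two well-separated classes)."""
    ds = simulate_origin_dataset(GeneratorConfig(seed=23), n_batches=1,
                                 n_per_batch=5)
    keep = np.nonzero(ds.labels < 2)[0]
    return ds.X[keep], ds.labels[keep]


class TestTraining:
    def test_memorises_ten_samples(self, tiny_train):
        X, y = tiny_train
        res = SpectralCNN((X, y), task="classify",
                          config=TrainConfig(seed=0, lr0=1e-3)).fit(
            epochs=120, record_val=False)
        assert res.history["train_loss"].iloc[-1] < 1e-2
        assert np.array_equal(res.predict(X), y)

    def test_same_seed_identical_results(self, tiny_train):
        X, y = tiny_train
        runs = [SpectralCNN((X, y), task="classify",
                            config=TrainConfig(seed=9, lr0=1e-3)).fit(
                    epochs=5, record_val=False) for _ in range(2)]
        np.testing.assert_array_equal(runs[0].predict_proba(X),
                                      runs[1].predict_proba(X))
        assert runs[0].history["train_loss"].equals(
            runs[1].history["train_loss"])

    def test_probability_rows_sum_to_one(self, tiny_train):
        X, y = tiny_train
        res = SpectralCNN((X, y), task="classify",
                          config=TrainConfig(seed=0)).fit(epochs=2,
                                                          record_val=False)
        p = res.predict_proba(X)
        np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)
        assert np.all(p >= 0)

    def test_divergent_loss_aborts_with_epoch_and_lr(self, tiny_train):
        X, _ = tiny_train
        y_bad = np.full(X.shape[0], np.inf)
        with pytest.raises(RuntimeError, match="epoch"):
            SpectralCNN((X, y_bad), task="regress",
                        config=TrainConfig(seed=0)).fit(epochs=1,
                                                        record_val=False)

    def test_feature_length_mismatch_rejected(self, tiny_train):
        X, y = tiny_train
        res = SpectralCNN((X, y), task="classify",
                          config=TrainConfig(seed=0)).fit(epochs=1,
                                                          record_val=False)
        with pytest.raises(ValueError, match="features"):
            res.predict(X[:, :100])

    def test_checkpoint_round_trip(self, tiny_train, tmp_path):
        X, y = tiny_train
        res = SpectralCNN((X, y), task="classify",
                          config=TrainConfig(seed=0)).fit(epochs=2,
                                                          record_val=False)
        res.save(tmp_path / "ckpt")
        back = CNNResults.load(tmp_path / "ckpt")
        np.testing.assert_allclose(back.predict_proba(X),
                                   res.predict_proba(X), atol=1e-6)


class TestBaselines:
    def test_svm_separates_linearly_separable_toy(self):
        X = np.array([[0.0, 0.0], [0.0, 1.0], [10.0, 10.0], [10.0, 11.0]])
        y = np.array([0, 0, 1, 1])
        pred = svm_baseline(X, y, X, folds=2)
        assert np.array_equal(pred, y)

    def test_depth_one_threshold_split_is_perfect(self):
        X = np.array([[0.1], [0.2], [0.9], [1.0], [0.15], [0.95]])
        y = np.array([0, 0, 1, 1, 0, 1])
        pred = dt_baseline(X, y, X, folds=2)
        assert np.array_equal(pred, y)

    def test_single_class_training_rejected(self):
        X = np.zeros((4, 3))
        with pytest.raises(ValueError):
            svm_baseline(X, np.zeros(4, dtype=int), X)

    def test_baselines_improve_with_scatter_removal(self):
        """Directional check: S-G+SNV helps on scatter-heavy spectra."""
        from fritqc.preprocess import pipeline_sg_snv
        cfg = GeneratorConfig(seed=31, scatter_slope_sd=0.25,
                              scatter_offset_sd=0.3, noise_sd=0.01)
        ds = simulate_origin_dataset(cfg, n_batches=2, n_per_batch=12)
        rng = np.random.default_rng(0)
        idx = rng.permutation(ds.n)
        tr, te = idx[:64], idx[64:]
        accs = {}
        for name, X in (("raw", ds.X), ("snv", pipeline_sg_snv(ds.X))):
            pred = dt_baseline(X[tr], ds.labels[tr], X[te], folds=3)
            accs[name] = np.mean(pred == ds.labels[te])
        assert accs["snv"] >= accs["raw"]
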