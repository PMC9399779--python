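"""Cross-validation layout, training protocol mechanics, and prediction."""

import numpy as np
import pytest

import scalestack.classifiers as clf
from scalestack.classifiers import (ProbTensor, TrainConfig, make_cv_splits,
                                    predict_logits, train_scale_model)
from scalestack.metrics import auc


class TestTrainConfigDefaults:
    def test_reference_learning_rate_table(self):
        cfg = TrainConfig()
        assert cfg.lr_for(256) == 0.0051
        assert cfg.lr_for(512) == 0.00034
        assert cfg.lr_for(1024) == 0.000181
        assert cfg.lr_for(2048) == 0.0000918

    def test_reference_batch_sizes(self):
        cfg = TrainConfig()
        assert [cfg.batch_for(s) for s in (256, 512, 1024, 2048)] == [512, 256, 180, 75]

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(lr_table={256: -1.0})
        with pytest.raises(ValueError):
            TrainConfig(plateau_patience=0)


class TestMakeCvSplits:
    def test_n100_arithmetic(self):
        folds = make_cv_splits(100, seed=0)
        assert len(folds) == 5
        for f in folds:
            assert len(f.test) == 20
            assert len(f.train) == 72
            assert len(f.validation) == 8

    def test_partition_invariants_many_random_cases(self, rng):
        for _ in range(1000):
            n = int(rng.integers(60, 400))
            seed = int(rng.integers(0, 2**31))
            folds = make_cv_splits(n, seed)
            test = set(folds[0].test.tolist())
            for f in folds:
                assert set(f.test.tolist()) == test
                tr, va = set(f.train.tolist()), set(f.validation.tolist())
                assert not (test & tr) and not (test & va) and not (tr & va)
                assert len(test | tr | va) == n

    def test_deterministic(self):
        a, b = make_cv_splits(123, seed=9), make_cv_splits(123, seed=9)
        for fa, fb in zip(a, b):
            assert np.array_equal(fa.train, fb.train)
            assert np.array_equal(fa.validation, fb.validation)

    def test_validation_blocks_disjoint_across_folds(self):
        folds = make_cv_splits(200, seed=1)
        blocks = [set(f.validation.tolist()) for f in folds]
        for i in range(len(blocks)):
            for j in range(i + 1, len(blocks)):
                assert not blocks[i] & blocks[j]

    def test_too_small_n_rejected(self):
        with pytest.raises(ValueError):
            make_cv_splits(5, seed=0)


def _separable_task(n=300, scale=32, seed=0):
    """Bright-square-present labels: linearly separable at this scale."""
    rng = np.random.default_rng(seed)
    labels = (rng.random((n, 1)) < 0.5).astype(np.int8)
    imgs = np.empty((n, scale, scale), np.uint8)
    for i in range(n):
        img = 120 + 10 * rng.standard_normal((scale, scale))
        if labels[i, 0]:
            img[8:24, 8:24] += 60.0
        imgs[i] = np.clip(img, 0, 255)
    return imgs, labels


class TestTrainScaleModel:
    def test_separable_finding_reaches_high_auc(self):
        imgs, labels = _separable_task()
        fold = make_cv_splits(300, seed=0)[0]
        cfg = TrainConfig(lr_table={32: 2e-3}, batch_table={32: 32},
                          max_epochs=30, seed=0)
        handle = train_scale_model(imgs, labels, 32, fold, cfg)
        logits = predict_logits(handle, imgs[fold.validation])
        assert auc(labels[fold.validation][:, 0], logits[:, 0]) >= 0.95

    def test_plateau_halves_lr_once_per_event(self, monkeypatch):
        """With validation loss pinned constant, the learning rate halves
        after every 3 non-improving epochs."""
        monkeypatch.setattr(clf, "_dataset_loss", lambda *a, **k: 1.0)
        imgs, labels = _separable_task(n=60)
        fold = make_cv_splits(60, seed=0)[0]
        cfg = TrainConfig(lr_table={32: 1e-3}, batch_table={32: 32},
                          max_epochs=8, early_stop_patience=100, seed=0)
        handle = train_scale_model(imgs, labels, 32, fold, cfg)
        lrs = handle.history["lr"].tolist()
        assert lrs == [1e-3] * 4 + [5e-4] * 3 + [2.5e-4]

    def test_early_stop_after_patience_epochs(self, monkeypatch):
        monkeypatch.setattr(clf, "_dataset_loss", lambda *a, **k: 1.0)
        imgs, labels = _separable_task(n=60)
        fold = make_cv_splits(60, seed=0)[0]
        cfg = TrainConfig(lr_table={32: 1e-3}, batch_table={32: 32},
                          max_epochs=50, early_stop_patience=4,
                          plateau_patience=100, seed=0)
        handle = train_scale_model(imgs, labels, 32, fold, cfg)
        assert len(handle.history) == 5  # first epoch improves over +inf

    def test_degenerate_finding_warned_and_recorded(self):
        imgs, labels = _separable_task(n=60)
        labels = np.hstack([labels, np.zeros_like(labels)])
        fold = make_cv_splits(60, seed=0)[0]
        cfg = TrainConfig(lr_table={32: 1e-3}, batch_table={32: 32},
                          max_epochs=1, seed=0)
        with pytest.warns(UserWarning, match="degenerate"):
            handle = train_scale_model(imgs, labels, 32, fold, cfg,
                                       finding_names=["ok", "empty"])
        assert handle.excluded_findings == ["empty"]

    def test_scale_mismatch_rejected(self):
        imgs, labels = _separable_task(n=60)
        fold = make_cv_splits(60, seed=0)[0]
        with pytest.raises(ValueError):
            train_scale_model(imgs, labels, 64, fold, TrainConfig())


class TestPredictLogits:
    @pytest.fixture(scope="class")
    def trained(self):
        imgs, labels = _separable_task(n=80)
        fold = make_cv_splits(80, seed=0)[0]
        cfg = TrainConfig(lr_table={32: 1e-3}, batch_table={32: 32},
                          max_epochs=2, seed=0)
        return train_scale_model(imgs, labels, 32, fold, cfg), imgs

    def test_eval_deterministic(self, trained):
        handle, imgs = trained
        a = predict_logits(handle, imgs[:10])
        b = predict_logits(handle, imgs[:10])
        assert np.array_equal(a, b)

    def test_probabilities_strictly_inside_unit_interval(self, trained):
        handle, imgs = trained
        logits = predict_logits(handle, imgs[:20])
        pt = ProbTensor([f"i{k}" for k in range(20)], handle.findings, [32],
                        logits[:, :, None])
        assert ((pt.probabilities > 0) & (pt.probabilities < 1)).all()

    def test_scale_mismatch_rejected(self, trained):
        handle, _ = trained
        with pytest.raises(ValueError):
            predict_logits(handle, np.zeros((2, 64, 64), np.uint8))


def test_checkpoint_round_trip(tmp_path):
    from scalestack.classifiers import load_model, save_model

    imgs, labels = _separable_task(n=60)
    fold = make_cv_splits(60, seed=0)[0]
    cfg = TrainConfig(lr_table={32: 1e-3}, batch_table={32: 32},
                      max_epochs=2, seed=0)
    handle = train_scale_model(imgs, labels, 32, fold, cfg)
    save_model(handle, tmp_path / "scale32")
    restored = load_model(tmp_path / "scale32")
    assert np.array_equal(predict_logits(handle, imgs[:8]),
                          predict_logits(restored, imgs[:8]))


def test_training_loss_running_best_non_increasing():
    imgs, labels = _separable_task(n=120)
    fold = make_cv_splits(120, seed=1)[0]
    cfg = TrainConfig(lr_table={32: 2e-3}, batch_table={32: 32},
                      max_epochs=10, seed=1)
    handle = train_scale_model(imgs, labels, 32, fold, cfg)
    best = np.minimum.accumulate(handle.history["train_loss"])
    assert (np.diff(best) <= 1e-12).all()
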