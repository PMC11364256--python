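"""Video-level aggregation, balanced sampling, schedules and training."""

import numpy as np
import pytest

from echoviews.classifier import (BackboneConfig, TrainConfig,
                                  aggregate_features, aggregate_logits,
                                  build_model, desk_train_config,
                                  forward_frames, load_checkpoint,
                                  lr_at_epoch, make_balanced_sampler,
                                  predict_view, save_checkpoint,
                                  train_classifier)
from echoviews.pipeline import evaluate_clips
from echoviews.preprocess import PreprocessConfig
from echoviews.synthdata import (DatasetConfig, GeneratorConfig,
                                 generate_dataset)

TOY_GEN = GeneratorConfig(frame_size=128)
TOY_PP = PreprocessConfig(target_size=64)


class TestAggregation:
    def test_logit_mean(self):
        assert np.allclose(aggregate_logits([[1, 2], [3, 4]]), [2, 3])

    def test_single_row_identity(self):
        assert np.allclose(aggregate_logits([[5, 1, 0]]), [5, 1, 0])

    def test_permutation_invariance_and_linearity(self, rng):
        fl = rng.normal(size=(7, 4))
        assert np.allclose(aggregate_logits(fl), aggregate_logits(fl[::-1]))
        assert np.allclose(aggregate_logits(2 * fl + 1),
                           2 * aggregate_logits(fl) + 1)

    def test_feature_mean_and_idempotence(self, rng):
        assert np.allclose(aggregate_features([[1, 3], [3, 1]]), [2, 2])
        v = rng.normal(size=5)
        assert np.allclose(aggregate_features(np.tile(v, (4, 1))), v)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_logits(np.empty((0, 3)))


class TestPredictView:
    def test_argmax(self):
        assert predict_view([0.1, 2.0, -1.0]) == 1

    def test_outlier_slot_never_predicted(self):
        assert predict_view([1.0, 2.0, 5.0], outlier_exposure=True) == 1

    def test_tie_breaks_to_lowest_index(self):
        assert predict_view([3.0, 3.0]) == 0

    def test_shift_invariance(self, rng):
        vl = rng.normal(size=6)
        assert predict_view(vl) == predict_view(vl + 17.3)


class TestBalancedSampler:
    def test_uniform_over_imbalanced_classes(self):
        labels = [0] * 1 + [1] * 99
        stream = make_balanced_sampler(labels, np.random.default_rng(0))
        draws = np.array([next(stream) for _ in range(10000)])
        freq0 = (draws == 0).mean()  # index 0 is the only class-0 clip
        assert abs(freq0 - 0.5) < 3 * np.sqrt(0.25 / 10000)

    def test_single_class_stream(self):
        stream = make_balanced_sampler([5, 5, 5], np.random.default_rng(0))
        assert {next(stream) for _ in range(50)} <= {0, 1, 2}

    def test_deterministic_given_seed(self):
        a = make_balanced_sampler([0, 0, 1], np.random.default_rng(3))
        b = make_balanced_sampler([0, 0, 1], np.random.default_rng(3))
        assert [next(a) for _ in range(20)] == [next(b) for _ in range(20)]

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            make_balanced_sampler([], np.random.default_rng(0))


def test_lr_schedule_follows_step_drops():
    cfg = TrainConfig()  # drops after epochs 150 and 250, factor 10
    assert lr_at_epoch(cfg, 149) == pytest.approx(1e-4)
    assert lr_at_epoch(cfg, 151) == pytest.approx(1e-5)
    assert lr_at_epoch(cfg, 251) == pytest.approx(1e-6)


@pytest.fixture(scope="module")
def toy_dataset():
    cfg = DatasetConfig(n_classes=2, train_per_class=10, val_per_class=2,
                        test_per_class=2, frames_per_clip=6,
                        generator=TOY_GEN)
    return generate_dataset(cfg, seed=1)


class TestTraining:
    def test_overfits_two_class_toy_set(self, toy_dataset):
        tc = desk_train_config(seed=0, epochs=30)
        tm = train_classifier(toy_dataset.train, None, tc,
                              BackboneConfig(num_known_classes=2), TOY_PP)
        records, _ = evaluate_clips(tm, toy_dataset.train, TOY_PP)
        acc = np.mean([r.predicted_class == r.true_label for r in records])
        assert acc == 1.0
        # log carries one entry per epoch with the scheduled lr
        assert len(tm.log) == 30
        assert tm.log[0]["lr"] == pytest.approx(tc.lr)

    def test_unknowns_in_training_rejected_without_exposure(self, toy_dataset):
        import dataclasses
        cfg = DatasetConfig(n_classes=2, train_per_class=3, val_per_class=2,
                            test_per_class=2, frames_per_clip=4,
                            generator=TOY_GEN, outlier_exposure=True)
        ds = generate_dataset(cfg, seed=0)
        with pytest.raises(ValueError, match="outlier_exposure"):
            train_classifier(ds.train, None, desk_train_config(epochs=1),
                             BackboneConfig(num_known_classes=2), TOY_PP)

    def test_outlier_exposure_trains_with_extra_logit(self):
        cfg = DatasetConfig(n_classes=2, train_per_class=3, val_per_class=2,
                            test_per_class=2, frames_per_clip=4,
                            generator=TOY_GEN, outlier_exposure=True)
        ds = generate_dataset(cfg, seed=0)
        bb = BackboneConfig(num_known_classes=2, outlier_exposure=True)
        tm = train_classifier(ds.train, None, desk_train_config(epochs=2), bb,
                              TOY_PP)
        frames = np.random.default_rng(0).random((3, 64, 64)).astype(np.float32)
        fl, _ = forward_frames(frames, tm.model)
        assert fl.shape[1] == 3  # C + 1 logits

    def test_checkpoint_roundtrip(self, toy_dataset, tmp_path):
        tc = desk_train_config(seed=0, epochs=1)
        tm = train_classifier(toy_dataset.train, None, tc,
                              BackboneConfig(num_known_classes=2), TOY_PP)
        save_checkpoint(tm, tmp_path / "model")
        back = load_checkpoint(tmp_path / "model")
        x = np.random.default_rng(1).random((2, 64, 64)).astype(np.float32)
        assert np.allclose(forward_frames(x, tm.model)[0],
                           forward_frames(x, back.model)[0])
        assert back.backbone == tm.backbone

    def test_resnet50_option_is_reserved(self):
        with pytest.raises(NotImplementedError):
            build_model(BackboneConfig(architecture="resnet50_v2"))


def test_forward_frames_duplicated_frame_duplicates_logits():
    gen = np.random.default_rng(0)
    m = build_model(BackboneConfig(num_known_classes=3, embedding_dim=16))
    f = gen.random((64, 64)).astype(np.float32)
    g = gen.random((64, 64)).astype(np.float32)
    fl, ff = forward_frames(np.stack([f, f, g]), m)
    assert fl.shape == (3, 3)
    assert np.allclose(fl[0], fl[1])
    assert not np.allclose(fl[0], fl[2])
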