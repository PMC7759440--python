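"""U-net architecture contracts, early stopping, and instance separation."""

import numpy as np
import pytest

from mrideface.augmentation import AugmentSpec
from mrideface.detector import (
    AttentionUNet3D,
    ConfigError,
    DetectorConfig,
    TrainConfig,
    _loss_and_grad,
    build_detector,
    early_stop_epoch,
    load_checkpoint,
    predict_labels,
    save_checkpoint,
    separate_instances,
    train_detector,
)
from mrideface.metrics_loss import one_hot
from mrideface.phantom import LabelMap, PhantomSpec, make_head_phantom


def tiny_config(**kw):
    kw.setdefault("depth", 2)
    kw.setdefault("base_channels", 4)
    kw.setdefault("input_patch", (16, 16, 16))
    return DetectorConfig(**kw)


@pytest.fixture(scope="module")
def tiny_cohort():
    spec = PhantomSpec(grid_size=(16, 16, 16), spacing=(4.0, 4.0, 4.0))
    return [make_head_phantom(
        PhantomSpec(grid_size=(16, 16, 16), spacing=(4.0, 4.0, 4.0), seed=s))
        for s in range(3)]


class TestArchitecture:
    def test_forward_outputs_normalized_probabilities(self):
        model = build_detector(tiny_config(seed=0))
        x = np.random.default_rng(0).random((16, 16, 16, 1)).astype(np.float32)
        probs = model.forward(x)
        assert probs.shape == (16, 16, 16, 4)
        np.testing.assert_allclose(probs.sum(axis=-1), 1.0, atol=1e-6)

    def test_attention_gates_add_parameters_and_both_run(self):
        with_att = build_detector(tiny_config(attention_gates=True))
        without = build_detector(tiny_config(attention_gates=False))
        assert with_att.n_parameters() > without.n_parameters()
        x = np.random.default_rng(1).random((16, 16, 16, 1)).astype(np.float32)
        for model in (with_att, without):
            assert model.forward(x).shape == (16, 16, 16, 4)

    def test_same_seed_same_input_same_output(self):
        x = np.random.default_rng(2).random((16, 16, 16, 1)).astype(np.float32)
        a = build_detector(tiny_config(seed=5)).forward(x)
        b = build_detector(tiny_config(seed=5)).forward(x)
        np.testing.assert_array_equal(a, b)

    def test_patch_depth_mismatch_rejected(self):
        with pytest.raises(ConfigError, match="divisible"):
            DetectorConfig(depth=4, input_patch=(20, 20, 20))

    def test_gradients_match_finite_differences(self):
        cfg = DetectorConfig(depth=2, base_channels=4, input_patch=(8, 8, 8), seed=0)
        model = AttentionUNet3D(cfg)
        rng = np.random.default_rng(1)
        x = rng.random((8, 8, 8, 1)).astype(np.float32)
        y = one_hot(rng.integers(0, 4, (8, 8, 8)))
        probs, cache = model.forward(x, want_cache=True)
        _, dlogits = _loss_and_grad(probs, y, 0.1)
        grads = model.backward(dlogits, cache)
        eps = 1e-3
        for name in ("enc0a.w", "dec0b.w", "att0.psi.w", "head.w"):
            p = model.params[name]
            idx = tuple(rng.integers(0, s) for s in p.shape)
            old = p[idx]
            p[idx] = old + eps
            up, _ = _loss_and_grad(model.forward(x), y, 0.1)
            p[idx] = old - eps
            down, _ = _loss_and_grad(model.forward(x), y, 0.1)
            p[idx] = old
            fd = (up - down) / (2 * eps)
            assert grads[name][idx] == pytest.approx(fd, rel=0.05, abs=1e-6)


class TestEarlyStopping:
    def test_plateau_sequence_stops_after_patience(self):
        scores = [0.5, 0.6, 0.6, 0.6, 0.6, 0.6, 0.6]
        assert early_stop_epoch(scores, patience=5) == (2, 7)

    def test_monotone_improvement_never_triggers(self):
        scores = [0.1 * i for i in range(1, 11)]
        best, stop = early_stop_epoch(scores, patience=5)
        assert (best, stop) == (10, 10)

    def test_peak_at_epoch_23_stops_at_28(self):
        """A validation trajectory peaking at epoch 23 stops 5 epochs later."""
        rng = np.random.default_rng(0)
        scores = list(np.linspace(0.3, 0.821, 23))   # maximum at epoch 23
        scores += list(0.79 + 0.02 * rng.random(10))  # no further improvement
        assert early_stop_epoch(scores, patience=5) == (23, 28)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_rule(self, seed):
        rng = np.random.default_rng(seed)
        scores = list(rng.random(rng.integers(1, 40)))
        patience = int(rng.integers(1, 8))
        best, stop = early_stop_epoch(scores, patience)
        # brute force: walk epochs, track first argmax, stop at gap == patience
        bf_best, bf_stop = 1, len(scores)
        for e in range(1, len(scores) + 1):
            if scores[e - 1] > scores[bf_best - 1]:
                bf_best = e
            if e - bf_best == patience:
                bf_stop = e
                break
        assert (best, stop) == (bf_best, bf_stop)
        assert stop <= best + patience


class TestTraining:
    def test_micro_run_records_history_and_checkpoints(self, tiny_cohort, tmp_path):
        model = build_detector(tiny_config(seed=0))
        tconf = TrainConfig(max_epochs=2, k_augment_train=1, k_augment_val=0, seed=0)
        model, history = train_detector(
            model, tiny_cohort[:2], tiny_cohort[2:], tconf, AugmentSpec(seed=0))
        assert len(history.train_loss) == len(history.val_dice) == 2
        assert history.stopped_epoch == 2
        assert 1 <= history.best_epoch <= 2
        assert history.val_dice[history.best_epoch - 1] == max(history.val_dice)
        save_checkpoint(model, tmp_path / "m.npz")
        back = load_checkpoint(tmp_path / "m.npz")
        vol = tiny_cohort[0][0]
        np.testing.assert_array_equal(
            predict_labels(model, vol).data, predict_labels(back, vol).data)

    def test_empty_cohorts_rejected(self):
        model = build_detector(tiny_config())
        with pytest.raises(ValueError):
            train_detector(model, [], [], TrainConfig())


class TestPredictLabels:
    def test_untrained_model_yields_valid_codes_on_input_lattice(self, tiny_cohort):
        model = build_detector(tiny_config(seed=3))
        vol = tiny_cohort[0][0]
        labels = predict_labels(model, vol)
        assert labels.data.shape == vol.data.shape
        assert set(np.unique(labels.data)) <= {0, 1, 2, 3}

    def test_non_divisible_lattice_padded_and_cropped(self):
        model = build_detector(tiny_config(seed=3))
        from mrideface.io_formats import Volume
        vol = Volume(np.random.default_rng(0).random((14, 18, 15)),
                     (1, 1, 1), np.eye(4))
        labels = predict_labels(model, vol)
        assert labels.data.shape == (14, 18, 15)

    def test_deterministic(self, tiny_cohort):
        model = build_detector(tiny_config(seed=3))
        vol = tiny_cohort[0][0]
        a = predict_labels(model, vol)
        b = predict_labels(model, vol)
        np.testing.assert_array_equal(a.data, b.data)


class TestSeparateInstances:
    def test_phantom_ground_truth_yields_five_regions(self, default_phantom):
        _, labels = default_phantom
        regions = separate_instances(labels)
        assert regions.n_present() == 5
        # left/right by lateral centroid: left instances at lower index
        for name in ("eye", "ear"):
            left = np.mean(np.nonzero(regions.mask(f"{name}_left"))[0])
            right = np.mean(np.nonzero(regions.mask(f"{name}_right"))[0])
            assert left < right

    def test_speckle_below_min_size_discarded(self, default_phantom):
        _, labels = default_phantom
        noisy = labels.data.copy()
        noisy[0, 0, 0:2] = 1  # 2-voxel eye speckle
        regions = separate_instances(LabelMap(noisy), min_voxels=10)
        assert regions.n_present() == 5
        assert not regions.eye_left[0, 0, 0]
        assert not regions.eye_right[0, 0, 0]

    def test_all_background_reports_everything_absent(self):
        regions = separate_instances(LabelMap(np.zeros((8, 8, 8), dtype=int)))
        assert regions.n_present() == 0
        assert not any(regions.present.values())
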