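"""Network contracts, BCE analytics, IoU, training loop, and metrics."""
import numpy as np
import pytest

from kneejsw import _nn
from kneejsw.imaging import LabelMask
from kneejsw.segmentation import (
    ProbabilityMaps,
    TrainingConfig,
    bce_loss,
    build_resunet18,
    build_resunet50,
    iou,
    labels_from_probabilities,
    load_checkpoint,
    mean_iou,
    one_hot,
    overfitting_score,
    parameter_count,
    predict_mask,
    predict_probabilities,
    save_checkpoint,
    train,
)

from conftest import small_phantom_pairs


@pytest.fixture(scope="module")
def tiny_model():
    return build_resunet18(base_width=8, seed=0)


class TestNetworkContracts:
    def test_forward_shape_and_range(self, tiny_model):
        rng = np.random.default_rng(0)
        maps = predict_probabilities(tiny_model, rng.random((256, 256)))
        assert maps.maps.shape == (4, 256, 256)
        assert maps.maps.min() >= 0.0 and maps.maps.max() <= 1.0

    def test_forward_deterministic_in_eval(self, tiny_model):
        x = np.random.default_rng(1).random((64, 64))
        a = predict_probabilities(tiny_model, x).maps
        b = predict_probabilities(tiny_model, x).maps
        assert np.array_equal(a, b)

    def test_side_not_divisible_by_32_rejected(self, tiny_model):
        with pytest.raises(ValueError, match="divisible by 32"):
            tiny_model.forward_logits(np.zeros((50, 50), np.float32))

    def test_18_layer_variant_is_smaller_than_50(self):
        n18 = parameter_count(build_resunet18(seed=0))
        n50 = parameter_count(build_resunet50(seed=0))
        assert n18 < n50

    def test_dilated_stage_keeps_shapes(self):
        model = build_resunet18(base_width=8, dilated=True, seed=0)
        maps = predict_probabilities(model, np.zeros((64, 64), np.float32))
        assert maps.maps.shape == (4, 64, 64)


class TestBCELoss:
    def test_perfect_prediction_is_near_zero(self):
        y = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert bce_loss(y, y) <= 2e-7

    def test_uniform_half_probability_is_ln2(self):
        pred = np.full((4, 8, 8), 0.5)
        target = np.random.default_rng(0).integers(0, 2, (4, 8, 8)).astype(float)
        assert bce_loss(pred, target) == pytest.approx(np.log(2), rel=1e-12)

    def test_single_pixel_analytic_value(self):
        assert bce_loss(np.array([0.25]), np.array([1.0])) == pytest.approx(
            -np.log(0.25), rel=1e-9)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bce_loss(np.zeros((2, 2)), np.zeros((3, 3)))

    def test_fused_training_loss_matches_public_bce(self):
        rng = np.random.default_rng(3)
        logits = rng.standard_normal((1, 4, 8, 8)).astype(np.float32)
        target = rng.integers(0, 2, (1, 4, 8, 8)).astype(np.float32)
        fused = float(_nn.sigmoid_bce(_nn.Tensor(logits), target).data)
        probs = 1 / (1 + np.exp(-logits.astype(np.float64)))
        assert fused == pytest.approx(bce_loss(probs[0], target[0]), rel=1e-5)


class TestArgmaxLabeling:
    def test_clear_winner_maps_to_femur(self):
        maps = ProbabilityMaps(maps=np.array([0.9, 0.1, 0.2, 0.3], np.float32)
                               .reshape(4, 1, 1))
        assert labels_from_probabilities(maps).labels[0, 0] == 1

    def test_tie_resolves_to_lowest_class_index(self):
        # femur (class 1) ties fibula (class 3): femur wins
        maps = ProbabilityMaps(maps=np.array([0.5, 0.5, 0.1, 0.1], np.float32)
                               .reshape(4, 1, 1))
        assert labels_from_probabilities(maps).labels[0, 0] == 1
        # tibia (class 2) ties fibula (class 3): tibia wins
        maps = ProbabilityMaps(maps=np.array([0.1, 0.5, 0.5, 0.2], np.float32)
                               .reshape(4, 1, 1))
        assert labels_from_probabilities(maps).labels[0, 0] == 2

    def test_background_dominant_gives_zero_mask(self):
        maps = ProbabilityMaps(maps=np.stack([np.zeros((4, 4))] * 3
                                             + [np.ones((4, 4))]).astype(np.float32))
        assert np.all(labels_from_probabilities(maps).labels == 0)


class TestIoU:
    def test_identical_masks_score_one(self, parabolic_phantom):
        mask = parabolic_phantom[1]
        assert iou(mask, mask, 1) == 1.0
        assert mean_iou(mask, mask) == 1.0

    def test_disjoint_regions_score_zero(self):
        a = np.zeros((10, 10), np.uint8)
        b = np.zeros((10, 10), np.uint8)
        a[:5], b[5:] = 1, 1
        assert iou(LabelMask(labels=a), LabelMask(labels=b), 1) == 0.0

    def test_half_overlapping_squares(self):
        # two 10x10 class-1 squares overlapping in a 10x5 block: 50/150
        a = np.zeros((10, 20), np.uint8)
        b = np.zeros((10, 20), np.uint8)
        a[:, 0:10] = 1
        b[:, 5:15] = 1
        assert iou(LabelMask(labels=a), LabelMask(labels=b), 1) == pytest.approx(1 / 3)

    def test_symmetric_and_flip_invariant(self):
        rng = np.random.default_rng(0)
        a = LabelMask(labels=rng.integers(0, 4, (16, 16)).astype(np.uint8))
        b = LabelMask(labels=rng.integers(0, 4, (16, 16)).astype(np.uint8))
        for c in range(4):
            assert iou(a, b, c) == iou(b, a, c)
            assert iou(a, b, c) == iou(LabelMask(labels=a.labels[:, ::-1]),
                                       LabelMask(labels=b.labels[:, ::-1]), c)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            iou(np.zeros((2, 2)), np.zeros((3, 3)), 0)


class TestOverfittingScore:
    @pytest.mark.parametrize("val,tr,expected", [
        (0.047, 0.008, 0.830),   # high-gap model
        (0.410, 0.409, 0.002),   # underfit model, near-zero gap
        (0.011, 0.005, 0.545),
        (0.006, 0.004, 0.333),
    ])
    def test_printed_loss_pairs(self, val, tr, expected):
        assert round(overfitting_score(val, tr), 3) == expected

    def test_equal_losses_score_zero(self):
        assert overfitting_score(0.123, 0.123) == 0.0

    def test_nonpositive_val_loss_rejected(self):
        with pytest.raises(ValueError):
            overfitting_score(0.0, 0.1)


class TestTraining:
    def test_two_runs_same_seed_identical_history(self, tiny_train_pairs):
        cfg = TrainingConfig(max_epochs=3, batch_size=2, seed=11)
        histories = []
        for _ in range(2):
            model = build_resunet18(base_width=8, seed=5)
            _, hist = train(model, tiny_train_pairs, tiny_train_pairs, cfg)
            histories.append(hist)
        assert histories[0]["train_loss"] == histories[1]["train_loss"]
        assert histories[0]["val_loss"] == histories[1]["val_loss"]

    def test_early_stop_on_worsening_validation(self, tiny_train_pairs):
        # validation masks are inverted relative to training: fitting the
        # training set drives validation loss up from the start
        img, mask = tiny_train_pairs[0]
        inverted = LabelMask(labels=np.where(mask.labels == 0, 1, 0).astype(np.uint8))
        cfg = TrainingConfig(max_epochs=50, early_stop_patience=3, batch_size=1,
                             seed=0)
        model = build_resunet18(base_width=8, seed=1)
        _, hist = train(model, [(img, mask)], [(img, inverted)], cfg)
        best = hist["best_epoch"]
        assert len(hist["val_loss"]) <= best + cfg.early_stop_patience + 1
        assert int(np.argmin(hist["val_loss"])) == best

    def test_empty_dataset_rejected(self, tiny_train_pairs):
        with pytest.raises(ValueError):
            train(build_resunet18(base_width=8), [], tiny_train_pairs,
                  TrainingConfig(max_epochs=1))

    def test_nan_input_aborts_with_diagnostic(self, tiny_train_pairs):
        img, mask = tiny_train_pairs[0]
        bad = np.full_like(img.pixels, np.nan)
        with pytest.raises(RuntimeError, match="non-finite"):
            train(build_resunet18(base_width=8), [(bad, mask)], [(bad, mask)],
                  TrainingConfig(max_epochs=2, jitter=0.0))

    def test_checkpoint_round_trip(self, tiny_train_pairs, tmp_path):
        cfg = TrainingConfig(max_epochs=2, batch_size=2, seed=0)
        model = build_resunet18(base_width=8, seed=2)
        model, hist = train(model, tiny_train_pairs, tiny_train_pairs, cfg)
        path = tmp_path / "model.npz"
        save_checkpoint(model, path, hist)
        loaded, hist2 = load_checkpoint(path)
        img = tiny_train_pairs[0][0]
        assert np.array_equal(predict_mask(model, img).labels,
                              predict_mask(loaded, img).labels)
        assert hist2["best_epoch"] == hist["best_epoch"]


class TestGradients:
    def test_conv_gradient_matches_numeric(self):
        rng = np.random.default_rng(0)
        x = _nn.Parameter(rng.standard_normal((1, 2, 6, 6)).astype(np.float32))
        w = _nn.Parameter((rng.standard_normal((3, 2, 3, 3)) * 0.5).astype(np.float32))
        y = rng.integers(0, 2, (1, 3, 3, 3)).astype(np.float32)

        loss = _nn.sigmoid_bce(_nn.conv2d(x, w, stride=2, padding=1), y)
        loss.backward()

        def scalar_loss():
            out = _nn.conv2d(_nn.Tensor(x.data), _nn.Parameter(w.data),
                             stride=2, padding=1)
            return float(_nn.sigmoid_bce(out, y).data)

        for p in (x, w):
            numeric = np.zeros_like(p.data, dtype=np.float64)
            it = np.nditer(p.data, flags=["multi_index"])
            for _ in it:
                i = it.multi_index
                orig = p.data[i]
                p.data[i] = orig + 1e-3
                up = scalar_loss()
                p.data[i] = orig - 1e-3
                down = scalar_loss()
                p.data[i] = orig
                numeric[i] = (up - down) / 2e-3
            rel = np.max(np.abs(numeric - p.grad)) / (np.max(np.abs(numeric)) + 1e-12)
            assert rel < 5e-3
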