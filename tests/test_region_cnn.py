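"""Architecture fidelity, preprocessing, training contracts of region CNNs."""

import numpy as np
import pytest

from equipain import (
    RegionCNNError,
    RegionModelSpec,
    RegionPrediction,
    TrainedRegionModel,
    build_architecture,
    fit_region_model_arrays,
    make_region_arrays,
    predict_region,
    preprocess_image,
)
from equipain.region_cnn import _resize_bilinear


class TestArchitecture:
    def test_eyes_feature_map_arithmetic(self):
        """80×80, valid 7×7 conv → 74; pool → 37; 5×5 conv → 33; pool → 16."""
        shapes = {s.name: s.output_shape for s in build_architecture(RegionModelSpec.for_region("eyes"))}
        assert shapes["conv1"] == (74, 74, 60)
        assert shapes["pool1"] == (37, 37, 60)
        assert shapes["conv2"] == (33, 33, 32)
        assert shapes["pool2"] == (16, 16, 32)
        assert shapes["flatten"] == (16 * 16 * 32,)

    @pytest.mark.parametrize("region", ["ears", "eyes", "mouth_nostrils"])
    def test_layer_sequence_and_softmax3_head(self, region):
        report = build_architecture(RegionModelSpec.for_region(region))
        names = [s.name for s in report]
        assert names == [
            "input", "conv1", "pool1", "bn1", "conv2", "pool2", "bn2",
            "flatten", "dense1", "dense_out",
        ]
        assert report[-1].output_shape == (3,)

    def test_reference_hyperparameters(self):
        ears = RegionModelSpec.for_region("ears")
        eyes = RegionModelSpec.for_region("eyes")
        mouth = RegionModelSpec.for_region("mouth_nostrils")
        assert (ears.conv1_filters, ears.conv1_kernel) == (60, 7)
        assert (ears.conv2_filters, ears.conv2_kernel) == (32, 5)
        assert (ears.input_size, ears.dense1, ears.epochs) == ((200, 200), 1000, 20)
        assert (eyes.input_size, eyes.dense1, eyes.epochs) == ((80, 80), 500, 30)
        assert (mouth.input_size, mouth.dense1, mouth.epochs) == ((120, 120), 1000, 30)
        assert ears.batch_size == 50 and ears.replicates == 3

    def test_too_small_input_rejected_naming_layer(self):
        spec = RegionModelSpec.for_region("eyes").replace(input_size=(6, 6))
        with pytest.raises(RegionCNNError, match="conv1"):
            build_architecture(spec)
        spec = RegionModelSpec.for_region("eyes").replace(input_size=(16, 16))
        with pytest.raises(RegionCNNError, match="conv2|pool2"):
            build_architecture(spec)


class TestPreprocess:
    def test_constant_white_image_scales_to_one(self):
        spec = RegionModelSpec.scaled("eyes")
        out = preprocess_image(np.full((32, 32), 255, dtype=np.uint8), spec)
        assert out.shape == (32, 32, 1)
        assert np.allclose(out, 1.0)

    def test_identity_resize_is_exact_division(self, rng):
        spec = RegionModelSpec.scaled("eyes")
        img = rng.integers(0, 256, (32, 32), dtype=np.uint8)
        assert np.allclose(preprocess_image(img, spec)[..., 0], img / 255.0)

    def test_checkerboard_upsampling_matches_hand_bilinear(self):
        """2×2 → 4×4: output center i maps to (i+0.5)/2 − 0.5, edge-clamped."""
        img = np.array([[0.0, 255.0], [255.0, 0.0]])
        out = _resize_bilinear(img, (4, 4))

        def sample(y, x):
            y = min(max(y, 0.0), 1.0)
            x = min(max(x, 0.0), 1.0)
            y0, x0 = int(np.floor(y)), int(np.floor(x))
            y1, x1 = min(y0 + 1, 1), min(x0 + 1, 1)
            fy, fx = y - y0, x - x0
            return (
                img[y0, x0] * (1 - fy) * (1 - fx)
                + img[y0, x1] * (1 - fy) * fx
                + img[y1, x0] * fy * (1 - fx)
                + img[y1, x1] * fy * fx
            )

        coords = [(i + 0.5) * 2 / 4 - 0.5 for i in range(4)]
        expected = np.array([[sample(y, x) for x in coords] for y in coords])
        assert np.allclose(out, expected)

    def test_unreadable_path_reports_file(self, tmp_path):
        bad = tmp_path / "missing.png"
        with pytest.raises(RegionCNNError, match="missing.png"):
            preprocess_image(bad, RegionModelSpec.scaled("ears"))


class TestRegionPrediction:
    def test_confidences_validated(self):
        with pytest.raises(RegionCNNError):
            RegionPrediction.from_confidences(np.array([0.5, 0.4, 0.4]))

    def test_argmax_recommendation(self):
        assert RegionPrediction.from_confidences(np.array([0.2, 0.2, 0.6])).recommended == 2

    def test_tie_goes_to_lowest_index(self):
        assert RegionPrediction.from_confidences(np.array([0.4, 0.4, 0.2])).recommended == 0


@pytest.fixture(scope="module")
def tiny_training_data():
    spec = RegionModelSpec.scaled("eyes", epochs=4, replicates=1)
    Xtr, ytr = make_region_arrays("eyes", 30, 1.0, 0.0, 100, spec)
    Xv, yv = make_region_arrays("eyes", 10, 1.0, 0.0, 900, spec)
    return spec, Xtr, ytr, Xv, yv


class TestTraining:
    def test_learns_separable_classes(self, tiny_training_data):
        spec, Xtr, ytr, Xv, yv = tiny_training_data
        model = fit_region_model_arrays(Xtr, ytr, Xv, yv, spec, seed=1)
        assert model.val_accuracy >= 0.8
        assert set(model.training_log.columns) == {
            "replicate", "epoch", "train_loss", "val_loss", "val_acc"
        }

    def test_same_seed_reproduces_weights_and_log(self, tiny_training_data):
        spec, Xtr, ytr, Xv, yv = tiny_training_data
        spec = spec.replace(epochs=2)
        a = fit_region_model_arrays(Xtr, ytr, Xv, yv, spec, seed=5)
        b = fit_region_model_arrays(Xtr, ytr, Xv, yv, spec, seed=5)
        assert all(np.array_equal(p, q) for p, q in zip(a.network.get_state(), b.network.get_state()))
        assert a.training_log.equals(b.training_log)
        assert a.selected_replicate == b.selected_replicate

    def test_empty_training_set_rejected(self, tiny_training_data):
        spec, Xtr, ytr, Xv, yv = tiny_training_data
        with pytest.raises(RegionCNNError, match="empty"):
            fit_region_model_arrays(Xtr[:0], ytr[:0], Xv, yv, spec, seed=1)

    def test_missing_class_recorded_as_warning(self, tiny_training_data):
        spec, Xtr, ytr, Xv, yv = tiny_training_data
        spec = spec.replace(epochs=1)
        keep = ytr != 2
        model = fit_region_model_arrays(Xtr[keep], ytr[keep], Xv, yv, spec, seed=1)
        assert any("absent" in w for w in model.training_log.attrs["warnings"])

    def test_save_load_round_trip_preserves_predictions(self, tiny_training_data, tmp_path):
        spec, Xtr, ytr, Xv, yv = tiny_training_data
        model = fit_region_model_arrays(Xtr, ytr, Xv, yv, spec.replace(epochs=2), seed=2)
        model.save(tmp_path / "model")
        again = TrainedRegionModel.load(tmp_path / "model")
        assert again.spec == model.spec
        assert np.allclose(again.predict_batch(Xv), model.predict_batch(Xv))

    def test_accuracy_non_decreasing_in_separability(self):
        """With fixed seed and sample size, validation accuracy rises with
        class separability (2-point tolerance at adjacent levels)."""
        spec = RegionModelSpec.scaled("eyes", epochs=8, replicates=1)
        accs = []
        for sep in (0.0, 0.5, 1.0):
            Xtr, ytr = make_region_arrays("eyes", 50, sep, 10.0, 70_000, spec)
            Xv, yv = make_region_arrays("eyes", 15, sep, 10.0, 80_000, spec)
            accs.append(fit_region_model_arrays(Xtr, ytr, Xv, yv, spec, seed=2).val_accuracy)
        assert accs[1] >= accs[0] - 0.02
        assert accs[2] >= accs[1] - 0.02

    def test_predict_region_consistent_with_batch(self, tiny_training_data):
        spec, Xtr, ytr, Xv, yv = tiny_training_data
        model = fit_region_model_arrays(Xtr, ytr, Xv, yv, spec.replace(epochs=2), seed=3)
        raw = (Xv[0, ..., 0] * 255.0).astype(np.uint8)
        single = predict_region(model, raw)
        batch = model.predict_batch(preprocess_image(raw, spec)[None])[0]
        assert np.allclose(single.confidences, batch, atol=1e-12)
        assert abs(single.confidences.sum() - 1.0) < 1e-6
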