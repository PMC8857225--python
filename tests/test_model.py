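"""Classifier contracts: architecture ledger, training loop, prediction."""

import dataclasses

import numpy as np
import pytest

from polarcnn import (
    ConfigError,
    LabeledCase,
    PolarMapImage,
    TrainingConfig,
    build_model,
    predict,
    predict_proba,
    train,
)
from polarcnn.model import load_weights, save_weights


def _blank_case(label, seed=0):
    rng = np.random.default_rng(seed)
    px = rng.random((256, 256, 3)).astype(np.float32)
    return LabeledCase(PolarMapImage(px), label, f"r{seed}")


class TestArchitecture:
    def test_cascade_halves_spatial_size_eight_times(self):
        model = build_model(TrainingConfig())
        shapes = [s for _, s in model.layer_shape_report]
        spatial = [s[0] for s in shapes if len(s) == 3]
        assert spatial == [256, 128, 64, 32, 16, 8, 4, 2, 1]
        assert shapes[-5] == (1, 1, 64)
        assert shapes[-4] == (64,)

    def test_first_conv_output_shape(self):
        model = build_model(TrainingConfig())
        assert model.layer_shape_report[1] == ("conv_12", (128, 128, 12))

    def test_parameter_count_matches_hand_ledger(self):
        model = build_model(TrainingConfig())
        conv = lambda cin, cout: (3 * 3 * cin + 1) * cout
        dense = lambda nin, nout: (nin + 1) * nout
        expected = (
            conv(3, 12)
            + conv(12, 16)
            + conv(16, 32)
            + conv(32, 64)
            + dense(64, 512)
            + dense(512, 128)
            + dense(128, 1)
        )
        assert expected == 124_289
        assert model.parameter_count == expected
        # per-layer sum equals the framework-side count over actual arrays
        actual = sum(
            p.size for layer in model.layers for p in layer.params
        )
        assert actual == expected

    @pytest.mark.parametrize(
        "field, value",
        [
            ("filters", (12, 16, 32)),
            ("filters", (12, 12, 32, 64)),
            ("decision_threshold", 1.0),
            ("input_size", 200),
            ("monitored_metric", "F1"),
        ],
    )
    def test_invalid_configuration_rejected(self, field, value):
        with pytest.raises(ConfigError):
            dataclasses.replace(TrainingConfig(), **{field: value}).validate()


class TestPredict:
    def test_tie_at_threshold_is_non_ischemic(self):
        model = build_model(TrainingConfig())
        out = model.layers[-1]
        out.W[...] = 0.0
        out.b[...] = 0.0  # logit 0 -> sigmoid exactly 0.5
        case = _blank_case(1)
        assert predict_proba(model, [case])[0] == 0.5
        assert predict(model, [case])[0] == 0
        assert predict(model, [case], threshold=0.49)[0] == 1

    def test_batch_predictions_equal_single_predictions(self):
        model = build_model(TrainingConfig(seed=7))
        cases = [_blank_case(0, s) for s in range(5)]
        batch = predict_proba(model, cases)
        single = np.array([predict_proba(model, [c])[0] for c in cases])
        assert np.allclose(batch, single, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        model = build_model(TrainingConfig())
        with pytest.raises(ValueError):
            predict(model, [np.zeros((128, 128, 3), dtype=np.float32)])


class TestTraining:
    def test_history_has_one_row_per_epoch(self, tiny_dataset):
        cases, _ = tiny_dataset
        cfg = TrainingConfig(epochs=3, seed=0)
        _, history = train(build_model(cfg), cases[:8], cases[8:], cfg)
        assert len(history) == 3
        assert set(history.columns) >= {
            "epoch",
            "loss",
            "metric",
            "val_loss",
            "val_metric",
        }

    def test_training_is_deterministic_given_seed(self, tiny_dataset):
        cases, _ = tiny_dataset
        cfg = TrainingConfig(epochs=2, seed=11)
        p = []
        for _ in range(2):
            model, _ = train(build_model(cfg), cases[:8], None, cfg)
            p.append(predict_proba(model, cases[8:]))
        assert np.array_equal(p[0], p[1])

    def test_single_class_training_set_rejected(self, tiny_dataset):
        cases, _ = tiny_dataset
        neg = [c for c in cases if c.label == 0]
        cfg = TrainingConfig(epochs=1)
        with pytest.raises(ValueError, match="single class"):
            train(build_model(cfg), neg, None, cfg)

    def test_acc_as_monitored_metric(self, tiny_dataset):
        cases, _ = tiny_dataset
        cfg = TrainingConfig(epochs=1, monitored_metric="ACC", seed=0)
        _, history = train(build_model(cfg), cases[:8], cases[8:], cfg)
        assert 0.0 <= history["metric"].iloc[0] <= 1.0

    def test_class_weighting_raises_sensitivity_on_imbalanced_data(self):
        """With a 3x weight on the rare ischemic class, training finds the
        positives; unweighted training at equal epochs does not. Statistical
        property over 10 seeds (higher learning rate to keep runs short)."""
        from polarcnn import SyntheticConfig
        from polarcnn.pipeline import synthesize_cases

        cases, _ = synthesize_cases(
            SyntheticConfig(
                n_cases=40, ischemic_fraction=0.2, image_size=256, seed=11
            )
        )
        ref = np.array([c.label for c in cases])
        pos = ref == 1
        assert 0 < pos.sum() < 15

        def mean_sensitivity(class_weights):
            sens = []
            for seed in range(10):
                cfg = TrainingConfig(
                    epochs=8,
                    seed=seed,
                    learning_rate=0.03,
                    class_weights=class_weights,
                    monitored_metric="ACC",
                )
                model, _ = train(build_model(cfg), cases, None, cfg)
                pred = np.asarray(predict(model, cases))
                sens.append(pred[pos].mean())
            return float(np.mean(sens))

        weighted = mean_sensitivity({0: 1.0, 1: 3.0})
        unweighted = mean_sensitivity({0: 1.0, 1: 1.0})
        assert weighted > unweighted

    def test_weights_round_trip_through_checkpoint(self, tiny_dataset, tmp_path):
        cases, _ = tiny_dataset
        cfg = TrainingConfig(epochs=1, seed=5)
        model, _ = train(build_model(cfg), cases[:8], None, cfg)
        ref = predict_proba(model, cases[8:])
        path = tmp_path / "weights.npz"
        save_weights(model, path)
        fresh = load_weights(build_model(cfg), path)
        assert np.array_equal(predict_proba(fresh, cases[8:]), ref)
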