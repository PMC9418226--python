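"""Architecture contracts, training mechanics and the estimator surface."""

import numpy as np
import pytest

from fafseg.estimator import AttentionUNetSegmenter
from fafseg.model import SegmentationModel, binarize, build_model, predict_soft
from fafseg.nn import NetworkConfig, UNet
from fafseg.synthetic import SceneSpec, generate_dataset


def scene_stack(n, size=64, seed=0):
    bundles = generate_dataset(n, SceneSpec(canvas_size=(size, size)), seed=seed)
    X = np.stack([b.image_t0 for b in bundles])
    y = np.stack([b.mask_t0 for b in bundles])
    return X, y


class TestArchitecture:
    @pytest.mark.parametrize("depth", [2, 3, 4])
    def test_neutral_gate_reduces_to_plain_unet(self, depth, rng):
        attended = UNet(NetworkConfig(depth=depth, base_filters=4, input_size=64,
                                      attended=True, seed=depth))
        plain = UNet(NetworkConfig(depth=depth, base_filters=4, input_size=64,
                                   attended=False, seed=depth))
        plain.copy_shared_weights_from(attended)
        x = rng.random((2, 1, 64, 64)).astype(np.float32)
        np.testing.assert_allclose(
            attended.forward(x, force_alpha=1.0), plain.forward(x), atol=1e-5
        )

    def test_forward_shape_and_range(self, rng):
        net = UNet(NetworkConfig(depth=3, base_filters=8, input_size=128, seed=0))
        prob = net.forward(rng.random((1, 1, 128, 128)).astype(np.float32))
        assert prob.shape == (1, 1, 128, 128)
        assert prob.min() >= 0 and prob.max() <= 1

    @pytest.mark.parametrize("depth", [2, 3, 4])
    def test_gate_parameter_count_closed_form(self, depth):
        cfg_a = NetworkConfig(depth=depth, base_filters=8, input_size=64, attended=True)
        cfg_p = NetworkConfig(depth=depth, base_filters=8, input_size=64, attended=False)
        diff = UNet(cfg_a).n_parameters - UNet(cfg_p).n_parameters
        expected = sum(
            2 * cfg_a.encoder_channels()[i] * cfg_a.f_int(i)  # W_x and W_s
            + 2 * cfg_a.f_int(i)                              # psi and b_g
            + 1                                               # b_psi
            for i in range(depth)
        )
        assert diff == expected

    def test_alpha_maps_recorded_and_in_range(self, rng):
        net = UNet(NetworkConfig(depth=3, base_filters=4, input_size=64, seed=1))
        net.forward(rng.random((2, 1, 64, 64)).astype(np.float32))
        assert sorted(net.attention_maps_) == [0, 1, 2]
        for att in net.attention_maps_.values():
            assert (att.alpha >= 0).all() and (att.alpha <= 1).all()

    def test_input_size_divisibility_enforced(self):
        with pytest.raises(ValueError, match="divisible"):
            NetworkConfig(depth=3, input_size=100).validate()

    def test_wrong_input_size_rejected_at_forward(self, rng):
        net = UNet(NetworkConfig(depth=2, base_filters=4, input_size=64))
        with pytest.raises(ValueError, match="expects"):
            net.forward(rng.random((1, 1, 32, 32)).astype(np.float32))


class TestPredictSoft:
    def test_deterministic_repeat(self, rng):
        model = build_model(NetworkConfig(depth=2, base_filters=4, input_size=64, seed=5))
        img = rng.random((64, 64))
        np.testing.assert_array_equal(predict_soft(model, img), predict_soft(model, img))

    def test_zero_final_layer_gives_half_probability(self, rng):
        model = build_model(NetworkConfig(depth=2, base_filters=4, input_size=64, seed=5))
        model.net.params["out_W"][...] = 0.0
        model.net.params["out_b"][...] = 0.0
        prob = predict_soft(model, rng.random((64, 64)))
        assert np.allclose(prob, 0.5)

    def test_checkpoint_roundtrip(self, rng, tmp_path):
        model = build_model(NetworkConfig(depth=2, base_filters=4, input_size=64, seed=6))
        img = rng.random((64, 64))
        model.save(tmp_path / "ckpt")
        loaded = SegmentationModel.load(tmp_path / "ckpt")
        np.testing.assert_array_equal(predict_soft(model, img), predict_soft(loaded, img))
        import json

        descriptor = json.loads((tmp_path / "ckpt.json").read_text())
        assert "1 + exp" in descriptor["sigma2"].replace(" ", " ")


class TestBinarize:
    def test_boundary_convention_is_geq(self):
        assert binarize(np.full((3, 3), 0.5), 0.5).all()

    def test_unreachable_threshold_gives_empty_mask(self, rng):
        assert binarize(rng.random((5, 5)) * 0.9, 1.0).sum() == 0

    def test_complement_duality(self, rng):
        p = rng.random((16, 16))
        t = 0.37
        eps = 1e-9
        lhs = binarize(p, t)
        rhs = 1 - binarize(1 - p, 1 - t + eps)
        np.testing.assert_array_equal(lhs, rhs)


class TestTrainingMechanics:
    def test_zero_learning_rate_leaves_weights_unchanged(self):
        X, y = scene_stack(4, size=64, seed=1)
        est = AttentionUNetSegmenter(depth=2, base_filters=4, learning_rate=0.0,
                                     epochs=1, random_state=0)
        ref = UNet(NetworkConfig(depth=2, base_filters=4, input_size=64,
                                 attended=True, seed=0))
        est.fit(X, y)
        for k, v in est.model_.net.params.items():
            np.testing.assert_allclose(v, ref.params[k], atol=1e-7)

    def test_training_reduces_loss(self):
        X, y = scene_stack(8, size=64, seed=2)
        est = AttentionUNetSegmenter(depth=2, base_filters=4, epochs=6, random_state=0)
        est.fit(X, y)
        h = est.history_
        assert h["train_loss"].iloc[-1] < h["train_loss"].iloc[0]

    def test_seeded_runs_reproduce_history_exactly(self):
        X, y = scene_stack(6, size=64, seed=3)
        kw = dict(depth=2, base_filters=4, epochs=3, random_state=11)
        h1 = AttentionUNetSegmenter(**kw).fit(X, y).history_
        h2 = AttentionUNetSegmenter(**kw).fit(X, y).history_
        assert (h1["train_loss"] == h2["train_loss"]).all()

    def test_validation_checkpoint_and_history(self):
        X, y = scene_stack(8, size=64, seed=4)
        est = AttentionUNetSegmenter(depth=2, base_filters=4, epochs=4, random_state=0)
        est.fit(X[:6], y[:6], validation_data=(X[6:], y[6:]))
        assert est.history_["val_loss"].notna().all()
        assert 0 <= est.best_epoch_ < est.n_epochs_

    def test_dice_loss_variant_trains(self):
        X, y = scene_stack(6, size=64, seed=5)
        est = AttentionUNetSegmenter(depth=2, base_filters=4, epochs=5,
                                     loss="dice", random_state=0)
        est.fit(X, y)
        assert est.history_["train_loss"].iloc[-1] < est.history_["train_loss"].iloc[0]

    @pytest.mark.filterwarnings("ignore:overflow", "ignore:invalid value")
    def test_diverging_run_aborts_with_diagnostic(self):
        X, y = scene_stack(4, size=64, seed=6)
        est = AttentionUNetSegmenter(depth=2, base_filters=4, epochs=10,
                                     learning_rate=1e12, random_state=0)
        with pytest.raises(RuntimeError, match="non-finite"):
            est.fit(X, y)

    def test_predict_shapes_and_score(self):
        X, y = scene_stack(6, size=64, seed=7)
        est = AttentionUNetSegmenter(depth=2, base_filters=4, epochs=8, random_state=0)
        est.fit(X, y)
        prob = est.predict_proba(X[:2])
        assert prob.shape == (2, 64, 64)
        assert 0 <= prob.min() and prob.max() <= 1
        masks = est.predict(X[:2])
        assert set(np.unique(masks)) <= {0, 1}
        assert 0.0 <= est.score(X, y) <= 1.0

    def test_sklearn_param_interface(self):
        est = AttentionUNetSegmenter(epochs=3)
        assert est.get_params()["epochs"] == 3
        est.set_params(attended=False)
        assert est.attended is False

    def test_invalid_labels_rejected(self, rng):
        X = rng.random((2, 64, 64))
        with pytest.raises(ValueError, match="binary"):
            AttentionUNetSegmenter(depth=2).fit(X, X)
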