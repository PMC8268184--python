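"""Network forward passes, losses, gradients, training, and prediction."""

import numpy as np
import pytest

import cellgcn as cg
from cellgcn.model import (SigGCNModel, _encode_labels, classification_loss,
                           reconstruction_loss, total_loss)

from conftest import random_gene_graph, tiny_model_setup


class TestGcnForward:
    def test_zero_input_gives_bias_activation(self):
        model, lap, x, _ = tiny_model_setup()
        theta1, _ = model.gcn_forward(lap, np.zeros_like(x))
        expected = np.maximum(model.params["b_gcn"], 0.0)
        np.testing.assert_allclose(theta1, np.tile(expected, (x.shape[0], 1)), atol=1e-12)

    def test_pooled_and_flat_shapes(self):
        model, lap, x, _ = tiny_model_setup(n=16, p=4, f=2)
        theta1, fmap = model.gcn_forward(lap, x)
        assert fmap.shape == (x.shape[0], 16, 2)
        assert theta1.shape == (x.shape[0], model.config.gcn_embed_dim)
        assert model.config.pooled_nodes == 4

    def test_identity_filter_reproduces_input(self, rng):
        # beta = [1, 0, ...] makes the convolution T_0(L~) x = x
        model, lap, x, _ = tiny_model_setup()
        model.params["beta"][:] = 0.0
        model.params["beta"][0, 0] = 1.0
        if model.config.conv_bias:
            model.params["conv_bias"][:] = 0.0
        _, fmap = model.gcn_forward(lap, x)
        np.testing.assert_allclose(fmap[:, :, 0], np.maximum(x, 0.0), atol=1e-12)

    def test_shape_mismatch_errors(self):
        model, lap, x, _ = tiny_model_setup()
        with pytest.raises(ValueError):
            model.gcn_forward(lap, x[:, :-1])


class TestDecode:
    def test_zero_embedding_returns_bias(self):
        model, lap, x, _ = tiny_model_setup()
        model.params["b_dec"][:] = 1.5
        x_hat = model.decode(np.zeros((3, model.config.gcn_embed_dim)))
        np.testing.assert_allclose(x_hat, 1.5)

    def test_affine_map_matches_explicit_multiply(self, rng):
        model, _, _, _ = tiny_model_setup()
        theta1 = rng.normal(size=(4, model.config.gcn_embed_dim))
        expected = theta1 @ model.params["W_dec"] + model.params["b_dec"]
        np.testing.assert_allclose(model.decode(theta1), expected)


class TestNnForward:
    def test_zero_input_zero_bias_gives_zero(self):
        model, _, x, _ = tiny_model_setup()
        model.params["b_nn1"][:] = 0.0
        model.params["b_nn2"][:] = 0.0
        np.testing.assert_array_equal(model.nn_forward(np.zeros_like(x)), 0.0)

    def test_hand_computed_toy_forward(self):
        cfg = cg.ModelConfig(n_genes=2, cheb_order=1, n_filters=1, pool_size=1,
                             gcn_embed_dim=1, nn_hidden_dims=(2, 2), n_classes=2,
                             gcn_enabled=False)
        model = SigGCNModel(cfg, ["a", "b"])
        model.params["W_nn1"] = np.array([[1.0, -1.0], [0.5, 2.0]])
        model.params["b_nn1"] = np.array([0.0, 1.0])
        model.params["W_nn2"] = np.array([[1.0, 0.0], [1.0, 1.0]])
        model.params["b_nn2"] = np.array([-1.0, 0.0])
        x = np.array([[2.0, 2.0]])
        # z1 = [3, 3] -> relu [3, 3]; z2 = [3+3-1, 3] = [5, 3]
        np.testing.assert_allclose(model.nn_forward(x), [[5.0, 3.0]])


class TestClassify:
    def test_identical_logits_give_uniform_rows(self):
        model, lap, x, _ = tiny_model_setup(n_classes=4)
        model.params["W_out"][:] = 0.0
        model.params["b_out"][:] = 0.7
        probs = model.forward(lap, x)
        np.testing.assert_allclose(probs, 0.25, atol=1e-12)

    def test_softmax_closed_form(self):
        from cellgcn.model import _softmax
        probs = _softmax(np.array([[np.log(2.0), 0.0]]))
        np.testing.assert_allclose(probs, [[2 / 3, 1 / 3]], atol=1e-12)

    def test_rows_on_simplex(self, rng):
        model, lap, x, _ = tiny_model_setup(batch=20)
        probs = model.forward(lap, rng.normal(size=x.shape))
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert (probs >= 0).all()


class TestLosses:
    def test_reconstruction_zero_on_perfect(self, rng):
        x = rng.uniform(size=(3, 5))
        assert reconstruction_loss(x, x) == 0.0

    def test_reconstruction_single_cell(self):
        assert reconstruction_loss(np.array([[1.0, 0.0]]), np.zeros((1, 2))) == 1.0

    def test_reconstruction_matches_double_loop(self, rng):
        x, x_hat = rng.uniform(size=(7, 9)), rng.uniform(size=(7, 9))
        expected = sum((x[i, j] - x_hat[i, j]) ** 2
                       for i in range(7) for j in range(9)) / 7
        assert reconstruction_loss(x, x_hat) == pytest.approx(expected)

    def test_classification_perfect_is_zero(self):
        probs = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert classification_loss(probs, [0, 1]) == pytest.approx(0.0, abs=1e-12)

    def test_classification_uniform_closed_form(self):
        probs = np.full((5, 4), 0.25)
        assert classification_loss(probs, [0, 1, 2, 3, 0]) == pytest.approx(np.log(4))

    def test_classification_matches_per_cell_loop(self, rng):
        probs = rng.dirichlet(np.ones(3), size=10)
        y = rng.integers(0, 3, size=10)
        expected = np.mean([-np.log(probs[i, y[i]]) for i in range(10)])
        assert classification_loss(probs, y) == pytest.approx(expected)

    def test_zero_probability_clipped_finite(self):
        probs = np.array([[0.0, 1.0]])
        assert np.isfinite(classification_loss(probs, [0]))

    def test_total_loss_arithmetic(self):
        assert total_loss(2.0, 3.0, 10.0) == pytest.approx(5.001)
        assert total_loss(1.7, 3.0, 10.0, 1.0, 0.0, 0.0) == pytest.approx(1.7)

    def test_total_loss_random_matches_formula(self, rng):
        l1, l2, l3 = rng.uniform(size=3)
        w1, w2, w3 = rng.uniform(size=3)
        assert total_loss(l1, l2, l3, w1, w2, w3) == pytest.approx(w1 * l1 + w2 * l2 + w3 * l3)

    def test_regularization_zero_model_and_increment(self):
        model, _, _, _ = tiny_model_setup()
        for v in model.params.values():
            v[:] = 0.0
        assert model.regularization_loss() == 0.0
        model.params["b_out"][0] = 2.0
        assert model.regularization_loss() == pytest.approx(4.0)

    def test_regularization_matches_parameter_walk(self, rng):
        model, _, _, _ = tiny_model_setup(seed=3)
        expected = sum(float(np.sum(v ** 2)) for v in model.params.values())
        assert model.regularization_loss() == pytest.approx(expected)

    def test_loss_decomposition(self):
        # with lambda_rec = lambda_reg = 0 the total equals the NLL exactly
        model, lap, x, y = tiny_model_setup()
        from dataclasses import replace
        model.config = replace(model.config, lambda_rec=0.0, lambda_reg=0.0)
        losses, _ = model.loss_and_grads(lap, x, y)
        assert losses["total"] == losses["cla"]


class TestParameterCount:
    def test_default_architecture_dimensions(self):
        cfg = cg.ModelConfig(n_genes=1000, n_classes=10)
        assert cfg.pooled_nodes * cfg.n_filters == 625
        assert cfg.gcn_embed_dim == 32
        assert cfg.nn_hidden_dims[1] == 32
        assert cfg.concat_dim == 64

    @pytest.mark.parametrize("kwargs", [
        dict(n_genes=1000, n_classes=10),
        dict(n_genes=16, cheb_order=3, n_filters=2, pool_size=4, n_classes=3,
             gcn_embed_dim=8, nn_hidden_dims=(12, 8)),
        dict(n_genes=37, pool_size=8, n_classes=5, conv_bias=False),
        dict(n_genes=50, n_classes=4, gcn_enabled=False),
    ])
    def test_closed_form_matches_actual_parameters(self, kwargs):
        cfg = cg.ModelConfig(**kwargs)
        model = SigGCNModel(cfg, [f"c{i}" for i in range(cfg.n_classes)])
        assert model.n_parameters() == cfg.parameter_count()


class TestGradients:
    def test_backprop_matches_finite_differences(self):
        """Central finite differences on 20 random parameters of the tiny
        model agree with analytic gradients to 1e-4 relative error."""
        model, lap, x, y = tiny_model_setup(n=16, k=3, f=2, p=4, n_classes=3)
        _, grads = model.loss_and_grads(lap, x, y)
        flat_grads = np.concatenate([grads[k].ravel() for k in sorted(grads)])
        theta = model.get_flat()
        rng = np.random.default_rng(11)
        idx = rng.choice(theta.size, size=20, replace=False)
        eps = 1e-6
        for i in idx:
            for sign, store in ((1, "hi"), (-1, "lo")):
                pert = theta.copy()
                pert[i] += sign * eps
                model.set_flat(pert)
                losses, _ = model.loss_and_grads(lap, x, y)
                if sign == 1:
                    hi = losses["total"]
                else:
                    lo = losses["total"]
            numeric = (hi - lo) / (2 * eps)
            diff = abs(numeric - flat_grads[i])
            # tolerate central-difference roundoff on near-zero gradients
            assert diff < 1e-8 or diff / max(abs(numeric), abs(flat_grads[i])) < 1e-4, \
                f"param {i}"
        model.set_flat(theta)

    def test_nn_only_gradients(self):
        model, lap, x, y = tiny_model_setup()
        from dataclasses import replace
        cfg = replace(model.config, gcn_enabled=False)
        model2 = SigGCNModel(cfg, model.classes)
        _, grads = model2.loss_and_grads(None, x, y)
        flat_grads = np.concatenate([grads[k].ravel() for k in sorted(grads)])
        theta = model2.get_flat()
        eps = 1e-6
        for i in np.random.default_rng(5).choice(theta.size, size=8, replace=False):
            pert = theta.copy(); pert[i] += eps
            model2.set_flat(pert)
            hi, _ = model2.loss_and_grads(None, x, y)
            pert[i] -= 2 * eps
            model2.set_flat(pert)
            lo, _ = model2.loss_and_grads(None, x, y)
            numeric = (hi["total"] - lo["total"]) / (2 * eps)
            assert numeric == pytest.approx(flat_grads[i], rel=1e-4, abs=1e-8)
            model2.set_flat(theta)


class TestTrain:
    def test_zero_epochs_returns_initialized_model(self, default_fixture):
        train, val, _, graph, _ = default_fixture
        lap = cg.scaled_laplacian(graph)
        cfg = cg.ModelConfig(n_genes=train.n_genes, n_classes=4, epochs=0, seed=1)
        model, history = cg.train(train, val, lap, cfg)
        reference = SigGCNModel(cfg, sorted(set(train.labels)))
        for k in model.params:
            np.testing.assert_array_equal(model.params[k], reference.params[k])
        assert history.epoch == []

    def test_same_seed_gives_identical_history(self, default_fixture):
        train, val, _, graph, _ = default_fixture
        lap = cg.scaled_laplacian(graph)
        cfg = cg.ModelConfig(n_genes=train.n_genes, n_classes=4, epochs=2, seed=9)
        _, h1 = cg.train(train, val, lap, cfg)
        _, h2 = cg.train(train, val, lap, cfg)
        assert h1.total == h2.total
        assert h1.val_accuracy == h2.val_accuracy

    def test_training_reduces_loss(self, trained_default):
        _, history, _ = trained_default
        assert history.total[-1] < history.total[0]

    def test_missing_class_errors(self, default_fixture):
        train, val, _, graph, _ = default_fixture
        lap = cg.scaled_laplacian(graph)
        cfg = cg.ModelConfig(n_genes=train.n_genes, n_classes=5, epochs=1)
        with pytest.raises(ValueError, match="ghost"):
            cg.train(train, val, lap, cfg,
                     classes=sorted(set(train.labels)) + ["ghost"])

    def test_history_csv(self, trained_default, tmp_path):
        _, history, _ = trained_default
        history.to_csv(tmp_path / "log.csv")
        import pandas as pd
        log = pd.read_csv(tmp_path / "log.csv")
        assert list(log.columns) == ["epoch", "l_cla", "l_rec", "l_reg", "total",
                                     "val_total", "val_accuracy"]
        assert len(log) == 50


class TestPredict:
    def test_rejection_rule(self):
        """A cell is unassigned exactly when its top probability is below
        the threshold (0.65 by the usual convention)."""
        result = cg.PredictionResult(
            probabilities=np.array([[0.6, 0.4], [0.7, 0.3]]),
            predicted_labels=np.array(["a", "a"], dtype=object),
            unassigned_mask=np.array([True, False]),
            classes=["a", "b"])
        assert result.unassigned_mask.tolist() == [True, False]
        assert result.predicted_labels[0] == "a"  # argmax kept alongside the flag

    def test_predict_threshold_semantics(self, trained_default, default_fixture):
        model, _, lap = trained_default
        _, _, test, _, _ = default_fixture
        res = cg.predict(model, lap, test, reject_threshold=0.65)
        np.testing.assert_array_equal(res.unassigned_mask,
                                      res.probabilities.max(axis=1) < 0.65)

    def test_threshold_zero_rejects_nothing(self, trained_default, default_fixture):
        model, _, lap = trained_default
        _, _, test, _, _ = default_fixture
        res = cg.predict(model, lap, test, reject_threshold=0.0)
        assert not res.unassigned_mask.any()

    def test_probability_rows_sum_to_one(self, trained_default, default_fixture):
        model, _, lap = trained_default
        _, _, test, _, _ = default_fixture
        res = cg.predict(model, lap, test)
        np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_array_equal(
            res.predicted_labels,
            [res.classes[i] for i in res.probabilities.argmax(axis=1)])


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path):
        model, lap, x, _ = tiny_model_setup()
        model.gene_ids = [f"g{i}" for i in range(model.config.n_genes)]
        model.save(tmp_path / "ckpt.npz")
        loaded = SigGCNModel.load(tmp_path / "ckpt.npz")
        for k in model.params:
            np.testing.assert_array_equal(loaded.params[k], model.params[k])
        np.testing.assert_allclose(loaded.forward(lap, x), model.forward(lap, x))

    def test_gene_order_mismatch_refused(self, tmp_path):
        model, _, _, _ = tiny_model_setup()
        model.gene_ids = [f"g{i}" for i in range(model.config.n_genes)]
        model.save(tmp_path / "ckpt.npz")
        wrong = list(reversed(model.gene_ids))
        with pytest.raises(ValueError, match="gene order"):
            SigGCNModel.load(tmp_path / "ckpt.npz", expected_gene_ids=wrong)
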