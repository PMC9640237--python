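"""RBM energetics, contrastive divergence, and DBN training."""

import itertools

import numpy as np
import pytest

from kymovoice import dbn
from kymovoice.dbn import (
    DBNModel,
    RBMParams,
    TrainConfig,
    cd_gradient,
    cd_update,
    energy,
    fine_tune,
    hidden_given_visible,
    init_rbm,
    predict,
    pretrain_stack,
    visible_given_hidden,
)


def random_gaussian_rbm(rng, nv=3, nh=2, scale=0.5):
    return RBMParams(
        W=rng.normal(0, scale, (nv, nh)),
        b_vis=rng.normal(0, scale, nv),
        b_hid=rng.normal(0, scale, nh),
        sigma=np.abs(rng.normal(1.0, 0.2, nv)) + 0.1,
    )


def random_bernoulli_rbm(rng, nv=2, nh=2, scale=0.8):
    return RBMParams(
        W=rng.normal(0, scale, (nv, nh)),
        b_vis=rng.normal(0, scale, nv),
        b_hid=rng.normal(0, scale, nh),
        sigma=np.ones(nv),
        visible_type="bernoulli",
    )


def enumerate_hidden(nh):
    return np.array(list(itertools.product([0, 1], repeat=nh)), dtype=float)


def bayes_hidden_probs(v, params):
    """Oracle: p(h_i=1|v) from the joint exp(-E) by enumerating h."""
    hs = enumerate_hidden(params.n_hidden)
    logw = -np.array([energy(v, h, params) for h in hs])
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return np.array(
        [w[hs[:, i] == 1].sum() for i in range(params.n_hidden)]
    )


def exact_bernoulli_gradient(batch, params):
    """Oracle: exact log-likelihood gradient of a tiny Bernoulli RBM by
    enumerating the full joint distribution."""
    vs = enumerate_hidden(params.n_visible)  # all binary visible states
    hs = enumerate_hidden(params.n_hidden)
    E = np.array([[energy(v, h, params) for h in hs] for v in vs])
    P = np.exp(-E)
    P /= P.sum()
    model_term = sum(
        P[i, j] * np.outer(vs[i], hs[j])
        for i in range(len(vs))
        for j in range(len(hs))
    )
    data_term = np.zeros_like(params.W)
    for v in batch:
        data_term += np.outer(v, bayes_hidden_probs(v, params))
    data_term /= len(batch)
    return data_term - model_term


class TestEnergy:
    def test_zero_when_visible_at_offsets(self, rng):
        p = RBMParams(np.zeros((3, 2)), rng.normal(size=3), np.zeros(2), np.ones(3))
        h = np.array([1.0, 0.0])
        assert energy(p.b_vis, h, p) == pytest.approx(0.0)

    def test_hand_computed_value(self):
        p = RBMParams(np.array([[2.0]]), np.zeros(1), np.zeros(1), np.ones(1))
        assert energy(np.array([3.0]), np.array([1.0]), p) == pytest.approx(-1.5)

    def test_shape_mismatch_rejected(self, rng):
        p = random_gaussian_rbm(rng)
        with pytest.raises(ValueError):
            energy(np.zeros(4), np.zeros(2), p)


class TestConditionals:
    def test_zero_weights_give_bias_logistic(self):
        p = RBMParams(np.zeros((3, 2)), np.zeros(3), np.array([0.0, 1.0]), np.ones(3))
        probs = hidden_given_visible(np.zeros(3), p)
        assert probs[0] == pytest.approx(0.5)
        assert probs[1] == pytest.approx(1 / (1 + np.exp(-1)))

    def test_hidden_probs_match_bayes_enumeration(self, rng):
        for _ in range(20):
            p = random_gaussian_rbm(rng)
            v = rng.normal(size=3)
            assert np.allclose(
                hidden_given_visible(v, p), bayes_hidden_probs(v, p), atol=1e-10
            )

    def test_visible_means_trivial_cases(self):
        p = RBMParams(np.array([[1.0], [2.0]]), np.zeros(2), np.zeros(1), np.ones(2))
        assert np.allclose(visible_given_hidden(np.zeros(1), p), [0.0, 0.0])
        assert np.allclose(visible_given_hidden(np.ones(1), p), [1.0, 2.0])

    def test_visible_mean_minimizes_energy_in_v(self, rng):
        # oracle: grid minimization of E(v, h) over v, one unit at a time
        p = random_gaussian_rbm(rng, nv=2, nh=2)
        h = np.array([1.0, 0.0])
        mean = visible_given_hidden(h, p)
        grid = np.linspace(-6, 6, 4001)
        for j in range(2):
            energies = []
            for g in grid:
                v = mean.copy()
                v[j] = g
                energies.append(energy(v, h, p))
            assert grid[int(np.argmin(energies))] == pytest.approx(mean[j], abs=0.01)


class TestContrastiveDivergence:
    def test_zero_learning_rate_leaves_params_unchanged(self, rng):
        p = random_gaussian_rbm(rng)
        cfg = TrainConfig(learning_rate=0.0)
        batch = rng.normal(size=(8, 3))
        new, _, _ = cd_update(batch, p, cfg, rng)
        assert np.array_equal(new.W, p.W)
        assert np.array_equal(new.b_vis, p.b_vis)
        assert np.array_equal(new.b_hid, p.b_hid)

    def test_nan_batch_rejected(self, rng):
        p = random_gaussian_rbm(rng)
        batch = np.full((4, 3), np.nan)
        with pytest.raises(ValueError):
            cd_gradient(batch, p, TrainConfig(), rng)

    def test_data_side_term_matches_exact_enumeration(self, rng):
        # Bernoulli-limit RBM: the data-side correlation <v h>_data uses the
        # exact conditional p(h|v); verified against Bayes on the joint
        p = random_bernoulli_rbm(rng)
        batch = np.array([[0, 1], [1, 1], [0, 0], [1, 0], [1, 1]], dtype=float)
        data_term = batch.T @ hidden_given_visible(batch, p) / len(batch)
        oracle = np.zeros_like(p.W)
        for v in batch:
            oracle += np.outer(v, bayes_hidden_probs(v, p))
        oracle /= len(batch)
        assert np.allclose(data_term, oracle, atol=1e-10)

    def test_long_chain_cd_approaches_exact_gradient(self, rng):
        p = random_bernoulli_rbm(rng)
        batch = np.array([[0, 1], [1, 1], [1, 0]], dtype=float)
        exact = exact_bernoulli_gradient(batch, p)
        big = np.repeat(batch, 1500, axis=0)  # many chains, averaged
        dW, _, _, _ = cd_gradient(big, p, TrainConfig(cd_steps=60, seed=0), rng)
        cos = float(
            dW.ravel() @ exact.ravel()
            / (np.linalg.norm(dW) * np.linalg.norm(exact))
        )
        assert cos > 0.99

    def test_momentum_accumulates_velocity(self, rng):
        p = random_gaussian_rbm(rng)
        cfg = TrainConfig(learning_rate=0.1, momentum=0.9)
        batch = rng.normal(size=(16, 3))
        _, vel1, _ = cd_update(batch, p, cfg, np.random.default_rng(0))
        _, vel2, _ = cd_update(batch, p, cfg, np.random.default_rng(0), vel1)
        assert np.linalg.norm(vel2[0]) > np.linalg.norm(vel1[0])


class TestPretrain:
    def test_single_layer_stack_is_plain_rbm_training(self, rng):
        X = rng.normal(size=(40, 4))
        cfg = TrainConfig(epochs=3, seed=5)
        model = pretrain_stack(X, [6], cfg)
        # replicate the training loop with the same draw order
        rng2 = np.random.default_rng(cfg.seed)
        p = init_rbm(4, 6, rng2)
        vel = None
        for _ in range(cfg.epochs):
            order = rng2.permutation(40)
            for start in range(0, 40, cfg.batch_size):
                p, vel, _ = cd_update(X[order[start : start + cfg.batch_size]], p, cfg, rng2, vel)
        assert np.allclose(model.layers[0].W, p.W)

    def test_fixed_seed_reproducible(self, rng):
        X = rng.normal(size=(30, 4))
        cfg = TrainConfig(epochs=2, seed=9)
        a = pretrain_stack(X, [8, 4], cfg)
        b = pretrain_stack(X, [8, 4], cfg)
        for la, lb in zip(a.layers, b.layers):
            assert np.array_equal(la.W, lb.W)

    def test_reconstruction_error_decreases_over_first_epochs(self, small_dataset):
        from kymovoice.pipeline import FEATURE_COLUMNS, MinMaxScaler

        X = MinMaxScaler().fit(
            small_dataset[FEATURE_COLUMNS].to_numpy(float)
        ).transform(small_dataset[FEATURE_COLUMNS].to_numpy(float))
        sigma = np.maximum(X.std(axis=0), 0.05)
        cfg = TrainConfig(learning_rate=0.05, momentum=0.5, epochs=10, seed=0)
        model = pretrain_stack(X, [32, 16], cfg, visible_sigma=sigma)
        first_layer = model.recon_errors[0]
        assert len(first_layer) == 10
        assert first_layer[-1] < first_layer[0]

    def test_top_layer_separates_distributed_signal_better_than_raw(self):
        # class signal spread across all 4 features: any single raw feature
        # overlaps, a learned projection should not
        rng = np.random.default_rng(0)
        n, a, noise = 150, 0.35, 0.5
        v = np.ones(4) / 2
        X = np.vstack(
            [rng.normal(0, noise, (n, 4)) - a * v, rng.normal(0, noise, (n, 4)) + a * v]
        )
        X = (X - X.min(0)) / (X.max(0) - X.min(0))
        y = np.r_[np.zeros(n), np.ones(n)].astype(bool)
        model = pretrain_stack(
            X, [16, 8],
            TrainConfig(learning_rate=0.05, momentum=0.5, epochs=20, seed=1),
            visible_sigma=X.std(0),
        )
        top = model.forward_hidden(X)

        def best_threshold_accuracy(F):
            best = 0.0
            for j in range(F.shape[1]):
                vals = np.sort(np.unique(F[:, j]))
                for thr in (vals[:-1] + vals[1:]) / 2:
                    best = max(
                        best,
                        ((F[:, j] > thr) == y).mean(),
                        ((F[:, j] <= thr) == y).mean(),
                    )
            return best

        assert best_threshold_accuracy(top) > best_threshold_accuracy(X)

    def test_invalid_layer_sizes(self, rng):
        X = rng.normal(size=(10, 3))
        with pytest.raises(ValueError):
            pretrain_stack(X, [], TrainConfig())
        with pytest.raises(ValueError):
            pretrain_stack(X, [4, 0], TrainConfig())


class TestFineTuneAndPredict:
    def _toy(self, rng, n=60):
        X = np.vstack(
            [rng.normal(-1.0, 0.3, (n, 2)), rng.normal(1.0, 0.3, (n, 2))]
        )
        y = np.array(["neg"] * n + ["pos"] * n)
        return X, y

    def test_zero_epochs_leaves_layers_unchanged(self, rng):
        X, y = self._toy(rng)
        model = pretrain_stack(X, [6], TrainConfig(epochs=1, seed=0))
        tuned = fine_tune(model, X, y, TrainConfig(epochs=0, seed=0))
        assert np.array_equal(tuned.layers[0].W, model.layers[0].W)
        assert tuned.head_W is not None and tuned.classes.tolist() == ["neg", "pos"]

    def test_single_class_rejected(self, rng):
        X, _ = self._toy(rng)
        model = pretrain_stack(X, [6], TrainConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            fine_tune(model, X, np.array(["a"] * len(X)), TrainConfig(epochs=1))

    def test_linearly_separable_data_perfectly_fit(self, rng):
        X, y = self._toy(rng)
        model = pretrain_stack(
            X, [8, 4], TrainConfig(epochs=5, seed=0), visible_sigma=X.std(axis=0)
        )
        cfg = TrainConfig(learning_rate=0.3, momentum=0.9, epochs=60, seed=0)
        tuned = fine_tune(model, X, y, cfg)
        _, pred = predict(tuned, X)
        assert (pred == y).mean() == 1.0

    def test_head_gradient_matches_finite_differences(self, rng):
        X = rng.normal(size=(12, 3))
        y = np.array(["a", "b"] * 6)
        model = pretrain_stack(X, [4, 3], TrainConfig(epochs=2, seed=1))
        model = fine_tune(model, X, y, TrainConfig(epochs=0, seed=1))
        onehot = (y[:, None] == model.classes[None, :]).astype(float)
        _, grads = dbn._loss_and_grads(model, X, onehot)
        eps = 1e-4
        checks = [
            (model.head_W, grads["head_W"]),
            (model.head_b, grads["head_b"]),
            (model.layers[0].W, grads["layers"][0]["W"]),
            (model.layers[1].W, grads["layers"][1]["W"]),
            (model.layers[0].b_hid, grads["layers"][0]["b_hid"]),
        ]
        for arr, g in checks:
            it = np.nditer(arr, flags=["multi_index"])
            while not it.finished:
                ix = it.multi_index
                old = arr[ix]
                arr[ix] = old + eps
                lp, _ = dbn._loss_and_grads(model, X, onehot)
                arr[ix] = old - eps
                lm, _ = dbn._loss_and_grads(model, X, onehot)
                arr[ix] = old
                fd = (lp - lm) / (2 * eps)
                assert abs(fd - g[ix]) <= 1e-5 * max(abs(fd), abs(g[ix]), 1e-3)
                it.iternext()

    def test_probabilities_sum_to_one(self, rng):
        X, y = self._toy(rng, n=20)
        model = pretrain_stack(X, [5], TrainConfig(epochs=1, seed=0))
        model = fine_tune(model, X, y, TrainConfig(epochs=2, seed=0))
        proba, _ = predict(model, rng.normal(size=(30, 2)))
        assert np.allclose(proba.sum(axis=1), 1.0)

    def test_untrained_head_near_uniform(self, rng):
        X, y = self._toy(rng, n=10)
        model = pretrain_stack(X, [5], TrainConfig(epochs=0, seed=0))
        model = fine_tune(model, X, y, TrainConfig(epochs=0, seed=0))
        proba, _ = predict(model, X)
        assert np.abs(proba - 0.5).max() < 0.05

    def test_prediction_matches_naive_forward_pass(self, rng):
        X, y = self._toy(rng, n=15)
        model = pretrain_stack(X, [6, 4], TrainConfig(epochs=2, seed=2))
        model = fine_tune(model, X, y, TrainConfig(epochs=3, seed=2))
        proba, labels = predict(model, X)
        for i, x in enumerate(X):
            a = x
            for layer in model.layers:
                z = [
                    layer.b_hid[k]
                    + sum(a[j] / layer.sigma[j] * layer.W[j, k] for j in range(len(a)))
                    for k in range(layer.n_hidden)
                ]
                a = np.array([1.0 / (1.0 + np.exp(-zz)) for zz in z])
            logits = a @ model.head_W + model.head_b
            e = np.exp(logits - logits.max())
            assert np.allclose(proba[i], e / e.sum(), atol=1e-10)
            assert labels[i] == model.classes[int(np.argmax(logits))]

    def test_dimension_mismatch_rejected(self, rng):
        X, y = self._toy(rng, n=10)
        model = pretrain_stack(X, [5], TrainConfig(epochs=1, seed=0))
        model = fine_tune(model, X, y, TrainConfig(epochs=1, seed=0))
        with pytest.raises(ValueError):
            predict(model, rng.normal(size=(4, 7)))

    def test_model_serialization_roundtrip(self, rng, tmp_path):
        X, y = self._toy(rng, n=10)
        model = pretrain_stack(X, [5, 3], TrainConfig(epochs=1, seed=0))
        model = fine_tune(model, X, y, TrainConfig(epochs=2, seed=0))
        path = tmp_path / "model.json"
        model.save(path)
        loaded = DBNModel.load(path)
        pa, la = predict(model, X)
        pb, lb = predict(loaded, X)
        assert np.allclose(pa, pb) and (la == lb).all()
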