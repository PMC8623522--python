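import numpy as np
import pytest

from tmidr import _nn
from tmidr.model import (
    BiRNNSmoother,
    CompartmentConvNet,
    EnsembleConfig,
    MembraneDisorderEnsemble,
    build_ensemble,
    smoother_inputs,
    smoother_predict,
)
from tmidr.topology import NON_MEMBRANE_CATEGORIES, Category


class TestEarlyStopping:
    def test_stops_ten_epochs_after_best(self):
        # 30 strictly improving epochs, then flat: stop at best + 10
        stopper = _nn.EarlyStopper(patience=10)
        losses = [1.0 - 0.01 * i for i in range(30)] + [0.71] * 20
        stopped_at = None
        for epoch, loss in enumerate(losses):
            if stopper.update(loss):
                stopped_at = epoch
                break
        assert stopper.best_epoch == 29
        assert stopped_at == 39

    def test_restores_weights_of_best_epoch(self):
        # loss improves for 2 epochs then worsens; patience hits at epoch 12
        # (1-based), and the best epoch is epoch 2
        stopper = _nn.EarlyStopper(patience=10)
        losses = [1.0, 0.5] + [0.6 + 0.01 * i for i in range(15)]
        stopped_at = None
        for epoch, loss in enumerate(losses):
            if stopper.update(loss):
                stopped_at = epoch
                break
        assert stopper.best_epoch == 1  # 0-based: the second epoch
        assert stopped_at == 11  # 0-based: the twelfth epoch

    def test_strictly_improving_runs_to_max(self):
        stopper = _nn.EarlyStopper(patience=10)
        assert not any(stopper.update(1.0 / (i + 1)) for i in range(100))

    def test_patience_below_one_rejected(self):
        with pytest.raises(ValueError):
            _nn.EarlyStopper(patience=0)


def _numeric_gradient(loss_fn, arr, i, eps=1e-6):
    flat = arr.ravel()
    orig = flat[i]
    flat[i] = orig + eps
    up = loss_fn()
    flat[i] = orig - eps
    down = loss_fn()
    flat[i] = orig
    return (up - down) / (2 * eps)


class TestGradients:
    def test_convnet_backward_matches_numeric(self, rng):
        X = rng.normal(size=(6, 11, 39))
        y = rng.integers(0, 2, 6).astype(float)
        params = _nn.init_convnet(11, 39, (4, 3), 3, rng)
        cache = {}
        _nn.convnet_forward(params, X, cache)
        grads = _nn.convnet_backward(params, cache, y)

        def loss():
            return _nn.bce_loss(_nn.convnet_forward(params, X, None), y)

        for key in ("W1", "b1", "W2", "b2", "W3", "b3"):
            i = params[key].size // 2
            assert grads[key].ravel()[i] == pytest.approx(
                _numeric_gradient(loss, params[key], i), abs=1e-6)

    def test_birnn_backward_matches_numeric(self, rng):
        U = rng.normal(size=(4, 25, 6))
        y = rng.integers(0, 2, 4).astype(float)
        params = _nn.init_birnn(6, 5, 12, rng)
        cache = {}
        _nn.birnn_forward(params, U, cache)
        grads = _nn.birnn_backward(params, cache, y)

        def loss():
            return _nn.bce_loss(_nn.birnn_forward(params, U, None), y)

        for key in ("Wxf", "Whf", "bhf", "Wxb", "Whb", "bhb", "Wo", "bo"):
            i = params[key].size // 2
            assert grads[key].ravel()[i] == pytest.approx(
                _numeric_gradient(loss, params[key], i), abs=1e-6)


class TestCompartmentConvNet:
    def _separable_data(self, rng, n=400):
        X = rng.normal(size=(n, 11, 39))
        y = rng.integers(0, 2, n).astype(float)
        X[y == 1, :, 0] += 2.0
        return X, y

    def test_learns_separable_windows(self, rng):
        X, y = self._separable_data(rng)
        cnn = CompartmentConvNet(max_epochs=40, seed=0).fit(X, y)
        scores = cnn.predict_score(X)
        assert ((scores > 0.5) == y).mean() > 0.9

    def test_scores_in_unit_interval(self, rng):
        X, y = self._separable_data(rng, 200)
        cnn = CompartmentConvNet(max_epochs=10, seed=0).fit(X, y)
        s = cnn.predict_score(X)
        assert s.min() >= 0 and s.max() <= 1

    def test_single_class_rejected(self, rng):
        X = rng.normal(size=(50, 11, 39))
        with pytest.raises(ValueError, match="single class"):
            CompartmentConvNet().fit(X, np.ones(50))

    def test_early_stop_returns_best_epoch_weights(self, rng):
        X, y = self._separable_data(rng, 300)
        X_val, y_val = self._separable_data(rng, 100)
        cnn = CompartmentConvNet(max_epochs=60, patience=5, seed=0)
        cnn.fit(X, y, X_val, y_val)
        val_losses = [v for _, v in cnn.history_]
        returned = _nn.bce_loss(cnn.predict_score(X_val), y_val)
        assert returned == pytest.approx(min(val_losses), abs=1e-9)
        assert returned <= val_losses[-1] + 1e-12

    def test_untrained_predict_rejected(self, rng):
        with pytest.raises(RuntimeError):
            CompartmentConvNet().predict_score(rng.normal(size=(3, 11, 39)))

    def test_sklearn_params_round_trip(self):
        cnn = CompartmentConvNet(max_epochs=7)
        assert cnn.get_params()["max_epochs"] == 7
        cnn.set_params(patience=3)
        assert cnn.patience == 3


class TestSmoother:
    def _trained(self, rng):
        tracks, labels, masks = [], [], []
        for _ in range(30):
            n = int(rng.integers(30, 60))
            lab = (rng.random(n) < 0.4).astype(float)
            raw = np.clip(lab * 0.7 + rng.normal(0.15, 0.1, n), 0, 1)
            cats = np.full(n, int(Category.INTRA_DISTANT))
            tracks.append(smoother_inputs(raw, cats))
            labels.append(lab)
            masks.append(np.ones(n, dtype=bool))
        return BiRNNSmoother(max_epochs=8, seed=0).fit(tracks, labels, masks)

    def test_output_length_preserved(self, rng):
        sm = self._trained(rng)
        raw = rng.random(45)
        cats = np.full(45, int(Category.EXTRA_PROXIMAL))
        assert len(smoother_predict(sm, raw, cats)) == 45

    def test_deterministic_given_same_input(self, rng):
        sm = self._trained(rng)
        raw = rng.random(40)
        cats = np.full(40, int(Category.EXTRA_DISTANT))
        a = smoother_predict(sm, raw, cats)
        b = smoother_predict(sm, raw, cats)
        np.testing.assert_array_equal(a, b)

    def test_truncated_lookback_contract(self, rng):
        # perturbing the input 13 positions away never changes the output
        sm = self._trained(rng)
        n, probe = 60, 30
        raw = rng.random(n)
        cats = np.full(n, int(Category.INTRA_DISTANT))
        base = smoother_predict(sm, raw, cats)
        for offset in (13, -13, 20, -20):
            perturbed = raw.copy()
            perturbed[probe + offset] = 1.0 - perturbed[probe + offset]
            out = smoother_predict(sm, perturbed, cats)
            assert out[probe] == base[probe]
        # while a perturbation within the window does change it
        perturbed = raw.copy()
        perturbed[probe + 5] = 1.0 - perturbed[probe + 5]
        assert smoother_predict(sm, perturbed, cats)[probe] != base[probe]

    def test_constant_zero_input_near_constant_output(self, rng):
        sm = self._trained(rng)
        cats = np.full(50, int(Category.INTRA_DISTANT))
        out = smoother_predict(sm, np.zeros(50), cats)
        interior = out[12:-12]
        assert interior.std() < 1e-9

    def test_length_mismatch_rejected(self, rng):
        sm = self._trained(rng)
        with pytest.raises(ValueError):
            smoother_predict(sm, np.zeros(10),
                             np.full(12, int(Category.INTRA_DISTANT)))


class TestEnsemble:
    def test_build_creates_four_cnns_and_a_smoother(self):
        model = build_ensemble()
        assert set(model.cnns_) == set(NON_MEMBRANE_CATEGORIES)
        assert len(model.cnns_) == 4
        assert isinstance(model.smoother_, BiRNNSmoother)

    def test_seeded_builds_are_identical(self, rng):
        a = _nn.init_convnet(11, 39, rng=np.random.default_rng(5))
        b = _nn.init_convnet(11, 39, rng=np.random.default_rng(5))
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_membrane_residues_scored_zero(self, tiny_ensemble, small_corpus):
        protein = small_corpus.proteins[0]
        result = tiny_ensemble.predict(
            protein, profile=small_corpus.profiles[protein.id],
            rsa=small_corpus.rsas[protein.id])
        mem = protein.topology.membrane_mask
        assert (result["raw"][mem] == 0).all()
        inputs = smoother_inputs(result["raw"], result["categories"])
        assert (inputs[mem, 0] == 0).all()

    def test_routing_ablation_leaves_other_compartments_unchanged(
            self, tiny_ensemble, small_corpus):
        protein = small_corpus.proteins[1]
        kw = dict(profile=small_corpus.profiles[protein.id],
                  rsa=small_corpus.rsas[protein.id])
        base = tiny_ensemble.predict(protein, **kw)
        for ablated_cat in NON_MEMBRANE_CATEGORIES:
            saved = tiny_ensemble.cnns_[ablated_cat].params_
            tiny_ensemble.cnns_[ablated_cat].params_ = {
                k: (v if k.startswith("_") else np.zeros_like(v))
                for k, v in saved.items()}
            try:
                out = tiny_ensemble.predict(protein, **kw)
            finally:
                tiny_ensemble.cnns_[ablated_cat].params_ = saved
            other = base["categories"] != ablated_cat
            np.testing.assert_array_equal(out["raw"][other],
                                          base["raw"][other])

    def test_save_load_round_trip(self, tiny_ensemble, small_corpus, tmp_path):
        tiny_ensemble.save(tmp_path / "bundle")
        loaded = MembraneDisorderEnsemble.load(tmp_path / "bundle")
        protein = small_corpus.proteins[2]
        kw = dict(profile=small_corpus.profiles[protein.id],
                  rsa=small_corpus.rsas[protein.id])
        a = tiny_ensemble.predict(protein, **kw)
        b = loaded.predict(protein, **kw)
        np.testing.assert_allclose(a["raw"], b["raw"])
        np.testing.assert_allclose(a["refined"], b["refined"])

    def test_schema_hash_mismatch_refused(self, tiny_ensemble, small_corpus):
        protein = small_corpus.proteins[0]
        with pytest.raises(ValueError, match="schema hash"):
            tiny_ensemble.predict(protein, expected_schema_hash="deadbeef")

    def test_refined_scores_in_unit_interval(self, tiny_ensemble,
                                             small_corpus):
        protein = small_corpus.proteins[3]
        result = tiny_ensemble.predict(
            protein, profile=small_corpus.profiles[protein.id],
            rsa=small_corpus.rsas[protein.id])
        for key in ("raw", "refined"):
            assert result[key].min() >= 0 and result[key].max() <= 1
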