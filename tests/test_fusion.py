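import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from treefuse.fusion import (
    FusionConfig,
    apply_other_threshold,
    assemble_features,
    predict_taxa,
    soft_f1_loss,
    train_fusion,
)


def closed_form(theta_t, k, eps=1e-7):
    """Soft-F1 loss for one-hot labels as a function of the true-class
    probability alone: 1 - 2*theta_t / (K*(1 + theta_t + eps))."""
    return 1.0 - 2.0 * theta_t / (k * (1.0 + theta_t + eps))


def random_simplex(rng, k):
    v = rng.dirichlet(np.ones(k))
    return v


class TestAssembleFeatures:
    def test_reference_configuration_length_440(self):
        fv = assemble_features(
            np.full(31, 1 / 31), np.zeros(369), np.zeros(40)
        )
        assert len(fv) == 440
        assert len(fv.values) == 440

    def test_toy_lengths(self):
        fv = assemble_features(np.array([0.5, 0.5]), np.zeros(3), np.zeros(4))
        assert len(fv.values) == 9

    def test_concatenation_order(self):
        fv = assemble_features(np.array([1.0]), np.array([2.0, 3.0]), np.array([4.0]))
        assert np.array_equal(fv.values, [1.0, 2.0, 3.0, 4.0])

    def test_block_length_mismatch_raises(self):
        cfg = FusionConfig(n_rgb=31, n_reflectance=369, n_lidar=40)
        with pytest.raises(ValueError):
            assemble_features(np.full(31, 1 / 31), np.zeros(368), np.zeros(40), cfg)

    def test_unnormalized_rgb_block_raises(self):
        with pytest.raises(ValueError):
            assemble_features(np.array([0.9, 0.3]), np.zeros(3), np.zeros(4))


class TestSoftF1Loss:
    def test_zero_true_class_probability_gives_exactly_one(self):
        for k in (2, 5, 31):
            theta = np.zeros(k)
            theta[1:] = 1.0 / (k - 1)
            y = np.zeros(k)
            y[0] = 1.0
            assert soft_f1_loss(theta, y) == 1.0

    def test_two_class_perfect_prediction_near_half(self):
        loss = soft_f1_loss(np.array([1.0, 0.0]), np.array([1.0, 0.0]))
        # true-class term ~ 1 - 2/(2+eps), other term exactly 1
        assert loss == pytest.approx(0.5, abs=1e-6)

    @given(st.integers(0, 2**31 - 1), st.integers(2, 40))
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form(self, seed, k):
        rng = np.random.default_rng(seed)
        theta = random_simplex(rng, k)
        t = int(rng.integers(k))
        y = np.zeros(k)
        y[t] = 1.0
        assert soft_f1_loss(theta, y) == pytest.approx(closed_form(theta[t], k), abs=1e-12)

    def test_depends_only_on_true_class_probability(self, rng):
        k = 6
        y = np.zeros(k)
        y[2] = 1.0
        theta_t = 0.3
        losses = []
        for _ in range(5):
            rest = rng.dirichlet(np.ones(k - 1)) * (1 - theta_t)
            theta = np.insert(rest, 2, theta_t)
            losses.append(soft_f1_loss(theta, y))
        assert np.ptp(losses) < 1e-12

    def test_strictly_decreasing_in_theta_t(self):
        k = 4
        y = np.eye(k)[0]
        grid = np.linspace(0.0, 1.0, 21)
        losses = [closed_form(t, k) for t in grid]
        # verify the closed form against direct evaluation, then monotonicity
        for t, l in zip(grid, losses):
            theta = np.zeros(k)
            theta[0] = t
            theta[1:] = (1 - t) / (k - 1)
            assert soft_f1_loss(theta, y) == pytest.approx(l, abs=1e-12)
        assert np.all(np.diff(losses) < 0)

    def test_minimum_approaches_k_minus_1_over_k(self):
        for k in (2, 10, 31):
            y = np.eye(k)[0]
            theta = np.eye(k)[0]
            assert soft_f1_loss(theta, y) == pytest.approx((k - 1) / k, abs=1e-6)

    def test_non_one_hot_label_rejected(self):
        with pytest.raises(ValueError):
            soft_f1_loss(np.array([0.5, 0.5]), np.array([1.0, 1.0]))


def separable_features(rng, n_per_class=300, n_classes=3, dim=12, margin=8.0):
    xs, ys = [], []
    for c in range(n_classes):
        center = np.zeros(dim)
        center[c] = margin
        xs.append(center + rng.normal(0, 1.0, (n_per_class, dim)))
        ys += [f"C{c}"] * n_per_class
    return np.vstack(xs), ys


class TestTrainFusion:
    def test_separable_classes_high_holdout_accuracy(self, rng):
        x, y = separable_features(rng)
        # nearest-centroid oracle confirms the separation is generous
        idx = rng.permutation(len(x))
        n_tr = int(0.8 * len(x))
        tr, ho = idx[:n_tr], idx[n_tr:]
        y = np.array(y)
        cents = {c: x[tr][y[tr] == c].mean(0) for c in set(y)}
        oracle = [
            min(cents, key=lambda c: np.linalg.norm(r - cents[c])) for r in x[ho]
        ]
        assert np.mean(np.array(oracle) == y[ho]) >= 0.99

        model = train_fusion(x[tr], y[tr].tolist(), FusionConfig(epochs=150, seed=0))
        probs = predict_taxa(model, x[ho])
        pred = [model.class_order[i] for i in probs.argmax(1)]
        assert np.mean(np.array(pred) == y[ho]) >= 0.9

    def test_training_loss_decreases(self, rng):
        x, y = separable_features(rng, n_per_class=100)
        model = train_fusion(x, y, FusionConfig(epochs=20, seed=0))
        assert model.epoch_losses[-1] <= model.epoch_losses[0]

    def test_deterministic_given_seed(self, rng):
        x, y = separable_features(rng, n_per_class=50)
        a = train_fusion(x, y, FusionConfig(epochs=5, seed=3))
        b = train_fusion(x, y, FusionConfig(epochs=5, seed=3))
        assert a.epoch_losses == b.epoch_losses
        assert all(np.array_equal(p, q) for p, q in zip(a.net.parameters(), b.net.parameters()))

    def test_single_class_rejected(self, rng):
        x = rng.normal(size=(10, 4))
        with pytest.raises(ValueError):
            train_fusion(x, ["A"] * 10)

    def test_cross_entropy_switch(self, rng):
        x, y = separable_features(rng, n_per_class=50)
        model = train_fusion(x, y, FusionConfig(epochs=20, loss="cross_entropy", seed=0))
        assert model.epoch_losses[-1] < model.epoch_losses[0]

    def test_save_load_round_trip(self, rng, tmp_path):
        x, y = separable_features(rng, n_per_class=30)
        model = train_fusion(x, y, FusionConfig(epochs=5, seed=0))
        from treefuse.fusion import FusionModel

        model.save(tmp_path / "m.npz")
        back = FusionModel.load(tmp_path / "m.npz")
        assert np.array_equal(predict_taxa(model, x[:5]), predict_taxa(back, x[:5]))


class TestPredictTaxa:
    @pytest.fixture(scope="class")
    def model(self):
        rng = np.random.default_rng(0)
        x, y = separable_features(rng, n_per_class=60, n_classes=4)
        return train_fusion(x, y, FusionConfig(epochs=20, seed=0)), x

    def test_probabilities_normalized(self, model):
        m, x = model
        probs = predict_taxa(m, x[:10])
        assert np.all(probs >= 0)
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)
        assert probs.shape[1] == 4

    def test_identical_inputs_identical_outputs(self, model):
        m, x = model
        assert np.array_equal(predict_taxa(m, x[0]), predict_taxa(m, x[0]))

    def test_length_mismatch_raises(self, model):
        m, _ = model
        with pytest.raises(ValueError):
            predict_taxa(m, np.zeros(5))


class TestApplyOtherThreshold:
    def test_below_threshold_redistributes(self):
        out = apply_other_threshold(np.array([0.4, 0.3, 0.3]))
        assert np.allclose(out, [0.2, 0.15, 0.15, 0.5])

    def test_above_threshold_passthrough(self):
        out = apply_other_threshold(np.array([0.7, 0.2, 0.1]))
        assert np.allclose(out, [0.7, 0.2, 0.1, 0.0])

    def test_boundary_exactly_half_passes_through(self):
        out = apply_other_threshold(np.array([0.5, 0.25, 0.25]))
        assert np.allclose(out, [0.5, 0.25, 0.25, 0.0])

    @given(st.integers(0, 2**31 - 1), st.integers(2, 30))
    @settings(max_examples=50, deadline=None)
    def test_ranking_preserved_and_normalized(self, seed, k):
        rng = np.random.default_rng(seed)
        probs = rng.dirichlet(np.ones(k))
        out = apply_other_threshold(probs)
        assert out.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.array_equal(np.argsort(out[:k]), np.argsort(probs))
        if probs.max() < 0.5:
            assert out[-1] == 0.5
        else:
            assert out[-1] == 0.0

    def test_unnormalized_input_rejected(self):
        with pytest.raises(ValueError):
            apply_other_threshold(np.array([0.9, 0.5]))
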