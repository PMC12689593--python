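"""Knowledge distillation: softened targets, KL, the combined objective."""

import numpy as np
import pytest

from quanvkd import distillation as kd
from quanvkd import nn


class TestSoftenedProbs:
    def test_temperature_one_is_plain_softmax(self, rng):
        logits = rng.uniform(-3, 3, size=5)
        assert np.allclose(kd.softened_probs(logits, 1.0), nn.softmax(logits))

    def test_huge_temperature_approaches_uniform(self):
        probs = kd.softened_probs(np.array([5.0, -1.0, 2.0, 0.0]), 1e9)
        assert np.allclose(probs, 0.25, atol=1e-6)

    def test_halved_logits_example(self):
        probs = kd.softened_probs(np.array([2.0, 0.0]), 2.0)
        assert probs == pytest.approx([0.7311, 0.2689], abs=1e-4)

    def test_raising_temperature_flattens_max_probability(self):
        logits = np.array([3.0, 1.0, 0.0])
        maxima = [kd.softened_probs(logits, t).max() for t in (1, 2, 5, 20)]
        assert all(a > b for a, b in zip(maxima, maxima[1:]))

    def test_rejects_nonpositive_temperature(self):
        with pytest.raises(ValueError):
            kd.softened_probs(np.zeros(2), 0.0)


class TestKL:
    def test_identical_distributions_give_zero(self, rng):
        p = nn.softmax(rng.uniform(size=4))
        assert kd.kl_divergence(p, p) == pytest.approx(0.0, abs=1e-12)

    def test_point_mass_versus_uniform_is_log2(self):
        assert kd.kl_divergence([1.0, 0.0], [0.5, 0.5]) == \
            pytest.approx(np.log(2), abs=1e-9)

    def test_nonnegative_over_random_pairs(self, rng):
        for _ in range(1000):
            p = nn.softmax(rng.uniform(-5, 5, size=4))
            q = nn.softmax(rng.uniform(-5, 5, size=4))
            assert kd.kl_divergence(p, q) >= -1e-12


class TestDistillLoss:
    def test_alpha_one_reduces_to_cross_entropy(self, rng):
        y = nn.one_hot(np.array([1]), 4)[0]
        s = rng.uniform(-2, 2, size=4)
        t = rng.uniform(-2, 2, size=4)
        cfg = kd.DistillConfig(temperature=5.0, alpha=1.0)
        assert kd.distill_loss(y, s, t, cfg) == \
            pytest.approx(nn.cross_entropy(y, nn.softmax(s)), abs=1e-12)

    def test_identical_logits_leave_only_ce_term(self, rng):
        y = nn.one_hot(np.array([0]), 3)[0]
        s = rng.uniform(-2, 2, size=3)
        cfg = kd.DistillConfig(temperature=5.0, alpha=0.5)
        expected = 0.5 * nn.cross_entropy(y, nn.softmax(s))
        assert kd.distill_loss(y, s, s, cfg) == pytest.approx(expected, abs=1e-12)

    def test_hand_computed_two_term_value(self):
        """y=(1,0), S=(0,0), T_logits=(2,0), T=2, alpha=0.5: CE = log 2 and
        the KL term compares (0.7311, 0.2689) against uniform."""
        y = np.array([1.0, 0.0])
        s = np.zeros(2)
        t = np.array([2.0, 0.0])
        cfg = kd.DistillConfig(temperature=2.0, alpha=0.5)
        soft_t = np.exp([1.0, 0.0]) / np.exp([1.0, 0.0]).sum()
        kl_hand = float(np.sum(soft_t * np.log(soft_t / 0.5)))
        expected = 0.5 * np.log(2) + 0.5 * kl_hand
        assert kd.distill_loss(y, s, t, cfg) == pytest.approx(expected, abs=1e-12)

    def test_continuous_in_alpha_with_exact_endpoints(self, rng):
        y = nn.one_hot(np.array([2]), 4)[0]
        s = rng.uniform(-2, 2, size=4)
        t = rng.uniform(-2, 2, size=4)
        ce = nn.cross_entropy(y, nn.softmax(s))
        kl = kd.kl_divergence(kd.softened_probs(t, 5.0), kd.softened_probs(s, 5.0))
        alphas = np.linspace(0, 1, 11)
        values = [kd.distill_loss(y, s, t, kd.DistillConfig(5.0, a))
                  for a in alphas]
        assert values[0] == pytest.approx(kl, abs=1e-12)
        assert values[-1] == pytest.approx(ce, abs=1e-12)
        assert np.allclose(values, [a * ce + (1 - a) * kl for a in alphas])

    def test_squared_t_scaling_multiplies_kl_term(self, rng):
        y = nn.one_hot(np.array([0]), 3)[0]
        s, t = rng.uniform(-1, 1, size=3), rng.uniform(-1, 1, size=3)
        base = kd.distill_loss(y, s, t, kd.DistillConfig(3.0, 0.0))
        scaled = kd.distill_loss(y, s, t,
                                 kd.DistillConfig(3.0, 0.0, squared_t_scaling=True))
        assert scaled == pytest.approx(9.0 * base, rel=1e-10)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            kd.distill_loss(np.zeros(3), np.zeros(3), np.zeros(4),
                            kd.DistillConfig())

    def test_kl_gradient_vanishes_when_student_matches_teacher(self):
        """The soft-target gradient must be zero at the matched point."""
        t_logits = np.array([[1.0, -0.5, 0.3]])
        cfg = kd.DistillConfig(temperature=4.0, alpha=0.0)
        loss_fn = kd.make_distill_loss_fn(t_logits, cfg)
        y = nn.one_hot(np.array([0]), 3)
        dlogits, _ = loss_fn(t_logits.copy(), y, np.array([0]))
        assert np.allclose(dlogits, 0.0, atol=1e-12)

    def test_loss_fn_gradient_matches_finite_difference(self, rng):
        t_logits = rng.uniform(-2, 2, size=(2, 4))
        s_logits = rng.uniform(-2, 2, size=(2, 4))
        y = nn.one_hot(np.array([1, 3]), 4)
        cfg = kd.DistillConfig(temperature=5.0, alpha=0.5)
        loss_fn = kd.make_distill_loss_fn(t_logits, cfg)
        idx = np.array([0, 1])
        dlogits, comp = loss_fn(s_logits, y, idx)
        h = 1e-6
        for i in range(2):
            for j in range(4):
                up, dn = s_logits.copy(), s_logits.copy()
                up[i, j] += h
                dn[i, j] -= h
                fd = (loss_fn(up, y, idx)[1]["total_loss"]
                      - loss_fn(dn, y, idx)[1]["total_loss"]) / (2 * h)
                assert dlogits[i, j] == pytest.approx(fd, abs=1e-6)


class TestTrainWithDistillation:
    @pytest.fixture
    def setup(self, rng):
        x = rng.uniform(size=(24, 4, 4, 1))
        labels = (x[:, :2].mean(axis=(1, 2, 3)) > 0.5).astype(int)
        y = nn.one_hot(labels, 2)
        t_spec = nn.ModelSpec("teacher", input_shape=(4, 4, 1), n_classes=2,
                              conv_filters=(4, 6), dense_units=8)
        teacher = nn.build_model(t_spec, seed=0)
        nn.train_classifier(teacher, x, y, x, y, nn.TrainConfig(max_epochs=3, seed=0))
        s_spec = nn.ModelSpec("student", input_shape=(4, 4, 1), n_classes=2,
                              conv_filters=(2, 3), dense_units=4)
        return x, y, teacher, s_spec

    def test_teacher_weights_frozen_through_run(self, setup):
        x, y, teacher, s_spec = setup
        before = nn.weights_checksum(teacher)
        kd.train_with_distillation(teacher, s_spec, x, y, x, y,
                                   kd.DistillConfig(), nn.TrainConfig(max_epochs=3, seed=1))
        assert nn.weights_checksum(teacher) == before

    def test_history_carries_loss_components(self, setup):
        x, y, teacher, s_spec = setup
        _, history = kd.train_with_distillation(
            teacher, s_spec, x, y, x, y, kd.DistillConfig(),
            nn.TrainConfig(max_epochs=3, seed=1))
        for row in history:
            assert {"total_loss", "ce_component", "kl_component",
                    "val_loss", "val_accuracy"} <= set(row)
            assert row["kl_component"] >= -1e-12

    def test_alpha_one_equals_plain_training_trajectory(self, setup):
        x, y, teacher, s_spec = setup
        cfg = nn.TrainConfig(max_epochs=3, seed=5)
        kd_student, _ = kd.train_with_distillation(
            teacher, s_spec, x, y, x, y,
            kd.DistillConfig(alpha=1.0), cfg)
        plain = nn.build_model(s_spec, seed=cfg.seed)
        nn.train_classifier(plain, x, y, x, y, cfg)
        assert np.array_equal(kd_student.predict_logits(x),
                              plain.predict_logits(x))

    def test_history_csv_round_trip(self, setup, tmp_path):
        import pandas as pd

        x, y, teacher, s_spec = setup
        _, history = kd.train_with_distillation(
            teacher, s_spec, x, y, x, y, kd.DistillConfig(),
            nn.TrainConfig(max_epochs=2, seed=1))
        path = tmp_path / "history.csv"
        kd.write_history_csv(history, path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["epoch", "total_loss", "ce_component",
                                       "kl_component", "val_loss", "val_accuracy"]
        assert len(frame) == len(history)
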