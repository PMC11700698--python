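import numpy as np
import pandas as pd
import pytest

from octmel import (
    ImageDataset,
    PairSampler,
    TrainConfig,
    build_model,
    eligible_week_pairs,
    load_model,
    relative_loss,
    save_model,
    train,
)
from octmel.dl_model import (
    ConfigError,
    PairSamplingError,
    SubjectLeakageError,
    bce_with_logits,
    relative_loss_grad,
    sigmoid,
)
from oracles import brute_force_relative_loss

TINY = dict(input_size=16, conv_channels=(4, 8), pool=4, dense_units=8)


def _dataset(rng, subjects, weeks, slices=2, size=16, group="induced"):
    rows, images = [], []
    for subj in subjects:
        for w in weeks:
            for s in range(slices):
                rows.append({"subject_id": subj, "group": group, "week": w,
                             "slice": s, "label": int(group == "induced")})
                images.append(rng.random((size, size, 3), dtype=np.float32))
    return ImageDataset(images=np.stack(images), index=pd.DataFrame(rows))


def _toy_train_sets(rng, size=16):
    """Separable two-class data: induced images brighter in a block."""
    rows, images = [], []
    for subj, group in [("I1", "induced"), ("I2", "induced"),
                        ("C1", "control"), ("C2", "control")]:
        for w in (0, 2, 4):
            for s in range(4):
                img = rng.random((size, size, 3), dtype=np.float32) * 0.3
                if group == "induced":
                    img[4:12, 4:12] += 0.6
                rows.append({"subject_id": subj, "group": group, "week": w,
                             "slice": s, "label": int(group == "induced")})
                images.append(img)
    ds = ImageDataset(images=np.stack(images), index=pd.DataFrame(rows))
    val_rows = np.arange(0, len(ds), 6)
    train_rows = np.setdiff1d(np.arange(len(ds)), val_rows)
    return ds.subset(train_rows), ds.subset(val_rows)


class TestRelativeLoss:
    def test_ordered_pairs_zero(self):
        assert relative_loss([0.2, 0.1], [0.9, 0.5]) == 0.0

    def test_single_violated_pair(self):
        assert relative_loss([0.9], [0.4]) == pytest.approx(0.5)

    def test_mixed_batch_hand_value(self):
        assert relative_loss([0.8, 0.2], [0.3, 0.7]) == pytest.approx(0.25)

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError):
            relative_loss([], [])

    def test_out_of_range_scores_rejected(self):
        with pytest.raises(ValueError):
            relative_loss([1.2], [0.5])

    def test_matches_bruteforce_on_random_batches(self):
        """Closed form equals per-pair ReLU enumeration, 1000 batches."""
        rng = np.random.default_rng(0)
        for _ in range(1000):
            n = int(rng.integers(1, 20))
            y1, y2 = rng.random(n), rng.random(n)
            expected = brute_force_relative_loss(list(zip(y1, y2)))
            assert relative_loss(y1, y2) == pytest.approx(expected, abs=1e-12)

    def test_gradient_signs(self):
        """dL/d(later) <= 0 and dL/d(earlier) >= 0 on active pairs, 0 else."""
        rng = np.random.default_rng(1)
        y1, y2 = rng.random(50), rng.random(50)
        g1, g2 = relative_loss_grad(y1, y2)
        active = y1 > y2
        assert np.all(g1[active] > 0) and np.all(g2[active] < 0)
        assert np.all(g1[~active] == 0) and np.all(g2[~active] == 0)
        # numerical check against central differences
        eps = 1e-6
        for i in range(0, 50, 10):
            if abs(y1[i] - y2[i]) < 10 * eps:
                continue
            up, down = y1.copy(), y1.copy()
            up[i] += eps
            down[i] -= eps
            num = (relative_loss(up, y2) - relative_loss(down, y2)) / (2 * eps)
            assert num == pytest.approx(g1[i], abs=1e-6)


class TestPairSampler:
    def test_week_pair_enumeration(self):
        assert eligible_week_pairs([0, 3, 6]) == [(0, 3), (0, 6), (3, 6)]
        assert eligible_week_pairs([0, 1]) == []

    def test_no_eligible_pair_raises_with_subjects(self):
        rng = np.random.default_rng(0)
        ds = _dataset(rng, ["A"], weeks=[0, 1])
        with pytest.raises(PairSamplingError, match="A"):
            PairSampler(ds.index)

    def test_emitted_pairs_time_ordered(self):
        rng = np.random.default_rng(1)
        ds = _dataset(rng, ["A", "B"], weeks=[0, 2, 5])
        sampler = PairSampler(ds.index)
        e, l = sampler.sample_batch(64, np.random.default_rng(2))
        weeks = ds.index["week"].to_numpy()
        subs = ds.index["subject_id"].to_numpy()
        assert np.all(weeks[l] - weeks[e] >= 2)
        assert np.all(subs[e] == subs[l])
        slices = ds.index["slice"].to_numpy()
        assert np.all(slices[e] == slices[l])

    def test_control_subjects_excluded_by_default(self):
        rng = np.random.default_rng(2)
        ind = _dataset(rng, ["A"], weeks=[0, 3])
        ctl = _dataset(rng, ["C"], weeks=[0, 3], group="control")
        both = ImageDataset(
            images=np.concatenate([ind.images, ctl.images]),
            index=pd.concat([ind.index, ctl.index], ignore_index=True))
        sampler = PairSampler(both.index)
        assert sampler.subjects == ["A"]


class TestModel:
    def test_single_logit_at_full_input_size(self):
        model = build_model(TrainConfig(backbone="tiny_vgg", input_size=512))
        x = np.random.default_rng(0).random((1, 512, 512, 3), dtype=np.float32)
        assert model.forward(x).shape == (1,)

    def test_batch_of_n_gives_n_logits(self):
        model = build_model(TrainConfig(**TINY))
        x = np.random.default_rng(1).random((5, 16, 16, 3), dtype=np.float32)
        assert model.forward(x).shape == (5,)

    def test_same_seed_same_initial_weights(self):
        a = build_model(TrainConfig(seed=3, **TINY))
        b = build_model(TrainConfig(seed=3, **TINY))
        for pa, pb in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_unknown_backbone_rejected(self):
        with pytest.raises(ConfigError):
            TrainConfig(backbone="resnet")

    def test_pretrained_without_weights_rejected(self):
        with pytest.raises(ConfigError):
            build_model(TrainConfig(backbone="vgg16", pretrained=True,
                                    input_size=32))

    def test_scores_bounded_and_deterministic(self):
        model = build_model(TrainConfig(**TINY))
        model.trained = True
        x = np.random.default_rng(2).random((4, 16, 16, 3), dtype=np.float32)
        s1 = model.predict_scores(x)
        s2 = model.predict_scores(x)
        np.testing.assert_array_equal(s1, s2)
        assert np.all((s1 >= 0) & (s1 <= 1))

    def test_backprop_matches_numerical_gradient(self):
        """End-to-end analytic gradients agree with central differences."""
        model = build_model(TrainConfig(input_size=8, conv_channels=(3,),
                                        pool=2, dense_units=4, seed=5))
        rng = np.random.default_rng(6)
        x = rng.random((2, 8, 8, 3)).astype(np.float32)
        y = np.array([1.0, 0.0])

        def loss_fn():
            return bce_with_logits(model.forward(x), y)[0]

        model.zero_grad()
        _, gz = bce_with_logits(model.forward(x), y)
        model.backward(gz)
        grads = [g.copy() for g in model.gradients()]
        eps = 1e-3
        checked = 0
        for p, g in zip(model.parameters(), grads):
            flat = p.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 3)):
                orig = flat[idx]
                flat[idx] = orig + eps
                up = loss_fn()
                flat[idx] = orig - eps
                down = loss_fn()
                flat[idx] = orig
                num = (up - down) / (2 * eps)
                assert num == pytest.approx(g.ravel()[idx], abs=5e-3)
                checked += 1
        assert checked >= 10

    def test_save_load_round_trip(self, tmp_path):
        model = build_model(TrainConfig(**TINY))
        model.trained = True
        save_model(model, tmp_path / "run")
        back = load_model(tmp_path / "run")
        x = np.random.default_rng(3).random((3, 16, 16, 3), dtype=np.float32)
        np.testing.assert_allclose(back.predict_scores(x),
                                   model.predict_scores(x), atol=1e-6)


class TestTraining:
    def test_zero_relative_weight_identical_to_plain_bce(self):
        rng = np.random.default_rng(0)
        train_ds, val_ds = _toy_train_sets(rng)
        losses = []
        for _ in range(2):
            cfg = TrainConfig(loss_weight_relative=0.0, learning_rate=1e-3,
                              batch_size=8, max_epochs=2, seed=9, **TINY)
            model = build_model(cfg)
            hist = train(model, train_ds, val_ds, cfg)
            losses.append(hist.train_loss)
        assert losses[0] == losses[1]

    def test_learns_separable_data(self):
        rng = np.random.default_rng(1)
        train_ds, val_ds = _toy_train_sets(rng)
        cfg = TrainConfig(learning_rate=3e-3, batch_size=8, max_epochs=15,
                          pairs_per_batch=4, seed=0, **TINY)
        model = build_model(cfg)
        hist = train(model, train_ds, val_ds, cfg)
        assert hist.best_val_accuracy >= 0.95

    def test_early_stopping_within_patience(self):
        rng = np.random.default_rng(2)
        train_ds, val_ds = _toy_train_sets(rng)
        cfg = TrainConfig(learning_rate=3e-3, batch_size=8, max_epochs=40,
                          patience=3, loss_weight_relative=0.0, seed=1, **TINY)
        model = build_model(cfg)
        hist = train(model, train_ds, val_ds, cfg)
        # terminates no later than patience epochs past the last acc improvement
        acc = hist.val_accuracy
        last_improve = max(i for i in range(len(acc))
                           if acc[i] == max(acc[: i + 1])
                           and (i == 0 or acc[i] > max(acc[:i])))
        assert hist.stopped_epoch <= last_improve + cfg.patience

    def test_subject_leakage_rejected(self):
        rng = np.random.default_rng(3)
        train_ds, val_ds = _toy_train_sets(rng)
        with pytest.raises(SubjectLeakageError):
            train(build_model(TrainConfig(max_epochs=1, **TINY)),
                  train_ds, val_ds,
                  TrainConfig(max_epochs=1, **TINY),
                  test_subjects=["I1"])

    def test_empty_validation_rejected(self):
        rng = np.random.default_rng(4)
        train_ds, _ = _toy_train_sets(rng)
        empty = train_ds.subset(np.array([], dtype=int))
        with pytest.raises(ValueError):
            train(build_model(TrainConfig(**TINY)), train_ds, empty,
                  TrainConfig(**TINY))
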