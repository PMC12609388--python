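"""Classifier construction, training behaviour and prediction contracts."""

import warnings

import numpy as np
import pytest

from virafall.core import build_graph
from virafall.model import (
    FallGCN,
    FallGCNResults,
    ModelConfig,
    TrainConfig,
    sequences_to_array,
)
from virafall.model import _Network
from virafall.synth import generate_sequences

from .conftest import desk_config

TINY = ModelConfig(
    num_streams=1, backbone_channels=(8,), temporal_strides=(1,),
    temporal_kernel=3, mask_fraction=0.0, seed=0,
)


@pytest.fixture(scope="module")
def small_seqs():
    return generate_sequences(desk_config(n_sequences=24, seed=42))


class TestConfig:
    def test_binary_only(self):
        with pytest.raises(ValueError, match="binary"):
            ModelConfig(num_classes=3)

    def test_masked_joint_count_is_ceil(self):
        assert ModelConfig(mask_fraction=0.3).masked_joint_count == 6  # ceil(5.1)
        assert ModelConfig(mask_fraction=0.0).masked_joint_count == 0


class TestBuild:
    def test_param_count_pure_function_of_config(self, small_seqs):
        counts = {
            FallGCN(config=ModelConfig(num_streams=2, seed=s)).param_count
            for s in (0, 1, 99)
        }
        assert len(counts) == 1

    def test_forward_zero_input_finite(self):
        net = _Network(ModelConfig(num_streams=2, seed=0), build_graph("COCO17"))
        logits, per_stream = net.forward(np.zeros((2, 3, 20, 17), np.float32),
                                         training=False)
        assert np.isfinite(logits).all()
        assert per_stream.shape == (2, 2, 2)

    def test_graph_joint_mismatch_rejected(self):
        with pytest.raises(ValueError, match="joints"):
            _Network(ModelConfig(num_streams=1), build_graph("KINECT25"))

    def test_stream_masking_removes_exact_joint_count(self, rng):
        cfg = ModelConfig(num_streams=2, mask_fraction=0.3, seed=0)
        net = _Network(cfg, build_graph("COCO17"))
        x = rng.normal(size=(3, 3, 20, 17)).astype(np.float32)
        # instrument: capture the second stream's input
        captured = {}
        orig = net.streams[1].forward

        def spy(xs, training):
            captured["x"] = xs
            return orig(xs, training)

        net.streams[1].forward = spy
        net.forward(x, training=False)
        zeroed = (captured["x"] == 0).all(axis=(1, 2))  # (N, V) all-zero joints
        assert (zeroed.sum(axis=1) >= cfg.masked_joint_count).all()

    def test_single_stream_no_mask_ignores_masking_machinery(self, rng):
        x = rng.normal(size=(2, 3, 20, 17)).astype(np.float32)
        cfg = ModelConfig(num_streams=1, mask_fraction=0.0, seed=3)
        a = _Network(cfg, build_graph("COCO17")).forward(x, False)[0]
        b = _Network(cfg, build_graph("COCO17")).forward(x, False)[0]
        np.testing.assert_array_equal(a, b)


class TestTraining:
    def test_loss_decreases_on_learnable_task(self, small_seqs):
        res = FallGCN(small_seqs, config=TINY).fit(
            TrainConfig(epochs=8, batch_size=8, lr=0.01, optimizer="adam", seed=0)
        )
        hist = res.history
        assert hist["loss"].iloc[-1] < hist["loss"].iloc[0]
        assert len(hist) == 8

    def test_zero_learning_rate_freezes_weights(self, small_seqs):
        model = FallGCN(small_seqs, config=TINY)
        res = model.fit(TrainConfig(epochs=1, batch_size=8, lr=0.0,
                                    optimizer="sgd", momentum=0.0, seed=0))
        fresh = _Network(TINY, model.graph)
        for p_trained, p_fresh in zip(res.network.params(), fresh.params()):
            np.testing.assert_array_equal(p_trained.value, p_fresh.value)

    def test_single_class_data_warns_but_proceeds(self):
        seqs = generate_sequences(desk_config(n_sequences=8, fall_fraction=1.0))
        with pytest.warns(UserWarning, match="single class"):
            FallGCN(seqs, config=TINY).fit(
                TrainConfig(epochs=1, batch_size=4, seed=0)
            )

    def test_identical_seeds_reproduce_history(self, small_seqs):
        tc = TrainConfig(epochs=3, batch_size=8, lr=0.01, optimizer="adam", seed=5)
        h1 = FallGCN(small_seqs, config=TINY).fit(tc).history
        h2 = FallGCN(small_seqs, config=TINY).fit(tc).history
        assert (h1["loss"] == h2["loss"]).all()

    def test_balanced_weighting_lifts_minority_recall(self):
        # 9:1 imbalance; compare minority (fall) recall across weightings
        train = generate_sequences(
            desk_config(n_sequences=100, fall_fraction=0.1, seed=8)
        )
        test = generate_sequences(
            desk_config(n_sequences=60, fall_fraction=0.5, seed=9)
        )
        recalls = {}
        for weighting in ("none", "balanced"):
            rec = []
            for seed in (0, 1):
                cfg = ModelConfig(num_streams=1, backbone_channels=(8,),
                                  temporal_strides=(1,), temporal_kernel=3,
                                  mask_fraction=0.0, seed=seed)
                res = FallGCN(train, config=cfg).fit(
                    TrainConfig(epochs=6, batch_size=16, lr=0.01,
                                optimizer="adam", class_weighting=weighting,
                                seed=seed)
                )
                preds = res.predict(test)
                y = np.array([s.label for s in test])
                hats = np.array([p.label_hat for p in preds])
                tp = ((y == 1) & (hats == 1)).sum()
                rec.append(tp / (y == 1).sum())
            recalls[weighting] = np.mean(rec)
        assert recalls["balanced"] >= recalls["none"]


@pytest.fixture(scope="module")
def fitted(small_seqs):
    return FallGCN(small_seqs, config=TINY).fit(
        TrainConfig(epochs=5, batch_size=8, lr=0.01, optimizer="adam", seed=1)
    )


class TestPredict:
    def test_eval_mode_deterministic(self, fitted, small_seqs):
        a = fitted.predict(small_seqs[:5])
        b = fitted.predict(small_seqs[:5])
        assert [p.prob_fall for p in a] == [p.prob_fall for p in b]

    def test_batch_order_equivariance(self, fitted, small_seqs):
        x, _ = sequences_to_array(small_seqs[:8])
        p = fitted.predict_proba(x)
        perm = np.array([3, 1, 7, 0, 2, 6, 4, 5])
        p_perm = fitted.predict_proba(x[perm])
        np.testing.assert_allclose(p_perm, p[perm], atol=1e-6)

    def test_probs_are_softmax_of_logits(self, fitted, small_seqs):
        x, _ = sequences_to_array(small_seqs[:4])
        logits, _ = fitted.network.forward(x.astype(np.float32), training=False)
        expect = np.exp(logits[:, 1]) / np.exp(logits).sum(axis=1)
        probs = np.array([p.prob_fall for p in fitted.predict(x)])
        np.testing.assert_allclose(probs, expect, rtol=1e-5)

    def test_threshold_sets_label(self, fitted, small_seqs):
        preds = fitted.predict(small_seqs[:6], threshold=0.5)
        for p in preds:
            assert p.label_hat == int(p.prob_fall >= 0.5)

    def test_wrong_convention_rejected(self, fitted, rng):
        from .conftest import random_sequence
        from virafall.core import Convention

        seq = random_sequence(rng, convention=Convention.KINECT25)
        with pytest.raises(ValueError, match="COCO17"):
            fitted.predict([seq])


class TestCheckpoint:
    def test_save_load_round_trip(self, small_seqs, tmp_path):
        res = FallGCN(small_seqs, config=TINY).fit(
            TrainConfig(epochs=2, batch_size=8, lr=0.01, optimizer="adam", seed=2)
        )
        path = tmp_path / "model.npz"
        res.save(path)
        back = FallGCNResults.load(path)
        x, _ = sequences_to_array(small_seqs[:5])
        np.testing.assert_allclose(
            back.predict_proba(x), res.predict_proba(x), atol=1e-7
        )
        assert back.config == res.config
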