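"""Consensus aggregation, metric formulas and the ablation driver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from virafall.evaluate import (
    AggregationSpec,
    ConfusionCounts,
    Recipe,
    aggregate_predict,
    compute_metrics,
    run_ablation,
)
from virafall.model import FallGCN, ModelConfig, TrainConfig
from virafall.synth import generate_sequences

from .conftest import desk_config


def _brute_force_metrics(tp, tn, fp, fn):
    """Independent oracle: the five ratios evaluated literally."""
    total = tp + tn + fp + fn
    acc = (tp + tn) / total
    prec = tp / (tp + fp) if tp + fp else math.nan
    sens = tp / (tp + fn) if tp + fn else math.nan
    spec = tn / (tn + fp) if tn + fp else math.nan
    if math.isnan(prec) or math.isnan(sens) or prec + sens == 0:
        f1 = math.nan
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return acc, prec, sens, spec, f1


class TestMetrics:
    def test_perfect_classifier_scores_100_everywhere(self):
        rep = compute_metrics(ConfusionCounts(tp=50, tn=50, fp=0, fn=0))
        assert rep.accuracy == rep.sensitivity == rep.specificity == rep.f1 == 1.0

    def test_hand_evaluated_mixed_table(self):
        rep = compute_metrics(ConfusionCounts(tp=90, tn=80, fp=20, fn=10))
        assert abs(rep.accuracy - 0.85) < 1e-12
        assert abs(rep.precision - 90 / 110) < 1e-12
        assert abs(rep.sensitivity - 0.90) < 1e-12
        assert abs(rep.specificity - 0.80) < 1e-12
        assert abs(rep.f1 - (2 * (90 / 110) * 0.9) / ((90 / 110) + 0.9)) < 1e-12
        assert rep.as_percent()["f1"] == "85.71%"

    def test_zero_false_positives_means_perfect_specificity(self):
        rep = compute_metrics(ConfusionCounts(tp=3, tn=7, fp=0, fn=2))
        assert rep.specificity == 1.0

    def test_undefined_ratios_are_nan_not_zero(self):
        rep = compute_metrics(ConfusionCounts(tp=0, tn=5, fp=0, fn=0))
        assert math.isnan(rep.precision) and math.isnan(rep.sensitivity)
        assert math.isnan(rep.f1)
        assert rep.as_percent()["precision"] == "undefined"

    @given(
        st.integers(0, 500), st.integers(0, 500),
        st.integers(0, 500), st.integers(0, 500),
    )
    @settings(max_examples=1000, deadline=None)
    def test_matches_brute_force_oracle(self, tp, tn, fp, fn):
        if tp + tn + fp + fn == 0:
            return
        rep = compute_metrics(ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn))
        for got, want in zip(
            (rep.accuracy, rep.precision, rep.sensitivity, rep.specificity, rep.f1),
            _brute_force_metrics(tp, tn, fp, fn),
        ):
            if math.isnan(want):
                assert math.isnan(got)
            else:
                assert abs(got - want) < 1e-12

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, tn=0, fp=0, fn=0)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError, match="zero samples"):
            compute_metrics(ConfusionCounts(tp=0, tn=0, fp=0, fn=0))


@pytest.fixture(scope="module")
def tiny_fitted():
    seqs = generate_sequences(desk_config(n_sequences=24, seed=55))
    cfg = ModelConfig(num_streams=1, backbone_channels=(8,),
                      temporal_strides=(1,), temporal_kernel=3,
                      mask_fraction=0.0, seed=0)
    return FallGCN(seqs, config=cfg).fit(
        TrainConfig(epochs=5, batch_size=8, lr=0.01, optimizer="adam", seed=0)
    ), seqs


class TestAggregation:
    def test_singleton_equals_plain_prediction(self, tiny_fitted):
        res, seqs = tiny_fitted
        spec = AggregationSpec(angles=((0.0, 0.0),))
        for s in seqs[:4]:
            agg = aggregate_predict(res, s, spec)
            plain = res.predict([s])[0]
            assert abs(agg.prob_fall - plain.prob_fall) < 1e-12

    def test_mean_combiner_is_arithmetic_mean(self, tiny_fitted):
        res, seqs = tiny_fitted
        spec = AggregationSpec()
        s = seqs[0]
        per_view = [
            res.predict([v])[0].prob_fall
            for v in (
                s,
                _rot(s, 15.0, 0.0),
                _rot(s, 25.0, 0.0),
            )
        ]
        agg = aggregate_predict(res, s, spec)
        assert abs(agg.prob_fall - np.mean(per_view)) < 1e-12

    def test_aggregate_bounded_by_view_extremes(self, tiny_fitted):
        res, seqs = tiny_fitted
        spec = AggregationSpec(
            angles=((0.0, 0.0), (15.0, 40.0), (25.0, 200.0), (15.0, 120.0))
        )
        for s in seqs[:6]:
            views = [_rot(s, tx, tz) for tx, tz in spec.angles]
            probs = [res.predict([v])[0].prob_fall for v in views]
            agg = aggregate_predict(res, s, spec)
            assert min(probs) - 1e-12 <= agg.prob_fall <= max(probs) + 1e-12

    def test_identical_views_idempotent(self, tiny_fitted):
        res, seqs = tiny_fitted
        spec = AggregationSpec(angles=((0.0, 0.0),) * 4)
        agg = aggregate_predict(res, seqs[1], spec)
        plain = res.predict([seqs[1]])[0]
        assert abs(agg.prob_fall - plain.prob_fall) < 1e-12

    def test_empty_angles_rejected(self):
        with pytest.raises(ValueError):
            AggregationSpec(angles=())


def _rot(seq, tx, tz):
    from virafall.augment import rotate_sequence

    return rotate_sequence(seq, tx, tz)


@pytest.fixture(scope="module")
def tiny_setup():
    train = generate_sequences(desk_config(n_sequences=24, seed=70))
    eval_set = generate_sequences(desk_config(n_sequences=16, seed=71))
    cfg = ModelConfig(num_streams=1, backbone_channels=(8,),
                      temporal_strides=(1,), temporal_kernel=3,
                      mask_fraction=0.0, seed=0)
    tc = TrainConfig(epochs=3, batch_size=8, lr=0.01, optimizer="adam", seed=0)
    return train, eval_set, cfg, tc


class TestAblation:
    def test_deterministic_given_recipe_and_seeds(self, tiny_setup):
        train, eval_set, cfg, tc = tiny_setup
        kwargs = dict(
            variants=[Recipe(name="base", sequences=train)],
            eval_sets={"plain": eval_set},
            model_config=cfg,
            train_config=tc,
            n_folds=2,
            seeds=(0,),
        )
        a = run_ablation(**kwargs)
        b = run_ablation(**kwargs)
        assert a.equals(b)
        assert set(a["metric"]) == {
            "accuracy", "precision", "sensitivity", "specificity", "f1"
        }

    def test_leakage_aborts(self, tiny_setup):
        train, _, cfg, tc = tiny_setup
        with pytest.raises(ValueError, match="leakage"):
            run_ablation(
                variants=[Recipe(name="base", sequences=train)],
                eval_sets={"bad": train[:4]},
                model_config=cfg,
                train_config=tc,
                seeds=(0,),
            )

    def test_recipe_materialization_counts(self, tiny_setup):
        train, _, _, _ = tiny_setup
        recipe = Recipe(name="spec", sequences=train, occluded=True, rotated=True)
        out = recipe.materialize(train[:3])
        # 3 plain + 3*2 occluded + 3*(6-1) rotated views
        assert len(out) == 3 + 6 + 15
        assert all(s.source_id in {t.source_id for t in train[:3]} for s in out)
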