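"""Consensus inference, confusion-matrix metrics, and the ablation driver.

Test-time aggregation classifies several rotated copies of one input and
averages the predicted fall probabilities — a consensus that exploits the
viewpoint invariance the rotation augmentation trains in.  Metrics follow
the standard binary conventions with falls as the positive class:

    accuracy    = (TP + TN) / (TP + TN + FP + FN)
    precision   = TP / (TP + FP)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)
    F1          = 2 * precision * sensitivity / (precision + sensitivity)

Undefined ratios (zero denominators) are reported as NaN, never silently 0.

The ablation driver trains model variants that differ only in their
training-data recipe (plain / +occlusions / +rotations / +second domain)
and scores each against a suite of evaluation sets, with folds split by
``source_id`` so augmented variants of one recording never straddle a
train/test boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import OcclusionSpec, RotationGrid, generate_views, occlude, rotate_sequence
from .core import SkeletonSequence
from .model import FallGCN, FallGCNResults, ModelConfig, Prediction, TrainConfig

__all__ = [
    "AggregationSpec",
    "ConfusionCounts",
    "MetricReport",
    "aggregate_predict",
    "compute_metrics",
    "Recipe",
    "run_ablation",
]


@dataclass(frozen=True)
class AggregationSpec:
    """Rotation angles and combiner for consensus inference.

    ``angles`` are (theta_x, theta_z) degree pairs; the default applies the
    identity view plus 15 and 25 degree tilts.  ``combiner`` is
    ``mean_prob`` (arithmetic mean of fall probabilities, the default),
    ``majority`` or ``logit_mean``.
    """

    angles: tuple = ((0.0, 0.0), (15.0, 0.0), (25.0, 0.0))
    combiner: str = "mean_prob"
    threshold: float = 0.5

    def __post_init__(self):
        if len(self.angles) < 1:
            raise ValueError("aggregation needs at least one angle pair")
        if self.combiner not in ("mean_prob", "majority", "logit_mean"):
            raise ValueError(f"unknown combiner {self.combiner!r}")


def aggregate_predict(
    results: FallGCNResults,
    seq: SkeletonSequence,
    spec: AggregationSpec = AggregationSpec(),
) -> Prediction:
    """Consensus prediction over rotated copies of one sequence."""
    views = [rotate_sequence(seq, tx, tz) for tx, tz in spec.angles]
    probs = np.array([results.predict([v])[0].prob_fall for v in views])
    if spec.combiner == "mean_prob":
        p = float(probs.mean())
    elif spec.combiner == "majority":
        votes = (probs >= spec.threshold).mean()
        p = float(votes)
    else:  # logit_mean
        eps = 1e-12
        logits = np.log(np.clip(probs, eps, 1 - eps)) - np.log(
            np.clip(1 - probs, eps, 1 - eps)
        )
        p = float(1.0 / (1.0 + math.exp(-logits.mean())))
    return Prediction(prob_fall=p, label_hat=int(p >= spec.threshold))


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN with falls as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(
            [p.label_hat if isinstance(p, Prediction) else p for p in y_pred],
            dtype=int,
        )
        if y_true.shape != y_pred.shape:
            raise ValueError("label/prediction length mismatch")
        return cls(
            tp=int(((y_true == 1) & (y_pred == 1)).sum()),
            tn=int(((y_true == 0) & (y_pred == 0)).sum()),
            fp=int(((y_true == 0) & (y_pred == 1)).sum()),
            fn=int(((y_true == 1) & (y_pred == 0)).sum()),
        )


@dataclass(frozen=True)
class MetricReport:
    """The five confusion-matrix metrics, stored as fractions in [0, 1].

    Undefined ratios are NaN.  ``as_percent`` renders the tabular form
    with two decimals.
    """

    accuracy: float
    precision: float
    sensitivity: float
    specificity: float
    f1: float

    def to_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "f1": self.f1,
        }

    def as_percent(self) -> dict[str, str]:
        return {
            k: ("undefined" if math.isnan(v) else f"{100.0 * v:.2f}%")
            for k, v in self.to_dict().items()
        }


def _ratio(num: int, den: int) -> float:
    return float("nan") if den == 0 else num / den


def compute_metrics(counts: ConfusionCounts) -> MetricReport:
    """Accuracy, precision, sensitivity, specificity and F1 from counts.

    F1 is computed from precision and sensitivity as their harmonic mean;
    it is NaN whenever either constituent is undefined or their sum is 0.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics over zero samples")
    accuracy = (counts.tp + counts.tn) / counts.total
    precision = _ratio(counts.tp, counts.tp + counts.fp)
    sensitivity = _ratio(counts.tp, counts.tp + counts.fn)
    specificity = _ratio(counts.tn, counts.tn + counts.fp)
    if math.isnan(precision) or math.isnan(sensitivity) or (precision + sensitivity) == 0:
        f1 = float("nan")
    else:
        f1 = 2.0 * precision * sensitivity / (precision + sensitivity)
    return MetricReport(
        accuracy=accuracy,
        precision=precision,
        sensitivity=sensitivity,
        specificity=specificity,
        f1=f1,
    )


@dataclass
class Recipe:
    """A training-data recipe for one ablation variant.

    ``sequences`` is the variant's training pool (normalized COCO17).
    ``occluded``/``rotated`` add skeleton-level occlusion variants and
    grid-rotated views of every training sequence (augmented copies keep
    their source's id).
    """

    name: str
    sequences: list[SkeletonSequence]
    occluded: bool = False
    rotated: bool = False
    occlusion: OcclusionSpec = field(default_factory=lambda: OcclusionSpec(n_variants=2))
    grid: RotationGrid = field(
        default_factory=lambda: RotationGrid(theta_x_set=(0.0, 25.0),
                                             theta_z_set=(0.0, 120.0, 240.0))
    )

    def materialize(self, subset: list[SkeletonSequence]) -> list[SkeletonSequence]:
        out = list(subset)
        if self.occluded:
            for s in subset:
                out.extend(occlude(s, self.occlusion))
        if self.rotated:
            for s in subset:
                out.extend(v for v in generate_views(s, self.grid)[1:])
        return out


def run_ablation(
    variants: list[Recipe],
    eval_sets: dict[str, list[SkeletonSequence]],
    model_config: ModelConfig = ModelConfig(),
    train_config: TrainConfig = TrainConfig(),
    n_folds: int = 2,
    seeds: tuple = (0, 1),
) -> pd.DataFrame:
    """Train every recipe over folds x seeds and score every eval set.

    Folds partition each recipe's pool by ``source_id``; each run trains on
    all but one fold.  Evaluation sets must be disjoint (by source id) from
    every training pool — an overlap aborts, since scoring a model on
    augmented variants of its own training recordings would leak.

    Returns a tidy frame: variant, eval_set, metric, mean, sd, n_runs.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    eval_source_ids = {
        name: {s.source_id for s in seqs} for name, seqs in eval_sets.items()
    }
    rows = []
    for recipe in variants:
        pool_ids = sorted({s.source_id for s in recipe.sequences})
        for name, ids in eval_source_ids.items():
            overlap = ids & set(pool_ids)
            if overlap:
                raise ValueError(
                    f"data leakage: eval set {name!r} shares source_ids with "
                    f"recipe {recipe.name!r} (e.g. {sorted(overlap)[:3]})"
                )
        metric_runs: dict[str, dict[str, list]] = {}
        for seed in seeds:
            rng = np.random.default_rng(seed)
            order = rng.permutation(len(pool_ids))
            fold_of = {pool_ids[i]: order[i] % n_folds for i in range(len(pool_ids))}
            for fold in range(n_folds):
                subset = [
                    s for s in recipe.sequences if fold_of[s.source_id] != fold
                ]
                train_seqs = recipe.materialize(subset)
                mc = ModelConfig(**{**_as_dict(model_config), "seed": int(seed)})
                tc = TrainConfig(**{**_as_dict(train_config), "seed": int(seed)})
                res = FallGCN(train_seqs, config=mc).fit(tc)
                for name, seqs in eval_sets.items():
                    counts = ConfusionCounts.from_predictions(
                        [s.label for s in seqs], res.predict(seqs)
                    )
                    rep = compute_metrics(counts)
                    store = metric_runs.setdefault(name, {})
                    for metric, value in rep.to_dict().items():
                        store.setdefault(metric, []).append(value)
        for name, store in metric_runs.items():
            for metric, values in store.items():
                arr = np.asarray(values, dtype=float)
                rows.append(
                    {
                        "variant": recipe.name,
                        "eval_set": name,
                        "metric": metric,
                        "mean": float(np.nanmean(arr)),
                        "sd": float(np.nanstd(arr, ddof=1)) if len(arr) > 1 else 0.0,
                        "n_runs": len(arr),
                    }
                )
    return pd.DataFrame(rows)


def _as_dict(cfg) -> dict:
    from dataclasses import asdict

    d = asdict(cfg)
    if "augment" in d and cfg.augment is not None:
        d["augment"] = cfg.augment  # keep the policy object, not its dict
    for key in ("backbone_channels", "temporal_strides"):
        if key in d:
            d[key] = tuple(d[key])
    return d
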