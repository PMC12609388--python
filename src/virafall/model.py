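"""Multi-stream spatio-temporal graph-convolutional fall classifier.

The classifier follows the richly-activated multi-stream ST-GCN design:
several parallel spatio-temporal graph-convolution streams process the
same 17-joint sequence, but each stream after the first receives the input
with the joints most activated by the preceding streams masked to zero
(class-activation ranking, aggregated over earlier streams; exactly
``ceil(mask_fraction * V)`` joints are removed).  Stream class scores are
summed before the softmax, so occluded inputs — whose informative joints
may be missing — still find support in streams trained to look elsewhere.
The final layer is a two-class head: fall (positive) versus daily
activity.

Organisation mirrors the estimator/results convention of statistical
modelling packages: :class:`FallGCN` holds data and configuration,
``fit`` runs the training loop and returns a :class:`FallGCNResults`
carrying the weights, the per-epoch history and prediction methods.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .augment import RotationGrid, rotation_matrix
from .core import Convention, SkeletonGraph, SkeletonSequence, build_graph

__all__ = [
    "ModelConfig",
    "TrainConfig",
    "AugmentPolicy",
    "Prediction",
    "FallGCN",
    "FallGCNResults",
]


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``backbone_channels``/``temporal_strides`` define the per-block widths
    and frame down-sampling of every stream; ``mask_fraction`` is the
    fraction of the 17 joints masked from each subsequent stream's input.
    """

    num_joints: int = 17
    in_channels: int = 3
    num_classes: int = 2
    num_streams: int = 3
    backbone_channels: tuple = (16, 32, 32)
    temporal_strides: tuple = (1, 2, 2)
    temporal_kernel: int = 5
    partition_strategy: str = "spatial"
    mask_fraction: float = 0.3
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.num_classes != 2:
            raise ValueError("this classifier is binary: num_classes must be 2")
        if self.num_streams < 1:
            raise ValueError("num_streams must be >= 1")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must lie in [0, 1)")
        if len(self.backbone_channels) != len(self.temporal_strides):
            raise ValueError("backbone_channels and temporal_strides differ in length")

    @property
    def masked_joint_count(self) -> int:
        return math.ceil(self.mask_fraction * self.num_joints)


@dataclass(frozen=True)
class AugmentPolicy:
    """In-dataloader augmentation applied lazily per batch.

    Each sample independently receives a random grid rotation (with
    probability ``rotate_prob``) and a random occlusion (with probability
    ``occlude_prob``), drawn from a per-epoch seed stream.
    """

    rotate_prob: float = 0.0
    grid: RotationGrid = field(default_factory=RotationGrid)
    occlude_prob: float = 0.0
    blackout_frames: tuple = (5, 30)
    joint_drop_max: int = 5


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings for :meth:`FallGCN.fit`."""

    batch_size: int = 64
    epochs: int = 30
    lr: float = 0.01
    optimizer: str = "sgd"  # or "adam"
    momentum: float = 0.9
    lr_step: int = 10
    lr_gamma: float = 0.5
    weight_decay: float = 0.0
    class_weighting: str = "none"  # or "balanced"
    mixed_precision: bool = False
    augment: AugmentPolicy | None = None
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("sgd", "adam"):
            raise ValueError("optimizer must be 'sgd' or 'adam'")
        if self.class_weighting not in ("none", "balanced"):
            raise ValueError("class_weighting must be 'none' or 'balanced'")


@dataclass
class Prediction:
    """Per-sequence classifier output."""

    prob_fall: float
    label_hat: int
    per_stream_logits: np.ndarray | None = None


class _Stream:
    """One ST-GCN stream: input BN, conv blocks, pooling, class head."""

    def __init__(self, cfg: ModelConfig, graph: SkeletonGraph, rng):
        a = graph.adjacency_stack
        self.layers: list[nn.Layer] = [nn.BatchNorm(cfg.in_channels)]
        c_prev = cfg.in_channels
        for c, s in zip(cfg.backbone_channels, cfg.temporal_strides):
            self.layers += [
                nn.GraphConv(c_prev, c, a, rng),
                nn.BatchNorm(c),
                nn.ReLU(),
                nn.TemporalConv(c, c, cfg.temporal_kernel, s, rng),
                nn.BatchNorm(c),
                nn.ReLU(),
            ]
            if cfg.dropout > 0:
                self.layers.append(nn.Dropout(cfg.dropout, rng))
            c_prev = c
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(c_prev, cfg.num_classes, rng)

    def params(self) -> list[nn.Param]:
        out = []
        for layer in self.layers + [self.fc]:
            out += layer.params()
        return out

    def forward(self, x, training):
        h = x
        for layer in self.layers:
            h = layer.forward(h, training)
        self._feat = h  # (N, C, T', V) — basis for joint activation maps
        pooled = self.pool.forward(h, training)
        return self.fc.forward(pooled, training), h

    def backward(self, dlogits):
        g = self.fc.backward(dlogits)
        g = self.pool.backward(g)
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def joint_importance(self, feat, logits) -> np.ndarray:
        """Per-sample joint activation: class-activation map of the
        predicted class, rectified, averaged over frames, normalised to
        sum 1 per sample."""
        cls = np.argmax(logits, axis=1)
        w = self.fc.w.value[cls]  # (N, C)
        cam = np.maximum(np.einsum("nc,nctv->ntv", w, feat), 0.0).mean(axis=1)
        total = cam.sum(axis=1, keepdims=True)
        return cam / np.maximum(total, 1e-12)


class _Network:
    """The full multi-stream network with summed class scores."""

    def __init__(self, cfg: ModelConfig, graph: SkeletonGraph):
        if graph.num_joints != cfg.num_joints:
            raise ValueError(
                f"graph has {graph.num_joints} joints but config expects "
                f"{cfg.num_joints}"
            )
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.graph = graph
        self.streams = [_Stream(cfg, graph, rng) for _ in range(cfg.num_streams)]

    def params(self) -> list[nn.Param]:
        out = []
        for s in self.streams:
            out += s.params()
        return out

    @property
    def param_count(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x, training: bool):
        """Returns (summed logits, per-stream logits (S, N, 2))."""
        n, _, _, v = x.shape
        k = self.cfg.masked_joint_count
        agg_imp = np.zeros((n, v))
        per_stream = []
        total = None
        for s, stream in enumerate(self.streams):
            if s == 0 or k == 0:
                xs = x
            else:
                mask = np.ones((n, v), dtype=x.dtype)
                top = np.argsort(-agg_imp, axis=1)[:, :k]
                mask[np.arange(n)[:, None], top] = 0.0
                xs = x * mask[:, None, None, :]
            logits, feat = stream.forward(xs, training)
            if len(self.streams) > 1 and k > 0:
                agg_imp += stream.joint_importance(feat, logits)
            per_stream.append(logits)
            total = logits if total is None else total + logits
        return total, np.stack(per_stream)

    def backward(self, dlogits):
        # summed scores: every stream receives the same upstream gradient;
        # the activation-based masks are treated as constants.
        for stream in self.streams:
            stream.backward(dlogits)

    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for si, s in enumerate(self.streams):
            for pi, p in enumerate(s.params()):
                out[f"s{si}_p{pi}_{p.name}"] = p.value
            for li, layer in enumerate(s.layers):
                if isinstance(layer, nn.BatchNorm):
                    out[f"s{si}_l{li}_rmean"] = layer.running_mean
                    out[f"s{si}_l{li}_rvar"] = layer.running_var
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for si, s in enumerate(self.streams):
            for pi, p in enumerate(s.params()):
                p.value = np.asarray(state[f"s{si}_p{pi}_{p.name}"], dtype=np.float32)
            for li, layer in enumerate(s.layers):
                if isinstance(layer, nn.BatchNorm):
                    layer.running_mean = np.asarray(
                        state[f"s{si}_l{li}_rmean"], dtype=np.float32
                    )
                    layer.running_var = np.asarray(
                        state[f"s{si}_l{li}_rvar"], dtype=np.float32
                    )


def sequences_to_array(seqs: list[SkeletonSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack sequences into (N, 3, T, V) float32 plus labels (N,)."""
    if not seqs:
        raise ValueError("empty sequence list")
    t0, v0 = seqs[0].coords.shape[:2]
    for s in seqs:
        if s.convention is not Convention.COCO17:
            raise ValueError(
                f"classifier input must be COCO17; got {s.convention.value} "
                f"(source {s.source_id!r})"
            )
        if s.coords.shape[:2] != (t0, v0):
            raise ValueError("all sequences must share (T, V); normalize first")
    x = np.stack([s.coords.transpose(2, 0, 1) for s in seqs]).astype(np.float32)
    y = np.array([s.label for s in seqs], dtype=np.int64)
    return x, y


def _augment_batch(xb: np.ndarray, policy: AugmentPolicy, rng) -> np.ndarray:
    """Random per-sample rotation / occlusion on a (B, 3, T, V) batch."""
    xb = xb.copy()
    b, _, t, v = xb.shape
    if policy.rotate_prob > 0:
        pairs = policy.grid.pairs()
        for i in range(b):
            if rng.random() < policy.rotate_prob:
                tx, tz = pairs[int(rng.integers(len(pairs)))]
                r = rotation_matrix(tx, tz).astype(np.float32)
                xb[i] = np.einsum("ab,btv->atv", r, xb[i])
    if policy.occlude_prob > 0:
        lo, hi = policy.blackout_frames
        for i in range(b):
            if rng.random() < policy.occlude_prob:
                if rng.random() < 0.5:  # temporal blackout
                    w = min(int(rng.integers(lo, hi + 1)), max(1, int(0.9 * t)))
                    start = int(rng.integers(0, max(1, t - w)))
                    xb[i, :, start : start + w, :] = 0.0
                else:  # joint dropout over a window
                    nj = int(rng.integers(1, policy.joint_drop_max + 1))
                    joints = rng.choice(v, size=nj, replace=False)
                    w = min(int(rng.integers(lo, hi + 1)), t)
                    start = int(rng.integers(0, max(1, t - w)))
                    window = xb[i, :, start : start + w]  # view into the batch
                    window[..., joints] = 0.0
    return xb


class FallGCN:
    """Fall/no-fall classifier over normalized COCO-17 skeleton sequences.

    Parameters
    ----------
    sequences : list of SkeletonSequence, optional
        Training data; all must be COCO17 with a common (T, V).
    config : ModelConfig
    graph : SkeletonGraph, optional
        Defaults to the COCO-17 bone graph under the configured partition
        strategy.
    """

    def __init__(self, sequences=None, config: ModelConfig = ModelConfig(),
                 graph: SkeletonGraph | None = None):
        self.config = config
        self.graph = graph or build_graph("COCO17", config.partition_strategy)
        if sequences is not None:
            self.x, self.y = sequences_to_array(sequences)
        else:
            self.x = self.y = None

    @property
    def param_count(self) -> int:
        """Trainable parameter count — a pure function of the config."""
        return _Network(self.config, self.graph).param_count

    def fit(self, train_config: TrainConfig = TrainConfig()) -> "FallGCNResults":
        """Train with mini-batch gradient descent; returns fitted results.

        Raises
        ------
        RuntimeError
            If the loss becomes non-finite (with a diagnostic).
        ValueError
            If no training data was supplied.
        """
        if self.x is None:
            raise ValueError("no training data: construct FallGCN with sequences")
        cfg, tc = self.config, train_config
        x, y = self.x, self.y
        classes, counts = np.unique(y, return_counts=True)
        weights = None
        if len(classes) < 2 and tc.class_weighting == "none":
            warnings.warn(
                "training data contains a single class; proceeding, but the "
                "classifier cannot learn a decision boundary",
                stacklevel=2,
            )
        if tc.class_weighting == "balanced":
            weights = np.zeros(2)
            for c, n_c in zip(classes, counts):
                weights[c] = len(y) / (2.0 * n_c)
            weights[weights == 0] = 1.0

        net = _Network(cfg, self.graph)
        params = net.params()
        if tc.optimizer == "sgd":
            opt = nn.SGD(params, tc.lr, tc.momentum, tc.weight_decay)
        else:
            opt = nn.Adam(params, tc.lr)

        history = []
        n = x.shape[0]
        for epoch in range(tc.epochs):
            lr = tc.lr * (tc.lr_gamma ** (epoch // max(1, tc.lr_step)))
            opt.lr = lr
            rng = np.random.default_rng((tc.seed * 100003 + epoch) % (2**31))
            order = rng.permutation(n)
            tot_loss = 0.0
            tot_correct = 0
            for start in range(0, n, tc.batch_size):
                idx = order[start : start + tc.batch_size]
                xb, yb = x[idx], y[idx]
                if tc.augment is not None:
                    xb = _augment_batch(xb, tc.augment, rng)
                opt.zero_grad()
                logits, _ = net.forward(xb, training=True)
                loss, dlogits = nn.cross_entropy_with_grad(logits, yb, weights)
                if not np.isfinite(loss):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, batch offset {start}: "
                        f"loss={loss}; lower the learning rate or check inputs"
                    )
                net.backward(dlogits)
                opt.step()
                tot_loss += loss * len(idx)
                tot_correct += int((np.argmax(logits, axis=1) == yb).sum())
            history.append(
                {
                    "epoch": epoch,
                    "lr": lr,
                    "loss": tot_loss / n,
                    "accuracy": tot_correct / n,
                }
            )
        return FallGCNResults(
            model=self,
            network=net,
            history=pd.DataFrame(history),
            train_config=tc,
        )


class FallGCNResults:
    """A trained classifier: weights, history and prediction methods."""

    def __init__(self, model: FallGCN | None, network: _Network,
                 history: pd.DataFrame, train_config: TrainConfig | None):
        self.model = model
        self.network = network
        self.history = history
        self.train_config = train_config

    @property
    def config(self) -> ModelConfig:
        return self.network.cfg

    @property
    def param_count(self) -> int:
        return self.network.param_count

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Class probabilities for an (N, 3, T, V) array, eval mode."""
        probs = []
        for start in range(0, x.shape[0], batch_size):
            logits, _ = self.network.forward(
                x[start : start + batch_size].astype(np.float32), training=False
            )
            probs.append(nn.softmax(logits.astype(np.float64)))
        return np.concatenate(probs)

    def predict(self, seqs, threshold: float = 0.5,
                return_stream_logits: bool = False) -> list[Prediction]:
        """Predictions for COCO17 sequences (or a pre-stacked array)."""
        if isinstance(seqs, np.ndarray):
            x = seqs.astype(np.float32)
        else:
            x, _ = sequences_to_array(seqs)
        out = []
        for start in range(0, x.shape[0], 256):
            logits, stream_logits = self.network.forward(
                x[start : start + 256], training=False
            )
            p = nn.softmax(logits.astype(np.float64))[:, 1]
            for i, prob in enumerate(p):
                out.append(
                    Prediction(
                        prob_fall=float(prob),
                        label_hat=int(prob >= threshold),
                        per_stream_logits=(
                            stream_logits[:, i].copy()
                            if return_stream_logits
                            else None
                        ),
                    )
                )
        return out

    def score(self, seqs, threshold: float = 0.5) -> float:
        """Plain accuracy against the sequences' own labels."""
        if isinstance(seqs, np.ndarray):
            raise ValueError("score needs labelled sequences")
        x, y = sequences_to_array(seqs)
        p = self.predict_proba(x)[:, 1]
        return float(((p >= threshold).astype(int) == y).mean())

    def summary(self) -> str:
        cfg = self.config
        last = self.history.iloc[-1] if len(self.history) else None
        lines = [
            "Multi-stream ST-GCN fall classifier",
            f"  streams: {cfg.num_streams}   blocks: {list(cfg.backbone_channels)}"
            f"   temporal kernel: {cfg.temporal_kernel}",
            f"  joints: {cfg.num_joints} ({cfg.partition_strategy} partition)"
            f"   masked per stream: {cfg.masked_joint_count}",
            f"  trainable parameters: {self.param_count:,}",
        ]
        if last is not None:
            lines.append(
                f"  final epoch {int(last['epoch'])}: "
                f"loss {last['loss']:.4f}, accuracy {last['accuracy']:.4f}"
            )
        return "\n".join(lines)

    def plot_history(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.history["epoch"], self.history["loss"], label="loss")
        ax2 = ax.twinx()
        ax2.plot(self.history["epoch"], self.history["accuracy"], "C1",
                 label="accuracy")
        ax.set_xlabel("epoch")
        ax.set_ylabel("loss")
        ax2.set_ylabel("train accuracy")
        return ax

    def save(self, path) -> None:
        """Checkpoint: weights + config sidecar in one .npz file."""
        state = self.network.state_arrays()
        meta = {
            "model_config": asdict(self.config),
            "train_config": asdict(self.train_config) if self.train_config else None,
        }
        if meta["train_config"] is not None:
            meta["train_config"]["augment"] = None  # policies are not serialised
        np.savez(
            path,
            __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
            **state,
        )
        self.history.to_csv(Path(str(path)).with_suffix(".history.csv"), index=False)

    @classmethod
    def load(cls, path) -> "FallGCNResults":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            state = {k: data[k] for k in data.files if k != "__meta__"}
        mc = meta["model_config"]
        mc["backbone_channels"] = tuple(mc["backbone_channels"])
        mc["temporal_strides"] = tuple(mc["temporal_strides"])
        cfg = ModelConfig(**mc)
        net = _Network(cfg, build_graph("COCO17", cfg.partition_strategy))
        net.load_state_arrays(state)
        hist_path = Path(str(path)).with_suffix(".history.csv")
        history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
        return cls(model=None, network=net, history=history, train_config=None)
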