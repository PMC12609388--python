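"""Skeleton sequence data model, joint conventions and graph construction.

A skeleton sequence is a ``(T, V, 3)`` array of per-frame 3D joint
coordinates ``p[t, v]`` together with a binary fall label, a joint-convention
tag and a per-frame validity mask.  Two conventions are supported:

* ``COCO17`` — the 17-keypoint body layout emitted by modern pose-estimation
  toolkits (nose, eyes, ears, shoulders, elbows, wrists, hips, knees, ankles);
* ``KINECT25`` — the 25-joint skeleton of the Kinect v2 sensor.

Coordinates live in a subject-centred world frame: the origin sits on the
floor beneath the subject, ``z`` points up (the yaw axis), ``x`` is the tilt
axis and ``y`` completes a right-handed frame.  Occluded joints are encoded
as exact zeros, never NaN; dead frames additionally clear ``valid_mask``.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "Convention",
    "PartitionStrategy",
    "SkeletonSequence",
    "SkeletonGraph",
    "DatasetManifest",
    "COCO17_JOINT_NAMES",
    "KINECT25_JOINT_NAMES",
    "COCO17_EDGES",
    "KINECT25_EDGES",
    "normalize_sequence",
    "build_graph",
    "recenter_mid_hip",
]

DEFAULT_TARGET_LEN = 300


class Convention(str, enum.Enum):
    """Joint-layout convention of a skeleton sequence."""

    COCO17 = "COCO17"
    KINECT25 = "KINECT25"

    @property
    def num_joints(self) -> int:
        return 17 if self is Convention.COCO17 else 25


class PartitionStrategy(str, enum.Enum):
    """Adjacency partitioning scheme for spatial graph convolution.

    ``uniform``  — one operator: row-normalized ``A + I``.
    ``distance`` — two operators: self-connections and 1-hop neighbours.
    ``spatial``  — three operators: root, centripetal (closer to the body
    centre) and centrifugal (farther from it) neighbour groups.
    """

    UNIFORM = "uniform"
    DISTANCE = "distance"
    SPATIAL = "spatial"


COCO17_JOINT_NAMES = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
)

# Standard COCO keypoint skeleton (head chain, arms, torso box, legs).
COCO17_EDGES = frozenset(
    frozenset(e)
    for e in [
        (0, 1), (0, 2), (1, 2), (1, 3), (2, 4), (3, 5), (4, 6),
        (5, 6), (5, 7), (7, 9), (6, 8), (8, 10),
        (5, 11), (6, 12), (11, 12),
        (11, 13), (13, 15), (12, 14), (14, 16),
    ]
)

KINECT25_JOINT_NAMES = (
    "spine_base", "spine_mid", "neck", "head",
    "left_shoulder", "left_elbow", "left_wrist", "left_hand",
    "right_shoulder", "right_elbow", "right_wrist", "right_hand",
    "left_hip", "left_knee", "left_ankle", "left_foot",
    "right_hip", "right_knee", "right_ankle", "right_foot",
    "spine_shoulder",
    "left_hand_tip", "left_thumb", "right_hand_tip", "right_thumb",
)

# Kinect v2 bone list (as used by the NTU RGB+D skeleton files).
KINECT25_EDGES = frozenset(
    frozenset(e)
    for e in [
        (0, 1), (1, 20), (20, 2), (2, 3),
        (20, 4), (4, 5), (5, 6), (6, 7), (7, 21), (7, 22),
        (20, 8), (8, 9), (9, 10), (10, 11), (11, 23), (11, 24),
        (0, 12), (12, 13), (13, 14), (14, 15),
        (0, 16), (16, 17), (17, 18), (18, 19),
    ]
)

_EDGES = {Convention.COCO17: COCO17_EDGES, Convention.KINECT25: KINECT25_EDGES}
# Reference joint for the spatial partition's notion of "body centre".
_CENTER_JOINT = {Convention.COCO17: 0, Convention.KINECT25: 20}


@dataclass
class SkeletonSequence:
    """A labelled 3D joint-coordinate sequence.

    Parameters
    ----------
    coords : ndarray, shape (T, V, 3)
        Per-frame joint positions.  Occluded joints are exact zeros.
    label : int
        1 = fall (positive class), 0 = no fall.
    convention : Convention
        Joint layout; fixes ``V``.
    valid_mask : ndarray of bool, shape (T,), optional
        True where the frame was observed; False marks padding or blackout.
    source_id : str
        Opaque identifier of the originating recording.  Augmented variants
        keep their source's id so train/test splits never straddle them.
    """

    coords: np.ndarray
    label: int
    convention: Convention
    valid_mask: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError(
                f"coords must have shape (T, V, 3); got {self.coords.shape}"
            )
        self.convention = Convention(self.convention)
        v_expected = self.convention.num_joints
        if self.coords.shape[1] != v_expected:
            raise ValueError(
                f"{self.convention.value} requires V={v_expected} joints; "
                f"got {self.coords.shape[1]}"
            )
        if not np.isfinite(self.coords).all():
            raise ValueError(
                "coords contain NaN/Inf; encode occlusions as zeros with "
                "valid_mask=False instead"
            )
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.coords.shape[0], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != (self.coords.shape[0],):
                raise ValueError("valid_mask must have shape (T,)")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1; got {self.label}")

    @property
    def num_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def num_joints(self) -> int:
        return self.coords.shape[1]

    def copy(self) -> "SkeletonSequence":
        return SkeletonSequence(
            coords=self.coords.copy(),
            label=self.label,
            convention=self.convention,
            valid_mask=self.valid_mask.copy(),
            source_id=self.source_id,
        )


@dataclass(frozen=True)
class SkeletonGraph:
    """Joint adjacency and its partitioned, row-normalized operator stack.

    ``adjacency_stack`` has shape ``(K, V, V)`` with one operator per
    partition group; rows of non-isolated vertices sum to 1.
    """

    num_joints: int
    edges: frozenset
    partition_strategy: PartitionStrategy
    adjacency_stack: np.ndarray = field(repr=False)

    def dense_adjacency(self) -> np.ndarray:
        """Binary symmetric adjacency without self-loops."""
        a = np.zeros((self.num_joints, self.num_joints))
        for e in self.edges:
            i, j = sorted(e)
            a[i, j] = a[j, i] = 1.0
        return a


def _row_normalize(a: np.ndarray) -> np.ndarray:
    deg = a.sum(axis=1, keepdims=True)
    out = np.zeros_like(a)
    nz = deg[:, 0] > 0
    out[nz] = a[nz] / deg[nz]
    return out


def _hop_distances(adj: np.ndarray, center: int) -> np.ndarray:
    """BFS hop distance of every joint from ``center``."""
    v = adj.shape[0]
    dist = np.full(v, -1, dtype=int)
    dist[center] = 0
    frontier = [center]
    d = 0
    while frontier:
        d += 1
        nxt = []
        for i in frontier:
            for j in np.nonzero(adj[i])[0]:
                if dist[j] < 0:
                    dist[j] = d
                    nxt.append(int(j))
        frontier = nxt
    return dist


def build_graph(
    convention: Convention | str,
    partition_strategy: PartitionStrategy | str = PartitionStrategy.SPATIAL,
) -> SkeletonGraph:
    """Construct the bone graph of a joint convention with a partitioned,
    row-normalized adjacency stack for spatial graph convolution.

    Raises
    ------
    ValueError
        If the convention or partition strategy is unknown.
    """
    convention = Convention(convention)
    strategy = PartitionStrategy(partition_strategy)
    edges = _EDGES[convention]
    v = convention.num_joints
    adj = np.zeros((v, v))
    for e in edges:
        i, j = sorted(e)
        adj[i, j] = adj[j, i] = 1.0

    eye = np.eye(v)
    if strategy is PartitionStrategy.UNIFORM:
        stack = _row_normalize(adj + eye)[None]
    elif strategy is PartitionStrategy.DISTANCE:
        stack = np.stack([eye, _row_normalize(adj)])
    else:  # spatial
        dist = _hop_distances(adj, _CENTER_JOINT[convention])
        root = eye.copy()
        closer = np.zeros_like(adj)
        farther = np.zeros_like(adj)
        for i in range(v):
            for j in np.nonzero(adj[i])[0]:
                if dist[j] < dist[i]:
                    closer[i, j] = 1.0
                elif dist[j] > dist[i]:
                    farther[i, j] = 1.0
                else:
                    root[i, j] = 1.0
        stack = np.stack(
            [_row_normalize(root), _row_normalize(closer), _row_normalize(farther)]
        )
    return SkeletonGraph(
        num_joints=v,
        edges=edges,
        partition_strategy=strategy,
        adjacency_stack=stack,
    )


def normalize_sequence(
    seq: SkeletonSequence, target_len: int = DEFAULT_TARGET_LEN
) -> SkeletonSequence:
    """Fix a sequence to exactly ``target_len`` frames.

    Longer sequences are uniformly subsampled: output frame ``i`` (1-based)
    takes input frame ``round(i * T / target_len)``.  Shorter sequences are
    tail-padded with zero coordinates and ``valid_mask=False``.  Coordinates
    of retained frames are unchanged, so the operation is idempotent.

    Raises
    ------
    ValueError
        On an empty sequence, an all-invalid mask, or ``target_len < 1``.
    """
    if target_len < 1:
        raise ValueError(f"target_len must be >= 1; got {target_len}")
    t = seq.num_frames
    if t == 0:
        raise ValueError("cannot normalize an empty sequence (0 frames)")
    if not seq.valid_mask.any():
        raise ValueError("cannot normalize a sequence with no valid frames")

    if t == target_len:
        return seq.copy()
    if t > target_len:
        idx = np.round(np.arange(1, target_len + 1) * t / target_len).astype(int) - 1
        idx = np.clip(idx, 0, t - 1)
        coords = seq.coords[idx].copy()
        mask = seq.valid_mask[idx].copy()
    else:
        coords = np.zeros((target_len, seq.num_joints, 3))
        coords[:t] = seq.coords
        mask = np.zeros(target_len, dtype=bool)
        mask[:t] = seq.valid_mask
    return SkeletonSequence(
        coords=coords,
        label=seq.label,
        convention=seq.convention,
        valid_mask=mask,
        source_id=seq.source_id,
    )


def recenter_mid_hip(seq: SkeletonSequence) -> SkeletonSequence:
    """Optionally re-express coordinates root-relative by subtracting the
    per-frame mid-hip point.  Invalid (all-zero) frames are left untouched.
    """
    if seq.convention is Convention.COCO17:
        hips = (11, 12)
    else:
        hips = (12, 16)
    out = seq.copy()
    mid = out.coords[:, hips, :].mean(axis=1, keepdims=True)
    out.coords[out.valid_mask] -= mid[out.valid_mask]
    return out


@dataclass
class DatasetManifest:
    """Tabular index of sequences with labels, conventions and split tags.

    Split assignment is by ``source_id`` so a sequence and its augmented
    variants never straddle train and test.
    """

    entries: pd.DataFrame  # columns: path,label,convention,split,source_id

    REQUIRED = ("path", "label", "convention", "split")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.entries.columns]
        if missing:
            raise ValueError(f"manifest missing columns: {missing}")
        if "source_id" not in self.entries.columns:
            self.entries = self.entries.assign(
                source_id=self.entries["path"].astype(str)
            )
        bad_split = set(self.entries["split"]) - {"train", "test"}
        if bad_split:
            raise ValueError(f"unknown split values: {sorted(bad_split)}")
        by_src = self.entries.groupby("source_id")["split"].nunique()
        leaked = by_src[by_src > 1]
        if len(leaked):
            raise ValueError(
                "source_ids appear in more than one split: "
                f"{list(leaked.index[:5])}"
            )

    @property
    def class_counts(self) -> dict[int, int]:
        return self.entries["label"].value_counts().to_dict()

    @classmethod
    def read_csv(cls, path) -> "DatasetManifest":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.entries.to_csv(path, index=False)


def split_by_source(
    source_ids: list[str], test_fraction: float, seed: int
) -> dict[str, str]:
    """Deterministic disjoint train/test assignment per source id."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    uniq = sorted(set(source_ids))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(uniq))
    n_test = max(1, int(math.floor(test_fraction * len(uniq))))
    test = {uniq[i] for i in perm[:n_test]}
    return {s: ("test" if s in test else "train") for s in uniq}
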