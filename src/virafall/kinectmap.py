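"""Per-joint affine alignment of Kinect-25 skeletons to the COCO-17 layout.

Each of the 17 target joints ``j`` is predicted from one corresponding
Kinect source joint through its own affine map,

    P_target,j = P_kinect,corr(j) @ A_j.T + b_j ,

where ``A_j`` is a full 3x3 matrix (rotation, scale and shear) and ``b_j``
a translation.  The 17 pairs ``(A_j, b_j)`` are estimated jointly-per-joint
by ordinary least squares in homogeneous coordinates on a small set of
randomly sampled paired frames (30 by default).  Fit quality is reported as
the per-joint mean squared Euclidean error (the MPJPE convention squared)
and its average over joints, plus the mean Euclidean distance per joint
before and after alignment.

The default joint correspondence is anatomically motivated configuration
(facial COCO keypoints all draw on the Kinect head joint and are separated
by their per-joint translations); callers may supply their own table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .core import COCO17_JOINT_NAMES, Convention, SkeletonSequence

__all__ = [
    "DEFAULT_CORRESPONDENCE",
    "AffineJointMap",
    "MapFitReport",
    "AffineAligner",
    "AffineMapResults",
    "fit_affine_map",
    "apply_affine_map",
    "evaluate_alignment",
]

# COCO target joint index -> Kinect-25 source joint index.
DEFAULT_CORRESPONDENCE: tuple = (
    3, 3, 3, 3, 3,      # nose, eyes, ears          <- head
    4, 8,               # shoulders                 <- shoulders
    5, 9,               # elbows                    <- elbows
    6, 10,              # wrists                    <- wrists
    12, 16,             # hips                      <- hips
    13, 17,             # knees                     <- knees
    14, 18,             # ankles                    <- ankles
)


@dataclass
class AffineJointMap:
    """17 per-joint affine maps plus the source-joint correspondence."""

    correspondence: tuple
    A: np.ndarray  # (17, 3, 3)
    b: np.ndarray  # (17, 3)
    n_train: int = 0

    def __post_init__(self) -> None:
        self.correspondence = tuple(int(i) for i in self.correspondence)
        self.A = np.asarray(self.A, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if len(self.correspondence) != 17:
            raise ValueError("correspondence must cover all 17 target joints")
        if self.A.shape != (17, 3, 3) or self.b.shape != (17, 3):
            raise ValueError(
                f"expected A (17,3,3) and b (17,3); got {self.A.shape}, {self.b.shape}"
            )
        if not (np.isfinite(self.A).all() and np.isfinite(self.b).all()):
            raise ValueError("affine parameters must be finite")

    @classmethod
    def identity(
        cls, correspondence: tuple = DEFAULT_CORRESPONDENCE
    ) -> "AffineJointMap":
        return cls(
            correspondence=correspondence,
            A=np.broadcast_to(np.eye(3), (17, 3, 3)).copy(),
            b=np.zeros((17, 3)),
        )

    def transform_frames(self, kinect_frames: np.ndarray) -> np.ndarray:
        """Map ``(N, 25, 3)`` Kinect frames to ``(N, 17, 3)`` COCO frames."""
        kinect_frames = np.asarray(kinect_frames, dtype=np.float64)
        src = kinect_frames[:, self.correspondence, :]  # (N, 17, 3)
        return np.einsum("jab,njb->nja", self.A, src) + self.b[None]

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "correspondence": list(self.correspondence),
                    "A": self.A.tolist(),
                    "b": self.b.tolist(),
                    "n_train": int(self.n_train),
                }
            )
        )

    @classmethod
    def from_json(cls, path) -> "AffineJointMap":
        doc = json.loads(Path(path).read_text())
        return cls(
            correspondence=tuple(doc["correspondence"]),
            A=np.asarray(doc["A"]),
            b=np.asarray(doc["b"]),
            n_train=int(doc.get("n_train", 0)),
        )


@dataclass
class MapFitReport:
    """Per-joint and overall alignment errors.

    ``mse_per_joint`` is the mean squared Euclidean distance per joint
    (squared coordinate units); ``overall_mse`` its mean over the 17 joints.
    The Euclidean columns are mean (not squared) distances, before and after
    applying the fitted maps.
    """

    mse_per_joint: np.ndarray
    overall_mse: float
    euclidean_error_per_joint_before: np.ndarray
    euclidean_error_per_joint_after: np.ndarray

    def __post_init__(self) -> None:
        for name in (
            "mse_per_joint",
            "euclidean_error_per_joint_before",
            "euclidean_error_per_joint_after",
        ):
            arr = np.asarray(getattr(self, name), dtype=np.float64)
            if arr.shape != (17,):
                raise ValueError(f"{name} must have 17 entries")
            if (arr < 0).any():
                raise ValueError(f"{name} contains negative errors")
            setattr(self, name, arr)
        expected = float(self.mse_per_joint.mean())
        if abs(self.overall_mse - expected) > 1e-12:
            raise ValueError("overall_mse must equal mean(mse_per_joint)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "joint": COCO17_JOINT_NAMES,
                "mse": self.mse_per_joint,
                "euclidean_before": self.euclidean_error_per_joint_before,
                "euclidean_after": self.euclidean_error_per_joint_after,
            }
        )


def _as_paired_arrays(paired_frames) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of (kinect_frame, coco_frame) pairs or a 2-tuple of
    stacked arrays; return ``(N,25,3)`` and ``(N,17,3)`` float arrays."""
    if isinstance(paired_frames, tuple) and len(paired_frames) == 2:
        kin, coco = paired_frames
    else:
        kin = [k for k, _ in paired_frames]
        coco = [c for _, c in paired_frames]
    kin = np.asarray(kin, dtype=np.float64)
    coco = np.asarray(coco, dtype=np.float64)
    if kin.ndim != 3 or kin.shape[1:] != (25, 3):
        raise ValueError(f"kinect frames must have shape (N, 25, 3); got {kin.shape}")
    if coco.ndim != 3 or coco.shape[1:] != (17, 3):
        raise ValueError(f"coco frames must have shape (N, 17, 3); got {coco.shape}")
    if kin.shape[0] != coco.shape[0]:
        raise ValueError("paired frame counts differ")
    return kin, coco


class AffineAligner:
    """Least-squares model for the per-joint Kinect->COCO affine alignment.

    Parameters
    ----------
    kinect_frames : array-like, (N, 25, 3)
    coco_frames : array-like, (N, 17, 3)
        Paired observations of the same instants in both conventions.
    correspondence : tuple of 17 ints, optional
        Source Kinect joint per COCO target joint.
    """

    def __init__(self, kinect_frames, coco_frames, correspondence=None):
        self.kinect, self.coco = _as_paired_arrays((kinect_frames, coco_frames))
        self.correspondence = tuple(
            DEFAULT_CORRESPONDENCE if correspondence is None else correspondence
        )
        if len(self.correspondence) != 17:
            raise ValueError("correspondence must cover all 17 target joints")

    @property
    def nobs(self) -> int:
        return self.kinect.shape[0]

    def fit(self, n_train: int = 30, seed: int = 0) -> "AffineMapResults":
        """Fit the 17 affine maps on ``n_train`` uniformly sampled frames.

        Raises
        ------
        ValueError
            With fewer than 4 available frames, or when a joint's source
            points are affinely degenerate (coplanar), naming the joint.
        """
        n = self.nobs
        if n < 4:
            raise ValueError(
                f"need at least 4 paired frames to determine a 3D affine map; got {n}"
            )
        n_train = min(int(n_train), n)
        if n_train < 4:
            raise ValueError("n_train must be at least 4")
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(n, size=n_train, replace=False))
        kin, coco = self.kinect[idx], self.coco[idx]

        a = np.empty((17, 3, 3))
        b = np.empty((17, 3))
        mse = np.empty(17)
        for j, src in enumerate(self.correspondence):
            x = kin[:, src, :]
            y = coco[:, j, :]
            design = np.hstack([x, np.ones((n_train, 1))])
            if np.linalg.matrix_rank(design, tol=1e-10) < 4:
                raise ValueError(
                    f"degenerate source geometry for target joint {j} "
                    f"({COCO17_JOINT_NAMES[j]}): points are affinely "
                    "dependent; sample more varied frames"
                )
            w, *_ = np.linalg.lstsq(design, y, rcond=None)
            a[j] = w[:3].T
            b[j] = w[3]
            resid = y - (x @ a[j].T + b[j])
            mse[j] = float((resid**2).sum(axis=1).mean())

        amap = AffineJointMap(
            correspondence=self.correspondence, A=a, b=b, n_train=n_train
        )
        transformed = amap.transform_frames(kin)
        before = np.linalg.norm(
            coco - kin[:, self.correspondence, :], axis=2
        ).mean(axis=0)
        after = np.linalg.norm(coco - transformed, axis=2).mean(axis=0)
        report = MapFitReport(
            mse_per_joint=mse,
            overall_mse=float(mse.mean()),
            euclidean_error_per_joint_before=before,
            euclidean_error_per_joint_after=after,
        )
        return AffineMapResults(self, amap, report, train_index=idx)


class AffineMapResults:
    """Fitted per-joint affine maps with their fit diagnostics."""

    def __init__(self, model, map_, report, train_index):
        self.model = model
        self.map_ = map_
        self.report = report
        self.train_index = train_index

    @property
    def overall_mse(self) -> float:
        return self.report.overall_mse

    def transform(self, seq: SkeletonSequence) -> SkeletonSequence:
        return apply_affine_map(seq, self.map_)

    def summary(self) -> str:
        df = self.report.to_frame()
        lines = [
            "Per-joint Kinect-25 -> COCO-17 affine alignment",
            f"  paired frames available: {self.model.nobs}",
            f"  frames used for fitting: {self.map_.n_train}",
            f"  overall MSE:             {self.overall_mse:.6e}",
            "",
            df.to_string(index=False, float_format=lambda v: f"{v:.6f}"),
        ]
        return "\n".join(lines)

    def plot_joint_errors(self, ax=None):
        """Bar chart of mean per-joint Euclidean error, raw vs aligned."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        x = np.arange(17)
        ax.bar(x - 0.2, self.report.euclidean_error_per_joint_before, 0.4,
               label="original Kinect")
        ax.bar(x + 0.2, self.report.euclidean_error_per_joint_after, 0.4,
               label="transformed")
        ax.set_xticks(x)
        ax.set_xticklabels(COCO17_JOINT_NAMES, rotation=60, ha="right")
        ax.set_ylabel("mean Euclidean error")
        ax.legend()
        return ax


def fit_affine_map(
    paired_frames,
    correspondence: tuple | None = None,
    n_train: int = 30,
    seed: int = 0,
) -> tuple[AffineJointMap, MapFitReport]:
    """Functional wrapper around :class:`AffineAligner`."""
    kin, coco = _as_paired_arrays(paired_frames)
    res = AffineAligner(kin, coco, correspondence).fit(n_train=n_train, seed=seed)
    return res.map_, res.report


def apply_affine_map(seq: SkeletonSequence, amap: AffineJointMap) -> SkeletonSequence:
    """Convert a KINECT25 sequence to COCO17 through the fitted maps."""
    if seq.convention is not Convention.KINECT25:
        raise ValueError(
            f"apply_affine_map expects a KINECT25 sequence; got {seq.convention.value}"
        )
    coords = amap.transform_frames(seq.coords)
    coords[~seq.valid_mask] = 0.0  # dead frames stay encoded as exact zeros
    return SkeletonSequence(
        coords=coords,
        label=seq.label,
        convention=Convention.COCO17,
        valid_mask=seq.valid_mask.copy(),
        source_id=seq.source_id,
    )


def evaluate_alignment(transformed, reference, baseline=None) -> MapFitReport:
    """MPJPE-style comparison of two matched COCO17 collections.

    Accepts lists of :class:`SkeletonSequence` (equal counts and lengths) or
    plain ``(N, 17, 3)`` frame arrays.  Only frames valid in both sequences
    contribute.  When ``baseline`` (an unaligned prediction of the same
    shape) is given, its error against ``reference`` fills the
    ``euclidean_error_per_joint_before`` column for before/after
    comparisons; otherwise both Euclidean columns report ``transformed``.
    """

    def to_frames(obj):
        if isinstance(obj, np.ndarray):
            return obj.reshape(-1, 17, 3), None
        frames, masks = [], []
        for s in obj:
            if s.convention is not Convention.COCO17:
                raise ValueError("evaluate_alignment expects COCO17 sequences")
            frames.append(s.coords)
            masks.append(s.valid_mask)
        return np.concatenate(frames), np.concatenate(masks)

    ft, mt = to_frames(transformed)
    fr, mr = to_frames(reference)
    if ft.shape != fr.shape:
        raise ValueError(f"shape mismatch: {ft.shape} vs {fr.shape}")
    keep = np.ones(ft.shape[0], dtype=bool)
    if mt is not None and mr is not None:
        keep = mt & mr
        if not keep.any():
            raise ValueError("no jointly valid frames to compare")
    d2 = ((ft[keep] - fr[keep]) ** 2).sum(axis=2)  # (N, 17)
    mse = d2.mean(axis=0)
    eucl = np.sqrt(d2).mean(axis=0)
    before = eucl
    if baseline is not None:
        fb, _ = to_frames(baseline)
        if fb.shape != fr.shape:
            raise ValueError("baseline shape mismatch with reference")
        before = np.linalg.norm(fb[keep] - fr[keep], axis=2).mean(axis=0)
    return MapFitReport(
        mse_per_joint=mse,
        overall_mse=float(mse.mean()),
        euclidean_error_per_joint_before=before,
        euclidean_error_per_joint_after=eucl,
    )
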