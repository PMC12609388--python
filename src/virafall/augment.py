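"""Synthetic viewpoint generation and occlusion simulation.

Viewpoint augmentation rotates a 3D skeleton sequence about two axes:
a yaw about the vertical ``z`` axis by ``theta_z`` and a tilt about the
horizontal ``x`` axis by ``theta_x``.  The combined operator is

    R(theta_x, theta_z) = Rx(theta_x) @ Rz(theta_z)

applied frame-wise to every joint, ``p' = R p``.  The default grid
``theta_x in {0, 15, 25}`` x ``theta_z in {0, 40, ..., 320}`` yields
3 x 9 = 27 synthetic viewpoints per sequence.

Occlusion simulation emulates the downstream effect of obscured video on a
pose extractor at the skeleton level: a spatial box zeroes every joint
inside a randomly placed axis-aligned box over a contiguous frame window,
and a temporal blackout zeroes whole frames and clears their validity mask.
All occluded entries are exact zeros; labels are never changed.  Angles are
degrees everywhere in the public API.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .core import SkeletonSequence

__all__ = [
    "RotationGrid",
    "OcclusionSpec",
    "rotation_matrix",
    "rotate_sequence",
    "generate_views",
    "occlude",
]


@dataclass(frozen=True)
class RotationGrid:
    """The two angle sets whose Cartesian product defines the views."""

    theta_x_set: tuple = (0.0, 15.0, 25.0)
    theta_z_set: tuple = (0.0, 40.0, 80.0, 120.0, 160.0, 200.0, 240.0, 280.0, 320.0)

    @property
    def n_views(self) -> int:
        return len(self.theta_x_set) * len(self.theta_z_set)

    def pairs(self):
        """(theta_x, theta_z) pairs, x-major order."""
        return list(itertools.product(self.theta_x_set, self.theta_z_set))


def rotation_matrix(theta_x: float, theta_z: float) -> np.ndarray:
    """Combined rotation ``Rx(theta_x) @ Rz(theta_z)`` (angles in degrees).

    ``Rz`` (yaw, applied first) rotates in the x-y plane; ``Rx`` (tilt)
    rotates in the y-z plane.  The result is orthonormal with det = +1.
    """
    if not (np.isfinite(theta_x) and np.isfinite(theta_z)):
        raise ValueError("rotation angles must be finite")
    ax, az = np.deg2rad(theta_x), np.deg2rad(theta_z)
    cx, sx = np.cos(ax), np.sin(ax)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1.0, 0.0, 0.0], [0.0, cx, -sx], [0.0, sx, cx]])
    rz = np.array([[cz, -sz, 0.0], [sz, cz, 0.0], [0.0, 0.0, 1.0]])
    return rx @ rz


def rotate_sequence(
    seq: SkeletonSequence, theta_x: float, theta_z: float
) -> SkeletonSequence:
    """Rotate every joint of every frame by ``R(theta_x, theta_z)``.

    The zero-angle view returns the input coordinates bit-exactly; occluded
    zeros stay exact zeros (the origin is a fixed point of the rotation).
    """
    out = seq.copy()
    if theta_x == 0.0 and theta_z == 0.0:
        return out
    r = rotation_matrix(theta_x, theta_z)
    out.coords = seq.coords @ r.T
    return out


def generate_views(
    seq: SkeletonSequence, grid: RotationGrid = RotationGrid()
) -> list[SkeletonSequence]:
    """One rotated copy of ``seq`` per (theta_x, theta_z) grid pair.

    Labels, masks and shapes are unchanged; only coordinates rotate.
    """
    pairs = grid.pairs()
    if not pairs:
        raise ValueError("rotation grid is empty")
    return [rotate_sequence(seq, tx, tz) for tx, tz in pairs]


@dataclass(frozen=True)
class OcclusionSpec:
    """Occlusion sampling parameters.

    ``box_fraction`` sizes the spatial box as a fraction of the skeleton's
    bounding-box extent per axis; ``blackout_frames`` bounds the blackout
    window length (inclusive).  All randomness flows from ``seed``.
    """

    mode: str = "spatial_box"  # or "temporal_blackout"
    n_variants: int = 10
    box_fraction: float = 0.3
    blackout_frames: tuple = (10, 60)
    seed: int = 0

    def __post_init__(self):
        if self.mode not in ("spatial_box", "temporal_blackout"):
            raise ValueError(f"unknown occlusion mode {self.mode!r}")
        if self.n_variants < 1:
            raise ValueError("n_variants must be >= 1")
        if not 0.0 < self.box_fraction < 1.0:
            raise ValueError("box_fraction must lie strictly in (0, 1)")


_MIN_VALID_FRACTION = 0.1  # blackout never erases more than 90% of frames


def _spatial_box_variant(
    seq: SkeletonSequence, spec: OcclusionSpec, rng: np.random.Generator
) -> SkeletonSequence:
    out = seq.copy()
    t = seq.num_frames
    valid = np.nonzero(seq.valid_mask)[0]
    pts = seq.coords[valid].reshape(-1, 3)
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    extent = np.maximum(hi - lo, 1e-9)
    for _ in range(32):  # resample until the box actually hits a joint
        size = spec.box_fraction * extent
        corner = lo + rng.random(3) * np.maximum(extent - size, 0.0)
        w = int(rng.integers(max(1, t // 10), max(2, t // 2)))
        start = int(rng.integers(0, max(1, t - w)))
        window = slice(start, start + w)
        inside = np.all(
            (out.coords[window] >= corner) & (out.coords[window] <= corner + size),
            axis=2,
        )
        inside &= out.valid_mask[window, None]
        if inside.any():
            block = out.coords[window]
            block[inside] = 0.0
            out.coords[window] = block
            return out
    # degenerate geometry: fall back to zeroing one random joint everywhere
    j = int(rng.integers(seq.num_joints))
    out.coords[out.valid_mask, j, :] = 0.0
    return out


def _temporal_blackout_variant(
    seq: SkeletonSequence, spec: OcclusionSpec, rng: np.random.Generator
) -> SkeletonSequence:
    out = seq.copy()
    t = seq.num_frames
    lo, hi = spec.blackout_frames
    max_dark = max(1, int((1.0 - _MIN_VALID_FRACTION) * t))
    w = int(rng.integers(lo, hi + 1))
    w = min(max(1, w), max_dark)
    start = int(rng.integers(0, max(1, t - w)))
    out.coords[start : start + w] = 0.0
    out.valid_mask[start : start + w] = False
    if not out.valid_mask.any():  # clamp: leave the first frame observable
        out.valid_mask[0] = True
        out.coords[0] = seq.coords[0]
    return out


def occlude(seq: SkeletonSequence, spec: OcclusionSpec) -> list[SkeletonSequence]:
    """Generate ``spec.n_variants`` independently occluded copies of ``seq``.

    Deterministic under ``spec.seed``; every variant differs from the source
    in at least one entry and keeps the source's label and id.
    """
    rng = np.random.default_rng(spec.seed)
    make = (
        _spatial_box_variant
        if spec.mode == "spatial_box"
        else _temporal_blackout_variant
    )
    return [make(seq, spec, rng) for _ in range(spec.n_variants)]
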