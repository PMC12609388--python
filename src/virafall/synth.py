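"""Synthetic labelled skeleton sequences for falls and daily activities.

The generator emulates the statistical structure that fall-detection
training data exhibits, without any video: a canonical unit-height body
(scale-jittered per sequence) is driven through piecewise keyframe motifs
in a subject-centred world frame (origin on the floor beneath the subject,
``z`` up).  Fall sequences show the standing -> descent -> prone-persistence
pattern; daily activities cycle walking, sitting, squatting, plus a slow
controlled recline to floor level that makes descent *speed* — not final
height — the discriminative cue within each domain.

Two domains with distinct fall dynamics are provided, mirroring the
contrast between realistic fast falls and slower staged descents:

================  fall descent (s)   recline descent (s)
``fast_fall``     U(0.20, 0.35)      U(1.1, 1.4)
``slow_fall``     U(2.00, 2.60)      U(4.0, 5.0)
================  ==================  ===================

The descent-duration bands are disjoint within each domain (separable by a
height-drop-rate threshold) and interleave across domains, so a classifier
trained on one domain has no basis for the other's fall speeds — the lever
for domain-shift experiments.  Mean peak vertical fall velocity differs
between domains by a factor of roughly 8 (configured to be at least 2).

A paired-skeleton mode emits the same motion in the Kinect-25 layout
together with a COCO-17 view produced by known per-joint affine maps, for
alignment-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .core import Convention, SkeletonSequence
from .kinectmap import DEFAULT_CORRESPONDENCE, AffineJointMap

__all__ = [
    "GeneratorConfig",
    "PairedSkeletonSample",
    "DOMAIN_PARAMS",
    "generate_sequences",
    "generate_paired_samples",
    "rebalance",
    "torso_height",
    "floor_descent_rate",
    "domain_peak_velocity_factor",
]

# body proportions as fractions of total height (z up, x forward, y left)
_HIP_H, _KNEE_H, _ANKLE_H = 0.53, 0.28, 0.05
_SHOULDER_UP, _NOSE_UP, _EYE_UP, _EAR_UP = 0.29, 0.40, 0.41, 0.40
_SHOULDER_HALF, _HIP_HALF, _EYE_HALF, _EAR_HALF = 0.11, 0.06, 0.03, 0.05
_THIGH, _SHANK = 0.25, 0.23
_UPPER_ARM, _FOREARM = 0.17, 0.16
_NOSE_FWD, _EYE_FWD = 0.05, 0.04

_FALL_END_H, _RECLINE_END_H = 0.10, 0.10
_SIT_H, _SQUAT_H = 0.24, 0.30

DOMAIN_PARAMS = {
    "fast_fall": {"fall_d": (0.20, 0.35), "recline_d": (1.1, 1.4)},
    "slow_fall": {"fall_d": (2.00, 2.60), "recline_d": (4.0, 5.0)},
}

_NONFALL_MOTIFS = ("walk", "sit", "squat", "recline")
_NONFALL_PROBS = (0.25, 0.20, 0.15, 0.40)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one generated dataset.

    ``noise_sd`` is Gaussian coordinate jitter in body-height units.
    ``frame_len`` and ``fps`` fix the clip duration; the default 300 frames
    at 25 fps (12 s) accommodates the slowest motif.  Identical config and
    seed give bit-identical output.
    """

    n_sequences: int = 100
    fall_fraction: float = 0.5
    domain: str = "fast_fall"
    frame_len: int = 300
    fps: float = 25.0
    noise_sd: float = 0.01
    scale_jitter: float = 0.10
    seed: int = 0

    def __post_init__(self):
        if self.n_sequences < 1:
            raise ValueError("n_sequences must be >= 1")
        if not 0.0 <= self.fall_fraction <= 1.0:
            raise ValueError(
                f"fall_fraction must lie in [0, 1]; got {self.fall_fraction}"
            )
        if self.domain not in DOMAIN_PARAMS:
            raise ValueError(
                f"unknown domain {self.domain!r}; choose from {sorted(DOMAIN_PARAMS)}"
            )
        if self.frame_len < 2 or self.fps <= 0:
            raise ValueError("frame_len must be >= 2 and fps > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PairedSkeletonSample:
    """One motion in both conventions, related by known per-joint maps."""

    kinect25: SkeletonSequence
    coco17: SkeletonSequence
    true_maps: AffineJointMap


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _leg_ik(h: np.ndarray, ankle_x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sagittal two-link leg: knee (x, z) given pelvis height and ankle x.

    The knee bends forward when the pelvis sits lower than full extension.
    """
    hip = np.stack([np.zeros_like(h), h], axis=-1)
    ankle = np.stack([ankle_x, np.full_like(h, _ANKLE_H)], axis=-1)
    d = ankle - hip
    dist = np.maximum(np.linalg.norm(d, axis=-1), 1e-9)
    reach = np.minimum(dist, _THIGH + _SHANK - 1e-9)
    cos_a = (_THIGH**2 + reach**2 - _SHANK**2) / (2 * _THIGH * reach)
    alpha = np.arccos(np.clip(cos_a, -1.0, 1.0))
    axis = d / dist[..., None]
    # rotate the hip->ankle direction by +alpha (forward bend) in the plane
    ca, sa = np.cos(alpha), np.sin(alpha)
    rot = np.stack(
        [ca * axis[..., 0] - sa * axis[..., 1],
         sa * axis[..., 0] + ca * axis[..., 1]],
        axis=-1,
    )
    knee = hip + _THIGH * rot
    return knee, ankle


def _pose_frames(
    h: np.ndarray,
    pitch: np.ndarray,
    gait: np.ndarray,
    gait_amp: np.ndarray,
) -> dict[str, np.ndarray]:
    """Joint positions (body frame) for T frames of scalar pose state.

    Returns named landmark arrays of shape (T, 3); legs blend from an
    upright inverse-kinematics solution to a prone extension as pitch
    approaches horizontal.
    """
    t = h.shape[0]
    lam = np.clip(pitch / (0.5 * np.pi), 0.0, 1.0)[:, None]
    u = np.stack([np.sin(pitch), np.zeros(t), np.cos(pitch)], axis=1)
    f = np.stack([np.cos(pitch), np.zeros(t), -np.sin(pitch)], axis=1)
    ey = np.array([0.0, 1.0, 0.0])

    mid_hip = np.stack([np.zeros(t), np.zeros(t), h], axis=1)
    out: dict[str, np.ndarray] = {}
    out["left_hip"] = mid_hip + _HIP_HALF * ey
    out["right_hip"] = mid_hip - _HIP_HALF * ey
    shoulder_c = mid_hip + _SHOULDER_UP * u
    out["left_shoulder"] = shoulder_c + _SHOULDER_HALF * ey
    out["right_shoulder"] = shoulder_c - _SHOULDER_HALF * ey
    out["nose"] = mid_hip + _NOSE_UP * u + _NOSE_FWD * f
    out["left_eye"] = mid_hip + _EYE_UP * u + _EYE_FWD * f + _EYE_HALF * ey
    out["right_eye"] = mid_hip + _EYE_UP * u + _EYE_FWD * f - _EYE_HALF * ey
    out["left_ear"] = mid_hip + _EAR_UP * u + _EAR_HALF * ey
    out["right_ear"] = mid_hip + _EAR_UP * u - _EAR_HALF * ey

    swing = (gait_amp * np.sin(gait))[:, None]
    for side, sign, arm_ph in (("left", 1.0, 1.0), ("right", -1.0, -1.0)):
        sh = out[f"{side}_shoulder"]
        elbow = sh - _UPPER_ARM * u + 0.4 * arm_ph * swing * f
        wrist = elbow - _FOREARM * u + 0.03 * f + 0.6 * arm_ph * swing * f
        out[f"{side}_elbow"] = elbow
        out[f"{side}_wrist"] = wrist

        ankle_x = 0.7 * sign * gait_amp * np.sin(gait)
        knee2d, ankle2d = _leg_ik(h, ankle_x)
        hip3 = out[f"{side}_hip"]
        knee_up = np.stack(
            [knee2d[:, 0], np.full(t, sign * _HIP_HALF), knee2d[:, 1]], axis=1
        )
        ankle_up = np.stack(
            [ankle2d[:, 0], np.full(t, sign * _HIP_HALF), ankle2d[:, 1]], axis=1
        )
        knee_pr = hip3 - _THIGH * u
        ankle_pr = knee_pr - _SHANK * u
        out[f"{side}_knee"] = (1 - lam) * knee_up + lam * knee_pr
        out[f"{side}_ankle"] = (1 - lam) * ankle_up + lam * ankle_pr

    out["mid_hip"] = mid_hip
    out["shoulder_c"] = shoulder_c
    out["spine_u"] = u
    out["forward_f"] = f
    return out


_COCO_ORDER = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
)


def _to_coco17(pose: dict[str, np.ndarray]) -> np.ndarray:
    return np.stack([pose[name] for name in _COCO_ORDER], axis=1)


def _to_kinect25(pose: dict[str, np.ndarray]) -> np.ndarray:
    """Derive the 25-joint Kinect layout from the same underlying pose."""
    u, f = pose["spine_u"], pose["forward_f"]
    mid_hip, shoulder_c = pose["mid_hip"], pose["shoulder_c"]
    ey = np.array([0.0, 1.0, 0.0])
    j = {}
    j[0] = mid_hip                                   # spine_base
    j[1] = 0.5 * (mid_hip + shoulder_c)              # spine_mid
    j[20] = shoulder_c                               # spine_shoulder
    j[2] = shoulder_c + 0.06 * u                     # neck
    j[3] = shoulder_c + 0.14 * u + 0.02 * f          # head
    j[4], j[8] = pose["left_shoulder"], pose["right_shoulder"]
    j[5], j[9] = pose["left_elbow"], pose["right_elbow"]
    j[6], j[10] = pose["left_wrist"], pose["right_wrist"]
    for side, w, tip, th, sign in (("left", 7, 21, 22, 1.0), ("right", 11, 23, 24, -1.0)):
        wrist = pose[f"{side}_wrist"]
        elbow = pose[f"{side}_elbow"]
        d = wrist - elbow
        d = d / np.maximum(np.linalg.norm(d, axis=1, keepdims=True), 1e-9)
        j[w] = wrist + 0.07 * d                      # hand
        j[tip] = wrist + 0.12 * d                    # hand tip
        j[th] = wrist + 0.05 * d + sign * 0.03 * ey  # thumb
    j[12], j[16] = pose["left_hip"], pose["right_hip"]
    j[13], j[17] = pose["left_knee"], pose["right_knee"]
    j[14], j[18] = pose["left_ankle"], pose["right_ankle"]
    for side, ank, foot in (("left", 14, 15), ("right", 18, 19)):
        j[foot] = j[ank] + 0.10 * f
    return np.stack([j[i] for i in range(25)], axis=1)


def _motif_profile(
    motif: str, tgrid: np.ndarray, params: dict, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """(pelvis height, torso pitch, gait phase, gait amplitude) over time."""
    t = tgrid
    l_sec = float(t[-1]) if len(t) > 1 else 1.0
    h = np.full_like(t, _HIP_H)
    pitch = np.zeros_like(t)
    gait_phase = np.zeros_like(t)
    gait_amp = np.zeros_like(t)

    def onset(d: float) -> tuple[float, float]:
        """Descent start and (possibly clamped) duration fitting the clip."""
        d = min(d, max(0.3, 0.8 * l_sec - 0.51))
        hi = max(0.51, 0.8 * l_sec - d)
        return float(rng.uniform(0.5, hi)), d

    if motif == "walk":
        freq = rng.uniform(1.5, 2.0)
        gait_phase = 2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi)
        gait_amp = np.full_like(t, rng.uniform(0.10, 0.14))
        h = _HIP_H + 0.015 * np.sin(2 * gait_phase)
    elif motif == "fall":
        t0, d = onset(rng.uniform(*params["fall_d"]))
        s = _smoothstep((t - t0) / d)
        h = _HIP_H + (_FALL_END_H - _HIP_H) * s
        pitch = np.deg2rad(85.0) * s
    elif motif == "recline":
        t0, d = onset(rng.uniform(*params["recline_d"]))
        s = _smoothstep((t - t0) / d)
        h = _HIP_H + (_RECLINE_END_H - _HIP_H) * s
        pitch = np.deg2rad(85.0) * s
    elif motif == "sit":
        t0, d = onset(rng.uniform(0.8, 1.2))
        s = _smoothstep((t - t0) / d)
        h = _HIP_H + (_SIT_H - _HIP_H) * s
        pitch = np.deg2rad(8.0) * s
    elif motif == "squat":
        t0, d = onset(rng.uniform(0.6, 1.0))
        hold = rng.uniform(0.5, 1.5)
        down = _smoothstep((t - t0) / d)
        up = _smoothstep((t - (t0 + d + hold)) / d)
        h = _HIP_H + (_SQUAT_H - _HIP_H) * (down - up)
    else:
        raise ValueError(f"unknown motif {motif!r}")
    return h, pitch, gait_phase, gait_amp


def _yaw_matrix(psi: float) -> np.ndarray:
    c, s = math.cos(psi), math.sin(psi)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _generate_motion(
    motif: str, cfg: GeneratorConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Pose landmark dict for one sequence, in world coordinates."""
    t = np.arange(cfg.frame_len) / cfg.fps
    params = DOMAIN_PARAMS[cfg.domain]
    h, pitch, gait_phase, gait_amp = _motif_profile(motif, t, params, rng)
    pose = _pose_frames(h, pitch, gait_phase, gait_amp)

    scale = 1.0 + rng.uniform(-cfg.scale_jitter, cfg.scale_jitter)
    yaw = _yaw_matrix(rng.uniform(0.0, 2 * np.pi))
    # slow rigid 3D body sway; keeps every joint trajectory full-rank
    ph = rng.uniform(0, 2 * np.pi, size=3)
    sway = np.stack(
        [
            0.015 * np.sin(2 * np.pi * 0.31 * t + ph[0]),
            0.015 * np.sin(2 * np.pi * 0.23 * t + ph[1]),
            0.008 * np.sin(2 * np.pi * 0.41 * t + ph[2]),
        ],
        axis=1,
    )
    world = {}
    for name, arr in pose.items():
        if name in ("spine_u", "forward_f"):
            world[name] = arr @ yaw.T
        else:
            world[name] = (scale * arr) @ yaw.T + sway
    return world


def generate_sequences(cfg: GeneratorConfig) -> list[SkeletonSequence]:
    """Generate ``cfg.n_sequences`` labelled COCO-17 sequences.

    The number of falls is ``round(n * fall_fraction)``; order is shuffled
    deterministically under the seed.  Gaussian jitter of sd ``noise_sd``
    is added to every coordinate.
    """
    rng = np.random.default_rng(cfg.seed)
    n_fall = int(round(cfg.n_sequences * cfg.fall_fraction))
    labels = np.array([1] * n_fall + [0] * (cfg.n_sequences - n_fall))
    rng.shuffle(labels)

    out = []
    for i, label in enumerate(labels):
        if label == 1:
            motif = "fall"
        else:
            motif = rng.choice(_NONFALL_MOTIFS, p=_NONFALL_PROBS)
        pose = _generate_motion(motif, cfg, rng)
        coords = _to_coco17(pose)
        if cfg.noise_sd > 0:
            coords = coords + rng.normal(0.0, cfg.noise_sd, size=coords.shape)
        out.append(
            SkeletonSequence(
                coords=coords,
                label=int(label),
                convention=Convention.COCO17,
                source_id=f"synth-{cfg.domain}-{cfg.seed}-{i:05d}",
            )
        )
    return out


def _random_affine_maps(rng: np.random.Generator) -> AffineJointMap:
    """Well-conditioned random per-joint maps (|det A_j| bounded below)."""
    a = np.empty((17, 3, 3))
    for j in range(17):
        while True:
            cand = np.eye(3) + 0.3 * rng.standard_normal((3, 3))
            if abs(np.linalg.det(cand)) >= 0.2:
                a[j] = cand
                break
    b = 0.1 * rng.standard_normal((17, 3))
    return AffineJointMap(correspondence=DEFAULT_CORRESPONDENCE, A=a, b=b)


def generate_paired_samples(
    cfg: GeneratorConfig, map_spec="random"
) -> list[PairedSkeletonSample]:
    """Paired Kinect-25 / COCO-17 sequences related by known affine maps.

    ``map_spec`` is ``"random"``, ``"identity"`` or an explicit
    :class:`AffineJointMap` (all 17 maps must be non-singular).  The COCO
    view is the map image of the correspondence-selected Kinect joints plus
    ``noise_sd`` jitter; the generating maps are returned for recovery
    tests.
    """
    rng = np.random.default_rng(cfg.seed)
    if isinstance(map_spec, AffineJointMap):
        dets = np.linalg.det(map_spec.A)
        if (np.abs(dets) < 1e-8).any():
            bad = int(np.argmin(np.abs(dets)))
            raise ValueError(f"requested A_j is singular for target joint {bad}")
        maps = map_spec
    elif map_spec == "identity":
        maps = AffineJointMap.identity()
    elif map_spec == "random":
        maps = _random_affine_maps(rng)
    else:
        raise ValueError(f"invalid map_spec {map_spec!r}")

    n_fall = int(round(cfg.n_sequences * cfg.fall_fraction))
    labels = np.array([1] * n_fall + [0] * (cfg.n_sequences - n_fall))
    rng.shuffle(labels)

    out = []
    for i, label in enumerate(labels):
        motif = "fall" if label == 1 else rng.choice(_NONFALL_MOTIFS, p=_NONFALL_PROBS)
        pose = _generate_motion(motif, cfg, rng)
        kin_coords = _to_kinect25(pose)
        coco_coords = maps.transform_frames(kin_coords)
        if cfg.noise_sd > 0:
            coco_coords = coco_coords + rng.normal(
                0.0, cfg.noise_sd, size=coco_coords.shape
            )
        sid = f"synthpair-{cfg.domain}-{cfg.seed}-{i:05d}"
        out.append(
            PairedSkeletonSample(
                kinect25=SkeletonSequence(
                    coords=kin_coords,
                    label=int(label),
                    convention=Convention.KINECT25,
                    source_id=sid,
                ),
                coco17=SkeletonSequence(
                    coords=coco_coords,
                    label=int(label),
                    convention=Convention.COCO17,
                    source_id=sid,
                ),
                true_maps=maps,
            )
        )
    return out


def rebalance(
    seqs: list[SkeletonSequence], seed: int = 0, jitter_sd: float = 0.01
) -> list[SkeletonSequence]:
    """Oversample the minority class with jittered copies until balanced.

    Copies keep their source's ``source_id`` so split logic treats them as
    variants of the original recording, never as independent samples.
    """
    rng = np.random.default_rng(seed)
    pos = [s for s in seqs if s.label == 1]
    neg = [s for s in seqs if s.label == 0]
    if not pos or not neg:
        return list(seqs)
    minority, n_needed = (pos, len(neg) - len(pos)) if len(pos) < len(neg) else (
        neg,
        len(pos) - len(neg),
    )
    out = list(seqs)
    for _ in range(n_needed):
        src = minority[int(rng.integers(len(minority)))]
        dup = src.copy()
        dup.coords = dup.coords + rng.normal(0.0, jitter_sd, size=dup.coords.shape)
        out.append(dup)
    return out


# --------------------------------------------------- analysis helpers

def torso_height(seq: SkeletonSequence) -> np.ndarray:
    """Per-frame mid-hip height (z) — the generator's torso-height channel."""
    if seq.convention is Convention.COCO17:
        hips = (11, 12)
    else:
        hips = (12, 16)
    return seq.coords[:, hips, 2].mean(axis=1)


def floor_descent_rate(
    seq: SkeletonSequence,
    fps: float,
    window_sec: float = 0.4,
    floor_frac: float = 0.25,
    smooth_sec: float = 0.2,
) -> float:
    """Fastest sustained torso drop rate of a descent that ends on the floor.

    The torso-height channel is box-smoothed over ``smooth_sec``.  If the
    terminal height (median of the last tenth of the clip) stays above
    ``floor_frac`` of the initial standing height the sequence never ended
    near the floor and the statistic is 0.  Otherwise it is the maximum of
    ``(h[t] - h[t+w]) / window_sec`` over all windows — the peak sustained
    descent speed.  This is the height-drop-rate statistic that separates
    falls from daily activities within a domain.
    """
    h = torso_height(seq)
    k = max(1, int(round(smooth_sec * fps)))
    if k > 1:
        h = np.convolve(h, np.ones(k) / k, mode="valid")
    w = max(1, int(round(window_sec * fps)))
    if len(h) <= w:
        w = len(h) - 1
        if w < 1:
            return 0.0
    h0 = float(np.median(h[: max(1, int(0.5 * fps))]))
    h_end = float(np.median(h[-max(2, len(h) // 10):]))
    if h_end >= floor_frac * h0:
        return 0.0
    drops = (h[:-w] - h[w:]) / (w / fps)
    return float(drops.max())


def domain_peak_velocity_factor() -> float:
    """Ratio of mean peak vertical fall velocity, fast over slow domain.

    Peak velocity of a smoothstep descent of depth ``dh`` over duration
    ``d`` is ``1.5 * dh / d``; the mean over the uniform duration band uses
    ``E[1/d] = ln(b/a) / (b - a)``.
    """

    def mean_peak(band):
        a, b = band
        return 1.5 * (_HIP_H - _FALL_END_H) * math.log(b / a) / (b - a)

    return mean_peak(DOMAIN_PARAMS["fast_fall"]["fall_d"]) / mean_peak(
        DOMAIN_PARAMS["slow_fall"]["fall_d"]
    )
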