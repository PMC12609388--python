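"""Reading and writing skeleton sequences.

Three on-disk dialects are supported:

* ``coco_json`` — one JSON document per file holding a list of sequences,
  each with per-frame 17-keypoint ``[x, y, z]`` triplets;
* ``ntu_skeleton`` — the NTU RGB+D plain-text ``.skeleton`` dialect
  (frame count, per-frame body count, per-body header + 25 joint lines);
* ``hdf5`` — an HDF5 container with one group per sequence
  (datasets ``coords``/``mask``, attrs ``label``/``convention``/``source_id``).

HDF5 round-trips are bit-exact; the text formats round-trip to at least six
decimal places.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import h5py
import numpy as np

from .core import Convention, SkeletonSequence

__all__ = ["read_sequences", "write_sequences", "ParseError"]


class ParseError(ValueError):
    """Malformed record; message names file, line and field."""


def read_sequences(path, format: str) -> list[SkeletonSequence]:
    """Read sequences from ``path`` in the named dialect.

    Parameters
    ----------
    path : path-like
    format : {"coco_json", "ntu_skeleton", "hdf5"}
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "coco_json":
        return _read_coco_json(path)
    if format == "ntu_skeleton":
        return [_read_ntu_skeleton(path)]
    if format == "hdf5":
        return _read_hdf5(path)
    raise ValueError(f"unknown format {format!r}")


def write_sequences(path, seqs: list[SkeletonSequence], format: str) -> None:
    path = Path(path)
    if not seqs:
        raise ValueError("refusing to write an empty sequence list")
    if format == "coco_json":
        _write_coco_json(path, seqs)
    elif format == "hdf5":
        _write_hdf5(path, seqs)
    else:
        raise ValueError(f"unknown or read-only format {format!r}")


# ---------------------------------------------------------------- COCO JSON

def _read_coco_json(path: Path) -> list[SkeletonSequence]:
    text = path.read_text()
    if not text.strip():
        raise ParseError(f"{path}: empty file")
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    if isinstance(doc, dict):
        doc = [doc]
    out = []
    for i, rec in enumerate(doc):
        for fld in ("frames", "label"):
            if fld not in rec:
                raise ParseError(f"{path}: sequence {i}: missing field {fld!r}")
        frames = rec["frames"]
        if not frames:
            raise ParseError(f"{path}: sequence {i}: field 'frames' is empty")
        coords = np.empty((len(frames), 17, 3))
        mask = np.ones(len(frames), dtype=bool)
        for t, fr in enumerate(frames):
            kp = fr.get("keypoints")
            if kp is None or len(kp) != 17:
                raise ParseError(
                    f"{path}: sequence {i}, frame {t}: field 'keypoints' "
                    "must hold 17 [x,y,z] triplets"
                )
            coords[t] = np.asarray(kp, dtype=np.float64)
            mask[t] = bool(fr.get("valid", True))
        out.append(
            SkeletonSequence(
                coords=coords,
                label=int(rec["label"]),
                convention=Convention.COCO17,
                valid_mask=mask,
                source_id=str(rec.get("source_id", f"{path.stem}:{i}")),
            )
        )
    return out


def _write_coco_json(path: Path, seqs: list[SkeletonSequence]) -> None:
    doc = []
    for s in seqs:
        if s.convention is not Convention.COCO17:
            raise ValueError("coco_json stores COCO17 sequences only")
        doc.append(
            {
                "label": int(s.label),
                "source_id": s.source_id,
                "frames": [
                    {
                        "keypoints": [[float(c) for c in joint] for joint in frame],
                        "valid": bool(v),
                    }
                    for frame, v in zip(s.coords, s.valid_mask)
                ],
            }
        )
    path.write_text(json.dumps(doc))


# ------------------------------------------------------------ NTU .skeleton

_NTU_NAME = re.compile(r"S\d+C\d+P\d+R\d+A(\d+)", re.IGNORECASE)
_NTU_FALL_ACTION = 43  # 'falling down' class in the NTU RGB+D label set


def _ntu_label_from_name(path: Path) -> int:
    m = _NTU_NAME.search(path.stem)
    if m is None:
        return 0
    return int(int(m.group(1)) == _NTU_FALL_ACTION)


def _read_ntu_skeleton(path: Path) -> SkeletonSequence:
    """Parse one NTU ``.skeleton`` file.

    Multi-body frames: every tracked body is accumulated by its body id and
    the one with the largest summed joint displacement (most motion) is kept.
    """
    lines = path.read_text().splitlines()
    if not lines or not lines[0].strip():
        raise ParseError(f"{path}: line 1: empty file")
    pos = 0

    def take(field: str) -> str:
        nonlocal pos
        if pos >= len(lines):
            raise ParseError(
                f"{path}: line {pos + 1}: unexpected end of file reading {field}"
            )
        val = lines[pos].strip()
        pos += 1
        return val

    def take_int(field: str) -> int:
        val = take(field)
        try:
            return int(val)
        except ValueError:
            raise ParseError(
                f"{path}: line {pos}: field {field!r}: expected integer, "
                f"got {val!r}"
            ) from None

    n_frames = take_int("frame_count")
    if n_frames < 1:
        raise ParseError(f"{path}: line 1: frame_count must be >= 1")
    bodies: dict[str, np.ndarray] = {}
    seen: dict[str, np.ndarray] = {}
    for t in range(n_frames):
        n_bodies = take_int("body_count")
        for _ in range(n_bodies):
            header = take("body_header").split()
            if not header:
                raise ParseError(f"{path}: line {pos}: empty body header")
            body_id = header[0]
            n_joints = take_int("joint_count")
            if n_joints != 25:
                raise ParseError(
                    f"{path}: line {pos}: field 'joint_count': expected 25, "
                    f"got {n_joints}"
                )
            joints = np.empty((25, 3))
            for v in range(25):
                parts = take("joint_record").split()
                if len(parts) < 3:
                    raise ParseError(
                        f"{path}: line {pos}: joint {v}: expected at least "
                        "3 coordinate fields"
                    )
                try:
                    joints[v] = [float(parts[0]), float(parts[1]), float(parts[2])]
                except ValueError:
                    raise ParseError(
                        f"{path}: line {pos}: joint {v}: non-numeric coordinate"
                    ) from None
            if body_id not in bodies:
                bodies[body_id] = np.zeros((n_frames, 25, 3))
                seen[body_id] = np.zeros(n_frames, dtype=bool)
            bodies[body_id][t] = joints
            seen[body_id][t] = True
    if not bodies:
        raise ParseError(f"{path}: no body records found")

    def displacement(bid: str) -> float:
        c = bodies[bid]
        return float(np.abs(np.diff(c, axis=0)).sum())

    best = max(sorted(bodies), key=displacement)
    return SkeletonSequence(
        coords=bodies[best],
        label=_ntu_label_from_name(path),
        convention=Convention.KINECT25,
        valid_mask=seen[best],
        source_id=path.stem,
    )


# ------------------------------------------------------------------- HDF5

def _write_hdf5(path: Path, seqs: list[SkeletonSequence]) -> None:
    with h5py.File(path, "w") as f:
        for i, s in enumerate(seqs):
            g = f.create_group(f"sequences/{i:06d}")
            g.create_dataset("coords", data=s.coords)
            g.create_dataset("mask", data=s.valid_mask)
            g.attrs["label"] = int(s.label)
            g.attrs["convention"] = s.convention.value
            g.attrs["source_id"] = s.source_id


def _read_hdf5(path: Path) -> list[SkeletonSequence]:
    out = []
    with h5py.File(path, "r") as f:
        if "sequences" not in f:
            raise ParseError(f"{path}: missing top-level 'sequences' group")
        for key in sorted(f["sequences"]):
            g = f["sequences"][key]
            out.append(
                SkeletonSequence(
                    coords=g["coords"][...],
                    label=int(g.attrs["label"]),
                    convention=Convention(str(g.attrs["convention"])),
                    valid_mask=g["mask"][...],
                    source_id=str(g.attrs["source_id"]),
                )
            )
    if not out:
        raise ParseError(f"{path}: container holds no sequences")
    return out
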