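"""Kinect V2 skeleton gait data model and preprocessing.

A gait record is a sequence of frames, each frame 25 joints with (x, y, z)
camera-frame coordinates in meters.  Preprocessing mirrors the acquisition
geometry of ceiling-mounted Kinect V2 cameras: rotate the coordinates about
the x-axis to undo the camera tilt, re-center every frame on the spine base,
cut fixed-length clips with a sliding window, and optionally keep only a
subset of informative joints (lower body plus the right upper limb by
default).

Joint indexing follows the Kinect V2 SDK layout:

====  ==============  ====  ==============
 0    SpineBase        13   KneeLeft
 1    SpineMid         14   AnkleLeft
 2    Neck             15   FootLeft
 3    Head             16   HipRight
 4    ShoulderLeft     17   KneeRight
 5    ElbowLeft        18   AnkleRight
 6    WristLeft        19   FootRight
 7    HandLeft         20   SpineShoulder
 8    ShoulderRight    21   HandTipLeft
 9    ElbowRight       22   ThumbLeft
10    WristRight       23   HandTipRight
11    HandRight        24   ThumbRight
====  ==============  ====  ==============
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

N_JOINTS = 25

KINECT_V2_JOINT_NAMES = (
    "SpineBase", "SpineMid", "Neck", "Head",
    "ShoulderLeft", "ElbowLeft", "WristLeft", "HandLeft",
    "ShoulderRight", "ElbowRight", "WristRight", "HandRight",
    "HipLeft", "KneeLeft", "AnkleLeft", "FootLeft",
    "HipRight", "KneeRight", "AnkleRight", "FootRight",
    "SpineShoulder", "HandTipLeft", "ThumbLeft", "HandTipRight", "ThumbRight",
)

#: Lower body (spine base, both legs) plus the right upper limb.
DEFAULT_KEYPOINT_INDICES = (0, 8, 9, 10, 11, 12, 13, 14, 15, 16, 17, 18, 19, 23, 24)


@dataclass(frozen=True)
class SkeletonFrame:
    """One frame: ``joints`` is a (V, 3) array of camera-frame coordinates."""

    joints: np.ndarray
    frame_index: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "joints", np.asarray(self.joints, dtype=np.float64))
        if self.joints.ndim != 2 or self.joints.shape[1] != 3:
            raise ValueError(f"joints must be (V, 3), got {self.joints.shape}")


@dataclass(frozen=True)
class SkeletonRecord:
    """A per-subject skeleton sequence.

    ``data`` is a (T, V, 3) array; individual frames are exposed through
    :meth:`frames`.  Only front-view records should enter the pipeline — the
    back-view skeleton estimates are too unreliable.
    """

    subject_id: str
    data: np.ndarray
    view: str = "front"
    joint_scheme: str = "kinect_v2_25"

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3 or data.shape[2] != 3:
            raise ValueError(f"data must be (T, V, 3), got {data.shape}")
        if data.shape[0] == 0:
            raise ValueError("record has no frames")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_joints(self) -> int:
        return int(self.data.shape[1])

    def frames(self) -> Iterator[SkeletonFrame]:
        for t in range(self.n_frames):
            yield SkeletonFrame(self.data[t], t)


@dataclass(frozen=True)
class JointSubset:
    """An ordered subset of joint indices (ascending original index)."""

    indices: tuple[int, ...] = DEFAULT_KEYPOINT_INDICES

    def __post_init__(self) -> None:
        idx = tuple(sorted(int(i) for i in self.indices))
        if len(idx) == 0:
            raise ValueError("joint subset is empty")
        if len(set(idx)) != len(idx):
            raise ValueError("joint subset has duplicate indices")
        if idx[0] < 0:
            raise ValueError("negative joint index")
        object.__setattr__(self, "indices", idx)

    def __len__(self) -> int:
        return len(self.indices)


@dataclass(frozen=True)
class GaitClip:
    """A fixed-size window of a record, shaped (D=3, T, V)."""

    data: np.ndarray
    subject_id: str
    label: str | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3 or data.shape[0] != 3:
            raise ValueError(f"clip must be (3, T, V), got {data.shape}")
        object.__setattr__(self, "data", data)

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_joints(self) -> int:
        return int(self.data.shape[2])


# ---------------------------------------------------------------------------
# preprocessing operations
# ---------------------------------------------------------------------------


def rotation_matrix_x(theta_deg: float) -> np.ndarray:
    """Rotation about the x-axis by ``theta_deg`` degrees."""
    th = math.radians(theta_deg)
    c, s = math.cos(th), math.sin(th)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def rotate_record(record: SkeletonRecord, theta_deg: float = -27.0) -> SkeletonRecord:
    """Rotate every joint about the x-axis, undoing the camera tilt.

    Ceiling-mounted cameras view the walkway at a 27° tilt; rotating by
    −27° brings the skeleton back to a horizontal reference frame.
    """
    if not math.isfinite(theta_deg):
        raise ValueError("rotation angle must be finite")
    if not np.isfinite(record.data).all():
        raise ValueError(f"record {record.subject_id!r} contains non-finite coordinates")
    rot = rotation_matrix_x(theta_deg)
    rotated = record.data @ rot.T
    return replace(record, data=rotated)


def center_record(record: SkeletonRecord, root_index: int = 0) -> SkeletonRecord:
    """Move the coordinate origin of every frame to the root joint.

    After centering, the root joint (spine base by default) is exactly
    (0, 0, 0) in every frame, which removes the absolute position of the
    subject in the room.
    """
    if not 0 <= root_index < record.n_joints:
        raise ValueError(f"root index {root_index} out of range for V={record.n_joints}")
    centered = record.data - record.data[:, root_index : root_index + 1, :]
    return replace(record, data=centered)


def extract_clips(
    record: SkeletonRecord,
    window: int = 60,
    stride: int = 3,
    label: str | None = None,
) -> list[GaitClip]:
    """Cut fixed-length clips with a sliding window.

    Windows start at frames 0, stride, 2·stride, …; a record shorter than
    the window yields no clips (short records are dropped, not padded —
    padding would fabricate gait frames).
    """
    if window < 1 or stride < 1:
        raise ValueError("window and stride must be >= 1")
    length = record.n_frames
    if length < window:
        logger.warning(
            "record %s has %d frames (< window %d); no clips extracted",
            record.subject_id, length, window,
        )
        return []
    n_clips = (length - window) // stride + 1
    clips = []
    for k in range(n_clips):
        start = k * stride
        # (T, V, 3) window -> (3, T, V)
        win = record.data[start : start + window].transpose(2, 0, 1)
        clips.append(GaitClip(win, record.subject_id, label))
    return clips


def select_joints(clip: GaitClip, subset: JointSubset) -> GaitClip:
    """Keep only the joints in ``subset``, in ascending original order."""
    if subset.indices[-1] >= clip.n_joints:
        raise ValueError(
            f"joint index {subset.indices[-1]} out of range for V={clip.n_joints}"
        )
    return replace(clip, data=clip.data[:, :, list(subset.indices)])


def clips_to_array(clips: Sequence[GaitClip]) -> np.ndarray:
    """Stack clips into a (N, 3, T, V) float32 batch array."""
    if len(clips) == 0:
        raise ValueError("no clips to stack")
    return np.stack([c.data for c in clips]).astype(np.float32)


# ---------------------------------------------------------------------------
# skeleton CSV / JSON-lines dialects
# ---------------------------------------------------------------------------

_COORD_COLUMNS = [f"{ax}{j}" for j in range(N_JOINTS) for ax in ("x", "y", "z")]


def write_skeleton_csv(record: SkeletonRecord, path: str | Path) -> None:
    """One row per frame: subject_id, frame_index, x0,y0,z0,…,x24,y24,z24."""
    flat = record.data.reshape(record.n_frames, -1)
    df = pd.DataFrame(flat, columns=_COORD_COLUMNS[: flat.shape[1]])
    df.insert(0, "frame_index", np.arange(record.n_frames))
    df.insert(0, "subject_id", record.subject_id)
    df.to_csv(path, index=False, float_format="%.6f")


def read_skeleton_csv(path: str | Path) -> SkeletonRecord:
    df = pd.read_csv(path)
    return _record_from_table(df, path)


def write_skeleton_jsonl(record: SkeletonRecord, path: str | Path) -> None:
    """JSON-lines dialect with the same fields as the CSV."""
    with open(path, "w") as fh:
        for t in range(record.n_frames):
            row: dict = {"subject_id": record.subject_id, "frame_index": t}
            flat = record.data[t].ravel()
            for name, val in zip(_COORD_COLUMNS, flat):
                row[name] = round(float(val), 6)
            fh.write(json.dumps(row) + "\n")


def read_skeleton_jsonl(path: str | Path) -> SkeletonRecord:
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    return _record_from_table(pd.DataFrame(rows), path)


def _record_from_table(df: pd.DataFrame, path: str | Path) -> SkeletonRecord:
    missing = [c for c in ("subject_id", "frame_index") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    coord_cols = [c for c in df.columns if c not in ("subject_id", "frame_index")]
    if len(coord_cols) % 3 != 0 or len(coord_cols) == 0:
        raise ValueError(
            f"{path}: expected 3·V coordinate columns, got {len(coord_cols)}"
        )
    subject_ids = df["subject_id"].unique()
    if len(subject_ids) != 1:
        raise ValueError(f"{path}: more than one subject_id in file")
    df = df.sort_values("frame_index")
    coords = df[coord_cols].to_numpy(dtype=np.float64)
    if not np.isfinite(coords).all():
        raise ValueError(f"{path}: non-finite coordinates")
    data = coords.reshape(len(df), -1, 3)
    return SkeletonRecord(subject_id=str(subject_ids[0]), data=data)


# ---------------------------------------------------------------------------
# label manifest
# ---------------------------------------------------------------------------

LABELS = ("HC", "MCI", "AD")


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    """Tab-delimited subject_id → label (HC / MCI / AD) mapping."""
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    bad = set(df["label"]) - set(LABELS)
    if bad:
        raise ValueError(f"{path}: unknown labels {sorted(bad)}")
    return df
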