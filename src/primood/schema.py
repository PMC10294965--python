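"""Channel layout, primitive taxonomy, and recording containers.

The motion-capture setup is an array of nine inertial sensors (bilateral
hands, forearms, and arms, plus C7, T10, and sacral spine) sampled at
100 Hz.  Each frame carries 76 channels: 27 linear accelerations
(9 sensors x 3 axes), 27 orientation components (9 sensors x 3 components),
and 22 anatomical joint angles.  Every frame is labeled with one of five
functional primitives: reach, transport, reposition, stabilization, idle;
the first three are "motion-based" (substantial limb displacement).

Angles are in degrees, accelerations in m/s^2; units are metadata only
(models standardize their inputs).  Frames are 0-based and segments are
half-open [start, end) so that a recording's segments tile it exactly.
"""

from __future__ import annotations

import enum
import functools
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "PrimitiveClass", "MOTION_BASED", "Channel", "ChannelSchema", "Segment",
    "Recording", "SubjectMeta", "build_channel_schema", "impairment_category",
    "validate_recording", "N_CHANNELS", "RATE_HZ",
]

N_CHANNELS = 76
RATE_HZ = 100


class PrimitiveClass(enum.Enum):
    """The five functional primitives, in canonical (model class) order."""

    REACH = "reach"
    TRANSPORT = "transport"
    REPOSITION = "reposition"
    STABILIZATION = "stabilization"
    IDLE = "idle"

    @property
    def is_motion_based(self) -> bool:
        return self in MOTION_BASED

    @property
    def index(self) -> int:
        return _CLASS_ORDER.index(self)

    @classmethod
    def from_index(cls, i: int) -> "PrimitiveClass":
        return _CLASS_ORDER[i]


_CLASS_ORDER = tuple(PrimitiveClass)
MOTION_BASED = frozenset(
    {PrimitiveClass.REACH, PrimitiveClass.TRANSPORT, PrimitiveClass.REPOSITION}
)

# sensor order is fixed so channel indices are stable
_SENSORS = [
    ("hand", "left"), ("forearm", "left"), ("arm", "left"),
    ("hand", "right"), ("forearm", "right"), ("arm", "right"),
    ("C7", None), ("T10", None), ("sacrum", None),
]
_AXES = ("x", "y", "z")
_ORIENT = ("q1", "q2", "q3")
_UE_ANGLES = [
    "shoulder_flexion_extension",
    "shoulder_internal_external_rotation",
    "shoulder_adduction_abduction",
    "shoulder_total_flexion",
    "elbow_flexion_extension",
    "wrist_flexion_extension",
    "wrist_pronation_supination",
    "wrist_radial_ulnar_deviation",
]
_TRUNK_ANGLES = [
    "thorax_flexion_extension",
    "thorax_axial_rotation",
    "thorax_lateral_flexion_extension",
    "lumbar_flexion_extension",
    "lumbar_axial_rotation",
    "lumbar_lateral_flexion_extension",
]


@dataclass(frozen=True)
class Channel:
    index: int
    kind: str               # acceleration | orientation | joint_angle
    body_location: str      # e.g. "hand_left", "C7", "shoulder_right"
    axis: str               # axis / component / angle name
    side_tag: str           # moving_ue | contralateral_ue | trunk

    @property
    def name(self) -> str:
        prefix = {"acceleration": "accel", "orientation": "orient",
                  "joint_angle": "angle"}[self.kind]
        return f"{prefix}_{self.body_location}_{self.axis}"


@dataclass(frozen=True)
class ChannelSchema:
    moving_side: str
    entries: tuple[Channel, ...]

    def __post_init__(self):
        if len(self.entries) != N_CHANNELS:
            raise ValueError(f"schema must have {N_CHANNELS} entries")

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.entries]

    def indices(self, side_tag: str | None = None, kind: str | None = None) -> np.ndarray:
        sel = [c.index for c in self.entries
               if (side_tag is None or c.side_tag == side_tag)
               and (kind is None or c.kind == kind)]
        return np.asarray(sel, dtype=int)


@functools.lru_cache(maxsize=4)
def build_channel_schema(moving_side: str) -> ChannelSchema:
    """Canonical 76-channel schema tagged relative to the moving side.

    Channels of the moving side's hand/forearm/arm sensors and its
    shoulder/elbow/wrist angles are tagged ``moving_ue``; back sensors
    (C7/T10/sacrum) and thorax/lumbar angles ``trunk``; everything else
    ``contralateral_ue``.
    """
    if moving_side not in ("left", "right"):
        raise ValueError(f"moving_side must be 'left' or 'right', got {moving_side!r}")

    entries: list[Channel] = []
    i = 0

    def sensor_tag(part, side):
        if side is None:
            return "trunk"
        return "moving_ue" if side == moving_side else "contralateral_ue"

    for part, side in _SENSORS:
        loc = part if side is None else f"{part}_{side}"
        for ax in _AXES:
            entries.append(Channel(i, "acceleration", loc, ax, sensor_tag(part, side)))
            i += 1
    for part, side in _SENSORS:
        loc = part if side is None else f"{part}_{side}"
        for comp in _ORIENT:
            entries.append(Channel(i, "orientation", loc, comp, sensor_tag(part, side)))
            i += 1
    for side in ("left", "right"):
        tag = "moving_ue" if side == moving_side else "contralateral_ue"
        for ang in _UE_ANGLES:
            joint, axis = ang.split("_", 1)
            entries.append(Channel(i, "joint_angle", f"{joint}_{side}", axis, tag))
            i += 1
    for ang in _TRUNK_ANGLES:
        joint, axis = ang.split("_", 1)
        entries.append(Channel(i, "joint_angle", joint, axis, "trunk"))
        i += 1

    return ChannelSchema(moving_side=moving_side, entries=tuple(entries))


def impairment_category(score: int) -> str:
    """Map a 0-66 impairment score to {severe, moderate, mild, none}.

    Clinical bands: 0-25 severe, 26-52 moderate, 53-65 mild; 66 denotes
    normal performance and maps to 'none' (the bands describe impaired
    subjects, whose maximum is 65).
    """
    score = int(score)
    if not 0 <= score <= 66:
        raise ValueError(f"impairment score must be in [0, 66], got {score}")
    if score <= 25:
        return "severe"
    if score <= 52:
        return "moderate"
    if score <= 65:
        return "mild"
    return "none"


@dataclass(frozen=True)
class Segment:
    start_frame: int
    end_frame: int          # half-open [start, end)
    label: PrimitiveClass

    def __post_init__(self):
        if not (0 <= self.start_frame < self.end_frame):
            raise ValueError(f"invalid segment bounds [{self.start_frame}, {self.end_frame})")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass
class Recording:
    subject_id: str
    trial_id: str
    side: str
    data: np.ndarray                    # frames x 76
    segments: list[Segment]
    rate_hz: int = RATE_HZ

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    def frame_labels(self) -> list[PrimitiveClass]:
        labels: list[PrimitiveClass] = []
        for seg in self.segments:
            labels.extend([seg.label] * seg.n_frames)
        return labels

    def frame_label_indices(self) -> np.ndarray:
        out = np.empty(self.n_frames, dtype=np.int64)
        for seg in self.segments:
            out[seg.start_frame:seg.end_frame] = seg.label.index
        return out


@dataclass(frozen=True)
class SubjectMeta:
    subject_id: str
    group: str                          # healthy | impaired
    impairment_score: int = 66
    category: str = field(default="none")

    def __post_init__(self):
        if self.group not in ("healthy", "impaired"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.group == "healthy" and self.category != "none":
            raise ValueError("healthy subjects have category 'none'")
        if self.group == "impaired" and self.impairment_score > 65:
            raise ValueError("impaired subjects have score <= 65")


def validate_recording(rec: Recording, schema: ChannelSchema) -> list[str]:
    """Return a list of invariant violations (empty list = well-formed)."""
    v: list[str] = []
    if rec.data.ndim != 2 or rec.data.shape[1] != len(schema.entries):
        v.append(f"data has shape {rec.data.shape}, expected (*, {len(schema.entries)})")
    if rec.rate_hz != RATE_HZ:
        v.append(f"rate is {rec.rate_hz} Hz, expected {RATE_HZ}")
    if not rec.segments:
        v.append("no segments")
        return v
    if rec.segments[0].start_frame != 0:
        v.append(f"first segment starts at {rec.segments[0].start_frame}, expected 0")
    for a, b in zip(rec.segments, rec.segments[1:]):
        if b.start_frame < a.end_frame:
            v.append(f"segments overlap: [{a.start_frame},{a.end_frame}) and "
                     f"[{b.start_frame},{b.end_frame})")
        elif b.start_frame > a.end_frame:
            v.append(f"gap between [{a.start_frame},{a.end_frame}) and "
                     f"[{b.start_frame},{b.end_frame})")
    if rec.segments[-1].end_frame != rec.n_frames:
        v.append(f"last segment ends at {rec.segments[-1].end_frame}, "
                 f"recording has {rec.n_frames} frames")
    return v


# --------------------------------------------------------------------------
# serialization: CSV pair and HDF5 container; round-trip lossless for labels
# and exact (full-precision text) for data
# --------------------------------------------------------------------------

def write_csv(rec: Recording, schema: ChannelSchema, data_path, labels_path) -> None:
    df = pd.DataFrame(rec.data, columns=schema.names)
    df.to_csv(data_path, index=False, float_format="%.17g")
    lab = pd.DataFrame(
        {"start_frame": [s.start_frame for s in rec.segments],
         "end_frame": [s.end_frame for s in rec.segments],
         "label": [s.label.value for s in rec.segments]}
    )
    lab.to_csv(labels_path, index=False)


def read_csv(data_path, labels_path, subject_id="", trial_id="", side="right") -> Recording:
    data = pd.read_csv(data_path).to_numpy(dtype=np.float64)
    lab = pd.read_csv(labels_path)
    segments = [Segment(int(r.start_frame), int(r.end_frame), PrimitiveClass(r.label))
                for r in lab.itertuples()]
    return Recording(subject_id, trial_id, side, data, segments)


def write_hdf5(rec: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=rec.data)
        f.create_dataset("seg_bounds",
                         data=np.array([[s.start_frame, s.end_frame] for s in rec.segments],
                                       dtype=np.int64))
        f.create_dataset("seg_labels",
                         data=np.array([s.label.value for s in rec.segments], dtype="S16"))
        f.attrs["subject_id"] = rec.subject_id
        f.attrs["trial_id"] = rec.trial_id
        f.attrs["side"] = rec.side
        f.attrs["rate_hz"] = rec.rate_hz


def read_hdf5(path) -> Recording:
    with h5py.File(path, "r") as f:
        data = f["data"][...]
        bounds = f["seg_bounds"][...]
        labels = [lb.decode() for lb in f["seg_labels"][...]]
        segments = [Segment(int(a), int(b), PrimitiveClass(lb))
                    for (a, b), lb in zip(bounds, labels)]
        return Recording(str(f.attrs["subject_id"]), str(f.attrs["trial_id"]),
                         str(f.attrs["side"]), data, segments,
                         rate_hz=int(f.attrs["rate_hz"]))
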