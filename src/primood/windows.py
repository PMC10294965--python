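"""Windowing of labeled recordings into model examples.

Models consume 6-s windows (600 frames at 100 Hz) and predict primitives
only within the middle 4 s (frames [100, 500) of the window); the flanking
seconds provide temporal context.  With the default stride of 400 frames
the middle segments tile the recording, so no label is predicted twice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .schema import PrimitiveClass, Recording

__all__ = [
    "WindowExample", "make_windows", "collapse_to_sequence",
    "filter_min_run", "Standardizer",
    "WINDOW_FRAMES", "TARGET_LO", "TARGET_HI", "DEFAULT_STRIDE", "MIN_RUN_FRAMES",
]

log = logging.getLogger(__name__)

WINDOW_FRAMES = 600
TARGET_LO, TARGET_HI = 100, 500   # middle 4 s within the window
DEFAULT_STRIDE = 400
MIN_RUN_FRAMES = 10               # flicker suppression for model outputs only


@dataclass
class WindowExample:
    input: np.ndarray                       # 600 x 76
    target_frames: np.ndarray               # 400 int class indices
    target_sequence: list[PrimitiveClass]   # collapsed middle-segment labels
    subject_id: str
    trial_id: str
    start_frame: int

    def __post_init__(self):
        assert self.input.shape[0] == WINDOW_FRAMES
        assert self.target_frames.shape[0] == TARGET_HI - TARGET_LO


def collapse_to_sequence(frame_labels) -> list[PrimitiveClass]:
    """Merge maximal runs of identical consecutive labels into tokens."""
    labels = list(frame_labels)
    if not labels:
        raise ValueError("cannot collapse an empty label track")
    out = [labels[0]]
    for lb in labels[1:]:
        if lb != out[-1]:
            out.append(lb)
    return out


def filter_min_run(indices: np.ndarray, min_run: int = MIN_RUN_FRAMES) -> np.ndarray:
    """Absorb runs shorter than ``min_run`` frames into the preceding run.

    Applied to *model* per-frame outputs (never to ground truth) to
    suppress single-frame flicker; real primitives last >= 0.5 s.
    """
    idx = np.asarray(indices).copy()
    changed = True
    while changed:
        changed = False
        runs = _runs(idx)
        if len(runs) <= 1:
            break
        for k, (s, e, lab) in enumerate(runs):
            if e - s < min_run:
                neighbor = runs[k - 1][2] if k > 0 else runs[k + 1][2]
                idx[s:e] = neighbor
                changed = True
                break
    return idx


def _runs(idx: np.ndarray) -> list[tuple[int, int, int]]:
    bounds = np.flatnonzero(np.diff(idx)) + 1
    starts = np.concatenate(([0], bounds))
    ends = np.concatenate((bounds, [idx.size]))
    return [(int(s), int(e), int(idx[s])) for s, e in zip(starts, ends)]


def make_windows(rec: Recording, stride_frames: int = DEFAULT_STRIDE) -> list[WindowExample]:
    """Slice a recording into 600-frame windows at the given stride."""
    if rec.n_frames < WINDOW_FRAMES:
        log.warning("recording %s/%s has %d frames (< %d); no windows",
                    rec.subject_id, rec.trial_id, rec.n_frames, WINDOW_FRAMES)
        return []
    labels = rec.frame_label_indices()
    out = []
    for start in range(0, rec.n_frames - WINDOW_FRAMES + 1, stride_frames):
        tf = labels[start + TARGET_LO:start + TARGET_HI]
        seq = collapse_to_sequence([PrimitiveClass.from_index(i) for i in tf])
        out.append(WindowExample(rec.data[start:start + WINDOW_FRAMES], tf, seq,
                                 rec.subject_id, rec.trial_id, start))
    return out


class Standardizer:
    """Per-channel z-scoring fit on the training split only (no leakage)."""

    def __init__(self, mean: np.ndarray, sd: np.ndarray):
        self.mean = mean
        self.sd = np.where(sd < 1e-12, 1.0, sd)

    @classmethod
    def fit(cls, windows: list[WindowExample]) -> "Standardizer":
        stacked = np.concatenate([w.input for w in windows], axis=0)
        return cls(stacked.mean(axis=0), stacked.std(axis=0))

    def apply(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.sd
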