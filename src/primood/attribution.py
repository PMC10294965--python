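"""Gradient-based localization of model confidence.

For a predicted motion-based token, the absolute gradient of its winning
softmax probability with respect to the raw 600 x 76 input window says
which input entries the model's confidence depends on.  Summing |gradient|
over time and windows per channel and normalizing to sum 1 yields a
per-subject attribution profile; averaging profiles across subjects gives
the group profile.  On impaired subjects this asks whether confidence is
driven by the (paretic) moving upper extremity or by compensatory trunk
motion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .models import TrainedModel, WindowPrediction, input_gradient, predict_batch
from .schema import ChannelSchema
from .windows import WindowExample

__all__ = [
    "AttributionProfile", "confidence_gradient", "subject_profile",
    "group_profile", "attribution_for_subject",
]

log = logging.getLogger(__name__)


@dataclass
class AttributionProfile:
    subject_id: str
    contributions: np.ndarray          # 76 entries, >= 0, sum 1

    def __post_init__(self):
        assert self.contributions.shape == (76,)


def confidence_gradient(model: TrainedModel, window: WindowExample,
                        prediction: WindowPrediction, token_index: int) -> np.ndarray:
    """|d winning probability / d input| for one token: 600 x 76 magnitudes."""
    return input_gradient(model, window, prediction, token_index)


def subject_profile(subject_id: str, gradients: list[np.ndarray]) -> AttributionProfile:
    """Sum |gradient| over time and windows per channel, normalize to sum 1."""
    if not gradients:
        raise ValueError("need at least one gradient tensor")
    total = np.zeros(76)
    for g in gradients:
        total += np.abs(g).sum(axis=0)
    s = total.sum()
    if s <= 0:
        log.warning("all-zero gradients for %s; returning uniform profile", subject_id)
        return AttributionProfile(subject_id, np.full(76, 1.0 / 76))
    return AttributionProfile(subject_id, total / s)


def group_profile(profiles: list[AttributionProfile],
                  schema: ChannelSchema | None = None):
    """Mean of per-subject profiles (re-normalized), plus ranked channels."""
    if not profiles:
        raise ValueError("need at least one profile")
    mean = np.mean([p.contributions for p in profiles], axis=0)
    mean = mean / mean.sum()
    avg = AttributionProfile("__group__", mean)
    ranked = None
    if schema is not None:
        order = np.argsort(mean)[::-1]
        ranked = [(schema.entries[i].name, schema.entries[i].side_tag, float(mean[i]))
                  for i in order]
    return avg, ranked


def attribution_for_subject(
    model: TrainedModel,
    subject_id: str,
    windows: list[WindowExample],
    max_windows: int = 2,
    max_tokens_per_window: int = 3,
    seed: int = 0,
) -> AttributionProfile:
    """Profile a subject from a seeded sample of its windows.

    Gradients are taken for up to ``max_tokens_per_window`` motion-based
    predicted tokens per sampled window (confidence is only pooled for
    motion-based predictions).
    """
    rng = np.random.default_rng(seed)
    preds = predict_batch(model, windows)
    # confidence is only pooled for motion-based predictions, so sample
    # among windows that contain at least one
    eligible = [i for i, p in enumerate(preds)
                if any(t.label.is_motion_based for t in p.tokens)]
    if not eligible:
        log.warning("no motion-based tokens for %s; uniform profile", subject_id)
        return AttributionProfile(subject_id, np.full(76, 1.0 / 76))
    if len(eligible) > max_windows:
        eligible = sorted(rng.choice(eligible, size=max_windows, replace=False))
    grads = []
    for i in eligible:
        w, pred = windows[i], preds[i]
        motion = [k for k, t in enumerate(pred.tokens) if t.label.is_motion_based]
        for k in motion[:max_tokens_per_window]:
            grads.append(confidence_gradient(model, w, pred, k))
    if not grads:
        log.warning("no motion-based tokens for %s; uniform profile", subject_id)
        return AttributionProfile(subject_id, np.full(76, 1.0 / 76))
    return subject_profile(subject_id, grads)
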