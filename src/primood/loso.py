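"""Leave-one-subject-out training and testing protocol.

One model version is trained per healthy subject, with that subject held
out; the version is tested on its held-out subject only (in-distribution
benchmark).  Impaired subjects are never trained on; each is scored by a
seeded sample of K versions, pooling predictions across versions.  The
validation subset is re-sampled per iteration at max(1, round(remaining/7))
subjects — with 28 remaining healthy subjects that reproduces a 24/4
train/validation split.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .models import ModelConfig, TrainedModel, predict_batch, train_model
from .windows import WindowExample

__all__ = ["LOSORun", "run_loso", "validation_split", "predictions_frame"]

log = logging.getLogger(__name__)

PREDICTION_COLUMNS = [
    "subject_id", "group", "version_id", "trial_id", "window_start",
    "token_index", "predicted_label", "winning_probability",
    "ground_truth_sequence",
]


def validation_split(remaining_subjects, seed: int) -> tuple[list[str], list[str]]:
    """Subject-level train/validation split of the remaining healthy subjects."""
    ids = sorted(remaining_subjects)
    if len(ids) < 2:
        raise ValueError("need >= 2 remaining subjects to split")
    n_val = max(1, round(len(ids) / 7))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    val = sorted(ids[i] for i in perm[:n_val])
    train = sorted(ids[i] for i in perm[n_val:])
    return train, val


def _version_seed(global_seed: int, held_out: str) -> int:
    return (global_seed * 0x9E3779B1 + zlib.crc32(held_out.encode())) & 0x7FFFFFFF


@dataclass
class LOSORun:
    arch: str
    versions: dict[str, TrainedModel]
    predictions: pd.DataFrame
    splits: dict[str, dict[str, list[str]]]           # held-out -> {train, val}
    impaired_version_ids: list[str] = field(default_factory=list)


def _prediction_rows(preds, group: str, version_id: str, windows):
    rows = []
    for w, p in zip(windows, preds):
        gt = "|".join(t.value for t in w.target_sequence)
        for tok in p.tokens:
            rows.append((tok.subject_id, group, version_id, tok.trial_id,
                         tok.start_frame, tok.token_index, tok.label.value,
                         tok.winning_probability, gt))
    return rows


def predictions_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def run_loso(
    healthy_windows: dict[str, list[WindowExample]],
    impaired_windows: dict[str, list[WindowExample]],
    mconfig: ModelConfig,
    k_versions_for_impaired: int = 5,
    seed: int = 0,
    schema_hash: str = "",
) -> LOSORun:
    """Execute the full protocol for one architecture."""
    healthy_ids = sorted(healthy_windows)
    if len(healthy_ids) < 6:
        raise ValueError("need >= 6 healthy subjects for train+validation+test")

    versions: dict[str, TrainedModel] = {}
    splits: dict[str, dict[str, list[str]]] = {}
    rows: list[tuple] = []
    for held_out in healthy_ids:
        vseed = _version_seed(seed, held_out)
        remaining = [s for s in healthy_ids if s != held_out]
        train_ids, val_ids = validation_split(remaining, vseed)
        assert not ({held_out} & set(train_ids)) and not ({held_out} & set(val_ids))
        assert not (set(train_ids) & set(val_ids)), "train/validation leakage"
        splits[held_out] = {"train": train_ids, "val": val_ids}
        train = [w for s in train_ids for w in healthy_windows[s]]
        val = [w for s in val_ids for w in healthy_windows[s]]
        cfg = replace(mconfig, seed=vseed)
        log.info("[%s] training version %s (train n=%d windows, val n=%d)",
                 mconfig.arch, held_out, len(train), len(val))
        model = train_model(cfg, train, val, schema_hash=schema_hash)
        versions[held_out] = model
        test = healthy_windows[held_out]
        rows.extend(_prediction_rows(predict_batch(model, test), "healthy",
                                     held_out, test))

    k = min(k_versions_for_impaired, len(healthy_ids))
    rng = np.random.default_rng(seed)
    chosen = sorted(rng.choice(healthy_ids, size=k, replace=False).tolist())
    for sid in sorted(impaired_windows):
        for vid in chosen:
            preds = predict_batch(versions[vid], impaired_windows[sid])
            rows.extend(_prediction_rows(preds, "impaired", vid,
                                         impaired_windows[sid]))
    return LOSORun(mconfig.arch, versions, predictions_frame(rows), splits, chosen)
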