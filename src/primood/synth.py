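"""Synthetic tabletop-task generator: healthy and impaired subjects.

Emulates the semi-structured object-moving task on a 9-target array: per
trial, the subject cycles through the eight outer targets with a
reach -> transport -> (occasional stabilization) -> reposition grammar,
interleaved with idles.  Motion-based primitives carry minimum-jerk
acceleration profiles on the moving upper extremity (UE), class-distinct
joint-angle and orientation signatures, and last 0.5-1 s each.

A scalar impairment parameter theta in [0, 1] distorts the moving side:
amplitude attenuation (0.7*theta), slowing (durations x (1+theta)),
band-limited 4-8 Hz kinetic tremor (0.5*theta of the healthy peak), and
trunk compensation (thorax/lumbar excursions with gain theta).  theta = 0
reproduces the healthy generator exactly.  theta maps to a clinical-style
0-66 score via ``fma_like_score``.

Per-subject idiosyncrasy: log-normal channel gains and a tempo factor,
sampled once per subject, so that leave-one-subject-out evaluation faces
genuine between-subject variation.  All randomness flows through numpy
generators seeded from (config seed, subject id); identical inputs
reproduce bit-identical recordings.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    MOTION_BASED, PrimitiveClass, Recording, Segment, SubjectMeta,
    build_channel_schema, impairment_category, N_CHANNELS, RATE_HZ,
)

__all__ = [
    "ImpairmentModel", "SynthConfig", "fma_like_score", "primitive_kinematics",
    "generate_subject", "simulate_dataset", "write_dataset",
]

# healthy kinematic scale constants
PEAK_ACCEL = 3.0            # m/s^2, hand-sensor peak during a reach
_SENSOR_GAIN = {"hand": 1.0, "forearm": 0.7, "arm": 0.45}
_TREMOR_BAND = (4.0, 8.0)   # Hz


@dataclass(frozen=True)
class ImpairmentModel:
    """Deterministic mapping from scalar impairment theta to distortions."""

    theta: float
    amplitude_attenuation: float
    slowing_factor: float
    tremor_amplitude: float
    trunk_compensation_gain: float

    @classmethod
    def from_theta(cls, theta: float) -> "ImpairmentModel":
        if not 0.0 <= theta <= 1.0:
            raise ValueError(f"theta must be in [0, 1], got {theta}")
        return cls(
            theta=theta,
            amplitude_attenuation=0.7 * theta,
            slowing_factor=1.0 + theta,
            tremor_amplitude=0.5 * theta * PEAK_ACCEL,
            trunk_compensation_gain=theta,
        )


@dataclass(frozen=True)
class SynthConfig:
    n_healthy: int = 8
    n_impaired: int = 9
    thetas: tuple[float, ...] = (0.2, 0.2, 0.2, 0.5, 0.5, 0.5, 0.8, 0.8, 0.8)
    trials_per_side: int = 5
    n_outer_targets: int = 8
    rate_hz: int = RATE_HZ
    duration_range_s: tuple[float, float] = (0.5, 1.0)
    subject_variability: float = 0.15
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.duration_range_s
        if not (0.0 < lo < hi <= 5.0):
            raise ValueError("duration_range_s must satisfy 0 < lo < hi <= 5")
        if self.n_healthy <= 0 or self.trials_per_side <= 0 or self.n_outer_targets <= 0:
            raise ValueError("counts must be positive")
        if len(self.thetas) != self.n_impaired:
            raise ValueError("need one theta per impaired subject")
        if any(not 0.0 <= t <= 1.0 for t in self.thetas):
            raise ValueError("thetas must lie in [0, 1]")


def fma_like_score(theta: float) -> int:
    """Map impairment theta to a 0-66 clinical-style score (65 = ceiling)."""
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"theta must be in [0, 1], got {theta}")
    return int(round(65.0 * (1.0 - theta)))


def subject_seed(config_seed: int, subject_id: str) -> int:
    """Stable per-subject seed (crc32 keeps it platform-independent)."""
    return (config_seed * 0x9E3779B1 + zlib.crc32(subject_id.encode())) & 0x7FFFFFFF


# --------------------------------------------------------------------- shapes

def _minjerk_accel(n: int) -> np.ndarray:
    """Minimum-jerk acceleration profile, unit peak magnitude."""
    tau = np.linspace(0.0, 1.0, n)
    a = 60.0 * tau - 180.0 * tau ** 2 + 120.0 * tau ** 3
    return a / np.abs(a).max()


def _bump(n: int) -> np.ndarray:
    """Smooth excursion that starts and ends at zero, unit peak."""
    tau = np.linspace(0.0, 1.0, n)
    return np.sin(np.pi * tau) ** 2


def _sway(n: int, rng: np.random.Generator, amp_lo: float, amp_hi: float,
          n_channels: int) -> np.ndarray:
    """Slow physiological wander (postural sway, micro-adjustments).

    One low-frequency sinusoid per channel with random amplitude, frequency
    (0.05-0.4 Hz) and phase.  Present in every subject; it keeps healthy
    'quiet' channels from being unrealistically constant, so impairment
    effects stay below moving-UE signal magnitude relative to normal
    variability.
    """
    t = np.arange(n)[:, None] / RATE_HZ
    amp = rng.uniform(amp_lo, amp_hi, size=n_channels)
    freq = rng.uniform(0.05, 0.4, size=n_channels)
    phase = rng.uniform(0.0, 2.0 * np.pi, size=n_channels)
    return amp * np.sin(2.0 * np.pi * freq * t + phase)


# class-specific signature scales (moving-UE channels)
#   accel_sign: outward (+1) vs return (-1); orient: hand-orientation excursion;
#   elbow/shoulder: joint-angle bump amplitudes in degrees
_SIGNATURES = {
    PrimitiveClass.REACH: dict(accel=1.0, sign=+1.0, hand_orient=0.15,
                               elbow=-30.0, shoulder=+22.0, total_flexion=+12.0),
    PrimitiveClass.TRANSPORT: dict(accel=0.9, sign=+1.0, hand_orient=0.55,
                                   elbow=-15.0, shoulder=+12.0, total_flexion=+30.0),
    PrimitiveClass.REPOSITION: dict(accel=0.85, sign=-1.0, hand_orient=0.15,
                                    elbow=+24.0, shoulder=-18.0, total_flexion=-10.0),
}


def primitive_kinematics(
    primitive: PrimitiveClass,
    duration_s: float,
    rng: np.random.Generator,
    impairment: ImpairmentModel | None = None,
    moving_side: str = "right",
    target_angle: float = 0.0,
    channel_gain: np.ndarray | None = None,
    noise_sd: float = 0.05,
) -> np.ndarray:
    """Generate one primitive's frames x 76 block.

    ``target_angle`` orients the planar acceleration direction (the 8 outer
    targets sit at multiples of 45 degrees).  ``channel_gain`` is the
    per-subject multiplicative idiosyncrasy on the deterministic motion
    component (defaults to 1).
    """
    if duration_s <= 0:
        raise ValueError(f"duration must be positive, got {duration_s}")
    imp = impairment or ImpairmentModel.from_theta(0.0)
    n = max(2, int(round(duration_s * RATE_HZ)))
    schema = build_channel_schema(moving_side)
    gain = np.ones(N_CHANNELS) if channel_gain is None else channel_gain
    att = 1.0 - imp.amplitude_attenuation

    block = rng.normal(0.0, noise_sd, size=(n, N_CHANNELS))
    # joint-angle sensor noise is small (degrees)
    angle_idx = schema.indices(kind="joint_angle")
    block[:, angle_idx] = rng.normal(0.0, 0.1, size=(n, angle_idx.size))
    # physiological baseline wander on top of sensor noise; trunk angles
    # stay under ~1 degree of excursion within a primitive
    trunk_angle_idx = schema.indices(side_tag="trunk", kind="joint_angle")
    limb_angle_idx = np.setdiff1d(angle_idx, trunk_angle_idx)
    block[:, trunk_angle_idx] += _sway(n, rng, 0.1, 0.45, trunk_angle_idx.size)
    block[:, limb_angle_idx] += _sway(n, rng, 0.2, 1.0, limb_angle_idx.size)
    accel_idx = schema.indices(kind="acceleration")
    # amplitude below noise_sd: an idle block's per-channel mean stays
    # under the sensor-noise scale
    block[:, accel_idx] += _sway(n, rng, 0.005, 0.04, accel_idx.size)
    orient_idx = schema.indices(kind="orientation")
    block[:, orient_idx] += _sway(n, rng, 0.01, 0.05, orient_idx.size)
    motion = np.zeros((n, N_CHANNELS))

    if primitive in MOTION_BASED:
        sig = _SIGNATURES[primitive]
        prof = _minjerk_accel(n)
        bump = _bump(n)
        direction = np.array([np.cos(target_angle), np.sin(target_angle), 0.35])
        direction /= np.linalg.norm(direction)
        for part, g in _SENSOR_GAIN.items():
            for c in schema.entries:
                if c.kind == "acceleration" and c.side_tag == "moving_ue" \
                        and c.body_location == f"{part}_{moving_side}":
                    ax = "xyz".index(c.axis)
                    motion[:, c.index] += (sig["sign"] * sig["accel"] * PEAK_ACCEL
                                           * g * direction[ax] * prof)
        for c in schema.entries:
            if c.side_tag != "moving_ue":
                continue
            if c.kind == "orientation":
                amp = sig["hand_orient"] if c.body_location.startswith("hand") else 0.08
                comp = 1 + "123".index(c.axis[1])
                motion[:, c.index] += sig["sign"] * amp * bump * np.sin(0.9 * comp + target_angle)
            elif c.kind == "joint_angle":
                if c.body_location.startswith("elbow"):
                    motion[:, c.index] += sig["elbow"] * bump
                elif c.body_location.startswith("shoulder"):
                    if c.axis == "total_flexion":
                        motion[:, c.index] += sig["total_flexion"] * bump
                    elif c.axis == "flexion_extension":
                        motion[:, c.index] += sig["shoulder"] * bump
                    elif c.axis == "adduction_abduction":
                        motion[:, c.index] += 0.4 * sig["shoulder"] * bump * np.sin(target_angle)
                elif c.body_location.startswith("wrist"):
                    motion[:, c.index] += 5.0 * sig["sign"] * bump

        # impairment: attenuate, add kinetic tremor, trunk compensation
        moving_idx = schema.indices(side_tag="moving_ue")
        motion[:, moving_idx] *= att
        if imp.tremor_amplitude > 0:
            t = np.arange(n) / RATE_HZ
            trem = np.zeros(n)
            for _ in range(3):
                f = rng.uniform(*_TREMOR_BAND)
                phase = rng.uniform(0, 2 * np.pi)
                trem += np.sin(2 * np.pi * f * t + phase)
            trem *= imp.tremor_amplitude / 3.0
            scale = {"acceleration": 1.0, "orientation": 0.05, "joint_angle": 0.6}
            for c in schema.entries:
                if c.side_tag == "moving_ue":
                    motion[:, c.index] += trem * scale[c.kind] * rng.uniform(0.5, 1.0)
        if imp.trunk_compensation_gain > 0:
            g = imp.trunk_compensation_gain
            bump_c = _bump(n)
            for c in schema.entries:
                if c.side_tag != "trunk":
                    continue
                if c.kind == "joint_angle" and c.axis == "flexion_extension":
                    motion[:, c.index] += g * 2.5 * bump_c
                elif c.kind == "acceleration" and c.axis == "x":
                    motion[:, c.index] += g * 0.15 * _minjerk_accel(n)
    elif primitive is PrimitiveClass.STABILIZATION:
        moving_idx = schema.indices(side_tag="moving_ue", kind="acceleration")
        motion[:, moving_idx] += rng.normal(0.0, 3.0 * noise_sd, size=(n, moving_idx.size))
    else:  # idle: strictly quieter than stabilization
        moving_idx = schema.indices(side_tag="moving_ue", kind="acceleration")
        motion[:, moving_idx] += rng.normal(0.0, 0.5 * noise_sd, size=(n, moving_idx.size))

    block += motion * gain
    return block


def _sample_duration(rng, tempo: float, imp: ImpairmentModel,
                     duration_range: tuple[float, float]) -> float:
    """Motion-primitive duration: within [lo, hi]*slowing by construction."""
    lo, hi = duration_range
    base = float(np.clip(rng.uniform(lo, hi) * tempo, lo, hi))
    return base * imp.slowing_factor


def generate_subject(
    config: SynthConfig,
    meta: SubjectMeta,
    theta: float,
    seed: int | None = None,
) -> list[Recording]:
    """Generate all trial recordings for one subject.

    Healthy subjects perform ``trials_per_side`` trials with each UE
    (2 x trials recordings); impaired subjects use the paretic side only.
    """
    if meta.group == "healthy" and theta != 0.0:
        raise ValueError("healthy subjects must have theta = 0")
    if meta.group == "impaired" and not 0.0 <= theta <= 1.0:
        raise ValueError("impaired theta must be in [0, 1]")
    imp = ImpairmentModel.from_theta(theta)
    sseed = subject_seed(config.seed, meta.subject_id) if seed is None else seed
    rng = np.random.default_rng(sseed)

    # subject idiosyncrasy: channel gains and tempo, drawn once
    gains = np.exp(rng.normal(0.0, config.subject_variability, size=N_CHANNELS))
    tempo = float(np.exp(rng.normal(0.0, 0.05)))

    if meta.group == "healthy":
        sides = ["left"] * config.trials_per_side + ["right"] * config.trials_per_side
    else:
        paretic = "left" if rng.random() < 0.5 else "right"
        sides = [paretic] * config.trials_per_side

    recordings: list[Recording] = []
    side_counter: dict[str, int] = {}
    for side in sides:
        side_counter[side] = side_counter.get(side, 0) + 1
        trial_id = f"{side[0].upper()}{side_counter[side]}"
        blocks: list[np.ndarray] = []
        segments: list[Segment] = []
        frame = 0

        def emit(prim: PrimitiveClass, dur: float, angle: float = 0.0):
            nonlocal frame
            block = primitive_kinematics(
                prim, dur, rng, imp, moving_side=side, target_angle=angle,
                channel_gain=gains, noise_sd=config.noise_sd)
            blocks.append(block)
            segments.append(Segment(frame, frame + block.shape[0], prim))
            frame += block.shape[0]

        emit(PrimitiveClass.IDLE, rng.uniform(0.4, 0.9))
        for k in range(config.n_outer_targets):
            angle = 2.0 * np.pi * k / config.n_outer_targets
            emit(PrimitiveClass.REACH, _sample_duration(rng, tempo, imp, config.duration_range_s), angle)
            emit(PrimitiveClass.TRANSPORT, _sample_duration(rng, tempo, imp, config.duration_range_s), angle)
            if rng.random() < 0.25:
                emit(PrimitiveClass.STABILIZATION, rng.uniform(0.5, 1.0))
            emit(PrimitiveClass.REPOSITION, _sample_duration(rng, tempo, imp, config.duration_range_s), angle)
            emit(PrimitiveClass.IDLE, rng.uniform(0.4, 0.9))

        data = np.concatenate(blocks, axis=0)
        recordings.append(Recording(meta.subject_id, trial_id, side, data, segments))
    return recordings


def simulate_dataset(config: SynthConfig) -> tuple[list[SubjectMeta], dict[str, list[Recording]], dict[str, float]]:
    """Generate the full cohort: (metas, recordings by subject, theta by subject)."""
    metas: list[SubjectMeta] = []
    recs: dict[str, list[Recording]] = {}
    thetas: dict[str, float] = {}
    for i in range(config.n_healthy):
        sid = f"H{i + 1:02d}"
        meta = SubjectMeta(sid, "healthy", 66, "none")
        metas.append(meta)
        thetas[sid] = 0.0
        recs[sid] = generate_subject(config, meta, 0.0)
    for i, theta in enumerate(config.thetas):
        sid = f"S{i + 1:02d}"
        score = fma_like_score(theta)
        meta = SubjectMeta(sid, "impaired", score, impairment_category(score))
        metas.append(meta)
        thetas[sid] = theta
        recs[sid] = generate_subject(config, meta, theta)
    return metas, recs, thetas


def write_dataset(config: SynthConfig, workdir) -> Path:
    """Materialize the cohort: one directory per subject plus subjects.csv."""
    from .schema import write_hdf5

    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    metas, recs, thetas = simulate_dataset(config)
    rows = []
    for meta in metas:
        sdir = workdir / meta.subject_id
        sdir.mkdir(exist_ok=True)
        sides = set()
        for rec in recs[meta.subject_id]:
            sides.add(rec.side)
            write_hdf5(rec, sdir / f"{rec.trial_id}.h5")
        rows.append(dict(subject_id=meta.subject_id, group=meta.group,
                         theta=thetas[meta.subject_id],
                         impairment_score=meta.impairment_score,
                         category=meta.category, side="|".join(sorted(sides))))
    manifest = workdir / "subjects.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
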