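"""Seeded generator of depth-camera-style skeleton streams.

Emulates a 20-joint skeleton stream at 30 Hz performing a "wiping" exercise:
the trunk and legs stand still while each wrist traces a Lissajous path in
the frontal plane (mediolateral × inferior–superior displacement relative to
the trunk), the elbow following by two-link inverse kinematics with fixed
segment lengths.  Lissajous paths are used instead of recorded-data playback
because closed forms exist for their length, area and principal axes, so the
downstream feature pipeline can be checked against analytic oracles.

The sensor noise model is i.i.d. isotropic Gaussian jitter per joint per
frame (default σ = 5 mm) plus an optional extra depth-axis term — the
simplest model sufficient for pipeline testing; it has no temporal or
anatomical correlation and is documented as non-physiological.

Group-level differences (healthy adults / elderly / stroke-like) are encoded
purely as a speed multiplier (the same path traversed slower over a
proportionally longer duration) with seeded between-subject variability; no
pathological synergy is modelled.  The default speed ordering
adults > elderly > stroke mirrors the clinically expected slowing.

All randomness flows from a single integer seed; identical seeds yield
identical streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import RecipeError
from .io import KINECT20_JOINTS, SkeletonSequence

__all__ = [
    "MotionRecipe",
    "BASE_POSE",
    "DEFAULT_GROUP_SCALES",
    "DEFAULT_GROUP_SIZES",
    "generate_wipe_sequence",
    "generate_cohort",
    "generate_calibration_poses",
]

UPPER_ARM = 0.30   # m, shoulder→elbow
FOREARM = 0.25     # m, elbow→wrist
HAND = 0.08        # m, wrist→hand

#: Neutral standing skeleton, metres.  Global frame: X = subject's
#: left→right, Y = up, Z = anterior (toward the camera).
BASE_POSE: dict[str, np.ndarray] = {
    "hip_center": np.array([0.0, 0.95, 0.0]),
    "spine": np.array([0.0, 1.10, 0.0]),
    "shoulder_center": np.array([0.0, 1.40, 0.0]),
    "head": np.array([0.0, 1.62, 0.0]),
    "shoulder_left": np.array([-0.18, 1.38, 0.0]),
    "shoulder_right": np.array([0.18, 1.38, 0.0]),
    "hip_left": np.array([-0.10, 0.92, 0.0]),
    "hip_right": np.array([0.10, 0.92, 0.0]),
    "knee_left": np.array([-0.10, 0.50, 0.0]),
    "knee_right": np.array([0.10, 0.50, 0.0]),
    "ankle_left": np.array([-0.10, 0.08, 0.0]),
    "ankle_right": np.array([0.10, 0.08, 0.0]),
    "foot_left": np.array([-0.10, 0.02, 0.12]),
    "foot_right": np.array([0.10, 0.02, 0.12]),
}

#: Group speed multipliers; ordering motivated by the clinically observed
#: slowing of reaching speed with age and after stroke.
DEFAULT_GROUP_SCALES: dict[str, float] = {"adults": 1.0, "elderly": 0.57, "stroke": 0.43}
DEFAULT_GROUP_SIZES: dict[str, int] = {"adults": 16, "elderly": 17, "stroke": 10}


@dataclass(frozen=True)
class MotionRecipe:
    """Parameters of one synthetic wiping trial.

    ``group_scale`` is a pure speed multiplier: the same wrist path is
    traversed at ``group_scale`` times the speed over a proportionally
    longer duration, so path geometry is unchanged.
    """

    duration: float = 60.0        # s of motion at group_scale = 1
    frequency: float = 30.0       # Hz
    amp_x: float = 0.16           # m, mediolateral wrist amplitude
    amp_y: float = 0.12           # m, inferior–superior wrist amplitude
    f1: float = 0.25              # Hz, mediolateral path frequency
    f2: float = 0.20              # Hz, inferior–superior path frequency
    phase: float = np.pi / 2      # rad, phase of the y component
    jitter: float = 0.005         # m, isotropic per-joint sensor noise σ
    depth_noise: float = 0.002    # m, extra z-axis noise σ
    group_scale: float = 1.0      # speed multiplier (> 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.jitter < 0 or self.depth_noise < 0:
            raise RecipeError("noise sigmas must be >= 0")
        if self.group_scale <= 0:
            raise RecipeError("group_scale must be > 0")
        if self.duration * self.frequency < 4:
            raise RecipeError("duration × frequency must be >= 4 samples")


def _two_link_ik(shoulder: np.ndarray, wrist: np.ndarray, side_sign: float,
                 l1: float = UPPER_ARM, l2: float = FOREARM) -> np.ndarray:
    """Elbow position for a two-link arm, deterministic out-and-down bend."""
    v = wrist - shoulder
    d = np.linalg.norm(v, axis=-1)
    if np.any(d >= l1 + l2 - 1e-9) or np.any(d <= abs(l1 - l2) + 1e-9):
        raise RecipeError(
            f"wrist target unreachable for arm lengths {l1}+{l2} "
            f"(distance range {d.min():.3f}–{d.max():.3f} m)"
        )
    u = v / d[..., None]
    a = (l1**2 - l2**2 + d**2) / (2.0 * d)
    h = np.sqrt(np.maximum(l1**2 - a**2, 0.0))
    hint = np.array([side_sign, -0.5, 0.0])
    perp = hint - (u @ hint)[..., None] * u
    pn = np.linalg.norm(perp, axis=-1)
    fallback = np.array([0.0, 0.0, -1.0])
    perp2 = fallback - (u @ fallback)[..., None] * u
    small = pn < 1e-9
    perp = np.where(small[..., None], perp2, perp)
    pn = np.linalg.norm(perp, axis=-1)
    perp /= pn[..., None]
    return shoulder + a[..., None] * u + h[..., None] * perp


def _assemble(frames_by_joint: Mapping[str, np.ndarray], n: int,
              frequency: float, rng: np.random.Generator,
              jitter: float, depth_noise: float,
              subject_id: str, meta: dict) -> SkeletonSequence:
    frames = np.empty((n, len(KINECT20_JOINTS), 3))
    for k, joint in enumerate(KINECT20_JOINTS):
        frames[:, k, :] = frames_by_joint[joint]
    if jitter > 0:
        frames = frames + rng.normal(0.0, jitter, size=frames.shape)
    if depth_noise > 0:
        frames[:, :, 2] += rng.normal(0.0, depth_noise, size=frames.shape[:2])
    return SkeletonSequence(frequency=frequency, joints=list(KINECT20_JOINTS),
                            frames=frames, subject_id=subject_id, meta=meta)


def _wrist_rest_offset() -> np.ndarray:
    # in front of the shoulder, slightly below: comfortably inside the
    # two-link workspace for every point of the default Lissajous path
    return np.array([0.0, -0.10, 0.33])


def generate_wipe_sequence(recipe: MotionRecipe, subject_id: str = "synthetic") -> SkeletonSequence:
    """One wiping trial as a 20-joint skeleton stream.

    Trunk and leg joints are static at the base pose; both wrists follow
    mirrored Lissajous paths in the frontal plane, elbows placed by two-link
    inverse kinematics; i.i.d. Gaussian jitter is added to every joint.
    Deterministic under ``recipe.seed``.
    """
    s = recipe.group_scale
    n = int(round(recipe.duration / s * recipe.frequency)) + 1
    t = np.arange(n) / recipe.frequency
    rng = np.random.default_rng(recipe.seed)

    dx = recipe.amp_x * np.sin(2.0 * np.pi * recipe.f1 * s * t)
    dy = recipe.amp_y * np.sin(2.0 * np.pi * recipe.f2 * s * t + recipe.phase)
    disp = np.column_stack([dx, dy, np.zeros(n)])

    frames_by_joint: dict[str, np.ndarray] = {
        j: np.broadcast_to(p, (n, 3)).copy() for j, p in BASE_POSE.items()
    }
    for side, sign in (("left", -1.0), ("right", 1.0)):
        shoulder = BASE_POSE[f"shoulder_{side}"]
        wrist = shoulder + _wrist_rest_offset() + disp * np.array([sign, 1.0, 1.0])
        elbow = _two_link_ik(np.broadcast_to(shoulder, (n, 3)), wrist, sign)
        fore = wrist - elbow
        hand = wrist + HAND * fore / np.linalg.norm(fore, axis=1)[:, None]
        frames_by_joint[f"wrist_{side}"] = wrist
        frames_by_joint[f"elbow_{side}"] = elbow
        frames_by_joint[f"hand_{side}"] = hand

    meta = {"recipe": {k: float(v) if isinstance(v, (int, float)) else v
                       for k, v in vars(recipe).items()},
            "task": "wipe"}
    return _assemble(frames_by_joint, n, recipe.frequency, rng,
                     recipe.jitter, recipe.depth_noise, subject_id, meta)


def generate_cohort(
    n_per_group: Mapping[str, int] | int | None = None,
    seed: int = 0,
    base_recipe: MotionRecipe | None = None,
    group_scales: Mapping[str, float] | None = None,
    subject_speed_cv: float = 0.15,
    subject_amp_cv: float = 0.10,
) -> list[tuple[str, SkeletonSequence]]:
    """Seeded three-group cohort of wiping trials with subject variability.

    Per subject, the group speed multiplier and the path amplitudes are
    perturbed log-normally (CVs ``subject_speed_cv``/``subject_amp_cv``), so
    group speed means follow the configured ordering while subjects differ.
    Returns ``(group_label, sequence)`` pairs.
    """
    sizes = dict(DEFAULT_GROUP_SIZES) if n_per_group is None else (
        {g: int(n_per_group) for g in DEFAULT_GROUP_SCALES}
        if isinstance(n_per_group, int) else dict(n_per_group)
    )
    scales = dict(group_scales) if group_scales is not None else dict(DEFAULT_GROUP_SCALES)
    for g, n in sizes.items():
        if n < 2:
            raise RecipeError(f"group {g!r} needs n_per_group >= 2, got {n}")
    base = base_recipe if base_recipe is not None else MotionRecipe()
    master = np.random.default_rng(seed)
    out: list[tuple[str, SkeletonSequence]] = []
    for g in sorted(sizes):
        for i in range(sizes[g]):
            speed = scales[g] * np.exp(master.normal(0.0, subject_speed_cv))
            # amplitude factor clipped so every subject's path stays inside
            # the two-link arm workspace
            amp = float(np.clip(np.exp(master.normal(0.0, subject_amp_cv)), 0.7, 1.4))
            sub_seed = int(master.integers(0, 2**31 - 1))
            recipe = replace(base, group_scale=float(speed),
                             amp_x=base.amp_x * amp, amp_y=base.amp_y * amp,
                             seed=sub_seed)
            out.append((g, generate_wipe_sequence(recipe, subject_id=f"{g}_{i:02d}")))
    return out


_POSES: dict[str, np.ndarray] = {
    # unit direction of the straight arm from the shoulder, per pose
    "t_pose": np.array([1.0, 0.0, 0.0]),
    "wide_pose": np.array([np.sqrt(0.5), np.sqrt(0.5), 0.0]),
    "upright_pose": np.array([0.15, -0.98869, 0.0]),  # arms at the sides
}


def generate_calibration_poses(
    seed: int = 0, jitter: float = 0.005, frequency: float = 30.0,
    pose_duration: float = 3.0,
) -> list[SkeletonSequence]:
    """Three static calibration-pose streams (3 s each at 30 Hz by default).

    Arms are held straight along a pose-specific direction (T, wide,
    upright) with exact segment lengths, so the true lengths — recorded in
    each sequence's ``meta["true_lengths"]`` — are recoverable by
    calibration; configurable Gaussian jitter is added on top.
    """
    rng = np.random.default_rng(seed)
    n = int(round(pose_duration * frequency))
    true_lengths = {
        "shoulder_center|spine": float(np.linalg.norm(
            BASE_POSE["shoulder_center"] - BASE_POSE["spine"])),
        "shoulder_left|shoulder_center": float(np.linalg.norm(
            BASE_POSE["shoulder_left"] - BASE_POSE["shoulder_center"])),
        "shoulder_right|shoulder_center": float(np.linalg.norm(
            BASE_POSE["shoulder_right"] - BASE_POSE["shoulder_center"])),
        "elbow_left|shoulder_left": UPPER_ARM,
        "elbow_right|shoulder_right": UPPER_ARM,
        "wrist_left|elbow_left": FOREARM,
        "wrist_right|elbow_right": FOREARM,
    }
    out: list[SkeletonSequence] = []
    for pose_name, direction in _POSES.items():
        frames_by_joint = {
            j: np.broadcast_to(p, (n, 3)).copy() for j, p in BASE_POSE.items()
        }
        for side, sign in (("left", -1.0), ("right", 1.0)):
            d = direction * np.array([sign, 1.0, 1.0])
            d = d / np.linalg.norm(d)
            shoulder = BASE_POSE[f"shoulder_{side}"]
            elbow = shoulder + UPPER_ARM * d
            wrist = elbow + FOREARM * d
            hand = wrist + HAND * d
            for j, p in (("elbow", elbow), ("wrist", wrist), ("hand", hand)):
                frames_by_joint[f"{j}_{side}"] = np.broadcast_to(p, (n, 3)).copy()
        meta = {"pose": pose_name, "true_lengths": dict(true_lengths)}
        out.append(_assemble(frames_by_joint, n, frequency, rng, jitter, 0.0,
                             subject_id=f"calibration_{pose_name}", meta=meta))
    return out
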