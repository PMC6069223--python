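"""Reading, validation, writing and resampling of skeleton streams.

A skeleton stream is a fixed-frequency sequence of frames, each frame holding
one 3D position (metres, global coordinate system) per labelled joint.  Three
text dialects are supported:

``csv-long``
    columns ``frame,time_s,joint,x,y,z`` (header mandatory, UTF-8, "." decimal)
``csv-wide``
    columns ``frame,time_s`` followed by ``x_<joint>,y_<joint>,z_<joint>``
    triplets
``json``
    ``{"frequency": .., "joints": [..], "frames": [[[x,y,z], ..], ..]}``

Positions are stored in metres internally; readers accept a ``unit`` of
``m``/``cm``/``mm`` and convert on ingest.  Missing samples are written as
empty fields or the literal ``NaN``; :func:`fill_gaps` interpolates short
runs and rejects long ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataQualityError, FormatError, ParseError

__all__ = [
    "KINECT20_JOINTS",
    "SkeletonSequence",
    "ReferenceTable",
    "read_sequence",
    "write_sequence",
    "fill_gaps",
    "resample",
    "smooth",
    "read_reference_table",
    "write_reference_table",
]

#: Canonical Kinect v1 20-joint vocabulary (data, not code: a 25-joint set for
#: the second sensor generation is a drop-in replacement).
KINECT20_JOINTS = (
    "hip_center", "spine", "shoulder_center", "head",
    "shoulder_left", "elbow_left", "wrist_left", "hand_left",
    "shoulder_right", "elbow_right", "wrist_right", "hand_right",
    "hip_left", "knee_left", "ankle_left", "foot_left",
    "hip_right", "knee_right", "ankle_right", "foot_right",
)

_UNIT_TO_M = {"m": 1.0, "cm": 0.01, "mm": 0.001}


def _canonical_alias(label: str) -> str:
    return label.replace("_", "").replace("-", "").replace(" ", "").lower()


_ALIAS_MAP = {_canonical_alias(j): j for j in KINECT20_JOINTS}
# Kinect SDK spellings such as "HipCenter", "ShoulderLeft" normalise via the
# same alias rule, plus a few common inversions ("LeftShoulder").
for _j in KINECT20_JOINTS:
    _part, _side = _j.rsplit("_", 1) if _j.endswith(("left", "right")) else (_j, "")
    if _side:
        _ALIAS_MAP[_canonical_alias(_side + _part)] = _j


def normalize_joint_label(label: str) -> str:
    """Map a joint label to the canonical vocabulary when recognizable.

    Unknown labels are returned unchanged with a warning.
    """
    key = _canonical_alias(str(label))
    if key in _ALIAS_MAP:
        return _ALIAS_MAP[key]
    warnings.warn(f"unknown joint label kept as-is: {label!r}", stacklevel=3)
    return str(label)


@dataclass
class SkeletonSequence:
    """Time-ordered frames of labelled 3D joint positions at fixed frequency.

    Attributes
    ----------
    frequency : float
        Sampling rate in Hz; frame ``i`` is at time ``i / frequency``.
    joints : list of str
        Ordered joint labels, length J.
    frames : ndarray, shape (N, J, 3)
        Positions in metres, global coordinate system.
    """

    frequency: float
    joints: list[str]
    frames: np.ndarray
    subject_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frequency <= 0:
            raise FormatError(f"frequency must be > 0, got {self.frequency}")
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise FormatError(
                f"frames must have shape (N, J, 3), got {self.frames.shape}"
            )
        n, j, _ = self.frames.shape
        if n < 1 or j < 1:
            raise FormatError("need at least one frame and one joint")
        if j != len(self.joints):
            raise FormatError(
                f"{len(self.joints)} joint labels for {j} position columns"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_joints(self) -> int:
        return self.frames.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frequency

    @property
    def duration(self) -> float:
        return (self.n_frames - 1) / self.frequency

    def joint_index(self, label: str) -> int:
        try:
            return self.joints.index(label)
        except ValueError:
            raise KeyError(f"joint {label!r} not in sequence") from None

    def positions(self, label: str) -> np.ndarray:
        """(N, 3) positions of one joint."""
        return self.frames[:, self.joint_index(label), :]

    def validate(self, allow_nan: bool = False) -> "SkeletonSequence":
        if not allow_nan and not np.isfinite(self.frames).all():
            bad = np.argwhere(~np.isfinite(self.frames).all(axis=2))
            f0, j0 = bad[0]
            raise DataQualityError(
                f"non-finite position at frame {f0}, joint {self.joints[j0]!r} "
                f"({len(bad)} missing samples total); apply fill_gaps first"
            )
        return self


@dataclass
class ReferenceTable:
    """Reference (control-group) parameter means and dispersions.

    Backed by a DataFrame with columns
    ``group, trajectory, param_index, param_name, mean, std, unit``;
    lookup is by ``(trajectory label, parameter index 1–41)``.
    """

    table: pd.DataFrame

    _COLUMNS = ("group", "trajectory", "param_index", "param_name", "mean", "std", "unit")

    def __post_init__(self) -> None:
        missing = set(self._COLUMNS) - set(self.table.columns)
        if missing:
            raise FormatError(f"reference table missing columns: {sorted(missing)}")
        idx = self.table["param_index"].to_numpy()
        if ((idx < 1) | (idx > 41)).any():
            raise FormatError("param_index must be in 1..41")
        if (self.table["std"].to_numpy() < 0).any():
            raise FormatError("dispersion (std) must be >= 0")

    def mean(self, trajectory: str, param_index: int, group: str | None = None) -> float:
        t = self.table
        sel = (t["trajectory"] == trajectory) & (t["param_index"] == param_index)
        if group is not None:
            sel &= t["group"] == group
        rows = t[sel]
        if rows.empty:
            raise KeyError(f"no reference for ({trajectory!r}, {param_index})")
        return float(rows["mean"].iloc[0])

    def covers(self, trajectory: str, param_index: int, group: str | None = None) -> bool:
        try:
            self.mean(trajectory, param_index, group)
            return True
        except KeyError:
            return False


# ---------------------------------------------------------------------------
# readers / writers

def _numeric_column(raw: pd.Series, col: str, path: str) -> np.ndarray:
    vals = pd.to_numeric(raw.replace("", np.nan), errors="coerce")
    bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "") \
        & (raw.astype(str).str.strip().str.lower() != "nan")
    if bad.any():
        line = int(raw.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ParseError(
            f"{path}: non-numeric value {raw[bad].iloc[0]!r} in column "
            f"{col!r} at line {line}"
        )
    return vals.to_numpy(dtype=float)


def _infer_frequency(times: np.ndarray, path: str, tol: float = 1e-4) -> float:
    if len(times) < 2:
        return 30.0  # single frame: assume the sensor default
    dt = np.diff(np.asarray(times, dtype=float))
    if (dt <= 0).any():
        raise FormatError(f"{path}: time stamps not strictly increasing")
    if dt.max() - dt.min() > tol:
        raise FormatError(
            f"{path}: mixed frequencies (frame intervals range "
            f"{dt.min():.6g}–{dt.max():.6g} s); regularize with resample"
        )
    return 1.0 / float(dt.mean())


def read_sequence(path: str | Path, dialect: str = "csv-long",
                  unit: str = "m", normalize_labels: bool = True) -> SkeletonSequence:
    """Read a skeleton stream from *path* in the given *dialect*.

    Frames are ordered by time; joint labels are normalized to the canonical
    vocabulary when recognizable.  Positions are converted to metres from
    *unit*.  The returned sequence may still contain NaN gaps; run
    :func:`fill_gaps` before analysis.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect not in ("csv-long", "csv-wide", "json"):
        raise FormatError(f"unknown dialect {dialect!r}")
    scale = _UNIT_TO_M.get(unit)
    if scale is None:
        raise FormatError(f"unknown unit {unit!r} (use m/cm/mm)")

    if dialect == "json":
        with open(path, encoding="utf-8") as fh:
            try:
                obj = json.load(fh)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from exc
        joints = [normalize_joint_label(j) if normalize_labels else str(j)
                  for j in obj["joints"]]
        frames = np.asarray(obj["frames"], dtype=float) * scale
        return SkeletonSequence(
            frequency=float(obj["frequency"]), joints=joints, frames=frames,
            subject_id=str(obj.get("subject_id", "")), meta=dict(obj.get("meta", {})),
        )

    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc

    if dialect == "csv-long":
        needed = {"frame", "time_s", "joint", "x", "y", "z"}
        if not needed.issubset(df.columns):
            raise FormatError(f"{path}: csv-long needs columns {sorted(needed)}")
        frame_no = _numeric_column(df["frame"], "frame", str(path)).astype(int)
        time_s = _numeric_column(df["time_s"], "time_s", str(path))
        xyz = np.column_stack([
            _numeric_column(df[c], c, str(path)) for c in ("x", "y", "z")
        ])
        labels = df["joint"].astype(str)
        if normalize_labels:
            labels = labels.map(normalize_joint_label)
        joints = list(dict.fromkeys(labels))  # first-appearance order
        frame_ids = np.unique(frame_no)
        times = np.array([time_s[frame_no == fi][0] for fi in frame_ids])
        order = np.argsort(times)
        frame_ids, times = frame_ids[order], times[order]
        jidx = {j: k for k, j in enumerate(joints)}
        fidx = {fi: k for k, fi in enumerate(frame_ids)}
        frames = np.full((len(frame_ids), len(joints), 3), np.nan)
        rows_f = np.array([fidx[f] for f in frame_no])
        rows_j = np.array([jidx[j] for j in labels])
        frames[rows_f, rows_j, :] = xyz
        freq = _infer_frequency(times, str(path))
        return SkeletonSequence(frequency=freq, joints=joints, frames=frames * scale)

    # csv-wide
    if not {"frame", "time_s"}.issubset(df.columns):
        raise FormatError(f"{path}: csv-wide needs 'frame' and 'time_s' columns")
    coord_cols = [c for c in df.columns if c[:2] in ("x_", "y_", "z_")]
    joints_raw = list(dict.fromkeys(c[2:] for c in coord_cols))
    for j in joints_raw:
        for ax in "xyz":
            if f"{ax}_{j}" not in df.columns:
                raise FormatError(f"{path}: incomplete triplet for joint {j!r}")
    joints = [normalize_joint_label(j) if normalize_labels else j for j in joints_raw]
    time_s = _numeric_column(df["time_s"], "time_s", str(path))
    order = np.argsort(time_s)
    frames = np.stack([
        np.column_stack([
            _numeric_column(df[f"{ax}_{j}"], f"{ax}_{j}", str(path)) for ax in "xyz"
        ])[order]
        for j in joints_raw
    ], axis=1)
    freq = _infer_frequency(time_s[order], str(path))
    return SkeletonSequence(frequency=freq, joints=joints, frames=frames * scale)


def write_sequence(seq: SkeletonSequence, path: str | Path,
                   dialect: str = "csv-long", precision: int = 6) -> Path:
    """Write *seq* to *path*; metres, ``precision`` decimals (default 1 µm)."""
    path = Path(path)
    fmt = f"{{:.{precision}f}}"

    def num(v: float) -> str:
        return "NaN" if not np.isfinite(v) else fmt.format(v)

    if dialect == "json":
        obj = {
            "frequency": seq.frequency,
            "joints": seq.joints,
            "subject_id": seq.subject_id,
            "meta": seq.meta,
            "frames": [[[float(num(c)) if np.isfinite(c) else None for c in pt]
                        for pt in fr] for fr in seq.frames],
        }
        path.write_text(json.dumps(obj), encoding="utf-8")
        return path

    times = seq.times
    lines: list[str] = []
    if dialect == "csv-long":
        lines.append("frame,time_s,joint,x,y,z")
        for i in range(seq.n_frames):
            for k, j in enumerate(seq.joints):
                x, y, z = seq.frames[i, k]
                lines.append(f"{i},{times[i]:.9f},{j},{num(x)},{num(y)},{num(z)}")
    elif dialect == "csv-wide":
        header = ["frame", "time_s"]
        for j in seq.joints:
            header += [f"x_{j}", f"y_{j}", f"z_{j}"]
        lines.append(",".join(header))
        for i in range(seq.n_frames):
            row = [str(i), f"{times[i]:.9f}"]
            for k in range(seq.n_joints):
                row += [num(c) for c in seq.frames[i, k]]
            lines.append(",".join(row))
    else:
        raise FormatError(f"unknown dialect {dialect!r}")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path


# ---------------------------------------------------------------------------
# gap filling & resampling

def fill_gaps(seq: SkeletonSequence, max_gap: int = 5) -> SkeletonSequence:
    """Linearly interpolate runs of ≤ *max_gap* missing samples per joint.

    A sample is missing when any of its three coordinates is non-finite.
    Runs longer than *max_gap* raise :class:`DataQualityError` naming the
    joint and frame range.  Missing runs touching the start or end of the
    stream are filled by holding the nearest observed sample (linear
    interpolation is undefined there); runs longer than *max_gap* still fail.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    frames = seq.frames.copy()
    n = seq.n_frames
    for k, joint in enumerate(seq.joints):
        missing = ~np.isfinite(frames[:, k, :]).all(axis=1)
        if not missing.any():
            continue
        if missing.all():
            raise DataQualityError(f"joint {joint!r} has no valid samples")
        # enumerate runs of consecutive missing frames
        idx = np.flatnonzero(missing)
        run_starts = idx[np.r_[True, np.diff(idx) > 1]]
        run_ends = idx[np.r_[np.diff(idx) > 1, True]]
        for a, b in zip(run_starts, run_ends):
            if b - a + 1 > max_gap:
                raise DataQualityError(
                    f"gap of {b - a + 1} frames for joint {joint!r} at frames "
                    f"{a}–{b} exceeds max_gap={max_gap}"
                )
        valid = np.flatnonzero(~missing)
        t = np.arange(n, dtype=float)
        for c in range(3):
            frames[missing, k, c] = np.interp(t[missing], t[valid], frames[valid, k, c])
    out = SkeletonSequence(seq.frequency, list(seq.joints), frames,
                           seq.subject_id, dict(seq.meta))
    return out.validate()


def resample(seq: SkeletonSequence, target_frequency: float) -> SkeletonSequence:
    """Linear time-interpolation of every coordinate onto a new fixed grid.

    Duration is preserved to within one sample period; resampling at the
    sequence's own frequency is the identity.
    """
    if target_frequency <= 0:
        raise ValueError("target_frequency must be > 0")
    if seq.n_frames < 2:
        raise DataQualityError("cannot resample a sequence with fewer than 2 frames")
    t_old = seq.times
    duration = t_old[-1]
    n_new = int(np.floor(duration * target_frequency + 1e-9)) + 1
    t_new = np.arange(n_new) / target_frequency
    flat = seq.frames.reshape(seq.n_frames, -1)
    out = np.empty((n_new, flat.shape[1]))
    for c in range(flat.shape[1]):
        out[:, c] = np.interp(t_new, t_old, flat[:, c])
    return SkeletonSequence(target_frequency, list(seq.joints),
                            out.reshape(n_new, seq.n_joints, 3),
                            seq.subject_id, dict(seq.meta))


def smooth(seq: SkeletonSequence, cutoff_hz: float = 6.0, order: int = 4) -> SkeletonSequence:
    """Zero-phase Butterworth low-pass filter on every joint coordinate.

    Voluntary upper-limb motion lives well below ~6 Hz while depth-sensor
    jitter is broadband, so low-pass filtering before any differentiation is
    the standard motion-analysis practice; without it, per-frame jitter
    dominates velocity estimates.  Uses a forward–backward (zero-phase)
    4th-order Butterworth filter by default.
    """
    from scipy.signal import butter, filtfilt

    nyquist = seq.frequency / 2.0
    if not 0 < cutoff_hz < nyquist:
        raise FormatError(f"cutoff must lie in (0, {nyquist}) Hz, got {cutoff_hz}")
    seq.validate()
    if seq.n_frames <= 3 * (order + 1):
        raise DataQualityError("sequence too short to filter; need more frames")
    b, a = butter(order, cutoff_hz / nyquist)
    frames = filtfilt(b, a, seq.frames, axis=0)
    return SkeletonSequence(seq.frequency, list(seq.joints), frames,
                            seq.subject_id, dict(seq.meta))


# ---------------------------------------------------------------------------
# reference tables

def read_reference_table(path: str | Path) -> ReferenceTable:
    df = pd.read_csv(path)
    return ReferenceTable(df)


def write_reference_table(ref: ReferenceTable, path: str | Path) -> Path:
    path = Path(path)
    ref.table.to_csv(path, index=False)
    return path
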