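"""Local coordinate systems, link-length correction and relative trajectories.

Nineteen local coordinate systems (LCS) are attached to the skeleton, one per
tracked segment origin.  Motion is then described not by joint angles but by
the trajectory of each *child* LCS origin expressed in its *parent* LCS — the
topology table lists which child/parent pairs are extracted (17 by default,
parent id 0 meaning the global frame).

Axis convention (shipped as an editable table, ``data/lcs_convention.csv``):
the Y axis runs along the segment longitudinal direction (distal → proximal),
the X axis is the reference direction (trunk-up or mediolateral, per segment)
orthogonalized against Y, and Z = X × Y completes a right-handed triad.  This
is compatible with common biomechanics segment-frame recommendations while
remaining constructible from a sparse 20-point skeleton.  When the primary
reference direction is nearly parallel to Y (within ~8°) a per-segment
fallback reference is used; if both are degenerate the frame is reported as
an error rather than guessed.

Because the Kinect's depth estimate makes bone lengths fluctuate frame to
frame, raw segments are re-scaled to per-subject calibrated lengths: assuming
the raw stick model supplies the correct line *orientation*, each link is
processed root-outward and its child joint repositioned at the calibrated
distance along the raw direction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import CalibrationError, ModelError
from .io import SkeletonSequence

__all__ = [
    "Topology",
    "LCSFrameSet",
    "RelativeTrajectory",
    "SegmentLengths",
    "LCSDefinition",
    "default_topology",
    "default_lcs_convention",
    "DEFAULT_ARM_CHAIN",
    "calibrate_reference_lengths",
    "correct_link_lengths",
    "build_lcs",
    "extract_relative_trajectories",
]

_EPS = 1e-12
#: cos of ~8°: above this the primary reference is considered parallel to the
#: longitudinal axis and the fallback reference is used instead.
_PARALLEL_COS = 0.99


# ---------------------------------------------------------------------------
# topology

@dataclass(frozen=True)
class Topology:
    """Ordered (motion_id, child_point_id, parent_point_id) entries.

    Point id 0 denotes the global coordinate system.  The default instance
    (17 entries) is loaded from ``data/topology_table1.csv``.
    """

    entries: tuple[tuple[int, int, int], ...]

    def __post_init__(self) -> None:
        # child→parent edges over non-zero ids must be acyclic
        parent_of: dict[int, set[int]] = {}
        for _, child, parent in self.entries:
            if parent != 0:
                parent_of.setdefault(child, set()).add(parent)
        for start in parent_of:
            seen = {start}
            stack = list(parent_of.get(start, ()))
            while stack:
                node = stack.pop()
                if node in seen and node == start:
                    raise ModelError(f"topology cycle through point {start}")
                if node in seen:
                    continue
                seen.add(node)
                stack.extend(parent_of.get(node, ()))

    def __len__(self) -> int:
        return len(self.entries)

    @classmethod
    def from_csv(cls, path: str | Path) -> "Topology":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls(tuple(
            (int(r["motion"]), int(r["child"]), int(r["parent"])) for r in rows
        ))


def default_topology() -> Topology:
    """The shipped 17-entry upper-limb topology."""
    with resources.as_file(
        resources.files("trajkin.data").joinpath("topology_table1.csv")
    ) as p:
        return Topology.from_csv(p)


# ---------------------------------------------------------------------------
# LCS convention

@dataclass(frozen=True)
class LCSDefinition:
    """Recipe for one LCS: origin joint(s) and axis joint pairs.

    A joint spec is either a joint name or ``"a|b"`` for the midpoint of two
    joints.  Y = unit(long_to − long_from); X = reference direction
    (ref_to − ref_from) orthogonalized against Y; Z = X × Y.
    """

    lcs_id: int
    name: str
    origin: str
    long_from: str
    long_to: str
    ref_from: str
    ref_to: str
    ref2_from: str = ""
    ref2_to: str = ""

    def required_joints(self) -> set[str]:
        out: set[str] = set()
        for spec in (self.origin, self.long_from, self.long_to,
                     self.ref_from, self.ref_to):
            out.update(spec.split("|"))
        return out


def default_lcs_convention() -> list[LCSDefinition]:
    with resources.as_file(
        resources.files("trajkin.data").joinpath("lcs_convention.csv")
    ) as p:
        return load_lcs_convention(p)


def load_lcs_convention(path: str | Path) -> list[LCSDefinition]:
    with open(path, newline="", encoding="utf-8") as fh:
        rows = list(csv.DictReader(fh))
    return [
        LCSDefinition(
            lcs_id=int(r["lcs_id"]), name=r["name"], origin=r["origin"],
            long_from=r["long_from"], long_to=r["long_to"],
            ref_from=r["ref_from"], ref_to=r["ref_to"],
            ref2_from=r.get("ref2_from") or "", ref2_to=r.get("ref2_to") or "",
        )
        for r in rows
    ]


@dataclass
class LCSFrameSet:
    """Per-frame origins and orientations of every constructed LCS.

    ``origins[lcs_id]`` is (N, 3) in metres (global frame);
    ``orientations[lcs_id]`` is (N, 3, 3), columns = LCS axes in global
    coordinates, orthonormal with determinant +1.
    """

    frequency: float
    origins: dict[int, np.ndarray]
    orientations: dict[int, np.ndarray]
    names: dict[int, str] = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return next(iter(self.origins.values())).shape[0]

    @property
    def lcs_ids(self) -> list[int]:
        return sorted(self.origins)


@dataclass
class RelativeTrajectory:
    """N×3 positions of one child LCS origin expressed in its parent LCS."""

    label: str
    motion_id: int
    points: np.ndarray  # (N, 3), metres
    frequency: float

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ModelError(f"points must be (N, 3), got {self.points.shape}")
        if not np.isfinite(self.points).all():
            raise ModelError(f"trajectory {self.label!r} has non-finite points")

    @property
    def n(self) -> int:
        return self.points.shape[0]


@dataclass
class SegmentLengths:
    """Per-link calibrated reference lengths in metres, keyed (child, parent)."""

    lengths: dict[tuple[str, str], float]

    def __post_init__(self) -> None:
        for link, value in self.lengths.items():
            if not value > 0:
                raise CalibrationError(f"link {link} length must be > 0, got {value}")

    def __getitem__(self, link: tuple[str, str]) -> float:
        return self.lengths[link]

    def __contains__(self, link: tuple[str, str]) -> bool:
        return link in self.lengths


#: Root-outward arm chains (child, parent) used for calibration & correction.
DEFAULT_ARM_CHAIN: tuple[tuple[str, str], ...] = (
    ("shoulder_center", "spine"),
    ("shoulder_left", "shoulder_center"),
    ("elbow_left", "shoulder_left"),
    ("wrist_left", "elbow_left"),
    ("shoulder_right", "shoulder_center"),
    ("elbow_right", "shoulder_right"),
    ("wrist_right", "elbow_right"),
)


# ---------------------------------------------------------------------------
# calibration & link correction

def calibrate_reference_lengths(
    pose_sequences: Sequence[SkeletonSequence],
    links: Iterable[tuple[str, str]] = DEFAULT_ARM_CHAIN,
) -> SegmentLengths:
    """Median child–parent distance over all calibration frames, per link.

    The subject holds a few static poses; the median over the pooled frames
    is robust to tracking jitter and brief losses.
    """
    if not pose_sequences:
        raise CalibrationError("need at least one calibration sequence")
    out: dict[tuple[str, str], float] = {}
    for child, parent in links:
        dists: list[np.ndarray] = []
        for seq in pose_sequences:
            if child in seq.joints and parent in seq.joints:
                d = np.linalg.norm(seq.positions(child) - seq.positions(parent), axis=1)
                dists.append(d[np.isfinite(d)])
        if not dists or not len(np.concatenate(dists)):
            raise CalibrationError(
                f"link ({child!r}, {parent!r}) endpoints absent from calibration data"
            )
        out[(child, parent)] = float(np.median(np.concatenate(dists)))
    return SegmentLengths(out)


def correct_link_lengths(
    seq: SkeletonSequence,
    lengths: SegmentLengths,
    chain_order: Sequence[tuple[str, str]] = DEFAULT_ARM_CHAIN,
) -> SkeletonSequence:
    """Re-scale each link to its calibrated length, root-outward.

    Per frame, each child joint is repositioned at
    ``parent_corrected + length × unit(child_raw − parent_raw)``: the raw
    direction is preserved, the length becomes exact.  *chain_order* must be
    topologically sorted root → extremity.  A zero-length raw link carries
    the previous frame's direction; on the first frame this is an error.
    """
    for link in chain_order:
        if link not in lengths:
            raise CalibrationError(f"no calibrated length for link {link}")
    raw = seq.frames
    corrected = raw.copy()
    jidx = {j: k for k, j in enumerate(seq.joints)}
    for child, parent in chain_order:
        ci, pi = jidx[child], jidx[parent]
        vec = raw[:, ci, :] - raw[:, pi, :]  # raw directions are authoritative
        norm = np.linalg.norm(vec, axis=1)
        unit = np.empty_like(vec)
        for i in range(seq.n_frames):
            if norm[i] > _EPS:
                unit[i] = vec[i] / norm[i]
            elif i > 0:
                unit[i] = unit[i - 1]
            else:
                raise ModelError(
                    f"zero-length raw link ({child!r}, {parent!r}) at first frame: "
                    "direction undefined"
                )
        corrected[:, ci, :] = corrected[:, pi, :] + lengths[(child, parent)] * unit
    return SkeletonSequence(seq.frequency, list(seq.joints), corrected,
                            seq.subject_id, dict(seq.meta))


# ---------------------------------------------------------------------------
# LCS construction

def _joint_spec_positions(seq: SkeletonSequence, spec: str) -> np.ndarray:
    parts = spec.split("|")
    pos = seq.positions(parts[0]).copy()
    for p in parts[1:]:
        pos += seq.positions(p)
    return pos / len(parts)


def build_lcs(
    seq: SkeletonSequence,
    convention: Sequence[LCSDefinition] | None = None,
) -> LCSFrameSet:
    """Construct every LCS origin and orientation for every frame.

    Each frame is built from scratch (no accumulation, hence no drift).
    Raises :class:`ModelError` naming the LCS when a required joint is
    missing or a frame is geometrically degenerate.
    """
    seq.validate()
    defs = list(convention) if convention is not None else default_lcs_convention()
    origins: dict[int, np.ndarray] = {}
    orientations: dict[int, np.ndarray] = {}
    names: dict[int, str] = {}
    for d in defs:
        missing = d.required_joints() - set(seq.joints)
        if missing:
            raise ModelError(
                f"LCS {d.lcs_id} ({d.name}): required joints missing: {sorted(missing)}"
            )
        origin = _joint_spec_positions(seq, d.origin)
        y_vec = (_joint_spec_positions(seq, d.long_to)
                 - _joint_spec_positions(seq, d.long_from))
        y_norm = np.linalg.norm(y_vec, axis=1)
        if (y_norm < _EPS).any():
            f0 = int(np.flatnonzero(y_norm < _EPS)[0])
            raise ModelError(
                f"LCS {d.lcs_id} ({d.name}): longitudinal joints coincident "
                f"at frame {f0}"
            )
        y = y_vec / y_norm[:, None]

        w = _joint_spec_positions(seq, d.ref_to) - _joint_spec_positions(seq, d.ref_from)
        w_norm = np.linalg.norm(w, axis=1)
        if (w_norm < _EPS).any():
            f0 = int(np.flatnonzero(w_norm < _EPS)[0])
            raise ModelError(
                f"LCS {d.lcs_id} ({d.name}): reference joints coincident at frame {f0}"
            )
        w_unit = w / w_norm[:, None]
        cos_wy = np.abs(np.einsum("ij,ij->i", w_unit, y))
        if d.ref2_from and d.ref2_to:
            near_parallel = cos_wy > _PARALLEL_COS
            if near_parallel.any():
                w2 = (_joint_spec_positions(seq, d.ref2_to)
                      - _joint_spec_positions(seq, d.ref2_from))
                w2n = np.linalg.norm(w2, axis=1)
                ok = w2n > _EPS
                w_unit = np.where((near_parallel & ok)[:, None],
                                  w2 / np.where(w2n > _EPS, w2n, 1.0)[:, None],
                                  w_unit)
                cos_wy = np.abs(np.einsum("ij,ij->i", w_unit, y))
        if (cos_wy > 1 - 1e-9).any():
            f0 = int(np.flatnonzero(cos_wy > 1 - 1e-9)[0])
            raise ModelError(
                f"LCS {d.lcs_id} ({d.name}): reference direction parallel to "
                f"longitudinal axis at frame {f0}"
            )
        # Gram–Schmidt: X = reference stripped of its Y component, Z = X × Y
        x = w_unit - np.einsum("ij,ij->i", w_unit, y)[:, None] * y
        x /= np.linalg.norm(x, axis=1)[:, None]
        z = np.cross(x, y)
        rot = np.stack([x, y, z], axis=2)  # columns = axes
        origins[d.lcs_id] = origin
        orientations[d.lcs_id] = rot
        names[d.lcs_id] = d.name
    return LCSFrameSet(seq.frequency, origins, orientations, names)


# ---------------------------------------------------------------------------
# relative trajectories

def extract_relative_trajectories(
    lcs: LCSFrameSet, topo: Topology | None = None
) -> list[RelativeTrajectory]:
    """One trajectory per topology entry: child origin in parent coordinates.

    ``point_i = parent_orientationᵀ · (child_origin − parent_origin)`` per
    frame; parent id 0 passes global coordinates through unchanged.  The
    default topology yields exactly 17 trajectories.
    """
    topo = topo if topo is not None else default_topology()
    missing = {c for _, c, _ in topo.entries} | {p for _, _, p in topo.entries if p != 0}
    missing -= set(lcs.origins)
    if missing:
        raise ModelError(f"topology point ids absent from LCS set: {sorted(missing)}")
    out: list[RelativeTrajectory] = []
    for motion_id, child, parent in topo.entries:
        child_o = lcs.origins[child]
        cname = lcs.names.get(child, f"lcs{child}")
        if parent == 0:
            pts = child_o.copy()
            label = f"{cname}_in_global"
        else:
            rel = child_o - lcs.origins[parent]
            pts = np.einsum("nij,nj->ni", np.swapaxes(lcs.orientations[parent], 1, 2), rel)
            label = f"{cname}_in_{lcs.names.get(parent, f'lcs{parent}')}"
        out.append(RelativeTrajectory(label=label, motion_id=motion_id,
                                      points=pts, frequency=lcs.frequency))
    return out
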