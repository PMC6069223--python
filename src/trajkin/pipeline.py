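"""End-to-end convenience path: skeleton stream → feature vectors."""

from __future__ import annotations

from typing import Sequence

from .features import FeatureVector, compute_feature_vector
from .io import SkeletonSequence, fill_gaps, smooth
from .kinematics import (
    DEFAULT_ARM_CHAIN,
    SegmentLengths,
    Topology,
    build_lcs,
    correct_link_lengths,
    extract_relative_trajectories,
)

__all__ = ["analyze_sequence"]


def analyze_sequence(
    seq: SkeletonSequence,
    lengths: SegmentLengths | None = None,
    topology: Topology | None = None,
    max_gap: int = 5,
    smooth_hz: float | None = None,
) -> dict[str, FeatureVector]:
    """Run the full analysis on one skeleton stream.

    Gaps are filled, an optional zero-phase low-pass filter applied
    (recommended for raw sensor data: pass e.g. ``smooth_hz=6``), calibrated
    link lengths applied when supplied, the 19 local coordinate systems
    built, the topology's relative trajectories extracted and one
    41-parameter feature vector computed per trajectory.  Returns a mapping
    from trajectory label to feature vector.
    """
    seq = fill_gaps(seq, max_gap=max_gap)
    if smooth_hz is not None:
        seq = smooth(seq, cutoff_hz=smooth_hz)
    if lengths is not None:
        seq = correct_link_lengths(seq, lengths, DEFAULT_ARM_CHAIN)
    lcs = build_lcs(seq)
    trajectories = extract_relative_trajectories(lcs, topology)
    return {t.label: compute_feature_vector(t) for t in trajectories}
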