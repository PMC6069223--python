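"""Dimensionless patient-vs-reference scoring and star-plot export.

Every trajectory parameter is turned into a dimensionless score by the ratio
``s = reference_mean / patient_value``: a score of 1 (100 %) means the
patient matches the reference group; scores above 1 mean the patient's value
is *smaller* than the reference (the typical direction of impairment for
reach, speed and workspace measures).  Scores are aggregated by weighted
means — per trajectory (S_pj), per display group (Ang/Len/Vol) and overall
(C_p) — with all weights defaulting to 1.  The joint-angle path mirrors the
same construction per joint axis (s_ij, S_φi, C_φ) when angle tables are
supplied externally.

For display the raw score is clamped into [−1, 1] (±100 %) so a single
outlying parameter cannot dominate a star plot; the raw channel is preserved
for longitudinal tracking.

The default 17-parameter visualization panel (6 angular, 6 length,
5 volumetric members, ``data/default_panel.json``) is a shipped, editable
default of this package — the grouping idea comes from clinical usage, the
exact membership is ours.  Signed coordinate parameters (16–30) are excluded
from it because ratios of signed coordinates are not meaningful scores.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ScoringError
from .features import PARAM_NAMES, FeatureVector
from .io import ReferenceTable

__all__ = [
    "WeightScheme",
    "ScoreCard",
    "default_panel",
    "parameter_scores",
    "aggregate",
    "angle_scores",
    "contralateral_reference",
    "reference_from_features",
    "star_plot_export",
    "plot_star",
]


def default_panel() -> dict[str, list[int]]:
    """Shipped default 17-parameter panel: group name → parameter indices."""
    text = resources.files("trajkin.data").joinpath("default_panel.json").read_text()
    obj = json.loads(text)
    return {k: list(v) for k, v in obj.items() if not k.startswith("_")}


@dataclass
class WeightScheme:
    """Nonnegative weights for score aggregation; anything absent weighs 1."""

    param_weights: dict[tuple[str, int], float] = field(default_factory=dict)
    trajectory_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for w in list(self.param_weights.values()) + list(self.trajectory_weights.values()):
            if not np.isfinite(w) or w < 0:
                raise ScoringError(f"weights must be finite and >= 0, got {w}")

    def param(self, trajectory: str, index: int) -> float:
        return self.param_weights.get((trajectory, index), 1.0)

    def trajectory(self, label: str) -> float:
        return self.trajectory_weights.get(label, 1.0)


@dataclass
class ScoreCard:
    """Per-parameter scores plus aggregates for one subject vs a reference.

    ``scores`` columns: trajectory, param_index, param_name, raw, display,
    flag.  ``trajectory_scores`` holds S_pj, ``group_scores`` the Ang/Len/Vol
    means, ``total`` the overall weighted score C_p (1.0 = 100 %).
    """

    scores: pd.DataFrame
    reference_group: str = ""
    side: str = ""
    trajectory_scores: dict[str, float] = field(default_factory=dict)
    group_scores: dict[str, float] = field(default_factory=dict)
    total: float | None = None

    @property
    def total_percent(self) -> float | None:
        return None if self.total is None else 100.0 * self.total


def _clamp_display(raw: np.ndarray) -> np.ndarray:
    return np.clip(raw, -1.0, 1.0)


def _score_rows(label: str, patient: FeatureVector,
                ref_value: "callable") -> list[dict]:
    rows = []
    for i in range(1, 42):
        ref = ref_value(label, i)
        if ref is None:
            continue
        pv = patient[i]
        flag = patient.flags.get(i, "")
        if pv == 0 or not np.isfinite(pv):
            raw = np.nan
            flag = flag or "zero_patient_value"
        else:
            raw = ref / pv
        rows.append({
            "trajectory": label, "param_index": i, "param_name": PARAM_NAMES[i],
            "raw": raw, "display": np.clip(raw, -1.0, 1.0) if np.isfinite(raw) else np.nan,
            "flag": flag,
        })
    return rows


def parameter_scores(
    patient: Mapping[str, FeatureVector],
    reference: ReferenceTable,
    group: str | None = None,
) -> ScoreCard:
    """Raw per-parameter scores ``s = reference_mean / patient_value``.

    Parameters whose patient value is zero (or flagged non-finite) get a NaN
    score with a flag and are excluded from later aggregation.
    """
    if not patient:
        raise ScoringError("no patient feature vectors supplied")

    def ref_value(label: str, i: int):
        try:
            return reference.mean(label, i, group)
        except KeyError:
            return None

    rows: list[dict] = []
    for label, fv in patient.items():
        rows.extend(_score_rows(label, fv, ref_value))
    if not rows:
        raise ScoringError("reference table covers none of the patient parameters")
    return ScoreCard(scores=pd.DataFrame(rows), reference_group=group or "")


def _weighted_mean(values: np.ndarray, weights: np.ndarray) -> float:
    total = weights.sum()
    if total <= 0:
        raise ScoringError("all-zero weights over a non-empty selection")
    return float(np.sum(values * weights) / total)


def aggregate(
    card: ScoreCard,
    weights: WeightScheme | None = None,
    selection: Iterable[int] | None = None,
    panel: Mapping[str, Sequence[int]] | None = None,
) -> ScoreCard:
    """Fill in S_pj, group scores and the total C_p by weighted means.

    *selection* restricts which parameter indices are aggregated (default:
    the union of the panel groups); *panel* maps display-group names to
    parameter indices (default: the shipped 17-parameter Ang/Len/Vol panel).
    Flagged scores are excluded.  Aggregates are convex combinations, so
    each lies between the min and max of its members.
    """
    weights = weights or WeightScheme()
    panel = dict(panel) if panel is not None else default_panel()
    selection = sorted(set(selection) if selection is not None
                       else {i for idxs in panel.values() for i in idxs})
    if not selection:
        raise ScoringError("empty parameter selection")
    df = card.scores
    ok = df["param_index"].isin(selection) & np.isfinite(df["raw"]) & (df["flag"] == "")
    sel = df[ok]
    if sel.empty:
        raise ScoringError("no finite scores in the selected parameter set")

    traj_scores: dict[str, float] = {}
    for label, grp in sel.groupby("trajectory"):
        w = np.array([weights.param(label, int(i)) for i in grp["param_index"]])
        traj_scores[str(label)] = _weighted_mean(grp["raw"].to_numpy(), w)

    group_scores: dict[str, float] = {}
    for gname, idxs in panel.items():
        grp = sel[sel["param_index"].isin(idxs)]
        if grp.empty:
            continue
        w = np.array([weights.param(t, int(i))
                      for t, i in zip(grp["trajectory"], grp["param_index"])])
        group_scores[gname] = _weighted_mean(grp["raw"].to_numpy(), w)

    labels = list(traj_scores)
    tw = np.array([weights.trajectory(t) for t in labels])
    total = _weighted_mean(np.array([traj_scores[t] for t in labels]), tw)
    return ScoreCard(scores=card.scores, reference_group=card.reference_group,
                     side=card.side, trajectory_scores=traj_scores,
                     group_scores=group_scores, total=total)


def angle_scores(
    patient_angles: pd.DataFrame,
    reference_angles: pd.DataFrame,
    axis_weights: Mapping[tuple[str, str], float] | None = None,
    joint_weights: Mapping[str, float] | None = None,
) -> ScoreCard:
    """Single-joint angle scores: s per axis, S_φi per joint, C_φ overall.

    Both tables need columns ``joint, axis, value`` with matched coverage;
    axes are x/y/z.  Zero patient angles are flagged and excluded.
    """
    for name, t in (("patient", patient_angles), ("reference", reference_angles)):
        if not {"joint", "axis", "value"}.issubset(t.columns):
            raise ScoringError(f"{name} angle table needs columns joint, axis, value")
    axis_weights = dict(axis_weights or {})
    joint_weights = dict(joint_weights or {})
    ref = reference_angles.set_index(["joint", "axis"])["value"]
    rows = []
    for _, r in patient_angles.iterrows():
        key = (r["joint"], r["axis"])
        if key not in ref.index:
            raise ScoringError(f"reference angle missing for {key}")
        pv = float(r["value"])
        raw = np.nan if pv == 0 else float(ref.loc[key]) / pv
        rows.append({
            "trajectory": r["joint"], "param_index": {"x": 1, "y": 2, "z": 3}[r["axis"]],
            "param_name": f"angle_{r['axis']}", "raw": raw,
            "display": np.clip(raw, -1.0, 1.0) if np.isfinite(raw) else np.nan,
            "flag": "" if np.isfinite(raw) else "zero_patient_value",
            "axis": r["axis"],
        })
    df = pd.DataFrame(rows)
    joint_scores: dict[str, float] = {}
    for joint, grp in df[np.isfinite(df["raw"])].groupby("trajectory"):
        w = np.array([axis_weights.get((str(joint), a), 1.0) for a in grp["axis"]])
        joint_scores[str(joint)] = _weighted_mean(grp["raw"].to_numpy(), w)
    if not joint_scores:
        raise ScoringError("no finite angle scores")
    labels = list(joint_scores)
    jw = np.array([joint_weights.get(j, 1.0) for j in labels])
    total = _weighted_mean(np.array([joint_scores[j] for j in labels]), jw)
    return ScoreCard(scores=df, trajectory_scores=joint_scores, total=total)


def reference_from_features(
    features: Mapping[str, FeatureVector], group: str = "self"
) -> ReferenceTable:
    """Build a reference table whose means are one subject's own values.

    Used for self-reference checks and for contralateral comparison.
    """
    from .features import PARAM_UNITS

    rows = []
    for label, fv in features.items():
        for i in range(1, 42):
            if i in fv.flags:
                continue
            rows.append({
                "group": group, "trajectory": label, "param_index": i,
                "param_name": PARAM_NAMES[i], "mean": fv[i], "std": 0.0,
                "unit": PARAM_UNITS[i],
            })
    return ReferenceTable(pd.DataFrame(rows))


def _mirror_label(label: str) -> str:
    if "_L" in label:
        return label.replace("_L", "_R")
    if "_R" in label:
        return label.replace("_R", "_L")
    return label


def contralateral_reference(
    affected: Mapping[str, FeatureVector],
    healthy: Mapping[str, FeatureVector],
) -> ScoreCard:
    """Score the affected side using the healthy side as its own reference.

    Labels are paired by mirroring the ``_L``/``_R`` side tag; a missing
    mirror partner is a pairing error.  Raw scores invert (s → 1/s) when the
    two sides are swapped.
    """
    pairs: dict[str, FeatureVector] = {}
    for label in affected:
        mirror = _mirror_label(label)
        if mirror not in healthy:
            raise ScoringError(
                f"no healthy-side trajectory matching {label!r} (expected {mirror!r})"
            )
        pairs[label] = healthy[mirror]

    def ref_value(label: str, i: int):
        fv = pairs[label]
        return None if i in fv.flags else fv[i]

    rows: list[dict] = []
    for label, fv in affected.items():
        rows.extend(_score_rows(label, fv, ref_value))
    return ScoreCard(scores=pd.DataFrame(rows), reference_group="contralateral",
                     side="affected")


# ---------------------------------------------------------------------------
# star plot

def star_plot_export(
    card: ScoreCard,
    panel: Mapping[str, Sequence[int]] | None = None,
) -> dict:
    """Sector list for a star (polar) plot, deterministic ordering.

    One sector per (group, parameter) of the panel, radius proportional to
    the display score; group means and the total score at the centre.
    Requires an aggregated card.
    """
    if card.total is None:
        raise ScoringError("aggregate the score card before exporting a star plot")
    panel = dict(panel) if panel is not None else default_panel()
    if not any(panel.values()):
        raise ScoringError("empty star-plot panel")
    df = card.scores
    sectors = []
    for gname in sorted(panel):
        for i in sorted(panel[gname]):
            grp = df[(df["param_index"] == i) & (df["flag"] == "")
                     & np.isfinite(df["raw"])]
            if grp.empty:
                continue
            display = float(np.clip(grp["raw"].mean(), -1.0, 1.0))
            sectors.append({
                "label": PARAM_NAMES[i], "param_index": i, "group": gname,
                "score_display": display, "radius": abs(display),
            })
    if not sectors:
        raise ScoringError("no plottable sectors in the selected panel")
    return {
        "sectors": sectors,
        "group_scores": dict(card.group_scores),
        "total_percent": card.total_percent,
        "reference_group": card.reference_group,
    }


def plot_star(data: dict, path: str | Path) -> Path:
    """Render exported star-plot data to a static polar figure (SVG/PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"Ang": "tab:red", "Len": "tab:blue", "Vol": "tab:green"}
    sectors = data["sectors"]
    n = len(sectors)
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    width = 2.0 * np.pi / n
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(7, 7))
    for t, s in zip(theta, sectors):
        ax.bar(t, s["radius"], width=width * 0.95, bottom=0.0,
               color=colors.get(s["group"], "tab:gray"), alpha=0.8,
               edgecolor="white")
        ax.text(t, max(s["radius"], 0.25) + 0.08, s["label"],
                ha="center", va="center", fontsize=7, rotation=0)
    ax.plot(np.linspace(0, 2 * np.pi, 200), np.ones(200), color="gold", lw=2)
    total = data.get("total_percent")
    if total is not None:
        ax.text(0.0, 0.0, f"{total:.0f}%", ha="center", va="center",
                fontsize=14, weight="bold",
                bbox={"boxstyle": "circle", "fc": "gold", "alpha": 0.9})
    ax.set_yticklabels([])
    ax.set_xticks([])
    ax.set_ylim(0, 1.35)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
    return Path(path)
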