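"""Device-agreement and group-comparison statistics.

Two study designs are supported:

* **paired devices** — the same subjects measured simultaneously by two
  capture systems (e.g. a markerless depth camera against an optoelectronic
  reference).  Agreement is summarised by Pearson's R, the reproducibility
  coefficient RCP = 1.96 × STD and the coefficient of variation
  CV = STD/Mean, both expressed as percentages.  The STD is taken over the
  paired differences and the percentage base is the pooled mean of both
  devices (the usual method-comparison convention); a ``basis`` switch
  computes them on raw values instead, since the percentage base is a
  reporting choice rather than a fixed definition.
* **independent groups** — per-group subject means compared by one-way
  ANOVA with Bonferroni-corrected pairwise t tests (multiply-and-cap), and
  significance flags at α = 0.05.

Normality checking delegates to the standard Shapiro–Wilk routine.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataQualityError

__all__ = [
    "AgreementResult",
    "GroupComparisonResult",
    "agreement_stats",
    "group_comparison",
    "normality_check",
]


@dataclass
class AgreementResult:
    r: float
    p: float
    rcp_percent: float
    cv_percent: float
    n: int
    basis: str
    flags: list[str] = field(default_factory=list)


@dataclass
class GroupComparisonResult:
    f: float
    p: float
    pairwise: dict[tuple[str, str], float]      # Bonferroni-corrected p
    pairwise_raw: dict[tuple[str, str], float]  # uncorrected p
    flags: dict[tuple[str, str], bool]          # significant at alpha
    alpha: float
    group_means: dict[str, float]
    group_stds: dict[str, float]
    notes: list[str] = field(default_factory=list)


def agreement_stats(
    a: Sequence[float], b: Sequence[float], basis: str = "differences"
) -> AgreementResult:
    """Pearson R plus RCP% and CV% for one paired device comparison.

    With ``basis="differences"`` (default) RCP% = 100·1.96·std(A−B)/mean
    and CV% = 100·std(A−B)/mean where the mean pools both devices; with
    ``basis="values"`` the std of the pooled raw values is used instead.
    Symmetric in (A, B) either way.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    n = len(a)
    if n < 3:
        raise DataQualityError(f"need n >= 3 paired values, got {n}")
    if basis not in ("differences", "values"):
        raise ValueError(f"unknown basis {basis!r}")
    flags: list[str] = []
    if np.std(a) == 0 or np.std(b) == 0:
        r, p = np.nan, np.nan
        flags.append("zero_variance")
    else:
        r, p = sps.pearsonr(a, b)
    pooled_mean = float(np.mean(np.concatenate([a, b])))
    if pooled_mean == 0:
        raise DataQualityError("pooled mean is zero; percentages undefined")
    std = float(np.std(a - b, ddof=1)) if basis == "differences" \
        else float(np.std(np.concatenate([a, b]), ddof=1))
    return AgreementResult(
        r=float(r), p=float(p),
        rcp_percent=100.0 * 1.96 * std / abs(pooled_mean),
        cv_percent=100.0 * std / abs(pooled_mean),
        n=n, basis=basis, flags=flags,
    )


def group_comparison(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> GroupComparisonResult:
    """One-way ANOVA plus Bonferroni-corrected pairwise t tests.

    Each pairwise two-sample t test p-value is multiplied by the number of
    comparisons and capped at 1; flags mark corrected p < *alpha*.  With two
    groups the Bonferroni factor is 1.  Results are invariant under group
    relabelling.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for k, v in arrays.items():
        if len(v) < 2:
            raise DataQualityError(f"group {k!r} needs n >= 2, got {len(v)}")
    notes: list[str] = []
    values = list(arrays.values())
    if all(np.std(v) == 0 for v in values) and len({float(v[0]) for v in values}) == 1:
        # all groups identical constants: no between- or within-variance
        f, p = 0.0, 1.0
    else:
        f, p = sps.f_oneway(*values)
    m = len(list(combinations(arrays, 2)))
    pairwise_raw: dict[tuple[str, str], float] = {}
    pairwise: dict[tuple[str, str], float] = {}
    flags: dict[tuple[str, str], bool] = {}
    for ka, kb in combinations(sorted(arrays), 2):
        va, vb = arrays[ka], arrays[kb]
        if np.std(va) == 0 and np.std(vb) == 0:
            praw = 1.0 if va[0] == vb[0] else 0.0
            notes.append(f"degenerate zero-variance pair ({ka}, {kb})")
        else:
            _, praw = sps.ttest_ind(va, vb)
        pairwise_raw[(ka, kb)] = float(praw)
        pairwise[(ka, kb)] = float(min(praw * m, 1.0))
        flags[(ka, kb)] = pairwise[(ka, kb)] < alpha
    return GroupComparisonResult(
        f=float(f), p=float(p), pairwise=pairwise, pairwise_raw=pairwise_raw,
        flags=flags, alpha=alpha,
        group_means={k: float(np.mean(v)) for k, v in arrays.items()},
        group_stds={k: float(np.std(v, ddof=1)) for k, v in arrays.items()},
        notes=notes,
    )


def normality_check(x: Sequence[float]) -> tuple[float, float]:
    """Shapiro–Wilk W statistic and p-value for 3 ≤ n ≤ 5000."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not (3 <= len(x) <= 5000):
        raise DataQualityError(f"Shapiro–Wilk needs 3 <= n <= 5000, got {len(x)}")
    if np.std(x) == 0:
        raise DataQualityError("constant vector: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p)
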