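"""Independent naive reimplementations used as oracles.

Everything here is written as explicit per-point loops over the defining
formulas, deliberately sharing no code with the package implementation.
"""

from __future__ import annotations

import math

import numpy as np


def naive_hodograph(points: np.ndarray, f: float) -> dict:
    n = len(points)
    speeds = []
    for i in range(n - 1):
        d = points[i + 1] - points[i]
        speeds.append(f * math.sqrt(d[0] ** 2 + d[1] ** 2 + d[2] ** 2))
    speeds.append(speeds[-1])
    travel = [0.0]
    for i in range(n - 1):
        travel.append(travel[-1] + speeds[i] / f)
    mean = sum(speeds) / n
    var = sum((v - mean) ** 2 for v in speeds) / (n - 1)
    return {
        "speeds": np.array(speeds),
        "travel": np.array(travel),
        "v_mean": mean,
        "v_std": math.sqrt(var),
        "v_max": max(speeds),
        "total_length": travel[-1],
    }


def naive_swept(points: np.ndarray, f: float) -> dict:
    n = len(points)
    areas, alphas = [], []
    for i in range(n - 1):
        a, b = points[i], points[i + 1]
        cx = a[1] * b[2] - a[2] * b[1]
        cy = a[2] * b[0] - a[0] * b[2]
        cz = a[0] * b[1] - a[1] * b[0]
        s = 0.5 * math.sqrt(cx * cx + cy * cy + cz * cz)
        areas.append(s)
        na = math.sqrt(a @ a)
        nb = math.sqrt(b @ b)
        h = 2.0 * s / na
        alphas.append(math.asin(min(max(h / nb, -1.0), 1.0)))
    omegas = [math.degrees(al) * f for al in alphas]
    om_mean = sum(omegas) / len(omegas)
    om_var = (sum((w - om_mean) ** 2 for w in omegas) / (len(omegas) - 1)
              if len(omegas) > 1 else 0.0)
    radii = [math.sqrt(p @ p) for p in points]
    hodo = naive_hodograph(points, f)
    return {
        "swept_area": sum(areas),
        "total_angle_deg": math.degrees(sum(alphas)),
        "omega_mean": om_mean,
        "omega_std": math.sqrt(om_var),
        "omega_max": max(omegas),
        "mean_rate": math.degrees(hodo["v_mean"] / (sum(radii) / n)),
        "angles": np.array(alphas),
        "angular_speeds": np.array(omegas),
    }


def naive_principal_axes(points: np.ndarray) -> dict:
    n = len(points)
    centre = np.zeros(3)
    for p in points:
        centre += p
    centre /= n
    inertia = np.zeros((3, 3))
    for p in points:
        q = p - centre
        inertia += (q @ q) * np.eye(3) - np.outer(q, q)
    evals, evecs = np.linalg.eigh(inertia)
    g1 = evecs[:, int(np.argmin(evals))]
    k = int(np.argmax(np.abs(g1)))
    if g1[k] < 0:
        g1 = -g1
    c = np.cross(centre, g1)
    nc = np.linalg.norm(c)
    if nc < max(1e-12, 1e-9 * max(np.linalg.norm(centre), 1.0)):
        e = np.zeros(3)
        e[int(np.argmin(np.abs(g1)))] = 1.0
        g2 = np.cross(g1, e)
        g2 /= np.linalg.norm(g2)
    else:
        g2 = c / nc
    g3 = np.cross(g1, g2)
    axes = [g1, g2, g3]
    q_min, q_max = [], []
    for ax in axes:
        projs = [float((p - centre) @ ax) for p in points]
        q_min.append(min(projs))
        q_max.append(max(projs))
    b1 = [centre + q_min[i] * axes[i] for i in range(3)]
    b2 = [centre + q_max[i] * axes[i] for i in range(3)]
    phib, lb = [], []
    for i in range(3):
        n1 = math.sqrt(b1[i] @ b1[i])
        n2 = math.sqrt(b2[i] @ b2[i])
        cosang = float(b1[i] @ b2[i]) / (n1 * n2)
        phib.append(math.degrees(math.acos(min(max(cosang, -1.0), 1.0))))
        lb.append(math.sqrt((b1[i] - b2[i]) @ (b1[i] - b2[i])))
    return {
        "centre": centre, "g1": g1, "g2": g2, "g3": g3,
        "q_min": np.array(q_min), "q_max": np.array(q_max),
        "b1": np.array(b1), "b2": np.array(b2),
        "angles_of_view": np.array(phib), "sizes": np.array(lb),
    }


def naive_agreement(a: np.ndarray, b: np.ndarray) -> dict:
    n = len(a)
    ma = sum(a) / n
    mb = sum(b) / n
    cov = sum((x - ma) * (y - mb) for x, y in zip(a, b))
    va = sum((x - ma) ** 2 for x in a)
    vb = sum((y - mb) ** 2 for y in b)
    r = cov / math.sqrt(va * vb)
    d = [x - y for x, y in zip(a, b)]
    md = sum(d) / n
    sd = math.sqrt(sum((x - md) ** 2 for x in d) / (n - 1))
    pooled = (sum(a) + sum(b)) / (2 * n)
    return {"r": r, "rcp": 100 * 1.96 * sd / abs(pooled),
            "cv": 100 * sd / abs(pooled)}


def random_trajectory(rng: np.random.Generator, n: int | None = None,
                      offset: float = 0.6) -> np.ndarray:
    """A random smooth-ish cloud kept away from the origin."""
    if n is None:
        n = int(rng.integers(5, 51))
    base = rng.normal(0.0, 0.15, size=(n, 3))
    shift = rng.normal(0.0, 1.0, size=3)
    shift = offset * shift / np.linalg.norm(shift) + rng.normal(0, 0.05, 3)
    return base + shift
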