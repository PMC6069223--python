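"""The 41 trajectory-shape parameters of one relative joint trajectory.

Given a trajectory ``p_i`` (i = 1..N, metres, parent-LCS coordinates, fixed
frequency f) the descriptors fall into four families:

* **hodograph kinematics** — per-sample speed ``v_i = f·‖p_{i+1} − p_i‖``,
  cumulative travel ``L_i``, and the angle swept per step as seen from the
  LCS origin: with triangle areas ``S_i = ½‖p_i × p_{i+1}‖`` and triangle
  height ``h_i = 2 S_i / ‖p_i‖``, the step angle is
  ``α_i = arcsin(h_i / ‖p_{i+1}‖)`` and the total angular travel is
  ``Φ_N = (180/π) Σ α_i``; angular speeds ``ω_i = (180/π) f α_i``.
* **principal axes of the point cloud** — the cloud is centred
  (``q_i = p_i − p_mean``) and its point-mass inertia tensor
  ``I = Σ (q_iᵀq_i)E − q_i q_iᵀ`` diagonalized; the main axis G1 is the
  direction of maximum spread (minimum inertia eigenvalue), G2 is the unit
  cross product ``p_mean × G1`` (perpendicular to the plane of G1 and the
  radius vector of the cloud centre), and G3 = G1 × G2.  Min/max projections
  on the axes give the axis end points B, their angles of view from the LCS
  origin, axis sizes, the mid-rhomboid area ``S_mid = LB₁·LB₂/2`` and the
  diamond (bipyramid) volume ``Vol = S_mid·LB₃/3``.
* **sphere fit** — algebraic (Kåsa) least squares refined geometrically;
  radius, centre offset, residual statistics.
* **hull metrics** — convex-hull surface area, the conic volume with apex at
  the LCS origin (signed tetrahedron sum, equal to the hull volume), and the
  solid angles subtended at the origin by the fitted sphere and by the
  origin-facing hull facets.

Everything is computed in SI and converted to the reporting units (mm, cm²,
cm³, deg, m/s, deg/s, sr) only when the 41-entry feature vector is
assembled.  Degenerate geometry (planar clouds, rays through the origin)
produces NaN entries with an explicit flag, never a silent number.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial import ConvexHull, QhullError

from .errors import FeatureError
from .kinematics import RelativeTrajectory

__all__ = [
    "PARAMETER_TABLE",
    "Hodograph",
    "PrincipalAxes",
    "SphereFit",
    "HullMetrics",
    "FeatureVector",
    "hodograph_kinematics",
    "swept_area_and_angle",
    "principal_axes",
    "rhomboid_diamond",
    "fit_sphere",
    "hull_metrics",
    "compute_feature_vector",
]

_EPS = 1e-12
_RAD2DEG = 180.0 / np.pi

#: (index, name, unit, scale from SI to reporting unit)
PARAMETER_TABLE: tuple[tuple[int, str, str, float], ...] = (
    (1, "trajectory_length", "m", 1.0),
    (2, "total_angle", "deg", 1.0),
    (3, "velocity_mean", "m/s", 1.0),
    (4, "velocity_std", "m/s", 1.0),
    (5, "velocity_max", "m/s", 1.0),
    (6, "angular_velocity_mean", "deg/s", 1.0),
    (7, "angular_velocity_std", "deg/s", 1.0),
    (8, "angular_velocity_max", "deg/s", 1.0),
    (9, "angular_velocity_from_radius", "deg/s", 1.0),
    (10, "rhomboid_area", "cm2", 1e4),
    (11, "diamond_volume", "cm3", 1e6),
    (12, "axis1_angle_of_view", "deg", 1.0),
    (13, "axis2_angle_of_view", "deg", 1.0),
    (14, "axis1_size", "mm", 1e3),
    (15, "axis2_size", "mm", 1e3),
    (16, "cloud_centre_x", "mm", 1e3),
    (17, "cloud_centre_y", "mm", 1e3),
    (18, "cloud_centre_z", "mm", 1e3),
    (19, "axis1_end1_x", "mm", 1e3),
    (20, "axis1_end1_y", "mm", 1e3),
    (21, "axis1_end1_z", "mm", 1e3),
    (22, "axis1_end2_x", "mm", 1e3),
    (23, "axis1_end2_y", "mm", 1e3),
    (24, "axis1_end2_z", "mm", 1e3),
    (25, "axis2_end1_x", "mm", 1e3),
    (26, "axis2_end1_y", "mm", 1e3),
    (27, "axis2_end1_z", "mm", 1e3),
    (28, "axis2_end2_x", "mm", 1e3),
    (29, "axis2_end2_y", "mm", 1e3),
    (30, "axis2_end2_z", "mm", 1e3),
    (31, "sphere_radius", "mm", 1e3),
    (32, "sphere_centre_distance", "mm", 1e3),
    (33, "sphere_residual_mean", "mm", 1e3),
    (34, "sphere_residual_std", "mm", 1e3),
    (35, "sphere_centre_x", "mm", 1e3),
    (36, "sphere_centre_y", "mm", 1e3),
    (37, "sphere_centre_z", "mm", 1e3),
    (38, "hull_surface_area", "mm2", 1e6),
    (39, "conic_volume", "mm3", 1e9),
    (40, "sphere_solid_angle", "sr", 1.0),
    (41, "surface_solid_angle", "sr", 1.0),
)

PARAM_NAMES = {i: n for i, n, _, _ in PARAMETER_TABLE}
PARAM_UNITS = {i: u for i, _, u, _ in PARAMETER_TABLE}


# ---------------------------------------------------------------------------
# containers

@dataclass
class Hodograph:
    """Per-sample speed/travel/angle sequences plus their scalar summaries."""

    speeds: np.ndarray            # V, (N,), m/s — last value repeated
    travel: np.ndarray            # L_i, (N,), m, cumulative, L_1 = 0
    angles: np.ndarray            # α_i, (N−1,), rad
    angular_speeds: np.ndarray    # Ω, (N−1,), deg/s
    v_mean: float
    v_std: float
    v_max: float
    omega_mean: float
    omega_std: float
    omega_max: float
    total_length: float           # L_N, m
    total_angle_deg: float        # Φ_N
    swept_area: float             # Δ_N, m² (auxiliary; not in the 41-vector)
    mean_rate: float              # parameter 9, deg/s


@dataclass
class PrincipalAxes:
    centre: np.ndarray            # p_mean, (3,), m
    axes: np.ndarray              # G, (3, 3), columns G1..G3, orthonormal
    q_min: np.ndarray             # (3,), m
    q_max: np.ndarray             # (3,), m
    b1: np.ndarray                # (3, 3), rows = B1_i per axis
    b2: np.ndarray                # (3, 3), rows = B2_i per axis
    angles_of_view: np.ndarray    # ΦB_i, (3,), deg
    sizes: np.ndarray             # LB_i, (3,), m
    g2_fallback: bool = False     # cloud centre (near-)parallel to G1


@dataclass
class SphereFit:
    centre: np.ndarray            # (3,), m
    radius: float                 # m
    centre_distance: float        # ‖centre‖, m
    residual_mean: float          # mean |‖p−c‖ − r|, m
    residual_std: float           # std of signed residuals, m
    degenerate: bool = False


@dataclass
class HullMetrics:
    surface_area: float           # m²
    conic_volume: float           # m³
    sphere_solid_angle: float     # sr
    surface_solid_angle: float    # sr
    degenerate: bool = False


@dataclass
class FeatureVector:
    """The 41 named parameter values for one trajectory, reporting units."""

    label: str
    n: int
    frequency: float
    values: np.ndarray                      # (41,), PARAMETER_TABLE order/units
    flags: dict[int, str] = field(default_factory=dict)
    aux: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (41,):
            raise FeatureError(f"feature vector must have 41 entries, got "
                               f"{self.values.shape}")
        bad = [i + 1 for i in range(41)
               if not np.isfinite(self.values[i]) and (i + 1) not in self.flags]
        if bad:
            raise FeatureError(f"unflagged non-finite parameters: {bad}")

    def __getitem__(self, param_index: int) -> float:
        return float(self.values[param_index - 1])

    def as_dict(self) -> dict[str, float]:
        return {PARAM_NAMES[i]: self[i] for i in range(1, 42)}


# ---------------------------------------------------------------------------
# hodograph

def _check(traj: RelativeTrajectory, min_n: int) -> np.ndarray:
    p = np.asarray(traj.points, dtype=float)
    if p.shape[0] < min_n:
        raise FeatureError(
            f"trajectory {traj.label!r}: need at least {min_n} points, got {p.shape[0]}"
        )
    if traj.frequency <= 0:
        raise FeatureError("frequency must be > 0")
    return p


def hodograph_kinematics(traj: RelativeTrajectory) -> Hodograph:
    """Speeds, travel and their scalar statistics (forward differences).

    The speed sequence has length N with the last value repeated; standard
    deviations use the N−1 divisor.  Angular quantities are filled in by
    :func:`swept_area_and_angle`; this function leaves them empty.
    """
    p = _check(traj, 2)
    f = traj.frequency
    step = np.linalg.norm(np.diff(p, axis=0), axis=1)      # (N−1,)
    speeds = np.concatenate([f * step, [f * step[-1]]])    # repeat last → N
    travel = np.concatenate([[0.0], np.cumsum(step)])
    v_mean = float(np.mean(speeds))
    v_std = float(np.std(speeds, ddof=1))
    v_max = float(np.max(speeds))
    empty = np.empty(0)
    return Hodograph(
        speeds=speeds, travel=travel, angles=empty, angular_speeds=empty,
        v_mean=v_mean, v_std=v_std, v_max=v_max,
        omega_mean=np.nan, omega_std=np.nan, omega_max=np.nan,
        total_length=float(travel[-1]), total_angle_deg=np.nan,
        swept_area=np.nan, mean_rate=np.nan,
    )


def swept_area_and_angle(traj: RelativeTrajectory) -> Hodograph:
    """Swept area Δ_N, total angle Φ_N and angular-speed statistics.

    Per step, ``S_i`` is the area of the triangle (origin, p_i, p_{i+1});
    the subtended angle uses the triangle height over the ray through p_i,
    ``α_i = arcsin(2S_i / (‖p_i‖ ‖p_{i+1}‖))`` with the arcsin argument
    clamped to [−1, 1] against floating-point overshoot.  Steps subtending
    more than 90° are under-counted by construction (arcsin range); no
    correction is applied.  Parameter 9 is the mean speed divided by the
    mean radius, in deg/s.
    """
    p = _check(traj, 2)
    f = traj.frequency
    radii = np.linalg.norm(p, axis=1)
    if (radii < _EPS).any():
        i0 = int(np.flatnonzero(radii < _EPS)[0])
        raise FeatureError(
            f"trajectory {traj.label!r}: point {i0} at the LCS origin — "
            "subtended angle undefined"
        )
    cross = np.cross(p[:-1], p[1:])
    areas = 0.5 * np.linalg.norm(cross, axis=1)            # S_i
    h = 2.0 * areas / radii[:-1]                           # h_i = 2S_i/‖p_i‖
    alphas = np.arcsin(np.clip(h / radii[1:], -1.0, 1.0))  # rad
    omegas = _RAD2DEG * f * alphas                         # deg/s
    hodo = hodograph_kinematics(traj)
    hodo.angles = alphas
    hodo.angular_speeds = omegas
    hodo.swept_area = float(np.sum(areas))
    hodo.total_angle_deg = float(_RAD2DEG * np.sum(alphas))
    hodo.omega_mean = float(np.mean(omegas))
    hodo.omega_std = float(np.std(omegas, ddof=1)) if len(omegas) > 1 else 0.0
    hodo.omega_max = float(np.max(omegas))
    hodo.mean_rate = float(_RAD2DEG * hodo.v_mean / np.mean(radii))
    return hodo


# ---------------------------------------------------------------------------
# principal axes

def _fix_sign(v: np.ndarray) -> np.ndarray:
    """Deterministic eigenvector sign: largest-|component| entry positive."""
    k = int(np.argmax(np.abs(v)))
    return -v if v[k] < 0 else v


def _smallest_component_perp(u: np.ndarray) -> np.ndarray:
    """A deterministic unit vector perpendicular to unit vector *u*."""
    e = np.zeros(3)
    e[int(np.argmin(np.abs(u)))] = 1.0
    w = np.cross(u, e)
    return w / np.linalg.norm(w)


def principal_axes(traj: RelativeTrajectory) -> PrincipalAxes:
    """Inertia-based principal axes, extents and end points of the cloud."""
    p = _check(traj, 3)
    centre = p.mean(axis=0)
    q = p - centre
    if np.linalg.norm(q, axis=1).max() < _EPS:
        raise FeatureError(f"trajectory {traj.label!r}: all points coincident")
    # total point-mass inertia: Σ (qᵀq)E − q qᵀ; the max-spread direction is
    # the minimum-inertia eigenvector (eigh returns ascending eigenvalues)
    sq = np.einsum("ij,ij->i", q, q).sum()
    inertia = sq * np.eye(3) - q.T @ q
    _, vecs = np.linalg.eigh(inertia)
    g1 = _fix_sign(vecs[:, 0])
    fallback = False
    c = np.cross(centre, g1)
    norm_c = np.linalg.norm(c)
    if norm_c < max(_EPS, 1e-9 * max(np.linalg.norm(centre), 1.0)):
        g2 = _smallest_component_perp(g1)
        fallback = True
    else:
        g2 = c / norm_c
    g3 = np.cross(g1, g2)
    g = np.column_stack([g1, g2, g3])
    q_g = q @ g                       # (N, 3) projections on the axes
    q_min = q_g.min(axis=0)
    q_max = q_g.max(axis=0)
    b1 = centre[None, :] + q_min[:, None] * g.T   # rows: B1_i = centre + QMin_i·G_i
    b2 = centre[None, :] + q_max[:, None] * g.T
    n1 = np.linalg.norm(b1, axis=1)
    n2 = np.linalg.norm(b2, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("ij,ij->i", b1, b2) / (n1 * n2)
    angles = _RAD2DEG * np.arccos(np.clip(cosang, -1.0, 1.0))
    sizes = np.linalg.norm(b1 - b2, axis=1)
    return PrincipalAxes(centre=centre, axes=g, q_min=q_min, q_max=q_max,
                         b1=b1, b2=b2, angles_of_view=angles, sizes=sizes,
                         g2_fallback=fallback)


def rhomboid_diamond(axes: PrincipalAxes) -> tuple[float, float]:
    """Mid-rhomboid area and diamond volume, in SI (m², m³).

    ``S_mid = LB₁·LB₂/2`` and ``Vol = S_mid·LB₃/3`` (two pyramids over the
    rhomboid).  Unit conversion to cm²/cm³ happens at reporting.
    """
    lb = axes.sizes
    s_mid = float(lb[0] * lb[1] / 2.0)
    vol = float(s_mid * lb[2] / 3.0)
    return s_mid, vol


# ---------------------------------------------------------------------------
# sphere fit

def fit_sphere(traj: RelativeTrajectory) -> SphereFit:
    """Least-squares sphere through the cloud (Kåsa init, geometric refine).

    The algebraic stage solves the linear system ``[2p | 1]·[c; k] = ‖p‖²``;
    the geometric stage minimises ``‖p_i − c‖ − r`` with
    ``scipy.optimize.least_squares``.  A coplanar/collinear cloud makes the
    system singular: the fit is returned flagged degenerate with NaN radius,
    never a silently huge sphere.
    """
    p = _check(traj, 4)
    design = np.column_stack([2.0 * p, np.ones(len(p))])
    rhs = np.einsum("ij,ij->i", p, p)
    sol, _, rank, sv = np.linalg.lstsq(design, rhs, rcond=None)
    span = np.ptp(p, axis=0).max()
    if rank < 4 or sv[-1] < 1e-9 * sv[0] or span < _EPS:
        nan3 = np.full(3, np.nan)
        return SphereFit(centre=nan3, radius=np.nan, centre_distance=np.nan,
                         residual_mean=np.nan, residual_std=np.nan, degenerate=True)
    c0 = sol[:3]
    r0 = float(np.sqrt(max(sol[3] + c0 @ c0, 0.0)))

    def resid(x: np.ndarray) -> np.ndarray:
        return np.linalg.norm(p - x[:3], axis=1) - x[3]

    fit = least_squares(resid, np.r_[c0, r0], method="lm", xtol=1e-14, ftol=1e-14)
    centre, radius = fit.x[:3], float(abs(fit.x[3]))
    d = np.linalg.norm(p - centre, axis=1) - radius
    # a pathological fit (e.g. near-planar cloud escaping the rank check)
    # shows up as a radius far beyond the cloud span
    degenerate = bool(radius > 1e3 * max(span, 1e-6))
    return SphereFit(
        centre=centre, radius=radius,
        centre_distance=float(np.linalg.norm(centre)),
        residual_mean=float(np.mean(np.abs(d))),
        residual_std=float(np.std(d, ddof=1)) if len(d) > 1 else 0.0,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# hull metrics

def _triangle_solid_angle(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    """Solid angle of triangle (a, b, c) seen from the origin
    (van Oosterom–Strackee)."""
    na, nb, nc = (np.linalg.norm(v) for v in (a, b, c))
    numer = float(np.dot(a, np.cross(b, c)))
    denom = na * nb * nc + np.dot(a, b) * nc + np.dot(a, c) * nb + np.dot(b, c) * na
    return 2.0 * float(np.arctan2(abs(numer), denom))


def sphere_cap_solid_angle(radius: float, distance: float) -> float:
    """Solid angle of a sphere of *radius* seen from *distance* away.

    ``2π(1 − √(1 − (r/d)²))`` for d > r; the full 4π when the viewpoint is
    inside or on the sphere.
    """
    if not np.isfinite(radius) or not np.isfinite(distance):
        return np.nan
    if distance <= radius:
        return 4.0 * np.pi
    return float(2.0 * np.pi * (1.0 - np.sqrt(1.0 - (radius / distance) ** 2)))


def hull_metrics(traj: RelativeTrajectory, sphere: SphereFit | None = None) -> HullMetrics:
    """Convex-hull surface area, conic volume and solid angles at the origin.

    The conic volume (apex at the LCS origin) is the signed tetrahedron sum
    over outward-oriented hull facets, which by the divergence theorem equals
    the hull volume for any apex position.  The surface solid angle sums the
    absolute spherical-triangle solid angles of the facets whose outer side
    faces the origin, capped at 4π; an origin enclosed by the hull subtends
    the full 4π.  A coplanar cloud is flagged degenerate: the planar hull
    area is reported, the volume is 0.
    """
    p = _check(traj, 4)
    if sphere is None:
        sphere = fit_sphere(traj)
    sph_sa = sphere_cap_solid_angle(sphere.radius, sphere.centre_distance)
    try:
        hull = ConvexHull(p)
    except QhullError:
        # coplanar or collinear cloud: 2D hull in its best plane
        centred = p - p.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        flat = centred @ vt[:2].T
        try:
            hull2 = ConvexHull(flat)
            area2 = float(hull2.volume)  # 2D "volume" is the polygon area
        except QhullError:
            area2 = 0.0
        return HullMetrics(surface_area=area2, conic_volume=0.0,
                           sphere_solid_angle=sph_sa,
                           surface_solid_angle=np.nan, degenerate=True)

    # equations: n·x + d = 0 with outward unit normal n, so −d is the signed
    # height of each facet plane above the origin
    offsets = -hull.equations[:, 3]
    tri = p[hull.simplices]                                # (F, 3, 3)
    facet_areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    conic_volume = float(np.sum(facet_areas * offsets) / 3.0)

    facing = offsets < 0.0  # origin on the outer side of the facet plane
    if not facing.any():
        surf_sa = 4.0 * np.pi  # origin inside the hull
    else:
        surf_sa = sum(
            _triangle_solid_angle(*tri[i]) for i in np.flatnonzero(facing)
        )
        surf_sa = float(min(surf_sa, 4.0 * np.pi))
    return HullMetrics(surface_area=float(hull.area), conic_volume=conic_volume,
                       sphere_solid_angle=sph_sa, surface_solid_angle=surf_sa,
                       degenerate=False)


# ---------------------------------------------------------------------------
# assembly

def compute_feature_vector(traj: RelativeTrajectory) -> FeatureVector:
    """Assemble all 41 parameters in table order with reporting units."""
    _check(traj, 4)
    hodo = swept_area_and_angle(traj)
    axes = principal_axes(traj)
    s_mid, vol = rhomboid_diamond(axes)
    sphere = fit_sphere(traj)
    hull = hull_metrics(traj, sphere)

    si = np.empty(41)
    flags: dict[int, str] = {}
    si[0] = hodo.total_length
    si[1] = hodo.total_angle_deg
    si[2:5] = hodo.v_mean, hodo.v_std, hodo.v_max
    si[5:8] = hodo.omega_mean, hodo.omega_std, hodo.omega_max
    si[8] = hodo.mean_rate
    si[9] = s_mid
    si[10] = vol
    si[11:13] = axes.angles_of_view[:2]
    si[13:15] = axes.sizes[:2]
    si[15:18] = axes.centre
    si[18:21] = axes.b1[0]
    si[21:24] = axes.b2[0]
    si[24:27] = axes.b1[1]
    si[27:30] = axes.b2[1]
    si[30] = sphere.radius
    si[31] = sphere.centre_distance
    si[32] = sphere.residual_mean
    si[33] = sphere.residual_std
    si[34:37] = sphere.centre
    si[37] = hull.surface_area
    si[38] = hull.conic_volume
    si[39] = hull.sphere_solid_angle
    si[40] = hull.surface_solid_angle

    if axes.g2_fallback:
        for i in (13, 25, 26, 27, 28, 29, 30):
            flags[i] = "g2_fallback"
    if sphere.degenerate:
        for i in range(31, 38):
            flags[i] = "degenerate_sphere_fit"
        flags[40] = "degenerate_sphere_fit"
    if hull.degenerate:
        flags.setdefault(39, "degenerate_hull")
        flags.setdefault(41, "degenerate_hull")

    scales = np.array([s for _, _, _, s in PARAMETER_TABLE])
    values = si * scales
    for i in range(1, 42):  # residual degenerate geometry (e.g. end point at origin)
        if not np.isfinite(values[i - 1]):
            flags.setdefault(i, "degenerate_geometry")
    aux = {
        "swept_area_m2": hodo.swept_area,
        "axis3_size_m": float(axes.sizes[2]),
        "axis3_angle_of_view_deg": float(axes.angles_of_view[2]),
    }
    return FeatureVector(label=traj.label, n=traj.n, frequency=traj.frequency,
                         values=values, flags=flags, aux=aux)


def feature_frame(vectors: Iterable[FeatureVector]):
    """Long-format DataFrame (trajectory, param_index, param_name, unit,
    value, flag) for a set of feature vectors."""
    import pandas as pd

    rows = []
    for fv in vectors:
        for i, name, unit, _ in PARAMETER_TABLE:
            rows.append({
                "trajectory": fv.label, "param_index": i, "param_name": name,
                "unit": unit, "value": fv[i], "flag": fv.flags.get(i, ""),
            })
    return pd.DataFrame(rows)
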