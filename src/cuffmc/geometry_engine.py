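"""Muscle-path geometry: vector strings with wrapping, frames, moment arms.

Muscles are modelled as taut strings from origin to insertion that may wrap
around spherical (humeral head) and cylindrical (humeral shaft) obstacles,
the classic obstacle-set formulation. The glenoid carries a local orthonormal
frame (x anterior-posterior, y superior-inferior from centroid to the superior
landmark, z lateral = compression direction); glenoid inclination is varied by
rotating the superior landmark about the x-axis.

Angles are degrees in the public interface and radians internally. All
positions are metres in a right-handed world frame (x anterior, y superior,
z lateral-right).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

logger = logging.getLogger(__name__)

_ARC_STEP_RAD = np.deg2rad(10.0)  # wrap arcs discretised for via points


def _unit(v: np.ndarray, name: str = "vector") -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise ValueError(f"cannot normalize near-zero {name}")
    return v / n


@dataclass(frozen=True)
class WrapSphere:
    center: np.ndarray
    radius: float


@dataclass(frozen=True)
class WrapCylinder:
    point: np.ndarray      # a point on the axis
    axis: np.ndarray       # unit axis direction
    radius: float


@dataclass(frozen=True)
class MusclePath:
    """A solved muscle vector string (origin first, insertion last)."""

    element: str
    via_points: np.ndarray            # (k, 3), k >= 2
    effective_origin_direction: np.ndarray  # unit pull direction at insertion
    path_length: float
    moment_arm: np.ndarray | None = None

    @property
    def origin(self) -> np.ndarray:
        return self.via_points[0]

    @property
    def insertion(self) -> np.ndarray:
        return self.via_points[-1]


@dataclass(frozen=True)
class GlenoidFrame:
    centroid: np.ndarray
    superior_point: np.ndarray
    x_axis: np.ndarray   # anterior
    y_axis: np.ndarray   # superior (centroid -> superior landmark)
    z_axis: np.ndarray   # lateral, compression direction
    inclination_angle_deg: float = 0.0


def build_glenoid_frame(
    centroid: np.ndarray,
    superior_point: np.ndarray,
    anterior_hint: np.ndarray = (1.0, 0.0, 0.0),
    inclination_angle_deg: float = 0.0,
) -> GlenoidFrame:
    """Orthonormal glenoid frame from the centroid and superior landmark."""
    centroid = np.asarray(centroid, dtype=float)
    superior_point = np.asarray(superior_point, dtype=float)
    y = _unit(superior_point - centroid, "glenoid y-axis")
    hint = np.asarray(anterior_hint, dtype=float)
    x = hint - np.dot(hint, y) * y
    x = _unit(x, "glenoid x-axis")
    z = np.cross(x, y)
    return GlenoidFrame(
        centroid=centroid,
        superior_point=superior_point,
        x_axis=x,
        y_axis=y,
        z_axis=z,
        inclination_angle_deg=inclination_angle_deg,
    )


def incline_glenoid(frame: GlenoidFrame, superior_point_shift_cm: float) -> GlenoidFrame:
    """Rotate the superior glenoid landmark about the anterior-posterior axis.

    ``superior_point_shift_cm`` is the arc-length shift of the superior
    landmark along the rotation arc, in centimetres; the induced inclination
    change is atan(shift / lever) where the lever is the centroid-to-superior
    distance. Positive shifts incline the glenoid face superiorly (rotation
    about +x through the centroid). The centroid and x-axis are preserved.
    """
    arm = frame.superior_point - frame.centroid
    dist_cm = np.linalg.norm(arm) * 100.0
    if dist_cm < 1e-9:
        raise ValueError("degenerate glenoid frame: superior point equals centroid")
    angle = np.arctan2(superior_point_shift_cm, dist_cm)
    c, s = np.cos(angle), np.sin(angle)
    x = frame.x_axis
    # Rodrigues rotation of the centroid->superior vector about x
    rotated = arm * c + np.cross(x, arm) * s + x * np.dot(x, arm) * (1.0 - c)
    return build_glenoid_frame(
        frame.centroid,
        frame.centroid + rotated,
        anterior_hint=x,
        inclination_angle_deg=frame.inclination_angle_deg + np.rad2deg(angle),
    )


class ClampCounter:
    """Counts attachment draws clamped to the bone's bounding box."""

    def __init__(self):
        self.count = 0

    def reset(self):
        self.count = 0


clamp_counter = ClampCounter()


def perturb_attachment(
    mean: np.ndarray,
    sd: np.ndarray,
    draw: np.ndarray,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Shift an attachment coordinate by ``sd * draw`` per axis.

    ``draw`` holds standard-normal deviates. When ``bounds`` (lower, upper
    fraction vectors) is given, the result is clamped into the bone's
    attachment bounding box and the clamp is counted and logged; clamping
    rather than rejection keeps Monte Carlo iteration counts exact.
    Broadcasts over leading dimensions of ``draw``.
    """
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    if np.any(sd < 0):
        raise ValueError("sd components must be >= 0")
    value = mean + sd * np.asarray(draw, dtype=float)
    if bounds is not None:
        lo, hi = bounds
        clipped = np.clip(value, lo, hi)
        n_clamped = int(np.sum(np.any(np.atleast_2d(clipped != value), axis=-1)))
        if n_clamped:
            clamp_counter.count += n_clamped
            logger.warning(
                "clamped %d attachment draw(s) to the bone bounding box", n_clamped
            )
        value = clipped
    return value


def couple_elements(parent_coords: np.ndarray, offsets: np.ndarray) -> np.ndarray:
    """Child attachment from a parent coordinate and fractional offsets.

    child = parent * (1 + offset) per axis, so children translate rigidly
    (per-axis ratio preserved) with every parent perturbation.
    """
    parent = np.asarray(parent_coords, dtype=float)
    offsets = np.asarray(offsets, dtype=float)
    bad = (parent == 0.0) & (offsets != 0.0)
    if np.any(bad):
        raise ValueError(
            "undefined percentage base: parent coordinate is zero on axis "
            f"{np.nonzero(bad)[0].tolist()} with nonzero relative offset"
        )
    return parent * (1.0 + offsets)


# ---------------------------------------------------------------------------
# path solving

def _straight_path(element: str, origin: np.ndarray, insertion: np.ndarray) -> MusclePath:
    u = _unit(origin - insertion, "muscle line of action")
    return MusclePath(
        element=element,
        via_points=np.vstack([origin, insertion]),
        effective_origin_direction=u,
        path_length=float(np.linalg.norm(insertion - origin)),
    )


def _segment_hits_sphere(o: np.ndarray, i: np.ndarray, c: np.ndarray, r: float) -> bool:
    w = i - o
    denom = np.dot(w, w)
    if denom < 1e-18:
        return False
    t = np.clip(np.dot(c - o, w) / denom, 0.0, 1.0)
    closest = o + t * w
    # only interior crossings count; endpoint grazing is handled by tangency
    return bool(np.linalg.norm(closest - c) < r - 1e-12 and 0.0 < t < 1.0)


def _wrap_sphere(
    element: str, origin: np.ndarray, insertion: np.ndarray, wrap: WrapSphere
) -> MusclePath | None:
    c, r = np.asarray(wrap.center, dtype=float), wrap.radius
    d_o = np.linalg.norm(origin - c)
    d_i = np.linalg.norm(insertion - c)
    if d_o < r - 1e-12 or d_i < r - 1e-12:
        raise ValueError(f"{element}: attachment lies inside wrap sphere")
    if not _segment_hits_sphere(origin, insertion, c, r):
        return None
    # geodesic lies in the plane through origin, insertion and the centre
    e1 = _unit(origin - c, "sphere wrap basis")
    normal = np.cross(origin - c, insertion - c)
    if np.linalg.norm(normal) < 1e-12:
        # collinear through the centre: plane undefined, pick any perpendicular
        probe = np.array([1.0, 0.0, 0.0])
        if abs(np.dot(probe, e1)) > 0.9:
            probe = np.array([0.0, 1.0, 0.0])
        normal = np.cross(e1, probe)
    n = _unit(normal, "sphere wrap normal")
    e2 = np.cross(n, e1)
    gamma = np.arctan2(np.dot(insertion - c, e2), np.dot(insertion - c, e1))
    if gamma < 0:
        e2, n, gamma = -e2, -n, -gamma
    phi_o = np.arccos(np.clip(r / d_o, -1.0, 1.0))
    phi_i = gamma - np.arccos(np.clip(r / d_i, -1.0, 1.0))
    arc = phi_i - phi_o
    if arc <= 1e-12:
        return None  # tangents clear the sphere
    t_o = np.sqrt(max(d_o**2 - r**2, 0.0))
    t_i = np.sqrt(max(d_i**2 - r**2, 0.0))
    length = t_o + r * arc + t_i
    n_arc = max(int(np.ceil(arc / _ARC_STEP_RAD)), 1)
    phis = np.linspace(phi_o, phi_i, n_arc + 1)
    arc_pts = c + r * (np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2)
    via = np.vstack([origin, arc_pts, insertion])
    u = _unit(via[-2] - insertion, "wrap pull direction")
    return MusclePath(
        element=element,
        via_points=via,
        effective_origin_direction=u,
        path_length=float(length),
    )


def _wrap_cylinder(
    element: str, origin: np.ndarray, insertion: np.ndarray, wrap: WrapCylinder
) -> MusclePath | None:
    a = _unit(np.asarray(wrap.axis, dtype=float), "cylinder axis")
    p = np.asarray(wrap.point, dtype=float)
    r = wrap.radius
    # planar basis perpendicular to the axis
    probe = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(probe, a)) > 0.9:
        probe = np.array([0.0, 0.0, 1.0])
    e1 = _unit(probe - np.dot(probe, a) * a, "cylinder basis")
    e2 = np.cross(a, e1)

    def flatten(x):
        rel = x - p
        return np.array([np.dot(rel, e1), np.dot(rel, e2)]), np.dot(rel, a)

    o2, z_o = flatten(origin)
    i2, z_i = flatten(insertion)
    d_o, d_i = np.linalg.norm(o2), np.linalg.norm(i2)
    if d_o < r - 1e-12 or d_i < r - 1e-12:
        raise ValueError(f"{element}: attachment lies inside wrap cylinder")
    # does the planar segment cross the circle?
    w = i2 - o2
    denom = np.dot(w, w)
    if denom < 1e-18:
        return None
    t = np.clip(-np.dot(o2, w) / denom, 0.0, 1.0)
    if np.linalg.norm(o2 + t * w) >= r - 1e-12 or not (0.0 < t < 1.0):
        return None
    ang_o = np.arctan2(o2[1], o2[0])
    gamma = np.arctan2(i2[1], i2[0]) - ang_o
    gamma = (gamma + np.pi) % (2 * np.pi) - np.pi  # short way around
    sign = 1.0 if gamma >= 0 else -1.0
    g = abs(gamma)
    phi_o = sign * np.arccos(np.clip(r / d_o, -1.0, 1.0))
    phi_i = sign * (g - np.arccos(np.clip(r / d_i, -1.0, 1.0)))
    arc = sign * (phi_i - phi_o)
    if arc <= 1e-12:
        return None
    t_o = np.sqrt(max(d_o**2 - r**2, 0.0))
    t_i = np.sqrt(max(d_i**2 - r**2, 0.0))
    planar_len = t_o + r * arc + t_i
    dz = z_i - z_o
    length = np.hypot(planar_len, dz)
    # axial coordinate interpolated by planar arc-length (unrolled geodesic)
    n_arc = max(int(np.ceil(arc / _ARC_STEP_RAD)), 1)
    phis = ang_o + phi_o + sign * np.linspace(0.0, arc, n_arc + 1)
    s_planar = t_o + r * np.linspace(0.0, arc, n_arc + 1)
    z_arc = z_o + dz * s_planar / planar_len
    arc_pts = (
        p
        + r * (np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2)
        + z_arc[:, None] * a
    )
    via = np.vstack([origin, arc_pts, insertion])
    u = _unit(via[-2] - insertion, "wrap pull direction")
    return MusclePath(
        element=element,
        via_points=via,
        effective_origin_direction=u,
        path_length=float(length),
    )


def solve_path(
    origin: np.ndarray,
    insertion: np.ndarray,
    wraps=(),
    element: str = "",
) -> MusclePath:
    """Shortest string path from origin to insertion around wrap obstacles.

    If the straight segment misses every obstacle the path is the straight
    line; otherwise the path wraps the obstructing obstacle (great-circle arc
    on spheres, unrolled tangent arc on cylinders). At most one obstacle is
    wrapped per element (the most deeply penetrated one).
    """
    origin = np.asarray(origin, dtype=float)
    insertion = np.asarray(insertion, dtype=float)
    if np.linalg.norm(origin - insertion) < 1e-12:
        raise ValueError("origin and insertion coincide")
    best = None
    for wrap in wraps:
        if isinstance(wrap, WrapSphere):
            candidate = _wrap_sphere(element, origin, insertion, wrap)
        elif isinstance(wrap, WrapCylinder):
            candidate = _wrap_cylinder(element, origin, insertion, wrap)
        else:
            raise TypeError(f"unknown wrap object {type(wrap)!r}")
        if candidate is not None and (best is None or candidate.path_length > best.path_length):
            best = candidate  # deepest penetration = longest detour
    return best if best is not None else _straight_path(element, origin, insertion)


def moment_arm(path: MusclePath, gh_center: np.ndarray) -> np.ndarray:
    """Geometric moment-arm vector of a muscle path about the joint centre.

    r x u, with r from the joint centre to the insertion (the effective
    application point) and u the unit pull direction of the joint-spanning
    segment. Satisfies the tendon-excursion identity
    dL/dtheta = -(r x u) . axis for rotations of the insertion-side bone.
    """
    r = path.insertion - np.asarray(gh_center, dtype=float)
    return np.cross(r, path.effective_origin_direction)


def with_moment_arm(path: MusclePath, gh_center: np.ndarray) -> MusclePath:
    return replace(path, moment_arm=moment_arm(path, gh_center))
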