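"""Synthetic study fixtures: support-phase postures and bone geometry.

The underlying deterministic models' raw kinematics and bone meshes are not
published, so this module generates idealized stand-ins with the documented
structure: three static support-phase instances of horizontal bimanual arm
suspension (arm elevated beyond 100 degrees, elbow near-extended, hand on the
overhead rung), and parametric scapula/humerus landmark sets with spherical
and cylindrical wrap obstacles scaled to species segment lengths.

Conventions. World frame: x anterior, y superior, z lateral-right; right arm;
glenohumeral (GH) joint centre at the origin. The stored humerothoracic
elevation is trunk-referenced (the suspended trunk leans), while the
world-frame tilt of the hanging arm from vertical is small, as in a loaded
pendulum. The generator is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .geometry_engine import WrapCylinder, WrapSphere
from .species_params import SpeciesParameterSet

SUPPORT_INSTANCES = ("early_support", "mid_support", "late_support")

#: Lever from glenoid centroid to the superior landmark of the glenoid
#: y-axis, chosen so the 0.3 cm inclination SD spans ~20 degrees over +/-3 SD:
#: distance = 3 sigma / tan(10 deg).
GLENOID_SUPERIOR_DISTANCE_M = 3 * 0.003 / np.tan(np.deg2rad(10.0))

#: Acromion marker offset from the GH centre in the reference (human) model.
ACROMION_OFFSET_M = np.array([0.0, 0.030, 0.005])

#: Fraction of hand length from the wrist to the grip point on the rung.
GRIP_FRACTION = 0.4

#: Per-instance idealized configuration: (humerothoracic elevation deg,
#: world-frame arm tilt from vertical deg [+ forward], forearm tilt deg).
#: The mid-support forearm tilt is solved so the grip point lies directly
#: above the GH centre.
_INSTANCE_PROGRAM = {
    "early_support": {"elevation": 151.0, "arm_tilt": 5.0, "forearm_tilt": 1.5},
    "mid_support": {"elevation": 168.0, "arm_tilt": 4.0, "forearm_tilt": None},
    "late_support": {"elevation": 158.0, "arm_tilt": -1.5, "forearm_tilt": -3.0},
}

#: Mid-support hand-over-joint tolerance (m), horizontal offset of the grip.
MID_SUPPORT_HAND_TOLERANCE_M = 0.02


@dataclass(frozen=True)
class Posture:
    """One static support-phase configuration of the right arm."""

    instance: str
    joint_centers: Mapping[str, np.ndarray]  # wrist, elbow, glenohumeral (m)
    humerothoracic_elevation_deg: float
    elbow_flexion_deg: float
    acromion_marker: np.ndarray

    def segment_length(self, segment: str) -> float:
        jc = self.joint_centers
        if segment == "arm":
            return float(np.linalg.norm(jc["elbow"] - jc["glenohumeral"]))
        if segment == "forearm":
            return float(np.linalg.norm(jc["wrist"] - jc["elbow"]))
        raise KeyError(segment)

    def forearm_direction(self) -> np.ndarray:
        v = self.joint_centers["wrist"] - self.joint_centers["elbow"]
        return v / np.linalg.norm(v)


@dataclass(frozen=True)
class BoneGeometry:
    """Parametric landmark set and wrap obstacles for one bone."""

    bone: str
    longitudinal_length_m: float
    landmark_set: Mapping[str, np.ndarray]
    wrap_objects: tuple


def _tilted(tilt_deg: float) -> np.ndarray:
    """Unit vector pointing upward, tilted ``tilt_deg`` toward anterior."""
    t = np.deg2rad(tilt_deg)
    return np.array([np.sin(t), np.cos(t), 0.0])


def generate_posture(
    instance: str, species: SpeciesParameterSet, seed: int
) -> Posture:
    """Deterministic idealized posture for one support instance and species.

    Elevation always exceeds 100 degrees and the elbow is near-extended.
    For mid support (single-limb support) the grip point is placed directly
    above the glenohumeral joint within ``MID_SUPPORT_HAND_TOLERANCE_M``.
    """
    if instance not in SUPPORT_INSTANCES:
        raise ValueError(f"unknown support instance {instance!r}")
    prog = _INSTANCE_PROGRAM[instance]
    rng = np.random.default_rng(
        np.random.SeedSequence([seed, SUPPORT_INSTANCES.index(instance)])
    )
    jitter = rng.uniform(-0.5, 0.5)
    arm_tilt = prog["arm_tilt"] + jitter
    lengths = species.segment_lengths_m
    l_arm, l_fa, l_hand = lengths["arm"], lengths["forearm"], lengths["hand"]
    gh = np.zeros(3)
    elbow = gh + l_arm * _tilted(arm_tilt)
    if prog["forearm_tilt"] is None:
        # solve the forearm tilt so the grip point sits above the GH centre
        reach = l_fa + GRIP_FRACTION * l_hand
        fa_tilt = -np.rad2deg(
            np.arcsin(np.clip(l_arm * np.sin(np.deg2rad(arm_tilt)) / reach, -1, 1))
        )
    else:
        fa_tilt = prog["forearm_tilt"] + jitter
    wrist = elbow + l_fa * _tilted(fa_tilt)
    flexion = abs(arm_tilt - fa_tilt)
    return Posture(
        instance=instance,
        joint_centers={"wrist": wrist, "elbow": elbow, "glenohumeral": gh},
        humerothoracic_elevation_deg=prog["elevation"],
        elbow_flexion_deg=float(flexion),
        acromion_marker=gh + ACROMION_OFFSET_M + species.scapular_reposition_m,
    )


def grip_point(posture: Posture, species: SpeciesParameterSet) -> np.ndarray:
    """Point of hand-force application on the rung."""
    return (
        posture.joint_centers["wrist"]
        + GRIP_FRACTION
        * species.segment_lengths_m["hand"]
        * posture.forearm_direction()
    )


def rescale_to_chimpanzee(
    human_posture: Posture, chimp: SpeciesParameterSet
) -> Posture:
    """Translate joint centres to chimpanzee segment lengths.

    Segment directions (unit vectors GH->elbow and elbow->wrist) are
    preserved exactly; segment magnitudes become the chimpanzee lengths; the
    acromion marker is shifted to reposition the scapula without rotating
    any segment.
    """
    jc = human_posture.joint_centers
    gh = jc["glenohumeral"]
    u_arm = jc["elbow"] - gh
    u_fa = jc["wrist"] - jc["elbow"]
    for name, v in (("arm", u_arm), ("forearm", u_fa)):
        if np.linalg.norm(v) < 1e-12:
            raise ValueError(f"degenerate zero-length {name} segment")
    u_arm = u_arm / np.linalg.norm(u_arm)
    u_fa = u_fa / np.linalg.norm(u_fa)
    lengths = chimp.segment_lengths_m
    elbow = gh + lengths["arm"] * u_arm
    wrist = elbow + lengths["forearm"] * u_fa
    return replace(
        human_posture,
        joint_centers={"wrist": wrist, "elbow": elbow, "glenohumeral": gh},
        acromion_marker=gh + ACROMION_OFFSET_M + chimp.scapular_reposition_m,
    )


# ---------------------------------------------------------------------------
# bone geometry

# Scapular landmarks as fractions of longitudinal scapular length, in local
# axes (anterior, superior, lateral) relative to the glenoid centroid.
_SCAPULA_LANDMARK_FRACTIONS = {
    # the acromion overhangs the humeral head laterally, so the acromial
    # deltoid origin lies lateral to the GH centre (abduction moment arm)
    "origin_deltoid_middle": (0.00, 0.24, 0.32),     # acromial
    "origin_deltoid_anterior": (0.19, 0.245, 0.22),  # clavicular
    "origin_deltoid_posterior": (-0.225, 0.19, 0.10),  # scapular spine
}

# Attachment-fraction bounding box of the scapular blade (AP, ML, SI axes);
# draws outside are clamped by the geometry engine.
SCAPULA_FRACTION_BOUNDS = (
    np.array([-0.60, 0.00, 0.00]),
    np.array([0.60, 0.90, 0.95]),
)

# Rotator-cuff footprint directions on the humeral head, in humerus-local
# axes (anterior, distal, lateral); scaled to 1.08 x head radius.
_HEAD_INSERTION_DIRECTIONS = {
    "insertion_supraspinatus": (0.05, 0.25, 0.95),
    "insertion_infraspinatus_upper": (-0.45, 0.22, 0.86),
    "insertion_infraspinatus_lower": (-0.55, 0.30, 0.73),
    "insertion_teres_minor": (-0.62, 0.40, 0.60),
    "insertion_subscapularis_upper": (0.55, 0.22, 0.80),
    "insertion_subscapularis_middle": (0.60, 0.30, 0.69),
    "insertion_subscapularis_lower": (0.64, 0.40, 0.62),
}

#: Offset of the scapular attachment reference point above the glenoid
#: centroid, as a fraction of scapular length.
SCAPULA_REFERENCE_SUPERIOR_FRACTION = 0.45

#: Glenoid centroid sits medial to the GH centre by head radius plus
#: cartilage/labrum clearance.
GLENOID_MEDIAL_CLEARANCE_M = 0.003


def generate_bone_geometry(
    species: SpeciesParameterSet, seed: int
) -> dict[str, BoneGeometry]:
    """Deterministic scapula and humerus landmark sets with wrap obstacles.

    Landmarks are in bone-local axes (metres): scapular positions relative to
    the glenoid centroid, humeral positions relative to the GH centre. The
    seed adds millimetre-scale jitter to the (assumed) deltoid origin
    landmarks only; metrologically defined landmarks are fixed.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    l_scap = species.segment_lengths_m["scapula"]
    r_head = species.humeral_head_radius_m

    scap_landmarks = {
        "glenoid_centroid": np.zeros(3),
        "glenoid_superior": np.array([0.0, GLENOID_SUPERIOR_DISTANCE_M, 0.0]),
        "attachment_reference": np.array(
            [0.0, SCAPULA_REFERENCE_SUPERIOR_FRACTION * l_scap, 0.0]
        ),
        "fossa_min_fraction": SCAPULA_FRACTION_BOUNDS[0],
        "fossa_max_fraction": SCAPULA_FRACTION_BOUNDS[1],
    }
    for name, frac in _SCAPULA_LANDMARK_FRACTIONS.items():
        jitter = rng.uniform(-0.001, 0.001, size=3)
        scap_landmarks[name] = l_scap * np.asarray(frac) + jitter
    scapula = BoneGeometry(
        bone="scapula",
        longitudinal_length_m=l_scap,
        landmark_set=scap_landmarks,
        wrap_objects=(),
    )

    hum_landmarks = {"head_center": np.zeros(3)}
    for name, direction in _HEAD_INSERTION_DIRECTIONS.items():
        d = np.asarray(direction, dtype=float)
        hum_landmarks[name] = 1.08 * r_head * d / np.linalg.norm(d)
    humerus = BoneGeometry(
        bone="humerus",
        longitudinal_length_m=species.segment_lengths_m["arm"],
        landmark_set=hum_landmarks,
        wrap_objects=(
            WrapSphere(center=np.zeros(3), radius=r_head),
            WrapCylinder(
                point=np.zeros(3),
                axis=np.array([0.0, 1.0, 0.0]),  # local distal axis
                radius=0.3 * r_head,
            ),
        ),
    )
    return {"scapula": scapula, "humerus": humerus}


def export_fixtures(species: SpeciesParameterSet, seed: int) -> dict:
    """JSON-serializable dump of all postures and bone landmarks."""
    out = {"species": species.species_id, "seed": seed, "postures": {}, "bones": {}}
    for instance in SUPPORT_INSTANCES:
        p = generate_posture(instance, species, seed)
        out["postures"][instance] = {
            "joint_centers": {k: v.tolist() for k, v in p.joint_centers.items()},
            "humerothoracic_elevation_deg": p.humerothoracic_elevation_deg,
            "elbow_flexion_deg": p.elbow_flexion_deg,
            "acromion_marker": p.acromion_marker.tolist(),
        }
    for bone, geom in generate_bone_geometry(species, seed).items():
        out["bones"][bone] = {
            "longitudinal_length_m": geom.longitudinal_length_m,
            "landmarks": {k: np.asarray(v).tolist() for k, v in geom.landmark_set.items()},
        }
    return out
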