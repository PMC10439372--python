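"""Assembled glenohumeral model for one species and support instance.

Binds the synthetic fixtures (posture, bone landmarks, wrap obstacles), the
external static load, and the muscle-path geometry into a single callable
that maps the 14 probabilistic inputs — four attachment groups x three axes,
glenoid inclination, and the stability-ratio offset — to a solved
muscle-force state. This is the deterministic kernel the Monte Carlo engine
perturbs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import external_dynamics, force_prediction, geometry_engine, synthetic_fixtures
from .force_prediction import MuscleForceSolution
from .geometry_engine import GlenoidFrame, WrapCylinder, WrapSphere
from .species_params import (
    CUFF_OUTPUTS,
    GROUP_TO_ELEMENT,
    SpeciesParameterSet,
)

#: Canonical ordering of the 14 probabilistic inputs.
INPUT_GROUPS = (
    "infraspinatus_origin",
    "subscapularis_origin",
    "supraspinatus_origin",
    "deltoid_insertion",
)
AXIS_SUFFIXES = ("ap", "ml", "si")
INPUT_NAMES = tuple(
    f"{g}_{s}" for g in INPUT_GROUPS for s in AXIS_SUFFIXES
) + ("glenoid_inclination", "stability_ratio")


def _world_axes_humerus(gh: np.ndarray, elbow: np.ndarray):
    """Humerus frame: y distal along the shaft, x anterior-ish, z lateral."""
    y = elbow - gh
    y = y / np.linalg.norm(y)
    x_hint = np.array([1.0, 0.0, 0.0])
    x = x_hint - np.dot(x_hint, y) * y
    if np.linalg.norm(x) < 1e-9:
        x_hint = np.array([0.0, 0.0, 1.0])
        x = x_hint - np.dot(x_hint, y) * y
    x = x / np.linalg.norm(x)
    z = np.cross(x, y)
    return x, y, z


@dataclass
class GlenohumeralModel:
    """Deterministic model closure for one (species, instance) pair."""

    species: SpeciesParameterSet
    instance: str
    seed: int = 0
    sigma_max: float = force_prediction.SIGMA_MAX_DEFAULT
    exponent: int = 3
    g: float = external_dynamics.G_DEFAULT
    hand_force_direction: np.ndarray | None = None  # None = vertical

    def __post_init__(self):
        sp = self.species
        self.posture = synthetic_fixtures.generate_posture(self.instance, sp, self.seed)
        self.bones = synthetic_fixtures.generate_bone_geometry(sp, self.seed)
        jc = self.posture.joint_centers
        self.gh = jc["glenohumeral"]
        self.hx, self.hy, self.hz = _world_axes_humerus(self.gh, jc["elbow"])

        # scapula translation follows the acromion marker (no rotation)
        acromion_shift = self.posture.acromion_marker - (
            self.gh + synthetic_fixtures.ACROMION_OFFSET_M
        )
        self.glenoid_centroid = (
            self.gh
            - (sp.humeral_head_radius_m + synthetic_fixtures.GLENOID_MEDIAL_CLEARANCE_M)
            * np.array([0.0, 0.0, 1.0])
            + acromion_shift
        )
        scap = self.bones["scapula"]
        self.scapula_landmarks = {
            k: self.glenoid_centroid + np.asarray(v)
            for k, v in scap.landmark_set.items()
            if not k.startswith("fossa")
        }
        self.fraction_bounds = (
            scap.landmark_set["fossa_min_fraction"],
            scap.landmark_set["fossa_max_fraction"],
        )
        self.scapula_length = scap.longitudinal_length_m
        self.attachment_reference = self.scapula_landmarks["attachment_reference"]

        hum = self.bones["humerus"]
        self.humerus_length = hum.longitudinal_length_m
        self.humerus_landmarks = {
            k: self._humerus_to_world(np.asarray(v))
            for k, v in hum.landmark_set.items()
        }
        self.wraps = []
        for w in hum.wrap_objects:
            if isinstance(w, WrapSphere):
                self.wraps.append(
                    WrapSphere(center=self._humerus_to_world(w.center), radius=w.radius)
                )
            else:
                self.wraps.append(
                    WrapCylinder(
                        point=self._humerus_to_world(w.point),
                        axis=self.hy,
                        radius=w.radius,
                    )
                )
        self.sphere = next(w for w in self.wraps if isinstance(w, WrapSphere))
        self.cylinder = next(w for w in self.wraps if isinstance(w, WrapCylinder))

        self.load = external_dynamics.external_load(
            self.posture, sp, g=self.g, hand_force_direction=self.hand_force_direction
        )
        self.base_frame = geometry_engine.build_glenoid_frame(
            self.glenoid_centroid,
            self.glenoid_centroid
            + np.array([0.0, synthetic_fixtures.GLENOID_SUPERIOR_DISTANCE_M, 0.0]),
        )
        self.elements = list(sp.muscle_elements)
        self.element_names = tuple(e.name for e in self.elements)
        self.pcsa = np.array([e.absolute_pcsa_cm2 for e in self.elements])
        self.max_forces = np.array(
            [force_prediction.max_force(e, self.sigma_max) for e in self.elements]
        )
        self.mean_inputs = self.mean_input_vector()

    # -- coordinate mapping ---------------------------------------------
    def _humerus_to_world(self, local: np.ndarray) -> np.ndarray:
        return self.gh + local[0] * self.hx + local[1] * self.hy + local[2] * self.hz

    def scapular_attachment(self, fraction: np.ndarray) -> np.ndarray:
        """World position of a scapular attachment given (AP, ML, SI) fractions.

        SI is measured downward and ML medially from the scapular attachment
        reference point (right arm: medial = -z).
        """
        f = np.asarray(fraction, dtype=float)
        return self.attachment_reference + self.scapula_length * (
            f[0] * np.array([1.0, 0.0, 0.0])
            - f[2] * np.array([0.0, 1.0, 0.0])
            - f[1] * np.array([0.0, 0.0, 1.0])
        )

    def humeral_attachment(self, fraction: np.ndarray) -> np.ndarray:
        """World position of a humeral attachment given (AP, ML, SI) fractions.

        SI measured distally along the shaft, ML laterally, in humeral axes.
        """
        f = np.asarray(fraction, dtype=float)
        return self.gh + self.humerus_length * (
            f[0] * self.hx + f[2] * self.hy + f[1] * self.hz
        )

    # -- probabilistic input handling -----------------------------------
    def mean_input_vector(self) -> np.ndarray:
        sp = self.species
        x = []
        for group in INPUT_GROUPS:
            x.extend(sp.distribution(group).mean)
        x.append(sp.glenoid_inclination_mean_cm)
        x.append(sp.stability.offset_pct)
        return np.array(x)

    def input_sds(self) -> np.ndarray:
        sp = self.species
        s = []
        for group in INPUT_GROUPS:
            s.extend(sp.distribution(group).sd)
        s.append(sp.glenoid_inclination_sd_cm)
        s.append(sp.stability.sd_pct)
        return np.array(s)

    def attachment_coordinates(self, x: np.ndarray) -> dict[str, np.ndarray]:
        """Variable-attachment fractions for all ten elements from inputs.

        Group coordinates are clamped to the scapular fraction box; coupled
        elements move rigidly with their parent (per-axis ratio preserved).
        """
        coords: dict[str, np.ndarray] = {}
        lo, hi = self.fraction_bounds
        for gi, group in enumerate(INPUT_GROUPS):
            raw = x[3 * gi : 3 * gi + 3]
            parent_name = GROUP_TO_ELEMENT[group]
            parent_elem = self.species.element(parent_name)
            if parent_elem.attachment_bone == "scapula":
                value = geometry_engine.perturb_attachment(
                    raw, np.zeros(3), np.zeros(3), bounds=(lo, hi)
                )
            else:
                value = np.asarray(raw, dtype=float)
            coords[parent_name] = value
        for e in self.elements:
            if e.coupling_parent is not None:
                coords[e.name] = geometry_engine.couple_elements(
                    coords[e.coupling_parent], e.coupling_offsets
                )
            elif e.name not in coords:
                coords[e.name] = e.attachment_mean  # fixed attachment
        return coords

    def glenoid_frame_for(self, inclination_value_cm: float) -> GlenoidFrame:
        shift = inclination_value_cm - self.species.glenoid_inclination_mean_cm
        return geometry_engine.incline_glenoid(self.base_frame, shift)

    def stability_ratios_for(self, stability_value_pct: float) -> np.ndarray:
        from .species_params import _offset_ratios

        return _offset_ratios(
            self.species.stability.baseline,
            stability_value_pct,
            self.species.stability_offset_mode,
        )

    def muscle_paths(self, coords: dict[str, np.ndarray]):
        paths = []
        for e in self.elements:
            if e.attachment_bone == "scapula":
                origin = self.scapular_attachment(coords[e.name])
                bone, landmark = e.fixed_end.split(":")
                insertion = self.humerus_landmarks[landmark]
            else:  # variable humeral insertion (deltoid)
                insertion = self.humeral_attachment(coords[e.name])
                bone, landmark = e.fixed_end.split(":")
                origin = self.scapula_landmarks[landmark]
            wraps = (self.cylinder,) if e.name.startswith("deltoid") else (self.sphere,)
            try:
                path = geometry_engine.solve_path(origin, insertion, wraps, element=e.name)
            except ValueError:
                # a perturbed attachment landed inside the idealized obstacle;
                # the wrap is moot there, fall back to the straight string
                path = geometry_engine.solve_path(origin, insertion, (), element=e.name)
            paths.append(path)
        return paths

    # -- evaluation ------------------------------------------------------
    def solve(self, x: np.ndarray | None = None) -> MuscleForceSolution:
        """Solve muscle forces for one 14-input state (default: the means)."""
        x = self.mean_inputs if x is None else np.asarray(x, dtype=float)
        coords = self.attachment_coordinates(x)
        frame = self.glenoid_frame_for(x[12])
        ratios = self.stability_ratios_for(x[13])
        paths = self.muscle_paths(coords)
        return force_prediction.solve_muscle_forces(
            paths,
            self.load,
            self.max_forces,
            self.pcsa,
            frame,
            ratios,
            self.gh,
            exponent=self.exponent,
        )

    def evaluate_outputs(self, x: np.ndarray | None = None):
        """Normalized cuff forces (%) for the seven reported outputs.

        Returns (outputs, feasible): a 7-vector ordered as CUFF_OUTPUTS and
        the feasibility flag of the underlying solve.
        """
        sol = self.solve(x)
        by_name = sol.normalized_by_name()
        return np.array([by_name[name] for name in CUFF_OUTPUTS]), sol.feasible
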