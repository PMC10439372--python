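"""Species parameter sets for the glenohumeral muscle-force models.

Each species (human, chimpanzee) is described by a single YAML configuration
holding anthropometry, the ten muscle elements of the deltoid/rotator-cuff
force-prediction module with their physiological cross-sectional areas (PCSA),
the probabilistic attachment distributions (means and standard deviations as
fractions of longitudinal bone length), the glenoid-inclination distribution,
and the eight-direction glenoid stability-ratio profile.

Axis order for every attachment coordinate is
(anterior-posterior, medial-lateral, superior-inferior).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

try:  # py3.9+: importlib.resources.files
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

AXIS_ORDER = ("anterior_posterior", "medial_lateral", "superior_inferior")

#: Eight glenoid-rim directions at 45 degree spacing, starting superior and
#: rotating toward anterior (in the glenoid x-y plane).
STABILITY_DIRECTIONS = (
    "superior",
    "anterosuperior",
    "anterior",
    "anteroinferior",
    "inferior",
    "posteroinferior",
    "posterior",
    "posterosuperior",
)

#: Which muscle element's variable attachment each probabilistic group drives.
GROUP_TO_ELEMENT = {
    "infraspinatus_origin": "infraspinatus_upper",
    "subscapularis_origin": "subscapularis_upper",
    "supraspinatus_origin": "supraspinatus",
    "deltoid_insertion": "deltoid_middle",
}

#: The seven rotator-cuff outputs reported by the probabilistic analysis.
CUFF_OUTPUTS = (
    "infraspinatus_upper",
    "infraspinatus_lower",
    "subscapularis_upper",
    "subscapularis_middle",
    "subscapularis_lower",
    "supraspinatus",
    "teres_minor",
)


class ValidationError(ValueError):
    """Raised when a species configuration violates a model invariant."""


def _vec3(value, name: str) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.shape != (3,):
        raise ValidationError(f"{name}: expected a 3-vector, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class MuscleElementSpec:
    """One string-muscle element of the force-prediction module."""

    name: str
    absolute_pcsa_cm2: float
    attachment_bone: str  # bone carrying the variable attachment
    attachment_mean: np.ndarray  # fractions of longitudinal bone length
    fixed_end: str  # landmark name of the non-varying attachment
    coupling_parent: str | None = None
    coupling_offsets: np.ndarray | None = None

    def __post_init__(self):
        if self.absolute_pcsa_cm2 <= 0:
            raise ValidationError(f"{self.name}: absolute_pcsa_cm2 must be > 0")
        if self.attachment_bone not in ("scapula", "humerus"):
            raise ValidationError(
                f"{self.name}: attachment_bone must be scapula or humerus"
            )
        object.__setattr__(
            self, "attachment_mean", _vec3(self.attachment_mean, f"{self.name}.attachment_mean")
        )
        if self.coupling_offsets is not None:
            object.__setattr__(
                self,
                "coupling_offsets",
                _vec3(self.coupling_offsets, f"{self.name}.coupling_offsets"),
            )


@dataclass(frozen=True)
class AttachmentDistribution:
    """Gaussian attachment distribution for one probabilistic input group."""

    element_group: str
    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        if self.element_group not in GROUP_TO_ELEMENT:
            raise ValidationError(f"unknown attachment group {self.element_group!r}")
        object.__setattr__(self, "mean", _vec3(self.mean, f"{self.element_group}.mean"))
        object.__setattr__(self, "sd", _vec3(self.sd, f"{self.element_group}.sd"))
        if np.any(self.sd <= 0):
            raise ValidationError(
                f"{self.element_group}: sd components must be strictly positive"
            )


@dataclass(frozen=True)
class StabilityRatios:
    """Eight-direction shear/compression tolerance profile of the glenoid.

    ``baseline`` holds the human reference profile; ``offset_pct`` is the
    species offset applied to every direction (0 for the human model, 13.13
    for the deeper chimpanzee glenoid), and ``sd_pct`` the common Gaussian
    spread used in the probabilistic runs.
    """

    baseline: np.ndarray
    offset_pct: float = 0.0
    sd_pct: float = 4.0
    directions: tuple = STABILITY_DIRECTIONS

    def __post_init__(self):
        arr = np.asarray(self.baseline, dtype=float)
        if arr.shape != (8,):
            raise ValidationError("stability baseline must contain exactly 8 ratios")
        if np.any(arr <= 0) or np.any(arr > 1.5):
            raise ValidationError("stability ratios must lie in (0, 1.5]")
        if self.sd_pct < 0:
            raise ValidationError("stability sd_pct must be >= 0")
        object.__setattr__(self, "baseline", arr)

    def effective(self, mode: str = "multiplicative") -> np.ndarray:
        """Directional ratios with the species offset applied."""
        return _offset_ratios(self.baseline, self.offset_pct, mode)


def _offset_ratios(baseline: np.ndarray, offset_pct: float, mode: str) -> np.ndarray:
    if offset_pct < -100:
        raise ValidationError("offset_pct must be >= -100")
    if mode == "multiplicative":
        return baseline * (1.0 + offset_pct / 100.0)
    if mode == "additive":
        return baseline + offset_pct / 100.0
    raise ValidationError(f"unknown stability offset mode {mode!r}")


def apply_stability_offset(
    baseline: StabilityRatios, offset_pct: float, mode: str = "multiplicative"
) -> StabilityRatios:
    """Return a new profile with every direction offset by ``offset_pct``.

    The offset is interpreted as a relative increase in shear tolerance
    (multiplicative scaling by ``1 + offset_pct/100``) by default; an
    additive interpretation (ratio + offset_pct/100) is selectable.
    """
    return dataclasses.replace(
        baseline,
        baseline=_offset_ratios(baseline.baseline, offset_pct, mode),
        offset_pct=0.0,
    )


def relative_pcsa(absolute_pcsa: float, body_mass: float) -> float:
    """PCSA relative to body mass (cm^2/kg), rounded to 3 decimals for tables."""
    if absolute_pcsa <= 0 or body_mass <= 0:
        raise ValidationError("absolute_pcsa and body_mass must be > 0")
    return round(absolute_pcsa / body_mass, 3)


@dataclass(frozen=True)
class SpeciesParameterSet:
    """All printed parameters of one species glenohumeral model."""

    species_id: str
    body_mass_kg: float
    stature_m: float
    segment_lengths_m: Mapping[str, float]
    segment_mass_fractions: Mapping[str, float]
    segment_com_fractions: Mapping[str, float]
    humeral_head_radius_m: float
    muscle_elements: tuple
    attachment_distributions: tuple
    glenoid_inclination_mean_cm: float
    glenoid_inclination_sd_cm: float
    stability: StabilityRatios
    stability_offset_mode: str = "multiplicative"
    scapular_reposition_m: np.ndarray = field(
        default_factory=lambda: np.zeros(3)
    )

    def __post_init__(self):
        if self.species_id not in ("human", "chimpanzee"):
            raise ValidationError(f"unknown species_id {self.species_id!r}")
        if self.body_mass_kg <= 0:
            raise ValidationError("body_mass_kg must be > 0")
        if self.stature_m <= 0:
            raise ValidationError("stature_m must be > 0")
        if self.glenoid_inclination_sd_cm < 0:
            raise ValidationError("glenoid_inclination_sd_cm must be >= 0")
        for seg in ("arm", "forearm", "hand", "scapula"):
            if seg not in self.segment_lengths_m:
                raise ValidationError(f"segment_lengths_m missing {seg!r}")
            if self.segment_lengths_m[seg] <= 0:
                raise ValidationError(f"segment length {seg!r} must be > 0")
        if len(self.muscle_elements) != 10:
            raise ValidationError(
                f"expected exactly 10 muscle elements, got {len(self.muscle_elements)}"
            )
        names = {e.name for e in self.muscle_elements}
        if len(names) != 10:
            raise ValidationError("duplicate muscle element names")
        for e in self.muscle_elements:
            if e.coupling_parent is not None and e.coupling_parent not in names:
                raise ValidationError(
                    f"{e.name}: coupling parent {e.coupling_parent!r} does not exist"
                )
        groups = {d.element_group for d in self.attachment_distributions}
        if groups != set(GROUP_TO_ELEMENT):
            raise ValidationError(
                f"attachment_distributions must cover exactly {sorted(GROUP_TO_ELEMENT)}"
            )
        by_name = {e.name: e for e in self.muscle_elements}
        for d in self.attachment_distributions:
            elem = by_name[GROUP_TO_ELEMENT[d.element_group]]
            if not np.allclose(d.mean, elem.attachment_mean, atol=1e-12):
                raise ValidationError(
                    f"{d.element_group}: distribution mean disagrees with "
                    f"element {elem.name} attachment_mean"
                )
        object.__setattr__(
            self,
            "scapular_reposition_m",
            _vec3(self.scapular_reposition_m, "scapular_reposition_m"),
        )

    # -- lookups ---------------------------------------------------------
    def element(self, name: str) -> MuscleElementSpec:
        for e in self.muscle_elements:
            if e.name == name:
                return e
        raise KeyError(name)

    def distribution(self, group: str) -> AttachmentDistribution:
        for d in self.attachment_distributions:
            if d.element_group == group:
                return d
        raise KeyError(group)

    def segment_mass_kg(self, segment: str) -> float:
        return self.segment_mass_fractions[segment] * self.body_mass_kg

    def relative_pcsa_of(self, name: str) -> float:
        return relative_pcsa(self.element(name).absolute_pcsa_cm2, self.body_mass_kg)


# ---------------------------------------------------------------------------
# serialization

def _element_to_dict(e: MuscleElementSpec) -> dict:
    d = {
        "name": e.name,
        "absolute_pcsa_cm2": float(e.absolute_pcsa_cm2),
        "attachment_bone": e.attachment_bone,
        "attachment_mean": [float(v) for v in e.attachment_mean],
        "fixed_end": e.fixed_end,
    }
    if e.coupling_parent is not None:
        d["coupling_parent"] = e.coupling_parent
        d["coupling_offsets"] = [float(v) for v in e.coupling_offsets]
    return d


def to_dict(params: SpeciesParameterSet) -> dict:
    return {
        "species_id": params.species_id,
        "body_mass_kg": float(params.body_mass_kg),
        "stature_m": float(params.stature_m),
        "segment_lengths_m": {k: float(v) for k, v in params.segment_lengths_m.items()},
        "segment_mass_fractions": {
            k: float(v) for k, v in params.segment_mass_fractions.items()
        },
        "segment_com_fractions": {
            k: float(v) for k, v in params.segment_com_fractions.items()
        },
        "humeral_head_radius_m": float(params.humeral_head_radius_m),
        "glenoid_inclination_mean_cm": float(params.glenoid_inclination_mean_cm),
        "glenoid_inclination_sd_cm": float(params.glenoid_inclination_sd_cm),
        "stability": {
            "baseline_ratios": {
                d: float(v)
                for d, v in zip(params.stability.directions, params.stability.baseline)
            },
            "offset_pct": float(params.stability.offset_pct),
            "sd_pct": float(params.stability.sd_pct),
            "offset_mode": params.stability_offset_mode,
        },
        "scapular_reposition_m": [float(v) for v in params.scapular_reposition_m],
        "muscle_elements": [_element_to_dict(e) for e in params.muscle_elements],
        "attachment_distributions": [
            {
                "element_group": d.element_group,
                "mean": [float(v) for v in d.mean],
                "sd": [float(v) for v in d.sd],
            }
            for d in params.attachment_distributions
        ],
    }


def from_dict(raw: Mapping) -> SpeciesParameterSet:
    try:
        elements = []
        by_name = {}
        # two passes: parents first so coupled means can be derived
        entries = list(raw["muscle_elements"])
        pending = []
        for entry in entries:
            if entry.get("coupling_parent") is None:
                e = MuscleElementSpec(
                    name=entry["name"],
                    absolute_pcsa_cm2=entry["absolute_pcsa_cm2"],
                    attachment_bone=entry["attachment_bone"],
                    attachment_mean=entry["attachment_mean"],
                    fixed_end=entry["fixed_end"],
                )
                by_name[e.name] = e
                elements.append((entries.index(entry), e))
            else:
                pending.append(entry)
        for entry in pending:
            parent = by_name.get(entry["coupling_parent"])
            if parent is None:
                raise ValidationError(
                    f"{entry['name']}: coupling parent "
                    f"{entry['coupling_parent']!r} not found"
                )
            offsets = _vec3(entry["coupling_offsets"], f"{entry['name']}.coupling_offsets")
            mean = entry.get("attachment_mean")
            if mean is None:
                mean = parent.attachment_mean * (1.0 + offsets)
            e = MuscleElementSpec(
                name=entry["name"],
                absolute_pcsa_cm2=entry["absolute_pcsa_cm2"],
                attachment_bone=entry.get("attachment_bone", parent.attachment_bone),
                attachment_mean=mean,
                fixed_end=entry["fixed_end"],
                coupling_parent=entry["coupling_parent"],
                coupling_offsets=offsets,
            )
            by_name[e.name] = e
            elements.append((entries.index(entry), e))
        elements = tuple(e for _, e in sorted(elements, key=lambda t: t[0]))

        dists = tuple(
            AttachmentDistribution(
                element_group=d["element_group"], mean=d["mean"], sd=d["sd"]
            )
            for d in raw["attachment_distributions"]
        )
        st = raw["stability"]
        baseline = [st["baseline_ratios"][d] for d in STABILITY_DIRECTIONS]
        stability = StabilityRatios(
            baseline=baseline,
            offset_pct=st["offset_pct"],
            sd_pct=st["sd_pct"],
        )
        return SpeciesParameterSet(
            species_id=raw["species_id"],
            body_mass_kg=raw["body_mass_kg"],
            stature_m=raw["stature_m"],
            segment_lengths_m=dict(raw["segment_lengths_m"]),
            segment_mass_fractions=dict(raw["segment_mass_fractions"]),
            segment_com_fractions=dict(raw["segment_com_fractions"]),
            humeral_head_radius_m=raw["humeral_head_radius_m"],
            muscle_elements=elements,
            attachment_distributions=dists,
            glenoid_inclination_mean_cm=raw["glenoid_inclination_mean_cm"],
            glenoid_inclination_sd_cm=raw["glenoid_inclination_sd_cm"],
            stability=stability,
            stability_offset_mode=st.get("offset_mode", "multiplicative"),
            scapular_reposition_m=raw.get("scapular_reposition_m", [0.0, 0.0, 0.0]),
        )
    except KeyError as exc:
        raise ValidationError(f"missing required field: {exc.args[0]!r}") from exc


def load_species(config_path: str | Path) -> SpeciesParameterSet:
    """Load and validate a species configuration from a YAML file."""
    path = Path(config_path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return from_dict(raw)


def save_species(params: SpeciesParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(to_dict(params), fh, sort_keys=False)


def default_config_path(species_id: str) -> Path:
    """Path to the packaged configuration for ``human`` or ``chimpanzee``."""
    return Path(str(_pkg_files("cuffmc") / "data" / f"{species_id}.yaml"))


def load_default(species_id: str) -> SpeciesParameterSet:
    return load_species(default_config_path(species_id))


def pcsa_table(parameter_sets: Iterable[SpeciesParameterSet]) -> pd.DataFrame:
    """Absolute and body-mass-relative PCSA for every element and species."""
    rows = []
    for p in parameter_sets:
        for e in p.muscle_elements:
            rows.append(
                {
                    "species": p.species_id,
                    "element": e.name,
                    "absolute_pcsa_cm2": e.absolute_pcsa_cm2,
                    "relative_pcsa_cm2_per_kg": relative_pcsa(
                        e.absolute_pcsa_cm2, p.body_mass_kg
                    ),
                }
            )
    return pd.DataFrame(rows)
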