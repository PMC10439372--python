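"""Static inverse dynamics for the suspended arm.

Converts a support-phase posture, segment masses and the substrate hand
force into the net glenohumeral moment and reaction-force demand. The task
is quasi-static (three static support instances, no accelerations). Hand
forces follow the suspension loading rule: half body weight per hand in the
double-support instances (early, late) and full body weight in single
support (mid); the substrate reaction at the hand is vertical by default,
optionally directed along the forearm.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .synthetic_fixtures import Posture, grip_point
from .species_params import SpeciesParameterSet

G_DEFAULT = 9.81  # m/s^2

_UP = np.array([0.0, 1.0, 0.0])

#: Winter-style centre-of-mass locations (fraction of segment length from
#: the proximal joint), used when a species set is not supplied.
DEFAULT_COM_FRACTIONS = {"arm": 0.436, "forearm": 0.430, "hand": 0.506}


@dataclass(frozen=True)
class ExternalLoad:
    """Net glenohumeral demand for one support instance."""

    instance: str
    hand_force: np.ndarray       # N, substrate reaction at the grip
    gh_moment: np.ndarray        # N.m, net external moment about the GH centre
    gh_force_demand: np.ndarray  # N, -(hand force + segment weights)


def hand_force(
    instance: str,
    body_mass: float,
    g: float = G_DEFAULT,
    direction: np.ndarray | None = None,
) -> np.ndarray:
    """Substrate reaction force at the hand for one support instance.

    Magnitude is half body weight in early/late (double) support and full
    body weight in mid (single) support; direction defaults to vertically
    upward.
    """
    if body_mass < 0:
        raise ValueError("body_mass must be >= 0")
    if instance in ("early_support", "late_support"):
        mag = 0.5 * body_mass * g
    elif instance == "mid_support":
        mag = body_mass * g
    else:
        raise ValueError(f"unknown support instance {instance!r}")
    if direction is None:
        u = _UP
    else:
        d = np.asarray(direction, dtype=float)
        u = d / np.linalg.norm(d)
    return mag * u


def segment_com_positions(
    posture: Posture,
    com_fractions: Mapping[str, float] | None = None,
    hand_length: float | None = None,
) -> dict[str, np.ndarray]:
    """World-frame centre-of-mass position of arm, forearm and hand."""
    fr = dict(DEFAULT_COM_FRACTIONS if com_fractions is None else com_fractions)
    jc = posture.joint_centers
    out = {
        "arm": jc["glenohumeral"] + fr["arm"] * (jc["elbow"] - jc["glenohumeral"]),
        "forearm": jc["elbow"] + fr["forearm"] * (jc["wrist"] - jc["elbow"]),
    }
    u_fa = posture.forearm_direction()
    length = hand_length if hand_length is not None else posture.segment_length("forearm") * 0.7
    out["hand"] = jc["wrist"] + fr["hand"] * length * u_fa
    return out


def gh_load(
    posture: Posture,
    hand_force_vec: np.ndarray,
    segment_masses: Mapping[str, float],
    g: float = G_DEFAULT,
    hand_point: np.ndarray | None = None,
    com_fractions: Mapping[str, float] | None = None,
    hand_length: float | None = None,
) -> ExternalLoad:
    """Net static glenohumeral moment and force demand.

    The moment about the GH centre sums r x F over the hand force (applied at
    ``hand_point``, default the wrist) and the segment weights; the force
    demand is -(hand force + segment weights). Both outputs are exactly
    linear in the applied forces (superposition).
    """
    jc = posture.joint_centers
    gh = jc["glenohumeral"]
    f_hand = np.asarray(hand_force_vec, dtype=float)
    p_hand = jc["wrist"] if hand_point is None else np.asarray(hand_point, dtype=float)
    moment = np.cross(p_hand - gh, f_hand)
    total_force = f_hand.copy()
    coms = segment_com_positions(posture, com_fractions, hand_length)
    for segment, mass in segment_masses.items():
        if mass < 0:
            raise ValueError(f"negative mass for segment {segment!r}")
        weight = -mass * g * _UP
        moment = moment + np.cross(coms[segment] - gh, weight)
        total_force = total_force + weight
    return ExternalLoad(
        instance=posture.instance,
        hand_force=f_hand,
        gh_moment=moment,
        gh_force_demand=-total_force,
    )


def external_load(
    posture: Posture,
    species: SpeciesParameterSet,
    g: float = G_DEFAULT,
    hand_force_direction: np.ndarray | None = None,
) -> ExternalLoad:
    """Convenience wrapper building the full species load for a posture."""
    f_hand = hand_force(posture.instance, species.body_mass_kg, g, hand_force_direction)
    masses = {s: species.segment_mass_kg(s) for s in ("arm", "forearm", "hand")}
    return gh_load(
        posture,
        f_hand,
        masses,
        g=g,
        hand_point=grip_point(posture, species),
        com_fractions=species.segment_com_fractions,
        hand_length=species.segment_lengths_m["hand"],
    )
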