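"""Internal muscle-force prediction by constrained static optimization.

Element forces are resolved by minimising a stress-based cost
sum_i (f_i / PCSA_i)^p (p = 3 by default) subject to

* three-axis moment equilibrium about the glenohumeral (GH) centre,
* force bounds 0 <= f_i <= PCSA_i * sigma_max, and
* eight-direction glenoid stability: the shear component of the glenoid
  reaction may not exceed the direction-specific tolerance ratio times the
  concurrent compressive component.

The glenoid reaction transmitted from the humeral head is
R = sum_i f_i u_i - gh_force_demand (u_i the unit pull direction on the
humerus), i.e. muscle pulls plus the net external force on the arm; its
component along the medial (-z) glenoid axis is the stabilising compression
and its in-plane part the dislocating shear. For a shear azimuth between two
of the 45-degree rim directions the allowable ratio is linearly interpolated.

Infeasibility is reported via a flag with diagnostics, never silently
relaxed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import linprog, minimize

from .external_dynamics import ExternalLoad
from .geometry_engine import GlenoidFrame, MusclePath, moment_arm
from .species_params import MuscleElementSpec, StabilityRatios

#: Default muscle specific tension (N/cm^2); a modelling assumption, exposed
#: in the study configuration. Normalised (% of maximum) outputs depend on it
#: only through the force bounds.
SIGMA_MAX_DEFAULT = 88.0

#: Internal safety offset on the stability constraint (N) so that reported
#: margins of feasible solutions are nonnegative at solver precision.
_STABILITY_SAFETY_N = 1e-6

_EQ_RESIDUAL_TOL = 1e-6  # N.m
_SHEAR_SMOOTHING = 1e-12  # N^2, smooths |shear| at the origin


def max_force(element: MuscleElementSpec, sigma_max: float = SIGMA_MAX_DEFAULT) -> float:
    """Maximum force capacity: PCSA times specific tension (N)."""
    if sigma_max <= 0:
        raise ValueError("sigma_max must be > 0")
    return element.absolute_pcsa_cm2 * sigma_max


@dataclass(frozen=True)
class StabilityAssessment:
    """Decomposition of a glenoid reaction against the stability profile."""

    compression: float          # N, along the medial (-z) glenoid axis
    shear_vector: np.ndarray    # (2,), (anterior, superior) in-plane N
    shear_magnitude: float
    azimuth_deg: float          # from superior toward anterior
    allowable_ratio: float      # interpolated at the shear azimuth
    margins: np.ndarray         # (8,), ratio_d * F_c - max(0, shear . d_hat)
    governing_margin: float     # allowable_ratio * F_c - |shear|
    dislocating: bool           # nonpositive compression with nonzero shear


def _direction_vectors() -> np.ndarray:
    """Rim direction unit vectors (superior -> anterior order), shape (8, 2)."""
    theta = np.deg2rad(45.0 * np.arange(8))
    # component order (anterior, superior); azimuth 0 = superior
    return np.column_stack([np.sin(theta), np.cos(theta)])


_DIRS_2D = _direction_vectors()


def interpolate_ratio(ratios: np.ndarray, azimuth_deg: float) -> float:
    """Allowable shear/compression ratio, linear between 45-degree directions."""
    az = azimuth_deg % 360.0
    k = int(az // 45.0)
    t = (az - 45.0 * k) / 45.0
    return float(ratios[k % 8] * (1.0 - t) + ratios[(k + 1) % 8] * t)


def stability_eval(
    reaction: np.ndarray, frame: GlenoidFrame, ratios: np.ndarray | StabilityRatios
) -> StabilityAssessment:
    """Evaluate a glenoid reaction force against the directional ratios.

    ``reaction`` is the force transmitted from the humeral head onto the
    glenoid (world frame, N). Compression is its component along the medial
    (-z) glenoid axis; shear is the in-plane remainder, decomposed in the
    (anterior, superior) glenoid plane.
    """
    if isinstance(ratios, StabilityRatios):
        ratios = ratios.effective()
    ratios = np.asarray(ratios, dtype=float)
    r = np.asarray(reaction, dtype=float)
    compression = float(-np.dot(r, frame.z_axis))
    shear = np.array([np.dot(r, frame.x_axis), np.dot(r, frame.y_axis)])
    shear_mag = float(np.linalg.norm(shear))
    azimuth = float(np.rad2deg(np.arctan2(shear[0], shear[1])) % 360.0)
    allowable = interpolate_ratio(ratios, azimuth)
    projections = _DIRS_2D @ shear
    margins = ratios * compression - np.maximum(projections, 0.0)
    return StabilityAssessment(
        compression=compression,
        shear_vector=shear,
        shear_magnitude=shear_mag,
        azimuth_deg=azimuth,
        allowable_ratio=allowable,
        margins=margins,
        governing_margin=allowable * compression - shear_mag,
        dislocating=bool(compression <= 0.0 and shear_mag > 0.0),
    )


@dataclass(frozen=True)
class MuscleForceSolution:
    """Solved element forces for one support instance and model state."""

    instance: str
    element_names: tuple
    forces: np.ndarray              # N
    normalized: np.ndarray          # % of per-element maximum force
    reaction_force: np.ndarray      # N, transmitted onto the glenoid
    equilibrium_residual: float     # N.m
    stability_margins: np.ndarray   # (8,) N
    feasible: bool
    objective_value: float = np.nan
    diagnostics: str = ""

    def normalized_by_name(self) -> dict[str, float]:
        return dict(zip(self.element_names, self.normalized))


def solve_muscle_forces(
    paths: Sequence[MusclePath],
    load: ExternalLoad,
    max_forces: np.ndarray,
    pcsa: np.ndarray,
    frame: GlenoidFrame,
    ratios: np.ndarray | StabilityRatios,
    gh_center: np.ndarray,
    exponent: int = 3,
) -> MuscleForceSolution:
    """Resolve element forces for one model state.

    The problem is solved in activation space a_i = f_i / fmax_i (bounds
    [0, 1]); with a uniform specific tension the stress objective reduces to
    sum a_i^p there. Deterministic solver settings (SLSQP, zero start,
    fixed tolerances) for reproducibility.
    """
    if exponent not in (2, 3):
        raise ValueError("objective exponent must be 2 or 3")
    if isinstance(ratios, StabilityRatios):
        ratios = ratios.effective()
    ratios = np.asarray(ratios, dtype=float)
    n = len(paths)
    if n < 1:
        raise ValueError("at least one muscle element is required")
    fmax = np.asarray(max_forces, dtype=float)
    pcsa = np.asarray(pcsa, dtype=float)
    names = tuple(p.element for p in paths)
    gh = np.asarray(gh_center, dtype=float)

    U = np.column_stack([p.effective_origin_direction for p in paths])  # 3 x n
    M = np.column_stack([moment_arm(p, gh) for p in paths])             # 3 x n
    target_moment = -np.asarray(load.gh_moment, dtype=float)
    f_ext = -np.asarray(load.gh_force_demand, dtype=float)  # net external force

    # force-space matrices scaled into activation space
    Mf = M * fmax  # moment per unit activation
    Uf = U * fmax

    # stability pieces: reaction R(a) = Uf a + f_ext
    cx, cy, cz = frame.x_axis, frame.y_axis, frame.z_axis

    def reaction(a):
        return Uf @ a + f_ext

    # eight linear half-plane constraints ratio_k * C(a) - shear(a).d_k >= 0;
    # opposite pairs jointly enforce C >= 0
    comp_row = -(cz @ Uf)              # (n,), compression per unit activation
    comp_0 = -np.dot(f_ext, cz)
    shear_rows = np.vstack([cx @ Uf, cy @ Uf])  # 2 x n
    shear_0 = np.array([np.dot(f_ext, cx), np.dot(f_ext, cy)])
    A_stab = ratios[:, None] * comp_row[None, :] - _DIRS_2D @ shear_rows
    b_stab = ratios * comp_0 - _DIRS_2D @ shear_0

    p = exponent
    # stress objective in activation space: sum ((a_i fmax_i)/pcsa_i)^p,
    # normalised by its largest coefficient for solver conditioning
    coeff = (fmax / pcsa) ** p
    coeff = coeff / coeff.max()

    def objective(a):
        return float(np.dot(coeff, a**p))

    def objective_grad(a):
        return coeff * p * a ** (p - 1)

    # drop identically-zero moment rows (planar problems) so the equality
    # Jacobian has full row rank; a zero row with nonzero target is an
    # immediate structural infeasibility
    row_scale = np.linalg.norm(Mf, axis=1)
    keep = row_scale > 1e-12 * max(row_scale.max(), 1.0)
    if np.any(~keep & (np.abs(target_moment) > 1e-12)):
        return MuscleForceSolution(
            instance=load.instance,
            element_names=names,
            forces=np.zeros(n),
            normalized=np.zeros(n),
            reaction_force=f_ext.copy(),
            equilibrium_residual=float(np.linalg.norm(target_moment)),
            stability_margins=stability_eval(f_ext, frame, ratios).margins,
            feasible=False,
            diagnostics="moment demanded about an axis with no muscle authority",
        )
    Mf_eq = Mf[keep]
    target_eq = target_moment[keep]

    constraints = [
        {
            "type": "eq",
            "fun": lambda a: Mf_eq @ a - target_eq,
            "jac": lambda a: Mf_eq,
        },
        {
            "type": "ineq",
            "fun": lambda a: A_stab @ a + b_stab - _STABILITY_SAFETY_N,
            "jac": lambda a: A_stab,
        },
    ]
    def valid(a):
        return bool(
            np.linalg.norm(Mf_eq @ a - target_eq) <= _EQ_RESIDUAL_TOL
            and np.min(A_stab @ a + b_stab) >= -1e-9
        )

    def attempt(a0):
        res = minimize(
            objective,
            a0,
            jac=objective_grad,
            bounds=[(0.0, 1.0)] * n,
            constraints=constraints,
            method="SLSQP",
            options={"maxiter": 300, "ftol": 1e-12},
        )
        return np.clip(res.x, 0.0, 1.0), res

    # deterministic multi-start: zero vector first; on failure reseed from an
    # LP feasibility point (whose absence certifies genuine infeasibility)
    # and polish once
    best_a, last_res = attempt(np.zeros(n))
    lp_infeasible = False
    if not (valid(best_a) and last_res.success):
        lp = linprog(
            np.ones(n),
            A_ub=-A_stab,
            b_ub=b_stab - 2 * _STABILITY_SAFETY_N,
            A_eq=Mf_eq,
            b_eq=target_eq,
            bounds=[(0.0, 1.0)] * n,
            method="highs",
        )
        if lp.status == 0:
            a2, res2 = attempt(lp.x)
            if valid(a2) and (
                not valid(best_a) or objective(a2) <= objective(best_a)
            ):
                best_a, last_res = a2, res2
            elif not valid(best_a) and valid(lp.x):
                best_a = np.clip(lp.x, 0.0, 1.0)
            if valid(best_a):
                a3, res3 = attempt(best_a)  # polish
                if valid(a3) and objective(a3) <= objective(best_a):
                    best_a, last_res = a3, res3
        else:
            lp_infeasible = lp.status == 2

    a = best_a
    forces = a * fmax
    r = reaction(a)
    assessment = stability_eval(r, frame, ratios)
    residual = float(np.linalg.norm(M @ forces - target_moment))
    feasible = valid(a)
    diagnostics = "" if feasible else (
        ("LP-certified infeasible; " if lp_infeasible else "")
        + f"status={last_res.status} {last_res.message}; "
        + f"residual={residual:.3e} N.m; "
        + f"min_margin={assessment.margins.min():.3e} N"
    )
    stress = forces / pcsa
    return MuscleForceSolution(
        instance=load.instance,
        element_names=names,
        forces=forces,
        normalized=100.0 * a,
        reaction_force=r,
        equilibrium_residual=residual,
        stability_margins=assessment.margins,
        feasible=feasible,
        objective_value=float(np.sum(stress**p)),
        diagnostics=diagnostics,
    )
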