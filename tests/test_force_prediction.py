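"""Stability evaluation and the constrained muscle-force solver.

Solver checks use brute-force grid-search oracles on planar toy problems:
the equality (moment) constraint is eliminated analytically, the remaining
force space is scanned on a dense grid with progressive refinement, and the
best feasible grid point is compared against the solver's optimum.
"""

import dataclasses

import numpy as np
import pytest

import cuffmc
from cuffmc import force_prediction as fp
from cuffmc.external_dynamics import ExternalLoad
from cuffmc.geometry_engine import MusclePath
from cuffmc.species_params import MuscleElementSpec


def _element(name="m", pcsa=3.0):
    return MuscleElementSpec(
        name=name,
        absolute_pcsa_cm2=pcsa,
        attachment_bone="scapula",
        attachment_mean=np.zeros(3),
        fixed_end="humerus:x",
    )


def test_max_force_is_pcsa_times_specific_tension():
    e = _element(pcsa=2.81)
    assert cuffmc.max_force(e, 88.0) == pytest.approx(247.28)
    assert cuffmc.max_force(_element(pcsa=2 * 2.81), 88.0) == pytest.approx(
        2 * 247.28
    )
    with pytest.raises(ValueError):
        cuffmc.max_force(e, 0.0)


# -- stability evaluation ----------------------------------------------------

def _toy_frame():
    """Glenoid frame whose compression direction is world -y (face up)."""
    return cuffmc.build_glenoid_frame(
        centroid=np.zeros(3),
        superior_point=np.array([1.0, 0.0, 0.0]),  # frame-superior = world +x
        anterior_hint=np.array([0.0, 0.0, 1.0]),
    )


def test_pure_compression_margins():
    frame = _toy_frame()
    ratios = np.linspace(0.3, 1.0, 8)
    reaction = -100.0 * frame.z_axis  # straight into the glenoid
    a = cuffmc.stability_eval(reaction, frame, ratios)
    assert a.compression == pytest.approx(100.0)
    np.testing.assert_allclose(a.margins, ratios * 100.0, atol=1e-9)
    assert not a.dislocating


def test_boundary_shear_margin_zero():
    frame = _toy_frame()
    ratios = np.full(8, 0.5)
    reaction = -100.0 * frame.z_axis + 50.0 * frame.y_axis  # shear along superior
    a = cuffmc.stability_eval(reaction, frame, ratios)
    assert a.margins[0] == pytest.approx(0.0, abs=1e-9)
    assert a.governing_margin == pytest.approx(0.0, abs=1e-9)


def test_interpolated_ratio_midway():
    """Shear at 22.5 degrees between ratios 0.4 and 0.6 allows 0.5."""
    ratios = np.array([0.4, 0.6, 1, 1, 1, 1, 1, 1])
    assert fp.interpolate_ratio(ratios, 22.5) == pytest.approx(0.5)
    assert fp.interpolate_ratio(ratios, 0.0) == pytest.approx(0.4)
    assert fp.interpolate_ratio(ratios, 45.0) == pytest.approx(0.6)


def test_dislocating_load_flagged():
    frame = _toy_frame()
    ratios = np.full(8, 0.5)
    a = cuffmc.stability_eval(10.0 * frame.y_axis + 1.0 * frame.z_axis, frame, ratios)
    assert a.dislocating
    assert np.all(a.margins <= 0.0)


# -- toy solver problems with grid-search oracles ----------------------------

def _straight(name, insertion, direction):
    direction = np.asarray(direction, float)
    direction = direction / np.linalg.norm(direction)
    insertion = np.asarray(insertion, float)
    return MusclePath(
        element=name,
        via_points=np.vstack([insertion + direction, insertion]),
        effective_origin_direction=direction,
        path_length=1.0,
    )


def _load(moment, demand=np.zeros(3)):
    return ExternalLoad(
        instance="mid_support",
        hand_force=np.zeros(3),
        gh_moment=np.asarray(moment, float),
        gh_force_demand=np.asarray(demand, float),
    )


def _solve(paths, load, fmax, pcsa, ratios, p):
    return cuffmc.solve_muscle_forces(
        paths,
        load,
        np.asarray(fmax, float),
        np.asarray(pcsa, float),
        _toy_frame(),
        np.asarray(ratios, float),
        gh_center=np.zeros(3),
        exponent=p,
    )


def _grid_refine(evaluate, lows, highs, n_pts=120, n_rounds=5, orig_bounds=None):
    """Progressively refined dense grid search; returns best point and value."""
    lows, highs = np.asarray(lows, float), np.asarray(highs, float)
    if orig_bounds is None:
        orig_bounds = (lows.copy(), highs.copy())
    best = None
    for _ in range(n_rounds):
        axes = [np.linspace(lo, hi, n_pts) for lo, hi in zip(lows, highs)]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        vals = evaluate(pts)
        k = np.nanargmin(vals)
        best = pts[k], vals[k]
        half = (highs - lows) / 8  # generous zoom keeps flat valleys inside
        lows = np.maximum(orig_bounds[0], best[0] - half)
        highs = np.minimum(orig_bounds[1], best[0] + half)
    return best


def test_two_muscle_p2_matches_grid_oracle():
    """Stress-weighted sharing between two antagonist-free muscles (p=2)."""
    paths = [
        _straight("a", [0.05, 0.0, 0.0], [0.0, -1.0, 0.0]),
        _straight("b", [-0.04, 0.0, 0.0], [0.0, -1.0, 0.0]),
    ]
    pcsa = np.array([3.0, 5.0])
    fmax = pcsa * 88.0
    # moment arms about z: -0.05 and +0.04; demand a moment mixing both
    load = _load([0.0, 0.0, 2.0])
    sol = _solve(paths, load, fmax, pcsa, np.full(8, 2.0) * 0.74, p=2)
    assert sol.feasible

    # oracle: eliminate f2 via the single active moment equation, scan f1
    a_z, b_z = -0.05, 0.04
    target = -2.0

    def evaluate(pts):
        f1 = pts[:, 0]
        f2 = (target - a_z * f1) / b_z
        bad = (f2 < 0) | (f2 > fmax[1])
        val = (f1 / pcsa[0]) ** 2 + (f2 / pcsa[1]) ** 2
        val[bad] = np.nan
        return val

    (f1_star,), _ = _grid_refine(evaluate, [0.0], [fmax[0]], n_pts=4001, n_rounds=4)
    f2_star = (target - a_z * f1_star) / b_z
    np.testing.assert_allclose(sol.forces, [f1_star, f2_star], atol=1e-3)


def test_three_muscle_stability_binding_matches_grid_oracle():
    """The unconstrained optimum violates the superior margin; the solution
    recruits the opposing (inferiorly directed) element."""
    s = np.sin(np.pi / 6)
    c = np.cos(np.pi / 6)
    paths = [
        _straight("pro", [0.05, 0.08, 0.0], [s, -c, 0.0]),   # +x shear
        _straight("anti", [-0.05, 0.08, 0.0], [-s, -c, 0.0]),  # -x shear
        _straight("comp", [0.0, 0.08, 0.0], [0.0, -1.0, 0.0]),  # pure compressor
    ]
    pcsa = np.array([4.0, 4.0, 4.0])
    fmax = pcsa * 88.0
    load = _load([0.0, 0.0, 2.0])
    ratios = np.array([0.15, 0.5, 0.8, 0.8, 0.8, 0.8, 0.8, 0.5])  # weak superior
    sol = _solve(paths, load, fmax, pcsa, ratios, p=3)
    assert sol.feasible

    U = np.column_stack([p.effective_origin_direction for p in paths])
    M = np.column_stack([cuffmc.moment_arm(p, np.zeros(3)) for p in paths])
    frame = _toy_frame()
    target = -np.asarray(load.gh_moment)

    def evaluate(pts):
        # eliminate f2 from the z-moment equation
        f1 = pts[:, 0]
        f3 = pts[:, 1]
        f2 = (target[2] - M[2, 0] * f1 - M[2, 2] * f3) / M[2, 1]
        F = np.stack([f1, f2, f3], axis=1)
        bad = (f2 < 0) | (f2 > fmax[1])
        R = F @ U.T
        comp = -(R @ frame.z_axis)
        sx = R @ frame.x_axis
        sy = R @ frame.y_axis
        proj = np.stack([sx, sy], axis=1) @ fp._DIRS_2D.T
        margins = ratios * comp[:, None] - np.maximum(proj, 0.0)
        bad |= np.any(margins < -1e-9, axis=1)
        val = np.sum((F / pcsa) ** 3, axis=1)
        val[bad] = np.nan
        return val

    (f1_star, f3_star), obj_star = _grid_refine(
        evaluate, [0.0, 0.0], fmax[[0, 2]], n_pts=201, n_rounds=12
    )
    f2_star = (target[2] - M[2, 0] * f1_star - M[2, 2] * f3_star) / M[2, 1]
    np.testing.assert_allclose(sol.forces, [f1_star, f2_star, f3_star], atol=1e-3)
    assert sol.forces[1] > 1.0  # opposing element genuinely recruited
    # and the margin for the weak superior direction is active (near zero)
    assert sol.stability_margins[0] < 1.0


def test_two_muscle_p3_bound_binding_matches_grid_oracle():
    """A force bound saturates; the remainder shifts to the weaker muscle."""
    paths = [
        _straight("a", [0.05, 0.0, 0.0], [0.0, -1.0, 0.0]),
        _straight("c", [0.08, 0.0, 0.0], [0.0, -1.0, 0.0]),
    ]
    pcsa = np.array([20.0, 2.0])
    fmax = np.array([60.0, 2.0 * 88.0])  # artificially low bound on muscle a
    load = _load([0.0, 0.0, 3.5])  # both arms negative; a is far cheaper
    sol = _solve(paths, load, fmax, pcsa, np.full(8, 1.2), p=3)
    assert sol.feasible

    a_z, c_z = -0.05, -0.08
    target = -3.5

    def evaluate(pts):
        f1 = pts[:, 0]
        f2 = (target - a_z * f1) / c_z
        bad = (f2 < -1e-12) | (f2 > fmax[1])
        val = (f1 / pcsa[0]) ** 3 + (np.maximum(f2, 0) / pcsa[1]) ** 3
        val[bad] = np.nan
        return val

    (f1_star,), _ = _grid_refine(evaluate, [0.0], [fmax[0]], n_pts=4001, n_rounds=4)
    f2_star = (target - a_z * f1_star) / c_z
    np.testing.assert_allclose(sol.forces, [f1_star, f2_star], atol=1e-3)
    assert sol.forces[0] == pytest.approx(60.0, abs=1e-4)  # bound saturated


def test_zero_load_gives_zero_forces():
    paths = [
        _straight("a", [0.05, 0.0, 0.0], [0.0, -1.0, 0.0]),
        _straight("b", [-0.05, 0.0, 0.0], [0.0, -1.0, 0.0]),
    ]
    sol = _solve(paths, _load(np.zeros(3)), [100, 100], [2, 2], np.full(8, 0.5), 3)
    assert sol.feasible
    # forces vanish up to the solver's internal stability safety offset
    np.testing.assert_allclose(sol.forces, 0.0, atol=1e-5)


def test_infeasible_flag_not_exception():
    """An unmeetable moment demand returns an infeasible flag with diagnostics."""
    paths = [_straight("a", [0.05, 0.0, 0.0], [0.0, -1.0, 0.0])]
    load = _load([0.0, 0.0, 1000.0])
    sol = _solve(paths, load, [100.0], [2.0], np.full(8, 0.5), 3)
    assert not sol.feasible
    assert sol.diagnostics != ""


def test_pcsa_scaling_leaves_normalized_invariant():
    """Scaling PCSAs (and the moment demand) by c preserves normalized forces."""
    paths = [
        _straight("a", [0.05, 0.0, 0.0], [0.1, -1.0, 0.0]),
        _straight("b", [-0.04, 0.0, 0.0], [-0.1, -1.0, 0.0]),
        _straight("c", [0.0, 0.01, 0.0], [0.0, -1.0, 0.0]),
    ]
    pcsa = np.array([3.0, 5.0, 2.0])
    ratios = np.full(8, 1.4)
    base = _solve(paths, _load([0, 0, 1.5]), pcsa * 88, pcsa, ratios, 3)
    c = 2.7
    scaled = _solve(paths, _load([0, 0, 1.5 * c]), c * pcsa * 88, c * pcsa, ratios, 3)
    assert base.feasible and scaled.feasible
    np.testing.assert_allclose(scaled.normalized, base.normalized, atol=1e-4)


def test_full_model_solutions_respect_invariants(human, chimp):
    """Feasible solutions satisfy equilibrium and stability at tolerance."""
    for sp in (human, chimp):
        for instance in ("early_support", "mid_support", "late_support"):
            model = cuffmc.GlenohumeralModel(sp, instance)
            sol = model.solve()
            assert sol.feasible
            assert sol.equilibrium_residual <= 1e-6
            assert np.all(sol.stability_margins >= -1e-9)
            assert np.all(sol.normalized >= 0) and np.all(sol.normalized <= 100)
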