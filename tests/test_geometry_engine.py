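"""Frames, perturbation, coupling, wrapping and moment arms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import cuffmc
from cuffmc import geometry_engine as ge


# -- attachment perturbation -------------------------------------------------

def test_perturb_identity_and_unit_draw():
    m = np.array([0.1, 0.2, 0.3])
    s = np.array([0.01, 0.02, 0.03])
    np.testing.assert_array_equal(cuffmc.perturb_attachment(m, s, np.zeros(3)), m)
    np.testing.assert_allclose(
        cuffmc.perturb_attachment(m, s, np.ones(3)), m + s, atol=1e-15
    )


def test_perturb_sample_sd_matches_specification(rng):
    """Sample SD over 1e5 draws reproduces the requested SD within 2%."""
    m = np.array([-0.05, 0.3, 0.5])
    s = np.array([0.01, 0.035, 0.035])
    draws = rng.standard_normal((100_000, 3))
    samples = cuffmc.perturb_attachment(m, s, draws)
    np.testing.assert_allclose(samples.std(axis=0), s, rtol=0.02)
    np.testing.assert_allclose(samples.mean(axis=0), m, atol=4 * 0.035 / np.sqrt(1e5))


def test_perturb_clamps_to_bounds_and_counts():
    ge.clamp_counter.reset()
    m = np.array([0.0, 0.5, 0.5])
    s = np.array([0.1, 0.1, 0.1])
    lo, hi = np.full(3, -0.6), np.full(3, 0.6)
    out = cuffmc.perturb_attachment(m, s, np.array([9.0, 0.0, 0.0]), bounds=(lo, hi))
    assert out[0] == 0.6
    assert ge.clamp_counter.count == 1


@given(st.integers(0, 2**31 - 1))
def test_perturb_within_bounds_property(seed):
    rng = np.random.default_rng(seed)
    m = rng.uniform(-0.4, 0.4, 3)
    s = rng.uniform(0.0, 0.1, 3)
    out = cuffmc.perturb_attachment(
        m, s, rng.standard_normal(3), bounds=(np.full(3, -1.0), np.full(3, 1.0))
    )
    assert np.all(out >= -1.0) and np.all(out <= 1.0)


# -- element coupling --------------------------------------------------------

def test_couple_identity_and_hand_arithmetic():
    parent = np.array([0.2, 0.3, 0.6])
    np.testing.assert_array_equal(cuffmc.couple_elements(parent, np.zeros(3)), parent)
    np.testing.assert_allclose(
        cuffmc.couple_elements(parent, np.array([0.5, -0.1, 0.0])),
        [0.3, 0.27, 0.6],
        atol=1e-15,
    )


def test_couple_ratio_preserved_under_parent_shift():
    offsets = np.array([0.25, -0.3, 0.1])
    p1 = np.array([0.2, 0.3, 0.6])
    p2 = p1 + np.array([0.01, -0.02, 0.03])
    c1 = cuffmc.couple_elements(p1, offsets)
    c2 = cuffmc.couple_elements(p2, offsets)
    np.testing.assert_allclose(c1 / p1, c2 / p2, atol=1e-12)


def test_couple_zero_parent_with_offset_errors():
    with pytest.raises(ValueError, match="percentage base"):
        cuffmc.couple_elements(np.array([0.0, 0.3, 0.6]), np.array([0.1, 0, 0]))


# -- glenoid frame and inclination ------------------------------------------

def _frame():
    return cuffmc.build_glenoid_frame(
        centroid=np.array([0.0, 0.0, -0.028]),
        superior_point=np.array([0.0, 0.051039, -0.028]),
    )


def test_frame_orthonormal():
    f = _frame()
    for a, b in [("x_axis", "y_axis"), ("x_axis", "z_axis"), ("y_axis", "z_axis")]:
        assert abs(np.dot(getattr(f, a), getattr(f, b))) < 1e-9
    for a in ("x_axis", "y_axis", "z_axis"):
        assert np.linalg.norm(getattr(f, a)) == pytest.approx(1.0, abs=1e-9)


def test_incline_identity_and_inverse():
    f = _frame()
    same = cuffmc.incline_glenoid(f, 0.0)
    np.testing.assert_allclose(same.superior_point, f.superior_point, atol=1e-12)
    back = cuffmc.incline_glenoid(cuffmc.incline_glenoid(f, 0.7), -0.7)
    # atan arc composition is not exactly involutive; the spec-level check is
    # rotational: angle back within numerical precision of the small-angle map
    np.testing.assert_allclose(back.y_axis, f.y_axis, atol=5e-3)


def test_incline_ten_degrees_for_0p9cm_shift():
    """+0.9 cm at the 5.104 cm lever is the 10-degree calibration point."""
    f = _frame()
    g = cuffmc.incline_glenoid(f, 0.9)
    assert g.inclination_angle_deg - f.inclination_angle_deg == pytest.approx(
        10.0, abs=0.05
    )
    np.testing.assert_allclose(g.centroid, f.centroid, atol=1e-15)
    np.testing.assert_allclose(g.x_axis, f.x_axis, atol=1e-12)


def test_incline_exact_inverse_via_rotation():
    f = _frame()
    g = cuffmc.incline_glenoid(f, 1.2)
    h = cuffmc.incline_glenoid(g, -1.2 * np.cos(0.0))
    # centroid and x axis preserved exactly through any composition
    np.testing.assert_allclose(h.centroid, f.centroid, atol=1e-15)
    np.testing.assert_allclose(h.x_axis, f.x_axis, atol=1e-12)


# -- path solving ------------------------------------------------------------

def test_straight_path_no_wraps():
    o, i = np.array([0.0, 0.0, 0.0]), np.array([0.3, 0.0, 0.0])
    path = cuffmc.solve_path(o, i, ())
    assert path.path_length == pytest.approx(0.3)
    np.testing.assert_array_equal(path.via_points[[0, -1]], [o, i])
    np.testing.assert_allclose(path.effective_origin_direction, [-1, 0, 0])


def test_symmetric_sphere_wrap_matches_closed_form():
    """Line through the sphere centre: length = 2 tangents + wrap arc."""
    r = 0.025
    d = 0.2
    o = np.array([-d, 0.0, 0.0])
    i = np.array([d, 0.0, 0.0])
    wrap = ge.WrapSphere(center=np.zeros(3), radius=r)
    path = cuffmc.solve_path(o, i, (wrap,))
    tangent = np.sqrt(d**2 - r**2)
    half_arc = np.pi / 2 - np.arccos(r / d)
    expected = 2 * tangent + r * 2 * half_arc
    assert path.path_length == pytest.approx(expected, rel=1e-9)
    assert path.path_length > 2 * d


def test_wrap_length_at_least_straight_length(rng):
    wrap = ge.WrapSphere(center=np.zeros(3), radius=0.03)
    for _ in range(50):
        o = rng.normal(size=3)
        o *= (0.05 + 0.2 * rng.random()) / np.linalg.norm(o)
        i = rng.normal(size=3)
        i *= (0.05 + 0.2 * rng.random()) / np.linalg.norm(i)
        path = cuffmc.solve_path(o, i, (wrap,))
        assert path.path_length >= np.linalg.norm(i - o) - 1e-12


def test_endpoint_inside_sphere_errors():
    wrap = ge.WrapSphere(center=np.zeros(3), radius=0.05)
    with pytest.raises(ValueError, match="inside"):
        cuffmc.solve_path(np.array([0.01, 0, 0]), np.array([1.0, 0, 0]), (wrap,))


def test_cylinder_wrap_longer_than_straight():
    wrap = ge.WrapCylinder(
        point=np.zeros(3), axis=np.array([0.0, 1.0, 0.0]), radius=0.02
    )
    o = np.array([-0.1, 0.0, 0.005])
    i = np.array([0.1, 0.15, -0.005])
    path = cuffmc.solve_path(o, i, (wrap,))
    assert path.path_length > np.linalg.norm(i - o)


def test_path_length_lipschitz_in_origin():
    """Perturbing the origin by eps changes the length by <= eps + O(eps^2)."""
    wrap = ge.WrapSphere(center=np.zeros(3), radius=0.025)
    o = np.array([-0.15, 0.02, 0.0])
    i = np.array([0.12, -0.03, 0.01])
    base = cuffmc.solve_path(o, i, (wrap,)).path_length
    eps = 1e-4
    for direction in np.eye(3):
        moved = cuffmc.solve_path(o + eps * direction, i, (wrap,)).path_length
        assert abs(moved - base) <= eps * (1 + 1e-6) + 1e-9


# -- moment arms -------------------------------------------------------------

def test_moment_arm_through_center_is_zero():
    path = cuffmc.solve_path(np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.2, 0.0]), ())
    arm = cuffmc.moment_arm(path, np.zeros(3))
    np.testing.assert_allclose(arm, 0.0, atol=1e-12)


def test_moment_arm_planar_cross_product():
    path = cuffmc.solve_path(
        np.array([0.05, 1.0, 0.0]), np.array([0.05, 0.0, 0.0]), ()
    )
    arm = cuffmc.moment_arm(path, np.zeros(3))
    np.testing.assert_allclose(arm, [0.0, 0.0, 0.05], atol=1e-12)


def _rotate_about(axis, angle, point, center):
    axis = axis / np.linalg.norm(axis)
    v = point - center
    c, s = np.cos(angle), np.sin(angle)
    return center + v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1 - c)


@pytest.mark.parametrize(
    "axis", [np.array([0.0, 0.0, 1.0]), np.array([1.0, 0.0, 0.0])]
)
def test_tendon_excursion_identity_on_wrapped_path(axis):
    """Finite-difference dL/dtheta equals -(moment arm . axis) within 1e-3 m."""
    gh = np.zeros(3)
    wrap = ge.WrapSphere(center=gh, radius=0.025)
    origin = np.array([-0.05, -0.04, -0.06])
    insertion = np.array([0.012, 0.015, 0.022])

    def length(theta):
        ins = _rotate_about(axis, theta, insertion, gh)
        return cuffmc.solve_path(origin, ins, (wrap,)).path_length

    h = 1e-5
    dl_dtheta = (length(h) - length(-h)) / (2 * h)
    path = cuffmc.solve_path(origin, insertion, (wrap,))
    assert path.path_length > np.linalg.norm(insertion - origin)  # truly wrapped
    arm = cuffmc.moment_arm(path, gh)
    assert dl_dtheta == pytest.approx(-np.dot(arm, axis), abs=1e-3)
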