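import numpy as np
import pytest

from equivol.laminar import (LaminarSystem, build_laminar_system, equivol_depth,
                             extract_equivol_layer, reparametrize,
                             surface_jacobian, surface_jacobian_transport,
                             thickness, time_change)
from equivol.registration import RegistrationResult
from equivol.kernels import KernelSpec
from equivol.synthetic import (concentric_spheres, flat_slab, icosphere,
                               normal_offset_system, radial_sphere_system)


@pytest.fixture(scope="module")
def radial_system():
    return radial_sphere_system(1.0, 2.0, 3, 21)


@pytest.fixture(scope="module")
def slab_system():
    lower, upper = flat_slab(2.0, 0.5, 9)
    return normal_offset_system(lower, 0.5, 11)


def zero_flow_result(surface, time_steps=4):
    traj = np.repeat(surface.vertices[None], time_steps + 1, axis=0)
    return RegistrationResult(
        trajectories=traj,
        momentum=np.zeros((time_steps, surface.n_vertices, 3)),
        faces=surface.faces.copy(), flow_kernel=KernelSpec(0.5),
        final_energy=0.0, final_discrepancy=0.0, initial_discrepancy=0.0,
        energy_trace=np.zeros(1), residual_trace=np.zeros(0))


# ---------------------------------------------------------------------------
# system construction
# ---------------------------------------------------------------------------

def test_zero_flow_layers_all_equal_inner(unit_icosphere):
    system = build_laminar_system(zero_flow_result(unit_icosphere))
    assert system.n_streamlines == unit_icosphere.n_vertices
    for j in range(system.n_times):
        np.testing.assert_array_equal(system.positions[j],
                                      unit_icosphere.vertices)
    assert thickness(system).max() == 0.0


def test_registration_streamlines_radial(small_constrained_registration):
    system = build_laminar_system(small_constrained_registration)
    chord = system.positions[-1] - system.positions[0]
    radial = system.positions[0] / np.linalg.norm(system.positions[0], axis=1,
                                                  keepdims=True)
    cosang = np.einsum("ij,ij->i", chord, radial) / np.linalg.norm(chord, axis=1)
    assert np.degrees(np.arccos(np.clip(cosang, -1, 1))).max() < 2.0


def test_refined_grid_has_expected_size(small_constrained_registration):
    system = build_laminar_system(small_constrained_registration,
                                  refinement=3, integrator="rk4")
    T = small_constrained_registration.time_steps
    assert system.n_times == 3 * T + 1
    np.testing.assert_array_equal(system.positions[0],
                                  small_constrained_registration.trajectories[0])


def test_normals_oriented_along_flow(radial_system, slab_system):
    for system in (radial_system, slab_system):
        dots = np.einsum("mnj,mnj->mn", system.normals, system.velocities)
        assert (dots >= 0).all()


# ---------------------------------------------------------------------------
# thickness
# ---------------------------------------------------------------------------

def test_thickness_is_polyline_length():
    # a single straight 3-segment streamline of known length
    verts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
    faces = np.array([[0, 1, 2]])
    direction = np.array([0.0, 0.0, 1.0])
    times = np.array([0.0, 1 / 3, 2 / 3, 1.0])
    positions = verts[None] + 2.4 * times[:, None, None] * direction
    system = LaminarSystem.from_positions(times, positions, faces)
    np.testing.assert_allclose(thickness(system), 2.4, rtol=1e-12)


def test_radial_thickness_matches_gap(radial_system):
    np.testing.assert_allclose(thickness(radial_system), 1.0, rtol=1e-12)


def test_registered_thickness_within_tolerance(small_constrained_registration):
    theta = thickness(build_laminar_system(small_constrained_registration))
    assert np.abs(theta - 1.0).max() < 0.05


# ---------------------------------------------------------------------------
# surface Jacobian (one-ring and transport)
# ---------------------------------------------------------------------------

def test_sigma_uniform_scaling_exact(unit_icosphere):
    times = np.linspace(0, 1, 6)
    s = 1.0 + 0.7 * times
    positions = s[:, None, None] * unit_icosphere.vertices[None]
    system = LaminarSystem.from_positions(times, positions, unit_icosphere.faces)
    sigma = surface_jacobian(system)
    np.testing.assert_allclose(sigma, np.broadcast_to((s ** 2)[:, None],
                                                      sigma.shape), rtol=1e-12)


def test_sigma_rigid_motion_is_one(unit_icosphere):
    times = np.linspace(0, 1, 5)
    angle = 0.8 * times
    positions = []
    for a in angle:
        rot = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1.0]])
        positions.append(unit_icosphere.vertices @ rot.T + [0.1 * a, 0, 0])
    system = LaminarSystem.from_positions(times, np.array(positions),
                                          unit_icosphere.faces)
    np.testing.assert_allclose(surface_jacobian(system), 1.0, rtol=1e-12)


def test_sigma_radial_flow_matches_area_ratio(radial_system):
    r = 1.0 + radial_system.times
    sigma = surface_jacobian(radial_system)
    np.testing.assert_allclose(
        sigma, np.broadcast_to((r ** 2)[:, None], sigma.shape), rtol=0.01)


def test_sigma_transport_identity_flow(unit_icosphere):
    sigma = surface_jacobian_transport(zero_flow_result(unit_icosphere))
    np.testing.assert_allclose(sigma, 1.0, rtol=1e-12)


def test_sigma_transport_agrees_with_one_ring(small_constrained_registration):
    res = small_constrained_registration
    system = build_laminar_system(res, refinement=2, integrator="rk4")
    ring = surface_jacobian(system)
    transported = surface_jacobian_transport(res, refinement=2)
    assert np.abs(transported / ring - 1.0).max() < 0.02


def test_sigma_transport_debug_ode_disagrees(small_constrained_registration):
    res = small_constrained_registration
    system = build_laminar_system(res, refinement=2, integrator="rk4")
    ring = surface_jacobian(system)
    literal = surface_jacobian_transport(res, refinement=2, debug_ode=True)
    assert np.abs(literal / ring - 1.0).max() > 0.05


# ---------------------------------------------------------------------------
# equivolumetric depth / time change
# ---------------------------------------------------------------------------

def test_gamma_zero_flow(unit_icosphere):
    system = build_laminar_system(zero_flow_result(unit_icosphere))
    gamma = equivol_depth(system, surface_jacobian(system))
    assert np.abs(gamma).max() == 0.0


def test_gamma_radial_closed_form(radial_system):
    gamma = equivol_depth(radial_system, surface_jacobian(radial_system))
    # int_0^1 r'(t) (r/r0)^2 dt = (r1^3 - r0^3) / (3 r0^2) = 7/3
    assert gamma[-1].mean() == pytest.approx(7.0 / 3.0, rel=0.02)


def test_gamma_slab_equals_height(slab_system):
    gamma = equivol_depth(slab_system, surface_jacobian(slab_system))
    np.testing.assert_allclose(gamma[-1], 0.5, rtol=1e-12)


def test_tau_slab_is_identity(slab_system):
    gamma = equivol_depth(slab_system, surface_jacobian(slab_system))
    c0, tau = time_change(gamma)
    np.testing.assert_allclose(
        tau, np.broadcast_to(slab_system.times[:, None], tau.shape),
        atol=1e-12)
    np.testing.assert_allclose(c0, np.full_like(c0, 0.5), rtol=1e-12)


def test_tau_radial_closed_form(radial_system):
    gamma = equivol_depth(radial_system, surface_jacobian(radial_system))
    c0, tau = time_change(gamma)
    r = 1.0 + radial_system.times
    expected = ((r ** 3 - 1.0) / 7.0)[:, None]
    assert np.abs(tau - expected).max() < 1e-3
    np.testing.assert_array_equal(tau[0], 0.0)
    np.testing.assert_array_equal(tau[-1], 1.0)
    assert (np.diff(tau, axis=0) >= -1e-12).all()


def test_backtracking_flow_rejected():
    gamma = np.array([[0.0, 0.0], [0.5, -0.1], [1.0, -0.2]])
    with pytest.raises(ValueError, match="vertex 1"):
        time_change(gamma)


# ---------------------------------------------------------------------------
# layer extraction / reparametrization
# ---------------------------------------------------------------------------

def test_extreme_levels_return_end_surfaces(radial_system):
    gamma = equivol_depth(radial_system, surface_jacobian(radial_system))
    _, tau = time_change(gamma)
    np.testing.assert_array_equal(
        extract_equivol_layer(radial_system, tau, 0.0).vertices,
        radial_system.positions[0])
    np.testing.assert_array_equal(
        extract_equivol_layer(radial_system, tau, 1.0).vertices,
        radial_system.positions[-1])


def test_equivolumetric_midlayer_radius(radial_system):
    gamma = equivol_depth(radial_system, surface_jacobian(radial_system))
    _, tau = time_change(gamma)
    layer = extract_equivol_layer(radial_system, tau, 0.5)
    radii = np.linalg.norm(layer.vertices, axis=1)
    assert radii.mean() == pytest.approx(4.5 ** (1 / 3), rel=0.01)
    assert abs(radii.mean() - 1.5) > 0.1     # clearly not the equidistant layer


def test_nonmonotone_tau_flagged(radial_system):
    gamma = equivol_depth(radial_system, surface_jacobian(radial_system))
    _, tau = time_change(gamma)
    tau = tau.copy()
    tau[5, 3] = tau[7, 3] + 0.05             # force a local decrease
    with pytest.raises(ValueError, match="vertex 3"):
        extract_equivol_layer(radial_system, tau, 0.5)


def test_reparametrize_self_consistency(radial_system):
    gamma = equivol_depth(radial_system, surface_jacobian(radial_system))
    c0, tau = time_change(gamma)
    resampled = reparametrize(radial_system, tau, 20)
    g2 = equivol_depth(resampled, surface_jacobian(resampled))
    c02, tau2 = time_change(g2)
    assert np.abs(tau2 - resampled.times[:, None]).max() < 1e-3


def test_reparametrize_slab_is_identity(slab_system):
    gamma = equivol_depth(slab_system, surface_jacobian(slab_system))
    _, tau = time_change(gamma)
    resampled = reparametrize(slab_system, tau, slab_system.n_times - 1)
    np.testing.assert_allclose(resampled.positions, slab_system.positions,
                               atol=1e-12)


def test_tau_invariant_under_time_resampling():
    # the same radial flow sampled on two grids yields the same mid layer
    coarse = radial_sphere_system(1.0, 2.0, 2, 11)
    fine = radial_sphere_system(1.0, 2.0, 2, 41)
    layers = []
    for system in (coarse, fine):
        gamma = equivol_depth(system, surface_jacobian(system))
        _, tau = time_change(gamma)
        layers.append(np.linalg.norm(
            extract_equivol_layer(system, tau, 0.5).vertices, axis=1).mean())
    assert layers[0] == pytest.approx(layers[1], rel=2e-3)


def test_streamlines_unchanged_by_reparametrization(radial_system):
    gamma = equivol_depth(radial_system, surface_jacobian(radial_system))
    _, tau = time_change(gamma)
    resampled = reparametrize(radial_system, tau, 20)
    # every resampled point lies on its original radial streamline
    unit0 = radial_system.positions[0] / np.linalg.norm(
        radial_system.positions[0], axis=1, keepdims=True)
    for j in range(resampled.n_times):
        p = resampled.positions[j]
        radii = np.linalg.norm(p, axis=1)
        np.testing.assert_allclose(p, radii[:, None] * unit0, atol=1e-12)
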