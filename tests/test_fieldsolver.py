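"""Field-solver oracles: analytic domains, conservation, convergence."""

import numpy as np
import pytest

from cordstim import toys
from cordstim.anatomy import (
    ConfigurationError,
    ElectrodeConfiguration,
    Placement,
    place_electrode,
    REGION_CONTACT0,
)
from cordstim.fieldsolver import (
    MeshControl,
    Mesh,
    convergence_study,
    graded_axis,
    scale_solution,
    solve_base_field,
    solve_dirichlet,
    sampled_potential_error,
    surface_current,
)


def test_slab_matches_series_resistance_exactly():
    sol, r_analytic = toys.slab()
    assert sol["r_access"] == pytest.approx(r_analytic, rel=1e-6)


def test_slab_current_scales_with_conductivity():
    a, _ = toys.slab(sigma=0.5)
    b, _ = toys.slab(sigma=1.0)
    assert b["i_app"] == pytest.approx(2.0 * a["i_app"], rel=1e-6)


def test_concentric_spheres_oracle():
    rc, ra = toys.concentric_spheres()
    assert rc == pytest.approx(ra, rel=0.10)


@pytest.mark.parametrize("n,tol", [(49, 0.05)])
def test_point_source_profile(n, tol):
    res, analytic = toys.point_source(n=n)
    mesh, phi, rg = res["mesh"], res["phi"], res["r_grid"]
    i0 = mesh.shape[1] // 2
    ray, r = phi[:, i0, i0], rg[:, i0, i0]
    sel = (r > 1.5) & (r < 5.0)
    err = np.abs(ray[sel] - analytic(r[sel])) / np.abs(analytic(r[sel]))
    assert err.max() < tol


def test_point_source_error_decreases_under_refinement():
    errs = []
    for n in (25, 37, 55):
        res, analytic = toys.point_source(n=n)
        mesh, phi, rg = res["mesh"], res["phi"], res["r_grid"]
        i0 = mesh.shape[1] // 2
        ray, r = phi[:, i0, i0], rg[:, i0, i0]
        sel = (r > 2.0) & (r < 5.0)
        errs.append(np.mean(np.abs(ray[sel] - analytic(r[sel])) /
                            np.abs(analytic(r[sel]))))
    assert errs[0] >= errs[1] >= errs[2]


def test_maximum_principle_interior_extrema_on_boundaries():
    res, _ = toys.point_source(n=33)
    phi = res["phi"]
    assert phi.min() >= -1e-9 and phi.max() <= 1.0 + 1e-9


def test_superposition_of_monopoles():
    """A (+1, -1) bipole field equals the difference of two monopolar
    solves with matched grounded-boundary treatment."""
    mesh = toys._uniform_mesh(((-8, 8),) * 3, (17, 17, 17), 0.5)
    ia, ib = (5, 8, 8), (11, 8, 8)
    base = np.full(mesh.shape, np.nan)
    d_bi = base.copy()
    d_bi[ia], d_bi[ib] = 1.0, -1.0
    d_a = base.copy()
    d_a[ia], d_a[ib] = 1.0, 0.0
    d_b = base.copy()
    d_b[ia], d_b[ib] = 0.0, -1.0
    phi_bi, _ = solve_dirichlet(mesh, d_bi, grounded_boundary=True)
    phi_a, _ = solve_dirichlet(mesh, d_a, grounded_boundary=True)
    phi_b, _ = solve_dirichlet(mesh, d_b, grounded_boundary=True)
    assert np.allclose(phi_bi, phi_a + phi_b, atol=1e-6)


def test_all_neumann_configuration_is_singular():
    mesh = toys._uniform_mesh(((-4, 4),) * 3, (9, 9, 9), 0.5)
    with pytest.raises(ConfigurationError):
        solve_dirichlet(mesh, np.full(mesh.shape, np.nan))


def test_graded_axis_respects_forced_edges_and_bounds():
    e = graded_axis(-50.0, 50.0, [(-5.0, 5.0, 0.5)], h_max=8.0,
                    forced=[-1.205, 1.205, 3.795])
    assert e[0] == -50.0 and e[-1] == 50.0
    for f in (-1.205, 1.205, 3.795):
        assert np.min(np.abs(e - f)) < 1e-9
    assert np.all(np.diff(e) > 0)


# -- patient-model solve (shared survey-resolution fixture) -----------------

def test_charge_conservation_bipolar(p2_extradural_coarse):
    """Current out of the anode equals current into the cathode."""
    placed, sol = p2_extradural_coarse
    anode = sol.mesh.region == REGION_CONTACT0 + 2
    cathode = sol.mesh.region == REGION_CONTACT0 + 1
    ia = surface_current(sol.mesh, sol.phi, anode)
    ic = surface_current(sol.mesh, sol.phi, cathode)
    assert abs(ia + ic) / abs(ia) < 0.02


def test_unit_potentials_on_contacts(p2_extradural_coarse):
    placed, sol = p2_extradural_coarse
    assert np.allclose(sol.phi[sol.mesh.region == REGION_CONTACT0 + 2], 1.0)
    assert np.allclose(sol.phi[sol.mesh.region == REGION_CONTACT0 + 1], -1.0)
    assert sol.i_app > 0 and sol.r_access > 0


def test_scale_solution_linear(p2_extradural_coarse):
    _, sol = p2_extradural_coarse
    assert np.array_equal(scale_solution(sol, 0.0), np.zeros_like(sol.phi))
    assert np.allclose(scale_solution(sol, 2.0), 2.0 * sol.phi)


def test_access_resistance_insensitive_to_lateral_angle(
        patient2_model, adtech, p2_extradural_coarse):
    _, sol0 = p2_extradural_coarse
    placed = place_electrode(patient2_model, adtech,
                             Placement(lateral_angle_deg=-20.0))
    sol20 = solve_base_field(placed, ElectrodeConfiguration.bipolar(),
                             MeshControl.coarse())
    assert sol20.r_access == pytest.approx(sol0.r_access, rel=0.15)


def test_convergence_study_identical_levels_zero_error(
        patient2_model, adtech):
    placed = place_electrode(patient2_model, adtech, Placement())
    pts = np.column_stack([np.zeros(40), np.full(40, 6.0),
                           np.linspace(-20, 20, 40)])
    rep = convergence_study(placed, ElectrodeConfiguration.bipolar(),
                            [MeshControl.coarse(), MeshControl.coarse()], pts)
    assert rep[0]["potential_error"] < 1e-6


def test_sampled_potential_error_metric():
    a = np.array([1.0, 2.0, 0.0, -1.0])
    assert sampled_potential_error(a, a) == 0.0
    b = a + 0.02 * np.max(np.abs(a))
    assert sampled_potential_error(b, a) == pytest.approx(0.02, rel=1e-9)


# -- property tests ----------------------------------------------------------

from hypothesis import given, settings, strategies as st


@given(st.floats(0.2, 2.0), st.floats(3.0, 12.0), st.floats(1.3, 2.0))
@settings(deadline=None, derandomize=True, max_examples=30)
def test_graded_axis_covers_domain_strictly_increasing(h_fine, h_max, growth):
    e = graded_axis(-30.0, 30.0, [(-4.0, 4.0, h_fine)], h_max, growth,
                    forced=[-2.5, 1.0])
    assert e[0] == -30.0 and e[-1] == 30.0
    d = np.diff(e)
    assert np.all(d > 0)
    assert d.max() <= h_max * 1.5 + 1e-9  # segment stretching headroom
    # the fine region is resolved at (or finer than) its target
    inside = (e[:-1] > -4.0) & (e[1:] < 4.0)
    if inside.any():
        assert d[inside].max() <= h_fine * 1.5 + 1e-9
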