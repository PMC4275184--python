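"""Cable-model physiology: rest, thresholds, conduction, activating function."""

import numpy as np
import pytest

from cordstim.axons import (
    AxonModelSpec,
    CableBatch,
    PulseSpec,
    TrajectoryError,
    activating_profile,
    build_axon,
    conduction_velocity,
    resting_drift,
    simulate_response,
    _mrg_geometry,
)
from cordstim.evaluation import batch_thresholds, find_threshold

from conftest import point_source_potentials, straight_trajectory


def _cable(model="MRG", diameter=9.0, n_internodes=40):
    spec = AxonModelSpec(model=model, diameter_um=diameter)
    length = (n_internodes + 1) * spec.internode_length_um * 1e-3
    return build_axon(spec, straight_trajectory(length), align_mm=length / 2)


# -- construction ------------------------------------------------------------

def test_mrg_geometry_interpolation_between_published_rows():
    g = _mrg_geometry(9.0)
    # between the published 8.7 and 10.0 um rows
    assert 1000.0 < g["internode_len"] < 1150.0
    assert 2.8 < g["node_d"] < 3.3


@pytest.mark.parametrize("model", ["SW", "MRG"])
def test_node_spacing_increases_with_diameter(model):
    spacings = [AxonModelSpec(model=model, diameter_um=d).internode_length_um
                for d in (3.0, 6.0, 9.0, 12.0, 15.0)]
    assert np.all(np.diff(spacings) > 0)


def test_straight_fiber_uniform_node_spacing():
    cable = _cable("SW", 9.0)
    z = cable.positions[:, 2]
    assert np.allclose(np.diff(z), 0.9, atol=1e-9)  # 100 x D rule


def test_curved_trajectory_conserves_arc_length():
    spec = AxonModelSpec(model="MRG", diameter_um=9.0)
    t = np.linspace(0, 1, 400)
    pts = np.column_stack([5 * np.sin(2 * np.pi * t), 3 * t, 60 * t])
    traj_len = np.linalg.norm(np.diff(pts, axis=0), axis=1).sum()
    cable = build_axon(spec, pts)
    assert cable.arc_length_mm == pytest.approx(traj_len, rel=1e-3)
    # consecutive nodes are one internode apart in arc length, so their
    # 3-D chords never exceed it and stay close to it for a gentle curve
    node_pos = cable.positions[cable.node_index]
    chords = np.linalg.norm(np.diff(node_pos, axis=0), axis=1)
    delta = spec.internode_length_um * 1e-3
    assert np.all(chords <= delta * 1.001)
    assert np.all(chords >= delta * 0.9)
    # compartment centres lie on the trajectory polyline
    d = np.min(np.linalg.norm(cable.positions[:, None, :] -
                              pts[None, :, :], axis=2), axis=1)
    assert np.max(d) < 0.2


def test_too_short_trajectory_rejected():
    spec = AxonModelSpec(model="MRG", diameter_um=15.0)
    with pytest.raises(TrajectoryError):
        build_axon(spec, straight_trajectory(10.0))


def test_node_alignment_is_deterministic():
    a, b = _cable("MRG"), _cable("MRG")
    assert np.array_equal(a.positions, b.positions)


# -- membrane dynamics -------------------------------------------------------

@pytest.mark.parametrize("model", ["SW", "MRG"])
def test_resting_state_is_fixed_point(model):
    assert resting_drift(AxonModelSpec(model=model)) < 0.1


def test_zero_amplitude_stays_at_rest():
    cable = _cable()
    pulse = PulseSpec()
    ve = point_source_potentials(cable)
    batch = CableBatch([cable], pulse)
    act = batch.run(ve[None, :], np.array([0.0]))
    assert not act[0]
    assert batch.last_max_deviation[0] < 1.0


def test_suprathreshold_cathodic_amplitude_activates():
    cable = _cable()
    ve = point_source_potentials(cable)
    assert simulate_response(cable, ve, PulseSpec(), 1000.0)


def test_sw_threshold_exceeds_mrg_on_matched_fibers():
    pulse = PulseSpec()
    for d in (6.0, 9.0, 12.0):
        ths = {}
        for model in ("SW", "MRG"):
            spec = AxonModelSpec(model=model, diameter_um=d)
            length = 41 * spec.internode_length_um * 1e-3
            cable = build_axon(spec, straight_trajectory(length),
                               align_mm=length / 2)
            ve = point_source_potentials(cable)
            ths[model] = find_threshold(cable, ve, pulse)
        assert ths["SW"] > ths["MRG"]


@pytest.mark.parametrize("model", ["SW", "MRG"])
def test_threshold_decreases_with_diameter(model):
    pulse = PulseSpec()
    ths = []
    for d in (3.0, 9.0, 15.0):
        spec = AxonModelSpec(model=model, diameter_um=d)
        length = max(25.0, 33 * spec.internode_length_um * 1e-3)
        cable = build_axon(spec, straight_trajectory(length),
                           align_mm=length / 2)
        ve = point_source_potentials(cable)
        ths.append(find_threshold(cable, ve, pulse))
    assert ths[0] > ths[1] > ths[2]


def test_strength_duration_monotone():
    cable = _cable()
    ths = [find_threshold(cable, point_source_potentials(cable),
                          PulseSpec(pw_us=pw))
           for pw in (100.0, 300.0, 1000.0)]
    assert ths[0] > ths[1] > ths[2]


def test_activation_monotone_in_amplitude_random_fields():
    """No activate->deactivate reversal across an amplitude sweep, for 20
    random source placements (seeded)."""
    rng = np.random.default_rng(42)
    cable = _cable(n_internodes=30)
    pulse = PulseSpec()
    cables = [cable] * 20
    ves = []
    for _ in range(20):
        along = rng.uniform(0.3, 0.7)
        dist = rng.uniform(1.0, 4.0)
        sigma = rng.uniform(0.1, 1.0)
        ves.append(point_source_potentials(cable, dist_mm=dist,
                                           sigma=sigma, along=along))
    ves = np.stack(ves)
    batch = CableBatch(cables, pulse)
    th = batch_thresholds(batch, ves)
    assert np.all(np.isfinite(th))
    for mult, expect in ((0.9, False), (1.05, True), (2.0, True), (5.0, True)):
        act = batch.run(ves, th * mult)
        assert np.all(act == expect), f"x{mult} sweep violated monotonicity"


def test_conduction_velocity_increases_with_diameter_and_matches_fine_dt():
    pulse = PulseSpec()
    cvs = []
    for d in (6.0, 9.0, 12.0):
        spec = AxonModelSpec(model="MRG", diameter_um=d)
        length = 41 * spec.internode_length_um * 1e-3
        cable = build_axon(spec, straight_trajectory(length),
                           align_mm=length / 2)
        ve = point_source_potentials(cable)
        th = find_threshold(cable, ve, pulse)
        cvs.append(conduction_velocity(cable, ve, pulse, 2 * th))
    assert cvs[0] < cvs[1] < cvs[2]

    # independent fine-time-step integration as the velocity oracle
    spec = AxonModelSpec(model="MRG", diameter_um=9.0)
    length = 41 * spec.internode_length_um * 1e-3
    cable = build_axon(spec, straight_trajectory(length), align_mm=length / 2)
    ve = point_source_potentials(cable)
    th = find_threshold(cable, ve, pulse)
    cv = conduction_velocity(cable, ve, pulse, 2 * th, dt_us=5.0)
    cv_oracle = conduction_velocity(cable, ve, pulse, 2 * th, dt_us=0.5)
    assert cv == pytest.approx(cv_oracle, rel=0.05)


def test_threshold_dt_converged():
    """Halving the default time step changes the threshold by <1 %."""
    cable = _cable(n_internodes=30)
    ve = point_source_potentials(cable)
    th5 = find_threshold(cable, ve, PulseSpec(), dt_us=5.0)
    th25 = find_threshold(cable, ve, PulseSpec(), dt_us=2.5)
    assert th5 == pytest.approx(th25, rel=0.01)


# -- activating function -----------------------------------------------------

def test_activating_profile_of_linear_ramp_is_zero():
    assert np.allclose(activating_profile(np.linspace(-3, 7, 11)), 0.0)


def test_activating_profile_point_source_triphasic():
    """Cathodic point source over a straight fiber: a central positive
    (depolarizing) lobe flanked by two negative (hyperpolarizing) lobes."""
    cable = _cable("SW", 9.0)
    ve = point_source_potentials(cable)
    prof = activating_profile(ve)
    i_max = int(np.argmax(prof))
    assert prof[i_max] > 0
    assert prof[:i_max].min() < 0 and prof[i_max:].min() < 0
    assert abs(prof[i_max]) > abs(prof.min())  # primary lobe dominates


def test_activating_profile_requires_three_samples():
    with pytest.raises(ValueError):
        activating_profile(np.array([1.0, 2.0]))


# -- property tests ----------------------------------------------------------

from hypothesis import given, settings, strategies as st

_vals = st.lists(st.floats(-10.0, 10.0, allow_nan=False), min_size=3,
                 max_size=40)


@given(_vals, st.floats(-5.0, 5.0), st.floats(-5.0, 5.0))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_activating_profile_ignores_affine_component(vals, slope, offset):
    """The second spatial difference annihilates any affine potential."""
    phi = np.asarray(vals)
    x = np.arange(len(phi), dtype=float)
    assert np.allclose(activating_profile(phi + slope * x + offset),
                       activating_profile(phi), atol=1e-9)


@given(_vals, st.floats(0.1, 20.0))
@settings(deadline=None, derandomize=True, max_examples=50)
def test_activating_profile_is_linear_in_the_field(vals, scale):
    phi = np.asarray(vals)
    assert np.allclose(activating_profile(scale * phi),
                       scale * activating_profile(phi), rtol=1e-9, atol=1e-12)
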