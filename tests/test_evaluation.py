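"""Threshold search, recruitment tables and selectivity/efficiency metrics."""

import numpy as np
import pandas as pd
import pytest

from cordstim.axons import AxonModelSpec, CableBatch, PulseSpec, build_axon
from cordstim.evaluation import (
    EvaluationError,
    INEXCITABLE,
    RecruitmentTable,
    average_power,
    batch_thresholds,
    clinical_match,
    dermatome_selectivity,
    design_comparison,
    find_threshold,
    power_curve,
    selectivity,
)

from conftest import point_source_potentials, straight_trajectory


def _cable(n_internodes=30):
    spec = AxonModelSpec()
    length = (n_internodes + 1) * spec.internode_length_um * 1e-3
    return build_axon(spec, straight_trajectory(length), align_mm=length / 2)


def _table(thresholds, dermatomes=None, r_access=100.0, cls="DC"):
    th = np.asarray(thresholds, float)
    n = len(th)
    if dermatomes is None:
        dermatomes = ["S1"] * n
    rows = pd.DataFrame({
        "fiber_id": np.arange(n), "class": cls,
        "dermatome": dermatomes,
        "dermatome_index": np.zeros(n, int), "side": "left",
        "diameter_um": 9.0, "threshold_scalar": th / 2.0,
        "threshold_voltage": th, "threshold_current": th / r_access,
    })
    return RecruitmentTable(table=rows, r_access=r_access, drive_voltage=2.0,
                            pulse=PulseSpec(), model="MRG")


# -- threshold search --------------------------------------------------------

def test_bisection_matches_brute_force_sweep():
    """Bisection agrees with an exhaustive amplitude sweep at step
    rel_tol/4, on several random source geometries."""
    rng = np.random.default_rng(99)
    cable = _cable()
    pulse = PulseSpec()
    batch = CableBatch([cable], pulse)
    for _ in range(3):
        ve = point_source_potentials(cable, dist_mm=rng.uniform(1.5, 3.0),
                                     along=rng.uniform(0.4, 0.6))
        th = find_threshold(cable, ve, pulse, rel_tol=0.01)
        step = th * 0.0025
        a = th * 0.97
        sweep = None
        while a < th * 1.03:
            if batch.run(ve[None, :], np.array([a]))[0]:
                sweep = a
                break
            a += step
        assert sweep is not None
        assert th == pytest.approx(sweep, rel=0.01)


def test_threshold_scales_inversely_with_field():
    """Doubling all base-field potentials halves the threshold scalar."""
    cable = _cable()
    pulse = PulseSpec()
    ve = point_source_potentials(cable)
    th1 = find_threshold(cable, ve, pulse, rel_tol=0.002)
    th2 = find_threshold(cable, 2.0 * ve, pulse, rel_tol=0.002)
    assert th1 == pytest.approx(2.0 * th2, rel=0.01)


def test_inexcitable_sentinel_recorded_not_raised():
    cable = _cable()
    ve = np.zeros(cable.n_comp)  # no field: nothing to activate
    th = find_threshold(cable, ve, PulseSpec(), max_amplitude=64.0)
    assert th == INEXCITABLE


def test_batch_thresholds_match_single_fiber():
    cable = _cable()
    pulse = PulseSpec()
    ves = np.stack([point_source_potentials(cable, dist_mm=d)
                    for d in (1.5, 2.5, 3.5)])
    batch = CableBatch([cable] * 3, pulse)
    th = batch_thresholds(batch, ves)
    for i in range(3):
        single = find_threshold(cable, ves[i], pulse)
        assert th[i] == pytest.approx(single, rel=0.02)
    assert th[0] < th[1] < th[2]  # farther source, higher threshold


# -- recruitment table -------------------------------------------------------

def test_threshold_current_voltage_consistency():
    tab = _table([1.0, 2.0, 4.0], r_access=50.0)
    assert np.allclose(tab.table["threshold_current"],
                       tab.table["threshold_voltage"] / 50.0)
    bad = tab.table.copy()
    bad["threshold_current"] = bad["threshold_current"] * 3.0
    with pytest.raises(EvaluationError):
        RecruitmentTable(table=bad, r_access=50.0, drive_voltage=2.0,
                         pulse=PulseSpec(), model="MRG")


def test_input_output_curve_properties():
    th = [3.0, 1.0, 2.0, 5.0, 4.0]
    tab = _table(th)
    curve = tab.input_output_curve()
    assert np.all(np.diff(curve["pct_active"]) >= 0)
    assert curve["pct_active"].iloc[-1] == 100.0
    assert tab.activation_fraction(max(th)) == 1.0
    # permutation invariance
    tab2 = _table(sorted(th))
    assert np.allclose(curve["voltage"], tab2.input_output_curve()["voltage"])
    assert tab.voltage_at_fraction(0.5) == 3.0


# -- power -------------------------------------------------------------------

def test_average_power_rectangular_pulse():
    assert average_power(1.0, 1.0, PulseSpec()) == 1.0
    assert average_power(0.5, 1.0, PulseSpec()) == 0.25  # halving V quarters P
    with pytest.raises(EvaluationError):
        average_power(1.0, 0.0, PulseSpec())


def test_power_curve_monotone():
    tab = _table([1.0, 2.0, 3.0, 4.0])
    pc = power_curve(tab, PulseSpec())
    assert np.all(np.diff(pc.curve["power_w"]) >= 0)
    assert pc.power_at_fraction(0.5) == pytest.approx(4.0 / 100.0)


# -- selectivity -------------------------------------------------------------

def test_dc0_all_dr_inexcitable_is_full_activation():
    dc = _table([1.0, 2.0, 3.0])
    dr = _table([INEXCITABLE, INEXCITABLE], cls="DR")
    assert selectivity(dc, dr).dc0 == 100.0


def test_dc0_strictness_ties_not_selective():
    dc = _table([1.0, 2.0, 3.0, 4.0])
    dr = _table([2.0, 5.0], cls="DR")
    sel = selectivity(dc, dr)
    # only the 1.0 fiber is strictly below the lowest DR threshold
    assert sel.dc0 == 25.0


def test_dc_x_curve_matches_enumeration_oracle():
    """DC_X from the sorted-threshold sweep equals brute-force counting
    over a dense amplitude grid, on a 20-fiber synthetic table."""
    rng = np.random.default_rng(17)
    dc_th = rng.uniform(1.0, 10.0, 20)
    dr_th = rng.uniform(2.0, 12.0, 20)
    dc, dr = _table(dc_th), _table(dr_th, cls="DR")
    sel = selectivity(dc, dr)
    amps = np.linspace(0.0, 15.0, 5000)
    pct_dc = 100.0 * np.mean(dc_th[None, :] <= amps[:, None], axis=1)
    pct_dr = 100.0 * np.mean(dr_th[None, :] <= amps[:, None], axis=1)
    for x in (0.0, 10.0, 50.0, 100.0):
        oracle = pct_dc[pct_dr <= x].max()
        assert sel.dc_at_dr_fraction(x) == pytest.approx(oracle, abs=1e-9)
    assert sel.dc_at_dr_fraction(0.0) == sel.dc0
    curve = sel.curve
    assert np.all(np.diff(curve["pct_dc"]) >= 0)
    assert curve["pct_dc"].iloc[-1] == 100.0


def test_selectivity_rejects_empty_tables():
    dc = _table([1.0])
    with pytest.raises(EvaluationError):
        selectivity(dc, _table([], cls="DR"))


def test_dermatome_report_co_activation():
    dermatomes = ["L2", "L3", "L4", "L5", "S1", "S2", "S3"]
    tab = _table([5.0, 6.0, 7.0, 8.0, 7.5, 9.0, 2.0], dermatomes=dermatomes)
    rep = dermatome_selectivity(tab, targets=("L2", "L3", "L4", "L5"))
    assert rep["target_amplitude_v"] == 8.0
    assert rep["co_activated"] == ["S1", "S3"]
    assert not rep["selective"]


# -- clinical matching -------------------------------------------------------

def test_clinical_match_expected_percentages():
    # 100 fibers with thresholds 1..100 -> % active at current a is a%
    th = np.arange(1.0, 101.0)
    tables = {9.0: _table(th, r_access=1.0)}
    res = clinical_match(tables, reported_dermatome_sides=1,
                         clinical_amplitude_a=5.0)
    assert res["expected_pct"] == 5.0
    assert res["per_diameter_pct"][9.0] == 5.0
    res4 = clinical_match(tables, 4, 20.0)
    assert res4["expected_pct"] == 20.0
    assert res4["best_diameters"] == [9.0]


def test_clinical_match_tie_flagged_ambiguous():
    th = np.arange(1.0, 101.0)
    tables = {6.0: _table(th + 1.0, r_access=1.0),
              12.0: _table(th - 1.0, r_access=1.0)}
    res = clinical_match(tables, 1, 5.0)
    assert res["ambiguous"]
    assert set(res["best_diameters"]) == {6.0, 12.0}


# -- design comparison -------------------------------------------------------

def test_design_comparison_degenerate_single_row():
    calls = []

    def runner(design, placement, patient):
        calls.append((design, patient))
        return {"dc0": 50.0, "r_access": 100.0, "power_50": 1.0}

    from cordstim.anatomy import Placement
    tab = design_comparison(runner, ["ADTECH"], [Placement()], ["patient_2"])
    assert len(tab) == 1
    assert tab.iloc[0]["dc0"] == 50.0
    assert calls == [("ADTECH", "patient_2")]
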