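"""Shared fixtures: small geometries, fields and fiber helpers."""

import numpy as np
import pytest

from cordstim.anatomy import (
    ElectrodeConfiguration,
    Placement,
    build_spine_model,
    catalog_design,
    load_patient,
    place_electrode,
)
from cordstim.fieldsolver import MeshControl, solve_base_field


@pytest.fixture(scope="session")
def patient2_model():
    return build_spine_model(load_patient(2))


@pytest.fixture(scope="session")
def adtech():
    return catalog_design("ADTECH")


@pytest.fixture(scope="session")
def p2_extradural_coarse(patient2_model, adtech):
    """One survey-resolution bipolar solve reused across modules."""
    placed = place_electrode(patient2_model, adtech, Placement())
    sol = solve_base_field(placed, ElectrodeConfiguration.bipolar(),
                           MeshControl.coarse())
    return placed, sol


def straight_trajectory(length_mm: float, y: float = 0.0) -> np.ndarray:
    return np.array([[0.0, y, 0.0], [0.0, y, length_mm]])


def point_source_potentials(cable, i_amp_ua=-1.0, sigma=0.3, dist_mm=2.0,
                            along=0.5):
    """Analytic extracellular potentials (V) of a point current source
    placed ``dist_mm`` off the cable at fraction ``along`` of its span."""
    pos = cable.positions
    src = pos[int(along * (len(pos) - 1))] + np.array([0.0, dist_mm, 0.0])
    r = np.linalg.norm(pos - src, axis=1) * 1e-3
    return (i_amp_ua * 1e-6) / (4.0 * np.pi * sigma * r)


@pytest.fixture
def ps_field():
    return point_source_potentials
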