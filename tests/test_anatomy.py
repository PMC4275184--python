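"""Geometry, conductivity assignment and electrode placement."""

import numpy as np
import pytest

from cordstim.anatomy import (
    ALL_DESIGNS,
    CANONICAL_PLACEMENTS,
    ConductivityMap,
    Depth,
    GeometryError,
    PatientGeometry,
    Placement,
    PlacementError,
    Tissue,
    build_spine_model,
    catalog_design,
    load_all_patients,
    load_patient,
    place_electrode,
)

PUBLISHED_CONDUCTIVITIES = {
    "white_matter_longitudinal": 0.60,
    "white_matter_transverse": 0.083,
    "grey_matter": 0.23,
    "csf": 1.8,
    "dura": 0.030,
    "extradural_space": 0.20,
    "vertebral_bone": 0.02,
    "intervertebral_disc": 0.65,
    "muscle": 0.20,
}

PUBLISHED_PATIENTS = {
    "patient_1": (7, 6, 19, 16, "center"),
    "patient_2": (8, 7, 21, 18, "ventral"),
    "patient_3": (8, 6, 20, 14, "center"),
    "patient_4": (9, 6, 18, 13, "center"),
    "patient_5": (8, 6, 18, 15, "ventral"),
}


def test_default_conductivities_match_published_values():
    cond = ConductivityMap.default()
    for name, value in PUBLISHED_CONDUCTIVITIES.items():
        assert getattr(cond, name) == value


def test_patient_fixtures_match_published_measurements():
    table = load_all_patients()
    assert set(table) == set(PUBLISHED_PATIENTS)
    for key, (cml, cvd, sml, svd, place) in PUBLISHED_PATIENTS.items():
        p = table[key]
        assert (p.cord_ml, p.cord_vd, p.csf_ml, p.csf_vd) == (cml, cvd, sml, svd)
        assert p.cord_placement.value == place


def test_white_matter_conductivity_is_cord_aligned_tensor(patient2_model):
    m = patient2_model
    yc = m.cord_center[1]
    # a point in the dorsomedial white matter
    sig = m.conductivity_at(np.array([[0.0, yc + 0.85 * m.cord_semi_axes[1], 0.0]]))[0]
    assert sig[0] == sig[1] == 0.083
    assert sig[2] == 0.60


def test_patient2_cross_section_labels(patient2_model):
    m = patient2_model
    yc = m.cord_center[1]
    pts = np.array([
        [0.0, yc, 0.0],                                        # cord centre
        [0.0, (yc + m.cord_semi_axes[1] + m.csf_semi_axes[1]) / 2, 0.0],
        [49.0, 49.0, 149.0],                                   # prism corner
    ])
    labels = m.tissue_at(pts)
    assert labels[0] in (Tissue.GREY, Tissue.WHITE)
    assert labels[1] == Tissue.CSF
    assert labels[2] == Tissue.MUSCLE


def test_ventral_cord_placement_distance_ratio(patient2_model):
    """Ventral placement: the cord centre is twice as far from the dorsal
    interior dura surface as from the ventral interior surface."""
    m = patient2_model
    yc = m.cord_center[1]
    b = m.csf_semi_axes[1]
    assert (b - yc) / (yc + b) == pytest.approx(2.0, rel=1e-9)


def test_invalid_geometry_rejected():
    with pytest.raises(GeometryError):
        PatientGeometry(cord_ml=20, cord_vd=7, csf_ml=19, csf_vd=16)
    with pytest.raises(GeometryError):
        PatientGeometry(cord_ml=-1, cord_vd=7, csf_ml=19, csf_vd=16)
    with pytest.raises(GeometryError):
        ConductivityMap(csf=0.0)


def test_labels_partition_and_volumes_stable(patient2_model):
    """Every point gets exactly one valid label; Monte-Carlo label volumes
    change <1 % when the sample is doubled."""
    m = patient2_model
    rng = np.random.default_rng(7)
    half = np.array(m.prism_dims) / 2.0

    def fractions(n):
        pts = rng.uniform(-half, half, size=(n, 3))
        lab = m.tissue_at(pts)
        assert lab.min() >= 0 and lab.max() <= max(Tissue)
        return np.bincount(lab, minlength=len(Tissue)) / n

    f1, f2 = fractions(100_000), fractions(200_000)
    for t in (Tissue.MUSCLE, Tissue.BONE, Tissue.CSF):
        assert abs(f1[t] - f2[t]) < 0.01


def test_tissue_labels_mirror_symmetric(patient2_model):
    m = patient2_model
    rng = np.random.default_rng(3)
    pts = rng.uniform([-40, -40, -140], [40, 40, 140], size=(5000, 3))
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    assert np.array_equal(m.tissue_at(pts), m.tissue_at(mirrored))


# -- electrode catalogue ----------------------------------------------------

def test_catalog_designs():
    lt15 = catalog_design("LT15")
    assert lt15.n_contacts == 3 and lt15.ies == 1.5
    assert catalog_design("TT3").ies == 3.0
    ad = catalog_design("ADTECH")
    assert ad.contact_pitch == pytest.approx(5.0)
    with pytest.raises(KeyError):
        catalog_design("NOPE")
    # overrides are applied
    assert catalog_design("ADTECH", contact_length=1.32).contact_length == 1.32


def test_all_canonical_placements_fit(patient2_model):
    for did in ALL_DESIGNS:
        d = catalog_design(did)
        for pl in CANONICAL_PLACEMENTS:
            place_electrode(patient2_model, d, pl)


def test_extradural_clearance_one_mm(patient2_model, adtech):
    placed = place_electrode(patient2_model, adtech, Placement())
    cx, cy = placed.pose.center_xy
    b_out = patient2_model.dura_outer_semi_axes[1]
    gap = (cy - adtech.shaft_diameter / 2.0) - b_out
    assert gap == pytest.approx(1.0, abs=0.05)


def test_above_cord_clearance_one_mm(patient2_model, adtech):
    placed = place_electrode(patient2_model, adtech,
                             Placement(depth=Depth.ABOVE_CORD))
    cx, cy = placed.pose.center_xy
    top = patient2_model.cord_center[1] + patient2_model.cord_semi_axes[1]
    gap = (cy - adtech.shaft_diameter / 2.0) - top
    assert gap == pytest.approx(1.0, abs=0.05)


def test_midline_placement_mirror_symmetric(patient2_model, adtech):
    placed = place_electrode(patient2_model, adtech, Placement())
    rng = np.random.default_rng(11)
    pts = rng.uniform([-2, 9, -9], [2, 13, 9], size=(4000, 3))
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    assert np.array_equal(placed.electrode_region(pts),
                          placed.electrode_region(mirrored))


def test_lateral_angle_reflection(patient2_model, adtech):
    """The -10 deg placement is the sagittal reflection of +10 deg."""
    neg = place_electrode(patient2_model, adtech,
                          Placement(lateral_angle_deg=-10.0))
    pos = place_electrode(patient2_model, adtech,
                          Placement(lateral_angle_deg=+10.0))
    rng = np.random.default_rng(5)
    pts = rng.uniform([-6, 8, -9], [6, 14, 9], size=(4000, 3))
    mirrored = pts * np.array([-1.0, 1.0, 1.0])
    assert np.array_equal(neg.electrode_region(pts),
                          pos.electrode_region(mirrored))


def test_azimuthal_array_full_turn_identity(patient2_model):
    at = catalog_design("AT")
    a = place_electrode(patient2_model, at, Placement(depth=Depth.ABOVE_CORD))
    b = place_electrode(patient2_model, at,
                        Placement(depth=Depth.ABOVE_CORD,
                                  axial_rotation_deg=360.0))
    rng = np.random.default_rng(13)
    pts = rng.uniform([-2, -4, -3], [2, 1, 3], size=(4000, 3))
    assert np.array_equal(a.electrode_region(pts), b.electrode_region(pts))


def test_collision_error_names_tissue(patient2_model, adtech):
    with pytest.raises(PlacementError, match="BONE|DURA"):
        place_electrode(patient2_model, adtech,
                        Placement(clearance_mm=4.5))
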