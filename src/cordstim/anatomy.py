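"""Parametric anatomy of the stimulated spine segment.

Builds the volume-conductor geometry used throughout the package: an
elliptical spinal cord (white + grey matter) inside an elliptical dural
sac filled with CSF, surrounded by the extradural space, a vertebral
column (12 vertebrae, T3--L2, with interposed discs) and a bounding
prism of soft tissue.  Also positions electrode arrays at the canonical
extradural and intradural placements.

Coordinate convention (right-handed, mm):

* ``x``  mediolateral, + left
* ``y``  ventrodorsal, + dorsal
* ``z``  rostrocaudal, + rostral

The origin is the centre of the dural sac at the level of the stimulating
cathode; the cord axis is parallel to ``z``.  Lateral placement angles are
measured about ``z`` and are negative clockwise viewed from rostral.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml


class GeometryError(ValueError):
    """Invalid anatomical geometry."""


class PlacementError(ValueError):
    """Electrode placement collides with tissue or lies outside the model."""


class ConfigurationError(ValueError):
    """Invalid electrode contact configuration."""


def _load_data(name: str) -> dict:
    with resources.files("cordstim.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


# --------------------------------------------------------------------------
# tissues and conductivities
# --------------------------------------------------------------------------

class Tissue(enum.IntEnum):
    MUSCLE = 0
    BONE = 1
    DISC = 2
    EXTRADURAL = 3
    DURA = 4
    CSF = 5
    WHITE = 6
    GREY = 7


@dataclass(frozen=True)
class ConductivityMap:
    """Tissue conductivities in S/m.

    White matter is anisotropic and stored as a diagonal tensor aligned
    with the cord axis: the longitudinal component applies along the
    rostrocaudal axis (z), the transverse component along x and y.
    """

    white_matter_longitudinal: float = 0.60
    white_matter_transverse: float = 0.083
    grey_matter: float = 0.23
    csf: float = 1.8
    dura: float = 0.030
    extradural_space: float = 0.20
    vertebral_bone: float = 0.02
    intervertebral_disc: float = 0.65
    muscle: float = 0.20

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not value > 0:
                raise GeometryError(f"conductivity {name!r} must be > 0, got {value}")

    @classmethod
    def default(cls) -> "ConductivityMap":
        return cls(**_load_data("conductivities.yaml"))

    def isotropic(self, tissue: Tissue) -> float:
        return {
            Tissue.MUSCLE: self.muscle,
            Tissue.BONE: self.vertebral_bone,
            Tissue.DISC: self.intervertebral_disc,
            Tissue.EXTRADURAL: self.extradural_space,
            Tissue.DURA: self.dura,
            Tissue.CSF: self.csf,
            Tissue.GREY: self.grey_matter,
            Tissue.WHITE: self.white_matter_transverse,  # transverse plane
        }[tissue]

    def tensor(self, tissue: Tissue) -> tuple[float, float, float]:
        """Diagonal (sigma_x, sigma_y, sigma_z) for a tissue."""
        if tissue == Tissue.WHITE:
            t, l = self.white_matter_transverse, self.white_matter_longitudinal
            return (t, t, l)
        s = self.isotropic(tissue)
        return (s, s, s)


# --------------------------------------------------------------------------
# patient geometry
# --------------------------------------------------------------------------

class CordPlacement(str, enum.Enum):
    CENTER = "center"
    VENTRAL = "ventral"


@dataclass(frozen=True)
class PatientGeometry:
    """Transverse cord/CSF-space dimensions (full widths, mm).

    ``ventral`` placement means the cord centre is twice as far from the
    dorsal interior dura surface as from the ventral interior surface.
    """

    cord_ml: float
    cord_vd: float
    csf_ml: float
    csf_vd: float
    cord_placement: CordPlacement = CordPlacement.CENTER

    def __post_init__(self):
        object.__setattr__(self, "cord_placement", CordPlacement(self.cord_placement))
        for name in ("cord_ml", "cord_vd", "csf_ml", "csf_vd"):
            if not getattr(self, name) > 0:
                raise GeometryError(f"{name} must be > 0")
        if not (self.cord_ml < self.csf_ml and self.cord_vd < self.csf_vd):
            raise GeometryError("cord must fit inside the dural sac")

    @property
    def cord_center_y(self) -> float:
        """y of the cord centre relative to the sac centre.

        For ventral placement, solving (b - y) = 2 (y + b) for the centre
        offset gives y = -b/3, with b the ventrodorsal inner dura semi-axis.
        """
        if self.cord_placement is CordPlacement.VENTRAL:
            return -self.csf_vd / 6.0
        return 0.0


def load_patient(patient: str | int) -> PatientGeometry:
    """Load one of the five shipped patient measurement sets."""
    key = patient if isinstance(patient, str) else f"patient_{patient}"
    table = _load_data("patients.yaml")
    if key not in table:
        raise KeyError(f"unknown patient {patient!r}; have {sorted(table)}")
    return PatientGeometry(**table[key])


def load_all_patients() -> dict[str, PatientGeometry]:
    return {k: PatientGeometry(**v) for k, v in _load_data("patients.yaml").items()}


# --------------------------------------------------------------------------
# electrode designs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeDesign:
    """Geometry of an electrode array on its carrier (lengths mm)."""

    design_id: str
    kind: str  # cylindrical | paddle | azimuthal
    n_contacts: int = 3
    # cylindrical / azimuthal
    shaft_diameter: float = 0.0
    shaft_length: float = 0.0
    contact_length: float = 0.0
    ies: float = 0.0
    # paddle
    paddle_width: float = 0.0
    paddle_length: float = 0.0
    paddle_thickness: float = 0.0
    contact_width: float = 0.0
    # azimuthal
    contact_arc_deg: float = 0.0
    contact_azimuths_deg: tuple[float, ...] = ()

    def __post_init__(self):
        if self.kind not in ("cylindrical", "paddle", "azimuthal"):
            raise GeometryError(f"unknown carrier kind {self.kind!r}")
        if self.kind == "azimuthal":
            az = np.sort(np.mod(self.contact_azimuths_deg, 360.0))
            gaps = np.diff(np.concatenate([az, [az[0] + 360.0]]))
            if np.any(gaps < self.contact_arc_deg - 1e-9):
                raise GeometryError("azimuthal contacts overlap")

    @property
    def contact_pitch(self) -> float:
        """Centre-to-centre spacing of adjacent contacts."""
        if self.kind == "paddle":
            return self.contact_width + self.ies
        if self.kind == "cylindrical":
            return self.contact_length + self.ies
        return 0.0


def catalog_design(design_id: str, **overrides) -> ElectrodeDesign:
    """Return a catalogued electrode design, optionally overriding dimensions."""
    catalog = _load_data("electrodes.yaml")
    if design_id not in catalog:
        raise KeyError(f"unknown electrode design {design_id!r}; have {sorted(catalog)}")
    params = dict(catalog[design_id])
    params.update(overrides)
    if "contact_azimuths_deg" in params:
        params["contact_azimuths_deg"] = tuple(params["contact_azimuths_deg"])
    return ElectrodeDesign(design_id=design_id, **params)


ALL_DESIGNS = ("ADTECH", "LT15", "LT6", "TT1", "TT3", "AT")


# --------------------------------------------------------------------------
# electrode configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ElectrodeConfiguration:
    """Per-contact applied potentials (V) for the unit-amplitude solve.

    ``potentials`` maps contact index -> applied potential; contacts not
    listed are electrically inactive (insulating, like the carrier).
    Monopolar runs ground the outer boundary of the tissue prism; bipolar
    and tripolar runs treat the outer boundary as insulating and use the
    cathode as the return.
    """

    mode: str  # monopolar | bipolar | tripolar
    potentials: dict[int, float]

    def __post_init__(self):
        if self.mode not in ("monopolar", "bipolar", "tripolar"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if not self.potentials:
            raise ConfigurationError("no active contacts")
        vals = list(self.potentials.values())
        if self.mode == "monopolar":
            if len(vals) != 1:
                raise ConfigurationError("monopolar requires exactly one active contact")
        else:
            if not any(v > 0 for v in vals) or not any(v < 0 for v in vals):
                raise ConfigurationError(f"{self.mode} requires both an anode and a cathode")

    @property
    def grounded_boundary(self) -> bool:
        return self.mode == "monopolar"

    @property
    def anode_contacts(self) -> list[int]:
        return [k for k, v in self.potentials.items() if v > 0]

    @property
    def cathode_contacts(self) -> list[int]:
        return [k for k, v in self.potentials.items() if v < 0]

    # -- canonical configurations ------------------------------------------
    @classmethod
    def monopolar(cls, contact: int = 1) -> "ElectrodeConfiguration":
        return cls("monopolar", {contact: 1.0})

    @classmethod
    def bipolar(cls, cathode: int = 1, anode: int = 2) -> "ElectrodeConfiguration":
        """Bipole; default anode on the contact rostral to the cathode."""
        return cls("bipolar", {cathode: -1.0, anode: +1.0})

    @classmethod
    def tripolar(cls, cathode: int = 1) -> "ElectrodeConfiguration":
        """Guarded cathode (+ - +) across three consecutive contacts."""
        return cls("tripolar", {cathode - 1: +1.0, cathode: -1.0, cathode + 1: +1.0})

    @classmethod
    def azimuthal_tripolar(cls) -> "ElectrodeConfiguration":
        """Cord-facing cathode (contact 0) flanked by two azimuthal anodes."""
        return cls("tripolar", {0: -1.0, 1: +1.0, 2: +1.0})


# --------------------------------------------------------------------------
# placement
# --------------------------------------------------------------------------

class Depth(str, enum.Enum):
    EXTRADURAL = "extradural_above_dura"
    BELOW_DURA = "intradural_below_dura"
    ABOVE_CORD = "intradural_above_cord"


@dataclass(frozen=True)
class Placement:
    """Electrode placement: dorsoventral depth, clearance and lateral angle.

    ``lateral_angle_deg`` rotates the placement about the cord axis
    (negative = clockwise viewed from rostral); the canonical locations use
    0, -10 and -20 degrees at each of the three depths.
    ``axial_rotation_deg`` additionally spins the lead about its own axis
    (used for the azimuthal-array rotation-sensitivity sweep).
    """

    depth: Depth = Depth.EXTRADURAL
    clearance_mm: float = 1.0
    lateral_angle_deg: float = 0.0
    axial_rotation_deg: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "depth", Depth(self.depth))
        if self.clearance_mm <= 0:
            raise PlacementError("clearance must be > 0")


CANONICAL_PLACEMENTS = tuple(
    Placement(depth=d, lateral_angle_deg=a)
    for d in (Depth.EXTRADURAL, Depth.BELOW_DURA, Depth.ABOVE_CORD)
    for a in (0.0, -10.0, -20.0)
)


# --------------------------------------------------------------------------
# spine model
# --------------------------------------------------------------------------

def _inside_ellipse(x, y, a, b):
    return (x / a) ** 2 + (y / b) ** 2 <= 1.0


@dataclass(frozen=True)
class SpineModel:
    """Labelled volume-conductor geometry for one patient.

    The model answers point queries (`tissue_at`, `conductivity_at`) over
    the bounding prism.  The thin dura mater is represented as a thickened
    shell whose conductivity is scaled to preserve the radial (trans-dural)
    resistance, so that coarse grids resolve it.
    """

    patient: PatientGeometry
    conductivities: ConductivityMap = field(default_factory=ConductivityMap.default)
    prism_dims: tuple[float, float, float] = (100.0, 100.0, 300.0)
    dura_thickness: float = 0.3        # physical, mm
    dura_shell_thickness: float = 0.9  # as represented, mm
    extradural_gap: float = 4.0        # dura outer surface -> canal wall, mm
    bone_thickness: float = 14.0
    vertebra_height: float = 22.0
    disc_height: float = 6.0
    # dorsomedial white-matter band (scales of the cord ellipse)
    dc_band_inner_scale: float = 0.78
    dc_band_lateral_scale: float = 0.62

    def __post_init__(self):
        a_csf, b_csf = self.csf_semi_axes
        a_c, b_c = self.cord_semi_axes
        yc = self.cord_center[1]
        if a_c >= a_csf or (abs(yc) + b_c) >= b_csf:
            raise GeometryError("cord does not fit inside the dural sac")

    # -- derived cross-section geometry ------------------------------------
    @property
    def cord_semi_axes(self) -> tuple[float, float]:
        return (self.patient.cord_ml / 2.0, self.patient.cord_vd / 2.0)

    @property
    def csf_semi_axes(self) -> tuple[float, float]:
        """Interior (CSF-facing) dura ellipse semi-axes."""
        return (self.patient.csf_ml / 2.0, self.patient.csf_vd / 2.0)

    @property
    def dura_outer_semi_axes(self) -> tuple[float, float]:
        a, b = self.csf_semi_axes
        t = self.dura_shell_thickness
        return (a + t, b + t)

    @property
    def canal_semi_axes(self) -> tuple[float, float]:
        a, b = self.dura_outer_semi_axes
        return (a + self.extradural_gap, b + self.extradural_gap)

    @property
    def bone_outer_semi_axes(self) -> tuple[float, float]:
        a, b = self.canal_semi_axes
        return (a + self.bone_thickness, b + self.bone_thickness)

    @property
    def cord_center(self) -> tuple[float, float]:
        return (0.0, self.patient.cord_center_y)

    @property
    def dura_sigma_effective(self) -> float:
        """Dura conductivity of the thickened shell.

        Scaled by shell/physical thickness so the radial resistance
        t/sigma of the real 0.3 mm membrane is preserved.
        """
        return self.conductivities.dura * self.dura_shell_thickness / self.dura_thickness

    @property
    def z_extent(self) -> tuple[float, float]:
        return (-self.prism_dims[2] / 2.0, self.prism_dims[2] / 2.0)

    # -- grey-matter butterfly ---------------------------------------------
    def _grey_mask(self, u, v):
        """Butterfly in cord-normalised coords u = x/a, v = (y-yc)/b."""
        m = (u / 0.55) ** 2 + (v / 0.18) ** 2 <= 1.0  # central bridge
        for sx in (-1.0, 1.0):
            # dorsal horns, tilted toward the midline
            ang = math.radians(25.0) * sx
            du, dv = u - sx * 0.32, v - 0.35
            ru = du * math.cos(ang) + dv * math.sin(ang)
            rv = -du * math.sin(ang) + dv * math.cos(ang)
            m |= (ru / 0.16) ** 2 + (rv / 0.32) ** 2 <= 1.0
            # ventral horns
            du, dv = u - sx * 0.30, v + 0.35
            m |= (du / 0.26) ** 2 + (dv / 0.34) ** 2 <= 1.0
        return m

    # -- labelling ----------------------------------------------------------
    def tissue_at(self, points: np.ndarray) -> np.ndarray:
        """Tissue label for each query point (N, 3) -> (N,) of Tissue codes."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        labels = np.full(x.shape, int(Tissue.MUSCLE), dtype=np.int8)

        a, b = self.bone_outer_semi_axes
        in_bone_outer = _inside_ellipse(x, y, a, b)
        a, b = self.canal_semi_axes
        in_canal = _inside_ellipse(x, y, a, b)
        # vertebra/disc alternation along z, phased so z=0 is mid-vertebra
        period = self.vertebra_height + self.disc_height
        phase = np.mod(z + self.vertebra_height / 2.0, period)
        in_vertebra = phase < self.vertebra_height
        ring = in_bone_outer & ~in_canal
        labels[ring & in_vertebra] = int(Tissue.BONE)
        labels[ring & ~in_vertebra] = int(Tissue.DISC)

        labels[in_canal] = int(Tissue.EXTRADURAL)
        a, b = self.dura_outer_semi_axes
        in_dura_outer = _inside_ellipse(x, y, a, b)
        labels[in_dura_outer] = int(Tissue.DURA)
        a, b = self.csf_semi_axes
        in_csf = _inside_ellipse(x, y, a, b)
        labels[in_csf] = int(Tissue.CSF)

        a, b = self.cord_semi_axes
        xc, yc = self.cord_center
        in_cord = _inside_ellipse(x - xc, y - yc, a, b)
        labels[in_cord] = int(Tissue.WHITE)
        u, v = (x - xc) / a, (y - yc) / b
        labels[in_cord & self._grey_mask(u, v)] = int(Tissue.GREY)
        return labels

    def conductivity_at(self, points: np.ndarray) -> np.ndarray:
        """Diagonal conductivity tensor (N, 3) at each query point."""
        labels = self.tissue_at(points)
        return self.conductivity_for_labels(labels)

    def conductivity_for_labels(self, labels: np.ndarray) -> np.ndarray:
        out = np.empty(labels.shape + (3,), dtype=float)
        for t in Tissue:
            mask = labels == int(t)
            if not mask.any():
                continue
            if t == Tissue.DURA:
                s = self.dura_sigma_effective
                out[mask] = (s, s, s)
            else:
                out[mask] = self.conductivities.tensor(t)
        return out

    # -- surfaces used for placement ---------------------------------------
    def cord_surface_point(self, direction_xy: np.ndarray) -> np.ndarray:
        a, b = self.cord_semi_axes
        xc, yc = self.cord_center
        d = direction_xy / np.hypot(*direction_xy)
        r = 1.0 / math.sqrt((d[0] / a) ** 2 + (d[1] / b) ** 2)
        return np.array([xc + r * d[0], yc + r * d[1]])

    def with_electrode(
        self,
        design: ElectrodeDesign,
        placement: Placement,
        check_collision: bool = True,
    ) -> "SpineModelWithElectrode":
        return place_electrode(self, design, placement, check_collision=check_collision)


def build_spine_model(
    patient: PatientGeometry,
    conductivities: ConductivityMap | None = None,
    prism_dims: tuple[float, float, float] = (100.0, 100.0, 300.0),
    **kwargs,
) -> SpineModel:
    """Build the labelled spine model for one patient."""
    return SpineModel(
        patient=patient,
        conductivities=conductivities or ConductivityMap.default(),
        prism_dims=tuple(prism_dims),
        **kwargs,
    )


# --------------------------------------------------------------------------
# electrode placement
# --------------------------------------------------------------------------

# electrode_region codes
REGION_NONE = 0
REGION_CARRIER = 1
REGION_CONTACT0 = 2  # contact k -> code REGION_CONTACT0 + k


@dataclass(frozen=True)
class ElectrodePose:
    """Resolved pose: carrier centre in the transverse plane, outward
    normal (pointing away from the cord) and cathode z position."""

    center_xy: tuple[float, float]
    outward_xy: tuple[float, float]
    z_center: float = 0.0


class SpineModelWithElectrode:
    """A spine model with an electrode carved into it.

    Point queries return the anatomy's label outside the carrier; the
    carrier is insulating and contact surfaces carry Dirichlet potentials.
    """

    def __init__(self, model: SpineModel, design: ElectrodeDesign,
                 placement: Placement, pose: ElectrodePose):
        self.model = model
        self.design = design
        self.placement = placement
        self.pose = pose

    # -- geometry helpers ---------------------------------------------------
    def _local_frame(self):
        """(t_hat, n_hat): tangential and outward-normal unit vectors."""
        nx, ny = self.pose.outward_xy
        return np.array([ny, -nx]), np.array([nx, ny])

    def contact_z_centers(self) -> np.ndarray:
        d = self.design
        if d.kind in ("cylindrical",):
            pitch = d.contact_pitch
            return self.pose.z_center + pitch * (np.arange(d.n_contacts) - 1.0)
        # paddle and azimuthal contacts are abreast at one z
        return np.full(d.n_contacts, self.pose.z_center)

    def electrode_region(self, points: np.ndarray) -> np.ndarray:
        """0 = tissue, 1 = insulating carrier, 2+k = contact k."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
        d = self.design
        cx, cy = self.pose.center_xy
        region = np.zeros(x.shape, dtype=np.int8)
        zc = self.pose.z_center

        if d.kind in ("cylindrical", "azimuthal"):
            r2 = (x - cx) ** 2 + (y - cy) ** 2
            in_shaft = (r2 <= (d.shaft_diameter / 2.0) ** 2) & \
                       (np.abs(z - zc) <= d.shaft_length / 2.0)
            region[in_shaft] = REGION_CARRIER
            if d.kind == "cylindrical":
                for k, zk in enumerate(self.contact_z_centers()):
                    band = in_shaft & (np.abs(z - zk) <= d.contact_length / 2.0)
                    region[band] = REGION_CONTACT0 + k
            else:
                # azimuth measured from the cord-facing direction (-outward)
                nx, ny = self.pose.outward_xy
                az0 = math.atan2(-ny, -nx)
                az = np.degrees(np.arctan2(y - cy, x - cx) - az0)
                az -= self.placement.axial_rotation_deg
                az = np.mod(az + 180.0, 360.0) - 180.0
                # contacts are arc shells on the shaft surface; the core
                # stays insulating so distinct contacts never touch
                shell = r2 >= (0.5 * d.shaft_diameter / 2.0) ** 2
                in_band = in_shaft & shell & \
                    (np.abs(z - zc) <= d.contact_length / 2.0)
                for k, azk in enumerate(d.contact_azimuths_deg):
                    dk = np.mod(az - azk + 180.0, 360.0) - 180.0
                    region[in_band & (np.abs(dk) <= d.contact_arc_deg / 2.0)] = \
                        REGION_CONTACT0 + k
        else:  # paddle
            t_hat, n_hat = self._local_frame()
            tt = (x - cx) * t_hat[0] + (y - cy) * t_hat[1]
            nn = (x - cx) * n_hat[0] + (y - cy) * n_hat[1]
            in_box = (np.abs(tt) <= d.paddle_width / 2.0) & \
                     (nn >= 0.0) & (nn <= d.paddle_thickness) & \
                     (np.abs(z - zc) <= d.paddle_length / 2.0)
            region[in_box] = REGION_CARRIER
            pitch = d.contact_pitch
            contact_depth = min(0.4, d.paddle_thickness / 2.0)
            for k in range(d.n_contacts):
                tk = pitch * (k - (d.n_contacts - 1) / 2.0)
                sel = in_box & (nn <= contact_depth) & \
                      (np.abs(tt - tk) <= d.contact_width / 2.0) & \
                      (np.abs(z - zc) <= d.contact_length / 2.0)
                region[sel] = REGION_CONTACT0 + k
        return region

    def tissue_at(self, points: np.ndarray) -> np.ndarray:
        return self.model.tissue_at(points)

    def bounding_box(self) -> tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounds of the carrier (for mesh grading)."""
        d = self.design
        cx, cy = self.pose.center_xy
        zc = self.pose.z_center
        if d.kind in ("cylindrical", "azimuthal"):
            r = d.shaft_diameter / 2.0
            lo = np.array([cx - r, cy - r, zc - d.shaft_length / 2.0])
            hi = np.array([cx + r, cy + r, zc + d.shaft_length / 2.0])
        else:
            r = math.hypot(d.paddle_width / 2.0, d.paddle_thickness)
            lo = np.array([cx - r, cy - r, zc - d.paddle_length / 2.0])
            hi = np.array([cx + r, cy + r, zc + d.paddle_length / 2.0])
        return lo, hi


def _placement_pose(model: SpineModel, design: ElectrodeDesign,
                    placement: Placement) -> ElectrodePose:
    ang = math.radians(placement.lateral_angle_deg)
    # rotate the dorsal direction (0, 1) by the (signed) lateral angle
    d = np.array([-math.sin(ang), math.cos(ang)])
    offset = placement.clearance_mm
    if design.kind in ("cylindrical", "azimuthal"):
        offset += design.shaft_diameter / 2.0
    elif placement.depth is Depth.BELOW_DURA:
        # the paddle body extends outward from its cord-facing face, so
        # drop it by its thickness to keep the clearance to the dura
        offset += design.paddle_thickness

    if placement.depth is Depth.ABOVE_CORD:
        p = model.cord_surface_point(d)
        a, b = model.cord_semi_axes
        xc, yc = model.cord_center
        n = np.array([(p[0] - xc) / a ** 2, (p[1] - yc) / b ** 2])
        n /= np.hypot(*n)
        center = p + offset * n
    elif placement.depth is Depth.BELOW_DURA:
        a, b = model.csf_semi_axes
        r = 1.0 / math.sqrt((d[0] / a) ** 2 + (d[1] / b) ** 2)
        p = r * d
        n = np.array([p[0] / a ** 2, p[1] / b ** 2])
        n /= np.hypot(*n)
        center = p - offset * n  # inward, into the CSF
    else:  # extradural
        a, b = model.dura_outer_semi_axes
        r = 1.0 / math.sqrt((d[0] / a) ** 2 + (d[1] / b) ** 2)
        p = r * d
        n = np.array([p[0] / a ** 2, p[1] / b ** 2])
        n /= np.hypot(*n)
        center = p + offset * n
    return ElectrodePose(center_xy=(center[0], center[1]),
                         outward_xy=(n[0], n[1]), z_center=0.0)


_FORBIDDEN = {
    Depth.EXTRADURAL: (Tissue.WHITE, Tissue.GREY, Tissue.BONE, Tissue.DISC,
                       Tissue.DURA, Tissue.CSF),
    Depth.BELOW_DURA: (Tissue.WHITE, Tissue.GREY, Tissue.BONE, Tissue.DISC,
                       Tissue.DURA),
    Depth.ABOVE_CORD: (Tissue.WHITE, Tissue.GREY, Tissue.BONE, Tissue.DISC,
                       Tissue.DURA),
}


def place_electrode(
    model: SpineModel,
    design: ElectrodeDesign,
    placement: Placement,
    check_collision: bool = True,
) -> SpineModelWithElectrode:
    """Position an electrode at a canonical placement.

    Raises :class:`PlacementError` naming the colliding tissue if the
    carrier intersects cord, dura or bone.
    """
    pose = _placement_pose(model, design, placement)
    placed = SpineModelWithElectrode(model, design, placement, pose)
    if check_collision:
        lo, hi = placed.bounding_box()
        # probe the carrier volume on a coarse lattice
        grid = np.stack(np.meshgrid(
            np.linspace(lo[0], hi[0], 9),
            np.linspace(lo[1], hi[1], 9),
            np.linspace(lo[2], hi[2], 15),
            indexing="ij"), axis=-1).reshape(-1, 3)
        inside = placed.electrode_region(grid) > 0
        labels = model.tissue_at(grid[inside])
        for t in _FORBIDDEN[placement.depth]:
            if np.any(labels == int(t)):
                raise PlacementError(
                    f"{design.design_id} at {placement.depth.value} "
                    f"(angle {placement.lateral_angle_deg}) collides with {t.name}")
    return placed
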