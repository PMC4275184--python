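"""Nonlinear cable models of myelinated axons under extracellular drive.

Two classic fiber models are implemented:

* **SW** -- a mammalian node-of-Ranvier membrane (CRRSS/Sweeney kinetics:
  fast sodium + leak at 37 C) with perfectly insulating myelin, so only
  the nodes and the internodal axoplasmic resistance are represented.
* **MRG** -- the double-cable mammalian fiber: nodes carry fast and
  persistent sodium, slow potassium and leak; paranodal (MYSA, FLUT) and
  internodal (STIN) sections have a passive axolemma beneath a
  finite-impedance myelin sheath, with a periaxonal conduction pathway.

Extracellular potentials sampled from a field solution drive each
compartment; integration is theta-weighted Crank-Nicolson on the
(banded) cable system with Rush-Larsen gate updates, batched over whole
fiber populations.  Activation is detected as an action potential that
propagates to recording nodes near both fiber ends.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml
from scipy.linalg import solve_banded


class TrajectoryError(ValueError):
    """Trajectory too short (or otherwise unusable) for the fiber model."""


class IntegrationError(RuntimeError):
    """Numerical failure (NaN/overflow) during cable integration."""


def _load_params(name):
    with resources.files("cordstim.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


_SW = _load_params("sw_params.yaml")
_MRG = _load_params("mrg_params.yaml")

DIAMETERS_UM = (3.0, 6.0, 9.0, 12.0, 15.0)


# --------------------------------------------------------------------------
# specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PulseSpec:
    """Monophasic rectangular stimulus pulse.

    ``amplitude`` values elsewhere are scalars applied to the
    unit-amplitude base field solution; the pulse is cathodic-leading at
    the stimulating contact by construction of the base solve.
    """

    pw_us: float = 300.0
    shape: str = "monophasic_rectangular"
    post_window_ms: float = 2.0

    def __post_init__(self):
        if self.pw_us <= 0:
            raise ValueError("pulse width must be > 0")
        if self.shape != "monophasic_rectangular":
            raise ValueError(f"unsupported pulse shape {self.shape!r}")


@dataclass(frozen=True)
class AxonModelSpec:
    """Which membrane model and fiber diameter to use.

    ``dt_us`` is the integrator step; the default is chosen so that
    halving it changes bisection thresholds by <1 %.
    """

    model: str = "MRG"
    diameter_um: float = 9.0
    dt_us: float = 5.0

    def __post_init__(self):
        if self.model not in ("SW", "MRG"):
            raise ValueError(f"unknown axon model {self.model!r}")
        if self.diameter_um <= 0:
            raise ValueError("diameter must be > 0")

    @property
    def internode_length_um(self) -> float:
        if self.model == "SW":
            return _SW["internode_length_ratio"] * self.diameter_um
        return float(_mrg_geometry(self.diameter_um)["internode_len"])

    @property
    def v_rest(self) -> float:
        return (_SW if self.model == "SW" else _MRG)["v_rest_mv"]


def _mrg_geometry(diameter_um: float) -> dict:
    """Interpolate the MRG geometry table in fiber diameter.

    The published table covers 5.7--16 um; smaller diameters (the 3 um
    population) are linear extrapolations, floored to stay physical.
    """
    tab = _MRG["geometry_table"]
    cols = tab["columns"]
    rows = np.asarray(tab["rows"], dtype=float)
    d = rows[:, 0]
    out = {}
    for j, c in enumerate(cols[1:], start=1):
        if d[0] <= diameter_um <= d[-1]:
            out[c] = float(np.interp(diameter_um, d, rows[:, j]))
        else:
            # linear extrapolation on the nearest two rows
            i0, i1 = (0, 1) if diameter_um < d[0] else (-2, -1)
            slope = (rows[i1, j] - rows[i0, j]) / (d[i1] - d[i0])
            out[c] = float(rows[i0, j] + slope * (diameter_um - d[i0]))
    out["n_lamellae"] = max(out["n_lamellae"], 10.0)
    for k in ("axon_d", "node_d", "mysa_d", "flut_d"):
        out[k] = max(out[k], 0.3 * diameter_um * 0.5)
    out["internode_len"] = max(out["internode_len"], 20.0 * diameter_um)
    return out


# --------------------------------------------------------------------------
# membrane kinetics
# --------------------------------------------------------------------------

def _vtrap(x, y):
    """x/(1-exp(-x/y)) with the removable singularity handled."""
    x = np.asarray(x, float)
    out = np.where(np.abs(x / y) < 1e-6, y * (1.0 + x / (2.0 * y)), x)
    den = np.where(np.abs(x / y) < 1e-6, 1.0, 1.0 - np.exp(-x / y))
    return np.where(np.abs(x / y) < 1e-6, out, x / den)


def mrg_gate_rates(v):
    """MRG nodal gate rates (1/ms) at 36 C; v is absolute Vm (mV)."""
    q10_12 = 2.2 ** ((_MRG["temperature_c"] - 20.0) / 10.0)
    q10_3 = 3.0 ** ((_MRG["temperature_c"] - 36.0) / 10.0)
    a_m = q10_12 * 6.57 * _vtrap(v + 20.4, 10.3)
    b_m = q10_12 * 0.304 * _vtrap(-(v + 25.7), 9.16)
    a_h = q10_12 * 0.34 * _vtrap(-(v + 114.0), 11.0)
    b_h = q10_12 * 12.6 / (1.0 + np.exp(-(v + 31.8) / 13.4))
    a_p = q10_12 * 0.0353 * _vtrap(v + 27.0, 10.2)
    b_p = q10_12 * 0.000883 * _vtrap(-(v + 34.0), 10.0)
    a_s = q10_3 * 0.3 / (1.0 + np.exp(-(v + 53.0) / 5.0))
    b_s = q10_3 * 0.03 / (1.0 + np.exp(-(v + 90.0) / 1.0))
    return (a_m, b_m, a_h, b_h, a_p, b_p, a_s, b_s)


def sw_gate_rates(v_abs):
    """CRRSS gate rates (1/ms) at 37 C; membrane voltage is handled
    relative to rest internally."""
    v = v_abs - _SW["v_rest_mv"]  # displacement from rest
    a_m = (97.0 + 0.363 * v) / (1.0 + np.exp((31.8 - v) / 5.43))
    b_m = a_m / np.exp((v - 23.8) / 4.17)
    b_h = 15.6 / (1.0 + np.exp((24.0 - v) / 10.0))
    a_h = b_h / np.exp((v - 5.5) / 5.0)
    return (a_m, b_m, a_h, b_h)


# --------------------------------------------------------------------------
# cable construction
# --------------------------------------------------------------------------

# compartment kinds
_NODE, _MYSA, _FLUT, _STIN = 0, 1, 2, 3


@dataclass
class Cable:
    """A compartmental cable laid out along a 3-D trajectory.

    All electrical quantities use mV / ms / mS / uF units; geometry in cm
    internally.  ``positions`` are the 3-D compartment centres (mm) used
    to sample extracellular potentials.
    """

    spec: AxonModelSpec
    positions: np.ndarray      # (n_comp, 3) mm
    kind: np.ndarray           # (n_comp,) compartment kinds
    c_m: np.ndarray            # (n_comp,) uF, axolemma
    g_pas: np.ndarray          # (n_comp,) mS, passive axolemma (0 at nodes)
    g_axial: np.ndarray        # (n_comp-1,) mS, intracellular
    g_peri: np.ndarray         # (n_comp-1,) mS, periaxonal (MRG; zeros for SW)
    c_my: np.ndarray           # (n_comp,) uF, myelin (0 at nodes)
    g_my: np.ndarray           # (n_comp,) mS, myelin
    arc_length_mm: float = 0.0

    @property
    def n_comp(self) -> int:
        return len(self.kind)

    @property
    def node_index(self) -> np.ndarray:
        return np.flatnonzero(self.kind == _NODE)

    @property
    def n_nodes(self) -> int:
        return int((self.kind == _NODE).sum())


def _resample_polyline(points: np.ndarray, s_query: np.ndarray) -> np.ndarray:
    """Positions at arc-length stations along a polyline (mm)."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return np.column_stack([np.interp(s_query, s, points[:, k]) for k in range(3)])


def _trajectory_points(trajectory) -> np.ndarray:
    pts = getattr(trajectory, "points", trajectory)
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise TrajectoryError("trajectory must be an (N, 3) polyline")
    return pts


def build_axon(spec: AxonModelSpec, trajectory, align_mm: float | None = None,
               min_nodes: int = 21) -> Cable:
    """Place model compartments along a trajectory.

    ``align_mm``: arc-length station (mm from the trajectory start) that
    should coincide with a node of Ranvier; by convention this is the
    trajectory point closest to the cathode, which is the conservative
    (lowest-threshold) grid alignment.  Defaults to mid-length.
    """
    pts = _trajectory_points(trajectory)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    total_mm = float(seg.sum())
    delta_mm = spec.internode_length_um * 1e-3
    n_nodes = int(np.floor(total_mm / delta_mm)) + 1
    if n_nodes < min_nodes:
        raise TrajectoryError(
            f"trajectory of {total_mm:.1f} mm supports only {n_nodes} nodes "
            f"of Ranvier (need >= {min_nodes}) at diameter "
            f"{spec.diameter_um} um")
    if align_mm is None:
        align_mm = total_mm / 2.0
    # shift the node grid so one node lands on the alignment station
    offset = align_mm - delta_mm * np.floor(align_mm / delta_mm)
    n_nodes = int(np.floor((total_mm - offset) / delta_mm)) + 1
    node_s = offset + delta_mm * np.arange(n_nodes)

    if spec.model == "SW":
        return _build_sw(spec, pts, node_s, total_mm)
    return _build_mrg(spec, pts, node_s, total_mm)


def _build_sw(spec, pts, node_s, total_mm) -> Cable:
    p = _SW
    n = len(node_s)
    d_cm = p["axon_diameter_ratio"] * spec.diameter_um * 1e-4
    len_cm = p["node_length_um"] * 1e-4
    area = np.pi * d_cm * len_cm
    c_m = np.full(n, p["c_m_uF_per_cm2"] * area)
    # internodal axoplasmic resistance over one internode
    inter_cm = spec.internode_length_um * 1e-4
    r_ax = p["rho_axial_ohm_cm"] * inter_cm / (np.pi * d_cm ** 2 / 4.0)
    g_axial = np.full(n - 1, 1e3 / r_ax)
    zeros = np.zeros(n)
    return Cable(spec=spec, positions=_resample_polyline(pts, node_s),
                 kind=np.full(n, _NODE, dtype=np.int8), c_m=c_m,
                 g_pas=zeros.copy(), g_axial=g_axial,
                 g_peri=np.zeros(n - 1), c_my=zeros.copy(), g_my=zeros.copy(),
                 arc_length_mm=total_mm)


def _build_mrg(spec, pts, node_s, total_mm) -> Cable:
    p = _MRG
    g = _mrg_geometry(spec.diameter_um)
    fiber_cm = spec.diameter_um * 1e-4
    node_len = p["node_length_um"] * 1e-4
    mysa_len = p["mysa_length_um"] * 1e-4
    flut_len = g["flut_len"] * 1e-4
    inter_cm = g["internode_len"] * 1e-4
    stin_len = (inter_cm - node_len - 2 * mysa_len - 2 * flut_len) / p["n_stin"]
    if stin_len <= 0:
        raise TrajectoryError("internode too short for the MRG layout")

    # per-internode compartment pattern (after each node)
    pat_kind = [_MYSA, _FLUT] + [_STIN] * p["n_stin"] + [_FLUT, _MYSA]
    pat_len = [mysa_len, flut_len] + [stin_len] * p["n_stin"] + [flut_len, mysa_len]

    n_nodes = len(node_s)
    kind = [_NODE]
    length = [node_len]
    for _ in range(n_nodes - 1):
        kind += pat_kind + [_NODE]
        length += pat_len + [node_len]
    kind = np.asarray(kind, dtype=np.int8)
    length = np.asarray(length)

    # arc stations (mm): centres of consecutive compartments starting at
    # the first node's centre
    cum = np.concatenate([[0.0], np.cumsum(length)]) * 1e1  # cm -> mm
    centers_mm = node_s[0] + 0.5 * (cum[:-1] + cum[1:]) - length[0] * 1e1 / 2.0

    diam = np.choose(kind, [g["node_d"], g["mysa_d"], g["flut_d"], g["axon_d"]]) * 1e-4
    space = np.choose(kind, [p["space"]["node"], p["space"]["mysa"],
                             p["space"]["flut"], p["space"]["stin"]]) * 1e-4
    area = np.pi * diam * length
    area_my = np.pi * fiber_cm * length

    c_spec = np.choose(kind, [p["node"]["c_m_uF_per_cm2"],
                              p["mysa"]["c_m_uF_per_cm2"],
                              p["flut"]["c_m_uF_per_cm2"],
                              p["stin"]["c_m_uF_per_cm2"]])
    g_pas_spec = np.choose(kind, [0.0, p["mysa"]["g_pas_mS_per_cm2"],
                                  p["flut"]["g_pas_mS_per_cm2"],
                                  p["stin"]["g_pas_mS_per_cm2"]])
    c_m = c_spec * area
    g_pas = g_pas_spec * area

    nl2 = 2.0 * g["n_lamellae"]
    is_node = kind == _NODE
    c_my = np.where(is_node, 0.0, (p["myelin"]["c_m_uF_per_cm2"] / nl2) * area_my)
    g_my = np.where(is_node, 0.0, (p["myelin"]["g_m_mS_per_cm2"] / nl2) * area_my)

    # axial conductances between adjacent compartments (series half-resistances)
    rho = p["rho_axial_ohm_cm"]
    r_half = rho * (length / 2.0) / (np.pi * diam ** 2 / 4.0)
    g_axial = 1e3 / (r_half[:-1] + r_half[1:])
    rho_p = p["rho_periaxonal_ohm_cm"]
    a_peri = np.pi * ((diam + 2 * space) ** 2 - diam ** 2) / 4.0
    rp_half = rho_p * (length / 2.0) / a_peri
    g_peri = 1e3 / (rp_half[:-1] + rp_half[1:])

    return Cable(spec=spec, positions=_resample_polyline(pts, centers_mm),
                 kind=kind, c_m=c_m, g_pas=g_pas, g_axial=g_axial,
                 g_peri=g_peri, c_my=c_my, g_my=g_my, arc_length_mm=total_mm)


# --------------------------------------------------------------------------
# activating function
# --------------------------------------------------------------------------

def activating_profile(sampled_potentials: np.ndarray) -> np.ndarray:
    """Centred second spatial difference of extracellular potentials.

    ``Delta2Phi_i = Phi_{i-1} - 2 Phi_i + Phi_{i+1}`` at interior
    samples; proportional to the source driving membrane polarisation.
    """
    phi = np.asarray(sampled_potentials, dtype=float)
    if phi.ndim != 1 or len(phi) < 3:
        raise ValueError("need at least 3 sampled nodes")
    return phi[:-2] - 2.0 * phi[1:-1] + phi[2:]


# --------------------------------------------------------------------------
# batched integration
# --------------------------------------------------------------------------

# --------------------------------------------------------------------------
# batched integration
# --------------------------------------------------------------------------

class CableBatch:
    """Backward-Euler integrator for a batch of identical-layout cables.

    All cables must share the same :class:`AxonModelSpec` and compartment
    count (their trajectories, and hence extracellular potentials, may
    differ).  The linear cable system is banded (bandwidth 1 for SW, 3
    for the interleaved MRG double cable) and block-diagonal across
    fibers; only nodal ionic conductances change per time step.

    MRG unknown layout per fiber: ``[Vm_0, W_0, Vm_1, W_1, ...]`` where
    ``W`` is the periaxonal potential relative to the local extracellular
    potential; at nodes the periaxonal space is shorted to extracellular
    (``W = 0`` identity rows), matching the standard implementation.
    """

    def __init__(self, cables: list[Cable], pulse: PulseSpec,
                 dt_us: float | None = None, theta: float = 0.5):
        if not cables:
            raise ValueError("empty batch")
        if not 0.5 <= theta <= 1.0:
            raise ValueError("theta must be in [0.5, 1]")
        self.theta = theta
        spec = cables[0].spec
        n_comp = cables[0].n_comp
        for c in cables[1:]:
            if c.spec != spec or c.n_comp != n_comp:
                raise ValueError("batch requires identical cable layouts")
        self.cables = cables
        self.spec = spec
        self.pulse = pulse
        self.dt = (dt_us if dt_us is not None else spec.dt_us) * 1e-3  # ms
        self.n_f = len(cables)
        self.n_comp = n_comp
        self.mrg = spec.model == "MRG"
        self._build_template(cables[0])

    # -- constant banded template ------------------------------------------
    def _build_template(self, c: Cable):
        """Assemble the constant conduction operator A (banded) and the
        mass vector M, with the system  M dV/dt + A(t) V = s(t); the
        time-varying part of A is the nodal ionic conductance on the
        diagonal.  W rows at nodes are identity rows (W = 0)."""
        n = self.n_comp
        self.is_node = c.kind == _NODE
        self.node_pos = np.flatnonzero(self.is_node)
        self.c_m, self.g_pas = c.c_m, c.g_pas
        ga = c.g_axial
        ga_sum = np.zeros(n)
        ga_sum[:-1] += ga
        ga_sum[1:] += ga
        self.ga = ga

        if not self.mrg:
            self.n_per = n
            diag = ga_sum + c.g_pas
            lower = np.zeros(n)   # band[off=-1][j] = A[j-1, j]
            lower[1:] = -ga
            upper = np.zeros(n)   # band[off=+1][j] = A[j+1, j]
            upper[:-1] = -ga
            self._bands = {0: diag, -1: lower, 1: upper}
            self.mass = c.c_m.copy()
            self.identity_rows = np.zeros(n, dtype=bool)
            self.node_cols_per = self.node_pos
        else:
            self.n_per = 2 * n
            gp = c.g_peri
            self.gp = gp
            self.c_my, self.g_my = c.c_my, c.g_my
            gp_sum = np.zeros(n)
            gp_sum[:-1] += gp
            gp_sum[1:] += gp
            nd = self.is_node
            row_ok_lo = ~nd[:-1]   # W_k row, coupling to k+1 neighbours
            row_ok_hi = ~nd[1:]    # W_{k+1} row, coupling to k neighbours

            dvm = ga_sum + c.g_pas
            dw = np.where(nd, 0.0, c.g_my + gp_sum + ga_sum)
            bands = {off: np.zeros(self.n_per) for off in
                     (0, -1, 1, -2, 2, -3, 3)}
            bands[0][0::2] = dvm
            bands[0][1::2] = dw
            # off = i - j; band[off][j] = A[j+off, j]
            # A[vm(k), w(k)] = +ga_sum_k            (i=2k,   j=2k+1, off=-1)
            bands[-1][1::2] = ga_sum
            # A[w(k), vm(k+1)] = -ga_k              (i=2k+1, j=2k+2, off=-1)
            bands[-1][2::2] = np.where(row_ok_lo, -ga, 0.0)
            # A[w(k), vm(k)] = +ga_sum_k            (i=2k+1, j=2k,   off=+1)
            bands[1][0::2] = np.where(nd, 0.0, ga_sum)
            # A[vm(k+1), w(k)] = -ga_k              (i=2k+2, j=2k+1, off=+1)
            bands[1][1:-2:2] = -ga
            # A[vm(k), vm(k+1)] = -ga_k             (i=2k,   j=2k+2, off=-2)
            bands[-2][2::2] = -ga
            # A[w(k), w(k+1)] = -(ga_k + gp_k)      (i=2k+1, j=2k+3, off=-2)
            bands[-2][3::2] = np.where(row_ok_lo, -(ga + gp), 0.0)
            # A[vm(k+1), vm(k)] = -ga_k             (i=2k+2, j=2k,   off=+2)
            bands[2][0:-2:2] = -ga
            # A[w(k+1), w(k)] = -(ga_k + gp_k)      (i=2k+3, j=2k+1, off=+2)
            bands[2][1:-2:2] = np.where(row_ok_hi, -(ga + gp), 0.0)
            # A[vm(k), w(k+1)] = -ga_k              (i=2k,   j=2k+3, off=-3)
            bands[-3][3::2] = -ga
            # A[w(k+1), vm(k)] = -ga_k              (i=2k+3, j=2k,   off=+3)
            bands[3][0:-2:2] = np.where(row_ok_hi, -ga, 0.0)
            self._bands = bands
            mass = np.empty(self.n_per)
            mass[0::2] = c.c_m
            mass[1::2] = np.where(nd, 0.0, c.c_my)
            self.mass = mass
            ident = np.zeros(self.n_per, dtype=bool)
            ident[1::2] = nd
            self.identity_rows = ident
            self.node_cols_per = 2 * self.node_pos

    # -- extracellular drive ----------------------------------------------
    def _drive(self, ve_unit: np.ndarray) -> np.ndarray:
        """Axial drive terms (per unit amplitude) from sampled potentials
        (V); the second-difference of Ve weighted by axial conductances."""
        ve = np.asarray(ve_unit, float) * 1e3  # V -> mV
        ga = self.ga
        dve = np.diff(ve, axis=1)
        drive_vm = np.zeros_like(ve)
        drive_vm[:, :-1] += ga * dve
        drive_vm[:, 1:] -= ga * dve
        if not self.mrg:
            return drive_vm
        gap = ga + self.gp
        drive_w = np.zeros_like(ve)
        drive_w[:, :-1] += gap * dve
        drive_w[:, 1:] -= gap * dve
        drive_w[:, self.is_node] = 0.0  # identity rows stay homogeneous
        out = np.zeros((ve.shape[0], self.n_per))
        out[:, 0::2] = drive_vm
        out[:, 1::2] = drive_w
        return out

    # -- gating ------------------------------------------------------------
    def _resting_gates(self):
        v0 = np.array(self.spec.v_rest)
        nn = len(self.node_pos)
        if self.mrg:
            a_m, b_m, a_h, b_h, a_p, b_p, a_s, b_s = mrg_gate_rates(v0)
            g0 = [a_m / (a_m + b_m), a_h / (a_h + b_h),
                  a_p / (a_p + b_p), a_s / (a_s + b_s)]
        else:
            a_m, b_m, a_h, b_h = sw_gate_rates(v0)
            g0 = [a_m / (a_m + b_m), a_h / (a_h + b_h)]
        return np.stack([np.full((self.n_f, nn), float(g)) for g in g0])

    def _update_gates(self, gates, v_nodes):
        # rate laws are clamped to a physiological window: far outside it
        # the exponentials degenerate numerically while the gates are
        # pinned at their limiting values anyway
        v = np.clip(v_nodes, -200.0, 100.0)
        rates = (mrg_gate_rates if self.mrg else sw_gate_rates)(v)
        for i in range(gates.shape[0]):
            a, b = rates[2 * i], rates[2 * i + 1]
            tau = 1.0 / (a + b)
            inf = a * tau
            gates[i] = np.clip(inf + (gates[i] - inf) * np.exp(-self.dt / tau),
                               0.0, 1.0)
        return gates

    def _nodal_conductance(self, gates):
        """Total nodal ionic conductance and reversal-weighted drive (mS,
        mS*mV).  The leak reversal is calibrated once, from the resting
        gate state, so that the resting potential is an exact fixed
        point of the unstimulated dynamics."""
        area = self._node_area
        v0 = self.spec.v_rest
        if self.mrg:
            p = _MRG["node"]
            m, h, pp, s = gates
            gnaf = p["g_naf_mS_per_cm2"] * m ** 3 * h
            gnap = p["g_nap_mS_per_cm2"] * pp ** 3
            gks = p["g_ks_mS_per_cm2"] * s
            gl = p["g_l_mS_per_cm2"]
            if self._el is None:
                i0 = (gnaf.flat[0] + gnap.flat[0]) * (v0 - p["e_na_mv"]) + \
                    gks.flat[0] * (v0 - p["e_k_mv"])
                self._el = v0 + i0 / gl
            g_tot = (gnaf + gnap + gks + gl) * area
            g_e = ((gnaf + gnap) * p["e_na_mv"] + gks * p["e_k_mv"] +
                   gl * self._el) * area
        else:
            p = _SW
            m, h = gates
            gna = p["g_na_mS_per_cm2"] * m ** 2 * h
            gl = p["g_l_mS_per_cm2"]
            e_na = p["v_rest_mv"] + p["e_na_rel_mv"]
            if self._el is None:
                self._el = v0 + gna.flat[0] * (v0 - e_na) / gl
            g_tot = (gna + gl) * area
            g_e = (gna * e_na + gl * self._el) * area
        return g_tot, g_e

    # -- main loop ----------------------------------------------------------
    @property
    def rec_node_ids(self) -> np.ndarray:
        """Indices (into the node list) of the two recording nodes, one
        internode in from either fiber end."""
        nn = len(self.node_pos)
        return np.array([1, nn - 2])

    def run(self, ve_unit: np.ndarray, amplitudes: np.ndarray,
            record: bool = False):
        """Integrate one stimulus per fiber.

        ``ve_unit``: (n_f, n_comp) unit-amplitude extracellular
        potentials (V) at the compartment positions; ``amplitudes``:
        scalar per fiber.  Uses the theta-weighted (Crank-Nicolson for
        theta=0.5) step  (M/dt + theta A) u' = (M/dt - (1-theta) A) u + s.
        Returns a boolean activation array (True if an AP reached both
        recording nodes); with ``record``, also per-node 0 mV
        upward-crossing times (ms, sub-step interpolated; NaN if none).
        Also stores ``last_max_deviation`` (mV from rest, per fiber).
        """
        ve_unit = np.atleast_2d(np.asarray(ve_unit, float))
        amplitudes = np.atleast_1d(np.asarray(amplitudes, float))
        if ve_unit.shape != (self.n_f, self.n_comp):
            raise ValueError(
                f"potentials shape {ve_unit.shape} != {(self.n_f, self.n_comp)}")
        dt, theta = self.dt, self.theta
        pw_ms = self.pulse.pw_us * 1e-3
        n_steps = int(np.ceil((pw_ms + self.pulse.post_window_ms) / dt))
        n_pulse = max(1, int(np.round(pw_ms / dt)))

        n_f, n_per = self.n_f, self.n_per
        p_node = self.node_cols_per
        drive = self._drive(ve_unit)
        amp = amplitudes[:, None]
        self._el = None
        self._node_area = self.c_m[self.node_pos] / (
            _MRG["node"]["c_m_uF_per_cm2"] if self.mrg
            else _SW["c_m_uF_per_cm2"])

        u = np.zeros((n_f, n_per))
        if self.mrg:
            u[:, 0::2] = self.spec.v_rest
        else:
            u[:] = self.spec.v_rest
        gates = self._resting_gates()

        lu = max(abs(o) for o in self._bands)
        N = n_f * n_per
        bands_tiled = {off: np.tile(arr, n_f)
                       for off, arr in self._bands.items()}
        mass_dt = np.tile(self.mass, n_f) / dt
        ident = np.tile(self.identity_rows, n_f)
        ab_const = np.zeros((2 * lu + 1, N))
        for off, arr in bands_tiled.items():
            ab_const[lu + off, :] = theta * arr
        ab_const[lu, :] += mass_dt + ident
        node_cols = (np.arange(n_f)[:, None] * n_per + p_node).ravel()

        # constant source: passive reversal; ionic reversal added per step
        src_const = np.zeros((n_f, n_per))
        if self.mrg:
            src_const[:, 0::2] = self.g_pas * self.spec.v_rest
        else:
            src_const[:] = self.g_pas * self.spec.v_rest

        nn = len(self.node_pos)
        crossed = np.zeros((n_f, nn), dtype=bool)
        t_cross = np.full((n_f, nn), np.nan)
        v_prev = np.full((n_f, nn), self.spec.v_rest)
        rec = self.rec_node_ids
        max_dev = np.zeros(n_f)

        for step in range(n_steps):
            v_nodes = u[:, p_node]
            gates = self._update_gates(gates, v_nodes)
            g_tot, g_e = self._nodal_conductance(gates)
            gt_flat = g_tot.ravel()

            ab = ab_const.copy()
            np.add.at(ab[lu], node_cols, theta * gt_flat)

            u_flat = u.ravel()
            au = np.zeros(N)
            for off, b in bands_tiled.items():
                contrib = b * u_flat
                if off == 0:
                    au += contrib
                elif off > 0:
                    au[off:] += contrib[:-off]
                else:
                    au[:off] += contrib[-off:]
            au[node_cols] += gt_flat * u_flat[node_cols]

            rhs = mass_dt * u_flat - (1.0 - theta) * au + src_const.ravel()
            rhs = rhs.reshape(n_f, n_per)
            rhs[:, p_node] += g_e
            if step < n_pulse:
                rhs += amp * drive

            u_flat = solve_banded((lu, lu), ab, rhs.ravel(),
                                  overwrite_ab=True, check_finite=False)
            if not np.all(np.isfinite(u_flat)):
                raise IntegrationError(
                    f"non-finite membrane state at t={(step + 1) * dt:.3f} ms; "
                    "reduce the time step")
            u = u_flat.reshape(n_f, n_per)

            v_new = u[:, p_node]
            vm = u[:, 0::2] if self.mrg else u
            max_dev = np.maximum(max_dev,
                                 np.max(np.abs(vm - self.spec.v_rest), axis=1))
            new = (v_new > 0.0) & (v_prev <= 0.0) & ~crossed
            if new.any():
                # sub-step linear interpolation of the 0 mV crossing
                frac = -v_prev[new] / (v_new[new] - v_prev[new])
                t_cross[new] = (step + frac) * dt
                crossed |= new
            v_prev = v_new
            if bool(crossed[:, rec].all()):
                break

        self.last_max_deviation = max_dev
        activated = crossed[:, rec].all(axis=1)
        if record:
            return activated, t_cross
        return activated


def simulate_response(cable: Cable, sampled_potentials: np.ndarray,
                      pulse: PulseSpec, amplitude: float,
                      dt_us: float | None = None) -> bool:
    """True if a propagating action potential reaches the recording
    nodes near both fiber ends for this stimulus."""
    batch = CableBatch([cable], pulse, dt_us=dt_us)
    return bool(batch.run(np.asarray(sampled_potentials)[None, :],
                          np.array([amplitude]))[0])


def conduction_velocity(cable: Cable, sampled_potentials: np.ndarray,
                        pulse: PulseSpec, amplitude: float,
                        dt_us: float | None = None) -> float:
    """Conduction velocity (m/s) between the two recording nodes for a
    suprathreshold stimulus; NaN if no propagating AP."""
    batch = CableBatch([cable], pulse, dt_us=dt_us)
    act, t_cross = batch.run(np.asarray(sampled_potentials)[None, :],
                             np.array([amplitude]), record=True)
    if not act[0]:
        return float("nan")
    # measure on one side of the initiation site to avoid the symmetric
    # two-way arrival cancelling the transit time
    nn = len(batch.node_pos)
    i, j = nn // 2 + 2, nn - 2
    nodes = batch.node_pos
    dist_mm = float(np.linalg.norm(cable.positions[nodes[j]] -
                                   cable.positions[nodes[i]]))
    dt_ms = abs(t_cross[0, j] - t_cross[0, i])
    return dist_mm / dt_ms if dt_ms > 0 else float("nan")


def resting_drift(spec: AxonModelSpec, t_ms: float = 10.0,
                  n_nodes: int = 25) -> float:
    """Max |Vm - Vrest| (mV) over an unstimulated integration of a
    straight fiber: a fixed-point check of the resting state."""
    length = (n_nodes + 1) * spec.internode_length_um * 1e-3
    traj = np.column_stack([np.zeros(2), np.zeros(2), [0.0, length]])
    cable = build_axon(spec, traj, min_nodes=min(n_nodes, 21))
    pulse = PulseSpec(pw_us=1.0, post_window_ms=t_ms)
    batch = CableBatch([cable], pulse)
    batch.run(np.zeros((1, cable.n_comp)), np.array([0.0]))
    return float(batch.last_max_deviation[0])
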