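"""Configuration, scenario driver, fixtures and the verification suite.

A scenario is fully described by a serialisable :class:`RunConfig`;
``run_scenario`` executes the pipeline anatomy -> field solve ->
populations -> axons -> evaluation and (optionally) writes tidy CSV
tables plus a JSON summary stamped with the config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import anatomy
from .anatomy import (
    ConductivityMap,
    Depth,
    ElectrodeConfiguration,
    Placement,
    build_spine_model,
    catalog_design,
    load_all_patients,
    load_patient,
    place_electrode,
)
from .axons import AxonModelSpec, PulseSpec, build_axon, resting_drift
from .evaluation import (
    RecruitmentTable,
    find_threshold,
    power_curve,
    recruit_population,
    selectivity,
)
from .fieldsolver import MeshControl, solve_base_field
from .populations import (
    PopulationSpec,
    build_populations,
    dc_metric_fibers,
    trajectories_frame,
)


class ConfigError(ValueError):
    """Missing or inconsistent run configuration."""


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_MESH_PROFILES = {"coarse": MeshControl.coarse,
                  "coarse_contact": MeshControl.coarse_contact,
                  "fine": MeshControl.fine}


@dataclass(frozen=True)
class RunConfig:
    """One reproducible scenario: patient, electrode, placement,
    population, pulse, axon model and solver controls."""

    patient: str = "patient_2"
    design: str = "ADTECH"
    mode: str = "bipolar"            # monopolar | bipolar | tripolar
    depth: str = "extradural_above_dura"
    clearance_mm: float = 1.0
    lateral_angle_deg: float = 0.0
    axial_rotation_deg: float = 0.0
    axon_model: str = "MRG"
    diameter_um: float = 9.0
    dt_us: float = 5.0
    pw_us: float = 300.0
    post_window_ms: float = 2.0
    n_dc_per_lamina: int = 10
    n_dr_per_side: int = 100
    fiber_span_mm: float | None = None
    jitter: float = 0.0
    seed: int = 0
    mesh: str = "fine"               # coarse | fine
    mesh_scale: float = 1.0
    rel_tol: float = 0.01
    amp0: float = 0.25
    max_amplitude: float = 4096.0
    include_dr: bool = True
    design_overrides: dict = field(default_factory=dict)
    conductivity_overrides: dict = field(default_factory=dict)
    prism_dims: tuple[float, float, float] = (100.0, 100.0, 300.0)
    out_dir: str | None = None

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["prism_dims"] = list(self.prism_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if "patient" not in d or d.get("patient") in (None, ""):
            raise ConfigError("missing required field: patient")
        if "prism_dims" in d:
            d["prism_dims"] = tuple(d["prism_dims"])
        if "design_overrides" in d and d["design_overrides"] is None:
            d["design_overrides"] = {}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific scenario (the output path is excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# --------------------------------------------------------------------------
# scenario driver
# --------------------------------------------------------------------------

@dataclass
class ScenarioResult:
    config: RunConfig
    r_access: float
    i_app: float
    dc_table: RecruitmentTable
    dr_table: RecruitmentTable | None
    selectivity: object | None
    power: object
    mesh_cells: int
    provenance: dict

    def summary(self) -> dict:
        v50 = None
        try:
            v50 = self.dc_table.voltage_at_fraction(0.5)
        except Exception:
            pass
        return {
            "config_hash": self.config.config_hash,
            "patient": self.config.patient,
            "design": self.config.design,
            "depth": self.config.depth,
            "lateral_angle_deg": self.config.lateral_angle_deg,
            "r_access_ohm": self.r_access,
            "i_app_a": self.i_app,
            "mesh_cells": self.mesh_cells,
            "dc0_pct": getattr(self.selectivity, "dc0", None),
            "v50_v": v50,
            "power50_w": (v50 ** 2 / self.r_access) if v50 is not None else None,
        }


def _stage(name):
    def deco(fn):
        def wrapper(*a, **k):
            try:
                return fn(*a, **k)
            except Exception as e:
                raise type(e)(f"[stage:{name}] {e}") from e
        return wrapper
    return deco


def build_scenario_model(cfg: RunConfig):
    """anatomy stage: patient model with the electrode placed."""
    patient = load_patient(cfg.patient)
    cond = ConductivityMap.default()
    if cfg.conductivity_overrides:
        cond = dataclasses.replace(cond, **cfg.conductivity_overrides)
    model = build_spine_model(patient, cond, prism_dims=cfg.prism_dims)
    design = catalog_design(cfg.design, **cfg.design_overrides)
    placement = Placement(depth=Depth(cfg.depth), clearance_mm=cfg.clearance_mm,
                          lateral_angle_deg=cfg.lateral_angle_deg,
                          axial_rotation_deg=cfg.axial_rotation_deg)
    return place_electrode(model, design, placement)


def electrode_configuration(cfg: RunConfig) -> ElectrodeConfiguration:
    if cfg.design == "AT" and cfg.mode == "tripolar":
        return ElectrodeConfiguration.azimuthal_tripolar()
    if cfg.mode == "monopolar":
        return ElectrodeConfiguration.monopolar()
    if cfg.mode == "bipolar":
        return ElectrodeConfiguration.bipolar()
    return ElectrodeConfiguration.tripolar()


def cathode_position(placed) -> np.ndarray:
    """3-D centre of the cathodal contact (for node alignment)."""
    cx, cy = placed.pose.center_xy
    return np.array([cx, cy, placed.pose.z_center])


def run_scenario(cfg: RunConfig) -> ScenarioResult:
    """Execute the full pipeline for one configuration.

    Stage failures abort with a stage-tagged message.  With
    ``cfg.out_dir`` set, writes recruitment/selectivity/power tables
    (CSV), the fiber trajectories, and a JSON summary carrying the
    config hash.
    """
    t0 = time.time()
    placed = _stage("anatomy")(build_scenario_model)(cfg)
    econf = electrode_configuration(cfg)
    ctrl = _MESH_PROFILES[cfg.mesh]().scaled(cfg.mesh_scale)
    sol = _stage("fieldsolver")(solve_base_field)(placed, econf, ctrl)

    pspec = PopulationSpec(n_dc_per_lamina=cfg.n_dc_per_lamina,
                           n_dr_per_side=cfg.n_dr_per_side,
                           diameter_um=cfg.diameter_um, seed=cfg.seed,
                           jitter=cfg.jitter, fiber_span_mm=cfg.fiber_span_mm)
    dc, dr = _stage("populations")(build_populations)(placed.model, pspec)
    med = dc_metric_fibers(dc)

    axspec = AxonModelSpec(model=cfg.axon_model, diameter_um=cfg.diameter_um,
                           dt_us=cfg.dt_us)
    pulse = PulseSpec(pw_us=cfg.pw_us, post_window_ms=cfg.post_window_ms)
    cath = cathode_position(placed)
    dc_table = _stage("evaluation")(recruit_population)(
        med, sol, pulse, axspec, cathode_xyz=cath, rel_tol=cfg.rel_tol,
        amp0=cfg.amp0, max_amplitude=cfg.max_amplitude)
    dr_table = None
    sel = None
    if cfg.include_dr:
        dr_table = _stage("evaluation")(recruit_population)(
            dr, sol, pulse, axspec, cathode_xyz=cath, rel_tol=cfg.rel_tol,
            amp0=cfg.amp0, max_amplitude=cfg.max_amplitude)
        sel = selectivity(dc_table, dr_table)
    power = power_curve(dc_table, pulse)

    prov = {
        "config_hash": cfg.config_hash,
        "mesh_cells": sol.n_cells,
        "solver_residual": sol.residual,
        "elapsed_s": round(time.time() - t0, 1),
        "config": cfg.to_dict(),
    }
    result = ScenarioResult(config=cfg, r_access=sol.r_access, i_app=sol.i_app,
                            dc_table=dc_table, dr_table=dr_table,
                            selectivity=sel, power=power,
                            mesh_cells=sol.n_cells, provenance=prov)
    if cfg.out_dir:
        _write_bundle(result, dc + dr, Path(cfg.out_dir))
    return result


def _write_bundle(res: ScenarioResult, fibers, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    h = res.config.config_hash
    res.dc_table.table.assign(config_hash=h).to_csv(
        out / "recruitment_dc.csv", index=False)
    if res.dr_table is not None:
        res.dr_table.table.assign(config_hash=h).to_csv(
            out / "recruitment_dr.csv", index=False)
    if res.selectivity is not None:
        res.selectivity.curve.assign(config_hash=h).to_csv(
            out / "selectivity_curve.csv", index=False)
    res.power.curve.assign(config_hash=h).to_csv(
        out / "power_curve.csv", index=False)
    trajectories_frame(fibers).assign(config_hash=h).to_csv(
        out / "fiber_trajectories.csv", index=False)
    with open(out / "summary.json", "w") as fh:
        json.dump({"summary": res.summary(), "provenance": res.provenance},
                  fh, indent=2, default=float)


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

def generate_fixtures(out_dir) -> dict:
    """Write the shipped fixtures (patient geometries, conductivities,
    electrode designs) and the three toy verification-domain parameter
    sets to ``out_dir``; returns the fixture data."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    patients = {k: dataclasses.asdict(v) for k, v in load_all_patients().items()}
    for p in patients.values():
        p["cord_placement"] = p["cord_placement"].value
    cond = dataclasses.asdict(ConductivityMap.default())
    designs = {d: dataclasses.asdict(catalog_design(d))
               for d in anatomy.ALL_DESIGNS}
    for d in designs.values():
        d["contact_azimuths_deg"] = list(d["contact_azimuths_deg"])
    toys = {
        "slab": {"sigma": 0.5, "length": 10.0, "side": 4.0,
                 "n_axial": 20, "n_side": 6},
        "concentric_spheres": {"sigma": 0.4, "r1": 3.0, "r2": 13.0,
                               "half": 15.0, "n": 41},
        "point_source": {"sigma": 0.25, "half": 12.0, "n": 49,
                         "r_ground": 10.0},
    }
    data = {"patients": patients, "conductivities": cond,
            "electrodes": designs, "toy_domains": toys}
    for name, blob in data.items():
        with open(out / f"{name}.yaml", "w") as fh:
            yaml.safe_dump(blob, fh, sort_keys=True)
    return data


# --------------------------------------------------------------------------
# verification oracle suite
# --------------------------------------------------------------------------

def verify(level: str = "fast") -> dict:
    """Run the oracle suite; failures are report entries, not raises.

    ``fast`` checks the analytic field-solver oracles, bisection vs a
    brute-force sweep, resting stability and the activating-function
    identities on toy domains; ``full`` adds one coarse end-to-end
    patient scenario.
    """
    from . import toys
    from .axons import CableBatch, activating_profile

    checks = []

    def check(name, passed, value=None, tol=None):
        checks.append({"name": name, "passed": bool(passed),
                       "value": None if value is None else float(value),
                       "tolerance": tol})

    sol, r_an = toys.slab()
    check("slab_resistance_exact",
          abs(sol["r_access"] / r_an - 1) < 1e-6,
          abs(sol["r_access"] / r_an - 1), 1e-6)

    rc, ra = toys.concentric_spheres()
    check("concentric_spheres", abs(rc / ra - 1) < 0.10,
          abs(rc / ra - 1), 0.10)

    res, analytic = toys.point_source()
    mesh, phi, rg = res["mesh"], res["phi"], res["r_grid"]
    i0 = mesh.shape[1] // 2
    ray, r = phi[:, i0, i0], rg[:, i0, i0]
    selr = (r > 1.5) & (r < 5.0)
    err = np.max(np.abs(ray[selr] - analytic(r[selr])) /
                 np.abs(analytic(r[selr])))
    check("point_source_profile", err < 0.05, err, 0.05)

    # activating function identities
    lin = activating_profile(np.linspace(0.0, 1.0, 9))
    check("activating_function_linear_ramp", np.allclose(lin, 0.0))

    # resting stability
    for model in ("SW", "MRG"):
        d = resting_drift(AxonModelSpec(model=model))
        check(f"resting_stability_{model}", d < 0.1, d, 0.1)

    # bisection vs brute-force sweep on a point-source-driven fiber
    spec = AxonModelSpec(model="MRG", diameter_um=9.0)
    pulse = PulseSpec()
    traj = np.column_stack([np.zeros(2), np.zeros(2), [0.0, 60.0]])
    cable = build_axon(spec, traj, align_mm=30.0)
    pos = cable.positions
    src = pos[len(pos) // 2] + np.array([0.0, 2.0, 0.0])
    ve = -1e-6 / (4 * np.pi * 0.3 *
                  np.linalg.norm(pos - src, axis=1) * 1e-3)
    th = find_threshold(cable, ve, pulse)
    batch = CableBatch([cable], pulse)
    step = th * 0.01 / 4.0
    sweep = None
    a = th * 0.95
    while a < th * 1.05:
        if batch.run(ve[None, :], np.array([a]))[0]:
            sweep = a
            break
        a += step
    check("bisection_vs_sweep", sweep is not None and
          abs(th - sweep) / sweep <= 0.01,
          None if sweep is None else abs(th - sweep) / sweep, 0.01)

    if level == "full":
        cfg = RunConfig(patient="patient_2", mesh="coarse",
                        n_dc_per_lamina=1, n_dr_per_side=4,
                        fiber_span_mm=60.0)
        extra = run_scenario(cfg)
        intra = run_scenario(dataclasses.replace(
            cfg, depth="intradural_above_cord"))
        check("ra_drop_extradural_to_intradural",
              intra.r_access < 0.15 * extra.r_access,
              intra.r_access / extra.r_access, 0.15)
        check("intradural_dc0_not_worse",
              intra.selectivity.dc0 >= extra.selectivity.dc0)

    return {"level": level, "passed": all(c["passed"] for c in checks),
            "checks": checks}
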