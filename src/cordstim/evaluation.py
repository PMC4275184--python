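"""Threshold search, recruitment, and efficiency/selectivity metrics.

All metrics derive from per-fiber threshold amplitudes found by
bisection against the linearly scaled base field solution:

* threshold voltage = threshold scalar x anode-cathode drive voltage;
* threshold current = threshold voltage / R_a;
* average pulse power P = V^2 / R_a for the rectangular pulse;
* DC_0 / DC_X neural-element selectivity and dermatome selectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .axons import AxonModelSpec, Cable, CableBatch, PulseSpec, build_axon
from .fieldsolver import FieldSolution
from .populations import FiberTrajectory

#: sentinel threshold for fibers that cannot be activated within the
#: amplitude cap (recorded, never raised)
INEXCITABLE = np.inf

#: low-back target dermatomes for dermatome-selectivity reporting
DEFAULT_TARGETS = ("L2", "L3", "L4", "L5")


class EvaluationError(ValueError):
    pass


# --------------------------------------------------------------------------
# threshold search
# --------------------------------------------------------------------------

def batch_thresholds(batch: CableBatch, ve_unit: np.ndarray,
                     rel_tol: float = 0.01, amp0: float = 0.25,
                     max_amplitude: float = 4096.0) -> np.ndarray:
    """Vectorised bisection thresholds (base-field scalars) for a batch.

    Brackets grow geometrically per fiber from ``amp0``; fibers that do
    not activate at ``max_amplitude`` get the ``INEXCITABLE`` sentinel.
    Bisection narrows each bracket to ``(hi-lo)/lo <= rel_tol``.
    """
    n = batch.n_f
    lo = np.zeros(n)
    hi = np.full(n, np.nan)
    amp = np.full(n, float(amp0))
    ve_unit = np.asarray(ve_unit, float)

    def run_subset(mask, amplitudes):
        """Integrate only the fibers still being searched."""
        idx = np.flatnonzero(mask)
        if len(idx) == n:
            return batch.run(ve_unit, amplitudes)
        sub = CableBatch([batch.cables[i] for i in idx], batch.pulse,
                         dt_us=batch.dt * 1e3, theta=batch.theta)
        act = np.zeros(n, dtype=bool)
        act[idx] = sub.run(ve_unit[idx], amplitudes[idx])
        return act

    while True:
        open_mask = np.isnan(hi) & (amp <= max_amplitude)
        if not open_mask.any():
            break
        act = run_subset(open_mask, amp)
        newly = open_mask & act
        hi[newly] = amp[newly]
        lo[open_mask & ~act] = amp[open_mask & ~act]
        amp[open_mask & ~act] *= 2.0

    excitable = ~np.isnan(hi)
    while True:
        with np.errstate(invalid="ignore", divide="ignore"):
            width = (hi - lo) / np.maximum(lo, 1e-300)
        todo = excitable & (width > rel_tol) & (lo > 0)
        # fibers activated on the very first trial have lo == 0: shrink
        # the bracket downward instead
        zero_lo = excitable & (lo == 0) & (hi > 1e-9)
        sel = todo | zero_lo
        if not sel.any():
            break
        mid = np.where(todo, 0.5 * (lo + hi), 0.0)
        mid = np.where(zero_lo, hi / 2.0, mid)
        act = run_subset(sel, mid)
        hi[sel & act] = mid[sel & act]
        lo[sel & ~act] = mid[sel & ~act]
    th = np.where(excitable, hi, INEXCITABLE)
    return th


def find_threshold(cable: Cable, base_field, pulse: PulseSpec,
                   rel_tol: float = 0.01, amp0: float = 0.25,
                   max_amplitude: float = 4096.0,
                   dt_us: float | None = None) -> float:
    """Bisection threshold scalar for a single fiber.

    ``base_field`` is either a :class:`FieldSolution` or a pre-sampled
    potential array (V, one value per cable compartment).  Returns the
    ``INEXCITABLE`` sentinel if the amplitude cap is reached.
    """
    if isinstance(base_field, FieldSolution):
        ve = base_field.potential_at(cable.positions)
    else:
        ve = np.asarray(base_field, float)
    batch = CableBatch([cable], pulse, dt_us=dt_us)
    return float(batch_thresholds(batch, ve[None, :], rel_tol=rel_tol,
                                  amp0=amp0, max_amplitude=max_amplitude)[0])


# --------------------------------------------------------------------------
# recruitment
# --------------------------------------------------------------------------

@dataclass
class RecruitmentTable:
    """Per-fiber thresholds for one (field, population, model) scenario.

    ``table`` columns: fiber_id, class, dermatome, dermatome_index,
    side, diameter_um, threshold_scalar, threshold_voltage (V),
    threshold_current (A).  Inexcitable fibers carry +inf.
    """

    table: pd.DataFrame
    r_access: float
    drive_voltage: float
    pulse: PulseSpec
    model: str

    def __post_init__(self):
        cur = self.table["threshold_voltage"] / self.r_access
        if not np.allclose(self.table["threshold_current"].replace(np.inf, 1.0),
                           cur.replace(np.inf, 1.0)):
            raise EvaluationError("threshold current/voltage inconsistency")

    @property
    def thresholds(self) -> np.ndarray:
        return self.table["threshold_voltage"].to_numpy()

    def excitable(self) -> pd.DataFrame:
        return self.table[np.isfinite(self.table["threshold_voltage"])]

    def activation_fraction(self, voltage: float) -> float:
        """Fraction of fibers with threshold voltage <= the amplitude."""
        th = self.thresholds
        return float(np.mean(th <= voltage))

    def voltage_at_fraction(self, fraction: float) -> float:
        """Smallest amplitude (V) activating at least this fraction."""
        th = np.sort(self.thresholds)
        k = int(np.ceil(fraction * len(th)))
        k = max(1, min(k, len(th)))
        v = th[k - 1]
        if not np.isfinite(v):
            raise EvaluationError(
                f"fewer than {fraction:.0%} of fibers are excitable")
        return float(v)

    def input_output_curve(self) -> pd.DataFrame:
        """Step curve: amplitude (V) vs % of fibers active."""
        th = np.sort(self.thresholds[np.isfinite(self.thresholds)])
        pct = 100.0 * np.arange(1, len(th) + 1) / len(self.thresholds)
        return pd.DataFrame({"voltage": th, "pct_active": pct})


def recruit_population(fibers: list[FiberTrajectory], sol: FieldSolution,
                       pulse: PulseSpec, axon_spec: AxonModelSpec,
                       cathode_xyz: np.ndarray | None = None,
                       rel_tol: float = 0.01, amp0: float = 0.25,
                       max_amplitude: float = 4096.0,
                       dt_us: float | None = None) -> RecruitmentTable:
    """Thresholds for a whole fiber population against one base field.

    Cables are aligned so a node of Ranvier sits at the trajectory point
    closest to the cathode, grouped by compartment count, and integrated
    as batches.
    """
    if not fibers:
        raise EvaluationError("empty fiber population")
    cables = []
    for f in fibers:
        pts = f.points
        if cathode_xyz is not None:
            seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
            s = np.concatenate([[0.0], np.cumsum(seg)])
            dense_s = np.linspace(0.0, s[-1], 512)
            dense = np.column_stack([np.interp(dense_s, s, pts[:, k])
                                     for k in range(3)])
            align = float(dense_s[np.argmin(
                np.linalg.norm(dense - np.asarray(cathode_xyz), axis=1))])
        else:
            align = None
        spec_f = axon_spec if axon_spec.diameter_um == f.diameter_um else \
            AxonModelSpec(model=axon_spec.model, diameter_um=f.diameter_um,
                          dt_us=axon_spec.dt_us)
        cables.append(build_axon(spec_f, pts, align_mm=align))

    thresholds = np.empty(len(fibers))
    groups: dict[int, list[int]] = {}
    for i, c in enumerate(cables):
        groups.setdefault(c.n_comp, []).append(i)
    for idxs in groups.values():
        batch = CableBatch([cables[i] for i in idxs], pulse, dt_us=dt_us)
        ve = np.stack([sol.potential_at(cables[i].positions) for i in idxs])
        th = batch_thresholds(batch, ve, rel_tol=rel_tol, amp0=amp0,
                              max_amplitude=max_amplitude)
        thresholds[idxs] = th

    rows = pd.DataFrame({
        "fiber_id": [f.fiber_id for f in fibers],
        "class": [f.fiber_class for f in fibers],
        "dermatome": [f.dermatome for f in fibers],
        "dermatome_index": [f.dermatome_index for f in fibers],
        "side": [f.side for f in fibers],
        "diameter_um": [f.diameter_um for f in fibers],
        "threshold_scalar": thresholds,
        "threshold_voltage": thresholds * sol.drive_voltage,
        "threshold_current": thresholds * sol.drive_voltage / sol.r_access,
    })
    return RecruitmentTable(table=rows, r_access=sol.r_access,
                            drive_voltage=sol.drive_voltage, pulse=pulse,
                            model=axon_spec.model)


# --------------------------------------------------------------------------
# efficiency
# --------------------------------------------------------------------------

def average_power(threshold_voltage: float, r_access: float,
                  pulse: PulseSpec) -> float:
    """Average electrical power (W) over the rectangular stimulation
    pulse: (1/PW) Int V(t)^2 / R_a dt = V^2 / R_a."""
    if r_access <= 0:
        raise EvaluationError("access resistance must be > 0")
    return threshold_voltage ** 2 / r_access


@dataclass
class PowerResult:
    """Power required as a function of the DC activation fraction."""

    curve: pd.DataFrame  # fraction, voltage, power_w
    r_access: float

    def power_at_fraction(self, fraction: float) -> float:
        idx = np.searchsorted(self.curve["fraction"].to_numpy(), fraction)
        idx = min(idx, len(self.curve) - 1)
        return float(self.curve["power_w"].iloc[idx])


def power_curve(dc_table: RecruitmentTable, pulse: PulseSpec) -> PowerResult:
    th = np.sort(dc_table.thresholds[np.isfinite(dc_table.thresholds)])
    frac = np.arange(1, len(th) + 1) / len(dc_table.table)
    power = th ** 2 / dc_table.r_access
    return PowerResult(curve=pd.DataFrame(
        {"fraction": frac, "voltage": th, "power_w": power}),
        r_access=dc_table.r_access)


# --------------------------------------------------------------------------
# selectivity
# --------------------------------------------------------------------------

@dataclass
class SelectivityResult:
    """Neural-element and dermatome selectivity for one scenario.

    ``dc0``: % of DC fibers activatable with zero DR fibers active
    (strict: a DC threshold equal to the lowest DR threshold does not
    count).  ``curve``: % DC active as a function of % DR active,
    evaluated at the sorted union of all thresholds.
    """

    dc0: float
    curve: pd.DataFrame           # voltage, pct_dr, pct_dc
    dermatome_report: dict

    def dc_at_dr_fraction(self, pct_dr: float) -> float:
        """DC_X: % DC active when ``pct_dr`` % of DR fibers are active."""
        c = self.curve
        ok = c["pct_dr"] <= pct_dr
        return float(c.loc[ok, "pct_dc"].max()) if ok.any() else 0.0


def selectivity(dc_table: RecruitmentTable, dr_table: RecruitmentTable,
                targets: tuple[str, ...] = DEFAULT_TARGETS) -> SelectivityResult:
    """DC_0, the DC_X curve, and the dermatome co-activation report."""
    if len(dc_table.table) == 0 or len(dr_table.table) == 0:
        raise EvaluationError("empty recruitment table")
    dc_th = dc_table.thresholds
    dr_th = dr_table.thresholds
    dr_min = dr_th.min()
    dc0 = 100.0 * float(np.mean(dc_th < dr_min))

    amps = np.unique(np.concatenate([dc_th, dr_th]))
    amps = amps[np.isfinite(amps)]
    pct_dc = 100.0 * np.mean(dc_th[None, :] <= amps[:, None], axis=1)
    pct_dr = 100.0 * np.mean(dr_th[None, :] <= amps[:, None], axis=1)
    curve = pd.DataFrame({"voltage": amps, "pct_dr": pct_dr, "pct_dc": pct_dc})

    try:
        report = dermatome_selectivity(dc_table, targets)
    except EvaluationError:
        report = {"targets": list(targets), "co_activated": None,
                  "selective": None,
                  "note": "no fibers in target dermatomes"}
    return SelectivityResult(dc0=dc0, curve=curve, dermatome_report=report)


def dermatome_selectivity(dc_table: RecruitmentTable,
                          targets: tuple[str, ...] = DEFAULT_TARGETS) -> dict:
    """Co-activation report for a target dermatome set.

    The target-set activation amplitude is the smallest amplitude at
    which every target dermatome has at least one active fiber; the
    report lists the non-target dermatomes with any fiber at or below
    that amplitude, and per-dermatome threshold ranges.
    """
    tab = dc_table.table
    present = [d for d in targets if (tab["dermatome"] == d).any()]
    if not present:
        raise EvaluationError(f"no fibers in target dermatomes {targets}")
    per_min = tab.groupby("dermatome")["threshold_voltage"].min()
    amp_target = float(max(per_min[d] for d in present))
    co = sorted(d for d, v in per_min.items()
                if d not in targets and v <= amp_target)
    ranges = tab.groupby("dermatome")["threshold_voltage"] \
        .agg(["min", "max"]).to_dict("index")
    return {
        "targets": list(targets),
        "target_amplitude_v": amp_target,
        "co_activated": co,
        "threshold_ranges": ranges,
        "selective": len(co) == 0,
    }


# --------------------------------------------------------------------------
# clinical matching
# --------------------------------------------------------------------------

def clinical_match(tables_by_diameter: dict[float, RecruitmentTable],
                   reported_dermatome_sides: int,
                   clinical_amplitude_a: float) -> dict:
    """Best-matching fiber diameter for a clinical threshold report.

    Paresthesia in one dermatome on one side of the body is taken to
    correspond to activation of 5 % of the modelled DC fibers, so the
    expected activation is ``5 x reported_dermatome_sides`` percent; the
    returned diameters are those whose % activation at the clinical
    amplitude (a current, compared against threshold currents) is
    nearest the expected value.  Ties are reported as ambiguous.
    """
    if not tables_by_diameter:
        raise EvaluationError("no candidate recruitment tables")
    expected = 5.0 * reported_dermatome_sides
    rows = []
    for d, tab in sorted(tables_by_diameter.items()):
        th = tab.table["threshold_current"].to_numpy()
        pct = 100.0 * float(np.mean(th <= clinical_amplitude_a))
        rows.append((d, pct, abs(pct - expected)))
    err = np.array([r[2] for r in rows])
    best = np.flatnonzero(np.isclose(err, err.min()))
    return {
        "expected_pct": expected,
        "per_diameter_pct": {r[0]: r[1] for r in rows},
        "best_diameters": [rows[i][0] for i in best],
        "ambiguous": len(best) > 1,
    }


# --------------------------------------------------------------------------
# design comparison
# --------------------------------------------------------------------------

def design_comparison(runner, designs, placements, patients,
                      **runner_kwargs) -> pd.DataFrame:
    """Cross table of selectivity/efficiency metrics.

    ``runner(design_id, placement, patient, **kwargs)`` must return a
    mapping with at least ``dc0``, ``r_access`` and ``power_50`` (and
    may add more columns); this function assembles the cross table over
    all (design, placement, patient) combinations.
    """
    records = []
    for d in designs:
        for pl in placements:
            for pat in patients:
                rec = dict(runner(d, pl, pat, **runner_kwargs))
                rec.update({"design": d, "patient": pat,
                            "depth": getattr(pl, "depth", pl).value
                            if hasattr(getattr(pl, "depth", pl), "value")
                            else str(pl),
                            "lateral_angle_deg":
                                getattr(pl, "lateral_angle_deg", np.nan),
                            "axial_rotation_deg":
                                getattr(pl, "axial_rotation_deg", 0.0)})
                records.append(rec)
    return pd.DataFrame(records)
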