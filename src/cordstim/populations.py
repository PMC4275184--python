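"""Dorsal-column and dorsal-root fiber populations.

The dorsomedial white matter between the dorsal cord surface and the
grey-matter dorsal horns is split, per side, into 11 equal-width
mediolateral laminae (dermatomes), named medial-to-lateral after the
body map they serve at this cord level (S5 ... L1, plus the lateral-most
entry-zone lamina).  DC fibers run axis-parallel within their lamina.
DR fibers are continuous with the lateral-most-lamina DC fibers: from
the dorsal root entry they descend ventrolaterally through the CSF
(via the rootlets) and exit the spine at the intervertebral foramen one
vertebral level caudal.

The default population reproduces the study condition: 10 DC fibers per
side in each of the 10 most medial dermatomes (200 DC fibers) plus 200
lateral-most DC fibers attached to 200 DR fibers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import CubicSpline

from .anatomy import SpineModel, Tissue

#: lamina names, medial to lateral; the last is the dorsal-root entry zone
DERMATOME_NAMES = ("S5", "S4", "S3", "S2", "S1",
                   "L5", "L4", "L3", "L2", "L1", "DREZ")


class PopulationError(ValueError):
    """Population cannot be built for this geometry/spec."""


@dataclass(frozen=True)
class FiberTrajectory:
    """An ordered 3-D polyline with fiber metadata (mm)."""

    points: np.ndarray
    fiber_class: str          # "DC" | "DR"
    dermatome: str
    dermatome_index: int      # 0 (medial) .. 10 (lateral-most)
    side: str                 # "left" | "right"
    diameter_um: float
    fiber_id: int

    def __post_init__(self):
        object.__setattr__(self, "points", np.asarray(self.points, float))

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass(frozen=True)
class PopulationSpec:
    """Counts, diameter and geometry parameters of the fiber populations.

    Defaults are the study conditions; ``n_dc_per_lamina`` and
    ``n_dr_per_side`` can be reduced for survey-resolution runs.
    """

    n_dc_per_lamina: int = 10      # per side, each of the 10 medial laminae
    n_dr_per_side: int = 100       # lateral-most lamina fibers == DR fibers
    n_dermatomes: int = 11
    diameter_um: float = 9.0
    seed: int = 0
    jitter: float = 0.0            # fraction of a lamina width
    fiber_span_mm: float | None = None  # None -> full model length
    # DR geometry
    dr_descent_angle_deg: float = 45.0  # ventrolateral inclination
    dr_entry_span_mm: tuple[float, float] = (-14.0, 0.0)
    dr_exit_extra_mm: float = 3.0       # run beyond the dura (foramen)

    def __post_init__(self):
        if self.n_dermatomes != len(DERMATOME_NAMES):
            raise PopulationError("lamination is defined for 11 dermatomes")
        if self.n_dc_per_lamina < 1 or self.n_dr_per_side < 1:
            raise PopulationError("fiber counts must be >= 1")


# --------------------------------------------------------------------------
# dorsomedial band geometry helpers
# --------------------------------------------------------------------------

def _band_scales(model: SpineModel):
    a, b = model.cord_semi_axes
    yc = model.cord_center[1]
    s_out = 0.97                       # just inside the cord surface
    s_in = model.dc_band_inner_scale   # dorsal horn boundary
    x_band = model.dc_band_lateral_scale * a
    return a, b, yc, s_out, s_in, x_band


def _band_y(model: SpineModel, x: np.ndarray, depth_frac: np.ndarray):
    """Dorsoventral position inside the band: depth_frac 0 = outer
    (cord surface side), 1 = inner (dorsal horn side)."""
    a, b, yc, s_out, s_in, _ = _band_scales(model)
    y_out = yc + b * s_out * np.sqrt(1.0 - (x / (a * s_out)) ** 2)
    y_in = yc + b * s_in * np.sqrt(np.clip(1.0 - (x / (a * s_in)) ** 2, 0.0, None))
    return (1.0 - depth_frac) * y_out + depth_frac * y_in


def _lamina_positions(model: SpineModel, lamina: int, n: int, rng,
                      jitter: float):
    """(x, y) positions for ``n`` fibers in one lamina (left side; mirror
    x for the right side).  Fibers sit on a uniform (ml x dv) grid with
    optional seeded jitter."""
    _, _, _, _, _, x_band = _band_scales(model)
    w = x_band / len(DERMATOME_NAMES)
    x0 = lamina * w
    n_ml = max(1, int(round(np.sqrt(n / 2.5))))
    n_dv = int(np.ceil(n / n_ml))
    uu, vv = np.meshgrid((np.arange(n_ml) + 0.5) / n_ml,
                         (np.arange(n_dv) + 0.5) / n_dv, indexing="ij")
    uu, vv = uu.ravel()[:n], vv.ravel()[:n]
    if jitter > 0:
        uu = np.clip(uu + rng.uniform(-jitter, jitter, n), 0.02, 0.98)
        vv = np.clip(vv + rng.uniform(-jitter, jitter, n), 0.02, 0.98)
    x = x0 + uu * w
    depth = 0.15 + 0.7 * vv  # keep a margin off both band boundaries
    y = _band_y(model, x, depth)
    return x, y


# --------------------------------------------------------------------------
# population builders
# --------------------------------------------------------------------------

def build_dc_population(model: SpineModel, spec: PopulationSpec
                        ) -> list[FiberTrajectory]:
    """Axis-parallel DC fibers in all 11 laminae of both sides.

    Lateral-most-lamina fibers terminate caudally at their (staggered)
    dorsal-root entry stations; they are the proximal ends of the DR
    fibers that :func:`build_dr_population` attaches.
    """
    rng = np.random.default_rng(spec.seed)
    z_lo, z_hi = model.z_extent
    if spec.fiber_span_mm is not None:
        z_lo, z_hi = -spec.fiber_span_mm / 2.0, spec.fiber_span_mm / 2.0
    fibers = []
    fid = 0
    for side, sgn in (("left", +1.0), ("right", -1.0)):
        for lam in range(len(DERMATOME_NAMES)):
            lateral = lam == len(DERMATOME_NAMES) - 1
            n = spec.n_dr_per_side if lateral else spec.n_dc_per_lamina
            x, y = _lamina_positions(model, lam, n, rng, spec.jitter)
            if lateral:
                z_entry = np.linspace(spec.dr_entry_span_mm[0],
                                      spec.dr_entry_span_mm[1], n)
            for k in range(n):
                z_end = z_entry[k] if lateral else z_lo
                pts = np.array([[sgn * x[k], y[k], z_hi],
                                [sgn * x[k], y[k], z_end]])
                fibers.append(FiberTrajectory(
                    points=pts, fiber_class="DC",
                    dermatome=DERMATOME_NAMES[lam], dermatome_index=lam,
                    side=side, diameter_um=spec.diameter_um, fiber_id=fid))
                fid += 1
    return fibers


def dc_metric_fibers(fibers: list[FiberTrajectory]) -> list[FiberTrajectory]:
    """The DC fibers entering selectivity metrics: the 10 medial laminae
    per side (the lateral-most lamina is continuous with the DR fibers
    and is counted with them)."""
    return [f for f in fibers if f.dermatome_index < len(DERMATOME_NAMES) - 1]


def build_dr_population(model: SpineModel, spec: PopulationSpec,
                        dc_fibers: list[FiberTrajectory]
                        ) -> list[FiberTrajectory]:
    """DR fibers continuous with the lateral-most-lamina DC fibers.

    Each returned trajectory is the full conducting path used for
    stimulation: the axis-parallel dorsal-column run from the rostral
    model boundary down to the dorsal root entry, then a smooth
    (spline-resampled) ventrolateral descent through the CSF that pierces
    the dura and ends in the foramen region.
    """
    lateral = [f for f in dc_fibers
               if f.dermatome_index == len(DERMATOME_NAMES) - 1]
    if not lateral:
        raise PopulationError("no lateral-most-lamina DC fibers to attach to")
    a_in, b_in = model.csf_semi_axes
    a_do, b_do = model.dura_outer_semi_axes
    tan = np.tan(np.radians(spec.dr_descent_angle_deg))
    out = []
    for fid, f in enumerate(lateral):
        p0 = f.points[-1]  # caudal end of the DC run = proximal DR end
        sgn = +1.0 if f.side == "left" else -1.0
        x0, y0, z0 = p0

        def ellipse_pt(angle_deg, aa, bb):
            # point on the ellipse at an angle from dorsal, on this side
            th = np.radians(angle_deg)
            d = np.array([sgn * np.sin(th), np.cos(th)])
            r = 1.0 / np.sqrt((d[0] / aa) ** 2 + (d[1] / bb) ** 2)
            return r * d

        # radial stations of the descent (angles from dorsal, degrees)
        ac, bc = model.cord_semi_axes
        yc = model.cord_center[1]
        p_surf = ellipse_pt(50.0, ac * 1.0, bc * 1.0) + np.array([0.0, yc])
        p_mid = 0.5 * (p_surf + ellipse_pt(75.0, a_in, b_in))
        p_dura_in = ellipse_pt(85.0, a_in, b_in)
        p_exit = ellipse_pt(88.0, a_do + spec.dr_exit_extra_mm,
                            b_do + spec.dr_exit_extra_mm)

        # rostrocaudal drop follows the descent inclination
        def zdrop(pa, pb):
            return np.hypot(*(pb - pa)) / max(tan, 1e-6)

        ctrl = [p0]
        zs = [z0]
        prev_xy = np.array([x0, y0])
        for q in (p_surf, p_mid, p_dura_in, p_exit):
            zs.append(zs[-1] - zdrop(prev_xy, q))
            ctrl.append(np.array([q[0], q[1], zs[-1]]))
            prev_xy = q
        ctrl = np.vstack(ctrl)

        # spline-resample the descent for tangent continuity, then
        # prepend the straight dorsal-column run
        chord = np.concatenate([[0.0],
                                np.cumsum(np.linalg.norm(np.diff(ctrl, axis=0),
                                                         axis=1))])
        cs = CubicSpline(chord, ctrl, axis=0)
        s_dense = np.linspace(0.0, chord[-1], 40)
        descent = cs(s_dense)
        pts = np.vstack([f.points[0], descent])
        out.append(FiberTrajectory(
            points=pts, fiber_class="DR", dermatome=f.dermatome,
            dermatome_index=f.dermatome_index, side=f.side,
            diameter_um=spec.diameter_um, fiber_id=fid))
    return out


def build_populations(model: SpineModel, spec: PopulationSpec):
    """Convenience: (dc_fibers, dr_fibers) with DR attached."""
    dc = build_dc_population(model, spec)
    dr = build_dr_population(model, spec, dc)
    return dc, dr


def trajectories_frame(fibers: list[FiberTrajectory]):
    """Tidy table of trajectory points (one row per point)."""
    import pandas as pd

    rows = []
    for f in fibers:
        for p in f.points:
            rows.append((f.fiber_id, f.fiber_class, f.dermatome, f.side,
                         f.diameter_um, p[0], p[1], p[2]))
    return pd.DataFrame(rows, columns=["fiber_id", "class", "dermatome",
                                       "side", "diameter_um", "x", "y", "z"])
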