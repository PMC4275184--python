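"""Analytic verification domains for the field solver.

Small closed-form problems (Ohmic slab, point source in a homogeneous
medium, concentric spheres) built directly on the finite-volume core.
They serve as independent oracles for the solver's potentials, applied
current and access resistance.
"""

from __future__ import annotations

import numpy as np

from .fieldsolver import Mesh, solve_dirichlet, surface_current, _SIGMA_METAL


def _uniform_mesh(bounds, n, sigma_iso):
    """Uniform isotropic cube mesh; ``bounds`` = (lo, hi) per axis."""
    edges = [np.linspace(lo, hi, ni + 1) for (lo, hi), ni in zip(bounds, n)]
    shape = tuple(ni for ni in n)
    sigma = np.full(shape + (3,), sigma_iso, dtype=float)
    return Mesh(xe=edges[0], ye=edges[1], ze=edges[2], sigma=sigma,
                region=np.zeros(shape, dtype=np.int8))


def slab(sigma: float = 0.5, length: float = 10.0, side: float = 4.0,
         n_axial: int = 20, n_side: int = 6):
    """Parallel-plate slab.

    Returns (solution dict, analytic R).  Metal plate layers close both
    ends; the analytic resistance of the interior tissue column is
    L/(sigma*A), which the 1-D series finite-volume network reproduces
    exactly.
    """
    mesh = _uniform_mesh(((0.0, length), (0.0, side), (0.0, side)),
                         (n_axial + 2, n_side, n_side), sigma)
    dx = length / (n_axial + 2)
    mesh.sigma[0], mesh.sigma[-1] = _SIGMA_METAL, _SIGMA_METAL
    dirich = np.full(mesh.shape, np.nan)
    dirich[0] = 1.0
    dirich[-1] = 0.0
    phi, _ = solve_dirichlet(mesh, dirich)
    anode = np.zeros(mesh.shape, bool)
    anode[0] = True
    i_app = surface_current(mesh, phi, anode)  # A
    interior_len = length - 2 * dx
    r_analytic = (interior_len * 1e-3) / (sigma * (side * 1e-3) ** 2)
    return {"mesh": mesh, "phi": phi, "i_app": i_app,
            "r_access": 1.0 / i_app}, r_analytic


def point_source(sigma: float = 0.25, half: float = 16.0, n: int = 65,
                 r_ground: float = 14.0):
    """Unit-potential point-like cubic contact in a homogeneous medium,
    grounded on a sphere of radius ``r_ground``.

    Analytic: Phi(r) = (I / 4 pi sigma) (1/r - 1/r_ground).
    Returns (phi interpolable arrays, current, analytic profile fn).
    """
    mesh = _uniform_mesh(((-half, half),) * 3, (n, n, n), sigma)
    xc, yc, zc = mesh.centers
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    R = np.sqrt(X**2 + Y**2 + Z**2)
    src = np.unravel_index(np.argmin(R), R.shape)
    dirich = np.full(mesh.shape, np.nan)
    mesh.sigma[src] = _SIGMA_METAL
    dirich[src] = 1.0
    dirich[R >= r_ground] = 0.0
    phi, _ = solve_dirichlet(mesh, dirich)
    anode = np.zeros(mesh.shape, bool)
    anode[src] = True
    i_app = surface_current(mesh, phi, anode)  # A

    def analytic(r_mm):
        return (i_app / (4.0 * np.pi * sigma)) * (1.0 / (np.asarray(r_mm) * 1e-3)
                                                  - 1.0 / (r_ground * 1e-3))

    return {"mesh": mesh, "phi": phi, "i_app": i_app, "r_grid": R}, analytic


def concentric_spheres(sigma: float = 0.4, r1: float = 3.0, r2: float = 13.0,
                       half: float = 15.0, n: int = 61):
    """Concentric-sphere resistor: R = (1/4 pi sigma)(1/r1 - 1/r2).

    Returns (computed access resistance in Ohm, analytic value).
    """
    mesh = _uniform_mesh(((-half, half),) * 3, (n, n, n), sigma)
    xc, yc, zc = mesh.centers
    X, Y, Z = np.meshgrid(xc, yc, zc, indexing="ij")
    R = np.sqrt(X**2 + Y**2 + Z**2)
    inner = R <= r1
    outer = R >= r2
    mesh.sigma[inner] = _SIGMA_METAL
    dirich = np.full(mesh.shape, np.nan)
    dirich[inner] = 1.0
    dirich[outer] = 0.0
    phi, _ = solve_dirichlet(mesh, dirich)
    i_app = surface_current(mesh, phi, inner)
    r_computed = 1.0 / i_app
    r_analytic = (1.0 / (4.0 * np.pi * sigma)) * (1.0 / (r1 * 1e-3) - 1.0 / (r2 * 1e-3))
    return r_computed, r_analytic
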