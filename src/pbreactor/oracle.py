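"""Independent finite-difference Newton solver for the dispersion model.

Verification companion to the collocation solver: the same two-species
steady-state equations are discretised with second-order central differences
on a uniform fine grid (default 2001 nodes per species), with the Dirichlet
inlet imposed directly and the zero-gradient outlet written with a one-sided
second-order stencil (3C_N - 4C_{N-1} + C_{N-2})/(2h) = 0.  The nonlinear
system is solved by a damped Newton iteration with an analytic sparse
Jacobian.  Nothing here calls ``solve_bvp``; agreement between the two
routes is the package's main numerical check.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csc_matrix, diags
from scipy.sparse.linalg import spsolve

from .errors import ConfigError, SolverError
from .kinetics import _rate_clamped, _rate_partials, volumetric_rate
from .model import AxialProfile, ModelConfig, _check_nonnegative, solve_plug_flow

__all__ = ["solve_finite_difference"]


def solve_finite_difference(cfg: ModelConfig, n_nodes: int = 2001,
                            tol: float = 1e-9, max_iter: int = 60) -> AxialProfile:
    """Solve the coupled CR/CA boundary-value problem by damped Newton.

    ``tol`` is a relative residual tolerance; the residual is scaled by the
    inlet convective flux u*CR0/L so the criterion is mesh-independent.
    """
    if cfg.inlet_bc != "dirichlet":
        raise ConfigError("the finite-difference oracle implements the "
                          "Dirichlet inlet condition only")
    if not cfg.dz_m2_s > 0:
        raise ConfigError("the finite-difference oracle requires Dz > 0")
    if n_nodes < 5:
        raise ConfigError("n_nodes must be >= 5")

    n = int(n_nodes)
    h = cfg.length_m / (n - 1)
    dz, u = cfg.dz_m2_s, cfg.velocity_m_s
    mass_factor = 1.0 / (cfg.spec.volume_m3 * cfg.spec.void_fraction * 60.0)

    a_lo = dz / h**2 + u / (2.0 * h)   # coefficient of C[i-1]
    a_hi = dz / h**2 - u / (2.0 * h)   # coefficient of C[i+1]
    a_di = -2.0 * dz / h**2            # linear part of C[i]

    def residual(cr: np.ndarray, ca: np.ndarray) -> np.ndarray:
        r = volumetric_rate(_rate_clamped(cr, ca, cfg.kinetics), cfg.spec)
        f = np.empty(2 * n)
        for k, (c, c0) in enumerate(((cr, cfg.cr0_mM), (ca, cfg.ca0_mM))):
            fk = f[k * n:(k + 1) * n]
            fk[0] = c[0] - c0
            fk[1:-1] = (a_lo * c[:-2] + a_di * c[1:-1] + a_hi * c[2:]
                        - r[1:-1])
            fk[-1] = (3.0 * c[-1] - 4.0 * c[-2] + c[-3]) / (2.0 * h)
        return f

    def jacobian(cr: np.ndarray, ca: np.ndarray) -> csc_matrix:
        dr_dcr, dr_dca = _rate_partials(cr, ca, cfg.kinetics)
        dr_dcr = dr_dcr * cfg.spec.enzyme_mass_kg * mass_factor
        dr_dca = dr_dca * cfg.spec.enzyme_mass_kg * mass_factor

        def species_block(drdc_same: np.ndarray) -> csc_matrix:
            main = np.full(n, a_di) - drdc_same
            main[0], main[-1] = 1.0, 3.0 / (2.0 * h)
            lower = np.full(n - 1, a_lo)
            lower[-1] = -4.0 / (2.0 * h)
            upper = np.full(n - 1, a_hi)
            upper[0] = 0.0
            block = diags([lower, main, upper], [-1, 0, 1], format="lil")
            block[-1, -3] = 1.0 / (2.0 * h)
            block[0, 1] = 0.0
            return block.tocsc()

        def cross_block(drdc_other: np.ndarray) -> csc_matrix:
            d = -drdc_other.copy()
            d[0] = 0.0
            d[-1] = 0.0
            return diags([d], [0], format="csc")

        from scipy.sparse import bmat
        return bmat([[species_block(dr_dcr), cross_block(dr_dca)],
                     [cross_block(dr_dcr), species_block(dr_dca)]],
                    format="csc")

    # Initial iterate: the plug-flow limit, the natural approximation at the
    # operating Peclet numbers (~50) of this reactor.
    pf = solve_plug_flow(cfg)
    zeta = np.linspace(0.0, 1.0, n)
    cr = np.interp(zeta, pf.z_m / cfg.length_m, pf.cr_mM)
    ca = cr + (cfg.ca0_mM - cfg.cr0_mM)

    scale = max(u * max(cfg.cr0_mM, 1.0) / cfg.length_m, 1e-12)
    f = residual(cr, ca)
    for _ in range(max_iter):
        norm = float(np.max(np.abs(f)))
        if norm <= tol * scale:
            break
        step = spsolve(jacobian(cr, ca), f)
        lam = 1.0
        for _ in range(25):
            cr_new = cr - lam * step[:n]
            ca_new = ca - lam * step[n:]
            f_new = residual(cr_new, ca_new)
            if float(np.max(np.abs(f_new))) < norm:
                break
            lam *= 0.5
        else:
            # Residual at the rounding floor of the stencil arithmetic.
            if norm <= 1e-6 * scale:
                break
            raise SolverError(
                f"oracle Newton line search stalled at residual {norm:.3e}")
        cr, ca, f = cr_new, ca_new, f_new
    else:
        raise SolverError(
            f"oracle Newton failed to converge in {max_iter} iterations; "
            f"residual norm {float(np.max(np.abs(f))):.3e}")

    profile = AxialProfile(
        z_m=zeta * cfg.length_m, cr_mM=cr, ca_mM=ca,
        cs_mM=np.full(n, cfg.cs0_mM),
        diagnostics={"method": "finite_difference_newton", "n_nodes": n,
                     "max_residual": float(np.max(np.abs(f))),
                     "residual_scale": scale})
    _check_nonnegative(profile, cfg.cr0_mM)
    return profile
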