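"""Closed forms for the fully mobile special case.

When every epitope is mobile (f_I = 0), the bilayer reservoir is effectively
infinite (beta = inf) and there is no nonspecific contact (Ans = 0), the
five-equation system collapses to two quadratics in the free mobile epitope
density u = M_out at the adhesion boundary (theta -> 0+):

  conservation:   2*K1*Kx*L*u^2 + (1 + 2*K1*L)*u - rhoT            = 0
  bond balance:   K1*Kx*L*pE^2*q*u^2 + 2*K1*L*pE*q*u - sigma*S     = 0

with q = K2*pR*RT and S = 1 + KR*L + KA*A.  Eliminating u by the resultant
of the two quadratics yields a single cubic in L whose positive roots are
the bounding ligand concentrations (two roots: an adhesion window; none: no
adhesion at any dose).  At fixed L the bond balance is solved directly for
u (its unique positive root) and conservation returns the minimal epitope
density rho_min.

On the adhered branch the bond balance pins u independently of theta, so the
contact fraction is linear in the cell's epitope density,

  theta(rho) = (rho - rho_min) / (G_in - rho_min),

where G_in is the total epitope density inside the contact region at the
pinned u.  The population average of the contact area over adhered cells
therefore needs only the conditional mean of rho above rho_min — no
numerical integration over the density distribution.

These closed forms serve both as the fast path for fitting and as an
independent oracle for the general numerical solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .params import ModelParams

__all__ = [
    "require_special_case", "window_cubic_coeffs", "closed_form_window",
    "boundary_state", "BoundaryState",
]


def require_special_case(params: ModelParams) -> None:
    if params.immobility.variant != "all_mobile":
        raise ValueError("closed forms require the all-mobile variant")
    if not math.isinf(params.beta):
        raise ValueError("closed forms require beta = inf")


def _coeffs(params: ModelParams, A_M: float):
    k = params.K1_per_M
    x = params.Kx_um2
    e = params.pE
    q = params.K2_um2 * params.pR * params.RT_per_um2
    r = params.KR_per_M
    S0 = 1.0 + params.KA_per_M * A_M
    sig = params.sigma_per_um2
    return k, x, e, q, r, S0, sig


def window_cubic_coeffs(params: ModelParams, rhoT: float,
                        A_M: float = 0.0) -> np.ndarray:
    """Ascending coefficients of the boundary cubic in L.

    Resultant of the two boundary quadratics in u, divided by the common
    factor K1*Kx*L:

      K1*Kx*L * (e^2*q*rho - 2*sigma*S)^2
        - e*q*(2*K1*L*(2-e) - e) * (2*K1*L*e*q*rho - (1+2*K1*L)*sigma*S) = 0
    """
    require_special_case(params)
    k, x, e, q, r, S0, sig = _coeffs(params, A_M)
    # P1 = k*x*L*(e^2*q*rho - 2*sigma*S0 - 2*sigma*r*L)^2   (ascending coeffs)
    lin = np.array([e * e * q * rhoT - 2.0 * sig * S0, -2.0 * sig * r])
    sq = np.convolve(lin, lin)                       # ascending, degree 2
    P1 = k * x * np.concatenate([[0.0], sq])         # multiply by L
    # P2 = e*q*(-e + 2k(2-e) L) * (-sigma*S0 + (2k e q rho - sigma r - 2k sigma S0) L - 2k sigma r L^2)
    lin2 = np.array([-e, 2.0 * k * (2.0 - e)])
    T3 = np.array([-sig * S0,
                   2.0 * k * e * q * rhoT - sig * r - 2.0 * k * sig * S0,
                   -2.0 * k * sig * r])
    P2 = e * q * np.convolve(lin2, T3)
    n = max(P1.size, P2.size)
    out = np.zeros(n)
    out[:P1.size] += P1
    out[:P2.size] -= P2
    return out


def closed_form_window(params: ModelParams, rhoT: float,
                       A_M: float = 0.0) -> tuple[float, float] | None:
    """Bounding ligand concentrations (L_min, L_max) from the cubic, or None.

    Roots are validated against both original quadratics (the resultant can
    introduce spurious roots through squaring).
    """
    require_special_case(params)
    if rhoT <= 0:
        return None
    coeffs = window_cubic_coeffs(params, rhoT, A_M)
    roots = np.roots(coeffs[::-1])
    good = []
    for z in roots:
        if abs(z.imag) > 1e-9 * max(1.0, abs(z.real)) or z.real <= 0:
            continue
        L = float(z.real)
        bs = boundary_state(params, L, A_M)
        # genuine root: conservation holds at the bond-balance u
        resid = (2 * params.K1_per_M * params.Kx_um2 * L * bs.u ** 2
                 + (1 + 2 * params.K1_per_M * L) * bs.u - rhoT)
        if abs(resid) < 1e-6 * rhoT:
            good.append(L)
    if len(good) < 2:
        return None
    good.sort()
    return good[0], good[-1]


@dataclass(frozen=True)
class BoundaryState:
    """Pinned boundary quantities at one ligand dose (all-mobile case)."""
    u: float          # free mobile epitope density at the boundary (um^-2)
    rho_min: float    # minimal adhering epitope density (um^-2)
    G_in: float       # total epitope density inside the contact region (um^-2)


def boundary_state(params: ModelParams, L_M: float, A_M: float = 0.0) -> BoundaryState:
    """Solve the bond balance at fixed L: unique positive root of a quadratic.

    ``rho_min`` is the larger (i.e. the positive) root substituted into the
    conservation law; cells below it cannot supply sigma bridging bonds.
    """
    require_special_case(params)
    k, x, e, q, r, S0, sig = _coeffs(params, A_M)
    if L_M <= 0:
        return BoundaryState(u=math.inf, rho_min=math.inf, G_in=math.inf)
    S = S0 + r * L_M
    kap = q / S                             # K2 * pR * R_free
    a = k * x * L_M * e * e * kap
    b = 2.0 * k * L_M * e * kap
    # a*u^2 + b*u - sigma = 0  ->  positive root
    if a > 0:
        u = (-b + math.sqrt(b * b + 4.0 * a * sig)) / (2.0 * a)
    elif b > 0:
        u = sig / b
    else:                                   # no bridge pathway at all
        return BoundaryState(u=math.inf, rho_min=math.inf, G_in=math.inf)
    rho_min = u * (1.0 + 2.0 * k * L_M) + 2.0 * k * x * L_M * u * u
    v = e * u
    G_in = (v * (1.0 + 2.0 * k * L_M) + 2.0 * k * x * L_M * v * v
            + kap * (2.0 * k * L_M * v + 2.0 * k * x * L_M * v * v))
    return BoundaryState(u=u, rho_min=rho_min, G_in=G_in)


def boundary_state_arrays(params: ModelParams, L_M: np.ndarray,
                          A_M: np.ndarray | float = 0.0,
                          RT: np.ndarray | float | None = None):
    """Vectorized :func:`boundary_state` over dose arrays.

    ``RT`` optionally overrides the receptor density per element (used when a
    titration spans several bilayer densities).  Returns (u, rho_min, G_in).
    """
    require_special_case(params)
    k, x, e, q, r, S0s, sig = _coeffs(params, 0.0)
    L = np.asarray(L_M, dtype=float)
    A = np.asarray(A_M, dtype=float)
    RTv = params.RT_per_um2 if RT is None else np.asarray(RT, dtype=float)
    q = params.K2_um2 * params.pR * RTv
    S = 1.0 + params.KA_per_M * A + r * L
    with np.errstate(divide="ignore", invalid="ignore"):
        kap = q / S
        a = k * x * L * e * e * kap
        b = 2.0 * k * L * e * kap
        u = np.where(a > 0,
                     (-b + np.sqrt(b * b + 4.0 * a * sig)) / np.where(a > 0, 2.0 * a, 1.0),
                     np.where(b > 0, sig / np.where(b > 0, b, 1.0), np.inf))
        rho_min = u * (1.0 + 2.0 * k * L) + 2.0 * k * x * L * u * u
        v = e * u
        G_in = (v * (1.0 + 2.0 * k * L) + 2.0 * k * x * L * v * v
                + kap * (2.0 * k * L * v + 2.0 * k * x * L * v * v))
    bad = L <= 0
    if np.any(bad):
        u = np.where(bad, np.inf, u)
        rho_min = np.where(bad, np.inf, rho_min)
        G_in = np.where(bad, np.inf, G_in)
    return u, rho_min, G_in
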