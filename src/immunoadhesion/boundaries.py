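"""Adhesion boundaries: ligand windows, minimal epitope densities, phase
diagrams and IgG competition.

A cell adheres when, at vanishing contact fraction (theta -> 0+) and with no
nonspecific area, the bridging-bond density it can muster reaches sigma.
For a fixed epitope density this admits a window of ligand concentrations
[L_min, L_max]: below L_min too few ligands load the epitopes, above L_max
free ligand saturates both epitope arms and receptors, leaving too few
bridge-competent complexes.  For fixed L there is likewise a minimal epitope
density.  The boundary condition is evaluated at theta = 0, so capping of
theta inside the window never affects boundary locations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams, CellDose
from .equilibrium import _Network
from .species import free_receptor
from . import special_case

__all__ = [
    "AdhesionWindow", "PhaseBoundary", "boundary_margin", "adhesion_window",
    "minimal_epitope_density", "approx_L_bounds", "igg_effective_params",
    "phase_boundary_50pct", "inhibition_curve",
]

#: scan limits for ligand concentration (molar) and points per decade
_L_LO, _L_HI, _PTS_PER_DECADE = 1e-15, 1e-2, 60


@dataclass(frozen=True)
class AdhesionWindow:
    L_min: float
    L_max: float
    exists: bool

    def __contains__(self, L: float) -> bool:
        return self.exists and self.L_min <= L <= self.L_max


@dataclass
class PhaseBoundary:
    """Phase-diagram rows: mean epitope count vs bounding ligand doses."""
    mean_counts: np.ndarray
    L_lower: np.ndarray       # NaN where the criterion is never reached
    L_upper: np.ndarray
    criterion: str


def _boundary_fI(params: ModelParams, dose: CellDose) -> float:
    """Self-consistent immobile fraction at the theta = 0 boundary."""
    spec = params.immobility
    if not spec.has_feedback:
        return spec.value(0.0, 0.0)
    if spec.variant == "linear_in_theta":
        return spec.f0                      # theta = 0 at the boundary
    R_out = free_receptor(params, dose)

    def g(fI):
        net = _Network(params, dose, fI, R_out)
        u0 = net.boundary_u()
        st = net.state(u0, 0.0)
        return fI - spec.value(0.0, st.X)

    lo, glo = spec.f0, g(spec.f0)
    if glo >= 0:
        return spec.f0
    step = max(1e-4, -glo)
    hi = lo
    while hi < 1.0:
        hi = min(1.0, hi + step)
        if g(hi) >= 0:
            return brentq(g, lo, hi, xtol=1e-13, maxiter=200)
        lo, step = hi, step * 1.6
    return 1.0


def boundary_margin(params: ModelParams, rhoT: float, L_M: float,
                    A_M: float = 0.0) -> float:
    """B_in(theta -> 0+) - sigma; the cell adheres iff this is >= 0."""
    if rhoT <= 0 or L_M <= 0:
        return -params.sigma_per_um2
    dose = CellDose(rhoT, L_M, A_M)
    fI = _boundary_fI(params, dose)
    net = _Network(params, dose, fI, free_receptor(params, dose))
    return net.B(net.boundary_u()) - params.sigma_per_um2


def adhesion_window(params: ModelParams, rhoT: float,
                    A_M: float = 0.0) -> AdhesionWindow:
    """Ligand-concentration window of adhesion for a cell of density rhoT.

    Brackets the two sign changes of the boundary margin on a log-L scan
    (60 points per decade over [1e-15, 1e-2] M) and polishes each with
    bisection on log10 L.
    """
    none = AdhesionWindow(math.nan, math.nan, False)
    if rhoT <= 0:
        return none
    n = int(_PTS_PER_DECADE * math.log10(_L_HI / _L_LO)) + 1
    logL = np.linspace(math.log10(_L_LO), math.log10(_L_HI), n)

    if params.immobility.variant == "all_mobile" and math.isinf(params.beta):
        _, rho_min, _ = special_case.boundary_state_arrays(params, 10.0 ** logL, A_M)
        margins = rhoT - rho_min            # same sign as B(theta->0) - sigma
    else:
        margins = np.array([boundary_margin(params, rhoT, 10.0 ** x, A_M)
                            for x in logL])

    inside = margins >= 0
    if not inside.any():
        return none
    i0 = int(np.argmax(inside))
    i1 = n - 1 - int(np.argmax(inside[::-1]))

    def margin_log(x):
        return boundary_margin(params, rhoT, 10.0 ** x, A_M)

    if i0 == 0:
        L_min = _L_LO
    else:
        L_min = 10.0 ** brentq(margin_log, logL[i0 - 1], logL[i0], xtol=1e-12)
    if i1 == n - 1:
        L_max = _L_HI
    else:
        L_max = 10.0 ** brentq(margin_log, logL[i1], logL[i1 + 1], xtol=1e-12)
    return AdhesionWindow(L_min, L_max, True)


def minimal_epitope_density(params: ModelParams, L_M: float,
                            A_M: float = 0.0) -> float:
    """Smallest epitope density (um^-2) admitting adhesion at ligand dose L.

    Returns ``inf`` when no density admits adhesion ("unreachable").  In the
    fully mobile special case this equals the positive root of the boundary
    quadratic, computed in closed form.
    """
    if L_M <= 0:
        raise ValueError("L must be > 0")
    if params.immobility.variant == "all_mobile" and math.isinf(params.beta):
        bs = special_case.boundary_state(params, L_M, A_M)
        return bs.rho_min
    lo = None
    for rho in np.logspace(-4, 9, 53):
        if boundary_margin(params, rho, L_M, A_M) >= 0:
            hi = rho
            break
        lo = rho
    else:
        return math.inf
    if lo is None:
        return 0.0
    return brentq(lambda r: boundary_margin(params, r, L_M, A_M), lo, hi,
                  xtol=1e-12, rtol=1e-12, maxiter=200)


def approx_L_bounds(params: ModelParams, rhoT: float,
                    A_M: float = 0.0) -> AdhesionWindow:
    """Closed-form approximations for the window endpoints.

    Low-L limit (all bridging bonds from bivalently bound epitopes, free
    epitope density ~ rhoT):

        L_min ~ sigma * (1 + KA*A) / (K1 * Kx * K2 * pR * RT * pE^2 * rhoT^2)

    so L_min falls with the square of both the epitope density and the
    ligand-epitope constants, and nonspecific IgG multiplies it by
    (1 + KA*A).  High-L limit (every epitope-bound ligand bound singly, so
    the singly-bound bridge channel must supply sigma):

        sigma * (1 + KA*A + KR*L) * (1 + 2*K1*L) = 2*K1*L * K2*pE*pR*RT*rhoT

    whose larger root is L_max; to leading order L_max ~ K2*pE*pR*RT*rhoT /
    (sigma*KR), which is unchanged by IgG (the receptor loss cancels against
    the relaxed receptor saturation).
    """
    k, x = params.K1_per_M, params.Kx_um2
    q = params.K2_um2 * params.pR * params.RT_per_um2
    r = params.KR_per_M
    S0 = 1.0 + params.KA_per_M * A_M
    sig = params.sigma_per_um2
    L_min = sig * S0 / (k * x * q * params.pE ** 2 * rhoT ** 2)
    # sigma*(S0 + r*L)*(1 + 2kL) = 2kL*q*pE*rho  ->  a L^2 + b L + c = 0
    a = 2.0 * k * sig * r
    b = sig * (2.0 * k * S0 + r) - 2.0 * k * q * params.pE * rhoT
    c = sig * S0
    disc = b * b - 4.0 * a * c
    if disc >= 0 and b < 0:
        L_max = (-b + math.sqrt(disc)) / (2.0 * a)
    else:
        # arm-loading already saturated (2*K1*L >> 1): receptor competition
        # alone sets the top of the window
        sat = q * params.pE * rhoT / sig - S0
        L_max = sat / r if sat > 0 else math.nan
    exists = math.isfinite(L_max) and L_min <= L_max
    return AdhesionWindow(L_min, L_max, exists)


def igg_effective_params(params: ModelParams, A_M: float) -> ModelParams:
    """Map nonspecific IgG at concentration A onto effective receptor
    parameters with A = 0.

    Free receptor obeys R = RT / (1 + KR*L + KA*A); dividing through by
    (1 + KA*A) shows that RT_eff = RT/(1+KA*A) and KR_eff = KR/(1+KA*A) with
    no IgG reproduce the original model exactly (the model depends on KA and
    A only through this combination).
    """
    if A_M < 0:
        raise ValueError("A must be >= 0")
    fac = 1.0 + params.KA_per_M * A_M
    return params.replace(RT_per_um2=params.RT_per_um2 / fac,
                          KR_per_M=params.KR_per_M / fac)


def phase_boundary_50pct(params: ModelParams, dist, mean_counts,
                         A_M: float = 0.0, criterion: str = "population",
                         fraction: float = 0.5) -> PhaseBoundary:
    """Phase-diagram boundary in the (mean epitope count, L) plane.

    For each mean count the epitope distribution is rescaled (fixed shape)
    and the two log-L roots of ``fraction_bound = fraction`` are bisected.
    ``criterion='single_cell'`` instead returns the adhesion window of a
    cell carrying exactly the mean count.  Rows where the criterion is never
    met carry NaN bounds.
    """
    from .population import fraction_bound   # deferred: avoids import cycle

    mean_counts = np.asarray(mean_counts, dtype=float)
    lo = np.full(mean_counts.shape, math.nan)
    hi = np.full(mean_counts.shape, math.nan)
    for i, m in enumerate(mean_counts):
        if criterion == "single_cell":
            w = adhesion_window(params, m / params.Acell_um2, A_M)
            if w.exists:
                lo[i], hi[i] = w.L_min, w.L_max
            continue
        d = dist.rescaled_to_mean(m)

        def f(x):
            return fraction_bound(params, d, 10.0 ** x, A_M) - fraction

        n = int(_PTS_PER_DECADE // 10 * math.log10(_L_HI / _L_LO)) + 1
        logL = np.linspace(math.log10(_L_LO), math.log10(_L_HI), n)
        vals = np.array([f(x) for x in logL])
        inside = vals >= 0
        if not inside.any():
            continue
        i0 = int(np.argmax(inside))
        i1 = len(logL) - 1 - int(np.argmax(inside[::-1]))
        lo[i] = 10.0 ** (brentq(f, logL[i0 - 1], logL[i0], xtol=1e-10)
                         if i0 > 0 else logL[0])
        hi[i] = 10.0 ** (brentq(f, logL[i1], logL[i1 + 1], xtol=1e-10)
                         if i1 < len(logL) - 1 else logL[-1])
    return PhaseBoundary(mean_counts, lo, hi, criterion)


def inhibition_curve(params: ModelParams, dist, L_M: float, A_grid):
    """Fraction of cells bound vs nonspecific IgG concentration at fixed L."""
    from .population import fraction_bound
    A_grid = np.asarray(A_grid, dtype=float)
    return np.array([fraction_bound(params, dist, L_M, A) for A in A_grid])
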