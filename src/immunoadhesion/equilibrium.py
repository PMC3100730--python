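"""Solve the coupled equilibrium constraint equations for a single cell.

For a cell with total epitope density rhoT facing a bilayer at ligand
concentration L, the unknowns are the free mobile epitope density outside the
contact region (``M_out``), the free immobile densities outside and inside
(``I_out``, ``I_in``), the free receptor density (``R_out``) and the contact
fraction ``theta``; feedback immobility models add the immobile fraction
``f_I`` as a sixth unknown.  The five constraints are mobile-epitope
conservation (area-weighted across the two regions), immobile-epitope
conservation outside and inside, receptor conservation, and the
Bell-Dembo-Bongrand contact-area growth law

    theta * Acell = Ans + B_in * theta * Acell / sigma,

which on an adhered branch with Ans = 0 pins the bridging-bond density
B_in = sigma.

With a sparse-cell bilayer (beta = inf) the system reduces exactly: R_out is
explicit, I_out and I_in are explicit in M_out, the bridge equation
B(M_out) = sigma is monotone in M_out (one bracketed root), and mobile
conservation then yields theta in closed form.  The returned state always
satisfies the full residual vector (:func:`conservation_residuals`) to
better than 1e-9 in scaled units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .params import ModelParams, CellDose
from .species import (complex_densities, bridging_bond_density, free_receptor,
                      crosslinked_fraction_from_species, epitope_census)

__all__ = [
    "EquilibriumState", "SolveReport", "solve_equilibrium",
    "conservation_residuals", "divergence_threshold_fI", "crosslinked_fraction",
]

_XTOL = 1e-14
_RTOL = 1e-14


@dataclass
class EquilibriumState:
    """One cell's equilibrium at one ligand/IgG dose."""
    M_out: float
    I_out: float
    I_in: float
    R_out: float
    theta: float
    fI: float
    X: float
    B_in: float
    Ac: float                      # contact area, theta * Acell (um^2)
    complexes: dict = field(default_factory=dict)


@dataclass
class SolveReport:
    converged: bool
    capped: bool                   # theta forced to 1
    adhered: bool                  # positive-bridging solution exists at Ans=0
    residual_norm: float


class _Network:
    """Explicit reductions of the constraint system at fixed f_I and R_out.

    All methods are functions of the single remaining unknown u = M_out.
    """

    def __init__(self, params: ModelParams, dose: CellDose, fI: float, R_out: float):
        p = params
        self.p, self.dose, self.fI = p, dose, fI
        self.R_out = R_out
        L = dose.L_M
        self.rhoT = dose.rhoT_per_um2
        self.k2R = p.K2_um2 * p.pR * R_out        # receptor-loading factor inside
        self.a = 2.0 * p.K1_per_M * L             # first-arm factor
        self.kxl = p.K1_per_M * p.Kx_um2 * L      # cross-linking factor
        self.pE = p.pE

    # -- immobile closures (exactly the outside/inside immobile conservation)
    def I_out(self, u):
        return self.fI * self.rhoT / (1.0 + self.a * (1.0 + self.p.Kx_um2 * u))

    def I_in(self, u):
        v = self.pE * u
        return self.fI * self.rhoT / (
            1.0 + self.a * (1.0 + self.p.Kx_um2 * v) * (1.0 + self.k2R))

    # -- bridging-bond density B_in as a function of u
    def B(self, u):
        v = self.pE * u
        mob = self.a * v + self.kxl * v * v
        imm = self.I_in(u) * self.a * (1.0 + self.p.Kx_um2 * v)
        return self.k2R * (mob + imm)

    # -- mobile-epitope densities per unit area, outside / inside
    def G_out(self, u):
        lmi = 2.0 * self.kxl * u * self.I_out(u)
        return u * (1.0 + self.a) + 2.0 * self.kxl * u * u + lmi

    def G_in(self, u):
        v = self.pE * u
        lmi = 2.0 * self.kxl * v * self.I_in(u)
        free_and_bound = v * (1.0 + self.a) + 2.0 * self.kxl * v * v + lmi
        bridges = self.k2R * (self.a * v + 2.0 * self.kxl * v * v
                              + self.a * self.p.Kx_um2 * v * self.I_in(u))
        return free_and_bound + bridges

    def boundary_u(self):
        """Free mobile density at theta = 0 (outside conservation alone)."""
        target = (1.0 - self.fI) * self.rhoT
        if target <= 0:
            return 0.0
        return brentq(lambda u: self.G_out(u) - target, 0.0, target * (1 + 1e-12),
                      xtol=_XTOL, rtol=_RTOL, maxiter=200)

    def theta_of(self, u):
        """Contact fraction from mobile conservation (may exceed 1)."""
        go, gi = self.G_out(u), self.G_in(u)
        num = (1.0 - self.fI) * self.rhoT - go
        den = gi - go
        if den <= 0:
            return math.inf if num > 0 else 0.0
        return num / den

    def u_at_theta1(self):
        """Solve mobile conservation with the whole surface in contact."""
        target = (1.0 - self.fI) * self.rhoT
        if target <= 0:
            return 0.0
        return brentq(lambda u: self.G_in(u) - target, 0.0,
                      target / self.pE * (1 + 1e-9) + 1e-300,
                      xtol=_XTOL, rtol=_RTOL, maxiter=200)

    def X_of(self, u, theta):
        """Cross-linked epitope fraction without building the species map."""
        if self.rhoT <= 0:
            return 0.0
        v = self.pE * u
        out = self.kxl * u * u + 2.0 * self.kxl * u * self.I_out(u)
        inner = (1.0 + self.k2R) * (self.kxl * v * v
                                    + 2.0 * self.kxl * v * self.I_in(u))
        X = 2.0 * ((1.0 - theta) * out + theta * inner) / self.rhoT
        return min(1.0, X)

    def state(self, u, theta):
        p, dose = self.p, self.dose
        sp = complex_densities(u, self.I_out(u), self.I_in(u), self.R_out, p, dose)
        B = bridging_bond_density(sp)
        X = crosslinked_fraction_from_species(sp, theta, self.rhoT)
        return EquilibriumState(
            M_out=u, I_out=self.I_out(u), I_in=self.I_in(u), R_out=self.R_out,
            theta=theta, fI=self.fI, X=X, B_in=B, Ac=theta * p.Acell_um2,
            complexes=sp)


def divergence_threshold_fI(params: ModelParams, dose: CellDose) -> float:
    """Immobile fraction above which the contact area diverges.

    When immobile epitopes alone are dense enough to supply sigma bridging
    bonds, contact growth dilutes the mobile species without relieving the
    bond surplus.  Setting the receptor-ligand-immobile-epitope bridge
    density to sigma in the inside-immobile conservation (with the mobile
    species fully diluted) gives

        fI* = sigma * (1 + 2*K1*L + 2*K1*K2*L*R_in) / (2*K1*K2*L*R_in * rhoT)

    Returns ``inf`` ("unreachable") when the threshold exceeds 1 or the
    bridge pathway is absent (L = 0 or no receptors).
    """
    if params.sigma_per_um2 <= 0:
        raise ValueError("sigma must be > 0")
    L = dose.L_M
    R_in = params.pR * free_receptor(params, dose)
    drive = 2.0 * params.K1_per_M * params.K2_um2 * L * R_in
    if drive <= 0 or dose.rhoT_per_um2 <= 0:
        return math.inf
    fI = params.sigma_per_um2 * (1.0 + 2.0 * params.K1_per_M * L + drive) \
        / (drive * dose.rhoT_per_um2)
    return fI if fI <= 1.0 else math.inf


def _solve_core(params: ModelParams, dose: CellDose, fI: float, Ans: float,
                R_out: float) -> tuple[_Network, float, float, bool]:
    """Solve the five constraints at a known immobile fraction.

    Returns ``(network, u, theta, capped)`` without materializing the full
    species map.  ``Ans`` is passed explicitly so the adhesion decision
    (Ans = 0) and the realized-area solve (actual Ans) share one code path.
    """
    net = _Network(params, dose, fI, R_out)
    sig = params.sigma_per_um2

    if fI > 0 and fI >= divergence_threshold_fI(params, dose):
        return net, net.u_at_theta1(), 1.0, True

    u0 = net.boundary_u()
    B0 = net.B(u0)

    if Ans == 0.0:
        if B0 < sig:                      # no adhered branch: theta = 0
            return net, u0, 0.0, False
        if net.B(0.0) >= sig:             # immobile epitopes alone exceed sigma
            return net, net.u_at_theta1(), 1.0, True
        u = brentq(lambda x: net.B(x) - sig, 0.0, u0,
                   xtol=_XTOL, rtol=_RTOL, maxiter=200)
        theta = net.theta_of(u)
        if not (0.0 <= theta <= 1.0):
            return net, net.u_at_theta1(), 1.0, True
        return net, u, theta, False

    # Ans > 0: theta = (Ans/Acell) / (1 - B/sigma) from the growth law,
    # substituted into mobile conservation -> one equation in u.
    theta0 = Ans / params.Acell_um2

    def theta_growth(u):
        B = net.B(u)
        if B >= sig:
            return 1.0
        return min(1.0, theta0 / (1.0 - B / sig))

    def h(u):
        th = theta_growth(u)
        return (1.0 - th) * net.G_out(u) + th * net.G_in(u) \
            - (1.0 - fI) * net.rhoT

    if net.rhoT <= 0:
        return net, 0.0, min(1.0, theta0), False
    hi = (1.0 - fI) * net.rhoT / min(1.0, net.pE) + 1e-300
    if h(hi) < 0:                          # cannot place all epitopes: flatten
        return net, net.u_at_theta1(), 1.0, True
    u = brentq(h, 0.0, hi, xtol=_XTOL, rtol=_RTOL, maxiter=200)
    th = theta_growth(u)
    if th >= 1.0:
        return net, net.u_at_theta1(), 1.0, True
    return net, u, th, False


def _solve_fixed_fI(params: ModelParams, dose: CellDose, fI: float, Ans: float,
                    R_out: float) -> tuple[EquilibriumState, bool]:
    net, u, theta, capped = _solve_core(params, dose, fI, Ans, R_out)
    return net.state(u, theta), capped


_FI_GRID = np.logspace(-6, 0, 31)


def _solve_feedback(params: ModelParams, dose: CellDose, Ans: float,
                    R_out: float) -> tuple[EquilibriumState, bool]:
    """Self-consistent immobile fraction for the feedback variants.

    Enumerates sign changes of fI - (f0 + slope * y) on a log-spaced f_I
    grid starting from small values and returns the smallest root, matching
    the physical expectation that a cell begins with minimal immobility.
    """
    spec = params.immobility

    def g(fI):
        net, u, theta, _ = _solve_core(params, dose, fI, Ans, R_out)
        return fI - spec.value(theta, net.X_of(u, theta))

    def first_root(lo, hi):
        """Smallest root inside a sign-change bracket: brentq, then re-scan
        [lo, root) for an earlier crossing the coarse grid skipped."""
        root = brentq(g, lo, hi, xtol=1e-13, rtol=1e-13, maxiter=200)
        for _ in range(4):
            sub = np.linspace(lo, root, 12)[1:-1]
            earlier = None
            prev = lo
            for f in sub:
                if g(f) >= 0:
                    earlier = (prev, f)
                    break
                prev = f
            if earlier is None:
                return root
            root = brentq(g, *earlier, xtol=1e-13, rtol=1e-13, maxiter=200)
        return root

    lo = spec.f0
    glo = g(lo)
    if glo >= 0:
        fI = lo
    else:
        fI = None
        for hi in spec.f0 + (1.0 - spec.f0) * _FI_GRID:
            ghi = g(hi)
            if ghi >= 0:
                fI = first_root(lo, hi)
                break
            lo, glo = hi, ghi
        if fI is None:                     # no self-consistent point: flatten
            st, _ = _solve_fixed_fI(params, dose, spec.value(1.0, 1.0), Ans, R_out)
            return st, True
    st, capped = _solve_fixed_fI(params, dose, fI, Ans, R_out)
    return st, capped


def _solve_at_R(params: ModelParams, dose: CellDose, Ans: float,
                R_out: float) -> tuple[EquilibriumState, bool]:
    if params.immobility.has_feedback:
        return _solve_feedback(params, dose, Ans, R_out)
    fI = params.immobility.value(0.0, 0.0)   # constant models: theta-independent
    return _solve_fixed_fI(params, dose, fI, Ans, R_out)


def solve_equilibrium(params: ModelParams, dose: CellDose,
                      nonspecific: bool = True, check: bool = True
                      ) -> tuple[EquilibriumState, SolveReport]:
    """Equilibrium state of one cell, with a solve report.

    ``nonspecific=False`` forces Ans = 0; this is the configuration used for
    adhesion decisions, since nonspecific forces enlarge existing contacts
    but do not initiate them.  The ``adhered`` flag is always evaluated at
    Ans = 0 regardless: it is true iff a positive-contact branch with
    B_in = sigma exists there.  ``check=False`` skips the residual
    re-verification (used in population-integration hot loops; every code
    path it skips is property-tested directly).
    """
    Ans = params.Ans_um2 if nonspecific else 0.0
    R_out = free_receptor(params, dose)

    if math.isinf(params.beta):
        state, capped = _solve_at_R(params, dose, Ans, R_out)
    else:
        # finite bilayer reservoir: fixed-point iteration on R_out
        state, capped = _solve_at_R(params, dose, Ans, R_out)
        for _ in range(200):
            R_new = free_receptor(params, dose, theta=state.theta, B_in=state.B_in)
            if abs(R_new - R_out) <= 1e-13 * max(params.RT_per_um2, 1.0):
                break
            R_out = R_new
            state, capped = _solve_at_R(params, dose, Ans, R_out)
        else:
            res = conservation_residuals(state, params, dose)
            return state, SolveReport(False, capped, False,
                                      float(np.linalg.norm(res)))

    # adhesion decision at Ans = 0
    if Ans == 0.0:
        adhered = ((not capped) and state.theta > 0.0) or \
            (capped and state.B_in >= params.sigma_per_um2)
    else:
        st0, _ = _solve_at_R(params, dose, 0.0, R_out)
        adhered = st0.theta > 0.0 or st0.B_in >= params.sigma_per_um2

    if not check:
        return state, SolveReport(True, capped, bool(adhered), math.nan)
    res = conservation_residuals(state, params, dose, Ans=Ans)
    norm = float(np.linalg.norm(res))
    converged = norm < 1e-9 or capped      # a capped state breaks the growth law
    return state, SolveReport(converged, capped, bool(adhered), norm)


def conservation_residuals(state: EquilibriumState, params: ModelParams,
                           dose: CellDose, Ans: float | None = None) -> np.ndarray:
    """Scaled residual vector of the full constraint system.

    Entries (each divided by its conserved total so tolerances are
    comparable): mobile-epitope conservation, immobile conservation outside,
    immobile conservation inside, receptor balance, contact-area growth law;
    feedback immobility variants append the immobility self-consistency
    constraint.  A capped state (theta forced to 1) legitimately violates the
    growth-law entry; it is flagged through :class:`SolveReport`, not raised.
    """
    p = params
    if Ans is None:
        Ans = p.Ans_um2
    rhoT = dose.rhoT_per_um2
    sp = complex_densities(state.M_out, state.I_out, state.I_in, state.R_out,
                           p, dose)
    census = epitope_census(sp, state.theta)
    B = bridging_bond_density(sp)
    fI = state.fI
    scale_e = max(rhoT, 1e-300)

    r_mobile = (census["mobile_weighted"] - (1.0 - fI) * rhoT) / scale_e
    r_imm_out = (census["immobile_out"] - fI * rhoT) / scale_e
    r_imm_in = (census["immobile_in"] - fI * rhoT) / scale_e

    S = 1.0 + p.KR_per_M * dose.L_M + p.KA_per_M * dose.A_M
    if math.isinf(p.beta):
        r_receptor = (state.R_out * S - p.RT_per_um2) / p.RT_per_um2 \
            if p.RT_per_um2 > 0 else state.R_out
    else:
        frac = state.theta / p.beta
        lhs = state.R_out * S * (1.0 - frac * (1.0 - p.pR)) + frac * B
        r_receptor = (lhs - p.RT_per_um2) / max(p.RT_per_um2, 1e-300)

    if state.theta >= 1.0:
        r_growth = 0.0                      # capped: growth law suspended
    else:
        r_growth = (state.theta * p.Acell_um2 - Ans
                    - B * state.theta * p.Acell_um2 / p.sigma_per_um2) / p.Acell_um2

    res = [r_mobile, r_imm_out, r_imm_in, r_receptor, r_growth]
    if p.immobility.has_feedback:
        res.append(fI - p.immobility.value(state.theta, state.X))
    return np.asarray(res)


def crosslinked_fraction(state: EquilibriumState, params: ModelParams,
                         dose: CellDose) -> float:
    """Fraction of the cell's epitopes held in cross-linking ligands."""
    if dose.rhoT_per_um2 == 0:
        return 0.0
    sp = state.complexes or complex_densities(
        state.M_out, state.I_out, state.I_in, state.R_out, params, dose)
    return crosslinked_fraction_from_species(sp, state.theta, dose.rhoT_per_um2)
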