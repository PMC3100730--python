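"""Population layer: integrate single-cell solutions over epitope-count
heterogeneity.

Target-cell populations carry widely varying epitope counts; a Weibull
distribution (shape c, scale lambda, location fixed at 0) is the default
description, with a lognormal alternative and empirical (flow-cytometry
histogram) support.  The fraction of cells bound at a ligand dose is the
distribution mass above the minimal adhering count, and contact-area /
bond-count observables are conditional means over adhered cells only — at
doses where almost no cells adhere these conditional averages are dominated
by the distribution's upper tail.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special as sps
from scipy import stats, optimize

from .params import ModelParams, CellDose
from .equilibrium import solve_equilibrium
from .boundaries import minimal_epitope_density
from . import special_case

__all__ = [
    "EpitopeDistribution", "PopulationMeans", "fraction_bound",
    "conditional_means", "mean_contact_area", "mean_bond_count",
    "distribution_fit_flow", "FlowFitResult",
]


@dataclass(frozen=True)
class EpitopeDistribution:
    """Distribution of per-cell epitope counts.

    ``weibull``: shape ``c`` and scale in counts; mean = scale * Gamma(1+1/c)
    (shape 1 reduces to the exponential distribution).  ``lognormal``: shape
    ``s`` (log-space standard deviation) and scale exp(mu).  ``empirical``:
    piecewise-constant over histogram bins.
    """

    family: str
    shape: float = math.nan
    scale: float = math.nan
    gamma: float = 0.0                     # location; fixed 0 in fits
    bin_edges: tuple = ()
    bin_probs: tuple = ()

    # -- constructors -------------------------------------------------------
    @classmethod
    def weibull(cls, c: float, scale: float, gamma: float = 0.0):
        if c <= 0 or scale <= 0:
            raise ValueError("Weibull shape and scale must be > 0")
        return cls("weibull", shape=c, scale=scale, gamma=gamma)

    @classmethod
    def weibull_from_mean(cls, c: float, mean_count: float, gamma: float = 0.0):
        """Scale from mean via the Gamma-function mean formula."""
        scale = (mean_count - gamma) / math.gamma(1.0 + 1.0 / c)
        return cls.weibull(c, scale, gamma)

    @classmethod
    def lognormal(cls, s: float, mean_count: float):
        if s <= 0 or mean_count <= 0:
            raise ValueError("lognormal shape and mean must be > 0")
        scale = mean_count * math.exp(-0.5 * s * s)   # exp(mu)
        return cls("lognormal", shape=s, scale=scale)

    @classmethod
    def empirical(cls, centers, freqs):
        centers = np.asarray(centers, dtype=float)
        freqs = np.asarray(freqs, dtype=float)
        if centers.size == 0 or np.any(freqs < 0):
            raise ValueError("histogram must be nonempty with freqs >= 0")
        tot = freqs.sum()
        if tot <= 0:
            raise ValueError("all-zero histogram")
        if centers.size == 1:
            warnings.warn("single-bin histogram: degenerate distribution")
            w = max(centers[0] * 1e-6, 1e-6)
            edges = np.array([centers[0] - w / 2, centers[0] + w / 2])
            return cls("empirical", bin_edges=tuple(edges), bin_probs=(1.0,))
        order = np.argsort(centers)
        centers, freqs = centers[order], freqs[order]
        mids = 0.5 * (centers[1:] + centers[:-1])
        first = max(0.0, centers[0] - (mids[0] - centers[0]))
        last = centers[-1] + (centers[-1] - mids[-1])
        edges = np.concatenate([[first], mids, [last]])
        return cls("empirical", bin_edges=tuple(edges),
                   bin_probs=tuple(freqs / tot))

    # -- frozen scipy handle ------------------------------------------------
    def _frozen(self):
        if self.family == "weibull":
            return stats.weibull_min(self.shape, loc=self.gamma, scale=self.scale)
        if self.family == "lognormal":
            return stats.lognorm(self.shape, scale=self.scale)
        raise ValueError(f"no frozen form for family {self.family!r}")

    # -- basic functionals --------------------------------------------------
    @property
    def mean(self) -> float:
        if self.family == "empirical":
            e = np.asarray(self.bin_edges)
            p = np.asarray(self.bin_probs)
            return float(np.sum(p * 0.5 * (e[1:] + e[:-1])))
        return float(self._frozen().mean())

    def pdf(self, x):
        if self.family == "empirical":
            e = np.asarray(self.bin_edges)
            p = np.asarray(self.bin_probs)
            dens = p / np.diff(e)
            idx = np.clip(np.searchsorted(e, x, side="right") - 1, 0, len(p) - 1)
            out = np.where((np.asarray(x) >= e[0]) & (np.asarray(x) <= e[-1]),
                           dens[idx], 0.0)
            return out
        return self._frozen().pdf(x)

    def cdf(self, x):
        if self.family == "empirical":
            e = np.asarray(self.bin_edges)
            p = np.asarray(self.bin_probs)
            cum = np.concatenate([[0.0], np.cumsum(p)])
            return np.interp(x, e, cum)
        return self._frozen().cdf(x)

    def sf(self, x):
        if self.family == "empirical":
            return 1.0 - self.cdf(x)
        return self._frozen().sf(x)

    def ppf(self, q):
        if self.family == "empirical":
            e = np.asarray(self.bin_edges)
            cum = np.concatenate([[0.0], np.cumsum(self.bin_probs)])
            return np.interp(q, cum, e)
        return self._frozen().ppf(q)

    def isf(self, p):
        """Inverse survival function (accurate deep in the upper tail)."""
        if self.family == "empirical":
            return self.ppf(1.0 - np.asarray(p))
        return self._frozen().isf(p)

    def rvs(self, size, rng):
        return self.ppf(rng.uniform(size=size))

    def mean_above(self, m: float) -> float:
        """Conditional mean E[N | N > m] (closed form where available)."""
        if self.sf(m) <= 0:
            return math.nan
        if self.family == "weibull" and self.gamma == 0.0:
            t = (m / self.scale) ** self.shape
            a = 1.0 + 1.0 / self.shape
            return self.scale * math.gamma(a) * sps.gammaincc(a, t) / math.exp(-t)
        if self.family == "lognormal":
            mu, s = math.log(self.scale), self.shape
            z = (math.log(m) - mu) / s if m > 0 else -math.inf
            return (self.scale * math.exp(0.5 * s * s)
                    * stats.norm.sf(z - s) / stats.norm.sf(z))
        # empirical / shifted: integrate the piecewise form
        qs = np.linspace(self.cdf(m), 1.0, 4097)[1:-1]
        return float(np.mean(self.ppf(qs)))

    def rescaled_to_mean(self, mean_count: float) -> "EpitopeDistribution":
        """Same shape, rescaled to a new mean (fixed-shape convention)."""
        if self.family == "weibull":
            return EpitopeDistribution.weibull_from_mean(self.shape, mean_count,
                                                         self.gamma)
        if self.family == "lognormal":
            return EpitopeDistribution.lognormal(self.shape, mean_count)
        fac = mean_count / self.mean
        return EpitopeDistribution("empirical",
                                   bin_edges=tuple(fac * np.asarray(self.bin_edges)),
                                   bin_probs=self.bin_probs)


@dataclass(frozen=True)
class PopulationMeans:
    """Conditional population observables at one dose.

    ``mean_area_um2`` and ``mean_bonds`` are averages over adhered cells
    only; ``defined`` is False (and the means NaN) when no cell adheres, so
    conditional means can never be misread as zeros.
    """
    fraction_adhered: float
    mean_area_um2: float
    mean_bonds: float
    defined: bool


def fraction_bound(params: ModelParams, dist: EpitopeDistribution,
                   L_M: float, A_M: float = 0.0) -> float:
    """Fraction of the cell population bound to the bilayer."""
    rho_min = minimal_epitope_density(params, L_M, A_M)
    if not math.isfinite(rho_min):
        return 0.0
    return float(dist.sf(rho_min * params.Acell_um2))


def _fast_path_ok(params: ModelParams) -> bool:
    return (params.immobility.variant == "all_mobile"
            and params.Ans_um2 == 0.0 and math.isinf(params.beta))


def conditional_means(params: ModelParams, dist: EpitopeDistribution,
                      L_M: float, A_M: float = 0.0, n_quad: int = 32,
                      force_quadrature: bool = False,
                      adaptive: bool = True) -> PopulationMeans:
    """Fraction bound plus conditional mean contact area and bond count.

    Fully mobile case with Ans = 0: uses the adhered-mean identity — theta
    is linear in the cell's epitope density at pinned boundary composition,
    so the conditional means follow from E[N | N > N_min] in closed form.
    Otherwise integrates single-cell solutions by quadrature on the
    conditional quantile axis, doubling the rule until convergence.
    """
    rho_min = minimal_epitope_density(params, L_M, A_M)
    Acell = params.Acell_um2
    if not math.isfinite(rho_min):
        return PopulationMeans(0.0, math.nan, math.nan, False)
    frac = float(dist.sf(rho_min * Acell))
    if frac <= 0.0:
        return PopulationMeans(0.0, math.nan, math.nan, False)

    if _fast_path_ok(params) and not force_quadrature:
        bs = special_case.boundary_state(params, L_M, A_M)
        rho_bar = dist.mean_above(rho_min * Acell) / Acell
        theta_bar = min((rho_bar - bs.rho_min) / (bs.G_in - bs.rho_min), 1.0) \
            if bs.G_in > bs.rho_min else 1.0
        area = theta_bar * Acell
        return PopulationMeans(frac, area, params.sigma_per_um2 * area, True)

    # exponential-tail substitution: with t = -ln SF(N), the conditional
    # mean over adhered cells is  int_0^inf f(isf(e^-(t_lo+s))) e^-s ds,
    # evaluated by Gauss-Laguerre (weights sum to one, so the rule IS the
    # conditional expectation); smooth in s for all supported families.
    t_lo = -math.log(max(frac, 1e-300))

    def estimate(n):
        s, w = np.polynomial.laguerre.laggauss(n)
        a_tot = b_tot = 0.0
        for si, wi in zip(s, w):
            rho = float(dist.isf(math.exp(-(t_lo + si)))) / Acell
            st, _ = solve_equilibrium(params, CellDose(rho, L_M, A_M),
                                      check=False)
            a_tot += wi * st.Ac
            b_tot += wi * st.B_in * st.theta * Acell
        return a_tot, b_tot

    if not adaptive:
        a, b = estimate(n_quad)
        return PopulationMeans(frac, a, b, True)
    a_prev = b_prev = None
    for n in (n_quad, 2 * n_quad, 4 * n_quad):
        a, b = estimate(n)
        if a_prev is not None and abs(a - a_prev) <= 1e-8 * max(abs(a), 1e-12) \
                and abs(b - b_prev) <= 1e-8 * max(abs(b), 1e-12):
            break
        a_prev, b_prev = a, b
    else:
        warnings.warn("conditional-mean quadrature did not reach 1e-8; "
                      "returning the finest estimate")
    return PopulationMeans(frac, a, b, True)


def mean_contact_area(params, dist, L_M, A_M=0.0, **kw) -> PopulationMeans:
    """Average contact area over adhered cells (with the adhered fraction)."""
    return conditional_means(params, dist, L_M, A_M, **kw)


def mean_bond_count(params, dist, L_M, A_M=0.0, **kw) -> float:
    """Average bridging-bond count per adhered cell (NaN if none adhere)."""
    return conditional_means(params, dist, L_M, A_M, **kw).mean_bonds


# ---------------------------------------------------------------------------
# vectorized titration curves (the fitting work-horse)
# ---------------------------------------------------------------------------

def _weibull_sf(N, c, lam):
    return np.exp(-np.power(np.clip(N, 0, None) / lam, c))


def _weibull_mean_above(N, c, lam):
    t = np.power(np.clip(N, 0, None) / lam, c)
    a = 1.0 + 1.0 / c
    return lam * math.gamma(a) * sps.gammaincc(a, t) * np.exp(t)


def cell_observables(params: ModelParams, rho, L_M: float, A_M: float = 0.0):
    """Per-cell contact area and bond count for an array of epitope densities.

    Fully mobile cells with Ans = 0 use the pinned-boundary linearity of
    theta in rho; otherwise each cell is solved individually.
    """
    rho = np.asarray(rho, dtype=float)
    if _fast_path_ok(params):
        bs = special_case.boundary_state(params, L_M, A_M)
        if bs.G_in > bs.rho_min:
            theta = np.clip((rho - bs.rho_min) / (bs.G_in - bs.rho_min), 0.0, 1.0)
        else:
            theta = np.where(rho >= bs.rho_min, 1.0, 0.0)
        area = theta * params.Acell_um2
        return area, params.sigma_per_um2 * area
    area = np.empty(rho.shape)
    bonds = np.empty(rho.shape)
    for i, r in np.ndenumerate(rho):
        st, _ = solve_equilibrium(params, CellDose(float(r), L_M, A_M),
                                  check=False)
        area[i] = st.Ac
        bonds[i] = st.B_in * st.theta * params.Acell_um2
    return area, bonds


def _ans_conditional_means(params, c, lam, L, A, RTv, rho_min, frac, n_quad):
    """Conditional means for mobile cells with a nonspecific area offset.

    Adhesion is still decided at Ans = 0 (cells above rho_min), but each
    adhered cell's realized contact obeys theta*(1 - B/sigma) = Ans/Acell,
    solved jointly with mobile conservation by vectorized bisection on the
    free mobile density u over a (dose x quadrature-node) grid.
    """
    k = params.K1_per_M
    x = params.Kx_um2
    e = params.pE
    sig = params.sigma_per_um2
    Acell = params.Acell_um2
    theta0 = params.Ans_um2 / Acell

    S = 1.0 + params.KR_per_M * L + params.KA_per_M * A
    kap = params.K2_um2 * params.pR * RTv / S            # per dose
    s_nodes, w_nodes = np.polynomial.laguerre.laggauss(max(n_quad, 8))
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t_lo = np.power(rho_min * Acell / lam, c)
        t = t_lo[:, None] + s_nodes[None, :]
        rho = lam * np.power(t, 1.0 / c) / Acell          # (dose, node)

    a2 = (k * x * L * e * e * kap)[:, None]
    b2 = (2.0 * k * L * e * kap)[:, None]
    one_arm = (1.0 + 2.0 * k * L)[:, None]
    cross = (2.0 * k * x * L)[:, None]
    kapc = kap[:, None]

    def h(u):
        B = np.minimum(a2 * u * u + b2 * u, sig * (1.0 - 1e-14))
        theta = np.minimum(theta0 / (1.0 - B / sig), 1.0)
        v = e * u
        G_out = u * one_arm + cross * u * u
        # G_in = v(1+2kL) + 2kxLv^2(1+kap) + kap*2kLv
        G_in = v * one_arm + cross * v * v * (1.0 + kapc) \
            + kapc * (one_arm - 1.0) * v
        return (1.0 - theta) * G_out + theta * G_in - rho, B, theta

    # bracket: u below the bond-balance boundary root (B < sigma there)
    with np.errstate(divide="ignore", invalid="ignore"):
        u_sig = (-b2 + np.sqrt(b2 * b2 + 4.0 * a2 * sig)) / (2.0 * a2)
    hi = np.broadcast_to(u_sig * (1.0 - 1e-13), rho.shape).copy()
    lo = np.zeros_like(hi)
    h_hi, _, _ = h(hi)
    capped = h_hi < 0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        val, _, _ = h(mid)
        take = val < 0
        lo = np.where(take, mid, lo)
        hi = np.where(take, hi, mid)
    u = 0.5 * (lo + hi)
    _, B, theta = h(u)

    if np.any(capped):
        # whole surface in contact: G_in(v) = rho, a quadratic in v
        qa = cross * (1.0 + kapc)
        qb = one_arm + kapc * (one_arm - 1.0)
        v = (-qb + np.sqrt(qb * qb + 4.0 * qa * rho)) / (2.0 * qa)
        u_cap = v / e
        B_cap = a2 * u_cap ** 2 + b2 * u_cap
        theta = np.where(capped, 1.0, theta)
        B = np.where(capped, B_cap, B)

    area_cells = theta * Acell
    bond_cells = B * theta * Acell
    area = area_cells @ w_nodes
    bonds = bond_cells @ w_nodes
    return area, bonds


def titration_curves(params: ModelParams, dist: EpitopeDistribution,
                     L_M, RT=None, A_M=0.0, n_quad: int = 24):
    """Model observables over arrays of doses: (fraction, mean area, bonds).

    ``RT`` optionally varies the bilayer receptor density per element.
    Conditional means are NaN wherever the model predicts zero adhesion.
    Fully mobile parameters with Ans = 0 evaluate in closed vectorized form;
    anything else falls back to per-dose conditional means.
    """
    L = np.atleast_1d(np.asarray(L_M, dtype=float))
    A = np.broadcast_to(np.asarray(A_M, dtype=float), L.shape)
    RTv = np.broadcast_to(np.asarray(
        params.RT_per_um2 if RT is None else RT, dtype=float), L.shape)
    Acell = params.Acell_um2

    all_mobile = (params.immobility.variant == "all_mobile"
                  and math.isinf(params.beta))
    if all_mobile and dist.family == "weibull" and dist.gamma == 0:
        c, lam = dist.shape, dist.scale
        u, rho_min, G_in = special_case.boundary_state_arrays(params, L, A, RTv)
        N_min = rho_min * Acell
        frac = np.where(np.isfinite(N_min), _weibull_sf(N_min, c, lam), 0.0)
        if params.Ans_um2 == 0.0:
            with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
                rho_bar = _weibull_mean_above(N_min, c, lam) / Acell
                theta = np.clip((rho_bar - rho_min) / (G_in - rho_min), 0.0, 1.0)
                theta = np.where(G_in > rho_min, theta,
                                 np.where(frac > 0, 1.0, np.nan))
            area = theta * Acell
            bonds = params.sigma_per_um2 * area
        else:
            area, bonds = _ans_conditional_means(
                params, c, lam, L, A, RTv, rho_min, frac, n_quad)
        area = np.where(frac > 0, area, np.nan)
        bonds = np.where(frac > 0, bonds, np.nan)
        return frac, area, bonds

    frac = np.empty(L.shape)
    area = np.empty(L.shape)
    bonds = np.empty(L.shape)
    for i in range(L.size):
        pm = params if RTv[i] == params.RT_per_um2 \
            else params.replace(RT_per_um2=float(RTv[i]))
        cm = conditional_means(pm, dist, float(L[i]), float(A[i]),
                               n_quad=n_quad, adaptive=False)
        frac[i] = cm.fraction_adhered
        area[i] = cm.mean_area_um2
        bonds[i] = cm.mean_bonds
    return frac, area, bonds


# ---------------------------------------------------------------------------
# flow-cytometry histogram fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FlowFitResult:
    empirical: EpitopeDistribution
    weibull: EpitopeDistribution
    lognormal: EpitopeDistribution
    mean_count: float


def _binned_nll(dist: EpitopeDistribution, edges, weights) -> float:
    p = np.diff(dist.cdf(edges))
    p = np.clip(p, 1e-300, None)
    return -float(np.sum(weights * np.log(p)))


def distribution_fit_flow(centers, freqs) -> FlowFitResult:
    """Fit Weibull and lognormal forms to a flow-cytometry count histogram.

    Maximum likelihood on the binned data (multinomial over bin masses),
    alongside the empirical piecewise-constant distribution and its mean.
    """
    emp = EpitopeDistribution.empirical(centers, freqs)
    edges = np.asarray(emp.bin_edges)
    weights = np.asarray(emp.bin_probs)
    mean = emp.mean

    def fit(maker, x0):
        res = optimize.minimize(
            lambda t: _binned_nll(maker(math.exp(t[0]), math.exp(t[1])),
                                  edges, weights),
            x0=np.log(x0), method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
        return maker(math.exp(res.x[0]), math.exp(res.x[1]))

    wb = fit(lambda c, m: EpitopeDistribution.weibull_from_mean(c, m),
             [1.5, mean])
    # moment seed for the log-sd
    mids = 0.5 * (edges[1:] + edges[:-1])
    lv = np.sqrt(max(np.sum(weights * (np.log(np.clip(mids, 1e-9, None))
                                       - np.log(mean)) ** 2), 1e-4))
    ln = fit(lambda s, m: EpitopeDistribution.lognormal(s, m), [lv, mean])
    return FlowFitResult(emp, wb, ln, mean)
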