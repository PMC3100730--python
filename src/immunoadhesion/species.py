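"""Mass-action species laws for the adhesion reaction network.

The network couples a bivalent ligand L (two epitope-binding arms, one Fc) to
mobile epitopes M and immobile epitopes I on the target cell and to mobile
receptors R on the bilayer.  Species labels follow the grammar
``<region>.<composition>`` with region ``out`` / ``in`` (outside / inside the
contact region) and composition letters R, L, M, I, e.g. ``in.RLMM`` is a
bridging complex of one receptor, one ligand and two mobile epitopes.

Statistical factors: the first arm of a free ligand binds an epitope with
rate-constant factor 2 (two equivalent arms), so [LM] = 2*K1*[L]*[M]; the
second arm of a membrane-bound ligand cross-links another epitope with 2D
constant Kx, and the symmetry factor 1/2 for two identical bound epitopes
cancels the factor 2, giving [LMM] = K1*Kx*[L]*[M]^2.  Mixed complexes keep
the factor 2: [LMI] = 2*K1*Kx*[L]*[M]*[I].  A ligand never cross-links two
immobile epitopes (their typical spacing exceeds the ~10 nm arm span).
Composite constants for any other construction order follow from detailed
balance, e.g. the constant for RL + M -> RLM is 2*K1*K2/KR, so every species
density is path-independent.
"""

from __future__ import annotations

import math

import numpy as np

from .params import ModelParams, CellDose, ImmobilitySpec

__all__ = [
    "SPECIES_OUT", "SPECIES_IN", "BRIDGING_SPECIES",
    "complex_densities", "bridging_bond_density", "free_receptor",
    "immobile_fraction", "crosslinked_fraction_from_species",
    "nearest_neighbor_prob", "estimate_Kx_from_scatchard", "scatchard_K_app",
]

SPECIES_OUT = ("M", "I", "LM", "LI", "LMM", "LMI", "R", "RL", "RA")
SPECIES_IN = SPECIES_OUT + ("RLM", "RLMM", "RLMI", "RLI")
#: receptor-containing, epitope-bound complexes that physically bridge the
#: cell to the bilayer (exist only inside the contact region)
BRIDGING_SPECIES = ("in.RLM", "in.RLMM", "in.RLMI", "in.RLI")

#: epitopes contributed per complex, split by mobility
_MOBILE_COUNT = {"M": 1, "LM": 1, "LMM": 2, "LMI": 1, "RLM": 1, "RLMM": 2, "RLMI": 1}
_IMMOBILE_COUNT = {"I": 1, "LI": 1, "LMI": 1, "RLI": 1, "RLMI": 1}
#: epitopes residing in doubly-epitope-bound (cross-linking) ligands
_CROSSLINKED_COUNT = {"LMM": 2, "LMI": 2, "RLMM": 2, "RLMI": 2}


def complex_densities(M_out: float, I_out: float, I_in: float, R_out: float,
                      params: ModelParams, dose: CellDose) -> dict[str, float]:
    """All species densities (um^-2) from the free densities by mass action.

    Inside-region free mobile species are the partitioned outside ones
    (M_in = pE*M_out, R_in = pR*R_out); the free immobile density inside,
    I_in, is an independent unknown because immobile epitopes cannot
    redistribute.

    Raises ``ValueError`` on negative free densities.
    """
    if min(M_out, I_out, I_in, R_out) < 0:
        raise ValueError("free species densities must be >= 0")
    K1, Kx, K2 = params.K1_per_M, params.Kx_um2, params.K2_um2
    KR, KA = params.KR_per_M, params.KA_per_M
    L, A = dose.L_M, dose.A_M

    out = _cell_side(M_out, I_out, K1, Kx, L)
    M_in = params.pE * M_out
    R_in = params.pR * R_out
    inner = _cell_side(M_in, I_in, K1, Kx, L)

    sp = {}
    for k, v in out.items():
        sp[f"out.{k}"] = v
    sp["out.R"] = R_out
    sp["out.RL"] = KR * L * R_out
    sp["out.RA"] = KA * A * R_out
    for k, v in inner.items():
        sp[f"in.{k}"] = v
    sp["in.R"] = R_in
    sp["in.RL"] = KR * L * R_in
    sp["in.RA"] = KA * A * R_in
    # bridges: an epitope-bound ligand's Fc binds a receptor with K2
    for epi_sp in ("LM", "LMM", "LMI", "LI"):
        sp["in.R" + epi_sp] = K2 * R_in * inner[epi_sp]
    return sp


def _cell_side(M: float, I: float, K1: float, Kx: float, L: float) -> dict[str, float]:
    return {
        "M": M,
        "I": I,
        "LM": 2.0 * K1 * L * M,
        "LI": 2.0 * K1 * L * I,
        "LMM": K1 * Kx * L * M * M,
        "LMI": 2.0 * K1 * Kx * L * M * I,
    }


def bridging_bond_density(species: dict[str, float]) -> float:
    """Total bridging-bond density B_in (um^-2) inside the contact region."""
    total = 0.0
    for name in BRIDGING_SPECIES:
        v = species.get(name, 0.0)
        if v < 0:
            raise ValueError(f"negative density for {name}")
        total += v
    return total


def free_receptor(params: ModelParams, dose: CellDose,
                  theta: float = 0.0, B_in: float = 0.0) -> float:
    """Free bilayer receptor density outside the contact region (um^-2).

    With sparsely adhered cells (beta = inf) receptor conservation gives the
    explicit form R = RT / (1 + KR*L + KA*A).  For finite beta the bridges and
    the partition deficit inside the contact region deplete the reservoir:

        R = (RT - (theta/beta) * B_in)
            / (S * (1 - (theta/beta) * (1 - pR)))      with S = 1 + KR*L + KA*A
    """
    if dose.L_M < 0 or dose.A_M < 0:
        raise ValueError("concentrations must be >= 0")
    S = 1.0 + params.KR_per_M * dose.L_M + params.KA_per_M * dose.A_M
    if math.isinf(params.beta):
        return params.RT_per_um2 / S
    frac = theta / params.beta
    return (params.RT_per_um2 - frac * B_in) / (S * (1.0 - frac * (1.0 - params.pR)))


def immobile_fraction(spec: ImmobilitySpec, theta: float, X: float) -> float:
    """Realized immobile fraction for one immobility model (clamped to [0,1])."""
    return spec.value(theta, X)


def crosslinked_fraction_from_species(species: dict[str, float], theta: float,
                                      rhoT: float) -> float:
    """Fraction X of all epitopes held in doubly-epitope-bound ligands.

    Each cross-linking ligand contributes its two epitopes; densities are
    area-weighted across the outside ((1-theta)) and inside (theta) regions.
    Defined as 0 when the cell carries no epitopes.
    """
    if rhoT == 0:
        return 0.0
    tot = 0.0
    for comp, n in _CROSSLINKED_COUNT.items():
        tot += (1.0 - theta) * n * species.get(f"out.{comp}", 0.0)
        tot += theta * n * species.get(f"in.{comp}", 0.0)
    return min(1.0, tot / rhoT)


def epitope_census(species: dict[str, float], theta: float) -> dict[str, float]:
    """Area-weighted epitope bookkeeping used by the conservation laws.

    Returns mobile epitopes (area-weighted across regions), and immobile
    epitopes per unit area outside and inside the contact region.
    """
    mob_out = sum(n * species[f"out.{c}"] for c, n in _MOBILE_COUNT.items()
                  if f"out.{c}" in species)
    mob_in = sum(n * species[f"in.{c}"] for c, n in _MOBILE_COUNT.items()
                 if f"in.{c}" in species)
    imm_out = sum(n * species[f"out.{c}"] for c, n in _IMMOBILE_COUNT.items()
                  if f"out.{c}" in species)
    imm_in = sum(n * species[f"in.{c}"] for c, n in _IMMOBILE_COUNT.items()
                 if f"in.{c}" in species)
    return {
        "mobile_weighted": (1.0 - theta) * mob_out + theta * mob_in,
        "immobile_out": imm_out,
        "immobile_in": imm_in,
    }


def nearest_neighbor_prob(rho, r):
    """P(nearest neighbor within distance r) for a 2D Poisson point field.

    P = 1 - exp(-pi * rho * r^2); rho in um^-2, r in um.  This bounds how
    often two immobile epitopes could fall within a ligand's ~10 nm arm span.
    """
    rho = np.asarray(rho, dtype=float)
    r = np.asarray(r, dtype=float)
    if np.any(rho < 0) or np.any(r < 0):
        raise ValueError("rho and r must be >= 0")
    out = -np.expm1(-math.pi * rho * r * r)
    return float(out) if out.ndim == 0 else out


def scatchard_K_app(K1: float, Kx: float, rhoT: float) -> float:
    """Apparent dissociation constant (M) from the Scatchard initial slope.

    For a bivalent ligand titrated against a cell with epitope density rhoT,
    the Scatchard plot (bound/free vs bound) has initial slope

        -1/K_app = 4*K1*(1 + Kx*rhoT)^2 / (2 + Kx*rhoT)
    """
    if min(K1, Kx, rhoT) <= 0:
        raise ValueError("K1, Kx and rhoT must be > 0")
    z = Kx * rhoT
    return (2.0 + z) / (4.0 * K1 * (1.0 + z) ** 2)


def estimate_Kx_from_scatchard(K_app_M: float, NT: float, Acell_um2: float,
                               K1_per_M: float) -> float:
    """Invert the Scatchard initial-slope relation for the 2D cross-linking
    constant Kx (um^2).

    Given the measured apparent dissociation constant ``K_app_M`` of the
    bivalent ligand for whole cells carrying ``NT`` epitopes on area
    ``Acell_um2``, solve  4*K1*(1+z)^2/(2+z) = 1/K_app  for z = Kx*rhoT.
    """
    if min(K_app_M, NT, Acell_um2, K1_per_M) <= 0:
        raise ValueError("all inputs must be > 0")
    rho = NT / Acell_um2
    g = 1.0 / (4.0 * K1_per_M * K_app_M)   # target value of (1+z)^2/(2+z)
    # (1+z)^2 = g*(2+z)  ->  z^2 + (2-g) z + (1-2g) = 0
    disc = (2.0 - g) ** 2 - 4.0 * (1.0 - 2.0 * g)
    if disc < 0:
        raise ValueError("inconsistent inputs: no real cross-linking constant")
    z = (-(2.0 - g) + math.sqrt(disc)) / 2.0
    if z <= 0:
        raise ValueError(
            "inconsistent inputs: implied Kx <= 0 (apparent affinity is weaker "
            "than the single-site limit 1/(2*K1))"
        )
    return z / rho
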