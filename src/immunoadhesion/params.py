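"""Model parameters for immunoadhesin-mediated cell-bilayer adhesion.

Units convention used throughout the package:

* bulk concentrations (ligand ``L``, nonspecific IgG ``A``) in molar;
* solution association constants (``K1``, ``KR``, ``KA``) in 1/M;
* surface densities in molecules/um^2;
* two-dimensional association constants (``Kx``, ``K2``) in um^2;
* areas (``Acell``, ``Ans``) in um^2.

The bivalent ligand (an IgG-scaffold molecule such as the immunoadhesin
alefacept) binds target-cell epitopes (CD2) through its two arms with
single-site constant ``K1`` and cross-linking constant ``Kx``, and bilayer Fc
receptors (Fc-gamma-RIIIb) through its Fc with 2D constant ``K2`` once
membrane-bound, or ``KR`` from solution.  ``sigma`` is the bridging-bond
density that balances the repulsive pressure between cell and bilayer and sets
the linear contact-area growth law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import yaml

__all__ = [
    "ImmobilitySpec",
    "ModelParams",
    "CellDose",
    "reference_fixed_params",
    "best_fit_params",
    "BEST_FIT",
    "load_params",
    "dump_params",
]

_VARIANTS = ("all_mobile", "constant", "linear_in_theta", "linear_in_X")


@dataclass(frozen=True)
class ImmobilitySpec:
    """How the immobile epitope fraction f_I behaves.

    ``all_mobile``      -> f_I = 0
    ``constant``        -> f_I = f0
    ``linear_in_theta`` -> f_I = f0 + slope * theta   (theta = contact fraction)
    ``linear_in_X``     -> f_I = f0 + slope * X       (X = cross-linked fraction)

    Results are clamped to [0, 1].  The baseline f0 = 0.13 is the measured
    immobile CD2 fraction on resting Jurkat cells in the absence of ligand.
    """

    variant: str = "all_mobile"
    f0: float = 0.0
    slope: float = 0.0

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(
                f"unknown immobility variant {self.variant!r}; expected one of {_VARIANTS}"
            )
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError(f"f0 must be in [0,1], got {self.f0}")
        if self.slope < 0:
            raise ValueError(f"slope must be >= 0, got {self.slope}")
        if self.variant == "all_mobile" and (self.f0 != 0.0 or self.slope != 0.0):
            raise ValueError("all_mobile requires f0 = slope = 0")

    @property
    def has_feedback(self) -> bool:
        return self.variant in ("linear_in_theta", "linear_in_X")

    def value(self, theta: float, X: float) -> float:
        """Realized immobile fraction at contact fraction theta and
        cross-linked fraction X, clamped to [0, 1]."""
        if not (0.0 <= theta <= 1.0 and 0.0 <= X <= 1.0):
            raise ValueError("theta and X must be in [0,1]")
        if self.variant == "all_mobile":
            return 0.0
        if self.variant == "constant":
            return self.f0
        if self.variant == "linear_in_theta":
            raw = self.f0 + self.slope * theta
        else:
            raw = self.f0 + self.slope * X
        return min(1.0, max(0.0, raw))


@dataclass(frozen=True)
class ModelParams:
    """All equilibrium, geometric and mechanical parameters of the model."""

    K1_per_M: float            # ligand arm <-> epitope, single site (1/M)
    Kx_um2: float              # membrane-bound arm <-> second epitope (um^2)
    K2_um2: float              # epitope-bound ligand Fc <-> receptor (um^2)
    KR_per_M: float            # solution ligand <-> receptor (1/M)
    KA_per_M: float            # solution nonspecific IgG <-> receptor (1/M)
    pE: float = 0.75           # epitope partition coefficient into contact
    pR: float = 0.75           # receptor partition coefficient into contact
    sigma_per_um2: float = 204.0   # bridging-bond density balancing repulsion
    Ans_um2: float = 0.0       # nonspecific contact area
    Acell_um2: float = 800.0   # target-cell surface area
    RT_per_um2: float = 1200.0  # total bilayer receptor density
    beta: float = math.inf     # bilayer area per cell / cell area
    immobility: ImmobilitySpec = field(default_factory=ImmobilitySpec)

    def __post_init__(self) -> None:
        for name in ("K1_per_M", "Kx_um2", "K2_um2", "KR_per_M", "KA_per_M",
                     "Ans_um2", "RT_per_um2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 < self.pE <= 1.0 and 0.0 < self.pR <= 1.0):
            raise ValueError("partition coefficients must lie in (0, 1]")
        if self.sigma_per_um2 <= 0:
            raise ValueError("sigma_per_um2 must be > 0")
        if self.Acell_um2 <= 0:
            raise ValueError("Acell_um2 must be > 0")
        if not (self.beta > 0):
            raise ValueError("beta must be > 0 (use math.inf for a sparse-cell bilayer)")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class CellDose:
    """Per-cell epitope content and the bulk solution composition.

    Ligand and nonspecific antibody are negligibly depleted, so their free
    bulk concentrations equal the total ones.
    """

    rhoT_per_um2: float        # cell-average total epitope density
    L_M: float                 # bulk ligand concentration (molar)
    A_M: float = 0.0           # bulk nonspecific IgG concentration (molar)

    def __post_init__(self) -> None:
        if self.rhoT_per_um2 < 0 or self.L_M < 0 or self.A_M < 0:
            raise ValueError("densities and concentrations must be >= 0")

    @classmethod
    def from_count(cls, NT: float, params: ModelParams, L_M: float,
                   A_M: float = 0.0) -> "CellDose":
        return cls(rhoT_per_um2=NT / params.Acell_um2, L_M=L_M, A_M=A_M)

    def NT(self, params: ModelParams) -> float:
        return self.rhoT_per_um2 * params.Acell_um2


# ---------------------------------------------------------------------------
# Reference parameter sets for the alefacept / CD2 / Fc-gamma-RIIIb system.
#
# Fixed physical parameters: cell area 800 um^2 (64,000 CD2 epitopes at an
# initial density of 80 um^-2), partition coefficients 0.75, single-site
# CD58-CD2 constant K1 = 1e5 /M (Kd = 10 uM), and the cross-linking constant
# Kx = 31.25 um^2 obtained by inverting the Scatchard initial-slope relation
# at an apparent cellular affinity of 1 nM (the initial slope pins the
# product K1*Kx*rho0, so K_app and K1 together fix Kx).  The remaining parameters are
# best-fit values per immobility variant (sigma, K2, KR, Ans, slope, and the
# Weibull shape/mean reported alongside in BEST_FIT).
# ---------------------------------------------------------------------------

_FIXED = dict(
    K1_per_M=1.0e5,
    Kx_um2=31.25,
    pE=0.75,
    pR=0.75,
    Acell_um2=800.0,
)

# variant -> (sigma, K2, KR, Ans, f0, slope, weibull_c, NT_mean)
BEST_FIT = {
    "all_mobile":      dict(sigma=204.0, K2=0.6, KR=4.1e6, Ans=0.0,
                            f0=0.0, slope=0.0, c=1.5, NT_mean=5200.0),
    "constant":        dict(sigma=204.0, K2=0.6, KR=4.3e6, Ans=0.0,
                            f0=0.0, slope=0.0, c=1.5, NT_mean=5200.0),
    "linear_in_X":     dict(sigma=201.0, K2=0.5, KR=3.6e6, Ans=0.0,
                            f0=0.13, slope=0.0, c=1.6, NT_mean=6100.0),
    "linear_in_theta": dict(sigma=203.0, K2=0.4, KR=4.2e5, Ans=0.0,
                            f0=0.13, slope=23.0, c=1.2, NT_mean=17000.0),
}


def reference_fixed_params() -> dict:
    """The fixed (non-fitted) physical parameters of the reference system."""
    return dict(_FIXED)


def best_fit_params(variant: str = "all_mobile", RT_per_um2: float = 1200.0) -> ModelParams:
    """Best-fit :class:`ModelParams` for one immobility-model variant.

    The nonspecific IgG constant KA is set equal to KR: in the reference
    system both the ligand's Fc and the competing IgG present the same human
    IgG1 Fc to the same receptor.
    """
    if variant not in BEST_FIT:
        raise ValueError(f"unknown variant {variant!r}")
    b = BEST_FIT[variant]
    imm = ImmobilitySpec(variant=variant, f0=b["f0"], slope=b["slope"])
    return ModelParams(
        K2_um2=b["K2"], KR_per_M=b["KR"], KA_per_M=b["KR"],
        sigma_per_um2=b["sigma"], Ans_um2=b["Ans"],
        RT_per_um2=RT_per_um2, immobility=imm, **_FIXED,
    )


# ---------------------------------------------------------------------------
# Config file I/O (strict YAML schema; keys carry explicit units)
# ---------------------------------------------------------------------------

_PARAM_KEYS = {
    "K1_per_M", "Kx_um2", "K2_um2", "KR_per_M", "KA_per_M", "pE", "pR",
    "sigma_per_um2", "Ans_um2", "Acell_um2", "RT_per_um2", "beta", "immobility",
}
_IMM_KEYS = {"variant", "f0", "slope"}


def load_params(path) -> ModelParams:
    """Load :class:`ModelParams` from a YAML config with unit-annotated keys."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path}: expected a mapping at top level")
    unknown = set(raw) - _PARAM_KEYS
    if unknown:
        raise ValueError(f"config {path}: unknown keys {sorted(unknown)}")
    imm_raw = raw.pop("immobility", None)
    if imm_raw is not None:
        bad = set(imm_raw) - _IMM_KEYS
        if bad:
            raise ValueError(f"config {path}: unknown immobility keys {sorted(bad)}")
        raw["immobility"] = ImmobilitySpec(**imm_raw)
    if isinstance(raw.get("beta"), str):
        raw["beta"] = float(raw["beta"].lstrip("."))
    return ModelParams(**raw)


def dump_params(params: ModelParams, path) -> None:
    d = asdict(params)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)   # inf serializes as .inf
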