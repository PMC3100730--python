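import math

import numpy as np
import pytest

from immunoadhesion import (ModelParams, ImmobilitySpec, CellDose,
                            best_fit_params, EpitopeDistribution)


@pytest.fixture
def all_mobile_params() -> ModelParams:
    return best_fit_params("all_mobile")


@pytest.fixture
def theta_feedback_params() -> ModelParams:
    return best_fit_params("linear_in_theta")


@pytest.fixture
def weibull_dist() -> EpitopeDistribution:
    return EpitopeDistribution.weibull_from_mean(1.5, 5200.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260923)


def random_params(rng, variant="all_mobile") -> ModelParams:
    """Physically plausible random parameter draw for property tests."""
    if variant == "constant":
        imm = ImmobilitySpec("constant", f0=float(rng.uniform(0.0, 0.5)))
    elif variant in ("linear_in_theta", "linear_in_X"):
        imm = ImmobilitySpec(variant, f0=float(rng.uniform(0.0, 0.3)),
                             slope=float(rng.uniform(0.0, 30.0)))
    else:
        imm = ImmobilitySpec("all_mobile")
    lo = lambda a, b: float(10 ** rng.uniform(math.log10(a), math.log10(b)))
    return ModelParams(
        K1_per_M=lo(1e4, 1e6), Kx_um2=lo(1.0, 100.0), K2_um2=lo(0.05, 2.0),
        KR_per_M=lo(1e5, 1e7), KA_per_M=lo(1e5, 1e7),
        pE=float(rng.uniform(0.5, 1.0)), pR=float(rng.uniform(0.5, 1.0)),
        sigma_per_um2=lo(50.0, 500.0), Ans_um2=float(rng.choice([0.0, 0.3])),
        Acell_um2=800.0, RT_per_um2=lo(300.0, 5000.0), immobility=imm)


def random_dose(rng, params) -> CellDose:
    NT = float(10 ** rng.uniform(3.0, 4.7))
    L = float(10 ** rng.uniform(-10.0, -5.5))
    A = float(rng.choice([0.0, 10 ** rng.uniform(-8.0, -5.0)]))
    return CellDose(NT / params.Acell_um2, L, A)
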