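"""Synthetic adhesion-titration and flow-cytometry data.

Emulates the study design the model is meant to analyze: adhesion titrations
at two bilayer receptor densities (1200 um^-2 and a four-fold higher 4800
um^-2) over ligand doses spanning 0.001-10 uM, with a few hundred cells
scored per point.  Fractions adhered carry binomial sampling noise;
conditional mean contact areas and bond counts are averages over the sampled
adhered cells with multiplicative lognormal measurement noise.  Points where
no sampled cell adheres report missing conditional observables (never
zeros), mirroring the conditional-average semantics of the real readout.

Every generated artifact is fully determined by an integer seed and carries
its generating parameters for parameter-recovery experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .params import ModelParams, best_fit_params
from .population import EpitopeDistribution, cell_observables
from .boundaries import minimal_epitope_density

__all__ = [
    "NoiseSpec", "default_L_grid", "DEFAULT_RT",
    "generate_population", "generate_titration", "generate_flow_histogram",
]

DEFAULT_RT = (1200.0, 4800.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Sampling design of one titration point."""
    n_cells: int = 300
    area_cv: float = 0.1
    bonds_cv: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.area_cv < 0 or self.bonds_cv < 0:
            raise ValueError("CVs must be >= 0")


def default_L_grid(n_per_decade: int = 4) -> np.ndarray:
    """Ligand doses from 0.001 to 10 uM, log-spaced (molar)."""
    return np.logspace(-9, -5, 4 * n_per_decade + 1)


def generate_population(dist: EpitopeDistribution, n_cells: int,
                        seed: int) -> np.ndarray:
    """I.i.d. per-cell epitope counts, reproducible by seed."""
    rng = np.random.default_rng(seed)
    return dist.rvs(n_cells, rng)


def _lognormal_factor(rng, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size else 1.0
    s = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * s * s, sigma=s, size=size)


def generate_titration(params: ModelParams, dist: EpitopeDistribution,
                       L_grid=None, RT_values=DEFAULT_RT,
                       noise: NoiseSpec = NoiseSpec(),
                       A_M: float = 0.0) -> pd.DataFrame:
    """Simulate a titration dataset.

    Per point: n_cells are drawn from the count distribution; those above
    the minimal adhering count adhere, giving a binomial adhered fraction;
    conditional observables are the means of the sampled adhered cells'
    contact areas and bond counts, degraded by multiplicative lognormal
    noise.  Returns a tidy DataFrame (one row per (RT, L)) whose ``attrs``
    record the generating parameters.
    """
    if L_grid is None:
        L_grid = default_L_grid()
    L_grid = np.asarray(L_grid, dtype=float)
    rng = np.random.default_rng(noise.seed)
    rows = []
    for RT in RT_values:
        pm = params.replace(RT_per_um2=float(RT))
        for L in L_grid:
            counts = dist.rvs(noise.n_cells, rng)
            rho_min = minimal_epitope_density(pm, float(L), A_M)
            adhered = counts / pm.Acell_um2 > rho_min
            k = int(adhered.sum())
            row = dict(L_M=float(L), RT_per_um2=float(RT), A_M=A_M,
                       fraction_adhered=k / noise.n_cells,
                       mean_area_um2=np.nan, mean_bonds=np.nan,
                       n_cells=noise.n_cells)
            if k > 0:
                rho = counts[adhered] / pm.Acell_um2
                areas, bonds = cell_observables(pm, rho, float(L), A_M)
                row["mean_area_um2"] = float(np.mean(areas)) \
                    * _lognormal_factor(rng, noise.area_cv)
                row["mean_bonds"] = float(np.mean(bonds)) \
                    * _lognormal_factor(rng, noise.bonds_cv)
            rows.append(row)
    df = pd.DataFrame(rows)
    df.attrs["generating"] = {
        "params": {k: (v if not isinstance(v, object) or isinstance(v, (int, float, str))
                       else str(v)) for k, v in _params_record(params).items()},
        "distribution": {"family": dist.family, "shape": dist.shape,
                         "scale": dist.scale, "mean": dist.mean},
        "noise": asdict(noise),
    }
    return df


def _params_record(params: ModelParams) -> dict:
    d = asdict(params)
    d["immobility"] = d["immobility"]["variant"]
    return d


def generate_flow_histogram(dist: EpitopeDistribution, n_cells: int,
                            n_bins: int = 64, seed: int = 0) -> pd.DataFrame:
    """Binned per-cell counts on a log axis, normalized to frequencies.

    Synthetic stand-in for a flow-cytometry epitope-count histogram
    (calibrated fluorescence already converted to counts).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    counts = generate_population(dist, n_cells, seed)
    counts = np.clip(counts, 1e-3, None)
    lo, hi = counts.min(), counts.max()
    if lo == hi:
        lo, hi = lo * 0.99, hi * 1.01
    edges = np.geomspace(lo, hi, n_bins + 1)
    freq, edges = np.histogram(counts, bins=edges)
    centers = np.sqrt(edges[1:] * edges[:-1])
    return pd.DataFrame({"count_center": centers,
                         "frequency": freq / freq.sum()})
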