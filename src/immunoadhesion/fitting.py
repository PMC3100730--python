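"""Weighted least-squares fitting of adhesion titrations, with bootstrap
uncertainties and fixed-parameter sensitivity scans.

The observables — fraction of cells adhered, conditional mean contact area,
conditional mean bridging-bond count — are fit simultaneously across all
ligand doses and receptor densities.  Mean-area and mean-bond residuals are
rescaled by the dataset maximum of each observable so that, like the
adhered fraction, they run between zero and one; the objective is the
pooled sum of squared residuals.  Rows where the model predicts zero
adhesion contribute no conditional-observable residuals (conditional means
are undefined there, not zero).

Free parameters per immobility variant (everything else fixed at the
reference values):

* ``all_mobile``:      sigma, K2, KR, Ans, Weibull shape c, mean count NT_mean
* ``constant``:        + baseline immobile fraction f0 (its optimum may sit
  on the boundary f0 = 0, recovering the fully mobile fit)
* ``linear_in_theta`` / ``linear_in_X``: + slope (>= 0), with f0 = 0.13

The estimator follows scikit-learn conventions (``get_params`` /
``set_params``, ``fit``, ``predict``, fitted attributes with trailing
underscores) so it composes with sklearn tooling; ``fit``, ``bootstrap``
and ``sensitivity_scan`` module functions are thin wrappers around it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .params import ModelParams, ImmobilitySpec, reference_fixed_params
from .population import EpitopeDistribution, titration_curves

__all__ = ["TitrationFit", "FitResult", "fit", "bootstrap", "sensitivity_scan",
           "objective_value", "FREE_PARAMS"]

log = logging.getLogger(__name__)

FREE_PARAMS = {
    "all_mobile": ("sigma", "K2", "KR", "Ans", "c", "NT_mean"),
    "constant": ("sigma", "K2", "KR", "Ans", "c", "NT_mean", "f0"),
    "linear_in_theta": ("sigma", "K2", "KR", "Ans", "c", "NT_mean", "slope"),
    "linear_in_X": ("sigma", "K2", "KR", "Ans", "c", "NT_mean", "slope"),
}

#: strictly positive parameters are searched in log space; the nonnegative
#: ones (which may legitimately sit at 0) in sqrt space
_LOG = {"sigma", "K2", "KR", "c", "NT_mean"}
_SQRT = {"Ans", "f0", "slope"}

_DEFAULT_INIT = {"sigma": 200.0, "K2": 0.5, "KR": 2e6, "Ans": 0.01,
                 "c": 1.5, "NT_mean": 6000.0, "f0": 0.05, "slope": 1.0}

_PENALTY = 1e8


@dataclass
class FitResult:
    """Best-fit parameters for one immobility-model variant."""
    variant: str
    params: dict
    objective: float
    seed: int
    n_starts: int = 1
    starts: list = field(default_factory=list)
    intervals: dict = field(default_factory=dict)   # name -> (lo, hi), 95%
    n_boot: int = 0
    n_boot_failed: int = 0

    def summary(self) -> str:
        lines = [f"variant: {self.variant}", f"objective: {self.objective:.6g}"]
        for k, v in self.params.items():
            ci = self.intervals.get(k)
            ci_s = f"  [{ci[0]:.4g}, {ci[1]:.4g}]" if ci else ""
            lines.append(f"  {k}: {v:.6g}{ci_s}")
        if self.n_boot:
            lines.append(f"bootstrap: {self.n_boot} replicates "
                         f"({self.n_boot_failed} failed)")
        return "\n".join(lines)


def _encode(free: dict, names) -> np.ndarray:
    out = []
    for n in names:
        v = free[n]
        out.append(math.log(v) if n in _LOG else math.sqrt(max(v, 0.0)))
    return np.asarray(out)


def _decode(vec, names) -> dict:
    return {n: (math.exp(v) if n in _LOG else v * v)
            for n, v in zip(names, vec)}


def _validate_data(X: pd.DataFrame) -> pd.DataFrame:
    X = X.reset_index(drop=True)
    for col in ("L_M", "RT_per_um2", "fraction_adhered"):
        if col not in X.columns:
            raise ValueError(f"dataset is missing required column {col!r}")
    if "A_M" not in X.columns:
        X = X.assign(A_M=0.0)
    for col in ("mean_area_um2", "mean_bonds"):
        if col not in X.columns:
            X = X.assign(**{col: np.nan})
    if (X["L_M"] <= 0).any() or (X["RT_per_um2"] <= 0).any():
        raise ValueError("L and RT must be positive in every row")
    f = X["fraction_adhered"]
    if ((f < 0) | (f > 1)).any():
        raise ValueError("fraction_adhered must lie in [0, 1]")
    obs = X[["fraction_adhered", "mean_area_um2", "mean_bonds"]].notna()
    if not obs.any(axis=1).all():
        raise ValueError("every row needs at least one observable")
    return X


class TitrationFit(BaseEstimator):
    """Simultaneous weighted least-squares fit of one immobility variant.

    Parameters
    ----------
    variant : immobility model ("all_mobile", "constant", "linear_in_theta",
        "linear_in_X").
    n_starts : multistart count for the derivative-free local search
        (log/sqrt-transformed Nelder-Mead); start 1 is ``init``, the rest
        are seeded perturbations of it.
    seed : controls every stochastic step (starts, bootstrap resampling).
    fixed : overrides for non-fitted physical parameters (K1_per_M, Kx_um2,
        pE, pR, Acell_um2, KA_per_M, or any free parameter to pin it).
    f0 : baseline immobile fraction for the feedback variants.
    """

    def __init__(self, variant: str = "all_mobile", n_starts: int = 10,
                 seed: int = 0, maxiter: int = 2000, init: dict | None = None,
                 fixed: dict | None = None, f0: float = 0.13,
                 n_quad: int = 16):
        self.variant = variant
        self.n_starts = n_starts
        self.seed = seed
        self.maxiter = maxiter
        self.init = init
        self.fixed = fixed
        self.f0 = f0
        self.n_quad = n_quad

    # -- model assembly -----------------------------------------------------
    def _free_names(self):
        names = list(FREE_PARAMS[self.variant])
        for n in list(names):
            if self.fixed and n in self.fixed:
                names.remove(n)
        return tuple(names)

    def _build(self, free: dict):
        fx = dict(reference_fixed_params())
        pin = dict(self.fixed or {})
        get = lambda n: pin.get(n, free.get(n))
        variant = self.variant
        if variant == "all_mobile":
            imm = ImmobilitySpec("all_mobile")
        elif variant == "constant":
            imm = ImmobilitySpec("constant", f0=get("f0"))
        else:
            imm = ImmobilitySpec(variant, f0=pin.get("f0", self.f0),
                                 slope=get("slope"))
        for k in ("K1_per_M", "Kx_um2", "pE", "pR", "Acell_um2"):
            if k in pin:
                fx[k] = pin[k]
        KR = get("KR")
        params = ModelParams(
            K2_um2=get("K2"), KR_per_M=KR,
            KA_per_M=pin.get("KA_per_M", KR),
            sigma_per_um2=get("sigma"), Ans_um2=get("Ans"),
            RT_per_um2=1200.0, immobility=imm, **fx)
        dist = EpitopeDistribution.weibull_from_mean(get("c"), get("NT_mean"))
        return params, dist

    # -- objective ----------------------------------------------------------
    def _objective(self, vec, X, scales) -> float:
        try:
            free = _decode(vec, self._names_)
            params, dist = self._build(free)
            frac, area, bonds = titration_curves(
                params, dist, X["L_M"].to_numpy(),
                RT=X["RT_per_um2"].to_numpy(), A_M=X["A_M"].to_numpy(),
                n_quad=self.n_quad)
        except Exception as exc:                    # solver failure: penalize
            log.warning("model evaluation failed (%s); penalizing", exc)
            return _PENALTY
        if not np.all(np.isfinite(frac)):
            return _PENALTY
        sse = float(np.nansum((frac - X["fraction_adhered"].to_numpy()) ** 2))
        # conditional observables only count where the model expects at
        # least half a sampled cell to adhere; below that its conditional
        # means are undefined for the experiment's design, not zero
        if "n_cells" in X.columns:
            n_cells = X["n_cells"].to_numpy(dtype=float)
            n_cells = np.where(np.isfinite(n_cells) & (n_cells > 0),
                               n_cells, 300.0)
        else:
            n_cells = np.full(len(X), 300.0)
        measurable = frac > 0.5 / n_cells
        for model, col in ((area, "mean_area_um2"), (bonds, "mean_bonds")):
            data = X[col].to_numpy()
            ok = ~np.isnan(data) & ~np.isnan(model) & measurable
            if ok.any():
                sse += float(np.sum(((model[ok] - data[ok]) / scales[col]) ** 2))
        return sse

    def _scales(self, X) -> dict:
        return {col: (np.nanmax(X[col].to_numpy())
                      if np.isfinite(np.nanmax(X[col].to_numpy())) else 1.0)
                if X[col].notna().any() else 1.0
                for col in ("mean_area_um2", "mean_bonds")}

    # -- sklearn API --------------------------------------------------------
    def fit(self, X: pd.DataFrame, y=None):
        X = _validate_data(X)
        self._names_ = self._free_names()
        scales = self._scales(X)
        init = dict(_DEFAULT_INIT)
        init.update(self.init or {})
        x0 = _encode(init, self._names_)
        rng = np.random.default_rng(self.seed)

        best = None
        self.starts_ = []
        for s in range(self.n_starts):
            xs = x0 if s == 0 else x0 + rng.normal(0.0, 0.35, size=x0.size)
            res = minimize(self._objective, xs, args=(X, scales),
                           method="Nelder-Mead",
                           options={"maxiter": self.maxiter,
                                    "xatol": 1e-6, "fatol": 1e-10})
            self.starts_.append({"start": s, "objective": float(res.fun),
                                 "success": bool(res.success),
                                 "nit": int(res.nit)})
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun) or best.fun >= _PENALTY:
            raise RuntimeError(
                f"all {self.n_starts} starts failed; diagnostics: {self.starts_}")

        free = _decode(best.x, self._names_)
        # snap sqrt-space parameters that converged to numerical zero
        for n in list(free):
            if n in _SQRT and free[n] < 1e-10:
                free[n] = 0.0
        self.params_ = free
        self.objective_ = float(self._objective(_encode(free, self._names_),
                                                X, scales))
        self.model_params_, self.dist_ = self._build(free)
        self.X_ = X
        self.scales_ = scales
        self.result_ = FitResult(self.variant, dict(free), self.objective_,
                                 self.seed, self.n_starts, list(self.starts_))
        return self

    def predict(self, X: pd.DataFrame) -> pd.DataFrame:
        """Model observables for the rows of ``X`` at the fitted parameters."""
        X = _validate_data(X)
        frac, area, bonds = titration_curves(
            self.model_params_, self.dist_, X["L_M"].to_numpy(),
            RT=X["RT_per_um2"].to_numpy(), A_M=X["A_M"].to_numpy(),
            n_quad=self.n_quad)
        return pd.DataFrame({"fraction_adhered": frac,
                             "mean_area_um2": area,
                             "mean_bonds": bonds})

    def score(self, X, y=None) -> float:
        X = _validate_data(X)
        return -self._objective(_encode(self.params_, self._names_),
                                X, self._scales(X))

    # -- bootstrap ----------------------------------------------------------
    def bootstrap(self, n_boot: int = 100, seed: int | None = None,
                  maxiter: int = 600) -> FitResult:
        """Case-resampling bootstrap; refits each replicate from the optimum.

        Returns a :class:`FitResult` with 95% percentile intervals.  Failed
        replicate fits are dropped and counted; more than 20% failures is an
        error.
        """
        if n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if not hasattr(self, "params_"):
            raise RuntimeError("call fit() first")
        rng = np.random.default_rng(self.seed if seed is None else seed)
        n = len(self.X_)
        x_opt = _encode(self.params_, self._names_)
        samples, failed = [], 0
        for b in range(n_boot):
            idx = rng.integers(0, n, size=n)
            Xb = self.X_.iloc[idx].reset_index(drop=True)
            scales = self._scales(Xb)
            try:
                res = minimize(self._objective, x_opt, args=(Xb, scales),
                               method="Nelder-Mead",
                               options={"maxiter": maxiter,
                                        "xatol": 1e-5, "fatol": 1e-9})
                if not np.isfinite(res.fun) or res.fun >= _PENALTY:
                    raise RuntimeError("penalized optimum")
                samples.append(_decode(res.x, self._names_))
            except Exception as exc:
                failed += 1
                log.warning("bootstrap replicate %d failed: %s", b, exc)
        if failed > 0.2 * n_boot:
            raise RuntimeError(f"{failed}/{n_boot} bootstrap replicates failed")
        intervals = {}
        for name in self._names_:
            vals = np.array([s[name] for s in samples])
            lo, hi = np.percentile(vals, [2.5, 97.5])
            # percentile intervals must contain the point estimate
            intervals[name] = (min(lo, self.params_[name]),
                               max(hi, self.params_[name]))
        result = FitResult(self.variant, dict(self.params_), self.objective_,
                           self.seed, self.n_starts, list(self.starts_),
                           intervals, len(samples), failed)
        self.result_ = result
        return result


# ---------------------------------------------------------------------------
# module-level wrappers
# ---------------------------------------------------------------------------

def objective_value(free: dict, data: pd.DataFrame,
                    variant: str = "all_mobile", fixed: dict | None = None,
                    n_quad: int = 16) -> float:
    """Weighted SSE of the model at explicit free-parameter values."""
    est = TitrationFit(variant=variant, fixed=fixed, n_quad=n_quad)
    X = _validate_data(data)
    est._names_ = est._free_names()
    return est._objective(_encode(free, est._names_), X, est._scales(X))


def fit(data: pd.DataFrame, variant: str = "all_mobile",
        init: dict | None = None, fixed: dict | None = None,
        seed: int = 0, n_starts: int = 10, **kw) -> FitResult:
    est = TitrationFit(variant=variant, init=init, fixed=fixed, seed=seed,
                       n_starts=n_starts, **kw)
    return est.fit(data).result_


def bootstrap(data: pd.DataFrame, variant: str = "all_mobile",
              n_boot: int = 100, seed: int = 0, init: dict | None = None,
              fixed: dict | None = None, n_starts: int = 10, **kw) -> FitResult:
    est = TitrationFit(variant=variant, init=init, fixed=fixed, seed=seed,
                       n_starts=n_starts, **kw)
    est.fit(data)
    return est.bootstrap(n_boot=n_boot)


_SCAN_KEYS = {"pE": "pE", "pR": "pR", "Kx": "Kx_um2"}


def sensitivity_scan(data: pd.DataFrame, name: str, grid,
                     variant: str = "all_mobile", seed: int = 0,
                     n_starts: int = 3, baseline: float | None = None,
                     **kw) -> pd.DataFrame:
    """Refit while holding one fixed physical parameter at each grid value.

    ``name`` is one of pE, pR, Kx.  Returns a tidy table of best-fit
    parameters and their relative change against the fit at the baseline
    (reference) value.
    """
    if name not in _SCAN_KEYS:
        raise ValueError(f"scan parameter must be one of {sorted(_SCAN_KEYS)}")
    key = _SCAN_KEYS[name]
    if baseline is None:
        baseline = reference_fixed_params()[key]
    base = fit(data, variant=variant, seed=seed, n_starts=n_starts,
               fixed={key: baseline}, **kw)
    kw_scan = {k: v for k, v in kw.items() if k != "init"}
    rows = []
    for val in grid:
        if val == baseline:
            r = base
        else:
            try:
                r = fit(data, variant=variant, seed=seed, n_starts=n_starts,
                        init=base.params, fixed={key: float(val)}, **kw_scan)
            except RuntimeError as exc:
                log.warning("scan point %s=%s failed: %s", name, val, exc)
                rows.append({name: float(val), "failed": True})
                continue
        row = {name: float(val), "objective": r.objective, "failed": False}
        for p, v in r.params.items():
            row[p] = v
            row[f"rel_change_{p}"] = (v - base.params[p]) / base.params[p] \
                if base.params[p] != 0 else (0.0 if v == 0 else math.inf)
        rows.append(row)
    return pd.DataFrame(rows)
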