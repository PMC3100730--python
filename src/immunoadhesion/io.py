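"""File formats, run configuration and the end-to-end pipeline.

Tabular artifacts are comma-separated with one header row; units ride in
parentheses inside the header names so files are self-describing and
diff-able.  Missing conditional observables (points where no cell adhered)
are empty fields, read back as NaN — never as zeros.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .params import ModelParams, load_params, best_fit_params, dump_params
from .population import EpitopeDistribution
from .simulate import NoiseSpec, generate_titration, default_L_grid, DEFAULT_RT
from .boundaries import phase_boundary_50pct
from .fitting import TitrationFit

log = logging.getLogger(__name__)

__all__ = ["read_titration", "write_titration", "RunConfig", "run_pipeline",
           "distribution_from_config"]

#: internal column name -> unit-annotated CSV header
_HEADERS = {
    "L_M": "L (M)",
    "RT_per_um2": "RT (per um2)",
    "A_M": "A (M)",
    "fraction_adhered": "fraction_adhered",
    "mean_area_um2": "mean_area (um2)",
    "mean_bonds": "mean_bonds",
    "n_cells": "n_cells",
}
_FROM_HEADER = {v: k for k, v in _HEADERS.items()}
_REQUIRED = ("L_M", "RT_per_um2", "fraction_adhered")


def write_titration(df: pd.DataFrame, path) -> None:
    out = df.rename(columns=_HEADERS)
    out.to_csv(path, index=False, float_format="%.12g")


def read_titration(path) -> pd.DataFrame:
    """Read and validate a titration dataset.

    Schema violations raise ``ValueError`` naming the offending column and
    row.  Unknown columns are preserved.
    """
    df = pd.read_csv(path)
    df = df.rename(columns=_FROM_HEADER)
    for col in _REQUIRED:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {_HEADERS[col]!r}")

    def bad_row(mask):
        return int(np.argmax(mask.to_numpy()))

    for col, lo, hi in (("L_M", 0.0, np.inf), ("RT_per_um2", 0.0, np.inf),
                        ("fraction_adhered", 0.0, 1.0)):
        m = ~df[col].between(lo, hi) | df[col].isna()
        if m.any():
            raise ValueError(
                f"{path}: column {_HEADERS[col]!r} out of range at row {bad_row(m)}")
    for col in ("mean_area_um2", "mean_bonds"):
        if col in df.columns:
            m = df[col].notna() & (df[col] < 0)
            if m.any():
                raise ValueError(
                    f"{path}: column {_HEADERS[col]!r} negative at row {bad_row(m)}")
    return df


def distribution_from_config(cfg: dict) -> EpitopeDistribution:
    fam = cfg.get("family", "weibull")
    if fam == "weibull":
        return EpitopeDistribution.weibull_from_mean(cfg["shape"], cfg["mean_count"])
    if fam == "lognormal":
        return EpitopeDistribution.lognormal(cfg["shape"], cfg["mean_count"])
    if fam == "empirical":
        hist = pd.read_csv(cfg["histogram"])
        return EpitopeDistribution.empirical(hist.iloc[:, 0], hist.iloc[:, 1])
    raise ValueError(f"unknown distribution family {fam!r}")


@dataclass
class RunConfig:
    """Configuration of an end-to-end run (simulate -> fit -> bootstrap ->
    phase diagram)."""
    seed: int = 0
    outdir: str = "run_output"
    params_file: str | None = None          # None: reference best fit
    variant: str = "all_mobile"
    distribution: dict = field(default_factory=lambda: {
        "family": "weibull", "shape": 1.5, "mean_count": 5200.0})
    n_cells: int = 300
    area_cv: float = 0.1
    bonds_cv: float = 0.1
    RT_values: tuple = DEFAULT_RT
    n_starts: int = 4
    maxiter: int = 2000
    n_boot: int = 0
    phase_counts: tuple = ()
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        if cfg.params_file and not Path(cfg.params_file).exists():
            raise FileNotFoundError(f"params_file {cfg.params_file} does not exist")
        return cfg


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.__dict__, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured pipeline; returns a dict of artifact paths.

    Every artifact directory carries a run log with the package version,
    seed, config hash and every parameter used (no silent defaults).
    """
    logging.basicConfig(level=cfg.verbosity)
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    params = (load_params(cfg.params_file) if cfg.params_file
              else best_fit_params(cfg.variant))
    dist = distribution_from_config(cfg.distribution)

    stamp = {"package_version": __version__, "seed": cfg.seed,
             "config_hash": _config_hash(cfg), "config": cfg.__dict__}
    with open(out / "run.yaml", "w") as fh:
        yaml.safe_dump(json.loads(json.dumps(stamp, default=str)), fh,
                       sort_keys=False)
    dump_params(params, out / "params.yaml")

    artifacts = {"run_log": str(out / "run.yaml")}
    log.info("simulating titration (seed=%d)", cfg.seed)
    noise = NoiseSpec(n_cells=cfg.n_cells, area_cv=cfg.area_cv,
                      bonds_cv=cfg.bonds_cv, seed=cfg.seed)
    data = generate_titration(params, dist, default_L_grid(),
                              cfg.RT_values, noise)
    write_titration(data, out / "titration.csv")
    artifacts["titration"] = str(out / "titration.csv")

    log.info("fitting variant %s", cfg.variant)
    est = TitrationFit(variant=cfg.variant, seed=cfg.seed,
                       n_starts=cfg.n_starts, maxiter=cfg.maxiter)
    est.fit(data)
    result = est.result_
    if cfg.n_boot:
        log.info("bootstrapping (%d replicates)", cfg.n_boot)
        result = est.bootstrap(n_boot=cfg.n_boot)
    with open(out / "fit_result.yaml", "w") as fh:
        yaml.safe_dump({
            "variant": result.variant, "objective": float(result.objective),
            "seed": result.seed,
            "params": {k: float(v) for k, v in result.params.items()},
            "intervals_95pct": {k: [float(a), float(b)]
                                for k, (a, b) in result.intervals.items()},
            "n_boot": result.n_boot, "n_boot_failed": result.n_boot_failed,
            "starts": result.starts,
        }, fh, sort_keys=False)
    artifacts["fit_result"] = str(out / "fit_result.yaml")

    if cfg.phase_counts:
        log.info("phase boundary over %d counts", len(cfg.phase_counts))
        pb = phase_boundary_50pct(est.model_params_, est.dist_,
                                  np.asarray(cfg.phase_counts, dtype=float))
        pd.DataFrame({"mean_count": pb.mean_counts,
                      "L_lower (M)": pb.L_lower,
                      "L_upper (M)": pb.L_upper}).to_csv(
            out / "phase_boundary.csv", index=False, float_format="%.12g")
        artifacts["phase_boundary"] = str(out / "phase_boundary.csv")
    return artifacts
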