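"""Objective definition, optimizer behavior, bootstrap and sensitivity."""

import numpy as np
import pandas as pd
import pytest

from immunoadhesion import (best_fit_params, EpitopeDistribution, NoiseSpec,
                            generate_titration, titration_curves,
                            default_L_grid)
from immunoadhesion.fitting import (TitrationFit, objective_value,
                                    sensitivity_scan)

TRUTH = dict(sigma=204.0, K2=0.6, KR=4.1e6, Ans=0.0, c=1.5, NT_mean=5200.0)


def noise_free_dataset(params, dist, L=None, RT=(1200.0, 4800.0)):
    """Exact model curves arranged as a titration dataset (no sampling)."""
    rows = []
    L = default_L_grid()[::2] if L is None else np.asarray(L)
    for rt in RT:
        frac, area, bonds = titration_curves(params, dist, L, RT=rt)
        rows.append(pd.DataFrame({
            "L_M": L, "RT_per_um2": rt, "fraction_adhered": frac,
            "mean_area_um2": area, "mean_bonds": bonds, "n_cells": 10**9}))
    return pd.concat(rows, ignore_index=True)


@pytest.fixture(scope="module")
def exact_data():
    p = best_fit_params("all_mobile")
    d = EpitopeDistribution.weibull_from_mean(1.5, 5200.0)
    return noise_free_dataset(p, d)


@pytest.fixture(scope="module")
def noisy_data():
    p = best_fit_params("all_mobile")
    d = EpitopeDistribution.weibull_from_mean(1.5, 5200.0)
    return generate_titration(p, d, noise=NoiseSpec(n_cells=300, seed=0))


@pytest.fixture(scope="module")
def fitted(noisy_data):
    """One shared fit of the noisy dataset (nonspecific area pinned at its
    generating value, which keeps the refits on the closed-form path)."""
    return TitrationFit(n_starts=2, seed=6, fixed={"Ans": 0.0},
                        maxiter=1200).fit(noisy_data)


@pytest.fixture(scope="module")
def exact_fit(exact_data):
    init = {k: v * f for (k, v), f in
            zip(TRUTH.items(), (1.15, 0.85, 1.2, 1.0, 1.05, 0.92))}
    return TitrationFit(n_starts=1, seed=0, init=init, fixed={"Ans": 0.0},
                        maxiter=6000).fit(exact_data)


class TestObjective:
    def test_noise_free_self_fit_has_zero_loss(self, exact_data):
        assert objective_value(TRUTH, exact_data) < 1e-12

    def test_matches_independent_weighted_sse(self, noisy_data):
        """Oracle recomputation: rescale area/bond residuals by the dataset
        maxima, pool with unscaled fraction residuals."""
        free = dict(TRUTH, sigma=180.0, NT_mean=6000.0)
        p = best_fit_params("all_mobile").replace(sigma_per_um2=180.0)
        d = EpitopeDistribution.weibull_from_mean(1.5, 6000.0)
        frac, area, bonds = titration_curves(
            p, d, noisy_data.L_M.to_numpy(),
            RT=noisy_data.RT_per_um2.to_numpy())
        expect = np.nansum((frac - noisy_data.fraction_adhered) ** 2)
        n = noisy_data.n_cells.to_numpy(dtype=float)
        for model, col in ((area, "mean_area_um2"), (bonds, "mean_bonds")):
            data = noisy_data[col].to_numpy()
            scale = np.nanmax(data)
            ok = ~np.isnan(data) & ~np.isnan(model) & (frac > 0.5 / n)
            expect += np.sum(((model[ok] - data[ok]) / scale) ** 2)
        assert objective_value(free, noisy_data) == pytest.approx(expect,
                                                                  rel=1e-12)

    def test_rows_with_undefined_model_conditionals_are_excluded(self):
        """Where the model expects no adhered cell in the sample, its
        conditional observables are undefined, not zero, and contribute no
        residual."""
        row = pd.DataFrame({
            "L_M": [1e-12], "RT_per_um2": [1200.0],
            "fraction_adhered": [0.0], "mean_area_um2": [5.0],
            "mean_bonds": [800.0], "n_cells": [300]})
        assert objective_value(TRUTH, row) == pytest.approx(0.0, abs=1e-15)

    def test_dataset_validation(self):
        bad = pd.DataFrame({"L_M": [0.0], "RT_per_um2": [1200.0],
                            "fraction_adhered": [0.5]})
        with pytest.raises(ValueError, match="L and RT"):
            objective_value(TRUTH, bad)


class TestFit:
    def test_optimum_not_worse_than_generating_parameters(self, fitted,
                                                          noisy_data):
        truth = {k: v for k, v in TRUTH.items() if k != "Ans"}
        assert fitted.objective_ <= objective_value(
            truth, noisy_data, fixed={"Ans": 0.0}) + 1e-9

    def test_noise_free_fit_recovers_parameters_sharply(self, exact_fit):
        assert exact_fit.objective_ < 1e-8
        for k in ("sigma", "K2", "KR", "c", "NT_mean"):
            assert exact_fit.params_[k] == pytest.approx(TRUTH[k],
                                                         rel=1e-2), k

    def test_constant_immobile_fraction_hits_lower_bound_on_mobile_data(
            self, noisy_data):
        """Data generated with every epitope mobile drive the fitted
        constant immobile fraction to the boundary f0 = 0."""
        est = TitrationFit(variant="constant", n_starts=1, seed=3,
                           fixed={"Ans": 0.0}, init=dict(TRUTH, f0=0.02),
                           maxiter=800, n_quad=8).fit(noisy_data)
        assert est.params_["f0"] <= 1e-3

    def test_predict_returns_model_curves(self, fitted, noisy_data):
        pred = fitted.predict(noisy_data)
        assert set(pred.columns) == {"fraction_adhered", "mean_area_um2",
                                     "mean_bonds"}
        assert len(pred) == len(noisy_data)
        assert pred.fraction_adhered.between(0, 1).all()

    def test_sklearn_param_protocol(self):
        est = TitrationFit(variant="constant", seed=7)
        params = est.get_params()
        assert params["variant"] == "constant" and params["seed"] == 7
        est.set_params(seed=9)
        assert est.seed == 9


class TestNestedModels:
    def test_feedback_variant_with_zero_slope_collapses_to_constant(self):
        """Fitting the contact-area-feedback model to data generated without
        feedback recovers slope ~ 0 at an objective no worse than the
        constant-immobility fit."""
        p = best_fit_params("constant")
        d = EpitopeDistribution.weibull_from_mean(1.5, 5200.0)
        L = np.geomspace(3e-9, 2e-6, 6)
        data = noise_free_dataset(p, d, L=L, RT=(1200.0,))
        common = dict(seed=4, n_starts=1, maxiter=300, n_quad=8,
                      fixed={"Ans": 0.0, "f0": 0.0})
        est_fb = TitrationFit(variant="linear_in_theta",
                              init=dict(TRUTH, slope=0.3), **common).fit(data)
        # contact fractions here are ~0.01, so the recovered slope implies a
        # negligible immobile fraction (slope * theta < 2e-3)
        assert est_fb.params_["slope"] < 0.15
        est_const = TitrationFit(variant="constant", init=dict(TRUTH),
                                 **common).fit(data)
        assert est_fb.objective_ <= est_const.objective_ + 1e-4


class TestBootstrap:
    def test_fixed_seed_gives_bit_identical_intervals(self, fitted):
        a = fitted.bootstrap(n_boot=15, seed=11, maxiter=200)
        b = fitted.bootstrap(n_boot=15, seed=11, maxiter=200)
        c = fitted.bootstrap(n_boot=15, seed=12, maxiter=200)
        assert a.intervals == b.intervals
        assert a.intervals != c.intervals

    def test_zero_noise_data_gives_narrow_intervals(self, exact_fit):
        res = exact_fit.bootstrap(n_boot=15, maxiter=400)
        for name, (lo, hi) in res.intervals.items():
            mid = exact_fit.params_[name]
            if mid > 0:
                assert (hi - lo) / mid < 0.01, name

    def test_interval_contains_point_estimate(self, fitted):
        res = fitted.bootstrap(n_boot=15, seed=1, maxiter=200)
        for name, (lo, hi) in res.intervals.items():
            assert lo <= fitted.params_[name] <= hi
        assert res.n_boot == 15

    def test_requires_at_least_two_replicates(self, fitted):
        with pytest.raises(ValueError):
            fitted.bootstrap(n_boot=1)


_SCAN_KW = dict(n_starts=1, maxiter=900,
                init=dict(sigma=204.0, K2=0.6, KR=4.1e6, Ans=0.01,
                          c=1.5, NT_mean=5200.0))


class TestSensitivity:
    def test_scanning_only_the_baseline_is_an_identity_row(self, noisy_data):
        table = sensitivity_scan(noisy_data, "pE", [0.75], **_SCAN_KW)
        row = table.iloc[0]
        for col in table.columns:
            if col.startswith("rel_change_"):
                assert row[col] == 0.0

    def test_bridging_constant_absorbs_the_assumed_crosslinking_value(
            self, noisy_data):
        """The lower boundary constrains the product K1*Kx*K2, so the fitted
        2D receptor constant K2 varies roughly inversely with the assumed
        Kx while the mean epitope count stays comparatively stable."""
        table = sensitivity_scan(noisy_data, "Kx", [15.625, 31.25, 62.5],
                                 **_SCAN_KW)
        t = table.set_index("Kx")
        assert t.loc[15.625, "K2"] / t.loc[31.25, "K2"] == pytest.approx(
            2.0, rel=0.25)
        assert t.loc[62.5, "K2"] / t.loc[31.25, "K2"] == pytest.approx(
            0.5, rel=0.35)
        assert abs(t.loc[15.625, "rel_change_NT_mean"]) < 0.10
        assert abs(t.loc[62.5, "rel_change_NT_mean"]) < 0.10

    def test_moderate_partition_changes_leave_most_parameters_stable(
            self, noisy_data):
        table = sensitivity_scan(noisy_data, "pE", [0.6, 0.75, 0.9],
                                 **_SCAN_KW)
        stable = 0
        for _, row in table.iterrows():
            if row["pE"] == 0.75:
                continue
            stable += sum(abs(row[f"rel_change_{p}"]) < 0.10
                          for p in ("sigma", "c", "NT_mean"))
        assert stable >= 4          # most fitted parameters move < 10%
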