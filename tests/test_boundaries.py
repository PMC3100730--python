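"""Adhesion windows, phase boundaries, approximations and IgG competition."""

import math

import numpy as np
import pytest

from immunoadhesion import (best_fit_params, adhesion_window,
                            minimal_epitope_density, approx_L_bounds,
                            igg_effective_params, phase_boundary_50pct,
                            inhibition_curve, fraction_bound,
                            EpitopeDistribution)


class TestApproxBounds:
    def test_tenfold_weaker_epitope_binding_raises_lmin_hundredfold(
            self, all_mobile_params):
        """L_min scales inversely with the square of the ligand-epitope
        constants: dividing K1 and Kx by 10 multiplies it by exactly 100."""
        p = all_mobile_params
        a1 = approx_L_bounds(p, 6.5)
        a2 = approx_L_bounds(p.replace(K1_per_M=p.K1_per_M / 10,
                                       Kx_um2=p.Kx_um2 / 10), 6.5)
        assert a2.L_min == pytest.approx(100.0 * a1.L_min, rel=1e-12)

    def test_doubling_density_quarters_lmin(self, all_mobile_params):
        a1 = approx_L_bounds(all_mobile_params, 6.5)
        a2 = approx_L_bounds(all_mobile_params, 13.0)
        assert a2.L_min == pytest.approx(a1.L_min / 4.0, rel=1e-12)

    def test_approximate_window_contains_and_tracks_full_solver(
            self, all_mobile_params):
        """The closed forms bracket the true window from outside; L_min
        tracks within 2x everywhere.  L_max reaches 2x only at high counts:
        at low counts the top of the window is still cross-link-dominated,
        where the singly-bound assumption deliberately overshoots."""
        for rho in (4.0, 6.5, 13.0, 40.0):
            full = adhesion_window(all_mobile_params, rho)
            approx = approx_L_bounds(all_mobile_params, rho)
            assert full.exists and approx.exists
            assert approx.L_min <= full.L_min * (1 + 1e-9)    # containment
            assert approx.L_max >= full.L_max * (1 - 1e-9)
            assert 0.3 < approx.L_min / full.L_min <= 1.0 + 1e-9
        full = adhesion_window(all_mobile_params, 40.0)
        approx = approx_L_bounds(all_mobile_params, 40.0)
        assert approx.L_max / full.L_max < 2.0


class TestWindowProperties:
    def test_enlarging_bridging_constant_never_shrinks_window(
            self, all_mobile_params):
        prev = adhesion_window(all_mobile_params, 6.5)
        for fac in (1.5, 2.5, 5.0):
            w = adhesion_window(
                all_mobile_params.replace(K2_um2=fac *
                                          all_mobile_params.K2_um2), 6.5)
            assert w.L_min <= prev.L_min * (1 + 1e-9)
            assert w.L_max >= prev.L_max * (1 - 1e-9)
            prev = w

    def test_density_below_threshold_has_no_window(self, all_mobile_params):
        assert not adhesion_window(all_mobile_params, 0.05).exists

    def test_minimal_density_weakly_increases_with_sigma(self,
                                                         all_mobile_params):
        p = all_mobile_params
        rhos = [minimal_epitope_density(p.replace(sigma_per_um2=s), 5e-8)
                for s in (100.0, 204.0, 400.0, 800.0)]
        assert all(b >= a for a, b in zip(rhos, rhos[1:]))

    def test_unreachable_when_bridging_pathway_absent(self, all_mobile_params):
        """With no Fc-receptor binding (K2 = 0) no epitope density admits
        adhesion at any dose, via both the closed form and the generic scan."""
        from immunoadhesion.params import ImmobilitySpec
        p = all_mobile_params.replace(K2_um2=0.0)
        assert minimal_epitope_density(p, 1e-7) == math.inf
        p_gen = p.replace(immobility=ImmobilitySpec("constant", f0=0.13))
        assert minimal_epitope_density(p_gen, 1e-7) == math.inf


class TestSquareLaw:
    def test_lower_boundary_slope_is_near_minus_two(self, all_mobile_params,
                                                    weibull_dist):
        """Lower branch of the 50%-adhesion phase boundary vs mean epitope
        count has log-log slope ~ -2 (one decade around the fitted mean)."""
        # the "bottom portion" of the boundary: counts above the fitted
        # mean, where the pure square law dominates
        counts = np.geomspace(10400, 104000, 7)
        pb = phase_boundary_50pct(all_mobile_params, weibull_dist, counts)
        assert np.isfinite(pb.L_lower).all()
        slope = np.polyfit(np.log10(counts), np.log10(pb.L_lower), 1)[0]
        assert -2.2 < slope < -1.8


class TestPhaseBoundary:
    def test_degenerate_distribution_recovers_single_cell_window(
            self, all_mobile_params):
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            point = EpitopeDistribution.empirical([5200.0], [1.0])
        pb = phase_boundary_50pct(all_mobile_params, point, [5200.0])
        w = adhesion_window(all_mobile_params, 5200.0 / 800.0)
        assert pb.L_lower[0] == pytest.approx(w.L_min, rel=1e-3)
        assert pb.L_upper[0] == pytest.approx(w.L_max, rel=1e-3)

    def test_boundary_points_sit_at_half_adhesion(self, all_mobile_params,
                                                  weibull_dist):
        pb = phase_boundary_50pct(all_mobile_params, weibull_dist, [5200.0])
        for L in (pb.L_lower[0], pb.L_upper[0]):
            f = fraction_bound(all_mobile_params, weibull_dist, L)
            assert f == pytest.approx(0.5, abs=1e-6)


class TestIgGCompetition:
    def test_zero_igg_is_identity_mapping(self, all_mobile_params):
        eff = igg_effective_params(all_mobile_params, 0.0)
        assert eff == all_mobile_params

    def test_effective_parameters_reproduce_igg_model_exactly(
            self, all_mobile_params, weibull_dist):
        """The model depends on KA and A only through 1 + KR*L + KA*A, so
        the substitution is exact to machine precision."""
        A = 2e-6
        eff = igg_effective_params(all_mobile_params, A)
        for L in np.geomspace(1e-9, 1e-6, 12):
            f_igg = fraction_bound(all_mobile_params, weibull_dist, L, A)
            f_eff = fraction_bound(eff, weibull_dist, L, 0.0)
            assert f_eff == pytest.approx(f_igg, rel=1e-12, abs=1e-15)

    def test_igg_shifts_lmin_by_competition_factor(self, all_mobile_params):
        # deep in the bivalent-bridging regime (rho well above the
        # cross-link-pair offset 2*sigma/(pE^2*K2*pR*RT)) the shift is
        # exactly (1 + KA*A) in the approximation and ~10% in the full model
        p = all_mobile_params
        rho = 40.0
        A = 1.0 / p.KA_per_M          # KA*A = 1
        a0 = approx_L_bounds(p, rho, 0.0)
        a1 = approx_L_bounds(p, rho, A)
        assert a1.L_min == pytest.approx(2.0 * a0.L_min, rel=1e-12)
        w0 = adhesion_window(p, rho, 0.0)
        w1 = adhesion_window(p, rho, A)
        assert w1.L_min / w0.L_min == pytest.approx(2.0, rel=0.10)

    def test_approx_lmax_nearly_invariant_under_igg(self, all_mobile_params):
        """Receptor loss and relaxed saturation cancel in the high-L limit."""
        p = all_mobile_params
        a0 = approx_L_bounds(p, 40.0, 0.0)
        a1 = approx_L_bounds(p, 40.0, 1.0 / p.KA_per_M)
        assert a1.L_max == pytest.approx(a0.L_max, rel=0.10)

    def test_inhibition_curve_decreases_to_zero(self, all_mobile_params,
                                                weibull_dist):
        p = all_mobile_params
        L = 1e-7                                  # inside the window at A = 0
        A = np.concatenate([[0.0], np.geomspace(1e-9, 3e-4, 14)])
        f = inhibition_curve(p, weibull_dist, L, A)
        assert f[0] == pytest.approx(
            fraction_bound(p, weibull_dist, L, 0.0), rel=1e-12)
        assert np.all(np.diff(f) <= 1e-12)
        assert f[-1] < 1e-3                       # KA*A >> 1 kills adhesion

    def test_half_inhibition_near_competition_scale(self, all_mobile_params,
                                                    weibull_dist):
        """50% inhibition occurs around KA*A ~ 1 + KR*L, checked against the
        effective-parameter route."""
        p = all_mobile_params
        L = 1e-7
        f0 = fraction_bound(p, weibull_dist, L, 0.0)
        A_scale = (1.0 + p.KR_per_M * L) / p.KA_per_M
        A = np.geomspace(A_scale / 100, A_scale * 100, 161)
        f = inhibition_curve(p, weibull_dist, L, A)
        A_half = A[int(np.argmin(np.abs(f - 0.5 * f0)))]
        assert 0.1 < A_half / A_scale < 10.0
        eff = igg_effective_params(p, float(A_half))
        assert fraction_bound(eff, weibull_dist, L, 0.0) == pytest.approx(
            0.5 * f0, rel=0.05)
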