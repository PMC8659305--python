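"""Sensitivity recovery: mixture fit, moving-bin curve, cusp fit, laws."""

import numpy as np
import pytest
from scipy import optimize

from crowdshift import (
    DomainError,
    clip_S,
    compute_S,
    cusp_fit_interval,
    d0_search_interval,
    fit_D0,
    fit_D0_records,
    fit_S_mixture,
    fit_cusp,
    moving_bin_curve,
    quadratic_cross_term,
    regress_params_vs_sigma,
)
from crowdshift.s_analysis import MixtureFit


class TestComputeS:
    @pytest.mark.parametrize(
        "X_p,X_s,M,expected",
        [
            (1.0, 1.0, 2.0, 0.0),       # keeps the personal estimate
            (1.0, 2.0, 2.0, 1.0),       # adopts the social mean
            (5.0, 5.1, 5.001, 100.0),   # blow-up when M is nearly X_p
        ],
    )
    def test_ratio(self, X_p, X_s, M, expected):
        s, defined = compute_S(X_p, X_s, M)
        assert defined and s == pytest.approx(expected)

    def test_undefined_flagged_not_raised(self):
        s, defined = compute_S(2.0, 2.5, 2.0)
        assert not defined and np.isnan(s)

    def test_vectorized_roundtrip_of_update(self, rng):
        X_p = rng.normal(size=100)
        M = X_p + rng.normal(size=100) + 0.5
        S_true = rng.normal(0.4, 0.3, size=100)
        X_s = (1 - S_true) * X_p + S_true * M
        S, defined = compute_S(X_p, X_s, M)
        assert defined.all()
        assert np.allclose(S, S_true)


class TestClipS:
    def test_all_in_range(self):
        kept, frac = clip_S([0.0, 0.5, 1.0])
        assert frac == 0.0 and kept.size == 3

    def test_blowup_removed(self):
        kept, frac = clip_S([0.2, 100.0])
        assert 100.0 not in kept and frac == 0.5

    def test_known_fraction(self, rng):
        inside = rng.uniform(-1.0, 2.0, size=80)
        outside = np.concatenate([rng.uniform(3, 5, size=15), rng.uniform(-9, -2, size=5)])
        _, frac = clip_S(np.concatenate([inside, outside]))
        assert frac == pytest.approx(20 / 100)

    def test_boundaries_inclusive(self):
        kept, frac = clip_S([-1.05, 2.05])
        assert frac == 0.0 and kept.size == 2


class TestMixtureFit:
    def test_parameter_recovery(self, rng):
        n = 5000
        zeros = np.zeros(int(0.4 * n))
        gauss = rng.normal(0.55, 0.3, size=n - zeros.size)
        S = np.concatenate([zeros, gauss])
        fit = fit_S_mixture(S)
        assert fit.P0 == pytest.approx(0.40, abs=0.03)
        assert fit.m_g == pytest.approx(0.55, abs=0.03)
        assert fit.sigma_g == pytest.approx(0.30, abs=0.03)

    def test_all_zeros_degenerate(self):
        fit = fit_S_mixture(np.zeros(100))
        assert fit.P0 == 1.0 and fit.Pg == 0.0
        assert np.isnan(fit.m_g)

    def test_mean_constraint_holds_by_construction(self, rng):
        S = np.concatenate([np.zeros(300), rng.normal(0.6, 0.2, size=700)])
        fit = fit_S_mixture(S)
        assert fit.mean_S == pytest.approx(fit.Pg * fit.m_g)
        assert fit.P0 + fit.Pg == pytest.approx(1.0)

    def test_provenance_zero_mask_wins_over_values(self, rng):
        # a Gaussian draw can be numerically ~0 without being a "keep"
        S = np.concatenate([np.zeros(400), rng.normal(0.5, 0.3, size=600)])
        mask = np.zeros(1000, dtype=bool)
        mask[:400] = True
        fit = fit_S_mixture(S, zero_mask=mask)
        assert fit.P0 == pytest.approx(0.4, abs=0.05)


class TestMovingBinCurve:
    def test_constant_signal(self):
        curve = moving_bin_curve(np.linspace(-2, 2, 500), np.full(500, 0.7))
        filled = curve[curve["count"] > 0]
        assert np.allclose(filled["mean_S"], 0.7)

    def test_single_record_window_membership(self):
        curve = moving_bin_curve([0.0], [1.0])
        hit = curve[curve["count"] > 0]["center"]
        assert hit.min() == pytest.approx(-0.5)
        assert hit.max() == pytest.approx(0.5)

    def test_piecewise_linear_fixture(self, rng):
        D = rng.uniform(-2.5, 2.5, size=200_000)
        S = 0.2 + 0.15 * np.abs(D + 0.3)
        curve = moving_bin_curve(D, S)
        # window smoothing inflates the mean near the vertex by <= b*w/4
        for c, m, cnt in curve:
            window = np.abs(D - c) <= 0.5
            assert m == pytest.approx(S[window].mean(), abs=1e-12)

    def test_step_equal_bin_size_is_disjoint_binning(self, rng):
        D = rng.uniform(-2, 2, size=5000)
        S = rng.normal(size=5000)
        curve = moving_bin_curve(D, S, bin_size=1.0, step=1.0, centers_range=(-1.5, 1.5))
        assert curve.shape[0] == 4
        for c, m, cnt in curve:
            mask = np.abs(D - c) <= 0.5
            assert cnt == mask.sum()


class TestFitD0:
    def test_recovery_from_clean_v_curve(self):
        # raw (unsmoothed) V points are the window = 0 model
        c = np.arange(-2, 2.01, 0.1)
        y = 0.3 + 0.2 * np.abs(c + 0.4)
        curve = np.zeros(c.size, dtype=[("center", float), ("mean_S", float), ("count", int)])
        curve["center"], curve["mean_S"], curve["count"] = c, y, 100
        assert fit_D0(curve, (-1.2, 0.2), window=0.0) == pytest.approx(-0.4, abs=0.02)

    def test_recovery_from_moving_bin_curve_of_records(self, rng):
        # the default window matches curves produced by moving_bin_curve
        D = rng.uniform(-2.5, 2.5, size=100_000)
        S = 0.3 + 0.2 * np.abs(D + 0.4) + rng.normal(0, 0.2, size=D.size)
        curve = moving_bin_curve(D, S)
        assert fit_D0(curve, (-1.2, 0.2)) == pytest.approx(-0.4, abs=0.03)

    def test_symmetric_v_centered_at_zero(self):
        c = np.arange(-1.2, 0.81, 0.1)
        curve = np.zeros(c.size, dtype=[("center", float), ("mean_S", float), ("count", int)])
        curve["center"], curve["mean_S"], curve["count"] = c, 0.1 + 0.3 * np.abs(c), 50
        assert fit_D0(curve, (-1.2, 0.8), window=0.0) == pytest.approx(0.0, abs=0.01)

    def test_too_few_points(self):
        curve = np.zeros(2, dtype=[("center", float), ("mean_S", float), ("count", int)])
        curve["center"] = [-0.1, 0.0]
        curve["count"] = 1
        with pytest.raises(DomainError):
            fit_D0(curve)

    def test_search_interval_exceptions(self):
        assert d0_search_interval("random", 3) == (-1.2, 0.6)
        assert d0_search_interval("random", 5) == (-1.2, 0.6)
        assert d0_search_interval("median", 3) == (-1.2, 0.6)
        assert d0_search_interval("median", 5) == (-1.2, 0.2)
        assert d0_search_interval("shifted_median", 3) == (-1.2, 0.2)

    def test_record_level_profile_recovers_asymmetric_vertex(self, rng):
        n = 150_000
        D = rng.laplace(0.0, 0.5, size=n)
        sig = rng.uniform(0.05, 0.4, size=n)
        S = (0.25 + np.where(D < -0.3, 0.1, 0.22) * np.abs(D + 0.3)
             - 0.2 * sig + rng.normal(0, 0.3, size=n))
        d0 = fit_D0_records(D, S, sig, tau=5)
        assert d0 == pytest.approx(-0.3, abs=0.02)


class TestFitCusp:
    def _make(self, rng, n=200, tau=5, noise=0.0):
        D = rng.uniform(-2.4, 2.4, size=n)
        sig = rng.uniform(0.0, 0.6, size=n)
        S = (0.2 + np.where(D < -0.25, 0.12, 0.21) * np.abs(D + 0.25)
             - 0.18 * sig + noise * rng.normal(size=n))
        return D, S, sig

    def test_noiseless_exact_recovery(self, rng):
        D, S, sig = self._make(rng)
        fit = fit_cusp(D, S, sig, D0=-0.25, tau=5)
        assert fit.alpha == pytest.approx(0.2, abs=1e-8)
        assert fit.beta_minus == pytest.approx(0.12, abs=1e-8)
        assert fit.beta_plus == pytest.approx(0.21, abs=1e-8)
        assert fit.beta_prime == pytest.approx(-0.18, abs=1e-8)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_generator_gives_equal_slopes(self, rng):
        D = rng.uniform(-2, 2, size=4000)
        S = 0.3 + 0.15 * np.abs(D) + 0.02 * rng.normal(size=4000)
        fit = fit_cusp(D, S, np.zeros_like(D), D0=0.0, tau=1)
        assert fit.beta_minus == pytest.approx(fit.beta_plus, abs=0.02)
        assert fit.beta_prime is None

    def test_agrees_with_numeric_minimizer(self, rng):
        D, S, sig = self._make(rng, n=200, noise=0.2)
        fit = fit_cusp(D, S, sig, D0=-0.25, tau=5)

        def loss(p):
            a, bm, bp, bpr = p
            pred = a + np.where(D < -0.25, bm, bp) * np.abs(D + 0.25) + bpr * sig
            return np.sum((S - pred) ** 2)

        res = optimize.minimize(loss, x0=[0, 0.1, 0.1, 0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
        assert fit.alpha == pytest.approx(res.x[0], abs=1e-6)
        assert fit.beta_minus == pytest.approx(res.x[1], abs=1e-6)
        assert fit.beta_plus == pytest.approx(res.x[2], abs=1e-6)
        assert fit.beta_prime == pytest.approx(res.x[3], abs=1e-6)

    def test_rank_deficient_design_names_regressor(self):
        D = np.full(50, 1.0)  # all on one side, |D - D0| constant
        S = np.random.default_rng(0).normal(size=50)
        with pytest.raises(DomainError, match="left slope"):
            fit_cusp(D, S, np.zeros(50), D0=0.0, tau=1)

    def test_fit_interval_exceptions(self):
        assert cusp_fit_interval("random", 1) == (-1.65, 2.5)
        assert cusp_fit_interval("median", 7) == (-1.9, 2.5)
        assert cusp_fit_interval("shifted_median", 9) == (-1.2, 1.5)
        assert cusp_fit_interval("median", 5) == (-2.5, 2.5)


class TestParamLaws:
    def test_two_points_exact_line(self):
        fits = [
            (MixtureFit(P0=0.5, Pg=0.5, m_g=0.6, sigma_g=0.3, mean_S=0.3), 0.2),
            (MixtureFit(P0=0.6, Pg=0.4, m_g=0.5, sigma_g=0.35, mean_S=0.2), 0.4),
        ]
        laws = regress_params_vs_sigma(fits)
        assert laws.m_g(0.2) == pytest.approx(0.6)
        assert laws.m_g(0.4) == pytest.approx(0.5)
        assert laws.Pg.slope == pytest.approx(-0.5)

    def test_noisy_law_recovery(self, rng):
        sig = np.linspace(0.1, 0.8, 12)
        fits = []
        for s in sig:
            m_g = 0.7 - 0.3 * s + rng.normal(0, 0.01)
            pg = 0.5 - 0.2 * s + rng.normal(0, 0.01)
            fits.append(
                (MixtureFit(P0=1 - pg, Pg=pg, m_g=m_g, sigma_g=0.3 + 0.1 * s,
                            mean_S=pg * m_g), s)
            )
        laws = regress_params_vs_sigma(fits)
        assert laws.m_g.slope == pytest.approx(-0.3, abs=0.05)
        assert laws.Pg.slope == pytest.approx(-0.2, abs=0.05)

    def test_single_point_rejected(self):
        with pytest.raises(DomainError):
            regress_params_vs_sigma(
                [(MixtureFit(P0=0.5, Pg=0.5, m_g=0.5, sigma_g=0.3, mean_S=0.25), 0.3)]
            )

    def test_quadratic_cross_term_magnitude(self):
        assert quadratic_cross_term(0.2, 0.2, 0.5) == pytest.approx(0.01)
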