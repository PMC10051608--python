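"""IVIVC chain: UIR, disposition fit, convolution, deconvolution, Levy,
plasma prediction and PK summaries."""

import numpy as np
import pytest

from gisivivc.ivivc import (
    AbsorptionProfile,
    LevyModel,
    PKSummary,
    PlasmaProfile,
    UIRParameters,
    _oral_biexp,
    convolve,
    deconvolve,
    fit_disposition,
    levy_fit,
    pk_summary,
    predict_plasma,
    prediction_error,
    uir_eval,
)
from gisivivc.metrics import DissolutionProfile, WeibullParams, weibull_cdf

GRID5 = np.arange(0.0, 721.0, 5.0)


class TestUIR:
    def test_value_at_origin(self, uir):
        assert uir_eval(uir, 0.0) == pytest.approx(50.327514, abs=1e-9)

    def test_decays_to_zero(self, uir):
        assert uir_eval(uir, 1e7) == pytest.approx(0.0, abs=1e-12)

    def test_monoexponential_special_case(self):
        u = UIRParameters(A1=10.0, A2=0.0, alpha1=0.01, alpha2=1.0)
        t_half = np.log(2) / 0.01
        assert uir_eval(u, t_half) == pytest.approx(5.0, rel=1e-12)

    def test_rejects_negative_time(self, uir):
        with pytest.raises(ValueError):
            uir_eval(uir, -1.0)


class TestFitDisposition:
    TRUTH = (50.32, 0.007514, 0.004773, 0.004006, 0.05)

    def _plasma(self, noise=None, seed=0):
        t = np.concatenate([np.arange(0.0, 120.0, 10.0), np.arange(120.0, 721.0, 30.0)])
        c = _oral_biexp(t, *self.TRUTH)
        if noise is not None:
            rng = np.random.default_rng(seed)
            c = c * rng.lognormal(0.0, noise, t.size)
        return PlasmaProfile(t, np.maximum(c, 0.0), dose=400.0)

    def test_noiseless_recovery(self, recwarn):
        u, report = fit_disposition(self._plasma())
        a1, a2, al1, al2, ka = self.TRUTH
        assert u.A1 == pytest.approx(a1, rel=1e-3)
        assert u.A2 == pytest.approx(a2, rel=1e-3)
        assert u.alpha1 == pytest.approx(al1, rel=1e-3)
        assert u.alpha2 == pytest.approx(al2, rel=1e-3)
        assert report["ka"] == pytest.approx(ka, rel=1e-3)

    def test_noisy_recovery_median_alpha1_error(self):
        """10% multiplicative noise: median relative error of the dominant
        disposition constant < 20% over 100 seeds."""
        errs = []
        for seed in range(100):
            u, _ = fit_disposition(self._plasma(noise=0.10, seed=seed), n_starts=20)
            errs.append(abs(u.alpha1 - self.TRUTH[2]) / self.TRUTH[2])
        assert np.median(errs) < 0.20

    def test_monotone_decreasing_data_warns(self):
        t = np.arange(0.0, 361.0, 30.0)
        c = 40.0 * np.exp(-0.01 * t)
        with pytest.warns(UserWarning, match="monotone decreasing"):
            fit_disposition(PlasmaProfile(t, c, dose=400.0))

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="at least 6"):
            fit_disposition(
                PlasmaProfile(np.array([0.0, 10, 20]), np.array([0.0, 5, 3]), dose=400)
            )


class TestConvolve:
    def test_bolus_reproduces_uir(self, uir):
        fa = AbsorptionProfile(GRID5, np.ones_like(GRID5))
        pl = convolve(uir, fa, dose=400.0)
        assert np.allclose(pl.concentrations, uir.evaluate(GRID5), rtol=1e-12)

    def test_dose_scaling(self, uir):
        fa = AbsorptionProfile(GRID5, np.ones_like(GRID5))
        pl = convolve(uir, fa, dose=200.0)
        assert np.allclose(pl.concentrations, 0.5 * uir.evaluate(GRID5), rtol=1e-12)

    def test_zero_absorption_gives_zero(self, uir):
        fa = AbsorptionProfile(GRID5, np.zeros_like(GRID5))
        pl = convolve(uir, fa, dose=400.0)
        assert np.all(pl.concentrations == 0)

    def test_exponential_absorption_matches_triexponential(self, uir):
        """First-order absorption Fa = 1 - exp(-k t): the convolution has a
        closed triexponential form; agreement < 1e-8 relative."""
        k = 0.05
        t = np.arange(0.0, 300.0005, 0.0005)  # fine grid: Fa is piecewise-linear
        fa = AbsorptionProfile(t, -np.expm1(-k * t))
        pl = convolve(uir, fa, dose=400.0)

        def closed(tt):
            out = np.zeros_like(tt)
            for A, al in ((uir.A1, uir.alpha1), (uir.A2, uir.alpha2)):
                out += A * k * (np.exp(-k * tt) - np.exp(-al * tt)) / (al - k)
            return out

        check = np.arange(5.0, 300.0, 12.5)
        idx = np.searchsorted(t, check)
        ref = closed(t[idx])
        assert np.max(np.abs(pl.concentrations[idx] - ref) / ref) < 1e-8

    def test_superposition_linearity(self, uir):
        """Convolution is linear in the Fa increments to ~machine precision."""
        rng = np.random.default_rng(11)
        inc_a = np.abs(rng.normal(size=GRID5.size)) * 0.002
        inc_b = np.abs(rng.normal(size=GRID5.size)) * 0.002
        inc_a[0] = inc_b[0] = 0.0

        def conv(inc):
            fa = np.minimum(np.cumsum(inc), 1.0)
            return convolve(
                uir, AbsorptionProfile(GRID5, fa), dose=400.0
            ).concentrations

        lhs = conv(inc_a + inc_b)
        rhs = conv(inc_a) + conv(inc_b)
        assert np.max(np.abs(lhs - rhs)) < 1e-10 * max(1.0, np.max(np.abs(lhs)))

    def test_nonuniform_grid_matches_uniform(self, uir):
        t_u = np.arange(0.0, 241.0, 1.0)
        fa_vals = -np.expm1(-0.02 * t_u)
        pl_u = convolve(uir, AbsorptionProfile(t_u, fa_vals), dose=400.0)
        # same breakpoints plus an extra midpoint => same piecewise-linear Fa
        t_n = np.sort(np.append(t_u, 100.5))
        fa_n = np.interp(t_n, t_u, fa_vals)
        pl_n = convolve(uir, AbsorptionProfile(t_n, fa_n), dose=400.0)
        assert np.allclose(
            pl_n.concentrations[np.isin(t_n, t_u)], pl_u.concentrations, rtol=1e-10
        )


class TestDeconvolve:
    def test_roundtrip_recovers_monotone_fa(self, uir):
        """deconvolve(convolve(Fa)) == Fa to < 0.01 absolute on a 5-min grid."""
        for seed in range(3):
            rng = np.random.default_rng(seed)
            inc = rng.random(GRID5.size)
            inc[0] = 0.0
            fa = np.cumsum(inc)
            fa /= fa[-1]
            plasma = convolve(uir, AbsorptionProfile(GRID5, fa), dose=400.0)
            rec, _ = deconvolve(plasma, uir)
            assert np.max(np.abs(rec.fraction_absorbed - fa)) < 0.01

    def test_uir_plasma_gives_unit_step(self, uir):
        plasma = PlasmaProfile(GRID5, uir.evaluate(GRID5), dose=400.0)
        fa, _ = deconvolve(plasma, uir)
        assert np.allclose(fa.fraction_absorbed, 1.0, atol=1e-9)

    def test_zero_plasma_gives_zero_fa(self, uir):
        plasma = PlasmaProfile(GRID5, np.zeros_like(GRID5), dose=400.0)
        fa, _ = deconvolve(plasma, uir)
        assert np.all(fa.fraction_absorbed == 0)

    def test_coarse_grid_is_refined(self, uir):
        """Coarse plasma sampling: the grid is refined to <= 5 min and the
        recovered Fa reproduces the observed concentrations (the refined
        system is underdetermined, so Fa itself is only loosely pinned)."""
        t = np.arange(0.0, 721.0, 30.0)
        fa_true = np.clip(t / 240.0, 0.0, 1.0)
        plasma = convolve(uir, AbsorptionProfile(t, fa_true), dose=400.0)
        rec, report = deconvolve(plasma, uir, max_interval=5.0)
        assert np.max(np.diff(rec.time_points)) <= 5.0 + 1e-9
        assert report["max_abs_residual"] < 1e-6 * plasma.concentrations.max()
        on_obs = np.isin(rec.time_points, t)
        assert np.max(np.abs(rec.fraction_absorbed[on_obs] - fa_true)) < 0.1


class TestLevy:
    def test_identical_curves(self):
        t = np.arange(0.0, 241.0, 5.0)
        f = np.clip(t / 180.0, 0.0, 1.0)
        fa = AbsorptionProfile(t, f)
        diss = DissolutionProfile(t, 100.0 * f)
        levy = levy_fit(fa, diss)
        assert levy.slope == pytest.approx(1.0, abs=1e-9)
        assert levy.intercept == pytest.approx(0.0, abs=1e-6)
        assert levy.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_time_doubling_gives_slope_two(self):
        t = np.arange(0.0, 241.0, 5.0)
        f = np.clip(t / 180.0, 0.0, 1.0)
        fa = AbsorptionProfile(2.0 * t, f)
        diss = DissolutionProfile(t, 100.0 * f)
        levy = levy_fit(fa, diss)
        assert levy.slope == pytest.approx(2.0, abs=1e-9)
        assert levy.intercept == pytest.approx(0.0, abs=1e-6)

    def test_weibull_vs_shifted_copy(self):
        wb = WeibullParams(B=1.759, MDT=71.55)
        t = np.arange(0.0, 400.25, 0.25)
        fa_vals = np.where(t >= 10.0, weibull_cdf(wb, np.maximum(t - 10.0, 0)) / 100.0, 0.0)
        fa = AbsorptionProfile(t, fa_vals)
        levy = levy_fit(fa, wb)
        assert levy.slope == pytest.approx(1.0, abs=2e-3)
        assert levy.intercept == pytest.approx(10.0, abs=0.3)

    def test_unreachable_level(self):
        t = np.arange(0.0, 61.0, 5.0)
        fa = AbsorptionProfile(t, np.clip(t / 200.0, 0, 1.0))  # tops out at 0.3
        with pytest.raises(ValueError, match="unreachable"):
            levy_fit(fa, WeibullParams(B=1.5, MDT=50.0), levels=(0.5,))


class TestPredictPlasma:
    def test_identity_levy_step_dissolution_reproduces_uir(self, uir):
        levy = LevyModel(slope=1.0, intercept=0.0)
        step = DissolutionProfile(GRID5, np.full_like(GRID5, 100.0))
        plasma, pk = predict_plasma(step, levy, uir, dose=400.0, t_grid=GRID5)
        assert np.allclose(plasma.concentrations, uir.evaluate(GRID5), rtol=1e-12)
        assert pk.tmax == 0.0
        assert pk.Cmax == pytest.approx(uir.A1 + uir.A2, rel=1e-12)

    def test_slower_dissolution_lower_cmax_later_tmax(self, uir):
        levy = LevyModel(slope=1.0, intercept=0.0)
        cmaxes, tmaxes = [], []
        for mdt in (30.0, 50.0, 70.0, 90.0):
            _, pk = predict_plasma(
                WeibullParams(B=1.759, MDT=mdt), levy, uir, dose=400.0
            )
            cmaxes.append(pk.Cmax)
            tmaxes.append(pk.tmax)
        assert np.all(np.diff(cmaxes) < 0)
        assert np.all(np.diff(tmaxes) > 0)

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ValueError, match="slope"):
            LevyModel(slope=0.0, intercept=0.0)


class TestPKSummary:
    def test_triangle_profile(self):
        t = np.array([0.0, 30.0, 60.0])
        c = np.array([0.0, 10.0, 0.0])
        pk = pk_summary(PlasmaProfile(t, c, dose=400.0))
        assert pk.Cmax == 10.0
        assert pk.tmax == 30.0
        assert pk.auc_0_last == pytest.approx(300.0)

    def test_flat_zero(self):
        t = np.array([0.0, 30.0, 60.0])
        pk = pk_summary(PlasmaProfile(t, np.zeros(3), dose=400.0))
        assert pk.Cmax == 0.0

    def test_ratio_against_itself_is_one(self):
        t = np.array([0.0, 30.0, 60.0])
        pk0 = pk_summary(PlasmaProfile(t, np.array([0.0, 10.0, 5.0]), dose=400.0))
        pk1 = pk_summary(PlasmaProfile(t, np.array([0.0, 10.0, 5.0]), dose=400.0), pk0)
        assert pk1.ratio_to_reference == pytest.approx(1.0)


class TestPredictionError:
    def test_identical_summaries(self):
        a = PKSummary(Cmax=37.7, tmax=80.0, auc_0_last=1000.0)
        pe = prediction_error(a, a)
        assert pe["Cmax"] == 0.0 and pe["AUC"] == 0.0

    def test_published_reference_row_arithmetic(self):
        obs = PKSummary(Cmax=37.70, tmax=82.1, auc_0_last=1000.0)
        pred = PKSummary(Cmax=37.80, tmax=81.7, auc_0_last=1000.0)
        assert prediction_error(obs, pred)["Cmax"] == pytest.approx(-0.27, abs=0.005)

    def test_half_prediction(self):
        obs = PKSummary(Cmax=10.0, tmax=1.0, auc_0_last=10.0)
        pred = PKSummary(Cmax=5.0, tmax=1.0, auc_0_last=5.0)
        pe = prediction_error(obs, pred)
        assert pe["Cmax"] == 50.0 and pe["AUC"] == 50.0

    def test_zero_observed_raises(self):
        obs = PKSummary(Cmax=0.0, tmax=1.0, auc_0_last=1.0)
        with pytest.raises(ZeroDivisionError):
            prediction_error(obs, obs)


def test_absorption_profile_validation():
    with pytest.raises(ValueError, match="non-decreasing"):
        AbsorptionProfile(np.array([0.0, 5.0, 10.0]), np.array([0.5, 0.3, 0.8]))
    with pytest.raises(ValueError, match="start at t = 0"):
        AbsorptionProfile(np.array([5.0, 10.0]), np.array([0.0, 0.5]))


def test_plasma_profile_validation():
    with pytest.raises(ValueError, match="negative concentrations"):
        PlasmaProfile(np.array([0.0, 5.0]), np.array([1.0, -0.5]), dose=400.0)
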