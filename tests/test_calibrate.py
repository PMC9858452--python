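"""AUC, correlation screening, calibration fitting and eGI prediction."""

import numpy as np
import pandas as pd
import pytest

from gikit import SimulationConfig, simulate_calibration_study, simulate_digestogram
from gikit.calibrate import (
    auc_analytic,
    auc_trapezoid,
    correlation_screen,
    error_rate,
    fit_calibration,
    predict_egi,
    significance_stars,
)
from gikit.types import Fraction, KineticsFit, Model

from conftest import make_digestogram


def sk_fit(c0, c_inf, k):
    return KineticsFit(model=Model.SK, c0=c0, fractions=[Fraction(c_inf - c0, k, 0.0)],
                       r_squared=1.0, rmse=0.0, converged=True, n_points=10)


class TestAUCAnalytic:
    def test_flat_curve(self):
        fit = KineticsFit(model=Model.SK, c0=5.0, fractions=[Fraction(0.0, 0.01, 0.0)],
                          r_squared=1.0, rmse=0.0, converged=True, n_points=10)
        assert auc_analytic(fit, 100.0).value == pytest.approx(500.0)

    def test_closed_form_oracle(self):
        # C_inf*T - (C_inf - C0)(1 - e^{-kT})/k with C0=0, C_inf=50, k=0.02, T=180
        got = auc_analytic(sk_fit(0.0, 50.0, 0.02), 180.0).value
        assert got == pytest.approx(6568.31, abs=0.005)

    def test_monotone_in_horizon(self):
        fit = sk_fit(0.0, 40.0, 0.03)
        a90, a120, a180 = (auc_analytic(fit, T).value for T in (90, 120, 180))
        assert a90 <= a120 <= a180

    def test_validation(self):
        with pytest.raises(ValueError):
            auc_analytic(sk_fit(0.0, 40.0, 0.03), 0.0)


class TestAUCTrapezoid:
    def test_triangle(self):
        d = make_digestogram([0, 10, 20, 30], [0, 10, 10, 10])
        assert auc_trapezoid(d, 10.0).value == pytest.approx(50.0)

    def test_rectangle(self):
        d = make_digestogram([0, 10, 20, 30], [7, 7, 7, 7])
        assert auc_trapezoid(d, 30.0).value == pytest.approx(210.0)

    def test_leading_flat_segment_when_t0_missing(self):
        d = make_digestogram([10, 20, 30, 40], [4, 4, 4, 4])
        assert auc_trapezoid(d, 40.0).value == pytest.approx(160.0)

    def test_matches_analytic_on_dense_curve(self):
        cfg = SimulationConfig(true_c0=0.0, fractions=[(50.0, 0.02, 0.0)],
                               schedule=np.arange(0.0, 180.001, 0.05),
                               noise_sd=0.0, n_replicates=1)
        d = simulate_digestogram(cfg)[0]
        trap = auc_trapezoid(d, 180.0).value
        ana = auc_analytic(sk_fit(0.0, 50.0, 0.02), 180.0).value
        assert abs(trap - ana) / ana < 1e-3

    def test_refuses_extrapolation(self):
        d = make_digestogram([0, 10, 20, 30], [0, 1, 2, 3])
        with pytest.raises(ValueError, match="auc_analytic"):
            auc_trapezoid(d, 60.0)


class TestCorrelationScreen:
    GI = [9, 9, 11, 13, 13, 13, 16, 30]
    GL = [1.27, 2.00, 2.44, 2.37, 2.35, 2.34, 2.98, 4.76]

    def test_reference_r_squared(self):
        out = correlation_screen(pd.DataFrame({"GI": self.GI}), self.GI, self.GL)
        assert out.loc[0, "r_vs_gl"] ** 2 == pytest.approx(0.933, abs=5e-4)

    def test_self_correlation(self):
        out = correlation_screen(pd.DataFrame({"x": self.GI}), self.GI, self.GL)
        assert out.loc[0, "r_vs_gi"] == pytest.approx(1.0)

    def test_three_point_perfect_line(self):
        out = correlation_screen(pd.DataFrame({"x": [1, 2, 3]}), [2, 4, 6], [1, 2, 3])
        assert out.loc[0, "r_vs_gi"] == pytest.approx(1.0)

    def test_constant_feature_flagged_not_raised(self):
        out = correlation_screen(pd.DataFrame({"x": [5, 5, 5, 5]}),
                                 [1, 2, 3, 4], [1, 2, 3, 4])
        assert bool(out.loc[0, "degenerate"])
        assert np.isnan(out.loc[0, "r_vs_gi"])
        assert out.loc[0, "stars_gi"] == ""

    def test_shift_scale_invariance(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        gi = [10, 20, 15, 40, 25]
        gl = [1, 2, 1.5, 4, 2.5]
        a = correlation_screen(pd.DataFrame({"x": x}), gi, gl)
        b = correlation_screen(pd.DataFrame({"x": 3 * x + 7}), gi, gl)
        assert a.loc[0, "r_vs_gi"] == pytest.approx(b.loc[0, "r_vs_gi"], rel=1e-12)

    def test_needs_three_points(self):
        with pytest.raises(ValueError):
            correlation_screen(pd.DataFrame({"x": [1, 2]}), [1, 2], [1, 2])


class TestSignificanceStars:
    @pytest.mark.parametrize("p,stars", [(0.004, "**"), (0.03, "*"), (0.2, "")])
    def test_convention(self, p, stars):
        assert significance_stars(p) == stars


class TestFitCalibration:
    def test_exact_line_recovery(self):
        x = np.array([500.0, 1000.0, 1800.0, 2500.0, 3400.0])
        y = 1.834 + 0.009 * x
        m = fit_calibration(x, y)
        assert m.intercept_a == pytest.approx(1.834, abs=1e-10)
        assert m.slope_b == pytest.approx(0.009, abs=1e-12)
        assert m.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_normal_equation_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 7.0])
        y = np.array([3.0, 5.0, 4.0, 10.0])
        m = fit_calibration(x, y)
        sxx = np.sum((x - x.mean()) ** 2)
        slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
        intercept = y.mean() - slope * x.mean()
        assert m.slope_b == pytest.approx(slope, rel=1e-12)
        assert m.intercept_a == pytest.approx(intercept, rel=1e-12)

    def test_monte_carlo_slope_recovery(self):
        rng = np.random.default_rng(99)
        slopes = []
        for _ in range(500):
            x = rng.uniform(500, 3500, size=8) + rng.normal(0, 50, size=8)
            y = 1.834 + 0.009 * x + rng.normal(0, 1.0, size=8)
            slopes.append(fit_calibration(x, y).slope_b)
        assert abs(np.mean(slopes) - 0.009) / 0.009 < 0.05

    def test_constant_predictor_errors(self):
        with pytest.raises(ValueError, match="constant"):
            fit_calibration([5.0, 5.0, 5.0, 5.0], [1, 2, 3, 4])


class TestPredictEGI:
    def test_published_pancreatin_line(self):
        from gikit.reference import CALIBRATION_PANCREATIN
        p = predict_egi(CALIBRATION_PANCREATIN, 1000.0)
        assert p.egi == pytest.approx(10.834, abs=1e-12)
        assert p.egi_sd is None

    def test_published_amylase_intercept(self):
        from gikit.reference import CALIBRATION_AMYLASE
        assert predict_egi(CALIBRATION_AMYLASE, 0.0).egi == pytest.approx(6.101)

    def test_zero_leverage_prediction_se(self):
        x = np.array([500.0, 1200.0, 2000.0, 2600.0, 3400.0])
        y = 1.834 + 0.009 * x + np.array([0.4, -0.2, 0.1, -0.5, 0.3])
        m = fit_calibration(x, y)
        p = predict_egi(m, float(x.mean()))
        assert p.egi_sd == pytest.approx(
            m.residual_se * np.sqrt(1.0 + 1.0 / m.n), rel=1e-12)

    def test_replicate_sd_in_quadrature(self):
        from gikit.reference import CALIBRATION_PANCREATIN
        p = predict_egi(CALIBRATION_PANCREATIN, 1000.0, aucr180_sd=100.0)
        assert p.egi_sd == pytest.approx(0.009 * 100.0)

    def test_error_rate_attached(self):
        from gikit.reference import CALIBRATION_PANCREATIN
        p = predict_egi(CALIBRATION_PANCREATIN, 1000.0, clinical_gi=10.0)
        assert p.error_rate_pct == pytest.approx(8.34, abs=0.005)

    def test_negative_aucr_rejected(self):
        from gikit.reference import CALIBRATION_PANCREATIN
        with pytest.raises(ValueError):
            predict_egi(CALIBRATION_PANCREATIN, -1.0)


class TestErrorRate:
    @pytest.mark.parametrize("gi,egi,expected", [
        (9, 12.30, 36.67),
        (52, 39.96, 23.15),
        (30, 30, 0.0),
    ])
    def test_examples(self, gi, egi, expected):
        assert error_rate(gi, egi) == expected

    def test_nonpositive_gi(self):
        with pytest.raises(ValueError):
            error_rate(0.0, 10.0)


class TestEndToEndRecovery:
    def test_noiseless_study_identifies_line_exactly(self):
        from gikit.kinetics import fit_sk
        study = simulate_calibration_study(
            n_samples=6, gi_noise_sd=0.0, digestogram_noise_sd=0.0,
            n_replicates=1, seed=3)
        aucr = [auc_analytic(fit_sk(d), 180.0).value for d in study.digestograms]
        m = fit_calibration(aucr, [meta.clinical_gi for meta in study.metas])
        assert m.intercept_a == pytest.approx(1.834, abs=1e-4)
        assert m.slope_b == pytest.approx(0.009, rel=1e-5)
        assert m.r_squared == pytest.approx(1.0, abs=1e-9)
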