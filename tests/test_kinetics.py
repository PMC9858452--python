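"""LOS transform, fraction counting and SK/CPS model fitting."""

import numpy as np
import pytest

from gikit import SimulationConfig, simulate_digestogram
from gikit.kinetics import count_fractions, fit_cps, fit_sk, los_transform
from gikit.types import Schedule

from conftest import CPS_TRUTH, SK_TRUTH, make_digestogram


class TestLOSTransform:
    def test_strictly_increasing_keeps_everything(self, sk_digestogram):
        los = los_transform(sk_digestogram)
        assert los.n_dropped == 0
        assert len(los.t_mid) == len(sk_digestogram) - 1

    def test_constant_series_raises(self):
        d = make_digestogram([0, 5, 10, 15, 20], [3.0] * 5)
        with pytest.raises(ValueError, match="insufficient LOS points"):
            los_transform(d)

    def test_flat_interval_dropped(self):
        d = make_digestogram([0, 5, 10, 15, 20], [0, 2, 2, 5, 6])
        los = los_transform(d)
        assert los.n_dropped == 1
        assert len(los.t_mid) == 3

    def test_midpoints_and_log_slopes(self):
        d = make_digestogram([0, 10, 20, 40], [0.0, 5.0, 8.0, 10.0])
        los = los_transform(d)
        assert los.t_mid.tolist() == [5.0, 15.0, 30.0]
        np.testing.assert_allclose(
            los.ln_slope, np.log([5 / 10, 3 / 10, 2 / 20]), rtol=1e-12)

    def test_dense_exact_sk_is_linear(self):
        cfg = SimulationConfig(true_c0=0.0, fractions=[(40.0, 0.03, 0.0)],
                               schedule=np.arange(0.0, 240.5, 1.0),
                               noise_sd=0.0, n_replicates=1)
        los = count_fractions(los_transform(simulate_digestogram(cfg)[0]),
                              max_fractions=1)
        seg = los.segments[0]
        assert seg.r_squared > 0.999
        assert -seg.slope == pytest.approx(0.03, rel=0.005)


class TestCountFractions:
    def test_sk_data_one_fraction(self, sk_digestogram):
        assert count_fractions(los_transform(sk_digestogram)).n_fractions == 1

    def test_cps_data_two_fractions(self, cps_digestogram):
        assert count_fractions(los_transform(cps_digestogram)).n_fractions == 2

    def test_four_points_fallback(self):
        d = make_digestogram([0, 10, 20, 40, 80],
                             [0.0, 5.0, 8.0, 10.0, 10.5])  # 4 LOS points
        los = count_fractions(los_transform(d))
        assert los.n_fractions == 1

    def test_value_domain_veto_on_sk_data(self, sk_digestogram):
        # with the originating digestogram supplied the verdict must still be 1
        los = count_fractions(los_transform(sk_digestogram),
                              digestogram=sk_digestogram)
        assert los.n_fractions == 1

    def test_segments_ordered_fast_then_slow(self, cps_digestogram):
        los = count_fractions(los_transform(cps_digestogram),
                              digestogram=cps_digestogram)
        assert los.n_fractions == 2
        s1, s2 = los.segments
        assert s1.slope < s2.slope < 0  # first pool decays faster
        assert -s1.slope == pytest.approx(0.1, rel=0.05)
        # the first slow-pool interval still carries the fast pool's tail,
        # so the second slope is only loosely -k2
        assert -s2.slope == pytest.approx(0.01, rel=0.30)


class TestFitSK:
    def test_noiseless_recovery(self, sk_digestogram):
        fit = fit_sk(sk_digestogram)
        assert fit.converged
        assert fit.c_inf_total == pytest.approx(SK_TRUTH["c_inf"], rel=1e-6)
        assert fit.fractions[0].k == pytest.approx(SK_TRUTH["k"], rel=1e-6)
        assert fit.c0 == pytest.approx(SK_TRUTH["c0"], abs=1e-5)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_monte_carlo_k_bias(self):
        # 200 seeded noisy realizations, additive sd=0.5: mean bias of k small
        rng = np.random.default_rng(1234)
        ks = []
        for _ in range(200):
            cfg = SimulationConfig(
                true_c0=0.0, fractions=[(40.0, 0.03, 0.0)],
                schedule=Schedule.SINGLE_ENZYME, noise_sd=0.5,
                n_replicates=1, seed=int(rng.integers(0, 2**31 - 1)))
            ks.append(fit_sk(simulate_digestogram(cfg)[0]).fractions[0].k)
        assert abs(np.mean(ks) - 0.03) < 0.002

    def test_bias_shrinks_with_noise(self):
        def mean_abs_err(sd, n=60):
            rng = np.random.default_rng(77)
            errs = []
            for _ in range(n):
                cfg = SimulationConfig(
                    true_c0=0.0, fractions=[(40.0, 0.03, 0.0)],
                    schedule=Schedule.SINGLE_ENZYME, noise_sd=sd,
                    n_replicates=1, seed=int(rng.integers(0, 2**31 - 1)))
                errs.append(abs(fit_sk(simulate_digestogram(cfg)[0]).fractions[0].k - 0.03))
            return float(np.mean(errs))

        e10, e05, e01 = mean_abs_err(1.0), mean_abs_err(0.5), mean_abs_err(0.1)
        assert e01 < e05 < e10

    def test_rss_not_worse_than_truth(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            cfg = SimulationConfig(
                true_c0=0.0, fractions=[(40.0, 0.03, 0.0)],
                schedule=Schedule.SINGLE_ENZYME, noise_sd=0.5,
                n_replicates=1, seed=int(rng.integers(0, 2**31 - 1)))
            d = simulate_digestogram(cfg)[0]
            fit = fit_sk(d)
            rss_fit = float(np.sum((d.values - fit.predict(d.times)) ** 2))
            rss_true = float(np.sum((d.values - cfg.truth_fit().predict(d.times)) ** 2))
            assert rss_fit <= rss_true + 1e-9

    def test_input_validation(self):
        with pytest.raises(ValueError, match="non-constant"):
            fit_sk(make_digestogram([0, 5, 10, 15], [2.0] * 4))


class TestFitCPS:
    def test_noiseless_recovery(self, cps_digestogram):
        fit = fit_cps(cps_digestogram, 2)
        for est, (c, k, ts) in zip(fit.fractions, CPS_TRUTH):
            assert est.c_inf == pytest.approx(c, rel=1e-4)
            assert est.k == pytest.approx(k, rel=1e-4)
            if ts > 0:
                assert est.t_start == pytest.approx(ts, rel=1e-4)

    def test_one_fraction_reduces_to_sk(self, sk_digestogram):
        a, b = fit_cps(sk_digestogram, 1), fit_sk(sk_digestogram)
        assert a.model == b.model
        assert a.c0 == b.c0
        assert a.fractions[0].k == b.fractions[0].k

    def test_nesting_rss(self, cps_digestogram):
        d = cps_digestogram
        rss_cps = float(np.sum((d.values - fit_cps(d, 2).predict(d.times)) ** 2))
        rss_sk = float(np.sum((d.values - fit_sk(d).predict(d.times)) ** 2))
        assert rss_cps <= rss_sk + 1e-9

    def test_too_few_points(self):
        d = make_digestogram([0, 5, 10, 15, 20], [0, 1, 2, 3, 4])
        with pytest.raises(ValueError, match="needs >= 9 points"):
            fit_cps(d, 2)
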