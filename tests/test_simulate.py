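"""Synthetic-data generators: determinism, noise model, inverse conversion."""

import numpy as np
import pytest

from gikit import (
    SimulationConfig,
    simulate_absorbance_series,
    simulate_calibration_study,
    simulate_digestogram,
)
from gikit.calibrate import auc_analytic
from gikit.convert import absorbance_to_percent_digested
from gikit.simulate import forward_model
from gikit.types import Basis, ConversionConstants, SampleMeta, Schedule


class TestSimulateDigestogram:
    def test_noiseless_equals_forward_model(self, sk_config):
        d = simulate_digestogram(sk_config)[0]
        np.testing.assert_allclose(d.values, forward_model(sk_config, d.times))

    def test_same_seed_identical(self):
        cfg = SimulationConfig(noise_sd=0.5, seed=21)
        assert simulate_digestogram(cfg) == simulate_digestogram(cfg)

    def test_different_seeds_differ(self):
        a = simulate_digestogram(SimulationConfig(noise_sd=0.5, seed=21))[0]
        b = simulate_digestogram(SimulationConfig(noise_sd=0.5, seed=22))[0]
        assert not np.array_equal(a.values, b.values)

    def test_noise_sd_matches_model(self):
        cfg = SimulationConfig(noise_sd=0.5, n_replicates=1000, seed=8)
        digs = simulate_digestogram(cfg)
        values = np.stack([d.values for d in digs])
        sds = values.std(axis=0, ddof=1)
        assert np.all(sds > 0.45) and np.all(sds < 0.55)

    def test_values_nonnegative(self):
        cfg = SimulationConfig(true_c0=0.0, fractions=[(1.0, 0.001, 0.0)],
                               noise_sd=2.0, n_replicates=50, seed=4)
        for d in simulate_digestogram(cfg):
            assert np.all(d.values >= 0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SimulationConfig(noise_sd=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(fractions=[(10.0, 0.0, 0.0)])


class TestSimulateAbsorbance:
    def setup_method(self):
        self.meta = SampleMeta("s", sample_mass_mg=2000.0,
                               total_starch_pct_db=25.0, total_carb_pct=50.0)
        self.consts = ConversionConstants(dilution_factor=750.0)

    def test_round_trip_noiseless(self, sk_config):
        recs = simulate_absorbance_series(sk_config, self.meta, self.consts)
        truth = forward_model(sk_config, sk_config.times)
        got = [absorbance_to_percent_digested(r, self.meta, self.consts) for r in recs]
        np.testing.assert_allclose(got, truth, atol=1e-9)

    def test_standard_scaling_invariance(self, sk_config):
        a = simulate_absorbance_series(sk_config, self.meta, self.consts, dA_standard=0.8)
        b = simulate_absorbance_series(sk_config, self.meta, self.consts, dA_standard=0.4)
        va = [absorbance_to_percent_digested(r, self.meta, self.consts) for r in a]
        vb = [absorbance_to_percent_digested(r, self.meta, self.consts) for r in b]
        np.testing.assert_allclose(va, vb, rtol=1e-12)


class TestCalibrationStudy:
    def test_deterministic(self):
        a = simulate_calibration_study(seed=13)
        b = simulate_calibration_study(seed=13)
        assert a.digestograms == b.digestograms
        assert [m.clinical_gi for m in a.metas] == [m.clinical_gi for m in b.metas]

    def test_noiseless_auc_hits_target(self):
        from gikit.types import Fraction, KineticsFit, Model
        study = simulate_calibration_study(gi_noise_sd=0.0,
                                           digestogram_noise_sd=0.0, seed=6)
        for (c_inf, k), target in zip(study.true_params, study.true_aucr):
            fit = KineticsFit(model=Model.SK, c0=0.0,
                              fractions=[Fraction(c_inf, k, 0.0)],
                              r_squared=1.0, rmse=0.0, converged=True, n_points=10)
            assert auc_analytic(fit, 180.0).value == pytest.approx(target, rel=1e-6)

    def test_noiseless_gi_on_line(self):
        study = simulate_calibration_study(gi_noise_sd=0.0,
                                           digestogram_noise_sd=0.0, seed=6)
        for meta, target in zip(study.metas, study.true_aucr):
            assert meta.clinical_gi == pytest.approx(1.834 + 0.009 * target, rel=1e-12)

    def test_study_shape(self):
        study = simulate_calibration_study(n_samples=5, n_replicates=2, seed=2)
        assert len(study.metas) == 5
        assert len(study.digestograms) == 10
        assert all(d.basis is Basis.REDUCING_SUGAR_NORMALIZED
                   for d in study.digestograms)
        assert all(np.array_equal(d.times, Schedule.SINGLE_ENZYME.times)
                   for d in study.digestograms)

    def test_validation(self):
        with pytest.raises(ValueError):
            simulate_calibration_study(n_samples=3)
        with pytest.raises(ValueError):
            simulate_calibration_study(slope=0.0)
        with pytest.raises(ValueError):
            simulate_calibration_study(aucr_range=(10.0, 5.0))
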