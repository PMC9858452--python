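"""Shared fixtures: canonical truths, digestograms and conversion setups."""

from __future__ import annotations

import numpy as np
import pytest

from gikit import SimulationConfig, simulate_digestogram
from gikit.types import (
    AbsorbanceRecord,
    Basis,
    ConversionConstants,
    Digestogram,
    Protocol,
    SampleMeta,
    Schedule,
)

SK_TRUTH = dict(c0=0.0, c_inf=40.0, k=0.03)
CPS_TRUTH = [(30.0, 0.1, 0.0), (20.0, 0.01, 30.0)]


@pytest.fixture
def sk_config() -> SimulationConfig:
    return SimulationConfig(
        true_c0=SK_TRUTH["c0"],
        fractions=[(SK_TRUTH["c_inf"], SK_TRUTH["k"], 0.0)],
        schedule=Schedule.SINGLE_ENZYME,
        noise_sd=0.0,
        n_replicates=1,
    )


@pytest.fixture
def sk_digestogram(sk_config) -> Digestogram:
    return simulate_digestogram(sk_config)[0]


@pytest.fixture
def cps_config() -> SimulationConfig:
    return SimulationConfig(
        true_c0=0.0,
        fractions=list(CPS_TRUTH),
        schedule=Schedule.SINGLE_ENZYME,
        noise_sd=0.0,
        n_replicates=1,
    )


@pytest.fixture
def cps_digestogram(cps_config) -> Digestogram:
    return simulate_digestogram(cps_config)[0]


@pytest.fixture
def oracle_record() -> AbsorbanceRecord:
    """The hand-chained conversion oracle reading: 0.5 mmol/L in a 100 uL aliquot."""
    return AbsorbanceRecord(
        sample_id="S", protocol=Protocol.INFOGEST, replicate=1, time_min=30.0,
        dA_sample=0.4, dA_standard=0.8,
        standard_conc_mmol_per_L=1.0, aliquot_volume_uL=100.0,
    )


@pytest.fixture
def oracle_meta() -> SampleMeta:
    """500 mg starch and 1000 mg carbohydrate loaded in the vessel."""
    return SampleMeta(
        sample_id="S", sample_mass_mg=2000.0,
        total_starch_pct_db=25.0, total_carb_pct=50.0,
    )


@pytest.fixture
def infogest_consts() -> ConversionConstants:
    return ConversionConstants(dilution_factor=2500.0)


@pytest.fixture
def noisy_digestograms() -> list[Digestogram]:
    cfg = SimulationConfig(
        true_c0=0.0, fractions=[(40.0, 0.03, 0.0)],
        schedule=Schedule.SINGLE_ENZYME, noise_sd=0.5,
        n_replicates=2, seed=11,
        basis=Basis.REDUCING_SUGAR_NORMALIZED,
    )
    return simulate_digestogram(cfg)


def make_digestogram(times, values, **kw) -> Digestogram:
    defaults = dict(sample_id="d", protocol=Protocol.PANCREATIN, replicate=1,
                    basis=Basis.REDUCING_SUGAR_NORMALIZED)
    defaults.update(kw)
    return Digestogram(times=np.asarray(times, float),
                       values=np.asarray(values, float), **defaults)
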