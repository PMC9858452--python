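"""Synthetic digestograms, absorbance series and calibration studies.

Laboratory digestion data is emulated by evaluating the SK/CPS forward
model on a preset aliquot schedule and adding i.i.d. Gaussian assay noise
(homoscedastic, truncated at zero), in duplicate by default — the replicate
structure of a plate-based reducing-sugar assay. Every generator is
deterministic under a fixed seed.

``simulate_calibration_study`` builds a full panel the way a calibration
experiment is designed: target AUCR180 values are drawn uniformly, SK
parameters solved to hit each target exactly (C0 = 0, rate drawn, asymptote
solved), and clinical GI assigned on a known line plus noise — so every
downstream stage has a known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np

from .types import (
    AbsorbanceRecord,
    Basis,
    ConversionConstants,
    Digestogram,
    Fraction,
    KineticsFit,
    Model,
    Protocol,
    SampleMeta,
    Schedule,
)

__all__ = [
    "SimulationConfig",
    "forward_model",
    "simulate_digestogram",
    "simulate_absorbance_series",
    "simulate_calibration_study",
    "CalibrationStudy",
]

DEFAULT_SCHEDULE = Schedule.SINGLE_ENZYME


@dataclass
class SimulationConfig:
    """Ground truth and sampling design for one simulated sample.

    ``fractions`` lists (c_inf, k, t_start) pools of the generating model
    (one pool → SK truth); ``noise_sd`` is the additive Gaussian SD on
    digestogram values; duplicates by default, matching assay practice.
    """

    true_c0: float = 0.0
    fractions: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(40.0, 0.03, 0.0)]
    )
    schedule: Union[Schedule, Sequence[float]] = DEFAULT_SCHEDULE
    noise_sd: float = 0.5
    n_replicates: int = 2
    seed: int = 0
    sample_id: str = "sim"
    protocol: Protocol = Protocol.PANCREATIN
    basis: Basis = Basis.PERCENT_STARCH

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        for c, k, ts in self.fractions:
            if k <= 0:
                raise ValueError("every fraction needs k > 0")
            if c < 0 or ts < 0:
                raise ValueError("fractions need c_inf >= 0 and t_start >= 0")

    @property
    def times(self) -> np.ndarray:
        if isinstance(self.schedule, Schedule):
            return self.schedule.times
        times = np.asarray(self.schedule, dtype=float)
        if not np.all(np.diff(times) > 0):
            raise ValueError("schedule times must be strictly increasing")
        return times

    def truth_fit(self) -> KineticsFit:
        """The generating parameters wrapped as a KineticsFit (for oracles)."""
        fracs = [Fraction(c, k, ts) for c, k, ts in self.fractions]
        model = Model.SK if len(fracs) == 1 and fracs[0].t_start == 0 else Model.CPS
        return KineticsFit(
            model=model, c0=self.true_c0, fractions=fracs,
            r_squared=1.0, rmse=0.0, converged=True, n_points=len(self.times),
        )


def forward_model(cfg: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Noise-free SK/CPS digestion extent at times ``t``."""
    return cfg.truth_fit().predict(t)


def simulate_digestogram(cfg: SimulationConfig) -> list[Digestogram]:
    """One noisy digestogram per replicate; values truncated at zero."""
    rng = np.random.default_rng(cfg.seed)
    t = cfg.times
    truth = forward_model(cfg, t)
    out = []
    for rep in range(1, cfg.n_replicates + 1):
        values = truth + rng.normal(0.0, cfg.noise_sd, size=t.shape) if cfg.noise_sd > 0 else truth.copy()
        values = np.clip(values, 0.0, None)
        out.append(
            Digestogram(
                sample_id=cfg.sample_id, protocol=cfg.protocol, replicate=rep,
                basis=cfg.basis, times=t, values=values,
            )
        )
    return out


def simulate_absorbance_series(
    cfg: SimulationConfig,
    meta: SampleMeta,
    consts: ConversionConstants,
    dA_standard: float = 0.8,
) -> list[AbsorbanceRecord]:
    """Absorbance records whose conversion reproduces the simulated digestogram.

    Inverts the percent-starch conversion chain exactly, so with
    ``noise_sd = 0`` :func:`gikit.convert.absorbance_to_percent_digested`
    recovers the forward-model values to round-off.
    """
    starch_mg = meta.starch_mass_mg
    records: list[AbsorbanceRecord] = []
    scale = (
        1e-4 * consts.maltose_mw * consts.dilution_factor
        * consts.starch_to_maltose_weight_ratio / starch_mg * 100.0
    )  # percent digested per (dA_sample/dA_standard) at 1 mmol/L, 100 uL
    for dg in simulate_digestogram(cfg):
        for t, v in zip(dg.times, dg.values):
            records.append(
                AbsorbanceRecord(
                    sample_id=cfg.sample_id, protocol=cfg.protocol,
                    replicate=dg.replicate, time_min=float(t),
                    dA_sample=float(v / scale * dA_standard),
                    dA_standard=dA_standard,
                    standard_conc_mmol_per_L=1.0,
                    aliquot_volume_uL=100.0,
                )
            )
    return records


@dataclass
class CalibrationStudy:
    """A simulated calibration panel with its generating truth."""

    metas: list[SampleMeta]
    digestograms: list[Digestogram]
    true_intercept: float
    true_slope: float
    true_aucr: np.ndarray
    true_params: list[tuple[float, float]]  # (c_inf, k) per sample, C0 = 0


def _solve_c_inf(target_auc: float, k: float, T: float = 180.0) -> float:
    """C_inf such that the SK curve (C0 = 0) has analytic AUC = target over [0, T]."""
    denom = T - (1.0 - np.exp(-k * T)) / k
    return target_auc / denom


def simulate_calibration_study(
    n_samples: int = 8,
    intercept: float = 1.834,
    slope: float = 0.009,
    aucr_range: tuple[float, float] = (500.0, 3500.0),
    gi_noise_sd: float = 1.0,
    digestogram_noise_sd: float = 0.3,
    seed: int = 0,
    n_replicates: int = 2,
    schedule: Union[Schedule, Sequence[float]] = Schedule.SINGLE_ENZYME,
    max_retries: int = 20,
) -> CalibrationStudy:
    """Panel of samples whose AUCR180 ↔ GI relation is known exactly.

    Per sample: AUCR180 target ~ U(aucr_range); k ~ U(0.005, 0.05) /min;
    C0 = 0 and C_inf solved so the analytic 180-min AUC hits the target;
    GI = intercept + slope·AUCR + N(0, gi_noise_sd²); noisy duplicate
    digestograms emitted on the given schedule.
    """
    if n_samples < 4:
        raise ValueError("a calibration study needs n_samples >= 4")
    lo, hi = aucr_range
    if not lo < hi:
        raise ValueError("aucr_range must satisfy lo < hi")
    if slope == 0:
        raise ValueError("slope must be nonzero")
    rng = np.random.default_rng(seed)
    metas, digs, params = [], [], []
    targets = rng.uniform(lo, hi, size=n_samples)
    for i, target in enumerate(targets):
        c_inf = -1.0
        for _ in range(max_retries):
            k = rng.uniform(0.005, 0.05)
            c_inf = _solve_c_inf(target, k)
            if c_inf > 0:
                break
        if c_inf <= 0:
            raise RuntimeError(f"could not solve C_inf for AUCR target {target:.1f}")
        gi = intercept + slope * target + rng.normal(0.0, gi_noise_sd) if gi_noise_sd > 0 \
            else intercept + slope * target
        sid = f"sim{i + 1:02d}"
        metas.append(SampleMeta(sample_id=sid, clinical_gi=max(gi, 1e-6)))
        cfg = SimulationConfig(
            true_c0=0.0, fractions=[(float(c_inf), float(k), 0.0)],
            schedule=schedule, noise_sd=digestogram_noise_sd,
            n_replicates=n_replicates,
            seed=int(rng.integers(0, 2**31 - 1)),
            sample_id=sid, protocol=Protocol.PANCREATIN,
            basis=Basis.REDUCING_SUGAR_NORMALIZED,
        )
        digs.extend(simulate_digestogram(cfg))
        params.append((float(c_inf), float(k)))
    return CalibrationStudy(
        metas=metas, digestograms=digs,
        true_intercept=intercept, true_slope=slope,
        true_aucr=targets, true_params=params,
    )
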