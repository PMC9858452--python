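"""Core data types for digestion time series, kinetic fits and calibration models.

The pipeline's vocabulary:

* A *digestogram* is the time course of digestion extent for one sample under
  one digestion protocol — either the percentage of starch digested or the
  released reducing sugar normalized to total carbohydrates (both ``×100``).
* Kinetic fits describe digestograms with first-order models: a single
  first-order (SK) pool, or a combination of parallel and sequential (CPS)
  pools, later pools switching on at an onset time.
* A calibration model is the ordinary-least-squares line mapping a digestogram
  summary statistic (AUCR180, the 180-min reducing-sugar-basis area under the
  curve) to clinical glycemic index (GI).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "Protocol",
    "Basis",
    "Schedule",
    "SampleMeta",
    "AbsorbanceRecord",
    "ConversionConstants",
    "Digestogram",
    "LOSResult",
    "LOSSegment",
    "Fraction",
    "KineticsFit",
    "AUCMetrics",
    "CalibrationModel",
    "PredictionResult",
]


class Protocol(str, Enum):
    """Which in vitro digestion protocol produced a measurement."""

    INFOGEST = "INFOGEST"
    PANCREATIN = "PANCREATIN"
    AMYLASE = "AMYLASE"


class Basis(str, Enum):
    """Units of a digestogram's values."""

    PERCENT_STARCH = "PERCENT_STARCH"
    REDUCING_SUGAR_NORMALIZED = "REDUCING_SUGAR_NORMALIZED"


class Schedule(str, Enum):
    """Preset aliquot-sampling schedules (minutes)."""

    INFOGEST_INTESTINAL = "INFOGEST_INTESTINAL"
    SINGLE_ENZYME = "SINGLE_ENZYME"

    @property
    def times(self) -> np.ndarray:
        return np.asarray(SCHEDULE_TIMES[self], dtype=float)


#: Intestinal-phase aliquot times of the standardized INFOGEST static protocol,
#: and the aliquot times of the single-enzyme (pancreatin / alpha-amylase) assay.
SCHEDULE_TIMES = {
    Schedule.INFOGEST_INTESTINAL: (0.0, 5.0, 10.0, 15.0, 20.0, 30.0, 60.0, 90.0, 120.0),
    Schedule.SINGLE_ENZYME: (5.0, 10.0, 15.0, 20.0, 30.0, 60.0, 90.0, 120.0, 180.0, 240.0),
}


def _check_pct(name: str, value: Optional[float]) -> None:
    if value is not None and not (0.0 <= value <= 100.0):
        raise ValueError(f"{name} must lie in [0, 100], got {value!r}")


@dataclass(frozen=True)
class SampleMeta:
    """Composition and clinical metadata for one food sample.

    Percentages refer to the sample as analysed (total starch on a dry basis);
    ``sample_mass_mg`` is the mass loaded into the digestion vessel under the
    protocol in question.
    """

    sample_id: str
    clinical_gi: Optional[float] = None
    total_carb_pct: Optional[float] = None
    total_starch_pct_db: Optional[float] = None
    protein_pct: Optional[float] = None
    fat_pct: Optional[float] = None
    moisture_pct: Optional[float] = None
    free_sugar_pct: Optional[float] = None
    sample_mass_mg: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("total_carb_pct", "total_starch_pct_db", "protein_pct",
                     "fat_pct", "moisture_pct", "free_sugar_pct"):
            _check_pct(name, getattr(self, name))
        if self.clinical_gi is not None and self.clinical_gi <= 0:
            raise ValueError("clinical_gi must be > 0 when present")
        if self.sample_mass_mg is not None and self.sample_mass_mg <= 0:
            raise ValueError("sample_mass_mg must be > 0")

    @property
    def starch_mass_mg(self) -> float:
        """Starch substrate mass (mg, dry basis) in the digestion vessel."""
        if self.sample_mass_mg is None or self.total_starch_pct_db is None:
            raise ValueError(f"{self.sample_id}: sample mass and starch % required")
        return self.sample_mass_mg * self.total_starch_pct_db / 100.0

    @property
    def carb_mass_mg(self) -> float:
        """Total carbohydrate mass (mg) in the digestion vessel."""
        if self.sample_mass_mg is None or self.total_carb_pct is None:
            raise ValueError(f"{self.sample_id}: sample mass and carbohydrate % required")
        return self.sample_mass_mg * self.total_carb_pct / 100.0


@dataclass(frozen=True)
class AbsorbanceRecord:
    """One reducing-sugar assay reading (sample vs maltose standard).

    ``dA_sample`` and ``dA_standard`` are background-corrected absorbance
    differences; the standard is read per ``standard_conc_mmol_per_L`` of
    maltose (default 1 mmol/L).
    """

    sample_id: str
    protocol: Protocol
    replicate: int
    time_min: float
    dA_sample: float
    dA_standard: float
    standard_conc_mmol_per_L: float = 1.0
    aliquot_volume_uL: float = 100.0

    def __post_init__(self) -> None:
        if self.dA_standard <= 0:
            raise ValueError("dA_standard must be > 0")
        if self.time_min < 0:
            raise ValueError("time_min must be >= 0")
        if self.dA_sample < 0:
            raise ValueError("dA_sample must be >= 0")
        if self.replicate < 1:
            raise ValueError("replicate must be >= 1")


#: Maltose molecular weight, mg/mmol.
MALTOSE_MW = 342.0
#: Weight ratio converting maltose (MW 342) to its two anhydroglucose
#: units (2 x 162 = 324), i.e. maltose mass -> starch-equivalent mass.
STARCH_TO_MALTOSE_WEIGHT_RATIO = 324.0 / 342.0

#: Printed protocol dilution multiples: 50 x 50 (INFOGEST, 50 mL vessel) and
#: 5 x 150 (single-enzyme, 18 mL vessel). These are kept as the defaults even
#: though they disagree with the vessel-volume arithmetic; override via config.
DEFAULT_DILUTION = {
    Protocol.INFOGEST: 2500.0,
    Protocol.PANCREATIN: 750.0,
    Protocol.AMYLASE: 750.0,
}


@dataclass(frozen=True)
class ConversionConstants:
    """Constants of the absorbance → digestion-extent conversion chain."""

    dilution_factor: float
    maltose_mw: float = MALTOSE_MW
    starch_to_maltose_weight_ratio: float = STARCH_TO_MALTOSE_WEIGHT_RATIO

    def __post_init__(self) -> None:
        if self.dilution_factor <= 0:
            raise ValueError("dilution_factor must be > 0")

    @classmethod
    def for_protocol(cls, protocol: Protocol) -> "ConversionConstants":
        return cls(dilution_factor=DEFAULT_DILUTION[Protocol(protocol)])


class Digestogram:
    """Digestion extent versus time for one sample × protocol × replicate.

    ``values`` are percent starch digested (``PERCENT_STARCH``) or reducing
    sugar normalized to total carbohydrates ×100
    (``REDUCING_SUGAR_NORMALIZED``). Values above 100 on the starch basis are
    tolerated up to 110 (assay overshoot) and flagged, never clipped.
    """

    __slots__ = ("sample_id", "protocol", "replicate", "basis", "times", "values")

    def __init__(
        self,
        sample_id: str,
        protocol: Protocol,
        replicate: int,
        basis: Basis,
        times: Sequence[float],
        values: Sequence[float],
    ) -> None:
        times = np.asarray(times, dtype=float)
        values = np.asarray(values, dtype=float)
        if times.ndim != 1 or times.shape != values.shape:
            raise ValueError("times and values must be 1-D of equal length")
        if len(times) < 4:
            raise ValueError("a digestogram needs at least 4 timepoints")
        if not np.all(np.diff(times) > 0):
            raise ValueError(f"{sample_id}: times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError(f"{sample_id}: negative digestion values")
        basis = Basis(basis)
        if basis is Basis.PERCENT_STARCH and np.any(values > 110.0):
            raise ValueError(f"{sample_id}: percent digested exceeds 110%")
        self.sample_id = sample_id
        self.protocol = Protocol(protocol)
        self.replicate = int(replicate)
        self.basis = basis
        self.times = times
        self.values = values

    @property
    def overshoot(self) -> bool:
        """True when any percent-starch value exceeds 100% (flag, not error)."""
        return self.basis is Basis.PERCENT_STARCH and bool(np.any(self.values > 100.0))

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Digestogram):
            return NotImplemented
        return (
            self.sample_id == other.sample_id
            and self.protocol == other.protocol
            and self.replicate == other.replicate
            and self.basis == other.basis
            and np.array_equal(self.times, other.times)
            and np.array_equal(self.values, other.values)
        )

    def __repr__(self) -> str:
        return (
            f"Digestogram({self.sample_id!r}, {self.protocol.value}, "
            f"rep={self.replicate}, {self.basis.value}, n={len(self)})"
        )


@dataclass(frozen=True)
class LOSSegment:
    """One fitted linear segment of a logarithm-of-slope plot."""

    slope: float          # 1/min; equals -k for a first-order pool
    intercept: float      # ln(value units / min)
    t_range: tuple[float, float]
    r_squared: float
    n_points: int


@dataclass
class LOSResult:
    """Logarithm-of-slope (LOS) transform of a digestogram.

    ``points`` holds (interval midpoint, ln of the discrete slope) for every
    interval with a positive increment; flat or decreasing intervals are
    counted in ``n_dropped`` (the log is undefined there). Linear segments and
    the inferred number of digestible fractions are filled by
    :func:`gikit.kinetics.count_fractions`.
    """

    points: np.ndarray                      # shape (m, 2): t_mid, ln_slope
    n_dropped: int
    segments: list[LOSSegment] = field(default_factory=list)
    n_fractions: int = 0
    #: retained per-interval increments C_{i+1} - C_i; under additive value
    #: noise var(ln_slope_i) ~ 2 sigma^2 / increment_i^2 (delta method), so
    #: segment fitting weights points by increment^2 when these are present
    increments: Optional[np.ndarray] = None
    #: retained interval widths t_{i+1} - t_i; a discrete slope over width
    #: delta overstates the midpoint derivative of an exponential by
    #: sinh(k delta/2)/(k delta/2), which segment fitting corrects for
    interval_widths: Optional[np.ndarray] = None
    #: every interval's midpoint and increment, dropped ones included —
    #: net progress over a time span telescopes from these, which the
    #: retained (positive-only) increments would overstate
    all_t_mid: Optional[np.ndarray] = None
    all_increments: Optional[np.ndarray] = None

    @property
    def t_mid(self) -> np.ndarray:
        return self.points[:, 0]

    @property
    def ln_slope(self) -> np.ndarray:
        return self.points[:, 1]


@dataclass(frozen=True)
class Fraction:
    """One digestible starch pool of a first-order model."""

    c_inf: float     # asymptotic digestion extent contributed by this pool
    k: float         # first-order rate coefficient, 1/min
    t_start: float   # onset time, min (0 for the first pool)

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("rate coefficient k must be > 0")
        if self.c_inf < 0:
            raise ValueError("fraction c_inf must be >= 0")
        if self.t_start < 0:
            raise ValueError("t_start must be >= 0")


class Model(str, Enum):
    SK = "SK"
    CPS = "CPS"


@dataclass
class KineticsFit:
    """Fitted first-order digestion model.

    Both models evaluate as ``C(t) = C0 + sum_j c_j (1 - exp(-k_j (t - t_j)))``
    over the pools active at time t. Each stored ``Fraction.c_inf`` is that
    pool's asymptotic *increment* above C0; for the single-pool SK model the
    curve's overall asymptote is therefore ``c0 + fractions[0].c_inf``
    (see :attr:`c_inf_total`), which is always >= C0.
    """

    model: Model
    c0: float
    fractions: list[Fraction]
    r_squared: float
    rmse: float
    converged: bool
    n_points: int

    def __post_init__(self) -> None:
        self.model = Model(self.model)
        if self.c0 < 0:
            raise ValueError("c0 must be >= 0")
        if not self.fractions:
            raise ValueError("at least one fraction required")
        if self.model is Model.SK:
            if len(self.fractions) != 1 or self.fractions[0].t_start != 0:
                raise ValueError("SK model has exactly one fraction with t_start = 0")
        else:
            starts = [f.t_start for f in self.fractions]
            if starts != sorted(starts) or starts[0] != 0:
                raise ValueError("CPS fractions must be ordered by t_start, first at 0")

    @property
    def c_inf_total(self) -> float:
        """Asymptotic digestion extent C_inf of the whole curve."""
        return self.c0 + sum(f.c_inf for f in self.fractions)

    def predict(self, t) -> np.ndarray:
        """Evaluate the fitted curve at times ``t`` (minutes)."""
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.c0)
        for f in self.fractions:
            dt = t - f.t_start
            out = out + np.where(dt > 0, f.c_inf * (1.0 - np.exp(-f.k * np.clip(dt, 0, None))), 0.0)
        return out


class AUCMethod(str, Enum):
    ANALYTIC = "ANALYTIC"
    TRAPEZOID = "TRAPEZOID"


@dataclass(frozen=True)
class AUCMetrics:
    """Area under a digestogram over [0, horizon_T] minutes."""

    sample_id: str
    protocol: Protocol
    basis: Basis
    horizon_T: float
    value: float          # (value units) · min
    method: AUCMethod

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("AUC must be >= 0")


@dataclass(frozen=True)
class CalibrationModel:
    """OLS line GI = intercept_a + slope_b · AUCR180 for one protocol/basis.

    ``x_mean`` and ``x_ss`` (predictor mean and centered sum of squares) allow
    exact new-observation prediction standard errors after deserialization.
    Models built from published coefficients alone carry ``None`` for the
    uncertainty fields and yield predictions without a model-based SD.
    """

    protocol: Protocol
    basis: Basis
    intercept_a: float
    slope_b: float
    r_squared: Optional[float] = None
    n: Optional[int] = None
    residual_se: Optional[float] = None
    se_intercept: Optional[float] = None
    se_slope: Optional[float] = None
    x_mean: Optional[float] = None
    x_ss: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n is not None and self.n < 3:
            raise ValueError("calibration needs n >= 3 samples")
        if self.r_squared is not None and not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must lie in [0, 1]")


@dataclass(frozen=True)
class PredictionResult:
    """Estimated GI for one sample, with optional validation against clinical GI."""

    sample_id: str
    egi: float
    egi_sd: Optional[float] = None
    clinical_gi: Optional[float] = None
    error_rate_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if self.egi_sd is not None and self.egi_sd < 0:
            raise ValueError("egi_sd must be >= 0")
        if self.error_rate_pct is not None and self.error_rate_pct < 0:
            raise ValueError("error_rate_pct must be >= 0")
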