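"""Read/write the pipeline's tabular formats (CSV, UTF-8, ``.`` decimals).

Formats
-------
Digestogram CSV  : ``sample_id,protocol,replicate,basis,time_min,value``
Absorbance CSV   : ``sample_id,protocol,replicate,time_min,dA_sample,
                   dA_standard,standard_conc_mmol_per_L,aliquot_volume_uL``
Metadata CSV     : ``sample_id,clinical_gi,total_carb_pct,total_starch_pct_db,
                   protein_pct,fat_pct,moisture_pct,free_sugar_pct,sample_mass_mg``
Config JSON      : per-protocol dilution factors, AUC horizons, basis, precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_DILUTION,
    AbsorbanceRecord,
    Basis,
    CalibrationModel,
    Digestogram,
    Protocol,
    SampleMeta,
)

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_digestion_table",
    "write_digestion_table",
    "read_metadata",
    "read_config",
]

DIGESTOGRAM_COLUMNS = ["sample_id", "protocol", "replicate", "basis", "time_min", "value"]
ABSORBANCE_COLUMNS = [
    "sample_id", "protocol", "replicate", "time_min",
    "dA_sample", "dA_standard", "standard_conc_mmol_per_L", "aliquot_volume_uL",
]
METADATA_COLUMNS = [
    "sample_id", "clinical_gi", "total_carb_pct", "total_starch_pct_db",
    "protein_pct", "fat_pct", "moisture_pct", "free_sugar_pct", "sample_mass_mg",
]


class SchemaError(ValueError):
    """A table does not match the expected column schema."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {', '.join(missing)}")


def read_digestion_table(
    path: Union[str, Path], schema: str = "digestogram"
) -> Union[list[Digestogram], list[AbsorbanceRecord]]:
    """Read a digestogram or absorbance CSV into validated records.

    Rows are grouped by (sample_id, protocol, replicate) and sorted by time;
    duplicate timepoints within a group are a validation error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, float_precision="round_trip")
    if schema == "digestogram":
        _require_columns(df, DIGESTOGRAM_COLUMNS, path)
        return _digestograms_from_frame(df, path)
    if schema == "absorbance":
        _require_columns(df, ABSORBANCE_COLUMNS[:6], path)
        return _absorbance_from_frame(df)
    raise ValueError(f"unknown schema {schema!r}")


def _digestograms_from_frame(df: pd.DataFrame, path) -> list[Digestogram]:
    out: list[Digestogram] = []
    for (sid, proto, rep, basis), grp in df.groupby(
        ["sample_id", "protocol", "replicate", "basis"], sort=True
    ):
        grp = grp.sort_values("time_min")
        times = grp["time_min"].to_numpy(float)
        dup = np.flatnonzero(np.diff(times) <= 0)
        if dup.size:
            rows = grp.index[dup + 1].tolist()
            raise ValueError(
                f"{path}: non-increasing/duplicate timepoints for "
                f"({sid}, {proto}, rep {rep}) at row index {rows}"
            )
        out.append(
            Digestogram(
                sample_id=str(sid),
                protocol=Protocol(proto),
                replicate=int(rep),
                basis=Basis(basis),
                times=times,
                values=grp["value"].to_numpy(float),
            )
        )
    return out


def _absorbance_from_frame(df: pd.DataFrame) -> list[AbsorbanceRecord]:
    recs = []
    for row in df.itertuples(index=False):
        recs.append(
            AbsorbanceRecord(
                sample_id=str(row.sample_id),
                protocol=Protocol(row.protocol),
                replicate=int(row.replicate),
                time_min=float(row.time_min),
                dA_sample=float(row.dA_sample),
                dA_standard=float(row.dA_standard),
                standard_conc_mmol_per_L=float(getattr(row, "standard_conc_mmol_per_L", 1.0)),
                aliquot_volume_uL=float(getattr(row, "aliquot_volume_uL", 100.0)),
            )
        )
    recs.sort(key=lambda r: (r.sample_id, r.protocol.value, r.replicate, r.time_min))
    return recs


def write_digestion_table(digestograms: list[Digestogram], path: Union[str, Path]) -> None:
    """Write digestograms to CSV; ``read_digestion_table`` round-trips exactly.

    Values are written with ``repr`` precision so the round-trip is lossless.
    """
    rows = []
    for d in digestograms:
        for t, v in zip(d.times, d.values):
            rows.append(
                {
                    "sample_id": d.sample_id,
                    "protocol": d.protocol.value,
                    "replicate": d.replicate,
                    "basis": d.basis.value,
                    "time_min": repr(float(t)),
                    "value": repr(float(v)),
                }
            )
    pd.DataFrame(rows, columns=DIGESTOGRAM_COLUMNS).to_csv(path, index=False)


def _opt(value) -> Optional[float]:
    return None if pd.isna(value) else float(value)


def read_metadata(path: Union[str, Path]) -> dict[str, SampleMeta]:
    """Read the sample-metadata CSV into a mapping keyed by sample_id."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    _require_columns(df, ["sample_id"], path)
    metas: dict[str, SampleMeta] = {}
    for row in df.itertuples(index=False):
        sid = str(row.sample_id)
        metas[sid] = SampleMeta(
            sample_id=sid,
            clinical_gi=_opt(getattr(row, "clinical_gi", np.nan)),
            total_carb_pct=_opt(getattr(row, "total_carb_pct", np.nan)),
            total_starch_pct_db=_opt(getattr(row, "total_starch_pct_db", np.nan)),
            protein_pct=_opt(getattr(row, "protein_pct", np.nan)),
            fat_pct=_opt(getattr(row, "fat_pct", np.nan)),
            moisture_pct=_opt(getattr(row, "moisture_pct", np.nan)),
            free_sugar_pct=_opt(getattr(row, "free_sugar_pct", np.nan)),
            sample_mass_mg=_opt(getattr(row, "sample_mass_mg", np.nan)),
        )
    return metas


@dataclass
class PipelineConfig:
    """Run-time configuration with protocol dilution defaults."""

    dilution_factor: dict[Protocol, float] = field(
        default_factory=lambda: dict(DEFAULT_DILUTION)
    )
    auc_times: list[float] = field(default_factory=lambda: [90.0, 120.0, 180.0])
    basis: Basis = Basis.REDUCING_SUGAR_NORMALIZED
    pool_replicates: bool = False       # fit pooled points instead of per-replicate
    holm_adjust: bool = False           # Holm correction for correlation stars
    report_precision: int = 2

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "PipelineConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls()
        if "dilution_factor" in raw:
            for proto, v in raw["dilution_factor"].items():
                cfg.dilution_factor[Protocol(proto)] = float(v)
        if "auc_times" in raw:
            cfg.auc_times = [float(t) for t in raw["auc_times"]]
        if "basis" in raw:
            cfg.basis = Basis(raw["basis"])
        for key in ("pool_replicates", "holm_adjust", "report_precision"):
            if key in raw:
                setattr(cfg, key, raw[key])
        return cfg


def read_config(path: Union[str, Path]) -> PipelineConfig:
    return PipelineConfig.from_json(path)


def write_calibration_json(model: CalibrationModel, path: Union[str, Path]) -> None:
    payload = {
        "protocol": model.protocol.value,
        "basis": model.basis.value,
        "intercept": model.intercept_a,
        "slope": model.slope_b,
        "r_squared": model.r_squared,
        "n": model.n,
        "residual_se": model.residual_se,
        "se_intercept": model.se_intercept,
        "se_slope": model.se_slope,
        "x_mean": model.x_mean,
        "x_ss": model.x_ss,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def read_calibration_json(path: Union[str, Path]) -> CalibrationModel:
    with open(path) as fh:
        raw = json.load(fh)
    return CalibrationModel(
        protocol=Protocol(raw["protocol"]),
        basis=Basis(raw["basis"]),
        intercept_a=float(raw["intercept"]),
        slope_b=float(raw["slope"]),
        r_squared=raw.get("r_squared"),
        n=raw.get("n"),
        residual_se=raw.get("residual_se"),
        se_intercept=raw.get("se_intercept"),
        se_slope=raw.get("se_slope"),
        x_mean=raw.get("x_mean"),
        x_ss=raw.get("x_ss"),
    )
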