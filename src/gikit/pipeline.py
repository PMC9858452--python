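"""Pipeline orchestration: convert → LOS/fit → AUC → calibrate or predict.

`run_pipeline` sequences the library stages over tabular inputs and collects
every stage's output in a `PipelineRun`, keyed throughout by
(sample_id, protocol, replicate) so each result is traceable to its input
rows. Validation errors abort; fit non-convergence and >100% digestion
values are warnings.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import convert
from .calibrate import auc_analytic, correlation_screen, fit_calibration, predict_egi
from .io import (
    PipelineConfig,
    read_calibration_json,
    read_digestion_table,
    read_metadata,
    write_calibration_json,
    write_digestion_table,
)
from .kinetics import count_fractions, fit_cps, fit_sk, los_transform
from .types import (
    AbsorbanceRecord,
    Basis,
    CalibrationModel,
    ConversionConstants,
    Digestogram,
    KineticsFit,
    PredictionResult,
    Protocol,
    SampleMeta,
)

__all__ = ["PipelineRun", "run_pipeline", "render_tables", "convert_absorbance", "fit_digestograms"]

logger = logging.getLogger(__name__)

FIT_COLUMNS = [
    "sample_id", "protocol", "basis", "replicate", "model", "c0",
    "c_inf_1", "k_1", "t_start_1", "c_inf_2", "k_2", "t_start_2",
    "r_squared", "rmse", "converged",
]


@dataclass
class PipelineRun:
    """Everything a pipeline invocation computed, plus its warning log."""

    config: PipelineConfig
    digestograms: list[Digestogram] = field(default_factory=list)
    fits: pd.DataFrame = field(default_factory=pd.DataFrame)
    auc: pd.DataFrame = field(default_factory=pd.DataFrame)
    correlations: Optional[pd.DataFrame] = None
    calibration: Optional[CalibrationModel] = None
    predictions: list[PredictionResult] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def warn(self, msg: str) -> None:
        self.warnings.append(msg)
        logger.warning(msg)


def convert_absorbance(
    records: list[AbsorbanceRecord],
    metas: dict[str, SampleMeta],
    config: PipelineConfig,
    run: Optional[PipelineRun] = None,
) -> list[Digestogram]:
    """Convert absorbance records to digestograms on the configured basis."""
    groups: dict[tuple, list[AbsorbanceRecord]] = {}
    for rec in records:
        groups.setdefault((rec.sample_id, rec.protocol, rec.replicate), []).append(rec)
    out = []
    for (sid, proto, rep), recs in sorted(groups.items(), key=lambda kv: (
            kv[0][0], kv[0][1].value, kv[0][2])):
        if sid not in metas:
            raise ValueError(f"no metadata for sample {sid!r}")
        meta = metas[sid]
        consts = ConversionConstants(dilution_factor=config.dilution_factor[proto])
        recs = sorted(recs, key=lambda r: r.time_min)
        if config.basis is Basis.PERCENT_STARCH:
            values = [convert.absorbance_to_percent_digested(r, meta, consts) for r in recs]
        else:
            values = [convert.absorbance_to_normalized_reducing_sugar(r, meta, consts)
                      for r in recs]
        d = Digestogram(sid, proto, rep, config.basis,
                        [r.time_min for r in recs], values)
        if run is not None and d.overshoot:
            run.warn(f"{sid}/{proto.value}/rep{rep}: digestion extent exceeds 100%")
        out.append(d)
    return out


def fit_digestograms(
    digestograms: list[Digestogram],
    run: Optional[PipelineRun] = None,
    max_fractions: int = 2,
) -> pd.DataFrame:
    """LOS-count then SK/CPS-fit each digestogram; tidy one-row-per-fit frame."""
    rows = []
    for d in digestograms:
        try:
            los = count_fractions(los_transform(d), max_fractions=max_fractions,
                                  digestogram=d)
            n_frac = los.n_fractions
            if run is not None and los.n_dropped:
                run.warn(f"{d.sample_id}/{d.protocol.value}/rep{d.replicate}: "
                         f"{los.n_dropped} LOS interval(s) dropped")
        except ValueError as exc:
            if run is not None:
                run.warn(f"{d.sample_id}: LOS unavailable ({exc}); assuming one fraction")
            n_frac = 1
        fit = fit_sk(d) if n_frac == 1 else fit_cps(d, n_frac)
        if run is not None and not fit.converged:
            run.warn(f"{d.sample_id}/{d.protocol.value}/rep{d.replicate}: "
                     "fit did not converge; best-effort parameters kept")
        row = {
            "sample_id": d.sample_id, "protocol": d.protocol.value,
            "basis": d.basis.value, "replicate": d.replicate,
            "model": fit.model.value, "c0": fit.c0,
            "r_squared": fit.r_squared, "rmse": fit.rmse,
            "converged": fit.converged,
        }
        for j in range(2):
            if j < len(fit.fractions):
                f = fit.fractions[j]
                row[f"c_inf_{j+1}"], row[f"k_{j+1}"], row[f"t_start_{j+1}"] = f.c_inf, f.k, f.t_start
            else:
                row[f"c_inf_{j+1}"] = row[f"k_{j+1}"] = row[f"t_start_{j+1}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def _fit_from_row(row) -> KineticsFit:
    from .types import Fraction, Model

    fractions = [Fraction(row.c_inf_1, row.k_1, row.t_start_1)]
    if not np.isnan(row.c_inf_2):
        fractions.append(Fraction(row.c_inf_2, row.k_2, row.t_start_2))
    return KineticsFit(model=Model(row.model), c0=row.c0, fractions=fractions,
                       r_squared=row.r_squared, rmse=row.rmse,
                       converged=bool(row.converged), n_points=4)


def compute_auc(fits: pd.DataFrame, auc_times: list[float]) -> pd.DataFrame:
    """Analytic AUC of every fitted curve at each configured horizon."""
    rows = []
    for row in fits.itertuples(index=False):
        fit = _fit_from_row(row)
        for T in auc_times:
            m = auc_analytic(fit, T, sample_id=row.sample_id,
                             protocol=Protocol(row.protocol), basis=Basis(row.basis))
            rows.append({
                "sample_id": row.sample_id, "protocol": row.protocol,
                "basis": row.basis, "replicate": row.replicate,
                "horizon_T": T, "value": m.value, "method": m.method.value,
            })
    return pd.DataFrame(rows)


def run_pipeline(
    config_path: Optional[Union[str, Path]] = None,
    digestogram_path: Optional[Union[str, Path]] = None,
    absorbance_path: Optional[Union[str, Path]] = None,
    metadata_path: Optional[Union[str, Path]] = None,
    mode: str = "calibrate",
    calibration_path: Optional[Union[str, Path]] = None,
    out_dir: Optional[Union[str, Path]] = None,
) -> PipelineRun:
    """Execute convert → LOS/fit → AUC → calibrate | predict.

    ``mode='calibrate'`` regresses clinical GI (from metadata) on the mean
    per-sample AUCR at the longest configured horizon; ``mode='predict'``
    applies a serialized calibration model instead. Artifacts are written
    under ``out_dir`` when given.
    """
    config = PipelineConfig.from_json(config_path) if config_path else PipelineConfig()
    run = PipelineRun(config=config)
    metas = read_metadata(metadata_path) if metadata_path else {}

    if absorbance_path:
        records = read_digestion_table(absorbance_path, schema="absorbance")
        run.digestograms = convert_absorbance(records, metas, config, run)
    elif digestogram_path:
        run.digestograms = read_digestion_table(digestogram_path, schema="digestogram")
    if not run.digestograms:
        raise ValueError("empty input: no digestograms to analyse")

    run.fits = fit_digestograms(run.digestograms, run)
    run.auc = compute_auc(run.fits, config.auc_times)

    horizon = max(config.auc_times)
    per_sample = (
        run.auc[run.auc["horizon_T"] == horizon]
        .groupby("sample_id")["value"]
        .agg(["mean", "std"])
    )

    if mode == "calibrate":
        gi = []
        for sid in per_sample.index:
            if sid not in metas or metas[sid].clinical_gi is None:
                raise ValueError(f"calibrate mode needs clinical GI for sample {sid!r}")
            gi.append(metas[sid].clinical_gi)
        proto = run.digestograms[0].protocol
        run.calibration = fit_calibration(per_sample["mean"].to_numpy(), gi,
                                          protocol=proto, basis=config.basis)
        feats = per_sample.rename(columns={"mean": f"AUCR{horizon:.0f}"})[[f"AUCR{horizon:.0f}"]]
        gl = [convert.glycemic_load(g, metas[s].total_carb_pct)
              if metas[s].total_carb_pct is not None else np.nan
              for g, s in zip(gi, per_sample.index)]
        if not any(np.isnan(gl)):
            run.correlations = correlation_screen(feats, gi, gl,
                                                  holm_adjust=config.holm_adjust)
    elif mode == "predict":
        if calibration_path is None:
            raise ValueError("predict mode requires a serialized calibration model")
        model = read_calibration_json(calibration_path)
        for sid, row in per_sample.iterrows():
            sd = None if np.isnan(row["std"]) else float(row["std"])
            gi = metas[sid].clinical_gi if sid in metas else None
            run.predictions.append(
                predict_egi(model, float(row["mean"]), aucr180_sd=sd,
                            sample_id=str(sid), clinical_gi=gi)
            )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    if out_dir is not None:
        _write_artifacts(run, Path(out_dir))
    return run


def _write_artifacts(run: PipelineRun, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    write_digestion_table(run.digestograms, out_dir / "digestograms.csv")
    run.fits.to_csv(out_dir / "fits.csv", index=False)
    run.auc.to_csv(out_dir / "auc.csv", index=False)
    if run.calibration is not None:
        write_calibration_json(run.calibration, out_dir / "calibration.json")
    tables = render_tables(run)
    for name, df in tables.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    if run.warnings:
        (out_dir / "warnings.log").write_text("\n".join(run.warnings) + "\n")


def render_tables(run: PipelineRun, precision: Optional[int] = None) -> dict[str, pd.DataFrame]:
    """Summary tables: starred correlation screen and eGI prediction report.

    The prediction table reports eGI ± SD and the relative error rate to the
    configured precision; the error-rate column is omitted when no clinical
    GI was supplied.
    """
    prec = precision if precision is not None else run.config.report_precision
    out: dict[str, pd.DataFrame] = {}
    if run.correlations is not None:
        corr = run.correlations.copy()
        for col in ("r_vs_gi", "r_vs_gl"):
            corr[col] = corr[col].round(3)
        out["correlation_table"] = corr
    if run.predictions:
        rows = []
        for p in run.predictions:
            row = {"sample_id": p.sample_id,
                   "egi": round(p.egi, prec),
                   "egi_sd": round(p.egi_sd, prec) if p.egi_sd is not None else np.nan}
            if p.clinical_gi is not None:
                row["clinical_gi"] = p.clinical_gi
                row["error_rate_pct"] = p.error_rate_pct
            rows.append(row)
        out["prediction_table"] = pd.DataFrame(rows)
    return out
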