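"""AUC summaries, correlation screening, eGI calibration and validation.

The digestion→GI bridge is a one-predictor OLS line: the area under the
reducing-sugar digestogram over 0–180 min (AUCR180) is regressed on clinical
glycemic index over a calibration panel, and applied to new samples as
eGI = a + b·AUCR180 with a new-observation prediction standard error.
Prediction quality is scored as the relative error |eGI − GI| / GI × 100.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import (
    AUCMethod,
    AUCMetrics,
    Basis,
    CalibrationModel,
    Digestogram,
    KineticsFit,
    PredictionResult,
    Protocol,
)

__all__ = [
    "auc_analytic",
    "auc_trapezoid",
    "correlation_screen",
    "fit_calibration",
    "predict_egi",
    "error_rate",
    "significance_stars",
]


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def _sk_fraction_auc(c_inf: float, k: float, t_start: float, T: float) -> float:
    """∫_{t_start}^{T} c_inf (1 - e^{-k (t - t_start)}) dt, 0 when T <= t_start."""
    span = T - t_start
    if span <= 0:
        return 0.0
    return c_inf * (span - (1.0 - math.exp(-k * span)) / k)


def auc_analytic(
    fit: KineticsFit,
    T: float,
    sample_id: str = "",
    protocol: Protocol = Protocol.PANCREATIN,
    basis: Basis = Basis.REDUCING_SUGAR_NORMALIZED,
) -> AUCMetrics:
    """Closed-form area under the fitted first-order curve over [0, T].

    For the SK model this is C_inf·T − (C_inf − C0)(1 − e^{−kT})/k; for CPS
    fits the per-pool closed forms over [t_start, T] are summed on top of
    the C0 baseline. Fitting the curve first lets the area extend past the
    last sampled time (e.g. a 180-min horizon on a 120-min schedule).
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    for f in fit.fractions:
        if f.k <= 0:
            raise ValueError("rate coefficient k must be > 0")
    area = fit.c0 * T + sum(
        _sk_fraction_auc(f.c_inf, f.k, f.t_start, T) for f in fit.fractions
    )
    return AUCMetrics(
        sample_id=sample_id, protocol=protocol, basis=basis,
        horizon_T=float(T), value=float(area), method=AUCMethod.ANALYTIC,
    )


def auc_trapezoid(d: Digestogram, T: float) -> AUCMetrics:
    """Trapezoidal area under the observed digestogram over [0, T].

    Linear interpolation at T; when the series starts after t = 0 a leading
    horizontal segment at the first value covers [0, t_first]. Refuses to
    extrapolate beyond the last observation.
    """
    if T <= 0:
        raise ValueError("T must be > 0")
    if T > d.times[-1]:
        raise ValueError(
            f"T={T} exceeds the last observation ({d.times[-1]} min); "
            "use auc_analytic on a fitted curve instead"
        )
    t, v = d.times, d.values
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[v[0]], v])
    vT = float(np.interp(T, t, v))
    keep = t < T
    tt = np.concatenate([t[keep], [T]])
    vv = np.concatenate([v[keep], [vT]])
    area = float(np.trapezoid(vv, tt))
    return AUCMetrics(
        sample_id=d.sample_id, protocol=d.protocol, basis=d.basis,
        horizon_T=float(T), value=area, method=AUCMethod.TRAPEZOID,
    )


# ---------------------------------------------------------------------------
# Correlation screen
# ---------------------------------------------------------------------------

def significance_stars(p: float) -> str:
    """Two-level convention: '**' for p < 0.01, '*' for 0.01 <= p < 0.05."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def correlation_screen(
    features: pd.DataFrame,
    gi: Sequence[float],
    gl: Sequence[float],
    holm_adjust: bool = False,
) -> pd.DataFrame:
    """Pearson screen of kinetics/AUC features against GI and GL.

    One row per feature column: r and two-sided p (t distribution, n−2 df)
    against each response, starred per the two-level convention. Constant
    features are flagged (``degenerate=True``) with NaN statistics rather
    than raising. ``holm_adjust`` applies a Holm step-down correction to the
    p-values before starring (off by default).
    """
    gi = np.asarray(gi, dtype=float)
    gl = np.asarray(gl, dtype=float)
    if len(gi) < 3:
        raise ValueError("correlation screen needs n >= 3 paired observations")
    rows = []
    for col in features.columns:
        x = features[col].to_numpy(float)
        if np.allclose(x, x[0]):
            rows.append(
                dict(parameter=col, r_vs_gi=np.nan, p_gi=np.nan, stars_gi="",
                     r_vs_gl=np.nan, p_gl=np.nan, stars_gl="", degenerate=True)
            )
            continue
        r_gi, p_gi = stats.pearsonr(x, gi)
        r_gl, p_gl = stats.pearsonr(x, gl)
        rows.append(
            dict(parameter=col, r_vs_gi=r_gi, p_gi=p_gi, stars_gi="",
                 r_vs_gl=r_gl, p_gl=p_gl, stars_gl="", degenerate=False)
        )
    out = pd.DataFrame(rows)
    p_gi = out["p_gi"].to_numpy()
    p_gl = out["p_gl"].to_numpy()
    if holm_adjust:
        from statsmodels.stats.multitest import multipletests
        ok = out["degenerate"] == False  # noqa: E712
        pooled = np.concatenate([p_gi[ok.to_numpy()], p_gl[ok.to_numpy()]])
        adj = multipletests(pooled, method="holm")[1]
        half = ok.sum()
        p_gi = p_gi.copy(); p_gl = p_gl.copy()
        p_gi[ok.to_numpy()] = adj[:half]
        p_gl[ok.to_numpy()] = adj[half:]
    out["stars_gi"] = ["" if np.isnan(p) else significance_stars(p) for p in p_gi]
    out["stars_gl"] = ["" if np.isnan(p) else significance_stars(p) for p in p_gl]
    return out


# ---------------------------------------------------------------------------
# Calibration and prediction
# ---------------------------------------------------------------------------

def fit_calibration(
    aucr180: Sequence[float],
    gi: Sequence[float],
    protocol: Protocol = Protocol.PANCREATIN,
    basis: Basis = Basis.REDUCING_SUGAR_NORMALIZED,
) -> CalibrationModel:
    """OLS of clinical GI on AUCR180 with full uncertainty accounting."""
    x = np.asarray(aucr180, dtype=float)
    y = np.asarray(gi, dtype=float)
    if len(x) < 3:
        raise ValueError("calibration needs n >= 3 samples")
    if np.allclose(x, x[0]):
        raise ValueError("constant AUCR180 predictor: calibration line unidentifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CalibrationModel(
        protocol=protocol,
        basis=basis,
        intercept_a=float(res.params[0]),
        slope_b=float(res.params[1]),
        r_squared=float(res.rsquared),
        n=len(x),
        residual_se=float(np.sqrt(res.mse_resid)),
        se_intercept=float(res.bse[0]),
        se_slope=float(res.bse[1]),
        x_mean=float(x.mean()),
        x_ss=float(np.sum((x - x.mean()) ** 2)),
    )


def predict_egi(
    model: CalibrationModel,
    aucr180: float,
    aucr180_sd: Optional[float] = None,
    sample_id: str = "",
    clinical_gi: Optional[float] = None,
) -> PredictionResult:
    """Apply the calibration line: eGI = a + b·AUCR180.

    ``egi_sd`` is the new-observation prediction standard error
    s·sqrt(1 + 1/n + (x − x̄)²/Sxx), combined in quadrature with the
    replicate contribution b·aucr180_sd when a replicate SD is supplied.
    Models lacking uncertainty fields (e.g. built from published
    coefficients) yield only the replicate term, or no SD at all.
    When ``clinical_gi`` is given the relative error rate is attached.
    """
    if aucr180 < 0:
        raise ValueError("aucr180 must be >= 0")
    egi = model.intercept_a + model.slope_b * aucr180
    var = 0.0
    have_any = False
    if model.residual_se is not None and model.n is not None:
        lev = 0.0
        if model.x_mean is not None and model.x_ss is not None and model.x_ss > 0:
            lev = (aucr180 - model.x_mean) ** 2 / model.x_ss
        var += model.residual_se**2 * (1.0 + 1.0 / model.n + lev)
        have_any = True
    if aucr180_sd is not None:
        var += (model.slope_b * aucr180_sd) ** 2
        have_any = True
    sd = math.sqrt(var) if have_any else None
    err = error_rate(clinical_gi, egi) if clinical_gi is not None else None
    return PredictionResult(
        sample_id=sample_id, egi=float(egi), egi_sd=sd,
        clinical_gi=clinical_gi, error_rate_pct=err,
    )


def error_rate(clinical_gi: float, egi: float) -> float:
    """Relative prediction error |eGI − GI| / GI × 100, to 2 dp."""
    if clinical_gi <= 0:
        raise ValueError("clinical_gi must be > 0")
    return round(abs(egi - clinical_gi) / clinical_gi * 100.0, 2)
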