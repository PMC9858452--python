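"""First-order digestion kinetics: LOS-plot analysis and SK/CPS model fitting.

Starch digested under excess amylolytic enzyme follows first-order kinetics,

    C(t) = C0 + (C_inf - C0) (1 - exp(-k t)),                      (SK)

so the log of the digestogram's slope is linear in time,

    ln dC/dt = ln(k (C_inf - C0)) - k t,

which is the logarithm-of-slope (LOS) plot: each linear segment is one
digestible substrate pool, its slope -k. Foods with several pools are fitted
with a combination of parallel and sequential (CPS) first-order terms, each
later pool switching on at an onset time t_start:

    C(t) = C0 + sum_j C_j_inf (1 - exp(-k_j (t - t_j_start))) [t > t_j_start].

`los_transform` builds the LOS points from discrete slopes,
`count_fractions` makes the usually-visual segment count reproducible via a
BIC-selected segmented regression, and `fit_sk` / `fit_cps` estimate the
model parameters by bounded nonlinear least squares.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy import optimize, stats

from .types import Digestogram, Fraction, KineticsFit, LOSResult, LOSSegment, Model

__all__ = ["los_transform", "count_fractions", "fit_sk", "fit_cps"]

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# LOS transform and segment counting
# ---------------------------------------------------------------------------

def los_transform(d: Digestogram) -> LOSResult:
    """Logarithm-of-slope points of a digestogram.

    For each consecutive pair with a positive increment the discrete slope
    (C_{i+1} - C_i)/(t_{i+1} - t_i) is evaluated and its log placed at the
    interval midpoint (t_i + t_{i+1})/2; flat or decreasing intervals are
    dropped (the log is undefined) and counted in ``n_dropped``.
    """
    if len(d) < 3:
        raise ValueError("LOS transform needs at least 3 timepoints")
    dt = np.diff(d.times)
    dc = np.diff(d.values)
    keep = dc > 0
    n_dropped = int(np.sum(~keep))
    if np.sum(keep) < 2:
        raise ValueError("insufficient LOS points: fewer than 2 positive increments")
    t_mid = (d.times[:-1] + d.times[1:])[keep] / 2.0
    ln_slope = np.log(dc[keep] / dt[keep])
    return LOSResult(points=np.column_stack([t_mid, ln_slope]),
                     n_dropped=n_dropped, increments=dc[keep],
                     interval_widths=dt[keep],
                     all_t_mid=(d.times[:-1] + d.times[1:]) / 2.0,
                     all_increments=dc)


def _fd_bias(k: float, widths: np.ndarray) -> np.ndarray:
    """ln(sinh(k d/2)/(k d/2)): excess of a width-d chord slope over the
    midpoint derivative of exp(-k t)."""
    x = k * widths / 2.0
    with np.errstate(over="ignore"):
        out = np.where(x > 1e-8, np.log(np.sinh(np.clip(x, 1e-8, 350.0)) / np.clip(x, 1e-8, None)), 0.0)
    return out


def _segment_fit(
    t: np.ndarray,
    y: np.ndarray,
    w: Optional[np.ndarray] = None,
    widths: Optional[np.ndarray] = None,
) -> Optional[tuple[float, float, float, float]]:
    """Weighted least-squares line through (t, y); None unless slope < 0.

    ``w`` are np.polyfit-style weights (sqrt of the precision). When
    interval ``widths`` are given, the finite-difference bias of discrete
    log-slopes (width-dependent on uneven schedules, so it masquerades as
    curvature) is removed iteratively using the segment's own rate estimate.
    Returns (slope, intercept, weighted rss, slope standard error) on the
    bias-corrected points.
    """
    slope, intercept = np.polyfit(t, y, 1, w=w)
    if slope >= 0:
        return None
    y_eff = y
    if widths is not None:
        for _ in range(100):
            y_eff = y - _fd_bias(-slope, widths)
            new_slope, intercept = np.polyfit(t, y_eff, 1, w=w)
            if new_slope >= 0:
                return None
            done = abs(new_slope - slope) <= 1e-13 * abs(slope)
            slope = new_slope
            if done:
                break
        y_eff = y - _fd_bias(-slope, widths)
        slope, intercept = np.polyfit(t, y_eff, 1, w=w)
    resid = y_eff - (slope * t + intercept)
    ww = np.ones_like(t) if w is None else w
    wrss = float((ww * resid) @ (ww * resid))
    # weighted-OLS slope SE; df = n - 2 (se = inf for a 2-point segment)
    n = len(t)
    sw2 = ww**2
    t_bar = float(np.sum(sw2 * t) / np.sum(sw2))
    sxx = float(np.sum(sw2 * (t - t_bar) ** 2))
    se = float(np.sqrt(wrss / (n - 2) / sxx)) if n > 2 and sxx > 0 else np.inf
    return float(slope), float(intercept), wrss, se


def _distinct_slopes(left, n_left: int, right, n_right: int, alpha: float = 0.05) -> bool:
    """Slope change at the breakpoint must be significant and in the
    fast-then-slow direction (the later pool digests more slowly), one-sided
    Welch test — two segments with statistically indistinguishable slopes
    are one digestion phase, not two."""
    sl_l, _, _, se_l = left
    sl_r, _, _, se_r = right
    if sl_r <= sl_l:
        return False
    se = np.hypot(se_l, se_r)
    if not np.isfinite(se) or se == 0:
        return True
    # Welch-Satterthwaite df
    df = se**4 / (
        se_l**4 / max(n_left - 2, 1) + se_r**4 / max(n_right - 2, 1)
    )
    return (sl_r - sl_l) / se > stats.t.ppf(1 - alpha, df=max(df, 1.0))


def _net_progress_ok(los: LOSResult, t_start: float, w: np.ndarray,
                     wrss2: float, n: int) -> bool:
    """A later pool must show net digestion progress above the noise floor.

    Over the candidate second segment's span the net extent change
    telescopes to C(end) - C(start); dropped (negative) intervals count,
    otherwise a plateau of noise would masquerade as a slow pool. The value
    noise SD is estimated from the weighted segmented-fit residuals (a
    weighted log-slope residual is delta(dC)/rms(dC), with
    sd(delta dC) = sigma*sqrt(2)).
    """
    if los.all_t_mid is None or los.increments is None:
        return True
    q = float(np.sqrt(np.mean(np.asarray(los.increments, float) ** 2)))
    df = max(n - 5, 1)
    sigma = q * np.sqrt(wrss2 / df) / np.sqrt(2.0)
    span = los.all_t_mid >= t_start - 1e-9
    net = float(np.sum(los.all_increments[span]))
    return net > stats.norm.ppf(0.95) * sigma * np.sqrt(2.0)


def _r2(y: np.ndarray, rss: float) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - rss / tss if tss > 0 else 1.0


def count_fractions(
    los: LOSResult,
    max_fractions: int = 2,
    digestogram: Optional[Digestogram] = None,
) -> LOSResult:
    """Fill ``segments`` and ``n_fractions`` by BIC-selected segmented regression.

    Candidate models place 1..max_fractions ordered linear segments over the
    LOS points, breakpoints restricted to observed midpoints, each segment
    holding >= 3 points and a negative slope. The segment count is chosen by
    BIC on the LOS residuals (parameters: 2 per segment + 1 per breakpoint);
    ties break toward fewer segments. When fewer than 4 points are available
    the single-segment model is used with a logged notice.

    Residuals are precision-weighted: under additive digestogram noise the
    log-slope variance scales as 1/increment², so plateau points (tiny
    increments, wild logs) are down-weighted instead of dominating the
    segmented fit.

    When the originating ``digestogram`` is supplied, a two-segment verdict
    must additionally be confirmed in the value domain: the two-fraction
    nonlinear fit has to beat the one-fraction fit by BIC on the raw
    digestion values. The log-slope transform amplifies plateau noise, so
    this parsimony check on the untransformed data vetoes spurious splits.
    """
    t, y = los.t_mid, los.ln_slope
    n = len(t)
    min_pts = 3

    if los.increments is not None:
        w = np.asarray(los.increments, dtype=float)
        w = w / np.sqrt(np.mean(w**2))  # polyfit weights = sqrt(precision)
    else:
        w = np.ones(n)
    widths = los.interval_widths

    candidates: list[tuple[float, list[LOSSegment]]] = []  # (bic, segments)

    # relative floor: residuals at round-off scale tie, and ties resolve
    # toward fewer segments below
    wtss = float(np.sum((w * (y - np.average(y, weights=w**2))) ** 2))
    floor = max(1e-12 * wtss, 1e-300)

    def bic(wrss: float, n_params: int) -> float:
        wrss = max(wrss, floor)
        return n * np.log(wrss / n) + n_params * np.log(n)

    def seg(sl: float, ic: float, ts: np.ndarray, ys: np.ndarray,
            ds: Optional[np.ndarray]) -> LOSSegment:
        y_eff = ys - _fd_bias(-sl, ds) if ds is not None else ys
        resid = y_eff - (sl * ts + ic)
        return LOSSegment(sl, ic, (float(ts[0]), float(ts[-1])),
                          _r2(y_eff, float(resid @ resid)), len(ts))

    def sub(arr, sl):
        return None if arr is None else arr[sl]

    one = _segment_fit(t, y, w, widths)
    if one is not None:
        s, b, wrss, _ = one
        candidates.append((bic(wrss, 2), [seg(s, b, t, y, widths)]))

    def significantly_negative(fit_res, n_seg: int) -> bool:
        # one-sided t-test at 5%: a plateau of noise-conditioned points does
        # not qualify as a digestible fraction
        slope, _, _, se = fit_res
        if not np.isfinite(se) or se == 0:
            return slope < 0
        return slope / se < stats.t.ppf(0.05, df=n_seg - 2)

    if n >= 2 * min_pts and max_fractions >= 2:
        # exhaustive breakpoint search between ordered segments; the
        # slope-change test is Bonferroni-corrected for the number of
        # candidate breakpoints examined
        n_cuts = n - 2 * min_pts + 1
        alpha = 0.05 / max(n_cuts, 1)
        best2: Optional[tuple[float, list[LOSSegment]]] = None
        for cut in range(min_pts, n - min_pts + 1):
            left = _segment_fit(t[:cut], y[:cut], w[:cut], sub(widths, slice(None, cut)))
            right = _segment_fit(t[cut:], y[cut:], w[cut:], sub(widths, slice(cut, None)))
            if left is None or right is None:
                continue
            if not (significantly_negative(left, cut) and significantly_negative(right, n - cut)):
                continue
            if not _distinct_slopes(left, cut, right, n - cut, alpha=alpha):
                continue
            if not _net_progress_ok(los, t[cut], w, left[2] + right[2], n):
                continue
            segs = [seg(left[0], left[1], t[:cut], y[:cut], sub(widths, slice(None, cut))),
                    seg(right[0], right[1], t[cut:], y[cut:], sub(widths, slice(cut, None)))]
            score = bic(left[2] + right[2], 5)
            if best2 is None or score < best2[0]:
                best2 = (score, segs)
        if best2 is not None:
            candidates.append(best2)
    elif max_fractions >= 2 and n < 4:
        logger.info("fewer than 4 LOS points: falling back to a single fraction")

    if not candidates:
        # All slopes non-negative (noise-dominated plateau): report one
        # unconstrained segment so downstream fitting still proceeds.
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        rss = float(resid @ resid)
        logger.info("no negative-slope LOS segment found; reporting one fraction")
        segs = [LOSSegment(float(slope), float(intercept),
                           (float(t[0]), float(t[-1])), _r2(y, rss), n)]
        return LOSResult(points=los.points, n_dropped=los.n_dropped,
                         segments=segs, n_fractions=1, increments=los.increments)

    # stable sort: on BIC ties the fewer-segment candidate (listed first) wins
    candidates.sort(key=lambda c: (c[0], len(c[1])))
    _, segments = candidates[0]

    if len(segments) == 2 and digestogram is not None:
        if not _value_domain_confirms_split(digestogram):
            logger.info("two-segment LOS verdict not confirmed on raw values; "
                        "reporting one fraction")
            singles = [c for _, c in candidates if len(c) == 1]
            segments = singles[0] if singles else segments[:1]

    return LOSResult(points=los.points, n_dropped=los.n_dropped,
                     segments=segments, n_fractions=len(segments),
                     increments=los.increments)


def _value_domain_confirms_split(d: Digestogram) -> bool:
    """True if the two-fraction fit beats the one-fraction fit by BIC on raw values."""
    t = np.asarray(d.times, dtype=float)
    y = np.asarray(d.values, dtype=float)
    n = len(t)

    def bic_of(fit: KineticsFit, n_params: int) -> float:
        resid = y - fit.predict(t)
        rss = max(float(resid @ resid), 1e-300)
        return n * np.log(rss / n) + n_params * np.log(n)

    return bic_of(fit_cps(d, 2), 7) < bic_of(fit_sk(d), 3)


# ---------------------------------------------------------------------------
# SK fitting
# ---------------------------------------------------------------------------

def _sk_curve(t: np.ndarray, c0: float, dc: float, k: float) -> np.ndarray:
    return c0 + dc * (1.0 - np.exp(-k * t))


def _fit_metrics(y: np.ndarray, yhat: np.ndarray) -> tuple[float, float]:
    resid = y - yhat
    rss = float(resid @ resid)
    return _r2(y, rss), float(np.sqrt(rss / len(y)))


def fit_sk(d: Digestogram, init: Optional[KineticsFit] = None) -> KineticsFit:
    """Fit the single first-order (SK) model by bounded least squares.

    Parameters are (C0, C_inf - C0, k) with k in (0, 10] /min, C0 in
    [0, max(values)] and the asymptote capped at 3x the observed maximum.
    Initialization: C0 <- first value, C_inf <- max value, and k from the
    LOS segment slope when available, else 0.02 /min; three k starts spanning
    a decade guard against local minima. Never raises on non-convergence —
    the best-effort parameters are returned with ``converged=False``.
    """
    if len(d) < 4:
        raise ValueError("SK fit needs at least 4 points")
    t, y = d.times, d.values
    vmax = float(y.max())
    if np.allclose(y, y[0]):
        raise ValueError("SK fit needs non-constant values")

    if init is not None:
        c0_init = init.c0
        dc_init = max(init.fractions[0].c_inf, 1e-6)
        k_init = init.fractions[0].k
    else:
        c0_init = float(y[0]) if t[0] == 0 else 0.0
        dc_init = max(vmax - c0_init, 1e-6)
        k_init = _k_from_los(d) or 0.02

    lb = np.array([0.0, 0.0, 1e-8])
    ub = np.array([max(vmax, 1e-6), 3.0 * max(vmax, 1e-6), 10.0])

    def residual(p):
        return _sk_curve(t, *p) - y

    def jac(p):
        c0, dc, k = p
        e = np.exp(-k * t)
        return np.column_stack([np.ones_like(t), 1.0 - e, dc * t * e])

    best = None
    converged = False
    for k0 in (k_init, k_init / np.sqrt(10.0), k_init * np.sqrt(10.0)):
        p0 = np.clip([c0_init, dc_init, k0], lb, ub)
        sol = optimize.least_squares(residual, p0, jac=jac, bounds=(lb, ub),
                                     method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
        if best is None or sol.cost < best.cost - 1e-14:
            best = sol
        if sol.success:
            converged = True
    c0, dc, k = best.x
    r2, rmse = _fit_metrics(y, _sk_curve(t, c0, dc, k))
    return KineticsFit(
        model=Model.SK,
        c0=float(c0),
        fractions=[Fraction(c_inf=float(dc), k=float(max(k, 1e-8)), t_start=0.0)],
        r_squared=r2,
        rmse=rmse,
        converged=bool(converged and best.success),
        n_points=len(d),
    )


def _k_from_los(d: Digestogram) -> Optional[float]:
    """Rate guess from the LOS slope; None when the transform is degenerate."""
    try:
        los = count_fractions(los_transform(d), max_fractions=1)
    except ValueError:
        return None
    slope = los.segments[0].slope
    return -slope if slope < 0 else None


# ---------------------------------------------------------------------------
# CPS fitting
# ---------------------------------------------------------------------------

def _cps_curve(t: np.ndarray, params: np.ndarray, n_frac: int) -> np.ndarray:
    """params = [c0, c1, k1, c2, k2, t2, c3, k3, t3, ...] (t1 fixed at 0)."""
    c0 = params[0]
    out = np.full_like(t, c0)
    c1, k1 = params[1], params[2]
    out = out + c1 * (1.0 - np.exp(-k1 * t))
    idx = 3
    for _ in range(1, n_frac):
        cj, kj, tj = params[idx], params[idx + 1], params[idx + 2]
        dt = t - tj
        out = out + np.where(dt > 0, cj * (1.0 - np.exp(-kj * np.clip(dt, 0, None))), 0.0)
        idx += 3
    return out


def fit_cps(d: Digestogram, n_fractions: int) -> KineticsFit:
    """Fit the CPS multi-pool model; with one pool, defers to :func:`fit_sk`.

    The first pool starts at t = 0; later onset times are free in
    (0, max t). Multi-start: onset candidates are placed on observed
    timepoints and the best bounded least-squares solution kept, followed by
    refinement from the best start. Returns best-effort parameters with
    ``converged=False`` rather than raising.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    if n_fractions == 1:
        return fit_sk(d)
    if len(d) < 3 + 3 * n_fractions:
        raise ValueError(
            f"CPS fit with {n_fractions} fractions needs >= {3 + 3 * n_fractions} points"
        )
    t, y = d.times, d.values
    vmax = float(y.max())
    tmax = float(t.max())

    n_params = 1 + 2 + 3 * (n_fractions - 1)
    lb = np.zeros(n_params)
    ub = np.empty(n_params)
    ub[0] = max(vmax, 1e-6)                # c0
    ub[1] = 3.0 * max(vmax, 1e-6)          # c1
    ub[2] = 10.0                           # k1
    lb[2] = 1e-8
    for j in range(1, n_fractions):
        base = 3 + 3 * (j - 1)
        ub[base] = 3.0 * max(vmax, 1e-6)   # cj
        ub[base + 1] = 10.0                # kj
        lb[base + 1] = 1e-8
        lb[base + 2] = 1e-6                # tj in (0, tmax)
        ub[base + 2] = tmax - 1e-6

    def residual(p):
        return _cps_curve(t, p, n_fractions) - y

    # onset-time multi-start on interior observed timepoints
    interior = t[(t > t[1]) & (t < tmax)]
    if interior.size == 0:
        interior = np.array([tmax / 2.0])
    k_guess = _k_from_los(d) or 0.02

    best = None
    converged = False
    for t2 in interior:
        p0 = np.zeros(n_params)
        p0[0] = float(y[0]) if t[0] == 0 else 0.0
        p0[1] = max(0.6 * vmax, 1e-3)
        p0[2] = max(k_guess * 2.0, 1e-4)
        for j in range(1, n_fractions):
            base = 3 + 3 * (j - 1)
            p0[base] = max(0.4 * vmax / max(n_fractions - 1, 1), 1e-3)
            p0[base + 1] = max(k_guess / 5.0, 1e-5)
            p0[base + 2] = t2 * j / max(n_fractions - 1, 1)
        p0 = np.clip(p0, lb, ub)
        sol = optimize.least_squares(residual, p0, bounds=(lb, ub), method="trf")
        if best is None or sol.cost < best.cost - 1e-14:
            best = sol
        if sol.success:
            converged = True
    # polish from the best start
    sol = optimize.least_squares(
        residual, best.x, bounds=(lb, ub), method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14
    )
    if sol.cost <= best.cost:
        best = sol

    p = best.x
    fractions = [Fraction(c_inf=float(p[1]), k=float(max(p[2], 1e-8)), t_start=0.0)]
    for j in range(1, n_fractions):
        base = 3 + 3 * (j - 1)
        fractions.append(
            Fraction(
                c_inf=float(p[base]),
                k=float(max(p[base + 1], 1e-8)),
                t_start=float(p[base + 2]),
            )
        )
    fractions.sort(key=lambda f: f.t_start)
    if fractions[0].t_start != 0.0:
        fractions[0] = Fraction(fractions[0].c_inf, fractions[0].k, 0.0)
    r2, rmse = _fit_metrics(y, _cps_curve(t, p, n_fractions))
    return KineticsFit(
        model=Model.CPS,
        c0=float(p[0]),
        fractions=fractions,
        r_squared=r2,
        rmse=rmse,
        converged=bool(converged and best.success),
        n_points=len(d),
    )
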