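"""Drug-response analytics for kinetic organoid screens.

Implements the screen-level statistics used on well metrics:

* control normalization of raw responses (vehicle = 100%, optional
  baseline/positive control = 0%, swapped for cell-death readouts),
* four-parameter logistic (4PL) dose-response fits on log10
  concentration — ``Y = bottom + (top − bottom)/(1 + 10^((logIC50 − X)·hill))``
  — with multi-start least squares,
* the extra sum-of-squares F test comparing log IC50 between two curves,
* the Z-factor screen-quality score
  ``1 − (3·SD_neg + 3·SD_pos)/(mean_neg − mean_pos)``,
* the growth-rate (GR) and normalized drug response (NDR) metrics on
  per-well viable-area fold changes from T0, and the derived
  proliferative / normal / cytostatic / cytotoxic classification,
* ordinary least-squares pairwise regression (slope, bias, R²) for
  method-comparison plots.

GR and NDR are anchored so that 1 means growth matching the untreated
(vehicle) control, 0 means complete growth arrest, and −1 (NDR) means
killing as complete as the positive control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .config import ValidationError


class FitError(RuntimeError):
    """Raised when a dose-response fit cannot be completed."""

    def __init__(self, message: str, best_rss: float | None = None):
        super().__init__(message)
        self.best_rss = best_rss


# ---------------------------------------------------------------------------
# Normalization


def normalize_viability(
    values: np.ndarray,
    vehicle: np.ndarray,
    positive: np.ndarray | None = None,
    mode: str = "vehicle-only",
    readout: str = "viability",
) -> np.ndarray:
    """Normalize raw responses to control wells on a percent scale.

    ``vehicle-only``: value / mean(vehicle) × 100. ``vehicle+baseline``:
    (value − mean(positive)) / (mean(vehicle) − mean(positive)) × 100,
    so vehicle maps to 100% and the maximal-kill baseline to 0%. For a
    cell-death readout (EC50 direction) the anchors swap: vehicle → 0%,
    positive → 100%.
    """
    values = np.asarray(values, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    if vehicle.size == 0:
        raise ValidationError("vehicle: at least one vehicle control required")
    veh = vehicle.mean()
    if mode == "vehicle-only":
        if readout != "viability":
            raise ValidationError("readout: cell-death normalization needs a baseline")
        if veh == 0:
            raise ValidationError("vehicle: zero mean, cannot normalize")
        return values / veh * 100.0
    if mode != "vehicle+baseline":
        raise ValidationError(f"mode: unknown normalization mode {mode!r}")
    if positive is None or np.asarray(positive).size == 0:
        raise ValidationError("positive: baseline control required for vehicle+baseline")
    pos = np.asarray(positive, dtype=float).mean()
    if veh == pos:
        raise ValidationError("controls: vehicle and baseline means are equal")
    frac = (values - pos) / (veh - pos)
    if readout == "viability":
        return frac * 100.0
    if readout == "death":
        return (1.0 - frac) * 100.0
    raise ValidationError(f"readout: unknown readout {readout!r}")


# ---------------------------------------------------------------------------
# 4PL fitting


@dataclass
class DoseResponseFit:
    """4PL parameters and diagnostics for one dose-response curve."""

    top: float
    bottom: float
    hill: float
    log_ic50: float
    rss: float
    df: int
    n_points: int
    degenerate: bool = False

    @property
    def ic50(self) -> float:
        return float(10.0**self.log_ic50)

    def predict(self, conc: np.ndarray) -> np.ndarray:
        x = np.log10(np.asarray(conc, dtype=float))
        return _four_pl(x, self.top, self.bottom, self.hill, self.log_ic50)


def _four_pl(x, top, bottom, hill, log_ic50):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ic50 - x) * hill))


def _fit_starts(x, y, direction):
    top0, bot0 = float(np.max(y)), float(np.min(y))
    mids = [float(np.median(x)), float(np.quantile(x, 0.25)), float(np.quantile(x, 0.75))]
    hills = [-1.0, -2.0] if direction == "inhibitory" else [1.0, 2.0]
    starts = []
    for mid in mids:
        for h in hills:
            starts.append((top0, bot0, h, mid))
    return starts[:5]


def fit_4pl(
    conc: np.ndarray,
    resp: np.ndarray,
    direction: str = "inhibitory",
    xtol: float = 1e-8,
) -> DoseResponseFit:
    """Least-squares 4PL fit of responses against log10 concentration.

    ``direction`` sets the sign of the hill-slope starting values only;
    the slope itself is free. Requires >= 5 distinct concentrations so
    the residual degrees of freedom are positive. A flat response curve
    is returned flagged ``degenerate`` (IC50 unidentifiable).
    """
    conc = np.asarray(conc, dtype=float)
    resp = np.asarray(resp, dtype=float)
    keep = np.isfinite(conc) & np.isfinite(resp)
    conc, resp = conc[keep], resp[keep]
    if np.any(conc <= 0):
        raise ValidationError("conc: concentrations must be > 0")
    if len(np.unique(conc)) < 5:
        raise FitError("fewer than 5 distinct concentrations (df < 1)")
    if direction not in ("inhibitory", "stimulatory"):
        raise ValidationError(f"direction: unknown direction {direction!r}")
    x = np.log10(conc)
    n = len(x)

    if np.ptp(resp) < 1e-9 * max(1.0, abs(float(np.mean(resp)))):
        return DoseResponseFit(
            top=float(resp.mean()), bottom=float(resp.mean()), hill=0.0,
            log_ic50=float(np.median(x)), rss=float(np.sum((resp - resp.mean()) ** 2)),
            df=n - 4, n_points=n, degenerate=True,
        )

    def residuals(p):
        return _four_pl(x, *p) - resp

    best = None
    for p0 in _fit_starts(x, resp, direction):
        try:
            sol = optimize.least_squares(residuals, p0, xtol=xtol, ftol=xtol, gtol=xtol,
                                         max_nfev=2000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None or not best[1].success:
        raise FitError("4PL fit did not converge",
                       best_rss=None if best is None else best[0])
    rss, sol = best
    top, bottom, hill, log_ic50 = (float(v) for v in sol.x)
    if top < bottom:  # canonical orientation: top >= bottom, slope sign flips
        top, bottom, hill = bottom, top, -hill
    return DoseResponseFit(top=top, bottom=bottom, hill=hill, log_ic50=log_ic50,
                           rss=rss, df=n - 4, n_points=n)


def compare_logic50(
    conc_a: np.ndarray, resp_a: np.ndarray, conc_b: np.ndarray, resp_b: np.ndarray,
    direction: str = "inhibitory",
) -> dict:
    """Extra sum-of-squares F test for a shared log IC50 between two curves.

    The null model fits both datasets with a common log IC50 (top, bottom
    and hill per dataset); the alternative fits all parameters per
    dataset. F = ((RSS_shared − RSS_sep)/(df_shared − df_sep)) /
    (RSS_sep/df_sep), with the p-value from the F distribution.
    """
    fit_a = fit_4pl(conc_a, resp_a, direction)
    fit_b = fit_4pl(conc_b, resp_b, direction)
    rss_sep = fit_a.rss + fit_b.rss
    n_tot = fit_a.n_points + fit_b.n_points
    df_sep = n_tot - 8
    df_shared = n_tot - 7
    if df_sep <= 0:
        raise FitError("not enough points for the separate-fits model (df <= 0)")

    xa, ya = np.log10(np.asarray(conc_a, float)), np.asarray(resp_a, float)
    xb, yb = np.log10(np.asarray(conc_b, float)), np.asarray(resp_b, float)

    def residuals(p):
        ta, ba, ha, tb, bb, hb, mid = p
        ra = _four_pl(xa, ta, ba, ha, mid) - ya
        rb = _four_pl(xb, tb, bb, hb, mid) - yb
        return np.concatenate([ra, rb])

    starts = [
        (fit_a.top, fit_a.bottom, fit_a.hill, fit_b.top, fit_b.bottom, fit_b.hill, m)
        for m in (
            (fit_a.log_ic50 + fit_b.log_ic50) / 2.0,
            fit_a.log_ic50,
            fit_b.log_ic50,
        )
    ]
    best_rss = None
    for p0 in starts:
        try:
            sol = optimize.least_squares(residuals, p0, xtol=1e-10, ftol=1e-10,
                                         gtol=1e-10, max_nfev=4000)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best_rss is None or rss < best_rss:
            best_rss = rss
    if best_rss is None:
        raise FitError("shared-IC50 fit did not converge")
    rss_shared = max(best_rss, rss_sep)  # nested model cannot beat the full model

    f_stat = ((rss_shared - rss_sep) / (df_shared - df_sep)) / (rss_sep / df_sep)
    p_value = float(stats.f.sf(f_stat, df_shared - df_sep, df_sep))
    return {
        "f_stat": float(f_stat),
        "p_value": p_value,
        "rss_shared": rss_shared,
        "rss_separate": rss_sep,
        "df_shared": df_shared,
        "df_separate": df_sep,
        "log_ic50_a": fit_a.log_ic50,
        "log_ic50_b": fit_b.log_ic50,
        "significant": p_value < 0.05,
    }


# ---------------------------------------------------------------------------
# Screen quality and growth metrics


def z_factor(negative: np.ndarray, positive: np.ndarray) -> float:
    """Screen-quality Z-factor: 1 − (3·SD_neg + 3·SD_pos)/(mean_neg − mean_pos).

    Uses the sample standard deviation (ddof=1). A score near 1 indicates
    well-separated controls; values below 0 indicate overlapping controls.
    """
    negative = np.asarray(negative, dtype=float)
    positive = np.asarray(positive, dtype=float)
    if negative.size < 2 or positive.size < 2:
        raise ValidationError("controls: >= 2 values per control group required")
    sep = negative.mean() - positive.mean()
    if sep == 0:
        raise ValidationError("controls: equal group means, Z-factor undefined")
    return float(1.0 - (3.0 * negative.std(ddof=1) + 3.0 * positive.std(ddof=1)) / abs(sep))


def gr_metric(fc_treated: float, fc_vehicle: float) -> float:
    """Growth-rate (GR) metric from per-well fold changes since T0.

    ``gr = 2^(log2(fc_treated)/log2(fc_vehicle)) − 1``: 1 for growth equal
    to the vehicle control, 0 for complete growth arrest, negative when
    the treated well shrinks (cytotoxic response).
    """
    if fc_treated <= 0 or fc_vehicle <= 0:
        raise ValidationError("fold changes must be > 0")
    if fc_vehicle == 1.0:
        raise ValidationError("fc_vehicle: control did not grow (fold change 1), GR undefined")
    return float(2.0 ** (np.log2(fc_treated) / np.log2(fc_vehicle)) - 1.0)


def ndr_metric(fc_treated: float, fc_vehicle: float, fc_positive: float) -> float:
    """Normalized drug response (NDR) from treated/negative/positive fold changes.

    Anchors: 1 when the treated well grows like the vehicle control, 0 at
    complete growth inhibition (no net change from T0), −1 when the well
    declines like the maximal-kill positive control; values above 1
    indicate a proliferative effect. Piecewise in log2 fold change f:
    ``f_t/f_v`` for f_t ≥ 0 (growth, scaled by control growth) and
    ``f_t/|f_p|`` for f_t < 0 (decline, scaled by control killing);
    strictly increasing in fc_treated.
    """
    if fc_treated <= 0:
        raise ValidationError("fc_treated: fold change must be > 0")
    if fc_vehicle <= 1.0:
        raise ValidationError("fc_vehicle: negative control must grow (fold change > 1)")
    if not 0.0 < fc_positive < 1.0:
        raise ValidationError(
            "fc_positive: positive control must decline (fold change in (0, 1))"
        )
    f_t = np.log2(fc_treated)
    f_v = np.log2(fc_vehicle)
    f_p = np.log2(fc_positive)
    if f_t >= 0:
        return float(f_t / f_v)
    return float(f_t / abs(f_p))


def classify_response(value: float, tol: float = 0.05) -> str:
    """Classify a GR/NDR value into the standard drug-effect categories.

    ≈1 normal growth; >1 proliferative; in (0, 1) cytostatic; ≈0 complete
    growth inhibition; <0 cytotoxic.
    """
    if not np.isfinite(value):
        raise ValidationError("value: GR/NDR must be finite")
    if abs(value - 1.0) <= tol:
        return "normal"
    if abs(value) <= tol:
        return "complete growth inhibition"
    if value > 1.0:
        return "proliferative"
    if value > 0.0:
        return "cytostatic"
    return "cytotoxic"


def pairwise_regression(x: np.ndarray, y: np.ndarray) -> dict:
    """Ordinary least-squares regression of y on x for method comparison.

    Reports slope, bias (intercept) and R², plus a residual summary
    around the line of unity (y = x).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("x/y: at least 3 paired finite values required")
    if np.ptp(x) == 0:
        raise ValidationError("x: zero variance, regression undefined")
    res = stats.linregress(x, y)
    unity = y - x
    return {
        "slope": float(res.slope),
        "bias": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "unity_mean_residual": float(unity.mean()),
        "unity_rms_residual": float(np.sqrt(np.mean(unity**2))),
        "n": int(x.size),
    }
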