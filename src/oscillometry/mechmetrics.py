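"""Derived mechanical indices.

* Temporal-variability indices: interquartile ranges of Gaussian kernel
  density estimates of the pre-DI inspiratory R5, R5-19 and X5 series —
  short-term variability of bronchial tone.
* Post-deep-inspiration kinetics: linear regression of per-breath R5 and X5
  against time after the DI, stopped when the pre-DI level is reached; the
  intercept (back-extrapolated to the moment the DI ended) measures the
  bronchodilator effect of lung inflation, the slope the velocity of airway
  renarrowing / reclosure.
* Methacholine dose-response interpolation (PD15/PD25) on a log2 dose axis,
  matching the doubling-dose challenge design.
* Obstruction-level classification from the FEV1 fall, and the
  maximal-to-partial flow ratio M40m/M40p.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "VariabilityIndices", "DIResponse",
    "density_iqr", "variability_indices", "di_response",
    "interpolate_pd", "classify_level", "mp_ratio",
]


@dataclass
class VariabilityIndices:
    r5_iqr: float
    r5_19_iqr: float
    x5_iqr: float
    n_breaths: int
    bandwidths: dict


@dataclass
class DIResponse:
    """Post-DI renarrowing kinetics.

    Intercepts are the regression values at ``t0`` (the time the DI ended);
    slopes are per minute.  ``reliable`` is False when fewer than three
    breaths entered a fit.
    """

    pre_r5: float
    pre_x5: float
    r5_int: float
    x5_int: float
    r5_slope: float
    x5_slope: float
    n_r: int
    n_x: int
    t0: float
    reliable: bool


def density_iqr(values, bw_method="silverman", grid_points: int = 2048,
                method: str = "kde") -> float:
    """IQR of the estimated probability density of a series.

    A Gaussian KDE (Silverman bandwidth by default) is integrated on a fine
    grid and the 25th/75th percentiles of the estimated CDF are
    interpolated.  ``method="sample"`` falls back to the plain empirical
    IQR.  At least 8 values are required; a constant series has IQR 0.
    """
    x = np.asarray(list(values), float)
    x = x[np.isfinite(x)]
    if x.size < 8:
        raise ValueError(f"density_iqr requires at least 8 values, got {x.size}")
    if np.ptp(x) == 0:
        return 0.0
    if method == "sample":
        q25, q75 = np.percentile(x, [25, 75])
        return float(q75 - q25)
    kde = gaussian_kde(x, bw_method=bw_method)
    h = math.sqrt(float(kde.covariance[0, 0]))
    grid = np.linspace(x.min() - 4 * h, x.max() + 4 * h, grid_points)
    cdf = cumulative_trapezoid(kde(grid), grid, initial=0.0)
    cdf /= cdf[-1]
    q25, q75 = np.interp([0.25, 0.75], cdf, grid)
    return float(q75 - q25)


def variability_indices(breaths: pd.DataFrame, pre_di_end: float | None = None,
                        method: str = "kde") -> VariabilityIndices:
    """Temporal-variability IQRs from accepted pre-DI breaths.

    Uses the inspiratory-phase series.  ``pre_di_end`` (s) truncates the
    table to breaths with mid-time before the DI; by default all rows of the
    given table are used (pass an already-filtered table or the DI time).
    """
    sel = breaths
    if "accepted" in sel.columns:
        sel = sel[sel["accepted"]]
    if "is_di" in sel.columns:
        sel = sel[~sel["is_di"].astype(bool)]
    if pre_di_end is not None:
        sel = sel[sel["t_mid"] < pre_di_end]
    bws = {}
    out = {}
    for key, col in (("r5", "r5_insp"), ("r5_19", "r5_19_insp"), ("x5", "x5_insp")):
        out[key] = density_iqr(sel[col], method=method)
    return VariabilityIndices(r5_iqr=out["r5"], r5_19_iqr=out["r5_19"],
                              x5_iqr=out["x5"], n_breaths=len(sel),
                              bandwidths=bws)


def _stopped_fit(t: np.ndarray, y: np.ndarray, stop_mask: np.ndarray):
    """OLS of y on t (minutes), truncated at the first breath where
    ``stop_mask`` is True (recovery reached the pre-DI level).
    Returns (intercept, slope_per_min, n, reliable).
    """
    hit = np.flatnonzero(stop_mask)
    k = hit[0] if hit.size else t.size
    if k == 0 and t.size:
        k = 1  # recovery complete within the first breath: report its value
    t, y = t[:k], y[:k]
    n = t.size
    if n == 0:
        return float("nan"), float("nan"), 0, False
    if n == 1:
        return float(y[0]), float("nan"), 1, False
    slope, intercept = np.polyfit(t / 60.0, y, 1)
    return float(intercept), float(slope), n, n >= 3


def di_response(breaths: pd.DataFrame, t0: float, pre_r5: float, pre_x5: float,
                max_window: float = 120.0, pre_r5_sd: float = 0.0,
                pre_x5_sd: float = 0.0,
                r_col: str = "r5", x_col: str = "x5") -> DIResponse:
    """Linear post-DI recovery kinetics of R5 and X5.

    Breaths with mid-time in ``(t0, t0 + max_window]`` are used, each series
    truncated at the first breath that reaches its pre-DI reference
    (R5 >= pre_r5 for the resistance fit, X5 <= pre_x5 for the reactance
    fit).  Time is measured from ``t0``; intercepts are the fitted values at
    t = 0 and slopes are per minute.  Fits with fewer than three breaths are
    flagged unreliable (and with fewer than two, the intercept falls back to
    the first-breath value with an undefined slope).
    """
    sel = breaths
    if "accepted" in sel.columns:
        sel = sel[sel["accepted"]]
    if "is_di" in sel.columns:
        sel = sel[~sel["is_di"].astype(bool)]
    sel = sel[(sel["t_mid"] > t0) & (sel["t_mid"] <= t0 + max_window)]
    sel = sel.sort_values("t_mid")
    t = sel["t_mid"].to_numpy() - t0
    r = sel[r_col].to_numpy()
    x = sel[x_col].to_numpy()

    # A breath counts as "reached pre-DI" when it is indistinguishable from
    # the pre-DI distribution: within one pre-DI SD of the median, or within
    # 2% of the observed DI drop.  Without a tolerance a recovery saturating
    # at the pre-DI plateau would asymptote strictly below the median, never
    # trigger the stop, and let censored (partially recovered) breaths
    # flatten the regression.
    tol_r = max(pre_r5_sd, 0.02 * max(pre_r5 - r[0], 0.0)) if r.size else 0.0
    tol_x = max(pre_x5_sd, 0.02 * max(x[0] - pre_x5, 0.0)) if x.size else 0.0
    r_int, r_slope, n_r, ok_r = _stopped_fit(t, r, r >= pre_r5 - tol_r)
    x_int, x_slope, n_x, ok_x = _stopped_fit(t, x, x <= pre_x5 + tol_x)
    if not (ok_r and ok_x):
        logger.warning("di_response: fewer than 3 usable post-DI breaths "
                       "(n_r=%d, n_x=%d); result flagged unreliable", n_r, n_x)
    return DIResponse(pre_r5=pre_r5, pre_x5=pre_x5,
                      r5_int=r_int, x5_int=x_int,
                      r5_slope=r_slope, x5_slope=x_slope,
                      n_r=n_r, n_x=n_x, t0=t0, reliable=ok_r and ok_x)


def interpolate_pd(doses, falls, target: float) -> float:
    """Provocative dose producing a target FEV1 fall (% of control).

    Linear interpolation of fall against log2(dose) between the bracketing
    doses of the dose-response curve; raises when the target fall is not
    bracketed (never reached, or below the first measured point).
    """
    doses = np.asarray(list(doses), float)
    falls = np.asarray(list(falls), float)
    if doses.size != falls.size or doses.size < 1:
        raise ValueError("doses and falls must be equal-length, non-empty")
    if np.any(doses <= 0) or np.any(np.diff(doses) <= 0):
        raise ValueError("doses must be strictly increasing and positive")
    exact = np.flatnonzero(falls == target)
    if exact.size:
        return float(doses[exact[0]])
    if target < falls[0]:
        raise ValueError("target fall is below the first dose-response point")
    for i in range(doses.size - 1):
        lo, hi = falls[i], falls[i + 1]
        if lo < target <= hi:
            frac = (target - lo) / (hi - lo)
            ld = math.log2(doses[i]) + frac * (math.log2(doses[i + 1]) - math.log2(doses[i]))
            return float(2.0 ** ld)
    raise ValueError("dose-response does not bracket target")


def classify_level(fev1_fall: float) -> str:
    """Obstruction level from the FEV1 fall (% of control).

    Bands are open as printed: (10, 20) mild, (20, 30) moderate; a fall of
    exactly 20% belongs to neither and is left unclassified.  Falls <= 10%
    are within the baseline range, >= 30% beyond the studied range.
    """
    if not np.isfinite(fev1_fall):
        raise ValueError("fev1_fall must be finite")
    if fev1_fall <= 10:
        return "baseline"
    if 10 < fev1_fall < 20:
        return "mild"
    if 20 < fev1_fall < 30:
        return "moderate"
    if fev1_fall >= 30:
        return "beyond"
    return "unclassified"


def mp_ratio(m40m: float, m40p: float) -> float:
    """Maximal-to-partial forced expiratory flow ratio at 40% of control FVC."""
    if m40p <= 0:
        raise ValueError("M40p must be > 0")
    return float(m40m / m40p)
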