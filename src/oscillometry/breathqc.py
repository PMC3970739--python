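"""Breath-rejection criteria and ventilation summaries.

Breaths contaminated by glottis closure or expiratory flow limitation are
discarded when any of three criteria fires:

(i)   tidal volume < 0.1 L or > 2.0 L;
(ii)  flow-distortion index > 0.2 (measured oscillation vs the ideal sine
      with the same Fourier coefficients);
(iii) ratio of minimum to average within-breath reactance > 3.5.

All thresholds are configurable; the bounds are strict inequalities, so a
breath sitting exactly on a threshold is accepted.  Ventilation (VT, BF,
minute ventilation) is summarized over the accepted breaths only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["QCThresholds", "QCResult", "VentilationSummary",
           "qc_breath", "qc_table", "summarize_ventilation"]

VT_RANGE = "VT_RANGE"
DISTORTION = "DISTORTION"
X_RATIO = "X_RATIO"
UNEVALUABLE = "UNEVALUABLE"


@dataclass(frozen=True)
class QCThresholds:
    vt_min: float = 0.1
    vt_max: float = 2.0
    distortion_max: float = 0.2
    xratio_max: float = 3.5


@dataclass
class QCResult:
    index: int
    accepted: bool
    reasons: frozenset
    thresholds: QCThresholds


@dataclass
class VentilationSummary:
    """Mean tidal volume (L), breathing frequency (breaths/min) and minute
    ventilation (L/min) over accepted breaths; BF is 60 over the mean breath
    duration, so VE = VT * BF holds by construction.
    """

    vt: float
    bf: float
    ve: float
    n_breaths: int


def qc_breath(vt: float, distortion: float, xratio: float,
              thresholds: QCThresholds = QCThresholds(),
              index: int = 0) -> QCResult:
    """Evaluate the three rejection criteria for one breath.

    Missing (NaN) distortion or reactance-ratio metrics make the breath
    unevaluable and it is rejected.
    """
    reasons = set()
    if not np.isfinite(vt) or not np.isfinite(distortion) or not np.isfinite(xratio):
        logger.info("breath %d rejected: QC metrics unevaluable", index)
        reasons.add(UNEVALUABLE)
    else:
        if vt < thresholds.vt_min or vt > thresholds.vt_max:
            reasons.add(VT_RANGE)
        if distortion > thresholds.distortion_max:
            reasons.add(DISTORTION)
        if xratio > thresholds.xratio_max:
            reasons.add(X_RATIO)
    return QCResult(index=index, accepted=not reasons,
                    reasons=frozenset(reasons), thresholds=thresholds)


def qc_table(breaths: pd.DataFrame,
             thresholds: QCThresholds = QCThresholds()) -> pd.DataFrame:
    """Apply QC to a per-breath table, adding ``accepted`` and ``qc_flags``.

    Breaths already flagged invalid by the impedance stage are rejected as
    unevaluable.  The DI breath keeps its QC verdict but downstream
    summaries exclude it (a maneuver, not tidal breathing).
    """
    out = breaths.copy()
    accepted, flags = [], []
    for _, row in out.iterrows():
        if not row.get("valid", True):
            accepted.append(False)
            flags.append(UNEVALUABLE)
            continue
        res = qc_breath(row["vt"], row["distortion"], row["xmin_ratio"],
                        thresholds, index=int(row["index"]))
        accepted.append(res.accepted)
        flags.append(",".join(sorted(res.reasons)))
    out["accepted"] = accepted
    out["qc_flags"] = flags
    return out


def summarize_ventilation(breaths: pd.DataFrame) -> VentilationSummary:
    """Ventilation over accepted, non-DI breaths (VT mean, BF = 60/mean
    duration, VE = VT*BF).  Raises on an empty set rather than returning NaN.
    """
    sel = breaths
    if "accepted" in sel.columns:
        sel = sel[sel["accepted"]]
    if "is_di" in sel.columns:
        sel = sel[~sel["is_di"].astype(bool)]
    if len(sel) == 0:
        raise ValueError("no accepted breaths to summarize")
    vt = float(sel["vt"].mean())
    bf = 60.0 / float(sel["duration"].mean())
    return VentilationSummary(vt=vt, bf=bf, ve=vt * bf, n_breaths=len(sel))
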