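"""Breath segmentation and within-breath impedance estimation.

Respiratory resistance R(f) and reactance X(f) at the stimulation
frequencies are obtained by ordinary least squares: within an analysis
window, pressure and flow are each regressed onto {sin, cos} pairs at every
oscillation frequency plus a low-order polynomial that absorbs the
breathing-frequency trend (in-regression detrending avoids the phase
distortion a pre-filter would introduce at 5 Hz).  The impedance is the
ratio of the complex pressure and flow coefficients:

    Z(f) = C_P(f) / C_F(f),   R = Re(Z),  X = Im(Z)

Breaths are delimited at inspiratory onsets (upward zero crossings of the
low-pass-filtered flow), and each breath carries the artifact metrics used
for quality control: the flow-distortion index and the within-breath
minimum-to-mean reactance ratio.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .signals import SignalRecord

logger = logging.getLogger(__name__)

FREQS_DEFAULT = (5.0, 11.0, 19.0)

__all__ = [
    "BreathSegment",
    "BreathImpedance",
    "segment_breaths",
    "fit_window_impedance",
    "estimate_breath_impedance",
    "distortion_index",
    "xmin_ratio",
    "breath_table",
]


@dataclass
class BreathSegment:
    """One breath as a half-open sample interval [start, end).

    ``insp_end`` marks the inspiration/expiration boundary; ``vt`` is the
    inspired volume (L) from the low-pass-filtered flow.
    """

    index: int
    start: int
    end: int
    insp_end: int
    vt: float
    duration: float
    t_mid: float
    is_di: bool = False


@dataclass
class BreathImpedance:
    """Per-breath impedance estimates and QC metrics.

    Inspiratory-phase values carry the ``_insp`` suffix; plain names are
    whole-breath.  ``r5_19 = r5 - r19`` exactly, per phase.
    """

    index: int
    t_mid: float
    vt: float
    duration: float
    is_di: bool
    r5_insp: float = np.nan
    x5_insp: float = np.nan
    r19_insp: float = np.nan
    x19_insp: float = np.nan
    r5_19_insp: float = np.nan
    r5: float = np.nan
    x5: float = np.nan
    r19: float = np.nan
    x19: float = np.nan
    r5_19: float = np.nan
    distortion: float = np.nan
    xmin_ratio: float = np.nan
    valid: bool = True
    invalid_reason: str | None = None


def _lowpass(flow: np.ndarray, fs: float, cutoff: float) -> np.ndarray:
    sos = butter(4, cutoff, btype="low", fs=fs, output="sos")
    return sosfiltfilt(sos, flow)


def segment_breaths(sig: SignalRecord, cutoff: float = 2.0,
                    min_breath_s: float = 1.0) -> list[BreathSegment]:
    """Delimit breaths at inspiratory onsets.

    Onsets are upward zero crossings of the flow low-pass-filtered below the
    lowest oscillation frequency (default 2 Hz); crossings closer than
    ``min_breath_s`` are merged.  A trailing segment is kept when it is at
    least half the median breath length.  The breath containing a
    ``di_onset`` event is labeled as the DI breath.
    """
    f = _lowpass(sig.flow, sig.fs, cutoff)
    up = np.flatnonzero((f[:-1] <= 0) & (f[1:] > 0))
    up = up + (f[up] < 0)
    if up.size == 0:
        logger.warning("segment_breaths: no zero crossings found; empty result")
        return []

    onsets = [int(up[0])]
    for i in up[1:]:
        if (i - onsets[-1]) / sig.fs >= min_breath_s:
            onsets.append(int(i))

    bounds = list(zip(onsets[:-1], onsets[1:]))
    if len(bounds) >= 1:
        med = float(np.median([b - a for a, b in bounds]))
        if sig.n - onsets[-1] >= 0.5 * med:
            bounds.append((onsets[-1], sig.n))

    down = np.flatnonzero((f[:-1] > 0) & (f[1:] <= 0)) + 1
    t_di = sig.event_time("di_onset")

    segs = []
    for start, end in bounds:
        d_after = down[(down > start) & (down <= end)]
        if d_after.size == 0:
            continue
        insp_end = int(d_after[0])
        vt = float(np.trapezoid(f[start:insp_end], dx=1.0 / sig.fs))
        t_start, t_end = sig.t[start], sig.t[min(end, sig.n - 1)]
        is_di = t_di is not None and t_start <= t_di < t_end
        segs.append(BreathSegment(
            index=len(segs), start=start, end=end, insp_end=insp_end,
            vt=vt, duration=float((end - start) / sig.fs),
            t_mid=float(0.5 * (t_start + t_end)), is_di=is_di,
        ))
    return segs


def _design(t: np.ndarray, freqs, poly_order: int, trend_freqs=()) -> np.ndarray:
    """Sin/cos columns at each oscillation frequency plus the trend basis
    (Legendre polynomial and optional low-frequency breathing harmonics).
    """
    cols = []
    for f in list(freqs) + list(trend_freqs):
        w = 2 * math.pi * f
        cols.append(np.cos(w * t))
        cols.append(np.sin(w * t))
    tn = np.linspace(-1.0, 1.0, t.size)
    cols.append(np.polynomial.legendre.legvander(tn, poly_order))
    return np.column_stack(cols[:-1] + [cols[-1]])


def breathing_trend_freqs(window_s: float, f_max: float, n_harmonics: int = 6):
    """Low-frequency harmonics of the half-window fundamental used to absorb
    the breathing trend inside a breath-length regression window; capped
    below ``f_max`` to stay clear of the oscillation tones.
    """
    f0 = 1.0 / (2.0 * window_s)
    return tuple(k * f0 for k in range(1, n_harmonics + 1) if k * f0 < f_max)


def fit_window_impedance(t: np.ndarray, flow: np.ndarray, pressure: np.ndarray,
                         freqs=FREQS_DEFAULT, poly_order: int = 3,
                         flow_amp_min: float = 0.01, trend_freqs=()) -> dict:
    """Least-squares impedance at each oscillation frequency in one window.

    Returns ``{f: (Z, valid)}``.  A frequency is flagged invalid when the
    fitted oscillatory flow amplitude falls below ``flow_amp_min`` (L/s),
    the guard against estimating impedance from noise.
    """
    t = np.asarray(t, float)
    A = _design(t, freqs, poly_order, trend_freqs)
    coef, *_ = np.linalg.lstsq(A, np.column_stack([pressure, flow]), rcond=None)
    out = {}
    for k, f in enumerate(freqs):
        cp = coef[2 * k, 0] - 1j * coef[2 * k + 1, 0]
        cf = coef[2 * k, 1] - 1j * coef[2 * k + 1, 1]
        if abs(cf) < flow_amp_min:
            out[f] = (complex(np.nan, np.nan), False)
        else:
            out[f] = (cp / cf, True)
    return out


def distortion_index(t: np.ndarray, flow: np.ndarray, f: float,
                     freqs=FREQS_DEFAULT, poly_order: int = 3,
                     trend_freqs=()) -> float:
    """Deviation of the measured flow oscillation from an ideal sine.

    The flow is decomposed into the fitted tones plus a polynomial trend;
    the ideal sine at ``f`` is its own sin/cos reconstruction, the measured
    oscillation is that sine plus everything the model does not explain.
    The index is RMS(measured - ideal) / RMS(ideal).  Returns NaN when the
    ideal sine has zero amplitude (undefined).
    """
    t = np.asarray(t, float)
    A = _design(t, freqs, poly_order, trend_freqs)
    coef, *_ = np.linalg.lstsq(A, np.asarray(flow, float), rcond=None)
    k = list(freqs).index(f)
    ideal = A[:, 2 * k : 2 * k + 2] @ coef[2 * k : 2 * k + 2]
    rms_ideal = math.sqrt(float(np.mean(ideal**2)))
    if rms_ideal == 0:
        return float("nan")
    resid = flow - A @ coef
    return math.sqrt(float(np.mean(resid**2))) / rms_ideal


def xmin_ratio(x_series) -> float:
    """Minimum-to-mean ratio of within-breath reactance estimates.

    Computed on signed values: with X < 0 throughout, this is
    |X_min| / |X_mean| >= 1, large when reactance transiently plunges
    (glottis closure, flow limitation).  Returns NaN with fewer than four
    estimates or a zero mean.
    """
    x = np.asarray([v for v in x_series if np.isfinite(v)], float)
    if x.size < 4:
        return float("nan")
    m = float(np.mean(x))
    if m == 0:
        return float("nan")
    return float(np.min(x) / m)


def _subwindow_x(sig: SignalRecord, start: int, end: int, f: float, freqs,
                 window: float, hop: float, flow_amp_min: float) -> list:
    nw = int(round(window * sig.fs))
    nh = max(1, int(round(hop * sig.fs)))
    xs = []
    i = start
    while i + nw <= end:
        fit = fit_window_impedance(
            sig.t[i:i + nw], sig.flow[i:i + nw], sig.pressure[i:i + nw],
            freqs=freqs, poly_order=2, flow_amp_min=flow_amp_min)
        z, ok = fit[f]
        if ok:
            xs.append(z.imag)
        i += nh
    return xs


def estimate_breath_impedance(sig: SignalRecord, seg: BreathSegment,
                              freqs=FREQS_DEFAULT, poly_order: int = 3,
                              window: float = 0.4, hop: float = 0.25,
                              flow_amp_min: float = 0.01) -> BreathImpedance:
    """Estimate inspiratory and whole-breath impedance for one breath.

    The inspiratory window must span at least two cycles of the lowest
    oscillation frequency (0.4 s at 5 Hz) or the breath is flagged invalid;
    so is a breath whose oscillatory flow amplitude fails the SNR guard.
    """
    bi = BreathImpedance(index=seg.index, t_mid=seg.t_mid, vt=seg.vt,
                         duration=seg.duration, is_di=seg.is_di)
    f_lo, f_hi = min(freqs), max(freqs)
    min_len = 2.0 / f_lo
    if (seg.insp_end - seg.start) / sig.fs < min_len:
        bi.valid = False
        bi.invalid_reason = "insp_window_short"
        return bi

    sl_i = slice(seg.start, seg.insp_end)
    sl_w = slice(seg.start, seg.end)
    tf_i = breathing_trend_freqs((seg.insp_end - seg.start) / sig.fs, f_lo / 2)
    tf_w = breathing_trend_freqs((seg.end - seg.start) / sig.fs, f_lo / 2)
    fit_i = fit_window_impedance(sig.t[sl_i], sig.flow[sl_i], sig.pressure[sl_i],
                                 freqs=freqs, poly_order=poly_order,
                                 flow_amp_min=flow_amp_min, trend_freqs=tf_i)
    fit_w = fit_window_impedance(sig.t[sl_w], sig.flow[sl_w], sig.pressure[sl_w],
                                 freqs=freqs, poly_order=poly_order,
                                 flow_amp_min=flow_amp_min, trend_freqs=tf_w)
    if not (fit_i[f_lo][1] and fit_w[f_lo][1]):
        bi.valid = False
        bi.invalid_reason = "low_osc_snr"
        return bi

    zi5, zw5 = fit_i[f_lo][0], fit_w[f_lo][0]
    bi.r5_insp, bi.x5_insp = zi5.real, zi5.imag
    bi.r5, bi.x5 = zw5.real, zw5.imag
    if f_hi in fit_i and fit_i[f_hi][1]:
        zi19 = fit_i[f_hi][0]
        bi.r19_insp, bi.x19_insp = zi19.real, zi19.imag
        bi.r5_19_insp = bi.r5_insp - bi.r19_insp
    if f_hi in fit_w and fit_w[f_hi][1]:
        zw19 = fit_w[f_hi][0]
        bi.r19, bi.x19 = zw19.real, zw19.imag
        bi.r5_19 = bi.r5 - bi.r19

    bi.distortion = distortion_index(sig.t[sl_w], sig.flow[sl_w], f_lo,
                                     freqs=freqs, poly_order=poly_order,
                                     trend_freqs=tf_w)
    bi.xmin_ratio = xmin_ratio(
        _subwindow_x(sig, seg.start, seg.end, f_lo, freqs, window, hop,
                     flow_amp_min))
    return bi


def breath_table(sig: SignalRecord, segs=None, **kwargs) -> pd.DataFrame:
    """Segment a recording (unless segments are given) and estimate every
    breath, returning one row per breath.
    """
    if segs is None:
        segs = segment_breaths(sig)
    rows = [estimate_breath_impedance(sig, s, **kwargs).__dict__ for s in segs]
    cols = [f.name for f in BreathImpedance.__dataclass_fields__.values()]
    return pd.DataFrame(rows, columns=cols)
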