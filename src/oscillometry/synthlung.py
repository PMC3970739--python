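"""Virtual-lung simulator for within-breath forced-oscillation studies.

A single-compartment respiratory system is driven by a *prescribed* flow —
sinusoidal tidal breathing, an optional deep inspiration (DI), and small
multi-sine oscillations — and the airway-opening pressure is computed from
the mechanics::

    P(t) = R(t) * V'(t) + E * V(t) + I * V''(t)

where the instantaneous resistance

    R(t) = R0 * (1 + x(t)) * (1 - vol_gain * V_slow(t)) * g_DI(t)

combines a stationary Ornstein-Uhlenbeck fluctuation ``x(t)`` (stochastic
airway tone), volume-dependent bronchodilation, and a post-DI factor that
drops to ``1 - di_drop`` at the end of the DI and recovers linearly at
``renarrow_slope`` (saturating at the pre-DI level).  Because flow is
prescribed, the true impedance Z(f) = R + j(2*pi*f*I - E/(2*pi*f)) is known
analytically, which makes every downstream estimator exactly testable.

The module also generates whole cohorts of subjects observed at baseline and
at two induced-obstruction levels, with Borg symptom scores planted as
linear functions of configured mechanics changes — the ground truth for the
symptom-statistics pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import lfilter

from .signals import SignalRecord

__all__ = [
    "MechConfig",
    "CohortConfig",
    "MECH_VARIABLES",
    "BORG_DESCRIPTORS",
    "nominal_impedance",
    "simulate_mechanics",
    "simulate_subject_protocol",
    "simulate_cohort",
]


@dataclass
class MechConfig:
    """Mechanical and protocol parameters of one simulated recording.

    Units: resistances cmH2O*s/L, elastance cmH2O/L, inertance cmH2O*s^2/L,
    volumes L, times s, ``renarrow_slope`` cmH2O*s/L per minute.

    ``tone_sd`` is the stationary SD of the resistance fluctuation in
    absolute units (cmH2O*s/L); internally the OU process runs on the
    fractional scale ``tone_sd / R0``.  ``vol_gain`` is the fractional
    resistance reduction per litre of volume above FRC.  ``di_time=None``
    disables the deep inspiration.  ``osc_flow_amps``, when given, fixes the
    oscillatory *flow* amplitudes directly; otherwise flow amplitudes are
    scaled so the oscillatory *pressure* is ~``osc_amp`` at each frequency.
    """

    R0: float = 2.5
    E: float = 35.0
    I: float = 0.01
    tone_sd: float = 0.2
    tone_tau: float = 10.0
    vol_gain: float = 0.05
    di_drop: float = 0.3
    renarrow_slope: float = 1.0
    VT: float = 1.1
    BF: float = 14.0
    di_time: float | None = 300.0
    di_volume: float = 2.0
    di_duration: float = 4.0
    osc_freqs: tuple = (5.0, 11.0, 19.0)
    osc_amp: float = 2.0
    osc_flow_amps: tuple | None = None
    fs: float = 200.0
    duration: float = 420.0

    def validate(self) -> None:
        if not self.R0 > 0:
            raise ValueError("R0 must be > 0")
        if self.E < 0 or self.I < 0:
            raise ValueError("E and I must be >= 0")
        if self.tone_sd < 0 or self.tone_tau <= 0:
            raise ValueError("tone_sd must be >= 0 and tone_tau > 0")
        if not (0 <= self.di_drop < 1):
            raise ValueError("di_drop must be in [0, 1)")
        if self.VT <= 0 or self.BF <= 0:
            raise ValueError("VT and BF must be > 0")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("duration and fs must be > 0")
        if self.osc_freqs and self.fs < 10 * max(self.osc_freqs):
            raise ValueError("fs must be >= 10x the highest oscillation frequency")
        if self.osc_flow_amps is not None and len(self.osc_flow_amps) != len(self.osc_freqs):
            raise ValueError("osc_flow_amps must match osc_freqs in length")
        if self.di_time is not None:
            if self.di_time < 0 or self.di_time + self.di_duration > self.duration:
                raise ValueError("DI maneuver must fit inside the recording")


def nominal_impedance(cfg: MechConfig, f: float) -> complex:
    """Analytic input impedance of the R0-E-I compartment at frequency f."""
    w = 2 * math.pi * f
    return cfg.R0 + 1j * (w * cfg.I - cfg.E / w)


def _ou_fractional(n: int, dt: float, sd: float, tau: float, rng) -> np.ndarray:
    """Stationary OU path with SD ``sd`` and correlation time ``tau``.

    Exact AR(1) discretization; the initial state is drawn from the
    stationary law so no burn-in is needed.
    """
    if sd == 0:
        return np.zeros(n)
    rho = math.exp(-dt / tau)
    eps = rng.standard_normal(n) * (sd * math.sqrt(1.0 - rho * rho))
    eps[0] = rng.standard_normal() * sd
    return lfilter([1.0], [1.0, -rho], eps)


def simulate_mechanics(cfg: MechConfig, seed: int) -> SignalRecord:
    """Simulate one recording of tidal breathing with superimposed oscillations.

    Flow is prescribed (tidal sinusoid + optional DI excursion + multi-sine
    oscillation); pressure follows from the time-varying single-compartment
    mechanics.  ``seed`` is required: the airway-tone fluctuation is the only
    stochastic element, but determinism is enforced for every run.
    """
    if seed is None:
        raise ValueError("seed is required (pass an explicit integer)")
    cfg.validate()
    rng = np.random.default_rng(seed)

    n = int(round(cfg.duration * cfg.fs))
    dt = 1.0 / cfg.fs
    t = np.arange(n) * dt

    # tidal component: V_tid = VT/2 * (1 - cos(wb t)) in [0, VT]
    wb = 2 * math.pi * cfg.BF / 60.0
    v_slow = cfg.VT / 2.0 * (1.0 - np.cos(wb * t))
    flow = cfg.VT / 2.0 * wb * np.sin(wb * t)
    dflow = cfg.VT / 2.0 * wb * wb * np.cos(wb * t)

    events = []
    if cfg.di_time is not None:
        t0, T = cfg.di_time, cfg.di_duration
        tau_di = t - t0
        in_di = (tau_di >= 0) & (tau_di < T)
        A = cfg.di_volume
        v_slow = v_slow + np.where(in_di, A * np.sin(math.pi * tau_di / T) ** 2, 0.0)
        flow = flow + np.where(
            in_di, A * math.pi / T * np.sin(2 * math.pi * tau_di / T), 0.0
        )
        dflow = dflow + np.where(
            in_di, A * 2 * math.pi**2 / T**2 * np.cos(2 * math.pi * tau_di / T), 0.0
        )
        events = [("di_onset", t0), ("di_end", t0 + T)]

    for k, f in enumerate(cfg.osc_freqs):
        if cfg.osc_flow_amps is not None:
            a = cfg.osc_flow_amps[k]
        else:
            zmag = abs(nominal_impedance(cfg, f))
            a = cfg.osc_amp / zmag if zmag > 0 else cfg.osc_amp
        w = 2 * math.pi * f
        flow = flow + a * np.sin(w * t)
        dflow = dflow + a * w * np.cos(w * t)

    volume = cumulative_trapezoid(flow, dx=dt, initial=0.0)

    x = _ou_fractional(n, dt, cfg.tone_sd / cfg.R0, cfg.tone_tau, rng)
    R = cfg.R0 * (1.0 + x) * (1.0 - cfg.vol_gain * v_slow)
    R = np.maximum(R, 0.05 * cfg.R0)

    if cfg.di_time is not None and cfg.di_drop > 0:
        t_end = cfg.di_time + cfg.di_duration
        # dilation develops linearly during the DI, then recovers linearly
        ramp = np.clip((t - cfg.di_time) / cfg.di_duration, 0.0, 1.0)
        dilated = R * (1.0 - cfg.di_drop * ramp)
        post = t >= t_end
        recovery = dilated + np.where(
            post, cfg.renarrow_slope * (t - t_end) / 60.0, 0.0
        )
        R = np.where(t >= cfg.di_time, np.minimum(R, recovery), R)

    pressure = R * flow + cfg.E * volume + cfg.I * dflow
    return SignalRecord(t=t, flow=flow, pressure=pressure, volume=volume,
                        fs=cfg.fs, events=events)


def simulate_subject_protocol(cfg: MechConfig, seed: int) -> SignalRecord:
    """Simulate the study-day recording: tidal breathing with a DI followed
    by at least two minutes of recovery breathing.
    """
    if cfg.di_time is None:
        raise ValueError("subject protocol requires a DI (di_time is None)")
    min_dur = cfg.di_time + 120.0
    if cfg.duration < min_dur:
        raise ValueError(
            f"duration {cfg.duration:g} s too short: protocol requires at least "
            f"{min_dur:g} s (di_time + 120 s of post-DI breathing)"
        )
    return simulate_mechanics(cfg, seed)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------

BORG_DESCRIPTORS = ("tightness", "insp_effort", "unrewarded", "exp_difficulty")

#: mechanics / lung-function variables available as planted or decoy
#: predictors: name -> (baseline mean, baseline SD, mean change at mild,
#: mean change at moderate).  Means are anchored to typical mild-asthma
#: challenge cohorts; changes are additive.
MECH_VARIABLES: dict = {
    "FVC": (4.58, 0.96, -0.29, -0.63),
    "TLC": (6.42, 1.17, 0.04, -0.11),
    "FRC": (3.03, 0.74, 0.30, 0.40),
    "RV": (1.84, 0.55, 0.32, 0.50),
    "M40m": (2.43, 1.08, -0.99, -1.48),
    "M40p": (2.39, 1.02, -1.32, -1.70),
    "R5": (2.8, 0.8, 1.2, 2.2),
    "X5": (-1.2, 0.5, -0.8, -1.6),
    "R5_19": (0.4, 0.3, 0.5, 1.0),
    "R5_IQR": (0.35, 0.15, 0.20, 0.45),
    "R5_19_IQR": (0.30, 0.12, 0.15, 0.35),
    "X5_IQR": (0.30, 0.12, 0.20, 0.50),
    "R5_int": (2.2, 0.7, 1.0, 1.8),
    "X5_int": (-1.0, 0.4, -0.6, -1.2),
    "R5_slope": (0.3, 0.2, 0.7, 1.3),
    "X5_slope": (-0.2, 0.15, -0.4, -0.8),
    "VT": (1.1, 0.4, -0.2, -0.2),
    "BF": (14.0, 4.0, 1.0, 2.0),
}

# strictly positive physiological quantities: right-skewed baselines
# (lognormal with matched moments) and multiplicative challenge responses,
# so induced values stay positive without censoring
_LOGNORMAL_VARS = {"FVC", "TLC", "FRC", "RV", "M40m", "M40p", "R5", "VT",
                   "BF", "R5_IQR", "R5_19_IQR", "X5_IQR", "R5_int", "R5_slope"}


@dataclass
class CohortConfig:
    """Configuration of a simulated challenge cohort.

    ``effect_map`` plants symptom-mechanics associations: descriptor name ->
    (predictor variable, effect slope, noise SD).  The predictor's induced
    change is standardized within level, so with slope b and noise SD s the
    planted population r-squared is b^2 / (b^2 + s^2).  Descriptors without
    a planted effect receive pure noise of SD ``borg_noise_sd``.  Dyspnea is
    always stored as the sum of the four descriptor scores.

    ``severity_share`` is the fraction of response variance shared across
    mechanics variables through a per-subject latent severity factor —
    induced changes in different indices are mutually correlated, as in real
    challenge data.  Variables named in the effect map respond
    idiosyncratically (no severity loading): a planted symptom association
    is mechanism-specific, orthogonal to global obstruction severity, which
    is precisely what distinguishes it from the shared bronchoconstrictor
    response every index tracks.
    """

    n_subjects: int = 64
    seed: int = 0
    fall_mild: float = 15.0
    fall_mild_sd: float = 2.0
    fall_moderate: float = 25.0
    fall_moderate_sd: float = 3.0
    effect_map: dict = field(default_factory=dict)
    severity_share: float = 0.6
    response_cv: float = 0.6
    borg_base: dict = field(
        default_factory=lambda: {"baseline": 0.3, "mild": 1.2, "moderate": 2.0}
    )
    borg_noise_sd: float = 0.5
    fev1_base_mean: float = 3.45
    fev1_base_sd: float = 0.81

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be > 0")
        if self.seed is None:
            raise ValueError("cohort simulation requires an explicit seed")
        if not (0 <= self.severity_share <= 1):
            raise ValueError("severity_share must be in [0, 1]")
        valid = set(MECH_VARIABLES) | {"FEV1", "MP_ratio", "VE"}
        for desc, (pred, slope, nsd) in self.effect_map.items():
            if desc not in BORG_DESCRIPTORS:
                raise ValueError(
                    f"unknown descriptor {desc!r}; valid: {sorted(BORG_DESCRIPTORS)}"
                )
            if pred not in valid:
                raise ValueError(
                    f"unknown predictor {pred!r}; valid: {sorted(valid)}"
                )
            if nsd < 0:
                raise ValueError("noise SD must be >= 0")


def _lognormal_params(mean: float, sd: float):
    s2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - s2 / 2.0, math.sqrt(s2)


def simulate_cohort(cc: CohortConfig, mech: MechConfig | None = None) -> pd.DataFrame:
    """Simulate a cohort table: one row per subject per obstruction level.

    Levels are ``baseline``, ``mild`` (~15% FEV1 fall) and ``moderate``
    (~25% fall).  Strictly positive indices (flows, volumes, resistances,
    IQRs) have lognormal baselines and respond multiplicatively to the
    challenge; signed indices (reactances and their kinetics) respond
    additively.  Each variable's response combines the shared latent
    severity with variable-specific variation.  Borg descriptor scores are
    clipped linear functions of the standardized induced change of the
    configured predictor plus Gaussian noise; dyspnea is their sum.  If
    ``mech`` is given, its ``R0`` re-anchors the baseline R5 mean.
    """
    cc.validate()
    rng = np.random.default_rng(cc.seed)
    var_table = dict(MECH_VARIABLES)
    if mech is not None:
        m = var_table["R5"]
        var_table["R5"] = (mech.R0, m[1], m[2], m[3])

    n = cc.n_subjects
    lam = cc.severity_share
    cv = cc.response_cv
    planted_vars = {pred for pred, _, _ in cc.effect_map.values()}
    names = list(var_table)
    level_falls = {
        "mild": (cc.fall_mild, cc.fall_mild_sd, (10.2, 19.8), 2),
        "moderate": (cc.fall_moderate, cc.fall_moderate_sd, (20.2, 29.8), 3),
    }

    base = {}
    for v, (mu, sd, _, _) in var_table.items():
        if v in _LOGNORMAL_VARS:
            m_ln, s_ln = _lognormal_params(mu, sd)
            base[v] = rng.lognormal(m_ln, s_ln, size=n)
        elif v in ("X5", "X5_int", "X5_slope"):
            base[v] = np.minimum(rng.normal(mu, sd, size=n), -0.05)
        else:
            base[v] = rng.normal(mu, sd, size=n)
    base["FEV1"] = np.maximum(
        rng.normal(cc.fev1_base_mean, cc.fev1_base_sd, size=n), 1.0)

    frames = []
    for level in ("baseline", "mild", "moderate"):
        vals = {}
        if level == "baseline":
            vals = {v: base[v].copy() for v in names}
            vals["FEV1"] = base["FEV1"].copy()
            fall = np.zeros(n)
        else:
            mu_f, sd_f, band, d_idx = level_falls[level]
            g = rng.standard_normal(n)
            fall = np.clip(mu_f + sd_f * g, *band)
            vals["FEV1"] = base["FEV1"] * (1.0 - fall / 100.0)
            for v in names:
                lv = 0.0 if v in planted_vars else lam
                zv = math.sqrt(lv) * g + math.sqrt(1 - lv) * rng.standard_normal(n)
                mu, sd, *_ = var_table[v]
                delta = var_table[v][d_idx]
                if v in _LOGNORMAL_VARS:
                    fold = (mu + delta) / mu
                    vals[v] = base[v] * fold ** (1.0 + cv * zv)
                else:
                    vals[v] = base[v] + delta * (1.0 + cv * zv)

        vals["MP_ratio"] = vals["M40m"] / vals["M40p"]
        vals["VE"] = vals["VT"] * vals["BF"]

        frame = pd.DataFrame({"subject": np.arange(n), "level": level,
                              "fall_fev1": fall, **vals})

        b0 = cc.borg_base.get(level, 0.0)
        total = np.zeros(n)
        for desc in BORG_DESCRIPTORS:
            if level != "baseline" and desc in cc.effect_map:
                pred, slope, nsd = cc.effect_map[desc]
                change = vals[pred] - (base[pred] if pred != "MP_ratio"
                                       else base["M40m"] / base["M40p"])
                if pred == "VE":
                    change = vals["VE"] - base["VT"] * base["BF"]
                if pred == "FEV1":
                    change = vals["FEV1"] - base["FEV1"]
                zc = (change - change.mean()) / change.std(ddof=0) \
                    if change.std(ddof=0) > 0 else np.zeros(n)
                score = b0 + slope * zc + nsd * rng.standard_normal(n)
            else:
                score = b0 + cc.borg_noise_sd * rng.standard_normal(n)
            score = np.clip(score, 0.0, 10.0)
            frame[desc] = score
            total = total + score
        frame["dyspnea"] = total
        frames.append(frame)

    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["subject", "level"], ignore_index=True)
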