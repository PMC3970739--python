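"""Self-validation studies: parameter-recovery experiments run against the
virtual lung, used both by the test suite and by ``scripts/acceptance.py``.

Each study simulates data with known ground truth, runs the estimation
pipeline, and reports recovery statistics.  All randomness is controlled by
an explicit seed.
"""

from __future__ import annotations

import math

import numpy as np

from .breathqc import qc_breath
from .impedance import breath_table, fit_window_impedance, segment_breaths
from .mechmetrics import interpolate_pd
from .pipeline import analyze_subject
from .symptomstats import borg_scores, delta_table, forward_stepwise, univariate_screen
from .synthlung import CohortConfig, MechConfig, nominal_impedance, simulate_cohort, simulate_mechanics

__all__ = [
    "impedance_recovery_study", "dft_oracle_study", "qc_boundary_cases",
    "variability_study", "di_kinetics_study", "dose_interpolation_check",
    "stepwise_study", "PLANTED_PREDICTORS", "DECOY_PREDICTORS",
]


def impedance_recovery_study(seed: int = 1) -> dict:
    """Estimate R5/X5 from a 60-s noise-free R-E-I simulation and compare
    each breath's inspiratory estimate with the analytic impedance.
    """
    cfg = MechConfig(R0=2.5, E=10.0, I=0.01, tone_sd=0.0, vol_gain=0.0,
                     di_time=None, duration=60.0)
    sig = simulate_mechanics(cfg, seed)
    tab = breath_table(sig, segment_breaths(sig))
    tab = tab[tab["valid"]]
    z5 = nominal_impedance(cfg, 5.0)
    return {
        "n_breaths": int(len(tab)),
        "max_r5_err_pct": float(np.max(np.abs(tab["r5_insp"] - z5.real))
                                / z5.real * 100.0),
        "max_x5_abs_err": float(np.max(np.abs(tab["x5_insp"] - z5.imag))),
        "max_r5_19_abs": float(np.max(np.abs(tab["r5_19"]))),
    }


def dft_oracle_study(seed: int = 1, n_windows: int = 100,
                     fs: float = 200.0) -> dict:
    """Compare the regression estimator with the DFT-bin ratio on random
    trend-free windows holding an integer number of cycles of every tone.
    """
    rng = np.random.default_rng(seed)
    freqs = (5.0, 11.0, 19.0)
    worst = 0.0
    for _ in range(n_windows):
        dur = int(rng.integers(1, 4))
        n = int(dur * fs)
        t = np.arange(n) / fs
        flow = np.zeros(n)
        pressure = np.zeros(n)
        for f in freqs:
            flow += rng.uniform(0.5, 2) * np.cos(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
            pressure += rng.uniform(0.5, 2) * np.cos(
                2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
        fit = fit_window_impedance(t, flow, pressure, freqs=freqs)
        F, P = np.fft.rfft(flow), np.fft.rfft(pressure)
        for f in freqs:
            k = int(round(f * dur))
            z_dft = P[k] / F[k]
            worst = max(worst, abs(fit[f][0] - z_dft) / abs(z_dft))
    return {"n_windows": n_windows, "max_rel_diff": float(worst)}


def qc_boundary_cases() -> list:
    """The nine threshold boundary cases of the three rejection criteria:
    (vt, distortion, x_ratio, expected_accept).
    """
    return [
        (0.05, 0.05, 1.2, False),
        (0.10, 0.05, 1.2, True),
        (1.00, 0.05, 1.2, True),
        (2.00, 0.05, 1.2, True),
        (2.50, 0.05, 1.2, False),
        (0.90, 0.20, 1.2, True),
        (0.90, 0.25, 1.2, False),
        (0.90, 0.05, 3.5, True),
        (0.90, 0.05, 4.0, False),
    ]


def qc_boundary_study() -> dict:
    cases = qc_boundary_cases()
    correct = sum(qc_breath(vt, d, xr).accepted is exp
                  for vt, d, xr, exp in cases)
    return {"n_cases": len(cases), "n_correct": int(correct)}


def variability_study(seed: int = 1, tone_sds=(0.25, 0.5), n_seeds: int = 20,
                      tone_tau: float = 10.0, window_s: float = 310.0) -> dict:
    """Recover the stationary tone IQR from 5-min recordings.

    The OU resistance fluctuation has stationary IQR 1.349 * tone_sd; the
    per-breath R5 KDE-IQR should track it, and doubling tone_sd should
    double the index.
    """
    seeds = np.random.SeedSequence(seed).generate_state(n_seeds) % (2**31)
    med = {}
    for sd in tone_sds:
        vals = []
        for s in seeds:
            cfg = MechConfig(tone_sd=sd, tone_tau=tone_tau, vol_gain=0.0,
                             di_time=None, duration=window_s)
            res, _ = analyze_subject(simulate_mechanics(cfg, int(s)))
            vals.append(res["variability"].r5_iqr)
        med[sd] = float(np.median(vals))
    lo, hi = min(tone_sds), max(tone_sds)
    return {
        "n_seeds": n_seeds,
        "median_iqr": med,
        "rel_err_pct": {sd: float((med[sd] / (1.349 * sd) - 1) * 100)
                        for sd in tone_sds},
        "iqr_ratio": float(med[hi] / med[lo]),
    }


def di_kinetics_study(seed: int = 1, slopes=(0.5, 1.0, 2.0),
                      n_seeds: int = 20) -> dict:
    """Recover post-DI renarrowing slope and intercept across seeds.

    Ground truth: intercept R0*(1-di_drop) = 1.75 cmH2O*s/L, slope as
    configured.  The simulation carries a small stochastic tone
    (tone_sd = 0.1) so the per-seed estimates vary realistically.
    """
    seeds = np.random.SeedSequence(seed + 1).generate_state(n_seeds) % (2**31)
    out = {"n_seeds": n_seeds, "intercept_true": 2.5 * 0.7,
           "median_slope": {}, "median_intercept": {}}
    for s_true in slopes:
        ints, slps = [], []
        for s in seeds:
            cfg = MechConfig(R0=2.5, tone_sd=0.1, vol_gain=0.0, di_drop=0.3,
                             renarrow_slope=s_true, di_time=60.0,
                             duration=185.0)
            res, _ = analyze_subject(simulate_mechanics(cfg, int(s)))
            ints.append(res["di"].r5_int)
            slps.append(res["di"].r5_slope)
        out["median_slope"][s_true] = float(np.median(slps))
        out["median_intercept"][s_true] = float(np.median(ints))
    return out


def dose_interpolation_check() -> dict:
    """Exactness of the log2 dose interpolation on a doubling-dose grid."""
    midpoint = interpolate_pd([100.0, 200.0], [10.0, 20.0], 15.0)
    doses = [20.0 * 2**k for k in range(6)]
    falls = [2.0, 5.0, 9.0, 14.0, 21.0, 29.0]
    pd15 = interpolate_pd(doses, falls, 15.0)
    pd25 = interpolate_pd(doses, falls, 25.0)
    return {
        "midpoint_dose": float(midpoint),
        "midpoint_abs_err": float(abs(midpoint - math.sqrt(100.0 * 200.0))),
        "pd15_ug": float(pd15),
        "pd25_ug": float(pd25),
    }


PLANTED_PREDICTORS = {
    "tightness": "R5_int",
    "insp_effort": "R5_19_IQR",
    "unrewarded": "R5_slope",
    "exp_difficulty": "X5_IQR",
}
DECOY_PREDICTORS = ["R5", "X5", "R5_19", "R5_IQR", "X5_int", "X5_slope",
                    "FRC", "RV", "M40p", "MP_ratio"]


def _fit_descriptor(coh, level, desc, planted):
    variables = {planted, *DECOY_PREDICTORS}
    changes = delta_table(coh, level)
    changes = changes[[c for c in changes.columns if c[:-4] in variables]]
    resp = borg_scores(coh, level)[desc]
    model = forward_stepwise(resp, changes, univariate_screen(resp, changes))
    return {t[:-4] for t in model.terms}


def stepwise_study(seed: int = 1, n_cohorts: int = 200, n_null: int = 100,
                   n_subjects: int = 64, planted_r2: float = 0.15,
                   level: str = "moderate") -> dict:
    """Selection behaviour of the screen + stepwise pipeline.

    Planted cohorts: each descriptor carries one planted predictor at the
    given population r-squared amid 10 decoys.  Null cohorts: no planted
    effects; models should come back empty.
    """
    slope = math.sqrt(planted_r2)
    nsd = math.sqrt(1.0 - planted_r2)
    effect_map = {d: (p, slope, nsd) for d, p in PLANTED_PREDICTORS.items()}
    seeds = np.random.SeedSequence(seed + 2).generate_state(
        n_cohorts + n_null) % (2**31)

    n_models = n_sel = n_sole_decoy = 0
    for s in seeds[:n_cohorts]:
        coh = simulate_cohort(CohortConfig(n_subjects=n_subjects, seed=int(s),
                                           effect_map=effect_map))
        for desc, planted in PLANTED_PREDICTORS.items():
            sel = _fit_descriptor(coh, level, desc, planted)
            n_models += 1
            if planted in sel:
                n_sel += 1
            elif sel:
                n_sole_decoy += 1

    n_null_models = n_empty = 0
    for s in seeds[n_cohorts:]:
        coh = simulate_cohort(CohortConfig(n_subjects=n_subjects, seed=int(s),
                                           effect_map={}))
        for desc, planted in PLANTED_PREDICTORS.items():
            sel = _fit_descriptor(coh, level, desc, planted)
            n_null_models += 1
            n_empty += not sel

    return {
        "n_cohorts": n_cohorts,
        "n_null_cohorts": n_null,
        "planted_selection_rate": n_sel / n_models if n_models else float("nan"),
        "sole_decoy_rate": n_sole_decoy / n_models if n_models else float("nan"),
        "null_empty_rate": n_empty / n_null_models if n_null_models else float("nan"),
    }
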