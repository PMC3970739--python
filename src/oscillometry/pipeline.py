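"""End-to-end orchestration: signal -> breaths -> impedance -> QC ->
variability + DI kinetics -> subject indices, and cohort tables -> change
tables -> univariate screen -> stepwise models.

Every stage writes its output under the configured directory, and identical
configuration plus seed yields byte-identical results files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from .breathqc import QCThresholds, qc_table, summarize_ventilation
from .impedance import breath_table, segment_breaths
from .mechmetrics import di_response, variability_indices
from .signals import SignalRecord
from .symptomstats import cohort_models
from .synthlung import (CohortConfig, MechConfig, simulate_cohort,
                        simulate_subject_protocol)

logger = logging.getLogger(__name__)

__all__ = ["AnalysisSettings", "PipelineConfig", "find_di_t0",
           "analyze_subject", "run_pipeline"]


@dataclass
class AnalysisSettings:
    """Knobs of the signal-analysis stages.

    ``t0_convention`` selects the definition of the time the DI ended:
    ``volume_return`` (volume back at the pre-DI end-expiratory level, the
    default), ``di_end_event`` (trust the recording's event mark), or
    ``full_inflation`` (peak DI volume).
    """

    cutoff: float = 2.0
    poly_order: int = 3
    window: float = 0.4
    hop: float = 0.25
    kde: str = "kde"
    t0_convention: str = "volume_return"
    max_post_di: float = 120.0
    thresholds: QCThresholds = field(default_factory=QCThresholds)
    alpha_screen: float = 0.05
    alpha_enter: float = 0.05


def find_di_t0(sig: SignalRecord, convention: str = "volume_return"):
    """Locate the end of the deep inspiration, or None without a DI."""
    t_on = sig.event_time("di_onset")
    if t_on is None:
        return None
    if convention == "di_end_event":
        te = sig.event_time("di_end")
        if te is not None:
            return te
        convention = "volume_return"
    i0 = int(np.searchsorted(sig.t, t_on))
    i1 = min(sig.n, i0 + int(30 * sig.fs))
    ipk = i0 + int(np.argmax(sig.volume[i0:i1]))
    if convention == "full_inflation":
        return float(sig.t[ipk])
    if convention != "volume_return":
        raise ValueError(f"unknown t0 convention {convention!r}")
    # end-expiratory level over the two minutes before the DI
    pre = sig.volume[max(0, i0 - int(120 * sig.fs)):i0]
    ee = float(np.percentile(pre, 5)) if pre.size else 0.0
    vpk = float(sig.volume[ipk])
    thresh = ee + 0.05 * (vpk - ee)
    after = np.flatnonzero(sig.volume[ipk:] <= thresh)
    if after.size == 0:
        return float(sig.event_time("di_end") or sig.t[ipk])
    return float(sig.t[ipk + int(after[0])])


def analyze_subject(sig: SignalRecord, settings: AnalysisSettings | None = None):
    """Full single-recording analysis.

    Returns ``(results, breaths)``: the per-breath QC'd table and a results
    dict with breath counts, rejection reasons, ventilation, variability
    indices and (when a DI is present) the post-DI kinetics.
    """
    settings = settings or AnalysisSettings()
    segs = segment_breaths(sig, cutoff=settings.cutoff)
    breaths = breath_table(sig, segs, poly_order=settings.poly_order,
                           window=settings.window, hop=settings.hop)
    breaths = qc_table(breaths, settings.thresholds)

    rejected = breaths[~breaths["accepted"]]
    counts = {
        "n_breaths": int(len(breaths)),
        "n_accepted": int(breaths["accepted"].sum()),
        "n_rejected": int((~breaths["accepted"]).sum()),
        "rejected_by_reason": {
            r: int(rejected["qc_flags"].str.contains(r).sum())
            for r in ("VT_RANGE", "DISTORTION", "X_RATIO", "UNEVALUABLE")
        },
    }
    logger.info("analyze_subject: %d breaths, %d accepted",
                counts["n_breaths"], counts["n_accepted"])

    t_di = sig.event_time("di_onset")
    pre = breaths if t_di is None else breaths[breaths["t_mid"] < t_di]
    results = {"counts": counts}

    acc = pre[pre["accepted"] & ~pre["is_di"].astype(bool)]
    results["ventilation"] = summarize_ventilation(breaths)
    if len(acc) >= 8:
        results["variability"] = variability_indices(acc, method=settings.kde)
    else:
        logger.warning("analyze_subject: only %d accepted pre-DI breaths; "
                       "variability indices skipped", len(acc))
        results["variability"] = None

    if t_di is not None and len(acc) > 0:
        t0 = find_di_t0(sig, settings.t0_convention)
        results["di"] = di_response(
            breaths, t0, pre_r5=float(acc["r5"].median()),
            pre_x5=float(acc["x5"].median()), max_window=settings.max_post_di,
            pre_r5_sd=float(acc["r5"].std(ddof=1)),
            pre_x5_sd=float(acc["x5"].std(ddof=1)))
    else:
        results["di"] = None
    return results, breaths


@dataclass
class PipelineConfig:
    """Configuration of a full run; see ``from_yaml`` for the file schema."""

    outdir: str = "results"
    seed: int | None = None
    subject: MechConfig | None = None
    cohort: CohortConfig | None = None
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(outdir=raw.get("outdir", "results"), seed=raw.get("seed"))
        if "subject" in raw:
            sub = dict(raw["subject"])
            for key in ("osc_freqs", "osc_flow_amps"):
                if sub.get(key) is not None:
                    sub[key] = tuple(sub[key])
            cfg.subject = MechConfig(**sub)
        if "cohort" in raw:
            coh = dict(raw["cohort"])
            if "effect_map" in coh:
                coh["effect_map"] = {k: tuple(v)
                                     for k, v in coh["effect_map"].items()}
            coh.setdefault("seed", raw.get("seed"))
            cfg.cohort = CohortConfig(**coh)
        if "analysis" in raw:
            ana = dict(raw["analysis"])
            if "thresholds" in ana:
                ana["thresholds"] = QCThresholds(**ana["thresholds"])
            cfg.settings = AnalysisSettings(**ana)
        return cfg

    def validate(self) -> None:
        if self.subject is None and self.cohort is None:
            raise ValueError("config must define a subject and/or a cohort run")
        if self.seed is None:
            raise ValueError("pipeline config requires an explicit seed")


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the configured stages and write every stage's output.

    Subject mode: simulate the study-day protocol, write the signal CSV and
    events, the per-breath TSV and the subject results JSON.  Cohort mode:
    simulate the cohort table, write it as TSV, and write the stepwise
    symptom-model report JSON.  Returns the paths and in-memory results.
    """
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"outputs": {}}

    if cfg.subject is not None:
        sig = simulate_subject_protocol(cfg.subject, cfg.seed)
        oio.write_signal(sig, outdir / "signal.csv")
        results, breaths = analyze_subject(sig, cfg.settings)
        oio.write_breaths(breaths, outdir / "breaths.tsv")
        oio.write_json(results, outdir / "subject_results.json")
        bundle["subject"] = results
        bundle["outputs"]["signal"] = "signal.csv"
        bundle["outputs"]["breaths"] = "breaths.tsv"
        bundle["outputs"]["subject_results"] = "subject_results.json"

    if cfg.cohort is not None:
        cohort = simulate_cohort(cfg.cohort, cfg.subject)
        cohort.to_csv(outdir / "cohort.tsv", sep="\t", index=False,
                      float_format="%.8g")
        models = cohort_models(cohort,
                               alpha_screen=cfg.settings.alpha_screen,
                               alpha_enter=cfg.settings.alpha_enter)
        n_lev = {lvl: int((cohort["level"] == lvl).sum())
                 for lvl in ("baseline", "mild", "moderate")}
        logger.info("cohort: subjects per level %s", n_lev)
        report = {"n_per_level": n_lev, "models": models}
        oio.write_json(report, outdir / "cohort_models.json")
        bundle["cohort"] = report
        bundle["outputs"]["cohort"] = "cohort.tsv"
        bundle["outputs"]["cohort_models"] = "cohort_models.json"

    # manifest paths are relative to outdir so identical runs are
    # byte-identical regardless of where they land
    oio.write_json(bundle["outputs"], outdir / "manifest.json")
    bundle["outdir"] = str(outdir)
    return bundle
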