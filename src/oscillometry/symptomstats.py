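"""Symptom-mechanics association analysis.

For each Borg descriptor (and their sum, dyspnea), the induced changes in
lung mechanics at a given obstruction level are screened univariately
(Pearson correlation, two-sided p < alpha), and the surviving candidates
enter a forward stepwise ordinary-least-squares selection: at each step the
candidate with the smallest per-term p-value is added while it stays below
the entry threshold.  Changes are offered on two bases — absolute
(level - baseline) and percent of baseline — and a variable significant on
both bases enters with its smaller-p basis only, to avoid self-collinearity.
A closed-form Holm-Sidak step-down adjustment is provided for families of
p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import pearsonr

from .synthlung import BORG_DESCRIPTORS

logger = logging.getLogger(__name__)

__all__ = [
    "Candidate", "CandidateSet", "RegressionModel",
    "delta_table", "borg_scores", "univariate_screen", "forward_stepwise",
    "holm_sidak", "cohort_models",
]

_ID_COLS = {"subject", "level", "fall_fev1"}
_RESPONSE_COLS = set(BORG_DESCRIPTORS) | {"dyspnea"}


@dataclass
class Candidate:
    name: str            # column in the change table, e.g. "R5_pct"
    variable: str        # underlying variable, e.g. "R5"
    basis: str           # "absolute" or "percent"
    r: float
    p: float


@dataclass
class CandidateSet:
    response: str
    entries: list = field(default_factory=list)

    @property
    def names(self):
        return [c.name for c in self.entries]


@dataclass
class RegressionModel:
    response: str
    terms: list
    coefs: dict
    pvalues: dict
    r2: float
    p_overall: float
    n: int


def delta_table(cohort: pd.DataFrame, level: str,
                variables=None) -> pd.DataFrame:
    """Per-subject changes in mechanics variables at one obstruction level.

    Returns one row per subject with ``<var>_abs`` (level - baseline) and
    ``<var>_pct`` (100 * change / baseline) columns.  Borg scores are
    responses, not predictors, and are excluded.  The percent basis is only
    offered for variables whose baseline is bounded away from zero with a
    single sign across subjects (otherwise 100*change/baseline is dominated
    by the near-zero baselines and carries no information about the change);
    variables failing the guard get only the absolute column.  Subjects
    missing either row are dropped with a log entry.
    """
    base = cohort[cohort["level"] == "baseline"].set_index("subject")
    lev = cohort[cohort["level"] == level].set_index("subject")
    if variables is None:
        variables = [c for c in cohort.columns
                     if c not in _ID_COLS | _RESPONSE_COLS
                     and pd.api.types.is_numeric_dtype(cohort[c])]
    common = base.index.intersection(lev.index)
    dropped = base.index.symmetric_difference(lev.index)
    if len(dropped):
        logger.info("delta_table: dropped %d subject(s) missing a %s or "
                    "baseline row", len(dropped), level)
    out = pd.DataFrame(index=common)
    for v in variables:
        b = base.loc[common, v].astype(float)
        d = lev.loc[common, v].astype(float) - b
        out[f"{v}_abs"] = d
        one_signed = bool((b > 0).all() or (b < 0).all())
        away_from_zero = (b.abs().min() > 0.1 * b.abs().median()
                          if len(b) else False)
        if one_signed and away_from_zero:
            out[f"{v}_pct"] = 100.0 * d / b
        else:
            logger.info("delta_table: %s baseline approaches zero; percent "
                        "basis not offered", v)
    return out


def borg_scores(cohort: pd.DataFrame, level: str) -> pd.DataFrame:
    """Borg descriptor scores (plus dyspnea) at one level, one row per subject."""
    lev = cohort[cohort["level"] == level].set_index("subject")
    return lev[list(BORG_DESCRIPTORS) + ["dyspnea"]].astype(float)


def _split_name(col: str):
    if col.endswith("_abs"):
        return col[:-4], "absolute"
    if col.endswith("_pct"):
        return col[:-4], "percent"
    return col, "absolute"


def univariate_screen(response: pd.Series, changes: pd.DataFrame,
                      alpha_screen: float = 0.05,
                      min_n: int = 10) -> CandidateSet:
    """Pearson prescreen of every (variable, basis) change column.

    Retains columns with two-sided p < ``alpha_screen``; when both bases of
    the same variable pass, only the smaller-p basis is kept.  Zero-variance
    columns are skipped with a log entry.
    """
    y = response.astype(float)
    best: dict = {}
    for col in changes.columns:
        x = changes[col].astype(float)
        pair = pd.DataFrame({"x": x, "y": y}).dropna()
        if len(pair) < min_n:
            raise ValueError(
                f"univariate_screen requires n >= {min_n} complete pairs "
                f"for {col!r}, got {len(pair)}")
        xv, yv = pair["x"].to_numpy(), pair["y"].to_numpy()
        if np.std(xv) == 0 or np.std(yv) == 0:
            logger.info("univariate_screen: %s has zero variance; skipped", col)
            continue
        r, p = pearsonr(xv, yv)
        if p < alpha_screen:
            var, basis = _split_name(col)
            cand = Candidate(name=col, variable=var, basis=basis,
                             r=float(r), p=float(p))
            if var not in best or p < best[var].p:
                best[var] = cand
    entries = sorted(best.values(), key=lambda c: c.p)
    return CandidateSet(response=str(response.name), entries=entries)


def forward_stepwise(response: pd.Series, changes: pd.DataFrame,
                     candidates: CandidateSet, alpha_enter: float = 0.05,
                     collinear_r: float = 0.999) -> RegressionModel:
    """Forward stepwise OLS selection among the screened candidates.

    Starting from the empty model, the candidate with the smallest per-term
    p-value (equivalent to the partial F test for a single added term) is
    added while that p-value is below ``alpha_enter``.  Candidates nearly
    collinear (|r| > ``collinear_r``) with an already-selected term are
    skipped.  The final refitted OLS model is reported with its r-squared
    and overall F-test p-value.
    """
    cols = candidates.names if isinstance(candidates, CandidateSet) else list(candidates)
    data = pd.concat([response.rename("__y__"), changes[cols]], axis=1).dropna()
    y = data["__y__"].to_numpy()
    n = len(data)

    selected: list = []
    while True:
        best_col, best_p = None, None
        for col in cols:
            if col in selected:
                continue
            if selected:
                cmax = data[selected].corrwith(data[col]).abs().max()
                if cmax > collinear_r:
                    logger.info("forward_stepwise: %s collinear with selected "
                                "set (|r|=%.4f); skipped", col, cmax)
                    continue
            X = sm.add_constant(data[selected + [col]].to_numpy())
            res = sm.OLS(y, X).fit()
            p = float(res.pvalues[-1])
            if best_p is None or p < best_p:
                best_col, best_p = col, p
        if best_col is None or best_p >= alpha_enter:
            break
        selected.append(best_col)

    if selected:
        X = sm.add_constant(data[selected].to_numpy())
        res = sm.OLS(y, X).fit()
        coefs = {c: float(b) for c, b in zip(selected, res.params[1:])}
        pvals = {c: float(p) for c, p in zip(selected, res.pvalues[1:])}
        r2 = float(res.rsquared)
        p_overall = float(res.f_pvalue)
    else:
        coefs, pvals, r2, p_overall = {}, {}, 0.0, float("nan")
    return RegressionModel(response=str(response.name), terms=selected,
                           coefs=coefs, pvalues=pvals, r2=r2,
                           p_overall=p_overall, n=n)


def holm_sidak(pvalues) -> np.ndarray:
    """Holm-Sidak step-down adjusted p-values.

    Sorted ascending, the i-th (1-based) of m p-values is adjusted to
    ``1 - (1 - p_i)**(m - i + 1)``, enforced monotone nondecreasing, and
    returned in the original order.
    """
    p = np.asarray(list(pvalues), float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    exps = m - np.arange(m)
    adj_sorted = 1.0 - (1.0 - p[order]) ** exps
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def cohort_models(cohort: pd.DataFrame, levels=("mild", "moderate"),
                  alpha_screen: float = 0.05, alpha_enter: float = 0.05,
                  variables=None) -> dict:
    """Stepwise explanatory models for every descriptor at every level.

    Returns ``{level: {descriptor: {"terms", "coefs", "r2", "p", "n"}}}`` —
    the shape of a symptom-correlate summary table.
    """
    out = {}
    for level in levels:
        changes = delta_table(cohort, level, variables=variables)
        scores = borg_scores(cohort, level)
        out[level] = {}
        for desc in list(BORG_DESCRIPTORS) + ["dyspnea"]:
            resp = scores[desc].rename(desc)
            resp = resp.loc[resp.index.intersection(changes.index)]
            try:
                cands = univariate_screen(resp, changes,
                                          alpha_screen=alpha_screen)
            except ValueError as err:
                # cohorts too small to screen get empty models, not a crash
                logger.warning("cohort_models: %s at %s: %s; empty model",
                               desc, level, err)
                cands = CandidateSet(response=desc)
            model = forward_stepwise(resp, changes, cands,
                                     alpha_enter=alpha_enter)
            out[level][desc] = {
                "terms": model.terms,
                "coefs": model.coefs,
                "r2": model.r2,
                "p": model.p_overall,
                "n": model.n,
            }
    return out
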