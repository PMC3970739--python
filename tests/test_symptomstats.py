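"""Univariate screen, forward stepwise selection, Holm-Sidak adjustment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oscillometry import (delta_table, forward_stepwise, holm_sidak,
                          simulate_cohort, univariate_screen)
from oscillometry.symptomstats import CandidateSet
from oscillometry.synthlung import CohortConfig


def _cohort_rows():
    return pd.DataFrame([
        {"subject": 0, "level": "baseline", "R5": 2.0, "FRC": 3.0},
        {"subject": 0, "level": "mild", "R5": 3.0, "FRC": 3.3},
        {"subject": 1, "level": "baseline", "R5": 2.5, "FRC": 2.8},
        {"subject": 1, "level": "mild", "R5": 2.5, "FRC": 2.8},
        {"subject": 2, "level": "baseline", "R5": 3.0, "FRC": 3.1},
    ])


class TestDeltaTable:
    def test_absolute_and_percent_changes(self):
        ch = delta_table(_cohort_rows(), "mild")
        assert ch.loc[0, "R5_abs"] == pytest.approx(1.0)
        assert ch.loc[0, "R5_pct"] == pytest.approx(50.0)

    def test_no_change_rows_zero(self):
        ch = delta_table(_cohort_rows(), "mild")
        assert ch.loc[1, "R5_abs"] == 0.0
        assert ch.loc[1, "R5_pct"] == 0.0

    def test_missing_level_row_drops_subject(self):
        ch = delta_table(_cohort_rows(), "mild")
        assert 2 not in ch.index and len(ch) == 2

    def test_zero_crossing_baseline_has_no_percent_basis(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(12):
            b = rng.normal(0.0, 1.0)
            rows.append({"subject": i, "level": "baseline", "X": b})
            rows.append({"subject": i, "level": "mild", "X": b + 1})
        ch = delta_table(pd.DataFrame(rows), "mild")
        assert "X_abs" in ch.columns and "X_pct" not in ch.columns


def _exact_r_data(r, n, seed=0):
    """Response with exact sample correlation r to the first predictor."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    e = rng.standard_normal(n)
    x = (x - x.mean()) / x.std()
    e = e - e.mean()
    e -= x * (e @ x) / (x @ x)
    e /= e.std()
    y = r * x + np.sqrt(1 - r * r) * e
    return pd.Series(x, name="x"), pd.Series(y, name="resp")


class TestScreen:
    def test_identical_predictor_retained_with_r_one(self):
        x, _ = _exact_r_data(0.5, 30)
        ch = pd.DataFrame({"R5_abs": x})
        cs = univariate_screen(pd.Series(x.values, name="resp"), ch)
        assert cs.names == ["R5_abs"]
        assert cs.entries[0].r == pytest.approx(1.0)

    def test_r_034_at_n_64_significant(self):
        # t-transform: r=0.34, n=64 gives p ~ 0.006 < 0.05
        x, y = _exact_r_data(0.34, 64)
        cs = univariate_screen(y, pd.DataFrame({"R5_abs": x}))
        assert cs.names == ["R5_abs"]
        assert 0.004 < cs.entries[0].p < 0.009

    def test_type_one_error_rate_near_alpha(self):
        rng = np.random.default_rng(9)
        n, reps, k = 64, 400, 3
        hits = 0
        for _ in range(reps):
            ch = pd.DataFrame(rng.standard_normal((n, k)),
                              columns=[f"V{i}_abs" for i in range(k)])
            y = pd.Series(rng.standard_normal(n), name="resp")
            hits += len(univariate_screen(y, ch).entries)
        rate = hits / (reps * k)
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_smaller_p_basis_wins(self):
        x, y = _exact_r_data(0.6, 40)
        ch = pd.DataFrame({"R5_abs": x, "R5_pct": x + np.random.default_rng(1)
                           .normal(0, 0.8, len(x))})
        cs = univariate_screen(y, ch)
        assert cs.names == ["R5_abs"]  # one basis per variable

    def test_zero_variance_skipped(self):
        x, y = _exact_r_data(0.6, 40)
        ch = pd.DataFrame({"R5_abs": x, "FRC_abs": np.ones(len(x))})
        assert univariate_screen(y, ch).names == ["R5_abs"]


class TestStepwise:
    def test_noiseless_effect_gives_r2_one(self):
        x, _ = _exact_r_data(0.5, 30)
        ch = pd.DataFrame({"R5_abs": x})
        y = pd.Series(2.0 * x.values + 1.0, name="resp")
        m = forward_stepwise(y, ch, univariate_screen(y, ch))
        assert m.terms == ["R5_abs"]
        assert m.r2 == pytest.approx(1.0, abs=1e-12)

    def test_no_qualifying_candidate_empty_model(self):
        x, y = _exact_r_data(0.05, 40)
        m = forward_stepwise(y, pd.DataFrame({"R5_abs": x}),
                             CandidateSet(response="resp", entries=[]))
        assert m.terms == [] and m.r2 == 0.0

    def test_r2_matches_independent_ols(self):
        rng = np.random.default_rng(3)
        n = 60
        ch = pd.DataFrame({"A_abs": rng.standard_normal(n),
                           "B_abs": rng.standard_normal(n)})
        y = pd.Series(ch["A_abs"] + 0.5 * ch["B_abs"]
                      + 0.3 * rng.standard_normal(n), name="resp")
        m = forward_stepwise(y, ch, univariate_screen(y, ch))
        X = np.column_stack([np.ones(n)] + [ch[c] for c in m.terms])
        beta, *_ = np.linalg.lstsq(X, y.values, rcond=None)
        resid = y.values - X @ beta
        r2 = 1 - resid.var() / y.values.var()
        assert m.r2 == pytest.approx(r2, abs=1e-10)

    def test_causal_variable_beats_correlated_decoy(self):
        # two candidates with rho = 0.6, one causal: the causal one should
        # enter first in the vast majority of fits at n = 200
        rng = np.random.default_rng(12)
        n, reps = 200, 150
        first_causal = 0
        for _ in range(reps):
            g = rng.standard_normal(n)
            a = np.sqrt(0.6) * g + np.sqrt(0.4) * rng.standard_normal(n)
            b = np.sqrt(0.6) * g + np.sqrt(0.4) * rng.standard_normal(n)
            y = pd.Series(0.5 * a + rng.standard_normal(n), name="resp")
            ch = pd.DataFrame({"A_abs": a, "B_abs": b})
            m = forward_stepwise(y, ch, univariate_screen(y, ch))
            if m.terms and m.terms[0] == "A_abs":
                first_causal += 1
        assert first_causal / reps >= 0.80

    def test_collinear_candidate_skipped(self):
        rng = np.random.default_rng(4)
        n = 50
        a = rng.standard_normal(n)
        ch = pd.DataFrame({"A_abs": a, "B_abs": a * 1.0000001})
        y = pd.Series(a + 0.1 * rng.standard_normal(n), name="resp")
        m = forward_stepwise(y, ch, univariate_screen(y, ch))
        assert len(m.terms) == 1


class TestHolmSidak:
    def test_closed_form_triplet(self):
        adj = holm_sidak([0.01, 0.02, 0.5])
        assert adj == pytest.approx([1 - 0.99**3, 1 - 0.98**2, 0.5])

    def test_degenerate_inputs(self):
        assert np.allclose(holm_sidak([1.0, 1.0]), [1.0, 1.0])
        assert holm_sidak([0.3]) == pytest.approx([0.3])

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 25)
        adj = holm_sidak(p)
        assert np.all(adj >= p)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_matches_statsmodels_reference(self):
        from statsmodels.stats.multitest import multipletests
        p = np.random.default_rng(6).uniform(0, 1, 12)
        _, ref, _, _ = multipletests(p, method="holm-sidak")
        assert np.allclose(holm_sidak(p), ref, atol=1e-12)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            holm_sidak([0.5, 1.2])


class TestCohortIntegration:
    def test_planted_predictor_recovered_single_cohort(self):
        slope, nsd = np.sqrt(0.5), np.sqrt(0.5)  # strong effect, one cohort
        cc = CohortConfig(n_subjects=64, seed=2,
                          effect_map={"tightness": ("R5_int", slope, nsd)})
        coh = simulate_cohort(cc)
        ch = delta_table(coh, "moderate")
        y = coh[coh["level"] == "moderate"].set_index("subject")["tightness"]
        m = forward_stepwise(y, ch, univariate_screen(y, ch))
        assert any(t.startswith("R5_int") for t in m.terms)
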