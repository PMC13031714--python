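"""MOA scan: oracle equivalences, calibration, thresholds, hit summaries."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from pgsomics import (
    MoaModel,
    SignificanceThresholds,
    bonferroni_threshold,
    build_orm,
    summarize_hits,
)

from conftest import random_covariates, random_expression


def scan_instance(rng, n=50, m=20, signal=0.0):
    expr = random_expression(rng, n=n, m=m)
    covar = random_covariates(rng, expr.sample_ids)
    y = rng.standard_normal(n) + signal * expr.values[:, 0]
    return y, expr, covar


class TestMoaFixedV:
    def test_ols_oracle_with_pinned_variance(self, rng):
        """With sigma_o^2 pinned to 0 the scan is covariate-adjusted
        regression: beta matches statsmodels OLS exactly, and the p-value
        matches the chi2_1 Wald statistic assembled from OLS quantities
        plus the null-model REML residual variance."""
        for _ in range(5):
            y, expr, covar = scan_instance(rng, n=50, m=12)
            res = MoaModel(y, expr, covariates=covar).fit(fix_sigma2_o=0.0)
            c = np.column_stack([np.ones(50), covar.design(expr.sample_ids)])
            # null REML residual variance: RSS of y ~ C over (n - p)
            resid = y - c @ np.linalg.lstsq(c, y, rcond=None)[0]
            s2e = resid @ resid / (50 - c.shape[1])
            for j, tid in enumerate(expr.transcript_ids):
                x = np.column_stack([c, expr.values[:, j]])
                ols = sm.OLS(y, x).fit()
                b = ols.params[-1]
                row = res.frame.loc[res.frame["transcript"] == tid].iloc[0]
                assert row["beta"] == pytest.approx(b, abs=1e-8)
                # w'Pw = w'Mw / s2e with M the OLS annihilator of C
                mw = expr.values[:, j] - c @ np.linalg.lstsq(
                    c, expr.values[:, j], rcond=None)[0]
                wpw = mw @ mw / s2e
                p_oracle = stats.chi2.sf(b * b * wpw, 1)
                assert row["p"] == pytest.approx(p_oracle, abs=1e-8)

    def test_wald_internal_consistency(self, rng):
        y, expr, covar = scan_instance(rng, n=40, m=15, signal=0.4)
        res = MoaModel(y, expr, covariates=covar).fit()
        ratio = (res.frame["beta"] / res.frame["se"]) ** 2
        np.testing.assert_allclose(res.frame["chi2"], ratio, atol=1e-12)

    def test_gls_dense_solve_oracle(self, rng):
        """b from the projection formula equals explicit GLS with the
        fitted V on small instances."""
        y, expr, covar = scan_instance(rng, n=25, m=10, signal=0.5)
        orm = build_orm(expr)
        model = MoaModel(y, expr, orm, covar)
        null_fit = model.null_model.fit()
        res = model.fit(null_fit=null_fit)
        v = null_fit.sigma2_o * orm.values + null_fit.sigma2_e * np.eye(25)
        c = np.column_stack([np.ones(25), covar.design(expr.sample_ids)])
        for j, tid in enumerate(expr.transcript_ids):
            x = np.column_stack([c, expr.values[:, j]])
            xtvx = x.T @ np.linalg.solve(v, x)
            beta = np.linalg.solve(xtvx, x.T @ np.linalg.solve(v, y))
            row = res.frame.loc[res.frame["transcript"] == tid].iloc[0]
            assert row["beta"] == pytest.approx(beta[-1], abs=1e-10)

    def test_affine_transcript_rescaling_invariance(self, rng):
        y, expr, covar = scan_instance(rng, n=40, m=10, signal=0.5)
        res1 = MoaModel(y, expr, covariates=covar).fit()
        expr2 = random_expression(rng, n=40, m=10)
        expr2.values[:] = expr.values * 3.7 - 1.2
        expr2.sample_ids = expr.sample_ids
        expr2.transcript_ids = expr.transcript_ids
        res2 = MoaModel(y, expr2, covariates=covar).fit()
        np.testing.assert_allclose(res1.frame["p"], res2.frame["p"], atol=1e-8)
        np.testing.assert_allclose(res1.frame["chi2"], res2.frame["chi2"], atol=1e-8)

    def test_power_sanity_strong_effect(self, rng):
        """An effect with OLS |t| > 10 must clear Bonferroni at m = 1000."""
        n = 100
        expr = random_expression(rng, n=n, m=30)
        y = 2.0 * expr.values[:, 0] + 0.5 * rng.standard_normal(n)
        c = np.column_stack([np.ones(n), expr.values[:, 0]])
        t = sm.OLS(y, c).fit().tvalues[-1]
        assert abs(t) > 10
        res = MoaModel(y, expr).fit()
        p0 = res.frame.loc[res.frame["transcript"] == expr.transcript_ids[0], "p"].iloc[0]
        assert p0 < bonferroni_threshold(1000)

    def test_zero_variance_transcript_skipped(self, rng):
        y, expr, covar = scan_instance(rng, n=30, m=8)
        expr.values[:, 3] = 5.0
        res = MoaModel(y, expr, covariates=covar).fit()
        assert expr.transcript_ids[3] in res.skipped_ids
        assert len(res.frame) == 7

    def test_exact_mode_close_to_fixed_v(self, rng):
        y, expr, covar = scan_instance(rng, n=40, m=6)
        model = MoaModel(y, expr, covariates=covar)
        fixed = model.fit()
        exact = model.fit(exact=True)
        merged = fixed.frame.merge(exact.frame, on="transcript",
                                   suffixes=("_f", "_x"))
        # per-transcript variance re-estimation perturbs but must not
        # contradict the fixed-V approximation
        assert np.corrcoef(merged["beta_f"], merged["beta_x"])[0, 1] > 0.99
        assert np.all(np.abs(np.log10(merged["p_f"] / merged["p_x"])) < 0.5)


class TestThresholds:
    @pytest.mark.parametrize("m, alpha, expected", [
        (20000, 0.05, 2.5e-6),
        (1, 0.05, 0.05),
        (4, 0.01, 0.0025),
    ])
    def test_bonferroni_arithmetic(self, m, alpha, expected):
        assert bonferroni_threshold(m, alpha) == pytest.approx(expected, rel=1e-12)

    def test_bonferroni_matches_study_scale(self):
        """~21k transcripts per tissue gives the 2.37e-6 stringent cutoff."""
        assert bonferroni_threshold(21097, 0.05) == pytest.approx(2.37e-6, rel=5e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0)
        with pytest.raises(ValueError):
            bonferroni_threshold(10, alpha=1.5)

    def test_thresholds_dataclass(self):
        th = SignificanceThresholds(m=500)
        assert th.bonferroni == pytest.approx(1e-4)
        assert th.nominal == 1e-3


class TestSummarizeHits:
    def make_frame(self):
        rows = []
        for tissue, ps in [("liver", [9.9e-4, 1e-3, 0.5]),
                           ("lung", [9.9e-4, 2e-7, 0.2]),
                           ("skin", [0.9, 0.8, 0.7])]:
            for tid, p in zip(["tA", "tB", "tC"], ps):
                rows.append({"transcript": tid, "tissue": tissue, "p": p,
                             "beta": 0.1, "se": 0.1, "n": 50})
        return pd.DataFrame(rows)

    def test_nominal_strict_inequality(self):
        summ = summarize_hits(self.make_frame(),
                              SignificanceThresholds(m=3, nominal=1e-3))
        counts = dict(zip(summ.per_tissue_nominal["tissue"],
                          summ.per_tissue_nominal["n_nominal"]))
        # 9.9e-4 counted, exactly 1e-3 NOT counted
        assert counts == {"liver": 1, "lung": 2, "skin": 0}

    def test_per_transcript_tissue_counts(self):
        summ = summarize_hits(self.make_frame(),
                              SignificanceThresholds(m=3, nominal=1e-3))
        per = dict(zip(summ.per_transcript_tissues["transcript"],
                       summ.per_transcript_tissues["n_tissues_nominal"]))
        assert per == {"tA": 2, "tB": 1}

    def test_bonferroni_hits_sorted(self):
        summ = summarize_hits(self.make_frame(),
                              SignificanceThresholds(m=10000))
        assert summ.bonferroni_hits["transcript"].tolist() == ["tB"]
        assert summ.bonferroni_hits["p"].iloc[0] == pytest.approx(2e-7)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_hits(pd.DataFrame(columns=["transcript", "p", "tissue"]))


def test_null_calibration_smoke():
    """Pooled null scans give ~5% rejections at alpha = 0.05 (full-size
    calibration lives in the acceptance suite)."""
    hits = total = 0
    for seed in range(4):
        rng = np.random.default_rng(100 + seed)
        y, expr, covar = scan_instance(rng, n=120, m=300)
        res = MoaModel(y, expr, covariates=covar).fit()
        hits += int((res.frame["p"] < 0.05).sum())
        total += len(res.frame)
    assert 0.03 <= hits / total <= 0.07
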