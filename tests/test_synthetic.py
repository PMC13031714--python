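"""Synthetic generator: distributional checks, exact variance targeting,
seeded determinism and the inverse normal transform."""

import numpy as np
import pytest
from scipy import stats

from pgsomics import (
    SimulationConfig,
    build_orm,
    compute_pgs,
    fit_oreml,
    rank_inverse_normal,
    simulate_expression_and_score,
    simulate_genotypes,
    simulate_study,
    simulate_weight_pair,
)


class TestGenotypes:
    def test_mean_dosage_at_maf_half(self):
        g = simulate_genotypes(10_000, 1, maf_range=(0.5, 0.5), seed=7)
        assert abs(g.dosages.mean() - 1.0) < 0.03

    def test_seeded_determinism(self):
        a = simulate_genotypes(100, 50, seed=42)
        b = simulate_genotypes(100, 50, seed=42)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.variants.equals(b.variants)

    def test_heterozygote_fraction(self):
        g = simulate_genotypes(2000, 1, maf_range=(0.5, 0.5), seed=3)
        het = np.mean(g.dosages == 1.0)
        assert abs(het - 0.5) < 0.04  # binomial(2, .5) heterozygosity

    def test_dosage_domain_and_missing(self):
        g = simulate_genotypes(200, 20, seed=1, missing_rate=0.1)
        present = g.dosages[~np.isnan(g.dosages)]
        assert set(np.unique(present)) <= {0.0, 1.0, 2.0}
        assert 0.02 < np.isnan(g.dosages).mean() < 0.2

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_genotypes(0, 5)
        with pytest.raises(ValueError):
            simulate_genotypes(5, 5, maf_range=(0.0, 0.5))
        with pytest.raises(ValueError):
            simulate_genotypes(5, 5, maf_range=(0.1, 0.6))


class TestWeightPair:
    def test_perfect_correlation_identical(self):
        wm, wf = simulate_weight_pair(200, 0.5, 1.0, seed=5)
        np.testing.assert_array_equal(wm.weights, wf.weights)

    def test_zero_correlation(self):
        wm, wf = simulate_weight_pair(5000, 1.0, 0.0, seed=6)
        r = np.corrcoef(wm.weights, wf.weights)[0, 1]
        assert abs(r) < 0.05  # ~1/sqrt(5000) Monte-Carlo error

    def test_all_causal_no_zeros(self):
        wm, wf = simulate_weight_pair(300, 1.0, 0.2, seed=8)
        assert np.all(wm.weights != 0) and np.all(wf.weights != 0)

    def test_noncausal_exactly_zero_and_shared_support(self):
        wm, wf = simulate_weight_pair(400, 0.25, 0.3, seed=9)
        assert np.sum(wm.weights != 0) == 100
        np.testing.assert_array_equal(wm.weights == 0, wf.weights == 0)

    def test_invalid_correlation(self):
        with pytest.raises(ValueError):
            simulate_weight_pair(10, 0.5, 1.5)

    def test_cross_sex_pgs_correlation_monotone(self):
        """Scores from the two weight sets on shared genotypes correlate
        more as the weight correlation rises (averaged over seeds)."""
        means = []
        for rho in (0.0, 0.5, 1.0):
            rs = []
            for seed in range(20):
                g = simulate_genotypes(150, 300, seed=1000 + seed)
                wm, wf = simulate_weight_pair(300, 0.2, rho, seed=seed,
                                              variants=g.variants)
                sm_ = compute_pgs(wm, g).score
                sf = compute_pgs(wf, g).score
                rs.append(np.corrcoef(sm_, sf)[0, 1])
            means.append(np.mean(rs))
        assert means[0] < means[1] < means[2]
        assert means[2] == pytest.approx(1.0, abs=1e-12)


class TestRankInverseNormal:
    def test_middle_of_odd_vector_maps_to_zero(self):
        out = rank_inverse_normal([10.0, -3.0, 4.0, 7.0, 0.5])
        assert out[2] == pytest.approx(0.0, abs=1e-12)  # 4.0 is the median

    def test_rank_monotonicity(self, rng):
        x = rng.normal(size=101)
        out = rank_inverse_normal(x)
        assert stats.spearmanr(x, out).statistic == pytest.approx(1.0)

    def test_three_point_ordering(self):
        out = rank_inverse_normal([3.0, 1.0, 2.0])
        assert out[0] > out[2] > out[1]

    def test_ties_get_equal_outputs(self):
        out = rank_inverse_normal([1.0, 2.0, 2.0, 5.0])
        assert out[1] == out[2]

    def test_blom_offset_option(self):
        x = [3.0, 1.0, 2.0]
        half = rank_inverse_normal(x)
        blom = rank_inverse_normal(x, offset="blom")
        assert half[1] == pytest.approx(stats.norm.ppf(0.5 / 3))
        assert blom[1] == pytest.approx(stats.norm.ppf(0.625 / 3.25))

    def test_nan_propagated(self):
        out = rank_inverse_normal([1.0, np.nan, 3.0, 2.0])
        assert np.isnan(out[1]) and np.isfinite(out[[0, 2, 3]]).all()

    def test_errors(self):
        with pytest.raises(ValueError, match="identical"):
            rank_inverse_normal([2.0, 2.0, 2.0])
        with pytest.raises(ValueError, match="finite"):
            rank_inverse_normal([1.0, np.nan])


class TestExpressionAndScore:
    def cfg(self, **kw):
        base = dict(n_samples_per_sex=80, n_snps=100, n_transcripts=120,
                    n_causal_transcripts=12, r2_target=0.4, seed=0)
        base.update(kw)
        return SimulationConfig(**base)

    def test_realized_variance_fraction_exact(self):
        """The expression share of var(y - covariates) hits r2_target to
        numerical precision, by construction."""
        for r2 in (0.1, 0.3, 0.7):
            cfg = self.cfg(r2_target=r2)
            g = simulate_genotypes(80, 100, seed=21)
            w, _ = simulate_weight_pair(100, 0.1, 0.2, seed=22, variants=g.variants)
            expr, covar, y, truth = simulate_expression_and_score(g, w, cfg, seed=23)
            gterm = expr.values @ truth.effects
            gterm = gterm - gterm.mean()
            age = covar.table["age"].to_numpy()
            bmi = covar.table["bmi"].to_numpy()
            cterm = (0.2 * (age - age.mean()) / age.std()
                     + 0.2 * (bmi - bmi.mean()) / bmi.std())
            e = y.score - cterm - gterm
            frac = gterm.var() / (gterm.var() + e.var())
            assert frac == pytest.approx(r2, abs=1e-10)

    def test_truth_effects_zero_off_causal(self):
        cfg = self.cfg()
        g = simulate_genotypes(80, 100, seed=31)
        w, _ = simulate_weight_pair(100, 0.1, 0.2, seed=32, variants=g.variants)
        expr, _, _, truth = simulate_expression_and_score(g, w, cfg, seed=33)
        causal_idx = [expr.transcript_ids.index(t)
                      for t in truth.causal_transcript_ids]
        assert len(causal_idx) == 12
        mask = np.zeros(120, dtype=bool)
        mask[causal_idx] = True
        assert np.all(truth.effects[~mask] == 0)
        assert np.all(truth.effects[mask] != 0)

    def test_noiseless_limit_linear_combination(self):
        """r2_target = 1 with zero covariate effects: the outcome lies in
        the affine span of the causal expression columns."""
        cfg = self.cfg(r2_target=1.0, covariate_effect_sizes=(0.0, 0.0))
        g = simulate_genotypes(60, 50, seed=41)
        w, _ = simulate_weight_pair(50, 0.2, 0.2, seed=42, variants=g.variants)
        expr, _, y, truth = simulate_expression_and_score(g, w, cfg, seed=43)
        causal = [expr.transcript_ids.index(t) for t in truth.causal_transcript_ids]
        x = np.column_stack([np.ones(60), expr.values[:, causal]])
        resid = y.score - x @ np.linalg.lstsq(x, y.score, rcond=None)[0]
        assert np.max(np.abs(resid)) < 1e-10

    def test_null_r2_zero_config_invariant(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_causal_transcripts=0, r2_target=0.2)
        cfg = SimulationConfig(n_causal_transcripts=0, r2_target=0.0,
                               n_samples_per_sex=40, n_snps=50, n_transcripts=30)
        g = simulate_genotypes(40, 50, seed=51)
        w, _ = simulate_weight_pair(50, 0.2, 0.2, seed=52, variants=g.variants)
        _, _, _, truth = simulate_expression_and_score(g, w, cfg, seed=53)
        assert truth.true_r2 == 0.0 and truth.causal_transcript_ids == []

    def test_null_oreml_estimates_near_zero(self):
        """r2_target = 0: outcome carries no expression signal.  The
        estimator is censored at zero, so its null mean is a small positive
        number ~ SE/sqrt(2*pi) (~0.06 at n=200, m=500), not zero; assert it
        stays below twice that."""
        cfg = SimulationConfig(n_samples_per_sex=200, n_snps=100,
                               n_transcripts=500, n_causal_transcripts=0,
                               r2_target=0.0)
        g = simulate_genotypes(200, 100, seed=61)
        w, _ = simulate_weight_pair(100, 0.2, 0.2, seed=62, variants=g.variants)
        est = []
        for seed in range(100):
            expr, covar, y, _ = simulate_expression_and_score(g, w, cfg, seed=seed)
            est.append(fit_oreml(y, build_orm(expr), covar).r2)
        assert np.mean(est) < 0.12
        assert np.median(est) < 0.05  # more than half of null fits at/near 0

    def test_seeded_determinism(self):
        cfg = self.cfg()
        g = simulate_genotypes(80, 100, seed=71)
        w, _ = simulate_weight_pair(100, 0.1, 0.2, seed=72, variants=g.variants)
        a = simulate_expression_and_score(g, w, cfg, seed=73)
        b = simulate_expression_and_score(g, w, cfg, seed=73)
        np.testing.assert_array_equal(a[0].values, b[0].values)
        np.testing.assert_array_equal(a[2].score, b[2].score)


class TestStudyBundle:
    def test_structure_and_sample_floors(self, small_bundle, small_config):
        assert len(small_bundle.tissues) == small_config.n_tissues * 2
        for (tissue, sex), parts in small_bundle.tissues.items():
            n = parts["expression"].n_samples
            assert small_config.min_tissue_samples <= n <= small_config.n_samples_per_sex
            assert parts["outcome"].sample_ids == parts["expression"].sample_ids

    def test_byte_identical_fixture_outputs(self, small_config, tmp_path):
        from pgsomics.io import write_study_bundle
        d1 = write_study_bundle(simulate_study(small_config), tmp_path / "a")
        d2 = write_study_bundle(simulate_study(small_config), tmp_path / "b")
        files = sorted(p.relative_to(d1) for p in d1.rglob("*") if p.is_file())
        assert files
        for rel in files:
            assert (d1 / rel).read_bytes() == (d2 / rel).read_bytes(), rel
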