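import numpy as np
import pytest
import statsmodels.api as sm

import medtrans as mt
from medtrans.eqtl import Trio
from medtrans.mediation import MediationData, MultiMediatorModel
from medtrans.simulate import make_scenario_config, simulate_dataset


def _random_data(rng, n=60, p=2, q=0, alphaX=(0.6, 0.6), betaM=(0.3, -0.2)):
    x = rng.binomial(2, 0.3, n).astype(float)
    if np.ptp(x) == 0:
        x[0] = 1.0
    C = rng.normal(size=(n, q)) if q else None
    M = np.column_stack([
        0.5 + alphaX[j] * x + rng.normal(size=n) for j in range(p)
    ])
    y = 0.5 + 0.3 * x + M[:, :len(betaM)] @ np.asarray(betaM[:p]) + rng.normal(size=n)
    if C is not None:
        y = y + C @ rng.normal(size=q)
    return MediationData(y, x, M, C)


class TestFitJoint:
    def test_noiseless_recovery(self):
        # M1 = X and M2 = 2X exactly make [1, X, M1, M2] singular; tiny
        # independent perturbations keep the stages identifiable while the
        # structural coefficients remain (1, 2) and (1, 1).
        rng = np.random.default_rng(0)
        x = np.array([0, 1, 2, 0, 1, 2, 0, 1, 2, 2], float)
        M = np.column_stack([x, 2 * x]) + 1e-6 * rng.normal(size=(10, 2))
        y = M[:, 0] + M[:, 1]
        fit = mt.fit_joint(MediationData(y, x, M))
        assert fit.alphaX == pytest.approx([1.0, 2.0], abs=1e-5)
        assert fit.betaM == pytest.approx([1.0, 1.0], abs=1e-5)
        assert mt.tme(fit) == pytest.approx(3.0, abs=1e-4)

    def test_matches_statsmodels_both_stages(self, rng):
        for _ in range(100):
            data = _random_data(rng, n=15, q=1)
            fit = mt.fit_joint(data)
            D1 = np.column_stack([data.X, data.M, data.C])
            ols_y = sm.OLS(data.Y, sm.add_constant(D1)).fit()
            assert fit.beta0 == pytest.approx(ols_y.params[0], rel=1e-9, abs=1e-12)
            assert fit.betaX == pytest.approx(ols_y.params[1], rel=1e-9, abs=1e-12)
            assert fit.betaM == pytest.approx(ols_y.params[2:4], rel=1e-9, abs=1e-12)
            D2 = np.column_stack([data.X, data.C])
            for j in range(2):
                ols_m = sm.OLS(data.M[:, j], sm.add_constant(D2)).fit()
                assert fit.alpha0[j] == pytest.approx(ols_m.params[0], rel=1e-9, abs=1e-12)
                assert fit.alphaX[j] == pytest.approx(ols_m.params[1], rel=1e-9, abs=1e-12)

    def test_sigma_properties(self, rng):
        fit = mt.fit_joint(_random_data(rng, n=80))
        assert np.allclose(fit.Sigma, fit.Sigma.T)
        assert np.linalg.eigvalsh(fit.Sigma).min() >= -1e-10

    def test_rank_deficiency_names_columns(self, rng):
        data = _random_data(rng, n=30)
        data2 = MediationData(data.Y, data.X, data.M, data.X[:, None].copy())
        with pytest.raises(ValueError, match="C1"):
            mt.fit_joint(data2)


class TestEstimands:
    def test_arithmetic(self):
        f = mt.MediationFit(0.5, 0.3, np.array([1.0, 1.0]), np.empty(0),
                            np.zeros(2), np.array([1.0, 2.0]), np.empty((0, 2)),
                            1.0, np.eye(2))
        assert mt.tme(f) == pytest.approx(3.0)
        assert mt.cme(f) == pytest.approx([1.0, 2.0])

    def test_cancellation_configuration(self):
        f = mt.MediationFit(0.5, 0.3, np.array([0.1, -0.1]), np.empty(0),
                            np.zeros(2), np.array([0.6, 0.6]), np.empty((0, 2)),
                            1.0, np.eye(2))
        assert mt.tme(f) == pytest.approx(0.0, abs=1e-15)
        assert mt.cme(f) == pytest.approx([0.06, -0.06])

    def test_tme_is_sum_of_cme_on_random_fits(self, rng):
        for _ in range(20):
            fit = mt.fit_joint(_random_data(rng))
            assert mt.tme(fit) == pytest.approx(mt.cme(fit).sum(), rel=1e-12)


class TestBootstrapTests:
    def test_p_value_bounds(self, rng):
        data = _random_data(rng, n=50)
        for res in (mt.bootstrap_test_tme(data, B=200, seed=1),
                    mt.bootstrap_test_cme(data, B=200, seed=1),
                    mt.bootstrap_test_sme(data, 0, B=200, seed=1)):
            assert 1 / 201 <= res.p_value <= 1.0

    def test_single_mediator_reduction(self, rng):
        data = _random_data(rng, n=60, p=1, alphaX=(0.8,), betaM=(0.4,))
        t = mt.bootstrap_test_tme(data, B=300, seed=9)
        c = mt.bootstrap_test_cme(data, B=300, seed=9)
        s = mt.bootstrap_test_sme(data, 0, B=300, seed=9)
        assert t.p_value == c.p_value == s.p_value
        assert t.estimate == pytest.approx(c.estimate[0]) == pytest.approx(s.estimate)

    def test_seed_reproducibility(self, rng):
        data = _random_data(rng)
        a = mt.bootstrap_test_tme(data, B=200, seed=5)
        b = mt.bootstrap_test_tme(data, B=200, seed=5)
        assert a.p_value == b.p_value

    def test_strong_effect_detected(self, rng):
        data = _random_data(rng, n=200, alphaX=(0.8, 0.8), betaM=(0.5, 0.5))
        res = mt.bootstrap_test_tme(data, B=500, seed=2)
        assert res.p_value <= 0.01

    def test_b_minimum_enforced(self, rng):
        with pytest.raises(ValueError):
            mt.bootstrap_test_tme(_random_data(rng), B=50, seed=1)

    def test_degenerate_resamples_redrawn(self):
        # one minor-allele carrier: many resamples would be constant in X
        rng = np.random.default_rng(0)
        x = np.zeros(30)
        x[0] = 1.0
        M = np.column_stack([0.5 * x + rng.normal(size=30),
                             rng.normal(size=30)])
        y = M[:, 0] + rng.normal(size=30)
        res = mt.bootstrap_test_tme(MediationData(y, x, M), B=200, seed=4)
        assert res.n_redrawn > 0
        assert 1 / 201 <= res.p_value <= 1.0


class TestSmeAny:
    def test_rule_application(self, rng):
        data = _random_data(rng, n=200, alphaX=(0.9, 0.6), betaM=(0.6, 0.0))
        res = mt.sme_any(data, B=300, seed=3)
        assert res.p_value == res.component_p.min()
        assert res.significant(0.05)

    def test_bonferroni_mode(self, rng):
        data = _random_data(rng, n=40)
        plain = mt.sme_any(data, B=200, seed=3)
        bonf = mt.sme_any(data, B=200, seed=3, correction="bonferroni")
        assert bonf.p_value == pytest.approx(min(1.0, 2 * plain.p_value))

    def test_single_mediator_equals_sme(self, rng):
        data = _random_data(rng, p=1, alphaX=(0.7,), betaM=(0.3,))
        a = mt.sme_any(data, B=200, seed=8)
        b = mt.bootstrap_test_sme(data, 0, B=200, seed=8)
        assert a.p_value == b.p_value


class TestModelResultsApi:
    def test_fit_and_summary(self, rng):
        data = _random_data(rng, n=80, q=1)
        model = MultiMediatorModel(data.Y, data.X, data.M, data.C)
        res = model.fit()
        assert res.tme == pytest.approx(res.cme.sum(), rel=1e-12)
        text = res.summary()
        assert "Delta" in text and "beta_X" in text

    def test_from_dataframe(self, rng):
        import pandas as pd
        data = _random_data(rng, n=50)
        df = pd.DataFrame({"y": data.Y, "x": data.X,
                           "m1": data.M[:, 0], "m2": data.M[:, 1]})
        res = MultiMediatorModel.from_dataframe(df, "y", "x", ["m1", "m2"]).fit()
        direct = MultiMediatorModel.from_data(data).fit()
        assert res.tme == pytest.approx(direct.tme)

    def test_data_validation(self):
        with pytest.raises(ValueError, match="n > p"):
            MediationData(np.ones(4), np.arange(4.0), np.ones((4, 2)))
        with pytest.raises(ValueError, match="complete-case"):
            MediationData(np.array([1, np.nan, 3, 4, 5, 6, 7.0]),
                          np.arange(7.0), np.ones((7, 1)))


class TestAnalyzeTrio:
    def _pipeline(self, seed, betaM=(0.3, 0.3), betaX=0.3):
        from medtrans.fixtures import (FixtureSpec, PlantedTrio,
                                       generate_expression,
                                       generate_genotype_matrix)
        spec = FixtureSpec(n_samples=300, n_snps=8, missing_rate=0.01,
                           planted_trios=[PlantedTrio(0, (0.8, 0.8), betaM, betaX)],
                           n_null_probes=2, seed=seed)
        rng = np.random.default_rng(seed)
        g, true = generate_genotype_matrix(spec, rng)
        e = generate_expression(spec, g, rng, true)
        trio = Trio("snp0000", ["med0_0", "med0_1"], "trans0", 1e-9)
        return mt.analyze_trio(trio, g, e, B=300, seed=seed)

    def test_planted_mediation_detected(self):
        rec = self._pipeline(seed=11)
        assert rec["p_tme"] < 0.05
        assert rec["n"] <= 300

    def test_trans_probe_equal_mediator_rejected(self, rng):
        from medtrans.fixtures import FixtureSpec, generate_expression, generate_genotype_matrix
        spec = FixtureSpec(n_samples=50, n_snps=4, seed=1,
                           planted_trios=[mt.PlantedTrio(0)])
        g, true = generate_genotype_matrix(spec, rng)
        e = generate_expression(spec, g, rng, true)
        bad = Trio("snp0000", ["med0_0"], "med0_0", 1e-9)
        with pytest.raises(ValueError, match="also a mediator"):
            mt.analyze_trio(bad, g, e, B=100, seed=1)

    def test_sample_relabeling_invariance(self, rng):
        from medtrans.fixtures import FixtureSpec, PlantedTrio, generate_expression, generate_genotype_matrix
        from medtrans.io_qc import ExpressionMatrix, GenotypeMatrix
        spec = FixtureSpec(n_samples=120, n_snps=4, missing_rate=0.0, seed=2,
                           planted_trios=[PlantedTrio(0)])
        g, true = generate_genotype_matrix(spec, rng)
        e = generate_expression(spec, g, rng, true)
        trio = Trio("snp0000", ["med0_0", "med0_1"], "trans0", 1e-9)
        rec1 = mt.analyze_trio(trio, g, e, B=200, seed=6)
        renamed = [f"renamed_{s}" for s in g.sample_ids]
        g2 = GenotypeMatrix(g.snp_ids, g.chrom, g.pos, g.dosages, renamed)
        e2 = ExpressionMatrix(e.probe_ids, e.chrom, e.start, e.end, e.values, renamed)
        rec2 = mt.analyze_trio(trio, g2, e2, B=200, seed=6)
        assert rec1["p_tme"] == rec2["p_tme"]
        assert rec1["p_cme"] == rec2["p_cme"]

    def test_monomorphic_snp_skipped(self, rng):
        from medtrans.io_qc import ExpressionMatrix, GenotypeMatrix
        n = 30
        g = GenotypeMatrix(["s0"], ["chr1"], [100], np.zeros((1, n)),
                           [f"x{i}" for i in range(n)])
        vals = rng.normal(size=(3, n))
        e = ExpressionMatrix(["m1", "m2", "t"], ["chr1", "chr1", "chr2"],
                             [90, 95, 100], [99, 99, 200], vals, g.sample_ids)
        trio = Trio("s0", ["m1", "m2"], "t", 1e-9)
        assert mt.analyze_trio(trio, g, e, B=100, seed=1) is None


class TestParameterRecoveryUnderNull:
    def test_permuted_outcome_gives_null_betaM(self):
        """With Y independent of (X, M), beta_M estimates centre on zero."""
        rng = np.random.default_rng(77)
        cfg = make_scenario_config("II", "power", n=100)
        vals = []
        for _ in range(200):
            data = simulate_dataset(cfg, 0.6, rng)
            perm = rng.permutation(data.n)
            fit = mt.fit_joint(MediationData(data.Y[perm], data.X, data.M))
            vals.append(fit.betaM)
        mean = np.mean(vals, axis=0)
        se = np.std(vals, axis=0, ddof=1) / np.sqrt(len(vals))
        assert np.all(np.abs(mean) < 4 * se + 1e-3)
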