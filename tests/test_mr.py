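"""MR core: kinship-GLS weights, polygenic score, 2SLS, multiplicative GMM,
Hausman test and observational comparators."""

import numpy as np
import pytest
from scipy import optimize, stats

from deprivmr.geno import GenotypeMatrix
from deprivmr.mr import (
    build_pgs,
    gls_snp_weights,
    haseman_elston,
    hausman,
    mgmm,
    observational_reference,
    tsls,
    SnpWeight,
)


def _matrix(dosages):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return GenotypeMatrix([f"S{i}" for i in range(n)],
                          [f"snp{j}" for j in range(m)],
                          ["A"] * m, ["G"] * m, d)


class TestGLSWeights:
    def test_identity_kinship_equals_ols(self, rng):
        n, m = 300, 8
        G = _matrix(rng.binomial(2, 0.4, (n, m)))
        y = rng.standard_normal(n)
        K = np.eye(n)
        import statsmodels.api as sm
        w = gls_snp_weights(y, G, K)
        for j, wj in enumerate(w):
            fit = sm.OLS(y, sm.add_constant(G.dosages[:, j])).fit()
            assert wj.weight == pytest.approx(abs(fit.params[1]), abs=1e-8)

    def test_weights_unbiased_on_unrelated(self, rng):
        n, m = 2000, 10
        betas = rng.choice([-1, 1], m) * 0.05
        G = _matrix(rng.binomial(2, 0.35, (n, m)))
        y = G.dosages @ betas + rng.normal(0, 0.3, n)
        w = gls_snp_weights(y, G, np.eye(n))
        bias = [wj.weight - abs(betas[j]) for j, wj in enumerate(w)]
        mean_se = np.mean([wj.se for wj in w])
        assert abs(np.mean(bias)) < 0.1 * mean_se * np.sqrt(m)

    def test_allele_flip_leaves_aligned_weight_unchanged(self, rng):
        n = 400
        g = rng.binomial(2, 0.4, n).astype(float)
        y = 0.2 * g + rng.normal(0, 0.5, n)
        G1 = _matrix(g[:, None])
        G2 = GenotypeMatrix(G1.sample_ids, G1.snp_ids, ["G"], ["A"],
                            (2.0 - g)[:, None])  # flipped coding
        w1 = gls_snp_weights(y, G1, np.eye(n))[0]
        w2 = gls_snp_weights(y, G2, np.eye(n))[0]
        assert w1.weight == pytest.approx(w2.weight, abs=1e-10)
        assert w1.increasing_allele == w2.increasing_allele == "A"
        assert not w1.flipped and w2.flipped

    def test_haseman_elston_recovers_components(self, rng):
        # block-diagonal kinship: 150 sib pairs
        n = 300
        K = np.eye(n)
        for i in range(0, n, 2):
            K[i, i + 1] = K[i + 1, i] = 0.5
        L = np.linalg.cholesky(2.0 * K + 1.0 * np.eye(n))
        ests = [haseman_elston(L @ rng.standard_normal(n), K)
                for _ in range(100)]
        s2g = np.mean([e[0] for e in ests])
        s2e = np.mean([e[1] for e in ests])
        assert s2g == pytest.approx(2.0, abs=0.4)
        assert s2g + s2e == pytest.approx(3.0, abs=0.3)


class TestPGS:
    def test_linearity(self):
        G = _matrix(np.array([[0.0], [1.0], [2.0]]))
        w = [SnpWeight("snp0", "A", 0.1, 0.01, 3, flipped=False)]
        np.testing.assert_allclose(build_pgs(G, w), [0.0, 0.1, 0.2])

    def test_zero_weights_zero_scores(self, rng):
        G = _matrix(rng.binomial(2, 0.4, (50, 4)))
        w = [SnpWeight(s, "A", 0.0, 0.01, 50, False) for s in G.snp_ids]
        assert np.all(build_pgs(G, w) == 0)

    def test_missing_imputed_to_mean_dosage(self):
        d = np.array([[0.0], [2.0], [np.nan]])
        G = _matrix(d)
        w = [SnpWeight("snp0", "A", 1.0, 0.01, 2, False)]
        scores = build_pgs(G, w)
        assert scores[2] == pytest.approx(2 * 0.5)  # 2 x allele freq

    def test_absent_snp_raises(self):
        G = _matrix(np.zeros((3, 1)))
        with pytest.raises(KeyError):
            build_pgs(G, [SnpWeight("other", "A", 0.1, 0.01, 3, False)])


class TestTSLS:
    def test_wald_ratio_identity(self, rng):
        n = 400
        z = rng.standard_normal(n)
        x = 0.5 * z + rng.standard_normal(n)
        y = 0.7 * x + rng.standard_normal(n)
        res = tsls(y, x, z)
        wald = np.cov(z, y)[0, 1] / np.cov(z, x)[0, 1]
        assert res.estimate == pytest.approx(wald, abs=1e-8)

    def test_f_partial_r2_consistency(self, rng):
        n = 600
        z = rng.standard_normal(n)
        cov = rng.standard_normal((n, 2))
        x = 0.4 * z + cov @ [0.2, -0.1] + rng.standard_normal(n)
        y = 0.5 * x + rng.standard_normal(n)
        res = tsls(y, x, z, cov)
        k = 4  # intercept + instrument + 2 covariates
        implied_F = (n - k) * res.first_stage_partial_r2 / \
            (1 - res.first_stage_partial_r2)
        assert implied_F == pytest.approx(res.first_stage_F, rel=1e-10)

    def test_confounded_design_debiased(self):
        """U -> X and U -> Y confounding: OLS biased, 2SLS near truth."""
        r = np.random.default_rng(8)
        n = 5000
        z = r.standard_normal(n)
        u = r.standard_normal(n)
        x = 0.4 * z + 0.8 * u + r.standard_normal(n)
        y = 0.5 * x + 0.8 * u + r.standard_normal(n)
        obs = observational_reference(y, x, family="linear")
        res = tsls(y, x, z, obs_result=(obs["estimate"], obs["variance"]))
        se_iv = (res.ci_high - res.ci_low) / (2 * 1.959964)
        assert abs(res.estimate - 0.5) <= 2 * se_iv
        assert abs(obs["estimate"] - 0.5) >= 4 * np.sqrt(obs["variance"])

    def test_irrelevant_instrument_flagged(self, rng):
        n = 500
        z = rng.standard_normal(n)
        x = rng.standard_normal(n)
        y = x + rng.standard_normal(n)
        res = tsls(y, x, z)
        assert res.first_stage_F < 10
        assert any("weak instrument" in w for w in res.warnings)


class TestMGMM:
    def test_matches_grid_search_oracle_small_n(self):
        """Just-identified moments at n=50, no covariates: the solver's
        (b0, bx) matches a brute-force minimizer of the moment norm."""
        r = np.random.default_rng(3)
        n = 50
        z = r.standard_normal(n)
        x = 0.8 * z + r.standard_normal(n)
        y = (r.random(n) < np.exp(-1.2 + 0.3 * x)).astype(float)
        res = mgmm(y, x, z, _point_only=True)

        def norm(p):
            lin = p[0] + p[1] * x
            m0 = np.mean(y * np.exp(-lin) - 1)
            m1 = np.mean((y * np.exp(-lin) - 1) * z)
            return m0 * m0 + m1 * m1

        grid = optimize.brute(norm, ((-4, 2), (-2, 2)), Ns=60,
                              finish=optimize.fmin)
        assert np.log(res.estimate) == pytest.approx(grid[1], abs=1e-4)

    def test_null_effect_ci_covers_one(self):
        hits = 0
        n_reps = 12
        for rep in range(n_reps):
            r = np.random.default_rng(100 + rep)
            n = 3000
            z = r.standard_normal(n)
            x = 0.5 * z + r.standard_normal(n)
            y = (r.random(n) < np.exp(-2.8 + 0.0 * x)).astype(float)
            res = mgmm(y, x, z, n_boot=300, seed=rep)
            hits += res.ci_low <= 1.0 <= res.ci_high
        assert hits >= 10

    def test_constant_instrument_rejected(self, rng):
        y = (rng.random(100) < 0.2).astype(float)
        with pytest.raises(ValueError, match="instrument"):
            mgmm(y, rng.standard_normal(100), np.ones(100), _point_only=True)

    def test_degenerate_outcome_rejected(self, rng):
        with pytest.raises(ValueError, match="degenerate"):
            mgmm(np.zeros(100), rng.standard_normal(100),
                 rng.standard_normal(100), _point_only=True)

    def test_small_n_boot_rejected(self, rng):
        n = 200
        z = rng.standard_normal(n)
        x = z + rng.standard_normal(n)
        y = (rng.random(n) < 0.3).astype(float)
        with pytest.raises(ValueError, match="n_boot"):
            mgmm(y, x, z, n_boot=50)

    def test_matches_poisson_when_exposure_is_own_instrument(self):
        """With no confounding and Z = X, the MGMM risk ratio and the robust
        Poisson IRR estimate the same quantity; their moment conditions
        differ only in residual weighting, so they agree to simulation
        error at large n."""
        r = np.random.default_rng(77)
        n = 20_000
        x = r.standard_normal(n)
        y = (r.random(n) < np.exp(-2.5 + 0.35 * x)).astype(float)
        res = mgmm(y, x, x, _point_only=True)
        obs = observational_reference(y, x, family="poisson")
        assert res.estimate == pytest.approx(obs["estimate"], rel=0.03)
        assert res.estimate == pytest.approx(np.exp(0.35), rel=0.05)


class TestHausman:
    def test_hand_computed_example(self):
        stat, p, flag = hausman(0.5, 0.04, 0.3, 0.01)
        assert stat == pytest.approx(0.04 / 0.03, rel=1e-9)
        assert p == pytest.approx(stats.chi2.sf(0.04 / 0.03, 1), rel=1e-12)
        assert p == pytest.approx(0.248, abs=0.001)
        assert not flag

    def test_identical_estimates(self):
        stat, p, flag = hausman(0.3, 0.05, 0.3, 0.01)
        assert stat == 0.0 and p == pytest.approx(stats.chi2.sf(0, 1))

    def test_degenerate_variance_ordering(self):
        stat, p, flag = hausman(0.5, 0.01, 0.3, 0.04)
        assert (stat, p, flag) == (0.0, 1.0, True)

    def test_invalid_variance(self):
        with pytest.raises(ValueError):
            hausman(0.5, 0.0, 0.3, 0.01)


class TestObservationalReference:
    def test_linear_slope_recovery(self, rng):
        n = 2000
        x = rng.standard_normal(n)
        y = 1.5 * x + rng.normal(0, 2, n)
        obs = observational_reference(y, x)
        assert obs["family"] == "linear"
        assert abs(obs["estimate"] - 1.5) <= 2 * np.sqrt(obs["variance"])

    def test_null_binary_irr_covers_one(self, rng):
        n = 4000
        x = rng.standard_normal(n)
        y = (rng.random(n) < 0.1).astype(float)
        obs = observational_reference(y, x)
        assert obs["family"] == "poisson"
        assert obs["ci"][0] <= 1.0 <= obs["ci"][1]
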