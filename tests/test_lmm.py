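"""GRM construction, REML heritability and the efficient-score scan."""

import numpy as np
import pytest
from scipy import stats

from cpeparch import (GRM, LinearMixedModel, SyntheticConfig, compute_grm,
                      reml_fit, score_test_scan, simulate_genotypes)
from cpeparch.exceptions import AlignmentError
from cpeparch.lmm import _restricted_loglik


def _unrelated_genotypes(seed, n, m, maf=0.3):
    rng = np.random.default_rng(seed)
    return rng.binomial(2, maf, size=(n, m)).astype(float)


class TestGRM:
    def test_duplicated_individual_matches_diagonal(self):
        G = _unrelated_genotypes(0, 50, 400)
        G[1] = G[0]
        K = compute_grm(G).values
        assert abs(K[0, 1] - K[0, 0]) / K[0, 0] < 1e-10

    def test_unrelated_off_diagonals_near_zero(self):
        K = compute_grm(_unrelated_genotypes(1, 100, 5000)).values
        off = K[~np.eye(100, dtype=bool)]
        assert abs(off.mean()) < 0.02
        assert np.allclose(np.diag(K).mean(), 1.0, atol=0.1)

    def test_full_sib_relatedness_near_half(self):
        cfg = SyntheticConfig(seed=2, n_loci=20, n_snps_per_locus=10,
                              n_null_snps=300)
        g = simulate_genotypes(cfg, 300, sib_fraction=0.5)
        K = compute_grm(g.dosages).values
        within = [K[i, j] for i, j in g.sib_pairs]
        assert np.mean(within) == pytest.approx(0.5, abs=0.1)

    def test_monomorphic_snps_skipped(self, caplog):
        G = _unrelated_genotypes(3, 30, 50)
        G[:, 0] = 2.0
        K1 = compute_grm(G).values
        K2 = compute_grm(G[:, 1:]).values
        np.testing.assert_allclose(K1, K2)
        with pytest.raises(AlignmentError):
            compute_grm(np.full((10, 3), 2.0))

    def test_psd_and_symmetry_enforced(self):
        K = compute_grm(_unrelated_genotypes(4, 40, 200))
        vals, _ = K.eigen()
        assert vals.min() >= -1e-8 * vals.max()
        bad = np.array([[1.0, 0.5], [0.4, 1.0]])
        with pytest.raises(AlignmentError):
            GRM(bad)

    def test_round_trip_save_load(self, tmp_path):
        K = compute_grm(_unrelated_genotypes(5, 12, 100),
                        ids=[f"I{i}" for i in range(12)])
        K.save(tmp_path / "test")
        K2 = GRM.load(tmp_path / "test")
        np.testing.assert_allclose(K.values, K2.values, atol=1e-9)
        assert K.ids == K2.ids


def _phenotype_from_grm(rng, grm, h2, sigma2=1.0, X=None, beta=None):
    lam, U = grm.eigen()
    g = U @ (rng.standard_normal(grm.n) * np.sqrt(np.clip(lam, 0, None) * h2 * sigma2))
    e = rng.standard_normal(grm.n) * np.sqrt((1 - h2) * sigma2)
    y = g + e
    if X is not None and beta is not None:
        y = y + X @ beta
    return y


class TestREML:
    def test_null_phenotype_h2_near_zero(self):
        grm = compute_grm(_unrelated_genotypes(6, 1000, 1200))
        rng = np.random.default_rng(6)
        X = np.ones((1000, 1))
        h2s = [reml_fit(rng.standard_normal(1000), X, grm).h2 for _ in range(50)]
        assert np.mean(h2s) < 0.05

    def test_recovers_moderate_h2(self):
        cfg = SyntheticConfig(seed=7, n_loci=10, n_snps_per_locus=10,
                              n_null_snps=900)
        g = simulate_genotypes(cfg, 800, sib_fraction=0.2)
        grm = compute_grm(g.dosages)
        rng = np.random.default_rng(7)
        X = np.ones((800, 1))
        h2s = [reml_fit(_phenotype_from_grm(rng, grm, 0.5), X, grm).h2
               for _ in range(30)]
        assert np.mean(h2s) == pytest.approx(0.5, abs=0.07)

    def test_two_individual_closed_form(self):
        """n=2, no covariates, K = [[1, k], [k, 1]]: the ML solution for the
        two variance components is available in closed form from the two
        eigen-contrasts z1, z2."""
        k = 0.6
        grm = GRM(np.array([[1.0, k], [k, 1.0]]))
        y = np.array([1.9, 0.3])
        z1 = (y[0] + y[1]) / np.sqrt(2)   # eigenvalue 1 + k
        z2 = (y[0] - y[1]) / np.sqrt(2)   # eigenvalue 1 - k
        sg = (z1 ** 2 - z2 ** 2) / (2 * k)
        se = (z1 ** 2 + z2 ** 2) / 2 - sg
        assert sg > 0 and se > 0  # interior solution exists for this y
        est = reml_fit(y, None, grm)
        assert est.converged
        assert est.h2 == pytest.approx(sg / (sg + se), abs=1e-8)
        assert est.sigma2_g == pytest.approx(sg, abs=1e-7)
        assert est.sigma2_e == pytest.approx(se, abs=1e-7)

    def test_projection_invariance_to_covariate_scaling(self):
        grm = compute_grm(_unrelated_genotypes(8, 150, 300))
        rng = np.random.default_rng(8)
        X = np.column_stack([np.ones(150), rng.normal(size=150)])
        y = _phenotype_from_grm(rng, grm, 0.4, X=X, beta=np.array([1.0, 0.5]))
        a = reml_fit(y, X, grm)
        X2 = X.copy()
        X2[:, 1] = X2[:, 1] * 3.0 + 5.0  # same column space
        b = reml_fit(y, X2, grm)
        assert a.h2 == pytest.approx(b.h2, abs=1e-7)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-6)

    def test_profile_optimum_matches_grid_oracle(self):
        grm = compute_grm(_unrelated_genotypes(9, 120, 200))
        rng = np.random.default_rng(9)
        X = np.ones((120, 1))
        y = _phenotype_from_grm(rng, grm, 0.6, X=X, beta=np.array([2.0]))
        est = reml_fit(y, X, grm)
        lam, U = grm.eigen()
        yt, Xt = U.T @ y, U.T @ X
        grid = np.linspace(0, 1, 2001)
        lls = [_restricted_loglik(h, lam, yt, Xt)[0] for h in grid]
        assert est.h2 == pytest.approx(grid[int(np.argmax(lls))], abs=1e-3)

    def test_input_validation(self):
        grm = GRM(np.eye(5))
        with pytest.raises(AlignmentError):
            reml_fit(np.zeros(4), None, grm)
        with pytest.raises(AlignmentError):
            reml_fit(np.zeros(5), np.ones((5, 4)), grm)


class TestScoreScan:
    def test_null_pvalues_uniform(self):
        G = _unrelated_genotypes(10, 500, 2000)
        grm = compute_grm(G[:, :1000])
        rng = np.random.default_rng(10)
        y = rng.standard_normal(500)
        scan = score_test_scan(y, np.ones((500, 1)), grm, G[:, 1000:])
        assert stats.kstest(scan["pvalue"].dropna(), "uniform").pvalue > 0.01

    def test_identity_grm_reduces_to_ols_score_test(self):
        rng = np.random.default_rng(11)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        y = X @ np.array([1.0, 0.3]) + rng.standard_normal(n)
        G = rng.binomial(2, 0.3, size=(n, 50)).astype(float)
        scan = score_test_scan(y, X, grm=GRM(np.eye(n)), test_genotypes=G)
        # OLS score-test oracle with the REML residual variance (RSS/(n-p))
        H = X @ np.linalg.solve(X.T @ X, X.T)
        r = y - H @ y
        s2 = r @ r / (n - X.shape[1])
        for j in range(50):
            g = G[:, j]
            gM = g - H @ g
            expect = (g @ r) ** 2 / (s2 * (g @ gM))
            assert scan["score_stat"].iloc[j] == pytest.approx(expect, abs=1e-6)

    def test_shift_and_scale_invariance(self):
        G = _unrelated_genotypes(12, 150, 100)
        grm = compute_grm(G)
        rng = np.random.default_rng(12)
        y = rng.standard_normal(150)
        X = np.ones((150, 1))
        base = score_test_scan(y, X, grm, G)
        shifted = score_test_scan(y + 7.0, X, grm, G)
        scaled = score_test_scan(y * 3.0, X, grm, G)
        np.testing.assert_allclose(base["score_stat"], shifted["score_stat"],
                                   rtol=1e-6)
        np.testing.assert_allclose(base["pvalue"], scaled["pvalue"], rtol=1e-5)

    def test_planted_effect_power_matches_noncentrality(self):
        """Score statistic for a planted SNP effect is chi-square with the
        analytic noncentrality: empirical power within 5%."""
        n, beta, maf, alpha = 300, 0.25, 0.3, 0.05
        hits = 0
        reps = 500
        lam_sum = 0.0
        for rep in range(reps):
            rng = np.random.default_rng([13, rep])
            g = rng.binomial(2, maf, size=n).astype(float)
            y = g * beta + rng.standard_normal(n)
            scan = score_test_scan(y, np.ones((n, 1)), GRM(np.eye(n)),
                                   g[:, None])
            hits += float(scan["pvalue"].iloc[0]) < alpha
            gc = g - g.mean()
            lam_sum += beta ** 2 * (gc @ gc)
        lam = lam_sum / reps
        power = stats.ncx2.sf(stats.chi2.isf(alpha, 1), 1, lam)
        assert hits / reps == pytest.approx(power, abs=0.05)

    def test_zero_variance_snp_is_nan_with_warning(self):
        G = _unrelated_genotypes(14, 60, 30)
        grm = compute_grm(G)
        y = np.random.default_rng(14).standard_normal(60)
        T = G[:, :3].copy()
        T[:, 1] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            scan = score_test_scan(y, np.ones((60, 1)), grm, T)
        assert np.isnan(scan["score_stat"].iloc[1])
        assert np.isfinite(scan["score_stat"].iloc[0])


class TestEstimatorWrapper:
    def test_fit_exposes_components_and_scan(self):
        G = _unrelated_genotypes(15, 200, 300)
        grm = compute_grm(G)
        rng = np.random.default_rng(15)
        y = _phenotype_from_grm(rng, grm, 0.5)
        model = LinearMixedModel().fit(np.ones((200, 1)), y, grm=grm)
        assert 0.0 <= model.h2_ <= 1.0
        assert model.sigma2_g_ >= 0 and model.sigma2_e_ >= 0
        assert model.converged_
        scan = model.score_scan(G[:, :20])
        assert len(scan) == 20
        assert model.get_params() == {"xatol": 1e-10}
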