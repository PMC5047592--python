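"""Association statistics against independent dense-matrix oracles.

Every statistic is recomputed here from scratch with dense linear algebra
(explicit inverses and projections) and compared at 1e-10 on small fixtures
with O(1)-scale covariates.
"""

import numpy as np
import pytest
import statsmodels.api as sm

from ceramic.association import (
    blue_allele_freq,
    blup_genotypes,
    ceramic_complete,
    ceramic_missing,
    chisq_pvalue,
    genome_scan,
    mqls_lin,
    mqls_log,
    sigmaG2_check,
    sigmaG2_complete,
    _logistic_irls,
    _retrospective_statistic,
    _sigma_check_from_sample,
)
from ceramic.data_model import SampleData, partition_missingness
from ceramic.null_model import BlockSpectra, fit_null
from ceramic.pedigree import KinshipMatrix, compute_kinship
from ceramic.simulation import build_fixture_pedigree


# ---------------------------------------------------------------------------
# dense oracles
# ---------------------------------------------------------------------------

def dense_M(PhiR):
    Ri = np.linalg.inv(PhiR)
    one = np.ones(PhiR.shape[0])
    return Ri - np.outer(Ri @ one, Ri @ one) / (one @ Ri @ one)

def dense_sigma2(G, X, Phi):
    n, k = X.shape
    Pi = np.linalg.inv(Phi)
    P = Pi - Pi @ X @ np.linalg.solve(X.T @ Pi @ X, X.T @ Pi)
    return float(G @ P @ G) / (n - k)

def dense_missing_stat(resid_W, G_R, R, W, Kdense, sigma2):
    PhiR = Kdense[np.ix_(R, R)]
    PhiRW = Kdense[np.ix_(R, W)]
    F = dense_M(PhiR) @ PhiRW @ resid_W
    return float(F @ G_R) ** 2 / (sigma2 * float(F @ PhiR @ F))

def dense_blup(G_R, R, W, Kdense):
    PhiR = Kdense[np.ix_(R, R)]
    PhiWR = Kdense[np.ix_(W, R)]
    Ri = np.linalg.inv(PhiR)
    one = np.ones(len(R))
    p_hat = float(one @ Ri @ G_R) / float(one @ Ri @ one)
    return p_hat + PhiWR @ Ri @ (G_R - p_hat), p_hat


# ---------------------------------------------------------------------------
# scenario fixtures
# ---------------------------------------------------------------------------

def _scenario(seed=0, n_sing=6, mask=True):
    """Two fixture families + singletons with a partially-missing pattern."""
    ped = build_fixture_pedigree()
    block = compute_kinship(ped).toarray()
    n = 32 + n_sing
    raw = [(np.arange(16), block), (np.arange(16, 32), block)]
    raw += [(np.array([32 + j]), np.array([[1.0]])) for j in range(n_sing)]
    K = KinshipMatrix.from_blocks(n, raw)
    rng = np.random.default_rng(seed)
    Y = rng.integers(0, 2, n).astype(float)
    X = np.column_stack([np.ones(n), rng.standard_normal(n),
                         rng.integers(0, 2, n).astype(float)])
    G = rng.integers(0, 3, n).astype(float)
    if mask:
        # some family members lose phenotype+covariates, some lose genotype;
        # singletons beyond the first two are genotype-only
        Y[[2, 17]] = np.nan
        X[[2, 17]] = np.nan
        G[[5, 6, 20]] = np.nan
        Y[34:] = np.nan
        X[34:] = np.nan
    data = SampleData(Y=Y, X=X, G=G[None, :])
    return data, K


def _fit_W(data, K, part):
    return fit_null(data.Y[part.W], data.X[part.W],
                    BlockSpectra(K.restrict(part.W)), subset=part.W)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

class TestAlleleFreq:
    def test_identity_phi_is_sample_mean(self, rng):
        G = rng.integers(0, 3, 12).astype(float)
        assert blue_allele_freq(G, np.eye(12)) == pytest.approx(G.mean())

    def test_constant_genotype(self):
        assert blue_allele_freq(np.full(5, 2.0), np.eye(5)) == pytest.approx(2.0)

    def test_parent_offspring_pair_plus_singleton(self):
        Phi = np.array([[1.0, 0.5, 0.0], [0.5, 1.0, 0.0], [0.0, 0.0, 1.0]])
        G = np.array([2.0, 1.0, 0.0])
        Ri = np.linalg.inv(Phi)
        one = np.ones(3)
        expect = (one @ Ri @ G) / (one @ Ri @ one)
        assert blue_allele_freq(G, Phi) == pytest.approx(expect, abs=1e-12)

    def test_kinship_matrix_argument(self, fixture_K, rng):
        G = rng.integers(0, 3, 16).astype(float)
        dense = blue_allele_freq(G, fixture_K.toarray())
        block = blue_allele_freq(G, fixture_K.restrict(np.arange(16)))
        assert block == pytest.approx(dense, abs=1e-12)


class TestBlup:
    def test_complete_data_returns_observed(self):
        data, K = _scenario(mask=False)
        part = partition_missingness(data, K, 0)
        res = blup_genotypes(data.G[0, part.R], part, K)
        assert np.allclose(res.G_hat_W, data.G[0, part.W], atol=1e-10)

    def test_observed_genotypes_preserved_on_U(self):
        data, K = _scenario()
        part = partition_missingness(data, K, 0)
        res = blup_genotypes(data.G[0, part.R], part, K)
        in_U = np.isin(part.W, part.U)
        assert np.allclose(res.G_hat_W[in_U], data.G[0, part.W[in_U]],
                           atol=1e-10)

    def test_isolated_member_shrinks_to_mean(self):
        # the married-in founder's only blood relatives are their children;
        # ungenotyping founder and children leaves a zero Phi_SR row, so the
        # BLUP shrinks to the allele-frequency mean (the founder stays
        # eligible through the family-anchor condition)
        data, K = _scenario()
        G = data.G[0].copy()
        G[[5, 8, 9, 10, 11]] = np.nan  # married-in founder + their sibship
        data = SampleData(Y=data.Y, X=data.X, G=G[None, :])
        part = partition_missingness(data, K, 0)
        assert 5 in part.S
        res = blup_genotypes(G[part.R], part, K)
        pos = int(np.flatnonzero(part.W == 5)[0])
        assert res.G_hat_W[pos] == pytest.approx(res.p_hat, abs=1e-10)

    def test_matches_dense_gls_oracle(self):
        data, K = _scenario(seed=4)
        part = partition_missingness(data, K, 0)
        res = blup_genotypes(data.G[0, part.R], part, K)
        expect, p_exp = dense_blup(data.G[0, part.R], part.R, part.W,
                                   K.toarray())
        assert res.p_hat == pytest.approx(p_exp, abs=1e-12)
        assert np.allclose(res.G_hat_W, expect, atol=1e-10)


class TestGenotypicVariance:
    def test_projection_annihilates_design(self, rng):
        data, K = _scenario(mask=False)
        c = rng.standard_normal(data.k)
        assert sigmaG2_complete(data.X @ c, data.X, K) == pytest.approx(0.0, abs=1e-10)

    def test_identity_phi_intercept_gives_sample_variance(self, rng):
        n = 25
        K = KinshipMatrix.from_blocks(
            n, [(np.array([i]), np.array([[1.0]])) for i in range(n)])
        G = rng.integers(0, 3, n).astype(float)
        assert sigmaG2_complete(G, np.ones((n, 1)), K) == pytest.approx(
            G.var(ddof=1), abs=1e-12)

    def test_matches_dense_oracle(self):
        data, K = _scenario(seed=7)
        part = partition_missingness(data, K, 0)
        got = _sigma_check_from_sample(data, part, K, 0)
        expect = dense_sigma2(data.G[0, part.Q], data.X[part.Q],
                              K.toarray()[np.ix_(part.Q, part.Q)])
        assert got == pytest.approx(expect, abs=1e-10)

    def test_q_equals_n_reduces_to_complete(self):
        data, K = _scenario(mask=False)
        part = partition_missingness(data, K, 0)
        full = sigmaG2_complete(data.G[0], data.X, K)
        restricted = sigmaG2_check(data.G[0, part.Q], data.X[part.Q],
                                   K.restrict(part.Q))
        assert restricted == pytest.approx(full, abs=1e-12)

    def test_too_few_individuals_rejected(self):
        with pytest.raises(ValueError):
            sigmaG2_check(np.array([1.0]), np.array([[1.0]]), np.eye(1))


class TestChisq:
    @pytest.mark.parametrize("stat,p,tol", [
        (0.0, 1.0, 1e-12), (3.841459, 0.05, 1e-4), (10.8276, 0.001, 1e-5),
    ])
    def test_reference_quantiles(self, stat, p, tol):
        assert chisq_pvalue(stat) == pytest.approx(p, abs=tol)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            chisq_pvalue(-0.5)


# ---------------------------------------------------------------------------
# the statistics
# ---------------------------------------------------------------------------

class TestCompleteData:
    def test_matches_dense_oracle(self):
        data, K = _scenario(mask=False)
        nf = fit_null(data.Y, data.X, BlockSpectra(K.restrict(np.arange(K.n))))
        res = ceramic_complete(nf, data.G[0], data.X, K)
        A = K.toarray()
        s2 = dense_sigma2(data.G[0], data.X, A)
        expect = float(nf.Z @ data.G[0]) ** 2 / (s2 * float(nf.Z @ A @ nf.Z))
        assert res.statistic == pytest.approx(expect, rel=1e-10)

    def test_invariant_to_adding_design_combination(self, rng):
        data, K = _scenario(mask=False, seed=2)
        nf = fit_null(data.Y, data.X, BlockSpectra(K.restrict(np.arange(K.n))))
        base = ceramic_complete(nf, data.G[0], data.X, K)
        shifted = ceramic_complete(nf, data.G[0] + data.X @ rng.standard_normal(data.k),
                                   data.X, K)
        assert shifted.statistic == pytest.approx(base.statistic, rel=1e-9)

    def test_invariant_to_allele_flip(self):
        data, K = _scenario(mask=False, seed=2)
        nf = fit_null(data.Y, data.X, BlockSpectra(K.restrict(np.arange(K.n))))
        base = ceramic_complete(nf, data.G[0], data.X, K)
        flipped = ceramic_complete(nf, 2.0 - data.G[0], data.X, K)
        assert flipped.statistic == pytest.approx(base.statistic, rel=1e-9)
        assert flipped.p_hat == pytest.approx(1.0 - base.p_hat, abs=1e-10)

    def test_monomorphic_flagged(self):
        data, K = _scenario(mask=False)
        nf = fit_null(data.Y, data.X, BlockSpectra(K.restrict(np.arange(K.n))))
        res = ceramic_complete(nf, np.ones(K.n), data.X, K)
        assert res.flag == "skipped-monomorphic"
        assert np.isnan(res.p_value)


class TestMissingData:
    def test_reduces_to_complete_when_nothing_missing(self):
        data, K = _scenario(mask=False)
        part = partition_missingness(data, K, 0)
        nf = _fit_W(data, K, part)
        full = ceramic_complete(nf, data.G[0], data.X, K)
        miss = ceramic_missing(nf, data.G[0, part.R], part, K, data=data)
        assert miss.statistic == pytest.approx(full.statistic, rel=1e-10)

    def test_matches_dense_oracle(self):
        data, K = _scenario(seed=9)
        part = partition_missingness(data, K, 0)
        nf = _fit_W(data, K, part)
        res = ceramic_missing(nf, data.G[0, part.R], part, K, data=data)
        s2 = _sigma_check_from_sample(data, part, K, 0)
        expect = dense_missing_stat(nf.Z, data.G[0, part.R], part.R, part.W,
                                    K.toarray(), s2)
        assert res.statistic == pytest.approx(expect, rel=1e-10)

    def test_equals_blup_form(self):
        """Score-of-BLUP formulation is algebraically identical."""
        data, K = _scenario(seed=9)
        part = partition_missingness(data, K, 0)
        nf = _fit_W(data, K, part)
        res = ceramic_missing(nf, data.G[0, part.R], part, K, data=data)
        A = K.toarray()
        PhiR = A[np.ix_(part.R, part.R)]
        PhiWR = A[np.ix_(part.W, part.R)]
        Ri = np.linalg.inv(PhiR)
        one_r = np.ones(part.r)
        C = (np.outer(np.ones(part.w), one_r @ Ri) / (one_r @ Ri @ one_r)
             + PhiWR @ dense_M(PhiR))
        G_hat = C @ data.G[0, part.R]
        blup = blup_genotypes(data.G[0, part.R], part, K, Z_W=nf.Z)
        assert np.allclose(G_hat, blup.G_hat_W, atol=1e-10)
        s2 = _sigma_check_from_sample(data, part, K, 0)
        num = float(nf.Z @ G_hat) ** 2
        var = s2 * float((C.T @ nf.Z) @ PhiR @ (C.T @ nf.Z))
        assert res.statistic == pytest.approx(num / var, rel=1e-10)

    def test_variance_monotone_in_genotyped_set(self):
        """Unmasking a relative's genotype cannot shrink the BLUP-score variance."""
        data, K = _scenario(seed=3)
        part = partition_missingness(data, K, 0)
        nf = _fit_W(data, K, part)
        _, var_small, _ = _retrospective_statistic(
            nf.Z, data.G[0, part.R], part, K, 1.0)
        G2 = data.G[0].copy()
        G2[5] = 1.0  # genotype one previously-missing family member
        d2 = SampleData(Y=data.Y, X=data.X, G=G2[None, :])
        p2 = partition_missingness(d2, K, 0)
        assert np.array_equal(part.W, p2.W)
        _, var_big, _ = _retrospective_statistic(nf.Z, G2[p2.R], p2, K, 1.0)
        assert var_big >= var_small - 1e-10


class TestMqls:
    def test_logistic_residuals_sum_to_zero(self):
        data, K = _scenario(seed=6)
        part = partition_missingness(data, K, 0)
        _, mu = _logistic_irls(data.Y[part.W], data.X[part.W])
        assert abs(np.sum(data.Y[part.W] - mu)) < 1e-8

    def test_irls_matches_statsmodels(self):
        data, K = _scenario(seed=6)
        part = partition_missingness(data, K, 0)
        beta, _ = _logistic_irls(data.Y[part.W], data.X[part.W])
        ref = sm.GLM(data.Y[part.W], data.X[part.W],
                     family=sm.families.Binomial()).fit()
        assert np.allclose(beta, ref.params, atol=1e-8)

    def test_mqls_log_matches_dense_oracle(self):
        data, K = _scenario(seed=6)
        part = partition_missingness(data, K, 0)
        res = mqls_log(data.Y[part.W], data.X[part.W], data.G[0, part.R],
                       part, K, data=data)
        _, mu = _logistic_irls(data.Y[part.W], data.X[part.W])
        s2 = _sigma_check_from_sample(data, part, K, 0)
        expect = dense_missing_stat(data.Y[part.W] - mu, data.G[0, part.R],
                                    part.R, part.W, K.toarray(), s2)
        assert res.statistic == pytest.approx(expect, rel=1e-10)

    def test_mqls_log_intercept_only_uses_centered_phenotype(self):
        data, K = _scenario(seed=6)
        part = partition_missingness(data, K, 0)
        X1 = np.ones((part.w, 1))
        res = mqls_log(data.Y[part.W], X1, data.G[0, part.R], part, K,
                       data=data)
        eps = data.Y[part.W] - data.Y[part.W].mean()
        s2 = _sigma_check_from_sample(data, part, K, 0)
        expect = dense_missing_stat(eps, data.G[0, part.R], part.R, part.W,
                                    K.toarray(), s2)
        assert res.statistic == pytest.approx(expect, rel=1e-9)

    def test_mqls_lin_matches_dense_oracle(self):
        data, K = _scenario(seed=6)
        part = partition_missingness(data, K, 0)
        res = mqls_lin(data.Y[part.W], data.X[part.W], data.G[0, part.R],
                       part, K, data=data)
        coef, *_ = np.linalg.lstsq(data.X[part.W], data.Y[part.W], rcond=None)
        e = data.Y[part.W] - data.X[part.W] @ coef
        assert np.abs(data.X[part.W].T @ e).max() < 1e-10
        s2 = _sigma_check_from_sample(data, part, K, 0)
        expect = dense_missing_stat(e, data.G[0, part.R], part.R, part.W,
                                    K.toarray(), s2)
        assert res.statistic == pytest.approx(expect, rel=1e-10)

    def test_mqls_lin_constant_phenotype_flagged(self):
        data, K = _scenario(seed=6)
        part = partition_missingness(data, K, 0)
        res = mqls_lin(np.ones(part.w), np.ones((part.w, 1)),
                       data.G[0, part.R], part, K, data=data)
        assert res.flag == "skipped-no-informative"


class TestGenomeScan:
    def _scan_data(self, n_snps=30, seed=1):
        data, K = _scenario(seed=seed)
        rng = np.random.default_rng(seed + 100)
        G = rng.integers(0, 3, (n_snps, K.n)).astype(float)
        G[:, np.isnan(data.G[0])] = np.nan  # shared missingness pattern
        G[::3, 7] = np.nan  # second pattern for every third SNP
        import pandas as pd
        snps = pd.DataFrame({"SNP": [f"rs{i}" for i in range(n_snps)],
                             "CHR": "1", "POS": np.arange(n_snps)})
        return SampleData(Y=data.Y, X=data.X, G=G, snps=snps), K

    def test_every_snp_produces_a_row(self):
        data, K = self._scan_data()
        rows, info = genome_scan(data, K, methods=("ceramic", "mqls-lin"))
        assert len(rows) == data.n_snps
        assert all("FLAG" in r for r in rows)
        assert np.isfinite(info["lambda_gc"])

    def test_partition_cache_reused_across_patterns(self):
        data, K = self._scan_data()
        _, info = genome_scan(data, K)
        assert info["cache_misses"] == 2
        assert info["cache_hits"] == data.n_snps - 2

    def test_monomorphic_snp_flagged_not_dropped(self):
        data, K = self._scan_data(n_snps=3)
        G = data.G.copy()
        G[1] = 1.0
        data = SampleData(Y=data.Y, X=data.X, G=G, snps=data.snps)
        rows, _ = genome_scan(data, K)
        assert rows[1]["FLAG"] == "skipped-monomorphic"
        assert rows[0]["FLAG"] == "ok" and rows[2]["FLAG"] == "ok"

    def test_per_snp_and_fixed_modes_agree_on_complete_data(self):
        data, K = _scenario(mask=False)
        import pandas as pd
        rng = np.random.default_rng(0)
        G = rng.integers(0, 3, (4, K.n)).astype(float)
        snps = pd.DataFrame({"SNP": list("abcd"), "CHR": "1", "POS": range(4)})
        sd = SampleData(Y=data.Y, X=data.X, G=G, snps=snps)
        rows_g, info = genome_scan(sd, K, xi_mode="once-per-genome")
        rows_s, _ = genome_scan(sd, K, xi_mode="per-snp")
        # with complete data W is identical for all SNPs, so the two modes
        # fit the same subsets and must agree exactly
        for rg, rs in zip(rows_g, rows_s):
            assert rs["STAT_CERAMIC"] == pytest.approx(rg["STAT_CERAMIC"],
                                                       rel=1e-8)
        rows_f, _ = genome_scan(sd, K, xi_mode="fixed-value",
                                xi_value=info["xi_genome"])
        for rg, rf in zip(rows_g, rows_f):
            assert rf["STAT_CERAMIC"] == pytest.approx(rg["STAT_CERAMIC"],
                                                       rel=1e-10)
        # with complete data the fixed-Z subset equals every SNP's W set
        rows_z, _ = genome_scan(sd, K, residual_mode="fixed-Z")
        for rg, rz in zip(rows_g, rows_z):
            assert rz["STAT_CERAMIC"] == pytest.approx(rg["STAT_CERAMIC"],
                                                       rel=1e-10)

    def test_fixed_z_mode_runs_with_missing_data(self):
        data, K = self._scan_data()
        rows, info = genome_scan(data, K, residual_mode="fixed-Z")
        assert len(rows) == data.n_snps
        assert all(r["FLAG"] in ("ok", "skipped-monomorphic") for r in rows)
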