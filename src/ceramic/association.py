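"""Retrospective association statistics for binary traits in pedigrees.

Significance is assessed under the null conditional distribution of the
genotype given phenotype and covariates:

    E0(G | Y, X) = X alpha,      Var0(G | Y, X) = sigma_G^2 * Phi,

which makes the tests robust to misspecification of the phenotype model.
With complete data the statistic is

    T_c = (Z' G)^2 / (sigma_G^2_hat * Z' Phi Z),

where Z are the transformed null phenotypic residuals and sigma_G^2_hat is
the mean squared residual of the GLS regression of G on X with covariance
proportional to Phi.  With partially missing data, genotypes are observed on
a set R while residuals live on a set W; the statistic

    T = (F' G_R)^2 / (sigma_G^2_check * F' Phi_R F),   F = M Phi_RW Z_W,

with M the Phi_R^{-1}-weighted centering projection, is algebraically
identical to scoring the BLUP-imputed genotypes Z_W' G_hat_W against their
retrospective variance, and reduces exactly to T_c when no data are missing.
The MQLS-LOG and MQLS-LIN variants substitute ordinary logistic-regression
or OLS residuals for Z_W.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import expit

from .data_model import (
    MissingnessPartition,
    NoInformativeIndividuals,
    PartitionCache,
    SampleData,
)
from .null_model import BlockSpectra, ConvergenceError, NullFit, fit_null
from .pedigree import KinshipMatrix

__all__ = [
    "TestResult",
    "BlupResult",
    "blue_allele_freq",
    "blup_genotypes",
    "sigmaG2_complete",
    "sigmaG2_check",
    "ceramic_complete",
    "ceramic_missing",
    "mqls_log",
    "mqls_lin",
    "chisq_pvalue",
    "genome_scan",
    "GC_NULL_MEDIAN",
]

_DENOM_TOL = 1e-12
GC_NULL_MEDIAN = float(sps.chi2.ppf(0.5, df=1))  # 0.4549...

FLAG_OK = "ok"
FLAG_MONO = "skipped-monomorphic"
FLAG_NOINF = "skipped-no-informative"
FLAG_NOCONV = "not-converged"


@dataclass
class TestResult:
    snp: str
    method: str
    statistic: float
    p_value: float
    n_geno: int
    n_pheno: int
    p_hat: float
    variance: float
    flag: str = FLAG_OK


@dataclass
class BlupResult:
    G_hat_W: np.ndarray
    p_hat: float
    F: np.ndarray | None = None


def chisq_pvalue(statistic: float) -> float:
    """Upper-tail p-value of the 1-df chi-square distribution."""
    if statistic < 0:
        raise ValueError(f"chi-square statistic must be nonnegative, got {statistic}")
    return float(sps.chi2.sf(statistic, df=1))


def _phi_spectra(K: KinshipMatrix, idx: np.ndarray) -> BlockSpectra:
    """Spectra of the restricted kinship matrix, memoized when K carries a cache.

    Replicate studies attach a per-replicate ``_spectra_cache`` dict to K so
    that analyses sharing an index set (e.g. a null fit and the variance
    estimate on the same subset) reuse one decomposition.
    """
    cache = getattr(K, "_spectra_cache", None)
    if cache is None:
        return BlockSpectra(K.restrict(idx))
    key = idx.tobytes()
    sp = cache.get(key)
    if sp is None:
        sp = BlockSpectra(K.restrict(idx))
        cache[key] = sp
    return sp


def blue_allele_freq(G_R: np.ndarray, Phi_R) -> float:
    """GLS mean of the genotypes with weights Phi_R^{-1}.

    On the 0/1/2 genotype scale this estimates twice the allele frequency;
    callers reporting an allele frequency should halve it.
    """
    G_R = np.asarray(G_R, dtype=float)
    if isinstance(Phi_R, KinshipMatrix):
        sol = BlockSpectra(Phi_R).phi_solve(np.column_stack([G_R, np.ones_like(G_R)]))
        a_g, a_1 = sol[:, 0], sol[:, 1]
    else:
        Phi_R = np.asarray(Phi_R, dtype=float)
        sol = np.linalg.solve(Phi_R, np.column_stack([G_R, np.ones_like(G_R)]))
        a_g, a_1 = sol[:, 0], sol[:, 1]
    return float(a_g.sum() / a_1.sum())


def blup_genotypes(
    G_R: np.ndarray,
    partition: MissingnessPartition,
    K: KinshipMatrix,
    Z_W: np.ndarray | None = None,
) -> BlupResult:
    """Best linear unbiased prediction of the W-set genotypes from G_R.

    G_hat_W = 1_w p_hat + Phi_WR Phi_R^{-1} (G_R - 1_r p_hat); observed
    genotypes (individuals in U) are reproduced exactly, and individuals
    unrelated to everyone genotyped shrink to the allele-frequency mean.
    When ``Z_W`` is supplied, F = M Phi_RW Z_W is also returned.
    """
    G_R = np.asarray(G_R, dtype=float)
    spec_R = _phi_spectra(K, partition.R)
    ones = np.ones_like(G_R)
    sol = spec_R.phi_solve(np.column_stack([G_R, ones]))
    a_g, a_1 = sol[:, 0], sol[:, 1]
    denom = a_1.sum()
    p_hat = float(a_g.sum() / denom)
    resid = spec_R.phi_solve(G_R - p_hat)
    G_hat_W = p_hat + K.cross_matmul(partition.W, partition.R, resid)
    F = None
    if Z_W is not None:
        t = K.cross_matmul(partition.R, partition.W, np.asarray(Z_W, dtype=float))
        a_t = spec_R.phi_solve(t)
        F = a_t - a_1 * (a_t.sum() / denom)
    return BlupResult(G_hat_W=G_hat_W, p_hat=p_hat, F=F)


def _gls_residual_ms(G: np.ndarray, X: np.ndarray, spec: BlockSpectra) -> float:
    """G' P G / (n - k) with P the Phi^{-1}-weighted projection off X."""
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need more individuals ({n}) than covariates ({k})")
    sol = spec.phi_solve(np.column_stack([G, X]))
    a_g, a_x = sol[:, 0], sol[:, 1:]
    xtx = X.T @ a_x
    coef = np.linalg.solve(xtx, X.T @ a_g)
    quad = G @ a_g - (X.T @ a_g) @ coef
    return float(max(quad, 0.0) / (n - k))


def sigmaG2_complete(G: np.ndarray, X: np.ndarray, K: KinshipMatrix) -> float:
    """Robust genotypic variance estimate: GLS residual mean square of G on X."""
    idx = np.arange(K.n)
    return _gls_residual_ms(np.asarray(G, float), np.asarray(X, float), _phi_spectra(K, idx))


def sigmaG2_check(G_Q: np.ndarray, X_Q: np.ndarray, Phi_Q) -> float:
    """The complete-data variance estimate restricted to the Q set."""
    if isinstance(Phi_Q, KinshipMatrix):
        spec = BlockSpectra(Phi_Q)
    else:
        spec = None
    G_Q = np.asarray(G_Q, dtype=float)
    X_Q = np.asarray(X_Q, dtype=float)
    if spec is not None:
        return _gls_residual_ms(G_Q, X_Q, spec)
    Phi_Q = np.asarray(Phi_Q, dtype=float)
    n, k = X_Q.shape
    if n <= k:
        raise ValueError(f"need more individuals ({n}) than covariates ({k})")
    Pi = np.linalg.inv(Phi_Q)
    P = Pi - Pi @ X_Q @ np.linalg.solve(X_Q.T @ Pi @ X_Q, X_Q.T @ Pi)
    return float(G_Q @ P @ G_Q / (n - k))


def _sigma_check_from_sample(
    data: SampleData, partition: MissingnessPartition, K: KinshipMatrix, snp: int
) -> float:
    Q = partition.Q
    G_Q = data.G[snp, Q]
    X_Q = data.X[Q]
    return _gls_residual_ms(G_Q, X_Q, _phi_spectra(K, Q))


def _retrospective_statistic(
    resid_W: np.ndarray,
    G_R: np.ndarray,
    partition: MissingnessPartition,
    K: KinshipMatrix,
    sigma2: float,
):
    """Core quadratic form shared by all three statistics.

    Computes F = M Phi_RW resid_W, the squared score (F' G_R)^2 and the
    variance sigma2 * F' Phi_R F, using the identity Phi_R F = t - a*1 with
    t = Phi_RW resid_W, so that F' Phi_R F = F' t.
    """
    spec_R = _phi_spectra(K, partition.R)
    ones = np.ones(partition.r)
    t = K.cross_matmul(partition.R, partition.W, resid_W)
    sol = spec_R.phi_solve(np.column_stack([G_R, ones, t]))
    a_g, a_1, a_t = sol[:, 0], sol[:, 1], sol[:, 2]
    denom = a_1.sum()
    p_hat = float(a_g.sum() / denom)
    F = a_t - a_1 * (a_t.sum() / denom)
    num = float(F @ G_R) ** 2
    var = sigma2 * float(F @ t)
    return num, var, p_hat


def _finish(snp_id, method, num, var, p_hat, partition) -> TestResult:
    if var < _DENOM_TOL:
        return TestResult(
            snp=snp_id, method=method, statistic=np.nan, p_value=np.nan,
            n_geno=partition.r, n_pheno=partition.w, p_hat=p_hat / 2.0,
            variance=var, flag=FLAG_MONO,
        )
    stat = num / var
    return TestResult(
        snp=snp_id, method=method, statistic=stat, p_value=chisq_pvalue(stat),
        n_geno=partition.r, n_pheno=partition.w, p_hat=p_hat / 2.0,
        variance=var, flag=FLAG_OK,
    )


def ceramic_complete(
    null_fit: NullFit,
    G: np.ndarray,
    X: np.ndarray,
    K: KinshipMatrix,
    snp_id: str = "snp",
) -> TestResult:
    """Complete-data retrospective quasi-score test."""
    G = np.asarray(G, dtype=float)
    Z = null_fit.Z
    sigma2 = sigmaG2_complete(G, X, K)
    zphiz = float(Z @ K.matmul(Z))
    var = sigma2 * zphiz
    n = K.n
    p_hat = blue_allele_freq(G, K.restrict(np.arange(n)))
    if var < _DENOM_TOL:
        return TestResult(snp_id, "CERAMIC", np.nan, np.nan, n, n, p_hat / 2.0,
                          var, FLAG_MONO)
    stat = float(Z @ G) ** 2 / var
    return TestResult(snp_id, "CERAMIC", stat, chisq_pvalue(stat), n, n,
                      p_hat / 2.0, var, FLAG_OK)


def ceramic_missing(
    null_fit_W: NullFit,
    G_R: np.ndarray,
    partition: MissingnessPartition,
    K: KinshipMatrix,
    data: SampleData | None = None,
    snp: int = 0,
    sigma2: float | None = None,
    snp_id: str = "snp",
) -> TestResult:
    """Missing-data retrospective test; equals the complete-data form when nothing is missing."""
    if partition.w == 0 or partition.r == 0:
        return TestResult(snp_id, "CERAMIC", np.nan, np.nan, partition.r,
                          partition.w, np.nan, np.nan, FLAG_NOINF)
    if sigma2 is None:
        sigma2 = _sigma_check_from_sample(data, partition, K, snp)
    num, var, p_hat = _retrospective_statistic(
        null_fit_W.Z, np.asarray(G_R, float), partition, K, sigma2
    )
    return _finish(snp_id, "CERAMIC", num, var, p_hat, partition)


def _logistic_irls(Y, X, tol=1e-10, max_iter=50):
    """Plain logistic-regression MLE by iteratively reweighted least squares.

    Solved in a column-scaled basis so the score tolerance does not depend
    on covariate units; returns (coefficients, fitted probabilities).
    """
    scale = np.sqrt(np.mean(np.square(X), axis=0))
    scale[scale == 0] = 1.0
    Xs = X / scale
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = Xs @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        score = Xs.T @ (Y - mu)
        if np.abs(score).max() < tol:
            return beta / scale, mu
        info = (Xs * w[:, None]).T @ Xs
        beta = beta + np.linalg.solve(info, score)
        if np.abs(eta).max() > 30:
            raise ConvergenceError("logistic regression diverged (separation?)")
    raise ConvergenceError("logistic regression did not converge")


def mqls_log(
    Y_W: np.ndarray,
    X_W: np.ndarray,
    G_R: np.ndarray,
    partition: MissingnessPartition,
    K: KinshipMatrix,
    data: SampleData | None = None,
    snp: int = 0,
    sigma2: float | None = None,
    snp_id: str = "snp",
) -> TestResult:
    """Covariate-adjusted MQLS with ordinary logistic-regression residuals."""
    try:
        _, mu = _logistic_irls(np.asarray(Y_W, float), np.asarray(X_W, float))
    except ConvergenceError:
        return TestResult(snp_id, "MQLS-LOG", np.nan, np.nan, partition.r,
                          partition.w, np.nan, np.nan, FLAG_NOCONV)
    eps = np.asarray(Y_W, float) - mu
    if sigma2 is None:
        sigma2 = _sigma_check_from_sample(data, partition, K, snp)
    num, var, p_hat = _retrospective_statistic(eps, np.asarray(G_R, float),
                                               partition, K, sigma2)
    return _finish(snp_id, "MQLS-LOG", num, var, p_hat, partition)


def mqls_lin(
    Y_W: np.ndarray,
    X_W: np.ndarray,
    G_R: np.ndarray,
    partition: MissingnessPartition,
    K: KinshipMatrix,
    data: SampleData | None = None,
    snp: int = 0,
    sigma2: float | None = None,
    snp_id: str = "snp",
) -> TestResult:
    """Covariate-adjusted MQLS with ordinary least-squares residuals."""
    Y_W = np.asarray(Y_W, float)
    X_W = np.asarray(X_W, float)
    if np.linalg.matrix_rank(X_W) < X_W.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    coef, *_ = np.linalg.lstsq(X_W, Y_W, rcond=None)
    e = Y_W - X_W @ coef
    if np.abs(e).max() < _DENOM_TOL:
        return TestResult(snp_id, "MQLS-LIN", np.nan, np.nan, partition.r,
                          partition.w, np.nan, np.nan, FLAG_NOINF)
    if sigma2 is None:
        sigma2 = _sigma_check_from_sample(data, partition, K, snp)
    num, var, p_hat = _retrospective_statistic(e, np.asarray(G_R, float),
                                               partition, K, sigma2)
    return _finish(snp_id, "MQLS-LIN", num, var, p_hat, partition)


_METHOD_KEYS = {"ceramic": "CERAMIC", "mqls-log": "MQLS-LOG", "mqls-lin": "MQLS-LIN"}


def genome_scan(
    data: SampleData,
    K: KinshipMatrix,
    methods: tuple[str, ...] = ("ceramic",),
    xi_mode: str = "once-per-genome",
    xi_value: float | None = None,
    residual_mode: str = "per-snp-beta",
):
    """Scan all SNPs in ``data``; yields one :class:`TestResult` row set per SNP.

    ``xi_mode``: "once-per-genome" estimates the variance component on all
    individuals with complete phenotype/covariates and re-solves only beta
    per SNP; "per-snp" refits (beta, xi) on each SNP's W set; "fixed-value"
    pins xi at ``xi_value``.  ``residual_mode`` "fixed-Z" goes one step
    further: the transformed residuals are computed once on the fixed
    complete-data subset and reused for every SNP (individuals without
    genotyped relatives then simply contribute nothing to a given SNP).
    Returns (results, info) where results is a list of dicts (one per SNP,
    possibly with several method columns) and info carries the genome-wide
    xi estimate, cache statistics and lambda_GC.
    """
    methods = tuple(m.lower() for m in methods)
    for m in methods:
        if m not in _METHOD_KEYS:
            raise ValueError(f"unknown method {m!r}")
    if residual_mode not in ("per-snp-beta", "fixed-Z", "fixed-z"):
        raise ValueError(f"unknown residual_mode {residual_mode!r}")
    fixed_z = residual_mode.lower() == "fixed-z"
    cache = PartitionCache(data, K)
    complete = np.flatnonzero(data.complete_pheno_cov())
    xi_genome = None
    base_fit = None
    if xi_mode == "once-per-genome" or fixed_z:
        spec_c = _phi_spectra(K, complete)
        base_fit = fit_null(data.Y[complete], data.X[complete], spec_c,
                            xi_fixed=xi_value if xi_mode == "fixed-value" else None,
                            subset=complete)
        xi_genome = base_fit.xi0
    elif xi_mode == "fixed-value":
        if xi_value is None:
            raise ValueError("xi_mode='fixed-value' requires xi_value")
        xi_genome = float(xi_value)
    elif xi_mode != "per-snp":
        raise ValueError(f"unknown xi_mode {xi_mode!r}")

    fit_cache: dict[bytes, NullFit] = {}
    rows = []
    stats_for_gc = []
    for s in range(data.n_snps):
        meta = data.snps.iloc[s] if len(data.snps) > s else None
        snp_id = str(meta["SNP"]) if meta is not None else f"snp{s}"
        row = {
            "SNP": snp_id,
            "CHR": meta["CHR"] if meta is not None else ".",
            "POS": meta["POS"] if meta is not None else ".",
        }
        try:
            part = cache.get(s)
            if fixed_z:
                # one residual vector for the whole scan; the statistic's W
                # set becomes the fixed complete-data subset
                part = MissingnessPartition(
                    N=part.N, R=part.R, U=part.U, V=part.V,
                    S=np.setdiff1d(complete, part.U), W=complete, Q=part.Q)
                nf = base_fit
            else:
                key = np.isnan(data.G[s]).tobytes()
                nf = fit_cache.get(key)
                if nf is None:
                    spec_w = _phi_spectra(K, part.W)
                    nf = fit_null(
                        data.Y[part.W], data.X[part.W], spec_w,
                        xi_fixed=xi_genome if xi_mode != "per-snp" else None,
                        subset=part.W,
                    )
                    fit_cache[key] = nf
            sigma2 = _sigma_check_from_sample(data, part, K, s)
            G_R = data.G[s, part.R]
            results = {}
            if "ceramic" in methods:
                results["CERAMIC"] = ceramic_missing(
                    nf, G_R, part, K, sigma2=sigma2, snp_id=snp_id)
            if "mqls-log" in methods:
                results["MQLS-LOG"] = mqls_log(
                    data.Y[part.W], data.X[part.W], G_R, part, K,
                    sigma2=sigma2, snp_id=snp_id)
            if "mqls-lin" in methods:
                results["MQLS-LIN"] = mqls_lin(
                    data.Y[part.W], data.X[part.W], G_R, part, K,
                    sigma2=sigma2, snp_id=snp_id)
            first = next(iter(results.values()))
            row.update(N_GENO=first.n_geno, N_PHENO=first.n_pheno,
                       FREQ=first.p_hat)
            flags = []
            for name, res in results.items():
                col = name.replace("-", "_")
                row[f"STAT_{col}"] = res.statistic
                row[f"P_{col}"] = res.p_value
                flags.append(res.flag)
                if name == "CERAMIC" and res.flag == FLAG_OK:
                    stats_for_gc.append(res.statistic)
            row["FLAG"] = FLAG_OK if all(f == FLAG_OK for f in flags) else \
                next(f for f in flags if f != FLAG_OK)
        except (NoInformativeIndividuals, ConvergenceError, ValueError,
                np.linalg.LinAlgError) as exc:
            row.update(N_GENO=int((~np.isnan(data.G[s])).sum()), N_PHENO=0,
                       FREQ=np.nan, FLAG=FLAG_NOINF if
                       isinstance(exc, NoInformativeIndividuals) else FLAG_NOCONV)
        rows.append(row)
    info = {
        "xi_genome": xi_genome,
        "cache_hits": cache.hits,
        "cache_misses": cache.misses,
        "lambda_gc": (float(np.median(stats_for_gc)) / GC_NULL_MEDIAN
                      if stats_for_gc else np.nan),
    }
    return rows, info
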