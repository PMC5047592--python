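"""Simulation study engine: data generation, calibration and replicate studies.

Samples combine three-generation 16-person families with unrelated
singletons.  Four covariates (age, sex, height, an i.i.d. normal covariate)
are simulated with height a heritable trait (additive variance 36, error
variance 13, narrow-sense heritability 36/49).  Binary traits come from
either a mixed-effects logistic model,

    Y_i | G, X, u ~ Bernoulli(expit(f(G_i) + X_i' beta + u_i)),

or a liability threshold model,

    Y_i = 1{L_i >= lambda(G_i)},   L_i = X_i' beta + u_i + eps_i,

with u ~ MVN(0, sigma_a^2 Phi) additive polygenic effects.  Two unlinked
causal SNPs (MAFs .1 and .2) act epistatically: carriers of at least one
minor allele at each have mean penetrance ~.15, everyone else ~.05, giving
population prevalence ~.057.  The genetic offsets f(G)/lambda(G) and the
covariate coefficient vector beta are calibrated by Monte Carlo.  Families
are ascertained to contain at least four affected members; a missingness
mechanism removes phenotypes/covariates jointly with probability .2 and
genotypes unless the individual is an affected phenotyped member or at
least half of their phenotyped first-degree relatives are affected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import beta as beta_dist

from .association import (
    _sigma_check_from_sample,
    ceramic_missing,
    mqls_lin,
    mqls_log,
)
from .data_model import SampleData, partition_missingness
from .null_model import ConvergenceError, fit_null
from .pedigree import Individual, KinshipMatrix, Pedigree, compute_kinship

__all__ = [
    "SimConfig",
    "Analysis",
    "TraitModelParams",
    "build_fixture_pedigree",
    "fixture_generations",
    "generate_covariates",
    "calibrate_beta",
    "gene_drop",
    "calibrate_penetrance",
    "simulate_trait",
    "ascertain",
    "apply_missingness",
    "simulate_sample",
    "population_prevalence",
    "run_study",
]

_CALIBRATION_SEED = 170039  # fixed: calibration constants are part of the model
_CAL_DRAWS = 1_000_000

# covariate model constants
SIGMA_HA2 = 36.0  # additive variance of height
SIGMA_HE2 = 13.0  # i.i.d. error variance of height
AGE_RANGES = {1: (78, 88), 2: (48, 58), 3: (18, 28)}
UNREL_GEN_PROBS = (0.5, 0.25, 0.25)
MALE, FEMALE = 1.0, 2.0

CARRIER_PROB = (1 - 0.9**2) * (1 - 0.8**2)  # both-SNP minor-allele carrier


# ---------------------------------------------------------------------------
# fixture pedigree
# ---------------------------------------------------------------------------

def build_fixture_pedigree(fid: str = "FAM") -> Pedigree:
    """Canonical 16-person, 3-generation family used throughout the studies.

    Two founder grandparent couples each have one child; those children marry
    married-in founders, and each second-generation couple has four
    offspring.  Generation sizes 4/4/8, six founders, fixed alternating sex
    pattern.
    """
    rows = [
        ("1", None, None, 1), ("2", None, None, 2),
        ("3", None, None, 1), ("4", None, None, 2),
        ("5", "1", "2", 1), ("7", None, None, 2),
        ("6", "3", "4", 2), ("8", None, None, 1),
    ]
    for child in range(9, 13):
        rows.append((str(child), "5", "7", 1 if child % 2 else 2))
    for child in range(13, 17):
        rows.append((str(child), "8", "6", 1 if child % 2 else 2))
    # the two grandparental branches share no common ancestor, so offspring
    # of the two sibships are unrelated despite belonging to one family
    return Pedigree(
        [Individual(fid, iid, fa, mo, sex) for iid, fa, mo, sex in rows]
    )


def fixture_generations() -> np.ndarray:
    """Generation label (1, 2 or 3) per fixture-pedigree member."""
    return np.array([1, 1, 1, 1, 2, 2, 2, 2, 3, 3, 3, 3, 3, 3, 3, 3])


_FIX_PED = build_fixture_pedigree()
_FIX_PHI = compute_kinship(_FIX_PED).toarray()
_FIX_SEX = np.array([float(i.sex) for i in _FIX_PED.individuals])
_FIX_GEN = fixture_generations()
_FIX_CHOL_H = np.linalg.cholesky(SIGMA_HA2 * _FIX_PHI + SIGMA_HE2 * np.eye(16))
_FIX_CHOL_A = np.linalg.cholesky(_FIX_PHI + 1e-12 * np.eye(16))


def _first_degree_matrix(ped: Pedigree) -> np.ndarray:
    """Boolean parent/offspring/full-sibling adjacency."""
    n = ped.n
    fd = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for p in (ped.father_idx[i], ped.mother_idx[i]):
            if p >= 0:
                fd[i, p] = fd[p, i] = True
    for i in range(n):
        for j in range(i + 1, n):
            if (
                ped.father_idx[i] >= 0
                and ped.father_idx[i] == ped.father_idx[j]
                and ped.mother_idx[i] == ped.mother_idx[j]
            ):
                fd[i, j] = fd[j, i] = True
    return fd


_FIX_FD = _first_degree_matrix(_FIX_PED)

# sibship labels for the shared-environment variant: only the two 4-child
# sibships are shared; everyone else is a singleton sibship
_FIX_SIBSHIP = np.array([0, 1, 2, 3, 4, 5, 6, 7, 8, 8, 8, 8, 9, 9, 9, 9])


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulation scenario.

    ``additive_frac`` is theta_a for the logistic trait model (with
    Var(X'beta) + sigma_a^2 = 100) and pi_a for the threshold models (total
    liability variance 100, error variance 20, theta_a-analogue constrained
    by pi_a + pi_c = .8).
    """

    trait_model: str = "logistic"  # logistic | threshold | threshold-shared-env | threshold-prev01
    additive_frac: float = 0.6
    n_families: int = 60
    n_unrelated: int = 240
    maf_causal: tuple[float, float] = (0.1, 0.2)
    maf_test: float = 0.2
    penetrance_targets: tuple[float, float] = (0.15, 0.05)
    ascertainment: str = "A"
    min_affected: int = 4
    missingness: bool = True
    pheno_present_prob: float = 0.8
    tested_snp: str = "null"  # null | causal1 | causal2

    def variance_split(self) -> tuple[float, float, float, float]:
        """(sigma_a^2, Var(X'beta), sigma_e^2, sigma_sib^2)."""
        if self.trait_model == "logistic":
            sa2 = 100.0 * self.additive_frac
            vb = 100.0 - sa2
            return sa2, vb, 0.0, 0.0
        sa2 = 100.0 * self.additive_frac
        vb = 100.0 * (0.8 - self.additive_frac)
        if vb < -1e-9:
            raise ValueError("pi_a cannot exceed 0.8 in the threshold models")
        if self.trait_model == "threshold-shared-env":
            return sa2, max(vb, 0.0), 10.0, 10.0
        return sa2, max(vb, 0.0), 20.0, 0.0

    def penetrances(self) -> tuple[float, float]:
        if self.trait_model == "threshold-prev01":
            # keep the 3:1 carrier ratio, rescale so prevalence is .01
            t0 = 0.01 / (1.0 + 2.0 * CARRIER_PROB)
            return 3.0 * t0, t0
        return self.penetrance_targets


@dataclass(frozen=True)
class Analysis:
    """One way of analyzing each simulated replicate."""

    methods: tuple[str, ...] = ("ceramic",)
    subset: str = "All"  # All | MX
    covariates_in_model: bool = True
    label: str | None = None

    @property
    def name(self) -> str:
        if self.label:
            return self.label
        cov = "" if self.covariates_in_model else "-nocov"
        return f"{self.subset}{cov}"


@dataclass
class TraitModelParams:
    model: str
    beta: np.ndarray
    sigma_a: float
    sigma_e: float
    sigma_sib: float
    f1: float = np.nan  # logistic offsets (carrier / non-carrier)
    f0: float = np.nan
    lam1: float = np.nan  # liability thresholds
    lam0: float = np.nan


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _ages_from_generations(gen: np.ndarray, rng) -> np.ndarray:
    age = np.empty(gen.shape, dtype=float)
    for g, (lo, hi) in AGE_RANGES.items():
        mask = gen == g
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))
    return age


def _mean_height(age: np.ndarray, sex: np.ndarray) -> np.ndarray:
    male = sex == MALE
    old = age >= 65
    out = np.where(male, np.where(old, 172.5, 176.5), np.where(old, 160.2, 163.2))
    return out


def _family_covariates(batch: int, rng) -> np.ndarray:
    """(batch, 16, 5) design matrices for fixture families."""
    gen = np.broadcast_to(_FIX_GEN, (batch, 16))
    age = _ages_from_generations(gen, rng)
    sex = np.broadcast_to(_FIX_SEX, (batch, 16)).astype(float)
    z = rng.standard_normal((batch, 16))
    height = _mean_height(age, sex) + z @ _FIX_CHOL_H.T
    iid = rng.normal(8.0, 3.0, size=(batch, 16))
    X = np.empty((batch, 16, 5))
    X[..., 0] = 1.0
    X[..., 1] = age
    X[..., 2] = sex
    X[..., 3] = height
    X[..., 4] = iid
    return X


def _population_covariates(m: int, rng) -> np.ndarray:
    """(m, 5) design matrices for independent individuals (unrelateds)."""
    gen = rng.choice([1, 2, 3], size=m, p=UNREL_GEN_PROBS)
    age = _ages_from_generations(gen, rng)
    sex = np.where(rng.random(m) < 0.5, MALE, FEMALE)
    height = _mean_height(age, sex) + rng.normal(
        0.0, np.sqrt(SIGMA_HA2 + SIGMA_HE2), size=m
    )
    iid = rng.normal(8.0, 3.0, size=m)
    return np.column_stack([np.ones(m), age, sex, height, iid])


def generate_covariates(
    ped: Pedigree, rng, generations: np.ndarray | None = None
) -> np.ndarray:
    """Covariate design matrix (1, age, sex, height, iid) for one pedigree.

    For the fixture pedigree the fixed sex pattern and generation labels are
    used; other pedigrees require explicit ``generations``.
    """
    if ped.n == 16 and generations is None:
        return _family_covariates(1, rng)[0]
    if generations is None:
        generations = np.minimum(ped.generation_depth() + 1, 3)
    age = _ages_from_generations(np.asarray(generations), rng)
    sex = np.array([float(i.sex) if i.sex else MALE for i in ped.individuals])
    K = compute_kinship(ped)
    cov = SIGMA_HA2 * K.toarray() + SIGMA_HE2 * np.eye(ped.n)
    height = _mean_height(age, sex) + np.linalg.cholesky(cov) @ rng.standard_normal(ped.n)
    iid = rng.normal(8.0, 3.0, size=ped.n)
    return np.column_stack([np.ones(ped.n), age, sex, height, iid])


# ---------------------------------------------------------------------------
# calibration
# ---------------------------------------------------------------------------

_beta_cache: dict[float, np.ndarray] = {}


def calibrate_beta(var_target: float) -> np.ndarray:
    """Covariate coefficients with E(X'beta) = 0 and Var(X'beta) = target.

    Loadings are equal on the standardized covariates (age, sex, height,
    iid); the level is set by Monte Carlo over a large population draw with
    a fixed calibration seed, and the intercept absorbs the centering.
    """
    if var_target < 0:
        raise ValueError("target variance must be nonnegative")
    key = round(float(var_target), 10)
    if key in _beta_cache:
        return _beta_cache[key]
    if var_target == 0.0:
        beta = np.zeros(5)
    else:
        rng = np.random.default_rng(_CALIBRATION_SEED)
        X = _population_covariates(_CAL_DRAWS, rng)
        w = 1.0 / X[:, 1:].std(axis=0)
        v = X[:, 1:] @ w
        scale = np.sqrt(var_target / v.var())
        beta = np.concatenate([[-scale * v.mean()], scale * w])
    _beta_cache[key] = beta
    return beta


_penetrance_cache: dict[tuple, TraitModelParams] = {}


def calibrate_penetrance(cfg: SimConfig) -> TraitModelParams:
    """Genetic effect offsets / liability thresholds hitting the penetrance targets.

    Logistic model: solve E[expit(f + X'beta + u)] = target for the scalar
    offset f by bracketed root finding on a fixed Monte Carlo sample.
    Threshold models: lambda is the Monte Carlo upper-tail quantile of the
    liability L = X'beta + u + (sibship) + eps at the target penetrance.
    """
    key = (cfg.trait_model, round(cfg.additive_frac, 10), cfg.penetrances())
    if key in _penetrance_cache:
        return _penetrance_cache[key]
    sa2, vb, se2, ssib2 = cfg.variance_split()
    beta = calibrate_beta(vb)
    t1, t0 = cfg.penetrances()
    rng = np.random.default_rng(_CALIBRATION_SEED + 1)
    X = _population_covariates(_CAL_DRAWS, rng)
    eta = X @ beta + rng.normal(0.0, np.sqrt(sa2), size=_CAL_DRAWS)
    params = TraitModelParams(
        model=cfg.trait_model, beta=beta, sigma_a=np.sqrt(sa2),
        sigma_e=np.sqrt(se2), sigma_sib=np.sqrt(ssib2),
    )
    if cfg.trait_model == "logistic":
        def mean_pen(f, target):
            return float(expit(f + eta).mean()) - target

        for name, target in (("f1", t1), ("f0", t0)):
            setattr(params, name, brentq(mean_pen, -40.0, 40.0, args=(target,),
                                         xtol=1e-10))
    else:
        L = eta + rng.normal(0.0, np.sqrt(se2 + ssib2), size=_CAL_DRAWS)
        params.lam1 = float(np.quantile(L, 1.0 - t1))
        params.lam0 = float(np.quantile(L, 1.0 - t0))
    _penetrance_cache[key] = params
    return params


# ---------------------------------------------------------------------------
# genotypes and traits
# ---------------------------------------------------------------------------

def _gene_drop_multi(ped: Pedigree, mafs, rng, size: int) -> np.ndarray:
    """Drop several unlinked loci through a pedigree: (L, size, n) allele counts."""
    mafs = np.asarray(mafs, dtype=float)
    if np.any(mafs <= 0.0) or np.any(mafs >= 1.0):
        raise ValueError("minor allele frequency must be in (0, 1)")
    L, n = mafs.size, ped.n
    alleles = np.empty((size, L, n, 2), dtype=np.int8)
    for i in ped._topo_order:
        f, m = int(ped.father_idx[i]), int(ped.mother_idx[i])
        if f < 0:
            alleles[:, :, i, :] = rng.random((size, L, 2)) < mafs[None, :, None]
        else:
            pick_f = rng.random((size, L)) < 0.5
            pick_m = rng.random((size, L)) < 0.5
            af = alleles[:, :, f, :]
            am = alleles[:, :, m, :]
            alleles[:, :, i, 0] = np.where(pick_f, af[..., 0], af[..., 1])
            alleles[:, :, i, 1] = np.where(pick_m, am[..., 0], am[..., 1])
    return alleles.sum(axis=3).transpose(1, 0, 2).astype(np.int8)


def gene_drop(ped: Pedigree, maf: float, rng, size: int = 1) -> np.ndarray:
    """Drop a biallelic locus through a pedigree: (size, n) minor-allele counts.

    Founder alleles are Bernoulli(maf) (Hardy-Weinberg), and each parent
    transmits one uniformly chosen allele.
    """
    return _gene_drop_multi(ped, [maf], rng, size)[0]


def simulate_trait(
    X: np.ndarray,
    u: np.ndarray,
    carrier: np.ndarray,
    params: TraitModelParams,
    rng,
    sibship: np.ndarray | None = None,
) -> np.ndarray:
    """Binary phenotypes from the selected trait model (vectorized over leading axes)."""
    eta = X @ params.beta + u
    if params.model == "logistic":
        f = np.where(carrier, params.f1, params.f0)
        return (rng.random(eta.shape) < expit(f + eta)).astype(np.int8)
    lam = np.where(carrier, params.lam1, params.lam0)
    eps = rng.normal(0.0, params.sigma_e, size=eta.shape)
    L = eta + eps
    if params.sigma_sib > 0:
        labels = _FIX_SIBSHIP if sibship is None else sibship
        per_sib = rng.normal(0.0, params.sigma_sib,
                             size=eta.shape[:-1] + (labels.max() + 1,))
        L = L + per_sib[..., labels]
    return (L >= lam).astype(np.int8)


def _simulate_family_batch(batch: int, params: TraitModelParams, cfg: SimConfig, rng):
    X = _family_covariates(batch, rng)
    u = params.sigma_a * (rng.standard_normal((batch, 16)) @ _FIX_CHOL_A.T)
    g1, g2 = _gene_drop_multi(_FIX_PED, cfg.maf_causal, rng, size=batch)
    carrier = (g1 >= 1) & (g2 >= 1)
    Y = simulate_trait(X, u, carrier, params, rng)
    return X, Y, g1, g2


def ascertain(cfg: SimConfig, params: TraitModelParams, rng, max_draws: int = 10**6):
    """Rejection-sample families until ``cfg.n_families`` have >= min_affected cases.

    Returns (X (nfam,16,5), Y (nfam,16), G_causal (2,nfam,16), n_drawn).
    Batch sizes adapt to the observed acceptance rate.  Unrelated
    individuals are handled separately by :func:`simulate_sample`.
    """
    need = cfg.n_families
    got_X, got_Y, got_g1, got_g2 = [], [], [], []
    drawn = 0
    accepted = 0
    batch = max(24 * need, 256)
    while need > 0:
        if drawn > max_draws:
            raise RuntimeError(
                f"ascertainment unattainable: {drawn} families drawn, "
                f"{accepted} accepted"
            )
        X, Y, g1, g2 = _simulate_family_batch(batch, params, cfg, rng)
        drawn += batch
        ok = np.flatnonzero(Y.sum(axis=1) >= cfg.min_affected)[:need]
        if ok.size:
            got_X.append(X[ok]); got_Y.append(Y[ok])
            got_g1.append(g1[ok]); got_g2.append(g2[ok])
            need -= ok.size
            accepted += ok.size
        rate = max(accepted / drawn, 1.0 / drawn)
        batch = int(min(max(1.4 * need / rate, 256), 50_000))
    X = np.concatenate(got_X); Y = np.concatenate(got_Y)
    G = np.stack([np.concatenate(got_g1), np.concatenate(got_g2)])
    return X, Y, G, drawn


def _simulate_unrelateds(cfg: SimConfig, params: TraitModelParams, rng):
    """Unrelated singletons; setting B enforces an exact 1:1 case-control ratio."""
    m = cfg.n_unrelated
    if cfg.ascertainment == "A":
        X = _population_covariates(m, rng)
        u = rng.normal(0.0, params.sigma_a, size=m)
        g1 = (rng.random((m, 2)) < cfg.maf_causal[0]).sum(axis=1)
        g2 = (rng.random((m, 2)) < cfg.maf_causal[1]).sum(axis=1)
        carrier = (g1 >= 1) & (g2 >= 1)
        sib = np.arange(m) if params.sigma_sib > 0 else None
        Y = simulate_trait(X, u, carrier, params, rng, sibship=sib)
        return X, Y, np.stack([g1, g2])
    if cfg.ascertainment != "B":
        raise ValueError(f"unknown ascertainment setting {cfg.ascertainment!r}")
    need_case, need_ctrl = m // 2, m - m // 2
    Xs, Ys, g1s, g2s = [], [], [], []
    while need_case > 0 or need_ctrl > 0:
        b = 4 * (need_case + need_ctrl) + 64
        X = _population_covariates(b, rng)
        u = rng.normal(0.0, params.sigma_a, size=b)
        g1 = (rng.random((b, 2)) < cfg.maf_causal[0]).sum(axis=1)
        g2 = (rng.random((b, 2)) < cfg.maf_causal[1]).sum(axis=1)
        carrier = (g1 >= 1) & (g2 >= 1)
        sib = np.arange(b) if params.sigma_sib > 0 else None
        Y = simulate_trait(X, u, carrier, params, rng, sibship=sib)
        cases = np.flatnonzero(Y == 1)[:need_case]
        ctrls = np.flatnonzero(Y == 0)[:need_ctrl]
        keep = np.concatenate([cases, ctrls])
        Xs.append(X[keep]); Ys.append(Y[keep])
        g1s.append(g1[keep]); g2s.append(g2[keep])
        need_case -= cases.size
        need_ctrl -= ctrls.size
    return (np.concatenate(Xs), np.concatenate(Ys),
            np.stack([np.concatenate(g1s), np.concatenate(g2s)]))


def apply_missingness(Y_fam: np.ndarray, rng, cfg: SimConfig):
    """Family-member missingness masks.

    Phenotype and covariates are jointly present with probability .8.  A
    genotype is present iff the member is phenotyped and affected, or at
    least half of their phenotyped first-degree relatives are affected
    (vacuously false with no phenotyped first-degree relatives).
    Returns (pheno_present, geno_present), each (nfam, 16) boolean.
    """
    pheno = rng.random(Y_fam.shape) < cfg.pheno_present_prob
    aff_ph = pheno & (Y_fam == 1)
    n_ph = pheno.astype(float) @ _FIX_FD.T
    n_aff = aff_ph.astype(float) @ _FIX_FD.T
    cond2 = (n_ph > 0) & (2.0 * n_aff >= n_ph)
    return pheno, aff_ph | cond2


def _study_kinship(cfg: SimConfig) -> KinshipMatrix:
    n = 16 * cfg.n_families + cfg.n_unrelated
    raw = [
        (np.arange(16 * f, 16 * (f + 1)), _FIX_PHI) for f in range(cfg.n_families)
    ] + [
        (np.array([16 * cfg.n_families + j]), np.array([[1.0]]))
        for j in range(cfg.n_unrelated)
    ]
    return KinshipMatrix.from_blocks(n, raw)


def simulate_sample(cfg: SimConfig, params: TraitModelParams, rng):
    """One ascertained replicate sample.

    Returns ``(data, diagnostics)`` where ``data`` is a
    :class:`~ceramic.data_model.SampleData` whose single genotype row is the
    tested SNP (a freshly dropped unlinked null SNP, or one of the causal
    SNPs in power mode) with missingness already applied, and whose
    phenotype/covariates carry the missingness pattern.
    """
    Xf, Yf, Gf, drawn = ascertain(cfg, params, rng)
    Xu, Yu, Gu = _simulate_unrelateds(cfg, params, rng)
    nf, m = 16 * cfg.n_families, cfg.n_unrelated
    n = nf + m

    if cfg.tested_snp == "null":
        gt_f = gene_drop(_FIX_PED, cfg.maf_test, rng, size=cfg.n_families)
        gt_u = (rng.random((m, 2)) < cfg.maf_test).sum(axis=1)
    else:
        which = {"causal1": 0, "causal2": 1}[cfg.tested_snp]
        gt_f, gt_u = Gf[which], Gu[which]

    Y = np.concatenate([Yf.reshape(-1), Yu]).astype(float)
    X = np.concatenate([Xf.reshape(-1, 5), Xu])
    G = np.concatenate([np.asarray(gt_f, float).reshape(-1),
                        np.asarray(gt_u, float)])

    if cfg.missingness:
        pheno_f, geno_f = apply_missingness(Yf, rng, cfg)
        pheno = np.concatenate([pheno_f.reshape(-1), np.zeros(m, dtype=bool)])
        geno = np.concatenate([geno_f.reshape(-1), np.ones(m, dtype=bool)])
    else:
        pheno = np.ones(n, dtype=bool)
        geno = np.ones(n, dtype=bool)
    Y = np.where(pheno, Y, np.nan)
    X = np.where(pheno[:, None], X, np.nan)
    G = np.where(geno, G, np.nan)
    data = SampleData(Y=Y, X=X, G=G[None, :],
                      snps=pd.DataFrame({"SNP": ["tested"], "CHR": ["0"],
                                         "POS": ["0"]}))
    return data, {"families_drawn": drawn}


# ---------------------------------------------------------------------------
# replicate studies
# ---------------------------------------------------------------------------

def _analyze_replicate(data: SampleData, K: KinshipMatrix, analysis: Analysis):
    """P-values of the requested methods for one analysis of one replicate."""
    if analysis.subset == "MX":
        keep = np.flatnonzero(
            ~np.isnan(data.Y)
            & ~np.isnan(data.X).any(axis=1)
            & ~np.isnan(data.G[0])
        )
        data = data.restrict(keep)
        K = K.restrict(keep)
        K._spectra_cache = {}
    if not analysis.covariates_in_model:
        X = np.where(np.isnan(data.Y)[:, None], np.nan, 1.0)
        data = SampleData(Y=data.Y, X=X, G=data.G, snps=data.snps)
    part = partition_missingness(data, K, 0)
    G_R = data.G[0, part.R]
    Y_W, X_W = data.Y[part.W], data.X[part.W]
    sigma2 = _sigma_check_from_sample(data, part, K, 0)
    out = {}
    fit = None
    for method in analysis.methods:
        if method == "ceramic":
            if fit is None:
                from .association import _phi_spectra

                fit = fit_null(Y_W, X_W, _phi_spectra(K, part.W), subset=part.W)
            res = ceramic_missing(fit, G_R, part, K, sigma2=sigma2)
        elif method == "mqls-log":
            res = mqls_log(Y_W, X_W, G_R, part, K, sigma2=sigma2)
        elif method == "mqls-lin":
            res = mqls_lin(Y_W, X_W, G_R, part, K, sigma2=sigma2)
        else:
            raise ValueError(f"unknown method {method!r}")
        out[method] = res
    return out


def run_study(
    cfg: SimConfig,
    analyses: tuple[Analysis, ...] = (Analysis(),),
    replicates: int = 1000,
    seed: int = 0,
    levels: tuple[float, ...] = (0.05, 0.001),
) -> pd.DataFrame:
    """Replicate study estimating rejection rates (type-1 error or power).

    Each replicate simulates one ascertained sample and analyzes it under
    every entry of ``analyses`` (sharing the simulated data across analyses,
    as when comparing subsets or fitted models on identical replicates).
    Returns a tidy frame with one row per analysis x method x level,
    including exact (Clopper-Pearson) 95% confidence intervals.  Per-replicate
    failures are excluded and counted.
    """
    params = calibrate_penetrance(cfg)
    K = _study_kinship(cfg)
    counts: dict[tuple[str, str, float], int] = {}
    totals: dict[tuple[str, str], int] = {}
    failures = 0
    for rep in range(replicates):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        data, _ = simulate_sample(cfg, params, rng)
        K._spectra_cache = {}  # restricted spectra are shared within a replicate
        for analysis in analyses:
            try:
                results = _analyze_replicate(data, K, analysis)
            except (ConvergenceError, ValueError, np.linalg.LinAlgError):
                failures += 1
                continue
            for method, res in results.items():
                if res.flag != "ok" or not np.isfinite(res.p_value):
                    failures += 1
                    continue
                totals[(analysis.name, method)] = totals.get(
                    (analysis.name, method), 0) + 1
                for lvl in levels:
                    key = (analysis.name, method, lvl)
                    counts[key] = counts.get(key, 0) + int(res.p_value < lvl)
    rows = []
    for (name, method, lvl), rej in sorted(counts.items()):
        tot = totals[(name, method)]
        lo = beta_dist.ppf(0.025, rej, tot - rej + 1) if rej > 0 else 0.0
        hi = beta_dist.ppf(0.975, rej + 1, tot - rej) if rej < tot else 1.0
        rows.append({
            "analysis": name, "method": method, "level": lvl,
            "rejections": rej, "replicates": tot, "rate": rej / tot,
            "ci_low": float(lo), "ci_high": float(hi),
            "failures": failures,
        })
    return pd.DataFrame(rows)


def population_prevalence(
    cfg: SimConfig, n_draws: int = 1_000_000, seed: int = 0
) -> float:
    """Mean phenotype over independent population draws (no ascertainment)."""
    params = calibrate_penetrance(cfg)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2**20]))
    X = _population_covariates(n_draws, rng)
    u = rng.normal(0.0, params.sigma_a, size=n_draws)
    g1 = (rng.random((n_draws, 2)) < cfg.maf_causal[0]).sum(axis=1)
    g2 = (rng.random((n_draws, 2)) < cfg.maf_causal[1]).sum(axis=1)
    carrier = (g1 >= 1) & (g2 >= 1)
    sib = np.arange(n_draws) if params.sigma_sib > 0 else None
    Y = simulate_trait(X, u, carrier, params, rng, sibship=sib)
    return float(Y.mean())
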