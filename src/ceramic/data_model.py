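"""Sample assembly and the per-variant missing-data partition.

The retrospective test distinguishes several nested subsets of the sample at
each tested variant:

- ``N``: all retained individuals;
- ``R``: individuals with observed genotype (``r = |R|``);
- ``U``: genotyped with complete phenotype and covariates;
- ``V = R \\ U``: genotyped but missing phenotype or some covariate
  (e.g. "controls of unknown phenotype");
- ``S``: ungenotyped individuals with complete phenotype/covariates who can
  still contribute through relatives (see :func:`partition_missingness`);
- ``W = U ∪ S``: everyone with complete phenotype and covariates;
- ``Q``: genotyped with complete covariates, phenotype not required
  (``U ⊂ Q ⊂ R``) — the subset on which the genotypic variance is estimated.

Ungenotyped individuals who fail the eligibility conditions carry no
information for the test and are pruned from ``N`` for that variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import KinshipMatrix, Pedigree

__all__ = [
    "SampleData",
    "MissingnessPartition",
    "NoInformativeIndividuals",
    "load_sample",
    "partition_missingness",
    "genotyped_unknown_phenotype_controls",
    "PartitionCache",
]

_REL_TOL = 1e-12  # 2*phi below this is "unrelated"


class NoInformativeIndividuals(ValueError):
    """No individual contributes both phenotype-side and genotype-side information."""


@dataclass
class SampleData:
    """Phenotype, covariates and genotypes aligned to a pedigree ordering.

    Missing values are ``nan``.  ``Y`` is 0/1, ``G`` rows are per-SNP vectors
    of minor-allele counts 0/1/2, ``X`` always has an intercept first column
    (ones wherever the covariate row is otherwise complete).
    """

    Y: np.ndarray  # (n,)
    X: np.ndarray  # (n, k)
    G: np.ndarray  # (m, n): one row per SNP
    snps: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["SNP", "CHR", "POS"])
    )
    ids: list[tuple[str, str]] = field(default_factory=list)

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def k(self) -> int:
        return self.X.shape[1]

    @property
    def n_snps(self) -> int:
        return self.G.shape[0]

    def complete_pheno_cov(self) -> np.ndarray:
        return ~np.isnan(self.Y) & ~np.isnan(self.X).any(axis=1)

    def complete_cov(self) -> np.ndarray:
        return ~np.isnan(self.X).any(axis=1)

    def restrict(self, idx) -> "SampleData":
        idx = np.asarray(idx, dtype=np.int64)
        return SampleData(
            Y=self.Y[idx],
            X=self.X[idx],
            G=self.G[:, idx],
            snps=self.snps,
            ids=[self.ids[i] for i in idx] if self.ids else [],
        )


@dataclass(frozen=True)
class MissingnessPartition:
    N: np.ndarray
    R: np.ndarray
    U: np.ndarray
    V: np.ndarray
    S: np.ndarray
    W: np.ndarray
    Q: np.ndarray

    @property
    def n(self) -> int:
        return self.N.size

    @property
    def r(self) -> int:
        return self.R.size

    @property
    def u(self) -> int:
        return self.U.size

    @property
    def v(self) -> int:
        return self.V.size

    @property
    def s(self) -> int:
        return self.S.size

    @property
    def w(self) -> int:
        return self.W.size

    @property
    def q(self) -> int:
        return self.Q.size

    @property
    def is_complete(self) -> bool:
        return self.s == 0 and self.v == 0


def load_sample(
    ped: Pedigree,
    pheno_path,
    geno_path,
    missing_codes: tuple[str, ...] = ("NA", "-9", "."),
) -> SampleData:
    """Read a phenotype/covariate TSV and a transposed-text genotype file.

    The phenotype file has a header ``FID IID PHENO <covariate...>`` and is
    whitespace/tab delimited with missing values coded ``NA``.  The genotype
    file has one SNP per row: ``SNP CHR POS`` followed by one 0/1/2 code per
    pedigree individual, in pedigree file order; missing genotypes use any of
    ``missing_codes``.  Pedigree members without a phenotype row get
    all-missing phenotype/covariates.
    """
    pheno = pd.read_csv(pheno_path, sep=r"\s+", dtype={0: str, 1: str})
    cols = list(pheno.columns)
    if len(cols) < 3 or cols[0].upper() != "FID" or cols[1].upper() != "IID":
        raise ValueError(
            f"phenotype file must start with columns FID IID PHENO, got {cols[:3]}"
        )
    n = ped.n
    covnames = cols[3:]
    Y = np.full(n, np.nan)
    X = np.full((n, 1 + len(covnames)), np.nan)
    for rowno, row in pheno.iterrows():
        key = (str(row.iloc[0]), str(row.iloc[1]))
        try:
            i = ped.index_of(*key)
        except KeyError:
            raise ValueError(
                f"phenotype row {rowno}: individual {key} not in pedigree"
            ) from None
        yval = row.iloc[2]
        if not (pd.isna(yval) or str(yval) in missing_codes):
            yf = float(yval)
            if yf not in (0.0, 1.0):
                raise ValueError(
                    f"phenotype row {rowno} ({key[1]}): non-binary phenotype {yval!r}"
                )
            Y[i] = yf
        covs = [
            np.nan if (pd.isna(c) or str(c) in missing_codes) else float(c)
            for c in row.iloc[3:]
        ]
        X[i, 0] = 1.0
        X[i, 1:] = covs
    # intercept defined wherever every covariate is defined
    X[np.isnan(X[:, 1:]).any(axis=1), 0] = np.nan

    snp_rows, gvecs = [], []
    with open(geno_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) != 3 + n:
                raise ValueError(
                    f"{geno_path}:{lineno}: expected {3 + n} columns, got {len(fields)}"
                )
            snp_rows.append(fields[:3])
            g = np.full(n, np.nan)
            for j, tok in enumerate(fields[3:]):
                if tok in missing_codes:
                    continue
                val = float(tok)
                if val not in (0.0, 1.0, 2.0):
                    raise ValueError(
                        f"{geno_path}:{lineno}: genotype {tok!r} outside 0/1/2"
                    )
                g[j] = val
            gvecs.append(g)
    G = np.vstack(gvecs) if gvecs else np.empty((0, n))
    snps = pd.DataFrame(snp_rows, columns=["SNP", "CHR", "POS"])
    return SampleData(
        Y=Y, X=X, G=G, snps=snps, ids=[(ind.fid, ind.iid) for ind in ped.individuals]
    )


def _eligibility_masks(
    K: KinshipMatrix, has_geno: np.ndarray, complete_pc: np.ndarray
):
    """Condition-1 and condition-2 masks for ungenotyped candidates.

    Condition 1: the individual has a genotyped relative (2*phi > 0).
    Condition 2: the individual shares a family with another individual who
    has complete phenotype/covariates and is genotyped or has a genotyped
    relative.
    """
    n = K.n
    geno_rel = np.zeros(n, dtype=bool)
    for idx, mat in K.blocks:
        rel = mat > _REL_TOL
        np.fill_diagonal(rel, False)
        geno_rel[idx] = rel @ has_geno[idx] > 0
    anchor = complete_pc & (has_geno | geno_rel)
    cond2 = np.zeros(n, dtype=bool)
    for idx, _ in K.blocks:
        cnt = int(anchor[idx].sum())
        cond2[idx] = (cnt - anchor[idx].astype(int)) > 0
    return geno_rel, cond2


def partition_missingness(
    data: SampleData, K: KinshipMatrix, snp: int = 0
) -> MissingnessPartition:
    """Compute the N/R/U/V/S/W/Q partition for one tested variant.

    Genotyped individuals are always retained.  An ungenotyped individual is
    retained (in ``S``) only with complete phenotype and covariates and when
    eligibility condition 1 or 2 holds; otherwise it is pruned from ``N`` for
    this variant.  Raises :class:`NoInformativeIndividuals` when both ``U``
    and ``S`` are empty.
    """
    if data.n != K.n:
        raise ValueError("sample and kinship matrix are not aligned")
    g = data.G[snp]
    has_geno = ~np.isnan(g)
    complete_pc = data.complete_pheno_cov()
    cond1, cond2 = _eligibility_masks(K, has_geno, complete_pc)

    in_S = ~has_geno & complete_pc & (cond1 | cond2)
    in_U = has_geno & complete_pc
    keep = has_geno | in_S

    N = np.flatnonzero(keep)
    R = np.flatnonzero(has_geno)
    U = np.flatnonzero(in_U)
    V = np.flatnonzero(has_geno & ~complete_pc)
    S = np.flatnonzero(in_S)
    W = np.flatnonzero(in_U | in_S)
    Q = np.flatnonzero(has_geno & data.complete_cov())
    if U.size == 0 and S.size == 0:
        raise NoInformativeIndividuals(
            f"SNP {snp}: no individual carries phenotype-side information"
        )
    return MissingnessPartition(N=N, R=R, U=U, V=V, S=S, W=W, Q=Q)


def genotyped_unknown_phenotype_controls(
    data: SampleData, K: KinshipMatrix, snp: int = 0
) -> np.ndarray:
    """Individuals usable only through the genotype side: V ∪ (Q \\ U)."""
    part = partition_missingness(data, K, snp)
    return np.union1d(part.V, np.setdiff1d(part.Q, part.U))


class PartitionCache:
    """Memoizes partitions by the variant's genotype-missingness pattern.

    Missingness patterns repeat heavily across a genome scan, so partitions
    (and downstream null fits) can be shared between SNPs with identical
    patterns.
    """

    def __init__(self, data: SampleData, K: KinshipMatrix):
        self.data = data
        self.K = K
        self._store: dict[bytes, MissingnessPartition] = {}
        self.hits = 0
        self.misses = 0

    def get(self, snp: int) -> MissingnessPartition:
        key = np.isnan(self.data.G[snp]).tobytes()
        part = self._store.get(key)
        if part is None:
            self.misses += 1
            part = partition_missingness(self.data, self.K, snp)
            self._store[key] = part
        else:
            self.hits += 1
        return part
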