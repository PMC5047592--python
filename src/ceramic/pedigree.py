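"""Pedigree parsing and pedigree-based kinship computation.

A pedigree is a set of individuals with parent links, grouped into families
by graph connectivity.  From it we compute the kinship matrix whose (i, j)
off-diagonal entry is twice the kinship coefficient, 2*phi_ij, and whose
diagonal entry is 1 + h_i, where h_i is the inbreeding coefficient of
individual i (the kinship of i's parents).  Because cross-family entries are
exactly zero, the matrix is stored block-diagonally: one dense block per
multi-member family plus a coalesced diagonal part for singletons.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Individual",
    "Pedigree",
    "PedigreeError",
    "KinshipMatrix",
    "parse_pedigree",
    "compute_kinship",
    "kinship_submatrix",
]

MALE, FEMALE, UNKNOWN = 1, 2, 0


class PedigreeError(ValueError):
    """Structural problem in a pedigree (cycle, half-specified parents, ...)."""


@dataclass(frozen=True)
class Individual:
    fid: str
    iid: str
    father: str | None  # None for founders
    mother: str | None
    sex: int = UNKNOWN


class Pedigree:
    """Validated pedigree with a stable individual ordering.

    Families are defined by graph connectivity of the parent links; when a
    family id in the input spans several connected components a warning is
    issued and the components are treated as separate families (kinship is
    zero between them regardless).
    """

    def __init__(self, individuals: Sequence[Individual]):
        self.individuals = list(individuals)
        self.n = len(self.individuals)
        self._index: dict[tuple[str, str], int] = {}
        for i, ind in enumerate(self.individuals):
            key = (ind.fid, ind.iid)
            if key in self._index:
                raise PedigreeError(
                    f"duplicate individual id {ind.iid!r} in family {ind.fid!r}"
                )
            self._index[key] = i

        self.father_idx = np.full(self.n, -1, dtype=np.int64)
        self.mother_idx = np.full(self.n, -1, dtype=np.int64)
        for i, ind in enumerate(self.individuals):
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"individual {ind.iid!r} in family {ind.fid!r} has exactly "
                    "one parent specified; founders must have neither"
                )
            if ind.father is not None:
                for which, pid, arr in (
                    ("father", ind.father, self.father_idx),
                    ("mother", ind.mother, self.mother_idx),
                ):
                    key = (ind.fid, pid)
                    if key not in self._index:
                        raise PedigreeError(
                            f"{which} {pid!r} of individual {ind.iid!r} not "
                            f"found in family {ind.fid!r}"
                        )
                    arr[i] = self._index[key]

        self._topo_order = self._toposort()
        self.families = self._family_groups()

    # -- structure ---------------------------------------------------------

    def _toposort(self) -> np.ndarray:
        """Parents-before-children ordering; raises on cycles."""
        n = self.n
        indeg = np.zeros(n, dtype=np.int64)
        children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            for p in (self.father_idx[i], self.mother_idx[i]):
                if p >= 0:
                    children[p].append(i)
                    indeg[i] += 1
        order = [i for i in range(n) if indeg[i] == 0]
        head = 0
        while head < len(order):
            for c in children[order[head]]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
            head += 1
        if len(order) < n:
            stuck = next(i for i in range(n) if indeg[i] > 0)
            ind = self.individuals[stuck]
            raise PedigreeError(
                f"pedigree cycle detected involving individual {ind.iid!r} "
                f"in family {ind.fid!r}"
            )
        return np.asarray(order, dtype=np.int64)

    def _family_groups(self) -> list[np.ndarray]:
        """Individuals grouped by family id.

        A family id may span several unconnected components (e.g. two
        marry-in branches that share no ancestor); kinship between them is
        zero, but they remain one pedigree for the missing-data eligibility
        rules, so the grouping follows the stated id rather than graph
        connectivity.
        """
        groups: dict[str, list[int]] = {}
        for i, ind in enumerate(self.individuals):
            groups.setdefault(ind.fid, []).append(i)
        return [np.asarray(m, dtype=np.int64) for m in groups.values()]

    @property
    def is_founder(self) -> np.ndarray:
        return self.father_idx < 0

    def generation_depth(self) -> np.ndarray:
        """0 for founders, 1 + max(parent depths) otherwise."""
        depth = np.zeros(self.n, dtype=np.int64)
        for i in self._topo_order:
            f, m = self.father_idx[i], self.mother_idx[i]
            if f >= 0:
                depth[i] = 1 + max(depth[f], depth[m])
        return depth

    def __len__(self) -> int:
        return self.n

    def index_of(self, fid: str, iid: str) -> int:
        return self._index[(fid, iid)]


def parse_pedigree(path, dialect: str = "linkage") -> Pedigree:
    """Read a LINKAGE pre-makeped / PLINK .fam style pedigree file.

    Columns: FID IID PAT MAT SEX [PHENO ...], whitespace-delimited, missing
    parent coded "0".  ``dialect`` is accepted for interface clarity; both
    dialects share this column layout.
    """
    if dialect not in ("linkage", "plink-fam"):
        raise ValueError(f"unknown pedigree dialect {dialect!r}")
    inds: list[Individual] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields or fields[0].startswith("#"):
                continue
            if len(fields) < 4:
                raise PedigreeError(
                    f"{path}:{lineno}: expected at least 4 columns, got {len(fields)}"
                )
            fid, iid, pat, mat = fields[:4]
            sex = UNKNOWN
            if len(fields) >= 5:
                sex = {"1": MALE, "2": FEMALE}.get(fields[4], UNKNOWN)
            inds.append(
                Individual(
                    fid=fid,
                    iid=iid,
                    father=None if pat == "0" else pat,
                    mother=None if mat == "0" else mat,
                    sex=sex,
                )
            )
    return Pedigree(inds)


class KinshipMatrix:
    """Block-diagonal pedigree relationship matrix (2*phi off-diagonal, 1+h diagonal).

    ``blocks`` holds (global-index-array, dense-block) pairs for families of
    size >= 2; singleton families are coalesced into ``sing_idx``/``sing_diag``
    so that samples with many unrelated individuals stay cheap to handle.
    """

    def __init__(
        self,
        n: int,
        blocks: list[tuple[np.ndarray, np.ndarray]],
        sing_idx: np.ndarray,
        sing_diag: np.ndarray,
    ):
        self.n = n
        self.blocks = blocks
        self.sing_idx = np.asarray(sing_idx, dtype=np.int64)
        self.sing_diag = np.asarray(sing_diag, dtype=float)

    # -- construction ------------------------------------------------------

    @classmethod
    def from_blocks(cls, n: int, raw: Iterable[tuple[np.ndarray, np.ndarray]]):
        blocks, sidx, sdiag = [], [], []
        for idx, mat in raw:
            idx = np.asarray(idx, dtype=np.int64)
            mat = np.asarray(mat, dtype=float)
            if idx.size == 1:
                sidx.append(int(idx[0]))
                sdiag.append(float(mat.reshape(())))
            else:
                blocks.append((idx, mat))
        return cls(n, blocks, np.asarray(sidx, dtype=np.int64), np.asarray(sdiag))

    # -- dense views -------------------------------------------------------

    def toarray(self) -> np.ndarray:
        out = np.zeros((self.n, self.n))
        for idx, mat in self.blocks:
            out[np.ix_(idx, idx)] = mat
        out[self.sing_idx, self.sing_idx] = self.sing_diag
        return out

    def diagonal(self) -> np.ndarray:
        d = np.zeros(self.n)
        for idx, mat in self.blocks:
            d[idx] = np.diag(mat)
        d[self.sing_idx] = self.sing_diag
        return d

    def submatrix(self, rows, cols) -> np.ndarray:
        """Dense K[rows, cols] in the given row/column order."""
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        if rows.size == 0 or cols.size == 0:
            raise ValueError("empty index set for kinship submatrix")
        rpos = np.full(self.n, -1, dtype=np.int64)
        rpos[rows] = np.arange(rows.size)
        cpos = np.full(self.n, -1, dtype=np.int64)
        cpos[cols] = np.arange(cols.size)
        out = np.zeros((rows.size, cols.size))
        for idx, mat in self.blocks:
            rsel = rpos[idx] >= 0
            csel = cpos[idx] >= 0
            if rsel.any() and csel.any():
                out[np.ix_(rpos[idx[rsel]], cpos[idx[csel]])] = mat[
                    np.ix_(np.flatnonzero(rsel), np.flatnonzero(csel))
                ]
        both_r = rpos[self.sing_idx] >= 0
        both_c = cpos[self.sing_idx] >= 0
        both = both_r & both_c
        out[rpos[self.sing_idx[both]], cpos[self.sing_idx[both]]] = self.sing_diag[both]
        return out

    # -- restriction and products -----------------------------------------

    def restrict(self, idx) -> "KinshipMatrix":
        """Principal submatrix K[idx, idx] as a new block-diagonal matrix.

        Row/column order of the result follows ``idx``.
        """
        idx = np.asarray(idx, dtype=np.int64)
        if idx.size == 0:
            raise ValueError("empty index set for kinship restriction")
        pos = np.full(self.n, -1, dtype=np.int64)
        pos[idx] = np.arange(idx.size)
        blocks = []
        sidx_parts, sdiag_parts = [], []
        for bidx, mat in self.blocks:
            sel = pos[bidx] >= 0
            k = int(sel.sum())
            if k == 0:
                continue
            local = np.flatnonzero(sel)
            new_idx = pos[bidx[sel]]
            if k == 1:
                sidx_parts.append(new_idx)
                sdiag_parts.append(mat[local, local])
            elif k == bidx.size:
                blocks.append((new_idx, mat))
            else:
                blocks.append((new_idx, mat[local][:, local]))
        ssel = pos[self.sing_idx] >= 0
        sidx_parts.append(pos[self.sing_idx[ssel]])
        sdiag_parts.append(self.sing_diag[ssel])
        return KinshipMatrix(
            idx.size,
            blocks,
            np.concatenate(sidx_parts) if sidx_parts else np.empty(0, dtype=np.int64),
            np.concatenate(sdiag_parts) if sdiag_parts else np.empty(0),
        )

    def cross_matmul(self, rows, cols, v: np.ndarray) -> np.ndarray:
        """K[rows, cols] @ v computed block-wise (v aligned with ``cols``)."""
        rows = np.asarray(rows, dtype=np.int64)
        cols = np.asarray(cols, dtype=np.int64)
        v = np.asarray(v, dtype=float)
        rpos = np.full(self.n, -1, dtype=np.int64)
        rpos[rows] = np.arange(rows.size)
        cpos = np.full(self.n, -1, dtype=np.int64)
        cpos[cols] = np.arange(cols.size)
        out_shape = (rows.size,) + v.shape[1:]
        out = np.zeros(out_shape)
        for idx, mat in self.blocks:
            rsel = rpos[idx] >= 0
            csel = cpos[idx] >= 0
            if rsel.any() and csel.any():
                sub = mat[rsel][:, csel]
                out[rpos[idx[rsel]]] += sub @ v[cpos[idx[csel]]]
        both = (rpos[self.sing_idx] >= 0) & (cpos[self.sing_idx] >= 0)
        if both.any():
            si = self.sing_idx[both]
            out[rpos[si]] += (self.sing_diag[both].reshape(
                (-1,) + (1,) * (v.ndim - 1)
            )) * v[cpos[si]]
        return out

    def matmul(self, v: np.ndarray) -> np.ndarray:
        """K @ v computed block-wise."""
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v, dtype=float)
        for idx, mat in self.blocks:
            out[idx] = mat @ v[idx]
        shape = (-1,) + (1,) * (v.ndim - 1)
        out[self.sing_idx] = self.sing_diag.reshape(shape) * v[self.sing_idx]
        return out

    def block_of(self, i: int) -> np.ndarray:
        """Global indices of the family block containing individual i."""
        for idx, _ in self.blocks:
            if i in idx:
                return idx
        return np.asarray([i], dtype=np.int64)


def compute_kinship(ped: Pedigree) -> KinshipMatrix:
    """Kinship matrix of a pedigree by the standard tabular recursion.

    Within each family, individuals are processed parents-first; for
    non-founder j, phi(i, j) = (phi(i, father_j) + phi(i, mother_j)) / 2 for
    every earlier i, and phi(j, j) = (1 + phi(father_j, mother_j)) / 2.
    Founders are taken non-inbred and mutually unrelated.
    """
    topo_rank = np.empty(ped.n, dtype=np.int64)
    topo_rank[ped._topo_order] = np.arange(ped.n)
    raw = []
    for fam in ped.families:
        members = fam[np.argsort(topo_rank[fam])]
        m = members.size
        local = {int(g): j for j, g in enumerate(members)}
        F = np.zeros((m, m))
        for j, g in enumerate(members):
            f, mo = int(ped.father_idx[g]), int(ped.mother_idx[g])
            if f < 0:
                F[j, j] = 0.5
            else:
                lf, lm = local[f], local[mo]
                F[j, j] = 0.5 + 0.5 * F[lf, lm]
                F[:j, j] = 0.5 * (F[:j, lf] + F[:j, lm])
                F[j, :j] = F[:j, j]
        order = np.argsort(members)  # store blocks in ascending global order
        raw.append((members[order], 2.0 * F[np.ix_(order, order)]))
    return KinshipMatrix.from_blocks(ped.n, raw)


def kinship_submatrix(K: KinshipMatrix, rows, cols) -> np.ndarray:
    """Dense sub-block K[rows, cols]; errors on empty index sets."""
    return K.submatrix(rows, cols)
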