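"""Quasi-likelihood null model for a binary trait with polygenic correlation.

The trait model specifies only the first two conditional moments:

    E(Y_i | X) = mu_i,   logit(mu_i) = X_i' beta          (null: no SNP term)
    Var(Y | X) = Gamma^{1/2} Sigma Gamma^{1/2},  Sigma = xi*Phi + (1-xi)*I

with Gamma = diag(mu_i (1 - mu_i)), Phi the pedigree kinship matrix and
0 <= xi <= 1 the share of (standardized) trait variance attributed to
additive polygenic effects.  The estimating equations are

    beta:  X' Gamma^{1/2} Sigma^{-1} Gamma^{-1/2} (Y - mu) = 0
    xi:    (Y-mu)' Gamma^{-1/2} Sigma^{-1} (Phi - I) Sigma^{-1}
              Gamma^{-1/2} (Y-mu) = trace(Sigma^{-1} (Phi - I))

solved by alternating damped quasi-Fisher scoring in beta with bracketed
scalar root finding in xi.  All Sigma^{-1} products use a single spectral
decomposition Phi = A J A' per family block, so that
Sigma^{-1} = A (xi*J + (1-xi) I)^{-1} A'.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .pedigree import KinshipMatrix

__all__ = [
    "BlockSpectra",
    "NullFit",
    "FullFit",
    "ConvergenceError",
    "sigma_inverse_apply",
    "solve_beta",
    "solve_xi",
    "fit_null",
    "fit_full",
]

_MU_CLAMP = 1e-10
_SING_TOL = 1e-12


class ConvergenceError(RuntimeError):
    pass


class BlockSpectra:
    """Per-family spectral decompositions Phi = A J A'.

    Multi-member blocks are zero-padded to a common size (the padding is an
    identity block, whose unit eigenvalues contribute nothing to any
    function-of-Phi product applied to zero-padded vectors), so that every
    solve reduces to two batched einsum products; singleton blocks are kept
    as a coalesced diagonal.  This keeps replicate-heavy simulation studies
    cheap without restricting pedigree structure.
    """

    def __init__(self, K: KinshipMatrix):
        self.n = K.n
        self.sing_idx = K.sing_idx
        self.sing_vals = K.sing_diag
        if K.blocks:
            g = len(K.blocks)
            M = max(idx.size for idx, _ in K.blocks)
            mats = np.zeros((g, M, M))
            # padded slots gather from / scatter to a dummy row (index n)
            idx = np.full((g, M), self.n, dtype=np.int64)
            pad_eye = np.eye(M)
            for b, (bidx, mat) in enumerate(K.blocks):
                m = bidx.size
                mats[b] = pad_eye
                mats[b, :m, :m] = mat
                idx[b, :m] = bidx
            vals, vecs = np.linalg.eigh(mats)
            self.idx, self.vals, self.vecs = idx, vals, vecs
            self.vecs_T = np.ascontiguousarray(vecs.transpose(0, 2, 1))
            self.flat_idx = idx.reshape(-1)
        else:
            self.idx = None
            self.vals = self.vecs = self.vecs_T = self.flat_idx = None
        self.min_eig = min(
            (float(self.vals.min()) if self.vals is not None else 1.0),
            (float(self.sing_vals.min()) if self.sing_vals.size else 1.0),
        )

    def _check(self, w: np.ndarray, xi: float):
        if w.size and w.min() <= _SING_TOL:
            raise np.linalg.LinAlgError(
                f"Sigma singular at xi={xi}: eigenvalue {w.min():.3e}"
            )

    def sigma_solve(self, xi: float, V: np.ndarray) -> np.ndarray:
        """(xi*Phi + (1-xi)*I)^{-1} V, block-wise."""
        V = np.asarray(V, dtype=float)
        vec_in = V.ndim == 1
        V2 = V[:, None] if vec_in else V
        out = np.zeros((self.n + 1,) + V2.shape[1:])
        Vx = np.concatenate([V2, np.zeros((1,) + V2.shape[1:])])
        if self.idx is not None:
            w = xi * self.vals + (1.0 - xi)
            self._check(w, xi)
            sub = Vx[self.idx]  # (g, M, k)
            e = self.vecs_T @ sub
            e /= w[:, :, None]
            out[self.flat_idx] = (self.vecs @ e).reshape(-1, V2.shape[1])
        if self.sing_idx.size:
            sw = xi * self.sing_vals + (1.0 - xi)
            self._check(sw, xi)
            out[self.sing_idx] = V2[self.sing_idx] / sw[:, None]
        out = out[:-1]
        return out[:, 0] if vec_in else out

    def phi_solve(self, V: np.ndarray) -> np.ndarray:
        return self.sigma_solve(1.0, V)

    def xi_gap_function(self, r: np.ndarray):
        """Returns g(xi) = quadratic form minus trace for residual r = Gamma^{-1/2}(Y-mu).

        With e = A' r per block, both sides are sums over eigenvalues d:
        sum e^2 (d-1)/(xi d + 1 - xi)^2  -  sum (d-1)/(xi d + 1 - xi).
        Padded dimensions have d = 1 and contribute to neither term.
        """
        e2_parts, d_parts = [], []
        if self.idx is not None:
            rx = np.concatenate([r, [0.0]])
            e = (self.vecs_T @ rx[self.idx][:, :, None])[:, :, 0]
            e2_parts.append(np.square(e).ravel())
            d_parts.append(self.vals.ravel())
        if self.sing_idx.size:
            e2_parts.append(np.square(r[self.sing_idx]))
            d_parts.append(self.sing_vals)
        e2 = np.concatenate(e2_parts) if e2_parts else np.empty(0)
        d = np.concatenate(d_parts) if d_parts else np.empty(0)
        dm1 = d - 1.0

        def gap(xi: float) -> float:
            w = xi * d + (1.0 - xi)
            return float(np.sum(e2 * dm1 / (w * w)) - np.sum(dm1 / w))

        return gap


def sigma_inverse_apply(spectra: BlockSpectra, xi: float, v: np.ndarray) -> np.ndarray:
    """(xi*Phi + (1-xi)*I)^{-1} v via the cached block spectra."""
    if not 0.0 <= xi <= 1.0:
        raise ValueError(f"xi must be in [0, 1], got {xi}")
    return spectra.sigma_solve(xi, v)


def _mu(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return np.clip(expit(X @ beta), _MU_CLAMP, 1.0 - _MU_CLAMP)


def _score(Y, X, spectra, xi, beta):
    """Estimating function for beta and the scoring matrix at (beta, xi)."""
    mu = _mu(X, beta)
    d = np.sqrt(mu * (1.0 - mu))
    resid = (Y - mu) / d
    DX = X * d[:, None]
    sol = spectra.sigma_solve(xi, np.column_stack([resid, DX]))
    score = DX.T @ sol[:, 0]
    info = DX.T @ sol[:, 1:]
    return score, info, mu


def solve_beta(
    Y: np.ndarray,
    X: np.ndarray,
    spectra: BlockSpectra,
    xi: float,
    beta_init: np.ndarray | None = None,
    tol: float = 1e-11,
    max_iter: int = 50,
) -> np.ndarray:
    """Solve the beta estimating equation at fixed xi by damped quasi-Fisher scoring.

    The system is solved in a column-scaled basis (each covariate divided by
    its root mean square) so that the convergence tolerance on the
    estimating function is meaningful regardless of covariate units.
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.min() == Y.max():
        # no interior solution: the logit drifts to +/- infinity
        raise ConvergenceError("phenotype is constant on the fitted subset")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    scale = np.sqrt(np.mean(np.square(X), axis=0))
    scale[scale == 0] = 1.0
    Xs = X / scale
    beta = (np.zeros(X.shape[1]) if beta_init is None
            else np.array(beta_init, dtype=float) * scale)
    score, info, _ = _score(Y, Xs, spectra, xi, beta)
    norm = np.abs(score).max()
    for _ in range(max_iter):
        if norm < tol:
            return beta / scale
        step = np.linalg.solve(info, score)
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            s2, i2, _ = _score(Y, Xs, spectra, xi, cand)
            n2 = np.abs(s2).max()
            if n2 < norm or n2 < tol:
                beta, score, info, norm = cand, s2, i2, n2
                break
            lam *= 0.5
        else:
            raise ConvergenceError(
                f"beta step failed to reduce score (|score|={norm:.3e}); "
                "possible separation or degenerate phenotype"
            )
    raise ConvergenceError(
        f"beta scoring did not converge in {max_iter} iterations (|score|={norm:.3e})"
    )


def solve_xi(
    Y: np.ndarray,
    X: np.ndarray,
    spectra: BlockSpectra,
    beta: np.ndarray,
) -> float:
    """Solve the variance-component estimating equation at fixed beta.

    Returns the bracketed root of the moment gap on [0, 1]; when the gap has
    no sign change the boundary with the smaller absolute gap is returned.
    """
    mu = _mu(X, beta)
    d = np.sqrt(mu * (1.0 - mu))
    r = (Y - mu) / d
    gap = spectra.xi_gap_function(r)
    ub = 1.0 if spectra.min_eig > _SING_TOL else 1.0 - 1e-8
    g0, g1 = gap(0.0), gap(ub)
    if g0 == 0.0 and g1 == 0.0:
        return 0.0  # Phi = I: the equation is vacuous
    if g0 * g1 < 0:
        return float(brentq(gap, 0.0, ub, xtol=1e-10))
    return 0.0 if abs(g0) <= abs(g1) else ub


@dataclass
class NullFit:
    beta0: np.ndarray
    xi0: float
    mu0: np.ndarray
    Z: np.ndarray
    converged: bool
    iterations: int
    spectra: BlockSpectra
    subset: np.ndarray | None = None

    @property
    def gamma_diag(self) -> np.ndarray:
        return self.mu0 * (1.0 - self.mu0)


@dataclass
class FullFit:
    gamma: float
    beta: np.ndarray
    xi: float
    cov: np.ndarray
    converged: bool
    iterations: int

    @property
    def standard_errors(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))


def _transformed_residuals(Y, X, spectra, xi, beta):
    """Z = Gamma^{1/2} Sigma^{-1} Gamma^{-1/2} (Y - mu)."""
    mu = _mu(X, beta)
    d = np.sqrt(mu * (1.0 - mu))
    return d * spectra.sigma_solve(xi, (Y - mu) / d), mu


def fit_null(
    Y: np.ndarray,
    X: np.ndarray,
    spectra: BlockSpectra,
    xi_fixed: float | None = None,
    tol: float = 1e-6,
    max_outer: int = 100,
    subset: np.ndarray | None = None,
) -> NullFit:
    """Fit (beta, xi) under the null by alternating the two estimating equations.

    ``xi_fixed`` pins the variance component (once-per-genome mode: estimate
    xi on a fixed subset, then re-solve only beta per variant).
    """
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    if Y.min() == Y.max():
        raise ValueError("phenotype subset is all-case or all-control; cannot fit")
    beta = solve_beta(Y, X, spectra, xi=0.0)  # ordinary logistic warm start
    xi = 0.5 if xi_fixed is None else float(xi_fixed)
    converged = False
    iterations = 0
    for iterations in range(1, max_outer + 1):
        xi_new = xi if xi_fixed is not None else solve_xi(Y, X, spectra, beta)
        beta_new = solve_beta(Y, X, spectra, xi_new, beta_init=beta)
        delta = max(np.abs(beta_new - beta).max(), abs(xi_new - xi))
        beta, xi = beta_new, xi_new
        if delta < tol:
            converged = True
            break
        if xi_fixed is not None and iterations >= 1:
            # with xi pinned a single beta solve is exact
            converged = True
            break
    Z, mu = _transformed_residuals(Y, X, spectra, xi, beta)
    return NullFit(
        beta0=beta,
        xi0=float(xi),
        mu0=mu,
        Z=Z,
        converged=converged,
        iterations=iterations,
        spectra=spectra,
        subset=subset,
    )


def fit_full(
    Y: np.ndarray,
    X: np.ndarray,
    G: np.ndarray,
    spectra: BlockSpectra,
    tol: float = 1e-6,
    max_outer: int = 100,
) -> FullFit:
    """Joint estimation of (gamma, beta, xi) with its asymptotic covariance.

    Solves the three-equation system with design (G, X); the covariance of
    (gamma, beta) is (Xt' Gamma^{1/2} Sigma^{-1} Gamma^{1/2} Xt)^{-1} at the
    estimate.  No standard error is produced for xi: that would require
    third- and fourth-moment assumptions beyond the quasi-likelihood model.
    """
    G = np.asarray(G, dtype=float)
    if G.min() == G.max():
        raise ValueError("genotype is constant; gamma is not identifiable")
    Xt = np.column_stack([G, X])
    if np.linalg.matrix_rank(Xt) < Xt.shape[1]:
        raise np.linalg.LinAlgError("genotype is collinear with the covariates")
    beta_t = solve_beta(Y, Xt, spectra, xi=0.0)
    xi = 0.5
    converged = False
    iterations = 0
    for iterations in range(1, max_outer + 1):
        xi_new = solve_xi(Y, Xt, spectra, beta_t)
        beta_new = solve_beta(Y, Xt, spectra, xi_new, beta_init=beta_t)
        delta = max(np.abs(beta_new - beta_t).max(), abs(xi_new - xi))
        beta_t, xi = beta_new, xi_new
        if delta < tol:
            converged = True
            break
    mu = _mu(Xt, beta_t)
    d = np.sqrt(mu * (1.0 - mu))
    DXt = Xt * d[:, None]
    cov = np.linalg.inv(DXt.T @ spectra.sigma_solve(xi, DXt))
    return FullFit(
        gamma=float(beta_t[0]),
        beta=beta_t[1:],
        xi=float(xi),
        cov=cov,
        converged=converged,
        iterations=iterations,
    )
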