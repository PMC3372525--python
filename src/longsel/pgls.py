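"""Phylogenetic generalized least squares under Brownian motion.

Under Brownian trait evolution on a rooted time tree, the covariance of
the residuals of two species is proportional to their shared history: the
root-to-MRCA path length.  PGLS is then ordinary GLS with that covariance:

    beta_hat = (X' V^-1 X)^-1 X' V^-1 y,   V_ij = lambda * t_MRCA(i,j)

with Pagel's lambda multiplying the off-diagonal only (lambda = 1, full
phylogenetic signal, is the default throughout).  The solve goes through a
Cholesky whitening of V rather than an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.stats import t as t_dist

from .core import ColumnFit, LongselError, PhylogeneticTree, TraitTable
from .scoring import ScoredColumn

#: Relative rank / variance tolerance for degenerate-fit detection.
_EPS = 1e-12


@dataclass
class BrownianCovariance:
    """Shared-history covariance for a species list on a time tree."""

    species: list[str]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        if not np.allclose(self.matrix, self.matrix.T):
            raise LongselError("covariance not symmetric")


def brownian_covariance(
    tree: PhylogeneticTree, species: list[str], lam: float = 1.0
) -> BrownianCovariance:
    """V_ij = lam * depth of MRCA(i, j); V_ii = depth of tip i.

    Depths are measured from the original root, so pruning a species is
    exactly deleting its row and column.
    """
    if tree.kind != "time":
        raise LongselError("Brownian covariance needs a time-scaled tree")
    if len(species) < 2:
        raise LongselError("need at least two species")
    if not 0.0 <= lam <= 1.0:
        raise LongselError(f"lambda must be in [0,1], got {lam}")
    V = tree.mrca_depths(list(species))
    if lam != 1.0:
        off = ~np.eye(len(species), dtype=bool)
        V = V.copy()
        V[off] *= lam
    return BrownianCovariance(list(species), V, lam)


@dataclass
class GlsFit:
    """A fitted two-predictor GLS: intercept, MLS slope, mass slope."""

    coef: np.ndarray        # (intercept, b_mls, b_mass)
    se: np.ndarray
    tstat: np.ndarray
    pvalues: np.ndarray     # two-sided
    n: int
    df: int
    sigma2: float
    degenerate: bool = False

    @property
    def b_mls(self) -> float:
        return float(self.coef[1])

    @property
    def p_mls(self) -> float:
        return float(self.pvalues[1])

    @property
    def b_mass(self) -> float:
        return float(self.coef[2])

    @property
    def p_mass(self) -> float:
        return float(self.pvalues[2])


def _degenerate(n: int) -> GlsFit:
    z = np.zeros(3)
    return GlsFit(coef=z, se=z.copy(), tstat=z.copy(), pvalues=np.ones(3),
                  n=n, df=max(n - 3, 0), sigma2=0.0, degenerate=True)


def gls_fit(y: np.ndarray, X: np.ndarray, cov: BrownianCovariance) -> GlsFit:
    """Fit y = a + b1*x1 + b2*x2 with error covariance sigma2 * V.

    ``X`` holds the two predictor columns (no intercept).  Implemented by
    Cholesky whitening: with V = L L', regress L^-1 y on L^-1 [1 X] by OLS.
    Degenerate designs (constant response or collinear predictors) return
    a flagged fit with zero slopes and p = 1 rather than erroring.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = y.shape[0]
    if X.shape != (n, 2):
        raise LongselError(f"X must be (n, 2), got {X.shape}")
    if cov.matrix.shape != (n, n):
        raise LongselError("covariance dimension mismatch")
    if n < 4:
        return _degenerate(n)
    try:
        L = np.linalg.cholesky(cov.matrix)
    except np.linalg.LinAlgError as exc:
        raise LongselError("covariance not positive definite") from exc
    Z = np.column_stack([np.ones(n), X])
    Wz = solve_triangular(L, Z, lower=True)
    wy = solve_triangular(L, y, lower=True)
    # rank check on the whitened design
    s = np.linalg.svd(Wz, compute_uv=False)
    if s[-1] <= _EPS * s[0]:
        return _degenerate(n)
    beta, _, _, _ = np.linalg.lstsq(Wz, wy, rcond=None)
    resid = wy - Wz @ beta
    rss = float(resid @ resid)
    df = n - 3
    sigma2 = rss / df
    scale = float(wy @ wy)
    if sigma2 <= _EPS * max(scale / n, 1.0):
        # Exact fit: no residual variance to test against.  Coefficients are
        # still exact; a zero coefficient (e.g. constant response) stays
        # untestable at p = 1, a nonzero one is recovered with p = 0.
        tol = 1e-8 * max(1.0, float(np.max(np.abs(beta))))
        nonzero = np.abs(beta) > tol
        beta = np.where(nonzero, beta, 0.0)
        pvals = np.where(nonzero, 0.0, 1.0)
        return GlsFit(coef=beta, se=np.zeros(3),
                      tstat=np.where(nonzero, np.inf, 0.0), pvalues=pvals,
                      n=n, df=df, sigma2=0.0, degenerate=True)
    XtX_inv = np.linalg.inv(Wz.T @ Wz)
    se = np.sqrt(np.diag(XtX_inv) * sigma2)
    tstat = beta / se
    pvals = 2.0 * t_dist.sf(np.abs(tstat), df)
    return GlsFit(coef=beta, se=se, tstat=tstat, pvalues=pvals,
                  n=n, df=df, sigma2=sigma2)


def gls_fit_dense(y: np.ndarray, X: np.ndarray, cov: BrownianCovariance) -> GlsFit:
    """Textbook GLS via explicit V^-1 normal equations (cross-check path)."""
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    Z = np.column_stack([np.ones(n), np.asarray(X, dtype=float)])
    Vinv = np.linalg.inv(cov.matrix)
    A = Z.T @ Vinv @ Z
    beta = np.linalg.solve(A, Z.T @ Vinv @ y)
    resid = y - Z @ beta
    df = n - 3
    sigma2 = float(resid @ Vinv @ resid) / df
    se = np.sqrt(np.diag(np.linalg.inv(A)) * sigma2)
    tstat = beta / se
    pvals = 2.0 * t_dist.sf(np.abs(tstat), df)
    return GlsFit(coef=beta, se=se, tstat=tstat, pvalues=pvals,
                  n=n, df=df, sigma2=sigma2)


def fit_column(
    scored: ScoredColumn,
    traits: TraitTable,
    tree: PhylogeneticTree,
    lam: float = 1.0,
    log_traits: bool = True,
    min_species: int = 4,
    cov: BrownianCovariance | None = None,
) -> ColumnFit:
    """PGLS of a column's similarity scores on lifespan and mass.

    The species fitted are the non-reference species with a score, traits,
    and a tree tip.  The reference never contributes a data point.  A
    precomputed covariance for exactly these species may be passed to skip
    the tree traversal.
    """
    tips = set(tree.tip_labels())
    species = sorted(
        sp for sp in scored.scores
        if sp in traits.data.index and sp in tips and sp != traits.reference
    )
    n = len(species)
    if n < min_species:
        return ColumnFit(0.0, 1.0, 0.0, 1.0, n=n, degenerate=True)
    y = np.array([scored.scores[sp] for sp in species])
    mls = np.array([traits.mls(sp) for sp in species])
    mass = np.array([traits.mass(sp) for sp in species])
    if log_traits:
        mls, mass = np.log10(mls), np.log10(mass)
    X = np.column_stack([mls, mass])
    if cov is None:
        cov = brownian_covariance(tree, species, lam)
    elif cov.species != species:
        raise LongselError("supplied covariance does not match the column's species")
    fit = gls_fit(y, X, cov)
    return ColumnFit(
        b_mls=fit.b_mls, p_mls=fit.p_mls,
        b_mass=fit.b_mass, p_mass=fit.p_mass,
        n=n, degenerate=fit.degenerate,
    )


def column_species(
    scored: ScoredColumn, traits: TraitTable, tree: PhylogeneticTree
) -> list[str]:
    """The (sorted) species a column's fit would use; mirrors fit_column."""
    tips = set(tree.tip_labels())
    return sorted(
        sp for sp in scored.scores
        if sp in traits.data.index and sp in tips and sp != traits.reference
    )
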