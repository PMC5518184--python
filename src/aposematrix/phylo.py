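"""Phylogenetic comparative statistics.

Trees are consumed as Newick with branch lengths (tree inference is out
of scope).  The module provides Pagel's lambda (ML over [0, 1] with a
likelihood-ratio test against lambda = 0), Blomberg's K with a
tip-permutation test, and phylogenetic generalized least squares (PGLS)
with residual covariance proportional to shared branch lengths.

The phylogenetic covariance C has C[i, j] equal to the shared
root-to-tip path length of tips i and j; Pagel's transform scales the
off-diagonals by lambda.  When both signal estimators are
nonsignificant the analysis can proceed without phylogenetic
correction, which is the workflow branch the signal test supports.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from .types import ValidationError

__all__ = [
    "PhyloTree",
    "read_newick",
    "lambda_cov",
    "pagel_lambda",
    "blomberg_k",
    "pgls",
    "LambdaResult",
    "KResult",
    "PglsResult",
]


class NewickError(ValueError):
    """Raised for malformed or unusable Newick input."""


@dataclass(frozen=True)
class PhyloTree:
    """A rooted tree with branch lengths, its tip labels (sorted) and
    the phylogenetic covariance matrix C in that tip order."""

    tree: dendropy.Tree
    taxa: tuple[str, ...]
    C: np.ndarray

    @property
    def n_tips(self) -> int:
        return len(self.taxa)

    def to_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def align_trait(self, trait: pd.Series) -> np.ndarray:
        """Reorder a tip-indexed trait to the tree's taxon order."""
        missing = set(self.taxa) - set(trait.index)
        if missing:
            raise ValidationError(f"trait values missing for tips: {sorted(missing)}")
        return trait.loc[list(self.taxa)].to_numpy(dtype=float)


def _vcv_from_tree(tree: dendropy.Tree, taxa: tuple[str, ...]) -> np.ndarray:
    depths = {}
    for leaf in tree.leaf_node_iter():
        depths[leaf.taxon.label] = leaf.distance_from_root()
    pdm = tree.phylogenetic_distance_matrix()
    tax_by_label = {t.label: t for t in tree.taxon_namespace}
    n = len(taxa)
    C = np.empty((n, n))
    for i, a in enumerate(taxa):
        C[i, i] = depths[a]
        for j in range(i + 1, n):
            b = taxa[j]
            d = pdm.patristic_distance(tax_by_label[a], tax_by_label[b])
            C[i, j] = C[j, i] = 0.5 * (depths[a] + depths[b] - d)
    return C


def read_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise NewickError(f"could not parse Newick: {exc}") from exc
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise NewickError("tree must have at least two tips")
    labels = []
    for leaf in leaves:
        if leaf.taxon is None or not leaf.taxon.label:
            raise NewickError("every tip must be labelled")
        labels.append(leaf.taxon.label)
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise NewickError(f"duplicate tip labels: {dupes}")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise NewickError(
                f"missing branch length above node near {edge.head_node}"
            )
        if edge.length < 0:
            raise NewickError("negative branch length")
    taxa = tuple(sorted(labels))
    return PhyloTree(tree=tree, taxa=taxa, C=_vcv_from_tree(tree, taxa))


def lambda_cov(C: np.ndarray, lam: float) -> np.ndarray:
    """Pagel transform: off-diagonal entries of C scaled by lambda."""
    out = lam * C
    np.fill_diagonal(out, np.diag(C))
    return out


def _profile_loglik(C_lam: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Gaussian log-likelihood with mean mu*1 and covariance s2*C,
    with mu and s2 profiled analytically.  Returns (loglik, mu, s2)."""
    n = y.size
    try:
        L = np.linalg.cholesky(C_lam)
    except np.linalg.LinAlgError:
        # near-singular covariance (e.g. effectively duplicated tips)
        L = np.linalg.cholesky(C_lam + 1e-10 * np.mean(np.diag(C_lam)) * np.eye(n))
    z = np.linalg.solve(L, y)
    one = np.linalg.solve(L, np.ones(n))
    mu = float(one @ z / (one @ one))
    r = z - mu * one
    s2 = float(r @ r / n)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + logdet + n)
    return ll, mu, s2


@dataclass(frozen=True)
class LambdaResult:
    lambda_: float
    loglik: float
    pvalue: float
    mu: float
    sigma2: float
    identifiable: bool = True


def pagel_lambda(tree: PhyloTree, trait: pd.Series | np.ndarray) -> LambdaResult:
    """ML estimate of Pagel's lambda on [0, 1] with an LR test against
    lambda = 0 (independent tips)."""
    y = tree.align_trait(trait) if isinstance(trait, pd.Series) else np.asarray(trait, float)
    if y.size != tree.n_tips:
        raise ValidationError("trait length does not match tip count")
    if tree.n_tips < 4:
        raise ValidationError("need at least 4 tips")
    if np.var(y) == 0:
        raise ValidationError("trait is constant")
    C = tree.C
    off = C - np.diag(np.diag(C))
    if np.abs(off).max() < 1e-12 * np.diag(C).max():
        # star phylogeny: C(lambda) does not depend on lambda
        ll, mu, s2 = _profile_loglik(lambda_cov(C, 0.0), y)
        return LambdaResult(np.nan, ll, 1.0, mu, s2, identifiable=False)

    def neg(lam: float) -> float:
        return -_profile_loglik(lambda_cov(C, lam), y)[0]

    res = optimize.minimize_scalar(neg, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-6})
    lam_hat = float(res.x)
    # the bounded optimizer can sit just inside an end point; snap if the
    # boundary is at least as good
    for edge in (0.0, 1.0):
        if neg(edge) <= res.fun + 1e-12:
            lam_hat, res = edge, res
            break
    ll1, mu, s2 = _profile_loglik(lambda_cov(C, lam_hat), y)
    ll0, _, _ = _profile_loglik(lambda_cov(C, 0.0), y)
    lr = max(0.0, 2.0 * (ll1 - ll0))
    p = float(stats.chi2.sf(lr, df=1))
    return LambdaResult(lam_hat, ll1, p, mu, s2)


@dataclass(frozen=True)
class KResult:
    k: float
    pvalue: float
    n_perm: int
    seed: int


def _k_stat(C_inv: np.ndarray, C: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(K, gls_mse) for one trait vector."""
    n = y.size
    one = np.ones(n)
    denom_mu = one @ C_inv @ one
    mu = float(one @ C_inv @ y / denom_mu)
    r = y - mu
    mse0 = float(r @ r / (n - 1))
    mse = float(r @ C_inv @ r / (n - 1))
    expected = (np.trace(C) - n / denom_mu) / (n - 1)
    return (mse0 / mse) / expected, mse


def blomberg_k(
    tree: PhyloTree,
    trait: pd.Series | np.ndarray,
    n_perm: int = 999,
    seed: int = 0,
) -> KResult:
    """Blomberg's K with a one-tailed tip-permutation test.

    K is the observed MSE0/MSE ratio (variance about the phylogenetic
    mean over GLS error variance) relative to its Brownian-motion
    expectation on the same tree; K near 1 indicates Brownian-like
    signal, K near 0 none.  The P-value is the (+1-corrected) fraction
    of tip permutations whose GLS error is at most the observed one.
    """
    y = tree.align_trait(trait) if isinstance(trait, pd.Series) else np.asarray(trait, float)
    if np.var(y) == 0:
        raise ValidationError("trait is constant")
    if n_perm < 99:
        raise ValidationError("use at least 99 permutations")
    C = tree.C
    C_inv = np.linalg.inv(C)
    k_obs, mse_obs = _k_stat(C_inv, C, y)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        _, mse_p = _k_stat(C_inv, C, rng.permutation(y))
        if mse_p <= mse_obs:
            hits += 1
    p = (hits + 1) / (n_perm + 1)
    return KResult(k=k_obs, pvalue=p, n_perm=n_perm, seed=seed)


@dataclass(frozen=True)
class PglsResult:
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    fvalue: float
    f_pvalue: float
    df_model: float
    df_resid: float


def pgls(
    tree: PhyloTree,
    response: pd.Series,
    predictors: pd.DataFrame | None = None,
    add_intercept: bool = True,
) -> PglsResult:
    """Phylogenetic GLS regression with residual covariance C.

    ``beta_hat = (X' C^-1 X)^-1 X' C^-1 y``; reduces to OLS when C is
    the identity.  Predictors and response are tip-indexed; rank
    deficiency raises an error naming the collinear columns.
    """
    y = tree.align_trait(response)
    if predictors is None:
        X = pd.DataFrame(index=list(tree.taxa))
    else:
        missing = set(tree.taxa) - set(predictors.index)
        if missing:
            raise ValidationError(f"predictor rows missing for tips: {sorted(missing)}")
        X = predictors.loc[list(tree.taxa)].astype(float)
    if add_intercept:
        X = X.copy()
        X.insert(0, "const", 1.0)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.loc[:, X.nunique() > 1]
        raise ValidationError(
            f"predictor matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"check columns {list(corr.columns)}"
        )
    model = sm.GLS(y, X, sigma=tree.C)
    fit = model.fit()
    return PglsResult(
        params=fit.params,
        bse=fit.bse,
        tvalues=fit.tvalues,
        pvalues=fit.pvalues,
        fvalue=float(fit.fvalue) if X.shape[1] > 1 else np.nan,
        f_pvalue=float(fit.f_pvalue) if X.shape[1] > 1 else np.nan,
        df_model=float(fit.df_model),
        df_resid=float(fit.df_resid),
    )
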