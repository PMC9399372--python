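"""Cluster eigengenes and correlation screening against SF2.

A gene cluster is summarized by the first principal component of its member
x cell-line expression submatrix (the "eigengene"); clusters whose eigengene
tracks radiosensitivity (Spearman correlation with SF2, the surviving
fraction at 2 Gy) are retained for single-gene follow-up.

PC sign is indeterminate under any linear-algebra backend, so the component
is oriented to correlate non-negatively with the members' mean standardized
expression; this makes screens reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .exceptions import InsufficientDataError

_VAR_TOL = 1e-12

__all__ = [
    "ClusterEigenvalue",
    "ClusterEigengene",
    "cluster_eigenvalue",
    "screen_clusters",
    "correlate_gene_sf2",
    "spearman_safe",
    "validate_sf2",
]


def validate_sf2(sf2: pd.Series) -> pd.Series:
    """Check an SF2 table: unique cell lines, values in (0, 1]."""
    sf2 = pd.Series(sf2, dtype=float)
    if sf2.index.duplicated().any():
        raise ValueError("duplicate cell lines in SF2 table")
    bad = sf2[(sf2 <= 0) | (sf2 > 1)]
    if len(bad):
        raise ValueError(f"SF2 values outside (0, 1]: {bad.to_dict()}")
    return sf2


class ClusterEigengene(TransformerMixin, BaseEstimator):
    """First principal component of a standardized gene group.

    ``fit`` expects a samples x genes matrix (samples are cell lines).  Genes
    are z-scored, the leading right singular vector gives the loadings, and
    the per-sample scores are the eigengene.  Orientation: the scores must
    correlate non-negatively with the mean standardized member profile.

    Attributes
    ----------
    loadings_ : (n_genes,) gene loadings on PC1.
    scores_ : (n_samples,) zero-mean eigengene of the fitted samples.
    explained_variance_ratio_ : float
    flipped_ : bool, whether orientation reversed the raw SVD sign.
    """

    def fit(self, X, y=None):
        self.fit_transform(X)
        return self

    def fit_transform(self, X, y=None):
        X = check_array(X, dtype=float, ensure_min_samples=2)
        mean = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        usable = sd > _VAR_TOL
        if not usable.any():
            raise ValueError("all member genes are constant across samples")
        Z = np.zeros_like(X)
        Z[:, usable] = (X[:, usable] - mean[usable]) / sd[usable]
        U, s, Vt = np.linalg.svd(Z, full_matrices=False)
        scores = U[:, 0] * s[0]
        loadings = Vt[0]
        ref = Z.mean(axis=1)
        orient = float(scores @ (ref - ref.mean()))
        self.flipped_ = orient < 0
        if self.flipped_:
            scores, loadings = -scores, -loadings
        self.mean_, self.scale_, self.usable_ = mean, sd, usable
        self.loadings_ = loadings
        self.scores_ = scores
        total = float((s**2).sum())
        self.explained_variance_ratio_ = float(s[0] ** 2 / total) if total > 0 else 0.0
        self.n_features_in_ = X.shape[1]
        return scores[:, None]

    def transform(self, X):
        check_is_fitted(self, "loadings_")
        X = check_array(X, dtype=float)
        Z = np.zeros_like(X)
        u = self.usable_
        Z[:, u] = (X[:, u] - self.mean_[u]) / self.scale_[u]
        return (Z @ self.loadings_)[:, None]


@dataclass
class ClusterEigenvalue:
    """PC1 summary of one gene cluster across cell lines."""

    cluster_id: object
    loadings: pd.Series  # gene -> loading
    scores: pd.Series  # cell line -> PC1 score (zero mean)
    explained_variance_ratio: float
    flipped: bool


def cluster_eigenvalue(
    expr: pd.DataFrame, members, cluster_id=None
) -> ClusterEigenvalue:
    """Eigengene of ``members`` over a genes x cell-lines expression matrix."""
    members = list(members)
    if not members:
        raise ValueError("empty member set")
    missing = [g for g in members if g not in expr.index]
    if missing:
        raise KeyError(f"member genes absent from expression matrix: {missing}")
    sub = expr.loc[members]  # genes x lines
    eg = ClusterEigengene()
    scores = eg.fit_transform(sub.T.to_numpy())[:, 0]
    return ClusterEigenvalue(
        cluster_id=cluster_id,
        loadings=pd.Series(eg.loadings_, index=members, name="loading"),
        scores=pd.Series(scores, index=sub.columns, name="pc1"),
        explained_variance_ratio=eg.explained_variance_ratio_,
        flipped=eg.flipped_,
    )


def spearman_safe(x, y) -> float:
    """Spearman rho mapping degenerate (constant) inputs to 0.0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() <= _VAR_TOL or y.std() <= _VAR_TOL:
        return 0.0
    rho = stats.spearmanr(x, y).statistic
    return 0.0 if np.isnan(rho) else float(rho)


def _shared_lines(scores: pd.Series, sf2: pd.Series) -> pd.Index:
    shared = scores.index.intersection(sf2.index)
    if len(shared) < 3:
        raise InsufficientDataError(
            f"only {len(shared)} shared cell lines between eigengene and SF2"
        )
    return shared


def screen_clusters(
    eigs: list[ClusterEigenvalue],
    sf2: pd.Series,
    threshold: float = 0.1,
    signed: bool = False,
) -> pd.DataFrame:
    """Spearman-screen cluster eigengenes against SF2.

    By default a cluster passes when |rho| > ``threshold`` so protective
    (negatively correlated) clusters are retained; ``signed=True`` applies the
    cutoff to the signed correlation instead.  Signed correlations are always
    reported.
    """
    sf2 = validate_sf2(sf2)
    rows = []
    for eig in eigs:
        shared = _shared_lines(eig.scores, sf2)
        rho = spearman_safe(eig.scores[shared], sf2[shared])
        stat = rho if signed else abs(rho)
        rows.append(
            {
                "cluster_id": eig.cluster_id,
                "rho": rho,
                "n_lines": len(shared),
                "selected": stat > threshold,
            }
        )
    return pd.DataFrame(rows)


def correlate_gene_sf2(
    expr: pd.DataFrame, gene, sf2: pd.Series, exact_max_n: int = 7
) -> tuple[float, float]:
    """Spearman rho and two-sided p for one gene's expression vs SF2.

    For n <= ``exact_max_n`` shared lines the p-value is the exact pairing
    permutation tail (all n! orderings); otherwise the asymptotic t-based
    p of the rank correlation is used.
    """
    if gene not in expr.index:
        raise KeyError(f"gene {gene!r} absent from expression matrix")
    sf2 = validate_sf2(sf2)
    x = expr.loc[gene]
    shared = _shared_lines(x, sf2)
    xv = x[shared].to_numpy(dtype=float)
    yv = sf2[shared].to_numpy(dtype=float)
    rho = spearman_safe(xv, yv)
    if xv.std() <= _VAR_TOL or yv.std() <= _VAR_TOL:
        return 0.0, 1.0
    n = len(shared)
    if n <= exact_max_n:
        res = stats.permutation_test(
            (xv,),
            statistic=lambda xp: stats.spearmanr(xp, yv).statistic,
            permutation_type="pairings",
            alternative="two-sided",
            n_resamples=math.factorial(n),
        )
        return rho, float(res.pvalue)
    return rho, float(stats.spearmanr(xv, yv).pvalue)
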