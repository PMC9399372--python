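"""Single-gene radiosensitivity models: SGLQ regression and forest importance.

The classical linear-quadratic (LQ) law relates dose D to clonogenic survival,
SF = exp(-aD - bD^2).  The single-gene LQ (SGLQ) analogue substitutes a gene's
expression E for dose:

    SF = exp(alpha * E - beta * E^2)

so that on the log scale ln SF is a no-intercept linear model in (E, E^2) and
SF(E=0) = 1 exactly.  Because expression enters z-scored (it can be negative),
alpha and beta are left unconstrained in sign.

A regression random forest predicting SF2 from all candidate genes jointly
provides a complementary, model-free importance: the increase in out-of-bag
mean-squared error when a gene's values are permuted.  A gene is excluded
from the signature search only when it fails both routes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .exceptions import InsufficientDataError
from .radioscreen import validate_sf2

__all__ = [
    "SGLQFit",
    "SGLQRegressor",
    "GeneImportance",
    "RadiosensitivityForest",
    "ExclusionReport",
    "fit_sglq",
    "rf_importance",
    "fail_both_filter",
    "dose_linearity_aic",
]


class SGLQRegressor(RegressorMixin, BaseEstimator):
    """Per-gene SGLQ model fit by ordinary least squares on ln SF.

    ``fit`` regresses y = ln(SF2) on (E, E^2) with no intercept; the linear
    coefficient is ``alpha_`` and the negated quadratic coefficient is
    ``beta_`` (so predictions are exp(alpha*E - beta*E^2)).  The overall
    regression F-test p-value (both coefficients zero) decides ``pass_``.

    Parameters
    ----------
    p_threshold : float, default 0.05
        F-test significance level below which the gene "performs well".

    Attributes
    ----------
    alpha_, beta_ : SGLQ coefficients per expression unit.
    r2_log_ : coefficient of determination of the no-intercept fit on the
        log-SF scale (uncentered, the statsmodels convention without a
        constant term).
    f_pvalue_ : overall F-test p-value; NaN when the design is degenerate.
    pass_ : bool; False for rank-deficient designs or SF2 without variation.
    """

    def __init__(self, p_threshold: float = 0.05):
        self.p_threshold = p_threshold

    def fit(self, X, y):
        X, y = check_X_y(
            np.asarray(X, dtype=float).reshape(-1, 1), np.asarray(y, dtype=float)
        )
        if X.shape[0] < 3:
            raise InsufficientDataError("SGLQ fit needs >= 3 cell lines")
        if (y <= 0).any():
            raise ValueError("survival fractions must be positive (log scale fit)")
        E = X[:, 0]
        design = np.column_stack([E, E**2])
        logsf = np.log(y)
        self.rank_deficient_ = np.linalg.matrix_rank(design, tol=1e-10) < 2
        if self.rank_deficient_:
            self.alpha_ = self.beta_ = np.nan
            self.r2_log_ = np.nan
            self.f_pvalue_ = np.nan
            self.pass_ = False
            self.n_features_in_ = 1
            return self
        if np.allclose(logsf, 0.0):
            # SF2 identically 1: nothing to explain, exact null fit.
            self.alpha_ = 0.0
            self.beta_ = 0.0
            self.r2_log_ = 1.0
            self.f_pvalue_ = 1.0
            self.pass_ = False
            self.n_features_in_ = 1
            return self
        res = sm.OLS(logsf, design).fit()
        self.alpha_ = float(res.params[0])
        self.beta_ = float(-res.params[1])
        self.r2_log_ = float(res.rsquared)
        self.f_pvalue_ = float(res.f_pvalue)
        self.pass_ = bool(self.f_pvalue_ < self.p_threshold)
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        check_is_fitted(self, "alpha_")
        if self.rank_deficient_:
            raise ValueError("rank-deficient SGLQ fit cannot predict")
        E = check_array(np.asarray(X, dtype=float).reshape(-1, 1))[:, 0]
        return np.exp(self.alpha_ * E - self.beta_ * E**2)


@dataclass
class SGLQFit:
    """Fitted SGLQ parameters and quality for one gene."""

    gene: object
    alpha: float
    beta: float
    r2_log: float
    f_pvalue: float
    sglq_pass: bool
    rank_deficient: bool = False


def fit_sglq(E: pd.Series, sf2: pd.Series, p_threshold: float = 0.05) -> SGLQFit:
    """Fit the SGLQ model for one gene over shared cell lines.

    ``E`` is the gene's expression per cell line; ``sf2`` the survival
    fraction table.  Collinear designs (e.g. constant expression) are flagged
    rank-deficient with ``sglq_pass=False`` instead of raising.
    """
    sf2 = pd.Series(sf2, dtype=float)
    shared = E.index.intersection(sf2.index)
    if len(shared) < 3:
        raise InsufficientDataError(f"only {len(shared)} shared cell lines")
    reg = SGLQRegressor(p_threshold=p_threshold)
    reg.fit(E[shared].to_numpy(), sf2[shared].to_numpy())
    return SGLQFit(
        gene=E.name,
        alpha=reg.alpha_,
        beta=reg.beta_,
        r2_log=reg.r2_log_,
        f_pvalue=reg.f_pvalue_,
        sglq_pass=reg.pass_,
        rank_deficient=reg.rank_deficient_,
    )


class RadiosensitivityForest(RegressorMixin, BaseEstimator):
    """Regression forest with out-of-bag permutation importance.

    Mirrors the classical random-forest regression importance: each tree is
    grown on a bootstrap sample; a feature's importance is the mean (over
    trees) increase in out-of-bag MSE when that feature's out-of-bag values
    are permuted.  Positive importance means permuting the gene damages SF2
    prediction, i.e. the gene carries signal.

    Parameters
    ----------
    n_trees : int, default 500
    max_features : float, default 1/3 of the features per split.
    min_samples_leaf : int, default 5
    random_state : int or None; fixing it makes fits bit-reproducible.
    """

    def __init__(
        self,
        n_trees: int = 500,
        max_features: float = 1.0 / 3.0,
        min_samples_leaf: int = 5,
        random_state: int | None = None,
    ):
        self.n_trees = n_trees
        self.max_features = max_features
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def fit(self, X, y):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        X, y = check_X_y(X, y, dtype=float)
        n, p = X.shape
        if n < 5:
            raise InsufficientDataError("forest fit needs >= 5 samples")
        rng = np.random.default_rng(self.random_state)
        self.trees_ = []
        imp_sum = np.zeros(p)
        imp_n = 0
        for _ in range(self.n_trees):
            boot = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), boot)
            tree = DecisionTreeRegressor(
                max_features=self.max_features,
                min_samples_leaf=self.min_samples_leaf,
                random_state=int(rng.integers(0, 2**31 - 1)),
            )
            tree.fit(X[boot], y[boot])
            self.trees_.append(tree)
            if oob.size == 0:
                continue
            Xo, yo = X[oob], y[oob]
            base = float(np.mean((tree.predict(Xo) - yo) ** 2))
            for j in range(p):
                Xp = Xo.copy()
                Xp[:, j] = rng.permutation(Xp[:, j])
                imp_sum[j] += float(np.mean((tree.predict(Xp) - yo) ** 2)) - base
            imp_n += 1
        self.importances_ = imp_sum / max(imp_n, 1)
        self.n_features_in_ = p
        return self

    def predict(self, X):
        check_is_fitted(self, "trees_")
        X = check_array(X, dtype=float)
        return np.mean([t.predict(X) for t in self.trees_], axis=0)


@dataclass
class GeneImportance:
    """Forest and SGLQ verdicts for one gene."""

    gene: object
    rf_importance: float
    rf_pass: bool
    sglq_pass: bool | None = None

    @property
    def fails_both(self) -> bool:
        if self.sglq_pass is None:
            raise ValueError("sglq_pass not populated")
        return (not self.rf_pass) and (not self.sglq_pass)


def rf_importance(
    expr: pd.DataFrame,
    sf2: pd.Series,
    n_trees: int = 500,
    seed: int | None = None,
    **forest_kwargs,
) -> pd.DataFrame:
    """OOB permutation importance of every gene for SF2 prediction.

    ``expr`` is genes x cell lines; all genes enter one joint forest.
    Returns a DataFrame indexed by gene with ``rf_importance`` and
    ``rf_pass`` (importance strictly positive).
    """
    sf2 = validate_sf2(sf2)
    shared = expr.columns.intersection(sf2.index)
    if len(shared) < 5:
        raise InsufficientDataError(f"only {len(shared)} shared cell lines")
    forest = RadiosensitivityForest(
        n_trees=n_trees, random_state=seed, **forest_kwargs
    )
    forest.fit(expr[shared].T.to_numpy(), sf2[shared].to_numpy())
    return pd.DataFrame(
        {
            "rf_importance": forest.importances_,
            "rf_pass": forest.importances_ > 0,
        },
        index=expr.index,
    )


@dataclass
class ExclusionReport:
    """Counts of the fail-both exclusion, percentages as printed reports."""

    n_total: int
    n_excluded: int
    excluded: list

    @property
    def n_retained(self) -> int:
        return self.n_total - self.n_excluded

    @property
    def pct_excluded(self) -> float:
        return round(100.0 * self.n_excluded / self.n_total, 1)

    @property
    def pct_retained(self) -> float:
        return round(100.0 * self.n_retained / self.n_total, 1)


def fail_both_filter(
    importances: pd.DataFrame, sglq_fits: dict | list
) -> tuple[list, ExclusionReport]:
    """Exclude genes that fail both the forest and the SGLQ screen.

    A gene is dropped iff ``rf_pass`` is False and ``sglq_pass`` is False;
    passing either route retains it.  Gene sets must coincide.
    """
    if isinstance(sglq_fits, list):
        sglq_fits = {f.gene: f for f in sglq_fits}
    rf_genes = set(importances.index)
    sg_genes = set(sglq_fits)
    if rf_genes != sg_genes:
        raise KeyError(
            "gene sets differ between forest and SGLQ analyses: "
            f"only-RF={sorted(rf_genes - sg_genes)[:5]} "
            f"only-SGLQ={sorted(sg_genes - rf_genes)[:5]}"
        )
    retained, excluded = [], []
    for gene in importances.index:
        rf_ok = bool(importances.loc[gene, "rf_pass"])
        sg_ok = bool(sglq_fits[gene].sglq_pass)
        (retained if rf_ok or sg_ok else excluded).append(gene)
    report = ExclusionReport(
        n_total=len(importances), n_excluded=len(excluded), excluded=excluded
    )
    return retained, report


def dose_linearity_aic(
    doses,
    expr: pd.DataFrame,
    degrees=(1, 2, 3),
    rss_floor: float = 1e-12,
    parsimony_delta: float = 2.0,
) -> pd.Series:
    """Best polynomial degree of the dose -> expression curve per gene.

    For each gene, polynomials of the requested degrees are fit to expression
    against dose and scored with AIC = n*ln(RSS/n) + 2k (k = coefficients
    including the intercept).  Following the usual information-theoretic
    convention that models within ``parsimony_delta`` AIC units are
    indistinguishable, the smallest such degree is returned
    (``parsimony_delta=0`` restores the strict argmin).  Degrees with more
    parameters than distinct dose levels are skipped; an RSS below
    ``rss_floor`` is clamped with a warning.
    """
    doses = np.asarray(doses, dtype=float)
    if len(np.unique(doses)) < 4:
        raise InsufficientDataError("need >= 4 distinct dose levels")
    n = len(doses)
    if expr.shape[1] != n:
        raise ValueError("expr must have one column per dose sample")
    n_levels = len(np.unique(doses))
    Y = expr.to_numpy(dtype=float)
    clamped = False
    aics = {}
    for d in degrees:
        if n_levels < d + 1:
            continue
        coef = np.polynomial.polynomial.polyfit(doses, Y.T, deg=d)
        fitted = np.polynomial.polynomial.polyval(doses, coef)
        rss = ((Y - fitted) ** 2).sum(axis=1)
        if (rss < rss_floor).any():
            clamped = True
        rss = np.maximum(rss, rss_floor)
        aics[d] = n * np.log(rss / n) + 2 * (d + 1)
    if clamped:
        warnings.warn(
            f"RSS below floor {rss_floor:g} clamped for some genes",
            UserWarning,
            stacklevel=2,
        )
    if not aics:
        raise InsufficientDataError("no requested degree is estimable")
    degs = np.array(sorted(aics))
    A = np.vstack([aics[d] for d in degs])  # degrees x genes
    best = A.min(axis=0)
    within = A <= best + parsimony_delta
    choice = degs[within.argmax(axis=0)]  # first (smallest) degree within delta
    return pd.Series(choice, index=expr.index, name="best_degree")
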