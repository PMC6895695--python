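"""Per-gene fate models and the joint L1-penalized signature model.

Each signature gene's association with the cardiomyocyte outcome fraction
is quantified with a GLM: ordinary least squares (identity link) for
estimate/CI-style reporting, or a quasi-binomial GLM with a logit link for
a fractional outcome.  The joint contribution of all signature genes is
assessed with LASSO regression under k-fold cross-validation; the reported
R-squared comes from held-out folds only, so it is an out-of-sample
variance-explained estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import Lasso, lasso_path

from .stats import pseudo_r2


@dataclass
class GeneFateFit:
    gene: str
    link: str
    estimate: float
    se: float
    p: float
    r2: float


@dataclass
class JointModelResult:
    selected_genes: list[str]
    coefficients: pd.Series
    cv_r2_mean: float
    cv_r2_per_fold: np.ndarray
    lambda_: float
    seed: int


def fit_gene_fate_model(
    expr_g: pd.Series,
    outcome: pd.Series,
    link: str = "identity",
) -> GeneFateFit:
    """Regress the outcome fraction on one gene's log2(TPM + 1) expression.

    ``identity`` fits OLS; ``logit`` fits a quasi-binomial GLM (fractional
    outcome, Pearson-chi2 dispersion).  The pseudo-R2 is the squared
    Pearson correlation between fitted and observed outcomes.
    """
    y = np.asarray(outcome, dtype=float)
    x = np.log2(np.asarray(expr_g, dtype=float) + 1.0)
    if y.size < 10:
        raise ValueError("at least 10 lines are required")
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("outcome fractions must lie in [0, 1]")
    if np.isclose(np.std(x), 0):
        raise ValueError("constant expression; association undefined")
    X = sm.add_constant(x)
    if link == "identity":
        fit = sm.OLS(y, X).fit()
        est, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        fitted = fit.fittedvalues
    elif link == "logit":
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(scale="X2")
        est, se, p = fit.params[1], fit.bse[1], fit.pvalues[1]
        fitted = fit.fittedvalues
    else:
        raise ValueError(f"unknown link {link!r}")
    name = expr_g.name if isinstance(expr_g, pd.Series) and expr_g.name else "gene"
    r2 = pseudo_r2(y, np.asarray(fitted), method="squared_correlation")
    return GeneFateFit(gene=str(name), link=link, estimate=float(est), se=float(se),
                       p=float(p), r2=float(r2))


def _stratified_folds(y: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Fold ids stratified by outcome rank: consecutive rank blocks are
    scattered across folds, stabilizing small cohorts."""
    order = np.argsort(y, kind="mergesort")
    fold_of = np.empty(y.size, dtype=int)
    for start in range(0, y.size, folds):
        block = order[start:start + folds]
        fold_of[block] = rng.permutation(folds)[: block.size]
    return fold_of


def joint_lasso_cv(
    expr: pd.DataFrame,
    outcome: pd.Series,
    folds: int = 10,
    seed: int = 0,
    n_alphas: int = 60,
) -> JointModelResult:
    """LASSO of the outcome fraction on all signature genes with k-fold CV.

    ``expr`` is lines x genes (TPM); predictors are standardized
    log2(TPM + 1).  The penalty is chosen at the minimum mean held-out
    squared error over a common alpha path; per-fold R2 at that penalty is
    1 - SSE/SST with SST measured against the training-fold mean, so pure
    noise yields R2 near or below zero.
    """
    if expr.shape[1] == 0:
        raise ValueError("empty gene set")
    if folds < 2:
        raise ValueError("folds must be at least 2")
    if expr.shape[0] < 3 * folds:
        raise ValueError("need at least 3 lines per fold")
    y = outcome.reindex(expr.index).to_numpy(dtype=float)
    if np.any(np.isnan(y)):
        raise ValueError("outcome missing for some lines")
    X = np.log2(expr.to_numpy(dtype=float) + 1.0)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - mu) / sd

    rng = np.random.default_rng(seed)
    fold_of = _stratified_folds(y, folds, rng)

    alphas, _, _ = lasso_path(X, y - y.mean(), alphas=n_alphas, eps=1e-3)
    mse = np.zeros((folds, alphas.size))
    for k in range(folds):
        tr, te = fold_of != k, fold_of == k
        xm, ym = X[tr].mean(axis=0), y[tr].mean()
        _, coefs, _ = lasso_path(X[tr] - xm, y[tr] - ym, alphas=alphas)
        pred = (X[te] - xm) @ coefs + ym  # path has no intercept; center explicitly
        mse[k] = ((pred - y[te, None]) ** 2).mean(axis=0)
    best_idx = int(np.argmin(mse.mean(axis=0)))  # ties -> larger alpha (sparser)
    lam = float(alphas[best_idx])

    r2_folds = np.empty(folds)
    for k in range(folds):
        tr, te = fold_of != k, fold_of == k
        model = Lasso(alpha=lam, max_iter=100000).fit(X[tr], y[tr])
        pred = model.predict(X[te])
        sst = ((y[te] - y[tr].mean()) ** 2).sum()
        r2_folds[k] = 1.0 - ((y[te] - pred) ** 2).sum() / sst if sst > 0 else 0.0

    final = Lasso(alpha=lam, max_iter=100000).fit(X, y)
    coefs = pd.Series(final.coef_, index=expr.columns, name="coefficient")
    selected = list(coefs.index[coefs != 0])
    return JointModelResult(
        selected_genes=selected,
        coefficients=coefs,
        cv_r2_mean=float(r2_folds.mean()),
        cv_r2_per_fold=r2_folds,
        lambda_=lam,
        seed=seed,
    )
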