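"""Covariate and genotype associations with differentiation outcome.

A logistic GLM links line/subject covariates (sex, age, ethnicity,
passage) to the binary fate outcome; perfect separation falls back to a
Firth-penalized fit.  The variant scan is a vectorized per-variant linear
regression of the continuous outcome fraction on allele dosage with
covariate adjustment, flagged at genome-wide significance (p < 5e-8).
Clone/twin concordance compares within-pair outcome differences against
all unrelated cross-pairs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

GENOME_WIDE_P = 5e-8


@dataclass
class CovariateFit:
    table: pd.DataFrame  # coef, se, z, p per term
    n_used: int
    n_dropped: int
    firth: bool


def _design_matrix(metadata: pd.DataFrame) -> pd.DataFrame:
    """Numeric covariates pass through; categoricals are one-hot encoded
    with the most frequent level as reference."""
    cols = []
    for name in metadata.columns:
        col = metadata[name]
        if pd.api.types.is_numeric_dtype(col) and not pd.api.types.is_bool_dtype(col):
            cols.append(col.astype(float))
        else:
            ref = col.value_counts().idxmax()
            for level in sorted(col.dropna().unique()):
                if level == ref:
                    continue
                cols.append((col == level).astype(float).rename(f"{name}[{level}]"))
    return pd.concat(cols, axis=1)


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-10):
    """Firth-penalized logistic regression (Jeffreys-prior score correction)."""
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1 - p)
        XtW = X.T * w
        info = XtW @ X
        info_inv = np.linalg.pinv(info)
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w  # hat diagonal
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        beta_new = beta + step
        if np.max(np.abs(step)) < tol:
            beta = beta_new
            break
        beta = beta_new
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1 - p)
    cov = np.linalg.pinv((X.T * w) @ X)
    se = np.sqrt(np.diag(cov))
    return beta, se


def covariate_glm(metadata: pd.DataFrame, fate: pd.Series) -> CovariateFit:
    """Logistic regression of binary fate (1 = CM) on line/subject covariates.

    Wald Z p-values; complete cases only, with the dropped-line count
    reported.  If ordinary maximum likelihood shows separation (divergent
    coefficients or failed convergence), a Firth-penalized fit is used and
    flagged.
    """
    y = fate.reindex(metadata.index)
    if set(pd.unique(y.dropna())) <= {"CM", "EPDC"}:
        y = (y == "CM").astype(float).where(y.notna())
    design = _design_matrix(metadata)
    data = pd.concat([design, y.rename("_y")], axis=1)
    complete = data.dropna()
    n_dropped = len(data) - len(complete)
    yv = complete["_y"].to_numpy(dtype=float)
    if len(np.unique(yv)) < 2 or min((yv == 0).sum(), (yv == 1).sum()) < 2:
        raise ValueError("fate outcome needs at least 2 lines per class")
    X = sm.add_constant(complete.drop(columns="_y"))
    terms = list(X.columns)
    firth = False
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(yv, X.to_numpy()).fit(disp=False, maxiter=200)
        coef, se = fit.params, fit.bse
        if not fit.mle_retvals.get("converged", True) or np.max(np.abs(coef)) > 15:
            raise np.linalg.LinAlgError("separation suspected")
    except Exception:
        firth = True
        coef, se = _firth_logit(X.to_numpy(dtype=float), yv)
    z = coef / se
    p = 2 * sps.norm.sf(np.abs(z))
    table = pd.DataFrame({"coef": coef, "se": se, "z": z, "p": p}, index=terms)
    return CovariateFit(table=table, n_used=len(complete), n_dropped=n_dropped, firth=firth)


def variant_scan(
    dosages: pd.DataFrame,
    outcome: pd.Series,
    covariates: pd.DataFrame | None = None,
    maf_min: float = 0.05,
) -> pd.DataFrame:
    """Per-variant OLS of the outcome fraction on dosage with covariates.

    Variants with folded allele frequency not exceeding ``maf_min`` or with
    no dosage variation are excluded (tallies in ``.attrs``).  Covariates
    are projected out of both outcome and dosages (Frisch-Waugh), so each
    variant costs one dot product.  ``genome_wide`` flags p < 5e-8.
    """
    lines = dosages.columns.intersection(outcome.index)
    if len(lines) < 10:
        raise ValueError("too few lines shared between dosages and outcome")
    D = dosages[lines].to_numpy(dtype=float)
    if np.any(D < 0) or np.any(D > 2):
        raise ValueError("dosages must lie in [0, 2]")
    y = outcome.loc[lines].to_numpy(dtype=float)

    maf = D.mean(axis=1) / 2.0
    maf = np.minimum(maf, 1 - maf)
    mono = D.std(axis=1) == 0
    keep = (maf > maf_min) & ~mono
    n_maf = int(((maf <= maf_min) & ~mono).sum())
    n_mono = int(mono.sum())
    D = D[keep]
    names = dosages.index[keep]

    n = len(lines)
    C = np.ones((n, 1))
    if covariates is not None:
        cov = _design_matrix(covariates.loc[lines])
        C = np.column_stack([C, cov.to_numpy(dtype=float)])
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    D_r = D - (D @ Q) @ Q.T

    dd = np.einsum("ij,ij->i", D_r, D_r)
    dy = D_r @ y_r
    ok = dd > 0
    beta = np.where(ok, dy / np.where(ok, dd, 1.0), np.nan)
    sse = (y_r @ y_r) - beta**2 * dd
    dof = n - C.shape[1] - 1
    if dof <= 0:
        raise ValueError("not enough residual degrees of freedom")
    sigma2 = np.clip(sse, 0, None) / dof
    se = np.sqrt(sigma2 / np.where(ok, dd, 1.0))
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
    p = 2 * sps.t.sf(np.abs(tstat), dof)
    out = pd.DataFrame(
        {"beta": beta, "se": se, "p": p, "genome_wide": p < GENOME_WIDE_P}, index=names
    )
    out.attrs["n_filtered_maf"] = n_maf
    out.attrs["n_skipped_monomorphic"] = n_mono
    return out


def genomic_inflation(pvalues: Sequence[float]) -> float:
    """Genomic inflation lambda: median association chi2 over its null median."""
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    chi2 = sps.chi2.isf(p, df=1)
    return float(np.median(chi2) / sps.chi2.ppf(0.5, df=1))


def relatedness_concordance(
    outcomes: pd.Series,
    pairs: Sequence[tuple[str, str]],
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Within-pair vs between-pair absolute outcome differences.

    ``pairs`` lists clone pairs from the same individual and twin pairs.
    Between-pair differences are taken over all cross-line combinations not
    sharing a pair.  Returns (within |diff|, between |diff|, U, two-sided p).
    """
    if len(pairs) < 2:
        raise ValueError("at least 2 related pairs are required")
    pair_of: dict[str, int] = {}
    for i, (a, b) in enumerate(pairs):
        pair_of[a] = i
        pair_of[b] = i
    within = np.array([abs(outcomes[a] - outcomes[b]) for a, b in pairs])
    lines = list(outcomes.index)
    between = np.array(
        [
            abs(outcomes[a] - outcomes[b])
            for a, b in combinations(lines, 2)
            if pair_of.get(a, -1) != pair_of.get(b, -2)
        ]
    )
    if between.size == 0:
        raise ValueError("no unrelated cross-pairs available")
    u, p = sps.mannwhitneyu(within, between, alternative="two-sided", method="asymptotic")
    return within, between, float(u), float(p)
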