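"""Shared statistical primitives.

Storey q-values with smoothed pi0 estimation, a class-size-preserving
permutation null for count statistics, and pseudo-R-squared measures for
fractional outcomes.  These are the building blocks the fate-threshold
sweep, the enrichment stage, and the per-gene variance models rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.special import xlogy

DEFAULT_LAMBDA_GRID = np.round(np.arange(0.05, 0.96, 0.05), 2)


@dataclass(frozen=True)
class QValueResult:
    """Per-test FDR-adjusted significance.

    Attributes
    ----------
    pvalues : original p-values, in input order.
    pi0 : estimated proportion of true nulls, in (0, 1].
    qvalues : Storey q-values, in input order.
    """

    pvalues: np.ndarray
    pi0: float
    qvalues: np.ndarray


def estimate_pi0(pvalues: np.ndarray, lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID) -> float:
    """Estimate the null proportion pi0 with the smoothed lambda-grid method.

    For each lambda, pi0(lambda) = #{p > lambda} / (m * (1 - lambda)); a cubic
    least-squares smoother over the grid is evaluated at the largest lambda.
    The estimate is clamped to (0, 1].  Degenerate grids (fewer than four
    points) fall back to the raw estimate at the largest lambda.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    lam = np.asarray(lambda_grid, dtype=float)
    if lam.size == 0 or np.any(lam < 0) or np.any(lam >= 1):
        raise ValueError("lambda_grid values must lie in [0, 1)")
    lam = np.sort(lam)
    raw = np.array([(p > l).sum() / (m * (1.0 - l)) for l in lam])
    if lam.size >= 4:
        coefs = np.polyfit(lam, raw, deg=3)
        pi0 = float(np.polyval(coefs, lam.max()))
    else:
        pi0 = float(raw[-1])
    return float(min(max(pi0, 1.0 / m), 1.0)) if m > 0 else 1.0


def storey_qvalue(
    pvalues: Sequence[float],
    lambda_grid: np.ndarray = DEFAULT_LAMBDA_GRID,
    pi0: float | None = None,
) -> QValueResult:
    """Storey q-values via the step-up rule scaled by an estimated pi0.

    Parameters
    ----------
    pvalues : p-values in [0, 1]; at least one required.
    lambda_grid : grid for the smoothed pi0 estimator.
    pi0 : optional override; ``pi0=1`` reduces exactly to Benjamini-Hochberg.

    Notes
    -----
    q_i = pi0 * min over {j : p_j >= p_i} of (m * p_j / rank(p_j)), with ties
    in p resolved by the largest rank (standard step-up convention).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("at least one p-value is required")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if pi0 is None:
        pi0 = estimate_pi0(p, lambda_grid)
    if not (0 < pi0 <= 1):
        raise ValueError("pi0 must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    # step-up: running minimum from the largest p downwards
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(pvalues=p, pi0=float(pi0), qvalues=q)


def pseudo_r2(
    observed: Sequence[float],
    fitted: Sequence[float],
    method: str = "squared_correlation",
) -> float:
    """Fraction of outcome variability captured by fitted values.

    ``squared_correlation`` is the Pearson r^2 between fitted and observed;
    ``deviance_ratio`` is 1 - residual/null binomial deviance, appropriate
    for fractional outcomes in [0, 1].  Both are clamped to [0, 1].
    """
    y = np.asarray(observed, dtype=float)
    mu = np.asarray(fitted, dtype=float)
    if y.shape != mu.shape or y.size < 3:
        raise ValueError("observed and fitted must share a length of at least 3")
    if np.any(y < 0) or np.any(y > 1):
        raise ValueError("observed fractions must lie in [0, 1]")
    if np.isclose(np.var(y), 0):
        raise ValueError("observed vector is constant; variance explained undefined")
    if method == "squared_correlation":
        if np.isclose(np.var(mu), 0):
            return 0.0
        r = np.corrcoef(y, mu)[0, 1]
        return float(np.clip(r * r, 0.0, 1.0))
    if method == "deviance_ratio":
        eps = 1e-12
        mu = np.clip(mu, eps, 1 - eps)
        ybar = np.clip(np.mean(y), eps, 1 - eps)

        def dev(m_):
            return 2.0 * np.sum(
                xlogy(y, y / m_) + xlogy(1 - y, (1 - y) / (1 - m_))
            )

        null_dev = dev(np.full_like(y, ybar))
        if null_dev <= 0:
            return 0.0
        return float(np.clip(1.0 - dev(mu) / null_dev, 0.0, 1.0))
    raise ValueError(f"unknown method {method!r}")


def permutation_count_null(
    statistic_fn: Callable[[np.ndarray], float],
    labels: Sequence,
    n_perm: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of a count statistic under label shuffling.

    Each permutation reassigns the observed labels to samples uniformly at
    random, preserving class sizes exactly (e.g. a 125/59 fate split stays
    125/59).  ``statistic_fn`` receives the permuted label vector and must
    return a scalar.
    """
    lab = np.asarray(labels)
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    classes = np.unique(lab)
    if classes.size < 2:
        raise ValueError("labels must contain at least two classes")
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for i in range(n_perm):
        out[i] = statistic_fn(rng.permutation(lab))
    return out
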