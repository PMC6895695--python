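"""Cross-cohort replication of the fate signature.

Two diagnostics and one test: (i) within- vs between-cohort sample
correlation distributions expose global batch effects; (ii) the per-gene
fate contrasts of the two cohorts are correlated over all shared genes;
(iii) signature genes replicating in the second cohort (nominal p below
alpha with matching direction) are counted against the background rate of
the same criterion among non-signature genes, with a Fisher exact test on
the resulting 2x2 table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class ReplicationResult:
    r: float
    r_p: float
    n_signature: int
    n_replicated: int
    background_rate: float
    expected: float
    fold_enrichment: float
    fisher_p: float
    contingency: np.ndarray  # [[sig_rep, sig_not], [bg_rep, bg_not]]


def cohort_correlation_diagnostics(
    expr_a: pd.DataFrame,
    expr_b: pd.DataFrame,
) -> dict[str, np.ndarray]:
    """Spearman sample-sample correlations within and across two cohorts.

    Returns arrays ``within_a``, ``within_b`` and ``between`` over the
    shared gene universe (at least 100 shared genes required).
    """
    shared = expr_a.index.intersection(expr_b.index)
    if len(shared) < 100:
        raise ValueError(f"only {len(shared)} shared genes; at least 100 required")
    if expr_a.shape[1] < 2 or expr_b.shape[1] < 2:
        raise ValueError("each cohort needs at least 2 samples")
    ra = expr_a.loc[shared].rank(axis=0).to_numpy()
    rb = expr_b.loc[shared].rank(axis=0).to_numpy()

    def _corr_block(x: np.ndarray, y: np.ndarray) -> np.ndarray:
        xc = (x - x.mean(axis=0)) / x.std(axis=0)
        yc = (y - y.mean(axis=0)) / y.std(axis=0)
        return (xc.T @ yc) / x.shape[0]

    ca = _corr_block(ra, ra)
    cb = _corr_block(rb, rb)
    cab = _corr_block(ra, rb)
    iu_a = np.triu_indices(ca.shape[0], k=1)
    iu_b = np.triu_indices(cb.shape[0], k=1)
    return {
        "within_a": ca[iu_a],
        "within_b": cb[iu_b],
        "between": cab.ravel(),
    }


def contrast_replication(
    contrast_a: pd.DataFrame,
    contrast_b: pd.DataFrame,
    signature: pd.DataFrame | pd.Series,
    alpha: float = 0.05,
) -> ReplicationResult:
    """Direction-consistent signature replication with Fisher enrichment.

    ``contrast_a`` / ``contrast_b`` carry per-gene ``mean_diff`` and ``p``
    for the discovery and replication cohorts.  A signature gene replicates
    when its cohort-b nominal p is below ``alpha`` and the cohort-b sign
    matches its discovery direction.  The random expectation is the rate of
    the same criterion (direction taken from cohort a) among non-signature
    shared genes; Fisher's exact test is applied to the 2x2 table of
    signature membership vs criterion status.
    """
    shared = contrast_a.index.intersection(contrast_b.index)
    if len(shared) == 0:
        raise ValueError("contrasts share no genes")
    if isinstance(signature, pd.Series):
        directions = np.sign(signature).astype(int)
    else:
        directions = np.sign(signature["direction"]).astype(int)
    sig_genes = directions.index.intersection(shared)
    if len(sig_genes) == 0:
        raise ValueError("signature is empty after restriction to the shared gene universe")
    if len(sig_genes) < len(directions):
        warnings.warn(
            f"{len(directions) - len(sig_genes)} signature genes absent from the shared "
            "universe were dropped",
            stacklevel=2,
        )

    a = contrast_a.loc[shared]
    b = contrast_b.loc[shared]
    r, r_p = sps.pearsonr(a["mean_diff"], b["mean_diff"])

    b_sig = b.loc[sig_genes]
    rep_mask = (b_sig["p"] < alpha) & (
        np.sign(b_sig["mean_diff"]).astype(int) == directions.loc[sig_genes]
    )
    n_rep = int(rep_mask.sum())

    bg_genes = shared.difference(sig_genes)
    a_bg, b_bg = a.loc[bg_genes], b.loc[bg_genes]
    bg_mask = (b_bg["p"] < alpha) & (
        np.sign(b_bg["mean_diff"]) == np.sign(a_bg["mean_diff"])
    )
    n_bg = int(bg_mask.sum())
    bg_rate = n_bg / max(len(bg_genes), 1)
    expected = len(sig_genes) * bg_rate
    fold = n_rep / expected if expected > 0 else np.inf

    table = np.array(
        [[n_rep, len(sig_genes) - n_rep], [n_bg, len(bg_genes) - n_bg]], dtype=int
    )
    _, fisher_p = sps.fisher_exact(table, alternative="two-sided")
    return ReplicationResult(
        r=float(r),
        r_p=float(r_p),
        n_signature=len(sig_genes),
        n_replicated=n_rep,
        background_rate=float(bg_rate),
        expected=float(expected),
        fold_enrichment=float(fold),
        fisher_p=float(fisher_p),
        contingency=table,
    )
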