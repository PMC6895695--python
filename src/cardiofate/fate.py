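"""Fate assignment and the CM/EPDC threshold sweep.

A line is CM-fated at threshold k when its estimated cardiomyocyte fraction
reaches k (the ``>=`` rule); differentiations terminated before harvest are
assigned a CM fraction of zero.  The sweep runs a two-group differential
expression analysis at every candidate threshold, counts genes passing a
Storey q cutoff, selects the threshold maximizing that count, and calibrates
the observed count against a class-size-preserving permutation null.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import permutation_count_null, storey_qvalue

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.0, 1.0, 0.1), 1))


def completion_percentage(n_completed: int, n_attempted: int) -> float:
    """Percentage of attempted differentiations that reached harvest."""
    if n_attempted <= 0 or n_completed < 0 or n_completed > n_attempted:
        raise ValueError("need 0 <= n_completed <= n_attempted with n_attempted > 0")
    return 100.0 * n_completed / n_attempted


def strongest_at_best_percentage(n_strongest: int, n_union: int) -> float:
    """Share of union DE genes whose strongest p-value sits at the chosen threshold."""
    if n_union <= 0 or not 0 <= n_strongest <= n_union:
        raise ValueError("need 0 <= n_strongest <= n_union with n_union > 0")
    return 100.0 * n_strongest / n_union


def assign_outcome(
    estimates: pd.DataFrame | pd.Series,
    terminated_lines: Iterable[str] = (),
    cm_column: str = "CM",
) -> pd.DataFrame:
    """Build the per-line fate table from deconvolution estimates.

    Completed lines take their CM fraction from ``estimates`` (a fraction
    DataFrame or a plain Series); terminated lines are assigned 0.  The two
    identifier sets must be disjoint and free of duplicates.
    """
    if isinstance(estimates, pd.DataFrame):
        cm = estimates[cm_column]
    else:
        cm = estimates
    terminated = list(terminated_lines)
    all_ids = list(cm.index) + terminated
    if len(set(all_ids)) != len(all_ids):
        dup = sorted({x for x in all_ids if all_ids.count(x) > 1})
        raise ValueError(f"duplicate line identifiers: {dup}")
    table = pd.DataFrame(
        {
            "cm_fraction": list(cm.to_numpy(dtype=float)) + [0.0] * len(terminated),
            "terminated": [False] * len(cm) + [True] * len(terminated),
        },
        index=pd.Index(all_ids, name="line"),
    )
    if np.any(table["cm_fraction"] < 0) or np.any(table["cm_fraction"] > 1):
        raise ValueError("cm_fraction must lie in [0, 1]")
    return table


def fate_labels(fate_table: pd.DataFrame, threshold: float) -> pd.Series:
    """CM/EPDC labels at a threshold: CM iff cm_fraction >= threshold."""
    return pd.Series(
        np.where(fate_table["cm_fraction"] >= threshold, "CM", "EPDC"),
        index=fate_table.index,
        name="fate",
    )


def filter_expressed(
    expr: pd.DataFrame,
    min_mean_tpm: float = 1.0,
    gene_chrom: Mapping[str, str] | pd.Series | None = None,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Keep expressed genes (mean TPM >= cutoff), optionally autosomal only."""
    keep = expr.mean(axis=1) >= min_mean_tpm
    if gene_chrom is not None and autosomes_only:
        chrom = pd.Series(gene_chrom).reindex(expr.index)
        sex_mito = chrom.str.replace("chr", "", regex=False).isin(["X", "Y", "M", "MT"])
        keep &= ~sex_mito.fillna(False)
    return expr.loc[keep]


def differential_expression(
    expr: pd.DataFrame,
    labels: pd.Series,
    q_cut: float = 0.1,
    positive_class: str = "CM",
) -> pd.DataFrame:
    """Per-gene Welch t-test between the two fate classes on log2(TPM + 1).

    ``mean_diff`` is signed positive-class minus the other (positive values
    mean overexpression in CM-fated lines).  Multiple testing is handled by
    Storey q-values; ``significant`` flags q < q_cut.
    """
    lab = labels.reindex(expr.columns)
    classes = pd.unique(lab.dropna())
    if len(classes) != 2:
        raise ValueError(f"labels must contain exactly two classes, got {list(classes)}")
    if positive_class not in classes:
        positive_class = sorted(classes)[0]
    other = [c for c in classes if c != positive_class][0]
    a_cols = lab.index[lab == positive_class]
    b_cols = lab.index[lab == other]
    if len(a_cols) < 3 or len(b_cols) < 3:
        raise ValueError(
            f"each class needs at least 3 samples (got {len(a_cols)} {positive_class}, "
            f"{len(b_cols)} {other})"
        )
    a = np.log2(expr[a_cols].to_numpy(dtype=float) + 1.0)
    b = np.log2(expr[b_cols].to_numpy(dtype=float) + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = sps.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.where(np.isfinite(p), p, 1.0)
    t = np.where(np.isfinite(t), t, 0.0)
    qres = storey_qvalue(p)
    out = pd.DataFrame(
        {
            "t": t,
            "p": p,
            "q": qres.qvalues,
            "mean_diff": a.mean(axis=1) - b.mean(axis=1),
        },
        index=expr.index,
    )
    out["significant"] = out["q"] < q_cut
    out.attrs["pi0"] = qres.pi0
    out.attrs["n_positive"] = len(a_cols)
    out.attrs["n_other"] = len(b_cols)
    return out


@dataclass
class SweepResult:
    """Outcome of the fate-threshold sweep.

    ``de_counts`` maps each tested threshold to its count of q-significant
    genes; ``pvalue_profile`` holds, for every gene significant at one or
    more thresholds (the union), its per-threshold p-values.
    ``strongest_at_best`` counts union genes whose minimum p occurs at the
    selected threshold.  ``null_counts`` is the permutation null of the DE
    count at the selected threshold.
    """

    thresholds: tuple[float, ...]
    skipped_thresholds: tuple[float, ...]
    de_counts: pd.Series
    best_threshold: float
    pvalue_profile: pd.DataFrame
    strongest_at_best: int
    null_counts: np.ndarray
    best_table: pd.DataFrame
    q_cut: float
    class_sizes: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def de_gene_union(self) -> list[str]:
        return list(self.pvalue_profile.index)

    def summary(self) -> dict:
        union = len(self.pvalue_profile)
        return {
            "best_threshold": self.best_threshold,
            "n_union": union,
            "de_count_at_best": int(self.de_counts.loc[self.best_threshold]),
            "strongest_at_best": self.strongest_at_best,
            "strongest_at_best_pct": (
                strongest_at_best_percentage(self.strongest_at_best, union) if union else float("nan")
            ),
            "null_max": float(np.max(self.null_counts)) if self.null_counts.size else float("nan"),
        }


def threshold_sweep(
    expr: pd.DataFrame,
    fate_table: pd.DataFrame,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    q_cut: float = 0.1,
    n_perm: int = 100,
    seed: int = 0,
) -> SweepResult:
    """Run differential expression at each candidate threshold and pick the best.

    Thresholds yielding fewer than three lines in either class are skipped
    and reported.  The best threshold is the argmax of the q-significant
    gene count, with ties broken toward the smaller threshold.  A
    class-size-preserving permutation null of the count is attached at the
    best threshold.
    """
    shared = fate_table.index.intersection(expr.columns)
    if len(shared) < 6:
        raise ValueError("fate table and expression matrix share too few lines")
    expr = expr[shared]
    fate_table = fate_table.loc[shared]

    tested: list[float] = []
    skipped: list[float] = []
    counts: dict[float, int] = {}
    tables: dict[float, pd.DataFrame] = {}
    sizes = []
    for thr in thresholds:
        lab = fate_labels(fate_table, thr)
        n_cm = int((lab == "CM").sum())
        n_ep = int((lab == "EPDC").sum())
        if min(n_cm, n_ep) < 3:
            skipped.append(float(thr))
            continue
        de = differential_expression(expr, lab, q_cut=q_cut)
        tested.append(float(thr))
        counts[float(thr)] = int(de["significant"].sum())
        tables[float(thr)] = de
        sizes.append((float(thr), n_cm, n_ep))
    if not tested:
        raise ValueError("all thresholds were skipped (fewer than 3 lines per class)")

    de_counts = pd.Series(counts).loc[tested]
    best = float(de_counts.index[np.argmax(de_counts.to_numpy())])  # ties -> smaller threshold

    union_genes = sorted(
        set().union(*[tables[t].index[tables[t]["significant"]] for t in tested])
    )
    profile = pd.DataFrame(
        {t: tables[t].loc[union_genes, "p"] for t in tested}, index=union_genes
    )
    if union_genes:
        argmin = profile.to_numpy().argmin(axis=1)  # ties -> smallest threshold
        strongest = int((profile.columns[argmin] == best).sum())
    else:
        strongest = 0

    best_labels = fate_labels(fate_table, best)

    def count_stat(perm_labels: np.ndarray) -> float:
        lab = pd.Series(perm_labels, index=expr.columns)
        de = differential_expression(expr, lab, q_cut=q_cut)
        return float(de["significant"].sum())

    null_counts = permutation_count_null(count_stat, best_labels.to_numpy(), n_perm=n_perm, seed=seed)

    return SweepResult(
        thresholds=tuple(tested),
        skipped_thresholds=tuple(skipped),
        de_counts=de_counts,
        best_threshold=best,
        pvalue_profile=profile,
        strongest_at_best=strongest,
        null_counts=null_counts,
        best_table=tables[best],
        q_cut=q_cut,
        class_sizes=pd.DataFrame(sizes, columns=["threshold", "n_CM", "n_EPDC"]).set_index("threshold"),
    )


def finalize_signature(
    sweep: SweepResult,
    borderline_p: float = 0.0015,
    pathway_annotations: Mapping[str, set] | None = None,
) -> pd.DataFrame:
    """Final signature: q-significant genes plus annotated borderline genes.

    A gene missing q-significance at the best threshold is rescued when its
    nominal (two-sided) p there is below ``borderline_p`` and it carries at
    least one pathway annotation (WNT / muscle-cardiac / EMT style).  Each
    signature gene carries direction = sign of the CM-minus-EPDC mean
    difference.
    """
    annotations = pathway_annotations or {}
    best = sweep.best_table
    sig_mask = best["significant"]
    annotated = pd.Series(
        [len(annotations.get(g, ())) > 0 for g in best.index], index=best.index
    )
    borderline_mask = ~sig_mask & (best["p"] < borderline_p) & annotated
    keep = best[sig_mask | borderline_mask].copy()
    keep["direction"] = np.sign(keep["mean_diff"]).astype(int)
    keep["borderline"] = borderline_mask[keep.index]
    return keep[["direction", "p", "q", "mean_diff", "borderline"]]
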