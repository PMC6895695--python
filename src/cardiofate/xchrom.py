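"""Allelic imbalance on the X chromosome.

The allelic imbalance fraction (AIF) of a gene in a sample is the fraction
of reads from the higher-expressed allele: 0.5 means balanced biallelic
expression (both X chromosomes active, XaXa), values near 1 mean
monoallelic expression (one X inactive, XaXi).  Genes in the
pseudoautosomal regions escape X-inactivation by construction and are
masked from chrX statistics; annotated escape genes can be stratified.
Coordinates are 1-based inclusive throughout.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

#: chrX pseudoautosomal regions, 1-based inclusive
PAR1 = (60_001, 2_699_520)
PAR2 = (154_931_044, 155_260_560)

_CHRX = {"chrX", "X"}


def compute_aif(counts: pd.DataFrame, min_coverage: int = 20) -> pd.DataFrame:
    """Per gene-sample AIF = max(ref, alt) / (ref + alt).

    Rows with total coverage below ``min_coverage`` are dropped; the tally
    of dropped rows is recorded in ``.attrs['n_low_coverage']``.
    """
    req = {"gene", "chrom", "sample", "ref_count", "alt_count"}
    missing = req - set(counts.columns)
    if missing:
        raise ValueError(f"allele-count table lacks columns: {sorted(missing)}")
    ref = counts["ref_count"].to_numpy()
    alt = counts["alt_count"].to_numpy()
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("allele counts must be nonnegative")
    total = ref + alt
    keep = total >= min_coverage
    table = counts.loc[keep].copy()
    tot = total[keep].astype(float)
    table["aif"] = np.maximum(ref[keep], alt[keep]) / tot
    table["total"] = tot.astype(int)
    if "is_par" not in table.columns:
        table["is_par"] = False
    if "escape_status" not in table.columns:
        table["escape_status"] = "unknown"
    table.attrs["n_low_coverage"] = int((~keep).sum())
    return table


def mask_par(
    table: pd.DataFrame,
    par1: tuple[int, int] = PAR1,
    par2: tuple[int, int] = PAR2,
) -> pd.DataFrame:
    """Flag chrX genes overlapping either pseudoautosomal interval.

    Any base of overlap masks the gene (``is_par=True``); downstream chrX
    statistics exclude masked rows.  Autosomal rows are untouched.
    """
    for lo, hi in (par1, par2):
        if lo > hi:
            raise ValueError(f"malformed interval {lo}-{hi} (start > end)")
    out = table.copy()
    if not {"start", "end"} <= set(out.columns):
        raise ValueError("PAR masking needs start/end gene coordinates")
    on_x = out["chrom"].isin(_CHRX)
    overlap = np.zeros(len(out), dtype=bool)
    for lo, hi in (par1, par2):
        overlap |= (out["start"].to_numpy() <= hi) & (out["end"].to_numpy() >= lo)
    out["is_par"] = on_x.to_numpy() & overlap
    return out


def annotate_escape(table: pd.DataFrame, escape_annotations: Mapping[str, str]) -> pd.DataFrame:
    """Attach escape / non_escape / unknown status per gene."""
    out = table.copy()
    out["escape_status"] = out["gene"].map(lambda g: escape_annotations.get(g, "unknown"))
    return out


def _scope_values(table: pd.DataFrame, scope: str) -> pd.DataFrame:
    if scope == "chrX":
        return table[table["chrom"].isin(_CHRX) & ~table["is_par"]]
    if scope == "autosomes":
        return table[~table["chrom"].isin(_CHRX)]
    raise ValueError(f"unknown scope {scope!r}")


def compare_aif_groups(
    table: pd.DataFrame,
    grouping: Mapping[str, str] | pd.Series,
    scope: str = "chrX",
) -> tuple[float, float]:
    """Mann-Whitney U on pooled gene-sample AIF values between two groups.

    ``grouping`` maps sample -> group label (exactly two labels after the
    scope filter).  Returns (U statistic, two-sided p with normal
    approximation and tie correction).
    """
    sub = _scope_values(table, scope)
    groups = pd.Series(dict(grouping) if not isinstance(grouping, pd.Series) else grouping)
    g = sub["sample"].map(groups)
    labels = [l for l in pd.unique(g.dropna())]
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    x = sub.loc[g == labels[0], "aif"].to_numpy()
    y = sub.loc[g == labels[1], "aif"].to_numpy()
    if x.size == 0 or y.size == 0:
        raise ValueError("a group is empty after scope filtering")
    u, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(u), float(p)


def aif_difference_profile(
    table: pd.DataFrame,
    group_a: Iterable[str],
    group_b: Iterable[str],
    intervals: Mapping[str, tuple[int, int]] | None = None,
    escape_annotations: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-gene AIF differences along chrX and per-interval tests.

    Delta AIF(gene) = mean AIF in ``group_a`` minus mean in ``group_b``
    (the sign convention is explicit in the output columns).  For each
    named chrX interval the member genes' deltas are tested against zero
    with a one-sample Wilcoxon; escape and non-escape strata are tested
    separately when annotations are supplied.  Intervals without genes are
    reported as not testable rather than raising.
    """
    ga, gb = set(group_a), set(group_b)
    if ga & gb:
        raise ValueError("group_a and group_b must be disjoint")
    sub = _scope_values(table, "chrX")
    if escape_annotations is not None:
        sub = annotate_escape(sub, escape_annotations)
    pos = sub.groupby("gene")[["start", "end"]].first()
    mean_a = sub[sub["sample"].isin(ga)].groupby("gene")["aif"].mean()
    mean_b = sub[sub["sample"].isin(gb)].groupby("gene")["aif"].mean()
    shared = mean_a.index.intersection(mean_b.index)
    delta = pd.DataFrame(
        {
            "start": pos.loc[shared, "start"],
            "end": pos.loc[shared, "end"],
            "mean_aif_a": mean_a.loc[shared],
            "mean_aif_b": mean_b.loc[shared],
            "delta_aif": mean_a.loc[shared] - mean_b.loc[shared],
        }
    )
    delta["escape_status"] = (
        sub.groupby("gene")["escape_status"].first().reindex(shared).fillna("unknown")
    )

    def _wilcoxon(vals: np.ndarray) -> float:
        vals = vals[np.isfinite(vals)]
        if vals.size < 3 or np.allclose(vals, 0):
            return np.nan
        try:
            return float(sps.wilcoxon(vals)[1])
        except ValueError:
            return np.nan

    rows = []
    for name, (lo, hi) in (intervals or {}).items():
        members = delta[(delta["start"] <= hi) & (delta["end"] >= lo)]
        strata = {"all": members}
        if escape_annotations is not None:
            strata["escape"] = members[members["escape_status"] == "escape"]
            strata["non_escape"] = members[members["escape_status"] == "non_escape"]
        for stratum, df in strata.items():
            p = _wilcoxon(df["delta_aif"].to_numpy())
            rows.append(
                {
                    "interval": name,
                    "stratum": stratum,
                    "n_genes": len(df),
                    "mean_delta_aif": float(df["delta_aif"].mean()) if len(df) else np.nan,
                    "p": p,
                    "testable": bool(len(df) >= 3 and np.isfinite(p)),
                }
            )
    tests = pd.DataFrame(rows)
    return delta, tests
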