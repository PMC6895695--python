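"""Gene-set enrichment on the CM-vs-EPDC expression contrast.

The input statistic is a per-gene normalized mean expression difference
between the two fate groups; each gene set is then compared against the
background with a two-sample t-test on member vs non-member statistics
(the unpaired, group-on-group mode of classical parametric set testing).
FDR correction is applied independently within each collection.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import storey_qvalue


def contrast_statistic(
    expr: pd.DataFrame,
    labels: pd.Series,
    positive_class: str = "CM",
) -> pd.DataFrame:
    """Normalized mean expression difference per gene on log2(TPM + 1).

    stat = (mean_CM - mean_EPDC) / pooled standard error; positive values
    mean higher expression in the positive (CM-fated) class.  Genes with
    zero pooled variance get statistic 0 and a flag.
    """
    lab = labels.reindex(expr.columns)
    classes = pd.unique(lab.dropna())
    if len(classes) != 2:
        raise ValueError("labels must contain exactly two classes")
    if positive_class not in classes:
        positive_class = sorted(classes)[0]
    other = [c for c in classes if c != positive_class][0]
    a = np.log2(expr[lab.index[lab == positive_class]].to_numpy(dtype=float) + 1.0)
    b = np.log2(expr[lab.index[lab == other]].to_numpy(dtype=float) + 1.0)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 3 or n2 < 3:
        raise ValueError("each class needs at least 3 samples")
    diff = a.mean(axis=1) - b.mean(axis=1)
    sp2 = ((n1 - 1) * a.var(axis=1, ddof=1) + (n2 - 1) * b.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    zero_var = se == 0
    stat = np.zeros_like(diff)
    stat[~zero_var] = diff[~zero_var] / se[~zero_var]
    return pd.DataFrame({"stat": stat, "zero_variance": zero_var}, index=expr.index)


def gene_set_test(
    stats: pd.Series,
    collections: Mapping[str, Mapping[str, Sequence[str]]],
    min_size: int = 10,
) -> pd.DataFrame:
    """Two-sample t-test of member vs non-member statistics per gene set.

    Both one-sided directions are evaluated and the smaller-p direction is
    reported (``up_in_CM`` when members exceed the background).  Storey
    q-values are computed independently within each collection; sets
    smaller than ``min_size`` after restriction to scored genes are dropped
    and tallied in ``.attrs['n_dropped']``.
    """
    s = stats.dropna()
    universe = set(s.index)
    rows = []
    n_dropped = 0
    for collection, sets in collections.items():
        for name, genes in sets.items():
            members = sorted(universe & set(genes))
            if len(members) < min_size:
                n_dropped += 1
                continue
            x = s.loc[members].to_numpy()
            y = s.drop(index=members).to_numpy()
            t, p_two = sps.ttest_ind(x, y, equal_var=False)
            p_up = p_two / 2 if t > 0 else 1 - p_two / 2
            p_down = p_two / 2 if t < 0 else 1 - p_two / 2
            direction = "up_in_CM" if p_up <= p_down else "down_in_CM"
            # report the smaller-p direction; the p itself is two-sided
            # (doubled one-sided minimum) so it is uniform under the null
            rows.append(
                {
                    "set_name": name,
                    "collection": collection,
                    "size_used": len(members),
                    "direction": direction,
                    "t": float(t),
                    "p": float(min(1.0, 2.0 * min(p_up, p_down))),
                }
            )
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = np.nan
        for collection, idx in out.groupby("collection").groups.items():
            out.loc[idx, "q"] = storey_qvalue(out.loc[idx, "p"].to_numpy()).qvalues
    out.attrs["n_dropped"] = n_dropped
    return out


def female_only(expr: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Restrict samples to female lines (chrX analyses use females only)."""
    fem = metadata.index[metadata["sex"] == "F"]
    return expr[[c for c in expr.columns if c in set(fem)]]
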