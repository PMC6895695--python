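"""Fate assignment, differential expression, and the threshold sweep."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cardiofate import synthetic
from cardiofate.fate import (
    assign_outcome,
    completion_percentage,
    differential_expression,
    fate_labels,
    filter_expressed,
    finalize_signature,
    strongest_at_best_percentage,
    threshold_sweep,
)


class TestAssignOutcome:
    def test_terminated_lines_are_epdc_at_every_positive_threshold(self):
        est = pd.DataFrame({"CM": [0.8, 0.4]}, index=["a", "b"])
        table = assign_outcome(est, ["t1", "t2"])
        assert table.loc["t1", "cm_fraction"] == 0.0
        for thr in (0.1, 0.3, 0.9):
            lab = fate_labels(table, thr)
            assert lab["t1"] == "EPDC"

    def test_boundary_rule_is_greater_equal(self):
        table = assign_outcome(pd.Series([0.30, 0.299], index=["x", "y"]), [])
        lab = fate_labels(table, 0.3)
        assert lab["x"] == "CM"  # produced >= 30% CMs
        assert lab["y"] == "EPDC"

    def test_duplicate_identifiers_rejected(self):
        est = pd.DataFrame({"CM": [0.8]}, index=["a"])
        with pytest.raises(ValueError, match="duplicate"):
            assign_outcome(est, ["a"])

    def test_bookkeeping_helpers(self):
        assert completion_percentage(193, 232) == pytest.approx(83.2, abs=0.05)
        assert strongest_at_best_percentage(55, 116) == pytest.approx(47.4, abs=0.05)


class TestDifferentialExpression:
    def test_single_gene_matches_welch_formula(self, rng):
        a_vals = np.array([5.1, 4.8, 5.6, 5.0, 5.3])
        b_vals = np.array([3.9, 4.2, 4.0, 4.4, 3.7])
        expr = pd.DataFrame(
            [np.concatenate([2**a_vals - 1, 2**b_vals - 1])],
            index=["g1"],
            columns=[f"s{i}" for i in range(10)],
        )
        labels = pd.Series(["CM"] * 5 + ["EPDC"] * 5, index=expr.columns)
        res = differential_expression(expr, labels)
        t_ref, p_ref = sps.ttest_ind(a_vals, b_vals, equal_var=False)
        assert res.loc["g1", "t"] == pytest.approx(t_ref, abs=1e-10)
        assert res.loc["g1", "p"] == pytest.approx(p_ref, abs=1e-10)
        assert res.loc["g1", "mean_diff"] == pytest.approx(a_vals.mean() - b_vals.mean(), abs=1e-9)

    def test_null_data_yields_uniform_p_and_no_calls(self, rng):
        expr = pd.DataFrame(
            rng.lognormal(1, 0.5, size=(400, 60)),
            index=[f"g{i}" for i in range(400)],
            columns=[f"s{i}" for i in range(60)],
        )
        labels = pd.Series(["CM"] * 35 + ["EPDC"] * 25, index=expr.columns)
        res = differential_expression(expr, labels)
        assert res["significant"].sum() <= 2
        ks = sps.kstest(res["p"], "uniform")
        assert ks.pvalue > 0.01

    def test_planted_shift_power(self, rng):
        recovered = []
        for seed in range(5):
            r = np.random.default_rng(seed)
            n1, n2 = 60, 30
            base = r.normal(4, 1, size=(500, n1 + n2))
            base[:50, :n1] += 2.0  # 2-sd shift in 50 genes
            expr = pd.DataFrame(
                2.0**base - 1,
                index=[f"g{i}" for i in range(500)],
                columns=[f"s{i}" for i in range(n1 + n2)],
            )
            labels = pd.Series(["CM"] * n1 + ["EPDC"] * n2, index=expr.columns)
            res = differential_expression(expr, labels)
            recovered.append(res["significant"][:50].sum())
        assert np.mean(recovered) >= 45

    def test_small_class_rejected(self, rng):
        expr = pd.DataFrame(rng.lognormal(1, 0.5, size=(10, 6)), columns=[f"s{i}" for i in range(6)])
        labels = pd.Series(["CM"] * 4 + ["EPDC"] * 2, index=expr.columns)
        with pytest.raises(ValueError, match="at least 3"):
            differential_expression(expr, labels)


@pytest.fixture(scope="module")
def planted_sweep(profiles):
    cohort = synthetic.simulate_ipsc_cohort(
        profiles,
        n_lines=120,
        n_terminated=20,
        n_signature=50,
        effect_size=1.5,
        fate_dist="boundary",
        coupling="step",
        step_threshold=0.3,
        effect_profile="exponential",
        seed=31,
    )
    table = assign_outcome(cohort.cm_fraction.drop(cohort.terminated_lines), cohort.terminated_lines)
    sweep = threshold_sweep(cohort.ipsc_expr, table, n_perm=30, seed=31)
    return cohort, table, sweep


class TestThresholdSweep:
    def test_recovers_planted_partition(self, planted_sweep):
        _, _, sweep = planted_sweep
        assert sweep.best_threshold == pytest.approx(0.3)

    def test_observed_count_exceeds_permutation_null(self, planted_sweep):
        _, _, sweep = planted_sweep
        observed = sweep.de_counts.loc[sweep.best_threshold]
        assert observed > sweep.null_counts.max()

    def test_strongest_at_best_bookkeeping(self, planted_sweep):
        _, _, sweep = planted_sweep
        assert 0 <= sweep.strongest_at_best <= len(sweep.de_gene_union)
        s = sweep.summary()
        assert s["n_union"] == len(sweep.de_gene_union)

    def test_sample_and_gene_order_invariance(self, planted_sweep, rng):
        cohort, table, sweep = planted_sweep
        expr = cohort.ipsc_expr
        perm_cols = rng.permutation(expr.columns)
        perm_rows = rng.permutation(expr.index)
        shuffled = expr.loc[perm_rows, perm_cols]
        sweep2 = threshold_sweep(shuffled, table.loc[perm_cols], n_perm=1, seed=31)
        assert sweep2.best_threshold == sweep.best_threshold
        pd.testing.assert_series_equal(sweep2.de_counts, sweep.de_counts)

    def test_global_null_count_within_null_range(self, profiles):
        cohort = synthetic.simulate_ipsc_cohort(
            profiles, n_lines=60, n_terminated=10, n_signature=10, effect_size=0.0, seed=37
        )
        table = assign_outcome(
            cohort.cm_fraction.drop(cohort.terminated_lines), cohort.terminated_lines
        )
        sweep = threshold_sweep(cohort.ipsc_expr.iloc[:600], table, n_perm=50, seed=37)
        observed = sweep.de_counts.loc[sweep.best_threshold]
        assert sweep.null_counts.min() <= observed <= max(sweep.null_counts.max(), 2)

    def test_degenerate_thresholds_skipped(self, planted_sweep):
        _, _, sweep = planted_sweep
        assert 0.0 in sweep.skipped_thresholds  # everyone is CM at threshold 0
        assert all(t not in sweep.thresholds for t in sweep.skipped_thresholds)


class TestFinalizeSignature:
    def test_borderline_rescue_requires_annotation(self, planted_sweep):
        _, _, sweep = planted_sweep
        best = sweep.best_table
        # pick the strongest non-significant gene and set the borderline
        # cutoff just above it, so the rescue rule is exercised by construction
        candidates = best[~best["significant"]].sort_values("p")
        g = candidates.index[0]
        cut = float(candidates["p"].iloc[0]) * 1.01
        with_annot = finalize_signature(sweep, borderline_p=cut, pathway_annotations={g: {"WNT"}})
        without = finalize_signature(sweep, borderline_p=cut, pathway_annotations={g: set()})
        assert g in with_annot.index
        assert g not in without.index
        assert bool(with_annot.loc[g, "borderline"])
        assert not without["borderline"].any()

    def test_no_annotations_gives_q_significant_set(self, planted_sweep):
        _, _, sweep = planted_sweep
        sig = finalize_signature(sweep)
        expected = set(sweep.best_table.index[sweep.best_table["significant"]])
        assert set(sig.index) == expected
        assert set(sig["direction"].unique()) <= {-1, 1}


class TestFilterExpressed:
    def test_drops_low_expression_and_sex_chromosomes(self):
        expr = pd.DataFrame(
            {"s1": [10.0, 0.1, 20.0], "s2": [12.0, 0.2, 25.0]},
            index=["g_auto", "g_low", "g_x"],
        )
        chrom = pd.Series({"g_auto": "chr1", "g_low": "chr2", "g_x": "chrX"})
        out = filter_expressed(expr, min_mean_tpm=1.0, gene_chrom=chrom)
        assert list(out.index) == ["g_auto"]
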