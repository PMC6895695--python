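"""Allelic imbalance fractions, PAR masking, and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from cardiofate import synthetic
from cardiofate.xchrom import (
    aif_difference_profile,
    compare_aif_groups,
    compute_aif,
    mask_par,
)


def _counts(rows):
    return pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "sample", "ref_count", "alt_count"]
    )


class TestComputeAif:
    def test_arithmetic(self):
        table = compute_aif(
            _counts(
                [
                    ("g1", "chr1", 1, 100, "s1", 50, 50),
                    ("g2", "chr1", 1, 100, "s1", 99, 1),
                    ("g3", "chr1", 1, 100, "s1", 1, 99),
                ]
            ),
            min_coverage=20,
        )
        assert table.set_index("gene")["aif"].tolist() == [0.5, 0.99, 0.99]

    def test_low_coverage_rows_dropped_and_tallied(self):
        table = compute_aif(
            _counts(
                [
                    ("g1", "chr1", 1, 100, "s1", 3, 2),
                    ("g2", "chr1", 1, 100, "s1", 30, 10),
                ]
            ),
            min_coverage=20,
        )
        assert list(table["gene"]) == ["g2"]
        assert table.attrs["n_low_coverage"] == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            compute_aif(_counts([("g1", "chr1", 1, 100, "s1", -1, 10)]))

    def test_ref_alt_swap_invariance(self, rng):
        ref = rng.integers(0, 200, 50)
        alt = rng.integers(0, 200, 50)
        rows = [(f"g{i}", "chr1", 1, 100, "s1", int(r), int(a)) for i, (r, a) in enumerate(zip(ref, alt))]
        swapped = [(g, c, s, e, sm, a, r) for g, c, s, e, sm, r, a in rows]
        t1 = compute_aif(_counts(rows), min_coverage=1)
        t2 = compute_aif(_counts(swapped), min_coverage=1)
        np.testing.assert_array_equal(t1["aif"].to_numpy(), t2["aif"].to_numpy())

    def test_min_coverage_stabilizes_aif(self, cohort):
        # higher coverage cutoffs shrink the folding bias of balanced genes
        sim = synthetic.simulate_ase_counts(cohort, depth=120, seed=9)
        means = []
        for cov in (20, 60, 100):
            t = compute_aif(sim.counts, min_coverage=cov)
            auto = t[~t["chrom"].isin(["chrX"])]
            means.append(auto["aif"].mean())
        assert means[0] >= means[-1] - 0.005
        assert 0.5 <= means[0] <= 0.55


class TestMaskPar:
    def test_fixture_genes_masked_exactly(self, par_gene_fixture):
        table = compute_aif(par_gene_fixture, min_coverage=20)
        masked = mask_par(table)
        got = masked.set_index("gene")["is_par"]
        expected = par_gene_fixture.set_index("gene")["expect_par"]
        pd.testing.assert_series_equal(got, expected.loc[got.index], check_names=False)

    def test_straddling_gene_masked_by_any_overlap(self):
        table = compute_aif(
            _counts([("g1", "chrX", 2_699_000, 2_705_000, "s1", 30, 30)]), min_coverage=1
        )
        assert mask_par(table)["is_par"].iloc[0]

    def test_malformed_interval_rejected(self, par_gene_fixture):
        table = compute_aif(par_gene_fixture, min_coverage=1)
        with pytest.raises(ValueError, match="start > end"):
            mask_par(table, par1=(100, 50))


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        rows = []
        for s in ("a1", "a2", "b1", "b2"):
            for i in range(30):
                rows.append((f"g{i}", "chrX", 3_000_000 + i, 3_000_100 + i, s, 40, 40 + i % 7))
        table = mask_par(compute_aif(_counts(rows), min_coverage=1))
        u, p = compare_aif_groups(table, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert p > 0.5

    def test_planted_xi_vs_xa_separation(self, cohort):
        sim = synthetic.simulate_ase_counts(cohort, depth=200, seed=10)
        table = mask_par(compute_aif(sim.counts, min_coverage=20))
        xi = cohort.xi_truth
        grouping = xi["state"][xi["state"].isin(["XaXa", "XaXi"])]
        u, p = compare_aif_groups(table, grouping, scope="chrX")
        assert p < 1e-4

    def test_autosomal_scope_is_null(self, cohort):
        sim = synthetic.simulate_ase_counts(cohort, depth=200, seed=10)
        table = mask_par(compute_aif(sim.counts, min_coverage=20))
        xi = cohort.xi_truth
        grouping = xi["state"][xi["state"].isin(["XaXa", "XaXi"])]
        u, p = compare_aif_groups(table, grouping, scope="autosomes")
        assert p > 0.01

    def test_empty_group_rejected(self, par_gene_fixture):
        table = mask_par(compute_aif(par_gene_fixture, min_coverage=1))
        with pytest.raises(ValueError):
            compare_aif_groups(table, {"S1": "A"})


class TestDifferenceProfile:
    @staticmethod
    def _two_group_table(reactivated_interval=(3_000_000, 40_000_000), seed=0):
        """Group A biallelic inside one interval, monoallelic elsewhere;
        group B monoallelic on all non-escape chrX genes."""
        rng = np.random.default_rng(seed)
        rows = []
        positions = np.linspace(3_000_000, 150_000_000, 40).astype(int)
        for s, group in [(f"a{i}", "A") for i in range(8)] + [(f"b{i}", "B") for i in range(8)]:
            for g, pos in enumerate(positions):
                inside = reactivated_interval[0] <= pos <= reactivated_interval[1]
                p_mono = 0.5 if (group == "A" and inside) else 0.98
                total = 200
                ref = rng.binomial(total, p_mono)
                rows.append((f"xg{g}", "chrX", pos, pos + 1000, s, ref, total - ref))
        return _counts(rows)

    def test_identical_composition_gives_zero_delta(self):
        # two disjoint sample sets with identical per-gene counts
        rows = []
        for s in ("a0", "a1", "b0", "b1"):
            for g in range(10):
                pos = 3_000_000 + 10_000 * g
                rows.append((f"xg{g}", "chrX", pos, pos + 1000, s, 150, 50))
        table = mask_par(compute_aif(_counts(rows), min_coverage=20))
        delta, _ = aif_difference_profile(table, ["a0", "a1"], ["b0", "b1"], intervals={})
        assert np.allclose(delta["delta_aif"], 0.0)

    def test_localized_reactivation_detected(self):
        hits, misses = 0, 0
        for seed in range(5):
            table = mask_par(compute_aif(self._two_group_table(seed=seed), min_coverage=20))
            intervals = {
                "reactivated": (3_000_000, 40_000_000),
                "quiet": (100_000_000, 150_000_000),
            }
            _, tests = aif_difference_profile(
                table,
                [f"a{i}" for i in range(8)],
                [f"b{i}" for i in range(8)],
                intervals=intervals,
            )
            t = tests.set_index(["interval", "stratum"])
            hits += t.loc[("reactivated", "all"), "p"] < 0.05
            misses += t.loc[("quiet", "all"), "p"] > 0.05
        assert hits >= 4
        assert misses >= 4

    def test_empty_interval_reported_not_raised(self):
        table = mask_par(compute_aif(self._two_group_table(), min_coverage=20))
        _, tests = aif_difference_profile(
            table,
            [f"a{i}" for i in range(8)],
            [f"b{i}" for i in range(8)],
            intervals={"empty": (160_000_000, 161_000_000)},
        )
        row = tests.set_index("interval").loc["empty"]
        assert not row["testable"]

    def test_overlapping_groups_rejected(self):
        table = mask_par(compute_aif(self._two_group_table(), min_coverage=20))
        with pytest.raises(ValueError, match="disjoint"):
            aif_difference_profile(table, ["a0", "a1"], ["a1", "b0"])
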