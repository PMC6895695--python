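"""Covariate GLM, variant scan, and relatedness concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from cardiofate import synthetic
from cardiofate.association import (
    covariate_glm,
    genomic_inflation,
    relatedness_concordance,
    variant_scan,
)


def _newton_logistic(X, y, iters=60):
    """Independent Newton-Raphson oracle for plain logistic regression."""
    beta = np.zeros(X.shape[1])
    for _ in range(iters):
        p = 1 / (1 + np.exp(-X @ beta))
        W = p * (1 - p)
        H = (X.T * W) @ X
        beta = beta + np.linalg.solve(H, X.T @ (y - p))
    return beta


class TestCovariateGlm:
    def test_matches_newton_oracle_on_six_lines(self):
        meta = pd.DataFrame(
            {"age": [25.0, 31.0, 40.0, 29.0, 35.0, 50.0]},
            index=[f"L{i}" for i in range(6)],
        )
        fate = pd.Series([0, 1, 1, 0, 1, 0], index=meta.index, dtype=float)
        fit = covariate_glm(meta, fate)
        X = np.column_stack([np.ones(6), meta["age"].to_numpy()])
        oracle = _newton_logistic(X, fate.to_numpy())
        np.testing.assert_allclose(fit.table["coef"].to_numpy(), oracle, atol=1e-8)

    def test_planted_sex_effect_detected(self, profiles):
        hits = 0
        for seed in range(10):
            c = synthetic.simulate_ipsc_cohort(
                profiles, n_lines=180, n_terminated=36, n_signature=5, seed=100 + seed
            )
            labels = pd.Series(
                np.where(c.cm_fraction >= 0.3, "CM", "EPDC"), index=c.lines
            )
            fit = covariate_glm(c.metadata[["sex", "age", "ethnicity", "passage"]], labels)
            sex_term = [t for t in fit.table.index if t.startswith("sex[")][0]
            hits += fit.table.loc[sex_term, "p"] < 0.01
        assert hits >= 7  # generator's sex effect was power-calibrated near 85%

    def test_null_covariates_give_uniform_p(self):
        ps = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            meta = pd.DataFrame(
                {"age": rng.uniform(20, 70, 80), "passage": rng.integers(10, 40, 80)},
                index=[f"L{i}" for i in range(80)],
            )
            fate = pd.Series(rng.integers(0, 2, 80).astype(float), index=meta.index)
            if fate.sum() < 2 or (1 - fate).sum() < 2:
                continue
            fit = covariate_glm(meta, fate)
            ps.append(fit.table.loc["age", "p"])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_single_class_outcome_rejected(self):
        meta = pd.DataFrame({"age": [25.0, 30.0, 40.0, 50.0]}, index=list("abcd"))
        with pytest.raises(ValueError, match="per class"):
            covariate_glm(meta, pd.Series([1.0, 1.0, 1.0, 1.0], index=meta.index))

    def test_separation_falls_back_to_firth(self):
        meta = pd.DataFrame(
            {"x": [0.0, 0.1, 0.2, 0.8, 0.9, 1.0, 0.05, 0.95]},
            index=[f"L{i}" for i in range(8)],
        )
        fate = pd.Series([0, 0, 0, 1, 1, 1, 0, 1], index=meta.index, dtype=float)
        fit = covariate_glm(meta, fate)  # perfectly separated on x
        assert fit.firth
        assert np.all(np.isfinite(fit.table["coef"]))


class TestVariantScan:
    def test_null_scan_lambda_calibrated(self):
        geno = synthetic.simulate_genotypes(180, 10_000, seed=5)
        rng = np.random.default_rng(5)
        outcome = pd.Series(rng.uniform(0, 1, 180), index=geno.dosages.columns)
        res = variant_scan(geno.dosages, outcome)
        lam = genomic_inflation(res["p"])
        assert 0.9 <= lam <= 1.1
        assert not res["genome_wide"].any()

    def test_planted_causal_variant_ranks_first(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            base = rng.uniform(0.1, 0.9, 150)
            beta = synthetic.planted_beta_for_r2(0.2, base.std(), 0.3)
            geno = synthetic.simulate_genotypes(
                150, 2000, maf_range=(0.3, 0.3), causal=(17, beta), seed=seed
            )
            outcome = pd.Series(base, index=geno.dosages.columns) + geno.outcome_shift
            res = variant_scan(geno.dosages, outcome.clip(0, None))
            hits += res["p"].idxmin() == "var000017"
        assert hits >= 9

    def test_affine_outcome_rescaling_leaves_p_unchanged(self):
        geno = synthetic.simulate_genotypes(100, 300, seed=6)
        rng = np.random.default_rng(6)
        outcome = pd.Series(rng.uniform(0, 1, 100), index=geno.dosages.columns)
        p1 = variant_scan(geno.dosages, outcome)["p"]
        p2 = variant_scan(geno.dosages, 3.0 * outcome + 11.0)["p"]
        np.testing.assert_allclose(p1.to_numpy(), p2.to_numpy(), atol=1e-10)

    def test_maf_filter_excludes_rare_variants(self):
        rng = np.random.default_rng(7)
        lines = [f"L{i}" for i in range(200)]
        dos = pd.DataFrame(
            {
                "common": rng.binomial(2, 0.3, 200),
                "rare": rng.binomial(2, 0.04, 200),
                "mono": np.zeros(200),
            },
            index=lines,
        ).T
        outcome = pd.Series(rng.uniform(0, 1, 200), index=lines)
        res = variant_scan(dos, outcome, maf_min=0.05)
        assert list(res.index) == ["common"]
        assert res.attrs["n_skipped_monomorphic"] == 1
        assert res.attrs["n_filtered_maf"] == 1

    def test_covariate_adjustment_removes_confounding(self):
        rng = np.random.default_rng(8)
        lines = [f"L{i}" for i in range(200)]
        passage = rng.uniform(10, 40, 200)
        # variant correlated with passage; outcome driven only by passage
        dos = pd.DataFrame(
            {"v": np.clip(np.round(passage / 20 + rng.normal(0, 0.4, 200)), 0, 2)}, index=lines
        ).T
        outcome = pd.Series(0.02 * passage + rng.normal(0, 0.1, 200), index=lines)
        cov = pd.DataFrame({"passage": passage}, index=lines)
        p_unadj = variant_scan(dos, outcome)["p"].iloc[0]
        p_adj = variant_scan(dos, outcome, covariates=cov)["p"].iloc[0]
        assert p_adj > 1e-3
        assert p_unadj < p_adj


class TestRelatednessConcordance:
    def test_identical_clones_separate_from_unrelated(self, rng):
        outcomes = pd.Series(rng.uniform(0, 1, 40), index=[f"L{i}" for i in range(40)])
        pairs = [(f"L{2 * i}", f"L{2 * i + 1}") for i in range(8)]
        for a, b in pairs:
            outcomes[b] = outcomes[a]  # clone_correlation = 1
        within, between, u, p = relatedness_concordance(outcomes, pairs)
        assert np.all(within == 0)
        assert p < 0.01

    def test_uncorrelated_pairs_look_like_background(self):
        ps = []
        for seed in range(40):
            rng = np.random.default_rng(seed)
            outcomes = pd.Series(rng.uniform(0, 1, 40), index=[f"L{i}" for i in range(40)])
            pairs = [(f"L{2 * i}", f"L{2 * i + 1}") for i in range(8)]
            ps.append(relatedness_concordance(outcomes, pairs)[3])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_intermediate_correlation_shrinks_within_pair_differences(self, profiles):
        closer = 0
        for seed in range(10):
            c = synthetic.simulate_ipsc_cohort(
                profiles,
                n_lines=60,
                n_terminated=0,
                n_signature=5,
                n_clone_pairs=10,
                clone_correlation=0.8,
                seed=200 + seed,
            )
            within, between, _, _ = relatedness_concordance(c.cm_fraction, c.related_pairs)
            closer += np.median(within) < np.median(between)
        assert closer >= 9

    def test_too_few_pairs_rejected(self, rng):
        outcomes = pd.Series(rng.uniform(0, 1, 4), index=list("abcd"))
        with pytest.raises(ValueError):
            relatedness_concordance(outcomes, [("a", "b")])
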