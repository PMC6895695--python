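"""End-to-end orchestration on a synthetic cohort.

Stages run in dependency order: reference profiles and cohort simulation,
signature-matrix construction, bulk deconvolution, fate assignment and the
threshold sweep, per-gene and joint signature models, allelic-imbalance
analysis, covariate (and optional genotype) association, and replication
against a second, independently simulated cohort.  Every stage writes its
outputs under the run directory together with the resolved configuration;
all randomness flows from the single config seed.
"""

from __future__ import annotations

import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, deconvolution, replication, signature_model, synthetic, xchrom
from . import fate as fate_mod
from .config import RunConfig
from .io import write_tsv, write_yaml


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns a dict of key results.

    Any stage failure raises with the stage name prefixed; optional inputs
    (e.g. genotypes disabled) skip their stage with a logged notice.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config.config_hash()
    config.to_yaml(outdir / "config.resolved.yaml")
    log: list[str] = []
    results: dict = {}

    def _log(msg: str) -> None:
        log.append(msg)

    def _stage(name: str, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:
            _log(f"{name}: FAILED ({exc})")
            (outdir / "run.log").write_text("\n".join(log) + "\n")
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        _log(f"{name}: ok ({time.perf_counter() - t0:.1f}s)")
        return out

    # --- simulate ---------------------------------------------------------
    def _simulate():
        profiles = synthetic.simulate_reference_profiles(
            n_genes=config.n_genes,
            n_populations=config.n_populations,
            n_markers_per_pop=config.n_markers_per_pop,
            fold_change=config.fold_change,
            seed=config.seed,
        )
        cohort = synthetic.simulate_ipsc_cohort(
            profiles,
            n_lines=config.n_lines,
            n_terminated=config.n_terminated,
            n_signature=config.n_signature,
            effect_size=config.effect_size,
            cvpc_noise_sd=config.bulk_noise_sd,
            seed=config.seed,
        )
        return profiles, cohort

    profiles, cohort = _stage("simulate", _simulate)
    write_tsv(cohort.ipsc_expr, outdir / "ipsc_expression.tsv", "simulate", chash)
    write_tsv(cohort.cvpc_expr, outdir / "cvpc_expression.tsv", "simulate", chash)
    write_tsv(cohort.metadata, outdir / "metadata.tsv", "simulate", chash)
    write_yaml(
        {
            "signature_truth": {
                g: int(s) for g, s in cohort.signature_truth["sign"].items()
            },
            "xi_truth": {l: str(s) for l, s in cohort.xi_truth["state"].items()},
        },
        outdir / "truth.yaml",
    )

    # --- deconvolution ----------------------------------------------------
    def _deconvolve():
        reps = profiles.make_replicates(seed=config.seed)
        sig = deconvolution.build_signature_matrix(
            reps, top_n=config.top_n, p_cutoff=config.p_cutoff
        )
        est = deconvolution.estimate_fractions(cohort.cvpc_expr, sig)
        r, p = deconvolution.correlate_fraction_with_purity(
            est, cohort.metadata["cTnT_pct"], population="CM"
        )
        return sig, est, r, p

    sig_matrix, estimates, purity_r, purity_p = _stage("deconvolution", _deconvolve)
    write_tsv(sig_matrix.values, outdir / "signature_matrix.tsv", "deconvolution", chash)
    write_tsv(estimates, outdir / "fractions.tsv", "deconvolution", chash)
    results["purity_correlation_r"] = purity_r
    results["purity_correlation_p"] = purity_p
    results["signature_matrix_genes"] = int(len(sig_matrix.genes))

    # --- fate sweep -------------------------------------------------------
    def _sweep():
        fate_table = fate_mod.assign_outcome(estimates, cohort.terminated_lines)
        expr = fate_mod.filter_expressed(cohort.ipsc_expr)
        sweep = fate_mod.threshold_sweep(
            expr,
            fate_table,
            thresholds=config.thresholds,
            q_cut=config.q_cut,
            n_perm=config.n_perm,
            seed=config.seed,
        )
        signature = fate_mod.finalize_signature(sweep, borderline_p=config.borderline_p)
        return fate_table, sweep, signature

    fate_table, sweep, signature = _stage("fate_sweep", _sweep)
    write_tsv(
        pd.DataFrame({"de_count": sweep.de_counts}), outdir / "sweep_counts.tsv", "fate_sweep", chash
    )
    write_tsv(signature, outdir / "signature_genes.tsv", "fate_sweep", chash)
    write_tsv(
        pd.DataFrame({"null_count": sweep.null_counts}), outdir / "sweep_null.tsv", "fate_sweep", chash
    )
    results["best_threshold"] = sweep.best_threshold
    results.update({f"sweep_{k}": v for k, v in sweep.summary().items()})

    # --- signature model --------------------------------------------------
    def _model():
        genes = list(signature.index)
        if not genes:
            _log("signature_model: skipped (empty signature)")
            return None, None
        outcome = fate_table["cm_fraction"]
        fits = []
        for g in genes:
            try:
                fit = signature_model.fit_gene_fate_model(
                    cohort.ipsc_expr.loc[g, outcome.index], outcome, link="identity"
                )
                fits.append((g, fit.estimate, fit.se, fit.p, fit.r2))
            except ValueError:
                continue
        fits_df = pd.DataFrame(
            fits, columns=["gene", "estimate", "se", "p", "r2"]
        ).set_index("gene")
        joint = signature_model.joint_lasso_cv(
            cohort.ipsc_expr.loc[genes, outcome.index].T,
            outcome,
            folds=min(config.folds, max(2, len(outcome) // 3)),
            seed=config.seed,
        )
        return fits_df, joint

    fits_df, joint = _stage("signature_model", _model)
    if fits_df is not None:
        write_tsv(fits_df, outdir / "gene_fits.tsv", "signature_model", chash)
        write_yaml(
            {
                "lambda": joint.lambda_,
                "cv_r2_mean": joint.cv_r2_mean,
                "selected_genes": joint.selected_genes,
                "seed": joint.seed,
            },
            outdir / "joint_model.yaml",
        )
        results["joint_cv_r2"] = joint.cv_r2_mean
        results["joint_selected"] = len(joint.selected_genes)

    # --- X-chromosome allelic imbalance ----------------------------------
    def _aif():
        ase = synthetic.simulate_ase_counts(
            cohort, depth=config.ase_depth, seed=config.seed
        )
        table = xchrom.compute_aif(ase.counts, min_coverage=config.min_coverage)
        table = xchrom.mask_par(table)
        fem = cohort.xi_truth.index
        labels = fate_mod.fate_labels(fate_table, sweep.best_threshold)
        grouping = labels.loc[[l for l in fem if l in labels.index]]
        try:
            u, p = xchrom.compare_aif_groups(table, grouping, scope="chrX")
        except ValueError as exc:
            _log(f"aif: group comparison not possible ({exc})")
            u, p = np.nan, np.nan
        return table, u, p

    aif_table, aif_u, aif_p = _stage("xchrom_aif", _aif)
    write_tsv(aif_table, outdir / "aif.tsv", "xchrom_aif", chash, index=False)
    results["aif_group_p"] = aif_p

    # --- associations -----------------------------------------------------
    def _assoc():
        labels = fate_mod.fate_labels(fate_table, sweep.best_threshold)
        meta = cohort.metadata[["sex", "age", "ethnicity", "passage"]]
        fit = association.covariate_glm(meta, labels)
        scan = None
        if config.n_variants > 0:
            geno = synthetic.simulate_genotypes(
                n_lines=len(fate_table), n_variants=config.n_variants, seed=config.seed
            )
            geno.dosages.columns = fate_table.index  # align line identifiers
            scan = association.variant_scan(
                geno.dosages,
                fate_table["cm_fraction"],
                covariates=cohort.metadata[["sex", "passage"]],
                maf_min=config.maf_min,
            )
        else:
            _log("variant_scan: skipped (n_variants=0)")
        return fit, scan

    cov_fit, scan = _stage("association", _assoc)
    write_tsv(cov_fit.table, outdir / "covariate_glm.tsv", "association", chash)
    sex_terms = [t for t in cov_fit.table.index if t.startswith("sex[")]
    if sex_terms:
        results["sex_p"] = float(cov_fit.table.loc[sex_terms[0], "p"])
    if scan is not None:
        write_tsv(scan, outdir / "variant_scan.tsv", "association", chash)
        results["scan_lambda"] = association.genomic_inflation(scan["p"])

    # --- replication ------------------------------------------------------
    def _replicate():
        profiles_b = synthetic.simulate_reference_profiles(
            n_genes=config.n_genes,
            n_populations=config.n_populations,
            n_markers_per_pop=config.n_markers_per_pop,
            fold_change=config.fold_change,
            seed=config.seed + 1,
        )
        cohort_b = synthetic.simulate_ipsc_cohort(
            profiles_b,
            n_lines=config.replication_n_lines,
            n_terminated=config.replication_n_terminated,
            n_signature=config.n_signature,
            effect_size=config.effect_size,
            seed=config.seed + 1,
        )
        if signature.empty:
            _log("replication: skipped (empty signature)")
            return None
        labels_a = fate_mod.fate_labels(fate_table, sweep.best_threshold)
        contrast_a = fate_mod.differential_expression(
            cohort.ipsc_expr[labels_a.index], labels_a, q_cut=config.q_cut
        )
        fate_b = fate_mod.assign_outcome(
            cohort_b.cm_fraction.drop(cohort_b.terminated_lines), cohort_b.terminated_lines
        )
        labels_b = pd.Series(
            np.where(fate_b["terminated"], "EPDC", "CM"), index=fate_b.index
        )
        contrast_b = fate_mod.differential_expression(
            cohort_b.ipsc_expr[labels_b.index], labels_b, q_cut=config.q_cut
        )
        return replication.contrast_replication(
            contrast_a, contrast_b, signature, alpha=config.alpha
        )

    rep = _stage("replication", _replicate)
    if rep is not None:
        write_yaml(
            {
                "r": rep.r,
                "r_p": rep.r_p,
                "n_signature": rep.n_signature,
                "n_replicated": rep.n_replicated,
                "fold_enrichment": rep.fold_enrichment,
                "fisher_p": rep.fisher_p,
            },
            outdir / "replication.yaml",
        )
        results["replication_n_replicated"] = rep.n_replicated
        results["replication_fisher_p"] = rep.fisher_p

    write_yaml({k: (float(v) if isinstance(v, (int, float, np.floating)) else v)
                for k, v in results.items()}, outdir / "summary.yaml")
    (outdir / "run.log").write_text("\n".join(log) + "\n")
    return results
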