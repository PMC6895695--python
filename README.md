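# cardiofate

Directed cardiac differentiation of induced pluripotent stem cell (iPSC)
lines yields heterogeneous samples: mixtures of cardiomyocytes (CM),
epicardium-derived cells (EPDC), and a residual stem-like population.
`cardiofate` implements, as a tested and reusable pipeline, the analysis
chain that links the transcriptome of an *undifferentiated* iPSC line to
its eventual cardiac fate:

1. **Deconvolution** — build a marker-gene signature matrix (top-N
   one-vs-rest overexpressed genes per population) and estimate each bulk
   sample's CM/EPDC/SC fractions by nonnegative least squares, validated
   against flow-cytometry purity (%cTnT).
2. **Fate-threshold sweep** — classify lines as CM- or EPDC-fated at each
   candidate CM:EPDC ratio (a line is CM-fated at ratio k when its CM
   fraction is ≥ k; terminated differentiations count as 0), count
   differentially expressed genes (Welch t on log2(TPM+1), Storey
   q < 0.1) at every threshold, select the optimum, and calibrate the
   count against a class-size-preserving permutation null.
3. **Signature models** — per-gene fate GLMs (identity or logit link,
   pseudo-R²) and a joint LASSO with 10-fold cross-validated R².
4. **X-chromosome allelic imbalance** — AIF = fraction of transcripts
   from the higher-expressed allele (0.5 biallelic XaXa, ~1 monoallelic
   XaXi), pseudoautosomal-region masking, Mann-Whitney group tests, and
   per-interval reactivation profiles.
5. **Enrichment, association, replication** — gene-set tests on the
   normalized CM-vs-EPDC contrast; covariate logistic GLM (Firth fallback
   under separation) and a vectorized genotype-dosage scan with a 5e-8
   genome-wide flag; direction-consistent cross-cohort signature
   replication with Fisher enrichment against an empirical background.

Every stage is exercisable on a built-in synthetic cohort generator that
plants known truth (signature genes, X states, mixture fractions), so the
whole chain is testable without access to restricted cohort data. It is
aimed at computational biologists studying differentiation variability
across stem-cell lines, and at anyone needing a transparent, scriptable
alternative to black-box deconvolution/fate pipelines.

## Worked example

Simulate a 184-line cohort (37 terminated differentiations) with 91
signature genes planted at the 30:70 CM/EPDC partition, then run the
first two stages:

```python
from cardiofate import synthetic, deconvolution, fate

profiles = synthetic.simulate_reference_profiles(n_genes=3000, seed=7)
cohort = synthetic.simulate_ipsc_cohort(
    profiles, n_lines=184, n_terminated=37, n_signature=91, effect_size=1.5,
    fate_dist="boundary", coupling="step", step_threshold=0.3,
    effect_profile="exponential", seed=7)

replicates = profiles.make_replicates(seed=7)
signature = deconvolution.build_signature_matrix(replicates, top_n=50, p_cutoff=1e-13)
estimates = deconvolution.estimate_fractions(cohort.cvpc_expr, signature)
r, p = deconvolution.correlate_fraction_with_purity(estimates, cohort.metadata["cTnT_pct"])

table = fate.assign_outcome(estimates, cohort.terminated_lines)
sweep = fate.threshold_sweep(cohort.ipsc_expr, table, n_perm=100, seed=7)
signature_genes = fate.finalize_signature(sweep)
```

Output:

```
signature matrix: 150 marker genes x 3 populations
estimated CM fraction vs %cTnT: r = 0.916 (p = 2.24e-59)
best CM/EPDC threshold: 0.3 (74 DE genes at q<0.1; permutation null max 2)
union of DE genes across thresholds: 99; 71 (71.7%) strongest at the best threshold
final signature: 74 genes (31 up in CM-fated, 43 up in EPDC-fated)
```

Reading this: the three populations yield the expected 150-gene signature
matrix (3 × top 50); deconvolved CM fractions track the orthogonal
flow-cytometry purity measure; the sweep recovers the planted 30:70
partition as the threshold with the most differentially expressed genes —
74 against a permutation-null maximum of 2, so the signal is far outside
chance — and most union genes have their strongest p-value there.

A full end-to-end run (deconvolution → sweep → signature models → AIF →
associations → replication) on a synthetic cohort:

```sh
cardiofate run --seed 7 --outdir runs/demo
```

which writes per-stage TSV/YAML outputs, the resolved configuration, and
a log under `runs/demo/`. Individual stages are exposed as
`cardiofate simulate|deconvolve|sweep|variance|gsea|aif|assoc|scan|replicate`.

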