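"""Synthetic cohorts with the statistical structure the analysis assumes.

The generators emulate (i) reference expression profiles for the two to
three cell populations a cardiac differentiation yields (cardiomyocytes,
epicardium-derived cells, residual stem-like cells), (ii) bulk mixtures of
those populations with multiplicative noise, (iii) an iPSC cohort whose
expression of planted signature genes is coupled to a latent cardiomyocyte
fate fraction, (iv) allele-specific read counts reflecting XaXa/XaXi states
with escape genes, and (v) genotype dosages with optional planted effects.

Planted truth (signature genes, X-inactivation states, true mixture
fractions) is emitted alongside the data and is never consumed by the
analysis modules; it exists so recovery can be scored.

All generators are bit-reproducible: every operation derives an independent
substream from its integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

DEFAULT_POPULATIONS = ("CM", "EPDC", "SC")
ETHNICITIES = ("European", "Asian", "African", "Hispanic", "Other")
ETHNICITY_WEIGHTS = (0.45, 0.2, 0.1, 0.15, 0.1)

#: chrX pseudoautosomal regions, 1-based inclusive
PAR1 = (60_001, 2_699_520)
PAR2 = (154_931_044, 155_260_560)


def _rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic substream `stream` of the global integer seed."""
    return np.random.default_rng([int(seed), int(stream)])


# ---------------------------------------------------------------------------
# reference profiles and bulk mixtures
# ---------------------------------------------------------------------------


@dataclass
class ReferenceProfiles:
    """Per-population mean expression with planted marker genes.

    ``mean_expr`` is genes x populations in TPM; ``marker_map`` lists, for
    each population, the genes whose mean in that population exceeds the
    mean in every other population by ``fold_change``.
    """

    mean_expr: pd.DataFrame
    marker_map: dict[str, list[str]]
    fold_change: float

    @property
    def genes(self) -> pd.Index:
        return self.mean_expr.index

    @property
    def populations(self) -> list[str]:
        return list(self.mean_expr.columns)

    @property
    def marker_genes(self) -> list[str]:
        return [g for pop in self.populations for g in self.marker_map[pop]]

    def make_replicates(
        self, n_replicates: int = 20, noise_sd: float = 0.2, seed: int = 0
    ) -> dict[str, pd.DataFrame]:
        """Pseudo-replicates around each population mean (log-normal noise).

        Stands in for the per-cell or per-sample replicates a reference
        atlas would provide; used to feed marker selection, which needs a
        within-population dispersion estimate.
        """
        rng = _rng(seed, 11)
        out = {}
        for pop in self.populations:
            mu = self.mean_expr[pop].to_numpy()[:, None]
            noise = rng.lognormal(0.0, noise_sd, size=(mu.shape[0], n_replicates))
            out[pop] = pd.DataFrame(
                mu * noise,
                index=self.genes,
                columns=[f"{pop}_rep{j}" for j in range(n_replicates)],
            )
        return out


def simulate_reference_profiles(
    n_genes: int = 3000,
    n_populations: int = 3,
    n_markers_per_pop: int = 50,
    fold_change: float = 8.0,
    seed: int = 0,
) -> ReferenceProfiles:
    """Reference profiles with disjoint marker blocks per population."""
    if fold_change <= 1:
        raise ValueError("fold_change must exceed 1")
    if n_populations < 1 or n_genes < 1 or n_markers_per_pop < 0:
        raise ValueError("counts must be positive")
    if n_markers_per_pop * n_populations > n_genes:
        raise ValueError(
            f"cannot place {n_markers_per_pop} markers in each of "
            f"{n_populations} populations with only {n_genes} genes"
        )
    rng = _rng(seed, 0)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    pops = [
        DEFAULT_POPULATIONS[k] if k < len(DEFAULT_POPULATIONS) else f"POP{k + 1}"
        for k in range(n_populations)
    ]
    base = rng.lognormal(mean=1.5, sigma=1.2, size=n_genes)
    jitter = rng.lognormal(0.0, 0.05, size=(n_genes, n_populations))
    values = base[:, None] * jitter
    marker_map: dict[str, list[str]] = {}
    for k, pop in enumerate(pops):
        block = slice(k * n_markers_per_pop, (k + 1) * n_markers_per_pop)
        idx = np.arange(n_genes)[block]
        values[idx, :] = base[idx, None]
        values[idx, k] = base[idx] * fold_change
        marker_map[pop] = [genes[i] for i in idx]
    mean_expr = pd.DataFrame(values, index=genes, columns=pops)
    return ReferenceProfiles(mean_expr=mean_expr, marker_map=marker_map, fold_change=fold_change)


def simulate_bulk_mixtures(
    profiles: ReferenceProfiles,
    fractions: pd.DataFrame | np.ndarray,
    noise_sd: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Bulk expression as a noisy linear mixture of the reference columns.

    Sample s is sum_k fractions[s, k] * mean_expr[:, k], perturbed entrywise
    by multiplicative log-normal noise with the given log-scale standard
    deviation.  ``noise_sd=0`` reproduces the exact mixture.
    """
    if isinstance(fractions, pd.DataFrame):
        frac = fractions.loc[:, profiles.populations]
    else:
        arr = np.atleast_2d(np.asarray(fractions, dtype=float))
        frac = pd.DataFrame(
            arr,
            index=[f"S{i:03d}" for i in range(arr.shape[0])],
            columns=profiles.populations,
        )
    vals = frac.to_numpy(dtype=float)
    if np.any(vals < 0):
        raise ValueError("composition fractions must be nonnegative")
    if np.any(np.abs(vals.sum(axis=1) - 1.0) > 1e-6):
        raise ValueError("each composition vector must sum to 1 within 1e-6")
    expr = profiles.mean_expr.to_numpy() @ vals.T
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if noise_sd > 0:
        rng = _rng(seed, 1)
        expr = expr * rng.lognormal(0.0, noise_sd, size=expr.shape)
    return pd.DataFrame(expr, index=profiles.genes, columns=frac.index)


# ---------------------------------------------------------------------------
# iPSC cohort with a latent fate fraction
# ---------------------------------------------------------------------------


@dataclass
class SyntheticCohort:
    """An iPSC cohort paired with its derived bulk samples and planted truth.

    ``ipsc_expr`` holds undifferentiated-line transcriptomes (genes x lines,
    TPM); ``cvpc_expr`` the day-25 derived samples for completed lines only.
    ``signature_truth``, ``xi_truth``, ``true_fractions`` and ``latent_cm``
    are truth objects for scoring recovery and must not feed the analysis.
    """

    ipsc_expr: pd.DataFrame
    cvpc_expr: pd.DataFrame
    metadata: pd.DataFrame
    true_fractions: pd.DataFrame
    signature_truth: pd.DataFrame
    xi_truth: pd.DataFrame
    latent_cm: pd.Series
    related_pairs: list[tuple[str, str]] = field(default_factory=list)

    @property
    def lines(self) -> pd.Index:
        return self.metadata.index

    @property
    def terminated_lines(self) -> list[str]:
        return list(self.metadata.index[self.metadata["terminated"]])

    @property
    def cm_fraction(self) -> pd.Series:
        """Outcome per line: true CM fraction, 0 for terminated lines."""
        return self.true_fractions["CM"].where(~self.metadata["terminated"], 0.0)


def _draw_fate(
    rng: np.random.Generator,
    n: int,
    fate_dist: str,
    high_weight: np.ndarray,
) -> np.ndarray:
    """Latent CM fraction for completed lines.

    ``bimodal`` mimics a cohort where most differentiations yield
    CM-dominated samples and a minority EPDC-dominated ones; ``boundary``
    concentrates mass around the 30% decision region (used when the point of
    an experiment is whether a threshold location is identifiable);
    ``uniform`` spreads fate evenly.
    """
    if fate_dist == "bimodal":
        is_high = rng.random(n) < high_weight
        f = np.where(is_high, rng.beta(9.0, 1.5, size=n), rng.beta(1.2, 5.0, size=n))
    elif fate_dist == "boundary":
        loc, scale = 0.32, 0.12
        a, b = (0.01 - loc) / scale, (0.99 - loc) / scale
        f = sps.truncnorm.rvs(a, b, loc=loc, scale=scale, size=n, random_state=rng)
    elif fate_dist == "uniform":
        f = rng.uniform(0.05, 0.95, size=n)
    else:
        raise ValueError(f"unknown fate_dist {fate_dist!r}")
    return np.clip(f, 0.0, 1.0)


def simulate_ipsc_cohort(
    profiles: ReferenceProfiles,
    n_lines: int = 184,
    n_terminated: int = 37,
    n_signature: int = 91,
    effect_size: float = 1.0,
    pct_positive: float = 36 / 91,
    pct_female: float = 113 / 184,
    sex_effect: float = 0.35,
    xi_mix: Sequence[float] = (0.25, 0.55, 0.20),
    fate_dist: str = "bimodal",
    coupling: str = "linear",
    step_threshold: float = 0.3,
    effect_profile: str = "fixed",
    noise_sd: float = 0.5,
    cvpc_noise_sd: float = 0.1,
    n_clone_pairs: int = 0,
    clone_correlation: float = 0.0,
    high_weight: float = 0.82,
    seed: int = 0,
) -> SyntheticCohort:
    """An iPSC cohort whose signature-gene expression tracks a latent fate.

    Each line receives a latent CM fraction; a planted signature gene g is
    shifted in log2 space by ``sign(g) * effect * noise_sd * (c - 0.5)``
    where c is the latent fraction (``coupling='linear'``) or the indicator
    of the latent fraction reaching ``step_threshold`` (``coupling='step'``).
    ``effect_profile='fixed'`` gives every gene the magnitude
    ``effect_size``; ``'exponential'`` draws magnitudes with that mean,
    mimicking the wide spread of per-gene contributions seen in real
    signatures.  Non-signature genes are exchangeable noise.

    The sex effect acts on both the termination odds and the probability of
    the high-fate component, so female lines are biased toward the CM fate;
    its default magnitude was set by an oracle logistic power calculation
    (see docs/methods.md), not fitted to data.
    """
    if abs(sum(xi_mix) - 1.0) > 1e-9:
        raise ValueError("xi_mix must sum to 1")
    if n_signature > len(profiles.genes):
        raise ValueError("n_signature exceeds the number of genes in the profiles")
    if not 0 <= pct_female <= 1:
        raise ValueError("pct_female must lie in [0, 1]")
    if n_terminated >= n_lines:
        raise ValueError("n_terminated must be smaller than n_lines")
    if coupling not in ("linear", "step"):
        raise ValueError(f"unknown coupling {coupling!r}")
    if 2 * n_clone_pairs > n_lines:
        raise ValueError("too many clone pairs for the cohort size")

    r_meta = _rng(seed, 20)
    r_fate = _rng(seed, 21)
    r_expr = _rng(seed, 22)
    r_xi = _rng(seed, 23)

    lines = [f"L{i:03d}" for i in range(n_lines)]
    n_female = int(round(pct_female * n_lines))
    sex = np.array(["F"] * n_female + ["M"] * (n_lines - n_female))
    r_meta.shuffle(sex)
    is_female = sex == "F"

    # termination: sex-biased weights, exact count
    p_term = n_terminated / n_lines
    w = np.where(is_female, p_term * (1 - sex_effect), 1.0)
    if (~is_female).any():
        f_frac = is_female.mean()
        p_term_m = (p_term - f_frac * p_term * (1 - sex_effect)) / max(1 - f_frac, 1e-9)
        w = np.where(is_female, p_term * (1 - sex_effect), max(p_term_m, 1e-6))
    terminated = np.zeros(n_lines, dtype=bool)
    if n_terminated > 0:
        idx = r_meta.choice(n_lines, size=n_terminated, replace=False, p=w / w.sum())
        terminated[idx] = True

    # latent CM fraction
    latent = np.empty(n_lines)
    n_term = int(terminated.sum())
    latent[terminated] = 0.5 * r_fate.beta(1.2, 8.0, size=n_term)  # low tail
    completed = ~terminated
    if fate_dist == "bimodal":
        hw = np.clip(
            np.where(is_female[completed], high_weight + sex_effect / 2, high_weight - sex_effect / 2),
            0.0,
            1.0,
        )
        latent[completed] = _draw_fate(r_fate, int(completed.sum()), fate_dist, hw)
    else:
        latent[completed] = _draw_fate(
            r_fate, int(completed.sum()), fate_dist, np.full(int(completed.sum()), high_weight)
        )
        latent[completed & is_female] = np.clip(
            latent[completed & is_female] + 0.15 * sex_effect, 0.0, 1.0
        )

    # clone/twin structure: pair members share a subject and correlate latents
    related_pairs: list[tuple[str, str]] = []
    subject = np.array([f"SUBJ{i:03d}" for i in range(n_lines)], dtype=object)
    for k in range(n_clone_pairs):
        a, b = 2 * k, 2 * k + 1
        latent[b] = np.clip(
            clone_correlation * latent[a] + (1 - clone_correlation) * latent[b], 0.0, 1.0
        )
        subject[b] = subject[a]
        related_pairs.append((lines[a], lines[b]))

    # true mixture fractions; terminated lines carry their (unobserved) zeros
    cm_true = np.where(terminated, 0.0, latent)
    sc = r_fate.uniform(0.0, 0.01, size=n_lines) * (1.0 - cm_true)
    frac = pd.DataFrame({"CM": cm_true, "EPDC": 1.0 - cm_true - sc, "SC": sc}, index=lines)

    ctnt = np.clip(100.0 * (0.92 * cm_true + r_meta.normal(0.0, 0.04, n_lines)), 0.0, 100.0)
    ctnt[terminated] = np.nan

    metadata = pd.DataFrame(
        {
            "subject": subject,
            "sex": sex,
            "age": r_meta.integers(20, 71, size=n_lines),
            "ethnicity": r_meta.choice(ETHNICITIES, size=n_lines, p=ETHNICITY_WEIGHTS),
            "passage": r_meta.integers(12, 41, size=n_lines),
            "terminated": terminated,
            "cTnT_pct": ctnt,
        },
        index=pd.Index(lines, name="line"),
    )

    # iPSC expression: gene baseline + exchangeable log2 noise + planted shifts
    base_log = np.log2(profiles.mean_expr.mean(axis=1).to_numpy() + 1.0)
    log2x = base_log[:, None] + r_expr.normal(0.0, noise_sd, size=(len(profiles.genes), n_lines))
    candidates = [g for g in profiles.genes if g not in set(profiles.marker_genes)]
    if n_signature > len(candidates):
        raise ValueError("not enough non-marker genes to plant the signature")
    sig_genes = list(r_expr.choice(candidates, size=n_signature, replace=False))
    n_pos = int(round(pct_positive * n_signature))
    signs = np.array([1] * n_pos + [-1] * (n_signature - n_pos))
    if effect_profile == "fixed":
        mags = np.full(n_signature, float(effect_size))
    elif effect_profile == "exponential":
        mags = r_expr.exponential(float(effect_size), size=n_signature)
    else:
        raise ValueError(f"unknown effect_profile {effect_profile!r}")
    c = latent if coupling == "linear" else (latent >= step_threshold).astype(float)
    gene_pos = {g: i for i, g in enumerate(profiles.genes)}
    for g, s, m in zip(sig_genes, signs, mags):
        log2x[gene_pos[g], :] += s * m * noise_sd * (c - 0.5)
    ipsc_expr = pd.DataFrame(
        np.clip(2.0 ** log2x - 1.0, 0.0, None), index=profiles.genes, columns=lines
    )

    signature_truth = pd.DataFrame(
        {"sign": signs, "effect": mags}, index=pd.Index(sig_genes, name="gene")
    )

    # day-25 bulk samples for completed lines only
    if not set(profiles.populations) <= {"CM", "EPDC", "SC"}:
        raise ValueError("cohort simulation expects populations named among CM/EPDC/SC")
    mix = frac.loc[completed, profiles.populations]
    mix = mix.div(mix.sum(axis=1), axis=0)  # renormalize if a population is absent
    cvpc_expr = simulate_bulk_mixtures(
        profiles, mix, noise_sd=cvpc_noise_sd, seed=int(_rng(seed, 24).integers(2**31))
    )

    # X-inactivation truth for female lines
    fem = [ln for ln, s in zip(lines, sex) if s == "F"]
    states = r_xi.choice(["XaXa", "XaXi", "mosaic"], size=len(fem), p=list(xi_mix))
    rho = np.where(
        states == "XaXa", 1.0, np.where(states == "XaXi", 0.0, r_xi.uniform(0.2, 0.8, len(fem)))
    )
    xi_truth = pd.DataFrame({"state": states, "rho": rho}, index=pd.Index(fem, name="line"))

    return SyntheticCohort(
        ipsc_expr=ipsc_expr,
        cvpc_expr=cvpc_expr,
        metadata=metadata,
        true_fractions=frac,
        signature_truth=signature_truth,
        xi_truth=xi_truth,
        latent_cm=pd.Series(latent, index=lines, name="latent_cm"),
        related_pairs=related_pairs,
    )


# ---------------------------------------------------------------------------
# allele-specific counts on chrX and autosomes
# ---------------------------------------------------------------------------


@dataclass
class AseSimulation:
    """Allele-count table plus the gene annotation truth used to build it."""

    counts: pd.DataFrame
    gene_annotations: pd.DataFrame


def simulate_ase_counts(
    cohort: SyntheticCohort,
    depth: float = 200.0,
    n_chrx_genes: int = 60,
    escape_fraction: float = 0.15,
    n_autosomal_genes: int = 60,
    n_par_genes: int = 0,
    allele_skew: float = 0.99,
    seed: int = 0,
) -> AseSimulation:
    """Binomial allele counts for female lines reflecting X-inactivation.

    For XaXi lines, non-escape chrX genes draw their minor-allele fraction at
    ``1 - allele_skew`` (near-monoallelic); XaXa lines, escape genes, PAR
    genes and autosomal genes draw at 0.5.  Mosaic lines reactivate each
    gene independently with their per-line probability rho.  Read totals are
    Poisson with mean ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be at least 1 read per gene")
    if not 0 <= escape_fraction <= 1:
        raise ValueError("escape_fraction must lie in [0, 1]")
    if not 0.5 < allele_skew <= 1:
        raise ValueError("allele_skew must lie in (0.5, 1]")
    rng = _rng(seed, 30)

    recs = []
    for i in range(n_chrx_genes):
        start = int(rng.integers(PAR1[1] + 1_000, PAR2[0] - 10_000))
        recs.append((f"XG{i:04d}", "chrX", start, start + 5000))
    for i in range(n_par_genes):
        start = int(rng.integers(PAR1[0], PAR1[1] - 10_000))
        recs.append((f"PARG{i:04d}", "chrX", start, start + 5000))
    for i in range(n_autosomal_genes):
        chrom = f"chr{int(rng.integers(1, 23))}"
        start = int(rng.integers(1_000_000, 100_000_000))
        recs.append((f"AG{i:04d}", chrom, start, start + 5000))
    genes = pd.DataFrame(recs, columns=["gene", "chrom", "start", "end"]).set_index("gene")
    n_escape = int(round(escape_fraction * n_chrx_genes))
    escape_ids = list(rng.choice(genes.index[:n_chrx_genes], size=n_escape, replace=False))
    genes["is_escape"] = genes.index.isin(escape_ids)
    genes["is_par"] = genes.index.str.startswith("PARG")

    rows = []
    for line in cohort.xi_truth.index:
        state = cohort.xi_truth.loc[line, "state"]
        rho = float(cohort.xi_truth.loc[line, "rho"])
        for gene, ginfo in genes.iterrows():
            if ginfo["chrom"] != "chrX" or ginfo["is_par"] or ginfo["is_escape"]:
                p = 0.5
            elif state == "XaXa":
                p = 0.5
            elif state == "XaXi":
                p = allele_skew
            else:  # mosaic: per-gene Bernoulli(rho) reactivation
                p = 0.5 if rng.random() < rho else allele_skew
            if p != 0.5 and rng.random() < 0.5:
                p = 1.0 - p  # which haplotype carries the silenced allele
            total = int(rng.poisson(depth))
            ref = int(rng.binomial(total, p)) if total > 0 else 0
            rows.append((gene, ginfo["chrom"], ginfo["start"], ginfo["end"], line, ref, total - ref))
    counts = pd.DataFrame(
        rows, columns=["gene", "chrom", "start", "end", "sample", "ref_count", "alt_count"]
    )
    return AseSimulation(counts=counts, gene_annotations=genes)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


@dataclass
class GenotypeSim:
    """Dosage matrix (variants x lines) with optional planted effect."""

    dosages: pd.DataFrame
    maf: pd.Series
    causal: tuple[str, float] | None
    outcome_shift: pd.Series | None


def planted_beta_for_r2(r2: float, outcome_sd: float, maf: float) -> float:
    """Per-allele effect size giving the target fraction of outcome variance.

    Under Hardy-Weinberg the dosage variance is 2 * maf * (1 - maf), so
    beta = outcome_sd * sqrt(r2 / (1 - r2)) / sqrt(2 maf (1 - maf)).
    """
    if not 0 < r2 < 1:
        raise ValueError("r2 must lie in (0, 1)")
    return outcome_sd * np.sqrt(r2 / (1 - r2)) / np.sqrt(2 * maf * (1 - maf))


def simulate_genotypes(
    n_lines: int,
    n_variants: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    causal: tuple[int, float] | None = None,
    seed: int = 0,
) -> GenotypeSim:
    """Biallelic dosages at Hardy-Weinberg proportions.

    ``causal=(variant_index, beta)`` plants an additive effect: the returned
    ``outcome_shift`` (beta x dosage at that variant) is meant to be added to
    the latent fate fraction by the caller before running an association
    scan.
    """
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be contained in (0, 0.5]")
    rng = _rng(seed, 40)
    maf = rng.uniform(lo, hi, size=n_variants)
    dos = rng.binomial(2, maf[:, None], size=(n_variants, n_lines)).astype(float)
    variants = [f"var{i:06d}" for i in range(n_variants)]
    lines = [f"L{i:03d}" for i in range(n_lines)]
    dosages = pd.DataFrame(dos, index=variants, columns=lines)
    shift = None
    causal_out = None
    if causal is not None:
        vi, beta = causal
        causal_out = (variants[vi], float(beta))
        shift = pd.Series(beta * dos[vi, :], index=lines, name="outcome_shift")
    return GenotypeSim(
        dosages=dosages, maf=pd.Series(maf, index=variants, name="maf"),
        causal=causal_out, outcome_shift=shift,
    )
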