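"""Run configuration: stage parameters, defaults, validation, hashing."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised when a configuration fails validation before any stage runs."""


@dataclass
class RunConfig:
    """End-to-end pipeline parameters.

    Stage defaults follow the study design this pipeline reproduces: top 50
    markers per population at p < 1e-13, fate thresholds 0.0-0.9 in steps
    of 0.1, Storey q < 0.1 for differential expression, 100 permutations,
    borderline rescue at nominal p < 0.0015, 10-fold cross-validation,
    20-read ASE coverage, replication alpha 0.05, and genome-wide
    significance at 5e-8.
    """

    seed: int = 0
    # deconvolution
    top_n: int = 50
    p_cutoff: float = 1e-13
    # fate sweep
    thresholds: tuple[float, ...] = tuple(round(0.1 * k, 1) for k in range(10))
    q_cut: float = 0.1
    n_perm: int = 100
    borderline_p: float = 0.0015
    # signature model
    folds: int = 10
    # ASE
    min_coverage: int = 20
    # replication / association
    alpha: float = 0.05
    gw_sig: float = 5e-8
    maf_min: float = 0.05
    # synthetic cohort shape
    n_genes: int = 3000
    n_populations: int = 3
    n_markers_per_pop: int = 50
    fold_change: float = 8.0
    n_lines: int = 184
    n_terminated: int = 37
    n_signature: int = 91
    effect_size: float = 1.0
    bulk_noise_sd: float = 0.1
    ase_depth: float = 200.0
    n_variants: int = 0  # 0 disables the genotype stage
    replication_n_lines: int = 39
    replication_n_terminated: int = 24

    def validate(self) -> None:
        if not (0 < self.q_cut < 1):
            raise ConfigError(f"q_cut must lie in (0, 1), got {self.q_cut}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_perm < 1 or self.folds < 2 or self.top_n < 1:
            raise ConfigError("n_perm >= 1, folds >= 2 and top_n >= 1 are required")
        if self.p_cutoff <= 0 or self.borderline_p <= 0:
            raise ConfigError("p cutoffs must be positive")
        if not all(0 <= t < 1 for t in self.thresholds):
            raise ConfigError("thresholds must lie in [0, 1)")
        if self.min_coverage < 1 or self.ase_depth < 1:
            raise ConfigError("min_coverage and ase_depth must be at least 1")
        if self.n_lines < 20 or not (0 <= self.n_terminated < self.n_lines):
            raise ConfigError("invalid cohort size")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "thresholds" in raw:
            raw["thresholds"] = tuple(raw["thresholds"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True).encode()
        return hashlib.sha1(payload).hexdigest()[:12]
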