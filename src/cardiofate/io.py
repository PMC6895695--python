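"""Readers and writers for the pipeline's on-disk formats.

TSV with ``#``-prefixed header lines is the lingua franca; YAML holds
configuration and summary objects.  Genomic coordinates are 1-based
inclusive internally; BED input (0-based half-open) is converted at the
boundary.  Every written table carries a header naming the producing
stage, the package version, and the configuration hash.
"""

from __future__ import annotations

from importlib.metadata import PackageNotFoundError, version
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

try:
    __version__ = version("cardiofate")
except PackageNotFoundError:  # pragma: no cover - editable-install edge
    __version__ = "0.0.0"


def write_tsv(
    df: pd.DataFrame,
    path: str | Path,
    stage: str = "unspecified",
    config_hash: str = "-",
    index: bool = True,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"#stage={stage}\tpackage=cardiofate-{__version__}\tconfig_hash={config_hash}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_table(path: str | Path, index_col=0) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=index_col)
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    """Genes x samples TPM matrix; duplicate gene identifiers are an error."""
    df = _read_table(path)
    if df.index.duplicated().any():
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"duplicate gene identifiers: {dups[:10]}")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise ValueError(f"non-numeric expression columns: {non_numeric}")
    return df


def read_metadata(path: str | Path) -> pd.DataFrame:
    return _read_table(path)


def read_allele_counts(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene", "chrom", "start", "end", "sample", "ref_count", "alt_count"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"allele-count table lacks columns: {sorted(missing)}")
    return df


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: one set per line (name, description, genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                if line.strip() == "":
                    continue
                raise ValueError(f"{path}: malformed GMT line {i} (need name, desc, >=1 gene)")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED intervals converted to 1-based inclusive coordinates."""
    rows = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: ragged BED line {i}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else f"interval{i}"
            rows.append((chrom, start + 1, end, name))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def read_dosages(path: str | Path) -> pd.DataFrame:
    """Variant x line dosage matrix from TSV, or from a VCF (alt-allele count)."""
    path = Path(path)
    if path.suffix in (".vcf", ".gz") or path.name.endswith(".vcf.gz"):
        return _read_vcf_dosages(path)
    df = _read_table(path)
    return df.astype(float)


def _read_vcf_dosages(path: Path) -> pd.DataFrame:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, names = [], []
    for v in vcf:
        if len(v.ALT) != 1:
            continue  # biallelic records only
        dosage = []
        for gt in v.genotypes:
            alleles = [a for a in gt[:-1] if a >= 0]
            dosage.append(float(sum(1 for a in alleles if a > 0)) if alleles else float("nan"))
        names.append(v.ID or f"{v.CHROM}:{v.POS}")
        rows.append(dosage)
    return pd.DataFrame(rows, index=names, columns=samples)


def _to_plain(obj):
    """Recursively convert numpy scalars/arrays to plain Python types."""
    import numpy as np

    if isinstance(obj, dict):
        return {_to_plain(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_to_plain(v) for v in obj.tolist()]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def write_yaml(obj: Mapping, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(dict(obj)), fh, sort_keys=True)


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
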