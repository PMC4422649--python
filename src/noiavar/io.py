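"""File formats: phenotype tables, effect/covariance tables, run manifests.

The canonical phenotype dialect is a CSV (XLSX accepted) with columns
``plant_id``, ``cohort``, ``family``, one genotype column per locus coded as
donor-allele counts 0/1/2 (string codes ww/Ww/WW also accepted), and one
numeric column per trait; missing trait values are allowed and accounted
per column.  A ``column_map`` renames externally named columns into this
dialect on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .design import GenotypeError, ModelSpec, normalize_genotype_column
from .effects import EffectEstimates

logger = logging.getLogger("noiavar")

__all__ = [
    "read_phenotypes",
    "write_phenotypes",
    "read_effects",
    "write_effects",
    "write_manifest",
]

_REQUIRED = ("plant_id", "cohort", "family")


def read_phenotypes(path, loci, traits, column_map=None) -> pd.DataFrame:
    """Read and validate a phenotype table (CSV or XLSX).

    ``loci`` may be a ModelSpec or a sequence of locus column names;
    ``traits`` the trait column names.  Genotype codes are normalized to
    donor-allele counts; unknown codes and non-numeric trait values raise
    with the offending row; missing required columns raise by name.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path)
    else:
        df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    locus_names = tuple(loci.loci) if isinstance(loci, ModelSpec) else tuple(loci)
    traits = tuple(traits)

    missing = [c for c in (*_REQUIRED, *locus_names, *traits) if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks required column(s) {missing}")

    for locus in locus_names:
        try:
            df[locus] = normalize_genotype_column(df[locus].to_numpy(), locus)
        except GenotypeError as err:
            raise GenotypeError(f"{path.name}: {err}") from None
    for trait in traits:
        vals = pd.to_numeric(df[trait], errors="coerce")
        bad = df[trait].notna() & vals.isna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0]) + 2  # 1-based + header line
            raise ValueError(
                f"{path.name}: non-numeric {trait!r} value at file line {row}"
            )
        df[trait] = vals
        n_missing = int(vals.isna().sum())
        if n_missing:
            logger.info("%s: %d missing %r values", path.name, n_missing, trait)
    return df[[*_REQUIRED, *locus_names, *traits]]


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.10g")


def write_effects(effects: EffectEstimates, est_path, cov_path=None) -> None:
    """Write estimates (+SEs) as CSV, and optionally the square covariance CSV."""
    effects.to_frame().to_csv(est_path, index=False, float_format="%.12g")
    if cov_path is not None:
        effects.cov_frame().to_csv(cov_path, float_format="%.12g")


def read_effects(est_path, cov_path=None, trait: str = "") -> EffectEstimates:
    est = pd.read_csv(est_path)
    labels = tuple(est["label"])
    cov = None
    if cov_path is not None:
        cov_df = pd.read_csv(cov_path, index_col=0)
        if tuple(cov_df.index) != labels or tuple(cov_df.columns) != labels:
            raise ValueError("covariance labels do not match estimate labels")
        cov = cov_df.to_numpy()
    return EffectEstimates(labels, est["estimate"].to_numpy(), cov, trait=trait)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, command: str, inputs=(), outputs=(), seed=None, params=None):
    """JSON manifest sufficient to re-run the producing command."""
    import noiavar

    manifest = {
        "command": command,
        "package_version": noiavar.__version__,
        "python": platform.python_version(),
        "seed": seed,
        "params": params or {},
        "inputs": {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()},
        "outputs": {str(p): _sha256(Path(p)) for p in outputs if Path(p).exists()},
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str))
    return manifest
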