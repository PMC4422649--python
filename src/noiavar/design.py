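"""Functional NOIA genotype coding and design-matrix construction.

The functional NOIA parameterization defines genetic effects as deviations
from a fixed reference genotype (the fully homozygous reference line).  Each
biallelic locus is coded by two index variables: an additive index ``xa``
(the donor-allele count, 0/1/2) and a dominance index ``xd`` (heterozygosity
indicator, 0/1).  The reference homozygote maps to (0, 0), so a genotype that
is reference at every locus produces an all-zero design row and the model
intercept is the reference genotypic value.  Pairwise epistatic contrasts are
the four products xa·xa, xa·xd, xd·xa and xd·xd for each modelled locus pair.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ModelSpec",
    "GenotypeError",
    "encode_locus",
    "decode_locus",
    "build_design",
    "count_parameters",
    "column_monomials",
    "normalize_genotype_column",
]

#: accepted spellings of the three genotype states, mapped to donor-allele count
_STATE_CODES = {
    0: 0, 1: 1, 2: 2,
    "0": 0, "1": 1, "2": 2,
    "ww": 0, "Ww": 1, "wW": 1, "WW": 2,
    "ref_hom": 0, "het": 1, "donor_hom": 2,
}

#: (xa, xd) per donor-allele count
_INDEX = {0: (0, 0), 1: (1, 1), 2: (2, 0)}


class GenotypeError(ValueError):
    """Raised when a genotype state or locus reference cannot be interpreted."""


def encode_locus(state) -> tuple[int, int]:
    """Map a single-locus genotype state to its (xa, xd) index variables.

    ``state`` may be a donor-allele count (0/1/2, int or str) or one of the
    string codes ``ww``/``Ww``/``WW`` (equivalently ``ref_hom``/``het``/
    ``donor_hom``).  Returns the additive index (donor-allele count) and the
    dominance index (1 for heterozygotes).
    """
    try:
        count = _STATE_CODES[state]
    except (KeyError, TypeError):
        raise GenotypeError(f"unknown genotype state: {state!r}") from None
    return _INDEX[count]


def decode_locus(xa: int, xd: int) -> int:
    """Inverse of :func:`encode_locus`; returns the donor-allele count."""
    for count, pair in _INDEX.items():
        if pair == (xa, xd):
            return count
    raise GenotypeError(f"invalid index pair (xa={xa}, xd={xd})")


def normalize_genotype_column(values, locus: str) -> np.ndarray:
    """Normalize a column of genotype codes to donor-allele counts 0/1/2."""
    out = np.empty(len(values), dtype=np.int64)
    for i, v in enumerate(np.asarray(values, dtype=object)):
        try:
            out[i] = _STATE_CODES[v]
        except (KeyError, TypeError):
            raise GenotypeError(
                f"unknown genotype state {v!r} at row {i} of locus {locus!r}"
            ) from None
    return out


# default locus names of the seven-QTL floral panel
STUDY_LOCI = ("x1", "x5a", "x5b", "x8", "x9", "x10a", "x10b")


@dataclass(frozen=True)
class ModelSpec:
    """Which loci and which epistatic locus pairs a model includes.

    Pairs not listed in ``pairs`` contribute no epistatic terms: their
    interaction effects are taken to be exactly zero with zero sampling
    variance.
    """

    loci: tuple[str, ...]
    pairs: tuple[tuple[str, str], ...] = field(default_factory=tuple)
    include_epistasis: bool = True

    def __post_init__(self):
        loci = tuple(self.loci)
        if len(set(loci)) != len(loci):
            raise ValueError("locus ids must be unique")
        order = {l: i for i, l in enumerate(loci)}
        norm = []
        for a, b in self.pairs:
            if a not in order or b not in order:
                raise ValueError(f"pair ({a}, {b}) references unknown locus")
            if a == b:
                raise ValueError(f"pair ({a}, {b}) repeats a locus")
            if order[a] > order[b]:
                a, b = b, a
            norm.append((a, b))
        if len(set(norm)) != len(norm):
            raise ValueError("duplicate locus pairs")
        norm.sort(key=lambda p: (order[p[0]], order[p[1]]))
        object.__setattr__(self, "loci", loci)
        object.__setattr__(self, "pairs", tuple(norm))

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def without_epistasis(self) -> "ModelSpec":
        return replace(self, include_epistasis=False)

    def design_columns(self) -> list[str]:
        """Ordered design-column labels: a/d per locus, then aa/ad/da/dd per pair."""
        cols = [f"a:{l}" for l in self.loci] + [f"d:{l}" for l in self.loci]
        if self.include_epistasis:
            for i, j in self.pairs:
                cols += [f"aa:{i}:{j}", f"ad:{i}:{j}", f"da:{i}:{j}", f"dd:{i}:{j}"]
        return cols

    def all_pairs(self) -> list[tuple[str, str]]:
        return list(itertools.combinations(self.loci, 2))


def count_parameters(spec: ModelSpec) -> tuple[int, int, int]:
    """Parameter accounting for the epistasis likelihood-ratio test.

    Returns ``(n_full, n_reduced, df_lrt)``.  Counts follow the convention of
    genetic-effect columns plus two random-effect terms (cohort and family);
    the intercept is not counted.  For the seven-locus, eleven-pair study
    design this gives 60, 16 and 44.
    """
    n_genetic = 2 * spec.n_loci
    n_epi = 4 * len(spec.pairs)
    n_full = n_genetic + n_epi + 2
    n_reduced = n_genetic + 2
    return n_full, n_reduced, n_full - n_reduced


def _genotype_matrix(genotypes, loci) -> np.ndarray:
    """Coerce genotypes to an (n, L) array of donor-allele counts.

    Accepts an (n, L) array-like of counts, a DataFrame with one column per
    locus, or a sequence of per-genotype mappings/sequences.
    """
    if isinstance(genotypes, pd.DataFrame):
        missing = [l for l in loci if l not in genotypes.columns]
        if missing:
            raise GenotypeError(f"genotype table lacks loci {missing}")
        cols = [normalize_genotype_column(genotypes[l].to_numpy(), l) for l in loci]
        return np.column_stack(cols)
    arr = np.asarray(genotypes, dtype=object)
    if arr.ndim == 1 and len(arr) and isinstance(arr[0], dict):
        rows = []
        for g in arr:
            unknown = set(g) - set(loci)
            if unknown:
                raise GenotypeError(f"genotype references unknown loci {sorted(unknown)}")
            rows.append([g[l] for l in loci])
        arr = np.asarray(rows, dtype=object)
    if arr.ndim == 1:
        arr = arr.reshape(1, -1)
    if arr.shape[1] != len(loci):
        raise GenotypeError(
            f"genotypes have {arr.shape[1]} loci, spec declares {len(loci)}"
        )
    out = np.empty(arr.shape, dtype=np.int64)
    for j, locus in enumerate(loci):
        out[:, j] = normalize_genotype_column(arr[:, j], locus)
    return out


def build_design(genotypes, spec: ModelSpec) -> pd.DataFrame:
    """Assemble the NOIA design matrix for a batch of multilocus genotypes.

    Column order is fixed and deterministic — loci in declared order for the
    a then d blocks, pairs in declared-locus order with the (aa, ad, da, dd)
    contrasts per pair — so effect vectors and covariance matrices from
    different fits are alignable.  The reference genotype yields an all-zero
    row.  The intercept is *not* included.
    """
    counts = _genotype_matrix(genotypes, spec.loci)
    xa = counts.astype(float)
    xd = (counts == 1).astype(float)
    data = {}
    for j, l in enumerate(spec.loci):
        data[f"a:{l}"] = xa[:, j]
    for j, l in enumerate(spec.loci):
        data[f"d:{l}"] = xd[:, j]
    if spec.include_epistasis:
        idx = {l: j for j, l in enumerate(spec.loci)}
        for i, j in spec.pairs:
            ii, jj = idx[i], idx[j]
            data[f"aa:{i}:{j}"] = xa[:, ii] * xa[:, jj]
            data[f"ad:{i}:{j}"] = xa[:, ii] * xd[:, jj]
            data[f"da:{i}:{j}"] = xd[:, ii] * xa[:, jj]
            data[f"dd:{i}:{j}"] = xd[:, ii] * xd[:, jj]
    return pd.DataFrame(data, columns=spec.design_columns())


def column_monomials(labels) -> list[dict[str, tuple[int, int]]]:
    """Parse design-column labels into per-locus (xa-exponent, xd-exponent) maps.

    The intercept label ``mu`` parses to the empty monomial.  Used by the
    variance engine to factorize expectations of design-variable products
    across loci under linkage equilibrium.
    """
    out = []
    for label in labels:
        if label == "mu":
            out.append({})
            continue
        parts = label.split(":")
        kind = parts[0]
        if kind in ("a", "d") and len(parts) == 2:
            out.append({parts[1]: (1, 0) if kind == "a" else (0, 1)})
        elif kind in ("aa", "ad", "da", "dd") and len(parts) == 3:
            e1 = (1, 0) if kind[0] == "a" else (0, 1)
            e2 = (1, 0) if kind[1] == "a" else (0, 1)
            out.append({parts[1]: e1, parts[2]: e2})
        else:
            raise ValueError(f"unparseable design column label {label!r}")
    return out
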