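"""From functional genetic effects to population variance components.

Given a set of functional effect estimates (deviations from a reference
genotype) and donor-allele frequencies at each locus, this module computes

* predicted multilocus genotypic values,
* the total genetic variance V_G = Var[Z_G] over the Hardy–Weinberg /
  linkage-equilibrium genotype distribution,
* locus-specific average effects of allele substitution α_k and the additive
  genetic variance V_A = Σ_k 2 p_k q_k α_k²,

each in an *uncorrected* form (direct substitution of estimates) and a
*bias-corrected* form that subtracts the contribution of estimation error.
Direct substitution is upwardly biased because estimates are squared and
multiplied together: E[b̂_i b̂_k] = b_i b_k + Cov(b̂_i, b̂_k).  The correction
subtracts the sampling (co)variance of every product of estimates entering
E[Z²] and E[Z]², and analogously (c_kᵀ b̂)² − c_kᵀ S c_k for the squared
average effect, which is a linear form c_kᵀ b̂ in the estimates.

The default implementation factorizes expectations of design-variable
products across loci (valid under linkage equilibrium), which is O(B²·L)
instead of O(3^L); an exhaustive enumeration backend over all 3^L genotypes
is retained and must agree to numerical precision.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ModelSpec, build_design, column_monomials
from .effects import EffectEstimates

logger = logging.getLogger("noiavar")

__all__ = [
    "GenotypeDistribution",
    "AverageEffectResult",
    "VarianceResult",
    "genotype_distribution",
    "predict_genotypic_value",
    "single_locus_va",
    "total_genetic_variance",
    "average_effect",
    "additive_variance",
]


def _freq_array(freqs, spec: ModelSpec) -> np.ndarray:
    """Coerce donor-allele frequencies to an array aligned with spec.loci."""
    if isinstance(freqs, dict):
        missing = [l for l in spec.loci if l not in freqs]
        if missing:
            raise ValueError(f"no frequency for loci {missing}")
        p = np.array([freqs[l] for l in spec.loci], dtype=float)
    else:
        p = np.asarray(freqs, dtype=float)
        if p.shape != (spec.n_loci,):
            raise ValueError(
                f"expected {spec.n_loci} frequencies, got shape {p.shape}"
            )
    if np.any((p < 0) | (p > 1)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    return p


@dataclass
class GenotypeDistribution:
    """All 3^L multilocus genotypes with their HW × LE probabilities."""

    loci: tuple[str, ...]
    genotypes: np.ndarray  # (3^L, L) donor-allele counts
    probs: np.ndarray      # (3^L,)


def genotype_distribution(freqs, spec: ModelSpec) -> GenotypeDistribution:
    """Enumerate the multilocus genotype distribution under HW and LE.

    Per-locus genotype probabilities are (q², 2pq, p²) for donor-allele
    counts (0, 1, 2); multilocus probabilities are their product (linkage
    equilibrium).
    """
    p = _freq_array(freqs, spec)
    q = 1.0 - p
    per_locus = np.stack([q * q, 2 * p * q, p * p], axis=1)  # (L, 3)
    counts = np.array(
        list(itertools.product((0, 1, 2), repeat=spec.n_loci)), dtype=np.int64
    ).reshape(3 ** spec.n_loci, spec.n_loci)
    probs = np.prod(per_locus[np.arange(spec.n_loci), counts], axis=1)
    return GenotypeDistribution(spec.loci, counts, probs)


def predict_genotypic_value(
    effects: EffectEstimates, genotypes, spec: ModelSpec, epistasis_included: bool = True
):
    """Predicted genotypic value Ẑ_G,u = μ + Σ_i b̂_i X_{i,u}.

    With ``epistasis_included=False`` only the single-locus a and d terms
    enter (the non-epistatic value).  Accepts a single genotype (returns a
    float) or a batch (returns an array).
    """
    work = spec if epistasis_included else spec.without_epistasis()
    single = (
        isinstance(genotypes, dict)
        or (np.asarray(genotypes, dtype=object).ndim == 1
            and not isinstance(genotypes, pd.DataFrame))
    )
    X = build_design([genotypes] if single else genotypes, work)
    b, _ = effects.aligned(X.columns)
    z = effects.mu + X.to_numpy() @ b
    return float(z[0]) if single else z


def single_locus_va(a: float, d: float, p: float, s=None) -> float:
    """Additive variance contributed by one biallelic locus.

    Uncorrected: V_A = 2pq[a + d(q − p)]².  When the 2×2 sampling covariance
    ``s`` of (â, d̂) is supplied, returns the bias-corrected value
    V_A* = V̂_A − 2pq(s_a² + 2(q − p)s_ad + (q − p)² s_d²).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    q = 1.0 - p
    va = 2 * p * q * (a + d * (q - p)) ** 2
    if s is not None:
        s = np.asarray(s, dtype=float)
        va -= 2 * p * q * (s[0, 0] + 2 * (q - p) * s[0, 1] + (q - p) ** 2 * s[1, 1])
    return float(va)


# per-locus moments of xa^r * xd^s under Hardy-Weinberg -----------------------

def _locus_moment(p: float, r: int, s: int) -> float:
    # xd = 1 only for heterozygotes (where xa = 1); xa = 2 w.p. p^2, 1 w.p. 2pq
    q = 1.0 - p
    if s >= 1:
        return 2 * p * q
    if r == 0:
        return 1.0
    return 2 * p * q + p * p * 2.0 ** r


def _fixed_factor(count: int, r: int, s: int) -> float:
    xa, xd = float(count), 1.0 if count == 1 else 0.0
    return (xa ** r if r else 1.0) * (xd ** s if s else 1.0)


def _moment_matrices(labels, p: np.ndarray, spec: ModelSpec, condition=None):
    """First and second moment structure of the design variables.

    Returns ``(m, M2)`` with m_i = E[X_i] and M2_ik = E[X_i X_k], factorized
    per locus under linkage equilibrium.  ``condition`` may be a
    ``(locus, count)`` pair fixing the genotype at one locus.
    """
    monos = column_monomials(labels)
    loc_index = {l: i for i, l in enumerate(spec.loci)}
    cond_locus, cond_count = condition if condition is not None else (None, None)

    def moment(merged: dict) -> float:
        out = 1.0
        for locus, (r, s) in merged.items():
            if locus == cond_locus:
                out *= _fixed_factor(cond_count, r, s)
            else:
                out *= _locus_moment(p[loc_index[locus]], r, s)
        return out

    B = len(labels)
    m = np.array([moment(mono) for mono in monos])
    M2 = np.empty((B, B))
    for i in range(B):
        for k in range(i, B):
            merged = dict(monos[i])
            for locus, (r, s) in monos[k].items():
                r0, s0 = merged.get(locus, (0, 0))
                merged[locus] = (r0 + r, s0 + s)
            M2[i, k] = M2[k, i] = moment(merged)
    return m, M2


def _working_effects(effects, spec, epistasis_included, corrected):
    work = spec if epistasis_included else spec.without_epistasis()
    labels = work.design_columns()
    b, S = effects.aligned(labels)
    if corrected and effects.cov is None:
        raise ValueError("bias correction requires a sampling covariance matrix")
    return work, labels, b, S


def total_genetic_variance(
    effects: EffectEstimates,
    freqs,
    spec: ModelSpec,
    corrected: bool = False,
    epistasis_included: bool = True,
    backend: str = "moments",
    eq13: str = "covariance",
) -> float:
    """Total genetic variance V_G = E[Z_G²] − E[Z_G]² over the population.

    ``corrected=True`` subtracts the sampling-(co)variance term from every
    product of estimates in both E[Z²] and E[Z]²; with the default
    ``eq13="covariance"`` the E[Z]² correction uses the sampling covariance
    s_{b̂i,b̂k} (the unbiased choice), while ``eq13="sd_product"`` uses the
    product of standard deviations s_{b̂i}·s_{b̂k} instead, for comparison.
    The intercept shifts all genotypic values equally and so contributes
    neither variance nor correction.

    ``backend="enumeration"`` computes the same quantity by exhaustive
    summation over all 3^L genotypes and serves as the correctness oracle for
    the default per-locus moment factorization.
    """
    if eq13 not in ("covariance", "sd_product"):
        raise ValueError("eq13 must be 'covariance' or 'sd_product'")
    work, labels, b, S = _working_effects(effects, spec, epistasis_included, corrected)
    p = _freq_array(freqs, spec)

    if backend == "moments":
        m, M2 = _moment_matrices(labels, p, work)
    elif backend == "enumeration":
        dist = genotype_distribution(p, work)
        X = build_design(dist.genotypes, work).to_numpy()
        m = dist.probs @ X
        M2 = X.T @ (dist.probs[:, None] * X)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    vg = b @ (M2 - np.outer(m, m)) @ b
    if corrected:
        ez2_corr = float(np.sum(S * M2))
        if eq13 == "covariance":
            ez_sq_corr = float(m @ S @ m)
        else:
            sd = np.sqrt(np.clip(np.diag(S), 0.0, None))
            ez_sq_corr = float(m @ np.outer(sd, sd) @ m)
        vg = vg - ez2_corr + ez_sq_corr
        if vg < 0:
            logger.warning(
                "bias-corrected V_G is negative (%.4g); reported unclipped", vg
            )
    return float(vg)


@dataclass
class AverageEffectResult:
    """Average effect of allele substitution at one locus.

    ``alpha = alpha1 - alpha2`` where alpha1/alpha2 are the allelic average
    effects (frequency-weighted conditional mean phenotypes of donor- and
    reference-allele carriers).  ``coeff`` is the vector c_k with
    α_k = c_kᵀ b̂ over ``coeff_labels``; ``contribution`` is 2 p_k q_k α_k²
    (bias-corrected when ``corrected``).
    """

    locus: str
    p: float
    alpha: float
    alpha1: float
    alpha2: float
    coeff: np.ndarray
    coeff_labels: tuple[str, ...]
    contribution: float
    corrected: bool = False


def average_effect(
    effects: EffectEstimates,
    freqs,
    spec: ModelSpec,
    locus: str,
    epistasis_included: bool = True,
    corrected: bool = False,
) -> AverageEffectResult:
    """Average effect α_k of substituting the donor allele at ``locus``.

    α_{k,1} = p_k E[Z|WW] + q_k E[Z|Ww] and α_{k,2} = p_k E[Z|Ww] +
    q_k E[Z|ww], with conditional means taken over Hardy–Weinberg / linkage-
    equilibrium genotypes at all other loci.  Without epistasis this reduces
    to α_k = a_k + d_k(q_k − p_k), independent of the other loci.  The
    corrected squared effect is (c_kᵀ b̂)² − c_kᵀ S c_k.
    """
    if locus not in spec.loci:
        raise ValueError(f"unknown locus {locus!r}")
    work, labels, b, S = _working_effects(effects, spec, epistasis_included, corrected)
    p = _freq_array(freqs, spec)
    pk = p[spec.loci.index(locus)]
    qk = 1.0 - pk

    cond_mean = {}
    for count in (2, 1, 0):
        m, _ = _moment_matrices(labels, p, work, condition=(locus, count))
        cond_mean[count] = m
    c1 = pk * cond_mean[2] + qk * cond_mean[1]
    c2 = pk * cond_mean[1] + qk * cond_mean[0]
    alpha1 = effects.mu + float(c1 @ b)
    alpha2 = effects.mu + float(c2 @ b)
    coeff = c1 - c2
    alpha = float(coeff @ b)

    alpha_sq = alpha * alpha
    if corrected:
        alpha_sq -= float(coeff @ S @ coeff)
    contribution = 2 * pk * qk * alpha_sq
    return AverageEffectResult(
        locus=locus, p=float(pk), alpha=alpha, alpha1=alpha1, alpha2=alpha2,
        coeff=coeff, coeff_labels=tuple(labels), contribution=float(contribution),
        corrected=corrected,
    )


@dataclass
class VarianceResult:
    """Variance components for one frequency set.

    Bias-corrected values may be negative when sampling error is large; they
    are reported unclipped.
    """

    vg: float
    va: float
    per_locus: list[AverageEffectResult]
    corrected: bool
    epistasis_included: bool

    def alpha(self, locus: str) -> float:
        for r in self.per_locus:
            if r.locus == locus:
                return r.alpha
        raise KeyError(locus)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"locus": r.locus, "p": r.p, "alpha": r.alpha,
             "contribution": r.contribution}
            for r in self.per_locus
        ]
        return pd.DataFrame(rows)


def additive_variance(
    effects: EffectEstimates,
    freqs,
    spec: ModelSpec,
    corrected: bool = False,
    epistasis_included: bool = True,
    eq13: str = "covariance",
) -> VarianceResult:
    """Additive variance V_A = Σ_k 2 p_k q_k α_k², with V_G alongside.

    Per-locus average effects (and, when ``corrected``, their bias-corrected
    squares) are summed over loci; the matching total genetic variance is
    computed with the same flags so callers get a coherent VarianceResult.
    """
    per_locus = [
        average_effect(effects, freqs, spec, locus, epistasis_included, corrected)
        for locus in spec.loci
    ]
    va = float(sum(r.contribution for r in per_locus))
    if corrected and va < 0:
        logger.warning("bias-corrected V_A is negative (%.4g); reported unclipped", va)
    vg = total_genetic_variance(
        effects, freqs, spec, corrected, epistasis_included, eq13=eq13
    )
    return VarianceResult(
        vg=vg, va=va, per_locus=per_locus,
        corrected=corrected, epistasis_included=epistasis_included,
    )
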