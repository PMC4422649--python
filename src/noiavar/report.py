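"""Derived summaries: epistatic deviations, pleiotropy, α trajectories,
and ensemble variance statistics.

These operations turn fitted effects into the study-level descriptions a
reader of a QTL-epistasis analysis expects: how far two-locus genotypic
values deviate from single-locus (non-epistatic) predictions, whether
effects are correlated across traits (pleiotropy), how the average effect of
a locus moves with allele frequencies at its epistatic partners, and the
distribution of variance components over an allele-frequency ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .design import ModelSpec
from .effects import EffectEstimates
from .freqs import FrequencyEnsemble
from .variance import additive_variance, predict_genotypic_value

__all__ = [
    "EpistasisDeviationSummary",
    "AlphaTrajectory",
    "EnsembleVarianceSummary",
    "epistatic_deviations",
    "pleiotropy_correlations",
    "alpha_trajectories",
    "ensemble_variance_summary",
]

#: two-locus genotype classes in AB-notation: A/a = donor/reference allele at
#: the first locus, B/b at the second
_CLASS_NAMES = {
    (0, 0): "aabb", (1, 0): "Aabb", (2, 0): "AAbb",
    (0, 1): "aaBb", (1, 1): "AaBb", (2, 1): "AABb",
    (0, 2): "aaBB", (1, 2): "AaBB", (2, 2): "AABB",
}
#: classes unobservable from single-segment lines (both loci non-reference)
UNOBSERVED_CLASSES = ("AABB", "AaBB", "AABb", "AaBb")


@dataclass
class EpistasisDeviationSummary:
    """Deviations between epistatic and non-epistatic genotypic values."""

    trait: str
    per_genotype: pd.DataFrame  # pair, class, value_epi, value_nonepi, deviation
    classes: tuple[str, ...]
    mean_dev: float
    sd_dev: float
    #: (Σ|non-epi| − Σ|epi|) normalized by Σ|non-epi| (and by Σ|epi|): negative
    #: values indicate synergism (epistasis amplifies deviations from the
    #: reference genotype), positive diminishing returns
    synergism_pct: float
    synergism_pct_alt: float


def epistatic_deviations(
    full: "NoiaResults | EffectEstimates",
    reduced: "NoiaResults | EffectEstimates",
    spec: ModelSpec,
    trait: str = "",
    classes: str = "unobserved",
) -> EpistasisDeviationSummary:
    """Per-pair, per-class deviation of epistatic from non-epistatic values.

    For each modelled pair, the nine two-locus genotype classes (all other
    loci reference) are predicted twice: with the full effect set including
    interactions, and with the a/d effects of the reduced (single-segment)
    fit only.  ``classes="unobserved"`` summarizes over the four classes that
    single-segment lines cannot produce; ``"all"`` uses all nine.
    """
    if classes not in ("unobserved", "all"):
        raise ValueError("classes must be 'unobserved' or 'all'")
    eff_full = full if isinstance(full, EffectEstimates) else full.effects
    eff_red = reduced if isinstance(reduced, EffectEstimates) else reduced.effects
    if not spec.pairs:
        raise ValueError("spec has no modelled pairs")

    rows = []
    for la, lb in spec.pairs:
        for (ga, gb), name in _CLASS_NAMES.items():
            geno = {l: 0 for l in spec.loci}
            geno[la], geno[lb] = ga, gb
            z_epi = predict_genotypic_value(eff_full, geno, spec, True)
            z_non = predict_genotypic_value(eff_red, geno, spec, False)
            rows.append({
                "pair": f"{la}:{lb}", "class": name,
                "value_epi": z_epi, "value_nonepi": z_non,
                "deviation": z_epi - z_non,
                # deviations from each model's own reference value
                "dev_from_ref_epi": z_epi - eff_full.mu,
                "dev_from_ref_nonepi": z_non - eff_red.mu,
            })
    table = pd.DataFrame(rows)
    use = tuple(_CLASS_NAMES.values()) if classes == "all" else UNOBSERVED_CLASSES
    sub = table[table["class"].isin(use)]
    sum_non = float(sub["dev_from_ref_nonepi"].abs().sum())
    sum_epi = float(sub["dev_from_ref_epi"].abs().sum())
    return EpistasisDeviationSummary(
        trait=trait or eff_full.trait,
        per_genotype=table,
        classes=use,
        mean_dev=float(sub["deviation"].mean()),
        sd_dev=float(sub["deviation"].std(ddof=1)),
        synergism_pct=(sum_non - sum_epi) / sum_non if sum_non else np.nan,
        synergism_pct_alt=(sum_non - sum_epi) / sum_epi if sum_epi else np.nan,
    )


def pleiotropy_correlations(effect_tables: dict[str, EffectEstimates]) -> pd.DataFrame:
    """Pearson correlations of genetic-effect vectors between trait pairs.

    All genetic effects (everything except the intercept) enter; effect
    labels must align exactly across traits.  Returns a tidy table with one
    row per unordered trait pair: r and the two-sided p-value.
    """
    traits = list(effect_tables)
    if len(traits) < 2:
        raise ValueError("need at least two traits")
    ref_labels = [l for l in effect_tables[traits[0]].labels if l != "mu"]
    vectors = {}
    for t in traits:
        eff = effect_tables[t]
        labels = [l for l in eff.labels if l != "mu"]
        if labels != ref_labels:
            raise ValueError(f"effect labels of trait {t!r} do not align")
        vectors[t] = np.array([eff[l] for l in ref_labels])
    rows = []
    for i, t1 in enumerate(traits):
        for t2 in traits[i + 1:]:
            r, p = scipy.stats.pearsonr(vectors[t1], vectors[t2])
            rows.append({"trait_1": t1, "trait_2": t2,
                         "r": float(r), "p_value": float(p),
                         "n_effects": len(ref_labels)})
    return pd.DataFrame(rows)


@dataclass
class AlphaTrajectory:
    """Average effect of one locus across an allele-frequency ensemble.

    ``points`` holds (p_k, α_k with epistasis) per ensemble set; ``slope``/
    ``intercept`` are the least-squares line through the scatter.  The
    non-epistatic baseline α_k(p) = a_k + d_k(1 − 2p) is a straight line
    with slope −2 d_k — horizontal if and only if the locus acts additively.
    """

    locus: str
    trait: str
    points: pd.DataFrame  # columns: p, alpha
    slope: float
    intercept: float
    baseline_intercept: float  # a + d at p = 0
    baseline_slope: float      # -2 d

    def baseline(self, p):
        return self.baseline_intercept + self.baseline_slope * np.asarray(p)


def alpha_trajectories(
    effects: EffectEstimates,
    ensemble: FrequencyEnsemble,
    spec: ModelSpec,
    locus: str,
    baseline_effects: EffectEstimates | None = None,
    trait: str = "",
) -> AlphaTrajectory:
    """α_k (with epistasis) at every ensemble set, with an OLS trend line.

    The baseline line uses the a/d estimates of ``baseline_effects`` (by
    default the same effect set), as a single-locus model would predict.
    """
    if tuple(ensemble.loci) != tuple(spec.loci):
        raise ValueError("ensemble loci do not match spec loci")
    from .variance import average_effect

    k = spec.loci.index(locus)
    pts = []
    for freq_set in ensemble:
        res = average_effect(effects, freq_set, spec, locus, epistasis_included=True)
        pts.append((freq_set[k], res.alpha))
    points = pd.DataFrame(pts, columns=["p", "alpha"])
    slope, intercept = np.polyfit(points["p"], points["alpha"], 1)
    base = baseline_effects if baseline_effects is not None else effects
    a, d = base[f"a:{locus}"], base[f"d:{locus}"]
    return AlphaTrajectory(
        locus=locus, trait=trait or effects.trait, points=points,
        slope=float(slope), intercept=float(intercept),
        baseline_intercept=float(a + d), baseline_slope=float(-2 * d),
    )


@dataclass
class EnsembleVarianceSummary:
    """Mean/SD of V_G and V_A over an allele-frequency ensemble."""

    trait: str
    distribution: str
    corrected: bool
    epistasis_included: bool
    n_sets: int
    mean_vg: float
    sd_vg: float
    mean_va: float
    sd_va: float
    #: ratio of mean V_A to mean V_G; NaN when mean V_G ≤ 0
    va_vg_ratio: float
    values: pd.DataFrame  # per-set vg, va

    def density(self, quantity: str = "va", bins: int = 30):
        """Binned histogram (density=True) of per-set values, for plotting."""
        return np.histogram(self.values[quantity], bins=bins, density=True)


def ensemble_variance_summary(
    effects: EffectEstimates,
    ensemble: FrequencyEnsemble,
    spec: ModelSpec,
    corrected: bool = True,
    epistasis_included: bool = True,
    trait: str = "",
) -> EnsembleVarianceSummary:
    """Evaluate V_G and V_A at every frequency set and summarize.

    The reported additive fraction is the ratio of the mean V_A to the mean
    V_G (reported as NaN when the mean V_G is non-positive, where the ratio
    is not meaningful).
    """
    rows = []
    for freq_set in ensemble:
        vr = additive_variance(effects, freq_set, spec, corrected, epistasis_included)
        rows.append({"vg": vr.vg, "va": vr.va})
    values = pd.DataFrame(rows)
    mean_vg = float(values["vg"].mean())
    mean_va = float(values["va"].mean())
    return EnsembleVarianceSummary(
        trait=trait or effects.trait, distribution=ensemble.distribution,
        corrected=corrected, epistasis_included=epistasis_included,
        n_sets=len(ensemble),
        mean_vg=mean_vg, sd_vg=float(values["vg"].std(ddof=1)),
        mean_va=mean_va, sd_va=float(values["va"].std(ddof=1)),
        va_vg_ratio=(mean_va / mean_vg) if mean_vg > 0 else float("nan"),
        values=values,
    )
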