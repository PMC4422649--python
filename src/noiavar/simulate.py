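"""Synthetic phenotype datasets: free-form, balanced and study-like designs.

Trait values are generated as

    trait = genotypic value (from the supplied functional effects)
          + cohort draw + family draw + residual draw,

with Gaussian random effects shared within their groups.  Two generators are
provided: :func:`simulate_dataset` for explicit configurations (including
parametric-bootstrap replicates that mirror the grouping structure of a
template table), and :func:`simulate_study_like` which emulates the
dimensions of the seven-QTL floral panel — 11 of 21 possible locus pairs
observed as two-segment lines with all nine two-locus genotype classes, 12
cohorts, seed families nested within genotype and cohort, and unbalanced
replication totalling roughly 10,500 plants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import STUDY_LOCI, ModelSpec
from .effects import EffectEstimates
from .variance import predict_genotypic_value

__all__ = [
    "SimulationConfig",
    "simulate_dataset",
    "simulate_study_like",
    "STUDY_PAIRS",
    "study_spec",
]

#: the eleven modelled locus pairs of the study-like design.  The four pairs
#: highlighted in the worked examples are included; the remainder is a fixed,
#: synthetic choice (the real panel's pair list is not part of this package).
STUDY_PAIRS = (
    ("x1", "x9"), ("x5a", "x9"), ("x5a", "x10a"), ("x8", "x10a"),
    ("x1", "x5a"), ("x1", "x8"), ("x1", "x10b"), ("x5b", "x8"),
    ("x5b", "x9"), ("x5b", "x10b"), ("x8", "x10b"),
)


def study_spec(include_epistasis: bool = True) -> ModelSpec:
    """The seven-locus, eleven-pair model specification."""
    return ModelSpec(STUDY_LOCI, STUDY_PAIRS, include_epistasis)


@dataclass
class SimulationConfig:
    """Generating model for one simulated trait.

    ``design="balanced"`` lays out ``n_per_cell`` plants (one family) for
    each of the nine two-locus genotype classes of every modelled pair in
    each of ``n_cohorts`` cohorts; ``design="mirror"`` replicates the row,
    cohort and family structure of ``template`` exactly (the parametric-
    bootstrap case).  The covariance attached to ``true_effects`` is ignored.
    """

    spec: ModelSpec
    true_effects: EffectEstimates
    var_cohort: float = 0.0
    var_family: float = 0.0
    var_residual: float = 0.0
    design: str = "balanced"
    template: pd.DataFrame | None = None
    n_per_cell: int = 4
    n_cohorts: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.var_cohort, self.var_family, self.var_residual) < 0:
            raise ValueError("variance components must be nonnegative")
        if self.design not in ("balanced", "mirror"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.design == "mirror" and self.template is None:
            raise ValueError("mirror design requires a template table")


def _balanced_skeleton(spec: ModelSpec, n_per_cell: int, n_cohorts: int) -> pd.DataFrame:
    """Row skeleton: cohort, family and genotype columns, no trait yet."""
    loci = spec.loci
    rows = []
    cells = []
    if spec.pairs:
        for pi, (la, lb) in enumerate(spec.pairs):
            for ga in (0, 1, 2):
                for gb in (0, 1, 2):
                    cells.append((f"p{pi}", {la: ga, lb: gb}))
    else:
        for locus in loci:
            for g in (0, 1, 2):
                cells.append((f"s:{locus}", {locus: g}))
    for c in range(n_cohorts):
        for tag, geno in cells:
            gcode = "".join(str(geno.get(l, 0)) for l in loci)
            fam = f"c{c}:{tag}:{gcode}"
            for _ in range(n_per_cell):
                row = {"cohort": f"c{c}", "family": fam}
                row.update({l: geno.get(l, 0) for l in loci})
                rows.append(row)
    return pd.DataFrame(rows)


def simulate_dataset(cfg: SimulationConfig, seed: int | None = None) -> pd.DataFrame:
    """Simulate one phenotype table under ``cfg`` (reproducible by seed)."""
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    if cfg.design == "mirror":
        keep = ["cohort", "family", *cfg.spec.loci]
        missing = [c for c in keep if c not in cfg.template.columns]
        if missing:
            raise ValueError(f"template lacks columns {missing}")
        df = cfg.template[keep].reset_index(drop=True).copy()
    else:
        df = _balanced_skeleton(cfg.spec, cfg.n_per_cell, cfg.n_cohorts)

    gvalues = predict_genotypic_value(cfg.true_effects, df, cfg.spec)
    coh_labels, coh_idx = np.unique(df["cohort"].astype(str), return_inverse=True)
    fam_labels, fam_idx = np.unique(df["family"].astype(str), return_inverse=True)
    coh_eff = rng.normal(0.0, np.sqrt(cfg.var_cohort), len(coh_labels))
    fam_eff = rng.normal(0.0, np.sqrt(cfg.var_family), len(fam_labels))
    resid = rng.normal(0.0, np.sqrt(cfg.var_residual), len(df))
    trait = cfg.true_effects.trait or "trait"
    df[trait] = gvalues + coh_eff[coh_idx] + fam_eff[fam_idx] + resid
    df.insert(0, "plant_id", [f"p{i:06d}" for i in range(len(df))])
    return df


# -------------------------------------------------------------- study-like

#: per-trait generating priors for the study-like fixture: intercept
#: (reference-line value), prior SDs of a/d/epistatic effects, and the three
#: variance components (trait units²).  Magnitudes are chosen to look like a
#: medium-effect floral QTL panel (mm-scale morphology, day-scale phenology).
_STUDY_TRAITS = {
    "CW":   dict(mu=20.0, sd_a=0.45, sd_d=0.30, sd_epi=0.30,
                 var_cohort=0.25, var_family=0.35, var_residual=2.9),
    "SA":   dict(mu=2.2,  sd_a=0.12, sd_d=0.08, sd_epi=0.10,
                 var_cohort=0.02, var_family=0.03, var_residual=0.20),
    "Pist": dict(mu=12.0, sd_a=0.25, sd_d=0.15, sd_epi=0.18,
                 var_cohort=0.08, var_family=0.12, var_residual=1.0),
    "DTF":  dict(mu=55.0, sd_a=0.90, sd_d=0.60, sd_epi=0.70,
                 var_cohort=4.0,  var_family=2.0,  var_residual=16.0),
}

#: each pair is grown in 3 of the 12 cohorts; families per cohort x pair x
#: genotype class ~ U{2..5}; family sizes ~ geometric (mean ≈ 10 x scale,
#: truncated at 40) to mimic unbalanced replication.
_N_COHORTS = 12
_COHORTS_PER_PAIR = 3
_MEAN_FAMILY_SIZE = 10.3


def draw_study_effects(spec: ModelSpec, trait: str, rng) -> EffectEstimates:
    """Draw one functional effect set for ``trait`` from the study priors."""
    pr = _STUDY_TRAITS[trait]
    labels = ["mu"] + spec.design_columns()
    values = []
    for lab in labels:
        if lab == "mu":
            values.append(pr["mu"])
        elif lab.startswith("a:"):
            values.append(rng.normal(0.0, pr["sd_a"]))
        elif lab.startswith("d:"):
            values.append(rng.normal(0.0, pr["sd_d"]))
        else:
            values.append(rng.normal(0.0, pr["sd_epi"]))
    return EffectEstimates(tuple(labels), np.array(values), None, trait=trait)


def simulate_study_like(
    seed: int, scale: float = 1.0, traits=("CW", "SA", "Pist", "DTF"),
    return_truth: bool = False,
):
    """A full study-like phenotype table with all four traits.

    ``scale`` multiplies the mean family size (hence total records); the
    design skeleton (cohorts, pairs, genotype classes, family counts) is
    unchanged, so ``scale < 1`` yields a structurally identical but lighter
    dataset.  With ``return_truth=True`` also returns the per-trait
    :class:`SimulationConfig` used, for recovery checks.
    """
    ss = np.random.SeedSequence(seed)
    rng_design, rng_effects, rng_noise = [
        np.random.default_rng(s) for s in ss.spawn(3)
    ]
    spec = study_spec()
    loci = spec.loci

    rows = []
    mean_size = max(1.05, _MEAN_FAMILY_SIZE * scale)
    for pi, (la, lb) in enumerate(spec.pairs):
        cohorts = [(pi + 4 * k) % _N_COHORTS for k in range(_COHORTS_PER_PAIR)]
        for c in cohorts:
            for ga in (0, 1, 2):
                for gb in (0, 1, 2):
                    gcode = "".join(
                        str({la: ga, lb: gb}.get(l, 0)) for l in loci
                    )
                    n_fam = int(rng_design.integers(2, 6))
                    for f in range(n_fam):
                        size = int(min(rng_design.geometric(1.0 / mean_size), 40))
                        fam = f"c{c:02d}:p{pi:02d}:{gcode}:f{f}"
                        for _ in range(size):
                            row = {"cohort": f"c{c:02d}", "family": fam}
                            row.update({l: {la: ga, lb: gb}.get(l, 0) for l in loci})
                            rows.append(row)
    df = pd.DataFrame(rows)
    df.insert(0, "plant_id", [f"p{i:06d}" for i in range(len(df))])

    truth = {}
    for trait in traits:
        pr = _STUDY_TRAITS[trait]
        effects = draw_study_effects(spec, trait, rng_effects)
        cfg = SimulationConfig(
            spec=spec, true_effects=effects,
            var_cohort=pr["var_cohort"], var_family=pr["var_family"],
            var_residual=pr["var_residual"], design="mirror", template=df,
        )
        truth[trait] = cfg
        sim = simulate_dataset(cfg, seed=int(rng_noise.integers(2 ** 31)))
        df[trait] = sim[trait].to_numpy()
    return (df, truth) if return_truth else df
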