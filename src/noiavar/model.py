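"""REML fitting of the NOIA mixed linear model and the epistasis LRT.

The observation model for one trait is

    Z = μ + Σ_i a_i Xa_i + d_i Xd_i + Σ_pairs (aa, ad, da, dd interactions)
        + cohort + family + ε,

with cohort and family (nested within multilocus genotype) as Gaussian
random intercepts and within-family residual ε.  Fixed genetic effects are
estimated by REML together with their full model-based sampling covariance;
nested fixed-effect structures are compared by a likelihood-ratio test after
ML refits (REML likelihoods are not comparable across fixed-effect sets).

Fitting is delegated to :class:`statsmodels` MixedLM.  When every family
occurs in a single cohort (true of nursery designs where a seed family is
sown in one grow-up) the model is fitted with cohort as the grouping factor,
a random intercept per cohort, and family variance components within cohort,
which is much faster and more stable than the general crossed layout; the
crossed layout (a single group containing all observations, with variance
components for both factors) is used as a fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
import statsmodels.api as sm

from .design import ModelSpec, build_design
from .effects import EffectEstimates

__all__ = [
    "NoiaModel",
    "NoiaResults",
    "LRTResult",
    "FitError",
    "fit_noia_model",
    "likelihood_ratio_test",
]


class FitError(RuntimeError):
    """Raised for rank-deficient designs or optimizer failures."""


@dataclass
class LRTResult:
    """Likelihood-ratio test of nested fixed-effect structures (ML refits)."""

    chi2: float
    df: int
    p_value: float


def _check_rank(X: np.ndarray, labels) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, pivoting=True, mode="economic")
        bad = sorted(labels[i] for i in piv[rank:])
        raise FitError(
            f"design is rank deficient: no informative contrast for {bad}"
        )


class NoiaModel:
    """NOIA mixed model for one trait of a multilocus phenotype table.

    Parameters
    ----------
    data : DataFrame
        One row per plant with ``cohort``, ``family``, one genotype column
        per locus (donor-allele counts 0/1/2 or ww/Ww/WW codes) and the trait
        column.  Rows with a missing trait value are dropped.
    spec : ModelSpec
        Loci, modelled pairs and whether epistatic terms are included.
    trait : str
        Name of the trait column to fit.
    scope : {"full", "single_locus_only"}
        ``single_locus_only`` restricts to plants that are non-reference at
        at most one locus (the single-segment subset used for non-epistatic
        genotypic-value prediction).
    """

    def __init__(self, data: pd.DataFrame, spec: ModelSpec, trait: str,
                 scope: str = "full", cohort_col: str = "cohort",
                 family_col: str = "family"):
        if scope not in ("full", "single_locus_only"):
            raise ValueError(f"unknown scope {scope!r}")
        for col in (cohort_col, family_col, trait):
            if col not in data.columns:
                raise ValueError(f"data lacks required column {col!r}")
        self.spec = spec
        self.trait = trait
        self.scope = scope

        df = data.loc[data[trait].notna()].copy()
        y = pd.to_numeric(df[trait], errors="coerce")
        if y.isna().any():
            row = int(df.index[y.isna()][0])
            raise ValueError(f"non-numeric {trait!r} value at input row {row}")
        X = build_design(df, spec)
        if scope == "single_locus_only":
            nonref = (X[[f"a:{l}" for l in spec.loci]].to_numpy() > 0).sum(axis=1)
            keep = nonref <= 1
            df, X, y = df.loc[keep], X.loc[keep], y.loc[keep]
        self.design = X.reset_index(drop=True)
        self.endog = y.to_numpy(dtype=float)
        self.cohort = df[cohort_col].astype(str).to_numpy()
        # family nested within genotype via composite keying
        gkey = X[[f"a:{l}" for l in spec.loci] + [f"d:{l}" for l in spec.loci]]
        gstr = gkey.astype(int).astype(str).agg("".join, axis=1).to_numpy()
        self.family = np.char.add(
            np.char.add(df[family_col].astype(str).to_numpy(), "|"), gstr
        )
        self.nobs = len(self.endog)
        self.labels = ("mu",) + tuple(self.design.columns)
        Xmat = np.column_stack([np.ones(self.nobs), self.design.to_numpy()])
        _check_rank(Xmat, self.labels)
        self._Xmat = Xmat

    @classmethod
    def from_dataframe(cls, data, spec, trait, **kwargs) -> "NoiaModel":
        return cls(data, spec, trait, **kwargs)

    # ------------------------------------------------------------------ fit
    def fit(self, re_structure: str = "auto", fit_ml: bool = True,
            reml: bool = True) -> "NoiaResults":
        """Fit by REML (plus an ML refit for likelihood-ratio testing).

        ``re_structure``: ``"auto"`` picks the nested cohort/family layout
        when families do not cross cohorts, else the crossed layout;
        ``"nested"``/``"crossed"`` force a layout; ``"none"`` drops the
        random effects and fits by OLS (appropriate for data simulated
        without grouping noise).  With ``reml=False`` only the ML fit is run
        and also supplies the effect estimates — cheaper when the fit exists
        solely for a likelihood-ratio comparison.
        """
        if re_structure == "auto":
            fam_coh = pd.DataFrame({"f": self.family, "c": self.cohort})
            nested = (fam_coh.groupby("f")["c"].nunique() <= 1).all()
            n_coh = len(np.unique(self.cohort))
            re_structure = "nested" if (nested and n_coh >= 2) else "crossed"

        # degenerate noiseless data: REML is undefined, exact OLS solution
        ols = sm.OLS(self.endog, self._Xmat).fit()
        if re_structure == "none" or ols.ssr <= 1e-10 * max(1.0, ols.uncentered_tss):
            return self._package_ols(ols)

        k = self.design.shape[1]
        safe = [f"g{i:03d}" for i in range(k)]
        df = pd.DataFrame(self.design.to_numpy(), columns=safe)
        df["_y"] = self.endog
        df["_cohort"] = self.cohort
        df["_family"] = self.family
        formula = "_y ~ " + " + ".join(safe)
        if re_structure == "nested":
            kwargs = dict(groups="_cohort", re_formula="1",
                          vc_formula={"family": "0 + C(_family)"})
        elif re_structure == "crossed":
            df["_one"] = 1
            vc = {}
            if len(np.unique(self.cohort)) > 1:
                vc["cohort"] = "0 + C(_cohort)"
            if len(np.unique(self.family)) > 1:
                vc["family"] = "0 + C(_family)"
            kwargs = dict(groups="_one", re_formula="0", vc_formula=vc)
        else:
            raise ValueError(f"unknown re_structure {re_structure!r}")

        mod = sm.MixedLM.from_formula(formula, data=df, **kwargs)

        def _fit(reml, start=None):
            # escalate through optimizers; variance components near a zero
            # boundary routinely defeat the default bfgs run
            res = mod.fit(reml=reml, start_params=start, maxiter=500)
            if not res.converged:
                res = mod.fit(reml=reml, method="powell", maxiter=3000)
            if not res.converged:
                res = mod.fit(reml=reml, method="nm", maxiter=5000)
            if not res.converged:
                raise FitError(
                    f"{'REML' if reml else 'ML'} fit failed to converge "
                    f"(trait {self.trait!r}, n={self.nobs}, layout {re_structure})"
                )
            return res

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if reml:
                res = _fit(reml=True)
                res_ml = _fit(reml=False, start=res.params_object) if fit_ml else None
            else:
                res = res_ml = _fit(reml=False)

        k_fe = k + 1
        fe = np.asarray(res.fe_params, dtype=float)
        cov = np.asarray(res.cov_params())[:k_fe, :k_fe]
        effects = EffectEstimates(self.labels, fe, cov, trait=self.trait)
        if re_structure == "nested":
            var_cohort = float(res.cov_re.iloc[0, 0])
            var_family = float(res.vcomp[0])
        else:
            vc_names = list(mod.exog_vc.names)
            var_cohort = (
                float(res.vcomp[vc_names.index("cohort")])
                if "cohort" in vc_names else 0.0
            )
            var_family = (
                float(res.vcomp[vc_names.index("family")])
                if "family" in vc_names else 0.0
            )
        return NoiaResults(
            model=self, effects=effects,
            llf_reml=float(res.llf) if reml else np.nan,
            llf_ml=float(res_ml.llf) if res_ml is not None else np.nan,
            aic=float(res_ml.aic) if res_ml is not None else np.nan,
            var_cohort=var_cohort, var_family=var_family,
            var_residual=float(res.scale), n_obs=self.nobs,
            re_structure=re_structure,
        )

    def _package_ols(self, ols) -> "NoiaResults":
        degenerate = ols.ssr <= 1e-10 * max(1.0, ols.uncentered_tss)
        cov = (np.zeros((len(self.labels),) * 2) if degenerate
               else np.asarray(ols.cov_params()))
        effects = EffectEstimates(
            self.labels, np.asarray(ols.params, dtype=float), cov, trait=self.trait
        )
        llf = np.nan if degenerate else float(ols.llf)
        return NoiaResults(
            model=self, effects=effects, llf_reml=llf, llf_ml=llf,
            aic=np.nan if degenerate else float(ols.aic),
            var_cohort=0.0, var_family=0.0,
            var_residual=0.0 if degenerate else float(ols.ssr / ols.df_resid),
            n_obs=self.nobs, re_structure="none",
        )


@dataclass
class NoiaResults:
    """Fitted NOIA model: effect estimates, covariance and likelihoods."""

    model: NoiaModel
    effects: EffectEstimates
    llf_reml: float
    llf_ml: float
    aic: float
    var_cohort: float
    var_family: float
    var_residual: float
    n_obs: int
    re_structure: str

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    # ------------------------------------------------------- derived output
    def predict(self, genotypes, epistasis_included: bool = True):
        from .variance import predict_genotypic_value

        return predict_genotypic_value(
            self.effects, genotypes, self.spec, epistasis_included
        )

    def variance_components(self, freqs, corrected: bool = True,
                            epistasis_included: bool | None = None, **kwargs):
        from .variance import additive_variance

        if epistasis_included is None:
            epistasis_included = self.spec.include_epistasis
        return additive_variance(
            self.effects, freqs, self.spec, corrected, epistasis_included, **kwargs
        )

    def average_effect(self, freqs, locus, **kwargs):
        from .variance import average_effect

        return average_effect(self.effects, freqs, self.spec, locus, **kwargs)

    def compare_lr_test(self, reduced: "NoiaResults") -> LRTResult:
        return likelihood_ratio_test(self, reduced)

    def summary(self) -> str:
        lines = [
            f"NOIA mixed model — trait {self.effects.trait!r}, "
            f"n = {self.n_obs}, scope = {self.model.scope}",
            f"loci: {', '.join(self.spec.loci)}; "
            f"{len(self.spec.pairs)} epistatic pair(s) "
            f"({'included' if self.spec.include_epistasis else 'excluded'})",
            f"logLik REML = {self.llf_reml:.3f}, ML = {self.llf_ml:.3f}, "
            f"AIC = {self.aic:.1f}",
            f"var(cohort) = {self.var_cohort:.4g}, "
            f"var(family) = {self.var_family:.4g}, "
            f"var(residual) = {self.var_residual:.4g}  [{self.re_structure}]",
            "",
            self.effects.to_frame().to_string(
                index=False, float_format=lambda v: f"{v: .4f}"
            ),
        ]
        return "\n".join(lines)


def fit_noia_model(data, spec: ModelSpec, trait: str,
                   dataset_scope: str = "full", **fit_kwargs) -> NoiaResults:
    """Convenience wrapper: build a :class:`NoiaModel` and fit it."""
    return NoiaModel(data, spec, trait, scope=dataset_scope).fit(**fit_kwargs)


def likelihood_ratio_test(full: NoiaResults, reduced: NoiaResults) -> LRTResult:
    """LRT of nested fixed-effect structures using the ML log-likelihoods.

    chi² = 2(ℓ_full − ℓ_reduced) referred to a chi-squared distribution with
    df equal to the number of extra fixed-effect columns.  Both fits must use
    the same observations.
    """
    if not set(reduced.effects.labels) <= set(full.effects.labels):
        raise ValueError("models are not nested (reduced effects not a subset)")
    if full.n_obs != reduced.n_obs:
        raise ValueError(
            f"models fitted to different data (n={full.n_obs} vs {reduced.n_obs})"
        )
    if np.isnan(full.llf_ml) or np.isnan(reduced.llf_ml):
        raise ValueError("ML log-likelihoods unavailable; refit with fit_ml=True")
    df = len(full.effects.labels) - len(reduced.effects.labels)
    chi2 = 2.0 * (full.llf_ml - reduced.llf_ml)
    if chi2 < -1e-3:
        warnings.warn(
            f"negative LR statistic ({chi2:.4g}); ML refit may not have "
            "reached the optimum", RuntimeWarning
        )
    chi2 = max(chi2, 0.0)
    p = 1.0 if df == 0 else float(scipy.stats.chi2.sf(chi2, df))
    return LRTResult(chi2=float(chi2), df=df, p_value=p)
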