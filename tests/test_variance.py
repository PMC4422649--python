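"""Variance engine: closed forms, enumeration oracles, bias correction."""

import itertools

import numpy as np
import pytest

from noiavar import (
    EffectEstimates,
    ModelSpec,
    additive_variance,
    average_effect,
    genotype_distribution,
    predict_genotypic_value,
    single_locus_va,
    total_genetic_variance,
)

from conftest import random_effects


# ------------------------------------------------------ genotype distribution

def test_hw_single_locus_half():
    dist = genotype_distribution([0.5], ModelSpec(("A",)))
    probs = dict(zip(map(tuple, dist.genotypes), dist.probs))
    assert probs[(0,)] == pytest.approx(0.25)
    assert probs[(1,)] == pytest.approx(0.5)
    assert probs[(2,)] == pytest.approx(0.25)


def test_fixation_concentrates_mass():
    dist = genotype_distribution([1.0, 0.0], ModelSpec(("A", "B")))
    idx = np.argmax(dist.probs)
    assert dist.probs[idx] == pytest.approx(1.0)
    assert tuple(dist.genotypes[idx]) == (2, 0)


def test_distribution_sums_and_marginals(rng):
    spec = ModelSpec(("A", "B", "C"))
    p = rng.random(3)
    dist = genotype_distribution(p, spec)
    assert dist.probs.sum() == pytest.approx(1.0, abs=1e-12)
    # marginal donor-allele frequency at each locus is recovered
    marg = (dist.probs[:, None] * dist.genotypes).sum(axis=0) / 2.0
    np.testing.assert_allclose(marg, p, atol=1e-12)


# ------------------------------------------------------------ genotypic value

def test_predict_reference_is_mu(spec3):
    eff = EffectEstimates.from_mapping(
        {"mu": 10.0}, labels=["mu"] + spec3.design_columns()
    )
    assert eff.mu == 10.0
    assert predict_genotypic_value(eff, {"A": 0, "B": 0, "C": 0}, spec3) == 10.0


def test_predict_direct_substitution(spec2):
    eff = EffectEstimates.from_mapping(
        {"mu": 10.0, "a:A": 1.5}, labels=["mu"] + spec2.design_columns()
    )
    assert predict_genotypic_value(eff, {"A": 2, "B": 0}, spec2) == pytest.approx(13.0)
    eff2 = EffectEstimates.from_mapping(
        {"mu": 0.0, "a:A": 1.0, "a:B": 1.0, "aa:A:B": 0.5},
        labels=["mu"] + spec2.design_columns(),
    )
    assert predict_genotypic_value(eff2, {"A": 2, "B": 2}, spec2) == pytest.approx(6.0)


# ------------------------------------------------------------- single locus

@pytest.mark.parametrize(
    "a, d, p, s, expected",
    [
        (1.0, 0.0, 0.5, None, 0.5),
        (0.0, 1.0, 0.5, None, 0.0),  # symmetric overdominance: alpha = 0
        (1.0, 0.0, 0.5, [[0.1, 0.0], [0.0, 0.0]], 0.45),
    ],
)
def test_single_locus_va_closed_forms(a, d, p, s, expected):
    assert single_locus_va(a, d, p, s) == pytest.approx(expected)


def test_single_locus_va_general_formula(rng):
    a, d, p = rng.normal(), rng.normal(), rng.random()
    q = 1 - p
    assert single_locus_va(a, d, p) == pytest.approx(2 * p * q * (a + d * (q - p)) ** 2)
    s = rng.normal(size=(2, 2))
    s = s @ s.T
    expected = 2 * p * q * (
        (a + d * (q - p)) ** 2
        - (s[0, 0] + 2 * (q - p) * s[0, 1] + (q - p) ** 2 * s[1, 1])
    )
    assert single_locus_va(a, d, p, s) == pytest.approx(expected)


# --------------------------------------------------------------- V_G engine

def test_vg_additive_locus_equals_va():
    spec = ModelSpec(("A",))
    eff = EffectEstimates.from_mapping(
        {"mu": 0.0, "a:A": 1.0, "d:A": 0.0}, labels=["mu", "a:A", "d:A"]
    )
    assert total_genetic_variance(eff, [0.5], spec) == pytest.approx(0.5)


def test_corrected_equals_uncorrected_when_cov_zero(spec3, rng):
    eff = random_effects(spec3, rng, with_cov=True)
    eff_zero = eff.replace_values(eff.values, np.zeros_like(eff.cov))
    p = rng.random(3)
    v_unc = total_genetic_variance(eff_zero, p, spec3, corrected=False)
    v_cor = total_genetic_variance(eff_zero, p, spec3, corrected=True)
    assert v_cor == pytest.approx(v_unc, abs=1e-12)


@pytest.mark.parametrize("corrected", [False, True])
@pytest.mark.parametrize("n_loci", [1, 2, 3, 4])
def test_moment_backend_matches_enumeration(n_loci, corrected, rng):
    """Per-locus moment factorization equals exhaustive 3^L summation."""
    loci = tuple(f"L{i}" for i in range(n_loci))
    pairs = tuple(itertools.combinations(loci, 2))[: max(0, n_loci - 1)]
    spec = ModelSpec(loci, pairs)
    for _ in range(5):
        eff = random_effects(spec, rng)
        p = rng.random(n_loci)
        v_mom = total_genetic_variance(eff, p, spec, corrected=corrected)
        v_enum = total_genetic_variance(
            eff, p, spec, corrected=corrected, backend="enumeration"
        )
        assert v_mom == pytest.approx(v_enum, abs=1e-10)


def test_eq13_sd_product_form_differs_but_matches_enumeration(spec3, rng):
    eff = random_effects(spec3, rng)
    p = rng.random(3)
    v_cov = total_genetic_variance(eff, p, spec3, corrected=True)
    v_sd = total_genetic_variance(eff, p, spec3, corrected=True, eq13="sd_product")
    v_sd_enum = total_genetic_variance(
        eff, p, spec3, corrected=True, eq13="sd_product", backend="enumeration"
    )
    assert v_sd == pytest.approx(v_sd_enum, abs=1e-10)
    assert v_sd != pytest.approx(v_cov, abs=1e-6)


def test_corrected_requires_covariance(spec3, rng):
    eff = random_effects(spec3, rng, with_cov=False)
    with pytest.raises(ValueError, match="covariance"):
        total_genetic_variance(eff, [0.5, 0.5, 0.5], spec3, corrected=True)


# ------------------------------------------------------------ average effect

def test_alpha_no_epistasis_closed_form():
    spec = ModelSpec(("A", "B"))
    eff = EffectEstimates.from_mapping(
        {"mu": 0.0, "a:A": 1.0, "d:A": 0.5, "a:B": -0.3, "d:B": 0.2},
        labels=["mu"] + spec.design_columns(),
    )
    res = average_effect(eff, [0.25, 0.7], spec, "A")
    assert res.alpha == pytest.approx(1.0 + 0.5 * (0.75 - 0.25))
    assert res.alpha == pytest.approx(res.alpha1 - res.alpha2)
    # additive locus: alpha = a at every frequency
    eff_add = EffectEstimates.from_mapping(
        {"mu": 0.0, "a:A": 1.0}, labels=["mu"] + spec.design_columns()
    )
    for p in (0.1, 0.5, 0.9):
        assert average_effect(eff_add, [p, 0.3], spec, "A").alpha == pytest.approx(1.0)


def _alpha_by_regression(eff, p, spec, locus):
    """Oracle: weighted least-squares regression of enumerated genotypic
    values on donor-allele counts; the partial slope at `locus` is alpha."""
    dist = genotype_distribution(p, spec)
    Z = predict_genotypic_value(eff, dist.genotypes, spec)
    X = np.column_stack([np.ones(len(Z)), dist.genotypes])
    W = dist.probs
    beta = np.linalg.lstsq(
        X.T @ (W[:, None] * X), X.T @ (W * Z), rcond=None
    )[0]
    return beta[1 + spec.loci.index(locus)]


def test_alpha_with_epistasis_matches_regression_oracle(rng):
    spec = ModelSpec(("A", "B"), (("A", "B"),))
    eff = EffectEstimates.from_mapping(
        {"mu": 1.0, "a:A": 1.0, "d:A": 0.2, "a:B": 0.5, "d:B": -0.4,
         "aa:A:B": 0.7, "ad:A:B": -0.2, "da:A:B": 0.3, "dd:A:B": 0.1},
        labels=["mu"] + spec.design_columns(),
    )
    alphas = []
    for p2 in (0.05, 0.25, 0.5, 0.75, 0.95):
        p = [0.4, p2]
        res = average_effect(eff, p, spec, "A")
        assert res.alpha == pytest.approx(_alpha_by_regression(eff, p, spec, "A"))
        # coefficient vector reproduces alpha as a linear form
        b, _ = eff.aligned(res.coeff_labels)
        assert res.coeff @ b == pytest.approx(res.alpha)
        alphas.append(res.alpha)
    # epistasis makes alpha_A depend on the partner's frequency
    assert np.ptp(alphas) > 0.1


def test_alpha_at_fixed_locus_is_finite_with_zero_contribution(spec2, rng):
    eff = random_effects(spec2, rng)
    for p_fixed in (0.0, 1.0):
        res = average_effect(eff, [p_fixed, 0.5], spec2, "A")
        assert np.isfinite(res.alpha)
        assert res.contribution == 0.0


# --------------------------------------------------------- additive variance

def test_va_sums_independent_loci_no_epistasis(rng):
    spec = ModelSpec(("A", "B", "C"))
    eff = random_effects(spec, rng, with_cov=False)
    p = rng.random(3)
    vr = additive_variance(eff, p, spec)
    expected = sum(
        single_locus_va(eff[f"a:{l}"], eff[f"d:{l}"], p[i])
        for i, l in enumerate(spec.loci)
    )
    assert vr.va == pytest.approx(expected)
    assert vr.va == pytest.approx(sum(r.contribution for r in vr.per_locus))


def test_va_equals_best_linear_predictor_variance(spec3, rng):
    """V_A is the variance of the best allele-count linear predictor."""
    eff = random_effects(spec3, rng, with_cov=False)
    p = rng.random(3)
    vr = additive_variance(eff, p, spec3)
    dist = genotype_distribution(p, spec3)
    Z = predict_genotypic_value(eff, dist.genotypes, spec3)
    X = np.column_stack([np.ones(len(Z)), dist.genotypes])
    W = dist.probs
    beta = np.linalg.lstsq(X.T @ (W[:, None] * X), X.T @ (W * Z), rcond=None)[0]
    fitted = X @ beta
    va_oracle = W @ (fitted - W @ Z) ** 2
    assert vr.va == pytest.approx(va_oracle)


def test_va_not_exceeding_vg_uncorrected(rng):
    """Least-squares projection: V_A <= V_G from exact effects (100 draws)."""
    spec = ModelSpec(("A", "B", "C"), (("A", "B"), ("A", "C"), ("B", "C")))
    for _ in range(100):
        eff = random_effects(spec, rng, with_cov=False)
        p = rng.random(3)
        vr = additive_variance(eff, p, spec)
        assert vr.va <= vr.vg + 1e-10


def test_all_fixed_frequencies_zero_variance(spec3, rng):
    eff = random_effects(spec3, rng, with_cov=False)
    for p in itertools.product((0.0, 1.0), repeat=3):
        vr = additive_variance(eff, np.array(p), spec3)
        assert vr.vg == pytest.approx(0.0, abs=1e-12)
        assert vr.va == pytest.approx(0.0, abs=1e-12)


def test_locus_relabelling_invariance(rng):
    spec = ModelSpec(("A", "B"), (("A", "B"),))
    mapping = {"mu": 0.5, "a:A": 1.0, "d:A": 0.3, "a:B": -0.6, "d:B": 0.1,
               "aa:A:B": 0.4, "ad:A:B": 0.2, "da:A:B": -0.1, "dd:A:B": 0.25}
    eff = EffectEstimates.from_mapping(mapping, labels=["mu"] + spec.design_columns())
    spec_r = ModelSpec(("X", "Y"), (("X", "Y"),))
    ren = {k.replace("A", "X").replace("B", "Y"): v for k, v in mapping.items()}
    eff_r = EffectEstimates.from_mapping(ren, labels=["mu"] + spec_r.design_columns())
    p = [0.3, 0.8]
    vr = additive_variance(eff, p, spec)
    vr_r = additive_variance(eff_r, p, spec_r)
    assert vr.vg == pytest.approx(vr_r.vg)
    assert vr.va == pytest.approx(vr_r.va)


def test_epistasis_flag_irrelevant_when_interactions_zero(spec2, rng):
    eff = EffectEstimates.from_mapping(
        {"mu": 2.0, "a:A": 0.8, "d:A": -0.3, "a:B": 0.4, "d:B": 0.6},
        labels=["mu"] + spec2.design_columns(),
    )
    p = rng.random(2)
    v_with = additive_variance(eff, p, spec2, epistasis_included=True)
    v_without = additive_variance(eff, p, spec2, epistasis_included=False)
    assert v_with.vg == pytest.approx(v_without.vg)
    assert v_with.va == pytest.approx(v_without.va)
    for r1, r2 in zip(v_with.per_locus, v_without.per_locus):
        assert r1.alpha == pytest.approx(r2.alpha)


def test_unmodelled_pairs_treated_as_zero(spec3, rng):
    """Effects lacking a modelled pair's labels behave as exact zeros."""
    full_labels = ["mu"] + spec3.design_columns()
    partial_labels = [l for l in full_labels if not l.endswith("B:C")]
    eff = EffectEstimates(
        tuple(partial_labels), rng.normal(0, 1, len(partial_labels)),
        np.eye(len(partial_labels)) * 0.01,
    )
    p = rng.random(3)
    v = total_genetic_variance(eff, p, spec3, corrected=True)
    assert np.isfinite(v)


def test_monte_carlo_unbiasedness_of_correction(spec3, rng):
    """Drawing b-hat ~ N(b, S): corrected V_G/V_A are mean-unbiased while
    uncorrected ones exceed the truth (the bias direction of estimation
    error entering squared effects)."""
    eff = random_effects(spec3, rng, scale=0.8, with_cov=False)
    k = len(eff.labels)
    A = rng.normal(0, 0.25, (k, k))
    S = A @ A.T
    S[0, :] = S[:, 0] = 0.0  # intercept estimated without error for clarity
    p = rng.random(3)
    true_vg = total_genetic_variance(eff, p, spec3)
    true_va = additive_variance(eff, p, spec3).va

    L = np.linalg.cholesky(S + 1e-12 * np.eye(k))
    n_draw = 2000
    vg_c, vg_u, va_c, va_u = [], [], [], []
    for _ in range(n_draw):
        b_hat = eff.values + L @ rng.standard_normal(k)
        e = EffectEstimates(eff.labels, b_hat, S)
        vg_u.append(total_genetic_variance(e, p, spec3, corrected=False))
        vg_c.append(total_genetic_variance(e, p, spec3, corrected=True))
        res_c = additive_variance(e, p, spec3, corrected=True)
        va_c.append(res_c.va)
        va_u.append(additive_variance(e, p, spec3, corrected=False).va)

    for vals_c, vals_u, truth in ((vg_c, vg_u, true_vg), (va_c, va_u, true_va)):
        se = np.std(vals_c, ddof=1) / np.sqrt(n_draw)
        assert abs(np.mean(vals_c) - truth) < 3 * se
        assert np.mean(vals_u) > truth
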