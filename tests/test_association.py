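"""Phenotype adjustment, rank-normal transform and dose association."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvgwas.association import (
    adjust_phenotype,
    gee_dose_association,
    inverse_normal_transform,
    linear_dose_association,
)


def make_covariates(rng, n):
    return pd.DataFrame(
        {
            "age": rng.uniform(20, 80, n),
            "sex": rng.integers(0, 2, n),
            "height": rng.uniform(1.5, 2.0, n),
            "PC1": rng.normal(size=n),
            "PC2": rng.normal(size=n),
            "PC3": rng.normal(size=n),
            "PC4": rng.normal(size=n),
        },
        index=[f"s{i}" for i in range(n)],
    )


def test_residuals_orthogonal_to_covariates(rng):
    cov = make_covariates(rng, 400)
    trait = pd.Series(rng.normal(size=400), index=cov.index)
    resid = adjust_phenotype(trait, cov)
    for col in ["age", "sex", "height", "PC1", "PC2", "PC3", "PC4"]:
        assert abs(np.corrcoef(resid, cov[col])[0, 1]) < 1e-10
    assert abs(np.corrcoef(resid, cov["age"] ** 2)[0, 1]) < 1e-10
    assert abs(resid.mean()) < 1e-10


def test_null_trait_residuals_are_centred_trait(rng):
    cov = make_covariates(rng, 3000)
    trait = pd.Series(rng.normal(loc=5.0, size=3000), index=cov.index)
    resid = adjust_phenotype(trait, cov)
    # covariates explain ~nothing, so residuals track the centred trait
    assert np.corrcoef(resid, trait - trait.mean())[0, 1] > 0.99


def test_covariate_coefficient_recovery(rng):
    import statsmodels.api as sm

    cov = make_covariates(rng, 4000)
    y = (2.0 - 0.03 * cov["age"] + 2e-4 * cov["age"] ** 2 + 0.3 * cov["sex"]
         + 3.0 * cov["height"] + rng.normal(scale=0.4, size=4000))
    from cnvgwas.association import build_adjustment_design

    X = build_adjustment_design(cov)
    fit = sm.OLS(y, X).fit()
    for name, truth in [("age", -0.03), ("age2", 2e-4), ("sex", 0.3),
                        ("height", 3.0)]:
        assert abs(fit.params[name] - truth) < 2 * fit.bse[name] + 1e-12


def test_constant_covariate_is_dropped_with_warning(rng):
    cov = make_covariates(rng, 200)
    cov["sex"] = 1
    trait = pd.Series(rng.normal(size=200), index=cov.index)
    with pytest.warns(UserWarning, match="sex"):
        resid = adjust_phenotype(trait, cov)
    assert len(resid) == 200


def test_inverse_normal_transform_blom_quantiles():
    # frozen Blom scores for n=5: Phi^-1((r-3/8)/5.25), r=1..5
    out = inverse_normal_transform(pd.Series([10.0, 20.0, 30.0, 40.0, 50.0]))
    expect = stats.norm.ppf((np.arange(1, 6) - 0.375) / 5.25)
    assert np.allclose(out, expect, atol=1e-12)
    assert np.allclose(
        out.to_numpy(),
        [-1.17976, -0.49720, 0.0, 0.49720, 1.17976], atol=1e-5)


def test_inverse_normal_transform_properties(rng):
    two = inverse_normal_transform(pd.Series([3.0, 7.0]))
    assert two.iloc[0] == pytest.approx(-two.iloc[1])
    x = pd.Series(rng.exponential(size=1000))
    z = inverse_normal_transform(x)
    assert abs(z.mean()) < 1e-10
    assert z.std() == pytest.approx(1.0, abs=0.05)
    # idempotence on tie-free input
    z2 = inverse_normal_transform(z)
    assert np.allclose(z, z2, atol=1e-6)
    with pytest.raises(ValueError):
        inverse_normal_transform(pd.Series([1.0, 1.0, 1.0]))


def test_perfect_linear_relation(rng):
    dose = rng.uniform(0, 2, 100)
    rec = linear_dose_association(2.0 * dose, dose)
    assert rec.beta == pytest.approx(2.0, abs=1e-10)
    assert rec.pvalue < 1e-100
    assert rec.direction == "+"


def test_zero_dose_variance_gives_no_result(rng):
    rec = linear_dose_association(rng.normal(size=50), np.ones(50))
    assert rec.direction == "."
    assert rec.beta is None


def test_permutation_null_type_one_error(rng):
    n, reps, alpha = 200, 400, 0.05
    dose = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.5, 0.4, 0.1])
    hits = 0
    for _ in range(reps):
        y = rng.normal(size=n)
        rec = linear_dose_association(y, dose)
        hits += rec.pvalue < alpha
    mc_se = np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(hits / reps - alpha) <= 2.5 * mc_se


def test_spiked_effect_recovered_within_two_se(rng):
    n = 5000
    dose = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.49, 0.42, 0.09])
    y = 0.05 * dose + rng.normal(scale=0.4, size=n)
    rec = linear_dose_association(y, dose)
    assert abs(rec.beta - 0.05) <= 2 * rec.se


def test_affine_dose_invariance(rng):
    n = 500
    dose = rng.choice([0.0, 1.0, 2.0], size=n)
    y = 0.1 * dose + rng.normal(scale=0.3, size=n)
    base = linear_dose_association(y, dose)
    shifted = linear_dose_association(y, dose + 5.0)
    assert shifted.beta == pytest.approx(base.beta, abs=1e-10)
    assert shifted.pvalue == pytest.approx(base.pvalue, abs=1e-10)
    scaled = linear_dose_association(y, 2.0 * dose)
    assert scaled.beta == pytest.approx(base.beta / 2.0, abs=1e-10)
    assert scaled.pvalue == pytest.approx(base.pvalue, rel=1e-8)


def test_gee_equals_ols_with_singleton_clusters(rng):
    n = 300
    dose = rng.uniform(0, 2, n)
    y = 0.2 * dose + rng.normal(size=n)
    ols = linear_dose_association(y, dose)
    gee = gee_dose_association(y, dose, np.arange(n))
    assert gee.beta == pytest.approx(ols.beta, rel=1e-8)
    assert gee.method == "gee"
    assert gee.direction == ("+" if gee.beta >= 0 else "-")


def _family_draw(rng, n_fam, size, icc, q=0.3, beta=0.0):
    """Families of siblings: genotype shared through parents, trait with ICC."""
    mother = rng.binomial(1, q, size=(n_fam, 2))
    father = rng.binomial(1, q, size=(n_fam, 2))
    pick_m = rng.integers(0, 2, size=(n_fam, size))
    pick_f = rng.integers(0, 2, size=(n_fam, size))
    g = (np.take_along_axis(mother, pick_m, axis=1)
         + np.take_along_axis(father, pick_f, axis=1))
    fam_eff = rng.normal(scale=np.sqrt(icc), size=(n_fam, 1))
    y = beta * g + fam_eff + rng.normal(scale=np.sqrt(1 - icc), size=(n_fam, size))
    groups = np.repeat(np.arange(n_fam), size)
    return y.ravel(), g.ravel().astype(float), groups


def test_gee_controls_family_type_one_error_where_ols_inflates(rng):
    reps, alpha = 300, 0.05
    gee_hits = ols_hits = 0
    for _ in range(reps):
        y, g, groups = _family_draw(rng, 80, 4, icc=0.5)
        gee_hits += gee_dose_association(y, g, groups).pvalue < alpha
        ols_hits += linear_dose_association(y, g).pvalue < alpha
    mc_se = np.sqrt(alpha * (1 - alpha) / reps)
    assert abs(gee_hits / reps - alpha) <= 3 * mc_se
    assert ols_hits / reps > 0.07


def test_gee_recovers_spiked_effect(rng):
    inside = 0
    for _ in range(40):
        y, g, groups = _family_draw(rng, 150, 4, icc=0.5, beta=0.15)
        rec = gee_dose_association(y, g, groups)
        inside += abs(rec.beta - 0.15) <= 2 * rec.se
    assert inside >= 36  # ~95% coverage
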