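"""Synthetic-data generator: HWE structure, noise model, tagging, determinism."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvgwas.simulate import (
    CohortSpec,
    SimConfig,
    hwe_class_frequencies,
    simulate_cnv_classes,
    simulate_intensities,
    simulate_multi_cohort_study,
    simulate_phenotypes,
    simulate_tag_snp,
)
from cnvgwas.simulate import small_study_config


@pytest.mark.parametrize(
    "cnv_type,k,q,expected",
    [
        ("deletion", 3, 0.3, (0.49, 0.42, 0.09)),
        ("deletion", 2, 0.1, (0.99, 0.01)),
        ("amplification", 3, 0.5, (0.25, 0.5, 0.25)),
    ],
)
def test_hwe_class_frequencies(cnv_type, k, q, expected):
    assert np.allclose(hwe_class_frequencies(cnv_type, k, q), expected, atol=1e-12)


def test_multiallelic_frequencies_are_truncated_convolution():
    # two independent variants at q: allele-sum 0..4 truncated at 3
    q = 0.3
    g = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    conv = np.convolve(g, g)
    expect = np.array([conv[0], conv[1], conv[2], conv[3] + conv[4]])
    assert np.allclose(hwe_class_frequencies("multiallelic", 4, q), expect)
    assert hwe_class_frequencies("multiallelic", 4, q).sum() == pytest.approx(1.0)


def test_simulated_class_frequencies_pass_goodness_of_fit():
    classes = simulate_cnv_classes("deletion", 3, 0.3, 10_000, seed=42)
    counts = np.bincount(classes, minlength=3)
    _, p = stats.chisquare(counts, 10_000 * np.array([0.49, 0.42, 0.09]))
    assert p > 0.001


@pytest.mark.parametrize("bad", [dict(k=5), dict(k=1), dict(q=0.0), dict(q=1.2)])
def test_class_simulation_rejects_bad_parameters(bad):
    kwargs = dict(cnv_type="deletion", k=3, q=0.3, n=10, seed=0)
    kwargs.update(bad)
    with pytest.raises(ValueError):
        simulate_cnv_classes(kwargs["cnv_type"], kwargs["k"], kwargs["q"],
                             kwargs["n"], seed=0)


def test_zero_noise_intensities_equal_class_means():
    mat = simulate_intensities(np.array([0, 1, 2]), 4, noise_sd=0.0, seed=0)
    expect = np.array([np.log2(0.125), -1.0, 0.0])
    assert mat.shape == (4, 3)
    assert np.allclose(mat, np.tile(expect, (4, 1)))
    assert not np.isnan(mat).any()  # missing_rate=0 injects nothing


def test_intensity_summary_standard_error_scales_with_probe_count(rng):
    # per-sample mean over 10 probes at noise 0.1 has SD 0.1/sqrt(10)
    classes = np.zeros(4000, dtype=int)
    mat = simulate_intensities(classes, 10, class_means=[0.0], noise_sd=0.1, seed=rng)
    summaries = mat.mean(axis=0)
    assert summaries.std() == pytest.approx(0.1 / np.sqrt(10), rel=0.05)


def test_intensities_reject_non_increasing_means():
    with pytest.raises(ValueError):
        simulate_intensities(np.array([0, 1]), 3, class_means=[0.0, -1.0], seed=0)


def test_phenotype_zero_noise_is_exact_covariate_function(rng):
    cov = pd.DataFrame({
        "age": rng.uniform(20, 70, 50),
        "sex": rng.integers(0, 2, 50),
        "height": rng.uniform(1.5, 1.9, 50),
    })
    betas = {"const": 1.0, "age": -0.02, "age2": 1e-4, "sex": 0.3,
             "height": 2.0, "height2": -0.1, "cnv": 0.0}
    y = simulate_phenotypes(np.zeros(50), cov, betas, residual_sd=1e-12, seed=0)
    mu = (1.0 - 0.02 * cov["age"] + 1e-4 * cov["age"] ** 2 + 0.3 * cov["sex"]
          + 2.0 * cov["height"] - 0.1 * cov["height"] ** 2)
    assert np.allclose(y, mu, atol=1e-9)


def test_family_intraclass_correlation_matches_target(rng):
    n_fam, size = 600, 4
    fam_ids = np.repeat(np.arange(n_fam), size)
    cov = pd.DataFrame({
        "age": np.full(n_fam * size, 50.0),
        "sex": np.zeros(n_fam * size),
        "height": np.full(n_fam * size, 1.7),
    })
    y = simulate_phenotypes(np.zeros(n_fam * size), cov, {}, residual_sd=1.0,
                            family_ids=fam_ids, family_icc=0.5, seed=rng)
    groups = y.to_numpy().reshape(n_fam, size)
    # one-way ANOVA ICC oracle
    grand = groups.mean()
    msb = size * ((groups.mean(axis=1) - grand) ** 2).sum() / (n_fam - 1)
    msw = ((groups - groups.mean(axis=1, keepdims=True)) ** 2).sum() / (n_fam * (size - 1))
    icc = (msb - msw) / (msb + (size - 1) * msw)
    assert icc == pytest.approx(0.5, abs=0.05)


def test_tag_snp_r2_calibration(rng):
    classes = simulate_cnv_classes("deletion", 3, 0.3, 5000, seed=rng)
    perfect = simulate_tag_snp(classes, target_r2=1.0, seed=rng)
    assert np.corrcoef(classes, perfect)[0, 1] ** 2 == pytest.approx(1.0)

    null = simulate_tag_snp(classes, target_r2=0.0, seed=rng)
    assert np.corrcoef(classes, null)[0, 1] ** 2 < 0.01  # E[r^2] ~ 1/(n-1)

    mid = simulate_tag_snp(classes, target_r2=0.94, seed=rng)
    r2 = np.corrcoef(classes, mid)[0, 1] ** 2
    assert 0.89 <= r2 <= 0.99


def test_tag_snp_rejects_multiallelic_without_generating_allele(rng):
    classes = simulate_cnv_classes("multiallelic", 4, 0.3, 100, seed=rng)
    with pytest.raises(ValueError):
        simulate_tag_snp(classes, target_r2=0.9, seed=0)


def test_same_seed_gives_identical_datasets():
    a = simulate_multi_cohort_study(small_study_config(seed=5))
    b = simulate_multi_cohort_study(small_study_config(seed=5))
    for name in a.cohorts:
        pd.testing.assert_frame_equal(a.cohorts[name].intensities,
                                      b.cohorts[name].intensities)
        pd.testing.assert_frame_equal(a.cohorts[name].phenotypes,
                                      b.cohorts[name].phenotypes)
        pd.testing.assert_frame_equal(a.cohorts[name].snp_dosages,
                                      b.cohorts[name].snp_dosages)


def test_cohort_sizes_and_structure_are_respected():
    cfg = small_study_config(seed=3)
    ds = simulate_multi_cohort_study(cfg)
    assert set(ds.cohorts) == {"A", "B"}
    for spec in cfg.cohorts:
        cd = ds.cohorts[spec.name]
        assert len(cd.phenotypes) == spec.n
        assert cd.true_classes.shape == (spec.n, len(cfg.cnvrs))
        n_probes = spec.probes_per_cnvr * len(cfg.cnvrs) + cfg.n_background_probes
        assert cd.intensities.shape == (spec.n, n_probes)
    # family cohort has multi-member families, the other has none
    fam_sizes = ds.cohorts["A"].phenotypes["family_id"].value_counts()
    assert (fam_sizes > 1).any()
    assert (ds.cohorts["B"].phenotypes["family_id"].value_counts() == 1).all()


def test_higher_noise_resolves_fewer_cnvrs():
    """Tripling the platform noise cannot increase the resolved-CNVR count."""
    from cnvgwas.calling import summarize_cnvr
    from cnvgwas.mixture import IntensityMixture

    def resolved_count(noise_sd, seed):
        cohorts = (CohortSpec("X", 250, noise_sd, 6),)
        cfg = SimConfig(cohorts=cohorts, cnvrs=small_study_config().cnvrs,
                        seed=seed)
        ds = simulate_multi_cohort_study(cfg)
        cd = ds.cohorts["X"]
        n = 0
        for region in ds.regions:
            summ = summarize_cnvr(cd.intensities, cd.probes, region)
            res = IntensityMixture(summ.values.to_numpy()).select(k_max=4, seed=0)
            n += res.is_polymorphic()
        return n

    lo = [resolved_count(0.10, s) for s in range(3)]
    hi = [resolved_count(0.60, s) for s in range(3)]
    assert sum(hi) <= sum(lo)
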