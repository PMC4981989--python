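"""Meta-analysis, thresholds, tag-SNP LD and replication logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cnvgwas.calling import CNVRegion
from cnvgwas.meta import (
    bonferroni_threshold,
    ivw_meta,
    replicate,
    select_suggestive,
    stouffer_meta,
    tag_r2,
    TagSNPResult,
)


def test_ivw_single_study_is_identity():
    res = ivw_meta([(0.5, 0.1)])
    assert res.beta == pytest.approx(0.5)
    assert res.se == pytest.approx(0.1)


def test_ivw_symmetric_studies_cancel():
    res = ivw_meta([(1.0, 1.0), (-1.0, 1.0)])
    assert res.beta == pytest.approx(0.0, abs=1e-12)
    assert res.se == pytest.approx(1.0 / np.sqrt(2.0))
    assert res.direction == "+-"


def test_ivw_identical_studies_shrink_se_by_sqrt_m():
    res = ivw_meta([(0.3, 0.05)] * 4)
    assert res.beta == pytest.approx(0.3)
    assert res.se == pytest.approx(0.05 / 2.0)


def test_ivw_rejects_zero_se():
    with pytest.raises(ValueError):
        ivw_meta([(0.1, 0.0)])


def test_stouffer_single_study_is_identity():
    res = stouffer_meta([(0.05, "+", 1000)])
    assert res.pvalue == pytest.approx(0.05, rel=1e-10)


def test_stouffer_equal_studies_closed_form():
    # m equal-weight studies at z: combined Z = z * sqrt(m)
    res = stouffer_meta([(0.05, "+", 500), (0.05, "+", 500)])
    z = stats.norm.isf(0.025)
    assert res.z == pytest.approx(z * np.sqrt(2), rel=1e-10)
    assert res.pvalue == pytest.approx(2 * stats.norm.sf(z * np.sqrt(2)), rel=1e-8)
    assert res.pvalue == pytest.approx(0.00556, abs=5e-5)


def test_stouffer_rejects_degenerate_p():
    with pytest.raises(ValueError):
        stouffer_meta([(0.0, "+", 100)])
    with pytest.raises(ValueError):
        stouffer_meta([(1.0, "+", 100)])


def test_z_to_p_roundtrip_is_stable():
    for z in np.linspace(0.1, 8.0, 40):
        p = 2 * stats.norm.sf(z)
        res = stouffer_meta([(p, "+", 100)])
        assert res.z == pytest.approx(z, abs=1e-8)


def test_bonferroni_thresholds():
    assert bonferroni_threshold(0.05, 1) == 0.05
    assert bonferroni_threshold(0.05, 8) == pytest.approx(6.25e-3)
    assert bonferroni_threshold(0.05, 1962) == pytest.approx(2.548e-5, rel=1e-3)


def test_suggestive_selection_is_strict():
    tab = pd.DataFrame({"pvalue": [0.001, 0.0009999, 0.5, 1e-6]})
    out = select_suggestive(tab, threshold=0.001)
    assert list(out.index) == [1, 3]
    assert select_suggestive(tab.iloc[:0], threshold=0.001).empty


def test_counting_against_constructed_table(rng):
    p = np.concatenate([rng.uniform(1e-6, 9e-4, 12), rng.uniform(0.01, 1, 88)])
    tab = pd.DataFrame({"pvalue": rng.permutation(p)})
    assert len(select_suggestive(tab, threshold=0.001)) == 12


def _snp_setup(rng, n, positions):
    samples = pd.Index([f"s{i}" for i in range(n)])
    pos = pd.DataFrame(
        [(f"snp{i}", "16", p, "A", "G") for i, p in enumerate(positions)],
        columns=["snp", "chrom", "pos", "effect_allele", "other_allele"],
    ).set_index("snp")
    return samples, pos


def test_tag_r2_perfect_and_null(rng):
    n = 5000
    region = CNVRegion("CNVRt", "16", 1_000_000, 1_003_000)
    classes = rng.choice([0.0, 1.0, 2.0], size=n, p=[0.49, 0.42, 0.09])
    samples, pos = _snp_setup(rng, n, [1_010_000, 1_500_000])
    dosages = pd.DataFrame(
        {"snp0": classes, "snp1": rng.binomial(2, 0.3, n).astype(float)},
        index=samples)
    res = tag_r2(pd.Series(classes, index=samples), pos, dosages, region)
    assert res.snp == "snp0"
    assert res.r2 == pytest.approx(1.0)
    assert res.tagged and res.align_sign == 1

    null_only = tag_r2(pd.Series(classes, index=samples), pos.iloc[[1]],
                       dosages[["snp1"]], region)
    assert null_only.r2 < 0.01
    assert not null_only.tagged


def test_tag_r2_window_and_no_tag(rng):
    n = 200
    region = CNVRegion("CNVRt", "16", 1_000_000, 1_003_000)
    classes = pd.Series(rng.choice([0.0, 1.0], size=n),
                        index=[f"s{i}" for i in range(n)])
    # 2 Mb away: outside the 1 Mb window
    samples, pos = _snp_setup(rng, n, [3_100_000])
    dosages = pd.DataFrame({"snp0": classes.to_numpy()}, index=samples)
    res = tag_r2(classes, pos, dosages, region)
    assert not res.tagged and res.snp is None
    assert "no tag" in res.reason


def test_tag_r2_negative_correlation_sets_alignment_sign(rng):
    n = 1000
    region = CNVRegion("CNVRt", "16", 1_000_000, 1_003_000)
    classes = pd.Series(rng.choice([0.0, 1.0, 2.0], size=n),
                        index=[f"s{i}" for i in range(n)])
    samples, pos = _snp_setup(rng, n, [1_050_000])
    dosages = pd.DataFrame({"snp0": 2.0 - classes.to_numpy()}, index=samples)
    res = tag_r2(classes, pos, dosages, region)
    assert res.r2 == pytest.approx(1.0)
    assert res.align_sign == -1


def test_threshold_boundary_strictness():
    assert TagSNPResult("r", "s", 0.766, 1, 0.766 > 0.7).tagged
    assert not (0.7 > 0.7)


def _replication_inputs(beta_sign=1.0, effect_allele="A"):
    suggestive = pd.DataFrame({"region_id": ["CNVRx"], "trait": ["FEV1"]})
    tags = {"CNVRx": TagSNPResult("CNVRx", "rs1", 0.94, 1, True)}
    study = pd.DataFrame(
        {"beta": [beta_sign * 0.02], "se": [0.008], "pvalue": [0.012],
         "n": [48000], "effect_allele": [effect_allele], "other_allele": ["G"]},
        index=pd.Index(["rs1"], name="snp"))
    return suggestive, tags, study


def test_replication_single_study_is_identity():
    suggestive, tags, study = _replication_inputs()
    rep = replicate(suggestive, tags, {"s1": study}, {"FEV1": "IVW"},
                    tag_effect_alleles={"CNVRx": "A"})
    assert len(rep) == 1
    row = rep.iloc[0]
    assert row["beta"] == pytest.approx(0.02)
    assert row["pvalue"] == pytest.approx(2 * stats.norm.sf(0.02 / 0.008), rel=1e-8)
    assert row["threshold"] == pytest.approx(0.05)


def test_replication_allele_flip_invariance():
    sug, tags, study_a = _replication_inputs(beta_sign=1.0, effect_allele="A")
    # same evidence reported on the other allele: beta flips sign
    _, _, study_g = _replication_inputs(beta_sign=-1.0, effect_allele="G")
    rep_a = replicate(sug, tags, {"s1": study_a}, {"FEV1": "IVW"},
                      tag_effect_alleles={"CNVRx": "A"})
    rep_g = replicate(sug, tags, {"s1": study_g}, {"FEV1": "IVW"},
                      tag_effect_alleles={"CNVRx": "A"})
    assert rep_a.iloc[0]["beta"] == pytest.approx(rep_g.iloc[0]["beta"])
    assert rep_a.iloc[0]["pvalue"] == pytest.approx(rep_g.iloc[0]["pvalue"])


def test_replication_missing_study_shows_dot():
    sug, tags, study = _replication_inputs()
    empty = study.iloc[:0]
    rep = replicate(sug, tags, {"s1": study, "s2": empty}, {"FEV1": "IVW"})
    assert rep.iloc[0]["direction"] == "+."


def test_replication_threshold_counts_tagged_tests():
    sug, tags, study = _replication_inputs()
    sug8 = pd.concat([sug] * 8, ignore_index=True)
    rep = replicate(sug8, tags, {"s1": study}, {"FEV1": "IVW"})
    assert rep.iloc[0]["threshold"] == pytest.approx(0.00625)
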