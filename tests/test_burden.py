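import math

import numpy as np
import pandas as pd
import pytest

from delload.burden import (burden_f_correlation, classify_deleterious,
                            compare_groups, heterozygosity_f,
                            individual_burden, interval_burden_frequency,
                            sift_gerp_overlap)

from conftest import intervals, make_annot, make_gm


def annot_frame(sift=None, gerp=None):
    n = len(sift) if sift is not None else len(gerp)
    return pd.DataFrame({
        "chrom": "chr1", "pos": np.arange(1, n + 1), "ref": "A", "alt": "G",
        "gene_id": "g", "effect": "ns",
        "sift_score": sift if sift is not None else [np.nan] * n,
        "gerp_score": gerp if gerp is not None else [np.nan] * n,
    })


@pytest.mark.parametrize("sift,gerp,expect_sift,expect_gerp", [
    (0.02, np.nan, True, False),     # predicted deleterious substitution
    (0.0, np.nan, True, False),      # fully intolerant site
    (0.05, 2.0, False, False),       # strict boundaries excluded
    (0.049, 2.001, True, True),
    (np.nan, np.nan, False, False),  # missing scores never flag
])
def test_classification_boundaries(sift, gerp, expect_sift, expect_gerp):
    out = classify_deleterious(annot_frame([sift], [gerp]))
    assert bool(out.loc[0, "is_deleterious_sift"]) is expect_sift
    assert bool(out.loc[0, "is_deleterious_gerp"]) is expect_gerp


def test_sift_gerp_overlap_matches_set_algebra():
    rng = np.random.default_rng(11)
    n = 50
    df = annot_frame(rng.uniform(0, 0.12, n), rng.uniform(0, 4, n))
    out = classify_deleterious(df)
    ov = sift_gerp_overlap(out)
    s = {i for i in range(n) if df.loc[i, "sift_score"] < 0.05}
    g = {i for i in range(n) if df.loc[i, "gerp_score"] > 2}
    assert ov["n_sift"] == len(s) and ov["n_gerp"] == len(g)
    assert ov["n_both"] == len(s & g)
    assert ov["fraction_of_gerp_in_sift"] == pytest.approx(len(s & g) / len(g))


def test_overlap_degenerate_sets():
    both = classify_deleterious(annot_frame([0.01, 0.01], [3.0, 3.0]))
    assert sift_gerp_overlap(both)["fraction_of_gerp_in_sift"] == 1.0
    disjoint = classify_deleterious(annot_frame([0.01, 0.5], [1.0, 3.0]))
    assert sift_gerp_overlap(disjoint)["n_both"] == 0


def test_individual_burden_hand_enumeration():
    gm = make_gm([[0, 0], [1, 0], [2, 0]])
    annot = make_annot(gm, [True, True, True])
    t = individual_burden(gm, annot).table.set_index("sample")
    assert t.loc["s0", ["n_total", "n_het", "n_hom"]].tolist() == [2, 1, 1]
    assert t.loc["s1", ["n_total", "n_het", "n_hom"]].tolist() == [0, 0, 0]
    alle = individual_burden(gm, annot, mode="allele").table.set_index("sample")
    assert alle.loc["s0", "n_total"] == 3   # dosage sum 0+1+2


def test_burden_partition_and_mode_bounds(small_cohort):
    annot = classify_deleterious(small_cohort.annotation)
    site = individual_burden(small_cohort.gm, annot).table
    assert (site["n_total"] == site["n_hom"] + site["n_het"]).all()
    alle = individual_burden(small_cohort.gm, annot, mode="allele").table
    assert (site["n_total"] <= alle["n_total"]).all()
    assert (alle["n_total"] <= 2 * site["n_total"]).all()


def test_interval_burden_frequency_formula():
    # 10 deleterious sites at 100..1000; intervals cover the first three
    gm = make_gm([[1]] * 10)
    annot = make_annot(gm, [True] * 10)
    iv = intervals(("chr1", 1, 300))
    assert interval_burden_frequency(gm, annot, iv)["s0"] == pytest.approx(30.0)
    whole = intervals(("chr1", 1, 10_000))
    assert interval_burden_frequency(gm, annot, whole)["s0"] == pytest.approx(100.0)


def test_interval_frequency_undefined_for_zero_burden():
    gm = make_gm([[0], [0]])
    annot = make_annot(gm, [True, True])
    out = interval_burden_frequency(gm, annot, intervals(("chr1", 1, 100)))
    assert np.isnan(out["s0"])


def test_interval_frequency_split_invariance(small_cohort):
    annot = classify_deleterious(small_cohort.annotation)
    one = intervals(("chr1", 10_001, 90_000))
    split = intervals(("chr1", 10_001, 40_000), ("chr1", 40_001, 90_000))
    a = interval_burden_frequency(small_cohort.gm, annot, one)
    b = interval_burden_frequency(small_cohort.gm, annot, split)
    pd.testing.assert_series_equal(a, b)


def test_heterozygosity_f_all_homozygous_is_one():
    gm = make_gm([[0, 2, 2], [2, 0, 1], [0, 2, 1]])
    f = heterozygosity_f(gm)
    assert f["s0"] == pytest.approx(1.0)
    assert f["s1"] == pytest.approx(1.0)


def test_heterozygosity_f_matches_per_site_enumeration():
    # 3 samples x 2 sites, dosages site1=(0,1,2), site2=(1,1,0)
    gm = make_gm([[0, 1, 2], [1, 1, 0]])
    f = heterozygosity_f(gm)
    # independent spreadsheet-style recomputation
    expected = {}
    dosages = {"s0": [0, 1], "s1": [1, 1], "s2": [2, 0]}
    site_p = [(0 + 1 + 2) / 6, (1 + 1 + 0) / 6]
    e_site = [1 - 2 * p * (1 - p) * (6 / 5) for p in site_p]
    for s, ds in dosages.items():
        o_hom = sum(1 for d in ds if d in (0, 2))
        e_hom = sum(e_site)
        n = 2
        expected[s] = (o_hom - e_hom) / (n - e_hom)
    for s in dosages:
        assert f[s] == pytest.approx(expected[s])


def test_monomorphic_site_contributes_equally():
    # p=0 site: E(hom)=1, observed hom for every sample -> no F shift
    gm_with = make_gm([[0, 1, 2], [0, 0, 0]])
    gm_without = make_gm([[0, 1, 2]])
    f_with = heterozygosity_f(gm_with)
    f_without = heterozygosity_f(gm_without)
    pd.testing.assert_series_equal(f_with, f_without)


def test_compare_groups_identical_is_null():
    v = pd.Series([1.0, 2, 3, 1, 2, 3], index=list("abcdef"))
    out = compare_groups(v, ["a", "b", "c"], ["d", "e", "f"])
    assert out["t"] == pytest.approx(0.0) and out["p"] == pytest.approx(1.0)


def test_compare_groups_matches_pooled_t_closed_form():
    v = pd.Series([1.0, 2, 3, 4, 5, 6], index=list("abcdef"))
    out = compare_groups(v, ["a", "b", "c"], ["d", "e", "f"])
    # pooled t by hand: means 2 and 5, s_p^2 = 1, se = sqrt(2/3)
    t_hand = (2 - 5) / math.sqrt(2 / 3)
    assert out["t"] == pytest.approx(t_hand)
    from scipy.stats import t as tdist
    assert out["p"] == pytest.approx(2 * tdist.sf(abs(t_hand), 4))


def test_compare_groups_type_i_error_rate():
    rng = np.random.default_rng(42)
    names = [f"s{i}" for i in range(20)]
    hits = 0
    reps = 1000
    for _ in range(reps):
        v = pd.Series(rng.normal(size=20), index=names)
        hits += compare_groups(v, names[:10], names[10:])["p"] < 0.05
    assert 0.03 < hits / reps < 0.07


def test_burden_f_correlation_limits_and_closed_form():
    x = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
    assert burden_f_correlation(x, -x)["pearson_r"] == pytest.approx(-1.0)
    assert burden_f_correlation(x, x)["pearson_r"] == pytest.approx(1.0)
    y = pd.Series([2.0, 1, 4, 3, 6], index=list("abcde"))
    r_hand = np.cov(x, y, bias=True)[0, 1] / (x.std(ddof=0) * y.std(ddof=0))
    assert burden_f_correlation(x, y)["pearson_r"] == pytest.approx(r_hand)


def test_group_burden_direction_on_spiked_cohort(small_cohort):
    """Groups with higher deleterious-allele frequency show higher mean burden."""
    from delload.sim import spike_gene_burden
    genes = [f"gene{i:05d}" for i in range(20)]
    spiked = spike_gene_burden(small_cohort, genes, 3.0, "P2", seed=1)
    annot = classify_deleterious(spiked.annotation)
    bt = individual_burden(spiked.gm, annot).table.set_index("sample")
    out = compare_groups(bt["n_total"], spiked.samples_of("P2"),
                         spiked.samples_of("P1"))
    assert out["mean_a"] > out["mean_b"]
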