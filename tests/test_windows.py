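import numpy as np
import pandas as pd
import pytest

from delload.windows import (global_fst, ld_decay, select_top_regions,
                             window_frame, windowed_fst, windowed_pi)

from conftest import make_gm


def test_windowed_pi_closed_form_single_site():
    # one site, p=0.5, 4 diploids, w=100: pi = 0.5 * 8/7 / 100
    gm = make_gm([[0, 1, 1, 2]], pos=[50])
    track = windowed_pi(gm, w=100, s=100, chrom_sizes={"chr1": 100})
    assert track.loc[0, "value"] == pytest.approx(0.5 * 8 / 7 / 100)
    assert track.loc[0, "n_sites"] == 1


def test_windowed_pi_no_variants_and_width_scaling():
    gm = make_gm([[0, 0, 0, 0]], pos=[50])
    t = windowed_pi(gm, w=100, s=100, chrom_sizes={"chr1": 100})
    assert t.loc[0, "value"] == 0.0
    gm2 = make_gm([[0, 1, 1, 2]], pos=[50])
    t100 = windowed_pi(gm2, w=100, s=100, chrom_sizes={"chr1": 200})
    t200 = windowed_pi(gm2, w=200, s=200, chrom_sizes={"chr1": 200})
    assert t200.loc[0, "value"] == pytest.approx(t100.loc[0, "value"] / 2)


def wc_oracle(d_a, d_b):
    """Independent per-site Weir-Cockerham (1984) two-population estimator,
    written directly from the published variance-component formulas."""
    a_sum = abc_sum = 0.0
    for row_a, row_b in zip(d_a, d_b):
        ga = [x for x in row_a if x >= 0]
        gb = [x for x in row_b if x >= 0]
        n1, n2 = len(ga), len(gb)
        if n1 == 0 or n2 == 0:
            continue
        p1, p2 = sum(ga) / (2 * n1), sum(gb) / (2 * n2)
        h1 = sum(1 for x in ga if x == 1) / n1
        h2 = sum(1 for x in gb if x == 1) / n2
        r = 2
        nbar = (n1 + n2) / 2
        if nbar <= 1:
            continue
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        if nc <= 0:
            continue
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        if a + b + c == 0:
            continue
        a_sum += a
        abc_sum += a + b + c
    return a_sum / abc_sum


def test_fst_extremes():
    fixed = make_gm([[2, 2, 2, 0, 0, 0]] * 3)
    assert global_fst(fixed, ["s0", "s1", "s2"], ["s3", "s4", "s5"]) == \
        pytest.approx(1.0)
    same = make_gm([[0, 1, 2, 0, 1, 2]] * 3)
    assert abs(global_fst(same, ["s0", "s1", "s2"], ["s3", "s4", "s5"])) < 0.35


def test_fst_matches_independent_wc_oracle():
    rng = np.random.default_rng(5)
    d = rng.integers(-1, 3, size=(10, 12))
    gm = make_gm(d)
    ga, gb = gm.samples[:6], gm.samples[6:]
    ours = global_fst(gm, ga, gb)
    oracle = wc_oracle(d[:, :6], d[:, 6:])
    assert ours == pytest.approx(oracle)


def test_fst_symmetry_and_sample_order(small_cohort):
    gm = small_cohort.gm
    a = small_cohort.samples_of("P1")
    b = small_cohort.samples_of("P2")
    t1 = windowed_fst(gm, a, b)
    t2 = windowed_fst(gm, b, a)
    pd.testing.assert_series_equal(t1["value"], t2["value"])
    t3 = windowed_fst(gm, a[::-1], b[::-1])
    pd.testing.assert_series_equal(t1["value"], t3["value"])


def test_ld_decay_duplicated_site_and_hand_r2():
    d = [[0, 1, 2, 1, 0, 2],
         [0, 1, 2, 1, 0, 2],     # identical -> r2 = 1
         [2, 1, 0, 1, 2, 0]]     # mirrored -> r2 = 1 (sign squared away)
    gm = make_gm(d, pos=[100, 200, 300])
    prof = ld_decay(gm, max_dist=1000, maf_min=0.0, bin_width=100)
    assert np.allclose(prof["mean_r2"], 1.0)
    rng = np.random.default_rng(8)
    d2 = rng.integers(0, 3, size=(3, 6))
    gm2 = make_gm(d2, pos=[100, 200, 300])
    prof2 = ld_decay(gm2, max_dist=1000, maf_min=0.0, bin_width=100)
    # brute-force pairwise r^2 by distance bin
    expected = {}
    for i in range(3):
        for j in range(i + 1, 3):
            r = np.corrcoef(d2[i], d2[j])[0, 1]
            expected.setdefault((gm2.pos[j] - gm2.pos[i]) // 100, []).append(r * r)
    for _, row in prof2.iterrows():
        key = int(row["dist_bin_start"] // 100)
        assert row["mean_r2"] == pytest.approx(np.mean(expected[key]))


def test_ld_r2_invariant_to_allele_relabeling():
    rng = np.random.default_rng(9)
    d = rng.integers(0, 3, size=(4, 8))
    gm = make_gm(d, pos=[100, 150, 260, 400])
    flipped = make_gm(2 - d, pos=[100, 150, 260, 400])
    p1 = ld_decay(gm, max_dist=500, maf_min=0.0, bin_width=50)
    p2 = ld_decay(flipped, max_dist=500, maf_min=0.0, bin_width=50)
    pd.testing.assert_frame_equal(p1, p2)


def test_ld_null_level_near_one_over_n():
    """Independent sites: mean r2 sits at the 1/n sampling-bias floor."""
    rng = np.random.default_rng(12)
    n = 50
    p = rng.uniform(0.2, 0.8, size=60)
    d = rng.binomial(2, p[:, None], size=(60, n))
    gm = make_gm(d, pos=np.arange(1, 61) * 100)
    prof = ld_decay(gm, max_dist=10_000, maf_min=0.05, bin_width=2_000)
    assert abs(prof["mean_r2"].mean() - 1 / n) < 0.015


def make_track(scores):
    n = len(scores)
    starts = np.arange(n) * 5_000 + 1
    return pd.DataFrame({"chrom": "chr1", "start": starts,
                         "end": starts + 9_999, "value": scores})


def test_top_region_selection_order_statistics():
    track = make_track(np.arange(1.0, 101.0))
    regions = select_top_regions(track, 0.95)
    # windows scored 96..100 selected; they overlap on the 5 kb step frame
    assert regions.table.loc[0, "start"] == 95 * 5_000 + 1
    assert len(regions) == 1    # merged into one region
    assert select_top_regions(make_track([1.0, 2.0]), 0.0).total_span() >= 15_000


def test_top_region_monotone_in_quantile():
    rng = np.random.default_rng(3)
    track = make_track(rng.random(100))
    spans = [select_top_regions(track, q).total_span()
             for q in (0.5, 0.8, 0.95)]
    assert spans[0] >= spans[1] >= spans[2]
    n_sel = (track["value"] >= np.quantile(track["value"], 0.95)).sum()
    assert n_sel >= 5   # covers >= (1-q) of windows


def test_adjacent_selected_windows_merge():
    scores = np.zeros(20)
    scores[[7, 8]] = 5.0
    regions = select_top_regions(make_track(scores), 0.9)
    assert len(regions) == 1
    assert regions.table.loc[0, "start"] == 7 * 5_000 + 1
    assert regions.table.loc[0, "end"] == 8 * 5_000 + 10_000


def test_window_frame_layout():
    f = window_frame({"chr1": 25_000}, w=10_000, s=5_000)
    assert list(f["start"]) == [1, 5_001, 10_001, 15_001]
    assert (f["end"] - f["start"] == 9_999).all()
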