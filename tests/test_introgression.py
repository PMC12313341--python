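import numpy as np
import pandas as pd
import pytest

from delload.burden import classify_deleterious, compare_groups, \
    interval_burden_frequency
from delload.introgression import (d_statistic, interval_enrichment,
                                   jackknife_z, polarize, windowed_fd)
from delload.io import IntervalSet
from delload.sim import SimulationConfig, simulate_cohort

from conftest import make_gm


def freq_frame(p1, p2, p3, pO=None, pos=None, usable=None):
    n = len(p1)
    return pd.DataFrame({
        "chrom": "chr1",
        "pos": pos if pos is not None else np.arange(1, n + 1) * 100,
        "p1": p1, "p2": p2, "p3": p3,
        "pO": pO if pO is not None else np.zeros(n),
        "usable": usable if usable is not None else np.ones(n, dtype=bool),
    })


# --- polarization -----------------------------------------------------------

def test_polarize_outgroup_fixed_ref():
    # outgroup (last 2 samples) fixed REF; P1/P2/P3 2 samples each
    gm = make_gm([[2, 1, 0, 1, 2, 2, 0, 0],
                  [0, 0, 1, 1, 2, 0, 0, 0]])
    fr = polarize(gm, ["s0", "s1"], ["s2", "s3"], ["s4", "s5"], ["s6", "s7"])
    assert fr["usable"].all()
    assert fr.loc[0, "p1"] == pytest.approx(3 / 4)   # derived = ALT
    assert fr.loc[0, "p3"] == pytest.approx(1.0)


def test_polarize_ambiguous_outgroup_unusable():
    gm = make_gm([[1, 1, 1, 1, 1, 1, 1, 1]])   # outgroup het everywhere: 50/50
    fr = polarize(gm, ["s0", "s1"], ["s2", "s3"], ["s4", "s5"], ["s6", "s7"])
    assert not fr["usable"].any()


def test_polarize_flips_when_outgroup_fixed_alt():
    gm = make_gm([[0, 1, 2, 1, 0, 0, 2, 2]])   # outgroup hom-ALT: ancestral=ALT
    fr = polarize(gm, ["s0", "s1"], ["s2", "s3"], ["s4", "s5"], ["s6", "s7"])
    assert fr.loc[0, "usable"]
    assert fr.loc[0, "p1"] == pytest.approx(1 - 1 / 4)  # derived = REF


def test_polarize_recovers_truth_ancestral():
    cfg = SimulationConfig(seed=3, n_sites=3000, chrom_length=150_000,
                           n_per_pop={"P1": 10, "P2": 10, "P3": 8, "O": 8},
                           outgroup_poly_rate=0.0, missing_rate=0.0)
    c = simulate_cohort(cfg)
    fr = polarize(c.gm, c.samples_of("P1"), c.samples_of("P2"),
                  c.samples_of("P3"), c.samples_of("O"))
    # truth: ALT is always derived, so derived frequency == ALT frequency
    usable = fr["usable"]
    assert usable.mean() > 0.99
    idx = c.gm.sample_indices(c.samples_of("P1"))
    np.testing.assert_allclose(fr.loc[usable, "p1"],
                               c.gm.alt_freq(idx)[usable.to_numpy()])


# --- D statistic ------------------------------------------------------------

def test_d_single_site_abba():
    fr = freq_frame([0.0], [1.0], [1.0])
    res = d_statistic(fr)
    assert (res.abba, res.baba, res.d) == (1.0, 0.0, 1.0)


def test_d_zero_when_p1_equals_p2():
    rng = np.random.default_rng(0)
    p = rng.random(50)
    p3 = rng.random(50)
    res = d_statistic(freq_frame(p, p, p3))
    assert res.d == pytest.approx(0.0)


def test_d_antisymmetric_under_p1_p2_swap():
    rng = np.random.default_rng(1)
    p1, p2, p3 = rng.random((3, 40))
    a = d_statistic(freq_frame(p1, p2, p3))
    b = d_statistic(freq_frame(p2, p1, p3))
    assert a.d == pytest.approx(-b.d)
    assert -1 <= a.d <= 1


def test_d_site_order_permutation_invariant():
    rng = np.random.default_rng(2)
    p1, p2, p3 = rng.random((3, 30))
    perm = rng.permutation(30)
    a = d_statistic(freq_frame(p1, p2, p3))
    b = d_statistic(freq_frame(p1[perm], p2[perm], p3[perm]))
    assert a.d == pytest.approx(b.d)


def test_jackknife_degenerate_se():
    # identical composition in every block -> SE -> 0, Z withheld
    fr = freq_frame([0.0] * 4, [1.0] * 4, [1.0] * 4,
                    pos=[100, 1100, 2100, 3100])
    res = jackknife_z(fr, block_size_bp=1000)
    assert res.z is None and res.d == pytest.approx(1.0)


def test_jackknife_z_grows_with_consistent_signal():
    rng = np.random.default_rng(4)
    n = 2000
    p1 = rng.uniform(0, 0.5, n)
    p2 = np.clip(p1 + 0.2, 0, 1)
    p3 = rng.uniform(0.5, 1, n)
    fr = freq_frame(p1, p2, p3, pos=np.arange(1, n + 1) * 50)
    res = jackknife_z(fr, block_size_bp=10_000)
    assert res.d > 0 and res.z > 4 and res.significant


# --- windowed fd ------------------------------------------------------------

def test_fd_window_filters():
    n = 300
    rng = np.random.default_rng(5)
    pos = np.sort(rng.choice(10_000, n, replace=False)) + 1
    p1 = rng.uniform(0, 0.3, n)
    p2 = np.clip(p1 + 0.3, 0, 1)
    p3 = np.clip(p1 + 0.3, 0, 1)
    fr = freq_frame(p1, p2, p3, pos=pos)
    # min_snps above the site count: every window missing
    track, _ = windowed_fd(fr, w=10_000, s=10_000, min_snps=n + 1,
                           chrom_sizes={"chr1": 10_000})
    assert track["value"].isna().all()
    track2, _ = windowed_fd(fr, w=10_000, s=10_000, min_snps=100,
                            chrom_sizes={"chr1": 10_000})
    assert track2.loc[0, "n_sites"] == n
    # p2 == p3 at every site: fd at the =1 boundary is retained
    assert track2.loc[0, "value"] == pytest.approx(1.0)


def test_fd_negative_d_window_dropped():
    rng = np.random.default_rng(6)
    n = 200
    p2 = rng.uniform(0, 0.3, n)
    p1 = np.clip(p2 + 0.3, 0, 1)    # BABA excess -> negative window D
    p3 = rng.uniform(0.5, 1, n)
    pos = np.sort(rng.choice(10_000, n, replace=False)) + 1
    fr = freq_frame(p1, p2, p3, pos=pos)
    track, _ = windowed_fd(fr, w=10_000, s=10_000, min_snps=50,
                           chrom_sizes={"chr1": 10_000})
    assert track["value"].isna().all()


def test_fd_min_snps_monotone():
    """Lowering min_snps never removes a previously retained window."""
    cfg = SimulationConfig(seed=9, n_sites=5000, chrom_length=250_000,
                           n_per_pop={"P1": 8, "P2": 8, "P3": 8, "O": 6})
    c = simulate_cohort(cfg)
    fr = polarize(c.gm, c.samples_of("P1"), c.samples_of("P2"),
                  c.samples_of("P3"), c.samples_of("O"))
    hi, _ = windowed_fd(fr, min_snps=120)
    lo, _ = windowed_fd(fr, min_snps=40)
    kept_hi = hi["value"].notna()
    assert (lo["value"].notna() | ~kept_hi).all()


def test_fd_retained_windows_within_unit_interval(small_cohort):
    fr = polarize(small_cohort.gm, small_cohort.samples_of("P1"),
                  small_cohort.samples_of("P2"), small_cohort.samples_of("P3"),
                  small_cohort.samples_of("O"))
    track, _ = windowed_fd(fr, min_snps=50)
    vals = track["value"].dropna()
    assert ((vals >= 0) & (vals <= 1)).all()


def test_fd_monotone_in_simulated_admixture():
    from delload.sim import Window
    means = []
    for f in (0.0, 0.1, 0.3, 0.5):
        vals = []
        for seed in (0, 1, 2):
            cfg = SimulationConfig(
                seed=seed, introgression_windows=[Window(1, 1_000_000, f)]
                if f > 0 else [])
            c = simulate_cohort(cfg)
            fr = polarize(c.gm, c.samples_of("P1"), c.samples_of("P2"),
                          c.samples_of("P3"), c.samples_of("O"))
            track, _ = windowed_fd(fr, min_snps=100)
            vals.append(np.nanmean(track["value"]))
        means.append(np.mean(vals))
    assert means[0] < means[1] < means[2] < means[3]


# --- interval enrichment ----------------------------------------------------

def test_interval_enrichment_whole_genome_consistency(small_cohort):
    annot = classify_deleterious(small_cohort.annotation)
    whole = IntervalSet(pd.DataFrame({"chrom": ["chr1"], "start": [1],
                                      "end": [200_000]}))
    ga = small_cohort.samples_of("P2")
    gb = small_cohort.samples_of("P1")
    out = interval_enrichment(small_cohort.gm, annot, whole, ga, gb)
    direct = compare_groups(
        interval_burden_frequency(small_cohort.gm, annot, whole), ga, gb)
    assert out == direct
    assert out["mean_a"] == pytest.approx(100.0)
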