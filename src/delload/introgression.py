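"""Four-taxon ABBA-BABA introgression statistics.

Topology (((P1, P2), P3), O): P1 and P2 are sister recipient populations
(wild and cultivated forms), P3 the candidate donor, O the outgroup used to
polarize alleles.  Site patterns are weighted by derived-allele frequencies
rather than counted from single sequences:

    ABBA = sum (1-p1) p2 p3 (1-pO),   BABA = sum p1 (1-p2) p3 (1-pO)
    D = (ABBA - BABA) / (ABBA + BABA)

Gene flow from P3 into P2 inflates ABBA, so D > 0 is read as an
introgression signal, significant when the block-jackknife Z exceeds 4.
The windowed admixture-fraction estimator fd normalizes the D numerator by
its value under complete introgression (the donor frequency substituted at
each site), and windows are discarded when they have fewer than the minimum
number of usable SNPs, a negative window D, or fd > 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .burden import compare_groups, interval_burden_frequency
from .io import GenotypeMatrix, IntervalSet, MISSING
from .windows import DEFAULT_STEP, DEFAULT_WINDOW, _chrom_sizes, \
    select_top_regions, window_frame

log = logging.getLogger(__name__)


def _pop_freq(gm: GenotypeMatrix, samples: list[str]) -> tuple[np.ndarray, np.ndarray]:
    idx = gm.sample_indices(samples)
    d = gm.dosage[:, idx]
    ok = d != MISSING
    n_alleles = 2 * ok.sum(axis=1)
    alt = np.where(ok, d, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
    return freq, n_alleles


def polarize(gm: GenotypeMatrix, p1: list[str], p2: list[str], p3: list[str],
             outgroup: list[str],
             min_outgroup_freq: float = 0.8) -> pd.DataFrame:
    """Derived-allele frequencies per population, polarized by the outgroup.

    The ancestral allele is the outgroup's majority allele, accepted only
    when its outgroup frequency reaches ``min_outgroup_freq``; sites where
    the outgroup is too polymorphic (or unobserved), or where any focal
    population has no called genotype, are flagged unusable.
    """
    if not outgroup:
        raise ValueError("outgroup must be non-empty")
    fO, nO = _pop_freq(gm, outgroup)
    f1, n1 = _pop_freq(gm, p1)
    f2, n2 = _pop_freq(gm, p2)
    f3, n3 = _pop_freq(gm, p3)
    with np.errstate(invalid="ignore"):
        alt_is_ancestral = fO >= 0.5
        major_freq = np.where(alt_is_ancestral, fO, 1 - fO)
        usable = (nO > 0) & (major_freq >= min_outgroup_freq) \
            & (n1 > 0) & (n2 > 0) & (n3 > 0)

    def derived(f: np.ndarray) -> np.ndarray:
        return np.where(alt_is_ancestral, 1 - f, f)

    return pd.DataFrame({
        "chrom": gm.chrom, "pos": gm.pos,
        "p1": derived(f1), "p2": derived(f2), "p3": derived(f3),
        "pO": derived(fO), "usable": usable,
    })


def _pattern_sums(freqs: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    p1 = freqs["p1"].to_numpy()
    p2 = freqs["p2"].to_numpy()
    p3 = freqs["p3"].to_numpy()
    pO = freqs["pO"].to_numpy()
    abba = (1 - p1) * p2 * p3 * (1 - pO)
    baba = p1 * (1 - p2) * p3 * (1 - pO)
    return abba, baba


@dataclass
class DStatResult:
    abba: float
    baba: float
    d: float
    z: float | None = None
    se: float | None = None
    n_blocks: int | None = None
    n_sites: int | None = None
    pseudovalues: np.ndarray | None = None

    @property
    def significant(self) -> bool:
        """Introgression call: D > 0 with jackknife Z > 4."""
        return bool(self.z is not None and np.isfinite(self.z)
                    and self.d > 0 and self.z > 4)


def d_statistic(freqs: pd.DataFrame) -> DStatResult:
    """Genome-wide frequency-weighted D over usable sites."""
    use = freqs[freqs["usable"]]
    if not len(use):
        raise ValueError("no usable sites")
    abba, baba = _pattern_sums(use)
    s_abba, s_baba = float(abba.sum()), float(baba.sum())
    if s_abba + s_baba == 0:
        log.warning("d_statistic: ABBA+BABA = 0, D undefined")
        return DStatResult(s_abba, s_baba, float("nan"), n_sites=len(use))
    d = (s_abba - s_baba) / (s_abba + s_baba)
    return DStatResult(s_abba, s_baba, d, n_sites=len(use))


def jackknife_z(freqs: pd.DataFrame,
                block_size_bp: int = 1_000_000) -> DStatResult:
    """D with a weighted delete-one block jackknife standard error.

    The genome is cut into contiguous blocks of ``block_size_bp``; blocks
    are weighted by their usable-site counts, and Z = D / SE.
    """
    use = freqs[freqs["usable"]].copy()
    if not len(use):
        raise ValueError("no usable sites")
    abba, baba = _pattern_sums(use)
    block = use["chrom"].astype(str) + ":" + \
        ((use["pos"].to_numpy() - 1) // block_size_bp).astype(str)
    df = pd.DataFrame({"block": block.to_numpy(), "abba": abba, "baba": baba})
    g = df.groupby("block", sort=True).agg(abba=("abba", "sum"),
                                           baba=("baba", "sum"),
                                           m=("abba", "size"))
    if len(g) < 2:
        raise ValueError("jackknife needs >= 2 non-empty blocks")
    tot_a, tot_b, n = g["abba"].sum(), g["baba"].sum(), int(g["m"].sum())
    d_hat = (tot_a - tot_b) / (tot_a + tot_b)
    loo_a = tot_a - g["abba"].to_numpy()
    loo_b = tot_b - g["baba"].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        d_loo = (loo_a - loo_b) / (loo_a + loo_b)
    m = g["m"].to_numpy(dtype=float)
    h = n / m
    n_blocks = len(g)
    # weighted delete-m_j jackknife (Busing-style pseudovalues)
    tau = h * d_hat - (h - 1) * d_loo
    theta_j = n_blocks * d_hat - np.sum((1 - m / n) * d_loo)
    var = np.sum((tau - theta_j) ** 2 / (h - 1)) / n_blocks
    se = float(np.sqrt(var))
    if se == 0 or not np.isfinite(se):
        log.warning("jackknife_z: zero/undefined jackknife SE; Z not reported")
        return DStatResult(float(tot_a), float(tot_b), float(d_hat), z=None,
                           se=None, n_blocks=n_blocks, n_sites=n,
                           pseudovalues=tau)
    return DStatResult(float(tot_a), float(tot_b), float(d_hat),
                       z=float(d_hat / se), se=se, n_blocks=n_blocks,
                       n_sites=n, pseudovalues=tau)


def windowed_fd(freqs: pd.DataFrame, w: int = DEFAULT_WINDOW,
                s: int = DEFAULT_STEP, min_snps: int = 100,
                quantile: float = 0.95,
                chrom_sizes: dict[str, int] | None = None
                ) -> tuple[pd.DataFrame, IntervalSet]:
    """Windowed fd track plus the top-quantile introgression regions.

    fd divides the window's ABBA-BABA numerator by its value with the
    per-site higher-derived-frequency population of {P2, P3} substituted as
    donor.  Windows with fewer than ``min_snps`` usable SNPs, negative
    window D, or fd > 1 are set missing; the quantile is taken over the
    surviving windows.
    """
    if chrom_sizes is None:
        chrom_sizes = {str(c): int(freqs.loc[freqs["chrom"] == c, "pos"].max())
                       for c in freqs["chrom"].unique()}
    frame = window_frame(chrom_sizes, w, s)
    use = freqs[freqs["usable"]]
    abba, baba = _pattern_sums(use)
    p1 = use["p1"].to_numpy()
    pO = use["pO"].to_numpy()
    pd_don = np.maximum(use["p2"].to_numpy(), use["p3"].to_numpy())
    num = abba - baba
    den = (1 - p1) * pd_don * pd_don * (1 - pO) \
        - p1 * (1 - pd_don) * pd_don * (1 - pO)
    chrom = use["chrom"].to_numpy()
    pos = use["pos"].to_numpy()
    from .windows import _aggregate
    (abba_s, baba_s, num_s, den_s, counts) = _aggregate(
        frame, chrom, pos, [abba, baba, num, den])
    track = frame.copy()
    track["n_sites"] = counts
    with np.errstate(invalid="ignore", divide="ignore"):
        d_win = np.where(abba_s + baba_s > 0,
                         (abba_s - baba_s) / np.where(abba_s + baba_s == 0, 1,
                                                      abba_s + baba_s), np.nan)
        fd = np.where(den_s != 0, num_s / np.where(den_s == 0, 1, den_s), np.nan)
    drop = (counts < min_snps) | (d_win < 0) | (fd > 1) | np.isnan(fd) \
        | np.isnan(d_win)
    track["window_d"] = np.where(drop, np.nan, d_win)
    track["value"] = np.where(drop, np.nan, fd)
    if track["value"].notna().sum() == 0:
        log.warning("windowed_fd: no windows survive the filters")
        return track, IntervalSet(pd.DataFrame(
            columns=["chrom", "start", "end", "label"]))
    regions = select_top_regions(track, quantile, label="introgression")
    return track, regions


def interval_enrichment(gm: GenotypeMatrix, annot: pd.DataFrame,
                        regions: IntervalSet, group_a: list[str],
                        group_b: list[str],
                        flag: str = "is_deleterious_sift") -> dict[str, float]:
    """Compare per-sample deleterious-mutation frequency inside candidate
    introgression regions between two groups (pooled Student's t)."""
    if not len(regions):
        raise ValueError("regions must be non-empty")
    freq = interval_burden_frequency(gm, annot, regions, flag=flag)
    return compare_groups(freq, group_a, group_b)
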