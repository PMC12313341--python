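"""Sliding-window diversity and differentiation statistics.

Tracks use a fixed frame of width ``w`` advanced by step ``s`` (defaults
10 kb / 5 kb).  π follows the windowed convention of dividing the summed
per-site unbiased heterozygosity by the full window width; Fst is the
Weir–Cockerham (1984) estimator combined across sites as a ratio of sums
of the a (among-population) and a+b+c variance components, with negative
windows reported as-is.  LD is genotype-dosage (composite) r².
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, IntervalSet, MISSING

log = logging.getLogger(__name__)

DEFAULT_WINDOW = 10_000
DEFAULT_STEP = 5_000


def window_frame(chrom_sizes: dict[str, int], w: int = DEFAULT_WINDOW,
                 s: int = DEFAULT_STEP) -> pd.DataFrame:
    """All windows [start, start+w-1] with start = 1, 1+s, ... per chromosome."""
    rows = []
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        starts = np.arange(1, max(length - w + 1, 1) + 1, s)
        for st in starts:
            rows.append((chrom, int(st), int(st + w - 1)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _chrom_sizes(gm: GenotypeMatrix, chrom_sizes: dict[str, int] | None) -> dict[str, int]:
    if chrom_sizes is not None:
        return chrom_sizes
    sizes: dict[str, int] = {}
    for c in np.unique(gm.chrom):
        sizes[str(c)] = int(gm.pos[gm.chrom == c].max())
    return sizes


def _aggregate(frame: pd.DataFrame, chrom: np.ndarray, pos: np.ndarray,
               per_site: list[np.ndarray]) -> list[np.ndarray]:
    """Sum per-site vectors over each window of the frame (+ site counts)."""
    sums = [np.zeros(len(frame)) for _ in per_site]
    counts = np.zeros(len(frame), dtype=np.int64)
    for c, grp in frame.groupby("chrom"):
        m = chrom == c
        if not m.any():
            continue
        p = pos[m]
        vecs = [v[m] for v in per_site]
        order = np.argsort(p)
        p = p[order]
        vecs = [v[order] for v in vecs]
        cums = [np.concatenate([[0], np.cumsum(np.nan_to_num(v))]) for v in vecs]
        valid = ~np.isnan(vecs[0])
        cum_n = np.concatenate([[0], np.cumsum(valid)])
        lo = np.searchsorted(p, grp["start"].to_numpy(), side="left")
        hi = np.searchsorted(p, grp["end"].to_numpy(), side="right")
        idx = grp.index.to_numpy()
        counts[idx] = cum_n[hi] - cum_n[lo]
        for k, cum in enumerate(cums):
            sums[k][idx] = cum[hi] - cum[lo]
    return sums + [counts]


def _site_pi(gm: GenotypeMatrix, sample_idx: np.ndarray) -> np.ndarray:
    d = gm.dosage[:, sample_idx]
    ok = d != MISSING
    n = ok.sum(axis=1)
    alt = np.where(ok, d, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = alt / np.maximum(2 * n, 1)
        pi = 2 * p * (1 - p) * (2 * n / np.maximum(2 * n - 1, 1))
    return np.where(n > 0, pi, np.nan)


def windowed_pi(gm: GenotypeMatrix, samples: list[str] | None = None,
                w: int = DEFAULT_WINDOW, s: int = DEFAULT_STEP,
                chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Windowed nucleotide diversity: sum of per-site unbiased heterozygosity
    2p(1-p)·2n/(2n-1) over variant sites in the window, divided by w."""
    idx = gm.sample_indices(samples) if samples is not None else \
        np.arange(gm.n_samples)
    if len(idx) < 2:
        raise ValueError("pi needs >= 2 samples")
    frame = window_frame(_chrom_sizes(gm, chrom_sizes), w, s)
    pi_site = _site_pi(gm, idx)
    (pi_sum, counts) = _aggregate(frame, gm.chrom, gm.pos, [pi_site])
    track = frame.copy()
    track["n_sites"] = counts
    track["value"] = pi_sum / w
    return track


def _wc_components(gm: GenotypeMatrix, idx_a: np.ndarray,
                   idx_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weir–Cockerham (1984) per-site variance components for two populations:
    returns (a, a+b+c) with NaN at unusable sites."""
    comps = []
    for idx in (idx_a, idx_b):
        d = gm.dosage[:, idx]
        ok = d != MISSING
        n = ok.sum(axis=1).astype(float)                       # diploids
        alt = np.where(ok, d, 0).sum(axis=1).astype(float)
        het = ((d == 1) & ok).sum(axis=1).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            comps.append((n, alt / np.maximum(2 * n, 1e-12),
                          het / np.maximum(n, 1e-12)))
    (n1, p1, h1), (n2, p2, h2) = comps
    r = 2.0
    nbar = (n1 + n2) / r
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (r * nbar - (n1 ** 2 + n2 ** 2) / (r * nbar)) / (r - 1)
        pbar = (n1 * p1 + n2 * p2) / (r * nbar)
        s2 = (n1 * (p1 - pbar) ** 2 + n2 * (p2 - pbar) ** 2) / ((r - 1) * nbar)
        hbar = (n1 * h1 + n2 * h2) / (r * nbar)
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r
                                 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - hbar * (2 * nbar - 1) / (4 * nbar))
        c = hbar / 2
    usable = (n1 > 0) & (n2 > 0) & (nbar > 1) & (nc > 0)
    a = np.where(usable, a, np.nan)
    abc = np.where(usable, a + b + c, np.nan)
    return a, abc


def windowed_fst(gm: GenotypeMatrix, group_a: list[str], group_b: list[str],
                 w: int = DEFAULT_WINDOW, s: int = DEFAULT_STEP,
                 chrom_sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Weir–Cockerham Fst per window (ratio of sums of variance components).

    Windows without usable polymorphic sites carry NaN; small negative
    values are legitimate estimator output and are not clamped.
    """
    idx_a, idx_b = gm.sample_indices(group_a), gm.sample_indices(group_b)
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise ValueError("fst needs >= 2 samples per group")
    frame = window_frame(_chrom_sizes(gm, chrom_sizes), w, s)
    a, abc = _wc_components(gm, idx_a, idx_b)
    # a site contributes only where the total variance term is non-zero
    usable = ~np.isnan(abc) & (abc != 0)
    a = np.where(usable, a, np.nan)
    abc = np.where(usable, abc, np.nan)
    (a_sum, abc_sum, counts) = _aggregate(frame, gm.chrom, gm.pos, [a, abc])
    track = frame.copy()
    track["n_sites"] = counts
    with np.errstate(invalid="ignore", divide="ignore"):
        track["value"] = np.where(abc_sum != 0, a_sum / np.where(abc_sum == 0, 1, abc_sum),
                                  np.nan)
    track.loc[counts == 0, "value"] = np.nan
    return track


def global_fst(gm: GenotypeMatrix, group_a: list[str],
               group_b: list[str]) -> float:
    """Genome-wide Weir–Cockerham Fst (ratio of sums over all usable sites)."""
    a, abc = _wc_components(gm, gm.sample_indices(group_a),
                            gm.sample_indices(group_b))
    ok = ~np.isnan(abc) & (abc != 0)
    return float(np.nansum(a[ok]) / np.nansum(abc[ok]))


def ld_decay(gm: GenotypeMatrix, samples: list[str] | None = None,
             max_dist: int = 500_000, maf_min: float = 0.05,
             bin_width: int = 1_000) -> pd.DataFrame:
    """Mean genotype-dosage r² binned by pairwise distance.

    Considers intra-chromosome site pairs separated by <= max_dist after a
    MAF filter; r² is the squared Pearson correlation of dosage vectors over
    samples non-missing at both sites.  The ``summary_distance`` attribute
    on the result is the smallest bin midpoint whose mean r² has fallen to
    half the maximum bin mean.
    """
    idx = gm.sample_indices(samples) if samples is not None else \
        np.arange(gm.n_samples)
    d = gm.dosage[:, idx].astype(float)
    d[d == MISSING] = np.nan
    p = gm.alt_freq(idx)
    maf = np.minimum(p, 1 - p)
    keep = ~np.isnan(p) & (maf >= maf_min)
    chrom, pos, d = gm.chrom[keep], gm.pos[keep], d[keep]
    bins: dict[int, list[float]] = {}
    for c in np.unique(chrom):
        m = chrom == c
        pc, dc = pos[m], d[m]
        order = np.argsort(pc)
        pc, dc = pc[order], dc[order]
        for i in range(len(pc)):
            j_hi = np.searchsorted(pc, pc[i] + max_dist, side="right")
            for j in range(i + 1, j_hi):
                x, y = dc[i], dc[j]
                ok = ~np.isnan(x) & ~np.isnan(y)
                if ok.sum() < 2:
                    continue
                xv, yv = x[ok], y[ok]
                sx, sy = xv.std(), yv.std()
                if sx == 0 or sy == 0:
                    continue
                r = np.corrcoef(xv, yv)[0, 1]
                bins.setdefault(int((pc[j] - pc[i]) // bin_width), []).append(r * r)
    if not bins:
        log.warning("ld_decay: no qualifying site pairs")
        return pd.DataFrame(columns=["dist_bin_start", "dist_bin_mid",
                                     "mean_r2", "n_pairs"])
    rows = [(b * bin_width, b * bin_width + bin_width / 2,
             float(np.mean(v)), len(v)) for b, v in sorted(bins.items())]
    prof = pd.DataFrame(rows, columns=["dist_bin_start", "dist_bin_mid",
                                       "mean_r2", "n_pairs"])
    half = prof["mean_r2"].max() / 2
    below = prof[prof["mean_r2"] <= half]
    prof.attrs["summary_distance"] = \
        float(below["dist_bin_mid"].iloc[0]) if len(below) else float("nan")
    return prof


def select_top_regions(track: pd.DataFrame, quantile: float = 0.95,
                       label: str = "selected") -> IntervalSet:
    """Merge windows scoring at or above the empirical ``quantile`` of the
    track's non-missing values into candidate regions (ties included)."""
    col = "value" if "value" in track.columns else "score"
    vals = track[col].to_numpy(dtype=float)
    ok = ~np.isnan(vals)
    if not ok.any():
        raise ValueError("track has no non-missing values")
    threshold = float(np.quantile(vals[ok], quantile))
    if vals[ok].min() == vals[ok].max():
        log.warning("select_top_regions: all values equal; selecting every window")
    sel = track.loc[ok & (vals >= threshold), ["chrom", "start", "end"]].copy()
    sel["label"] = label
    return IntervalSet(sel).merge()
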