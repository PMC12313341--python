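"""Deleterious-site classification and per-individual load statistics.

A site is called deleterious when its SIFT score is strictly below 0.05 or
its GERP score strictly above 2 (both rules exposed, SIFT-based flags drive
the default burden accounting, mirroring how such scans treat GERP as a
confirmation track).  Burden is reported per individual as the number of
sites carrying at least one deleterious (ALT) allele, split into
heterozygous and homozygous carriers, alongside the fraction of that burden
falling inside a set of genomic intervals and the method-of-moments
heterozygosity coefficient F.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, IntervalSet, MISSING

log = logging.getLogger(__name__)

SIFT_CUTOFF = 0.05
GERP_CUTOFF = 2.0


def classify_deleterious(annot: pd.DataFrame, sift_cutoff: float = SIFT_CUTOFF,
                         gerp_cutoff: float = GERP_CUTOFF) -> pd.DataFrame:
    """Add boolean ``is_deleterious_sift`` / ``is_deleterious_gerp`` columns.

    Strict inequalities: SIFT < cutoff, GERP > cutoff; a missing score never
    flags a site.
    """
    out = annot.copy()
    sift = pd.to_numeric(out["sift_score"], errors="coerce")
    gerp = pd.to_numeric(out["gerp_score"], errors="coerce")
    out["is_deleterious_sift"] = (sift < sift_cutoff).fillna(False).astype(bool)
    out["is_deleterious_gerp"] = (gerp > gerp_cutoff).fillna(False).astype(bool)
    return out


def sift_gerp_overlap(annot: pd.DataFrame) -> dict[str, float]:
    """Cardinalities of the SIFT- and GERP-flagged site sets and their overlap."""
    key = annot[["chrom", "pos", "ref", "alt"]].apply(tuple, axis=1)
    s = set(key[annot["is_deleterious_sift"]])
    g = set(key[annot["is_deleterious_gerp"]])
    both = len(s & g)
    return {"n_sift": len(s), "n_gerp": len(g), "n_both": both,
            "fraction_of_gerp_in_sift": both / len(g) if g else float("nan")}


@dataclass
class BurdenTable:
    """Per-sample burden accounting.

    ``table`` columns: sample, n_total, n_hom, n_het (site mode) or the
    dosage-weighted equivalents (allele mode), plus F and any interval
    frequency columns added later.
    """
    table: pd.DataFrame
    mode: str = "site"


def _deleterious_mask(annot: pd.DataFrame, flag: str = "is_deleterious_sift") -> np.ndarray:
    if flag not in annot.columns:
        raise ValueError("annotation not classified; run classify_deleterious first")
    return annot[flag].to_numpy(dtype=bool)


def individual_burden(gm: GenotypeMatrix, annot: pd.DataFrame,
                      mode: str = "site",
                      flag: str = "is_deleterious_sift") -> BurdenTable:
    """Per-individual deleterious burden.

    mode='site' counts sites carrying >= 1 deleterious ALT allele
    (n_het: dosage 1, n_hom: dosage 2); mode='allele' weights by dosage.
    Missing genotypes contribute nothing.
    """
    if mode not in ("site", "allele"):
        raise ValueError("mode must be 'site' or 'allele'")
    dele = _deleterious_mask(annot, flag)
    d = gm.dosage[dele]
    n_het = (d == 1).sum(axis=0)
    n_hom = (d == 2).sum(axis=0)
    if mode == "site":
        tot = n_het + n_hom
    else:
        tot = n_het + 2 * n_hom
    df = pd.DataFrame({"sample": gm.samples, "n_total": tot,
                       "n_hom": n_hom, "n_het": n_het})
    return BurdenTable(df, mode=mode)


def interval_burden_frequency(gm: GenotypeMatrix, annot: pd.DataFrame,
                              intervals: IntervalSet,
                              flag: str = "is_deleterious_sift") -> pd.Series:
    """Percentage of each individual's deleterious sites inside the intervals:
    (deleterious sites in intervals / deleterious sites genome-wide) x 100.

    An individual with zero genome-wide deleterious sites has an undefined
    ratio and is reported as NaN.
    """
    dele = _deleterious_mask(annot, flag)
    carrier = (gm.dosage >= 1) & dele[:, None]
    inside = intervals.contains(gm.chrom, gm.pos) if len(intervals) else \
        np.zeros(gm.n_sites, dtype=bool)
    n_in = (carrier & inside[:, None]).sum(axis=0).astype(float)
    n_all = carrier.sum(axis=0).astype(float)
    undefined = n_all == 0
    if undefined.any():
        log.warning("interval_burden_frequency: %d samples carry zero "
                    "deleterious sites (frequency undefined)", int(undefined.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(undefined, np.nan, n_in / np.maximum(n_all, 1) * 100.0)
    return pd.Series(pct, index=pd.Index(gm.samples, name="sample"),
                     name="interval_freq_pct")


def heterozygosity_f(gm: GenotypeMatrix) -> pd.Series:
    """Method-of-moments heterozygosity coefficient per sample:
    F = (O(hom) - E(hom)) / (N - E(hom)).

    O(hom): observed homozygous sites; N: genotyped sites; E(hom) sums the
    per-site expected homozygosity 1 - 2p(1-p)·2n/(2n-1) over the sample's
    genotyped sites, with p the cohort ALT frequency over non-missing
    alleles (the convention of the standard ``--het`` implementation).
    Negative F marks heterozygote excess.
    """
    if gm.n_samples < 2:
        raise ValueError("heterozygosity F needs >= 2 samples")
    ok = gm.dosage != MISSING
    n_dip = ok.sum(axis=1)                      # non-missing diploids per site
    p = gm.alt_freq()
    with np.errstate(invalid="ignore", divide="ignore"):
        e_hom_site = 1 - 2 * p * (1 - p) * (2 * n_dip / np.maximum(2 * n_dip - 1, 1))
    e_hom_site = np.where(n_dip > 0, e_hom_site, 0.0)

    n_geno = ok.sum(axis=0).astype(float)
    o_hom = (((gm.dosage == 0) | (gm.dosage == 2)) & ok).sum(axis=0).astype(float)
    e_hom = (e_hom_site[:, None] * ok).sum(axis=0)
    denom = n_geno - e_hom
    degenerate = np.isclose(denom, 0)
    if degenerate.any():
        log.warning("heterozygosity_f: %d samples with degenerate denominator",
                    int(degenerate.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        f = np.where(degenerate, np.nan, (o_hom - e_hom) / np.where(degenerate, 1, denom))
    return pd.Series(f, index=pd.Index(gm.samples, name="sample"), name="F")


def compare_groups(values: pd.Series, group_a: list[str], group_b: list[str],
                   test: str = "student_t") -> dict[str, float]:
    """Two-sided two-sample test of a per-sample statistic between groups.

    'student_t' is the pooled-variance Student's t; 'welch_t' relaxes the
    equal-variance assumption.
    """
    a = values.reindex(group_a).dropna().to_numpy(dtype=float)
    b = values.reindex(group_b).dropna().to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 non-missing values")
    if test == "student_t":
        t, p = stats.ttest_ind(a, b, equal_var=True)
    elif test == "welch_t":
        t, p = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    if np.isnan(t):  # zero variance in both groups
        t, p = (0.0, 1.0) if np.isclose(a.mean(), b.mean()) else (np.inf, 0.0)
    return {"mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "n_a": len(a), "n_b": len(b), "t": float(t), "p": float(p)}


def burden_f_correlation(burden: pd.Series, f: pd.Series) -> dict[str, float]:
    """Pearson correlation between per-sample burden and heterozygosity F."""
    df = pd.concat([burden.rename("burden"), f.rename("F")], axis=1).dropna()
    if len(df) < 3:
        raise ValueError("correlation needs >= 3 paired values")
    if df["burden"].std() == 0 or df["F"].std() == 0:
        log.warning("burden_f_correlation: zero variance, r undefined")
        return {"pearson_r": float("nan"), "p": float("nan"), "n": len(df)}
    r, p = stats.pearsonr(df["burden"], df["F"])
    return {"pearson_r": float(r), "p": float(p), "n": len(df)}


def burden_table(gm: GenotypeMatrix, annot: pd.DataFrame,
                 manifest=None, intervals: IntervalSet | None = None,
                 mode: str = "site") -> pd.DataFrame:
    """Assemble the full per-sample burden report (counts, F, interval %)."""
    bt = individual_burden(gm, annot, mode=mode).table.set_index("sample")
    bt["F"] = heterozygosity_f(gm)
    if intervals is not None:
        bt["interval_freq_pct"] = interval_burden_frequency(gm, annot, intervals)
    if manifest is not None:
        meta = manifest.table.set_index("sample_id")[["population", "status"]]
        bt = meta.join(bt, how="right")
    return bt.reset_index(names="sample")
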