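"""Genotype-group phenotype testing for candidate deleterious SNPs.

Downstream of an external GWAS: given a candidate site, samples are grouped
by genotype and a trait is compared across groups — either REF homozygotes
versus ALT-allele carriers (two-class, the usual boxplot contrast where ALT
is the predicted-deleterious allele), or the three genotype classes with a
one-way ANOVA and Dunnett-style comparisons against the REF class.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import GenotypeMatrix, MISSING, PopulationManifest


def _site_index(gm: GenotypeMatrix, chrom: str, pos: int) -> int:
    hit = np.flatnonzero((gm.chrom == chrom) & (gm.pos == pos))
    if not len(hit):
        raise KeyError(f"site {chrom}:{pos} not in genotype matrix")
    return int(hit[0])


def genotype_group_test(gm: GenotypeMatrix, chrom: str, pos: int,
                        phenotype: pd.Series,
                        grouping: str = "REF_vs_ALT") -> dict:
    """Test a trait across genotype groups at one site.

    grouping='REF_vs_ALT' pools heterozygotes with ALT homozygotes
    (carriers of the deleterious allele) against REF homozygotes;
    'three_genotypes' runs a one-way ANOVA over dosage classes plus
    Dunnett-adjusted comparisons of each non-REF class against REF.
    ``phenotype`` is indexed by sample id.
    """
    i = _site_index(gm, chrom, pos)
    dos = pd.Series(gm.dosage[i], index=gm.samples)
    df = pd.concat([dos.rename("dosage"), phenotype.rename("value")],
                   axis=1, join="inner").dropna()
    df = df[df["dosage"] != MISSING]
    if grouping == "REF_vs_ALT":
        labels = {0: "REF", 1: "ALT", 2: "ALT"}
    elif grouping == "three_genotypes":
        labels = {0: "REF", 1: "HET", 2: "ALT"}
    else:
        raise ValueError(f"unknown grouping {grouping!r}")
    df["group"] = df["dosage"].map(labels)
    groups = {g: sub["value"].to_numpy(dtype=float)
              for g, sub in df.groupby("group")}
    small = [g for g, v in groups.items() if len(v) < 2]
    if len(groups) < 2 or small:
        raise ValueError(f"genotype classes too small or empty: {small or list(groups)}")
    arrays = [groups[g] for g in sorted(groups)]
    if all(np.ptp(np.concatenate(arrays)) == 0 for _ in [0]):
        f_stat, p = 0.0, 1.0
    else:
        f_stat, p = stats.f_oneway(*arrays)
        if np.isnan(f_stat):
            f_stat, p = 0.0, 1.0
    out = {
        "chrom": chrom, "pos": pos, "grouping": grouping,
        "group_means": {g: float(v.mean()) for g, v in groups.items()},
        "group_n": {g: int(len(v)) for g, v in groups.items()},
        "F": float(f_stat), "p": float(p),
    }
    if grouping == "three_genotypes" and "REF" in groups and len(groups) > 1:
        others = [g for g in sorted(groups) if g != "REF"]
        res = stats.dunnett(*[groups[g] for g in others],
                            control=groups["REF"])
        out["dunnett"] = {g: float(pv)
                          for g, pv in zip(others, np.atleast_1d(res.pvalue))}
    return out


def allele_status_by_population(gm: GenotypeMatrix, chrom: str, pos: int,
                                manifest: PopulationManifest) -> pd.DataFrame:
    """Per-population genotype-class fractions (REF-hom / het / ALT-hom)
    over non-missing samples at one site."""
    i = _site_index(gm, chrom, pos)
    dos = pd.Series(gm.dosage[i], index=gm.samples, name="dosage")
    meta = manifest.table.set_index("sample_id")["population"]
    df = pd.concat([dos, meta.rename("population")], axis=1, join="inner")
    df = df[df["dosage"] != MISSING]
    rows = []
    for popn, sub in df.groupby("population"):
        n = len(sub)
        rows.append({
            "population": popn, "n": n,
            "ref_hom": float((sub["dosage"] == 0).sum() / n),
            "het": float((sub["dosage"] == 1).sum() / n),
            "alt_hom": float((sub["dosage"] == 2).sum() / n),
        })
    return pd.DataFrame(rows)
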