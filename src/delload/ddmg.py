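"""Differentially deleterious mutated gene (DDMG) detection.

Per-gene deleterious-mutation counts per individual are compared between a
cultivated and a wild group the way differential expression is tested:
log2 fold change of (pseudocounted) group means, a two-sided per-gene test,
Benjamini–Hochberg adjustment across testable genes, and the classification
rule |log2FC| >= 1 with Padj <= 0.05 (both inclusive).  "up" means a higher
burden in the cultivated group.

Per-gene counts are small zero-inflated integers with no library-size
analogue, so the default test is the Mann–Whitney U (exact for small
groups); a Welch t alternative is available.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneModelSet, GenotypeMatrix
from .burden import _deleterious_mask

import logging

log = logging.getLogger(__name__)


def gene_burden_matrix(gm: GenotypeMatrix, annot: pd.DataFrame,
                       genes: GeneModelSet, mode: str = "site",
                       flag: str = "is_deleterious_sift") -> pd.DataFrame:
    """Genes x samples matrix of per-individual deleterious burden.

    Sites are assigned to genes by the annotation's ``gene_id``; genes with
    no deleterious site are kept as all-zero rows.  Annotation gene ids
    absent from the gene models are still counted (with a warning).
    """
    if mode not in ("site", "allele"):
        raise ValueError("mode must be 'site' or 'allele'")
    dele = _deleterious_mask(annot, flag)
    gene_of_site = annot["gene_id"].to_numpy(dtype=object)
    d = gm.dosage[dele]
    gids = gene_of_site[dele]
    contrib = np.where(d == 1, 1, np.where(d == 2, 2 if mode == "allele" else 1, 0))
    df = pd.DataFrame(contrib, columns=gm.samples)
    df["gene_id"] = gids
    counts = df.groupby("gene_id", sort=False).sum()
    mat = counts.reindex(genes.gene_ids, fill_value=0)
    orphan = set(counts.index) - set(genes.gene_ids)
    if orphan:
        log.warning("gene_burden_matrix: %d annotation gene ids absent from "
                    "gene models; kept under their own ids", len(orphan))
        mat = pd.concat([mat, counts.loc[sorted(orphan)]])
    mat.index.name = "gene_id"
    return mat.astype(np.int64)


def _mwu_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        return 1.0
    method = "exact" if (len(a) <= 8 and len(b) <= 8) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided",
                                    method=method, use_continuity=False).pvalue)


def ddmg_test(mat: pd.DataFrame, cultivated: list[str], wild: list[str],
              fc_threshold: float = 1.0, padj_threshold: float = 0.05,
              pseudocount: float = 0.5, test: str = "mannwhitney"
              ) -> pd.DataFrame:
    """Per-gene differential deleterious-burden test.

    Returns one row per gene: group means, log2FC (cultivated over wild,
    with pseudocount), p, BH-adjusted padj (computed across genes with at
    least one nonzero count; all-zero genes are untestable and carry NaN p),
    and class in {up, down, ns}.
    """
    if len(cultivated) < 3 or len(wild) < 3:
        raise ValueError("ddmg_test needs >= 3 samples per group")
    a = mat[cultivated].to_numpy(dtype=float)   # cultivated
    b = mat[wild].to_numpy(dtype=float)
    mean_c = a.mean(axis=1)
    mean_w = b.mean(axis=1)
    log2fc = np.log2((mean_c + pseudocount) / (mean_w + pseudocount))
    testable = (a.sum(axis=1) + b.sum(axis=1)) > 0
    pvals = np.full(len(mat), np.nan)
    idx = np.flatnonzero(testable)
    if test == "mannwhitney" and len(cultivated) > 8 and len(wild) > 8 \
            and len(idx):
        # large groups: vectorized normal approximation with tie correction
        res = stats.mannwhitneyu(a[idx], b[idx], axis=1,
                                 alternative="two-sided",
                                 method="asymptotic", use_continuity=False)
        pvals[idx] = res.pvalue
        const = np.all(np.concatenate([a, b], axis=1)
                       == a[:, :1], axis=1) & testable
        pvals[const] = 1.0
    else:
        for i in idx:
            if test == "mannwhitney":
                pvals[i] = _mwu_p(a[i], b[i])
            elif test == "welch_t":
                t = stats.ttest_ind(a[i], b[i], equal_var=False)
                pvals[i] = 1.0 if np.isnan(t.pvalue) else float(t.pvalue)
            else:
                raise ValueError(f"unknown test {test!r}")
    padj = np.full(len(mat), np.nan)
    if testable.any():
        padj[testable] = multipletests(pvals[testable], method="fdr_bh")[1]
    cls = np.where((log2fc >= fc_threshold) & (padj <= padj_threshold), "up",
                   np.where((log2fc <= -fc_threshold) & (padj <= padj_threshold),
                            "down", "ns"))
    cls[np.isnan(padj)] = "ns"
    return pd.DataFrame({"gene_id": mat.index, "mean_cultivated": mean_c,
                         "mean_wild": mean_w, "log2fc": log2fc, "p": pvals,
                         "padj": padj, "class": cls}).set_index("gene_id")


def ddmg_genes(result: pd.DataFrame) -> set[str]:
    return set(result.index[result["class"] != "ns"])


def ddmg_overlap(result_a: pd.DataFrame, result_b: pd.DataFrame,
                 result_c: pd.DataFrame) -> dict[str, int]:
    """Venn counts of DDMG gene sets from three comparisons."""
    sa, sb, sc = ddmg_genes(result_a), ddmg_genes(result_b), ddmg_genes(result_c)
    return {
        "a": len(sa), "b": len(sb), "c": len(sc),
        "ab": len(sa & sb), "ac": len(sa & sc), "bc": len(sb & sc),
        "abc": len(sa & sb & sc),
        "a_only": len(sa - sb - sc), "b_only": len(sb - sa - sc),
        "c_only": len(sc - sa - sb),
    }
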