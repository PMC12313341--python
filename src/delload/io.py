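"""Readers, writers and validated in-memory containers.

All genomic coordinates are 1-based inclusive internally (the VCF
convention); BED input/output converts at the boundary.  Genotypes are
stored as ALT-allele dosages in {0, 1, 2} with -1 marking a missing call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from cyvcf2 import VCF

log = logging.getLogger(__name__)

MISSING = -1


@dataclass
class GenotypeMatrix:
    """Biallelic diploid SNP dosages (sites x samples) with coordinates.

    ``dosage[i, j]`` is the count of ALT alleles carried by sample ``j``
    at site ``i``; ``-1`` marks a missing genotype.  Sites are kept sorted
    by (chrom, pos).
    """

    chrom: np.ndarray          # (n_sites,) str
    pos: np.ndarray            # (n_sites,) int64, 1-based
    ref: np.ndarray            # (n_sites,) str
    alt: np.ndarray            # (n_sites,) str
    dosage: np.ndarray         # (n_sites, n_samples) int8
    samples: list[str]

    def __post_init__(self) -> None:
        if len(self.samples) != len(set(self.samples)):
            raise ValueError("duplicate sample ids")
        n = len(self.pos)
        if not (len(self.chrom) == len(self.ref) == len(self.alt) == n
                and self.dosage.shape == (n, len(self.samples))):
            raise ValueError("inconsistent array shapes")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def missing(self) -> np.ndarray:
        """Boolean (sites x samples) missingness mask."""
        return self.dosage == MISSING

    def site_key(self) -> pd.MultiIndex:
        return pd.MultiIndex.from_arrays(
            [self.chrom, self.pos, self.ref, self.alt],
            names=["chrom", "pos", "ref", "alt"])

    def sample_indices(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise KeyError(f"samples not in genotype matrix: {missing}")
        return np.asarray([lookup[s] for s in ids], dtype=np.intp)

    def take_sites(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.chrom[idx], self.pos[idx], self.ref[idx],
                              self.alt[idx], self.dosage[idx], list(self.samples))

    def take_samples(self, ids: Sequence[str]) -> "GenotypeMatrix":
        j = self.sample_indices(ids)
        return GenotypeMatrix(self.chrom, self.pos, self.ref, self.alt,
                              self.dosage[:, j], list(ids))

    def alt_freq(self, sample_idx: np.ndarray | None = None) -> np.ndarray:
        """Per-site ALT allele frequency over non-missing alleles (NaN if none)."""
        d = self.dosage if sample_idx is None else self.dosage[:, sample_idx]
        ok = d != MISSING
        n_alleles = 2 * ok.sum(axis=1)
        alt = np.where(ok, d, 0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)

    def sort(self) -> "GenotypeMatrix":
        order = np.lexsort((self.pos, self.chrom))
        return self.take_sites(order)


@dataclass
class PopulationManifest:
    """Sample -> population / wild-cultivated status, plus named comparisons."""

    table: pd.DataFrame                      # columns: sample_id, population, status
    comparisons: dict[str, tuple[list[str], list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        need = {"sample_id", "population", "status"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"manifest requires columns {sorted(need)}")
        bad = set(self.table["status"]) - {"wild", "cultivated"}
        if bad:
            raise ValueError(f"unknown status values: {sorted(bad)}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in manifest")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_of(self, population: str) -> list[str]:
        return list(self.table.loc[self.table["population"] == population, "sample_id"])

    def samples_with_status(self, status: str) -> list[str]:
        return list(self.table.loc[self.table["status"] == status, "sample_id"])

    def add_comparison(self, name: str, group_a: Sequence[str],
                       group_b: Sequence[str]) -> None:
        a, b = list(group_a), list(group_b)
        if not a or not b or set(a) & set(b):
            raise ValueError(f"comparison {name!r}: groups must be disjoint and non-empty")
        self.comparisons[name] = (a, b)

    def validate_against(self, gm: GenotypeMatrix) -> None:
        unknown = sorted(set(self.sample_ids) - set(gm.samples))
        if unknown:
            raise ValueError(f"manifest samples absent from genotypes: {unknown}")


@dataclass
class GeneModelSet:
    """Gene coordinates: gene_id, chrom, start, end (1-based inclusive), strand."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        need = {"gene_id", "chrom", "start", "end"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"gene models require columns {sorted(need)}")
        if "strand" not in self.table.columns:
            self.table = self.table.assign(strand=".")
        if (self.table["start"] > self.table["end"]).any():
            raise ValueError("gene with start > end")
        if self.table["gene_id"].duplicated().any():
            raise ValueError("duplicate gene_id")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table["gene_id"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class IntervalSet:
    """Labelled genomic intervals, 1-based inclusive."""

    table: pd.DataFrame  # columns chrom, start, end, label

    def __post_init__(self) -> None:
        need = {"chrom", "start", "end"}
        if not need.issubset(self.table.columns):
            raise ValueError(f"intervals require columns {sorted(need)}")
        if "label" not in self.table.columns:
            self.table = self.table.assign(label="custom")
        if len(self.table) and (self.table["start"] > self.table["end"]).any():
            raise ValueError("interval with start > end")

    def __len__(self) -> int:
        return len(self.table)

    def total_span(self) -> int:
        m = self.merge().table
        return int((m["end"] - m["start"] + 1).sum())

    def merge(self) -> "IntervalSet":
        """Collapse overlapping or bookended intervals per chromosome."""
        if not len(self.table):
            return IntervalSet(self.table.copy())
        rows = []
        t = self.table.sort_values(["chrom", "start", "end"])
        for chrom, grp in t.groupby("chrom", sort=True):
            cur_s = cur_e = None
            for s, e in zip(grp["start"], grp["end"]):
                if cur_s is None:
                    cur_s, cur_e = s, e
                elif s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = s, e
            rows.append((chrom, cur_s, cur_e))
        out = pd.DataFrame(rows, columns=["chrom", "start", "end"])
        out["label"] = "merged"
        return IntervalSet(out)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        """Boolean mask: does each (chrom, pos) fall inside any interval."""
        mask = np.zeros(len(pos), dtype=bool)
        for c, grp in self.merge().table.groupby("chrom"):
            sel = chrom == c
            if not sel.any():
                continue
            p = pos[sel]
            starts = grp["start"].to_numpy()
            ends = grp["end"].to_numpy()
            # merged intervals are sorted and disjoint: searchsorted lookup
            i = np.searchsorted(starts, p, side="right") - 1
            hit = (i >= 0) & (p <= ends[np.clip(i, 0, len(ends) - 1)])
            mask[sel] = hit
        return mask


# ---------------------------------------------------------------------------
# readers


def read_vcf(path: str, region: str | None = None) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records, indels and records without a SNP REF/ALT pair are
    dropped (counted in the log).  Phased and unphased genotypes are treated
    identically: dosage is the number of ALT alleles.
    """
    vcf = VCF(path, gts012=True)
    samples = list(vcf.samples)
    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    rows: list[np.ndarray] = []
    n_dropped = 0
    it = vcf(region) if region else vcf
    for rec in it:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_dropped += 1
            continue
        chroms.append(rec.CHROM)
        poss.append(rec.POS)
        refs.append(rec.REF)
        alts.append(rec.ALT[0])
        gt = rec.gt_types  # gts012: 0=hom-ref 1=het 2=hom-alt 3=missing
        rows.append(np.where(gt == 3, MISSING, gt).astype(np.int8))
    vcf.close()
    if n_dropped:
        log.info("read_vcf: dropped %d non-biallelic-SNP records", n_dropped)
    if not rows:
        log.warning("read_vcf: no biallelic SNPs in %s", path)
        return GenotypeMatrix(np.array([], dtype=object), np.array([], dtype=np.int64),
                              np.array([], dtype=object), np.array([], dtype=object),
                              np.zeros((0, len(samples)), dtype=np.int8), samples)
    gm = GenotypeMatrix(np.asarray(chroms, dtype=object), np.asarray(poss, dtype=np.int64),
                        np.asarray(refs, dtype=object), np.asarray(alts, dtype=object),
                        np.vstack(rows), samples)
    return gm.sort()


def write_vcf(gm: GenotypeMatrix, path: str, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal VCF v4.2 (GT only) for a biallelic SNP matrix."""
    code = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if contig_lengths:
            for c, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={c},length={ln}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(gm.samples) + "\n")
        for i in range(gm.n_sites):
            gts = "\t".join(code[int(d)] for d in gm.dosage[i])
            fh.write(f"{gm.chrom[i]}\t{gm.pos[i]}\t.\t{gm.ref[i]}\t{gm.alt[i]}"
                     f"\t.\t.\t.\tGT\t{gts}\n")


def apply_site_filters(gm: GenotypeMatrix, maf_min: float = 0.05,
                       missing_max: float = 0.70) -> GenotypeMatrix:
    """Keep sites with MAF >= maf_min and missing fraction <= missing_max.

    MAF is computed over non-missing alleles only; sites with every genotype
    missing have undefined MAF and are dropped.
    """
    if not 0 <= maf_min <= 0.5:
        raise ValueError("maf_min must be in [0, 0.5]")
    if not 0 <= missing_max <= 1:
        raise ValueError("missing_max must be in [0, 1]")
    miss_frac = gm.missing.mean(axis=1) if gm.n_samples else np.ones(gm.n_sites)
    p = gm.alt_freq()
    maf = np.minimum(p, 1 - p)
    all_missing = np.isnan(p)
    keep = (~all_missing) & (maf >= maf_min) & (miss_frac <= missing_max)
    log.info("apply_site_filters: kept %d / %d sites (%d all-missing)",
             int(keep.sum()), gm.n_sites, int(all_missing.sum()))
    return gm.take_sites(np.flatnonzero(keep))


ANNOT_COLUMNS = ["chrom", "pos", "ref", "alt", "gene_id", "effect",
                 "sift_score", "gerp_score"]


def read_annotation_table(path: str) -> pd.DataFrame:
    """Read a per-site annotation TSV (SIFT/GERP scores, gene assignment).

    Columns: chrom, pos, ref, alt, gene_id, effect, sift_score, gerp_score
    (scores nullable).  Duplicate (chrom,pos,ref,alt) keys are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str,
                                            "effect": str})
    missing_cols = set(ANNOT_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"annotation table missing columns {sorted(missing_cols)}")
    for col in ("sift_score", "gerp_score"):
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & df[col].notna())[0]) + 2
            raise ValueError(f"non-numeric {col} at line {row} of {path}") from exc
    key = df[["chrom", "pos", "ref", "alt"]]
    if key.duplicated().any():
        raise ValueError("duplicate (chrom,pos,ref,alt) keys in annotation table")
    return df


def join_annotation(gm: GenotypeMatrix, annot: pd.DataFrame) -> pd.DataFrame:
    """Align annotation rows to matrix sites; returns annotation reindexed
    to the matrix site order with a boolean ``in_matrix`` diagnostic column
    dropped for unmatched rows (their count is logged)."""
    key = pd.MultiIndex.from_frame(annot[["chrom", "pos", "ref", "alt"]])
    a = annot.set_index(key)
    mk = gm.site_key()
    unmatched = (~key.isin(mk)).sum()
    if unmatched:
        log.warning("join_annotation: %d annotation rows not present in matrix",
                    unmatched)
    out = a.reindex(mk).reset_index(drop=True)
    out[["chrom", "pos", "ref", "alt"]] = np.column_stack(
        [gm.chrom, gm.pos, gm.ref, gm.alt])
    out["pos"] = out["pos"].astype(np.int64)
    return out


def read_manifest(path: str, gm: GenotypeMatrix | None = None) -> PopulationManifest:
    df = pd.read_csv(path, sep="\t", dtype=str)
    mf = PopulationManifest(df)
    if gm is not None:
        mf.validate_against(gm)
    return mf


def read_gene_models(path: str) -> GeneModelSet:
    """Read gene models from GFF3 (type == gene) or a 4/5-column TSV."""
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("##gff") or first.count("\t") == 8:
        cols = ["chrom", "source", "type", "start", "end", "score", "strand",
                "phase", "attrs"]
        df = pd.read_csv(path, sep="\t", comment="#", names=cols,
                         dtype={"chrom": str})
        df = df[df["type"] == "gene"].copy()
        df["gene_id"] = df["attrs"].str.extract(r"ID=([^;]+)")
        df = df[["gene_id", "chrom", "start", "end", "strand"]]
    else:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene_id": str})
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return GeneModelSet(df.reset_index(drop=True))


def read_intervals(path: str, label: str = "custom") -> IntervalSet:
    """Read BED3(+label): 0-based half-open converted to 1-based inclusive."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype={0: str})
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "end", "label"][: df.shape[1]]
    df["start"] = df["start"].astype(np.int64) + 1
    df["end"] = df["end"].astype(np.int64)
    if "label" not in df.columns:
        df["label"] = label
    return IntervalSet(df)


def write_intervals(iv: IntervalSet, path: str) -> None:
    """Write BED (internal 1-based inclusive back to 0-based half-open)."""
    out = iv.table.copy()
    out["start"] = out["start"] - 1
    out[["chrom", "start", "end", "label"]].to_csv(path, sep="\t", header=False,
                                                   index=False)


def read_score_track(path: str) -> pd.DataFrame:
    """Read a windowed score track TSV: chrom, start, end, score[, n_sites]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "start", "end", "score"}
    if not need.issubset(df.columns):
        raise ValueError(f"score track requires columns {sorted(need)}")
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_score_track(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    """Phenotype TSV: sample_id, trait, value (one row per sample x trait)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "trait": str})
    need = {"sample_id", "trait", "value"}
    if not need.issubset(df.columns):
        raise ValueError(f"phenotype table requires columns {sorted(need)}")
    if df.duplicated(["sample_id", "trait"]).any():
        raise ValueError("duplicate (sample, trait) phenotype rows")
    df["value"] = pd.to_numeric(df["value"])
    return df
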