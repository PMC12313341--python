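"""Synthetic wild/cultivated cohort generator with truth labels.

The generator works at the allele-frequency level rather than simulating
forward-in-time genealogies: each population's site frequencies are drawn
from a Balding–Nichols distribution around a shared ancestral frequency,
which creates the drift/differentiation, rare-deleterious-allele, sweep and
admixture structure the downstream statistics measure, at a tiny fraction
of the cost of a coalescent or Wright–Fisher simulation.

Four populations are emitted — P1 (wild recipient), P2 (cultivated
recipient), P3 (cultivated donor) and O (outgroup) — so that the same
cohort exercises two-population comparisons (P2 vs P1) and the four-taxon
(((P1, P2), P3), O) introgression tests.

All randomness flows from a single ``numpy`` generator created from
``SimulationConfig.seed``.  The draw order is fixed (deleterious flags,
positions, alleles, ancestral frequencies, per-population frequencies,
outgroup polymorphism, genotypes per population in P1/P2/P3/O order,
missingness, annotation scores), so a given seed reproduces the cohort
byte-for-byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import (GeneModelSet, GenotypeMatrix, IntervalSet, MISSING,
                 PopulationManifest, write_vcf)

POPULATIONS = ("P1", "P2", "P3", "O")
_STATUS = {"P1": "wild", "P2": "cultivated", "P3": "cultivated", "O": "wild"}
_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class Window:
    """A genomic window [start, end] (1-based inclusive) carrying a parameter:
    the diversity-reduction factor for sweeps, the admixture fraction f for
    introgression."""
    start: int
    end: int
    value: float


@dataclass
class SimulationConfig:
    seed: int = 0
    n_per_pop: dict[str, int] = field(
        default_factory=lambda: {"P1": 20, "P2": 20, "P3": 20, "O": 12})
    n_sites: int = 20_000
    chrom: str = "chr1"
    chrom_length: int = 1_000_000
    # Balding–Nichols drift parameter per population.  P1 and P2 are sister
    # populations: they first share the drift of their common ancestor
    # (f_recipient_shared) and then each accumulates its own private drift
    # (their f_pop entries); P3 and O drift independently from the root.
    f_pop: dict[str, float] = field(
        default_factory=lambda: {"P1": 0.01, "P2": 0.01, "P3": 0.3, "O": 0.5})
    f_recipient_shared: float = 0.15
    fraction_deleterious: float = 0.05
    # deleterious ancestral frequencies ~ Beta(a, b) truncated to (lo, hi)
    del_freq_beta: tuple[float, float] = (0.5, 5.0)
    del_freq_range: tuple[float, float] = (0.005, 0.5)
    neutral_freq_range: tuple[float, float] = (0.05, 0.95)
    sweep_windows: list[Window] = field(default_factory=list)
    sweep_population: str = "P2"
    introgression_windows: list[Window] = field(default_factory=list)
    # heterozygote-excess coefficient per population (0 = Hardy–Weinberg)
    het_excess: dict[str, float] = field(default_factory=dict)
    missing_rate: float = 0.02
    outgroup_poly_rate: float = 0.02
    gene_width: int = 10_000
    gerp_missing_rate: float = 0.3

    def __post_init__(self) -> None:
        for pop, f in self.f_pop.items():
            if not 0 < f < 1:
                raise ValueError(f"f_pop[{pop}] must be in (0,1)")
        if not 0 <= self.f_recipient_shared < 1:
            raise ValueError("f_recipient_shared must be in [0,1)")
        for w in list(self.sweep_windows) + list(self.introgression_windows):
            if not (1 <= w.start <= w.end <= self.chrom_length):
                raise ValueError(f"window {w} outside [1, {self.chrom_length}]")
        for w in self.introgression_windows:
            if not 0 <= w.value <= 1:
                raise ValueError("admixture fraction f must be in [0, 1]")
            if w.value > 0 and self.n_per_pop.get("P3", 0) == 0:
                raise ValueError("introgression requires a donor population P3")


@dataclass
class Cohort:
    """A simulated cohort plus its ground truth."""
    gm: GenotypeMatrix
    annotation: pd.DataFrame
    manifest: PopulationManifest
    genes: GeneModelSet
    truth_sites: pd.DataFrame    # per site: deleterious, ancestral, p_<pop>
    truth_windows: pd.DataFrame  # per generator window: kind, start, end, value
    config: SimulationConfig

    def samples_of(self, pop: str) -> list[str]:
        return self.manifest.samples_of(pop)

    def write(self, outdir: str) -> dict[str, str]:
        """Write the cohort in the exchange formats the readers consume."""
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "vcf": os.path.join(outdir, "cohort.vcf"),
            "annotation": os.path.join(outdir, "annotation.tsv"),
            "manifest": os.path.join(outdir, "manifest.tsv"),
            "genes": os.path.join(outdir, "genes.tsv"),
            "truth_sites": os.path.join(outdir, "truth_sites.tsv"),
            "truth_windows": os.path.join(outdir, "truth_windows.tsv"),
        }
        write_vcf(self.gm, paths["vcf"],
                  {self.config.chrom: self.config.chrom_length})
        self.annotation.to_csv(paths["annotation"], sep="\t", index=False)
        self.manifest.table.to_csv(paths["manifest"], sep="\t", index=False)
        self.genes.table.to_csv(paths["genes"], sep="\t", index=False)
        self.truth_sites.to_csv(paths["truth_sites"], sep="\t", index=False)
        self.truth_windows.to_csv(paths["truth_windows"], sep="\t", index=False)
        return paths


def _truncated_beta(rng: np.random.Generator, a: float, b: float,
                    lo: float, hi: float, size: int) -> np.ndarray:
    out = rng.beta(a, b, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.beta(a, b, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _balding_nichols(rng: np.random.Generator, p0: np.ndarray,
                     f: float) -> np.ndarray:
    k = (1 - f) / f
    return rng.beta(np.maximum(p0 * k, 1e-9), np.maximum((1 - p0) * k, 1e-9))


def _sweep_transform(p: np.ndarray, reduction: float) -> np.ndarray:
    """Move allele frequencies toward the nearer boundary so that expected
    heterozygosity 2p(1-p) shrinks by ``reduction`` (solves the quadratic)."""
    h_new = (1 - reduction) * 2 * p * (1 - p)
    disc = np.sqrt(np.clip(1 - 2 * h_new, 0, 1))
    return np.where(p < 0.5, (1 - disc) / 2, (1 + disc) / 2)


def _sample_genotypes(rng: np.random.Generator, p: np.ndarray, n: int,
                      het_excess: float = 0.0) -> np.ndarray:
    """Diploid dosages for n individuals at sites with ALT frequencies p.

    het_excess = 0 gives Hardy–Weinberg (binomial) sampling; h > 0 inflates
    P(het) to 2pq(1+h), removing mass equally from the homozygote classes.
    """
    q = 1 - p
    if het_excess == 0.0:
        return rng.binomial(2, p[:, None], size=(len(p), n)).astype(np.int8)
    p_het = np.clip(2 * p * q * (1 + het_excess), 0, 1)
    p_hom_alt = np.clip(p * p - het_excess * p * q, 0, None)
    p_hom_ref = np.clip(q * q - het_excess * p * q, 0, None)
    tot = p_het + p_hom_alt + p_hom_ref
    probs = np.stack([p_hom_ref, p_het, p_hom_alt], axis=1) / tot[:, None]
    u = rng.random((len(p), n))
    c0 = probs[:, 0][:, None]
    c1 = (probs[:, 0] + probs[:, 1])[:, None]
    return ((u >= c0).astype(np.int8) + (u >= c1).astype(np.int8))


def _window_mask(pos: np.ndarray, windows: list[Window]) -> np.ndarray:
    mask = np.zeros(len(pos), dtype=bool)
    for w in windows:
        mask |= (pos >= w.start) & (pos <= w.end)
    return mask


def simulate_cohort(cfg: SimulationConfig) -> Cohort:
    """Draw a full cohort (genotypes, annotation, manifest, genes, truth)."""
    rng = np.random.default_rng(cfg.seed)
    n_sites = cfg.n_sites

    # 1-3: site identity
    deleterious = rng.random(n_sites) < cfg.fraction_deleterious
    pos = np.sort(rng.choice(cfg.chrom_length, size=n_sites, replace=False)) + 1
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4
    ref = _BASES[ref_idx].astype(object)
    alt = _BASES[alt_idx].astype(object)

    # 4: ancestral (derived-allele) frequencies; ALT is the derived allele
    lo, hi = cfg.neutral_freq_range
    p0 = rng.uniform(lo, hi, size=n_sites)
    a, b = cfg.del_freq_beta
    dlo, dhi = cfg.del_freq_range
    p0[deleterious] = _truncated_beta(rng, a, b, dlo, dhi,
                                      int(deleterious.sum()))

    # 5: per-population frequencies (Balding–Nichols drift); the recipient
    # sister pair P1/P2 drifts jointly to p12 first, then splits
    p12 = _balding_nichols(rng, p0, cfg.f_recipient_shared) \
        if cfg.f_recipient_shared > 0 else p0
    freqs: dict[str, np.ndarray] = {}
    for pop in POPULATIONS:
        root = p12 if pop in ("P1", "P2") else p0
        freqs[pop] = _balding_nichols(rng, root, cfg.f_pop[pop])

    # 6: outgroup carries the ancestral (REF) allele except at a small
    # polymorphism fraction, used to exercise polarization filtering
    out_poly = rng.random(n_sites) < cfg.outgroup_poly_rate
    freqs["O"] = np.where(out_poly, freqs["O"], 0.0)

    # 7: sweeps reduce the cultivated population's window diversity
    for w in cfg.sweep_windows:
        m = (pos >= w.start) & (pos <= w.end)
        freqs[cfg.sweep_population] = freqs[cfg.sweep_population].copy()
        freqs[cfg.sweep_population][m] = _sweep_transform(
            freqs[cfg.sweep_population][m], w.value)

    # 8: introgression — each P2 haplotype is drawn from the donor with
    # probability f, which for independent haplotypes is Hardy–Weinberg
    # sampling at the mixture frequency (1-f)·p2 + f·p3
    p2_eff = freqs["P2"].copy()
    for w in cfg.introgression_windows:
        m = (pos >= w.start) & (pos <= w.end)
        p2_eff[m] = (1 - w.value) * freqs["P2"][m] + w.value * freqs["P3"][m]

    # 9: genotypes, population by population in fixed order
    blocks = []
    sample_ids: list[str] = []
    pop_col: list[str] = []
    for pop in POPULATIONS:
        n = cfg.n_per_pop.get(pop, 0)
        if n == 0:
            continue
        p = p2_eff if pop == "P2" else freqs[pop]
        h = cfg.het_excess.get(pop, 0.0)
        blocks.append(_sample_genotypes(rng, p, n, h))
        sample_ids += [f"{pop}_{i:03d}" for i in range(n)]
        pop_col += [pop] * n
    dosage = np.concatenate(blocks, axis=1)

    # 10: missingness
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage = np.where(miss, MISSING, dosage).astype(np.int8)

    gm = GenotypeMatrix(np.full(n_sites, cfg.chrom, dtype=object), pos.astype(np.int64),
                        ref, alt, dosage, sample_ids)

    manifest = PopulationManifest(pd.DataFrame({
        "sample_id": sample_ids,
        "population": pop_col,
        "status": [_STATUS[p] for p in pop_col],
    }))
    manifest.add_comparison("cultivated_vs_wild",
                            manifest.samples_of("P2"), manifest.samples_of("P1"))

    # genes tile the chromosome as fixed-width blocks
    starts = np.arange(1, cfg.chrom_length + 1, cfg.gene_width)
    genes = GeneModelSet(pd.DataFrame({
        "gene_id": [f"gene{i:05d}" for i in range(len(starts))],
        "chrom": cfg.chrom,
        "start": starts,
        "end": np.minimum(starts + cfg.gene_width - 1, cfg.chrom_length),
        "strand": ".",
    }))
    gene_of_site = np.array(genes.gene_ids, dtype=object)[
        (pos - 1) // cfg.gene_width]

    # 11: annotation scores — SIFT < 0.05 iff truly deleterious; GERP > 2
    # for deleterious sites (when present), in (-2, 2) otherwise
    sift = np.where(deleterious, rng.uniform(0.0, 0.05, n_sites) * 0.999,
                    rng.uniform(0.05, 1.0, n_sites))
    gerp = np.where(deleterious, rng.uniform(2.001, 6.0, n_sites),
                    rng.uniform(-2.0, 2.0, n_sites))
    gerp_missing = rng.random(n_sites) < cfg.gerp_missing_rate
    annotation = pd.DataFrame({
        "chrom": cfg.chrom, "pos": pos, "ref": ref, "alt": alt,
        "gene_id": gene_of_site,
        "effect": np.where(deleterious, "nonsynonymous", "synonymous"),
        "sift_score": np.round(sift, 6),
        "gerp_score": np.where(gerp_missing, np.nan, np.round(gerp, 4)),
    })

    truth_sites = pd.DataFrame({
        "chrom": cfg.chrom, "pos": pos, "deleterious": deleterious,
        "ancestral": ref,
        **{f"p_{pop}": np.round(freqs[pop], 6) for pop in POPULATIONS},
        "p_P2_effective": np.round(p2_eff, 6),
    })
    wrows = ([("sweep", w.start, w.end, w.value) for w in cfg.sweep_windows]
             + [("introgression", w.start, w.end, w.value)
                for w in cfg.introgression_windows])
    truth_windows = pd.DataFrame(wrows,
                                 columns=["kind", "start", "end", "value"])
    return Cohort(gm, annotation, manifest, genes, truth_sites, truth_windows,
                  cfg)


def fst_recovery_config(seed: int, n_per_pop: int = 50,
                        f: float = 0.1) -> SimulationConfig:
    """Two independently drifted populations (no shared recipient drift) for
    checking that the Weir–Cockerham estimator recovers the simulated
    drift parameter."""
    return SimulationConfig(
        seed=seed, f_recipient_shared=0.0,
        f_pop={"P1": f, "P2": f, "P3": 0.3, "O": 0.5},
        n_per_pop={"P1": n_per_pop, "P2": n_per_pop, "P3": 4, "O": 4})


def fd_recovery_config(seed: int, f: float = 0.3,
                       window: Window | None = None) -> SimulationConfig:
    """Default drift structure plus one introgressed span at admixture
    fraction f (default 200 kb of the 1 Mb chromosome)."""
    w = window or Window(300_001, 500_000, f)
    return SimulationConfig(seed=seed, introgression_windows=[w])


def ddmg_power_config(seed: int) -> SimulationConfig:
    """Study conditions for the spiked-gene recovery simulation: deleterious
    ancestral frequencies concentrated near 0.1, modest wild/cultivated
    differentiation, 20 samples per group, ~20 deleterious sites per gene."""
    return SimulationConfig(
        seed=seed, fraction_deleterious=0.1,
        del_freq_beta=(2.0, 18.0), del_freq_range=(0.08, 0.12),
        f_recipient_shared=0.02,
        n_per_pop={"P1": 20, "P2": 20, "P3": 4, "O": 4})


def ddmg_null_config(seed: int, n_genes: int = 2000) -> SimulationConfig:
    """Null differential-burden conditions: both groups drawn from identical
    distributions, genes tiled finely so ~2000 are testable."""
    return SimulationConfig(
        seed=seed, fraction_deleterious=0.3, gene_width=1_000_000 // n_genes,
        del_freq_beta=(2.0, 18.0), del_freq_range=(0.05, 0.3),
        f_recipient_shared=0.02,
        n_per_pop={"P1": 20, "P2": 20, "P3": 4, "O": 4})


def spike_gene_burden(cohort: Cohort, gene_ids: list[str], multiplier: float,
                      population: str = "P2", seed: int = 0) -> Cohort:
    """Multiply deleterious-allele frequencies inside named genes (capped at
    0.95) in one population and resample that population's genotypes at the
    affected sites.  ``multiplier=1`` returns the cohort unchanged."""
    if multiplier < 1:
        raise ValueError("multiplier must be >= 1")
    unknown = set(gene_ids) - set(cohort.genes.gene_ids)
    if unknown:
        raise KeyError(f"unknown gene ids: {sorted(unknown)}")
    if multiplier == 1:
        return cohort
    rng = np.random.default_rng(seed)
    gene_of_site = cohort.annotation["gene_id"].to_numpy()
    deleterious = cohort.truth_sites["deleterious"].to_numpy()
    hit = np.isin(gene_of_site, list(gene_ids)) & deleterious
    pcol = ("p_P2_effective" if population == "P2" else f"p_{population}")
    truth = cohort.truth_sites.copy()
    p_new = np.minimum(truth.loc[hit, pcol].to_numpy() * multiplier, 0.95)
    truth.loc[hit, pcol] = p_new

    cols = cohort.gm.sample_indices(cohort.samples_of(population))
    h = cohort.config.het_excess.get(population, 0.0)
    new_geno = _sample_genotypes(rng, p_new, len(cols), h)
    dosage = cohort.gm.dosage.copy()
    was_missing = dosage[np.ix_(np.flatnonzero(hit), cols)] == MISSING
    block = np.where(was_missing, MISSING, new_geno).astype(np.int8)
    dosage[np.ix_(np.flatnonzero(hit), cols)] = block
    gm = GenotypeMatrix(cohort.gm.chrom, cohort.gm.pos, cohort.gm.ref,
                        cohort.gm.alt, dosage, list(cohort.gm.samples))
    return replace(cohort, gm=gm, truth_sites=truth)
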