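import numpy as np
import pandas as pd
import pytest

from delload.io import GenotypeMatrix, IntervalSet
from delload.sim import SimulationConfig, Window, simulate_cohort


def make_gm(dosage, samples=None, chrom=None, pos=None, ref=None, alt=None):
    """Toy GenotypeMatrix from a (sites x samples) dosage list."""
    d = np.asarray(dosage, dtype=np.int8)
    n_sites, n_samples = d.shape
    samples = samples or [f"s{j}" for j in range(n_samples)]
    chrom = np.asarray(chrom if chrom is not None else ["chr1"] * n_sites,
                       dtype=object)
    pos = np.asarray(pos if pos is not None else
                     np.arange(1, n_sites + 1) * 100, dtype=np.int64)
    ref = np.asarray(ref if ref is not None else ["A"] * n_sites, dtype=object)
    alt = np.asarray(alt if alt is not None else ["G"] * n_sites, dtype=object)
    return GenotypeMatrix(chrom, pos, ref, alt, d, samples)


def make_annot(gm, deleterious, gene_ids=None):
    """Annotation frame flagging the given sites deleterious by SIFT."""
    dele = np.asarray(deleterious, dtype=bool)
    return pd.DataFrame({
        "chrom": gm.chrom, "pos": gm.pos, "ref": gm.ref, "alt": gm.alt,
        "gene_id": gene_ids if gene_ids is not None else "g1",
        "effect": "nonsynonymous",
        "sift_score": np.where(dele, 0.01, 0.5),
        "gerp_score": np.nan,
        "is_deleterious_sift": dele,
        "is_deleterious_gerp": np.zeros(gm.n_sites, dtype=bool),
    })


def intervals(*rows):
    return IntervalSet(pd.DataFrame(list(rows),
                                    columns=["chrom", "start", "end"]))


@pytest.fixture(scope="session")
def small_cohort():
    """A small deterministic cohort reused across read-only tests."""
    cfg = SimulationConfig(
        seed=7, n_sites=4000, chrom_length=200_000,
        n_per_pop={"P1": 10, "P2": 10, "P3": 8, "O": 6},
        sweep_windows=[Window(50_001, 70_000, 0.8)],
        introgression_windows=[Window(120_001, 160_000, 0.3)],
        gene_width=5_000)
    return simulate_cohort(cfg)
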