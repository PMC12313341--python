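"""Generate a synthetic wild/cultivated cohort and inspect its ground truth.

The generator emits four populations on one chromosome — wild and
cultivated sister recipients (P1, P2), a cultivated donor (P3) and an
outgroup (O) — with truth labels for deleterious sites, sweep windows and
introgressed windows.
"""

from delload.sim import SimulationConfig, Window, simulate_cohort

cfg = SimulationConfig(
    seed=1,
    sweep_windows=[Window(400_001, 450_000, 0.8)],
    introgression_windows=[Window(700_001, 750_000, 0.3)],
)
cohort = simulate_cohort(cfg)

n_del = int(cohort.truth_sites["deleterious"].sum())
print(f"sites simulated:      {cohort.gm.n_sites}")
print(f"samples:              {cohort.gm.n_samples} "
      f"({dict((p, len(cohort.samples_of(p))) for p in ('P1', 'P2', 'P3', 'O'))})")
print(f"true deleterious:     {n_del} "
      f"({100 * n_del / cohort.gm.n_sites:.1f}% of sites)")
print(cohort.truth_windows.to_string(index=False))

paths = cohort.write("scratch/example_cohort")
print("cohort written to:", paths["vcf"])
# The VCF/TSV bundle is exactly what the readers in delload.io consume, so
# every downstream example can start from these files or from the in-memory
# cohort object directly.
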