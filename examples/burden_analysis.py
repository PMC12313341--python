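"""Per-individual deleterious load: burden counts, heterozygosity F, and
wild-vs-cultivated comparisons.

Prints mean burden per group with a pooled t-test, and the Pearson
correlation between burden and F (more heterozygous individuals carry more
deleterious sites in heterozygous state, so burden and F are negatively
related when heterozygosity varies across samples).
"""

import delload as dl
from delload.sim import SimulationConfig, simulate_cohort

# give cultivated samples a heterozygote excess, as seen in domesticates
cfg = SimulationConfig(seed=3, het_excess={"P2": 0.4})
cohort = simulate_cohort(cfg)

annot = dl.classify_deleterious(cohort.annotation)   # SIFT < 0.05, GERP > 2
bt = dl.burden_table(cohort.gm, annot, cohort.manifest).set_index("sample")

wild = cohort.samples_of("P1")
cult = cohort.samples_of("P2")
cmp_burden = dl.compare_groups(bt["n_total"], cult, wild)
print(f"mean burden cultivated: {cmp_burden['mean_a']:.1f}")
print(f"mean burden wild:       {cmp_burden['mean_b']:.1f}")
print(f"pooled t-test:          t={cmp_burden['t']:.2f}, p={cmp_burden['p']:.3g}")

corr = dl.burden_f_correlation(bt.loc[cult + wild, "n_total"],
                               bt.loc[cult + wild, "F"])
print(f"burden-F correlation:   r={corr['pearson_r']:.2f}, p={corr['p']:.2g}")
print("negative r: heterozygote-excess samples (low F) carry more "
      "deleterious sites")
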