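# Methods

## Data model and conventions

Genotypes live in a `GenotypeMatrix`: biallelic diploid SNPs as ALT-allele
dosages in {0, 1, 2}, with missing calls stored explicitly (−1). Coordinates
are 1-based inclusive throughout (the VCF convention); BED input/output
converts at the boundary. Multi-allelic VCF records are dropped, not split —
every downstream statistic assumes biallelic sites, and dropping is the
conservative choice (counts are logged). Phased and unphased genotypes are
treated identically. MAF and all allele frequencies are computed over
non-missing alleles only; "missing rate" is the fraction of samples without
a call at the site. Sites where every genotype is missing have undefined MAF
and are removed by the site filter.

The annotation exchange format is a deliberately simple TSV
(chrom, pos, ref, alt, gene_id, effect, sift_score, gerp_score) rather than
any annotator's native output: score production is out of scope, and a
stable minimal schema keeps the join to the genotype matrix unambiguous
(keyed on chrom/pos/ref/alt, duplicates rejected).

## Deleterious classification and burden

A site is deleterious by SIFT when `sift_score < 0.05` and by GERP when
`gerp_score > 2`; both inequalities are strict (a score of exactly 0.05 or
2.0 does not qualify) and a missing score never flags a site. SIFT flags
drive burden accounting by default, with GERP as a confirmation track via
`sift_gerp_overlap`.

Per-individual burden counts sites carrying at least one deleterious ALT
allele (heterozygous: dosage 1; homozygous: dosage 2). This matches the
"number of deleterious mutation sites" reading; an allele-dosage mode
(hets count 1, homs count 2) is provided because the site/allele choice is
genuinely ambiguous in common usage. Site-mode ≤ allele-mode ≤ 2 × site-mode
always. Missing genotypes never contribute — no imputation. The deleterious
orientation is the annotation's ALT allele; reference-deleterious sites are
out of scope (substitution annotators score changes away from the
reference).

The interval burden frequency is the printed two-count ratio
`100 · n_in / n_total` per individual; an individual with zero genome-wide
deleterious sites has an undefined ratio and is reported missing rather
than zero. The statistic is invariant to splitting intervals into adjacent
sub-intervals (intervals are merged before counting).

The heterozygosity coefficient `F = (O(hom) − E(hom)) / (N − E(hom))`
follows the method-of-moments convention of the standard `--het`
implementations: per site, `E(hom) = 1 − 2p(1−p) · 2n/(2n−1)` with `n` the
non-missing diploid count, summed over the individual's genotyped sites.
The small-sample factor `2n/(2n−1)` matters for reproducibility against
those tools and is therefore kept. `N = E(hom)` (possible when every site
is monomorphic) yields a missing value with a warning.

Group contrasts use the pooled-variance Student's t by default because that
is the test conventionally attached to these burden comparisons; Welch's t
is selectable. Burden–F association is a Pearson correlation with the usual
t-distribution p-value.

## Windowed statistics

All tracks share a fixed frame: windows of width `w` starting at
1, 1+s, 2s+1, … (defaults 10 kb / 5 kb). π sums per-site unbiased
heterozygosity `2p(1−p)·2n/(2n−1)` over variant sites and divides by the
full window width — the windowed-π convention of VCF-based tools, since a
VCF alone cannot say which invariant bases were callable. Windows with no
genotyped sites report π = 0 with `n_sites = 0`.

F<sub>ST</sub> is the Weir–Cockerham (1984) two-population estimator,
combined across the window's usable sites as a ratio of sums
(Σa / Σ(a+b+c)). Negative window values are legitimate small-sample output
and are reported, not clamped. Sites where a group has no calls, or where
the total variance term is zero, are excluded from both sums.

LD decay uses genotype-dosage r² (composite LD; phase is unknown), over all
intra-chromosome pairs within `max_dist` after a MAF filter, binned by
distance. The decay summary distance is the first bin whose mean r² falls
to half the maximum bin mean. The pair enumeration is quadratic per
chromosome and intended for the scales at which decay profiles are actually
summarized (thousands of sites), not for genome-wide exhaustive scans.

Sweep regions come from an externally computed score track (XP-CLR or
similar): the empirical `quantile` (default 0.95) of non-missing window
scores is the threshold, ties are included, and selected windows that
overlap or bookend on the step frame are merged into regions. If all scores
are equal every window is selected, with a warning.

## Introgression

Sites are polarized by the outgroup: the ancestral allele is the outgroup
majority allele, accepted when its outgroup frequency is ≥ 0.8 (the
threshold is exposed; the convention in the underlying scripts varies).
Unpolarizable sites and sites with an uncalled focal population are
unusable.

ABBA/BABA are frequency-weighted over usable sites:
`ABBA = Σ (1−p1)p2p3(1−pO)`, `BABA = Σ p1(1−p2)p3(1−pO)`. The jackknife is
a weighted delete-one over contiguous blocks (default 1 Mb; block
usable-site counts as weights), Z = D/SE, with the significance rule
D > 0 and Z > 4. The SE degenerates to zero when all blocks are identical;
Z is then withheld with a warning.

Windowed f<sub>d</sub> divides the window's ABBA−BABA numerator by its
value with the donor substituted per site — the donor being whichever of
{P2, P3} has the higher derived frequency at that site. Three filters are
applied before anything else: windows with fewer than `min_snps` (default
100) usable SNPs, windows whose own D is negative, and windows with
f<sub>d</sub> > 1 are set missing. The top-5% quantile for region calling
is taken over the surviving windows only (the alternative — quantile over
all windows — is a one-line change via `select_top_regions`, but filtering
first is the coherent reading of "ignored").

## DDMGs

The genes × individuals matrix assigns deleterious sites to genes by the
annotation's `gene_id`; genes with no deleterious site remain as all-zero
rows, and annotation gene ids missing from the gene models are kept under
their own ids with a warning (dropping data silently would bias totals).

Per gene, `log2FC = log2((mean_cult + 0.5) / (mean_wild + 0.5))`. The
pseudocount of 0.5 stabilizes zero-mean genes; no per-sample normalization
is applied by default because the counts are genotype-determined, with no
sequencing-depth analogue (an optional total-burden normalization exists
for strongly unequal-load cohorts). The per-gene test is the two-sided
Mann–Whitney U — per-gene deleterious counts are small zero-inflated
integers without the mean-dispersion structure that would justify a
negative-binomial fit — exact when both groups have ≤ 8 samples, otherwise
the tie-corrected normal approximation (vectorized across genes). A Welch-t
alternative is selectable. BH adjustment runs across genes with at least
one nonzero count in the compared groups; all-zero genes are untestable and
never influence other genes' ranks. Classification is exactly
`log2FC ≥ 1 ∧ padj ≤ 0.05` (up, higher in cultivated) /
`log2FC ≤ −1 ∧ padj ≤ 0.05` (down), both thresholds inclusive.

## Candidate-SNP association

`REF_vs_ALT` pools heterozygotes with ALT homozygotes (carriers of the
predicted-deleterious allele) against REF homozygotes; `three_genotypes`
runs a one-way ANOVA over the dosage classes plus Dunnett-adjusted
comparisons of each non-REF class against REF (scipy's Dunnett
implementation). With two groups the ANOVA F equals the squared pooled t,
which is tested. GWAS itself (mixed models, kinship) is out of scope; the
module consumes candidate sites from configuration.

## Synthetic cohort generator

The generator works at the allele-frequency level. Per site, an ancestral
derived-allele frequency p₀ is drawn — Uniform(0.05, 0.95) for neutral
sites, Beta(0.5, 5) truncated to (0.005, 0.5) for deleterious sites, a
low-frequency skew mimicking purifying selection keeping damaging alleles
rare. Population frequencies then follow Balding–Nichols Beta draws:
`p_pop ~ Beta(p(1−F)/F, (1−p)(1−F)/F)` with drift parameter F. The
recipient sister pair P1/P2 first drifts jointly to a shared frequency
(`f_recipient_shared`, default 0.15) and then each accumulates private
drift (default 0.01 each); the donor P3 (default F 0.3) and outgroup O
(default 0.5) drift independently from the root. The shared-drift topology
is what makes P1 and P2 sisters — it is also what the f<sub>d</sub>
estimator assumes, and without it f<sub>d</sub> is strongly conservative.

The ALT allele is always the derived allele; the outgroup is fixed for REF
except at a small polymorphism fraction (default 2%) that exercises
polarization filtering. Sweep windows transform the cultivated population's
frequencies so that per-site expected heterozygosity shrinks by the stated
factor, moving p toward the nearer boundary (the closed-form root of
`2p′(1−p′) = (1−r)·2p(1−p)`). Introgression replaces each P2 haplotype with
a donor draw with probability f, which for independent haplotypes equals
Hardy–Weinberg sampling at the mixture frequency `(1−f)p2 + f·p3`.
Heterozygote-excess groups are sampled with `P(het) = 2pq(1+h)`, mass taken
equally from the homozygote classes — expected F decreases monotonically in
h. Genes tile the chromosome as fixed-width blocks (default 10 kb); SIFT
scores are drawn below 0.05 for true-deleterious sites and in [0.05, 1)
otherwise, GERP above 2 for deleterious sites (with a 30% missing rate) and
in (−2, 2) otherwise. All randomness flows from one seed through a single
generator with a fixed draw order, so a seed reproduces the cohort
byte-for-byte.

Default cohort size is 20 samples per recipient population, 20 donors and
12 outgroup samples at 20,000 sites on a 1 Mb chromosome — small enough
that every simulation study runs in seconds on one core, dense enough
(~200 SNPs per 10 kb window) that windowed statistics are well above their
minimum-SNP filters.

What the generator does **not** emulate: recombination-scale LD structure
within windows (sites are conditionally independent given frequencies),
selection dynamics through time, mutation-rate heterogeneity, genotyping
error beyond uniform missingness, and reference bias. Passing tests
therefore demonstrate the estimators' correctness and calibration under the
assumed frequency model, not robustness to those real-data complications.

### Named study configurations

- `fst_recovery_config`: two independent populations at F = 0.1, 50
  diploids each — the Weir–Cockerham estimate should recover 0.1 (observed
  ≈ 0.100 over 10 seeds).
- `fd_recovery_config`: defaults plus one 200 kb introgressed span at
  f = 0.3; mean window f<sub>d</sub> inside the span ≈ 0.22 (the estimator
  is conservative, within the ±0.1 recovery band used in the tests).
- Null D: defaults (no introgression); the D > 0, Z > 4 rule fires in ≈ 0
  of 40 seeds. With genome-wide f = 0.3 it fires in every seed.
- `ddmg_null_config` / `ddmg_power_config`: ~2000 finely tiled genes for
  null FDR control; deleterious frequencies concentrated near 0.1, modest
  drift and ~20 deleterious sites per gene for the ×3 spiked-gene power
  study (sensitivity ≈ 0.9, observed FDR ≈ 0 in the acceptance runs).

## Numerical notes and limitations

- Degenerate inputs are reported as missing with warnings rather than
  silently clamped: undefined MAF, `N = E(hom)`, `ABBA + BABA = 0`,
  zero jackknife SE, zero-variance correlations.
- Quantile thresholds use numpy's default (linear-interpolation) empirical
  quantile; ties at the threshold are included.
- `apply_site_filters` is idempotent; filtering can only raise a site's
  measured MAF, never lower it below the threshold it already passed.
- The exact Mann–Whitney path assumes the usual null enumeration; with
  heavy ties and n ≤ 8 the exact p is computed by scipy over the observed
  pattern, which is the standard behaviour.
- The pipeline writes per-stage artifacts plus a `report.json` with input
  SHA-256 hashes and parameter echoes; reruns with identical inputs and
  config are byte-identical on all numeric outputs.
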