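# Methods

## Setting and assumptions

The pipeline analyzes a taxon × sample table of microbial read counts
extracted from tumor RNA-seq (fungal and archaeal taxa, annotated per
taxon), together with per-sample annotations (tissue class, histologic
subtype, gender, sequencing date and plate, BRAF V600E status, clinical
variables). It assumes counts are non-negative integers aggregated from
per-sample alignment reports, that every analyzed sample has complete
batch annotations, and that the data are compositional: sequencing depth
is a nuisance, only relative information is interpretable.

## Contamination correction

Three detectors operationalize the standard visual batch-artefact checks
as deterministic rules.

**Slope detector.** For each taxon, OLS regression of its log abundance
ln(count + 1) on the sample's ln(total microbial reads). A genuine
tissue-resident taxon's counts scale with the sample's overall microbial
yield (slope ≈ 1); a reagent contaminant contributes a roughly constant
number of reads regardless of yield (slope ≈ 0). Flag when
|slope| ≤ margin, default **0.1, boundary inclusive** (a tolerance of
1e-12 absorbs float round-off at the boundary). A `scale="clr"` switch
regresses CLR abundance instead; note that on the CLR scale a
depth-tracking taxon sits near slope 0 and a constant contaminant near −1,
so the flag semantics invert — the log-count scale is the default because
it matches the intended "slope of zero ⇒ contaminant" reading. Taxa
present in fewer than max(3, 10% of samples) samples are skipped (slope
NaN, unflagged, logged): an OLS line through fewer points carries no
evidence. Zero variance in totals is a detector error.

**Plate detector.** Per taxon, the share of its reads contributed by its
two highest-yield plates. Flag when that share ≥ 0.9 **and** those plates
hold < 50% of all samples — the guard keeps the detector from flagging
ubiquitous taxa merely because plates are few or unbalanced, and makes it
abstain entirely with < 3 distinct plates.

**Date detector.** Same construction with the single highest-yield
sequencing date (share ≥ 0.9, date holds < 50% of samples).

Removal takes the **union** of the three flags. Thresholds (margin, share
threshold, max plates, prevalence floor) are config-exposed. Diagnostic
scatter/boxplots per taxon reproduce the views a human reviewer would
inspect, with flagged taxa styled in red.

## CLR transform

clr(x)ₜ = ln(xₜ + pc) − mean over taxa of ln(x·+ pc), natural log,
pseudocount default 1 added to raw counts (the simplest widely used zero
handling; config-exposed). Contracts: each transformed sample sums to zero
(within 1e-9); exact invariance to per-sample scaling at pseudocount 0 on
positive data, approximate otherwise; strictly monotone within a sample.
The pipeline's default order is: detect contaminants on the raw/log scale,
remove, then transform the filtered table for downstream statistics.

## Differential abundance

Per taxon, the Kruskal–Wallis statistic is computed from its rank
definition — mid-ranks, H = 12/(N(N+1)) Σ R²_g/n_g − 3(N+1), divided by
the tie correction 1 − Σ(t³−t)/(N³−N) — with the p-value from the χ²
tail with k−1 degrees of freedom, the large-sample reference standard
implementations report. All observations identical gives (H, p) = (0, 1);
a single group or N < 3 is a domain error. In the two-group case this is
the Wilcoxon rank-sum test. The implementation is validated against
scipy's independent version and against exhaustive enumeration of group
assignments with a hand-written rank oracle.

Effect size is logFC = log₂((mean relative abundance in group A + 1e-6) /
(same in group B + 1e-6)); the pseudo-fraction prevents division by zero
and is negligible at realistic abundances. Bonferroni correction
multiplies each p by the number of taxa tested **within one cohort
comparison** (per-comparison families match how each comparison is
reported; a config switch disables adjustment). A taxon is significantly
dysregulated when adjusted p < 0.05 (switchable to raw p) and |logFC| > 1.
Direction is `over_in_a` exactly when logFC > 0.

Seven default cohort comparisons: all tumors vs normals; each of the
classical (CPTC), follicular-variant (FVPTC) and tall-cell (TCPTC)
subtypes vs normals; male and female tumors vs gender-matched normals;
and BRAF V600E-positive vs -negative tumors (tumor-vs-tumor, no normals).
Cohorts are field == value conjunction predicates in the config, resolved
against the metadata with disjointness and non-emptiness enforced.

## Direction-concordant overlap partition

Given k cohort tables over one taxon universe, a taxon significant
somewhere lands in region S ⊆ cohorts iff it is significant with one
common direction in every cohort of S and in none outside S (strict Venn
semantics). Taxa with conflicting significant directions go to a
`discordant` list rather than being forced into a region — lossless and
explicit. The partition law (regions pairwise disjoint; regions plus
discordant cover exactly the taxa significant in ≥ 1 cohort) is tested
against per-taxon brute-force enumeration. Default groupings mirror the
two natural figure panels: the three subtype comparisons, and the two
gender comparisons.

## Clinical association

For taxa significant in ≥ 1 cohort comparison (pipeline default,
overridable), Kruskal–Wallis of CLR abundance across the levels of each
clinical variable — vital status, perineural invasion, pathologic stage,
T, N and M stage — on **tumor samples only**, NA levels dropped per
variable, variables with < 2 remaining levels skipped with a warning.
Stage sub-levels (IVA, IVB, …) collapse to their roman-numeral majors by
default (config-exposed); the test itself is unordered — no trend test is
added. The Bonferroni family is every (taxon, variable) pair tested. The
reported direction summary is the level with the highest median abundance.

## Gene-set enrichment

Continuous-phenotype GSEA: the phenotype is a microbe's abundance
(log-scale) across expression samples. Genes are ranked by Pearson
correlation with the phenotype (Spearman available); zero-variance genes
get metric 0 with a log note; a zero-variance phenotype is an error; ties
break by gene symbol ascending so rankings are deterministic.

The weighted-KS running sum steps up by |metric|^weight / Σ_hits
|metric|^weight at set members (weight default 1, the classic weighted
scheme; if all hit metrics are exactly 0 the hit mass falls back to equal
shares) and down by 1/(N − N_hits) at non-members. ES is the running-sum
value of maximum magnitude, clamped to [−1, 1] against float accumulation;
when the maximum magnitude is attained at several positions the earliest
wins. Degenerate sets (disjoint from the list, or covering it) are errors.

Significance is by **phenotype permutation** (n_perm default 1000, minimum
100, seeded): the full ranking and every ES are recomputed per
permutation. p is the same-sign tail fraction with +1 smoothing (hence
p > 0 always); NES divides ES by the mean |null ES| of the same sign; the
FDR q follows the NES-based convention — the same-sign tail fraction of
null NES pooled across sets divided by the same-sign tail fraction of
observed NES, capped at 1. A signature passes the reporting filter at
p < 0.05 and q < 0.25. Results are bit-reproducible given the seed.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes,
not any real cohort's biology:

- **Design**: 453 tumors / 54 adjacent normals by default, subtypes
  assigned at proportions 385:102:36, genders 140:366, BRAF-positive
  fraction 0.6 (typical of PTC); normals pair with the first 54 patients
  and share their gender; 12 sequencing dates and 10 plates assigned
  uniformly at random; clinical levels drawn at PTC-like frequencies
  (e.g. stage I/II/III/IV at 0.56/0.14/0.20/0.10).
- **Counts**: per-sample depth log-normal (median 5 × 10⁴ microbial
  reads, σ = 0.8); per-taxon base weights log-normal (σ = 1.2) with the
  archaeal block down-weighted ×0.1 (fungi dominate these data); counts
  negative-binomial with shape 2 (moderate overdispersion, standard for
  sequencing counts) around mean = weight × depth.
- **Contaminants** (default 20 slope / 10 plate / 10 date among 550
  taxa): slope archetypes draw a constant mean (~200 reads) independent
  of depth with tighter dispersion (shape 20 — reagent input is roughly
  constant); plate/date archetypes concentrate all reads on 2 random
  plates / 1 random date.
- **Planted effects**: cohort effects multiply the group's mean by
  2^logFC (default 34 taxa at |logFC| = 2 spread over the seven cohorts);
  a clinical effect shifts 3 of the tumor-overabundant taxa by 2² in
  stage III/IV tumors. Planted taxa are drawn from the 50th–80th weight
  percentile: prevalent enough to be testable, light enough that boosting
  them barely inflates sample totals (keeping relative-abundance fold
  changes near their nominal value despite compositional closure).
- **Expression block**: 1000 genes × tumor samples; 20 planted genes
  share a latent factor with the designated microbe's log abundance at
  target correlation 0.8; one planted gene set plus 5 random null sets.

Everything is reproducible from a single seed, including the files
written to disk. What passing tests on this generator show is that the
*procedures* recover known structure under the stated noise model; they
do not show robustness to features real data add — taxon–taxon
correlations, zero-inflation beyond the NB, batch effects entangled with
biology, mislabeled metadata, or reference-database misassignment.

## Problem sizes and numerical choices

The default simulated study is a ~20× scale-down of a full transcriptome
screen (550 taxa instead of ~10,000) so the complete pipeline runs in
seconds; validation studies use 500-taxon / 200-sample benchmarks for the
detectors, 200 all-null and 100 planted replicates at n = 100 vs 50 for
calibration and power, 500 random call tables for the partition law, and
1000 random instances for the enrichment-score oracle. p-values are
floored at the smallest positive float before Bonferroni multiplication;
detector shares of zero-count taxa are NaN and never flagged; an
all-flagged table empties with a hard warning rather than erroring.

## Known limitations

- The χ² reference for Kruskal–Wallis is a large-sample approximation;
  at very small group sizes exact-permutation p-values would differ.
- The date/plate detectors are share-concentration rules; gradual batch
  drifts that do not concentrate reads will not be flagged.
- logFC uses group mean relative abundances; compositional closure means
  a strong change in one abundant taxon slightly deflects every other
  taxon's logFC.
- No covariate adjustment, paired testing, count-model (e.g.
  negative-binomial GLM) differential abundance, or survival modelling.
- Enrichment reports no leading-edge subsets, and the FDR q inherits the
  known conservativeness/anticonservativeness trade-offs of the NES
  pooling convention at small set counts.
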