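# Methods

## Gene ranking

Input is a table of probe-level differential-expression p-values with two
columns per probe, one per normalization channel (MAS5.0-style and
RMA-style), per learning condition.  The chain is:

1. **Probe filter.** Probes without a unique gene target are removed (the
   count is logged).
2. **Fisher combination, per probe.**  X = −2(ln p₁ + ln p₂) is referred
   to χ² with 4 degrees of freedom — exactly two p-values enter, hence
   2·2 d.f.  P-values are floored at 10⁻³⁰⁰ before the log transform;
   the floor is logged when applied and exists purely to keep underflowed
   inputs finite.  The p-values are treated as two-sided significance of
   differential expression in either direction; no sign survives into the
   ranking.
3. **Simes collapse, per gene.**  Where several probes target one gene,
   the gene-level p is min over i of m·p₍ᵢ₎/i on the ordered Fisher
   values, capped at 1.  Simes is valid under independence or positive
   dependence of the probe-level values; with one probe it is the
   identity.
4. **Homology mapping.**  Source (rat) genes map to human identifiers via
   a HomoloGene-style group table.  Uniqueness is enforced in *both*
   directions by default — a source gene mapping to several human genes
   is dropped, and so is a human gene receiving several source genes —
   because one-directional filtering would let a single human gene be
   double-counted in the burden step.  One-directional mode is available
   (`bidirectional_unique=False`).
5. **Ranking and selection.**  Genes are ranked by combined p (ties broken
   lexicographically by gene id, making selection deterministic) and the
   top floor(fraction · N) genes form the gene set.  Floor is the
   conservative rounding choice.  Default fraction grid: 1, 2, 5, 10, 15,
   20, 25%, with 5% as the primary set.

## CNV processing

The `.cnv` dialect (FID IID CHR BP1 BP2 TYPE SCORE SITES; TYPE 1=deletion,
3=duplication) is 1-based inclusive; all interval arithmetic is performed
on 0-based half-open intervals after conversion at the parse boundary, and
length is end − start + 1 on the input convention.  The reliability filter
retains CNVs with length ≥ 100 kb *and* ≥ 15 supporting probes, both
thresholds inclusive and configurable.  Annotation attaches every gene
whose interval shares at least one base with the CNV (an
interval-tree query); a minimum-overlap-fraction option exists but
defaults to any overlap.  Deletion/duplication strata are disjoint views
of the same records.  Cohorts genotyped on different genome builds must be
annotated each against its own build's gene intervals before results are
merged on human gene identifiers; the package performs no liftover.

## Burden regression

One row per subject — including CNV-free subjects, who keep zeros rather
than being dropped, since excluding them would condition on CNV carriage.
Exposure `set_hits` is the number of *distinct* gene-set genes overlapped
by the subject's filtered, stratified CNVs.  Covariates: total CNV kb,
total distinct annotated genes hit, chip type and study (dummy-coded;
single-level factors are dropped with a log message).  The
"genes per CNV" covariate is read as a per-subject total because the
outcome is a subject property; a per-subject mean-genes-per-CNV column is
available as the alternative reading (`genes_per_cnv_mode="mean"`).
`total_genes_hit` counts genes from the full annotation while `set_hits`
counts ranking-universe genes only, since gene content of a CNV is a
property of the genome, not of the expression experiment.

The model is maximum-likelihood logistic regression (statsmodels Logit,
Newton), with a two-tailed Wald test on the `set_hits` coefficient by
default and a likelihood-ratio alternative (`test="lr"`).  Degenerate
inputs are flagged, never silently NaN: constant exposure, a single
outcome class, perfect separation and quasi-separation (standard error
above 10³) all return a non-estimable result carrying a diagnostic flag.
Bonferroni correction uses m = the number of gene sets in the family
(3 for consolidation/retrieval/extinction) by default; m is configurable
because the original family size is a judgment call.  Per-gene
attribution refits the same model with a single gene's carrier indicator
as exposure, deliberately uncorrected, as an exploratory ranking of
contributors.

## Permutation correction

Covariate adjustment does not remove all gene-set-agnostic burden signal
("background enrichment").  The empirical correction permutes the ranked
gene list (default 2000 times), takes top-fraction sets of the same sizes
from each shuffle — nested within a shuffle, so one permutation serves
the whole fraction grid — and refits the model for each.  Only the
exposure column changes between fits; per-subject hit counts against any
set come from a subject×gene hit structure computed once from the
annotated CNVs, never by re-annotating.  The empirical p is the plain
fraction of null fits with p as small or smaller (ties count); an
add-one (k+1)/(N+1) variant is available and logged when used.  "As or
more significant" compares two-tailed p-values regardless of direction by
default; a direction-respecting mode additionally requires the null Z to
be at least as extreme in the observed direction.  Non-estimable permuted
fits are dropped from the null with a logged count, and a profile is
flagged if more than 1% drop.  The reported statistic is
−log₁₀(P_emp) × sgn(Z), with P_emp floored at 1/N inside the log so an
empirical zero stays finite (the floor is logged); the profile table
keeps the unfloored value.

## Synthetic data generator

The generator emulates the *structure* of a compiled case-control CNV
resource and a two-channel microarray experiment, not any particular
dataset:

- **Genes**: non-overlapping intervals, lognormal lengths (median
  ~24 kb), at human-like density (~6.8 genes/Mb at the defaults of
  18 000 genes on 22 chromosomes × 120 Mb).
- **Probes**: 1–3 probes per gene; null probes draw two independent
  Uniform(0,1) p-values; signal genes (default 5%) share one latent
  normal effect (shift `signal_effect`, default 3) observed with
  independent channel noise, producing small, positively correlated
  p-value pairs — the situation of testing one contrast under two
  normalizations without modeling raw intensities.  A configurable
  fraction of probes targets no unique gene.
- **Homology**: each gene pairs with one synthetic source gene; a
  fraction is left unmapped and a fraction multimapped to exercise the
  uniqueness filters.
- **CNVs**: Poisson count per subject (default mean 1), lognormal lengths
  (median ~220 kb, safely above the 100 kb filter; the generator warns if
  configured below it), uniform placement, probe count =
  rate × length (min 1), deletion/duplication per a configured fraction,
  chip and study labels uniform over 3 levels each.
- **Phenotype**: drawn *conditionally on CNV burden* through a logistic
  model, logit P(case) = α + planted_log_or × (distinct planted-set genes
  hit), with α solved numerically (Brent) so the expected case fraction
  matches n_cases/(n_cases+n_controls).  This inversion makes the planted
  log odds ratio the literal estimand of the downstream regression.
- **Size confounding**: with factor f > 1, case CNV intervals are
  physically stretched by f *after* the phenotype draw, so cases hit more
  genes of every kind — the mechanism behind background enrichment.

Default cohort scale mirrors the motivating resource (11 917 cases,
16 416 controls, three studies); sizes, rates and effect magnitudes are
all configurable and every generator is byte-reproducible under a seed.
What the generator does **not** emulate: raw intensities, linkage
disequilibrium, recurrent CNV hotspots, locus clustering, gene-length
bias in set membership, ancestry structure.  Passing tests therefore
demonstrate the statistical machinery is correct and calibrated under
the stated model, not that any particular real-data finding would
replicate.

## Validation problem sizes

The test suite and `scripts/acceptance.py` run the simulations at a
scaled-down study size chosen to keep gene density, CNV size distribution
and probe rate at their full-scale values: 1200 genes on 6 × 30 Mb
chromosomes, cohorts of 1000 subjects (5000 for parameter recovery,
2500 for the end-to-end profile), and 100–200 permutations instead of
2000.  At these sizes: type-I error of the adjusted model sits inside
[0.03, 0.08] over 500 null cohorts; the mean recovered coefficient over
100 replicates is within 25% of the planted log 2 with power ≥ 0.8;
under 1.3× case CNV-size confounding the adjusted model stays ≤ 0.08
while the unadjusted model inflates severalfold; empirical p-values for
random sets pass a Kolmogorov–Smirnov uniformity check; and in the
three-condition end-to-end run only the planted-causal condition crosses
the 0.05 empirical threshold.

## Known limitations

- Uniform gene-list permutation, as specified; no gene-length or
  LD-matched nulls.
- Plain-fraction empirical p can be exactly 0; it is reported as 0 in
  tables and floored only inside the signed log statistic.
- No Firth or penalized regression: very sparse gene sets in small
  cohorts will flag separation rather than estimate.
- Genome builds are the caller's responsibility; annotate per build, then
  merge on human gene ids.
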