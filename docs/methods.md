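# Methods

## Study design and model

The package models a four-cohort bulk RNA-seq comparison — benign breast
lesions and ER+, triple-negative (TN), and HER2-positive tumors, eight
samples per group by default — in which the HER2 group is the target: a
feature (gene expression level, isoform proportion, or expressed variant)
is of interest only when it separates HER2 from *every* other cohort
simultaneously. The three feature lists are then treated as one candidate
gene set and interpreted through their mutual functional interactions
rather than gene by gene.

## Expression and splicing

**Normalization.** Library-scale differences are removed by mode
normalization: for each sample, the kernel-density mode (Gaussian KDE,
Silverman bandwidth, 512-point grid) of the log2 ratios against a per-gene
geometric-mean pseudo-reference, over genes nonzero in both; the sample is
divided by 2^mode. The mode, unlike the mean or median, ignores the
asymmetric tail contributed by genuinely differential genes. Whether the
original procedure used a pooled or single-sample reference is not
documented; the pseudo-reference variant is used and is validated only for
scale recovery (planted global scalings up to 8-fold recovered within 5%,
and re-normalizing an already-normalized matrix returns factors within 1%
of unity).

**Detection filter.** A gene is analyzable when its per-group median count
is strictly greater than 16 in at least one group; below that, counts are
at the detection limit. The same gate (plus ≥ 2 annotated isoforms)
defines eligibility for splicing analysis; the gate's exact scope for
splicing (per-sample vs per-group) is not documented and the group-median
rule is used for consistency.

**DTK comparisons.** All pairwise group contrasts use the
Dunnett–Tukey–Kramer procedure on mean log2(count+1): pairwise standard
errors from the two groups' own variances, Welch–Satterthwaite degrees of
freedom, and p-values from the upper tail of the studentized range with
k = 4 groups (scipy's `studentized_range`, accurate to well below the
1e-6 level at which the test suite pins it against R's `ptukey` and the
Welch t special case at k = 2). Log base 2 is chosen to match how such
data are conventionally displayed. Degenerate inputs: zero variance in
both groups gives p = 1 for equal means and p = 0 otherwise. An
`equal_var=True` mode implements the classical Tukey–Kramer special case
(pooled variance, df = N − k), which is what an independent equal-variance
implementation computes; the Welch mode remains the default. Confidence
intervals use the studentized-range quantile and are skipped
(`compute_ci=False`) in genome-wide screens, where only p-values drive the
calls — the quantile inversion dominates runtime otherwise.

**Group-specific call.** A feature is flagged iff all three HER2-vs-other
p-values are below alpha (default 0.05). No direction-consistency across
the three contrasts is required; the direction of HER2 minus the pooled
other-group mean is reported. The triple-test rule makes the empirical
type-I rate far below alpha under the global null, which the suite checks.
Splicing applies DTK to raw isoform ratios (not transformed); samples with
a zero isoform-total are dropped per transcript, and unequal group sizes
are handled natively by the procedure.

## Expressed-variant chain

Candidate sites come from a BWA-dialect mpileup; the confirming evidence
(strand balance, read-end position) comes from a TopHat-dialect pileup of
the same sample. Probabilistic genotyping is deliberately replaced by
deterministic threshold calling: with the published depth-4 /
ratio-0.1 / four-alternate-read filters in force, the thresholds dominate
any genotype-likelihood decision, and mapping-quality screening is
attributed to upstream pileup generation. Filters are conjunctive
predicates evaluated independently — each candidate records exactly which
filters it failed — so the surviving set is order-invariant and every
planted artifact class can be attributed to its designated filter.

Numerical/policy choices:

* Strand balance is symmetric (min/max of the two strand counts > 0.1,
  both ≥ 1), since the direction of the published ratio is ambiguous.
* The read-end window is 5 bases (configurable); a variant fails only when
  *every* alternate observation with a known offset is within the window,
  and passes with a flag when offsets are unavailable.
* Known-site matching is allele-aware by default; position-only matching
  (the behavior of common annotation tools) is available behind a flag.
* Coordinates: pileups and VCF are 1-based; refFlat exon bounds are
  0-based half-open and converted internally. Minus-strand transcripts are
  reverse-complemented before codon lookup; transcripts whose coding
  length is not a multiple of 3 are skipped with a warning.
* Cohort exclusivity counts passing calls only (default): low-confidence
  evidence in another cohort does not veto a target-exclusive variant. The
  permissive mode (any stored candidate vetoes) is available.
* Recurrence: a variant is recurrent with ≥ 2 high-confidence samples, or
  one high plus at least one low-confidence (2–3 alternate reads) sample.

## Network integration

The induced model keeps only candidate–candidate edges (linker genes
excluded), drops isolated candidates, upper-cases symbols, deduplicates
edges and removes self-loops. Integration is quantified as
(observed − null mean)/null SD over random same-size draws from the
expressed-gene universe (20 draws by default, sample SD with n−1; an
exhaustive mode enumerates all subsets on tiny graphs and is pinned
against a brute-force oracle). With SD = 0 the z-score is ±inf by sign.
Module detection is Louvain modularity maximization at resolution 1.0 with
a fixed seed; since the original clustering algorithm is unnamed, module
*count* is not treated as a reproducible quantity — only recovery of
planted partitions (ARI ≥ 0.9 on stochastic-block-model graphs) is.
Pathway enrichment is the one-sided (greater) Fisher exact test on the
[[m, N−m], [P−m, G−N−P+m]] table, identical to the hypergeometric upper
tail P(X ≥ m); one-sided is the correct enrichment reading and reproduces
the published table's printed values.

## Association layers

**Drug response.** Spearman rank correlation (midranks) with the two-sided
t-approximation p-value; "log-rank correlation against EC50" reduces to
rank correlation since ranks are invariant to the log. An exact
permutation p is available for n ≤ 8 and the t-approximation is verified
to stay within a factor of two of it. The random-panel simulation draws
panels of the observed size, counts significant genes sharing a single
annotation term, and reports the empirical probability of reaching the
observed configuration.

**Outcome.** Per-gene scores are univariable Cox partial-likelihood score
statistics at beta = 0 (U/√I, Breslow ties), vectorized over genes; the
implementation is pinned to R `survival::coxph`'s score test at 1e-6.
Gene set analysis uses the maxmean statistic — the larger in magnitude of
the mean positive part and mean negative part of the member scores — with
each score catalog (observed and permuted) restandardized by its own mean
and SD before the statistic is formed. Inference permutes the patient
outcome vector and propagates through the Cox scores; p-values are
two-sided permutation tails with the +1 correction, and FDR is the
permutation plug-in estimate (expected false positives over observed
positives at each threshold). For survival input the gene scores are
negated so that a negative set score means association with increased
relapse risk, matching the reporting convention of such analyses.

## Synthetic data: what it emulates and what it does not

The generators plant every signal class the pipeline is supposed to find
and every artifact class its filters are supposed to remove, with
deterministic output given the seed (a per-stream child generator per file
family). Defaults are the study conditions: 4 × 8 samples, 50 nt reads,
and otherwise a realistic recoverable regime chosen once — a 2-fold log2
DE shift, negative-binomial dispersion 0.15, a 0.4 isoform-proportion
switch, variant depths 20–60 at VAF 0.2–0.6, SBM communities at
p_within = 0.5 / p_between = 0.02, a log-hazard of 1 per SD of module
expression with 20% censoring. Counts are gamma-Poisson (single global
dispersion) with per-sample library factors so normalization is
non-trivial; isoform counts are exact multinomial splits of the gene
counts. Pileups carry a seventh column of per-read offsets (distance from
the nearer read end) so the end-bias filter is exercisable; read starts
(`^q`), ends (`$`) and indel markers appear in the base strings to
exercise the parser. Clean variants are constructed to clear every filter
(alternate depth ≥ 4, balanced strands, interior offsets), which is what
makes the precision = recall = 1.0 property meaningful as a correctness
check of the chain rather than a statement about real tumors.

Accordingly, passing tests demonstrate correctness of the decision rules
and statistics, not performance on real data: real RNA-seq has
gene-specific dispersion, GC and length biases, correlated genes,
alignment-dependent artifact mixtures, germline contamination without a
matched normal, and batch structure — none of which are modeled. Truth
files are written as side-car TSVs that the pipeline never reads.

## Scaling of shipped analyses

Test and acceptance runs use scaled-down problem sizes chosen to exercise
every code path with comfortable statistical margins: 120–200 genes for
DE/splicing cohorts, 8–12 true variants over 8–12 samples per variant
replicate (20–50 replicates), 300-gene interactomes, and 100–200
permutations / 10–40 replicates for the resampling-based checks. All
recovery margins (sensitivity ≥ 0.9, ARI ≥ 0.9, power ≥ 0.8) hold with
slack at these sizes.

## Known limitations

* Mode normalization depends on a unimodal log-ratio distribution; heavily
  perturbed samples (most genes shifted) would mislead it.
* DTK on raw ratios near the [0, 1] boundary can be anticonservative for
  tiny groups; ratio transformation is left to the user.
* The variant chain calls substitutions only (no indels) and cannot
  distinguish somatic from rare germline variation without a matched
  normal; the known-catalog filter is the only germline guard.
* The cohort-exclusivity rule is sensitive to cohort size: absence of
  evidence in small comparison groups is weak evidence of absence.
* GSA restandardization uses the catalog mean/SD rather than the full
  Efron–Tibshirani randomization moments; for the set sizes and score
  scales tested the permutation null is uniform (KS-checked).
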