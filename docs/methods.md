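# Methods

## Variant model and the filter cascade

A somatic missense variant carries read support in three compartments —
tumor DNA, tumor RNA and matched normal DNA — each as (alt count, depth),
plus a transcript-level protein-change annotation (1-based position,
reference and alternate residue). VAF is alt/depth; depth 0 makes VAF
undefined and is an error when queried directly. Inside the cascade an
uncovered tumor compartment simply fails the depth requirement, and an
uncovered normal cannot certify absence, so `normal_absent` fails.

The five criteria (binding, tumor_support, normal_absent, expressed,
not_germline) are evaluated per (variant, transcript) row with all
thresholds inclusive. Defaults: median percentile rank ≤ 2 %, tumor
depth ≥ 20× with VAF ≥ 0.10 at DNA and RNA level, normal depth ≥ 20× with
VAF ≤ 0.01, TPM ≥ 1 for gene and transcript, tumor DNA VAF ≤ 0.6. All are
configurable through `FilterConfig` / a JSON config file; candidate counts
are monotone in each threshold by construction (each predicate is a
single comparison), which the tests verify in both directions.

Aggregation choices that the criteria leave open:

- **Per-variant binding value.** The median percentile rank is computed per
  peptide across the predictor roster (sample median; mean of the two
  central order statistics for even counts), then the variant takes the
  *minimum* over its 8–11-mer windows — the strongest predicted binder
  represents the mutation, the permissive standard convention. Ties break
  toward the shorter window, then the smaller start coordinate.
- **Incomplete predictor coverage.** A peptide with fewer predictions than
  the configured roster (default 8) is scored on what is available, with a
  warning, rather than erroring.
- **Missing expression annotation** fails `expressed` with a warning; a
  partially annotated cohort degrades gracefully instead of aborting.
- **Multi-transcript mutations.** Each (variant, transcript) row is
  evaluated independently; a mutation is reported once, through its
  best-passing row (lowest best median rank, ties by variant id).

The funnel's intermediate "expressed" stage — the transcriptome
confirmation that shrinks the exome mutation list before the binding and
germline screens — uses RNA depth ≥ 20, RNA VAF ≥ 0.1 and *gene* TPM ≥ 1
(the transcript requirement belongs to the full criterion 4 only).

## Peptide construction

Window enumeration returns every distinct substring of lengths 8–11 that
lies fully inside the protein and covers the mutated position,
deduplicated on (sequence, length, offset) and sorted by (length, start);
an interior site yields exactly 8+9+10+11 = 38 windows, and the count
equals 38 iff the site is ≥ 10 residues from both termini. Proteins
shorter than 8 AA yield zero windows with a warning — an empty candidate,
not an error. The long vaccine peptide spans residues max(1, p−8) to
min(L, p+8): a 17-mer with the mutation centered at offset 8 whenever both
flanks fit, otherwise clipped to the protein bounds (a synthesizable
peptide must be a real subsequence; padding or discarding would either
fabricate sequence or lose a candidate). One MHC allele (default H-2Kb) is
modeled per run; it is a parameter, not a constant.

## ssGSEA

The single-sample enrichment score is the Barbie-style weighted running
sum. Per sample: genes are ranked by expression ascending with average
ranks on ties; walking genes from highest to lowest expression, the score
is Σ_i [P_in(i) − P_out(i)], where P_in accumulates rank^α (α = 0.25,
the conventional exponent) normalized by the total in-set weight and P_out
accumulates 1/(N − m) over out-of-set genes. Scores are therefore invariant
to any strictly increasing per-sample transform and to gene-row
permutation. Cross-sample min–max normalization is available behind a flag
but off by default — whether to normalize is a presentation choice that
does not affect ranks, correlations' signs, or median splits. CD8+ T-cell
infiltration is the ssGSEA score of {CD8A, CD8B}; CD4 infiltration is
deliberately the raw CD4 expression value (a one-gene "signature" would be
a monotone transform of the same numbers). Cluster signatures (e.g. an
antigen-presenting CAF or Treg score) take the top 20 markers by fold
change, ties at the cutoff broken alphabetically.

## Correlation and survival

Spearman correlation is the average-rank transform followed by Pearson on
ranks, with the t-approximation (n−2 df) p-value (scipy's
implementation, which is exactly that recipe); constant vectors are an
error, not NaN. The median split sends scores strictly above the median to
the high group and ties to the low group, keeping the low group the weakly
larger one deterministically; all-equal scores are a degenerate-split
error. Kaplan–Meier curves are product-limit estimates and the two-group
comparison is the standard log-rank chi-square with 1 df and no continuity
correction (lifelines). Times are in months; censored records carry
event = False.

## Synthetic data

The generator stands in for unreleased tumor/normal sequencing data and
public bulk cohorts. What it emulates — and what it does not:

- **Variant cohort.** `generate_variant_cohort(n_total, n_expressed,
  n_candidates, seed)` plants funnel counts exactly: candidates satisfy
  all five criteria by construction; expressed non-candidates each carry
  one planted violation cycled round-robin over binding / DNA support /
  normal contamination / transcript TPM / germline VAF, so every predicate
  path is exercised; non-expressed variants cycle over RNA depth / RNA VAF
  / gene TPM failures. Depths are uniform on 20–200× (violations dip to
  5–19×), target VAFs are beta(2,2)-shaped inside their admissible
  interval and then realized as integer counts clipped so the planted
  inequality holds *exactly* at the read level. Proteins are uniform
  random over the 20-letter alphabet, length 100–1000, one transcript per
  gene; peptide windows are kept globally unique across variants (a
  colliding protein is redrawn) so predictor ranks are unambiguous.
  Predictor ranks are uniform in [0.05, 1.9] for the planted best window
  and [2.5, 95] elsewhere, guaranteeing the median side of the 2 %
  threshold. No mutational-signature, homology or linkage realism: the
  cascade never inspects sequence content beyond the window predicates, so
  passing tests certify the selection logic, not predictor behavior on
  real proteomes.
- **Correlated expression.** A Gaussian copula over latent quantities (a
  gene, or one shared factor per gene set) with pairwise latent Pearson
  correlation 2·sin(πρ/6) — the exact Spearman→Pearson map for bivariate
  normals — pushed through exp() to non-negative levels. Gene–gene rank
  correlations hit the target in distribution; gene–signature correlations
  attenuate slightly (the ssGSEA score is a noisy monotone image of the
  set factor; member genes load with 5 % residual noise and the background
  is independent log-normal). The planted ρ = −0.5 at n = 500 is
  recovered within ±0.1, and its sign in ≥ 95 % of seeds at n = 178, the
  bulk-cohort size used throughout.
- **Survival.** Exponential event times (baseline median 20 months), arm
  B's hazard scaled by the hazard ratio; each subject is independently
  censored with probability `censor_rate` at a uniform time before its
  event, so the censoring fraction is exact in expectation and
  censoring is independent of arm.

A single seed fans out to per-table substreams via
`numpy.random.SeedSequence.spawn`, so adding one output table never
perturbs the others and identical (parameters, seed) give byte-identical
files.

## Immunoassays

ELISPOT positivity is strictly greater than the 500-spot threshold
(configurable); replicate averaging is left to the caller. Cytotoxicity is
the LDH formula applied verbatim; values outside [0, 100] % are returned
unclamped with an `out_of_range` flag, since out-of-range wells are a QC
signal. Fold change is 2^−ΔΔCt with the reference gene (e.g. GAPDH)
differenced within sample and control conditions.

## Numerical and testing notes

Problem sizes in the default test run and the acceptance script: the
study-scale funnel at n = 1164, the window oracle over 1000 random
(length, position) pairs including both termini and sub-8-AA proteins, the
filter oracle over 100 cohorts of 200 variants, log-rank calibration over
1000 null pairs (n = 50/arm, 20 % censoring) with power measured at hazard
ratio 3 over 100 seeds, and correlation recovery at n = 500 plus 100
sign-recovery seeds at n = 178. The whole suite runs in about two minutes
on one CPU. Oracles in the tests (brute-force substring enumeration, a
single-expression filter predicate, a naive running-sum ssGSEA, a
first-principles risk-table log-rank) are coded independently of the
library paths they check.

Known limitations: no real MHC binding predictors (a pluggable
prediction-table interface replaces them), no indel/frameshift/fusion
neoantigens, no clonality modeling, no proteasomal-cleavage or TAP
filtering, no Cox regression or multi-group survival comparison, and the
synthetic cohorts make no claim of biological realism beyond the planted
statistical structure described above.
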