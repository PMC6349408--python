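# Methods

This note documents the models and procedures implemented in
`txevents`, the choices made where the design was genuinely open, and
what the synthetic-data generators do and do not emulate.

## Coordinates and annotation model

All internal coordinates are 0-based half-open; GTF I/O converts
to/from the format's 1-based inclusive convention, and the conversion
is its own inverse at the boundary (tested). Interval arithmetic —
exact-coordinate exon identity, containment, unions — is simplest in
the half-open convention.

Transcript tags are read from repeated `tag` attributes in the
Ensembl GTF dialect and accumulated per transcript across feature
lines. This matters because the truncation flags (`cds_start_NF`,
`cds_end_NF`) are carried only there. Genes whose transcripts span
multiple chromosomes or both strands are rejected with a validation
error rather than silently split; duplicate transcript ids across
genes (as occur in pseudoautosomal regions) are likewise rejected.

## Truncation repair

A transcript end is considered truncated when the corresponding `NF`
tag is present or when the biotype is `retained_intron`,
`processed_transcript` or `nonsense_mediated_decay` (these mark both
ends, since such annotations frequently stop mid-exon). The repair
template is the gene's longest-spliced transcript among those tagged
`basic` (all transcripts when none is tagged; ties break to the
smallest transcript id).

Repair prepends (or appends) all template exons strictly beyond the
transcript's terminal exon and, when the terminal exon's outer
boundary falls inside a template exon, widens that boundary to the
template exon's edge. Internal exon boundaries are never altered, the
original chain is preserved as a subsequence, and the operation is
idempotent. If the template is itself truncated at the required end
the transcript passes through unchanged with an
`ExtensionSkippedWarning` — extension never trims. Repaired ends are
recorded with marker tags (`txevents_extended_start`/`_end`) so that
re-classification treats them as complete; this is what makes
"repair clears the truncation flags" well-defined for
biotype-truncated transcripts whose biotype cannot be rewritten.

## Transcript grouping

The grouping objective is the set of transcripts sharing the largest
number of exons with each other, where sharing means exact coordinate
identity of both boundaries — overlap-based sharing would make the
scaffold ill-defined. The search is greedy: seed with the transcript
pair of maximal exon-set intersection (ties: lexicographic ids), then
add every remaining transcript whose exon set contains that scaffold,
so the scaffold size is maximised first and the member count second.
Up to two groups are built; the second group repeats the procedure on
ungrouped transcripts, which handles genes with non-overlapping
transcript sets. Exhaustive search over all transcript subsets is used
as an independent oracle in the tests (the optimum over subsets of
size ≥ 2 is attained by a pair, since intersections shrink as members
are added); the greedy scaffold equals that optimum on all tested
random gene structures and can never exceed it.

## Event construction

Within a group, let `s_first`/`s_last` be the scaffold exons 5′-/3′-
most in transcript orientation. Each member's non-scaffold exons are
partitioned positionally: entirely 5′ of `s_first` → upstream
(promoter), entirely 3′ of `s_last` → downstream (3′ end), everything
else → contained (internal). An event is the scaffold plus the
member's variable exons of one type; events identical in exon chain
are deduplicated (representative: smallest transcript id) and an event
set is emitted only when at least two distinct structures remain —
singleton types are dropped because their relative usage would be
constant 1. On the minus strand "upstream" is the highest genomic
coordinates; building events on a coordinate-mirrored gene and
mirroring back reproduces the original event sets exactly (tested on
1000 random structures).

Because members always contain every scaffold exon, a member's
variable exon can never overlap a scaffold exon; exons lying between
scaffold exons are internal by the partition above, so constructed
promoter/3′-end events carry variation only outside the scaffold span.

## Masking

To prevent promoter and 3′-end events from tagging splicing changes,
each event of an upstream (downstream) set keeps only its terminal
variable exon — the exon that defines the alternative promoter (3′
end) — and every other variable exon position is replaced by the
interval union of overlapping exons across the set's events. After
masking, all events of a set are exon-identical outside their terminal
exons; the union (rather than deletion) preserves read-assignment
territory for quantification. Masking can merge events; deduplication
is re-applied and sets that collapse to one structure are dropped.
The operation is idempotent and is not applied to internal-exon
events. It can be skipped (`mask=False` / `--no-mask`) to discover
more associations at the cost of interpretability.

## Relative usage

Event TPMs are imported from per-sample quantifier tables
(`Name Length EffectiveLength TPM NumReads`) and normalised within
each (gene, group, event type) block and sample: usage = TPM / block
sum. Normalisation is separate per event type and per group, so a
value is always the share of one event among the alternatives built on
the same scaffold. Blocks with zero total TPM in a sample are
undefined (NaN) there and excluded pairwise downstream rather than
imputed — how zero-expression blocks were to be handled was an open
choice; undefined-and-exclude is the least inventive option.

The expression filter retains genes whose mean gene-level TPM exceeds
1 in at least one condition (strict inequality). Gene-level TPM is
approximated by summing the event TPMs of one block per gene (the
`contained` block when present, else the first available) — an
approximation to a count-based gene filter, documented here because
event TPMs are what this package has.

Before association testing, each feature is mapped through a
rank-based inverse-normal transform, `Φ⁻¹(r/(n+1))` with ties
averaged, giving mean-zero phenotypes that satisfy the normality
assumptions of the linear tests; constant features are flagged
undefined. The transform is optional but on by default.

## QTL mapping

The nominal pass regresses a feature on each variant's allele dosage
(0–2) plus covariates by OLS and reports the two-sided t-test p-value;
results agree with a reference least-squares implementation to 1e-8.
The permutation pass works per scope — one gene × event type, pooling
the two construction groups, so the empirical p-value is automatically
corrected for the number of alternative events tested. The observed
statistic is the minimum nominal p over (variants in ±100 kb of the
gene anchor) × (features in the scope); permutations shuffle sample
labels of all the scope's phenotypes jointly, preserving inter-feature
correlation, and the empirical p-value uses the pseudo-count
estimator `(1 + #{perm ≤ obs}) / (n_perm + 1)` — chosen over a
beta-tail approximation because it is simpler and exactly testable;
its floor is `1/(n_perm + 1)`. With covariates, phenotypes and
dosages are residualised once and the residuals are permuted. The
anchor is the 5′-most genomic position of the gene's exons,
strand-independent. Lead-variant ties break to the smallest position,
then the lexicographically smallest id. BH FDR is applied across
scopes. Conditional (secondary) association analysis is deliberately
not implemented.

Replication between two analyses is the fraction of query gene-level
leads (query pre-filtered to FDR < 0.01; gene-level lead = smallest
empirical p across the gene's events) whose reference lead for the
same gene has r² > 0.8 with the query lead. Genes absent from the
reference count as non-replicated by default (the conservative
reading; configurable). The measure is asymmetric by construction.

## Response QTLs

The interaction test compares, by maximum likelihood,

    H0: y ~ genotype + condition + (1|donor)
    H1: y ~ genotype + condition + condition:genotype + (1|donor)

and refers 2·(ll₁ − ll₀) to χ² with (conditions − 1) degrees of
freedom — one for the standard stimulated-versus-naive contrast (a
multi-condition generalisation is available but off by default). ML
rather than REML is used throughout so the LRT on fixed effects is
valid. Donors observed in only one condition are retained; the mixed
model handles unbalancedness.

The variance decomposition fits `y ~ (1|genotype) + (1|condition) +
(1|condition:genotype)` with genotype as an unordered three-level
factor of rounded dosages — this ignores the expected linear
allele-dosage relationship and is acknowledged as suboptimal, but the
ratio σ²_relative = σ²_int/(σ²_int + σ²_geno) built from it is an
effective filter for large effect-size differences; an additive-coding
alternative is provided behind a flag for sensitivity analysis.

Both models are fitted by direct maximum likelihood inside the
package (`lmm.py`): the random-intercept model by profiling the fixed
effects and residual variance out of the likelihood and optimising the
single variance ratio on a guarded 1-D grid-plus-Brent search
(Woodbury identities make each evaluation O(n)), the three-component
model by bounded L-BFGS-B on the exact Gaussian likelihood with
Cholesky factorisations and several starting points. Profiled and
bounded optimisation keeps the fits well behaved when a component sits
on the zero boundary, which happens routinely in null simulations;
both fitters reproduce lme4 (`REML=FALSE`) log-likelihoods, LRT
p-values and variance components to ~1e-4 on test fixtures, and the
zero-variance boundary falls back exactly to the fixed-effects model.

A candidate (pre-selected as significant at FDR < 10% in the
stimulated condition) is a response QTL iff its interaction-LRT BH FDR
within the condition is < 0.10 **and** σ²_relative > 0.5.

## Colocalisation filtering

Posterior tables computed externally (for running coloc upstream the
conventional priors are p1 = 1e-4, p2 = 1e-4, p12 = 1e-5) are
filtered by: PP3+PP4 ≥ 0.8 (the removal rule is "< 0.8", so the kept
set uses ≥); PP4/(PP3+PP4) > 0.9 (strict); no overlap with the GRCh38
MHC region 6:28,510,120–33,480,577 (1-based inclusive, compared
against half-open regions); minimal GWAS p < 1e-6 (strict). The
filter preserves order and is idempotent. Candidate regions for
colocalisation are 400 kb windows centered on lead variants that lie
within 100 kb of a GWAS variant with p < 1e-5.

## Synthetic data

`simulate.make_gene` lays out core exons left-to-right with random
lengths (defaults: exons 80–200 bp, introns 200–1000 bp — compact but
plausibly shaped gene structures), gives each transcript optional
alternative first/last exons (placed wholly outside the core span),
one skipped internal exon, and whole-exon truncations with the
matching `NF` tag; minus-strand genes are built by mirroring the
layout. The generator returns a ground-truth record — computed by
independent tuple-set arithmetic, including the effect of repair and
mask-induced merges — of exactly which event sets the builder must
produce; generator truth and builder output agree on thousands of
random structures. What it does not emulate: partial-exon
truncations, overlapping genes, unannotated (novel) transcripts, and
annotation errors, so passing tests show correctness of the
construction logic, not robustness to mis-annotation.

`simulate.simulate_usage_qtl` plants a per-allele usage shift on one
event: target usage = baseline + dosage·shift (+ optional Gaussian
noise, clipped to [0, 1]), with the other events sharing the
complement proportionally to their baselines so usage sums to one by
construction; TPM = usage × gene TPM. Defaults follow the canonical
scenario: n = 84 samples (the size of a typical stimulated-macrophage
QTL panel), MAF 0.3, shift 0.10 on the second of two events with
baseline (0.7, 0.3), gene TPM 100. With zero noise, OLS recovers the
shift exactly. Dosages are Hardy–Weinberg binomial draws, re-drawn if
constant. No LD structure is simulated; "null" variants are
independent draws.

`simulate.simulate_conditions` draws paired two-condition phenotypes
per donor as a sum of independent effects: donor (default variance
0.5 — moderate repeatability across conditions), condition (0.5),
genotype (per-level effects matching the fitted factor model; an
additive mode exists for the sensitivity flag), genotype×condition
interaction, and residual (1.0), with 40 donors by default. The donor
component is present in the generator but absent from the fitted
variance-component model, as in the real analysis setting; it is
largely absorbed by the residual and the genotype component, which is
why recovered σ²_relative under matched genotype/interaction variances
averages slightly above 0.5 rather than exactly 0.5.

## Problem sizes used in tests and the acceptance script

The test suite exercises 1000 random gene structures for the
construction oracles, 500 null scopes (n = 84, 1000 permutations) for
permutation calibration, 1000 replicates of 40 donors × 2 conditions
for LRT type-I error, 100 × 200-scope null scans for the
FDR-discovery check, 100 planted-QTL simulations for power, and
500/200 replicates for σ²_relative recovery. The acceptance script
repeats the same computations at moderately smaller replicate counts
(300 genes, 300 scopes, 500 LRT replicates, 40 × 200-scope scans,
60 power simulations, 200/100 variance-component replicates) — sizes
chosen so a full run completes in a few minutes on a single CPU while
keeping Monte-Carlo error well inside the decision margins.

## Known limitations

- Exon sharing is exact-coordinate; transcripts differing by a single
  splice-site shift share nothing at that position, which can shrink
  scaffolds in heavily annotated genes.
- The greedy grouping is a heuristic; optimality is checked against
  exhaustive search only on small random structures.
- The expression filter approximates gene-level TPM from one event
  block.
- The permutation scheme residualises covariates once rather than
  refitting within each permutation (exact only under the null of no
  covariate–genotype dependence).
- Empirical p-values are lower-bounded by 1/(n_perm+1); very small
  FDR thresholds need correspondingly many permutations.
- No LD-aware fine-mapping, no trans-QTLs, no mixed-model population
  structure correction, no GC-content (cqn) normalisation.
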