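# Methods

## Problem and model

`varsieve` implements a consensus pipeline for calling nonsynonymous
SNPs (nsSNPs) pathogenic and prioritizing them to a short list of
high-confidence candidates. The core statistical object is a k-of-n
voting classifier over five functional-effect predictors (SIFT,
PolyPhen-2, Condel, PROVEAN, PANTHER). For a variant with significant
calls s out of the five tools, model X ∈ {A, B, C, D} predicts
*deleterious* iff s ≥ k(X), with k(A..D) = 1..4. The X3 variants add
two conjunctive gates: the residue must be evolutionarily conserved
(ConSurf grade ≥ 7) and the mutation must be predicted to decrease
protein stability. Model performance against a labeled standard
dataset is summarised as

- Se = TP/(TP+FN) × 100%
- Sp = TN/(TN+FP) × 100%
- Ac = (TP+TN)/(TP+TN+FP+FN) × 100%

computed with exact rational arithmetic; an empty class yields an
explicit undefined marker, never 0 or 100. Display rounding
(half-to-even, one decimal) happens only at output.

## Per-tool significance thresholds

| tool | significant | notes |
|---|---|---|
| SIFT | score ≤ 0.05 | inclusive by default; strict `<` by config. |
| PolyPhen-2 | score > 0.9 | the "possibly damaging" band is *not* significant. |
| Condel | score > 0.5 | a score-of-exactly-1.0 rule is selectable but unusable for a continuous score, so > 0.5 is the default. |
| PROVEAN | score ≤ −2.5 | inclusive, matching the tool's published convention. |
| PANTHER | PSEP > 450 My | "possibly damaging" (200–450 My) is *not* significant. |

Categorical labels map onto the same calls (Del/Del_low_con,
Prob_dam, etc.); `_low_con` suffixes keep the base call and carry a
low-confidence flag as metadata. When a score and a label are both
present and disagree, the score wins by default (`prefer="label"`
flips this): labels are quantized scores and carry less information.
An output with neither score nor label is a *missing* call, which is
distinct from a non-significant one.

## Missing-data policies

The vote denominator is always five tools. Three policies interpret
missing calls:

- **strict** (default): missing is no evidence; the variant needs
  k significant calls out of all five. Chosen as default because the
  reference benchmark's confusion-table denominators are fixed at the
  class sizes, implying every variant received a binary decision.
- **permissive**: missing counts as significant (an upper bound on
  the vote).
- **fraction**: the threshold rescales to the available calls,
  s/(5−m) ≥ k/5, evaluated in integer arithmetic; a variant with all
  five calls missing is benign (no evidence).

Under every policy the models nest: the deleterious set of model k+1
is a subset of model k's, and X3 ⊆ X. The test suite checks this on
the packaged candidate set and on 1,000 random profiles, and checks
the engine against an independent brute-force counter over all 3⁵
call-state combinations.

In benchmark evaluation, an X3 decision of *not evaluated* (missing
conservation/stability evidence) is counted as a benign prediction so
that TP+FN and TN+FP stay fixed at the class sizes; cascade traces
still report the state separately.

## Prioritization cascade

Stages run in order, survivors nested; a failure at stage j leaves
later stages not evaluated:

1. **consensus** — the configured model (default D, strict) calls the
   variant deleterious. Skippable (`consensus_model=None`) when the
   input is already a consensus-selected set.
2. **conservation** — ConSurf grade ≥ 7. On the packaged candidate
   set this gate is pass-through (all grades are 8–9) but it is still
   enforced as part of the workflow.
3. **stability** — predicted stability *decrease* AND reliability
   index ≥ 5. The gate deliberately keys on the predicted direction
   rather than the ΔΔG class: a −0.48 kcal/mol decrease (neutral by
   the ±0.5 ΔΔG convention) passes the direction test and is excluded
   only by its RI of 0. A ΔΔG-class gate is available by
   configuration.
4. **structure** — the mutant homology model keeps the native fold:
   TM-score > 0.5 and RMSD < 6.5 Å (both bounds strict).

MutPred2 (pathogenic iff score ≥ 0.5; hypothesis tiers actionable /
confident / very confident at g > 0.5, p < 0.05 / g > 0.75, p < 0.05 /
g > 0.75, p < 0.01) and ModPred PTM confidence (< 0.7 low, ≥ 0.7
medium, ≥ 0.9 high by default; a coarser > 0.5 = high scheme by
configuration) annotate the final shortlist and never eliminate from
it.

On the packaged eight-candidate evidence set the cascade yields
8 → 8 → 6 → 3, with shortlist {rs10936600, rs757978, rs1126809}.

## Dataset construction and cohort matching

The catalog filter keeps association rows whose trait contains any of
seven keywords (cancer, carcinoma, glioma, leukemia, lymphoma,
melanoma, sarcoma) as a case-insensitive substring; substring rather
than word-boundary matching is the default because compound tumour
names ('leiomyosarcoma') are intended hits. Rows deduplicate on
(rsid, trait) — the same variant under two traits is two
associations. Consequence strings map onto a closed enumeration;
unknown spellings raise rather than default. Coordinates are 1-based
GRCh37 throughout and VCF positions are consumed as-is.

Cohort matching streams VCF v4.x (cyvcf2), splits multi-allelic
records, takes site depth from INFO/DP (falling back to summed
FORMAT/DP), and applies the quality filter DP ≥ 5 and QUAL ≥ 30 —
inclusive bounds, since the stated exclusions are "less than" both
values. Records missing DP or QUAL fail closed by default. A dataset
variant matches when a passing record at its chrom+pos shows the
alternate allele in at least one sample (the rsID column is the
fallback when coordinates disagree); when the dataset row names a
risk allele, only that alternate counts. Allele frequency is the
alt-allele count over non-missing called alleles.

The published cohort-specific match counts (52 of 80, 43 + 43 by
population) require the underlying whole-genome VCFs and are not
reproducible from printed tables; the matcher is validated on
simulated cohorts instead.

## Synthetic data

`generate_benchmark` emulates a 50 pathogenic / 50 benign clinical
validation set. Each tool's score is drawn from a two-region mixture
on that tool's own scale: with probability `separation` the score
falls in the region agreeing with the truth label, otherwise in the
opposing region. `separation` is thus the marginal per-tool accuracy;
its default of 0.85 puts the generator in the regime where models A–D
visibly trade sensitivity for specificity, and 1.0 gives a fully
separable dataset every model classifies perfectly.
Conservation/stability/structure evidence follows the same
agreement-probability scheme. One seed fans out through
`numpy.random.SeedSequence.spawn` into per-tool substreams, so adding
a tool leaves the other tools' draws unchanged.

`generate_vcf` draws diploid genotypes from Hardy–Weinberg
proportions at per-site allele frequencies and draws site DP/QUAL so
that a configurable fraction of sites fails the quality filter (half
by depth, half by quality); it emits VCF v4.2 text plus a truth table
of which sites a matcher should recover.

What the generators do **not** emulate: linkage between sites,
correlated errors between predictors (real tools share training data
and alignments, so their errors are far from independent), realistic
score distributions within regions (uniform is used), sequencing
error profiles, or population structure. Passing tests on synthetic
data therefore demonstrate the correctness of the voting, metric and
filtering machinery — not the real-world accuracy of the external
predictors.

## Packaged reference tables

The published printed tables ship as TSV package data with a sha256
manifest checked at load: the per-model benchmark confusion counts,
the cohort candidate variants with per-tool labels, and
conservation/stability/structure/annotation evidence for the eight
high-risk variants. The candidate table's printed source lists 52
rows of which 48 are recoverable from the available text and
transcribed (all eight high-risk variants among them); tests pin the
count at 48. Two printed MutPred scores differ between the source's
prose and its table (0.78/0.73 vs 0.74/0.70); the table values are
recorded.

One known irreproducibility is documented rather than patched: under
the printed labels, rs3124765 has three significant calls with
PANTHER missing, the same structure as rs671, yet only the former is
listed in the published eight-member high-risk set. No consistent
label-level rule separates them. Strict model D recovers seven of the
eight; the test suite asserts ≥ 7-of-8 recovery and that no selected
variant has fewer than three significant calls.

## Numerical and design choices

- Exact arithmetic (`fractions.Fraction`) for metrics; integer
  arithmetic for the fraction policy's threshold comparison — no
  float ties.
- Boundary semantics are spelled per threshold above; all are tested
  at the boundary.
- Undefined metrics propagate as `None`, and serialize as nulls.
- The consensus engine is exposed both as functions and as a
  scikit-learn estimator (`ConsensusClassifier`); the estimator is
  rule-based, so `fit` only validates input and records `classes_`.
- Problem sizes in the test suite (50/50 benchmarks, 1,000-profile
  property sweeps, 40-site simulated cohorts) are chosen to exercise
  every code path with stable statistics while keeping the whole
  suite in seconds.

## Known limitations

- The external predictors themselves are out of scope; the package
  consumes their scores/labels and never recomputes them.
- Only diploid GT-based allele frequencies are supported.
- The fraction missing-data policy has no published reference values;
  it is validated against the brute-force oracle only.
- Homology modeling, docking, model QC and interaction-network
  analysis sit outside the package boundary; TM-score/RMSD are
  consumed as given.
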