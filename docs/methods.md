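# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmark does and does not establish.

## Sequence auto-covariance encoding

A sequence of length L is mapped, per physicochemical scale j, to the
lag-d auto-covariance of the per-residue property values around the
*sequence* mean, for d = 1..30. The seven scales (hydrophobicity,
hydrophilicity, side-chain volume, polarity, polarizability,
solvent-accessible surface area, net charge index) ship as a fixed
resource table of standard published amino-acid indices
(`seq_features._RAW_SCALES`) and are standardized to zero mean / unit
SD over the 20 residues before use. Standardization makes the encoding
invariant to affine changes of the raw tables, so the pipeline does
not depend on the units of any particular index compilation — the
trade-off is that absolute AC magnitudes are not comparable to
implementations that use un-normalized tables.

Choices worth knowing:

* **Ambiguous residues** (B, Z, X, U, O) map to the scale mean (0
  after standardization): a neutral contribution rather than a dropped
  position.
* **Pair order.** The 420-dim pair vector concatenates the two 210-dim
  vectors in lexicographic id order, making the representation
  well-defined for unordered pairs.
* **Minimum length.** The encoder requires L > max_lag (= 30). The
  benchmark filter separately removes proteins under 50 residues;
  sequences of 31–50 residues are encodable but never enter training.
* **Finite-sample bias.** Because AC centers on the empirical sequence
  mean, its expectation for an i.i.d. sequence is −σ²/L, not 0 (the
  classic sample-autocovariance bias). The property tests assert this
  exact finite-sample value.

## GO semantics

Information content is corpus-based: IC(t) = −log(fraction of
annotated proteins whose propagated annotations include t); roots get
0, terms unseen in the corpus get an +inf sentinel and are excluded
from common-ancestor searches (similarity involving them is 0). Term
similarity is Lin's measure, 2·IC(MICA)/(IC(t1)+IC(t2)); FunSim
between two proteins is the mean over all cross term pairs of their CC
annotations ("all-pairs average" — best-match averaging is a known
alternative and the measure is a single pluggable function). Predicted
annotations participate only above a confidence threshold (default
10000, strict), experimental ones always.

The association scores IAS / CAS / PAS share one estimator: a
pointwise-mutual-information log2-odds of two terms co-occurring in a
corpus of events, with pseudocount 1. What differs is the corpus —
interacting protein pairs (IAS), per-gene annotation sets (CAS), or
per-document term sets (PAS). A protein pair's score aggregates over
all cross term pairs (sum by default; mean and max are available).
Because the scores are corpus-relative, absolute tier thresholds
(e.g. IAS > 200) are meaningful only against a fixed precomputed
table; the tiering thresholds are therefore configuration, not
constants.

## Profiles and co-expression

Profile similarity is the cosine of nonnegative bit-score-ratio
vectors (best-hit ratios are assumed; the BLAST searches themselves
are upstream of this package). All-zero profiles yield NaN
("undefined") rather than 0. Mutual rank excludes the gene itself from
its ranking and averages tied ranks, which makes MR symmetric, ≥ 1,
and attainable at exactly 1 for reciprocal best partners. Precomputed
(ATTED-style) tables take precedence over matrix-derived values;
missing co-expression is carried explicitly as NaN and routes a pair
to the 4-feature forest rather than being imputed.

## Benchmark construction

Positive-pair filtering (length ≥ 50, physical evidence only,
deduplication) logs a drop count per rule, since benchmark bookkeeping
is count-based. Negatives: "loc" samples uniformly among pairs with
disjoint localization sets (proteins without labels are ineligible);
"rand" samples pairs from the positive set's protein universe
excluding positives. Both schemes return exactly one negative per
positive. Global identity is Needleman–Wunsch (match +1, mismatch 0,
linear gap −1 by default; configurable) with identity defined as
matches / alignment length including gap columns — the stricter of the
two common denominators. Redundancy pruning is a deterministic greedy
pass in input order: a pair survives only if neither protein exceeds
the identity cutoff against any protein already kept; lowering the
cutoff can only shrink the survivor set. Folds are stratified 6-fold
with a seeded shuffle.

## Learners and evaluation

The SVM branch is a StandardScaler + RBF-SVM pipeline (scaler fitted
on training folds only). Hyperparameters are selected by an inner
5-fold grid search over log2 C ∈ {−5..15} and log2 γ ∈ {−15..3}
(step 2) maximizing accuracy; the published operating points
(log2 C = 5, log2 γ = −1 for loc; 1, 1 for rand) are kept as
documented defaults but any new dataset gets its own selection — on
420 standardized dimensions a γ of 2^−1 collapses the RBF kernel
(every test point is far from every training point), which is why
selection, not the literal constants, is the protocol. ε- and
ν-regression variants are provided for score-based comparisons; their
outputs threshold at 0.5 for binary use.

The forest (500 trees by default, seeded) reports probability as the
fraction of trees voting positive — ties at exactly 0.5 classify
negative — and two importances: MDA (mean accuracy decrease over 10
seeded permutations of each feature) and MDGI (impurity-based).
Metrics come from explicit confusion counts; AUC is the trapezoid area
under the ROC curve and is verified in the tests against the
Mann–Whitney U identity. Nested cross-validation evaluates each outer
fold exactly once with hyperparameters chosen on the remaining folds;
a label-shuffling test confirms selection never sees held-out labels.

## Consensus and tiering

The CC pre-screen keeps pairs with FunSim strictly above 0.4 and drops
(with counts) pairs lacking usable CC annotation. Consensus is the
conjunction of the two branch decisions. Tier 1 requires RF
probability ≥ 0.95, an association-database score > 900 and at least
one further evidence flag; tier 2 exactly one flag; tier 3 no external
evidence but RF probability 1.0, IAS > 200, PAS > 20 and profile
similarity > 0.9. All thresholds are configurable (per-genome
overrides are expected — e.g. 0.9 instead of 0.95 for a sparser
proteome). Candidates are an explicit list; all-vs-all enumeration at
proteome scale is the caller's decision.

## Network analysis

The degree exponent is the negated slope of an ordinary least-squares
fit of log10 frequency on log10 degree over observed degrees —
sub-1 exponents reported for real plant networks are characteristic of
this estimator, which is why it is the default; a Clauset-style
discrete MLE (accurate for k_min ≳ 6) is available as an alternative.
Degree-0 proteins do not appear (only proteins in edges have
degrees). The configuration-model generator used in recovery
simulations draws degrees from a truncated power law with the standard
structural cutoff k_max = √n, keeping multi-edge/self-loop losses
small; with that cutoff the OLS estimator recovers γ = 2.0 within
±0.25 on every tested seed at n = 5000.

## The synthetic organism

`phytoppi.synthetic` generates proteins organized into 4-member
modules (complex-like groups). Module members share: a low-complexity
dipeptide-repeat segment drawn from a pool of four families (the
sequence branch's learnable signal), a module CC term with probability
`funsim_boost` (plus their compartment's CC term always, with a small
rate of extra random CC terms), expression driven by a shared
per-module factor giving pair correlation ≈ `coexpr_rho` on both
platforms (a fraction `1 − coexpr_coverage` of genes is omitted per
platform to exercise the missing-data path), phylogenetic presence
patterns copied per genome with probability `profile_overlap`, and
co-occurrence of module terms in a toy literature corpus. Defaults:
400 proteins, 400 planted pairs, coexpr_rho 0.8, profile_overlap 0.9,
funsim_boost 0.8, 100 reference genomes, 50 samples per platform.
These sizes keep the full test suite and the acceptance script within
a few minutes on a single CPU while leaving enough data for the
classifiers to be non-trivial.

What passing tests on this organism show: that the encoders compute
their definitions, that the training protocol is leak-free, and that
the *architecture* behaves as designed — the sequence SVM generalizes
but over-calls on random negatives, the functional forest is
conservative, and their intersection attains the forest's precision
(≥ 0.9 with ~0.9 recall at the default signal strengths). What they do
not show: performance on real proteomes. Real sequence signals are not
shared repeat segments, real GO DAGs are far deeper than the toy
ontologies, and real co-expression compendia have structured (not
factor-model) covariance; absolute accuracies on this benchmark
therefore do not transfer.

## Known limitations

* FunSim uses all-pairs averaging; best-match variants can rank pairs
  differently for proteins with many annotations.
* The association-score estimator is corpus-relative; scores from
  different corpora (and hence tier thresholds) are not comparable.
* The greedy identity pruning is order-dependent by design
  (deterministic for a fixed input order), not a globally optimal
  clustering.
* The log-log OLS exponent is a descriptive fit; for inferential work
  on heavy tails use the MLE variant with an explicit k_min.
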