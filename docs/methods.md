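# Methods

## The selection problem

One QSAR dataset is a (compounds × features, bioactivity) pair for a single
protein target; a *workflow* is a (learner, representation) combination.
The package casts "which workflow should model this target?" as supervised
learning at the meta level: the inputs are measurable properties of the
dataset and of the target protein, the response is either the identity of
the best workflow (classification) or the full vector of workflow RMSEs
(ranking). Everything below documents how each stage is defined, which
knobs matter, and what the synthetic testbed does and does not demonstrate.

## Base-level benchmarking

**Protocol.** Every compatible (target, workflow) pair is scored by the
mean over 10 cross-validation folds of the per-fold RMSE. Fold assignment
is one seeded shuffle per *target*, shared by all workflows and all
representations of that target. The shared assignment is a deliberate
convention: downstream Friedman and Wilcoxon tests treat workflows as
paired observations per target, which is only clean if they saw identical
splits. A workflow that raises on any fold is recorded as failed for that
target (structurally missing): it can never win, is ranked worse than every
observed workflow, and is excluded from rank statistics for that target.

**Registry.** Learner settings are fixed once for the whole collection —
no per-dataset tuning. Tree and forest learners use 500 trees with
minimum-split 20 and minimum-leaf 7; boosting uses 100 depth-1 trees;
nearest-neighbour regression uses k=1; the RBF support-vector machines use
nu=0.2 with standardized inputs and C=10 (a setting that behaves well
across the activity scales the generator produces); the two-layer network
sizes its hidden layers to 1/3 and 2/3 of the input dimension at fit time.
Four learners of the registry have no exact scikit-learn counterpart and
are realised as documented nearest equivalents: conditional trees/forests
as variance-split CART with the same node-size settings, adaptive
regression splines as a spline-basis expansion followed by ridge
regression, the relevance vector machine as RBF kernel ridge, and
response-surface regression as a degree-2 polynomial ridge. The Tanimoto
SVM is implemented in-package as support-vector regression on a precomputed
Tanimoto (Jaccard) kernel, with the 0/0 similarity of two empty
fingerprints defined as 1.

**Scores.** The aRMSEr score averages, over all opponents q (including the
self term, which contributes exactly 1 and keeps the printed divisor m),
the geometric mean over targets of the RMSE ratio RMSE_q/RMSE_p. Products
are computed as sums of logs. When a pair of workflows is defined on
different target subsets, the geometric mean runs over their common
targets. Consequences worth knowing: the score is invariant to rescaling
all workflows on any one target, and it is *not* a linear functional of
RMSE — a workflow can have the best mean RMSE but not the best aRMSEr.
Excluding the self term is available behind a flag.

**Friedman + Nemenyi.** The Friedman statistic uses mid-rank ties with the
tie-corrected denominator (it agrees with `scipy.stats.friedmanchisquare`
on tie-free blocks); the p-value is the chi-square tail with k−1 degrees of
freedom. The Nemenyi post-hoc compares mean-rank differences against the
critical difference `q_α √(k(k+1)/6n)`, with q_α from the studentized range
distribution at infinite degrees of freedom. The chi-square approximation
is what the type-I calibration test exercises: under an exchangeable null
(20 targets × 4 workflows, 1000 replicates) the rejection rate at α = 0.05
sits near the nominal level.

## Preprocessing conventions

* **Consensus activity.** Multiple reported activities for one
  compound–target pair collapse to the median of the values in the modal
  unit-width log bin. Bins are anchored at integers (…[4,5), [5,6)…); when
  two bins tie for the mode, the bin containing the global median wins,
  then the lower bin. Anchoring and tie handling are conventions — the
  underlying rule does not specify them — and both are fixed and tested.
* **Imputation.** Missing descriptor cells are replaced by the per-column
  median of observed values; the operation is idempotent and a fully
  missing column is an error rather than a silent zero. Fingerprint tables
  are complete by contract and never imputed. The unimputed descriptor
  variants can be materialised for inspection but are excluded from
  benchmarking.

## Meta-features

**Dataset meta-features** (prefix `ds_`, plus `fp_agg_` for the aggregated
fingerprint). Information-theoretic quantities are plug-in estimates in
nats on nominal variables: fingerprint bits are nominal as-is; the
continuous response is made nominal by equal-frequency binning into
⌈√n⌉ bins (minimum 2). `mutualinfo` is the mean over bits of MI(bit,
binned response); `multiinfo` (total correlation) is Σ H(X_j) − H(joint)
over a seeded random subset of 8 bits, because the joint entropy over all
bits is intractable and any fixed small subset would be arbitrary.
`nentropyfeat` divides the mean bit entropy by log(number of features),
taken literally; normalising by log(number of levels) instead is available
behind a flag, and the response entropy uses the level-count denominator so
it stays in [0, 1]. Feature moments (`mmeanfeat`, `msdfeat`) are computed
on the all-descriptor table ignoring missing cells; response moments use
population (biased) conventions with kurtosis as the plain fourth
standardised moment (3 for a normal), not excess-corrected. The aggregated
fingerprint is the per-bit fraction of compounds with the bit set.

**Target meta-features** (prefix `tg_`). Aliphatic index uses the
mole-percent formula X(A) + 2.9·X(V) + 3.9·(X(I)+X(L)). The Boman
(protein-interaction) index is the mean residue solubility value, kcal/mol
per residue. Hydrophobicity is reported as the sequence mean on each of 38
published per-residue scales compiled into a registry in
`metafeatures/scales.py`; the registry is content-hashed
(`registry_checksum`) so a feature set can be tied to the exact values that
produced it, and callers may substitute their own registry. Net charge is
the Henderson–Hasselbalch sum over ionisable side chains (D, E, C, Y, H, K,
R) and both termini with the EMBOSS pKa set (switchable); it is strictly
decreasing in pH, so the isoelectric point is found by bisection on
[0.1, 13.9] to 1e-4. The instability index uses the Guruprasad
dipeptide-weight table as shipped with Biopython ((10/L)·Σ over adjacent
pairs; values below 40 predict a stable protein), and molecular weight uses
Biopython's average masses, water-corrected. Dipeptide composition is the
400-vector of adjacent ordered-pair counts divided by L−1. All target
features are case-insensitive and composition/adjacency-based; non-canonical
residues are rejected with the offending symbols named.

**Groupings.** The six-level class hierarchy is a labelled tree under a
virtual root; the distance between targets is the edge count of the unique
tree path between their leaves (12 for full-depth leaves in different
level-1 classes). Preferred-name groups are equivalence classes of the
curated name; only groups of size ≥ 2 are reported as groupings, but the
name is retained as a per-target feature. Class-path levels and the
preferred name enter the meta-dataset as categoricals and are one-hot
encoded inside each estimator with encoders fitted on training folds only
(unseen labels encode to all-zeros), so no label vocabulary leaks across
cross-validation folds.

## Meta-learners

All three families are scikit-learn-style estimators fitted as
`fit(M, R)` with the meta-feature frame and the targets × workflows RMSE
frame. Numeric features are median-imputed; k-NN additionally z-scores them
(training-fold statistics) before Euclidean distances — the meta-features
mix units spanning several orders of magnitude, so unscaled distances would
be dominated by molecular weight.

* **Selector.** Random forest, 500 trees. For top-k variants the label
  space is the k workflows with the best *training* aRMSEr; training
  targets whose winner is outside the set are relabelled to their best
  in-set workflow. Deriving the set from training folds only costs a little
  fidelity to a global ranking but avoids selection leakage.
* **k-NN ranker.** Workflows are ordered by the mean of their within-target
  mid-ranks across the k nearest training targets. Ranks, not raw RMSEs,
  are averaged so targets with different RMSE scales contribute equally.
  Missing (failed) entries share the worst rank. With k equal to the
  training size the ranking is the same for every query.
* **Multivariate RF ranker.** One 500-tree forest jointly regresses the
  full RMSE vector; the recommendation is the ascending order of predicted
  RMSEs. Missing training RMSEs are imputed pessimistically (column worst
  plus 10% of its range) so a failed workflow is never predicted
  attractive.

Meta-level evaluation is tenfold cross-validation over targets: the
selected workflow's *realized* RMSE is looked up from the benchmark matrix;
rankers that select an unobserved workflow fall back to their next-ranked
observed one. Method-vs-default comparison uses the Wilcoxon signed-rank
test on paired per-target differences — the design is paired, so the
signed-rank test is the default and the unpaired rank-sum variant is
available behind a flag. Meta-feature importance is permutation importance
(mean decrease accuracy) of the fitted all-class selector on its training
data, summarised by feature group.

## The synthetic testbed

The generator emulates the *structure* of a curated bioactivity corpus —
per-target compound tables of varying size (default 80–300 compounds, full
range 10–6000), a binary fingerprint table (complete), continuous
descriptor tables with ~5% missing cells (basic = a column subset of all),
a six-level class hierarchy, class-biased protein sequences, and
preferred-name groups — not its chemistry. There are no molecules: nothing
is a valid structure, descriptors are Gaussian with per-target location and
scale, and fingerprint bits are independent Bernoulli draws with per-target
Beta(0.9, 3) probabilities (so aggregated-fingerprint meta-features vary
between targets).

Activities are generated on a log-potency scale (intercept ~U(5.5, 7),
signal standardised to unit spread, Gaussian noise of 0.5 log units —
the order of inter-assay reproducibility of heterogeneous potency data) by
one of three mechanisms:

* **linear-descriptor** — a sparse linear form on 8 descriptors: penalised
  linear learners on the all-descriptor table are near-optimal;
* **substructure-rule** — signed indicator effects on 6 fingerprint bits
  plus 3 pairwise interactions, left on its natural unit scale so the rule's
  step sizes are exact: tree ensembles on fingerprints are near-optimal;
* **smooth-nonlinear** — a sum of 6 signed Gaussian bumps in standardized
  descriptor space, centred on the target's own compounds with squared
  length scale p/2 (matching typical inter-compound distances): RBF kernel
  machines are near-optimal. Centring the bumps on the data is essential —
  bumps centred off the data shell look locally linear and stop
  discriminating kernel from linear learners.

By default the mechanism is a deterministic function of the L1 class
(realised with balanced class assignment), so "the best algorithm depends
on the target family" holds by construction and sequence-composition
meta-features carry the selection signal; an unconditioned mixture is
available. Sequences are i.i.d. residues from class-specific frequency
profiles (each L1 class up-weights a disjoint residue block), lengths
uniform in [100, 600].

**What passing tests show — and don't.** On these collections the planted
family structure is strong and low-dimensional, so selector accuracies near
1 and large RMSE reductions are expected, not remarkable; the tests
demonstrate that the machinery recovers structure that is present, not that
comparable gains exist in real bioactivity data, where mechanism boundaries
are soft, meta-features are noisier, and assay heterogeneity adds
label noise the generator does not model. One scale interaction is worth
knowing: with 60 targets and tenfold meta-CV, a 50-nearest-neighbour
ranker sees 50 of 54 training targets, so its ranking is nearly global —
it converges to the single globally best workflow rather than adapting per
family. Its per-target selection *accuracy* therefore cannot exceed the
majority-class rate whenever one workflow family dominates the global
ranking; this is a property of k ≈ n, visible only at desk scale, and
disappears when the collection is orders of magnitude larger than k.

## Problem sizes and numerics

Desk-scale defaults (60 targets, 80–300 compounds, 128 bits, 16/64
descriptors, 8-workflow experiment registry) were chosen so the full
pipeline — benchmark, meta-features, three meta-learners under tenfold
meta-CV — completes in minutes on a single CPU; the full 52-workflow
enumeration is exercised structurally. All stages are deterministic given
the experiment seed: per-target random streams are spawned from a seed
sequence, fold seeds are CRC-derived per target, and every estimator with
internal randomness receives an explicit seed. Benchmark results are cached
tidily on disk and runs resume from the cache; cached and fresh runs agree
exactly.

Degenerate inputs are handled explicitly rather than silently: empty
activity record lists, all-missing descriptor columns, non-binary
fingerprints, unfoldable compound counts (< 2 × folds), constant responses
(NaN skewness/kurtosis), all-zero fingerprint pairs in the Tanimoto kernel
(similarity 1), and exact RMSE ties (first workflow in enumeration order
wins, logged).

## Known limitations

* The learner registry reproduces settings, not implementations; the
  substituted learners (conditional trees, splines, RVM, response-surface)
  are nearest equivalents and their absolute RMSEs should not be read as
  faithful to the originals.
* The hydrophobicity registry is a compiled convenience: scale values for
  the most widely used scales follow the original publications, but the
  registry as a whole is versioned by checksum rather than certified
  against a canonical source, and it is configurable precisely so users can
  substitute a vetted set.
* Total correlation over a capped random bit subset is an estimator choice;
  different subsets give different values (the subset is seeded for
  reproducibility).
* The generator makes no attempt to mimic real assay noise distributions,
  activity-cliff structure, or correlated fingerprint bits.
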