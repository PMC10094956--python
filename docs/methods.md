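# Methods

## Epidemiological indices

For each patch-tested substance the pipeline takes the *medians* of
sensitization rates reported across published studies, separately for
ACD patients (Me_ACD) and the general population (Me_gen), both in
percent. Medians are plain sample medians (mean of the two central
order statistics for even-length lists); an empty patient-rate list is
an error, since the record then carries no epidemiological information.

Two indices and thresholds define the binary endpoint labels:

- eOR = Me_ACD / Me_gen; label 1 iff eOR ≥ 3, with Me_gen = 0 mapped to
  a typed NOT_CALCULABLE sentinel that is *also* labeled 1 (a positive
  patient signal against zero background is maximal concern). The
  sentinel is deliberately not `inf` so downstream code must branch on
  it explicitly. Me_ACD = Me_gen = 0 is rejected.
- eAR = Me_ACD − Me_gen (percentage points, may be negative); label 1
  iff eAR ≥ 1.

Threshold comparisons carry an `isclose` guard (relative and absolute
tolerance 1e−12). The inputs are ratios and differences of two-decimal
percentages, and several real substances sit exactly on a threshold
(e.g. medians 0.30/0.10, a ratio of exactly 3); without the guard,
binary-float roundoff (0.30/0.10 = 2.999…96) would flip those labels.

The shipped index tables contain a handful of printed values that are
arithmetically inconsistent with their own medians (their 0/1 codes are
consistent). These rows are listed in `fixtures.EOR_SKIP` /
`fixtures.EAR_SKIP` with the discrepancy documented inline, and
bulk-recompute tests skip exactly those cells rather than trying to
reverse-engineer the source's rounding. Display rounding is half away
from zero to two decimals, and recomputed indices are required to match
the printed ones to ±0.01 after rounding.

## Label propagation

Prevalence data label substances; the classifiers need labeled hapten
structures. Rules, in order:

1. an endpoint-excluded substance emits nothing;
2. a non-organic substance (metal salts) emits nothing — 2D organic
   descriptors cannot characterize them on the same footing;
3. a single-hapten substance passes its label through;
4. a multi-component mix labeled 0 emits every component with label 0
   (if the mix does not sensitize, no component does);
5. a mix labeled 1 emits nothing — the signal cannot be attributed to a
   specific component without component-level epidemiology.

On the shipped composition table this yields 50 eAR haptens (19
sensitizers) and 43 eOR haptens. Hapten identity is matched by
normalized name (case-folded, whitespace-collapsed) through a small
alias table covering spelling variants between tables ("Neomycin" vs
"Neomycin sulfate", "Sorbitan sesquilate" vs "... sesquioleate").

SMILES for the 50 training and 15 forecast haptens are hand-curated
from names and CAS numbers and shipped as CSV. Five entries (lanolin,
colophonium, Myroxylon pereirae resin, Evernia prunastri extract,
cocamidopropyl betaine) are UVCB substances or homologue mixtures with
no single structure; the fixture stores a documented representative
structure (cholesterol, abietic acid, benzyl cinnamate, a depside, the
lauryl homologue) flagged `representative=true`, and no test asserts
descriptor values for flagged entries.

## Descriptors

Descriptor computation is a provider interface with two
implementations: the RDKit 2D descriptor set (~210 constitutional,
topological, electrotopological and surface-area descriptors;
deterministic for a fixed RDKit version, which is recorded in the
matrix provenance) and a file-based provider serving precomputed
matrices from CSV/ARFF for chemistry-free, bit-exact testing. The
descriptor *definitions* therefore differ from the 1444-descriptor
program used to build the original learning sets; headline
cross-validated numbers that depend on descriptor identities are not
expected to reproduce bit-exactly, and the package makes no such
promise. Missing values use column-median imputation fitted on the
training partition only (refit inside every CV fold, so no leakage).

## Feature selection

Four selectors mirror the classic WEKA attribute evaluators:

- |Pearson correlation| between descriptor and the 0/1 label (constant
  columns score 0);
- information gain IG = H(Y) − H(Y|bin) in bits after equal-frequency
  discretization (default 10 bins; the original tool's internal
  discretization is unspecified, so this is a declared choice), and its
  gain-ratio variant IG/H(bin) with 0 for single-bin columns;
- CFS subset search maximizing Merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff)
  by best-first forward search over the subset lattice, terminating
  after 5 consecutive non-improving expansions or a configurable
  evaluation budget. On small feature spaces the search covers the
  lattice and coincides with exhaustive merit maximization, which the
  tests assert.

Rankings break ties lexicographically by descriptor name so runs are
reproducible. Input-vector sizes (9/17/24 for eAR, 11/17/26 for eOR)
are configuration, not hard-coded; defaults are 24 (eAR) and 17 (eOR),
the sizes of the selected published models.

## Classifiers

**Gaussian Naive Bayes** (eAR): priors are class frequencies;
per-class, per-descriptor means and *biased* (n-denominator) variances
— the convention common to NB implementations; the original procedure
description leaves it unspecified. Variances are floored at 1e−9 × the largest overall descriptor
variance (1e−9 absolute if everything is constant) so a within-class
constant descriptor gives a sharp but finite density. Prediction works
in log space with max-subtraction normalization; a brute-force
density-product oracle (no logs) agrees to 1e−9 wherever it does not
underflow.

**Random committee** (eOR): 10 unpruned binary trees, each trained on
the full training set (no bagging); members differ only through the
random stream that draws K = ⌊log₂D⌋ + 1 candidate descriptors at every
node. Splits are midpoints between consecutive distinct values, chosen
by information gain; growth stops at purity or fewer than two rows.
Member i uses derived seed `seed + i`. The committee posterior is the
arithmetic mean of member leaf probabilities.

A posterior of exactly 0.5 resolves to class 1 in both models: outputs
are read as "more concern"/"less concern", and the precautionary
reading favors concern.

Models serialize to a documented JSON layout (priors/means/variances,
or the full tree structures); there is no foreign binary-format
compatibility.

## Evaluation

Confusion counts use class 1 as positive. Metrics: AG% =
(TP+TN)/total·100, SE = TP/(TP+FN), SP = TN/(TN+FP), FP rate =
FP/(FP+TN), FN rate = FN/(FN+TP). A zero denominator yields an
*undefined* metric (`None`), never 0.

Cross-validation permutes the records once with the given seed and
splits them into k near-equal folds (default 10). Folds are plain
random, matching the original procedure's description; stratification
is available behind a flag, default off. Any per-fold refitting
(imputation, selection) lives inside the model spec's `fit`, so each
fold is leakage-free. A fold whose training remainder has fewer than
two records of a class cannot fit class parameters; it is recorded as
degenerate, its test records predicted by the training majority, and
the run flagged rather than aborted. Pooled matrices are elementwise
sums, so the pooled total always equals n. Fixed seed ⇒ bit-identical
results.

`compare_methods` evaluates several call lists (e.g. an in silico
model, LLNA, an in vitro battery) against the same reference labels,
dropping missing calls pairwise per method and reporting the counts
used/dropped alongside each confusion matrix.

## Synthetic data

Generators emulate the statistical shape of the real inputs so every
stage is testable without chemistry:

- *prevalence*: Me_ACD ~ U(0.2, 10.5)%, Me_gen zero with probability
  7/50 else U(0.1, 3.4)% — the envelope and zero-inflation of the real
  index tables, placing synthetic indices on both sides of both
  thresholds. Stored truth labels are produced by the index definitions
  themselves, so the epidemiology module must recover them exactly.
- *descriptors*: class-conditional Gaussians with independent unit-
  variance coordinates; a configurable number of informative
  descriptors separated by `class_separation` pooled SDs (means ±Δ/2),
  the rest pure noise. The Bayes error Φ(−Δ√m/2) is stored with each
  dataset; NB cross-validated accuracy must land within 3 percentage
  points of 1 − BayesError at 500 rows per class (with separation 4σ in
  one dimension, Bayes error 0.0228, accuracy ≈ 97.7%).
- *mix tables*: a configurable fraction of 2–4-component mixes with
  labels drawn so that every propagation rule (0-mix, 1-mix, inorganic)
  is exercised.

What the synthetic data deliberately does not emulate: real descriptor
distributions are neither Gaussian nor independent, class balance in
the real tables is 19:31 rather than 1:1, and synthetic "structures"
are abstract numeric vectors, not chemistry. Passing synthetic tests
therefore validates the *mechanics* (estimation, CV bookkeeping,
thresholds, propagation), not real-world predictive performance.

Sampling sizes in the test suite (1000 oracle instances, 2000-row
parameter recovery, 500 rows per class for the Bayes-rate check) were
chosen so the whole suite runs in seconds while keeping sampling error
well inside the stated tolerances.

## Known limitations

- Descriptor identities differ from the original 1444-descriptor
  program, so the re-selected input vectors and the forecast calls can
  differ from the published ones; the published confusion matrix is
  instead reconstructed exactly from the shipped label and
  misclassification tables.
- The published three-way comparison against LLNA and in vitro
  batteries needs per-hapten reference calls that live in external
  references; the comparison harness is exercised on constructed
  fixtures instead.
- The eOR/eAR indices are ecological estimates built from medians of
  heterogeneous studies; the package reproduces that construction, it
  does not improve on it (no confidence intervals, by design).
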