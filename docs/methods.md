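# Methods

## Model

The predictor assigns a protein sequence to one of K channel
subfamilies from its tripeptide composition. The underlying assumption
is that subfamily membership leaves a signature in short-motif usage:
some 3-residue words occur in one subfamily far more often than the
subfamily's overall share of sequence would predict. The pipeline has
four stages, each implemented in its own module and composed by the
`OTCClassifier` estimator.

### Encoding (`features`)

A sequence of length L yields L − 2 overlapping windows of length 3;
the composition vector is `f_i = n_i / (L − 2)` over the 8000
tripeptides of the 20-letter alphabet, indexed lexicographically
(`AAA` → 0 … `YYY` → 7999). The ordering is a free choice — nothing
downstream depends on it — and the lexicographic one is self-documenting
and stable. Sequences shorter than 3 residues are a hard error: the
denominator L − 2 would be non-positive, and a zero vector would
silently misrepresent the record. Counts are exact integers; the
frequency vector sums to 1 to within 1e−12 (one floating division per
entry).

### Confidence-level ranking (`selection`)

Window counts are pooled per class over the whole training set — the
statistic is a dataset-level occurrence model, not a per-sequence
average. With `p_k = M_k / M` the prior occupancy of class k, the upper
binomial tail `P_ik = P(X ≥ n_ik)`, `X ~ Binomial(N_i, p_k)`, measures
how surprising tripeptide i's concentration in class k is;
`CL_ik = 1 − P_ik` and `CL_i = max_k CL_ik`. The tail is computed with
the regularized-incomplete-beta survival function, stable for totals in
the millions of windows.

Ties in `CL_i` are the rule, not the exception: every never-observed
tripeptide has CL exactly 0, and strongly enriched ones saturate at
CL = 1 in double precision. The ordering is therefore made fully
deterministic: `CL_i` descending, then smaller `min_k P_ik` first —
resolved in the tail domain, where precision near CL = 1 survives the
`1 − P` rounding — then smaller feature index. Determinism here is what
makes IFS and the jackknife reproducible run to run.

### Incremental feature selection

Nested prefixes `S_τ` of the ranking are evaluated by a caller-supplied
accuracy functional (jackknife accuracy of the downstream SVM in the
standard pipeline); `Θ` is the τ of the first maximum, so ties resolve
to the smallest subset. The exhaustive protocol evaluates every
τ = 1…8000; the default grid (`default_taus`) keeps stride 1 up to 1000
and stride 10 beyond, preserving single-feature resolution where the
optimum typically falls while bounding the number of cross-validation
runs. Both the grid and the (c, γ) treatment during the sweep are
overridable; by default the sweep holds (c, γ) fixed and a grid search,
if wanted, runs once at the located peak.

### Classification (`svm`)

The kernel machine is libsvm (scikit-learn's `SVC`), which trains a
binary classifier per class pair and predicts by one-vs-one majority
vote; voting ties fall to the earlier class in the model's class order.
The (c, γ) search grid is exponential with integer exponents,
c ∈ {2⁻⁵…2¹⁵}, γ ∈ {2⁻¹⁵…2⁻⁵} (21 × 11 pairs); grid ties resolve to
smaller γ, then smaller c (smoother models preferred).

**Feature scaling.** Features are z-scored on the training set before
the kernel, and the fitted scaler is stored in the model so prediction
applies the identical transform. This is a deliberate design choice,
and a necessary one: composition entries are of order 1/L (≈ 0.002 for
a 500-residue protein), so squared Euclidean distances between
composition vectors are ~1e−4 — several orders of magnitude below 1/γ
for every γ in the search range. Without scaling the RBF kernel is
numerically constant, the dual problem cannot separate anything at
moderate c, and the classifier degenerates to the majority class
(measured: leave-one-out accuracy equal to the largest class share on
the default synthetic benchmark; only the extreme corner c = 2¹⁵,
γ = 2⁻⁵ escapes). Standardizing attributes before an RBF kernel is the
documented libsvm best practice and restores the kernel's resolution at
the grid's midpoint.

**Defaults.** (c, γ) = (2⁰, 2⁻¹⁰) — the γ-grid midpoint exponent — are
the fixed parameters used while tracing IFS curves on the full-size
(~200-sequence) benchmark. They are sample-size dependent: with only a
few dozen training sequences the same pair underfits even after
scaling, and a width near γ ≈ 1/τ (e.g. 2⁻⁵ at τ ≈ 30) is appropriate.
The test suite and acceptance script use the midpoint defaults at
benchmark scale and scale-matched parameters on deliberately tiny
fixtures.

### Evaluation (`evaluation`)

Leave-one-out over the N sequences: fold j trains on the other N − 1
and predicts sequence j. In **"paper" mode** (default) the feature
subset is fixed before the folds — ranking runs once on the full
dataset, matching the protocol this family of predictors historically
published. That leaks selection information into every fold and biases
accuracy upward; **"nested" mode** re-ranks inside each fold on the
training remainder only and is the honest estimate. Neither direction
of the difference is guaranteed; both are merely reported.

Metrics come from the K × K confusion matrix by one-vs-rest
marginalisation: Sn = TP/(TP+FN), Sp = TN/(TN+FP), the standard MCC
with the value 0 whenever a denominator factor vanishes (the usual
convention for degenerate margins), OA = trace/N, plus macro averages
of Sn and Sp.

## Synthetic data (`simulate`)

The generator emulates the one property the method depends on — classes
distinguishable by tripeptide usage — and nothing else. Sequences are
i.i.d. draws from a background residue distribution (uniform by
default, to keep count arithmetic exactly checkable); then a fixed
number of non-overlapping 3-residue windows per sequence is overwritten
with tripeptides drawn uniformly from the class's planted set. Window
overwrite, rather than mixture sampling, gives an exact lower bound on
each class's pooled planted count (insertions plus chance background
hits), which the tests assert. Placement uses the gap construction
(sample m values from L − 2m slots, re-expand), so it is uniform over
non-overlapping placements and needs no retries; an infeasible request
(3m > L) is rejected at spec construction.

The default spec mirrors the published benchmark's shape: six classes
of 82/16/37/32/10/40 sequences (217 total), lengths uniform in 300–700
residues, 10 disjoint planted tripeptides per class, 12 insertions per
sequence, seed 20140722. The unbalanced sizes matter: the n = 10 class
is where sensitivity estimation is fragile, and the jackknife results
show exactly that (its Sn is the only one below 1.0 in the worked
example). Twelve insertions in a ~500-residue sequence raise a planted
tripeptide's class frequency roughly 20-fold over its background
expectation ((L−2)/8000 ≈ 0.06 per sequence) — strong but not
caricatural enrichment, enough that ranking recovers ≥ 90% of planted
features in the top 60 across seeds without making every stage
trivially perfect.

What the generator does **not** model: homology within a subfamily,
transmembrane-domain architecture, skewed residue composition
(available as an option, not default), alignable motif positions, or
fragments. Passing tests therefore demonstrate that the pipeline's
statistics and protocol are implemented correctly and recover planted
signal at realistic sizes — not that the classifier attains any
particular accuracy on real channel sequences.

## Curation (`io`)

Validation enforces the canonical 20-letter alphabet; ambiguity codes
(B, X, Z), selenocysteine (U), `*` and `-` are reported with 1-based
positions, never silently stripped. Redundancy reduction is a greedy
longest-first single-pass clustering at an identity cutoff (default
0.60): each sequence joins the first previously kept representative at
or above the cutoff, else founds a cluster. Identity is computed from
an exact global alignment (match +1, mismatch 0, linear gap −1) as
identical aligned pairs divided by the shorter sequence's length — the
convention of the word-filter clustering tools this replaces, computed
exactly because a few hundred sequences make exactness affordable and
bit-stable. Fragment detection requires source-database annotation and
is out of scope; the CLI accepts an id-exclusion list instead.

## Problem sizes

The shipped configuration runs everything at desk scale: the 217 × 8000
encoding and full CL ranking take under a second; a 217-fold jackknife
at τ = 60 a few seconds; the reduced IFS sweep (3 classes × 10
sequences, τ ∈ {5,…,50}) a few seconds more. Tracing the full
8000-point IFS curve with a grid search per prefix — the exhaustive
protocol — is supported but left to the user's budget.

## Known limitations

- "paper"-mode jackknife accuracy is optimistically biased (selection
  leakage); use nested mode for honest estimates.
- The greedy identity filter is order-dependent by construction
  (longest-first, deterministic) and is not guaranteed to reproduce the
  clustering of word-filter tools at the same nominal cutoff.
- CL saturates at 1.0 in double precision, so ordering among strongly
  enriched tripeptides rests on the documented tail-domain tie-break
  rather than on meaningful CL differences.
- The SVM defaults are tuned to benchmark-scale sample sizes; very
  small datasets need a wider kernel or the full grid search.
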