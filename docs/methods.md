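# Methods

This note records the models and procedures the package implements, the
choices made where the design was genuinely open, and what the tests do
and do not demonstrate.

## Clique decomposition

A molecule (parsed by RDKit, stereochemistry stripped) is dissected
into fragments by two rules:

1. every smallest ring is one clique; rings sharing **more than two
   atoms** are merged into a single bridged clique (fused rings, which
   share exactly two atoms, and spiro rings, which share one, stay
   separate);
2. every bond not in any ring is a two-atom clique.

The union of clique atom sets covers all heavy atoms. Bond *ownership*
is disjoint: a ring-fusion bond is drawn in both rings' fragment
strings (each fragment must be a complete ring) but is owned, for
accounting purposes, by the ring whose smallest atom index comes first.
Molecules with a single heavy atom yield one single-atom clique so that
no record is featureless.

Fragment strings are canonical SMILES of the induced substructure,
**kekulized** (benzene is `C1=CC=CC=C1`, tetrazole `C1=NN=NN1`) and
stereo-free, with formal charges retained (a nitro group contributes
`[N+][O-]` and `[N+]=O` cliques). Kekulization of fused aromatic
systems is not unique and RDKit's choice depends on the order in which
atoms are written; `decompose` therefore re-parses every molecule from
its canonical SMILES first, which makes the decomposition a function of
the molecular graph alone and the feature vector invariant under atom
reordering. A residual consequence, inherent to kekulized fragments, is
that chemically equivalent aromatic rings embedded in different fused
environments can still produce different kekulé fragment strings.

Implicit hydrogens stay implicit. The descriptor encodes *which*
fragments a molecule contains and how many times — nothing about their
connectivity or 3-D arrangement.

## Vocabulary and featurization

The vocabulary maps each distinct fragment string to a column index,
ordered by descending document frequency (molecules containing the
clique at least once) with lexicographic tie-break, so rebuilding from
the same data gives identical maps. Occurrence frequency (total count,
weighting repeats within a molecule) is tracked alongside, since both
notions of "relative abundance" are defensible. A molecule's feature
vector is the per-clique occurrence count; fragments outside the
vocabulary are dropped and tallied. Inside cross-validation the default
is to build the vocabulary from the training fold only; a `full` scope
(vocabulary from all molecules) exists for parity with workflows that
featurize the whole dataset up front — the difference is benign (no
labels are involved) but the stricter default avoids even nominal
leakage.

## Classification and evaluation

The classifier is a scikit-learn random forest: 64 trees, Gini
impurity `1 − Σ pᵢ²` as the split criterion, all other hyperparameters
at library defaults, with no tuning. A molecule's score is the
fraction of trees voting for the permeable class (computed from the
individual trees' hard votes, not from averaged leaf probabilities);
ties at exactly 0.5 classify as positive.

Evaluation is repeated k-fold cross-validation, default 5 folds × 10
repeats. Folds are plain shuffled k-fold (not stratified — a stratified
option exists but is off by default). Repeat *r* uses split seed
`base_seed + r` and forest seed `forest_seed + r`, so repeats are
statistically independent yet the whole run is reproducible. Metrics
per fold: SN = tp/(tp+fn) and SP = tn/(tn+fp) for the BBB+ class,
MCC with the convention MCC = 0 when its denominator vanishes, and
trapezoidal ROC AUC (equivalent to the tie-corrected Mann–Whitney
statistic, asserted to 1e−9 in the tests). Aggregates are the mean and
(population) standard deviation over all k × repeats folds. A random
scorer gives AUC ≈ 0.5 and MCC ≈ 0; at a fixed 0.5 threshold its
expected SN and SP equal the chance rates (≈ 0.5 for uniform scores),
not zero.

MDI importances are averaged over trees and normalized so the full
vector sums to one; cliques found in fewer than 50 molecules are
excluded from the ranked report but deliberately kept in the
normalization, so reported values are comparable across filter
settings. The per-tree standard deviation is reported because MDI
ranks can be unstable for correlated features.

## Discretized SMOTE

Class balancing synthesizes minority rows until the classes are equal:
draw two *distinct* minority rows uniformly at random (not k-nearest
neighbours), interpolate with `t ~ Uniform(0,1)` (endpoints allowed, so
exact copies can occur), and round half-away-from-zero — on the
non-negative count lattice, ordinary half-up — so synthetic rows are
valid integer descriptors. Each synthetic coordinate lies within its
parents' bounds. Majority rows are never removed. Balancing applies to
training folds only; the evaluation harness hashes every validation
fold's indices and features, and identical hashes with and without
SMOTE prove no synthetic row ever reaches validation.

## Naive-Bayes marginal analysis

Binarize the counts (presence/absence), then fit a Bernoulli naive
Bayes: empirical class prior and conditionals
`P(xᵢ=1|y) = (count(xᵢ=1, y) + α) / (count(y) + 2α)`. The per-clique
marginal `P(y=1|xᵢ=1)` follows by Bayes' rule with the exact binary
evidence term. With α = 0 it is exactly the empirical fraction
`count(xᵢ=1, y=1)/count(xᵢ=1)` (undefined if the clique occurs
nowhere). The default is α = 1 (Laplace), which keeps marginals off the
degenerate 0/1 endpoints for rare cliques; α = 0 is exposed for the
exact empirical statistic. Priors are always empirical frequencies,
never uniform. The analysis is fitted on the full labelled dataset —
it is an interpretation device, not a predictor — while the naive-Bayes
*classifier* (posterior with the normalizer over y restored, computed
in log space with clipped logs so zero-probability evidence cannot
produce NaN) can also be cross-validated for reference; it is the
weaker classifier.

The clique report lists enhancers (marginal ≥ 0.8) and suppressors
(≤ 0.2) among cliques present in ≥ 50 molecules, each with document
frequency and the fragment's Wildman–Crippen clogP. clogP of an
isolated fragment is a qualitative lipophilicity indicator only.

## Synthetic data generator

The generator emulates the B3DB-style table: decorated-ring molecules
with a yes/no label, quality grades, and log BB for a subset. One ring
block (default cyclopentane, piperidine, morpholine, azetidine,
tetrahydropyran, uniform) is decorated with 0–3 distinct substituent
bond blocks (methyl → `CC`, fluoro → `CF`, hydroxyl → `CO`, exocyclic
imine → `C=N`; count uniform, subset uniform given the count), each on
its own ring carbon. The chemistry is deliberately minimal so the
decomposition recovers exactly the planted blocks and clique-level
ground truth is exact.

Labels are Bernoulli with `logit = β₀ + Σ β_c · [block c present]`.
Default effects (log-odds): cyclopentane +4, piperidine +3, morpholine
+2, azetidine −4, tetrahydropyran −2, `CF` +4, `CC` +1, `CO` −1, `C=N`
−3; the intercept is calibrated by bisection on the exact enumerated
positive rate to hit the target class balance (default 0.64 positive,
the rough positive fraction of the public BBBP database the dialect
emulates). These effect sizes were fixed at design time by enumerating
the composition space: they put the Bayes-optimal AUC near 0.96 and
spread the analytic marginals over ≈ 0.16–0.95, a clearly-resolvable
planted signal with both enhancer and suppressor blocks. Every
block's exact marginal P(y=1 | block present) comes from brute-force
enumeration of the finite composition space (75 compositions by
default) — no simulation.

log BB is emitted for a random 15% of rows (flagged grade A, matching
the convention that grade A means a numeric log BB is available) as
`−1 + 0.5·logit + N(0, 0.3)`: a noisy monotone image of the planted
log-odds, so molecular-weight/clogP/log BB correlations in the
exploratory analysis have real signal.

What the generator does *not* emulate: realistic medicinal-chemistry
coverage, fused or aromatic ring systems, correlated fragment
co-occurrence beyond the composition rules, label noise structure of
curated experimental sources, or duplicate structures. Passing the
recovery tests therefore shows the estimators are correct and well
calibrated on clean planted structure, not that any particular accuracy
will be attained on real data.

## Data layer

The reader accepts `{"BBB+", "yes", "1", "true"}` (case-insensitive) as
positive labels and `{"BBB-", "no", "0", "false"}` as negative;
anything else is an error, since silently guessing a label convention
is worse than failing. Unparseable SMILES are dropped with a logged
warning and an exclusion count — never silently. Duplicate structures
are retained as distinct records. Canonicalization strips
stereochemistry (fragment descriptors encode chemistry, not 3-D
structure). Exploratory summaries use Gaussian KDEs with Scott's
bandwidth on a 256-point grid padded 5% beyond the sample range;
degenerate (constant) samples are flagged instead of smoothed. The
Pearson table correlates molecular weight and clogP with log BB within
each class, over the records that have log BB.

## Numerical conventions and problem sizes

- MCC denominator 0 → MCC = 0; score ties at threshold → positive.
- Marginal undefined (clique absent everywhere, α = 0) → explicit
  error, not NaN propagation.
- Half-up rounding in SMOTE (values are non-negative, so half-up and
  half-away-from-zero coincide).
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / scikit-learn `random_state`); identical
  configurations give byte-identical outputs.
- The bundled experiments use 2 000 molecules for cross-validated
  benchmarks and 5 000 for marginal-recovery (three seeds in the test
  suite), sizes at which binomial error on a marginal with ≥ 50
  occurrences is comfortably below the 0.05 recovery tolerance.

## Known limitations

- Kekulized fragment strings of fused aromatic systems are not unique
  across different fused environments (see above).
- MDI is biased toward high-cardinality/high-frequency features and
  can be unstable (large per-tree spread); the naive-Bayes marginal is
  the statistic to interpret directionally.
- The naive-Bayes marginal is a *univariate* association measure: it
  inherits confounding between co-occurring cliques.
- clogP values for fragments are qualitative.
- The discretized SMOTE interpolates existing minority structure only;
  it creates no new information, and on these descriptors it mainly
  trades sensitivity for specificity at roughly constant MCC/AUC.
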