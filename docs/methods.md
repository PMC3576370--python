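# Methods

This note documents the models implemented in `hubseq`, the assumptions they
make, the parameter choices that were genuinely open, and what the synthetic
test corpora do and do not establish about behaviour on real proteomes.

## Generative sequence classifiers

All three classifiers are generative models over the 20-letter amino-acid
alphabet and classify by maximum posterior log-score
`log P(c) + log P(s | c)`; ties break to the first class in sorted label
order so results are reproducible.

* **Multinomial naive Bayes (k = 1).** A sequence is a bag of residues;
  `θ(a|c) = (n_{a,c} + 1)/(N_c + 20)` with Laplace add-one smoothing.
* **NB k-gram (k ≤ 4).** A bag of overlapping k-grams from a sliding
  window; `θ(g|c) = (n_{g,c} + 1)/(N_c + 20^k)`. Successive windows share
  k−1 residues, so the conditional-independence assumption is knowingly
  violated; the model is kept because it is cheap and surprisingly strong.
* **NB(k) (k ≤ 4).** A per-class Markov chain of order k−1 that models the
  window overlap explicitly: transitions
  `P(a | ctx, c) = (n_{ctx·a,c} + 1)/(n_{ctx·*,c} + 20)`, and an initial
  distribution over the 20^(k−1) starting contexts estimated from the first
  clean (k−1)-gram of each training sequence, Laplace-smoothed. For k = 1
  the chain has a single empty context and the model is exactly the
  multinomial classifier; this equivalence is asserted in the tests to
  1e-9.

k is capped at 4 because the 20^k parameter space outgrows any realistic
training set beyond that. The Laplace pseudocount is fixed at 1 (exposed
implicitly through the formulas; a different smoothing regime would change
every denominator coherently). Class priors default to training-set
frequencies with a uniform-prior option.

**Ambiguity handling.** B→D, Z→E, J→L, U→C, O→K at parse time; X and `*`
are kept in the stored residues but every k-gram window containing them is
skipped, including the initial-context window. This keeps the event space
at exactly 20^k and makes all smoothing denominators well defined.
Sequences with no scoreable window fall back to the prior and are flagged.

**Numerics.** Tables are stored sparsely as log-probabilities with a
per-context (or per-class) default for unseen events, so a full 20^4 table
is never materialised; the row-normalisation invariant (sum to 1 within
1e-9 over the full event space) is tested directly.

## Homology search and transfer rules

The default backend is a deterministic Smith–Waterman local aligner
(BLOSUM62, gap open 11 / extend 1, via Biopython's pairwise aligner). Raw
scores are converted to bit scores with the Karlin–Altschul formula using
fixed gapped-BLOSUM62 parameters (λ = 0.267, K = 0.041) and to e-values
with a search space of query length × total database residues. This
approximation is adequate for ranking and thresholding at the default
cutoff of 1e-4; it does not reproduce BLAST e-values exactly and performs
no profile iteration. An external BLAST+ backend (`psiblast`, tabular
outfmt 6) is available behind the same interface for users who want true
PSI-BLAST semantics. Hits are always re-sorted by (e-value ascending, bit
score descending, subject id), so results are deterministic regardless of
backend; self-hits are excluded by id.

Three transfer rules sit on top:

* **Top-hit classification** (the ensemble's homology vote): 1 iff the
  top-scoring hit carries the target class; an empty hit list votes 0.
  The empty-list convention matters for queries without homologs — they
  can never receive a positive homology vote, which the stage-2 SVM learns
  to discount.
* **Hub calling** over the top four hits: 4/4 → definite, 3/4 → likely,
  2–2 → unknown, no hits → unknown. With one to three hits only a
  unanimous "likely" call is made — a deliberate extrapolation; a definite
  call is never issued with fewer than four hits.
* **Interactor estimation**: the top hit's partner count, the (min, max)
  range over the top four, and the weighted mean `Σ wᵢnᵢ / Σ wᵢ`. The
  weight is the bit score (e-values are unbounded below and scale with the
  database, making them unusable as weights); `-log10(e)` is available as
  an option. The estimate is invariant to uniform weight scaling and
  always lies inside the reported range.

## The stacked ensemble

HybSVM converts each sequence into a fixed 8-tuple of binary votes
(multinomial NB, NB 2/3/4-gram, NB(2), NB(3), NB(4), homology top hit) and
trains an SVM on those tuples. Design choices:

* **Out-of-fold stacking.** Stage-2 training vectors are produced by an
  internal stratified 5-fold split: stage-1 models fitted on four folds
  vote on the fifth, with the homology reference likewise restricted.
  In-fold stacking would let stage 2 read memorised stage-1 outputs and
  inflate accuracy; the cost is that stage-1 votes at training time are
  slightly noisier than at prediction time (they come from models fitted
  on 80% of the data).
* **SVM hyperparameters.** Polynomial kernel of degree 1 (i.e. linear on
  the 8-bit cube) and C = 1 — conventional SMO-style defaults; both are
  exposed in the config. Degree > 1 buys nothing on an 8-bit input in our
  experiments and is harder to calibrate.
* **Calibration.** A logistic fit from the SVM margin to a probability
  (Platt scaling) on the stacking vectors. The map is monotone by
  construction; the probability of the *predicted* class is
  `max(p, 1−p) ∈ [0.5, 1]`, and the decision threshold on p is adjustable
  for ROC sweeps and coverage/reliability trade-offs.
* **Degenerate input.** If every stacking vector is identical the stage-2
  problem is vacuous and training raises an error advising a baseline.

Baselines: majority class (label and frequency), and a multinomial naive
Bayes over domain-identifier counts (add-one smoothing over the observed
domain vocabulary; a protein with no domains is classified by the prior).

## Evaluation

Standard definitions throughout: precision = TP/(TP+FP), recall =
TP/(TP+FN), F = harmonic mean, MCC as the binary correlation coefficient.
Any measure with a zero denominator is reported as 0 and flagged rather
than raised, because degenerate constant predictors are a legitimate
baseline outcome. AUC is computed as the Mann–Whitney rank statistic (ties
credited 0.5); the ROC curve is computed independently and the equality of
rank AUC with the trapezoidal curve area is a test invariant.
Cross-validation is stratified (per-fold class counts within one of
proportional), seeded, and pools out-of-fold predictions; homology-based
classifiers receive only the training folds as their reference database.

## Dataset construction rules

* **Redundancy reduction**: greedy incremental clustering, longest sequence
  first; a sequence joins the first cluster whose *founder* it matches at
  ≥50% identity over ≥80% coverage, else founds a new cluster;
  representatives are then redrawn uniformly per cluster with the given
  seed. Identity is matches over alignment columns of the best local
  alignment; coverage is the aligned span over the shorter sequence's
  length by default (the longer-sequence and query conventions are
  selectable, since "80% of the sequence" is ambiguous between them).
* **Hub labelling** comes in two conventions, kept as separate functions:
  a banded rule (>5 partners → hub, <3 → non-hub, 3–5 excluded as too
  close to the arbitrary cutoff) and a plain ≥5 rule used for the
  structural/kinetic hub classes.
* **Interface rule**: ≥5 partners, then ≤2 mutually exclusive interfaces →
  SIH, ≥3 → MIH. **Kinetic rule**: ≥5 partners, then mean PCC ≤ 0.5 →
  date, > 0.5 → party (0.5 itself is date).

## Synthetic data: what it emulates and what it does not

The generator draws per-class Markov emitters (order 0 or 1) with
transition rows from a symmetric Dirichlet; the concentration parameter
controls the expected total-variation separation between classes (0.1
gives separation ≈ 0.8; 10⁶ gives indistinguishable classes). Homolog
families are produced by i.i.d. substitutions at rate 1 − target identity
(no indels, keeping identity analytically controllable). Interactor counts
are drawn from shifted negative binomials truncated to each hub tier's
band; interface counts and mean-PCC values are drawn inside their class's
region; domain counts are Poisson per class profile. Everything is driven
by a single integer seed and outputs are byte-identical across runs.

The `complementary_corpus` fixture deliberately splits the class signal:
half the corpus carries composition signal only (near-uniform letter
frequencies, distinct transitions — invisible to alignment), half carries
homology signal only (paralog families whose pos/neg subfamilies descend
from a common ancestor, so family-level composition quirks cancel across
the class boundary). This is the regime in which a stacked ensemble must
beat each component, and the tests assert that it does.

What passing these tests does **not** show: real proteomes are not Markov
chains — they have domain architecture, low-complexity regions, indels,
and phylogenetic correlation between training and test sequences that no
i.i.d.-substitution family model reproduces. The synthetic results
establish correctness of the machinery (estimators converge to the
generator, the stack exploits complementary signal, the rules implement
their thresholds exactly), not expected accuracy on biological data.

## Problem sizes

The test suite and the acceptance script use deliberately modest corpora:
parameter recovery uses 200 sequences per class at length 500 plus a
100,000-symbol emission for transition convergence (where the worst-case
binomial standard error times a ~3.5σ max over 400 cells stays inside the
0.02 band only for moderately skewed rows, hence Dirichlet concentration
2.0 for that experiment); the stacking comparison uses 160 sequences of
length 100 with a 20-permutation null. These sizes keep a full run in the
minutes range on one CPU while leaving the statistical margins comfortable.

## Known limitations

* The built-in aligner's e-values are approximate (fixed Karlin–Altschul
  parameters, no edge-effect correction, no profile iteration).
* The banded and ≥5 hub conventions are both implemented but nothing
  reconciles them; callers choose per dataset.
* Only binary tasks are supported; the three-phase pipeline composes
  binary classifiers rather than generalising to multi-class.
* Probability calibration is a single logistic fit; with very few stacking
  vectors the calibrated probabilities are coarse.
* The homology vote for a query with no hits is a hard 0, which biases
  Phase I against positive calls for orphan sequences; the ensemble
  compensates only insofar as the composition models are informative.
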