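# Methods

This note records the models, parameter choices and numerical
conventions behind `fundusml`, and what the synthetic-data experiments
do and do not establish.

## Problem setting

The pipeline studies multi-categorical classification of retinal fundus
photographs across ten categories: normal retina plus nine diseases
(BDR, PDR, dry AMD, wet AMD, RVO, RAO, hypertensive retinopathy, Coat's
disease, retinitis — the fixed ordering used whenever categories are
added one at a time).  The per-category counts of the curated
source-image collection the protocol is modelled on (25, 63, 17, 25,
48, 38, 12, 19, 12, 20; total 279) are recorded in
`fundusml.datatypes.STARE_CLASS_COUNTS` and motivate the oversampling
stage: raw class frequencies are far too unbalanced to train on
directly.

## Synthetic data

Two generators make every stage testable without clinical images.

**Image generator.**  Each image is a circular fundus disc with a
radial colour gradient, an optic-disc blob and six Bezier vessel
arcades, plus one parametric lesion motif per class (dark dot
haemorrhages, neovascular fronds, drusen, a grey-green macular patch,
sectoral flame streaks, a pale ischaemic sector, tortuous vessels,
peripheral exudate, scattered pale patches).  `motif_intensity` scales
lesion count and contrast; intensity 0 skips the motif entirely, so the
class collapses onto the normal-retina distribution by construction.
Channel values are real in [0, 1]; 8-bit conversion happens only at PNG
write time so augmentation arithmetic stays exact.  Every image draws
from its own `SeedSequence`-spawned substream, making output
bit-identical across runs and independent of generation order.

**Feature generator.**  A fast stand-in for image pipeline + descriptor:
class-conditional unit-variance Gaussians in `dim` dimensions whose
means sit at `separation` × random unit vectors, so mean pairwise class
distance scales linearly with `separation` and `separation = 0` yields
identical class distributions.  Desk-scale experiment defaults are 100
samples per class in 256 dimensions at separation 2.0 — chosen to put
ten-class accuracy in the informative mid-range (well above chance,
well below ceiling) at a size every analysis script finishes in minutes.

Neither generator models camera optics, inter-patient anatomy,
label noise or the correlated texture statistics of real fundus
photographs.  Passing tests therefore establish that the *computational
protocol* behaves as specified (balance, determinism, monotone response
to separability, metric identities), not that any accuracy level
transfers to clinical data.

## Augmentation

Oversampling balances every class to `target_per_class` (default 1000)
by sampling source images with replacement and applying transforms with
parameters drawn uniformly from: translation ±10% of width/height,
rotation ±15°, brightness ±10%, noise σ ∈ [0, 0.04]; output 224×224.
Conventions the protocol leaves open, fixed here:

* operation order translation → rotation → brightness → noise →
  resize; geometric before photometric keeps the noise field unwarped,
  and both geometric steps fold into a single bilinear warp to avoid
  double interpolation;
* brightness is multiplicative, value × (1 + f) — "±10% change" read as
  relative change;
* rotation is about the image centre, out-of-frame pixels fill with
  black (matching the fundus surround), and resizing is a plain
  bilinear resize without aspect-ratio cropping;
* every output image uses its own seed substream, so results do not
  depend on class iteration order;
* all-zero parameters on an image already at the output size are an
  exact identity (each stage is skipped when inactive), which the tests
  exploit.

## Feature stage

The descriptor contract is 4096 real values per image, mirroring the
width of the fully-connected layer a transfer-learning extractor would
expose; downstream subset sizes (1024/2048/3072/4096) stay meaningful.
The built-in descriptor concatenates per-channel 64-bin histograms
(192), mean/variance over 1×1, 2×2, 4×4, 8×8 grids (510), and
9-orientation gradient-magnitude histograms over 8×8 and 16×16 grids
(2880), zero-padded from 3582 to 4096.  Orientations are unsigned
(folded to [0, π)); flat cells keep all-zero histograms.  No
standardisation happens at extraction time — scaling is fitted inside
the classifier on training rows only, so preprocessing has a single
point of truth and cannot leak test statistics.

## Multiclass decision schemes

The base learner is a soft-margin RBF SVM (scikit-learn `SVC`) with
k(x, y) = exp(−‖x−y‖²/2σ²), i.e. `gamma = 1/(2σ²)` — σ is a length
scale, which keeps the log₁₀σ grid interpretable.  Defaults C = 100,
σ = 10.  The schemes themselves:

* **OVO** — K(K−1)/2 pairwise learners; label = most pairwise votes;
  scores = vote fractions (rows sum to 1).
* **OVA** — K one-vs-rest learners; label = largest decision value;
  scores = softmax of decision values.  For K = 2 a single learner is
  held and mirrored (the second one-vs-rest problem is its exact
  negation), so all three schemes coincide on binary problems.
* **DAG** — the same pairwise learners evaluated as a decision list:
  test (first, last) of the active class list, eliminate the loser,
  K−1 tests per sample.  Scores are normalised elimination-order
  weights (the class removed at step t scores t, the winner K), which
  guarantees the score argmax equals the decision-list label — raw
  pairwise-vote fractions cannot guarantee that, since the DAG winner
  need not be the vote maximiser.

Ties break toward the lowest class index everywhere (votes, score
argmax, decision values at exactly zero).  How multiclass SVMs should
emit class probabilities is genuinely open; vote fractions and softmax
are the least-committal deterministic choices and are what the ensemble
consumes.  An alternative calibration would change ensemble scores.

## Ensemble

The pool enumerates {OVO, OVA, DAG} × log₁₀C ∈ {−4 … 5} × log₁₀σ ∈
{−4 … 5} (the ten integers in (−5, 5]; 300 members).  Member behaviour
is cached on a held-out evaluation split (resubstitution available as a
flag but not default — distances measured on training errors would
reward overfitting).  With 0/1 misclassification indicators the
classifier distance reduces to 1 − (fraction of samples both members
get wrong), and a member's self-distance is 1 minus its error rate.
The "misclassification probability" reading of d_ik is left as a
documented switch; the indicator form is what the joint-error branch
("both predict incorrectly") defines cleanly.

**Clustering.**  Affinity propagation (damping 0.9, 500 iterations,
50-iteration convergence window) on similarity −Distance.  Affinity
propagation takes no cluster count, so the shared preference is tuned:
a ladder of candidate preferences spanning the similarity range (with a
geometric tail reaching the single-cluster regime) brackets the target
count, then the bracket is bisected; non-converged runs are discarded.
Exemplar count is a step function of the preference and can jump past
the target (e.g. 3 → 5 → 11 on near-duplicate pools); when exactly
seven converged clusters do not exist, the closest achievable count is
used and a `ClusterCountWarning` is raised.  The cluster representative
is the affinity-propagation exemplar; a best-accuracy-per-cluster
switch is provided.

**Fractional voting.**  Y = (1/n) Σ Fᵢ Pᵢ with n the representative
count (1/7 in the default seven-cluster configuration).  Fractions are
optimised by coordinate ascent over {0.0, 0.1, …, 1.0}, initial value
1.0, sweeping members in index order until a full pass changes nothing;
only strict improvements move a fraction, so ties keep the incumbent
and the search is deterministic.  Fractions are not constrained to sum
to one — the 1/n factor already normalises the average, and the argmax
label is scale-invariant.  Within cross-validation the validation set
for fraction optimisation is carved out of each training fold (default
20%), never touching the test fold.

## Feature ranking

* **KW** — Kruskal–Wallis H per feature (constant features score 0).
* **BW** — Σₖ nₖ(x̄ₖ−x̄)² / ΣₖΣᵢ(xᵢ−x̄ₖ)², within-class sum of squares
  floored at 1e−12 (effective ceiling numerator/1e−12) so zero-variance
  features rank first instead of dividing by zero.
* **MRMD** — |Spearman correlation with the label| plus the mean
  Euclidean distance of the standardised column to all other columns,
  each component scaled by its maximum before the equally weighted sum
  (the raw distance term grows with √n and would otherwise swamp the
  relevance term).  The distance matrix is computed from the Gram
  matrix in one BLAS call, O(d²n).

Ranking ties break toward the lower feature index (stable sort), making
top-k subsets deterministic and nested by construction.

## Metrics

RCI is implemented as normalised mutual information,
[H(true) − H(true|pred)] / H(true) in natural logs, with 0·log 0 ≡ 0,
empty prediction columns contributing nothing, and H(true) = 0 mapped
to 0.  The unnormalised mutual information is also exposed
(`rci_unnormalized`).  The normalised form is the one consistent with
the protocol's own reported binary operating point: a balanced
symmetric binary confusion matrix at accuracy 87.4% gives
I/H = 0.4536 and kappa 0.748, matching the published pairing of 87.4%
accuracy with RCI 0.453 and kappa 0.747 to rounding, whereas the
unnormalised value (0.314 nats) does not.  Kappa returns 0 with a
warning on degenerate single-row/column margins.  ROC thresholds sweep
every unique score plus a sentinel above the maximum; AUC is
trapezoidal (equal to the concordant-pair fraction on tie-free scores),
and Youden-index ties resolve to the lowest threshold.

## Experiment harnesses

Folds are stratified and seeded (unstratified folds degenerate under
the raw class imbalance) and metrics are computed on pooled out-of-fold
predictions, with per-fold accuracies reported alongside; the protocol
reports single numbers per setting without fixing a pooling rule, and
pooling keeps rare-class cells populated.  When augmentation precedes
cross-validation, augmented copies of one source image must stay within
one fold — the harnesses here generate features per-sample
independently, so the concern arises only for the image pipeline, where
`augment_oversample` should be applied per fold.

Problem sizes in the analysis scripts and acceptance script are
desk-scale choices: 100 samples/class × 256 features for the single-
classifier studies, 40/class × 64 features with the full 300-member
grid for ensemble structure, 40/class × 32 features with a 27-member
grid (all three schemes × 3 × 3 hyper-parameters) for the ten-seed
ensemble-vs-single comparison.  The seed-averaged trends (accuracy
non-increasing in category count; ensemble median at least the single
SVM's) are statements about these synthetic conditions.

## Known limitations

* The built-in descriptor is a classical image statistic, not a learned
  representation; absolute accuracies on real fundus images would
  differ, and the CNN adapter slot exists for that reason.
* Exactly seven affinity-propagation clusters are not always achievable
  on near-duplicate pools (see above); downstream code treats the
  representative count as data, never as a constant.
* Coordinate ascent over the fraction grid finds a local optimum of a
  discrete search; it is deterministic, not globally optimal.
* A pool member whose validation accuracy is below the majority-class
  rate can be assigned fraction 0; a single-member "ensemble" then
  degenerates to the majority vote, which is the correct reading of the
  vote formula rather than a defect.
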