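# Methods

This note documents the statistical models, the synthetic-data
assumptions, and the numerical choices behind `catcart`, in the order the
pipeline uses them.

## Instruments and scoring

Seven instruments are encoded in `catcart/data/instruments.yaml`: the
QLMI physical (10 items) and social (7 items) subscales on a 1–7 scale,
scored as the item mean; HADS-A, HADS-D and GAD-7 (7 items each) and
PHQ-9 (9 items) on 0–3 scales, scored as sums; and MPSSS (12 items, 1–7,
sum). Each instrument carries ordered class bands. Several published
cutoff tables leave gaps between integer bands (e.g. a moderate band
ending at 7 and a serious band starting "above 8"); bands here are made
contiguous by treating "above x" as "x or more", so every attainable
score has exactly one class. Two special cases:

- **QLMI-P** is binary: high exercise capacity strictly above a mean
  score of 4.0, low otherwise (the published low band ends at 3.39 and
  the high band starts above 4.0; a single cut at 4.0 closes the gap and
  matches the instrument's binary use).
- **QLMI-S** bands are realized half-open on the continuous mean score:
  [1.0, 4.5) / [4.5, 6.0) / [6.0, 7.0], lowest scores meaning highest
  risk of social dysfunctioning. Class labels are internally always
  {low, moderate, high} *by score*, with the clinical risk wording stored
  per band, since high scores are symptoms on HADS/PHQ/GAD but protective
  resource on MPSSS/QLMI.
- **HADS** subscales span 0–21 (7 items × 0–3); a published "1 to 21"
  range is inconsistent with its own 0-starting bands and is treated as a
  typo.

Exact mean scores are banded without rounding. A questionnaire with every
item absent counts as *missing*, one with some but not all items absent
as *insufficiently filled out*; only complete rows are scored.
Completeness percentages are rounded half-up to two decimals; note that a
consistent rounding rule cannot reproduce every cell of a hand-formatted
table (15/2837 = 0.5287% rounds to 0.53).

## Graded response model

Category probabilities follow Samejima's cumulative-logistic form;
information is the standard GRM Fisher information. Design choices:

- **Latent metric.** Fixed by a standard-normal population distribution
  (mean 0, SD 1) during calibration.
- **Trait estimation.** Bounded maximum likelihood on [−4, 4] by scalar
  minimisation (tolerance 1e−6). All-minimum / all-maximum patterns have
  monotone likelihoods; the estimate clamps to the bound and is flagged.
  The standard error is $1/\sqrt{I(\hat\theta)}$ from *expected*
  information at the estimate, giving the 95% CI as
  $\hat\theta \pm 1.96\,\mathrm{SE}$.
- **Calibration.** Marginal maximum likelihood via EM with 61 equally
  spaced quadrature nodes on [−6, 6], normal weights renormalised. The
  M-step is generalized-EM: per item, a few warm-started L-BFGS-B
  iterations on the reparameterisation (log slope, first threshold, log
  threshold gaps), which enforces positivity and strict threshold
  ordering and only ever accepts objective improvements — so the marginal
  likelihood is nondecreasing across cycles. Convergence: maximum
  parameter change < 1e−4, cap 500 cycles (typically ~25). Starting
  values: unit slope, thresholds at normal quantiles of observed
  cumulative category frequencies. A category never observed in the
  training data is collapsed into its lower neighbour and the recoding
  recorded on the fitted item. Calibration requires ≥ 200 respondents.
- **Score-to-trait cutoffs.** The test characteristic curve
  $T(\theta)$ is strictly increasing, so each raw-score class boundary —
  the midpoint between adjacent integer bands (4.5, 7.5 for HADS; 64.5,
  78.5 for MPSSS), or the continuous band edge times the item count for
  mean-scored instruments — is inverted by bisection to residual < 1e−8.

## Adaptive administration

The CAT replays a respondent's recorded (complete) answers: common first
item = maximal information at θ = 0; next item = maximal information at
the current estimate among unadministered items, ties to the lowest item
index; trait re-estimated by ML after every response; stopping checked
after every item from the first (no minimum beyond one item). The rule is
*strict* CI containment — a CI endpoint exactly on a cutoff continues —
which is the conservative reading of "classifiable with 95% confidence".
If the pool is exhausted without classification, the final class is the
full raw-score class, which makes a never-stopping CAT coincide exactly
with conventional scoring (a contract the tests assert).

## Trees

Classification trees minimise Gini impurity, regression trees within-node
SSE; the node risk used for split search is n·Gini or SSE, so a split's
"weighted impurity decrease" is the absolute risk decrease. Defaults
mirror common recursive-partitioning practice: minimum node size to split
20, minimum child size 1, complexity parameter 0.01 scaled by the root
risk, no depth cap. Item responses are ordinal (threshold splits at
midpoints between consecutive distinct observed values), gender and
diagnosis categorical (exhaustive binary subsets, ≤ 8 levels), age
numeric. Tie-breaks are fully deterministic: lowest predictor index, then
lowest threshold / lexicographically first level subset; near-equal
decreases (relative 1e−9) count as ties so float summation order cannot
flip a choice. Pruning is weakest-link cost-complexity with the penalty
selected among geometric means of consecutive alphas by 10-fold CV
(stratified by class for classification), risk = misclassification count
or SSE, ties toward the smaller tree. Regression-tree class predictions
are the leaf mean passed through the instrument's bands, so trees of both
kinds are scored on the same sensitivity/specificity grid. Missing
predictor values on a routing path raise (complete-case contract; no
surrogate splits).

## Synthetic cohorts

The generator emulates the structure the analysis assumes, not any real
item-level marginals (which are unpublished):

- one standard-normal latent trait per construct (anxiety, depression,
  exercise capacity, social functioning, social support), independent
  across constructs; instruments sharing a construct (HADS-A/GAD-7,
  HADS-D/PHQ-9) share the trait;
- GRM item banks with slopes uniform on [1.0, 2.5] and K−1 thresholds
  drawn N(0, 1.2), sorted with a minimum gap of 0.05 — generic,
  reasonably informative psychometric items;
- demographics with cardiac-rehabilitation marginals (70% male, age
  N(66.6, 11.1) truncated to [18, 100], five diagnosis categories at
  29.29/22.84/21.29/14.24/12.33%), independent of the traits by default —
  which is exactly what makes "trees never split on demographics" a
  testable property;
- optional missingness: whole-questionnaire dropout with probability
  p, else item-level MCAR. No informative (MNAR) missingness.

Every artifact embeds its seed and config; regeneration is bit-identical.
Passing tests on these cohorts show the *pipeline* behaves correctly
under the assumed model; they cannot show how either method performs on
real multi-clinic patient data, where dimensionality, local dependence,
and informative missingness may differ.

## Evaluation

75/25 train/validation split (training size = floor(0.75·n); at n = 2837
this is 2127/710). Ground truth for every sensitivity/specificity cell is
the class of the fully observed questionnaire score. One-vs-rest
sensitivity/specificity per class; classes absent from the validation
truth are reported as not-applicable rather than 0/0. NRMSE normalises
RMSE by the observed range of the true scores in the validation set (the
normaliser is a convention; range is this package's documented choice).
Tree-length statistics count *distinct questionnaire items* on each
validation respondent's path, excluding demographic predictors; CAT
lengths count administered items. Percentage reduction is
100·(1 − mean/instrument length).

## Problem sizes and determinism

The shipped test suite and the acceptance script use seeded cohorts of
400–2837 respondents — large enough for stable calibration (the
generate-then-refit check recovers thresholds to MAE < 0.15 and slopes to
MAE < 0.25 at n = 2000) while keeping a full seven-instrument comparison
around a minute on one CPU. All randomness flows from a single seed
through named spawn streams, and identical config + seed yields a
byte-identical evaluation report.

## Known limitations

- Unidimensionality per instrument is assumed everywhere; no
  multidimensional IRT, no 3-parameter or nominal models, no EAP/MAP
  scoring.
- The CAT has no exposure control or content balancing.
- Trees handle complete cases only.
- Synthetic item parameters are generic draws, not estimates of the real
  instruments, so absolute metric values on synthetic cohorts are not
  comparable to values on any clinical dataset; only the qualitative
  contrasts (trees shorter than CAT, both accurate, demographics unused)
  are transportable claims.
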