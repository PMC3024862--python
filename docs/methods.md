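# Methods

`regmine` mines candidate gene regulatory relationships from expression
matrices with a small set of intuitive per-pair parameters, integrates
them with a naive-Bayes likelihood-ratio model, and assigns a regulatory
direction from the time delay between expression peaks. This note
records the model, the numerical choices, and what the built-in
synthetic benchmark does and does not demonstrate.

## Per-pair features

For a directed candidate pair (TF, TG) with expression profiles
`x = (x_1..x_T)` and `y = (y_1..y_T)` (signed values, typically
log-ratios):

* **PCC** — the Pearson product-moment correlation r(x, y). Constant
  profiles leave it undefined; the pair is then flagged and excluded
  from PCC-based tables rather than erroring.
* **ELD** (expression level differences distance) — each profile maps to
  the point (Q1, Q3) of its lower/upper quartiles; ELD is the Euclidean
  distance between the TF and TG points. It measures how differently the
  two expression ranges are located and spread, which rescues truly
  regulated pairs whose correlation is modest. Quartiles use linear
  interpolation (numpy's default, "type 7"); the choice of quartile
  estimator is a convention, not part of the model.
* **dmean / dsd** — |mean(x) − mean(y)| and |sd(x) − sd(y)| with the
  n−1 sample standard deviation. Absolute differences are used; the
  signed variant carries the same information for symmetric classes.
* **Quadrant main vector (|x|, theta)** — each measurement t is a
  sub-vector (x_t, y_t) in the TF-TG expression plane. Sub-vectors are
  summed per quadrant and the per-quadrant sum with the largest modulus
  is the pair's main vector, reported as modulus and argument in degrees
  [0, 360). Summing per quadrant prevents time-shifted or inverted
  patterns from cancelling in a single global sum. Conventions where the
  geometry is silent: axis-lying points belong to the lower-indexed
  adjacent quadrant (positive x-axis and positive y-axis to Q1, negative
  x-axis to Q2, negative y-axis to Q3; the origin to Q1); modulus ties
  between quadrants go to the lowest quadrant index; an all-zero pair is
  flagged undefined with sentinel angle 0.
* **GO co-annotation score** — annotations are propagated to all
  ancestors; C is the set of terms shared by both genes. Each leaf of
  the sub-DAG induced by C contributes its grade (1 + longest path to a
  root), and each divergent node d with k >= 2 children in C is
  penalised (k−1)·grade(d), removing credit duplicated below a common
  parent; the score floors at 0. Genes without any annotation yield an
  unavailable flag, not a zero observation.

PCC, ELD, dmean and dsd are symmetric in the pair; the quadrant vector
is not (TF on the x-axis), which is the only expression feature that can
in principle distinguish a pair from its reverse.

## Likelihood-ratio calibration and integration

Feature values observed on gold-standard positive and negative pairs are
binned on equal-frequency (quantile) edges of the pooled sample: 10 bins
for 1-D tables, 6 x 6 for the paired groups. Quantile edges avoid the
empty-bin instability of fixed-width histograms and make the tables
invariant under any monotone rescaling of a feature. Each bin's
likelihood ratio is smoothed with an additive pseudocount c = 1:

    LR_b = ((pos_b + c) / (n_pos + B c)) / ((neg_b + c) / (n_neg + B c))

Values outside the edge range clamp to the first/last bin; interior
edges belong to the right (higher) bin; a flagged-undefined feature
looks up as the non-informative ratio 1.

The four feature groups {PCC, ELD}, {dmean, dsd}, {|x|, theta} and
{GO} are combined by the naive-Bayes rule

    O_post = O_prior × Π_g LR_g ,

joint 2-D tables within each pair sidestepping any independence
argument between the paired parameters; independence **across** the four
groups is assumed, not tested, and no calibration step is applied. The
prior odds default to (#positives / #negatives) of the training
universe and are overridable, since the positive:negative training
ratio demonstrably shifts the attainable PPV (see the ratio sweep
below). A pair is called regulatory when its total LR (posterior/prior)
clears `lr_cutoff` (>= wins ties).

## Direction from time delay

Peaks of a profile are interior extrema where consecutive first
differences change sign strictly, Δy(t−1)·Δy(t) < 0; runs of equal
values are collapsed to their first index beforehand, since a zero
difference is uninformative. Amplitude is the value minus a mean or
median baseline; an extremum whose amplitude contradicts its type (a
local maximum at or below baseline, or the converse) is not counted as a
peak — peaks are excursions from baseline. The k strongest peaks per
profile (default k = 2) enter matching.

Matching is a global greedy pass over all same-sign (TF peak, TG peak)
candidates within `max_delay` (default ceil(T/3), which prevents
wrap-around matches in cyclic data), ordered by (|delay|, earlier
index, later index). This ordering is symmetric under swapping the two
profiles, so direction calls are exactly antisymmetric — a property a
TF-first greedy scan does not have. With amount-of-delay aggregation
(default) the reported delay is the median of matched delays truncated
toward zero; the existence-only variant reports just the sign consensus.
Positive delay (target lags) calls forward, negative reverse, zero or no
matches undetermined. All four variants (1–4 peaks x mean/median x
existence/amount) are exposed through `DirectionConfig`.

## Evaluation

ROC curves sweep the LR cutoff over every unique score with ties
grouped; the AUC is the trapezoidal area, which equals the Mann-Whitney
U statistic scaled by 1/(n1 n2) — the identity the tests use as an
oracle. Cross-validation refits every LR table per training fold
(stratified shuffled folds, default seed 42; plain shuffled folds when
the fold count exceeds the minority class so leave-one-out still runs)
and pools held-out scores. Operating points: *Se priority* takes the
largest cutoff with sensitivity >= the anchor (0.8 by default), *PPV
priority* the smallest cutoff holding PPV >= the anchor, *balanced* the
cutoff maximizing min(PPV, Se). PPV at a cutoff where nothing is called
is reported as 1 by convention. An unattainable anchor returns the
boundary cutoff flagged.

## Synthetic data

The generator provides ground truth for every stage without downloads.

**Networks.** `make_network` draws a directed graph on n genes with
independent edge probability `density`; edge weights are uniform
±[0.5, 1.5] and self-decay terms uniform [−1.5, −0.5], giving the linear
system dx/dt = M x with M = Wᵀ + diag(decay). Edges are the
gold-standard positives; ordered non-edges form the negative universe,
sampled 1:1 with positives by default.

**Expression.** Three regimes mirror common experiment designs:
*dynamic* integrates the ODE with forward Euler (dt = 0.1, 5-step
burn-in) through a compendium of perturbation episodes — the state is
re-displaced uniformly in ±`perturb_magnitude` every `episode_length`
samples (default 10, i.e. 100 samples = 10 short perturbation time
courses). A single decaying transient would leave most of a 100-point
series as pure noise; the episode design keeps every sample inside an
informative relaxation, which is how multi-experiment time-course
compendia look in practice. *global* solves one steady state per sample
with all genes perturbed; *local* perturbs one gene per experiment.
Every recorded value carries additive white measurement noise
N(0, noise_sd), default sd 0.1. Integration that exceeds |x| > 1e6
raises with advice to reduce dt.

**Lagged pairs (direction harness).** Each TF profile is an
induction/repression pulse pair — one positive and one negative Gaussian
bump (amplitude 0.8–1.3, width 1.0–1.5 samples) at random positions
separated by >= 6 samples and placed so both extrema stay interior to
the TF window and to every lag-shifted copy — over a small band-limited
noise background, standardized to sd 1. TG is the TF shifted right by a
lag cycling through `lag_set` plus N(0, noise_sd). The interior-placement
constraint is what makes noiseless recovery exact: a free random curve
loses boundary extrema differently in the two windows and the top-k peak
sets then disagree.

**Toy GO.** A rooted random term tree (default 80 terms, depth 7,
guaranteed depth chain). Every gene receives two random terms. In the
network-annotation variant each true edge is, with probability
`coann_bias` (default 0.6, a moderate, yeast-like degree of TF-target
functional co-annotation fixed a priori), co-annotated to its own fresh
leaf term hung under a random deep term — regulon-specific annotation,
so unrelated genes share at most shallow ancestors by chance.

**Standard benchmark.** A 10-gene, density-0.2 network yields at most 90
ordered pairs, so the 300 positive / 300 negative benchmark accumulates
gold pairs and features over independently seeded 10-gene dynamic
simulations (each with its own toy GO annotation) until the counts are
reached; draws whose random weights destabilize the integration are
skipped and redrawn from the seeded sub-seed stream.

## What the benchmark does and does not show

The benchmark exercises the full pipeline end to end and verifies the
calibration, integration and ranking machinery. Its negative universe
is, however, deliberately hard: every negative is a non-edge *inside* a
small dense network, so roughly a quarter of sampled negatives are the
reverse of a true edge — indistinguishable from positives for every
symmetric feature — and most of the rest are two-hop neighbours whose
profiles are confounded by shared regulators. Under these conditions the
integrated 5-fold CV AUC sits near 0.65–0.70 (seed-dependent), with the
GO group strongest and the expression groups individually near 0.5–0.6.
Real-data evaluations that draw negatives as random genome pairs face a
much easier discrimination problem, and results there (AUC ≈ 0.8 on
curated yeast regulons) should not be read off this benchmark, nor vice
versa. The ratio sweep reproduces the expected monotone decline of PPV
at fixed sensitivity as training negatives accumulate, and the direction
harness recovers noiseless lags exactly with coverage ≈ 0.97 and
accuracy ≈ 1.0 at noise sd 0.1.

## Problem sizes and determinism

Default problem sizes (10-gene networks, 100-sample series, 600–2400
benchmark pairs, 500 direction pairs) were chosen as comfortable desk
scale; every generator is a pure function of its config and seed, and
the command-line pipeline writes byte-identical outputs when re-run with
the same seed.

## Known limitations

* The GO-score divergence correction follows one admissible reading of
  the coannotation-tree idea (leaf credit minus duplicated-parent
  credit); other weightings are conceivable.
* Conditional independence across the four feature groups is assumed;
  no calibration of the posterior odds is attempted.
* Direction calls use integer-step peak delays only — no continuous
  alignment, no dynamic time warping.
* Steady-state (global/local) matrices carry no usable time axis, so
  direction is reported undetermined there.
* The simulator is linear with additive Gaussian noise; saturation,
  mRNA/protein lags and multiplicative noise in real arrays are out of
  scope.
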