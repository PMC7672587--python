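# Methods

This note documents the models, algorithms and design choices behind
`enrichopt`: what is computed, under which assumptions, which parameters
matter, and what the synthetic benchmarks do and do not establish.

## Data model and preprocessing

A dataset is an M × N matrix of real-valued molecular descriptors with
per-compound annotations: continuous activity (pKi units), a binary
active/inactive label, or both, plus a set tag (train / validation / test1 /
test2).  Descriptors are consumed, never computed; missing values are
rejected rather than imputed.

Preprocessing follows standard QSAR filtering, applied in a fixed order:

1. **Constant** descriptors (one distinct value) are dropped.
2. **Nearly constant** descriptors are dropped when the most frequent value
   (exact equality) occupies ≥ 70 % of compounds.  A modal-fraction rule was
   chosen over a value-range rule because it is parameter-free, reproducible
   and matches common descriptor-filtering practice; the threshold is
   configurable.
3. **Correlated** pairs with squared Pearson correlation > 0.7 lose the later
   column in input order — a deterministic, order-stable tie-break.

Filter statistics and the z-scoring mean/sd (sample sd, n−1) are computed on
the *training* subset only and frozen into `NormalizationParams`.  Freezing on
train — rather than normalizing the pooled data — is a deliberate choice: it
is the only protocol under which previously unseen compounds can be screened
without information leaking from the screening set into the model, at the
price of validation/test columns not being exactly standard normal.
Preprocessing is idempotent: re-running it on its own output removes nothing
and changes no value.

## The enrichment-optimizing search

The model class is a k-descriptor linear score A_j = Σ Xᵢ·Cᵢ over z-scored
descriptors, used only through the ranking it induces.  The objective
P ∈ {0, …, L} counts actives in the top L ranks (L = number of training
actives).  Ranking uses a stable descending sort with ties broken by
ascending input index, so results are deterministic and independent of any
random state.

Search is Metropolis MC with simulated annealing:

- **Initialization**: k distinct descriptors uniformly at random, weights
  ~ Uniform(−1, 1).  On z-scored descriptors this is a scale-free start.
- **Moves** (one position per step): with probability `p_swap` (default
  0.25), replace one descriptor with a uniformly drawn outsider and a fresh
  Uniform(−1, 1) weight; otherwise shift one weight by ±ΔJ with
  ΔJ ~ Uniform(0, `delta_j_max`), default half-range 0.5.  k never changes
  within a run.  A configuration flag can switch to perturbing all weights
  per step; the default single-position move keeps the acceptance rate in
  the conventional 25–60 % window.
- **Acceptance**: improving moves always; otherwise accept iff
  r < exp(−(P₁−P₂)/RT).  RT has no physical meaning; its range only sets the
  acceptance rate.
- **Schedule**: saw-tooth — RT walks linearly from `rt_max` (0.3 default;
  0.6 preset for runs needing a hotter regime) down to 0.01 in 0.01
  decrements, 300 steps per level (a 9 000-step cycle), then resets;
  cycles repeat until `total_steps` (default 10⁶) or until P = L, whichever
  comes first.
- **Archive**: every accepted model attaining the running best P is kept
  (reset on improvement), deduplicated by descriptor set and weights within
  10⁻⁹.  On long plateaus the archive can grow to thousands of tied models;
  they are small (k indices + k floats) and the final tie-break pass is
  linear in the archive size.
- **Reproducibility**: a single seeded generator owns every stochastic
  choice in a fixed order (initialization; then per step: move type,
  position, value, Metropolis draw), so identical seed + inputs give
  bit-identical results.

### Tie-break score

Solutions tying at P_best are ranked by
S_Z = S_active − S_inactive, where ranks of actives and inactives are
z-scored *within their own class* (sample sd) to offset the class imbalance,
S_active sums the normalized ranks of actives placed beyond L, and S_inactive
sums the normalized ranks of inactives placed inside the top L.  A perfect
ranking scores exactly 0; otherwise lower is better, preferring solutions
whose misplaced compounds sit close to the cut.  Two caveats are worth
recording.  First, the class populations being self-normalized means the two
sums are coupled through the realized rank distributions; at very small M
(≲ 10 compounds) this coupling can invert the intended "nearer miss is
better" ordering — at realistic set sizes (hundreds of compounds) the
ordering behaves as intended, and the tests check it at M = 100.  Second,
when P_best = L the search stops at the first such model rather than ranking
perfect solutions; S_Z degenerates to 0 there by construction.

## The residual-sd baseline

The conventional comparator selects descriptor subsets by stochastic search
minimizing the residual standard deviation √(RSS/(n−k−1)) of an OLS fit (with
intercept) of continuous activity.  It reuses the same MC/SA engine with two
changes: moves alter descriptor identity only (coefficients always come from
the exact least-squares solution), and the Metropolis energy is
(sd_new − sd_old)/`sd_scale`.  Since sd is continuous while the enrichment
objective is integer-valued, `sd_scale` (default: training-activity sd / 10)
maps sd differences into the same acceptance regime the RT range was designed
for.  Rank-deficient proposals are rejected outright.  This is a
reimplementation of the *stated objective* of commercial MLR feature
selection, not of any proprietary implementation.

## Evaluation metrics

- R² = 1 − RSS/SS on the training fit.
- Q²F1 = 1 − PRESS/SS_EXT(ȳ_TR), Q²F2 = 1 − PRESS/SS_EXT(ȳ_EXT),
  Q²F3 = 1 − (PRESS/n_EXT)/(SS_TR(ȳ_TR)/n_TR), with
  PRESS = Σ(y_pred − y)² over the external set.  A zero denominator leaves
  that one coefficient undefined (NaN) without suppressing the others.
- Top-L count, enrichment E = (tp/L)/(n_active/M), maximal enrichment
  M/n_active, confusion counts at the top-L cut (and optionally at an
  arbitrary score threshold, since classifier-style evaluation may binarize
  at a threshold rather than a rank cut), and MCC with the standard
  convention of 0 when any marginal is empty.
- Report rounding follows screening-table precision — one decimal for
  enrichment, two for MCC and R²/Q² — using half-up rounding (1286.25 prints
  as 1286.3); stored values keep full precision.

## The synthetic benchmark generator

The generator emulates the statistical shape of a small-scale screening
study, not its chemistry.  Defaults describe the canonical composition: 50
actives + 450 inactives in train and validation (1:9, within the ≤ 1:10
imbalance guidance), and a test pool of 50 actives + 5 141 decoys (maximal
enrichment 103.8).

Construction: descriptors are standard normal, optionally sharing a common
factor (`correlation` = pairwise equicorrelation ρ).  A planted unit-norm
model over `k_informative` random descriptors defines latent activity
x·ŵ.  Actives are baseline draws displaced by `effect_size` descriptor-sd
units along ŵ; inactives are undisplaced baseline draws.  This
mean-displacement construction makes `effect_size` exactly the active/
inactive separation and makes the null case (`effect_size` = 0) give
enrichment 1 in expectation, which a tail-rejection construction would not.
Continuous activity is pKi = 5.5 + latent + N(0, `noise_sd`), clipped to a
plausible 4–11 range, so default actives land near pKi 8–9 and inactives near
5–6.  Decoys are baseline draws displaced by `domain_shift` sd units along a
random direction with i.i.d. components — deliberately *off* any descriptor
correlation structure — labeled inactive with unknown pKi, and appear only in
test pools.  Everything is deterministic under the config seed.

What passing tests on these benchmarks show: the search machinery finds
planted linear structure, the metrics are computed correctly, and the
qualitative regression-vs-enrichment dissociation has a reproducible
mechanism.  What they do not show: performance on real descriptor
distributions (heavy-tailed, discrete, blockwise-correlated), scaffold
effects, or property-matched decoys.

## The dissociation experiment

With *uncorrelated* descriptors the generator cannot produce the headline
phenomenon (good regression statistics, failed screens): the sd-minimizing
direction and the optimal ranking direction then coincide, and OLS is the
statistically efficient way to find it — the baseline wins or ties on every
set.  This is itself an informative negative result: the dissociation
requires structure for the two objectives to disagree about.

With correlated descriptors (ρ > 0) the objectives genuinely separate.  The
regression, fitting y generated along ŵ, converges to ŵ itself; but the best
*class-separating* direction is ≈ Σ⁻¹ŵ, which de-correlates the shared
factor.  An sd-optimizing search cannot move toward Σ⁻¹ŵ (doing so raises
residual sd), while the enrichment objective rewards it directly.  Decoys
displaced off the correlation structure then hurt the regression's ranking
more.  The experiment therefore uses ρ = 0.4, effect size 5 (so both methods
keep high train/validation enrichment, matching the phenomenon being
modeled), decoy shift 3, at a scaled-down composition (25/225 train and
validation, 25 actives + 1 000 decoys test) over 10 seeds, asserting that the
validation-to-test retrieval drop is larger for the sd-optimized models and
that the enrichment-optimized models win the per-seed test comparison more
often than they lose it.

## Problem sizes and budgets

Test and verification runs use scaled-down instances chosen so the whole
suite exercises every code path in well under a minute of search time:
oracle-equivalence checks on N = 8–10, k = 2–3 (where exhaustive enumeration
is exact), recovery and dissociation runs at 15–25 actives with 10–30× decoy
pools and 2 000–8 000 MC steps, and a 10⁵-trial acceptance-frequency check.
Production-scale defaults (10⁶ steps, 5 000-compound decoy pools) remain the
package defaults; the scaled instances are an experimental-design choice, and
the oracle checks confirm the search reaches enumerated optima at these
scales.

## Known limitations

- The enrichment objective is a single-point count; it carries no information
  about the ranking below the cut, which is why the tie-break exists at all.
  Values-richer objectives (penalizing high-ranked inactives continuously)
  are out of scope.
- Model selection across seeds by test-set performance is reported (it
  mirrors common practice) but flagged: the summary also marks the best model
  by training-set tie-break score, which is the selection rule that does not
  touch held-out data.
- k is fixed within a run; choosing k is the user's problem.
- The search is sequential; multi-seed runs loop rather than parallelize.
- With ≳ 1:10 class imbalance the top-L objective becomes insensitive
  (a warning is emitted, not an error).
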