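# Methods

This note documents the models, calibrations and numerical choices behind
`tlrct`, in the spirit of a statistical appendix.

## Label classification

The UK FOP scheme bands each of fat, saturates, sugars and salt per 100 g of
food: green for `value ≤ g`, amber for `g < value ≤ a`, red above, with
`(g, a)` = (3.0, 17.5) for fat, (1.5, 5.0) for saturates, (5.0, 22.5) for
sugars and (0.3, 1.5) for salt. Band edges are inclusive on the milder side
(3.0 g fat is green) — the conventional reading of "low/medium/high" cutoffs.
For portions heavier than 100 g a per-portion red override applies when the
portion contains more than 21 g fat, 6 g saturates, 27 g sugars or 1.8 g
salt; the override can only worsen a colour. The table lives in
`src/tlrct/data/fop_thresholds_uk.yaml` and is injectable so other
jurisdictions' bands (or a drinks variant) can be dropped in. Products
missing any of the four nutrients cannot be labelled; they are excluded from
scoring and counted in the filter log rather than guessed at.

## Healthiness score

A product's score sums per-light points: 0.25 per green, 0.15 per amber, 0
per red, giving the 0–1 scale with 0 = four reds and 1 = four greens. The
weights originate in a discrete-choice experiment on how shoppers trade off
label colours; they are a `ScoreWeights` value object so alternative
weightings can be tested. Catalog summaries use the sample SD (n−1); a
single-product catalog reports SD 0 rather than erroring so batch runs never
crash on degenerate slices.

## Trial calendar and aggregation

Periods run contiguously from the calendar start (default 2014-11-11):
baseline T-1 (26 wk), recruitment T0 (4 wk), a 10-week data-processing gap,
intervention T1 (6 wk), washout T2 (12 wk); intervals are half-open
`[start, end)` and dates are ISO-8601. Outcomes exist for T-1/T1/T2 only.

Per participant × period: healthiness is the quantity-weighted mean product
score over in-scope purchases (each purchased unit counts once — a
quantity-2 line counts twice); per-week rates divide by the *nominal* period
length, not the participant's active span; nutrient totals use the whole
pack weight (purchases are whole packs, whatever the labelled portion);
fruit & veg and total spend are computed over the full ledger, while the
own-brand restriction applies only to the labelled scope (healthiness,
items, ready-meal spend, nutrient grams — with a category/brand switch
available, since reports of grams-per-week outcomes do not always state the
brand scope). Withdrawal removes transactions on/after the withdrawal date;
a participant withdrawn before a period's start contributes a fully missing
row for it, flagged `withdrawal` as distinct from `zero_purchases`.

## Missing outcomes

Missing cells are filled by stochastic regression within the period: OLS of
the observed outcome on the allocation stratifiers, then fitted value plus a
normal residual draw. Two deliberate strengthenings of the simplest scheme:

* **Proper draws.** By default each imputation copy first draws the
  regression coefficients and residual variance from their posterior
  (σ*² = SSE/χ²_ν, β* ~ N(β̂, σ*²(X'X)⁻¹)) before drawing residuals — the
  Bayesian form of stochastic-regression imputation (as in `mice::norm`).
  With coefficients held fixed instead (`proper=False`, also the variant the
  unit tests use to pin the fill distribution), Rubin's between-imputation
  variance misses the estimation uncertainty of the fill model and the
  pooled test becomes anticonservative at this trial's ~50% missingness
  (measured rejection ≈ 0.12 at nominal 0.05 on null simulations).
* **Group in the imputation model.** The default predictor set is sex,
  dependent children *and* allocation group. Omitting group — imputing from
  the stratifiers alone — makes the fills independent of allocation, which
  biases the pooled group effect toward zero by roughly the missing fraction
  and overstates its variance (uncongenial imputation); on null simulations
  at study conditions the test then essentially never rejects (0/200).
  With both strengthenings the pipeline's type-I error is 0.05 (300-replicate
  pilot; the acceptance suite re-verifies over 1000 replicates). The
  stratifier-only scheme remains available via
  `analyze_trial(..., mi_predictors=("sex", "dependents"))`.

The primary outcome uses multiple imputation (default m = 20 — standard
practice at trivial cost; m is configurable) with fills paired across
periods (copy k of the baseline accompanies copy k of the follow-up in each
ANCOVA); secondaries use a single fill. Primary fills are clipped to [0, 1]
(the score range is a hard invariant) and secondary per-week fills at 0.
Pooling follows Rubin's rules with the Barnard–Rubin small-sample degrees of
freedom. Collinear or constant predictors degrade gracefully (dropped with a
warning); a period with zero observed values aborts with an explicit error
rather than inventing data. Seeds: one master seed spawns per-period,
per-copy `SeedSequence` streams, so runs are bit-reproducible at fixed m.

MCAR diagnostics cross-tabulate "any missing primary outcome across the
three periods" against each stratifier with a Pearson chi-square (no Yates
correction by default, configurable).

## Effect estimation

The primary model is the Vickers–Altman baseline-adjusted ANCOVA; codings
are female = 1, dependents = 1, intervention = 1, so positive β4 means the
intervention arm purchased healthier. At baseline (nothing earlier to adjust
for) the model drops the baseline covariate. The OLS fit uses a QR
least-squares solve with conventional covariance; rank-deficient designs
raise an error naming the collinear columns. Tests are two-sided at α = .05
with no multiplicity adjustment — a pilot-appropriate reporting decision, as
many secondary outcomes are screened for effect-size estimation rather than
confirmatory claims.

Mann-Whitney U uses the rank-sum statistic; for samples of at most 8 per arm
the two-sided p-value comes from exhaustive enumeration of group relabelings
(exact even under ties), otherwise from the tie-corrected normal
approximation with continuity correction. Outcomes route between ANCOVA and
Mann-Whitney by a Shapiro–Wilk gate at α = .05, with per-outcome overrides so
a published analysis's routing can be reproduced exactly; degenerate inputs
(n < 3 or constant) route to the non-parametric branch with a warning.

Allocation is stratified permuted-block randomization over the four
sex × dependents strata with block size 4 (a common stratified-pilot choice;
configurable, balance holds for any even size). Within a stratum
participants are processed in sorted-id order and the per-stratum RNG stream
derives from the master seed and stratum index, so the assignment is
invariant to roster row order. Subgroup fits split NS-SEC 1–2 vs 3–5
(participants with missing NS-SEC excluded and counted); the interaction
test adds SES and group×SES terms to the ANCOVA, and both are Rubin-pooled
across imputation copies in the pipeline.

## Synthetic-data generator

The generator's defaults are the study conditions: 496 participants (67%
female, 32% with dependents, NS-SEC class probabilities 0.554/0.050/0.067/
0.036/0.083 with 21% undisclosed), a 438-product ready-meal/pizza catalog
with exactly round(72.4%) own-brand, score calibration mean 0.63 / SD 0.21,
zero-purchase probabilities (0.224, 0.520, 0.395) per period, 0.35 scope
items per purchaser-week, 79.3% of scope purchases own-brand, 3 withdrawals
during recruitment, and questionnaire completion hitting the marginal rates
(79%/54%/63%) and the joint 42% complete-data rate by explicit set
construction (a core completes everything; top-ups are arranged so no one
outside the core completes all three).

**Catalog.** Target scores are drawn from a normal truncated to [0, 1] whose
*post-truncation* moments are matched to the configured mean/SD by a
two-parameter root-find — naive truncation of N(0.63, 0.21²) would yield
mean ≈ 0.612, SD ≈ 0.191, drifting off the calibration target. Each target
is snapped to the nearest-score feasible colour pattern (ties broken
uniformly; the quantization grid is ≈ 0.05 wide and near-unbiased). Patterns
with green fat and red saturates are excluded as physically impossible
(saturates > 5 g forces fat > 5 g); since the score is permutation-invariant
every achievable score keeps a feasible pattern. Nutrients are then drawn
uniformly inside each colour's per-100 g band, capped so the per-portion
override cannot overturn an intended green/amber light, with saturates ≤ fat
enforced by rejection (bounded at 1000 tries). Pack weights are 250–550 g;
packs over 300 g are two-portion, keeping portions ≤ 300 g, below which all
amber bands stay non-empty under the portion caps — so re-labelling through
the engine reproduces the intended pattern for 100% of products, by
construction and by test. Red-band draws are capped at twice the amber bound;
prices (£1.50–£6.00) and filler-product parameters are documented constants
affecting only secondary spend outcomes.

**Purchases.** Each participant carries a latent healthfulness tilt
t_i ~ N(t₀, 3²); product choice among own-brand scope products follows the
softmax p_j ∝ exp(t_i·s_j) over product scores s_j, with t₀ solved so the
expected purchased score is 0.57 (purchasers skew slightly less healthy
than the catalog mean) and the tilt SD chosen to give realistic
between-participant spread in period means (≈ 0.13). Zero-purchase
missingness is MCAR by construction: an independent Bernoulli per
participant × period. Non-zero purchasers draw max(1, Poisson(rate×weeks))
scope items. The intervention effect is injected in T1 and T2 by a tilt
shift Δ solved by bisection so the mean expected-score lift over the
realized intervention tilts equals δ exactly; δ beyond the catalog's
attainable range raises a calibration error. The ground-truth record stores
δ, Δ and every tilt so estimator bias can be scored.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: basket composition and promotions,
seasonality, shared loyalty cards, partial card usage (real ledgers
undercount purchases), brand-level price structure, and any
missingness-not-at-random mechanism. Conclusions from the simulations are
about the estimators under MCAR and the stated purchase process, not about
field effectiveness.

## Problem sizes in the simulation studies

Operating-characteristic suites run the full pipeline (generation →
aggregation → MI with m = 20 → ANCOVA → Rubin pooling) at n = 496: 1000
null replicates for the type-I check (95% binomial envelope 0.036–0.064) and
200 replicates at δ = 0.04 for recovery, scored on the complete-case path —
the imputation path is *expected* to attenuate the effect toward zero by
about the missing fraction, since fills for non-purchasers carry no signal;
that attenuation is a property of the estimand under ~50% missingness, not a
bug. These simulations skip filler (non-scope) transactions, which touch
only secondary spend outcomes. Generator calibration checks use 20 seeds at
the 406-product calibration-sample size.

## Known limitations

* The single-fill path for secondaries inherits the usual understatement of
  uncertainty of single imputation; secondary p-values are screening-grade.
* The Shapiro–Wilk gate is itself a pre-test; for strict error control use
  the per-outcome routing overrides.
* The interaction and subgroup analyses are exploratory: the pilot scale
  gives them little power, and no multiplicity adjustment is applied.
* Healthiness aggregation weights purchased units equally; an alternative
  (per-transaction-line weighting) is not implemented.
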