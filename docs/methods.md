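# Methods

`pvsignal` implements the standard post-marketing signal-detection workflow
for spontaneous adverse-event reporting systems (FAERS-style databases),
specialized to a single event of interest defined by a narrow preferred-term
(PT) list — by default the vitreous-opacity terms *vitreous floaters*,
*vitreous opacities*, *myodesopsia*, *vitreous haze*. Because real FAERS
extracts are multi-gigabyte external downloads, every stage is exercised and
validated on a synthetic report generator with injected ground truth; the
same code paths accept real quarter-file-style input.

## Synthetic report generator (`pvsignal.synth`)

The generator emulates a spontaneous reporting stream:

- **Exposure.** Each case is independently exposed to each catalog drug
  `g` with probability `p_g`. Drug rows are written under a brand or
  generic alias chosen uniformly (and upper-cased with probability 0.5) to
  exercise name normalization.
- **Event model.** A case exposed to an injected drug `g` develops the
  target event with probability `min(1, RR_g × p0)`, where `p0` is the
  background per-case event probability (default 0.003, giving a realistic
  rare-event rate); with several injected drugs on board the maximum RR
  applies. The ground-truth signal set is `{g : RR_g > 1}`.
- **Latency.** Time from therapy start to event is lognormal per drug
  category, parameterized by the target arithmetic mean in days and a
  log-scale sd (default 1.0, a typical right-skew for onset times; only
  the means are pinned by the emulated study — antimicrobial 43.62 d,
  hormonal 409.16 d, ocular 203.49 d; oncology 120 d, immunological 180 d,
  other 140 d are this package's fill-ins chosen to keep the non-ocular
  average near 154 d). Therapy start is derived as event date minus the
  latency draw, so start always precedes the event. Non-event cases get
  exponential(mean 180 d) therapy durations.
- **Reporters, demographics, countries, routes, indications, outcomes**
  are sampled from fixed categorical mixes patterned on the demographic
  profile of published vitreous-opacity case series (age ≈ 62 ± 18 y,
  ~62% female, ~54% US reports, physician-dominated reporter mix with a
  10% consumer / 4% lawyer admixture so the healthcare-professional filter
  removes something).
- **Duplicates.** `round(n_cases × duplicate_rate)` cases (default 10%)
  are re-emitted with an incremented version stamp and, half the time, a
  perturbed weight — exercising keep-the-latest deduplication. Ground
  truth is frozen *before* duplication and missingness are applied.
- **Missingness** is field-wise Bernoulli (defaults: age 15%, weight 25%,
  sex 5%, event date 10%, therapy start 20%, route 20%, reporter code 2%),
  applied last.

All randomness flows from one `numpy.random.Generator` seeded from the
config, so output is bit-identical for identical seeds. What the generator
does **not** emulate: MedDRA hierarchy beyond a flat PT list, correlated
polypharmacy, reporting-rate secular trends, country-specific coding
quirks, or free-text drug names beyond brand/generic aliases — so passing
tests demonstrate correctness of the statistics and plumbing, not
robustness to every real-data pathology.

Two ready-made configurations define the package's study conditions: the
*study profile* (named 18-drug catalog across six categories with injected
signals in each category) and the *recovery profile* (50 anonymous drugs,
exposure probabilities spread over [0.004, 0.030], three injected signals
at RR = 20) used for sensitivity/false-discovery calibration.

## Cleaning (`pvsignal.ingest`)

Steps, each with an attrition entry whose in/out counts chain exactly:
drop records without a case id → deduplicate (greatest version stamp per
case id wins; ties broken by last occurrence in file order; a
`dedup_key="primaryid"` flag switches to per-report granularity) → keep
healthcare-professional reporters (MD/PH/OT/HP; missing code excluded) →
classify event cases by exact match of trimmed, case-folded PT text against
the narrow PT list (no fuzzy matching — the dictionary cannot be shipped) →
normalize drug names through a user-supplied brand→generic map (unmapped
names pass through case-folded with a warning), collapsing to one exposure
per (case, generic) keeping the earliest therapy start → exclude drugs with
fewer than 3 event cases from the signal report (they still count in every
denominator). A packaged category map pre-classifies 38 drugs known to be
associated with vitreous opacities into
ocular/oncology/hormonal/antimicrobial/immunological/other.

## Disproportionality statistics (`pvsignal.signals`, `pvsignal.mgps`)

For each drug, the 2×2 table (a, b, c, d) counts event/non-event cases
exposed/unexposed; E = (a+b)(a+c)/N.

- **ROR** = ad/bc with 95% Wald interval exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d)).
  Any zero cell triggers the Haldane–Anscombe +0.5 correction (flagged;
  disable to get an undefined result instead).
- **PRR** = [a/(a+b)]/[c/(c+d)], interval exp(ln PRR ± 1.96·√(1/a − 1/(a+b)
  + 1/c − 1/(c+d))); the +0.5 correction applies only when a or c is zero
  (zeros in b or d leave both the estimate and variance defined). The
  accompanying χ² is the uncorrected 1-df Pearson statistic
  N(ad−bc)²/((a+b)(c+d)(a+c)(b+d)) (Yates behind a flag); a zero margin
  gives χ² = 0, matching the Σ(O−E)²/E convention.
- **BCPNN information component.** The posterior model treats the joint
  cell and margin probabilities as independent Beta variables with the
  conventional pseudo-counts (joint 1, margins 1 of 2) and the joint prior
  total chosen so the prior IC expectation is zero. IC's posterior mean
  and variance are computed *exactly* for this model via digamma/trigamma
  identities. The 95% credible bounds default to a Cornish–Fisher quantile
  built from the exact first four posterior cumulants (polygamma), because
  the posterior of IC is markedly left-skewed at small counts — at a = 1 a
  plain normal bound misses the true 2.5th percentile by ≈ 0.4 log2-units,
  while the Cornish–Fisher bound tracks a 10⁵-draw Monte-Carlo sample of
  the same posterior to within a few hundredths; `interval="normal"`
  restores IC ± z·sd. (Published per-drug IC intervals in this area
  sometimes show count-independent half-widths that no count-dependent
  variance formula reproduces; no attempt is made to imitate such
  variants.)
- **MGPS / EBGM.** Counts follow Poisson(λE) with a two-component gamma
  mixture prior on λ; the five hyperparameters are fitted by maximizing
  the negative-binomial mixture marginal likelihood over all drug-event
  pairs (Nelder–Mead from the conventional start (0.2, 0.1, 2, 4, 1/3)
  plus three fixed alternative starts; best optimum kept; non-convergence
  raises an error carrying the best point). The posterior is again a
  two-gamma mixture; EBGM = exp(E[ln λ | a]) via digamma, and EB05/EB95
  are posterior percentiles found by bracketed root-finding on the mixture
  CDF. The (EB05, EB95) pair is the conventional 90% shrinkage band; pass
  `interval=(0.025, 0.975)` for a 95% band where a report labels it so.
- **Positivity and consensus.** Defaults (all configurable): ROR — a ≥ 3
  and interval lower bound > 1; PRR — PRR ≥ 2, χ² ≥ 4, a ≥ 3; BCPNN — IC
  lower bound > 0; MGPS — EB05 > 2. A *consensus signal* requires all
  four simultaneously (intersection rule), which trades sensitivity for a
  very low false-discovery rate; on the null calibration database no drug
  is flagged.

The scan fits the MGPS prior on all drugs of the database (shrinkage
borrows strength across the scan), reports drugs passing the min-count
filter, and sorts consensus-first by descending ROR.

## Time-to-onset (`pvsignal.onset`)

Latency records pair each event case with each consensus drug carrying
both dates; negative latencies and missing dates are excluded with counts
reported. Spontaneous reports contain only observed events, so the
cumulative risk curve 1 − S(t) (product-limit via `lifelines`) reduces to
the ECDF; the censoring hook remains for reuse. Group comparisons:
k-sample log-rank (lifelines statistic; p from χ², df = k − 1, which
matches a label-permutation distribution within Monte-Carlo error on the
test fixtures); one-way ANOVA from sums of squares on raw days (a
`log_scale` option analyses log1p days, since latencies are right-skewed
— raw days is the default to match mean-days reporting conventions) with
Tukey HSD (Tukey–Kramer for unequal n, statsmodels) summarized by an
insert-and-absorb compact letter display ordered by ascending group mean;
Welch's unequal-variance t with Satterthwaite df for the two-group
(ocular vs non-ocular) comparison. Degenerate inputs: all-constant groups
with unequal means report F = ∞, p = 0; equal constant groups t = 0,
p = 1.

## Case/non-case regression (`pvsignal.regress`)

Event status is regressed on drug indicators plus confounders with
reference-level dummy coding: age and weight in quartile bins (preset
edges 48/61/71 years and 57.14/69.00/82.10 kg; sample quartiles when no
edges are supplied), sex (reference female), US vs non-US country,
reporter qualification (reference HP), route (reference intramuscular),
indication (reference erectile dysfunction), and drug-use duration in
days, untransformed (the "time" covariate is not otherwise defined in the
reporting conventions this follows). Rows missing any covariate are
listwise-deleted with a per-covariate missingness report. Fitting is IRLS
with step-halving, so the deviance path is provably non-increasing;
convergence at max|score| < 1e-8 or relative deviance change < 1e-10;
covariance is the inverse observed information. Perfect separation is
flagged on the result (never silent); an optional ridge stabilizer (λ)
is available and always reflected in the covariance; rank deficiency
raises an error naming the collinear columns. Wald odds-ratio intervals
exp(β ± 1.96·se) with normal p-values. One joint model with all drug
indicators is the default; nothing prevents per-drug univariate use of
the same functions.

## Evaluation (`pvsignal.evaluate`)

AUC is the midrank Mann–Whitney statistic (ties count ½), with the ROC
curve stepped through distinct thresholds; the DeLong test uses the
placement-value (structural-component) variance/covariance estimator for
two correlated AUCs on the same cases, two-sided normal p; a
self-comparison has zero variance and reports z = 0, p = 1 by convention.
Classifier *training* is out of scope by design: any externally produced
score vectors can be evaluated. `recovery_metrics` scores a detection set
against generator ground truth (sensitivity, false discovery proportion,
0/0 → 0).

## Numerical and design choices

- Event-case granularity defaults to unique subject (deduplicated case);
  `dedup_key="primaryid"` gives per-report counting.
- All drug-exposure roles enter the 2×2 counts (no suspect-only
  restriction); restricting would require role codes the generator does
  not emit.
- MGPS quantile root-finding brackets between the component quantiles and
  expands the bracket geometrically on roundoff; tolerances 1e-13.
- The ROR/PRR/χ² implementations are validated to 1e-12 relative against
  independently coded formulas, exhaustively for all tables with N ≤ 40.
- Config files are plain JSON (schema documented in
  `pvsignal.synth.config_from_dict`).

## Problem sizes used in the shipped checks

The acceptance script analyses databases of 100,000 cases (recovery and
null calibration, 50 drugs) and 60,000 cases (study profile), a 50,000-row
regression, and 2,000-case score evaluation — sizes chosen so a full run
completes in well under a minute while keeping Monte-Carlo error small
relative to every tolerance. The test suite uses 20,000–100,000-case
databases, 5,000 pairs for MGPS prior recovery, 500-replicate coverage and
calibration loops, and 2,000-permutation oracles.

## Known limitations

- The intersection consensus rule is conservative; weak true signals
  (RR ≲ 6 at low exposure) are routinely missed — visible in the study
  profile, where the lowest-RR injected drugs fall below EB05 > 2.
- MGPS hyperparameter fitting on very few pairs (tens of drugs) can land
  in a concentrated optimum; estimates remain valid empirical-Bayes
  shrinkage but the mixture parameters themselves are not interpretable.
- Stratified MGPS, sequence-symmetry designs, Weibull onset-shape
  analysis, interval-censored likelihoods, and classifier training/SHAP
  attribution are out of scope.
- No multiplicity adjustment is applied across drugs beyond the consensus
  intersection itself.
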