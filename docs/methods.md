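# Methods

## Estimation

**Delivery collapse.** Birth histories list one row per child; the analysis
unit is the delivery. Children sharing (country, mother, birth month)
collapse to one delivery, twin if it has two or more children or if any
child carries the multiple-birth flag — a flagged child whose co-twin is
unlisted (e.g. died before listing) still marks a twin delivery, because
the outcome is the delivery's multiplicity, not the children observed.
More than four children at one date is treated as a data anomaly (flagged,
collapsed, twin). All multiple deliveries are treated as twin deliveries;
higher-order multiples are rare enough that this barely distorts rates.
Records are restricted to births within a recall window (default 10 years
before interview, month resolution) to limit recall bias, and
country/period exclusion rules (e.g. dropping a country entirely, or all
births after a given year) handle populations where assisted reproduction
would contaminate the age gradient.

**Twinning propensity.** The binary twin outcome is regressed by OLS on
maternal-age-category dummies plus country indicators (no global
intercept; the country indicators absorb it). A linear probability model is
used deliberately: for very rare binary outcomes its predicted
probabilities track observed frequencies closely, and coefficients read
directly as probability differences. The default age scheme is 5-year
categories 15–19 … 45–49 with 15–19 the reference; 2-year and 1-year
dummies are available for robustness. Ages below 15 clamp into the
youngest and above 49 into the oldest category rather than being dropped,
since retrospective histories contain such births even though survey
eligibility is 15–49. Coefficient covariance is heteroskedasticity-robust
(HC1) by default — LPM errors are heteroskedastic by construction —
with classical and mother-clustered options. The estimated age effects
deliberately absorb the correlated parity gradient: projection inputs
carry age structure but not parity, so an age-only gradient that includes
parity's contribution is what the projection needs. Country effects are
static by default (a period-dummy option exists); an empty age category is
dropped from the design with a warning.

**Posteriors.** "Posterior" means the flat-prior limit: multivariate
normal centred at the OLS estimates with the fitted covariance, which
coincides with the OLS sampling distribution and is exactly reproducible
from a seed. A numerically non-PSD covariance is repaired by eigenvalue
clipping (logged). The age-free country-rate model has point estimates
equal to each country's observed twin fraction, with normal draws at the
binomial standard error sqrt(p(1-p)/n); draws are truncated at zero only
when consumed as probabilities, never in storage.

**Per-country fits and pooling.** Separate per-country age-dummy LPMs feed
an inverse-variance random-effects meta-analysis (DerSimonian–Laird
method-of-moments heterogeneity, truncated at zero, where it reduces to
fixed-effects pooling). Random effects is the conservative default since
between-country homogeneity of the age gradient is an empirical question.
Categories estimated in a single country are fixed to that estimate and
flagged.

## The country × period panel

Within each country, consecutive birth years are merged greedily from the
earliest year forward until each group holds at least 4000 deliveries; a
trailing undersized group merges into its predecessor; a country below the
minimum altogether becomes a single flagged cell. The 4000 floor ensures
that at twinning rates of 15–20 per 1000 a cell expects 60–80 twin
deliveries (`check_min_group_rule` reports the expectation and the exact
binomial probability of at least 50), enough for a stable period rate.
Countries whose observed span is under 10 years are dropped to balance the
panel. Mean maternal age at birth (MAB) per cell is categorised into
half-open bins <26, [26, 26.5), [26.5, 27), and 27+ (ties upward, so 27.0
is "27+"): observed MAB concentrates in a narrow window, and categories
are robust to the skew of the within-cell age distribution. The panel
regression has country fixed effects and 5-year period fixed effects with
pooled tails (before 1980, after 2015), assigned by each cell's midpoint
year; cells are equally weighted by default (a delivery-count WLS option
exists), with classical standard errors by default and a cluster-by-country
option. GDP per capita and the share of women with at least primary
education enter linearly when supplied. The reported R² is the total
(centred) R² of the dummy regression.

## Projection

From the identities b = d + dt and tr = dt/d, deliveries follow from
projected births as d = b/(1+tr), per posterior draw of tr. Deliveries are
partitioned by the scenario's birth age shares (the last group takes the
exact float remainder so the partition sums to d); expected twin
deliveries are dt = Σ d_a p_{c,a} with p_{c,a} = γ_c + β_a per draw.

Two fits supply levels: the age-free country rate tr drives Eq-style
delivery counts, while the age model supplies the gradient. They are
reconciled per draw by recentring: the age-specific probabilities are
shifted so their baseline-share-weighted mean equals the same draw's tr.
This guarantees the identity scenario yields exactly 0% change and b = d +
dt closes at baseline; raw (unrecentred) mode is available and the
recentring magnitude is logged. Probabilities are clipped into [0, 1] only
at consumption. The same draw index pairs tr, γ and β so sampling
correlations propagate; an independent-pairing mode exists for
sensitivity. Scenario flags select whether births and/or age shares come
from the scenario year, supporting structure-only counterfactuals
(scenario shares with baseline births). Percent changes are computed per
draw and summarised as median and Q1–Q3; expected counts stay fractional
until report formatting. The share-of-children metric assumes every twin
delivery yields two children: of b = d(1+tr) children, 2·d·tr are twins,
so one child in (1+tr)/(2tr) has a twin sibling.

**Decomposition.** Birth age shares factor as s_a ∝ W_a·ASFR_a (women by
age times age-specific fertility). Changes in the implied twinning rate
decompose over {ASFR, composition}, and twin-delivery counts over {scale
of b, composition, ASFR}, by counterfactual substitution evaluated at all
2^k corners. Three views are reported, each exact per draw: sequential
contributions in a fixed order (sum to the total), Shapley-symmetrised
contributions (average over all substitution orders; sum to the total),
and pure single-substitution effects with a lumped interaction (pure +
interaction = total). Summaries report medians (and means, which preserve
additivity) across draws.

## Synthetic data

The generator emulates DHS-style retrospective histories: per mother, an
interview date, 1 + Poisson(1.8) deliveries at distinct month-resolution
dates inside the recall window (≈2.8 deliveries per mother over 10 years,
a high-fertility yield), maternal-age categories drawn from a fertility
schedule peaked in the early 20s, uniform exact ages within category, and
per-delivery twin outcomes with probability baseline + age effect. Default
country baselines span 0.0069–0.0263 per delivery (the observed
low-to-high country range); default age effects rise to +0.01 at 35–39 and
decline slightly after. Twin deliveries emit two child rows sharing mother
and date. Per-country substreams make countries independent under a shared
master seed, and identical seeds reproduce byte-identical tables.

Projection tables are constructed, not modelled: birth age shares shift
older by moving a fraction of each group's mass one group up (0.5% of mass
per year from the 2010 baseline, capped), total births grow 1% per year,
and the women age structure absorbs half the shift so both composition and
ASFR change; births = ASFR × women holds by construction.

What the generator does *not* emulate: survey weights, clusters and
strata; within-mother longitudinal coherence (a mother's age gaps need not
equal her birth-date gaps, though ages increase with parity — nothing
downstream consumes the joint distribution); sibling mortality and recall
error; zygosity; higher-order multiples; cohort-component projection
mechanics. Deliveries are independent by default; a mother-level gamma
frailty knob exists because the within-mother correlation of twinning is
not well established. Passing tests therefore demonstrate correctness of
the estimators and projections under the stated generating process, not
robustness to survey design effects or recall bias in real data.

## Numerical choices and problem sizes

Tolerances: oracle equivalence of the OLS fits is asserted to 10
significant digits against explicit dummy-matrix least squares;
decomposition additivity and the delivery partition are exact identities
(float remainder assigned to the last term); birth conservation at
baseline is checked to 1e-6 relative. MVN draws use eigendecomposition, so
positive-semidefinite (including exactly singular) covariances are valid.

Test problem sizes, chosen as the smallest that make the statistical
checks sharp: single-fit parameter recovery uses ~250k deliveries (3
countries × 30k mothers); interval-calibration checks use 200 replicates
of ~20k deliveries (coverage does not depend on n); the end-to-end
projection coverage check uses 100 replicates of 2 countries × 2.5k
mothers with 400 posterior draws, testing whether the 95% central
posterior interval of the rate change covers the analytic truth computed
from the generator's parameters.

## Known limitations

Country rate draws are normal approximations, poor for countries with very
few twin deliveries (a zero-twin country gets a degenerate point at 0).
The recentring closure imposes the age-free rate as the level anchor; if
the age mix of the estimation sample differs strongly from the baseline
projection year, raw and recentred modes diverge (logged). The panel's
greedy year grouping is deterministic but not unique — any contiguous
grouping satisfying the minimum would do. Covariates merge into panel
cells as unweighted means over the cell's year span. The package does not
parse native survey recode or projection-spreadsheet formats; inputs are
the normalised CSV schemas described in `twinproj.schemas`.
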