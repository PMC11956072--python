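# Methods

## Indicator construction

All scoring starts from a complete vector of 29 yes/no food-group
consumption responses for the previous 24 hours. Each indicator is a
fixed membership table (`dqqkit/taxonomy.py`, loaded from the packaged
`data/food_groups.csv` plus frozen item mappings): an *item* is a set of
food groups with an integer weight, an item is "hit" when any member group
was consumed, and the score is the weighted count of hit items. This makes
every indicator monotone in consumption, integer-valued, and exhaustively
enumerable (no indicator touches more than 20 groups), which the test
suite exploits to verify the published ranges (FGDS 0–10, NCD-Protect 0–9,
NCD-Risk 0–9, GDR 0–18, MDD-W threshold at FGDS 5) over *every*
consumption pattern rather than a sample.

Decisions where the standard indicator definitions leave room, and what
this package does:

* **FGDS aggregation.** The ten items follow the MDD-W convention:
  grains/tubers pools the grain staples, whole grains and roots/tubers
  groups; dairy pools cheese/yogurt/milk; meat/poultry/fish pools the two
  unprocessed red meats, processed meats, poultry and fish; vitamin-A-rich
  orange vegetables and vitamin-A-rich fruits form the "other
  vitamin-A-rich fruits/vegetables" item; citrus counts with other fruits.
  Processed meat counting toward meat/poultry/fish is DQQ convention; it
  is a single row of the frozen table if an analysis needs to differ.
* **All-5.** Animal-source foods include all meat groups (also the red and
  processed meats that sit on the foods-to-limit side), eggs and dairy:
  the recommendation is about consuming *any* animal-source food, not
  about its healthfulness.
* **Fruit juice is a sweet beverage, never a fruit**, so a juice-only day
  counts as zero fruit/vegetable *and* sweet-beverage positive.
* **"Sweetened tea/milk/coffee"** is the sweet tea/coffee/cocoa question;
  the plain-milk group is not pulled into the sweet-beverage indicator.
* **MDD-W applicability** is women aged 15–49 inclusive; everyone else is
  *not applicable* (distinct from "no"), so prevalence denominators are
  restricted exactly to eligible women. The window is a parameter of
  `mddw()` because some analyses restrict adults further.
* Scores are integers. The construction is integer-valued by definition;
  keeping them as ints makes the enumeration checks exact.

## Comparison statistics

**Cluster-adjusted χ².** For an R×C table of weighted estimated cell
proportions p̂, the Pearson statistic X² = n Σ (p̂_rc − p̂_r₊p̂_₊c)²/(p̂_r₊p̂_₊c)
is referred to a Rao–Scott-corrected distribution. The covariance of p̂
under the design is estimated by Taylor linearization with
with-replacement PSU totals, V = K/(K−1) Σ_k Z_k Z_kᵀ, where Z_k is
cluster k's total of w_i(y_i − p̂)/W; the multinomial (SRS) covariance is
V₀ = (diag p̂ − p̂p̂ᵀ)/n. Generalized design effects are the eigenvalues of
(H V₀ Hᵀ)⁻¹ (H V Hᵀ) with H the Jacobian of the (R−1)(C−1) independence
contrasts h_rc = p_rc − p_r₊p_₊c. With δ̄ their mean and a² their squared
coefficient of variation, the reported p-value is
F = X²/(d·δ̄) on (d/(1+a²), ν·d/(1+a²)) degrees of freedom, ν = K−1
(second-order Satterthwaite correction; a² = 0 gives the first-order
correction, used as a fallback when the design-effect matrix is
rank-deficient, and recorded in the `correction` field). The *statistic*
field reports the uncorrected Pearson X², the quantity conventionally
printed next to a design-adjusted p-value. With one respondent per
cluster and unit weights the construction reduces exactly to the
classical Pearson X² scaled by (n−1)/n on an F reference, which the tests
verify. Unweighted n is used as the sample-size factor; weights default
to 1 since the analysis this package implements reports unweighted
frequencies.

Zero-margin outcome or group levels are dropped with a warning; a test
with fewer than two remaining levels, or fewer than two clusters, is an
error — the reporting layer converts that into an explicit "—"
(not-testable) cell rather than a number.

**Mann–Whitney U.** Two-sided, tie-corrected normal approximation without
continuity correction (matching the exact enumeration asymptotically);
when both samples have ≤ 8 observations the p-value is instead computed
by enumerating all C(n₁+n₂, n₁) rank assignments, which handles ties
exactly. The test is deliberately *not* cluster-adjusted — the analysis
this package mirrors uses the plain test for medians — and that
limitation is recorded in the result metadata.

**Descriptives.** Proportions are weighted means reported in percent with
*unweighted* frequencies; medians and quartiles use linear interpolation
between order statistics (numpy's default percentile rule), fixed for
cross-implementation determinism. Display rounding (one decimal for
percentages, "6 [5–8]" median cells, p floored at "p < 0.001") applies
only to display strings; CSV outputs keep full precision alongside.

**ICC estimation** (generator validation) uses the one-way ANOVA
estimator (MSB − MSW)/(MSB + (m₀−1)MSW) with the size-adjusted mean
cluster size m₀.

## Synthetic survey generator

The generator emulates the *structure* the analysis assumes, not any real
country's data: five countries of ~1000 respondents aged 15+ (three
in-person, multistage: 100–125 clusters × 8–10 interviews, bounds
enforced; two telephone: independent respondents modelled as
single-respondent clusters, since phone sampling has no cluster stage).
Default parameters are the pooled study conditions: adolescent (15–19)
share ≈ 9.5% overall with per-country shares matching the pooled country
mix; gender, education, residence and wealth margins per age group from
the published sociodemographic table; per-food-group consumption
prevalences from the published adolescent/adult pooled rates. Adult ages
are 20 + Gamma(shape 2, scale 11), rounded and capped at 95 — a
realistic right-skewed adult age pyramid; the survey only uses the
15–19/20+ dichotomy, so the exact shape is immaterial downstream.

Consumption is drawn with a cluster-level random effect: the cluster's
group-specific probability is Beta with mean p and variance icc·p(1−p)
(a = p(1−icc)/icc, b = (1−p)(1−icc)/icc), giving exact marginal
prevalence p and pairwise within-cluster correlation icc; icc = 0 reduces
to independent draws. The cluster effect is applied through a shared
per-cluster uniform quantile, so both age strata in a cluster move
together — a cluster's food environment affects everyone — which means
between-stratum contrasts are much less design-inflated than level
estimates, as in real surveys. Default icc = 0.05, a typical magnitude
for behavioural outcomes in national cluster surveys.

Food groups are independent given the cluster effect by default, which
gives closed-form checks: P(any of set S) = 1 − Π_{g∈S}(1 − p_g). An
optional latent "diet healthfulness" factor (per-respondent standard
normal, entering each group's logit with +s for promote groups and −s for
limit groups) induces realistic cross-group correlation at the cost of
slightly perturbing marginal prevalences; it is off (s = 0) by default
because real cross-group dependence is unconstrained by available
aggregate data.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: the true joint distribution of food
groups (real diets are correlated, so derived indicator prevalences such
as unhealthy/UPF are *higher* under independence than observed in real
populations — the generated default-scenario UPF prevalence is ≈ 91%
among adolescents versus ≈ 77% reported from real pooled data);
probability-proportional-to-size cluster selection, nonresponse, and
post-stratification weights (all weights are 1).

Determinism: the root seed sequence spawns one child per country; each
country spawns streams for demographics, cluster effects, and one per
food group. Identical config + seed ⇒ byte-identical CSV.

## Problem sizes used in validation

Monte-Carlo calibration of the cluster-adjusted χ² uses 2000 replicates
of a null scenario (equal prevalences 0.30, ICC 0.05, 100 clusters × 10)
and 400 replicates of the published unhealthy-food effect size (76.8% vs
69.5%, 9.5% minority group, 507 clusters × 10). Generator recovery uses a
50 000-respondent independent-draw dataset (half adolescent, so each
stratum has ~25 000 respondents and the 1-percentage-point check is a
≈ 3σ bound) and a 2000-cluster × 10 run for ICC recovery. Exhaustive
enumerations cover 2⁹–2²⁰ patterns and run in seconds.

## Known limitations

* The exact Rao–Scott flavour (first- vs second-order, weight handling)
  used by any given published analysis is rarely stated; numerically
  matching published test statistics from restricted microdata is out of
  scope. The correction used is always recorded in the result.
* Mann–Whitney ignores clustering (by design, see above).
* Stratification and finite-population corrections beyond first-stage
  clusters are not implemented; no multiple-testing adjustment is applied.
* The DQQ records no quantities, so none of the indicators measure actual
  nutrient adequacy — they are population-level proxies.
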