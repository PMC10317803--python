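# Methods

## The family genetic risk score

The family genetic risk score (FGRS) estimates a person's aggregate genetic
liability to a disorder from the registered diagnoses of their extended
family.  For a proband *i* and disorder *d*, every enumerable relative *j*
of first through fifth degree contributes the product of four components:

* **z<sub>j</sub>** — the relative's liability z-score.  Under the
  liability-threshold model, a disorder with stratum prevalence *K* has
  threshold *t* = Φ⁻¹(1−K) on a standard-normal liability; a registered
  relative contributes the conditional mean above the threshold,
  z<sub>aff</sub> = φ(t)/K, and an unregistered one the conditional mean
  below it, z<sub>unaff</sub> = −φ(t)/(1−K).  Prevalences, and hence
  thresholds and conditional means, are estimated per (disorder, sex,
  birth-decade) stratum so secular and sex differences in registration
  rates move the threshold instead of biasing the score.
* **w<sub>j</sub>** — a time-at-risk weight for unregistered relatives
  (registered relatives have w = 1).  With *F* the empirical CDF of age at
  first registration, a<sub>obs</sub> the age at end of follow-up, and
  a<sub>start</sub> the age at which register coverage began for this
  person, w = (F(a<sub>obs</sub>) − F(a<sub>start</sub>)) / (1 −
  F(a<sub>start</sub>)), clamped to [0, 1].  The renormalization handles
  left truncation by register era: a relative who died before the register
  opened carries weight 0 (their absence of registration is uninformative).
* **r<sub>ij</sub>** — the relatedness coefficient: the expected proportion
  of genes shared identical by descent, summed over all genealogical paths
  (0.5 for first degree, halving per degree; 0.25 for double first
  cousins).  Computed by the tabular method on each connected pedigree
  component; degree is bookkeeping, round(−log₂ r).
* **c<sub>j</sub>** — a cohabitation correction in (0, 1] applied to
  first-degree relatives who shared a household with the proband, intended
  to strip shared-environment signal from the score (below).

The raw score is the weighted mean Σ z·w·r·c / Σ w·r, with n<sub>w</sub> =
Σ w·r the weighted number of relatives.  An empirical-Bayes reliability
factor v<sub>b</sub> / (v<sub>b</sub> + v<sub>w</sub>/n<sub>w</sub>) shrinks
the score of probands with little family information toward the population
mean; v<sub>w</sub> is the variance of z·c over all relative contributions
and v<sub>b</sub> the between-proband variance of raw scores minus
v<sub>w</sub>/mean(n<sub>w</sub>), floored at a small positive value (1e−6).
Finally, scores are standardized to mean 0 and s.d. 1 within year of birth,
which also absorbs residual register-coverage differences between cohorts.

### Cohabitation correction

The correction factor is the ratio of affection resemblance in pairs reared
apart to pairs reared together, clipped to [0, 1]: for parent–offspring
pairs, fathers who sired and raised their child versus fathers who never
lived with them; for siblings, half-sibs reared together versus apart.
Resemblance is the tetrachoric correlation of the 2×2 affection table
(thresholds from the table margins; the correlation solves the
bivariate-normal orthant equation by bisection).  The factor multiplies the
z of cohabiting first-degree relatives: the parent–offspring factor for
reared parent/offspring pairs, the sibling factor for reared-together full
sibs.  Degenerate inputs (a pair class below 50 pairs, a zero margin, or
non-positive reared resemblance) yield factor 1, i.e. no correction — the
conservative direction, since the factor only ever shrinks contributions.
Absent household data entirely, pairs are treated as reared for the same
reason.

Design notes on open points: the aggregation literature describes the four
components but not the factor's algebraic placement; multiplying the
contribution is the simplest reading consistent with "average of the
product".  Weights for registered relatives are fixed at 1.  Probands are
scored on every disorder regardless of their own affection status, and a
proband's own registrations never enter their own score (a proband is not
its own relative).

### Relative-exclusion sensitivity

`ScoreOptions.exclude_relative_disorders` supports two semantics:
`exclude_mode="events"` ignores the excluded disorder's registrations when
computing relatives' contributions (thresholds and onset CDFs stay estimated
from the full event table, so the liability scale is unchanged);
`exclude_mode="relatives"` removes any relative carrying such a registration
from every proband's relative set, which is the variant used in the
sensitivity analysis asking whether cross-disorder familial aggregation
survives removal of the index disorder from families.

## The synthetic registry

No real national-register data are available, so every analysis runs on a
simulated registry whose generative model matches the assumptions above.

**Pedigrees.**  Each family is a proband-centred kindred: a binary tree of
lineal ancestor couples (four generations by default), with every lineal
ancestor's extra siblings married to new founders and their descendants
carried down to the proband generation.  A proband therefore has parents,
siblings, grandparents, great-grandparents, aunts/uncles, first cousins,
grand-aunts/-uncles, parents' first cousins and second cousins — degrees
one through five — plus half-sibs from remarriage.  Mating is always with
unrelated founders, so pedigrees are outbred and relatedness theory is
exact.  Offspring counts are Poisson (mean 2.1, capped at 6), which under
the default structure yields a mean of roughly 35–40 enumerable relatives
per proband.  Probands are the members of the last generation.  Remarriage
creates paternal half-sibs reared apart (the father moves to a second
household) and maternal half-sibs reared together; a configurable fraction
of fathers (8% by default) never live in the child's household.

**Phenotypes.**  Liability is L = A + C + E per disorder with variances
h², c², 1−h²−c².  Founders draw A from N(0, Σ_A) with Σ_A = D R_g D,
D = diag(h); children receive the parental midpoint plus a segregation
deviation with covariance Σ_A/2, so Var(A) = h² in every generation and all
cross-disorder structure lives in the genetic correlation matrix R_g
(validated symmetric, unit-diagonal, positive semi-definite).  The
household component C is the mean of per-household effects over the
households a person was reared in or reared children in, normalized to unit
variance: cohabiting parent–offspring pairs and reared-together siblings
share environment; reared-apart pairs do not.  A parent who reared children
in one household after being reared in another carries two exposures, which
attenuates the parent–offspring environmental correlation relative to the
sibling one — a deliberate, documented asymmetry rather than a calibrated
quantity.  E is independent across disorders.

**Registration.**  Affection is L > Φ⁻¹(1−K<sub>sex</sub>) with the
threshold set analytically from the target prevalence.  Affected persons
draw an onset age (Weibull by default); the event is recorded only if the
onset year falls inside the person's follow-up (birth to death or
administrative censoring at 2017) *and* at or after the disorder's register
start year.  With most registers opening in 1997, older relatives are
systematically false-negative — the structure the time-at-risk weights are
designed to absorb.  Sex-specific registered prevalences, heritabilities
and onset distributions for the 13-disorder panel (three functional somatic
disorders and ten comparison disorders spanning internalizing, autoimmune,
pain and sleep classes) are package defaults chosen as plausible registry
values; they are study conditions, not fitted quantities.

**What the simulator does not model:** assortative mating, inbreeding,
monozygotic twins, mortality differentials by disorder, migration,
residual (non-genetic) cross-disorder correlation, and geographic
structure.  Passing tests therefore demonstrate internal consistency of
the method under its own assumptions, not performance on real registries.

## Analysis scenarios and problem sizes

Scenario builders in `fgrs.synthetic_data` freeze the study conditions used
by the tests, the analysis drivers, and `scripts/acceptance.py`:

* `single_disorder_config(h2, ...)` — one disorder, prevalence 0.08, full
  register coverage, 620 families (≈ 18–20k probands): heritability
  recovery.  Full coverage isolates genetic recovery from the coverage
  effects exercised elsewhere.
* `two_disorder_config(rg, ...)` — two disorders at h² = 0.5: genetic-
  correlation recovery via the cross-disorder score among cases.
* `cohabitation_config()` — h² = 0, c² = 0.3, half of fathers absent,
  elevated remarriage rates, ≈ 10⁴ father–offspring pairs per rearing
  class: correction efficacy.
* `profile_scenario_config()` — the 13-disorder panel (900 families,
  ≈ 26k probands, case groups around 1500) with block-structured
  correlations; the FM row is amplified (0.45–0.5 to the internalizing,
  pain and sleep blocks, ≤ 0.25 to the autoimmune block) because
  desk-scale case groups can only resolve cross-block elevations at the
  conservative α = 10⁻⁴ when the correlations sit at the strong end; the
  RA-like architecture is strictly confined to the autoimmune block
  (every outside-block correlation zero), so the qualitative contrast
  under study — broad functional-somatic profile versus class-confined
  autoimmune profile — is preserved at desk scale.
* `null_profile_config()` — h² = c² = 0 and R_g = I: every FGRS is pure
  noise and every profile comparison a true null, measuring the testing
  layer's type-I error.

## Profile statistics

Group profiles report means with normal-approximation 95% CIs (group sizes
in any realistic run make this adequate).  Comparisons are two-stage: a
one-way analysis of means across groups per disorder (the overall test,
implemented as one-way ANOVA since the original procedure's statistic is
unnamed), then unique pairwise unequal-variance Welch tests, validated
against a label-permutation oracle.  Significance uses α = 10⁻⁴ throughout,
the conservative threshold appropriate to batteries of above a hundred
non-independent tests.  Elevation of a group (versus the scored population)
is a one-sample z-test of the group mean against 0, which is exact under
the standardization.

## Latent classes

Etiologic heterogeneity is probed with diagonal-covariance Gaussian
mixtures over a selected set of score dimensions — the continuous-indicator
analogue of latent class analysis, assuming local independence within
class.  EM runs from 20 seeded k-means++ starts; convergence is a relative
log-likelihood change below 1e−7; variances are floored at 1e−4 and any
start in which a component's effective size falls below d+1 members is
discarded as collapsed.  Model choice is minimum BIC with ties broken
toward fewer classes.  Because score dimensions are correlated while the
within-class model is diagonal, BIC on real score vectors tends to add
classes to absorb correlation; the collinearity of the selected class means
(share of class-mean variance on the leading axis) distinguishes graded
severity (quantitative classes) from distinct subtypes.

## Numerical conventions

Dates are years throughout.  Birth-decade bins are calendar decades.
Zero-case threshold strata floor K at 0.5/n to keep thresholds finite.
Standardization cells are single birth years when a year has at least two
scored probands with non-constant scores (exact mean 0, s.d. 1, population
s.d.); sparser or constant-valued years — which carry no usable s.d. —
borrow the parameters of the nearest such anchor year, so they can never
perturb it.  Missing scores (probands with no weighted relative) propagate
as missing.  All randomness flows through `numpy.random.default_rng`
seeds; identical inputs, options and seeds reproduce bit-identical score
matrices.
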