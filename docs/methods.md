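# Methods

## The design being modelled

The package models the first wave of a national face-to-face smoker survey
in which each country is partitioned into geographic strata (major regions
crossed with an urban / semi-urban–rural / rural indicator), a fixed budget
of area clusters is allocated to strata approximately proportionally to the
adult (18+) population with a floor of two clusters per stratum, and
fieldwork inside each sampled cluster proceeds by a random route over
dwellings, a household screener counting resident adult smokers (smoking at
least monthly, over 100 lifetime cigarettes), next-birthday selection of at
most one male and one female smoker per household, and a quota of ten
completed smoker interviews per cluster.  Everything downstream — outcome
rates, the four-step weighting chain, the Rao–Wu bootstrap — is exercised
against simulated populations whose truth is known.

## Synthetic populations

`generate_population` builds strata → clusters → households → adults.
Parameters that matter, with defaults:

- `adult_population` per stratum (exact; household sizes are truncated at
  the cluster boundary so realized counts match the configuration).
- `household_size_probs` — adults per household; default mass
  {1: 0.30, 2: 0.45, 3: 0.17, 4: 0.08} (mean ≈ 2.0, a realistic European
  adults-per-dwelling distribution).
- `smoking_prevalence` — a sex × age-group table; defaults (male
  0.30/0.38/0.36/0.22, female 0.22/0.28/0.26/0.14 over bins
  18–24/25–39/40–54/55+) give ~27% overall prevalence with the usual male
  excess and middle-age peak, in the range reported for the surveyed
  countries in the mid-2010s.  `stratum_prevalence_scale` adds geographic
  gradients.  Smoker status is Bernoulli per adult; an optional
  within-household correlation replaces an adult's uniform draw with a
  household-shared draw with the given probability, preserving marginals.
- `contact` / `cooperation` propensities — constant (optionally by sex) or
  Beta-distributed per adult; default 1.0 (full response) so that
  design-based properties are tested without nonresponse confounding.
  Nonresponse scenarios set these explicitly.
- binary `attributes` among smokers (sex × age tables; defaults
  `daily_smoker`, rising with age, and `plans_to_quit`, falling with age)
  serve as estimands with known truth.

`true_margins` enumerates the exact smoker count per stratum × sex × age
cell; it stands in for the external benchmark source (a prevalence survey)
that a real weighting step would calibrate to.  Using the *true* margins is
deliberate: it isolates the properties of the estimator chain from
benchmark error, which the package does not model.

## Fieldwork simulation

Two protocol elements cannot be reproduced literally and are replaced by
statistically equivalent devices:

- The GPS-seeded random walk has no geography here; it is modelled as a
  uniform random permutation of the cluster's dwellings visited
  systematically (every k-th from a random start; skipped offsets are
  revisited in later passes so the frame can be exhausted).  This preserves
  the approximately-equal household inclusion probability within a stratum
  that the weighting step assumes.
- Next-birthday selection is a uniform random draw among the k same-sex
  smokers: birthdays are uniform over the year, so the rule is an
  equal-probability device and simulating calendars adds nothing testable.

Contact is a household-level event (propensity = household mean of member
propensities) with up to `max_contact_attempts` Bernoulli tries; screener
and selection refusals are optional household-level propensities (default
0); individual refusals come from the respondent's cooperation propensity.
A refusing respondent is *not* replaced within the household by default
(no-substitution rule); an opt-in `replace_unavailable` flag models the
replacement exception for people absent for the whole fieldwork period.
Selections are still recorded when the quota fills mid-household, but no
further interviews are conducted, so completed interviews per cluster never
exceed the quota.  Clusters that exhaust their frame below quota are
returned partially filled with a logged warning.  Multi-household addresses
are treated as single households (the random sub-selection collapses to
identity).

Disposition counts follow the standard accounting ladder: attempted →
contacted → eligibility determined → (no eligibles | eligibles) →
selection → individuals selected → refusals / completions, with internal
consistency enforced by `DispositionCounts.validate`.

## Outcome rates

All seven derived quantities are ratios of disposition rows, computed at
full floating precision; rounding (half-up, 3 decimals for rates, nearest
integer for the estimated eligible-household count) happens only in the
reporting layer.  Two conventions matter and were chosen because they are
the only ones consistent with the published six-country table shipped as a
fixture: the estimated eligible-household count multiplies the *unrounded*
eligibility rate by the attempted-address count, and the household response
rate divides by that unrounded estimate.  A zero denominator yields an
explicit `None` marker, never a silent NaN.  The packaged table's
completed-interview row lists 1003 for Romania while the published sample
sizes list 1001; the calculator takes counts as given and
`cross_check_sample_sizes` surfaces the discrepancy as a warning.

## Weighting chain

1. **Initial**: weight = k, the screener's count of same-sex smokers
   (selection probability 1/k under one-per-sex uniform selection).
2. **Design**: within stratum h, weights are scaled by a single factor so
   that stratum totals are proportional to the stratum adult population —
   the unknown household-inclusion constant of the route sampling cancels
   into the factor.  A stratum with population but no respondents is merged
   into the nearest stratum of the same region, with a warning.
3. **Calibration**: raking over the three margins (stratum, sex, age
   group) is the default — with ~400–1000 respondents and dozens of joint
   cells, joint-cell post-stratification is fragile while raking is robust
   to sparse cells.  Joint-cell mode is available when joint benchmarks are
   supplied; cells below `min_cell_count` (default 5) respondents are
   collapsed with the adjacent age group within stratum × sex.  Tolerance
   is a maximum relative margin error of 1e-8 within 200 IPF iterations;
   non-convergence raises an error carrying the final margin errors.  No
   weight trimming is applied (an optional cap would be a one-line
   post-step; none is reported for the design being modelled, and none is
   needed at these sample sizes).
4. **Rescaling**: weights are multiplied by n/Σw so the country mean is
   exactly 1 (floating tolerance 1e-10), making countries comparable;
   Hájek estimators are invariant to this scale.

Nonresponse adjustment is implicit in calibration; there is no separate
response-propensity step, matching the four-step chain above.

## Rao–Wu rescaled bootstrap

Per replicate and stratum, n_h − 1 of the n_h sampled clusters are drawn
with replacement (a multinomial draw); respondents in cluster c get their
base weight times (n_h/(n_h − 1))·m_c.  E[m_c] = (n_h − 1)/n_h, so replicate
weights are unbiased for the base weights; the probability a respondent's
weight is exactly zero is (1 − 1/n_h)^(n_h − 1), which the test suite checks
empirically.  Variance is (1/B) Σ (θ_b − θ̂)² about the full-sample point
estimate; percentile intervals use type-7 (linear-interpolation) quantiles,
normal intervals θ̂ ± z·SE.  Single-cluster strata are collapsed with the
adjacent stratum of the same region before replication.  By default
replicates are re-raked to the benchmark margins (so the variance carries
the calibration step's effect); a flag disables this for speed or for
fixed-weight variance studies.  A degenerate replicate that rakes slowly is
kept at its best-effort weights with a logged warning rather than aborting
the whole replicate set.

## Simulation studies and problem sizes

`smokesurvey.studies` fixes the study country used for validation: ~40 000
adults, 8 strata (4 regions × 2 urbanization levels) with unequal
populations and a ±10% urban/rural prevalence gradient, 50 equal-sized
frame clusters per stratum (400 total, ~100 adults each), 40 sampled
clusters, quota 10 — about 400 respondents per run, a faithful ~1:2.5
scale-down of a 1000-interview national survey chosen so a 500-replicate
Monte-Carlo study runs in seconds.  The validation suite checks:

- **Recovery** (R = 500 fieldwork draws, full response): the mean of the
  calibrated weighted prevalence estimator falls within 3 Monte-Carlo
  standard errors of the true population value for each configured
  attribute.
- **Calibration correction**: with cooperation 0.9 (men) vs 0.55 (women),
  the design-only estimator of a sex-correlated attribute is materially
  biased and the calibrated estimator strictly less so.
- **Bootstrap validity** (B = 500, fixed non-recalibrated weights so the
  replicated estimator matches the bootstrap's assumption): median
  bootstrap/Monte-Carlo variance ratio over 20 seeds within [0.75, 1.33];
  95% percentile-interval coverage within [0.90, 0.99]; zero-weight
  frequencies at their analytic values within Monte-Carlo error.  The
  with-replacement bootstrap ignores the ~10% without-replacement cluster
  sampling fraction, so ratios modestly above 1 are expected and observed.

What passing these tests does *not* show about real data: benchmark error
(true margins are used), informative nonresponse beyond sex/age/stratum
composition, interviewer and mode effects, frame undercoverage, and any
within-household correlation of outcomes with selection are all outside the
generator's scope.

## Numerical choices

- Half-up decimal rounding (via `decimal.Decimal`) in the reporting layer;
  banker's rounding would mis-reproduce published tables.
- Cluster-allocation ties in largest-remainder apportionment break toward
  larger populations, then frame order.
- All randomness flows through `numpy.random.Generator` seeded per stage
  (population / fieldwork / bootstrap are independent streams in the
  pipeline); identical configuration and seeds give byte-identical CSV
  artifacts.
- Raking operates on precomputed integer category codes (`bincount`), so
  re-raking B = 1000 replicates is cheap; order of respondents never
  affects weights beyond 1e-10 (group sums are order-independent).
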