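# Methods

## Model structure

`diethia` implements a dynamic multi-state life-table (cohort-component)
model in the tradition of DYNAMO-HIA-style health impact assessment. The
population is stratified by single year of age (0–95, closed), sex, and
consumption category of one food group at a time. For each calendar year a
separate life table is maintained for every birth cohort; national results
are the aggregation over cohorts and categories. Health states are the
full joint disease-state space over the D modeled diseases — all 2^D
combinations plus an absorbing dead state — so that one disease's
mortality correctly removes its carriers from the risk pool of every other
disease (competing risks) and multimorbid combinations are tracked
explicitly rather than approximated.

All rates are annual probabilities (risks), not hazards; any
hazard-to-risk conversion is the data producer's responsibility. The two
scenarios of an assessment share one calibrated rate set and differ only
in how the population is distributed across consumption categories.

### Annual cycle

The within-year event order is fixed and documented because the stochastic
validation oracle must replay it exactly:

1. **Incidence.** For every alive joint state S and disease d ∉ S, a
   fraction i_d^c (the category-calibrated incidence) moves to S ∪ {d}.
   Diseases are applied as independent Bernoulli thinnings (product
   expansion), so simultaneous multi-incidence is represented. Of newly
   incident cases of a disease flagged acute (coronary heart disease,
   stroke), the acutely-fatal fraction dies at onset; these deaths count
   as both incident cases and deaths of the year.
2. **Mortality.** Each alive state S dies with probability
   q(S) = min(1, m_other + Σ_{d∈S} μ_d), where μ_d is disease d's excess
   mortality and m_other = m_total − Σ_d π_d μ_d is other-cause mortality
   (total mortality minus prevalence-weighted excess, floored at zero with
   a logged warning). Newly incident cases are exposed to the full-year
   excess mortality of their new state.
3. **Aging and churn.** Survivors age one year; newborn cohorts enter
   disease-free at age 0 at the stated inflow (no migration). A
   risk-factor churn then restores the scenario's category distribution
   among the living at every age and sex, independently of disease state.

Remission is not modeled. Age 95 is terminal: the mortality step kills
everyone at that age, so total mortality at 95 must be 1.

### Why the churn step

Both scenarios hold category prevalences constant over time. A tempting
shortcut fixes each person's category for life, arguing that with
category-constant RRs individual churn cannot matter. That argument fails
under selective mortality: high-RR categories deplete faster, so the
*living* population's category mix drifts away from the prevalences the
scenario is supposed to hold fixed, and cross-sectional rates acquire a
spurious secular trend (visible as a slow drift in reference disease-free
life expectancy). The annual state-independent rebalance removes the
drift; with it, the counterfactual's disease-free exit rates are constant
in calendar time and life-expectancy gains evolve only through genuine
prevalence dynamics.

### Calibration and effect sizes

Relative risks act on disease incidence only; diet affects mortality
solely through the presence of disease. Dose–response estimates
RR_u per u g/day convert to category RRs multiplicatively,
RR(Δ) = RR_u^(Δ/u), with the adherent category as reference. Band-wise
age-specific RRs are expanded piecewise-constant over single years; below
the adult minimum age (default 19) RRs are forced to 1 — children carry
exposure but no diet effect, and age into risk at adulthood. Per-category
incidence is normalized so the observed (reference) population reproduces
baseline incidence exactly:

    i^c = i · RR^c / Σ_c p^c RR^c ,

the standard comparative-risk-assessment convention; without it the
reference scenario would contradict the observed epidemiology. The
first-cycle incidence reduction of the counterfactual then equals the
population impact fraction analytically, which the test suite exploits.

### Outcomes

- **Preventable cases**: difference in prevalent cases
  (reference − counterfactual) in a report year, summed over ages and
  scaled per 100,000 persons of that sex alive in the *reference*
  scenario. The label "cases" is read as point prevalence; the cumulative
  incident-case difference is also computed as a secondary column so
  either reading is available. Negative values are meaningful: removing
  one risk factor lengthens survival and mechanically raises later-life
  cases of unrelated diseases.
- **Life expectancy**: period life expectancy at ages 0/50/70 from the
  cross-sectional age-specific mortality of the report year, with a
  half-year person-years credit in the year of death; terminal age 95
  contributes half a year under q = 1.
- **Disease-free life expectancy**: the same life-table machinery applied
  to *exit* from the all-disease-free state (first onset of any modeled
  disease, or death, whichever first; an acutely fatal onset counts
  once). DFLE ≤ LE whenever exit rates dominate mortality rates, which
  holds throughout the tested parameter space.

### Uncertainty analysis

The assessment is repeated (default 100 replicates) with every RR table
redrawn from its 95% confidence interval. Draws are lognormal with median
at the point estimate and ln-scale sd (ln CI_high − ln CI_low)/(2·1.959964)
— the standard choice for ratio measures; a degenerate CI reproduces the
point estimate exactly. All cells of one table (categories × age bands)
share a single standard-normal deviate, since they descend from one
dose–response estimate and independent cell-level draws would scramble the
category ordering; draws for different disease endpoints are independent
(the correlation structure across endpoints is unknown; independence is
declared). Substreams are keyed by (master seed, replicate index, CRC of
food-group:disease), so adding or removing a disease never perturbs other
draws. 95% uncertainty intervals are empirical 2.5th/97.5th percentiles
with linear interpolation between order statistics.

## Synthetic data

The generator produces complete, internally consistent input bundles with
known ground truth:

- **Consumption** is zero-inflated and right-skewed: a point mass π₀ at
  zero plus a gamma positive component per sex. Defaults emulate a
  processed-meat-like group with a 0 g/day recommendation: π₀ = 0.186
  (women) / 0.130 (men), gamma shape/scale 1.432/34.25 and 1.397/49.11,
  chosen to match survey medians and interquartile ranges of roughly
  28.9 (7.7–59.0) and 44.3 (17.0–86.5) g/day. Survey size defaults to
  1,000 persons per sex over ages 19–79.
- **Exposure categories**: one adherent category plus tertiles of the
  non-adherent intakes (four categories total, configurable);
  representative intakes are within-category medians, robust to the skew.
  Sparse single-year strata borrow prevalences from a widening pooled-sex
  age window; children reuse the youngest adult stratum.
- **Epidemiology**: three diseases by default — an acute
  coronary-heart-disease-like endpoint (acutely fatal fraction 0.2), a
  non-acute type-2-diabetes-like endpoint, and an RR-1 lung-cancer-like
  bystander that makes larger-population effects observable. Incidence
  and prevalence are logistic in age, excess mortality grows
  exponentially in adulthood, and total (Gompertz) mortality dominates
  prevalence-weighted excess at every age so other-cause mortality stays
  positive. Dose–response RRs per 50 g/day: CHD 1.18 (1.04–1.33) at ages
  19–64 attenuating to 1.12 (1.01–1.24) at 65+, T2D 1.30 (1.18–1.44)
  attenuating to 1.18 (1.10–1.27).
- **Population**: stationary — counts proportional to survival under the
  Gompertz schedule, 1,000,000 persons total, newborn inflow equal to the
  age-0 count. The engine is deterministic in the population mass, so the
  scale only sets the units of absolute case counts.

What the generator does **not** emulate: survey weights and measurement
error of 24-hour recalls, co-morbidity correlations at initialization
(disease prevalences enter independently), secular trends in consumption
or epidemiology, and migration. Passing tests therefore demonstrate the
correctness of the machinery under the stated statistical structure, not
the realism of any particular national projection.

### Agent-based oracle

An independent stochastic implementation simulates individuals one by one
with the exact cycle order above (Bernoulli incidence, acute death,
state mortality, aging, per-agent category redraw) and Poisson newborn
inflow per batch. Agents are split into independent batches (default 10);
the Monte Carlo standard error of any scalar outcome is estimated from
the spread over batches. The deterministic engine is required to agree
with the oracle within three standard errors at 100,000 agents on
prevalence, death rates, and both life-expectancy measures, in both
scenarios.

## Numerical choices and degenerate inputs

- Problem sizes: default runs use the 96×2 age/sex grid, four categories,
  three diseases (33-state joint space) and a 31-year horizon; a run pair
  takes well under a second, and the 100-replicate uncertainty analysis a
  few seconds, so no scaling-down is needed anywhere.
- Category prevalences must sum to 1 within 1e-9 per stratum; cohort mass
  is conserved to better than 1e-12 relative in practice (tested at 1e-9).
- Calibrated incidences exceeding 1 are clipped with a logged warning;
  negative other-cause mortality is floored at 0 with a warning.
- An all-adherent sample leaves the non-adherent categories empty; they
  receive a rule-consistent placeholder intake and zero prevalence.
- Life tables treat strata with zero alive population as q = 1; report
  years require one extra simulated cycle, so the engine runs
  horizon + 1 cycles and exposes flows *in* the final year.
- Equality-sensitive comparisons (e.g. gains between report years that
  are analytically tied) are made up to 1e-9 absolute, reflecting float
  summation noise, not model tolerance.

## Known limitations

- One food group at a time; effects across food groups are not additive
  and combined scenarios are out of scope.
- No energy-intake adjustment or substitution modeling; no direct
  diet→mortality pathway; no time lag between exposure change and risk
  change (the counterfactual's RR shift is immediate).
- Epidemiology is time-invariant: no treatment trends, no cohort effects
  in consumption.
- The GBD-style mediation method for deriving age-specific RRs from
  metabolic risk factors is not implemented; age-specific RRs enter as
  data.
- Disease prevalences are combined independently at initialization for
  lack of co-morbidity correlation data.
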