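# Methods

`pymslt` estimates the lifetime health gain (QALYs) and net health-system
cost of a one-off, population-level weight-loss intervention — the mass-media
promotion of smartphone weight-loss apps in New Zealand in 2011 — with a
proportional multistate life table (MSLT), and quantifies parameter
uncertainty by correlated Monte Carlo and tornado decomposition.  This note
records the model, its assumptions, the synthetic data that drive it, and
the numerical and design choices made where the problem left them open.

## Cohort and life-table structure

The model follows the closed national cohort alive in the base year 2011:
444 strata formed by sex × ethnicity (Māori / non-Māori) × single year of
age 0–110.  No births or migration enter after 2011.  Each stratum occupies

* a **main life table** (alive / dead), advanced in annual cycles at the
  stratum's all-cause mortality probability for its attained age, and
* **14 parallel disease life tables** — coronary heart disease, stroke,
  type 2 diabetes, osteoarthritis, and ten cancers (endometrial, kidney,
  liver, esophageal, pancreatic, thyroid, colorectal, breast, ovarian,
  gallbladder) — each a closed three-state system
  (healthy → prevalent → dead-of-disease) driven by annual incidence
  *i*, case fatality *f* and remission *r* (*r* ≡ 0 for the four
  non-cancers; cancer remission represents five-year relative survival).

The annual disease update, per stratum and arm, is

    new_cases  = healthy · i·(1 − PIF)
    remissions = prevalent · r
    deaths     = prevalent · f

with exact conservation of the three states.  Disease tables are run
independently; comorbidity enters only through the (pre-scaled)
disability rates.  Cohorts are simulated for 111 cycles (2011–2121), by
which time the youngest stratum has reached the terminal age 110, where
the all-cause mortality probability is 1 and the cohort closes with
certainty.

Incidence, case fatality and remission carry annual proportional trends
that compound from 2011 and freeze after 2026.

### Coupling of arms

Both arms (business-as-usual, BAU, and intervention) run side by side on
identical inputs; they differ only through the population impact
fractions (PIFs) scaling disease inflow in the intervention arm.  The
main table feels the intervention through the prevalence gap:

* mortality: the intervention arm's all-cause rate is
  `acm − Σ_d f_d·(prev_d,BAU − prev_d,int)`;
* morbidity: its prevalent-YLD rate is
  `pyld − Σ_d dr_d·(prev_d,BAU − prev_d,int)`, clamped to [0, 1].

Anchoring the relief to the BAU arm makes the null intervention an exact
(bitwise) identity: a zero BMI-change profile reproduces the BAU arm to
the last bit, which the test suite asserts.  The prevalence gap may turn
negative decades out (survivors age into disease); at the terminal age
this can nudge the adjusted rate past the closed interval by ~1e-9, which
is clamped (larger violations raise an error as a symptom of incoherent
rates).

Life-years credit deaths half a cycle (midpoint rule) — the within-year
timing is not observable in an annual model, and the midpoint is the
conventional neutral choice.  QALYs weight life-years by one minus the
prevalent-YLD rate.

## Risk model

Exposure is BMI.  Relative risk is flat at 1 up to the theoretical
minimum risk exposure level (TMREL, default BMI 21) and exponential above
it:

    RR(x) = rr_per_unit ^ max(0, x − TMREL)

with `rr_per_unit` specific to disease, sex and (attenuating with) age,
and equal to 1 below attained age 25 in effect: PIFs are forced to zero
under that age.  Stratum BMI is log-normal (right-skewed, as adult BMI
data are), parameterised by arithmetic mean and SD per sex × ethnicity ×
age; the intervention shifts the distribution's location, preserving its
shape.  The PIF for a shift δ is

    PIF = 1 − E[RR(X + δ)] / E[RR(X)].

Two integrators compute these expectations.  The reference (`risk.pif`)
uses adaptive quadrature at relative tolerance 1e-8 over the central
1 − 2×1e-12 mass of the distribution; the exponential risk form has no
finite raw expectation against a log-normal tail, so a truncation
convention is required — any finite Monte Carlo sample is an implicit
truncation of the same kind, and a dedicated test shows agreement with a
10⁶-draw Monte Carlo estimate within 3 Monte Carlo standard errors.  The
engine's vectorised backend uses 48-node Gauss–Legendre quadrature in
quantile space; it agrees with the adaptive reference to better than 1%
relative on the PIF (the residual being the differing tail conventions),
which is far below parameter uncertainty.

**Time lags.** Incidence responds to the *mean* BMI change over a past
window: 0–5 years (inclusive of both endpoints) for the non-cancers,
10–30 years for cancers, with years before the intervention contributing
zero.  Window boundaries are uncertain (±20% SD), drawn per PSA
iteration and rounded to whole years with the non-cancer lower bound
fixed at 0.

## Intervention

A one-off promotion campaign in 2011.  The uptake cascade multiplies four
proportions — smartphone access 74.42%, campaign exposure 77.94%, app
download 13.46% (scaled by the scenario's download multiplier, capped at
1), regular use (10+ uses) 26% — giving 2.03% of overweight/obese adults
effectively intervened on at central values.  Regular users lose 0.43 kg
(95% CI 0.25–0.61), converted to BMI units with the stratum mean height,
and the loss decays back to baseline at 0.03 BMI units per month from the
end of the intervention year (about five months to full regain at this
effect size; a no-decay scenario keeps the loss for life).  The stratum
population-mean BMI change is the product `uptake × overweight
proportion × decayed ΔBMI`; adults only (under-18 strata are untouched),
with disease response further restricted to attained age ≥ 25.
Intervention cost is NZ$2,883,000 (web promotion 72,000 + mass media
2,791,000 + app identification 20,000), charged once in 2011.

## Economics

Annual health-system costs use the staged model: everyone alive and free
of a modelled disease accrues a sex- and age-specific baseline cost;
excess costs attach to the first year after diagnosis, to
otherwise-prevalent years, and to the last six months of life when dying
of a modelled disease (charged in the death year — annual cycles cannot
resolve six months).  The baseline cost applies to the alive fraction net
of prevalent cases; disease deaths come out of the prevalent state, so no
double charging occurs.  Costs and QALYs are discounted year-end at 3%
(0% and 6% in scenarios) to 2011.  Net cost = intervention cost +
discounted difference in projected expenditure, so added longevity buys
added baseline cost.  ICERs are NZ$ per QALY, converted to US$ at the
2011 purchasing-power parity of NZ$1.486 per US$1, with negative-cost /
positive-gain results flagged cost-saving.  Reported results are scoped
to strata aged 25+ in 2011 (younger strata are exact zeros by the risk
age floor) as totals, per-1000-adult rates, overweight/obese-restricted
rates, sex and ethnic-group breakdowns, and directly age-standardized
ethnic rates using the dataset's standard population.

## Synthetic baseline data

No real registry inputs are used; the generator emits a seeded,
NZ-*like* baseline with the statistical structure the analysis needs:

* **Demography:** 4.4 M people, 15% Māori, with a younger Māori age
  structure.
* **Mortality:** Gompertz–Makeham hazard per sex with an infant excess, a
  Māori hazard multiplier (1.6) and a female reduction; converted to
  annual probabilities, mildly noised, forced non-decreasing above age
  60, and set to 1 at age 110.
* **Morbidity:** prevalent-YLD per capita rising with age, Māori ×1.25.
* **BMI:** log-normal per stratum from banded mean/SD templates (5-year
  bands, linearly interpolated at band midpoints); Māori adult means
  +1.8 units.  The overweight/obese proportion is *derived* from the same
  distribution (P[BMI ≥ 25]), so the cascade and the PIF stage see one
  consistent exposure model.
* **Heights:** sex × ethnicity means (1.62–1.77 m) with survey-like SDs.
* **Diseases:** banded rate templates — cardiovascular rates rising
  exponentially with age, diabetes and osteoarthritis incidence peaking
  in mid/late life, cancers at low incidence with remission
  r = max(0, 0.2 − f), giving a ~5-year prevalent sojourn whose fatal
  share approximates one minus five-year relative survival.  Initial
  prevalence is the steady state i/(i+f+r) of the local rates.
* **Coherence:** a calibration pass scales case fatality so that total
  disease deaths (Σ f·prevalence) never exceed 60% of all-cause mortality
  in any stratum; `coherence_check` verifies this bound, rate ranges,
  zero non-cancer remission, and (when an explicit prevalence table is
  supplied) steady-state consistency within 25% relative tolerance.

What the generator does **not** emulate: cohort effects in BMI, real
incidence-prevalence histories (steady-state initialisation overstates
prevalence at young ages), competing-risk structure between diseases,
within-stratum cost heterogeneity, and the actual NZ rate levels.
Passing tests therefore demonstrate the *mechanics and directional
behaviour* of the pipeline — orderings across download multipliers and
discount rates, the no-decay amplification, the equity result, tornado
ranking — not the published absolute QALY or cost totals, which depend on
the non-public national inputs.  On the synthetic baseline the base case
yields a few QALYs and an ICER near NZ$1M/QALY; the qualitative scenario
structure matches the real-data analysis, the levels do not.

## Uncertainty analysis

Each uncertain input is catalogued with a family (beta for proportions,
gamma for costs, log-normal for rates and multiplicative effects, normal
for effect size, trends and heights, uniform for the TMREL fraction) and
is moment-matched from its central value plus an SD, an SD fraction, or a
95% interval (SD = width/3.92).  Log-normals are parameterised from their
*arithmetic* mean and SD.  Disease rates get ±5% multipliers, morbidity
±10%, health-system costs ±10%, intervention cost and cascade/decay
parameters as published (±20% SD where stated).  The ambiguous uniform
(0, 1) TMREL uncertainty is read as an interpolation fraction across BMI
21–23; the base case fixes TMREL at 21.

Draws pass through a Gaussian copula: latent normals with pairwise
correlation 2·sin(π·0.75/6) ≈ 0.765 inside the named correlation group
(intervention cost with smartphone access, campaign exposure and
downloads), so the delivered *rank* correlation is 0.75; marginals are
recovered exactly through each inverse CDF.  Effect-size draws are
truncated at zero (no harmful draws).  Default 2000 draws; 95%
uncertainty intervals are the empirical 2.5th/97.5th percentiles;
probability cost-effective uses the NZ$45,000/QALY threshold (cost-saving
draws count as cost-effective).  Draws that violate the model's numeric
invariants are rejected and counted; more than 1% rejections aborts the
run.  The expected-value reference run places every parameter at its
distribution mean (hence TMREL 22, since the uniform fraction's mean is
0.5), which keeps the degenerate-PSA identity exact.

The tornado varies one parameter group at a time (downloads, effect size,
regular use, relative risks, smartphone access, heights, campaign
exposure, disease rates, morbidity, time lags, TMREL, trends, BMI decay,
intervention costs, health-system costs), holding all others at their
means, and ranks groups by the 2.5–97.5 percentile span of the output
(ΔQALY or net cost).  Ranking, not bar length, is the stable quantity on
synthetic data.

## Problem sizes and runtimes

A full paired run is 111 annual cycles × 444 strata × 14 diseases × 2
arms (~0.13 s).  The packaged acceptance script uses 500 PSA draws and
150 tornado draws per group; the test suite uses 100-draw tornadoes and a
10⁶-sample Monte Carlo PIF oracle.  These sizes give Monte Carlo errors
comfortably below the assertions they support while keeping a full run of
everything in minutes on one core.

## Known limitations

* Steady-state initial prevalence is biologically optimistic at young
  ages and pessimistic right after real epidemiologic transitions.
* Disease tables ignore competing risks between modelled diseases; the
  all-cause table absorbs the interaction only through the coherence cap.
* The exponential RR form is a convention; J-shaped BMI–mortality
  relations are out of scope.
* The heavy-tail truncation of E[RR] is a modelling convention shared by
  any sampled estimate; reported PIFs are insensitive to it at the <1%
  level.
* Annual cycles cannot place within-year events (diagnosis, death,
  last-six-months costs) more finely than the midpoint/death-year rules
  described above.
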