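# Methods

`labelsim` chains five components: a calibrated synthetic survey cohort,
label-effect intake scenarios, an adult dynamic energy-balance weight
model, survey-weighted outcome aggregation, and a discounted cost model.
This note records the model equations, the defaults and why they were
chosen, what the synthetic data does and does not emulate, and the
numerical decisions.

## Synthetic cohort generator

The generator emulates the analytic sample of a cleaned national
nutrition survey of Mexican adults aged 20–59 — not any individual
record.  Only marginal moments and a few orderings are published, so the
joint distribution is a modelling choice:

- **BMI** is log-normal with `(μ, σ)` solved in closed form so the mean
  (28.34 kg/m²) and the obesity prevalence P(BMI ≥ 30) = 0.3381 are both
  hit exactly: with `z = Φ⁻¹(1 − prev)`, σ solves
  `σ²/2 − zσ + ln(30/mean) = 0` (smaller positive root).  Targets with no
  real root are reported as infeasible rather than approximated.  Draws
  are truncated to the plausible window [16, 60) — the survey itself
  excludes BMI ≥ 60, and below ≈ 15.9 the male body-fat regression
  (below) leaves no fat mass.
- **Heights** are sex-specific log-normals around 1.55 m (women) / 1.67 m
  (men), sd_log 0.04; weight is `BMI·height²`, and one multiplicative
  height adjustment pins the weighted mean weight at 72.38 kg exactly.
- **Labelled intakes** (beverage and snack kcal/day) are log-normal with
  `σ_log = 1.0` — chosen so that design-based confidence intervals of the
  intake means have roughly the published widths under a cluster design
  effect of about 2 — multiplied by subgroup factors (age < 40: 1.20 vs
  0.80; men 1.15 vs women 0.87; SES low/middle/high 0.85/1.05/1.10) that
  make younger, male and middle/high-SES adults the heavier consumers,
  then ratio-calibrated to the target weighted means.  Beverage energy is
  capped at 16 servings × 150 kcal (the survey's own exclusion bound);
  snack energy at 3,500 kcal/day, emulating the energy-plausibility
  cleaning that food-frequency pipelines apply (the raw log-normal tail
  would otherwise report impossible 10,000+ kcal/day snack intakes).
- **Total energy** adds a log-normal "all other foods" component sized so
  labelled products average 31.1% of energy; this guarantees
  `beverage + snack ≤ total` record-by-record.
- **Sodium** from labelled products is proportional to category energy
  (0.20 mg/kcal beverages, 1.50 mg/kcal snacks — light for mostly-sugar
  drinks, salty for snacks).  Only its *change* enters the model (through
  the fluid channel), so the level matters little.
- **Survey design**: strata of ~120 records with 2 PSUs each; log-normal
  weights (sd_log 0.30) raked to the obesity margin and to the 48,289,840
  population total.  Raking keeps the weighted prevalence pinned to the
  unweighted one, which a randomized-systematic (Latin-hypercube) sampler
  holds at the target to O(1/n).
- **Dependence**: labelled intake is rank-independent of BMI by default;
  `bmi_intake_rank_corr` switches on a Gaussian-copula dependence if a
  user wants heavier consumers to be heavier people.

What the generator does **not** emulate: item-level diets (category
totals are primitives), regional/urban structure, pregnancy and
lactation (such records are simply never generated; the exclusion stage
still reports the category), intake–BMI dependence (off by default), and
any secular obesity trend.  Tests passing on this cohort therefore
validate the pipeline's arithmetic and the model's response to *these*
study conditions, not the joint distribution of the real survey — the
published prevalence change is reproduced to about 0.5 pp, not exactly,
and that residual is a joint-distribution artifact, not solver error.

Exclusions follow the survey rules — missing/non-positive weight or
height, BMI ≥ 60 kg/m², more than 16 beverage servings/day — applied
first-match-wins so the per-rule counts add up to the input size.

## Scenarios

A scenario is a set of fractional daily intake changes (energy and sodium
per category), applied as a step at t = 0 and held constant over the
horizon.  Stratified (Chilean-style) scenarios split the beverage change
between "high in" and "not high in" shares of beverage energy; the share
defaults to 0.80 under Chilean stage-1 limits and 0.90 under the stricter
Mexican limits.  The shipped per-100 g / per-100 mL nutrient limits are
**illustrative placeholders** — the official legal values should be
supplied via config or CSV; classification uses a strict `>` comparison
(a product exactly at a limit carries no label), switchable to `≥`.
Sensitivity scenarios vary one axis at a time: beverage-axis scenarios
keep snacks at the main-scenario values, and vice versa.  The Chilean
aggregate scenario leaves beverage sodium unchanged (its source reports
no sodium effect).

## Weight-change model

State per adult: fat `F`, lean `L`, glycogen `G`, extracellular fluid
`ECF`, adaptive thermogenesis `AT`; body weight
`BW = F + L + (1 + h_G)·G + ECF` with `h_G = 2.7` g water per g glycogen.

- Partition: `p = C/(C + F)`, `C = 10.4·ρ_L/ρ_F ≈ 2.0 kg` — the Forbes
  rule; p is the fraction of tissue-directed energy going to lean.
- Expenditure: `EE = K + γ_F F + γ_L L + δ_PA·BW + TEF + AT + η_F dF/dt
  + η_L dL/dt`, linear in `dF/dt, dL/dt`, hence solved in closed form
  each step.  `TEF = β_TEF·ΔEI`; `τ_AT dAT/dt = β_AT·ΔEI − AT`.
- Glycogen: `dG/dt = (carb_in − k_G G²)/ρ_G` with `k_G` fixed by baseline
  carbohydrate intake (`carb_fraction` = 0.5 of energy, also the assumed
  carbohydrate share of the intake change — it only shapes the small
  glycogen transient).
- Fluid: `dECF/dt = (ΔNa − ξ_Na(ECF − ECF₀) − ξ_CI(1 − EI/EI_b))/Na_conc`.

Defaults (kcal/kg, kcal/kg/day, days, mg/L as appropriate): ρ_F 9,440,
ρ_L 1,816, γ_F 3.2, γ_L 22, η_F 180, η_L 230, β_TEF 0.10, β_AT 0.14,
τ_AT 14, ρ_G 4,180, G₀ 0.5 kg, Na_conc 3,220, ξ_Na 3,000, ξ_CI 4,000 —
the published adult-model values; every one is config-overridable.

**Initialization.**  Fat mass comes from sex-specific regressions of
percent fat on age and ln BMI (women `0.14·age + 39.96·ln BMI − 102.01`;
men `0.14·age + 37.31·ln BMI − 103.94`); ECF starts at 22% of body
weight; lean is the remainder after glycogen and its water.  Baseline
expenditure must equal reported intake (weight stability).  The split of
that total follows predicted requirements, not reported intake: resting
rate from Mifflin-St Jeor, physical activity
`δ_PA·BW = RMR_pred·(PAL·(1−β_TEF) − 1)` at PAL 1.6, and the constant `K`
absorbing the offset between reported intake and predicted expenditure.
Tying `δ_PA` to predicted rather than reported requirements keeps
reporting noise in survey intakes out of the per-kilocalorie response;
with intake-proportional activity the population response is attenuated
about 10% by the heavy intake tail.

**Numerics.**  Classic RK4, dt = 1 day, one continuous integration with
snapshots at exact 365-day multiples (BMI uses the fixed adult height).
Because the intake change is constant, the glycogen equation decouples
into a Riccati equation with an exact tanh solution; it is integrated
analytically and sampled at solver stage times.  This removes the only
stiff direction — its relaxation rate grows with carbohydrate intake and
exceeds the explicit stability limit at dt = 1 for high-intake adults —
while leaving the dynamics unchanged.  The activity load `δ_PA·BW` is
evaluated with ECF at baseline so the sodium/fluid channel never leaks
into fat and lean dynamics.  Halving dt moves 5-year weights by ~1e-7 kg;
RK4 at dt = 1 agrees with forward Euler at dt = 0.01 to ~5e-6 kg; state
variables are clamped at zero (flagged in metadata) rather than aborting,
so population runs survive pathological tail records.

A closed-form plateau serves as an oracle:
`ΔBW_∞ ≈ (1 − β_TEF − β_AT)·ΔEI / ε` with
`ε = q·γ_L + (1−q)·γ_F + δ_PA` and `q` the lean *mass* fraction of the
weight change implied by the Forbes partition,
`q = (p/ρ_L)/(p/ρ_L + (1−p)/ρ_F)`.  For the reference adult (72.38 kg,
BMI 28.34, 2,200 kcal/day) ε ≈ 16.8 per net kilocalorie — equivalently
≈ 22 kcal/kg/day per gross kilocalorie of intake change, the familiar
adult rule of thumb — giving a −1.67 kg plateau for ΔEI = −36.8, ~98%
reached by year 5.

## Outcomes

Prevalence is the survey-weighted fraction with BMI ≥ 30.  Confidence
intervals use a stratified cluster bootstrap: PSU totals are resampled
with replacement within strata (1,000 replicates, seeded); a stratum with
a single PSU triggers a warned fallback to a record-level bootstrap.
Yearly changes are in percentage points against year 0.  The
beverage/snack decomposition reruns the simulation with the other
category's deltas zeroed (matching the additive presentation of the
published tables; at survey scale the two sources add to within 0.2 pp of
the joint run).  Cases averted multiply the prevalence reduction by the
adults living with obesity — 26,174 thousand by default, consistent with
the 37.8% steady-state prevalence applied to a bundled *synthetic*
population projection averaging 69.2 M adults; the horizon assumes
prevalence moves only through the intervention (closed cohort, no
aging-in/out, no secular trend).  Subgroup summaries report relative
(percent-of-baseline) year-5 changes for age bands, sexes and SES levels.

## Costs

Baseline direct and indirect obesity costs are restated from their base
year to 2019 with a national CPI deflator (an approximate series is
bundled; supply the official one for production), discounted 3%/year over
5 years, and converted at 0.05190017 USD/MXP.  Because only the 5-year
USD totals are published (26,591 direct, 17,944 indirect, million USD),
the default inputs invert the discount annuity so the projected stream
reproduces those totals exactly.  Savings multiply end-of-year prevalence
reductions (the within-year convention is a choice; end-of-year is used)
by yearly costs; the benefit–cost ratio divides total savings by the
US$312.6M implementation cost.  Savings are by construction bounded by
the uniform application of the year-1 and final-year reductions.

## Pipeline and reproducibility

All stages run under one master seed; per-stage RNG streams are spawned
from it, so changing the bootstrap replicate count never perturbs cohort
generation.  Report tables carry a SHA-256 hash of the configuration and
are byte-identical across reruns.  Default problem sizes — 6,049 adults,
1,825 daily steps, 1,000 bootstrap replicates — run the full report in
well under a minute on one core.

## Known limitations

- The synthetic joint distribution reproduces published marginals, not
  the real survey: the simulated prevalence reduction runs ~0.4–1.0 pp
  below the published −4.98 pp (the synthetic BMI density just above the
  obesity cutoff is slightly thinner than the real one), and 5-year cost
  savings land ~5–15% below the published −US$1,842M accordingly.
- Purchase-to-consumption conversion, price responses, industry
  reformulation, compliance below 100%, and non-obesity pathways of
  sodium, sugar and fat are out of scope.
- The nutrient-threshold tables are placeholders; "high in" energy shares
  for stratified scenarios are assumptions, not measurements.
- Children and adolescents are excluded; the weight model is adult-only.
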