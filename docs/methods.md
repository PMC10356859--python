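# Methods

`weightbench` validates individualized body-weight prediction models
against weekly clinic weights from a very-low-calorie-diet (VLCD) program:
1200 kcal/day in program week 0, then a 900 kcal/day meal-replacement diet
in weeks 1–7.  This note documents the models, the cohort rules, the
synthetic-data generator, the statistics, and the numerical and design
choices behind them.

## Timebase

Baseline is day 0, the start of the 1200 kcal week.  Intake is
1200 kcal/day on days 0–6 and 900 kcal/day on days 7–55.  "The weight
after program week *w*" is the model weight at day `7·(w+1)`; prediction
series therefore carry weeks 0–7 (days 7–56).  Observed follow-up weights
occupy weeks 1–7; the week −1 (program intake) and week 0 (initiation)
visits are pre-diet and define the baseline weight as their mean (a single
visit is used, and flagged, when only one exists).  Whether the original
clinic measurements fell exactly on this day grid is unknowable from the
published description; the grid above is the simplest consistent mapping
and is used uniformly for observed-vs-expected pairing.

## The dynamic energy-balance model (NIH-BWP)

State variables: fat mass F, lean mass L, glycogen G and extracellular
fluid ECF (kg).  Body weight is `BW = F + L + (1 + h_G)·G + ECF` with
`h_G = 2.7` kg water stored per kg glycogen.  Energy balance:

    ρ_F dF/dt + ρ_L dL/dt + ρ_G dG/dt = I − E

with the fat/lean split along the Forbes curve, `p = C/(C + F)`,
`C = 10.4 kg` (lean share p of the imbalance).  Expenditure

    E = K + γ_F F + γ_L L + δ·BW + β_TEF·I + AT + η_F dF/dt + η_L dL/dt

comprises a constant K calibrated to baseline balance, tissue maintenance
(γ_F = 3.2, γ_L = 22 kcal/kg/d), physical activity proportional to weight
(δ from the physical activity level, PAL), the thermic effect of food
(β_TEF = 0.10), adaptive thermogenesis AT (first-order,
`τ dAT/dt = β_AT ΔI − AT`, β_AT = 0.14, τ = 14 d), and tissue-turnover
costs (η_F = 180, η_L = 230 kcal/kg).  Because E contains dF/dt and dL/dt,
the imbalance is solved in closed form each step.  Glycogen relaxes toward
the level set by carbohydrate intake (`ρ_G dG/dt = CI − k_G G²`, with k_G
fixed by baseline balance); ECF responds to sodium and carbohydrate intake
changes with the standard renal coefficients.  Every constant, unit and
source is listed in `src/weightbench/data/model_constants.yaml`.

Initialization: body-fat percentage from the sex-specific age/ln(BMI)
regressions of Jackson et al. (2002) — the initialization used by the
public planner — clipped to [5, 60]%; glycogen starts at 0.5 kg; ECF is
0.24 × fat-free mass (extracellular water ≈ one third of total body water,
total body water ≈ 73% of FFM); lean mass absorbs the remainder so the
components close to baseline weight exactly.  The exact ECF initialization
of the original publication was not reproducible here; since only ECF
*deviations* enter the dynamics, this choice affects the lean/ECF split of
the expenditure term but not the fluid response.

Baseline calibration: resting metabolic rate from Mifflin-St Jeor;
maintenance intake `I_b = PAL · RMR`; δ and K are set so that the model is
exactly stationary at baseline under I_b.  PAL defaults to 1.4
("sedentary"), the value applied to every participant in this pipeline.
The carbohydrate share of intake, needed by the glycogen and fluid states,
is not published for the program formula; 50% of energy is assumed and
configurable.

## The one-dimensional model (PBRC-WLP)

A single state, body weight W:

    ρ_W dW/dt = I − E(W, I),
    E = (RMR(W) + β_DIT·I) / (1 − s_SPA)

with RMR affine in weight (Mifflin-St Jeor: slope 9.99 kcal/kg/d and a
sex-, age- and height-dependent intercept), dietary-induced thermogenesis
β_DIT = 0.075 of intake, a spontaneous-activity share s_SPA = 0.326 of
total expenditure (both from Thomas et al.'s expenditure decomposition),
and ρ_W = 7700 kcal per kg of mixed-tissue weight change.  The model takes
no activity input: it receives exactly the shared covariates (age, sex,
height, baseline weight, intake).  The exact constants of the distributed
spreadsheet implementation were not available for transcription; the
structure above is the published one-dimensional form, and all validation
statistics treat the model as given.

With these parameterizations the one-dimensional model predicts slightly
*less* week-7 loss than the dynamic model for typical cohort profiles
(e.g. 99.86 vs 99.28 kg for a 46-year-old, 1.64 m, 112.1 kg woman) — the
same direction of disagreement the original cohort comparison reported.

## Integration

Both models use fixed-step classical Runge-Kutta with one step per day by
default.  Intake is piecewise constant on days and steps never straddle a
discontinuity, so halving the step changes week-7 weight by < 1e-5 kg
(the tested tolerance is 0.01 kg) and a 0.1-day oracle agrees to ~1e-6 kg.
The integrator tracks cumulative `∫(I − E) dt` as an extra state, so the
energy-closure identity (tissue energy change equals cumulative imbalance)
is checked to 1e-6 kcal.  Non-finite or non-physical states raise an
error naming the day, step size and state.  The Hall integrator is
vectorized across subjects; per-subject prediction wraps the same
element-wise arithmetic, so batch and single calls agree bit-for-bit.

## Cohort construction

Screening applies the program's rules in listed order, first match wins:
no consent → model-ineligible (age < 18 y, baseline weight > 204.5 kg
(450 lb), height < 1.397 m (55 in)) → missing required variables → no
follow-up weights in weeks 1–7 → non-adherent.  Exclusion conditions are
strict inequalities, so boundary values (exactly 80% usage, exactly
two-thirds attendance, exactly 18 y) are included.  Eligibility uses the
computed baseline weight; records missing usage or attendance data are
non-adherent by default (configurable to raise).  The tally is
mass-conserving by construction and order-independent, and both properties
are tested.

## Synthetic cohort

Demographics: sex Bernoulli(0.735 female); per-sex truncated normals with
the published cohort means/SDs (female 46.1 ± 11.1 y, 64.4 ± 2.5 in,
247.2 ± 47.0 lb; male 48.9 ± 11.1 y, 69.7 ± 2.7 in, 299.5 ± 47.0 lb),
truncated to the eligibility envelope.  Height and weight are drawn
independently given sex (only marginals are published).

Enrollment flow: each record independently receives consent refusal,
an injected eligibility violation, a missing variable, absent follow-up,
or out-of-range adherence, with stage-conditional probabilities equal to
the published stage hazards (409/5057, 66/4648, 3/4582, 9/4579, 869/4570),
so expected flow fractions reproduce the published 26.8% overall exclusion
and its 30.2/4.9/0.2/0.7/64.1% split.

Observed weights: ground truth is the dynamic model (configurable) driven
by the prescribed schedule shifted by a person-level intake bias
~Normal(−250, 450) kcal/day, plus Normal(0, 0.5 kg) scale noise per
weighing; each follow-up week is missing independently with probability
0.05.  The bias defaults were fixed from the models' energy arithmetic: a
250 kcal/day deficit over 56 days maps to ≈ −1.8 kg ≈ −2% relative
difference at week 7, the scale of the published observed-vs-expected
spread; 0.5 kg is a conventional within-person scale repeatability (none
is published for the cohort); 5% weekly missingness reproduces ≈ 97% of
participants with ≥ 5 follow-up weights.  What the generator does *not*
emulate: height-weight correlation, time-varying adherence drift,
within-person intake fluctuation (the bias is constant), digit preference
in scale readings, and secular enrollment trends.  Passing tests therefore
demonstrate the pipeline's arithmetic and calibration under a known
generating process, not the models' accuracy on real patients — the
published cohort statistics serve only as plausibility references.

## Statistics and inference

Per-person accuracy: percent relative weight difference
`100·(O − Ê)/Ê` (negative ⇒ the model underestimated observed loss).
Cohort error: MSE `Σ(O − Ê)²/n` over people at a week, reported in lb² to
match the published scale.  Weekly analyses are available-case.  Summaries
are Tukey-plot statistics — median, quartiles, whiskers at the most
extreme points within 1.5 × IQR of the box — plus mean, SD and 5th/95th
percentiles.  All quantiles use linear interpolation between order
statistics (the numpy default), fixed package-wide and cross-checked
against a brute-force sorted oracle.

Model comparison: percentile bootstrap with 1000 resamples of
*participants* (MSE is defined over people), paired — one subject resample
scored under both models — with 83% intervals (quantiles 8.5 and 91.5);
two MSEs differ at p < 0.05 when the closed intervals do not overlap
(touching endpoints count as overlap, the conservative reading).  Coverage
of the percentile interval is verified by simulation (500 replications,
n = 200, B = 2000) against the nominal 83% within Monte-Carlo error.

## Reproducibility and degenerate inputs

Every stochastic component draws from `numpy.random.default_rng` seeded
from the run configuration; reports embed the config hash and seed.
Degenerate inputs are defined behaviour: constant data yield zero-width
summaries and degenerate bootstrap intervals; weeks with no available
cases are omitted with a warning; empty cohorts, mixed units, nonpositive
expected weights, subject mismatches and infeasible truncation bounds
raise informative errors.

## Known limitations

Both model parameterizations are faithful in structure but cannot be
guaranteed numerically identical to the public web calculator and
spreadsheet; the validation statistics are model-agnostic, so conclusions
about the pipeline do not depend on this.  The program's weeks 8–26,
goal-seeking calculator modes, weight-gain scenarios, children, and
longitudinal (mixed-effects) modelling are out of scope.  Synthetic
headline values (e.g. median week-7 loss ≈ 36 lb) are larger than the
published cohort's 25 lb because the generator inherits the implemented
models' loss predictions plus the negative intake bias.
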