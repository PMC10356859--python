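# Model parameters for the two individualized weight-prediction models.
# Every entry: value, unit, source, and what the parameter means.
# Sources:
#   Hall2011      : Hall KD et al. "Quantification of the effect of energy
#                   imbalance on bodyweight." Lancet 2011;378:826-37 (dynamic
#                   energy-balance model behind the NIH Body Weight Planner).
#   Forbes1987    : Forbes GB. "Lean body mass-body fat interrelationships in
#                   humans." Nutr Rev 1987;45:225-31 (fat/lean partitioning).
#   Jackson2002   : Jackson AS et al. "The effect of sex, age and race on
#                   estimating percentage body fat from body mass index."
#                   Int J Obes 2002;26:789-96 (initial body-fat regression
#                   used by the Body Weight Planner).
#   Mifflin1990   : Mifflin MD et al. "A new predictive equation for resting
#                   energy expenditure in healthy individuals." Am J Clin Nutr
#                   1990;51:241-7.
#   Thomas2011    : Thomas DM et al. "A simple model predicting individual
#                   weight change in humans." J Biol Dyn 2011;5:579-99
#                   (one-dimensional model behind the Pennington Weight Loss
#                   Predictor; expenditure decomposition).
#   Wishnofsky1958: Wishnofsky M. "Caloric equivalents of gained or lost
#                   weight." Am J Clin Nutr 1958;6:542-6 (3500 kcal/lb).
#   physiology    : standard body-composition relations (total body water
#                   ~73% of fat-free mass, extracellular water ~1/3 of total
#                   body water).

hall:
  rho_fat:
    value: 9440.0
    unit: kcal/kg
    source: Hall2011
    description: energy density of body fat change (39.5 MJ/kg)
  rho_lean:
    value: 1807.0
    unit: kcal/kg
    source: Hall2011
    description: energy density of lean-tissue change (7.6 MJ/kg)
  gamma_fat:
    value: 3.2
    unit: kcal/kg/day
    source: Hall2011
    description: resting metabolic rate per kg fat mass (13 kJ/kg/d)
  gamma_lean:
    value: 22.0
    unit: kcal/kg/day
    source: Hall2011
    description: resting metabolic rate per kg lean mass (92 kJ/kg/d)
  eta_fat:
    value: 180.0
    unit: kcal/kg
    source: Hall2011
    description: biochemical cost of fat deposition (750 kJ/kg)
  eta_lean:
    value: 230.0
    unit: kcal/kg
    source: Hall2011
    description: biochemical cost of lean-tissue deposition (960 kJ/kg)
  beta_tef:
    value: 0.10
    unit: dimensionless
    source: Hall2011
    description: thermic effect of food as a fraction of intake
  beta_at:
    value: 0.14
    unit: dimensionless
    source: Hall2011
    description: adaptive-thermogenesis fraction of the intake change
  tau_at:
    value: 14.0
    unit: day
    source: Hall2011
    description: adaptive-thermogenesis first-order time constant
  forbes_c:
    value: 10.4
    unit: kg
    source: Forbes1987
    description: Forbes-curve constant; lean fraction of imbalance p = C/(C+F)
  rho_glycogen:
    value: 4180.0
    unit: kcal/kg
    source: Hall2011
    description: energy density of glycogen (4.18 kcal/g carbohydrate)
  glycogen_init:
    value: 0.5
    unit: kg
    source: Hall2011
    description: baseline glycogen store
  glycogen_water_ratio:
    value: 2.7
    unit: kg water / kg glycogen
    source: Hall2011
    description: water stored per unit of glycogen
  sodium_conc_ecf:
    value: 3220.0
    unit: mg/L
    source: Hall2011
    description: sodium concentration of extracellular fluid
  xi_na:
    value: 3000.0
    unit: mg/L/day
    source: Hall2011
    description: renal response to extracellular-fluid deviation
  xi_ci:
    value: 4000.0
    unit: mg/day
    source: Hall2011
    description: natriuretic effect of a full carbohydrate-intake withdrawal
  sodium_intake_baseline:
    value: 4000.0
    unit: mg/day
    source: Hall2011
    description: baseline dietary sodium; scaled in proportion to intake
  carb_fraction_default:
    value: 0.5
    unit: dimensionless
    source: package default
    description: >
      carbohydrate share of dietary energy assumed for the glycogen and
      extracellular-fluid dynamics; configurable per run
  ecf_fraction_ffm:
    value: 0.24
    unit: dimensionless
    source: physiology
    description: >
      initial extracellular fluid as a fraction of fat-free mass
      (ECW ~ 1/3 of total body water, TBW ~ 0.73 * FFM)
  bodyfat_female_age:
    value: 0.14
    unit: percent/year
    source: Jackson2002
    description: female body-fat regression, age coefficient
  bodyfat_female_lnbmi:
    value: 39.96
    unit: percent
    source: Jackson2002
    description: female body-fat regression, ln(BMI) coefficient
  bodyfat_female_intercept:
    value: -102.01
    unit: percent
    source: Jackson2002
    description: female body-fat regression intercept
  bodyfat_male_age:
    value: 0.14
    unit: percent/year
    source: Jackson2002
    description: male body-fat regression, age coefficient
  bodyfat_male_lnbmi:
    value: 37.31
    unit: percent
    source: Jackson2002
    description: male body-fat regression, ln(BMI) coefficient
  bodyfat_male_intercept:
    value: -103.94
    unit: percent
    source: Jackson2002
    description: male body-fat regression intercept
  pal_default:
    value: 1.4
    unit: dimensionless
    source: package default
    description: physical activity level, "sedentary"

mifflin_st_jeor:
  weight_coef:
    value: 9.99
    unit: kcal/kg/day
    source: Mifflin1990
    description: resting metabolic rate, weight coefficient
  height_coef:
    value: 6.25
    unit: kcal/cm/day
    source: Mifflin1990
    description: resting metabolic rate, height coefficient
  age_coef:
    value: 4.92
    unit: kcal/year/day
    source: Mifflin1990
    description: resting metabolic rate, age coefficient (subtracted)
  male_offset:
    value: 5.0
    unit: kcal/day
    source: Mifflin1990
    description: sex offset for males
  female_offset:
    value: -161.0
    unit: kcal/day
    source: Mifflin1990
    description: sex offset for females

thomas:
  dit_fraction:
    value: 0.075
    unit: dimensionless
    source: Thomas2011
    description: dietary-induced thermogenesis as a fraction of intake
  spa_fraction:
    value: 0.326
    unit: dimensionless
    source: Thomas2011
    description: spontaneous physical activity as a fraction of expenditure
  rho_bodyweight:
    value: 7700.0
    unit: kcal/kg
    source: Wishnofsky1958
    description: energy density of mixed-tissue body-weight change
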