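"""Model constants loaded from the package constants file.

``data/model_constants.yaml`` is the single source of truth: it names every
parameter with its value, unit and literature source.  This module flattens
it into python attributes for the numerical code.
"""

from __future__ import annotations

from importlib import resources

import yaml


def _load() -> dict:
    text = resources.files("weightbench").joinpath("data/model_constants.yaml").read_text()
    return yaml.safe_load(text)


CONSTANTS: dict = _load()


def constant(group: str, name: str) -> float:
    """Look up one parameter value from the constants file."""
    return float(CONSTANTS[group][name]["value"])


# -- Hall dynamic energy-balance model (NIH Body Weight Planner) -------------
RHO_F = constant("hall", "rho_fat")
RHO_L = constant("hall", "rho_lean")
GAMMA_F = constant("hall", "gamma_fat")
GAMMA_L = constant("hall", "gamma_lean")
ETA_F = constant("hall", "eta_fat")
ETA_L = constant("hall", "eta_lean")
BETA_TEF = constant("hall", "beta_tef")
BETA_AT = constant("hall", "beta_at")
TAU_AT = constant("hall", "tau_at")
FORBES_C = constant("hall", "forbes_c")
RHO_G = constant("hall", "rho_glycogen")
G_INIT = constant("hall", "glycogen_init")
H_G = constant("hall", "glycogen_water_ratio")
NA_CONC = constant("hall", "sodium_conc_ecf")
XI_NA = constant("hall", "xi_na")
XI_CI = constant("hall", "xi_ci")
NA_BASELINE = constant("hall", "sodium_intake_baseline")
CARB_FRACTION_DEFAULT = constant("hall", "carb_fraction_default")
ECF_FRACTION_FFM = constant("hall", "ecf_fraction_ffm")
PAL_DEFAULT = constant("hall", "pal_default")

BF_FEMALE_AGE = constant("hall", "bodyfat_female_age")
BF_FEMALE_LNBMI = constant("hall", "bodyfat_female_lnbmi")
BF_FEMALE_INTERCEPT = constant("hall", "bodyfat_female_intercept")
BF_MALE_AGE = constant("hall", "bodyfat_male_age")
BF_MALE_LNBMI = constant("hall", "bodyfat_male_lnbmi")
BF_MALE_INTERCEPT = constant("hall", "bodyfat_male_intercept")

# -- Mifflin-St Jeor resting metabolic rate ----------------------------------
MSJ_WEIGHT = constant("mifflin_st_jeor", "weight_coef")
MSJ_HEIGHT = constant("mifflin_st_jeor", "height_coef")
MSJ_AGE = constant("mifflin_st_jeor", "age_coef")
MSJ_MALE = constant("mifflin_st_jeor", "male_offset")
MSJ_FEMALE = constant("mifflin_st_jeor", "female_offset")

# -- Thomas one-dimensional model (Pennington Weight Loss Predictor) ---------
DIT_FRACTION = constant("thomas", "dit_fraction")
SPA_FRACTION = constant("thomas", "spa_fraction")
RHO_BW = constant("thomas", "rho_bodyweight")
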