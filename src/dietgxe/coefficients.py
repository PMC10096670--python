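"""Default generating parameters for the synthetic cohort.

The effect sizes below are the covariate-adjusted estimates reported by a
large Dutch adult population-cohort analysis (n = 33,047) of an ADHD
polygenic risk score (PRS), diet and other lifestyle behaviours, and a
standardized trait-impulsivity outcome.  They are used as ground truth by
the simulator so that parameter-recovery experiments have a realistic,
documented target.

Coefficient keys are design-matrix term names understood by
:func:`dietgxe.models.term_vector`.  All effects are on the scale of a
standardized impulsivity score (SD units); the PRS is standardized, age is
in years, BMI in kg/m^2, income in euros/month.
"""

from __future__ import annotations

# Basic covariate-adjusted model: impulsivity ~ PRS + demographic, SES,
# health and stress covariates (genetic-control terms generate no signal).
BASIC_MODEL_COEFFS: dict[str, float] = {
    "prs": 0.03,
    "age": -0.021,
    "sex_female": 0.036,
    "bmi": 0.03,
    "neighborhood_ses": -0.011,
    "education_middle": -0.086,
    "education_high": -0.185,
    "income": 2.25e-5,
    "occupational_status": -0.002,
    "disease": -0.016,
    "stress_events": 0.021,
    "longterm_difficulties": 0.091,
    "depression": 0.259,
    "anxiety": 0.156,
}

# Moderator blocks: main effects of each diet/lifestyle moderator, the PRS
# main effect in that model, and the PRS x moderator interaction terms.
# Reference levels (lowest tertile / SUGAR==1 / normal sleep / never smoked /
# abstinent) carry no term.
MODERATOR_MODEL_COEFFS: dict[str, dict[str, float]] = {
    "llds_i": {
        "llds_i_Q2": 0.058,
        "llds_i_Q3": 0.14,
        "prs": 0.025,
        "prs_x_llds_i_Q2": 0.009,
        "prs_x_llds_i_Q3": 0.005,
    },
    "kcal": {
        "kcal_Q2": 0.058,
        "kcal_Q3": 0.128,
        "prs": 0.008,
        "prs_x_kcal_Q2": 0.032,
        "prs_x_kcal_Q3": 0.038,
    },
    "fat": {
        "fat_Q2": 0.065,
        "fat_Q3": 0.145,
        "prs": 0.019,
        "prs_x_fat_Q2": 0.017,
        "prs_x_fat_Q3": 0.016,
    },
    "sugar": {
        "sugar_Q2": 0.001,
        "prs": 0.031,
        "prs_x_sugar_Q2": -0.002,
    },
    "sleep": {
        "sleep_short": 0.078,
        "sleep_long": 0.049,
        "prs": 0.027,
        "prs_x_sleep_short": 0.022,
        "prs_x_sleep_long": 0.011,
    },
    "smoking": {
        "smoking_current": 0.302,
        "smoking_past": 0.208,
        "prs": 0.03,
        "prs_x_smoking_current": -0.012,
        "prs_x_smoking_past": -0.014,
    },
    "alcohol": {
        "alcohol_occasional": 0.091,
        "alcohol_light": 0.267,
        "alcohol_moderate": 0.435,
        "alcohol_heavy": 0.498,
        "prs": 0.025,
        "prs_x_alcohol_occasional": 0.018,
        "prs_x_alcohol_light": -0.001,
        "prs_x_alcohol_moderate": 0.001,
        "prs_x_alcohol_heavy": 0.042,
    },
    "mvpaq": {
        "mvpaq": 0.019,
        "prs": 0.03,
        "prs_x_mvpaq": -0.001,
    },
}

#: Share of impulsivity variance (percent) attributable to the PRS after
#: residualizing on age, sex, chip and genetic PCs, as reported by the
#: two-step procedure in the source cohort.
PRS_VARIANCE_SHARE_PCT = 0.39


def interaction_model_coeffs(moderator: str) -> dict[str, float]:
    """Generating coefficients for a moderator model: basic covariates plus
    the moderator block (the block's PRS main effect replaces the basic one).
    """
    if moderator not in MODERATOR_MODEL_COEFFS:
        raise KeyError(
            f"unknown moderator {moderator!r}; valid: {sorted(MODERATOR_MODEL_COEFFS)}"
        )
    coeffs = dict(BASIC_MODEL_COEFFS)
    coeffs.update(MODERATOR_MODEL_COEFFS[moderator])
    return coeffs


# Population marginals for covariate and exposure generation, calibrated to
# the descriptive characteristics of the same cohort (means/SDs, medians and
# interquartile ranges, class frequencies).
POPULATION: dict[str, float | dict] = {
    "female_fraction": 0.598,
    "age_mean": 42.12,
    "age_sd": 12.35,
    "age_range": (18.0, 90.0),
    "bmi_mean": 25.51,
    "bmi_sd": 4.04,
    "bmi_range": (15.0, 60.0),
    "height_mean": {"male": 1.81, "female": 1.68},
    "height_sd": 0.07,
    "neighborhood_ses_mean": -0.61,
    "neighborhood_ses_sd": 1.08,
    "income_mean": 1641.75,
    "income_sd": 517.12,
    "occupational_status_mean": 43.88,
    "occupational_status_sd": 13.08,
    "education_probs": {"low": 0.255, "middle": 0.408, "high": 0.337},
    "disease_prob": 0.316,
    "depression_prob": 0.025,
    "anxiety_prob": 0.071,
    "stress_events_rate": 1.3,        # Poisson; median 1, IQR [0, 2]
    "longterm_difficulties_rate": 2.6,  # Poisson; median 2, IQR [1, 4]
    # Diet: energy/BMR ratio roughly normal with median 1.28, IQR ~[1.08, 1.50]
    "kcal_ratio_mean": 1.28,
    "kcal_ratio_sd": 0.30,
    # Percent energy from fat: FAT = fat_pct/30 with median 1.18, IQR [1.08, 1.28]
    "fat_pct_mean": 35.4,
    "fat_pct_sd": 4.45,
    # Percent energy from free sugars: lognormal, SUGAR median 1.06, 75th pct 1.43
    "sugar_pct_log_median": 10.6,
    "sugar_pct_log_sd": 0.445,
    # Lifestyle
    "sleep_intercept": 8.0,
    "sleep_age_slope": -0.012,
    "sleep_female_effect": 0.28,
    "sleep_resid_sd": 0.75,
    "mvpa_log_median": 200.0,
    "mvpa_log_sd": 0.95,
    "mvpa_zero_prob": 0.05,
    "alcohol_abstinent_prob": 0.157,
    "alcohol_log_median": 6.0,
    "alcohol_log_sd": 1.1,
    "smoking_probs": {"never": 0.491, "past": 0.316, "current": 0.193},
    # Genotyping chips (Global Screening Array vs CytoSNP, roughly 82/18)
    "chip_probs": {"gsa": 0.82, "cytosnp": 0.18},
    # NEO facet backfill: loadings of the inverted facet z-scores on the
    # latent impulsivity outcome, matching the reported PC structure.
    "facet_loadings": {
        "deliberateness": 0.822,
        "impulsivity": 0.816,
        "self_discipline": 0.678,
        "excitement_seeking": 0.371,
    },
    "facet_mean": 24.0,
    "facet_sd": 5.0,
}

#: 12 LLDS food groups (g per 1000 kcal) and their health polarity.
LLDS_POSITIVE_GROUPS = (
    "vegetables",
    "fruits",
    "whole_grains",
    "legumes_nuts",
    "fish",
    "oils_soft_margarines",
    "unsweetened_dairy",
    "coffee",
    "tea",
)
LLDS_NEGATIVE_GROUPS = (
    "red_processed_meat",
    "butter_hard_margarines",
    "sugar_sweetened_beverages",
)
LLDS_GROUPS = LLDS_POSITIVE_GROUPS + LLDS_NEGATIVE_GROUPS

#: Median g/1000 kcal used when back-filling food-group intakes (plausible
#: magnitudes for a Dutch FFQ; only the within-sample ranking matters for
#: the diet score).
LLDS_GROUP_MEDIANS: dict[str, float] = {
    "vegetables": 60.0,
    "fruits": 55.0,
    "whole_grains": 70.0,
    "legumes_nuts": 15.0,
    "fish": 10.0,
    "oils_soft_margarines": 12.0,
    "unsweetened_dairy": 120.0,
    "coffee": 200.0,
    "tea": 150.0,
    "red_processed_meat": 40.0,
    "butter_hard_margarines": 8.0,
    "sugar_sweetened_beverages": 50.0,
}
LLDS_GROUP_LOG_SD = 0.6
#: Loading of each group's log-intake on a latent diet-healthiness factor;
#: sign follows polarity.  With 12 groups the diet-score variance is
#: 12*Var(quintile score) + pairwise covariances, so a loading of ~0.22
#: (score correlations ~0.05) reproduces the observed SD of ~6 points.
LLDS_FACTOR_LOADING = 0.22
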