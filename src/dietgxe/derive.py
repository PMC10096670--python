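"""Outcome and moderator construction.

Builds the trait-impulsivity score (first principal component of four NEO
facet sum scores), the four unhealthy-diet indices (LLDS-I, KCAL, FAT,
SUGAR) with their censoring and grouping rules, and the lifestyle
classifications (MVPA quintile score, sleep-duration residual deciles,
alcohol and smoking categories).

All sample-relative operations (quintile/tertile/decile cuts, the facet
PCA) are computed on the sample that is passed in; boundary values are
assigned to the lower bin so that the printed half-open group ranges
(e.g. "Q3: KCAL > 1.41") are reproduced exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .coefficients import LLDS_GROUPS, LLDS_NEGATIVE_GROUPS, LLDS_POSITIVE_GROUPS

__all__ = [
    "FACETS",
    "ImpulsivityScore",
    "impulsivity_pc",
    "invert_facet",
    "schofield_bmr",
    "energy_reliability",
    "excess_ratios",
    "llds",
    "tertile_groups",
    "binary_sugar",
    "mvpa_quintile",
    "sleep_class",
    "alcohol_class",
    "smoking_class",
    "derive_moderators",
    "derive_all",
]

#: NEO facet order used throughout; the last two are reverse-keyed.
FACETS = ("impulsivity", "excitement_seeking", "deliberateness", "self_discipline")
INVERTED_FACETS = ("deliberateness", "self_discipline")

FACET_MIN, FACET_MAX = 8, 40


class DegenerateSampleError(ValueError):
    """A sample-relative derivation has no variation to work with."""


def invert_facet(sums):
    """Reflect a Likert facet sum so higher means more impulsive.

    Eight items scored 1-5 give sums in [8, 40]; the reflection 48 - sum
    maps that range onto itself.
    """
    arr = np.asarray(sums)
    if np.any((arr < FACET_MIN) | (arr > FACET_MAX)):
        raise ValueError(f"facet sums must lie in [{FACET_MIN}, {FACET_MAX}]")
    return (FACET_MIN + FACET_MAX) - arr


@dataclass
class ImpulsivityScore:
    """Per-person impulsivity score with the facet loading pattern."""

    score: pd.Series
    loadings: pd.Series          # keyed by facet, inverted facets already reflected
    variance_explained_by_pc1: float


def _pc1(corr: np.ndarray) -> tuple[np.ndarray, float]:
    """Leading eigenvector and variance fraction of a correlation matrix."""
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    return v, float(eigvals[-1] / eigvals.sum())


def impulsivity_pc(
    facets: pd.DataFrame, estimation_sample: pd.DataFrame | None = None
) -> ImpulsivityScore:
    """First principal component of the four facet sum scores.

    ``facets`` needs the columns in :data:`FACETS` (raw sums in [8, 40]).
    Deliberateness and self-discipline are reflected first so every facet
    points toward impulsivity.  The component is extracted from the Pearson
    correlation matrix of the (optionally separate, larger) estimation
    sample, oriented so the impulsivity facet loads positively, and each
    person's score is the standardized projection of their z-scored facets.
    """
    missing = [f for f in FACETS if f not in facets.columns]
    if missing:
        raise KeyError(f"facet columns missing: {missing}")
    est = facets if estimation_sample is None else estimation_sample
    if len(est) < 4:
        raise DegenerateSampleError("need at least 4 complete observations")

    def _oriented(df: pd.DataFrame) -> pd.DataFrame:
        out = df.loc[:, list(FACETS)].astype(float).copy()
        for f in INVERTED_FACETS:
            out[f] = invert_facet(out[f].to_numpy())
        return out

    est_o = _oriented(est)
    sds = est_o.std(ddof=0)
    if (sds == 0).any():
        bad = list(sds.index[sds == 0])
        raise DegenerateSampleError(f"constant facet(s): {bad}")
    corr = est_o.corr().to_numpy()
    v, var_frac = _pc1(corr)
    if v[FACETS.index("impulsivity")] < 0:
        v = -v

    target_o = _oriented(facets)
    z = (target_o - est_o.mean()) / sds
    raw = z.to_numpy() @ v
    score = (raw - raw.mean()) / raw.std(ddof=0)
    return ImpulsivityScore(
        score=pd.Series(score, index=facets.index, name="impulsivity_pc"),
        loadings=pd.Series(v, index=list(FACETS)),
        variance_explained_by_pc1=var_frac,
    )


# --- Schofield basal metabolic rate -------------------------------------

#: Weight+height Schofield coefficients (kcal/day): BMR = a*W(kg) + b*H(m) + c,
#: by sex and adult age band.
SCHOFIELD_WH = {
    ("male", "18-30"): (15.4, -27.0, 717.0),
    ("male", "30-60"): (11.3, 16.0, 901.0),
    ("male", "60+"): (8.8, 1128.0, -1071.0),
    ("female", "18-30"): (13.3, 334.0, 35.0),
    ("female", "30-60"): (8.7, -25.0, 865.0),
    ("female", "60+"): (9.2, 637.0, -302.0),
}


def _age_band(age: np.ndarray) -> np.ndarray:
    bands = np.where(age < 30.0, "18-30", np.where(age < 60.0, "30-60", "60+"))
    return bands


def schofield_bmr(age, sex, weight_kg, height_m):
    """Predicted basal metabolic rate (kcal/day), Schofield weight+height
    equations by sex and adult age band (18-30, 30-60, >=60)."""
    age = np.asarray(age, dtype=float)
    weight = np.asarray(weight_kg, dtype=float)
    height = np.asarray(height_m, dtype=float)
    sex = np.asarray(sex)
    if np.any(age < 18):
        raise ValueError("Schofield bands implemented for adults (age >= 18) only")
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValueError("weight and height must be positive")
    bands = _age_band(age)
    bmr = np.empty(age.shape, dtype=float)
    for (s, band), (a, b, c) in SCHOFIELD_WH.items():
        mask = (sex == s) & (bands == band)
        bmr[mask] = a * weight[mask] + b * height[mask] + c
    unknown = ~np.isin(sex, ["male", "female"])
    if np.any(unknown):
        raise ValueError("sex labels must be 'male' or 'female'")
    return bmr


RELIABILITY_LOW, RELIABILITY_HIGH = 0.79, 2.49


def energy_reliability(energy, bmr):
    """FFQ plausibility filter: True iff energy/BMR lies in [0.79, 2.49]
    (reporting outside roughly +/-2 SD of required energy is excluded;
    the boundaries themselves are retained)."""
    energy = np.asarray(energy, dtype=float)
    bmr = np.asarray(bmr, dtype=float)
    if np.any(bmr <= 0):
        raise ValueError("BMR must be positive")
    if np.any(energy <= 0):
        raise ValueError("non-positive energy intake is not a valid record")
    ratio = energy / bmr
    return (ratio >= RELIABILITY_LOW) & (ratio <= RELIABILITY_HIGH)


WHO_FAT_MAX_PCT = 30.0
WHO_SUGAR_MAX_PCT = 10.0


def excess_ratios(energy, bmr, fat_pct, sugar_pct) -> pd.DataFrame:
    """Energy-excess indices KCAL, FAT, SUGAR, each floored at 1.

    KCAL = energy / Schofield BMR; FAT and SUGAR are percent energy from
    fat / free sugars relative to the WHO maxima (30% and 10%).  Values
    below 1 denote non-excessive intake and are censored to 1, so only the
    excess varies.
    """
    energy = np.asarray(energy, dtype=float)
    bmr = np.asarray(bmr, dtype=float)
    fat_pct = np.asarray(fat_pct, dtype=float)
    sugar_pct = np.asarray(sugar_pct, dtype=float)
    for name, pct in (("fat_pct", fat_pct), ("sugar_pct", sugar_pct)):
        if np.any((pct < 0) | (pct > 100)):
            raise ValueError(f"{name} must lie in [0, 100]")
    kcal = np.maximum(1.0, energy / bmr)
    fat = np.maximum(1.0, fat_pct / WHO_FAT_MAX_PCT)
    sugar = np.maximum(1.0, sugar_pct / WHO_SUGAR_MAX_PCT)
    return pd.DataFrame({"kcal": kcal, "fat": fat, "sugar": sugar})


def _quintile_scores(values: np.ndarray) -> np.ndarray:
    """Within-sample quintile rank scored 0-4; ties get average ranks and
    boundary values fall in the lower bin."""
    pct = stats.rankdata(values, method="average") / len(values)
    return np.digitize(pct, [0.2, 0.4, 0.6, 0.8], right=True)


LLDS_MAX = 48


def llds(groups: pd.DataFrame) -> pd.DataFrame:
    """Lifelines Diet Score and its inversion.

    ``groups`` holds the 12 food-group intakes in g/1000 kcal (columns in
    :data:`~dietgxe.coefficients.LLDS_GROUPS`).  Each of the 9 healthy
    groups scores its within-sample quintile 0-4; the 3 unhealthy groups
    score 4-0.  llds = sum (0-48, higher = healthier); llds_i = 48 - llds
    (higher = poorer diet).
    """
    missing = [g for g in LLDS_GROUPS if g not in groups.columns]
    if missing:
        raise KeyError(f"food-group columns missing: {missing}")
    if len(groups) < 5:
        raise DegenerateSampleError("need >= 5 records to form quintiles")
    total = np.zeros(len(groups), dtype=int)
    for g in LLDS_POSITIVE_GROUPS:
        total += _quintile_scores(groups[g].to_numpy(dtype=float))
    for g in LLDS_NEGATIVE_GROUPS:
        total += 4 - _quintile_scores(groups[g].to_numpy(dtype=float))
    return pd.DataFrame(
        {"llds": total, "llds_i": LLDS_MAX - total}, index=groups.index
    )


TERTILE_LABELS = ("Q1", "Q2", "Q3")


def tertile_groups(values, cuts: tuple[float, float] | None = None):
    """Empirical tertile labels Q1/Q2/Q3; values equal to a cut-point go to
    the lower tertile (half-open ranges, e.g. Q3 strictly above the upper
    cut).  Pass precomputed ``cuts`` to label a superset of the estimation
    sample."""
    arr = np.asarray(values, dtype=float)
    if cuts is None:
        if len(np.unique(arr)) < 3:
            raise DegenerateSampleError("need >= 3 distinct values for tertiles")
        cuts = tuple(np.quantile(arr, [1 / 3, 2 / 3]))
    idx = np.digitize(arr, list(cuts), right=True)
    return np.asarray(TERTILE_LABELS)[idx], cuts


def binary_sugar(sugar):
    """Binary free-sugar grouping: Q1 = non-excessive (SUGAR == 1),
    Q2 = excessive (SUGAR > 1)."""
    arr = np.asarray(sugar, dtype=float)
    if np.any(arr < 1):
        raise ValueError("SUGAR is censored at 1; values below 1 are invalid")
    return np.where(arr > 1.0, "Q2", "Q1")


#: MVPA quintile-score boundaries in minutes/week.  The published band edges
#: print "150-255" followed by "250-420"; a single 255 boundary restores
#: contiguity and is adopted here.
MVPA_CUTS = (60.0, 150.0, 255.0, 420.0)


def mvpa_quintile(minutes):
    """Semi-continuous quintile score 1-5 for weekly MVPA minutes with fixed
    cuts [0,60), [60,150), [150,255), [255,420], (420,inf)."""
    arr = np.asarray(minutes, dtype=float)
    if np.any(arr < 0):
        raise ValueError("MVPA minutes must be non-negative")
    return 1 + np.digitize(arr, MVPA_CUTS, right=False) - (arr == MVPA_CUTS[-1])


def sleep_class(hours, age, sex):
    """Short/normal/long sleep from deciles of sleep residuals on age + sex.

    Sleep need varies with age in a sex-dependent way, so raw-hour cuts
    would misclassify; residuals from a least-squares fit of hours on age
    and sex are ranked instead.  Lowest decile -> short, highest -> long.
    """
    hours = np.asarray(hours, dtype=float)
    age = np.asarray(age, dtype=float)
    female = (np.asarray(sex) == "female").astype(float)
    n = len(hours)
    if n < 20:
        raise DegenerateSampleError("need >= 20 observations for decile classes")
    X = np.column_stack([np.ones(n), age, female])
    beta, *_ = np.linalg.lstsq(X, hours, rcond=None)
    resid = hours - X @ beta
    ranks = stats.rankdata(resid, method="ordinal")
    k = int(round(0.1 * n))
    labels = np.full(n, "normal", dtype=object)
    labels[ranks <= k] = "short"
    labels[ranks > n - k] = "long"
    return labels


ALCOHOL_LABELS = ("abstinent", "occasional", "light", "moderate", "heavy")


def alcohol_class(grams_per_day):
    """Drinking level from alcohol grams/day: abstinent (0), occasional
    (<2.5), light [2.5,15), moderate [15,30), heavy (>=30).  The published
    one-decimal band labels leave [14.9,15) and [29.9,30) unprinted;
    half-open bins close those gaps."""
    arr = np.asarray(grams_per_day, dtype=float)
    if np.any(arr < 0):
        raise ValueError("alcohol intake must be non-negative")
    idx = np.digitize(arr, [2.5, 15.0, 30.0], right=False) + 1
    return np.where(arr == 0, "abstinent", np.asarray(ALCOHOL_LABELS)[idx])


def smoking_class(current, ever_ge_1yr):
    """current > past > never precedence: current if smoked within the past
    month, past if ever smoked for >= 1 year, else never."""
    current = np.asarray(current, dtype=bool)
    ever = np.asarray(ever_ge_1yr, dtype=bool)
    return np.where(current, "current", np.where(ever, "past", "never"))


# --- cohort-level assembly ----------------------------------------------

def derive_moderators(cohort: pd.DataFrame, apply_reliability: bool = True) -> pd.DataFrame:
    """Compute all diet and lifestyle moderators for a raw cohort table.

    Returns one row per record that passes the energy-reliability filter
    (or all records when ``apply_reliability`` is False); sample-relative
    cuts are estimated on the returned (analysis) sample.
    """
    df = cohort
    bmr = schofield_bmr(df["age"], df["sex"], df["weight"], df["height"])
    reliable = energy_reliability(df["energy_kcal"], bmr)
    out = pd.DataFrame(index=df.index)
    out["bmr"] = bmr
    out["reliable"] = reliable
    if apply_reliability:
        out = out.loc[reliable].copy()
        df = df.loc[reliable]
    ratios = excess_ratios(
        df["energy_kcal"], out["bmr"], df["fat_pct"], df["sugar_pct"]
    ).set_index(df.index)
    out[["kcal", "fat", "sugar"]] = ratios
    out[["llds", "llds_i"]] = llds(df[list(LLDS_GROUPS)])
    out["llds_i_tertile"], _ = tertile_groups(out["llds_i"])
    out["kcal_tertile"], _ = tertile_groups(out["kcal"])
    out["fat_tertile"], _ = tertile_groups(out["fat"])
    out["sugar_group"] = binary_sugar(out["sugar"])
    out["mvpaq"] = mvpa_quintile(df["mvpa_minutes"])
    out["sleep_class"] = sleep_class(df["sleep_hours"], df["age"], df["sex"])
    out["alcohol_class"] = alcohol_class(df["alcohol_g_day"])
    out["smoking_class"] = smoking_class(
        df["smoking_current"], df["smoking_ever_ge_1yr"]
    )
    return out


def derive_all(
    cohort: pd.DataFrame,
    estimation_sample: pd.DataFrame | None = None,
    apply_reliability: bool = True,
) -> pd.DataFrame:
    """Moderators plus the facet-PCA impulsivity score, joined with the
    passthrough analysis columns (covariates, PRS, genetic controls)."""
    derived = derive_moderators(cohort, apply_reliability=apply_reliability)
    sub = cohort.loc[derived.index]
    facet_cols = {f"neo_{f}": f for f in FACETS}
    facets = sub[list(facet_cols)].rename(columns=facet_cols)
    est = None
    if estimation_sample is not None:
        est = estimation_sample[list(facet_cols)].rename(columns=facet_cols)
    derived["impulsivity_pc"] = impulsivity_pc(facets, est).score
    passthrough = [
        c
        for c in sub.columns
        if c not in set(facet_cols) | set(LLDS_GROUPS)
    ]
    return sub[passthrough].join(derived)
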