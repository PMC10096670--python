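"""Interaction-regression battery.

Ordinary least-squares models of a standardized impulsivity outcome:

* step 1 — the basic model: PRS plus demographic/SES/health/stress
  covariates and genetic controls (genotyping chip, four genetic PCs and
  chip x PC products);
* step 2 — eight moderator models, one per diet or lifestyle moderator,
  adding the moderator main effects and PRS x moderator products;
* the two-step variance-explained procedure (residualize, then regress
  residuals on the PRS and report adjusted R^2);
* a sensitivity refit that augments a step-2 model with moderator x SES
  products to gauge confounder-interaction inflation.

Interaction tests use a Bonferroni bound of 0.05/4 = 0.0125 (four models
per step).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import statsmodels.api as sm

__all__ = [
    "BONFERRONI_ALPHA",
    "BASIC_COVARIATES",
    "GENETIC_CONTROLS",
    "MODERATOR_TERMS",
    "ModelSpec",
    "ModelResult",
    "term_vector",
    "design_matrix",
    "basic_spec",
    "step2_spec",
    "fit_linear",
    "fit_step2",
    "two_step_r2",
    "sensitivity_ses",
    "simple_impute",
    "report",
]

#: Four step-2a (diet) and four step-2b (lifestyle) models share this bound.
BONFERRONI_ALPHA = 0.05 / 4

#: Dummy terms: name -> (categorical column, level coded 1).
DUMMY_TERMS: dict[str, tuple[str, object]] = {
    "sex_female": ("sex", "female"),
    "education_middle": ("education", "middle"),
    "education_high": ("education", "high"),
    "chip_cytosnp": ("chip", "cytosnp"),
    "llds_i_Q2": ("llds_i_tertile", "Q2"),
    "llds_i_Q3": ("llds_i_tertile", "Q3"),
    "kcal_Q2": ("kcal_tertile", "Q2"),
    "kcal_Q3": ("kcal_tertile", "Q3"),
    "fat_Q2": ("fat_tertile", "Q2"),
    "fat_Q3": ("fat_tertile", "Q3"),
    "sugar_Q2": ("sugar_group", "Q2"),
    "sleep_short": ("sleep_class", "short"),
    "sleep_long": ("sleep_class", "long"),
    "smoking_current": ("smoking_class", "current"),
    "smoking_past": ("smoking_class", "past"),
    "alcohol_occasional": ("alcohol_class", "occasional"),
    "alcohol_light": ("alcohol_class", "light"),
    "alcohol_moderate": ("alcohol_class", "moderate"),
    "alcohol_heavy": ("alcohol_class", "heavy"),
}

#: Continuous terms: name -> data column.
CONTINUOUS_TERMS: dict[str, str] = {
    "prs": "prs",
    "age": "age",
    "bmi": "bmi",
    "neighborhood_ses": "neighborhood_ses",
    "income": "income",
    "occupational_status": "occupational_status",
    "disease": "disease",
    "depression": "depression",
    "anxiety": "anxiety",
    "stress_events": "stress_events",
    "longterm_difficulties": "longterm_difficulties",
    "mvpaq": "mvpaq",
    "pc1": "pc1",
    "pc2": "pc2",
    "pc3": "pc3",
    "pc4": "pc4",
}

BASIC_COVARIATES = (
    "age",
    "sex_female",
    "bmi",
    "neighborhood_ses",
    "income",
    "education_middle",
    "education_high",
    "occupational_status",
    "disease",
    "stress_events",
    "longterm_difficulties",
    "depression",
    "anxiety",
)

GENETIC_CONTROLS = (
    "chip_cytosnp",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "chip_cytosnp_x_pc1",
    "chip_cytosnp_x_pc2",
    "chip_cytosnp_x_pc3",
    "chip_cytosnp_x_pc4",
)

#: Focal moderator terms per step-2 model (reference levels: lowest
#: tertile, SUGAR == 1, normal sleep, never smoked, abstinent).  MVPA
#: enters as a single semi-continuous quintile score.
MODERATOR_TERMS: dict[str, tuple[str, ...]] = {
    "llds_i": ("llds_i_Q2", "llds_i_Q3"),
    "kcal": ("kcal_Q2", "kcal_Q3"),
    "fat": ("fat_Q2", "fat_Q3"),
    "sugar": ("sugar_Q2",),
    "sleep": ("sleep_short", "sleep_long"),
    "smoking": ("smoking_current", "smoking_past"),
    "alcohol": (
        "alcohol_occasional",
        "alcohol_light",
        "alcohol_moderate",
        "alcohol_heavy",
    ),
    "mvpaq": ("mvpaq",),
}

#: SES terms interacted with the moderator in the sensitivity analysis.
SES_TERMS = (
    "neighborhood_ses",
    "income",
    "education_middle",
    "education_high",
    "occupational_status",
)


class UnknownTermError(KeyError):
    pass


class CollinearityError(ValueError):
    pass


def term_vector(data: pd.DataFrame, term: str) -> np.ndarray:
    """Numeric design column for a named term.

    ``a_x_b`` denotes the elementwise product of terms ``a`` and ``b``
    (the product split is resolved left-greedily over known term names).
    """
    if term in CONTINUOUS_TERMS:
        return data[CONTINUOUS_TERMS[term]].to_numpy(dtype=float)
    if term in DUMMY_TERMS:
        col, level = DUMMY_TERMS[term]
        return (data[col] == level).to_numpy(dtype=float)
    if "_x_" in term:
        for i in range(len(term) - 3, 0, -1):
            left, mid, right = term[:i], term[i : i + 3], term[i + 3 :]
            if mid != "_x_":
                continue
            if (left in CONTINUOUS_TERMS or left in DUMMY_TERMS) and right:
                try:
                    return term_vector(data, left) * term_vector(data, right)
                except UnknownTermError:
                    continue
    raise UnknownTermError(f"unknown model term {term!r}")


def design_matrix(data: pd.DataFrame, terms: list[str] | tuple[str, ...]) -> pd.DataFrame:
    """Design matrix (without intercept) for the given ordered terms."""
    return pd.DataFrame(
        {t: term_vector(data, t) for t in terms}, index=data.index
    )


@dataclass
class ModelSpec:
    """Declarative model description: ordered focal terms first (so the
    report reads like a results table), then covariates and genetic
    controls."""

    outcome: str = "impulsivity"
    focal_terms: tuple[str, ...] = ("prs",)
    covariates: tuple[str, ...] = BASIC_COVARIATES
    genetic_controls: tuple[str, ...] = GENETIC_CONTROLS
    name: str = "basic"

    @property
    def terms(self) -> tuple[str, ...]:
        return tuple(self.focal_terms) + tuple(self.covariates) + tuple(
            self.genetic_controls
        )


def basic_spec(outcome: str = "impulsivity") -> ModelSpec:
    return ModelSpec(outcome=outcome)


def step2_spec(moderator: str, outcome: str = "impulsivity") -> ModelSpec:
    if moderator not in MODERATOR_TERMS:
        raise KeyError(
            f"unknown moderator {moderator!r}; valid: {sorted(MODERATOR_TERMS)}"
        )
    mod_terms = MODERATOR_TERMS[moderator]
    focal = mod_terms + ("prs",) + tuple(f"prs_x_{t}" for t in mod_terms)
    return ModelSpec(outcome=outcome, focal_terms=focal, name=f"step2_{moderator}")


@dataclass
class ModelResult:
    """Per-term estimates in results-table layout.

    ``table`` columns: b, ci_low, ci_high, p, beta (standardized
    coefficient), significant (p < alpha).
    """

    table: pd.DataFrame
    n_used: int
    adjusted_r2: float
    alpha: float = BONFERRONI_ALPHA
    name: str = "model"

    def __getitem__(self, term: str) -> pd.Series:
        return self.table.loc[term]


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.column_stack([np.ones(len(X)), X.to_numpy(dtype=float)])
    if len(X) <= arr.shape[1]:
        raise CollinearityError(
            f"n = {len(X)} observations for {arr.shape[1]} parameters"
        )
    rank = np.linalg.matrix_rank(arr)
    if rank < arr.shape[1]:
        # name the columns implicated via QR pivoting
        _, _, piv = scipy.linalg.qr(arr, mode="economic", pivoting=True)
        dropped = [c - 1 for c in piv[rank:] if c > 0]
        names = [X.columns[i] for i in dropped]
        raise CollinearityError(f"design matrix rank deficient; check columns {names}")


def fit_linear(
    spec: ModelSpec, data: pd.DataFrame, alpha: float = BONFERRONI_ALPHA
) -> ModelResult:
    """Ordinary least squares for one model specification.

    Complete cases on all model variables; two-sided t-test p-values and
    95% confidence intervals from the t distribution with residual degrees
    of freedom.  The standardized coefficient for term x is
    B * sd(x) / sd(outcome), computed on the analysis sample (dummy
    columns included).
    """
    X = design_matrix(data, list(spec.terms))
    y = data[spec.outcome].astype(float)
    frame = pd.concat([y.rename("_y"), X], axis=1).dropna()
    if frame.empty:
        raise CollinearityError("no complete cases")
    yv = frame["_y"]
    Xv = frame.drop(columns="_y")
    _check_rank(Xv)
    fit = sm.OLS(yv, sm.add_constant(Xv)).fit()
    ci = fit.conf_int(alpha=0.05)
    sd_y = yv.std(ddof=0)
    table = pd.DataFrame(
        {
            "b": fit.params,
            "ci_low": ci[0],
            "ci_high": ci[1],
            "p": fit.pvalues,
            "beta": fit.params * Xv.std(ddof=0).reindex(fit.params.index) / sd_y,
        }
    ).drop(index="const")
    table["significant"] = table["p"] < alpha
    return ModelResult(
        table=table,
        n_used=int(fit.nobs),
        adjusted_r2=float(fit.rsquared_adj),
        alpha=alpha,
        name=spec.name,
    )


def fit_step2(
    basic: ModelSpec, moderator: str, data: pd.DataFrame,
    alpha: float = BONFERRONI_ALPHA,
) -> ModelResult:
    """One step-2 moderator model: moderator main effects + PRS + PRS x
    moderator products on top of the basic covariate/genetic-control
    block."""
    spec = step2_spec(moderator, outcome=basic.outcome)
    spec = ModelSpec(
        outcome=basic.outcome,
        focal_terms=spec.focal_terms,
        covariates=basic.covariates,
        genetic_controls=basic.genetic_controls,
        name=spec.name,
    )
    return fit_linear(spec, data, alpha=alpha)


#: Residualization terms of the two-step variance-explained procedure.
R2_RESIDUAL_TERMS = (
    "age",
    "sex_female",
    "chip_cytosnp",
    "pc1",
    "pc2",
    "pc3",
    "pc4",
    "chip_cytosnp_x_pc1",
    "chip_cytosnp_x_pc2",
    "chip_cytosnp_x_pc3",
    "chip_cytosnp_x_pc4",
)


def two_step_r2(
    data: pd.DataFrame, outcome: str = "impulsivity", prs: str = "prs"
) -> tuple[float, float]:
    """Percent of outcome variance explained by the PRS, two-step style.

    Step 1 residualizes the outcome on age, sex, genotyping chip, the four
    genetic PCs and chip x PC products; step 2 regresses those residuals
    on the PRS alone.  Returns (adjusted R^2 x 100, PRS-slope p-value).
    Slightly negative adjusted R^2 under the null is reported as computed.
    """
    X1 = design_matrix(data, list(R2_RESIDUAL_TERMS))
    frame = pd.concat(
        [data[outcome].rename("_y"), data[prs].rename("_prs"), X1], axis=1
    ).dropna()
    step1 = sm.OLS(
        frame["_y"], sm.add_constant(frame.drop(columns=["_y", "_prs"]))
    ).fit()
    resid = step1.resid
    step2 = sm.OLS(resid, sm.add_constant(frame["_prs"])).fit()
    return float(step2.rsquared_adj * 100), float(step2.pvalues["_prs"])


def sensitivity_ses(
    spec2: ModelSpec, data: pd.DataFrame, alpha: float = BONFERRONI_ALPHA
) -> tuple[ModelResult, pd.Series]:
    """Refit a step-2 model with moderator x SES product terms added.

    Interactions between the moderator and all four SES indices are
    appended; the attenuation series reports the change in each PRS x
    moderator coefficient relative to the unadjusted step-2 fit (how much
    of the GxE estimate was carried by confounder x exposure structure).
    """
    base = fit_linear(spec2, data, alpha=alpha)
    mod_terms = [
        t for t in spec2.focal_terms if t != "prs" and not t.startswith("prs_x_")
    ]
    candidates = [f"{m}_x_{s}" for m in mod_terms for s in SES_TERMS]
    # constant products (e.g. an education level absent from the sample)
    # carry no information and would only break the design rank
    extra = tuple(
        t for t in candidates if np.std(term_vector(data, t)) > 0
    )
    aug = ModelSpec(
        outcome=spec2.outcome,
        focal_terms=tuple(spec2.focal_terms) + extra,
        covariates=spec2.covariates,
        genetic_controls=spec2.genetic_controls,
        name=f"{spec2.name}_ses_sensitivity",
    )
    result = fit_linear(aug, data, alpha=alpha)
    inter = [t for t in spec2.focal_terms if t.startswith("prs_x_")]
    attenuation = result.table.loc[inter, "b"] - base.table.loc[inter, "b"]
    attenuation.name = "attenuation"
    return result, attenuation


def simple_impute(
    data: pd.DataFrame,
    covariate_columns: list[str] | None = None,
    protected: tuple[str, ...] = ("impulsivity", "prs"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Median/mode single imputation for covariate columns (plumbing; the
    source analysis used chained-equation imputation, which is out of
    scope here).  Outcome and PRS are never imputed: missingness there is
    an error.  Returns (imputed table, per-column imputation report)."""
    out = data.copy()
    for col in protected:
        if col in out.columns and out[col].isna().any():
            raise ValueError(f"missing values in protected column {col!r}")
    cols = covariate_columns
    if cols is None:
        cols = [c for c in out.columns if c not in protected]
    rows = []
    for col in cols:
        n_missing = int(out[col].isna().sum())
        if n_missing == 0:
            continue
        if pd.api.types.is_numeric_dtype(out[col]):
            fill = out[col].median()
        else:
            fill = out[col].mode(dropna=True).iloc[0]
        out[col] = out[col].fillna(fill)
        rows.append({"column": col, "n_imputed": n_missing, "fill": fill})
    return out, pd.DataFrame(rows, columns=["column", "n_imputed", "fill"])


def report(results: list[ModelResult] | dict[str, ModelResult]) -> str:
    """Plain-text results tables: B (95% CI), p, standardized beta, and a
    significance star at the Bonferroni bound."""
    if isinstance(results, dict):
        results = list(results.values())
    if not results:
        raise ValueError("no model results to report")
    chunks = []
    for res in results:
        lines = [
            f"== {res.name} (n = {res.n_used}, adj. R^2 = {res.adjusted_r2:.4f}) ==",
            f"{'term':<28} {'B (95% CI)':<32} {'p':>10}  {'Beta':>8}",
        ]
        for term, row in res.table.iterrows():
            star = " *" if row["significant"] else ""
            bci = f"{row['b']:.3g} ({row['ci_low']:.3g}, {row['ci_high']:.3g})"
            lines.append(
                f"{term:<28} {bci:<32} {row['p']:>10.3g}  {row['beta']:>8.3f}{star}"
            )
        chunks.append("\n".join(lines))
    return "\n\n".join(chunks) + "\n"


def results_frame(results: dict[str, ModelResult]) -> pd.DataFrame:
    """Long-format frame of all model tables (round-trips through CSV)."""
    rows = []
    for name, res in results.items():
        t = res.table.reset_index(names="term")
        t.insert(0, "model", name)
        t["n_used"] = res.n_used
        t["adjusted_r2"] = res.adjusted_r2
        rows.append(t)
    return pd.concat(rows, ignore_index=True)
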