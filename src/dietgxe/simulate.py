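"""Synthetic cohort generator.

Produces seeded GWAS summary statistics, LD-block genotype dosages, an
FFQ-like diet layer, lifestyle variables, covariates and a standardized
impulsivity outcome with the statistical structure the downstream analysis
assumes, so the whole pipeline is testable without access-controlled data.

Generating mechanism
--------------------
Genotypes use a Gaussian copula per LD block: one latent factor per block
and allele copy, with the latent correlation calibrated (via the bivariate
normal rectangle probability) so that the realized *dosage* correlation
within a block matches ``block_r``.  Summary statistics add sampling noise
with variance 1/(gwas_n * 2 * MAF * (1-MAF)) to sparse true log-odds
effects.  The cohort's outcome is a linear model over the *derived*
variables (tertile indicators, lifestyle classes, covariates) with
coefficients supplied in the config — defaults are the published estimates
in :mod:`dietgxe.coefficients` — plus Gaussian noise whose SD is, by
default, calibrated so the outcome variance is ~1.  Raw ingredients
(food-group intakes, energy, fat and sugar percent, NEO facet sums, sleep
hours, MVPA minutes, alcohol grams) are back-filled consistently with each
derived value so the derivation code can be exercised end to end.

An optional gene-environment correlation (rGE) path adds
``rge_gamma * sd(exposure) * PRS`` to each continuous diet exposure, so
cor(PRS, exposure) ~= rge_gamma / sqrt(1 + rge_gamma^2).

All randomness flows from ``SimulationConfig.seed`` through fixed-order
``numpy.random.SeedSequence`` children (genotypes, summary stats,
covariates, exposures, outcome, facets), so identical configs give
bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import stats

from . import derive
from .coefficients import (
    BASIC_MODEL_COEFFS,
    LLDS_FACTOR_LOADING,
    LLDS_GROUP_LOG_SD,
    LLDS_GROUP_MEDIANS,
    LLDS_GROUPS,
    LLDS_NEGATIVE_GROUPS,
    POPULATION,
)
from .genetics import GenotypeData
from .models import UnknownTermError, term_vector

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_genotypes",
    "simulate_summary_stats",
    "simulate_cohort_table",
    "simulate",
    "analysis_table",
    "rge_gamma_for_target_r",
]

_STREAMS = {
    "genotypes": 0,
    "summary_stats": 1,
    "covariates": 2,
    "exposures": 3,
    "outcome": 4,
    "facets": 5,
}


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the analysed cohort: n = 33,047 adults, a discovery
    GWAS of ~225k individuals, and the published generating coefficients
    of the basic covariate model.  ``residual_sd=None`` calibrates the
    noise so the outcome variance is ~1.
    """

    n_samples: int = 33_047
    n_variants: int = 1_000
    n_blocks: int = 50
    block_r: float = 0.5
    causal_fraction: float = 0.3
    effect_sd: float = 0.02
    gwas_n: float = 38_691 + 186_843
    outcome_coefficients: Mapping[str, float] | None = None
    residual_sd: float | None = None
    rge_gamma: float = 0.0
    seed: int = 0
    maf_range: tuple[float, float] = (0.05, 0.5)
    ambiguous_fraction: float = 0.02
    flip_fraction: float = 0.05
    n_duplicate_ids: int = 2
    unreliable_fraction: float = 0.02

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError("n_samples must be >= 1")
        if self.n_blocks > self.n_variants:
            raise ConfigurationError("n_blocks may not exceed n_variants")
        if not 0 <= self.block_r < 1:
            raise ConfigurationError("block_r must lie in [0, 1)")
        if not 0 <= self.causal_fraction <= 1:
            raise ConfigurationError("causal_fraction must lie in [0, 1]")
        if self.residual_sd is not None and self.residual_sd <= 0:
            raise ConfigurationError("residual_sd must be positive")
        if not 0 <= self.unreliable_fraction < 1:
            raise ConfigurationError("unreliable_fraction must lie in [0, 1)")

    def coefficients(self) -> dict[str, float]:
        if self.outcome_coefficients is None:
            return dict(BASIC_MODEL_COEFFS)
        return dict(self.outcome_coefficients)

    def rng(self, stream: str) -> np.random.Generator:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[_STREAMS[stream]])


@dataclass
class SyntheticCohort:
    """Bundle of all simulated tables plus the generating truth."""

    genotypes: GenotypeData
    summary_stats: pd.DataFrame
    cohort: pd.DataFrame
    truth: dict


def rge_gamma_for_target_r(r: float) -> float:
    """Gamma giving cor(PRS, continuous exposure) ~= r before censoring."""
    return r / np.sqrt(1.0 - r * r)


# --- genotype layer ------------------------------------------------------

def _bvn_lower(t1, t2, rho: float, n_nodes: int = 24):
    """P(Z1 <= t1, Z2 <= t2) for standard bivariate normals with
    correlation rho, via the identity dC/drho = bivariate density
    (Gauss-Legendre on [0, rho]); vectorized over t1, t2."""
    t1 = np.asarray(t1, dtype=float)
    t2 = np.asarray(t2, dtype=float)
    base = stats.norm.cdf(t1) * stats.norm.cdf(t2)
    if rho == 0:
        return base
    x, w = leggauss(n_nodes)
    r = 0.5 * rho * (x + 1.0)          # nodes mapped to [0, rho]
    w = 0.5 * rho * w
    t1 = t1[..., None]
    t2 = t2[..., None]
    dens = np.exp(
        -(t1**2 - 2 * r * t1 * t2 + t2**2) / (2 * (1 - r**2))
    ) / (2 * np.pi * np.sqrt(1 - r**2))
    return base + (dens * w).sum(axis=-1)


def _mean_pair_correlation(rho: float, thresholds: np.ndarray, p: np.ndarray) -> float:
    """Mean pairwise phi correlation of allele indicators within a block
    given latent correlation rho."""
    i, j = np.triu_indices(len(p), k=1)
    p11 = _bvn_lower(thresholds[i], thresholds[j], rho)
    phi = (p11 - p[i] * p[j]) / np.sqrt(
        p[i] * (1 - p[i]) * p[j] * (1 - p[j])
    )
    return float(phi.mean())


def _calibrate_latent_rho(mafs: np.ndarray, target_r: float) -> float:
    """Latent equicorrelation such that the mean within-block dosage
    correlation is ~target_r (dosage correlation equals the allele-
    indicator phi correlation because the two allele copies are iid)."""
    if target_r == 0 or len(mafs) < 2:
        return float(target_r)
    t = stats.norm.ppf(mafs)
    hi = 0.999
    if _mean_pair_correlation(hi, t, mafs) < target_r:
        warnings.warn(
            f"block_r={target_r} not attainable for these MAFs; using the "
            "maximum achievable latent correlation",
            stacklevel=2,
        )
        return hi
    lo = 0.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if _mean_pair_correlation(mid, t, mafs) < target_r:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_NON_AMBIGUOUS_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_AMBIGUOUS_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


def simulate_genotypes(config: SimulationConfig) -> GenotypeData:
    """LD-block dosage matrix with variant and sample metadata.

    Within a block, dosages correlate ~block_r; across blocks they are
    independent.  Each sample gets a genotyping-chip label (~82/18 split)
    and four independent standard-normal genetic PCs.
    """
    rng = config.rng("genotypes")
    n, m = config.n_samples, config.n_variants
    mafs = rng.uniform(*config.maf_range, size=m)
    block_edges = np.array_split(np.arange(m), config.n_blocks)

    dosages = np.zeros((n, m), dtype=np.int8)
    for block in block_edges:
        p = mafs[block]
        rho = _calibrate_latent_rho(p, config.block_r)
        t = stats.norm.ppf(p)
        for _copy in range(2):
            f = rng.standard_normal((n, 1))
            e = rng.standard_normal((n, len(block)))
            z = np.sqrt(rho) * f + np.sqrt(1.0 - rho) * e
            dosages[:, block] += z <= t

    alleles = np.array(
        [
            _AMBIGUOUS_PAIRS[rng.integers(len(_AMBIGUOUS_PAIRS))]
            if rng.random() < config.ambiguous_fraction
            else _NON_AMBIGUOUS_PAIRS[rng.integers(len(_NON_AMBIGUOUS_PAIRS))]
            for _ in range(m)
        ]
    )
    chroms = np.empty(m, dtype=object)
    positions = np.empty(m, dtype=np.int64)
    for b, block in enumerate(block_edges):
        chroms[block] = str(b % 22 + 1)
        start = 1_000_000 + (b // 22) * 50_000_000
        positions[block] = start + 5_000 * np.arange(len(block))
    variants = pd.DataFrame(
        {
            "snp": [f"snp{i:05d}" for i in range(m)],
            "chr": chroms,
            "pos": positions,
            "a1": alleles[:, 0],
            "a2": alleles[:, 1],
            "maf": mafs,
            "info": 1.0,
        }
    )
    chip_probs = POPULATION["chip_probs"]
    samples = pd.DataFrame(
        {
            "sample_id": [f"S{i:06d}" for i in range(n)],
            "chip": rng.choice(
                list(chip_probs), size=n, p=list(chip_probs.values())
            ),
        }
    )
    pcs = rng.standard_normal((n, 4))
    for k in range(4):
        samples[f"pc{k + 1}"] = pcs[:, k]
    return GenotypeData(
        dosages=dosages.astype(float), variants=variants, samples=samples
    )


def simulate_summary_stats(
    genotypes: GenotypeData, config: SimulationConfig
) -> pd.DataFrame:
    """Discovery-GWAS summary statistics for the simulated variants.

    True log-odds effects are N(0, effect_sd^2) for a ``causal_fraction``
    of variants, zero elsewhere; observed effects add noise with variance
    1/(gwas_n * 2 * MAF * (1-MAF)) and two-sided p-values follow from the
    implied z.  A fraction of rows is emitted allele-flipped (a1/a2
    swapped, beta negated) and a few duplicated ids stand in for
    multiallelic sites, to exercise QC and harmonization.  The extra
    ``beta_true`` column carries the generating truth in the *genotype*
    allele orientation and is not part of the file schema.
    """
    rng = config.rng("summary_stats")
    var = genotypes.variants
    m = len(var)
    maf = var["maf"].to_numpy()

    causal = rng.random(m) < config.causal_fraction
    beta_true = np.where(causal, rng.normal(0.0, config.effect_sd, size=m), 0.0)
    var_noise = 1.0 / (config.gwas_n * 2.0 * maf * (1.0 - maf))
    se = np.sqrt(var_noise)
    if np.isinf(config.gwas_n):
        beta_obs = beta_true.copy()
        p = np.where(beta_obs != 0, np.finfo(float).tiny, 1.0)
    else:
        beta_obs = beta_true + rng.normal(0.0, se)
        z = beta_obs / se
        p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)

    ss = pd.DataFrame(
        {
            "snp": var["snp"],
            "chr": var["chr"],
            "pos": var["pos"],
            "a1": var["a1"],
            "a2": var["a2"],
            "beta": beta_obs,
            "p": p,
            "freq": maf,
            "info": var["info"],
            "beta_true": beta_true,
        }
    )

    flip = rng.random(m) < config.flip_fraction
    ss.loc[flip, ["a1", "a2"]] = ss.loc[flip, ["a2", "a1"]].to_numpy()
    ss.loc[flip, "beta"] = -ss.loc[flip, "beta"]
    ss.loc[flip, "freq"] = 1.0 - ss.loc[flip, "freq"]

    if config.n_duplicate_ids > 0:
        picks = rng.choice(m, size=min(config.n_duplicate_ids, m), replace=False)
        extra = ss.iloc[picks].copy()
        extra["beta"] = rng.normal(0.0, config.effect_sd, size=len(extra))
        ss = pd.concat([ss, extra], ignore_index=True)
    return ss


# --- cohort layer --------------------------------------------------------

def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    """Truncated normal whose *post-truncation* mean equals ``mean`` (the
    location is shifted to undo the truncation bias, so cohort descriptives
    match their calibration targets)."""
    loc = mean
    for _ in range(8):  # fixed-point iteration, converges in 2-3 steps
        a, b = (lo - loc) / sd, (hi - loc) / sd
        loc = loc - (stats.truncnorm.mean(a, b, loc=loc, scale=sd) - mean)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return stats.truncnorm.rvs(a, b, loc=loc, scale=sd, size=size, random_state=rng)


def _true_prs(genotypes: GenotypeData, summary_stats: pd.DataFrame) -> np.ndarray:
    if "beta_true" not in summary_stats.columns:
        raise ConfigurationError(
            "summary statistics carry no 'beta_true' generating truth"
        )
    truth = summary_stats.drop_duplicates("snp").set_index("snp")["beta_true"]
    beta = truth.reindex(genotypes.variants["snp"]).fillna(0.0).to_numpy()
    raw = genotypes.dosages @ beta
    sd = raw.std()
    if sd == 0:
        return np.zeros(len(raw))
    return (raw - raw.mean()) / sd


def simulate_cohort_table(
    genotypes: GenotypeData,
    summary_stats: pd.DataFrame,
    config: SimulationConfig,
) -> SyntheticCohort:
    """Raw phenotype/exposure/covariate table plus outcome and truth map.

    The outcome is assembled from the derived variables (computed with the
    same code the analysis uses), so the configured coefficients are the
    exact generating values for recovery experiments.  Records drawn as
    energy-unreliable contribute no diet-moderator signal and are meant to
    be excluded upstream of any model fit.
    """
    pop = POPULATION
    n = genotypes.n_samples
    prs = _true_prs(genotypes, summary_stats)
    gamma = config.rge_gamma

    rng_cov = config.rng("covariates")
    female = rng_cov.random(n) < pop["female_fraction"]
    sex = np.where(female, "female", "male")
    age = _truncated_normal(
        rng_cov, pop["age_mean"], pop["age_sd"], *pop["age_range"], size=n
    )
    bmi = _truncated_normal(
        rng_cov, pop["bmi_mean"], pop["bmi_sd"], *pop["bmi_range"], size=n
    )
    height = np.where(
        female,
        rng_cov.normal(pop["height_mean"]["female"], pop["height_sd"], n),
        rng_cov.normal(pop["height_mean"]["male"], pop["height_sd"], n),
    )
    weight = bmi * height**2
    edu_probs = pop["education_probs"]
    education = rng_cov.choice(list(edu_probs), size=n, p=list(edu_probs.values()))
    cohort = pd.DataFrame(
        {
            "sample_id": genotypes.samples["sample_id"].to_numpy(),
            "age": age,
            "sex": sex,
            "bmi": bmi,
            "height": height,
            "weight": weight,
            "neighborhood_ses": rng_cov.normal(
                pop["neighborhood_ses_mean"], pop["neighborhood_ses_sd"], n
            ),
            "income": np.maximum(
                100.0, rng_cov.normal(pop["income_mean"], pop["income_sd"], n)
            ),
            "education": education,
            "occupational_status": rng_cov.normal(
                pop["occupational_status_mean"], pop["occupational_status_sd"], n
            ),
            "disease": (rng_cov.random(n) < pop["disease_prob"]).astype(int),
            "depression": (rng_cov.random(n) < pop["depression_prob"]).astype(int),
            "anxiety": (rng_cov.random(n) < pop["anxiety_prob"]).astype(int),
            "stress_events": rng_cov.poisson(pop["stress_events_rate"], n),
            "longterm_difficulties": rng_cov.poisson(
                pop["longterm_difficulties_rate"], n
            ),
            "chip": genotypes.samples["chip"].to_numpy(),
        }
    ).set_index("sample_id")
    for k in range(1, 5):
        cohort[f"pc{k}"] = genotypes.samples[f"pc{k}"].to_numpy()
    cohort["prs"] = prs

    # exposures (diet + lifestyle); rGE enters the continuous diet layers
    rng_exp = config.rng("exposures")
    bmr = derive.schofield_bmr(age, sex, weight, height)
    ratio = rng_exp.normal(pop["kcal_ratio_mean"], pop["kcal_ratio_sd"], n)
    ratio += gamma * pop["kcal_ratio_sd"] * prs
    # clip strictly inside the plausibility bounds so float round-trips of
    # energy/BMR cannot push a reliable record over the boundary
    ratio = np.clip(ratio, derive.RELIABILITY_LOW + 1e-3, derive.RELIABILITY_HIGH - 1e-3)
    unreliable = rng_exp.random(n) < config.unreliable_fraction
    ratio[unreliable] = rng_exp.choice([0.55, 2.75], size=int(unreliable.sum()))
    cohort["energy_kcal"] = ratio * bmr

    fat_pct = rng_exp.normal(pop["fat_pct_mean"], pop["fat_pct_sd"], n)
    fat_pct += gamma * pop["fat_pct_sd"] * prs
    cohort["fat_pct"] = np.clip(fat_pct, 5.0, 70.0)
    log_sugar = rng_exp.normal(
        np.log(pop["sugar_pct_log_median"]), pop["sugar_pct_log_sd"], n
    )
    log_sugar += gamma * pop["sugar_pct_log_sd"] * prs
    cohort["sugar_pct"] = np.clip(np.exp(log_sugar), 0.1, 60.0)

    # food groups: shared diet-healthiness factor (lower with higher PRS
    # under rGE) plus independent noise, lognormal marginals
    healthiness = rng_exp.standard_normal(n) - gamma * prs
    lam = LLDS_FACTOR_LOADING
    for g in LLDS_GROUPS:
        sign = -1.0 if g in LLDS_NEGATIVE_GROUPS else 1.0
        z = sign * lam * healthiness + np.sqrt(1 - lam**2) * rng_exp.standard_normal(n)
        cohort[g] = np.exp(np.log(LLDS_GROUP_MEDIANS[g]) + LLDS_GROUP_LOG_SD * z)

    mvpa = np.exp(
        rng_exp.normal(np.log(pop["mvpa_log_median"]), pop["mvpa_log_sd"], n)
    )
    mvpa[rng_exp.random(n) < pop["mvpa_zero_prob"]] = 0.0
    cohort["mvpa_minutes"] = mvpa
    cohort["sleep_hours"] = (
        pop["sleep_intercept"]
        + pop["sleep_age_slope"] * age
        + pop["sleep_female_effect"] * female
        + rng_exp.normal(0.0, pop["sleep_resid_sd"], n)
    )
    drinker = rng_exp.random(n) >= pop["alcohol_abstinent_prob"]
    grams = np.exp(
        rng_exp.normal(np.log(pop["alcohol_log_median"]), pop["alcohol_log_sd"], n)
    )
    cohort["alcohol_g_day"] = np.where(drinker, grams, 0.0)
    smoke_u = rng_exp.random(n)
    probs = pop["smoking_probs"]
    cohort["smoking_current"] = (smoke_u < probs["current"]).astype(int)
    cohort["smoking_ever_ge_1yr"] = (
        smoke_u < probs["current"] + probs["past"]
    ).astype(int)

    # outcome from the derived variables
    derived = derive.derive_moderators(cohort, apply_reliability=True)
    frame = cohort.copy()
    for col in (
        "llds_i_tertile", "kcal_tertile", "fat_tertile", "sugar_group",
        "sleep_class", "alcohol_class", "smoking_class",
    ):
        ref = {"sugar_group": "Q1", "sleep_class": "normal",
               "alcohol_class": "abstinent", "smoking_class": "never"}.get(col, "Q1")
        frame[col] = derived[col].reindex(frame.index).fillna(ref)
    frame["mvpaq"] = derive.mvpa_quintile(cohort["mvpa_minutes"])

    coeffs = config.coefficients()
    lp = np.zeros(n)
    for term, value in coeffs.items():
        try:
            lp += value * term_vector(frame, term)
        except UnknownTermError as err:
            raise ConfigurationError(
                f"outcome coefficient for unknown term {term!r}"
            ) from err

    if config.residual_sd is None:
        resid_sd = float(np.sqrt(max(1.0 - lp.var(), 0.0025)))
    else:
        resid_sd = config.residual_sd
    rng_out = config.rng("outcome")
    outcome = lp + rng_out.normal(0.0, resid_sd, n)
    cohort["impulsivity"] = outcome

    # back-fill NEO facet sums consistent with the outcome
    rng_fac = config.rng("facets")
    yz = (outcome - outcome.mean()) / outcome.std()
    loadings = pop["facet_loadings"]
    for facet in derive.FACETS:
        lam_f = loadings[facet]
        fz = lam_f * yz + np.sqrt(1 - lam_f**2) * rng_fac.standard_normal(n)
        raw = np.clip(
            np.rint(pop["facet_mean"] + pop["facet_sd"] * fz),
            derive.FACET_MIN,
            derive.FACET_MAX,
        ).astype(int)
        if facet in derive.INVERTED_FACETS:
            raw = derive.invert_facet(raw)
        cohort[f"neo_{facet}"] = raw

    truth = {
        "seed": config.seed,
        "coefficients": {k: float(v) for k, v in coeffs.items()},
        "residual_sd": resid_sd,
        "linear_predictor_variance": float(lp.var()),
        "rge_gamma": float(gamma),
        "n_samples": int(n),
        "n_reliable": int(len(derived)),
        "n_causal_variants": int((summary_stats["beta_true"] != 0).sum()),
    }
    return SyntheticCohort(
        genotypes=genotypes, summary_stats=summary_stats, cohort=cohort, truth=truth
    )


def simulate(config: SimulationConfig) -> SyntheticCohort:
    """Full simulation: genotypes -> summary statistics -> cohort."""
    genotypes = simulate_genotypes(config)
    ss = simulate_summary_stats(genotypes, config)
    return simulate_cohort_table(genotypes, ss, config)


def analysis_table(sc: SyntheticCohort) -> pd.DataFrame:
    """Model-ready frame: derived moderators + outcome + PRS + covariates,
    restricted to energy-reliable records."""
    return derive.derive_all(sc.cohort)


def write_fixture(
    sc: SyntheticCohort, directory, vcf: bool = False
) -> dict:
    """Write the cohort bundle as plain-text files and return a manifest.

    Emits the summary-stats TSV, genotypes (dosage-TSV trio, or VCF 4.2
    plus the sample sidecar when ``vcf=True``), the raw cohort CSV and the
    generating-truth YAML.  The manifest records the seed and a sha256 per
    file, so reruns of the same config are verifiably byte-identical.
    """
    from pathlib import Path

    from . import io

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ss_path = directory / "summary_stats.tsv"
    io.write_summary_stats(sc.summary_stats, ss_path)
    paths["summary_stats"] = ss_path

    if vcf:
        vcf_path = directory / "genotypes.vcf"
        io.write_vcf(sc.genotypes, vcf_path)
        paths["genotypes"] = vcf_path
        samples_path = directory / "samples.tsv"
        sc.genotypes.samples.to_csv(samples_path, sep="\t", index=False)
        paths["samples"] = samples_path
    else:
        paths.update(io.write_dosage_tsv(sc.genotypes, directory))

    cohort_path = directory / "cohort.csv"
    io.write_cohort_csv(sc.cohort, cohort_path)
    paths["cohort"] = cohort_path

    truth_path = directory / "truth.yaml"
    io.write_yaml(sc.truth, truth_path)
    paths["truth"] = truth_path

    manifest = {
        "seed": sc.truth["seed"],
        "n_samples": sc.truth["n_samples"],
        "n_variants": int(sc.genotypes.n_variants),
        "files": {k: str(p.name) for k, p in paths.items()},
        "sha256": {k: io.file_sha256(p) for k, p in paths.items()},
    }
    io.write_yaml(manifest, directory / "manifest.yaml")
    return manifest
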