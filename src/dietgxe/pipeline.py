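"""End-to-end orchestration.

Sequences the whole analysis: (optional) simulation -> summary-statistic
QC -> LD clumping -> multi-threshold scoring -> PRS-PCA -> outcome and
moderator derivation -> cohort exclusions -> basic model, the eight
moderator models, the two-step variance-explained estimate, SES
sensitivity refits and the rGE correlation screen.  Every stage logs its
record counts so the run manifest reproduces a flowchart-style exclusion
table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import derive, genetics, io, models, simulate

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """All constants of a run; defaults are the published analysis values."""

    simulation: simulate.SimulationConfig | None = None
    # input paths, used when no simulation is requested
    summary_stats_path: str | None = None
    dosages_path: str | None = None
    variants_path: str | None = None
    samples_path: str | None = None
    vcf_path: str | None = None
    cohort_path: str | None = None
    # filter and model constants
    maf_min: float = 0.01
    info_min: float = 0.8
    clump_r2: float = 0.1
    clump_window_kb: int = 250
    thresholds: tuple[float, ...] = genetics.DEFAULT_THRESHOLDS
    alpha: float = models.BONFERRONI_ALPHA
    age_min: float = 18.0
    seed: int = 0
    log_level: str = "INFO"

    def config_hash(self) -> str:
        import hashlib

        payload = repr(sorted(asdict(self).items())).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


DIET_MODERATORS = ("llds_i", "kcal", "fat", "sugar")
LIFESTYLE_MODERATORS = ("sleep", "smoking", "alcohol", "mvpaq")


def _load_inputs(config: RunConfig):
    if config.simulation is not None:
        sc = simulate.simulate(config.simulation)
        return sc.genotypes, sc.summary_stats, sc.cohort
    if config.vcf_path:
        genotypes = io.read_vcf(config.vcf_path, config.samples_path)
    else:
        genotypes = io.read_dosage_tsv(
            config.dosages_path, config.variants_path, config.samples_path
        )
    ss = io.read_summary_stats(config.summary_stats_path)
    cohort = io.read_cohort_csv(config.cohort_path)
    return genotypes, ss, cohort


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute every stage and write all artifacts; returns the manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}

    genotypes, ss_raw, cohort = _load_inputs(config)
    counts["variants_input"] = len(ss_raw)
    counts["cohort_input"] = len(cohort)

    # genetics
    ss_qc, qc_report = genetics.qc_summary_stats(
        ss_raw, maf_min=config.maf_min, info_min=config.info_min, panel=genotypes
    )
    counts.update({f"qc_{k}": v for k, v in qc_report.items()})
    ss_clumped = genetics.ld_clump(
        ss_qc, genotypes, r2_max=config.clump_r2, window_kb=config.clump_window_kb
    )
    counts["variants_clumped"] = len(ss_clumped)
    panel = genetics.score_prs(genotypes, ss_clumped, thresholds=config.thresholds)
    prs = genetics.prs_pca(panel)
    prs_out = panel.scores.copy()
    prs_out["prs"] = prs.score
    prs_out.to_csv(outdir / "prs.csv")
    io.write_yaml(
        {
            "loadings": dict(prs.loadings),
            "variance_explained_by_pc1": prs.variance_explained_by_pc1,
            "snp_counts": dict(panel.snp_counts),
        },
        outdir / "prs_meta.yaml",
    )

    # exclusions + derivation (reliability filter happens inside derive_all)
    adults = cohort.loc[cohort["age"] >= config.age_min]
    counts["excluded_age"] = len(cohort) - len(adults)
    facet_cols = [f"neo_{f}" for f in derive.FACETS]
    complete = adults.dropna(subset=facet_cols + ["energy_kcal"])
    counts["excluded_incomplete"] = len(adults) - len(complete)
    analysis = derive.derive_all(complete)
    counts["excluded_unreliable_ffq"] = len(complete) - len(analysis)
    counts["analysis_n"] = len(analysis)

    # the estimated PRS replaces any simulation-truth column
    analysis["prs"] = prs.score.reindex(analysis.index)
    analysis = analysis.dropna(subset=["prs"])
    analysis.to_csv(outdir / "derived.csv", index_label="sample_id")

    outcome = "impulsivity_pc"
    basic = models.basic_spec(outcome=outcome)
    results: dict[str, models.ModelResult] = {
        "basic": models.fit_linear(basic, analysis, alpha=config.alpha)
    }
    for moderator in DIET_MODERATORS + LIFESTYLE_MODERATORS:
        results[f"step2_{moderator}"] = models.fit_step2(
            basic, moderator, analysis, alpha=config.alpha
        )
    r2_pct, r2_p = models.two_step_r2(analysis, outcome=outcome)

    sensitivity = {}
    for moderator in DIET_MODERATORS:
        spec2 = models.step2_spec(moderator, outcome=outcome)
        _, attenuation = models.sensitivity_ses(spec2, analysis, alpha=config.alpha)
        sensitivity[moderator] = {k: float(v) for k, v in attenuation.items()}

    exposures = analysis[
        ["llds_i", "kcal", "fat", "sugar", "mvpaq"]
    ].join(cohort[["sleep_hours", "alcohol_g_day"]])
    rge = genetics.rge_correlations(analysis["prs"], exposures)
    rge.to_csv(outdir / "rge_correlations.csv", index=False)

    models.results_frame(results).to_csv(outdir / "model_results.csv", index=False)
    (outdir / "report.txt").write_text(models.report(results))

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "counts": counts,
        "two_step_r2_pct": r2_pct,
        "two_step_r2_p": r2_p,
        "ses_sensitivity_attenuation": sensitivity,
        "n_models": len(results),
        "outputs": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    io.write_yaml(manifest, outdir / "manifest.yaml")
    log.info("pipeline complete: %d models, n=%d", len(results), counts["analysis_n"])
    return manifest
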