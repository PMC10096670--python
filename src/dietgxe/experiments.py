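"""Replicated simulation experiments.

Parameter-recovery and calibration studies used by the test suite and the
reproduction script: cohorts are generated under documented generating
coefficients, the corresponding model is re-fit on each, and estimates are
averaged across replicates.  Genotypes use a small independent-variant
panel here — the PRS entering the outcome model is the standardized true
genetic score, so recovery of regression coefficients does not depend on
the LD structure of the panel.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import models
from .coefficients import (
    BASIC_MODEL_COEFFS,
    PRS_VARIANCE_SHARE_PCT,
    interaction_model_coeffs,
)
from .derive import sleep_class
from .simulate import SimulationConfig, analysis_table, simulate

__all__ = [
    "replicate_seeds",
    "recovery_experiment",
    "variance_explained_experiment",
    "short_sleep_share",
]


def replicate_seeds(seed: int, n_reps: int) -> np.ndarray:
    """Independent per-replicate seeds (< 2^31) from one root seed."""
    return np.random.SeedSequence(seed).generate_state(n_reps) >> 1


def _config(coeffs, n_samples: int, seed: int, **overrides) -> SimulationConfig:
    kwargs = dict(
        n_samples=n_samples,
        n_variants=40,
        n_blocks=4,
        block_r=0.0,
        outcome_coefficients=coeffs,
        unreliable_fraction=0.0,
        seed=int(seed),
    )
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


def recovery_experiment(
    moderator: str | None,
    n_reps: int,
    n_samples: int,
    seed: int,
    **config_overrides,
) -> pd.DataFrame:
    """Coefficient estimates across replicates, one row per replicate.

    ``moderator=None`` runs the basic PRS + covariates model under its
    generating coefficients; otherwise the named step-2 moderator model is
    generated and re-fit.  Columns are the focal model terms.
    """
    coeffs = (
        BASIC_MODEL_COEFFS
        if moderator is None
        else interaction_model_coeffs(moderator)
    )
    rows = []
    for rep_seed in replicate_seeds(seed, n_reps):
        sc = simulate(_config(coeffs, n_samples, rep_seed, **config_overrides))
        table = analysis_table(sc)
        spec = models.basic_spec(outcome="impulsivity")
        if moderator is None:
            result = models.fit_linear(spec, table)
        else:
            result = models.fit_step2(spec, moderator, table)
        rows.append(result.table["b"].rename(int(rep_seed)))
    return pd.DataFrame(rows)


def variance_explained_experiment(
    n_reps: int,
    n_samples: int,
    seed: int,
    share_pct: float = PRS_VARIANCE_SHARE_PCT,
) -> np.ndarray:
    """Two-step adjusted R^2 (percent) across replicates.

    The outcome is generated as beta * PRS + noise with
    beta = sqrt(share_pct/100) and unit total variance, so ``share_pct``
    is the true variance share after residualizing on covariates that
    carry no signal.
    """
    coeffs = {"prs": float(np.sqrt(share_pct / 100.0))}
    out = np.empty(n_reps)
    for i, rep_seed in enumerate(replicate_seeds(seed, n_reps)):
        sc = simulate(_config(coeffs, n_samples, rep_seed))
        table = analysis_table(sc)
        out[i], _ = models.two_step_r2(table, outcome="impulsivity")
    return out


def short_sleep_share(n_samples: int, seed: int) -> float:
    """Percent of a synthetic cohort labelled short-sleep by the
    residual-decile rule."""
    sc = simulate(_config(None, n_samples, seed))
    cohort = sc.cohort
    labels = sleep_class(cohort["sleep_hours"], cohort["age"], cohort["sex"])
    return 100.0 * float((labels == "short").mean())
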