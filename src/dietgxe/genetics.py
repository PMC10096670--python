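"""Polygenic-score construction from GWAS summary statistics.

Implements the standard clumping + thresholding (C+T) pipeline: summary-
statistic quality control, greedy LD clumping against a dosage reference
panel, additive scoring at a grid of p-value inclusion thresholds, and
PRS-PCA aggregation (first principal component of the standardized
threshold scores), which avoids picking a single "best" threshold.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "SUMMARY_STAT_COLUMNS",
    "DEFAULT_THRESHOLDS",
    "GenotypeData",
    "PRSPanel",
    "PRSScore",
    "qc_summary_stats",
    "ld_clump",
    "score_prs",
    "prs_pca",
    "rge_correlations",
]

SUMMARY_STAT_COLUMNS = ("snp", "chr", "pos", "a1", "a2", "beta", "p", "freq", "info")
VALID_BASES = frozenset("ACGT")
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: The 11 p-value inclusion thresholds of the aggregated score.
DEFAULT_THRESHOLDS = (
    5e-8, 1e-7, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0,
)


class SummaryStatsFormatError(ValueError):
    pass


class EmptyResultError(ValueError):
    pass


class VariantLookupError(KeyError):
    pass


class AlleleMismatchError(ValueError):
    pass


@dataclass
class GenotypeData:
    """Sample x variant dosage matrix with variant and sample metadata.

    ``dosages`` counts copies of each variant's ``a1`` allele (entries in
    [0, 2], NaN = missing).  ``variants`` columns: snp, chr, pos, a1, a2,
    maf, info.  ``samples`` columns: sample_id, chip, pc1..pc4.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.dosages.shape
        if len(self.variants) != m:
            raise ValueError("variant metadata length != dosage columns")
        if len(self.samples) != n:
            raise ValueError("sample metadata length != dosage rows")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.dosages, initial=0) < 0 or np.nanmax(
                self.dosages, initial=0
            ) > 2:
                raise ValueError("dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass
class PRSPanel:
    """Standardized polygenic scores at each p-value threshold."""

    scores: pd.DataFrame           # n_samples x n_thresholds (standardized)
    thresholds: tuple[float, ...]
    snp_counts: pd.Series          # variants contributing per threshold
    degenerate: tuple[float, ...] = ()  # thresholds dropped (no variants / zero var)
    raw_scores: pd.DataFrame | None = None  # pre-standardization sums


@dataclass
class PRSScore:
    """Final aggregated PRS: standardized PC1 across threshold scores."""

    score: pd.Series
    loadings: pd.Series
    variance_explained_by_pc1: float


def _check_columns(ss: pd.DataFrame) -> None:
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in ss.columns]
    if missing:
        raise SummaryStatsFormatError(f"summary statistics missing columns: {missing}")


def qc_summary_stats(
    ss: pd.DataFrame,
    maf_min: float = 0.01,
    info_min: float = 0.8,
    panel: GenotypeData | None = None,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Quality-control a GWAS summary-statistics table.

    Removes (in order) multiallelic sites (all rows of a duplicated id),
    strand-ambiguous A/T and C/G variants, variants failing the MAF or
    imputation-INFO filters, and — when a target ``panel`` is supplied —
    variants absent from it.  Returns the filtered table and a count
    report per filter.
    """
    _check_columns(ss)
    report = {"input": len(ss)}
    if len(ss) == 0:
        report.update(
            multiallelic=0, ambiguous=0, maf=0, info=0, not_in_panel=0, output=0
        )
        return ss.copy(), report

    bad_alleles = ~(
        ss["a1"].isin(VALID_BASES) & ss["a2"].isin(VALID_BASES)
    )
    if bad_alleles.any():
        line = int(np.flatnonzero(bad_alleles.to_numpy())[0])
        raise SummaryStatsFormatError(
            f"invalid allele code at row {line} (snp={ss['snp'].iloc[line]!r})"
        )

    dup = ss["snp"].duplicated(keep=False)
    out = ss.loc[~dup]
    report["multiallelic"] = int(dup.sum())

    ambiguous = np.fromiter(
        ((a1, a2) in AMBIGUOUS_PAIRS for a1, a2 in zip(out["a1"], out["a2"])),
        dtype=bool,
        count=len(out),
    )
    report["ambiguous"] = int(ambiguous.sum())
    out = out.loc[~ambiguous]

    maf = np.minimum(out["freq"], 1 - out["freq"])
    keep_maf = maf > maf_min
    report["maf"] = int((~keep_maf).sum())
    out = out.loc[keep_maf]

    keep_info = out["info"] > info_min
    report["info"] = int((~keep_info).sum())
    out = out.loc[keep_info]

    if panel is not None:
        in_panel = out["snp"].isin(panel.variants["snp"])
        report["not_in_panel"] = int((~in_panel).sum())
        out = out.loc[in_panel]
    else:
        report["not_in_panel"] = 0

    report["output"] = len(out)
    if len(out) == 0:
        raise EmptyResultError("no variants survived summary-statistic QC")
    return out.reset_index(drop=True), report


def _dosage_r2(dosages: np.ndarray, i: int, others: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between variant column i and each column
    in ``others``, using pairwise-complete samples."""
    x = dosages[:, i]
    out = np.empty(len(others))
    for k, j in enumerate(others):
        y = dosages[:, j]
        mask = ~(np.isnan(x) | np.isnan(y))
        xv, yv = x[mask], y[mask]
        sx, sy = xv.std(), yv.std()
        if sx == 0 or sy == 0:
            out[k] = 0.0
            continue
        r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
        out[k] = r * r
    return out


def ld_clump(
    ss: pd.DataFrame,
    ref: GenotypeData,
    r2_max: float = 0.1,
    window_kb: int = 250,
) -> pd.DataFrame:
    """Greedy LD clumping.

    Repeatedly selects the remaining variant with the smallest p-value as
    an index variant and removes all unselected variants on the same
    chromosome within +/- ``window_kb`` whose squared dosage correlation
    with it is >= ``r2_max``.  Survivors within a window therefore have
    r^2 < r2_max, mirroring the standard PLINK clumping rule.  Ties on p
    are broken toward the smaller genomic position.
    """
    _check_columns(ss)
    idx_in_ref = pd.Index(ref.variants["snp"])
    lookup = ss["snp"].map(pd.Series(np.arange(len(idx_in_ref)), index=idx_in_ref))
    if lookup.isna().any():
        missing = ss.loc[lookup.isna(), "snp"].tolist()
        raise VariantLookupError(f"variants absent from reference panel: {missing}")
    ref_col = lookup.to_numpy(dtype=int)

    order = np.lexsort((ss["pos"].to_numpy(), ss["p"].to_numpy()))
    alive = np.ones(len(ss), dtype=bool)
    selected = np.zeros(len(ss), dtype=bool)
    chrom = ss["chr"].to_numpy()
    pos = ss["pos"].to_numpy()
    window = window_kb * 1000

    for i in order:
        if not alive[i]:
            continue
        selected[i] = True
        near = np.flatnonzero(
            alive
            & ~selected
            & (chrom == chrom[i])
            & (np.abs(pos - pos[i]) <= window)
        )
        if len(near) == 0:
            continue
        r2 = _dosage_r2(ref.dosages, ref_col[i], ref_col[near])
        alive[near[r2 >= r2_max]] = False

    return ss.loc[selected].reset_index(drop=True)


def _harmonized_dosages(genotypes: GenotypeData, ss: pd.DataFrame) -> np.ndarray:
    """Dosage matrix for the ss variants, counted on each ss effect allele.

    Matches by id; if the summary-stat effect allele equals the panel's
    other allele the dosage is flipped (2 - d).  Ambiguous variants are
    assumed to have been removed upstream, so strand flips never arise.
    Missing dosages are mean-imputed per variant so scores stay defined.
    """
    var = genotypes.variants.set_index("snp")
    try:
        panel = var.loc[ss["snp"]]
    except KeyError as err:
        raise VariantLookupError(f"variant absent from genotype panel: {err}") from err
    cols = var.index.get_indexer(ss["snp"])
    d = genotypes.dosages[:, cols].astype(float).copy()
    col_means = np.nanmean(d, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(d))
    d[nan_r, nan_c] = col_means[nan_c]

    same = (ss["a1"].to_numpy() == panel["a1"].to_numpy()) & (
        ss["a2"].to_numpy() == panel["a2"].to_numpy()
    )
    flipped = (ss["a1"].to_numpy() == panel["a2"].to_numpy()) & (
        ss["a2"].to_numpy() == panel["a1"].to_numpy()
    )
    bad = ~(same | flipped)
    if bad.any():
        names = ss.loc[bad, "snp"].tolist()
        raise AlleleMismatchError(f"unresolvable allele mismatch for: {names}")
    d[:, flipped] = 2.0 - d[:, flipped]
    return d


def score_prs(
    genotypes: GenotypeData,
    ss: pd.DataFrame,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> PRSPanel:
    """Additive polygenic scores at each p-value threshold.

    score_i(t) = sum over variants with p <= t of beta_j * dosage_ij,
    then each column is z-standardized.  Thresholds with no qualifying
    variants (or zero score variance) are flagged degenerate and excluded.
    """
    _check_columns(ss)
    thresholds = tuple(sorted(thresholds))
    d = _harmonized_dosages(genotypes, ss)
    beta = ss["beta"].to_numpy(dtype=float)
    p = ss["p"].to_numpy(dtype=float)

    std = {}
    raw = {}
    counts = {}
    degenerate = []
    for t in thresholds:
        include = p <= t
        counts[t] = int(include.sum())
        col = d[:, include] @ beta[include]
        raw[t] = col
        if counts[t] == 0 or col.std() == 0:
            degenerate.append(t)
            warnings.warn(
                f"threshold {t:g}: no usable variants, column excluded", stacklevel=2
            )
            continue
        std[t] = (col - col.mean()) / col.std()

    index = pd.Index(genotypes.samples["sample_id"], name="sample_id")
    return PRSPanel(
        scores=pd.DataFrame(std, index=index),
        thresholds=thresholds,
        snp_counts=pd.Series(counts),
        degenerate=tuple(degenerate),
        raw_scores=pd.DataFrame(raw, index=index),
    )


def prs_pca(panel: PRSPanel) -> PRSScore:
    """Aggregate the threshold scores into one PRS via their first PC.

    The PC is extracted from the correlation matrix of the standardized
    columns, sign-fixed so the mean loading is positive (a higher score
    means higher risk at most thresholds), and re-standardized.
    """
    X = panel.scores.to_numpy(dtype=float)
    keep = X.std(axis=0) > 0
    X = X[:, keep]
    names = panel.scores.columns[keep]
    if X.shape[1] < 2:
        raise ValueError(
            "PRS-PCA needs >= 2 non-degenerate threshold scores; "
            "fall back to a single-threshold score instead"
        )
    Z = (X - X.mean(axis=0)) / X.std(axis=0)
    corr = (Z.T @ Z) / Z.shape[0]
    eigvals, eigvecs = np.linalg.eigh(corr)
    v = eigvecs[:, -1]
    if v.mean() < 0:
        v = -v
    raw = Z @ v
    score = (raw - raw.mean()) / raw.std()
    return PRSScore(
        score=pd.Series(score, index=panel.scores.index, name="prs"),
        loadings=pd.Series(v, index=names),
        variance_explained_by_pc1=float(eigvals[-1] / eigvals.sum()),
    )


def rge_correlations(prs: pd.Series, exposures: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of the PRS with each exposure (gene-environment
    correlation screen); constant exposures are reported with missing r."""
    rows = []
    for name in exposures.columns:
        pair = pd.concat([prs, exposures[name]], axis=1).dropna()
        x, y = pair.iloc[:, 0], pair.iloc[:, 1].astype(float)
        if y.std() == 0 or len(pair) < 3:
            rows.append({"exposure": name, "r": np.nan, "p": np.nan,
                         "note": "constant exposure"})
            continue
        r, pval = stats.pearsonr(x, y)
        rows.append({"exposure": name, "r": r, "p": pval, "note": ""})
    return pd.DataFrame(rows)
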