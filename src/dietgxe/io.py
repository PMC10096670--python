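"""Readers and writers for the pipeline's text formats.

Formats: GWAS summary-statistics TSV (columns ``snp chr pos a1 a2 beta p
freq info``), genotype dosages as either a samples x variants TSV trio
(dosages + variant metadata + sample metadata) or a VCF 4.2 with a DS
FORMAT field, the raw cohort CSV, derived/results CSVs and YAML
configuration/truth files.  Integer and label round-trips are exact;
floats round-trip to full repr precision.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genetics import (
    SUMMARY_STAT_COLUMNS,
    GenotypeData,
    SummaryStatsFormatError,
    VALID_BASES,
)

__all__ = [
    "read_summary_stats",
    "write_summary_stats",
    "read_dosage_tsv",
    "write_dosage_tsv",
    "read_vcf",
    "write_vcf",
    "read_cohort_csv",
    "write_cohort_csv",
    "read_yaml",
    "write_yaml",
    "file_sha256",
]

SAMPLE_COLUMNS = ("sample_id", "chip", "pc1", "pc2", "pc3", "pc4")
VARIANT_COLUMNS = ("snp", "chr", "pos", "a1", "a2", "maf", "info")


def read_summary_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chr": str})
    missing = [c for c in SUMMARY_STAT_COLUMNS if c not in df.columns]
    if missing:
        raise SummaryStatsFormatError(f"{path}: missing columns {missing}")
    for col in ("a1", "a2"):
        bad = ~df[col].isin(VALID_BASES)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise SummaryStatsFormatError(
                f"{path}: malformed allele in column {col!r} at line {line}"
            )
    return df


def write_summary_stats(ss: pd.DataFrame, path: str | Path) -> None:
    ss.loc[:, list(SUMMARY_STAT_COLUMNS)].to_csv(path, sep="\t", index=False)


def write_dosage_tsv(genotypes: GenotypeData, directory: str | Path) -> dict[str, Path]:
    """Writes dosages.tsv (samples x variants, variant-id header),
    variants.tsv and samples.tsv into ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosages": directory / "dosages.tsv",
        "variants": directory / "variants.tsv",
        "samples": directory / "samples.tsv",
    }
    dosage_frame = pd.DataFrame(
        genotypes.dosages,
        index=pd.Index(genotypes.samples["sample_id"], name="sample_id"),
        columns=genotypes.variants["snp"],
    )
    dosage_frame.to_csv(paths["dosages"], sep="\t")
    genotypes.variants.to_csv(paths["variants"], sep="\t", index=False)
    genotypes.samples.to_csv(paths["samples"], sep="\t", index=False)
    return paths


def _read_samples(path: str | Path) -> pd.DataFrame:
    samples = pd.read_csv(path, sep="\t")
    missing = [c for c in SAMPLE_COLUMNS if c not in samples.columns]
    if missing:
        raise ValueError(f"{path}: missing sample columns {missing}")
    return samples


def read_dosage_tsv(
    dosages: str | Path, variants: str | Path, samples: str | Path
) -> GenotypeData:
    dosage_frame = pd.read_csv(dosages, sep="\t", index_col="sample_id")
    var = pd.read_csv(variants, sep="\t", dtype={"chr": str})
    missing = [c for c in VARIANT_COLUMNS if c not in var.columns]
    if missing:
        raise ValueError(f"{variants}: missing variant columns {missing}")
    smp = _read_samples(samples)
    if list(dosage_frame.columns) != list(var["snp"]):
        raise ValueError("dosage header does not match variant metadata order")
    if list(dosage_frame.index) != list(smp["sample_id"]):
        raise ValueError("dosage rows do not match sample metadata order")
    return GenotypeData(
        dosages=dosage_frame.to_numpy(dtype=float), variants=var, samples=smp
    )


def write_vcf(genotypes: GenotypeData, path: str | Path) -> None:
    """VCF 4.2 with per-sample DS (dosage of the ALT allele = counted a1)."""
    path = Path(path)
    var = genotypes.variants
    ids = list(genotypes.samples["sample_id"])
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=AF,Number=A,Type=Float,Description="ALT frequency">\n')
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write(
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="ALT dosage">\n'
        )
        for chrom in dict.fromkeys(var["chr"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(ids) + "\n")
        for j, row in enumerate(var.itertuples(index=False)):
            ds = genotypes.dosages[:, j]
            ds_txt = "\t".join(f"{d:g}" for d in ds)
            fh.write(
                f"{row.chr}\t{row.pos}\t{row.snp}\t{row.a2}\t{row.a1}\t.\tPASS\t"
                f"AF={row.maf:g};R2={row.info:g}\tDS\t{ds_txt}\n"
            )


def read_vcf(path: str | Path, samples: str | Path) -> GenotypeData:
    """Read a DS-field VCF plus the sample sidecar TSV (chip, genetic PCs)."""
    from cyvcf2 import VCF

    smp = _read_samples(samples)
    vcf = VCF(str(path))
    if list(vcf.samples) != list(smp["sample_id"]):
        raise ValueError("VCF sample order does not match sample metadata")
    rows = []
    dosages = []
    for v in vcf:
        rows.append(
            {
                "snp": v.ID,
                "chr": v.CHROM,
                "pos": v.POS,
                "a1": v.ALT[0],
                "a2": v.REF,
                "maf": float(v.INFO.get("AF")),
                "info": float(v.INFO.get("R2")),
            }
        )
        dosages.append(np.asarray(v.format("DS"), dtype=float).ravel())
    var = pd.DataFrame(rows)
    return GenotypeData(
        dosages=np.column_stack(dosages) if dosages else np.empty((len(smp), 0)),
        variants=var,
        samples=smp,
    )


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: cohort CSV needs a 'sample_id' column")
    return df.set_index("sample_id")


def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    cohort.to_csv(path, index=True, index_label="sample_id")


def read_yaml(path: str | Path):
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_yaml(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_plain(obj), fh, sort_keys=True)


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML/JSON dumping."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, Path):
        return str(obj)
    return obj


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(_plain(obj), fh, indent=2, sort_keys=True)
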