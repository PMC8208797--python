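"""Readers and writers for the formats the pipeline touches.

Genotypes come in as VCF (``DS`` dosage preferred, else ``GT`` allele
counts; multi-allelic records are skipped with a warning). Cohort tables,
summary statistics and all result tables are plain TSV; run configuration
is a single TOML file with one section per stage. Every writer/reader
pair round-trips losslessly.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CohortTable, GenotypeMatrix, SchemaError

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

log = logging.getLogger(__name__)

__all__ = [
    "ParseError",
    "CohortSchema",
    "read_vcf",
    "write_vcf",
    "read_cohort_tsv",
    "write_cohort_tsv",
    "write_summary_stats",
    "read_summary_stats",
    "load_config",
]


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending spot."""


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def read_vcf(path, region_filter: tuple[str, int, int] | None = None) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix`.

    The effect allele is ALT; dosage is the ``DS`` FORMAT value when the
    record carries one, otherwise the ALT-allele count from ``GT``
    (missing calls -> NaN). The per-SNP imputation information score is
    taken from the ``INFO`` or ``R2`` INFO keys when present.
    ``region_filter=(chrom, start, end)`` keeps records with
    ``start <= POS <= end`` on ``chrom``.

    Multi-allelic records are skipped with a logged warning.
    """
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises bare OSError/Exception
        raise ParseError(f"{path}: cannot open as VCF ({exc})") from exc

    samples = list(vcf.samples)
    metas: list[dict] = []
    cols: list[np.ndarray] = []
    n_multi = 0
    record_no = 0
    try:
        for var in vcf:
            record_no += 1
            if len(var.ALT) != 1:
                n_multi += 1
                continue
            if region_filter is not None:
                chrom, start, end = region_filter
                if str(var.CHROM) != str(chrom) or not (start <= var.POS <= end):
                    continue
            ds = var.format("DS")
            if ds is not None:
                dose = np.asarray(ds, dtype=float).reshape(-1)
                dose = np.where((dose < 0) | (dose > 2), np.nan, dose)
            else:
                # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
                gt = np.asarray(var.gt_types, dtype=float)
                dose = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
            info_score = var.INFO.get("INFO", var.INFO.get("R2"))
            metas.append({
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "bp": int(var.POS),
                "effect_allele": var.ALT[0],
                "other_allele": var.REF,
                "freq": np.nan,
                "info": float(info_score) if info_score is not None else np.nan,
            })
            cols.append(dose)
    except Exception as exc:
        raise ParseError(f"{path}: malformed VCF near record {record_no}: {exc}") from exc
    finally:
        vcf.close()

    if n_multi:
        log.warning("read_vcf %s: skipped %d multi-allelic records", path, n_multi)
    dosage = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    snps = pd.DataFrame(metas, columns=["id", "chrom", "bp", "effect_allele",
                                        "other_allele", "freq", "info"])
    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)


def write_vcf(geno: GenotypeMatrix, path) -> None:
    """Write a dosage matrix as an uncompressed VCF (GT + DS fields).

    Integer dosages produce exact unphased GT calls; fractional dosages
    get the nearest hard call in GT with the dosage preserved in DS.
    REF is the other allele and ALT the effect allele, matching
    :func:`read_vcf`'s ALT-counts-as-effect convention.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=INFO,Number=1,Type=Float,Description="Imputation information score">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Effect allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(geno.samples) + "\n")
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, snp in geno.snps.iterrows():
            info = "." if not np.isfinite(snp["info"]) else f"INFO={snp['info']:.6g}"
            fields = [str(snp["chrom"]), str(int(snp["bp"])), str(snp["id"]),
                      str(snp["other_allele"]), str(snp["effect_allele"]),
                      ".", "PASS", info, "GT:DS"]
            for d in geno.dosage[:, j]:
                if np.isnan(d):
                    fields.append("./.:.")
                else:
                    fields.append(f"{gt_map[int(round(d))]}:{d:.6g}")
            fh.write("\t".join(fields) + "\n")


# --------------------------------------------------------------------------
# Cohort TSV
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortSchema:
    """Maps TSV columns to roles and declares biomarker units.

    ``biomarkers`` maps column name -> unit string; ``covariates`` lists
    extra adjustment columns; ``categorical`` marks covariates to keep as
    strings (e.g. assessment-centre codes).
    """

    biomarkers: dict[str, str] = field(default_factory=dict)
    covariates: tuple[str, ...] = ()
    categorical: tuple[str, ...] = ()


_NA_STRINGS = ["", "NA", "NaN", "nan", "."]


def read_cohort_tsv(path, schema: CohortSchema = CohortSchema()) -> CohortTable:
    """Read a tab-separated cohort table.

    Mandatory columns: ``id``, ``age``, ``sex``. Optional: ``follow_up_time``
    and ``event`` (event requires follow_up_time), biomarkers and covariates
    per the schema. Unparseable numeric cells become missing and are
    counted in the log.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=_NA_STRINGS,
                     keep_default_na=False)
    for col in ("id", "age", "sex"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    if "event" in df.columns and "follow_up_time" not in df.columns:
        raise SchemaError(f"{path}: event column present without follow_up_time")

    numeric = ["age", "follow_up_time", "event", *schema.biomarkers]
    numeric += [c for c in schema.covariates if c not in schema.categorical]
    out = pd.DataFrame(index=pd.Index(df["id"].astype(str), name="id"))
    for col in df.columns:
        if col == "id":
            continue
        if col in numeric:
            vals = pd.to_numeric(df[col], errors="coerce").astype(float)
            n_bad = int(vals.isna().sum() - df[col].isna().sum())
            if n_bad:
                log.warning("read_cohort_tsv %s: %d unparseable cells in %r set missing",
                            path, n_bad, col)
            out[col] = vals.to_numpy()
        else:
            out[col] = df[col].to_numpy()
    missing_bm = [b for b in schema.biomarkers if b not in out.columns]
    if missing_bm:
        raise SchemaError(f"{path}: declared biomarkers absent: {missing_bm}")
    return CohortTable(
        data=out,
        biomarkers=list(schema.biomarkers),
        units=dict(schema.biomarkers),
        covariates=list(schema.covariates),
    )


def write_cohort_tsv(cohort: CohortTable, path) -> None:
    """Write a cohort table as TSV (inverse of :func:`read_cohort_tsv`)."""
    df = cohort.data.reset_index().rename(columns={"index": "id"})
    if "id" not in df.columns:
        df.insert(0, "id", cohort.sample_ids)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


# --------------------------------------------------------------------------
# Summary statistics
# --------------------------------------------------------------------------

#: TSV layout of an association summary-statistics table.
SUMMARY_COLUMNS = ["SNP", "Chr", "bp", "refA", "freq", "b", "se", "p", "n"]

_INTERNAL_TO_SUMMARY = {
    "snp": "SNP", "chrom": "Chr", "bp": "bp", "effect_allele": "refA",
    "freq": "freq", "beta": "b", "se": "se", "p": "p", "n": "n",
}


def write_summary_stats(records: pd.DataFrame, path) -> None:
    """Write scan records as a summary-statistics TSV.

    Expects the scan's internal columns (``snp, chrom, bp, effect_allele,
    freq, beta, se, p, n``); writes the conventional ``SNP Chr bp refA
    freq b se p n`` layout, preserving row order, losslessly re-readable
    via :func:`read_summary_stats`.
    """
    df = records.rename(columns=_INTERNAL_TO_SUMMARY)
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"summary records missing columns {missing}")
    df[SUMMARY_COLUMNS].to_csv(path, sep="\t", index=False,
                               float_format="%.17g", na_rep="NA")


def read_summary_stats(path) -> pd.DataFrame:
    """Read a summary-statistics TSV back to the scan's internal columns."""
    df = pd.read_csv(path, sep="\t", na_values=_NA_STRINGS, keep_default_na=False,
                     dtype={"SNP": str, "Chr": str, "refA": str},
                     float_precision="round_trip")
    missing = [c for c in SUMMARY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing summary columns {missing}")
    inv = {v: k for k, v in _INTERNAL_TO_SUMMARY.items()}
    out = df.rename(columns=inv)
    out["bp"] = out["bp"].astype(int)
    if out["n"].notna().all():
        out["n"] = out["n"].astype(int)
    return out


# --------------------------------------------------------------------------
# Config
# --------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a TOML run configuration (one section per pipeline stage)."""
    with open(path, "rb") as fh:
        return tomllib.load(fh)
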