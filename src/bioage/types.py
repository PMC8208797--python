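"""Core in-memory containers shared by every pipeline stage.

Two containers carry all data through the pipeline:

``GenotypeMatrix``
    An ``n_samples x n_snps`` dosage matrix (expected count of the effect
    allele, in ``[0, 2]``; ``NaN`` marks a missing call) plus a per-SNP
    metadata frame. SNPs are kept sorted by ``(chromosome, bp)`` on GRCh37
    1-based coordinates.

``CohortTable``
    A per-individual phenotype table: chronological age (years), sex,
    named biomarker columns with declared units, optional survival
    follow-up ``(follow_up_time, event)`` and optional covariate columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["SnpMeta", "GenotypeMatrix", "CohortTable", "SchemaError"]

#: Columns of the SNP metadata frame, in canonical order.
SNP_COLUMNS = ["id", "chrom", "bp", "effect_allele", "other_allele", "freq", "info"]


class SchemaError(ValueError):
    """A table does not satisfy the declared schema or an invariant."""


@dataclass(frozen=True)
class SnpMeta:
    """Metadata for a single biallelic SNP.

    ``effect_allele`` is the allele counted by the dosage (the "refA" of a
    summary-statistics table); ``freq`` is its frequency. ``bp`` is a
    1-based GRCh37 position. ``info`` is the imputation information score,
    ``None`` when unavailable.
    """

    id: str
    chrom: str
    bp: int
    effect_allele: str
    other_allele: str
    freq: float | None = None
    info: float | None = None

    def __post_init__(self) -> None:
        if self.bp < 1:
            raise SchemaError(f"SNP {self.id}: bp must be >= 1, got {self.bp}")


def _chrom_sort_key(chrom: pd.Series) -> pd.Series:
    """Numeric-aware chromosome ordering: 1..22 before X, Y, MT, others."""
    special = {"X": 23, "Y": 24, "XY": 25, "MT": 26, "M": 26}

    def key(c: str) -> int:
        c = str(c).removeprefix("chr")
        if c.isdigit():
            return int(c)
        return special.get(c.upper(), 99)

    return chrom.map(key)


@dataclass
class GenotypeMatrix:
    """Dosage matrix with per-SNP metadata.

    Invariants enforced at construction: dosages in ``[0, 2]`` where
    present, unique sample and SNP ids, SNPs sorted by ``(chrom, bp)``.
    Effect-allele frequencies absent from the metadata are recomputed from
    the dosages as ``mean(dosage) / 2`` over non-missing entries.
    """

    samples: list[str]
    snps: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.shape != (len(self.samples), len(self.snps)):
            raise SchemaError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        if len(set(self.samples)) != len(self.samples):
            raise SchemaError("sample ids are not unique")
        missing_cols = [c for c in SNP_COLUMNS if c not in self.snps.columns]
        if missing_cols:
            raise SchemaError(f"SNP metadata missing columns: {missing_cols}")
        if self.snps["id"].duplicated().any():
            dups = self.snps.loc[self.snps["id"].duplicated(), "id"].tolist()
            raise SchemaError(f"duplicate SNP ids: {dups[:5]}")
        with np.errstate(invalid="ignore"):
            bad = (self.dosage < 0) | (self.dosage > 2)
        if bad.any():
            raise SchemaError("dosage entries outside [0, 2]")

        order = np.lexsort(
            (self.snps["bp"].to_numpy(), _chrom_sort_key(self.snps["chrom"]).to_numpy())
        )
        if not np.array_equal(order, np.arange(len(order))):
            self.snps = self.snps.iloc[order].reset_index(drop=True)
            self.dosage = self.dosage[:, order]
        else:
            self.snps = self.snps.reset_index(drop=True)

        freq = self.snps["freq"].to_numpy(dtype=float)
        need = ~np.isfinite(freq)
        if need.any():
            freq = freq.copy()
            freq[need] = self.empirical_freq()[need]
            self.snps = self.snps.assign(freq=freq)

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def empirical_freq(self) -> np.ndarray:
        """Effect-allele frequency from dosages: mean(dosage)/2, NaN-aware.

        All-missing SNPs get NaN frequency.
        """
        n_obs = np.sum(np.isfinite(self.dosage), axis=0)
        total = np.nansum(self.dosage, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, total / (2.0 * np.maximum(n_obs, 1)), np.nan)

    # -- subsetting -----------------------------------------------------
    def take_snps(self, mask_or_ids) -> "GenotypeMatrix":
        """Subset SNPs by boolean mask or by a sequence of SNP ids."""
        if isinstance(mask_or_ids, np.ndarray) and mask_or_ids.dtype == bool:
            idx = np.flatnonzero(mask_or_ids)
        else:
            wanted = list(mask_or_ids)
            pos = {s: i for i, s in enumerate(self.snps["id"])}
            missing = [s for s in wanted if s not in pos]
            if missing:
                raise KeyError(f"SNP ids not in matrix: {missing[:5]}")
            idx = np.array([pos[s] for s in wanted], dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            snps=self.snps.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
        )

    def take_samples(self, sample_ids) -> "GenotypeMatrix":
        pos = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"sample ids not in matrix: {missing[:5]}")
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return GenotypeMatrix(
            samples=list(sample_ids),
            snps=self.snps.copy(),
            dosage=self.dosage[idx, :].copy(),
        )

    def dosage_of(self, snp_id: str) -> np.ndarray:
        """Dosage column for one SNP id."""
        hits = np.flatnonzero((self.snps["id"] == snp_id).to_numpy())
        if hits.size == 0:
            raise KeyError(f"SNP {snp_id!r} not in matrix")
        return self.dosage[:, hits[0]]

    def imputed_dosage(self) -> np.ndarray:
        """Dosage with missing entries replaced by the per-SNP mean."""
        out = self.dosage.copy()
        col_mean = np.nanmean(np.where(np.isnan(out), np.nan, out), axis=0)
        col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
        nan_r, nan_c = np.nonzero(np.isnan(out))
        out[nan_r, nan_c] = col_mean[nan_c]
        return out


MANDATORY_COHORT_COLUMNS = ("age", "sex")
SEX_LEVELS = ("female", "male")


@dataclass
class CohortTable:
    """Per-individual phenotype table.

    ``data`` is indexed by sample id and holds ``age`` (years, > 0),
    ``sex`` (``"female"``/``"male"``), the biomarker columns listed in
    ``biomarkers`` (units declared in ``units``), optional
    ``follow_up_time`` (years, >= 0) / ``event`` (0/1) survival columns
    and any extra covariate columns listed in ``covariates``.
    """

    data: pd.DataFrame
    biomarkers: list[str] = field(default_factory=list)
    units: dict[str, str] = field(default_factory=dict)
    covariates: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data
        for col in MANDATORY_COHORT_COLUMNS:
            if col not in df.columns:
                raise SchemaError(f"cohort table missing mandatory column {col!r}")
        if df.index.duplicated().any():
            raise SchemaError("duplicate sample ids in cohort table")
        age = df["age"].to_numpy(dtype=float)
        if np.any(age[np.isfinite(age)] <= 0):
            raise SchemaError("age must be > 0")
        bad_sex = set(df["sex"].dropna().unique()) - set(SEX_LEVELS)
        if bad_sex:
            raise SchemaError(f"sex values outside {SEX_LEVELS}: {sorted(bad_sex)}")
        if "event" in df.columns and "follow_up_time" not in df.columns:
            raise SchemaError("event present without follow_up_time")
        if "follow_up_time" in df.columns:
            t = df["follow_up_time"].to_numpy(dtype=float)
            if np.any(t[np.isfinite(t)] < 0):
                raise SchemaError("follow_up_time must be >= 0")
        for b in self.biomarkers:
            if b not in df.columns:
                raise SchemaError(f"declared biomarker {b!r} not in table")
        for c in self.covariates:
            if c not in df.columns:
                raise SchemaError(f"declared covariate {c!r} not in table")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.index]

    def sex_male(self) -> np.ndarray:
        """Sex as a 0/1 indicator (male = 1)."""
        return (self.data["sex"] == "male").to_numpy(dtype=float)

    def covariate_frame(self, extra: list[str] | None = None) -> pd.DataFrame:
        """Standard adjustment set: age, sex indicator, declared covariates.

        Categorical covariate columns (e.g. assessment centre codes) are
        expanded to treatment-coded dummies.
        """
        cols = {"age": self.data["age"].to_numpy(dtype=float), "sex_male": self.sex_male()}
        out = pd.DataFrame(cols, index=self.data.index)
        names = list(self.covariates) + list(extra or [])
        for c in names:
            col = self.data[c]
            if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
                dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
                out = pd.concat([out, dummies], axis=1)
            else:
                out[c] = col.to_numpy(dtype=float)
        return out

    def with_columns(self, **cols) -> "CohortTable":
        """Return a copy with extra/overwritten columns."""
        return replace(self, data=self.data.assign(**cols))
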