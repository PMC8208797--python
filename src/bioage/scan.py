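"""SNP QC, association scan, inflation diagnostics, lead-SNP selection.

QC drops SNPs with imputation information score < 0.3 (or missing), minor
allele frequency < 0.1%, or an exact Hardy–Weinberg test p-value below the
Bonferroni-corrected level over the SNPs tested.

The scan regresses a biological-age measure on each SNP's dosage plus
covariates by OLS — chronological age is among the covariates, so the
dosage coefficient targets *accelerated* biological age. Mixed-model
machinery is unnecessary here because the synthetic cohorts carry no
relatedness or population structure. Genome-wide significance uses the
conventional 5e-8 line. Lead SNPs are picked by a greedy conditional
pruning: repeatedly take the most significant remaining SNP, then drop
neighbours within a physical window whose multiple-regression R^2 against
the selected set exceeds a threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .types import GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "GENOME_WIDE_P",
    "QcSpec",
    "hwe_exact_test",
    "snp_qc",
    "scan",
    "genomic_lambda",
    "select_lead_snps",
]

#: Conventional genome-wide significance line.
GENOME_WIDE_P = 5e-8

_CHI2_1_MEDIAN = stats.chi2.ppf(0.5, df=1)  # 0.4549...


@dataclass(frozen=True)
class QcSpec:
    """SNP quality-control thresholds.

    ``hwe_alpha`` is Bonferroni-corrected by the number of SNPs entering
    QC. ``drop_missing_info=False`` admits panels that never had an
    imputation score (e.g. directly simulated genotypes).
    """

    min_info: float = 0.3
    min_maf: float = 0.001
    hwe_alpha: float = 0.05
    drop_missing_info: bool = True


def hwe_exact_test(n_aa_hom: int, n_het: int, n_bb_hom: int) -> float:
    """Exact two-sided Hardy–Weinberg test p-value.

    Conditions on the allele counts and sums the probabilities of all
    heterozygote counts no more likely than the observed one (the standard
    exact formulation). Monomorphic samples return 1.
    """
    counts = (int(n_aa_hom), int(n_het), int(n_bb_hom))
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("need at least one genotyped individual")
    n_a = 2 * counts[0] + counts[1]
    return _hwe_exact_from_alleles(n, min(n_a, 2 * n - n_a), counts[1])


@lru_cache(maxsize=100_000)
def _hwe_exact_from_alleles(n: int, n_minor: int, het_obs: int) -> float:
    # support: het with same parity as n_minor, 0 <= het <= n_minor
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    n_a = n_minor
    logps = (hets * np.log(2.0)
             + gammaln(n + 1)
             - gammaln((n_a - hets) / 2 + 1)
             - gammaln(hets + 1)
             - gammaln((2 * n - n_a - hets) / 2 + 1))
    logps = logps - logps.max()
    probs = np.exp(logps)
    probs /= probs.sum()
    p_obs = probs[np.searchsorted(hets, het_obs)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hardcall_counts(dosage_col: np.ndarray) -> tuple[int, int, int]:
    """Round dosages to genotypes; returns (hom other, het, hom effect)."""
    ok = np.isfinite(dosage_col)
    g = np.rint(dosage_col[ok]).astype(int)
    return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())


def snp_qc(geno: GenotypeMatrix, spec: QcSpec = QcSpec()) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Filter a genotype matrix; returns (filtered matrix, QC report).

    Removal rules, applied to every SNP entering QC: (1) info < min_info,
    (2) MAF < min_maf, (3) HWE exact p below ``hwe_alpha / m`` with m the
    number of SNPs entering QC, (4) missing info score (if
    ``drop_missing_info``) or undeterminable MAF. The report records the
    per-rule decisions; counts in/out are logged.
    """
    m = geno.n_snps
    info = geno.snps["info"].to_numpy(dtype=float)
    freq = geno.empirical_freq()
    maf = np.minimum(freq, 1.0 - freq)

    hwe_p = np.empty(m)
    for j in range(m):
        hwe_p[j] = hwe_exact_test(*_hardcall_counts(geno.dosage[:, j]))
    hwe_cut = spec.hwe_alpha / max(m, 1)

    fail_info = (info < spec.min_info) & np.isfinite(info)
    fail_info_missing = ~np.isfinite(info) if spec.drop_missing_info else np.zeros(m, bool)
    fail_maf = (maf < spec.min_maf) | ~np.isfinite(maf)
    fail_hwe = hwe_p < hwe_cut
    keep = ~(fail_info | fail_info_missing | fail_maf | fail_hwe)

    report = pd.DataFrame({
        "snp": geno.snps["id"],
        "maf": maf,
        "info": info,
        "hwe_p": hwe_p,
        "fail_info": fail_info,
        "fail_info_missing": fail_info_missing,
        "fail_maf": fail_maf,
        "fail_hwe": fail_hwe,
        "kept": keep,
    })
    log.info(
        "snp_qc: %d in, %d out (info %d, missing info %d, maf %d, hwe %d at p<%.3g)",
        m, int(keep.sum()), int(fail_info.sum()), int(fail_info_missing.sum()),
        int(fail_maf.sum()), int(fail_hwe.sum()), hwe_cut,
    )
    return geno.take_snps(keep), report


def scan(
    geno: GenotypeMatrix,
    y,
    covariates: pd.DataFrame | np.ndarray,
) -> pd.DataFrame:
    """Per-SNP OLS of a biological-age vector on dosage + covariates.

    Missing dosages are mean-imputed per SNP; rows with missing y or
    covariates are dropped for all SNPs. Returns one row per SNP with the
    dosage coefficient (``beta``, per effect allele), its ``se``,
    two-sided ``p`` and the sample size used.

    Implemented via Frisch–Waugh residualization, which makes the
    per-SNP coefficient identical to the full OLS fit but vectorizes over
    all SNPs at once. Raises if the covariate matrix is rank-deficient,
    naming the columns involved.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(covariates, pd.DataFrame):
        cov_names = list(covariates.columns)
        C = covariates.to_numpy(dtype=float)
    else:
        C = np.asarray(covariates, dtype=float)
        cov_names = [f"cov{i}" for i in range(C.shape[1])]
    if C.shape[0] != y.shape[0] or y.shape[0] != geno.n_samples:
        raise ValueError("y, covariates and genotypes must share sample count")

    ok = np.isfinite(y) & np.all(np.isfinite(C), axis=1)
    if (~ok).any():
        log.info("scan: dropping %d rows with missing outcome/covariates", int((~ok).sum()))
    y = y[ok]
    X = np.column_stack([np.ones(ok.sum()), C[ok]])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify a redundant column for the error message
        bad = []
        for k in range(1, X.shape[1]):
            sub = np.delete(X, k, axis=1)
            if np.linalg.matrix_rank(sub) == np.linalg.matrix_rank(X):
                bad.append((["intercept"] + cov_names)[k])
        raise ValueError(f"collinear covariates: {bad or cov_names}")

    G = geno.imputed_dosage()[ok]
    n, q = X.shape
    df = n - q - 1
    if df <= 0:
        raise ValueError("not enough rows for the covariate set")

    Q, _ = np.linalg.qr(X)
    y_res = y - Q @ (Q.T @ y)
    G_res = G - Q @ (Q.T @ G)

    gg = np.einsum("ij,ij->j", G_res, G_res)
    gy = G_res.T @ y_res
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(gg > 0, gy / gg, np.nan)
        rss = (y_res @ y_res) - np.where(gg > 0, gy**2 / gg, 0.0)
        sigma2 = rss / df
        se = np.sqrt(np.where(gg > 0, sigma2 / gg, np.nan))
        tstat = beta / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df)

    return pd.DataFrame({
        "snp": geno.snps["id"],
        "chrom": geno.snps["chrom"],
        "bp": geno.snps["bp"],
        "effect_allele": geno.snps["effect_allele"],
        "freq": geno.empirical_freq(),
        "beta": beta,
        "se": se,
        "p": p,
        "n": n,
    })


def genomic_lambda(pvals) -> float:
    """Genomic inflation factor: median association chi-square over the
    null chi-square(1) median (~0.455). Uniform p-values give ~1."""
    p = np.asarray(pvals, dtype=float)
    p = p[np.isfinite(p)]
    if p.size < 100:
        raise ValueError("need at least 100 p-values for a stable lambda")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / _CHI2_1_MEDIAN)


def select_lead_snps(
    records: pd.DataFrame,
    geno: GenotypeMatrix,
    r2_max: float = 0.9,
    window_kb: float = 10_000.0,
    p_threshold: float = GENOME_WIDE_P,
) -> pd.DataFrame:
    """Greedy conditional pruning of significant SNPs to independent leads.

    Repeatedly promotes the smallest-p remaining significant SNP to lead,
    then drops remaining candidates on the same chromosome within
    ``window_kb`` whose multiple-regression R^2 against the already
    selected leads (restricted to in-window leads) exceeds ``r2_max``.
    SNPs farther apart than the window are treated as linkage-free. Ties
    in p are broken by (chromosome, bp) order, so the output is
    deterministic and independent of input row order.
    """
    sig = records[records["p"] < p_threshold].copy()
    if sig.empty:
        return sig.assign(lead=pd.Series(dtype=bool)).iloc[0:0]
    sig = sig.sort_values(["p", "chrom", "bp"], kind="mergesort").reset_index(drop=True)

    dose = {s: _standardized(geno.dosage_of(s)) for s in sig["snp"]}
    window_bp = window_kb * 1_000.0

    leads: list[int] = []
    remaining = list(sig.index)
    while remaining:
        best = remaining.pop(0)
        leads.append(best)
        kept = []
        for i in remaining:
            in_window = [
                j for j in leads
                if sig.at[i, "chrom"] == sig.at[j, "chrom"]
                and abs(sig.at[i, "bp"] - sig.at[j, "bp"]) <= window_bp
            ]
            if in_window:
                r2 = _multiple_r2(dose[sig.at[i, "snp"]],
                                  np.column_stack([dose[sig.at[j, "snp"]] for j in in_window]))
                if r2 > r2_max:
                    continue
            kept.append(i)
        remaining = kept

    out = sig.loc[leads].copy()
    out["_ck"] = out["chrom"].map(lambda c: int(c) if str(c).isdigit() else 99)
    out = out.sort_values(["_ck", "bp"], kind="mergesort").drop(columns="_ck")
    return out.reset_index(drop=True)


def _standardized(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    x = np.where(np.isfinite(x), x, np.nanmean(x))
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def _multiple_r2(y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of y on (1, X); y and X columns already centred."""
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tss = float(y @ y)
    if tss == 0:
        return 1.0
    return 1.0 - float(resid @ resid) / tss
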