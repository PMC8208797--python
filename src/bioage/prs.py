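"""Polygenic-risk-score construction and quintile stratification.

The pipeline mirrors common PRS practice: the cohort is split 1:2 into a
training set (association scan) and a testing set; training summary
statistics are LD-clumped (pairwise r^2 < 0.1 within a physical window,
250 kb by default); a p-value threshold is chosen by grid search to
maximize the incremental variance in biological age explained by the PRS
beyond covariates in the testing set; subjects are then divided into PRS
quintiles and the top 20% is compared with the bottom 20% (and the middle
quintile with the bottom, for a dosage trend) across outcomes:

* continuous outcomes — OLS on z-transformed values (mean SD-difference);
* binary outcomes — logistic regression (odds ratio);
* lifespan outcomes — parametric Gompertz proportional-hazards fit
  (hazard ratio), matching the generator's hazard family.

Significant contrasts are flagged at the 5% Benjamini–Hochberg FDR level
across all results of one stratification run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .survival import fit_gompertz_ph
from .types import CohortTable, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "PrsModel",
    "DEFAULT_THRESHOLD_GRID",
    "split_cohort",
    "clump_for_prs",
    "prs_score",
    "threshold_grid_search",
    "quintile_stratify",
    "outcome_association",
]

#: Desk-scale logarithmic p-threshold grid (a dense arithmetic grid from
#: 1e-5 to 0.5 can be supplied instead via ``full_grid``).
DEFAULT_THRESHOLD_GRID = (1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.3, 0.45, 0.5, 1.0)


def full_grid(step: float = 1e-5) -> np.ndarray:
    """The dense arithmetic grid: 1e-5 to 0.5 in steps of ``step``, plus 1."""
    return np.append(np.arange(1e-5, 0.5 + step / 2, step), 1.0)


@dataclass(frozen=True)
class PrsModel:
    """A fitted PRS: SNP weights (training betas) at a chosen p-threshold."""

    snps: tuple[str, ...]
    effect_alleles: tuple[str, ...]
    weights: tuple[float, ...]
    p_threshold: float
    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    incremental_r2: float = np.nan

    def __post_init__(self) -> None:
        if len(set(self.snps)) != len(self.snps):
            raise ValueError("PRS SNPs must be unique")
        if not all(np.isfinite(self.weights)):
            raise ValueError("PRS weights must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"snp": self.snps, "effect_allele": self.effect_alleles,
                             "weight": self.weights})


def split_cohort(sample_ids, ratio: tuple[int, int] = (1, 2), seed: int = 0):
    """Random disjoint exhaustive train/test split, 1:2 by default.

    The training size is ``round(n * ratio[0] / sum(ratio))`` (banker-free
    half-up rounding), so sizes are within one of the exact ratio.
    Reproducible for a given seed.
    """
    ids = list(sample_ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 samples to split")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    n_train = int(np.floor(len(ids) * ratio[0] / (ratio[0] + ratio[1]) + 0.5))
    train = sorted(ids[i] for i in perm[:n_train])
    test = sorted(ids[i] for i in perm[n_train:])
    return train, test


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors (composite LD)."""
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 2:
        return 0.0
    r = np.corrcoef(x[ok], y[ok])[0, 1]
    return 0.0 if np.isnan(r) else float(r**2)


def clump_for_prs(
    records: pd.DataFrame,
    geno: GenotypeMatrix,
    r2: float = 0.1,
    window_kb: float = 250.0,
) -> pd.DataFrame:
    """Greedy p-ascending LD clumping.

    Walk SNPs from smallest p upward, retaining a SNP only if its r^2
    with every already-retained SNP on the same chromosome within
    ``window_kb`` stays below ``r2``. Ties in p break by (chrom, bp).
    """
    recs = records.dropna(subset=["p"]).sort_values(
        ["p", "chrom", "bp"], kind="mergesort").reset_index(drop=True)
    window_bp = window_kb * 1_000.0
    kept: list[int] = []
    dose: dict[str, np.ndarray] = {}
    for i in recs.index:
        snp_i = recs.at[i, "snp"]
        if snp_i not in dose:
            dose[snp_i] = geno.dosage_of(snp_i)
        ok = True
        for j in kept:
            if (recs.at[i, "chrom"] == recs.at[j, "chrom"]
                    and abs(recs.at[i, "bp"] - recs.at[j, "bp"]) <= window_bp
                    and _pairwise_r2(dose[snp_i], dose[recs.at[j, "snp"]]) >= r2):
                ok = False
                break
        if ok:
            kept.append(i)
    log.info("clump_for_prs: %d of %d SNPs retained (r2<%g, %g kb)",
             len(kept), len(recs), r2, window_kb)
    return recs.loc[kept].reset_index(drop=True)


def prs_score(geno: GenotypeMatrix, model: PrsModel) -> pd.Series:
    """Dosage-weighted sum of effect alleles, mean-imputed dosages.

    Model SNPs absent from the matrix are dropped with a warning; raises
    if none overlap.
    """
    present = set(geno.snps["id"])
    pairs = [(s, w) for s, w in zip(model.snps, model.weights) if s in present]
    dropped = len(model.snps) - len(pairs)
    if dropped:
        log.warning("prs_score: %d model SNPs absent from genotypes", dropped)
    if not pairs:
        raise ValueError("no PRS model SNPs present in the genotype matrix")
    sub = geno.take_snps([s for s, _ in pairs])
    w = np.array([w for _, w in pairs])
    score = sub.imputed_dosage() @ w
    return pd.Series(score, index=pd.Index(geno.samples, name="id"), name="prs")


def _incremental_r2(y: np.ndarray, cov: np.ndarray, score: np.ndarray) -> float:
    """R^2 gain of adding the PRS to the covariate-only OLS (nested fits)."""
    X0 = sm.add_constant(cov)
    X1 = np.column_stack([X0, score])
    r0 = sm.OLS(y, X0).fit().rsquared
    r1 = sm.OLS(y, X1).fit().rsquared
    return float(max(r1 - r0, 0.0))


def threshold_grid_search(
    train_records: pd.DataFrame,
    test_geno: GenotypeMatrix,
    test_ba,
    test_covariates: pd.DataFrame,
    grid=DEFAULT_THRESHOLD_GRID,
    clump_r2: float = 0.1,
    clump_window_kb: float = 250.0,
    clump_geno: GenotypeMatrix | None = None,
) -> PrsModel:
    """Choose the PRS p-threshold maximizing incremental test-set R^2.

    Training records are clumped once (in ``clump_geno``, defaulting to
    the test genotypes); each grid threshold keeps the clumped SNPs with
    ``p < threshold`` and scores the testing set; the objective is the
    variance of the biological-age outcome explained by the PRS beyond
    the covariates. Grid points with no passing SNP are skipped. Ties
    resolve to the smallest threshold.
    """
    if len(list(grid)) == 0:
        raise ValueError("threshold grid is empty")
    clumped = clump_for_prs(train_records, clump_geno or test_geno,
                            r2=clump_r2, window_kb=clump_window_kb)
    y = np.asarray(test_ba, dtype=float)
    cov = test_covariates.to_numpy(dtype=float)

    best: PrsModel | None = None
    for thr in sorted(set(float(t) for t in grid)):
        sel = clumped[clumped["p"] < thr]
        if sel.empty:
            continue
        model = PrsModel(
            snps=tuple(sel["snp"]),
            effect_alleles=tuple(sel["effect_allele"]),
            weights=tuple(sel["beta"]),
            p_threshold=thr,
            clump_r2=clump_r2,
            clump_window_kb=clump_window_kb,
        )
        score = prs_score(test_geno, model).to_numpy()
        r2_inc = _incremental_r2(y, cov, score)
        if best is None or r2_inc > best.incremental_r2:
            from dataclasses import replace
            best = replace(model, incremental_r2=r2_inc)
    if best is None:
        raise ValueError("no SNP passed any grid threshold")
    log.info("threshold_grid_search: best p<%g with %d SNPs, incremental R2=%.4g",
             best.p_threshold, len(best.snps), best.incremental_r2)
    return best


def quintile_stratify(scores) -> np.ndarray:
    """Assign PRS quintile labels 1..5 (5 = highest scores).

    Group sizes differ by at most one. Ties at a boundary are broken by
    stable input order, so the grouping is invariant to any strictly
    monotone transform of the scores.
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n < 5:
        raise ValueError("need at least 5 scores for quintiles")
    order = np.argsort(s, kind="stable")
    bounds = np.floor(np.arange(1, 6) * n / 5).astype(int)
    labels = np.empty(n, dtype=int)
    start = 0
    for g, stop in enumerate(bounds, start=1):
        labels[order[start:stop]] = g
        start = stop
    return labels


@dataclass(frozen=True)
class _Contrast:
    label: str
    exposed: int
    reference: int


_CONTRASTS = (_Contrast("top20_vs_bottom20", 5, 1),
              _Contrast("mid40to60_vs_bottom20", 3, 1))


def outcome_association(
    groups: np.ndarray,
    cohort: CohortTable,
    outcomes: dict[str, str],
    covariates: pd.DataFrame | None = None,
    fdr_level: float = 0.05,
) -> pd.DataFrame:
    """Associate PRS quintile membership with outcomes.

    ``outcomes`` maps column name -> kind in {"continuous", "binary",
    "survival"}; the survival kind uses the cohort's
    ``(follow_up_time, event)`` columns and ignores the named column's
    values. Contrasts are quintile 5 vs 1 and quintile 3 vs 1,
    covariate-adjusted. Continuous outcomes are z-transformed first, so
    estimates are mean SD-differences; binary outcomes report odds
    ratios; survival outcomes report Gompertz-PH hazard ratios.
    Benjamini–Hochberg FDR flags are computed across all rows at
    ``fdr_level``. Logistic fits with separation are flagged and their
    estimates withheld.
    """
    groups = np.asarray(groups)
    if not (groups == 1).any():
        raise ValueError("empty bottom-quintile reference group")
    cov = covariates if covariates is not None else cohort.covariate_frame()
    cov_m = cov.to_numpy(dtype=float)

    rows = []
    for name, kind in outcomes.items():
        for c in _CONTRASTS:
            mask = (groups == c.exposed) | (groups == c.reference)
            indicator = (groups[mask] == c.exposed).astype(float)
            sub_cov = cov_m[mask]
            row = {"outcome": name, "kind": kind, "contrast": c.label,
                   "n": int(mask.sum()), "estimate": np.nan, "ci_low": np.nan,
                   "ci_high": np.nan, "p": np.nan, "note": ""}
            try:
                if kind == "survival":
                    t = cohort.data["follow_up_time"].to_numpy(float)[mask]
                    d = cohort.data["event"].to_numpy(float)[mask]
                    X = pd.DataFrame(np.column_stack([indicator, sub_cov]),
                                     columns=["exposed", *cov.columns])
                    fit = fit_gompertz_ph(t, d, X)
                    hr, lo, hi, p = fit.hazard_ratio("exposed")
                    row.update(estimate=hr, ci_low=lo, ci_high=hi, p=p)
                elif kind == "binary":
                    yb = cohort.data[name].to_numpy(float)[mask]
                    est, lo, hi, p, note = _logistic_or(yb, indicator, sub_cov)
                    row.update(estimate=est, ci_low=lo, ci_high=hi, p=p, note=note)
                elif kind == "continuous":
                    yc = cohort.data[name].to_numpy(float)[mask]
                    ok = np.isfinite(yc)
                    z = (yc - np.nanmean(yc)) / np.nanstd(yc, ddof=1)
                    X = sm.add_constant(np.column_stack([indicator, sub_cov]))
                    fit = sm.OLS(z[ok], X[ok]).fit()
                    ci = fit.conf_int()[1]
                    row.update(estimate=float(fit.params[1]), ci_low=float(ci[0]),
                               ci_high=float(ci[1]), p=float(fit.pvalues[1]))
                else:
                    raise ValueError(f"unknown outcome kind {kind!r}")
            except ValueError as exc:
                row["note"] = str(exc)
            rows.append(row)

    out = pd.DataFrame(rows)
    ok_p = out["p"].notna()
    out["fdr_significant"] = False
    if ok_p.any():
        flags = multipletests(out.loc[ok_p, "p"], alpha=fdr_level, method="fdr_bh")[0]
        out.loc[ok_p, "fdr_significant"] = flags
    return out


def _logistic_or(y, indicator, cov):
    """Odds ratio of the exposure indicator; detects separation."""
    ok = np.isfinite(y)
    X = sm.add_constant(np.column_stack([indicator, cov]))[ok]
    y = y[ok]
    import warnings

    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # non-convergence is detected and reported via the note field
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        return np.nan, np.nan, np.nan, np.nan, "separation"
    if not fit.mle_retvals.get("converged", True) or np.any(~np.isfinite(fit.bse)) \
            or fit.bse[1] > 50:
        return np.nan, np.nan, np.nan, np.nan, "separation"
    b, s = fit.params[1], fit.bse[1]
    from scipy import stats as _st
    p = 2 * _st.norm.sf(abs(b / s))
    return (float(np.exp(b)), float(np.exp(b - 1.96 * s)),
            float(np.exp(b + 1.96 * s)), float(p), "")
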