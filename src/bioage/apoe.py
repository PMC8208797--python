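"""APOE isoform calling and genotype-group contrasts.

The three common APOE haplotypes are determined by two coding SNPs,
written as (allele at rs429358, allele at rs7412):

====  =========  =======
hap   rs429358   rs7412
====  =========  =======
e2    T          T
e3    T          C
e4    C          C
====  =========  =======

Unphased genotype pairs map to diplotypes; the double heterozygote
(TC, TC) is called e2e4 under the standard no-e1 assumption (the rare e1
haplotype (C, T) is treated as absent). Genotype pairs only explicable by
an e1 haplotype are returned as ``ambiguous``.

Contrasts compare each non-e3e3 diplotype group with the e3e3 reference
on z-transformed outcomes (biomarkers or biological-age measures) by OLS
with covariate adjustment, reporting the mean SD-difference, its standard
error, p-value and a significance tier (* p<0.05, ** p<0.01, *** p<0.001).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .simulate import APOE_E2_SNP, APOE_E4_SNP
from .types import CohortTable, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "DIPLOTYPES",
    "call_apoe",
    "call_apoe_from_dosage",
    "call_cohort_apoe",
    "genotype_contrasts",
]

_HAP = {("T", "T"): "e2", ("T", "C"): "e3", ("C", "C"): "e4"}  # no e1 = (C, T)
DIPLOTYPES = ("e2e2", "e2e3", "e2e4", "e3e3", "e3e4", "e4e4")


def _genotype_alleles(g: str) -> tuple[str, str] | None:
    if g is None or g == "missing":
        return None
    g = g.upper()
    if len(g) != 2 or any(a not in "TC" for a in g):
        raise ValueError(f"genotype must be two alleles from {{T,C}}, got {g!r}")
    return g[0], g[1]


def call_apoe(g429358: str, g7412: str) -> str:
    """Call an APOE diplotype from unphased genotypes at the two SNPs.

    Arguments are two-letter genotype strings over {T, C} (order
    irrelevant) or ``"missing"``. Returns one of the six diplotypes,
    ``"ambiguous"`` (consistent only with the ignored e1 haplotype) or
    ``"missing"``.
    """
    a = _genotype_alleles(g429358)
    b = _genotype_alleles(g7412)
    if a is None or b is None:
        return "missing"

    # enumerate the two phase assignments of the unphased genotypes; a
    # pairing is valid only if both implied haplotypes are e2/e3/e4. For
    # the (TC, TC) double heterozygote this leaves exactly e2e4 — the
    # e3 + e1 alternative needs the ignored e1 haplotype.
    calls = set()
    for a_perm in {a, a[::-1]}:
        for b_perm in {b, b[::-1]}:
            h1 = _HAP.get((a_perm[0], b_perm[0]))
            h2 = _HAP.get((a_perm[1], b_perm[1]))
            if h1 is not None and h2 is not None:
                calls.add("".join(sorted((h1, h2))))
    return calls.pop() if calls else "ambiguous"


def call_apoe_from_dosage(e4_dosage, e2_dosage, hard_call_margin: float = 0.1):
    """Hard-call diplotypes from effect-allele dosages at the two SNPs.

    ``e4_dosage`` counts the C allele at rs429358; ``e2_dosage`` the T
    allele at rs7412. Dosages are rounded at thresholds 0.5/1.5; values
    within ``hard_call_margin`` of a threshold (uncertain imputations)
    give a missing call.
    """
    e4 = np.asarray(e4_dosage, dtype=float)
    e2 = np.asarray(e2_dosage, dtype=float)
    out = []
    for d4, d2 in zip(e4, e2):
        g4 = _hard_call(d4, hard_call_margin, hom_effect="CC", het="TC", hom_other="TT")
        g2 = _hard_call(d2, hard_call_margin, hom_effect="TT", het="TC", hom_other="CC")
        out.append(call_apoe(g4, g2) if g4 != "missing" and g2 != "missing" else "missing")
    return np.array(out)


def _hard_call(d: float, margin: float, hom_effect: str, het: str, hom_other: str) -> str:
    if not np.isfinite(d) or min(abs(d - 0.5), abs(d - 1.5)) < margin:
        return "missing"
    g = int(round(min(max(d, 0.0), 2.0)))
    return (hom_other, het, hom_effect)[g]


def call_cohort_apoe(geno: GenotypeMatrix, hard_call_margin: float = 0.1) -> pd.Series:
    """Diplotype per sample from a genotype matrix carrying both APOE SNPs."""
    calls = call_apoe_from_dosage(
        geno.dosage_of(APOE_E4_SNP), geno.dosage_of(APOE_E2_SNP), hard_call_margin
    )
    return pd.Series(calls, index=pd.Index(geno.samples, name="id"), name="apoe")


def _tier(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def genotype_contrasts(
    cohort: CohortTable,
    calls: pd.Series,
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    reference: str = "e3e3",
) -> pd.DataFrame:
    """Per-outcome contrasts of each diplotype group against e3e3.

    Outcomes are z-transformed (over samples with a valid call), so each
    contrast is a mean SD-difference. One OLS per outcome regresses the
    z-scored outcome on the five non-reference group indicators plus
    covariates. Results are sorted by p-value within outcome. Raises if
    the reference group is empty.
    """
    calls = calls.reindex(cohort.data.index)
    valid = calls.isin(DIPLOTYPES)
    if not (calls[valid] == reference).any():
        raise ValueError(f"empty reference group {reference!r}")
    groups = [g for g in DIPLOTYPES if g != reference and (calls[valid] == g).any()]

    cov = covariates if covariates is not None else cohort.covariate_frame()
    cov = cov.reindex(cohort.data.index)

    rows = []
    for name in outcomes.columns:
        y = outcomes[name].reindex(cohort.data.index).to_numpy(dtype=float)
        ok = valid.to_numpy() & np.isfinite(y) & np.all(np.isfinite(cov.to_numpy(float)), axis=1)
        if ok.sum() < 3:
            continue
        sd = np.nanstd(y[ok], ddof=1)
        yz = (y[ok] - np.nanmean(y[ok])) / sd if sd > 0 else np.zeros(int(ok.sum()))
        dummies = pd.DataFrame(
            {g: (calls[ok] == g).astype(float).to_numpy() for g in groups})
        X = sm.add_constant(pd.concat(
            [dummies.reset_index(drop=True),
             cov[ok].reset_index(drop=True)], axis=1))
        fit = sm.OLS(yz, X).fit()
        for g in groups:
            p = float(fit.pvalues[g])
            rows.append({
                "outcome": name,
                "group": g,
                "n_group": int((calls[ok] == g).sum()),
                "sd_diff": float(fit.params[g]),
                "se": float(fit.bse[g]),
                "p": p,
                "tier": _tier(p),
            })
    out = pd.DataFrame(rows, columns=["outcome", "group", "n_group",
                                      "sd_diff", "se", "p", "tier"])
    return out.sort_values(["outcome", "p"], kind="mergesort").reset_index(drop=True)


def enumerate_genotype_pairs() -> pd.DataFrame:
    """The 9 possible unphased genotype pairs and their diplotype calls."""
    gts = ["TT", "TC", "CC"]
    rows = [
        {"g429358": a, "g7412": b, "diplotype": call_apoe(a, b)}
        for a in gts for b in gts
    ]
    return pd.DataFrame(rows)
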