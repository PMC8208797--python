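"""Independent brute-force oracles used by the tests.

Everything here is written naively — exact integer arithmetic, explicit
loops, statsmodels fits — and deliberately shares no code with the
package implementations it checks.
"""

from fractions import Fraction
from math import comb

import numpy as np


def hwe_exact_oracle(n_aa: int, n_ab: int, n_bb: int) -> float:
    """Exact HWE test by full enumeration with exact rational arithmetic.

    P(het = h | allele counts) is proportional to the integer weight
    multinomial(n; n_aa, h, n_bb) * 2^h; the two-sided p sums the weights
    of all heterozygote counts with weight <= the observed one.
    """
    n = n_aa + n_ab + n_bb
    na = 2 * n_aa + n_ab

    def weight(h: int) -> int:
        x = (na - h) // 2
        z = (2 * n - na - h) // 2
        # multinomial(n; x, h, z) * 2^h
        return comb(n, x) * comb(n - x, h) * (2 ** h)

    support = [h for h in range(min(na, 2 * n - na) + 1) if (na - h) % 2 == 0]
    weights = {h: weight(h) for h in support}
    w_obs = weights[n_ab]
    total = sum(weights.values())
    hit = sum(w for w in weights.values() if w <= w_obs)
    return float(Fraction(hit, total))


def pairwise_r2_oracle(x, y) -> float:
    r = np.corrcoef(np.asarray(x, float), np.asarray(y, float))[0, 1]
    return 0.0 if np.isnan(r) else r ** 2


def greedy_clump_oracle(records, dosages, r2: float, window_bp: float):
    """Naive p-ascending clumping: returns the retained SNP ids in order.

    ``records`` is a list of dicts with snp/chrom/bp/p; ``dosages`` maps
    snp id -> vector.
    """
    pending = sorted(records, key=lambda r: (r["p"], r["chrom"], r["bp"]))
    kept = []
    for rec in pending:
        ok = True
        for prev in kept:
            if rec["chrom"] != prev["chrom"]:
                continue
            if abs(rec["bp"] - prev["bp"]) > window_bp:
                continue
            if pairwise_r2_oracle(dosages[rec["snp"]], dosages[prev["snp"]]) >= r2:
                ok = False
                break
        if ok:
            kept.append(rec)
    return [r["snp"] for r in kept]


def greedy_lead_oracle(records, dosages, r2_max: float, window_bp: float,
                       p_threshold: float):
    """Naive greedy conditional lead selection using statsmodels R^2."""
    import statsmodels.api as sm

    sig = [r for r in records if r["p"] < p_threshold]
    sig.sort(key=lambda r: (r["p"], r["chrom"], r["bp"]))
    leads = []
    remaining = list(sig)
    while remaining:
        lead = remaining.pop(0)
        leads.append(lead)
        survivors = []
        for rec in remaining:
            in_window = [l for l in leads
                         if l["chrom"] == rec["chrom"]
                         and abs(l["bp"] - rec["bp"]) <= window_bp]
            if in_window:
                X = sm.add_constant(np.column_stack(
                    [dosages[l["snp"]] for l in in_window]))
                fit = sm.OLS(np.asarray(dosages[rec["snp"]], float), X).fit()
                if fit.rsquared > r2_max:
                    continue
            survivors.append(rec)
        remaining = survivors
    return sorted(l["snp"] for l in leads)


def percentile_oracle(values, q: float) -> float:
    """Inverted-CDF percentile from first principles: the smallest observed
    value whose empirical CDF reaches q."""
    xs = sorted(v for v in values if np.isfinite(v))
    n = len(xs)
    for x in xs:
        if sum(1 for v in xs if v <= x) >= q * n:
            return x
    return xs[-1]
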