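"""QC, HWE exact test, association scan and lead-SNP selection tests."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

import bioage as ba
from bioage.scan import QcSpec, _hardcall_counts, select_lead_snps, snp_qc
from bioage.simulate import SimConfig, simulate_genotypes
from bioage.types import GenotypeMatrix

from .oracles import greedy_lead_oracle, hwe_exact_oracle


class TestHweExact:
    def test_monomorphic_p_is_one(self):
        assert ba.hwe_exact_test(10, 0, 0) == 1.0
        assert ba.hwe_exact_test(0, 0, 7) == 1.0

    def test_small_counts_match_enumeration_oracle(self):
        assert ba.hwe_exact_test(1, 2, 1) == pytest.approx(
            hwe_exact_oracle(1, 2, 1), rel=1e-12)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_allele_label_symmetry(self, a, h, b):
        if a + h + b == 0:
            return
        assert ba.hwe_exact_test(a, h, b) == pytest.approx(
            ba.hwe_exact_test(b, h, a), rel=1e-12)

    def test_exhaustive_equality_with_oracle_up_to_n_50(self):
        """Implementation equals exact rational enumeration for every
        genotype-count triple with total <= 50."""
        for n in range(1, 51):
            for n_aa in range(n + 1):
                for n_ab in range(n - n_aa + 1):
                    n_bb = n - n_aa - n_ab
                    got = ba.hwe_exact_test(n_aa, n_ab, n_bb)
                    want = hwe_exact_oracle(n_aa, n_ab, n_bb)
                    assert got == pytest.approx(want, rel=1e-9, abs=1e-12), \
                        (n_aa, n_ab, n_bb)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ba.hwe_exact_test(-1, 2, 3)


def _panel(dosages: dict[str, np.ndarray], info=None, bps=None) -> GenotypeMatrix:
    ids = list(dosages)
    m = len(ids)
    n = len(next(iter(dosages.values())))
    snps = pd.DataFrame({
        "id": ids, "chrom": ["1"] * m,
        "bp": bps if bps is not None else [1000 * (i + 1) for i in range(m)],
        "effect_allele": ["G"] * m, "other_allele": ["A"] * m,
        "freq": [np.nan] * m,
        "info": info if info is not None else [1.0] * m,
    })
    return GenotypeMatrix(samples=[f"s{i}" for i in range(n)], snps=snps,
                          dosage=np.column_stack([dosages[i] for i in ids]))


class TestSnpQc:
    def test_constructed_violations_match_hand_checked_set(self, rng):
        n = 2000
        hwe_ok = rng.binomial(2, 0.3, n).astype(float)
        rare = np.zeros(n)
        rare[0] = 1.0  # maf 1/(2n) = 0.00025 < 0.001
        hwe_bad = np.ones(n)  # all heterozygous: gross HWE violation
        g = _panel(
            {"ok": hwe_ok, "low_info": hwe_ok.copy(), "rare": rare,
             "het_excess": hwe_bad, "no_info": hwe_ok.copy()},
            info=[1.0, 0.1, 1.0, 1.0, np.nan],
        )
        kept, report = snp_qc(g, QcSpec())
        assert set(kept.snps["id"]) == {"ok"}
        r = report.set_index("snp")
        assert r.loc["low_info", "fail_info"]
        assert r.loc["rare", "fail_maf"]
        assert r.loc["het_excess", "fail_hwe"]
        assert r.loc["no_info", "fail_info_missing"]

    def test_missing_info_kept_when_policy_disabled(self, rng):
        x = rng.binomial(2, 0.3, 500).astype(float)
        g = _panel({"a": x}, info=[np.nan])
        kept, _ = snp_qc(g, QcSpec(drop_missing_info=False))
        assert list(kept.snps["id"]) == ["a"]

    def test_hwe_bonferroni_denominator_is_panel_size(self, rng):
        """A SNP with exact HWE p ~= 0.024 fails alone (0.024 < 0.05/1) but
        survives in a 10-SNP panel (0.024 > 0.05/10)."""
        borderline = np.concatenate([np.zeros(20), np.ones(10), np.full(7, 2.0)])
        assert 0.005 < ba.hwe_exact_test(20, 10, 7) < 0.05
        n = borderline.size
        alone, _ = snp_qc(_panel({"b": borderline}), QcSpec())
        assert alone.n_snps == 0
        good = {f"g{i}": rng.binomial(2, 0.3, n).astype(float) for i in range(9)}
        padded, _ = snp_qc(_panel({"b": borderline, **good}), QcSpec())
        assert "b" in set(padded.snps["id"])


class TestScan:
    def test_matches_per_snp_statsmodels_ols(self, null_sim):
        g = null_sim.genotypes.take_snps(list(null_sim.genotypes.snps["id"][:5]))
        y = null_sim.cohort.data["rdw"].to_numpy()
        cov = null_sim.cohort.covariate_frame()
        rec = ba.scan(g, y, cov)
        for j, snp in enumerate(g.snps["id"]):
            X = sm.add_constant(np.column_stack([cov.to_numpy(), g.dosage[:, j]]))
            fit = sm.OLS(y, X).fit()
            assert rec.loc[j, "beta"] == pytest.approx(fit.params[-1], rel=1e-9)
            assert rec.loc[j, "se"] == pytest.approx(fit.bse[-1], rel=1e-9)
            assert rec.loc[j, "p"] == pytest.approx(fit.pvalues[-1], rel=1e-6)

    def test_collinear_covariates_error_names_columns(self, null_sim):
        cov = null_sim.cohort.covariate_frame()
        cov["age_copy"] = cov["age"]
        with pytest.raises(ValueError, match="age_copy"):
            ba.scan(null_sim.genotypes, null_sim.cohort.data["rdw"].to_numpy(), cov)

    def test_permuted_outcome_destroys_signal(self, ld_sim):
        """With the outcome permuted, no SNP should reach genome-wide
        significance in a 120-SNP panel."""
        res = ld_sim
        sc = ba.score_cohort(res.cohort)
        rng = np.random.default_rng(77)
        y = rng.permutation(sc["phenoage"].to_numpy())
        rec = ba.scan(res.genotypes, y, res.cohort.covariate_frame())
        assert (rec["p"] < ba.GENOME_WIDE_P).sum() == 0

    def test_mean_imputation_of_missing_dosages(self):
        d = np.array([0.0, 1.0, 2.0, np.nan, 1.0, 0.0, 2.0, 1.0])
        g = _panel({"a": d})
        y = np.array([0.1, 1.1, 2.2, 0.9, 1.0, -0.1, 2.1, 1.2])
        rec = ba.scan(g, y, pd.DataFrame(index=range(8)))
        filled = np.where(np.isnan(d), np.nanmean(d), d)
        X = sm.add_constant(filled)
        fit = sm.OLS(y, X).fit()
        assert rec.loc[0, "beta"] == pytest.approx(fit.params[-1], rel=1e-9)


class TestGenomicLambda:
    def test_constant_half_pvalues_give_exactly_one(self):
        assert ba.genomic_lambda(np.full(1000, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_pvalues_within_band(self, rng):
        p = rng.uniform(size=10_000)
        assert 0.95 < ba.genomic_lambda(p) < 1.05

    def test_inflated_mixture_raises_lambda(self, rng):
        p = np.concatenate([rng.uniform(size=9000), rng.uniform(0, 1e-4, 1000)])
        assert ba.genomic_lambda(p) > 1.0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            ba.genomic_lambda(np.concatenate([np.full(200, 0.5), [0.0]]))


def _random_instance(rng, n_snps, n=400):
    """Random panel with some LD pairs + synthetic summary stats."""
    base = rng.binomial(2, rng.uniform(0.1, 0.5), size=(n, n_snps)).astype(float)
    for j in range(1, n_snps, 3):  # entangle some neighbours
        copy_from = base[:, j - 1]
        flip = rng.random(n) < 0.1
        base[:, j] = np.where(flip, rng.binomial(2, 0.3, n), copy_from)
    dosages = {f"snp{j}": base[:, j] for j in range(n_snps)}
    bps = sorted(rng.choice(np.arange(1000, 10_000_000, 1000), n_snps, replace=False))
    g = _panel(dosages, bps=[int(b) for b in bps])
    records = g.snps.assign(
        snp=g.snps["id"], beta=rng.normal(0, 0.2, n_snps),
        se=0.05, p=10.0 ** rng.uniform(-12, 0, n_snps), n=n)
    return g, records[["snp", "chrom", "bp", "effect_allele", "freq", "beta", "se", "p", "n"]]


class TestLeadSelection:
    def test_single_significant_snp_is_the_lead(self, rng):
        g, rec = _random_instance(rng, 5)
        rec["p"] = [0.5, 0.2, 1e-9, 0.9, 0.3]
        leads = select_lead_snps(rec, g)
        assert list(leads["snp"]) == ["snp2"]

    def test_perfectly_correlated_pair_yields_single_lead(self, rng):
        x = rng.binomial(2, 0.3, 300).astype(float)
        g = _panel({"a": x, "b": x.copy()}, bps=[1000, 2000])
        rec = pd.DataFrame({
            "snp": ["a", "b"], "chrom": ["1", "1"], "bp": [1000, 2000],
            "effect_allele": "G", "freq": 0.3, "beta": 0.5, "se": 0.05,
            "p": [1e-10, 1e-9], "n": 300})
        leads = select_lead_snps(rec, g)
        assert list(leads["snp"]) == ["a"]  # smaller p wins

    def test_matches_brute_force_greedy_oracle_on_random_instances(self, rng):
        for rep in range(60):
            n_snps = int(rng.integers(10, 16))
            g, rec = _random_instance(rng, n_snps)
            rec["p"] = 10.0 ** rng.uniform(-12, -2, n_snps)  # many significant
            got = sorted(select_lead_snps(rec, g, r2_max=0.5, window_kb=2000,
                                          p_threshold=1e-4)["snp"])
            dosages = {s: g.dosage_of(s) for s in rec["snp"]}
            want = greedy_lead_oracle(rec.to_dict("records"), dosages,
                                      r2_max=0.5, window_bp=2_000_000,
                                      p_threshold=1e-4)
            assert got == want, f"instance {rep}"

    def test_result_independent_of_input_order(self, rng):
        g, rec = _random_instance(rng, 12)
        rec["p"] = 10.0 ** rng.uniform(-10, -3, 12)
        a = select_lead_snps(rec, g, p_threshold=1e-2)
        b = select_lead_snps(rec.sample(frac=1, random_state=1), g, p_threshold=1e-2)
        pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))

    def test_no_significant_snps_gives_empty_frame(self, rng):
        g, rec = _random_instance(rng, 6)
        rec["p"] = 0.5
        assert select_lead_snps(rec, g).empty
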