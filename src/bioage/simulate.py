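"""Synthetic-cohort generator.

Emulates the statistical structure the downstream analysis assumes, so
every stage is testable without access-restricted cohort data:

* biallelic SNPs in Hardy–Weinberg equilibrium at configurable MAFs, with
  optional LD blocks induced by a Gaussian copula on latent haplotypes;
* an APOE-like two-SNP locus (rs429358 / rs7412) whose joint genotypes
  arise from random pairing of e2/e3/e4 haplotypes;
* biomarkers with linear age and sex effects, additive per-allele SNP
  effects, and Gaussian noise;
* death times drawn from the Gompertz proportional hazard implied by the
  PhenoAge linear predictor, censored at a follow-up horizon.

Every stage consumes its own RNG stream spawned from the master seed, so
stages are independently reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clocks import GompertzClockParams, KDMParams, linear_predictor
from .types import CohortTable, GenotypeMatrix

log = logging.getLogger(__name__)

__all__ = [
    "BiomarkerModel",
    "ApoeSpec",
    "SimConfig",
    "SimResult",
    "simulate_genotypes",
    "simulate_ages_sexes",
    "simulate_biomarkers",
    "simulate_mortality",
    "simulate_cohort",
    "kdm_params_from_sim",
]

APOE_E4_SNP = "rs429358"  # effect allele C tags the e4 haplotype
APOE_E2_SNP = "rs7412"    # effect allele T tags the e2 haplotype
_APOE_BP = {APOE_E4_SNP: 45411941, APOE_E2_SNP: 45412079}  # GRCh37, chr 19

# haplotype -> (allele at rs429358, allele at rs7412)
_APOE_HAPLOTYPES = {"e2": ("T", "T"), "e3": ("T", "C"), "e4": ("C", "C")}


@dataclass(frozen=True)
class BiomarkerModel:
    """Linear generative model for one biomarker.

    ``value = intercept + age_slope * age + sex_offset * male
    + sum(effect * dosage over causal SNPs) + Normal(0, noise_sd)``.
    """

    intercept: float
    age_slope: float
    sex_offset: float
    noise_sd: float
    unit: str = ""


@dataclass(frozen=True)
class ApoeSpec:
    """Haplotype frequencies for the two-SNP APOE-like locus."""

    freq_e2: float = 0.08
    freq_e3: float = 0.77
    freq_e4: float = 0.15

    def __post_init__(self) -> None:
        total = self.freq_e2 + self.freq_e3 + self.freq_e4
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"APOE haplotype frequencies must sum to 1, got {total}")

    @property
    def freqs(self) -> np.ndarray:
        return np.array([self.freq_e2, self.freq_e3, self.freq_e4])


def _default_biomarker_models() -> dict[str, BiomarkerModel]:
    """Mid-life clinical-chemistry baselines on the NHANES unit scales."""
    return {
        "albumin": BiomarkerModel(50.0, -0.08, 1.0, 2.5, "g/L"),
        "creatinine": BiomarkerModel(60.0, 0.20, 14.0, 11.0, "umol/L"),
        "glucose": BiomarkerModel(4.0, 0.02, 0.1, 0.55, "mmol/L"),
        "crp": BiomarkerModel(0.28, 0.002, -0.02, 0.05, "mg/dL"),
        "lymphocyte_pct": BiomarkerModel(34.0, -0.05, -0.5, 5.5, "%"),
        "mcv": BiomarkerModel(88.0, 0.04, 0.8, 4.0, "fL"),
        "rdw": BiomarkerModel(12.8, 0.008, -0.1, 0.75, "%"),
        "alkaline_phosphatase": BiomarkerModel(65.0, 0.10, 4.0, 14.0, "U/L"),
        "wbc": BiomarkerModel(6.8, 0.0, 0.2, 1.5, "10^3 cells/uL"),
        "total_cholesterol": BiomarkerModel(4.3, 0.015, -0.15, 0.85, "mmol/L"),
    }


#: Default APOE-locus effects: reproduce the qualitative inversion seen in
#: cohort data — the e4-tagging C allele of rs429358 raises cholesterol and
#: lowers CRP; the e2-tagging T allele of rs7412 does the opposite.
_APOE_CAUSAL = (
    (APOE_E4_SNP, "total_cholesterol", 0.25),
    (APOE_E2_SNP, "total_cholesterol", -0.35),
    (APOE_E4_SNP, "crp", -0.008),
    (APOE_E2_SNP, "crp", 0.012),
)

#: Default non-APOE causal SNPs (included when the panel is large enough).
_PANEL_CAUSAL = (
    ("snp_0010", "rdw", 0.12),
    ("snp_0040", "glucose", 0.10),
)


@dataclass(frozen=True)
class SimConfig:
    """Full configuration of the synthetic cohort.

    ``maf_range`` draws each SNP's MAF uniformly from the interval;
    ``ld_block_size``/``ld_rho`` control latent-copula LD blocks among
    consecutive SNPs on a chromosome. ``gamma`` is the Gompertz shape per
    month; ``horizon_years`` is the censoring horizon of follow-up.
    """

    n_samples: int = 5000
    n_snps: int = 200
    maf_range: tuple[float, float] = (0.05, 0.5)
    mafs: tuple[float, ...] | None = None
    ld_block_size: int = 10
    ld_rho: float = 0.4
    age_range: tuple[float, float] = (40.0, 70.0)
    biomarker_models: dict[str, BiomarkerModel] = field(
        default_factory=_default_biomarker_models)
    causal_effects: tuple[tuple[str, str, float], ...] | None = None
    apoe: ApoeSpec | None = field(default_factory=ApoeSpec)
    mortality_params: GompertzClockParams | None = None  # None -> NHANES III PhenoAge
    gamma: float = 0.0076927
    horizon_years: float = 10.0
    n_chromosomes: int = 22
    snp_spacing_bp: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mafs is not None and len(self.mafs) != self.n_snps:
            raise ValueError("mafs must have length n_snps")
        mafs = self.mafs if self.mafs is not None else self.maf_range
        if any(m < 0 or m > 0.5 for m in mafs):
            raise ValueError("MAFs must lie in [0, 0.5]")
        if not (0 <= self.ld_rho < 1):
            raise ValueError("ld_rho must lie in [0, 1)")
        if self.horizon_years <= 0:
            raise ValueError("horizon must be > 0")

    def resolved_causal_effects(self) -> tuple[tuple[str, str, float], ...]:
        """Causal map with defaults adapted to the configured panel."""
        if self.causal_effects is not None:
            return self.causal_effects
        effects = _APOE_CAUSAL if self.apoe is not None else ()
        if self.n_snps > 40:
            effects = effects + _PANEL_CAUSAL
        return effects

    def resolved_mortality_params(self) -> GompertzClockParams:
        """Clock whose linear predictor drives the hazard (xb source)."""
        return self.mortality_params or GompertzClockParams.nhanes3()


class ConfigError(ValueError):
    """The simulation configuration is internally inconsistent."""


@dataclass
class SimResult:
    """A simulated cohort with its generating truth."""

    genotypes: GenotypeMatrix
    cohort: CohortTable
    true_xb: pd.Series
    causal: pd.DataFrame  # columns: snp, biomarker, effect


def _rng_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


# --------------------------------------------------------------------------
# Genotypes
# --------------------------------------------------------------------------

def simulate_genotypes(cfg: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """Draw an HWE genotype matrix with copula LD and the APOE locus.

    Each haplotype's allele indicator is a thresholded latent Gaussian;
    within an LD block the latents share an equicorrelation ``ld_rho``,
    which induces LD between SNPs while each SNP remains marginally
    Bernoulli(maf) per haplotype — hence in HWE.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    if cfg.mafs is not None:
        mafs = np.asarray(cfg.mafs, dtype=float)
    else:
        lo, hi = cfg.maf_range
        mafs = rng.uniform(lo, hi, size=cfg.n_snps)

    # assign positions: chromosomes 1..n_chromosomes filled in turn; each
    # chromosome holds at least one full LD block so blocks never collapse
    per_chrom = max(int(np.ceil(cfg.n_snps / cfg.n_chromosomes)),
                    max(1, cfg.ld_block_size))
    chroms = [str(1 + i // per_chrom) for i in range(cfg.n_snps)]
    bps = [1_000_000 + (i % per_chrom) * cfg.snp_spacing_bp for i in range(cfg.n_snps)]

    dosage = np.empty((n, cfg.n_snps))
    thresholds = stats.norm.ppf(mafs)  # allele present iff latent < threshold
    block = max(1, cfg.ld_block_size)
    start = 0
    while start < cfg.n_snps:
        stop = min(start + block, cfg.n_snps)
        # keep blocks within one chromosome
        while stop > start + 1 and chroms[stop - 1] != chroms[start]:
            stop -= 1
        width = stop - start
        rho = cfg.ld_rho if width > 1 else 0.0
        common = rng.standard_normal((n, 1, 2))
        idio = rng.standard_normal((n, width, 2))
        latent = np.sqrt(rho) * common + np.sqrt(1.0 - rho) * idio
        alleles = latent < thresholds[None, start:stop, None]
        dosage[:, start:stop] = alleles.sum(axis=2)
        start = stop

    snps = pd.DataFrame({
        "id": [f"snp_{i:04d}" for i in range(cfg.n_snps)],
        "chrom": chroms,
        "bp": bps,
        "effect_allele": "G",
        "other_allele": "A",
        "freq": mafs,
        "info": 1.0,
    })

    if cfg.apoe is not None:
        apoe_dosage, apoe_meta = _simulate_apoe(n, cfg.apoe, rng)
        dosage = np.column_stack([dosage, apoe_dosage])
        snps = pd.concat([snps, apoe_meta], ignore_index=True)

    samples = [f"s{i:06d}" for i in range(n)]
    return GenotypeMatrix(samples=samples, snps=snps, dosage=dosage)


def _simulate_apoe(n: int, spec: ApoeSpec, rng: np.random.Generator):
    """Two APOE SNPs from random pairing of e2/e3/e4 haplotypes."""
    haps = rng.choice(3, size=(n, 2), p=spec.freqs)  # 0=e2, 1=e3, 2=e4
    names = np.array(["e2", "e3", "e4"])
    # effect alleles: C at rs429358 (e4 haplotype), T at rs7412 (e2 haplotype)
    e4_dosage = (haps == 2).sum(axis=1).astype(float)
    e2_dosage = (haps == 0).sum(axis=1).astype(float)
    hap_freq = spec.freqs
    meta = pd.DataFrame({
        "id": [APOE_E4_SNP, APOE_E2_SNP],
        "chrom": ["19", "19"],
        "bp": [_APOE_BP[APOE_E4_SNP], _APOE_BP[APOE_E2_SNP]],
        "effect_allele": ["C", "T"],
        "other_allele": ["T", "C"],
        "freq": [hap_freq[2], hap_freq[0]],
        "info": [1.0, 1.0],
    })
    del names
    return np.column_stack([e4_dosage, e2_dosage]), meta


# --------------------------------------------------------------------------
# Phenotypes
# --------------------------------------------------------------------------

def simulate_ages_sexes(cfg: SimConfig, rng: np.random.Generator | None = None):
    """Ages uniform on the recruitment window; sex Bernoulli(1/2)."""
    rng = rng or np.random.default_rng(cfg.seed)
    ages = rng.uniform(*cfg.age_range, size=cfg.n_samples)
    sexes = np.where(rng.random(cfg.n_samples) < 0.5, "female", "male")
    return ages, sexes


def simulate_biomarkers(
    geno: GenotypeMatrix,
    cfg: SimConfig,
    ages: np.ndarray,
    sexes: np.ndarray,
    rng: np.random.Generator | None = None,
) -> CohortTable:
    """Linear age/sex/SNP biomarker model with Gaussian noise."""
    rng = rng or np.random.default_rng(cfg.seed)
    ages = np.asarray(ages, dtype=float)
    male = (np.asarray(sexes) == "male").astype(float)

    causal = cfg.resolved_causal_effects()
    snp_ids = set(geno.snps["id"])
    for snp, bm, _ in causal:
        if snp not in snp_ids:
            raise ConfigError(f"causal SNP {snp!r} not in genotype matrix")
        if bm not in cfg.biomarker_models:
            raise ConfigError(f"causal target biomarker {bm!r} has no model")

    data = pd.DataFrame(index=pd.Index(geno.samples, name="id"))
    data["age"] = ages
    data["sex"] = np.asarray(sexes)
    for name, model in cfg.biomarker_models.items():
        value = (model.intercept + model.age_slope * ages + model.sex_offset * male)
        for snp, bm, effect in causal:
            if bm == name:
                value = value + effect * geno.dosage_of(snp)
        if model.noise_sd > 0:
            value = value + rng.normal(0.0, model.noise_sd, size=len(ages))
        data[name] = value

    return CohortTable(
        data=data,
        biomarkers=list(cfg.biomarker_models),
        units={n_: m.unit for n_, m in cfg.biomarker_models.items()},
    )


def simulate_mortality(
    cohort: CohortTable,
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[CohortTable, pd.Series]:
    """Gompertz proportional-hazard death times from the clock's xb.

    Hazard ``h(t) = exp(xb) * exp(gamma * t)`` with t in months; death time
    by inverse transform of the cumulative hazard
    ``H(t) = exp(xb) * (exp(gamma t) - 1) / gamma``. Deaths after the
    follow-up horizon are censored exactly at the horizon. ``gamma <= 0``
    falls back to the exponential (gamma -> 0) limit, logged.

    Returns the augmented cohort (``follow_up_time`` in years, ``event``)
    and the true xb used.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    params = cfg.resolved_mortality_params()
    xb = linear_predictor(cohort, params)
    lam = np.exp(xb.to_numpy())  # baseline hazard scale per month

    e = rng.exponential(size=cohort.n)  # H(T) ~ Exp(1)
    gamma = cfg.gamma
    if gamma <= 0:
        log.warning("simulate_mortality: gamma <= 0, using exponential hazard limit")
        t_months = e / lam
    else:
        with np.errstate(divide="ignore", over="ignore"):
            t_months = np.log1p(gamma * e / lam) / gamma
    horizon_months = cfg.horizon_years * 12.0
    event = (t_months <= horizon_months).astype(int)
    follow_years = np.minimum(t_months, horizon_months) / 12.0

    out = cohort.with_columns(follow_up_time=follow_years, event=event)
    return out, xb.rename("true_xb")


def simulate_cohort(cfg: SimConfig) -> SimResult:
    """Run the full generator: genotypes, biomarkers, mortality.

    One RNG stream per stage, spawned from ``cfg.seed``, so regenerating
    any single stage with the same seed reproduces it exactly.
    """
    g_rng, p_rng, b_rng, m_rng = _rng_streams(cfg.seed, 4)
    geno = simulate_genotypes(cfg, g_rng)
    ages, sexes = simulate_ages_sexes(cfg, p_rng)
    cohort = simulate_biomarkers(geno, cfg, ages, sexes, b_rng)
    cohort, true_xb = simulate_mortality(cohort, cfg, m_rng)
    causal = pd.DataFrame(list(cfg.resolved_causal_effects()) or None,
                          columns=["snp", "biomarker", "effect"])
    return SimResult(genotypes=geno, cohort=cohort, true_xb=true_xb, causal=causal)


def kdm_params_from_sim(cfg: SimConfig, biomarkers: list[str] | None = None) -> KDMParams:
    """Klemera–Doubal parameters implied by the generator's truth.

    Uses each biomarker's generating intercept (+ half the sex offset, for
    the mixed-sex average) as q_j, age slope as k_j and noise SD as s_j.
    Zero-slope biomarkers are excluded (they carry no age information).
    """
    names = biomarkers or [n for n, m in cfg.biomarker_models.items() if m.age_slope != 0]
    models = {n: cfg.biomarker_models[n] for n in names}
    return KDMParams(
        q={n: m.intercept + 0.5 * m.sex_offset for n, m in models.items()},
        k={n: m.age_slope for n, m in models.items()},
        s={n: m.noise_sd for n, m in models.items()},
        s_ba=31.63,
        units={n: m.unit for n, m in models.items()},
    )
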