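"""Biological-age clocks and age acceleration.

Two composite clocks are implemented:

**PhenoAge** — a Gompertz-mortality clock. A linear predictor *xb* over 9
clinical-chemistry biomarkers plus chronological age feeds a Gompertz
proportional-hazards model; the implied 10-year (120-month) mortality risk

.. math:: \\mathrm{risk} = 1 - \\exp\\{-e^{xb}\\,[e^{120\\gamma}-1]/\\gamma\\}

is mapped to years through the monotone transform

.. math:: \\mathrm{PhenoAge} = 141.50 + \\ln(-0.00553\\,\\ln(1-\\mathrm{risk}))/0.09165.

The coefficients shipped in :func:`GompertzClockParams.nhanes3` were
trained on NHANES III and are tied to those assay units; the module
refuses to score a cohort whose declared units disagree.

**BioAge** — the Klemera–Doubal BA_E estimator: a precision-weighted
average of the per-biomarker implied ages ``(x_j - q_j)/k_j`` (weight
``k_j^2/s_j^2``) and chronological age (weight ``1/s_BA^2``), with
``s_BA = 31.63`` years by default.

**Age acceleration** is the residual of either clock after OLS regression
on chronological age (PhenoAgeAccel / BioAgeAccel).
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import CohortTable, SchemaError

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

log = logging.getLogger(__name__)

__all__ = [
    "GompertzClockParams",
    "KDMParams",
    "linear_predictor",
    "mortality_risk",
    "phenoage_from_risk",
    "risk_from_phenoage",
    "phenoage",
    "kdm_bioage",
    "residual_acceleration",
    "score_cohort",
]


@dataclass(frozen=True)
class GompertzClockParams:
    """Parameters of the Gompertz-mortality (PhenoAge) clock.

    ``coefficients`` maps biomarker name -> per-unit log-hazard weight;
    ``log_biomarkers`` lists biomarkers entered on the natural-log scale
    (raw values <= 0 become missing). ``gamma`` is the Gompertz shape per
    month and ``horizon_months`` the risk horizon (120 months = 10 years).
    ``outer_a/b/c`` are the constants of the risk -> years transform.
    """

    intercept: float
    coefficients: dict[str, float]
    age_coefficient: float
    gamma: float
    horizon_months: float
    outer_a: float
    outer_b: float
    outer_c: float
    log_biomarkers: tuple[str, ...] = ()
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.horizon_months <= 0:
            raise ValueError("horizon must be > 0")

    @classmethod
    def nhanes3(cls) -> "GompertzClockParams":
        """The published NHANES III PhenoAge parameter set."""
        return _load_phenoage_toml()

    @classmethod
    def from_toml(cls, path) -> "GompertzClockParams":
        with open(path, "rb") as fh:
            return cls._from_dict(tomllib.load(fh))

    @classmethod
    def _from_dict(cls, d: dict) -> "GompertzClockParams":
        return cls(
            intercept=float(d["intercept"]),
            coefficients={k: float(v) for k, v in d["coefficients"].items()},
            age_coefficient=float(d["age_coefficient"]),
            gamma=float(d["gamma"]),
            horizon_months=float(d["horizon_months"]),
            outer_a=float(d["outer"]["a"]),
            outer_b=float(d["outer"]["b"]),
            outer_c=float(d["outer"]["c"]),
            log_biomarkers=tuple(d.get("log_biomarkers", ())),
            units=dict(d.get("units", {})),
        )


@dataclass(frozen=True)
class KDMParams:
    """Klemera–Doubal parameters: per-biomarker (q_j, k_j, s_j) and s_BA.

    ``q`` is the intercept and ``k`` the slope of the regression of
    biomarker j on age in the training data; ``s`` its residual SD. The
    chronological-age term enters with precision ``1/s_ba**2``.
    """

    q: dict[str, float]
    k: dict[str, float]
    s: dict[str, float]
    s_ba: float = 31.63
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = set(self.q)
        if not names:
            raise ValueError("KDMParams needs at least one biomarker")
        if set(self.k) != names or set(self.s) != names:
            raise ValueError("q, k, s must cover the same biomarker names")
        if any(sj <= 0 for sj in self.s.values()):
            raise ValueError("all s_j must be > 0")
        if not self.s_ba > 0:
            raise ValueError("s_ba must be > 0")
        if all(kj == 0 for kj in self.k.values()) and not np.isfinite(self.s_ba):
            raise ValueError("degenerate parameters: all k_j zero and no age term")

    @property
    def biomarkers(self) -> list[str]:
        return list(self.q)

    @classmethod
    def from_toml(cls, path) -> "KDMParams":
        with open(path, "rb") as fh:
            d = tomllib.load(fh)
        bm = d["biomarkers"]
        return cls(
            q={n: float(v["q"]) for n, v in bm.items()},
            k={n: float(v["k"]) for n, v in bm.items()},
            s={n: float(v["s"]) for n, v in bm.items()},
            s_ba=float(d.get("s_ba", 31.63)),
            units={n: v.get("unit", "") for n, v in bm.items()},
        )


def _load_phenoage_toml() -> GompertzClockParams:
    from importlib import resources

    ref = resources.files("bioage").joinpath("params/phenoage_nhanes3.toml")
    with ref.open("rb") as fh:
        return GompertzClockParams._from_dict(tomllib.load(fh))


def _check_units(cohort: CohortTable, expected: dict[str, str], names) -> None:
    """Refuse to score when declared cohort units contradict the clock's."""
    mismatches = []
    for name in names:
        want = expected.get(name)
        have = cohort.units.get(name)
        if want and have and want != have:
            mismatches.append(f"{name}: cohort={have!r} clock={want!r}")
    if mismatches:
        raise SchemaError("biomarker unit mismatch — " + "; ".join(mismatches))


def linear_predictor(cohort: CohortTable, params: GompertzClockParams) -> pd.Series:
    """Gompertz log-hazard linear predictor xb per individual.

    ``xb = intercept + sum_j coef_j * x_j + age_coef * age``. Biomarkers in
    ``params.log_biomarkers`` (CRP in the shipped set) are log-transformed
    here; raw values <= 0 are treated as missing. Rows with any missing
    input get a missing xb (counted in the log, never silently dropped).
    """
    unknown = [b for b in params.coefficients if b not in cohort.data.columns]
    if unknown:
        raise SchemaError(f"clock biomarkers absent from cohort: {unknown}")
    _check_units(cohort, params.units, params.coefficients)

    xb = np.full(cohort.n, params.intercept, dtype=float)
    for name, coef in params.coefficients.items():
        x = cohort.data[name].to_numpy(dtype=float).copy()
        if name in params.log_biomarkers:
            with np.errstate(invalid="ignore", divide="ignore"):
                x = np.where(x > 0, np.log(np.where(x > 0, x, 1.0)), np.nan)
        xb = xb + coef * x
    xb = xb + params.age_coefficient * cohort.data["age"].to_numpy(dtype=float)
    n_missing = int(np.isnan(xb).sum())
    if n_missing:
        log.info("linear_predictor: %d of %d rows have missing inputs", n_missing, cohort.n)
    return pd.Series(xb, index=cohort.data.index, name="xb")


def mortality_risk(xb, params: GompertzClockParams) -> np.ndarray:
    """Gompertz mortality risk over the clock horizon, strictly in (0, 1).

    ``risk = 1 - exp(-exp(xb) * (exp(horizon*gamma) - 1) / gamma)``; strictly
    increasing in xb. Extreme xb saturates at the nearest representable
    value inside (0, 1) rather than 0 or 1 exactly.
    """
    xb = np.asarray(xb, dtype=float)
    scale = np.expm1(params.horizon_months * params.gamma) / params.gamma
    with np.errstate(over="ignore"):
        risk = -np.expm1(-np.exp(xb) * scale)
    tiny = np.finfo(float).tiny
    eps = np.finfo(float).eps
    clipped = (risk <= 0) | (risk >= 1)
    if np.any(clipped & np.isfinite(xb)):
        log.info("mortality_risk: %d values clamped at floating-point extremes",
                 int((clipped & np.isfinite(xb)).sum()))
    return np.clip(risk, tiny, 1 - eps)


def phenoage_from_risk(risk, params: GompertzClockParams) -> np.ndarray:
    """Convert mortality risk in (0,1) to PhenoAge years.

    ``PhenoAge = a + ln(-b * ln(1 - risk)) / c`` with the shipped constants
    a=141.50, b=0.00553, c=0.09165. Strictly increasing in risk.
    """
    risk = np.asarray(risk, dtype=float)
    bad = ~np.isnan(risk) & ((risk <= 0) | (risk >= 1))
    if np.any(bad):
        raise ValueError("risk must lie strictly in (0, 1)")
    return params.outer_a + np.log(-params.outer_b * np.log1p(-risk)) / params.outer_c


def risk_from_phenoage(years, params: GompertzClockParams) -> np.ndarray:
    """Inverse of :func:`phenoage_from_risk` (exact on (0, 1))."""
    years = np.asarray(years, dtype=float)
    return -np.expm1(-np.exp((years - params.outer_a) * params.outer_c) / params.outer_b)


def phenoage(cohort: CohortTable, params: GompertzClockParams | None = None) -> pd.DataFrame:
    """Score a cohort: columns ``xb``, ``mortality_risk_10y``, ``phenoage``."""
    params = params or GompertzClockParams.nhanes3()
    xb = linear_predictor(cohort, params)
    risk = np.where(np.isnan(xb), np.nan, np.nan)
    ok = ~np.isnan(xb.to_numpy())
    risk = np.full(cohort.n, np.nan)
    risk[ok] = mortality_risk(xb.to_numpy()[ok], params)
    years = np.full(cohort.n, np.nan)
    years[ok] = phenoage_from_risk(risk[ok], params)
    return pd.DataFrame(
        {"xb": xb, "mortality_risk_10y": risk, "phenoage": years}, index=cohort.data.index
    )


def kdm_bioage(cohort: CohortTable, params: KDMParams) -> pd.Series:
    """Klemera–Doubal biological age (BA_E), in years.

    Weighted average of biomarker-implied ages ``(x_j - q_j)/k_j`` with
    weights ``k_j^2/s_j^2`` and of chronological age with weight
    ``1/s_BA^2``; consequently BA always lies between the minimum and
    maximum of those implied ages and chronological age.
    """
    missing = [b for b in params.biomarkers if b not in cohort.data.columns]
    if missing:
        raise SchemaError(f"KDM biomarkers absent from cohort: {missing}")
    _check_units(cohort, params.units, params.biomarkers)

    age = cohort.data["age"].to_numpy(dtype=float)
    num = age / params.s_ba**2
    den = np.full_like(age, 1.0 / params.s_ba**2)
    for name in params.biomarkers:
        x = cohort.data[name].to_numpy(dtype=float)
        kj, qj, sj = params.k[name], params.q[name], params.s[name]
        num = num + (x - qj) * kj / sj**2
        den = den + kj**2 / sj**2
    return pd.Series(num / den, index=cohort.data.index, name="bioage")


def residual_acceleration(ba, age) -> np.ndarray:
    """Age acceleration: OLS residual of a biological age on (1, age).

    Missing pairs get missing residuals; the fit uses complete pairs only.
    By construction the residuals have mean 0 and zero covariance with age.
    """
    ba = np.asarray(ba, dtype=float)
    age = np.asarray(age, dtype=float)
    ok = np.isfinite(ba) & np.isfinite(age)
    if ok.sum() < 3:
        raise ValueError("need at least 3 complete (ba, age) pairs")
    if np.ptp(age[ok]) == 0:
        raise ValueError("age is constant; acceleration undefined")
    X = np.column_stack([np.ones(ok.sum()), age[ok]])
    coef, *_ = np.linalg.lstsq(X, ba[ok], rcond=None)
    out = np.full(ba.shape, np.nan)
    out[ok] = ba[ok] - X @ coef
    return out


def score_cohort(
    cohort: CohortTable,
    phenoage_params: GompertzClockParams | None = None,
    kdm_params: KDMParams | None = None,
) -> pd.DataFrame:
    """Run both clocks and their accelerations over a cohort.

    Returns a frame with ``xb``, ``mortality_risk_10y``, ``phenoage``,
    ``phenoage_accel`` and, when ``kdm_params`` is given, ``bioage`` and
    ``bioage_accel``.
    """
    out = phenoage(cohort, phenoage_params)
    age = cohort.data["age"].to_numpy(dtype=float)
    out["phenoage_accel"] = residual_acceleration(out["phenoage"].to_numpy(), age)
    if kdm_params is not None:
        ba = kdm_bioage(cohort, kdm_params)
        out["bioage"] = ba
        out["bioage_accel"] = residual_acceleration(ba.to_numpy(), age)
    return out
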