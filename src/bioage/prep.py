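"""Biomarker cleaning applied before clock computation.

The only transformation is two-sided winsorization: values below the 1st
percentile are set to it and values above the 99th to it, correcting
distributional skew before the clocks are evaluated. Percentiles are
computed on non-missing values with the inverted-CDF definition
(Hyndman–Fan type 1): the quantile is an observed order statistic, which
makes the winsorizing map exactly idempotent as well as monotone
non-decreasing (interpolating definitions break the fixed-point property
by pulling the re-computed percentile inside the clipped range).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .types import CohortTable

log = logging.getLogger(__name__)

__all__ = ["WinsorSpec", "winsorize", "apply_prep"]


@dataclass(frozen=True)
class WinsorSpec:
    """Winsorization quantiles with a per-biomarker opt-out.

    ``enabled`` restricts clipping to the named biomarkers; ``None`` means
    every biomarker column of the cohort.
    """

    lower_quantile: float = 0.01
    upper_quantile: float = 0.99
    enabled: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower_quantile < self.upper_quantile <= 1.0):
            raise ValueError(
                f"need 0 <= lower < upper <= 1, got "
                f"({self.lower_quantile}, {self.upper_quantile})"
            )


def winsorize(values, spec: WinsorSpec = WinsorSpec()) -> np.ndarray:
    """Clip a vector to its [lower, upper] sample percentiles.

    Missing entries are untouched and excluded from percentile
    computation. Raises if fewer than 2 non-missing values are present.
    """
    x = np.asarray(values, dtype=float).copy()
    ok = np.isfinite(x)
    if ok.sum() < 2:
        raise ValueError("winsorize needs at least 2 non-missing values")
    lo, hi = np.quantile(x[ok], [spec.lower_quantile, spec.upper_quantile],
                         method="inverted_cdf")
    x[ok] = np.clip(x[ok], lo, hi)
    return x


def apply_prep(cohort: CohortTable, spec: WinsorSpec = WinsorSpec()) -> tuple[CohortTable, pd.DataFrame]:
    """Winsorize biomarker columns of a cohort; returns (cohort, report).

    The report has one row per processed biomarker with the clip bounds
    and the number of values clipped at each tail.
    """
    names = list(spec.enabled) if spec.enabled is not None else list(cohort.biomarkers)
    data = cohort.data.copy()
    rows = []
    for name in names:
        before = data[name].to_numpy(dtype=float)
        after = winsorize(before, spec)
        ok = np.isfinite(before)
        lo, hi = np.quantile(before[ok], [spec.lower_quantile, spec.upper_quantile],
                             method="inverted_cdf")
        n_lo = int((before[ok] < lo).sum())
        n_hi = int((before[ok] > hi).sum())
        data[name] = after
        rows.append({"biomarker": name, "lower": lo, "upper": hi,
                     "n_clipped_low": n_lo, "n_clipped_high": n_hi})
        log.info("winsorize %s: %d low / %d high of %d clipped", name, n_lo, n_hi, ok.sum())
    report = pd.DataFrame(rows, columns=["biomarker", "lower", "upper",
                                         "n_clipped_low", "n_clipped_high"])
    return replace(cohort, data=data), report
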