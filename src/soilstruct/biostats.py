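"""Biomass conversions, yield conversion, two-group tests and correlations.

Chloroform fumigation-extraction converts extractable flushes to microbial
biomass with the standard factors B_C = 2.64 E_C and B_N = 5.0 E_NIN.
Fresh-mass crop yields convert to dry mass via moisture percentage.  Group
comparisons follow the study protocol: a two-tailed F test on the variance
ratio decides between the pooled-variance Student t test and the Welch
(unequal-variance) t test, with significance stars at 0.05 / 0.01 / 0.001.
Profile-level weighted means are correlated with dry yield by Pearson's r
(four farms, so only 2 residual df -- low power, flagged in the output).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "BiomassInput",
    "GroupSummary",
    "CorrelationResult",
    "TwoGroupTestResult",
    "microbial_biomass_c",
    "microbial_biomass_n",
    "dry_yield",
    "round_half_up",
    "f_then_t_test",
    "stars",
    "correlate_with_yield",
]

BIOMASS_C_FACTOR = 2.64
BIOMASS_N_FACTOR = 5.0


@dataclass(frozen=True)
class BiomassInput:
    """Fumigated-minus-unfumigated flushes, ug per g dry soil."""

    E_C: float = float("nan")
    E_NIN: float = float("nan")


@dataclass(frozen=True)
class GroupSummary:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2 replicates")


@dataclass(frozen=True)
class TwoGroupTestResult:
    t_statistic: float
    t_p: float
    f_statistic: float
    f_p: float
    df: float
    variance_assumption: str  # "pooled" | "welch"
    stars: str


@dataclass(frozen=True)
class CorrelationResult:
    parameter: str
    r: float
    n: int
    p_value: float
    low_power: bool = False

    def __post_init__(self) -> None:
        if not -1.0000001 <= self.r <= 1.0000001:
            raise ValueError("Pearson r outside [-1, 1]")


def microbial_biomass_c(E_C: float) -> float:
    """Microbial biomass C (ug g-1) from the fumigation C flush."""
    if not math.isfinite(E_C):
        raise ValueError("E_C must be finite")
    return BIOMASS_C_FACTOR * E_C


def microbial_biomass_n(E_NIN: float) -> float:
    """Microbial biomass N (ug g-1) from the ninhydrin-reactive N flush."""
    if not math.isfinite(E_NIN):
        raise ValueError("E_NIN must be finite")
    return BIOMASS_N_FACTOR * E_NIN


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Decimal round-half-up (the convention used for printed comparisons)."""
    factor = 10.0 ** ndigits
    return math.floor(x * factor + 0.5) / factor


def dry_yield(fresh_t_ha: float, moisture_pct: float, ndigits: int | None = None) -> float:
    """Dry-matter yield from fresh yield and moisture percentage."""
    if not 0 <= moisture_pct <= 100:
        raise ValueError("moisture must be in [0, 100] %")
    if fresh_t_ha < 0:
        raise ValueError("fresh yield must be non-negative")
    value = fresh_t_ha * (1.0 - moisture_pct / 100.0)
    return value if ndigits is None else round_half_up(value, ndigits)


def stars(p: float) -> str:
    """Significance stars at the 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def f_then_t_test(
    a: GroupSummary, b: GroupSummary, alpha_f: float = 0.05
) -> TwoGroupTestResult:
    """Two-tailed F test on variances, then Student or Welch t on the means.

    If the F test does not reject at ``alpha_f`` the pooled-variance Student
    t test is used, otherwise the Welch t test.  t is signed a - b.
    """
    if a.sd == 0 and b.sd == 0:
        if a.mean == b.mean:
            raise ValueError("zero variance in both groups with equal means: t undefined")
        return TwoGroupTestResult(
            t_statistic=math.copysign(float("inf"), a.mean - b.mean),
            t_p=0.0, f_statistic=float("nan"), f_p=float("nan"),
            df=a.n + b.n - 2, variance_assumption="pooled", stars="***",
        )
    va, vb = a.sd**2, b.sd**2
    if va >= vb:
        f_stat, dfn, dfd = (va / vb if vb > 0 else float("inf")), a.n - 1, b.n - 1
    else:
        f_stat, dfn, dfd = vb / va, b.n - 1, a.n - 1
    f_p = min(1.0, 2.0 * float(stats.f.sf(f_stat, dfn, dfd)))
    equal_var = f_p >= alpha_f
    t_stat, t_p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = a.n + b.n - 2
    else:
        df = (va / a.n + vb / b.n) ** 2 / (
            (va / a.n) ** 2 / (a.n - 1) + (vb / b.n) ** 2 / (b.n - 1)
        )
    return TwoGroupTestResult(
        t_statistic=float(t_stat),
        t_p=float(t_p),
        f_statistic=float(f_stat),
        f_p=f_p,
        df=float(df),
        variance_assumption="pooled" if equal_var else "welch",
        stars=stars(float(t_p)),
    )


def correlate_with_yield(
    means_by_farm: dict[str, dict[str, float]],
    yields_by_farm: dict[str, float],
    low_power_n: int = 4,
) -> list[CorrelationResult]:
    """Pearson correlation of each parameter's per-farm means against yield.

    ``means_by_farm`` maps parameter -> {farm: value}.  Farms missing either
    value are dropped per parameter; at least 3 complete pairs are required.
    p comes from the two-sided t transform; correlations with n <= 4 carry a
    low-power flag.
    """
    out: list[CorrelationResult] = []
    for parameter, by_farm in means_by_farm.items():
        farms = [f for f in by_farm if f in yields_by_farm]
        x = np.array([by_farm[f] for f in farms], dtype=float)
        y = np.array([yields_by_farm[f] for f in farms], dtype=float)
        if len(farms) < 3:
            raise ValueError(f"{parameter}: need at least 3 farms with both values")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            raise ValueError(f"{parameter}: zero variance, Pearson r undefined")
        r, p = stats.pearsonr(x, y)
        out.append(
            CorrelationResult(
                parameter=parameter,
                r=float(r),
                n=len(farms),
                p_value=float(p),
                low_power=len(farms) <= low_power_n,
            )
        )
    return out
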