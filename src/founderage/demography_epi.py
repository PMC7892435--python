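"""Demographic conversions and prevalence/cohort arithmetic.

Growth model: T1 = T0 * exp(g * r), so r = ln(T1/T0) / g. Ages in
generations convert to years at a fixed years-per-generation and to calendar
dates by subtracting from an anchor birth year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

from scipy import stats


@dataclass(frozen=True)
class DemographyParams:
    T0: float = 3.5e6
    T1: float = 9.8e6
    years_per_generation: float = 25.0
    anchor_year: int = 1990

    def __post_init__(self) -> None:
        if self.T0 <= 0 or self.T1 <= 0:
            raise ValueError("population sizes must be positive")
        if self.years_per_generation <= 0:
            raise ValueError("years_per_generation must be positive")


@dataclass(frozen=True)
class PrevalenceResult:
    count: int
    n: int
    freq: float
    ci95: tuple[float, float]
    projected: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 <= self.count <= self.n:
            raise ValueError("count must lie in [0, n]")
        if not self.ci95[0] <= self.freq <= self.ci95[1]:
            raise ValueError("CI must contain the point estimate")

    @property
    def percent(self) -> float:
        return 100.0 * self.freq


def growth_rate(T0: float, T1: float, g: float) -> float:
    """Exponential growth rate per generation solving T1 = T0 * e^(g*r)."""
    if T0 <= 0 or T1 <= 0 or g <= 0:
        raise ValueError("T0, T1 and g must be positive")
    return math.log(T1 / T0) / g


def population_size(T0: float, g: float, r: float) -> float:
    """Inverse of growth_rate: T1 implied by (T0, g, r)."""
    if T0 <= 0:
        raise ValueError("T0 must be positive")
    return T0 * math.exp(g * r)


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def generations_to_calendar(
    g: float, params: DemographyParams = DemographyParams()
) -> tuple[int, int]:
    """(elapsed years, calendar date) for an age of g generations.

    Years are rounded to integer before the date subtraction, so the two
    outputs are always consistent.
    """
    if g < 0:
        raise ValueError("g must be non-negative")
    years = _round_half_up(g * params.years_per_generation)
    return years, params.anchor_year - years


def interval_to_calendar(
    g_low: float, g_high: float, params: DemographyParams = DemographyParams()
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Endpoint-wise conversion of a generation interval.

    Returns ((years_low, years_high), (date_early, date_late)); note the date
    axis runs backwards (larger g means an earlier calendar year).
    """
    y_low, d_late = generations_to_calendar(g_low, params)
    y_high, d_early = generations_to_calendar(g_high, params)
    return (y_low, y_high), (d_early, d_late)


def carrier_frequency(count: int, n: int) -> PrevalenceResult:
    """Carrier proportion with an exact (Clopper-Pearson) 95% CI."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= count <= n:
        raise ValueError("count must lie in [0, n]")
    freq = count / n
    lo = 0.0 if count == 0 else float(stats.beta.ppf(0.025, count, n - count + 1))
    hi = 1.0 if count == n else float(stats.beta.ppf(0.975, count + 1, n - count))
    return PrevalenceResult(count=count, n=n, freq=freq, ci95=(lo, hi))


def project_carriers(freq: float, population_size: float) -> int:
    """Expected carrier count in a target population, rounded."""
    if not 0 <= freq <= 1:
        raise ValueError("freq must lie in [0, 1]")
    if population_size < 0:
        raise ValueError("population size must be non-negative")
    return _round_half_up(freq * population_size)


@dataclass(frozen=True)
class TwoByTwoResult:
    odds_ratio: float
    ci95: tuple[float, float]
    chi2_p: float
    fisher_p: float
    corrected: bool  # Haldane-Anscombe +0.5 applied because of a zero cell


def two_by_two(a: int, b: int, c: int, d: int) -> TwoByTwoResult:
    """2x2 association: OR with Woolf 95% CI, chi-square p, Fisher exact p.

    Cells are (a, b) = exposed yes/no, (c, d) = unexposed yes/no. A zero cell
    triggers the Haldane-Anscombe +0.5 correction for the OR and its CI,
    flagged in the result.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError("cells must be non-negative integers")
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        raise ValueError("a row or column of the table sums to zero")
    corrected = 0 in cells
    aa, bb, cc, dd = ((x + 0.5 for x in cells) if corrected else cells)
    or_ = (aa * dd) / (bb * cc)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    ci = (math.exp(math.log(or_) - 1.96 * se), math.exp(math.log(or_) + 1.96 * se))
    chi2_p = float(stats.chi2_contingency([[a, b], [c, d]], correction=False)[1])
    fisher_p = float(stats.fisher_exact([[a, b], [c, d]])[1])
    return TwoByTwoResult(
        odds_ratio=or_, ci95=ci, chi2_p=chi2_p, fisher_p=fisher_p, corrected=corrected
    )
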