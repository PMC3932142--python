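"""Maternal mortality ratio (MMR) arithmetic and national projections.

Cause-specific MMRs are deaths per 100,000 live births.  Scenario-level
overall MMRs add the simulated PPH-specific MMR to the fixed total of all
other cause-specific ratios (default 134 per 100,000, from the national
survey), and national death counts apply the overall MMR to the annual
number of births.

Defaults back-derived from the published tables, all overridable:

* project live-birth denominator 75,000 (117 deaths / overall MMR 156);
* annual national births 3,038,000 (5,620 deaths / overall MMR 185);
* non-PPH cause-specific MMR total 134 per 100,000.

Observed-vs-expected comparisons use a two-sided exact Poisson test (sum of
the probabilities of all counts no more likely than the observed one under
the expected rate).  The published comparison table's test is unstated, so
its printed p-values are not reproduced; this is the defensible default for
rare-event rate comparison.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_LIVE_BIRTHS",
    "DEFAULT_ANNUAL_BIRTHS",
    "DEFAULT_OTHER_CAUSES_MMR",
    "CauseSpecificMMR",
    "NationalProjection",
    "ObservedExpected",
    "cause_specific_mmr",
    "poisson_exact_test",
    "compare_observed_expected",
    "overall_mmr",
    "national_projection",
    "mmr_reduction",
    "project_scenario",
    "observed_expected_table",
    "scenario_projection_table",
]

DEFAULT_LIVE_BIRTHS = 75_000
DEFAULT_ANNUAL_BIRTHS = 3_038_000
DEFAULT_OTHER_CAUSES_MMR = 134.0


@dataclass(frozen=True)
class CauseSpecificMMR:
    cause: str
    deaths: int
    live_births: int
    mmr: float


@dataclass(frozen=True)
class ObservedExpected:
    observed_mmr: float
    expected_mmr: float
    difference: float
    p_value: float
    underflow: bool = False  # expected count 0 with observed deaths > 0


@dataclass(frozen=True)
class NationalProjection:
    scenario_name: str
    pph_mmr: float
    other_causes_mmr: float
    overall_mmr: float
    annual_births: int
    total_deaths: int


def cause_specific_mmr(deaths: float, live_births: float) -> float:
    """Deaths per 100,000 live births for one attributed cause."""
    if live_births <= 0:
        raise ValueError("live_births must be positive")
    if deaths < 0 or deaths > live_births:
        raise ValueError("deaths must lie in [0, live_births]")
    return deaths / live_births * 100_000.0


def poisson_exact_test(observed: int, expected_count: float) -> float:
    """Two-sided exact Poisson test of an observed count against a rate.

    Sums the probabilities of every count whose likelihood under
    ``Poisson(expected_count)`` does not exceed that of the observed count
    (minimum-likelihood method).  Returns 1.0 when observed equals the
    (integer) expectation.
    """
    if observed < 0:
        raise ValueError("observed must be non-negative")
    if expected_count < 0:
        raise ValueError("expected_count must be non-negative")
    if expected_count == 0:
        return 1.0 if observed == 0 else 0.0
    hi = int(max(observed, expected_count + 10.0 * math.sqrt(expected_count) + 30))
    k = np.arange(0, hi + 1)
    pmf = stats.poisson.pmf(k, expected_count)
    p_obs = stats.poisson.pmf(observed, expected_count)
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-7)].sum())
    # counts beyond hi have negligible mass by construction
    return min(p, 1.0)


def compare_observed_expected(
    observed_deaths: int,
    live_births: float,
    expected_mmr: float,
) -> ObservedExpected:
    """Contrast an observed cause-specific MMR with an expected one.

    The difference is observed − expected (per 100,000); the p-value comes
    from :func:`poisson_exact_test` at the expected count
    ``expected_mmr * live_births / 100,000``.
    """
    if expected_mmr < 0:
        raise ValueError("expected_mmr must be non-negative")
    observed = cause_specific_mmr(observed_deaths, live_births)
    expected_count = expected_mmr * live_births / 100_000.0
    underflow = expected_count == 0 and observed_deaths > 0
    if underflow:
        warnings.warn(
            "expected count is 0 with observed deaths > 0; p-value reported as 0",
            RuntimeWarning,
            stacklevel=2,
        )
    p = poisson_exact_test(observed_deaths, expected_count)
    return ObservedExpected(
        observed_mmr=observed,
        expected_mmr=expected_mmr,
        difference=observed - expected_mmr,
        p_value=p,
        underflow=underflow,
    )


def overall_mmr(pph_mmr: float, other_causes_mmr: float = DEFAULT_OTHER_CAUSES_MMR) -> float:
    """Overall MMR: PPH-specific ratio plus the fixed non-PPH total."""
    if pph_mmr < 0 or other_causes_mmr < 0:
        raise ValueError("rates must be non-negative")
    return pph_mmr + other_causes_mmr


def national_projection(
    overall: float, annual_births: int = DEFAULT_ANNUAL_BIRTHS
) -> int:
    """Total annual maternal deaths implied by an overall MMR."""
    if annual_births <= 0:
        raise ValueError("annual_births must be positive")
    return round(overall * annual_births / 100_000.0)


def mmr_reduction(mmr_a: float, mmr_b: float) -> tuple[float, float]:
    """Absolute and relative (%) reduction going from ``mmr_a`` to ``mmr_b``."""
    if mmr_a <= 0:
        raise ValueError("baseline MMR must be positive")
    absolute = mmr_a - mmr_b
    return absolute, absolute / mmr_a * 100.0


def project_scenario(
    scenario_name: str,
    pph_mmr: float,
    other_causes_mmr: float = DEFAULT_OTHER_CAUSES_MMR,
    annual_births: int = DEFAULT_ANNUAL_BIRTHS,
) -> NationalProjection:
    total = overall_mmr(pph_mmr, other_causes_mmr)
    return NationalProjection(
        scenario_name=scenario_name,
        pph_mmr=pph_mmr,
        other_causes_mmr=other_causes_mmr,
        overall_mmr=total,
        annual_births=annual_births,
        total_deaths=national_projection(total, annual_births),
    )


def observed_expected_table(
    deaths_by_cause: Mapping[str, int],
    live_births: float = DEFAULT_LIVE_BIRTHS,
    expected_mmrs: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Observed (and, where available, expected) cause-specific MMRs.

    Causes without an expected ratio get NaN difference and p-value, mirroring
    categories absent from the reference survey.
    """
    expected_mmrs = expected_mmrs or {}
    rows = []
    for cause, deaths in deaths_by_cause.items():
        obs = cause_specific_mmr(deaths, live_births)
        if cause in expected_mmrs:
            cmp = compare_observed_expected(deaths, live_births, expected_mmrs[cause])
            rows.append((cause, deaths, round(obs, 1), cmp.expected_mmr,
                         round(cmp.difference, 2), cmp.p_value))
        else:
            rows.append((cause, deaths, round(obs, 1), np.nan, np.nan, np.nan))
    return pd.DataFrame(
        rows,
        columns=["cause", "deaths", "observed_mmr", "expected_mmr", "difference", "p_value"],
    )


def scenario_projection_table(
    pph_means: Mapping[str, float],
    other_causes_mmr: float = DEFAULT_OTHER_CAUSES_MMR,
    annual_births: int = DEFAULT_ANNUAL_BIRTHS,
) -> pd.DataFrame:
    """Scenario table: PPH MMR, overall MMR and national death counts."""
    # Display convention: the overall MMR and national count are computed
    # from the whole-number PPH MMR, as in the published scenario table.
    rows = []
    for name, mean in pph_means.items():
        pph_r = round(mean)
        overall_r = overall_mmr(pph_r, other_causes_mmr)
        rows.append(
            (name, pph_r, other_causes_mmr, overall_r,
             national_projection(overall_r, annual_births))
        )
    return pd.DataFrame(
        rows,
        columns=["scenario", "pph_mmr", "other_causes_mmr", "overall_mmr", "total_deaths"],
    )
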