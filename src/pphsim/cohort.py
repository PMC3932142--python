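"""Decision-tree cohort model for PPH deaths at home births.

A hypothetical cohort of ``N`` singleton home live births (default 100,000)
flows through four branch points: receipt of a clean delivery kit (CDK), use
of the misoprostol it contains, experience of postpartum haemorrhage (PPH),
and death from PPH.  With fractions ``c`` (CDK coverage), ``u`` (use given
CDK), ``q_m``/``q_n`` (PPH incidence with/without misoprostol) and
``d_m``/``d_n`` (death given PPH with/without misoprostol), one evaluation of
the tree gives

    users      = N * c * u
    non-users  = N * (1 - c * u)
    deaths     = users * q_m * d_m + non-users * q_n * d_n

All quantities are real-valued expectations: the tree propagates assumption
uncertainty, it does not resample individual women (the synthetic-data module
does that).  Women who receive a kit but do not use the misoprostol merge
with the never-received branch, so the population always sums to ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .distributions import (
    AssumptionError,
    TriangleSpec,
    load_assumption_table,
    specs_by_id,
)

__all__ = [
    "ASSUMPTION_ORDER",
    "AssumptionSet",
    "Scenario",
    "CohortOutcome",
    "TreeDrawError",
    "evaluate_tree",
    "analytic_mean_deaths",
    "analytic_variance_deaths_no_coverage",
    "scenario_names",
    "load_scenario",
    "load_assumption_set",
]

#: Sampling order of the six assumption cells; the engine and the
#: sensitivity report both follow it.
ASSUMPTION_ORDER = (
    "cdk",
    "use",
    "pph_user",
    "die_user",
    "pph_nonuser",
    "die_nonuser",
)

DEFAULT_COHORT_SIZE = 100_000


class TreeDrawError(ValueError):
    """A sampled value fell outside its assumption's support."""


@dataclass(frozen=True)
class AssumptionSet:
    """The four PPH/death assumptions shared by every scenario (percent).

    Death probabilities are conditional on PPH, not marginal; the published
    elicitation puts both death-given-PPH cells at Tri(0.2, 0.3, 0.4)%.
    """

    pph_user: TriangleSpec
    die_user: TriangleSpec
    pph_nonuser: TriangleSpec
    die_nonuser: TriangleSpec

    @classmethod
    def from_table(cls, table: pd.DataFrame) -> "AssumptionSet":
        shared = specs_by_id(table)
        try:
            return cls(
                pph_user=shared["pph_given_use"],
                die_user=shared["death_given_pph_use"],
                pph_nonuser=shared["pph_given_nonuse"],
                die_nonuser=shared["death_given_pph_nonuse"],
            )
        except KeyError as exc:  # pragma: no cover - malformed user table
            raise AssumptionError(f"shared assumption missing: {exc}") from exc

    @classmethod
    def default(cls) -> "AssumptionSet":
        return cls.from_table(load_assumption_table())

    def spec_for(self, key: str) -> TriangleSpec:
        return getattr(self, key)


@dataclass(frozen=True)
class Scenario:
    """A named misoprostol-coverage assumption bundle.

    The four canonical scenarios are ``project`` (CDK coverage
    Tri(49,69,89)%), ``none`` (0%), ``low`` (Tri(20,40,60)%) and ``high``
    (Tri(60,80,100)%); all but ``none`` share use-given-CDK Tri(80,94,100)%.
    """

    name: str
    p_cdk: TriangleSpec
    p_use_given_cdk: TriangleSpec
    cohort_size: int = DEFAULT_COHORT_SIZE

    def __post_init__(self) -> None:
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")

    def spec_for(self, key: str) -> TriangleSpec:
        return {"cdk": self.p_cdk, "use": self.p_use_given_cdk}[key]


@dataclass(frozen=True)
class CohortOutcome:
    """Branch totals from one tree evaluation (real-valued counts)."""

    n_users: float | np.ndarray
    n_nonusers: float | np.ndarray
    pph_users: float | np.ndarray
    pph_nonusers: float | np.ndarray
    deaths: float | np.ndarray


def _spec_for(scenario: Scenario, assumptions: AssumptionSet, key: str) -> TriangleSpec:
    if key in ("cdk", "use"):
        return scenario.spec_for(key)
    return assumptions.spec_for(key)


def evaluate_tree(
    scenario: Scenario,
    assumptions: AssumptionSet,
    draw: Mapping[str, float | np.ndarray],
) -> CohortOutcome:
    """Evaluate the decision tree at one draw of the six assumptions.

    ``draw`` maps each key in :data:`ASSUMPTION_ORDER` to a percent value
    (scalar or array; arrays are evaluated elementwise).  Values outside the
    corresponding assumption's support raise :class:`TreeDrawError`.
    """
    vals: dict[str, np.ndarray] = {}
    for key in ASSUMPTION_ORDER:
        if key not in draw:
            raise TreeDrawError(f"draw is missing assumption {key!r}")
        x = np.asarray(draw[key], dtype=float)
        spec = _spec_for(scenario, assumptions, key)
        if np.any(x < spec.minimum - 1e-9) or np.any(x > spec.maximum + 1e-9):
            raise TreeDrawError(
                f"draw for {key!r} outside support "
                f"[{spec.minimum}, {spec.maximum}]"
            )
        vals[key] = x / 100.0  # percent -> fraction

    n = float(scenario.cohort_size)
    coverage = vals["cdk"] * vals["use"]  # fraction actually using misoprostol
    n_users = n * coverage
    n_nonusers = n - n_users
    pph_users = n_users * vals["pph_user"]
    pph_nonusers = n_nonusers * vals["pph_nonuser"]
    deaths = pph_users * vals["die_user"] + pph_nonusers * vals["die_nonuser"]
    return CohortOutcome(
        n_users=n_users,
        n_nonusers=n_nonusers,
        pph_users=pph_users,
        pph_nonusers=pph_nonusers,
        deaths=deaths,
    )


def analytic_mean_deaths(scenario: Scenario, assumptions: AssumptionSet) -> float:
    """Exact expectation of the death count.

    Assumptions are sampled independently, so the expectation distributes
    over the products in the tree equation.
    """
    n = float(scenario.cohort_size)
    c = scenario.p_cdk.mean() / 100.0
    u = scenario.p_use_given_cdk.mean() / 100.0
    qm = assumptions.pph_user.mean() / 100.0
    dm = assumptions.die_user.mean() / 100.0
    qn = assumptions.pph_nonuser.mean() / 100.0
    dn = assumptions.die_nonuser.mean() / 100.0
    cov = c * u
    return n * (cov * qm * dm + (1.0 - cov) * qn * dn)


def analytic_variance_deaths_no_coverage(
    assumptions: AssumptionSet, cohort_size: int = DEFAULT_COHORT_SIZE
) -> float:
    """Exact variance of the death count when coverage is zero.

    With no coverage the tree collapses to ``deaths = N * q_n * d_n``, a
    product of two independent variables, whose variance is
    ``E[q]^2 Var[d] + E[d]^2 Var[q] + Var[q] Var[d]`` (exact, including the
    cross term).
    """
    q = assumptions.pph_nonuser
    d = assumptions.die_nonuser
    eq, ed = q.mean() / 100.0, d.mean() / 100.0
    vq, vd = q.variance() / 1e4, d.variance() / 1e4
    return float(cohort_size) ** 2 * (eq * eq * vd + ed * ed * vq + vq * vd)


def scenario_names(table: pd.DataFrame | None = None) -> list[str]:
    """Scenario labels present in an assumption table, in file order."""
    df = table if table is not None else load_assumption_table()
    names = [s for s in df["scenario"].unique() if s != "all"]
    return list(names)


def load_scenario(
    name: str,
    table: pd.DataFrame | None = None,
    cohort_size: int = DEFAULT_COHORT_SIZE,
) -> Scenario:
    """Build one canonical scenario from an assumption table."""
    df = table if table is not None else load_assumption_table()
    block = specs_by_id(df, name)
    if not block:
        raise AssumptionError(
            f"scenario {name!r} not found; available: {scenario_names(df)}"
        )
    try:
        scen = Scenario(
            name=name,
            p_cdk=block["cdk_received"],
            p_use_given_cdk=block["miso_given_cdk"],
            cohort_size=cohort_size,
        )
    except KeyError as exc:  # pragma: no cover - malformed user table
        raise AssumptionError(f"scenario {name!r} missing row: {exc}") from exc
    return scen


def load_assumption_set(table: pd.DataFrame | None = None) -> AssumptionSet:
    df = table if table is not None else load_assumption_table()
    return AssumptionSet.from_table(df)
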