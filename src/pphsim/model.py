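"""Monte Carlo engine: scenario model and results objects.

The surface follows the model/results convention of statsmodels: a
:class:`ScenarioModel` is built from a scenario and an assumption set, its
:meth:`~ScenarioModel.fit` runs the plain Monte Carlo simulation (default
50,000 iterations) and returns a :class:`MonteCarloResults` carrying the
per-iteration draws and death counts, summary statistics, the sensitivity
analysis and downstream mortality projections.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import mmr as _mmr
from .cohort import (
    ASSUMPTION_ORDER,
    DEFAULT_COHORT_SIZE,
    AssumptionSet,
    Scenario,
    analytic_mean_deaths,
    evaluate_tree,
    load_assumption_set,
    load_assumption_table,
    load_scenario,
    scenario_names,
)

__all__ = [
    "DEFAULT_ITERATIONS",
    "ScenarioModel",
    "MonteCarloResults",
    "SimulationResult",
    "ForecastSummary",
    "run_scenario",
    "run_all_scenarios",
    "summarize",
]

DEFAULT_ITERATIONS = 50_000


@dataclass(frozen=True)
class ForecastSummary:
    """Summary of a forecast distribution (deaths per cohort of live births)."""

    scenario: str
    n_iterations: int
    mean: float
    sd: float
    minimum: float
    maximum: float

    def rounded(self) -> "ForecastSummary":
        """Display convention: whole deaths for mean/range, 2 d.p. for SD."""
        return ForecastSummary(
            scenario=self.scenario,
            n_iterations=self.n_iterations,
            mean=round(self.mean),
            sd=round(self.sd, 2),
            minimum=round(self.minimum),
            maximum=round(self.maximum),
        )


class ScenarioModel:
    """Monte Carlo model of PPH deaths for one coverage scenario.

    Parameters
    ----------
    scenario
        Coverage assumption bundle (see :class:`pphsim.cohort.Scenario`).
    assumptions
        Shared PPH/death assumptions; the packaged defaults are used when
        omitted.
    cohort_size
        Overrides the scenario's cohort size when given.
    """

    def __init__(
        self,
        scenario: Scenario,
        assumptions: AssumptionSet | None = None,
        cohort_size: int | None = None,
    ) -> None:
        if cohort_size is not None:
            scenario = Scenario(
                name=scenario.name,
                p_cdk=scenario.p_cdk,
                p_use_given_cdk=scenario.p_use_given_cdk,
                cohort_size=cohort_size,
            )
        self.scenario = scenario
        self.assumptions = assumptions if assumptions is not None else load_assumption_set()

    @classmethod
    def from_name(
        cls,
        name: str,
        table: pd.DataFrame | None = None,
        cohort_size: int = DEFAULT_COHORT_SIZE,
    ) -> "ScenarioModel":
        """Build a model for one canonical scenario of an assumption table."""
        df = table if table is not None else load_assumption_table()
        return cls(
            load_scenario(name, df, cohort_size=cohort_size),
            AssumptionSet.from_table(df),
        )

    def expected_deaths(self) -> float:
        """Closed-form expectation of the forecast (no simulation)."""
        return analytic_mean_deaths(self.scenario, self.assumptions)

    def fit(
        self,
        n_iterations: int = DEFAULT_ITERATIONS,
        seed: int | np.random.SeedSequence | None = None,
    ) -> "MonteCarloResults":
        """Run the simulation: one independent draw per assumption per
        iteration, evaluated through the decision tree.

        Deterministic given ``seed``; the per-assumption draw matrix is
        retained so the sensitivity analysis needs no rerun.
        """
        if n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        rng = np.random.default_rng(seed)
        draws: dict[str, np.ndarray] = {}
        for key in ASSUMPTION_ORDER:
            spec = (
                self.scenario.spec_for(key)
                if key in ("cdk", "use")
                else self.assumptions.spec_for(key)
            )
            draws[key] = spec.sample(n_iterations, rng)
        outcome = evaluate_tree(self.scenario, self.assumptions, draws)
        return MonteCarloResults(
            model=self,
            draws=pd.DataFrame(draws, columns=list(ASSUMPTION_ORDER)),
            deaths=np.asarray(outcome.deaths, dtype=float),
            seed=seed,
        )


class MonteCarloResults:
    """Results of one simulated scenario.

    Attributes
    ----------
    draws
        DataFrame (n_iterations x 6) of the sampled assumption values, in
        percent, columns ordered as :data:`pphsim.cohort.ASSUMPTION_ORDER`.
    deaths
        Per-iteration PPH death counts (length n_iterations).
    """

    def __init__(
        self,
        model: ScenarioModel,
        draws: pd.DataFrame,
        deaths: np.ndarray,
        seed,
    ) -> None:
        if len(draws) != len(deaths):
            raise ValueError("draw matrix and death sequence disagree in length")
        self.model = model
        self.draws = draws
        self.deaths = deaths
        self.seed = seed

    # -- basic accessors ---------------------------------------------------
    @property
    def scenario_name(self) -> str:
        return self.model.scenario.name

    @property
    def n_iterations(self) -> int:
        return len(self.deaths)

    @property
    def mean_deaths(self) -> float:
        return float(np.mean(self.deaths))

    @property
    def sd_deaths(self) -> float:
        return float(np.std(self.deaths, ddof=1)) if len(self.deaths) > 1 else 0.0

    # -- spec surface ------------------------------------------------------
    def forecast(self) -> ForecastSummary:
        if self.n_iterations == 0:
            raise ValueError("empty simulation result")
        return ForecastSummary(
            scenario=self.scenario_name,
            n_iterations=self.n_iterations,
            mean=self.mean_deaths,
            sd=self.sd_deaths,
            minimum=float(np.min(self.deaths)),
            maximum=float(np.max(self.deaths)),
        )

    def sensitivity(self):
        """Contribution-to-variance report (see :mod:`pphsim.sensitivity`)."""
        from .sensitivity import contribution_to_variance

        return contribution_to_variance(self)

    def overall_mmr(self, other_causes_mmr: float = _mmr.DEFAULT_OTHER_CAUSES_MMR) -> float:
        """PPH-specific MMR from this run plus the fixed non-PPH total."""
        return _mmr.overall_mmr(self.mean_deaths, other_causes_mmr)

    def national_projection(
        self,
        annual_births: int = _mmr.DEFAULT_ANNUAL_BIRTHS,
        other_causes_mmr: float = _mmr.DEFAULT_OTHER_CAUSES_MMR,
    ):
        return _mmr.project_scenario(
            self.scenario_name, self.mean_deaths, other_causes_mmr, annual_births
        )

    def to_frame(self) -> pd.DataFrame:
        """Per-iteration draws (percent) plus the death count."""
        out = self.draws.copy()
        out["deaths"] = self.deaths
        return out

    def summary(self) -> str:
        f = self.forecast()
        a = self.model.expected_deaths()
        lines = [
            "Monte Carlo forecast of PPH deaths",
            "==================================",
            f"Scenario:            {f.scenario}",
            f"Cohort size:         {self.model.scenario.cohort_size:,} home live births",
            f"Iterations:          {f.n_iterations:,}   (seed={self.seed!r})",
            f"Mean PPH deaths:     {f.mean:8.2f}   (analytic expectation {a:.2f})",
            f"Std deviation:       {f.sd:8.2f}",
            f"Range:               {f.minimum:8.2f} - {f.maximum:.2f}",
            f"Overall MMR (+{_mmr.DEFAULT_OTHER_CAUSES_MMR:.0f}):  {self.overall_mmr():8.1f} per 100,000 live births",
        ]
        return "\n".join(lines)

    def plot_forecast(self, ax=None, bins: int = 60):
        """Histogram of the forecast distribution."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.deaths, bins=bins, color="#4878a8", edgecolor="white")
        ax.set_xlabel("PPH deaths per 100,000 home live births")
        ax.set_ylabel("iterations")
        ax.set_title(f"Scenario {self.scenario_name!r}")
        return ax


#: Spec-level alias: a fitted results object is the simulation record.
SimulationResult = MonteCarloResults


def run_scenario(
    scenario: Scenario,
    assumptions: AssumptionSet,
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int | np.random.SeedSequence | None = None,
) -> MonteCarloResults:
    """Functional wrapper over ``ScenarioModel(...).fit(...)``."""
    return ScenarioModel(scenario, assumptions).fit(n_iterations=n_iterations, seed=seed)


def run_all_scenarios(
    n_iterations: int = DEFAULT_ITERATIONS,
    seed: int | None = None,
    table: pd.DataFrame | None = None,
    cohort_size: int = DEFAULT_COHORT_SIZE,
) -> dict[str, MonteCarloResults]:
    """Run every scenario in the assumption table.

    Each scenario gets an independent child stream spawned from ``seed`` so
    results do not depend on execution order.
    """
    df = table if table is not None else load_assumption_table()
    names = scenario_names(df)
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: ScenarioModel.from_name(name, df, cohort_size=cohort_size).fit(
            n_iterations=n_iterations, seed=child
        )
        for name, child in zip(names, children)
    }


def summarize(result: MonteCarloResults) -> ForecastSummary:
    """Summary statistics of a simulation (mean, sample SD, min, max)."""
    return result.forecast()
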