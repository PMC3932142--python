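import pytest

import pphsim


@pytest.fixture(scope="session")
def table():
    return pphsim.load_assumption_table()


@pytest.fixture(scope="session")
def assumptions(table):
    return pphsim.AssumptionSet.from_table(table)


@pytest.fixture(scope="session")
def scenarios(table):
    return {name: pphsim.load_scenario(name, table) for name in pphsim.scenario_names(table)}


@pytest.fixture(scope="session")
def full_runs(table):
    """One 50,000-iteration run per canonical scenario, fixed seed."""
    return pphsim.run_all_scenarios(n_iterations=50_000, seed=1234, table=table)
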