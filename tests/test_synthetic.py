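import math

import numpy as np
import pandas as pd
import pytest

from pphsim import (
    GeneratorParams,
    Scenario,
    TriangleSpec,
    analytic_mean_deaths,
    generate_cohort,
    load_reference_deaths,
    recover_parameters,
    reference_death_records,
    tabulate_deaths,
)
from pphsim.cohort import AssumptionSet
from pphsim.synthetic import CAUSES


def binom_se(p, n):
    return math.sqrt(p * (1 - p) / n)


class TestReferenceDeaths:
    def test_packaged_file_matches_builder(self):
        pd.testing.assert_frame_equal(load_reference_deaths(), reference_death_records())

    def test_totals_and_shares(self):
        tab = tabulate_deaths(reference_death_records())
        assert tab.n_deaths == 117
        assert tab.pph_share_pct == 46.2
        assert tab.direct_share_pct == 94.0

    def test_marginals_match_published_counts(self):
        tab = tabulate_deaths(reference_death_records())
        timing = tab.crosstabs["timing"]
        assert timing.sum().to_dict() == {"after": 71, "before": 27, "during": 17, "unknown": 2}
        assert int(tab.crosstabs["took_misoprostol"]["yes"].sum()) == 27
        place = tab.crosstabs["place"]
        assert int(place["home"].sum()) == 47 and int(place["facility"].sum()) == 35
        att = tab.crosstabs["attendant"]
        assert int(att["skilled"].sum()) == 38 and int(att["unskilled"].sum()) == 73

    def test_pph_misoprostol_split(self):
        deaths = reference_death_records()
        pph = deaths[deaths["cause_of_death"] == "pph"]
        counts = pph["took_misoprostol"].value_counts().to_dict()
        assert counts["yes"] == 17 and counts["no"] == 16
        assert counts["unknown"] == 54 - 17 - 16


class TestGeneratorParams:
    def test_fraction_bounds_enforced(self):
        with pytest.raises(ValueError, match="p_cdk"):
            GeneratorParams(p_cdk=1.2)

    def test_cause_weights_must_sum_to_one(self):
        with pytest.raises(ValueError):
            GeneratorParams(cause_weights={"eclampsia": 0.5, "indirect": 0.4})

    def test_unknown_cause_rejected(self):
        with pytest.raises(ValueError, match="unknown causes"):
            GeneratorParams(cause_weights={"plague": 1.0})


@pytest.fixture(scope="module")
def cohort():
    return generate_cohort(GeneratorParams(n_deliveries=100_000, seed=42))


class TestGenerateCohort:
    def test_deterministic_given_seed(self):
        a = generate_cohort(GeneratorParams(n_deliveries=2_000, seed=9))
        b = generate_cohort(GeneratorParams(n_deliveries=2_000, seed=9))
        pd.testing.assert_frame_equal(a, b)

    def test_record_invariants_hold_everywhere(self, cohort):
        used = cohort["used_misoprostol"].fillna(False).to_numpy(dtype=bool)
        assert not np.any(used & ~cohort["received_cdk"].to_numpy())
        died = cohort["died"].to_numpy()
        assert np.array_equal(cohort["cause_of_death"].ne("").to_numpy(), died)
        assert np.array_equal(cohort["timing"].ne("").to_numpy(), died)
        pph_cause = cohort["cause_of_death"].eq("pph").to_numpy()
        assert not np.any(pph_cause & ~cohort["had_pph"].to_numpy())
        assert set(cohort.loc[died, "cause_of_death"]) <= set(CAUSES)

    def test_branch_fractions_near_defaults(self, cohort):
        n = len(cohort)
        frac_cdk = cohort["received_cdk"].mean()
        assert abs(frac_cdk - 0.69) < 3 * binom_se(0.69, n)
        use = cohort["used_misoprostol"].fillna(False)
        frac_use = use[cohort["received_cdk"]].mean()
        assert abs(frac_use - 0.94) < 3 * binom_se(0.94, int(cohort["received_cdk"].sum()))
        assert abs(cohort["used_mat"].mean() - 0.68) < 3 * binom_se(0.68, n)

    def test_pph_deaths_match_cohort_model_expectation(self, cohort):
        """Binomially sampled PPH deaths agree with the expectation-propagating
        tree at the generator's fixed fractions."""
        point = lambda v: TriangleSpec(v, v, v)
        scen = Scenario("gen", point(69.0), point(94.0), cohort_size=len(cohort))
        a = AssumptionSet(point(11.5), point(0.3), point(17.0), point(0.3))
        expected = analytic_mean_deaths(scen, a)
        observed = int((cohort["cause_of_death"] == "pph").sum())
        assert abs(observed - expected) < 4 * math.sqrt(expected)

    def test_no_pph_deaths_when_death_rate_zero(self):
        cohort = generate_cohort(
            GeneratorParams(n_deliveries=20_000, p_die_given_pph=0.0, seed=1)
        )
        assert not (cohort["cause_of_death"] == "pph").any()

    def test_unknown_misoprostol_case_injection(self):
        cohort = generate_cohort(
            GeneratorParams(n_deliveries=50_000, seed=2,
                            include_unknown_misoprostol_case=True)
        )
        assert int(cohort["used_misoprostol"].isna().sum()) == 1
        tab = tabulate_deaths(cohort)
        assert int(tab.crosstabs["took_misoprostol"].get("unknown", pd.Series()).sum()) == 1


class TestTabulation:
    def test_totals_equal_death_records(self):
        cohort = generate_cohort(GeneratorParams(n_deliveries=100_000, seed=7))
        tab = tabulate_deaths(cohort)
        assert tab.n_deaths == int(cohort["died"].sum())
        assert int(tab.by_cause["deaths"].sum()) == tab.n_deaths
        for attr_tab in tab.crosstabs.values():
            assert int(attr_tab.to_numpy().sum()) == tab.n_deaths

    def test_single_death_is_100_pct(self):
        one = reference_death_records().iloc[[0]]
        tab = tabulate_deaths(one)
        assert tab.by_cause.loc["pph", "pct"] == 100.0

    def test_cause_shares_track_generator_weights(self):
        cohort = generate_cohort(GeneratorParams(n_deliveries=100_000, seed=11))
        tab = tabulate_deaths(cohort)
        other = tab.by_cause.drop("pph")
        n_other = int(other["deaths"].sum())
        for cause in other.index:
            w = GeneratorParams().cause_weights[cause]
            frac = other.loc[cause, "deaths"] / n_other
            assert abs(frac - w) < 3 * binom_se(w, n_other) + 1e-9

    def test_empty_records_rejected(self):
        with pytest.raises(ValueError):
            tabulate_deaths(reference_death_records().iloc[:0])


class TestParameterRecovery:
    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_round_trip_within_four_se(self, seed):
        params = GeneratorParams(n_deliveries=50_000, seed=seed)
        cohort = generate_cohort(params)
        est = recover_parameters(cohort).to_dict()
        strata = {
            "p_cdk": len(cohort),
            "p_use_given_cdk": int(cohort["received_cdk"].sum()),
            "p_mat": len(cohort),
            "p_pph_user": int(cohort["used_misoprostol"].fillna(False).sum()),
            "p_pph_nonuser": int((~cohort["used_misoprostol"].fillna(False)).sum()),
            "p_die_given_pph": int(cohort["had_pph"].sum()),
        }
        for name, n in strata.items():
            truth = getattr(params, name)
            assert abs(est[name] - truth) < 4 * binom_se(truth, n) + 1e-12, name

    def test_deterministic_params_recover_exactly(self):
        params = GeneratorParams(
            n_deliveries=5_000, p_cdk=1.0, p_use_given_cdk=1.0, p_mat=0.0,
            p_pph_user=1.0, p_pph_nonuser=1.0, p_die_given_pph=0.0,
            p_die_other=0.0, seed=0,
        )
        est = recover_parameters(generate_cohort(params))
        assert est.p_cdk == 1.0 and est.p_use_given_cdk == 1.0
        assert est.p_pph_user == 1.0 and est.p_mat == 0.0
        assert math.isnan(est.p_die_given_pph) is False
        assert est.p_die_given_pph == 0.0

    def test_empty_stratum_flagged_as_nan(self):
        params = GeneratorParams(n_deliveries=1_000, p_cdk=0.0, seed=4)
        est = recover_parameters(generate_cohort(params))
        assert math.isnan(est.p_use_given_cdk)
        assert math.isnan(est.p_pph_user)

    def test_recovered_params_feed_cohort_model(self):
        """Round trip: estimates evaluated through the tree reproduce the
        cohort's realised PPH deaths within binomial noise."""
        cohort = generate_cohort(GeneratorParams(n_deliveries=100_000, seed=12))
        est = recover_parameters(cohort)
        point = lambda v: TriangleSpec(v * 100, v * 100, v * 100)
        scen = Scenario("rt", point(est.p_cdk), point(est.p_use_given_cdk),
                        cohort_size=len(cohort))
        a = AssumptionSet(point(est.p_pph_user), point(est.p_die_given_pph),
                          point(est.p_pph_nonuser), point(est.p_die_given_pph))
        expected = analytic_mean_deaths(scen, a)
        observed = int((cohort["cause_of_death"] == "pph").sum())
        assert abs(observed - expected) < 4 * math.sqrt(max(observed, 1)) + 1
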